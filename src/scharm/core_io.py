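"""Data model for connectomes and cohorts, edge indexing, and file I/O.

A structural connectome is a symmetric, zero-diagonal matrix of
non-negative integer fiber counts over the regions of a parcellation.
Each connectome is annotated with the acquisition setting it was derived
from: spatial resolution ``res`` in mm (cube root of the voxel volume)
and maximal b-value ``bval`` in s/mm^2.

On-disk formats
---------------
* Connectome matrix: tab-delimited text; first row and first column carry
  region labels; cell (i, j) is an integer fiber count.
* Cohort manifest: CSV with header ``subject_id,session,res_mm,bval,path``;
  ``path`` is resolved relative to the manifest's directory.

Edge ordering is canonical throughout the package: row-major over the
strict upper triangle (all pairs (i, j) with i < j).  Every module that
vectorizes a connectome uses this one ordering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from scharm.errors import DimensionError, FormatError

__all__ = [
    "Parcellation",
    "AcquisitionSetting",
    "Connectome",
    "EdgeIndex",
    "Cohort",
    "upper_triangle_index",
    "vectorize",
    "devectorize",
    "read_connectome",
    "write_connectome",
    "read_manifest",
    "write_manifest",
]


@dataclass(frozen=True)
class Parcellation:
    """An ordered set of uniquely labeled gray-matter regions."""

    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.region_labels)
        object.__setattr__(self, "region_labels", labels)
        if len(set(labels)) != len(labels):
            raise FormatError("region labels must be unique")
        if len(labels) < 2:
            raise FormatError("a parcellation needs at least 2 regions")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @classmethod
    def generic(cls, n_regions: int, prefix: str = "R") -> "Parcellation":
        """Auto-labeled parcellation R001..Rn (width adapts to n)."""
        width = max(3, len(str(n_regions)))
        return cls(tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n_regions)))


@dataclass(frozen=True)
class AcquisitionSetting:
    """A (res, bval) pair: spatial resolution in mm and b-value in s/mm^2.

    ``res`` is the cube root of the voxel volume, so anisotropic voxels
    reduce to a single scalar.  Equality is exact numeric equality on both
    fields — settings are experiment keys, not measurements.
    """

    res: float
    bval: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "res", float(self.res))
        object.__setattr__(self, "bval", float(self.bval))
        if not (self.res > 0 and np.isfinite(self.res)):
            raise FormatError(f"res must be a positive finite number, got {self.res}")
        if not (self.bval > 0 and np.isfinite(self.bval)):
            raise FormatError(f"bval must be a positive finite number, got {self.bval}")

    def __str__(self) -> str:  # e.g. "(1.25 mm, 3000 s/mm2)"
        return f"({self.res:g} mm, {self.bval:g} s/mm2)"


def _validate_matrix(matrix: np.ndarray, n_regions: int, source: str = "matrix") -> np.ndarray:
    """Validate and coerce a connectivity matrix to int64.

    Raises :class:`FormatError` naming the first offending cell.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"{source}: expected a square matrix, got shape {m.shape}")
    if m.shape[0] != n_regions:
        raise DimensionError(
            f"{source}: matrix has {m.shape[0]} regions, parcellation has {n_regions}"
        )
    if np.issubdtype(m.dtype, np.floating):
        if not np.all(np.isfinite(m)):
            i, j = np.argwhere(~np.isfinite(m))[0]
            raise FormatError(f"{source}: non-finite entry at cell ({i}, {j})")
        rounded = np.rint(m)
        if not np.array_equal(rounded, m):
            i, j = np.argwhere(rounded != m)[0]
            raise FormatError(f"{source}: non-integer entry {m[i, j]} at cell ({i}, {j})")
        m = rounded
    m = m.astype(np.int64)
    neg = np.argwhere(m < 0)
    if neg.size:
        i, j = neg[0]
        raise FormatError(f"{source}: negative entry {m[i, j]} at cell ({i}, {j})")
    asym = np.argwhere(m != m.T)
    if asym.size:
        i, j = asym[0]
        raise FormatError(
            f"{source}: asymmetric at cell ({i}, {j}): {m[i, j]} != {m[j, i]}"
        )
    diag = np.argwhere(np.diag(m) != 0)
    if diag.size:
        i = int(diag[0][0])
        raise FormatError(f"{source}: nonzero diagonal entry {m[i, i]} at cell ({i}, {i})")
    return m


@dataclass(frozen=True)
class Connectome:
    """A structural connectome: fiber counts plus subject/acquisition metadata.

    Invariants enforced at construction: the matrix is square, symmetric,
    non-negative integer, with a zero diagonal, and its size matches the
    parcellation.
    """

    matrix: np.ndarray
    subject_id: str
    setting: AcquisitionSetting
    parcellation: Parcellation
    session: str = "1"

    def __post_init__(self) -> None:
        m = _validate_matrix(self.matrix, self.parcellation.n_regions,
                             source=f"connectome {self.subject_id!r}")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "subject_id", str(self.subject_id))
        object.__setattr__(self, "session", str(self.session))

    @property
    def n_regions(self) -> int:
        return self.parcellation.n_regions

    @property
    def key(self) -> tuple[str, str, AcquisitionSetting]:
        return (self.subject_id, self.session, self.setting)

    def with_matrix(self, matrix: np.ndarray, setting: AcquisitionSetting | None = None) -> "Connectome":
        """Copy with a new matrix (and optionally a new setting)."""
        return Connectome(
            matrix=matrix,
            subject_id=self.subject_id,
            session=self.session,
            setting=self.setting if setting is None else setting,
            parcellation=self.parcellation,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Connectome):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.session == other.session
            and self.setting == other.setting
            and self.parcellation == other.parcellation
            and np.array_equal(self.matrix, other.matrix)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical mapping between the strict upper triangle and a flat vector.

    Pair ordering is row-major: (0,1), (0,2), ..., (0,n-1), (1,2), ...
    """

    n_regions: int
    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)

    @property
    def n_edges(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.rows.tolist(), self.cols.tolist()))


def upper_triangle_index(n_regions: int) -> EdgeIndex:
    """Build the canonical edge index for ``n_regions`` regions.

    >>> upper_triangle_index(274).n_edges
    37401
    """
    if n_regions < 2:
        raise FormatError(f"need at least 2 regions to define edges, got {n_regions}")
    rows, cols = np.triu_indices(n_regions, k=1)
    rows.setflags(write=False)
    cols.setflags(write=False)
    return EdgeIndex(n_regions=int(n_regions), rows=rows, cols=cols)


def vectorize(connectome: Connectome | np.ndarray, index: EdgeIndex) -> np.ndarray:
    """Extract the strict upper triangle as a flat vector of length n_edges."""
    m = connectome.matrix if isinstance(connectome, Connectome) else np.asarray(connectome)
    if m.shape[0] != index.n_regions:
        raise DimensionError(
            f"connectome has {m.shape[0]} regions but edge index expects {index.n_regions}"
        )
    return m[index.rows, index.cols]


def devectorize(vector: np.ndarray, index: EdgeIndex) -> np.ndarray:
    """Rebuild the full symmetric zero-diagonal matrix from an edge vector."""
    v = np.asarray(vector)
    if v.shape != (index.n_edges,):
        raise DimensionError(f"expected vector of length {index.n_edges}, got shape {v.shape}")
    m = np.zeros((index.n_regions, index.n_regions), dtype=v.dtype)
    m[index.rows, index.cols] = v
    m[index.cols, index.rows] = v
    return m


# ---------------------------------------------------------------------------
# Connectome matrix files (TSV with region labels)
# ---------------------------------------------------------------------------

def write_connectome(connectome: Connectome, path: str | Path) -> None:
    """Write a connectome matrix as labeled TSV (lossless for counts)."""
    path = Path(path)
    labels = connectome.parcellation.region_labels
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(("region",) + labels) + "\n")
        for label, row in zip(labels, connectome.matrix):
            fh.write(label + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


def read_connectome(
    path: str | Path,
    subject_id: str = "",
    session: str = "1",
    setting: AcquisitionSetting | None = None,
    parcellation: Parcellation | None = None,
) -> Connectome:
    """Read a labeled TSV connectome matrix.

    Metadata (subject, session, setting) comes from the caller — typically
    a manifest row.  If ``parcellation`` is given, the file's labels must
    match it exactly.
    """
    path = Path(path)
    if setting is None:
        raise FormatError(f"{path}: an acquisition setting is required to build a connectome")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        labels = tuple(header[1:])
        n = len(labels)
        if n < 2:
            raise FormatError(f"{path}: fewer than 2 regions in header")
        matrix = np.zeros((n, n), dtype=np.int64)
        row_labels: list[str] = []
        for r, row in enumerate(reader):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != n + 1:
                raise FormatError(
                    f"{path}: row {r + 2} has {len(row)} fields, expected {n + 1}"
                )
            row_labels.append(row[0])
            for c, cell in enumerate(row[1:]):
                try:
                    matrix[r, c] = int(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-integer entry {cell!r} at cell ({r}, {c})"
                    ) from None
    if len(row_labels) != n:
        raise FormatError(f"{path}: {len(row_labels)} rows for {n} columns (not square)")
    if tuple(row_labels) != labels:
        raise FormatError(f"{path}: row labels do not match column labels")
    parc = Parcellation(labels)
    if parcellation is not None and parcellation != parc:
        raise FormatError(f"{path}: region labels do not match the expected parcellation")
    try:
        return Connectome(matrix=matrix, subject_id=subject_id, session=session,
                          setting=setting, parcellation=parc)
    except (FormatError, DimensionError) as exc:
        raise FormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Cohorts and manifests
# ---------------------------------------------------------------------------

class Cohort:
    """A collection of connectomes sharing one parcellation.

    Indexed by (subject_id, session, setting); duplicate keys are rejected.
    Iteration order is insertion order, which makes downstream analyses
    reproducible from the manifest row order.
    """

    def __init__(self, connectomes: Iterable[Connectome] = ()):
        self._items: list[Connectome] = []
        self._index: dict[tuple[str, str, AcquisitionSetting], Connectome] = {}
        self.parcellation: Parcellation | None = None
        for c in connectomes:
            self.add(c)

    def add(self, connectome: Connectome) -> None:
        if self.parcellation is None:
            self.parcellation = connectome.parcellation
        elif connectome.parcellation != self.parcellation:
            raise FormatError(
                f"mixed parcellations in cohort: connectome {connectome.subject_id!r} "
                f"has {connectome.n_regions} regions or different labels"
            )
        key = connectome.key
        if key in self._index:
            raise FormatError(
                f"duplicate cohort key: subject={key[0]!r} session={key[1]!r} setting={key[2]}"
            )
        self._items.append(connectome)
        self._index[key] = connectome

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[Connectome]:
        return iter(self._items)

    def __getitem__(self, key: tuple[str, str, AcquisitionSetting]) -> Connectome:
        return self._index[key]

    def get(self, subject_id: str, session: str, setting: AcquisitionSetting) -> Connectome | None:
        return self._index.get((subject_id, session, setting))

    @property
    def subjects(self) -> list[str]:
        """Unique subject ids in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self._items:
            seen.setdefault(c.subject_id, None)
        return list(seen)

    @property
    def settings(self) -> list[AcquisitionSetting]:
        """Unique settings in first-appearance order."""
        seen: dict[AcquisitionSetting, None] = {}
        for c in self._items:
            seen.setdefault(c.setting, None)
        return list(seen)

    def subset(self, setting: AcquisitionSetting | None = None,
               subjects: Sequence[str] | None = None) -> "Cohort":
        keep = set(subjects) if subjects is not None else None
        return Cohort(
            c for c in self._items
            if (setting is None or c.setting == setting)
            and (keep is None or c.subject_id in keep)
        )


def read_manifest(path: str | Path) -> Cohort:
    """Load a cohort from a manifest CSV.

    Columns: ``subject_id, session, res_mm, bval, path``; the session
    column may be blank (defaults to "1"); matrix paths are resolved
    relative to the manifest location.
    """
    path = Path(path)
    base = path.parent
    required = {"subject_id", "res_mm", "bval", "path"}
    cohort = Cohort()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or ()))
            raise FormatError(f"{path}: manifest missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                setting = AcquisitionSetting(res=float(row["res_mm"]), bval=float(row["bval"]))
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: line {lineno}: bad setting ({exc})") from None
            session = (row.get("session") or "1").strip() or "1"
            mpath = base / row["path"]
            if not mpath.exists():
                raise FormatError(f"{path}: line {lineno}: matrix file not found: {mpath}")
            conn = read_connectome(mpath, subject_id=row["subject_id"],
                                   session=session, setting=setting)
            cohort.add(conn)
    if len(cohort) == 0:
        raise FormatError(f"{path}: manifest contains no rows")
    return cohort


def write_manifest(cohort: Cohort, out_dir: str | Path,
                   manifest_name: str = "manifest.csv") -> Path:
    """Write a cohort as matrix files plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / manifest_name
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "session", "res_mm", "bval", "path"])
        for c in cohort:
            fname = (
                f"sub-{c.subject_id}_ses-{c.session}_res-{c.setting.res:g}"
                f"_bval-{c.setting.bval:g}.tsv"
            )
            write_connectome(c, out_dir / fname)
            writer.writerow([c.subject_id, c.session, repr(c.setting.res),
                             repr(c.setting.bval), fname])
    return manifest_path
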