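"""Per-edge linear harmonization of connectomes across acquisition settings.

Each connection y of a structural connectome is modeled as a linear
function of the acquisition parameters

    y = b0 + b1 * X_r + b2 * X_b + b3 * X_r * X_b + noise,

where X_r is the spatial resolution (mm) and X_b the b-value (s/mm^2).
The four coefficients are estimated per edge by ordinary least squares
on a training cohort whose settings span a full-rank design; subject
identity is deliberately not a covariate, so the fitted model transfers
to subjects it has never seen.

A scan acquired at setting AP1 is harmonized to setting AP2 by adding
the model-implied shift

    y_AP2 = y_AP1 + b1 * (Xr2 - Xr1) + b2 * (Xb2 - Xb1)
                  + b3 * (Xr2*Xb2 - Xr1*Xb1),

after which values are rounded to the nearest integer
(half-away-from-zero) and negatives clamped to zero, in that order —
fiber counts are non-negative integers.  The intercept cancels, so
between-subject differences carried by b0 are untouched.

Covariates enter in raw physical units; because the correction depends
only on the span of {1, X_r, X_b, X_r*X_b}, predictions are invariant
to any affine rescaling of the covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import warnings

import numpy as np

from scharm.core_io import (
    AcquisitionSetting,
    Cohort,
    Connectome,
    EdgeIndex,
    devectorize,
    upper_triangle_index,
    vectorize,
)
from scharm.errors import DesignError, DimensionError, FormatError

__all__ = [
    "HarmonizationModel",
    "build_design",
    "fit",
    "fit_edges",
    "harmonize",
    "save_model",
    "load_model",
    "round_half_away",
    "ExtrapolationWarning",
]

MODEL_FORMAT_VERSION = 1


class ExtrapolationWarning(UserWarning):
    """Harmonization target lies outside the hull of the training settings."""


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties away from zero.

    numpy's ``rint`` rounds half to even; "rounded off" semantics put
    2.5 at 3 and -2.5 at -3.
    """
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def build_design(settings: list[AcquisitionSetting]) -> tuple[np.ndarray, int]:
    """Design matrix [1, X_r, X_b, X_r*X_b] and its numerical rank."""
    if not settings:
        raise DesignError("cannot build a design from an empty setting list")
    xr = np.array([s.res for s in settings], dtype=float)
    xb = np.array([s.bval for s in settings], dtype=float)
    design = np.column_stack([np.ones_like(xr), xr, xb, xr * xb])
    rank = int(np.linalg.matrix_rank(design))
    return design, rank


@dataclass
class HarmonizationModel:
    """Fitted per-edge coefficients plus fit metadata.

    ``betas`` has shape (n_edges, 4) ordered [b0, b1, b2, b3] with edges
    in the canonical upper-triangle order of ``edge_index``.
    """

    edge_index: EdgeIndex
    region_labels: tuple[str, ...]
    betas: np.ndarray
    training_settings: list[tuple[AcquisitionSetting, int]]
    n_observations: int
    design_rank: int
    residual_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, dtype=float)
        if betas.shape != (self.edge_index.n_edges, 4):
            raise DimensionError(
                f"betas shape {betas.shape} does not match "
                f"({self.edge_index.n_edges}, 4)"
            )
        if not np.all(np.isfinite(betas)):
            raise FormatError("model betas contain non-finite values")
        self.betas = betas

    def _hull(self) -> tuple[float, float, float, float]:
        res = [s.res for s, _ in self.training_settings]
        bval = [s.bval for s, _ in self.training_settings]
        return min(res), max(res), min(bval), max(bval)

    def in_training_hull(self, setting: AcquisitionSetting) -> bool:
        rmin, rmax, bmin, bmax = self._hull()
        return rmin <= setting.res <= rmax and bmin <= setting.bval <= bmax

    def correction(self, source: AcquisitionSetting,
                   target: AcquisitionSetting) -> np.ndarray:
        """Per-edge additive shift from ``source`` to ``target`` (continuous)."""
        d_r = target.res - source.res
        d_b = target.bval - source.bval
        d_rb = target.res * target.bval - source.res * source.bval
        return (self.betas[:, 1] * d_r + self.betas[:, 2] * d_b
                + self.betas[:, 3] * d_rb)


def fit_edges(settings: list[AcquisitionSetting], edge_values: np.ndarray,
              region_labels: tuple[str, ...]) -> HarmonizationModel:
    """OLS fit on pre-vectorized edge observations.

    ``edge_values`` has shape (n_observations, n_edges) in canonical edge
    order; rows pair with ``settings``.  The shared design is factorized
    once and solved against all edge columns simultaneously.  Accepts
    continuous (pre-rounding) values, which is how exact-recovery
    diagnostics bypass integer observation.
    """
    edge_values = np.asarray(edge_values, dtype=float)
    if len(settings) != edge_values.shape[0]:
        raise DimensionError(
            f"{len(settings)} settings for {edge_values.shape[0]} observation rows"
        )
    if len(settings) < 4:
        raise DesignError(
            f"need at least 4 observations to fit 4 coefficients, got {len(settings)}"
        )
    design, rank = build_design(settings)
    if rank < 4:
        distinct = sorted({(s.res, s.bval) for s in settings})
        raise DesignError(
            f"rank-deficient design (rank {rank} < 4); distinct settings "
            f"observed: {distinct}. The settings must vary in res, bval, "
            "and their product."
        )
    index = upper_triangle_index(len(region_labels))
    if edge_values.shape[1] != index.n_edges:
        raise DimensionError(
            f"{edge_values.shape[1]} edge columns for {len(region_labels)} regions; "
            f"expected {index.n_edges}"
        )
    betas, _, _, _ = np.linalg.lstsq(design, edge_values, rcond=None)
    residuals = edge_values - design @ betas
    dof = max(edge_values.shape[0] - 4, 1)
    resid_var = (residuals ** 2).sum(axis=0) / dof

    counts: dict[AcquisitionSetting, int] = {}
    for s in settings:
        counts[s] = counts.get(s, 0) + 1
    return HarmonizationModel(
        edge_index=index,
        region_labels=tuple(region_labels),
        betas=betas.T,
        training_settings=sorted(counts.items(), key=lambda kv: (kv[0].res, kv[0].bval)),
        n_observations=edge_values.shape[0],
        design_rank=rank,
        residual_variance=resid_var,
    )


def fit(cohort: Cohort) -> HarmonizationModel:
    """Ordinary least squares fit of the acquisition model on a cohort.

    Every connectome contributes one observation per edge.  The design
    over the observed settings must have rank 4, otherwise the
    coefficients are unidentifiable and a :class:`DesignError` names the
    distinct settings seen.  Subject identity is not a covariate:
    subject-specific offsets average into the intercept.
    """
    connectomes = list(cohort)
    if not connectomes:
        raise DesignError("cannot fit on an empty cohort")
    index = upper_triangle_index(cohort.parcellation.n_regions)
    y = np.stack([vectorize(c, index) for c in connectomes]).astype(float)
    return fit_edges([c.setting for c in connectomes], y,
                     cohort.parcellation.region_labels)


def harmonize(connectome: Connectome, model: HarmonizationModel,
              target: AcquisitionSetting, integer_output: bool = True
              ) -> Connectome:
    """Shift a connectome from its own setting to ``target``.

    Order of operations: additive correction, round half-away-from-zero,
    clamp negatives to zero.  ``integer_output=False`` is a continuous
    diagnostics mode: rounding and clamping are skipped and the corrected
    matrix is returned as a plain float ndarray (a :class:`Connectome`
    cannot hold non-integer counts).
    """
    if connectome.parcellation.region_labels != model.region_labels:
        raise DimensionError(
            "connectome parcellation does not match the model's region labels"
        )
    if not model.in_training_hull(target):
        warnings.warn(
            f"target setting {target} lies outside the training hull "
            f"{model._hull()}; harmonization extrapolates",
            ExtrapolationWarning,
            stacklevel=2,
        )
    shift = model.correction(connectome.setting, target)
    if not np.all(np.isfinite(shift)):
        raise FormatError("non-finite harmonization correction")
    y = vectorize(connectome, model.edge_index).astype(float) + shift
    if not integer_output:
        return devectorize(y, model.edge_index)
    y = np.maximum(round_half_away(y), 0.0).astype(np.int64)
    return connectome.with_matrix(devectorize(y, model.edge_index), setting=target)


# ---------------------------------------------------------------------------
# Persistence: TSV with '#' metadata header
# ---------------------------------------------------------------------------

def save_model(model: HarmonizationModel, path: str | Path) -> None:
    """Serialize a model to TSV with full-precision coefficients."""
    path = Path(path)
    labels = model.region_labels
    with open(path, "w") as fh:
        fh.write(f"# scharm_model_version: {MODEL_FORMAT_VERSION}\n")
        fh.write(f"# n_regions: {model.edge_index.n_regions}\n")
        fh.write(f"# n_observations: {model.n_observations}\n")
        fh.write(f"# design_rank: {model.design_rank}\n")
        fh.write("# rounding: half-away-from-zero\n")
        for s, count in model.training_settings:
            fh.write(f"# training_setting: res={s.res!r} bval={s.bval!r} count={count}\n")
        fh.write("# region_labels: " + "\t".join(labels) + "\n")
        fh.write("region_i\tregion_j\tbeta0\tbeta1\tbeta2\tbeta3\n")
        idx = model.edge_index
        for e, (i, j) in enumerate(zip(idx.rows, idx.cols)):
            b0, b1, b2, b3 = (float(x) for x in model.betas[e])
            fh.write(
                f"{labels[i]}\t{labels[j]}\t{b0!r}\t{b1!r}\t{b2!r}\t{b3!r}\n"
            )


def load_model(path: str | Path) -> HarmonizationModel:
    """Load a model saved by :func:`save_model` (bit-exact coefficients)."""
    path = Path(path)
    meta: dict[str, str] = {}
    training: list[tuple[AcquisitionSetting, int]] = []
    labels: tuple[str, ...] | None = None
    rows: list[tuple[str, str, float, float, float, float]] = []
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# "):
                key, _, value = line[2:].partition(": ")
                if key == "training_setting":
                    parts = dict(kv.split("=") for kv in value.split())
                    training.append((
                        AcquisitionSetting(res=float(parts["res"]),
                                           bval=float(parts["bval"])),
                        int(parts["count"]),
                    ))
                elif key == "region_labels":
                    labels = tuple(value.split("\t"))
                else:
                    meta[key] = value
                continue
            fields = line.split("\t")
            if not header_seen:
                expected = ["region_i", "region_j", "beta0", "beta1", "beta2", "beta3"]
                if fields != expected:
                    raise FormatError(
                        f"{path}: bad model header {fields}; expected {expected}"
                    )
                header_seen = True
                continue
            if len(fields) != 6:
                raise FormatError(f"{path}: model row has {len(fields)} fields, expected 6")
            rows.append((fields[0], fields[1], float(fields[2]), float(fields[3]),
                         float(fields[4]), float(fields[5])))
    if meta.get("scharm_model_version") != str(MODEL_FORMAT_VERSION):
        raise FormatError(
            f"{path}: unsupported model version {meta.get('scharm_model_version')!r}"
        )
    if labels is None:
        raise FormatError(f"{path}: missing region_labels metadata")
    n_regions = int(meta["n_regions"])
    index = upper_triangle_index(n_regions)
    if len(rows) != index.n_edges:
        raise FormatError(
            f"{path}: {len(rows)} edge rows for {n_regions} regions; expected "
            f"{index.n_edges}"
        )
    betas = np.array([r[2:] for r in rows], dtype=float)
    return HarmonizationModel(
        edge_index=index,
        region_labels=labels,
        betas=betas,
        training_settings=training,
        n_observations=int(meta.get("n_observations", 0)),
        design_rank=int(meta.get("design_rank", 4)),
    )
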