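"""Mass-univariate two-way ANOVA for acquisition-parameter effects.

Each edge (or each node, for a nodal metric) is analyzed independently
with a fixed-effects 2x2 factorial ANOVA: factor A is the b-value level,
factor B is the spatial-resolution level, plus their interaction.  All
subjects observed in a cell are treated as independent replicates; the
design must be balanced, which makes Type I/II/III sums of squares
coincide.

Multiplicity is controlled by Bonferroni: the corrected p-value is
min(1, p * m) where m is the number of edges (37,401 for a 274-region
parcellation) or nodes; a unit is significant when the raw p is strictly
below 0.05/m.  Significance maps report -log10 of the corrected p.

Degenerate units — zero within-cell variance — follow an explicit
convention: if the effect sum of squares is also zero the unit is
reported as F = 0, p = 1 (no evidence); if the effect is nonzero against
zero residual variance, F = inf, p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from scharm.core_io import AcquisitionSetting, Cohort, upper_triangle_index, vectorize
from scharm.errors import DesignError
from scharm.graph_metrics import METRIC_NAMES

__all__ = [
    "AnovaResult",
    "two_way_anova_2x2",
    "edgewise_anova",
    "nodal_anova",
    "format_percentage",
    "ALPHA",
]

ALPHA = 0.05

FACTORS = ("bval", "res", "interaction")


@dataclass
class AnovaResult:
    """Per-unit F/p/corrected-p tables for the three factorial effects.

    ``unit_ids`` are edge pairs (label tuples) or node labels; ``m`` is
    the Bonferroni multiplicity.  ``degenerate`` flags units whose total
    variance was zero.
    """

    unit_ids: list
    m: int
    F: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.unit_ids), dtype=bool)

    @property
    def corrected_p(self) -> dict[str, np.ndarray]:
        return {f: np.minimum(1.0, self.p[f] * self.m) for f in FACTORS}

    @property
    def significant(self) -> dict[str, np.ndarray]:
        # strict inequality: "less than alpha / m"
        return {f: self.p[f] < ALPHA / self.m for f in FACTORS}

    @property
    def neglog(self) -> dict[str, np.ndarray]:
        out = {}
        for f, cp in self.corrected_p.items():
            with np.errstate(divide="ignore"):
                out[f] = np.where(cp >= 1.0, 0.0, -np.log10(np.maximum(cp, 0.0)))
        return out

    def summary(self) -> pd.DataFrame:
        """Counts and percentages of significant units per factor."""
        sig = self.significant
        rows = []
        for f in FACTORS:
            count = int(sig[f].sum())
            rows.append({
                "factor": f,
                "n_significant": count,
                "m": self.m,
                "percent": format_percentage(count, self.m),
            })
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        cp = self.corrected_p
        sig = self.significant
        nl = self.neglog
        data: dict[str, object] = {"unit": [str(u) for u in self.unit_ids]}
        for f in FACTORS:
            data[f"F_{f}"] = self.F[f]
            data[f"p_{f}"] = self.p[f]
            data[f"corrected_p_{f}"] = cp[f]
            data[f"significant_{f}"] = sig[f]
            data[f"neglog_{f}"] = nl[f]
        data["degenerate"] = self.degenerate
        return pd.DataFrame(data)


def format_percentage(count: int, m: int) -> str:
    """Percentage of significant units: nearest integer, two decimals below 1%."""
    pct = 100.0 * count / m
    if pct == 0:
        return "0"
    if pct < 1:
        return f"{pct:.2f}"
    return str(int(round(pct)))


def _balanced_2x2(values: np.ndarray, a_codes: np.ndarray, b_codes: np.ndarray):
    """Vectorized balanced 2x2 factorial decomposition.

    ``values``: (n_obs, n_units); ``a_codes``/``b_codes``: 0/1 per
    observation.  Returns (F, p, degenerate) with F and p keyed by
    factor; uses the degenerate-variance convention described in the
    module docstring.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    a_codes = np.asarray(a_codes)
    b_codes = np.asarray(b_codes)
    cells = {}
    for a in (0, 1):
        for b in (0, 1):
            mask = (a_codes == a) & (b_codes == b)
            cells[(a, b)] = values[mask]
    sizes = {k: v.shape[0] for k, v in cells.items()}
    s = sizes[(0, 0)]
    if len(set(sizes.values())) != 1:
        raise DesignError(f"unbalanced 2x2 design: cell sizes {sizes}")
    if s < 2:
        raise DesignError(f"need at least 2 observations per cell, got {s}")

    cell_means = {k: v.mean(axis=0) for k, v in cells.items()}
    grand = values.mean(axis=0)
    a_means = {a: (cell_means[(a, 0)] + cell_means[(a, 1)]) / 2 for a in (0, 1)}
    b_means = {b: (cell_means[(0, b)] + cell_means[(1, b)]) / 2 for b in (0, 1)}

    ss_a = 2 * s * sum((a_means[a] - grand) ** 2 for a in (0, 1))
    ss_b = 2 * s * sum((b_means[b] - grand) ** 2 for b in (0, 1))
    ss_ab = s * sum(
        (cell_means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
        for a in (0, 1) for b in (0, 1)
    )
    ss_within = sum(((cells[k] - cell_means[k][None, :]) ** 2).sum(axis=0) for k in cells)
    ss_total = ((values - grand[None, :]) ** 2).sum(axis=0)

    df_within = 4 * (s - 1)
    ms_within = ss_within / df_within
    # numerical floor: integer inputs can leave ~1e-25 float dust
    zero_within = ms_within <= 1e-12 * np.maximum(ss_total, 1.0)
    degenerate = ss_total == 0.0

    F: dict[str, np.ndarray] = {}
    p: dict[str, np.ndarray] = {}
    for name, ss in (("bval", ss_a), ("res", ss_b), ("interaction", ss_ab)):
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = np.where(zero_within, 0.0, ss / np.where(zero_within, 1.0, ms_within))
        effect_nonzero = ss > 1e-12 * np.maximum(ss_total, 1.0)
        f_stat = np.where(zero_within & effect_nonzero, np.inf, f_stat)
        p_val = stats.f.sf(f_stat, 1, df_within)
        p_val = np.where(zero_within & ~effect_nonzero, 1.0, p_val)
        p_val = np.where(zero_within & effect_nonzero, 0.0, p_val)
        F[name] = f_stat
        p[name] = p_val
    return F, p, degenerate


def two_way_anova_2x2(values, a_levels, b_levels):
    """Two-way fixed-effects ANOVA for one response on a balanced 2x2 grid.

    ``values`` are the observations; ``a_levels``/``b_levels`` give each
    observation's factor level (two distinct values per factor).  Returns
    a dict keyed by 'bval' (factor A), 'res' (factor B), 'interaction',
    each mapping to an (F, p) tuple.
    """
    values = np.asarray(values, dtype=float)
    a_levels = np.asarray(a_levels)
    b_levels = np.asarray(b_levels)
    ua, ub = np.unique(a_levels), np.unique(b_levels)
    if ua.size != 2 or ub.size != 2:
        raise DesignError(
            f"each factor needs exactly two levels, got {ua.size} and {ub.size}"
        )
    a_codes = (a_levels == ua[1]).astype(int)
    b_codes = (b_levels == ub[1]).astype(int)
    F, p, _ = _balanced_2x2(values[:, None], a_codes, b_codes)
    return {f: (float(F[f][0]), float(p[f][0])) for f in FACTORS}


def _grid_codes(settings: list[AcquisitionSetting]):
    """Check that settings form a 2x2 (res x bval) grid; return level codes."""
    res_levels = sorted({s.res for s in settings})
    bval_levels = sorted({s.bval for s in settings})
    if len(res_levels) != 2 or len(bval_levels) != 2:
        raise DesignError(
            f"settings must form a 2x2 grid; got res levels {res_levels}, "
            f"bval levels {bval_levels}"
        )
    expected = {(r, b) for r in res_levels for b in bval_levels}
    observed = {(s.res, s.bval) for s in settings}
    if observed != expected:
        raise DesignError(
            f"settings do not cover the full 2x2 grid: missing "
            f"{sorted(expected - observed)}"
        )
    return bval_levels, res_levels


def edgewise_anova(cohort: Cohort) -> AnovaResult:
    """Per-edge two-way ANOVA over a cohort observed on a 2x2 setting grid.

    Multiplicity m equals the number of possible connections
    (n_regions choose 2).  Edges with zero variance across all
    observations are flagged degenerate and reported non-significant.
    """
    settings = cohort.settings
    bval_levels, res_levels = _grid_codes(settings)
    index = upper_triangle_index(cohort.parcellation.n_regions)
    values = np.stack([vectorize(c, index) for c in cohort]).astype(float)
    a_codes = np.array([int(c.setting.bval == bval_levels[1]) for c in cohort])
    b_codes = np.array([int(c.setting.res == res_levels[1]) for c in cohort])
    F, p, degenerate = _balanced_2x2(values, a_codes, b_codes)
    labels = cohort.parcellation.region_labels
    unit_ids = [(labels[i], labels[j]) for i, j in zip(index.rows, index.cols)]
    return AnovaResult(unit_ids=unit_ids, m=index.n_edges, F=F, p=p,
                       degenerate=degenerate)


def nodal_anova(metric_table: pd.DataFrame, metric_name: str) -> AnovaResult:
    """Per-node two-way ANOVA on one nodal metric.

    ``metric_table`` is the long-format output of
    :func:`scharm.graph_metrics.cohort_metric_table`; multiplicity m is
    the number of nodes.
    """
    if metric_name not in METRIC_NAMES:
        raise DesignError(
            f"unknown metric {metric_name!r}; expected one of {METRIC_NAMES}"
        )
    wide = metric_table.pivot_table(
        index=["subject_id", "session", "res_mm", "bval"],
        columns="node_label", values=metric_name, sort=False,
    )
    node_labels = list(wide.columns)
    idx = wide.index.to_frame(index=False)
    settings = [AcquisitionSetting(res=r, bval=b)
                for r, b in zip(idx["res_mm"], idx["bval"])]
    bval_levels, res_levels = _grid_codes(settings)
    a_codes = np.array([int(s.bval == bval_levels[1]) for s in settings])
    b_codes = np.array([int(s.res == res_levels[1]) for s in settings])
    F, p, degenerate = _balanced_2x2(wide.to_numpy(), a_codes, b_codes)
    return AnovaResult(unit_ids=node_labels, m=len(node_labels), F=F, p=p,
                       degenerate=degenerate)
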