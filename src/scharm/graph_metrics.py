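"""Weighted nodal graph metrics for structural connectomes.

Four metrics are computed on the weighted, undirected fiber-count graph:

* nodal strength        k_i = sum_j w_ij                       (integration)
* closeness centrality  (reachable count) / (sum of shortest
  path distances), with edge lengths l_ij = 1/w_ij             (integration)
* clustering coefficient, weighted geometric-mean triangle
  form: C_i = 1/(k_i(k_i-1)) * sum_{j!=h} (w_ij w_ih w_jh)^{1/3}  (segregation)
* local efficiency: like clustering but the triangle-closing
  weight is replaced by the inverse shortest distance between
  the two neighbors inside the subgraph induced by node i's
  neighbors (node i removed)                                   (segregation)

The formulas are applied literally to the raw fiber counts.  Standard
toolkits rescale weights by the graph maximum before taking cube roots,
which bounds clustering by 1; here the default keeps raw counts (so
values can exceed 1) and ``normalize=True`` opts into max-weight
rescaling for cross-checking.

Conventions: a zero weight means *no edge* (not a zero-length edge);
nodes with degree < 2 have clustering and local efficiency 0; an
unreachable neighbor pair contributes 0 to local efficiency (1/inf = 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from scharm.core_io import Cohort, Connectome

__all__ = [
    "nodal_strength",
    "length_matrix",
    "shortest_paths",
    "closeness_centrality",
    "clustering_coefficient",
    "local_efficiency",
    "nodal_metrics",
    "cohort_metric_table",
    "METRIC_NAMES",
]

METRIC_NAMES = ("strength", "closeness", "clustering", "local_efficiency")


def _weights(connectome: Connectome | np.ndarray) -> np.ndarray:
    w = connectome.matrix if isinstance(connectome, Connectome) else np.asarray(connectome)
    return w.astype(float)


def nodal_strength(connectome: Connectome | np.ndarray) -> np.ndarray:
    """Sum of each node's connection weights."""
    return _weights(connectome).sum(axis=1)


def length_matrix(connectome: Connectome | np.ndarray) -> np.ndarray:
    """Edge lengths l_ij = 1/w_ij; ``inf`` marks absent edges; zero diagonal."""
    w = _weights(connectome)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_paths(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances on a length matrix (inf = unreachable)."""
    lengths = np.asarray(lengths, dtype=float)
    finite = np.where(np.isfinite(lengths), lengths, 0.0)
    graph = csr_array(finite)
    return dijkstra(graph, directed=False)


def closeness_centrality(connectome: Connectome | np.ndarray) -> np.ndarray:
    """Reachable-node count over summed shortest-path distances, per node.

    The numerator counts nodes actually reachable from i (excluding i);
    an isolated node gets 0.
    """
    d = shortest_paths(length_matrix(connectome))
    n = d.shape[0]
    reachable = np.isfinite(d) & ~np.eye(n, dtype=bool)
    counts = reachable.sum(axis=1).astype(float)
    sums = np.where(reachable, d, 0.0).sum(axis=1)
    out = np.zeros(n)
    ok = sums > 0
    out[ok] = counts[ok] / sums[ok]
    return out


def clustering_coefficient(connectome: Connectome | np.ndarray,
                           normalize: bool = False) -> np.ndarray:
    """Weighted clustering via geometric-mean triangle intensities.

    Sums (w_ij * w_ih * w_jh)^(1/3) over ordered neighbor pairs (j, h),
    normalized by k_i(k_i - 1).  With ``normalize=True`` weights are
    first divided by the graph maximum (toolkit convention, bounds the
    value by 1); default applies the formula to raw counts.
    """
    w = _weights(connectome)
    if normalize and w.max() > 0:
        w = w / w.max()
    a = np.cbrt(w)
    # (a^3)_ii enumerates ordered pairs (j, h): terms with j == h or
    # touching the zero diagonal vanish.
    numer = np.einsum("ij,jh,hi->i", a, a, a)
    k = (w > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    out = np.zeros(w.shape[0])
    ok = denom > 0
    out[ok] = numer[ok] / denom[ok]
    return out


def local_efficiency(connectome: Connectome | np.ndarray,
                     normalize: bool = False) -> np.ndarray:
    """Weighted local efficiency on the neighbor-induced subgraph.

    For each node i, neighbors' pairwise shortest distances are computed
    inside the subgraph formed by i's neighbors with i removed, then
    (w_ij * w_ih / d_jh)^(1/3) is summed over ordered pairs and divided
    by k_i(k_i - 1).  Unreachable pairs contribute 0.
    """
    w = _weights(connectome)
    if normalize and w.max() > 0:
        w = w / w.max()
    n = w.shape[0]
    out = np.zeros(n)
    adj = w > 0
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        k = nb.size
        if k < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        d = shortest_paths(length_matrix(sub))
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
        wi = w[i, nb]
        terms = np.cbrt(np.outer(wi, wi) * inv_d)
        np.fill_diagonal(terms, 0.0)
        out[i] = terms.sum() / (k * (k - 1))
    return out


def nodal_metrics(connectome: Connectome | np.ndarray,
                  normalize: bool = False) -> dict[str, np.ndarray]:
    """All four nodal metrics as a name -> vector mapping."""
    return {
        "strength": nodal_strength(connectome),
        "closeness": closeness_centrality(connectome),
        "clustering": clustering_coefficient(connectome, normalize=normalize),
        "local_efficiency": local_efficiency(connectome, normalize=normalize),
    }


def cohort_metric_table(cohort: Cohort, normalize: bool = False
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node metrics for every connectome in a cohort.

    Returns ``(table, means)``: ``table`` has one row per (connectome,
    node) with columns subject_id, session, res_mm, bval, node_label and
    the four metrics; ``means`` averages each metric across nodes per
    connectome.
    """
    rows = []
    labels = cohort.parcellation.region_labels if cohort.parcellation else ()
    for c in cohort:
        metrics = nodal_metrics(c, normalize=normalize)
        frame = pd.DataFrame({
            "subject_id": c.subject_id,
            "session": c.session,
            "res_mm": c.setting.res,
            "bval": c.setting.bval,
            "node_label": list(labels),
            **{name: metrics[name] for name in METRIC_NAMES},
        })
        rows.append(frame)
    table = pd.concat(rows, ignore_index=True)
    means = (
        table.groupby(["subject_id", "session", "res_mm", "bval"], sort=False)[
            list(METRIC_NAMES)
        ]
        .mean()
        .reset_index()
    )
    return table, means
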