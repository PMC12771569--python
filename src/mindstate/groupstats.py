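"""Group-level node contrasts and Benjamini-Hochberg FDR.

The statistical engine behind the marker/connectivity topography maps:
per-node state contrasts computed as a two-stage hierarchical surrogate for a
mixed model (subject-level state means, then a paired across-subject test),
masked by BH-FDR within one contrast's node family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

#: below this many subjects the paired t-test is replaced by Wilcoxon signed-rank
WILCOXON_BELOW = 15


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: returns (q_values, mask).

    q-values are the monotone-adjusted ``p * m / rank`` (step-up cumulative
    minimum, capped at 1); the mask is ``q_value < q``.  Empty input returns
    empty arrays.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ParameterError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    return qvals, qvals < q


@dataclass
class GroupContrastMap:
    """Per-node effect/p/q/mask for one state pair."""

    pair: tuple
    nodes: list
    effect: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray
    n_subjects: int
    excluded_nodes: list
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.nodes, "effect": self.effect,
                             "p": self.p, "q": self.q, "significant": self.mask})


def _paired_test(diffs: np.ndarray):
    """Paired test on per-subject differences: t for n >= 15, else Wilcoxon
    signed-rank (falling back to t when all differences are tied at 0)."""
    n = diffs.shape[0]
    if n >= WILCOXON_BELOW:
        return stats.ttest_1samp(diffs, 0.0).pvalue
    if np.allclose(diffs, 0.0):
        return 1.0
    try:
        return stats.wilcoxon(diffs, zero_method="wilcox").pvalue
    except ValueError:
        return 1.0


def node_state_contrast(values: pd.DataFrame, pair: tuple,
                        alpha: float = 0.05) -> GroupContrastMap:
    """Two-stage per-node contrast between two states.

    ``values`` is tidy with columns ``subject, state, node, value`` (one or
    more rows per subject x state x node; rows are averaged within that cell
    first).  Effect per node = mean over subjects of (state A mean - state B
    mean); p from the paired across-subject test; BH-FDR across nodes.
    Nodes whose values are all flagged (NaN) are excluded and listed.
    """
    a, b = pair
    required = {"subject", "state", "node", "value"}
    if not required.issubset(values.columns):
        raise DataError(f"values needs columns {sorted(required)}")
    cell = (values.groupby(["subject", "state", "node"], sort=True)["value"]
            .mean().unstack("state"))
    for s in pair:
        if s not in cell.columns:
            raise DataError(f"state {s!r} absent from values")
    diff = (cell[a] - cell[b]).unstack("node")      # subjects x nodes
    nodes_all = list(diff.columns)
    effects, ps, kept, excluded = [], [], [], []
    for node in nodes_all:
        d = diff[node].dropna().to_numpy()
        if d.size < 2:
            excluded.append(node)
            continue
        kept.append(node)
        effects.append(float(d.mean()))
        ps.append(float(_paired_test(d)))
    if excluded:
        logger.warning("excluded %d node(s) with insufficient paired data: %s",
                       len(excluded), excluded[:10])
    if not kept:
        raise DataError("no node with >= 2 paired subject values")
    ps = np.asarray(ps)
    q, mask = fdr_bh(ps, q=alpha)
    return GroupContrastMap(pair=pair, nodes=kept, effect=np.asarray(effects),
                            p=ps, q=q, mask=mask,
                            n_subjects=int(diff.dropna(how="all").shape[0]),
                            excluded_nodes=excluded, alpha=alpha)


def marker_long_table(marker_matrices: dict, marker: str,
                      label_col: str = "state_label") -> pd.DataFrame:
    """Tidy (subject, state, node, value) rows for one marker from per-subject
    MarkerMatrix objects, ready for :func:`node_state_contrast`."""
    rows = []
    for subject, mm in marker_matrices.items():
        vals = mm.marker(marker)
        states = mm.metadata[label_col].to_numpy()
        for t in range(vals.shape[0]):
            for c in range(vals.shape[1]):
                rows.append({"subject": subject, "state": states[t],
                             "node": mm.channel_names[c] if mm.channel_names else c,
                             "value": vals[t, c]})
    return pd.DataFrame(rows)


def plot_topography(map_: GroupContrastMap, positions: dict, path=None):
    """Optional scatter-style topographic rendering of a contrast map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = np.array([positions[n] for n in map_.nodes])
    fig, ax = plt.subplots(figsize=(4, 4))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=map_.effect, cmap="RdBu_r", s=120,
                    edgecolors=np.where(map_.mask, "goldenrod", "none"), linewidths=2)
    fig.colorbar(sc, ax=ax, label=f"{map_.pair[0]} - {map_.pair[1]}")
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
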