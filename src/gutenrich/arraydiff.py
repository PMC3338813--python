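"""Microarray stage: normalisation, per-time t-tests, ANOVA, Venn overlaps,
PCA and sample clustering.

Intensities arrive as a probes x samples matrix with per-sample metadata
(condition, exposure time in hours, dye, replicate).  Columns are mean-scaled
to a common mean and log2-transformed; differential expression uses the
pooled-variance two-sample t-test per time point, or a one-way fixed-effects
ANOVA of the control level against all intoxication times.  Dye-swapped
arrays are treated as independent samples.

Fold changes are reported with the signed convention: a ratio x below 1 is
written as -1/x (e.g. 0.125 -> -8.0), so induced and repressed probes read
symmetrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "treated")
ZERO_VARIANCE = "zero_variance"


@dataclass
class ExpressionMatrix:
    """Probe x sample intensities plus per-sample metadata.

    ``values``: DataFrame indexed by probe id, one column per sample id.
    ``samples``: DataFrame indexed by sample id with columns
    ``condition`` (control/treated), ``time_h``, ``dye``, ``replicate``.
    ``log2`` records whether values are on the log2 scale.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log2: bool = False

    def __post_init__(self):
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples absent from metadata: {missing}")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions in metadata: {sorted(bad)}")

    def columns_for(self, condition: str | None = None, time_h: int | None = None) -> list[str]:
        meta = self.samples.loc[list(self.values.columns)]
        mask = pd.Series(True, index=meta.index)
        if condition is not None:
            mask &= meta["condition"] == condition
        if time_h is not None:
            mask &= meta["time_h"] == time_h
        return list(meta.index[mask])

    @property
    def times(self) -> list[int]:
        return sorted(self.samples["time_h"].unique())


def signed_fold(ratio: float) -> float:
    """Signed fold convention: ratios below 1 become the negative reciprocal."""
    if ratio <= 0 or not np.isfinite(ratio):
        raise ValueError("ratio must be a positive finite number")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Mean-scale each sample column to the grand mean, then log2-transform.

    Zeros are replaced by half the smallest positive intensity (logged).
    After scaling and before the log, every column mean equals the grand mean
    of the original column means.
    """
    if matrix.log2:
        raise ValueError("matrix is already log2-transformed")
    values = matrix.values.astype(float)
    if (values < 0).any().any():
        raise ValueError("intensities must be non-negative")
    if (values == 0).any().any():
        positive_min = values.values[values.values > 0].min()
        logger.info("replacing zero intensities by %g", positive_min / 2)
        values = values.mask(values == 0, positive_min / 2)
    col_means = values.mean(axis=0)
    if (col_means <= 0).any():
        raise ValueError("a sample column has zero mean")
    grand = col_means.mean()
    scaled = values * (grand / col_means)
    return ExpressionMatrix(values=np.log2(scaled), samples=matrix.samples, log2=True)


def _pooled_t(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised pooled-variance two-sample t along axis 1.

    Returns (t, p, zero_variance_mask).  Zero pooled variance yields p = 1
    when the means agree and the smallest positive float when they differ.
    """
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    ss = x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)
    df = n1 + n2 - 2
    pooled = ss / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    delta = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    zero = se == 0.0
    # with zero variance, mean differences at rounding level are no signal,
    # not infinite evidence
    tol = 1e-9 * np.maximum(1.0, np.abs(m1) + np.abs(m2))
    equal = zero & (np.abs(delta) <= tol)
    differ = zero & (np.abs(delta) > tol)
    t[equal], p[equal] = 0.0, 1.0
    t[differ] = np.sign(delta[differ]) * np.inf
    p[differ] = np.finfo(float).tiny
    return t, p, zero


def pairwise_de(matrix: ExpressionMatrix, time_h: int, welch: bool = False) -> pd.DataFrame:
    """Treated vs control two-sample t-test at one exposure time.

    Requires a normalised (log2) matrix.  Returns one row per probe with the
    group means, the signed fold (2**delta with the -1/x convention), t, the
    two-sided p and the BH q across probes.  ``welch=True`` drops the
    equal-variance assumption.
    """
    if not matrix.log2:
        raise ValueError("pairwise_de expects a normalised log2 matrix")
    cols_t = matrix.columns_for("treated", time_h)
    cols_c = matrix.columns_for("control", time_h)
    if len(cols_t) < 2 or len(cols_c) < 2:
        raise ValueError(f"need >=2 replicates per condition at {time_h} h")
    x = matrix.values[cols_t].to_numpy(float)
    y = matrix.values[cols_c].to_numpy(float)
    if welch:
        t, p = sps.ttest_ind(x, y, axis=1, equal_var=False)
        zero = np.zeros(len(t), dtype=bool)
        bad = ~np.isfinite(p)
        if bad.any():
            delta0 = x.mean(axis=1) - y.mean(axis=1)
            p = np.where(bad & (delta0 == 0), 1.0, p)
            p = np.where(bad & (delta0 != 0), np.finfo(float).tiny, p)
            zero = bad
    else:
        t, p, zero = _pooled_t(x, y)
    delta = x.mean(axis=1) - y.mean(axis=1)
    fold = np.array([signed_fold(2.0 ** d) for d in delta])
    out = pd.DataFrame({
        "probe": matrix.values.index,
        "mean_log_control": y.mean(axis=1),
        "mean_log_treated": x.mean(axis=1),
        "fold": fold,
        "t": t,
        "p": p,
        "q": bh_adjust(p),
        "flags": np.where(zero, ZERO_VARIANCE, ""),
    }).set_index("probe")
    return out


def anova_de(matrix: ExpressionMatrix, times: Sequence[int] | None = None) -> pd.DataFrame:
    """One-way fixed-effects ANOVA: one control level vs each intoxication time.

    Levels are all control columns pooled, plus the treated columns at each
    time in ``times`` (default: every time present).  Per probe: F, p from
    F(k-1, N-k), BH q, and the signed fold of the most extreme treated level
    relative to control.
    """
    if not matrix.log2:
        raise ValueError("anova_de expects a normalised log2 matrix")
    if times is None:
        times = matrix.times
    level_cols = [matrix.columns_for("control")]
    level_cols += [matrix.columns_for("treated", t) for t in times]
    for cols in level_cols:
        if len(cols) < 2:
            raise ValueError("every level needs >=2 replicates")
    arrays = [matrix.values[cols].to_numpy(float) for cols in level_cols]
    k = len(arrays)
    n_total = sum(a.shape[1] for a in arrays)
    grand = np.hstack(arrays).mean(axis=1)
    ss_between = sum(a.shape[1] * (a.mean(axis=1) - grand) ** 2 for a in arrays)
    ss_within = sum(((a.T - a.mean(axis=1)) ** 2).sum(axis=0) for a in arrays)
    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    p = sps.f.sf(f, df_b, df_w)
    zero = ss_within == 0.0
    flat = zero & np.isclose(ss_between, 0.0)
    f[flat], p[flat] = 0.0, 1.0
    spiked = zero & ~flat
    f[spiked] = np.inf
    p[spiked] = np.finfo(float).tiny
    control_mean = arrays[0].mean(axis=1)
    treated_means = np.column_stack([a.mean(axis=1) for a in arrays[1:]])
    deltas = treated_means - control_mean[:, None]
    extreme = deltas[np.arange(len(deltas)), np.abs(deltas).argmax(axis=1)]
    fold = np.array([signed_fold(2.0 ** d) for d in extreme])
    out = pd.DataFrame({
        "probe": matrix.values.index,
        "mean_log_control": control_mean,
        "F": f,
        "p": p,
        "q": bh_adjust(p),
        "fold": fold,
        "flags": np.where(zero, ZERO_VARIANCE, ""),
    }).set_index("probe")
    for t, col in zip(times, deltas.T):
        out[f"delta_log2_{t}h"] = col
    return out


def venn_counts(sets_by_label: Mapping[str, Set[str]]) -> Dict[Tuple[str, ...], int]:
    """Exclusive region counts for a 3-set Venn diagram.

    Keys of the result are sorted tuples of labels naming each region;
    region counts sum to the cardinality of the union.
    """
    if len(sets_by_label) != 3:
        raise ValueError("venn_counts expects exactly three sets")
    labels = sorted(sets_by_label)
    universe = set().union(*sets_by_label.values())
    counts: Dict[Tuple[str, ...], int] = {}
    from itertools import combinations
    for r in (1, 2, 3):
        for combo in combinations(labels, r):
            inside = set(universe)
            for lab in labels:
                if lab in combo:
                    inside &= sets_by_label[lab]
                else:
                    inside -= sets_by_label[lab]
            counts[combo] = len(inside)
    return counts


def significant_sets(
    results_by_time: Mapping[int, pd.DataFrame], direction: str, alpha: float = 0.05,
    use_q: bool = False,
) -> Dict[str, Set[str]]:
    """Significant induced or repressed probe sets per time, for Venn overlap.

    ``direction`` is 'induced' (fold > 1) or 'repressed' (fold < -1); the
    cut-off applies to raw p by default (use_q switches to the BH q).
    """
    if direction not in ("induced", "repressed"):
        raise ValueError("direction must be 'induced' or 'repressed'")
    out: Dict[str, Set[str]] = {}
    for time_h, frame in results_by_time.items():
        stat = frame["q"] if use_q else frame["p"]
        if direction == "induced":
            mask = (stat < alpha) & (frame["fold"] > 1)
        else:
            mask = (stat < alpha) & (frame["fold"] < -1)
        out[f"{time_h}h"] = set(frame.index[mask])
    return out


def pca(matrix: ExpressionMatrix) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Principal components of the samples (columns) of a log2 matrix.

    Samples are observations; probes are variables.  Returns (scores,
    explained_variance, components): scores is samples x components,
    explained variance sums to the total sample variance, and the component
    loadings are orthonormal rows.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    x = matrix.values.to_numpy(float).T  # samples x probes
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    n = x.shape[0]
    explained = s ** 2 / (n - 1)
    scores = pd.DataFrame(
        u * s,
        index=matrix.values.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return scores, explained, vt


def hcluster_manhattan_average(matrix: ExpressionMatrix) -> Tuple[np.ndarray, list[str]]:
    """Average-linkage agglomeration of samples on Manhattan distances.

    Returns the scipy linkage matrix together with the sample labels in
    leaf-input order; merge heights are non-decreasing.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    x = matrix.values.to_numpy(float).T
    dist = pdist(x, metric="cityblock")
    z = linkage(dist, method="average")
    return z, list(matrix.values.columns)


def linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(z)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.10g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
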