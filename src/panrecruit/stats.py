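"""Alpha diversity, sample clustering, and permutation-based differential
abundance for feature-by-sample count tables.

Alpha diversity reports observed richness, the Chao1 estimator
(bias-corrected by default: S_obs + F1(F1-1)/(2(F2+1)), which stays finite
when no doubletons are seen; the classic F1^2/(2 F2) form is selectable),
Shannon entropy in natural log, and Simpson's lambda = sum(p^2) together
with the Gini-Simpson 1 - lambda, since "Simpson diversity" is reported
both ways in the literature.

Group comparison follows the resampling-based "non-parametric t-test"
tradition for metagenomic count tables: a Welch t statistic on relative
proportions, a null built by permuting sample labels, and a false discovery
rate estimated from the same permutations (mean permuted exceedance count
over observed exceedance count, minimized over thresholds and monotonized).
Unreplicated samples can be expanded into multinomial pseudo-replicates, a
documented stand-in matching how sparse-count pipelines handle single
metagenomes.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .errors import ConfigError


@dataclass(frozen=True)
class DiversityReport:
    s_obs: int
    chao1: float
    shannon: float
    simpson_lambda: float

    @property
    def gini_simpson(self) -> float:
        return 1.0 - self.simpson_lambda


def alpha_diversity(
    counts: Sequence[float] | np.ndarray | pd.Series,
    chao1_variant: str = "bias_corrected",
) -> DiversityReport:
    """Alpha-diversity indices of one sample's feature counts.

    Chao1 extrapolates unseen richness from singletons (F1) and doubletons
    (F2); Shannon is -sum(p ln p); Simpson's lambda is sum(p^2), both over
    the positive counts only.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0 or np.all(x == 0):
        raise ConfigError("alpha_diversity needs at least one positive count")
    if np.any(x < 0):
        raise ConfigError("counts must be nonnegative")
    x = x[x > 0]
    s_obs = int(x.size)
    f1 = int(np.count_nonzero(x == 1))
    f2 = int(np.count_nonzero(x == 2))
    if chao1_variant == "bias_corrected":
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    elif chao1_variant == "classic":
        if f2 == 0:
            raise ConfigError("classic Chao1 requires at least one doubleton")
        chao1 = s_obs + f1 * f1 / (2.0 * f2)
    else:
        raise ConfigError(f"unknown chao1_variant {chao1_variant!r}")
    p = x / x.sum()
    shannon = float(-(p * np.log(p)).sum())
    simpson = float((p * p).sum())
    return DiversityReport(s_obs, float(chao1), shannon, simpson)


def relative_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample (column) to proportions summing to one."""
    totals = table.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ConfigError(f"sample {zero.index[0]!r} has zero total count")
    return table / totals


def complete_linkage(table: pd.DataFrame, metric: str = "braycurtis") -> str:
    """Complete-linkage dendrogram of samples on Bray-Curtis distances of
    their relative proportions, returned as a newick string with branch
    lengths equal to merge-height differences.

    Samples are sorted lexicographically before clustering so ties break
    deterministically.
    """
    if table.shape[1] < 2:
        raise ConfigError("complete_linkage needs at least 2 samples")
    props = relative_proportions(table)
    labels = sorted(map(str, props.columns))
    mat = props[labels].to_numpy().T
    dist = pdist(mat, metric=metric)
    z = linkage(dist, method="complete")
    root = to_tree(z)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = render(node.left)
        right = render(node.right)
        bl = node.dist - node.left.dist
        br = node.dist - node.right.dist
        return f"({left}:{bl:.10g},{right}:{br:.10g})"

    return render(root) + ";"


def _welch_t(x: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
    """Vectorized Welch t per feature (rows of x); zero-variance features
    with equal means get t = 0, with unequal means +-inf."""
    a = x[:, a_idx]
    b = x[:, b_idx]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1) / a.shape[1]
    vb = b.var(axis=1, ddof=1) / b.shape[1]
    denom = np.sqrt(va + vb)
    diff = ma - mb
    t = np.zeros_like(diff)
    ok = denom > 0
    t[ok] = diff[ok] / denom[ok]
    degenerate = ~ok & (diff != 0)
    t[degenerate] = np.sign(diff[degenerate]) * np.inf
    return t


def permutation_t_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-feature Welch t on proportions with a label-permutation null.

    ``group_a``/``group_b`` are feature-by-observation tables of relative
    proportions with identical feature indexes.  With ``exhaustive`` (the
    default below 2000 distinct label assignments) every way of splitting
    the pooled observations into the two group sizes is enumerated and
    p = #{|t_perm| >= |t_obs|} / #assignments (the identity assignment makes
    p >= 1/#assignments); otherwise ``n_perm`` random label permutations
    give p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1).

    Returns (results frame with ``statistic`` and ``p_perm``, the permuted
    statistic matrix used — feed it to :func:`permutation_fdr`).
    """
    if not group_a.index.equals(group_b.index):
        raise ConfigError("groups must share the same feature index")
    na, nb = group_a.shape[1], group_b.shape[1]
    if na < 2 or nb < 2:
        raise ConfigError(
            "need >= 2 observations per group; expand single samples with "
            "pseudo_replicates() first"
        )
    if n_perm < 99:
        raise ConfigError("n_perm must be >= 99")
    x = np.hstack([group_a.to_numpy(float), group_b.to_numpy(float)])
    n = na + nb
    idx = np.arange(n)
    t_obs = _welch_t(x, idx[:na], idx[na:])
    n_assign = comb(n, na)
    if exhaustive is None:
        exhaustive = n_assign <= 2000
    perm_cols: list[np.ndarray] = []
    if exhaustive:
        for a_set in combinations(range(n), na):
            a_idx = np.array(a_set)
            mask = np.zeros(n, dtype=bool)
            mask[a_idx] = True
            perm_cols.append(_welch_t(x, idx[mask], idx[~mask]))
        perm = np.column_stack(perm_cols)
        exceed = (np.abs(perm) >= np.abs(t_obs)[:, None]).sum(axis=1)
        p = exceed / perm.shape[1]
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            order = rng.permutation(n)
            perm_cols.append(_welch_t(x, order[:na], order[na:]))
        perm = np.column_stack(perm_cols)
        exceed = (np.abs(perm) >= np.abs(t_obs)[:, None]).sum(axis=1)
        p = (1.0 + exceed) / (n_perm + 1.0)
    res = pd.DataFrame(
        {"statistic": t_obs, "p_perm": p}, index=group_a.index.copy()
    )
    return res, perm


def permutation_fdr(
    observed: np.ndarray | pd.Series,
    perm_matrix: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> np.ndarray:
    """Permutation-based q-values from observed statistics and their
    permuted counterparts (same features x permutations).

    For each threshold t: FDR(t) = mean over permutations of
    #{|perm| >= t} / max(1, #{|obs| >= t}).  A feature's q is the minimum
    FDR over thresholds not exceeding its |statistic|, monotonized so q is
    non-increasing in |statistic|, and clipped to [0, 1].
    """
    s = np.abs(np.asarray(observed, dtype=float))
    sp = np.abs(np.asarray(perm_matrix, dtype=float))
    if sp.shape[0] != s.size:
        raise ConfigError("perm_matrix must have one row per feature")
    grid = np.unique(s) if thresholds is None else np.unique(np.abs(thresholds))
    # exceedance counts via sorted arrays
    s_sorted = np.sort(s)
    sp_sorted = np.sort(sp.ravel())
    n_perm = sp.shape[1]
    r = s.size - np.searchsorted(s_sorted, grid, side="left")
    v = (sp_sorted.size - np.searchsorted(sp_sorted, grid, side="left")) / n_perm
    fdr = v / np.maximum(1, r)
    # q(feature) = min FDR over thresholds <= its |statistic|; the prefix
    # minimum over the ascending grid makes q non-increasing in |statistic|
    cmin = np.minimum.accumulate(fdr)
    pos = np.searchsorted(grid, s, side="right") - 1
    q = np.where(pos >= 0, cmin[np.maximum(pos, 0)], 1.0)
    return np.clip(q, 0.0, 1.0)


def pseudo_replicates(
    column: pd.Series, k: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Expand one sample's counts into k multinomial resamples of the same
    depth (a documented stand-in for biological replicates)."""
    if k < 2:
        raise ConfigError("need at least 2 pseudo-replicates")
    counts = column.to_numpy(float)
    total = counts.sum()
    if total <= 0:
        raise ConfigError(f"sample {column.name!r} has zero total count")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(int(total), counts / total, size=k).T
    return pd.DataFrame(
        draws,
        index=column.index,
        columns=[f"{column.name}_rep{i}" for i in range(k)],
    )


def fold_enrichment(table: pd.DataFrame, focal_sample: str) -> pd.Series:
    """Per-feature fold enrichment of the focal sample over the mean
    proportion across all samples, with zeros replaced by half the smallest
    nonzero proportion in the table."""
    props = relative_proportions(table)
    positive = props.to_numpy()[props.to_numpy() > 0]
    eps = positive.min() / 2.0
    padded = props.where(props > 0, eps)
    return padded[focal_sample] / padded.mean(axis=1)


def differential_abundance(
    table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    n_pseudo: int = 4,
) -> pd.DataFrame:
    """End-to-end group comparison on a count table.

    Columns named in ``group_a``/``group_b`` are normalized to proportions;
    groups with a single sample are expanded into ``n_pseudo`` multinomial
    pseudo-replicates.  Returns a per-feature frame with the Welch
    statistic, permutation p, permutation-FDR q, and the fold enrichment of
    group A's mean proportion over the overall mean.
    """

    def expand(names: Sequence[str], tag: int) -> pd.DataFrame:
        if len(names) == 1:
            return relative_proportions(
                pseudo_replicates(table[names[0]], k=n_pseudo, seed=seed + tag)
            )
        return relative_proportions(table[list(names)])

    a = expand(list(group_a), 1)
    b = expand(list(group_b), 2)
    res, perm = permutation_t_test(a, b, n_perm=n_perm, seed=seed)
    res["q_fdr"] = permutation_fdr(res["statistic"].to_numpy(), perm)
    props = relative_proportions(table[list(group_a) + list(group_b)])
    positive = props.to_numpy()[props.to_numpy() > 0]
    eps = positive.min() / 2.0
    padded = props.where(props > 0, eps)
    res["fold_enrichment"] = (
        padded[list(group_a)].mean(axis=1) / padded.mean(axis=1)
    )
    return res
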