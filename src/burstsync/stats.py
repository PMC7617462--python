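"""Inferential machinery: cluster-based permutation tests on paired
time-frequency maps, Wilcoxon signed-rank with |Z|/sqrt(n) effect size,
one-way repeated-measures ANOVA with Greenhouse-Geisser correction, and
Holm-Bonferroni adjustment.

The cluster test forms connected components of pixels whose paired
t-statistic exceeds 1.645 (the one-sided 5% normal critical value) and
compares both the largest cluster size (pixels) and the largest
accumulated t against a sign-flip permutation null of per-permutation
maxima.  Two p-values are returned; the accumulated-t one is primary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterResult",
    "TestSummary",
    "paired_t_map",
    "find_clusters",
    "cluster_permutation",
    "wilcoxon_signed_rank",
    "rm_anova",
    "holm_bonferroni",
    "cluster_forming_threshold",
]


def cluster_forming_threshold(alpha: float = 0.05) -> float:
    """One-sided critical value of the large-sample (normal) null of the
    paired t statistic; 1.645 at alpha = 0.05."""
    return float(sstats.norm.ppf(1 - alpha))


@dataclass
class Cluster:
    pixels: np.ndarray  # boolean mask on the map grid
    size: int
    accumulated_t: float


@dataclass
class ClusterResult:
    t_map: np.ndarray
    threshold: float
    clusters: list
    max_size: int
    max_accumulated_t: float
    null_max_size: np.ndarray
    null_max_accumulated_t: np.ndarray
    p_size: float
    p_accumulated_t: float
    n_permutations: int
    seed: int

    @property
    def p_value(self) -> float:
        """Primary p-value (accumulated-t statistic)."""
        return self.p_accumulated_t

    @property
    def significant_mask(self) -> np.ndarray:
        """Union of clusters whose accumulated t exceeds the null 95th percentile."""
        if not self.clusters:
            return np.zeros_like(self.t_map, dtype=bool)
        crit = np.quantile(self.null_max_accumulated_t, 0.95)
        mask = np.zeros_like(self.t_map, dtype=bool)
        for c in self.clusters:
            if c.accumulated_t > crit:
                mask |= c.pixels
        return mask


@dataclass
class TestSummary:
    test: str
    statistic: float
    p: float
    df: tuple | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    extras: dict = field(default_factory=dict)


def paired_t_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise paired t across participants (first axis).

    Zero-variance pixels yield t = 0 and are thereby excluded from
    positive clusters.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape[0] < 2:
        raise ValueError("need matching stacks with n >= 2 participants")
    return _t_from_diffs(a - b)


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def find_clusters(t_map: np.ndarray, threshold: float = 1.645, connectivity: int = 4) -> list:
    """Maximal connected supra-threshold components (positive tail)."""
    labels, n = ndimage.label(t_map > threshold, structure=_STRUCTURES[connectivity])
    out = []
    for i in range(1, n + 1):
        mask = labels == i
        out.append(Cluster(pixels=mask, size=int(mask.sum()), accumulated_t=float(t_map[mask].sum())))
    return out


def _null_maxima(
    diffs: np.ndarray, threshold: float, n_perm: int, connectivity: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sign-flip null of per-permutation maxima.

    Sign flips leave sum(d^2) unchanged, so each permutation's t-map
    needs only the flipped mean - computed for all permutations in one
    matrix product.
    """
    n = diffs.shape[0]
    shape = diffs.shape[1:]
    flat = diffs.reshape(n, -1)
    ssq = np.sum(flat**2, axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = signs @ flat / n
    var = (ssq[None, :] - n * means**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(var > 0, means / np.sqrt(var / n), 0.0)
    max_size = np.zeros(n_perm)
    max_acc = np.zeros(n_perm)
    struct = _STRUCTURES[connectivity]
    for i in range(n_perm):
        tm = t_all[i].reshape(shape)
        labels, k = ndimage.label(tm > threshold, structure=struct)
        if k:
            sizes = ndimage.sum_labels(np.ones_like(tm), labels, index=np.arange(1, k + 1))
            accs = ndimage.sum_labels(tm, labels, index=np.arange(1, k + 1))
            max_size[i] = sizes.max()
            max_acc[i] = accs.max()
    return max_size, max_acc


def cluster_permutation(
    a: np.ndarray,
    b: np.ndarray,
    threshold: float = 1.645,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 4,
) -> ClusterResult:
    """Paired cluster-based permutation test (positive tail).

    ``a``/``b``: (n_participants, n_freqs, n_times) map stacks.  The null
    randomly swaps the pairing per participant (sign flip of the paired
    difference); p = (1 + #{null >= observed}) / (1 + n_perm) for both the
    largest cluster size and the largest accumulated t.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    t_map = _t_from_diffs(diffs)
    clusters = find_clusters(t_map, threshold, connectivity)
    obs_size = max((c.size for c in clusters), default=0)
    obs_acc = max((c.accumulated_t for c in clusters), default=0.0)
    rng = np.random.default_rng(seed)
    null_size, null_acc = _null_maxima(diffs, threshold, n_perm, connectivity, rng)
    if clusters:
        p_size = (1 + np.sum(null_size >= obs_size)) / (1 + n_perm)
        p_acc = (1 + np.sum(null_acc >= obs_acc)) / (1 + n_perm)
    else:
        p_size = p_acc = 1.0
    return ClusterResult(
        t_map=t_map,
        threshold=threshold,
        clusters=clusters,
        max_size=obs_size,
        max_accumulated_t=obs_acc,
        null_max_size=null_size,
        null_max_accumulated_t=null_acc,
        p_size=float(p_size),
        p_accumulated_t=float(p_acc),
        n_permutations=n_perm,
        seed=seed,
    )


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> TestSummary:
    """Wilcoxon signed-rank with the normal approximation (no continuity
    correction) and effect size r = |Z|/sqrt(n) signed by the median
    difference.

    Zero differences are dropped (Wilcoxon's rule); ties share mid-ranks
    with the usual variance correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must share shape")
    d = x - y
    n_pairs = len(d)
    dz = d[d != 0]
    if len(dz) == 0:
        return TestSummary("wilcoxon", 0.0, 1.0, effect_size=0.0, effect_size_name="r",
                           extras={"W": 0.0, "Z": 0.0, "n": n_pairs})
    ranks = sstats.rankdata(np.abs(dz))
    w_plus = float(ranks[dz > 0].sum())
    m = len(dz)
    mean_w = m * (m + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w = m * (m + 1) * (2 * m + 1) / 24 - np.sum(tie_counts**3 - tie_counts) / 48
    z = (w_plus - mean_w) / np.sqrt(var_w)
    p = 2 * sstats.norm.sf(abs(z))
    r = abs(z) / np.sqrt(n_pairs) * np.sign(np.median(d)) if np.median(d) != 0 else abs(z) / np.sqrt(n_pairs)
    return TestSummary(
        "wilcoxon", z, float(min(p, 1.0)), effect_size=float(r), effect_size_name="r",
        extras={"W": w_plus, "Z": float(z), "n": n_pairs},
    )


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centred covariance."""
    k = data.shape[1]
    s = np.cov(data, rowvar=False, ddof=1)
    sc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(sc) ** 2
    den = (k - 1) * np.sum(sc**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova(data: np.ndarray) -> TestSummary:
    """One-way within-subject ANOVA (participants x conditions) with
    Greenhouse-Geisser corrected degrees of freedom.

    Effect size: partial eta squared SS_cond / (SS_cond + SS_error);
    plain eta squared (SS_cond / SS_total) is in ``extras``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a complete participants x conditions matrix")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    n, k = data.shape
    grand = data.mean()
    ss_total = float(np.sum((data - grand) ** 2))
    ss_subj = float(k * np.sum((data.mean(axis=1) - grand) ** 2))
    ss_cond = float(n * np.sum((data.mean(axis=0) - grand) ** 2))
    ss_err = ss_total - ss_subj - ss_cond
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f = ms_cond / ms_err if ms_err > 0 else np.inf
    eps = _gg_epsilon(data) if k > 2 else 1.0
    p = float(sstats.f.sf(f, eps * df1, eps * df2))
    eta_p = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return TestSummary(
        "rm_anova", float(f), p, df=(eps * df1, eps * df2),
        effect_size=float(eta_p), effect_size_name="partial_eta_sq",
        extras={"epsilon": eps, "eta_sq_total": ss_cond / ss_total if ss_total > 0 else 0.0,
                "df_uncorrected": (df1, df2)},
    )


def holm_bonferroni(pvals) -> np.ndarray:
    """Step-down Holm adjustment, order preserved, capped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def cluster_test_type1_error(
    n_cohorts: int = 200,
    n_participants: int = 20,
    shape: tuple[int, int] = (40, 60),
    n_perm: int = 500,
    alpha: float = 0.05,
    threshold: float = 1.645,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the cluster permutation test on null
    Gaussian cohorts (paired maps with no true difference), using the
    primary accumulated-t p-value at the given nominal level."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_cohorts):
        a = rng.standard_normal((n_participants, *shape))
        b = rng.standard_normal((n_participants, *shape))
        res = cluster_permutation(a, b, threshold=threshold, n_perm=n_perm,
                                  seed=int(rng.integers(2**31)))
        rejections += res.p_accumulated_t < alpha
    return rejections / n_cohorts
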