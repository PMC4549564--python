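"""Univariate screening and group-comparison statistics.

Covers the statistics used around the signature model: signal-to-noise with
label-permutation nulls, Pearson correlation screening against a continuous
outcome, Welch's unequal-variance t-test with Storey q-value FDR correction,
hypergeometric (one-sided Fisher) category enrichment, copy-number vs
expression correlation ranking, and strand-aware cis-proximity linking of
lincRNAs to neighboring genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .io import CopyNumberMatrix, ExpressionMatrix, FeatureAnnotation

__all__ = [
    "GroupComparison",
    "ScreenResult",
    "signal_to_noise",
    "permutation_pvalue",
    "pearson_screen",
    "welch_t",
    "welch_screen",
    "storey_qvalues",
    "hypergeometric_enrichment",
    "enrichment_screen",
    "cnv_expression_correlation",
    "proximal_feature_link",
]


@dataclass
class GroupComparison:
    """Two-class comparison summarized by the signal-to-noise statistic
    theta = (mu_x - mu_y) / (sd_x + sd_y)."""

    x: np.ndarray
    y: np.ndarray
    mu_x: float
    mu_y: float
    sd_x: float
    sd_y: float
    theta: float


@dataclass
class ScreenResult:
    """Per-feature screening outcome; ``q_value`` is NaN when no FDR
    correction applies (deliberately uncorrected local screens)."""

    feature_id: str
    statistic: float
    p_value: float
    q_value: float
    passed: bool


def signal_to_noise(x, y) -> GroupComparison:
    """Difference of means relative to the summed (n-1) standard deviations.

    Antisymmetric in (x, y); undefined when both spreads are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("signal_to_noise requires >= 2 values per class")
    mu_x, mu_y = float(np.mean(x)), float(np.mean(y))
    sd_x, sd_y = float(np.std(x, ddof=1)), float(np.std(y, ddof=1))
    if sd_x + sd_y == 0:
        raise ValueError("degenerate comparison: zero spread in both classes")
    return GroupComparison(
        x=x, y=y, mu_x=mu_x, mu_y=mu_y, sd_x=sd_x, sd_y=sd_y,
        theta=(mu_x - mu_y) / (sd_x + sd_y),
    )


def permutation_pvalue(
    x,
    y,
    statistic_fn: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Two-sided empirical p-value by permuting class labels.

    Uses the add-one estimator p = (1 + #{|stat_perm| >= |stat_obs|}) /
    (n_perm + 1), so the smallest attainable p is 1/(n_perm+1). Permutations
    on which the statistic is undefined (zero spread) count as ties, so a
    fully degenerate input yields p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic_fn is None:
        statistic_fn = lambda a, b: signal_to_noise(a, b).theta
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n_x = len(x)
    try:
        obs = abs(statistic_fn(x, y))
    except ValueError:
        return 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        try:
            s = abs(statistic_fn(perm[:n_x], perm[n_x:]))
        except ValueError:
            hits += 1  # degenerate permutation counts as extreme-or-tied
            continue
        if s >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every row of X against y, and the zero-variance row mask."""
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    degenerate = (sx == 0) | (sy == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    r[degenerate] = np.nan
    return r, degenerate


def pearson_correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via t = r sqrt((n-2)/(1-r^2)), n-2 df."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def pearson_screen(
    X: ExpressionMatrix, y, alpha_local: float = 0.05
) -> list[ScreenResult]:
    """Per-feature Pearson correlation screen against a continuous outcome.

    The pass criterion is a deliberately *uncorrected* local type-I rate
    (p < alpha_local): false positives are tolerated here because the
    downstream penalized regression removes uninformative inputs.
    Zero-variance features are excluded (NaN statistic, never passed).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[1] != n:
        raise ValueError("X and y sample counts differ")
    if n < 4:
        raise ValueError("pearson_screen requires n >= 4")
    r, degenerate = _pearson_rows(X.values, y)
    p = pearson_correlation_pvalues(r, n)
    n_excluded = int(degenerate.sum())
    if n_excluded:
        warnings.warn(f"pearson_screen: excluded {n_excluded} zero-variance features")
    out = []
    for fid, ri, pi, bad in zip(X.feature_ids, r, p, degenerate):
        out.append(
            ScreenResult(
                feature_id=fid,
                statistic=float(ri),
                p_value=float("nan") if bad else float(pi),
                q_value=float("nan"),
                passed=bool(not bad and pi < alpha_local),
            )
        )
    return out


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t: (t, Welch-Satterthwaite df, two-sided p).

    The degenerate case (zero variance in both groups, equal means) returns
    t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t requires >= 2 values per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.inf) * np.sign(np.mean(a) - np.mean(b)), float(
            len(a) + len(b) - 2
        ), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def storey_qvalues(
    p_values, min_m_for_smoothing: int = 100
) -> tuple[np.ndarray, float]:
    """Storey q-values with the lambda-grid smoother estimate of pi0.

    pi0(lam) = #{p > lam} / (m (1 - lam)) is evaluated on lam = 0.05..0.95,
    a cubic polynomial in lam is fitted and read off at lam = 0.95, then
    clipped to (0, 1]. With fewer than ``min_m_for_smoothing`` tests the
    smoother is unreliable and pi0 falls back to 1 (the q-values then equal
    Benjamini-Hochberg adjusted p-values).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m < min_m_for_smoothing:
        warnings.warn(
            f"storey_qvalues: m={m} < {min_m_for_smoothing}, using pi0 = 1 (BH)"
        )
        pi0 = 1.0
    else:
        lams = np.arange(0.05, 0.951, 0.05)
        pi0_lam = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lams])
        coeffs = np.polyfit(lams, pi0_lam, deg=3)
        pi0 = float(np.polyval(coeffs, 0.95))
        pi0 = min(max(pi0, np.finfo(float).tiny), 1.0)
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    # enforce monotonicity: q(i) = min_{j >= i} pi0 m p(j) / j
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def welch_screen(
    X: ExpressionMatrix,
    responder_ids: Sequence[str],
    nonresponder_ids: Sequence[str],
    q_threshold: float = 0.05,
) -> list[ScreenResult]:
    """Responder vs non-responder differential screen: per-feature Welch t
    with Storey q-value correction; passed iff q < q_threshold."""
    ia = [X.sample_ids.index(s) for s in responder_ids]
    ib = [X.sample_ids.index(s) for s in nonresponder_ids]
    A, B = X.values[:, ia], X.values[:, ib]
    t, p = _welch_rows(A, B)
    q, _ = storey_qvalues(p)
    return [
        ScreenResult(
            feature_id=fid,
            statistic=float(ti),
            p_value=float(pi),
            q_value=float(qi),
            passed=bool(qi < q_threshold),
        )
        for fid, ti, pi, qi in zip(X.feature_ids, t, p, q)
    ]


def _welch_rows(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t and two-sided p (vectorized over features)."""
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    degenerate = se2 == 0
    se2_safe = np.where(degenerate, 1.0, se2)
    t = (ma - mb) / np.sqrt(se2_safe)
    df = se2_safe**2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1) + np.finfo(float).tiny
    )
    p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(df, 1.0))
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return t, p


def hypergeometric_enrichment(hits, category, universe) -> float:
    """Right-tail overlap probability P(X >= k), X ~ Hypergeom(N, K, n).

    N = |universe|, K = |category|, n = |hits|, k = |hits & category|.
    The tail is inclusive, so k = 0 gives p = 1. Identical to the one-sided
    Fisher exact test on the corresponding 2x2 table.
    """
    hits, category, universe = set(hits), set(category), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe or not category <= universe:
        raise ValueError("hits and category must be subsets of the universe")
    N, K, n = len(universe), len(category), len(hits)
    k = len(hits & category)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_screen(hits, collection) -> list[tuple[str, int, float]]:
    """Hypergeometric p per category: list of (category_id, overlap, p)."""
    hits = set(hits)
    out = []
    for name, members in collection.categories.items():
        p = hypergeometric_enrichment(hits, members, collection.universe)
        out.append((name, len(hits & members), p))
    out.sort(key=lambda t: t[2])
    return out


def cnv_expression_correlation(
    expr: ExpressionMatrix,
    cnv: CopyNumberMatrix,
    use_absolute: bool = False,
) -> list[tuple[str, float, float]]:
    """Per-gene Pearson correlation of expression with copy number, ranked.

    Returns (feature_id, r, percentile_rank) for every feature shared by the
    two matrices, over their shared samples. ``percentile_rank`` is the
    average rank of r in descending order divided by the number of genes, so
    "top 1.6%" means percentile_rank <= 0.016. Strong *positive*
    expression-CNV coupling ranks first; ``use_absolute`` ranks by |r|.
    """
    shared_samples = [s for s in expr.sample_ids if s in set(cnv.sample_ids)]
    if len(shared_samples) < 3:
        raise ValueError("need >= 3 shared samples for CNV-expression correlation")
    shared_features = [f for f in expr.feature_ids if f in set(cnv.feature_ids)]
    if not shared_features:
        raise ValueError("no shared features between expression and CNV")
    e = expr.subset_features(shared_features).subset_samples(shared_samples).values
    c = cnv.subset_features(shared_features).subset_samples(shared_samples).values
    ec = e - e.mean(axis=1, keepdims=True)
    cc = c - c.mean(axis=1, keepdims=True)
    denom = np.sqrt((ec**2).sum(axis=1) * (cc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (ec * cc).sum(axis=1) / denom, np.nan)
    key = np.abs(r) if use_absolute else r
    ranks = stats.rankdata(-key, method="average", nan_policy="omit")
    pct = ranks / len(shared_features)
    return [
        (fid, float(ri), float(pi))
        for fid, ri, pi in zip(shared_features, r, pct)
    ]


def proximal_feature_link(
    linc: FeatureAnnotation,
    genes: Sequence[FeatureAnnotation],
    expr: ExpressionMatrix,
    max_distance: int = 100_000,
    alpha: float = 0.05,
) -> list[tuple[FeatureAnnotation, int, float, float]]:
    """Link a lincRNA to nearby downstream genes it may cis-regulate.

    A gene is reported when the lincRNA interval lies *upstream* of the
    gene's TSS on the same chromosome -- interval end before the TSS for '+'
    strand genes, interval start after the TSS for '-' strand -- within
    ``max_distance`` bp (TSS to nearest interval edge), and the Pearson
    correlation between the two expression rows is significant at ``alpha``.
    Genes of unknown strand are skipped with a warning.

    Returns (gene, distance_bp, r, p) sorted by distance.
    """
    ids = set(expr.feature_ids)
    if linc.feature_id not in ids:
        raise ValueError(f"lincRNA {linc.feature_id!r} absent from expression matrix")
    linc_row = expr.row(linc.feature_id)
    n = len(linc_row)
    out = []
    for gene in genes:
        if gene.feature_id == linc.feature_id:
            continue
        if gene.strand == "unknown":
            warnings.warn(f"gene {gene.feature_id!r} has unknown strand; skipped")
            continue
        if gene.chrom != linc.chrom:
            continue
        tss = gene.tss
        if gene.strand == "+":
            if linc.end >= tss:
                continue
            distance = tss - linc.end
        else:
            if linc.start <= tss:
                continue
            distance = linc.start - tss
        if distance > max_distance:
            continue
        if gene.feature_id not in ids:
            continue
        gene_row = expr.row(gene.feature_id)
        r, _ = _pearson_rows(gene_row[None, :], linc_row)
        r = float(r[0])
        if np.isnan(r):
            continue
        p = float(pearson_correlation_pvalues(np.array([r]), n)[0])
        if p < alpha:
            out.append((gene, int(distance), r, p))
    out.sort(key=lambda t: t[1])
    return out
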