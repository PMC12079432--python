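"""Library-size and TMM normalization, filtering, and two-group tests.

The differential test is a moderated t-test on log2(CPM + 0.5): the
per-feature pooled variance is shrunk toward a common prior by the
empirical-Bayes moment estimator of Smyth's scaled-F fit, giving extra
denominator degrees of freedom at small n.  Fold changes come from
TMM-normalized mean CPM (prior count 0.5) and p-values are BH adjusted.
The test preserves the thresholded criterion |log2FC| > 1 and adjusted
p < 0.05 used throughout the downstream integration; it is not a
negative-binomial GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, Peak


@dataclass
class DifferentialResult:
    feature_id: str
    log2fc: float
    p: float
    adj_p: float
    status: str  # up | down | ns


def cpm(
    counts: CountMatrix | np.ndarray,
    factors: np.ndarray | None = None,
) -> np.ndarray:
    """Counts per million per sample, optionally under TMM scaling factors.

    cpm[f, s] = counts[f, s] / (libsize[s] * factor[s]) * 1e6.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    mat = np.asarray(mat, dtype=float)
    libsizes = mat.sum(axis=0)
    zero = np.flatnonzero(libsizes == 0)
    if zero.size:
        if isinstance(counts, CountMatrix):
            names = [counts.sample_ids[i] for i in zero]
        else:
            names = list(zero)
        raise ValueError(f"zero column sum for sample(s): {names}")
    if factors is None:
        factors = np.ones(mat.shape[1])
    return mat / (libsizes * np.asarray(factors, dtype=float)) * 1e6


def filter_expressed(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Keep features with CPM > ``min_cpm`` in at least ``min_samples``.

    CPM is computed on raw library sizes; feature order is preserved.
    """
    c = cpm(counts)
    keep = (c > min_cpm).sum(axis=1) >= min_samples
    return counts.subset_features(keep)


def tmm_factors(
    counts: CountMatrix | np.ndarray,
    ref_sample: str | int = "auto",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    Per sample, the factor is the weighted mean of log2 ratios versus a
    reference column after trimming the top/bottom ``trim_m`` of M-values
    and ``trim_a`` of A-values; weights are the inverse asymptotic
    variances of the log ratios.  The reference is the column whose 75th
    CPM percentile is closest to the mean of those percentiles.
    """
    if isinstance(counts, CountMatrix):
        mat = np.asarray(counts.counts, dtype=float)
        sample_ids = counts.sample_ids
    else:
        mat = np.asarray(counts, dtype=float)
        sample_ids = list(range(mat.shape[1]))
    n_samples = mat.shape[1]
    if n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    lib = mat.sum(axis=0)

    if ref_sample == "auto":
        q75 = np.percentile(mat / lib * 1e6, 75, axis=0)
        ref = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref = sample_ids.index(ref_sample)

    log2fac = np.zeros(n_samples)
    for s in range(n_samples):
        if s == ref:
            continue
        log2fac[s] = _tmm_pair(
            mat[:, s], mat[:, ref], lib[s], lib[ref], trim_m, trim_a
        )
    factors = 2.0 ** log2fac
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    pos = (obs > 0) & (ref > 0)
    if pos.sum() < 2:
        warnings.warn("fewer than 2 shared positive features; factor set to 1")
        return 0.0
    o, r = obs[pos], ref[pos]
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    # doubly trimmed: drop extreme M and extreme A ranks, keep intersection
    n = m.size
    m_rank = stats.rankdata(m, method="ordinal")
    a_rank = stats.rankdata(a, method="ordinal")
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    keep = (
        (m_rank >= lo_m)
        & (m_rank <= hi_m)
        & (a_rank >= lo_a)
        & (a_rank <= hi_a)
    )
    if not keep.any():
        return 0.0
    # edgeR convention: factor > 1 when the sample is *less* concentrated;
    # weighted mean of M with inverse-variance weights
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (ties keep input order)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorized)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-8 * y):
            break
    return y


def squeeze_variances(
    s2: np.ndarray, df: float
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-feature sample variances.

    Fits a scaled F prior to the observed variances by the moment method
    on log(s^2) (Smyth 2004) and returns (posterior variances, prior df
    d0, prior variance s0^2).  d0 = inf collapses every variance to the
    common value.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(np.where(ok, s2, np.nan))
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = np.nanmean(e)
    e_var = np.nanvar(e, ddof=1) - special.polygamma(1, df / 2)
    if not np.isfinite(e_var) or e_var <= 0:
        d0 = np.inf
        s0 = float(np.exp(e_mean))
        return np.full_like(s2, s0), d0, s0
    d0 = float(2.0 * _trigamma_inverse(e_var)[0])
    s0 = float(
        np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2))
    )
    post = (d0 * s0 + df * s2) / (d0 + df)
    return post, d0, s0


def differential_test(
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    prior_count: float = 0.5,
) -> list[DifferentialResult]:
    """Two-group differential test (condition B over A) with BH correction.

    log2FC = log2((mean CPM_B + prior) / (mean CPM_A + prior)) on
    TMM-normalized CPM; p-values from a moderated t on log2(CPM + prior)
    whose pooled per-feature variance is EB-shrunk (``squeeze_variances``),
    with denominator df = residual df + prior df.  Status is up/down when
    |log2FC| exceeds ``fc_threshold`` and the adjusted p-value falls below
    ``alpha``.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    for s in group_a + group_b:
        if s not in counts.sample_ids:
            raise KeyError(f"unknown sample {s}")
    factors = tmm_factors(counts)
    c = cpm(counts, factors)
    ia = [counts.sample_ids.index(s) for s in group_a]
    ib = [counts.sample_ids.index(s) for s in group_b]
    log_a = np.log2(c[:, ia] + prior_count)
    log_b = np.log2(c[:, ib] + prior_count)
    log2fc = np.log2(c[:, ib].mean(axis=1) + prior_count) - np.log2(
        c[:, ia].mean(axis=1) + prior_count
    )
    na, nb = len(ia), len(ib)
    df_resid = na + nb - 2
    if df_resid < 1:
        raise ValueError("need >= 2 samples per group for the t-test")
    s2 = (
        log_a.var(axis=1, ddof=1) * (na - 1)
        + log_b.var(axis=1, ddof=1) * (nb - 1)
    ) / df_resid
    s2_post, d0, _ = squeeze_variances(s2, df_resid)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    diff = log_b.mean(axis=1) - log_a.mean(axis=1)
    df_total = df_resid + d0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(p) | (se == 0), 1.0, p)
    adj = bh_adjust(p)
    results = []
    for i, fid in enumerate(counts.feature_ids):
        if log2fc[i] > fc_threshold and adj[i] < alpha:
            status = "up"
        elif log2fc[i] < -fc_threshold and adj[i] < alpha:
            status = "down"
        else:
            status = "ns"
        results.append(
            DifferentialResult(fid, float(log2fc[i]), float(p[i]),
                               float(adj[i]), status)
        )
    return results


def promoter_da_de_correlation(
    da: list[DifferentialResult],
    de: list[DifferentialResult],
    peaks: list[Peak],
    fc_threshold: float = 1.0,
) -> tuple[float, float, dict[str, int]]:
    """Promoter accessibility fold change versus transcript fold change.

    Pairs each promoter-annotated peak's accessibility log2FC with the
    log2FC of its closest gene's transcript.  Returns the Pearson r, its
    p-value, and quadrant counts restricted to pairs where both fold
    changes exceed ``fc_threshold`` in magnitude.
    """
    da_by_id = {r.feature_id: r for r in da}
    de_by_id = {r.feature_id: r for r in de}
    xs, ys = [], []
    for p in peaks:
        if p.annotation is None or p.annotation.value != "promoter":
            continue
        if p.id not in da_by_id or p.closest_gene not in de_by_id:
            continue
        xs.append(da_by_id[p.id].log2fc)
        ys.append(de_by_id[p.closest_gene].log2fc)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 promoter peak/gene pairs, got {len(xs)}")
    x, y = np.asarray(xs), np.asarray(ys)
    r, pval = stats.pearsonr(x, y)
    big = (np.abs(x) > fc_threshold) & (np.abs(y) > fc_threshold)
    quad = {
        "up_up": int(((x > 0) & (y > 0) & big).sum()),
        "up_down": int(((x > 0) & (y < 0) & big).sum()),
        "down_up": int(((x < 0) & (y > 0) & big).sum()),
        "down_down": int(((x < 0) & (y < 0) & big).sum()),
    }
    return float(r), float(pval), quad
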