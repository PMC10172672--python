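"""Normalization and differential testing for counts and methylation betas.

Counts (mRNA, miRNA) are scale-normalized by trimmed-mean-of-M-values factors
and tested gene-by-gene with an exact conditional negative-binomial test on
library-size-equalized pseudo-counts, with per-gene method-of-moments
dispersions shrunk toward the common dispersion. Methylation betas are tested
on the M-value scale (M = log2(beta/(1-beta))) with an empirical-Bayes
moderated t statistic whose prior (d0, s0^2) is moment-matched on log sample
variances.

Decision rules follow the conventions used throughout: genes are deregulated
at FDR < 0.01 with |logFC| > 1, probes at adjusted p < 0.01, miRNAs at
FDR < 0.05 with no fold-change threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import FeatureMatrix, ValidationError

logger = logging.getLogger(__name__)

_PHI_MIN = 1e-8
_PHI_MAX = 10.0


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, FeatureMatrix) else matrix


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix):
    """Force every sample to share the cross-sample mean quantile profile.

    Rows containing NA are dropped with a warning; ties within a sample map to
    the same (interpolated) reference value, which keeps the operation
    idempotent.
    """
    df = _as_frame(matrix)
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    na_rows = df.isna().any(axis=1)
    if na_rows.any():
        logger.warning("quantile_normalize: dropping %d rows with NA", int(na_rows.sum()))
        df = df.loc[~na_rows]
    arr = df.to_numpy(dtype=float)
    n = arr.shape[0]
    ref = np.sort(arr, axis=0).mean(axis=1)
    ranks = pd.DataFrame(arr).rank(method="average").to_numpy()
    out = np.interp(ranks, np.arange(1, n + 1), ref)
    result = pd.DataFrame(out, index=df.index, columns=df.columns)
    if isinstance(matrix, FeatureMatrix):
        return FeatureMatrix(result, kind=matrix.kind)
    return result


# ---------------------------------------------------------------------------
# TMM scale normalization
# ---------------------------------------------------------------------------

def scale_normalize_counts(
    counts, trim_m: float = 0.30, trim_a: float = 0.05
) -> tuple[pd.Series, pd.DataFrame]:
    """Trimmed-mean-of-M-values scale factors plus the normalized matrix.

    Per-gene log-ratios (M) to a reference sample are trimmed 30% on M and 5%
    on average abundance (A); the factor is 2^(mean of surviving M). Factors
    are rescaled to geometric mean 1. Normalized values are counts divided by
    the effective library size (library size x factor), put back on the counts
    scale by the geometric-mean effective library size.
    """
    df = _as_frame(counts)
    if df.shape[1] < 2:
        raise ValueError("scale normalization needs at least 2 samples")
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    lib = arr.sum(axis=0)
    if np.any(lib == 0):
        dead = list(df.columns[lib == 0])
        raise ValidationError(f"all-zero samples: {dead}")

    cpm = arr / lib
    uq = np.array([np.quantile(cpm[:, j][cpm[:, j] > 0], 0.75) if (cpm[:, j] > 0).any() else 0
                   for j in range(arr.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    r = cpm[:, ref_j]

    factors = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref_j:
            continue
        y = cpm[:, j]
        keep = (y > 0) & (r > 0)
        if keep.sum() < 10:
            logger.warning("TMM: sample %s shares <10 expressed genes with reference",
                           df.columns[j])
            continue
        m = np.log2(y[keep] / r[keep])
        a = 0.5 * np.log2(y[keep] * r[keep])
        m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
        sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if sel.any():
            factors[j] = 2.0 ** np.mean(m[sel])
    factors = factors / np.exp(np.mean(np.log(factors)))

    eff_lib = lib * factors
    scale = np.exp(np.mean(np.log(eff_lib)))
    normalized = pd.DataFrame(arr / eff_lib * scale, index=df.index, columns=df.columns)
    return pd.Series(factors, index=df.columns, name="tmm_factor"), normalized


# ---------------------------------------------------------------------------
# Exact conditional negative-binomial test
# ---------------------------------------------------------------------------

def _exact_nb_pvalue(xa: int, s: int, r_a: float, r_b: float) -> float:
    """Two-sided exact p for X_A = xa given X_A + X_B = s, where the group
    sums are NB with sizes r_a, r_b and a shared success probability (which
    cancels conditionally). p sums all outcomes no more probable than xa."""
    if s == 0:
        return 1.0
    x = np.arange(s + 1)
    logp = (
        special.gammaln(x + r_a) - special.gammaln(x + 1)
        + special.gammaln(s - x + r_b) - special.gammaln(s - x + 1)
    )
    logp -= special.logsumexp(logp)
    probs = np.exp(logp)
    return float(min(1.0, probs[probs <= probs[xa] * (1 + 1e-12)].sum()))


def _mom_dispersion(*arrays: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene method-of-moments dispersion components: returns (num, den)
    with phi_g = num/den, pooled over the given groups. Under NB,
    E[within-group var] = mu + phi mu^2, so num estimates phi * mu^2."""
    num = np.zeros(arrays[0].shape[0])
    den = np.zeros(arrays[0].shape[0])
    for arr in arrays:
        n = arr.shape[1]
        mu = arr.mean(axis=1)
        var = arr.var(axis=1, ddof=1)
        num += (n - 1) * (var - mu)
        den += (n - 1) * mu ** 2
    return num, den


def _shrunk_phi(num: np.ndarray, den: np.ndarray, d: int, prior_df: float) -> np.ndarray:
    """Shrink per-gene MoM dispersions toward the common (ratio-estimator)
    dispersion with prior_df worth of prior observations."""
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_gene = np.where(den > 0, num / den, 0.0)
    phi_common = max(float(num.sum() / den.sum()) if den.sum() > 0 else 0.0, 0.0)
    phi = (prior_df * phi_common + d * phi_gene) / (prior_df + d)
    return np.clip(phi, _PHI_MIN, _PHI_MAX)


def count_de_test(
    counts,
    group_a: list[str],
    group_b: list[str],
    fdr_threshold: float = 0.01,
    lfc_threshold: float = 1.0,
    normalize: bool = True,
    prior_df: float = 20.0,
    prior_count: float = 0.5,
    group_dispersion: str = "pooled",
) -> pd.DataFrame:
    """Exact conditional NB test of group A over group B.

    Counts are equalized to a common library size (TMM effective sizes when
    ``normalize``; as-is otherwise, for inputs already on a shared scale) and
    rounded to pseudo-counts. Per-gene dispersions are method-of-moments
    estimates shrunk toward the common dispersion with ``prior_df`` worth of
    prior observations; ``group_dispersion='max'`` estimates the shrunk
    dispersion per group and uses the larger one — appropriate when one group
    is noisier than the other (e.g. decontaminated profiles vs raw controls).
    Returns a feature-indexed frame with logFC (A over B,
    with a prior count of 0.5 per group), raw p, BH fdr, mean expression, and
    the decision flag fdr < fdr_threshold and |logFC| > lfc_threshold.
    """
    df = _as_frame(counts)
    missing = [s for s in list(group_a) + list(group_b) if s not in df.columns]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples to estimate dispersion")
    sub = df[list(group_a) + list(group_b)]

    if normalize:
        _, norm = scale_normalize_counts(sub)
    else:
        norm = sub.astype(float)
    pseudo = np.rint(norm.to_numpy()).astype(np.int64)
    na, nb = len(group_a), len(group_b)
    arr_a, arr_b = pseudo[:, :na], pseudo[:, na:]

    keep = (arr_a.sum(axis=1) + arr_b.sum(axis=1)) > 0
    features = norm.index[keep]
    arr_a, arr_b = arr_a[keep], arr_b[keep]

    d = na + nb - 2
    if group_dispersion == "pooled":
        phi = _shrunk_phi(*_mom_dispersion(arr_a, arr_b), d, prior_df)
    elif group_dispersion == "max":
        phi_a = _shrunk_phi(*_mom_dispersion(arr_a), na - 1, prior_df)
        phi_b = _shrunk_phi(*_mom_dispersion(arr_b), nb - 1, prior_df)
        phi = np.maximum(phi_a, phi_b)
    else:
        raise ValueError(f"unknown group_dispersion {group_dispersion!r}")

    mean_a = arr_a.mean(axis=1)
    mean_b = arr_b.mean(axis=1)
    logfc = np.log2(mean_a + prior_count) - np.log2(mean_b + prior_count)

    pvals = np.empty(arr_a.shape[0])
    for i in range(arr_a.shape[0]):
        xa, xb = int(arr_a[i].sum()), int(arr_b[i].sum())
        r_a, r_b = na / phi[i], nb / phi[i]
        pvals[i] = _exact_nb_pvalue(xa, xa + xb, r_a, r_b)

    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "mean_expr": (mean_a * na + mean_b * nb) / (na + nb),
            "p_value": pvals,
            "fdr": fdr,
            "significant": (fdr < fdr_threshold) & (np.abs(logfc) > lfc_threshold),
        },
        index=pd.Index(features, name="feature_id"),
    )


def mirna_de(
    counts,
    group_a: list[str],
    group_b: list[str],
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """miRNA differential expression: the count test at FDR < 0.05 and no
    fold-change threshold by default."""
    return count_de_test(
        counts, group_a, group_b,
        fdr_threshold=fdr_threshold, lfc_threshold=lfc_threshold, normalize=normalize,
    )


# ---------------------------------------------------------------------------
# Moderated-t methylation testing
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square variance prior (d0, s0^2)
    on log sample variances (empirical-Bayes squeezing)."""
    z = np.log(s2[np.isfinite(s2) & (s2 > 0)])
    if z.size < 10:
        raise ValueError("too few positive variances to fit a prior")
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    var_e = float(np.var(e, ddof=1))
    excess = var_e - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = float(np.exp(
            np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        ))
    return d0, s0_sq


def m_transform(beta: np.ndarray, epsilon: float = 1e-3) -> np.ndarray:
    """M = log2(beta / (1 - beta)) on betas clipped to [eps, 1 - eps]."""
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    return np.log2(b / (1.0 - b))


def dm_test(
    betas,
    group_a: list[str],
    group_b: list[str],
    epsilon: float = 1e-3,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Moderated-t differential methylation of group A vs B on M-values.

    Delta-beta is reported on the beta scale (mean A - mean B); the t statistic
    uses the empirical-Bayes posterior variance with d + d0 degrees of freedom.
    Probes with a whole group missing are dropped with a warning.
    """
    df = _as_frame(betas)
    missing = [s for s in list(group_a) + list(group_b) if s not in df.columns]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    beta_a = df[list(group_a)].to_numpy(dtype=float)
    beta_b = df[list(group_b)].to_numpy(dtype=float)

    whole_group_na = np.isnan(beta_a).all(axis=1) | np.isnan(beta_b).all(axis=1)
    if whole_group_na.any():
        logger.warning("dm_test: dropping %d probes with a whole group missing",
                       int(whole_group_na.sum()))
    any_na = np.isnan(beta_a).any(axis=1) | np.isnan(beta_b).any(axis=1)
    keep = ~(whole_group_na | any_na)
    if any_na.any() and not whole_group_na.all():
        logger.warning("dm_test: dropping %d probes with missing values",
                       int((any_na & ~whole_group_na).sum()))
    features = df.index[keep]
    beta_a, beta_b = beta_a[keep], beta_b[keep]

    m_a = m_transform(beta_a, epsilon)
    m_b = m_transform(beta_b, epsilon)
    na, nb = m_a.shape[1], m_b.shape[1]
    d = na + nb - 2
    diff_m = m_a.mean(axis=1) - m_b.mean(axis=1)
    s2 = (m_a.var(axis=1, ddof=1) * (na - 1) + m_b.var(axis=1, ddof=1) * (nb - 1)) / d

    try:
        d0, s0_sq = fit_variance_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = 1e6
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d + d0
    except ValueError:
        logger.warning("dm_test: variance prior not estimable, using unmoderated t")
        s2_post = s2
        df_total = d

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff_m / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (diff_m != 0), np.inf * np.sign(diff_m), t)
    pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    pvals = np.clip(pvals, 0.0, 1.0)
    fdr = bh_adjust(pvals)
    delta_beta = np.nanmean(beta_a, axis=1) - np.nanmean(beta_b, axis=1)
    direction = np.where(delta_beta > 0, "hyper", np.where(delta_beta < 0, "hypo", "none"))
    return pd.DataFrame(
        {
            "delta_beta": delta_beta,
            "t": t,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
            "significant": fdr < fdr_threshold,
        },
        index=pd.Index(features, name="probe_id"),
    )


def filter_tissue_bias_probes(
    liver_betas, colon_betas, tau: float = 0.2
) -> pd.Series:
    """Keep-mask over shared probes: drop probes whose mean beta differs
    between normal liver and control colon by more than tau (tissue markers
    that would masquerade as tumor methylation changes)."""
    liver = _as_frame(liver_betas)
    colon = _as_frame(colon_betas)
    shared = liver.index.intersection(colon.index)
    if shared.empty:
        raise ValueError("no shared probes between liver and colon matrices")
    diff = (liver.loc[shared].mean(axis=1) - colon.loc[shared].mean(axis=1)).abs()
    keep = diff <= tau
    logger.info("tissue-bias filter: dropping %d of %d probes",
                int((~keep).sum()), len(keep))
    keep.name = "keep"
    return keep
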