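"""Spike-in calibrated differential expression.

The count model is the standard negative-binomial one: gene ``g`` in sample
``i`` has ``K_gi ~ NB(mean = s_i * q_gc(i), dispersion alpha_g)`` where
``s_i`` is a per-sample size factor and ``q_gc`` a per-condition mean.  The
calibrated twist is where the size factors come from: instead of the target
gene counts (whose median-of-ratios silently removes any genome-wide shift),
they are computed from a parallel block of spike-in gene counts, after
dividing each sample's spike counts by its gDNA spike/target read ratio
``rho_i`` to cancel cell-mixing variation.  A genuine global change in
target transcription then survives normalization.

Testing is a two-group Wald test: per-condition means are size-factor
weighted averages (the exact NB maximum-likelihood estimate when size
factors are shared within condition, and the standard closed form
otherwise), with standard errors from the NB observed information and a
method-of-moments dispersion shrunk toward a mean-dispersion trend.
Benjamini-Hochberg controls FDR; reported fold changes are optionally
shrunk toward zero with an empirical-Bayes normal prior whose variance is
moment-matched from the MLE fold-change distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "prenormalize_spike",
    "size_factors_median_of_ratios",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "shrink_lfc",
    "classify_significance",
    "rpkm_and_threshold",
    "kde_valley",
    "run_calibrated_de",
]

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0


@dataclass
class CountMatrix:
    """Target and spike-in gene count blocks plus per-sample metadata.

    ``target``/``spike``: genes x samples integer counts on a shared sample
    axis; ``rho``: per-sample gDNA spike/target total-read ratio;
    ``conditions``: per-sample condition label (exactly two levels, the
    first level in order of appearance is the reference).
    """

    target: pd.DataFrame
    spike: pd.DataFrame
    rho: pd.Series
    conditions: pd.Series

    def __post_init__(self) -> None:
        samples = list(self.target.columns)
        for other, what in ((self.spike.columns, "spike block"),
                            (self.rho.index, "rho"),
                            (self.conditions.index, "conditions")):
            if list(other) != samples:
                raise ValueError(f"{what} samples do not match target block")
        if (self.target.to_numpy() < 0).any() or (self.spike.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.rho <= 0).any():
            raise ValueError("rho must be > 0")
        levels = pd.unique(self.conditions)
        if len(levels) != 2:
            raise ValueError("exactly two conditions required")
        if (self.conditions.value_counts() < 2).any():
            raise ValueError("need >= 2 replicates per condition")


def prenormalize_spike(spike: pd.DataFrame, rho: pd.Series) -> pd.DataFrame:
    """Divide each sample's spike-in counts by its gDNA mixing ratio.

    Doubling the spike-in cell input doubles both the spike counts and rho,
    so the quotient depends only on sequencing depth per target cell.
    """
    rho = rho.reindex(spike.columns)
    if (rho <= 0).any() or rho.isna().any():
        raise ValueError("rho must be > 0 for every sample")
    return spike / rho


def size_factors_median_of_ratios(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with nonzero counts in every sample, the size factor of sample
    ``i`` is the median of ``count_gi / geometric_mean_g``.
    """
    x = matrix.to_numpy(dtype=float)
    ok = (x > 0).all(axis=1)
    if not ok.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logx = np.log(x[ok])
    log_gm = logx.mean(axis=1, keepdims=True)
    # median taken on the ratios themselves (not their logs)
    sf = np.median(np.exp(logx - log_gm), axis=0)
    return pd.Series(sf, index=matrix.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame, size_factors: pd.Series, conditions: pd.Series
) -> pd.Series:
    """Per-gene NB dispersion: method of moments with empirical-Bayes
    shrinkage toward a mean-dispersion trend.

    The raw estimate is ``alpha = (v - mu) / mu^2`` on size-factor
    normalized counts, with ``v`` the within-condition pooled variance (so
    real condition effects do not inflate it).  Because the pooled variance
    carries only ``m = n - #conditions`` residual degrees of freedom, the
    log-scale estimate is biased by the Jensen offset of a chi-square with
    m df, ``log(m/2) - digamma(m/2)``, which is corrected before fitting.
    The trend is a log-log linear fit through bin-averaged raw estimates
    (linear-space bin means, so the fit targets the mean dispersion, not
    its downward-biased geometric mean).  The per-gene weight on the raw
    estimate is moment-matched: the sampling variance of the log estimate
    is ``trigamma(m/2)``, so genuine gene-to-gene dispersion spread is the
    excess of the observed log variance over that, and data whose spread is
    pure noise shrink fully to the trend — which also removes the
    selection effect of noisy small estimates producing small Wald errors.
    """
    from scipy.special import digamma, polygamma

    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    mu = norm.mean(axis=1)
    levels = pd.unique(conditions)
    num = np.zeros(len(norm))
    dof = 0
    for lev in levels:
        mask = (conditions == lev).to_numpy()
        n = int(mask.sum())
        num += norm[:, mask].var(axis=1, ddof=1) * (n - 1)
        dof += n - 1
    v = num / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (v - mu) / np.maximum(mu, 1e-300) ** 2, MIN_DISPERSION)
    raw = np.clip(raw, MIN_DISPERSION, MAX_DISPERSION)
    bias = float(np.log(dof / 2.0) - digamma(dof / 2.0))  # E[log] offset, chi2_m
    log_raw = np.log(raw) + bias
    fit_mask = (mu > 0) & (raw > MIN_DISPERSION * 10)
    log_mu = np.log(np.maximum(mu, 1e-300))
    if fit_mask.sum() >= 50 and np.std(log_mu[fit_mask]) > 0.1:
        # bin by mean, average raw dispersions in linear space per bin
        qs = np.quantile(log_mu[fit_mask], np.linspace(0, 1, 21))
        qs[-1] += 1e-9
        which = np.digitize(log_mu[fit_mask], qs) - 1
        xs, ys = [], []
        for b in range(20):
            sel = which == b
            if sel.sum() >= 5:
                xs.append(np.mean(log_mu[fit_mask][sel]))
                ys.append(np.log(np.mean(raw[fit_mask][sel])))
        slope, intercept = np.polyfit(xs, ys, 1)
        trend = np.exp(intercept + slope * log_mu)
    else:
        pool = raw[fit_mask] if fit_mask.any() else raw
        trend = np.full(len(raw), np.mean(pool))
    trend = np.clip(trend, MIN_DISPERSION, MAX_DISPERSION)
    log_trend = np.log(trend)
    # delta method: log((v - mu)/mu^2) amplifies the chi-square noise of v
    # by (1 + 1/(alpha*mu)); genes in the Poisson regime carry almost no
    # information about the dispersion and shrink fully to the trend
    base_var = float(polygamma(1, dof / 2.0))
    with np.errstate(divide="ignore"):
        amp = 1.0 + 1.0 / np.maximum(trend * mu, 1e-12)
    samp_var = np.minimum(base_var * amp**2, 1e6)
    resid2 = (log_raw - log_trend) ** 2
    sel = fit_mask if fit_mask.any() else np.ones(len(raw), dtype=bool)
    tau2 = max(float(np.mean(resid2[sel]) - np.mean(samp_var[sel])), 0.0)
    w = tau2 / (tau2 + samp_var)
    final = np.exp(log_trend + w * (log_raw - log_trend))
    return pd.Series(
        np.clip(final, MIN_DISPERSION, MAX_DISPERSION),
        index=counts.index,
        name="dispersion",
    )


def nb_wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    conditions: pd.Series,
    dispersions: Optional[pd.Series] = None,
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Two-group NB Wald test per gene; LFC is test condition over reference.

    Per-condition means are the NB maximum-likelihood estimates: Newton
    iterations on the score for ``log q_c``, started from the closed form
    ``sum(K_i) / sum(s_i)`` (already exact when size factors are equal
    within the condition, or when the dispersion is zero).  The Wald
    statistic is ``log2(q_B/q_A) / se`` with the standard error from the NB
    information ``I_c = sum_i s_i q_c / (1 + alpha s_i q_c)``, referred to a
    standard normal, two-sided.  Genes with zero counts everywhere get NA
    results and are excluded from multiple-testing correction downstream.
    A half-count continuity offset keeps the fold change finite when one
    condition is all-zero.
    """
    levels = list(pd.unique(conditions))
    if len(levels) != 2:
        raise ValueError("exactly two conditions required")
    if reference is None:
        reference = levels[0]
    test = [l for l in levels if l != reference][0]
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    K = counts.to_numpy(dtype=float)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, size_factors, conditions)
    alpha = dispersions.reindex(counts.index).to_numpy(dtype=float)
    mask_a = (conditions == reference).to_numpy()
    mask_b = (conditions == test).to_numpy()
    Ka, Kb = K[:, mask_a].sum(axis=1), K[:, mask_b].sum(axis=1)
    sa, sb = sf[mask_a].sum(), sf[mask_b].sum()
    def fit_group(Ksum: np.ndarray, mask: np.ndarray) -> np.ndarray:
        s_tot = sf[mask].sum()
        q = np.where(Ksum > 0, Ksum / s_tot, 0.5 / s_tot)
        Kg = K[:, mask]
        sg = sf[mask][None, :]
        for _ in range(5):  # Newton on the score for log q
            mu = sg * q[:, None]
            w = 1.0 + alpha[:, None] * mu
            score = ((Kg - mu) / w).sum(axis=1)
            curv = (mu / w).sum(axis=1)
            step = np.clip(score / np.maximum(curv, 1e-12), -2.0, 2.0)
            q = q * np.exp(step)
        return np.where(Ksum > 0, q, 0.5 / s_tot)

    qa = fit_group(Ka, mask_a)
    qb = fit_group(Kb, mask_b)
    lfc = np.log2(qb / qa)

    def info(q: np.ndarray, mask: np.ndarray) -> np.ndarray:
        mu = sf[mask][None, :] * q[:, None]  # genes x samples in group
        return (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)

    var_log = 1.0 / info(qa, mask_a) + 1.0 / info(qb, mask_b)
    se = np.sqrt(var_log) / np.log(2.0)
    z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    base_mean = (K / sf[None, :]).mean(axis=1)
    dead = (Ka == 0) & (Kb == 0)
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "lfc_mle": np.where(dead, np.nan, lfc),
            "se": np.where(dead, np.nan, se),
            "p": np.where(dead, np.nan, p),
        },
        index=counts.index,
    )
    return out


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NAs pass through and do not count toward the number of tests.  Enforced
    monotone nonincreasing from the largest p downward; capped at 1.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    x = arr[ok]
    if ((x < 0) | (x > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(x)
    if m == 0:
        return out
    order = np.argsort(x, kind="mergesort")
    ranked = x[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def shrink_lfc(lfc_mle: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, float]:
    """Empirical-Bayes normal-prior shrinkage of log2 fold changes.

    The prior is N(0, tau2); under it ``E[lfc_g^2] = tau2 + se_g^2``, so
    tau2 is matched to the upper tail of the observed MLE distribution,
    ``tau2 = max(q95(lfc^2 - se^2), 1e-6)`` — an upper-quantile match keeps
    the prior wide enough that genuine large effects (including a global
    shift shared by most genes) are not crushed toward zero, while pure
    noise still shrinks hard.  The posterior mean is
    ``lfc * tau2 / (tau2 + se^2)``.  Returns the shrunken vector and tau2.
    """
    lfc_mle = np.asarray(lfc_mle, dtype=float)
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(lfc_mle) & np.isfinite(se)
    if not ok.any():
        return np.full_like(lfc_mle, np.nan), 1e-6
    tau2 = max(float(np.percentile(lfc_mle[ok] ** 2 - se[ok] ** 2, 95)), 1e-6)
    shrunk = np.where(ok, lfc_mle * tau2 / (tau2 + se**2), np.nan)
    return shrunk, tau2


def classify_significance(
    padj: np.ndarray,
    lfc: np.ndarray,
    padj_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> np.ndarray:
    """up / down / no_change calls: padj < alpha and |fold change| > theta."""
    if padj_threshold <= 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    lfc_cut = np.log2(fc_threshold)
    padj = np.asarray(padj, dtype=float)
    lfc = np.asarray(lfc, dtype=float)
    sig = (padj < padj_threshold) & np.isfinite(lfc)
    return np.where(
        sig & (lfc > lfc_cut),
        "up",
        np.where(sig & (lfc < -lfc_cut), "down", "no_change"),
    )


def kde_valley(
    values: np.ndarray, grid_points: int = 512, min_prominence: float = 0.05
) -> float:
    """Local minimum of a Gaussian KDE between its two highest modes.

    Modes must have a prominence of at least ``min_prominence`` times the
    peak density, so sampling wiggles do not count.  Raises ``ValueError``
    when the density has fewer than two such modes (unimodal distributions
    have no valley to threshold at).
    """
    from scipy.signal import find_peaks

    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    kde = stats.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), grid_points)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=min_prominence * dens.max())
    if len(peaks) < 2:
        raise ValueError("density is unimodal: no valley between modes")
    top2 = peaks[np.argsort(dens[peaks])][-2:]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])


def rpkm_and_threshold(
    normalized_counts: pd.DataFrame,
    gene_lengths_bp: pd.Series,
    pseudocount: float = 1.0,
    fallback_threshold: Optional[float] = None,
) -> pd.DataFrame:
    """RPKM from replicate-averaged normalized counts, plus an expression
    threshold at the KDE valley of the log2(RPKM + 1) distribution.

    ``RPKM_g = mean_count_g / (length_kb_g * total_counts / 1e6)`` where the
    total is the summed replicate-averaged normalized counts.  The
    pseudocount is added to RPKM before the log2 transform.  If the log2
    distribution is unimodal the valley is undefined; a user-supplied
    fallback threshold is used with a warning (or an error if none given).

    Returns per-gene RPKM, log2 value, expressed flag; the threshold (on the
    RPKM scale) is stored in ``DataFrame.attrs["rpkm_threshold"]``.
    """
    lengths = gene_lengths_bp.reindex(normalized_counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for every gene")
    mean_counts = normalized_counts.mean(axis=1)
    total_millions = mean_counts.sum() / 1e6
    rpkm = mean_counts / ((lengths / 1000.0) * total_millions)
    log2val = np.log2(rpkm + pseudocount)
    try:
        valley = kde_valley(log2val.to_numpy())
        threshold = float(2.0**valley - pseudocount)
    except ValueError:
        if fallback_threshold is None:
            raise
        warnings.warn(
            "expression distribution is unimodal; using the supplied threshold"
        )
        threshold = float(fallback_threshold)
    out = pd.DataFrame(
        {"rpkm": rpkm, "log2_rpkm": log2val, "expressed": rpkm > threshold}
    )
    out.attrs["rpkm_threshold"] = threshold
    return out


def run_calibrated_de(
    cm: CountMatrix,
    padj_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    use_shrunk_for_fc: bool = True,
    gene_lengths_bp: Optional[pd.Series] = None,
    fallback_rpkm_threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Full calibrated DE pipeline on a :class:`CountMatrix`.

    Spike counts are prenormalized by the gDNA ratio, size factors come from
    the spike block by median of ratios and are applied to the target block;
    NB Wald tests, BH correction, normal-prior LFC shrinkage and
    significance classes follow.  When gene lengths are supplied, RPKM and
    the expressed flag are appended.
    """
    spike_pre = prenormalize_spike(cm.spike, cm.rho)
    sf = size_factors_median_of_ratios(spike_pre)
    res = nb_wald_test(cm.target, sf, cm.conditions)
    res["padj"] = bh_adjust(res["p"].to_numpy())
    shrunk, tau2 = shrink_lfc(res["lfc_mle"].to_numpy(), res["se"].to_numpy())
    res["lfc_shrunk"] = shrunk
    fc_basis = res["lfc_shrunk"] if use_shrunk_for_fc else res["lfc_mle"]
    res["sig_class"] = classify_significance(
        res["padj"].to_numpy(), fc_basis.to_numpy(), padj_threshold, fc_threshold
    )
    res.attrs["size_factors"] = sf
    res.attrs["prior_tau2"] = tau2
    if gene_lengths_bp is not None:
        norm = cm.target / sf
        expr = rpkm_and_threshold(
            norm, gene_lengths_bp, fallback_threshold=fallback_rpkm_threshold
        )
        res = res.join(expr)
        res.attrs["rpkm_threshold"] = expr.attrs["rpkm_threshold"]
    return res
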