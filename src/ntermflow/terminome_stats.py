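"""Differential abundance of N-terminal peptides between genotypes.

The test is an empirical-Bayes moderated two-sample t-test: per-terminus
sample variances s^2 (pooled, d residual degrees of freedom) are assumed
to follow a scaled F hierarchy, s^2 ~ s0^2 * F(d, d0).  The hyperparameters
(d0, s0^2) are estimated by moment matching of log s^2 and each terminus'
variance is shrunk to

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

with the moderated statistic t = log2FC / sqrt(s~^2 * (1/nA + 1/nB))
referred to a t distribution on d0 + d degrees of freedom.  Shrinkage buys
power at the small replicate numbers typical of proteomics (n = 4 per
genotype here).

A terminus is called significant when p < alpha AND |log2FC| > tau
(default tau = 0.58, a 50% change in abundance); no multiple-testing
correction is applied by default, with Benjamini-Hochberg available as an
option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from ntermflow.io_formats import AnalysisConfig, QuantTable

logger = logging.getLogger(__name__)


@dataclass
class ModeratedTestResult:
    """Result of one moderated two-sample comparison."""

    terminus_id: str
    log2fc: float  # mean(log2 A) - mean(log2 B)
    s2: float  # pooled sample variance
    s2_prior: float  # s0^2
    d0: float  # prior degrees of freedom (may be inf)
    s2_tilde: float  # shrunken variance
    t_mod: float
    df: float  # d0 + d
    p_value: float
    significant: bool = False
    skipped: bool = False
    skip_reason: str = ""


def _trigamma_inverse(y: float | np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is strictly decreasing on (0, inf) with range (0, inf), so the
    solution is unique.  Start from the large-x asymptote x ~ 1/y.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif / x) < tol):
            break
    return x


def fit_moderation(
    variances: Sequence[float] | np.ndarray, d: int
) -> tuple[float, float]:
    """Estimate prior degrees of freedom d0 and prior variance s0^2.

    Moment matching on z = log(s^2): under the scaled-F hierarchy,
    E[z] = log(s0^2) + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)
    and Var[z] = trigamma(d/2) + trigamma(d0/2).  The excess of the
    empirical variance of z over trigamma(d/2) identifies d0; at or below
    zero excess the prior is degenerate and d0 = inf with s0^2 the
    (bias-corrected) geometric mean variance.

    Parameters
    ----------
    variances : array-like
        Per-terminus pooled sample variances (non-positive and non-finite
        entries are dropped).
    d : int
        Residual degrees of freedom each variance was computed with.

    Returns
    -------
    (d0, s0_sq)
    """
    v = np.asarray(variances, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size == 0:
        raise ValueError(
            "all variances are zero or missing; add a pseudo-variance floor "
            "before moderation"
        )
    if v.size < 10:
        warnings.warn(
            f"only {v.size} finite positive variances; hyperparameter "
            "estimates will be unstable",
            stacklevel=2,
        )
    z = np.log(v)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    n = v.size
    # Unbiased variance of e, with a small-sample correction as in moment
    # matching of the log-F: subtract the sampling noise of the mean.
    e_var = float(np.var(z, ddof=1)) if n > 1 else 0.0
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        # degenerate zero-dispersion prior: under d0 = inf, E[s^2] = s0^2,
        # so the arithmetic mean is the natural estimate (exact when all
        # variances coincide)
        return np.inf, float(np.mean(v))
    d0 = float(2.0 * _trigamma_inverse(excess)[0])
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _pooled_stats(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Mean difference, pooled variance and residual df of two samples."""
    na, nb = a.size, b.size
    diff = float(np.mean(a) - np.mean(b))
    d = na + nb - 2
    ssa = float(np.sum((a - a.mean()) ** 2))
    ssb = float(np.sum((b - b.mean()) ** 2))
    s2 = (ssa + ssb) / d if d > 0 else np.nan
    return diff, s2, d


def moderated_t(
    term_a: Sequence[float] | np.ndarray,
    term_b: Sequence[float] | np.ndarray,
    d0: float,
    s0_sq: float,
    terminus_id: str = "",
    min_quant_reps: int = 2,
) -> ModeratedTestResult:
    """Moderated two-sample t-test on log2 intensities.

    Missing values (NaN) are dropped and reduce the residual degrees of
    freedom accordingly.  ``d0 = 0`` reproduces the ordinary pooled t-test;
    ``d0 = inf`` uses the prior variance s0^2 exactly (z-test against a
    normal reference in the limit).  A group with fewer than
    ``min_quant_reps`` present values yields a skipped result.
    """
    a = np.asarray(term_a, dtype=float)
    b = np.asarray(term_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < min_quant_reps or b.size < min_quant_reps:
        return ModeratedTestResult(
            terminus_id, np.nan, np.nan, s0_sq, d0, np.nan, np.nan, np.nan,
            np.nan, skipped=True,
            skip_reason=f"fewer than {min_quant_reps} quantified replicates in a group",
        )
    diff, s2, d = _pooled_stats(a, b)
    if np.isinf(d0):
        s2_tilde = s0_sq
        df = np.inf
    elif d0 == 0:
        s2_tilde = s2
        df = float(d)
    else:
        s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
        df = d0 + d
    se = np.sqrt(s2_tilde * (1.0 / a.size + 1.0 / b.size))
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(df) else 2.0 * stats.norm.sf(abs(t))
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return ModeratedTestResult(
        terminus_id, diff, s2, s0_sq, d0, float(s2_tilde), float(t), float(df), p
    )


def moderated_t_table(
    table: QuantTable,
    genotype_a: str,
    genotype_b: str,
    cfg: AnalysisConfig,
    log2_transform: bool = True,
) -> pd.DataFrame:
    """Moderated t-tests for every terminus of a quant table, one comparison.

    Intensities are log2-transformed (zeros already missing by the reading
    convention); hyperparameters are estimated from the pooled variances of
    all termini quantifiable in both groups.
    """
    cols_a = table.columns_for(genotype_a)
    cols_b = table.columns_for(genotype_b)
    mat_a = table.data[cols_a].to_numpy(dtype=float)
    mat_b = table.data[cols_b].to_numpy(dtype=float)
    if log2_transform:
        with np.errstate(divide="ignore", invalid="ignore"):
            mat_a, mat_b = np.log2(mat_a), np.log2(mat_b)

    na = np.isfinite(mat_a).sum(axis=1)
    nb = np.isfinite(mat_b).sum(axis=1)
    testable = (na >= cfg.min_quant_reps) & (nb >= cfg.min_quant_reps)
    if not testable.any():
        raise ValueError("no terminus quantifiable in both groups")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows are skipped below
        mean_a = np.nanmean(mat_a, axis=1)
        mean_b = np.nanmean(mat_b, axis=1)
        ssa = np.nansum((mat_a - mean_a[:, None]) ** 2, axis=1)
        ssb = np.nansum((mat_b - mean_b[:, None]) ** 2, axis=1)
    d = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(d > 0, (ssa + ssb) / np.maximum(d, 1), np.nan)
    d_typical = int(np.median(d[testable]))
    d0, s0_sq = fit_moderation(s2[testable], d_typical)

    diff = mean_a - mean_b
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.full(s2.shape, np.inf)
    else:
        s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
        t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf) * np.sign(diff + 1e-300))
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    df = pd.DataFrame(
        {
            "log2fc": np.where(testable, diff, np.nan),
            "s2": np.where(testable, s2, np.nan),
            "s2_tilde": np.where(testable, s2_tilde, np.nan),
            "t_mod": np.where(testable, t, np.nan),
            "df": np.where(testable, df_total, np.nan),
            "p_value": np.where(testable, p, np.nan),
            "skipped": ~testable,
        },
        index=table.data.index.rename("terminus_id"),
    )
    df["skip_reason"] = np.where(
        testable, "", f"fewer than {cfg.min_quant_reps} quantified replicates in a group"
    )
    df.attrs["d0"] = d0
    df.attrs["s0_sq"] = s0_sq
    return df


def significance_filter(
    results: pd.DataFrame, cfg: AnalysisConfig, bh_correct: bool = False
) -> pd.DataFrame:
    """Flag significant termini: p < alpha AND |log2FC| > tau.

    With ``bh_correct`` the p-values are replaced by Benjamini-Hochberg
    adjusted values before thresholding.  Adds columns ``significant`` and
    ``direction`` ('up', 'down' or '') and attrs ``n_up`` / ``n_down``.
    """
    out = results.copy()
    tested = ~out["skipped"].astype(bool) if "skipped" in out else out["p_value"].notna()
    p = out.loc[tested, "p_value"].to_numpy(dtype=float)
    if bh_correct and p.size:
        p = multipletests(p, method="fdr_bh")[1]
    crit = pd.Series(False, index=out.index)
    crit.loc[tested] = (p < cfg.alpha) & (
        np.abs(out.loc[tested, "log2fc"].to_numpy(dtype=float)) > cfg.log2fc_tau
    )
    out["significant"] = crit
    out["direction"] = ""
    out.loc[crit & (out["log2fc"] > 0), "direction"] = "up"
    out.loc[crit & (out["log2fc"] < 0), "direction"] = "down"
    out.attrs["n_up"] = int((out["direction"] == "up").sum())
    out.attrs["n_down"] = int((out["direction"] == "down").sum())
    return out


@dataclass
class CorrelationResult:
    """Pearson correlation of terminus vs parent-protein fold changes."""

    genotype_a: str
    genotype_b: str
    n: int
    r: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        assert -1.0 <= self.r <= 1.0
        assert self.ci_low <= self.r <= self.ci_high


def correlate_termini_protein(
    terminus_log2fc: Sequence[float] | pd.Series,
    protein_log2fc: Sequence[float] | pd.Series,
    genotype_a: str = "A",
    genotype_b: str = "B",
    confidence: float = 0.95,
) -> CorrelationResult:
    """Pearson r between matched terminus and protein fold changes.

    The confidence interval uses the Fisher z-transform,
    z = atanh(r) +/- z_crit / sqrt(n - 3).  Requires >= 3 matched pairs
    with both values present.
    """
    x = np.asarray(terminus_log2fc, dtype=float)
    y = np.asarray(protein_log2fc, dtype=float)
    if x.shape != y.shape:
        raise ValueError("fold-change vectors must be matched pairs")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 matched pairs, got {n}")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if n > 3 and abs(r) < 1.0:
        zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
        z = np.arctanh(r)
        half = zcrit / np.sqrt(n - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    else:
        lo = hi = r
    return CorrelationResult(genotype_a, genotype_b, n, r, lo, hi)


def volcano_table(
    results: pd.DataFrame, plastid_flags: Optional[pd.Series] = None
) -> pd.DataFrame:
    """One row per tested terminus: log2FC, -log10 p, significance class.

    ``plastid_flags`` (boolean, indexed by terminus id) highlights termini
    of plastid-located proteins, as in the study's volcano plots.
    """
    tested = (
        results[~results["skipped"].astype(bool)] if "skipped" in results else results
    )
    out = pd.DataFrame(
        {
            "log2fc": tested["log2fc"],
            "neg_log10_p": -np.log10(tested["p_value"]),
            "significant": tested.get("significant", False),
            "direction": tested.get("direction", ""),
        }
    )
    out["plastid"] = (
        plastid_flags.reindex(out.index, fill_value=False).astype(bool)
        if plastid_flags is not None
        else False
    )
    return out
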