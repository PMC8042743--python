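"""Label-free proteome differential analysis.

Pipeline: quantifiability filter (>= min_quant_reps present values in at
least one genotype) -> log2 transform -> per-sample downshifted-Gaussian
imputation of missing values -> one-way ANOVA across genotypes with
Benjamini-Hochberg FDR -> Tukey HSD post-hoc on the significant set ->
optional pairwise two-tailed t-tests -> z-score hierarchical clustering and
PCA of the significant proteins.

Imputation draws each missing cell of sample j from
N(mean_j - downshift * sd_j, (width * sd_j)^2), the downshifted-normal
strategy used for left-censored missingness in label-free proteomics
(missing values concentrate at low abundance, so imputed values are placed
in the low tail of the observed distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from ntermflow.io_formats import AnalysisConfig, QuantTable

logger = logging.getLogger(__name__)


def filter_quantifiable(table: QuantTable, cfg: AnalysisConfig) -> QuantTable:
    """Keep proteins quantified in >= min_quant_reps replicates of >= 1 genotype.

    Logs kept/dropped counts.  Raises if any genotype has fewer than two
    replicate columns (the rule is meaningless below that).
    """
    design = table.design
    for g in table.genotypes:
        if (design["genotype"] == g).sum() < 2:
            raise ValueError(f"genotype {g!r} has fewer than 2 replicates")
    keep = pd.Series(False, index=table.data.index)
    for g in table.genotypes:
        cols = table.columns_for(g)
        keep |= table.data[cols].notna().sum(axis=1) >= cfg.min_quant_reps
    kept = table.data[keep]
    logger.info(
        "quantifiability filter: kept %d of %d proteins (dropped %d)",
        keep.sum(), len(keep), (~keep).sum(),
    )
    out = QuantTable(data=kept.copy(), design=design)
    out.data.attrs["n_dropped"] = int((~keep).sum())
    return out


def log2_transform(table: QuantTable) -> QuantTable:
    """log2 of the intensity columns; annotation columns untouched."""
    data = table.data.copy()
    cols = list(table.design["sample"])
    with np.errstate(divide="ignore", invalid="ignore"):
        data[cols] = np.log2(data[cols].to_numpy(dtype=float))
    return QuantTable(data=data, design=table.design)


def impute_missing(
    table: QuantTable, cfg: AnalysisConfig, seed: Optional[int] = None
) -> tuple[QuantTable, pd.DataFrame]:
    """Per-sample downshifted-Gaussian imputation of missing log2 values.

    Each missing cell in sample column j is drawn from a Gaussian with
    mean = mean_j - impute_downshift * sd_j and sd = impute_width * sd_j,
    where mean_j/sd_j are computed from the observed values of that column.
    Columns with fewer than 3 observed values fall back to the global mean
    and SD with a warning.  Deterministic given ``seed``.

    Returns the completed table and a boolean mask of imputed cells.
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    data = table.data.copy()
    cols = list(table.design["sample"])
    values = data[cols].to_numpy(dtype=float)
    all_obs = values[np.isfinite(values)]
    if all_obs.size == 0:
        raise ValueError("no observed values to impute from")
    g_mean, g_sd = float(all_obs.mean()), float(all_obs.std(ddof=1)) if all_obs.size > 1 else 0.0
    mask = pd.DataFrame(False, index=data.index, columns=cols)
    for j, col in enumerate(cols):
        colvals = values[:, j]
        miss = ~np.isfinite(colvals)
        if not miss.any():
            continue
        obs = colvals[~miss]
        if obs.size < 3:
            logger.warning(
                "sample %s has %d observed values; using global imputation parameters",
                col, obs.size,
            )
            mu, sd = g_mean, g_sd
        else:
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        draw = rng.normal(
            loc=mu - cfg.impute_downshift * sd,
            scale=cfg.impute_width * sd,
            size=int(miss.sum()),
        )
        colvals[miss] = draw
        values[:, j] = colvals
        mask.loc[miss, col] = True
    data[cols] = values
    return QuantTable(data=data, design=table.design), mask


def anova_bh(table: QuantTable, cfg: AnalysisConfig) -> pd.DataFrame:
    """One-way fixed-effects ANOVA across genotypes with BH step-up q-values.

    Returns a frame with columns ``anova_p``, ``anova_q``, ``significant``
    (q < fdr_q), indexed like the input.  q-values are computed with the
    standard step-up procedure (cumulative minimum of m*p/rank from the
    largest p down), which keeps them monotone in p.
    """
    groups = [table.data[table.columns_for(g)].to_numpy(dtype=float) for g in table.genotypes]
    f, p = stats.f_oneway(*groups, axis=1)
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    out = pd.DataFrame(
        {"anova_F": f, "anova_p": p, "anova_q": q, "significant": q < cfg.fdr_q},
        index=table.data.index,
    )
    return out


def tukey_hsd(
    table: QuantTable,
    significant: Sequence[str] | pd.Index,
    cfg: AnalysisConfig,
    compute_p: bool = False,
) -> pd.DataFrame:
    """Tukey honest-significant-difference post-hoc per genotype pair.

    Applied only to ANOVA-significant proteins.  For each protein, the
    studentized range statistic of each pair,
    q_ij = |mean_i - mean_j| / sqrt(MSE / n), is referred to the
    studentized-range distribution with k groups and N - k error degrees
    of freedom (unequal group sizes use the Tukey-Kramer harmonic mean).
    A pair is flagged at family-wise alpha = cfg.alpha when q_ij exceeds
    the upper critical value q(alpha; k, df); per-pair p-values (slow, the
    distribution is evaluated by numerical integration) are added only
    with ``compute_p``.
    """
    genos = table.genotypes
    k = len(genos)
    pairs = [(genos[i], genos[j]) for i in range(k) for j in range(i + 1, k)]
    sub = table.data.loc[list(significant)]
    if sub.empty:
        return pd.DataFrame(index=pd.Index([], name="accession"))
    mats = [sub[table.columns_for(g)].to_numpy(dtype=float) for g in genos]
    ns = np.stack([np.isfinite(m).sum(axis=1) for m in mats], axis=1)  # (p, k)
    means = np.stack([np.nanmean(m, axis=1) for m in mats], axis=1)
    sse = np.stack(
        [np.nansum((m - mu[:, None]) ** 2, axis=1) for m, mu in zip(mats, means.T)],
        axis=1,
    ).sum(axis=1)
    df_err = ns.sum(axis=1) - k
    mse = np.where(df_err > 0, sse / np.maximum(df_err, 1), np.nan)

    out = pd.DataFrame(index=sub.index)
    out.index.name = "accession"
    # one critical value per distinct error df (df varies only with missingness)
    crit = {d: float(stats.studentized_range.isf(cfg.alpha, k, d)) for d in np.unique(df_err) if d > 0}
    qcrit = np.array([crit.get(d, np.nan) for d in df_err])
    for idx, (a, b) in enumerate(pairs):
        ia, ib = genos.index(a), genos.index(b)
        n_eff = 2.0 / (1.0 / ns[:, ia] + 1.0 / ns[:, ib])  # Tukey-Kramer
        diff = np.abs(means[:, ia] - means[:, ib])
        se = np.sqrt(mse / n_eff)
        with np.errstate(divide="ignore", invalid="ignore"):
            qstat = np.where(se > 0, diff / se, np.where(diff > 0, np.inf, 0.0))
        out[f"tukey_q_{a}_vs_{b}"] = qstat
        out[f"tukey_flag_{a}_vs_{b}"] = qstat > qcrit
        if compute_p:
            out[f"tukey_p_{a}_vs_{b}"] = [
                float(stats.studentized_range.sf(q, k, d)) if d > 0 else np.nan
                for q, d in zip(qstat, df_err)
            ]
    return out


def pairwise_t_flags(
    table: QuantTable, cfg: AnalysisConfig, pooled: bool = True
) -> pd.DataFrame:
    """Two-tailed two-sample t-tests per genotype pair (default pooled).

    Mirrors candidate-table style per-pair significance columns.  Proteins
    with fewer than ``min_quant_reps`` present values in a group get NaN p
    and an unset flag for that pair.
    """
    genos = table.genotypes
    pairs = [(genos[i], genos[j]) for i in range(len(genos)) for j in range(i + 1, len(genos))]
    out = pd.DataFrame(index=table.data.index)
    for a, b in pairs:
        xa = table.data[table.columns_for(a)].to_numpy(dtype=float)
        xb = table.data[table.columns_for(b)].to_numpy(dtype=float)
        na = np.isfinite(xa).sum(axis=1)
        nb = np.isfinite(xb).sum(axis=1)
        res = stats.ttest_ind(
            xa, xb, axis=1, equal_var=pooled, nan_policy="omit"
        )
        p = np.asarray(res.pvalue, dtype=float)
        p[(na < cfg.min_quant_reps) | (nb < cfg.min_quant_reps)] = np.nan
        out[f"t_p_{a}_vs_{b}"] = p
        out[f"t_flag_{a}_vs_{b}"] = p < cfg.alpha
    return out


def zscore(table: QuantTable, proteins: Sequence[str] | pd.Index) -> pd.DataFrame:
    """Per-protein z-scores across all samples (mean 0, SD 1 per row)."""
    cols = list(table.design["sample"])
    mat = table.data.loc[list(proteins), cols].to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0  # flat profiles stay at zero
    return pd.DataFrame((mat - mu) / sd, index=list(proteins), columns=cols)


def zscore_cluster(
    table: QuantTable,
    significant: Sequence[str] | pd.Index,
    cfg: AnalysisConfig,
) -> tuple[pd.Series, pd.DataFrame]:
    """Hierarchical clustering of z-scored abundance profiles.

    Agglomerative, Euclidean distance, average linkage; the tree is cut
    into ``cfg.n_clusters_k`` clusters.  Returns per-protein cluster ids
    (1-based, relabelled in decreasing cluster size) and the per-cluster
    mean z-score profile.
    """
    z = zscore(table, significant)
    if len(z) == 0:
        return pd.Series(dtype=int), pd.DataFrame(columns=z.columns)
    k = min(cfg.n_clusters_k, len(z))
    if len(z) == 1 or k == 1:
        ids = pd.Series(1, index=z.index)
    else:
        tree = linkage(z.to_numpy(), method="average", metric="euclidean")
        raw = fcluster(tree, t=k, criterion="maxclust")
        # relabel so cluster 1 is the largest
        sizes = pd.Series(raw).value_counts()
        remap = {old: new + 1 for new, old in enumerate(sizes.index)}
        ids = pd.Series([remap[c] for c in raw], index=z.index)
    profiles = z.groupby(ids).mean()
    profiles.index.name = "cluster_id"
    return ids, profiles


def pca_coordinates(
    table: QuantTable, significant: Sequence[str] | pd.Index, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the first principal components of the z-scored matrix.

    Samples are observations, proteins are features.  Returns the score
    frame (one row per sample, with genotype annotation) and the explained
    variance ratios.
    """
    z = zscore(table, significant)
    x = z.to_numpy().T  # samples x proteins
    n_components = min(n_components, min(x.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x - x.mean(axis=0, keepdims=True))
    frame = pd.DataFrame(
        scores, index=z.columns, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    frame["genotype"] = [
        table.design.set_index("sample").loc[s, "genotype"] for s in frame.index
    ]
    return frame, pca.explained_variance_ratio_


@dataclass
class ProteomeResults:
    """Bundle of all per-protein proteome outcomes."""

    filtered: QuantTable
    completed: QuantTable
    imputed_mask: pd.DataFrame
    anova: pd.DataFrame
    tukey: pd.DataFrame
    pairwise_t: pd.DataFrame
    cluster_ids: pd.Series
    cluster_profiles: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = self.completed.data.join(self.anova)
        out = out.join(self.tukey, how="left")
        out = out.join(self.pairwise_t, how="left")
        out["cluster_id"] = self.cluster_ids.reindex(out.index)
        return out


def run_proteome_pipeline(
    table: QuantTable, cfg: AnalysisConfig, seed: Optional[int] = None
) -> ProteomeResults:
    """Full proteome workflow: filter -> log2 -> impute -> ANOVA/BH -> Tukey
    -> pairwise t -> cluster."""
    filtered = filter_quantifiable(table, cfg)
    logged = log2_transform(filtered)
    completed, mask = impute_missing(logged, cfg, seed=seed)
    anova = anova_bh(completed, cfg)
    sig = anova.index[anova["significant"]]
    tukey = tukey_hsd(completed, sig, cfg)
    pt = pairwise_t_flags(completed, cfg)
    ids, profiles = zscore_cluster(completed, sig, cfg)
    return ProteomeResults(filtered, completed, mask, anova, tukey, pt, ids, profiles)
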