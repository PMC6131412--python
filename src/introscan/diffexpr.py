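"""Differential-transcription analysis of gene-level count matrices.

Implements the genotype-contrast workflow: CPM filtering of
transcribed genes, TMM between-sample normalization, profile-likelihood NB
dispersion estimation with tagwise shrinkage, a per-gene NB log-linear model
with a likelihood-ratio test of the group factor, BH FDR control and
up/down/not-DT class labelling, plus CPM/FPKM conversion, FPKM binning and
Table-style contrast summaries.

The NB test is a from-scratch stand-in for the GLM route of edgeR: identical
model family (log mean linear in the group factor, offset by the effective
library size) but validated by simulation properties rather than
bit-compatibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from .stats import bh_adjust, nb_loglik

logger = logging.getLogger(__name__)

DT_CLASSES = ("up", "down", "not_DT")
DEFAULT_LOGFC_PSEUDO = 0.125


@dataclass
class CountMatrix:
    """Raw gene-level counts (genes x samples) with sample metadata.

    ``samples`` is indexed by sample id and must carry ``group`` and
    ``replicate`` columns; its index must match the count columns exactly.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample metadata index must match count columns")
        if "group" not in self.samples.columns:
            raise ValueError("samples table must have a 'group' column")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.samples["group"]))

    def samples_of(self, group: str) -> pd.Index:
        if group not in set(self.samples["group"]):
            raise KeyError(f"unknown group label {group!r}")
        return self.samples.index[self.samples["group"] == group]

    def subset_groups(self, groups) -> "CountMatrix":
        keep = self.samples.index[self.samples["group"].isin(groups)]
        return CountMatrix(self.counts[keep], self.samples.loc[keep])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.samples)

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM factors; effective size = product."""

    lib_size: pd.Series
    factor: pd.Series

    def __post_init__(self) -> None:
        if (self.factor <= 0).any():
            raise ValueError("TMM factors must be > 0")

    @property
    def effective(self) -> pd.Series:
        return self.lib_size * self.factor


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """Log2 TMM factor of one sample against the reference sample."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        logger.warning("TMM: no co-expressed genes with reference; factor set to 1")
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M, used as precision weight
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = sps.rankdata(m)
    rank_a = sps.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        logger.warning("TMM: trimming removed all genes; factor set to 1")
        return 0.0
    wk = 1.0 / np.maximum(w[keep], 1e-12)
    f = float(np.sum(wk * m[keep]) / np.sum(wk))
    return 0.0 if not np.isfinite(f) else f


def tmm_factors(
    matrix: CountMatrix,
    reference: str | None = None,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample against a reference, gene-wise log2 expression ratios (M)
    and average log intensities (A) are computed over co-expressed genes; the
    most extreme 30% of M (each tail) and 5% of A are discarded, and the
    factor is 2 to the precision-weighted mean of the retained M values.
    Factors are rescaled so their geometric mean is 1.

    ``reference`` names the reference sample; by default the sample whose
    75th count-fraction percentile is closest to the across-sample mean.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("TMM: sample with zero library size")
    if reference is None:
        uq = np.percentile(counts / lib, 75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(matrix.counts.columns).index(reference)

    log_factors = np.array(
        [
            _tmm_pair_factor(
                counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx],
                logratio_trim, abs_trim,
            )
            for j in range(counts.shape[1])
        ]
    )
    factors = 2.0 ** (log_factors - log_factors.mean())
    return NormFactors(
        lib_size=pd.Series(lib, index=matrix.counts.columns),
        factor=pd.Series(factors, index=matrix.counts.columns),
    )


# ---------------------------------------------------------------------------
# CPM / FPKM


def cpm(matrix: CountMatrix, factors: NormFactors) -> pd.DataFrame:
    """Counts per million, normalized by the effective library size."""
    eff = factors.effective.reindex(matrix.counts.columns)
    if (eff <= 0).any():
        raise ValueError("effective library sizes must be > 0")
    return matrix.counts / eff * 1.0e6


def fpkm(matrix: CountMatrix, factors: NormFactors, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million: count x 1e9 / (effective size x length)."""
    missing = matrix.counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise ValueError(f"missing gene lengths for: {sorted(missing)[:10]}")
    lengths = lengths.reindex(matrix.counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    eff = factors.effective.reindex(matrix.counts.columns)
    return matrix.counts * 1.0e9 / eff / lengths.to_numpy()[:, None]


def group_means(table: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Average a per-sample table (CPM or FPKM) within each sample group."""
    return table.T.groupby(samples["group"]).mean().T


def filter_transcribed(
    matrix: CountMatrix,
    factors: NormFactors,
    group_a: str,
    group_b: str,
    threshold: float = 1.0,
) -> pd.Index:
    """Genes with group-mean CPM strictly above ``threshold`` in >=1 group."""
    table = cpm(matrix, factors)
    mean_a = table[matrix.samples_of(group_a)].mean(axis=1)
    mean_b = table[matrix.samples_of(group_b)].mean(axis=1)
    return matrix.counts.index[(mean_a > threshold) | (mean_b > threshold)]


# ---------------------------------------------------------------------------
# dispersion estimation


@dataclass
class DispersionEstimates:
    common: float
    tagwise: pd.Series


def _nb_ll_per_gene(z: np.ndarray, groups_idx: list, alpha: float) -> np.ndarray:
    """Per-gene NB log-likelihood at dispersion ``alpha``.

    ``z`` are library-size-equalized pseudo-counts, so within each group the
    MLE of the mean is the sample mean at any dispersion; a Cox–Reid term
    (−0.5 log of the per-group Fisher information) corrects for profiling
    out the group means.
    """
    total = np.zeros(z.shape[0])
    for idx in groups_idx:
        zg = z[:, idx]
        mu = zg.mean(axis=1)
        total += nb_loglik(zg, mu[:, None], alpha).sum(axis=1)
        pos = mu > 0
        info = len(idx) / (mu[pos] + alpha * mu[pos] ** 2)
        total[pos] -= 0.5 * np.log(info)
    return total


def estimate_dispersion(
    matrix: CountMatrix,
    prior_df: float = 20.0,
    grid: np.ndarray | None = None,
) -> DispersionEstimates:
    """Common and tagwise NB dispersions by profile likelihood.

    The common value maximizes the summed (Cox–Reid adjusted) profile
    log-likelihood across genes; tagwise values maximize the gene's own
    likelihood plus ``prior_df / residual_df`` times the average likelihood,
    shrinking noisy per-gene estimates toward the common one.  Estimates are
    floored at 1e-6.
    """
    group_labels = matrix.groups
    groups_idx = [
        [matrix.counts.columns.get_loc(s) for s in matrix.samples_of(g)]
        for g in group_labels
    ]
    if all(len(idx) < 2 for idx in groups_idx):
        raise ValueError(
            "dispersion estimation needs >=2 replicates in some group; "
            "supply a fixed dispersion instead"
        )
    counts = matrix.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if not (lib > 0).all():
        raise ValueError("sample with zero library size")
    geo = np.exp(np.mean(np.log(lib)))
    z = counts * (geo / lib)[None, :]

    if grid is None:
        grid = np.geomspace(1e-6, 10.0, 81)
    ll = np.stack([_nb_ll_per_gene(z, groups_idx, a) for a in grid], axis=1)
    ll_sum = ll.sum(axis=0)
    best = int(np.argmax(ll_sum))

    def neg_total(log_a: float) -> float:
        return -_nb_ll_per_gene(z, groups_idx, float(np.exp(log_a))).sum()

    lo = np.log(grid[max(best - 1, 0)])
    hi = np.log(grid[min(best + 1, len(grid) - 1)])
    if lo < hi:
        res = minimize_scalar(neg_total, bounds=(lo, hi), method="bounded")
        common = float(np.exp(res.x))
    else:
        common = float(grid[best])
    common = max(common, 1e-6)

    df_resid = max(counts.shape[1] - len(group_labels), 1)
    prior_n = prior_df / df_resid
    weighted = ll + prior_n * ll.mean(axis=0)[None, :]
    tagwise_vals = np.maximum(grid[np.argmax(weighted, axis=1)], 1e-6)
    tagwise = pd.Series(tagwise_vals, index=matrix.counts.index)
    return DispersionEstimates(common=common, tagwise=tagwise)


# ---------------------------------------------------------------------------
# the NB group-factor test


def _nb_ll_rows(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood with a per-gene dispersion vector."""
    from scipy.special import gammaln

    r = 1.0 / np.maximum(alpha, 1e-10)[:, None]
    out = np.zeros_like(mu)
    pos = mu > 0
    yv = np.broadcast_to(y, mu.shape)
    rv = np.broadcast_to(r, mu.shape)
    out[pos] = (
        gammaln(yv[pos] + rv[pos])
        - gammaln(rv[pos])
        - gammaln(yv[pos] + 1.0)
        + rv[pos] * np.log(rv[pos] / (rv[pos] + mu[pos]))
        + yv[pos] * np.log(mu[pos] / (rv[pos] + mu[pos]))
    )
    out[~pos & (yv > 0)] = -np.inf
    return out


def _fit_group_mu(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, max_iter: int = 80
):
    """MLE of a single NB mean-per-unit-library for each gene row.

    Model: counts ~ NB(mu * s_j, alpha_gene).  Newton iteration on log mu;
    rows that are all zero get mu = 0 with log-likelihood 0 (the NB point
    mass at zero).  Returns (mu, loglik, converged).
    """
    n_genes = y.shape[0]
    tot = y.sum(axis=1)
    mu = np.zeros(n_genes)
    ll = np.zeros(n_genes)
    converged = np.ones(n_genes, dtype=bool)
    active = tot > 0
    if not active.any():
        return mu, ll, converged

    ya = y[active]
    aa = alpha[active][:, None]
    u = np.log(tot[active] / s.sum())
    for _ in range(max_iter):
        m = np.exp(u)[:, None] * s[None, :]
        common = (1.0 + aa * ya) / (1.0 + aa * m)
        score = (ya - m * common).sum(axis=1)
        info = (m * common / (1.0 + aa * m)).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -5.0, 5.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    m = np.exp(u)[:, None] * s[None, :]
    final_score = (ya - m * (1.0 + aa * ya) / (1.0 + aa * m)).sum(axis=1)
    conv_a = np.abs(final_score) <= 1e-4 * (1.0 + ya.sum(axis=1))
    mu[active] = np.exp(u)
    ll[active] = _nb_ll_rows(ya, m, alpha[active]).sum(axis=1)
    converged[active] = conv_a
    return mu, ll, converged


def test_dt(
    matrix: CountMatrix,
    factors: NormFactors,
    dispersions,
    group_ref: str,
    group_test: str,
    alpha: float = 0.05,
    logfc_pseudo: float = DEFAULT_LOGFC_PSEUDO,
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of the group factor.

    For each gene a negative-binomial model with log mean linear in the group
    factor and an offset for the effective library size is fitted twice (with
    and without the group term); twice the log-likelihood difference is
    referred to chi-square with 1 df.  P-values are BH-adjusted across the
    tested genes and classes assigned at FDR ``alpha``: ``up`` (q < alpha,
    logFC > 0, i.e. higher in ``group_test``), ``down`` (q < alpha,
    logFC < 0) or ``not_DT``.

    logFC is log2 of the ratio of normalized group means with a pseudo-count
    of ``logfc_pseudo`` added to each mean, so genes silent in one group get
    a large but finite logFC.  Non-converged fits are reported with p = 1 and
    logged, never dropped silently.

    ``dispersions`` may be a ``DispersionEstimates`` (tagwise values are
    used), a per-gene Series, or a scalar.
    """
    for g in (group_ref, group_test):
        if len(matrix.samples_of(g)) < 2:
            raise ValueError(f"group {g!r} needs >=2 replicates")
    cols_ref = matrix.samples_of(group_ref)
    cols_test = matrix.samples_of(group_test)
    cols = cols_ref.append(cols_test)
    y = matrix.counts[cols].to_numpy(dtype=float)
    eff = factors.effective.reindex(cols).to_numpy(dtype=float)
    if (eff <= 0).any():
        raise ValueError("effective library sizes must be > 0")
    # offsets scaled to the geometric-mean library so mu is on a count scale
    geo = np.exp(np.mean(np.log(eff)))
    s = eff / geo

    genes = matrix.counts.index
    if isinstance(dispersions, DispersionEstimates):
        disp = dispersions.tagwise.reindex(genes).to_numpy(dtype=float)
    elif np.isscalar(dispersions):
        disp = np.full(len(genes), float(dispersions))
    else:
        disp = pd.Series(dispersions).reindex(genes).to_numpy(dtype=float)
    if np.any(~np.isfinite(disp)) or np.any(disp < 0):
        raise ValueError("dispersions must be finite and >= 0")
    disp = np.maximum(disp, 1e-6)

    n_ref = len(cols_ref)
    mu_ref, ll_ref, conv_ref = _fit_group_mu(y[:, :n_ref], s[:n_ref], disp)
    mu_test, ll_test, conv_test = _fit_group_mu(y[:, n_ref:], s[n_ref:], disp)
    _, ll_null, conv_null = _fit_group_mu(y, s, disp)

    lrt = np.maximum(2.0 * (ll_ref + ll_test - ll_null), 0.0)
    pvalues = sps.chi2.sf(lrt, df=1)

    bad = ~(conv_ref & conv_test & conv_null)
    if bad.any():
        logger.warning(
            "test_dt: %d gene fits did not converge; their p-values set to 1 (%s%s)",
            int(bad.sum()),
            ", ".join(map(str, genes[bad][:5])),
            "..." if bad.sum() > 5 else "",
        )
        pvalues[bad] = 1.0

    logfc = np.log2((mu_test + logfc_pseudo) / (mu_ref + logfc_pseudo))
    qvalues = bh_adjust(pvalues)
    cls = np.where(
        (qvalues < alpha) & (logfc > 0),
        "up",
        np.where((qvalues < alpha) & (logfc < 0), "down", "not_DT"),
    )
    return pd.DataFrame(
        {
            "logFC": logfc,
            "pvalue": pvalues,
            "qvalue": qvalues,
            "dt_class": cls,
        },
        index=genes,
    )


# ---------------------------------------------------------------------------
# summaries


def summarize_contrast(dt: pd.DataFrame) -> dict:
    """Counts and percentages of the DT classes among transcribed genes.

    Percentages are of the transcribed total, rounded to 2 decimals, so the
    output mirrors the standard contrast-table layout.
    """
    n = len(dt)
    n_up = int((dt["dt_class"] == "up").sum())
    n_down = int((dt["dt_class"] == "down").sum())
    n_not = int((dt["dt_class"] == "not_DT").sum())
    n_dt = n_up + n_down

    def pct(k: int) -> float:
        return round(100.0 * k / n, 2) if n else 0.0

    return {
        "transcribed": n,
        "not_DT": n_not,
        "DT": n_dt,
        "up": n_up,
        "down": n_down,
        "pct_not_DT": pct(n_not),
        "pct_DT": pct(n_dt),
        "pct_up": pct(n_up),
        "pct_down": pct(n_down),
    }


def count_silenced(
    fpkm_table: pd.DataFrame, samples: pd.DataFrame, group: str
) -> pd.Index:
    """Genes with FPKM exactly zero in every replicate of ``group``."""
    cols = samples.index[samples["group"] == group]
    if len(cols) == 0:
        raise ValueError(f"group {group!r} has no samples")
    sub = fpkm_table[cols]
    return fpkm_table.index[(sub == 0).all(axis=1)]


NOT_DETECTABLE = "not_detectable"


def expression_bins(values: pd.Series, edges=(1.0, 5.0, 20.0)):
    """Assign half-open abundance bins ``[e_i, e_{i+1})`` to FPKM values.

    Values below the first edge are labelled ``not_detectable``; the last bin
    is open-ended.  Returns ``(labels, counts)``.
    """
    edges = list(edges)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly increasing")
    if (np.asarray(values) < 0).any():
        raise ValueError("FPKM values must be non-negative")
    labels = [NOT_DETECTABLE]
    for i in range(len(edges) - 1):
        labels.append(f"{edges[i]:g}-{edges[i + 1]:g}")
    labels.append(f">={edges[-1]:g}")
    cut = pd.cut(
        values,
        bins=[-np.inf] + edges + [np.inf],
        labels=labels,
        right=False,
    )
    counts = cut.value_counts().reindex(labels).astype(int)
    return cut, counts
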