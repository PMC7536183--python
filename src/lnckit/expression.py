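"""Sample/gene expression filters and TMM-normalized log2-CPM.

Implements the pre-processing applied before per-tissue association
analyses: samples with fewer than 10⁶ reads assigned to genes are dropped;
genes are kept only when TPM > 0.50 in at least 20% of samples and raw
counts exceed a biotype-specific threshold (> 2 for protein-coding, > 1 for
non-coding) in at least 20% of samples; between-sample scaling uses trimmed
mean of M-values (TMM) factors, and counts become
log2((count + 0.5) / (effective library size + 1) × 10⁶).

"At least 20% of the samples" is ⌈0.20·n⌉ samples and all threshold
comparisons are strict inequalities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .specificity import ExpressionMatrix


@dataclass
class FilterConfig:
    tpm_threshold: float = 0.50
    tpm_fraction: float = 0.20
    count_threshold_pcg: int = 2
    count_threshold_lnc: int = 1
    count_fraction: float = 0.20
    min_assigned_reads: int = 10**6

    def __post_init__(self) -> None:
        for frac in (self.tpm_fraction, self.count_fraction):
            if not (0 < frac <= 1):
                raise ValueError("fractions must lie in (0, 1]")
        if min(self.tpm_threshold, self.count_threshold_pcg,
               self.count_threshold_lnc, self.min_assigned_reads) < 0:
            raise ValueError("thresholds must be non-negative")


#: co-expression-network preset: log2-CPM > 2 in at least 50% of samples is
#: applied downstream of this config via `log2cpm_prefilter`
WGCNA_PRESET = FilterConfig()


@dataclass
class NormalizedMatrix:
    log2cpm: pd.DataFrame
    tmm_factors: pd.Series


def filter_samples(
    counts: ExpressionMatrix, cfg: FilterConfig = FilterConfig()
) -> Tuple[ExpressionMatrix, List[str]]:
    """Drop samples whose total assigned reads fall below the minimum.

    The rule is strict: a column sum of exactly ``min_assigned_reads`` is
    kept; anything below is dropped and listed.
    """
    sums = counts.values.sum(axis=0)
    dropped = list(sums.index[sums < cfg.min_assigned_reads])
    kept = [s for s in counts.samples if s not in set(dropped)]
    if not kept:
        raise ValueError("all samples fall below the minimum assigned-read count")
    return counts.subset_samples(kept), dropped


def filter_genes(
    counts: ExpressionMatrix,
    tpm: ExpressionMatrix,
    cfg: FilterConfig = FilterConfig(),
) -> pd.Index:
    """Two-step low-expression gene filter; returns the keep-list.

    A gene is kept iff TPM exceeds ``tpm_threshold`` in at least
    ⌈tpm_fraction·n⌉ samples *and* its raw count exceeds the
    biotype-specific threshold (protein_coding → ``count_threshold_pcg``,
    anything else → ``count_threshold_lnc``) in at least
    ⌈count_fraction·n⌉ samples.
    """
    if not counts.genes.equals(tpm.genes):
        raise ValueError("counts and TPM matrices must share the same gene set")
    bio = counts.biotypes()
    n = counts.values.shape[1]
    need_tpm = math.ceil(cfg.tpm_fraction * n)
    need_cnt = math.ceil(cfg.count_fraction * n)

    tpm_pass = (tpm.values > cfg.tpm_threshold).sum(axis=1) >= need_tpm
    thresh = bio.map(
        lambda b: cfg.count_threshold_pcg if b == "protein_coding"
        else cfg.count_threshold_lnc
    )
    cnt_pass = counts.values.gt(thresh, axis=0).sum(axis=1) >= need_cnt
    return counts.genes[tpm_pass & cnt_pass]


def _cpm(col: np.ndarray) -> np.ndarray:
    return col / col.sum() * 1e6


def tmm_factors(
    counts: ExpressionMatrix | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference sample is the one whose 75th percentile of CPM is closest
    to the mean of those percentiles. For each sample, genes with zero
    counts in either the sample or the reference are excluded; the log2
    expression ratios (M) are doubly trimmed — the ``trim_m`` fraction at
    each end by M and the ``trim_a`` fraction at each end by average log2
    abundance (A) — and the factor is 2 to the precision-weighted mean of
    the surviving M values. Factors are rescaled so their geometric mean
    is 1.
    """
    values = counts.values if isinstance(counts, ExpressionMatrix) else counts
    mat = values.to_numpy(dtype=float)
    n_genes, n_samples = mat.shape
    if n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = list(values.columns[lib == 0])
        raise ValueError(f"samples with all-zero counts: {bad}")

    q75 = np.array([np.percentile(_cpm(mat[:, j]), 75) for j in range(n_samples)])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = mat[:, ref_idx]
    nref = lib[ref_idx]

    factors = np.ones(n_samples)
    for j in range(n_samples):
        obs = mat[:, j]
        nobs = lib[j]
        ok = (obs > 0) & (ref > 0)
        if j == ref_idx or ok.sum() == 0:
            factors[j] = 1.0
            continue
        o, r = obs[ok], ref[ok]
        p_o, p_r = o / nobs, r / nref
        m = np.log2(p_o / p_r)
        a = 0.5 * np.log2(p_o * p_r)
        # asymptotic binomial variance of M; weights are its inverse
        w = (nobs - o) / (nobs * o) + (nref - r) / (nref * r)
        n = len(m)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0:
            factors[j] = 1.0
            continue
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        if not np.isfinite(f) or abs(f) < 1e-6:
            f = 0.0
        factors[j] = 2.0 ** f

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=values.columns, name="tmm_factor")


def log2_cpm(
    counts: ExpressionMatrix | pd.DataFrame,
    factors: pd.Series,
) -> NormalizedMatrix:
    """log2 counts-per-million on TMM-adjusted effective library sizes.

    log2cpm_gs = log2((count_gs + 0.5) / (libsize_s · factor_s + 1) × 10⁶).
    """
    values = counts.values if isinstance(counts, ExpressionMatrix) else counts
    lib = values.sum(axis=0)
    eff = lib * factors.loc[values.columns]
    out = np.log2((values + 0.5).div(eff + 1.0, axis=1) * 1e6)
    return NormalizedMatrix(log2cpm=out, tmm_factors=factors)


def log2cpm_prefilter(
    norm: NormalizedMatrix, threshold: float = 2.0, fraction: float = 0.50
) -> pd.Index:
    """Co-expression-network preset: keep genes with log2-CPM above
    ``threshold`` in at least ``fraction`` of samples."""
    n = norm.log2cpm.shape[1]
    need = math.ceil(fraction * n)
    keep = (norm.log2cpm > threshold).sum(axis=1) >= need
    return norm.log2cpm.index[keep]


def prepare_eqtl_matrix(
    counts: ExpressionMatrix,
    tpm: ExpressionMatrix,
    cfg: FilterConfig = FilterConfig(),
) -> Tuple[NormalizedMatrix, pd.Index, List[str]]:
    """Full pipeline: sample filter → gene filter → TMM → log2-CPM."""
    kept_counts, dropped = filter_samples(counts, cfg)
    kept_tpm = tpm.subset_samples(list(kept_counts.samples))
    keep = filter_genes(kept_counts, kept_tpm, cfg)
    sub = kept_counts.values.loc[keep]
    if sub.shape[0] == 0:
        warnings.warn("no genes survive the expression filters")
    factors = tmm_factors(sub)
    return log2_cpm(sub, factors), keep, dropped
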