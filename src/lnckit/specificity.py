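"""TPM normalization, tissue averaging, and the Tau and PEM specificity scores.

Tau condenses a gene's expression profile over N tissues into one number in
[0, 1]: with x_i the tissue values and x̂_i = x_i / max_i x_i,

    τ = Σ_i (1 − x̂_i) / (N − 1)

so τ = 0 for perfectly uniform expression and τ = 1 for expression confined
to a single tissue. The preferential expression measure (PEM) scores each
(gene, tissue) cell against an independence model: with row totals r_g,
column totals c_t and grand total G, expected_gt = r_g·c_t/G and

    PEM_gt = log10(observed_gt / expected_gt)

Cells with zero observed expression are reported as missing rather than −∞
so that downstream maxima stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with sample→tissue and gene metadata.

    ``values``: DataFrame, gene ids as index, sample ids as columns.
    ``tissue_of``: Series mapping sample id → tissue label.
    ``gene_meta``: DataFrame indexed by gene id with optional columns
    ``length`` (effective length, bp) and ``biotype``.
    """

    values: pd.DataFrame
    tissue_of: pd.Series
    gene_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.tissue_of.index]
        if missing:
            raise ValueError(f"samples with no tissue mapping: {missing[:5]} ...")
        self.tissue_of = self.tissue_of.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def lengths(self) -> pd.Series:
        if "length" not in self.gene_meta.columns:
            raise ValueError("gene_meta lacks a 'length' column")
        lens = self.gene_meta["length"].reindex(self.values.index)
        if lens.isna().any() or (lens <= 0).any():
            raise ValueError("every gene needs a positive length")
        return lens.astype(float)

    def biotypes(self) -> pd.Series:
        if "biotype" not in self.gene_meta.columns:
            raise ValueError("gene_meta lacks a 'biotype' column")
        bio = self.gene_meta["biotype"].reindex(self.values.index)
        if bio.isna().any():
            raise ValueError("every gene needs a biotype")
        return bio

    def subset_samples(self, keep) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[keep], self.tissue_of.loc[keep], self.gene_meta
        )


@dataclass
class SpecificityResult:
    """Per-gene Tau plus the genes × tissues PEM matrix."""

    tau: pd.Series
    pem: pd.DataFrame
    pem_max_norm: pd.Series
    excluded_genes: pd.Index

    def to_frame(self) -> pd.DataFrame:
        out = self.pem.add_prefix("PEM_")
        out.insert(0, "tau", self.tau)
        out["pem_max_norm"] = self.pem_max_norm
        return out


def tpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to transcripts per kilobase million.

    Per sample: rate_g = count_g / (length_g / 1000); TPM_g = rate_g /
    Σ rate × 10⁶. Columns sum to 10⁶ except all-zero samples, which stay
    all-zero (with a warning).
    """
    lens_kb = counts.lengths() / 1000.0
    rate = counts.values.div(lens_kb, axis=0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum[colsum == 0].index
    if len(zero_cols):
        warnings.warn(f"all-zero samples left unnormalized: {list(zero_cols)}")
        colsum = colsum.replace(0, np.nan)
    tpm = rate.div(colsum, axis=1).fillna(0.0) * 1e6
    return ExpressionMatrix(tpm, counts.tissue_of, counts.gene_meta)


def tissue_mean(m: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean across the replicate samples of each tissue."""
    groups = m.tissue_of.groupby(m.tissue_of).groups
    cols = {}
    for tissue in sorted(groups):
        samples = list(groups[tissue])
        if not samples:
            warnings.warn(f"tissue {tissue!r} has no samples; excluded")
            continue
        cols[tissue] = m.values[samples].mean(axis=1)
    return pd.DataFrame(cols)


def _drop_unexpressed(e: pd.DataFrame, strict: bool) -> Tuple[pd.DataFrame, pd.Index]:
    """Apply the expression-exclusion rule before scoring.

    Default reading: drop genes with zero expression in *every* tissue.
    ``strict=True`` applies the alternative reading — require non-zero
    expression in all tissues.
    """
    if strict:
        keep = (e > 0).all(axis=1)
    else:
        keep = (e > 0).any(axis=1)
    return e.loc[keep], e.index[~keep]


def tau(
    e: pd.DataFrame, log_transform: bool = True, strict_exclusion: bool = False
) -> Tuple[pd.Series, pd.Index]:
    """Tau tissue-specificity index per gene, on a genes × tissues matrix.

    ``log_transform`` applies log2(x + 1) to tissue means first (default).
    Returns (tau, excluded gene index).
    """
    if e.shape[1] < 2:
        raise ValueError("tau needs at least two tissues")
    kept, excluded = _drop_unexpressed(e, strict_exclusion)
    x = np.log2(kept + 1.0) if log_transform else kept.astype(float)
    xmax = x.max(axis=1)
    xhat = x.div(xmax, axis=0)
    n = x.shape[1]
    t = (1.0 - xhat).sum(axis=1) / (n - 1)
    return t, excluded


def pem(
    e: pd.DataFrame, strict_exclusion: bool = False
) -> Tuple[pd.DataFrame, pd.Series, pd.Index]:
    """Preferential expression measure per (gene, tissue).

    Returns (PEM matrix with NaN where observed is 0, per-gene maximum
    min–max rescaled to [0, 1] across genes, excluded gene index).
    """
    kept, excluded = _drop_unexpressed(e, strict_exclusion)
    grand = float(kept.to_numpy().sum())
    if grand == 0:
        raise ValueError("grand total of expression matrix is zero")
    r = kept.sum(axis=1)
    c = kept.sum(axis=0)
    expected = np.outer(r, c) / grand
    obs = kept.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.log10(obs / expected)
    scores[obs == 0] = np.nan
    pem_mat = pd.DataFrame(scores, index=kept.index, columns=kept.columns)
    pmax = pem_mat.max(axis=1)
    lo, hi = pmax.min(), pmax.max()
    if hi > lo:
        pmax_norm = (pmax - lo) / (hi - lo)
    else:
        pmax_norm = pd.Series(0.0, index=pmax.index)
    return pem_mat, pmax_norm, excluded


def specificity_scores(
    counts: ExpressionMatrix,
    already_tpm: bool = False,
    log_transform: bool = True,
    strict_exclusion: bool = False,
) -> SpecificityResult:
    """Full pipeline: TPM → tissue means → Tau and PEM."""
    m = counts if already_tpm else tpm_normalize(counts)
    e = tissue_mean(m)
    t, excl_tau = tau(e, log_transform=log_transform, strict_exclusion=strict_exclusion)
    pem_mat, pmax_norm, _ = pem(e, strict_exclusion=strict_exclusion)
    return SpecificityResult(
        tau=t, pem=pem_mat, pem_max_norm=pmax_norm, excluded_genes=excl_tau
    )
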