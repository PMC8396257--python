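"""Expression units and replicate QC: TPM, z-scores, Pearson correlation, PCA.

TPM (transcripts per kilobase million) divides each gene's count by its
length in kilobases and rescales every sample so the values sum to 1e6;
per-sample totals are therefore comparable by construction.  QC statistics
(replicate correlation, PCA) operate on log2(TPM + 1) by default, a
pseudocount-stabilised transform that keeps zeros at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from revertome.synthdata import CountMatrix

UNITS = ("counts", "TPM", "log2TPM1", "zscore")


@dataclass
class ExpressionMatrix:
    """A genes x samples value matrix with a unit tag and QC flags."""

    values: pd.DataFrame
    unit: str
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")


def tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Convert integer counts to TPM using per-gene lengths in bp.

    Samples with zero total signal yield an all-zero column and are
    recorded under ``flags['zero_samples']``.
    """
    if len(counts.gene_lengths) != len(counts.counts.index):
        raise ValueError(
            "length vector shorter than gene list: "
            f"{len(counts.gene_lengths)} != {len(counts.counts.index)}"
        )
    lengths_kb = counts.gene_lengths.to_numpy(dtype=float) / 1e3
    rate = counts.counts.to_numpy(dtype=float) / lengths_kb[:, None]
    totals = rate.sum(axis=0)
    zero = totals == 0
    safe_totals = np.where(zero, 1.0, totals)
    values = rate / safe_totals[None, :] * 1e6
    values[:, zero] = 0.0
    flags: dict = {}
    if zero.any():
        zero_samples = list(counts.counts.columns[zero])
        flags["zero_samples"] = zero_samples
        warnings.warn(f"samples with zero total signal: {zero_samples}")
    return ExpressionMatrix(
        pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns),
        unit="TPM",
        flags=flags,
    )


def log2_tpm1(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform."""
    if expr.unit != "TPM":
        raise ValueError(f"expected TPM input, got {expr.unit!r}")
    return ExpressionMatrix(np.log2(expr.values + 1.0), unit="log2TPM1", flags=dict(expr.flags))


def zscore_rows(expr: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Standardise each gene across samples to mean 0, sd 1.

    Sample standard deviation (``ddof=1``) is used because sample numbers
    are small.  Constant rows are set to all zeros and listed under
    ``flags['constant_genes']``.
    """
    if expr.unit not in ("TPM", "log2TPM1"):
        raise ValueError(f"z-scores expect TPM or log2TPM1 input, got {expr.unit!r}")
    if expr.values.shape[1] < 2:
        raise ValueError("z-scores require at least 2 samples")
    x = expr.values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    constant = sd[:, 0] == 0
    safe_sd = np.where(constant[:, None], 1.0, sd)
    z = (x - mean) / safe_sd
    z[constant] = 0.0
    flags = dict(expr.flags)
    if constant.any():
        flags["constant_genes"] = list(expr.values.index[constant])
    return ExpressionMatrix(
        pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns),
        unit="zscore",
        flags=flags,
    )


def replicate_correlation(expr: ExpressionMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between replicates of each condition.

    Input in TPM is transformed to log2(TPM+1) first; log2TPM1 or zscore
    input is used as-is.  Conditions with a single replicate are omitted
    with a warning.  Returns a DataFrame with columns
    ``condition, sample_i, sample_j, r``.
    """
    if expr.unit == "TPM":
        values = np.log2(expr.values + 1.0)
    elif expr.unit in ("log2TPM1", "zscore"):
        values = expr.values
    else:
        raise ValueError(f"replicate correlation expects expression data, got {expr.unit!r}")
    rows = []
    for cond, sub in design.groupby("condition", sort=True):
        samples = [s for s in sub.index if s in values.columns]
        if len(samples) < 2:
            warnings.warn(f"condition {cond!r} has <2 replicates; omitted from QC")
            continue
        for a, b in combinations(samples, 2):
            r = float(np.corrcoef(values[a], values[b])[0, 1])
            rows.append({"condition": cond, "sample_i": a, "sample_j": b, "r": r})
    return pd.DataFrame(rows, columns=["condition", "sample_i", "sample_j", "r"])


def pca_scores(
    expr: ExpressionMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples in gene space.

    Samples are observations; the gene dimension is centred.  Returns
    sample scores and the explained-variance fractions (non-increasing,
    summing to <= 1).  ``n_components`` above the matrix rank is truncated
    with a warning.
    """
    x = expr.values.to_numpy(dtype=float).T  # samples x genes
    n_samples = x.shape[0]
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(x.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples)={min(x.shape)}"
        )
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    total = float((s**2).sum())
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds matrix rank {rank}; truncated"
        )
        n_components = max(rank, 1)
    scores = u[:, :n_components] * s[:n_components]
    if total == 0:
        frac = np.zeros(n_components)
    else:
        frac = (s[:n_components] ** 2) / total
    score_df = pd.DataFrame(
        scores,
        index=expr.values.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return score_df, frac
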