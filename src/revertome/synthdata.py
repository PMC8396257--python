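"""Synthetic four-condition RNA-seq counts with planted gene classes.

The generator emulates a replicated bulk RNA-seq experiment with four
conditions — control, perturbation A, perturbation B, and the double
perturbation A+B — in which a known subset of genes responds to A and is
(or is not) pulled back toward its control level when B is added.  Counts
are drawn from a negative binomial with mean ``mu`` and dispersion ``alpha``
(variance ``mu + alpha * mu**2``); ``alpha = 0`` degenerates to Poisson.

Every gene belongs to one of six classes:

``null``
    flat across all four conditions;
``up_reversed`` / ``down_reversed``
    shifted up/down by A (``effect_log2fc`` log2 units) and returned toward
    baseline in A+B (fully by default, partially via ``reversion``);
``up_not_reversed`` / ``down_not_reversed``
    shifted by A and unchanged by the addition of B;
``b_only``
    responds to B alone — the shift appears in both the B and A+B samples.

The returned :class:`TruthTable` records each gene's class and its true
log2 fold changes for the three canonical contrasts (A vs control,
A+B vs A, B vs control), so downstream estimates can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("control", "A", "B", "AB")

GENE_CLASSES = (
    "null",
    "up_reversed",
    "down_reversed",
    "up_not_reversed",
    "down_not_reversed",
    "b_only",
)

#: Default class mix: ~12% of genes respond to A, 90% of those reverting
#: when B is added, plus a small set of B-only responders.
DEFAULT_PROPORTIONS = {
    "null": 0.85,
    "up_reversed": 0.054,
    "down_reversed": 0.054,
    "up_not_reversed": 0.006,
    "down_not_reversed": 0.006,
    "b_only": 0.03,
}


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    Defaults mirror the emulated study design: 17,108 annotated genes,
    two biological replicates per condition, and a class mix in which 90%
    of A-responsive genes revert on addition of B.
    """

    n_genes: int = 17108
    n_reps: int = 2
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    effect_log2fc: float = 2.0
    dispersion: float = 0.05
    base_mean_range: tuple[float, float] = (10.0, 1000.0)
    length_range: tuple[int, int] = (200, 20000)
    libsize_factors: list[float] | None = None
    reversion: float = 1.0  # 1 = full return to baseline in A+B
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes in proportions: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total!r}")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name, (lo, hi) in (
            ("base_mean_range", self.base_mean_range),
            ("length_range", self.length_range),
        ):
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 < low <= high")
        if not 0.0 <= self.reversion <= 1.0:
            raise ValueError("reversion must lie in [0, 1]")
        if self.libsize_factors is not None:
            if len(self.libsize_factors) != 4 * self.n_reps:
                raise ValueError(
                    "libsize_factors must have one entry per sample "
                    f"({4 * self.n_reps}), got {len(self.libsize_factors)}"
                )
            if any(f <= 0 for f in self.libsize_factors):
                raise ValueError("libsize_factors must be positive")


@dataclass
class CountMatrix:
    """Gene-level integer counts with lengths and a sample->condition design.

    ``counts`` is genes x samples; ``design`` is indexed by sample id with
    columns ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    design: pd.DataFrame

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts contain negative entries")
        if not self.counts.index.equals(self.gene_lengths.index):
            raise ValueError("gene_lengths index does not match counts index")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene_lengths must be positive")
        if not set(self.counts.columns) == set(self.design.index):
            raise ValueError("design samples do not match count columns")
        for cond in self.design["condition"].unique():
            if (self.design["condition"] == cond).sum() < 1:
                raise ValueError(f"condition {cond} has no samples")

    def samples_for(self, condition: str) -> list[str]:
        sel = self.design.index[self.design["condition"] == condition]
        missing = set(sel) - set(self.counts.columns)
        if missing:
            raise ValueError(f"design samples missing from counts: {sorted(missing)}")
        return list(sel)

    # -- plain-text round-trip -------------------------------------------

    def write(self, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        """Write counts/lengths as TSV and the design as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / f"{prefix}_counts.tsv",
            "lengths": outdir / f"{prefix}_lengths.tsv",
            "design": outdir / f"{prefix}_design.json",
        }
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(paths["counts"], sep="\t")
        lengths = self.gene_lengths.rename("length").to_frame()
        lengths.index.name = "gene_id"
        lengths.to_csv(paths["lengths"], sep="\t")
        design = {
            s: {
                "condition": str(self.design.loc[s, "condition"]),
                "replicate": int(self.design.loc[s, "replicate"]),
            }
            for s in self.design.index
        }
        paths["design"].write_text(json.dumps(design, indent=2, sort_keys=True) + "\n")
        return paths


def expected_profile(
    gene_class: str,
    base_mean: float,
    effect: float,
    reversion: float = 1.0,
) -> np.ndarray:
    """Per-condition expected mean ``(control, A, B, AB)`` for one gene.

    ``effect`` is a log2 magnitude; the direction comes from the class.
    ``reversion`` in [0, 1] scales how far an A-induced shift returns to
    baseline in the A+B condition (1 = fully back to control level).
    """
    if base_mean <= 0:
        raise ValueError("base_mean must be positive")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    m = float(base_mean)
    up = m * 2.0**effect
    down = m * 2.0**-effect
    if gene_class == "null":
        prof = (m, m, m, m)
    elif gene_class == "up_reversed":
        prof = (m, up, m, m * 2.0 ** (effect * (1.0 - reversion)))
    elif gene_class == "down_reversed":
        prof = (m, down, m, m * 2.0 ** (-effect * (1.0 - reversion)))
    elif gene_class == "up_not_reversed":
        prof = (m, up, m, up)
    elif gene_class == "down_not_reversed":
        prof = (m, down, m, down)
    elif gene_class == "b_only":
        # B is present in both the B and A+B conditions.
        prof = (m, m, up, up)
    else:
        raise ValueError(f"unknown gene class: {gene_class!r}")
    return np.asarray(prof, dtype=float)


def _class_counts(proportions: dict[str, float], n_genes: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n_genes`` over the classes."""
    classes = [c for c in GENE_CLASSES if proportions.get(c, 0.0) > 0]
    raw = {c: proportions[c] * n_genes for c in classes}
    counts = {c: math.floor(raw[c]) for c in classes}
    short = n_genes - sum(counts.values())
    # ties broken by canonical class order for determinism
    by_remainder = sorted(
        classes, key=lambda c: (-(raw[c] - counts[c]), GENE_CLASSES.index(c))
    )
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def _true_lfcs(gene_class: str, effect: float, reversion: float) -> tuple[float, float, float]:
    """True (lfc_A, lfc_AB_vs_A, lfc_B) in log2 units for one class."""
    e = effect
    if gene_class == "null":
        return 0.0, 0.0, 0.0
    if gene_class == "up_reversed":
        return e, -e * reversion, 0.0
    if gene_class == "down_reversed":
        return -e, e * reversion, 0.0
    if gene_class == "up_not_reversed":
        return e, 0.0, 0.0
    if gene_class == "down_not_reversed":
        return -e, 0.0, 0.0
    if gene_class == "b_only":
        return 0.0, e, e
    raise ValueError(f"unknown gene class: {gene_class!r}")


def generate(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw one synthetic experiment.

    Returns the :class:`CountMatrix` and the truth table (a DataFrame
    indexed by gene id with columns ``class_label``, ``true_lfc_A``,
    ``true_lfc_AB_vs_A``, ``true_lfc_B``).  Identical configs (including
    the seed) produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    sample_ids = [f"{cond}_{r + 1}" for cond in CONDITIONS for r in range(config.n_reps)]
    design = pd.DataFrame(
        {
            "condition": [cond for cond in CONDITIONS for _ in range(config.n_reps)],
            "replicate": [r + 1 for _ in CONDITIONS for r in range(config.n_reps)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    if n == 0:
        counts = pd.DataFrame(
            np.zeros((0, len(sample_ids)), dtype=np.int64),
            index=gene_ids,
            columns=sample_ids,
        )
        lengths = pd.Series(np.array([], dtype=np.int64), index=gene_ids, name="length")
        truth = pd.DataFrame(
            columns=["class_label", "true_lfc_A", "true_lfc_AB_vs_A", "true_lfc_B"],
            index=gene_ids,
        )
        return CountMatrix(counts, lengths, design), truth

    counts_per_class = _class_counts(config.class_proportions, n)
    labels = np.concatenate(
        [np.repeat(c, k) for c, k in counts_per_class.items()]
    )
    labels = labels[rng.permutation(n)]

    lo, hi = config.base_mean_range
    base_means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    llo, lhi = config.length_range
    lengths = np.exp(rng.uniform(np.log(llo), np.log(lhi), size=n))
    lengths = np.maximum(np.round(lengths).astype(np.int64), 1)

    # per-gene per-condition expected means
    mu = np.empty((n, 4), dtype=float)
    for cls in counts_per_class:
        mask = labels == cls
        profile = expected_profile(cls, 1.0, config.effect_log2fc, config.reversion)
        mu[mask] = base_means[mask, None] * profile[None, :]

    lib = (
        np.ones(len(sample_ids))
        if config.libsize_factors is None
        else np.asarray(config.libsize_factors, dtype=float)
    )
    cond_of_sample = [CONDITIONS.index(design.loc[s, "condition"]) for s in sample_ids]

    mat = np.empty((n, len(sample_ids)), dtype=np.int64)
    alpha = config.dispersion
    for j, s in enumerate(sample_ids):
        m = mu[:, cond_of_sample[j]] * lib[j]
        if alpha == 0.0:
            mat[:, j] = rng.poisson(m)
        else:
            # NB with mean m, variance m + alpha m^2
            size = 1.0 / alpha
            p = size / (size + m)
            mat[:, j] = rng.negative_binomial(size, p)

    counts = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
    gene_lengths = pd.Series(lengths, index=gene_ids, name="length")

    lfc = np.array([_true_lfcs(c, config.effect_log2fc, config.reversion) for c in labels])
    truth = pd.DataFrame(
        {
            "class_label": labels,
            "true_lfc_A": lfc[:, 0],
            "true_lfc_AB_vs_A": lfc[:, 1],
            "true_lfc_B": lfc[:, 2],
        },
        index=gene_ids,
    )
    return CountMatrix(counts, gene_lengths, design), truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    # keep_default_na: the class label "null" is a real value, not missing
    return pd.read_csv(
        path, sep="\t", index_col="gene_id", keep_default_na=False, na_values=[]
    )
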