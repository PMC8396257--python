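"""Cross-contrast sign-concordance classification of reversed genes.

Given two differential-expression contrasts over the same gene universe —
A = perturbation A vs control, and C = (A+B) vs A — a gene significant in
both is called *reversed* when its two log2 fold changes have opposite
signs (the gene moves back toward control when B is added) and
*concordant* when they share a sign.  The summary reports the Venn
overlap, the reversed fraction, and its directional split; a companion
three-contrast classifier labels candidate genes the way the field reads
such dynamics (up by the oncogenic perturbation and reversed by the
suppressor = putative oncogene, the mirror image = putative tumor
suppressor, significant in A but not in C = not reversed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from revertome.dge import DGEResult, deg_set

STATUSES = ("reversed", "concordant", "A_only", "C_only", "neither")

CATEGORIES = ("putative_oncogene", "putative_suppressor", "not_reversed", "other")


@dataclass
class ReversalSummary:
    """Counts over the two significant sets and their overlap.

    ``fraction_reversed`` is None (undefined), not 0, when the overlap is
    empty.
    """

    n_A: int
    n_C: int
    n_overlap: int
    n_reversed: int
    n_concordant: int
    fraction_reversed: float | None
    n_up_reversed: int
    n_down_reversed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def overlap_sets(set_a: pd.Series, set_c: pd.Series) -> dict[str, int]:
    """Venn counts for two signed gene sets: A_only, C_only, both."""
    a = set(set_a.index)
    c = set(set_c.index)
    return {
        "A_only": len(a - c),
        "C_only": len(c - a),
        "both": len(a & c),
    }


def _check_universe(dge_a: DGEResult, dge_c: DGEResult) -> None:
    ua, uc = set(dge_a.table.index), set(dge_c.table.index)
    if ua != uc:
        raise ValueError(
            "contrasts do not share a gene universe; symmetric difference "
            f"has {len(ua ^ uc)} genes"
        )


def classify_reversal(
    dge_a: DGEResult,
    dge_c: DGEResult,
    threshold: float = 0.01,
) -> tuple[pd.DataFrame, ReversalSummary]:
    """Classify every gene by joint significance and fold-change signs.

    Returns a per-gene table (``lfc_A, lfc_C, in_A, in_C, status,
    zero_lfc``) and the :class:`ReversalSummary`.  Overlap genes whose
    fold-change product is exactly zero cannot carry a sign comparison;
    they are counted as concordant (preserving
    ``reversed + concordant = overlap``) and flagged ``zero_lfc``.
    """
    _check_universe(dge_a, dge_c)
    genes = dge_a.table.index
    lfc_a = dge_a.table["log2fc"]
    lfc_c = dge_c.table["log2fc"].reindex(genes)

    in_a = genes.isin(deg_set(dge_a, threshold).index)
    in_c = genes.isin(deg_set(dge_c, threshold).index)
    both = in_a & in_c
    prod = lfc_a.to_numpy() * lfc_c.to_numpy()
    zero_lfc = both & (prod == 0)
    reversed_ = both & (prod < 0)
    concordant = both & ~reversed_

    status = np.full(len(genes), "neither", dtype=object)
    status[in_a & ~in_c] = "A_only"
    status[~in_a & in_c] = "C_only"
    status[reversed_] = "reversed"
    status[concordant] = "concordant"

    table = pd.DataFrame(
        {
            "lfc_A": lfc_a,
            "lfc_C": lfc_c,
            "in_A": in_a,
            "in_C": in_c,
            "status": status,
            "zero_lfc": zero_lfc,
        },
        index=genes,
    )

    n_overlap = int(both.sum())
    n_rev = int(reversed_.sum())
    summary = ReversalSummary(
        n_A=int(in_a.sum()),
        n_C=int(in_c.sum()),
        n_overlap=n_overlap,
        n_reversed=n_rev,
        n_concordant=int(concordant.sum()),
        fraction_reversed=(n_rev / n_overlap) if n_overlap > 0 else None,
        n_up_reversed=int((reversed_ & (lfc_a.to_numpy() > 0)).sum()),
        n_down_reversed=int((reversed_ & (lfc_a.to_numpy() < 0)).sum()),
    )
    return table, summary


def candidate_categories(
    dge_a: DGEResult,
    dge_b: DGEResult,
    dge_c: DGEResult,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Label A-deregulated genes by their reversion dynamics.

    * ``putative_oncogene`` — up in A, significantly down in (A+B) vs A;
    * ``putative_suppressor`` — down in A, significantly up in (A+B) vs A;
    * ``not_reversed`` — significant in A but absent from the (A+B)-vs-A
      significant set;
    * ``other`` — remaining A-significant genes (reversal with the same
      sign, i.e. concordant amplification).

    Genes outside the A significant set are left unlabelled (NaN).  The B
    contrast is attached as a ``regulated_by_B_alone`` flag, separating
    genes whose reversion requires the A context from genes B moves on
    its own.
    """
    for name, d in (("B", dge_b), ("C", dge_c)):
        if d is None:
            raise ValueError(f"missing contrast {name}")
    _check_universe(dge_a, dge_c)
    _check_universe(dge_a, dge_b)

    genes = dge_a.table.index
    set_a = deg_set(dge_a, threshold)
    set_c = deg_set(dge_c, threshold)
    set_b = deg_set(dge_b, threshold)

    in_a = genes.isin(set_a.index)
    in_c = genes.isin(set_c.index)
    lfc_a = dge_a.table["log2fc"].to_numpy()
    lfc_c = dge_c.table["log2fc"].reindex(genes).to_numpy()

    category = np.full(len(genes), np.nan, dtype=object)
    category[in_a & ~in_c] = "not_reversed"
    onc = in_a & in_c & (lfc_a > 0) & (lfc_c < 0)
    sup = in_a & in_c & (lfc_a < 0) & (lfc_c > 0)
    category[in_a & in_c] = "other"
    category[onc] = "putative_oncogene"
    category[sup] = "putative_suppressor"

    return pd.DataFrame(
        {
            "category": category,
            "lfc_A": lfc_a,
            "lfc_C": lfc_c,
            "regulated_by_B_alone": genes.isin(set_b.index),
        },
        index=genes,
    )


def heatmap_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Genes x 2 matrix of the overlap genes' fold changes, for plotting."""
    sel = table["status"].isin(["reversed", "concordant"])
    return table.loc[sel, ["lfc_A", "lfc_C"]]
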