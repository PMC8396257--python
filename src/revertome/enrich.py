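"""Hypergeometric gene-set over-representation analysis on GMT collections.

For a query list drawn from a background universe, each named set is
tested with the upper tail of the hypergeometric distribution
(``P[X >= n_hit]`` for X ~ Hypergeom(N universe, K set members in
universe, n query)), and p-values are Benjamini–Hochberg adjusted across
the collection.  No gene-ontology database is bundled; collections come
from user-supplied GMT files (tab-delimited: name, description,
members...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from revertome.dge import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions; members are de-duplicated."""

    sets: dict[str, set] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; duplicate members within a set are collapsed."""
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc, *members = fields
            if not name:
                raise ValueError(f"{path}:{lineno}: empty set name")
            members = [m for m in members if m]
            unique = set(members)
            if len(unique) < len(members):
                warnings.warn(f"set {name!r} lists duplicate members; collapsed")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def ora(
    query,
    collection: GeneSetCollection,
    universe,
    under_representation: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of the collection.

    The universe is the background (typically all genes tested for
    differential expression); query members outside it are dropped with a
    warning.  Returns one row per set with the hypergeometric p, BH FDR
    across sets, and fold enrichment; rows are sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped"
        )
        query &= universe

    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for name, members in collection.sets.items():
        in_universe = members & universe
        n_set = len(in_universe)
        n_hit = len(in_universe & query)
        if under_representation:
            p = float(stats.hypergeom.cdf(n_hit, n_universe, n_set, n_query))
        else:
            # upper tail P[X >= n_hit]
            p = float(stats.hypergeom.sf(n_hit - 1, n_universe, n_set, n_query))
        p = min(max(p, 0.0), 1.0)
        expected_rate = n_set / n_universe
        observed_rate = n_hit / n_query if n_query else 0.0
        fold = observed_rate / expected_rate if expected_rate > 0 else float("nan")
        rows.append(
            {
                "set": name,
                "description": collection.descriptions.get(name, ""),
                "n_universe": n_universe,
                "n_set": n_set,
                "n_query": n_query,
                "n_hit": n_hit,
                "p": p,
                "fold_enrichment": fold,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set",
            "description",
            "n_universe",
            "n_set",
            "n_query",
            "n_hit",
            "p",
            "fold_enrichment",
        ],
    )
    if len(result):
        result["fdr"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        result["fdr"] = pd.Series(dtype=float)
    return result
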