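"""Readers and writers for the pipeline's plain-text formats.

Counts and lengths travel as TSV (first column ``gene_id``), the design
as JSON (or two/three-column TSV), results as TSV, reports as JSON.
Reads are strict: duplicate gene ids and non-integer count cells are
errors with positions, so a malformed matrix fails loudly rather than
silently coercing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from revertome.synthdata import CountMatrix


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix.

    Header row holds sample ids; the first column holds gene ids.  Exact
    integers are preserved; duplicate gene ids or non-integer cells raise.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id(s): {sorted(set(dup))}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            as_float = pd.to_numeric(vals, errors="coerce")
            bad = as_float.isna() | (as_float != np.floor(as_float))
            if bad.any():
                gene = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"non-integer count at gene {gene!r}, sample {col!r}"
                )
            df[col] = as_float.astype(np.int64)
    df.index.name = "gene_id"
    return df


def read_lengths_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"lengths file must have exactly 2 columns, got {df.shape[1] + 1}")
    s = df.iloc[:, 0].astype(np.int64)
    s.name = "length"
    s.index.name = "gene_id"
    if (s <= 0).any():
        raise ValueError("gene lengths must be positive")
    return s


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample -> condition design from JSON or TSV.

    JSON maps sample id to ``{"condition": ..., "replicate": ...}``; TSV
    needs columns ``sample_id, condition`` (optional ``replicate``).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        rows = {
            s: {
                "condition": str(v["condition"]),
                "replicate": int(v.get("replicate", 1)),
            }
            for s, v in raw.items()
        }
        design = pd.DataFrame.from_dict(rows, orient="index")
    else:
        design = pd.read_csv(path, sep="\t", index_col="sample_id")
        if "replicate" not in design.columns:
            design["replicate"] = design.groupby("condition").cumcount() + 1
    design.index.name = "sample_id"
    if "condition" not in design.columns:
        raise ValueError("design lacks a 'condition' column")
    return design[["condition", "replicate"]]


def load_count_matrix(
    counts_path: str | Path,
    lengths_path: str | Path,
    design_path: str | Path,
) -> CountMatrix:
    counts = read_counts_tsv(counts_path)
    lengths = read_lengths_tsv(lengths_path)
    design = read_design(design_path)
    missing = set(counts.index) - set(lengths.index)
    if missing:
        raise ValueError(f"{len(missing)} genes lack a length entry")
    cm = CountMatrix(counts, lengths.reindex(counts.index), design)
    cm.validate()
    return cm


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, trailing newline, no timestamps."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path, index_name: str = "gene_id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.10g")
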