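"""End-to-end orchestration of the four-condition reversion analysis.

``run_all`` chains quantification/QC, differential expression on the
three canonical contrasts (A vs control, B vs control, A+B vs A),
reversal classification, dynamics clustering of the A-deregulated genes,
and (optionally) gene-set over-representation of the up-and-reversed
genes.  All artifacts are written under the output directory as TSV or
JSON; with a fixed seed a rerun on the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from revertome import clustering as cl
from revertome import io
from revertome import quantify as qt
from revertome import reversal as rv
from revertome.dge import Contrast, deg_set, test_contrast
from revertome.synthdata import CountMatrix

log = logging.getLogger("revertome")

#: condition names of the emulated study, by role
DEFAULT_CONDITION_NAMES = {"control": "control", "A": "A", "B": "B", "AB": "AB"}


@dataclass
class PipelineConfig:
    counts: str | Path = ""
    lengths: str | Path = ""
    design: str | Path = ""
    gmt: str | Path | None = None
    output_dir: str | Path = "results"
    fdr: float = 0.01
    cluster_fdr: float = 0.05
    k: int = cl.DEFAULT_K
    epsilon: float = cl.DEFAULT_EPSILON
    pseudocount: float = 0.5
    seed: int = 0
    condition_names: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_NAMES)
    )
    condition_means: bool = False  # cluster on condition means (4 cols) not samples
    run_qc: bool = True
    run_dge: bool = True
    run_reversal: bool = True
    run_clustering: bool = True
    run_enrich: bool = True

    def validate(self) -> None:
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must lie in (0, 1]")
        if not 0 < self.cluster_fdr <= 1:
            raise ValueError("cluster_fdr must lie in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        missing = {"control", "A", "B", "AB"} - set(self.condition_names)
        if missing:
            raise ValueError(f"condition_names lacks roles: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(config: PipelineConfig, counts: CountMatrix | None = None) -> dict:
    """Run every enabled stage and return the run report (also written).

    ``counts`` may be passed in memory; otherwise the configured paths
    are loaded.  Dependencies are enforced: reversal, clustering and
    enrichment require the DGE stage.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "seed": config.seed,
        "package_version": __import__("revertome").__version__,
        "parameters": {
            "fdr": config.fdr,
            "cluster_fdr": config.cluster_fdr,
            "k": config.k,
            "epsilon": config.epsilon,
            "pseudocount": config.pseudocount,
            "condition_means": config.condition_means,
        },
        "stages": {},
        "inputs": {},
        "outputs": [],
    }

    if counts is None:
        counts = io.load_count_matrix(config.counts, config.lengths, config.design)
        report["inputs"] = {
            "counts": {"path": str(config.counts), "sha256": _sha256(config.counts)},
            "lengths": {"path": str(config.lengths), "sha256": _sha256(config.lengths)},
            "design": {"path": str(config.design), "sha256": _sha256(config.design)},
        }
    counts.validate()
    names = config.condition_names
    design = counts.design
    log.info(
        "loaded %d genes x %d samples; library sizes %s",
        counts.counts.shape[0],
        counts.counts.shape[1],
        counts.counts.sum(axis=0).to_dict(),
    )

    def _emit(path: Path) -> None:
        report["outputs"].append(str(path.relative_to(outdir)))

    def _fail(stage: str, err: Exception):
        report["stages"][stage] = "failed"
        io.write_json(report, outdir / "run_report.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed") from err

    # ---- quantify / QC -------------------------------------------------
    expr_tpm = qt.tpm(counts)
    expr_log = qt.log2_tpm1(expr_tpm)
    if config.run_qc:
        try:
            rep_corr = qt.replicate_correlation(expr_log, design)
            n_pc = min(4, min(expr_log.values.shape))
            scores, frac = qt.pca_scores(expr_log, n_components=n_pc)
            path = outdir / "tpm.tsv"
            io.write_tsv(expr_tpm.values, path)
            _emit(path)
            path = outdir / "qc_replicate_correlation.tsv"
            rep_corr.to_csv(path, sep="\t", index=False, float_format="%.10g")
            _emit(path)
            path = outdir / "qc_pca.tsv"
            io.write_tsv(scores, path, index_name="sample_id")
            _emit(path)
            report["qc"] = {
                "replicate_pearson_min": (
                    float(rep_corr["r"].min()) if len(rep_corr) else None
                ),
                "pca_explained_fraction": [float(f) for f in frac],
            }
            report["stages"]["qc"] = "ok"
        except Exception as err:  # pragma: no cover - defensive
            _fail("qc", err)

    # ---- differential expression --------------------------------------
    dge_results = {}
    if config.run_dge:
        try:
            contrasts = {
                "A_vs_control": Contrast("A_vs_control", names["A"], names["control"]),
                "B_vs_control": Contrast("B_vs_control", names["B"], names["control"]),
                "AB_vs_A": Contrast("AB_vs_A", names["AB"], names["A"]),
            }
            for key, contrast in contrasts.items():
                res = test_contrast(
                    counts.counts, design, contrast, pseudocount=config.pseudocount
                )
                dge_results[key] = res
                path = outdir / f"dge_{key}.tsv"
                io.write_tsv(res.table, path)
                _emit(path)
            report["stages"]["dge"] = "ok"
        except Exception as err:
            _fail("dge", err)

    # ---- reversal classification --------------------------------------
    if config.run_reversal:
        if not dge_results:
            raise ValueError("reversal stage requires the dge stage")
        try:
            table, summary = rv.classify_reversal(
                dge_results["A_vs_control"], dge_results["AB_vs_A"], config.fdr
            )
            venn = rv.overlap_sets(
                deg_set(dge_results["A_vs_control"], config.fdr),
                deg_set(dge_results["AB_vs_A"], config.fdr),
            )
            cats = rv.candidate_categories(
                dge_results["A_vs_control"],
                dge_results["B_vs_control"],
                dge_results["AB_vs_A"],
                config.fdr,
            )
            path = outdir / "reversal_table.tsv"
            io.write_tsv(table, path)
            _emit(path)
            path = outdir / "reversal_summary.json"
            io.write_json(summary.__dict__, path)
            _emit(path)
            path = outdir / "venn.json"
            io.write_json(venn, path)
            _emit(path)
            path = outdir / "reversal_heatmap.tsv"
            io.write_tsv(rv.heatmap_matrix(table), path)
            _emit(path)
            path = outdir / "candidate_categories.tsv"
            io.write_tsv(cats, path)
            _emit(path)
            report["reversal_summary"] = summary.__dict__
            report["stages"]["reversal"] = "ok"
        except Exception as err:
            _fail("reversal", err)

    # ---- dynamics clustering ------------------------------------------
    if config.run_clustering:
        if not dge_results:
            raise ValueError("clustering stage requires the dge stage")
        try:
            genes = deg_set(dge_results["A_vs_control"], config.cluster_fdr).index
            if len(genes) < 2:
                report["stages"]["clustering"] = "skipped (too few deregulated genes)"
            else:
                sub = qt.ExpressionMatrix(
                    expr_log.values.loc[genes], unit="log2TPM1"
                )
                if config.condition_means:
                    means = sub.values.T.groupby(design["condition"]).mean().T
                    means = means[[names[c] for c in ("control", "A", "B", "AB")]]
                    sub = qt.ExpressionMatrix(means, unit="log2TPM1")
                    conditions = ["control", "A", "B", "AB"]
                else:
                    role_of = {v: k for k, v in names.items()}
                    conditions = [
                        role_of[design.loc[s, "condition"]] for s in sub.values.columns
                    ]
                prof = qt.zscore_rows(sub)
                k_eff = min(config.k, len(genes))
                if k_eff < config.k:
                    log.warning("k reduced to %d (only %d genes)", k_eff, len(genes))
                model = cl.kmeans(prof.values, k=k_eff, seed=config.seed)
                cat_map = cl.label_clusters(model, conditions, config.epsilon)
                gene_cat = cat_map.gene_categories(model.assignments)
                out = pd.DataFrame(
                    {"cluster": model.assignments, "category": gene_cat}
                )
                path = outdir / "cluster_assignments.tsv"
                io.write_tsv(out, path)
                _emit(path)
                path = outdir / "cluster_centroids.tsv"
                io.write_tsv(
                    pd.DataFrame(
                        model.centroids,
                        index=pd.Index(range(model.k), name="cluster"),
                        columns=model.columns,
                    ),
                    path,
                    index_name="cluster",
                )
                _emit(path)
                sizes = model.assignments.value_counts().sort_index()
                summary_json = {
                    "k": model.k,
                    "inertia": model.inertia,
                    "converged": model.converged,
                    "cluster_sizes": {int(i): int(v) for i, v in sizes.items()},
                    "cluster_categories": {
                        int(i): c for i, c in cat_map.categories.items()
                    },
                    "category_shares": cat_map.shares(model.assignments),
                }
                path = outdir / "cluster_summary.json"
                io.write_json(summary_json, path)
                _emit(path)
                report["cluster_category_shares"] = summary_json["category_shares"]
                report["stages"]["clustering"] = "ok"
        except Exception as err:
            _fail("clustering", err)

    # ---- over-representation ------------------------------------------
    if config.run_enrich and config.gmt:
        if not dge_results:
            raise ValueError("enrich stage requires the dge stage")
        try:
            from revertome.enrich import ora, read_gmt

            collection = read_gmt(config.gmt)
            table, _ = rv.classify_reversal(
                dge_results["A_vs_control"], dge_results["AB_vs_A"], config.fdr
            )
            query = table.index[
                (table["status"] == "reversed") & (table["lfc_A"] > 0)
            ]
            universe = dge_results["A_vs_control"].table.index[
                dge_results["A_vs_control"].table["tested"]
            ]
            enr = ora(query, collection, universe)
            path = outdir / "enrichment.tsv"
            enr.to_csv(path, sep="\t", index=False, float_format="%.10g")
            _emit(path)
            report["inputs"]["gmt"] = {
                "path": str(config.gmt),
                "sha256": _sha256(config.gmt),
            }
            report["stages"]["enrich"] = "ok"
        except Exception as err:
            _fail("enrich", err)

    io.write_json(report, outdir / "run_report.json")
    return report
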