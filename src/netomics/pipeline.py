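"""End-to-end orchestration of the integrative pipeline.

Stage order mirrors the analysis workflow: spectra are calibrated and fitted
into a raw metabolite matrix, normalized in two steps (DNA concentration,
then median scaling), the expression matrix becomes a weighted co-expression
network with modules/eigengenes/kME, eigengenes are correlated with
metabolites and meta-clustered, modules are enriched against a gene-set
collection ranked by kME, and sample-level clustering plus survival
statistics close the loop. Every intermediate table is written to the
output directory, and a JSON run report records seeds, counts and QC
exclusions. A stage failure aborts with the stage name; artifacts of
completed stages are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort, enrich, integrate, io, network, nmr

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str | Path = "pipeline_out"
    expression_path: str | Path | None = None
    spectra_dir: str | Path | None = None
    templates_path: str | Path | None = None
    dna_path: str | Path | None = None
    metabolites_path: str | Path | None = None  # alternative to spectra_dir
    gmt_path: str | Path | None = None
    survival_path: str | Path | None = None
    seed: int = 0
    network: network.NetworkConfig = field(default_factory=network.NetworkConfig)
    fit: nmr.FitConfig = field(default_factory=nmr.FitConfig)
    n_meta_clusters: int | None = 4
    edge_threshold: float = 0.5
    hub_quantile: float = 0.9
    gsea_n_perm: int = 200
    gsea_weight_p: float = 1.0
    consensus_kmax: int = 6
    consensus_reps: int = 50
    consensus_fraction: float = 0.8


def _preflight(config: PipelineConfig) -> None:
    if config.expression_path is None:
        raise ValueError("expression_path is required")
    if config.spectra_dir is None and config.metabolites_path is None:
        raise ValueError("either spectra_dir or metabolites_path is required")
    for name in (
        "expression_path",
        "spectra_dir",
        "templates_path",
        "dna_path",
        "metabolites_path",
        "gmt_path",
        "survival_path",
    ):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            raise ValueError(f"{name} does not exist: {value}")


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run report."""
    _preflight(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    def run_stage(name, fn):
        logger.info("stage %s", name)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            io.write_json_report(report, outdir / "report.json")
            raise PipelineError(name, exc) from exc
        report["stages"].append(name)
        return result

    expr = run_stage("read-expression", lambda: io.read_matrix(config.expression_path))
    report["n_genes"], report["n_samples"] = map(int, expr.shape)

    # --- metabolite quantification -------------------------------------
    def metabolite_stage() -> pd.DataFrame:
        if config.metabolites_path is not None:
            # pre-quantified matrix (e.g. a simulated cohort): used as-is
            report["n_spectra_excluded_qc"] = 0
            values = io.read_matrix(config.metabolites_path)
            io.write_matrix(values, outdir / "metabolites.tsv", "metabolite")
            return values
        library = (
            nmr.load_template_library(config.templates_path)
            if config.templates_path
            else nmr.default_template_library()
        )
        spectra = [
            nmr.read_spectrum(p)
            for p in sorted(Path(config.spectra_dir).glob("*.tsv"))
        ]
        raw, fits = nmr.quantify_spectra(spectra, library, config.fit)
        report["n_spectra_excluded_qc"] = sum(not f.passed_qc for f in fits)
        if config.dna_path is not None:
            dna = io.read_matrix(config.dna_path).iloc[:, 0]
            raw = nmr.normalize_dna(raw, dna)
        else:
            raw = nmr.MetaboliteMatrix(values=raw.values, stage="dna_normalized")
        final = nmr.normalize_median(raw)
        io.write_matrix(final.values, outdir / "metabolites.tsv", "metabolite")
        return final.values

    metabolites = run_stage("fit-nmr+normalize", metabolite_stage)
    report["n_metabolites"] = int(metabolites.shape[0])

    # --- network ---------------------------------------------------------
    def network_stage() -> network.NetworkState:
        state = network.build_network(expr, config.network, metabolites)
        io.write_matrix(
            state.module_labels.to_frame(), outdir / "modules.tsv", "gene"
        )
        io.write_matrix(state.eigengenes, outdir / "eigengenes.tsv", "module")
        io.write_matrix(state.kme, outdir / "kme.tsv", "gene")
        if state.gs is not None:
            io.write_matrix(state.gs, outdir / "gs.tsv", "gene")
        return state

    state = run_stage("network", network_stage)
    report["beta"] = state.beta
    report["n_modules"] = int(state.eigengenes.shape[0])

    # --- integration -----------------------------------------------------
    def integration_stage():
        cm = integrate.correlate_modules_metabolites(state.eigengenes, metabolites)
        mc = integrate.cluster_of_clusters(cm, k=config.n_meta_clusters)
        keys = integrate.key_metabolites(mc, cm)
        net = integrate.export_network(
            cm,
            kme=state.kme,
            threshold=config.edge_threshold,
            hub_quantile=config.hub_quantile,
        )
        io.write_matrix(cm.r, outdir / "corr.tsv", "module")
        io.write_matrix(cm.p_adj, outdir / "pvals_adj.tsv", "module")
        mc.entity_labels.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"cluster": c, "key_metabolite": m} for c, m in keys.items()]
        ).to_csv(outdir / "key_metabolites.tsv", sep="\t", index=False)
        io.write_edges(net.edges, outdir / "network_edges.tsv")
        return cm, mc, keys

    cm, mc, keys = run_stage("integrate", integration_stage)
    report["n_meta_clusters"] = int(mc.n_clusters)
    report["key_metabolites"] = {str(c): m for c, m in keys.items()}

    # --- enrichment ------------------------------------------------------
    if config.gmt_path is not None:

        def gsea_stage() -> pd.DataFrame:
            collection = enrich.read_gmt(config.gmt_path)
            tables = []
            for module in state.eigengenes.index:
                ranked = enrich.rank_by_connectivity(state.kme, module)
                table = enrich.gsea_table(
                    ranked,
                    collection,
                    weight_p=config.gsea_weight_p,
                    n_perm=config.gsea_n_perm,
                    seed=config.seed,
                )
                tables.append(table.assign(module=module))
            out = pd.concat(tables, ignore_index=True)
            out.to_csv(outdir / "gsea.tsv", sep="\t", index=False)
            return out

        gsea = run_stage("gsea", gsea_stage)
        report["n_enrichment_tests"] = int(len(gsea))

    # --- cohort clustering ----------------------------------------------
    def cluster_stage() -> cohort.ConsensusResult:
        result = cohort.consensus_cluster(
            expr.T,
            kmax=config.consensus_kmax,
            reps=config.consensus_reps,
            subsample_fraction=config.consensus_fraction,
            seed=config.seed,
        )
        result.labels[result.best_k].to_frame().to_csv(
            outdir / "sample_clusters.tsv", sep="\t", index_label="sample"
        )
        return result

    consensus = run_stage("cluster", cluster_stage)
    report["consensus_best_k"] = int(consensus.best_k)

    # --- survival --------------------------------------------------------
    if config.survival_path is not None:

        def survival_stage() -> dict:
            table = io.read_survival(config.survival_path)
            km = cohort.km_estimate(table)
            km.to_csv(outdir / "km.tsv", sep="\t", index=False)
            chi2_stat, p = cohort.logrank_test(table)
            tests = {"logrank_chi2": chi2_stat, "logrank_p": p}
            if table["group"].nunique() == 2:
                hr, ci = cohort.cox_hr(table)
                tests.update({"cox_hr": hr, "cox_ci_low": ci[0], "cox_ci_high": ci[1]})
            io.write_json_report(tests, outdir / "tests.json")
            return tests

        tests = run_stage("survival", survival_stage)
        report["survival"] = tests

    io.write_json_report(report, outdir / "report.json")
    return report
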