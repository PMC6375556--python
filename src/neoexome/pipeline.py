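"""End-to-end demo pipeline: simulate -> filter -> impact -> burden ->
signatures -> enrichment -> clonal -> clinical, with a JSON manifest.

Each stage is a thin call into the corresponding library module; outputs are
written as the documented text formats under one output directory. The
manifest records the package version, the seed, and per-stage counts, and is
byte-identical across reruns with the same configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

from . import burden as B
from . import clinical as C
from . import clonal as K
from . import enrichment as E
from . import filters as F
from . import impact as I
from . import io_formats as io
from . import refdata
from . import signatures as S
from . import synthetic as syn


@dataclass
class PipelineConfig:
    out_dir: str = "neoexome_out"
    seed: int = 0
    n_snvs: int = 400
    n_indels: int = 60
    planted_failures: dict[str, int] = field(
        default_factory=lambda: {"tumour_depth": 5, "vaf": 5, "indel_interior_support": 3}
    )
    signature_weights: dict[str, float] = field(
        default_factory=lambda: {"Signature 1": 0.6, "Signature 3": 0.4}
    )
    clone_vafs_diagnostic: list[float] = field(default_factory=lambda: [0.45, 0.15])
    clone_vafs_residual: list[float] = field(default_factory=lambda: [0.40, 0.25])
    clone_map_residual: list[int | None] | None = field(default_factory=lambda: [0, None])
    depth_track_bp: int = 200_000
    callable_fraction: float = 0.9
    signature_matrix: str | None = None  # CSV path; None: bundled synthetic catalog
    gene_sets: str | None = None  # GMT path; None: bundled demo sets
    filter_overrides: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _package_version() -> str:
    try:
        return version("neoexome")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic data; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": _package_version(), "seed": config.seed, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                manifest["stages"][name] = fn()
            except Exception as exc:
                raise StageError(name, exc) from exc

        return deco

    if config.signature_matrix:
        if not Path(config.signature_matrix).exists():
            raise StageError("signatures", FileNotFoundError(config.signature_matrix))
        matrix = io.read_signature_matrix(config.signature_matrix)
    else:
        matrix = refdata.synthetic_signature_catalog()
    gene_sets = io.read_gmt(config.gene_sets) if config.gene_sets else refdata.demo_gene_sets()
    params = F.FilterParams(**config.filter_overrides)

    sim = syn.SimulationConfig(
        seed=config.seed,
        n_snvs=config.n_snvs,
        n_indels=config.n_indels,
        planted_failures=dict(config.planted_failures),
        signature_weights=dict(config.signature_weights),
        clone_vafs_diagnostic=list(config.clone_vafs_diagnostic),
        clone_vafs_residual=list(config.clone_vafs_residual),
        clone_map_residual=config.clone_map_residual,
    )

    state: dict = {}

    @stage("simulate")
    def _():
        tumour, germ, truth = syn.generate_pair(sim, matrix)
        io.write_variants(tumour, out / "tumour_variants.tsv")
        io.write_variants(germ, out / "germline_variants.tsv")
        (out / "ground_truth.json").write_text(
            json.dumps(
                {
                    "fates": {u: [fate, reasons] for u, (fate, reasons) in truth.fates.items()},
                    "signatures": truth.signatures,
                },
                indent=2,
            )
        )
        state.update(tumour=tumour, germ=germ, truth=truth)
        return {"n_tumour_records": len(tumour), "n_germline_records": len(germ)}

    @stage("filter")
    def _():
        audit = F.filter_variants(state["tumour"], params)
        audit.write_tsv(out / "filter_audit.tsv")
        audit.write_json(out / "filter_summary.json")
        state["kept"] = F.apply_audit(state["tumour"], audit)
        return {"n_kept": len(audit.kept), "n_rejected": len(audit.rejected),
                "reason_counts": audit.reason_counts}

    @stage("impact")
    def _():
        genic = F.restrict_for_gene_analysis(I.select_nonsynonymous(state["kept"]), params)
        table = I.impact_table(genic)
        table.to_csv(out / "impact.tsv", sep="\t", index=False)
        state["hfi_genes"] = I.hfi_gene_list(genic)
        return {"n_candidates": len(genic), "n_hfi": int(table["hfi"].sum()),
                "n_hfi_genes": len(state["hfi_genes"])}

    @stage("burden")
    def _():
        track = syn.generate_depth_track(config.depth_track_bp, config.callable_fraction, config.seed)
        io.write_depth_track(track, out / "depth_track.bed")
        bases = B.callable_bases(track)
        result = B.mutation_burden(state["kept"], bases)
        (out / "burden.json").write_text(json.dumps(result.__dict__, indent=2) + "\n")
        return {"callable_bases": bases, "burden_all_per_mb": result.burden_all,
                "burden_nonsyn_per_mb": result.burden_nonsyn}

    @stage("signatures")
    def _():
        catalog = S.build_catalog([r for r in state["tumour"] if r.kind == "SNV"])
        catalog.to_frame().to_csv(out / "catalog.tsv", sep="\t", index=False)
        fit = S.fit_signatures(catalog, matrix)
        (out / "signature_fit.json").write_text(
            json.dumps({"weights": fit.weights, "unexplained": fit.unexplained,
                        "sse": fit.sse, "n_mutations": fit.n_mutations}, indent=2) + "\n"
        )
        return {"n_catalog_mutations": catalog.total, "weights": fit.weights}

    @stage("enrichment")
    def _():
        genes = state["hfi_genes"] or ["TP53"]
        results = E.enrich_sample(genes, gene_sets, sample_id="S01")
        E.results_table(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return {"n_query_genes": len(genes), "n_overlapping_sets": len(results),
                "n_significant": sum(r.significant for r in results)}

    @stage("clonal")
    def _():
        diag, resid, truth = syn.generate_timepoint_pair(sim, matrix)
        d_clusters = K.cluster_vafs(diag, seed=config.seed)
        r_clusters = K.cluster_vafs(resid, seed=config.seed)
        trajectories = K.track_clones(d_clusters, r_clusters, patient_id=sim.sample_id)
        K.river_table(trajectories).to_csv(out / "river.tsv", sep="\t", index=False)
        return {"n_diagnostic_clusters": len(d_clusters), "n_residual_clusters": len(r_clusters),
                "fates": {t.clone_label: t.fate for t in trajectories}}

    @stage("clinical")
    def _():
        cohort = syn.generate_cohort(syn.CohortSpec(seed=config.seed))
        C.write_outcomes(cohort, out / "outcomes.csv")
        rates = C.response_rates(cohort)
        (out / "rates.json").write_text(json.dumps(rates, indent=2) + "\n")
        curve, median = C.km_dfs(cohort)
        curve.to_csv(out / "km_dfs.tsv", sep="\t", index=False)
        rdi = C.dose_intensity(cohort)
        C.ae_table(cohort).to_csv(out / "adverse_events.tsv", sep="\t", index=False)
        alpha, power = C.design_operating_characteristics(C.DesignSpec())
        return {
            "n_patients": len(cohort),
            "breast_pcr_pct": rates["breast_pcr"]["percent"],
            "median_dfs": median,
            "rdi_ge_085_pct": rdi["at_or_above_threshold"]["percent"],
            "design_alpha_pct": round(100 * alpha),
            "design_power_pct": round(100 * power),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
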