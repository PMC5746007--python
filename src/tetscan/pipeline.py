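"""End-to-end orchestration: simulate -> preprocess -> annotate -> DE ->
cross-strain -> cis scan -> dose response, from one seeded configuration.

Every stage writes its outputs under the configured directory and records
parameters, output checksums and headline counts in a machine-readable run
report. All randomness funnels through one root seed, expanded per stage
deterministically, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, cis_scan, cross_strain, de, dose_response, preprocess, simulate

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("tetscan.pipeline")

STAGE_ORDER = ["simulate", "preprocess", "annotate", "de", "crossstrain", "cisscan", "doseresponse"]
STAGE_DEPS = {
    "preprocess": ["simulate"],
    "annotate": ["simulate"],
    "de": ["preprocess", "annotate"],
    "crossstrain": ["de"],
    "cisscan": ["de"],
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Flat configuration for the whole pipeline; unknown keys are rejected
    by :func:`load_config`. Defaults give a desk-scale synthetic run of the
    five-strain, two-stage, two-condition, three-replicate design."""

    out_dir: str = "tetscan_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))

    # simulate
    n_genes: int = 2000
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"2L": 23_000_000, "2R": 25_000_000, "3L": 28_000_000,
                                 "3R": 32_000_000, "4": 1_350_000, "X": 23_500_000}
    )
    n_strains: int = 5  # first strain is the non-transgenic control
    replicates: int = 3
    stages_biological: tuple[str, ...] = ("adult", "larva")
    probes_per_gene: int = 2
    n_negative_controls: int = 200
    k_shared: int = 0
    delta_shared: float = 0.0
    k_trans: int = 0
    trans_mean: float = 0.0
    trans_sd: float = 0.5
    cis_mode: str = "genes"
    cis_size: float = 0
    delta_cis: float = 0.0
    global_shift: float = 0.0
    mu_b: float = 100.0
    sigma_b: float = 10.0
    alpha_s: float = 1.0
    sigma_r: float = 0.2

    # preprocess
    factor: float = 0.9
    min_arrays: int = 3
    offset: float = 0.0
    filter_convention: str = "paper"

    # annotate
    max_evalue: float = 1e-20
    min_identity: float = 100.0

    # de
    fdr_q: float = 0.10
    straddle_alpha: float = 0.05

    # cisscan
    window: int = 10
    tau: float = 0.30
    iterations: int = 10_000
    stratum: str = "arm"
    scan_scope: str = "genome"

    # doseresponse
    doses: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)
    vials_per_dose: int = 10
    offspring_mean: float = 80.0
    dr_ec50: float = 3.3
    dr_hill: float = 2.0
    dr_ceiling: float = 1.0

    def stage_seed(self, stage: str) -> int:
        idx = STAGE_ORDER.index(stage)
        return int(np.random.SeedSequence((self.seed, idx)).generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    for key in ("stages_biological", "doses"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _design(config: PipelineConfig, genome: simulate.GenomeModel) -> simulate.StrainDesign:
    """One non-transgenic control plus transgenic strains with insertion loci
    at mid-chromosome, round-robin over the simulated chromosomes."""
    chroms = list(config.chromosomes)
    strains: list[tuple[str, str | None, int | None, str]] = [("non-tTAV", None, None, "none")]
    for i in range(1, config.n_strains):
        chrom = chroms[(i - 1) % len(chroms)]
        strains.append((f"strain{i:02d}-tTAV", chrom, config.chromosomes[chrom] // 2,
                        "hom" if i == config.n_strains - 1 else "het"))
    return simulate.StrainDesign(
        strains=strains, stages=config.stages_biological, replicates=config.replicates
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in canonical order and return the run
    report (also written to ``report.json``)."""
    t0 = time.time()
    enabled = [s for s in STAGE_ORDER if s in config.stages]
    for stage in enabled:
        for dep in STAGE_DEPS.get(stage, []):
            if dep not in enabled:
                raise PipelineError(f"stage {stage!r} requires stage {dep!r}, which is disabled")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(config).items()},
                    "stages": {}, "files": {}}

    experiment: simulate.SimulatedExperiment | None = None
    normalized: dict[str, pd.DataFrame] = {}
    expressed_probes: dict[tuple[str, str], set[str]] = {}  # (strain, stage) -> probes
    probe_map: annotation.ProbeGeneMap | None = None
    de_tables: dict[tuple[str, str], pd.DataFrame] = {}

    def record(stage: str, paths: dict[str, Path], **counts) -> None:
        report["stages"][stage] = {"counts": counts, "seed": config.stage_seed(stage)}
        for name, p in paths.items():
            report["files"][f"{stage}/{name}"] = _sha256(Path(p))

    # ---------------------------------------------------------------- simulate
    if "simulate" in enabled:
        log.info("stage simulate")
        seed = config.stage_seed("simulate")
        genome = simulate.make_genome(config.n_genes, list(config.chromosomes.items()), seed=seed)
        design = _design(config, genome)
        effects = simulate.EffectModel(
            shared_core=(config.k_shared, config.delta_shared),
            trans_per_strain=(config.k_trans, config.trans_mean, config.trans_sd),
            cis=(config.cis_mode, config.cis_size, config.delta_cis),
            global_shift=config.global_shift,
            seed=seed + 1,
        )
        truth = simulate.simulate_effects(genome, design, effects)
        experiment = simulate.simulate_intensities(
            genome, design, truth,
            noise=(config.mu_b, config.sigma_b, config.alpha_s, config.sigma_r),
            probes_per_gene=config.probes_per_gene,
            n_negative_controls=config.n_negative_controls,
            seed=seed + 2,
        )
        paths = simulate.write_fixture(experiment, out)
        paths["hits"] = simulate.write_synthetic_hits(experiment, out / "hits.tsv")
        record("simulate", paths,
               n_genes=genome.n_genes, n_probes=len(experiment.probes),
               n_samples=len(experiment.samples))
    elif any(s in enabled for s in ("preprocess", "annotate")):
        experiment = simulate.read_fixture(out)

    # -------------------------------------------------------------- preprocess
    if "preprocess" in enabled:
        log.info("stage preprocess")
        assert experiment is not None
        control_mask = pd.Series(
            experiment.probes["gene_id"].eq("NEG").to_numpy(),
            index=experiment.probes["probe_id"],
        )
        paths = {}
        counts = {}
        for stage_bio in config.stages_biological:
            sample_ids = experiment.samples.loc[
                experiment.samples["stage"] == stage_bio, "sample_id"
            ].tolist()
            norm, _params = preprocess.normalize_stage(
                experiment.intensities[sample_ids], control_mask, offset=config.offset
            )
            normalized[stage_bio] = norm
            # the expression filter runs per strain within the stage, over that
            # strain's arrays, so each strain gets its own expressed universe
            for strain in experiment.samples["strain"].unique():
                cols = experiment.samples.loc[
                    (experiment.samples["stage"] == stage_bio)
                    & (experiment.samples["strain"] == strain),
                    "sample_id",
                ].tolist()
                retained, _rep = preprocess.low_intensity_filter(
                    norm[cols], control_mask,
                    min_arrays=config.min_arrays, factor=config.factor,
                    convention=config.filter_convention,
                )
                expressed_probes[(strain, stage_bio)] = set(retained)
            qc = preprocess.qc_summaries(norm)
            norm_path = out / f"normalized_{stage_bio}.tsv"
            norm.to_csv(norm_path, sep="\t", float_format="%.6f")
            qc_path = out / f"qc_{stage_bio}.json"
            qc_path.write_text(json.dumps({
                "rle_median": qc["rle_median"].round(6).to_dict(),
                "variance_explained": qc["variance_explained"],
            }, indent=1))
            expr_path = out / f"expressed_probes_{stage_bio}.txt"
            union = sorted(set().union(*(expressed_probes[(s, stage_bio)]
                                         for s in experiment.samples["strain"].unique())))
            expr_path.write_text("\n".join(union) + "\n")
            paths[f"normalized_{stage_bio}"] = norm_path
            paths[f"qc_{stage_bio}"] = qc_path
            paths[f"expressed_probes_{stage_bio}"] = expr_path
            counts[f"expressed_probes_{stage_bio}"] = len(union)
        record("preprocess", paths, **counts)

    # ---------------------------------------------------------------- annotate
    if "annotate" in enabled:
        log.info("stage annotate")
        hits = annotation.read_hits(out / "hits.tsv")
        retained = annotation.filter_hits(hits, min_identity=config.min_identity,
                                          max_evalue=config.max_evalue)
        gene_table = simulate.read_genes_bed(out / "genes.bed")
        probe_map = annotation.build_probe_gene_map(retained, gene_table)
        map_path = out / "probe_gene_map.tsv"
        probe_map.table.to_csv(map_path, sep="\t", index=False)
        rep_path = out / "annotation_report.json"
        rep_path.write_text(json.dumps({
            "n_hits": len(hits), "n_retained": len(retained),
            "n_mapped": len(probe_map.table),
            "dropped_no_coords": probe_map.dropped_no_coords,
        }, indent=1))
        record("annotate", {"probe_gene_map": map_path, "annotation_report": rep_path},
               n_hits=len(hits), n_retained=len(retained), n_mapped=len(probe_map.table))

    # ---------------------------------------------------------------------- de
    if "de" in enabled:
        log.info("stage de")
        assert experiment is not None and probe_map is not None
        mapping = pd.Series(probe_map.mapping)
        paths = {}
        summary = {}
        for stage_bio in config.stages_biological:
            norm = normalized[stage_bio]
            for strain in experiment.samples["strain"].unique():
                sel = experiment.samples[
                    (experiment.samples["stage"] == stage_bio)
                    & (experiment.samples["strain"] == strain)
                ]
                contrast = de.ContrastSpec(
                    strain=strain, stage=stage_bio,
                    group_a=tuple(sel.loc[sel["condition"] == simulate.TET_OFF, "sample_id"]),
                    group_b=tuple(sel.loc[sel["condition"] == simulate.TET_ON, "sample_id"]),
                )
                probes = sorted(expressed_probes[(strain, stage_bio)] & set(mapping.index))
                genes = de.run_contrast(
                    norm.loc[probes], contrast, mapping,
                    q=config.fdr_q, straddle_alpha=config.straddle_alpha,
                )
                de_tables[(strain, stage_bio)] = genes
                path = out / f"de_{strain}_{stage_bio}.tsv"
                genes.to_csv(path, sep="\t", float_format="%.6g")
                paths[f"de_{strain}_{stage_bio}"] = path
                summary[f"{strain}/{stage_bio}"] = {
                    "n_genes": len(genes), "n_de": int(genes["de"].sum()),
                }
        sum_path = out / "de_summary.json"
        sum_path.write_text(json.dumps(summary, indent=1))
        paths["de_summary"] = sum_path
        record("de", paths, **{k.replace("/", "_") + "_de": v["n_de"] for k, v in summary.items()})

    # -------------------------------------------------------------- crossstrain
    if "crossstrain" in enabled:
        log.info("stage crossstrain")
        assert experiment is not None
        paths = {}
        counts = {}
        strains = list(experiment.samples["strain"].unique())
        for stage_bio in config.stages_biological:
            expressed_sets = {
                s: set(de_tables[(s, stage_bio)].index) for s in strains
            }
            overlap = cross_strain.set_intersections(expressed_sets)
            ov_path = out / f"overlap_{stage_bio}.tsv"
            overlap.to_frame().to_csv(ov_path, sep="\t", index=False)
            paths[f"overlap_{stage_bio}"] = ov_path
            counts[f"shared_expressed_{stage_bio}"] = overlap.intersection_size

            de_sets = {
                s: set(de_tables[(s, stage_bio)].query("de").index)
                for s in strains if s != strains[0]  # transgenic strains only
            }
            shared_de = set.intersection(*de_sets.values()) if de_sets else set()
            counts[f"shared_de_{stage_bio}"] = len(shared_de)
            if shared_de:
                fc = pd.DataFrame({
                    s: np.exp2(de_tables[(s, stage_bio)].loc[sorted(shared_de), "beta"])
                    for s in de_sets
                })
                cons = cross_strain.direction_consistency(fc)
                cons_path = out / f"consistency_{stage_bio}.tsv"
                cons.to_csv(cons_path, sep="\t", float_format="%.4f")
                paths[f"consistency_{stage_bio}"] = cons_path

            diffs = {
                s: de_tables[(s, stage_bio)]["beta"] for s in strains
            }
            corr = cross_strain.pairwise_diff_correlation(diffs)
            corr_path = out / f"correlations_{stage_bio}.tsv"
            corr.to_csv(corr_path, sep="\t", index=False, float_format="%.6g")
            paths[f"correlations_{stage_bio}"] = corr_path
        record("crossstrain", paths, **counts)

    # ------------------------------------------------------------------ cisscan
    if "cisscan" in enabled:
        log.info("stage cisscan")
        assert experiment is not None
        seed = config.stage_seed("cisscan")
        gene_table = experiment.genome.genes
        paths = {}
        counts = {}
        strains = list(experiment.samples["strain"].unique())
        for stage_bio in config.stages_biological:
            common = set.intersection(*(set(de_tables[(s, stage_bio)].index) for s in strains))
            order = cis_scan.order_genes(gene_table[gene_table["gene_id"].isin(common)])
            for strain in strains:
                de_flags = de_tables[(strain, stage_bio)]["de"]
                labels = {g: bool(de_flags.get(g, False)) for g in common}
                windows = cis_scan.build_windows(order, w=config.window, scope=config.scan_scope)
                scan = cis_scan.flag_windows(windows, labels, tau=config.tau)
                scan_path = out / f"scan_{strain}_{stage_bio}.tsv"
                scan.table.to_csv(scan_path, sep="\t", index=False, float_format="%.3f")
                perm = cis_scan.permutation_test(
                    order, labels, w=config.window, tau=config.tau,
                    n_iterations=config.iterations, seed=seed, stratum=config.stratum,
                )
                perm_path = out / f"perm_{strain}_{stage_bio}.json"
                perm_path.write_text(json.dumps({
                    "n_iterations": perm.n_iterations, "seed": perm.seed,
                    "strata": perm.per_stratum.to_dict(orient="records"),
                }, indent=1))
                paths[f"scan_{strain}_{stage_bio}"] = scan_path
                paths[f"perm_{strain}_{stage_bio}"] = perm_path
                counts[f"flagged_{strain}_{stage_bio}"] = scan.flagged_total
        record("cisscan", paths, **counts)

    # --------------------------------------------------------------- doseresponse
    if "doseresponse" in enabled:
        log.info("stage doseresponse")
        seed = config.stage_seed("doseresponse")
        cross_cfg = dose_response.CrossConfig(
            doses=config.doses, vials_per_dose=config.vials_per_dose,
            offspring_mean=config.offspring_mean, seed=seed,
        )
        params = dose_response.ViabilityParams(
            ec50=config.dr_ec50, hill=config.dr_hill, ceiling=config.dr_ceiling
        )
        vials = dose_response.simulate_cross(cross_cfg, params)
        vials_path = out / "vials.tsv"
        vials.assign(compound="tetracycline")[
            ["compound", "dose_ugml", "vial", "red", "white"]
        ].to_csv(vials_path, sep="\t", index=False)
        results = dose_response.DoseResponseModel.from_vials(vials, "tetracycline").fit()
        fit_path = out / "fit.json"
        fit_path.write_text(json.dumps(results.to_dict(), indent=1))
        record("doseresponse", {"vials": vials_path, "fit": fit_path},
               ic50=results.ec50, converged=results.converged)

    # ------------------------------------------------------------------- report
    if de_tables:
        for (strain, stage_bio), table in de_tables.items():
            n_de = int(table["de"].sum())
            if n_de > len(table):
                raise PipelineError("inconsistent report: DE set larger than expressed set")
    report["wall_time_s"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
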