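"""Synthetic probe-level microarray experiments with known ground truth.

The generator emulates the design of the insertion-site study: five strains
(four transgenic insertion lines plus a non-transgenic control), two life
stages, two tetracycline conditions and three biological replicates per cell.
Observed intensities follow the additive model assumed by normexp background
correction — an exponential-scale true signal plus Gaussian background — and
negative-control probes carry background only.

Truth is expressed as per-strain, per-stage gene-level log2 fold changes
(tet-off minus tet-on). A positive value means higher expression without
tetracycline, i.e. with the feedback circuit active, matching the fold-change
convention used downstream. Three effect classes encode the biological
hypotheses the downstream analysis probes: a shared core gene set (same genes,
same effect in every strain), strain-specific trans effects (independent gene
draws per strain), and cis effects (the genes nearest each strain's insertion
locus), plus an optional genome-wide shift when the circuit is active (a
squelching surrogate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "StrainDesign",
    "EffectModel",
    "SimulatedExperiment",
    "make_genome",
    "simulate_effects",
    "simulate_intensities",
    "write_fixture",
    "read_fixture",
    "write_synthetic_hits",
]

TET_ON = "tet_on"
TET_OFF = "tet_off"


class ConfigurationError(ValueError):
    """Raised when simulation parameters are inconsistent or out of range."""


@dataclass(frozen=True)
class GenomeModel:
    """An ordered gene map over a set of chromosomes.

    ``genes`` has columns ``gene_id, chrom, start, end`` with 1-based
    inclusive coordinates, sorted by (chrom, start); ``chromosomes`` maps
    label -> length in bp.
    """

    genes: pd.DataFrame
    chromosomes: dict[str, int]

    def __post_init__(self) -> None:
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise ConfigurationError("duplicate gene ids in genome")
        if (g["start"] < 1).any() or (g["start"] > g["end"]).any():
            raise ConfigurationError("gene coordinates must satisfy 1 <= start <= end")
        for chrom, sub in g.groupby("chrom", sort=False):
            if not sub["start"].is_monotonic_increasing:
                raise ConfigurationError(f"genes on {chrom} not sorted by start")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class StrainDesign:
    """Experimental design: strains with insertion loci, stages, replicates.

    ``strains`` is a list of ``(strain_id, insertion_chrom, insertion_pos,
    zygosity)``; a strain with ``insertion_chrom=None`` is a non-transgenic
    control. ``zygosity`` is "het" or "hom" (recorded, not modelled).
    """

    strains: list[tuple[str, str | None, int | None, str]]
    stages: tuple[str, ...] = ("adult", "larva")
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ConfigurationError("need >= 2 replicates per cell")

    @property
    def conditions(self) -> tuple[str, str]:
        return (TET_ON, TET_OFF)


def default_design() -> StrainDesign:
    """The study's five-strain design: one non-transgenic control and four
    insertion lines on chromosomes 2R, 3L, 3R and 4 (one homozygous)."""
    return StrainDesign(
        strains=[
            ("non-tTAV", None, None, "none"),
            ("51D-tTAV", "2R", 15_054_298, "het"),
            ("76A2-tTAV", "3L", 19_204_358, "het"),
            ("86F-tTAV", "3R", 11_808_607, "het"),
            ("102D-tTAV", "4", 988_349, "hom"),
        ]
    )


@dataclass(frozen=True)
class EffectModel:
    """True-effect configuration for :func:`simulate_effects`.

    shared_core : (k_shared, delta_shared)
        k genes carrying the identical log2 effect in every transgenic strain.
    trans_per_strain : (k_trans, mean, sd)
        per-strain independent gene draws with Normal(mean, sd) log2 effects.
    cis : (mode, size, delta_cis)
        mode "genes" (size = gene count nearest the insertion) or "bp"
        (size = bp radius around the insertion); effect delta_cis in log2.
    global_shift : log2 offset added to every gene when the circuit is on.
    """

    shared_core: tuple[int, float] = (0, 0.0)
    trans_per_strain: tuple[int, float, float] = (0, 0.0, 0.0)
    cis: tuple[str, float, float] = ("genes", 0, 0.0)
    global_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shared_core[0] < 0 or self.trans_per_strain[0] < 0:
            raise ConfigurationError("effect gene counts must be >= 0")
        if self.cis[0] not in ("genes", "bp"):
            raise ConfigurationError("cis mode must be 'genes' or 'bp'")


@dataclass
class SimulatedExperiment:
    """A complete synthetic experiment: linear-scale intensities (probes x
    samples), sample sheet, probe table with negative-control flags and
    per-probe affinities, the gene-level truth table and the genome."""

    intensities: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame
    truth: pd.DataFrame
    genome: GenomeModel


def make_genome(
    n_genes: int,
    chromosome_spec: list[tuple[str, int]],
    seed: int,
) -> GenomeModel:
    """Distribute ``n_genes`` over chromosomes proportionally to length.

    Gene ids are FBgn-style and assigned in genome order; starts are strictly
    increasing within a chromosome, and gene lengths are drawn uniformly in
    [500, 5000] bp (clipped to the chromosome end).
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    if not chromosome_spec:
        raise ConfigurationError("chromosome spec is empty")
    rng = np.random.default_rng(seed)
    lengths = np.array([length for _, length in chromosome_spec], dtype=float)
    if (lengths <= 0).any():
        raise ConfigurationError("chromosome lengths must be positive")
    # largest-remainder apportionment so per-arm counts sum exactly to n_genes
    quota = n_genes * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    remainder = n_genes - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1

    rows = []
    gid = 1
    for (chrom, length), k in zip(chromosome_spec, counts):
        if k == 0:
            continue
        starts = _sorted_unique_starts(rng, k, length)
        gene_len = rng.integers(500, 5001, size=len(starts))
        ends = np.minimum(starts + gene_len - 1, length)
        for s, e in zip(starts, ends):
            rows.append((f"FBgn{gid:07d}", chrom, int(s), int(e)))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return GenomeModel(genes=genes, chromosomes={c: int(l) for c, l in chromosome_spec})


def _sorted_unique_starts(rng: np.random.Generator, k: int, length: int) -> np.ndarray:
    """k strictly increasing start coordinates in [1, length], sampled
    uniformly without materialising the full coordinate range."""
    k = min(k, length)
    draw = k
    starts: np.ndarray = np.array([], dtype=np.int64)
    while len(starts) < k:
        draw = max(draw * 2, 2 * k)
        starts = np.unique(rng.integers(1, length + 1, size=draw))
    return np.sort(rng.choice(starts, size=k, replace=False))


def nearest_genes(genome: GenomeModel, chrom: str, pos: int, k: int) -> list[str]:
    """The k genes nearest ``pos`` on ``chrom`` by midpoint distance, ties
    broken toward the lower start coordinate."""
    sub = genome.genes[genome.genes["chrom"] == chrom]
    mid = (sub["start"] + sub["end"]) / 2.0
    dist = (mid - pos).abs()
    order = sub.assign(_d=dist).sort_values(["_d", "start"], kind="mergesort")
    return order["gene_id"].head(k).tolist()


def genes_within(genome: GenomeModel, chrom: str, pos: int, radius: float) -> list[str]:
    """Genes whose midpoint lies within ``radius`` bp of ``pos`` on ``chrom``,
    clipping (with a warning) when the window exceeds the chromosome."""
    length = genome.chromosomes.get(chrom)
    if length is not None and (pos - radius < 1 or pos + radius > length):
        warnings.warn(f"cis window around {chrom}:{pos} clipped to chromosome bounds")
    sub = genome.genes[genome.genes["chrom"] == chrom]
    mid = (sub["start"] + sub["end"]) / 2.0
    return sub.loc[(mid - pos).abs() <= radius, "gene_id"].tolist()


def simulate_effects(
    genome: GenomeModel,
    design: StrainDesign,
    model: EffectModel,
) -> pd.DataFrame:
    """Build the truth table: one row per (strain, stage, gene) with the true
    log2 fold change (tet-off minus tet-on).

    Shared-core genes carry the identical effect in every transgenic strain;
    trans genes are drawn independently per strain; cis genes are the genes
    nearest each strain's insertion locus; the global shift applies genome
    wide. Non-transgenic control strains have all-zero truth. Effects are
    stage-invariant.
    """
    k_shared, delta_shared = model.shared_core
    k_trans, mu_t, sd_t = model.trans_per_strain
    cis_mode, cis_size, delta_cis = model.cis
    n = genome.n_genes
    if k_shared > n or k_trans > n:
        raise ConfigurationError("effect gene counts exceed genome size")

    rng = np.random.default_rng(model.seed)
    gene_ids = genome.genes["gene_id"].to_numpy()
    shared_genes = rng.choice(gene_ids, size=k_shared, replace=False)

    rows = []
    for strain_id, ins_chrom, ins_pos, _zyg in design.strains:
        fc = pd.Series(0.0, index=gene_ids)
        if ins_chrom is not None:  # transgenic strains only
            fc[shared_genes] += delta_shared
            if k_trans:
                pool = np.setdiff1d(gene_ids, shared_genes)
                trans_genes = rng.choice(pool, size=k_trans, replace=False)
                fc[trans_genes] += rng.normal(mu_t, sd_t, size=k_trans)
            if cis_size and delta_cis:
                if cis_mode == "genes":
                    cis_genes = nearest_genes(genome, ins_chrom, ins_pos, int(cis_size))
                else:
                    cis_genes = genes_within(genome, ins_chrom, ins_pos, cis_size)
                fc[cis_genes] += delta_cis
            fc += model.global_shift
        for stage in design.stages:
            rows.append(
                pd.DataFrame(
                    {
                        "strain": strain_id,
                        "stage": stage,
                        "gene_id": gene_ids,
                        "true_log2fc": fc.to_numpy(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_intensities(
    genome: GenomeModel,
    design: StrainDesign,
    truth: pd.DataFrame,
    noise: tuple[float, float, float, float] = (100.0, 10.0, 1.0, 0.2),
    probes_per_gene: int = 2,
    n_negative_controls: int = 200,
    seed: int = 0,
) -> SimulatedExperiment:
    """Generate linear-scale probe intensities X = background + signal.

    Background ~ Normal(mu_b, sigma_b) for every probe; signal for a probe of
    gene g in sample s is ``alpha_s * affinity * 2**(baseline_g +
    truth_gs*[tet_off] + Normal(0, sigma_r))``; negative-control probes carry
    background only. Per-gene baseline log2 expression is Uniform(6, 14) and
    per-probe affinity is LogNormal(0, 0.25). ``noise`` is
    (mu_b, sigma_b, alpha_s, sigma_r). Intensities are floored at 1e-3 so the
    linear-scale matrix is strictly positive.
    """
    mu_b, sigma_b, alpha_s, sigma_r = noise
    if sigma_b <= 0 or alpha_s <= 0:
        raise ConfigurationError("sigma_b and alpha_s must be positive")
    if probes_per_gene < 1:
        raise ConfigurationError("probes_per_gene must be >= 1")

    rng = np.random.default_rng(seed)
    gene_ids = genome.genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)

    probe_rows = []
    for g in gene_ids:
        for j in range(probes_per_gene):
            probe_rows.append((f"P_{g}_{j + 1}", g))
    for j in range(n_negative_controls):
        probe_rows.append((f"NEG_{j + 1:05d}", "NEG"))
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id"])
    probes["affinity"] = np.where(
        probes["gene_id"].eq("NEG"),
        1.0,
        rng.lognormal(0.0, 0.25, size=len(probes)),
    )

    baseline = pd.Series(rng.uniform(6.0, 14.0, size=n_genes), index=gene_ids)

    sample_rows = []
    for strain_id, _c, _p, _z in design.strains:
        for stage in design.stages:
            for cond in (TET_ON, TET_OFF):
                for rep in range(1, design.replicates + 1):
                    sample_rows.append((strain_id, stage, cond, rep))
    samples = pd.DataFrame(sample_rows, columns=["strain", "stage", "condition", "replicate"])
    samples.insert(
        0,
        "sample_id",
        [
            f"{s}.{st}.{c}.r{r}"
            for s, st, c, r in samples[["strain", "stage", "condition", "replicate"]].itertuples(index=False)
        ],
    )
    samples["chip_position"] = rng.permutation(len(samples)) + 1

    truth_idx = truth.set_index(["strain", "stage", "gene_id"])["true_log2fc"]

    gene_of_probe = probes["gene_id"].to_numpy()
    is_neg = gene_of_probe == "NEG"
    affinity = probes["affinity"].to_numpy()
    base_per_probe = np.where(is_neg, 0.0, baseline.reindex(gene_of_probe, fill_value=0.0).to_numpy())

    cols = {}
    for row in samples.itertuples(index=False):
        fc = truth_idx.loc[(row.strain, row.stage)].reindex(gene_ids).to_numpy()
        fc_per_probe = np.where(is_neg, 0.0, pd.Series(fc, index=gene_ids).reindex(gene_of_probe, fill_value=0.0).to_numpy())
        active = 1.0 if row.condition == TET_OFF else 0.0
        log2_sig = base_per_probe + active * fc_per_probe + rng.normal(0.0, sigma_r, size=len(probes))
        signal = alpha_s * affinity * np.exp2(log2_sig)
        signal[is_neg] = 0.0
        background = rng.normal(mu_b, sigma_b, size=len(probes))
        cols[row.sample_id] = np.maximum(background + signal, 1e-3)

    intensities = pd.DataFrame(cols, index=probes["probe_id"])
    intensities.index.name = "probe_id"
    return SimulatedExperiment(
        intensities=intensities, samples=samples, probes=probes, truth=truth, genome=genome
    )


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(experiment: SimulatedExperiment, directory: str | Path) -> dict[str, Path]:
    """Write the experiment as plain TSV/BED files.

    Emits ``intensities.tsv`` (probe_id + one column per sample),
    ``samples.tsv``, ``probes.tsv``, ``truth.tsv`` and ``genes.bed``
    (0-based half-open starts). Round-trips losslessly via
    :func:`read_fixture`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": directory / "intensities.tsv",
        "samples": directory / "samples.tsv",
        "probes": directory / "probes.tsv",
        "truth": directory / "truth.tsv",
        "genes": directory / "genes.bed",
    }
    experiment.intensities.to_csv(paths["intensities"], sep="\t", float_format="%.6f")
    experiment.samples.to_csv(paths["samples"], sep="\t", index=False)
    experiment.probes.to_csv(paths["probes"], sep="\t", index=False, float_format="%.6f")
    experiment.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6f")
    bed = experiment.genome.genes.copy()
    bed["start0"] = bed["start"] - 1  # BED is 0-based half-open
    bed[["chrom", "start0", "end", "gene_id"]].to_csv(
        paths["genes"], sep="\t", index=False, header=False
    )
    return paths


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene table (chrom, start, end, gene_id), converting
    0-based half-open starts to 1-based inclusive coordinates."""
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start0", "end", "gene_id"])
    return pd.DataFrame(
        {
            "gene_id": bed["gene_id"],
            "chrom": bed["chrom"].astype(str),
            "start": bed["start0"] + 1,
            "end": bed["end"],
        }
    )


def read_fixture(directory: str | Path) -> SimulatedExperiment:
    """Read back a fixture directory written by :func:`write_fixture`."""
    directory = Path(directory)
    intensities = pd.read_csv(directory / "intensities.tsv", sep="\t", index_col="probe_id")
    samples = pd.read_csv(directory / "samples.tsv", sep="\t")
    probes = pd.read_csv(directory / "probes.tsv", sep="\t")
    truth = pd.read_csv(directory / "truth.tsv", sep="\t")
    genes = read_genes_bed(directory / "genes.bed")
    chrom_lengths = genes.groupby("chrom")["end"].max().to_dict()
    genome = GenomeModel(genes=genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True),
                         chromosomes={c: int(l) for c, l in chrom_lengths.items()})
    return SimulatedExperiment(
        intensities=intensities, samples=samples, probes=probes, truth=truth, genome=genome
    )


def write_synthetic_hits(experiment: SimulatedExperiment, path: str | Path) -> Path:
    """Emit a synthetic alignment hit table (qseqid sseqid evalue pident
    stitle) with one perfect hit per non-control probe, so the annotation
    stage can run end-to-end on simulated data. Synthetic stand-in for a real
    alignment run."""
    path = Path(path)
    rows = []
    for probe_id, gene_id in experiment.probes[["probe_id", "gene_id"]].itertuples(index=False):
        if gene_id == "NEG":
            continue
        rows.append((probe_id, f"{gene_id}-RA", 1e-50, 100.0, f"cdna transcript gene:{gene_id}"))
    pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "pident", "stitle"]).to_csv(
        path, sep="\t", index=False, header=False
    )
    return path
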