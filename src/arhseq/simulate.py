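"""Synthetic two-condition count data with injected cassette-exon skipping.

The generator emulates the count regime of a single-replicate bulk RNA-seq
case-control comparison: multi-exon gene models on one chromosome, expected
exon read counts proportional to gene abundance times exon length, sparse
junction coverage, per-gene expression fold changes between conditions, and
Poisson sampling noise (optionally Gamma-overdispersed).

Skipping events are cassette-exon semantics: one randomly chosen *internal*
exon of each spliced gene has its inclusion rate in the case condition
reduced by psi (first/last exons are never skipped). The skipped exon's own
reads and its incident adjacent junctions lose the excluded mass while the
skip junction bridging the exon gains it, mirroring what a real skipping
event does to exon and junction coverage.

What it does not model: read sequences and alignment errors, positional
coverage bias, paired ends, overlapping genes, multiple simultaneous
isoforms per gene, and biological replicate variability beyond the optional
overdispersion knob.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import (
    AnnotationIndex,
    ExonRecord,
    GeneModel,
    assign_window_lengths,
    enumerate_junctions,
)
from .counting import FeatureCounts, write_count_table

__all__ = [
    "SimulationError",
    "SimConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "write_fixture",
]


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a small but realistic single-replicate comparison:
    200 multi-exon genes (4-12 exons of 80-300 bp), 10% of genes carrying
    one strong cassette skipping event (psi = 0.8 inclusion drop in the
    case condition), two million assigned reads per sample, junction
    coverage at a tenth of exon coverage (junction reads are sparse), and
    moderate per-gene expression fold changes so that splicing detection
    must cope with differential expression.
    """

    n_genes: int = 200
    min_exons: int = 4
    max_exons: int = 12
    min_exon_length: int = 80
    max_exon_length: int = 300
    read_length: int = 75
    library_size: int = 2_000_000
    spliced_fraction: float = 0.1
    psi: float = 0.8  # inclusion-rate drop of the skipped exon in the case
    fold_change_log2_sd: float = 0.5
    abundance_log_sd: float = 1.0
    junction_coverage: float = 0.1
    overdispersion: float = 0.0  # Gamma-mixed Poisson when > 0
    chrom: str = "chrS"
    intron_length: int = 200
    intergenic_gap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.spliced_fraction <= 1:
            raise SimulationError("spliced_fraction must lie in [0, 1]")
        if not 0 <= self.psi <= 1:
            raise SimulationError("psi must lie in [0, 1]")
        if self.min_exons < 2 or self.max_exons < self.min_exons:
            raise SimulationError("need 2 <= min_exons <= max_exons")
        if self.spliced_fraction > 0 and self.max_exons < 3:
            raise SimulationError(
                "cassette skipping needs internal exons; raise max_exons to >= 3"
            )
        if self.library_size <= 0 or self.junction_coverage < 0:
            raise SimulationError("rates must be positive")


@dataclass
class GroundTruth:
    """Which genes/exons carry the injected skipping events."""

    spliced_genes: list[str]
    spliced_exons: list[str]
    psi: dict[str, float]  # per spliced gene
    fold_change: dict[str, float]  # log2, per gene (all genes)


@dataclass
class SimulatedDataset:
    index: AnnotationIndex
    counts_case: FeatureCounts
    counts_control: FeatureCounts
    truth: GroundTruth
    config: SimConfig = field(repr=False, default=None)


def _build_annotation(config: SimConfig, rng: np.random.Generator) -> AnnotationIndex:
    genes: dict[str, GeneModel] = {}
    pos = 1000
    width = len(str(config.n_genes))
    for g in range(config.n_genes):
        gene_id = f"g{g + 1:0{width}d}"
        n_exons = int(rng.integers(config.min_exons, config.max_exons + 1))
        exons = []
        for e in range(n_exons):
            length = int(
                rng.integers(config.min_exon_length, config.max_exon_length + 1)
            )
            exons.append(
                ExonRecord(
                    exon_id=f"{gene_id}e{e + 1}",
                    gene_id=gene_id,
                    chrom=config.chrom,
                    start=pos,
                    end=pos + length,
                )
            )
            pos += length + config.intron_length
        pos += config.intergenic_gap
        gene = GeneModel(gene_id=gene_id, exons=exons)
        gene.junctions = enumerate_junctions(gene)
        genes[gene_id] = gene
    index = AnnotationIndex(
        genes=genes,
        scoring_gene_ids=sorted(genes),
        provenance={"annotation": "simulated", "sha256": ""},
    )
    assign_window_lengths(index, config.read_length, "synthetic")
    return index


def _expected_counts(
    index: AnnotationIndex,
    config: SimConfig,
    abundance: dict[str, float],
    skipped_exon: dict[str, str],
    condition: str,
) -> dict[str, float]:
    """Expected (unscaled) read mass per feature for one condition."""
    w: dict[str, float] = {}
    for gene in index.scoring_genes():
        a = abundance[gene.gene_id]
        skip = skipped_exon.get(gene.gene_id) if condition == "case" else None
        inclusion = {
            e.exon_id: (1.0 - config.psi if e.exon_id == skip else 1.0)
            for e in gene.exons
        }
        for e in gene.exons:
            w[e.exon_id] = a * inclusion[e.exon_id] * e.length
        order = {e.exon_id: i for i, e in enumerate(gene.exons)}
        skip_idx = order.get(skip) if skip is not None else None
        for j in gene.junctions:
            li, ri = order[j.left_exon_id], order[j.right_exon_id]
            mass = 0.0
            if ri == li + 1:  # adjacent junction: both exons in one transcript
                mass = min(inclusion[j.left_exon_id], inclusion[j.right_exon_id])
            elif skip_idx is not None and li == skip_idx - 1 and ri == skip_idx + 1:
                mass = config.psi  # skip junction gains the excluded isoform
            w[j.junction_id] = (
                config.junction_coverage * a * mass * (j.window_length or 0)
            )
    return w


def _sample_counts(
    expected: dict[str, float],
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, int]:
    fids = list(expected)
    w = np.array([expected[f] for f in fids], dtype=float)
    lam = w * (config.library_size / w.sum())
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        lam = np.where(
            lam > 0, rng.gamma(shape, np.maximum(lam, 1e-300) / shape), 0.0
        )
    counts = rng.poisson(lam)
    return dict(zip(fids, (int(c) for c in counts)))


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Generate annotation, case/control counts and ground truth.

    Fully reproducible from ``config.seed``; running twice with the same
    configuration yields identical output.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    index = _build_annotation(config, rng)

    gene_ids = sorted(index.genes)
    n_spliced = round(config.n_genes * config.spliced_fraction)
    eligible = [g for g in gene_ids if index.genes[g].n_exons >= 3]
    if n_spliced > len(eligible):
        raise SimulationError(
            f"cannot place {n_spliced} skipping events: only {len(eligible)} "
            "genes have internal exons"
        )
    spliced = sorted(rng.choice(eligible, size=n_spliced, replace=False).tolist())
    skipped_exon: dict[str, str] = {}
    for g in spliced:
        exons = index.genes[g].exons
        internal = [e.exon_id for e in exons[1:-1]]
        skipped_exon[g] = str(rng.choice(internal))

    base_abundance = {
        g: float(np.exp(rng.normal(0.0, config.abundance_log_sd))) for g in gene_ids
    }
    log2_fold = {
        g: float(rng.normal(0.0, config.fold_change_log2_sd)) for g in gene_ids
    }
    abundance_case = {g: base_abundance[g] * 2.0 ** log2_fold[g] for g in gene_ids}

    def build(condition: str, abundance: dict[str, float]) -> FeatureCounts:
        expected = _expected_counts(index, config, abundance, skipped_exon, condition)
        counts = _sample_counts(expected, config, rng)
        ftype, lengths, genes = {}, {}, {}
        for gene in index.scoring_genes():
            for e in gene.exons:
                ftype[e.exon_id] = "exon"
                lengths[e.exon_id] = e.length
                genes[e.exon_id] = gene.gene_id
            for j in gene.junctions:
                ftype[j.junction_id] = "junction"
                lengths[j.junction_id] = int(j.window_length)
                genes[j.junction_id] = gene.gene_id
        return FeatureCounts(
            sample_id=condition,
            counts=counts,
            feature_type=ftype,
            lengths=lengths,
            gene_ids=genes,
        )

    counts_case = build("case", abundance_case)
    counts_control = build("control", base_abundance)
    truth = GroundTruth(
        spliced_genes=spliced,
        spliced_exons=sorted(skipped_exon.values()),
        psi={g: config.psi for g in spliced},
        fold_change=log2_fold,
    )
    return SimulatedDataset(index, counts_case, counts_control, truth, config)


def write_fixture(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Emit a fixture directory: GTF, count TSVs, truth TSV, config echo.

    The GTF round-trips through the annotation parser and the count TSVs
    through the count-table reader; the truth TSV loads as a true-positive
    event list (conditions named "case"/"control").
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.gtf",
        "counts_case": out / "counts_case.tsv",
        "counts_control": out / "counts_control.tsv",
        "truth": out / "truth.tsv",
        "config": out / "simconfig.json",
    }
    with open(paths["annotation"], "w") as fh:
        for gene_id in sorted(dataset.index.genes):
            for e in dataset.index.genes[gene_id].exons:
                attrs = f'gene_id "{e.gene_id}"; exon_id "{e.exon_id}";'
                fh.write(
                    f"{e.chrom}\tarhseq_sim\texon\t{e.start + 1}\t{e.end}\t.\t+\t.\t{attrs}\n"
                )
    write_count_table(dataset.counts_case, paths["counts_case"])
    write_count_table(dataset.counts_control, paths["counts_control"])
    exon_of_gene = {
        g: e for g, e in zip(dataset.truth.spliced_genes, sorted_exons(dataset))
    }
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\texon_id\tcondition_a\tcondition_b\tpsi\tlog2_fold_change\n")
        for g in dataset.truth.spliced_genes:
            fh.write(
                f"{g}\t{exon_of_gene[g]}\tcase\tcontrol\t"
                f"{dataset.truth.psi[g]}\t{dataset.truth.fold_change[g]}\n"
            )
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(dataset.config), fh, indent=2)
        fh.write("\n")
    return paths


def sorted_exons(dataset: SimulatedDataset) -> list[str]:
    """Skipped exon per spliced gene, aligned with truth.spliced_genes."""
    by_gene = {}
    for eid in dataset.truth.spliced_exons:
        by_gene[dataset.counts_case.gene_ids[eid]] = eid
    return [by_gene[g] for g in dataset.truth.spliced_genes]
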