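"""Shared fixtures: toy annotations, SAM builders, simulated datasets."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from arhseq.annotation import AnnotationIndex, ExonRecord, GeneModel, enumerate_junctions
from arhseq.simulate import SimConfig, simulate_dataset


def build_index(gene_exons: dict[str, list[tuple[int, int]]], chrom: str = "chr1") -> AnnotationIndex:
    """AnnotationIndex from {gene_id: [(start, end), ...]} (0-based half-open)."""
    genes = {}
    for gid, coords in gene_exons.items():
        exons = [
            ExonRecord(
                exon_id=f"{gid}e{i + 1}", gene_id=gid, chrom=chrom, start=s, end=e
            )
            for i, (s, e) in enumerate(sorted(coords))
        ]
        gene = GeneModel(gene_id=gid, exons=exons)
        if len(exons) >= 2:
            gene.junctions = enumerate_junctions(gene)
        genes[gid] = gene
    return AnnotationIndex(
        genes=genes,
        scoring_gene_ids=sorted(g for g, c in gene_exons.items() if len(c) >= 2),
        excluded=[(g, "single_exon") for g, c in gene_exons.items() if len(c) < 2],
    )


def write_gtf(path: Path, gene_exons: dict[str, list[tuple[int, int]]], chrom: str = "chr1") -> Path:
    """Write {gene_id: [(start, end), ...]} (0-based half-open) as GTF."""
    with open(path, "w") as fh:
        for gid, coords in gene_exons.items():
            for i, (s, e) in enumerate(sorted(coords), 1):
                fh.write(
                    f"{chrom}\ttest\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f'gene_id "{gid}"; exon_id "{gid}e{i}";\n'
                )
    return path


def write_sam(
    path: Path,
    references: list[tuple[str, int]],
    reads: list[tuple[str, str, int, str]],
    unmapped: int = 0,
) -> Path:
    """Write a SAM file: references [(name, length)], reads [(qname, ref, pos0, cigar)]."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in references],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        refmap = {name: i for i, (name, _) in enumerate(references)}
        for qname, ref, pos, cigar in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.reference_id = refmap[ref]
            a.reference_start = pos
            a.cigarstring = cigar
            a.mapping_quality = 30
            a.flag = 0
            out.write(a)
        for i in range(unmapped):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"unmapped{i}"
            a.flag = 4
            out.write(a)
    return path


@pytest.fixture(scope="session")
def sim_dataset():
    """Default-condition synthetic dataset (200 genes, 20 skipped)."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_fixture_dir(sim_dataset, tmp_path_factory):
    """The same dataset written out as a fixture directory."""
    from arhseq.simulate import write_fixture

    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(sim_dataset, out)
    return paths
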