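"""RPKM normalization, gene expression and combi-counts.

RPKM = count / (feature length / 1000) / (library size / 1e6), where the
library size is the per-sample total of assigned exon plus junction counts.
Junction features use their window length as the length denominator so that
junction expression is on the same scale as exon expression.

The *combi-count* of an exon is its RPKM plus the RPKM of every junction
incident to it (as left or right partner). A cassette skipping event changes
the skipped exon's own expression and all of its incident junctions at once,
so combi-counts amplify the splicing signal relative to expression noise and
stay informative even when some junctions have no matching reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationIndex
from .counting import FeatureCounts

__all__ = [
    "QuantificationError",
    "ExpressionTable",
    "CombiTable",
    "rpkm",
    "combi_counts",
    "gene_rpkm",
    "average_replicates",
]


class QuantificationError(ValueError):
    """Inconsistent quantification input."""


@dataclass
class ExpressionTable:
    """Per-sample RPKM values keyed by feature id."""

    sample_id: str
    values: dict[str, float]
    library_size: int
    feature_type: dict[str, str] = field(default_factory=dict)
    gene_ids: dict[str, str] = field(default_factory=dict)

    def by_type(self, feature_type: str) -> dict[str, float]:
        return {
            fid: v
            for fid, v in self.values.items()
            if self.feature_type.get(fid) == feature_type
        }


@dataclass
class CombiTable:
    """Per-sample combi-counts keyed by exon id, grouped by scoring gene."""

    sample_id: str
    values: dict[str, float]
    genes: dict[str, list[str]]  # gene_id -> exon ids in annotation order
    provenance: list[str] = field(default_factory=list)

    def gene_vector(self, gene_id: str) -> np.ndarray:
        return np.array([self.values[e] for e in self.genes[gene_id]], dtype=float)


def rpkm(counts: FeatureCounts) -> ExpressionTable:
    """Reads per kilobase of feature length per million assigned reads."""
    library_size = counts.total
    if library_size <= 0:
        raise QuantificationError(
            f"sample {counts.sample_id}: library size is zero; cannot normalize"
        )
    scale = 1e6 / library_size
    values = {
        fid: c / (counts.lengths[fid] / 1000.0) * scale
        for fid, c in counts.counts.items()
    }
    return ExpressionTable(
        sample_id=counts.sample_id,
        values=values,
        library_size=library_size,
        feature_type=dict(counts.feature_type),
        gene_ids=dict(counts.gene_ids),
    )


def combi_counts(expr: ExpressionTable, index: AnnotationIndex) -> CombiTable:
    """Exon RPKM plus incident-junction RPKMs, per exon of each scoring gene.

    Junctions absent from the expression table contribute zero (unmeasured
    junctions are expected; most candidate junctions have no reads).
    Exons absent from the table are an error — the count scaffold must
    cover the annotation.
    """
    values: dict[str, float] = {}
    genes: dict[str, list[str]] = {}
    missing: list[str] = []
    for gene in index.scoring_genes():
        incident: dict[str, float] = {e.exon_id: 0.0 for e in gene.exons}
        for j in gene.junctions:
            jv = expr.values.get(j.junction_id, 0.0)
            incident[j.left_exon_id] += jv
            incident[j.right_exon_id] += jv
        exon_ids = [e.exon_id for e in gene.exons]
        for eid in exon_ids:
            if eid not in expr.values:
                missing.append(eid)
                continue
            values[eid] = expr.values[eid] + incident[eid]
        genes[gene.gene_id] = exon_ids
    if missing:
        raise QuantificationError(
            f"exons missing from expression table: {sorted(missing)[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    return CombiTable(
        sample_id=expr.sample_id,
        values=values,
        genes=genes,
        provenance=[expr.sample_id],
    )


def gene_rpkm(counts: FeatureCounts, index: AnnotationIndex) -> dict[str, float]:
    """Gene-level RPKM from exon counts only.

    value = (sum of exon counts) / (sum of exon lengths / 1000)
    / (library size / 1e6); equals the exon-length-weighted mean of the
    gene's exon RPKMs.
    """
    library_size = counts.total
    if library_size <= 0:
        raise QuantificationError(
            f"sample {counts.sample_id}: library size is zero; cannot normalize"
        )
    out: dict[str, float] = {}
    for gene_id, gene in index.genes.items():
        total = sum(counts.counts.get(e.exon_id, 0) for e in gene.exons)
        length = sum(e.length for e in gene.exons)
        if length <= 0:
            raise QuantificationError(f"gene {gene_id}: zero total exon length")
        out[gene_id] = total / (length / 1000.0) / (library_size / 1e6)
    return out


def average_replicates(tables: list[CombiTable]) -> CombiTable:
    """Arithmetic per-exon mean of replicate combi-count tables.

    Replicates are averaged on the combi-count (RPKM) scale before the
    splicing deviation is computed.
    """
    if not tables:
        raise QuantificationError("no replicate tables given")
    first = tables[0]
    if len(tables) == 1:
        return first
    exon_sets = {frozenset(t.values) for t in tables}
    if len(exon_sets) != 1:
        raise QuantificationError("replicate tables cover different exon sets")
    values = {
        eid: float(np.mean([t.values[eid] for t in tables])) for eid in first.values
    }
    provenance = [s for t in tables for s in (t.provenance or [t.sample_id])]
    return CombiTable(
        sample_id="mean(" + ",".join(t.sample_id for t in tables) + ")",
        values=values,
        genes={g: list(e) for g, e in first.genes.items()},
        provenance=provenance,
    )
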