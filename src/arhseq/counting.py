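"""Read counting for exon and junction features from two-pass alignments.

The genome pass contributes exon counts: an alignment increments an exon iff
its aligned span lies completely within the exon interval (reads overhanging
an exon edge and spliced alignments are never exon-counted; short exons below
the read length therefore receive no counts — a deliberate property of the
containment rule). The junction pass, aligned against junction-window
references named ``JCT|gene|left|right``, contributes junction counts under
the same full-containment rule within the window.

Multi-mapped reads: the default policy counts every reported alignment once
("count_all", matching a bowtie run that reports up to k alignments per
read); "primary_only" skips secondary/supplementary records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import pysam

from .annotation import (
    AnnotationError,
    AnnotationIndex,
    make_junction_id,
    parse_junction_id,
)

__all__ = [
    "CountingError",
    "FeatureCounts",
    "count_exon_reads",
    "count_junction_reads",
    "merge_counts",
    "read_count_table",
    "write_count_table",
]


class CountingError(ValueError):
    """Invalid counting input (alignments or count tables)."""


@dataclass
class FeatureCounts:
    """Per-sample raw read counts over exon and junction features.

    ``lengths`` holds the exon length or junction window length used later
    as the RPKM denominator; ``gene_ids`` maps every feature to its gene.
    ``report`` carries counting bookkeeping (totals, unassigned reads,
    dropped junctions, ...).
    """

    sample_id: str
    counts: dict[str, int]
    feature_type: dict[str, str]
    lengths: dict[str, int]
    gene_ids: dict[str, str]
    report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, c in self.counts.items():
            if c < 0:
                raise CountingError(f"negative count for feature {fid}")
            if self.lengths.get(fid, 0) <= 0:
                raise CountingError(f"missing or non-positive length for {fid}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def by_type(self, feature_type: str) -> dict[str, int]:
        return {
            fid: c
            for fid, c in self.counts.items()
            if self.feature_type[fid] == feature_type
        }


def _open_alignments(alignments) -> pysam.AlignmentFile:
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments
    return pysam.AlignmentFile(str(alignments))


def _exon_scaffold(index: AnnotationIndex) -> FeatureCounts:
    counts: dict[str, int] = {}
    ftype: dict[str, str] = {}
    lengths: dict[str, int] = {}
    genes: dict[str, str] = {}
    for gene in index.genes.values():
        for e in gene.exons:
            counts[e.exon_id] = 0
            ftype[e.exon_id] = "exon"
            lengths[e.exon_id] = e.length
            genes[e.exon_id] = gene.gene_id
    return FeatureCounts("", counts, ftype, lengths, genes)


def count_exon_reads(
    alignments,
    index: AnnotationIndex,
    multimap_policy: str = "count_all",
    sample_id: str | None = None,
) -> FeatureCounts:
    """Count genome-pass alignments fully contained in annotated exons.

    A read contained in k overlapping exons increments each of the k.
    Spliced (N-cigar) alignments are tallied separately and never counted.
    """
    if multimap_policy not in ("count_all", "primary_only"):
        raise CountingError(f"unknown multimap policy {multimap_policy!r}")
    sam = _open_alignments(alignments)
    fc = _exon_scaffold(index)
    fc.sample_id = sample_id or (Path(str(alignments)).stem if not isinstance(alignments, pysam.AlignmentFile) else "sample")

    sam_chroms = set(sam.references or ())
    if sam_chroms and not (sam_chroms & index.chroms):
        raise CountingError(
            "no chromosome names shared between alignments and annotation; "
            f"alignment names: {sorted(sam_chroms)[:5]}..., "
            f"annotation names: {sorted(index.chroms)[:5]}..."
        )

    processed = unassigned = unmapped = spliced = skipped_secondary = 0
    for read in sam.fetch(until_eof=True):
        if read.is_unmapped:
            unmapped += 1
            continue
        if multimap_policy == "primary_only" and (
            read.is_secondary or read.is_supplementary
        ):
            skipped_secondary += 1
            continue
        processed += 1
        if read.cigartuples and any(op == 3 for op, _ in read.cigartuples):  # N
            spliced += 1
            continue
        hits = index.containing_exons(
            read.reference_name, read.reference_start, read.reference_end
        )
        if not hits:
            unassigned += 1
            continue
        for exon in hits:
            fc.counts[exon.exon_id] += 1
    fc.report = {
        "processed": processed,
        "unmapped": unmapped,
        "spliced_skipped": spliced,
        "secondary_skipped": skipped_secondary,
        "unassigned": unassigned,
        "assigned_reads": processed - spliced - unassigned,
    }
    return fc


def count_junction_reads(
    alignments,
    index: AnnotationIndex,
    require_full_containment: bool = True,
    id_mapping: Mapping[str, tuple[str, str, str]] | None = None,
    sample_id: str | None = None,
) -> FeatureCounts:
    """Count junction-pass alignments over junction-window references.

    Reference names must follow ``JCT|gene|left|right`` or be resolvable via
    ``id_mapping`` (reference name -> (gene, left exon, right exon), for
    third-party junction aligners). Junctions whose exon identifiers do not
    both belong to the named gene are dropped and tallied.
    """
    sam = _open_alignments(alignments)
    window_lengths = dict(zip(sam.references or (), sam.lengths or ()))

    counts: dict[str, int] = {}
    ftype: dict[str, str] = {}
    lengths: dict[str, int] = {}
    genes: dict[str, str] = {}
    resolved: dict[str, tuple[str, str, str] | None] = {}

    def resolve(ref: str) -> tuple[str, str, str] | None:
        if ref in resolved:
            return resolved[ref]
        if id_mapping is not None and ref in id_mapping:
            trip = tuple(id_mapping[ref])
        else:
            try:
                trip = parse_junction_id(ref)
            except AnnotationError:
                if id_mapping is not None:
                    resolved[ref] = None
                    return None
                raise CountingError(
                    f"cannot parse junction reference {ref!r} and no id mapping given"
                )
        gene_id, left, right = trip
        gene = index.genes.get(gene_id)
        if gene is None or any(
            eid not in {e.exon_id for e in gene.exons} for eid in (left, right)
        ):
            resolved[ref] = None  # same-gene filter: drop
            return None
        resolved[ref] = trip
        return trip

    processed = unmapped = dropped = overhang = 0
    # register every parseable reference so zero-count junctions keep lengths
    for ref, wlen in window_lengths.items():
        trip = resolve(ref)
        if trip is None:
            continue
        gene_id, left, right = trip
        jid = make_junction_id(gene_id, left, right)
        counts[jid] = 0
        ftype[jid] = "junction"
        lengths[jid] = int(wlen)
        genes[jid] = gene_id

    for read in sam.fetch(until_eof=True):
        if read.is_unmapped:
            unmapped += 1
            continue
        processed += 1
        trip = resolve(read.reference_name)
        if trip is None:
            dropped += 1
            continue
        wlen = window_lengths[read.reference_name]
        if require_full_containment and not (
            read.reference_start >= 0 and read.reference_end <= wlen
        ):
            overhang += 1
            continue
        counts[make_junction_id(*trip)] += 1

    fc = FeatureCounts(
        sample_id=sample_id or "sample",
        counts=counts,
        feature_type=ftype,
        lengths=lengths,
        gene_ids=genes,
        report={
            "processed": processed,
            "unmapped": unmapped,
            "dropped_junction_reads": dropped,
            "overhanging_skipped": overhang,
        },
    )
    return fc


def merge_counts(*parts: FeatureCounts, sample_id: str | None = None) -> FeatureCounts:
    """Merge exon- and junction-pass counts of one sample into one table."""
    if not parts:
        raise CountingError("nothing to merge")
    counts: dict[str, int] = {}
    ftype: dict[str, str] = {}
    lengths: dict[str, int] = {}
    genes: dict[str, str] = {}
    report: dict[str, int] = {}
    for part in parts:
        overlap = counts.keys() & part.counts.keys()
        if overlap:
            raise CountingError(
                f"feature id spaces overlap across parts: {sorted(overlap)[:3]}"
            )
        counts.update(part.counts)
        ftype.update(part.feature_type)
        lengths.update(part.lengths)
        genes.update(part.gene_ids)
        for k, v in part.report.items():
            report[k] = report.get(k, 0) + v
    return FeatureCounts(
        sample_id=sample_id or parts[0].sample_id,
        counts=counts,
        feature_type=ftype,
        lengths=lengths,
        gene_ids=genes,
        report=report,
    )


_TABLE_COLUMNS = ["feature_id", "feature_type", "gene_id", "length", "count"]


def write_count_table(fc: FeatureCounts, path: str | Path) -> None:
    """Write a per-sample count table as TSV, sorted by feature id."""
    df = pd.DataFrame(
        {
            "feature_id": list(fc.counts),
            "feature_type": [fc.feature_type[f] for f in fc.counts],
            "gene_id": [fc.gene_ids[f] for f in fc.counts],
            "length": [fc.lengths[f] for f in fc.counts],
            "count": [fc.counts[f] for f in fc.counts],
        }
    ).sort_values("feature_id", kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path, sample_id: str | None = None) -> FeatureCounts:
    """Read a count table written by :func:`write_count_table`.

    Validates column names, non-negative counts and positive lengths,
    reporting the offending 1-based data row on failure.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CountingError(f"{path}: missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.count < 0:
            raise CountingError(f"{path}: row {i}: negative count ({row.count})")
        if row.length <= 0:
            raise CountingError(f"{path}: row {i}: non-positive length ({row.length})")
    return FeatureCounts(
        sample_id=sample_id or Path(str(path)).stem,
        counts=dict(zip(df.feature_id, df["count"].astype(int))),
        feature_type=dict(zip(df.feature_id, df.feature_type)),
        lengths=dict(zip(df.feature_id, df.length.astype(int))),
        gene_ids=dict(zip(df.feature_id, df.gene_id)),
    )
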