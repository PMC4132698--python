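"""Gene-structure parsing and exon-junction enumeration.

A gene is represented as its set of distinct exons (collapsed across
transcripts on identical coordinates). Candidate junctions are all ordered
exon pairs (a, b) of a gene where exon b starts strictly after exon a ends
on the genome; overlapping pairs are silently skipped. Single-exon genes
cannot splice differentially and are excluded from the scoring gene set.

Junction *windows* are short reference sequences used to re-align reads that
failed genomic alignment: the last ``floor(3L/4)`` bases of the upstream exon
concatenated with the first ``floor(3L/4)`` bases of the downstream exon for
read length ``L``, so any read fully inside the window overlaps each exon by
at least a quarter of its length. Windows are built on the genomic forward
strand regardless of gene strand; counting downstream is unstranded.

Coordinates are stored 0-based half-open internally; GTF input (1-based,
inclusive) is converted at the boundary, so ``length == end - start`` holds
exactly.
"""

from __future__ import annotations

import hashlib
import itertools
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

__all__ = [
    "AnnotationError",
    "GtfParseError",
    "ExonRecord",
    "JunctionRecord",
    "GeneModel",
    "AnnotationIndex",
    "parse_gtf",
    "enumerate_junctions",
    "junction_window",
    "external_window_length",
    "synthetic_window_length",
    "assign_window_lengths",
    "make_junction_id",
    "parse_junction_id",
    "write_junction_fasta",
    "write_annotation_summary",
]

JUNCTION_PREFIX = "JCT"
_SEP = "|"


class AnnotationError(ValueError):
    """Inconsistent or unusable annotation input."""


class GtfParseError(AnnotationError):
    """A GTF line could not be parsed; carries the 1-based line number."""


@dataclass(frozen=True)
class ExonRecord:
    """One collapsed exon of a gene (0-based half-open coordinates)."""

    exon_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"exon {self.exon_id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class JunctionRecord:
    """A candidate junction between two non-overlapping exons of one gene."""

    junction_id: str
    gene_id: str
    left_exon_id: str
    right_exon_id: str
    window_length: int | None = None


@dataclass
class GeneModel:
    """A gene: exons in ascending genomic order plus enumerated junctions."""

    gene_id: str
    exons: list[ExonRecord]
    junctions: list[JunctionRecord] = field(default_factory=list)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, exon_id: str) -> ExonRecord:
        for e in self.exons:
            if e.exon_id == exon_id:
                return e
        raise KeyError(exon_id)


@dataclass
class AnnotationIndex:
    """Lookup structure over all gene models of one annotation.

    ``genes`` holds every parsed gene (possibly including single-exon genes
    kept for read counting); ``scoring_gene_ids`` is the subset with at least
    two exons that enters splicing analysis. ``excluded`` records genes
    dropped from scoring with a reason.
    """

    genes: dict[str, GeneModel]
    scoring_gene_ids: list[str]
    excluded: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)
    _exons: dict[str, ExonRecord] = field(default_factory=dict, repr=False)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._exons:
            for gene in self.genes.values():
                for e in gene.exons:
                    self._exons[e.exon_id] = e
        if not self._trees:
            for e in self._exons.values():
                self._trees.setdefault(e.chrom, IntervalTree()).addi(
                    e.start, e.end, e.exon_id
                )
        for gene in self.genes.values():
            for j in gene.junctions:
                if j.left_exon_id not in self._exons or j.right_exon_id not in self._exons:
                    raise AnnotationError(
                        f"junction {j.junction_id} references unknown exons"
                    )

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    def exon(self, exon_id: str) -> ExonRecord:
        return self._exons[exon_id]

    @property
    def exons(self) -> Mapping[str, ExonRecord]:
        return self._exons

    def scoring_genes(self) -> Iterator[GeneModel]:
        for gid in self.scoring_gene_ids:
            yield self.genes[gid]

    def overlapping_exons(self, chrom: str, start: int, end: int) -> list[ExonRecord]:
        """Exons overlapping [start, end) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self._exons[iv.data] for iv in tree.overlap(start, end)]

    def containing_exons(self, chrom: str, start: int, end: int) -> list[ExonRecord]:
        """Exons that fully contain [start, end)."""
        return [
            e
            for e in self.overlapping_exons(chrom, start, end)
            if e.start <= start and end <= e.end
        ]


def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        n = 0
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if fields[2] == "exon" and end < start:
                raise GtfParseError(
                    f"{path}: line {lineno}: end < start ({end} < {start})"
                )
            n += 1
        if n == 0:
            raise GtfParseError(f"{path}: no feature lines found")


def _file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def parse_gtf(
    path: str | Path,
    keep_single_exon_for_counting: bool = True,
    enumerate_gene_junctions: bool = True,
) -> AnnotationIndex:
    """Parse exon features from an Ensembl-dialect GTF into an index.

    Exons sharing coordinates across transcripts are collapsed to one record
    per unique (gene, start, end). Genes with a single distinct exon are
    excluded from the scoring set; with ``keep_single_exon_for_counting``
    they remain available for read counting. Junctions are enumerated per
    scoring gene unless disabled.
    """
    _validate_gtf_lines(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises a mix of types
        raise GtfParseError(f"{path}: GTF parsing failed: {exc}") from exc

    per_gene: dict[str, dict[tuple[str, int, int], tuple[str | None, str]]] = {}
    for feat in db.features_of_type("exon"):
        try:
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise GtfParseError(
                f"{path}: exon feature without gene_id attribute "
                f"({feat.seqid}:{feat.start}-{feat.end})"
            ) from exc
        exon_id = feat.attributes.get("exon_id", [None])[0]
        key = (feat.seqid, feat.start - 1, feat.end)  # to 0-based half-open
        strand = feat.strand if feat.strand in "+-" else "unknown"
        # first annotation of a coordinate-identical exon wins
        per_gene.setdefault(gene_id, {}).setdefault(key, (exon_id, strand))

    if not per_gene:
        raise GtfParseError(f"{path}: no exon features with gene_id parsed")

    genes: dict[str, GeneModel] = {}
    scoring: list[str] = []
    excluded: list[tuple[str, str]] = []
    for gene_id in sorted(per_gene):
        items = sorted(per_gene[gene_id].items())  # by (chrom, start, end)
        exons = []
        for rank, ((chrom, start, end), (exon_id, strand)) in enumerate(items, 1):
            exons.append(
                ExonRecord(
                    exon_id=exon_id if exon_id is not None else f"{gene_id}:{rank}",
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
        gene = GeneModel(gene_id=gene_id, exons=exons)
        if gene.n_exons < 2:
            excluded.append((gene_id, "single_exon"))
            if not keep_single_exon_for_counting:
                continue
        else:
            scoring.append(gene_id)
            if enumerate_gene_junctions:
                gene.junctions = enumerate_junctions(gene)
        genes[gene_id] = gene

    return AnnotationIndex(
        genes=genes,
        scoring_gene_ids=scoring,
        excluded=excluded,
        provenance={
            "annotation": os.path.basename(str(path)),
            "sha256": _file_sha256(path),
        },
    )


def make_junction_id(gene_id: str, left_exon_id: str, right_exon_id: str) -> str:
    for part in (gene_id, left_exon_id, right_exon_id):
        if _SEP in part:
            raise AnnotationError(f"identifier {part!r} must not contain {_SEP!r}")
    return _SEP.join((JUNCTION_PREFIX, gene_id, left_exon_id, right_exon_id))


def parse_junction_id(junction_id: str) -> tuple[str, str, str]:
    """Decompose ``JCT|gene|left|right`` back into its three identifiers."""
    parts = junction_id.split(_SEP)
    if len(parts) != 4 or parts[0] != JUNCTION_PREFIX:
        raise AnnotationError(f"not a junction identifier: {junction_id!r}")
    return parts[1], parts[2], parts[3]


def enumerate_junctions(gene: GeneModel) -> list[JunctionRecord]:
    """All exon pairs (a, b) of a gene with start(b) > end(a).

    Pairs of mutually overlapping exons are skipped, so a gene with n
    mutually non-overlapping exons yields n(n-1)/2 junctions. Order is
    deterministic: by left then right exon genomic start.
    """
    if gene.n_exons < 2:
        raise AnnotationError(f"gene {gene.gene_id}: need >=2 exons for junctions")
    exons = sorted(gene.exons, key=lambda e: (e.start, e.end, e.exon_id))
    out: list[JunctionRecord] = []
    for a, b in itertools.combinations(exons, 2):
        left, right = (a, b) if a.start <= b.start else (b, a)
        if right.start > left.end:
            out.append(
                JunctionRecord(
                    junction_id=make_junction_id(
                        gene.gene_id, left.exon_id, right.exon_id
                    ),
                    gene_id=gene.gene_id,
                    left_exon_id=left.exon_id,
                    right_exon_id=right.exon_id,
                )
            )
    return out


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    try:
        seq = genome[chrom]
    except KeyError:
        raise AnnotationError(f"chromosome {chrom!r} not present in genome source")
    return str(seq[start:end]).upper()


def junction_window(
    junction: JunctionRecord,
    index: AnnotationIndex,
    genome,
    read_length: int,
) -> tuple[str, int]:
    """Build the junction-window sequence for one junction.

    Flank length is ``floor(3 * read_length / 4)``, clipped to each exon's
    length; the window is the terminal flank of the left exon concatenated
    with the initial flank of the right exon on the genomic forward strand.
    Returns ``(sequence, window_length)``.
    """
    if read_length < 4:
        raise AnnotationError(f"read length {read_length} too short (need >= 4)")
    left = index.exon(junction.left_exon_id)
    right = index.exon(junction.right_exon_id)
    f = (3 * read_length) // 4
    lf = min(f, left.length)
    rf = min(f, right.length)
    seq = _fetch(genome, left.chrom, left.end - lf, left.end) + _fetch(
        genome, right.chrom, right.start, right.start + rf
    )
    return seq, lf + rf


def synthetic_window_length(
    junction: JunctionRecord, index: AnnotationIndex, read_length: int
) -> int:
    """Window length of the in-house junction window (flanks clipped)."""
    f = (3 * read_length) // 4
    return min(f, index.exon(junction.left_exon_id).length) + min(
        f, index.exon(junction.right_exon_id).length
    )


_EXTERNAL_WINDOW = {
    "tophat": lambda L: 2 * L - 10,
    "mapsplice": lambda L: 2 * L - 2,
    "splicemap": lambda L: 2 * L - 20,
    "synthetic": lambda L: 2 * ((3 * L) // 4),
}


def external_window_length(aligner: str, read_length: int) -> int:
    """Junction-window length (RPKM denominator) per junction aligner.

    tophat: 2L-10; MapSplice: 2L-2; SpliceMap: 2L-20; the in-house
    "synthetic" windows: 2*floor(3L/4) (unclipped).
    """
    if read_length <= 10:
        raise AnnotationError(f"read length must exceed 10, got {read_length}")
    try:
        return _EXTERNAL_WINDOW[aligner](read_length)
    except KeyError:
        raise AnnotationError(
            f"unknown aligner {aligner!r}; expected one of {sorted(_EXTERNAL_WINDOW)}"
        )


def assign_window_lengths(
    index: AnnotationIndex, read_length: int, aligner: str = "synthetic"
) -> None:
    """Set ``window_length`` on every junction of the scoring genes.

    For the in-house windows the per-junction clipped length is used; for
    external junction aligners the aligner's fixed formula applies to all
    junctions alike.
    """
    for gene in index.scoring_genes():
        for j in gene.junctions:
            if aligner == "synthetic":
                j.window_length = synthetic_window_length(j, index, read_length)
            else:
                j.window_length = external_window_length(aligner, read_length)


def write_junction_fasta(
    windows: Iterable[tuple[JunctionRecord, str]], path: str | Path
) -> int:
    """Write junction windows as FASTA (header = junction id); returns count."""
    records = [
        SeqRecord(Seq(seq), id=j.junction_id, description="") for j, seq in windows
    ]
    if not records:
        raise AnnotationError("no junction windows to write")
    return SeqIO.write(records, str(path), "fasta")


def write_annotation_summary(index: AnnotationIndex, path: str | Path) -> None:
    """Per-gene TSV: gene_id, n_exons, n_junctions, excluded_reason."""
    reasons = dict(index.excluded)
    with open(path, "w") as fh:
        fh.write("gene_id\tn_exons\tn_junctions\texcluded_reason\n")
        for gid in sorted(index.genes):
            gene = index.genes[gid]
            fh.write(
                f"{gid}\t{gene.n_exons}\t{len(gene.junctions)}\t"
                f"{reasons.get(gid, '')}\n"
            )
        for gid, reason in sorted(reasons.items()):
            if gid not in index.genes:
                fh.write(f"{gid}\t1\t0\t{reason}\n")
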