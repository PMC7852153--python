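"""Transcript/gene data model, GTF I/O, interval logic and genomic classification.

Coordinates are 0-based half-open internally; GTF I/O converts at the boundary
(GTF is 1-based closed).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Biotype labels a transcript may carry.
KNOWN_MRNA = "known_mRNA"
KNOWN_LNCRNA = "known_lncRNA"
CANDIDATE = "candidate"
_BIOTYPES = (KNOWN_MRNA, KNOWN_LNCRNA, CANDIDATE)


class GTFParseError(ValueError):
    """Malformed GTF input; carries the offending line number."""


class AnnotationError(ValueError):
    """Inconsistent transcript model (strand/chrom mismatch, bad intervals...)."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon intervals on a chromosome strand plus a biotype label.

    Exons are half-open 0-based ``(start, end)`` tuples, sorted, non-overlapping.
    """

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = CANDIDATE

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in _BIOTYPES:
            raise AnnotationError(f"{self.id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            raise AnnotationError(f"{self.id}: transcript has no exons")
        exons = tuple(tuple(map(int, e)) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if start >= end:
                raise AnnotationError(f"{self.id}: empty/inverted exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise AnnotationError(f"{self.id}: exons overlap or are unsorted")
            prev_end = end

    def length(self) -> int:
        """Total exonic length in nt."""
        return sum(end - start for start, end in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint from first exon start to last exon end."""
        return self.start, self.end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons (the intron chain)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)


class RelationKind(str, Enum):
    OVERLAP = "overlap"
    INTRON = "intron"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"


@dataclass(frozen=True)
class GenomicRelation:
    """How a lncRNA sits relative to a gene: exonic overlap, inside the gene
    body without exonic overlap ("intron"), or at a distance up/downstream."""

    kind: RelationKind
    distance_bp: int = 0

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be non-negative")
        if self.kind in (RelationKind.OVERLAP, RelationKind.INTRON) and self.distance_bp != 0:
            raise ValueError(f"{self.kind.value} relation must have distance 0")

    def __str__(self) -> str:
        if self.kind is RelationKind.OVERLAP:
            return "Overlap"
        if self.kind is RelationKind.INTRON:
            return "Intron"
        return f"{self.kind.value.capitalize()}:{self.distance_bp:,}"


class GenomeAnnotation:
    """Collection of transcripts with a gene index and per-(chrom, strand)
    interval indexes supporting fast span-overlap queries."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._transcripts: dict[str, TranscriptModel] = {}
        self._gene_index: dict[str, list[str]] = defaultdict(list)
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.id in self._transcripts:
            raise AnnotationError(f"duplicate transcript id {t.id!r}")
        self._transcripts[t.id] = t
        self._gene_index[t.gene_id].append(t.id)
        self._trees[(t.chrom, t.strand)].addi(t.start, t.end, t.id)

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, tid: str) -> bool:
        return tid in self._transcripts

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self._transcripts[tid]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self._transcripts)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._gene_index)

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self._transcripts[tid] for tid in self._gene_index.get(gene_id, [])]

    def chromosomes(self) -> set[str]:
        return {t.chrom for t in self}

    def subset(self, ids: Iterable[str]) -> "GenomeAnnotation":
        return GenomeAnnotation(self._transcripts[i] for i in ids)

    def by_biotype(self, *biotypes: str) -> "GenomeAnnotation":
        return GenomeAnnotation(t for t in self if t.biotype in biotypes)

    def overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[TranscriptModel]:
        """Transcripts whose genomic span intersects [start, end)."""
        strands = ("+", "-") if strand is None else (strand,)
        hits: list[TranscriptModel] = []
        for s in strands:
            tree = self._trees.get((chrom, s))
            if tree is None:
                continue
            hits.extend(self._transcripts[iv.data] for iv in tree.overlap(start, end))
        hits.sort(key=lambda t: t.id)
        return hits


# --- GTF I/O -----------------------------------------------------------------

_BIOTYPE_ALIASES = {
    "known_mrna": KNOWN_MRNA,
    "protein_coding": KNOWN_MRNA,
    "mrna": KNOWN_MRNA,
    "known_lncrna": KNOWN_LNCRNA,
    "lncrna": KNOWN_LNCRNA,
    "lincrna": KNOWN_LNCRNA,
    "candidate": CANDIDATE,
}


def read_gtf(path, default_biotype: str = CANDIDATE) -> GenomeAnnotation:
    """Read exon features from a GTF 2.2 file into a :class:`GenomeAnnotation`.

    Coordinates convert from 1-based closed to 0-based half-open. The biotype is
    taken from a ``transcript_biotype``/``biotype``/``gene_biotype`` attribute
    when present (``protein_coding`` → known_mRNA, ``lncRNA`` → known_lncRNA),
    else ``default_biotype``.

    Raises :class:`GTFParseError` with a line number on malformed lines and
    :class:`AnnotationError` when exons of one transcript disagree on
    chromosome or strand.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GTFParseError(
                    f"{path}: malformed GTF at line {lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GTFParseError(f"{path}: malformed GTF at line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise GTFParseError(
                    f"{path}: line {lineno}: exon missing {exc} attribute"
                ) from exc
            biotype = default_biotype
            for key in ("transcript_biotype", "biotype", "gene_biotype"):
                if key in feat.attributes:
                    raw = feat.attributes[key][0].lower()
                    biotype = _BIOTYPE_ALIASES.get(raw, default_biotype)
                    break
            rec = per_tx.get(tid)
            if rec is None:
                per_tx[tid] = {
                    "gene_id": gid,
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "biotype": biotype,
                    "exons": [],
                }
                order.append(tid)
                rec = per_tx[tid]
            if rec["chrom"] != feat.seqid or rec["strand"] != feat.strand:
                raise AnnotationError(
                    f"{path}: line {lineno}: transcript {tid} mixes chromosomes or strands"
                )
            rec["exons"].append((feat.start - 1, feat.end))
    ann = GenomeAnnotation()
    for tid in order:
        rec = per_tx[tid]
        exons = tuple(sorted(rec["exons"]))
        ann.add(
            TranscriptModel(
                id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=exons,
                biotype=rec["biotype"],
            )
        )
    return ann


def write_gtf(ann: GenomeAnnotation, path) -> None:
    """Write exon features (1-based closed coordinates, GTF 2.2 attributes)."""
    with open(path, "w") as fh:
        for t in ann:
            for start, end in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.id}"; '
                    f'transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\tlncsuite\texon\t{start + 1}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def write_bed6(ann: GenomeAnnotation, path) -> None:
    """Export transcript spans as BED6 (0-based half-open, score 0)."""
    with open(path, "w") as fh:
        for t in ann:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.id}\t0\t{t.strand}\n")


# --- interval logic ----------------------------------------------------------


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True if any exon of ``a`` shares at least one base with an exon of ``b``."""
    if a.chrom != b.chrom or not _intervals_overlap(a.span, b.span):
        return False
    return any(_intervals_overlap(ea, eb) for ea in a.exons for eb in b.exons)


def within_intron(t: TranscriptModel, host: TranscriptModel) -> bool:
    """True if ``t``'s span lies entirely inside one intron of ``host``."""
    if t.chrom != host.chrom:
        return False
    return any(i0 <= t.start and t.end <= i1 for i0, i1 in host.introns)


def deduplicate_transcripts(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Collapse replicate structures: identical (chrom, strand, intron chain)
    for multi-exon transcripts, identical exon coordinates for monoexonic ones.

    The survivor is the transcript with the longest total exonic length; ties
    break lexicographically by id.
    """
    groups: dict[tuple, list[TranscriptModel]] = defaultdict(list)
    for t in ann:
        if t.n_exons == 1:
            key = (t.chrom, t.strand, "mono", t.exons)
        else:
            key = (t.chrom, t.strand, "chain", t.introns)
        groups[key].append(t)
    survivors = [
        min(members, key=lambda t: (-t.length(), t.id)) for members in groups.values()
    ]
    survivors.sort(key=lambda t: t.id)
    return GenomeAnnotation(survivors)


def classify_candidate(t: TranscriptModel, ref: GenomeAnnotation) -> str:
    """Classify a candidate against known transcripts.

    Returns one of ``sense_overlap``, ``antisense``, ``intronic``,
    ``intergenic``. Exonic same-strand overlap wins over antisense, which wins
    over intronic (either-strand gene body); anything else is intergenic.
    """
    if t.chrom not in ref.chromosomes():
        logger.info("candidate %s: chromosome %s absent from reference; intergenic", t.id, t.chrom)
        return "intergenic"
    known = [
        k
        for k in ref.overlapping(t.chrom, t.start, t.end)
        if k.biotype != CANDIDATE and k.id != t.id
    ]
    sense = [k for k in known if k.strand == t.strand and exonic_overlap(t, k)]
    if sense:
        return "sense_overlap"
    anti = [k for k in known if k.strand != t.strand and exonic_overlap(t, k)]
    if anti:
        return "antisense"
    if any(within_intron(t, k) for k in known):
        return "intronic"
    return "intergenic"


def genomic_relation(
    lnc: TranscriptModel, gene: TranscriptModel, orientation: str = "gene"
) -> GenomicRelation | None:
    """Relation of a lncRNA to a gene: exonic overlap, within the gene body
    ("intron"), or up/downstream with the gap between spans.

    ``orientation`` controls what up/downstream means: ``"gene"`` (default)
    orients by the gene's strand (upstream = toward the gene's 5'),
    ``"genomic"`` by coordinate order (upstream = lower coordinates).
    Returns ``None`` when the two lie on different chromosomes.
    """
    if lnc.chrom != gene.chrom:
        return None
    if exonic_overlap(lnc, gene):
        return GenomicRelation(RelationKind.OVERLAP)
    gs, ge = gene.span
    if gs <= lnc.start and lnc.end <= ge:
        return GenomicRelation(RelationKind.INTRON)
    if lnc.end <= gs:
        gap = gs - lnc.end
        left = True
    elif lnc.start >= ge:
        gap = lnc.start - ge
        left = False
    else:
        # spans intersect without exonic overlap and lnc is not contained:
        # partial gene-body overlap, treated as distance-0 intron-like relation
        return GenomicRelation(RelationKind.INTRON)
    if orientation == "genomic":
        upstream = left
    elif orientation == "gene":
        upstream = left if gene.strand == "+" else not left
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    kind = RelationKind.UPSTREAM if upstream else RelationKind.DOWNSTREAM
    return GenomicRelation(kind, gap)


def shift_transcript(t: TranscriptModel, offset: int) -> TranscriptModel:
    """Translate all exon coordinates by ``offset`` (testing aid)."""
    return replace(t, exons=tuple((s + offset, e + offset) for s, e in t.exons))
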