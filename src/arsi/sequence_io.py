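"""Genome/annotation IO and per-gene sequence extraction.

Reads FASTA genomes and GFF3 gene structures, and turns each gene into
the objects the rest of the package works on:

* :class:`GeneModel` — intervals on the chromosome (0-based half-open
  internally; GFF3's 1-based inclusive convention is converted at the
  boundary).
* :class:`RegionSet` — per-region nucleotide strings in transcript
  orientation (5'UTR, ORF, introns, 3'UTR and fixed-length flanks).
* :class:`GeneParts` — the strand-free decomposition (5'UTR, spliced ORF,
  3'UTR, introns with their mature-transcript insertion offsets) from
  which pre-mRNAs are assembled and on which the randomization schemes
  operate.
* :class:`AnchoredTranscript` — a pre-mRNA with anchor coordinates
  (ORF start/end, donor/acceptor splice sites).  Following the profile
  convention, a gene with m > 1 introns is duplicated m times, each
  duplicate retaining a different intron with the others spliced out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO

from .core import reverse_complement

logger = logging.getLogger(__name__)

Interval = tuple[int, int]  # 0-based, half-open

REGION_KINDS = ("five_utr", "orf", "intron", "three_utr",
                "upstream_flank", "downstream_flank")
ANCHOR_KINDS = ("orf_start", "orf_end", "five_ss", "three_ss")

_VALID = set("ACGTN")


def _clean(seq: str) -> str:
    s = seq.upper()
    if set(s) - _VALID:
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


def read_genome(fasta_path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{chrom: sequence}``.

    Sequences are uppercased; characters outside A/C/G/T become N.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path) as fh:
        head = fh.read(1)
        if head not in (">", ""):
            raise ValueError(f"malformed FASTA {path}: does not start with '>'")
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"malformed FASTA {path}: duplicate record {rec.id!r}")
        genome[rec.id] = _clean(str(rec.seq))
    if not genome:
        raise ValueError(f"malformed FASTA {path}: no records")
    return genome


@dataclass
class GeneModel:
    """One gene's structure in chromosome coordinates.

    ``exons`` are non-overlapping and listed in transcription order (for a
    minus-strand gene the 3'-most genomic exon comes first).  ``introns``
    are exactly the genomic gaps between consecutive exons.  UTR and CDS
    intervals tile the exonic sequence without overlap.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    five_utr: list[Interval] = field(default_factory=list)
    three_utr: list[Interval] = field(default_factory=list)
    cds_frame_ok: bool = True

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        genomic = sorted(self.exons)
        for (a, b), (c, d) in zip(genomic, genomic[1:]):
            if c < b:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def cds_span(self) -> Interval:
        return (min(a for a, _ in self.cds), max(b for _, b in self.cds))

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in transcription order."""
        genomic = sorted(self.exons)
        gaps = [(b, c) for (a, b), (c, d) in zip(genomic, genomic[1:])]
        return gaps if self.strand == "+" else [(a, b) for a, b in reversed(gaps)]

    @property
    def tx_span(self) -> Interval:
        return (min(a for a, _ in self.exons), max(b for _, b in self.exons))


@dataclass
class RegionSet:
    """Per-region sequences of one gene, in transcript orientation."""

    gene_id: str
    sequences: dict[str, str]
    flank_length: int = 250

    def __getitem__(self, kind: str) -> str:
        return self.sequences[kind]

    def __contains__(self, kind: str) -> bool:
        return kind in self.sequences


@dataclass
class GeneParts:
    """Strand-free decomposition of one gene's transcript.

    ``introns`` holds ``(offset, sequence)`` pairs where ``offset`` is the
    position in the *mature* transcript before which the intron sits.
    ``mature = five_utr + orf + three_utr``.
    """

    gene_id: str
    five_utr: str
    orf: str
    three_utr: str
    introns: list[tuple[int, str]] = field(default_factory=list)
    cds_frame_ok: bool = True

    @property
    def mature(self) -> str:
        return self.five_utr + self.orf + self.three_utr

    def premrna(self, retained: set[int] | None = None) -> str:
        """Assemble the pre-mRNA retaining the given introns (default all)."""
        keep = set(range(len(self.introns))) if retained is None else retained
        mat = self.mature
        out, prev = [], 0
        for k, (off, seq) in enumerate(self.introns):
            out.append(mat[prev:off])
            if k in keep:
                out.append(seq)
            prev = off
        out.append(mat[prev:])
        return "".join(out)


@dataclass
class AnchoredTranscript:
    """A pre-mRNA with anchor positions (0-based, on ``premrna``).

    ``anchors['orf_start']`` is the first nucleotide of the start codon,
    ``anchors['orf_end']`` the first nucleotide of the stop codon;
    ``five_ss``/``three_ss`` are the first/last intronic nucleotides of
    the retained intron (absent for intronless transcripts).
    """

    element_id: str
    gene_id: str
    premrna: str
    anchors: dict[str, int]
    retained_intron_index: int | None = None


def _subtract(intervals: list[Interval], minus: list[Interval]) -> list[Interval]:
    """Set-difference of sorted interval lists (both genomic order)."""
    out = []
    for a, b in intervals:
        cur = a
        for c, d in minus:
            if d <= cur or c >= b:
                continue
            if c > cur:
                out.append((cur, c))
            cur = max(cur, d)
        if cur < b:
            out.append((cur, b))
    return out


def read_annotation(gff_path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 into :class:`GeneModel` objects.

    The first mRNA per gene is used; genes with overlapping exons are
    rejected with a logged reason; a CDS whose length is not a multiple
    of three is kept but flagged (``cds_frame_ok=False``).  Where UTR
    features are absent, UTRs are inferred as the exon−CDS difference.
    """
    path = Path(gff_path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: (f.start, f.id))
        parent = mrnas[0] if mrnas else gene
        def ivals(ftype):
            return sorted((f.start - 1, f.end) for f in db.children(parent, featuretype=ftype))
        exons = ivals("exon")
        cds = ivals("CDS")
        if not cds:
            logger.warning("gene %s has no CDS; skipped", gid)
            continue
        if not exons:
            exons = list(cds)  # prokaryote-style gene: CDS is the exon
        utr5 = ivals("five_prime_UTR")
        utr3 = ivals("three_prime_UTR")
        if not utr5 and not utr3:
            span = (min(a for a, _ in cds), max(b for _, b in cds))
            before = _subtract([iv for iv in exons if iv[0] < span[0]],
                               [(span[0], span[1])])
            after = _subtract([iv for iv in exons if iv[1] > span[1]],
                              [(span[0], span[1])])
            before = [iv for iv in before if iv[1] <= span[0]]
            after = [iv for iv in after if iv[0] >= span[1]]
            utr5, utr3 = (before, after) if gene.strand == "+" else (after, before)
        cds_len = sum(b - a for a, b in cds)
        frame_ok = cds_len % 3 == 0
        if not frame_ok:
            logger.warning("gene %s: CDS length %d not divisible by 3", gid, cds_len)
        tx_order = exons if gene.strand == "+" else list(reversed(exons))
        try:
            models.append(GeneModel(
                gene_id=gid, chrom=gene.seqid, strand=gene.strand,
                exons=tx_order, cds=cds, five_utr=utr5, three_utr=utr3,
                cds_frame_ok=frame_ok,
            ))
        except ValueError as exc:
            logger.warning("gene %s rejected: %s", gid, exc)
    return models


def _fetch(genome: dict[str, str], model: GeneModel,
           intervals: list[Interval]) -> str:
    """Concatenate genomic intervals into transcript orientation."""
    chrom = genome[model.chrom]
    parts = [chrom[a:b] for a, b in sorted(intervals)]
    seq = "".join(parts)
    return seq if model.strand == "+" else reverse_complement(seq)


def extract_regions(genome: dict[str, str], model: GeneModel,
                    flank_length: int = 250) -> RegionSet:
    """Extract the per-region sequences of one gene.

    Flanks are measured from the transcript span and truncated at
    chromosome edges; zero-length regions are omitted.
    """
    chrom = genome[model.chrom]
    lo, hi = model.tx_span
    seqs: dict[str, str] = {}
    for kind, ivs in (("five_utr", model.five_utr), ("orf", model.cds),
                      ("three_utr", model.three_utr)):
        if ivs:
            s = _fetch(genome, model, ivs)
            if s:
                seqs[kind] = s
    for k, (a, b) in enumerate(model.introns):
        s = chrom[a:b]
        if model.strand == "-":
            s = reverse_complement(s)
        if s:
            seqs[f"intron[{k}]"] = s
    left = chrom[max(0, lo - flank_length):lo]
    right = chrom[hi:hi + flank_length]
    up, down = (left, right) if model.strand == "+" else (
        reverse_complement(right), reverse_complement(left))
    if up:
        seqs["upstream_flank"] = up
    if down:
        seqs["downstream_flank"] = down
    return RegionSet(model.gene_id, seqs, flank_length)


def gene_parts(genome: dict[str, str], model: GeneModel) -> GeneParts:
    """Decompose a gene into 5'UTR / ORF / 3'UTR strings plus introns.

    Intron offsets are mature-transcript coordinates: the number of exonic
    nucleotides (in transcript orientation) preceding the intron.
    """
    five = _fetch(genome, model, model.five_utr) if model.five_utr else ""
    orf = _fetch(genome, model, model.cds)
    three = _fetch(genome, model, model.three_utr) if model.three_utr else ""
    chrom = genome[model.chrom]
    introns = []
    for a, b in model.introns:
        seq = chrom[a:b]
        if model.strand == "-":
            seq = reverse_complement(seq)
        # exonic nt preceding the intron, transcript orientation
        if model.strand == "+":
            off = sum(min(b2, a) - a2 for a2, b2 in sorted(model.exons) if a2 < a)
        else:
            off = sum(b2 - max(a2, b) for a2, b2 in sorted(model.exons) if b2 > b)
        introns.append((off, seq))
    introns.sort(key=lambda t: t[0])
    return GeneParts(model.gene_id, five, orf, three, introns,
                     cds_frame_ok=model.cds_frame_ok)


def transcripts_from_parts(parts: GeneParts) -> list[AnchoredTranscript]:
    """Build anchored pre-mRNA transcript(s) from one gene's parts.

    A gene with m > 1 introns yields m duplicates, each retaining one
    intron; 0 or 1 intron yields a single transcript.
    """
    m = len(parts.introns)
    orf_start_m = len(parts.five_utr)
    orf_end_m = orf_start_m + max(len(parts.orf) - 3, 0)
    if m == 0:
        anchors = {"orf_start": orf_start_m, "orf_end": orf_end_m}
        return [AnchoredTranscript(parts.gene_id, parts.gene_id,
                                   parts.mature, anchors, None)]
    out = []
    for k in range(m):
        off, iseq = parts.introns[k]
        ilen = len(iseq)
        def lift(x: int) -> int:
            return x + ilen if x >= off else x
        anchors = {
            "orf_start": lift(orf_start_m),
            "orf_end": lift(orf_end_m),
            "five_ss": off,
            "three_ss": off + ilen - 1,
        }
        eid = parts.gene_id if m == 1 else f"{parts.gene_id}|intron{k}"
        out.append(AnchoredTranscript(eid, parts.gene_id,
                                      parts.premrna({k}), anchors, k))
    return out


def build_anchored_transcripts(model: GeneModel,
                               genome: dict[str, str]) -> list[AnchoredTranscript]:
    return transcripts_from_parts(gene_parts(genome, model))


def region_elements(parts_list: list[GeneParts], kind: str,
                    utr_fallback: dict[str, str] | None = None,
                    ) -> list[tuple[str, str, str]]:
    """Collect ``(element_id, gene_id, sequence)`` triples for one region kind.

    ``kind`` is one of five_utr/orf/three_utr (one element per gene),
    intron (one element per intron) or premrna (all introns retained).
    ``utr_fallback`` optionally maps gene_id to a stand-in sequence used
    when a UTR is unannotated (e.g. a fixed-length flank).
    """
    out = []
    for p in parts_list:
        if kind == "intron":
            for k, (_, seq) in enumerate(p.introns):
                out.append((f"{p.gene_id}|intron[{k}]", p.gene_id, seq))
        elif kind == "premrna":
            out.append((f"{p.gene_id}|premrna", p.gene_id, p.premrna()))
        elif kind in ("five_utr", "orf", "three_utr"):
            seq = getattr(p, kind)
            if not seq and utr_fallback is not None and kind != "orf":
                seq = utr_fallback.get(p.gene_id, "")
                if seq:
                    logger.info("gene %s: %s missing, using flank fallback",
                                p.gene_id, kind)
            if seq:
                out.append((f"{p.gene_id}|{kind}", p.gene_id, seq))
        else:
            raise ValueError(f"unknown region kind {kind!r}")
    return out


def write_region_fasta(path: str | Path, elements: list[tuple[str, str, str]]) -> None:
    """Write region elements as FASTA with ``gene_id|region_kind[index]`` headers."""
    with open(path, "w") as fh:
        for eid, _, seq in elements:
            fh.write(f">{eid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
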