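"""Synthetic genomes with known motif placements and expression classes.

The generator operationalizes the premise behind repetitive-substring
scoring: transcripts carry short regulatory motifs (8-25 nt) shared
across genes, concentrated near ORF boundaries and splice sites; in
highly expressed genes the copies are intact, while in lowly expressed
genes each copy has acquired random point mutations.  Everything else is
i.i.d. background at a configurable GC content, so every downstream
signal a test recovers is attributable to the planted structure.

Outputs are a FASTA genome, a GFF3 annotation, an expression table and a
ground-truth table of motif placements, plus the in-memory objects the
rest of the package consumes directly.  Identical spec + seed gives
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import GeneParts
from .core import reverse_complement

_NT = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults define the study conditions.

    Densities are motif starts per 100 nt; the enriched band spans
    ``anchor_band`` nt on each side of every anchor (ORF start/end, donor
    and acceptor sites).  Expression is log-normal by class with
    ``mu_high > mu_low`` (natural-log scale).
    """

    n_genes: int = 200
    frac_high: float = 0.5
    motif_count: int = 30
    motif_len_range: tuple[int, int] = (8, 25)
    background_gc: float = 0.40
    utr5_len_range: tuple[int, int] = (50, 150)
    utr3_len_range: tuple[int, int] = (80, 200)
    orf_codon_range: tuple[int, int] = (150, 500)
    intron_prob: float = 0.5
    two_intron_prob: float = 0.2
    intron_len_range: tuple[int, int] = (80, 400)
    anchor_band: int = 50
    anchor_density: float = 3.0
    background_density: float = 0.2
    mutation_rate_low: float = 0.15
    mu_high: float = 3.0
    mu_low: float = 1.0
    sigma: float = 0.6
    spacer_len: int = 200
    genes_per_chrom: int = 100
    seed: int = 0

    def __post_init__(self):
        for p in (self.frac_high, self.intron_prob, self.two_intron_prob,
                  self.mutation_rate_low, self.background_gc):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.mu_high > self.mu_low:
            raise ValueError("mu_high must exceed mu_low")


@dataclass
class SyntheticTruth:
    """Ground truth: per-gene class/expression and per-placement records."""

    genes: pd.DataFrame       # gene_id, expression_class, mrna
    placements: pd.DataFrame  # gene_id, motif_id, offset, length, n_mutations

    def to_tsv(self, path: str | Path) -> None:
        merged = self.placements.merge(self.genes, on="gene_id", how="right")
        cols = ["gene_id", "expression_class", "mrna",
                "motif_id", "offset", "length", "n_mutations"]
        merged[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SyntheticTruth":
        df = pd.read_csv(path, sep="\t")
        genes = (df[["gene_id", "expression_class", "mrna"]]
                 .drop_duplicates("gene_id").reset_index(drop=True))
        pl = df.dropna(subset=["motif_id"]).copy()
        for col in ("offset", "length", "n_mutations"):
            pl[col] = pl[col].astype(int)
        return cls(genes, pl[["gene_id", "motif_id", "offset",
                              "length", "n_mutations"]].reset_index(drop=True))


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    chromosomes: dict[str, str]
    parts: list[GeneParts]
    strands: dict[str, str]
    gff_text: str
    expression: pd.DataFrame  # index gene_id; columns mrna, pa
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "annotation": out / "annotation.gff3",
            "expression": out / "expression.tsv",
            "truth": out / "truth.tsv",
        }
        with open(paths["genome"], "w") as fh:
            for chrom in sorted(self.chromosomes):
                fh.write(f">{chrom}\n")
                seq = self.chromosomes[chrom]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        paths["annotation"].write_text(self.gff_text)
        self.expression.reset_index().to_csv(
            paths["expression"], sep="\t", index=False, float_format="%.6g")
        self.truth.to_tsv(paths["truth"])
        return paths


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_NT[rng.choice(4, size=n, p=p)])


def make_motif_library(spec: SyntheticSpec,
                       rng: np.random.Generator | None = None) -> list[str]:
    """Draw pairwise-distinct i.i.d. motifs at the background GC content."""
    if spec.motif_count < 1:
        raise ValueError("motif_count must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lo, hi = spec.motif_len_range
    motifs: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(motifs) < spec.motif_count:
        attempts += 1
        if attempts > 100 * spec.motif_count:
            raise RuntimeError("could not draw distinct motifs; shrink the library")
        m = _random_seq(int(rng.integers(lo, hi + 1)), spec.background_gc, rng)
        if m not in seen:
            seen.add(m)
            motifs.append(m)
    return motifs


def _random_orf(n_codons: int, gc: float, rng: np.random.Generator) -> str:
    """ATG + stop-free random codons + a stop codon."""
    body = list(_random_seq(3 * (n_codons - 2), gc, rng))
    for i in range(0, len(body), 3):
        while "".join(body[i:i + 3]) in _STOPS:
            body[i:i + 3] = list(_random_seq(3, gc, rng))
    return "ATG" + "".join(body) + _STOPS[rng.integers(0, 3)]


def _random_intron(length: int, gc: float, rng: np.random.Generator) -> tuple[str, int]:
    """Yeast-like intron: GTATGT ... TACTAAC ... AG; returns (seq, branch_pos)."""
    tail_fill = int(rng.integers(3, 40))
    head_fill = length - 6 - 7 - tail_fill - 2
    assert head_fill >= 0, "intron too short for consensus layout"
    seq = ("GTATGT" + _random_seq(head_fill, gc, rng) + "TACTAAC"
           + _random_seq(tail_fill, gc, rng) + "AG")
    return seq, 6 + head_fill


def _mature_to_premrna(x: int, introns: list[tuple[int, str]]) -> int:
    shift = sum(len(s) for off, s in introns if off <= x)
    return x + shift


def synthesize_genome(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a multi-gene genome with planted motifs and ground truth.

    Genes are laid head-to-tail with random spacers, one chromosome per
    ``genes_per_chrom`` genes, on random strands.  High-expression genes
    receive intact motif copies; low-expression genes receive copies
    point-mutated at ``mutation_rate_low``.  Placements never overlap each
    other or the protected codons/splicing signals.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = make_motif_library(spec, rng)
    n_high = int(round(spec.n_genes * spec.frac_high))
    classes = np.array(["high"] * n_high + ["low"] * (spec.n_genes - n_high))
    rng.shuffle(classes)

    parts_list: list[GeneParts] = []
    strands: dict[str, str] = {}
    placements_rows = []
    gene_rows = []
    chrom_parts: dict[str, list[str]] = {}
    gff_lines = ["##gff-version 3"]
    width = len(str(spec.n_genes))

    for gi in range(spec.n_genes):
        gid = f"g{gi + 1:0{width}d}"
        is_high = classes[gi] == "high"
        u5 = _random_seq(int(rng.integers(*_incl(spec.utr5_len_range))),
                         spec.background_gc, rng)
        orf = _random_orf(int(rng.integers(*_incl(spec.orf_codon_range))),
                          spec.background_gc, rng)
        u3 = _random_seq(int(rng.integers(*_incl(spec.utr3_len_range))),
                         spec.background_gc, rng)
        n_introns = 0
        if rng.random() < spec.intron_prob:
            n_introns = 2 if rng.random() < spec.two_intron_prob else 1
        orf_start_m, orf_len = len(u5), len(orf)
        introns: list[tuple[int, str]] = []
        branch_pos: list[int] = []
        if n_introns:
            lo = orf_start_m + 30
            hi = orf_start_m + orf_len - 30
            for _ in range(200):
                offs = np.sort(rng.integers(lo, hi, size=n_introns))
                if n_introns == 1 or np.all(np.diff(offs) >= 60):
                    break
            else:
                offs = offs[:1]
            for off in offs:
                ilen = int(rng.integers(*_incl(spec.intron_len_range)))
                iseq, bp = _random_intron(ilen, spec.background_gc, rng)
                introns.append((int(off), iseq))
                branch_pos.append(bp)

        mature = u5 + orf + u3
        pre = list(_splice_in(mature, introns))
        L = len(pre)

        # protected positions: start/stop codons and splicing signals
        protected = np.zeros(L, dtype=bool)
        p_start = _mature_to_premrna(orf_start_m, introns)
        p_stop = _mature_to_premrna(orf_start_m + orf_len - 3, introns)
        protected[p_start:p_start + 3] = True
        protected[p_stop:p_stop + 3] = True
        anchor_pos = [p_start, p_stop]
        cum = 0
        for k, (off, iseq) in enumerate(introns):
            s = off + cum  # pre-mRNA start of intron k
            cum += len(iseq)
            protected[s:s + 6] = True
            protected[s + branch_pos[k]:s + branch_pos[k] + 7] = True
            protected[s + len(iseq) - 3:s + len(iseq)] = True
            anchor_pos.extend([s, s + len(iseq) - 1])

        rate = np.full(L, spec.background_density / 100.0)
        for a in anchor_pos:
            rate[max(0, a - spec.anchor_band):a + spec.anchor_band + 1] = \
                spec.anchor_density / 100.0
        occupied = protected.copy()
        starts = np.flatnonzero(rng.random(L) < rate)
        for s in starts:
            mid = int(rng.integers(0, len(motifs)))
            mseq = motifs[mid]
            e = s + len(mseq)
            if e > L or occupied[s:e].any():
                continue
            copy = list(mseq)
            n_mut = 0
            if not is_high and spec.mutation_rate_low > 0:
                hits = np.flatnonzero(rng.random(len(copy)) < spec.mutation_rate_low)
                for h in hits:
                    cur = copy[h]
                    copy[h] = _NT[(int(np.searchsorted(_NT, cur))
                                   + int(rng.integers(1, 4))) % 4]
                n_mut = len(hits)
            pre[s:e] = copy
            occupied[s:e] = True
            placements_rows.append((gid, f"m{mid}", int(s), len(mseq), n_mut))

        # decompose the edited pre-mRNA back into parts
        premrna = "".join(pre)
        cut = []
        cum = 0
        new_introns = []
        for off, iseq in introns:
            s = off + cum
            new_introns.append((off, premrna[s:s + len(iseq)]))
            cut.append((s, s + len(iseq)))
            cum += len(iseq)
        mat = _splice_out(premrna, cut)
        p = GeneParts(gid, mat[:len(u5)], mat[len(u5):len(u5) + orf_len],
                      mat[len(u5) + orf_len:], new_introns)
        parts_list.append(p)

        mrna = float(np.exp(rng.normal(spec.mu_high if is_high else spec.mu_low,
                                       spec.sigma)))
        pa = float(mrna * np.exp(rng.normal(0.0, 0.4)))
        gene_rows.append((gid, str(classes[gi]), mrna, pa))

        strand = "+" if rng.random() < 0.5 else "-"
        strands[gid] = strand
        chrom = f"chr{gi // spec.genes_per_chrom + 1}"
        seqs = chrom_parts.setdefault(chrom, [])
        if not seqs:
            seqs.append(_random_seq(spec.spacer_len, spec.background_gc, rng))
        g0 = sum(len(s) for s in seqs)
        seqs.append(premrna if strand == "+" else reverse_complement(premrna))
        seqs.append(_random_seq(spec.spacer_len, spec.background_gc, rng))
        gff_lines.extend(_gff_records(gid, chrom, strand, g0, p, len(premrna)))

    chromosomes = {c: "".join(v) for c, v in chrom_parts.items()}
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "expression_class", "mrna", "pa"])
    expression = genes.set_index("gene_id")[["mrna", "pa"]]
    truth = SyntheticTruth(
        genes[["gene_id", "expression_class", "mrna"]].copy(),
        pd.DataFrame(placements_rows,
                     columns=["gene_id", "motif_id", "offset",
                              "length", "n_mutations"]),
    )
    return SyntheticDataset(spec, chromosomes, parts_list, strands,
                            "\n".join(gff_lines) + "\n", expression, truth)


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def _splice_in(mature: str, introns: list[tuple[int, str]]) -> str:
    out, prev = [], 0
    for off, seq in introns:
        out.append(mature[prev:off])
        out.append(seq)
        prev = off
    out.append(mature[prev:])
    return "".join(out)


def _splice_out(premrna: str, cuts: list[tuple[int, int]]) -> str:
    out, prev = [], 0
    for a, b in cuts:
        out.append(premrna[prev:a])
        prev = b
    out.append(premrna[prev:])
    return "".join(out)


def _gff_records(gid: str, chrom: str, strand: str, g0: int,
                 parts: GeneParts, pre_len: int) -> list[str]:
    """GFF3 features (1-based inclusive) for one gene placed at offset g0."""
    introns_pre = []
    cum = 0
    for off, seq in parts.introns:
        introns_pre.append((off + cum, off + cum + len(seq)))
        cum += len(seq)
    # exons: complement of introns within [0, pre_len)
    exons, prev = [], 0
    for a, b in introns_pre:
        exons.append((prev, a))
        prev = b
    exons.append((prev, pre_len))
    u5, orf = len(parts.five_utr), len(parts.orf)

    def pieces(a_m: int, b_m: int) -> list[tuple[int, int]]:
        """Map a mature interval to pre-mRNA pieces split at introns."""
        edges = [a_m] + [off for off, _ in parts.introns if a_m < off < b_m] + [b_m]
        out = []
        for a, b in zip(edges, edges[1:]):
            if b > a:
                s = _map_piece_start(a, parts)
                out.append((s, s + (b - a)))
        return out

    utr5_iv = pieces(0, u5)
    cds_iv = pieces(u5, u5 + orf)
    utr3_iv = pieces(u5 + orf, u5 + orf + len(parts.three_utr))

    def genomic(iv: tuple[int, int]) -> tuple[int, int]:
        a, b = iv
        if strand == "+":
            return g0 + a + 1, g0 + b
        return g0 + pre_len - b + 1, g0 + pre_len - a

    lines = []
    ga, gb = genomic((0, pre_len))
    lines.append(f"{chrom}\tsynthetic\tgene\t{ga}\t{gb}\t.\t{strand}\t.\tID={gid}")
    lines.append(f"{chrom}\tsynthetic\tmRNA\t{ga}\t{gb}\t.\t{strand}\t.\t"
                 f"ID={gid}.t1;Parent={gid}")
    for i, iv in enumerate(exons):
        a, b = genomic(iv)
        lines.append(f"{chrom}\tsynthetic\texon\t{a}\t{b}\t.\t{strand}\t.\t"
                     f"ID={gid}.exon{i};Parent={gid}.t1")
    cumlen = 0
    for i, iv in enumerate(cds_iv):
        a, b = genomic(iv)
        phase = (3 - cumlen % 3) % 3
        cumlen += iv[1] - iv[0]
        lines.append(f"{chrom}\tsynthetic\tCDS\t{a}\t{b}\t.\t{strand}\t{phase}\t"
                     f"ID={gid}.cds;Parent={gid}.t1")
    for tag, ivs in (("five_prime_UTR", utr5_iv), ("three_prime_UTR", utr3_iv)):
        for i, iv in enumerate(ivs):
            a, b = genomic(iv)
            lines.append(f"{chrom}\tsynthetic\t{tag}\t{a}\t{b}\t.\t{strand}\t.\t"
                         f"ID={gid}.{tag}{i};Parent={gid}.t1")
    return lines


def _map_piece_start(a_m: int, parts: GeneParts) -> int:
    """Pre-mRNA position of mature position ``a_m`` as an exonic piece start.

    A mature coordinate that coincides with an intron offset denotes the
    first exonic base *after* that intron.
    """
    shift = sum(len(s) for off, s in parts.introns if off <= a_m)
    return a_m + shift
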