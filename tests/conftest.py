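"""Shared fixtures: brute-force oracle, handcrafted gene files, small genomes."""

from __future__ import annotations

import random

import pytest

from arsi.synthetic import SyntheticSpec, synthesize_genome


def brute_force_profile(S: str, refs: list[str]) -> list[int]:
    """O(|S|^2 * |G|) longest-match lengths by direct substring search.

    Independent arbiter for the automaton: for each start position extend
    until no reference contains the substring; N matches nothing.
    """
    out = []
    for i in range(len(S)):
        best = 0
        for k in range(1, len(S) - i + 1):
            sub = S[i:i + k]
            if "N" in sub:
                break
            if any(sub in r for r in refs):
                best = k
            else:
                break
        out.append(best)
    return out


def random_instance(rnd: random.Random, max_s: int = 50, max_refs: int = 5,
                    max_ref_len: int = 100, alphabet: str = "ACGT"):
    S = "".join(rnd.choice(alphabet) for _ in range(rnd.randint(1, max_s)))
    refs = ["".join(rnd.choice(alphabet) for _ in range(rnd.randint(1, max_ref_len)))
            for _ in range(rnd.randint(1, max_refs))]
    return S, refs


@pytest.fixture(scope="session")
def small_dataset():
    """Compact synthetic genome shared by integration-level tests."""
    return synthesize_genome(SyntheticSpec(n_genes=60, seed=11))


@pytest.fixture(scope="session")
def small_parts(small_dataset):
    return small_dataset.parts


# --- handcrafted two-gene mini-genome with known coordinates ---------------

U5_A = "ACAAC"
CDS1_A = "ATGAAA"
INTRON_A = "GTATGT" + "CC" + "TACTAAC" + "TT" + "AG"  # 19 nt, GT...AG
CDS2_A = "GGGTAA"
U3_A = "CCTCC"
PRE_A = "TTTTT"
POST_A = "GAGAG"


def _gene_a_layout():
    """Plus-strand two-exon gene; returns (chrom_seq, gff feature rows)."""
    chrom = PRE_A + U5_A + CDS1_A + INTRON_A + CDS2_A + U3_A + POST_A
    s = len(PRE_A)  # gene start, 0-based
    u5 = (s, s + len(U5_A))
    c1 = (u5[1], u5[1] + len(CDS1_A))
    iv = (c1[1], c1[1] + len(INTRON_A))
    c2 = (iv[1], iv[1] + len(CDS2_A))
    u3 = (c2[1], c2[1] + len(U3_A))
    return chrom, u5, c1, iv, c2, u3


def _gff_row(chrom, ftype, iv, strand, attrs, phase="."):
    return (f"{chrom}\ttest\t{ftype}\t{iv[0] + 1}\t{iv[1]}\t.\t{strand}\t"
            f"{phase}\t{attrs}")


@pytest.fixture()
def mini_genome_files(tmp_path):
    """FASTA + GFF3 with one plus-strand and one minus-strand intron gene.

    geneB is the strand mirror of geneA on a second chromosome: its
    transcript-orientation regions must be identical to geneA's.
    """
    chromA, u5, c1, iv, c2, u3 = _gene_a_layout()
    # minus-strand mirror: reverse-complement the whole chromosome
    comp = str.maketrans("ACGT", "TGCA")
    chromB = chromA.translate(comp)[::-1]
    L = len(chromA)

    def mirror(ivl):
        return (L - ivl[1], L - ivl[0])

    rows = ["##gff-version 3"]
    rows.append(_gff_row("cA", "gene", (u5[0], u3[1]), "+", "ID=geneA"))
    rows.append(_gff_row("cA", "mRNA", (u5[0], u3[1]), "+",
                         "ID=geneA.t1;Parent=geneA"))
    rows.append(_gff_row("cA", "exon", (u5[0], c1[1]), "+",
                         "ID=geneA.e1;Parent=geneA.t1"))
    rows.append(_gff_row("cA", "exon", (c2[0], u3[1]), "+",
                         "ID=geneA.e2;Parent=geneA.t1"))
    rows.append(_gff_row("cA", "CDS", c1, "+", "ID=geneA.c;Parent=geneA.t1", "0"))
    rows.append(_gff_row("cA", "CDS", c2, "+", "ID=geneA.c;Parent=geneA.t1", "0"))
    rows.append(_gff_row("cA", "five_prime_UTR", u5, "+",
                         "ID=geneA.u5;Parent=geneA.t1"))
    rows.append(_gff_row("cA", "three_prime_UTR", u3, "+",
                         "ID=geneA.u3;Parent=geneA.t1"))
    rows.append(_gff_row("cB", "gene", mirror((u5[0], u3[1])), "-", "ID=geneB"))
    rows.append(_gff_row("cB", "mRNA", mirror((u5[0], u3[1])), "-",
                         "ID=geneB.t1;Parent=geneB"))
    rows.append(_gff_row("cB", "exon", mirror((u5[0], c1[1])), "-",
                         "ID=geneB.e1;Parent=geneB.t1"))
    rows.append(_gff_row("cB", "exon", mirror((c2[0], u3[1])), "-",
                         "ID=geneB.e2;Parent=geneB.t1"))
    rows.append(_gff_row("cB", "CDS", mirror(c1), "-",
                         "ID=geneB.c;Parent=geneB.t1", "0"))
    rows.append(_gff_row("cB", "CDS", mirror(c2), "-",
                         "ID=geneB.c;Parent=geneB.t1", "0"))
    rows.append(_gff_row("cB", "five_prime_UTR", mirror(u5), "-",
                         "ID=geneB.u5;Parent=geneB.t1"))
    rows.append(_gff_row("cB", "three_prime_UTR", mirror(u3), "-",
                         "ID=geneB.u3;Parent=geneB.t1"))
    # single-exon gene, CDS == exon, no UTR features, near chromosome start
    chromC = "ATGCATGATTACTAG" + "CCCCC"
    rows.append(_gff_row("cC", "gene", (0, 15), "+", "ID=geneC"))
    rows.append(_gff_row("cC", "mRNA", (0, 15), "+", "ID=geneC.t1;Parent=geneC"))
    rows.append(_gff_row("cC", "exon", (0, 15), "+", "ID=geneC.e1;Parent=geneC.t1"))
    rows.append(_gff_row("cC", "CDS", (0, 15), "+",
                         "ID=geneC.c;Parent=geneC.t1", "0"))

    fasta = tmp_path / "mini.fa"
    fasta.write_text(f">cA\n{chromA}\n>cB\n{chromB}\n>cC\n{chromC}\n")
    gff = tmp_path / "mini.gff3"
    gff.write_text("\n".join(rows) + "\n")
    return fasta, gff
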