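"""Composition-preserving genome randomizations and Z-scoring.

Three schemes scramble one region type each while conserving the
properties selection is *not* being tested for:

* ``codons`` — synonymous codons are pooled genome-wide by amino acid and
  permuted within each family: every encoded protein and the genome-wide
  codon-usage vector are unchanged exactly.
* ``introns`` — each intron's nucleotides are uniformly permuted with the
  donor-site prefix, the acceptor-site suffix and the best branch-motif
  hit held fixed; per-intron base composition (hence GC) is conserved.
* ``utrs`` — each UTR is cyclically rotated (composition conserved); the
  nucleotides immediately preceding the start codon (the ATG context) are
  additionally held fixed for 5'UTRs.

Schemes act on disjoint sequence, each from its own seeded RNG stream, so
applying them together equals applying them in any order.  An ensemble of
R randomized genomes gives per-position null means/SDs, from which the
real signal's Z-score profile is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy import stats

from .core import arsi_scores_leave_one_out, build_index
from .profiles import AlignedAnchorProfile, WindowParams, align_and_average, window_profile
from .sequence_io import GeneParts, region_elements, transcripts_from_parts

logger = logging.getLogger(__name__)

SCHEMES = ("codons", "introns", "utrs")
_SCHEME_TAG = {"codons": 11, "introns": 12, "utrs": 13}

_TABLE = unambiguous_dna_by_id[1]
_CODON_AA = dict(_TABLE.forward_table)
_CODON_AA.update({c: "*" for c in _TABLE.stop_codons})

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class ConsensusSpec:
    """Splicing-signal positions held fixed during intron permutation.

    Defaults fit budding-yeast-like introns: a 6-nt donor site (GTATGT
    consensus), a 3-nt acceptor site and the TACTAAC branch motif searched
    within the last ``branch_window`` nucleotides.
    """

    five_ss_len: int = 6
    three_ss_len: int = 3
    branch_motif: str = "TACTAAC"
    branch_window: int = 60


def _as_rng(seed=None, rng=None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(seed)


def permute_synonymous_codons(
    orfs: Sequence[tuple[str, str]],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    per_gene: bool = False,
) -> list[tuple[str, str]]:
    """Permute synonymous codons within amino-acid families.

    Pooling is genome-wide by default (``per_gene=True`` restricts each
    family to one gene).  Stop codons form their own family — internal
    stops, if present, are permuted within it.  Every protein sequence and
    the codon-count vector are conserved exactly.  ORFs whose length is
    not a multiple of three are returned unchanged with a warning.
    """
    rng = _as_rng(seed, rng)
    codons: list[list[str]] = []
    slots: dict[object, list[tuple[int, int]]] = {}
    for gi, (gid, seq) in enumerate(orfs):
        if len(seq) % 3 != 0:
            logger.warning("ORF %s length %d not divisible by 3; left unchanged",
                           gid, len(seq))
            codons.append([seq])  # opaque, untouched
            continue
        row = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        codons.append(row)
        for ci, cod in enumerate(row):
            aa = _CODON_AA.get(cod, f"?{cod}")  # N-containing codons: own family
            key = (gid, aa) if per_gene else aa
            slots.setdefault(key, []).append((gi, ci))
    for key in sorted(slots, key=str):
        members = slots[key]
        vals = [codons[gi][ci] for gi, ci in members]
        perm = rng.permutation(len(vals))
        for (gi, ci), j in zip(members, perm):
            codons[gi][ci] = vals[j]
    return [(gid, "".join(codons[gi])) for gi, (gid, _) in enumerate(orfs)]


def _best_branch_hit(intron: str, spec: ConsensusSpec) -> tuple[int, int] | None:
    """Locate the branch motif: rightmost full IUPAC match in the window."""
    m = len(spec.branch_motif)
    lo = max(spec.five_ss_len, len(intron) - spec.branch_window)
    hi = len(intron) - spec.three_ss_len - m
    best = None
    for i in range(lo, hi + 1):
        if all(intron[i + j] in _IUPAC[b] for j, b in enumerate(spec.branch_motif)):
            best = (i, i + m)
    return best


def permute_intron(
    intron: str,
    spec: ConsensusSpec = ConsensusSpec(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Uniformly permute an intron's nucleotides, consensus held fixed.

    Fixed positions: the 5'SS prefix, the 3'SS suffix, and the best branch
    motif hit if one exists in the search window (logged if absent).  The
    nucleotide multiset — hence GC content — is conserved exactly.  Introns
    too short to carry both splice sites are returned unchanged.
    """
    rng = _as_rng(seed, rng)
    n = len(intron)
    if n <= spec.five_ss_len + spec.three_ss_len:
        logger.warning("intron of length %d too short to randomize", n)
        return intron
    fixed = np.zeros(n, dtype=bool)
    fixed[:spec.five_ss_len] = True
    fixed[n - spec.three_ss_len:] = True
    hit = _best_branch_hit(intron, spec)
    if hit is not None:
        fixed[hit[0]:hit[1]] = True
    else:
        logger.debug("no branch motif %s found in intron", spec.branch_motif)
    free = np.flatnonzero(~fixed)
    chars = np.array(list(intron))
    chars[free] = chars[free[rng.permutation(free.size)]]
    return "".join(chars)


def cyclic_shift_utr(
    utr: str,
    kind: str,
    context_len: int = 6,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Cyclically rotate a UTR by a uniform random offset.

    3'UTRs rotate whole; for 5'UTRs the terminal ``context_len``
    nucleotides (the start-codon context) stay fixed and only the prefix
    rotates.  Length and base composition are conserved exactly; UTRs too
    short to rotate are returned unchanged.
    """
    if kind not in ("five", "three"):
        raise ValueError("kind must be 'five' or 'three'")
    rng = _as_rng(seed, rng)
    if kind == "five":
        if len(utr) <= context_len:
            return utr
        head, tail = utr[:-context_len], utr[-context_len:]
    else:
        head, tail = utr, ""
    if len(head) <= 1:
        return utr
    r = int(rng.integers(1, len(head)))
    return head[-r:] + head[:-r] + tail


def _seed_list(seed) -> list[int]:
    return list(seed) if isinstance(seed, (list, tuple)) else [int(seed)]


def randomize_parts(
    parts_list: Sequence[GeneParts],
    scheme: Sequence[str],
    seed,
    consensus: ConsensusSpec = ConsensusSpec(),
    context_len: int = 6,
    per_gene_codons: bool = False,
) -> list[GeneParts]:
    """Apply the requested randomization schemes to every gene.

    Each scheme draws from its own RNG stream derived from ``seed``, so
    scheme combinations commute exactly: randomizing with
    ``("codons","introns","utrs")`` equals applying the three schemes
    sequentially in any order with the same seed.
    """
    chosen = set(scheme)
    unknown = chosen - set(SCHEMES)
    if unknown:
        raise ValueError(f"unknown scheme(s): {sorted(unknown)}")
    out = [GeneParts(p.gene_id, p.five_utr, p.orf, p.three_utr,
                     list(p.introns), p.cds_frame_ok) for p in parts_list]
    if "codons" in chosen:
        rng = np.random.default_rng(_seed_list(seed) + [_SCHEME_TAG["codons"]])
        permuted = permute_synonymous_codons(
            [(p.gene_id, p.orf) for p in out], rng=rng, per_gene=per_gene_codons)
        for p, (_, orf) in zip(out, permuted):
            p.orf = orf
    if "introns" in chosen:
        rng = np.random.default_rng(_seed_list(seed) + [_SCHEME_TAG["introns"]])
        for p in out:
            p.introns = [(off, permute_intron(seq, consensus, rng=rng))
                         for off, seq in p.introns]
    if "utrs" in chosen:
        rng = np.random.default_rng(_seed_list(seed) + [_SCHEME_TAG["utrs"]])
        for p in out:
            p.five_utr = cyclic_shift_utr(p.five_utr, "five", context_len, rng=rng)
            p.three_utr = cyclic_shift_utr(p.three_utr, "three", context_len, rng=rng)
    return out


@dataclass
class NullEnsemble:
    """R randomized-genome replicates with their recomputed signals.

    ``scores[r]`` holds one replicate's leave-one-out ARSI scores (aligned
    with ``element_ids``); ``anchor_profiles[anchor][r]`` one replicate's
    aligned mean profile over ``offsets``.
    """

    scheme: tuple[str, ...]
    R: int
    seed: int
    element_ids: list[str] | None = None
    scores: np.ndarray | None = None
    offsets: np.ndarray | None = None
    anchor_profiles: dict[str, np.ndarray] | None = None


def randomize_genome(
    parts_list: Sequence[GeneParts],
    scheme: Sequence[str],
    R: int,
    seed: int,
    score_kind: str | None = None,
    params: WindowParams | None = None,
    anchors: Sequence[str] = (),
    consensus: ConsensusSpec = ConsensusSpec(),
    exclusion: str = "gene",
) -> NullEnsemble:
    """Build an R-replicate null ensemble and re-measure it.

    For each replicate the genome is re-randomized under ``scheme`` and the
    requested signals are recomputed with parameters identical to the real
    run: leave-one-out region scores (``score_kind``) and/or anchor-aligned
    window profiles (``params`` + ``anchors``).
    """
    if R < 2:
        raise ValueError("R must be >= 2 to estimate a standard deviation")
    ens = NullEnsemble(tuple(sorted(set(scheme))), R, seed)
    score_rows = []
    profile_rows: dict[str, list[np.ndarray]] = {a: [] for a in anchors}
    for r in range(R):
        rparts = randomize_parts(parts_list, scheme, seed=[int(seed), r],
                                 consensus=consensus)
        if score_kind is not None:
            elements = region_elements(list(rparts), score_kind)
            scores = arsi_scores_leave_one_out(elements, exclusion=exclusion)
            if ens.element_ids is None:
                ens.element_ids = [s.element_id for s in scores]
            score_rows.append(np.array([s.value for s in scores]))
        if params is not None and anchors:
            prof_by_anchor = mean_anchor_profiles(list(rparts), params, anchors,
                                                  exclusion=exclusion)
            for a in anchors:
                profile_rows[a].append(prof_by_anchor[a].mean_values)
                if ens.offsets is None:
                    ens.offsets = prof_by_anchor[a].offsets
    if score_rows:
        ens.scores = np.vstack(score_rows)
    if params is not None and anchors:
        ens.anchor_profiles = {a: np.vstack(rows) for a, rows in profile_rows.items()}
    return ens


def mean_anchor_profiles(
    parts_list: Sequence[GeneParts],
    params: WindowParams = WindowParams(),
    anchors: Sequence[str] = ("orf_start", "orf_end", "five_ss", "three_ss"),
    exclusion: str = "gene",
) -> dict[str, AlignedAnchorProfile]:
    """Anchor-aligned mean window profiles for a whole genome.

    The reference set for every window is the full pre-mRNA (all introns
    retained) of every *other* gene; each gene's duplicated transcripts are
    profiled and averaged per anchor offset.
    """
    refs = [(f"{p.gene_id}|premrna", p.premrna()) for p in parts_list]
    groups = {f"{p.gene_id}|premrna": p.gene_id for p in parts_list}
    index = build_index(refs, groups=groups)
    profs = []
    for p in parts_list:
        for tx in transcripts_from_parts(p):
            exclude = p.gene_id if exclusion == "gene" else None
            profs.append(window_profile(tx, index, params, exclude=exclude))
    out = {}
    for a in anchors:
        out[a] = align_and_average(profs, a, params)
    return out


@dataclass(frozen=True)
class ZProfile:
    """Per-offset Z of the real profile against a null ensemble.

    ``defined`` flags offsets where both the real value and a positive
    null SD exist; elsewhere ``z`` is NaN, never silently zero.
    """

    anchor: str
    offsets: np.ndarray
    real: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    defined: np.ndarray
    n_replicates: int


def zscore_scalars(real: np.ndarray, null: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z = (real - null mean) / null SD (ddof=1) per element; NaN where SD=0."""
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    z = np.full(mu.shape, np.nan)
    ok = sd > 0
    z[ok] = (np.asarray(real)[ok] - mu[ok]) / sd[ok]
    return z, mu, sd


def zscore_profile(real: AlignedAnchorProfile, ensemble: NullEnsemble) -> ZProfile:
    """Z-score profile of a real anchor-aligned profile against the null."""
    if ensemble.anchor_profiles is None or real.anchor not in ensemble.anchor_profiles:
        raise ValueError(f"ensemble has no profiles for anchor {real.anchor!r}")
    null = ensemble.anchor_profiles[real.anchor]
    n_ok = np.sum(~np.isnan(null), axis=0)
    mu = np.full(null.shape[1], np.nan)
    sd = np.full(null.shape[1], np.nan)
    some = n_ok > 0
    enough = n_ok >= 2
    if some.any():
        mu[some] = np.nanmean(null[:, some], axis=0)
    if enough.any():
        sd[enough] = np.nanstd(null[:, enough], axis=0, ddof=1)
    defined = enough & (sd > 0) & ~np.isnan(real.mean_values)
    z = np.full(mu.shape, np.nan)
    z[defined] = (real.mean_values[defined] - mu[defined]) / sd[defined]
    if not defined.all():
        logger.info("anchor %s: %d/%d offsets undefined in Z profile",
                    real.anchor, int((~defined).sum()), defined.size)
    return ZProfile(real.anchor, real.offsets, real.mean_values,
                    mu, sd, z, defined, null.shape[0])


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    median_real: float
    median_random: float
    n: int
    note: str = ""


def paired_real_vs_random_test(
    real_scores: Sequence[float],
    random_scores: Sequence[float],
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test of real vs matched randomized scores.

    One randomized replicate is matched element-by-element to the real
    genome; all-zero differences give p = 1 with a notice.
    """
    x = np.asarray(real_scores, dtype=float)
    y = np.asarray(random_scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired test needs equal-length score vectors")
    diffs = x - y
    if np.all(diffs == 0):
        return PairedTestResult(0.0, 1.0, float(np.median(x)), float(np.median(y)),
                                x.size, note="all paired differences are zero")
    stat, p = stats.wilcoxon(x, y, alternative="two-sided")
    return PairedTestResult(float(stat), float(p),
                            float(np.median(x)), float(np.median(y)), x.size)
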