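"""ARSI scoring core: longest-match profiles and their means.

The Average Repetitive Substring Index (ARSI) of a sequence S against a
reference set G is the mean, over the positions i of S, of the length of
the longest substring starting at i that occurs contiguously in at least
one element of G.  Long shared substrings indicate shared (intact)
regulatory motifs; random point mutations break them, so ARSI ranks
elements by how much sequence they share with the rest of the genome.

Matching is exact, strand-specific by default, and treats N as
unmatchable on both sides.  The index is a generalized suffix automaton
(:mod:`arsi._automaton`); queries are amortized linear in |S|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._automaton import encode, build_automaton, propagate_owners, matching_statistics

logger = logging.getLogger(__name__)

_NO_EXCLUSION = -2

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatchLengthProfile:
    """Per-position longest-match lengths L(i) of one query element.

    Satisfies 0 <= L(i) <= |S|-i and the shift bound L(i+1) >= L(i)-1
    (dropping the first character of a match leaves a match).
    """

    element_id: str
    lengths: np.ndarray

    def __len__(self) -> int:
        return int(self.lengths.size)


@dataclass(frozen=True)
class ArsiScore:
    """Mean match length (nt) of one element; ``length`` is |S|."""

    element_id: str
    value: float
    length: int
    gene_id: str | None = None


class ReferenceIndex:
    """Substring index over a set of reference elements.

    Each element carries a *group* label (by default its own id; for
    leave-one-out scoring, its gene id).  Queries may exclude one group:
    matches are then required to occur in an element of a different group.
    Answers are independent of insertion order, and a match never spans
    the boundary between two reference elements.
    """

    def __init__(
        self,
        references: Sequence[tuple[str, str]],
        groups: Mapping[str, object] | None = None,
        both_strands: bool = False,
    ):
        refs = list(references)
        if not refs or all(len(s) == 0 for _, s in refs):
            raise ValueError("empty reference")
        seen = set()
        for rid, _ in refs:
            if rid in seen:
                raise ValueError(f"duplicate reference id {rid!r}")
            seen.add(rid)
        self.reference_ids = [rid for rid, _ in refs]
        self.total_length = sum(len(s) for _, s in refs)

        group_of = {rid: (groups[rid] if groups is not None else rid) for rid, _ in refs}
        labels = sorted({str(g) for g in group_of.values()})
        self._group_num = {g: i for i, g in enumerate(labels)}
        self.n_groups = len(labels)

        chunks: list[np.ndarray] = []
        docchunks: list[np.ndarray] = []
        sep = np.array([4], dtype=np.int8)
        sepdoc = np.array([-1], dtype=np.int32)
        for rid, seq in refs:
            strands = [seq, reverse_complement(seq)] if both_strands else [seq]
            for s in strands:
                codes = encode(s)
                docs = np.full(codes.size, self._group_num[str(group_of[rid])], dtype=np.int32)
                docs[codes == 4] = -1  # N positions own nothing
                chunks.extend((codes, sep))
                docchunks.extend((docs, sepdoc))
        text = np.concatenate(chunks)
        docpos = np.concatenate(docchunks)
        trans, link, length, own1, own2, size = build_automaton(text, docpos)
        propagate_owners(link, length, own1, own2, size)
        self._trans = np.ascontiguousarray(trans)
        self._link = link
        self._len = length
        self._own1 = own1
        self._own2 = own2

    def _exclude_code(self, exclude: object | None) -> int:
        if exclude is None:
            return _NO_EXCLUSION
        key = str(exclude)
        if key not in self._group_num:
            raise KeyError(f"unknown reference group {key!r}")
        return self._group_num[key]

    def lengths(self, seq: str, exclude: object | None = None) -> np.ndarray:
        if len(seq) == 0:
            raise ValueError("empty query sequence")
        return matching_statistics(
            self._trans, self._link, self._len, self._own1, self._own2,
            encode(seq), self._exclude_code(exclude),
        )


def build_index(
    references: Sequence[tuple[str, str]],
    groups: Mapping[str, object] | None = None,
    both_strands: bool = False,
) -> ReferenceIndex:
    """Build a :class:`ReferenceIndex` from ``(id, sequence)`` pairs."""
    return ReferenceIndex(references, groups=groups, both_strands=both_strands)


def longest_match_at(index: ReferenceIndex, seq: str, i: int) -> int:
    """Longest k such that ``seq[i:i+k]`` occurs in the reference set."""
    if not 0 <= i < len(seq):
        raise IndexError(f"position {i} out of range for |S|={len(seq)}")
    return int(index.lengths(seq[i:])[0])


def match_length_profile(
    index: ReferenceIndex,
    seq: str,
    exclude: object | None = None,
    element_id: str = "query",
) -> MatchLengthProfile:
    """L(i) for every position i of ``seq`` against ``index``."""
    return MatchLengthProfile(element_id, index.lengths(seq, exclude=exclude))


def arsi_score(
    index: ReferenceIndex,
    seq: str,
    exclude: object | None = None,
    element_id: str = "query",
    gene_id: str | None = None,
) -> ArsiScore:
    """ARSI = sum_i L(i) / |S| for one query sequence."""
    L = index.lengths(seq, exclude=exclude)
    return ArsiScore(element_id, float(L.sum()) / L.size, int(L.size), gene_id)


def arsi_scores_leave_one_out(
    elements: Sequence[tuple[str, str, str]],
    exclusion: str = "gene",
    both_strands: bool = False,
) -> list[ArsiScore]:
    """Score every element against all the others.

    ``elements`` are ``(element_id, gene_id, sequence)`` triples.  With
    ``exclusion="gene"`` (default) an element's reference excludes every
    element of the same gene — a multi-intron gene's duplicated transcripts
    never match themselves; ``exclusion="element"`` excludes only the
    element itself.
    """
    items = [e for e in elements]
    if len(items) < 2:
        raise ValueError("leave-one-out needs >=2 elements")
    if exclusion not in ("gene", "element"):
        raise ValueError(f"unknown exclusion policy {exclusion!r}")
    keyfn = (lambda eid, gid: gid) if exclusion == "gene" else (lambda eid, gid: eid)
    groups = {eid: keyfn(eid, gid) for eid, gid, _ in items}
    index = build_index([(eid, seq) for eid, _, seq in items],
                        groups=groups, both_strands=both_strands)
    return [
        arsi_score(index, seq, exclude=groups[eid], element_id=eid, gene_id=gid)
        for eid, gid, seq in items
    ]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_read_errors(
    sequences: Iterable[str],
    error_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Apply uniform per-nucleotide substitution errors to each sequence.

    Each A/C/G/T position is independently replaced, with probability
    ``error_rate``, by one of the three other bases chosen uniformly
    (mirroring uniform sequencing error).  N positions are left as-is.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for seq in sequences:
        if error_rate == 0 or len(seq) == 0:
            out.append(seq)
            continue
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        is_base = (raw[:, None] == _BASES[None, :]).any(axis=1)
        hit = (rng.random(raw.size) < error_rate) & is_base
        if hit.any():
            idx = np.flatnonzero(hit)
            cur = np.searchsorted(_BASES, raw[idx])  # ACGT are sorted bytes
            shift = rng.integers(1, 4, size=idx.size)
            raw[idx] = _BASES[(cur + shift) % 4]
        out.append(raw.tobytes().decode("ascii"))
    return out
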