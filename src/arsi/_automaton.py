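"""Suffix-automaton kernels for exact longest-substring matching.

The reference set is concatenated into a single integer-coded text
(alphabet A,C,G,T = 0..3; 4 is both the inter-sequence separator and the
code for N, so matches can neither span two reference elements nor touch
an ambiguous base).  A generalized suffix automaton is built online over
that text; every automaton state keeps up to two *distinct* document
labels drawn from the documents its substring occurs in, which is exactly
enough information to answer "does this substring occur in a document
other than d?" — the primitive behind leave-one-out scoring.

All hot loops are numba-compiled; the Python-facing wrapper lives in
:mod:`arsi.core`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: nucleotide codes; 4 doubles as separator and as N (never matchable)
A, C, G, T, SEP = 0, 1, 2, 3, 4
ALPHABET_SIZE = 5

_ENCODE = np.full(256, SEP, dtype=np.int8)
for _ch, _code in (("A", A), ("C", C), ("G", G), ("T", T),
                   ("a", A), ("c", C), ("g", G), ("t", T)):
    _ENCODE[ord(_ch)] = _code


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes; anything not ACGT becomes 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


@njit(cache=True)
def build_automaton(text, docpos):  # pragma: no cover - exercised via core
    """Online suffix-automaton construction over coded ``text``.

    ``docpos[j]`` is the document label of position j (-1 for separators;
    such positions are never marked as owners).  Returns transition table,
    suffix links, state lengths, the two per-state owner slots (positions
    only; call :func:`propagate_owners` afterwards) and the state count.
    """
    n = text.size
    max_states = 2 * n + 2
    trans = np.full((max_states, ALPHABET_SIZE), -1, dtype=np.int32)
    link = np.full(max_states, -1, dtype=np.int32)
    length = np.zeros(max_states, dtype=np.int32)
    own1 = np.full(max_states, -1, dtype=np.int32)
    own2 = np.full(max_states, -1, dtype=np.int32)

    size = 1  # state 0 is the root (empty string)
    last = 0
    for pos in range(n):
        c = text[pos]
        cur = size
        size += 1
        length[cur] = length[last] + 1
        d = docpos[pos]
        if d >= 0:
            own1[cur] = d
        p = last
        while p >= 0 and trans[p, c] < 0:
            trans[p, c] = cur
            p = link[p]
        if p < 0:
            link[cur] = 0
        else:
            q = trans[p, c]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = size
                size += 1
                length[clone] = length[p] + 1
                link[clone] = link[q]
                for a in range(ALPHABET_SIZE):
                    trans[clone, a] = trans[q, a]
                while p >= 0 and trans[p, c] == q:
                    trans[p, c] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        last = cur
    return trans[:size], link[:size], length[:size], own1[:size], own2[:size], size


@njit(cache=True)
def propagate_owners(link, length, own1, own2, size):  # pragma: no cover
    """Push owner labels up the suffix-link tree (decreasing state length).

    Afterwards each state's two slots hold up to two distinct documents in
    which its substrings occur; two distinct slots mean "occurs in at least
    two documents", a single slot names the sole owning document.
    """
    maxlen = 0
    for i in range(size):
        if length[i] > maxlen:
            maxlen = length[i]
    start = np.zeros(maxlen + 2, dtype=np.int64)
    for i in range(size):
        start[length[i] + 1] += 1
    for l in range(1, maxlen + 2):
        start[l] += start[l - 1]
    order = np.zeros(size, dtype=np.int64)
    fill = start.copy()
    for i in range(size):
        order[fill[length[i]]] = i
        fill[length[i]] += 1
    for idx in range(size - 1, -1, -1):
        v = order[idx]
        p = link[v]
        if p < 0:
            continue
        o = own1[v]
        if o >= 0:
            if own1[p] < 0:
                own1[p] = o
            elif own1[p] != o and own2[p] < 0:
                own2[p] = o
        o = own2[v]
        if o >= 0 and own2[p] < 0 and own1[p] != o:
            if own1[p] < 0:
                own1[p] = o
            else:
                own2[p] = o


@njit(cache=True)
def matching_statistics(trans, link, length, own1, own2, query, exclude):
    """Per-position longest-match lengths of ``query`` against the index.

    ``L[i]`` is the length of the longest prefix of ``query[i:]`` occurring
    as a substring of some reference element whose document label differs
    from ``exclude`` (pass a negative sentinel to disable exclusion).
    Amortized linear: a single left-to-right walk with suffix-link descents.
    """
    n = query.size
    L = np.zeros(n, dtype=np.int32)
    v = 0
    l = 0
    for i in range(n):
        while i + l < n:
            c = query[i + l]
            if c >= 4:
                break
            u = trans[v, c]
            if u < 0:
                break
            if own1[u] == exclude and own2[u] < 0:
                break
            v = u
            l += 1
        L[i] = l
        if l > 0:
            l -= 1
            if l == length[link[v]]:
                v = link[v]
    return L
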