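"""Sliding-window ARSI profiles and anchor-aligned (metagene) averages.

A window profile assigns to each pre-mRNA position i the ARSI of the
WL-nucleotide window centered on i, treated as its own query sequence.
This is computed without re-querying each window: the window's per-start
match lengths equal the full-transcript lengths truncated at the window
boundary, ``min(L_full(p), window_end - p)`` — a window substring's match
is exactly a prefix-truncated full-sequence match.

Profiles from many genes are then aligned on a shared anchor (ORF
start/end, donor or acceptor splice site) and averaged per offset over
the genes that still have a full window at that offset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import ReferenceIndex
from .sequence_io import AnchoredTranscript

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window geometry.

    ``wl`` is the (odd) window length in nucleotides — 31/41/51/71 are the
    conventional choices, 41 the default; ``n`` controls the anchor-flank
    extent: profiles span +/- floor((n - 1/2) * wl) around the anchor.
    """

    wl: int = 41
    n: int = 4

    def __post_init__(self):
        if self.wl < 1 or self.wl % 2 == 0:
            raise ValueError("window length must be odd and positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def half(self) -> int:
        return (self.wl - 1) // 2

    @property
    def flank(self) -> int:
        return math.floor((self.n - 0.5) * self.wl)


@dataclass(frozen=True)
class WindowProfileVector:
    """Windowed ARSI values of one transcript.

    ``values[j]`` is the window score centered on pre-mRNA position
    ``center_start + j``; only full windows are kept, so ``center_start``
    equals ``(wl-1)//2``.
    """

    element_id: str
    gene_id: str
    wl: int
    center_start: int
    values: np.ndarray
    anchors: dict[str, int]


@dataclass(frozen=True)
class AlignedAnchorProfile:
    """Mean windowed ARSI per offset from an anchor, across genes.

    ``mean_values[o]`` averages exactly ``counts[o]`` genes (NaN where no
    gene reaches that offset).
    """

    anchor: str
    offsets: np.ndarray
    mean_values: np.ndarray
    counts: np.ndarray


def window_values(lengths: np.ndarray, wl: int) -> np.ndarray:
    """Windowed means of boundary-truncated match lengths.

    ``out[a]`` is the ARSI of the window starting at position a:
    ``mean_p min(L(p), a + wl - p)`` over ``p in [a, a+wl)``.
    """
    L = np.asarray(lengths, dtype=np.int64)
    if L.size < wl:
        return np.empty(0, dtype=float)
    caps = np.arange(wl, 0, -1, dtype=np.int64)
    win = sliding_window_view(L, wl)
    return np.minimum(win, caps[None, :]).mean(axis=1)


def window_profile(
    transcript: AnchoredTranscript,
    index: ReferenceIndex,
    params: WindowParams = WindowParams(),
    exclude: object | None = None,
) -> WindowProfileVector:
    """Sliding-window ARSI profile of one transcript (1-nt step).

    Transcripts shorter than one window yield an empty profile with a
    logged warning.
    """
    if len(transcript.premrna) < params.wl:
        logger.warning("transcript %s shorter than window (%d < %d)",
                       transcript.element_id, len(transcript.premrna), params.wl)
        vals = np.empty(0, dtype=float)
    else:
        L = index.lengths(transcript.premrna, exclude=exclude)
        vals = window_values(L, params.wl)
    return WindowProfileVector(
        element_id=transcript.element_id, gene_id=transcript.gene_id,
        wl=params.wl, center_start=params.half, values=vals,
        anchors=dict(transcript.anchors),
    )


def align_and_average(
    profiles: list[WindowProfileVector],
    anchor: str,
    params: WindowParams = WindowParams(),
) -> AlignedAnchorProfile:
    """Average window profiles across genes after aligning on ``anchor``.

    Offset 0 is the anchor nucleotide itself; offsets run from -flank to
    +flank and a gene contributes wherever its transcript still contains a
    full window.
    """
    F = params.flank
    width = 2 * F + 1
    sums = np.zeros(width)
    counts = np.zeros(width, dtype=np.int64)
    used = 0
    for prof in profiles:
        if anchor not in prof.anchors or prof.values.size == 0:
            continue
        a = prof.anchors[anchor]
        cs = prof.center_start
        ce = cs + prof.values.size - 1  # last valid center
        lo = max(-F, cs - a)
        hi = min(F, ce - a)
        if lo > hi:
            continue
        sums[lo + F:hi + F + 1] += prof.values[a + lo - cs:a + hi - cs + 1]
        counts[lo + F:hi + F + 1] += 1
        used += 1
    if used == 0:
        raise ValueError(f"no profiles carry anchor {anchor!r}")
    mean = np.full(width, np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    return AlignedAnchorProfile(anchor, np.arange(-F, F + 1), mean, counts)
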