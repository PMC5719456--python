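"""Pustell-style windowed dot-matrix comparison.

A window of odd length centered on a point of the (a x b) comparison
matrix is "on" when the number of matching positions along the diagonal
reaches ``ceil(min_identity * window)`` — with window 15 and identity
0.70 that is 11 of 15.  Adjacent on-windows along a diagonal are merged
into maximal segments, which is what a dot-plot renders and what the
snake-element search scans for.  IUPAC ambiguity codes match when their
base sets intersect, so clade consensus sequences compare sensibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from firetrace import iupac
from firetrace.io import SequenceRecord


@dataclass(frozen=True)
class DotMatrixParams:
    window: int = 15
    min_identity: float = 0.70
    strands: str = "both"  # '+', '-', or 'both'

    def __post_init__(self) -> None:
        if self.window < 5:
            raise ValueError("window must be at least 5")
        if self.window % 2 == 0:
            raise ValueError("window must be odd (centered)")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.strands not in ("+", "-", "both"):
            raise ValueError("strands must be '+', '-' or 'both'")

    @property
    def required_matches(self) -> int:
        return math.ceil(self.min_identity * self.window)


@dataclass(frozen=True)
class DiagonalSegment:
    """A maximal run of on-windows along one diagonal.

    ``x_start``/``y_start`` are 0-based starts in sequence a and b of the
    union of the windows in the run; on the '-' strand the y
    coordinates refer to the forward strand of b.
    """

    x_start: int
    y_start: int
    length: int
    strand: str
    mean_identity: float


def _mask_array(seq: str) -> np.ndarray:
    return np.array([iupac.CODE_TO_MASK[c] for c in seq], dtype=np.uint8)


def _strand_segments(a: str, b: str, params: DotMatrixParams) -> list[tuple[int, int, int, float]]:
    """Segments of a vs b on one strand: (x_start, y_start, length, identity)."""
    w = params.window
    need = params.required_matches
    ma, mb = _mask_array(a), _mask_array(b)
    la, lb = len(ma), len(mb)
    segments = []
    kernel = np.ones(w)
    # diagonal offset k: positions (x, y) with x - y = k
    for k in range(-(lb - w), la - w + 1):
        if k >= 0:
            xs, ys = k, 0
        else:
            xs, ys = 0, -k
        length = min(la - xs, lb - ys)
        if length < w:
            continue
        match = ((ma[xs:xs + length] & mb[ys:ys + length]) != 0).astype(float)
        counts = np.convolve(match, kernel, mode="valid")  # window starting at t
        on = counts >= need - 1e-9
        t = 0
        nwin = len(on)
        while t < nwin:
            if not on[t]:
                t += 1
                continue
            run_start = t
            while t < nwin and on[t]:
                t += 1
            run_end = t  # exclusive; windows run_start..run_end-1 are on
            seg_len = (run_end - 1) - run_start + w
            ident = float(np.mean(counts[run_start:run_end]) / w)
            segments.append((xs + run_start, ys + run_start, seg_len, ident))
    return segments


def dot_matrix(a: SequenceRecord, b: SequenceRecord,
               params: DotMatrixParams | None = None) -> list[DiagonalSegment]:
    """All maximal on-window diagonal segments between two sequences."""
    params = params or DotMatrixParams()
    if params.window > min(len(a), len(b)):
        raise ValueError("window longer than the shorter sequence")
    out: list[DiagonalSegment] = []
    if params.strands in ("+", "both"):
        for x, y, length, ident in _strand_segments(a.seq, b.seq, params):
            out.append(DiagonalSegment(x, y, length, "+", ident))
    if params.strands in ("-", "both"):
        rc = iupac.revcomp(b.seq)
        for x, y, length, ident in _strand_segments(a.seq, rc, params):
            # map the window union back to forward-strand b coordinates
            y_fwd = len(b) - (y + length)
            out.append(DiagonalSegment(x, y_fwd, length, "-", ident))
    out.sort(key=lambda s: (s.x_start, s.y_start, s.strand))
    return out


def locate_by_dotplot(query: SequenceRecord, intron: SequenceRecord,
                      params: DotMatrixParams | None = None,
                      min_cover_windows: float = 3.0) -> tuple[int, int] | None:
    """Best query-sized interval of *intron* by on-diagonal segment evidence.

    Slides a window of ``len(query)`` over the intron and scores each
    placement by the identity-weighted total length of dot-matrix
    segments falling inside it (ties -> smallest start).  Isolated
    chance windows are expected on any long comparison (the binomial
    tail of the window threshold), so a candidate is only returned when
    the best placement accumulates at least *min_cover_windows* windows'
    worth of weighted coverage; otherwise ``None``.
    """
    params = params or DotMatrixParams()
    if len(intron) < len(query):
        raise ValueError("intron shorter than query")
    segments = dot_matrix(query, intron, params)
    if not segments:
        return None
    qlen = len(query)
    max_start = len(intron) - qlen
    # candidate starts: segment-aligned placements are enough to find the max
    starts = sorted({max(0, min(s.y_start, max_start)) for s in segments}
                    | {max(0, min(s.y_start + s.length - qlen, max_start))
                       for s in segments})
    best_start, best_cover = None, -1.0
    for start in starts:
        end = start + qlen
        cover = sum(
            s.mean_identity
            * max(0, min(s.y_start + s.length, end) - max(s.y_start, start))
            for s in segments
        )
        if cover > best_cover:
            best_start, best_cover = start, cover
    if best_cover < min_cover_windows * params.window:
        return None
    return (best_start, best_start + qlen)


def write_segments_tsv(segments: list[DiagonalSegment], a_id: str, b_id: str,
                       path) -> None:
    """BED-like TSV: seq_a, start, end, seq_b, start, end, strand, identity."""
    with open(path, "w") as handle:
        handle.write("#seq_a\ta_start\ta_end\tseq_b\tb_start\tb_end\tstrand\tidentity\n")
        for s in segments:
            handle.write(
                f"{a_id}\t{s.x_start}\t{s.x_start + s.length}\t"
                f"{b_id}\t{s.y_start}\t{s.y_start + s.length}\t"
                f"{s.strand}\t{s.mean_identity:.4f}\n"
            )
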