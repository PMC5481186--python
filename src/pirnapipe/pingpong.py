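"""The ping-pong distance score between two position-weighted read sets.

For plus-strand weights M and minus-strand weights N (both keyed by
reference coordinate of the chosen read end),

    score(delta) = sum_i M(i) * N(i + delta)

Minus-strand 5' ends are expressed in plus coordinates as ``end - 1`` (the
coordinate of the 5' nucleotide itself), so delta = 0 means the two 5' ends
share a nucleotide and delta = 9 corresponds to the canonical 10-nt 5'
overlap of slicer-generated piRNA pairs.  ``fraction`` normalizes the score
to sum to one over the examined window, i.e. the fraction of read pairs at
each distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .readproc import AlignedRead, Read, align_hamming

__all__ = [
    "PositionWeights",
    "PingPongProfile",
    "weights_from_alignments",
    "pingpong_score",
    "end_distance_score",
    "genic_pingpong",
]


@dataclass(frozen=True)
class PositionWeights:
    """Read-end weights at reference positions for one strand."""

    reference_id: str
    strand: str                     # '+' or '-'
    weights: dict[int, float]
    end_type: str = "five_prime"    # or "three_prime"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.end_type not in ("five_prime", "three_prime"):
            raise ValueError("end_type must be five_prime or three_prime")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.weights.values()))


def _end_position(read: AlignedRead, end_type: str) -> int:
    """Plus-coordinate of the requested read end (the nucleotide itself)."""
    if end_type == "five_prime":
        return read.start if read.strand == "+" else read.end - 1
    return read.end - 1 if read.strand == "+" else read.start


def weights_from_alignments(
    reads: list[AlignedRead],
    strand: str,
    end_type: str = "five_prime",
    reference_id: str | None = None,
    rpm_total: int | None = None,
) -> PositionWeights:
    """Accumulate end positions of reads on one strand into PositionWeights.

    Weights are raw counts, or rpm when ``rpm_total`` is given (the Methods
    convention for the ping-pong score).
    """
    w: dict[int, float] = {}
    rid = reference_id
    for read in reads:
        if read.strand != strand:
            continue
        if rid is None:
            rid = read.reference_id
        if read.reference_id != rid:
            continue
        pos = _end_position(read, end_type)
        w[pos] = w.get(pos, 0.0) + 1.0
    if rpm_total:
        w = {p: v * 1e6 / rpm_total for p, v in w.items()}
    return PositionWeights(rid or "ref", strand, w, end_type)


@dataclass(frozen=True)
class PingPongProfile:
    deltas: tuple[int, ...]
    score: tuple[float, ...]
    fraction: tuple[float, ...] = field(default_factory=tuple)

    @property
    def argmax_delta(self) -> int | None:
        """Delta with maximal score; None when the profile is all zero."""
        arr = np.asarray(self.score)
        if arr.size == 0 or arr.max() <= 0:
            return None
        return self.deltas[int(arr.argmax())]

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.deltas, self.score))


def pingpong_score(
    M: PositionWeights,
    N: PositionWeights,
    delta_range: tuple[int, int] = (-20, 30),
) -> PingPongProfile:
    """score(delta) = sum_i M(i) * N(i + delta) over an inclusive delta window."""
    if M.reference_id != N.reference_id:
        raise ValueError("M and N must live on the same reference")
    lo, hi = delta_range
    deltas = tuple(range(lo, hi + 1))
    score = []
    for d in deltas:
        s = 0.0
        for i, wm in M.weights.items():
            wn = N.weights.get(i + d)
            if wn:
                s += wm * wn
        score.append(s)
    total = sum(score)
    if total > 0:
        fraction = tuple(s / total for s in score)
    else:
        warnings.warn("all-zero ping-pong score: fraction undefined")
        fraction = tuple(float("nan") for _ in score)
    return PingPongProfile(deltas, tuple(score), fraction)


def end_distance_score(
    A: PositionWeights,
    B: PositionWeights,
    delta_range: tuple[int, int] = (-20, 30),
) -> PingPongProfile:
    """Same summation with arbitrary end types (e.g. 3'-to-5' distances).

    Used to detect by-products (their 3' ends register against targeting
    5' ends) and pre-piRNA intermediates.
    """
    return pingpong_score(A, B, delta_range)


def genic_pingpong(
    transcripts: dict[str, str],
    targeting_reads: list[Read],
    produced_reads: list[Read],
    top_n: int = 500,
    delta_range: tuple[int, int] = (-20, 30),
    max_mm_targeting: int = 3,
    forbidden_positions: frozenset[int] = frozenset(range(2, 11)),
    rpm_total: int | None = None,
) -> PingPongProfile:
    """Ping-pong signature over the transcripts most targeted by piRNAs.

    Targeting reads map antisense with up to ``max_mm_targeting`` mismatches,
    none at read positions 2-10; produced reads map sense with no mismatch.
    Transcripts are ranked by targeting-read count and the score is summed
    over the ``top_n`` best-targeted ones.
    """
    targeting_hits: dict[str, list[AlignedRead]] = {t: [] for t in transcripts}
    produced_hits: dict[str, list[AlignedRead]] = {t: [] for t in transcripts}
    for read in targeting_reads:
        best = None
        for tid in sorted(transcripts):
            hit = align_hamming(
                read,
                transcripts[tid],
                reference_id=tid,
                max_mm=max_mm_targeting,
                forbidden_positions=forbidden_positions,
                strands=("-",),
            )
            if hit is not None and (best is None or hit.n_mismatch < best.n_mismatch):
                best = hit
        if best is not None:
            targeting_hits[best.reference_id].append(best)
    for read in produced_reads:
        for tid in sorted(transcripts):
            hit = align_hamming(
                read, transcripts[tid], reference_id=tid, max_mm=0, strands=("+",)
            )
            if hit is not None:
                produced_hits[tid].append(hit)
                break
    ranked = sorted(
        transcripts, key=lambda t: (-len(targeting_hits[t]), t)
    )
    if not any(targeting_hits[t] for t in transcripts):
        warnings.warn("no targeting reads mapped: empty ping-pong profile")
    if len(ranked) < top_n:
        kept = ranked
    else:
        kept = ranked[:top_n]
    lo, hi = delta_range
    deltas = tuple(range(lo, hi + 1))
    total_score = np.zeros(len(deltas))
    for tid in kept:
        if not targeting_hits[tid] or not produced_hits[tid]:
            continue
        M = weights_from_alignments(
            produced_hits[tid], "+", "five_prime", tid, rpm_total
        )
        N = weights_from_alignments(
            targeting_hits[tid], "-", "five_prime", tid, rpm_total
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = pingpong_score(M, N, delta_range)
        total_score += np.asarray(prof.score)
    total = total_score.sum()
    if total > 0:
        fraction = tuple(float(s) / total for s in total_score)
    else:
        fraction = tuple(float("nan") for _ in deltas)
    return PingPongProfile(deltas, tuple(float(s) for s in total_score), fraction)
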