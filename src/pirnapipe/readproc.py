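"""Demultiplexing, 3' adapter clipping, length filtering and Hamming alignment.

The aligner scans every offset of a read against a reference on one or both
strands and keeps placements whose Hamming distance is within a mismatch
budget, optionally excluding mismatches from a set of read positions (the
guide "seed" rule used when mapping targeting piRNAs: up to 3 mismatches,
none at read positions 2-10).  With a zero budget this is exact substring
search.  References here are single transcripts or consensus sequences, so
a full scan is appropriate; genome-scale seeded alignment is out of scope.

Coordinate conventions (shared with the distance statistics downstream):
0-based half-open [start, end) reference coordinates; for a minus-strand
placement the read's 5' nucleotide sits at reference coordinate ``end - 1``.
Mismatch positions are reported 1-based along the read, 5'->3' of the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simulate import revcomp

__all__ = [
    "Read",
    "AlignedRead",
    "demultiplex",
    "trim_adapter",
    "filter_min_length",
    "align_hamming",
    "align_reads",
]

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    library_tag: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("read sequence must be non-empty")
        if not set(self.sequence) <= _ALPHABET:
            raise ValueError("read contains characters outside {A,C,G,T,N}")


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    reference_id: str
    strand: str                      # '+' or '-'
    start: int                       # 0-based half-open
    end: int
    mismatch_positions: tuple[int, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatch_positions)


def demultiplex(
    reads: list[Read],
    barcode_map: dict[str, str],
    adapter_seq: str = "",
    anchor: int = 4,
) -> dict[str, list[Read]]:
    """Sort reads into libraries by their inline 3'-end barcode.

    The barcode sits between the insert and the 3' adapter, so a read is
    assigned to the library whose ``barcode + adapter[:anchor]`` occurs in
    it, or whose barcode(+adapter prefix) forms the read's suffix when the
    tail was truncated by the sequencing length.  Reads matching no barcode
    (e.g. maximum-length reads that never sequence their barcode) go to the
    ``"undetermined"`` bin.  Total read count is conserved across bins.
    """
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("barcode collision: barcodes must be unique")
    lengths = {len(b) for b in barcode_map.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must have equal length")

    bins: dict[str, list[Read]] = {tag: [] for tag in barcode_map}
    bins["undetermined"] = []
    for read in reads:
        assigned = None
        for tag, bc in barcode_map.items():
            if bc + adapter_seq[:anchor] in read.sequence:
                assigned = tag
                break
        if assigned is None:
            # truncated tail: barcode fully present as part of the suffix
            for tag, bc in barcode_map.items():
                full = bc + adapter_seq
                top = min(len(read.sequence), len(full))
                if any(
                    read.sequence.endswith(full[:ov])
                    for ov in range(top, len(bc) - 1, -1)
                ):
                    assigned = tag
                    break
        key = assigned if assigned is not None else "undetermined"
        bins[key].append(
            Read(read.read_id, read.sequence, library_tag=assigned)
        )
    counts = {tag: len(v) for tag, v in bins.items()}
    logger.info("demultiplex bin counts: %s", counts)
    return bins


def trim_adapter(sequence: str, adapter: str, min_overlap: int = 3) -> str:
    """Clip the 3' adapter from a read sequence (exact match).

    If the full adapter occurs internally the read is truncated at its first
    occurrence; otherwise the longest read suffix equal to an adapter prefix
    of length >= ``min_overlap`` is removed; otherwise the read is returned
    unchanged.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    idx = sequence.find(adapter)
    if idx >= 0:
        return sequence[:idx]
    top = min(len(sequence), len(adapter) - 1)
    for ov in range(top, min_overlap - 1, -1):
        if sequence.endswith(adapter[:ov]):
            return sequence[: len(sequence) - ov]
    return sequence


def filter_min_length(reads: list[Read], min_len: int = 15) -> list[Read]:
    """Keep reads of at least ``min_len`` nucleotides."""
    kept = [r for r in reads if len(r.sequence) >= min_len]
    dropped = len(reads) - len(kept)
    if dropped:
        logger.info("filter_min_length dropped %d/%d reads", dropped, len(reads))
    return kept


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _scan_strand(
    read_seq: str,
    reference: str,
    strand: str,
    max_mm: int,
    forbidden: frozenset[int],
) -> list[tuple[int, int, str, tuple[int, ...]]]:
    """All valid placements of a read on one strand: (n_mm, start, strand, mmpos)."""
    L = len(read_seq)
    if L > len(reference):
        return []
    query = read_seq if strand == "+" else revcomp(read_seq)
    if max_mm == 0:
        out = []
        pos = reference.find(query)
        while pos >= 0:
            out.append((0, pos, strand, ()))
            pos = reference.find(query, pos + 1)
        return out
    ref_arr = _encode(reference)
    q_arr = _encode(query)
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    mism = windows != q_arr                      # (n_offsets, L)
    # N in the read always counts as a mismatch
    n_mask = q_arr == ord("N")
    if n_mask.any():
        mism = mism | n_mask
    counts = mism.sum(axis=1)
    cand_offsets = np.nonzero(counts <= max_mm)[0]
    out = []
    for off in cand_offsets:
        cols = np.nonzero(mism[off])[0]
        if strand == "+":
            read_pos = tuple(int(c) + 1 for c in cols)
        else:
            # window column j pairs with read position L - j (1-based)
            read_pos = tuple(sorted(L - int(c) for c in cols))
        if forbidden and any(p in forbidden for p in read_pos):
            continue
        out.append((int(counts[off]), int(off), strand, read_pos))
    return out


def align_hamming(
    read: Read | str,
    reference: str,
    reference_id: str = "ref",
    max_mm: int = 0,
    forbidden_positions: frozenset[int] | set[int] | None = None,
    both_strands: bool = True,
    strands: tuple[str, ...] | None = None,
) -> AlignedRead | None:
    """Best Hamming placement of a read on a reference, or None.

    Among valid placements (mismatches <= ``max_mm``, none at a forbidden
    1-based read position) the one with fewest mismatches wins; ties break
    toward the smallest start, then '+' before '-'.
    """
    if isinstance(read, str):
        read = Read("query", read)
    forbidden = frozenset(forbidden_positions or ())
    if strands is None:
        strands = ("+", "-") if both_strands else ("+",)
    candidates: list[tuple[int, int, int, str, tuple[int, ...]]] = []
    for strand in strands:
        for n_mm, start, st, mmpos in _scan_strand(
            read.sequence, reference, strand, max_mm, forbidden
        ):
            candidates.append((n_mm, start, 0 if st == "+" else 1, st, mmpos))
    if not candidates:
        return None
    n_mm, start, _, strand, mmpos = min(candidates, key=lambda c: c[:3])
    return AlignedRead(
        read_id=read.read_id,
        reference_id=reference_id,
        strand=strand,
        start=start,
        end=start + len(read.sequence),
        mismatch_positions=mmpos,
    )


def align_reads(
    reads: list[Read],
    references: dict[str, str],
    max_mm: int = 0,
    forbidden_positions: frozenset[int] | None = None,
    both_strands: bool = True,
    strands: tuple[str, ...] | None = None,
) -> tuple[list[AlignedRead], list[Read]]:
    """Align each read to its best reference; returns (aligned, unaligned).

    Across references the placement with fewest mismatches wins; ties break
    by reference id order.  References are expected to be built so that
    reads map uniquely; residual ties are resolved deterministically.
    """
    aligned: list[AlignedRead] = []
    unaligned: list[Read] = []
    ref_ids = sorted(references)
    for read in reads:
        best: AlignedRead | None = None
        for rid in ref_ids:
            hit = align_hamming(
                read,
                references[rid],
                reference_id=rid,
                max_mm=max_mm,
                forbidden_positions=forbidden_positions,
                both_strands=both_strands,
                strands=strands,
            )
            if hit is not None and (best is None or hit.n_mismatch < best.n_mismatch):
                best = hit
        if best is None:
            unaligned.append(read)
        else:
            aligned.append(best)
    return aligned, unaligned
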