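"""Library-level statistics: length distributions, normalizations, annotation,
5'-end sharing classes, PCC x 100, nucleotide composition and signed coverage.

Normalization follows two conventions used for small-RNA libraries:
``rpm`` (reads per million mapped reads) and ``per_normalizer_length``
(counts divided by the number of reads of a fixed normalizer length,
default 23 nt, i.e. scaled to the contaminating miRNA population that is
unaffected by piRNA-pathway genotype).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .readproc import AlignedRead

__all__ = [
    "LibraryCounts",
    "length_distribution",
    "modal_length",
    "normalize",
    "annotate_reads",
    "compare_features",
    "build_five_prime_groups",
    "classify_sharing",
    "pcc100",
    "nucleotide_bias",
    "coverage_consensus",
]

SHARING_CLASSES = (
    "MILI_specific",
    "MIWI_specific",
    "MILI_and_MIWI",
    "MVH_specific",
    "unclassified",
)


@dataclass
class LibraryCounts:
    """Per-library bookkeeping used by the normalizers."""

    library_id: str
    genotype: str = ""
    ip_target: str = ""
    length_counts: dict[int, int] = field(default_factory=dict)
    feature_counts: dict[str, float] = field(default_factory=dict)
    total_mapped: int = 0
    normalizer_length: int = 23

    @property
    def normalizer_count(self) -> int:
        return int(self.length_counts.get(self.normalizer_length, 0))


def length_distribution(lengths) -> pd.DataFrame:
    """Histogram over observed read lengths with fractions.

    Returns a DataFrame indexed by length with columns ``count``/``fraction``.
    """
    s = pd.Series(list(lengths), dtype=int)
    counts = s.value_counts().sort_index()
    df = pd.DataFrame({"count": counts})
    df["fraction"] = df["count"] / df["count"].sum() if len(df) else np.nan
    df.index.name = "length"
    return df


def modal_length(lengths) -> int | None:
    """Modal length; ties break toward the smaller length."""
    df = length_distribution(lengths)
    if df.empty:
        return None
    return int(df["count"].idxmax())  # idxmax returns the first (smallest) index


def normalize(counts, library: LibraryCounts, mode: str = "rpm"):
    """Scale counts to rpm or to the normalizer-length read count."""
    arr = pd.Series(counts, dtype=float) if not np.isscalar(counts) else float(counts)
    if mode == "rpm":
        if library.total_mapped <= 0:
            raise ValueError("total_mapped must be positive for rpm")
        return arr * 1e6 / library.total_mapped
    if mode == "per_normalizer_length":
        nc = library.normalizer_count
        if nc <= 0:
            raise ValueError(
                f"no reads of normalizer length {library.normalizer_length} nt; "
                "use mode='rpm' instead"
            )
        return arr / nc
    raise ValueError(f"unknown normalization mode {mode!r}")


def annotate_reads(
    reads: list[AlignedRead],
    annotations: pd.DataFrame,
    min_overlap_frac: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each read the highest-priority overlapping annotation class.

    ``annotations`` columns: reference_id, start, end, strand, label,
    priority (smaller = higher priority); intervals are half-open.  A read
    must overlap an interval over at least ``min_overlap_frac`` of its own
    length; orientation is sense when read and feature strands agree.
    Non-overlapping reads are ``non_annotated``.  Returns (per-read
    assignments, summary counts by label and orientation); the summary
    conserves the total read count.
    """
    ann = annotations.sort_values(["priority", "start"]).reset_index(drop=True)
    rows = []
    for read in reads:
        label, orient = "non_annotated", "."
        need = min_overlap_frac * read.length
        for rec in ann.itertuples():
            if rec.reference_id != read.reference_id:
                continue
            ov = min(read.end, rec.end) - max(read.start, rec.start)
            if ov >= need and ov > 0:
                label = rec.label
                orient = "sense" if read.strand == rec.strand else "antisense"
                break
        rows.append((read.read_id, label, orient))
    per_read = pd.DataFrame(rows, columns=["read_id", "label", "orientation"])
    summary = (
        per_read.groupby(["label", "orientation"]).size().rename("count").reset_index()
    )
    return per_read, summary


def compare_features(
    rpm_a: pd.Series,
    rpm_b: pd.Series,
    min_rpm: float = 10.0,
) -> tuple[pd.DataFrame, float]:
    """Per-feature B/A ratios for features with >= ``min_rpm`` in either library.

    Features absent from one library count as 0 rpm.  Ratios with a zero
    denominator are flagged infinite and excluded from the median.  Returns
    (table, median ratio across kept finite-ratio features).
    """
    feats = sorted(set(rpm_a.index) | set(rpm_b.index))
    a = rpm_a.reindex(feats).fillna(0.0)
    b = rpm_b.reindex(feats).fillna(0.0)
    keep = (a >= min_rpm) | (b >= min_rpm)
    a, b = a[keep], b[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = b / a
    table = pd.DataFrame(
        {
            "rpm_a": a,
            "rpm_b": b,
            "ratio": ratio,
            "infinite": ~np.isfinite(ratio),
        }
    )
    finite = ratio[np.isfinite(ratio)]
    median = float(finite.median()) if len(finite) else float("nan")
    return table, median


def build_five_prime_groups(
    alignments_by_library: dict[str, list[AlignedRead]],
    rpm: bool = True,
) -> pd.DataFrame:
    """Group reads sharing (reference, strand, 5' coordinate) across libraries.

    Returns a DataFrame indexed by that key with one abundance column per
    library (rpm of the library's aligned reads by default, raw counts
    otherwise).
    """
    cols = {}
    for lib, reads in alignments_by_library.items():
        w: dict[tuple, float] = {}
        for read in reads:
            pos = read.start if read.strand == "+" else read.end - 1
            key = (read.reference_id, read.strand, pos)
            w[key] = w.get(key, 0.0) + 1.0
        s = pd.Series(w, dtype=float)
        if rpm and len(reads):
            s = s * 1e6 / len(reads)
        cols[lib] = s
    df = pd.DataFrame(cols).fillna(0.0)
    df.index.set_names(["reference_id", "strand", "position"], inplace=True)
    return df


def classify_sharing(
    groups: pd.DataFrame,
    mili_col: str = "MILI",
    miwi_col: str = "MIWI",
    mvh_col: str = "MVH",
    min_rpm: float = 0.25,
    fold: float = 3.0,
) -> pd.Series:
    """Sort 5'-end groups by preferential association with MILI/MIWI/MVH.

    Criteria applied in order: MILI-specific (>= ``min_rpm`` in MILI and
    >= ``fold`` x more abundant than in MIWI); MIWI-specific (symmetric);
    MILI-and-MIWI (>= ``min_rpm`` in both, difference < ``fold`` x);
    MVH-specific (>= ``min_rpm`` in MVH and in none of the above);
    everything else unclassified.
    """
    for col in (mili_col, miwi_col, mvh_col):
        if col not in groups.columns:
            raise ValueError(f"missing library column {col!r}")
    mili = groups[mili_col]
    miwi = groups[miwi_col]
    mvh = groups[mvh_col]
    mili_sp = (mili >= min_rpm) & (mili >= fold * miwi)
    miwi_sp = ~mili_sp & (miwi >= min_rpm) & (miwi >= fold * mili)
    both = ~mili_sp & ~miwi_sp & (mili >= min_rpm) & (miwi >= min_rpm)
    mvh_sp = ~mili_sp & ~miwi_sp & ~both & (mvh >= min_rpm)
    out = pd.Series("unclassified", index=groups.index, name="sharing_class")
    out[mvh_sp] = "MVH_specific"
    out[both] = "MILI_and_MIWI"
    out[miwi_sp] = "MIWI_specific"
    out[mili_sp] = "MILI_specific"
    return out


def pcc100(
    groups: pd.DataFrame,
    lib_a: str,
    lib_b: str,
    presence_threshold: float = 0.25,
) -> float:
    """Pearson correlation x 100 of two libraries' 5'-end abundances.

    Positions enter when either library reaches ``presence_threshold`` rpm.
    """
    a = groups[lib_a]
    b = groups[lib_b]
    mask = (a >= presence_threshold) | (b >= presence_threshold)
    x, y = a[mask], b[mask]
    if len(x) < 2:
        raise ValueError("fewer than 2 positions pass the presence threshold")
    if float(np.std(x)) == 0.0 or float(np.std(y)) == 0.0:
        warnings.warn("zero variance: PCC undefined")
        return float("nan")
    r = stats.pearsonr(x, y).statistic
    return float(r) * 100.0


def nucleotide_bias(sequences) -> dict:
    """Base composition at read positions 1 and 10 (1-based, 5'->3').

    Reads shorter than 10 nt are excluded from the position-10 tally and
    counted in ``n_short``.  Reports the U1 fraction (T at position 1) and
    the A10 fraction alongside full 4-vectors.
    """
    bases = "ACGT"
    c1 = {b: 0 for b in bases}
    c10 = {b: 0 for b in bases}
    n1 = n10 = n_short = 0
    for seq in sequences:
        if seq[0] in c1:
            c1[seq[0]] += 1
            n1 += 1
        if len(seq) >= 10:
            if seq[9] in c10:
                c10[seq[9]] += 1
                n10 += 1
        else:
            n_short += 1
    frac1 = {b: (c1[b] / n1 if n1 else float("nan")) for b in bases}
    frac10 = {b: (c10[b] / n10 if n10 else float("nan")) for b in bases}
    return {
        "pos1": frac1,
        "pos10": frac10,
        "u1_fraction": frac1["T"],
        "a10_fraction": frac10["A"],
        "n_short": n_short,
    }


def coverage_consensus(
    reads: list[AlignedRead],
    reference_length: int,
    weight: float | dict[str, float] = 1.0,
    five_prime_only: bool = False,
) -> np.ndarray:
    """Signed per-position coverage on a consensus sequence.

    Sense reads add positive, antisense reads negative weight over their
    span (or only at their 5'-end position when ``five_prime_only``).
    ``weight`` may be a constant or a per-read_id mapping of normalized
    counts.
    """
    cov = np.zeros(reference_length, dtype=float)
    for read in reads:
        w = weight if np.isscalar(weight) else weight.get(read.read_id, 0.0)
        sign = 1.0 if read.strand == "+" else -1.0
        if five_prime_only:
            pos = read.start if read.strand == "+" else read.end - 1
            if 0 <= pos < reference_length:
                cov[pos] += sign * w
        else:
            lo = max(read.start, 0)
            hi = min(read.end, reference_length)
            if hi > lo:
                cov[lo:hi] += sign * w
    return cov
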