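"""Synthetic small-RNA libraries emulating PIWI slicing-triggered piRNA biogenesis.

The generator builds an artificial piRNA precursor (a reporter transcript
carrying perfectly complementary binding sites for a set of guide piRNAs),
simulates slicer cleavage at each site and the downstream processing events,
and emits sequencing-ready FASTQ records with per-read ground-truth labels.

Cleavage geometry
-----------------
A guide piRNA of length ``guide_length`` binds the precursor antisense, with
its 5'-most nucleotide paired to precursor coordinate ``q`` (0-based).  The
slicer cuts the target between the positions paired to guide nucleotides 10
and 11, i.e. 10 nt downstream of the guide 5' end.  In half-open coordinates
the downstream cleavage fragment therefore starts at

    cleavage_coord = q - cleavage_offset + 1   (= q - 9 at defaults)

Each cleavage event produces (i) with probability ``conversion_efficiency``
a secondary piRNA starting at ``cleavage_coord`` followed by a run of phased
("trail"/"inchworm") piRNAs, or (ii) otherwise an unprocessed pre-piRNA
intermediate; and independently (iii) a short by-product fragment whose 3'
end lies exactly at the cleavage site and whose length is the slicer
footprint ``guide_length - cleavage_offset`` (16 nt at defaults).  A
configurable fraction of unrelated 21-23-nt contaminant reads (miRNA-like,
not mapping to the reporter) completes the library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimParams",
    "TargetSite",
    "ReporterSpec",
    "Fragment",
    "TruthRecord",
    "revcomp",
    "build_reporter",
    "simulate_biogenesis",
    "simulate_library",
    "simulate_feature_counts",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (U is written as T throughout)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _default_secondary_length_probs() -> dict[int, float]:
    # 24-30 nt with a clear mode at 26, matching the MILI piRNA size profile.
    return {24: 0.05, 25: 0.10, 26: 0.40, 27: 0.20, 28: 0.12, 29: 0.08, 30: 0.05}


def _default_mirna_length_probs() -> dict[int, float]:
    # contaminating miRNA peak at 22 nt; 23-mers present so the 23-nt
    # normalizer count is never zero.
    return {21: 0.20, 22: 0.60, 23: 0.20}


def _default_barcode_map() -> dict[str, str]:
    return {"control": "ATCACG", "mutant": "CGATGT"}


@dataclass(frozen=True)
class SimParams:
    """Parameters of the reporter simulation.

    All lengths are in nucleotides; all probabilities in [0, 1].
    """

    n_sites: int = 35
    guide_length: int = 26
    cleavage_offset: int = 10
    secondary_length_probs: dict[int, float] = field(
        default_factory=_default_secondary_length_probs
    )
    trail_mean: float = 2.0          # mean of the geometric trail-count law
    trail_max: int = 4               # hard cap on trails per event
    max_read_length: int = 51        # maximum sequencing length
    mirna_length_probs: dict[int, float] = field(
        default_factory=_default_mirna_length_probs
    )
    mirna_fraction: float = 0.15
    conversion_efficiency: float = 0.8   # genotype knob; mutant-like ~0.15
    u1_bias: float = 0.8             # P(trail 5' nucleotide is U)
    adapter_seq: str = "AGATCGGAAGAGCACACGTCT"
    barcode_map: dict[str, str] = field(default_factory=_default_barcode_map)
    spacer_length: int = 300
    intermediate_length: int = 80    # true length of the unprocessed fragment
    depth: int = 30000               # reads per library
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0 < self.cleavage_offset < self.guide_length:
            raise ValueError("cleavage_offset must be in (0, guide_length)")
        for name in ("mirna_fraction", "conversion_efficiency", "u1_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(not 24 <= k <= 30 for k in self.secondary_length_probs):
            raise ValueError("secondary piRNA lengths must lie within [24, 30]")
        if self.spacer_length < self.max_read_length:
            raise ValueError("spacer_length must be >= max_read_length")
        if len(set(self.barcode_map.values())) != len(self.barcode_map):
            raise ValueError("barcodes must be unique")

    @property
    def byproduct_length(self) -> int:
        """Slicer footprint on the upstream fragment: guide_length - cleavage_offset."""
        return self.guide_length - self.cleavage_offset

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TargetSite:
    """Geometry of one guide-piRNA binding site on the precursor.

    ``q`` is the 0-based precursor coordinate paired with the guide's 5'
    (first) nucleotide; the guide covers [q - guide_length + 1, q].
    ``cleavage_coord`` is the first nucleotide of the downstream cleavage
    fragment and ``origin`` (= q + 1) is the zero of the signed distance
    axis: distance 0 is the position immediately downstream of the guide
    5' end, distance -10 is the cleavage site.
    """

    site_id: str
    guide_seq: str
    q: int
    cleavage_coord: int
    origin: int

    @classmethod
    def from_q(cls, site_id: str, guide_seq: str, q: int, cleavage_offset: int) -> "TargetSite":
        return cls(
            site_id=site_id,
            guide_seq=guide_seq,
            q=q,
            cleavage_coord=q - cleavage_offset + 1,
            origin=q + 1,
        )

    @property
    def start(self) -> int:
        """Half-open start of the guide-complementary region."""
        return self.q - len(self.guide_seq) + 1

    @property
    def end(self) -> int:
        return self.q + 1


@dataclass(frozen=True)
class ReporterSpec:
    """A precursor sequence plus its target-site geometry."""

    name: str
    sequence: str
    sites: tuple[TargetSite, ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for site in sorted(self.sites, key=lambda s: s.start):
            if site.start < 0 or site.end > len(self.sequence):
                raise ValueError(f"{site.site_id} outside precursor bounds")
            if site.start < prev_end:
                raise ValueError(f"{site.site_id} overlaps a previous site")
            prev_end = site.end
            region = self.sequence[site.start:site.end]
            if revcomp(site.guide_seq) != region:
                raise ValueError(
                    f"{site.site_id}: precursor region is not the reverse "
                    "complement of the guide"
                )


@dataclass(frozen=True)
class Fragment:
    """A raw (pre-sequencing) RNA fragment with its ground truth."""

    read_id: str
    sequence: str
    true_class: str            # secondary | trail | byproduct16 | intermediate | mirna
    site_id: str | None
    start: int | None          # reporter coordinates, half-open; None for miRNA
    end: int | None
    untruncated_length: int
    truncated: bool = False


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    true_class: str
    site_id: str | None
    untruncated_length: int
    truncated: bool = False


def truth_of(fragment: Fragment) -> TruthRecord:
    return TruthRecord(
        read_id=fragment.read_id,
        true_class=fragment.true_class,
        site_id=fragment.site_id,
        untruncated_length=fragment.untruncated_length,
        truncated=fragment.truncated,
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _sample_guides(params: SimParams, rng: np.random.Generator) -> list[str]:
    guides: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(guides) < params.n_sites:
        g = "T" + _random_seq(rng, params.guide_length - 1)  # enforce 5'-U
        attempts += 1
        if g in seen:
            if attempts > 100 * params.n_sites:
                raise RuntimeError("could not sample unique guide sequences")
            continue
        seen.add(g)
        guides.append(g)
    return guides


def build_reporter(
    params: SimParams,
    guides: list[str] | None = None,
    rng: np.random.Generator | None = None,
    name: str = "reporter",
    max_retries: int = 50,
) -> ReporterSpec:
    """Assemble a precursor embedding each guide's reverse complement once.

    Sites are separated by ``spacer_length`` random spacer nucleotides (>=
    max_read_length, so reads from neighbouring sites cannot be confused) and
    flanked by a leader/trailer of the same length.  If a guide (or its
    reverse complement) happens to recur elsewhere, spacers are re-sampled up
    to ``max_retries`` times.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if guides is None:
        guides = _sample_guides(params, rng)
    else:
        if len(guides) != params.n_sites:
            raise ValueError("number of guides must equal n_sites")
        if any(len(g) != params.guide_length for g in guides):
            raise ValueError("every guide must have length guide_length")
        if len(set(guides)) != len(guides):
            raise ValueError("duplicate guide sequence")

    for _ in range(max_retries):
        parts: list[str] = [_random_seq(rng, params.spacer_length)]
        qs: list[int] = []
        pos = params.spacer_length
        for g in guides:
            site_seq = revcomp(g)
            parts.append(site_seq)
            qs.append(pos + params.guide_length - 1)
            pos += params.guide_length
            parts.append(_random_seq(rng, params.spacer_length))
            pos += params.spacer_length
        sequence = "".join(parts)
        ok = all(
            sequence.count(revcomp(g)) == 1 and g not in sequence for g in guides
        )
        if ok:
            sites = tuple(
                TargetSite.from_q(f"site_{i + 1:02d}", g, q, params.cleavage_offset)
                for i, (g, q) in enumerate(zip(guides, qs))
            )
            return ReporterSpec(name=name, sequence=sequence, sites=sites)
    raise RuntimeError("could not assemble a reporter with unique sites")


def _choose_length(
    seq: str,
    start: int,
    params: SimParams,
    rng: np.random.Generator,
    bias_next_u: bool,
) -> int:
    """Pick a piRNA length; optionally prefer 3' ends placing the next 5' on U."""
    lengths = np.array(sorted(params.secondary_length_probs))
    probs = np.array([params.secondary_length_probs[int(k)] for k in lengths], float)
    probs /= probs.sum()
    if bias_next_u and rng.random() < params.u1_bias:
        ok = np.array(
            [start + L < len(seq) and seq[start + L] == "T" for L in lengths]
        )
        if ok.any():
            p = probs * ok
            return int(rng.choice(lengths, p=p / p.sum()))
    return int(rng.choice(lengths, p=probs))


def _n_trails(params: SimParams, rng: np.random.Generator) -> int:
    # geometric on {0,1,2,...} with the configured mean, capped at trail_max
    p = 1.0 / (params.trail_mean + 1.0)
    return min(int(rng.geometric(p)) - 1, params.trail_max)


def simulate_biogenesis(
    reporter: ReporterSpec,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[Fragment], list[TruthRecord]]:
    """Sample cleavage events and emit labeled RNA fragments.

    The number of events is chosen so that the expected total read count
    (reporter products plus contaminants) approximates ``params.depth``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    seq = reporter.sequence
    ce = params.conversion_efficiency
    # expected fragments per event: secondary branch, intermediate branch,
    # plus the unconditional by-product
    exp_trails = min(params.trail_mean, params.trail_max)  # slight overcount, fine
    e_frags = ce * (1.0 + exp_trails) + (1.0 - ce) * 1.0 + 1.0
    n_mirna = int(round(params.depth * params.mirna_fraction))
    n_events = max(1, int(round((params.depth - n_mirna) / e_frags)))

    fragments: list[Fragment] = []
    serial = 0

    def emit(true_class: str, site_id: str | None, start: int | None,
             end: int | None, untrunc: int, truncated: bool = False,
             sequence: str | None = None) -> None:
        nonlocal serial
        serial += 1
        if sequence is None:
            sequence = seq[start:end]
        fragments.append(
            Fragment(
                read_id=f"sim{serial:07d}",
                sequence=sequence,
                true_class=true_class,
                site_id=site_id,
                start=start,
                end=end,
                untruncated_length=untrunc,
                truncated=truncated,
            )
        )

    site_idx = rng.integers(0, len(reporter.sites), size=n_events)
    for ev in range(n_events):
        site = reporter.sites[int(site_idx[ev])]
        cc = site.cleavage_coord
        # by-product: upstream fragment trimmed to the slicer footprint,
        # 3' end exactly at the cleavage site
        bp = params.byproduct_length
        emit("byproduct16", site.site_id, cc - bp, cc, bp)
        if rng.random() < ce:
            k = _n_trails(params, rng)
            start = cc
            for j in range(k + 1):  # secondary followed by k trails
                L = _choose_length(seq, start, params, rng, bias_next_u=(j < k))
                end = start + L
                truncated = end > len(seq)
                end = min(end, len(seq))
                if end - start < 1:
                    break
                emit(
                    "secondary" if j == 0 else "trail",
                    site.site_id, start, end, L, truncated,
                )
                if truncated:
                    break
                start = end
        else:
            L = params.intermediate_length
            end = cc + L
            truncated = end > len(seq)
            end = min(end, len(seq))
            emit("intermediate", site.site_id, cc, end, L, truncated)

    # contaminant miRNA-like reads: random sequences absent from the reporter
    lengths = np.array(sorted(params.mirna_length_probs))
    probs = np.array([params.mirna_length_probs[int(k)] for k in lengths], float)
    probs /= probs.sum()
    rc_seq = revcomp(seq)
    for _ in range(n_mirna):
        L = int(rng.choice(lengths, p=probs))
        for _attempt in range(10):
            s = _random_seq(rng, L)
            if s not in seq and s not in rc_seq:
                break
        emit("mirna", None, None, None, L, sequence=s)

    truths = [truth_of(f) for f in fragments]
    return fragments, truths


def simulate_library(
    fragments: list[Fragment],
    params: SimParams,
    library_tag: str,
) -> list[tuple[str, str, str]]:
    """Turn fragments into FASTQ-ready records for one barcoded library.

    Each record is ``insert + barcode + adapter`` truncated to
    ``max_read_length`` (the maximum sequencing length), with a constant
    quality string.  Returns (read_id, sequence, quality) tuples; read ids
    are ``<tag>.<fragment read_id>`` and trace back to TruthRecords.
    """
    if library_tag not in params.barcode_map:
        raise KeyError(f"unknown library tag {library_tag!r}")
    if not fragments:
        warnings.warn("empty fragment list: writing an empty library")
    barcode = params.barcode_map[library_tag]
    tail = barcode + params.adapter_seq
    records = []
    for frag in fragments:
        seq = (frag.sequence + tail)[: params.max_read_length]
        records.append((f"{library_tag}.{frag.read_id}", seq, "I" * len(seq)))
    return records


def simulate_feature_counts(
    n_features: int = 200,
    enrichment: float = 5.0,
    base_mean_log10: float = 1.5,
    base_sigma_log10: float = 0.6,
    noise_sigma: float = 0.15,
    seed: int = 0,
):
    """Per-feature rpm tables for a control/mutant pair with a known fold change.

    Emulates the genic piRNA comparison: mutant abundances are the control
    abundances scaled by ``enrichment`` with multiplicative log-normal noise.
    Returns a pandas DataFrame indexed by feature with columns
    ``control``/``mutant`` in rpm.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    control = 10 ** rng.normal(base_mean_log10, base_sigma_log10, size=n_features)
    noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=n_features)
    mutant = control * enrichment * noise
    idx = [f"gene_{i + 1:04d}" for i in range(n_features)]
    return pd.DataFrame({"control": control, "mutant": mutant}, index=idx)
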