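"""End-distance profiles around slicer target sites and product classification.

Distances are signed offsets from a site's ``origin`` (the position
immediately downstream of the targeting guide's 5' end):

    d5 = read.start - origin        d3 = read.end - origin

with half-open read coordinates, so ``d3`` is measured one past the last
nucleotide.  Under this single convention the secondary piRNA 5' end and the
by-product 3' end both register at distance -10 (the cleavage site), and
distance 0 means a 5' end flush with the guide's 5' end + 1.

Product classes (sense reads only, precedence top to bottom):

    secondary_piRNA   d5 == -10 and 24 <= length <= 30
    intermediate      d5 == -10 and length == max_read_length
    byproduct_16mer   d3 == -10 and length == byproduct_length
    trail_piRNA       24 <= length <= 30 and d5 in the downstream window
    other             anything else
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .readproc import AlignedRead
from .simulate import TargetSite

__all__ = [
    "ProductCall",
    "ClassifyParams",
    "end_distances",
    "assign_site",
    "profile_distances",
    "classify_product",
    "classify_all",
    "relative_ratios",
]

CLEAVAGE_D5 = -10  # distance of a slicer-generated 5' end from the origin


@dataclass(frozen=True)
class ClassifyParams:
    pirna_min: int = 24
    pirna_max: int = 30
    max_read_length: int = 51
    byproduct_length: int = 16
    trail_window: tuple[int, int] = (-10, 150)  # half-open low, inclusive high


@dataclass(frozen=True)
class ProductCall:
    read_id: str
    call: str
    site_id: str
    d5: int
    d3: int
    length: int


def end_distances(read: AlignedRead, site: TargetSite) -> tuple[int, int]:
    """Signed 5'/3' end distances of a sense read from a site origin."""
    return read.start - site.origin, read.end - site.origin


def assign_site(read: AlignedRead, sites: list[TargetSite]) -> TargetSite:
    """Nearest site by |d5|; an equidistant read goes to the upstream site."""
    return min(sites, key=lambda s: (abs(read.start - s.origin), s.origin))


def profile_distances(
    reads: list[AlignedRead],
    sites: list[TargetSite],
    length_range: tuple[int, int] | None = (24, 30),
    rpm_total: int | None = None,
) -> pd.DataFrame:
    """Histograms of 5' and 3' end distances aggregated across sites.

    Restricted to sense-strand reads whose length lies in ``length_range``
    (inclusive; None keeps all lengths).  If ``rpm_total`` is given, counts
    are scaled to reads per million of that total.  Returns a DataFrame
    indexed by distance with columns ``count_5p``/``count_3p``.
    """
    c5: dict[int, float] = {}
    c3: dict[int, float] = {}
    for read in reads:
        if read.strand != "+":
            continue
        if length_range is not None and not (
            length_range[0] <= read.length <= length_range[1]
        ):
            continue
        site = assign_site(read, sites)
        d5, d3 = end_distances(read, site)
        c5[d5] = c5.get(d5, 0) + 1
        c3[d3] = c3.get(d3, 0) + 1
    idx = sorted(set(c5) | set(c3))
    df = pd.DataFrame(
        {
            "count_5p": [c5.get(d, 0) for d in idx],
            "count_3p": [c3.get(d, 0) for d in idx],
        },
        index=pd.Index(idx, name="distance"),
        dtype=float,
    )
    if rpm_total:
        df *= 1e6 / rpm_total
    return df


def classify_product(
    read: AlignedRead,
    site: TargetSite,
    params: ClassifyParams = ClassifyParams(),
) -> ProductCall:
    """Classify one sense aligned read relative to its target site."""
    d5, d3 = end_distances(read, site)
    L = read.length
    lo, hi = params.trail_window
    if read.strand != "+":
        call = "other"
    elif d5 == CLEAVAGE_D5 and params.pirna_min <= L <= params.pirna_max:
        call = "secondary_piRNA"
    elif d5 == CLEAVAGE_D5 and L == params.max_read_length:
        call = "intermediate"
    elif d3 == CLEAVAGE_D5 and L == params.byproduct_length:
        call = "byproduct_16mer"
    elif params.pirna_min <= L <= params.pirna_max and lo < d5 <= hi:
        call = "trail_piRNA"
    else:
        call = "other"
    return ProductCall(read.read_id, call, site.site_id, d5, d3, L)


def classify_all(
    reads: list[AlignedRead],
    sites: list[TargetSite],
    params: ClassifyParams = ClassifyParams(),
) -> pd.DataFrame:
    """ProductCalls for every aligned read, as a tidy DataFrame."""
    calls = [
        classify_product(r, assign_site(r, sites), params) for r in reads
    ]
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in calls],
            "call": [c.call for c in calls],
            "site_id": [c.site_id for c in calls],
            "d5": [c.d5 for c in calls],
            "d3": [c.d3 for c in calls],
            "length": [c.length for c in calls],
        }
    )


def relative_ratios(
    calls: pd.DataFrame, rpm_total: int | None = None
) -> dict[str, float]:
    """16-mer and intermediate abundance relative to piRNAs of the same library.

    piRNAs are secondary plus trail calls.  Ratios with a zero denominator
    are returned as NaN with a warning rather than raising.
    """
    n = calls["call"].value_counts()
    n_pirna = int(n.get("secondary_piRNA", 0) + n.get("trail_piRNA", 0))
    n_bp = int(n.get("byproduct_16mer", 0))
    n_int = int(n.get("intermediate", 0))
    if n_pirna == 0:
        warnings.warn("no piRNA calls: relative ratios undefined")
        r_bp = r_int = float("nan")
    else:
        r_bp = n_bp / n_pirna
        r_int = n_int / n_pirna
    out = {
        "n_piRNA": float(n_pirna),
        "n_byproduct": float(n_bp),
        "n_intermediate": float(n_int),
        "byproduct_per_piRNA": r_bp,
        "intermediate_per_piRNA": r_int,
    }
    if rpm_total:
        scale = 1e6 / rpm_total
        out.update(
            rpm_piRNA=n_pirna * scale,
            rpm_byproduct=n_bp * scale,
            rpm_intermediate=n_int * scale,
        )
    return out
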