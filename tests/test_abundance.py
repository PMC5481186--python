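"""Length distributions, normalizations, annotation, sharing classes,
PCC x 100, nucleotide composition, signed coverage, feature comparison."""

import numpy as np
import pandas as pd
import pytest

from pirnapipe import (
    AlignedRead,
    LibraryCounts,
    build_five_prime_groups,
    classify_sharing,
    compare_features,
    coverage_consensus,
    length_distribution,
    modal_length,
    normalize,
    nucleotide_bias,
    pcc100,
    simulate_feature_counts,
)
from pirnapipe.abundance import annotate_reads


def read(start, end, strand="+", read_id="r", ref="ref"):
    return AlignedRead(read_id, ref, strand, start, end)


# ------------------------------------------------------------------ lengths
def test_length_distribution_and_mode(simulation):
    fragments, _ = simulation
    pirna = [f.end - f.start for f in fragments
             if f.true_class in ("secondary", "trail") and not f.truncated]
    assert modal_length(pirna) == 26
    mirna = [f.untruncated_length for f in fragments if f.true_class == "mirna"]
    assert modal_length(mirna) == 22
    df = length_distribution(pirna)
    assert df["count"].sum() == len(pirna)
    assert df["fraction"].sum() == pytest.approx(1.0)


def test_modal_length_tie_breaks_to_smaller():
    assert modal_length([24, 24, 27, 27, 30]) == 24
    assert modal_length([30]) == 30
    assert modal_length([]) is None


# -------------------------------------------------------------- normalize
def test_normalize_rpm_and_per_normalizer():
    lib = LibraryCounts("L", total_mapped=2_000_000, length_counts={23: 4})
    assert normalize(5, lib, "rpm") == pytest.approx(2.5)
    assert normalize(8, lib, "per_normalizer_length") == pytest.approx(2.0)
    assert normalize(0, lib, "rpm") == 0.0
    assert normalize(0, lib, "per_normalizer_length") == 0.0


def test_normalize_zero_normalizer_directs_to_rpm():
    lib = LibraryCounts("L", total_mapped=100, length_counts={})
    with pytest.raises(ValueError, match="rpm"):
        normalize(8, lib, "per_normalizer_length")


# --------------------------------------------------------------- annotate
ANN = pd.DataFrame(
    {
        "reference_id": ["ref", "ref", "ref"],
        "start": [0, 100, 300],
        "end": [80, 200, 400],
        "strand": ["+", "+", "-"],
        "label": ["gene_exon", "repeat:LINE", "cluster"],
        "priority": [1, 2, 3],
    }
)


def test_annotate_sense_antisense_and_priority():
    per_read, _ = annotate_reads(
        [
            read(10, 36, "+", "sense_exon"),
            read(110, 136, "-", "anti_line"),
            read(250, 276, "+", "nowhere"),
        ],
        ANN,
    )
    rec = per_read.set_index("read_id")
    assert tuple(rec.loc["sense_exon"]) == ("gene_exon", "sense")
    assert tuple(rec.loc["anti_line"]) == ("repeat:LINE", "antisense")
    assert tuple(rec.loc["nowhere"]) == ("non_annotated", ".")


def test_annotate_priority_order_on_overlap():
    ann = pd.DataFrame(
        {
            "reference_id": ["ref", "ref"],
            "start": [0, 0],
            "end": [100, 100],
            "strand": ["+", "+"],
            "label": ["repeat:LTR", "gene_exon"],
            "priority": [2, 1],
        }
    )
    per_read, _ = annotate_reads([read(10, 36)], ann)
    assert per_read["label"].iloc[0] == "gene_exon"


def test_annotation_conserves_read_count(rng):
    reads = [
        read(int(s), int(s) + 26, rng.choice(["+", "-"]), f"r{i}")
        for i, s in enumerate(rng.integers(0, 380, size=200))
    ]
    _, summary = annotate_reads(reads, ANN)
    assert summary["count"].sum() == len(reads)


# ------------------------------------------------------- compare_features
def test_compare_features_filter_and_ratio():
    a = pd.Series({"f1": 12.0, "f2": 5.0, "f3": 3.0})
    b = pd.Series({"f1": 3.0, "f2": 5.0, "f3": 12.0})
    table, median = compare_features(a, b, min_rpm=10)
    assert set(table.index) == {"f1", "f3"}  # f2 below 10 rpm in both
    assert table.loc["f3", "ratio"] == pytest.approx(4.0)
    assert table.loc["f1", "ratio"] == pytest.approx(0.25)


def test_compare_features_identical_libraries():
    a = pd.Series({"f1": 20.0, "f2": 15.0})
    _, median = compare_features(a, a, min_rpm=10)
    assert median == pytest.approx(1.0)


def test_compare_features_zero_denominator_flagged():
    a = pd.Series({"f1": 0.0})
    b = pd.Series({"f1": 20.0})
    table, _ = compare_features(a, b, min_rpm=10)
    assert bool(table.loc["f1", "infinite"])


def test_compare_features_recovers_simulated_enrichment():
    df = simulate_feature_counts(n_features=300, enrichment=5.0, seed=4)
    _, median = compare_features(df["control"], df["mutant"], min_rpm=10)
    assert median == pytest.approx(5.0, rel=0.10)


# ------------------------------------------------------- sharing classes
def groups_frame(rows):
    return pd.DataFrame(rows, columns=["MILI", "MIWI", "MVH"])


@pytest.mark.parametrize(
    "mili,miwi,mvh,expected",
    [
        (0.9, 0.2, 0.0, "MILI_specific"),     # >=0.25 and >=3x MIWI
        (0.2, 0.9, 0.0, "MIWI_specific"),
        (0.5, 0.5, 0.0, "MILI_and_MIWI"),     # both >=0.25, <3x apart
        (0.1, 0.1, 0.3, "MVH_specific"),
        (0.1, 0.1, 0.1, "unclassified"),
        (0.25, 0.0, 0.0, "MILI_specific"),    # threshold boundary
        (0.75, 0.25, 0.0, "MILI_specific"),   # exactly 3x
        (0.74, 0.25, 0.9, "MILI_and_MIWI"),   # just under 3x; both present
    ],
)
def test_classify_sharing_printed_criteria(mili, miwi, mvh, expected):
    out = classify_sharing(groups_frame([(mili, miwi, mvh)]))
    assert out.iloc[0] == expected


def test_classify_sharing_partitions_exhaustive_grid():
    """Every group gets exactly one class over an exhaustive small table."""
    vals = [0.0, 0.1, 0.25, 0.5, 0.76, 2.5]
    rows = [(a, b, c) for a in vals for b in vals for c in vals]
    df = groups_frame(rows)
    out = classify_sharing(df)
    assert len(out) == len(rows)
    assert out.isin(
        ["MILI_specific", "MIWI_specific", "MILI_and_MIWI", "MVH_specific",
         "unclassified"]
    ).all()
    # re-derive every row independently from the printed criteria
    for (a, b, c), got in zip(rows, out):
        if a >= 0.25 and a >= 3 * b:
            want = "MILI_specific"
        elif b >= 0.25 and b >= 3 * a:
            want = "MIWI_specific"
        elif a >= 0.25 and b >= 0.25:
            want = "MILI_and_MIWI"
        elif c >= 0.25:
            want = "MVH_specific"
        else:
            want = "unclassified"
        assert got == want


def test_classify_sharing_missing_library_errors():
    with pytest.raises(ValueError):
        classify_sharing(pd.DataFrame({"MILI": [1.0], "MIWI": [1.0]}))


# ------------------------------------------------------------------- PCC
def test_pcc100_identical_and_antiproportional():
    df = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [2.0, 4.0, 6.0],
                       "C": [3.0, 2.0, 1.0]})
    assert pcc100(df, "A", "B") == pytest.approx(100.0)
    assert pcc100(df, "A", "C") == pytest.approx(-100.0)


def test_pcc100_hand_computed_value():
    # r for (1,2,3) vs (2,4,7): cov=2.5/ (1 * sqrt(sum((x-13/3)^2)/2))
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([2.0, 4.0, 7.0])
    r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    df = pd.DataFrame({"A": x, "B": y})
    assert pcc100(df, "A", "B") == pytest.approx(100 * r)


def test_pcc100_symmetry_and_scale_invariance():
    df = pd.DataFrame({"A": [0.5, 1.0, 4.0, 2.0], "B": [1.0, 0.5, 3.0, 2.5]})
    assert pcc100(df, "A", "B") == pytest.approx(pcc100(df, "B", "A"))
    df2 = df.assign(A=df["A"] * 7.5)
    assert pcc100(df2, "A", "B") == pytest.approx(pcc100(df, "A", "B"))


def test_pcc100_threshold_and_degenerate_cases():
    df = pd.DataFrame({"A": [0.1, 0.1], "B": [0.1, 0.1]})
    with pytest.raises(ValueError):
        pcc100(df, "A", "B")  # nothing passes the presence threshold
    df2 = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0]})
    with pytest.warns(UserWarning):
        assert np.isnan(pcc100(df2, "A", "B"))  # zero variance


def test_build_five_prime_groups_keys_and_rpm():
    reads_by_lib = {
        "MILI": [read(10, 36, "+", "a"), read(10, 36, "+", "b"),
                 read(50, 76, "-", "c"), read(90, 116, "+", "d")],
        "MIWI": [read(10, 36, "+", "e")],
    }
    df = build_five_prime_groups(reads_by_lib, rpm=False)
    assert df.loc[("ref", "+", 10), "MILI"] == 2
    assert df.loc[("ref", "-", 75), "MILI"] == 1  # minus 5' end at end-1
    assert df.loc[("ref", "+", 10), "MIWI"] == 1
    assert df.loc[("ref", "+", 90), "MIWI"] == 0


# ------------------------------------------------------------ composition
def test_nucleotide_bias_examples():
    out = nucleotide_bias(["TACGTACGTA", "TTTTTTTTTT"])
    assert out["u1_fraction"] == 1.0
    assert out["pos10"]["A"] == 0.5
    short = nucleotide_bias(["TACGT"])
    assert short["n_short"] == 1 and np.isnan(short["pos10"]["A"])


def test_nucleotide_bias_uniform_reads_near_quarter(rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=26)) for _ in range(4000)]
    out = nucleotide_bias(seqs)
    se = np.sqrt(0.25 * 0.75 / 4000)
    for base in "ACGT":
        assert abs(out["pos1"][base] - 0.25) < 4 * se
        assert abs(out["pos10"][base] - 0.25) < 4 * se


def test_simulated_trail_reads_show_u1_bias(reporter, simulation):
    fragments, _ = simulation
    seqs = [f.sequence for f in fragments if f.true_class == "trail"]
    out = nucleotide_bias(seqs)
    assert out["u1_fraction"] > 0.5  # biased well above the 0.25 background


# -------------------------------------------------------------- coverage
def test_coverage_single_reads():
    cov = coverage_consensus([read(4, 12, "+")], 20)
    assert cov[3] == 0 and all(cov[4:12] == 1) and cov[12] == 0
    cov_anti = coverage_consensus([read(4, 12, "-")], 20)
    assert all(cov_anti[4:12] == -1)


def test_coverage_five_prime_only():
    cov = coverage_consensus([read(4, 12, "+"), read(4, 12, "-")], 20,
                             five_prime_only=True)
    assert cov[4] == 1 and cov[11] == -1 and cov.sum() == 0


def test_coverage_matches_per_read_accumulation(rng):
    reads = [
        read(int(s), int(s) + int(L), rng.choice(["+", "-"]), f"r{i}")
        for i, (s, L) in enumerate(
            zip(rng.integers(0, 150, 100), rng.integers(16, 52, 100))
        )
    ]
    cov = coverage_consensus(reads, 220)
    oracle = np.zeros(220)
    for r in reads:
        for p in range(r.start, min(r.end, 220)):
            oracle[p] += 1 if r.strand == "+" else -1
    assert np.allclose(cov, oracle)
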