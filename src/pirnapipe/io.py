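"""Reading and writing the standard file formats used by the pipeline.

FASTQ/FASTA go through Biopython; tables (sites BED, truth TSV, alignment
TSV, profiles) through pandas.  All coordinates in files follow the same
0-based half-open convention as the in-memory types.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .readproc import AlignedRead, Read
from .simulate import ReporterSpec, TruthRecord

ALIGNMENT_COLUMNS = [
    "read_id",
    "reference_id",
    "strand",
    "start",
    "end",
    "n_mismatch",
    "mismatch_positions",
]


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write (read_id, sequence, quality) tuples as 4-line Phred+33 FASTQ."""
    seqrecords = []
    for read_id, seq, qual in records:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        seqrecords.append(rec)
    SeqIO.write(seqrecords, str(path), "fastq")


def read_fastq(path: str | Path, library_tag: str | None = None) -> list[Read]:
    return [
        Read(rec.id, str(rec.seq).upper(), library_tag)
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()],
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_sites_bed(reporter: ReporterSpec, path: str | Path) -> None:
    """Guide-complementary regions as BED6 (strand '+', name = site_id).

    Columns 7-8 carry the cleavage coordinate and the distance origin so the
    geometry round-trips without the FASTA.
    """
    rows = [
        (
            reporter.name,
            site.start,
            site.end,
            site.site_id,
            0,
            "+",
            site.cleavage_coord,
            site.origin,
        )
        for site in reporter.sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_sites_bed(path: str | Path):
    """Recover TargetSites from a sites BED written by :func:`write_sites_bed`."""
    from .simulate import TargetSite

    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["ref", "start", "end", "site_id", "score", "strand", "cleavage", "origin"],
    )
    sites = []
    for rec in df.itertuples():
        q = int(rec.end) - 1
        sites.append(
            TargetSite(
                site_id=str(rec.site_id),
                guide_seq="N" * (int(rec.end) - int(rec.start)),
                q=q,
                cleavage_coord=int(rec.cleavage),
                origin=int(rec.origin),
            )
        )
    return sites


def write_truth(truths: list[TruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "read_id": [t.read_id for t in truths],
            "true_class": [t.true_class for t in truths],
            "site_id": [t.site_id if t.site_id else "." for t in truths],
            "untruncated_length": [t.untruncated_length for t in truths],
            "truncated": [int(t.truncated) for t in truths],
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_alignments(reads: list[AlignedRead], path: str | Path) -> None:
    pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "reference_id": [r.reference_id for r in reads],
            "strand": [r.strand for r in reads],
            "start": [r.start for r in reads],
            "end": [r.end for r in reads],
            "n_mismatch": [r.n_mismatch for r in reads],
            "mismatch_positions": [
                ",".join(map(str, r.mismatch_positions)) or "." for r in reads
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_alignments(path: str | Path) -> list[AlignedRead]:
    df = pd.read_csv(path, sep="\t", dtype={"mismatch_positions": str})
    out = []
    for rec in df.itertuples():
        mm = rec.mismatch_positions
        positions = (
            tuple(int(p) for p in mm.split(",")) if mm not in (".", "", None) else ()
        )
        out.append(
            AlignedRead(
                read_id=str(rec.read_id),
                reference_id=str(rec.reference_id),
                strand=str(rec.strand),
                start=int(rec.start),
                end=int(rec.end),
                mismatch_positions=positions,
            )
        )
    return out
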