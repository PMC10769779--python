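"""Readers and writers for the tabular and sequence inputs of the pipeline.

Formats: long-format TSV for per-sample relative abundances
(``sample_id  taxon_id  rel_abundance``), a sample-metadata TSV
(``sample_id  patient_id  visit  lichtiger``), and standard FASTA for 16S
sequences (parsed with Biopython).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VISITS = ("V1", "V2")
LICHTIGER_MAX = 21  # clinical activity index ranges 0 (inactive) to 21
ABUNDANCE_SUM_TOL = 1e-6

DNA_ALPHABET = set("ACGTN")


@dataclass
class AbundanceTable:
    """Per-sample taxon relative abundances, renormalized to sum exactly 1.

    ``data`` is a long-format frame with columns ``sample_id``, ``taxon_id``
    and ``rel_abundance``; one row per (sample, taxon) pair.
    """

    data: pd.DataFrame

    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))

    def sample_abundances(self, sample_id: str) -> dict[str, float]:
        sub = self.data[self.data["sample_id"] == sample_id]
        if sub.empty:
            raise KeyError(f"sample {sample_id!r} not in abundance table")
        return dict(zip(sub["taxon_id"], sub["rel_abundance"]))

    @classmethod
    def from_entries(
        cls, entries: list[tuple[str, str, float]], renormalize: bool = True
    ) -> "AbundanceTable":
        df = pd.DataFrame(entries, columns=["sample_id", "taxon_id", "rel_abundance"])
        return cls(_validate_abundances(df, renormalize=renormalize))


def _validate_abundances(df: pd.DataFrame, renormalize: bool = True) -> pd.DataFrame:
    if df.duplicated(["sample_id", "taxon_id"]).any():
        dup = df[df.duplicated(["sample_id", "taxon_id"])].iloc[0]
        raise ValueError(
            f"duplicated (sample, taxon) row: ({dup['sample_id']}, {dup['taxon_id']})"
        )
    if (df["rel_abundance"] < 0).any():
        bad = df[df["rel_abundance"] < 0].iloc[0]
        raise ValueError(
            f"negative abundance for ({bad['sample_id']}, {bad['taxon_id']})"
        )
    sums = df.groupby("sample_id")["rel_abundance"].sum()
    off = sums[(sums - 1.0).abs() > ABUNDANCE_SUM_TOL]
    if not off.empty:
        sid, total = off.index[0], off.iloc[0]
        raise ValueError(
            f"abundances of sample {sid!r} sum to {total:.8f}, expected 1"
        )
    if renormalize:
        df = df.copy()
        df["rel_abundance"] = df["rel_abundance"] / df.groupby("sample_id")[
            "rel_abundance"
        ].transform("sum")
    return df.reset_index(drop=True)


def read_abundances(path: str | Path) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "taxon_id": str})
    expected = ["sample_id", "taxon_id", "rel_abundance"]
    if list(df.columns) != expected:
        raise ValueError(
            f"abundance TSV {path} must have columns {expected}, got {list(df.columns)}"
        )
    return AbundanceTable(_validate_abundances(df))


def write_abundances(table: AbundanceTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    patient_id: str
    visit: str
    lichtiger: int

    def __post_init__(self):
        if self.visit not in VISITS:
            raise ValueError(f"visit must be one of {VISITS}, got {self.visit!r}")
        if not 0 <= self.lichtiger <= LICHTIGER_MAX:
            raise ValueError(
                f"lichtiger score {self.lichtiger} outside 0..{LICHTIGER_MAX}"
            )


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    expected = ["sample_id", "patient_id", "visit", "lichtiger"]
    if list(df.columns) != expected:
        raise ValueError(
            f"metadata TSV {path} must have columns {expected}, got {list(df.columns)}"
        )
    rows = [
        SampleMetadata(r.sample_id, r.patient_id, r.visit, int(r.lichtiger))
        for r in df.itertuples()
    ]
    seen: set[tuple[str, str]] = set()
    for m in rows:
        key = (m.patient_id, m.visit)
        if key in seen:
            raise ValueError(f"more than one sample for patient/visit {key}")
        seen.add(key)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return rows


def write_metadata(rows: list[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.sample_id, m.patient_id, m.visit, m.lichtiger) for m in rows],
        columns=["sample_id", "patient_id", "visit", "lichtiger"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)``; sequences uppercased.

    Rejects duplicate ids, empty sequences and symbols outside A/C/G/T/N.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
        extra = set(seq) - DNA_ALPHABET
        if extra:
            raise ValueError(
                f"record {rec.id!r} contains non-ACGTN symbols {sorted(extra)}"
            )
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=rec_id, description="") for rec_id, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
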