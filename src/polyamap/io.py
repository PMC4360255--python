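"""Reading and writing the standard formats the pipeline touches.

Transcript and genome sequences come in as FASTA (possibly RNA-spelled,
possibly gzipped); everything downstream works on an upper-case DNA alphabet
``{A, C, G, T, N}``.  The catalogued poly(A) sites are exchanged as a
tab-separated *site table* with one row per unique site and its 201-nt
region.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

REGION_LEN = 201

_VALID_INPUT = set("ACGTUNacgtun")
_DNA = set("ACGTN")

SITE_TABLE_COLUMNS = [
    "site_id",
    "chrom",
    "strand",
    "tailstart_coord",
    "region201",
    "n_source_mrnas",
]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty sequence, bad residues...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry normalized to the DNA alphabet.

    ``source_alphabet`` is ``"rna"`` when any U was seen in the raw record,
    else ``"dna"``.
    """

    id: str
    description: str
    residues: str
    source_alphabet: str = "dna"

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.residues)


@dataclass(frozen=True)
class SiteTableRow:
    """One unique poly(A) site with its 201-nt region and genome locus."""

    site_id: str
    chrom: str
    strand: str
    tailstart_coord: int
    region201: str
    n_source_mrnas: int

    def __post_init__(self) -> None:
        if len(self.region201) != REGION_LEN:
            raise ValueError(
                f"region201 must be {REGION_LEN} nt, got {len(self.region201)}"
            )
        if self.n_source_mrnas < 1:
            raise ValueError("n_source_mrnas must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def normalize_residues(residues: str) -> tuple[str, str]:
    """Uppercase, map U->T and report which alphabet the input used.

    Returns ``(dna_residues, source_alphabet)``.  Any residue outside
    ``{A,C,G,T,U,N}`` (case-insensitive) is rejected.
    """
    bad = set(residues) - _VALID_INPUT
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)!r}")
    upper = residues.upper()
    alphabet = "rna" if "U" in upper else "dna"
    return upper.replace("U", "T"), alphabet


def normalize_to_dna(record: SequenceRecord) -> SequenceRecord:
    """Return the record with residues normalized to ``{A,C,G,T,N}``.

    Idempotent: normalizing an already-DNA record is the identity (the
    rna flag, once set, is preserved).
    """
    residues, alphabet = normalize_residues(record.residues)
    if record.source_alphabet == "rna":
        alphabet = "rna"
    return replace(record, residues=residues, source_alphabet=alphabet)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a (possibly gzipped) multi-record FASTA into normalized records.

    Order is preserved.  Duplicate ids, empty sequences, and residues outside
    the DNA/RNA alphabet are hard errors naming the offending record index.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fasta")):
            if not rec.id:
                raise FastaParseError(f"record {i}: empty id")
            if rec.id in seen:
                raise FastaParseError(f"record {i}: duplicate id {rec.id!r}")
            seq = str(rec.seq)
            if not seq:
                raise FastaParseError(f"record {i} ({rec.id}): empty sequence")
            try:
                residues, alphabet = normalize_residues(seq)
            except ValueError as exc:
                raise FastaParseError(f"record {i} ({rec.id}): {exc}") from exc
            seen.add(rec.id)
            records.append(
                SequenceRecord(
                    id=rec.id,
                    description=rec.description,
                    residues=residues,
                    source_alphabet=alphabet,
                )
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as handle:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            handle.write(f">{header}\n")
            for start in range(0, len(rec.residues), width):
                handle.write(rec.residues[start : start + width] + "\n")


def write_site_table(rows: Iterable[SiteTableRow], path: str | Path) -> None:
    """Serialize site rows as TSV with the fixed six-column header."""
    df = pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "chrom": r.chrom,
                "strand": r.strand,
                "tailstart_coord": r.tailstart_coord,
                "region201": r.region201,
                "n_source_mrnas": r.n_source_mrnas,
            }
            for r in rows
        ],
        columns=SITE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[SiteTableRow]:
    """Read a site-table TSV back into validated rows.

    Round-trips with :func:`write_site_table`.  Invalid regions are reported
    with their 1-based data row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "site_id": str, "region201": str})
    missing = set(SITE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    rows: list[SiteTableRow] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            rows.append(
                SiteTableRow(
                    site_id=str(rec.site_id),
                    chrom=str(rec.chrom),
                    strand=str(rec.strand),
                    tailstart_coord=int(rec.tailstart_coord),
                    region201=str(rec.region201),
                    n_source_mrnas=int(rec.n_source_mrnas),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"site table row {i}: {exc}") from exc
    return rows
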