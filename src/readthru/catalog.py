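"""Transcript catalog: spliced mRNA records, region arithmetic, and the
in-frame extension region downstream of the canonical stop codon.

A record partitions its sequence into 5'-UTR / CDS / 3'-UTR where, by
convention, the stop codon is counted as part of the 3'-UTR (so ``cds_len``
covers sense codons only).  The extension region is the stretch of in-frame
codons between the canonical stop codon and the next in-frame stop codon;
ribosome footprint density over it, relative to the CDS, quantifies
readthrough.

Coordinates are 0-based half-open internally; user-facing tables are
1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import STOP_CODONS, normalize_rna

logger = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGUN")

REGIONS_COLUMNS = ["transcript_id", "utr5_len", "cds_len", "utr3_len"]


@dataclass(frozen=True)
class MrnaRecord:
    """One spliced transcript with region annotation.

    ``utr3_len`` includes the stop codon; ``cds_len`` excludes it.
    """

    transcript_id: str
    sequence: str  # RNA, 5'->3'
    utr5_len: int
    cds_len: int
    utr3_len: int

    @property
    def stop_offset(self) -> int:
        """0-based offset of the stop codon's first base."""
        return self.utr5_len + self.cds_len

    @property
    def stop_codon(self) -> str:
        return self.sequence[self.stop_offset:self.stop_offset + 3]

    @property
    def utr3_seq(self) -> str:
        """3'-UTR including the stop codon."""
        return self.sequence[self.stop_offset:]

    def validation_errors(self) -> list[str]:
        """All invariant violations, empty for a valid record."""
        errors = []
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            errors.append(f"invalid characters {sorted(bad)}")
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            errors.append("negative region length")
        if self.utr5_len + self.cds_len + self.utr3_len != len(self.sequence):
            errors.append("region lengths do not sum to sequence length")
        if self.cds_len % 3 != 0:
            errors.append("CDS not multiple of 3")
        if self.cds_len < 3:
            errors.append("CDS shorter than one codon")
        if self.utr3_len < 3:
            errors.append("3'-UTR shorter than the stop codon")
        if not errors and self.stop_codon not in STOP_CODONS:
            errors.append(f"codon at CDS end is {self.stop_codon!r}, not a stop codon")
        return errors

    @property
    def is_valid(self) -> bool:
        return not self.validation_errors()


@dataclass(frozen=True)
class ExtensionRegion:
    """In-frame region between the canonical stop and the next in-frame stop.

    ``start``/``end`` are 0-based half-open offsets into the transcript
    sequence.  The downstream stop codon itself is excluded.  When no
    in-frame stop exists, the region runs to the last complete in-frame
    codon boundary and ``has_downstream_stop`` is False.
    """

    start: int
    end: int
    has_downstream_stop: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def find_extension_region(record: MrnaRecord) -> ExtensionRegion:
    """Scan in-frame codons after the canonical stop until the next stop codon."""
    seq = record.sequence
    start = record.stop_offset + 3
    pos = start
    while pos + 3 <= len(seq):
        if seq[pos:pos + 3] in STOP_CODONS:
            return ExtensionRegion(start=start, end=pos, has_downstream_stop=True)
        pos += 3
    return ExtensionRegion(start=start, end=pos, has_downstream_stop=False)


def read_catalog(
    fasta_path: str | Path, regions_path: str | Path
) -> tuple[list[MrnaRecord], pd.DataFrame]:
    """Read sequences plus a region table; return valid records and exclusions.

    DNA input (T) is accepted and transcribed to U.  Records violating any
    invariant, or present in only one of the two inputs, are reported in the
    exclusion table (columns ``transcript_id``, ``reason``) rather than
    raised.  Malformed region rows (non-integer lengths) are fatal with the
    offending line number.
    """
    fasta_path, regions_path = Path(fasta_path), Path(regions_path)
    regions = pd.read_csv(regions_path, sep="\t", comment="#", dtype=str)
    missing = set(REGIONS_COLUMNS) - set(regions.columns)
    if missing:
        raise ValueError(f"{regions_path}: missing columns {sorted(missing)}")
    for col in ("utr5_len", "cds_len", "utr3_len"):
        parsed = pd.to_numeric(regions[col], errors="coerce")
        bad = parsed.isna() | (parsed != parsed.astype("Int64").astype("Float64"))
        if bad.any():
            line = int(bad.idxmax()) + 2  # header line + 1-based
            raise ValueError(f"{regions_path}: malformed {col} at line {line}")
        regions[col] = parsed.astype(int)
    if regions["transcript_id"].duplicated().any():
        dupes = regions.loc[regions["transcript_id"].duplicated(), "transcript_id"]
        raise ValueError(f"{regions_path}: duplicate transcript ids {sorted(set(dupes))}")
    region_map = regions.set_index("transcript_id")

    records: list[MrnaRecord] = []
    exclusions: list[tuple[str, str]] = []
    seen = set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        seen.add(entry.id)
        if entry.id not in region_map.index:
            exclusions.append((entry.id, "no region annotation"))
            continue
        row = region_map.loc[entry.id]
        record = MrnaRecord(
            transcript_id=entry.id,
            sequence=normalize_rna(str(entry.seq)),
            utr5_len=int(row["utr5_len"]),
            cds_len=int(row["cds_len"]),
            utr3_len=int(row["utr3_len"]),
        )
        errors = record.validation_errors()
        if errors:
            exclusions.extend((entry.id, reason) for reason in errors)
        else:
            records.append(record)
    for tid in region_map.index:
        if tid not in seen:
            exclusions.append((tid, "no sequence in FASTA"))

    excl = pd.DataFrame(exclusions, columns=["transcript_id", "reason"])
    if len(excl):
        logger.info(
            "read_catalog: %d records retained, %d excluded", len(records),
            excl["transcript_id"].nunique(),
        )
    return records, excl


def write_catalog(
    records: list[MrnaRecord], fasta_path: str | Path, regions_path: str | Path
) -> None:
    """Write records back to FASTA + region TSV (inverse of read_catalog)."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.transcript_id, description="")
        for r in records
    ]
    SeqIO.write(entries, str(fasta_path), "fasta")
    pd.DataFrame(
        [(r.transcript_id, r.utr5_len, r.cds_len, r.utr3_len) for r in records],
        columns=REGIONS_COLUMNS,
    ).to_csv(regions_path, sep="\t", index=False)
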