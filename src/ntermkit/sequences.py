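"""Proteome sequence store and positional-annotation tables.

This module owns the coordinate conventions used throughout the package:

* Residue indices are **1-based and inclusive**. Residue ``i`` of a protein is
  ``record.sequence[i - 1]``.
* A cleavage site is identified by its P1 residue index; the scissile bond is
  the bond **after** that residue, i.e. between residues ``p1`` and ``p1 + 1``
  (Schechter–Berger nomenclature: P1 precedes the cleaved bond, P1' follows it).
  A cleavage "between Asp93 and Ser94" therefore has ``p1_position == 93`` and
  the neo-N-terminal peptide starts at residue 94.

Sequences use the 20 canonical amino acids; the ambiguity/rare codes X, U, B
and Z are tolerated but never match any protease specificity residue or motif
position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Tolerated non-canonical codes (never matched by motifs or proteases).
TOLERATED_EXTRA = "XUBZ"

TOLERATED_ALPHABET = frozenset(AA20 + TOLERATED_EXTRA)

#: Feature types describing co/posttranslational processing of a precursor.
FEATURE_TYPES = frozenset(
    {"init_met", "signal_peptide", "transit_peptide", "propeptide", "chain"}
)


class ProteomeError(ValueError):
    """Raised for malformed proteome or annotation inputs."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry.

    Parameters
    ----------
    accession : str
        Unique identifier within the loaded proteome.
    sequence : str
        Uppercase residue string (canonical amino acids plus tolerated
        X/U/B/Z), length >= 1.
    entry_name, description : str, optional
        Parsed from UniProt-style ``db|ACC|NAME description`` headers.
    """

    accession: str
    sequence: str
    entry_name: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ProteomeError("empty accession")
        if not self.sequence:
            raise ProteomeError(f"{self.accession}: empty sequence")
        bad = sorted(set(self.sequence) - TOLERATED_ALPHABET)
        if bad:
            raise ProteomeError(
                f"{self.accession}: residues outside tolerated alphabet: {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at 1-based ``position``."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"{self.accession}: position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class ProcessingAnnotation:
    """A UniProt-style positional processing feature (1-based inclusive)."""

    accession: str
    feature_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ProteomeError(f"unknown feature_type {self.feature_type!r}")
        if not 1 <= self.start <= self.end:
            raise ProteomeError(
                f"{self.accession}: bad coordinates {self.start}..{self.end}"
            )
        if self.feature_type == "init_met" and not (self.start == self.end == 1):
            raise ProteomeError(
                f"{self.accession}: init_met must span exactly residue 1"
            )


@dataclass(frozen=True)
class KnownCleavageSite:
    """A previously reported cleavage site (database export row).

    ``p1_position`` follows the global convention: the cleaved bond lies
    between ``p1_position`` and ``p1_position + 1``.
    """

    accession: str
    p1_position: int
    source: str

    def __post_init__(self) -> None:
        if self.p1_position < 1:
            raise ProteomeError(f"{self.accession}: p1_position must be >= 1")


def _parse_header(record_id: str, description: str) -> tuple[str, str | None, str | None]:
    """Split a FASTA header into (accession, entry_name, free-text description).

    UniProt-style ``db|ACC|NAME desc`` headers yield ACC/NAME; anything else
    uses the first whitespace-delimited token as the accession.
    """
    parts = record_id.split("|")
    if len(parts) >= 3 and parts[1]:
        accession, entry_name = parts[1], parts[2]
    else:
        accession, entry_name = record_id, None
    desc = description[len(record_id):].strip() if description.startswith(record_id) else description
    return accession, entry_name, (desc or None)


def load_proteome(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a FASTA proteome into an accession-keyed, order-preserving dict.

    Raises
    ------
    ProteomeError
        On an empty file, a duplicate accession (named in the message), or a
        sequence containing characters outside the tolerated alphabet.
    """
    path = Path(path)
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, entry_name, desc = _parse_header(rec.id, rec.description)
        if accession in records:
            raise ProteomeError(f"duplicate accession {accession!r} in {path}")
        records[accession] = ProteinRecord(
            accession=accession,
            sequence=str(rec.seq).upper(),
            entry_name=entry_name,
            description=desc,
        )
    if not records:
        raise ProteomeError(f"no FASTA records found in {path}")
    return records


def write_proteome(records: Iterable[ProteinRecord] | Mapping[str, ProteinRecord],
                   path: str | Path, width: int = 60) -> None:
    """Write records back to FASTA (UniProt-style headers when parseable)."""
    if isinstance(records, Mapping):
        records = records.values()
    with open(path, "w") as fh:
        for rec in records:
            if rec.entry_name:
                header = f"sp|{rec.accession}|{rec.entry_name}"
            else:
                header = rec.accession
            if rec.description:
                header = f"{header} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


@dataclass
class TableReport:
    """Bookkeeping for row-level filtering while loading a table."""

    n_rows: int = 0
    n_kept: int = 0
    dropped_missing_accession: int = 0
    rejected: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def load_annotations(
    path: str | Path,
    proteome: Mapping[str, ProteinRecord],
) -> tuple[list[ProcessingAnnotation], TableReport]:
    """Read a processing-annotation TSV (columns accession, feature_type,
    start, end).

    Rows referencing accessions absent from the proteome are dropped and
    counted; rows with out-of-range coordinates or an unknown feature type are
    rejected and reported. Nothing disappears silently:
    ``n_rows == n_kept + dropped + rejected``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "feature_type", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ProteomeError(f"annotation table missing columns: {sorted(missing)}")

    report = TableReport(n_rows=len(df))
    annotations: list[ProcessingAnnotation] = []
    for row in df.itertuples(index=False):
        acc = row.accession
        if acc not in proteome:
            report.dropped_missing_accession += 1
            continue
        try:
            ann = ProcessingAnnotation(
                accession=acc,
                feature_type=row.feature_type,
                start=int(row.start),
                end=int(row.end),
            )
        except (ProteomeError, ValueError) as exc:
            report.rejected.append(f"{acc}: {exc}")
            continue
        if ann.end > len(proteome[acc]):
            report.rejected.append(
                f"{acc}: feature end {ann.end} beyond protein length {len(proteome[acc])}"
            )
            continue
        annotations.append(ann)
        report.n_kept += 1
    if report.dropped_missing_accession:
        logger.info(
            "load_annotations: dropped %d rows with accessions absent from proteome",
            report.dropped_missing_accession,
        )
    return annotations, report


def load_known_sites(
    path: str | Path,
    proteome: Mapping[str, ProteinRecord] | None = None,
    source: str | None = None,
) -> tuple[list[KnownCleavageSite], TableReport]:
    """Read a known-cleavage-site TSV (columns accession, p1_position and
    optionally source).

    When a proteome is supplied, rows for unknown accessions are dropped and
    sites at or beyond the last residue rejected (a bond must follow P1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"accession", "p1_position"} <= set(df.columns):
        raise ProteomeError("known-site table needs columns accession, p1_position")
    has_source = "source" in df.columns

    report = TableReport(n_rows=len(df))
    sites: list[KnownCleavageSite] = []
    for row in df.itertuples(index=False):
        acc = row.accession
        if proteome is not None and acc not in proteome:
            report.dropped_missing_accession += 1
            continue
        try:
            p1 = int(row.p1_position)
            site = KnownCleavageSite(
                accession=acc,
                p1_position=p1,
                source=(row.source if has_source else None) or source or "unknown",
            )
        except (ProteomeError, ValueError) as exc:
            report.rejected.append(f"{acc}: {exc}")
            continue
        if proteome is not None and site.p1_position >= len(proteome[acc]):
            report.rejected.append(
                f"{acc}: p1_position {site.p1_position} has no downstream residue"
            )
            continue
        sites.append(site)
        report.n_kept += 1
    return sites, report
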