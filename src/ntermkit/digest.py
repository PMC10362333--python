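"""In silico protease digestion, caspase motif scanning, and per-method
identifiability of N-terminal peptides.

The scientific question this module answers: given a protease cleavage event
at some P1 position, would the resulting neo-N-terminal peptide be observable
by an N-terminomics workflow? Two workflows are modelled:

* **LATE** — LysN digestion. LysN cleaves N-terminally to lysine, so the
  neo-N-terminal peptide runs from P1' up to (but not including) the first K
  strictly downstream of P1'.
* **HYTANE** — whole-protein amine dimethylation blocks lysines, so trypsin
  behaves with ArgC-like specificity (cleavage C-terminal to arginine only).
  The neo-N-terminal peptide runs from P1' through the first R at or after
  P1', inclusive.

A peptide is called *identifiable* when its length falls in a configurable
window, by default 7–35 residues — the mass-spectrometry-amenable size range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequences import AA20, ProteinRecord

__all__ = [
    "ProteaseSpec",
    "LYSN",
    "ARGC_LIKE",
    "TRYPSIN",
    "CleavageSite",
    "NeoPeptide",
    "Peptide",
    "digest",
    "scan_motif",
    "parse_motif",
    "CASPASE3_MOTIF",
    "neo_peptide",
    "peptide_from_start",
    "is_identifiable",
    "nearest_residue_distance",
    "coverage_report",
    "METHODS",
]

METHODS = ("LATE", "HYTANE")

DEFAULT_WINDOW = (7, 35)


@dataclass(frozen=True)
class ProteaseSpec:
    """Cleavage specificity of a digestion protease.

    ``side`` is "C" when the bond C-terminal to a recognized residue is cut
    (trypsin, ArgC) and "N" when the bond N-terminal to it is cut (LysN).
    ``blocked_next`` lists P1' residues that suppress cleavage (e.g. proline
    for trypsin).
    """

    name: str
    side: str
    residues: frozenset
    blocked_next: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.side not in ("C", "N"):
            raise ValueError("side must be 'C' or 'N'")
        if not self.residues:
            raise ValueError("residues must be non-empty")
        for rset in (self.residues, self.blocked_next):
            bad = set(rset) - set(AA20)
            if bad:
                raise ValueError(f"specificity residues outside 20-aa alphabet: {sorted(bad)}")

    def cut_positions(self, sequence: str) -> list[int]:
        """1-based bond indices b (bond between residues b and b+1) cut by
        this protease."""
        cuts = []
        for b in range(1, len(sequence)):
            if self.side == "C":
                if sequence[b - 1] in self.residues and sequence[b] not in self.blocked_next:
                    cuts.append(b)
            else:
                if sequence[b] in self.residues:
                    cuts.append(b)
        return cuts


LYSN = ProteaseSpec("LysN", "N", frozenset("K"))
ARGC_LIKE = ProteaseSpec("ArgC-like", "C", frozenset("R"))
TRYPSIN = ProteaseSpec("trypsin", "C", frozenset("KR"))
TRYPSIN_NO_P = ProteaseSpec("trypsin/P", "C", frozenset("KR"), frozenset("P"))

#: Digestion specificity of each N-terminomics workflow.
METHOD_PROTEASE: Mapping[str, ProteaseSpec] = {"LATE": LYSN, "HYTANE": ARGC_LIKE}


@dataclass(frozen=True)
class CleavageSite:
    """A peptide bond position; the bond lies after residue ``p1_position``."""

    accession: str
    p1_position: int
    p1_residue: str
    origin: str = "motif_scan"  # motif_scan | observed | annotation

    @property
    def neo_start(self) -> int:
        return self.p1_position + 1


@dataclass(frozen=True)
class Peptide:
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class NeoPeptide(Peptide):
    """Neo-N-terminal peptide produced by a workflow's digestion; flagged when
    no terminating residue exists and the peptide runs to the C terminus."""

    runs_to_end: bool = False


def digest(protein: ProteinRecord | str, protease: ProteaseSpec,
           missed_cleavages: int = 0, max_missed: int = 5) -> list[Peptide]:
    """Digest a protein, returning peptides ordered by (start, end).

    At ``missed_cleavages == 0`` the peptides tile the sequence exactly; with
    m missed cleavages every contiguous union of up to m+1 adjacent fragments
    is also emitted.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not seq:
        raise ValueError("cannot digest a zero-length protein")
    if not 0 <= missed_cleavages <= max_missed:
        raise ValueError(f"missed_cleavages must be in 0..{max_missed}")

    cuts = protease.cut_positions(seq)
    bounds = [0] + cuts + [len(seq)]  # fragment i spans bounds[i]+1 .. bounds[i+1]
    n_frag = len(bounds) - 1
    peptides = []
    for i in range(n_frag):
        for j in range(i, min(i + missed_cleavages + 1, n_frag)):
            start, end = bounds[i] + 1, bounds[j + 1]
            peptides.append(Peptide(start, end, seq[start - 1:end]))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


#: Canonical caspase-3 recognition motif, P4..P1 (cleavage after the P1 Asp).
CASPASE3_MOTIF = ("D", "E", "V", "D")


def parse_motif(motif: str | Sequence[str]) -> tuple[frozenset, ...]:
    """Normalize a motif to a tuple of per-position residue sets.

    A plain string like ``"DEVD"`` is one residue per position; a sequence of
    strings like ``["DE"]`` gives one position allowing D or E. The motif is
    anchored at its last position = P1 and may span 1–4 positions (P4..P1).
    """
    if isinstance(motif, str):
        positions = tuple(frozenset(c) for c in motif)
    else:
        positions = tuple(frozenset(p) for p in motif)
    if not 1 <= len(positions) <= 4:
        raise ValueError("motif must span 1-4 positions ending at P1")
    for p in positions:
        if not p:
            raise ValueError("empty motif position")
        bad = set().union(p) - set(AA20)
        if bad:
            raise ValueError(f"motif residues outside 20-aa alphabet: {sorted(bad)}")
    return positions


def scan_motif(protein: ProteinRecord, motif: str | Sequence[str]) -> list[CleavageSite]:
    """Find all motif matches; one site per match, bond after the P1 residue.

    A match whose P1 is the last residue is excluded (no downstream residue,
    hence no neo-N-terminal peptide). Overlapping matches are all reported.
    X/U/B/Z never match a motif position.
    """
    positions = parse_motif(motif)
    seq = protein.sequence
    L = len(positions)
    sites = []
    for p1 in range(L, len(seq)):  # p1 is 1-based; p1 == len(seq) excluded
        window = seq[p1 - L:p1]
        if all(window[k] in positions[k] for k in range(L)):
            sites.append(CleavageSite(protein.accession, p1, seq[p1 - 1], "motif_scan"))
    return sites


def peptide_from_start(protein: ProteinRecord, start: int, method: str) -> NeoPeptide:
    """The N-terminal peptide a workflow observes for a terminus at ``start``.

    LATE: ends immediately before the first K strictly after ``start``.
    HYTANE: ends at the first R at or after ``start``, inclusive.
    If no terminating residue exists before the protein end, the C-terminal
    fragment is returned flagged ``runs_to_end``.
    """
    seq = protein.sequence
    if not 1 <= start <= len(seq):
        raise ValueError(f"start {start} outside 1..{len(seq)}")
    if method == "LATE":
        idx = seq.find("K", start)  # 0-based index >= start → residue position > start
        if idx == -1:
            end, runs = len(seq), True
        else:
            end, runs = idx, False  # residue before the K (0-based idx = 1-based idx-? )
    elif method == "HYTANE":
        idx = seq.find("R", start - 1)
        if idx == -1:
            end, runs = len(seq), True
        else:
            end, runs = idx + 1, False
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return NeoPeptide(start, end, seq[start - 1:end], runs)


def neo_peptide(protein: ProteinRecord, site: CleavageSite, method: str) -> NeoPeptide:
    """Neo-N-terminal peptide for a cleavage site under a workflow's digestion."""
    if site.accession != protein.accession:
        raise ValueError(
            f"site accession {site.accession!r} does not match protein {protein.accession!r}"
        )
    if site.p1_position >= len(protein.sequence):
        raise ValueError("site at the last residue produces no downstream peptide")
    return peptide_from_start(protein, site.p1_position + 1, method)


def is_identifiable(peptide_length: int, window: tuple[int, int] = DEFAULT_WINDOW) -> bool:
    """True iff min_len <= length <= max_len (inclusive on both ends)."""
    min_len, max_len = window
    if min_len > max_len:
        raise ValueError(f"window min {min_len} > max {max_len}")
    if peptide_length < 1:
        raise ValueError("peptide_length must be >= 1")
    return min_len <= peptide_length <= max_len


def nearest_residue_distance(protein: ProteinRecord | str, start: int,
                             residue_set: Iterable[str]) -> int | None:
    """Distance (>= 1) to the nearest residue of ``residue_set`` at or after
    ``start``, counting the start residue as distance 1; None if absent
    through the C terminus.

    For HYTANE this distance from a neo start equals the neo peptide length
    (peptide ends at the arginine, inclusive).
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not 1 <= start <= len(seq):
        raise ValueError(f"start {start} outside 1..{len(seq)}")
    rset = set(residue_set)
    for i in range(start - 1, len(seq)):
        if seq[i] in rset:
            return i - (start - 1) + 1
    return None


def _verdict_row(protein: ProteinRecord, start: int, methods: Sequence[str],
                 window: tuple[int, int]) -> dict:
    row: dict = {}
    for method in methods:
        pep = peptide_from_start(protein, start, method)
        row[f"{method}_length"] = len(pep)
        row[f"{method}_runs_to_end"] = pep.runs_to_end
        # a peptide running to the C terminus is still judged by its length
        row[f"{method}_identifiable"] = is_identifiable(len(pep), window)
    return row


def _partition_label(row: dict, methods: Sequence[str]) -> str:
    flags = [row[f"{m}_identifiable"] for m in methods]
    if all(flags):
        return "both" if len(methods) == 2 else "all"
    if not any(flags):
        return "neither"
    return f"{methods[flags.index(True)]}_only"


def summarize_partition(table: pd.DataFrame, methods: Sequence[str] = METHODS) -> dict:
    """Count sites by which method(s) can identify them; the four categories
    partition the site set."""
    counts = {f"{m}_only": 0 for m in methods}
    counts.update({"both": 0, "neither": 0, "total": len(table)})
    if len(table):
        for label, n in table["identifiable_by"].value_counts().items():
            counts[label] = int(n)
    return counts


def coverage_report(
    proteome: Mapping[str, ProteinRecord],
    motif: str | Sequence[str] = CASPASE3_MOTIF,
    methods: Sequence[str] = METHODS,
    window: tuple[int, int] = DEFAULT_WINDOW,
    missed_cleavages: int = 0,
) -> dict:
    """Per-method identifiability of motif cleavage sites and of ORF N termini.

    Returns a dict with:

    * ``sites`` — DataFrame, one row per motif site, with per-method peptide
      lengths, identifiability flags and the partition label;
    * ``site_summary`` — counts {<m>_only, both, neither, total} over sites;
    * ``orf`` — DataFrame, two rows per protein (Met-retained start 1,
      Met-excised start 2) with the same columns;
    * ``orf_summary`` — dict keyed "start1"/"start2" of partition counts.

    ``missed_cleavages`` is accepted for interface symmetry; the identifiable
    window logic is defined on the zero-missed-cleavage peptide (the nearest
    terminating residue), which is what the per-site table reports.
    """
    if not proteome:
        raise ValueError("empty proteome")
    site_rows = []
    orf_rows = []
    for rec in proteome.values():
        for site in scan_motif(rec, motif):
            row = {
                "accession": rec.accession,
                "p1_position": site.p1_position,
                "p1_residue": site.p1_residue,
                "neo_start": site.neo_start,
            }
            row.update(_verdict_row(rec, site.neo_start, methods, window))
            row["identifiable_by"] = _partition_label(row, methods)
            site_rows.append(row)
        for label, start in (("start1", 1), ("start2", 2)):
            if start > len(rec.sequence):
                continue
            row = {"accession": rec.accession, "orf_form": label, "start": start}
            row.update(_verdict_row(rec, start, methods, window))
            row["identifiable_by"] = _partition_label(row, methods)
            orf_rows.append(row)

    site_cols = ["accession", "p1_position", "p1_residue", "neo_start"] + [
        f"{m}_{f}" for m in methods for f in ("length", "runs_to_end", "identifiable")
    ] + ["identifiable_by"]
    sites = pd.DataFrame(site_rows, columns=site_cols)
    orf = pd.DataFrame(orf_rows)
    orf_summary = {
        label: summarize_partition(orf[orf["orf_form"] == label], methods)
        for label in ("start1", "start2")
    }
    return {
        "sites": sites,
        "site_summary": summarize_partition(sites, methods),
        "orf": orf,
        "orf_summary": orf_summary,
    }
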