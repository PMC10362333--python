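"""Candidate-selection (winnowing) workflows.

Staged, monotone set-shrinking filters that turn quantified neo-N-terminal
records into credible protease cleavage-site calls:

* **caspase winnow** — keep neo termini whose ratio meets the fold threshold
  or that were seen exclusively in the treated sample, and whose P1 residue
  matches caspase specificity (Asp, optionally Glu);
* **minimum evidence** — keep sites identified at least k times (PSMs pooled
  across methods and runs);
* **reported/novel annotation** — exact-position lookup against known
  cleavage-site tables; protein-level novelty when the accession appears in
  no table;
* **known-processing match** — a neo start at (signal/transit/propeptide
  end + 1) or at an annotated chain start is a maturation event, not a new
  cleavage;
* **neo-acetylation winnow** — route acetylated N termini into ORF
  acetylations, processing-derived acetylations, and candidate
  posttranslational neo-Nt-acetylation events, optionally flagging the
  caspase-linked subset.

Every stage logs (stage name, n_in, n_out); outputs are always subsets of
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequences import KnownCleavageSite, ProcessingAnnotation

__all__ = [
    "StageLog",
    "caspase_winnow",
    "min_evidence",
    "annotate_reported",
    "known_processing_match",
    "neo_acetylation_winnow",
    "form_cooccurrence",
]


@dataclass
class StageLog:
    """Input/output counts of each filter stage, in order."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise AssertionError(f"stage {name} grew the set: {n_in} -> {n_out}")
        self.stages.append((name, n_in, n_out))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_out"])


def _p1_set(p1: str | Iterable[str]) -> frozenset:
    return frozenset(p1)


def caspase_winnow(
    neo_quantified: pd.DataFrame,
    p1_set: str | Iterable[str] = "D",
    mode: str = "strict",
    fold_threshold_log2: float = 1.0,
) -> tuple[pd.DataFrame, StageLog]:
    """Select credible caspase cleavage sites from quantified neo records.

    A record passes the ratio stage when its log2 ratio is at or above
    ``fold_threshold_log2`` (inclusive) **or** it is a treated-only
    singleton; it passes the specificity stage when its P1 residue lies in
    ``p1_set`` ("D" canonical, "DE" to admit the Glu cleavages).

    ``mode="strict"`` returns only records passing both stages;
    ``mode="report-all"`` returns every record with the flags set.
    """
    if mode not in ("strict", "report-all"):
        raise ValueError(f"unknown mode {mode!r}")
    allowed = _p1_set(p1_set)
    df = neo_quantified.copy()
    log = StageLog()

    ratio_ok = df["log2_ratio"].apply(
        lambda v: v is not None and not pd.isna(v) and v >= fold_threshold_log2
    )
    treated_only = df["singleton_channel"] == "treated_only"
    df["passes_ratio"] = (ratio_ok | treated_only).astype(bool)
    df["treated_only"] = treated_only.astype(bool)
    df["caspase_p1"] = df["p1_residue"].isin(allowed)
    df["p1_position"] = df["start"].astype(int) - 1
    df["neo_start"] = df["start"].astype(int)

    if mode == "report-all":
        log.record("flags", len(df), len(df))
        return df, log

    n0 = len(df)
    after_ratio = df[df["passes_ratio"]]
    log.record("ratio_or_treated_only", n0, len(after_ratio))
    after_p1 = after_ratio[after_ratio["caspase_p1"]]
    log.record(f"p1_in_{''.join(sorted(allowed))}", len(after_ratio), len(after_p1))
    return after_p1.reset_index(drop=True), log


def min_evidence(
    records: pd.DataFrame,
    k: int = 2,
    evidence_column: str = "psm_count",
    log: StageLog | None = None,
) -> pd.DataFrame:
    """Keep records identified at least ``k`` times (PSMs pooled across
    methods and runs by default)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out = records[records[evidence_column] >= k].reset_index(drop=True)
    if log is not None:
        log.record(f"min_evidence_{k}", len(records), len(out))
    return out


def annotate_reported(
    sites: pd.DataFrame,
    known_tables: Mapping[str, Sequence[KnownCleavageSite]],
) -> pd.DataFrame:
    """Attach reported/novel flags from known-cleavage-site tables.

    ``reported`` — exact (accession, p1_position) match in any table, with
    the matching source names listed; ``novel_substrate`` — the accession
    appears nowhere in any table (protein-level novelty).
    """
    site_index: dict[tuple, list[str]] = {}
    known_proteins: set = set()
    for name, table in known_tables.items():
        for ks in table:
            site_index.setdefault((ks.accession, ks.p1_position), []).append(name)
            known_proteins.add(ks.accession)
    df = sites.copy()
    keys = list(zip(df["accession"], df["p1_position"]))
    df["reported"] = [key in site_index for key in keys]
    df["reported_sources"] = [tuple(sorted(site_index.get(key, ()))) for key in keys]
    df["novel_substrate"] = ~df["accession"].isin(known_proteins)
    return df


def known_processing_match(
    neo_start: int,
    annotations: Sequence[ProcessingAnnotation],
) -> tuple[bool, ProcessingAnnotation | None]:
    """Does a neo N terminus coincide with a known maturation event?

    True when ``neo_start`` equals the residue after the end of a
    signal/transit peptide or propeptide, or the start (> 1) of an annotated
    chain.
    """
    for ann in annotations:
        if ann.feature_type in ("signal_peptide", "transit_peptide", "propeptide"):
            if neo_start == ann.end + 1:
                return True, ann
        elif ann.feature_type == "chain":
            if ann.start > 1 and neo_start == ann.start:
                return True, ann
    return False, None


def _annotations_by_accession(
    annotations: Iterable[ProcessingAnnotation],
) -> dict[str, list[ProcessingAnnotation]]:
    index: dict[str, list[ProcessingAnnotation]] = {}
    for ann in annotations:
        index.setdefault(ann.accession, []).append(ann)
    return index


def neo_acetylation_winnow(
    classified_quantified: pd.DataFrame,
    annotations: Iterable[ProcessingAnnotation],
    alt_init_table: Iterable[tuple[str, int]] = (),
    caspase_sites: pd.DataFrame | None = None,
    p1_set: str | Iterable[str] = "DE",
) -> tuple[dict[str, pd.DataFrame], StageLog]:
    """Winnow acetylated N-terminal records down to candidate
    posttranslational neo-Nt-acetylation events.

    Stages (each logged):

    1. keep acetylated N termini;
    2. drop ORF starts (positions 1/2) — cotranslational acetylation;
    3. split off known-processing matches into the ``processing_derived``
       output (maturation-linked acetylation, e.g. after transit-peptide
       removal);
    4. drop termini matching the alternative-initiation table;
    5. the remainder are ``candidates``;
    6. when a caspase winnow output is supplied, candidates whose
       (accession, p1_position) it contains — or failing quant linkage,
       whose P1 residue lies in ``p1_set`` — are flagged ``caspase_linked``.

    Returns the output tables and the stage log.
    """
    ann_index = _annotations_by_accession(annotations)
    alt_init = set(alt_init_table)
    log = StageLog()
    df = classified_quantified.copy()
    if "neo_start" not in df.columns:
        df["neo_start"] = df["start"].astype(int)
    df["p1_position"] = df["neo_start"] - 1

    acet = df[df["nterm_state"] == "acetylated"]
    log.record("acetylated_nterm", len(df), len(acet))

    non_orf = acet[~acet["category"].isin(["ORF_start1", "ORF_start2"])]
    log.record("drop_orf_start", len(acet), len(non_orf))

    proc_mask = non_orf.apply(
        lambda row: known_processing_match(
            int(row["neo_start"]), ann_index.get(row["accession"], [])
        )[0],
        axis=1,
    ) if len(non_orf) else pd.Series(dtype=bool)
    processing = non_orf[proc_mask] if len(non_orf) else non_orf
    remaining = non_orf[~proc_mask] if len(non_orf) else non_orf
    log.record("split_known_processing", len(non_orf), len(remaining))

    alt_mask = remaining.apply(
        lambda row: (row["accession"], int(row["neo_start"])) in alt_init, axis=1
    ) if len(remaining) else pd.Series(dtype=bool)
    candidates = remaining[~alt_mask] if len(remaining) else remaining
    log.record("drop_alt_init", len(remaining), len(candidates))

    candidates = candidates.copy()
    if caspase_sites is not None and len(caspase_sites):
        linked_keys = set(
            zip(caspase_sites["accession"], caspase_sites["p1_position"].astype(int))
        )
        candidates["caspase_linked"] = [
            (acc, int(p1)) in linked_keys
            for acc, p1 in zip(candidates["accession"], candidates["p1_position"])
        ]
    else:
        allowed = _p1_set(p1_set)
        candidates["caspase_linked"] = candidates["p1_residue"].isin(allowed)
    return (
        {
            "candidates": candidates.reset_index(drop=True),
            "processing_derived": processing.reset_index(drop=True),
            "dropped_orf": acet[acet["category"].isin(["ORF_start1", "ORF_start2"])]
            .reset_index(drop=True),
        },
        log,
    )


def form_cooccurrence(
    classified: pd.DataFrame,
    by_sample: bool = True,
) -> pd.DataFrame:
    """Per-(accession, start) PSM counts of the acetylated vs free forms.

    Supports the time-course readout of which N-terminal form of a site
    appears in which experiment: with ``by_sample`` the counts are further
    split per sample label. Count totals equal the input size.
    """
    df = classified[classified["accession"].notna()].copy()
    df["form"] = (df["nterm_state"] == "acetylated").map(
        {True: "acetylated", False: "free"}
    )
    keys = ["accession", "start"] + (["sample_id"] if by_sample and "sample_id" in df else [])
    table = (
        df.groupby(keys + ["form"], observed=True).size().rename("n_psm")
        .reset_index()
        .pivot_table(index=keys, columns="form", values="n_psm",
                     fill_value=0, aggfunc="sum")
        .reset_index()
    )
    for col in ("acetylated", "free"):
        if col not in table.columns:
            table[col] = 0
    table.columns.name = None
    return table
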