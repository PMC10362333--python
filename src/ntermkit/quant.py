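"""Two-channel isotopic ratio quantification.

The experimental design compares a treated sample against a control, each
labeled with one isotopologue of the dimethyl pair. Processing order:

1. **Per-run median normalization** — each MS run's quantified PSM ratios are
   centered so that the median log2 ratio is zero, removing the channel
   mixing error. Singletons (one channel only) are untouched. Normalization
   is applied at the PSM level, before aggregation.
2. **Aggregation** — PSMs sharing (accession, start, N-terminal state) are
   combined by summing peak areas per channel; the aggregate ratio is
   Σ treated-area / Σ control-area given the experiment's channel
   orientation. Keys observed in only one channel become directional
   singletons; no pseudo-ratio is ever imputed.
3. **Fixed-threshold significance** — a record is significant when its log2
   ratio meets the fold threshold (inclusive, default 2-fold i.e. log2 ≥ 1)
   or it was observed exclusively in the treated channel.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_runs",
    "aggregate",
    "call_significant",
    "pair_forms",
    "susceptibility_table",
]

ORIENTATIONS = ("heavy=treated", "light=treated")


def normalize_runs(
    classified: pd.DataFrame,
    min_quantified: int = 3,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Median-center log2(heavy/light) per run at the PSM level.

    Adds ``heavy_area_norm`` (heavy area divided by the run's median ratio) so
    that downstream area-sum aggregation inherits the normalization exactly.
    Runs with fewer than ``min_quantified`` two-channel PSMs pass through
    unnormalized with a warning. Returns the table and the per-run log2
    normalization constants.
    """
    df = classified.copy()
    df["heavy_area_norm"] = df["heavy_area"].astype(float)
    constants: dict[str, float] = {}
    for run, grp in df.groupby("run_id", sort=False):
        both = grp[(grp["light_area"] > 0) & (grp["heavy_area"] > 0)]
        if len(both) < min_quantified:
            logger.warning(
                "run %s has only %d quantified PSMs (< %d); passed through unnormalized",
                run, len(both), min_quantified,
            )
            constants[run] = 0.0
            continue
        log2r = np.log2(both["heavy_area"].to_numpy() / both["light_area"].to_numpy())
        c = float(np.median(log2r))
        constants[run] = c
        df.loc[grp.index, "heavy_area_norm"] = grp["heavy_area"] / (2.0 ** c)
    return df, constants


def _treated_control(row_heavy: float, row_light: float, orientation: str):
    if orientation == "heavy=treated":
        return row_heavy, row_light
    return row_light, row_heavy


def aggregate(
    classified: pd.DataFrame,
    orientation: str = "heavy=treated",
    key: tuple = ("accession", "start", "nterm_state"),
) -> pd.DataFrame:
    """Aggregate normalized PSMs into one record per key.

    Ratio = Σ treated area / Σ control area over the key's PSMs, then log2.
    Records with areas in only one channel carry ``singleton_channel``
    ("treated_only"/"control_only") and a None ratio. Keys with zero area in
    both channels are dropped and the drop is logged.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    heavy_col = "heavy_area_norm" if "heavy_area_norm" in classified.columns else "heavy_area"
    df = classified[classified["accession"].notna()]
    rows = []
    n_dropped = 0
    for key_vals, grp in df.groupby(list(key), sort=False):
        sum_heavy = float(grp[heavy_col].sum())
        sum_light = float(grp["light_area"].sum())
        treated, control = _treated_control(sum_heavy, sum_light, orientation)
        if treated == 0 and control == 0:
            n_dropped += 1
            continue
        if treated > 0 and control > 0:
            log2_ratio = math.log2(treated / control)
            singleton = "none"
        elif treated > 0:
            log2_ratio, singleton = None, "treated_only"
        else:
            log2_ratio, singleton = None, "control_only"
        peptides = grp["peptide"].tolist()
        row = dict(zip(key, key_vals))
        row.update({
            "category": grp["category"].iloc[0] if "category" in grp else None,
            "p1_residue": grp["p1_residue"].iloc[0] if "p1_residue" in grp else None,
            "peptide": max(peptides, key=len),
            "log2_ratio": log2_ratio,
            "psm_count": int(len(grp)),
            "runs": tuple(sorted(set(grp["run_id"]))),
            "methods": tuple(sorted(set(grp["enzyme"]))) if "enzyme" in grp else (),
            "singleton_channel": singleton,
        })
        rows.append(row)
    if n_dropped:
        logger.info("aggregate: dropped %d keys with zero area in both channels", n_dropped)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["start"] = out["start"].astype(int)
    return out


def call_significant(
    quantified: pd.DataFrame,
    fold_threshold: float = 2.0,
    strict: bool = False,
) -> pd.DataFrame:
    """Flag records meeting the fixed fold threshold.

    Inclusive by default (ratio ≥ threshold, i.e. log2 ≥ log2(threshold));
    ``strict=True`` switches to a strictly-greater comparison. Treated-only
    singletons are always significant; control-only singletons never are.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    cut = math.log2(fold_threshold)
    df = quantified.copy()

    def flag(row) -> bool:
        if row["singleton_channel"] == "treated_only":
            return True
        if row["log2_ratio"] is None or pd.isna(row["log2_ratio"]):
            return False
        return row["log2_ratio"] > cut if strict else row["log2_ratio"] >= cut

    df["significant"] = df.apply(flag, axis=1) if len(df) else pd.Series(dtype=bool)
    return df


def pair_forms(quantified_orf: pd.DataFrame) -> dict:
    """Pair the acetylated and free forms of each ORF N terminus.

    One pair per (accession, start) observed in both N-terminal states, each
    side keeping its own ratio; keys with a single state are excluded from
    the pairs but counted.
    """
    orf = quantified_orf[
        quantified_orf["category"].isin(["ORF_start1", "ORF_start2"])
    ]
    pairs = []
    n_single = 0
    for (acc, start), grp in orf.groupby(["accession", "start"], sort=False):
        states = dict(zip(grp["nterm_state"], grp.index))
        acet = states.get("acetylated")
        free = states.get("free_labeled", states.get("free_unlabeled"))
        if acet is not None and free is not None:
            pairs.append({
                "accession": acc,
                "start": int(start),
                "acetyl_log2_ratio": grp.loc[acet, "log2_ratio"],
                "free_log2_ratio": grp.loc[free, "log2_ratio"],
                "peptide": grp.loc[free, "peptide"],
            })
        else:
            n_single += 1
    return {
        "pairs": pd.DataFrame(pairs),
        "n_pairs": len(pairs),
        "n_single_state": n_single,
    }


def _quartiles(values: pd.Series) -> dict:
    clean = values.dropna().astype(float)
    if clean.empty:
        return {"n": 0, "median": None, "q1": None, "q3": None}
    q = clean.quantile([0.25, 0.5, 0.75])
    return {
        "n": int(clean.shape[0]),
        "median": float(q.loc[0.5]),
        "q1": float(q.loc[0.25]),
        "q3": float(q.loc[0.75]),
    }


def susceptibility_table(quantified_orf: pd.DataFrame) -> pd.DataFrame:
    """Ratio summaries of ORF N-terminal peptides grouped by N-terminal state
    (free vs acetylated) × literal presence of Asp or Glu in the peptide.

    Peptides carrying a potential caspase P1 residue (D/E) and an
    unprotected (free) N terminus are the group expected to shift toward the
    control channel when the treated sample carries active caspase.
    """
    orf = quantified_orf[
        quantified_orf["category"].isin(["ORF_start1", "ORF_start2"])
    ].copy()
    orf["nterm_group"] = np.where(orf["nterm_state"] == "acetylated", "acetylated", "free")
    orf["has_DE"] = orf["peptide"].str.contains("D") | orf["peptide"].str.contains("E")
    rows = []
    for (state, has_de), grp in orf.groupby(["nterm_group", "has_DE"], sort=True):
        stats = _quartiles(grp["log2_ratio"])
        rows.append({"nterm_group": state, "has_DE": bool(has_de), **stats})
    return pd.DataFrame(rows)
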