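"""Cleavage-context statistics.

* P4–P4' windows around a scissile bond ('-' padding at protein termini);
* differential amino-acid-usage (DAU) logo matrices: per position, the
  foreground amino-acid frequency minus a background frequency, expressed in
  percent — positive values mark residues enriched at that position relative
  to the proteome background;
* nearest-basic-residue distance histograms (the method-coverage readout:
  an arginine 7–35 residues downstream makes a site reachable by ArgC-like
  workflows, a lysine in the same range by LysN workflows);
* secondary-structure / relative-solvent-accessibility context summaries with
  a seeded permutation contrast between two site groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import DEFAULT_WINDOW, nearest_residue_distance
from .sequences import AA20, ProteinRecord

__all__ = [
    "POSITIONS",
    "LogoMatrix",
    "extract_window",
    "background_frequencies",
    "dag_logo",
    "distance_histogram",
    "context_summary",
    "compare_rsa_groups",
]

#: Schechter–Berger position labels for an 8-residue cleavage window.
POSITIONS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")

PAD = "-"


def extract_window(protein: ProteinRecord | str, p1_position: int, flank: int = 4) -> str:
    """Residues P<flank>..P1 | P1'..P<flank>' around the bond after
    ``p1_position``; out-of-range slots are '-'-padded."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not 1 <= p1_position <= len(seq):
        raise ValueError(f"p1_position {p1_position} outside 1..{len(seq)}")
    chars = []
    for pos in range(p1_position - flank + 1, p1_position + flank + 1):
        chars.append(seq[pos - 1] if 1 <= pos <= len(seq) else PAD)
    return "".join(chars)


@dataclass(frozen=True)
class LogoMatrix:
    """Percent-difference logo matrix.

    ``values`` is a 20-amino-acid × 8-position DataFrame where entry (a, p) =
    100 × (foreground frequency of a at p − background frequency of a).
    Padded slots are excluded from both numerator and denominator of the
    foreground frequency, which keeps every column summing to zero.
    """

    values: pd.DataFrame
    n_sites: int
    background: pd.Series

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "amino_acid"
        out.to_csv(path, sep="\t", float_format="%.6f")


def background_frequencies(
    source: Mapping[str, ProteinRecord] | Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Amino-acid background frequency vector (sums to 1 over the 20
    canonical residues) from a proteome or a ready-made mapping."""
    if isinstance(source, pd.Series):
        freqs = source.reindex(list(AA20)).fillna(0.0)
    else:
        first = next(iter(source.values()), None)
        if isinstance(first, ProteinRecord):
            counts = {aa: 0 for aa in AA20}
            for rec in source.values():
                for aa in rec.sequence:
                    if aa in counts:
                        counts[aa] += 1
            total = sum(counts.values())
            if total == 0:
                raise ValueError("proteome contains no canonical residues")
            freqs = pd.Series({aa: c / total for aa, c in counts.items()})
        else:
            freqs = pd.Series(source, dtype=float).reindex(list(AA20)).fillna(0.0)
    s = float(freqs.sum())
    if abs(s - 1.0) > 1e-6:
        freqs = freqs / s
    return freqs.reindex(list(AA20))


def dag_logo(
    windows: Sequence[str],
    background: Mapping[str, ProteinRecord] | Mapping[str, float] | pd.Series,
) -> LogoMatrix:
    """Differential amino-acid-usage matrix over P4..P4' windows.

    One background vector applies to every position. Per column the
    foreground frequency is computed over non-padding residues only, then the
    background is subtracted and the difference scaled to percent.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("dag_logo requires at least one window")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("all windows must share one length")
    bg = background_frequencies(background)
    labels = POSITIONS if width == 8 else tuple(f"pos{i+1}" for i in range(width))

    values = pd.DataFrame(0.0, index=list(AA20), columns=list(labels))
    for col, label in enumerate(labels):
        residues = [w[col] for w in windows if w[col] != PAD and w[col] in AA20]
        if residues:
            counts = pd.Series(residues).value_counts()
            fg = counts.reindex(list(AA20)).fillna(0.0) / len(residues)
        else:
            fg = bg  # empty column: no information, difference 0
        values[label] = 100.0 * (fg - bg)
    return LogoMatrix(values=values, n_sites=len(windows), background=bg)


def distance_histogram(
    sites: Iterable,  # CleavageSite or (accession, p1_position)
    proteome: Mapping[str, ProteinRecord],
    residue_set: Iterable[str] = frozenset("R"),
    max_d: int = 100,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> dict:
    """Histogram of nearest-residue distances from each neo start (P1').

    Sites with no such residue through the C terminus are censored into the
    ``> max_d`` bin. Reports the fraction of sites whose distance falls
    outside the identifiable window — for {R} this is the fraction of sites
    an ArgC-like workflow cannot reach.
    """
    counts: dict = {}
    censored = 0
    outside = 0
    total = 0
    for site in sites:
        acc, p1 = (site.accession, site.p1_position) if hasattr(site, "accession") else site
        rec = proteome[acc]
        if p1 >= len(rec.sequence):
            continue
        d = nearest_residue_distance(rec, p1 + 1, residue_set)
        total += 1
        if d is None or d > max_d:
            censored += 1
            outside += 1
            continue
        counts[d] = counts.get(d, 0) + 1
        if not window[0] <= d <= window[1]:
            outside += 1
    return {
        "histogram": dict(sorted(counts.items())),
        "censored": censored,
        "n_sites": total,
        "fraction_outside_window": (outside / total) if total else 0.0,
        "window": window,
    }


def _site_context(site, annotation: Mapping[str, dict], flank: int = 4):
    acc, p1 = (site.accession, site.p1_position) if hasattr(site, "accession") else site
    entry = annotation.get(acc)
    if entry is None:
        return None
    ss = entry.get("ss")
    rsa = entry.get("rsa")
    out = {"accession": acc, "p1_position": p1}
    if ss is not None and 1 <= p1 <= len(ss):
        out["ss_P1"] = ss[p1 - 1]
        out["ss_P1p"] = ss[p1] if p1 < len(ss) else None
    if rsa is not None and 1 <= p1 <= len(rsa):
        out["rsa_P1"] = float(rsa[p1 - 1])
        out["rsa_P1p"] = float(rsa[p1]) if p1 < len(rsa) else None
    return out


def context_summary(
    sites: Iterable,
    annotation: Mapping[str, dict],
) -> dict:
    """Secondary-structure and solvent-accessibility context at P1/P1'.

    ``annotation`` maps accession → {"ss": per-residue code string, "rsa":
    per-residue accessibility values in [0, 1]} (precomputed externally).
    Sites on accessions missing from the table are skipped and counted.
    """
    rows = []
    skipped = 0
    for site in sites:
        ctx = _site_context(site, annotation)
        if ctx is None:
            skipped += 1
        else:
            rows.append(ctx)
    df = pd.DataFrame(rows)
    summary: dict = {"n_sites": len(df), "n_skipped": skipped, "table": df}
    if not df.empty and "ss_P1" in df:
        dist = df["ss_P1"].value_counts(normalize=True).to_dict()
        summary["ss_distribution_P1"] = dist
    if not df.empty and "rsa_P1" in df:
        q = df["rsa_P1"].quantile([0.25, 0.5, 0.75])
        summary["rsa_P1"] = {
            "median": float(q.loc[0.5]),
            "q1": float(q.loc[0.25]),
            "q3": float(q.loc[0.75]),
        }
    return summary


def compare_rsa_groups(
    rsa_a: Sequence[float],
    rsa_b: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Permutation contrast of two relative-solvent-accessibility samples.

    Statistic: difference of group medians (a − b). The p-value is the
    two-sided fraction of label permutations whose |difference| is at least
    the observed one (plus-one correction keeps it in (0, 1]).
    """
    a = np.asarray(rsa_a, dtype=float)
    b = np.asarray(rsa_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a = a.size
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = np.median(perm[:n_a]) - np.median(perm[n_a:])
        if abs(diff) >= abs(observed) - 1e-15:
            hits += 1
    return {
        "median_difference": observed,
        "p_value": (hits + 1) / (n_permutations + 1),
        "n_permutations": n_permutations,
    }
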