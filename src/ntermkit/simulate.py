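"""Synthetic proteomes, spiked cleavage events, and two-channel PSM tables
with known ground truth.

The generator emulates the statistical structure of a two-channel (treated vs
control) N-terminomics experiment so that every pipeline stage can be tested
end-to-end without any external data:

* a random proteome (human-like amino-acid frequencies, every protein
  Met-initiated) with per-protein Met-excision and ORF Nt-acetylation states
  drawn at the rates typical of the human N-terminome (~70% Met excision,
  ~74% Nt-acetylation);
* spiked protease cleavage events with assigned log2 effect sizes; the local
  sequence downstream of each planted site is engineered so that the
  LysN-workflow (LATE) and ArgC-workflow (HYTANE) observability classes —
  both / LATE-only / HYTANE-only / neither — occur in known numbers. The
  truth table's ``observable_by`` is always *recomputed* through the
  digestion engine, never set by hand;
* two-channel PSM rows with multiplicative (log-normal) ratio noise around
  each event's true log2 ratio, written in the same PSM TSV dialect the
  ingestion module reads, so the pipeline is exercised only through its
  public interfaces.

Everything is deterministic under the config seed; floats are written with
fixed precision so repeated runs are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import (METHODS, METHOD_PROTEASE, digest as run_digest,
                     is_identifiable, peptide_from_start)
from .psms import MOD_MASSES, ModificationState, NTermObservation, write_psm_tsv
from .sequences import (
    AA20,
    KnownCleavageSite,
    ProcessingAnnotation,
    ProteinRecord,
    write_proteome,
)

__all__ = ["SimConfig", "SimDataset", "make_proteome", "simulate_experiment",
           "generate", "write_dataset", "score_recovery", "HUMAN_AA_FREQUENCIES"]

#: Swiss-Prot-like global amino-acid frequencies (fractions, sum to 1).
HUMAN_AA_FREQUENCIES: Mapping[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

OBSERVABILITY_CLASSES = ("both", "late_only", "hytane_only", "neither")

#: Downstream-zone layout per observability class: relative positions
#: (neo start = 1) of the first K and first R. The identifiable window is
#: 7-35: LATE peptide length = posK - 1, HYTANE peptide length = posR.
_CLASS_LAYOUT = {
    "both": {"K": 13, "R": 10},
    "late_only": {"K": 11, "R": 40},
    "hytane_only": {"K": 41, "R": 10},
    "neither": {"K": 3, "R": 2},
}

_ZONE_LEN = 45  # residues downstream of P1 rewritten when planting a site


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    The defaults are the package's reference conditions: 500 spiked caspase
    cleavage events at a true log2(treated/control) of 2.0, log-normal PSM
    ratio noise of 0.3 (log2 scale), 4 PSMs per event and per ORF form, a
    2-fold inclusive significance threshold downstream, and treated sample
    on the heavy dimethyl channel.
    """

    seed: int
    n_proteins: int = 2500
    length_range: tuple[int, int] = (150, 450)
    aa_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(HUMAN_AA_FREQUENCIES))
    p_met_excision: float = 0.70
    p_orf_acetylation: float = 0.74
    n_caspase_sites: int = 500
    p1_set: str = "D"
    effect_log2: float = 2.0
    n_background_cleavages: int = 150
    n_treated_only: int = 25
    n_processing: int = 12
    n_neo_acetylation: int = 15
    n_alt_init: int = 8
    psm_per_event: int = 4
    psm_per_orf: int = 4
    ratio_noise_sigma: float = 0.3
    global_mix_bias_log2: float = 0.0
    internal_fraction: float = 0.08
    epsilon_label_rate: float = 0.04
    window: tuple[int, int] = (7, 35)
    orientation: str = "heavy=treated"
    observability_mix: Mapping[str, float] = field(
        default_factory=lambda: {"both": 0.5, "late_only": 0.2,
                                 "hytane_only": 0.2, "neither": 0.1})

    def __post_init__(self) -> None:
        for p in (self.p_met_excision, self.p_orf_acetylation,
                  self.internal_fraction, self.epsilon_label_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        total = sum(self.aa_frequencies.values())
        if abs(total - 1.0) > 5e-3:
            raise ValueError("aa_frequencies must sum to 1")
        if abs(total - 1.0) > 1e-12:  # renormalize away rounding of tabulated values
            self.aa_frequencies = {a: f / total for a, f in self.aa_frequencies.items()}
        if abs(sum(self.observability_mix.values()) - 1.0) > 1e-6:
            raise ValueError("observability_mix must sum to 1")
        n_events = (self.n_caspase_sites + self.n_background_cleavages
                    + self.n_treated_only + self.n_processing
                    + self.n_neo_acetylation + self.n_alt_init)
        if n_events > self.n_proteins:
            raise ValueError(
                f"{n_events} planted events exceed {self.n_proteins} proteins "
                "(one planted site per protein)")


@dataclass
class SimDataset:
    """Everything one simulation produces."""

    config: SimConfig
    proteome: dict[str, ProteinRecord]
    truth: pd.DataFrame
    annotations: list[ProcessingAnnotation]
    alt_init: list[tuple[str, int]]
    known_sites: list[KnownCleavageSite]
    observations: dict[str, list[NTermObservation]]


def _class_counts(mix: Mapping[str, float], n: int) -> list[str]:
    """Deterministic largest-remainder allocation of n events to classes."""
    exact = {c: mix.get(c, 0.0) * n for c in OBSERVABILITY_CLASSES}
    counts = {c: int(math.floor(v)) for c, v in exact.items()}
    short = n - sum(counts.values())
    remainders = sorted(OBSERVABILITY_CLASSES,
                        key=lambda c: exact[c] - counts[c], reverse=True)
    for c in remainders[:short]:
        counts[c] += 1
    out: list[str] = []
    for c in OBSERVABILITY_CLASSES:
        out.extend([c] * counts[c])
    return out


def _plant_site(seq: list[str], p1: int, p1_residue: str, obs_class: str,
                rng: np.random.Generator, non_kr: np.ndarray,
                non_kr_p: np.ndarray, motif_p4_p2: str = "DEV") -> None:
    """Overwrite seq in place: motif at P4..P1 and a K/R-controlled
    downstream zone realizing the requested observability class."""
    upstream = motif_p4_p2 + p1_residue if p1_residue in "DE" else \
        "".join(rng.choice(non_kr, size=3, p=non_kr_p)) + p1_residue
    for k, ch in enumerate(upstream):
        seq[p1 - 4 + k] = ch
    zone = rng.choice(non_kr, size=_ZONE_LEN, p=non_kr_p)
    layout = _CLASS_LAYOUT[obs_class]
    zone[layout["K"] - 1] = "K"
    zone[layout["R"] - 1] = "R"
    seq[p1:p1 + _ZONE_LEN] = list(zone)


def make_proteome(config: SimConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[dict[str, ProteinRecord], pd.DataFrame,
                             list[ProcessingAnnotation], list[tuple[str, int]]]:
    """Generate the proteome, the event truth table, processing annotations
    and the alternative-initiation exclusion table.

    One planted event per protein at most; every protein additionally
    contributes an ORF-terminus truth row. ``observable_by`` is recomputed
    from the final sequences with the digestion engine.
    """
    rng = rng or np.random.default_rng(config.seed)
    alphabet = np.array(list(AA20))
    probs = np.array([config.aa_frequencies[a] for a in AA20])
    non_kr_mask = np.array([a not in "KR" for a in AA20])
    non_kr = alphabet[non_kr_mask]
    non_kr_p = probs[non_kr_mask] / probs[non_kr_mask].sum()

    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    sequences = []
    for L in lengths:
        chars = rng.choice(alphabet, size=int(L), p=probs)
        chars[0] = "M"
        sequences.append(list(chars))

    # event bookkeeping: (protein index, event_type, obs_class, p1_residue,
    # true_log2, treated_only, acetylated_neo)
    events = []
    idx = 0

    def take(n: int) -> list[int]:
        nonlocal idx
        out = list(range(idx, idx + n))
        idx += n
        return out

    def p1_choices(n: int) -> list[str]:
        allowed = list(config.p1_set)
        return [allowed[i % len(allowed)] for i in range(n)]

    for i, cls, p1r in zip(take(config.n_caspase_sites),
                           _class_counts(config.observability_mix,
                                         config.n_caspase_sites),
                           p1_choices(config.n_caspase_sites)):
        events.append((i, "caspase", cls, p1r, config.effect_log2, False, False))
    non_de = [a for a in AA20 if a not in "DE"]
    for j, (i, cls) in enumerate(zip(take(config.n_background_cleavages),
                                     _class_counts(config.observability_mix,
                                                   config.n_background_cleavages))):
        events.append((i, "background", cls, non_de[j % len(non_de)], 0.0,
                       False, False))
    for i, p1r in zip(take(config.n_treated_only),
                      p1_choices(config.n_treated_only)):
        events.append((i, "caspase", "both", p1r, config.effect_log2, True, False))
    for i in take(config.n_processing):
        events.append((i, "processing", "both", None, 0.0, False, True))
    for i in take(config.n_neo_acetylation):
        events.append((i, "neo_acetylation", "both", "D", config.effect_log2,
                       False, True))
    for i in take(config.n_alt_init):
        events.append((i, "alt_init", "both", None, 0.0, False, True))

    annotations: list[ProcessingAnnotation] = []
    alt_init: list[tuple[str, int]] = []
    truth_rows = []
    accs = [f"SIM{i:05d}" for i in range(config.n_proteins)]

    for i, event_type, cls, p1r, true_log2, treated_only, acet_neo in events:
        seq = sequences[i]
        L = len(seq)
        if event_type == "processing":
            transit_len = int(rng.integers(20, 41))
            p1 = transit_len
            annotations.append(ProcessingAnnotation(accs[i], "transit_peptide",
                                                    1, transit_len))
        else:
            p1 = int(rng.integers(60, L - _ZONE_LEN - 5))
        if p1r is None:
            p1r = str(rng.choice(non_kr))
        _plant_site(seq, p1, p1r, cls, rng, non_kr, non_kr_p)
        if event_type == "alt_init":
            alt_init.append((accs[i], p1 + 1))
        truth_rows.append({
            "accession": accs[i],
            "event_type": event_type,
            "p1_position": p1,
            "neo_start": p1 + 1,
            "p1_residue": seq[p1 - 1],
            "planted_class": cls,
            "true_log2": true_log2,
            "treated_only": treated_only,
            "acetylated_neo": acet_neo,
        })

    proteome: dict[str, ProteinRecord] = {}
    for i, acc in enumerate(accs):
        proteome[acc] = ProteinRecord(accession=acc, sequence="".join(sequences[i]),
                                      entry_name=f"{acc}_SIM")

    # ORF truth rows (Met excision + cotranslational acetylation states)
    met_excised = rng.random(config.n_proteins) < config.p_met_excision
    acetylated = rng.random(config.n_proteins) < config.p_orf_acetylation
    for i, acc in enumerate(accs):
        truth_rows.append({
            "accession": acc,
            "event_type": "orf",
            "p1_position": 0,
            "neo_start": 2 if met_excised[i] else 1,
            "p1_residue": None,
            "planted_class": None,
            "true_log2": 0.0,
            "treated_only": False,
            "acetylated_neo": bool(acetylated[i]),
        })

    truth = pd.DataFrame(truth_rows)
    # observable_by is never set by hand: recompute through the digestion engine
    observable = []
    for row in truth.itertuples(index=False):
        rec = proteome[row.accession]
        methods = []
        for method in METHODS:
            pep = peptide_from_start(rec, int(row.neo_start), method)
            if is_identifiable(len(pep), config.window):
                methods.append(method)
        observable.append("+".join(methods))
    truth = truth.assign(observable_by=observable)
    return proteome, truth, annotations, alt_init


def _emit_psms(dataset_rows: list, method: str, rec: ProteinRecord,
               start: int, nterm_mod: str, true_log2: float,
               treated_only: bool, n_psm: int, config: SimConfig,
               rng: np.random.Generator, counter: list[int],
               category_truth: str) -> None:
    pep = peptide_from_start(rec, start, method)
    enzyme = "LysN" if method == "LATE" else "trypsin_argc"
    for _ in range(n_psm):
        counter[0] += 1
        base = 2.0 ** rng.normal(17.0, 1.5)
        noise = rng.normal(0.0, config.ratio_noise_sigma) \
            if config.ratio_noise_sigma > 0 else 0.0
        ratio = 2.0 ** (true_log2 + noise + config.global_mix_bias_log2)
        if config.orientation == "heavy=treated":
            light, heavy = base, base * ratio
        else:
            light, heavy = base * ratio, base
        if treated_only:
            if config.orientation == "heavy=treated":
                light = 0.0
            else:
                heavy = 0.0
        kmods = []
        if enzyme == "trypsin_argc":
            # HYTANE chemistry labels every lysine side chain
            label = "dimethyl_heavy" if config.orientation == "heavy=treated" \
                else "dimethyl_light"
            kmods = [(k + 1, label) for k, ch in enumerate(pep.sequence)
                     if ch == "K"]
        elif config.epsilon_label_rate > 0:
            kmods = [(k + 1, "dimethyl_light")
                     for k, ch in enumerate(pep.sequence)
                     if ch == "K" and rng.random() < config.epsilon_label_rate]
        dataset_rows.append((
            NTermObservation(
                spectrum_id=f"{method}.{counter[0]:06d}",
                run_id=f"{method}_run1",
                sample_id="casp3_vs_ctrl",
                peptide=pep.sequence,
                mods=ModificationState(nterm_mod=nterm_mod,
                                       lysine_mods=tuple(kmods)),
                enzyme=enzyme,
                probability=0.99,
                light_area=light,
                heavy_area=heavy,
            ),
            category_truth,
        ))


def simulate_experiment(
    proteome: Mapping[str, ProteinRecord],
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, list[tuple[NTermObservation, str]]]:
    """Emit PSMs for every truth event in each workflow that can observe it.

    Returns per method a list of (observation, truth category) pairs; the
    truth category is the classification label the pipeline should recover
    ("ORF_start1"/"ORF_start2"/"neo"/"internal").
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    out: dict[str, list] = {m: [] for m in METHODS}
    counters = {m: [0] for m in METHODS}

    for row in truth.itertuples(index=False):
        rec = proteome[row.accession]
        methods = [m for m in row.observable_by.split("+") if m]
        if row.event_type == "orf":
            start = int(row.neo_start)
            nterm = "acetyl" if row.acetylated_neo else "dimethyl_light"
            category = "ORF_start1" if start == 1 else "ORF_start2"
            n_psm = config.psm_per_orf
        else:
            start = int(row.neo_start)
            nterm = "acetyl" if row.acetylated_neo else "dimethyl_light"
            category = "neo"
            n_psm = config.psm_per_event
        for method in methods:
            _emit_psms(out[method], method, rec, start, nterm,
                       float(row.true_log2), bool(row.treated_only),
                       n_psm, config, rng, counters[method], category)

    # internal-peptide background (NET = 2, free unlabeled alpha-amine)
    accs = list(proteome)
    for method in METHODS:
        n_terminal = len(out[method])
        f = config.internal_fraction
        n_internal = int(round(f / (1.0 - f) * n_terminal)) if f > 0 else 0
        protease = METHOD_PROTEASE[method]
        made = 0
        while made < n_internal:
            rec = proteome[accs[int(rng.integers(0, len(accs)))]]
            frags = [p for p in run_digest(rec, protease, 0)
                     if p.start > 2 and is_identifiable(len(p), config.window)]
            if not frags:
                continue
            frag = frags[int(rng.integers(0, len(frags)))]
            counters[method][0] += 1
            base = 2.0 ** rng.normal(17.0, 1.5)
            noise = rng.normal(0.0, config.ratio_noise_sigma) \
                if config.ratio_noise_sigma > 0 else 0.0
            ratio = 2.0 ** (noise + config.global_mix_bias_log2)
            enzyme = "LysN" if method == "LATE" else "trypsin_argc"
            kmods = []
            if config.epsilon_label_rate > 0:
                kmods = [(k + 1, "dimethyl_light")
                         for k, ch in enumerate(frag.sequence)
                         if ch == "K" and rng.random() < config.epsilon_label_rate]
            out[method].append((
                NTermObservation(
                    spectrum_id=f"{method}.{counters[method][0]:06d}",
                    run_id=f"{method}_run1",
                    sample_id="casp3_vs_ctrl",
                    peptide=frag.sequence,
                    mods=ModificationState(nterm_mod="free",
                                           lysine_mods=tuple(kmods)),
                    enzyme=enzyme,
                    probability=0.99,
                    light_area=base,
                    heavy_area=base * ratio,
                ),
                "internal",
            ))
            made += 1
    return out


def generate(config: SimConfig) -> SimDataset:
    """Run the full simulation: proteome + truth + PSMs, one seeded stream."""
    rng = np.random.default_rng(config.seed)
    proteome, truth, annotations, alt_init = make_proteome(config, rng)
    labelled = simulate_experiment(proteome, truth, config, rng)
    observations = {m: [obs for obs, _ in rows] for m, rows in labelled.items()}
    # carry the truth category of every PSM for classification scoring
    truth_categories = {
        m: pd.DataFrame(
            {"spectrum_id": [o.spectrum_id for o, _ in rows],
             "truth_category": [c for _, c in rows]})
        for m, rows in labelled.items()
    }
    truth = truth.copy()
    truth.attrs["psm_truth"] = truth_categories
    known = [
        KnownCleavageSite(r.accession, int(r.p1_position), "simulated_db")
        for r in truth.itertuples(index=False)
        if r.event_type == "caspase" and not r.treated_only
    ][: config.n_caspase_sites // 3]  # a third of spiked sites are "previously reported"
    return SimDataset(config, proteome, truth, annotations, alt_init,
                      known, observations)


def write_dataset(dataset: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text files (FASTA + TSVs), byte-stable."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"proteome": outdir / "proteome.fasta"}
    write_proteome(dataset.proteome, paths["proteome"])

    truth = dataset.truth.drop(columns=[], errors="ignore").copy()
    truth["true_log2"] = truth["true_log2"].map(lambda v: f"{v:.4f}")
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)

    paths["annotations"] = outdir / "annotations.tsv"
    with open(paths["annotations"], "w") as fh:
        fh.write("accession\tfeature_type\tstart\tend\n")
        for ann in dataset.annotations:
            fh.write(f"{ann.accession}\t{ann.feature_type}\t{ann.start}\t{ann.end}\n")

    paths["alt_init"] = outdir / "alt_init.tsv"
    with open(paths["alt_init"], "w") as fh:
        fh.write("accession\tposition\n")
        for acc, pos in dataset.alt_init:
            fh.write(f"{acc}\t{pos}\n")

    paths["known_sites"] = outdir / "known_sites.tsv"
    with open(paths["known_sites"], "w") as fh:
        fh.write("accession\tp1_position\tsource\n")
        for ks in dataset.known_sites:
            fh.write(f"{ks.accession}\t{ks.p1_position}\t{ks.source}\n")

    for method, obs in dataset.observations.items():
        p = outdir / f"psms_{method}.tsv"
        write_psm_tsv(obs, p)
        paths[f"psms_{method}"] = p
    return paths


def score_recovery(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    event_types: Sequence[str] = ("caspase",),
    require_observable: bool = True,
) -> dict:
    """Exact set arithmetic of predicted vs planted cleavage sites.

    ``predicted`` needs accession and p1_position columns. Recall is over
    planted events of the requested types (restricted, by default, to events
    at least one workflow can observe — unobservable events emit no data).
    Precision is over predictions that match any planted non-ORF event.
    """
    if not {"accession", "p1_position"} <= set(predicted.columns):
        raise KeyError("predicted table needs accession and p1_position columns")
    pred = set(zip(predicted["accession"], predicted["p1_position"].astype(int)))
    t = truth[truth["event_type"].isin(event_types)]
    if require_observable:
        t = t[t["observable_by"] != ""]
    target = set(zip(t["accession"], t["p1_position"].astype(int)))
    tp = len(pred & target)
    return {
        "n_predicted": len(pred),
        "n_true": len(target),
        "true_positives": tp,
        "precision": tp / len(pred) if pred else (1.0 if not target else 0.0),
        "recall": tp / len(target) if target else 1.0,
    }
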