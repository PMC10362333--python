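"""Ingestion of search-engine / quantification outputs into N-terminal
peptide-spectrum-match (PSM) records.

Two readers share one record contract:

* a documented TSV dialect (the package's reference interchange format, also
  written by the simulator), and
* pepXML as produced by a TPP-style Comet + PeptideProphet + XPRESS run.

Modification deltas are mapped to named states by monoisotopic mass. The
isotopic dimethyl pair used for two-channel quantification:

* light dimethyl, +C2H4 = +28.031300 Da (CH2O formaldehyde + reduction),
* heavy dimethyl, +13C2D4 = +34.063117 Da (13CD2-formaldehyde),

6.031817 Da apart, far above the 0.01 Da matching tolerance. N-terminal
acetylation adds C2H2O = +42.010565 Da.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import pepxml as _pepxml

__all__ = [
    "MOD_MASSES",
    "ModificationState",
    "NTermObservation",
    "IngestReport",
    "assign_mod_names",
    "name_for_mass",
    "read_psm_tsv",
    "write_psm_tsv",
    "read_pepxml",
    "PSM_TSV_COLUMNS",
]

# Monoisotopic deltas (Da) from standard atomic masses:
# H 1.0078250319, C 12, 13C 13.0033548351, D 2.0141017779, O 15.9949146221
MOD_MASSES: Mapping[str, float] = {
    "free": 0.0,
    "dimethyl_light": 28.031300,   # 2 C + 4 H
    "dimethyl_heavy": 34.063117,   # 2 13C + 4 D
    "acetyl": 42.010565,           # 2 C + 2 H + O
}

#: pepXML reports terminal/residue mod masses as totals; these are the
#: unmodified masses subtracted to recover the delta.
H_MASS = 1.0078250319
LYS_RESIDUE_MASS = 128.0949630177

ENZYMES = ("LysN", "trypsin_argc")

PSM_TSV_COLUMNS = [
    "spectrum_id", "run_id", "sample_id", "peptide", "nterm_mod_mass",
    "lysine_mod_masses", "enzyme", "probability", "light_area", "heavy_area",
]


class IngestError(ValueError):
    pass


def name_for_mass(delta: float, tolerance: float = 0.01,
                  registry: Mapping[str, float] = MOD_MASSES) -> str:
    """Nearest named modification within ``tolerance`` Da of ``delta``;
    "unknown" when nothing matches; error when two names are ambiguous."""
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    hits = [name for name, mass in registry.items()
            if math.isclose(delta, mass, abs_tol=tolerance)]
    if len(hits) > 1:
        raise IngestError(
            f"mass {delta} matches several named modifications at tolerance "
            f"{tolerance}: {hits}"
        )
    return hits[0] if hits else "unknown"


@dataclass(frozen=True)
class ModificationState:
    """Named N-terminal and lysine-side-chain modification assignments.

    ``lysine_mods`` holds (1-based position within the peptide, name) pairs;
    unmodified lysines are omitted. ``raw_masses`` keeps unmatched deltas.
    """

    nterm_mod: str = "free"
    lysine_mods: tuple = ()
    raw_masses: tuple = ()

    @property
    def nterm_labeled(self) -> bool:
        return self.nterm_mod in ("dimethyl_light", "dimethyl_heavy")

    @property
    def nterm_blocked(self) -> bool:
        """Labeled by dimethylation or naturally blocked by acetylation."""
        return self.nterm_labeled or self.nterm_mod == "acetyl"


def assign_mod_names(
    nterm_delta: float = 0.0,
    lysine_deltas: Sequence[tuple[int, float]] = (),
    tolerance: float = 0.01,
    registry: Mapping[str, float] = MOD_MASSES,
) -> ModificationState:
    """Map observed delta masses to a :class:`ModificationState`."""
    raw = []
    nterm = name_for_mass(nterm_delta, tolerance, registry)
    if nterm == "unknown":
        raw.append(("nterm", round(nterm_delta, 6)))
    kmods = []
    for pos, delta in lysine_deltas:
        name = name_for_mass(delta, tolerance, registry)
        if name == "unknown":
            raw.append((pos, round(delta, 6)))
        elif name != "free":
            kmods.append((int(pos), name))
    return ModificationState(nterm_mod=nterm, lysine_mods=tuple(kmods),
                             raw_masses=tuple(raw))


@dataclass(frozen=True)
class NTermObservation:
    """One PSM-level record with two-channel quantification.

    ``raw_ratio`` is fixed here as heavy_area / light_area when both channels
    are present (direction semantics — which channel is the treated sample —
    are applied downstream in quantification). A record observed in only one
    channel is a *singleton*: ``raw_ratio`` is None and ``singleton_channel``
    records the side.
    """

    spectrum_id: str
    run_id: str
    sample_id: str
    peptide: str
    mods: ModificationState
    enzyme: str
    probability: float
    light_area: float
    heavy_area: float

    def __post_init__(self) -> None:
        if not self.peptide:
            raise IngestError("empty peptide")
        if self.light_area < 0 or self.heavy_area < 0:
            raise IngestError(f"{self.spectrum_id}: negative channel area")

    @property
    def raw_ratio(self) -> float | None:
        if self.light_area > 0 and self.heavy_area > 0:
            return self.heavy_area / self.light_area
        return None

    @property
    def singleton_channel(self) -> str | None:
        if self.light_area > 0 and self.heavy_area == 0:
            return "light_only"
        if self.heavy_area > 0 and self.light_area == 0:
            return "heavy_only"
        return None


@dataclass
class IngestReport:
    n_rows: int = 0
    n_kept: int = 0
    n_below_probability: int = 0
    rejected: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def check_conserved(self) -> bool:
        """Row conservation: nothing invented or silently dropped."""
        return self.n_rows == self.n_kept + self.n_below_probability + self.n_rejected


def _parse_lysine_field(text: str) -> list[tuple[int, float]]:
    """Parse 'pos:mass;pos:mass' into (position, delta) pairs."""
    if not text or (isinstance(text, float) and math.isnan(text)):
        return []
    out = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        pos, mass = token.split(":")
        out.append((int(pos), float(mass)))
    return out


def read_psm_tsv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    probability_floor: float = 0.95,
    tolerance: float = 0.01,
) -> tuple[list[NTermObservation], IngestReport]:
    """Read the PSM TSV dialect.

    ``schema`` optionally remaps file column names onto the canonical ones
    (``{"canonical": "file_column"}``). Rows below the probability floor are
    dropped and counted; rows with unparseable numerics are rejected and
    reported. ``n_rows == n_kept + n_below_probability + n_rejected`` always.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = set(PSM_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise IngestError(f"PSM table missing required columns: {sorted(missing)}")

    report = IngestReport(n_rows=len(df))
    observations = []
    for row in df.itertuples(index=False):
        try:
            prob = float(row.probability)
            light = float(row.light_area)
            heavy = float(row.heavy_area)
            nterm = float(row.nterm_mod_mass)
            kdeltas = _parse_lysine_field(row.lysine_mod_masses)
        except (TypeError, ValueError) as exc:
            report.rejected.append(f"{row.spectrum_id}: {exc}")
            continue
        if prob < probability_floor:
            report.n_below_probability += 1
            continue
        try:
            obs = NTermObservation(
                spectrum_id=str(row.spectrum_id),
                run_id=str(row.run_id),
                sample_id=str(row.sample_id),
                peptide=str(row.peptide),
                mods=assign_mod_names(nterm, kdeltas, tolerance),
                enzyme=str(row.enzyme),
                probability=prob,
                light_area=light,
                heavy_area=heavy,
            )
        except IngestError as exc:
            report.rejected.append(str(exc))
            continue
        observations.append(obs)
        report.n_kept += 1
    return observations, report


def write_psm_tsv(observations: Iterable[NTermObservation], path: str | Path) -> None:
    """Write observations in the reference TSV dialect (fixed float precision
    so outputs are byte-stable)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PSM_TSV_COLUMNS) + "\n")
        for obs in observations:
            kfield = ";".join(
                f"{pos}:{MOD_MASSES[name]:.6f}" for pos, name in obs.mods.lysine_mods
            )
            fh.write(
                f"{obs.spectrum_id}\t{obs.run_id}\t{obs.sample_id}\t{obs.peptide}\t"
                f"{MOD_MASSES.get(obs.mods.nterm_mod, 0.0):.6f}\t{kfield}\t"
                f"{obs.enzyme}\t{obs.probability:.4f}\t"
                f"{obs.light_area:.4f}\t{obs.heavy_area:.4f}\n"
            )


def _pepxml_mods(hit: Mapping, peptide: str,
                 tolerance: float) -> ModificationState:
    """Recover named modifications from a pyteomics search-hit dict.

    pepXML stores *total* masses (residue + modification); deltas are
    recovered by subtracting the proton (N terminus) or lysine residue mass.
    """
    nterm_delta = 0.0
    kdeltas = []
    modinfo = hit.get("modifications", [])
    for mod in modinfo:
        pos = int(mod.get("position", 0))
        mass = float(mod["mass"])
        if pos == 0:  # terminal modification, pyteomics convention
            nterm_delta = mass - H_MASS
        elif peptide[pos - 1] == "K":
            kdeltas.append((pos, mass - LYS_RESIDUE_MASS))
    return assign_mod_names(nterm_delta, kdeltas, tolerance)


def read_pepxml(
    path: str | Path,
    probability_floor: float = 0.95,
    tolerance: float = 0.01,
    run_id: str | None = None,
    sample_id: str = "",
    enzyme: str = "LysN",
) -> tuple[list[NTermObservation], IngestReport]:
    """Read a pepXML file (Comet/PeptideProphet/XPRESS style) into the same
    record contract as :func:`read_psm_tsv`.

    A search hit without an XPRESS quantification element becomes a singleton
    observation with zero areas in both channels set from whatever the file
    carries (absent quant → both zero, flagged by ``singleton_channel`` =
    None; such rows survive ingestion but are dropped at aggregation).
    """
    report = IngestReport()
    observations = []
    with _pepxml.read(str(path)) as reader:
        for query in reader:
            hits = query.get("search_hit", [])
            if not hits:
                continue
            hit = hits[0]
            report.n_rows += 1
            prob = 0.0
            light = heavy = 0.0
            for result in hit.get("analysis_result", []):
                if "peptideprophet_result" in result:
                    prob = float(result["peptideprophet_result"]["probability"])
                if "xpressratio_result" in result:
                    xr = result["xpressratio_result"]
                    light = float(xr.get("light_area", 0.0))
                    heavy = float(xr.get("heavy_area", 0.0))
            if prob < probability_floor:
                report.n_below_probability += 1
                continue
            peptide = hit["peptide"]
            try:
                obs = NTermObservation(
                    spectrum_id=str(query.get("spectrum", query.get("start_scan", ""))),
                    run_id=run_id or Path(path).stem,
                    sample_id=sample_id,
                    peptide=peptide,
                    mods=_pepxml_mods(hit, peptide, tolerance),
                    enzyme=enzyme,
                    probability=prob,
                    light_area=light,
                    heavy_area=heavy,
                )
            except IngestError as exc:
                report.rejected.append(str(exc))
                continue
            observations.append(obs)
            report.n_kept += 1
    return observations, report
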