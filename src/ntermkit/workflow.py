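"""End-to-end pipeline orchestration.

Chains the package's stages over one simulated (or user-supplied) dataset:

    PSM TSVs → ingest → classify against the proteome → per-run median
    normalization → key-level aggregation → fixed-threshold significance →
    caspase winnow → minimum evidence → reported/novel annotation →
    neo-Nt-acetylation winnow → form co-occurrence.

All TSV outputs are written with fixed float precision, so a pipeline run on
a fixed simulation config is byte-reproducible.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Mapping

import pandas as pd

from .classify import classify_all
from . import quant as qt
from . import winnow as wn
from .digest import ARGC_LIKE, LYSN
from .psms import read_psm_tsv
from .sequences import KnownCleavageSite, ProcessingAnnotation, ProteinRecord
from .simulate import SimConfig, SimDataset, generate, write_dataset

__all__ = ["PROTEASES_BY_ENZYME", "run_pipeline", "pipeline_from_simulation"]

PROTEASES_BY_ENZYME = {"LysN": LYSN, "trypsin_argc": ARGC_LIKE}


def run_pipeline(
    psm_paths: Mapping[str, str | Path],
    proteome: Mapping[str, ProteinRecord],
    annotations: list[ProcessingAnnotation] = (),
    alt_init: list[tuple[str, int]] = (),
    known_tables: Mapping[str, list[KnownCleavageSite]] | None = None,
    p1_set: str = "D",
    fold_threshold: float = 2.0,
    min_evidence_k: int = 2,
    orientation: str = "heavy=treated",
    outdir: str | Path | None = None,
) -> dict:
    """Run the full analysis over PSM TSV files (one per method/run batch).

    Returns a dict with the classified PSM table, quantified records,
    winnowed caspase sites, neo-acetylation routing outputs, stage logs and
    normalization constants. With ``outdir`` every major table is also
    written as a TSV with fixed float precision.
    """
    observations = []
    ingest_reports = {}
    for label, path in psm_paths.items():
        obs, report = read_psm_tsv(path)
        observations.extend(obs)
        ingest_reports[label] = report

    classified = classify_all(observations, proteome, PROTEASES_BY_ENZYME)
    normalized, norm_constants = qt.normalize_runs(classified)
    quantified = qt.aggregate(normalized, orientation=orientation)
    quantified = qt.call_significant(quantified, fold_threshold=fold_threshold)

    neo = quantified[quantified["category"] == "neo"].reset_index(drop=True)
    winnowed, caspase_log = wn.caspase_winnow(neo, p1_set=p1_set)
    winnowed = wn.min_evidence(winnowed, k=min_evidence_k, log=caspase_log)
    if known_tables:
        winnowed = wn.annotate_reported(winnowed, known_tables)

    neo_for_acet = quantified.copy()
    acet_outputs, acet_log = wn.neo_acetylation_winnow(
        neo_for_acet, annotations, alt_init, caspase_sites=winnowed,
        p1_set=p1_set if len(set(p1_set)) > 1 else p1_set + "E",
    )
    cooccurrence = wn.form_cooccurrence(classified)

    results = {
        "classified": classified,
        "quantified": quantified,
        "winnowed_caspase": winnowed,
        "caspase_log": caspase_log,
        "neo_acetylation": acet_outputs,
        "neo_acetylation_log": acet_log,
        "form_cooccurrence": cooccurrence,
        "normalization_constants": norm_constants,
        "ingest_reports": ingest_reports,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write = lambda df, name: df.to_csv(
            outdir / name, sep="\t", index=False, float_format="%.6f")
        _write(classified.drop(columns=["window_P4_P4p"]), "classified_psms.tsv")
        _write(quantified.assign(
            runs=quantified["runs"].map(lambda t: "+".join(t)),
            methods=quantified["methods"].map(lambda t: "+".join(t)),
        ), "quantified.tsv")
        _write(winnowed.assign(
            runs=winnowed["runs"].map(lambda t: "+".join(t)),
            methods=winnowed["methods"].map(lambda t: "+".join(t)),
            **({"reported_sources": winnowed["reported_sources"].map(
                lambda t: "+".join(t))} if "reported_sources" in winnowed else {}),
        ), "winnowed_caspase_sites.tsv")
        _write(caspase_log.as_frame(), "caspase_winnow_log.tsv")
        for name, table in acet_outputs.items():
            t = table.copy()
            for col in ("runs", "methods"):
                if col in t.columns:
                    t[col] = t[col].map(lambda v: "+".join(v))
            _write(t, f"neo_acetylation_{name}.tsv")
        _write(acet_log.as_frame(), "neo_acetylation_log.tsv")
        _write(cooccurrence, "form_cooccurrence.tsv")
    return results


def pipeline_from_simulation(
    config: SimConfig,
    workdir: str | Path | None = None,
    outdir: str | Path | None = None,
) -> tuple[SimDataset, dict]:
    """Simulate a dataset, round-trip it through the TSV interchange files,
    and run the full pipeline on what was read back."""
    dataset = generate(config)
    if workdir is None:
        tmp = tempfile.TemporaryDirectory()
        workdir = tmp.name
    paths = write_dataset(dataset, workdir)
    psm_paths = {m: paths[f"psms_{m}"] for m in dataset.observations}
    results = run_pipeline(
        psm_paths,
        dataset.proteome,
        annotations=dataset.annotations,
        alt_init=dataset.alt_init,
        known_tables={"simulated_db": dataset.known_sites},
        p1_set=config.p1_set,
        orientation=config.orientation,
        outdir=outdir,
    )
    return dataset, results
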