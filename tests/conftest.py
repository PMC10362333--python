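"""Shared fixtures: the coordinate-convention exemplar, toy proteomes, and
session-scoped simulation runs used by several module suites."""

from __future__ import annotations

import numpy as np
import pytest

import ntermkit as nk
from ntermkit.sequences import AA20, ProteinRecord

# ---------------------------------------------------------------------------
# Coordinate convention exemplar, shared by every module's tests:
# protein AADEVDGSKL, DEVD motif with P1 = Asp at residue 6, scissile bond
# 6|7, neo-N-terminal peptide starting at residue 7 (G).
# ---------------------------------------------------------------------------
CONVENTION_SEQ = "AADEVDGSKL"
CONVENTION_P1 = 6
CONVENTION_NEO_START = 7


@pytest.fixture(scope="session")
def convention_protein() -> ProteinRecord:
    return ProteinRecord(accession="CONV1", sequence=CONVENTION_SEQ)


def random_protein(rng: np.random.Generator, min_len: int = 50,
                   max_len: int = 500, accession: str = "RND") -> ProteinRecord:
    L = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list(AA20), size=L))
    return ProteinRecord(accession=accession, sequence=seq)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230524)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (never share code with the implementation).
# ---------------------------------------------------------------------------

def brute_force_digest(seq: str, side: str, residues: set,
                       blocked_next: set = frozenset()) -> list[tuple[int, int, str]]:
    """Scan every bond, split, and return (start, end, sequence) fragments."""
    cut_after = []
    for b in range(1, len(seq)):  # bond after residue b (1-based)
        left, right = seq[b - 1], seq[b]
        if side == "C" and left in residues and right not in blocked_next:
            cut_after.append(b)
        if side == "N" and right in residues:
            cut_after.append(b)
    frags = []
    start = 1
    for b in cut_after + [len(seq)]:
        frags.append((start, b, seq[start - 1:b]))
        start = b + 1
    return frags


def brute_force_motif_scan(seq: str, motif: list[str]) -> list[int]:
    """P1 positions of all motif matches (each motif element = allowed set)."""
    L = len(motif)
    hits = []
    for p1 in range(L, len(seq)):  # exclude p1 == len(seq): no downstream residue
        if all(seq[p1 - L + k] in motif[k] for k in range(L)):
            hits.append(p1)
    return hits


def brute_force_frequency_matrix(windows: list[str]) -> dict:
    """Per-column amino-acid frequency over non-'-' residues."""
    width = len(windows[0])
    out = {}
    for col in range(width):
        residues = [w[col] for w in windows if w[col] != "-"]
        n = len(residues)
        out[col] = {aa: residues.count(aa) / n for aa in set(residues)} if n else {}
    return out


# ---------------------------------------------------------------------------
# Session-scoped simulation runs (expensive; shared across suites).
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the package's reference simulation conditions."""
    config = nk.SimConfig(seed=11)
    dataset, results = nk.pipeline_from_simulation(config)
    return config, dataset, results


@pytest.fixture(scope="session")
def noiseless_run():
    """Smaller noiseless simulation for exact winnow/routing checks."""
    config = nk.SimConfig(
        seed=5, n_proteins=500, n_caspase_sites=80, n_background_cleavages=40,
        n_treated_only=8, n_processing=6, n_neo_acetylation=10, n_alt_init=5,
        ratio_noise_sigma=0.0,
    )
    dataset, results = nk.pipeline_from_simulation(config)
    return config, dataset, results
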