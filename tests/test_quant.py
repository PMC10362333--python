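"""Two-channel quantification: normalization, aggregation, thresholding."""

import math

import numpy as np
import pandas as pd
import pytest

import ntermkit as nk
from ntermkit.quant import (
    aggregate,
    call_significant,
    normalize_runs,
    pair_forms,
    susceptibility_table,
)


def _psm_frame(rows):
    """rows: (run, accession, start, state, light, heavy[, peptide])"""
    records = []
    for i, row in enumerate(rows):
        run, acc, start, state, light, heavy = row[:6]
        peptide = row[6] if len(row) > 6 else "GSAAELVK"
        records.append({
            "spectrum_id": f"s{i}", "run_id": run, "sample_id": "a",
            "enzyme": "LysN", "peptide": peptide, "accession": acc,
            "start": start, "category": "neo", "nterm_state": state,
            "p1_residue": "D", "light_area": float(light),
            "heavy_area": float(heavy),
        })
    return pd.DataFrame(records)


class TestNormalizeRuns:
    def test_median_centering(self):
        df = _psm_frame([("r1", "P1", 10, "free_labeled", 100, 100 * r)
                         for r in (1, 2, 4)])
        out, constants = normalize_runs(df)
        log2r = np.log2(out["heavy_area_norm"] / out["light_area"])
        assert sorted(np.round(log2r, 9)) == [-1.0, 0.0, 1.0]
        assert abs(np.median(log2r)) < 1e-9
        assert constants["r1"] == pytest.approx(1.0)

    def test_idempotent_on_centered_run(self):
        df = _psm_frame([("r1", "P1", 10, "free_labeled", 100, 100 * r)
                         for r in (0.5, 1, 2)])
        once, _ = normalize_runs(df)
        twice, constants = normalize_runs(
            once.assign(heavy_area=once["heavy_area_norm"]))
        assert constants["r1"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(once["heavy_area_norm"], twice["heavy_area_norm"])

    def test_global_scaling_invariance(self):
        rows = [("r1", "P1", i, "free_labeled", 100, 100 * r)
                for i, r in enumerate((0.5, 1.7, 3, 8), start=10)]
        plain, _ = normalize_runs(_psm_frame(rows))
        scaled, _ = normalize_runs(
            _psm_frame([(r0, a, s, st, l, h * 10) for r0, a, s, st, l, h in rows]))
        assert np.allclose(
            plain["heavy_area_norm"] / plain["light_area"],
            scaled["heavy_area_norm"] / scaled["light_area"])

    def test_sparse_run_passes_through_with_warning(self, caplog):
        df = _psm_frame([("tiny", "P1", 10, "free_labeled", 100, 400),
                         ("tiny", "P1", 11, "free_labeled", 100, 400)])
        out, constants = normalize_runs(df)
        assert constants["tiny"] == 0.0
        assert np.allclose(out["heavy_area_norm"], out["heavy_area"])

    def test_singletons_untouched(self):
        df = _psm_frame(
            [("r1", "P1", i, "free_labeled", 100, 100 * r)
             for i, r in enumerate((1, 2, 4), start=10)]
            + [("r1", "P2", 50, "free_labeled", 0, 500)])
        out, _ = normalize_runs(df)
        singleton = out[out["accession"] == "P2"]
        # the zero light channel stays zero; heavy is rescaled like all rows
        assert float(singleton["light_area"].iloc[0]) == 0.0


class TestAggregate:
    def test_sum_of_areas_then_log2(self):
        df = _psm_frame([("r1", "P1", 10, "free_labeled", 50, 100),
                         ("r1", "P1", 10, "free_labeled", 50, 300)])
        out = aggregate(df)
        assert len(out) == 1
        assert out["log2_ratio"].iloc[0] == pytest.approx(2.0)  # 400/100
        assert out["psm_count"].iloc[0] == 2

    def test_singleton_direction_respects_orientation(self):
        df = _psm_frame([("r1", "P1", 10, "free_labeled", 80, 0),
                         ("r1", "P1", 10, "free_labeled", 20, 0)])
        heavy_treated = aggregate(df, orientation="heavy=treated")
        assert heavy_treated["singleton_channel"].iloc[0] == "control_only"
        light_treated = aggregate(df, orientation="light=treated")
        assert light_treated["singleton_channel"].iloc[0] == "treated_only"

    def test_bad_orientation_rejected(self):
        with pytest.raises(ValueError):
            aggregate(_psm_frame([("r1", "P1", 10, "free_labeled", 1, 1)]),
                      orientation="sideways")

    def test_oracle_equivalence_on_random_groupings(self, rng):
        rows = []
        for _ in range(300):
            acc = f"P{int(rng.integers(0, 20))}"
            start = int(rng.integers(5, 8))
            light = float(rng.uniform(10, 1000))
            heavy = float(rng.uniform(10, 1000))
            rows.append(("r1", acc, start, "free_labeled", light, heavy))
        df = _psm_frame(rows)
        df["heavy_area_norm"] = df["heavy_area"]  # skip normalization
        out = aggregate(df).set_index(["accession", "start"])
        # brute-force: sum per key, then log2
        sums: dict = {}
        for _, acc, start, _, light, heavy in rows:
            l0, h0 = sums.get((acc, start), (0.0, 0.0))
            sums[(acc, start)] = (l0 + light, h0 + heavy)
        for (acc, start), (light, heavy) in sums.items():
            assert out.loc[(acc, start), "log2_ratio"] == \
                pytest.approx(math.log2(heavy / light))

    def test_permutation_invariance(self, rng):
        rows = [("r1", "P1", 10, "free_labeled", float(l), float(h))
                for l, h in rng.uniform(10, 500, size=(8, 2))]
        df = _psm_frame(rows)
        shuffled = df.sample(frac=1.0, random_state=0)
        a = aggregate(df)["log2_ratio"].iloc[0]
        b = aggregate(shuffled)["log2_ratio"].iloc[0]
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_both_channels_dropped(self):
        df = _psm_frame([("r1", "P1", 10, "free_labeled", 0, 0)])
        assert aggregate(df).empty


class TestCallSignificant:
    def _frame(self, log2s, singletons=None):
        n = len(log2s)
        singletons = singletons or ["none"] * n
        return pd.DataFrame({
            "accession": [f"P{i}" for i in range(n)],
            "start": [10] * n, "nterm_state": ["free_labeled"] * n,
            "category": ["neo"] * n, "p1_residue": ["D"] * n,
            "peptide": ["GSAAELVK"] * n, "log2_ratio": log2s,
            "psm_count": [2] * n, "runs": [("r1",)] * n,
            "methods": [("LysN",)] * n, "singleton_channel": singletons,
        })

    def test_inclusive_threshold_at_log2_of_1(self):
        out = call_significant(self._frame([1.0, 0.99, 3.0]))
        assert list(out["significant"]) == [True, False, True]

    def test_strict_mode_excludes_the_boundary(self):
        out = call_significant(self._frame([1.0]), strict=True)
        assert not out["significant"].iloc[0]

    def test_treated_only_singleton_is_significant(self):
        out = call_significant(
            self._frame([None, None], ["treated_only", "control_only"]))
        assert list(out["significant"]) == [True, False]

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            call_significant(self._frame([1.0]), fold_threshold=1.0)


class TestPairForms:
    def _orf(self, rows):
        return pd.DataFrame([{
            "accession": acc, "start": start, "nterm_state": state,
            "category": "ORF_start2", "p1_residue": None,
            "peptide": "SDGSAAELVK", "log2_ratio": ratio, "psm_count": 2,
            "runs": ("r1",), "methods": ("LysN",), "singleton_channel": "none",
        } for acc, start, state, ratio in rows])

    def test_pairs_require_both_states(self):
        q = self._orf([
            ("P1", 2, "acetylated", 0.1), ("P1", 2, "free_labeled", -1.4),
            ("P2", 2, "acetylated", 0.3),
        ])
        result = pair_forms(q)
        assert result["n_pairs"] == 1
        assert result["n_single_state"] == 1
        pair = result["pairs"].iloc[0]
        assert pair["acetyl_log2_ratio"] == pytest.approx(0.1)
        assert pair["free_log2_ratio"] == pytest.approx(-1.4)

    def test_pair_count_equals_set_intersection(self, rng):
        rows = []
        accs = [f"P{i}" for i in range(40)]
        with_acet = set(a for a in accs if rng.random() < 0.6)
        with_free = set(a for a in accs if rng.random() < 0.6)
        for a in with_acet:
            rows.append((a, 2, "acetylated", float(rng.normal())))
        for a in with_free:
            rows.append((a, 2, "free_labeled", float(rng.normal())))
        result = pair_forms(self._orf(rows))
        assert result["n_pairs"] == len(with_acet & with_free)


class TestSusceptibility:
    def test_group_membership_and_partition(self):
        rows = [
            ("P1", "free_labeled", "SAAADK", 0.5),   # free, D/E present
            ("P2", "free_labeled", "SAAAGK", 0.1),   # free, no D/E
            ("P3", "acetylated", "SAEAGK", -0.2),    # acet, D/E present
            ("P4", "acetylated", "SAAAGK", 0.0),     # acet, no D/E
            ("P5", "free_labeled", "SAAEGK", -2.0),  # free, D/E present
        ]
        q = pd.DataFrame([{
            "accession": acc, "start": 2, "nterm_state": state,
            "category": "ORF_start2", "peptide": pep, "log2_ratio": ratio,
            "psm_count": 1, "runs": ("r1",), "methods": ("LysN",),
            "singleton_channel": "none",
        } for acc, state, pep, ratio in rows])
        table = susceptibility_table(q)
        assert int(table["n"].sum()) == len(rows)
        free_de = table[(table["nterm_group"] == "free") & table["has_DE"]]
        assert int(free_de["n"].iloc[0]) == 2
        assert free_de["median"].iloc[0] == pytest.approx((0.5 - 2.0) / 2)


class TestParameterRecovery:
    """Simulator-level recovery of the spiked effect size."""

    def test_spiked_keys_recovered_and_nulls_quiet(self, default_run):
        config, dataset, results = default_run
        truth = dataset.truth
        q = results["quantified"]
        neo = q[q["category"] == "neo"]

        spiked = truth[(truth["event_type"] == "caspase")
                       & ~truth["treated_only"] & (truth["observable_by"] != "")]
        keys = set(zip(spiked["accession"], spiked["neo_start"]))
        hits = neo[[k in keys for k in zip(neo["accession"], neo["start"])]]
        assert len(hits) >= 0.9 * len(spiked)
        errors = hits["log2_ratio"].astype(float) - config.effect_log2
        assert abs(errors.mean()) <= 0.15

        nulls = truth[(truth["event_type"] == "background")
                      & (truth["observable_by"] != "")]
        null_keys = set(zip(nulls["accession"], nulls["neo_start"]))
        null_hits = neo[[k in null_keys for k in zip(neo["accession"], neo["start"])]]
        assert len(null_hits) > 50
        fp_rate = float(null_hits["significant"].mean())
        assert fp_rate <= 0.02

    def test_global_mix_bias_removed_exactly(self):
        """A 1.5x mixing bias changes no post-normalization ratio by > 1e-9."""
        base = dict(seed=21, n_proteins=300, n_caspase_sites=40,
                    n_background_cleavages=20, n_treated_only=0, n_processing=0,
                    n_neo_acetylation=0, n_alt_init=0)
        plain = nk.generate(nk.SimConfig(**base))
        biased = nk.generate(nk.SimConfig(**base,
                                          global_mix_bias_log2=math.log2(1.5)))
        out = {}
        for name, ds in (("plain", plain), ("biased", biased)):
            obs = [o for rows in ds.observations.values() for o in rows]
            classified = nk.classify_all(obs, ds.proteome,
                                         {"LysN": nk.LYSN,
                                          "trypsin_argc": nk.ARGC_LIKE})
            normalized, _ = normalize_runs(classified)
            q = aggregate(normalized)
            out[name] = q.set_index(["accession", "start", "nterm_state"])["log2_ratio"]
        a, b = out["plain"].dropna(), out["biased"].dropna()
        assert set(a.index) == set(b.index)
        diff = (a - b.reindex(a.index)).abs().max()
        assert diff <= 1e-9
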