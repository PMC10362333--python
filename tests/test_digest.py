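"""Digestion engine, motif scanning and identifiability logic, checked
against independent per-bond brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntermkit.digest import (
    ARGC_LIKE,
    CASPASE3_MOTIF,
    LYSN,
    TRYPSIN_NO_P,
    CleavageSite,
    ProteaseSpec,
    coverage_report,
    digest,
    is_identifiable,
    nearest_residue_distance,
    neo_peptide,
    peptide_from_start,
    scan_motif,
)
from ntermkit.sequences import ProteinRecord

from conftest import (
    CONVENTION_NEO_START,
    CONVENTION_P1,
    brute_force_digest,
    brute_force_motif_scan,
    random_protein,
)


class TestDigest:
    def test_lysn_cleaves_before_lysine(self):
        peps = digest("MKAAKTR", LYSN, 0)
        assert [(p.start, p.end, p.sequence) for p in peps] == [
            (1, 1, "M"), (2, 4, "KAA"), (5, 7, "KTR")]

    def test_argc_cleaves_after_arginine(self):
        peps = digest("MARVKDR", ARGC_LIKE, 0)
        assert [(p.start, p.end, p.sequence) for p in peps] == [
            (1, 3, "MAR"), (4, 7, "VKDR")]

    def test_zero_length_protein_rejected(self):
        with pytest.raises(ValueError):
            digest("", LYSN, 0)

    @pytest.mark.parametrize("protease", [LYSN, ARGC_LIKE, TRYPSIN_NO_P],
                             ids=lambda p: p.name)
    def test_tiling_and_terminal_residues(self, protease, rng):
        for _ in range(50):
            rec = random_protein(rng)
            peps = digest(rec, protease, 0)
            assert "".join(p.sequence for p in peps) == rec.sequence
            if protease.side == "N":
                for p in peps[1:]:
                    assert p.sequence[0] in protease.residues
            else:
                for p in peps[:-1]:
                    assert p.sequence[-1] in protease.residues

    @pytest.mark.parametrize("protease", [LYSN, ARGC_LIKE, TRYPSIN_NO_P],
                             ids=lambda p: p.name)
    def test_oracle_equivalence(self, protease, rng):
        """Engine output equals an independent per-bond brute-force splitter."""
        for _ in range(200):
            rec = random_protein(rng)
            got = [(p.start, p.end, p.sequence) for p in digest(rec, protease, 0)]
            expected = brute_force_digest(
                rec.sequence, protease.side, set(protease.residues),
                set(protease.blocked_next))
            assert got == expected

    def test_missed_cleavages_enumerate_adjacent_unions(self, rng):
        rec = random_protein(rng, 80, 120)
        base = digest(rec, LYSN, 0)
        for m in (1, 2):
            expected = set()
            for i in range(len(base)):
                for j in range(i, min(i + m + 1, len(base))):
                    expected.add((base[i].start, base[j].end))
            got = {(p.start, p.end) for p in digest(rec, LYSN, m)}
            assert got == expected

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=200),
           protease=st.sampled_from([LYSN, ARGC_LIKE, TRYPSIN_NO_P]))
    def test_digest_properties_hold_on_arbitrary_sequences(self, seq, protease):
        """Tiling, terminal-residue rule and oracle agreement for arbitrary
        canonical sequences, including single residues and homopolymers."""
        peps = digest(seq, protease, 0)
        assert "".join(p.sequence for p in peps) == seq
        got = [(p.start, p.end, p.sequence) for p in peps]
        assert got == brute_force_digest(seq, protease.side,
                                         set(protease.residues),
                                         set(protease.blocked_next))

    def test_missed_cleavage_cap(self):
        with pytest.raises(ValueError):
            digest("MKAK", LYSN, 9)

    def test_blocked_next_suppresses_cleavage(self):
        # K followed by P is not cut by trypsin/P
        peps = digest("MAKPAKA", TRYPSIN_NO_P, 0)
        assert [p.sequence for p in peps] == ["MAKPAK", "A"]


class TestScanMotif:
    def test_devd_site_and_neo_start(self):
        rec = ProteinRecord("t", "AADEVDGK")
        sites = scan_motif(rec, "DEVD")
        assert len(sites) == 1
        assert sites[0].p1_position == 6
        assert sites[0].p1_residue == "D"
        assert sites[0].neo_start == 7

    def test_p1_at_last_residue_excluded(self):
        assert scan_motif(ProteinRecord("t", "DEVD"), "DEVD") == []

    def test_single_position_motif(self):
        sites = scan_motif(ProteinRecord("t", "MDAD"), ["D"])
        assert [s.p1_position for s in sites] == [2]  # last-residue D excluded

    def test_residue_set_positions(self):
        sites = scan_motif(ProteinRecord("t", "MDAEA"), ["DE"])
        assert [s.p1_position for s in sites] == [2, 4]

    def test_ambiguity_codes_never_match(self):
        # X/U/B/Z are tolerated in sequences but match no motif position
        sites = scan_motif(ProteinRecord("t", "XDXDA"), ["D"])
        assert [s.p1_position for s in sites] == [2, 4]
        assert scan_motif(ProteinRecord("t", "AXXA"), ["D"]) == []

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            scan_motif(ProteinRecord("t", "MDAD"), "")

    def test_oracle_equivalence(self, rng):
        motifs = ["DEVD", "D", ["DE"], ["D", "ES", "V", "DE"]]
        for _ in range(100):
            rec = random_protein(rng, 30, 200)
            for motif in motifs:
                sets = [motif[k] for k in range(len(motif))] if not isinstance(motif, str) \
                    else list(motif)
                got = [s.p1_position for s in scan_motif(rec, motif)]
                assert got == brute_force_motif_scan(rec.sequence, sets)


class TestNeoPeptide:
    def test_convention_neo_start_follows_p1(self, convention_protein):
        site = CleavageSite("CONV1", CONVENTION_P1, "D")
        pep = neo_peptide(convention_protein, site, "HYTANE")
        assert pep.start == CONVENTION_NEO_START

    def test_late_ends_before_first_downstream_lysine(self):
        rec = ProteinRecord("t", "MDGSAAKLL")
        pep = neo_peptide(rec, CleavageSite("t", 2, "D"), "LATE")
        assert (pep.start, pep.sequence, pep.runs_to_end) == (3, "GSAA", False)

    def test_hytane_ends_at_first_arginine_inclusive(self):
        rec = ProteinRecord("t", "MDGSARLL")
        pep = neo_peptide(rec, CleavageSite("t", 2, "D"), "HYTANE")
        assert (pep.start, pep.sequence, pep.runs_to_end) == (3, "GSAR", False)

    def test_runs_to_end_flag_when_no_terminator(self):
        rec = ProteinRecord("t", "MDGSAALL")
        pep = neo_peptide(rec, CleavageSite("t", 2, "D"), "HYTANE")
        assert pep.runs_to_end and pep.sequence == "GSAALL"

    def test_wrong_accession_rejected(self, convention_protein):
        with pytest.raises(ValueError):
            neo_peptide(convention_protein, CleavageSite("OTHER", 3, "D"), "LATE")

    def test_eif4h_style_site_coordinates(self):
        # a cleavage between Asp93 and Ser94: P1 index 93, neo start 94
        seq = "M" + "A" * 91 + "D" + "S" + "A" * 20 + "R" + "A" * 5
        rec = ProteinRecord("t", seq)
        assert rec.residue(93) == "D" and rec.residue(94) == "S"
        pep = neo_peptide(rec, CleavageSite("t", 93, "D"), "HYTANE")
        assert pep.start == 94


class TestIdentifiability:
    @pytest.mark.parametrize("length, expected",
                             [(6, False), (7, True), (35, True), (36, False)])
    def test_window_boundaries_inclusive(self, length, expected):
        assert is_identifiable(length, (7, 35)) is expected

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            is_identifiable(10, (35, 7))


class TestNearestResidueDistance:
    def test_counting_starts_at_one(self):
        rec = ProteinRecord("t", "GSAARAA")
        assert nearest_residue_distance(rec, 1, {"R"}) == 5

    def test_start_residue_itself(self):
        assert nearest_residue_distance(ProteinRecord("t", "RAA"), 1, {"R"}) == 1

    def test_absent_returns_none(self):
        assert nearest_residue_distance(ProteinRecord("t", "GSAA"), 1, {"R"}) is None


def _engineered_toy_proteome():
    """Three DEVD sites: HYTANE-only (R near, K far), LATE-only (K near,
    R far), and both-identifiable."""
    def body(k_off, r_off):
        # downstream zone of 45 alanines with K/R planted at 1-based offsets
        zone = ["A"] * 45
        zone[k_off - 1] = "K"
        zone[r_off - 1] = "R"
        return "M" + "G" * 10 + "DEVD" + "".join(zone) + "GG"
    return {
        "HONLY": ProteinRecord("HONLY", body(40, 10)),  # LATE len 39, HYTANE len 10
        "LONLY": ProteinRecord("LONLY", body(10, 40)),  # LATE len 9, HYTANE len 40
        "BOTH": ProteinRecord("BOTH", body(12, 10)),
    }


class TestCoverageReport:
    def test_engineered_counts_match_brute_force_plan(self):
        report = coverage_report(_engineered_toy_proteome(), CASPASE3_MOTIF)
        assert report["site_summary"] == {
            "LATE_only": 1, "HYTANE_only": 1, "both": 1, "neither": 0, "total": 3}
        by_acc = report["sites"].set_index("accession")["identifiable_by"]
        assert by_acc["HONLY"] == "HYTANE_only"
        assert by_acc["LONLY"] == "LATE_only"
        assert by_acc["BOTH"] == "both"

    def test_no_motif_matches_yields_empty_table(self):
        proteome = {"a": ProteinRecord("a", "MKKKKRRRR")}
        report = coverage_report(proteome, CASPASE3_MOTIF)
        assert report["site_summary"]["total"] == 0
        assert report["sites"].empty

    def test_partition_property_on_random_proteins(self, rng):
        proteome = {f"r{i}": random_protein(rng, 100, 400, f"r{i}") for i in range(200)}
        report = coverage_report(proteome, ["D"])
        s = report["site_summary"]
        assert s["LATE_only"] + s["HYTANE_only"] + s["both"] + s["neither"] == s["total"]
        assert s["total"] == len(report["sites"])

    def test_orf_forms_reported_separately(self):
        report = coverage_report(_engineered_toy_proteome(), CASPASE3_MOTIF)
        assert set(report["orf_summary"]) == {"start1", "start2"}
        for counts in report["orf_summary"].values():
            assert counts["total"] == 3

    def test_widening_window_is_monotone(self, rng):
        proteome = {f"r{i}": random_protein(rng, 100, 300, f"r{i}") for i in range(50)}
        narrow = coverage_report(proteome, ["D"], window=(7, 35))["site_summary"]
        wide = coverage_report(proteome, ["D"], window=(5, 50))["site_summary"]
        n_narrow = narrow["total"] - narrow["neither"]
        n_wide = wide["total"] - wide["neither"]
        assert n_wide >= n_narrow

    def test_complementarity_with_distance(self, rng):
        """A site is HYTANE-identifiable iff its nearest-R distance from the
        neo start lies in the window (the distance equals peptide length)."""
        for _ in range(50):
            rec = random_protein(rng, 60, 300)
            proteome = {rec.accession: rec}
            report = coverage_report(proteome, ["D"])
            for row in report["sites"].itertuples(index=False):
                d = nearest_residue_distance(rec, row.neo_start, {"R"})
                if d is not None:
                    # the peptide ends at that arginine: distance == length
                    assert row.HYTANE_length == d
                    assert not row.HYTANE_runs_to_end
                    assert row.HYTANE_identifiable == (7 <= d <= 35)
                else:
                    # censored: peptide runs to the C terminus, judged by length
                    assert row.HYTANE_runs_to_end
                    assert row.HYTANE_identifiable == (7 <= row.HYTANE_length <= 35)
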