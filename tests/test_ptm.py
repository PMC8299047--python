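"""Phosphosite bookkeeping, motif enrichment, kinome and acetyl occupancy."""

import math

import numpy as np
import pandas as pd
import pytest

from melamap.ptm import (DEFAULT_KINASE_MOTIFS, Motif, PhosphoPeptide,
                         acetyl_occupancy, classify_sites, enrich_motifs,
                         extract_window, kinome_union, multiplicity_histogram,
                         occupancy_distribution, occupancy_table, parse_motif,
                         predict_kinases, set_enrichment)
from melamap.synthetic import SimConfig, gen_acetylome, gen_phospho_table


def _pep(probs, residues=None, pid="P1"):
    residues = residues or tuple("S" for _ in probs)
    positions = tuple(10 + 5 * i for i in range(len(probs)))
    return PhosphoPeptide("AAASAAA", pid, positions, residues, tuple(probs))


class TestClassifySites:
    def test_threshold_is_inclusive(self):
        sites = classify_sites([_pep((0.75, 0.749))])
        assert [(s[1], s[3]) for s in sites] == [(10, 0.75)]

    def test_all_certain_sites_retained(self):
        assert len(classify_sites([_pep((1.0, 1.0, 1.0))])) == 3

    def test_matches_filter_oracle(self):
        rng = np.random.default_rng(0)
        peps = [_pep(tuple(rng.random(rng.integers(1, 4)))) for _ in range(50)]
        got = classify_sites(peps, threshold=0.6)
        expected = [(p.protein_id, pos, res, prob)
                    for p in peps
                    for pos, res, prob in zip(p.site_positions,
                                              p.site_residues,
                                              p.localization_probs)
                    if prob >= 0.6]
        assert got == expected


def test_multiplicity_histogram_bins():
    peps = [_pep((0.9,) * m) for m in (1, 1, 2, 3, 4)]
    assert multiplicity_histogram(peps) == (2, 1, 2)
    assert multiplicity_histogram([]) == (0, 0, 0)


class TestWindows:
    def test_interior_site_no_pads(self):
        seq = "ABCDEFGSIJKLMNOPQRST".replace("B", "A")
        win = extract_window(seq, 8)
        assert len(win.window) == 15
        assert win.window[7] == "S" == win.center_residue
        assert "_" not in win.window

    def test_n_terminal_site_padded(self):
        win = extract_window("SAAAAAAAAA", 1)
        assert win.window.startswith("_" * 7)
        assert win.window[7] == "S"

    def test_non_sty_center_rejected(self):
        with pytest.raises(ValueError, match="phospho-acceptor"):
            extract_window("AAAAAAAA", 1)

    def test_reconstructs_local_sequence_slicing_oracle(self):
        rng = np.random.default_rng(1)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seq = "".join(aa[rng.integers(0, 20, 40)])
        for pos in range(1, 41):
            if seq[pos - 1] not in "STY":
                continue
            win = extract_window(seq, pos).window
            padded = "_" * 7 + seq + "_" * 7
            assert win == padded[pos - 1:pos + 14]


class TestMotifs:
    def test_pattern_round_trip(self):
        m = parse_motif("R-x-x-S#")
        assert m.center == "S" and m.fixed == ((-3, "R"),)
        assert m.pattern == "R-x-x-S#"
        assert parse_motif("S#-P").pattern == "S#-P"

    def test_bad_patterns_rejected(self):
        with pytest.raises(ValueError):
            parse_motif("R-x-x-S")  # no center mark
        with pytest.raises(ValueError):
            parse_motif("A#-P")     # center not S/T/Y

    def test_planted_motif_recovered_first(self):
        sim = gen_phospho_table(seed=3, n_foreground=1500, n_background=15000,
                                planted_motif="R-x-x-S#",
                                planted_fraction=0.30)
        hits = enrich_motifs(sim.foreground_windows, sim.background_windows)
        assert hits, "no motif found"
        assert hits[0].motif.pattern == "R-x-x-S#"
        # planted count is ~30% of foreground plus chance co-occurrence
        assert hits[0].n_foreground >= sim.ground_truth.extras["n_planted"]

    def test_null_foreground_type_i_control(self):
        # foreground sampled from the background distribution: across 100
        # simulations at p_cutoff 1e-6, false motifs must be rare
        false_hits = 0
        for rep in range(100):
            sim = gen_phospho_table(seed=100 + rep, n_foreground=300,
                                    n_background=3000, planted_fraction=0.0)
            false_hits += len(enrich_motifs(sim.foreground_windows,
                                            sim.background_windows,
                                            min_occurrences=10))
        assert false_hits <= 5

    def test_single_window_below_min_occurrences(self):
        sim = gen_phospho_table(seed=5, n_foreground=200, n_background=2000)
        hits = enrich_motifs(sim.foreground_windows[:1],
                             sim.background_windows)
        assert hits == []

    def test_background_smaller_than_foreground_rejected(self):
        with pytest.raises(ValueError, match="background"):
            enrich_motifs(["A" * 7 + "S" + "A" * 7] * 3,
                          ["A" * 7 + "S" + "A" * 7] * 2)

    def test_deterministic(self):
        sim = gen_phospho_table(seed=6, n_foreground=800, n_background=8000)
        h1 = enrich_motifs(sim.foreground_windows, sim.background_windows)
        h2 = enrich_motifs(sim.foreground_windows, sim.background_windows)
        assert [(h.motif, h.p_cumulative) for h in h1] == \
            [(h.motif, h.p_cumulative) for h in h2]


class TestKinases:
    def _hit(self, pattern, n=100):
        from melamap.ptm import MotifHit
        return MotifHit(parse_motif(pattern), 1e-10, n, 5.0)

    def test_lookup_by_exact_motif(self):
        kin = predict_kinases([self._hit("S#-P")])
        assert {"CDK1", "CDK2", "MAPK1", "MAPK3", "GSK3B"} <= set(kin)
        assert kin["MAPK1"] == 100

    def test_table_motif_matches_as_subset(self):
        # enriched R-x-R-x-x-S# also satisfies the basophilic R-x-x-S#
        kin = predict_kinases([self._hit("R-x-R-x-x-S#")])
        assert "AKT1" in kin and "PRKACA" in kin

    def test_empty_motif_list(self):
        assert predict_kinases([]) == {}

    def test_planted_fixture_recovery(self):
        table = {"R-x-x-S#": ("KINASE_A",), "T#-P": ("KINASE_B",)}
        hits = [self._hit("R-x-x-S#", 40), self._hit("T#-P", 7)]
        assert predict_kinases(hits, table) == {"KINASE_A": 40, "KINASE_B": 7}


class TestKinomeUnion:
    def test_printed_counts_inclusion_exclusion(self):
        kinome = {f"K{i}" for i in range(620)}
        identified = {f"K{i}" for i in range(425)}
        # intersection of 147 follows from |identified|=425, |predicted|=244
        # and |union|=522 by inclusion-exclusion
        predicted = ({f"K{i}" for i in range(278, 425)}
                     | {f"K{i}" for i in range(425, 522)})
        assert len(predicted) == 244
        cov = kinome_union(identified, predicted, kinome)
        assert cov.union_count == 522
        assert len(identified & predicted) == 147
        assert cov.coverage_fraction == pytest.approx(100 * 522 / 620)
        assert cov.coverage_fraction > 84

    def test_disjoint_and_nested_cases(self):
        kinome = set(range(10))
        assert kinome_union({0, 1}, {2, 3}, kinome).union_count == 4
        assert kinome_union({0, 1, 2}, {1, 2}, kinome).union_count == 3

    def test_empty_kinome_rejected(self):
        with pytest.raises(ValueError):
            kinome_union({"a"}, set(), set())


class TestAcetylOccupancy:
    @pytest.mark.parametrize("light,heavy,expected", [
        (0.0, 100.0, 0.0), (50.0, 50.0, 50.0), (100.0, 0.0, 100.0)])
    def test_formula(self, light, heavy, expected):
        assert acetyl_occupancy(light, heavy) == expected

    def test_scale_invariance_and_undefined(self):
        assert acetyl_occupancy(3.0, 9.0) == acetyl_occupancy(300.0, 900.0)
        assert math.isnan(acetyl_occupancy(0.0, 0.0))
        with pytest.raises(ValueError):
            acetyl_occupancy(-1.0, 5.0)

    def test_noiseless_inversion_is_exact(self):
        cfg = SimConfig(occupancy_noise_sd=0.0, seed=2)
        table, truth = gen_acetylome(cfg, n_samples=5,
                                     sites_per_sample=(50, 100))
        occ = occupancy_table(table)
        expected = 100.0 * truth.true_occupancies[occ["site_key"]].to_numpy()
        assert np.allclose(occ["occupancy"].to_numpy(), expected, atol=1e-9)

    def test_noisy_recovery_error_below_two_points(self):
        cfg = SimConfig(seed=3)  # default multiplicative noise
        table, truth = gen_acetylome(cfg, n_samples=10,
                                     sites_per_sample=(500, 1000))
        occ = occupancy_table(table)
        err = np.abs(occ["occupancy"].to_numpy()
                     - 100.0 * truth.true_occupancies[occ["site_key"]].to_numpy())
        assert np.median(err) < 2.0

    def test_beta_low_occupancy_median(self):
        # alpha=1, beta=9: Beta median = 1 - 0.5**(1/9) ~ 7.4%
        cfg = SimConfig(occupancy_alpha=1.0, occupancy_beta=9.0, seed=4)
        table, _ = gen_acetylome(cfg, n_samples=2,
                                 sites_per_sample=(1000, 2000))
        occ = occupancy_table(table)
        assert occ["occupancy"].median() < 15.0


class TestOccupancyDistribution:
    def _table(self):
        return pd.DataFrame({
            "sample_id": ["A1"] * 3 + ["A2"] * 2,
            "group": ["primary"] * 3 + ["lymph_node"] * 2,
            "light_intensity": [10.0, 20.0, 30.0, 0.0, 5.0],
            "heavy_intensity": [90.0, 80.0, 70.0, 0.0, 95.0]})

    def test_per_sample_median_and_undefined_count(self):
        per_sample, per_group = occupancy_distribution(self._table())
        assert per_sample.loc["A1", "median"] == 20.0
        assert per_sample.loc["A2", "n_undefined"] == 1
        assert per_sample.loc["A2", "n"] == 1
        assert per_group.loc["primary", "median"] == 20.0

    def test_pooled_summary_invariant_to_group_permutation(self):
        t = self._table()
        pooled1 = occupancy_table(t)["occupancy"].median()
        t2 = t.assign(group=list(t["group"])[::-1])
        pooled2 = occupancy_table(t2)["occupancy"].median()
        assert pooled1 == pooled2


class TestSetEnrichment:
    def test_matches_exact_enumeration_on_toy(self):
        from itertools import combinations
        background = set(range(20))
        annotation = set(range(10))  # half of the background
        target = set(range(6))       # all inside the annotation
        res = set_enrichment(target, {"t": annotation}, background)
        k_obs = len(annotation & target)
        # exhaustive enumeration of all 6-subsets of the background
        total = hits = 0
        for comb in combinations(background, len(target)):
            total += 1
            if len(annotation & set(comb)) >= k_obs:
                hits += 1
        assert res.loc["t", "p_raw"] == pytest.approx(hits / total)

    def test_disjoint_annotation_no_enrichment(self):
        res = set_enrichment({1, 2}, {"t": {8, 9}}, set(range(10)))
        assert res.loc["t", "p_raw"] == pytest.approx(1.0)

    def test_target_equal_background_degenerate(self):
        bg = set(range(10))
        res = set_enrichment(bg, {"t": {0, 1, 2}}, bg)
        assert res.loc["t", "n_target"] == 3
        assert res.loc["t", "p_raw"] == pytest.approx(1.0)

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError):
            set_enrichment({99}, {"t": {1}}, {1, 2})
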