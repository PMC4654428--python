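import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rdsoil import screen, synth


class TestAnovaOneway:
    def test_all_equal_gives_zero_f(self):
        F, p = screen.anova_oneway({"a": [2, 2, 2], "b": [2, 2, 2]})
        assert F == 0.0
        assert p == 1.0

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        F, pF = screen.anova_oneway({"a": a, "b": b})
        t, pt = stats.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t ** 2, abs=1e-9)
        assert pF == pytest.approx(pt, abs=1e-9)

    def test_power_with_planted_five_sd_steps(self, rng):
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            groups = {"a": rng.normal(0, 1, 4), "b": rng.normal(5, 1, 4),
                      "c": rng.normal(10, 1, 4)}
            hits += screen.anova_oneway(groups)[1] < 0.001
        assert hits / n_runs >= 0.99

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            screen.anova_oneway({"a": [1, 2, 3]})


class TestTukeyLetters:
    def test_identical_groups_share_letter(self):
        letters, _ = screen.tukey_letters({"a": [1, 1, 1], "b": [1, 1, 1],
                                           "c": [1, 1, 1]})
        assert set(letters.values()) == {"a"}

    def test_forced_separation(self, rng):
        groups = {"g1": rng.normal(0, 1, 4), "g2": rng.normal(0, 1, 4),
                  "g3": rng.normal(100, 1, 4)}
        letters, _ = screen.tukey_letters(groups)
        assert letters["g1"] == letters["g2"] == "a"
        assert letters["g3"] == "b"

    def test_pairwise_p_matches_scipy(self, rng):
        arrays = [rng.normal(m, 1, 5) for m in (0, 1, 2)]
        P = screen.tukey_pairwise({"a": arrays[0], "b": arrays[1], "c": arrays[2]})
        ref = stats.tukey_hsd(*arrays).pvalue
        assert np.allclose(P.values, ref, atol=1e-12)

    def test_two_group_tukey_reduces_to_t_test(self, rng):
        # algebraic identity: for k=2 the studentized-range p equals the
        # pooled two-sided t-test p
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        P = screen.tukey_pairwise({"a": a, "b": b})
        _, pt = stats.ttest_ind(a, b, equal_var=True)
        assert P.loc["a", "b"] == pytest.approx(pt, abs=1e-7)

    def test_pairwise_p_against_permutation_oracle(self, rng):
        # 2 groups of 4: enumerate all C(8,4)=70 assignments of the pooled
        # values and compare the |mean difference| permutation p with the
        # Tukey p (exact t in the 2-group case); agreement is approximate
        a, b = rng.normal(0, 1, 4), rng.normal(1.5, 1, 4)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        hits = 0
        combos = list(itertools.combinations(range(8), 4))
        for combo in combos:
            mask = np.zeros(8, bool)
            mask[list(combo)] = True
            if abs(pooled[mask].mean() - pooled[~mask].mean()) >= obs - 1e-12:
                hits += 1
        perm_p = hits / len(combos)
        tukey_p = screen.tukey_pairwise({"a": a, "b": b}).loc["a", "b"]
        assert abs(perm_p - tukey_p) < 0.1

    def test_familywise_error_controlled(self, rng):
        # vectorized studentized-range oracle over 2000 null datasets, then
        # spot-check agreement of screen.tukey_letters on a few of them
        k, n, n_sim = 3, 4, 2000
        data = rng.normal(size=(n_sim, k, n))
        means = data.mean(axis=2)
        sse = ((data - means[..., None]) ** 2).sum(axis=(1, 2))
        mse = sse / (k * (n - 1))
        q = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(mse / n)
        pmin = stats.studentized_range.sf(q, k, k * (n - 1))
        fwe = (pmin < 0.05).mean()
        assert fwe <= 0.07
        for i in range(10):
            groups = {f"g{j}": data[i, j] for j in range(k)}
            _, P = screen.tukey_letters(groups)
            iu = np.triu_indices(k, 1)
            assert (P.values[iu] < 0.05).any() == bool(pmin[i] < 0.05)

    def test_zero_variance_distinct_means(self):
        letters, P = screen.tukey_letters({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert letters["a"] != letters["b"]
        assert P.loc["a", "b"] == 0.0


class TestCompactLetters:
    def test_chain_structure(self):
        # a~b, b~c significant pairs absent; only a-c significant
        letters = screen.compact_letters(["a", "b", "c"], [("a", "c")])
        assert set(letters["a"]) & set(letters["c"]) == set()
        assert set(letters["b"]) & set(letters["a"])
        assert set(letters["b"]) & set(letters["c"])

    def test_all_pairs_significant(self):
        letters = screen.compact_letters(["x", "y", "z"],
                                         [("x", "y"), ("x", "z"), ("y", "z")])
        assert len({letters["x"], letters["y"], letters["z"]}) == 3

    def test_letters_follow_input_order(self):
        letters = screen.compact_letters(["first", "second"], [("first", "second")])
        assert letters["first"] == "a"
        assert letters["second"] == "b"


class TestDunnett:
    def test_identical_treatment_p_near_one(self, rng):
        c = rng.normal(0, 1, 10)
        p = screen.dunnett_vs_control({"Con": c, "T1": c.copy(), "T2": c + 0.01},
                                      control="Con")
        assert p["T1"] > 0.9

    def test_single_treatment_reduces_to_t_test(self, rng):
        c, t = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        p = screen.dunnett_vs_control({"Con": c, "T": t}, control="Con")
        _, pt = stats.ttest_ind(t, c, equal_var=True)
        assert p["T"] == pytest.approx(pt, abs=1e-6)

    def test_power_three_sd_shift(self, rng):
        hits = 0
        n_runs = 100
        for _ in range(n_runs):
            groups = {"Con": rng.normal(0, 1, 10), "T1": rng.normal(3, 1, 10),
                      "T2": rng.normal(0, 1, 10)}
            hits += screen.dunnett_vs_control(groups, control="Con")["T1"] < 0.05
        assert hits / n_runs >= 0.95

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            screen.dunnett_vs_control({"a": [1, 2], "b": [3, 4]}, control="Con")


class TestScreenResponders:
    def test_planted_responder_recovered(self):
        params = synth.OtuSimParams(
            groups=(("Kle", "Con"), ("Kle", "H50"), ("Kle", "Gamma")),
            n_otus=20, depth_range=(5_000, 5_000), overdispersion=5_000.0,
            responder_spec=((2, "H50", 3.0),), seed=42)
        table = synth.simulate_otu_table(params)
        records = screen.screen_responders(table, level="genus")
        rec = next(r for r in records if r.taxon.endswith(";Genus3"))
        assert rec.direction["H50"] == "increased"

    def test_direction_consistent_with_letters(self):
        table = synth.simulate_otu_table(synth.OtuSimParams(
            n_otus=30, depth_range=(800, 1_200), seed=7))
        for rec in screen.screen_responders(table, level="genus"):
            for t, direction in rec.direction.items():
                shared = set(rec.letters[t]) & set(rec.letters["Con"])
                if direction == "none":
                    assert shared
                else:
                    assert not shared
                    if direction == "increased":
                        assert rec.means[t] > rec.means["Con"]
                    else:
                        assert rec.means[t] < rec.means["Con"]

    def test_absent_taxon_excluded(self, small_table, caplog):
        counts = small_table.counts.copy()
        counts["Otu4"] = 0
        table = type(small_table)(counts, small_table.taxonomy, small_table.metadata)
        with caplog.at_level("INFO", logger="rdsoil.screen"):
            records = screen.screen_responders(table, level="genus")
        taxa = {r.taxon for r in records}
        assert not any(t.endswith("unclassified") and "PhyB" in t for t in taxa)
        assert any("skipped" in m for m in caplog.messages)

    def test_output_sorted_by_soil_phylum_taxon(self):
        table = synth.simulate_otu_table(synth.OtuSimParams(n_otus=24, seed=3))
        records = screen.screen_responders(table, level="genus")
        keys = [(r.soil, r.phylum, r.taxon) for r in records]
        assert keys == sorted(keys)


class TestDiversityCompare:
    def _frame(self, kle, alv):
        import pandas as pd
        rows = []
        for soil, vals in (("Kle", kle), ("Alv", alv)):
            for t, tv in vals.items():
                for i, v in enumerate(tv):
                    rows.append({"soil": soil, "treatment": t, "replicate": i,
                                 "invsimpson": v})
        return pd.DataFrame(rows)

    def test_identical_indices_share_letter(self):
        div = self._frame({"Con": [5, 5], "H50": [5, 5]},
                          {"Con": [5, 5], "H50": [5, 5]})
        comp = screen.diversity_compare(div)
        for letters in comp.within_soil_letters.values():
            assert set(letters.values()) == {"a"}

    def test_soils_three_sd_apart_detected(self, rng):
        hits = 0
        n_runs = 100
        for _ in range(n_runs):
            kle = {t: rng.normal(40, 3, 4) for t in ("Con", "H50", "Gamma")}
            alv = {t: rng.normal(31, 3, 4) for t in ("Con", "H50", "Gamma")}
            comp = screen.diversity_compare(self._frame(kle, alv))
            hits += comp.cross_soil_p < 0.001
        assert hits / n_runs >= 0.95

    def test_within_soil_null_rarely_separates(self, rng):
        diff = 0
        n_runs = 100
        for _ in range(n_runs):
            kle = {t: rng.normal(40, 3, 4) for t in ("Con", "H50", "Gamma")}
            alv = {t: rng.normal(40, 3, 4) for t in ("Con", "H50", "Gamma")}
            comp = screen.diversity_compare(self._frame(kle, alv))
            diff += any(len(set(l.values())) > 1
                        for l in comp.within_soil_letters.values())
        assert diff / n_runs <= 0.10 + 2 * math.sqrt(0.1 * 0.9 / n_runs)


class TestQpcr:
    def test_analysis_shape_on_synthetic_copy_numbers(self):
        means = {("Kle", "Con"): 9.2, ("Kle", "H50"): 9.1, ("Kle", "Gamma"): 8.6,
                 ("Alv", "Con"): 9.1, ("Alv", "H50"): 9.1, ("Alv", "Gamma"): 9.1}
        sds = {k: 0.1 for k in means}
        qpcr = synth.simulate_qpcr(synth.QpcrSimParams(
            group_log10_means=means, group_log10_sds=sds, n_reps=4, seed=11))
        res = screen.qpcr_compare(qpcr)
        assert set(res) == {"Kle", "Alv"}
        # planted reduction only in Kle Gamma
        assert res["Kle"]["letters"]["Gamma"] != res["Kle"]["letters"]["Con"]
        assert res["Alv"]["letters"]["Gamma"] == res["Alv"]["letters"]["Con"]
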