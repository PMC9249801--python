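"""Origin classification, selection tests, maternal-age and mutation rate."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mitofam.transmission import (classify_origin, maternal_age_trend,
                                  mutation_rate, selection_bootstrap,
                                  selection_t_test, transmission_model,
                                  transmission_table)

from conftest import make_pileup


def calls_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "pos", "ref", "alt",
                                       "vaf", "depth"])


class TestClassifyOrigin:
    def test_maternal_sharing_makes_inherited(self, reference):
        alt = "A" if reference.base(4000) != "A" else "C"
        child = calls_frame([("c", 4000, reference.base(4000), alt, 0.08,
                              4000)])
        mother = make_pileup(reference, [(4000, alt, 0.10)], depth=4000)
        out = classify_origin(child, {"m": mother})
        assert out.origin.iloc[0] == "inherited"

    def test_absent_in_lineage_is_de_novo(self, reference):
        alt = "A" if reference.base(4000) != "A" else "C"
        child = calls_frame([("c", 4000, reference.base(4000), alt, 0.03,
                              4000)])
        mother = make_pileup(reference, positions=[4000], depth=4000)
        out = classify_origin(child, {"m": mother})
        assert out.origin.iloc[0] == "de_novo"

    def test_secondary_heteroplasmy_below_call_floor_still_inherited(
            self, reference):
        """Mother at 6/1000 (0.6%, under the 1.5% primary floor) passes the
        sharing test, rescuing the child call as inherited."""
        refb = reference.base(4000)
        alt = "A" if refb != "A" else "C"
        child = calls_frame([("c", 4000, refb, alt, 0.03, 4000)])
        mother = make_pileup(reference, [(4000, alt, 0.006)], depth=1000)
        out = classify_origin(child, {"m": mother})
        assert out.origin.iloc[0] == "inherited"

    def test_no_mother_means_unknown(self, reference):
        refb = reference.base(4000)
        child = calls_frame([("c", 4000, refb,
                              "A" if refb != "A" else "C", 0.05, 4000)])
        out = classify_origin(child, {})
        assert out.origin.iloc[0] == "unknown"

    def test_sibling_sharing_blocks_de_novo(self, reference):
        refb = reference.base(4000)
        alt = "A" if refb != "A" else "C"
        child = calls_frame([("c", 4000, refb, alt, 0.05, 4000)])
        mother = make_pileup(reference, positions=[4000], depth=4000)
        sib = make_pileup(reference, [(4000, alt, 0.04)], depth=4000)
        out = classify_origin(child, {"m": mother, "s": sib})
        assert out.origin.iloc[0] == "inherited"
        assert out.shared_with.iloc[0] == "s"


class TestTransmissionTable:
    def test_transmitted_untransmitted_and_increase(self, reference):
        refb5, refb6 = reference.base(5000), reference.base(6000)
        alt5 = "A" if refb5 != "A" else "C"
        alt6 = "A" if refb6 != "A" else "C"
        maternal = calls_frame([("m", 5000, refb5, alt5, 0.10, 4000),
                                ("m", 6000, refb6, alt6, 0.10, 4000)])
        child = make_pileup(reference, [(5000, alt5, 0.20)], depth=4000,
                            positions=[5000, 6000])
        out = transmission_table(maternal, child, "c")
        out = out.set_index("pos")
        assert out.loc[5000].transmitted and out.loc[5000].increased
        assert not out.loc[6000].transmitted
        assert out.loc[6000].child_vaf == 0.0


class TestSelectionTTest:
    def test_null_rejection_rate_nominal(self):
        rng = np.random.default_rng(0)
        reject = 0
        B = 1000
        for _ in range(B):
            _, p = selection_t_test(rng.normal(size=50))
            reject += p < 0.05
        se = np.sqrt(0.05 * 0.95 / B)
        assert abs(reject / B - 0.05) < 3 * se

    def test_shifted_set_detected_with_direction(self):
        rng = np.random.default_rng(1)
        mean, p = selection_t_test(rng.normal(-1.0, 0.3, 40))
        assert mean < 0 and p < 1e-6

    def test_symmetric_pairs_give_p_one(self):
        mean, p = selection_t_test([-1.2, 1.2, -0.4, 0.4])
        assert mean == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            selection_t_test([1.0])
        with pytest.raises(ValueError):
            selection_t_test([2.0, 2.0, 2.0])


def toy_universe(n_ox=10, n_tr=10, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "pos": np.arange(n_ox + n_tr),
        "category": ["OXPHOS"] * n_ox + ["tRNA"] * n_tr,
        "is_transition": ([True, False] * ((n_ox + n_tr) // 2 + 1))
        [:n_ox + n_tr],
        "z": rng.normal(size=n_ox + n_tr),
    })
    return df


class TestSelectionBootstrap:
    def test_extreme_set_hits_floor(self):
        uni = toy_universe(200, 0)
        stratum = uni[uni.is_transition]
        obs = stratum.nsmallest(3, "z")
        B = 2000
        res = selection_bootstrap(obs, uni, B=B, seed=1)
        # the observed minimum-mean set can only be tied, never beaten
        assert res.boot_p == pytest.approx(1 / (B + 1), abs=2 / (B + 1))
        assert res.boot_p >= 1 / (B + 1)

    def test_composition_is_matched_exactly(self):
        uni = toy_universe(20, 20)
        obs = pd.concat([uni[(uni.category == "OXPHOS")
                             & uni.is_transition].head(2),
                         uni[(uni.category == "tRNA")
                             & ~uni.is_transition].head(1)])
        res = selection_bootstrap(obs, uni, B=500, seed=2)
        assert res.composition == {"OXPHOS:Ts": 2, "tRNA:Tv": 1}
        with pytest.raises(ValueError, match="stratum"):
            big = pd.concat([uni[(uni.category == "tRNA")
                                 & ~uni.is_transition]] * 3)
            selection_bootstrap(big, uni, B=10, seed=0)

    def test_matches_full_stratified_enumeration(self):
        """On a 20-entry universe with a 2-draw composition the resampling
        probability converges to the exact enumeration value."""
        uni = toy_universe(12, 8, seed=3)
        obs = pd.concat([
            uni[(uni.category == "OXPHOS") & uni.is_transition].iloc[[1]],
            uni[(uni.category == "tRNA") & ~uni.is_transition].iloc[[0]]])
        mean_obs = obs.z.mean()
        ox = uni[(uni.category == "OXPHOS") & uni.is_transition].z.to_numpy()
        tr = uni[(uni.category == "tRNA") & ~uni.is_transition].z.to_numpy()
        means = [(a + b) / 2 for a, b in itertools.product(ox, tr)]
        exact = np.mean([m <= mean_obs for m in means])
        B = 40000
        res = selection_bootstrap(obs, uni, B=B, seed=4)
        se = np.sqrt(exact * (1 - exact) / B)
        assert abs(res.boot_p - exact) < 4 * se + 2 / B

    def test_uniform_draw_gives_uniform_p(self):
        """Observed sets drawn at random from the universe reject at about
        the nominal rate."""
        uni = toy_universe(60, 60, seed=5)
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            take = uni.iloc[rng.choice(len(uni), 6, replace=False)]
            res = selection_bootstrap(take, uni, B=499,
                                      seed=int(rng.integers(2**31)))
            rejections += res.boot_p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3 * se

    def test_deterministic_under_seed(self):
        uni = toy_universe(30, 30)
        obs = uni.sample(5, random_state=1)
        a = selection_bootstrap(obs, uni, B=999, seed=11)
        b = selection_bootstrap(obs, uni, B=999, seed=11)
        assert a.boot_p == b.boot_p


class TestTransmissionModel:
    def test_permuted_z_gives_null_or(self):
        rng = np.random.default_rng(7)
        n = 2000
        vaf = 10 ** rng.uniform(np.log10(0.02), np.log10(0.5), n)
        y = rng.random(n) < 0.4 + 0.5 * vaf
        df = pd.DataFrame({"z": rng.permutation(rng.normal(size=n)),
                           "maternal_vaf": vaf, "transmitted": y,
                           "category": "OXPHOS",
                           "male": rng.random(n) < 0.5})
        res = transmission_model(df)
        assert res["ci_low"] < 1.0 < res["ci_high"]

    def test_minimum_counts_enforced(self):
        df = pd.DataFrame({"z": np.arange(12, dtype=float),
                           "transmitted": [True] * 11 + [False]})
        with pytest.raises(ValueError):
            transmission_model(df)


class TestMaternalAgeTrend:
    def test_slope_recovery_and_null(self):
        rng = np.random.default_rng(8)
        n = 2000
        ages = rng.uniform(18, 45, n)
        slope = 0.02
        counts = rng.poisson(0.3 + slope * (ages - 18))
        res = maternal_age_trend(pd.DataFrame({"n_de_novo": counts,
                                               "maternal_age": ages}))
        assert res["ci_low"] < slope < res["ci_high"]

    def test_identical_groups_have_no_slope_difference(self):
        rng = np.random.default_rng(9)
        n = 3000
        ages = rng.uniform(18, 45, n)
        counts = rng.poisson(0.2 + 0.015 * (ages - 18))
        df = pd.DataFrame({"n_de_novo": counts, "maternal_age": ages,
                           "group": rng.choice(["case", "control"], n)})
        res = maternal_age_trend(df)
        assert abs(res["slope_difference"]) < 0.02
        assert res["interaction_p"] > 0.01

    def test_constant_age_rejected(self):
        df = pd.DataFrame({"n_de_novo": [1] * 20, "maternal_age": [30] * 20})
        with pytest.raises(ValueError, match="constant"):
            maternal_age_trend(df)


class TestMutationRate:
    def test_zero_counts_zero_rate(self):
        assert mutation_rate(0, 100, 16000) == 0.0

    def test_linearity_in_children(self):
        one = mutation_rate(50, 1000, 16000)
        assert mutation_rate(50, 2000, 16000) == pytest.approx(one / 2)

    def test_detectability_correction_round_trip(self):
        """With the correction set to the true detection probability the
        estimator recovers the underlying rate."""
        rng = np.random.default_rng(10)
        mu, sites, kids, detect = 2e-5, 13000, 5000, 0.6
        counts = rng.binomial(1, detect, size=rng.poisson(
            mu * sites * kids)).sum()
        est = mutation_rate(int(counts), kids, sites,
                            detectable_fraction=detect)
        se = np.sqrt(mu / (kids * sites * detect))
        assert abs(est - mu) < 4 * se

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mutation_rate(1, 0, 100)
        with pytest.raises(ValueError):
            mutation_rate(1, 10, 100, detectable_fraction=0.0)
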