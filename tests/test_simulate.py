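"""Generator: determinism, maternal inheritance, calibrated mechanisms."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mitofam.simulate import (SimulationConfig, simulate_content,
                              simulate_de_novo, simulate_families,
                              simulate_phenotype, simulate_pileup,
                              simulate_score_table, transmit_heteroplasmy)


def test_same_seed_same_output(small_study):
    again = simulate_families(SimulationConfig(n_families=30, seed=7))
    assert small_study.sample_sheet.equals(again.sample_sheet)
    assert small_study.truth_het.equals(again.truth_het)
    assert small_study.truth_content.equals(again.truth_content)


def test_earlier_families_stable_when_cohort_grows():
    a = simulate_families(SimulationConfig(n_families=5, seed=3))
    b = simulate_families(SimulationConfig(n_families=9, seed=3))
    fams = a.truth_het.family_id.unique()
    bh = b.truth_het[b.truth_het.family_id.isin(fams)].reset_index(drop=True)
    assert a.truth_het.equals(bh)


def test_maternal_inheritance_only(small_study):
    """Children's inherited heteroplasmies all trace to the mother; none
    to the father."""
    het = small_study.truth_het
    for fid, fam in het.groupby("family_id"):
        mother_keys = set(map(tuple, fam[
            fam.sample_id.str.endswith("mother")][["pos", "alt"]].values))
        father_keys = set(map(tuple, fam[
            fam.sample_id.str.endswith("father")][["pos", "alt"]].values))
        kids = fam[fam.sample_id.str.contains("child")
                   & (fam.origin == "inherited")]
        kid_keys = set(map(tuple, kids[["pos", "alt"]].values))
        assert kid_keys <= mother_keys
        assert not (kid_keys & (father_keys - mother_keys))


def test_no_mutation_no_de_novo():
    st = simulate_families(SimulationConfig(
        n_families=8, seed=1, mu=0.0, maternal_age_slope=0.0))
    assert (st.truth_het.origin == "de_novo").sum() == 0


def test_truth_vafs_conserved(small_study):
    assert small_study.truth_het.true_vaf.between(0, 1).all()


class TestTransmission:
    def test_selection_off_equals_bottleneck_survival(self):
        cfg = SimulationConfig(seed=0, selection_or_per_sd=1.0,
                               bottleneck_n=20)
        rng = np.random.default_rng(2)
        vaf = 0.10
        n = 20000
        transmitted = sum(transmit_heteroplasmy(vaf, 0.0, cfg, rng) > 0
                          for _ in range(n)) / n
        expect = 1 - (1 - vaf) ** cfg.bottleneck_n
        assert abs(transmitted - expect) < 4 * np.sqrt(expect * (1 - expect) / n)

    def test_single_unit_bottleneck_fixes_or_loses(self):
        cfg = SimulationConfig(seed=0, selection_or_per_sd=1.0, bottleneck_n=1)
        rng = np.random.default_rng(3)
        vals = {transmit_heteroplasmy(0.3, 0.0, cfg, rng) for _ in range(200)}
        assert vals <= {0.0, 1.0}

    def test_logistic_refit_recovers_selection_or(self):
        """Refitting transmitted ~ z (+ maternal VAF) on 10^4 draws puts
        log(0.64) inside the slope's 95% CI."""
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(4)
        n = 10000
        z = rng.normal(size=n)
        vaf = 10 ** rng.uniform(np.log10(0.02), np.log10(0.5), n)
        y = np.array([transmit_heteroplasmy(vaf[i], z[i], cfg, rng) > 0
                      for i in range(n)], dtype=int)
        X = sm.add_constant(np.column_stack([z, vaf]))
        fit = sm.Logit(y, X).fit(disp=0)
        lo, hi = fit.conf_int()[1]
        assert lo < np.log(cfg.selection_or_per_sd) < hi

    def test_vaf_domain_enforced(self):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(0)
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                transmit_heteroplasmy(bad, 0.0, cfg, rng)


@pytest.fixture(scope="module")
def universe():
    return simulate_score_table(SimulationConfig(seed=7))


class TestDeNovo:
    def test_rate_zero_always_empty(self, universe):
        cfg = SimulationConfig(seed=0, mu=0.0, maternal_age_slope=0.0)
        rng = np.random.default_rng(1)
        for age in (20, 30, 45):
            assert len(simulate_de_novo(age, cfg, rng, universe)) == 0

    def test_age_slope_recovered_by_regression(self, universe):
        """OLS of simulated counts on maternal age recovers the configured
        slope within its 95% CI at n = 2,000."""
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(5)
        ages = rng.uniform(18, 45, 2000)
        counts = [len(simulate_de_novo(a, cfg, rng, universe)) for a in ages]
        fit = sm.OLS(np.asarray(counts, float),
                     sm.add_constant(ages)).fit()
        lo, hi = fit.conf_int()[1]
        assert lo < cfg.maternal_age_slope < hi

    def test_no_slope_means_age_independent_counts(self, universe):
        cfg = SimulationConfig(seed=0, maternal_age_slope=0.0)
        rng = np.random.default_rng(6)
        ages = rng.uniform(18, 45, 4000)
        counts = np.array([len(simulate_de_novo(a, cfg, rng, universe))
                           for a in ages])
        young = counts[ages < 30].mean()
        old = counts[ages >= 30].mean()
        se = np.sqrt(counts.var() * (1 / (ages < 30).sum()
                                     + 1 / (ages >= 30).sum()))
        assert abs(young - old) < 4 * se

    def test_negative_mean_raises(self, universe):
        cfg = SimulationConfig(seed=0, mu=0.0, maternal_age_slope=0.01)
        with pytest.raises(ValueError, match="negative"):
            simulate_de_novo(20.0, cfg, np.random.default_rng(0), universe)


class TestPileup:
    def test_clean_sample_is_reference_only(self):
        cfg = SimulationConfig(n_families=1, seed=5, error_floor=0.0,
                               mother_het_mean=0, mu=0,
                               maternal_age_slope=0,
                               lineage_homoplasmy_mean=0)
        st = simulate_families(cfg)
        p = simulate_pileup(st, st.sample_sheet.sample_id.iloc[0])
        counts = sum(
            np.column_stack([p[f"{b}_{s}"] for b in "ACGT"])
            for s in ("fwd", "rev"))
        nonref = counts.sum() - counts[np.arange(len(p)),
                                       ["ACGT".index(b) for b in p.ref]].sum()
        assert nonref == 0

    def test_counts_sum_to_depth_per_strand(self, small_study):
        p = simulate_pileup(small_study,
                            small_study.sample_sheet.sample_id.iloc[2])
        for s in ("fwd", "rev"):
            tot = sum(p[f"{b}_{s}"] for b in "ACGT")
            assert (tot >= 0).all()
        depth = sum(p[f"{b}_{s}"] for b in "ACGT" for s in ("fwd", "rev"))
        assert depth.mean() == pytest.approx(
            small_study.config.depth_mean, rel=0.02)

    def test_background_error_rate_calibrated(self):
        """Observed minor-allele rate on variant-free pileups ~ 0.02%."""
        cfg = SimulationConfig(n_families=1, seed=9, mother_het_mean=0,
                               mu=0, maternal_age_slope=0,
                               lineage_homoplasmy_mean=0)
        st = simulate_families(cfg)
        p = simulate_pileup(st, st.sample_sheet.sample_id.iloc[0])
        counts = sum(
            np.column_stack([p[f"{b}_{s}"] for b in "ACGT"])
            for s in ("fwd", "rev"))
        total = counts.sum()
        ref_n = counts[np.arange(len(p)),
                       ["ACGT".index(b) for b in p.ref]].sum()
        rate = (total - ref_n) / total
        se = np.sqrt(cfg.error_floor / total)
        assert abs(rate - cfg.error_floor) < 4 * se

    def test_truth_vaf_recovered_unbiased(self, reference):
        """Mean observed VAF over 100 planted 10% sites at depth 4,000 is
        within binomial error of truth."""
        cfg = SimulationConfig(n_families=1, seed=11, mother_het_mean=0,
                               mu=0, maternal_age_slope=0,
                               lineage_homoplasmy_mean=0, depth_mean=4000)
        st = simulate_families(cfg)
        sid = st.sample_sheet.sample_id.iloc[0]
        positions = np.linspace(1000, 15000, 100).astype(int)
        rows = []
        for pos in positions:
            ref = reference.base(int(pos))
            alt = "A" if ref != "A" else "C"
            rows.append({"family_id": "F00000", "sample_id": sid,
                         "pos": int(pos), "ref": ref, "alt": alt,
                         "category": "OXPHOS",
                         "consequence": "nonsynonymous",
                         "is_transition": False, "z": 0.0, "pp": False,
                         "true_vaf": 0.10, "origin": "inherited",
                         "maternal_vaf": 0.10})
        st.truth_het = pd.DataFrame(rows)
        p = simulate_pileup(st, sid).set_index("pos")
        vafs = []
        for r in rows:
            row = p.loc[r["pos"]]
            k = row[f"{r['alt']}_fwd"] + row[f"{r['alt']}_rev"]
            n = sum(row[f"{b}_{s}"] for b in "ACGT" for s in ("fwd", "rev"))
            vafs.append(k / n)
        se = np.sqrt(0.1 * 0.9 / (4000 * 100))
        assert abs(np.mean(vafs) - 0.10) < 3 * se


class TestContent:
    def test_no_heritability_no_parent_child_correlation(self):
        cfg = SimulationConfig(seed=0, content_h2=0.0,
                               content_parent_child_r=0.0)
        df = simulate_content(5000, cfg, np.random.default_rng(1))
        w = df.pivot_table(index="family", columns="role", values="latent")
        r = np.corrcoef(w.mother, w.child0)[0, 1]
        assert abs(r) < 3 / np.sqrt(5000)

    def test_h2_recovered_by_midparent_regression(self):
        cfg = SimulationConfig(seed=0)
        df = simulate_content(5000, cfg, np.random.default_rng(2))
        w = df.pivot_table(index="family", columns="role", values="latent")
        mid = ((w.mother + w.father) / 2).to_numpy()
        fit = sm.OLS(w.child0.to_numpy(), sm.add_constant(mid)).fit()
        lo, hi = fit.conf_int()[1]
        assert lo < cfg.content_h2 < hi

    def test_age_slope_sign(self):
        cfg = SimulationConfig(seed=0)
        df = simulate_content(3000, cfg, np.random.default_rng(3))
        kids = df[df.role.str.startswith("child")]
        fit = sm.OLS(kids.raw_content.to_numpy(),
                     sm.add_constant(kids.age.to_numpy())).fit()
        assert fit.params[1] < 0

    def test_h2_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(content_h2=1.4)


class TestPhenotype:
    def test_null_effect_gives_null_or(self):
        from mitofam.association import conditional_logistic
        cfg = SimulationConfig(n_families=800, seed=13, pp_asd_or=1.0,
                               pp_lowcn_interaction_or=1.0, cn_asd_or=1.0)
        st = simulate_families(cfg)
        ch = st.sample_sheet.dropna(subset=["affected"]).copy()
        ch["affected"] = ch.affected.astype(int)
        ch["carry"] = ch.carry_pp.astype(float)
        fit = conditional_logistic(ch, ["carry"])
        assert fit.ci_low.iloc[0] < 1.0 < fit.ci_high.iloc[0]

    def test_interaction_orders_stratified_ors(self):
        """With a low-content interaction, the carrier odds ratio among
        low-tertile children exceeds the OR among the upper tertiles."""
        cfg = SimulationConfig(seed=17, design="dyad",
                               pp_lowcn_interaction_or=2.5, cn_asd_or=1.0)
        rng = np.random.default_rng(21)
        n = 40000
        exposures = pd.DataFrame({
            "family": np.arange(n),
            "carry_pp": rng.random(n) < 0.3,
            "low_tertile": rng.random(n) < 1 / 3,
            "mtcnz": np.zeros(n),
            "male": rng.random(n) < 0.5,
        })
        y = simulate_phenotype(exposures, cfg, rng).to_numpy()

        def odds_ratio(mask):
            e = exposures.carry_pp.to_numpy()[mask]
            yy = y[mask]
            a, b = ((e & (yy == 1)).sum(), (e & (yy == 0)).sum())
            c, d = ((~e & (yy == 1)).sum(), (~e & (yy == 0)).sum())
            return (a * d) / (b * c)

        low = odds_ratio(exposures.low_tertile.to_numpy())
        high = odds_ratio(~exposures.low_tertile.to_numpy())
        assert low > high > 1.0

    def test_quartets_have_one_case_per_family(self, small_study):
        ch = small_study.sample_sheet.dropna(subset=["affected"])
        per_fam = ch.groupby("family_id").affected.sum()
        assert (per_fam == 1).all()
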