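"""The family simulator: Hardy-Weinberg, disease model, missingness."""

import numpy as np
import pytest

from famtrio.genetics import MISSING, Chrom, Model, Sex, score_tables
from famtrio.simulation import (
    MissingnessSpec,
    SimConfig,
    _disease_probability,
    _probe_prevalence,
    _probe_rep,
    assign_disease,
    calibrate_prevalence,
    draw_marker_freqs,
    inject_missingness,
    measure_prevalence,
    select_case_control,
    simulate_families,
)


@pytest.fixture(scope="module")
def small_cfg():
    return SimConfig(n_families=400, n_markers=40, p_env=0.12)


@pytest.fixture(scope="module")
def small_ped(small_cfg):
    rng = np.random.default_rng(99)
    ped = simulate_families(small_cfg, rng)
    assign_disease(ped, rng)
    return ped


class TestFrequencies:
    def test_law_mean_and_clipping(self):
        cfg = SimConfig(n_families=10, n_markers=20000)
        base, pops = draw_marker_freqs(cfg, np.random.default_rng(0))
        # Gamma(2, 2)/35 has mean 4/35 ~ 0.114 before clipping
        assert abs(base.mean() - 4 / 35) < 0.01
        assert base.min() >= cfg.freq_bounds[0]
        assert base.max() <= cfg.freq_bounds[1]
        assert pops.shape == (2, 20000)

    def test_zero_differentiation_shares_base(self):
        cfg = SimConfig(n_families=10, n_markers=50, fst=0.0)
        base, pops = draw_marker_freqs(cfg, np.random.default_rng(0))
        assert np.array_equal(pops[0], base)
        assert np.array_equal(pops[1], base)


class TestFamilies:
    def test_population_split_sizes(self, small_ped):
        counts = np.bincount(small_ped.fam_pop, minlength=2)
        assert counts[0] == round(400 / 3)
        assert counts[1] == 400 - round(400 / 3)

    def test_parental_genotypes_follow_hardy_weinberg(self):
        cfg = SimConfig(n_families=20000, n_markers=1, n_causative=1, fst=0.0)
        p = 0.3
        freqs = (np.array([p]), np.array([[p], [p]]))
        ped = simulate_families(cfg, np.random.default_rng(4), freqs=freqs)
        dose = np.concatenate([ped.father_geno[:, 0], ped.mother_geno[:, 0]])
        obs = np.bincount(dose, minlength=3) / len(dose)
        want = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        assert np.allclose(obs, want, atol=0.01)

    def test_every_trio_is_mendelian_consistent(self, small_ped):
        _, _, _, cons = score_tables(Model.ADDITIVE, Chrom.AUTOSOMAL, Sex.FEMALE)
        F = small_ped.father_geno[small_ped.off_family]
        M = small_ped.mother_geno[small_ped.off_family]
        O = small_ped.off_geno
        assert cons[F, M, O].all()

    def test_offspring_counts_and_sex(self, small_ped):
        counts = np.bincount(small_ped.off_family, minlength=400)
        assert set(counts) <= {1, 2}
        assert set(np.unique(small_ped.off_sex)) <= {1, 2}


class TestDiseaseModel:
    def test_penetrance_endpoints_are_exact(self):
        """Zero copies, unexposed -> f0; two copies at one marker -> f2."""
        cfg = SimConfig(p_env=0.0)
        f0 = np.array([0.001])
        f2 = np.array([0.1])
        fam = np.zeros(3, dtype=int)
        unexposed = np.array([False])
        pi = _disease_probability(cfg, np.array([0.0, 1.0, 2.0]), fam, f0, f2, unexposed)
        assert pi[0] == pytest.approx(0.001)
        assert pi[1] == pytest.approx(np.sqrt(0.001 * 0.1))  # log-additive midpoint
        assert pi[2] == pytest.approx(0.1)

    def test_exposed_baseline_scales_with_lambda_s(self):
        cfg = SimConfig(p_env=1.0)
        pi = _disease_probability(
            cfg,
            np.array([0.0]),
            np.zeros(1, dtype=int),
            np.array([0.001]),
            np.array([0.1]),
            np.array([True]),
        )
        assert pi[0] == pytest.approx(cfg.lambda_s * 0.1)

    def test_assign_disease_requires_calibration(self):
        cfg = SimConfig(n_families=10, n_markers=5)
        ped = simulate_families(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="p_env"):
            assign_disease(ped, np.random.default_rng(0))

    def test_siblings_share_exposure_hence_correlate(self):
        """Phenotype correlation between siblings exceeds the population one."""
        cfg = SimConfig(n_families=4000, n_markers=3, p_env=0.12)
        rng = np.random.default_rng(11)
        ped = simulate_families(cfg, rng)
        assign_disease(ped, rng)
        fam = ped.off_family
        aff = ped.affected.astype(float)
        two = np.flatnonzero(np.bincount(fam, minlength=cfg.n_families) == 2)
        first = np.array([np.flatnonzero(fam == f)[0] for f in two[:1500]])
        second = first + 1
        sib_corr = np.corrcoef(aff[first], aff[second])[0, 1]
        assert sib_corr > 0.05


class TestCalibration:
    def test_prevalence_monotone_in_p_env(self):
        cfg = SimConfig()
        rep = _probe_rep(cfg, np.random.default_rng(2))
        prevs = [_probe_prevalence(cfg, rep, p) for p in (0.0, 0.1, 0.3, 0.6, 1.0)]
        assert all(a <= b + 1e-12 for a, b in zip(prevs, prevs[1:]))

    def test_calibrated_value_recovers_target(self):
        rng = np.random.default_rng(3)
        cfg = SimConfig()
        p_env = calibrate_prevalence(cfg, rng, n_reps=150)
        assert 0.0 < p_env < 1.0
        measured = measure_prevalence(cfg.replace(p_env=p_env), np.random.default_rng(77), n_reps=150)
        assert measured == pytest.approx(cfg.prevalence_target, abs=0.012)

    def test_unattainable_targets_raise(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="floor"):
            calibrate_prevalence(SimConfig(), rng, target=1e-05, n_reps=10)
        with pytest.raises(ValueError, match="ceiling"):
            calibrate_prevalence(SimConfig(), rng, target=0.9, n_reps=10)


class TestCaseControlSelection:
    def test_balanced_and_disjoint(self, small_ped):
        cases, controls = select_case_control(small_ped, np.random.default_rng(0))
        assert len(cases) == len(controls)
        assert not set(cases) & set(controls)
        assert small_ped.affected[cases].all()
        assert not small_ped.affected[controls].any()

    def test_insufficient_controls_raise_or_trim(self):
        cfg = SimConfig(n_families=50, n_markers=3, p_env=0.12)
        ped = simulate_families(cfg, np.random.default_rng(1))
        ped.affected = np.ones(ped.n_offspring, dtype=bool)
        ped.affected[:5] = False
        with pytest.raises(ValueError):
            select_case_control(ped, np.random.default_rng(0))
        cases, controls = select_case_control(ped, np.random.default_rng(0), allow_trim=True)
        assert len(cases) == len(controls) == 5


class TestMissingness:
    def _select(self, ped):
        return select_case_control(ped, np.random.default_rng(5))

    def test_rate_zero_changes_nothing(self, small_ped):
        cases, controls = self._select(small_ped)
        out = inject_missingness(
            small_ped, cases, controls, MissingnessSpec(rate=0.0), np.random.default_rng(0)
        )
        assert np.array_equal(out.off_geno, small_ped.off_geno)
        assert np.array_equal(out.father_geno, small_ped.father_geno)

    def test_mcar_hits_the_requested_entry_rate(self, small_ped):
        cases, controls = self._select(small_ped)
        spec = MissingnessSpec(mode="MCAR", rate=0.10)
        out = inject_missingness(small_ped, cases, controls, spec, np.random.default_rng(1))
        trios = np.concatenate([cases, controls])
        F, M, O = out.trio_genotypes(trios)
        frac = np.mean(np.concatenate([F, M, O]) == MISSING)
        assert abs(frac - 0.10) < 0.02
        # the original pedigree is untouched
        assert (small_ped.off_geno != MISSING).all()

    def test_mar_males_carry_eighty_percent(self, small_ped):
        cases, controls = self._select(small_ped)
        spec = MissingnessSpec(mode="MAR", target="males", rate=0.10)
        out = inject_missingness(small_ped, cases, controls, spec, np.random.default_rng(2))
        fam = small_ped.off_family
        miss_father = (out.father_geno == MISSING).sum()
        miss_mother = (out.mother_geno == MISSING).sum()
        male_off = (out.off_geno[small_ped.off_sex == 1] == MISSING).sum()
        female_off = (out.off_geno[small_ped.off_sex == 2] == MISSING).sum()
        male_frac = (miss_father + male_off) / max(
            miss_father + miss_mother + male_off + female_off, 1
        )
        assert abs(male_frac - 0.8) < 0.05

    def test_mnar_cases_concentrates_on_affected_offspring(self, small_ped):
        """Disease status belongs to offspring: parents absorb only the 20%."""
        cases, controls = self._select(small_ped)
        spec = MissingnessSpec(mode="MNAR", target="cases", rate=0.10)
        out = inject_missingness(small_ped, cases, controls, spec, np.random.default_rng(3))
        n_case_off = (out.off_geno[cases] == MISSING).sum()
        n_total = (
            (out.father_geno == MISSING).sum()
            + (out.mother_geno == MISSING).sum()
            + (out.off_geno == MISSING).sum()
        )
        assert n_case_off / n_total == pytest.approx(0.8, abs=0.05)

    def test_heterozygote_target_prefers_hets(self, small_ped):
        cases, controls = self._select(small_ped)
        spec = MissingnessSpec(mode="MNAR", target="heterozygotes", rate=0.05)
        out = inject_missingness(small_ped, cases, controls, spec, np.random.default_rng(4))
        was_het = small_ped.off_geno == 1
        now_missing = out.off_geno == MISSING
        frac_het_missing = np.mean(now_missing[was_het])
        frac_other_missing = np.mean(now_missing[~was_het])
        assert frac_het_missing > 2 * frac_other_missing

    def test_spill_is_counted_not_silent(self, small_ped):
        """A tiny target group forces spillover into the complement."""
        cases, controls = self._select(small_ped)
        spec = MissingnessSpec(mode="MNAR", target="homozygotes", rate=0.3)
        out = inject_missingness(small_ped, cases, controls, spec, np.random.default_rng(6))
        assert out.n_missing_spilled > 0
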