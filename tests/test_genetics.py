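"""Trio scoring, transmission distributions, consistency and completions."""

import itertools

import numpy as np
import pytest
from conftest import (
    CONTEXTS,
    oracle_completions,
    oracle_member_spaces,
    oracle_outcomes,
    oracle_score,
)
from hypothesis import given, settings
from hypothesis import strategies as st

from famtrio.genetics import (
    MISSING,
    Chrom,
    MendelianError,
    Model,
    Sex,
    Trio,
    code_genotype,
    enumerate_completions,
    is_informative,
    is_mendelian_consistent,
    offspring_distribution,
    score_tables,
    trio_score,
)


class TestOffspringDistribution:
    def test_het_by_refhom_splits_evenly(self):
        assert offspring_distribution(0, 1) == {0: 0.5, 1: 0.5}

    def test_double_refhom_is_degenerate(self):
        assert offspring_distribution(0, 0) == {0: 1.0}

    def test_x_daughter_gets_paternal_allele_surely(self):
        d = offspring_distribution(1, 1, Chrom.X, Sex.FEMALE)
        assert d == {1: 0.5, 2: 0.5}

    def test_x_son_depends_on_mother_only(self):
        assert offspring_distribution(0, 1, Chrom.X, Sex.MALE) == {0: 0.5, 1: 0.5}
        assert offspring_distribution(1, 1, Chrom.X, Sex.MALE) == {0: 0.5, 1: 0.5}

    @pytest.mark.parametrize("chrom,sex", CONTEXTS)
    def test_sums_to_one_everywhere(self, chrom, sex):
        fs, ms, _ = oracle_member_spaces(chrom, sex)
        for f, m in itertools.product(fs, ms):
            dist = offspring_distribution(f, m, chrom, sex)
            assert sum(dist.values()) == pytest.approx(1.0, abs=0)

    def test_invalid_genotype_raises(self):
        with pytest.raises(ValueError):
            offspring_distribution(2, 0, Chrom.X, Sex.FEMALE)  # hemizygous father
        with pytest.raises(ValueError):
            offspring_distribution(MISSING, 1)


class TestCodeGenotype:
    @pytest.mark.parametrize(
        "g,model,chrom,sex,expected",
        [
            (1, Model.ADDITIVE, Chrom.AUTOSOMAL, Sex.FEMALE, 1.0),
            (2, Model.DOMINANT, Chrom.AUTOSOMAL, Sex.FEMALE, 1.0),
            (1, Model.RECESSIVE, Chrom.AUTOSOMAL, Sex.FEMALE, 0.0),
            (2, Model.RECESSIVE, Chrom.AUTOSOMAL, Sex.FEMALE, 1.0),
            (1, Model.RECESSIVE, Chrom.X, Sex.MALE, 1.0),  # hemizygous alternate
            (0, Model.RECESSIVE, Chrom.X, Sex.MALE, 0.0),
        ],
    )
    def test_codings(self, g, model, chrom, sex, expected):
        assert code_genotype(g, model, chrom, sex) == expected

    def test_missing_raises(self):
        with pytest.raises(ValueError):
            code_genotype(MISSING, Model.ADDITIVE)


class TestTrioScore:
    def test_worked_example(self):
        s = trio_score(Trio(0, 1, 1), Model.ADDITIVE)
        assert s.x_minus_e == 0.5
        assert s.var_x == 0.25

    def test_het_by_het_ref_offspring(self):
        s = trio_score(Trio(1, 1, 0), Model.ADDITIVE)
        assert s == (-1.0, 0.5)

    @pytest.mark.parametrize("chrom,sex", CONTEXTS)
    @pytest.mark.parametrize("model", list(Model))
    def test_matches_enumeration_oracle_exhaustively(self, model, chrom, sex):
        """Every genotype combination agrees with the brute-force oracle."""
        fs, ms, os_ = oracle_member_spaces(chrom, sex)
        for f, m, o in itertools.product(fs, ms, os_):
            t = Trio(f, m, o, sex=sex)
            if o in oracle_outcomes(f, m, chrom, sex):
                got = trio_score(t, model, chrom)
                want = oracle_score(f, m, o, model, chrom, sex)
                assert got.x_minus_e == pytest.approx(want[0], abs=1e-12)
                assert got.var_x == pytest.approx(want[1], abs=1e-12)
            else:
                with pytest.raises(MendelianError):
                    trio_score(t, model, chrom)

    @pytest.mark.parametrize("model", list(Model))
    def test_both_homozygous_parents_score_zero(self, model):
        for f, m in itertools.product((0, 2), (0, 2)):
            o = (f + m) // 2
            assert trio_score(Trio(f, m, o), model) == (0.0, 0.0)

    def test_dominant_het_by_althom_noninformative(self):
        """Het x alternate-hom matings carry no dominant-model signal."""
        for f, m in ((1, 2), (2, 1)):
            for o in (1, 2):
                assert trio_score(Trio(f, m, o), Model.DOMINANT) == (0.0, 0.0)

    def test_recessive_het_by_refhom_noninformative(self):
        for f, m in ((1, 0), (0, 1)):
            for o in (0, 1):
                assert trio_score(Trio(f, m, o), Model.RECESSIVE) == (0.0, 0.0)

    def test_allele_relabel_antisymmetry_additive(self):
        """Swapping ref/alt labels negates x - E[x] and preserves Var(x)."""
        for f, m, o in itertools.product(range(3), range(3), range(3)):
            if o not in oracle_outcomes(f, m, Chrom.AUTOSOMAL, Sex.FEMALE):
                continue
            s = trio_score(Trio(f, m, o), Model.ADDITIVE)
            flipped = trio_score(Trio(2 - f, 2 - m, 2 - o), Model.ADDITIVE)
            assert flipped.x_minus_e == pytest.approx(-s.x_minus_e, abs=1e-12)
            assert flipped.var_x == pytest.approx(s.var_x, abs=1e-12)

    def test_incomplete_trio_rejected(self):
        with pytest.raises(ValueError):
            trio_score(Trio(MISSING, 1, 1), Model.ADDITIVE)


class TestInformativeness:
    def test_examples(self):
        assert not is_informative(0, 0, Model.ADDITIVE)
        assert is_informative(1, 0, Model.ADDITIVE)
        assert is_informative(1, 1, Model.RECESSIVE)
        assert not is_informative(1, 2, Model.DOMINANT)

    @pytest.mark.parametrize("chrom,sex", CONTEXTS)
    @pytest.mark.parametrize("model", list(Model))
    def test_equivalent_to_positive_variance(self, model, chrom, sex):
        fs, ms, _ = oracle_member_spaces(chrom, sex)
        for f, m in itertools.product(fs, ms):
            outcomes = oracle_outcomes(f, m, chrom, sex)
            want = oracle_score(f, m, outcomes[0], model, chrom, sex)[1] > 0
            assert is_informative(f, m, model, chrom, sex) == want


class TestMendelianConsistency:
    @pytest.mark.parametrize(
        "trio,expected",
        [
            (Trio(0, 0, 1), False),
            (Trio(0, 1, 1), True),
            (Trio(MISSING, 0, 2), False),
            (Trio(MISSING, MISSING, MISSING), True),
            (Trio(2, 2, 2), True),
            (Trio(2, 0, 0), False),
        ],
    )
    def test_examples(self, trio, expected):
        assert is_mendelian_consistent(trio) is expected

    @pytest.mark.parametrize("chrom,sex", CONTEXTS)
    def test_matches_oracle_over_all_patterns(self, chrom, sex):
        """Closed-form allele-set logic equals transmission enumeration."""
        fs, ms, os_ = oracle_member_spaces(chrom, sex)
        for f, m, o in itertools.product(
            fs + (MISSING,), ms + (MISSING,), os_ + (MISSING,)
        ):
            want = len(oracle_completions(f, m, o, chrom, sex)) > 0
            got = is_mendelian_consistent(Trio(f, m, o, sex=sex), chrom)
            assert got == want, (f, m, o, chrom, sex)


class TestEnumerateCompletions:
    def test_father_missing_example(self):
        comps = enumerate_completions(Trio(MISSING, 1, 2))
        assert sorted(c.father for c in comps) == [1, 2]

    def test_fully_missing_autosomal_has_15(self):
        assert len(enumerate_completions(Trio(MISSING, MISSING, MISSING))) == 15

    def test_complete_trio_rejected(self):
        with pytest.raises(ValueError):
            enumerate_completions(Trio(0, 1, 1))

    def test_inconsistent_observed_members_raise(self):
        with pytest.raises(MendelianError):
            enumerate_completions(Trio(MISSING, 0, 2))

    @pytest.mark.parametrize("chrom,sex", CONTEXTS)
    def test_matches_brute_force_for_all_patterns(self, chrom, sex):
        """All missingness patterns equal the genotype-space brute force."""
        fs, ms, os_ = oracle_member_spaces(chrom, sex)
        for f, m, o in itertools.product(
            fs + (MISSING,), ms + (MISSING,), os_ + (MISSING,)
        ):
            if MISSING not in (f, m, o):
                continue
            want = oracle_completions(f, m, o, chrom, sex)
            if not want:
                with pytest.raises(MendelianError):
                    enumerate_completions(Trio(f, m, o, sex=sex), chrom)
                continue
            got = enumerate_completions(Trio(f, m, o, sex=sex), chrom)
            got_tuples = [(c.father, c.mother, c.offspring) for c in got]
            assert sorted(got_tuples) == sorted(want)
            assert len(set(got_tuples)) == len(got_tuples)  # pairwise distinct

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        f=st.sampled_from([MISSING, 0, 1, 2]),
        m=st.sampled_from([MISSING, 0, 1, 2]),
        o=st.sampled_from([MISSING, 0, 1, 2]),
    )
    def test_completions_agree_with_observed_members(self, f, m, o):
        """Property: every completion preserves observed genotypes and is consistent."""
        if MISSING not in (f, m, o):
            return
        t = Trio(f, m, o)
        try:
            comps = enumerate_completions(t)
        except MendelianError:
            return
        for c in comps:
            assert c.is_complete
            assert is_mendelian_consistent(c)
            for role in ("father", "mother", "offspring"):
                if getattr(t, role) != MISSING:
                    assert getattr(c, role) == getattr(t, role)


class TestScoreTables:
    @pytest.mark.parametrize("chrom,sex", CONTEXTS)
    @pytest.mark.parametrize("model", list(Model))
    def test_tables_match_scalar_functions(self, model, chrom, sex):
        code, ex, var, cons = score_tables(model, chrom, sex)
        fs, ms, os_ = oracle_member_spaces(chrom, sex)
        for f, m in itertools.product(fs, ms):
            for o in os_:
                consistent = o in oracle_outcomes(f, m, chrom, sex)
                assert cons[f, m, o] == consistent
                if consistent:
                    s = trio_score(Trio(f, m, o, sex=sex), model, chrom)
                    assert code[o] - ex[f, m] == pytest.approx(s.x_minus_e)
                    assert var[f, m] == pytest.approx(s.var_x)
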