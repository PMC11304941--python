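"""Trio phasing rules, imputation and post-imputation correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magicphase.constants import (
    ST_IMPUTED,
    ST_MD,
    ST_ME,
    ST_RESOLVED,
    ST_TH,
)
from magicphase.phasing import (
    FounderHeterozygosityError,
    PhasePair,
    check_phase_consistency,
    correct_phases,
    effective_genotype,
    impute_phases,
    phase_g1,
    phase_trio,
)

from conftest import mosaic_from_strings


def g(*pairs):
    return np.array(pairs, dtype=np.int8)


class TestPhaseG1:
    def test_offspring_inherits_founder_alleles(self):
        ph = phase_g1(g((1, 1), (1, 1)), g((2, 2), (1, 1)))
        assert ph.pat_allele.tolist() == [1, 1]
        assert ph.mat_allele.tolist() == [2, 1]
        assert (ph.pat_state == ST_RESOLVED).all()

    def test_missing_founder_genotype_gives_md(self):
        ph = phase_g1(g((1, 1)), g((0, 0)))
        assert ph.pat_state[0] == ST_MD and ph.mat_state[0] == ST_MD
        assert ph.pat_allele[0] == 0

    def test_heterozygous_founder_raises(self):
        with pytest.raises(FounderHeterozygosityError, match="father1.*m2"):
            phase_g1(g((1, 1), (1, 2)), g((2, 2), (2, 2)),
                     father_id="father1", markers=["m1", "m2"])


class TestPhaseTrio:
    @pytest.mark.parametrize(
        "fa, mo, of, expect",
        [
            # only one consistent assignment
            ((1, 1), (1, 2), (1, 2), ("resolved", 1, 2)),
            ((1, 2), (1, 1), (1, 2), ("resolved", 2, 1)),
            # all trio members heterozygous
            ((1, 2), (1, 2), (1, 2), ("TH", None, None)),
            # Mendelian errors
            ((1, 1), (1, 1), (1, 2), ("ME", None, None)),
            ((1, 1), (2, 2), (1, 1), ("ME", None, None)),
            ((1, 1), (2, 2), (2, 2), ("ME", None, None)),
            # missing data
            ((0, 0), (1, 2), (1, 2), ("MD", None, None)),
            ((1, 1), (1, 2), (0, 0), ("MD", None, None)),
            # homozygous offspring
            ((1, 2), (1, 2), (1, 1), ("resolved", 1, 1)),
            ((1, 2), (1, 2), (2, 2), ("resolved", 2, 2)),
        ],
    )
    def test_segregation_rules(self, fa, mo, of, expect):
        ph = phase_trio(g(fa), g(mo), g(of))
        kind, pat, mat = expect
        if kind == "resolved":
            assert ph.pat_state[0] == ST_RESOLVED
            assert (ph.pat_allele[0], ph.mat_allele[0]) == (pat, mat)
        else:
            code = {"TH": ST_TH, "MD": ST_MD, "ME": ST_ME}[kind]
            assert ph.pat_state[0] == code and ph.mat_state[0] == code
            assert ph.pat_allele[0] == 0 and ph.mat_allele[0] == 0

    @given(
        st.lists(
            st.tuples(*[st.sampled_from([0, 1, 2])] * 6),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_under_allele_relabeling(self, rows):
        def norm(pairs):
            return np.sort(np.array(pairs, np.int8).reshape(-1, 3, 2), axis=2)

        trio = norm(rows)
        fa, mo, of = trio[:, 0], trio[:, 1], trio[:, 2]
        # promote half-missing to missing, as the reader does
        for arr in (fa, mo, of):
            half = (arr == 0).any(axis=1)
            arr[half] = 0
        swapped = [np.sort(np.where(a == 0, 0, 3 - a), axis=1) for a in (fa, mo, of)]
        ph = phase_trio(fa, mo, of)
        ph2 = phase_trio(*swapped)
        assert np.array_equal(ph.pat_state, ph2.pat_state)
        assert np.array_equal(ph.mat_state, ph2.mat_state)
        resolved = ph.pat_allele > 0
        assert np.array_equal(
            np.where(resolved, 3 - ph.pat_allele, 0), ph2.pat_allele
        )

    def test_phase_consistency_on_resolved_loci(self):
        fa, mo, of = g((1, 1), (1, 2)), g((1, 2), (1, 2)), g((1, 2), (2, 2))
        ph = phase_trio(fa, mo, of)
        check_phase_consistency(ph, of)


class TestImputePhases:
    def _th_setup(self):
        # one TH locus; origin on both homologs imputed as P
        ph = phase_trio(g((1, 2)), g((1, 2)), g((1, 2)))
        mosaic = mosaic_from_strings("P", "P", pat_inf=[False], mat_inf=[False])
        father = PhasePair(np.array([2], np.int8), np.array([1], np.int8),
                           np.zeros(1, np.int8), np.zeros(1, np.int8),
                           np.zeros(1, np.int8))
        mother = PhasePair(np.array([1], np.int8), np.array([2], np.int8),
                           np.zeros(1, np.int8), np.zeros(1, np.int8),
                           np.zeros(1, np.int8))
        return ph, mosaic, father, mother

    def test_th_locus_takes_parent_haplotype_allele(self):
        ph, mosaic, father, mother = self._th_setup()
        out = impute_phases(ph, mosaic, father, mother, "imputeTHonly")
        assert out.pat_allele[0] == 2 and out.pat_state[0] == ST_IMPUTED
        assert out.mat_allele[0] == 1 and out.mat_state[0] == ST_IMPUTED

    def test_impute_not_is_identity(self):
        ph, mosaic, father, mother = self._th_setup()
        out = impute_phases(ph, mosaic, father, mother, "imputeNot")
        assert (out.pat_state == ph.pat_state).all()
        assert (out.pat_allele == 0).all()

    def test_me_locus_untouched_under_imputeTHonly(self):
        ph = phase_trio(g((1, 1)), g((1, 1)), g((1, 2)))  # ME
        mosaic = mosaic_from_strings("P", "P", [False], [False])
        fa = PhasePair(np.array([2], np.int8), np.array([1], np.int8),
                       np.zeros(1, np.int8), np.zeros(1, np.int8), np.zeros(1, np.int8))
        out = impute_phases(ph, mosaic, fa, fa, "imputeTHonly")
        assert out.pat_state[0] == ST_ME and out.pat_allele[0] == 0

    def test_me_locus_imputed_under_imputeAll_from_origin_side(self):
        ph = phase_trio(g((1, 1)), g((1, 1)), g((1, 2)))  # ME
        mosaic = mosaic_from_strings("M", "M", [False], [False])
        parent = PhasePair(np.array([2], np.int8), np.array([1], np.int8),
                           np.zeros(1, np.int8), np.zeros(1, np.int8),
                           np.zeros(1, np.int8))
        out = impute_phases(ph, mosaic, parent, parent, "imputeAll")
        # origin M -> mother-side haplotype allele (parent maternal = 1)
        assert out.pat_allele[0] == 1 and out.pat_state[0] == ST_IMPUTED

    def test_unassigned_origin_leaves_locus_unchanged(self):
        ph, mosaic, father, mother = self._th_setup()
        mosaic = mosaic_from_strings("*", "*")
        out = impute_phases(ph, mosaic, father, mother, "imputeAll")
        assert out.pat_state[0] == ST_TH


class TestCorrectPhases:
    def _imputed(self, pat, mat, pat_state, mat_state, cause=ST_TH):
        n = len(pat)
        return PhasePair(
            np.array(pat, np.int8),
            np.array(mat, np.int8),
            np.array(pat_state, np.int8),
            np.array(mat_state, np.int8),
            np.full(n, cause, np.int8),
        )

    def test_false_hom_undone(self):
        ph = self._imputed([1], [1], [ST_IMPUTED], [ST_IMPUTED])
        out = correct_phases(ph, g((1, 2)), "correctFalseHom")
        assert out.pat_allele[0] == 0 and out.pat_state[0] == ST_TH
        assert out.mat_allele[0] == 0 and out.mat_state[0] == ST_TH

    def test_reimpute_fills_remaining_genotype_allele(self):
        ph = self._imputed([1], [0], [ST_IMPUTED], [ST_TH])
        out = correct_phases(ph, g((1, 2)), "reImpute")
        assert out.mat_allele[0] == 2 and out.mat_state[0] == ST_IMPUTED

    def test_correct_all_chains_both(self):
        ph = self._imputed([1, 1], [1, 0], [ST_IMPUTED] * 2, [ST_IMPUTED, ST_TH])
        out = correct_phases(ph, g((1, 2), (1, 2)), "correctAll")
        assert out.pat_allele[0] == 0  # false hom undone
        assert out.mat_allele[1] == 2  # re-imputed

    def test_correct_not_is_identity(self):
        ph = self._imputed([1], [1], [ST_IMPUTED], [ST_IMPUTED])
        out = correct_phases(ph, g((1, 2)), "correctNot")
        assert out.pat_allele[0] == 1

    def test_false_hom_never_touches_resolved_loci(self):
        ph = self._imputed([1], [1], [ST_RESOLVED], [ST_RESOLVED], cause=ST_RESOLVED)
        out = correct_phases(ph, g((1, 2)), "correctFalseHom")
        assert out.pat_allele[0] == 1 and out.pat_state[0] == ST_RESOLVED


class TestEffectiveGenotype:
    def test_phase_pair_overrides_missing_genotype(self):
        ph = PhasePair(
            np.array([1], np.int8), np.array([2], np.int8),
            np.full(1, ST_IMPUTED, np.int8), np.full(1, ST_IMPUTED, np.int8),
            np.full(1, ST_MD, np.int8),
        )
        eff = effective_genotype(ph, g((0, 0)))
        assert eff.tolist() == [[1, 2]]

    def test_unresolved_loci_fall_back_to_genotype(self):
        ph = PhasePair(
            np.zeros(1, np.int8), np.zeros(1, np.int8),
            np.full(1, ST_TH, np.int8), np.full(1, ST_TH, np.int8),
            np.full(1, ST_TH, np.int8),
        )
        eff = effective_genotype(ph, g((1, 2)))
        assert eff.tolist() == [[1, 2]]
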