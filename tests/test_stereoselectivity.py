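"""Enantiomer assignment and the optical-purity/ee calculus."""

import math

import numpy as np
import pytest

from chirospec import (DELTA_EPSILON, Spectrum, ValidationError,
                       assign_enantiomer, enantiomer_calculus, estimate_op,
                       normalized_difference, table_row,
                       unreacted_fraction_check)
from chirospec.stereoselectivity import DELTA, LAMBDA, RACEMIC
from chirospec.synthetic import CoupletModel

# Published enantiomer table: Δε_295, op, ee%, frac_Λ, frac_Δ
ENANTIOMER_TABLE = [
    ("A23C-Ru", +37.73, 0.331, 33.1, 0.665, 0.335),
    ("K29C-Ru", -74.73, 0.656, 65.6, 0.172, 0.828),
    ("E39C-Ru", +4.75, 0.042, 4.2, 0.521, 0.479),
]

GRID = np.arange(240.0, 331.0)


def deps(values, grid=GRID):
    return Spectrum(grid, values, DELTA_EPSILON)


class TestNormalizedDifference:
    def test_full_labeling_zero_parent_is_identity(self):
        conj = deps(np.linspace(-5, 5, GRID.size))
        parent = deps(np.zeros(GRID.size))
        out = normalized_difference(conj, parent, 1.0)
        np.testing.assert_array_equal(out.values, conj.values)

    def test_equal_spectra_give_zero_regardless_of_labeling(self):
        s = deps(np.sin(GRID / 10.0))
        for ratio in (0.5, 0.82, 1.0):
            assert np.all(normalized_difference(s, s, ratio).values == 0.0)

    def test_partial_labeling_recovers_pure_couplet(self):
        couplet = CoupletModel().evaluate(GRID)
        host = 10.0 * np.exp(-0.5 * ((GRID - 285) / 25) ** 2)
        conj = deps(host + 0.8 * couplet)
        parent = deps(host)
        out = normalized_difference(conj, parent, 0.8)
        np.testing.assert_allclose(out.values, couplet, atol=1e-10)

    def test_invalid_label_ratio_rejected(self):
        s = deps(np.zeros(GRID.size))
        with pytest.raises(ValidationError):
            normalized_difference(s, s, 0.0)


class TestAssignEnantiomer:
    def test_positive_cotton_effect_is_lambda(self):
        diff = deps(0.331 * CoupletModel().evaluate(GRID))   # Δε(295) = +37.7
        assignment, couplet = assign_enantiomer(diff)
        assert assignment == LAMBDA
        assert couplet            # compensating negative lobe at 270 nm

    def test_negative_cotton_effect_is_delta(self):
        diff = deps(-0.656 * CoupletModel().evaluate(GRID))  # Δε(295) = -74.8
        assignment, couplet = assign_enantiomer(diff)
        assert assignment == DELTA
        assert couplet

    def test_zero_spectrum_is_racemic_without_couplet(self):
        assignment, couplet = assign_enantiomer(deps(np.zeros(GRID.size)))
        assert assignment == RACEMIC and not couplet

    def test_lone_band_without_opposite_lobe_flags_inconsistent(self):
        diff = deps(50.0 * np.exp(-0.5 * ((GRID - 295) / 10) ** 2))
        assignment, couplet = assign_enantiomer(diff)
        assert assignment == LAMBDA and not couplet


class TestEnantiomerCalculus:
    @pytest.mark.parametrize("name,de,op,ee,fl,fd", ENANTIOMER_TABLE)
    def test_published_rows_reproduced_to_printed_precision(self, name, de, op,
                                                            ee, fl, fd):
        row = table_row(enantiomer_calculus(de, 114.0), name)
        assert row["op"] == op
        assert row["ee_percent"] == ee
        assert row["frac_lambda"] == fl
        assert row["frac_delta"] == fd

    @pytest.mark.parametrize("name,ratio", [("A23C-Ru", 0.504), ("E39C-Ru", 0.919)])
    def test_published_selection_ratios(self, name, ratio):
        de = dict((n, d) for n, d, *_ in ENANTIOMER_TABLE)[name]
        assert table_row(enantiomer_calculus(de, 114.0))["selection_ratio_dl"] == ratio

    def test_racemic_input(self):
        r = enantiomer_calculus(0.0)
        assert r.op == 0.0 and r.ee_percent == 0.0
        assert r.frac_lambda == r.frac_delta == 0.5
        assert r.er == 1.0 and r.selection_ratio_dl == 1.0
        assert r.major == RACEMIC

    def test_fractions_always_sum_to_one_and_er_consistent(self):
        for de in np.linspace(-114, 114, 41):
            r = enantiomer_calculus(de)
            assert r.frac_lambda + r.frac_delta == 1.0
            lo = min(r.frac_lambda, r.frac_delta)
            hi = max(r.frac_lambda, r.frac_delta)
            if lo > 0:
                assert r.er * lo == pytest.approx(hi, rel=1e-12)
                assert r.selection_ratio_dl * (r.frac_lambda / r.frac_delta) == \
                    pytest.approx(1.0, rel=1e-12)

    def test_mirror_symmetry(self):
        plus, minus = enantiomer_calculus(37.73), enantiomer_calculus(-37.73)
        assert plus.frac_lambda == pytest.approx(minus.frac_delta)
        assert plus.ee_percent == pytest.approx(minus.ee_percent)
        assert plus.er == pytest.approx(minus.er)
        assert plus.major == LAMBDA and minus.major == DELTA

    def test_fractions_match_brute_force_linear_system(self):
        """Closed-form fractions equal numpy solutions of
        E1 − E2 = op, E1 + E2 = 1, over a dense op grid."""
        A = np.array([[1.0, -1.0], [1.0, 1.0]])
        worst = 0.0
        for op in np.linspace(-1.0, 1.0, 201):
            r = enantiomer_calculus(op * 114.0, 114.0)
            e1, e2 = np.linalg.solve(A, np.array([op, 1.0]))
            worst = max(worst, abs(r.frac_lambda - e1), abs(r.frac_delta - e2))
        assert worst < 1e-12

    def test_marginal_overshoot_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            r = enantiomer_calculus(115.0, 114.0)
        assert r.op == 1.0 and r.clipped

    def test_gross_overshoot_rejected(self):
        with pytest.raises(ValidationError):
            enantiomer_calculus(120.0, 114.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError):
            enantiomer_calculus(10.0, 0.0)


class TestEstimateOp:
    def test_noiseless_projection_is_exact(self):
        ref = CoupletModel().spectrum(GRID)
        for op in (-0.9, -0.33, 0.0, 0.042, 0.656):
            diff = deps(op * ref.values)
            assert estimate_op(diff, ref) == pytest.approx(op, abs=1e-12)

    def test_zero_reference_rejected(self):
        ref = deps(np.zeros(GRID.size))
        with pytest.raises(ValidationError):
            estimate_op(ref, ref)


class TestMassBalance:
    def test_perfect_balance(self):
        b = enantiomer_calculus(0.5 * 114.0)
        f = enantiomer_calculus(-0.5 * 114.0)
        res = unreacted_fraction_check(b, f, 1.0, 1.0)
        assert res.residual == pytest.approx(0.0, abs=1e-15)
        assert res.opposite_majors

    def test_equal_partition_of_published_op(self):
        b = enantiomer_calculus(+37.73)
        f = enantiomer_calculus(-37.73)
        res = unreacted_fraction_check(b, f, 1.0, 1.0)
        assert res.residual == pytest.approx(0.0, abs=1e-15)

    def test_same_sign_flags_failure(self):
        b = enantiomer_calculus(30.0)
        res = unreacted_fraction_check(b, b, 1.0, 1.0)
        assert not res.opposite_majors
        assert res.residual != 0.0

    def test_both_amounts_zero_rejected(self):
        b = enantiomer_calculus(30.0)
        with pytest.raises(ValidationError):
            unreacted_fraction_check(b, b, 0.0, 0.0)


def test_er_is_infinite_for_enantiopure():
    assert math.isinf(enantiomer_calculus(114.0, 114.0).er)
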