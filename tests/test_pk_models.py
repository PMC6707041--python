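"""Closed-form model curves checked against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkprop import (
    PKParamsIM,
    PKParamsIV,
    PKProfile,
    auc_analytic,
    auc_numeric,
    canonicalize_im,
    canonicalize_iv,
    cmax_im,
    conc_im,
    conc_iv,
    tmax_im,
    ug_per_ml_to_uM,
)


class TestConcIV:
    def test_t_zero_is_sum_of_amplitudes(self):
        p = PKParamsIV(A=10, B=5, alpha=3, beta=0.5)
        assert conc_iv(0.0, p) == pytest.approx(15.0)

    def test_monoexponential_half_life(self):
        p = PKParamsIV(A=0, B=5, alpha=3, beta=0.5)
        assert conc_iv(math.log(2) / 0.5, p) == pytest.approx(2.5)

    def test_matches_separately_coded_arithmetic(self):
        p = PKParamsIV(A=10, B=5, alpha=3, beta=0.5)
        expected = 10 * math.exp(-3 * 1.0) + 5 * math.exp(-0.5 * 1.0)
        assert conc_iv(1.0, p) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing(self):
        p = PKParamsIV(A=10, B=5, alpha=3, beta=0.5)
        t = np.linspace(0, 10, 500)
        assert np.all(np.diff(conc_iv(t, p)) < 0)

    def test_negative_time_rejected(self):
        p = PKParamsIV(A=10, B=5, alpha=3, beta=0.5)
        with pytest.raises(ValueError):
            conc_iv(-0.1, p)


class TestConcIM:
    def test_zero_at_dosing_time(self):
        p = PKParamsIM(amplitude=50, gamma=6, beta=0.5)
        assert conc_im(0.0, p) == 0.0

    def test_peak_matches_grid_search(self):
        p = PKParamsIM(amplitude=50, gamma=6, beta=0.5)
        grid = np.linspace(0, 3, 100_001)
        assert cmax_im(p) == pytest.approx(conc_im(grid, p).max(), rel=1e-6)

    def test_instantaneous_absorption_limit(self):
        p = PKParamsIM(amplitude=50, gamma=1e6, beta=0.5)
        t = np.array([0.1, 0.5, 1.0, 2.0])
        np.testing.assert_allclose(conc_im(t, p), 50 * np.exp(-0.5 * t), rtol=1e-6)

    def test_single_maximum_shape(self):
        p = PKParamsIM(amplitude=50, gamma=6, beta=0.5)
        t = np.linspace(0, 6, 2000)
        c = np.asarray(conc_im(t, p))
        i_max = int(np.argmax(c))
        assert np.all(np.diff(c[: i_max + 1]) > 0)
        assert np.all(np.diff(c[i_max:]) < 0)

    def test_degenerate_equal_rates_rejected(self):
        with pytest.raises(ValueError):
            PKParamsIM(amplitude=50, gamma=0.5, beta=0.5)


class TestTmaxCmax:
    def test_tmax_closed_form_vs_grid_argmax(self):
        p = PKParamsIM(amplitude=50, gamma=6, beta=0.5)
        assert tmax_im(p) == pytest.approx(math.log(12) / 5.5, rel=1e-12)
        grid = np.linspace(0, 3, 300_001)
        t_grid = grid[np.argmax(conc_im(grid, p))]
        assert tmax_im(p) == pytest.approx(t_grid, rel=1e-3)

    def test_tmax_symmetric_ratio(self):
        beta = 0.7
        p = PKParamsIM(amplitude=10, gamma=2 * beta, beta=beta)
        assert tmax_im(p) == pytest.approx(math.log(2) / beta, rel=1e-12)

    def test_tmax_formula_swap_invariant(self):
        # ln(g/b)/(g-b) is symmetric under exchanging the two rates
        g, b = 6.0, 0.5
        assert math.log(g / b) / (g - b) == pytest.approx(math.log(b / g) / (b - g))

    def test_cmax_matches_dense_grid(self):
        p = PKParamsIM(amplitude=50, gamma=6, beta=0.5)
        grid = np.linspace(0, 10 / p.beta, 10_000)
        assert cmax_im(p) == pytest.approx(conc_im(grid, p).max(), rel=1e-3)

    def test_cmax_linear_in_amplitude(self):
        p1 = PKParamsIM(amplitude=50, gamma=6, beta=0.5)
        p2 = PKParamsIM(amplitude=100, gamma=6, beta=0.5)
        assert cmax_im(p2) == pytest.approx(2 * cmax_im(p1), rel=1e-12)

    def test_cmax_fast_absorption_limit_is_amplitude(self):
        p = PKParamsIM(amplitude=50, gamma=1e7, beta=0.5)
        assert cmax_im(p) == pytest.approx(50.0, rel=1e-3)


class TestAUC:
    def test_iv_analytic_value_and_quadrature(self):
        from scipy.integrate import quad

        p = PKParamsIV(A=10, B=5, alpha=2, beta=0.5)
        assert auc_analytic(p) == pytest.approx(10 / 2 + 5 / 0.5, rel=1e-12)
        num, _ = quad(lambda t: conc_iv(t, p), 0, np.inf)
        assert auc_analytic(p) == pytest.approx(num, rel=1e-8)

    def test_im_analytic_value_and_quadrature(self):
        from scipy.integrate import quad

        p = PKParamsIM(amplitude=50, gamma=6, beta=0.5)
        assert auc_analytic(p) == pytest.approx(50 * (2 - 1 / 6), rel=1e-12)
        num, _ = quad(lambda t: conc_im(t, p), 0, np.inf)
        assert auc_analytic(p) == pytest.approx(num, rel=1e-8)

    def test_empty_iv_model_rejected(self):
        with pytest.raises(ValueError):
            PKParamsIV(A=0, B=0, alpha=2, beta=0.5)

    def test_trapezoid_rectangle(self):
        prof = PKProfile(times=[0.0, 1.0], concentrations=[10.0, 10.0])
        assert auc_numeric(prof) == pytest.approx(10.0)

    def test_trapezoid_matches_analytic_on_dense_long_grid(self):
        # grid long (20 / slowest rate) and fine enough that truncation
        # plus discretization stay below 0.5%
        for p in (PKParamsIM(amplitude=50, gamma=6, beta=0.5), PKParamsIV(8, 4, 3, 0.4)):
            rmin = min(p.beta, p.gamma if isinstance(p, PKParamsIM) else p.alpha)
            t = np.arange(0, 20 / rmin, 0.001 / rmin)
            c = conc_im(t, p) if isinstance(p, PKParamsIM) else conc_iv(t, p)
            prof = PKProfile(times=t, concentrations=c)
            assert auc_numeric(prof) == pytest.approx(auc_analytic(p), rel=5e-3)

    def test_all_zero_concentrations(self):
        prof = PKProfile(times=[0.0, 1.0, 2.0], concentrations=[0.0, 0.0, 0.0])
        assert auc_numeric(prof) == 0.0

    def test_single_point_rejected(self):
        prof = PKProfile(times=[0.0], concentrations=[1.0])
        with pytest.raises(ValueError):
            auc_numeric(prof)


class TestUnitConversion:
    @pytest.mark.parametrize(
        "c,mw,expected",
        [
            (6.0, 467.5, 6000 / 467.5),  # tobramycin free base -> 12.83 μM
            (0.0, 467.5, 0.0),
            (1.0, 1000.0, 1.0),
        ],
    )
    def test_mass_to_molar(self, c, mw, expected):
        assert ug_per_ml_to_uM(c, mw) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_molar_mass_rejected(self):
        with pytest.raises(ValueError):
            ug_per_ml_to_uM(1.0, 0.0)


class TestCanonicalization:
    def test_swapped_bateman_parameters_reproduce_identical_curve(self):
        # a(e^{-βt} − e^{-γt}) with rates exchanged and amplitude negated
        # is the same function; canonicalization recovers one fixed form
        t = np.linspace(0, 5, 101)
        canon = canonicalize_im(-50.0, 0.5, 6.0)  # swapped branch
        ref = PKParamsIM(amplitude=50.0, gamma=6.0, beta=0.5)
        np.testing.assert_array_equal(conc_im(t, canon), conc_im(t, ref))
        assert canon == ref

    def test_canonical_branch_passes_through(self):
        p = canonicalize_im(50.0, 6.0, 0.5)
        assert (p.amplitude, p.gamma, p.beta) == (50.0, 6.0, 0.5)

    def test_nonpositive_canonical_amplitude_rejected(self):
        with pytest.raises(ValueError):
            canonicalize_im(50.0, 0.5, 6.0)  # a negative curve everywhere

    def test_iv_phase_ordering(self):
        p = canonicalize_iv(A=4.0, B=8.0, alpha=0.4, beta=3.0)
        assert p.alpha > p.beta
        assert (p.A, p.alpha) == (8.0, 3.0)
        assert (p.B, p.beta) == (4.0, 0.4)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    amp=st.floats(0.1, 1e3),
    beta=st.floats(0.01, 5.0),
    ratio=st.floats(1.01, 100.0),
    t=st.floats(0, 50),
)
def test_bateman_nonnegative_for_all_valid_params(amp, beta, ratio, t):
    p = PKParamsIM(amplitude=amp, gamma=beta * ratio, beta=beta)
    assert conc_im(t, p) >= 0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    A=st.floats(0.0, 1e3),
    B=st.floats(0.1, 1e3),
    beta=st.floats(0.01, 5.0),
    ratio=st.floats(1.01, 100.0),
    t=st.floats(0, 50),
)
def test_biexponential_nonnegative_and_decreasing(A, B, beta, ratio, t):
    p = PKParamsIV(A=A, B=B, alpha=beta * ratio, beta=beta)
    c0, c1 = conc_iv(t, p), conc_iv(t + 0.1, p)
    assert c0 >= 0 and c1 < c0


def test_profile_validation():
    with pytest.raises(ValueError):
        PKProfile(times=[0.0, 1.0, 0.5], concentrations=[1, 2, 3])
    with pytest.raises(ValueError):
        PKProfile(times=[0.0, 1.0], concentrations=[1.0])
    with pytest.raises(ValueError):
        PKProfile(times=[-0.5, 1.0], concentrations=[1.0, 2.0])
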