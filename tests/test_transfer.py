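"""Pairwise transfer rule and the discrete transfer operator."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pgptransfer as pt


class TestTransferFraction:
    def test_inside_window_returns_efficiency(self, linear_params):
        # delta_min ~ 25.12, delta_max ~ 79.43: d = 50 is admissible
        assert pt.transfer_fraction(50.0, linear_params) == 0.2

    @pytest.mark.parametrize("d", [0.0, 10.0, 1.0e4])
    def test_outside_window_returns_zero(self, d, linear_params):
        assert pt.transfer_fraction(d, linear_params) == 0.0

    def test_equality_at_thresholds_returns_zero(self, linear_params):
        assert pt.transfer_fraction(linear_params.delta_min, linear_params) == 0.0
        assert pt.transfer_fraction(linear_params.delta_max, linear_params) == 0.0

    def test_negative_difference_rejected(self, linear_params):
        with pytest.raises(ValueError, match="nonnegative"):
            pt.transfer_fraction(-1.0, linear_params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            pt.TransferParams(0.4, 1.5, 10.0, 100.0)
        with pytest.raises(ValueError, match="delta"):
            pt.TransferParams(0.4, 0.2, 100.0, 10.0)
        with pytest.raises(ValueError, match="tau"):
            pt.TransferParams(-0.1, 0.2, 10.0, 100.0)
        with pytest.raises(ValueError, match="threshold_space"):
            pt.TransferParams(0.4, 0.2, 10.0, 100.0, "sqrt")


class TestTransferPair:
    def test_admissible_pair_exchanges_a_fifth_of_the_difference(self, linear_params):
        # difference 50 inside (25.1, 79.4): 0.2 * 50 = 10 moves
        assert pt.transfer_pair(10.0, 60.0, linear_params) == (20.0, 50.0)

    def test_identical_and_distant_pairs_unchanged(self, linear_params):
        assert pt.transfer_pair(100.0, 100.0, linear_params) == (100.0, 100.0)
        assert pt.transfer_pair(1.0, 1000.0, linear_params) == (1.0, 1000.0)

    def test_log_mode_exchanges_fraction_of_decades(self, log_params):
        # 1.75 decades apart, inside (1.4, 1.9): 0.2 * 1.75 = 0.35 decades move
        p1, p2 = pt.transfer_pair(10.0 ** 0.75, 10.0 ** 2.5, log_params)
        assert np.log10(p1) == pytest.approx(1.10, abs=1e-12)
        assert np.log10(p2) == pytest.approx(2.15, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        p1=st.floats(min_value=1.0, max_value=1.0e4),
        p2=st.floats(min_value=1.0, max_value=1.0e4),
        sigma=st.floats(min_value=0.01, max_value=0.99),
        lo=st.floats(min_value=0.0, max_value=500.0),
        width=st.floats(min_value=1.0, max_value=5000.0),
    )
    def test_linear_pair_conserves_sum_exactly(self, p1, p2, sigma, lo, width):
        params = pt.TransferParams(0.4, sigma, lo, lo + width, "linear")
        q1, q2 = pt.transfer_pair(p1, p2, params)
        assert q1 + q2 == p1 + p2  # bit-level conservation

    @settings(max_examples=100, deadline=None)
    @given(
        p1=st.floats(min_value=1.0, max_value=1.0e4),
        p2=st.floats(min_value=1.0, max_value=1.0e4),
    )
    def test_argument_order_symmetry(self, p1, p2, linear_params):
        q1, q2 = pt.transfer_pair(p1, p2, linear_params)
        r2, r1 = pt.transfer_pair(p2, p1, linear_params)
        assert (q1, q2) == (r1, r2)

    def test_smaller_gains_larger_loses(self, linear_params):
        q1, q2 = pt.transfer_pair(60.0, 10.0, linear_params)
        assert q1 == 50.0 and q2 == 20.0  # larger first argument lost mass

    def test_out_of_range_rejected(self, linear_params):
        with pytest.raises(ValueError, match="outside"):
            pt.transfer_pair(0.5, 100.0, linear_params)


@pytest.fixture(scope="module", params=["linear", "log10"])
def kernel(request, grid):
    params = pt.TransferParams(
        0.4, 0.2, 10.0 ** 1.4, 10.0 ** 1.9, request.param
    )
    return pt.build_redistribution_kernel(grid, params)


class TestRedistributionKernel:
    def test_all_pair_rows_sum_to_one(self, kernel, grid):
        n = grid.n_bins
        totals = kernel._matrix.sum(axis=0)
        assert np.allclose(np.asarray(totals).ravel(), 1.0, atol=1e-12)

    def test_no_transfer_pair_stays_in_source_bin(self, kernel):
        # adjacent bins differ by far less than delta_min in either space
        idx, weights = kernel.pair_destination(10, 11)
        dest = idx[weights > 0]
        assert set(dest.tolist()) <= {10}

    def test_expected_destination_matches_pair_rule(self, kernel, grid):
        """First-moment preservation: the destination's expected working-space
        coordinate equals the transfer_pair outcome, for every pair."""
        x = kernel.working_midpoints()
        logspace = kernel.params.threshold_space == "log10"
        rng = np.random.default_rng(0)
        for i, j in zip(rng.integers(0, 80, 200), rng.integers(0, 80, 200)):
            idx, wts = kernel.pair_destination(i, j)
            expected = float(wts @ x[idx])
            q1, _ = pt.transfer_pair(grid.midpoints[i], grid.midpoints[j],
                                     kernel.params)
            target = np.log10(q1) if logspace else q1
            assert expected == pytest.approx(target, abs=1e-10)


class TestTransferOperator:
    def test_point_mass_is_a_fixed_point(self, grid, linear_params):
        q = np.zeros(80)
        q[40] = 1.0
        dens = pt.DensityState(grid, q)
        kernel = pt.build_redistribution_kernel(grid, linear_params)
        out = pt.apply_transfer_operator(dens, kernel)
        assert np.allclose(out.bin_prob, q, atol=1e-14)

    def test_output_normalized_for_any_density(self, grid, kernel, rng):
        q = rng.random(80)
        dens = pt.DensityState(grid, q / q.sum())
        out = pt.apply_transfer_operator(dens, kernel)
        assert abs(out.bin_prob.sum() - 1.0) < 1e-10

    def test_two_point_density_splits_into_quarter_masses(self, grid, linear_params):
        """Half mass near p=10, half near p=60 (difference inside the window):
        a random pair transfers with probability 1/2, leaving quarter masses
        at (bins containing) 10, 20, 50 and 60."""
        i10, i60 = grid.bin_index(10.0), grid.bin_index(60.0)
        q = np.zeros(80)
        q[i10] = q[i60] = 0.5
        kernel = pt.build_redistribution_kernel(grid, linear_params)
        out = pt.apply_transfer_operator(pt.DensityState(grid, q), kernel)
        m10, m60 = grid.midpoints[i10], grid.midpoints[i60]
        new_lo, new_hi = pt.transfer_pair(m10, m60, linear_params)
        # untransferred pairs (same-bin partner) stay exactly at their midpoint
        assert out.bin_prob[i10] == pytest.approx(0.25, abs=1e-10)
        assert out.bin_prob[i60] == pytest.approx(0.25, abs=1e-10)
        # transferred outcomes split across the two bracketing bins
        for target in (new_lo, new_hi):
            k = np.searchsorted(grid.midpoints, target)
            mass = out.bin_prob[k - 1: k + 1].sum()
            assert mass == pytest.approx(0.25, abs=1e-10)

    def test_monte_carlo_pair_sampling_oracle(self, grid, kernel, rng):
        """Independent oracle: sample 1e6 random pairs from the density, apply
        the pair rule, bin the outcomes; agreement within 3 standard errors
        (plus the sub-bin-width discretization of the kernel's mass split)."""
        dens = pt.day0_coculture_template(grid=grid)
        out = pt.apply_transfer_operator(dens, kernel)
        n_pairs = 1_000_000
        mids = grid.midpoints
        i = rng.choice(80, size=n_pairs, p=dens.bin_prob)
        j = rng.choice(80, size=n_pairs, p=dens.bin_prob)
        params = kernel.params
        logspace = params.threshold_space == "log10"
        xi, xj = (np.log10(mids[i]), np.log10(mids[j])) if logspace else (
            mids[i], mids[j])
        d = np.abs(xi - xj)
        if logspace:
            d = np.rint(d / grid.bin_width_log10) * grid.bin_width_log10
        phi = np.where((d > params.threshold_lo) & (d < params.threshold_hi),
                       params.sigma, 0.0)
        x_new = xi + phi * (xj - xi)
        p_new = 10.0 ** x_new if logspace else x_new
        if logspace:
            # outcomes stay on the midpoint lattice: binning is exact and the
            # comparison can be bin-wise at 3 standard errors
            mc = np.bincount(grid.bin_index(p_new), minlength=80) / n_pairs
            se = np.sqrt(
                np.maximum(out.bin_prob * (1 - out.bin_prob), 1e-12) / n_pairs
            )
            assert np.all(np.abs(mc - out.bin_prob) < 3 * se + 1e-9)
        else:
            # the kernel's moment-preserving split displaces mass by less than
            # one bin width; compare distributions by W1 on the log10 axis
            from scipy.stats import wasserstein_distance

            w1 = wasserstein_distance(
                np.log10(p_new), grid.log_midpoints, v_weights=out.bin_prob
            )
            assert w1 < grid.bin_width_log10

    def test_mean_conserved_in_working_space(self, grid, kernel, rng):
        x = kernel.working_midpoints()
        for _ in range(5):
            q = rng.random(80)
            q /= q.sum()
            out = kernel.apply(q)
            assert float(out @ x) == pytest.approx(float(q @ x), rel=1e-8)

    def test_variance_contracts_with_wide_open_thresholds(self, grid, day0):
        """sigma < 1/2 and an unrestricted window: each transfer shrinks the
        pair difference by (1 - 2 sigma), so density variance never grows."""
        params = pt.TransferParams(0.4, 0.2, 0.0, 1.0e9, "linear")
        kernel = pt.build_redistribution_kernel(grid, params)
        mids = grid.midpoints
        q = day0.bin_prob.copy()
        prev = None
        for _ in range(10):
            mean = q @ mids
            var = q @ (mids - mean) ** 2
            if prev is not None:
                assert var <= prev + 1e-8 * prev
            prev = var
            q = kernel.apply(q)
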