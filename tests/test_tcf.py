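import logging

import numpy as np
import pytest

from imtkit import (
    GapEnsemble,
    TimeGrid,
    analytic_equilibrium_stats,
    batch_errors,
    compute_tcfs,
    equilibrium_stats,
    generate_gap_ensemble,
    reweighting_diagnostics,
)
from imtkit.core import K_B

BETA300 = 1.0 / (K_B * 300.0)


def make_ensemble(u_jk, u_jg, dt=0.1, j=1, g=3):
    """Equilibrium-tagged ensemble from explicit channel arrays."""
    u_jk = np.asarray(u_jk, dtype=float)
    grid = TimeGrid(u_jk.shape[1], dt)
    return GapEnsemble(
        propagation_state=j,
        sampling_state=j,
        grid=grid,
        channels={(j, 2): u_jk, (j, g): np.asarray(u_jg, dtype=float)},
    )


class TestEquilibriumStats:
    def test_constant_channel(self):
        ens = make_ensemble(np.full((4, 6), 0.3), np.zeros((4, 6)))
        st = equilibrium_stats(ens, 1, 2)
        assert st.mean_gap == pytest.approx(0.3)
        assert st.variance == pytest.approx(0.0, abs=1e-15)

    def test_surrogate_mean_matches_closed_form(self, one_mode_model):
        n = 20000
        ens = generate_gap_ensemble(
            one_mode_model, 2, 2, n=n, grid=TimeGrid(40, 0.1), seed=31
        )
        st = equilibrium_stats(ens, 2, 3, n_batches=10)
        exact = analytic_equilibrium_stats(one_mode_model, 2, 3)
        assert exact.mean_gap == pytest.approx(-0.1125)
        assert st.mean_gap == pytest.approx(exact.mean_gap, abs=3 * st.se_mean)

    def test_surrogate_variance_matches_closed_form(self, one_mode_model):
        n = 20000
        ens = generate_gap_ensemble(
            one_mode_model, 2, 2, n=n, grid=TimeGrid(40, 0.1), seed=32
        )
        st = equilibrium_stats(ens, 2, 3, n_batches=10)
        # SE of the variance via its batch-level ingredients
        se_var = np.sqrt(
            st.se_second_moment**2 + (2 * st.mean_gap * st.se_mean) ** 2
        )
        assert st.variance == pytest.approx(0.0155274, abs=3 * se_var + 1e-6)

    def test_rejects_nonequilibrium_ensemble(self, one_mode_model):
        ens = generate_gap_ensemble(
            one_mode_model, 2, 1, n=10, grid=TimeGrid(5, 0.1), seed=33
        )
        with pytest.raises(ValueError, match="equilibrium"):
            equilibrium_stats(ens, 2, 3)


class TestReweightingDiagnostics:
    def test_uniform_weights_full_ess(self):
        ens = make_ensemble(np.random.default_rng(0).normal(size=(8, 5)),
                            np.zeros((8, 5)))
        diag = reweighting_diagnostics(ens, 1, 300.0, ground_index=3)
        assert diag.ess == pytest.approx(diag.n_origins)
        np.testing.assert_allclose(diag.weights, 1.0 / diag.n_origins)

    def test_two_origin_ess_value(self):
        # beta dU_jg = +2 and -2: ESS = (e^2+e^-2)^2/(e^4+e^-4) = 1.0366
        du = 2.0 / BETA300
        ens = make_ensemble(
            np.zeros((2, 2)), np.array([[du, du], [-du, -du]])
        )
        diag = reweighting_diagnostics(ens, 1, 300.0, ground_index=3, n_lags=2)
        assert diag.ess == pytest.approx(56.6165 / 54.6165, abs=1e-4)

    def test_low_ess_logged(self, caplog):
        rng = np.random.default_rng(1)
        # huge fluctuations of U_jg force weight collapse
        ujg = rng.normal(scale=0.5, size=(50, 4))
        ens = make_ensemble(rng.normal(size=(50, 4)), ujg)
        with caplog.at_level(logging.WARNING, logger="imtkit"):
            reweighting_diagnostics(ens, 1, 300.0, ground_index=3, ess_floor=0.5)
        assert any("effective sample size" in r.message for r in caplog.records)


class TestComputeTcfs:
    def test_zero_fluctuations_give_zero_tcfs(self):
        ens = make_ensemble(np.full((6, 8), 0.42), np.zeros((6, 8)))
        tcf = compute_tcfs(ens, 1, 2, temperature=300.0, ground_index=3)
        np.testing.assert_allclose(tcf.c1, 0.0, atol=1e-14)
        np.testing.assert_allclose(tcf.c2, 0.0, atol=1e-14)

    def test_two_origin_weighted_average(self):
        # beta dU_jg in {+2, -2}, dU_jk(lag) in {0.10, -0.02} eV:
        # C1 = (0.10 e^2 - 0.02 e^-2)/(e^2 + e^-2) = 0.097842 eV
        # lag-0 cells are chosen so the pooled mean of U_jk vanishes and
        # the lag-1 fluctuations are exactly the stated values
        du = 2.0 / BETA300
        u_jk = np.array([[-0.04, 0.10], [-0.04, -0.02]])
        assert abs(u_jk.mean()) < 1e-15
        u_jg = np.array([[du, 0.0], [-du, 0.0]])
        ens = make_ensemble(u_jk, u_jg)
        tcf = compute_tcfs(
            ens, 1, 2, temperature=300.0, ground_index=3,
            n_lags=2, origin_stride=1, n_batches=2,
        )
        # restrict to origin t0=0 only: trajectory span 2, n_lags 2 -> one origin
        assert tcf.c1[1] == pytest.approx(0.097842, abs=1e-6)

    def test_two_origin_squared_fluctuation_average(self):
        # d(U^2) in {0.012, -0.004} with the same weights: C2 = 0.011712
        du = 2.0 / BETA300
        # choose U values whose squares fluctuate by the target amounts
        m2 = 0.02  # pooled second moment
        u_hi = np.sqrt(m2 + 0.012)
        u_lo = np.sqrt(m2 - 0.004)
        u_jk = np.array([[0.0, u_hi], [0.0, -u_lo]])
        # make the pooled second moment exactly m2: <U^2> over 4 cells
        # = (u_hi^2 + u_lo^2)/4; rescale lag-0 cells to fix it
        fill = np.sqrt((4 * m2 - u_hi**2 - u_lo**2) / 2.0)
        u_jk[0, 0] = fill
        u_jk[1, 0] = -fill
        u_jg = np.array([[du, 0.0], [-du, 0.0]])
        ens = make_ensemble(u_jk, u_jg)
        tcf = compute_tcfs(
            ens, 1, 2, temperature=300.0, ground_index=3,
            n_lags=2, origin_stride=1, n_batches=2,
        )
        assert tcf.c2[1] == pytest.approx(0.011712, abs=1e-6)

    def test_uniform_weight_reduction_to_plain_tcf(self):
        # dU_jg = 0 must reduce the estimator to the unweighted
        # origin-averaged fluctuation correlation, exactly
        rng = np.random.default_rng(7)
        u = rng.normal(size=(30, 20))
        ens = make_ensemble(u, np.zeros_like(u))
        n_lags, stride = 8, 3
        tcf = compute_tcfs(
            ens, 1, 2, temperature=300.0, ground_index=3,
            n_lags=n_lags, origin_stride=stride, n_batches=3,
        )
        du = u - u.mean()
        du2 = u**2 - (u**2).mean()
        origins = np.arange(0, 20 - n_lags + 1, stride)
        c1_ref = np.mean(
            [du[:, o : o + n_lags] for o in origins], axis=(0, 1)
        )
        c2_ref = np.mean(
            [du2[:, o : o + n_lags] for o in origins], axis=(0, 1)
        )
        np.testing.assert_allclose(tcf.c1, c1_ref, atol=1e-12)
        np.testing.assert_allclose(tcf.c2, c2_ref, atol=1e-12)

    def test_numerator_and_denominator_exposed(self, small_emd):
        tcf = compute_tcfs(
            small_emd, 1, 2, temperature=300.0, ground_index=4,
            n_lags=20, origin_stride=10,
        )
        assert tcf.denominator is not None and tcf.denominator > 0.0
        np.testing.assert_allclose(
            tcf.numerator_c1, tcf.c1 * tcf.denominator, rtol=1e-12
        )
        # forward/backward signs come from the data; no symmetrization:
        # the numerator of C1 keeps whatever sign the correlation has
        assert np.any(tcf.numerator_c1 != 0.0)

    def test_window_exhaustion_truncates_with_warning(self, caplog, small_emd):
        with caplog.at_level(logging.WARNING, logger="imtkit"):
            tcf = compute_tcfs(
                small_emd, 1, 2, temperature=300.0, ground_index=4,
                n_lags=small_emd.grid.n_points + 50,
            )
        assert tcf.grid.n_points == small_emd.grid.n_points
        assert any("truncating" in r.message for r in caplog.records)

    def test_wrong_propagation_state_rejected(self, small_emd):
        with pytest.raises(ValueError, match="propagated"):
            compute_tcfs(small_emd, 2, 1, temperature=300.0, ground_index=4)


class TestLongTimeDecay:
    def test_tcfs_vanish_beyond_relaxation_on_mixing_bath(self):
        # on a diffusive (mixing) surrogate both TCFs are fluctuation
        # correlations and must decay to zero within error for lags far
        # beyond the relaxation time
        from imtkit import default_triad_model

        _, model = default_triad_model(dynamics="overdamped")
        relax = 1.0 / model.relaxation_rates().min()  # slowest mode, ps
        grid = TimeGrid(401, 0.1)  # 40 ps trajectories
        ens = generate_gap_ensemble(model, 1, 1, n=4000, grid=grid, seed=71)
        tcf = compute_tcfs(
            ens, 1, 2, temperature=300.0, ground_index=4,
            n_lags=301, origin_stride=10, n_batches=20,
        )
        tail = tcf.grid.times > 4.0 * relax
        assert tail.sum() > 20
        z = np.concatenate(
            [tcf.c1[tail] / tcf.se_c1[tail], tcf.c2[tail] / tcf.se_c2[tail]]
        )
        # consistent with zero: almost all tail lags within 3 SE and
        # none far outside (the tail lags are a large correlated family)
        assert np.mean(np.abs(z) > 3.0) <= 0.01
        assert np.abs(z).max() <= 5.0
        # and the early-time TCFs are genuinely nonzero in comparison
        assert abs(tcf.c1[0]) > 5 * tcf.se_c1[0]


class TestBatchErrors:
    def test_duplicated_trajectories_zero_se(self):
        rng = np.random.default_rng(3)
        base_u = rng.normal(size=(1, 12))
        base_g = rng.normal(scale=0.01, size=(1, 12))
        u = np.repeat(base_u, 8, axis=0)
        g = np.repeat(base_g, 8, axis=0)
        ens = make_ensemble(u, g)
        se1, se2 = batch_errors(
            ens, 1, 2, temperature=300.0, ground_index=3, n_batches=4
        )
        np.testing.assert_allclose(se1, 0.0, atol=1e-13)
        np.testing.assert_allclose(se2, 0.0, atol=1e-13)

    def test_se_scales_with_sample_size(self):
        # white-noise channels: SE from n trajectories ~ 1/sqrt(n)
        rng = np.random.default_rng(4)
        u_big = rng.normal(size=(3200, 6))
        g = np.zeros_like(u_big)
        se_big, _ = batch_errors(
            make_ensemble(u_big, g), 1, 2, temperature=300.0,
            ground_index=3, n_batches=8,
        )
        se_small, _ = batch_errors(
            make_ensemble(u_big[:200], g[:200]), 1, 2, temperature=300.0,
            ground_index=3, n_batches=8,
        )
        ratio = np.median(se_small / se_big)
        assert ratio == pytest.approx(4.0, rel=0.5)

    def test_more_batches_than_trajectories_rejected(self):
        ens = make_ensemble(np.zeros((3, 4)), np.zeros((3, 4)))
        with pytest.raises(ValueError, match="batches"):
            batch_errors(ens, 1, 2, temperature=300.0, ground_index=3,
                         n_batches=10)
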