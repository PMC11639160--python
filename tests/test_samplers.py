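"""Conditional updates of the Metropolis-within-Gibbs sampler.

Closed-form conjugacy oracles, the hand-derived allocation weight example,
the undersampling schedule, conservation and exchangeability properties,
and a Geweke-style successive-conditional test of joint correctness.
"""

import numpy as np
import pytest

from diffreg.ec_data import (
    BULK,
    ECDataset,
    EquivalenceClass,
    FeatureIndex,
    LatentCounts,
)
from diffreg.hyperprior import HyperPrior
from diffreg.model_fit import _initial_state
from diffreg.samplers import (
    ChainState,
    CompiledSample,
    MHState,
    ModelParams,
    allocation_weights,
    delta_log_target,
    gibbs_sweep,
    update_delta,
    update_latent,
    update_pi,
    update_rho,
)
from conftest import S, U, A, make_bulk_index, make_sc_index, singleton_dataset


def _mc_mean(draws):
    m = draws.mean(axis=0)
    se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
    return m, se


class TestUpdateRho:
    def test_zero_counts_recover_uniform_prior(self):
        rng = np.random.default_rng(0)
        x = LatentCounts(np.zeros((1, 2, 2), dtype=int))
        draws = np.stack([update_rho(x, 1.0, rng)[0] for _ in range(4000)])
        m, se = _mc_mean(draws)
        assert np.all(np.abs(m - 0.5) < 3 * se + 1e-9)

    def test_posterior_mean_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x = np.zeros((1, 2, 2), dtype=int)
        x[0, 0, 0] = 98
        draws = np.stack([update_rho(LatentCounts(x), 1.0, rng)[0] for _ in range(10000)])
        m, se = _mc_mean(draws)
        expected = np.array([99 / 100, 1 / 100])  # Dirichlet(1+98, 1+0) mean
        assert np.all(np.abs(m - expected) < 3 * se)


class TestUpdatePi:
    def test_prior_recovery_with_no_counts(self):
        rng = np.random.default_rng(2)
        x = LatentCounts(np.zeros((1, 1, 2), dtype=int))
        delta = np.array([[2.0, 2.0]])
        draws = np.stack([update_pi(x, delta, rng)[0, 0, 0] for _ in range(4000)])
        assert draws.mean() == pytest.approx(0.5, abs=3 * draws.std() / np.sqrt(len(draws)))

    def test_bulk_beta_posterior_mean(self):
        rng = np.random.default_rng(3)
        x = LatentCounts(np.array([[[30, 10]]]))
        delta = np.array([[1.0, 1.0]])
        draws = np.stack([update_pi(x, delta, rng)[0, 0, 0] for _ in range(6000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert draws.mean() == pytest.approx(31 / 42, abs=3 * se)

    def test_single_cell_dirichlet_posterior_mean(self):
        rng = np.random.default_rng(4)
        x = LatentCounts(np.array([[[5, 3, 2]]]))
        delta = np.array([[1.0, 1.0, 1.0]])
        draws = np.stack([update_pi(x, delta, rng)[0, 0] for _ in range(6000)])
        m, se = _mc_mean(draws)
        assert np.all(np.abs(m - np.array([6, 4, 3]) / 13) < 3 * se)


class TestUpdateDelta:
    def test_pi_bar_and_delta_plus_are_functions_of_delta(self):
        params = ModelParams(
            rho=np.array([[0.5, 0.5]]),
            pi=np.full((1, 2, 2), 0.5),
            delta=np.array([[2.0, 6.0], [1.0, 3.0]]),
        )
        np.testing.assert_allclose(params.delta_plus, [8.0, 4.0])
        np.testing.assert_allclose(params.pi_bar, [[0.25, 0.75], [0.25, 0.75]])

    def test_acceptance_rate_in_healthy_band_after_adaptation(self):
        rng = np.random.default_rng(5)
        prior = HyperPrior(np.log(20.0), 0.5)
        n_feat = 20
        pbar = rng.uniform(0.2, 0.8, n_feat)
        pi = np.stack(
            [rng.beta(20 * pbar, 20 * (1 - pbar)) for _ in range(3)]
        )  # (N, F)
        pi = np.stack([pi, 1 - pi], axis=2)
        state = MHState(z=np.log(np.full((n_feat, 2), 5.0)))
        for _ in range(3000):
            update_delta(pi, prior, state, rng)
        rates = state.acceptance_rate()
        assert np.all(rates > 0.1) and np.all(rates < 0.6)

    def test_non_finite_target_aborts_with_diagnostic(self):
        rng = np.random.default_rng(6)
        prior = HyperPrior(1.0, 0.5)
        pi = np.full((2, 1, 2), np.nan)
        state = MHState(z=np.zeros((1, 2)))
        with pytest.raises(FloatingPointError, match="non-finite"):
            update_delta(pi, prior, state, rng)

    def test_log_target_prior_matches_change_of_variables(self):
        # against a brute-force density transform: sample log D ~ N, pbar ~ U,
        # the z-space density integrates to the same normalizer on a grid
        prior = HyperPrior(np.log(10.0), 0.4)
        grid = np.linspace(-9.0, 5.5, 400)
        z = np.stack(np.meshgrid(grid, grid, indexing="ij"), axis=-1).reshape(-1, 2)
        log_pi_sum = np.zeros((1, 2))  # no likelihood contribution
        lt = delta_log_target(z, np.broadcast_to(log_pi_sum, z.shape), 0, prior)
        dz = (grid[1] - grid[0]) ** 2
        total = np.exp(lt).sum() * dz
        assert total == pytest.approx(1.0, rel=0.01)


class TestUpdateLatent:
    def test_singleton_class_allocates_deterministically(self):
        index = make_bulk_index(1)
        ds = ECDataset(index, ["s"], [[EquivalenceClass(((0, S),), 7)]])
        comp = CompiledSample.from_dataset(ds, 0)
        rng = np.random.default_rng(0)
        x = update_latent(comp, np.array([1.0]), np.array([[0.5, 0.5]]),
                          index.eff_len_matrix(), rng)
        assert x[0, S] == 7 and x.sum() == 7

    def test_hand_derived_two_member_weight(self):
        # class {(w,S),(z,U)}, rho=(0.5,0.5), pi_S(w)=0.8, pi_U(z)=0.4, equal
        # lengths -> P(w,S) = 0.8/1.2 = 2/3
        index = make_bulk_index(2, lengths=(np.array([1.0, 1.0]), np.array([1.0, 1.0])))
        n = 60000
        ds = ECDataset(index, ["s"], [[EquivalenceClass(((0, S), (1, U)), n)]])
        comp = CompiledSample.from_dataset(ds, 0)
        rho = np.array([0.5, 0.5])
        pi = np.array([[0.8, 0.2], [0.6, 0.4]])
        w = allocation_weights(comp, rho, pi, index.eff_len_matrix())
        np.testing.assert_allclose(w[0, 0] / w[0].sum(), 2 / 3)
        x = update_latent(comp, rho, pi, index.eff_len_matrix(), np.random.default_rng(1))
        frac = x[0, S] / n
        assert frac == pytest.approx(2 / 3, abs=4 * np.sqrt((2 / 3) * (1 / 3) / n))

    def test_length_scaling_leaves_allocation_invariant(self):
        base = make_bulk_index(2, lengths=(np.array([1.0, 2.0]), np.array([3.0, 1.0])))
        scaled = make_bulk_index(2, lengths=(np.array([10.0, 20.0]), np.array([30.0, 10.0])))
        ds = ECDataset(base, ["s"], [[EquivalenceClass(((0, S), (1, U)), 500)]])
        comp = CompiledSample.from_dataset(ds, 0)
        rho = np.array([0.3, 0.7])
        pi = np.array([[0.8, 0.2], [0.6, 0.4]])
        x1 = update_latent(comp, rho, pi, base.eff_len_matrix(), np.random.default_rng(9))
        x2 = update_latent(comp, rho, pi, scaled.eff_len_matrix(), np.random.default_rng(9))
        np.testing.assert_array_equal(x1, x2)

    def test_single_cell_three_way_weights(self):
        # read compatible with (w,S), (z,U), (q,A): weights proportional to
        # rho*pi with no length division
        index = make_sc_index(3)
        ds = ECDataset(index, ["s"], [[EquivalenceClass(((0, S), (1, U), (2, A)), 1)]])
        comp = CompiledSample.from_dataset(ds, 0)
        rho = np.array([0.2, 0.3, 0.5])
        pi = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.1, 0.2, 0.7]])
        w = allocation_weights(comp, rho, pi, None)
        expected = np.array([0.2 * 0.6, 0.3 * 0.5, 0.5 * 0.7])
        np.testing.assert_allclose(w[0], expected)

    def test_all_zero_weights_raise(self):
        index = make_bulk_index(2)
        ds = ECDataset(index, ["s"], [[EquivalenceClass(((0, S), (1, U)), 3)]])
        comp = CompiledSample.from_dataset(ds, 0)
        with pytest.raises(FloatingPointError, match="all-zero"):
            update_latent(comp, np.zeros(2), np.full((2, 2), 0.5),
                          index.eff_len_matrix(), np.random.default_rng(0))


class TestGibbsSweep:
    def _state(self, seed=0, n_feat=4, multimap=True):
        rng = np.random.default_rng(seed)
        index = make_bulk_index(n_feat)
        counts = rng.integers(5, 40, size=(2, n_feat, 2))
        ds = singleton_dataset(counts, index)
        if multimap:
            for i in range(2):
                ds.classes[i] = ds.classes[i] + [
                    EquivalenceClass(((0, S), (1, U)), 11),
                    EquivalenceClass(((1, S), (2, S), (3, U)), 7),
                ]
        prior = HyperPrior(np.log(15.0), 0.5)
        return _initial_state(ds, prior, 1.0), ds

    def test_latent_updates_follow_undersampling_schedule(self):
        state, _ = self._state()
        rng = np.random.default_rng(1)
        for it in range(1, 21):
            gibbs_sweep(state, it, rng, thin_latent=10)
        assert state.latent_update_iters == [10, 20]

    def test_thin_latent_one_updates_every_sweep(self):
        state, _ = self._state()
        rng = np.random.default_rng(2)
        for it in range(1, 6):
            gibbs_sweep(state, it, rng, thin_latent=1)
        assert state.latent_update_iters == [1, 2, 3, 4, 5]

    def test_reads_conserved_through_sweeps(self):
        state, ds = self._state()
        totals = [ds.total_count(i) for i in range(2)]
        rng = np.random.default_rng(3)
        for it in range(1, 31):
            gibbs_sweep(state, it, rng, thin_latent=10)
        assert list(state.x.x.sum(axis=(1, 2))) == totals

    def test_feature_permutation_equivariance_of_deterministic_maps(self):
        # the stochastic draws are elementwise, so exchangeability holds in
        # distribution; the deterministic maps must be exactly equivariant
        rng0 = np.random.default_rng(12)
        counts = rng0.integers(5, 60, size=(2, 5, 2))
        perm = np.array([3, 0, 4, 1, 2])
        inv = np.argsort(perm)
        prior = HyperPrior(np.log(15.0), 0.5)

        ds = singleton_dataset(counts, make_bulk_index(5))
        ds_perm = singleton_dataset(counts[:, perm, :], make_bulk_index(5))
        st = _initial_state(ds, prior, 1.0)
        st_p = _initial_state(ds_perm, prior, 1.0)
        np.testing.assert_array_equal(st.x.x, st_p.x.x[:, inv])
        np.testing.assert_array_equal(st.params.delta, st_p.params.delta[inv])
        np.testing.assert_allclose(st.params.rho, st_p.params.rho[:, inv])

        log_pi_sum = np.log(st.params.pi).sum(axis=0)
        lt = delta_log_target(st.mh.z, log_pi_sum, 2, prior)
        lt_p = delta_log_target(st_p.mh.z, np.log(st_p.params.pi).sum(axis=0), 2, prior)
        np.testing.assert_allclose(lt, lt_p[inv])


class TestGewekeJointCorrectness:
    def test_successive_conditional_marginals_match_prior(self):
        """Alternating exact data draws and sampler sweeps keeps the
        marginal law of the hyper-parameters equal to their prior."""
        rng = np.random.default_rng(42)
        n_feat, n_samples, reads = 2, 2, 60
        prior = HyperPrior(2.0, 0.5)
        index = make_bulk_index(n_feat, lengths=(np.ones(n_feat), np.ones(n_feat)))
        alpha0 = 1.0

        # symmetric compatibility channel: (0,S)-(1,S) and (0,U)-(1,U) pair up
        pair_of = {(0, 0): ((0, S), (1, S)), (1, 0): ((0, S), (1, S)),
                   (0, 1): ((0, U), (1, U)), (1, 1): ((0, U), (1, U))}

        def simulate_z(rho, pi):
            classes = []
            for i in range(n_samples):
                y = rng.multinomial(reads, rho[i])
                xs = rng.binomial(y, pi[i, :, 0])
                counts = np.stack([xs, y - xs], axis=1)
                ecs: dict = {}
                for f in range(n_feat):
                    for k in range(2):
                        c = int(counts[f, k])
                        amb = rng.binomial(c, 0.5)
                        if c - amb:
                            key = ((f, S if k == 0 else U),)
                            ecs[key] = ecs.get(key, 0) + c - amb
                        if amb:
                            key = pair_of[(f, k)]
                            ecs[key] = ecs.get(key, 0) + amb
                classes.append([EquivalenceClass(m, c) for m, c in sorted(ecs.items())])
            return ECDataset(index, [f"s{i}" for i in range(n_samples)], classes)

        # initialize from the prior
        log_dp = rng.normal(prior.mu_log_prec, prior.sd_log_prec, n_feat)
        pbar = rng.uniform(size=n_feat)
        delta = np.exp(log_dp)[:, None] * np.stack([pbar, 1 - pbar], axis=1)
        rho = rng.dirichlet(np.full(n_feat, alpha0), size=n_samples)
        pi_s = rng.beta(delta[:, 0], delta[:, 1], size=(n_samples, n_feat))
        pi = np.stack([pi_s, 1 - pi_s], axis=2)

        n_cycles, keep = 6000, []
        mh = MHState(z=np.log(delta))
        for _ in range(n_cycles):
            ds = simulate_z(rho, pi)
            compiled = [CompiledSample.from_dataset(ds, i) for i in range(n_samples)]
            # conditional X | Z draw, then one parameter sweep
            x = np.stack([
                update_latent(compiled[i], rho[i], pi[i], None, rng)
                for i in range(n_samples)
            ])
            state = ChainState(
                compiled=compiled, x=LatentCounts(x),
                params=ModelParams(rho=rho, pi=pi, delta=np.exp(mh.z)),
                mh=mh, prior=prior, eff_len=None, alpha0=alpha0, delta_substeps=1,
            )
            gibbs_sweep(state, 1, rng, thin_latent=1)
            delta, pi, rho = state.params.delta, state.params.pi, state.params.rho
            x = state.x
            log_dp = np.log(delta.sum(axis=1))
            pb_u = delta[:, 1] / delta.sum(axis=1)
            keep.append([log_dp[0], log_dp[1], log_dp[0] ** 2, log_dp[1] ** 2,
                         pb_u[0], pb_u[1], pb_u[0] ** 2, pb_u[1] ** 2,
                         rho[0, 0], rho[0, 0] ** 2, pi[0, 0, 1], pi[1, 1, 1]])
        keep = np.asarray(keep)[500:]

        mu, sd = prior.mu_log_prec, prior.sd_log_prec
        expected = np.array([
            mu, mu, mu**2 + sd**2, mu**2 + sd**2,
            0.5, 0.5, 1 / 3, 1 / 3,
            0.5, 1 / 3, 0.5, 0.5,
        ])
        # batch-means Monte Carlo standard errors
        n_batch = 50
        batches = keep[: (len(keep) // n_batch) * n_batch].reshape(n_batch, -1, keep.shape[1])
        bmeans = batches.mean(axis=1)
        se = bmeans.std(axis=0, ddof=1) / np.sqrt(n_batch)
        z = (keep.mean(axis=0) - expected) / se
        assert np.all(np.abs(z) < 4.0), f"z-scores {np.round(z, 2)}"
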