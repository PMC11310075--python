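import numpy as np
import pytest
from scipy import stats

from allometree.allometry import AllometryModelSpec, build_design
from allometree.phylo_gls import gls_ml_fit
from allometree.synthgen import _clade_branch_mask, generate_study, simulate_tree
from allometree.varrates import (MCMCSettings, VarRatesPriors, _CollapsedModel,
                                 _run_chain, fit_variable_rates,
                                 mean_scaled_tree, median_scaled_tree,
                                 shift_count_log_prior)


def small_problem(seed=0, n=20):
    tree = simulate_tree(n, seed=seed, age=100.0)
    rng = np.random.default_rng(seed)
    X = np.ones((n, 1))
    y = rng.normal(size=n)
    return tree, X, y


class TestSampler:
    def test_identical_seeds_bit_identical(self):
        tree, X, y = small_problem()
        settings = MCMCSettings(n_iter=4000, n_chains=1, seed=9)
        a = fit_variable_rates(tree, X, y, settings=settings)
        b = fit_variable_rates(tree, X, y, settings=settings)
        assert np.array_equal(a.samples_r, b.samples_r)
        assert np.array_equal(a.samples_beta, b.samples_beta)
        assert np.array_equal(a.samples_sigma2, b.samples_sigma2)

    def test_flat_likelihood_recovers_shift_prior(self):
        """Detailed balance: with the likelihood forced constant, the
        sampled shift count follows the (geometric) prior — χ² GOF on
        ~50,000 near-independent draws."""
        tree, X, y = small_problem(1, 12)
        pri = VarRatesPriors()
        model = _CollapsedModel(tree, X, y, pri)
        settings = MCMCSettings(n_iter=1_500_000, burn_frac=0.05, thin=28,
                                n_chains=1, seed=0)
        out = _run_chain(model, settings, 3, log_ml=lambda r: 0.0)
        k = out["k"]
        assert k.size >= 50_000
        B = model.branches.size
        logp = np.array([shift_count_log_prior(i, pri) for i in range(B + 1)])
        pmf = np.exp(logp)
        pmf /= pmf.sum()
        obs = np.bincount(k, minlength=B + 1)
        exp = pmf * k.size
        cut = np.max(np.flatnonzero(exp >= 5))
        obs2 = np.append(obs[:cut], obs[cut:].sum())
        exp2 = np.append(exp[:cut], exp[cut:].sum())
        chi2 = float(((obs2 - exp2) ** 2 / exp2).sum())
        p = stats.chi2.sf(chi2, len(obs2) - 1)
        assert p > 0.01, (p, obs2[:6], exp2[:6])

    def test_poisson_prior_ratio(self):
        pri = VarRatesPriors(shift_prior="poisson", shift_mean=3.0)
        d = shift_count_log_prior(4, pri) - shift_count_log_prior(3, pri)
        assert d == pytest.approx(np.log(3.0 / 4.0))

    def test_convergence_flag_warns(self):
        tree, X, y = small_problem(2, 15)
        settings = MCMCSettings(n_iter=600, burn_frac=0.2, thin=1,
                                n_chains=2, seed=0, rhat_tol=1.0000001)
        with pytest.warns(RuntimeWarning, match="not converged"):
            post = fit_variable_rates(tree, X, y, settings=settings)
        assert not post.converged


class TestScaledTrees:
    def make_posterior(self, tree, r_samples):
        settings = MCMCSettings(n_iter=10, n_chains=1)
        from allometree.varrates import RatePosterior
        S = r_samples.shape[0]
        return RatePosterior(
            names=["x0"], branches=np.array(
                [i for i in range(tree.n_nodes) if i != tree.root]),
            samples_r=r_samples, samples_beta=np.zeros((S, 1)),
            samples_sigma2=np.ones(S), samples_logml=np.zeros(S),
            samples_k=(r_samples != 1).sum(axis=1),
            chain_id=np.zeros(S, dtype=np.int64), settings=settings,
            priors=VarRatesPriors(), diagnostics={}, converged=True)

    def test_no_shifts_identity(self, balanced4):
        post = self.make_posterior(balanced4, np.ones((5, 6)))
        out = median_scaled_tree(post, balanced4)
        assert np.allclose(out.length, balanced4.length)

    def test_branch_median_doubles_length(self, balanced4):
        r = np.ones((3, 6))
        r[:, 0] = [1.0, 2.0, 4.0]
        post = self.make_posterior(balanced4, r)
        out = median_scaled_tree(post, balanced4)
        b = post.branches[0]
        assert out.length[b] == pytest.approx(2.0 * balanced4.length[b])

    def test_time_by_rate_product(self):
        # branch scaling is t × r: 9.52 Myr at median rate 20.72 → 197.25
        assert 9.52 * 20.72 == pytest.approx(197.25, abs=5e-3)

    def test_mean_tree_uses_mean(self, balanced4):
        r = np.ones((4, 6))
        r[:, 2] = [1.0, 1.0, 1.0, 9.0]
        post = self.make_posterior(balanced4, r)
        out = mean_scaled_tree(post, balanced4)
        b = post.branches[2]
        assert out.length[b] == pytest.approx(3.0 * balanced4.length[b])


class TestRecovery:
    def test_homogeneous_rates_calibrated(self):
        """Without simulated shifts, at least 90% of branches keep a
        posterior median scalar within [0.5, 2]."""
        tree, table, truth, _ = generate_study(
            {"seed": 12, "tree": {"n_tips": 60}, "shifts": {}, "trends": {}})
        info = build_design(table, AllometryModelSpec("quadratic"))
        post = fit_variable_rates(
            tree, info.X, table["log_brain"].to_numpy(),
            settings=MCMCSettings(n_iter=20000, n_chains=2, seed=5))
        med = post.median_r()
        assert np.mean((med >= 0.5) & (med <= 2.0)) >= 0.90

    def test_shifted_clade_rate_signal(self):
        """A ×10-rate clade is recovered in aggregate: the collapsed
        evidence prefers the true configuration and posterior mean scalars
        inside the clade exceed those outside."""
        tree, table, truth, _ = generate_study({
            "seed": 11, "tree": {"group_sizes": {"G1": 45, "G2": 10, "G3": 45}},
            "shifts": {"G2": 10.0}, "trends": {}, "rate_jitter": 0.0})
        info = build_design(table, AllometryModelSpec("quadratic"))
        y = table["log_brain"].to_numpy()
        model = _CollapsedModel(tree, info.X, y, VarRatesPriors())
        mask = _clade_branch_mask(tree, "G2")[model.branches]
        r_true = np.where(mask, 10.0, 1.0)
        assert model.log_ml(r_true) > model.log_ml(np.ones(mask.size)) + 5
        post = fit_variable_rates(
            tree, info.X, y,
            settings=MCMCSettings(n_iter=30000, n_chains=2, seed=5))
        mean_r = post.samples_r.mean(axis=0)
        assert mean_r[mask].mean() > 2.0 * mean_r[~mask].mean()
        assert (mean_r[mask] > 3.0).sum() >= 3

    def test_scaled_tree_refit_recovers_background_rate(self):
        """Fitting a homogeneous model on the truly-scaled tree returns the
        generating σ²_b within its sampling interval (simulation)."""
        rng = np.random.default_rng(3)
        covered = 0
        for rep in range(20):
            tree, table, truth, nodes = generate_study({
                "seed": 300 + rep,
                "tree": {"group_sizes": {"G1": 25, "G2": 25}},
                "shifts": {"G2": 8.0}, "trends": {}, "rate_jitter": 0.0})
            scaled = tree.length.copy()
            scaled *= nodes["r_true"].to_numpy()
            st = tree.with_lengths(scaled)
            u = (table["log_brain"].to_numpy()
                 - truth.bbm(table["log_body"].to_numpy()))
            fit = gls_ml_fit(st, np.ones((tree.n_tips, 1)), u, st.length)
            n = tree.n_tips
            s2 = fit.sigma2 * n / (n - 1)
            lo, hi = (s2 * (n - 1) / stats.chi2.ppf(q, n - 1)
                      for q in (0.975, 0.025))
            covered += (lo <= truth.sigma2_b <= hi)
        assert covered >= 17  # 95% intervals, 20 reps
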