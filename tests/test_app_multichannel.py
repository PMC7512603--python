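"""Multichannel wavelet-GMEP restoration: priors, conditionals, hyper steps."""

import numpy as np
import pytest
import scipy.stats

from auxgibbs.app_multichannel import (
    GMEPModel,
    HyperPriors,
    MCIConfig,
    SubbandPrior,
    block_cond_neglog,
    default_subband_priors,
    gamma_posterior_params,
    gmep_neglog_prior,
    init_hyperparams,
    restore_mci,
    sample_aux_mci,
    sample_blocks,
    sample_correlation_R,
    sample_gamma_m,
    sample_ss_prior,
    ss_logdensity,
)
from auxgibbs.linops import CirculantMap2D, as_dense, build_wavelet_frame


def _toy_model(rng, B=2, shape=(8, 8), levels=1, gaussian_only=False,
               sigma2=1.0, gammas=None):
    frame = build_wavelet_frame("db2", levels, shape)
    M = frame.n_subbands
    if gaussian_only:
        priors = [SubbandPrior(1.0, 0.0, gaussian=True) for _ in range(M)]
    else:
        priors = [SubbandPrior(0.5, 1e-4) for _ in range(M - 1)] + [
            SubbandPrior(1.0, 0.0, gaussian=True)
        ]
    kernel = np.array([[0.0, 0.2, 0.0], [0.2, 0.2, 0.2], [0.0, 0.2, 0.0]])
    blurs = [CirculantMap2D(kernel, shape) for _ in range(B)]
    if B == 2:
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        n_w = np.array([0.4, 0.6])
    else:
        R = np.eye(B)
        n_w = np.full(B, 1.0 / B)
    if gammas is None:
        gammas = rng.uniform(0.5, 2.0, M)
    return GMEPModel(
        frame=frame, blurs=blurs, sigma2=sigma2, subband_priors=priors,
        R=R, n_weights=n_w, gammas=gammas,
    )


class TestGMEPPrior:
    def test_quadratic_reduction(self, rng):
        """beta = 1, delta = 0, identity scale: the prior is (1/2)||x||^2
        in the whitened coordinates."""
        model = _toy_model(rng, B=1, gaussian_only=True,
                           gammas=np.ones(4))
        # B = 1: W = n^2 R^{-1} = 1, gamma = 1 -> psi = x^2 / 2 per coefficient
        x = rng.standard_normal(model.Q)
        assert gmep_neglog_prior(x, model) == pytest.approx(0.5 * float(x @ x), rel=1e-12)

    def test_location_gives_zero(self, rng):
        model = _toy_model(rng, B=2)
        for sp in model.subband_priors:
            sp.delta = 0.0
        model.a_loc = rng.standard_normal(model.a_loc.shape)
        x = np.zeros(model.Q)
        for sb in model.frame.subbands:
            blocks = np.tile(model.a_loc[sb.m - 1], (sb.size, 1))
            model.selector.set_subband(x, sb.m, blocks)
        assert gmep_neglog_prior(x, model) == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_double_loop(self, rng):
        model = _toy_model(rng, B=2)
        x = rng.standard_normal(model.Q)
        W = model.whitener()
        total = 0.0
        for sb in model.frame.subbands:
            sp = model.subband_priors[sb.m - 1]
            g = model.gammas[sb.m - 1]
            for k in range(sb.size):
                u = model.selector.extract(x, sb.m, k) - model.a_loc[sb.m - 1]
                d2 = float(u @ W @ u)
                t2 = g ** (1.0 / sp.beta) * d2
                total += 0.5 * (t2 + sp.delta) ** sp.beta
        assert gmep_neglog_prior(x, model) == pytest.approx(total, rel=1e-12)


class TestAuxMCI:
    def test_identity_blur_orthonormal_variance(self, rng):
        """Identity blur, orthonormal frame: H^T H = I so each coordinate
        of v has variance (1/sigma^2)(1/mu - 1)."""
        model = _toy_model(rng, B=1, sigma2=4.0)
        model.blurs = [CirculantMap2D(np.array([[1.0]]), (8, 8))]
        model.__post_init__()
        mu = 0.5
        draws = np.array(
            [sample_aux_mci(np.zeros(model.Q), mu, 4.0, model, rng).ravel()
             for _ in range(30_000)]
        )
        var_t = (1.0 / mu - 1.0) / 4.0
        assert np.allclose(draws.var(axis=0).mean(), var_t, rtol=0.02)

    def test_zero_state_zero_mean(self, rng):
        model = _toy_model(rng, B=2)
        mu = 0.9 / max(op.spectral_norm() ** 2 for op in model.channel_ops)
        draws = np.array(
            [sample_aux_mci(np.zeros(model.Q), mu, 1.0, model, rng).ravel()
             for _ in range(20_000)]
        )
        se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.max(np.abs(draws.mean(axis=0)) / se) < 5.0

    def test_moments_vs_dense_oracle(self, rng):
        model = _toy_model(rng, B=1, sigma2=2.0)
        op = model.channel_ops[0]
        mu = 0.9 / op.spectral_norm() ** 2
        x = rng.standard_normal(model.Q)
        A = as_dense(op)
        cov_t = (np.eye(model.Q) / mu - A.T @ A) / 2.0
        mean_t = cov_t @ x * (2.0 / 2.0)  # (1/sigma2) Gamma x with Gamma = sigma2*cov_t
        draws = np.array(
            [sample_aux_mci(x, mu, 2.0, model, rng).ravel() for _ in range(60_000)]
        )
        n = len(draws)
        se_mean = draws.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.max(np.abs(draws.mean(axis=0) - mean_t) / se_mean) < 5.0
        emp = np.cov(draws.T)
        var = np.diag(cov_t)
        se_cov = np.sqrt((np.outer(var, var) + cov_t**2) / n)
        assert np.max(np.abs(emp - cov_t) / se_cov) < 5.0


class TestBlockConditional:
    def test_quadratic_mode_value(self, rng):
        """With the prior term negligible the minimizer mu sigma^2 P v +
        mu P H^T z gives (numerically) zero."""
        model = _toy_model(rng, B=2)
        model.gammas = np.full(model.M, 1e-30)
        for sp in model.subband_priors:
            sp.delta = 0.0
        mu = 0.1
        v = rng.standard_normal(model.Q)
        z = rng.standard_normal((2, 8, 8))
        r = mu * model.sigma2 * v + mu * model.apply_Ht(z).ravel()
        c_star = model.selector.extract(r, 2, 3)
        val = block_cond_neglog(c_star, 2, 3, v, z, mu, model.sigma2, model)
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_blocks_sum_to_full_conditional(self, rng):
        """Sum of block neg-logs equals the full x-conditional up to an
        x-free constant (checked as a constant difference)."""
        model = _toy_model(rng, B=2)
        mu = 0.4 / max(op.spectral_norm() ** 2 for op in model.channel_ops)
        v = rng.standard_normal(model.Q)
        z = rng.standard_normal((2, 8, 8))
        r = mu * model.sigma2 * v + mu * model.apply_Ht(z).ravel()

        def full_neglog(x):
            quad = float(np.sum((x - r) ** 2)) / (2 * mu * model.sigma2)
            return quad + gmep_neglog_prior(x, model)

        def block_sum(x):
            total = 0.0
            for sb in model.frame.subbands:
                for k in range(sb.size):
                    c = model.selector.extract(x, sb.m, k)
                    total += block_cond_neglog(c, sb.m, k, v, z, mu, model.sigma2, model)
            return total

        x1, x2 = rng.standard_normal((2, model.Q))
        d1 = block_sum(x1) - full_neglog(x1)
        d2 = block_sum(x2) - full_neglog(x2)
        assert d1 == pytest.approx(d2, abs=1e-8)

    def test_grid_oracle_against_joint_density(self, rng):
        """exp(-J_{m,k}) matches p(v|x) p(z|x) p(x) as a function of one
        block, up to a block-free constant (B=1, 8x8, one level)."""
        model = _toy_model(rng, B=1, sigma2=1.5)
        op = model.channel_ops[0]
        A = as_dense(op)
        mu = 0.9 / op.spectral_norm() ** 2
        Gamma = (np.eye(model.Q) / mu - A.T @ A) / model.sigma2
        Gamma_inv = np.linalg.inv(Gamma)
        v = rng.standard_normal(model.Q)
        z = rng.standard_normal((8, 8))
        x0 = rng.standard_normal(model.Q)

        def joint(x):
            r_v = v - Gamma @ x * model.sigma2 / model.sigma2  # (1/s2)Gamma_cov x
            r_v = v - (np.eye(model.Q) / mu - A.T @ A) @ x / model.sigma2
            r_z = A @ x - z.ravel()
            return (
                0.5 * r_v @ Gamma_inv @ r_v
                + 0.5 * float(r_z @ r_z) / model.sigma2
                + gmep_neglog_prior(x, model)
            )

        m, k = 1, 5
        idx = model.selector._offsets(m, k)[0]
        cs = np.linspace(-2, 2, 9)
        diffs = []
        for c in cs:
            x = x0.copy()
            x[idx] = c
            diffs.append(
                block_cond_neglog(np.array([c]), m, k, v, z, mu, model.sigma2, model)
                - joint(x)
            )
        assert np.ptp(diffs) < 1e-8


class TestSampleBlocks:
    def test_gaussian_subband_conjugate_stationarity(self, rng):
        """All-Gaussian B=1 toy: alternating aux/block draws leave the dense
        posterior invariant (moment check against the closed form)."""
        model = _toy_model(rng, B=1, gaussian_only=True, sigma2=1.0,
                           gammas=np.full(4, 0.8))
        op = model.channel_ops[0]
        A = as_dense(op)
        mu = 0.9 / op.spectral_norm() ** 2
        z = rng.standard_normal((8, 8))
        # dense posterior: G = H^T H / s2 + gamma I (W = 1, B = 1)
        G = A.T @ A / model.sigma2 + 0.8 * np.eye(model.Q)
        m_post = np.linalg.solve(G, A.T @ z.ravel() / model.sigma2)
        C, burn, keep = 60, 50, 200
        chain_means = np.empty((C, model.Q))
        for c in range(C):
            r = np.random.default_rng(3000 + c)
            x = m_post.copy()
            acc = np.zeros(model.Q)
            for t in range(burn + keep):
                v = sample_aux_mci(x, mu, model.sigma2, model, r).ravel()
                x, _ = sample_blocks(x, v, z, mu, model, "rw", np.full(4, 0.1), r)
                if t >= burn:
                    acc += x
            chain_means[c] = acc / keep
        se = chain_means.std(axis=0, ddof=1) / np.sqrt(C)
        assert np.max(np.abs(chain_means.mean(axis=0) - m_post) / se) < 5.0

    @pytest.mark.parametrize("kernel", ["rw", "mala"])
    def test_mh_blocks_accept_reasonably(self, rng, kernel):
        model = _toy_model(rng, B=2)
        mu = 0.9 / max(op.spectral_norm() ** 2 for op in model.channel_ops)
        z = rng.standard_normal((2, 8, 8))
        x = rng.standard_normal(model.Q)
        v = sample_aux_mci(x, mu, model.sigma2, model, rng).ravel()
        steps = np.full(model.M, np.sqrt(mu * model.sigma2))
        _, acc = sample_blocks(x, v, z, mu, model, kernel, steps, rng)
        assert np.all((acc[:-1] > 0.05) & (acc[:-1] <= 1.0))
        assert np.isnan(acc[-1])  # conjugate Gaussian subband


class TestCorrelationStep:
    def test_prior_marginal_uniform_correlation(self, rng):
        """SS(I, B+1) prior: the off-diagonal correlation is marginally
        uniform on [-1, 1] (chi-squared goodness of fit)."""
        rhos = np.array(
            [sample_ss_prior(np.eye(2), 3.0, rng)[0, 1] for _ in range(20_000)]
        )
        hist, _ = np.histogram(rhos, bins=20, range=(-1, 1))
        chi2 = float(np.sum((hist - 1000.0) ** 2 / 1000.0))
        assert scipy.stats.chi2.sf(chi2, df=19) > 0.01

    def test_prior_recovery_with_independence_proposal(self, rng):
        """Psi == 0, c-tilde = c, A-tilde = A fixed: the MH chain's
        stationary law is exactly the SS prior (moment check)."""
        model = _toy_model(rng, B=2)
        model.gammas = np.full(model.M, 1e-30)  # likelihood term negligible
        priors = HyperPriors(
            A_ss=np.eye(2), c=3.0, c_tilde=3.0,
            a_gamma=np.full(model.M, 1e-3), b_gamma=np.full(model.M, 1e-3),
        )
        # neutralize the det(R)^{-K/2} block-normalization term by pairing
        # with x exactly at the block locations (Psi = 0, d2 = 0) and a
        # K = 0 effect: compare against prior draws reweighted the same way
        # -> instead run the pure-prior acceptance directly
        R = np.eye(2)
        rhos = np.empty(6_000)
        for t in range(6_000):
            prop = sample_ss_prior(priors.A_ss, priors.c_tilde, rng)
            la = (
                ss_logdensity(prop, priors.A_ss, priors.c)
                - ss_logdensity(R, priors.A_ss, priors.c)
                + ss_logdensity(R, priors.A_ss, priors.c_tilde)
                - ss_logdensity(prop, priors.A_ss, priors.c_tilde)
            )
            if np.log(rng.uniform()) < la:
                R = prop
            rhos[t] = R[0, 1]
        direct = np.array(
            [sample_ss_prior(np.eye(2), 3.0, rng)[0, 1] for _ in range(20_000)]
        )
        assert abs(rhos.mean() - direct.mean()) < 0.05
        assert abs(np.mean(rhos**2) - np.mean(direct**2)) < 0.05

    def test_posterior_grid_oracle_b2(self, rng):
        """B=2: an exactly-symmetric RW-on-rho MH chain targeting the
        implemented R-conditional matches the grid-normalized density."""
        from auxgibbs.app_multichannel import _correlation_neglog_target

        model = _toy_model(rng, B=2, shape=(4, 4))
        priors = HyperPriors.default(2, model.M)
        x = rng.standard_normal(model.Q) * 0.5

        def neglog(rho):
            R = np.array([[1.0, rho], [rho, 1.0]])
            return _correlation_neglog_target(R, x, model, priors)

        grid = np.linspace(-0.99, 0.99, 199)
        dens = np.exp(-(np.vectorize(neglog)(grid) - min(neglog(r) for r in grid)))
        dens /= dens.sum()
        # symmetric random-walk MH on rho (reflection keeps symmetry)
        r = np.random.default_rng(17)
        rho = 0.0
        j = neglog(rho)
        samples = np.empty(60_000)
        for t in range(60_000 + 2000):
            prop = rho + 0.15 * r.standard_normal()
            if abs(prop) < 0.995:
                jp = neglog(prop)
                if np.log(r.uniform()) < j - jp:
                    rho, j = prop, jp
            if t >= 2000:
                samples[t - 2000] = rho
        grid_mean = float(np.sum(grid * dens))
        grid_sd = np.sqrt(float(np.sum(grid**2 * dens)) - grid_mean**2)
        bm = samples.reshape(100, -1).mean(axis=1)
        se = bm.std(ddof=1) / 10.0
        assert abs(samples.mean() - grid_mean) < 5 * se + 1e-3
        assert abs(samples.std() - grid_sd) < 0.1 * grid_sd + 0.01


class TestGammaStep:
    def test_zero_residual_prior_plus_count(self, rng):
        """x at the block locations: gamma_m | x ~ Gamma(a + K_m B/(2 beta), b)."""
        model = _toy_model(rng, B=2)
        priors = HyperPriors.default(2, model.M)
        x = np.zeros(model.Q)
        for sb in model.frame.subbands:
            model.selector.set_subband(
                x, sb.m, np.tile(model.a_loc[sb.m - 1], (sb.size, 1))
            )
        m = 1
        sp = model.subband_priors[m - 1]
        shape, rate = gamma_posterior_params(x, m, model, priors)
        K_m = model.frame.subbands[m - 1].size
        assert shape == pytest.approx(1e-3 + K_m * 2 / (2 * sp.beta))
        assert rate == pytest.approx(1e-3)

    def test_scalar_conjugacy_beta_one(self, rng):
        """B=1, K_m=1, beta=1, delta=0: the standard normal-precision
        conjugate update Gamma(a + 1/2, b + x^2/2)."""
        frame = build_wavelet_frame("db2", 1, (2, 2))
        priors_list = [SubbandPrior(1.0, 0.0) for _ in range(4)]
        kernel = np.array([[1.0]])
        model = GMEPModel(
            frame=frame,
            blurs=[CirculantMap2D(kernel, (2, 2))],
            sigma2=1.0,
            subband_priors=priors_list,
            R=np.eye(1),
            n_weights=np.array([1.0]),
            gammas=np.ones(4),
        )
        hp = HyperPriors(
            A_ss=np.eye(1), c=2.0, c_tilde=51.0,
            a_gamma=np.full(4, 2.0), b_gamma=np.full(4, 1.5),
        )
        x = rng.standard_normal(4)
        m = 2
        shape, rate = gamma_posterior_params(x, m, model, hp)
        xm = model.selector.extract(x, m, 0)[0]
        assert shape == pytest.approx(2.0 + 0.5)
        assert rate == pytest.approx(1.5 + 0.5 * xm**2)
        draws = np.array([sample_gamma_m(x, m, model, hp, rng)[0] for _ in range(30_000)])
        assert draws.mean() == pytest.approx(shape / rate, rel=0.03)

    def test_delta_positive_quadrature_oracle(self, rng):
        """delta > 0 independent-MH target density matches the assembled
        Gamma-prior x GMEP-normalization density on a 1-D grid (constant
        log-difference)."""
        model = _toy_model(rng, B=2)
        priors = HyperPriors.default(2, model.M)
        x = rng.standard_normal(model.Q)
        m = 1
        sp = model.subband_priors[m - 1]
        blocks = model.selector.subband_view(x, m)
        d2 = model.block_d2(blocks, m)
        K_m = blocks.shape[0]
        a_g, b_g = priors.a_gamma[m - 1], priors.b_gamma[m - 1]

        def assembled(g):
            # Gamma prior x prod_k [gamma^{B/(2 beta)} exp(-psi)]
            log_p = (a_g - 1.0) * np.log(g) - b_g * g
            log_p += K_m * 2 / (2.0 * sp.beta) * np.log(g)
            log_p -= float(np.sum(0.5 * (g ** (1 / sp.beta) * d2 + sp.delta) ** sp.beta))
            return -log_p

        shape, rate = gamma_posterior_params(x, m, model, priors)

        def impl(g):
            return (
                -(shape - 1.0) * np.log(g)
                + b_g * g
                + float(np.sum(0.5 * (g ** (1 / sp.beta) * d2 + sp.delta) ** sp.beta))
            )

        gs = np.linspace(0.2, 3.0, 15)
        diffs = [impl(g) - assembled(g) for g in gs]
        assert np.ptp(diffs) < 1e-8

    def test_prior_sampling_self_consistency(self, rng):
        """Draw x from the GMEP prior at known gamma, then repeated
        gamma-updates with x fixed concentrate near the truth (10%)."""
        from auxgibbs.synthdata import gen_gmep_multichannel

        frame = build_wavelet_frame("sym3", 2, (128, 128))
        M = frame.n_subbands
        priors_list = [SubbandPrior(0.5, 0.0) for _ in range(M - 1)] + [
            SubbandPrior(1.0, 0.0, gaussian=True)
        ]
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        n_w = np.array([0.5, 0.5])
        gam_true = np.array([0.8, 0.8, 0.8, 0.3, 0.3, 0.3, 0.05])
        img = gen_gmep_multichannel(frame, 2, R, n_w, gam_true, priors_list, seed=9,
                                    mh_steps=600)
        kernel = np.array([[1.0]])
        model = GMEPModel(
            frame=frame,
            blurs=[CirculantMap2D(kernel, (128, 128))] * 2,
            sigma2=1.0,
            subband_priors=priors_list,
            R=R,
            n_weights=n_w,
            gammas=np.ones(M),
        )
        hp = HyperPriors.default(2, M)
        x = np.stack([frame.analyze(c) for c in img]).ravel()
        for m in (1, 4, 7):  # one subband per scale, K_m >= 4096
            draws = np.array(
                [sample_gamma_m(x, m, model, hp, rng)[0] for _ in range(200)]
            )
            assert abs(draws.mean() - gam_true[m - 1]) / gam_true[m - 1] < 0.10


class TestInitHyperparams:
    def test_identity_blur_sigma_zero_recovers_observed(self, rng):
        frame = build_wavelet_frame("db2", 2, (16, 16))
        z = rng.standard_normal((2, 16, 16))
        blurs = [CirculantMap2D(np.array([[1.0]]), (16, 16))] * 2
        stats, n0, R0, gam = init_hyperparams(z, frame, blurs, 0.0)
        assert np.allclose(stats.alpha, 1.0, atol=1e-10)
        coefs = np.stack([frame.analyze(zb) for zb in z])
        sb = frame.subbands[-2]  # a coarse detail subband (not extrapolated)
        obs = np.var(coefs[:, sb.start : sb.stop], axis=1)
        assert np.allclose(stats.subband_vars[sb.m - 1], obs, rtol=1e-10)

    def test_power_law_exact_fit(self, rng):
        """Coefficients built with exact power-law variances: the regression
        recovers slope and intercept to near machine precision."""
        frame = build_wavelet_frame("db2", 3, (32, 32))
        rho_true, varpi_true = -0.8, 2.0
        coefs = np.zeros(frame.in_dim)
        big = np.zeros(frame.in_dim)
        r = np.random.default_rng(0)
        base = r.standard_normal(frame.in_dim)
        for sb in frame.subbands:
            v = np.exp(rho_true * sb.scale + varpi_true) if sb.orientation != "a" else 4.0
            seg = base[sb.start : sb.stop]
            seg = seg / seg.std()  # exact unit variance, zero-mean-ish
            seg = seg - seg.mean()
            seg = seg / seg.std()
            big[sb.start : sb.stop] = np.sqrt(v) * seg
        z = frame.synthesize(big)[None]
        blurs = [CirculantMap2D(np.array([[1.0]]), (32, 32))]
        stats, *_ = init_hyperparams(z, frame, blurs, 0.0)
        for orient in "hvd":
            slope, intercept = stats.power_law[orient]
            assert slope == pytest.approx(rho_true, abs=1e-10)
            assert intercept == pytest.approx(varpi_true, abs=1e-9)

    def test_noise_only_input_clamps_at_floor(self, rng):
        """Pure noise (no signal): recovered signal variances hit the floor."""
        frame = build_wavelet_frame("db2", 1, (16, 16))
        sigma2 = 4.0
        z = np.sqrt(sigma2) * rng.standard_normal((1, 16, 16))
        blurs = [CirculantMap2D(np.array([[1.0]]), (16, 16))]
        stats, *_ = init_hyperparams(z, frame, blurs, 100.0 * sigma2)
        assert np.all(stats.subband_vars <= 1e-7)


class TestRestorePipeline:
    def test_zero_kept_sweeps_rejected(self):
        with pytest.raises(ValueError):
            MCIConfig(n_iter=10, burn_in=10)

    def test_small_restoration_improves_psnr_and_is_deterministic(self, rng):
        from auxgibbs.diagnostics import image_metrics
        from auxgibbs.synthdata import (
            DegradationSpec,
            degrade,
            gen_gmep_multichannel,
            uniform_kernel,
        )

        shape, levels, B = (32, 32), 1, 2
        frame = build_wavelet_frame("sym3", levels, shape)
        priors_list = default_subband_priors(levels)
        R = np.array([[1.0, 0.7], [0.7, 1.0]])
        n_w = np.array([0.5, 0.5])
        gam = np.array([0.05, 0.05, 0.05, 1e-3])
        img = gen_gmep_multichannel(frame, B, R, n_w, gam, priors_list, seed=4,
                                    mh_steps=300) + 100.0
        spec = DegradationSpec(uniform_kernel(3), ("gaussian", 4.0))
        z, _ = degrade(img, spec, rng=5)
        blurs = [CirculantMap2D(spec.kernel, shape) for _ in range(B)]
        cfg = MCIConfig(wavelet="sym3", levels=levels, n_iter=150, burn_in=75)
        mmse, summ, _ = restore_mci(z, blurs, 4.0, cfg, rng=6)
        mmse2, _, _ = restore_mci(z, blurs, 4.0, cfg, rng=6)
        assert np.array_equal(mmse, mmse2)
        for b in range(B):
            before = image_metrics(img[b], z[b])["psnr"]
            after = image_metrics(img[b], mmse[b])["psnr"]
            assert after > before
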