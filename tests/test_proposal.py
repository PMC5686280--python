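"""Proposal distributions: sampling, density ratios, inflation, Box-Cox fits."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sirnlme import proposal as prop
from sirnlme.model_core import ParameterSpec, ParameterVector


def _spec(k, classes=None, bounds=None):
    return ParameterSpec(
        names=tuple(f"p{i}" for i in range(k)),
        classes=classes or ("fixed_effect",) * k,
        bounds=bounds or (),
    )


def _center(values, classes=None, bounds=None):
    values = np.asarray(values, dtype=float)
    return ParameterVector(_spec(values.size, classes, bounds), values)


class TestMvnProposal:
    def test_identity_covariance_sampling_moments(self):
        p = prop.from_covariance(_center([0.0, 0.0, 0.0]), np.eye(3))
        x = prop.sample(p, 20000, seed=0).values
        np.testing.assert_allclose(x.mean(axis=0), 0.0, atol=3.0 / np.sqrt(20000))
        np.testing.assert_allclose(np.cov(x, rowvar=False), np.eye(3), atol=0.05)

    def test_near_psd_input_repaired_with_warning(self, caplog):
        cov = np.array([[1.0, 1.0], [1.0, 1.0 - 1e-14]])  # eigenvalue ~ -5e-15
        with caplog.at_level(logging.WARNING, logger="sirnlme.proposal"):
            p = prop.from_covariance(_center([0.0, 0.0]), cov)
        assert np.linalg.eigvalsh(p.covariance).min() >= 0.0

    def test_relpdf_is_one_at_center(self):
        p = prop.from_covariance(_center([2.0, -1.0]), np.diag([0.5, 2.0]))
        assert prop.relpdf(p, np.array([[2.0, -1.0]]))[0] == pytest.approx(1.0)

    def test_relpdf_closed_form_z_score_two(self):
        p = prop.from_covariance(_center([0.0, 0.0]), np.eye(2))
        val = prop.relpdf(p, np.array([[2.0, 0.0]]))[0]
        assert val == pytest.approx(np.exp(-2.0), rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prop.from_covariance(_center([0.0, 0.0]), np.eye(3))

    def test_same_seed_identical_samples(self):
        p = prop.from_covariance(_center([0.0]), np.eye(1))
        a = prop.sample(p, 50, seed=5).values
        b = prop.sample(p, 50, seed=5).values
        np.testing.assert_array_equal(a, b)

    def test_bound_truncation_by_rejection(self):
        center = _center([0.1], classes=("iiv_variance",))
        p = prop.from_covariance(center, np.array([[0.04]]))
        res = prop.sample(p, 2000, seed=1)
        assert np.all(res.values >= 0.0)
        assert res.n_rejected > 0  # N(0.1, 0.2^2) puts ~30% mass below 0

    def test_grossly_misplaced_proposal_aborts(self):
        center = _center([0.0], bounds=((100.0, np.inf),))
        p = prop.MvnProposal(center=center, covariance=np.eye(1))
        with pytest.raises(RuntimeError, match="rejection rate"):
            prop.sample(p, 500, seed=0)


class TestGenericProposal:
    def test_class_specific_rses(self):
        center = _center(
            [2.0, 0.09, 0.04],
            classes=("fixed_effect", "iiv_variance", "residual_variance"),
        )
        p = prop.generic_proposal(center)
        np.testing.assert_allclose(
            p.marginal_sds(), [0.30 * 2.0, 0.50 * 0.09, 0.10 * 0.04]
        )
        off_diag = p.covariance[~np.eye(3, dtype=bool)]
        assert np.all(off_diag == 0.0)

    def test_zero_valued_parameter_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            prop.generic_proposal(_center([0.0]))


class TestInflate:
    def test_variances_scaled_elementwise(self):
        p = prop.from_covariance(_center([1.0, 1.0]), np.diag([0.04, 0.01]))
        q = prop.inflate(p, 1.5)
        np.testing.assert_allclose(np.diag(q.covariance), [0.06, 0.015])

    def test_factor_one_is_identity(self):
        p = prop.from_covariance(_center([1.0]), np.array([[0.2]]))
        np.testing.assert_array_equal(prop.inflate(p, 1.0).covariance, p.covariance)

    def test_marginal_sds_scale_by_sqrt_factor(self):
        p = prop.from_covariance(_center([1.0, 2.0]), np.array([[1.0, 0.3], [0.3, 2.0]]))
        q = prop.inflate(p, 3.0)
        np.testing.assert_allclose(q.marginal_sds(), np.sqrt(3.0) * p.marginal_sds())

    def test_correlations_unchanged(self):
        cov = np.array([[1.0, 0.6, 0.1], [0.6, 2.0, -0.4], [0.1, -0.4, 0.5]])
        p = prop.from_covariance(_center([0.0, 0.0, 0.0]), cov)
        q = prop.inflate(p, 2.3)
        corr = lambda c: c / np.sqrt(np.outer(np.diag(c), np.diag(c)))
        assert np.abs(corr(q.covariance) - corr(p.covariance)).max() < 1e-12

    def test_shrinking_factor_rejected(self):
        p = prop.from_covariance(_center([0.0]), np.eye(1))
        with pytest.raises(ValueError):
            prop.inflate(p, 0.9)


class TestBoxCox:
    def test_lognormal_vectors_recover_shape_near_zero(self):
        rng = np.random.default_rng(1)
        X = np.exp(rng.normal(0.0, 0.5, size=(1000, 1)))
        bc = prop.fit_boxcox(X, _center([1.0]))
        assert -0.2 <= bc.shapes[0] <= 0.2

    def test_normal_vectors_recover_shape_near_one(self):
        # CV 0.2: large enough relative spread for the shape to be identified
        rng = np.random.default_rng(2)
        X = rng.normal(10.0, 2.0, size=(1000, 1))
        bc = prop.fit_boxcox(X, _center([10.0]))
        assert 0.7 <= bc.shapes[0] <= 1.3

    def test_fixed_shapes_honored_exactly(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(5, 1, 200), np.exp(rng.normal(-1, 0.3, 200))])
        center = _center([5.0, 0.4], classes=("fixed_effect", "iiv_variance"))
        bc = prop.fit_boxcox(
            X, center, fixed_shapes={"fixed_effect": 1.0, "iiv_variance": 0.0}
        )
        np.testing.assert_array_equal(bc.shapes, [1.0, 0.0])

    def test_lambda_zero_samples_stay_positive(self):
        rng = np.random.default_rng(4)
        X = np.exp(rng.normal(0.0, 1.0, size=(500, 1)))
        center = _center([1.0])
        bc = prop.fit_boxcox(X, center, fixed_shapes={"fixed_effect": 0.0})
        x = prop.sample(bc, 2000, seed=0).values
        assert np.all(x > 0.0)

    def test_lambda_one_moment_matches_mvn(self):
        # BoxCox(lambda=1, shift 0) with mean_z = mean - 1 is distributionally
        # equal to the MVN proposal: z = x - 1 is an affine relabelling
        mean = np.array([3.0, 8.0])
        cov = np.array([[1.0, 0.4], [0.4, 0.8]])
        center = _center(mean)
        bc = prop.BoxCoxProposal(
            center=center,
            shapes=np.ones(2),
            shifts=np.zeros(2),
            mean_z=mean - 1.0,
            covariance_z=cov,
        )
        mvn = prop.from_covariance(center, cov)
        xb = prop.sample(bc, 100_000, seed=6).values
        xm = prop.sample(mvn, 100_000, seed=7).values
        # 4x the Monte-Carlo SE of a mean / covariance entry at 1e5 draws
        np.testing.assert_allclose(xb.mean(0), xm.mean(0), atol=4 * 1.0 / np.sqrt(1e5))
        np.testing.assert_allclose(
            np.cov(xb, rowvar=False), np.cov(xm, rowvar=False), atol=0.03
        )

    def test_relpdf_matches_numerically_normalized_lognormal(self):
        # lambda=0, one parameter: density ratio must equal the log-normal
        # ratio with its 1/x Jacobian; check the implied density integrates
        # to 1 by quadrature, and the ratio against the closed form
        from scipy import integrate, stats

        rng = np.random.default_rng(8)
        mu, sd = 0.5, 0.4
        X = np.exp(rng.normal(mu, sd, size=(2000, 1)))
        center = _center([float(np.exp(mu))])
        bc = prop.fit_boxcox(X, center, fixed_shapes={"fixed_effect": 0.0})
        mz, vz = bc.mean_z[0], bc.covariance_z[0, 0]
        dens = lambda x: stats.norm.pdf(np.log(x), mz, np.sqrt(vz)) / x
        total, _ = integrate.quad(dens, 1e-9, 200.0)
        assert total == pytest.approx(1.0, abs=1e-6)
        x_test = 2.7
        expected = dens(x_test) / dens(center.values[0])
        got = prop.relpdf(bc, np.array([[x_test]]))[0]
        assert got == pytest.approx(expected, rel=1e-8)

    def test_out_of_support_vector_gets_zero_relpdf(self):
        rng = np.random.default_rng(9)
        X = np.exp(rng.normal(0.0, 0.3, size=(200, 1)))
        bc = prop.fit_boxcox(X, _center([1.0]), fixed_shapes={"fixed_effect": 0.0})
        assert prop.relpdf(bc, np.array([[-1.0]]))[0] == 0.0

    def test_shifted_fit_covers_negative_values(self):
        rng = np.random.default_rng(10)
        X = rng.normal(-3.0, 0.5, size=(500, 1))
        bc = prop.fit_boxcox(X, _center([-3.0]))
        assert bc.shifts[0] > 3.0  # support shifted to positive
        x = prop.sample(bc, 1000, seed=0).values
        assert np.isfinite(x).all()

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError, match="50"):
            prop.fit_boxcox(np.ones((10, 1)), _center([1.0]))

    def test_degenerate_marginal_flagged(self):
        rng = np.random.default_rng(11)
        X = np.column_stack([np.full(100, 2.0), rng.normal(0, 1, 100)])
        bc = prop.fit_boxcox(X, _center([2.0, 0.0]))
        assert bc.shapes[0] == 1.0
        assert bc.zero_variance_flags is not None and bc.zero_variance_flags[0]

    def test_correlation_cap_applied(self):
        rng = np.random.default_rng(12)
        z = rng.normal(size=(500, 1))
        X = np.column_stack([z[:, 0] + 10, 0.999 * z[:, 0] + 10])
        X += rng.normal(scale=1e-3, size=X.shape)
        bc = prop.fit_boxcox(X, _center([10.0, 10.0]), cap_correlation=0.95)
        c = bc.covariance_z
        rho = c[0, 1] / np.sqrt(c[0, 0] * c[1, 1])
        assert rho <= 0.95 + 1e-9

    def test_skewness_sign_preserved_through_refit(self):
        # sample -> fit -> sample keeps each marginal's skewness sign
        from scipy.stats import skew

        rng = np.random.default_rng(13)
        X = np.exp(rng.normal(0.0, 0.7, size=(10_000, 1)))
        bc = prop.fit_boxcox(X, _center([1.0]))
        x2 = prop.sample(bc, 10_000, seed=14).values
        assert np.sign(skew(x2[:, 0])) == np.sign(skew(X[:, 0])) == 1.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    center=st.lists(st.floats(-5, 5), min_size=1, max_size=4),
    scale=st.floats(0.1, 3.0),
)
def test_relpdf_at_center_is_always_one(center, scale):
    c = _center(center)
    p = prop.from_covariance(c, scale * np.eye(len(center)))
    assert prop.relpdf(p, np.array([center]))[0] == pytest.approx(1.0)
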