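"""Classification heads, Gaussian-mixture regression and the joint loss."""

import numpy as np
import pytest
from scipy.integrate import simpson

import gaitgcn as gg
from gaitgcn import nn
from gaitgcn.heads import (GMMParams, MultiTaskHeads, TargetScaler,
                           cross_entropy, gmm_density, gmm_nll,
                           gmm_nll_tensor, multitask_loss, point_estimate,
                           prediction_entropy)

LOG_2PI = np.log(2 * np.pi)


@pytest.fixture
def heads():
    return MultiTaskHeads(8, np.random.default_rng(0), hidden=(16, 8),
                          gmm_components=3)


def test_zero_weights_give_uniform_probabilities():
    h = MultiTaskHeads(8, np.random.default_rng(0), hidden=(16, 8))
    for layers in (h.med, h.fog):
        for W, b in layers:
            W.data[:] = 0.0
            b.data[:] = 0.0
    feat = nn.Tensor(np.random.default_rng(1).standard_normal((4, 8)))
    med_logits, fog_logits = h.classify_logits(feat)
    np.testing.assert_allclose(nn.softmax(med_logits).data, 0.5, atol=1e-7)
    np.testing.assert_allclose(nn.softmax(fog_logits).data, 0.2, atol=1e-7)


def test_probabilities_sum_to_one_random(heads):
    feat = nn.Tensor(np.random.default_rng(2).standard_normal((6, 8)))
    med_logits, fog_logits = heads.classify_logits(feat)
    for logits, k in ((med_logits, 2), (fog_logits, 5)):
        p = nn.softmax(logits).data
        assert p.shape[1] == k
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_entropy_bounds():
    assert prediction_entropy(np.full((1, 5), 0.2))[0] == pytest.approx(
        np.log(5), abs=1e-9
    )
    one_hot = np.zeros((1, 5))
    one_hot[0, 2] = 1.0
    assert prediction_entropy(one_hot)[0] == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------- #
# GMM head parameterization
# ---------------------------------------------------------------------- #
def test_single_component_mixing_is_one():
    h = MultiTaskHeads(8, np.random.default_rng(3), hidden=(16, 8),
                       gmm_components=1)
    feat = nn.Tensor(np.random.default_rng(4).standard_normal((5, 8)))
    params = h.gmm_params(feat)
    np.testing.assert_allclose(params.alpha, 1.0, atol=1e-7)


def test_zero_sigma_head_output_gives_unit_sigma():
    h = MultiTaskHeads(8, np.random.default_rng(5), hidden=(16, 8),
                       gmm_components=2)
    for W, b in h.f_sigma:
        W.data[:] = 0.0
        b.data[:] = 0.0
    feat = nn.Tensor(np.random.default_rng(6).standard_normal((3, 8)))
    params = h.gmm_params(feat)
    np.testing.assert_allclose(params.sigma, 1.0, atol=1e-7)


def test_alpha_simplex_random(heads):
    feat = nn.Tensor(np.random.default_rng(7).standard_normal((10, 8)))
    params = heads.gmm_params(feat)
    np.testing.assert_allclose(params.alpha.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(params.alpha >= 0)
    assert np.all(params.sigma > 0)


# ---------------------------------------------------------------------- #
# mixture negative log-likelihood
# ---------------------------------------------------------------------- #
def test_nll_at_peak_of_unit_gaussian():
    """m=1, mu=y, sigma=1 -> NLL = 0.5*ln(2*pi)."""
    params = GMMParams(alpha=np.array([[1.0]]), mu=np.array([[0.7]]),
                       sigma=np.array([[1.0]]))
    assert gmm_nll(0.7, params) == pytest.approx(0.5 * LOG_2PI, abs=1e-9)


def test_density_integrates_to_one_by_quadrature():
    rng = np.random.default_rng(8)
    for _ in range(10):
        a = rng.dirichlet(np.ones(3))
        params = GMMParams(
            alpha=a[None], mu=rng.normal(0, 2, (1, 3)),
            sigma=rng.uniform(0.3, 1.5, (1, 3)),
        )
        y = np.linspace(-10, 10, 4001)
        mass = simpson(gmm_density(y, params), x=y)
        assert mass == pytest.approx(1.0, abs=1e-3)


def test_mixture_nll_component_bound():
    """NLL <= single-component NLL + ln(1/alpha_i) for every component."""
    rng = np.random.default_rng(9)
    a = rng.dirichlet(np.ones(3))
    params = GMMParams(alpha=a[None], mu=rng.normal(0, 1, (1, 3)),
                       sigma=rng.uniform(0.5, 2.0, (1, 3)))
    y = 0.3
    total = gmm_nll(y, params)
    for i in range(3):
        single = GMMParams(alpha=np.array([[1.0]]),
                           mu=params.mu[:, i : i + 1],
                           sigma=params.sigma[:, i : i + 1])
        assert total <= gmm_nll(y, single) + np.log(1.0 / a[i]) + 1e-9


def test_tensor_nll_matches_numpy_closed_form():
    rng = np.random.default_rng(10)
    B, m = 4, 3
    la = np.log(rng.dirichlet(np.ones(m), B)).astype(np.float32)
    mu = rng.normal(0, 1, (B, m)).astype(np.float32)
    ls = rng.normal(0, 0.3, (B, m)).astype(np.float32)
    y = rng.normal(0, 1, B)
    out = gmm_nll_tensor(y, nn.Tensor(la), nn.Tensor(mu), nn.Tensor(ls))
    per = [
        gmm_nll(y[b], GMMParams(alpha=np.exp(la[b : b + 1]),
                                mu=mu[b : b + 1], sigma=np.exp(ls[b : b + 1])))
        for b in range(B)
    ]
    assert float(out.data) == pytest.approx(np.mean(per), abs=1e-4)


# ---------------------------------------------------------------------- #
# point estimate
# ---------------------------------------------------------------------- #
def test_point_estimate_inverse_transform():
    scaler = TargetScaler(mean=30.0, sd=10.0)
    params = GMMParams(alpha=np.array([[1.0]]), mu=np.array([[0.0]]),
                       sigma=np.array([[1.0]]))
    assert point_estimate(params, scaler)[0] == pytest.approx(30.0)


def test_point_estimate_symmetric_mixture_zero_mean():
    scaler = TargetScaler(mean=0.0, sd=1.0)
    params = GMMParams(alpha=np.array([[0.5, 0.5]]),
                       mu=np.array([[-1.0, 1.0]]),
                       sigma=np.array([[0.7, 0.7]]))
    assert point_estimate(params, scaler)[0] == pytest.approx(0.0, abs=1e-12)


def test_point_estimate_matches_quadrature_mean():
    rng = np.random.default_rng(11)
    a = rng.dirichlet(np.ones(3))
    params = GMMParams(alpha=a[None], mu=rng.normal(0, 1.5, (1, 3)),
                       sigma=rng.uniform(0.4, 1.2, (1, 3)))
    y = np.linspace(-12, 12, 6001)
    quad_mean = simpson(y * gmm_density(y, params), x=y)
    scaler = TargetScaler(mean=0.0, sd=1.0)
    assert point_estimate(params, scaler)[0] == pytest.approx(quad_mean, abs=1e-3)


def test_dominant_component_mode():
    scaler = TargetScaler(mean=10.0, sd=2.0)
    params = GMMParams(alpha=np.array([[0.2, 0.8]]),
                       mu=np.array([[-1.0, 1.0]]),
                       sigma=np.array([[1.0, 1.0]]))
    assert point_estimate(params, scaler, mode="dominant")[0] == pytest.approx(12.0)


# ---------------------------------------------------------------------- #
# joint loss
# ---------------------------------------------------------------------- #
def test_loss_weight_zeroing_single_task(heads):
    feat = nn.Tensor(np.random.default_rng(12).standard_normal((4, 8)))
    med = np.array([0, 1, 0, 1])
    fog = np.array([0, 2, 4, 1])
    y_z = np.zeros(4)
    fog_only = multitask_loss(heads, feat, med, fog, y_z, weights=(0, 1, 0))
    ce = cross_entropy(heads.classify_logits(feat)[1], fog)
    assert float(fog_only.data) == pytest.approx(float(ce.data), abs=1e-6)
    with pytest.raises(ValueError, match="zero"):
        multitask_loss(heads, feat, med, fog, y_z, weights=(0, 0, 0))


def test_loss_finite_for_random_inputs(heads):
    rng = np.random.default_rng(13)
    feat = nn.Tensor(rng.standard_normal((8, 8)) * 50)
    med = rng.integers(0, 2, 8)
    fog = rng.integers(0, 5, 8)
    y_z = rng.normal(0, 1, 8)
    loss = multitask_loss(heads, feat, med, fog, y_z)
    assert np.isfinite(float(loss.data))


def test_gmm_nll_descends_under_gradient_steps():
    """Adam on a fixed toy regression set monotonically improves the NLL
    (checked on a smoothed trajectory)."""
    rng = np.random.default_rng(14)
    h = MultiTaskHeads(4, rng, hidden=(8, 8), gmm_components=2)
    feat = nn.Tensor(rng.standard_normal((32, 4)).astype(np.float32))
    y = (0.5 * feat.data[:, 0] - 0.2 * feat.data[:, 1]).astype(np.float64)
    opt = nn.Adam(h.params, lr=1e-2)
    losses = []
    for _ in range(60):
        la, mu, ls = h.gmm_tensors(feat)
        loss = gmm_nll_tensor(y, la, mu, ls)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    assert losses[-1] < losses[0] - 0.3
    assert np.mean(losses[-10:]) < np.mean(losses[:10])


def test_m1_gmm_equals_gaussian_nll_closed_form():
    """With one component the loss is exactly Gaussian NLL."""
    rng = np.random.default_rng(15)
    mu = rng.normal(0, 1, (5, 1)).astype(np.float32)
    ls = rng.normal(0, 0.2, (5, 1)).astype(np.float32)
    y = rng.normal(0, 1, 5)
    la = np.zeros((5, 1), dtype=np.float32)
    out = float(gmm_nll_tensor(y, nn.Tensor(la), nn.Tensor(mu),
                               nn.Tensor(ls)).data)
    sigma = np.exp(ls[:, 0])
    expect = np.mean(0.5 * ((y - mu[:, 0]) / sigma) ** 2 + np.log(sigma)
                     + 0.5 * LOG_2PI)
    assert out == pytest.approx(expect, abs=1e-5)


def test_scaler_requires_positive_sd():
    with pytest.raises(ValueError):
        TargetScaler(mean=0.0, sd=0.0)
    s = TargetScaler.fit(np.array([30.0, 40.0, 50.0]))
    np.testing.assert_allclose(s.inverse(s.transform([35.0])), [35.0])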