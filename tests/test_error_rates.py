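import numpy as np
import pytest
from scipy import stats

from allocbias import (BiasPolicy, ConfigurationError, DegenerateSequenceError,
                       RPSpec, TrialDesign, aon_t1e, batch_rates, bias_matrix,
                       generate_sequences, noncentrality, pca_transform,
                       sidak_fwer, sidak_fwer_correlated)

from conftest import ROSTER


def exchangeable(m, rho):
    corr = np.full((m, m), rho)
    np.fill_diagonal(corr, 1.0)
    return corr


def test_design_validation():
    with pytest.raises(ConfigurationError):
        TrialDesign(N=3, m=2, alpha=0.05)
    with pytest.raises(ConfigurationError):
        TrialDesign(N=8, m=2, alpha=0.0)
    with pytest.raises(ConfigurationError):
        TrialDesign(N=8, m=2, alpha=0.05, sigma=[1.0, -1.0])
    with pytest.raises(ConfigurationError):
        TrialDesign(N=8, m=2, alpha=0.05, corr=[[1.0, 0.3], [0.4, 1.0]])
    with pytest.raises(ConfigurationError):
        TrialDesign(N=8, m=2, alpha=0.05, corr=exchangeable(2, -1.5))


def test_noncentrality_hand_examples():
    nc = noncentrality(np.array([1, 0, 1, 0]), [0, -0.1, 0, -0.1], 1.0)
    assert (nc.delta, nc.lam) == (pytest.approx(0.1), pytest.approx(0.0))
    nc = noncentrality(np.array([1, 1, 0, 0]), [0, -0.1, -0.1, -0.1], 1.0)
    assert nc.delta == pytest.approx(0.05)
    assert nc.lam == pytest.approx(0.005)
    nc = noncentrality(np.array([1, 0, 1, 0]), [0, 0, 0, 0], 2.0)
    assert (nc.delta, nc.lam) == (0.0, 0.0)
    with pytest.raises(DegenerateSequenceError):
        noncentrality(np.array([1, 1, 1, 1]), [0, 0, 0, 0], 1.0)


def test_unbiased_rates_equal_alpha_exactly():
    t = np.array([1, 0, 0, 1, 1, 0])
    for m in (1, 2, 5):
        design = TrialDesign(N=6, m=m, alpha=0.05)
        tau = bias_matrix(t, BiasPolicy(np.zeros(m)))
        assert sidak_fwer(t, tau, design) == pytest.approx(0.05, abs=1e-10)
        assert aon_t1e(t, tau, design) == pytest.approx(0.05, abs=1e-10)


def test_sidak_lam0_closed_form():
    """Alternating list: zero within-arm bias spread, so the FWER reduces
    to a closed form in singly non-central t CDFs."""
    t = np.array([1, 0, 1, 0])
    design = TrialDesign(N=4, m=2, alpha=0.05)
    tau = bias_matrix(t, BiasPolicy([0.1, 0.1]))
    alpha_star = 1 - 0.95 ** 0.5
    c_low = stats.t.ppf(alpha_star / 2, 2)
    p = stats.nct.cdf(c_low, 2, 0.1) + stats.nct.cdf(c_low, 2, -0.1)
    expected = 1 - (1 - p) ** 2
    assert sidak_fwer(t, tau, design) == pytest.approx(expected, abs=1e-12)


def test_pca_transform_examples():
    d = TrialDesign(N=8, m=3, alpha=0.05)
    pca = pca_transform(d)
    assert np.allclose(pca.eigenvalues, 1.0)
    assert np.allclose(pca.A, np.eye(3))

    d2 = TrialDesign(N=8, m=2, alpha=0.05, corr=exchangeable(2, 0.5))
    pca2 = pca_transform(d2)
    assert np.allclose(pca2.eigenvalues, [1.5, 0.5])
    assert np.allclose(np.abs(pca2.A), 1 / np.sqrt(2))
    assert np.allclose(pca2.A.T @ pca2.A, np.eye(2), atol=1e-10)

    d5 = TrialDesign(N=8, m=5, alpha=0.05, corr=exchangeable(5, 0.9))
    pca5 = pca_transform(d5)
    assert np.allclose(pca5.eigenvalues, [4.6, 0.1, 0.1, 0.1, 0.1])
    cov = d5.covariance
    for k in range(5):
        assert np.allclose(cov @ pca5.A[:, k],
                           pca5.eigenvalues[k] * pca5.A[:, k], atol=1e-8)


def test_correlated_identity_matches_independent():
    t = np.array([1, 1, 0, 0, 1, 0, 0, 1])
    tau = bias_matrix(t, BiasPolicy([0.2, 0.3]))
    d_ind = TrialDesign(N=8, m=2, alpha=0.05)
    d_eye = TrialDesign(N=8, m=2, alpha=0.05, corr=np.eye(2))
    assert sidak_fwer_correlated(t, tau, d_eye) == \
        pytest.approx(sidak_fwer(t, tau, d_ind), abs=1e-12)


def test_endpoint_relabeling_invariance():
    t = np.array([1, 1, 0, 0, 1, 0])
    eta = np.array([0.1, 0.4, 0.25])
    sigma = np.array([1.0, 2.0, 0.5])
    perm = [2, 0, 1]
    tau = bias_matrix(t, BiasPolicy(eta))
    d1 = TrialDesign(N=6, m=3, alpha=0.05, sigma=sigma)
    d2 = TrialDesign(N=6, m=3, alpha=0.05, sigma=sigma[perm])
    tau_p = bias_matrix(t, BiasPolicy(eta[perm]))
    assert sidak_fwer(t, tau, d1) == pytest.approx(
        sidak_fwer(t, tau_p, d2), abs=1e-12)
    assert aon_t1e(t, tau, d1) == pytest.approx(
        aon_t1e(t, tau_p, d2), abs=1e-12)


def test_homogeneous_exchangeable_symmetric_under_relabeling():
    t = np.array([1, 0, 0, 1, 1, 0])
    d = TrialDesign(N=6, m=3, alpha=0.05, corr=exchangeable(3, 0.6))
    tau = bias_matrix(t, BiasPolicy([0.3, 0.3, 0.3]))
    v = sidak_fwer_correlated(t, tau, d)
    assert 0 <= v <= 1
    # any permutation leaves the exchangeable design and policy unchanged
    assert sidak_fwer_correlated(t, tau[:, ::-1], d) == pytest.approx(v, abs=1e-12)


def test_arm_swap_negates_delta_keeps_lam_and_sidak():
    """Complementing the allocation while holding the bias shifts fixed
    negates delta, preserves lam, and leaves the two-sided FWER unchanged."""
    t = np.array([1, 1, 0, 1, 0, 0])
    tau = bias_matrix(t, BiasPolicy([0.4]))
    nc = noncentrality(t, tau[:, 0], 1.0)
    nc_sw = noncentrality(1 - t, tau[:, 0], 1.0)
    assert nc_sw.delta == pytest.approx(-nc.delta, abs=1e-12)
    assert nc_sw.lam == pytest.approx(nc.lam, abs=1e-12)
    d = TrialDesign(N=6, m=1, alpha=0.05)
    assert sidak_fwer(1 - t, tau, d) == \
        pytest.approx(sidak_fwer(t, tau, d), abs=1e-12)
    # re-deriving the shifts for the swapped list instead restores delta:
    # the biasing policy itself is arm-symmetric
    tau_sw = bias_matrix(1 - t, BiasPolicy([0.4]))
    nc_re = noncentrality(1 - t, tau_sw[:, 0], 1.0)
    assert nc_re.delta == pytest.approx(nc.delta, abs=1e-12)


def test_aon_identical_endpoints_independent_of_m():
    t = np.array([1, 1, 0, 0, 1, 0, 1, 0])
    for m in (2, 5):
        d = TrialDesign(N=8, m=m, alpha=0.05)
        tau = bias_matrix(t, BiasPolicy(np.full(m, 0.25)))
        if m == 2:
            ref = aon_t1e(t, tau, d)
        else:
            assert aon_t1e(t, tau, d) == pytest.approx(ref, abs=1e-14)


def test_sidak_requires_independent_corr():
    t = np.array([1, 0, 1, 0])
    d = TrialDesign(N=4, m=2, alpha=0.05, corr=exchangeable(2, 0.5))
    tau = bias_matrix(t, BiasPolicy([0.1, 0.1]))
    with pytest.raises(ConfigurationError):
        sidak_fwer(t, tau, d)


@pytest.mark.parametrize("procedure", ["sidak", "all_or_none"])
@pytest.mark.parametrize("corr_rho", [None, 0.5])
def test_batch_matches_per_list(procedure, corr_rho, rng):
    """The vectorized profile-cached batch path reproduces the per-list
    functions exactly."""
    m = 2
    corr = None if corr_rho is None else exchangeable(m, corr_rho)
    design = TrialDesign(N=12, m=m, alpha=0.05, sigma=[1.0, 1.5], corr=corr)
    policy = BiasPolicy([0.3, 0.2])
    T = np.concatenate([
        generate_sequences(spec, 12, 10, rng) for spec in ROSTER
    ])
    rates = batch_rates(T, design, policy, procedure)
    for i in range(0, T.shape[0], 7):
        t = T[i]
        tau = bias_matrix(t, policy)
        if procedure == "sidak":
            ref = (sidak_fwer(t, tau, design) if corr_rho is None
                   else sidak_fwer_correlated(t, tau, design))
        else:
            ref = aon_t1e(t, tau, design)
        assert rates[i] == pytest.approx(ref, abs=1e-12)


def test_batch_marks_degenerate_lists_nan():
    design = TrialDesign(N=4, m=1, alpha=0.05)
    T = np.array([[1, 1, 1, 1], [1, 0, 1, 0], [0, 0, 0, 0]])
    rates = batch_rates(T, design, BiasPolicy([0.1]), "sidak")
    assert np.isnan(rates[0]) and np.isnan(rates[2])
    assert 0 <= rates[1] <= 1
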