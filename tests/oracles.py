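"""Independent numerical oracles used across the test suite.

Everything here evaluates the defining integrals directly (Gauss-Hermite or
tensor-grid quadrature, Monte Carlo), sharing no code path with the package's
closed forms.
"""

import numpy as np
from scipy.special import ndtr, roots_hermitenorm, xlogy

_NODES, _WEIGHTS = roots_hermitenorm(200)
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()  # weights of a standard normal expectation


def gh_expect(fn, mu, sigma):
    """E[fn(t)] for t ~ N(mu, sigma^2) by 200-node Gauss-Hermite quadrature."""
    return float(np.sum(_WEIGHTS * fn(mu + sigma * _NODES)))


def quad_probit_gaussian(y, h, mu, sigma, sigma_p):
    """∫ Phi(y (h - t)/sigma_p) N(t | mu, sigma^2) dt by quadrature."""
    return gh_expect(lambda t: ndtr(y * (h - t) / sigma_p), mu, sigma)


def quad_se_entropy_term(h, mu, sigma, sigma_p):
    """∫ exp(-(h - t)^2 / (sigma_p^2 pi ln 2)) N(t | mu, sigma^2) dt by quadrature."""
    return gh_expect(
        lambda t: np.exp(-((h - t) ** 2) / (sigma_p**2 * np.pi * np.log(2.0))), mu, sigma
    )


def quad_evidence(component, trials, sigma_p, n_nodes=200):
    """Tensor-grid quadrature of Z = ∫ p(D|t) p_c(t) dt over 1-2 distinct freqs."""
    u, w = roots_hermitenorm(n_nodes)
    w = w / w.sum()
    xs = np.unique([t.stimulus.x for t in trials])
    if xs.size > 2:
        raise ValueError("tensor-grid oracle supports at most 2 distinct frequencies")
    mu = component.mean(xs)
    K = component.cov(xs) + 1e-10 * np.eye(xs.size)
    L = np.linalg.cholesky(K)
    idx = {x: i for i, x in enumerate(xs)}
    if xs.size == 1:
        T = (mu[0] + L[0, 0] * u)[None, :]
        W = w
    else:
        U1, U2 = np.meshgrid(u, u, indexing="ij")
        W = np.outer(w, w)
        T = mu[:, None, None] + np.einsum("ij,jkl->ikl", L, np.stack([U1, U2]))
    lik = np.ones_like(T[0])
    for t in trials:
        lik = lik * ndtr(t.y * (t.stimulus.h - T[idx[t.stimulus.x]]) / sigma_p)
    return float(np.sum(W * lik))


def entropy_bits(p):
    p = np.asarray(p, dtype=float)
    return -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / np.log(2.0)


def mc_mutual_information_bits(mu, sigma, h, sigma_p, n_samples, rng):
    """Monte-Carlo I[y; t] (bits) for t ~ N(mu, sigma^2), y ~ probit response."""
    t = rng.normal(mu, sigma, n_samples)
    p = ndtr((h - t) / sigma_p)
    return float(entropy_bits(p.mean()) - entropy_bits(p).mean())
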