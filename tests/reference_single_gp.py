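"""A self-contained single-GP probit audiometry implementation.

Used as the independent reference path for the C=1 reduction check: a plain
GP prior (cubic mean in centered Bark coordinates, SE kernel) with a probit
likelihood, Laplace posterior, GP-conditioned predictions, and the BALD
acquisition for a single Gaussian posterior.  Deliberately shares no code
with the package beyond numpy/scipy.
"""

import numpy as np
from scipy.special import log_ndtr, ndtr, xlogy
from scipy.stats import norm


class SingleGP:
    def __init__(self, coeffs, variance, lengthscale, center, sigma_p):
        self.coeffs = np.asarray(coeffs, dtype=float)
        self.variance = float(variance)
        self.lengthscale = float(lengthscale)
        self.center = float(center)
        self.sigma_p = float(sigma_p)

    def mean(self, xs):
        u = np.asarray(xs, dtype=float) - self.center
        return sum(a * u**k for k, a in enumerate(self.coeffs))

    def kernel(self, a, b):
        a = np.asarray(a, dtype=float)[:, None]
        b = np.asarray(b, dtype=float)[None, :]
        return self.variance * np.exp(-((a - b) ** 2) / (2 * self.lengthscale**2))

    def fit(self, xs_trials, hs, ys, tol=1e-10, max_iter=200):
        """Laplace fit; returns (unique_xs, mode, cov, K_chol, weights)."""
        xs, inv = np.unique(np.asarray(xs_trials, dtype=float), return_inverse=True)
        hs = np.asarray(hs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        n = xs.size
        m = self.mean(xs)
        K = self.kernel(xs, xs) + 1e-8 * self.variance * np.eye(n)
        Kinv = np.linalg.inv(K)
        t = m.copy()
        for _ in range(max_iter):
            z = ys * (hs - t[inv]) / self.sigma_p
            lam = np.exp(norm.logpdf(z) - log_ndtr(z))
            g = np.zeros(n)
            np.add.at(g, inv, -(ys / self.sigma_p) * lam)
            grad = g - Kinv @ (t - m)
            if np.linalg.norm(grad) < tol:
                break
            w = np.zeros(n)
            np.add.at(w, inv, (z * lam + lam**2) / self.sigma_p**2)
            H = Kinv + np.diag(w)
            t = t + np.linalg.solve(H, grad)
        z = ys * (hs - t[inv]) / self.sigma_p
        lam = np.exp(norm.logpdf(z) - log_ndtr(z))
        w = np.zeros(n)
        np.add.at(w, inv, (z * lam + lam**2) / self.sigma_p**2)
        cov = np.linalg.inv(Kinv + np.diag(w))
        self._xs, self._mode, self._cov = xs, t, 0.5 * (cov + cov.T)
        self._K = K
        return xs, t, self._cov

    def predict(self, xq):
        xq = np.atleast_1d(np.asarray(xq, dtype=float))
        mu0 = self.mean(xq)
        if not hasattr(self, "_xs") or self._xs.size == 0:
            return mu0, np.full(xq.size, np.sqrt(self.variance))
        ks = self.kernel(xq, self._xs)
        Kinv = np.linalg.inv(self._K)
        mu = mu0 + ks @ Kinv @ (self._mode - self.mean(self._xs))
        var = (
            self.variance
            - np.einsum("qn,nm,qm->q", ks, Kinv, ks)
            + np.einsum("qn,nm,mk,kl,ql->q", ks, Kinv, self._cov, Kinv, ks)
        )
        return mu, np.sqrt(np.maximum(var, 1e-12))

    def bald(self, x, h):
        mu, sd = self.predict(x)
        mu, sd = mu[0], sd[0]
        p = ndtr((h - mu) / np.sqrt(self.sigma_p**2 + sd**2))
        ent = -(xlogy(p, p) + xlogy(1 - p, 1 - p)) / np.log(2)
        Kc = self.sigma_p * np.sqrt(np.pi * np.log(2) / 2)
        s2 = sd**2 + Kc**2
        return float(ent - (Kc / np.sqrt(s2)) * np.exp(-((h - mu) ** 2) / (2 * s2)))

    def select(self, freqs_bark, intensities):
        best, best_val = None, -np.inf
        for i, x in enumerate(freqs_bark):
            for h in intensities:
                val = self.bald(x, h)
                if val > best_val:
                    best, best_val = (i, h), val
        return best
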