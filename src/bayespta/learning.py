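"""Maximum-likelihood learning of the GP mixture from annotated audiograms.

Because audiograms tabulate thresholds on a fixed finite frequency grid F, the
infinite-dimensional GP mixture restricted to F is an ordinary Gaussian
mixture.  Learning therefore proceeds in three steps:

1. fit a full-covariance Gaussian mixture to the complete-case audiograms on F
   by expectation-maximization;
2. for each fitted Gaussian, find the GP component (cubic mean polynomial +
   squared-exponential kernel) whose finite-dimensional prior on F minimizes
   the KL divergence to it;
3. build the side-information table alpha(I): per-record component
   responsibilities are averaged within (age-bucket, gender) strata and
   queried by nearest neighbor.

The perceptual noise sigma_p cannot be identified from audiograms alone (they
contain no individual responses) and is supplied by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .gp_mixture import (
    AGE_BUCKET_YEARS,
    AlphaTable,
    GaussianDensity,
    GPComponent,
    MixtureModel,
    SideInfo,
    component_prior_at,
)
from .inference import posterior_log_likelihood, posterior_mixture
from .psychoacoustics import BARK_CENTER, STANDARD_FREQUENCIES_HZ, bark

__all__ = [
    "AudiogramRecord",
    "AudiogramDataset",
    "GMMParams",
    "fit_gmm",
    "gp_predictive_on_grid",
    "match_gp_to_gaussian",
    "build_alpha_table",
    "fit_model",
    "average_posterior_log_likelihood",
]

logger = logging.getLogger(__name__)

_MIN_DEFINED_FREQS = 4  # fit degrees of freedom for the cubic mean


@dataclass(frozen=True)
class AudiogramRecord:
    """Thresholds (dB-HL) on a subset of the standard grid, plus side info."""

    thresholds: dict  # frequency Hz -> dB-HL
    info: SideInfo = SideInfo()

    def __post_init__(self):
        if len(self.thresholds) < _MIN_DEFINED_FREQS:
            raise ValueError(
                f"record needs >= {_MIN_DEFINED_FREQS} defined frequencies, got {len(self.thresholds)}"
            )
        if not all(np.isfinite(v) for v in self.thresholds.values()):
            raise ValueError("thresholds must be finite")

    def frequencies(self) -> np.ndarray:
        return np.array(sorted(self.thresholds), dtype=float)

    def values(self) -> np.ndarray:
        return np.array([self.thresholds[f] for f in sorted(self.thresholds)], dtype=float)


@dataclass
class AudiogramDataset:
    records: list  # list[AudiogramRecord]

    def __len__(self) -> int:
        return len(self.records)

    def complete_on(self, grid_hz: Sequence[float]):
        """Records defined at every frequency of ``grid_hz``; also the drop count."""
        grid = [float(f) for f in grid_hz]
        kept = [r for r in self.records if all(f in r.thresholds for f in grid)]
        return kept, len(self.records) - len(kept)


@dataclass
class GMMParams:
    """MLE parameters of the finite-dimensional Gaussian mixture on grid F."""

    weights: np.ndarray  # (C,)
    means: np.ndarray  # (C, |F|)
    covariances: np.ndarray  # (C, |F|, |F|)
    grid_hz: np.ndarray  # (|F|,)
    log_likelihood: float


def fit_gmm(
    dataset: AudiogramDataset,
    n_components: int,
    rng: np.random.Generator,
    n_init: int = 4,
    grid_hz: Optional[Sequence[float]] = None,
    reg_covar: float = 1e-6,
) -> GMMParams:
    """EM fit of a full-covariance Gaussian mixture on the complete cases.

    Incomplete records (missing any grid frequency) are dropped with a logged
    count.  The best of ``n_init`` k-means++-initialized restarts is returned.

    ``reg_covar`` is the diagonal floor added to every covariance.  For
    thresholds recorded at a finite resolution it should be at least the
    quantization variance (step^2/12): with the default near-zero floor, EM on
    quantized data can chase degenerate high-likelihood components that
    collapse onto the value lattice.
    """
    grid = np.asarray(grid_hz if grid_hz is not None else STANDARD_FREQUENCIES_HZ, dtype=float)
    complete, dropped = dataset.complete_on(grid)
    if dropped:
        logger.info("fit_gmm: dropped %d incomplete records (complete-case EM)", dropped)
    if len(complete) < 10 * n_components:
        raise ValueError(
            f"need >= {10 * n_components} complete records for C={n_components}, got {len(complete)}"
        )
    X = np.array([[r.thresholds[f] for f in grid] for r in complete])
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        tol=1e-6,
        max_iter=500,
        n_init=n_init,
        init_params="k-means++",
        reg_covar=reg_covar,
        random_state=int(rng.integers(2**31 - 1)),
    )
    gm.fit(X)
    covs = gm.covariances_.copy()
    for c in range(n_components):
        eigvals = np.linalg.eigvalsh(covs[c])
        if eigvals.min() < 1e-6:
            logger.warning("fit_gmm: component %d near-singular, regularizing diagonal", c)
            covs[c] += (1e-6 - eigvals.min()) * np.eye(grid.size)
    return GMMParams(
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=covs,
        grid_hz=grid,
        log_likelihood=float(gm.score(X) * len(X)),
    )


def gp_predictive_on_grid(component: GPComponent, F_bark) -> GaussianDensity:
    """Finite-dimensional prior of a GP component on a Bark grid (= prior at F)."""
    return component_prior_at(component, F_bark)


def _gaussian_kl(mu0, cov0, mu1, cov1_chol) -> float:
    """KL( N(mu0, cov0) || N(mu1, cov1) ) with cov1 given by Cholesky factor L."""
    L = cov1_chol
    n = mu0.size
    solve = np.linalg.solve
    half = solve(L, cov0)
    trace = np.trace(solve(L.T, half))
    dev = solve(L, mu1 - mu0)
    quad = dev @ dev
    logdet1 = 2.0 * np.sum(np.log(np.diag(L)))
    sign, logdet0 = np.linalg.slogdet(cov0)
    if sign <= 0:
        return np.inf
    return 0.5 * (trace + quad - n + logdet1 - logdet0)


def match_gp_to_gaussian(
    target: GaussianDensity,
    F_bark,
    init: Optional[GPComponent] = None,
    noise_variance: float = 0.0,
) -> GPComponent:
    """Fit a GP component whose prior on ``F_bark`` is KL-closest to ``target``.

    Minimizes KL(target || GP prior) over the cubic mean coefficients and the
    log kernel hyperparameters.  For fixed hyperparameters the KL is a
    generalized-least-squares quadratic in the mean coefficients, so those are
    profiled out in closed form and only (log variance, log lengthscale) are
    optimized numerically.

    ``noise_variance`` (dB^2) is added to the model covariance diagonal during
    matching: targets estimated from *observed* audiograms contain observation
    noise (e.g. 5 dB quantization contributes step^2/12 ~ 2.1 dB^2) that the
    smooth SE kernel itself must not absorb.  The returned component carries
    only the SE hyperparameters.
    """
    F_bark = np.asarray(F_bark, dtype=float)
    mu_t = np.asarray(target.mean, dtype=float)
    cov_t = np.asarray(target.cov, dtype=float)
    # one shared regularizer keeps the KL of an exact SE target at zero even
    # though SE covariances on dense grids are numerically near-singular
    jitter = 1e-8 * max(float(np.mean(np.diag(cov_t))), 1.0)
    cov_t = cov_t + jitter * np.eye(F_bark.size)
    sign, _ = np.linalg.slogdet(cov_t)
    if sign <= 0:
        cov_t = cov_t + 1e-6 * np.eye(F_bark.size)
        sign, _ = np.linalg.slogdet(cov_t)
        if sign <= 0:
            raise ValueError("target covariance is not positive definite")

    u = F_bark - BARK_CENTER
    B = np.vander(u, 4, increasing=True)  # (|F|, 4): 1, u, u^2, u^3

    def kernel(theta):
        v, ell = np.exp(theta)
        d = F_bark[:, None] - F_bark[None, :]
        K = v * np.exp(-0.5 * (d / ell) ** 2)
        return K + (jitter + noise_variance) * np.eye(F_bark.size)

    def profiled_coeffs(L):
        # GLS: argmin_(beta) (B beta - mu_t)^T K^{-1} (B beta - mu_t)
        Bw = np.linalg.solve(L, B)
        yw = np.linalg.solve(L, mu_t)
        beta, *_ = np.linalg.lstsq(Bw, yw, rcond=None)
        return beta

    def objective(theta):
        try:
            L = np.linalg.cholesky(kernel(theta))
        except np.linalg.LinAlgError:
            return 1e12
        beta = profiled_coeffs(L)
        kl = _gaussian_kl(mu_t, cov_t, B @ beta, L)
        return kl if np.isfinite(kl) else 1e12

    if init is not None:
        theta0 = np.log([init.kernel_variance, init.kernel_lengthscale])
    else:
        theta0 = np.log([max(np.mean(np.diag(cov_t)), 1e-3), 3.0])
    res = minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        options={"maxiter": 1000, "gtol": 1e-6, "ftol": 1e-14},
    )
    theta = res.x
    L = np.linalg.cholesky(kernel(theta))
    beta = profiled_coeffs(L)
    v, ell = np.exp(theta)
    fitted = GPComponent(tuple(beta), float(v), float(ell))
    logger.info(
        "match_gp_to_gaussian: final KL=%.3e (v=%.2f dB^2, l=%.2f Bark)", res.fun, v, ell
    )
    return fitted


def _responsibilities(
    record: AudiogramRecord,
    components: Sequence[GPComponent],
    weights: np.ndarray,
    noise_variance: float = 0.0,
) -> np.ndarray:
    """Posterior component probabilities of one audiogram (marginal likelihoods
    on the record's own defined frequencies).

    ``noise_variance`` models the observation noise of the recorded thresholds
    (quantization); without it the near-singular smooth GP covariances make the
    density of discretized records meaningless.
    """
    xs = bark(record.frequencies())
    t = record.values()
    logs = np.empty(len(components))
    for c, comp in enumerate(components):
        mean, cov = component_prior_at(comp, xs)
        cov = cov + (1e-8 * comp.kernel_variance + noise_variance) * np.eye(xs.size)
        logs[c] = multivariate_normal.logpdf(t, mean, cov)
    with np.errstate(divide="ignore"):
        logs = logs + np.log(weights)
    logs -= logs.max()
    r = np.exp(logs)
    return r / r.sum()


def build_alpha_table(
    dataset: AudiogramDataset,
    components: Sequence[GPComponent],
    sigma_p: float,
    marginal_weights: Optional[np.ndarray] = None,
    smoothing: float = 5.0,
    noise_variance: float = 0.0,
) -> AlphaTable:
    """Average per-record responsibilities within (age-bucket, gender) strata.

    Records missing some frequencies still contribute: Gaussian responsibilities
    marginalize trivially to the defined subset.  The unconditional entry is
    the mixture's own marginal weights.

    ``smoothing`` is a Dirichlet-style pseudo-count: every stratum average is
    shrunk toward the marginal weights as if ``smoothing`` marginal records had
    been observed there.  Component responsibilities of full audiograms are
    near-hard assignments, so without shrinkage a thinly populated stratum can
    store a weight of exactly zero for a component that merely happened not to
    occur there, which is ruinous for log-density scoring of new records.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    C = len(components)
    w = (
        np.full(C, 1.0 / C)
        if marginal_weights is None
        else np.asarray(marginal_weights, dtype=float)
    )

    sums: dict = {}
    counts: dict = {}
    age_sums: dict = {}
    age_counts: dict = {}
    gender_sums: dict = {}
    gender_counts: dict = {}
    for rec in dataset.records:
        r = _responsibilities(rec, components, w, noise_variance=noise_variance)
        b, g = rec.info.age_bucket, rec.info.gender
        if b is not None and g != "unspecified":
            key = (b, g)
            sums[key] = sums.get(key, 0.0) + r
            counts[key] = counts.get(key, 0) + 1
        if b is not None:
            age_sums[b] = age_sums.get(b, 0.0) + r
            age_counts[b] = age_counts.get(b, 0) + 1
        if g != "unspecified":
            gender_sums[g] = gender_sums.get(g, 0.0) + r
            gender_counts[g] = gender_counts.get(g, 0) + 1

    def shrink(total, count):
        return (total + smoothing * w) / (count + smoothing)

    return AlphaTable(
        n_components=C,
        unconditional=w,
        entries={k: shrink(sums[k], counts[k]) for k in sums},
        age_marginal={k: shrink(age_sums[k], age_counts[k]) for k in age_sums},
        gender_marginal={k: shrink(gender_sums[k], gender_counts[k]) for k in gender_sums},
    )


def fit_model(
    dataset: AudiogramDataset,
    n_components: int,
    sigma_p: float,
    rng: np.random.Generator,
    n_init: int = 4,
    grid_hz: Optional[Sequence[float]] = None,
    quantization_step: float = 5.0,
) -> MixtureModel:
    """The full three-step pipeline: EM -> KL matching -> alpha table.

    ``quantization_step`` is the resolution (dB) at which the input thresholds
    were recorded; the corresponding uniform-quantization variance step^2/12 is
    treated as observation noise when matching GP components to the fitted
    Gaussians.  Pass 0 for continuous-valued audiograms.
    """
    grid = np.asarray(grid_hz if grid_hz is not None else STANDARD_FREQUENCIES_HZ, dtype=float)
    quant_var = quantization_step**2 / 12.0
    reg = max(quant_var, 1e-6)
    gmm = fit_gmm(dataset, n_components, rng, n_init=n_init, grid_hz=grid, reg_covar=reg)
    logger.info("fit_model: GMM log-likelihood %.2f", gmm.log_likelihood)
    F_bark = bark(grid)
    # the fitted covariances carry quantization noise plus the diagonal floor;
    # neither belongs to the latent smooth threshold process
    components = [
        match_gp_to_gaussian(
            GaussianDensity(gmm.means[c], gmm.covariances[c]),
            F_bark,
            noise_variance=quant_var + reg,
        )
        for c in range(n_components)
    ]
    alpha = build_alpha_table(
        dataset, components, sigma_p, marginal_weights=gmm.weights, noise_variance=quant_var
    )
    return MixtureModel(components=components, alpha=alpha, sigma_p=sigma_p)


def average_posterior_log_likelihood(
    model: MixtureModel,
    dataset: AudiogramDataset,
    use_age: bool = False,
    use_gender: bool = False,
) -> float:
    """Average per-record predictive score of a model on held-out audiograms.

    Evaluates the zero-trial posterior (i.e. the possibly-conditioned prior)
    marginal mixture density at each record's defined frequencies.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    # zero-trial posteriors depend on info only through alpha; cache per weight key
    total = 0.0
    cache: dict = {}
    for rec in dataset.records:
        info = SideInfo(
            age=rec.info.age if use_age else None,
            gender=rec.info.gender if use_gender else "unspecified",
        )
        key = (info.age_bucket, info.gender)
        if key not in cache:
            cache[key] = posterior_mixture(model, info, [])
        state = cache[key]
        total += posterior_log_likelihood(state, bark(rec.frequencies()), rec.values())
    return total / len(dataset)
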