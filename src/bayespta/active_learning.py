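"""Optimal stimulus selection by expected information gain (BALD).

The next tone is chosen to maximize the mutual information between the binary
response and the latent hearing threshold under the current mixture posterior.
Both entropy terms have closed forms (in bits): the marginal response entropy
is the binary entropy of the mixture predictive probability, and the expected
conditional entropy uses the squared-exponential approximation of the binary
entropy of a probit, which turns the Gaussian integral into an exact
convolution with constant ``K = sigma_p * sqrt(pi ln 2 / 2)``:

    I(y; t) ≈ h( sum_c pi_c Phi((h - mu_c)/sqrt(sigma_p^2 + sigma_c^2)) )
              - sum_c pi_c * K/sqrt(sigma_c^2 + K^2)
                          * exp(-(h - mu_c)^2 / (2 (sigma_c^2 + K^2))).

A cheaper variant first moment-matches the mixture to a single Gaussian per
frequency: the most informative frequency is then the one with the largest
posterior variance, and the best intensity is the posterior mean there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, xlogy

from .inference import PosteriorState, _component_marginals, posterior_threshold_estimate
from .psychoacoustics import STANDARD_FREQUENCIES_HZ, bark
from .response_model import Stimulus

__all__ = [
    "StimulusGrid",
    "bald_constant",
    "binary_entropy",
    "bald_objective",
    "select_stimulus",
    "select_stimulus_fast",
]


@dataclass(frozen=True)
class StimulusGrid:
    """Feasible stimuli: a frequency list (Hz) crossed with intensity levels (dB-HL)."""

    frequencies_hz: tuple
    intensities_db: tuple

    def __post_init__(self):
        if len(self.frequencies_hz) == 0 or len(self.intensities_db) == 0:
            raise ValueError("grid must be non-empty")
        for name, vals in (("frequencies_hz", self.frequencies_hz), ("intensities_db", self.intensities_db)):
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be sorted strictly ascending")

    @classmethod
    def default(cls) -> "StimulusGrid":
        """Standard 11 audiometric frequencies, -20..120 dB-HL in 5 dB steps."""
        return cls(
            frequencies_hz=tuple(STANDARD_FREQUENCIES_HZ),
            intensities_db=tuple(np.arange(-20.0, 125.0, 5.0)),
        )


def bald_constant(sigma_p: float) -> float:
    """K = sigma_p * sqrt(pi ln 2 / 2), the width of the entropy approximation."""
    return float(sigma_p) * float(np.sqrt(np.pi * np.log(2.0) / 2.0))


def binary_entropy(p) -> float:
    """Binary entropy in bits, with the convention 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability must lie in [0, 1]")
    out = -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / np.log(2.0)
    return out.item() if out.ndim == 0 else out


def _bald_terms(pi, mus, sigmas, sigma_p, intensities):
    """Objective matrix over (n_freq, n_int) from per-component marginals.

    pi: (C,); mus, sigmas: (C, n_freq); intensities: (n_int,).
    """
    h = np.asarray(intensities, dtype=float)[None, None, :]  # (1, 1, n_int)
    mu = mus[:, :, None]
    sig = sigmas[:, :, None]
    pred = np.sum(pi[:, None, None] * ndtr((h - mu) / np.sqrt(sigma_p**2 + sig**2)), axis=0)
    marginal_entropy = binary_entropy(np.clip(pred, 0.0, 1.0))
    K = bald_constant(sigma_p)
    s2 = sig**2 + K**2
    cond = np.sum(pi[:, None, None] * (K / np.sqrt(s2)) * np.exp(-((h - mu) ** 2) / (2 * s2)), axis=0)
    return marginal_entropy - cond


def bald_objective(state: PosteriorState, stimulus: Stimulus) -> float:
    """Expected information gain (bits) of one stimulus under the posterior."""
    mus, sigmas = _component_marginals(state, stimulus.x)
    surface = _bald_terms(state.pi, mus, sigmas, state.model.sigma_p, [stimulus.h])
    return float(surface[0, 0])


def _grid_surface(state: PosteriorState, grid: StimulusGrid) -> np.ndarray:
    xs = bark(np.asarray(grid.frequencies_hz, dtype=float))
    mus, sigmas = _component_marginals(state, xs)
    return _bald_terms(state.pi, mus, sigmas, state.model.sigma_p, grid.intensities_db)


def select_stimulus(state: PosteriorState, grid: StimulusGrid) -> tuple[float, float]:
    """Exhaustive BALD maximization over the grid.

    Returns (frequency_hz, intensity_db).  Exact ties resolve to the lowest
    frequency, then the lowest intensity.
    """
    surface = _grid_surface(state, grid)
    flat = int(np.argmax(surface))  # row-major: first max = lowest freq, then intensity
    i, j = np.unravel_index(flat, surface.shape)
    return float(grid.frequencies_hz[i]), float(grid.intensities_db[j])


def select_stimulus_fast(state: PosteriorState, grid: StimulusGrid) -> tuple[float, float]:
    """Moment-matched selection: max-variance frequency, posterior-mean intensity.

    The mixture posterior at each grid frequency is collapsed to a single
    Gaussian; the chosen frequency maximizes its variance (ties to the lowest
    frequency) and the intensity is the collapsed mean snapped to the nearest
    grid level (ties to the lower level).
    """
    xs = bark(np.asarray(grid.frequencies_hz, dtype=float))
    mean, sd, _, _ = posterior_threshold_estimate(state, xs)
    i = int(np.argmax(sd))
    levels = np.asarray(grid.intensities_db, dtype=float)
    j = int(np.argmin(np.abs(levels - mean[i])))
    return float(grid.frequencies_hz[i]), float(levels[j])
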