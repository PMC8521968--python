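"""Probit model of "audible"/"inaudible" responses to pure tones.

A subject is assumed to compare the stimulus intensity ``h`` (dB-HL) against
their true hearing threshold ``t(x)`` at the stimulus frequency, evaluated
under additive white Gaussian perceptual noise with standard deviation
``sigma_p``.  The response ``y`` is +1 ("audible") or -1 ("inaudible"), with

    P(y | h, t) = Phi(y * (h - t) / sigma_p),

where Phi is the standard normal CDF.  ``sigma_p`` is a single
frequency-independent scalar; the default of 5 dB matches the resolution at
which clinical audiograms are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "DEFAULT_SIGMA_P",
    "Stimulus",
    "Trial",
    "response_probability",
    "sample_response",
]

#: Default perceptual-noise standard deviation (dB).
DEFAULT_SIGMA_P = 5.0


@dataclass(frozen=True)
class Stimulus:
    """A pure tone: Bark-transformed frequency ``x`` and intensity ``h`` (dB-HL)."""

    x: float
    h: float


@dataclass(frozen=True)
class Trial:
    """One stimulus together with the binary response (+1 audible, -1 not)."""

    stimulus: Stimulus
    y: int

    def __post_init__(self):
        if self.y not in (-1, 1):
            raise ValueError(f"response must be -1 or +1, got {self.y!r}")


def _check_sigma_p(sigma_p: float) -> float:
    sigma_p = float(sigma_p)
    if not sigma_p > 0:
        raise ValueError(f"sigma_p must be positive, got {sigma_p}")
    return sigma_p


def response_probability(y, h, t_x, sigma_p: float = DEFAULT_SIGMA_P):
    """Probability of response ``y`` given intensity ``h`` and threshold ``t_x``.

    All of ``y``, ``h``, ``t_x`` broadcast; ``y`` must be in {-1, +1}.
    Returns ``Phi(y * (h - t_x) / sigma_p)``.
    """
    sigma_p = _check_sigma_p(sigma_p)
    y = np.asarray(y)
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("responses must be -1 or +1")
    out = norm.cdf(y * (np.asarray(h, dtype=float) - np.asarray(t_x, dtype=float)) / sigma_p)
    return out.item() if np.ndim(out) == 0 else out


def sample_response(
    stimulus: Stimulus,
    threshold_fn: Callable[[float], float],
    sigma_p: float,
    rng: np.random.Generator,
) -> int:
    """Draw a Bernoulli response to ``stimulus`` given a true threshold function.

    ``threshold_fn`` maps Bark frequency to dB-HL.  Returns +1 with probability
    ``Phi((h - t(x)) / sigma_p)``.  Reproducible given the generator state.
    """
    sigma_p = _check_sigma_p(sigma_p)
    t = float(threshold_fn(stimulus.x))
    if not np.isfinite(t):
        raise ValueError(f"threshold undefined (non-finite) at x={stimulus.x}")
    p_audible = norm.cdf((stimulus.h - t) / sigma_p)
    return 1 if rng.random() < p_audible else -1


def sample_trials(
    stimuli: Sequence[Stimulus],
    threshold_fn: Callable[[float], float],
    sigma_p: float,
    rng: np.random.Generator,
) -> list[Trial]:
    """Convenience: sample one response per stimulus, in order."""
    return [Trial(s, sample_response(s, threshold_fn, sigma_p, rng)) for s in stimuli]
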