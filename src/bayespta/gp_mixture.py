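"""Mixture-of-Gaussian-processes prior over hearing threshold curves.

The population of hearing thresholds is modeled as ``C`` independent Gaussian
processes over Bark-transformed frequency, each with a cubic-polynomial mean
and a squared-exponential kernel.  A categorical distribution over components,
with weights that may depend on side information (age, gender), selects which
GP generated a given subject's threshold:

    c ~ Categorical(alpha(I)),    t | c ~ GP(m_c, k_c).

Component weights for arbitrary side information are resolved through a
lookup table (:class:`AlphaTable`) built at learning time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .psychoacoustics import BARK_CENTER
from .response_model import DEFAULT_SIGMA_P

__all__ = [
    "SideInfo",
    "GPComponent",
    "GaussianDensity",
    "AlphaTable",
    "MixtureModel",
    "se_kernel",
    "component_prior_at",
    "mixing_weights",
    "sample_threshold",
    "AGE_BUCKET_YEARS",
]

#: Width of the age buckets (years) used as lookup keys for alpha(I).
AGE_BUCKET_YEARS = 5

GENDERS = ("unspecified", "female", "male")


@dataclass(frozen=True)
class SideInfo:
    """Optional subject annotations: age (0-120 or None) and gender."""

    age: Optional[int] = None
    gender: str = "unspecified"

    def __post_init__(self):
        if self.age is not None and not (0 <= int(self.age) <= 120):
            raise ValueError(f"age must be in [0, 120] or None, got {self.age}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")

    @property
    def age_bucket(self) -> Optional[int]:
        return None if self.age is None else int(self.age) // AGE_BUCKET_YEARS


class GaussianDensity(NamedTuple):
    """A finite-dimensional Gaussian: mean vector (dB-HL) and covariance (dB^2)."""

    mean: np.ndarray
    cov: np.ndarray


@dataclass(frozen=True)
class GPComponent:
    """One mixture component: cubic mean polynomial + squared-exponential kernel.

    The mean polynomial is evaluated in powers of the *centered* Bark frequency
    ``u = x - BARK_CENTER``: ``m(x) = a0 + a1*u + a2*u^2 + a3*u^3``.
    """

    mean_coeffs: tuple  # (a0, a1, a2, a3), dB-HL per Bark^k
    kernel_variance: float  # dB^2
    kernel_lengthscale: float  # Bark

    def __post_init__(self):
        if len(self.mean_coeffs) != 4:
            raise ValueError("mean_coeffs must have length 4 (cubic polynomial)")
        if not self.kernel_variance > 0:
            raise ValueError("kernel_variance must be positive")
        if not self.kernel_lengthscale > 0:
            raise ValueError("kernel_lengthscale must be positive")
        object.__setattr__(self, "mean_coeffs", tuple(float(a) for a in self.mean_coeffs))

    def mean(self, xs) -> np.ndarray:
        """Polynomial mean (dB-HL) at Bark frequencies ``xs``."""
        u = np.asarray(xs, dtype=float) - BARK_CENTER
        a0, a1, a2, a3 = self.mean_coeffs
        return a0 + u * (a1 + u * (a2 + u * a3))

    def cov(self, xs, ys=None) -> np.ndarray:
        """SE-kernel (cross-)covariance matrix between Bark frequency sets."""
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        ys = xs if ys is None else np.atleast_1d(np.asarray(ys, dtype=float))
        d = xs[:, None] - ys[None, :]
        return self.kernel_variance * np.exp(-0.5 * (d / self.kernel_lengthscale) ** 2)

    def to_dict(self) -> dict:
        return {
            "mean_coeffs": list(self.mean_coeffs),
            "kernel_variance": self.kernel_variance,
            "kernel_lengthscale": self.kernel_lengthscale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPComponent":
        return cls(tuple(d["mean_coeffs"]), float(d["kernel_variance"]), float(d["kernel_lengthscale"]))


def se_kernel(x1: float, x2: float, component: GPComponent) -> float:
    """Squared-exponential covariance ``v * exp(-(x1-x2)^2 / (2 l^2))``."""
    d = float(x1) - float(x2)
    return component.kernel_variance * float(
        np.exp(-0.5 * (d / component.kernel_lengthscale) ** 2)
    )


def component_prior_at(component: GPComponent, xs) -> GaussianDensity:
    """Finite-dimensional prior of one GP component at Bark frequencies ``xs``."""
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    if xs.size == 0:
        raise ValueError("xs must be non-empty")
    return GaussianDensity(component.mean(xs), component.cov(xs))


def _normalize_key_weights(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w < -1e-12) or not np.isclose(w.sum(), 1.0, atol=1e-10):
        raise ValueError("weight vector must be non-negative and sum to 1")
    return np.clip(w, 0.0, None) / w.sum()


@dataclass
class AlphaTable:
    """Side-information-conditioned mixing weights, resolved by nearest neighbor.

    Stored entries are keyed by (5-year age bucket, gender).  Queries resolve:

    * both age and gender specified -> nearest stored key, with distance
      ``|bucket difference| + 1000 * (gender mismatch)``;
    * only age -> nearest bucket in the age-marginal table;
    * only gender -> gender-marginal entry;
    * neither -> the unconditional (population-marginal) weights.

    Marginal tables are responsibility averages over the corresponding strata
    of the training data; the unconditional vector is the mixture's own
    marginal weights.
    """

    n_components: int
    unconditional: np.ndarray
    entries: dict = field(default_factory=dict)  # (bucket, gender) -> weights
    age_marginal: dict = field(default_factory=dict)  # bucket -> weights
    gender_marginal: dict = field(default_factory=dict)  # gender -> weights

    def __post_init__(self):
        self.unconditional = _normalize_key_weights(self.unconditional)
        if self.unconditional.size != self.n_components:
            raise ValueError("unconditional weights length must equal n_components")
        self.entries = {k: _normalize_key_weights(v) for k, v in self.entries.items()}
        self.age_marginal = {k: _normalize_key_weights(v) for k, v in self.age_marginal.items()}
        self.gender_marginal = {
            k: _normalize_key_weights(v) for k, v in self.gender_marginal.items()
        }

    @classmethod
    def constant(cls, weights) -> "AlphaTable":
        """A table that returns the same weights for every query."""
        w = np.asarray(weights, dtype=float)
        return cls(n_components=w.size, unconditional=w)

    def lookup(self, info: SideInfo) -> np.ndarray:
        b, g = info.age_bucket, info.gender
        if b is None and g == "unspecified":
            return self.unconditional.copy()
        if b is not None and g != "unspecified" and self.entries:
            key = min(
                sorted(self.entries),
                key=lambda k: abs(k[0] - b) + (0 if k[1] == g else 1000),
            )
            return self.entries[key].copy()
        if b is not None and self.age_marginal:
            key = min(sorted(self.age_marginal), key=lambda k: abs(k - b))
            return self.age_marginal[key].copy()
        if g != "unspecified" and g in self.gender_marginal:
            return self.gender_marginal[g].copy()
        return self.unconditional.copy()

    # -- serialization -------------------------------------------------------

    @staticmethod
    def _key_str(key) -> str:
        return f"{key[0]}|{key[1]}"

    @staticmethod
    def _key_from_str(s: str):
        bucket, gender = s.split("|")
        return (int(bucket), gender)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "unconditional": self.unconditional.tolist(),
            "entries": {self._key_str(k): v.tolist() for k, v in self.entries.items()},
            "age_marginal": {str(k): v.tolist() for k, v in self.age_marginal.items()},
            "gender_marginal": {k: v.tolist() for k, v in self.gender_marginal.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlphaTable":
        return cls(
            n_components=int(d["n_components"]),
            unconditional=np.asarray(d["unconditional"], dtype=float),
            entries={cls._key_from_str(k): np.asarray(v, float) for k, v in d["entries"].items()},
            age_marginal={int(k): np.asarray(v, float) for k, v in d["age_marginal"].items()},
            gender_marginal={k: np.asarray(v, float) for k, v in d["gender_marginal"].items()},
        )


@dataclass
class MixtureModel:
    """The full prior: C GP components, an alpha table, and perceptual noise."""

    components: list  # list[GPComponent]
    alpha: AlphaTable
    sigma_p: float = DEFAULT_SIGMA_P

    def __post_init__(self):
        if len(self.components) < 1:
            raise ValueError("need at least one component")
        if self.alpha.n_components != len(self.components):
            raise ValueError("alpha table size does not match component count")
        if not self.sigma_p > 0:
            raise ValueError("sigma_p must be positive")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "bayespta-model",
                "version": 1,
                "sigma_p": self.sigma_p,
                "components": [c.to_dict() for c in self.components],
                "alpha": self.alpha.to_dict(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        d = json.loads(text)
        return cls(
            components=[GPComponent.from_dict(c) for c in d["components"]],
            alpha=AlphaTable.from_dict(d["alpha"]),
            sigma_p=float(d["sigma_p"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "MixtureModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def mixing_weights(model: MixtureModel, info: SideInfo) -> np.ndarray:
    """Prior component weights alpha(I) for the given side information."""
    w = model.alpha.lookup(info)
    return w / w.sum()


def sample_threshold(
    model: MixtureModel,
    info: SideInfo,
    xs: Sequence[float],
    rng: np.random.Generator,
):
    """Draw (component index, threshold values at ``xs``) from the generative model."""
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    if xs.size == 0:
        raise ValueError("xs must be non-empty")
    w = mixing_weights(model, info)
    c = int(rng.choice(model.n_components, p=w))
    mean, cov = component_prior_at(model.components[c], xs)
    jitter = 1e-8 * model.components[c].kernel_variance
    L = np.linalg.cholesky(cov + jitter * np.eye(xs.size))
    values = mean + L @ rng.standard_normal(xs.size)
    return c, values
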