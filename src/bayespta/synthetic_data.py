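"""Synthetic annotated-audiogram populations for testing and simulation.

Real clinical audiogram collections are rarely shareable, so this module
generates datasets with the same statistical structure: thresholds quantized
to 5 dB on the 11 standard audiometric frequencies, drawn from a small set of
archetypal threshold-shape prototypes (flat mild loss, high-frequency sloping
"old-age" loss, mid-frequency "cookie-bite" loss) whose mixing probabilities
depend on age and gender.  Each generated record carries its latent truth
(component index, pre-quantization curve) separately from the public dataset,
so recovery tests never leak it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gp_mixture import AGE_BUCKET_YEARS, AlphaTable, GPComponent, MixtureModel, SideInfo
from .learning import AudiogramDataset, AudiogramRecord
from .psychoacoustics import BARK_CENTER, STANDARD_FREQUENCIES_HZ, bark
from .response_model import DEFAULT_SIGMA_P

__all__ = [
    "PopulationSpec",
    "GroundTruthRecord",
    "default_population",
    "generate_dataset",
    "missingness_mask",
]

#: Frequencies never blanked by :func:`missingness_mask`, guaranteeing that
#: every record keeps at least 4 defined thresholds.
ANCHOR_FREQUENCIES_HZ = (250.0, 1000.0, 4000.0, 8000.0)


@dataclass
class PopulationSpec:
    """A generative population: named prototypes + demographic mixing rules."""

    prototypes: list  # list[(name, GPComponent)]
    alpha_rule: dict  # (age_bucket, gender) -> weight vector
    age_distribution: dict  # age_bucket -> probability
    gender_distribution: dict  # gender -> probability
    quantization_step: float = 5.0

    def __post_init__(self):
        C = len(self.prototypes)
        for key, w in self.alpha_rule.items():
            w = np.asarray(w, dtype=float)
            if w.size != C or np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-10):
                raise ValueError(f"alpha_rule[{key}] is not a length-{C} simplex vector")
            self.alpha_rule[key] = w
        for name, dist in (("age", self.age_distribution), ("gender", self.gender_distribution)):
            total = sum(dist.values())
            if not np.isclose(total, 1.0, atol=1e-10):
                raise ValueError(f"{name}_distribution must sum to 1, got {total}")
        if not self.quantization_step > 0:
            raise ValueError("quantization_step must be positive")

    @property
    def n_components(self) -> int:
        return len(self.prototypes)

    def weights_for(self, info: SideInfo) -> np.ndarray:
        key = (info.age_bucket, info.gender)
        if key not in self.alpha_rule:
            raise KeyError(f"alpha_rule has no entry for {key}")
        return self.alpha_rule[key]

    def marginal_weights(self) -> np.ndarray:
        """Population-level component weights, averaging alpha over demographics."""
        w = np.zeros(self.n_components)
        for b, pb in self.age_distribution.items():
            for g, pg in self.gender_distribution.items():
                w += pb * pg * self.alpha_rule[(b, g)]
        return w / w.sum()

    def prior_model(self, sigma_p: float = DEFAULT_SIGMA_P) -> MixtureModel:
        """The population's own GP mixture (exact alpha table), e.g. for oracle runs."""
        entries = {k: v for k, v in self.alpha_rule.items()}
        age_marg: dict = {}
        for b, pb in self.age_distribution.items():
            acc = np.zeros(self.n_components)
            for g, pg in self.gender_distribution.items():
                acc += pg * self.alpha_rule[(b, g)]
            age_marg[b] = acc / acc.sum()
        gender_marg: dict = {}
        for g in self.gender_distribution:
            acc = np.zeros(self.n_components)
            for b, pb in self.age_distribution.items():
                acc += pb * self.alpha_rule[(b, g)]
            gender_marg[g] = acc / acc.sum()
        alpha = AlphaTable(
            n_components=self.n_components,
            unconditional=self.marginal_weights(),
            entries=entries,
            age_marginal=age_marg,
            gender_marginal=gender_marg,
        )
        return MixtureModel(
            components=[c for _, c in self.prototypes], alpha=alpha, sigma_p=sigma_p
        )

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "prototypes": [[name, c.to_dict()] for name, c in self.prototypes],
            "alpha_rule": {f"{b}|{g}": w.tolist() for (b, g), w in self.alpha_rule.items()},
            "age_distribution": {str(b): p for b, p in self.age_distribution.items()},
            "gender_distribution": dict(self.gender_distribution),
            "quantization_step": self.quantization_step,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        alpha_rule = {}
        for key, w in d["alpha_rule"].items():
            b, g = key.split("|")
            alpha_rule[(int(b), g)] = np.asarray(w, dtype=float)
        return cls(
            prototypes=[(name, GPComponent.from_dict(c)) for name, c in d["prototypes"]],
            alpha_rule=alpha_rule,
            age_distribution={int(b): float(p) for b, p in d["age_distribution"].items()},
            gender_distribution={g: float(p) for g, p in d["gender_distribution"].items()},
            quantization_step=float(d["quantization_step"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class GroundTruthRecord:
    """Latent truth for one generated audiogram (kept out of the public CSV)."""

    info: SideInfo
    true_component: int
    true_continuous_threshold: np.ndarray  # dB-HL on the standard grid


def _sloping_coeffs() -> tuple:
    # linear in Bark from 20 dB at 125 Hz to 70 dB at 8 kHz
    x_lo, x_hi = bark(125.0), bark(8000.0)
    slope = (70.0 - 20.0) / (x_hi - x_lo)
    a0 = 20.0 + slope * (BARK_CENTER - x_lo)
    return (a0, slope, 0.0, 0.0)


def _cookie_bite_coeffs() -> tuple:
    # quadratic bump peaking at ~50 dB near 1-2 kHz (0.9 Bark below grid center)
    peak, curvature, offset = 50.0, 0.5, -0.9
    return (peak - curvature * offset**2, 2 * curvature * offset, -curvature, 0.0)


def default_population(seed: Optional[int] = None) -> PopulationSpec:
    """The default three-prototype population.

    Prototypes: flat mild loss (20 dB), high-frequency sloping loss (20 -> 70
    dB across the grid), and a mid-frequency cookie-bite (peaking ~50 dB).
    The sloping prototype's weight increases with age (0.05 + 0.008/year,
    capped at 0.85), men get a further +0.05 at the expense of the flat
    prototype, and the cookie-bite holds a constant 0.15 share.  Ages follow a
    clinic-like distribution centered on the late 60s; genders are balanced.

    Deterministic; ``seed`` is accepted for interface uniformity.
    """
    prototypes = [
        ("flat-mild", GPComponent((20.0, 0.0, 0.0, 0.0), 64.0, 6.0)),
        ("sloping-old-age", GPComponent(_sloping_coeffs(), 100.0, 4.0)),
        ("cookie-bite", GPComponent(_cookie_bite_coeffs(), 64.0, 3.0)),
    ]
    buckets = range(0, 121 // AGE_BUCKET_YEARS + 1)  # 5-year buckets, ages 0-120
    alpha_rule = {}
    for b in buckets:
        age_mid = b * AGE_BUCKET_YEARS + AGE_BUCKET_YEARS / 2
        sloping = min(0.85, 0.05 + 0.008 * age_mid)
        for g in ("female", "male"):
            s = min(0.85, sloping + (0.05 if g == "male" else 0.0))
            cookie = 0.15
            flat = 1.0 - s - cookie
            alpha_rule[(b, g)] = np.array([flat, s, cookie])
    mids = np.array([b * AGE_BUCKET_YEARS + AGE_BUCKET_YEARS / 2 for b in buckets])
    age_w = np.exp(-(((mids - 65.0) / 25.0) ** 2))
    age_w /= age_w.sum()
    return PopulationSpec(
        prototypes=prototypes,
        alpha_rule=alpha_rule,
        age_distribution={b: float(p) for b, p in zip(buckets, age_w)},
        gender_distribution={"female": 0.5, "male": 0.5},
        quantization_step=5.0,
    )


def _quantize(values: np.ndarray, step: float) -> np.ndarray:
    """Round to the nearest multiple of ``step``, halves away from zero."""
    scaled = values / step
    return step * np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)


def generate_dataset(
    spec: PopulationSpec, n: int, rng: np.random.Generator
) -> tuple[AudiogramDataset, list]:
    """Draw ``n`` annotated audiograms from the population.

    Per record: sample (age bucket, gender), pick a prototype from the
    corresponding alpha weights, draw the threshold curve from that GP on the
    standard grid, and quantize.  Returns the public dataset and the parallel
    ground-truth list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grid_bark = bark(STANDARD_FREQUENCIES_HZ)
    buckets = sorted(spec.age_distribution)
    bucket_p = np.array([spec.age_distribution[b] for b in buckets])
    genders = sorted(spec.gender_distribution)
    gender_p = np.array([spec.gender_distribution[g] for g in genders])

    chols = {}
    for ci, (_, comp) in enumerate(spec.prototypes):
        cov = comp.cov(grid_bark) + 1e-8 * comp.kernel_variance * np.eye(grid_bark.size)
        chols[ci] = (comp.mean(grid_bark), np.linalg.cholesky(cov))

    records, truths = [], []
    for _ in range(n):
        b = buckets[int(rng.choice(len(buckets), p=bucket_p))]
        g = genders[int(rng.choice(len(genders), p=gender_p))]
        age = int(
            min(120, b * AGE_BUCKET_YEARS + rng.integers(AGE_BUCKET_YEARS))
        )
        info = SideInfo(age=age, gender=g)
        w = spec.weights_for(info)
        c = int(rng.choice(spec.n_components, p=w))
        mean, L = chols[c]
        continuous = mean + L @ rng.standard_normal(grid_bark.size)
        quantized = _quantize(continuous, spec.quantization_step)
        records.append(
            AudiogramRecord(
                thresholds={float(f): float(t) for f, t in zip(STANDARD_FREQUENCIES_HZ, quantized)},
                info=info,
            )
        )
        truths.append(GroundTruthRecord(info=info, true_component=c, true_continuous_threshold=continuous))
    return AudiogramDataset(records), truths


def missingness_mask(
    dataset: AudiogramDataset, fraction: float, rng: np.random.Generator
) -> AudiogramDataset:
    """Independently blank non-anchor thresholds with probability ``fraction``.

    The anchor frequencies (250, 1000, 4000, 8000 Hz) are never blanked, so
    every record keeps at least 4 defined thresholds.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    anchors = set(ANCHOR_FREQUENCIES_HZ)
    out = []
    for rec in dataset.records:
        kept = {
            f: t
            for f, t in rec.thresholds.items()
            if f in anchors or rng.random() >= fraction
        }
        out.append(AudiogramRecord(thresholds=kept, info=rec.info))
    return AudiogramDataset(out)
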