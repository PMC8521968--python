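"""Simulated adaptive pure-tone audiometry sessions and experiments.

A session targets one audiogram: the tabulated thresholds are linearly
interpolated in Hz to a continuous "true" threshold, and the active-learning
loop repeatedly selects a stimulus, samples the subject's probit response
against that true threshold, and refits the mixture posterior.  The tracked
error is the mean absolute difference between the posterior mean threshold and
the true threshold over the 11 standard audiometric frequencies, recorded
before the first trial and after every response.

The experiment harness crosses models, side-information usage, and selection
strategies over a set of audiograms and summarizes error-versus-trial curves
with means and quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .active_learning import StimulusGrid, select_stimulus, select_stimulus_fast
from .gp_mixture import MixtureModel, SideInfo
from .inference import PosteriorState, posterior_mixture, posterior_threshold_estimate
from .learning import AudiogramRecord
from .psychoacoustics import STANDARD_FREQUENCIES_HZ, bark, bark_inverse
from .response_model import Stimulus, Trial, sample_response

__all__ = [
    "SimulationTrace",
    "ExperimentResult",
    "interpolate_threshold",
    "run_pta_simulation",
    "mean_absolute_error",
    "run_experiment",
]

SELECTORS = ("full", "fast", "random")


def interpolate_threshold(thresholds: dict) -> Callable:
    """Piecewise-linear (in Hz) interpolant of tabulated thresholds.

    Constant extrapolation beyond the outermost defined frequencies.  Accepts
    scalar or array frequency input in Hz.
    """
    if len(thresholds) < 2:
        raise ValueError("need at least 2 defined frequencies to interpolate")
    freqs = np.array(sorted(thresholds), dtype=float)
    vals = np.array([thresholds[f] for f in sorted(thresholds)], dtype=float)

    def target(f_hz):
        out = np.interp(np.asarray(f_hz, dtype=float), freqs, vals)
        return out.item() if out.ndim == 0 else out

    return target


def mean_absolute_error(estimate, target, frequencies_hz=None) -> float:
    """Mean absolute difference (dB) between two threshold curves on a grid.

    ``estimate`` may be an array on the grid or a callable of Hz; likewise
    ``target``.  Defaults to the standard 11-frequency grid.
    """
    F = np.asarray(
        STANDARD_FREQUENCIES_HZ if frequencies_hz is None else frequencies_hz, dtype=float
    )
    est = np.asarray(estimate(F) if callable(estimate) else estimate, dtype=float)
    tgt = np.asarray(target(F) if callable(target) else target, dtype=float)
    if est.shape != tgt.shape:
        raise ValueError("estimate and target must match the grid shape")
    return float(np.mean(np.abs(est - tgt)))


@dataclass
class SimulationTrace:
    """Record of one simulated session."""

    target: Callable  # Hz -> dB-HL
    info: SideInfo
    trials: list  # list[Trial], in presentation order
    errors: np.ndarray  # (n_trials + 1,), dB; errors[0] is the prior estimate
    pi_history: np.ndarray  # (n_trials + 1, C)
    final_state: PosteriorState


def run_pta_simulation(
    model: MixtureModel,
    audiogram,
    info: Optional[SideInfo],
    n_trials: int,
    grid: Optional[StimulusGrid] = None,
    rng: Optional[np.random.Generator] = None,
    selector: str = "full",
    true_sigma_p: Optional[float] = None,
) -> SimulationTrace:
    """Run one adaptive audiometry session against a target audiogram.

    ``audiogram`` is an :class:`AudiogramRecord` or a {Hz: dB} mapping.  The
    simulated subject responds with the model's sigma_p unless
    ``true_sigma_p`` overrides it.  ``selector`` is "full" (exhaustive BALD
    grid search), "fast" (moment-matched), or "random" (uniform baseline).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if selector not in SELECTORS:
        raise ValueError(f"selector must be one of {SELECTORS}")
    grid = grid or StimulusGrid.default()
    rng = rng if rng is not None else np.random.default_rng()
    if isinstance(audiogram, AudiogramRecord):
        thresholds = audiogram.thresholds
    else:
        thresholds = dict(audiogram)
    info = info if info is not None else SideInfo()
    target = interpolate_threshold(thresholds)
    sigma_sim = float(true_sigma_p) if true_sigma_p is not None else model.sigma_p
    grid_bark = bark(STANDARD_FREQUENCIES_HZ)
    target_on_grid = np.asarray(target(STANDARD_FREQUENCIES_HZ), dtype=float)

    def record(state):
        mean, _, _, _ = posterior_threshold_estimate(state, grid_bark)
        return mean_absolute_error(mean, target_on_grid), state.pi.copy()

    trials: list[Trial] = []
    state = posterior_mixture(model, info, trials)
    err0, pi0 = record(state)
    errors, pis = [err0], [pi0]
    for _ in range(n_trials):
        if selector == "full":
            f_hz, h = select_stimulus(state, grid)
        elif selector == "fast":
            f_hz, h = select_stimulus_fast(state, grid)
        else:
            f_hz = float(rng.choice(grid.frequencies_hz))
            h = float(rng.choice(grid.intensities_db))
        stim = Stimulus(x=bark(f_hz), h=h)
        y = sample_response(stim, lambda x: target(bark_inverse(x)), sigma_sim, rng)
        trials.append(Trial(stim, y))
        state = posterior_mixture(model, info, trials)
        err, pi = record(state)
        errors.append(err)
        pis.append(pi)
    return SimulationTrace(
        target=target,
        info=info,
        trials=trials,
        errors=np.asarray(errors),
        pi_history=np.vstack(pis),
        final_state=state,
    )


@dataclass
class ExperimentResult:
    """Per-run error trajectories and their per-step summaries."""

    runs: pd.DataFrame  # columns: model, selector, side_info, audiogram, step, abs_error

    def summary(self) -> pd.DataFrame:
        """Mean and first/third quartiles of the error at each step per condition."""
        g = self.runs.groupby(["model", "selector", "side_info", "step"])["abs_error"]
        out = g.agg(mean="mean", q1=lambda s: s.quantile(0.25), median="median",
                    q3=lambda s: s.quantile(0.75)).reset_index()
        return out

    def save(self, path) -> None:
        self.runs.to_csv(path, index=False)


def run_experiment(
    models: dict,
    audiograms: Sequence,
    n_trials: int,
    rng: np.random.Generator,
    selectors: Sequence[str] = ("full",),
    side_info_modes: Sequence[str] = ("none",),
    grid: Optional[StimulusGrid] = None,
    true_sigma_p: Optional[float] = None,
) -> ExperimentResult:
    """Cross models x selectors x side-info usage over a list of audiograms.

    ``models`` maps names to :class:`MixtureModel`; ``side_info_modes`` entries
    are "none", "age", "gender", or "both".  All conditions for a given
    audiogram share a per-audiogram seed, so comparisons are paired.
    """
    grid = grid or StimulusGrid.default()
    rows = []
    seeds = rng.integers(2**31 - 1, size=len(audiograms))
    for a_idx, rec in enumerate(audiograms):
        base_info = rec.info if isinstance(rec, AudiogramRecord) else SideInfo()
        for model_name, model in models.items():
            for selector in selectors:
                for mode in side_info_modes:
                    info = SideInfo(
                        age=base_info.age if mode in ("age", "both") else None,
                        gender=base_info.gender if mode in ("gender", "both") else "unspecified",
                    )
                    trace = run_pta_simulation(
                        model,
                        rec,
                        info,
                        n_trials,
                        grid=grid,
                        rng=np.random.default_rng(seeds[a_idx]),
                        selector=selector,
                        true_sigma_p=true_sigma_p,
                    )
                    for step, err in enumerate(trace.errors):
                        rows.append(
                            {
                                "model": model_name,
                                "selector": selector,
                                "side_info": mode,
                                "audiogram": a_idx,
                                "step": step,
                                "abs_error": err,
                            }
                        )
    return ExperimentResult(runs=pd.DataFrame(rows))


def plot_experiment(result: ExperimentResult, ax=None):
    """Optional error-vs-responses plot (mean line, quartile band) per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (model, selector, side), df in result.summary().groupby(
        ["model", "selector", "side_info"]
    ):
        label = f"{model}/{selector}/{side}"
        ax.plot(df["step"], df["mean"], label=label)
        ax.fill_between(df["step"], df["q1"], df["q3"], alpha=0.2)
    ax.set_xlabel("number of responses")
    ax.set_ylabel("mean absolute HT error (dB)")
    ax.legend(fontsize="small")
    return ax
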