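"""Synthetic RD29A::LUC luminescence data with known ground truth.

Reporter-plant luminescence rises from near baseline after ABA exposure,
peaks a few hours in, declines thereafter, and saturates with dose over the
0-200 uM range.  The default generator emulates exactly that shape with a
log-normal pulse times a Michaelis/Hill dose amplitude — deliberately *not*
the ODE model, so that calibrating the model against these data is not a
circular exercise.  A second constructor, :func:`from_model`, wraps the
simulator's own RD29A trace in the same replicate-noise model for
parameter-recovery experiments.

Noise is multiplicative log-normal (luminescence is positive and its
scatter grows with signal), mean-preserving at a given coefficient of
variation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import RD29A_MRNA, ModelDefinition
from .simulate import run_aba_protocol

__all__ = ["LuminescenceDataset", "generate_luminescence", "from_model",
           "generate_dose_series"]


@dataclass
class LuminescenceDataset:
    """Replicate luminescence time courses at one ABA dose.

    ``values`` has one row per replicate (relative luminescence units);
    ``truth`` records every generator parameter so recovery experiments can
    score themselves.
    """

    times: np.ndarray          # h after ABA exposure
    dose: float                # uM ABA
    values: np.ndarray         # (n_replicates, n_times), RLU > 0
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.times):
            raise ValueError("values/time grid mismatch")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one replicate")
        if np.any(self.values <= 0):
            raise ValueError("luminescence values must be positive")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    def mean_curve(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def sem_curve(self) -> np.ndarray:
        n = self.n_replicates
        return self.values.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 \
            else np.zeros_like(self.times)

    def at_time(self, t: float) -> np.ndarray:
        """Per-replicate values at time t; t must lie on the grid."""
        hits = np.flatnonzero(np.isclose(self.times, t))
        if len(hits) == 0:
            raise ValueError(f"sample time {t} h is not on the time grid")
        return self.values[:, hits[0]]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        rows = [
            {"time_h": t, "dose_uM": self.dose, "replicate": r + 1,
             "rlu": self.values[r, i]}
            for r in range(self.n_replicates)
            for i, t in enumerate(self.times)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(self.truth, indent=2, default=float))


def _pulse(times: np.ndarray, peak_time: float, shape_width: float) -> np.ndarray:
    """Unimodal log-normal-shaped pulse with its mode exactly at peak_time."""
    g = np.zeros_like(times, dtype=float)
    pos = times > 0
    g[pos] = np.exp(-0.5 * (np.log(times[pos] / peak_time) / shape_width) ** 2)
    return g


def _amplitude(dose: float, amplitude_max: float, dose_K: float,
               dose_hill: float) -> float:
    if dose == 0:
        return 0.0
    dh = dose ** dose_hill
    return amplitude_max * dh / (dose_K ** dose_hill + dh)


def _apply_noise(mean: np.ndarray, noise_cv: float, n_reps: int,
                 rng: np.random.Generator) -> np.ndarray:
    if noise_cv == 0:
        return np.tile(mean, (n_reps, 1))
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    factors = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                            size=(n_reps, len(mean)))
    return mean[None, :] * factors


def generate_luminescence(
    dose: float,
    peak_time: float = 5.0,
    n_reps: int = 3,
    noise_cv: float = 0.1,
    seed: int | None = 0,
    times: np.ndarray | None = None,
    shape_width: float = 0.6,
    dose_K: float = 75.0,
    dose_hill: float = 1.0,
    amplitude_max: float = 1000.0,
    baseline: float = 20.0,
) -> LuminescenceDataset:
    """Phenomenological reporter dataset: baseline + A(dose) * pulse(t) + noise.

    Defaults reflect the reporter experiments being emulated: a pulse
    peaking at 5 h, three replicates, ~10% replicate scatter, and a
    saturating dose amplitude (half-max 75 uM, so near-saturation at
    200 uM).  Deterministic under a fixed seed.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if times is None:
        times = np.arange(0.0, 24.0 + 1e-9, 0.25)
    times = np.asarray(times, dtype=float)

    mean = baseline + _amplitude(dose, amplitude_max, dose_K, dose_hill) \
        * _pulse(times, peak_time, shape_width)
    rng = np.random.default_rng(seed)
    values = _apply_noise(mean, noise_cv, n_reps, rng)
    truth = {
        "mode": "phenomenological", "dose": dose, "peak_time": peak_time,
        "shape_width": shape_width, "dose_K": dose_K, "dose_hill": dose_hill,
        "amplitude_max": amplitude_max, "baseline": baseline,
        "noise_cv": noise_cv, "n_reps": n_reps, "seed": seed,
    }
    return LuminescenceDataset(times, float(dose), values, truth)


def from_model(
    model: ModelDefinition,
    dose: float = 100.0,
    n_reps: int = 3,
    noise_cv: float = 0.1,
    seed: int | None = 0,
    times: np.ndarray | None = None,
    amplitude_max: float = 1000.0,
    baseline: float = 0.0,
    **protocol_kwargs,
) -> LuminescenceDataset:
    """Model-generated dataset: the simulated RD29A trace in RLU plus noise.

    The trace is rescaled so its maximum maps to `amplitude_max` RLU (the
    absolute luminescence scale is arbitrary); replicate noise is identical
    to the phenomenological generator's.
    """
    if times is None:
        times = np.arange(0.0, 24.0 + 1e-9, 0.25)
    times = np.asarray(times, dtype=float)
    traj = run_aba_protocol(model, dose, **protocol_kwargs)
    y = np.interp(times, traj.times, traj[RD29A_MRNA])
    if y.max() <= 0:
        raise ValueError("model trace is identically zero; nothing to emulate")
    mean = baseline + amplitude_max * y / y.max()
    rng = np.random.default_rng(seed)
    values = _apply_noise(np.maximum(mean, 1e-12), noise_cv, n_reps, rng)
    truth = {
        "mode": "from_model", "dose": dose, "noise_cv": noise_cv,
        "n_reps": n_reps, "seed": seed, "amplitude_max": amplitude_max,
        "baseline": baseline,
        "parameters": {p: model.parameters.value(p)
                       for p in ("kf26", "kf27", "kf28")},
    }
    return LuminescenceDataset(times, float(dose), values, truth)


def generate_dose_series(
    doses: Sequence[float],
    sample_time: float = 5.0,
    seed: int | None = 0,
    **generator_kwargs,
) -> pd.DataFrame:
    """Mean and SEM luminescence per dose, read at one sampling time.

    Mimics reading each reporter plant once, a fixed delay after spraying:
    one dataset per dose (independent sub-seeds derived from `seed`), all
    replicates evaluated at `sample_time`.
    """
    doses = list(doses)
    if not doses:
        raise ValueError("dose list must not be empty")
    root = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        sub = int(root.integers(0, 2 ** 31 - 1))
        ds = generate_luminescence(dose, seed=sub, **generator_kwargs)
        reps = ds.at_time(sample_time)
        sem = reps.std(ddof=1) / np.sqrt(len(reps)) if len(reps) > 1 else 0.0
        rows.append({"dose_uM": float(dose), "mean_rlu": reps.mean(),
                     "sem_rlu": float(sem), "n": len(reps)})
    return pd.DataFrame(rows)
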