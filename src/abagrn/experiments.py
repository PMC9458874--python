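"""In-silico experiment battery: peaks, dose-response, genetics, sensitivity.

The readout for every experiment is the accumulated *RD29A* message
(species ``RD29A_mRNA``).  Gene knockouts mimic null mutants by silencing a
gene's translation channels; feedback ablations remove only the ABRE-driven
transcription channel of one feedback gene, leaving constitutive expression
untouched.  Local sensitivity is the time-integrated absolute logarithmic
gain of the RD29A trace with respect to each rate constant, computed by
central finite differences of full protocol runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network import RD29A_MRNA, ModelDefinition
from .simulate import Trajectory, equilibrate, run_aba_protocol

__all__ = [
    "PeakSummary",
    "peak_metrics",
    "dose_response",
    "DEFAULT_DOSES",
    "knockout",
    "feedback_ablation",
    "fold_change",
    "local_sensitivity",
    "SENSITIVITY_PARAMS",
    "KNOCKOUT_TARGETS",
]

#: ABA doses (uM) of the standard dose-response scan
DEFAULT_DOSES = (0.0, 1.0, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0)

#: genes whose null mutants have been characterized in planta
KNOCKOUT_TARGETS = ("PYR", "PP2C", "SnRK2", "ABF")

#: the fourteen binding / catalytic / turnover constants scanned for
#: sensitivity: dissociation constants of every signalling complex, the
#: DNA-binding constants (feedback ABREs kr10, RD29A ABRE kr14, RD29A DRE
#: kr11), DREB2A-proteasome dissociation (kr16), the two phosphocycle
#: catalytic rates (kf15, kf17) and one protein-turnover rate (kf21)
SENSITIVITY_PARAMS = (
    "kr1", "kr2", "kr3", "kr4", "kr5", "kr7", "kr9",
    "kr10", "kr11", "kr14", "kr16", "kf15", "kf17", "kf21",
)


@dataclass(frozen=True)
class PeakSummary:
    """Shape summary of one species' post-step time course."""

    species: str
    peak_value: float   # uM
    peak_time: float    # h after the ABA step
    value_at_5h: float  # uM
    value_at_24h: float
    decline_ratio: float  # value_at_24h / peak_value; nan for an all-zero trace


def peak_metrics(traj: Trajectory, species: str = RD29A_MRNA) -> PeakSummary:
    """Locate the maximum of a trace on the reporting grid plus fixed readouts."""
    y = traj[species]  # raises KeyError for unknown species
    i = int(np.argmax(y))
    peak = float(y[i])
    v5 = traj.at_time(species, 5.0)
    v24 = traj.at_time(species, 24.0)
    ratio = v24 / peak if peak > 0 else float("nan")
    return PeakSummary(species, peak, float(traj.times[i]), v5, v24, ratio)


def dose_response(
    model: ModelDefinition,
    doses: Sequence[float] = DEFAULT_DOSES,
    species: str = RD29A_MRNA,
    **protocol_kwargs,
) -> pd.DataFrame:
    """Run the full step protocol once per ABA dose and summarize the readout.

    All doses share a single pre-stimulus equilibration (the protocol's
    ABA = 0 phase does not depend on the dose).  The returned frame carries
    a ``monotone_nondecreasing`` flag in ``.attrs``.
    """
    doses = sorted(set(float(d) for d in doses))
    if not doses:
        raise ValueError("dose list must not be empty")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be non-negative")
    pre = equilibrate(model).state
    rows = []
    for dose in doses:
        traj = run_aba_protocol(model, dose, pre_state=pre, **protocol_kwargs)
        pk = peak_metrics(traj, species)
        rows.append({"dose_uM": dose, "peak_value": pk.peak_value,
                     "peak_time": pk.peak_time, "value_at_5h": pk.value_at_5h,
                     "value_at_24h": pk.value_at_24h,
                     "decline_ratio": pk.decline_ratio})
    table = pd.DataFrame(rows)
    table.attrs["species"] = species
    table.attrs["monotone_nondecreasing"] = bool(
        np.all(np.diff(table["peak_value"].to_numpy()) >= 0))
    return table


def knockout(model: ModelDefinition, target: str) -> ModelDefinition:
    """Null-mutant model: silence the target's translation channels.

    The constitutive channel (rate kf30) is silenced for every target; for
    ABF and PP2C — the targets that also carry an ABRE feedback channel
    translated at kf28 — that channel is silenced too.  (DREB2A null mutants
    were not part of the in-planta validation set and are not offered.)
    """
    if target not in KNOCKOUT_TARGETS:
        raise KeyError(f"unknown knockout target {target!r}; "
                       f"choose from {KNOCKOUT_TARGETS}")
    disabled = [f"translate_{target}_const"]
    if target in ("ABF", "PP2C"):
        disabled.append(f"translate_{target}_fb")
    return model.with_disabled(disabled)


def feedback_ablation(model: ModelDefinition, gene: str) -> ModelDefinition:
    """Remove one gene's ABRE-driven transcription; constitutive channel stays."""
    if gene not in ("ABF", "DREB2A", "PP2C"):
        raise KeyError(f"unknown feedback gene {gene!r}")
    return model.with_disabled([f"transcribe_{gene}_fb"])


def fold_change(traj_a: Trajectory, traj_b: Trajectory,
                species: str = RD29A_MRNA) -> float:
    """Ratio of peak values, peak(a)/peak(b)."""
    pa = peak_metrics(traj_a, species).peak_value
    pb = peak_metrics(traj_b, species).peak_value
    if pb == 0:
        raise ZeroDivisionError(
            f"reference trajectory has zero {species} peak")
    return pa / pb


#: trace values below this (uM) are treated as numerically zero when taking
#: logarithms in the sensitivity analysis; well above solver atol, far below
#: any biologically meaningful RD29A signal
_LOG_FLOOR = 1e-10


def local_sensitivity(
    model: ModelDefinition,
    parameter_names: Sequence[str] = SENSITIVITY_PARAMS,
    perturbation: float = 0.01,
    dose: float = 100.0,
    window: float = 24.0,
    species: str = RD29A_MRNA,
) -> pd.DataFrame:
    """Normalized local sensitivity of the RD29A trace per parameter.

    For each parameter p the index is the time integral over the transient
    window of |d ln y(t) / d ln p|, estimated by a central finite difference
    of two full protocol runs at p*(1 +/- perturbation).  The logarithmic
    (relative-relative) form makes indices comparable across parameters of
    different units.  Times where the unperturbed trace is numerically zero
    are excluded from the integral.

    Returns a frame (parameter, sensitivity_index, rank) sorted by rank.
    """
    if perturbation <= 0:
        raise ValueError("perturbation must be positive")
    for p in parameter_names:
        if p not in model.parameters:
            raise KeyError(f"unknown parameter {p!r}")

    base = run_aba_protocol(model, dose)
    mask_t = base.times <= window
    t = base.times[mask_t]
    y_base = base[species][mask_t]
    valid = y_base > _LOG_FLOOR

    dlnp = np.log1p(perturbation) - np.log1p(-perturbation)
    rows = []
    for p in parameter_names:
        v = model.parameters.value(p)
        traces = []
        for mult in (1.0 + perturbation, 1.0 - perturbation):
            traj = run_aba_protocol(model.with_parameters({p: v * mult}), dose)
            traces.append(traj[species][mask_t])
        hi, lo = traces
        s = np.zeros_like(y_base)
        ok = valid & (hi > _LOG_FLOOR) & (lo > _LOG_FLOOR)
        s[ok] = (np.log(hi[ok]) - np.log(lo[ok])) / dlnp
        index = float(np.trapezoid(np.abs(s), t))
        rows.append({"parameter": p, "sensitivity_index": index})

    table = pd.DataFrame(rows).sort_values(
        "sensitivity_index", ascending=False, kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
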