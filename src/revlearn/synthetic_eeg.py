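"""Synthetic feedback- and response-locked ERP epochs.

Generates epochs with the statistical structure the ERP analyses assume —
P1/N1/FRN/P3 deflections time-locked to feedback, and a slow
pre-feedback negative ramp (SPN) on response-locked epochs — so that every
quantification routine can be tested against a closed-form oracle without
any recorded data.  Component templates are raised-cosine bumps (compact
support, analytic extrema); condition effects are additive amplitude
offsets keyed on trial-log labels; noise is zero-mean white or
spectrally-shaped (1/f) Gaussian.  Alongside the epochs the generator emits
the ground-truth per-trial component amplitudes for oracle testing.

No human waveform is imitated quantitatively: amplitudes, widths and
topographies are plausible round numbers, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import erp_quant as eq
from . import task_engine as te
from .erp_quant import (EpochSet, FRONTOCENTRAL_CLUSTER, P3_CLUSTER,
                        SCALP_CHANNELS, SPN_CLUSTERS, VISUAL_CLUSTER)


@dataclass(frozen=True)
class ComponentTemplate:
    """One raised-cosine ERP component.

    The waveform is amplitude * 0.5*(1+cos(2*pi*(t-latency)/width)) on
    |t - latency| <= width/2 and zero outside; the peak value equals
    ``amplitude_uv`` exactly at ``latency_ms``.  ``topography`` maps channel
    name -> weight; unlisted channels get zero.
    """
    name: str
    latency_ms: float
    width_ms: float
    amplitude_uv: float
    topography: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError("template width must be positive")
        if any(abs(w) > 1.0 + 1e-9 for w in self.topography.values()):
            raise ValueError("topography weights must be bounded by 1")

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        x = times_ms - self.latency_ms
        support = np.abs(x) <= self.width_ms / 2.0
        out = np.zeros_like(times_ms, dtype=float)
        out[support] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[support]
                                           / self.width_ms))
        return out


def _cluster_topography(cluster, halo_weight: float = 0.3) -> dict:
    """Unit weight on the measurement cluster, a weak halo elsewhere."""
    topo = {ch: halo_weight for ch in SCALP_CHANNELS}
    topo.update({ch: 1.0 for ch in cluster})
    return topo


def default_components() -> tuple[ComponentTemplate, ...]:
    return (
        ComponentTemplate("P1", 80.0, 60.0, 3.0,
                          _cluster_topography(VISUAL_CLUSTER)),
        ComponentTemplate("N1", 170.0, 60.0, -4.0,
                          _cluster_topography(VISUAL_CLUSTER)),
        ComponentTemplate("FRN", 260.0, 40.0, -5.0,
                          _cluster_topography(FRONTOCENTRAL_CLUSTER)),
        ComponentTemplate("P3", 360.0, 120.0, 8.0,
                          _cluster_topography(P3_CLUSTER)),
    )


def _spn_topography() -> dict:
    """Right-lateralized weighting over the SPN analysis clusters."""
    topo = {}
    for name, weight in (("left", 0.5), ("central", 0.75), ("right", 1.0)):
        topo.update({ch: weight for ch in SPN_CLUSTERS[name]})
    return topo


@dataclass(frozen=True)
class SyntheticERPSpec:
    """Recipe for synthetic epochs.

    ``condition_deltas`` maps component name -> label column -> label value
    -> additive amplitude offset in uV (e.g.
    ``{"FRN": {"feedback": {"negative": -3.0}}}``).  ``noise_sd_uv`` is the
    per-sample noise SD; ``noise_model`` is "white" or "pink".
    """
    components: tuple[ComponentTemplate, ...] = \
        field(default_factory=default_components)
    condition_deltas: dict = field(default_factory=dict)
    noise_sd_uv: float = 10.0
    noise_model: str = "white"
    sfreq: float = 250.0
    window_ms: tuple[float, float] = (-500.0, 1496.0)
    spn_amplitude_uv: float = -4.0
    spn_topography: dict = field(default_factory=_spn_topography)

    def __post_init__(self):
        if self.noise_sd_uv < 0:
            raise ValueError("noise SD must be non-negative")
        if self.noise_model not in ("white", "pink"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def trial_amplitude(spec: SyntheticERPSpec, component: ComponentTemplate,
                    trial: pd.Series) -> float:
    """Base amplitude plus all condition deltas that apply to one trial."""
    amp = component.amplitude_uv
    for column, table in spec.condition_deltas.get(component.name,
                                                   {}).items():
        if column not in trial.index:
            raise KeyError(f"condition delta references column {column!r} "
                           f"absent from the trial log")
        amp += table.get(trial[column], 0.0)
    return amp


def _noise(spec: SyntheticERPSpec, shape: tuple,
           rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sd_uv == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if spec.noise_model == "white":
        return spec.noise_sd_uv * white
    # pink: shape the spectrum by 1/sqrt(f), renormalise to the target SD
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(shape[1], d=1.0 / spec.sfreq)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spectrum * scale[None, :, None], n=shape[1],
                          axis=1)
    sd = shaped.std()
    return spec.noise_sd_uv * shaped / (sd if sd > 0 else 1.0)


_LABEL_COLUMNS = ("block_index", "trial_index", "instruction", "feedback",
                  "phase", "rule_correct", "applied_mapping",
                  "has_reversal")


def _trial_info(log: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _LABEL_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"trial log lacks label columns {missing}")
    info = log[[c for c in log.columns if c in
                ("subject_id",) + _LABEL_COLUMNS]].reset_index(drop=True)
    info["next_behaviour"] = eq.label_next_trial_behaviour(log).to_numpy()
    return info


def generate_epochs(spec: SyntheticERPSpec, trial_log: pd.DataFrame,
                    seed: int = 0) -> tuple[EpochSet, pd.DataFrame]:
    """Feedback-locked epochs for every trial of a log.

    Each trial's epoch is the sum of the component templates, scaled by the
    trial's condition deltas and projected through the component
    topographies, plus noise.  Returns the EpochSet and a trials x
    components table of ground-truth amplitudes.
    """
    if len(trial_log) == 0:
        raise ValueError("empty trial log")
    rng = np.random.default_rng(seed)
    info = _trial_info(trial_log)
    ch_names = SCALP_CHANNELS
    times = np.arange(spec.window_ms[0], spec.window_ms[1] + 1e-9,
                      1000.0 / spec.sfreq)
    n_ch, n_t, n_tr = len(ch_names), len(times), len(info)

    data = _noise(spec, (n_ch, n_t, n_tr), rng)
    truth = pd.DataFrame(index=info.index)
    for comp in spec.components:
        wave = comp.waveform(times)
        topo = np.array([comp.topography.get(ch, 0.0) for ch in ch_names])
        amps = np.array([trial_amplitude(spec, comp, info.iloc[i])
                         for i in range(n_tr)])
        # unit-height template scaled by the trial amplitude
        data += (topo[:, None, None] * wave[None, :, None]
                 * amps[None, None, :])
        truth[comp.name] = amps
    epochs = EpochSet(data=data, sfreq=spec.sfreq, ch_names=ch_names,
                      tmin_ms=spec.window_ms[0], time_zero="feedback",
                      trial_info=info)
    return epochs, truth


def generate_spn_epochs(spec: SyntheticERPSpec, trial_log: pd.DataFrame,
                        seed: int = 0, interval_ms: float = 1200.0,
                        ) -> tuple[EpochSet, pd.DataFrame]:
    """Response-locked epochs carrying a pre-feedback SPN ramp.

    The SPN is a linear negative ramp over the last 600 ms before feedback
    onset, reaching the (condition-adjusted) amplitude at onset and held
    constant afterwards, projected through a right-lateralized topography.
    Returns the EpochSet and the per-trial ground-truth onset amplitude.
    """
    if len(trial_log) == 0:
        raise ValueError("empty trial log")
    rng = np.random.default_rng(seed)
    info = _trial_info(trial_log)
    info["interval_ms"] = interval_ms
    ch_names = SCALP_CHANNELS
    tmin, tmax = -500.0, interval_ms + 500.0
    times = np.arange(tmin, tmax + 1e-9, 1000.0 / spec.sfreq)
    n_ch, n_t, n_tr = len(ch_names), len(times), len(info)

    ramp = np.clip((times - (interval_ms - 600.0)) / 600.0, 0.0, 1.0)
    topo = np.array([spec.spn_topography.get(ch, 0.0) for ch in ch_names])
    spn_tpl = ComponentTemplate("SPN", 0.0, 1.0, spec.spn_amplitude_uv,
                                spec.spn_topography)
    amps = np.array([trial_amplitude(spec, spn_tpl, info.iloc[i])
                     for i in range(n_tr)])
    data = _noise(spec, (n_ch, n_t, n_tr), rng)
    data += topo[:, None, None] * ramp[None, :, None] * amps[None, None, :]
    truth = pd.DataFrame({"SPN": amps}, index=info.index)
    epochs = EpochSet(data=data, sfreq=spec.sfreq, ch_names=ch_names,
                      tmin_ms=tmin, time_zero="response", trial_info=info)
    return epochs, truth
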