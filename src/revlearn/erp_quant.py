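"""ERP preprocessing contracts and component quantification.

Operates on an :class:`EpochSet` container (channels x samples x trials, in
microvolts) with a standard 32-electrode cap montage.  The pipeline
implements the analysis contracts: peak-to-peak artifact rejection at
100 uV, downsampling to 250 Hz, zero-phase Hamming-window FIR band-pass
filtering (0.1-24 Hz; 0.05-24 Hz on the slow-wave path), and baseline
correction; the feedback-related negativity (FRN) is quantified as an
average-base-to-peak measure with deterministic window widening, the
stimulus-preceding negativity (SPN) as mean amplitudes in three
pre-feedback windows per laterality sub-cluster, and P3/P1/N1 as window
extrema over their clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from . import task_engine as te

# 32-channel scalp montage plus the auxiliary (ocular / mastoid) channels.
SCALP_CHANNELS = (
    "FP1", "FPZ", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "FT7", "FC3", "FCZ", "FC4", "FT8", "T7", "C3", "CZ", "C4", "T8",
    "TP7", "CP3", "CPZ", "CP4", "TP8", "P7", "P3", "PZ", "P4", "P8",
    "POZ", "O1", "OZ", "O2")
AUX_CHANNELS = ("HEOGL", "HEOGR", "VEOGU", "VEOGD", "M1", "M2")

FRONTOCENTRAL_CLUSTER = ("F3", "FZ", "F4", "FC3", "FCZ", "FC4",
                         "C3", "CZ", "C4")
P3_CLUSTER = ("CP3", "CPZ", "CP4", "P3", "PZ", "P4", "POZ")
VISUAL_CLUSTER = ("P7", "P3", "PZ", "P4", "P8", "POZ", "O1", "OZ", "O2")
SPN_CLUSTERS = {"left": ("FC3", "C3", "CP3"),
                "central": ("FCZ", "CZ", "CPZ"),
                "right": ("FC4", "C4", "CP4")}

CANONICAL_SFREQ = 250.0
REJECT_PTP_UV = 100.0

FRN_TROUGH_WINDOW = (240.0, 280.0)
FRN_PEAK1_WINDOW = (160.0, 220.0)
FRN_PEAK2_WINDOW = (300.0, 420.0)
FRN_HARD_BOUNDS = (0.0, 800.0)
P3_WINDOW = (300.0, 420.0)
P1_WINDOW = (60.0, 100.0)
N1_WINDOW = (140.0, 200.0)
SPN_WINDOWS = ((-600.0, -400.0), (-400.0, -200.0), (-200.0, 0.0))

FEEDBACK_BASELINE = (-200.0, -100.0)
SPN_BASELINE = (200.0, 300.0)          # relative to response onset


class EpochError(ValueError):
    pass


# --------------------------------------------------------------------------
# Container
# --------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Voltage epochs (channels x samples x trials, uV) with metadata.

    ``time_zero`` names the event the epochs are locked to ("feedback" or
    "response"); ``tmin_ms`` is the time of the first sample relative to
    that event.  ``trial_info`` holds one row of condition labels per trial.
    """
    data: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...]
    tmin_ms: float
    time_zero: str = "feedback"
    trial_info: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.data.ndim != 3:
            raise EpochError("data must be channels x samples x trials")
        if len(self.ch_names) != self.data.shape[0]:
            raise EpochError("channel-name count does not match data")
        if len(self.trial_info) not in (0, self.data.shape[2]):
            raise EpochError("trial_info row count does not match trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[1]
        return self.tmin_ms + np.arange(n) * 1000.0 / self.sfreq

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        info = self.trial_info.iloc[mask].reset_index(drop=True) \
            if len(self.trial_info) else self.trial_info
        return replace(self, data=self.data[:, :, mask], trial_info=info)

    def save(self, basepath: str | Path) -> None:
        """Binary voltage array (.npy) plus a JSON sidecar (.json)."""
        basepath = Path(basepath)
        np.save(basepath.with_suffix(".npy"), self.data)
        sidecar = {
            "sfreq": self.sfreq, "ch_names": list(self.ch_names),
            "tmin_ms": self.tmin_ms, "time_zero": self.time_zero,
            "trial_info": self.trial_info.to_dict(orient="list"),
        }
        with open(basepath.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, basepath: str | Path) -> "EpochSet":
        basepath = Path(basepath)
        data = np.load(basepath.with_suffix(".npy"))
        with open(basepath.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        return cls(data=data, sfreq=sidecar["sfreq"],
                   ch_names=tuple(sidecar["ch_names"]),
                   tmin_ms=sidecar["tmin_ms"],
                   time_zero=sidecar["time_zero"],
                   trial_info=pd.DataFrame(sidecar["trial_info"]))


@dataclass(frozen=True)
class ComponentAmplitude:
    value: float
    windows_used: dict
    cell: Optional[str] = None


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def reject_artifacts(epochs: EpochSet,
                     threshold_uv: float = REJECT_PTP_UV
                     ) -> tuple[EpochSet, int]:
    """Drop trials whose within-epoch peak-to-peak range exceeds the
    threshold on any scalp channel."""
    scalp = [i for i, ch in enumerate(epochs.ch_names)
             if ch in SCALP_CHANNELS]
    ptp = epochs.data[scalp].max(axis=1) - epochs.data[scalp].min(axis=1)
    keep = (ptp <= threshold_uv).all(axis=0)
    n_rejected = int((~keep).sum())
    if not keep.any():
        raise EpochError("all trials rejected by the peak-to-peak criterion")
    return epochs.select_trials(keep), n_rejected


def _fir_bandpass(data: np.ndarray, sfreq: float, l_freq: float,
                  h_freq: float) -> np.ndarray:
    """Zero-phase Hamming-window FIR band-pass along the last axis.

    A textbook 0.1 Hz transition band would need a filter far longer than a
    2 s epoch, so the tap count is capped at roughly a third of the epoch
    (the zero-phase forward-backward pass needs padding headroom).  The
    low-pass edge keeps a sharp transition; the high-pass edge is
    correspondingly soft, which is the standard compromise when filtering
    short epochs.
    """
    n_times = data.shape[-1]
    numtaps = min(int(3.3 * sfreq / 1.0) | 1, (n_times // 3 - 2) | 1)
    if numtaps < 9:
        raise EpochError("epoch too short to filter")
    taps = signal.firwin(numtaps, [l_freq, h_freq], pass_zero=False,
                         window="hamming", fs=sfreq)
    return signal.filtfilt(taps, [1.0], data, axis=-1)


def preprocess(epochs: EpochSet, l_freq: float = 0.1, h_freq: float = 24.0,
               target_sfreq: float = CANONICAL_SFREQ,
               reject_ptp_uv: float = REJECT_PTP_UV,
               ) -> tuple[EpochSet, int]:
    """Artifact rejection, downsampling to 250 Hz, band-pass filtering.

    Pass ``l_freq=0.05`` for the slow-wave (SPN) path.  Returns the cleaned
    EpochSet and the number of rejected trials.
    """
    if epochs.sfreq < target_sfreq:
        raise EpochError("epochs must be sampled at >= 250 Hz")
    epochs, n_rejected = reject_artifacts(epochs, reject_ptp_uv)
    # (channels, samples, trials) -> time on the last axis
    arr = np.moveaxis(epochs.data, 1, 2).astype(float)
    if epochs.sfreq != target_sfreq:
        from fractions import Fraction
        frac = Fraction(target_sfreq / epochs.sfreq).limit_denominator(1000)
        arr = signal.resample_poly(arr, frac.numerator, frac.denominator,
                                   axis=-1)
    arr = _fir_bandpass(arr, target_sfreq, l_freq, h_freq)
    out = replace(epochs, data=np.moveaxis(arr, 2, 1), sfreq=target_sfreq)
    return out, n_rejected


def baseline_correct(epochs: EpochSet,
                     window_ms: tuple[float, float]) -> EpochSet:
    """Subtract the per-channel, per-trial mean over the baseline window."""
    idx = _window_indices(epochs.times_ms, window_ms)
    base = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return replace(epochs, data=epochs.data - base)


# --------------------------------------------------------------------------
# Waveforms and measures
# --------------------------------------------------------------------------

def _window_indices(times_ms: np.ndarray,
                    window_ms: tuple[float, float]) -> np.ndarray:
    lo, hi = window_ms
    if lo < times_ms[0] - 1e-9 or hi > times_ms[-1] + 1e-9:
        raise EpochError(f"window {window_ms} outside epoch "
                         f"[{times_ms[0]:g}, {times_ms[-1]:g}] ms")
    idx = np.flatnonzero((times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9))
    if len(idx) == 0:
        raise EpochError(f"window {window_ms} contains no samples")
    return idx


def cluster_waveform(epochs: EpochSet, cluster: Sequence[str],
                     trial_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Condition-average time series: mean over the cluster channels, then
    over the selected trials."""
    missing = [ch for ch in cluster if ch not in epochs.ch_names]
    if missing:
        raise EpochError(f"cluster channels not in montage: {missing}")
    rows = [epochs.ch_names.index(ch) for ch in cluster]
    data = epochs.data[rows]
    if trial_mask is not None:
        data = data[:, :, np.asarray(trial_mask)]
    if data.shape[2] == 0:
        raise EpochError("no trials selected")
    return data.mean(axis=0).mean(axis=1)


def _widened_extremum(waveform: np.ndarray, times_ms: np.ndarray,
                      window_ms: tuple[float, float], mode: str,
                      inner_bound: Optional[float], outer_bound: float,
                      widen: bool) -> tuple[float, tuple[float, float]]:
    """Window extremum with deterministic edge widening.

    If the extremum falls on a window edge, that edge is moved outward one
    sample at a time, never across ``inner_bound`` (the trough window) nor
    past ``outer_bound``, until the extremum is interior or the edge is
    capped.  Returns the extremum value and the window finally used.
    """
    step = times_ms[1] - times_ms[0]
    lo, hi = window_ms
    pick = np.argmax if mode == "max" else np.argmin
    # bounds for each edge of this particular window
    if inner_bound is None:
        lo_bound, hi_bound = outer_bound, np.inf
    elif hi <= inner_bound:          # pre-trough window: right edge capped
        lo_bound, hi_bound = FRN_HARD_BOUNDS[0], inner_bound
    else:                            # post-trough window: left edge capped
        lo_bound, hi_bound = inner_bound, outer_bound
    lo_bound = max(lo_bound, times_ms[0])
    hi_bound = min(hi_bound, times_ms[-1])
    while True:
        idx = _window_indices(times_ms, (lo, hi))
        k = idx[pick(waveform[idx])]
        on_left = k == idx[0]
        on_right = k == idx[-1]
        if not widen or (not on_left and not on_right):
            break
        moved = False
        if on_left and lo - step >= lo_bound - 1e-9:
            lo -= step
            moved = True
        if on_right and hi + step <= hi_bound + 1e-9:
            hi += step
            moved = True
        if not moved:
            break
    return float(waveform[k]), (lo, hi)


def frn_amplitude(waveform: np.ndarray, times_ms: np.ndarray,
                  widen: bool = True,
                  mode: str = "mean_peaks") -> ComponentAmplitude:
    """FRN average-base-to-peak measure.

    Trough = lowest voltage in 240-280 ms; peaks = highest voltages in
    160-220 ms and 300-420 ms, each widened outward (away from the trough
    window, within 0-800 ms) whenever the maximum sits on a window edge.
    ``mode="mean_peaks"`` returns mean(peak1, peak2) - trough;
    ``mode="preceding_peak"`` is the simple base-to-peak variant
    peak1 - trough.
    """
    trough_idx = _window_indices(times_ms, FRN_TROUGH_WINDOW)
    trough = float(waveform[trough_idx].min())
    peak1, w1 = _widened_extremum(waveform, times_ms, FRN_PEAK1_WINDOW,
                                  "max", FRN_TROUGH_WINDOW[0],
                                  FRN_HARD_BOUNDS[1], widen)
    peak2, w2 = _widened_extremum(waveform, times_ms, FRN_PEAK2_WINDOW,
                                  "max", FRN_TROUGH_WINDOW[1],
                                  FRN_HARD_BOUNDS[1], widen)
    if mode == "mean_peaks":
        value = 0.5 * (peak1 + peak2) - trough
    elif mode == "preceding_peak":
        value = peak1 - trough
    else:
        raise ValueError(f"unknown FRN mode {mode!r}")
    return ComponentAmplitude(value=value, windows_used={
        "trough": FRN_TROUGH_WINDOW, "peak1": w1, "peak2": w2})


def spn_amplitude(epochs: EpochSet,
                  interval_ms: Optional[float] = None,
                  trial_mask: Optional[np.ndarray] = None) -> pd.DataFrame:
    """SPN mean amplitudes: 3 pre-feedback windows x 3 laterality clusters.

    Epochs must be response-locked; ``interval_ms`` is the response-feedback
    interval (defaults to the value stored in ``trial_info``, else 1200).
    Returns a window x laterality table of mean uV, ready for the
    INSTRUCTION x TIME x LATERALITY analysis.
    """
    if epochs.time_zero != "response":
        raise EpochError("SPN requires response-locked epochs")
    if interval_ms is None:
        interval_ms = float(epochs.trial_info["interval_ms"].iloc[0]) \
            if "interval_ms" in epochs.trial_info.columns else 1200.0
    if interval_ms + SPN_WINDOWS[0][0] < 0:
        raise EpochError("response-feedback interval too short for the "
                         "SPN windows")
    times = epochs.times_ms
    rows = {}
    for name, cluster in SPN_CLUSTERS.items():
        wave = cluster_waveform(epochs, cluster, trial_mask)
        rows[name] = [
            float(wave[_window_indices(
                times, (interval_ms + lo, interval_ms + hi))].mean())
            for lo, hi in SPN_WINDOWS]
    out = pd.DataFrame(rows, index=["window1", "window2", "window3"])
    out.index.name = "window"
    return out[["left", "central", "right"]]


def _window_extremum(waveform: np.ndarray, times_ms: np.ndarray,
                     window_ms: tuple[float, float],
                     mode: str) -> ComponentAmplitude:
    idx = _window_indices(times_ms, window_ms)
    fn = np.max if mode == "max" else np.min
    return ComponentAmplitude(value=float(fn(waveform[idx])),
                              windows_used={"window": window_ms})


def p3_amplitude(waveform: np.ndarray, times_ms) -> ComponentAmplitude:
    """Maximum voltage 300-420 ms (centro-parietal cluster average)."""
    return _window_extremum(waveform, np.asarray(times_ms), P3_WINDOW, "max")


def p1_amplitude(waveform: np.ndarray, times_ms) -> ComponentAmplitude:
    """Maximum voltage 60-100 ms (parietal/occipital cluster average)."""
    return _window_extremum(waveform, np.asarray(times_ms), P1_WINDOW, "max")


def n1_amplitude(waveform: np.ndarray, times_ms) -> ComponentAmplitude:
    """Minimum voltage 140-200 ms (parietal/occipital cluster average)."""
    return _window_extremum(waveform, np.asarray(times_ms), N1_WINDOW, "min")


def p3_by_next_trial_behaviour(epochs: EpochSet) -> pd.DataFrame:
    """P3 amplitude per NEXT TRIAL BEHAVIOUR x INSTRUCTION cell.

    Uses negative-feedback trials from the pre-reversal block halves whose
    ``next_behaviour`` label (repeat/reverse, from the next trial's applied
    mapping) is defined; block-final trials carry no label and are excluded.
    Cells with no trials are flagged with NaN.
    """
    info = epochs.trial_info
    for col in ("feedback", "phase", "instruction", "next_behaviour"):
        if col not in info.columns:
            raise EpochError(f"trial_info lacks required column {col!r}")
    base = ((info["feedback"] == te.NEGATIVE)
            & (info["phase"] == te.PRE_REVERSAL)
            & info["next_behaviour"].isin(["repeat", "reverse"])).to_numpy()
    rows = []
    for instr in sorted(info["instruction"].unique()):
        for behaviour in ("repeat", "reverse"):
            mask = base & ((info["instruction"] == instr)
                           & (info["next_behaviour"] == behaviour)).to_numpy()
            if mask.any():
                wave = cluster_waveform(epochs, P3_CLUSTER, mask)
                amp = p3_amplitude(wave, epochs.times_ms).value
            else:
                amp = float("nan")
            rows.append({"instruction": instr, "next_behaviour": behaviour,
                         "p3_uv": amp, "n_trials": int(mask.sum()),
                         "defined": bool(mask.any())})
    return pd.DataFrame(rows)


def label_next_trial_behaviour(log: pd.DataFrame) -> pd.Series:
    """repeat/reverse label from the next trial's applied mapping within
    the same block; block-final trials get NA."""
    keys = [c for c in ("subject_id", "block_index") if c in log.columns]
    out = pd.Series(pd.NA, index=log.index, dtype=object)
    for _, block in log.groupby(keys, sort=False):
        block = block.sort_values("trial_index")
        applied = block["applied_mapping"].to_numpy()
        labels = np.where(applied[1:] != applied[:-1], "reverse", "repeat")
        out.loc[block.index[:-1]] = labels
    return out
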