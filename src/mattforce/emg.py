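"""Surface-EMG processing: band-pass + notch filtering, RMS envelopes, %MVC.

The muscle-activity validation chain normalizes each trial's EMG envelope to
the subject's maximal voluntary contraction (MVC): raw signals are band-pass
filtered 20-500 Hz (4th-order Butterworth) with a 50 Hz mains notch, reduced
to a moving-RMS envelope (66.7 ms window), and expressed as a percentage of
the peak MVC envelope across the (typically 3) MVC repetitions. Measured
%MVC is then rank-correlated (Spearman) against model-predicted activity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy import stats


@dataclass(frozen=True)
class EMGTrace:
    """One channel of raw or filtered EMG.

    ``samples`` in arbitrary amplifier units; ``sampling_rate`` in Hz (the
    study hardware samples at 1500 Hz).
    """

    samples: np.ndarray
    sampling_rate: float
    muscle: str = ""
    side: str = ""

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite EMG samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", x)


@dataclass(frozen=True)
class ActivityValue:
    muscle: str
    percent_mvc: float
    statistic: str
    mvc_peak: float

    def __post_init__(self):
        if self.percent_mvc < 0:
            raise ValueError("%MVC must be non-negative")


def filter_emg(
    trace: EMGTrace,
    band: tuple[float, float] = (20.0, 500.0),
    notch: float = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> EMGTrace:
    """Zero-phase Butterworth band-pass plus mains notch.

    Forward-backward filtering (``filtfilt``) keeps the envelope timing
    aligned with the raw signal; the notch is a second-order IIR with
    quality factor ``notch_q``.
    """
    lo, hi = band
    nyq = trace.sampling_rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(
            f"band ({lo}, {hi}) Hz invalid for Nyquist {nyq} Hz"
        )
    if not 0 < notch < nyq:
        raise ValueError("notch frequency must lie below Nyquist")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=trace.sampling_rate,
                        output="sos")
    x = signal.sosfiltfilt(sos, trace.samples)
    b, a = signal.iirnotch(notch, notch_q, fs=trace.sampling_rate)
    x = signal.filtfilt(b, a, x)
    return replace(trace, samples=x)


def moving_rms(trace: EMGTrace, window_s: float = 0.0667) -> np.ndarray:
    """Centered moving-RMS envelope; edge windows are truncated.

    The default 66.7 ms window spans 100 samples at 1500 Hz. Output length
    equals input length.
    """
    n = trace.samples.size
    w = int(round(window_s * trace.sampling_rate))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if w > n:
        raise ValueError(f"window of {w} samples exceeds trace length {n}")
    sq = trace.samples**2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    half_lo = (w - 1) // 2
    half_hi = w // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    return np.sqrt((csum[hi] - csum[lo]) / (hi - lo))


def percent_mvc(
    trial_envelope: np.ndarray,
    mvc_envelopes: list[np.ndarray],
    muscle: str = "",
    statistic: str = "mean",
) -> ActivityValue:
    """Normalize a trial envelope to the peak MVC envelope value.

    The denominator is the maximum envelope value across all MVC
    repetitions. ``statistic`` reduces the trial envelope: ``"mean"``
    (default, the sustained activity over the trial) or ``"peak"``.
    """
    if not mvc_envelopes:
        raise ValueError("need at least one MVC envelope")
    if statistic not in ("mean", "peak"):
        raise ValueError(f"unknown statistic {statistic!r}")
    denom = max(float(np.max(e)) for e in mvc_envelopes)
    if denom <= 0:
        raise ValueError("MVC envelope peak is zero; cannot normalize")
    trial_envelope = np.asarray(trial_envelope, dtype=float)
    num = float(trial_envelope.mean() if statistic == "mean" else trial_envelope.max())
    return ActivityValue(
        muscle=muscle,
        percent_mvc=100.0 * num / denom,
        statistic=statistic,
        mvc_peak=denom,
    )


def spearman_activity(measured, predicted) -> float:
    """Spearman rank correlation between measured %MVC and predicted activity.

    Ties are mid-ranked. Raises on constant input, where the coefficient is
    undefined.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape or measured.size < 3:
        raise ValueError("need paired series of length >= 3")
    if np.ptp(measured) == 0 or np.ptp(predicted) == 0:
        raise ValueError("correlation undefined for a constant series")
    rho = stats.spearmanr(measured, predicted).statistic
    return float(rho)


def read_emg_csv(
    path: str | Path, sampling_rate: float
) -> dict[str, EMGTrace]:
    """Read a multi-channel EMG CSV (header row of muscle labels)."""
    df = pd.read_csv(Path(path))
    return {
        col: EMGTrace(df[col].to_numpy(), sampling_rate, muscle=col)
        for col in df.columns
    }
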