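"""Firing-rate metrics from cell-attached recordings.

Spontaneously active neurons (striatal cholinergic interneurons fire
regularly at ~1.5 Hz) are recorded extracellularly; opioid agonists
suppress firing.  Two scalar readouts summarize an experiment:

* **percent inhibition** — 100 × (1 − rate in the 1–2 min window after
  agonist onset / baseline rate), clamped to [0, 100];
* **percent desensitization** — the decline of that inhibition during
  sustained application: inhibition in the 1–2 min window minus inhibition
  at the 5-min time point (operationalized as the 4.5–5 min window),
  clamped to [0, 100].

Cells without steady baseline firing are excluded (a zero baseline rate
raises).  Spike detection on raw 10-kHz traces uses a robust
(median-absolute-deviation) noise estimate so the spikes themselves do not
inflate the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator

from receptorquant.errors import EpochError, ZeroBaselineError

__all__ = [
    "SpikeExperiment",
    "InhibitionResult",
    "FiringAnalyzer",
    "detect_spikes",
    "bin_rates",
    "percent_inhibition",
    "percent_desensitization",
]

#: MAD-to-SD conversion for Gaussian noise
_MAD_SCALE = 1.4826

#: measurement windows relative to agonist onset, seconds
EARLY_WINDOW_S = (60.0, 120.0)
LATE_WINDOW_S = (270.0, 300.0)


@dataclass
class SpikeExperiment:
    """Spike times with epoch annotations for one cell.

    Attributes
    ----------
    spike_times : ndarray
        Seconds from record start, strictly increasing.
    agonist_onset_s : float
        Start of agonist application.
    agonist_end_s : float
        End of agonist application (NaN if it runs to the record end).
    baseline_start_s : float
        Start of the baseline epoch (ends at agonist onset).
    sampling_rate_hz : float
        Acquisition rate of the underlying trace (10 kHz typical); kept as
        provenance even when spike times are supplied directly.
    """

    spike_times: np.ndarray
    agonist_onset_s: float
    agonist_end_s: float = float("nan")
    baseline_start_s: float = 0.0
    sampling_rate_hz: float = 10_000.0
    cell_id: str = ""
    condition: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike_times must be strictly increasing")
        if not self.baseline_start_s < self.agonist_onset_s:
            raise ValueError("baseline must precede agonist onset")

    @property
    def baseline_duration_s(self) -> float:
        return self.agonist_onset_s - self.baseline_start_s

    @property
    def agonist_duration_s(self) -> float:
        end = self.agonist_end_s
        if np.isnan(end):
            end = float(self.spike_times[-1]) if self.spike_times.size else self.agonist_onset_s
        return end - self.agonist_onset_s

    def count_in(self, t0: float, t1: float) -> int:
        """Spike count in the half-open interval [t0, t1)."""
        return int(np.count_nonzero((self.spike_times >= t0) & (self.spike_times < t1)))

    def rate_in(self, t0: float, t1: float) -> float:
        """Mean firing rate (Hz) in [t0, t1)."""
        if not t1 > t0:
            raise ValueError("window must have positive length")
        return self.count_in(t0, t1) / (t1 - t0)


@dataclass
class InhibitionResult:
    """Per-cell firing inhibition summary (Table-style semantics)."""

    baseline_rate_hz: float
    agonist_rate_hz: float
    percent_inhibition: float
    percent_desensitization: float | None = None
    late_rate_hz: float | None = None
    rebound: bool = False


def detect_spikes(
    trace: np.ndarray,
    sampling_rate_hz: float,
    threshold_sd: float = 4.0,
    refractory_ms: float = 2.0,
    polarity: str = "both",
    smooth_ms: float = 0.5,
) -> np.ndarray:
    """Threshold-crossing spike detection with a robust noise estimate.

    The trace is lightly boxcar-smoothed (``smooth_ms``; 0 disables) to
    suppress single-sample noise peaks, then the noise SD is estimated as
    1.4826 × the median absolute deviation so sparse large spikes barely
    perturb it.  An event is any excursion beyond ``threshold_sd`` × noise
    SD (negative-going, positive-going, or either); the extremum sample
    within each excursion is kept and events closer than ``refractory_ms``
    are suppressed.

    Returns spike times in seconds.  A flat trace returns an empty array
    with a warning.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise ValueError("trace must be 1-D")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    width = int(round(smooth_ms * 1e-3 * sampling_rate_hz))
    if width > 1:
        kernel = np.full(width, 1.0 / width)
        trace = np.convolve(trace, kernel, mode="same")
    center = np.median(trace)
    noise_sd = _MAD_SCALE * np.median(np.abs(trace - center))
    if noise_sd == 0:
        warnings.warn("flat trace: no noise scale, returning no spikes", stacklevel=2)
        return np.array([], dtype=np.float64)
    dev = trace - center
    if polarity == "positive":
        dev = dev
    elif polarity == "negative":
        dev = -dev
    elif polarity == "both":
        dev = np.abs(dev)
    else:
        raise ValueError("polarity must be 'positive', 'negative' or 'both'")
    distance = max(1, int(round(refractory_ms * 1e-3 * sampling_rate_hz)))
    peaks, _ = signal.find_peaks(dev, height=threshold_sd * noise_sd, distance=distance)
    return peaks / sampling_rate_hz


def bin_rates(
    spike_times: np.ndarray,
    bin_seconds: float = 15.0,
    t_start: float = 0.0,
    t_end: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike counts in half-open bins [k·b, (k+1)·b) from ``t_start``.

    Returns ``(counts, edges)`` with ``len(edges) == len(counts) + 1``.
    A spike exactly on an edge falls in the later bin; counts over the
    covered span sum to the number of spikes in it.
    """
    if bin_seconds <= 0:
        raise ValueError("bin_seconds must be positive")
    t = np.asarray(spike_times, dtype=np.float64)
    if t_end is None:
        t_end = float(t.max()) + np.finfo(float).eps if t.size else t_start + bin_seconds
    n_bins = max(1, int(np.ceil((t_end - t_start) / bin_seconds)))
    idx = np.floor((t - t_start) / bin_seconds).astype(np.int64)
    in_range = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[in_range], minlength=n_bins)
    edges = t_start + bin_seconds * np.arange(n_bins + 1)
    return counts, edges


def _clamp_percent(x: float) -> float:
    return float(min(100.0, max(0.0, x)))


class FiringAnalyzer(BaseEstimator):
    """Inhibition/desensitization metrics over fixed post-onset windows.

    Parameters
    ----------
    early_window_s, late_window_s : (float, float)
        Measurement windows in seconds after agonist onset.  Defaults are
        the 1–2 min maximal-effect window and the 4.5–5 min window standing
        in for "at 5 min".
    min_baseline_s : float
        Minimum baseline epoch length (the steady-firing inclusion rule
        needs at least a minute of baseline).
    normalize_desensitization : bool
        If True, report desensitization as a percentage of the early
        (maximal) inhibition instead of the raw difference of the two
        inhibition percentages.
    """

    def __init__(
        self,
        early_window_s: tuple[float, float] = EARLY_WINDOW_S,
        late_window_s: tuple[float, float] = LATE_WINDOW_S,
        min_baseline_s: float = 60.0,
        normalize_desensitization: bool = False,
    ):
        self.early_window_s = early_window_s
        self.late_window_s = late_window_s
        self.min_baseline_s = min_baseline_s
        self.normalize_desensitization = normalize_desensitization

    def fit(self, X=None, y=None) -> "FiringAnalyzer":
        return self

    def _baseline_rate(self, exp: SpikeExperiment) -> float:
        if exp.baseline_duration_s < self.min_baseline_s:
            raise EpochError(
                f"baseline epoch {exp.baseline_duration_s:.1f} s shorter than "
                f"{self.min_baseline_s:.0f} s"
            )
        rate = exp.rate_in(exp.baseline_start_s, exp.agonist_onset_s)
        if rate == 0:
            raise ZeroBaselineError(
                "zero baseline firing rate: cell fails the steady-firing inclusion rule"
            )
        return rate

    def _window_rate(self, exp: SpikeExperiment, window: tuple[float, float]) -> float:
        a, b = window
        if exp.agonist_duration_s < b:
            raise EpochError(
                f"agonist epoch {exp.agonist_duration_s:.1f} s too short for the "
                f"[{a:.0f}, {b:.0f}] s window"
            )
        return exp.rate_in(exp.agonist_onset_s + a, exp.agonist_onset_s + b)

    def percent_inhibition(self, exp: SpikeExperiment) -> float:
        """Inhibition (%) of firing in the early window, clamped to [0, 100]."""
        baseline = self._baseline_rate(exp)
        early = self._window_rate(exp, self.early_window_s)
        return _clamp_percent(100.0 * (1.0 - early / baseline))

    def percent_desensitization(self, exp: SpikeExperiment) -> float:
        """Decline of inhibition between the early and 5-min windows (%)."""
        baseline = self._baseline_rate(exp)
        early = self._window_rate(exp, self.early_window_s)
        late = self._window_rate(exp, self.late_window_s)
        inh_early = _clamp_percent(100.0 * (1.0 - early / baseline))
        inh_late = _clamp_percent(100.0 * (1.0 - late / baseline))
        desens = _clamp_percent(inh_early - inh_late)
        if self.normalize_desensitization:
            if inh_early == 0:
                raise EpochError("cannot normalize desensitization: zero early inhibition")
            desens = _clamp_percent(100.0 * desens / inh_early)
        return desens

    def analyze(self, exp: SpikeExperiment) -> InhibitionResult:
        """Full per-cell summary; desensitization is None for short epochs."""
        baseline = self._baseline_rate(exp)
        early = self._window_rate(exp, self.early_window_s)
        inhibition = _clamp_percent(100.0 * (1.0 - early / baseline))
        late = desens = None
        if exp.agonist_duration_s >= self.late_window_s[1]:
            late = self._window_rate(exp, self.late_window_s)
            desens = self.percent_desensitization(exp)
        return InhibitionResult(
            baseline_rate_hz=baseline,
            agonist_rate_hz=early,
            percent_inhibition=inhibition,
            percent_desensitization=desens,
            late_rate_hz=late,
            rebound=early > baseline,
        )


def percent_inhibition(exp: SpikeExperiment, **kwargs) -> float:
    """Percent inhibition of firing (thin wrapper over FiringAnalyzer)."""
    return FiringAnalyzer(**kwargs).percent_inhibition(exp)


def percent_desensitization(exp: SpikeExperiment, **kwargs) -> float:
    """Percent desensitization (thin wrapper over FiringAnalyzer)."""
    return FiringAnalyzer(**kwargs).percent_desensitization(exp)
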