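"""Passive cavitation dose analysis for microbubble-mediated BBB opening.

Each therapy burst recorded by the passive cavitation detector (PCD) is split
into short analysis windows. A discrete Fourier transform of every window
yields two band-power indices:

* **IUD** — intrapulse ultra-harmonic dose: power summed in 50 kHz bands around
  1.5, 2.5 and 3.5 times the drive frequency f0. Ultra-harmonics (and the
  broadband floor they ride on) mark the onset of inertial cavitation, i.e.
  violent bubble collapse.
* **IHD** — intrapulse harmonic dose: the same around 2, 3 and 4 times f0,
  tracking stable (non-collapsing) bubble oscillation.

The method needs no pre-injection baseline: a noise reference is taken from
the recording itself (the quiet fraction of all windows). Windows whose IUD
exceeds ``threshold_multiplier`` times the noise reference are flagged as
inertial events; runs of consecutive events within a burst are counted, and
the sonication is classified as *soft*, *mild* or *hard*.

FFT normalisation convention
----------------------------
One-sided power spectrum with ``P[k] = 2 |X[k]|^2 / N^2`` for interior bins
(``1/N^2`` at DC and Nyquist), so a unit-amplitude sinusoid centred on a bin
contributes band power 0.5 (``A^2/2`` for amplitude A). No taper is applied by
default; a Hann taper (with coherent-gain compensation) is available by flag.
Band integration covers the closed-open interval ``[fc - bw/2, fc + bw/2)`` on
the discrete frequency grid: the lower band edge is included, the upper
excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "ULTRAHARMONIC_MULTIPLES",
    "HARMONIC_MULTIPLES",
    "PCDRecording",
    "WindowLayout",
    "DoseSeries",
    "EventStats",
    "CavitationVerdict",
    "ClassificationCutoffs",
    "EventRelation",
    "segment_pulse",
    "window_dose",
    "compute_doses",
    "estimate_noise",
    "flag_events",
    "classify",
    "analyze_recording",
    "fit_event_relation",
]

#: Ultra-harmonic band centers as multiples of the drive frequency f0.
ULTRAHARMONIC_MULTIPLES: tuple[float, ...] = (1.5, 2.5, 3.5)
#: Harmonic band centers as multiples of f0.
HARMONIC_MULTIPLES: tuple[float, ...] = (2.0, 3.0, 4.0)


@dataclass
class PCDRecording:
    """A single sonication's PCD time series.

    ``samples`` holds the gated acquisition: only the transmit bursts are
    recorded (acquisition is triggered by the therapy system), concatenated in
    pulse order. ``pulse_starts`` indexes the first sample of each burst.
    """

    samples: np.ndarray
    sampling_rate: float
    f0: float
    pulse_starts: np.ndarray
    pulse_length: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.pulse_starts = np.asarray(self.pulse_starts, dtype=np.int64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        spp = self.samples_per_pulse
        starts = np.sort(self.pulse_starts)
        if np.any(np.diff(starts) < spp):
            raise ValueError("pulse segments overlap")
        if starts.size and (starts[0] < 0 or starts[-1] + spp > self.samples.size):
            raise ValueError("pulse segment outside the recorded series")

    @property
    def samples_per_pulse(self) -> int:
        return int(round(self.pulse_length * self.sampling_rate))

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_starts.size)

    def pulse(self, index: int) -> np.ndarray:
        """Samples of one burst."""
        if not 0 <= index < self.n_pulses:
            raise IndexError(f"pulse index {index} out of range")
        start = int(self.pulse_starts[index])
        return self.samples[start : start + self.samples_per_pulse]


@dataclass(frozen=True)
class WindowLayout:
    """Intrapulse analysis-window layout.

    The head of each burst is discarded (non-linear transducer switching
    transients), the remainder is cut into contiguous fixed-length windows,
    and a tail is discarded as well (switch-off distortion). With the default
    layout on a 50 ms burst this yields 247 windows of 200 µs.
    """

    head_cut: float = 200e-6
    window_length: float = 200e-6
    tail_cut: float = 400e-6

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if self.head_cut < 0 or self.tail_cut < 0:
            raise ValueError("cuts must be nonnegative")

    def n_windows(self, pulse_length: float) -> int:
        usable = pulse_length - self.head_cut - self.tail_cut
        n = int(np.floor(usable / self.window_length + 1e-9))
        if n < 1:
            raise ValueError(
                f"pulse of {pulse_length:g} s too short for head cut "
                f"{self.head_cut:g} s + tail cut {self.tail_cut:g} s + one "
                f"window of {self.window_length:g} s"
            )
        return n

    def samples_per_window(self, sampling_rate: float) -> int:
        return int(round(self.window_length * sampling_rate))


def segment_pulse(
    recording: PCDRecording, pulse_index: int, layout: WindowLayout | None = None
) -> np.ndarray:
    """Cut one burst into its analysis windows.

    Returns an array of shape ``(n_windows, samples_per_window)``; the first
    window starts ``head_cut`` after the burst onset, tail samples are never
    included.
    """
    layout = layout or WindowLayout()
    pulse = recording.pulse(pulse_index)
    nwin = layout.n_windows(recording.pulse_length)
    spw = layout.samples_per_window(recording.sampling_rate)
    head = int(round(layout.head_cut * recording.sampling_rate))
    block = pulse[head : head + nwin * spw]
    return block.reshape(nwin, spw)


def _band_bins(
    n_samples: int, sampling_rate: float, bands: Sequence[float], bandwidth: float
) -> np.ndarray:
    """Indices of rFFT bins falling in [fc - bw/2, fc + bw/2) for any band."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    nyquist = sampling_rate / 2.0
    sel = np.zeros(freqs.size, dtype=bool)
    for fc in bands:
        if fc + bandwidth / 2.0 > nyquist:
            raise ValueError(
                f"band at {fc:g} Hz (bw {bandwidth:g}) exceeds Nyquist {nyquist:g} Hz"
            )
        # closed-open inclusion; nudge edges to absorb float round-off so a
        # band edge landing exactly on a bin includes the lower edge only
        lo = fc - bandwidth / 2.0 - 1e-6
        hi = fc + bandwidth / 2.0 - 1e-6
        sel |= (freqs >= lo) & (freqs < hi)
    return np.flatnonzero(sel)


def _power_spectra(windows: np.ndarray, taper: str | None = None) -> np.ndarray:
    """One-sided power spectra of each row; unit-amp on-bin sinusoid -> 0.5."""
    n = windows.shape[-1]
    if taper is None:
        w = windows
        gain = 1.0
    elif taper == "hann":
        win = np.hanning(n)
        w = windows * win
        gain = win.mean()  # coherent gain compensation
    else:
        raise ValueError(f"unknown taper {taper!r}")
    spec = np.fft.rfft(w, axis=-1)
    power = (np.abs(spec) ** 2) * (2.0 / (n * n * gain * gain))
    power[..., 0] /= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    return power


def window_dose(
    window: np.ndarray,
    sampling_rate: float,
    f0: float,
    bands: Sequence[float],
    bandwidth: float = 50e3,
    taper: str | None = None,
) -> float:
    """Band power of one analysis window summed over the listed band centers.

    ``bands`` gives absolute center frequencies in Hz (use
    ``m * f0`` for the harmonic/ultra-harmonic multiples).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("window must be a 1-D array of at least 2 samples")
    bins = _band_bins(window.size, sampling_rate, bands, bandwidth)
    power = _power_spectra(window[None, :], taper=taper)[0]
    return float(power[bins].sum())


@dataclass
class DoseSeries:
    """Per-window IUD/IHD band powers for one sonication."""

    iud: np.ndarray  # [n_pulses, n_windows], a.u.^2
    ihd: np.ndarray
    f0: float
    sampling_rate: float
    bands_uh: tuple[float, ...]
    bands_h: tuple[float, ...]
    bandwidth: float
    layout: WindowLayout
    noise_level: float | None = None
    noise_method: str | None = None
    threshold_multiplier: float | None = None
    event_flags: np.ndarray | None = None

    @property
    def n_pulses(self) -> int:
        return int(self.iud.shape[0])

    @property
    def n_windows(self) -> int:
        return int(self.iud.shape[1])

    def relative_iud(self) -> np.ndarray:
        """IUD normalised by the noise reference (dimensionless)."""
        if self.noise_level is None or self.noise_level <= 0:
            raise ValueError("noise_level not set or nonpositive")
        return self.iud / self.noise_level


def compute_doses(
    recording: PCDRecording,
    layout: WindowLayout | None = None,
    bandwidth: float = 50e3,
    taper: str | None = None,
) -> DoseSeries:
    """Compute the IUD and IHD matrices for every burst and window."""
    layout = layout or WindowLayout()
    nwin = layout.n_windows(recording.pulse_length)
    spw = layout.samples_per_window(recording.sampling_rate)
    bands_uh = tuple(m * recording.f0 for m in ULTRAHARMONIC_MULTIPLES)
    bands_h = tuple(m * recording.f0 for m in HARMONIC_MULTIPLES)
    bins_uh = _band_bins(spw, recording.sampling_rate, bands_uh, bandwidth)
    bins_h = _band_bins(spw, recording.sampling_rate, bands_h, bandwidth)

    iud = np.empty((recording.n_pulses, nwin))
    ihd = np.empty((recording.n_pulses, nwin))
    for p in range(recording.n_pulses):
        windows = np.asarray(segment_pulse(recording, p, layout), dtype=float)
        power = _power_spectra(windows, taper=taper)
        iud[p] = power[:, bins_uh].sum(axis=1)
        ihd[p] = power[:, bins_h].sum(axis=1)
    return DoseSeries(
        iud=iud,
        ihd=ihd,
        f0=recording.f0,
        sampling_rate=recording.sampling_rate,
        bands_uh=bands_uh,
        bands_h=bands_h,
        bandwidth=bandwidth,
        layout=layout,
    )


def estimate_noise(
    doses: DoseSeries,
    method: str = "lower_quantile",
    q: float = 0.25,
    reference_pulses: Sequence[int] | None = None,
) -> float:
    """Estimate the IUD noise reference from the recording itself.

    ``lower_quantile`` takes the median of the lowest ``q`` fraction of all
    IUD values — robust to a minority of cavitation-active windows, and
    needing no pre-injection baseline. ``reference_pulses`` averages the IUD
    of user-designated quiet bursts instead.
    """
    if doses.iud.size == 0:
        raise ValueError("empty dose matrix")
    if method == "lower_quantile":
        if not 0.0 < q <= 1.0:
            raise ValueError("q must lie in (0, 1]")
        flat = np.sort(doses.iud, axis=None)
        k = max(1, int(np.ceil(q * flat.size)))
        noise = float(np.median(flat[:k]))
    elif method == "reference_pulses":
        if not reference_pulses:
            raise ValueError("reference_pulses must be a non-empty index list")
        idx = np.asarray(reference_pulses, dtype=int)
        noise = float(doses.iud[idx].mean())
    else:
        raise ValueError(f"unknown noise method {method!r}")
    doses.noise_level = noise
    doses.noise_method = method
    return noise


@dataclass
class EventStats:
    """Inertial-event counts derived from the flagged dose matrix."""

    flags: np.ndarray
    pct_inertial: float
    pct_consecutive: float
    n_total: int
    n_consecutive: int
    n_windows_analysed: int
    run_min: int


def _runs_of_true(row: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    if not row.any():
        return []
    padded = np.concatenate(([False], row, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(edges[1::2] - edges[0::2])


def flag_events(
    doses: DoseSeries,
    threshold_multiplier: float = 6.0,
    run_min: int = 2,
) -> EventStats:
    """Flag inertial windows and count total / consecutive events.

    A window is inertial when its relative IUD (IUD / noise reference)
    exceeds ``threshold_multiplier``. Consecutive events are windows lying in
    runs of at least ``run_min`` flagged windows *within* a burst (runs never
    span burst boundaries). Both counts are reported as percentages of all
    analysed windows.
    """
    if threshold_multiplier <= 0:
        raise ValueError("threshold must be positive")
    if run_min < 1:
        raise ValueError("run_min must be >= 1")
    if doses.noise_level is None:
        estimate_noise(doses)
    rel = doses.relative_iud()
    flags = rel > threshold_multiplier
    n_total = int(flags.sum())
    n_consec = 0
    for p in range(flags.shape[0]):
        for length in _runs_of_true(flags[p]):
            if length >= run_min:
                n_consec += int(length)
    n_all = int(flags.size)
    doses.event_flags = flags
    doses.threshold_multiplier = float(threshold_multiplier)
    return EventStats(
        flags=flags,
        pct_inertial=100.0 * n_total / n_all,
        pct_consecutive=100.0 * n_consec / n_all,
        n_total=n_total,
        n_consecutive=n_consec,
        n_windows_analysed=n_all,
        run_min=run_min,
    )


@dataclass(frozen=True)
class ClassificationCutoffs:
    """Soft/mild/hard decision boundaries, all in percent of analysed windows.

    The soft boundaries default to the maxima observed in histologically clean
    sonications (1.4% inertial, 0.3% consecutive); the hard boundary sits
    between those and the extremes seen with erythrocyte extravasation. A
    burst whose *mean* relative IUD stays above the inertial threshold is hard
    regardless of the percentages (the sustained-suprathreshold signature).
    """

    soft_inertial: float = 1.4
    soft_consecutive: float = 0.3
    hard_consecutive: float = 3.0


@dataclass(frozen=True)
class CavitationVerdict:
    label: str  # soft | mild | hard
    pct_inertial: float
    pct_consecutive: float
    any_pulse_mean_above: bool
    cutoffs: ClassificationCutoffs
    threshold_multiplier: float

    #: ordering used by monotonicity checks
    SEVERITY = {"soft": 0, "mild": 1, "hard": 2}

    @property
    def severity(self) -> int:
        return self.SEVERITY[self.label]


def classify(
    pct_inertial: float,
    pct_consecutive: float,
    pulse_mean_relative: np.ndarray,
    threshold_multiplier: float = 6.0,
    cutoffs: ClassificationCutoffs | None = None,
) -> CavitationVerdict:
    """Classify a sonication as soft, mild or hard.

    Parameters
    ----------
    pulse_mean_relative : array
        Per-burst mean of the relative IUD (IUD / noise reference).
    """
    cutoffs = cutoffs or ClassificationCutoffs()
    pulse_mean_relative = np.asarray(pulse_mean_relative, dtype=float)
    if not (np.isfinite(pct_inertial) and np.isfinite(pct_consecutive)):
        raise ValueError("percentages must be finite")
    any_above = bool(np.any(pulse_mean_relative > threshold_multiplier))
    if any_above or pct_consecutive > cutoffs.hard_consecutive:
        label = "hard"
    elif (
        pct_inertial <= cutoffs.soft_inertial
        and pct_consecutive <= cutoffs.soft_consecutive
    ):
        label = "soft"
    else:
        label = "mild"
    return CavitationVerdict(
        label=label,
        pct_inertial=float(pct_inertial),
        pct_consecutive=float(pct_consecutive),
        any_pulse_mean_above=any_above,
        cutoffs=cutoffs,
        threshold_multiplier=float(threshold_multiplier),
    )


def analyze_recording(
    recording: PCDRecording,
    layout: WindowLayout | None = None,
    bandwidth: float = 50e3,
    threshold_multiplier: float = 6.0,
    run_min: int = 2,
    cutoffs: ClassificationCutoffs | None = None,
    noise_method: str = "lower_quantile",
) -> tuple[DoseSeries, EventStats, CavitationVerdict]:
    """Full analysis chain: doses -> noise -> events -> verdict."""
    doses = compute_doses(recording, layout=layout, bandwidth=bandwidth)
    estimate_noise(doses, method=noise_method)
    events = flag_events(doses, threshold_multiplier=threshold_multiplier, run_min=run_min)
    verdict = classify(
        events.pct_inertial,
        events.pct_consecutive,
        doses.relative_iud().mean(axis=1),
        threshold_multiplier=threshold_multiplier,
        cutoffs=cutoffs,
    )
    return doses, events, verdict


@dataclass(frozen=True)
class EventRelation:
    slope: float
    intercept: float
    r_squared: float


def fit_event_relation(
    pct_inertial: Sequence[float], pct_consecutive: Sequence[float]
) -> EventRelation:
    """Ordinary least squares of consecutive-event % on total inertial-event %."""
    x = np.asarray(pct_inertial, dtype=float)
    y = np.asarray(pct_consecutive, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired subjects")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in total inertial events")
    if np.ptp(y) == 0:
        warnings.warn(
            "consecutive events constant across subjects; R^2 reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return EventRelation(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    res = _scipy_stats.linregress(x, y)
    return EventRelation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
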