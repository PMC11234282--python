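"""Seeded simulation of passive-cavitation-detector recordings.

The emission model is deliberately at the signal level, not the physics
level: stable cavitation appears as sinusoids at the harmonic multiples of
the drive frequency, the onset of inertial cavitation as ultra-harmonic
sinusoids plus band-limited broadband noise confined to designated analysis
windows, and the transducer's own switch-on non-linearity as a decaying chirp
in the head-cut interval. This is exactly the content the intrapulse dose
engine is designed to separate, with ground truth known per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..cavitation import (
    HARMONIC_MULTIPLES,
    PCDRecording,
    ULTRAHARMONIC_MULTIPLES,
    WindowLayout,
)
from ..exposure import FusProtocol

__all__ = ["EmissionScenario", "simulate_pcd"]

#: band limits of the simulated broadband (inertial) emission, Hz
BROADBAND_LO = 0.3e6
BROADBAND_HI = 6.0e6


@dataclass(frozen=True)
class EmissionScenario:
    """Acoustic content of a simulated sonication.

    Parameters
    ----------
    harmonic_amps : amplitudes (a.u.) of sinusoids at 2, 3, 4 x f0.
    ultraharmonic_amps : amplitudes at 1.5, 2.5, 3.5 x f0.
    broadband_bursts : tuples ``(pulse_index, (w_lo, w_hi), density)``:
        band-limited white noise (0.3-6 MHz) of amplitude scale ``density``
        injected into analysis windows ``w_lo..w_hi`` (inclusive) of the
        given burst.
    background_noise_sd : white Gaussian noise s.d. over the whole recording.
    transient_amp : amplitude of the decaying switch-on chirp occupying the
        head-cut interval of every burst (0 disables it).
    seed : RNG seed; identical seed and configuration give bit-identical
        output.
    """

    harmonic_amps: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ultraharmonic_amps: tuple[float, float, float] = (0.0, 0.0, 0.0)
    broadband_bursts: tuple[tuple[int, tuple[int, int], float], ...] = ()
    background_noise_sd: float = 0.0
    transient_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (*self.harmonic_amps, *self.ultraharmonic_amps):
            if a < 0:
                raise ValueError("amplitudes must be nonnegative")
        if self.background_noise_sd < 0:
            raise ValueError("noise s.d. must be nonnegative")


def _bandlimited_noise(rng: np.random.Generator, n: int, sd: float, fs: float) -> np.ndarray:
    """White noise spectrally masked to the broadband emission band.

    The in-band spectral level equals that of white noise of s.d. ``sd``;
    out-of-band bins are zeroed.
    """
    white = rng.normal(0.0, sd, size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < BROADBAND_LO) | (freqs > BROADBAND_HI)] = 0.0
    return np.fft.irfft(spec, n=n)


def simulate_pcd(
    protocol: FusProtocol,
    scenario: EmissionScenario,
    layout: WindowLayout | None = None,
) -> PCDRecording:
    """Render a PCD recording for the given protocol and emission scenario.

    Burst window indices in ``scenario.broadband_bursts`` refer to the
    analysis windows defined by ``layout`` (default layout if omitted).
    """
    layout = layout or WindowLayout()
    fs = protocol.sampling_rate
    f0 = protocol.center_frequency
    spp = protocol.samples_per_pulse
    nwin = layout.n_windows(protocol.pulse_length)
    spw = layout.samples_per_window(fs)
    head = int(round(layout.head_cut * fs))

    for pulse_idx, (w_lo, w_hi), density in scenario.broadband_bursts:
        if not 0 <= pulse_idx < protocol.n_pulses:
            raise ValueError(f"burst pulse index {pulse_idx} out of range")
        if not (0 <= w_lo <= w_hi < nwin):
            raise ValueError(f"burst window range ({w_lo}, {w_hi}) outside 0..{nwin - 1}")
        if density < 0:
            raise ValueError("broadband density must be nonnegative")

    rng = np.random.default_rng(scenario.seed)
    t = np.arange(spp) / fs

    tones = np.zeros(spp)
    for mult, amp in zip(HARMONIC_MULTIPLES, scenario.harmonic_amps):
        if amp > 0:
            tones += amp * np.sin(2 * np.pi * mult * f0 * t)
    for mult, amp in zip(ULTRAHARMONIC_MULTIPLES, scenario.ultraharmonic_amps):
        if amp > 0:
            tones += amp * np.sin(2 * np.pi * mult * f0 * t)

    transient = np.zeros(spp)
    if scenario.transient_amp > 0 and head > 0:
        th = t[:head]
        tau = layout.head_cut / 4.0
        # frequency sweeping f0 -> 3 f0 across the head interval
        sweep = f0 * (1.0 + 2.0 * th / layout.head_cut)
        transient[:head] = scenario.transient_amp * np.exp(-th / tau) * np.sin(
            2 * np.pi * sweep * th
        )

    pulses = np.empty((protocol.n_pulses, spp), dtype=np.float64)
    for p in range(protocol.n_pulses):
        sig = tones + transient
        if scenario.background_noise_sd > 0:
            sig = sig + rng.normal(0.0, scenario.background_noise_sd, size=spp)
        else:
            sig = sig.copy()
        pulses[p] = sig
    for pulse_idx, (w_lo, w_hi), density in scenario.broadband_bursts:
        a = head + w_lo * spw
        b = head + (w_hi + 1) * spw
        pulses[pulse_idx, a:b] += _bandlimited_noise(rng, b - a, density, fs)

    samples = pulses.reshape(-1).astype(np.float32)
    starts = np.arange(protocol.n_pulses, dtype=np.int64) * spp
    return PCDRecording(
        samples=samples,
        sampling_rate=fs,
        f0=f0,
        pulse_starts=starts,
        pulse_length=protocol.pulse_length,
    )
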