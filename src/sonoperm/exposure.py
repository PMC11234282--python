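"""Acoustic exposure bookkeeping: burst timing, pressure derating, mechanical index.

The therapy sequence is a train of long tone bursts (tens of ms) at a
repetition frequency around 1 Hz, so the duty cycle stays low enough to avoid
thermal buildup. In-situ peak negative pressure (PNP) is estimated from the
free-field calibration by attenuating through skull and brain tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FusProtocol",
    "mechanical_index",
    "derate_pressure",
]


@dataclass(frozen=True)
class FusProtocol:
    """Focused-ultrasound burst sequence parameters.

    Parameters
    ----------
    center_frequency : float
        Transmit center frequency f0 in Hz.
    pulse_length : float
        Burst (tone pulse) duration in seconds.
    prf : float
        Pulse repetition frequency in Hz.
    n_pulses : int
        Number of bursts in the sequence.
    target_pnp : float
        Target in-situ peak negative pressure, MPa.
    sampling_rate : float
        Acquisition sampling rate of the passive cavitation detector, Hz.
        Must resolve at least the 4th harmonic of f0.
    """

    center_frequency: float = 1.5e6
    pulse_length: float = 0.050
    prf: float = 1.0
    n_pulses: int = 60
    target_pnp: float = 0.6
    sampling_rate: float = 15.625e6

    def __post_init__(self) -> None:
        if self.center_frequency <= 0 or self.sampling_rate <= 0:
            raise ValueError("frequencies must be positive")
        if self.pulse_length <= 0 or self.prf <= 0:
            raise ValueError("pulse_length and prf must be positive")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if not 0.0 < self.duty_cycle <= 1.0:
            raise ValueError(
                f"duty cycle {self.duty_cycle:.3f} outside (0, 1]: "
                "pulse_length * prf must not exceed 1"
            )
        # Need spectral headroom for the 4th harmonic band.
        if self.sampling_rate <= 2 * 4 * self.center_frequency:
            raise ValueError(
                "sampling_rate must exceed twice the 4th harmonic "
                f"(got {self.sampling_rate:g} Hz for f0 {self.center_frequency:g} Hz)"
            )

    @property
    def duty_cycle(self) -> float:
        """Fraction of time transmitting: pulse_length * prf."""
        return self.pulse_length * self.prf

    @property
    def samples_per_pulse(self) -> int:
        return int(round(self.pulse_length * self.sampling_rate))


def mechanical_index(pnp_mpa: float, frequency_mhz: float) -> float:
    """Mechanical index: PNP (MPa) divided by the square root of frequency (MHz)."""
    if pnp_mpa < 0:
        raise ValueError("PNP must be nonnegative")
    if frequency_mhz <= 0:
        raise ValueError("frequency must be positive")
    return pnp_mpa / math.sqrt(frequency_mhz)


def derate_pressure(
    free_field_pnp: float,
    frequency_mhz: float,
    brain_depth_m: float,
    alpha_brain: float = 5.0,
    skull_transmission: float = 1.0,
) -> float:
    """Derate a free-field PNP to the in-situ value at a given brain depth.

    in_situ = free_field * skull_transmission * exp(-alpha * f * depth)

    Parameters
    ----------
    free_field_pnp : float
        Calibrated free-field peak negative pressure, MPa.
    frequency_mhz : float
        Center frequency in MHz.
    brain_depth_m : float
        Path length through brain tissue, metres.
    alpha_brain : float
        Brain amplitude attenuation coefficient, Np/m/MHz (default 5).
    skull_transmission : float
        Skull pressure transmission factor in (0, 1].
    """
    if free_field_pnp < 0:
        raise ValueError("free-field PNP must be nonnegative")
    if brain_depth_m < 0:
        raise ValueError("depth must be nonnegative")
    if not 0.0 < skull_transmission <= 1.0:
        raise ValueError("skull_transmission must lie in (0, 1]")
    return free_field_pnp * skull_transmission * math.exp(
        -alpha_brain * frequency_mhz * brain_depth_m
    )
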