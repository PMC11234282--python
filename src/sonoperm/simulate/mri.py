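"""Digital phantom and signal-level MRI forward models.

The phantom is a cortex-like slab with mirrored contralateral/ipsilateral
hemispheres and a BBB-opened core inside the ipsilateral region; each region
carries ground-truth CBF, BVf, ADC, T1 and Gd-enhancement values. Forward
models are the exact inverses of the quantification formulas in
:mod:`sonoperm.mri` (single-compartment pCASL difference signal, magnitude
inversion recovery, mono-exponential multi-echo decay with a
susceptibility-driven post-contrast R2* increase, mono-exponential diffusion
attenuation, multiplicative post-Gd T1-weighted enhancement), evaluated at
the signal-equation level — no k-space or physics simulation. Magnitude
noise is Rician (Gaussian on the two complex channels) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..mri import AslModelParams, SusceptibilityConstants

__all__ = [
    "Phantom",
    "PcaslParams",
    "IrParams",
    "MgeParams",
    "DwiParams",
    "T1wParams",
    "PcaslSeries",
    "IrSeries",
    "MgeSeries",
    "DwiSeries",
    "T1wPair",
    "fibonacci_directions",
    "simulate_mri",
]

LABEL_BACKGROUND = 0
LABEL_CONTRA = 1
LABEL_IPSI = 2
LABEL_CORE = 3


@dataclass
class Phantom:
    """Ground-truth parameter volumes for the forward models.

    label_map codes: 0 background, 1 contralateral ROI, 2 ipsilateral ROI,
    3 BBB-opened core (a subset of the ipsilateral support).
    """

    label_map: np.ndarray
    truth_cbf: np.ndarray  # mL/100g/min
    truth_bvf: np.ndarray  # %
    truth_adc: np.ndarray  # mm^2/s
    truth_t1: np.ndarray  # s
    truth_enhancement: np.ndarray  # %
    voxel_size: tuple[float, float, float] = (0.234, 0.234, 1.5)
    m0: float = 100.0
    r2s_baseline: float = 30.0  # s^-1, pre-contrast R2*
    kappa: float = 1.0  # inversion factor of the IR acquisition
    alpha: float = 0.85  # labelling efficiency realized by the scanner
    seed: int = 0

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        maps = [self.truth_cbf, self.truth_bvf, self.truth_adc, self.truth_t1, self.truth_enhancement]
        for m in maps:
            arr = np.asarray(m)
            if arr.shape != self.label_map.shape:
                raise ValueError("truth maps and label_map must share shape")
            if np.any(arr < 0):
                raise ValueError("truth maps must be nonnegative")
        core = self.label_map == LABEL_CORE
        ipsi = self.label_map == LABEL_IPSI
        if core.any():
            # the opened core must sit inside the ipsilateral region: every
            # core voxel borders ipsilateral (or other core) tissue
            from scipy import ndimage as _ndi

            surround = _ndi.binary_dilation(core) & ~core
            if not ipsi.any() or not (surround & ipsi).any():
                raise ValueError("BBB-opened core must lie inside the ipsilateral ROI")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_map > 0

    @property
    def contra_mask(self) -> np.ndarray:
        return self.label_map == LABEL_CONTRA

    @property
    def ipsi_mask(self) -> np.ndarray:
        """Ipsilateral ROI including the opened core."""
        return (self.label_map == LABEL_IPSI) | (self.label_map == LABEL_CORE)

    @property
    def core_mask(self) -> np.ndarray:
        return self.label_map == LABEL_CORE

    @classmethod
    def cortex_slab(
        cls,
        shape: tuple[int, int, int] = (64, 64, 8),
        voxel_size: tuple[float, float, float] = (0.234, 0.234, 1.5),
        cbf: tuple[float, float] = (93.57, 42.24),
        bvf: tuple[float, float] = (3.9, 3.4),
        adc: tuple[float, float] = (1.0e-3, 1.0e-3),
        t1: tuple[float, float] = (1.5, 1.5),
        core_enhancement: float = 18.66,
        core_fraction: float = 0.05,
        margin: int = 4,
        seed: int = 0,
        **kwargs,
    ) -> "Phantom":
        """Mirrored two-hemisphere slab with an enhanced core in the ipsilateral side.

        ``cbf``/``bvf``/``adc``/``t1`` give (contralateral, ipsilateral)
        region values; the core occupies ``core_fraction`` of the ipsilateral
        volume and is the only region with nonzero Gd enhancement.
        """
        nx, ny, nz = shape
        label = np.zeros(shape, dtype=np.int16)
        xs = slice(margin, nx - margin)
        ys = slice(margin, ny - margin)
        label[xs, ys, :] = LABEL_CONTRA
        label[nx // 2 : nx - margin, ys, :] = LABEL_IPSI

        ipsi = label == LABEL_IPSI
        n_core = max(1, int(round(core_fraction * ipsi.sum())))
        # compact core: voxels nearest the ipsilateral centroid
        idx = np.argwhere(ipsi)
        centroid = idx.mean(axis=0)
        order = np.argsort(((idx - centroid) ** 2).sum(axis=1), kind="stable")
        chosen = idx[order[:n_core]]
        label[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = LABEL_CORE

        contra = label == LABEL_CONTRA
        ipsi_all = (label == LABEL_IPSI) | (label == LABEL_CORE)

        def region_map(pair: tuple[float, float]) -> np.ndarray:
            out = np.zeros(shape)
            out[contra] = pair[0]
            out[ipsi_all] = pair[1]
            return out

        enh = np.zeros(shape)
        enh[label == LABEL_CORE] = core_enhancement
        return cls(
            label_map=label,
            truth_cbf=region_map(cbf),
            truth_bvf=region_map(bvf),
            truth_adc=region_map(adc),
            truth_t1=region_map(t1),
            truth_enhancement=enh,
            voxel_size=voxel_size,
            seed=seed,
            **kwargs,
        )


# --- acquisition parameter records -----------------------------------------


@dataclass(frozen=True)
class PcaslParams:
    tau: float = 3.0  # label duration, s
    pld: float = 0.3  # post-labelling delay, s
    n_repetitions: int = 30


@dataclass(frozen=True)
class IrParams:
    """Inversion-recovery series: 18 TIs log-spaced between 30 ms and 10 s."""

    tis: tuple[float, ...] = tuple(np.geomspace(0.030, 10.0, 18))


@dataclass(frozen=True)
class MgeParams:
    te1: float = 3.5e-3
    delta_te: float = 5.0e-3
    n_echoes: int = 8

    @property
    def tes(self) -> np.ndarray:
        return self.te1 + self.delta_te * np.arange(self.n_echoes)


@dataclass(frozen=True)
class DwiParams:
    bval: float = 1000.0  # s/mm^2
    n_directions: int = 30


@dataclass(frozen=True)
class T1wParams:
    base_intensity: float = 100.0


# --- series containers ------------------------------------------------------


@dataclass
class PcaslSeries:
    control: np.ndarray  # (n_rep, *vol)
    label: np.ndarray
    params: PcaslParams
    #: downstream vessel-slice pair for inversion-efficiency estimation
    alpha_control: np.ndarray
    alpha_label: np.ndarray
    vessel_mask: np.ndarray


@dataclass
class IrSeries:
    signals: np.ndarray  # (n_ti, *vol)
    tis: np.ndarray


@dataclass
class MgeSeries:
    pre: np.ndarray  # (n_echo, *vol)
    post: np.ndarray
    tes: np.ndarray


@dataclass
class DwiSeries:
    b0: np.ndarray
    dwi: np.ndarray  # (n_dir, *vol)
    bval: float
    directions: np.ndarray


@dataclass
class T1wPair:
    pre: np.ndarray
    post: np.ndarray


def fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _add_noise(
    rng: np.random.Generator, signal: np.ndarray, sd: float, rician: bool
) -> np.ndarray:
    if sd == 0:
        return signal.copy()
    if rician:
        re = signal + rng.normal(0.0, sd, size=signal.shape)
        im = rng.normal(0.0, sd, size=signal.shape)
        return np.hypot(re, im)
    return signal + rng.normal(0.0, sd, size=signal.shape)


def simulate_mri(
    phantom: Phantom,
    acquisition: str,
    params=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    rician: bool = True,
):
    """Forward-simulate one acquisition from the phantom.

    ``acquisition`` is one of ``pcasl``, ``ir_t1``, ``mge_pre_post``, ``dwi``,
    ``t1w_pre_post_gd``. Magnitude (Rician) noise of scale ``noise_sd`` is
    applied to every frame; the same seed reproduces the series bit for bit.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    brain = phantom.brain_mask
    m0 = np.where(brain, phantom.m0, 0.0)
    t1 = np.where(brain, phantom.truth_t1, np.nan)

    if acquisition == "pcasl":
        p = params or PcaslParams()
        with np.errstate(invalid="ignore", divide="ignore"):
            dm = (
                phantom.truth_cbf
                * 2.0
                * phantom.alpha
                * t1
                * m0
                * (1.0 - np.exp(-p.tau / t1))
                / (6000.0 * 0.9 * np.exp(p.pld / t1))
            )
        dm = np.where(brain, dm, 0.0)
        control = np.stack(
            [_add_noise(rng, m0, noise_sd, rician) for _ in range(p.n_repetitions)]
        )
        label = np.stack(
            [_add_noise(rng, m0 - dm, noise_sd, rician) for _ in range(p.n_repetitions)]
        )
        # vessel slice downstream of the labelling plane: bright blood signal.
        # The pair is phase-corrected (signed), as the efficiency formula
        # |control - label| / (2 |control|) requires; noise is Gaussian here.
        vessel_mask = np.zeros(brain.shape[:2], dtype=bool)
        cx, cy = brain.shape[0] // 2, brain.shape[1] // 2
        vessel_mask[cx - 2 : cx + 2, cy - 2 : cy + 2] = True
        v_control = np.where(vessel_mask, 2.0 * phantom.m0, 0.1 * phantom.m0)
        v_label = np.where(
            vessel_mask, v_control * (1.0 - 2.0 * phantom.alpha), v_control
        )
        return PcaslSeries(
            control=control,
            label=label,
            params=p,
            alpha_control=_add_noise(rng, v_control, noise_sd, rician=False),
            alpha_label=_add_noise(rng, v_label, noise_sd, rician=False),
            vessel_mask=vessel_mask,
        )

    if acquisition == "ir_t1":
        p = params or IrParams()
        tis = np.asarray(p.tis, dtype=float)
        with np.errstate(invalid="ignore"):
            sig = np.abs(
                m0[None]
                * (1.0 - 2.0 * phantom.kappa * np.exp(-tis[:, None, None, None] / t1[None]))
            )
        sig = np.where(brain[None], sig, 0.0)
        return IrSeries(signals=_add_noise(rng, sig, noise_sd, rician), tis=tis)

    if acquisition == "mge_pre_post":
        p = params or MgeParams()
        tes = p.tes
        consts = SusceptibilityConstants()
        dr2s = (
            phantom.truth_bvf
            / 100.0
            * (4.0 * np.pi / 3.0)
            * consts.gamma
            * consts.delta_chi
            * consts.b0
        )
        r2s_pre = np.where(brain, phantom.r2s_baseline, phantom.r2s_baseline)
        r2s_post = r2s_pre + np.where(brain, dr2s, 0.0)
        s0 = np.where(brain, phantom.m0, 0.05 * phantom.m0)
        pre = s0[None] * np.exp(-tes[:, None, None, None] * r2s_pre[None])
        post = s0[None] * np.exp(-tes[:, None, None, None] * r2s_post[None])
        return MgeSeries(
            pre=_add_noise(rng, pre, noise_sd, rician),
            post=_add_noise(rng, post, noise_sd, rician),
            tes=tes,
        )

    if acquisition == "dwi":
        p = params or DwiParams()
        dirs = fibonacci_directions(p.n_directions)
        s0 = np.where(brain, phantom.m0, 0.05 * phantom.m0)
        adc = np.where(brain, phantom.truth_adc, 1e-5)
        att = np.exp(-p.bval * adc)
        dwi = np.stack(
            [_add_noise(rng, s0 * att, noise_sd, rician) for _ in range(p.n_directions)]
        )
        return DwiSeries(
            b0=_add_noise(rng, s0, noise_sd, rician),
            dwi=dwi,
            bval=p.bval,
            directions=dirs,
        )

    if acquisition == "t1w_pre_post_gd":
        p = params or T1wParams()
        pre = np.where(brain, p.base_intensity, 0.02 * p.base_intensity)
        post = pre * (1.0 + phantom.truth_enhancement / 100.0)
        return T1wPair(
            pre=_add_noise(rng, pre, noise_sd, rician),
            post=_add_noise(rng, post, noise_sd, rician),
        )

    raise ValueError(f"unknown acquisition kind {acquisition!r}")


def asl_model_params_from(phantom: Phantom, t1_map=None, m0_map=None, alpha=None) -> AslModelParams:
    """Convenience: model parameters matching the phantom's forward model."""
    brain = phantom.brain_mask
    return AslModelParams(
        tau=PcaslParams().tau,
        pld=PcaslParams().pld,
        lam=0.9,
        alpha=phantom.alpha if alpha is None else alpha,
        t1_map=np.where(brain, phantom.truth_t1, np.nan) if t1_map is None else t1_map,
        m0_map=np.where(brain, phantom.m0, np.nan) if m0_map is None else m0_map,
    )
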