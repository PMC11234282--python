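"""Synthetic fluorescence microscopy fixtures with known ground truth.

Renders three object kinds on a 2-D canvas: *cell* blobs (a disk body with
radial protrusions, emulating ramified/amoeboid glial shapes), *vessel*
tubes swept along an explicit centerline polyline with a known radius, and
*rbc* point clusters. The returned truth masks and centerlines serve as
oracles for segmentation and morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["FluorObject", "FluorScene", "simulate_fluorescence", "sine_path", "arc_path"]


@dataclass(frozen=True)
class FluorObject:
    """One renderable object.

    kind : 'cell' | 'vessel' | 'rbc'
    geometry : cell -> (cy, cx, radius, n_arms, arm_length);
               vessel -> (path, radius) with path an (N, 2) row/col polyline;
               rbc -> (N, 2) array of point coordinates.
    intensity : peak intensity added inside the object, a.u.
    """

    kind: str
    geometry: tuple
    intensity: float


@dataclass
class FluorScene:
    image: np.ndarray
    truth_masks: dict  # kind -> boolean mask
    centerlines: list  # (path, radius) per vessel
    rbc_points: np.ndarray  # all rbc coordinates, (N, 2)


def sine_path(start: tuple[float, float], length: float, amplitude: float, period: float, n: int = 200) -> np.ndarray:
    """Horizontal sinusoidal centerline (row oscillates, col advances)."""
    x = np.linspace(0, length, n)
    return np.column_stack([start[0] + amplitude * np.sin(2 * np.pi * x / period), start[1] + x])


def arc_path(center: tuple[float, float], radius: float, theta0: float, theta1: float, n: int = 400) -> np.ndarray:
    """Circular-arc centerline from theta0 to theta1 (radians)."""
    th = np.linspace(theta0, theta1, n)
    return np.column_stack([center[0] + radius * np.sin(th), center[1] + radius * np.cos(th)])


def _dist_to_polyline(shape: tuple[int, int], path: np.ndarray) -> np.ndarray:
    """Distance from every pixel to a densely sampled polyline."""
    # rasterize the path onto the grid and distance-transform its complement
    on = np.zeros(shape, dtype=bool)
    # densify so consecutive samples are < 0.5 px apart
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    pts = [path[0]]
    for i, L in enumerate(seglen):
        k = max(1, int(np.ceil(L / 0.5)))
        for j in range(1, k + 1):
            pts.append(path[i] + seg[i] * (j / k))
    pts = np.asarray(pts)
    rr = np.clip(np.round(pts[:, 0]).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int), 0, shape[1] - 1)
    on[rr, cc] = True
    return ndimage.distance_transform_edt(~on)


def simulate_fluorescence(
    shape: tuple[int, int],
    objects: Sequence[FluorObject],
    background_sd: float = 0.0,
    background_level: float = 0.0,
    seed: int = 0,
) -> FluorScene:
    """Render the objects onto a canvas and return image plus truth masks."""
    if background_sd < 0:
        raise ValueError("background_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    img = np.full(shape, float(background_level))
    masks = {"cell": np.zeros(shape, bool), "vessel": np.zeros(shape, bool), "rbc": np.zeros(shape, bool)}
    centerlines: list = []
    rbc_pts: list = []

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for obj in objects:
        if obj.kind == "cell":
            cy, cx, radius, n_arms, arm_len = obj.geometry
            if not (0 <= cy < shape[0] and 0 <= cx < shape[1]):
                raise ValueError("cell center outside canvas")
            r = np.hypot(yy - cy, xx - cx)
            body = r <= radius
            mask = body.copy()
            ang = np.arctan2(yy - cy, xx - cx)
            for a in range(int(n_arms)):
                theta = 2 * np.pi * a / max(1, int(n_arms))
                dang = np.angle(np.exp(1j * (ang - theta)))
                mask |= (r <= radius + arm_len) & (np.abs(dang) < 0.18)
            img[mask] += obj.intensity
            masks["cell"] |= mask
        elif obj.kind == "vessel":
            path, radius = obj.geometry
            path = np.asarray(path, dtype=float)
            if path[:, 0].min() < 0 or path[:, 0].max() >= shape[0] or path[:, 1].min() < 0 or path[:, 1].max() >= shape[1]:
                raise ValueError("vessel path outside canvas")
            mask = _dist_to_polyline(shape, path) <= radius
            img[mask] += obj.intensity
            masks["vessel"] |= mask
            centerlines.append((path, float(radius)))
        elif obj.kind == "rbc":
            pts = np.asarray(obj.geometry, dtype=float)
            if pts.min() < 0 or pts[:, 0].max() >= shape[0] or pts[:, 1].max() >= shape[1]:
                raise ValueError("rbc point outside canvas")
            for py, px in pts:
                mask = np.hypot(yy - py, xx - px) <= 1.5
                img[mask] += obj.intensity
                masks["rbc"] |= mask
            rbc_pts.extend(pts.tolist())
        else:
            raise ValueError(f"unknown object kind {obj.kind!r}")

    if background_sd > 0:
        img = img + rng.normal(0.0, background_sd, size=shape)
    return FluorScene(
        image=img,
        truth_masks=masks,
        centerlines=centerlines,
        rbc_points=np.asarray(rbc_pts) if rbc_pts else np.empty((0, 2)),
    )
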