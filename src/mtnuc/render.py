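"""Forward imaging model: trajectories -> kymographs, templates -> spot fields.

A kymograph is the standard position-vs-time representation of a single
filament: one row per acquired frame, one column per pixel along the
filament axis.  Rendering integrates the point-spread function over the
filament segment, so each end appears as an error-function edge whose
half-maximum crossing sits exactly at the true end position — the property
the edge-tracking stage relies on.  Spot images are sums of Gaussians at
the template positions, emulating the single-molecule template channel.
Both renderers add white Gaussian read noise and are deterministic for a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "Kymograph",
    "SpotImage",
    "render_kymograph",
    "render_spot_image",
    "write_kymograph_tiff",
    "read_kymograph_tiff",
    "write_image_png",
]

#: Default optics: camera sampling of a 60x TIRF objective and a diffraction
#: limited PSF for far-red emission.  Intensities are arbitrary units.
DEFAULT_PIXEL_SIZE_UM = 0.107
DEFAULT_PSF_FWHM_UM = 0.30
DEFAULT_NOISE_SD = 0.1

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass(frozen=True)
class Kymograph:
    """Position-time intensity image of one filament."""

    intensity: np.ndarray          # (n_frames, n_pixels), arbitrary units
    pixel_size: float              # um per column
    frame_interval: float          # s per row
    origin: float                  # axis coordinate (um) of column 0 centre
    event_id: int = -1
    config_key: str = ""

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    def column_positions(self) -> np.ndarray:
        """Axis coordinate (um) of each column centre."""
        return self.origin + np.arange(self.intensity.shape[1]) * self.pixel_size

    def mirrored(self) -> "Kymograph":
        """Left-right mirrored copy (used for symmetry checks)."""
        return dataclasses.replace(self, intensity=self.intensity[:, ::-1].copy())


@dataclasses.dataclass(frozen=True)
class SpotImage:
    """Single channel image of point-like templates with ground truth."""

    intensity: np.ndarray          # (ny, nx)
    pixel_size: float              # um
    true_coords: np.ndarray        # (n, 2) array of (row, col) pixel coords


def _segment_profile(x: np.ndarray, lo: float, hi: float,
                     sigma: float) -> np.ndarray:
    """PSF-blurred image of a unit-intensity segment [lo, hi] sampled at x.

    The integral of a normalised Gaussian over the segment; at each edge the
    profile crosses half the plateau value exactly at the segment end (for
    segments long compared to sigma).
    """
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((hi - x) / s) - erf((lo - x) / s))


def render_kymograph(traj: pd.DataFrame, pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                     psf_fwhm: float = DEFAULT_PSF_FWHM_UM,
                     noise_sd: float = DEFAULT_NOISE_SD,
                     seed: int = 0, intensity: float = 1.0,
                     margin_um: float = 2.0,
                     frame_interval: Optional[float] = None) -> Kymograph:
    """Render one filament trajectory into a kymograph.

    ``traj`` must hold a single filament's rows (columns ``t``,
    ``plus_end_pos``, ``minus_end_pos`` in um).  Each frame shows the
    segment [minus_end, plus_end] convolved with a Gaussian PSF of the
    given FWHM, plus additive Gaussian read noise.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if "event_id" in traj and traj["event_id"].nunique() > 1:
        raise ValueError("render_kymograph expects a single filament")

    t = np.asarray(traj["t"], dtype=float)
    plus = np.asarray(traj["plus_end_pos"], dtype=float)
    minus = np.asarray(traj["minus_end_pos"], dtype=float)
    if frame_interval is None:
        frame_interval = float(np.median(np.diff(t))) if t.size > 1 else 1.0

    lo = float(minus.min()) - margin_um
    hi = float(plus.max()) + margin_um
    n_px = max(8, int(np.ceil((hi - lo) / pixel_size)))
    x = lo + (np.arange(n_px) + 0.5) * pixel_size
    sigma = psf_fwhm * _FWHM_TO_SIGMA

    img = np.empty((t.size, n_px))
    for i in range(t.size):
        img[i] = intensity * _segment_profile(x, minus[i], plus[i], sigma)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)

    event_id = int(traj["event_id"].iloc[0]) if "event_id" in traj else -1
    return Kymograph(intensity=img, pixel_size=pixel_size,
                     frame_interval=frame_interval,
                     origin=float(x[0]), event_id=event_id,
                     config_key=str(traj.attrs.get("config_key", "")))


def render_spot_image(coords: Sequence[Tuple[float, float]] | np.ndarray,
                      shape: Tuple[int, int] = (512, 512),
                      pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                      psf_fwhm: float = DEFAULT_PSF_FWHM_UM,
                      intensity: float = 1.0,
                      noise_sd: float = DEFAULT_NOISE_SD,
                      seed: int = 0) -> SpotImage:
    """Render point templates as a sum of Gaussian spots plus read noise.

    ``coords`` are (row, col) positions in pixels; um positions should be
    divided by ``pixel_size`` by the caller.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    ny, nx = shape
    img = np.zeros(shape)
    sigma_px = psf_fwhm * _FWHM_TO_SIGMA / pixel_size
    half = max(3, int(np.ceil(4.0 * sigma_px)))
    for r, c in coords:
        r0, r1 = int(np.floor(r)) - half, int(np.floor(r)) + half + 1
        c0, c1 = int(np.floor(c)) - half, int(np.floor(c)) + half + 1
        rr = np.arange(max(0, r0), min(ny, r1))
        cc = np.arange(max(0, c0), min(nx, c1))
        if rr.size == 0 or cc.size == 0:
            continue
        g = np.exp(-((rr[:, None] - r) ** 2 + (cc[None, :] - c) ** 2)
                   / (2.0 * sigma_px ** 2))
        img[rr[0]:rr[-1] + 1, cc[0]:cc[-1] + 1] += intensity * g
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return SpotImage(intensity=img, pixel_size=pixel_size, true_coords=coords)


def write_kymograph_tiff(k: Kymograph, path: str | Path) -> None:
    """Write a kymograph as 16-bit TIFF with a JSON calibration sidecar."""
    import tifffile

    path = Path(path)
    img = k.intensity
    lo, hi = float(img.min()), float(img.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    tifffile.imwrite(path, ((img - lo) * scale).astype(np.uint16))
    sidecar = {
        "pixel_size_um": k.pixel_size,
        "frame_interval_s": k.frame_interval,
        "origin_um": k.origin,
        "event_id": k.event_id,
        "config_key": k.config_key,
        "intensity_offset": lo,
        "intensity_scale": scale,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def write_image_png(intensity: np.ndarray, path: str | Path) -> None:
    """Write any intensity matrix as an 8-bit PNG (display convenience)."""
    import imageio.v3 as iio

    img = np.asarray(intensity, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    iio.imwrite(Path(path), ((img - lo) * scale).astype(np.uint8))


def read_kymograph_tiff(path: str | Path) -> Kymograph:
    """Read a kymograph TIFF written by :func:`write_kymograph_tiff`."""
    import tifffile

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    raw = tifffile.imread(path).astype(float)
    img = raw / meta["intensity_scale"] + meta["intensity_offset"]
    return Kymograph(intensity=img, pixel_size=meta["pixel_size_um"],
                     frame_interval=meta["frame_interval_s"],
                     origin=meta["origin_um"], event_id=meta["event_id"],
                     config_key=meta.get("config_key", ""))
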