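"""Hybrid radiosity-radiance free-space model: surface flux to detector.

Photons escaping the tissue surface propagate through non-scattering space
to a lens-coupled planar detector (the noncontact CCD geometry).  Each
surface element of flux density ``J_n`` (W/mm^2) acts as a Lambertian
source of radiance ``L = J_n / pi``; a detector pixel of area ``dA``
receives, from an element of area ``dS`` at distance ``|r_d - r|``,

    dP = (1/pi) J_n cos(theta_s) cos(theta_d) dS dA / |r_d - r|^2,

the cosines measuring the element and detector orientations against the
line of sight (clamped at zero: back-facing contributes nothing).

Two rendering modes exist.  SIMPLE sums the expression above per pixel —
a lens-free direct integration, exact for the radiosity model and the
validated path of this package.  LENS additionally applies a thin-lens
magnification/visibility correction; the printed form of that correction is
ambiguous in its source, so LENS mode implements one documented
interpretation (offset length t*u2*cos(theta)/f along the line of sight in
the denominator, u2 being the surface point's axial distance to the lens
plane) and should be treated as qualitative; for f -> infinity at fixed
magnification it reduces to SIMPLE times t^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import Scene, _as_vec
from . import _kernels as _k

__all__ = [
    "SurfaceElement", "DetectorSpec", "LensSpec", "DetectorImage",
    "radiance_from_flux", "differential_power", "visibility_factor",
    "render_detector", "extract_profile",
]


@dataclass
class SurfaceElement:
    """One patch of the organism surface carrying escaped flux."""
    centroid: np.ndarray      # mm
    normal: np.ndarray        # outward unit vector
    area: float               # mm^2
    flux_density: float       # J_n, W/mm^2

    def __post_init__(self):
        self.centroid = _as_vec(self.centroid)
        self.normal = _as_vec(self.normal)
        if self.area <= 0:
            raise ValueError("element area must be positive")
        if self.flux_density < 0:
            raise ValueError("flux density must be nonnegative")


@dataclass
class DetectorSpec:
    """Planar pixelated detector.

    The pixel grid spans ``width`` (columns, first in-plane axis) by
    ``height`` (rows, second in-plane axis) centered at ``center`` with the
    plane normal ``normal`` pointing toward the scene.
    """
    center: np.ndarray
    normal: np.ndarray
    width: float
    height: float
    pixels: tuple  # (rows, cols)
    up: Optional[np.ndarray] = None   # in-plane row axis; default auto

    def __post_init__(self):
        self.center = _as_vec(self.center)
        self.normal = _as_vec(self.normal)
        self.normal = self.normal / np.linalg.norm(self.normal)
        rows, cols = self.pixels
        if rows < 1 or cols < 1:
            raise ValueError("pixel counts must be positive")
        if self.up is None:
            # choose the global axis least aligned with the normal
            trial = np.eye(3)[np.argmin(np.abs(self.normal))]
            up = trial - (trial @ self.normal) * self.normal
        else:
            up = _as_vec(self.up)
            up = up - (up @ self.normal) * self.normal
        self.up = up / np.linalg.norm(up)
        self.right = np.cross(self.up, self.normal)

    @property
    def pixel_area(self) -> float:
        rows, cols = self.pixels
        return (self.width / cols) * (self.height / rows)

    def pixel_centers(self) -> np.ndarray:
        """(rows, cols, 3) array of pixel-center positions."""
        rows, cols = self.pixels
        u = (np.arange(cols) + 0.5) / cols - 0.5
        v = (np.arange(rows) + 0.5) / rows - 0.5
        uu, vv = np.meshgrid(u * self.width, v * self.height)
        return (self.center
                + uu[..., None] * self.right
                + vv[..., None] * self.up)

    def pixel_row_coords(self) -> np.ndarray:
        """Row coordinates (along ``up``) of pixel centers, in mm."""
        rows = self.pixels[0]
        return ((np.arange(rows) + 0.5) / rows - 0.5) * self.height


@dataclass
class LensSpec:
    """Thin-lens system description for LENS-mode rendering.

    ``u`` and ``v`` are object and image distances along the optical
    ``axis`` from the lens ``center``; the thin-lens law 1/f = 1/u + 1/v
    must hold, and the magnification is ``t = v/u``.  ``mode`` SIMPLE
    ignores the lens entirely (direct radiosity integration).
    """
    mode: str = "simple"            # "simple" | "lens"
    f: float = 0.0                  # focal length, mm
    u: float = 0.0                  # object distance, mm
    v: float = 0.0                  # image distance, mm
    center: Optional[np.ndarray] = None
    axis: Optional[np.ndarray] = None

    def __post_init__(self):
        self.mode = self.mode.lower()
        if self.mode not in ("simple", "lens"):
            raise ValueError("mode must be 'simple' or 'lens'")
        if self.mode == "lens":
            if self.f <= 0 or self.u <= 0 or self.v <= 0:
                raise ValueError("LENS mode needs positive f, u, v")
            if abs(1.0 / self.f - (1.0 / self.u + 1.0 / self.v)) > 1e-9:
                raise ValueError(
                    "thin-lens law 1/f = 1/u + 1/v violated")
            if self.center is None or self.axis is None:
                raise ValueError("LENS mode needs lens center and axis")
            self.center = _as_vec(self.center)
            ax = _as_vec(self.axis)
            self.axis = ax / np.linalg.norm(ax)

    @property
    def magnification(self) -> float:
        return self.v / self.u


class DetectorImage:
    """Per-pixel received power P(r_d) in W, plus the pixel geometry."""

    def __init__(self, power: np.ndarray, detector: DetectorSpec):
        self.power = np.asarray(power, dtype=np.float64)
        self.detector = detector

    @property
    def total_power(self) -> float:
        return float(self.power.sum())

    def save_pgm(self, path, maxval: int = 65535):
        """Plain-text PGM (P2) image, max-normalized."""
        img = self.power
        peak = img.max() if img.max() > 0 else 1.0
        q = np.round(img / peak * maxval).astype(int)
        rows, cols = img.shape
        with open(path, "w") as fh:
            fh.write(f"P2\n{cols} {rows}\n{maxval}\n")
            for r in range(rows):
                fh.write(" ".join(str(v) for v in q[r]) + "\n")

    def save_tsv(self, path):
        np.savetxt(path, self.power, delimiter="\t", fmt="%.9g")


def radiance_from_flux(flux_density) -> np.ndarray:
    """Lambertian radiance L = J_n / pi (W mm^-2 sr^-1)."""
    j = np.asarray(flux_density, dtype=np.float64)
    if (j < 0).any():
        raise ValueError("flux density must be nonnegative")
    return j / math.pi


def differential_power(elem: SurfaceElement, pixel_center, pixel_normal,
                       pixel_area: float) -> float:
    """Radiosity power transfer from one surface element to one pixel.

    dP = (1/pi) J_n cos(theta_s) cos(theta_d) dS dA / |r_d - r|^2, clamped
    to zero when either side faces away.
    """
    rd = _as_vec(pixel_center)
    nd = _as_vec(pixel_normal)
    sep = rd - elem.centroid
    dist2 = float(sep @ sep)
    if dist2 <= 0:
        raise ValueError("pixel and element coincide")
    s = sep / math.sqrt(dist2)
    cos_s = float(s @ elem.normal)
    cos_d = float(-s @ nd)
    if cos_s <= 0.0 or cos_d <= 0.0:
        return 0.0
    return (elem.flux_density / math.pi * cos_s * cos_d
            * elem.area * pixel_area / dist2)


def visibility_factor(elem: SurfaceElement, lens: LensSpec,
                      scene: Optional[Scene] = None) -> int:
    """1 iff the element faces the lens center and the sight line is not
    self-occluded by the scene surface; cos(theta_s) = 0 counts invisible."""
    to_lens = lens.center - elem.centroid
    dist = np.linalg.norm(to_lens)
    if dist <= 0:
        return 0
    s = to_lens / dist
    if float(s @ elem.normal) <= 0.0:
        return 0
    if scene is not None:
        pk = scene.pack()
        # nudge off the surface before the occlusion ray test
        p0 = elem.centroid + 1e-6 * elem.normal
        t, *_ = _k.scene_nearest_hit(pk.shape_type, pk.prm, pk.tri,
                                     pk.tri_off, p0[0], p0[1], p0[2],
                                     s[0], s[1], s[2])
        if t < dist - 1e-6:
            return 0
    return 1


def _element_arrays(surface):
    cen = np.array([e.centroid for e in surface])
    nrm = np.array([e.normal for e in surface])
    area = np.array([e.area for e in surface])
    jn = np.array([e.flux_density for e in surface])
    return cen, nrm, area, jn


def render_detector(surface, det: DetectorSpec, lens: LensSpec,
                    scene: Optional[Scene] = None,
                    chunk: int = 4096) -> DetectorImage:
    """Integrate surface radiance into a per-pixel detector image.

    SIMPLE mode sums :func:`differential_power` over all elements per pixel
    (visibility by cosine sign only).  LENS mode weights each element by a
    visibility factor (element faces the lens, no self-occlusion) and uses
    the magnified thin-lens denominator; see the module docstring for the
    interpretation caveat.
    """
    rows, cols = det.pixels
    if len(surface) == 0:
        warnings.warn("empty surface: returning a zero image")
        return DetectorImage(np.zeros((rows, cols)), det)
    cen, nrm, area, jn = _element_arrays(surface)
    pix = det.pixel_centers().reshape(-1, 3)
    dA = det.pixel_area
    out = np.zeros(pix.shape[0])

    if lens.mode == "lens":
        vis = np.array([visibility_factor(e, lens, scene) for e in surface],
                       dtype=float)
        t_mag = lens.magnification
    else:
        vis = None
        t_mag = 1.0

    for lo in range(0, pix.shape[0], chunk):
        hi = min(lo + chunk, pix.shape[0])
        sep = pix[lo:hi, None, :] - cen[None, :, :]     # (P, M, 3)
        dist2 = np.einsum("pmx,pmx->pm", sep, sep)
        dist = np.sqrt(dist2)
        s_hat = sep / dist[..., None]
        cos_s = np.einsum("pmx,mx->pm", s_hat, nrm)
        cos_d = -s_hat @ det.normal
        np.clip(cos_s, 0.0, None, out=cos_s)
        np.clip(cos_d, 0.0, None, out=cos_d)
        if lens.mode == "simple":
            contrib = (jn[None, :] / math.pi * cos_s * cos_d
                       * area[None, :] * dA / dist2)
        else:
            # line of sight vs optical axis; magnified denominator with the
            # per-point axial object distance u2
            cos_ax = np.abs(s_hat @ lens.axis)
            u2 = (cen[None, :, :] - lens.center) @ lens.axis  # (1, M)
            u2 = np.abs(u2)
            offset = t_mag * u2 * cos_ax / lens.f
            d_eff = sep - offset[..., None] * s_hat
            dist2_eff = np.einsum("pmx,pmx->pm", d_eff, d_eff)
            dist2_eff = np.maximum(dist2_eff, 1e-12)
            contrib = (jn[None, :] * vis[None, :] / math.pi
                       * cos_s * cos_d * area[None, :] * dA
                       * t_mag ** 2 / dist2_eff)
        out[lo:hi] = contrib.sum(axis=1)
    return DetectorImage(out.reshape(rows, cols), det)


def extract_profile(image, row_coords, z: float) -> np.ndarray:
    """Row of ``image`` nearest to coordinate ``z`` (floor-to-grid rule).

    ``image`` is a (rows, cols) array whose row centers sit at
    ``row_coords`` (mm, ascending).  Raises when ``z`` is outside the map
    extent by more than half a row pitch.
    """
    img = np.asarray(image, dtype=np.float64)
    rc = np.asarray(row_coords, dtype=np.float64)
    if img.shape[0] != rc.shape[0]:
        raise ValueError("row_coords length must match image rows")
    pitch = rc[1] - rc[0] if len(rc) > 1 else np.inf
    if z < rc[0] - 0.5 * pitch or z > rc[-1] + 0.5 * pitch:
        raise ValueError(f"z={z} outside map extent "
                         f"[{rc[0] - 0.5 * pitch}, {rc[-1] + 0.5 * pitch}]")
    idx = int(np.floor((z - (rc[0] - 0.5 * pitch)) / pitch)) \
        if np.isfinite(pitch) else 0
    idx = min(max(idx, 0), img.shape[0] - 1)
    return img[idx].copy()
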