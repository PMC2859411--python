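"""Photon-packet Monte Carlo transport in heterogeneous tissue.

The engine follows the standard weighted photon-packet scheme of tissue
optics.  Each packet carries power ``W`` (total source power / packet
count).  Its life cycle:

1. birth uniformly inside the internal isotropic source, isotropic initial
   direction;
2. exponential free paths with rate ``mu_t = mu_a + mu_s``; at the end of a
   completed path the packet deposits ``W * mu_a/mu_t`` into the absorption
   voxel grid and scatters into a Henyey-Greenstein deflection;
3. at a region boundary the unpolarized Fresnel reflectance decides (by one
   random draw) between total reflection and total transmission with Snell
   refraction; the unconsumed dimensionless path length is carried across
   the boundary and rescaled by the new medium's ``mu_t`` (MCML convention);
4. a packet escaping the root region records its residual power in the
   transmission tally; a packet whose weight falls below the roulette
   threshold survives with probability ``1/m`` at weight ``m W`` or dies.

All randomness flows through the counter-based substreams of
:mod:`photonmc.rng`; a run with fixed ``(seed, n_workers)`` is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels as _k
from .geometry import (Region, Scene, Shape, OpticalProperties, BoundaryHit,
                       _as_vec)
from .rng import SubStream, make_substreams

__all__ = [
    "SourceSpec", "PhotonPacket", "RouletteConfig", "SimulationTallies",
    "sample_source_position", "sample_isotropic_direction",
    "sample_free_path", "deposit_absorption", "sample_scatter_direction",
    "sample_deflection_cos",
    "critical_angle", "fresnel_reflectance", "boundary_event", "roulette",
    "run_simulation",
]


@dataclass
class SourceSpec:
    """Internal steady isotropic source: an emissive analytic shape.

    The source is an abstract emitter — it has no optical properties of its
    own; packets transport in whatever tissue encloses the birth point.
    """
    shape: Shape
    total_power: float = 1e-9   # W; the reference phantoms use 1 nW

    def __post_init__(self):
        if self.total_power <= 0:
            raise ValueError("total_power must be positive")

    def bbox(self) -> np.ndarray:
        return self.shape.bbox()


@dataclass
class PhotonPacket:
    """Mobile state of the MC loop (exposed for unit-level operations)."""
    position: np.ndarray
    direction: np.ndarray
    W: float
    region: Optional[Region] = None
    alive: bool = True


@dataclass
class RouletteConfig:
    """Russian-roulette policy: trigger below ``threshold`` W, survive with
    probability 1/m at amplified weight m*W."""
    threshold: float
    m: float = 10.0

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("roulette threshold must be positive")
        if self.m <= 1:
            raise ValueError("roulette m must exceed 1")


class SimulationTallies:
    """Absorption voxel grid plus per-escape transmission records.

    ``absorption`` is a (nx, ny, nz) grid of absorbed power (W) over the
    root-region bounding box at ``pitch`` mm; ``exit_positions`` /
    ``exit_weights`` list every escaped packet (surface point and residual
    power), which downstream rasterization turns into a surface flux-density
    map Jn (W/mm^2).
    """

    def __init__(self, scene: Scene, pitch: float, n_packets: int,
                 packet_power: float):
        bb = scene.bbox()
        nx = max(1, int(math.ceil((bb[1] - bb[0]) / pitch)))
        ny = max(1, int(math.ceil((bb[3] - bb[2]) / pitch)))
        nz = max(1, int(math.ceil((bb[5] - bb[4]) / pitch)))
        self.absorption = np.zeros((nx, ny, nz), dtype=np.float64)
        self.origin = np.array([bb[0], bb[2], bb[4]])
        self.pitch = float(pitch)
        self.exit_positions = np.empty((0, 3))
        self.exit_weights = np.empty(0)
        self.exit_triangles = np.empty(0, dtype=np.int64)
        self.n_launched = int(n_packets)
        self.packet_power = float(packet_power)
        self.absorbed_power = 0.0
        self.transmitted_power = 0.0
        self.lost_power = 0.0
        self.n_events = 0

    @property
    def launched_power(self) -> float:
        return self.n_launched * self.packet_power

    def voxel_index(self, p) -> tuple:
        p = _as_vec(p)
        idx = np.floor((p - self.origin) / self.pitch).astype(int)
        shape = self.absorption.shape
        if ((idx < 0) | (idx >= np.array(shape))).any():
            raise IndexError(
                f"position {p} outside the tally grid (grid must cover the "
                "root region)")
        return tuple(idx)

    def summary(self) -> dict:
        tot = self.launched_power
        return {
            "n_launched": self.n_launched,
            "packet_power_w": self.packet_power,
            "launched_w": tot,
            "absorbed_w": self.absorbed_power,
            "transmitted_w": self.transmitted_power,
            "lost_w": self.lost_power,
            "absorbed_fraction": self.absorbed_power / tot,
            "transmitted_fraction": self.transmitted_power / tot,
            "n_events": self.n_events,
            "n_escaped": int(len(self.exit_weights)),
        }

    def save_absorption_h5(self, path):
        """Self-describing HDF5 container for the absorption grid."""
        import h5py
        with h5py.File(path, "w") as f:
            d = f.create_dataset("absorbed_power_w", data=self.absorption)
            d.attrs["voxel_pitch_mm"] = self.pitch
            d.attrs["origin_mm"] = self.origin
            for k, v in self.summary().items():
                f.attrs[k] = v

    def save_transmission_tsv(self, path):
        """Escape records as TSV: index, x, y, z, power_w, triangle."""
        n = len(self.exit_weights)
        with open(path, "w") as f:
            f.write("element\tx_mm\ty_mm\tz_mm\tpower_w\ttriangle\n")
            for i in range(n):
                x, y, z = self.exit_positions[i]
                f.write(f"{i}\t{x:.9g}\t{y:.9g}\t{z:.9g}\t"
                        f"{self.exit_weights[i]:.9g}\t"
                        f"{self.exit_triangles[i]}\n")


# ---------------------------------------------------------------------------
# Unit-level operations
# ---------------------------------------------------------------------------

def sample_source_position(src: SourceSpec, stream: SubStream) -> np.ndarray:
    """Uniform point inside the source shape by bounding-box rejection."""
    st, prm = src.shape._pack()
    prm = np.asarray(prm, dtype=np.float64)
    bb = src.bbox()
    tri = np.empty((0, 3, 3))
    for _ in range(1_000_000):
        x = bb[0] + (bb[1] - bb[0]) * stream.uniform()
        y = bb[2] + (bb[3] - bb[2]) * stream.uniform()
        z = bb[4] + (bb[5] - bb[4]) * stream.uniform()
        if _k._shape_contains(st, prm, tri, 0, 0, x, y, z):
            return np.array([x, y, z])
    raise RuntimeError("degenerate source: 10^6 consecutive rejections")


def sample_isotropic_direction(stream: SubStream, size: int | None = None):
    """Uniform direction(s) on the unit sphere: phi = 2 pi xi_phi,
    theta = arccos(2 xi_theta - 1).  ``size=None`` returns one 3-vector,
    otherwise a (size, 3) array."""
    if size is None:
        phi = 2.0 * math.pi * stream.uniform()
        ct = 2.0 * stream.uniform() - 1.0
        st_ = math.sqrt(max(0.0, 1.0 - ct * ct))
        return np.array([st_ * math.cos(phi), st_ * math.sin(phi), ct])
    u = stream.uniforms(2 * size)
    phi = 2.0 * math.pi * u[0::2]
    ct = 2.0 * u[1::2] - 1.0
    st_ = np.sqrt(np.maximum(0.0, 1.0 - ct * ct))
    return np.column_stack([st_ * np.cos(phi), st_ * np.sin(phi), ct])


def sample_free_path(props: OpticalProperties, stream: SubStream,
                     size: int | None = None):
    """Exponential free path(s) s = -ln(xi) / mu_t (exact zeros redrawn)."""
    if props.mu_t <= 0:
        raise ValueError("mu_a + mu_s must be positive (vacuum is not a "
                         "tissue)")
    if size is None:
        xi = stream.uniform()
        while xi <= 0.0:
            xi = stream.uniform()
        return -math.log(xi) / props.mu_t
    xi = stream.uniforms(size)
    bad = xi <= 0.0
    while bad.any():
        xi[bad] = stream.uniforms(int(bad.sum()))
        bad = xi <= 0.0
    return -np.log(xi) / props.mu_t


def sample_deflection_cos(g: float, stream: SubStream,
                          size: int | None = None):
    """Henyey-Greenstein deflection cosine(s); isotropic for g == 0."""
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must lie in (-1, 1)")
    if size is None:
        return float(_k.hg_cos_theta(g, stream.uniform()))
    xi = stream.uniforms(size)
    if g == 0.0:
        return 2.0 * xi - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return np.clip((1.0 + g * g - f * f) / (2.0 * g), -1.0, 1.0)


def deposit_absorption(packet: PhotonPacket, props: OpticalProperties,
                       tallies: SimulationTallies) -> float:
    """Deposit dW = W mu_a/mu_t at the packet position; returns new W."""
    dw = props.mu_a / props.mu_t * packet.W
    idx = tallies.voxel_index(packet.position)
    tallies.absorption[idx] += dw
    tallies.absorbed_power += dw
    packet.W -= dw
    return packet.W


def sample_scatter_direction(old_dir, g: float,
                             stream: SubStream) -> np.ndarray:
    """New unit direction after a Henyey-Greenstein scattering event."""
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must lie in (-1, 1)")
    d = _as_vec(old_dir)
    ct = sample_deflection_cos(g, stream)
    phi = 2.0 * math.pi * stream.uniform()
    return np.array(_k.rotate_direction(d[0], d[1], d[2], ct, phi))


def critical_angle(n_i: float, n_t: float) -> float:
    """Total-internal-reflection threshold: arcsin(n_t/n_i) for n_i > n_t,
    else pi/2 (matched or rarer-to-denser crossings never totally reflect)."""
    if n_i > n_t:
        return math.asin(n_t / n_i)
    return 0.5 * math.pi


def fresnel_reflectance(theta_i: float, n_i: float, n_t: float) -> float:
    """Unpolarized Fresnel reflectance at incidence angle theta_i (rad)."""
    if not 0.0 <= theta_i <= 0.5 * math.pi + 1e-12:
        raise ValueError("theta_i must lie in [0, pi/2]")
    return float(_k.fresnel_unpolarized(math.cos(theta_i), n_i, n_t))


def boundary_event(packet: PhotonPacket, hit: BoundaryHit,
                   stream: SubStream, scene: Scene) -> PhotonPacket:
    """Resolve a boundary: total reflection or total transmission.

    One uniform draw against the Fresnel reflectance decides; weight is
    unchanged either way.  On transmission the packet's region becomes the
    far side (``None`` = escaped to ambient).
    """
    d = _as_vec(packet.direction)
    n = _as_vec(hit.outward_normal)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9 or \
            abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("incident direction and normal must be unit vectors")
    n_i = packet.region.props.n if packet.region is not None else \
        scene.ambient_n
    n_t = (hit.next_region.props.n if hit.next_region is not None
           else scene.ambient_n)
    c = float(d @ n)
    refl = _k.fresnel_unpolarized(abs(c), n_i, n_t)
    if stream.uniform() <= refl:
        packet.direction = d - 2.0 * c * n
    else:
        packet.direction = np.array(
            _k.refract_direction(d[0], d[1], d[2], n[0], n[1], n[2],
                                 n_i, n_t))
        packet.region = hit.next_region
    packet.direction /= np.linalg.norm(packet.direction)
    return packet


def roulette(packet: PhotonPacket, cfg: RouletteConfig,
             stream: SubStream) -> PhotonPacket:
    """Russian roulette: survive with probability 1/m at weight m*W."""
    if stream.uniform() <= 1.0 / cfg.m:
        packet.W *= cfg.m
    else:
        packet.W = 0.0
        packet.alive = False
    return packet


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

def run_simulation(scene: Scene, src: SourceSpec, n_packets: int,
                   seed: int = 0, n_workers: int = 1,
                   voxel_pitch: float = 0.5,
                   roulette_threshold_frac: float = 1e-4,
                   roulette_m: float = 10.0,
                   max_events: int = 1_000_000) -> SimulationTallies:
    """Run the full photon-packet simulation and return merged tallies.

    Each worker simulates ``n_packets / n_workers`` packets (remainder to
    the first workers) with its own non-overlapping substream into private
    tallies; the host sums them.  Workers execute sequentially — the worker
    count partitions the random stream and the packet load, so results for a
    given ``(seed, n_workers)`` are bit-identical regardless of how the
    chunks are scheduled.

    Parameters
    ----------
    voxel_pitch
        Absorption-grid pitch in mm (grid covers the root bounding box).
    roulette_threshold_frac
        Roulette trigger as a fraction of the initial packet power.
    max_events
        Safety cap per packet; weight beyond it goes to the lost-power
        counter reported in the run summary.
    """
    if n_packets < 1:
        raise ValueError("n_packets must be >= 1")
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    packet_power = src.total_power / n_packets
    tallies = SimulationTallies(scene, voxel_pitch, n_packets, packet_power)
    pk = scene.pack()
    s_type, s_prm = src.shape._pack()
    s_prm = np.asarray(s_prm, dtype=np.float64)
    s_bbox = np.asarray(src.bbox(), dtype=np.float64)

    counts = [n_packets // n_workers] * n_workers
    for i in range(n_packets % n_workers):
        counts[i] += 1
    streams = make_substreams(seed, n_workers)

    w_threshold = roulette_threshold_frac * packet_power
    for wi, stream in enumerate(streams):
        nw = counts[wi]
        if nw == 0:
            continue
        exit_pos = np.empty((nw, 3), dtype=np.float64)
        exit_w = np.empty(nw, dtype=np.float64)
        exit_tri = np.full(nw, -1, dtype=np.int64)
        grid = np.zeros_like(tallies.absorption)
        k0, k1 = stream.key
        n_exit, absorbed, transmitted, lost, nev = _k.run_chunk(
            pk.shape_type, pk.prm, pk.parent, pk.depth, pk.props,
            pk.tri, pk.tri_off, scene.ambient_n,
            s_type, s_prm, s_bbox,
            nw, packet_power, w_threshold, roulette_m, max_events,
            np.uint64(k0), np.uint64(k1),
            grid, tallies.origin[0], tallies.origin[1], tallies.origin[2],
            voxel_pitch,
            exit_pos, exit_w, exit_tri)
        tallies.absorption += grid
        tallies.absorbed_power += absorbed
        tallies.transmitted_power += transmitted
        tallies.lost_power += lost
        tallies.n_events += int(nev)
        tallies.exit_positions = np.vstack(
            [tallies.exit_positions, exit_pos[:n_exit]])
        tallies.exit_weights = np.concatenate(
            [tallies.exit_weights, exit_w[:n_exit]])
        tallies.exit_triangles = np.concatenate(
            [tallies.exit_triangles, exit_tri[:n_exit]])
    return tallies
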