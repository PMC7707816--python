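"""Synthetic multichannel confocal volumes of inhibitory boutons.

Generates 3D stacks that emulate confocal imaging of inhibitory presynaptic
terminals: a Vgat channel in which every bouton appears as an anisotropic
Gaussian punctum, plus marker channels (Syp-TdT for glycinergic identity,
Syt1/2 for fast calcium sensors, optionally ChR2-YFP) that either co-vary
with the Vgat signal (class-true boutons) or contain only background
(class-false boutons).  Every generated bouton is recorded in a ground-truth
table so downstream detection/scoring/classification can be validated
against known labels.

Geometry follows typical high-NA confocal acquisition of brainstem tissue:
0.1 µm/pixel in xy, 0.2 µm z-sections, 8-bit intensities.

Conventions
-----------
* Arrays are indexed ``(z, y, x)``; physical tuples in user-facing dataclasses
  are ``(x, y, z)`` in µm.
* Physical coordinates are voxel-center positions: voxel index ``i`` along an
  axis with size ``v`` µm sits at ``(i + 0.5) * v`` µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError

CHANNEL_NAMES = ("vgat", "syp_tdt", "syt12", "yfp")
MARKER_FLAGS = {"syp_tdt": "glyt2", "syt12": "syt12", "yfp": "yfp"}


@dataclass(frozen=True)
class VolumeSpec:
    """Geometry and background statistics of one imaged stack.

    Defaults correspond to a full 101.6 × 101.6 × 3 µm tile; tests use
    smaller ``shape_xy``.
    """

    shape_xy: tuple[int, int] = (1016, 1016)
    n_z: int = 15
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.2)  # (x, y, z) µm
    bit_depth: int = 8
    background_mean: float = 20.0
    background_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel sizes must be strictly positive")
        if self.bit_depth != 8:
            raise ParameterError("bit_depth is fixed at 8")
        if min(self.shape_xy) < 1 or self.n_z < 1:
            raise ParameterError("volume shape must be positive")
        if not 0 <= self.background_mean <= 255:
            raise ParameterError("background_mean must lie in [0, 255]")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return (self.n_z, self.shape_xy[1], self.shape_xy[0])

    @property
    def voxel_zyx(self) -> tuple[float, float, float]:
        x, y, z = self.voxel_size
        return (z, y, x)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) in µm."""
        return (
            self.shape_xy[0] * self.voxel_size[0],
            self.shape_xy[1] * self.voxel_size[1],
            self.n_z * self.voxel_size[2],
        )


@dataclass(frozen=True)
class GroundTruthBouton:
    """One generated bouton with its class labels (the recovery oracle)."""

    id: int
    centroid_um: tuple[float, float, float]  # (x, y, z)
    glyt2: bool
    syt12: bool
    yfp: bool
    peak_intensity: float
    sigma_xy: float
    sigma_z: float
    region_label: str = "volume"
    neighbor: bool = False


@dataclass
class ChannelStack:
    """Named set of same-shape 3D intensity arrays; ``vgat`` is mandatory."""

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.2)  # (x, y, z) µm

    def __post_init__(self):
        if "vgat" not in self.channels:
            raise ParameterError("a ChannelStack must contain a 'vgat' channel")
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ParameterError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels["vgat"].shape

    @property
    def voxel_zyx(self) -> tuple[float, float, float]:
        x, y, z = self.voxel_size
        return (z, y, x)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclass(frozen=True)
class BoutonPopulation:
    """Parameters of the bouton population rendered into a volume.

    ``coloc_rho`` sets the expected voxelwise correlation between the Vgat
    punctum and a class-true marker punctum: the marker signal is
    ``alpha * (rho * s + sqrt(1 - rho^2) * e)`` where ``s`` is the Vgat
    punctum profile and ``e`` is independent voxel noise of matched scale,
    plus ``epsilon_sd`` additive residual noise.  Negative ``rho`` inverts
    the marker (anticorrelated signal).  ``bleed`` renders a fraction of the
    Vgat punctum into class-false marker channels to stress the classifier's
    0.1–0.4 dead band.
    """

    count: int = 50
    p_glyt2: float = 0.5
    p_syt12: float = 0.5
    p_yfp: float = 0.0
    coloc_rho: float = 1.0
    alpha: float = 1.0
    epsilon_sd: float = 0.0
    bleed: float = 0.0
    noise_sd: float | None = None  # defaults to spec.background_sd
    peak_mean: float = 180.0
    peak_sd: float = 20.0
    sigma_xy: float = 0.3  # µm
    sigma_z: float = 0.4  # µm
    min_separation_um: float = 2.0
    neighbor_density: float = 0.0  # contaminating neighbors per target bouton
    neighbor_offset_um: tuple[float, float] = (0.6, 1.1)
    max_attempts_per_bouton: int = 1000
    region_label: str = "volume"
    # emulate source-specific release machinery: boutons carrying the viral
    # YFP label never carry fast synaptotagmins
    yfp_excludes_syt12: bool = False

    def __post_init__(self):
        if self.count < 0:
            raise ParameterError("count must be >= 0")
        if not -1.0 <= self.coloc_rho <= 1.0:
            raise ParameterError("coloc_rho must lie in [-1, 1]")
        for p in (self.p_glyt2, self.p_syt12, self.p_yfp, self.bleed):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities/fractions must lie in [0, 1]")
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ParameterError("punctum sigmas must be positive")


def _render_punctum(vol, centroid_um, peak, sigma_xy, sigma_z, voxel_zyx):
    """Add one anisotropic Gaussian punctum (in place) to ``vol`` (z, y, x)."""
    vz, vy, vx = voxel_zyx
    cx, cy, cz = centroid_um
    nz, ny, nx = vol.shape
    # bounding box at 4 sigma
    rz = max(1, int(np.ceil(4 * sigma_z / vz)))
    ry = max(1, int(np.ceil(4 * sigma_xy / vy)))
    rx = max(1, int(np.ceil(4 * sigma_xy / vx)))
    iz, iy, ix = int(cz / vz), int(cy / vy), int(cx / vx)
    z0, z1 = max(0, iz - rz), min(nz, iz + rz + 1)
    y0, y1 = max(0, iy - ry), min(ny, iy + ry + 1)
    x0, x1 = max(0, ix - rx), min(nx, ix + rx + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zc = (np.arange(z0, z1) + 0.5) * vz
    yc = (np.arange(y0, y1) + 0.5) * vy
    xc = (np.arange(x0, x1) + 0.5) * vx
    dz2 = ((zc - cz) ** 2)[:, None, None] / (2 * sigma_z**2)
    dy2 = ((yc - cy) ** 2)[None, :, None] / (2 * sigma_xy**2)
    dx2 = ((xc - cx) ** 2)[None, None, :] / (2 * sigma_xy**2)
    vol[z0:z1, y0:y1, x0:x1] += peak * np.exp(-(dz2 + dy2 + dx2))


def _place_centroids(spec, pop, rng):
    """Rejection-sample target centroids with a minimum mutual separation."""
    ex, ey, ez = spec.extent_um
    # keep a margin so a full 1.5 x 1.5 x 1 µm VOI (plus the punctum tail)
    # fits inside the volume around every target bouton
    mx = my = 0.75 + 2 * pop.sigma_xy
    mz = min(0.5 + pop.sigma_z, ez / 2 * 0.99)
    if ex <= 2 * mx or ey <= 2 * my or ez <= 2 * mz:
        raise PlacementError("volume too small for the requested margins")
    placed: list[np.ndarray] = []
    min_d2 = pop.min_separation_um**2
    for _ in range(pop.count):
        for _attempt in range(pop.max_attempts_per_bouton):
            c = np.array(
                [
                    rng.uniform(mx, ex - mx),
                    rng.uniform(my, ey - my),
                    rng.uniform(mz, ez - mz),
                ]
            )
            if all(np.sum((c - q) ** 2) >= min_d2 for q in placed):
                placed.append(c)
                break
        else:
            raise PlacementError(
                f"could not place bouton {len(placed) + 1}/{pop.count} after "
                f"{pop.max_attempts_per_bouton} attempts"
            )
    return placed


def generate_volume(
    spec: VolumeSpec, pop: BoutonPopulation
) -> tuple[ChannelStack, list[GroundTruthBouton]]:
    """Render a synthetic multichannel stack plus its ground-truth table.

    Channels produced: ``vgat`` always; ``syp_tdt`` and ``syt12`` always
    (their class-false boutons contain only background); ``yfp`` only when
    ``pop.p_yfp > 0``.

    Identical ``spec.seed`` gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape_zyx
    names = ["vgat", "syp_tdt", "syt12"] + (["yfp"] if pop.p_yfp > 0 else [])
    acc = {n: np.zeros(shape, dtype=np.float64) for n in names}

    centroids = _place_centroids(spec, pop, rng)
    truth: list[GroundTruthBouton] = []
    bid = 0
    marker_channels = [n for n in names if n != "vgat"]

    def render_bouton(centroid, neighbor):
        nonlocal bid
        flags = {
            "glyt2": bool(rng.random() < pop.p_glyt2),
            "syt12": bool(rng.random() < pop.p_syt12),
            "yfp": bool(rng.random() < pop.p_yfp) if pop.p_yfp > 0 else False,
        }
        if pop.yfp_excludes_syt12 and flags["yfp"]:
            flags["syt12"] = False
        peak = float(np.clip(rng.normal(pop.peak_mean, pop.peak_sd), 10, 255))
        punctum = np.zeros(shape, dtype=np.float64)
        _render_punctum(
            punctum, centroid, peak, pop.sigma_xy, pop.sigma_z, spec.voxel_zyx
        )
        acc["vgat"] += punctum
        rho = pop.coloc_rho
        for ch in marker_channels:
            if flags[MARKER_FLAGS[ch]]:
                signal = rho * punctum
                if abs(rho) < 1.0:
                    # independent component of matched scale, confined to
                    # the punctum support so background stays untouched
                    indep = rng.normal(0.0, 1.0, size=shape) * punctum
                    indep *= np.sqrt(1.0 - rho**2)
                    signal = signal + indep
                if rho < 0:
                    signal = signal + abs(rho) * peak  # keep intensities positive
                acc[ch] += pop.alpha * signal
                if pop.epsilon_sd > 0:
                    mask = punctum > 0.01 * peak
                    acc[ch][mask] += rng.normal(0, pop.epsilon_sd, mask.sum())
            elif pop.bleed > 0:
                acc[ch] += pop.bleed * punctum
        truth.append(
            GroundTruthBouton(
                id=bid,
                centroid_um=tuple(float(v) for v in centroid),
                glyt2=flags["glyt2"],
                syt12=flags["syt12"],
                yfp=flags["yfp"],
                peak_intensity=peak,
                sigma_xy=pop.sigma_xy,
                sigma_z=pop.sigma_z,
                region_label=pop.region_label,
                neighbor=neighbor,
            )
        )
        bid += 1

    for c in centroids:
        render_bouton(c, neighbor=False)

    # contaminating neighbors: offset from a target so they overlap the
    # outer shell of its VOI but not its core
    n_neighbors = int(round(pop.neighbor_density * len(centroids)))
    for _ in range(n_neighbors):
        host = centroids[rng.integers(len(centroids))]
        lo, hi = pop.neighbor_offset_um
        r = rng.uniform(lo, hi)
        theta = rng.uniform(0, 2 * np.pi)
        offset = np.array([r * np.cos(theta), r * np.sin(theta), 0.0])
        c = host + offset
        ex, ey, ez = spec.extent_um
        c = np.clip(c, [0.2, 0.2, 0.1], [ex - 0.2, ey - 0.2, ez - 0.1])
        render_bouton(c, neighbor=True)

    noise_sd = spec.background_sd if pop.noise_sd is None else pop.noise_sd
    channels = {}
    for n in names:
        img = acc[n] + spec.background_mean
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape)
        channels[n] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ChannelStack(channels, voxel_size=spec.voxel_size), truth


def truth_to_frame(truth: list[GroundTruthBouton]) -> pd.DataFrame:
    """Ground-truth table: one row per bouton, physical coordinates in µm."""
    cols = [
        "id", "x_um", "y_um", "z_um", "glyt2", "syt12", "yfp",
        "peak_intensity", "sigma_xy", "sigma_z", "region", "neighbor",
    ]
    rows = [
        {
            "id": b.id,
            "x_um": b.centroid_um[0],
            "y_um": b.centroid_um[1],
            "z_um": b.centroid_um[2],
            "glyt2": b.glyt2,
            "syt12": b.syt12,
            "yfp": b.yfp,
            "peak_intensity": b.peak_intensity,
            "sigma_xy": b.sigma_xy,
            "sigma_z": b.sigma_z,
            "region": b.region_label,
            "neighbor": b.neighbor,
        }
        for b in truth
    ]
    return pd.DataFrame(rows, columns=cols)
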