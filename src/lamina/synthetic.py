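"""Seeded synthetic aggregate images with known ground-truth organisation.

Emulates single confocal sections of re-aggregated SoFa1 retinal
organoids: a roughly circular DAPI-positive aggregate in which
CFP-positive cells (Crx reporter) concentrate centrally, GFP-positive
cells (Ptf1a reporter) form a peripheral ring, RFP-positive cells
(Atoh7 reporter) are broadly distributed, optionally with a small
non-fluorescent central core (pigment epithelium) and non-fluorescent
debris outside the aggregate boundary.

The ``organization`` parameter (lambda) interpolates between fully
laminated placement (lambda = 1: every cell inside its class's radial
zone) and placement independent of radius (lambda = 0).  All
randomness flows from ``SyntheticConfig.seed`` through
``numpy.random.SeedSequence`` spawning, so every output is reproducible
bit for bit and cohort items are mutually independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import AggregateMask, ImageStack

#: Cell classes and the fluorescence channels each is positive in.
#: Every class is DAPI-positive.
CLASS_CHANNELS: dict[str, tuple[str, ...]] = {
    "CFP": ("CFP",),
    "GFP_RFP": ("GFP", "RFP"),
    "RFP": ("RFP",),
    "CFP_RFP": ("CFP", "RFP"),
}

FLUOR_CHANNELS = ("CFP", "GFP", "RFP")


@dataclass
class NoiseParams:
    """Detector noise: Poisson shot noise (photon gain, 0 disables)
    followed by additive Gaussian read noise (intensity units)."""

    gaussian_sigma: float = 2.0
    poisson_gain: float = 1.0


@dataclass
class SyntheticConfig:
    """Geometry, composition and noise of one synthetic aggregate.

    Defaults mimic the published aggregate proportions at reduced
    resolution: a 512x512 frame, aggregate radius 120 px, the CFP zone
    inside 0.55 of the local radius and the GFP ring between 0.55 and
    0.85, with 60/60/40/60 cells of the four classes at radius 6 px.
    """

    image_size: int = 512
    aggregate_radius: float = 120.0
    shape_perturbation: float = 0.08
    n_cells_per_class: dict[str, int] = field(
        default_factory=lambda: {"CFP": 60, "GFP_RFP": 60, "RFP": 40, "CFP_RFP": 60}
    )
    organization: float = 1.0
    r_inner: float = 0.55
    r_outer: float = 0.85
    rpe_core: bool = False
    core_radius_fraction: float = 0.12
    debris_rate: float = 0.0
    cell_radius: float = 6.0
    amplitude: float = 100.0
    amplitude_cv: float = 0.3
    dapi_tissue_level: float = 60.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    background_level: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.organization <= 1.0:
            raise ValueError("organization must lie in [0, 1]")
        if not 0.0 < self.r_inner < self.r_outer < 1.0:
            raise ValueError("need 0 < r_inner < r_outer < 1")
        if any(n < 0 for n in self.n_cells_per_class.values()):
            raise ValueError("cell counts must be nonnegative")
        unknown = set(self.n_cells_per_class) - set(CLASS_CHANNELS)
        if unknown:
            raise ValueError(f"unknown cell classes {sorted(unknown)}")
        if self.shape_perturbation < 0:
            raise ValueError("shape_perturbation must be nonnegative")
        if isinstance(self.noise, dict):
            self.noise = NoiseParams(**self.noise)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)

    def _seed_seq(self, *key: int) -> np.random.SeedSequence:
        """Named sub-stream of the config's root entropy."""
        return np.random.SeedSequence(entropy=self.seed, spawn_key=tuple(key))

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(self._seed_seq(*key))


# Sub-stream keys: 0 = mask shape, 1 = cell placement, 2 = rendering noise.
_MASK_STREAM, _CELL_STREAM, _RENDER_STREAM = 0, 1, 2


def make_aggregate_mask(cfg: SyntheticConfig) -> AggregateMask:
    """Rasterise a radially perturbed circle as the aggregate footprint.

    The boundary is r(theta) = R * (1 + sum_k a_k cos(k theta + phi_k))
    over harmonics k = 2..5, with the amplitudes drawn from the seeded
    generator and normalised so their absolute sum equals
    ``shape_perturbation`` (hence the boundary stays within
    R * (1 +/- shape_perturbation) exactly).
    """
    R = cfg.aggregate_radius
    pert = cfg.shape_perturbation
    if cfg.image_size <= 2 * R * (1 + pert):
        raise ValueError(
            f"image_size={cfg.image_size} cannot contain an aggregate of "
            f"radius {R} perturbed by {pert}; increase image_size"
        )
    rng = cfg.rng(_MASK_STREAM)
    ks = np.arange(2, 6)
    raw = rng.uniform(-1.0, 1.0, size=ks.size)
    phases = rng.uniform(0.0, 2 * np.pi, size=ks.size)
    if pert > 0 and np.abs(raw).sum() > 0:
        amps = pert * raw / np.abs(raw).sum()
    else:
        amps = np.zeros_like(raw)

    n = cfg.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - c, xx - c
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = R * (1.0 + sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, ks, phases)))
    mask = rho <= boundary

    # The boundary is star-shaped so the region is connected and
    # hole-free by construction; enforce defensively anyway.
    mask = ndimage.binary_fill_holes(mask)
    labels, ncomp = ndimage.label(mask)
    if ncomp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, ncomp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    out = AggregateMask(mask=mask, provenance="truth")
    out.validate()
    return out


def _normalised_radius(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """1 - d/d_max per pixel, where d is the Euclidean distance to the
    outline: 0 at the deepest point, 1 at the boundary."""
    d = ndimage.distance_transform_edt(mask)
    d_max = float(d.max())
    if d_max <= 0:
        raise ValueError("mask is empty")
    return 1.0 - d / d_max, d_max


def _zone_pixels(nr: np.ndarray, mask: np.ndarray, cls: str, cfg: SyntheticConfig):
    """Flat pixel indices of the radial zone a laminated cell of class
    ``cls`` may occupy."""
    if cls in ("CFP", "CFP_RFP"):
        zone = mask & (nr < cfg.r_inner)
    elif cls == "GFP_RFP":
        zone = mask & (nr >= cfg.r_inner) & (nr < cfg.r_outer)
    elif cls == "RFP":
        zone = mask
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown class {cls!r}")
    idx = np.flatnonzero(zone)
    if idx.size == 0:
        raise ValueError(f"radial zone for class {cls!r} has zero area")
    return idx


def place_cells(mask: AggregateMask, cfg: SyntheticConfig) -> pd.DataFrame:
    """Draw cell centres and per-channel amplitudes.

    With probability ``organization`` a cell lands uniformly within its
    class's radial zone; otherwise uniformly anywhere inside the mask.
    Returns a CellTable: columns x, y (pixel coordinates, col/row),
    cell_class, and amp_<channel> for CFP/GFP/RFP/DAPI (zero where the
    class is negative for that channel).
    """
    m = mask.mask
    if not m.any():
        raise ValueError("mask is empty")
    nr, _ = _normalised_radius(m)
    all_idx = np.flatnonzero(m)
    zone_idx = {cls: _zone_pixels(nr, m, cls, cfg) for cls in CLASS_CHANNELS}

    rng = cfg.rng(_CELL_STREAM)
    rows = []
    ncols = m.shape[1]
    for cls in CLASS_CHANNELS:  # fixed order for determinism
        count = cfg.n_cells_per_class.get(cls, 0)
        for _ in range(count):
            pool = zone_idx[cls] if rng.random() < cfg.organization else all_idx
            flat = int(pool[rng.integers(pool.size)])
            r, c = divmod(flat, ncols)
            # sub-pixel jitter keeps the centre inside the chosen pixel
            x = c + rng.uniform(-0.5, 0.5)
            y = r + rng.uniform(-0.5, 0.5)
            amps = {f"amp_{ch}": 0.0 for ch in (*FLUOR_CHANNELS, "DAPI")}
            for ch in (*CLASS_CHANNELS[cls], "DAPI"):
                a = cfg.amplitude * rng.lognormal(
                    mean=-0.5 * np.log1p(cfg.amplitude_cv**2),
                    sigma=np.sqrt(np.log1p(cfg.amplitude_cv**2)),
                )
                amps[f"amp_{ch}"] = a
            rows.append({"x": x, "y": y, "cell_class": cls, **amps})
    cols = ["x", "y", "cell_class"] + [f"amp_{ch}" for ch in (*FLUOR_CHANNELS, "DAPI")]
    return pd.DataFrame(rows, columns=cols)


def _stamp_blob(img: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    """Add an isotropic Gaussian blob in place, windowed to 4 sigma."""
    h, w = img.shape
    half = int(np.ceil(4 * sigma)) + 1
    r0, r1 = max(0, int(y) - half), min(h, int(y) + half + 1)
    c0, c1 = max(0, int(x) - half), min(w, int(x) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amp * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma**2)
    )


def render_image(
    cells: pd.DataFrame, mask: AggregateMask, cfg: SyntheticConfig
) -> ImageStack:
    """Render the CellTable into CFP/GFP/RFP/DAPI channels.

    Each cell contributes a Gaussian blob (sd = cell_radius / 2) to the
    channels its class is positive in, and to DAPI; DAPI additionally
    carries a uniform tissue term inside the mask (aggregates are
    densely cellular, so DAPI is positive throughout).  If ``rpe_core`` is
    set, the blob signal of the fluorescence channels (not DAPI) is
    zeroed inside the central core disk before background and noise are
    applied.  Debris blobs (DAPI only) are added just outside the mask
    at rate ``debris_rate``.  Output intensities are nonnegative.
    """
    sigma = cfg.cell_radius / 2.0
    shape = mask.shape
    signal = {ch: np.zeros(shape) for ch in (*FLUOR_CHANNELS, "DAPI")}
    # aggregates are densely cellular: DAPI is positive throughout the
    # tissue, not only at the explicitly modelled cells
    if cfg.dapi_tissue_level > 0:
        signal["DAPI"][mask.mask] += cfg.dapi_tissue_level
    for row in cells.itertuples(index=False):
        for ch in (*FLUOR_CHANNELS, "DAPI"):
            amp = getattr(row, f"amp_{ch}")
            if amp > 0:
                _stamp_blob(signal[ch], row.x, row.y, amp, sigma)

    if cfg.rpe_core:
        n = cfg.image_size
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        core = np.hypot(yy - c, xx - c) <= cfg.core_radius_fraction * cfg.aggregate_radius
        for ch in FLUOR_CHANNELS:
            signal[ch][core] = 0.0

    rng = cfg.rng(_RENDER_STREAM)
    if cfg.debris_rate > 0:
        n_debris = rng.poisson(cfg.debris_rate)
        d_out = ndimage.distance_transform_edt(~mask.mask)
        ring = np.flatnonzero((d_out > 2) & (d_out < 6 * cfg.cell_radius))
        for _ in range(n_debris):
            if ring.size == 0:
                break
            flat = int(ring[rng.integers(ring.size)])
            r, c = divmod(flat, shape[1])
            _stamp_blob(signal["DAPI"], c, r, cfg.amplitude, sigma * 1.5)

    noise = cfg.noise
    out = {}
    for ch, img in signal.items():
        img = img + cfg.background_level
        if noise.poisson_gain > 0:
            img = rng.poisson(img * noise.poisson_gain) / noise.poisson_gain
        if noise.gaussian_sigma > 0:
            img = img + rng.normal(0.0, noise.gaussian_sigma, size=img.shape)
        out[ch] = np.clip(img, 0.0, None)
    return ImageStack(channels=out)


def generate(cfg: SyntheticConfig) -> tuple[ImageStack, AggregateMask, pd.DataFrame]:
    """Mask, cells and rendered image for one aggregate."""
    mask = make_aggregate_mask(cfg)
    cells = place_cells(mask, cfg)
    stack = render_image(cells, mask, cfg)
    return stack, mask, cells


def cohort_seeds(seed: int, n: int) -> list[int]:
    """Per-item seeds derived from one root seed.

    Uses ``SeedSequence(seed).spawn`` entropy pools folded to 32-bit
    integers, so items are independent, reproducible streams.
    """
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1, np.uint32)[0]) for c in children]


def generate_cohort(
    cfg: SyntheticConfig, n: int
) -> list[tuple[ImageStack, AggregateMask, pd.DataFrame]]:
    """n independent aggregates with ground truth retained.

    Item i uses the same configuration with a seed derived
    deterministically from ``cfg.seed`` and i.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    out = []
    for item_seed in cohort_seeds(cfg.seed, n):
        item_cfg = SyntheticConfig(**{**cfg.to_dict(), "seed": item_seed})
        out.append(generate(item_cfg))
    return out
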