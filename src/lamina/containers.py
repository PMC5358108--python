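"""Shared in-memory containers for the lamination-analysis pipeline.

Conventions: rasters are 2D numpy arrays indexed (row, col), 0-based;
all intensities are nonnegative; masks are boolean with ``True`` marking
the aggregate.  Channel names follow the SoFa1 reporter semantics:
``CFP`` (Crx:gapCFP, bipolar/photoreceptor), ``GFP`` (Ptf1a:cytGFP,
amacrine/horizontal), ``RFP`` (Atoh7:gapRFP, broadly expressed) and
``DAPI`` (nuclei, used for segmentation only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Channels that must be present for an image to be scored.
REQUIRED_CHANNELS = ("CFP", "GFP", "DAPI")

#: Canonical channel ordering used when writing stacks.
CHANNEL_ORDER = ("CFP", "GFP", "RFP", "DAPI", "BF")


@dataclass
class ImageStack:
    """A named set of co-registered single-section channels.

    Parameters
    ----------
    channels
        Mapping of channel name to 2D nonnegative float array.  All
        channels must share one shape.
    pixel_size
        Optional physical pixel size (microns per pixel).  Purely
        informational; all analysis is done in pixel units.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack needs at least one channel")
        shapes = {ch: np.asarray(img).shape for ch, img in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError(f"channels must be 2D, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel dimensions differ: {shapes}")
        for ch, img in self.channels.items():
            arr = np.asarray(img, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {ch!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {ch!r} contains negative intensities")
            self.channels[ch] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def require(self, names=REQUIRED_CHANNELS) -> None:
        """Raise ``KeyError`` naming the first missing required channel."""
        for name in names:
            if name not in self.channels:
                raise KeyError(f"required channel {name!r} is missing")


@dataclass
class AggregateMask:
    """Binary raster marking one aggregate: a single connected,
    hole-free foreground region.

    ``provenance`` records whether the mask came from automatic
    segmentation (``"auto"``) or was supplied by the user (``"manual"``).
    """

    mask: np.ndarray
    provenance: str = "auto"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2D")
        self.mask = m.astype(bool)
        if self.provenance not in ("auto", "manual", "truth"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def validate(self) -> None:
        """Check the single-component / no-holes invariant."""
        from scipy import ndimage

        _, n = ndimage.label(self.mask)
        if n != 1:
            raise ValueError(f"mask has {n} connected components, expected 1")
        filled = ndimage.binary_fill_holes(self.mask)
        if filled.sum() != self.mask.sum():
            raise ValueError("mask has interior holes")


@dataclass
class DistanceMap:
    """Euclidean distance from each in-mask pixel to the nearest
    background pixel; zero outside the mask."""

    distances: np.ndarray
    d_max: float

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.d_max <= 0:
            raise ValueError("d_max must be positive for a non-empty mask")


@dataclass
class RadialProfile:
    """Per-channel mean intensity in concentric bands.

    ``radial_px`` is measured from the centre outward (0 = centre), so
    a channel enriched near the aggregate centre has its mass at small
    radii.  Bands are ordered by increasing radius; every in-mask pixel
    belongs to exactly one band, so ``n_pixels`` sums to the mask area.
    """

    mode: str
    band_width: float
    radial_px: np.ndarray
    n_pixels: np.ndarray
    means: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.mode not in ("centroid", "periphery"):
            raise ValueError(f"unknown profile mode {self.mode!r}")
        self.radial_px = np.asarray(self.radial_px, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if np.any(np.diff(self.radial_px) <= 0):
            raise ValueError("band radii must be strictly increasing")
        for ch, m in self.means.items():
            arr = np.asarray(m, dtype=float)
            if arr.shape != self.radial_px.shape:
                raise ValueError(f"channel {ch!r} has wrong number of bands")
            self.means[ch] = arr

    @property
    def n_bands(self) -> int:
        return len(self.radial_px)

    @property
    def channel_names(self) -> list[str]:
        return list(self.means)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "mode": self.mode,
                "band_index": np.arange(self.n_bands),
                "radial_px": self.radial_px,
                "n_pixels": self.n_pixels,
            }
        )
        for ch, m in self.means.items():
            df[f"mean_{ch}"] = m
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, band_width: float = float("nan")):
        means = {
            c.removeprefix("mean_"): df[c].to_numpy()
            for c in df.columns
            if c.startswith("mean_")
        }
        return cls(
            mode=str(df["mode"].iloc[0]),
            band_width=band_width,
            radial_px=df["radial_px"].to_numpy(),
            n_pixels=df["n_pixels"].to_numpy(),
            means=means,
        )


@dataclass
class NormalizedProfile:
    """Piecewise-linear per-channel intensity densities on the common
    0-100 radial-unit (ru) axis.

    Each channel integrates (trapezoid rule) to 1 over [0, 100]; the
    grid always contains the endpoints 0 and 100 (constant
    continuation of the outermost band samples).
    """

    x: np.ndarray
    densities: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x[0] != 0.0 or self.x[-1] != 100.0:
            raise ValueError("normalized grid must span [0, 100]")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("grid must be strictly increasing")
        for ch, d in self.densities.items():
            arr = np.asarray(d, dtype=float)
            if arr.shape != self.x.shape:
                raise ValueError(f"channel {ch!r} density has wrong length")
            if arr.min() < -1e-12:
                raise ValueError(f"channel {ch!r} density is negative")
            integral = np.trapezoid(arr, self.x)
            if abs(integral - 1.0) > 1e-9:
                raise ValueError(
                    f"channel {ch!r} density integrates to {integral}, not 1"
                )
            self.densities[ch] = arr

    @property
    def channel_names(self) -> list[str]:
        return list(self.densities)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"x_ru": self.x})
        for ch, d in self.densities.items():
            df[f"density_{ch}"] = d
        return df


@dataclass
class ECDFCurve:
    """Cumulative normalised fluorescence for one channel:
    nondecreasing F on [0, 100] with F(0)=0, F(100)=1."""

    x: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.x.shape != self.F.shape:
            raise ValueError("x and F must have the same length")
        if self.F[0] != 0.0 or abs(self.F[-1] - 1.0) > 1e-9:
            raise ValueError("ECDF must start at 0 and end at 1")
        if np.any(np.diff(self.F) < -1e-12):
            raise ValueError("ECDF must be nondecreasing")

    def __call__(self, x) -> np.ndarray:
        return np.interp(x, self.x, self.F)


@dataclass
class ECDFSet:
    """Per-channel ECDF curves sharing one radial grid."""

    curves: dict[str, ECDFCurve]

    def __getitem__(self, name: str) -> ECDFCurve:
        return self.curves[name]

    def __contains__(self, name: str) -> bool:
        return name in self.curves

    @property
    def channel_names(self) -> list[str]:
        return list(self.curves)


@dataclass
class LaminationScore:
    """Areas beneath the per-channel ECDF curves and the lamination
    statistic.

    ``score`` is area_beneath(CFP) - area_beneath(GFP), in radial units
    on the 0-100 axis (range -100..100); positive when the CFP signal
    sits more centrally than the GFP signal.  ``diagonal_deviation`` is
    each channel's area minus 50, the area under the diagonal that a
    spatially uniform signal would produce.
    """

    area_beneath: dict[str, float]
    score: float
    diagonal_deviation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.score) > 100 + 1e-9:
            raise ValueError("|score| cannot exceed 100")
        if not self.diagonal_deviation:
            self.diagonal_deviation = {
                ch: a - 50.0 for ch, a in self.area_beneath.items()
            }

    def to_dict(self) -> dict:
        out = {f"area_{ch.lower()}": a for ch, a in self.area_beneath.items()}
        out["score"] = self.score
        out.update(
            {f"deviation_{ch.lower()}": d for ch, d in self.diagonal_deviation.items()}
        )
        return out


@dataclass
class MeanProfileSet:
    """Cohort-averaged densities on a common grid with an error band."""

    x: np.ndarray
    mean: dict[str, np.ndarray]
    error: dict[str, np.ndarray]
    n: int
    error_type: str = "sem"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("averaging needs at least 2 profiles")
        if self.error_type not in ("sem", "sd"):
            raise ValueError(f"unknown error type {self.error_type!r}")
        for ch in self.mean:
            if self.mean[ch].min() < -1e-12 or self.error[ch].min() < -1e-12:
                raise ValueError("mean and error must be nonnegative")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"x_ru": self.x})
        for ch in self.mean:
            df[f"mean_{ch}"] = self.mean[ch]
            df[f"{self.error_type}_{ch}"] = self.error[ch]
        return df


@dataclass
class TestResult:
    """Two-sample Mann-Whitney U comparison of lamination scores."""

    U: float
    n1: int
    n2: int
    pvalue: float
    method: str

    def __post_init__(self) -> None:
        if not (0 <= self.U <= self.n1 * self.n2):
            raise ValueError("U out of range [0, n1*n2]")
        if not (0 < self.pvalue <= 1):
            raise ValueError("p-value out of range (0, 1]")

    def to_dict(self) -> dict:
        return {
            "U": self.U,
            "n1": self.n1,
            "n2": self.n2,
            "pvalue": self.pvalue,
            "method": self.method,
        }
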