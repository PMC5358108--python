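"""Readers and writers for stacks, masks, profiles and scores.

Stacks travel as multipage TIFF (one page per channel, the channel
name stored in each page's description) or as a directory of
single-channel images.  Masks are 8-bit PNG/TIFF with background 0 and
foreground 255.  Tables are CSV; scores and test results are JSON.
No intensity rescaling happens on read: profiles are normalised later,
so acquisition units cancel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import AggregateMask, ImageStack, LaminationScore, RadialProfile

IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multichannel TIFF, one page per channel, channel names
    in the page descriptions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tif:
        for name in stack.channel_names:
            tif.write(
                stack[name].astype(np.float32),
                description=name,
                contiguous=False,
            )
    return path


def read_stack(path: str | Path, channel_map: dict | None = None) -> ImageStack:
    """Read an ImageStack from a multipage TIFF or a directory of
    single-channel images.

    ``channel_map`` maps page index (0-based int) or file stem to the
    channel name; without it, page descriptions (TIFF) or file stems
    (directory) are used directly.  8/16-bit and float inputs are
    accepted; intensities are kept as written.
    """
    path = Path(path)
    channels: dict[str, np.ndarray] = {}
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"no channel images found in {path}")
        import imageio.v3 as iio

        for f in files:
            name = (channel_map or {}).get(f.stem, f.stem)
            channels[str(name)] = np.asarray(iio.imread(f), dtype=float)
    else:
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                desc = (page.description or "").strip()
                name = None
                if channel_map is not None:
                    if i in channel_map:
                        name = channel_map[i]
                    elif desc and desc in channel_map:
                        name = channel_map[desc]
                if name is None:
                    name = desc or f"page{i}"
                channels[str(name)] = page.asarray().astype(float)

    shapes = {ch: img.shape for ch, img in channels.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"pages have mismatched dimensions: {shapes}")
    return ImageStack(channels=channels)


def write_mask(mask: AggregateMask, path: str | Path) -> Path:
    """Write a mask as 8-bit 0/255 PNG or TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = (mask.mask.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img)
    return path


def write_profile(profile: RadialProfile, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    profile.to_dataframe().to_csv(path, index=False)
    return path


def read_profile(path: str | Path, band_width: float = float("nan")) -> RadialProfile:
    return RadialProfile.from_dataframe(pd.read_csv(path), band_width=band_width)


def write_score(score: LaminationScore, path: str | Path, extra: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(score.to_dict())
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_cells(cells: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, index=False)
    return path


def read_scores_csv(path: str | Path, column: str = "score") -> np.ndarray:
    """Read a 1D vector of lamination scores from a CSV column."""
    df = pd.read_csv(path)
    if column not in df.columns:
        raise ValueError(f"column {column!r} not found in {path}")
    return df[column].to_numpy(dtype=float)


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
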