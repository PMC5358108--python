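"""Shared fixtures: small synthetic aggregates sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from lamina.containers import AggregateMask
from lamina.synthetic import SyntheticConfig, generate


def small_config(**overrides) -> SyntheticConfig:
    """A reduced-geometry configuration (256 px frame, radius 60) that
    keeps the default zone fractions and noise model."""
    base = dict(
        image_size=256,
        aggregate_radius=60.0,
        n_cells_per_class={"CFP": 30, "GFP_RFP": 30, "RFP": 20, "CFP_RFP": 30},
        cell_radius=4.0,
        seed=42,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_aggregate(small_cfg):
    """(stack, truth mask, cells) for one organised small aggregate."""
    return generate(small_cfg)


def disk_mask(radius: int = 50, size: int | None = None) -> AggregateMask:
    size = size or (2 * radius + 11)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return AggregateMask(np.hypot(yy - c, xx - c) <= radius, provenance="truth")


@pytest.fixture(scope="session")
def disk50() -> AggregateMask:
    return disk_mask(50)
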