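"""Optional plots: radial profiles and ECDF curves with the diagonal
reference.  Uses the Agg backend; nothing here is part of the
computational contract."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .containers import ECDFSet, MeanProfileSet, NormalizedProfile, RadialProfile

CHANNEL_COLORS = {"CFP": "tab:cyan", "GFP": "tab:green", "RFP": "tab:red",
                  "DAPI": "tab:blue", "BF": "gray"}


def _color(ch: str) -> str | None:
    return CHANNEL_COLORS.get(ch)


def plot_profile(profile: RadialProfile | NormalizedProfile | MeanProfileSet,
                 path: str | Path) -> Path:
    """Relative fluorescence against radial position, per channel."""
    fig, ax = plt.subplots(figsize=(5, 4))
    if isinstance(profile, RadialProfile):
        for ch, m in profile.means.items():
            ax.plot(profile.radial_px, m, label=ch, color=_color(ch))
        ax.set_xlabel("radial position (px, centre → periphery)")
        ax.set_ylabel("mean intensity")
    elif isinstance(profile, NormalizedProfile):
        for ch, d in profile.densities.items():
            ax.plot(profile.x, d, label=ch, color=_color(ch))
        ax.set_xlabel("radial position (ru)")
        ax.set_ylabel("normalised intensity (1/ru)")
    else:
        for ch in profile.mean:
            ax.plot(profile.x, profile.mean[ch], label=ch, color=_color(ch))
            ax.fill_between(
                profile.x,
                profile.mean[ch] - profile.error[ch],
                profile.mean[ch] + profile.error[ch],
                color=_color(ch),
                alpha=0.25,
                linewidth=0,
            )
        ax.set_xlabel("radial position (ru)")
        ax.set_ylabel(f"normalised intensity (mean ± {profile.error_type.upper()})")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_ecdf(curves: ECDFSet, path: str | Path) -> Path:
    """ECDF per channel with the dotted diagonal marking a perfectly
    even centre-to-periphery distribution."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for ch, curve in curves.curves.items():
        ax.plot(curve.x, curve.F, label=ch, color=_color(ch))
    ax.plot([0, 100], [0, 1], "k:", label="uniform")
    ax.set_xlabel("radial position (ru)")
    ax.set_ylabel("cumulative normalised fluorescence")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
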