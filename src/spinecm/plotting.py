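"""Plot helpers (Bland-Altman agreement plot, profile/fit overlay)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .agreement import BlandAltmanResult
from .core import NormalizedProfile, PolynomialFit

__all__ = ["plot_bland_altman", "plot_profile_fit"]


def plot_bland_altman(result: BlandAltmanResult, path: str | Path, title: str = "") -> None:
    """Bland-Altman scatter: bias as a dashed line, limits as solid lines."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.diffs, s=18, color="tab:blue", alpha=0.8)
    ax.axhline(result.bias, linestyle="--", color="k", label=f"bias {result.bias:.2f}")
    for lim in (result.loa_low, result.loa_high):
        ax.axhline(lim, color="tab:red")
    ax.set_xlabel("mean of paired measurements (deg)")
    ax.set_ylabel("difference (deg)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profile_fit(profile: NormalizedProfile, fit: PolynomialFit, path: str | Path) -> None:
    """Normalized profile with its polynomial reconstruction overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    s = profile.arc_positions
    ax.plot(s, profile.values, lw=0.8, color="0.6", label="normalized profile")
    ax.plot(s, fit.fitted_values, lw=1.8, color="tab:blue", label=f"degree-{fit.degree} fit")
    ax.set_xlabel("arc position s (0 = C7, 1 = S1)")
    ax.set_ylabel("angle (deg)")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
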