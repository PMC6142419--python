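"""Static diagnostic plots: VAF scatter, filtered track and KDE."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cna_imbalance import kde, median_filter, mirror_af


def plot_chromosome(series, out_path, filter_radius: int = 100) -> Path:
    """VAF scatter + mirrored median-filtered track + density, one figure."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 3.2), width_ratios=[3, 1])
    ax = axes[0]
    ax.scatter(series.positions, series.values, s=4, alpha=0.4, label="VAF")
    filtered = median_filter(mirror_af(series.values), radius=filter_radius)
    ax.plot(series.positions, filtered, color="crimson", lw=1.5, label="mirrored, filtered")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel(f"{series.chrom} position")
    ax.set_ylabel("allele frequency")
    ax.legend(fontsize=7)

    profile = kde(series.values, peak_scaled=True)
    axes[1].plot(profile.grid, profile.density, lw=1.2)
    axes[1].set_xlabel("VAF")
    axes[1].set_ylabel("scaled density")
    fig.suptitle(series.chrom)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
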