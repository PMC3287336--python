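"""Plot helpers for sweep curves and diet composition."""

from __future__ import annotations

from .clustering import ThresholdSweep


def plot_threshold_sweep(sweep: ThresholdSweep, ax=None):
    """MOTU count vs divergence threshold, with the selected threshold
    marked if one has been chosen."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pct = [100 * t for t in sweep.thresholds]
    ax.plot(pct, sweep.motu_counts, marker="o", color="0.2")
    if sweep.selected_threshold is not None:
        ax.axvline(
            100 * sweep.selected_threshold,
            color="crimson",
            ls="--",
            label=f"selected {100 * sweep.selected_threshold:g}%",
        )
        ax.legend()
    ax.set_xlabel("divergence threshold (%)")
    ax.set_ylabel("MOTU count")
    return ax
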