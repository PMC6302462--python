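"""Minimal trace-comparison figure helper (requires matplotlib)."""

from __future__ import annotations

from .core import PotentialTrace


def plot_comparison(
    lead_ii: PotentialTrace,
    wct: PotentialTrace,
    mwct: PotentialTrace,
    path,
) -> None:
    """Save a stacked comparison of lead II, WCT and M-WCT to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    t = np.arange(len(lead_ii.values)) / lead_ii.sample_rate
    fig, axes = plt.subplots(2, 1, figsize=(9, 5), sharex=True)
    axes[0].plot(t, 1e3 * lead_ii.values, lw=0.8, color="k")
    axes[0].set_ylabel("lead II [mV]")
    axes[1].plot(t, 1e3 * wct.values, lw=0.8, label="WCT")
    axes[1].plot(t, 1e3 * mwct.values, lw=1.2, label="M-WCT")
    axes[1].set_ylabel("terminal [mV]")
    axes[1].set_xlabel("time [s]")
    axes[1].legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
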