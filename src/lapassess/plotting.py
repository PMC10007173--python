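"""Session time-series plot (per-hand and final grades over time)."""

from __future__ import annotations


def plot_session(result, path=None):
    """Plot SRHPA, SLHPA and FPA against time; save to ``path`` if given.

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = result.series
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(s["timestamp"], s["srhpa"], label="right hand (SRHPA)", lw=1)
    ax.plot(s["timestamp"], s["slhpa"], label="left hand (SLHPA)", lw=1)
    ax.plot(s["timestamp"], s["fpa"], label="final (FPA)", lw=1.5, color="k")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("assessment (%)")
    ax.set_ylim(0, 100)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
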