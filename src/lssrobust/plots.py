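"""Simple report plots for robustness studies."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_shift_mae", "plot_rsd_p15"]

_POINT_LABELS = {0: "10 min", 1: "30 min", 2: "2 h", 3: "5 h"}


def plot_shift_mae(report, ax=None):
    """Mean absolute GFR error versus single-point shift, one line per
    sample point; the dashed line marks the 2 mL/min window threshold."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ref = report["reference"]["mae_mean"]
    for point, cells in sorted(report["single_shift"].items()):
        deltas, maes = [0.0], [ref]
        for delta, metrics in cells.items():
            if metrics is not None:
                deltas.append(float(delta))
                maes.append(metrics["mae_mean"])
        order = np.argsort(deltas)
        ax.plot(np.asarray(deltas)[order], np.asarray(maes)[order],
                marker="o", label=_POINT_LABELS.get(int(point), str(point)))
    ax.axhline(2.0, ls="--", c="grey", lw=1)
    ax.set_xlabel("shift in sample time (min)")
    ax.set_ylabel("mean absolute GFR error (mL/min)")
    ax.legend(title="sample point")
    return ax


def plot_rsd_p15(report, ax=None):
    """P15 versus the relative SD of the random multi-point time error."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    rsds = sorted(float(k) for k in report["random_shift"])
    p15 = [report["random_shift"][f"{r:g}"]["p15"] for r in rsds]
    ax.plot([100 * r for r in rsds], p15, marker="s")
    ax.axhline(report["reference"]["p15"], ls="--", c="grey", lw=1,
               label="reference")
    ax.set_xlabel("random time error RSD (%)")
    ax.set_ylabel("P15 (%)")
    ax.legend()
    return ax
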