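"""Boxplot figures for sweep results.

Conventions: boxes span the 25th-75th percentile, the colored line is the
median, the solid black line the mean, whiskers extend 1.5*IQR beyond the
quartiles but are clipped to the data range, and on the log axis zero
estimates are pinned at the bottom of the y range.
"""

from __future__ import annotations

import numpy as np

from .experiments import SweepResult


def sweep_boxplot(sweep: SweepResult, true_value: float | None = None,
                  ax=None, methods=("LDM", "SIM"), log_floor: float = None):
    """Draw side-by-side estimate-distribution boxes per axis value.

    Returns the matplotlib Axes.  ``true_value`` draws the gray dashed
    reference line for the generating donor conjugation rate.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(sweep.cells) + 2, 4))
    colors = {"LDM": "tab:brown", "SIM": "tab:orange"}
    positions = np.arange(len(sweep.cells), dtype=float)

    all_pos = [e.value for c in sweep.cells
               for e in (c.ldm + c.sim) if e.is_finite_nonzero]
    floor = log_floor or (min(all_pos) / 10 if all_pos else 1e-12)

    for j, method in enumerate(methods):
        offset = (j - (len(methods) - 1) / 2) * 0.35
        for i, cell in enumerate(sweep.cells):
            ests = cell.ldm if method == "LDM" else cell.sim
            vals = np.array([e.value for e in ests if e.valid])
            if vals.size == 0:
                continue
            shown = np.where(vals > 0, vals, floor)  # zeros at the bottom
            q1, med, q3 = np.quantile(shown, [0.25, 0.5, 0.75])
            iqr = q3 - q1
            lo = max(shown.min(), q1 - 1.5 * iqr)
            hi = min(shown.max(), q3 + 1.5 * iqr)
            x = positions[i] + offset
            ax.add_patch(plt.Rectangle((x - 0.15, q1), 0.3, max(q3 - q1,
                                                                1e-300),
                                       fill=False,
                                       edgecolor=colors.get(method, "k")))
            ax.plot([x - 0.15, x + 0.15], [med, med],
                    color=colors.get(method, "k"),
                    label=method if i == 0 else None)
            ax.plot([x - 0.15, x + 0.15], [shown.mean(), shown.mean()],
                    color="k")
            ax.plot([x, x], [lo, q1], color=colors.get(method, "k"))
            ax.plot([x, x], [q3, hi], color=colors.get(method, "k"))

    if true_value is not None:
        ax.axhline(true_value, color="gray", linestyle="--",
                   label="true rate")
    ax.set_yscale("log")
    ax.set_xticks(positions)
    ax.set_xticklabels([f"{v:g}" for v in sweep.values])
    ax.set_xlabel(sweep.axis_name)
    ax.set_ylabel("donor conjugation rate (ml cell$^{-1}$ hr$^{-1}$)")
    ax.legend(loc="best", fontsize="small")
    return ax
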