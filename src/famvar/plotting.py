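"""Plotting helpers (deterministic styling, matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from famvar.valid import DecompositionTable

__all__ = ["plot_decomposition"]

_RESIDUAL_COLOR = "0.75"


def plot_decomposition(table: DecompositionTable, path: str | Path | None = None,
                       ax=None):
    """Stacked bands of familial variance by age group.

    One coloured band per component (familial contribution), the
    residual unexplained familial variance shaded grey with hatching,
    and each component's nonfamilial contribution stacked above with
    reduced opacity. Mirrors the stacked-by-age presentation of
    age-specific variance decompositions.
    """
    import matplotlib.pyplot as plt

    comps = table.components
    totals = table.totals
    if comps.empty and totals.empty:
        raise ValueError("cannot plot an empty decomposition table")
    age_groups = list(totals["age_group"])
    names = list(dict.fromkeys(comps["component"])) if not comps.empty else []
    x = np.arange(len(age_groups))

    if ax is None:
        fig, ax = plt.subplots(figsize=(1.8 + 1.1 * len(age_groups), 4.5))
    else:
        fig = ax.figure
    cmap = plt.get_cmap("tab10")
    bottom = np.zeros(len(age_groups))
    for i, name in enumerate(names):
        sub = comps[comps["component"] == name].set_index("age_group")
        heights = sub.loc[age_groups, "familial_variance"].to_numpy()
        ax.bar(x, heights, bottom=bottom, color=cmap(i % 10), label=name, width=0.7)
        bottom = bottom + heights
    residual = totals.set_index("age_group").loc[age_groups, "residual_familial"]
    ax.bar(x, residual.to_numpy(), bottom=bottom, color=_RESIDUAL_COLOR,
           hatch="//", label="unexplained familial", width=0.7)
    bottom = bottom + residual.to_numpy()
    for i, name in enumerate(names):
        sub = comps[comps["component"] == name].set_index("age_group")
        heights = sub.loc[age_groups, "nonfamilial_variance"].to_numpy()
        if np.any(heights > 0):
            ax.bar(x, heights, bottom=bottom, color=cmap(i % 10), alpha=0.35,
                   label=f"{name} (nonfamilial)", width=0.7)
            bottom = bottom + heights

    ax.set_xticks(x, age_groups)
    ax.set_xlabel("age group")
    ax.set_ylabel("variance in log(incidence)")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
    return ax
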