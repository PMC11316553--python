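"""Null-distribution figures: grey KDE with observed ANI values as
colored vertical lines."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .nulldist import PooledNull, fit_kde


def plot_null(null: PooledNull, observed: dict[str, float] | None = None,
              out_path=None, title: str | None = None):
    """Plot a species' same-strain ANI null density with observed values.

    ``observed`` maps pair labels to ANI percentages; each gets a vertical
    line.  Returns the matplotlib figure (saved to ``out_path`` if given).
    """
    kde = null.kde or fit_kde(null.ani_values)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(kde.support, kde.density, color="0.75", alpha=0.8,
                    label=f"same-strain null (n={len(null.values)})")
    ax.plot(kde.support, kde.density, color="0.4", lw=1)
    if observed:
        cmap = plt.get_cmap("tab10")
        for i, (label, ani) in enumerate(sorted(observed.items())):
            ax.axvline(ani, color=cmap(i % 10), lw=1.5, label=f"{label}: {ani:.3f}")
    ax.set_xlabel("ANI (%)")
    ax.set_ylabel("density")
    ax.set_title(title or f"{null.species}: same-strain ANI null")
    ax.legend(fontsize=8, loc="upper left")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
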