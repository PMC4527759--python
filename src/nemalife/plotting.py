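"""Survival, fecundity and egg-production figures."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .lifetable import FecundityPoint
from .records import LifeTable

__all__ = ["plot_life_history"]


def plot_life_history(
    lt: LifeTable | None,
    fecundity: Sequence[FecundityPoint] | None,
    out: str | Path,
) -> None:
    """Render the cohort's survival step curve, fecundity percentage and
    mean eggs laid per interval into one figure (format by file extension).

    Either input may be omitted; a missing fecundity schedule drops the two
    fecundity panels with a warning.
    """
    n_panels = (1 if lt is not None else 0) + (2 if fecundity else 0)
    if n_panels == 0:
        raise ValueError("nothing to plot: no life table and no fecundity points")
    if not fecundity:
        warnings.warn("no fecundity points; fecundity and egg curves omitted")

    fig, axes = plt.subplots(
        n_panels, 1, figsize=(7, 2.8 * n_panels), sharex=True, squeeze=False
    )
    axes = axes.ravel()
    k = 0
    if lt is not None:
        ax = axes[k]
        k += 1
        ax.step(lt.time_x, lt.lx, where="post", color="tab:blue")
        ax.set_ylabel("survival $l_x$")
        ax.set_ylim(0, 1.05)
    if fecundity:
        times = [p.time_x for p in fecundity]
        pct = [
            p.fecundity_pct if p.fecundity_pct is not None else float("nan")
            for p in fecundity
        ]
        eggs = [p.eggs_per_interval for p in fecundity]
        ax = axes[k]
        k += 1
        ax.plot(times, pct, "o-", color="tab:green", ms=3)
        ax.set_ylabel("fecundity (%)")
        ax.set_ylim(-2, 102)
        ax = axes[k]
        k += 1
        ax.plot(times, eggs, "o-", color="tab:orange", ms=3)
        ax.set_ylabel("eggs / interval")
    axes[-1].set_xlabel("age (h)")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
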