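"""AFROC curve figures (vector output)."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .afroc import AFROCCurve

__all__ = ["plot_afroc_curves"]


def plot_afroc_curves(
    curves: Mapping[str, AFROCCurve],
    path: str | Path | None = None,
    *,
    title: str | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Plot one or more AFROC polylines on the unit square.

    ``curves`` maps a legend label (e.g. a group name) to a curve —
    typically the output of :func:`kyt_froc.afroc.average_curves`. When
    ``path`` is given the figure is saved (SVG recommended) and closed.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        ax.plot(curve.fpf, curve.llf, label=label)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("False-positive fraction (FPF)")
    ax.set_ylabel("Lesion-localization fraction (LLF)")
    if title:
        ax.set_title(title)
    if len(curves) > 1:
        ax.legend(loc="lower right", fontsize="small")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
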