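"""Minimal concentration-time plotting."""

from __future__ import annotations

from typing import Sequence

from .simulate import SimulationResult


def plot_concentrations(
    result: SimulationResult,
    matrices: Sequence[str] = ("blood", "brain", "liver", "fat"),
    logy: bool = True,
    ax=None,
):
    """Concentration-time curves for the chosen matrices on one axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for mat in matrices:
        t, c = result.concentration_series(mat)
        ax.plot(t / 24.0, c, label=mat)
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("gestational day")
    ax.set_ylabel("concentration (µg/ml or µg/g)")
    ax.legend(frameon=False)
    return ax
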