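"""Simple diagnostic plots (traces with replicate bands, flux profiles)."""

from __future__ import annotations

from typing import Iterable, Sequence


def plot_traces(traces: Sequence, ax=None, by_condition: bool = True):
    """Overlay kinetic traces, colored by condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    seen = set()
    for tr in traces:
        label = tr.condition_id if by_condition and tr.condition_id not in seen else None
        seen.add(tr.condition_id)
        ax.plot(tr.time, tr.signal, alpha=0.6, label=label)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("signal" + (" (normalized)" if any(t.is_normalized for t in traces) else " (a.u.)"))
    if by_condition:
        ax.legend(fontsize="small")
    return ax


def plot_flux(profiles: Iterable, ax=None):
    """Overlay oligomer-flux profiles phi(t) per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for pr in profiles:
        ax.plot(pr.t_grid, pr.phi, label=f"{pr.condition_id} (exp {pr.replicate[0]})", alpha=0.7)
    ax.set_xlabel("time (h)")
    ax.set_ylabel(r"$\phi(t)$")
    ax.legend(fontsize="x-small")
    return ax
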