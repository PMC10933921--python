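"""Quick-look plots of simulated traces and detected events."""

from __future__ import annotations

from typing import Optional, Sequence

from .simulate import MilkingPhases, SlipEvent, VacuumTrace

__all__ = ["plot_trace"]


def plot_trace(trace: VacuumTrace, events: Optional[Sequence[SlipEvent]] = None,
               phases: Optional[MilkingPhases] = None, ax=None):
    """Plot SMT vacuum and air-bleed channels with event/phase overlays.

    Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(10, 4))
    else:
        fig = ax.figure
    ax.plot(trace.time_s, trace.smt_vacuum_kpa, lw=0.5, color="tab:blue",
            label="SMT vacuum (kPa)")
    ax2 = ax.twinx()
    ax2.plot(trace.time_s, trace.airbleed_index, lw=0.4, color="tab:orange",
             alpha=0.6, label="air-bleed index")
    ax2.set_ylabel("air-bleed index (0-255)")
    ax2.set_ylim(0, 255)
    if events:
        for ev in events:
            ax.axvspan(ev.start_s, ev.end_s, color="tab:red", alpha=0.2)
    if phases is not None:
        for name, x in (
            ("peak flow", phases.peak_flow_start_s),
            ("overmilking", phases.overmilking_start_s),
            ("take-off", phases.takeoff_start_s),
        ):
            ax.axvline(x, color="k", ls=":", lw=0.8)
            ax.annotate(name, (x, ax.get_ylim()[1]), rotation=90,
                        va="top", fontsize=7)
    ax.set_xlabel("time since attachment (s)")
    ax.set_ylabel("SMT vacuum (kPa)")
    ax.set_title(trace.observation_id)
    return fig
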