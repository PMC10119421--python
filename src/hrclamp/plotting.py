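"""Static plot helper: mean HR (± sd band) versus the target line.

Optional convenience for eyeballing ensembles of clamped sessions; the
numeric comparison lives in :mod:`hrclamp.metrics`.
"""

from __future__ import annotations

import numpy as np


def plot_ensemble(traces, ax=None, label: str | None = None, color=None):
    """Plot mean measured HR across traces with a ± sd shaded band, plus
    the (shared) target profile as a dashed line. Returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    t = traces[0].t / 60.0
    hr = np.vstack([tr.hr_measured for tr in traces])
    mean, sd = hr.mean(axis=0), hr.std(axis=0)
    line, = ax.plot(t, mean, label=label, color=color)
    ax.fill_between(t, mean - sd, mean + sd, alpha=0.25, color=line.get_color())
    ax.plot(t, traces[0].target, "k--", linewidth=1)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("heart rate (bpm)")
    if label:
        ax.legend()
    return ax
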