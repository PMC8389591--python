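"""Optional plotting helpers (Kaplan-Meier step curves)."""

from __future__ import annotations

import numpy as np

from .survival import KMCurve


def km_plot(curves: dict[str, KMCurve], ax=None, title: str | None = None):
    """Draw one KM step curve per labelled group on ``ax``.

    Curves start at S(0)=1 and step down at each event time.
    """
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(5, 4))
    for label, curve in sorted(curves.items()):
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
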