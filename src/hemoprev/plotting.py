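"""Optional figures: reference and empirical score CDFs."""

from __future__ import annotations

import pandas as pd


def plot_reference_cdfs(
    curves: pd.DataFrame,
    ecdfs: dict[str, pd.Series] | None = None,
    path: str | None = None,
):
    """Plot the clean/doped reference CDFs and optional empirical curves.

    ``curves`` needs columns grid, F_clean, F_dope; ``ecdfs`` maps labels to
    CDF values on the same grid. Writes SVG/PNG when ``path`` is given,
    returns the matplotlib figure either way.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curves["grid"], curves["F_clean"], "-", color="tab:blue", label="reference: no doping")
    ax.plot(curves["grid"], curves["F_dope"], "-", color="tab:red", label="reference: doping")
    for label, values in (ecdfs or {}).items():
        ax.plot(curves["grid"], values, "--", label=label)
    ax.set_xlabel("adjusted blood profile score")
    ax.set_ylabel("cumulative probability")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path)
    return fig
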