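"""Matplotlib helpers for the dilution envelope and growth fits."""

from __future__ import annotations

import numpy as np

from . import dilution as _dil
from . import growth as _gr

__all__ = ["plot_envelope", "plot_growth_fit"]


def plot_envelope(params: _dil.DilutionParams = _dil.DilutionParams(),
                  dw_max: float = 6.0, ax=None):
    """N content envelope (Nmin/Nc/Nmax) over a dry-biomass range."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    dw = np.linspace(0.05, dw_max, 400)
    ax.plot(dw, _dil.n_max_curve(dw, params), label="N$_{max}$")
    ax.plot(dw, _dil.critical_n(dw, params), label="N$_c$")
    ax.plot(dw, _dil.n_min_curve(dw, params), label="N$_{min}$")
    ax.axvline(params.dw_break, ls=":", c="grey", lw=0.8)
    ax.set_xlabel("aboveground dry biomass (t ha$^{-1}$)")
    ax.set_ylabel("N content (% of DW)")
    ax.legend()
    return ax


def plot_growth_fit(results: _gr.ExponentialGrowthResults, ax=None):
    """Observed points and the fitted exponential trajectory in LTF."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = results.model
    ax.scatter(m.ltf, m.y, s=12, alpha=0.6, label="observed")
    grid = np.linspace(0, float(np.max(m.ltf)), 200)
    ax.plot(grid, results.predict(grid), c="C3",
            label=f"{results.intercept_a:.3f}·e$^{{{results.rate_b:.3f}·LTF}}$")
    ax.set_xlabel("cumulative photothermal effect (LTF)")
    ax.set_ylabel(results.response)
    ax.legend()
    return ax
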