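"""Small plotting helper: a QQ plot of p-values against Uniform(0, 1)."""

from __future__ import annotations

import numpy as np


def qq_plot(pvalues, ax=None, label=None, band: bool = True):
    """-log10 QQ plot with an optional pointwise 95% uniform-order band."""
    import matplotlib.pyplot as plt
    from scipy.stats import beta

    p = np.sort(np.asarray(pvalues, dtype=float))
    n = p.size
    if n == 0:
        raise ValueError("no p-values to plot")
    expected = (np.arange(n) + 0.5) / n
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    if band:
        k = np.arange(1, n + 1)
        lo = beta.ppf(0.025, k, n - k + 1)
        hi = beta.ppf(0.975, k, n - k + 1)
        ax.fill_between(-np.log10(expected), -np.log10(hi), -np.log10(lo),
                        color="0.85", lw=0)
    ax.plot(-np.log10(expected), -np.log10(np.maximum(p, 1e-300)),
            ".", ms=3, label=label)
    lim = -np.log10(0.5 / n)
    ax.plot([0, lim], [0, lim], "r-", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    if label:
        ax.legend(frameon=False)
    return ax
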