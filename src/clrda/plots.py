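"""Effect-size and volcano plots from a pipeline run."""
from __future__ import annotations

import numpy as np

from .inference import RunResult, export_plot_data


def effect_size_plot(result: RunResult, ax=None, top: int = 30):
    """Horizontal bars of debiased effects (log2 scale) for the most
    significant taxa, with the un-debiased effect marked for comparison."""
    import matplotlib.pyplot as plt

    data = export_plot_data(result).nsmallest(top, "pvalue").iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(data))))
    y = np.arange(len(data))
    ax.barh(y, data["log2fc"], color=np.where(data["significant"], "C0", "0.7"))
    ax.plot(data["alpha_raw"] / np.log(2), y, "k.", label="un-debiased")
    ax.set_yticks(y, data["taxon"], fontsize=7)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def volcano_plot(result: RunResult, ax=None):
    """-log10 p against the debiased log2 fold change."""
    import matplotlib.pyplot as plt

    data = export_plot_data(result)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sig = data["significant"].to_numpy(dtype=bool)
    ax.scatter(data.loc[~sig, "log2fc"], data.loc[~sig, "neg_log10_p"], s=8, c="0.6")
    ax.scatter(data.loc[sig, "log2fc"], data.loc[sig, "neg_log10_p"], s=10, c="C3")
    ax.set_xlabel("log2 fold change (debiased)")
    ax.set_ylabel("-log10 p")
    return ax
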