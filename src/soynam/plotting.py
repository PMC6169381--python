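"""Optional diagnostic plot: -log10(p) by genetic position."""

from __future__ import annotations


def manhattan(result, ax=None, threshold: float | None = None):
    """Scatter of per-marker -log10(p) along the map, one panel-wide axis.

    Requires matplotlib (the ``plot`` extra).  Returns the axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    stats = result.stats
    offset = 0.0
    for chrom, sub in stats.groupby("chrom", sort=False):
        ax.scatter(sub["cM"] + offset, sub["neg_log10_p"], s=8, label=str(chrom))
        offset += sub["cM"].max() + 10.0
    thr = result.config.sig_threshold if threshold is None else threshold
    ax.axhline(thr, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("position (cM, chromosomes concatenated)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    if result.trait:
        ax.set_title(result.trait)
    return ax
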