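"""Expression-profile line plots along hairpin sequences."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_profile_grid(
    profiles_tsv: str | Path, output: str | Path, max_loci: int = 12
) -> None:
    """One panel per hairpin: 5'-start counts by position, coloured by tissue."""
    df = pd.read_csv(profiles_tsv, sep="\t")
    hids = sorted(df.hairpin_id.unique())[:max_loci]
    if not hids:
        raise ValueError("no profiles to plot")
    ncols = 3
    nrows = (len(hids) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 2.6 * nrows), squeeze=False)
    for ax, hid in zip(axes.flat, hids):
        sub = df[df.hairpin_id == hid]
        for tissue, tsub in sub.groupby("tissue"):
            ax.plot(tsub.position, tsub.start_count, label=tissue, lw=1)
        ax.set_title(hid, fontsize=8)
        ax.set_xlabel("hairpin position")
        ax.set_ylabel("5' start count")
    for ax in axes.flat[len(hids):]:
        ax.axis("off")
    handles, labels = axes.flat[0].get_legend_handles_labels()
    fig.legend(handles, labels, loc="lower center", ncol=5, fontsize=7)
    fig.tight_layout(rect=(0, 0.06, 1, 1))
    fig.savefig(output, dpi=120)
    plt.close(fig)
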