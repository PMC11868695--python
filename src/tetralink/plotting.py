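"""Minimal figures: the bubble matrix of MAG counts/fractions and profile
line plots.  Figures are optional outputs; no analysis depends on them."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .attribution_profiles import MagFractionCell
from .depth_abundance import TaxonDepthProfile


def bubble_matrix(cells: Sequence[MagFractionCell], path: str) -> None:
    """Taxon x sample bubble plot: size = number of MAGs, colour = fraction
    of MAGs carrying the gene family."""
    if not cells:
        raise ValueError("no cells to plot")
    taxa = sorted({c.taxon for c in cells})
    samples = sorted({c.sample for c in cells}, key=_depth_key)
    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * len(samples), 1 + 0.4 * len(taxa))
    )
    xs = [samples.index(c.sample) for c in cells]
    ys = [taxa.index(c.taxon) for c in cells]
    sizes = [30 * c.n_mags for c in cells]
    colours = [c.fraction for c in cells]
    sc = ax.scatter(xs, ys, s=sizes, c=colours, cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(samples)), samples, rotation=90)
    ax.set_yticks(range(len(taxa)), taxa)
    ax.set_xlabel("sample (depth, m)")
    fig.colorbar(sc, ax=ax, label="fraction of MAGs with homologue")
    family = cells[0].family
    ax.set_title(f"MAGs with {family} homologue")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def profile_lines(
    profiles: Iterable[TaxonDepthProfile],
    samples: Sequence[str],
    path: str,
    title: str = "",
) -> None:
    """Normalized-depth profiles of each taxon across the sample series."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for p in profiles:
        ax.plot(range(len(samples)), [p.values.get(s, 0.0) for s in samples],
                marker="o", label=f"{p.taxon} ({p.family})")
    ax.set_xticks(range(len(samples)), samples, rotation=90)
    ax.set_xlabel("sample (depth, m)")
    ax.set_ylabel("summed normalized depth")
    if title:
        ax.set_title(title)
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _depth_key(label: str):
    try:
        return (0, float(label))
    except ValueError:
        return (1, label)
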