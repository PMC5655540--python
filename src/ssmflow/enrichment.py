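"""Mutation probabilities and log2 enrichment with low-count masking.

Per-cell mutation probabilities are counts normalized by the grand total
over all positions and all 21 mutation types (wild-type identity cells
excluded from numerator and denominator). Enrichment is the log2 ratio of
selected over naive probabilities, computed only where the naive library
has more than ``min_count`` reads for that mutation; everything else is
masked with an explicit reason rather than numerically faked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

from .variant_counting import CountMatrix

__all__ = [
    "Mask",
    "FrequencyMatrix",
    "EnrichmentMatrix",
    "compute_probabilities",
    "compute_enrichment",
    "render_heatmap",
]


class Mask(IntEnum):
    OK = 0
    LOW_COUNT = 1
    WT_CELL = 2
    NO_DATA = 3


@dataclass
class FrequencyMatrix:
    """Per-cell mutation probabilities p_ij summing to 1 over unmasked cells."""

    p: np.ndarray  # (N, 21) floats in [0, 1]
    wt_mask: np.ndarray
    library_label: str = ""

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("probabilities outside [0, 1]")


@dataclass
class EnrichmentMatrix:
    """Masked log2 enrichment values E_ij with mask provenance."""

    E: np.ndarray  # (N, 21) floats; NaN wherever mask != OK
    mask: np.ndarray  # (N, 21) Mask codes
    min_count: int = 15
    rounds_compared: tuple[str, str] = ("naive", "selected")
    metadata: dict = field(default_factory=dict)

    columns = CountMatrix.columns

    def ok(self) -> np.ndarray:
        return self.mask == Mask.OK

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = pd.RangeIndex(1, self.E.shape[0] + 1, name="position")
        cols = list(self.columns)
        e_frame = pd.DataFrame(self.E, index=idx, columns=cols)
        mask_frame = pd.DataFrame(
            np.vectorize(lambda m: Mask(m).name)(self.mask), index=idx, columns=cols
        )
        return e_frame, mask_frame


def compute_probabilities(counts: CountMatrix, library_label: str | None = None) -> FrequencyMatrix:
    """Normalize a count matrix into mutation probabilities.

    p_ij = f_ij / sum_{i,j} f_ij, summed over all positions and the 21
    mutation types; wild-type identity cells are excluded throughout.
    """
    f = counts.counts.astype(np.float64)
    f[counts.wt_mask] = 0.0
    total = f.sum()
    if total == 0:
        raise ValueError("empty_library: all counts are zero")
    return FrequencyMatrix(
        p=f / total,
        wt_mask=counts.wt_mask.copy(),
        library_label=library_label if library_label is not None else counts.library_label,
    )


def compute_enrichment(
    naive: CountMatrix,
    selected: CountMatrix,
    min_count: int = 15,
    require_selected_count: bool = False,
    pseudocount: float = 0.0,
) -> EnrichmentMatrix:
    """Compute E_ij = log2(p_ij^selected / p_ij^naive) with masking.

    Cells are masked LOW_COUNT when the naive count is <= ``min_count``
    (optionally also requiring the selected count to exceed it), WT_CELL at
    wild-type identities, and NO_DATA when the naive library qualifies but
    the selected count is zero. ``pseudocount`` (default 0, i.e. none) is an
    additive count applied to both libraries before normalization, for
    exploratory use only; it is recorded in the metadata.
    """
    if naive.counts.shape != selected.counts.shape:
        raise ValueError("count matrices differ in shape")
    if not np.array_equal(naive.wt_mask, selected.wt_mask):
        raise ValueError("count matrices disagree on wild-type identity cells")

    def probs(matrix: CountMatrix) -> np.ndarray:
        f = matrix.counts.astype(np.float64) + pseudocount
        f[matrix.wt_mask] = 0.0
        return f / f.sum()

    p_naive = probs(naive)
    p_sel = probs(selected)

    mask = np.full(naive.counts.shape, Mask.OK, dtype=np.int64)
    mask[naive.counts <= min_count] = Mask.LOW_COUNT
    if require_selected_count:
        mask[selected.counts <= min_count] = Mask.LOW_COUNT
    if pseudocount == 0.0:
        mask[(mask == Mask.OK) & (selected.counts == 0)] = Mask.NO_DATA
    mask[naive.wt_mask] = Mask.WT_CELL

    E = np.full(naive.counts.shape, np.nan)
    ok = mask == Mask.OK
    with np.errstate(divide="ignore"):
        E[ok] = np.log2(p_sel[ok] / p_naive[ok])

    return EnrichmentMatrix(
        E=E,
        mask=mask,
        min_count=min_count,
        rounds_compared=(naive.library_label, selected.library_label),
        metadata={
            "min_count": min_count,
            "require_selected_count": require_selected_count,
            "pseudocount": pseudocount,
        },
    )


# green = depletion, red = enrichment; grey for insufficient data
_CMAP = LinearSegmentedColormap.from_list(
    "enrichment", ["#1a7a1a", "#ffffff", "#c21807"]
)


def render_heatmap(E: EnrichmentMatrix, path_prefix) -> dict[str, str]:
    """Write the enrichment matrix as TSVs plus a heat-map image.

    Emits ``<prefix>.tsv`` (E values, empty cells where masked),
    ``<prefix>.mask.tsv``, ``<prefix>.png`` and ``<prefix>.json`` run
    metadata; returns the paths.
    """
    prefix = str(path_prefix)
    e_frame, mask_frame = E.to_frames()
    paths = {
        "values": prefix + ".tsv",
        "mask": prefix + ".mask.tsv",
        "image": prefix + ".png",
        "metadata": prefix + ".json",
    }
    e_frame.to_csv(paths["values"], sep="\t")
    mask_frame.to_csv(paths["mask"], sep="\t")
    with open(paths["metadata"], "w") as out:
        json.dump(
            {"rounds_compared": list(E.rounds_compared), **E.metadata}, out, indent=2
        )

    n_pos = E.E.shape[0]
    fig, ax = plt.subplots(figsize=(max(6.0, n_pos * 0.12), 4.5))
    ok = E.ok()
    span = np.nanmax(np.abs(E.E)) if ok.any() else 1.0
    span = max(float(span), 1e-9)
    shown = np.ma.masked_where(~ok, E.E)
    ax.pcolormesh(
        shown.T,
        cmap=_CMAP,
        norm=TwoSlopeNorm(vcenter=0.0, vmin=-span, vmax=span),
    )
    ax.set_facecolor("#9a9a9a")  # grey shows through masked cells
    wt_i, wt_j = np.nonzero(E.mask == Mask.WT_CELL)
    ax.plot(wt_i + 0.5, wt_j + 0.5, ".", color="black", markersize=2)
    ax.set_yticks(np.arange(21) + 0.5, list(E.columns))
    ax.set_xlabel("position")
    ax.set_ylabel("mutation")
    ax.set_title(f"log2 enrichment: {E.rounds_compared[1]} vs {E.rounds_compared[0]}")
    fig.tight_layout()
    fig.savefig(paths["image"], dpi=150)
    plt.close(fig)
    return paths


def read_enrichment_tsv(path, mask_path) -> EnrichmentMatrix:
    """Read back a rendered enrichment TSV pair."""
    e_frame = pd.read_csv(path, sep="\t", index_col="position")
    mask_frame = pd.read_csv(mask_path, sep="\t", index_col="position")
    mask = np.vectorize(lambda name: int(Mask[name]))(mask_frame.to_numpy())
    return EnrichmentMatrix(E=e_frame.to_numpy(dtype=np.float64), mask=mask)
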