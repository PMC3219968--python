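"""Dot-plot rendering of whole-genome comparisons.

Matches are drawn in concatenated genome coordinates (one axis per
genome, sequences laid end to end with boundary gridlines) and coloured
by percent similarity.  A per-pair view links two sequence bars with
lines coloured by orientation (red = parallel, blue = anti-parallel).

The plot *data layer* — the coordinates and colours handed to the
renderer — is exposed separately from the rendering so it can be tested
without touching image bytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless-safe; figures are written, not shown

import matplotlib.pyplot as plt
import pandas as pd

from .io import PARALLEL, GenomeIndex, MatchSet

ORDER_BY_LENGTH_DESC = "by_length_desc"
ORDER_BY_ID = "by_id"


@dataclass(frozen=True)
class PlotSpec:
    """Rendering options for whole-genome dot plots."""

    ordering: str = ORDER_BY_ID
    min_seq_len: int = 0
    color_scale: tuple[float, float] = (50.0, 100.0)
    highlight_boxes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.color_scale
        if not (0.0 <= lo <= 100.0 and 0.0 <= hi <= 100.0):
            raise ValueError("color scale endpoints must lie in [0, 100]")
        if self.ordering not in (ORDER_BY_LENGTH_DESC, ORDER_BY_ID):
            raise ValueError(f"unknown ordering {self.ordering!r}")


def axis_offsets(genome: GenomeIndex, spec: PlotSpec) -> dict[str, int]:
    """Concatenated-coordinate offset of each retained sequence."""
    seqs = [(s, l) for s, l in genome.sequences if l >= spec.min_seq_len]
    if spec.ordering == ORDER_BY_LENGTH_DESC:
        seqs.sort(key=lambda sl: (-sl[1], sl[0]))
    else:
        seqs.sort(key=lambda sl: sl[0])
    offsets: dict[str, int] = {}
    pos = 0
    for seq_id, length in seqs:
        offsets[seq_id] = pos
        pos += length
    return offsets


def genome_pair_layout(matchset: MatchSet, spec: PlotSpec | None = None) -> pd.DataFrame:
    """Data layer of the whole-genome dot plot.

    One row per match with concatenated ``x``/``y`` midspan
    coordinates, the percent similarity used for colouring, and the
    sequence pair it belongs to.  Matches on sequences below the spec's
    length floor are omitted.
    """
    spec = spec or PlotSpec()
    off_a = axis_offsets(matchset.genome_a, spec)
    off_b = axis_offsets(matchset.genome_b, spec)
    rows = []
    for m in matchset.matches:
        if m.ref_id not in off_a or m.qry_id not in off_b:
            continue
        rows.append(
            {
                "seq_a": m.ref_id,
                "seq_b": m.qry_id,
                "x": off_a[m.ref_id] + (m.ref_start + m.ref_end) / 2,
                "y": off_b[m.qry_id] + (m.qry_start + m.qry_end) / 2,
                "pct_similarity": m.pct_similarity,
                "orientation": m.orientation,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["seq_a", "seq_b", "x", "y", "pct_similarity", "orientation"],
    )


def pair_links_layout(matchset: MatchSet, seq_a: str, seq_b: str) -> pd.DataFrame:
    """Data layer of the two-bar pair view: one link per match.

    Raises
    ------
    KeyError
        When the pair shares no matches or a sequence id is unknown.
    """
    if seq_a not in matchset.genome_a or seq_b not in matchset.genome_b:
        raise KeyError(f"unknown sequence pair ({seq_a!r}, {seq_b!r})")
    rows = [
        {
            "a_mid": (m.ref_start + m.ref_end) / 2,
            "b_mid": (m.qry_start + m.qry_end) / 2,
            "orientation": m.orientation,
            "color": "red" if m.orientation == PARALLEL else "blue",
        }
        for m in matchset.matches
        if m.ref_id == seq_a and m.qry_id == seq_b
    ]
    if not rows:
        raise KeyError(f"no matches between {seq_a!r} and {seq_b!r}")
    return pd.DataFrame(rows, columns=["a_mid", "b_mid", "orientation", "color"])


def plot_genome_pair(
    matchset: MatchSet, spec: PlotSpec | None = None, out: str | Path = "dotplot.png"
) -> Path:
    """Render the whole-genome dot plot to ``out`` (PNG/SVG by suffix)."""
    spec = spec or PlotSpec()
    layout = genome_pair_layout(matchset, spec)
    off_a = axis_offsets(matchset.genome_a, spec)
    off_b = axis_offsets(matchset.genome_b, spec)
    len_a = matchset.genome_a.lengths
    len_b = matchset.genome_b.lengths

    fig, ax = plt.subplots(figsize=(8, 8))
    if not layout.empty:
        sc = ax.scatter(
            layout["x"],
            layout["y"],
            c=layout["pct_similarity"],
            s=2,
            cmap="viridis",
            vmin=spec.color_scale[0],
            vmax=spec.color_scale[1],
        )
        fig.colorbar(sc, ax=ax, label="% similarity")
    for seq_id, off in off_a.items():
        ax.axvline(off + len_a[seq_id], color="0.8", lw=0.4)
    for seq_id, off in off_b.items():
        ax.axhline(off + len_b[seq_id], color="0.8", lw=0.4)
    for a, b in spec.highlight_boxes:
        if a in off_a and b in off_b:
            ax.add_patch(
                plt.Rectangle(
                    (off_a[a], off_b[b]),
                    len_a[a],
                    len_b[b],
                    fill=False,
                    edgecolor="red",
                    lw=1.0,
                )
            )
    ax.set_xlim(0, sum(len_a[s] for s in off_a))
    ax.set_ylim(0, sum(len_b[s] for s in off_b))
    ax.set_xlabel(matchset.genome_a.label)
    ax.set_ylabel(matchset.genome_b.label)
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_pair_links(
    matchset: MatchSet, seq_a: str, seq_b: str, out: str | Path = "links.png"
) -> Path:
    """Render the two-bar homology-link view for one sequence pair."""
    layout = pair_links_layout(matchset, seq_a, seq_b)
    la = matchset.genome_a.length_of(seq_a)
    lb = matchset.genome_b.length_of(seq_b)
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.hlines([1.0, 0.0], 0, [la, lb], color="black", lw=4)
    for _, row in layout.iterrows():
        ax.plot([row["a_mid"], row["b_mid"]], [1.0, 0.0], color=row["color"], lw=0.5)
    ax.set_yticks([0.0, 1.0])
    ax.set_yticklabels([seq_b, seq_a])
    ax.set_xlim(0, max(la, lb))
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
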