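"""Per-residue spatial MTR scoring, chain averaging, complex scoring, colors.

A score track holds one MTR per mapped (chain, residue); positions without
density neither score nor serve as window neighbours.  Chain-averaged
tracks are indexed by protein position; multi-protein ("complex") scoring
pools window tallies across all member residues regardless of source gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import pandas as pd

from .mtr_core import CodonVariantCounts, MTRScore, mtr_over_set
from .structure3d import ResidueAlignmentMap, ResidueSite, knn_window

__all__ = [
    "MTRScoreTrack",
    "ColorScale",
    "score_structure",
    "average_chains",
    "score_complex",
    "assign_colors",
    "track_to_frame",
]

GREY = (0.5, 0.5, 0.5)
BLUE = (0.0, 0.0, 1.0)
WHITE = (1.0, 1.0, 1.0)
RED = (1.0, 0.0, 0.0)


@dataclass
class MTRScoreTrack:
    structure_id: str
    gene_id: str
    window_size: int
    per_chain: dict[tuple[str, int], MTRScore] = field(default_factory=dict)
    averaged: dict[int, float] = field(default_factory=dict)  # protein position -> mean score

    def defined_chain_scores(self) -> dict[tuple[str, int], float]:
        return {k: s.value for k, s in self.per_chain.items() if s.value is not None}


@dataclass(frozen=True)
class ColorScale:
    """Piecewise-linear blue-white-red scale anchored at (min, mid, max)."""

    low: float
    mid: float
    high: float
    policy: str = "median"

    def __post_init__(self) -> None:
        if not (self.low <= self.mid <= self.high):
            raise ValueError(f"anchors must satisfy min <= mid <= max, got {self}")

    def rgb(self, value: float | None) -> tuple[float, float, float]:
        if value is None:
            return GREY
        if self.low == self.high:
            return WHITE
        v = min(max(value, self.low), self.high)
        if v <= self.mid:
            t = 1.0 if self.mid == self.low else (v - self.low) / (self.mid - self.low)
            a, b = BLUE, WHITE
        else:
            t = (v - self.mid) / (self.high - self.mid)
            a, b = WHITE, RED
        return tuple(a[i] + t * (b[i] - a[i]) for i in range(3))


def _counts_by_position(counts: list[CodonVariantCounts]) -> dict[int, CodonVariantCounts]:
    return {c.codon_index: c for c in counts}


def score_structure(
    counts: list[CodonVariantCounts],
    amap: ResidueAlignmentMap,
    sites: list[ResidueSite],
    k: int,
) -> MTRScoreTrack:
    """Score every mapped residue with the MTR of its k-nearest window.

    Windows are drawn over mapped residues only; the focal residue's
    score keys by (chain, residue number).
    """
    if k < 1:
        raise ValueError("window size k must be >= 1")
    if amap.coverage == 0 or not amap.entries:
        raise ValueError("alignment map covers no positions")
    by_pos = _counts_by_position(counts)
    mapped_sites = [s for s in sites if amap.position_of(s.chain_id, s.residue_number) is not None]
    if not mapped_sites:
        raise ValueError("no structure sites are mapped by the alignment map")
    for s in mapped_sites:
        pos = amap.position_of(s.chain_id, s.residue_number)
        if pos not in by_pos:
            raise ValueError(f"no codon counts for mapped position {pos}")

    gene_id = counts[0].gene_id if counts else amap.gene_id
    track = MTRScoreTrack(
        structure_id=mapped_sites[0].structure_id, gene_id=gene_id, window_size=k
    )
    for focal in mapped_sites:
        window = knn_window(mapped_sites, focal, k)
        window_counts = [
            by_pos[amap.position_of(w.chain_id, w.residue_number)] for w in window
        ]
        track.per_chain[focal.key] = mtr_over_set(window_counts)
    return track


def average_chains(track: MTRScoreTrack, amap: ResidueAlignmentMap) -> MTRScoreTrack:
    """Collapse per-chain scores to one value per protein position.

    Unweighted arithmetic mean over chains with a defined score; positions
    undefined in every chain stay missing.
    """
    if not track.per_chain:
        raise ValueError("track has no per-chain scores")
    averaged: dict[int, float] = {}
    for pos in amap.positions:
        values = []
        for chain, resnum in amap.residues_at(pos):
            score = track.per_chain.get((chain, resnum))
            if score is not None and score.value is not None:
                values.append(score.value)
        if values:
            averaged[pos] = sum(values) / len(values)
    out = MTRScoreTrack(
        structure_id=track.structure_id,
        gene_id=track.gene_id,
        window_size=track.window_size,
        per_chain=dict(track.per_chain),
        averaged=averaged,
    )
    return out


def score_complex(
    gene_inputs: list[tuple[str, list[CodonVariantCounts], ResidueAlignmentMap]],
    sites: list[ResidueSite],
    k: int,
    pooled: bool = True,
) -> dict[str, MTRScoreTrack]:
    """Intra-complex scoring over a pooled multi-protein site cloud.

    Each window may mix residues from several proteins; with
    ``pooled=True`` (default) its tallies sum over all member residues
    using each member's own gene table, with ``pooled=False`` only the
    focal gene's members contribute.  Every residue must belong to
    exactly one gene.
    """
    if len(gene_inputs) < 2:
        raise ValueError("complex scoring needs at least two genes")
    owner: dict[tuple[str, int], tuple[str, int]] = {}  # residue key -> (gene, position)
    counts_by_gene: dict[str, dict[int, CodonVariantCounts]] = {}
    for gene_id, counts, amap in gene_inputs:
        counts_by_gene[gene_id] = _counts_by_position(counts)
        for pos, chain, resnum in amap.entries:
            key = (chain, resnum)
            if key in owner and owner[key][0] != gene_id:
                raise ValueError(f"residue {key} mapped to two genes")
            owner[key] = (gene_id, pos)

    mapped_sites = [s for s in sites if s.key in owner]
    if not mapped_sites:
        raise ValueError("no structure sites are mapped by any gene")

    tracks = {
        gene_id: MTRScoreTrack(
            structure_id=mapped_sites[0].structure_id, gene_id=gene_id, window_size=k
        )
        for gene_id, _, _ in gene_inputs
    }
    for focal in mapped_sites:
        focal_gene, _ = owner[focal.key]
        window = knn_window(mapped_sites, focal, k)
        window_counts = []
        for w in window:
            gene_id, pos = owner[w.key]
            if not pooled and gene_id != focal_gene:
                continue
            window_counts.append(counts_by_gene[gene_id][pos])
        tracks[focal_gene].per_chain[focal.key] = mtr_over_set(window_counts)
    return tracks


def assign_colors(
    track: MTRScoreTrack,
    policy: str = "median",
) -> tuple[dict[int, tuple[float, float, float]], ColorScale]:
    """Per-position RGB from the averaged track under a per-structure scale.

    ``policy`` is ``"median"`` (mid anchor at the track median) or
    ``"fixed"`` (mid anchor pinned to 1.0).  Missing positions are grey.
    """
    values = [v for v in track.averaged.values() if v is not None]
    if not values:
        raise ValueError("track has no defined averaged scores")
    lo, hi = min(values), max(values)
    if policy == "median":
        mid = median(values)
    elif policy == "fixed":
        mid = min(max(1.0, lo), hi)
    else:
        raise ValueError(f"unknown color policy {policy!r}")
    scale = ColorScale(low=lo, mid=mid, high=hi, policy=policy)
    colors = {pos: scale.rgb(track.averaged.get(pos)) for pos in track.averaged}
    return colors, scale


def track_to_frame(track: MTRScoreTrack, amap: ResidueAlignmentMap | None = None) -> pd.DataFrame:
    """Averaged track as a `gene_id position score n_obs` DataFrame.

    ``n_obs`` is the largest window observation total among the chains
    contributing to a position (0 when the map is not supplied).
    """
    rows = []
    for pos in sorted(track.averaged):
        n_obs = 0
        if amap is not None:
            for chain, resnum in amap.residues_at(pos):
                score = track.per_chain.get((chain, resnum))
                if score is not None:
                    n_obs = max(n_obs, score.n_obs)
        rows.append(
            {
                "gene_id": track.gene_id,
                "position": pos,
                "score": track.averaged[pos],
                "n_obs": n_obs,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "position", "score", "n_obs"])
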