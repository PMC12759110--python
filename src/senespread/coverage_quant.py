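"""Density readouts from coverage tracks: window densities, TSS-centered
profiles, per-gene profile matrices, and scaled gene-body metagene profiles.

Normalization unit throughout: tags per kb per 10 million library tags.
Fractional bin overlap is apportioned by exact base overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, GeneModel, GenomicWindow, resolve_window

__all__ = [
    "WindowDensity",
    "MetageneProfile",
    "ProfileMatrix",
    "window_density",
    "tss_profile",
    "metagene_profile",
    "profile_matrix",
    "gene_body_density",
    "norm_factor",
]

log = logging.getLogger(__name__)

LIBRARY_UNIT = 1e7  # densities reported per 10 million library tags


def norm_factor(window_len: float, library_size: float) -> float:
    """Divisor converting raw tags to tags/kb/10M library tags."""
    if library_size <= 0:
        return 0.0
    return (window_len / 1000.0) * (library_size / LIBRARY_UNIT)


@dataclass(frozen=True)
class WindowDensity:
    gene_id: str
    chrom: str
    start: int
    end: int
    raw_tags: float
    norm_density: float


@dataclass(frozen=True)
class MetageneProfile:
    n_flank_bins: int
    n_body_bins: int
    flank_bp: int
    bin_means: np.ndarray  # length 2*n_flank_bins + n_body_bins
    n_genes: int
    n_excluded_short: int

    @property
    def body_means(self) -> np.ndarray:
        return self.bin_means[self.n_flank_bins : self.n_flank_bins + self.n_body_bins]

    def to_frame(self) -> pd.DataFrame:
        labels = (
            [f"flank5_{i}" for i in range(self.n_flank_bins)]
            + [f"body_{i}" for i in range(self.n_body_bins)]
            + [f"flank3_{i}" for i in range(self.n_flank_bins)]
        )
        return pd.DataFrame({"bin": labels, "mean_density": self.bin_means})


@dataclass(frozen=True)
class ProfileMatrix:
    gene_ids: list[str]
    bin_starts: np.ndarray  # window-relative coordinates of bin left edges
    values: np.ndarray  # genes x bins, norm_density

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[str(int(s)) for s in self.bin_starts]
        )
        df.insert(0, "gene_id", self.gene_ids)
        return df


# ---------------------------------------------------------------------------


def window_density(
    track: CoverageTrack, gene: GeneModel, window: GenomicWindow
) -> WindowDensity:
    """Raw tag sum and normalized density over a gene-relative window."""
    chrom, start, end = resolve_window(gene, window)
    if end <= start:
        raise ValueError(
            f"window {window} fully clipped away for gene {gene.gene_id}"
        )
    raw = track.window_sum(chrom, start, end)
    nf = norm_factor(end - start, track.library_size)
    return WindowDensity(
        gene_id=gene.gene_id, chrom=chrom, start=start, end=end,
        raw_tags=raw, norm_density=raw / nf if nf > 0 else 0.0,
    )


def _gene_bin_densities(
    track: CoverageTrack, gene: GeneModel, edges: np.ndarray
) -> np.ndarray:
    """Per-bin normalized densities over monotone edges in genomic orientation,
    flipped to transcribed orientation for minus-strand genes."""
    sums = track.binned_sums(gene.chrom, edges)
    widths = np.diff(edges)
    nf = (widths / 1000.0) * (track.library_size / LIBRARY_UNIT)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(nf > 0, sums / np.where(nf > 0, nf, 1.0), 0.0)
    if gene.strand == "-":
        dens = dens[::-1]
    return dens


def tss_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    flank_bp: int = 3000,
    bin_bp: int = 50,
) -> pd.DataFrame:
    """Mean normalized density per bin around the TSS, transcribed orientation.

    Returns a frame with columns ``rel_start`` (bin left edge relative to the
    TSS), ``mean_density`` and ``n_genes``.  Genes whose window is clipped at
    the chromosome start are excluded from the clipped bins' means only.
    """
    if not genes:
        raise ValueError("empty gene list")
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be divisible by bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    total = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for gene in genes:
        if gene.strand == "+":
            edges = gene.tss + np.arange(-flank_bp, flank_bp + bin_bp, bin_bp)
        else:
            edges = gene.tss + np.arange(flank_bp, -flank_bp - bin_bp, -bin_bp)[::-1]
        valid = edges[:-1] >= 0  # genomic orientation mask for unclipped bins
        dens = _gene_bin_densities(track, gene, np.maximum(edges, 0))
        if gene.strand == "-":
            valid = valid[::-1]
        total[valid] += dens[valid]
        counts[valid] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, total / np.maximum(counts, 1), 0.0)
    return pd.DataFrame(
        {
            "rel_start": np.arange(-flank_bp, flank_bp, bin_bp),
            "mean_density": means,
            "n_genes": counts,
        }
    )


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    n_body_bins: int = 100,
    flank_bp: int = 2000,
    n_flank_bins: int = 20,
) -> MetageneProfile:
    """Mean density over scaled gene bodies with fixed-width flanks.

    Each gene body is split into ``n_body_bins`` equal-width bins in
    transcribed orientation; flanks are fixed ``flank_bp`` windows in
    ``n_flank_bins`` bins.  Genes shorter than ``n_body_bins`` bases are
    excluded and counted.
    """
    usable = [g for g in genes if g.length >= n_body_bins]
    n_excluded = len(genes) - len(usable)
    if n_excluded:
        log.info("metagene_profile: excluded %d genes shorter than %d bp",
                 n_excluded, n_body_bins)
    if not usable:
        raise ValueError("all genes excluded from metagene profile")

    n_bins = 2 * n_flank_bins + n_body_bins
    total = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    flank_edges = np.linspace(0, flank_bp, n_flank_bins + 1)
    for gene in usable:
        body = np.linspace(gene.start, gene.end, n_body_bins + 1)
        edges = np.concatenate(
            [gene.start - flank_bp + flank_edges[:-1], body, gene.end + flank_edges[1:]]
        )
        valid = edges[:-1] >= 0
        dens = _gene_bin_densities(track, gene, np.maximum(edges, 0.0))
        if gene.strand == "-":
            valid = valid[::-1]
        total[valid] += dens[valid]
        counts[valid] += 1
    means = np.where(counts > 0, total / np.maximum(counts, 1), 0.0)
    return MetageneProfile(
        n_flank_bins=n_flank_bins,
        n_body_bins=n_body_bins,
        flank_bp=flank_bp,
        bin_means=means,
        n_genes=len(usable),
        n_excluded_short=n_excluded,
    )


def profile_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    anchor_window: GenomicWindow,
    bin_bp: int,
    sort_window: GenomicWindow | None = None,
) -> ProfileMatrix:
    """Per-gene binned densities over an anchor window, one row per gene.

    When ``sort_window`` is given rows are ordered by descending density in
    that window, ties broken by ascending gene_id; otherwise by gene_id.
    """
    span = anchor_window.length
    if span < bin_bp:
        raise ValueError("anchor window spans less than one bin")
    n_bins = span // bin_bp
    rows = []
    for gene in genes:
        rel = gene.tss if anchor_window.anchor == "tss" else gene.tes
        if gene.strand == "+":
            edges = rel + anchor_window.rel_start + np.arange(0, n_bins * bin_bp + bin_bp, bin_bp)
        else:
            edges = rel - anchor_window.rel_start - np.arange(0, n_bins * bin_bp + bin_bp, bin_bp)[::-1]
        dens = _gene_bin_densities(track, gene, np.maximum(edges, 0))
        key = (
            -window_density(track, gene, sort_window).norm_density
            if sort_window is not None
            else 0.0
        )
        rows.append((key, gene.gene_id, dens))
    rows.sort(key=lambda r: (r[0], r[1]))
    return ProfileMatrix(
        gene_ids=[r[1] for r in rows],
        bin_starts=anchor_window.rel_start + np.arange(n_bins) * bin_bp,
        values=np.vstack([r[2] for r in rows]),
    )


def gene_body_density(
    track: CoverageTrack, gene: GeneModel, promoter_exclusion_bp: int = 0
) -> WindowDensity:
    """Density over the gene body from TSS + exclusion to the TES."""
    if gene.length <= promoter_exclusion_bp:
        raise ValueError(
            f"gene {gene.gene_id} length {gene.length} <= exclusion "
            f"{promoter_exclusion_bp}"
        )
    window = GenomicWindow("tss", promoter_exclusion_bp, gene.length)
    return window_density(track, gene, window)
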