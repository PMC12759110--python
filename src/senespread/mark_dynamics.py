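"""Histone-mark redistribution between conditions: promoter loss, gene-body
gain, spreading ratios, mark-defined gene selection, and the association of
mark change with expression change.

Mark fold changes use a pseudocount on normalized densities (default 0.5
tags/kb/10M): zero-signal promoters make this mandatory.  Selection thresholds
are strict inequalities.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage_quant import gene_body_density, window_density
from .genome_io import CoverageTrack, GeneModel, GenomicWindow
from .set_stats import two_tailed_ztest
from .transcription_analysis import LengthBinning

__all__ = [
    "GENE_BODY",
    "mark_change",
    "select_by_mark_change",
    "mark_expression_association",
    "spreading_summary",
    "DEFAULT_MARK_PSEUDOCOUNT",
]

log = logging.getLogger(__name__)

GENE_BODY = "gene_body"
DEFAULT_MARK_PSEUDOCOUNT = 0.5  # tags/kb/10M, applied to normalized densities


def _region_density(
    track: CoverageTrack,
    gene: GeneModel,
    region: GenomicWindow | str,
    promoter_exclusion_bp: int = 0,
) -> float:
    if region == GENE_BODY:
        return gene_body_density(track, gene, promoter_exclusion_bp).norm_density
    return window_density(track, gene, region).norm_density


def mark_change(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    genes: Sequence[GeneModel],
    region: GenomicWindow | str,
    pseudocount: float = DEFAULT_MARK_PSEUDOCOUNT,
    promoter_exclusion_bp: int = 0,
) -> pd.DataFrame:
    """Per-gene log2 change of normalized density in a region between conditions.

    ``region`` is either a :class:`GenomicWindow` or the string ``"gene_body"``.
    log2fc_mark = log2((density_b + pc) / (density_a + pc)); swapping the
    conditions negates it exactly.
    """
    region_name = region if isinstance(region, str) else (
        f"{region.anchor}:{region.rel_start}..{region.rel_end}"
    )
    rows = []
    for gene in genes:
        da = _region_density(track_a, gene, region, promoter_exclusion_bp)
        db = _region_density(track_b, gene, region, promoter_exclusion_bp)
        rows.append(
            (
                gene.gene_id,
                region_name,
                da,
                db,
                float(np.log2(db + pseudocount) - np.log2(da + pseudocount)),
            )
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "region", "density_a", "density_b", "log2fc_mark"]
    )
    df["pseudocount"] = pseudocount
    return df


def select_by_mark_change(
    records: pd.DataFrame, threshold: float, direction: str = "below"
) -> set[str]:
    """Genes whose log2fc_mark is strictly below (or above) the threshold."""
    if records.empty:
        raise ValueError("no mark-change records")
    if direction == "below":
        mask = records["log2fc_mark"] < threshold
    elif direction == "above":
        mask = records["log2fc_mark"] > threshold
    else:
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    return set(records.loc[mask, "gene_id"])


def mark_expression_association(
    mark_records: pd.DataFrame,
    fc_records: pd.DataFrame,
    bin_edges: Sequence[float],
    min_n: int = 3,
    reference: str = "all",
) -> pd.DataFrame:
    """Expression log2FC distribution per mark-change bin, with z-tests against
    a reference set.

    Bins on log2fc_mark are (-inf, e1), [e1, e2), ..., [ek, inf).  Each bin
    reports n, mean and median expression log2FC, and a two-tailed z-test
    against the reference; bins with n < min_n are flagged and not tested.

    ``reference="all"`` compares each bin against the full overlapping gene
    set (so a bin equal to the reference gives z = 0 exactly);
    ``reference="rest"`` compares against the disjoint complement, which is
    the form whose permutation null is uniform.  The choice is recorded in
    the output.
    """
    if reference not in ("all", "rest"):
        raise ValueError(f"reference must be 'all' or 'rest', got {reference!r}")
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    mark = mark_records.set_index("gene_id")["log2fc_mark"]
    expr = fc_records["combined"] if "combined" in fc_records else fc_records
    if isinstance(expr, pd.DataFrame):
        expr = expr.iloc[:, 0]
    common = mark.index.intersection(expr.index)
    if len(common) == 0:
        raise ValueError("no gene overlap between mark and expression records")
    mark, expr = mark[common], expr[common]

    bounds = [-np.inf, *edges, np.inf]
    rows = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        in_bin = (mark >= lo) & (mark < hi)
        sel = expr[in_bin].to_numpy()
        ref = expr.to_numpy() if reference == "all" else expr[~in_bin].to_numpy()
        row = {
            "bin": f"[{lo},{hi})",
            "bin_low": lo,
            "bin_high": hi,
            "n": len(sel),
            "mean_expr_log2fc": float(np.mean(sel)) if len(sel) else np.nan,
            "median_expr_log2fc": float(np.median(sel)) if len(sel) else np.nan,
            "reference": reference,
        }
        if len(sel) >= min_n and len(ref) >= 3:
            res = two_tailed_ztest(sel, ref)
            row.update(z=res.statistic, p_value=res.p_value, tested=True)
        else:
            row.update(z=np.nan, p_value=np.nan, tested=False)
        rows.append(row)
    return pd.DataFrame(rows)


def spreading_summary(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    genes: Sequence[GeneModel],
    promoter_window: GenomicWindow,
    promoter_exclusion_bp: int = 0,
    length_binning: LengthBinning | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-gene body/promoter spreading ratios in both conditions and their
    log2 difference, optionally aggregated to per-length-bin medians.

    Genes with zero promoter density in either condition are dropped (count
    logged and attached as attrs).
    """
    rows = []
    n_dropped = 0
    for gene in genes:
        if gene.length <= promoter_exclusion_bp:
            n_dropped += 1
            continue
        pa = window_density(track_a, gene, promoter_window).norm_density
        pb = window_density(track_b, gene, promoter_window).norm_density
        if pa <= 0 or pb <= 0:
            n_dropped += 1
            continue
        ba = gene_body_density(track_a, gene, promoter_exclusion_bp).norm_density
        bb = gene_body_density(track_b, gene, promoter_exclusion_bp).norm_density
        ratio_a, ratio_b = ba / pa, bb / pb
        delta = (
            float(np.log2(ratio_b) - np.log2(ratio_a))
            if ratio_a > 0 and ratio_b > 0
            else np.nan
        )
        rows.append((gene.gene_id, pa, pb, ba, bb, ratio_a, ratio_b, delta))
    if n_dropped:
        log.info("spreading_summary: dropped %d genes (short or zero promoter)", n_dropped)
    records = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "promoter_density_a", "promoter_density_b",
            "body_density_a", "body_density_b",
            "spreading_ratio_a", "spreading_ratio_b", "delta_spreading",
        ],
    )
    records.attrs["n_dropped"] = n_dropped

    by_bin = None
    if length_binning is not None and not records.empty:
        merged = records.set_index("gene_id").join(length_binning.assignment, how="inner")
        agg = merged.groupby("length_bin")["delta_spreading"].agg(["median", "count"])
        agg = agg.reindex(range(length_binning.n_bins))
        by_bin = pd.DataFrame(
            {
                "length_bin": length_binning.labels,
                "median_delta_spreading": agg["median"].to_numpy(),
                "n": agg["count"].fillna(0).astype(int).to_numpy(),
            }
        )
    return records, by_bin
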