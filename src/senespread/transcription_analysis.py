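"""Per-gene fold changes, regulated-set classification, length stratification,
and Pol II pausing indices.

Fold changes are log2 ratios of library-normalized counts with a pseudocount;
the combined value is the arithmetic mean of the RNA and nascent-transcription
components when both are present.  Classification thresholds and pausing
windows are configuration, defaulting to +/-1 log2 and (-50, +300) promoter /
body from +300.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage_quant import gene_body_density, window_density
from .genome_io import CoverageTrack, GeneModel, GenomicWindow

__all__ = [
    "S_GAINED",
    "S_LOST",
    "UNCHANGED",
    "NOT_EXPRESSED",
    "PausingRecord",
    "LengthBinning",
    "log2_fold_change",
    "combine_fold_changes",
    "expressed_genes",
    "classify_regulation",
    "length_stratify",
    "pausing_index",
    "pi_curve",
    "delta_pi",
    "DEFAULT_PROMOTER_WINDOW",
]

log = logging.getLogger(__name__)

S_GAINED = "S_GAINED"
S_LOST = "S_LOST"
UNCHANGED = "UNCHANGED"
NOT_EXPRESSED = "NOT_EXPRESSED"

DEFAULT_PROMOTER_WINDOW = GenomicWindow("tss", -50, 300)


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------


def log2_fold_change(
    counts_a: Mapping[str, float] | pd.Series,
    counts_b: Mapping[str, float] | pd.Series,
    libsize_a: float,
    libsize_b: float,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2[(count_b + pc)/libsize_b / ((count_a + pc)/libsize_a)] per gene."""
    if libsize_a <= 0 or libsize_b <= 0:
        raise ValueError("library sizes must be > 0")
    a = pd.Series(counts_a, dtype=float)
    b = pd.Series(counts_b, dtype=float)
    if not a.index.equals(b.index):
        common = a.index.intersection(b.index)
        a, b = a[common], b[common]
    return np.log2((b + pseudocount) / libsize_b) - np.log2((a + pseudocount) / libsize_a)


def combine_fold_changes(
    log2fc_rna: pd.Series, log2fc_gro: pd.Series | None = None, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Assemble the per-gene fold-change table with the combined value.

    combined = mean(rna, gro) where both exist, the available one otherwise.
    """
    df = pd.DataFrame({"log2fc_rna": log2fc_rna})
    df["log2fc_gro"] = log2fc_gro if log2fc_gro is not None else np.nan
    df["combined"] = df[["log2fc_rna", "log2fc_gro"]].mean(axis=1, skipna=True)
    df["pseudocount"] = pseudocount
    df.index.name = "gene_id"
    return df


def expressed_genes(
    counts: pd.DataFrame,
    libsizes: Mapping[str, float],
    feature_lengths: Mapping[str, float],
    min_density: float = 0.5,
) -> set[str]:
    """Genes whose mean normalized density (tags/kb/10M) across the count
    columns is at least ``min_density``.

    ``counts`` is indexed by gene_id with one column per condition.
    """
    dens = pd.DataFrame(index=counts.index, dtype=float)
    lengths = pd.Series(feature_lengths, dtype=float).reindex(counts.index)
    for col in counts.columns:
        dens[col] = counts[col] / (lengths / 1000.0) / (libsizes[col] / 1e7)
    return set(dens.index[dens.mean(axis=1) >= min_density])


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_regulation(
    fc: pd.DataFrame,
    expressed: set[str],
    up_thresh: float = 1.0,
    down_thresh: float = -1.0,
    require_concordance: bool = True,
) -> pd.DataFrame:
    """Partition genes into S_GAINED / S_LOST / UNCHANGED / NOT_EXPRESSED.

    A gene is S_GAINED when combined >= up_thresh and, when concordance is
    required and a nascent-transcription value exists, the RNA and nascent
    signs agree; S_LOST symmetric.  Labels are mutually exclusive and
    exhaustive over the input genes.
    """
    if not (down_thresh < 0 < up_thresh):
        raise ValueError("thresholds must satisfy down < 0 < up")
    labels = []
    for gid, row in fc.iterrows():
        if gid not in expressed:
            labels.append(NOT_EXPRESSED)
            continue
        concordant = True
        if require_concordance and np.isfinite(row["log2fc_gro"]):
            concordant = np.sign(row["log2fc_rna"]) == np.sign(row["log2fc_gro"])
        if row["combined"] >= up_thresh and concordant:
            labels.append(S_GAINED)
        elif row["combined"] <= down_thresh and concordant:
            labels.append(S_LOST)
        else:
            labels.append(UNCHANGED)
    out = pd.DataFrame(
        {
            "gene_id": fc.index,
            "label": labels,
            "combined": fc["combined"].to_numpy(),
            "up_thresh": up_thresh,
            "down_thresh": down_thresh,
        }
    )
    return out


# ---------------------------------------------------------------------------
# Length stratification
# ---------------------------------------------------------------------------

DEFAULT_LENGTH_EDGES = (10_000, 30_000, 100_000)


@dataclass(frozen=True)
class LengthBinning:
    edges: tuple[int, ...]
    assignment: pd.Series  # gene_id -> bin index

    @property
    def labels(self) -> list[str]:
        bounds = [0, *self.edges]
        out = [f"[{bounds[i]},{bounds[i+1]})" for i in range(len(self.edges))]
        out.append(f"[{bounds[-1]},inf)")
        return out

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1


def length_stratify(
    genes: Sequence[GeneModel], edges: Iterable[int] = DEFAULT_LENGTH_EDGES
) -> LengthBinning:
    """Assign each gene to a half-open length bin [0,e1), [e1,e2), ..., [ek,inf)."""
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    edge_arr = np.array(edges, dtype=float)
    lengths = np.array([g.length for g in genes], dtype=float)
    idx = np.searchsorted(edge_arr, lengths, side="right")
    return LengthBinning(
        edges=edges,
        assignment=pd.Series(idx, index=[g.gene_id for g in genes], name="length_bin"),
    )


# ---------------------------------------------------------------------------
# Pausing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PausingRecord:
    gene_id: str
    promoter_density: float
    body_density: float
    pi: float  # promoter / body density; nan when invalid
    valid: bool
    reason: str = ""


def pausing_index(
    gro_track: CoverageTrack,
    gene: GeneModel,
    promoter_window: GenomicWindow = DEFAULT_PROMOTER_WINDOW,
    body_from: int = 300,
) -> PausingRecord:
    """Promoter-proximal over gene-body density ratio for one gene.

    Invalid (with a reason) for genes shorter than ``body_from + 100`` or with
    zero body density; the ratio itself is scale-invariant.
    """
    if gene.length <= body_from + 100:
        return PausingRecord(gene.gene_id, np.nan, np.nan, np.nan, False, "too_short")
    prom = window_density(gro_track, gene, promoter_window).norm_density
    body = gene_body_density(gro_track, gene, promoter_exclusion_bp=body_from).norm_density
    if body == 0:
        return PausingRecord(gene.gene_id, prom, 0.0, np.nan, False, "zero_body")
    return PausingRecord(gene.gene_id, prom, body, prom / body, True)


def pi_curve(records: Sequence[PausingRecord]) -> pd.DataFrame:
    """Empirical cumulative distribution of pausing indices over valid records.

    One point per valid record (duplicates preserved); columns ``pi`` and
    ``cum_fraction``; the invalid count is attached as frame attrs.
    """
    valid = [r.pi for r in records if r.valid]
    if not valid:
        raise ValueError("no valid pausing records")
    pis = np.sort(np.asarray(valid))
    df = pd.DataFrame(
        {"pi": pis, "cum_fraction": np.arange(1, len(pis) + 1) / len(pis)}
    )
    df.attrs["n_invalid"] = len(records) - len(valid)
    return df


def delta_pi(
    records_a: Sequence[PausingRecord], records_b: Sequence[PausingRecord]
) -> pd.Series:
    """Per-gene log2 PI_b - log2 PI_a over genes valid in both conditions."""
    a = {r.gene_id: r.pi for r in records_a if r.valid}
    b = {r.gene_id: r.pi for r in records_b if r.valid}
    common = sorted(set(a) & set(b))
    n_excluded = len(set(a) | set(b)) - len(common)
    if not common:
        raise ValueError("no genes valid in both conditions")
    if n_excluded:
        log.info("delta_pi: excluded %d genes invalid in one condition", n_excluded)
    out = pd.Series(
        [np.log2(b[g]) - np.log2(a[g]) for g in common], index=common, name="delta_log2_pi"
    )
    out.attrs["n_excluded"] = n_excluded
    return out
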