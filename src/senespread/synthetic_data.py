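"""Synthetic gene models, coverage tracks and count tables with planted effects.

The generator plants the structure the downstream pipeline is meant to
recover: a log-normal gene-length distribution, an upregulated gene set
optionally biased toward long genes, a downregulated set, promoter-peaked vs.
body-spread mark coverage, promoter mark loss coupled to induction, and
Poisson or negative-binomial count noise.  A ground-truth table makes every
planted per-gene effect available as an oracle.

Determinism: one master seed; each output stream draws from a child generator
derived by stable hashing of ``(seed, stream label)``, so adding a track never
perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .genome_io import CoverageTrack, GeneModel, write_coverage, write_gene_models, write_table

__all__ = [
    "MarkShape",
    "NoiseModel",
    "SyntheticConfig",
    "GroundTruth",
    "generate_genes",
    "generate_expression_counts",
    "generate_mark_track",
    "write_dataset",
    "GAINED",
    "LOST",
    "UNCHANGED",
]

GAINED = "GAINED"
LOST = "LOST"
UNCHANGED = "UNCHANGED"

CHROM = "chrSyn"
TRACK_BIN_BP = 25  # resolution of emitted bedGraph tracks
GENE_FLANK_BP = 4000  # mark signal simulated this far past gene ends
MIN_GAP_BP = 10_000


@dataclass
class MarkShape:
    """Expected per-gene signal shape for one (mark, condition).

    Promoter component: Gaussian of the given amplitude and standard
    deviation (bp) centered on the TSS.  Body component: uniform
    ``body_level`` over the gene body, scaled by
    ``1 + spread_coefficient * log10(gene_length)`` when the coefficient is
    non-zero.
    """

    promoter_amplitude: float = 5.0
    promoter_width_bp: float = 250.0
    body_level: float = 1.0
    spread_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.promoter_amplitude < 0 or self.body_level < 0:
            raise ValueError("mark shape amplitudes must be >= 0")


@dataclass
class NoiseModel:
    kind: str = "poisson"  # "poisson" | "negative_binomial"
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.kind!r}")
        if self.kind == "negative_binomial" and self.dispersion <= 0:
            raise ValueError("negative_binomial requires dispersion > 0")

    def sample(self, rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        if self.kind == "poisson":
            return rng.poisson(mean)
        # gamma-Poisson mixture: var = mean + dispersion * mean^2
        shape = 1.0 / self.dispersion
        lam = rng.gamma(shape, mean * self.dispersion)
        return rng.poisson(lam)


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    length_lognormal: tuple[float, float] = (9.6, 1.1)  # (mu, sigma) of log bp
    frac_gained: float = 0.15
    frac_lost: float = 0.15
    gained_length_bias: float = 1.0
    lost_length_bias: float = 1.0
    expr_effect: float = 2.0  # |log2FC| planted in GAINED (+) / LOST (-)
    level_sigma: float = 0.5  # spread of per-gene baseline expression levels
    mark_shapes: dict = field(default_factory=dict)  # {(mark, condition): MarkShape}
    mark_loss_coupling: float = 0.0  # log2 promoter-mark change on GAINED, cond 2
    noise: NoiseModel = field(default_factory=NoiseModel)
    depth: float = 1e6  # expected tags per track / count column
    seed: int = 0
    conditions: tuple[str, str] = ("epq", "sen")

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if not (0 <= self.frac_gained <= 1 and 0 <= self.frac_lost <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_gained + self.frac_lost > 1:
            raise ValueError("frac_gained + frac_lost must be <= 1")
        if isinstance(self.noise, dict):
            self.noise = NoiseModel(**self.noise)
        shapes = {}
        for key, shape in self.mark_shapes.items():
            if isinstance(key, str):  # "mark/condition" from YAML
                key = tuple(key.split("/", 1))
            shapes[key] = shape if isinstance(shape, MarkShape) else MarkShape(**shape)
        self.mark_shapes = shapes

    def shape_for(self, mark: str, condition: str) -> MarkShape:
        try:
            return self.mark_shapes[(mark, condition)]
        except KeyError:
            raise KeyError(
                f"no mark shape configured for ({mark!r}, {condition!r})"
            ) from None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mark_shapes"] = {
            f"{m}/{c}": asdict(s) if isinstance(s, MarkShape) else s
            for (m, c), s in self.mark_shapes.items()
        }
        d["length_lognormal"] = list(self.length_lognormal)
        d["conditions"] = list(self.conditions)
        return d


GroundTruth = pd.DataFrame  # columns: gene_id, label, true_expr_log2fc,
#                                      true_promoter_mark_log2fc, true_body_mark_log2fc


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Stable per-stream generator: hash of (seed, label), independent of the
    order in which streams are drawn."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------


def generate_genes(config: SyntheticConfig) -> tuple[list[GeneModel], GroundTruth]:
    """Draw gene models on a single synthetic chromosome plus ground truth.

    Lengths are log-normal; planted GAINED (LOST) genes have their lengths
    multiplied by the respective bias; genes are placed non-overlapping with
    >= 10 kb gaps.  Deterministic for a fixed config seed.
    """
    rng = child_rng(config.seed, "genes")
    n = config.n_genes
    mu, sigma = config.length_lognormal
    lengths = np.exp(rng.normal(mu, sigma, size=n))

    n_gain = int(round(config.frac_gained * n))
    n_lost = int(round(config.frac_lost * n))
    labels = np.array([UNCHANGED] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_gain]] = GAINED
    labels[order[n_gain : n_gain + n_lost]] = LOST
    lengths[labels == GAINED] *= config.gained_length_bias
    lengths[labels == LOST] *= config.lost_length_bias
    lengths = np.maximum(lengths.astype(np.int64), 400)

    gaps = MIN_GAP_BP + rng.integers(0, 5000, size=n)
    strands = rng.choice(["+", "-"], size=n)
    genes: list[GeneModel] = []
    pos = GENE_FLANK_BP + int(gaps[0])
    width = len(str(n))
    for i in range(n):
        start = pos
        end = start + int(lengths[i])
        exons = _make_exons(rng, start, end)
        genes.append(
            GeneModel(
                gene_id=f"g{i:0{width}d}",
                chrom=CHROM,
                strand=str(strands[i]),
                start=start,
                end=end,
                exons=exons,
            )
        )
        pos = end + int(gaps[i])

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "label": labels,
            "true_expr_log2fc": np.where(
                labels == GAINED, config.expr_effect,
                np.where(labels == LOST, -config.expr_effect, 0.0),
            ),
            "true_promoter_mark_log2fc": np.where(
                labels == GAINED, config.mark_loss_coupling, 0.0
            ),
            "true_body_mark_log2fc": 0.0,
        }
    )
    return genes, truth


def _make_exons(
    rng: np.random.Generator, start: int, end: int
) -> tuple[tuple[int, int], ...]:
    length = end - start
    k = 1 + int(rng.integers(0, min(6, max(1, length // 600))))
    if k == 1:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(start + 1, end - 1), size=2 * (k - 1), replace=False))
    bounds = [start, *cuts.tolist(), end]
    return tuple((bounds[2 * i], bounds[2 * i + 1]) for i in range(k))


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------


def generate_expression_counts(
    genes: list[GeneModel], truth: GroundTruth, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RNA-like (exonic) and GRO-like (gene-body) count tables per condition.

    Baseline expected counts are proportional to (exonic or body) length times
    a per-gene log-normal level; condition-2 means are scaled by
    ``2 ** true_expr_log2fc``.  RNA and GRO planted effects are concordant in
    sign by construction.  Each condition column is scaled so its expected
    total equals ``config.depth`` in condition 1 units.
    """
    rng = child_rng(config.seed, "expression")
    n = len(genes)
    levels = np.exp(rng.normal(0.0, config.level_sigma, size=n))
    effect = 2.0 ** truth["true_expr_log2fc"].to_numpy()
    cond_a, cond_b = config.conditions

    tables = {}
    for assay, size_fn in (
        ("rna", lambda g: g.exonic_length),
        ("gro", lambda g: g.length),
    ):
        base = np.array([size_fn(g) for g in genes], dtype=float) * levels
        scale = config.depth / base.sum()
        mean_a = base * scale
        mean_b = base * effect * scale
        counts_a = config.noise.sample(child_rng(config.seed, f"{assay}_{cond_a}"), mean_a)
        counts_b = config.noise.sample(child_rng(config.seed, f"{assay}_{cond_b}"), mean_b)
        tables[assay] = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                cond_a: counts_a,
                cond_b: counts_b,
            }
        )
    return tables["rna"], tables["gro"]


# ---------------------------------------------------------------------------
# Mark tracks
# ---------------------------------------------------------------------------


def generate_mark_track(
    genes: list[GeneModel],
    truth: GroundTruth,
    config: SyntheticConfig,
    mark: str,
    condition: str,
) -> CoverageTrack:
    """Sample one coverage track for (mark, condition) at the configured depth.

    Expected per-gene signal: a Gaussian promoter peak at the TSS plus a
    uniform body level scaled by ``1 + spread_coefficient * log10(length)``.
    In condition 2, promoter amplitudes of GAINED genes are multiplied by
    ``2 ** mark_loss_coupling``.  Tags are sampled per the noise model on a
    fixed 25 bp grid; bedGraph values are per-base densities (count / bin bp).
    """
    shape = config.shape_for(mark, condition)
    is_cond2 = condition == config.conditions[1]
    labels = truth.set_index("gene_id")["label"]

    bin_edges_all: list[np.ndarray] = []
    expected_all: list[np.ndarray] = []
    for gene in genes:
        lo = gene.start - GENE_FLANK_BP
        hi = gene.end + GENE_FLANK_BP
        edges = np.arange(lo, hi + TRACK_BIN_BP, TRACK_BIN_BP, dtype=np.int64)
        centers = (edges[:-1] + edges[1:]) / 2.0

        amp = shape.promoter_amplitude
        if is_cond2 and labels[gene.gene_id] == GAINED:
            amp *= 2.0 ** config.mark_loss_coupling
        w = shape.promoter_width_bp
        prom = amp * np.exp(-0.5 * ((centers - gene.tss) / w) ** 2) if amp > 0 else 0.0

        body = shape.body_level
        if shape.spread_coefficient:
            body *= 1.0 + shape.spread_coefficient * np.log10(gene.length)
        in_body = (centers >= gene.start) & (centers < gene.end)

        expected = (prom + body * in_body) * TRACK_BIN_BP
        bin_edges_all.append(edges)
        expected_all.append(np.asarray(expected, dtype=float))

    total = sum(e.sum() for e in expected_all)
    scale = config.depth / total if total > 0 else 0.0
    rng = child_rng(config.seed, f"mark_{mark}_{condition}")
    records = []
    for edges, expected in zip(bin_edges_all, expected_all):
        counts = config.noise.sample(rng, expected * scale)
        nz = np.flatnonzero(counts)
        for i in nz:
            records.append(
                (CHROM, int(edges[i]), int(edges[i + 1]), counts[i] / TRACK_BIN_BP)
            )
    return CoverageTrack.from_intervals(records, label=f"{mark}_{condition}")


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------


def write_dataset(
    config: SyntheticConfig, out_dir: str | Path, marks: Iterable[str] = ()
) -> dict[str, Path]:
    """Generate and write the full synthetic dataset; returns output paths.

    Emits genes.bed, rna_counts.tsv, gro_counts.tsv, ground_truth.tsv, a YAML
    config echo, and one bedGraph per (mark, condition) found in the config
    (restricted to ``marks`` if given).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes, truth = generate_genes(config)
    rna, gro = generate_expression_counts(genes, truth, config)

    paths: dict[str, Path] = {}
    paths["genes"] = out_dir / "genes.bed"
    write_gene_models(genes, paths["genes"])
    paths["rna_counts"] = out_dir / "rna_counts.tsv"
    write_table(rna, paths["rna_counts"])
    paths["gro_counts"] = out_dir / "gro_counts.tsv"
    write_table(gro, paths["gro_counts"])
    paths["ground_truth"] = out_dir / "ground_truth.tsv"
    write_table(truth, paths["ground_truth"])

    wanted = set(marks)
    for mark, condition in sorted(config.mark_shapes):
        if wanted and mark not in wanted:
            continue
        track = generate_mark_track(genes, truth, config, mark, condition)
        key = f"{mark}_{condition}"
        paths[key] = out_dir / f"{key}.bedGraph"
        write_coverage(track, paths[key])

    paths["config"] = out_dir / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return paths
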