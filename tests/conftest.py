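import numpy as np
import pytest

from senespread.genome_io import CoverageTrack, GeneModel
from senespread.synthetic_data import (
    MarkShape,
    SyntheticConfig,
    generate_expression_counts,
    generate_genes,
    generate_mark_track,
)


@pytest.fixture
def plus_gene():
    return GeneModel("gplus", "chr1", "+", 10_000, 18_000)


@pytest.fixture
def minus_gene():
    return GeneModel("gminus", "chr1", "-", 2_000, 10_000)


@pytest.fixture
def uniform_track():
    """Constant per-base value 2.0 over chr1[0, 50k)."""
    return CoverageTrack.from_intervals([("chr1", 0, 50_000, 2.0)])


def random_track(rng, chrom="chr1", n=30, span=2_000, max_val=5.0):
    """Small random track with overlapping intervals for oracle tests."""
    records = []
    for _ in range(n):
        s = int(rng.integers(0, span - 10))
        e = int(rng.integers(s + 1, min(s + 200, span)))
        records.append((chrom, s, e, float(rng.uniform(0, max_val))))
    return records, CoverageTrack.from_intervals(records)


def per_base_expansion(records, chrom, span):
    """Brute-force per-base signal array: the oracle for all density math."""
    arr = np.zeros(span)
    for c, s, e, v in records:
        if c == chrom:
            arr[s:e] += v
    return arr


# ---------------------------------------------------------------------------
# Shared synthetic datasets (session-scoped: generation is the expensive part)
# ---------------------------------------------------------------------------

SPREAD_SEED = 11


@pytest.fixture(scope="session")
def spread_config():
    """Condition 1 promoter-peaked, condition 2 body-spread."""
    return SyntheticConfig(
        n_genes=2000,
        seed=SPREAD_SEED,
        length_lognormal=(9.9, 1.15),
        frac_gained=0.15,
        frac_lost=0.15,
        depth=2e6,
        # promoter-dominated library: the planted body gain survives the
        # fixed-depth rescaling instead of being normalized away
        mark_shapes={
            ("h3k79me3", "epq"): MarkShape(
                promoter_amplitude=16.0, promoter_width_bp=125.0, body_level=0.05
            ),
            ("h3k79me3", "sen"): MarkShape(
                promoter_amplitude=16.0,
                promoter_width_bp=125.0,
                body_level=0.05,
                spread_coefficient=1.2,
            ),
        },
    )


@pytest.fixture(scope="session")
def spread_dataset(spread_config):
    genes, truth = generate_genes(spread_config)
    track_a = generate_mark_track(genes, truth, spread_config, "h3k79me3", "epq")
    track_b = generate_mark_track(genes, truth, spread_config, "h3k79me3", "sen")
    return spread_config, genes, truth, track_a, track_b


@pytest.fixture(scope="session")
def coupling_config():
    """Promoter mark loss planted on GAINED genes, coupled to induction."""
    return SyntheticConfig(
        n_genes=2000,
        seed=7,
        expr_effect=2.0,
        depth=1e6,
        mark_loss_coupling=-5.0,
        mark_shapes={
            ("h4r3me2s", "epq"): MarkShape(
                promoter_amplitude=10.0, promoter_width_bp=150.0, body_level=0.1
            ),
            ("h4r3me2s", "sen"): MarkShape(
                promoter_amplitude=10.0, promoter_width_bp=150.0, body_level=0.1
            ),
        },
    )


@pytest.fixture(scope="session")
def coupling_dataset(coupling_config):
    cfg = coupling_config
    genes, truth = generate_genes(cfg)
    rna, gro = generate_expression_counts(genes, truth, cfg)
    track_a = generate_mark_track(genes, truth, cfg, "h4r3me2s", "epq")
    track_b = generate_mark_track(genes, truth, cfg, "h4r3me2s", "sen")
    return cfg, genes, truth, rna, gro, track_a, track_b


@pytest.fixture(scope="session")
def classification_dataset():
    cfg = SyntheticConfig(n_genes=2000, seed=3, expr_effect=2.0, depth=1e6)
    genes, truth = generate_genes(cfg)
    rna, gro = generate_expression_counts(genes, truth, cfg)
    return cfg, genes, truth, rna, gro
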