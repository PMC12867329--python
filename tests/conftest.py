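import numpy as np
import pytest

from chromstates.core import (
    GeneModel,
    GeneModelSet,
    GenomicInterval,
    StateSegmentation,
)
from chromstates.synth import (
    CoexprSpec,
    ExpressionSpec,
    SyntheticConfig,
    TEBlockSpec,
    generate_study,
)


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A compact synthetic study for fast tests (120 kb, 60 genes, 10 TFs)."""
    from chromstates.synth import default_tf_specs

    defaults = dict(
        chrom_length=120_000,
        gene_count=60,
        te_blocks=TEBlockSpec(count=6, length_bins=10),
        tf_specs=default_tf_specs(n_tfs=10),
        expression=ExpressionSpec(noise_sd=0.0),
        coexpr=CoexprSpec(functional_rank_ceiling=12, negative_tail=6),
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


def make_segmentation(spec, chrom_sizes, bin_size=200, states=None):
    """Build a segmentation from [(chrom, start, end, label), ...]."""
    return StateSegmentation.from_intervals(
        [(GenomicInterval(c, s, e), lab) for c, s, e, lab in spec],
        chrom_sizes,
        bin_size=bin_size,
        states=states,
    )


def random_segmentation(rng, chrom_sizes, n_states=4, bin_size=200,
                        gap_prob=0.0):
    """Random per-bin states, optionally with unassigned gaps."""
    labels = [f"S{i + 1}" for i in range(n_states)]
    spec = []
    for chrom, size in chrom_sizes.items():
        n = -(-size // bin_size)
        for b in range(n):
            if gap_prob and rng.random() < gap_prob:
                continue
            s, e = b * bin_size, min((b + 1) * bin_size, size)
            spec.append((chrom, s, e, labels[rng.integers(n_states)]))
    return make_segmentation(spec, chrom_sizes, bin_size, states=labels)


def random_genes(rng, chrom_sizes, n=10, min_len=300, max_len=2000):
    genes = []
    classes = ["protein_coding", "TE", "other"]
    for i in range(n):
        chrom = list(chrom_sizes)[rng.integers(len(chrom_sizes))]
        size = chrom_sizes[chrom]
        length = int(rng.integers(min_len, max_len))
        start = int(rng.integers(0, max(1, size - length)))
        genes.append(
            GeneModel(
                gene_id=f"g{i:03d}",
                interval=GenomicInterval(
                    chrom, start, start + length,
                    "+" if rng.random() < 0.5 else "-",
                ),
                feature_class=classes[rng.integers(3)],
            )
        )
    return GeneModelSet(genes)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
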