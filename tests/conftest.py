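from dataclasses import replace

import pytest

import damidkit as dk

# Small-but-nontrivial design used by most module tests; the full default
# design is exercised only in the acceptance suite.
SMALL_CONFIG = dk.SimulationConfig(
    seed=11,
    n_chromosomes=2,
    chromosome_length=60_000,
    n_genes=40,
    n_derepressed=6,
    library_size=300_000,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_dataset():
    """(genome, fmap, annotation, truth, counts) for the small design."""
    return dk.simulate_experiment(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_assignment(small_dataset):
    _, fmap, annotation, _, _ = small_dataset
    return dk.map_fragments_to_transcripts(fmap, annotation)


@pytest.fixture(scope="session")
def polII_tracks(small_dataset):
    """Dict (genotype, replicate) -> unscaled Dam-PolII ratio track."""
    _, fmap, _, _, counts = small_dataset
    return {
        (gt, r): dk.compute_ratio_track(
            counts[(gt, "Dam-PolII", r)],
            counts[(gt, "Dam", r)],
            fmap,
            sample_kind="Dam-PolII",
            genotype=gt,
            replicate=r,
        )
        for gt in ("control", "knockdown")
        for r in range(SMALL_CONFIG.replicates)
    }


@pytest.fixture(scope="session")
def pc_tracks(small_dataset):
    _, fmap, _, _, counts = small_dataset
    return {
        (gt, r): dk.compute_ratio_track(
            counts[(gt, "Dam-Pc", r)],
            counts[(gt, "Dam", r)],
            fmap,
            sample_kind="Dam-Pc",
            genotype=gt,
            replicate=r,
        )
        for gt in ("control", "knockdown")
        for r in range(SMALL_CONFIG.replicates)
    }


def null_config(seed: int) -> dk.SimulationConfig:
    """A design with no occupancy signal anywhere."""
    return replace(
        SMALL_CONFIG,
        seed=seed,
        n_derepressed=0,
        expressed_fraction=0.0,
    )
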