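import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from liposcan.profile_hmm import MsaFamily, build_hmm, calibrate
from liposcan.synthetic_data import (
    ROUTE_CONFIRM_PROFILE,
    ROUTE_FAMILY,
    GeneratorConfig,
    gen_families,
    gen_protein_set,
    gen_reference_registry,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_msa(rng: np.random.Generator, name: str = "fam") -> MsaFamily:
    """A tiny random ungapped alignment for oracle checks (L <= 3)."""
    width = int(rng.integers(1, 4))
    n_rows = int(rng.integers(2, 5))
    rows = ["".join(rng.choice(list(AA), size=width)) for _ in range(n_rows)]
    return MsaFamily(name, rows)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Down-scaled generator settings for fast unit tests."""
    return GeneratorConfig(
        seed=7,
        n_families=3,
        family_length=(210, 260),
        n_members=6,
        n_positives_per_family=4,
        n_random_decoys=6,
        n_twilight_decoys=4,
        include_route_family=True,
        route_length=(360, 400),
        n_habitats=3,
        n_samples_per_habitat=4,
        n_core_categories=10,
        hits_per_sample=500,
    )


@pytest.fixture(scope="session")
def small_families(small_config):
    return gen_families(small_config)


@pytest.fixture(scope="session")
def small_benchmark(small_config, small_families):
    """Proteins + truth + references + registry + calibrated databases."""
    proteins, truth = gen_protein_set(small_config, small_families)
    refs, registry = gen_reference_registry(small_config, small_families)
    elf = [f for f in small_families if f.family_name != ROUTE_FAMILY]
    route = [f for f in small_families if f.family_name == ROUTE_FAMILY]
    db = [build_hmm(f.msa) for f in elf]
    route_db = [build_hmm(f.msa) for f in route]
    confirm_db = [build_hmm(MsaFamily(ROUTE_CONFIRM_PROFILE, route[0].msa.rows[:4]))]
    for h in db + route_db + confirm_db:
        calibrate(h, n_decoys=60, decoy_length=150, seed=11)
    return {
        "config": small_config,
        "families": small_families,
        "proteins": proteins,
        "truth": truth,
        "refs": refs,
        "registry": registry,
        "db": db,
        "route_db": route_db,
        "confirm_db": confirm_db,
    }
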