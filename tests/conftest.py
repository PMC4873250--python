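import numpy as np
import pytest
from hypothesis import settings

# property tests are derandomised so runs are reproducible everywhere
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hspclass import (
    BenchmarkSpec,
    KernelConfig,
    ProteinRecord,
    TieredPredictor,
    build_tier1,
    build_tier2,
    make_benchmark,
)

#: compact class shape used by unit tests (fast); keeps every family >= 12
SMALL_COUNTS = {
    "HSP20": 20,
    "HSP40": 30,
    "HSP60": 15,
    "HSP70": 15,
    "HSP90": 12,
    "HSP100": 12,
    "non-HSP": 80,
}


def random_record(rng: np.random.Generator, length: int, rec_id: str) -> ProteinRecord:
    from hspclass import AMINO_ACIDS

    letters = rng.choice(list(AMINO_ACIDS), size=length)
    return ProteinRecord(id=rec_id, residues="".join(letters))


@pytest.fixture(scope="session")
def small_benchmark():
    return make_benchmark(
        BenchmarkSpec(class_counts=SMALL_COUNTS, separation="strong", master_seed=11)
    )


@pytest.fixture(scope="session")
def small_holdout():
    return make_benchmark(
        BenchmarkSpec(class_counts=SMALL_COUNTS, separation="strong", master_seed=12)
    )


@pytest.fixture(scope="session")
def toy_predictor(small_benchmark) -> TieredPredictor:
    config = KernelConfig.linear()
    tier1 = build_tier1(
        small_benchmark.hsp_records,
        small_benchmark.non_hsp_records,
        "coupled",
        config,
        seed=11,
    )
    tier2 = build_tier2(small_benchmark.by_family(), "coupled", config, seed=11)
    return TieredPredictor(tier1=tier1, tier2=tier2, encoding="coupled")
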