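import random

import pytest
from hypothesis import HealthCheck, settings

from orthoess.io import Proteome, ProteinRecord
from orthoess.orthology import AlignmentParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def random_proteome(
    genome_id: str,
    n_genes: int,
    length: int = 40,
    seed: int = 0,
    prefix: str = "g",
) -> Proteome:
    rng = random.Random(seed)
    records = [
        ProteinRecord(
            f"{prefix}{i:03d}", "", "".join(rng.choices(STANDARD_AA, k=length))
        )
        for i in range(n_genes)
    ]
    return Proteome(genome_id, tuple(records))


def mutate(sequence: str, rate: float, seed: int) -> str:
    rng = random.Random(seed)
    return "".join(
        rng.choice(STANDARD_AA) if rng.random() < rate else c for c in sequence
    )


@pytest.fixture(scope="session")
def loose_params() -> AlignmentParams:
    """Alignment params with no score floor, for tiny fixtures."""
    return AlignmentParams(min_score=0.0)
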