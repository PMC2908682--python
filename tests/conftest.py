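from __future__ import annotations

import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from mimdesign.design import DesignParams
from mimdesign.duplex import ScoringParams, classify_pair
from mimdesign.fixtures import FixtureSpec, generate_mirna_set
from mimdesign.seqio import Alphabet, MatureMiRNA, NucleotideSequence

sys.path.insert(0, str(Path(__file__).parent))  # for `helpers`

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sparams() -> ScoringParams:
    return ScoringParams()


@pytest.fixture(scope="session")
def dparams() -> DesignParams:
    return DesignParams()


@pytest.fixture(scope="session")
def mirna21() -> MatureMiRNA:
    """A fixed synthetic 21-nt mature miRNA used across the suite."""
    return MatureMiRNA.from_id(
        "xxx-miR500a", NucleotideSequence("UGAGCUCAUCAAGCAUUCGGC", Alphabet.RNA)
    )


@pytest.fixture(scope="session")
def catalogue5() -> list[MatureMiRNA]:
    """Five synthetic singleton families, 21 nt each."""
    return generate_mirna_set(FixtureSpec(seed=1, n_families=5, members_per_family=1))


def perfect_site(mirna: MatureMiRNA) -> NucleotideSequence:
    """Exact reverse complement of the miRNA as a DNA site."""
    return mirna.sequence.reverse_complement(Alphabet.DNA)


def mismatch11_site(mirna: MatureMiRNA) -> NucleotideSequence:
    """Reverse complement with a single mismatch opposite miRNA position 11."""
    site = list(str(perfect_site(mirna)))
    idx = len(mirna) - 11  # 0-based partner of position 11
    for base in "ACGT":
        if classify_pair(mirna.sequence[10], base).name == "MISMATCH":
            site[idx] = base
            break
    return NucleotideSequence("".join(site), Alphabet.DNA)
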