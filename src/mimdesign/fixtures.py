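"""Deterministic synthetic miRNA catalogues and backbones.

Every other module is exercised on generated data with controlled family
structure, so no external catalogue download is ever needed.  A catalogue is
built from uniform-random family ancestors; members are derived by a small
number of substitutions.  Two deliberate asymmetries mirror real families:

* Within-family substitutions use only A->G and C->U at positions where the
  ancestor carries A or C.  The consensus covering base at such a position
  keeps every non-substituted member Watson-Crick and gives the substituted
  member a single G:U wobble, so family members remain jointly capturable by
  one consensus mimic -- the behaviour that makes one-mimic-per-family work.
* Subfamily blocks are separated by substitutions drawn from the
  non-coverable map A<->C, G<->U at disjoint position sets outside the
  central window, so no single site base can serve both blocks and the
  partitioner must split them.

All randomness flows from one integer seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .seqio import Alphabet, Backbone, MatureMiRNA, NucleotideSequence

__all__ = ["FixtureSpec", "generate_mirna_set", "generate_backbone"]

_RNA = "ACGU"
_DNA = "ACGT"
# substitutions whose consensus cover keeps the ancestor Watson-Crick
_WOBBLE_SAFE = {"A": "G", "C": "U"}
# substitutions that no single site base can cover together with the original
_NON_COVERABLE = {"A": "C", "C": "A", "G": "U", "U": "G"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic catalogue; fully determined by ``seed``."""

    seed: int = 0
    n_families: int = 5
    members_per_family: int = 3
    mirna_length: int = 21
    within_family_subs: int = 1
    subfamily_blocks: Mapping[int, int] | None = None  # family index -> n blocks
    between_block_subs: int = 5
    backbone_length: int = 300
    species: str = "xxx"
    first_family_number: int = 101
    central_window: tuple[int, int] = (9, 12)

    def __post_init__(self) -> None:
        if min(self.n_families, self.members_per_family, self.mirna_length) < 1:
            raise ValueError("counts must be >= 1")
        if self.members_per_family > 26:
            raise ValueError("at most 26 members per family (letter variants)")
        if self.within_family_subs >= self.between_block_subs:
            raise ValueError("within-family subs must stay below between-block subs")


def _random_sequence(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _block_ancestors(
    rng: np.random.Generator, ancestor: str, n_blocks: int, spec: FixtureSpec
) -> list[str]:
    """Block 0 keeps the ancestor; later blocks diverge at disjoint positions."""
    win_lo, win_hi = spec.central_window
    eligible = [p for p in range(len(ancestor)) if not (win_lo <= p + 1 <= win_hi)]
    needed = (n_blocks - 1) * spec.between_block_subs
    if needed > len(eligible):
        raise ValueError("not enough non-central positions for the requested blocks")
    chosen = rng.choice(len(eligible), size=needed, replace=False)
    ancestors = [ancestor]
    for block in range(1, n_blocks):
        positions = [eligible[i] for i in
                     chosen[(block - 1) * spec.between_block_subs:
                            block * spec.between_block_subs]]
        bases = list(ancestor)
        for p in positions:
            bases[p] = _NON_COVERABLE[bases[p]]
        ancestors.append("".join(bases))
    return ancestors


def _derive_member(rng: np.random.Generator, ancestor: str, max_subs: int) -> str:
    bases = list(ancestor)
    eligible = [p for p, b in enumerate(bases) if b in _WOBBLE_SAFE]
    n_subs = int(rng.integers(0, max_subs + 1)) if max_subs else 0
    n_subs = min(n_subs, len(eligible))
    if n_subs:
        for p in rng.choice(len(eligible), size=n_subs, replace=False):
            pos = eligible[int(p)]
            bases[pos] = _WOBBLE_SAFE[bases[pos]]
    return "".join(bases)


def generate_mirna_set(spec: FixtureSpec) -> list[MatureMiRNA]:
    """Synthetic catalogue with the family/block structure of ``spec``."""
    rng = np.random.default_rng(spec.seed)
    blocks = dict(spec.subfamily_blocks or {})
    catalogue: list[MatureMiRNA] = []
    for fam_idx in range(spec.n_families):
        family_number = spec.first_family_number + fam_idx
        ancestor = _random_sequence(rng, spec.mirna_length, _RNA)
        n_blocks = blocks.get(fam_idx, 1)
        ancestors = _block_ancestors(rng, ancestor, n_blocks, spec)
        # contiguous, near-equal block sizes: members a.. belong to block 0 etc.
        sizes = [spec.members_per_family // n_blocks] * n_blocks
        for i in range(spec.members_per_family % n_blocks):
            sizes[i] += 1
        letters = iter(string.ascii_lowercase)
        for block_idx, size in enumerate(sizes):
            for _ in range(size):
                variant = next(letters)
                seq = _derive_member(rng, ancestors[block_idx], spec.within_family_subs)
                mirna_id = f"{spec.species}-miR{family_number}{variant}"
                catalogue.append(
                    MatureMiRNA.from_id(
                        mirna_id,
                        NucleotideSequence(seq, Alphabet.RNA),
                        description=f"synthetic family {family_number} block {block_idx}",
                    )
                )
    return catalogue


def generate_backbone(spec: FixtureSpec, motif_len: int = 24) -> Backbone:
    """Random backbone with a centred motif interval; deterministic by seed."""
    if not (20 <= motif_len <= 30):
        raise ValueError(f"motif_len {motif_len} outside [20, 30]")
    # independent stream so the backbone does not shift with catalogue settings
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    sequence = _random_sequence(rng, spec.backbone_length, _DNA)
    start = (spec.backbone_length - motif_len) // 2
    return Backbone(
        name=f"synIPS1_seed{spec.seed}",
        sequence=NucleotideSequence(sequence, Alphabet.DNA),
        motif_interval=(start, start + motif_len),
    )
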