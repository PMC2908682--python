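"""Partitioning miRNA families into subgroups that share one mimic each.

Members of a plant miRNA family often differ by a handful of substitutions.
A single decoy site can still capture several variants by exploiting G:U
wobble: at a position where members carry {A, G}, a site T pairs A by
Watson-Crick and G by wobble.  Where no single site base covers all member
bases, the family must be split and each subgroup gets its own mimic.  The
partition is computed by greedy set cover over maximal compatible subgroups
seeded from each member, with deterministic tie-breaking, and every reported
subgroup is re-validated: its designed mimic must capture every member.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

from .duplex import PairState, ScoringParams, classify_pair
from .seqio import MatureMiRNA

__all__ = [
    "FamilyGroup",
    "GroupingError",
    "group_by_family",
    "choose_site_base",
    "partition_for_mimics",
    "partition_catalogue",
    "partition_report_tsv",
]


class GroupingError(ValueError):
    """Raised when a family member cannot be covered by any mimic."""


def group_by_family(catalogue: Iterable[MatureMiRNA]) -> dict[str, list[MatureMiRNA]]:
    """Catalogue keyed by family label, members in deterministic id order."""
    families: dict[str, list[MatureMiRNA]] = {}
    for mirna in catalogue:
        families.setdefault(mirna.family, []).append(mirna)
    return {
        family: sorted(members, key=lambda m: m.id)
        for family, members in sorted(families.items())
    }


# Candidate site bases tried for every consensus column, in tie-break order.
_BASE_ORDER = "TGCA"


def choose_site_base(column_bases: Iterable[str]) -> str | None:
    """One DNA base pairing (WC or wobble) every member base, or None.

    Candidates incurring fewer wobble pairs are preferred (Watson-Crick
    coverage beats wobble coverage); remaining ties go T > G > C > A.
    """
    bases = set(column_bases)
    if not bases:
        raise ValueError("empty base set")
    best: tuple[int, int] | None = None
    best_cand: str | None = None
    for rank, cand in enumerate(_BASE_ORDER):
        states = [classify_pair(b, cand) for b in bases]
        if any(s is PairState.MISMATCH for s in states):
            continue
        wobbles = sum(1 for s in states if s is PairState.WOBBLE)
        key = (wobbles, rank)
        if best is None or key < best:
            best, best_cand = key, cand
    return best_cand


@dataclass(frozen=True)
class FamilyGroup:
    """A family with its partition into independently-mimicked subgroups."""

    family: str
    members: tuple[MatureMiRNA, ...]
    subgroups: tuple[tuple[MatureMiRNA, ...], ...]

    def __post_init__(self) -> None:
        ids = [m.id for sub in self.subgroups for m in sub]
        if sorted(ids) != sorted(m.id for m in self.members) or len(set(ids)) != len(ids):
            raise ValueError("subgroups must partition the family members")


def _subgroup_feasible(members: Sequence[MatureMiRNA], sparams, dparams) -> bool:
    from . import design  # local import: design builds on grouping

    try:
        design.design_mimic_site(list(members), sparams, dparams)
    except design.DesignError:
        return False
    return True


def partition_for_mimics(
    members: Sequence[MatureMiRNA],
    sparams: ScoringParams | None = None,
    dparams=None,
) -> list[list[MatureMiRNA]]:
    """Greedy minimal partition so that one mimic per subgroup captures all.

    Candidate subgroups are grown greedily from each still-uncovered seed (in
    id order): a member joins if a consensus site base exists at every
    non-bulge position and the designed mimic still captures everyone.  Each
    round selects the candidate covering the most uncovered members, ties
    broken by the lexicographically smallest seed id.  The result is a
    deterministic partition, independent of input order.
    """
    from . import design  # local import: design builds on grouping

    sparams = sparams or ScoringParams()
    dparams = dparams or design.DesignParams()
    members = sorted(members, key=lambda m: m.id)
    if not members:
        return []
    families = {m.family for m in members}
    if len(families) > 1:
        raise GroupingError(f"members span multiple families: {sorted(families)}")
    for m in members:
        if not _subgroup_feasible([m], sparams, dparams):
            raise GroupingError(
                f"member {m.id!r} cannot be captured even by its own dedicated mimic"
            )

    uncovered = {m.id: m for m in members}
    subgroups: list[list[MatureMiRNA]] = []
    while uncovered:
        pool = sorted(uncovered.values(), key=lambda m: m.id)
        best_cand: list[MatureMiRNA] | None = None
        for seed in pool:
            cand = [seed]
            for other in pool:
                if other.id == seed.id:
                    continue
                trial = sorted(cand + [other], key=lambda m: m.id)
                if _subgroup_feasible(trial, sparams, dparams):
                    cand = trial
            if best_cand is None or len(cand) > len(best_cand):
                best_cand = cand  # seeds scanned in id order: ties keep first
        assert best_cand is not None
        subgroups.append(best_cand)
        for m in best_cand:
            del uncovered[m.id]
    return subgroups


def partition_catalogue(
    catalogue: Iterable[MatureMiRNA],
    sparams: ScoringParams | None = None,
    dparams=None,
) -> list[FamilyGroup]:
    """Partition every family of a catalogue."""
    groups = []
    for family, members in group_by_family(catalogue).items():
        subs = partition_for_mimics(members, sparams, dparams)
        groups.append(
            FamilyGroup(family, tuple(members), tuple(tuple(s) for s in subs))
        )
    return groups


def partition_report_tsv(
    groups: Sequence[FamilyGroup], dest: Union[str, Path, TextIO, None] = None
) -> str:
    """TSV report: family, subgroup index, member ids, consensus coverage."""
    lines = ["family\tsubgroup\tn_members\tmember_ids\tconsensus_site_bases"]
    for group in groups:
        for idx, sub in enumerate(group.subgroups, start=1):
            length = max(len(m) for m in sub)
            consensus = []
            for pos in range(1, length + 1):
                bases = {m.sequence[pos - 1] for m in sub if len(m) >= pos}
                consensus.append(choose_site_base(bases) or "-")
            lines.append(
                "\t".join(
                    [
                        group.family,
                        str(idx),
                        str(len(sub)),
                        ",".join(m.id for m in sub),
                        "".join(consensus),
                    ]
                )
            )
    text = "\n".join(lines) + "\n"
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)  # type: ignore[union-attr]
        else:
            Path(dest).write_text(text)
    return text
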