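"""Building, validating and naming mimic sites; cross-capture matrices.

A mimic site is the reverse complement of its target miRNA (as DNA), with
the partner of one central miRNA position (position 11 by default, the 3'
partner of the scissile bond) removed and a 3-nt bulge sequence inserted in
its place.  For a 21-nt miRNA this yields the classic 23-nt decoy motif with
the bulge at site positions 11-13.  The bulge 3-mer is not arbitrary: a
poorly chosen sequence can re-pair with the central miRNA residues and
reconstitute a sliceable site, so candidates are screened until the
assembled site is provably non-cleavable, captures every source miRNA with
the bulge at the intended interval, and introduces no long homopolymer run.

For subgroups the site is built from per-position covering bases (see
:mod:`mimdesign.grouping`) against the longest member; shorter members are
checked with their 3'-most positions left unpaired at no penalty.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import pandas as pd

from . import grouping
from .duplex import (
    AlignmentError,
    DuplexAlignment,
    DuplexScore,
    ScoringParams,
    align_duplex,
    is_capturing,
    is_cleavable,
    noncentral_score,
    score_duplex,
)
from .seqio import Alphabet, MatureMiRNA, NucleotideSequence

__all__ = [
    "DesignError",
    "DesignParams",
    "MimicStatus",
    "MimicSite",
    "ValidationReport",
    "CaptureMatrix",
    "design_mimic_site",
    "choose_bulge_sequence",
    "validate_mimic",
    "capture_matrix",
    "name_mimic",
    "trim_site_for",
]


class DesignError(RuntimeError):
    """Raised when no admissible mimic site exists for a target."""


@dataclass(frozen=True)
class DesignParams:
    """Geometry of the decoy motif.

    ``bulge_replaces_position`` is the 1-based miRNA position whose site
    partner is removed; the inserted bulge then sits across the cleavage
    site.  Candidate bulge 3-mers are enumerated lexicographically (A<C<G<T)
    so the design is a pure function of its inputs.
    """

    bulge_length: int = 3
    bulge_replaces_position: int = 11
    homopolymer_max: int = 3
    bulge_alphabet: str = "ACGT"

    def __post_init__(self) -> None:
        if self.bulge_length < 3:
            raise ValueError("bulge_length must be >= 3 to block slicing")
        if self.homopolymer_max < 1:
            raise ValueError("homopolymer_max must be positive")


class MimicStatus(Enum):
    MIMIC_FUNCTIONAL = "MIMIC_FUNCTIONAL"
    CLEAVABLE = "CLEAVABLE"
    INERT = "INERT"


@dataclass(frozen=True)
class MimicSite:
    """A designed decoy motif (DNA) with its bulge interval and provenance."""

    name: str
    site: NucleotideSequence
    bulge_interval: tuple[int, int]  # 0-based half-open site coordinates
    sources: tuple[str, ...]
    status: MimicStatus
    report: Mapping | None = None

    def __len__(self) -> int:
        return len(self.site)


@dataclass(frozen=True)
class ValidationReport:
    status: MimicStatus
    alignment: DuplexAlignment
    score: DuplexScore
    cleavable: bool
    capturing: bool


def name_mimic(
    family: str, subgroup: Sequence[MatureMiRNA], whole_family: bool
) -> str:
    """``MIM<family>`` for whole families, ``MIM<family><variants>`` otherwise."""
    if not subgroup:
        raise ValueError("empty subgroup")
    if whole_family:
        return f"MIM{family}"
    variants = sorted({m.variant for m in subgroup})
    return f"MIM{family}{''.join(variants)}"


def trim_site_for(
    site: NucleotideSequence, design_len: int, mirna_len: int
) -> NucleotideSequence:
    """Drop the site 5' overhang pairing target positions beyond ``mirna_len``.

    The site's 5' end pairs the (longest) target's 3' end, so a member
    shorter by d nucleotides simply ignores the first d site bases.
    """
    drop = design_len - mirna_len
    if drop <= 0:
        return site
    return NucleotideSequence(site[drop:], Alphabet.DNA)


def _homopolymer_ok(site: str, bulge: tuple[int, int], max_run: int) -> bool:
    """No homopolymer run longer than ``max_run`` may touch the bulge."""
    bstart, bend = bulge
    run_start = 0
    for i in range(1, len(site) + 1):
        if i == len(site) or site[i] != site[run_start]:
            if i - run_start > max_run and i > bstart and run_start < bend:
                return False
            run_start = i
    return True


def _consensus_partners(
    targets: Sequence[MatureMiRNA], length: int, skip_position: int
) -> dict[int, str]:
    """Covering site base for each miRNA position except the bulged one."""
    partners: dict[int, str] = {}
    for pos in range(1, length + 1):
        if pos == skip_position:
            continue
        bases = {m.sequence[pos - 1] for m in targets if len(m) >= pos}
        partner = grouping.choose_site_base(bases)
        if partner is None:
            raise DesignError(
                f"no single site base covers bases {sorted(bases)} at miRNA "
                f"position {pos}; split the subgroup"
            )
        partners[pos] = partner
    return partners


def choose_bulge_sequence(
    targets: Sequence[MatureMiRNA],
    site_five: str,
    site_three: str,
    sparams: ScoringParams | None = None,
    dparams: DesignParams | None = None,
) -> tuple[str, list[dict]]:
    """First admissible bulge k-mer in lexicographic order, plus rejection log.

    A candidate is admissible when, for every source miRNA, the assembled
    site (i) is not cleavable, (ii) is capturing with the canonical
    minimum-score alignment placing a full-length bulge at the intended
    interval, and (iii) creates no homopolymer run longer than
    ``homopolymer_max`` together with its flanks.
    """
    sparams = sparams or ScoringParams()
    dparams = dparams or DesignParams()
    design_len = max(len(m) for m in targets)
    log: list[dict] = []
    for candidate in itertools.product(sorted(dparams.bulge_alphabet), repeat=dparams.bulge_length):
        bulge = "".join(candidate)
        site = site_five + bulge + site_three
        intended = (len(site_five), len(site_five) + dparams.bulge_length)
        reason = None
        if not _homopolymer_ok(site, intended, dparams.homopolymer_max):
            reason = f"homopolymer run longer than {dparams.homopolymer_max} at the bulge"
        else:
            for mirna in sorted(targets, key=lambda m: m.id):
                drop = design_len - len(mirna)
                member_site = site[drop:]
                member_intended = (intended[0] - drop, intended[1] - drop)
                aln = align_duplex(mirna, member_site, sparams)
                score = score_duplex(aln, sparams)
                if is_cleavable(aln, score, sparams):
                    reason = f"restores a cleavable site for {mirna.id}"
                    break
                if not is_capturing(aln, score, sparams):
                    reason = f"not capturing for {mirna.id}"
                    break
                if aln.bulge_site_interval != member_intended or (
                    aln.bulge_length != dparams.bulge_length
                ):
                    reason = (
                        f"minimum-score bulge for {mirna.id} at "
                        f"{aln.bulge_site_interval}, expected {member_intended}"
                    )
                    break
        if reason is None:
            return bulge, log
        log.append({"candidate": bulge, "reason": reason})
    raise DesignError(
        "all bulge candidates rejected: "
        + "; ".join(f"{e['candidate']}: {e['reason']}" for e in log)
    )


def design_mimic_site(
    target: Union[MatureMiRNA, Sequence[MatureMiRNA]],
    sparams: ScoringParams | None = None,
    dparams: DesignParams | None = None,
    name: str | None = None,
) -> MimicSite:
    """Design and validate a decoy site for one miRNA or a subgroup.

    The returned site is ``longest_target - 1 + bulge_length`` nucleotides
    long, carries the bulge across the cleavage site, and is guaranteed
    MIMIC_FUNCTIONAL (non-cleavable and capturing) for every source.
    """
    sparams = sparams or ScoringParams()
    dparams = dparams or DesignParams()
    targets = [target] if isinstance(target, MatureMiRNA) else sorted(
        target, key=lambda m: m.id
    )
    if not targets:
        raise DesignError("no target miRNAs given")
    families = {m.family for m in targets}
    if len(families) > 1:
        raise DesignError(f"targets span multiple families: {sorted(families)}")
    length = max(len(m) for m in targets)
    pos = dparams.bulge_replaces_position
    win_lo, win_hi = sparams.central_window
    if not (win_lo < pos < win_hi) and not (win_lo <= pos <= win_hi):
        raise DesignError(f"bulge position {pos} outside central window {sparams.central_window}")
    if min(len(m) for m in targets) <= pos:
        raise DesignError(
            f"targets shorter than {pos + 1} nt cannot host a central bulge"
        )
    partners = _consensus_partners(targets, length, pos)
    site_five = "".join(partners[p] for p in range(length, pos, -1))
    site_three = "".join(partners[p] for p in range(pos - 1, 0, -1))
    bulge, rejections = choose_bulge_sequence(targets, site_five, site_three, sparams, dparams)
    site = NucleotideSequence(site_five + bulge + site_three, Alphabet.DNA)
    bulge_interval = (len(site_five), len(site_five) + dparams.bulge_length)

    validations = {}
    for mirna in targets:
        drop = length - len(mirna)
        member_site = NucleotideSequence(site[drop:], Alphabet.DNA)
        rep = validate_mimic(member_site, mirna, sparams)
        if rep.status is not MimicStatus.MIMIC_FUNCTIONAL:
            raise DesignError(
                f"designed site fails validation for {mirna.id}: {rep.status.value}"
            )
        validations[mirna.id] = {
            "score_total": rep.score.total,
            "noncentral_score": noncentral_score(rep.alignment, rep.score),
            "bulge_between": rep.score.bulge_between,
        }
    if name is None:
        name = name_mimic(targets[0].family, targets, whole_family=False)
    report = {
        "bulge": bulge,
        "bulge_interval": list(bulge_interval),
        "rejected_candidates": rejections,
        "validation": validations,
    }
    return MimicSite(
        name=name,
        site=site,
        bulge_interval=bulge_interval,
        sources=tuple(m.id for m in targets),
        status=MimicStatus.MIMIC_FUNCTIONAL,
        report=report,
    )


def validate_mimic(
    site: Union[NucleotideSequence, str],
    mirna: MatureMiRNA,
    sparams: ScoringParams | None = None,
) -> ValidationReport:
    """Three-way call for an arbitrary candidate site against one miRNA.

    MIMIC_FUNCTIONAL if the duplex captures the loaded RISC; otherwise
    CLEAVABLE if it would be sliced; otherwise INERT (binds too poorly to do
    either, or pairs in a geometry that does neither).
    """
    sparams = sparams or ScoringParams()
    aln = align_duplex(mirna, site, sparams)
    score = score_duplex(aln, sparams)
    capturing = is_capturing(aln, score, sparams)
    cleavable = is_cleavable(aln, score, sparams)
    if capturing:
        status = MimicStatus.MIMIC_FUNCTIONAL
    elif cleavable:
        status = MimicStatus.CLEAVABLE
    else:
        status = MimicStatus.INERT
    return ValidationReport(status, aln, score, cleavable, capturing)


@dataclass(frozen=True)
class CaptureMatrix:
    """Predicted capture of every catalogue miRNA by every designed mimic."""

    captures: pd.DataFrame      # bool, mimic rows x miRNA columns
    noncentral: pd.DataFrame    # float, NaN where the pair is not alignable
    sources: Mapping[str, tuple[str, ...]]

    def off_targets(self) -> list[tuple[str, str]]:
        """(mimic, miRNA) pairs captured although not a design source."""
        flagged = []
        for mimic in self.captures.index:
            for mirna_id in self.captures.columns:
                if self.captures.at[mimic, mirna_id] and mirna_id not in self.sources[mimic]:
                    flagged.append((mimic, mirna_id))
        return flagged

    def to_tsv(self, dest: Union[str, Path, TextIO]) -> None:
        frame = self.captures.copy()
        frame.index.name = "mimic"
        if hasattr(dest, "write"):
            frame.to_csv(dest, sep="\t")
        else:
            frame.to_csv(Path(dest), sep="\t")


def capture_matrix(
    mimics: Sequence[MimicSite],
    catalogue: Sequence[MatureMiRNA],
    sparams: ScoringParams | None = None,
) -> CaptureMatrix:
    """Align and classify every (mimic, miRNA) pair.

    Pairs whose length difference falls outside the supported bulge range
    are marked not-alignable: capture False, score NaN.
    """
    sparams = sparams or ScoringParams()
    names = [m.name for m in mimics]
    ids = [m.id for m in catalogue]
    captures = pd.DataFrame(False, index=names, columns=ids, dtype=bool)
    noncentral = pd.DataFrame(float("nan"), index=names, columns=ids, dtype=float)
    for mimic in mimics:
        for mirna in catalogue:
            try:
                aln = align_duplex(mirna, mimic.site, sparams)
            except AlignmentError:
                continue
            score = score_duplex(aln, sparams)
            captures.at[mimic.name, mirna.id] = is_capturing(aln, score, sparams)
            noncentral.at[mimic.name, mirna.id] = noncentral_score(aln, score)
    return CaptureMatrix(
        captures=captures,
        noncentral=noncentral,
        sources={m.name: m.sources for m in mimics},
    )


def design_report_json(mimics: Sequence[MimicSite], sparams: ScoringParams,
                       dparams: DesignParams) -> str:
    """JSON design report: effective parameters plus per-mimic details."""
    payload = {
        "scoring_params": {k: list(v) if isinstance(v, tuple) else v
                           for k, v in vars(sparams).items()},
        "design_params": vars(dparams).copy(),
        "mimics": [
            {
                "name": m.name,
                "site": str(m.site),
                "bulge_interval": list(m.bulge_interval),
                "sources": list(m.sources),
                "status": m.status.value,
                "report": m.report,
            }
            for m in mimics
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
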