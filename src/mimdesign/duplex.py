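"""The antiparallel miRNA:site duplex model and the cleavability/capture calls.

A mature miRNA (RNA, numbered 1-based from its 5' end) is aligned end-to-end
against a candidate decoy site (DNA, written 5'->3').  Base pairs are
Watson-Crick (A:T, U:A, G:C, C:G), G:U wobble (G:T, U:G with T standing in
for U on the DNA site) or mismatches.  When the site is longer than the
miRNA, the surplus site nucleotides form exactly one contiguous site-side
bulge; the loop may additionally leave up to ``max_unpaired_mirna`` miRNA
positions unpaired, which reproduces the geometry of natural bulged decoy
sites such as IPS1: three unpaired site nucleotides sitting opposite a
single unpaired miRNA position at the cleavage site.  miRNA-side bulges and
multiple loops are not modelled.

Scoring follows the position-weighted penalty convention of plant
target-prediction rules: mismatches cost 1, wobbles 0.5, bulged site
nucleotides 1 per nt, everything doubled inside the core region (miRNA
positions 2-13 by default).  A duplex is *cleavable* when the scissile bond
opposite miRNA positions 10-11 is intact (no loop across the central window,
at most one non-Watson-Crick column at positions 9-11) and overall pairing
is good; it is *capturing* (a functional mimic interaction) when a >=3 nt
site bulge spans the central window, the seed-like region 2-9 pairs with
Watson-Crick or wobble geometry, and the remaining penalties are small.
The two calls are mutually exclusive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, Union

from .seqio import Alphabet, MatureMiRNA, NucleotideSequence

__all__ = [
    "PairState",
    "Column",
    "ScoringParams",
    "DuplexAlignment",
    "DuplexScore",
    "AlignmentError",
    "classify_pair",
    "align_duplex",
    "score_duplex",
    "is_cleavable",
    "is_capturing",
    "noncentral_score",
    "format_duplex_diagram",
    "alignment_to_tsv",
]


class AlignmentError(ValueError):
    """Raised for duplexes outside the supported alignment family."""


class PairState(Enum):
    WATSON_CRICK = "WATSON_CRICK"
    WOBBLE = "WOBBLE"
    MISMATCH = "MISMATCH"
    SITE_BULGE = "SITE_BULGE"       # unpaired site nucleotide (no miRNA residue)
    MIRNA_UNPAIRED = "MIRNA_UNPAIRED"  # miRNA position left without a partner


_WC = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("U", "G")}


def classify_pair(mirna_base: str, site_base: str) -> PairState:
    """Pair state of one miRNA (RNA) residue against one site (DNA) residue."""
    if mirna_base not in "ACGU":
        raise AlignmentError(f"invalid miRNA residue {mirna_base!r}")
    if site_base not in "ACGT":
        raise AlignmentError(f"invalid site residue {site_base!r}")
    pair = (mirna_base, site_base)
    if pair in _WC:
        return PairState.WATSON_CRICK
    if pair in _WOBBLE:
        return PairState.WOBBLE
    return PairState.MISMATCH


@dataclass(frozen=True)
class ScoringParams:
    """Penalties and geometric constants for duplex scoring and the two calls.

    The central constants (cleavage site opposite miRNA positions 10-11,
    central window 9-12) are the field's standard geometry; the penalty
    magnitudes are the conventional plant target-prediction weights and are
    configurable because no single canonical formula exists.
    """

    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    bulge_penalty_per_nt: float = 1.0
    core_region: tuple[int, int] = (2, 13)
    core_weight: float = 2.0
    central_window: tuple[int, int] = (9, 12)
    cleavage_site_positions: tuple[int, int] = (10, 11)
    max_site_bulge: int = 5
    max_unpaired_mirna: int = 1
    min_capture_bulge: int = 3
    capture_seed_region: tuple[int, int] = (2, 9)
    cleavable_max_score: float = 4.0
    capture_max_noncentral_score: float = 3.0

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.wobble_penalty, self.bulge_penalty_per_nt) < 0:
            raise ValueError("penalties must be non-negative")
        lo, hi = self.cleavage_site_positions
        if hi != lo + 1:
            raise ValueError("cleavage_site_positions must be adjacent")
        for name in ("core_region", "central_window", "capture_seed_region"):
            a, b = getattr(self, name)
            if not (1 <= a <= b):
                raise ValueError(f"{name} must be an increasing 1-based interval")


class Column(NamedTuple):
    mirna_pos: int | None  # 1-based from the miRNA 5' end; None for site bulges
    site_pos: int | None   # 1-based from the site 5' end; None for unpaired miRNA
    state: PairState


@dataclass(frozen=True)
class DuplexAlignment:
    """A global antiparallel alignment with at most one internal loop.

    ``columns`` run along the miRNA 5'->3'; site positions strictly decrease
    (antiparallel).  ``bulge_flanks`` are the miRNA positions flanking the
    loop (0 / mirna_len+1 when the loop touches an end); ``unpaired_mirna``
    lists miRNA positions inside the loop that have no partner.
    """

    mirna: str
    site: str
    columns: tuple[Column, ...]
    bulge_site_interval: tuple[int, int] | None  # 0-based half-open site coords
    bulge_flanks: tuple[int, int] | None         # miRNA positions around the loop
    unpaired_mirna: tuple[int, ...] = ()

    @property
    def mirna_len(self) -> int:
        return len(self.mirna)

    @property
    def site_len(self) -> int:
        return len(self.site)

    @property
    def bulge_length(self) -> int:
        if self.bulge_site_interval is None:
            return 0
        return self.bulge_site_interval[1] - self.bulge_site_interval[0]


@dataclass(frozen=True)
class DuplexScore:
    total: float
    per_column: tuple[float, ...]
    bulge_length: int
    bulge_between: tuple[int, int] | None


MiRNALike = Union[MatureMiRNA, NucleotideSequence, str]
SiteLike = Union[NucleotideSequence, str]


def _mirna_residues(mirna: MiRNALike) -> str:
    if isinstance(mirna, MatureMiRNA):
        return mirna.sequence.to_rna().residues
    if isinstance(mirna, NucleotideSequence):
        return mirna.to_rna().residues
    return NucleotideSequence(str(mirna), Alphabet.RNA).residues


def _site_residues(site: SiteLike) -> str:
    if isinstance(site, NucleotideSequence):
        return site.to_dna().residues
    return NucleotideSequence(str(site), Alphabet.DNA).residues


def _build_alignment(mirna: str, site: str, gap_index: int, n_skipped: int) -> DuplexAlignment:
    """Alignment with the loop after miRNA position ``gap_index``.

    ``n_skipped`` miRNA positions (gap_index+1 ..) are left unpaired inside
    the loop; the site contributes ``site_len - mirna_len + n_skipped``
    bulged nucleotides.
    """
    L, S = len(mirna), len(site)
    b = S - L + n_skipped
    columns: list[Column] = []
    for i in range(1, gap_index + 1):
        sp = S - i + 1
        columns.append(Column(i, sp, classify_pair(mirna[i - 1], site[sp - 1])))
    bulge_interval = None
    flanks = None
    if b > 0 or n_skipped > 0:
        top = S - gap_index  # highest bulged site position
        for k in range(b):
            columns.append(Column(None, top - k, PairState.SITE_BULGE))
        for i in range(gap_index + 1, gap_index + n_skipped + 1):
            columns.append(Column(i, None, PairState.MIRNA_UNPAIRED))
        bulge_interval = (top - b, top)  # 0-based half-open
        flanks = (gap_index, gap_index + n_skipped + 1)
    for i in range(gap_index + n_skipped + 1, L + 1):
        sp = S - b - i + n_skipped + 1
        columns.append(Column(i, sp, classify_pair(mirna[i - 1], site[sp - 1])))
    return DuplexAlignment(
        mirna=mirna,
        site=site,
        columns=tuple(columns),
        bulge_site_interval=bulge_interval,
        bulge_flanks=flanks,
        unpaired_mirna=tuple(range(gap_index + 1, gap_index + n_skipped + 1)),
    )


def enumerate_alignments(
    mirna: MiRNALike, site: SiteLike, params: ScoringParams | None = None
) -> Iterable[DuplexAlignment]:
    """Every alignment in the supported family, in canonical gap-index order.

    Equal lengths admit only the ungapped alignment; a longer site admits one
    contiguous loop at every gap index, optionally consuming up to
    ``max_unpaired_mirna`` miRNA positions.
    """
    params = params or ScoringParams()
    m = _mirna_residues(mirna)
    s = _site_residues(site)
    L, S = len(m), len(s)
    if S < L:
        raise AlignmentError(f"site ({S} nt) shorter than miRNA ({L} nt): unsupported")
    if S - L > params.max_site_bulge:
        raise AlignmentError(
            f"length difference {S - L} exceeds max_site_bulge {params.max_site_bulge}"
        )
    if S == L:
        yield _build_alignment(m, s, 0, 0)
        return
    for n_skipped in range(0, params.max_unpaired_mirna + 1):
        if S - L + n_skipped > params.max_site_bulge:
            break
        for gap_index in range(0, L - n_skipped + 1):
            yield _build_alignment(m, s, gap_index, n_skipped)


def score_duplex(aln: DuplexAlignment, params: ScoringParams | None = None) -> DuplexScore:
    """Position-weighted penalty total for one alignment.

    Bulge columns inherit the core weighting of their nearest flanking miRNA
    position; unpaired miRNA positions inside the loop carry no penalty of
    their own (the loop is already paid for through its site nucleotides).
    """
    params = params or ScoringParams()
    L = aln.mirna_len
    core_lo, core_hi = params.core_region
    core_hi = min(core_hi, L)

    def weight(pos: int) -> float:
        return params.core_weight if core_lo <= pos <= core_hi else 1.0

    base = {
        PairState.WATSON_CRICK: 0.0,
        PairState.WOBBLE: params.wobble_penalty,
        PairState.MISMATCH: params.mismatch_penalty,
        PairState.SITE_BULGE: params.bulge_penalty_per_nt,
        PairState.MIRNA_UNPAIRED: 0.0,
    }
    flanks = aln.bulge_flanks
    b = aln.bulge_length
    per_column: list[float] = []
    bulge_seen = 0
    for col in aln.columns:
        penalty = base[col.state]
        if col.state is PairState.SITE_BULGE:
            left, right = flanks  # type: ignore[misc]
            left_ok, right_ok = left >= 1, right <= L
            if left_ok and right_ok:
                eff = left if bulge_seen < (b + 1) // 2 else right
            elif left_ok:
                eff = left
            else:
                eff = right
            bulge_seen += 1
        else:
            eff = col.mirna_pos if col.mirna_pos is not None else 0
        per_column.append(penalty * weight(eff) if eff else penalty)
    between = None
    if flanks is not None:
        between = (max(flanks[0], 1), min(flanks[1], L))
    return DuplexScore(
        total=sum(per_column),
        per_column=tuple(per_column),
        bulge_length=b,
        bulge_between=between,
    )


def align_duplex(
    mirna: MiRNALike, site: SiteLike, params: ScoringParams | None = None
) -> DuplexAlignment:
    """Minimum-score alignment under :func:`score_duplex`.

    Ties are broken deterministically: prefer the larger site bulge (the
    structural convention for decoy sites, where poorly pairing central
    residues are drawn as loop rather than forced into a pair), then the
    smallest gap index.
    """
    params = params or ScoringParams()
    best: tuple[float, int, int] | None = None
    best_aln: DuplexAlignment | None = None
    for aln in enumerate_alignments(mirna, site, params):
        total = score_duplex(aln, params).total
        gap_index = aln.bulge_flanks[0] if aln.bulge_flanks else 0
        key = (total, -aln.bulge_length, gap_index)
        if best is None or key < best:
            best, best_aln = key, aln
    assert best_aln is not None
    return best_aln


def _loop_intersects_window(aln: DuplexAlignment, window: tuple[int, int]) -> bool:
    if aln.bulge_flanks is None:
        return False
    left, right = aln.bulge_flanks
    lo, hi = window
    return left < hi and right > lo


def _loop_within_window(aln: DuplexAlignment, window: tuple[int, int]) -> bool:
    if aln.bulge_flanks is None:
        return False
    left, right = aln.bulge_flanks
    lo, hi = window
    return left >= lo and right <= hi


def is_cleavable(
    aln: DuplexAlignment, score: DuplexScore, params: ScoringParams | None = None
) -> bool:
    """Would RISC slice this site?  True iff the scissile bond is intact.

    Requires (a) no loop across the central window, (b) at most one
    non-Watson-Crick column at miRNA positions 9-11, and (c) an overall
    score no worse than ``cleavable_max_score``.
    """
    params = params or ScoringParams()
    if _loop_intersects_window(aln, params.central_window):
        return False
    lo = params.cleavage_site_positions[0] - 1
    hi = params.cleavage_site_positions[1]
    non_wc = sum(
        1
        for col in aln.columns
        if col.mirna_pos is not None
        and lo <= col.mirna_pos <= hi
        and col.state is not PairState.WATSON_CRICK
    )
    if non_wc > 1:
        return False
    return score.total <= params.cleavable_max_score


def noncentral_score(aln: DuplexAlignment, score: DuplexScore) -> float:
    """Score total excluding the loop columns (site bulge and skipped miRNA)."""
    excluded = sum(
        pen
        for col, pen in zip(aln.columns, score.per_column)
        if col.state in (PairState.SITE_BULGE, PairState.MIRNA_UNPAIRED)
    )
    return score.total - excluded


def is_capturing(
    aln: DuplexAlignment, score: DuplexScore, params: ScoringParams | None = None
) -> bool:
    """Would this site stably sequester the loaded RISC without being sliced?

    Requires (a) a site bulge of >= ``min_capture_bulge`` nt lying within the
    central window, (b) Watson-Crick or wobble pairing throughout miRNA
    positions 2-9, and (c) non-loop penalties within
    ``capture_max_noncentral_score``.
    """
    params = params or ScoringParams()
    if aln.bulge_length < params.min_capture_bulge:
        return False
    if not _loop_within_window(aln, params.central_window):
        return False
    lo, hi = params.capture_seed_region
    for col in aln.columns:
        if col.mirna_pos is not None and lo <= col.mirna_pos <= hi:
            if col.state not in (PairState.WATSON_CRICK, PairState.WOBBLE):
                return False
    return noncentral_score(aln, score) <= params.capture_max_noncentral_score


_SYMBOL = {
    PairState.WATSON_CRICK: "|",
    PairState.WOBBLE: ":",
    PairState.MISMATCH: ".",
    PairState.SITE_BULGE: " ",
    PairState.MIRNA_UNPAIRED: " ",
}


def format_duplex_diagram(aln: DuplexAlignment) -> str:
    """Three-line text diagram: site 3'->5', pairing symbols, miRNA 5'->3'."""
    top = "".join(
        aln.site[c.site_pos - 1] if c.site_pos is not None else "-" for c in aln.columns
    )
    mid = "".join(_SYMBOL[c.state] for c in aln.columns)
    bottom = "".join(
        aln.mirna[c.mirna_pos - 1] if c.mirna_pos is not None else "-" for c in aln.columns
    )
    return f"site  3'-{top}-5'\n         {mid}\nmiRNA 5'-{bottom}-3'"


def alignment_to_tsv(aln: DuplexAlignment, score: DuplexScore | None = None) -> str:
    """Per-column TSV (1-based positions; '-' marks a gap)."""
    header = ["mirna_pos", "mirna_base", "site_pos", "site_base", "state"]
    if score is not None:
        header.append("penalty")
    lines = ["\t".join(header)]
    for idx, col in enumerate(aln.columns):
        row = [
            str(col.mirna_pos) if col.mirna_pos else "-",
            aln.mirna[col.mirna_pos - 1] if col.mirna_pos else "-",
            str(col.site_pos) if col.site_pos else "-",
            aln.site[col.site_pos - 1] if col.site_pos else "-",
            col.state.value,
        ]
        if score is not None:
            row.append(f"{score.per_column[idx]:g}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
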