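"""Motif replacement in the decoy backbone and overlap-extension primers.

The mimic motif is swapped into the backbone in place of its natural
miRNA-complementary motif; the construct is then produced in the wet lab by
overlap-extension mutagenesis PCR: an internal mutagenic primer pair carries
the full replacement motif flanked by backbone anchors, and an outer primer
pair amplifies from the backbone ends.  The two partial products share the
mutagenic region and are stitched by their overlap.  Primer melting
temperatures use the Wallace rule, Tm = 2*(A+T) + 4*(G+C) degC, which is
closed-form and makes the whole design a pure function of its inputs.
Vector context (promoter, selection) is annotation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO, Union

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from Bio.SeqUtils import MeltingTemp

from .design import MimicSite
from .seqio import Alphabet, Backbone, NucleotideSequence, reverse_complement

__all__ = [
    "PrimerError",
    "PrimerParams",
    "Construct",
    "PrimerPair",
    "MutagenesisDesign",
    "assemble_construct",
    "melting_temperature",
    "design_mutagenesis_primers",
    "stitch_products",
    "simulate_overlap_extension",
    "write_construct_genbank",
    "primers_to_tsv",
]

# Fixed LOCUS date so identical runs emit byte-identical flat files.
_GENBANK_DATE = "01-JAN-2000"


class PrimerError(RuntimeError):
    """Raised when no admissible primer set exists for a construct."""


@dataclass(frozen=True)
class PrimerParams:
    min_flank: int = 20          # nt of backbone anchor on each side of the motif
    tm_target: float = 55.0      # degC, Wallace rule
    outer_tm_window: float = 8.0  # outer primers must land in [target, target+window]

    def __post_init__(self) -> None:
        if self.min_flank < 1:
            raise ValueError("min_flank must be positive")


@dataclass(frozen=True)
class Construct:
    """A backbone with its motif replaced by a designed mimic site."""

    name: str
    sequence: NucleotideSequence
    motif_interval: tuple[int, int]
    annotations: tuple[tuple[str, tuple[int, int], str], ...] = ()
    notes: tuple[str, ...] = ()

    @property
    def motif(self) -> str:
        start, end = self.motif_interval
        return self.sequence[start:end]


@dataclass(frozen=True)
class PrimerPair:
    forward: NucleotideSequence
    reverse: NucleotideSequence
    forward_interval: tuple[int, int]  # 0-based half-open on the construct
    reverse_interval: tuple[int, int]
    tm_forward: float
    tm_reverse: float
    role: str  # "MUTAGENIC" | "OUTER"


@dataclass(frozen=True)
class MutagenesisDesign:
    construct: Construct
    mutagenic: PrimerPair
    outer: PrimerPair


def melting_temperature(seq: Union[NucleotideSequence, str]) -> float:
    """Wallace-rule Tm in degC: 2*(#A + #T) + 4*(#G + #C)."""
    residues = str(seq)
    if not residues:
        raise PrimerError("cannot compute Tm of an empty sequence")
    return float(MeltingTemp.Tm_Wallace(residues))


def assemble_construct(backbone: Backbone, mimic: MimicSite) -> Construct:
    """Replace the backbone motif with the mimic site, preserving the flanks."""
    start, end = backbone.motif_interval
    seq = backbone.sequence[:start] + str(mimic.site) + backbone.sequence[end:]
    motif_interval = (start, start + len(mimic.site))
    bulge = (start + mimic.bulge_interval[0], start + mimic.bulge_interval[1])
    annotations = (
        ("misc_feature", motif_interval, f"{mimic.name} target mimic motif"),
        ("misc_feature", bulge, "central bulge (blocks RISC slicing)"),
    )
    return Construct(
        name=mimic.name,
        sequence=NucleotideSequence(seq, Alphabet.DNA),
        motif_interval=motif_interval,
        annotations=annotations,
        notes=("expression context placeholder: p35S promoter, binary vector "
               "(not modelled)",),
    )


def _extend_to_tm(sequence: str, start: int, tm_target: float, direction: int) -> int:
    """Smallest k with Wallace Tm >= target, growing one base at a time.

    ``direction`` +1 grows construct[start:start+k]; -1 grows
    construct[start-k:start].  Returns k or raises if the sequence runs out.
    """
    k = 0
    while True:
        k += 1
        if direction > 0:
            if start + k > len(sequence):
                raise PrimerError("Tm target unreachable before the end of the backbone")
            segment = sequence[start:start + k]
        else:
            if start - k < 0:
                raise PrimerError("Tm target unreachable before the start of the backbone")
            segment = sequence[start - k:start]
        if melting_temperature(segment) >= tm_target:
            return k


def design_mutagenesis_primers(
    backbone: Backbone, mimic: MimicSite, pparams: PrimerParams | None = None
) -> MutagenesisDesign:
    """Mutagenic + outer primer pairs for overlap-extension motif replacement.

    The mutagenic forward primer is ``min_flank`` upstream backbone bases,
    the full mimic site, then downstream bases extended 3' one at a time
    until the downstream anchor reaches the Tm target; the mutagenic reverse
    primer covers the symmetric region on the other strand.  Outer primers
    anchor at the construct ends and are extended 3' until their Tm enters
    [tm_target, tm_target + outer_tm_window].
    """
    pparams = pparams or PrimerParams()
    construct = assemble_construct(backbone, mimic)
    seq = str(construct.sequence)
    ms, me = construct.motif_interval
    if ms < pparams.min_flank or len(seq) - me < pparams.min_flank:
        raise PrimerError(
            f"backbone flank shorter than min_flank={pparams.min_flank} nt"
        )

    k_down = _extend_to_tm(seq, me, pparams.tm_target, +1)
    fwd_interval = (ms - pparams.min_flank, me + k_down)
    fwd = NucleotideSequence(seq[fwd_interval[0]:fwd_interval[1]], Alphabet.DNA)

    k_up = _extend_to_tm(seq, ms, pparams.tm_target, -1)
    rev_interval = (ms - k_up, me + pparams.min_flank)
    rev_region = NucleotideSequence(seq[rev_interval[0]:rev_interval[1]], Alphabet.DNA)
    rev = reverse_complement(rev_region, Alphabet.DNA)
    mutagenic = PrimerPair(
        forward=fwd,
        reverse=rev,
        forward_interval=fwd_interval,
        reverse_interval=rev_interval,
        tm_forward=melting_temperature(fwd),
        tm_reverse=melting_temperature(rev),
        role="MUTAGENIC",
    )

    k_of = _extend_to_tm(seq, 0, pparams.tm_target, +1)
    outer_fwd = NucleotideSequence(seq[:k_of], Alphabet.DNA)
    k_or = _extend_to_tm(seq, len(seq), pparams.tm_target, -1)
    outer_rev_region = NucleotideSequence(seq[len(seq) - k_or:], Alphabet.DNA)
    outer_rev = reverse_complement(outer_rev_region, Alphabet.DNA)
    lo, hi = pparams.tm_target, pparams.tm_target + pparams.outer_tm_window
    for tm in (melting_temperature(outer_fwd), melting_temperature(outer_rev)):
        if not (lo <= tm <= hi):
            raise PrimerError(f"outer primer Tm {tm} outside [{lo}, {hi}] degC")
    outer = PrimerPair(
        forward=outer_fwd,
        reverse=outer_rev,
        forward_interval=(0, k_of),
        reverse_interval=(len(seq) - k_or, len(seq)),
        tm_forward=melting_temperature(outer_fwd),
        tm_reverse=melting_temperature(outer_rev),
        role="OUTER",
    )
    return MutagenesisDesign(construct=construct, mutagenic=mutagenic, outer=outer)


def stitch_products(product_a: str, product_b: str, min_overlap: int = 15) -> str:
    """Join two PCR products at their longest exact 3'/5' overlap."""
    max_k = min(len(product_a), len(product_b))
    for k in range(max_k, min_overlap - 1, -1):
        if product_a[-k:] == product_b[:k]:
            return product_a + product_b[k:]
    raise PrimerError(f"products share no exact overlap of >= {min_overlap} nt")


def simulate_overlap_extension(design: MutagenesisDesign) -> str:
    """In-silico overlap-extension: amplify both halves, stitch the overlap.

    Product A runs from the outer forward primer to the 5' end of the
    mutagenic reverse primer; product B from the mutagenic forward primer to
    the outer reverse primer.  Both are located on the template by exact
    primer matches before stitching, so a primer that does not anchor
    perfectly fails loudly.
    """
    template = str(design.construct.sequence)
    if not template.startswith(str(design.outer.forward)):
        raise PrimerError("outer forward primer does not anchor at the template start")
    if not template.endswith(
        str(reverse_complement(design.outer.reverse, Alphabet.DNA))
    ):
        raise PrimerError("outer reverse primer does not anchor at the template end")
    mr_start, mr_end = design.mutagenic.reverse_interval
    if template[mr_start:mr_end] != str(
        reverse_complement(design.mutagenic.reverse, Alphabet.DNA)
    ):
        raise PrimerError("mutagenic reverse primer does not anchor on the template")
    mf_start, mf_end = design.mutagenic.forward_interval
    if template[mf_start:mf_end] != str(design.mutagenic.forward):
        raise PrimerError("mutagenic forward primer does not anchor on the template")
    product_a = template[0:mr_end]
    product_b = template[mf_start:]
    return stitch_products(product_a, product_b)


def write_construct_genbank(
    design: MutagenesisDesign, dest: Union[str, Path, TextIO]
) -> None:
    """GenBank-style flat file: motif as misc_feature, primers as primer_bind."""
    construct = design.construct
    record = SeqRecord(
        Seq(str(construct.sequence)),
        id=construct.name,
        name=construct.name[:16],
        description=f"{construct.name} artificial target mimic construct",
        annotations={"molecule_type": "DNA", "date": _GENBANK_DATE,
                     "topology": "linear"},
    )
    if construct.notes:
        record.annotations["comment"] = "; ".join(construct.notes)
    for key, (start, end), label in construct.annotations:
        record.features.append(
            SeqFeature(FeatureLocation(start, end), type=key,
                       qualifiers={"note": [label]})
        )
    primers = [
        ("mutagenic_fwd", design.mutagenic.forward_interval, 1),
        ("mutagenic_rev", design.mutagenic.reverse_interval, -1),
        ("outer_fwd", design.outer.forward_interval, 1),
        ("outer_rev", design.outer.reverse_interval, -1),
    ]
    for label, (start, end), strand in primers:
        record.features.append(
            SeqFeature(FeatureLocation(start, end, strand=strand),
                       type="primer_bind",
                       qualifiers={"note": [f"{construct.name} {label}"]})
        )
    if hasattr(dest, "write"):
        SeqIO.write([record], dest, "genbank")
    else:
        with open(dest, "w") as handle:
            SeqIO.write([record], handle, "genbank")


def primers_to_tsv(
    designs: Sequence[MutagenesisDesign], dest: Union[str, Path, TextIO, None] = None
) -> str:
    """Primer table: name, role, sequence, 1-based inclusive anchor, Tm."""
    lines = ["name\trole\tsequence\tanchor_start\tanchor_end\ttm_c"]
    for design in designs:
        rows = [
            ("mutagenic_fwd", design.mutagenic.role, design.mutagenic.forward,
             design.mutagenic.forward_interval, design.mutagenic.tm_forward),
            ("mutagenic_rev", design.mutagenic.role, design.mutagenic.reverse,
             design.mutagenic.reverse_interval, design.mutagenic.tm_reverse),
            ("outer_fwd", design.outer.role, design.outer.forward,
             design.outer.forward_interval, design.outer.tm_forward),
            ("outer_rev", design.outer.role, design.outer.reverse,
             design.outer.reverse_interval, design.outer.tm_reverse),
        ]
        for label, role, seq, (start, end), tm in rows:
            lines.append(
                f"{design.construct.name}_{label}\t{role}\t{seq}\t"
                f"{start + 1}\t{end}\t{tm:g}"
            )
    text = "\n".join(lines) + "\n"
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)  # type: ignore[union-attr]
        else:
            Path(dest).write_text(text)
    return text
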