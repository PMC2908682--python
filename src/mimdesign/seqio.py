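"""Reading, writing and normalising miRNA catalogues and backbone sequences.

Mature miRNA catalogues follow the miRBase ``mature.fa`` dialect: the first
whitespace-delimited header token is the identifier (e.g. ``ath-miR172a``),
the remainder is kept as free-text description.  Sequences are normalised to
uppercase RNA; ambiguity codes are rejected outright so that unusable records
fail fast.  Coordinates are 0-based half-open everywhere in this package;
1-based inclusive intervals appear only in human-readable reports.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alphabet",
    "NucleotideSequence",
    "MatureMiRNA",
    "Backbone",
    "CatalogueError",
    "family_label",
    "parse_mirna_fasta",
    "reverse_complement",
    "write_fasta",
    "read_backbone",
    "read_motif_tsv",
    "write_motif_tsv",
]


class CatalogueError(ValueError):
    """Raised for unusable catalogue or backbone input."""


class Alphabet(str, Enum):
    RNA = "RNA"
    DNA = "DNA"


_VALID = {Alphabet.RNA: frozenset("ACGU"), Alphabet.DNA: frozenset("ACGT")}
_RNA_TO_DNA = str.maketrans("U", "T")
_DNA_TO_RNA = str.maketrans("T", "U")


@dataclass(frozen=True)
class NucleotideSequence:
    """An unambiguous nucleotide sequence read 5'->3' in a declared alphabet."""

    residues: str
    alphabet: Alphabet = Alphabet.RNA

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        object.__setattr__(self, "alphabet", Alphabet(self.alphabet))
        if not self.residues:
            raise CatalogueError("empty sequence")
        valid = _VALID[self.alphabet]
        for pos, base in enumerate(self.residues, start=1):
            if base not in valid:
                raise CatalogueError(
                    f"invalid {self.alphabet.value} residue {base!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, item):
        return self.residues[item]

    def to(self, alphabet: Alphabet) -> "NucleotideSequence":
        """Convert between RNA and DNA spelling (U<->T); lossless and involutive."""
        alphabet = Alphabet(alphabet)
        if alphabet is self.alphabet:
            return self
        table = _RNA_TO_DNA if alphabet is Alphabet.DNA else _DNA_TO_RNA
        return NucleotideSequence(self.residues.translate(table), alphabet)

    def to_rna(self) -> "NucleotideSequence":
        return self.to(Alphabet.RNA)

    def to_dna(self) -> "NucleotideSequence":
        return self.to(Alphabet.DNA)

    def reverse_complement(self, out_alphabet: Alphabet | None = None) -> "NucleotideSequence":
        return reverse_complement(self, out_alphabet)


def reverse_complement(
    seq: NucleotideSequence, out_alphabet: Alphabet | None = None
) -> NucleotideSequence:
    """Antiparallel complement of *seq* in the requested alphabet.

    Biopython's :meth:`Bio.Seq.Seq.reverse_complement` emits DNA letters even
    for RNA input, so conversion is applied explicitly on both sides.
    """
    out_alphabet = Alphabet(out_alphabet) if out_alphabet is not None else seq.alphabet
    rc_dna = str(Seq(seq.to_dna().residues).reverse_complement())
    return NucleotideSequence(rc_dna, Alphabet.DNA).to(out_alphabet)


_ID_RE = re.compile(
    r"^(?P<species>[A-Za-z][A-Za-z0-9]*)-miR(?P<family>\d+)(?P<variant>[a-z]+|\.\d+)?$"
)


def family_label(mirna_id: str) -> tuple[str, str]:
    """Split an id like ``ath-miR172a`` into (family, variant).

    The family is the numeric token; the variant is the trailing letter run
    or a ``.n`` token, empty when absent (``ath-miR172a`` -> ``("172", "a")``,
    ``ath-miR161.1`` -> ``("161", ".1")``).
    """
    match = _ID_RE.match(mirna_id)
    if match is None:
        raise CatalogueError(f"cannot parse miRNA id {mirna_id!r}")
    return match.group("family"), match.group("variant") or ""


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA with family/variant labels parsed from its id."""

    id: str
    family: str
    variant: str
    sequence: NucleotideSequence
    description: str = ""

    @classmethod
    def from_id(
        cls, mirna_id: str, sequence: NucleotideSequence, description: str = ""
    ) -> "MatureMiRNA":
        family, variant = family_label(mirna_id)
        return cls(mirna_id, family, variant, sequence.to_rna(), description)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Backbone:
    """A decoy backbone (DNA) with the interval of the motif to be replaced."""

    name: str
    sequence: NucleotideSequence
    motif_interval: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.motif_interval
        if not (0 <= start < end <= len(self.sequence)):
            raise CatalogueError(
                f"motif interval {self.motif_interval} outside backbone of "
                f"length {len(self.sequence)}"
            )
        if not (20 <= end - start <= 30):
            raise CatalogueError(
                f"motif length {end - start} outside the supported 20-30 nt range"
            )

    @property
    def motif(self) -> NucleotideSequence:
        start, end = self.motif_interval
        return NucleotideSequence(self.sequence[start:end], Alphabet.DNA)


Source = Union[str, Path, TextIO]


def _as_handle(source: Source) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    text = str(source)
    if "\n" in text or text.lstrip().startswith(">"):
        return io.StringIO(text)
    return open(text)


def parse_mirna_fasta(
    source: Source,
    species_prefix: str | None = None,
    min_len: int = 18,
    max_len: int = 26,
) -> list[MatureMiRNA]:
    """Parse a mature-miRNA FASTA into a catalogue of :class:`MatureMiRNA`.

    Records whose id does not start with ``species_prefix + "-"`` are dropped
    before any validation.  Sequences are uppercased and converted to RNA;
    residues outside {A,C,G,U,T} (any case) and duplicate ids are errors.
    """
    records: list[MatureMiRNA] = []
    seen: set[str] = set()
    handle = _as_handle(source)
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            if species_prefix is not None and not rec.id.startswith(species_prefix + "-"):
                continue
            raw = str(rec.seq).upper()
            for pos, base in enumerate(raw, start=1):
                if base not in "ACGUT":
                    raise CatalogueError(
                        f"record {rec.id!r}: invalid residue {base!r} at position {pos}"
                    )
            if not (min_len <= len(raw) <= max_len):
                raise CatalogueError(
                    f"record {rec.id!r}: length {len(raw)} outside [{min_len}, {max_len}]"
                )
            if rec.id in seen:
                raise CatalogueError(f"duplicate miRNA id {rec.id!r}")
            seen.add(rec.id)
            seq = NucleotideSequence(raw.translate(_DNA_TO_RNA), Alphabet.RNA)
            description = rec.description[len(rec.id):].strip()
            records.append(MatureMiRNA.from_id(rec.id, seq, description))
    finally:
        if handle is not source:
            handle.close()
    return records


def write_fasta(
    entries: Iterable[Union[MatureMiRNA, tuple[str, NucleotideSequence]]],
    dest: Union[str, Path, TextIO],
) -> None:
    """Write records as 60-column-wrapped FASTA (ids and order preserved)."""
    seqrecords = []
    for entry in entries:
        if isinstance(entry, MatureMiRNA):
            name, seq, desc = entry.id, entry.sequence, entry.description
        else:
            (name, seq), desc = entry, ""
        seqrecords.append(SeqRecord(Seq(str(seq)), id=name, description=desc))
    if hasattr(dest, "write"):
        SeqIO.write(seqrecords, dest, "fasta")
    else:
        with open(dest, "w") as handle:
            SeqIO.write(seqrecords, handle, "fasta")


def read_motif_tsv(source: Source) -> dict[str, tuple[int, int]]:
    """Read a 3-column ``name  start  end`` TSV of 0-based half-open intervals."""
    intervals: dict[str, tuple[int, int]] = {}
    handle = _as_handle(source)
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise CatalogueError(f"motif TSV line {lineno}: expected 3 columns")
            name, start, end = parts
            intervals[name] = (int(start), int(end))
    finally:
        if handle is not source:
            handle.close()
    return intervals


def write_motif_tsv(backbones: Sequence[Backbone], dest: Union[str, Path, TextIO]) -> None:
    lines = [f"{b.name}\t{b.motif_interval[0]}\t{b.motif_interval[1]}\n" for b in backbones]
    if hasattr(dest, "write"):
        dest.writelines(lines)  # type: ignore[union-attr]
    else:
        Path(dest).write_text("".join(lines))


def read_backbone(fasta: Source, motif_tsv: Source | None = None,
                  interval: tuple[int, int] | None = None) -> Backbone:
    """Load the first backbone record from FASTA plus its motif coordinates."""
    handle = _as_handle(fasta)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if handle is not fasta:
            handle.close()
    if not records:
        raise CatalogueError("backbone FASTA contains no records")
    rec = records[0]
    if interval is None:
        if motif_tsv is None:
            raise CatalogueError("backbone requires a motif interval (TSV or explicit)")
        table = read_motif_tsv(motif_tsv)
        if rec.id not in table:
            raise CatalogueError(f"no motif interval for backbone {rec.id!r}")
        interval = table[rec.id]
    seq = NucleotideSequence(str(rec.seq).upper(), Alphabet.DNA)
    return Backbone(rec.id, seq, interval)
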