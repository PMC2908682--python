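# mimdesign

Design and in-silico validation of **artificial miRNA target mimics** for
plants: IPS1-style decoy sites that bind a miRNA-loaded RISC but cannot be
sliced, so they sequester the complex and knock down the activity of a whole
miRNA family.

## The problem

Plant miRNAs act through near-perfect complementarity: RISC slices the
target opposite miRNA positions 10–11. A perfectly complementary "sponge"
site is therefore useless in plants — it is simply cleaved. The natural
non-coding transcript *IPS1* evades slicing with a three-nucleotide bulge on
the target strand exactly across the cleavage position, turning the site
into a stable, non-productive trap for RISC^miR399^. Artificial mimics copy
this trick for any miRNA family: take the reverse complement of the mature
miRNA, remove the partner of position 11, and insert a 3-nt bulge whose
sequence must *not* re-create a cleavable duplex.

`mimdesign` automates the desk work behind such a collection:

* **duplex model** — antiparallel miRNA:site alignment with G:U wobble and a
  single site-side loop; position-weighted penalties (mismatch 1, wobble
  0.5, bulged nt 1, all ×2 in the core region, miRNA positions 2–13);
  predicates `is_cleavable` (intact scissile bond at 10/11) and
  `is_capturing` (≥3-nt central bulge, WC/wobble seed pairing at 2–9,
  non-loop penalty ≤ 3).
* **mimic design** — builds the `L − 1 + 3`-nt motif (23 nt for a 21-nt
  miRNA), screens all 64 bulge 3-mers in fixed order and keeps the first one
  that is non-cleavable, capturing with the bulge at the intended interval,
  and homopolymer-safe.
* **family partitioning** — greedy set cover splits a family into the
  fewest subgroups such that one consensus mimic (wobble-aware covering
  bases) captures every subgroup member; mimics are named `MIM<family>`
  or `MIM<family><variants>` (e.g. `MIM169defg`).
* **specificity** — a capture matrix of every mimic against the whole
  catalogue, flagging off-target capture between near-identical families.
* **construct assembly** — motif replacement in a backbone plus
  overlap-extension mutagenesis primers (Wallace-rule Tm), with FASTA,
  GenBank-style and TSV outputs.
* **fixtures** — a seeded generator of synthetic catalogues and backbones
  with controlled family/subfamily structure, so everything is testable
  without downloads.

## Worked example

```python
from mimdesign import *

mir = MatureMiRNA.from_id(
    "xxx-miR500a", NucleotideSequence("UGAGCUCAUCAAGCAUUCGGC", Alphabet.RNA)
)
mimic = design_mimic_site(mir)
print(mimic.name, mimic.site, len(mimic.site))
aln = align_duplex(mir, mimic.site)
print(format_duplex_diagram(aln))
```

prints

```
MIM500a GCCGAATGCTAAAGATGAGCTCA 23
site  3'-ACTCGAGTAGAAA-TCGTAAGCCG-5'
         ||||||||||    ||||||||||
miRNA 5'-UGAGCUCAUC---AAGCAUUCGGC-3'
```

The 21-nt miRNA yields a 23-nt motif: ten Watson–Crick pairs on either side
of a central loop in which the three site nucleotides `AAA` (chosen by the
screen; here the lexicographically first admissible 3-mer) bulge out opposite
the unpaired miRNA position 11. Scoring this duplex gives total 6.0 (three
core-weighted bulge nucleotides), `is_cleavable` False and `is_capturing`
True — a functional mimic. The exact reverse complement of the same miRNA
instead scores 0.0 and classifies `CLEAVABLE`: a perfect site would simply
be sliced, which is why the bulge is required.

The same pipeline runs from the shell:

```sh
mimdesign fixtures --seed 1 --out fx
mimdesign design --mirnas fx/catalogue.fasta \
    --backbone fx/backbone.fasta --motif-tsv fx/backbone.tsv --out run
```

writing `mimics.fasta`, `partition.tsv`, `capture_matrix.tsv`,
`design_report.json`, `constructs.gb`, `primers.tsv` and a run summary.

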