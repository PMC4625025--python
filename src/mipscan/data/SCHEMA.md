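# Packaged data files

All tables are UTF-8 TSV with a header row; `-` encodes a missing value.
Gene/protein names keep the family's `RcXIP2;1`-style punctuation; slugify
(`RcXIP2-1`) when deriving file names.

## table1.tsv — gene models (37 castor-bean aquaporin loci)

| column | type | meaning |
|---|---|---|
| name | str | gene name |
| scaffold | str | scaffold identifier |
| strand | `+`/`-` | coding strand |
| gene_len | int | nucleotides from start to stop codon (introns included, UTRs excluded) |
| cds_len | int | coding-sequence length |
| intron_count | int | number of introns within the start-to-stop span |

Total intron length per gene is `gene_len - cds_len` by construction.

Note: the source census states that 8 scaffolds carry two aquaporin loci
and 21 carry one; tallying this table's scaffold column gives a different
split (6 scaffolds with two loci, 25 with one). The scaffolds are recorded
verbatim; the discrepancy is inherited from the source, not resolved here.

## table2.tsv — diagnostic-feature profiles (37 proteins)

Columns: `name`, `length_aa`, `mw_kda`, `pi`, `tm` (predicted transmembrane
helix count, pass-through), `loc_wolf_psort`, `loc_plant_mploc`
(subcellular-localization predictions, pass-through annotations), ar/R
selectivity filter residues `H2 H5 LE1 LE2`, NPA half-helix motifs
`NPA_LB NPA_LE` (3-letter), Froger positions `P1..P5`.

## table3_rules.tsv — substrate specificity-determining-position rules

One row per substrate (`NH3`, `boric acid`, `CO2`, `H2O2`, `silicic acid`,
`urea`); columns `SDP1..SDP9` hold slash-separated allowed residue sets,
e.g. `K/L/N/V`.

## table3_profiles.tsv — observed SDP residues per (protein, substrate)

Columns: `protein`, `substrate` (the rule section the row is evaluated
against), `SDP1..SDP9` single residues.

## template_synthetic.fasta + positions.yaml

A synthetic PIP-like reference backbone (290 aa, fixed pseudo-random
sequence with canonical PIP diagnostic residues planted) and its named
1-based diagnostic coordinates. Queries are anchored to this template by
global alignment; the synthetic family generator plants subfamily
signatures at the same coordinates. Both files can be overridden together
to use a real structural template.

## rules.yaml

Subfamily classification cascade and subgroup rules (see comments inside).
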