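# Methods

## Diagnostic-residue model

A MIP/aquaporin monomer is summarised by a *diagnostic profile*: the two
NPA half-helix motifs (loops LB and LE), the four ar/R selectivity-filter
residues (H2, H5, LE1, LE2), the five Froger positions (P1–P5), the nine
specificity-determining positions (SDP1–SDP9) and two conserved
phosphosites. Profiles come either from a curated feature table or from
raw sequences via template anchoring.

### Template anchoring

Each query is aligned to a reference template with a global
Needleman–Wunsch alignment: BLOSUM62 substitution scores, affine gaps
with open 10 and extend 0.5 (a gap of length *L* costs 10 + 0.5(*L*−1)),
end gaps penalised. Alignment is delegated to Biopython's
`PairwiseAligner`; the first optimal alignment it reports is used, which
makes the output a pure function of the inputs. Named 1-based template
coordinates are then mapped through the alignment; a template column
aligned to a gap yields a missing profile field, which is how truncated
proteins (e.g. one retaining only the first NPA motif) degrade
gracefully. Exhaustive enumeration of all global alignments on short
random sequences verifies the optimal score in the test suite.

The shipped template is **synthetic**: a 290-residue fixed pseudo-random
backbone carrying canonical PIP diagnostic residues, with curated
coordinates in `data/positions.yaml`. The published record gives no
numeric coordinates for the ar/R or SDP positions on a real structural
template, so the table is validated functionally — planted-truth recovery
on generated families and reproduction of the reference feature table —
rather than copied from a structure. Both files are overridable together
(`--template`/`--positions`) to anchor against a real reference such as a
structure-resolved PIP2;1.

One simplification is deliberate: the SDP literature defines a separate
set of nine positions per substrate panel. The profile carries a single
SDP1–SDP9 mapping; per-substrate observed residues are supported
separately as (protein, substrate) rows, which is how the packaged
reference table is stored and matched.

## Subfamily cascade

Classification is a deterministic ordered cascade over the profile
(configuration, not code: `data/rules.yaml`):

1. **PIP** iff ar/R = F-H-T-R;
2. **NIP** iff Froger P5 ∈ {I, L, M};
3. **XIP** iff P2 = C, or the LB motif starts with S, or it is NPV/NPI;
4. **TIP** iff P4 = Y and H2 ∈ {H, N};
5. **SIP** iff P4 = Y;
6. otherwise UNCLASSIFIED (also the result for an all-missing profile).

Rule order is part of the contract — PIPs and TIPs share the water-type
P4/P5 pattern and are separated by the filter test coming first; the NIP
P5 test must precede the XIP motif tests. Missing residues never satisfy
a predicate, so a truncated XIP retaining only H2 and an S-initial first
motif still classifies via rule 3. On the packaged 37-protein reference
family the cascade reproduces the published subfamily of every protein
(10/9/8/6/4). The cascade replaces reference-phylogeny classification so
that the call is testable without external proteomes; for cross-species
placement the package provides identity matrices and neighbor joining
instead.

Subgroups follow the ar/R nomenclatures where defined: NIP I (W-V-A-R or
W-A-A-R), NIP III (G-S-G-R), NIP II (NPS/NPV motifs or H2 ∈ {A, T},
checked after I and III); XIP1/2/3 (V-F-V-R / I-F-V-R / V-Y-A-R), matched
missing-tolerantly with the first compatible pattern winning — an
incomplete filter beginning with V therefore resolves to XIP1, matching
the published placement of the one truncated reference XIP. Numbered
subgroups inside PIP/TIP are phylogenetic, not residue-defined; they are
only emitted by nearest-reference identity voting (threshold 0.55
fractional identity, below it UNASSIGNED).

## Substrate prediction

The three evidence lines are reported independently, never merged:
NPA typing (CANONICAL/VARIANT per motif), the Froger GLP/AQP call
(aromatic = {F,W,Y}, acidic = {D,E}, basic = {K,R,H}; GLYCEROL_TYPE
requires all five positions GLP-like, WATER_TYPE none, otherwise MIXED;
missing positions give INCOMPLETE), and SDP matching. For SDP matching
the *novel-type candidate* threshold defaults to one deviating position
(configurable `--max-novel-deviations`), generalising the field's
practice of flagging single substitutions; missing positions are counted
separately and never create deviations. Widening an allowed set can never
worsen a match (tested as a property).

## Neighbor joining

Canonical Saitou–Nei agglomeration on 1 − fractional-identity distances.
Ties in the Q-criterion are broken by the lexicographically smallest id
pair (internal nodes inherit the smallest leaf id beneath them), making
the topology a pure function of the matrix. Negative limb lengths are
clamped to zero with the deficit moved to the sister branch, preserving
the pair's summed length. For additive matrices the method provably
recovers the generating topology; the tests verify this against a
brute-force enumeration of all unrooted 4- and 5-leaf topologies fitted
by non-negative least squares, and against an independent library
implementation.

## Protein properties

Molecular weight is the sum of average residue masses plus one water
(values in `genestats.RESIDUE_MASS`). The isoelectric point is the root
of the Henderson–Hasselbalch net-charge equation on pH 0–14, found by
bisection to 1e-4, using the EMBOSS pKa set (N-term 8.6, C-term 3.6,
K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1). Published pI tools
use different pKa tables; recomputed pI should be compared to tabulated
values only loosely (±0.3 is typical), so family statistics over the
reference fixture use the table's printed values, not recomputed ones.
Presentation rounding (pI means at two decimals) is half-up via decimal
arithmetic; full precision is kept internally.

## Gene-structure statistics

`gene_len` is the start-to-stop-codon span (introns included, UTRs
excluded), so the total intron length is `gene_len − cds_len` exactly and
the family-wide mean intron length is Σ(gene_len − cds_len) / Σ introns.
On the reference fixture this gives ≈386 bp; the published "about 380 bp"
average is reproduced only approximately because the source's averaging
convention (per-intron vs per-gene) is unstated. The source also quotes
an ORF range (627–830 bp) narrower than its own table's CDS column
(627–930 bp); the fixture keeps the table values.

## Expression

Read cleaning removes, in order: reads empty after adaptor trimming,
reads with an ambiguous-base fraction strictly above 10%, and reads with
strictly more than 50% of bases at Phred quality ≤ 5 (offset 33 by
default); each read is counted in exactly one category and input order is
preserved. RPKM is counts × 10⁹ / (library size × transcript length);
library size defaults to total clean reads per library (whether the
original analyses used clean or mapped totals is unstated, so it is a
parameter). Detection means RPKM strictly above a threshold, default 0.
Subfamily shares (the "dominant isoform" statistics) are computed on
RPKM, not raw counts. The log display matrix is log₁₀(RPKM + 1);
optional row ordering uses average-linkage hierarchical clustering on
Euclidean distances of the log values (the display convention most
heatmap figures use, stated here because it is a choice).

## Synthetic data

Generators exist so that every stage is testable with known ground truth
and no downloads; one integer seed drives an independent, documented
stream per artifact type, so regeneration is byte-identical and adding a
generator never perturbs existing fixtures.

*Families*: the template backbone with one subfamily signature planted at
the template coordinates (signatures taken from the canonical reference
filters, e.g. PIP = F-H-T-R + NPA/NPA + E-S-A-F-W) and uniform random
substitutions elsewhere at a configurable rate. Diagnostic columns and a
two-residue flank around each are never mutated: in real aquaporins these
positions sit inside structurally conserved motifs, and the conserved
context is what anchors them in an alignment. With the flank, planted
diagnostic residues are recovered at 100% for mutation rates up to 0.25
across thousands of generated sequences; the test suite asserts exact
recovery at rate 0.2 (50 proteins × 3 seeds). The generator makes no
attempt at membrane-protein residue composition or indel realism, so
passing these tests demonstrates correctness of the anchoring/extraction
machinery, not performance on diverged natural sequences.

*Gene models*: intron counts drawn from a subfamily-style architecture
mix (defaults mirroring the reference family: PIPs three introns, most
TIPs two, most NIPs four, intronless SIP/XIP members); intron lengths
log-normal (median ≈245 bp) clipped to the 46–3360 bp range observed in
the reference introns; spans are consistent by construction.

*Counts*: planted per-gene expression levels on the RPKM scale (so a
planted dominance share is directly the expected RPKM share), strict
tissue-specific zeroing, and negative-binomial sampling with dispersion
α (variance μ + αμ²); α = 0 gives deterministic rounded means, making
noise-free recovery tests exact.

## Problem sizes and defaults

Reference fixtures: 37 genes/proteins, 6 substrate rules, 59
per-substrate SDP rows. Property suites run on 50-protein synthetic
families (3 seeds, mutation rate 0.2), all 3 + 15 unrooted 4/5-leaf
topologies, and 300-read simulated FASTQ files; the whole suite and the
acceptance script each run in well under a minute on one CPU.

## Known limitations

* Subfamily rules were derived from the reference family's signatures;
  exotic families (GIP/HIP subfamilies of algae and mosses) are outside
  the rule set and will come back UNCLASSIFIED.
* The synthetic template is not a natural sequence; extracted profiles
  from real proteomes require supplying a real template and coordinate
  table.
* Transmembrane-helix counts and subcellular localisations are
  pass-through annotations, not predictions.
* Maximum-likelihood phylogenetics and bootstrap support are out of
  scope; neighbor joining is provided as classification support only.
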