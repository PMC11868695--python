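# Methods

This note documents the models, conventions and numerical choices behind
tetralink, and what the synthetic-data tests do and do not demonstrate.

## Homologue screen

Hits arrive as standard 12-column tabular protein-alignment output (one
query per gene family).  A hit survives iff `evalue < 1e-30` **and**
`pident >= 30`: the e-value cut is deliberately strict (`<`, not `<=`) and
the identity cut inclusive, and the test suite pins both operators with
boundary cases (e-value exactly 1e-30 is rejected; identity exactly 30.0 is
kept).  Surviving hits are reduced to one record per (family, scaffold,
protein) — lowest e-value, ties by bitscore then first occurrence — and
then to presence per unit, where a unit is a MAG or an
`unbinned:<scaffold>` singleton.  Tandem duplicates therefore never inflate
counts: all downstream statistics are presence- and scaffold-based.

`sw_identity` is a Smith–Waterman local aligner under simple
match/mismatch/linear-gap scoring.  It exists to validate synthetic protein
plants and is verified against exhaustive enumeration of all local
alignments for short strings; it is not a BLAST substitute (no substitution
matrix, no e-values).  When several alignments are co-optimal the identity
of one canonical traceback (diagonal > gap-in-b > gap-in-a) is reported;
when no positive-scoring alignment exists the identity is 0 by convention.

## Taxonomy resolution

Lineages are GTDB-style rank-prefixed strings over the seven canonical
ranks; bare NCBI-style name lists are accepted positionally (superkingdom
maps to domain).  A bin's classification is the deepest lineage whose
hierarchically accumulated weight strictly exceeds `f x total` (default
`f = 0.5`); support is hierarchical, i.e. a scaffold classified to a phylum
also supports that phylum's domain, so mixed bins degrade gracefully to a
shallower rank instead of failing.  At `f >= 0.5` the winner at every rank
is unique; the 0.5/0.5 tie resolves to the parent rank by the
strictly-greater rule.  Weights default to scaffold lengths (scaffold
counts are available); real bin annotation tools vote with per-ORF
alignment bit-scores, which are not present in lineage tables, so
length-weighted votes are an approximation and may diverge from a bit-score
vote on heterogeneous bins.  Hit-bearing scaffolds take their bin's lineage
when binned, their own otherwise, and are reported as fully unclassified —
never dropped — when absent from both tables.

## Depth normalization and aggregation

A depth record carries the average depth (mapped reads per base pair) of
one scaffold under one sample's mapping plus that mapping's total mapped
reads.  Normalized depth is `avg_depth * scale / mapping_total_reads` with
`scale = 1e8`, making samples of different sequencing effort comparable.
"Total mapped reads" is interpreted per mapping (mapping sample x
assembly), which is what a depth summarizer reports; whether those totals
count all alignments or primary alignments only is an upstream decision the
table simply carries.

Aggregation over the hit-bearing scaffolds of one (taxon, family) uses the
own-sample rule: sample *s* receives only records with
`assembly_sample == mapping_sample == s`.  Reads from one sample can map
onto similar strains assembled in other samples; the naive all-mappings sum
counts such reads once per assembly and systematically inflates taxa
present in many samples.  The naive sum is still computed for comparison,
and `own <= naive` holds record-wise by construction.  Samples with no
qualifying scaffold appear as explicit zeros so profiles are plottable
against the full depth series; scaffolds unclassified at the reporting rank
are pooled under `unclassified`, preserving the invariant that per-taxon
profiles sum to the pooled all-scaffold profile.

## Attribution

The MAG-fraction matrix reports, per (taxon, sample), how many MAGs exist
and how many carry a family; a high fraction over many MAGs is evidence of
a real clade-level capability rather than a spuriously binned gene.  MAGs
are grouped by the sample they were binned from.  Gene co-occurrence
counts, per taxon, MAGs carrying both or exactly one of a family pair
(e.g. the chain-coupling synthase plus the ether-forming reductase needed
for a complete branched-tetraether pathway).

Lipid-vs-gene profile agreement uses Spearman rank correlation with average
ranks for ties, computed on the shared samples (at least three required).
Rank correlation was chosen because depth profiles are non-Gaussian and the
scientific claims are ordinal (where the maxima lie); the numeric ρ is a
package convention for ranking candidates, not a significance statement —
no null model is attached.  Taxa with all-zero gene profiles are excluded
from rankings, ties break alphabetically.

## Lipid mass arithmetic and quantification

Monoisotopic masses use IUPAC atomic masses (C 12.000000, H 1.0078250,
N 14.0030740, O 15.9949146, Na 22.9897693); adduct masses are fixed
constants (M+H 1.00728, M+NH4 18.03383, M+Na 22.98922).  The proton
constant already carries the electron-mass deficit, so no separate electron
correction is applied — consistent with the 4–5 significant figures the
identifications need.  Nominal masses round half away from zero, pinned by
the brGDGT-1a/brGMGT-1a pair (1022.0097 → 1022; 1019.9940 → 1020).

Homologue-series steps are compositional deltas — methylation +CH2
(+14.01565 Da), cyclopentane ring −H2, GMGT bridge −H2 (−2.01565 Da each) —
and commute.  Species ship in a YAML registry (name, series class, formula
or parent + steps, declared nominal [M+H]+ m/z); `verify_registry` flags
any species whose computed rounded m/z conflicts with its declared nominal
mass.  Retention-time behaviour is registry metadata only; no peak picking
is performed.

Quantification sums the peak areas of whichever adducts are present,
divides by the internal-standard area of the sample (cancelling
multiplicative matrix effects and instrument drift, assuming an
analyte/standard response factor of 1, since no factor is published) and by
the litres of water filtered (defaulting to 1 when volumes are unknown, in
which case values are response units rather than response units per litre).
Relative abundances divide by the per-sample sum over the reported lipid
set; all-zero samples are NaN (undefined), never 0/0.

## Genome selection and supermatrix

The representative score is `completeness - 5 x contamination` (percent
units).  Dereplication collapses the usual two-stage (coarse sketch, then
ANI) clustering to one greedy pass over a user-supplied ANI matrix at the
secondary threshold (0.99): MAGs under 50 % completeness are removed,
the rest are visited in decreasing score order (ties by id) and join the
first cluster whose representative they match, so representatives are
always cluster-maximal and runs are deterministic.  The primary threshold
(0.90) is retained as a pre-filter option only — ANI computation itself is
out of scope.  Markers are included iff present in exactly one copy;
trimmed sequences with strictly more than 60 % gaps are dropped (60/100 is
kept, 61/100 dropped); concatenation gap-fills absent families and emits
0-based half-open partitions.  The marker family list is user input.

## Synthetic study generator

The generator emulates the data model of a 15-depth water-column survey
(default labels 50–2000 m).  Per genome: a phylum from the pool
(round-robin), presence over a contiguous run of samples grown from a
random anchor with probability `sharing_prob = 0.5` per adjacent sample
(so strains shared across samples exist and cross-sample mappings occur),
and a lognormal(0, 1) abundance per sample, normalized to relative
abundance.  Default community: 24 genomes, 10 scaffolds of 20 kb each,
1e6 reads per sample.  Per (scaffold, mapping sample) read counts are
Poisson around `reads x rel_abundance / scaffolds_per_genome`, converted
to reads/bp; cross-sample mappings use the same Poisson model as
own-sample ones, deliberately reproducing the double-counting artefact the
own-sample rule corrects.  Mapping totals are the summed draws, so depth x
length sums to the mapping total exactly.

Binning keeps a `bin_completeness = 0.9` fraction of each genome's
scaffolds per sample (whole genomes are left unbinned with probability
`unbinned_frac = 0.1`); contaminant scaffolds are drawn binomially at rate
`bin_contamination` (default 0) from the completeness-dropped scaffolds of
other-phylum genomes in the same sample, so bins stay disjoint and every
contaminant is cross-phylum by construction.  Gene plants put one
above-threshold hit on every scaffold of every producer genome; decoys at
both threshold boundaries (e-value exactly 1e-30; identity 29.99) are
added per family and assembly so that exactly the plants survive a correct
screen.  Lipid peaks split an abundance-proportional signal over three
adducts, scale analyte and standard by a per-sample lognormal(0, 0.3)
matrix factor that cancels under normalization, and carry a configurable
litres value (default 1, since filtered volumes are site-specific).

What passing synthetic tests shows: the bookkeeping — thresholds,
deduplication, own-sample aggregation, majority votes, fractions,
rankings — is implemented correctly and recovers planted truth, and
mis-attribution grows with the planted contamination rate.  What it does
not show: robustness to real-data phenomena the generator omits — chimeric
scaffolds, assembly fragmentation correlated with abundance, homologues at
intermediate identity, compositional biases of real read mappers, shared
genes across phyla, or response-factor differences between lipids.

## Problem sizes and determinism

Test and demo runs use scaled-down communities (5–6 samples, 6–12 genomes,
4–6 scaffolds per genome) chosen so the full suite exercises hundreds of
synthetic studies; parameter-recovery checks run 20 seeds and the
contamination trend 30 seeds per rate over rates {0, 0.05, 0.1}.  All
randomness flows from a single named generator per bundle (a fixed seed
yields byte-identical outputs); the lipid-peak generator derives an
independent stream from the same seed so peak tables do not depend on call
order.  Spearman values come from scipy; profile and table writers emit
`repr` floats so round-trips are exact.
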