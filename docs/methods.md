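# Methods

`polydonor` identifies the two diploid genome donors of an allotetraploid
(amphidiploid) species from co-dominant SSR genotypes scored as fragment
sizes in bp. This note documents the statistical machinery, the defaults
and the design choices, in the order the pipeline applies them.

## Data model

A genotype table holds, per accession x marker, the list of discrete PCR
products (integer bp, optionally with peak heights in RFU). Zero products
is missing data (never imputed); one product is the norm for a highly
selfing diploid; two products in a diploid is a heterozygote; two products
in a tetraploid are the two homoeologous loci amplified by one primer pair.
Sizes are rounded to integer bp on ingest; an optional binning tolerance
(default 0) merges sizes within +/- tolerance to the modal size per marker,
because fragment-analysis sizes are near-integer but instrument panels
occasionally split one allele across adjacent integers.

Two scoring conventions coexist in this kind of data and both are
supported through an explicit `copies_per_call` parameter. With
`copies_per_call=1` (the default) each call contributes one gene copy —
the strongest peak when heights exist, else the smallest size — matching
single-allele scoring of predominantly selfing material. With
`copies_per_call=2` both alleles count and a single-size call is coded as
a homozygote. Observed heterozygosity is only informative under two-allele
coding; under single-allele scoring it is structurally 0, which is also
the only possible value for tetraploid sub-genome slots (one product per
sub-genome per accession).

## Marker selection

Markers are assigned to exactly one quality category with a fixed
precedence: not amplified > amplified in only some accessions > product
above the size cap (default 500 bp) > multiple products (more than two
anywhere, or more than one distinct product in a diploid) > monomorphic >
single product in at least one tetraploid > two products in every
tetraploid (the donor-analysis pass category). The precedence makes the
classifier total and deterministic for pathological markers. Tables
without tetraploid accessions cannot populate the last two categories; a
polymorphic diploid-only marker is reported under a dedicated
`POLYMORPHIC_DIPLOID` category so the classifier stays total. When
`copies_per_call=1` the pipeline classifies the scored (single-allele)
view, so residual diploid heterozygotes are not mistaken for multi-product
amplification artifacts.

## Sub-genome partition

For each selected marker, the allele sizes observed in a diploid
reference-anchor taxon define the reference pool. Each tetraploid call
with two discrete products assigns the product with the smaller minimum
|Delta bp| to the pool to sub-genome A and the other to B. "Near the
anchor" is operationalised as nearest-neighbour distance because size is
the only information that survives genotyping. Exact distance ties are
flagged (`TIED`, never silent) and resolved to the smaller size in slot A.
Single-product calls fill both slots and are excluded from frequency
computations by default (they may be homoeolog homozygosity or allele
dropout; a switch includes them). Calls at markers with no reference data
are flagged `NO_REFERENCE` and excluded downstream; unsupervised
2-clustering of such loci is deliberately out of scope because the method
is anchor-based. Calls with more than two discrete products are recorded
as missing — such markers fail selection and should not reach this stage.

Genome groups are then one per diploid taxon and two (A, B) per tetraploid
taxon; with the study-shaped taxon set (six diploid taxa, one tetraploid
species sampled as two varieties) this yields 10 groups. Optional
accession labels (e.g. sub-taxa of a species complex, taken from prior
work or ordination inspection — never inferred here) split labelled taxa
further, e.g. into a 12-group layout.

## Diversity statistics

Per group and locus, with p_i the allele frequencies:

- gene diversity H = 1 - sum p_i^2 (optional n/(n-1) small-sample
  correction, off by default);
- PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2 (Botstein convention);
- observed heterozygosity = fraction of non-missing two-allele calls with
  distinct sizes;
- allelic richness A_g = sum_i [1 - C(N - N_i, g) / C(N, g)], the expected
  number of distinct alleles in g gene copies drawn without replacement
  (hypergeometric rarefaction), computed with exact integer binomials.

The rarefaction size g defaults, per locus, to the smallest per-group copy
count among groups with data — the only choice that makes per-group
columns comparable. Loci monomorphic within a group contribute H = PIC = 0
to the group means; loci with no data in a group are excluded. A group's
allele count is the number of distinct (marker, size) pairs it shows; the
overall row pools gene copies across groups before recomputing, so the
pooled allele count is a union, not a sum.

## Distances, trees, ordination

The distance is Nei's DA: for entities x, y with spectra over r shared
loci, DA = 1 - (1/r) sum_loci sum_alleles sqrt(x_i y_i). Each pair is
averaged over its own shared loci (r reported per pair; a pair sharing no
typed locus is an error by default, or DA = 1 on request). At the
individual level an accession is a population of one (heterozygote = two
alleles at 0.5); each tetraploid accession enters as two pseudo-individuals
carrying its A and B slots, so a study-shaped table of 268 accessions with
58 tetraploids yields 326 tips. The within-group diagonal of the group
matrix report is the mean pairwise individual-level DA among members.

Trees are standard neighbor joining (Q criterion, Studier–Keppler
updates). Ties in Q are broken by the lexicographically smallest label
pair, a cluster being labelled by its smallest leaf label, so output is
deterministic and invariant to input order. Negative branch lengths are
clamped to zero by default (display convention; topology unaffected).
Branch support is a locus bootstrap — loci resampled with replacement,
DA and NJ recomputed per replicate, support = percent of replicates
containing the bipartition — defaulting to 1000 replicates for the
individual tree and 400 for the group tree. Replicates are reduced to
weighted averages of precomputed per-locus sqrt-frequency inner products,
and replicate trees run in single precision on a compacting distance
buffer, which keeps the study-scale run (326 tips x 1000 replicates)
around 1–2 minutes on one CPU. Loci are used in sorted order, so supports
are invariant to input locus ordering and reproducible per seed. Trees
serialise to Newick with supports as internal-node labels.

PCoA Gower-centres -D^2/2 and eigendecomposes. DA matrices are generally
non-Euclidean; negative eigenvalues are reported but excluded from the
percent-variance denominator (plain positive-eigenvalue ratios, no
Cailliez/Lingoes correction by default — a Cailliez flag exists). Axis
signs are fixed by making each axis's largest-magnitude coordinate
positive.

## Donor report

For each tetraploid sub-genome group the diploid groups are ranked by DA;
the call is the nearest group, with the margin to the runner-up, and an
exact tie yields no call with both candidates listed. Because the anchor
taxon is itself a donor candidate, the report also prints each ranking
with the anchor's group(s) excluded, surfacing any anchor-induced
circularity quantitatively.

## SSR mining

The miner detects di-/tri-/tetra-nucleotide repeats of >= 15 nt. A perfect
hit is a maximal exact tandem run; an imperfect hit is a maximal
same-phase window within Hamming distance <= 2 (configurable) of a perfect
array of its motif — a deterministic, oracle-checkable reading of
"allowing one or two base mismatches", since pattern-matching tools leave
the array definition ambiguous. Runs whose unit is a repetition of a
shorter unit (e.g. ATAT) are suppressed to avoid double counting;
homopolymers are therefore never reported. Motifs are canonicalised to the
lexicographically smallest cyclic rotation of the motif or its reverse
complement (family AG covers GA/TC/CT, etc.). Overlapping windows of one
family keep the single best hit (longest, then fewest mismatches, then
leftmost); two windows count as overlapping when they share at least one
full repeat unit, which lets phase-shifted exact runs that abut over a
partial unit coexist — necessary for the zero-mismatch search to be
hit-for-hit identical to the perfect-run finder. Coordinates are 0-based
half-open; sequences are uppercased; non-ACGT characters break runs.
Density is reported as total bases per hit. Primer design is out of scope
beyond a 90–300 bp amplicon-size filter.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes, with
full ground truth. Defaults: 38 loci; six diploid taxa of 13/47/49/13/42/46
accessions; one amphidiploid sampled as a cultivated (7) and a wild (51)
variety; sub-genome A donated by the anchor-taxon analogue and B by a
second diploid.

Per locus, a repeat unit (2/3/4 nt, weighted 8.2/83.5/8.3% like EST-SSR
class tallies) and a base size (100–280 bp) are drawn; each diploid taxon
receives an allele pool of 5 sizes on the unit grid around a taxon center.
Centers sit on a ladder of 2-unit steps with a per-locus random assignment
of taxa to rungs, so neighbouring taxa share alleles and distant ones do
not — pool medians are always separated by at least one repeat unit. A
`disjoint_pools` switch widens the ladder to 10-unit steps, making every
taxon's attainable size range disjoint; in that regime nearest-neighbour
partition is provably exact, giving a clean benchmark, while the default
overlapping regime exercises realistic ambiguity (ties, single-product
calls, ~5% mis-assignment).

Each diploid taxon evolves as a Wright–Fisher population (census 50 by
default, decoupled from the sample size so small samples are not
drift-starved) for 30 generations with selfing rate 0.98 and stepwise
mutation (+/- one repeat unit at rate 1e-3 per allele per generation,
reflecting at the pool bounds). Founder genotypes draw from
Dirichlet(0.8)-weighted pools. These values were calibrated once so that
realised diploid gene diversity averages in the 0.30–0.50 band and
observed heterozygosity stays near the (1-s)/(2-s)-scale residual of a
strong selfer — the regime the analysis is designed for.

The amphidiploid arises from a single hybridisation (monophyletic origin
by default; `n_founders` raises it): one gamete from a random donor-A
individual and one from donor-B, doubled, so the founder is homozygous in
both sub-genomes. The combined population drifts 40 generations with
disomic inheritance (sub-genomes segregate independently inside shared
individuals), then each variety drifts 15 more at its own census size.
Sub-genome mutation rates default to 5e-4 (A) and 2e-3 (B); the faster B
clock reproduces, directionally, a higher realised diversity on B than A.
Emission scores one product per sub-genome (the strongest-peak analogue);
coincident A/B sizes yield single-product calls, as in real data.

What the generator does not emulate: null alleles and allele dropout,
stutter artifacts, size homoplasy across taxa beyond pool overlap,
population structure within taxa, migration, selection, and polysomic
inheritance. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability under the stated model, not
robustness to these artifacts.

## Numerical choices

- NJ Q-matrices are symmetrised with an elementwise min before the argmin
  so float summation order cannot hide a tie; exact ties fall back to the
  label rule.
- DA values are clipped to [0, 1] against rounding drift; matrices are
  symmetrised by averaging.
- Rarefaction uses exact integer binomial coefficients (no log-gamma
  approximation), so oracle tests can demand 1e-12 agreement.
- PCoA treats eigenvalues below a relative 1e-10 as zero.
- Bootstrap replicates that leave a pair with no shared loci set that pair
  to DA = 1 rather than aborting the replicate.
- Problem sizes in the test suite: oracle equivalence runs on sequences up
  to 2 kb, exhaustive rarefaction up to N = 12 copies, exhaustive topology
  search up to 7 taxa, additive recovery up to 12 leaves; recovery checks
  use 20 study-shaped simulations. These sizes make brute-force oracles
  exact while keeping the default suite a few minutes long.

## Known limitations

- The anchor-based partition cannot separate sub-genomes at loci where the
  donors' pools coincide; such calls surface as ties or mis-assignments
  and are quantified, not hidden.
- Group-level DA treats the partition as error-free; partition errors
  propagate into both sub-genome spectra.
- PIC and gene diversity are reported under the scoring convention chosen
  by `copies_per_call`; with single-allele scoring of heterozygous
  material both are biased by the peak-picking rule.
- The miner's imperfect-repeat definition is one of several defensible
  readings of mismatch-tolerant SSR searches; counts are comparable within
  this package, not across tools.
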