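# Methods

## Problem setting

A single low-recombination locus is sequenced in a focal species (n ≈ 37
haploid/hemizygous sequences), a sister species (n ≈ 20) and an outgroup
lineage. The focal sample splits into two haplogroups at intermediate
frequency, tagged by diagnostic indels and SNPs in complete linkage
disequilibrium. One haplogroup has a lower net divergence (Da) to the
sister species and is therefore suspected of being introgressed. The
package decides between that hypothesis and a within-species spread of a
single progenitor haplotype.

## Statistics and conventions

**Site policy.** The default is complete deletion: any column containing a
gap or `N` anywhere in the analysis set is excluded globally, so every pair
is compared over the same columns. Pairwise deletion is available for
distance matrices and the LD scan (where sequences are dropped per site
pair). `N` is missing data everywhere; coordinates are 1-based inclusive
alignment columns.

**π, Dxy, Da.** All are uncorrected p-distances (no substitution-model
correction). Within a two-group comparison, π of each group, Dxy and Da
are computed on the *shared* complete-deletion column set, which makes
`da = dxy − (πX + πY)/2` an exact construction identity, verified to
machine precision in the tests. π of a singleton group is defined as 0.
Note that Dxy is the mean over all nX·nY cross pairs: for literally
duplicated polymorphic samples this includes zero-distance self-pairs, so
`dxy = (1 − 1/n)·π` and `da = −π/n` is negative, not zero; the da = 0
identity holds for identical *populations* (in expectation), and exactly
only for monomorphic groups.

**Site classification.** A variable column is `fixed` when the two groups'
allele sets are disjoint, `shared` when both groups are polymorphic and the
sets overlap, otherwise `private` to the polymorphic group. The three
labels partition the variable columns. Indel events enter as single
pseudo-sites only when indel coding is enabled (below).

**Indel policy.** Diagnostic indels are *excluded* by default: the
haplogroups are defined by them, so counting them toward divergence would
be circular. The alternative `coded_as_snps` policy replaces each marker
span with one biallelic pseudo-column (gap-run present → `T`, absent →
`A`, partial → `N`), counting each indel event as exactly one site.

**Tajima's D.** Standard constants (a1, a2, b1, b2, c1, c2, e1, e2); S and
the mean pairwise difference count k̂ are taken over the same
complete-deletion column set, with multi-allelic columns counting once
toward S. Requires n ≥ 4 and S ≥ 1. The implementation is cross-checked
against an independent reference implementation and a hand-derived n = 4
case (D ≈ +0.5916).

**Fisher's exact test.** Two-tailed by the point-probability rule (sum of
hypergeometric probabilities ≤ the observed table's, with relative
tolerance 1e-7 for float ties), delegated to scipy and verified in the
tests against full enumeration for every table with N ≤ 40. All four
margins must be positive. One published analysis of the fixed/shared
contingency at this kind of locus prints p = 0.019 for the table
[[1, 9], [10, 2]]; exact enumeration gives 1232/646646 ≈ 0.0019. The
package implements the exact definition and makes no attempt to match the
printed value.

**LD scan.** Sites are reduced to their two most frequent alleles (count
ties broken alphabetically); sequences missing or carrying a dropped third
allele at either site of a pair are excluded for that pair only. Tiers use
strict thresholds — `p<0.05`, `p<0.005`, `p<0.0005` — so p = 0.05 exactly
is not significant; no multiple-testing correction (the tiers display raw
p-values, as in the original figure style).

**Haplogroup classification.** Trait discovery starts from a seed indel
marker and collects every SNP column and gap-run marker whose alleles are
perfectly concordant with it over sequences non-missing at both traits
(complete LD required; one discordant sequence excludes the site). A
sequence is psA only if *all* its non-missing diagnostic traits carry the
psA allele (with at least one non-missing trait); any mismatch makes it
psB; all-missing is unclassified. Partial gap runs inside a marker span
are ambiguous and score missing, since indels are genotyped physically as
presence/absence.

**Bootstrap.** The observed distance matrix is fixed; individuals are
resampled with replacement independently within each group at the original
sizes (realised as multinomial count draws, which is distribution-
identical and allows the replicate means to be computed as count-weighted
matrix averages). Each replicate compares the mean cross-individual
distance of the two focal haplogroups against one haplogroup vs the
sister; the reported p is the fraction of replicates where the within-pair
mean is ≥ the between-pair mean. Ties use exact ≥ on the rational
p-distances. The number is descriptive, not a calibrated test: sequences
sharing a recent coalescent event are pseudoreplicated, which is why the
verdict never gates on it.

**In-silico expansion.** Each haplotype of the candidate group is cloned
into an artificial haplogroup of size equal to the source group and
re-compared to the sister. Clone groups are monomorphic, so
`dxy − da = π(sister)/2` identically and da/dxy/fixed/shared are invariant
to copy number; the combined-sample Tajima's D (clones + source group) is
the only copy-sensitive quantity. Empirically the *mean* combined D is not
monotone in copies — large clone fractions collapse k̂ through the excess
of identical pairs — but at a balanced mixture at least one expansion per
dataset drives combined D strongly positive, which is the signature the
experiment looks for.

**Polarization.** The outgroup allele is the strict-majority consensus of
the outgroup sequences (tie or all-missing → unpolarized). At a fixed
X–Y difference, an outgroup allele inside exactly one group's allele set
marks the *other* group as derived; a third allele is unpolarized. Counts
conserve: derived_in_X + derived_in_Y + unpolarized = n_fixed.

## Adjudication

The candidate (introgression-suspect) haplogroup is the one with the lower
Da to the sister — the relative-divergence signal that raises the suspicion
in the first place. Six directional predictions are scored with strict
inequalities (ties unsupported):

| id | prediction | follows from |
|----|-----------|--------------|
| I1 | Dxy(cand, sister) < Dxy(other, sister) | introgression |
| I2 | π(cand) < π(sister) | introgression |
| I3 | π(cand) < π(other) | introgression |
| I4 | mean in-silico Da < Da(cand, sister) | introgression |
| W1 | Dxy(cand, other) < both cross-species Dxy | within-species spread |
| W2 | all fixed other–sister differences derived in other | within-species spread |

The verdict is hierarchical rather than unanimous:
`within-species-consistent` iff W1 ∧ W2; `introgression-consistent` iff
I1 ∧ I2 ∧ I3 ∧ ¬W1; otherwise `mixed/inconclusive`. The design reasons:

* W1 is decisive in principle — a haplogroup that truly entered from the
  sister species cannot be closer in absolute divergence to its
  conspecific alternative than to its source population — and W2 confirms
  the divergent haplogroup's differences arose on the focal lineage.
* I1 and I2 compare quantities whose direction depends on *which*
  haplotype happened to spread and on the relative diversities of the two
  species; under a genuine within-species spread they fall on either side
  roughly at random, so requiring them to be unsupported would misclassify
  many true within-species datasets.
* I4 is structurally conservative: the mean expanded Da equals
  Da(cand, sister) + π(cand)/2 *identically* (an immediate consequence of
  the clone-group offset identity), so it can only support introgression
  when the candidate is internally monomorphic. It is computed and
  reported (mean and median) but does not gate the verdict.
* W2 is computed in both directions but gates only the within-species
  side: introgression makes no prediction about the polarity of the other
  group's fixed differences.

All six rows, their observed values, and the bootstrap annotations appear
in the report regardless of the verdict.

## Synthetic-data generator

The generator produces the statistical structure the analysis assumes, not
a demographically realistic history. Defaults are the study conditions:
37 focal + 20 sister + 1 outgroup sequences, L = 900 bp, per-locus θ = 5
within each species, focal–sister divergence t_split = 0.02 and outgroup
divergence t_outgroup = 0.05 substitutions/site, post-event haplotype
frequency f = 24/37, two 15-bp indel markers (columns 151–165, 451–465)
plus 7 diagnostic SNPs (columns 120…800), and ε = 0.1 expected private
mutations per spread copy.

Model choices worth knowing:

* **Independent coalescents per species, no recombination, no shared
  ancestral polymorphism.** Within-species variation is a Kingman
  coalescent with mutations at rate θ/2 per lineage per coalescent time
  unit (a random pair differs at θ sites in expectation).
* **Global infinite sites.** Every mutation — species-branch substitution,
  coalescent mutation, post-event private mutation — takes a fresh column
  from one registry (marker columns reserved up front). Every variable
  column is biallelic and polarization is exact; this removes homoplasy
  that would otherwise blur the polarization signatures at this mutation
  load (~1 expected double-hit per dataset otherwise).
* **Interspecies divergence on the focal branch.** All t_split
  substitutions are placed on the focal terminal branch; the sister
  retains ancestral states, and the outgroup diverges on its own branch.
  This emulates the polarization structure of the kind of locus the
  analysis targets, where essentially every fixed interspecies difference
  proves derived within the focal species. A symmetric allocation would
  instead produce a large class of fixed differences derived in the
  sister, a pattern the real system does not show.
* **Scenario transforms.** `sweep` copies one focal haplotype over
  round(f·n_focal) = 24 sample slots; `introgression` copies one sister
  haplotype; both add Poisson(ε) private mutations per copy and inject the
  markers (two gap runs + 7 derived SNPs, in complete LD) on the copies;
  `neutral` applies no transform and injects no markers.

What passing tests on this generator do **not** show about real data: the
generator has no shared ancestral polymorphism, so real sister-species
pairs with heavy incomplete lineage sorting will show more shared
polymorphism and fewer, less cleanly polarized fixed differences than the
synthetic scenarios; there is no recombination, so partial LD decay across
the locus is absent; and diversity is homogeneous along the sequence.

## Measured behaviour at the defaults

Over 100 seeded replicates per scenario (recomputed by
`scripts/acceptance.py`): sweep datasets are adjudicated
within-species-consistent and introgression datasets
introgression-consistent at or near 100%; the fraction of swept-vs-sister
fixed differences polarized as derived in the swept group is ~1.0. The
focal-sample Tajima's D under a sweep is positive in expectation
(mean ≈ +0.2) but only in ~60% of individual replicates: the clone group
contributes ~9 intermediate-frequency sites while the 13 surviving
ancestral lineages contribute a full low-frequency spectrum, so the sign
straddles zero replicate-to-replicate. A per-replicate positive-sign rate
of 80% is not reached at these conditions; the corresponding acceptance
test is left failing rather than weakening the generator conditions or the
assertion.

## Problem sizes and determinism

Default analyses run in well under a second per dataset; the scenario
studies use 100 replicates per scenario and the bootstrap 10⁶ replicates
(multinomial-matmul formulation, a few seconds). Every stochastic stage
takes an explicit integer seed; a fixed config + seed reproduces all
outputs byte-identically, including the 10⁶-replicate bootstrap count.

## Known limitations

* The microinversion-mask coordinates and the seed indel marker must be
  supplied by the user; the pipeline refuses to guess region coordinates.
* `divergence_summary` supports complete deletion only; pairwise deletion
  is available for distance matrices and the LD scan.
* The bootstrap reproduces the published resampling idea
  (individual-level resampling of a fixed distance matrix); it is reported
  as descriptive, with its pseudoreplication caveat, never as a test.
* The verdict vocabulary deliberately does not distinguish among
  within-species mechanisms (sweep in progress, balanced polymorphism,
  bottleneck-and-gene-flow); the data pattern cannot separate them.
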