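# haplospread

**Is that haplotype introgressed, or did it just spread?** When one of two
intermediate-frequency haplogroups within a species looks closer to a sister
species by *relative* divergence (F_ST-style measures, Nei's D_a), it is
tempting to call introgression. But a recent within-species spread of a
single haplotype — a sweep in progress, a new balanced polymorphism —
produces exactly the same relative-divergence signal, because it drains
diversity from one haplogroup and thereby inflates its D_a to the sister
species. `haplospread` implements the locus-scale analysis that separates
the two explanations using *absolute* divergence and outgroup polarization,
plus a seeded synthetic-data generator so the whole pipeline is testable
without any sequence downloads.

It is aimed at population geneticists working with small multi-species
alignment panels (tens of sequences, a few hundred bp — e.g. Sanger-era
locus surveys) rather than genome-wide scans.

## The statistics

For groups X and Y of aligned haploid sequences (complete deletion of
gapped/ambiguous columns; uncorrected p-distances):

- **π** — nucleotide diversity, the mean pairwise per-site difference within
  a group;
- **D_xy** — absolute divergence, the mean per-site difference over all
  n_X·n_Y cross-group pairs (Nei 1987, eq. 10.20);
- **D_a = D_xy − (π_X + π_Y)/2** — net (relative) divergence (eq. 10.21);
- **fixed / shared / private sites** — per-column classification of variable
  sites by allele-set overlap between the groups;
- **Tajima's D** — intermediate-frequency excess within a sample;
- pairwise **Fisher-exact LD scan** with figure-style significance tiers.

The adjudication logic: a haplogroup that truly entered from the sister
species must be closer to the sister than to its conspecific alternative in
**D_xy**; a haplogroup that spread within the species keeps both haplogroups
mutually closest, and its fixed differences from the sister polarize as
*derived* against an outgroup. Six directional predictions (I1–I4 for
introgression of the low-D_a "candidate" haplogroup, W1–W2 for
within-species spread) are scored from the computed statistics, and the
verdict is `within-species-consistent`, `introgression-consistent`, or
`mixed/inconclusive`.

Supporting machinery includes the in-silico expansion experiment (clone each
candidate haplotype into an artificial monomorphic haplogroup and recompute
D_a / fixed counts against the sister; D_xy − D_a = π_sister/2 identically
for such clones) and a 10⁶-replicate bootstrap of the pairwise-distance
matrix comparing within- vs between-group mean divergence.

## Worked example

Simulate a within-species sweep (37 focal + 20 sister + 1 outgroup
sequences, 900 bp, two 15-bp indel markers and 7 diagnostic SNPs injected on
the spread lineage), split the FASTA by species, and adjudicate:

```sh
haplospread simulate --scenario sweep --seed 11 --out-prefix demo
haplospread adjudicate --focal demo_focal.fasta --sister demo_sister.fasta \
    --outgroup demo_outgroup.fasta --seed-marker 151:165
```

```
Candidate (introgression-suspect) haplogroup: psB
Alternative haplogroup: psA

id  support  description
I1  YES      Dxy(psB, sister) is less than Dxy(psA, sister)
    observed: dxy_cand_sister=0.0408, dxy_other_sister=0.0503
I2  NO       pi(psB) is less than pi(sister)
    observed: pi_cand=0.0121, pi_sister=0.0062
I3  NO       pi(psB) is less than pi(psA)
    observed: pi_cand=0.0121, pi_other=0.0002
I4  NO       mean Da of in-silico expanded haplotypes vs sister is less than Da(psB, sister)
    observed: mean_insilico_da=0.0377, median_insilico_da=0.0391, da_cand_sister=0.0316
W1  YES      Dxy(psB, psA) is less than both cross-species Dxy values
    observed: dxy_cand_other=0.0184, dxy_cand_sister=0.0408, dxy_other_sister=0.0503
W2  YES      all fixed differences between psA and sister are derived in psA
    observed: n_fixed=39, derived_in_other=39, derived_in_sister=0, unpolarized=0

Verdict: within-species-consistent
```

Reading it: the diverse haplogroup (psB here, π = 0.0121) has the lower D_a
to the sister and so is the introgression suspect, and it even has the lower
D_xy (I1 YES — the relative-divergence mirage at full strength). But the two
haplogroups are mutually closest in absolute divergence (W1: 0.0184 vs
0.0408/0.0503) and every one of the 39 fixed differences between the
near-monomorphic haplogroup and the sister species is derived (W2), so the
pattern is adjudicated as a within-species spread — which is exactly how the
dataset was generated.

The same engine runs on real data: `haplospread run --config cfg.yaml
--outdir out/` takes per-species FASTA files, an optional region mask (e.g.
a microinversion to drop before diversity calculations), and a seed indel
marker from which the full diagnostic trait set is discovered; it writes the
haplogroup partition, a summary table, expansion and polarization tables,
bootstrap results and the adjudication report. Subcommands `classify`,
`stats`, `ld`, `bootstrap`, `expand`, and `polarize` expose the individual
stages.

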