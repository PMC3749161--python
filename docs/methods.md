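# Methods

This note records the models, parameter choices and numerical conventions
behind `rrlmarkers`, and what the synthetic data can and cannot establish.

## The pipeline model

The pipeline assumes a reduced-representation design: each diploid founder
is sequenced as an indexed library of size-selected restriction fragments,
deeply enough (≈30 read pairs per fragment per founder) that allele depths
are informative at single loci. Because no reference genome exists, loci
are *defined* by the data: near-identical read pairs are clustered and the
cluster consensus — 101 forward bases, a 98-base N spacer, 101 reverse
bases — acts as the locus reference. All later evidence is counted in
read-pair units ("depth").

Key structural assumptions, inherited from the design:

* mates of a 250–350 bp fragment never overlap, so the 202 informative
  consensus bases are independent observations of the fragment's two ends;
* the insert is pinned to the consensus length, so mapping needs no
  positional search — mates are compared end-to-end at fixed offsets;
* depth is the unit of evidence everywhere: the reference floor (≥ 10),
  SNP prediction (pooled ≥ 100), the per-founder cap (> 300 removed, a
  collapsed-repeat guard), genotyping (≥ 20 per founder) and the 5%
  presence rule all operate on read-pair counts.

## Tunable parameters

| parameter | default | role |
|---|---|---|
| `min_ref_depth` | 10 pairs | consensus floor for the mapping reference |
| `cluster_max_mismatch` / `map_max_mismatch` | 3 subs | clustering and mapping budget over both mates |
| `min_pooled_depth` | 100 pairs | SNP prediction floor (pooled over founders) |
| `max_founder_depth` | 300 pairs | per-founder cap, rule 2 (strict >) |
| `presence_frac` | 0.05 | allele presence threshold, rule 3 (strict >) |
| `max_ratio` | 3 | allele-depth ratio cap, rule 4 (strict >) |
| `min_founder_depth` | 20 pairs | genotyping floor, per founder |
| `haplotype_tolerance` | 4 pairs | depth-matching window (strict <) |
| `str_di/tri/tetra` | 8/5/4 units | minimal repeat counts |
| `nboot` | 10,000 | bootstrap replicates per scale |

Defaults are the published operating point of the protocol; all are exposed
in `PipelineParams` and on the command line. Strict versus inclusive
comparisons follow the protocol's "more than"/"at least" phrasing
throughout (e.g. founder depth 300 passes, 301 fails).

## The simulator

`simdata` emulates the study design with planted truth: an ancestral
sequence (uniform base composition), biallelic SNPs at a configurable
density with per-locus alternate-allele frequencies drawn from Beta(2, 2)
(founders are thereby related but distinct; an optional `related_pairs`
knob raises sharing between chosen founders), and length-polymorphic STR
loci planted inside the forward-read window of chosen host fragments.
Digestion is complete; MboI inserts retain the filled-in GATC overhang at
the downstream end, so both-end MboI pairs carry the GATC signature at both
termini. Sequencing draws Poisson pair counts per fragment (half the
founder target per haplotype copy) and applies uniform substitution errors;
qualities are a constant placeholder.

Planting is constrained so truth stays exact: SNPs never sit on or next to
a restriction site and never create one, so fragment boundaries are
identical across haplotypes; STR runs avoid restriction sites, other
fragments' read windows, and each other, so each planted STR surfaces in
exactly one locus per allele. Read identifiers encode the source fragment,
which is how `evaluate` traces a called variant back to an ancestral
coordinate. Recall is measured against *discoverable* planted SNPs — those
segregating among the founders and lying in a read window of a
size-selected fragment; variants outside the sampled fraction of the
genome are invisible to the design, not to the implementation.

What the simulator does **not** model — and hence what passing tests do not
show about real data: partial digestion, adaptor read-through and trimming,
cycle- and quality-dependent error profiles, indel sequencing errors, PCR
duplicates and coverage bias, paralogy and repeat families (the ancestral
sequence is random, so near-identical paralogous loci essentially never
occur, whereas real genomes produce them and the depth cap and ratio rules
exist largely for their sake), and STR polymerase stutter.

## Numerical conventions

* **Clustering order**: distinct (fwd, rev) sequences are processed by
  decreasing multiplicity, ties lexicographic; a sequence joins the
  earliest-founded cluster within the budget. Candidate clusters come from
  a pigeonhole index (budget+1 exact chunks of the 202 bases), which is
  exhaustive for substitution distances within the budget — verified
  against an all-pairs scan.
* **Consensus ties** break in fixed base order A < C < G < T.
* **Mapping ties** (equal mismatch count) go to the lowest locus id; a
  deterministic stand-in for an aligner's pseudo-random best-hit choice.
* **Major allele**: larger pooled depth, ties to the lexicographically
  smaller base.
* **Rule 4 scope**: the ratio test applies to any founder carrying both
  site alleles at nonzero post-rule-1 depth, not only founders where both
  alleles pass the presence rule. The narrower reading lets sites through
  whose second allele is a duplicated sequencing error in one founder
  (e.g. 42/2 — below the 5% line but far above ratio 3) and measurably
  destroys precision on simulated data.
* **Haplotype ambiguity**: a record compatible (by depth alone) with two or
  more existing groups marks the locus undetermined, as does any group not
  covering every offset exactly once. Pooled depths are used, not
  per-founder depths, since haplotype counts are per locus.
* **STR motifs** are canonicalised to the lexicographically least rotation;
  motifs that are powers of a shorter unit are excluded. STR merging
  compares the repeat-bearing segment's flanks only (aligned at the run
  boundaries), because the mate window of a length-polymorphic fragment is
  shifted between alleles and can never match ungapped.
* **Eigenvector signs** (PCA/MDS): the largest-magnitude entry of each
  component is made positive. Variance proportions are eigenvalue/n.
* **AU fit**: scales with degenerate recovery frequencies (0 or 1) carry no
  quantile information and are dropped; if fewer than two scales remain the
  node is assigned AU 1 (recovered essentially always) or 0. Frequencies
  are clipped to [1/(B+1), 1−1/(B+1)] before the probit transform.
* **Percentages** are rounded half-up to one decimal, matching the
  published tables.
* Degenerate inputs: empty FASTQ pairs yield empty results; a zero-variance
  founder makes the correlation (and everything downstream) undefined and
  raises an error naming the founder; `nboot` < 100 warns that AU is
  unstable; fewer than 3 founders cannot be clustered.

## Problem sizes

Desk-scale runs use a 2-Mb ancestral sequence: with two 4-cutters this
yields ≈1,900 size-selected fragments per founder and ≈290,000 read pairs
pooled — enough that every depth threshold operates at its intended
operating point (pooled locus depth ≈150, founder depth ≈30) while a full
pipeline run stays under half a minute. Unit tests use 120–300 kb. The
bootstrap sanity checks use 1,000 replicates per scale; the default for
real analyses remains 10,000.

## Known limitations

* Loci are never deduplicated across terminal groups, and one physical
  fragment sequenced from both orientations can found two loci; both
  behaviours are inherent to the reference-free design.
* Depth-matching phasing with pooled depths can only resolve loci whose
  alleles separate cleanly by depth; with many founders pooled, most
  multi-SNP loci are legitimately undetermined at realistic depths.
* The mapper is ungapped by construction; indel variation (outside the STR
  machinery) is invisible.
* AU p-values follow the standard multiscale-bootstrap fit with ordinary
  least squares; no external implementation is available in this
  environment to cross-validate the exact weighting scheme, so only
  internal properties (determinism, BP consistency, planted-structure
  recovery) are asserted.
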