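# Methods

`csnptrack` implements the computational side of a 22-marker coding-SNP
(cSNP) panel for tracking the origin of whole-exome sequencing (WES)
samples: confirming that a sequenced library belongs to the person it is
labelled with, and confirming parentage inside trio families sequenced
together. This note documents the statistical model, the conventions and
thresholds the toolkit fixes, what the synthetic-data generators do and do
not emulate, and the known limitations — including one deliberate
discrepancy against the panel's published characterisation.

## The panel and its selection pipeline

The markers are synonymous exonic SNPs so that (a) they are covered by
exome capture and (b) they are unlikely to be disease-associated. The
`selection` module reproduces the screening pipeline as a reusable
procedure over variant tables:

1. **primary screen** — synonymous sites with minor-allele frequency
   (MAF) ≥ 0.3 *or* at least three observed alleles;
2. **refined screen** — biallelic MAF ≥ 0.4 or triallelic MAF ≥ 0.1, no
   other variant within ±400 bp on the same chromosome (so amplification
   primers and extraction probes sit on invariant sequence), and a flank
   that maps uniquely in the genome;
3. **ranking** — per autosomal chromosome, the top six candidates by MAF
   subject to >10 Mb pairwise spacing (to keep loci effectively
   unlinked), then one marker per chromosome.

Conventions this module fixes where the procedure is under-specified:
the MAF of a multi-allelic site is its *smallest* allele frequency;
"allele amounts ≥ 3" counts the reference allele; multi-allelic sites are
placed ahead of all biallelic sites in the greedy spacing pass so they
are never crowded out by higher-MAF biallelic neighbours; spacing is
enforced greedily in that order with a deterministic tie-break
(MAF descending, position ascending, rsid ascending). Flank uniqueness
is accepted as an input flag rather than re-implementing an alignment
heuristic. The test-suite oracle re-evaluates every rule exhaustively
and replays the same documented greedy order for spacing; it checks rule
correctness and determinism, not spacing optimality, which the greedy
pass does not guarantee.

## Per-locus forensic parameters

All per-locus statistics except PIC are plug-in estimates from *observed
genotype* proportions, matching the desktop-tool conventions the packaged
reference values were produced with. With genotype frequencies `f_g`,
heterozygote proportion `h` and homozygote proportion `H = 1 − h`:

- match probability `MP = Σ_g f_g²`, discrimination power `DP = 1 − MP`;
- power of exclusion `PE = h²(1 − 2hH²)`;
- typical paternity index `TPI = 1/(2H)` (infinite, with a warning, when
  no homozygote was observed);
- polymorphism information content, from *allele* frequencies `p_i`:
  `PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²`.

The observed/allele split matters: PIC computed from the packaged
allele-frequency table reproduces the packaged per-locus PIC column,
while DP/PE/TPI cannot be recomputed from allele frequencies alone —
they need the (unpublished) genotype counts. `PE = h²(1 − 2hH²)` is the
classical one-parent exclusion formula; it equals the exact
random-man exclusion probability only at allele frequency 1/2 and is
otherwise a close approximation for common alleles (at the panel's
frequencies the combined gap is ≈0.0015, well inside sampling noise at
the simulation sizes used here).

Panel-level summaries: cumulative MP `Π MP`, combined PE
`1 − Π(1 − PE)`, and **two** combined-DP variants. The standard
definition is `1 − Π MP` (the probability that two random individuals
differ somewhere), algebraically `1 − cumulative MP`. The panel's
published combined DP (0.99997) is instead consistent only with
`1 − Π DP`, so both are always computed and reported
(`combined_dp_standard`, `combined_dp_published`); reports default to
showing both rather than resolving the inconsistency.

## Hardy–Weinberg and inter-locus independence

Biallelic loci use the exact conditional (Levene) distribution of the
heterozygote count given the allele counts, enumerated in full; the
p-value is the total probability of tables no more probable than the one
observed (the standard two-sided exact-test tail). Multi-allelic loci
use a seeded Monte-Carlo version: the allele vector is shuffled
(default 100,000 steps) and the same tail is estimated with the add-one
estimator `(hits + 1)/(steps + 1)`. Probabilities are compared in log
space with a 1e-12 slack for ties.

Pairwise independence between loci is tested by a seeded permutation
test of the G statistic (likelihood-ratio chi-square) on the joint
genotype contingency table, permuting one locus's genotype column. This
is a calibrated stand-in for an exact linkage-disequilibrium test — the
tests verify its type-I error, not equivalence to any particular EM-based
implementation. The multiple-testing threshold over L loci is Bonferroni
`0.05 / C(L,2)` (0.05/231 ≈ 0.000216 for the 22-marker panel).

## Kinship and identity

Paternity indices use the standard no-mutation likelihood ratios (see
the `kinship_identity` docstrings for the closed forms). The combined
paternity index (CPI) is the per-locus product, accumulated in log
space; a single excluding locus forces CPI = 0. No mutation model is
applied — the panel was validated on families without observed mutations
— but a frequency-floor option (5/(2n)) exists for alleles absent from
the reference table. Identity evidence is the likelihood ratio of the
prosecution hypothesis (same source) against the defense hypothesis
(unrelated individual): LR = 1/RMP on a full profile match, 0 on any
mismatch, where RMP is the product of per-locus Hardy–Weinberg genotype
probabilities (`p²` / `2pq`). Loci missing in either profile are skipped
and reported, never imputed.

**Strand harmonization.** Read-level extraction may report a locus on
the opposite strand to the allele-frequency reference (the packaged trio
read counts do, at several loci — e.g. a T/G locus reported as A/A).
Rule: if any allele of a genotype is absent from the reference allele
set, the whole genotype is complemented (one strand flip per locus); if
it still does not fit, an error names the locus. Complementing is the
biologically principled mapping; positional letter-matching against the
reference table was considered and rejected. Note the six C/G markers
are strand-ambiguous — complementing swaps their alleles — so the rule
deliberately leaves any genotype that already fits the reference
untouched.

## Genotype extraction from reads

Each marker gets a probe: the `k = 20` bases immediately 5′ of the
variant (drawn from the upstream flank). A read containing the probe as
an exact substring — forward, or reverse-complement with the reported
base complemented back — contributes one count to the base it carries at
the variant offset; each read counts at most once per locus. Exact
matching is appropriate because the selection pipeline guarantees
variant-free, unique ±400 bp flanks; a Hamming ≤ 1 tolerant mode is
available but off by default. Genotypes are called from the counts with
three thresholds: ≥ 3 reads per allele, ≥ 0.15 allele fraction, ≥ 6
surviving reads in total; one surviving allele ⇒ homozygote, two ⇒
heterozygote, three or more ⇒ flagged no-call (possible contamination).
The source the calling rule emulates states only that "low" read counts
were filtered, so the defaults are this package's decision; they call
all 66 sample-locus cells of the packaged trio read counts without
dropping any listed allele. Base qualities are ignored (none are
modelled upstream); that is a documented limitation, not an option.

## Synthetic data

The simulators define the study conditions the statistical claims are
tested under: 114 unrelated individuals genotyped at the panel's
observed allele frequencies (two independent allele draws per genotype —
Hardy–Weinberg, no inbreeding or population structure), Mendelian trios
with mutation rate 0 by default, and single-end 100 bp reads at 30× per
allele copy with a uniform per-base substitution error rate (0 by
default, capped at 0.1). Flanking sequences are pseudo-random per locus
(seeded), keeping the package reference-genome-free. Everything is a
pure function of (configuration, seed).

What the generators do **not** emulate — and therefore what passing
tests do not show about real data: exome capture bias and uneven
coverage, indels and alignment artefacts, base-quality structure,
linked loci, population substructure/coancestry (θ), and genotyping
error in the reference (CE) profiles.

## Problem sizes and numerical choices

Simulation-backed tests use sizes chosen to make the binomial/3σ bounds
they assert meaningful while keeping the default suite fast: 1,000
trio-versus-random-male cases for the exclusion-rate check, 200
replicates of the n = 114 panel simulation for the closed-form
comparison (with an O(1/n) allowance for the plug-in estimators' finite-
sample bias), 100 replicates × 400 permutations for the independence-
test calibration, 60 seeded replicates for the noisy-extraction
recovery claim, and exhaustive enumeration up to n = 50 for the
Hardy–Weinberg oracle. All products (RMP, CPI) accumulate in log space;
reports round to 3 decimals for display only — full precision is kept
internally and in JSON output.

## Known discrepancy: the trio's published CPIs

The packaged trio read counts (child/mother/father) plus the packaged
observed allele frequencies give duo CPIs of **24.864** (father) and
**25.362** (mother). The published characterisation of the same trio
reports 86.007 and 48.700. These could not be reconciled under any
standard convention: single-parent and other-parent-conditioned indices,
observed and reference-population frequency columns, both strand
harmonizations at every ambiguous locus, and re-calling the read counts
under a wide threshold grid all fail to reproduce the published pair —
as do the trio's published per-profile match probabilities. The likely
cause is that the published values were computed from the
capillary-electrophoresis genotypes (available only as electropherogram
images), which differ from the read-count table at one or more loci: the
read-count table itself is trio-inconsistent at rs2249057 (child G/T
with both parents G-homozygous on the sequencing strand), while the CE
profiles were reported fully Mendelian-consistent. The toolkit therefore
reports what the shipped data imply, and the corresponding comparison in
the acceptance suite is expected to fail against the published values;
it is kept unchanged rather than tuned.

Two further published numbers are intentionally out of reach at desk
scale and excluded from testing: the exome-database screening counts
(database-version dependent) and the per-locus DP/PE/TPI/HWE columns
(they require the unpublished genotype counts of the 114-individual
sample).
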