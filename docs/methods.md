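# Methods

This note documents the models, defaults and numerical choices behind
polyplex, and what the synthetic benchmarks do and do not demonstrate
about real resequencing data.

## Hard filters

SNV sites pass when the GATK-style site annotations satisfy MQ > 40,
QD > 2, FS < 60, MQRankSum > −12.5, ReadPosRankSum > −8, SOR < 3 and
DP ≥ 10, the site is biallelic and no sample genotype is missing.
Indels pass with QD > 2, QUAL > 30.0, FS < 200, no missing genotypes
and the indel allele carried by ≥ 2 individuals (regardless of
zygosity). All inequalities are strict except the DP floor, which is
inclusive; boundary tests pin both conventions. An absent annotation
fails the site by default (conservative) with a config switch to pass
it through; the filter report names every failed rule per site so the
policy is auditable. "Any missing genotype drops the site" is the
deliberate reading of joint-genotyped data: a site unscorable in one
sample cannot enter cross-sample comparisons downstream.

## Allele-balance ploidy estimation

At a heterozygous biallelic site, AB = alt depth / (ref + alt depth).
A sample contributes a site only when its genotype is heterozygous AND
0 < alt depth < total depth — an AB of exactly 0 or 1 contradicts the
het call and is excluded. The AB density is estimated with a Gaussian
kernel of absolute bandwidth 0.02 evaluated exactly on a fixed
512-point grid over (0, 1) (chunked direct summation; no
std-normalized bandwidth, so the estimator is fully pinned). Modes are
the local maxima of the grid density; modes below 0.1 of the global
maximum are discarded, high enough to drop lattice ripple and low
enough to keep the broad low-balance secondary mode detectable.

Candidate ploidies k ∈ {2, 4, 6} are scored by greedily matching
detected modes to the template {i/k} within a tolerance (default
0.05); the k explaining the most template peaks wins, ties breaking to
the lower mean absolute deviation, then the smaller k. Modes inside
the low-balance window [0.05, 0.25) whose relative height is below 0.6
are withheld from matching and only set the secondary-mode flag: the
repeat-region secondary peak seen even in diploids is characteristically
low and broad, while a genuine tetraploid 0.25 or hexaploid 0.17 peak
carries nearly full height. Without the height condition a diploid with
a secondary peak at ~0.12 would be mistaken for a hexaploid (0.12 is
within tolerance of 1/6).

A resolution caveat, verified against the infinite-sample density: at
mean depth 30 the binomial spread of a dosage-i/6 class
(sd ≈ √(p(1−p)/30) ≈ 0.086) exceeds half the 1/6 peak spacing, so the
smoothed hexaploid density's interior maxima sit ~0.02–0.03 away from
2/6, 3/6, 4/6 (e.g. the second maximum at ≈ 0.359, pulled inward by the
asymmetric widths of neighbouring classes), and their sampled positions
wobble by a few hundredths at 100k sites. The outer peaks (1/6, 5/6)
and all diploid/tetraploid peaks are sharp to < 0.02. Template matching
is robust to this because its tolerance (0.05) exceeds the shift;
positional accuracy at the 0.02 level is therefore asserted on
well-separated mixtures (component sd 0.03), plus the sharp subset of
the depth-30 simulation.

The low-balance classification window is configurable; [0.05, 0.25] is
the default with a [0.05, 0.20] alternative, since both conventions are
in use for selecting repeat-driven positions and neither is canonical.
A position inside both a repeat and a gene interval counts in both
categories.

## Exclusive SNVs and polyploid parentage

For a focal diploid group, a biallelic site is exclusive when every
focal member carries the candidate allele (all hom → homozygous_only;
some het → includes_heterozygous) and every member of every other
diploid group is homozygous for the other allele. Either the
reference or the alternative allele can be the exclusive one.
Polyploids take no part in defining exclusivity. All-heterozygous
focal configurations qualify for the includes_heterozygous class and
are sub-counted separately (`n_all_het`). Sites with any missing
focal or other-group genotype are dropped (conservative; moot after
the default filters).

A polyploid shares an exclusive site when its genotype contains ≥ 1
copy of the exclusive allele; the reported percentage divides by the
polyploid's own genome-wide hom-alt or het SNV total (matching the
zygosity class of the exclusive set). Totals may be supplied
externally — as in analyses that use fixed genome-wide counts — in
which case supplied values win over recomputed ones.

## Nei's gene diversity

Per site h = n/(n−1) · (1 − Σ pᵢ²) with n the non-missing allele
copies; the group value H averages h over all callable sites, with
monomorphic sites contributing zero. Because variant records only
carry polymorphic sites, `diversity_from_records` accepts the callable
total (`n_callable_sites`) and dilutes accordingly; genome-wide values
then land on the ~1e-3 scale.

## ABBA-BABA

Site patterns are frequency-weighted: with derived-allele frequencies
p1, p2, p3 and outgroup p4, abba = (1−p1)p2p3(1−p4) and
baba = p1(1−p2)p3(1−p4); D = (ABBA−BABA)/(ABBA+BABA). The outgroup's
majority allele defines "ancestral" per site; a polymorphic outgroup
is down-weighted through (1−p4) rather than discarded (a strict
fixed-outgroup switch exists). Significance uses a delete-one block
jackknife over contiguous blocks (default 25, minimum 20 informative),
Z = D/SE against a two-sided normal, and BH-FDR across trios. By
default only trios whose (P1, P2) pair is sister relative to P3 on the
inferred group tree are tested; an exhaustive mode exists. The block
count, not a physical span, parameterizes blocks at desk scale; with
independently simulated sites any contiguous partition is valid, and
on real data blocks should span ≥ the LD scale.

## Pseudo-alignment phylogeny

Each sample's sequence substitutes its homozygous alternative alleles
into the reference. Nuclear mode drops any column with ≥ 1
heterozygous call across samples (default), because a polyploid het
has no single state for its column; a per-sample het→N policy is
available by flag. Trimming keeps exactly the columns with ≥ 2
distinct non-N states. p-distances exclude N-containing columns
pairwise; neighbor joining (with negative branch estimates clamped to
zero) gives the desk-scale tree, and bootstrap support resamples
columns with replacement (default 100 replicates, seeded). The
trimmed alignment is exported in FASTA/relaxed PHYLIP for external
maximum-likelihood tools, which remain the intended path for
publication trees.

## The simulator

`simulate_complex` draws a uniform-random reference, then builds
per-lineage derived-allele frequencies from two site classes:

- branch mutations, Poisson-placed per branch of the lineage tree
  (infinite-sites, biallelic); internal-branch mutations fix in all
  descendant lineages, terminal-branch mutations segregate within
  their lineage at a frequency uniform on [0.3, 1.0] (a mix of
  polymorphic and near-fixed private variants);
- ancestral standing variation (density 0.005/bp by default): a root
  frequency uniform on [0.05, 0.95] drifts independently into each
  lineage via a Balding–Nichols Beta with F = 0.2. This class is what
  gives the complex incompletely sorted shared polymorphism — without
  it a clean tree produces exactly zero ABBA/BABA weight and D is
  undefined; with it the null is exchangeable across P1/P2 so E[D]=0.

Introgression copies the donor lineage's frequency into the recipient
at the configured fraction of sites. Diploid genotypes are
Hardy–Weinberg draws; the allotetraploid concatenates one diploid
genome drawn from each parent, the allohexaploid adds a third diploid
genome; optional post-formation private mutations add single derived
copies (recorded as non-parental in the truth object). Depths are
Poisson (mean 30, zero-truncated) with Binomial alternative reads at
dosage/ploidy plus an error rate of 0.002; INFO annotations are
written as clean passing values so the simulator tests the analysis
stack, not the filters' rejection path (fuzz tests cover that
separately).

Default scale — 200 kb over 4 chromosomes, 4 diploid lineages with
terminal branches of 0.004 substitutions/site, 2 samples per lineage,
one tetraploid (D1×D2) and one hexaploid (tetraploid×D2) — yields
roughly 6,000 variant sites and runs every pipeline stage in a couple
of seconds, so the recovery suites (20 seeds each for ploidy, parent
ranking, and D calibration/power) finish in minutes.

What the simulator omits, and hence what passing tests do not show:
recombination and linkage (sites are independent given the tree — the
jackknife's robustness to LD is untested), recurrent mutation,
polyploid meiosis and homoeologous exchange after formation, mapping
and calling artifacts (collapsed repeats, allele-specific bias), and
depth heterogeneity along the genome. The low-balance secondary peak
of real data is a mapping artifact and is therefore absent from
simulated profiles; its handling is exercised with constructed mode
lists and mixtures instead.

## Determinism

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from the global seed via CRC-keyed `SeedSequence`, so
stages are reproducible independently and the JSON summary is
byte-identical across reruns (timings go to the log, not the
summary).
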