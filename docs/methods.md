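# Methods and design notes

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make runs
reproducible.

## Data model and conventions

All statistics operate on pre-aligned haploid sequences. Sequences are
uppercased on ingest (`U`→`T`); `N` and `-` are missing data; any other
non-ACGT letter is an IUPAC ambiguity code. Coordinates are 0-based and
half-open everywhere. Ambiguous-site removal — done by hand in many
published workflows — is replaced by a deterministic rule: drop every
column containing an ambiguity code (N included), with an opt-in
gap-fraction filter. Reproducibility requires a rule, not curation.

Clone correction collapses identical sequences to one genotype, keeping
the first-encountered sample id as representative (a deterministic
tie-break). The default matching is strict (N/`-` are ordinary
characters), which is conservative and keeps m\* well defined; a
`missing_matches_any` mode merges sequences that differ only where one
carries N, resolving chains transitively toward the most-complete
consensus. Under that mode the emitted genotype sequence is the class
consensus, which makes the correction idempotent (final consensuses are
pairwise incompatible by construction).

Where samples lack some loci, concatenation supports both dropping
incomplete samples (default) and padding absent loci with N; both are
exposed because published multilocus datasets rarely state which was
used.

## Diversity statistics

π is the mean over unordered sequence pairs of the per-pair difference
proportion. The default site handling is complete deletion (columns with
any gap/N removed globally), matching the behavior of the desktop tools
these analyses traditionally used; pairwise deletion is available. The
quantity feeding Tajima's D and Fu's Fs is π̂_total, the mean pairwise
difference *count* on complete-deletion columns.

Confidence intervals for π are 2.5/97.5 percentile intervals over 1000
replicates (default) of either a **sequence bootstrap** (resample the n
sequences with replacement, recompute π) or a **two-sequence
subsampling permutation** (draw 2 distinct sequences, record their
pairwise π). The resampling unit is the sequence: the natural contrast
to the two-sequence subsample is resampling individuals, not sites. A
site-resampling variant is not the default. Note a known property of the
percentile sequence bootstrap: for small n the interval center is pulled
low by duplicate resampled pairs (distance 0), by roughly a factor
(n−1)/n, and empirical coverage at n≈20 falls to ~80–90%. The
calibration tests therefore exercise the interval at n=50, where the
asymptotic method behaves nominally; users with very small samples
should prefer the subsampling interval or treat the bootstrap interval
as approximate.

Tajima's D uses the canonical constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂
and is undefined (reported `n/a`) when S=0. Fu's Fs computes
S′ = P(K ≥ k_obs | θ̂ = π̂_total, n) under the Ewens sampling
distribution, with unsigned Stirling numbers of the first kind built by
the triangular recurrence entirely in log space (stable to hundreds of
sequences); Fs = ln(S′/(1−S′)), with signed infinities reported when S′
saturates. Both statistics run on clone-corrected data and are reported
`n/a` for groups with fewer than three genotypes. Significance stars are
deliberately not emitted: the usual p-values come from coalescent
simulation, which is out of scope here, and printing a raw statistic is
more honest than approximating its null.

θ̂ for Fs is π̂_total (the mean pairwise difference count), not the
per-site value; desktop implementations differ by version on this
point, so the choice is documented here and asserted in tests.

## Recombination detection

The four-gamete test considers all pairs of biallelic sites (exactly two
determinate states; gaps/N carry no allele) and flags pairs where all
four haplotype combinations occur among sequences determinate at both
sites. R_m reduces the flagged pairs to intervals, keeps minimal ones,
and greedily counts disjoint intervals left to right (intervals sharing
an endpoint are disjoint, because each required event lies strictly
between its sites); this greedy count equals the maximum disjoint subset
and is verified against exhaustive search in tests.

I_A and r̄_d operate on multilocus genotypes: an allele is a distinct
locus sequence (gaps as missing, missing-tolerant collapsing; an
entirely missing sequence carries no allele). Pair distance per locus is
the binary mismatch indicator — the standard I_A definition — so
I_A = V_O/V_E − 1 with V_O the variance across sample pairs of summed
mismatches and V_E the sum of per-locus mismatch variances;
r̄_d = (V_O − V_E) / (2 Σ_{j<k} √(v_j v_k)). Monomorphic loci carry no
variance and drop out of the denominator. The permutation null shuffles
alleles among samples independently within each locus (allele
frequencies preserved, linkage destroyed); p = (1 + #{perm ≥ obs}) /
(1 + n_perm) with 999 permutations by default, matching the reporting
convention of the R ecosystem these indices come from.

The suite applies 4GT/R_m to concatenated sequences and I_A/r̄_d to
MLGs, per lineage and pooled, on clone-corrected genotypes by default
(raw data behind a flag, since published workflows are often silent on
this point). Two structural facts, both reproduced by the tests, matter
for interpretation: pooling diverged clonal lineages produces
four-gamete incompatibilities *without* recombination (lineage-private
substitution histories look like homoplasy), and a pure star genealogy
within a lineage is close to linkage equilibrium once clones are
removed — the clonal LD signal in I_A lives in repeated multilocus
genotypes and lineage structure, which is why the power check runs on
pooled, non-clone-corrected data.

## Statistical-parsimony network

The connection limit is the largest step count j whose probability of
parsimony is at least the confidence level (default 0.95). The
probability model: substitution events per site are Poisson with
intensity estimated by maximum likelihood (Jukes–Cantor correction of
the observed difference fraction j/m); a differing site is parsimonious
when exactly one event occurred there, so
P(parsimony | j) = [λe^(−λ) / (¾(1 − e^(−4λ/3)))]^j. The limit is
floored at one step, and a user-supplied fixed limit overrides the
computation. This is an operationalization of the classic 95%
statistical-parsimony criterion, not a line-by-line port of any
published program, whose internal tie-breaking is not fully published.

The network is a minimum spanning network: candidate haplotype pairs are
processed by increasing step distance (ties: higher combined frequency,
then lexicographic ids), and within one distance class every pair whose
endpoints lay in different components at the start of the class is
admitted — so alternative equal-distance connections survive as
reticulations. Admitted multi-step links are expanded through inferred
median nodes whose sequences interpolate the differing columns left to
right (any order is equally parsimonious; fixing one makes runs
deterministic). Every rendered edge is one mutational step; an edge of k
steps contributes exactly k−1 medians. Gap handling defaults to
`missing` (gap/N columns ignored in identity and distance), with a
fifth-state mode available.

The "ancestral" designation reported with the network is the observed
haplotype maximizing frequency × degree — a deliberately simple
heuristic for the outgroup-weight concept, flagged as such.

## Divergence and dating

Pairwise distances use the Tamura–Nei (1993) maximum-likelihood formula
from the two transition proportions (A↔G, C↔T), the transversion
proportion, and base frequencies estimated from the pooled pair; no
gamma rate variation is applied. Saturated pairs (non-positive log
arguments) return +∞ rather than a silently clipped value. D_xy is the
mean over between-population pairs (self-comparison of a population
excludes self-pairs, so D_A(X, X) = 0 exactly), D_x/D_y over unordered
within pairs, and D_A = D_xy − (D_x + D_y)/2. D_A can be legitimately
negative for unstructured pairs; it is reported raw, and only the dating
step refuses negative input.

The SE of D_A comes from resampling alignment columns with replacement
(1000 replicates by default) and recomputing D_A each time — the
site-bootstrap convention of distance-matrix software. The interval is
D_A ± 2·SE, floored at zero. Dating is the strict clock
D_T = D_A / (2μ); three ITS rate priors are bundled
(2.43×10⁻⁹, 2.38×10⁻⁹, 2.52×10⁻⁹ subs/site/year) and table output
rounds Myr half-up to one decimal.

## The synthetic generator

Each lineage founder is derived from one random ancestral sequence per
locus by Poisson(d/2 × L) substitutions (d = configured founder
divergence), so founder pairs are separated by ≈d per site. Samples
within a lineage follow a star genealogy: with probability
`clone_fraction` a sample copies an existing member exactly; otherwise
it receives Poisson(θ × L) private substitutions from the founder.
Substitutions use a transition/transversion kernel (default κ=2) with
multiple hits allowed and no back-mutation bookkeeping, so realized
distances can slightly undershoot expectations; tests use tolerant
bounds. Chemotype is a per-lineage Bernoulli label assigned
independently of genotype; optional reassortment draws each locus from
one of two same-lineage parents. No indels are simulated — gap handling
is exercised by hand-built fixtures instead — and there is no
coalescent, migration, or selection.

Defaults (3 lineages of 9/5/30 samples; loci of 500/400/450 bp; founder
divergence 0.02; θ 0.003; clone fraction 0.6; chemotype mix 1.0/0.0/0.5)
mirror a survey of a clonal lichen mycobiont: two small geographically
restricted lineages — one diverse, one near-monomorphic — and one large
widespread clonal lineage with mixed chemotypes, within-lineage π of a
few per mil and between-lineage divergence of ~2%. Consequences for
ground truth: within-lineage π estimates 2θ (each pair of star tips
carries two independent mutation loads), D_x within lineages averages
2θ, and the generating net divergence D_A equals the realized
founder-to-founder separation — the quantity the recovery tests check.

Passing tests on this generator demonstrate estimator correctness and
calibration under the clonal star-lineage model; they do not certify
behavior on real data with indel variation, recurrent mutation
hotspots, within-lineage phylogenetic structure, or sequencing error.

`free_reassortment` permutes the sample→sequence assignment
independently within each locus, giving exact linkage equilibrium with
preserved allele frequencies — the null used to calibrate the I_A test.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; the pipeline fans a
single global seed out to per-stage seeds by fixed offsets, and a rerun
with the same config is bit-identical (asserted over output hashes).
The validation suite uses desk-scale problem sizes chosen to make the
statistical checks sharp while keeping the full run in the low minutes:
50 random toy alignments (n ≤ 8, L ≤ 60) for the enumeration oracles,
exhaustive R_m on ≤ 20-site instances, 200 replicates at n=40 and 3
loci for the I_A null calibration, 100 replicates for its power check
and for D_A recovery, and 200 replicates at n=50 for π CI coverage.

## Known limitations

- Tajima's D and Fu's Fs p-values are not computed (no coalescent
  machinery); only the statistics are reported.
- The parsimony probability treats differing sites as independent and
  ignores shared-branch effects; the network is an MSN-with-medians
  approximation, not a cladogram-estimation replica, and its ancestral
  flag is a heuristic.
- TN93 distances become +∞ near saturation instead of switching models.
- The percentile bootstrap interval for π undercovers for small n (see
  above).
- The generator's star genealogy has no within-lineage shared branches,
  so it cannot emulate clonal LD that survives clone correction.
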