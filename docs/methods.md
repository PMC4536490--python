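# Methods

## The estimand

For each gene with an ortholog in a related strain we estimate ω = Ka/Ks
with the Nei–Gojobori (1986) counting method, then ask whether essential
genes have systematically lower Ka, Ks and Ka/Ks than nonessential genes
— per organism, across organisms, and within COG functional categories.

## Ortholog pairing

Orthology is approximated by the one-directional best protein hit:
among hits with E-value strictly below 10⁻⁵, the hit with the highest
bit score wins; ties are broken by lower e-value, then lexicographically
smallest subject id, so the result is independent of input order.
Reciprocal-best-hit filtering is deliberately not applied. A QC report
flags pairs with >30% identity (strict) and ≥50% of query residues
aligned (inclusive); the coverage denominator is the query length, a
choice that had to be fixed here because "aligned residues" alone does
not define one.

The preferred input is a 12-column BLAST tabular file. For offline and
synthetic use, `built_in_pairing` aligns every candidate pair globally
(BLOSUM62, gap open −10, extend −0.5). Because all-vs-all global
alignment is quadratic, candidates are prescreened by exact shared
4-mers (default: at least 10 shared words), the same idea as BLAST word
seeding; this keeps the search near-linear for panels of hundreds of
genes and reliably retains pairs down to roughly 50% identity at
~300 residues. The emitted bit score and e-value come from a
Karlin–Altschul-style transform of the raw alignment score (λ = 0.267,
K = 0.041, length-normalized). These are synthetic statistics: monotone
in the score and adequate for thresholding and ranking, not calibrated
against any database — use real BLAST output when e-values matter.

## Codon alignment

Each protein pair is aligned by deterministic optimal global alignment
(Needleman–Wunsch with affine gaps under BLOSUM62). For two sequences
the optimal pairwise alignment is the natural deterministic replacement
for a progressive multiple aligner; among co-optimal alignments the
first in the aligner's fixed enumeration order is taken, so repeated
runs agree exactly. The protein alignment is back-translated onto the
coding sequences: one amino-acid column becomes one codon column,
protein gaps become codon gaps ('---'). A CDS that does not translate
exactly to its alignment row is an error, never silently trimmed; a
terminal stop codon is trimmed, an internal stop rejects the gene with a
logged warning (internal stops indicate annotation artefacts that would
corrupt site counting).

## NG86 estimation

Per codon, the synonymous site count s is the mean over the three
positions of the fraction of the three single-nucleotide changes that
preserve the amino acid; n = 3 − s. Changes that create a stop codon
count as nonsynonymous under the default policy (`StopPolicy.sites`,
also available: excluded from both classes, giving s + n < 3).

Per codon pair differing at k positions, the k! orderings of the
changes are enumerated; each single-nucleotide step is synonymous or
nonsynonymous, and (sd, nd) is the unweighted mean over orderings, so
sd + nd = k exactly. Orderings passing through a stop intermediate are
excluded (`StopPolicy.paths`); if every ordering is excluded the average
falls back to all orderings with stop-touching steps counted
nonsynonymous. Both stop policies are recorded in the run manifest
because published pipelines rarely state them.

Alignment columns containing a gap, an ambiguous base or a stop codon
are excluded at codon granularity (pairwise-complete deletion). Sites
are averaged over the two sequences, S = (S₁ + S₂)/2; proportions
pS = Sd/S and pN = Nd/N are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3). An estimate is *valid* when p < 3/4 with the
corresponding site count positive; the ratio additionally requires
Ks > 0. Pairs with no differences at all are flagged `zero_variation`
(Ka = Ks = 0, ratio undefined) — these matter downstream for PNE calls
and are *excluded* from Ka/Ks class comparisons while still contributing
Ka = Ks = 0 to the Ka and Ks means.

Numerics: all site and difference counting is exact. Site fractions are
thirds and pathway means have denominators dividing lcm(1…6) = 60, so
counts accumulate as 60×-scaled integers and floating point enters only
at the Jukes–Cantor step. Results are therefore bit-stable and exactly
symmetric in the two sequences.

## Statistics

*Mann–Whitney U*, two-sided, compares per-gene metric values between
classes. For pooled sample size ≤ 10 the null distribution is enumerated
over all group assignments of the pooled values (exact under ties, with
two-sidedness defined by |U − n₁n₂/2|); larger samples use the midrank
normal approximation with tie correction. The conservation direction is
read from the sign of the class-mean difference, not from the test.

*Bootstrap*: each replicate draws ⌊n/2⌋ values (minimum 1) with
replacement and records the mean; 1000 replicates by default. Replicate
means are computed centred on the first value, so constant input yields
exactly constant output. Half-sampling damps the influence of extreme
per-gene estimates on class means.

*Cross-organism test*: paired two-sided Student's t-test on the
(essential mean, nonessential mean) pairs, with organisms as the pairing
unit; at least three organisms are required. All-equal pairs return
t = 0, p = 1 rather than 0/0.

*COG matrix*: per (organism, letter), Mann–Whitney on the per-gene Ka/Ks
of essential vs nonessential genes in that category, significance at
α = 0.01. Letters R and S (general prediction / unknown function) are
excluded; genes annotated with several letters count in each of them —
the alternative (first letter only) is supported by filtering the input.
A letter is a conserved function subcategory when the essential-conserved
direction is significant in strictly more than half of all organisms in
the COG analysis; opposite-direction cells do not subtract, and the
denominator is the organism panel, not the testable subset. Organisms
without COG annotation are skipped in this stage only.

*PNE*: a nonessential gene with zero_variation and homologs in ≥ 2 other
organisms. The reported proportion divides by nonessential genes that
have an ortholog pair.

No multiple-testing correction is applied anywhere, matching the
analysis design this package reimplements.

## Synthetic panels

The generator emulates the statistical structure the analysis assumes:
per organism, genes are assigned a class (default 20% essential), a COG
letter, and an ω (essential 0.05, nonessential 0.3 by default; per-letter
overrides let some categories be class-differential and others null —
defaults: J and L differential, C and E null at ω = 0.2). Each gene is a
uniform random sense-codon sequence (300 codons by default, terminal
stop appended); its homolog is produced by rejection sampling: uniform
single-nucleotide proposals, stop-creating changes rejected, synonymous
changes accepted, nonsynonymous changes accepted with probability ω,
until round(divergence × S₀) synonymous substitutions have accumulated
(S₀ = NG86 synonymous sites of the original; divergence defaults to 0.2
synonymous substitutions per synonymous site). Because acceptance rates
are proportional to S : ωN, the realized NG86 Ks concentrates on
`divergence` and Ka/Ks on ω as length grows.

A configurable fraction of nonessential genes (default 5%, within the
range reported for real bacterial panels) is emitted as true PNE: zero
divergence and a homolog count drawn from {2, …, n_organisms}. Other
genes draw homolog counts uniformly from {0, …, n_organisms}; the panel
does not actually cross-align organisms. Not emulated: indel evolution
(homologs are gap-free, so the aligner is exercised trivially there;
gapped cases are covered by hand-written fixtures), codon-usage bias,
rate variation among sites, and database-calibrated e-values. Passing
tests on these panels therefore demonstrate correctness of the
estimator and decision rules under the stated model, not robustness to
annotation errors or alignment ambiguity in real genomes.

Generation is fully deterministic: one seed, per-organism child
generators, byte-identical file sets for identical configs.

## Problem sizes

The recovery analyses run on panels of 5 organisms × 200 genes × 300
codons with 1000 bootstrap replicates, repeated over 10 seeds — large
enough that the class contrast (ω 0.05 vs 0.3 at divergence 0.2) is
detected in every organism with Mann–Whitney p < 0.01, and the
conserved-subcategory rule returns exactly the differential letters.
The estimator cross-checks run over all 61×61 sense-codon pairs and
hundreds of random 30-codon alignments against independent brute-force
enumerations.

## Known limitations

- NG86 only: no transition/transversion or codon-frequency correction
  (LWL85, YN00 and ML estimators are out of scope), so absolute Ka/Ks
  values carry the usual NG86 biases at high divergence.
- The built-in pairing is not BLAST: its e-values are synthetic, and the
  word prescreen can miss orthologs below ~50% identity unless loosened.
- Strain choice for real data (diverged enough that Ks > 0, close enough
  that alignment is trivial) is left to the user; the generator controls
  divergence directly instead.
- The exact Mann–Whitney branch is capped at pooled n = 10
  (enumeration is combinatorial); beyond that the normal approximation
  is used even under heavy ties.
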