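# Methods

This note records the models, conventions and numerical choices behind
splkit, and what the synthetic-data tests do and do not establish about
real data.

## Co-expression networks

For a set of transcripts and a sample panel, all pairwise Spearman rank
correlations are computed in one pass: values are average-ranked per
transcript (ties get average ranks) and Pearson-correlated. The two-sided
p-value uses the t approximation `t = rho·sqrt((n−2)/(1−rho²))` on n−2
degrees of freedom; `|rho| = 1` maps to p = 0. An exact rank-permutation
p (`exact_rho_pvalue`) is available for n ≤ 8. The t approximation is
accurate to ≤ 0.02 against full permutation enumeration from n = 7
upward (mid-p tie convention); at n = 6 the discrete permutation law is
coarse enough that the deviation peaks at 0.029 near |rho| ≈ 0.14 — a
property of the approximation itself, worth knowing when sample panels
are tiny.

A network at threshold α keeps edges with p ≤ α. Conventions:

- **Nodes are incident transcripts only.** A transcript whose every edge
  fails the threshold is not a node, so node counts fall as α tightens —
  this is what makes the p-value ladder informative.
- **Raw p-values, no multiple-testing correction.** The procedure
  thresholds raw p from 0.05 down to 1e-8; at α = 0.05 roughly 5% of
  independent pairs connect by chance. This is a deliberate statistical
  caveat, and the reason the method carries two chance controls: a
  size-matched network of unrelated "unknown" transcripts, and the
  two-thirds subsampling scheme (20 replicates by default) whose
  replicate means and standard deviations are compared between focal and
  control sets along the ladder.
- **Zero-variance transcripts** have no defined rank correlation; they
  are dropped before the correlation pass with a warning.

Clustering is Markov clustering (MCL): column-stochastic adjacency with
self-loops, alternating expansion (matrix squaring) and inflation
(elementwise power, default 2.0, renormalized), pruning entries below
1e-6, until the maximum column change is below 1e-8 or 100 iterations.
Clusters are the connected components of the converged matrix's support;
they never span components of the input graph. MCL granularity depends
strongly on inflation, so cluster *counts* are reported but not treated
as calibrated quantities; connected components are reported alongside.
"Recovery" of a planted co-expression block means the block's members
form a single connected unit of the thresholded graph.

## Synthetic expression model

Expression is simulated at the quantified-matrix level (no reads) by a
log-normal latent-factor model. For a planted block with loading
`l ∈ [0,1]`, each sample s draws a factor `f_s ~ N(0,1)` shared by the
block, and transcript t takes `x_ts = exp(l·f_s + σ·ε_ts)` with
independent `ε ~ N(0,1)` and dispersion σ (default 0.5). On the log scale
the within-block correlation is `l²/(l²+σ²)` (loading 0.9 → ≈ 0.76), and
rank correlations inherit it through monotonicity. Loading 0 gives fully
independent transcripts — the negative-control regime used for null
calibration. Background "unknown" transcripts are independent draws of
the same marginal.

Zero inflation is independent Bernoulli dropout (default rate 0.1).
The default is deliberately moderate: dropout scrambles ranks at the
zeroed entries, and the generator's contract — blocks with loading ≥ 0.9
observed over ≥ 30 samples are recovered as one connected unit at
α = 0.05 in ≥ 90% of seeds — holds with margin at 0.1 (measured 20/20
seeds) but degrades beyond ≈ 0.2 (16/20). Heavier zero inflation is a
config knob, not a default. Group-specific transcripts are exactly zero
outside their group and dropout-free inside it, so specificity calls on
them are deterministic.

One global integer seed drives a named substream per generator
(`named_rng(seed, name)`), so adding a generator never perturbs the
draws of the others; identical (config, seed) reproduces outputs
byte-for-byte in serialized form.

What passing these tests shows about real data — and what it does not:
the generator controls rank-correlation structure, zero inflation and
group specificity, which is what the expression and network stages
consume. It does not emulate library-size effects, count noise,
transcript-length bias, batch structure or correlated dropout, so
passing calibrations here demonstrate correctness of the procedure, not
robustness to every artifact of real quantification pipelines.

## SBP domain model

The scanner slides a 74-residue positional template. Offsets of the key
residues (relative, 0-based) are derived from the spacings between the
conserved columns of plant SBP-domain alignments: zinc finger 1 at
0/5/22/25 (C-x4-C-x16-C-x2-[H|C]), zinc finger 2 at 41/44/48/60
(C-x2-C-x3-H-x11-C), NLS basics at 57/58/70/71/72/73 (overlapping finger
2). The residue at offset 25 discriminates the type: His → C3HC2HC,
Cys → C4C2HC. A complete match satisfies all 8 zinc positions plus the
NLS rule (≥ 5 of 6 basics); windows with ≥ 6 of 8 zinc positions are
reported as incomplete candidates. Spacings are configurable
(`DomainSpec`) since they vary slightly across lineages. Literature
describes the domain as 74–76 residues; 74 is used as the span because it
is the operational width of the aligned logo analyses, with the length an
explicit field of `DomainSpec`.

The domain/transcript length ratio defaults to the nucleotide basis
(74·3 = 222 nt over transcript bp), switchable to amino acids. The group
comparison uses Welch's t-test (unequal variances) — the safer default;
with the separations of interest the pooled variant does not change the
call, and the test suite checks decision agreement with a label-
permutation test.

## Phylogeny

p-distances are computed over pairwise gap-free columns. Neighbor joining
follows Saitou–Nei with two determinism rules: ties in the Q criterion
break to the smallest (i, j) index pair, and negative branch lengths are
clamped to zero with the deficit moved to the sister branch. The final
three lineages attach to an unresolved center, giving the 2n−3 branches
of an unrooted binary tree. NJ recovers additive matrices exactly, which
the suite verifies on 500 random trees (5–8 taxa) by split-set equality.
Group assignment gives each query leaf the group of its patristically
nearest reference (ties: lexicographically smallest reference, flagged
ambiguous) and reports per-group monophyly under midpoint rooting —
chosen because no outgroup-based rooting is assumed. Distance-based NJ
stands in for maximum-likelihood inference here; for group assignment
against references the topological demands are modest, and NJ's exactness
on additive inputs makes it testable, but deep-branch placements should
not be over-interpreted.

## Ka/Ks (NG86)

The Nei–Gojobori counting estimator: fractional synonymous site counts
per codon averaged over the two sequences; differences averaged with
equal weights over all minimal substitution pathways, excluding pathways
through stop codons (if every pathway is blocked, stop-crossing pathways
are used so differences are never lost); proportions corrected by
`d = −(3/4)·ln(1 − (4/3)p)`, flagged saturated at p ≥ 3/4; omega = Ka/Ks,
flagged undefined when Ks = 0. One convention matters: changes that would
create a stop codon are excluded from the site denominators. In coding
sequence such changes are not part of the observable substitution
process, and counting them as nonsynonymous sites biases omega downward
(measurably ≈ 0.92 instead of 1.0 in neutral simulations). Codons
containing N are skipped and reported as excluded. NG86 ignores
transition/transversion and codon-usage bias; for the question it
answers here — is omega well below 1 — that bias is immaterial, and the
neutral and purifying calibrations in the suite bound it empirically.

The codon-pair simulator evolves a derived sequence from a random
ancestor by single-nucleotide proposals: synonymous changes accepted with
probability min(1, 1/ω), nonsynonymous with min(1, ω), stops rejected;
`divergence` sets the expected accepted substitutions per codon (default
0.2, below saturation).

## Sequence logos

Per-column information content is `IC = log2 20 − H` with H the Shannon
entropy of gap-excluded residue frequencies, floored at 0; the optional
small-sample correction subtracts `e(n) = 19/(2·ln2·n)` with n the
non-gap count. Gaps are excluded from frequencies and tracked separately;
columns that are majority-gap are flagged since their apparent
conservation is usually an alignment artifact. Conserved positions are
columns whose modal gap-excluded residue reaches a threshold fraction,
reported 1-based.

## Family table and protein parameters

The packaged inventory table is stored exactly as published, pinned by a
checksum test; internally odd rows (e.g. an ORF length inconsistent with
a naive reading of the transcript length) are kept verbatim because the
table is metadata, not a recomputation target. The ORF finder reports the
longest ATG-initiated, stop-terminated frame over all six frames, ties
broken forward-strand-first then smaller start — common ORF-finder
defaults. MW uses average (not monoisotopic) residue masses plus one
water; pI solves the Henderson–Hasselbalch net-charge equation (termini
plus D/E/C/Y/H/K/R side chains, Bjellqvist pKa set) by bisection on
[0, 14], unique because net charge is monotone in pH. Family-size CV is
the sample standard deviation over the mean by default.

## Percentages and counting conventions

Reported percentages use round-half-up at the last kept digit, which
reproduces the conventional spreadsheet/SPSS rounding of published
tables. Percentage operations take an explicit denominator because
surveys switch bases between sections (annotated totals vs expressed
totals). "Expressed in a group" means strictly greater than a threshold
(default 0) in at least one sample of the group; cultivar panels are
treated as single-sample groups.

## Problem sizes and determinism

Default problem sizes are chosen so the full synthetic pipeline completes
in seconds and the whole test suite in a few minutes on one CPU: the
pipeline default is 106 focal + 2000 background transcripts over 42
samples; calibration suites use 20–100 seeds with 20–36 samples and
focal sets of 20–30 transcripts; NJ recovery uses 500 random 5–8-taxon
trees; the exact-permutation comparison enumerates n = 7. All randomness
flows from explicit integer seeds through named substreams; reruns with
the same configuration reproduce every output checksum.

## Known limitations

- Raw-p thresholding (by design, with controls) rather than FDR control.
- NG86 rather than a codon-model (e.g. kappa-aware) Ka/Ks estimator.
- NJ/p-distance rather than maximum likelihood for the tree.
- The motif scanner is a positional template, not an HMM profile; domains
  with indels inside the 74-residue span will be reported incomplete.
- The expression generator's independence and log-normal assumptions
  listed above.
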