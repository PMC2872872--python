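# Methods

This note records the models, parameter choices and numerical conventions
behind `gensurvey`, and what the synthetic-data tests do and do not
demonstrate about real survey data.

## The survey model

The whole package rests on one sampling model: shotgun reads of mean length
*L* fall uniformly (both strands) on a genome of size *G* at coverage
fraction *c* = total read bp / *G*. Two consequences are used repeatedly:

* **Depth → copy number.** A window of *w* bp belonging to a sequence
  present in CN copies is matched by reads whose start lies in any of the
  CN intervals of length *w + L*, so E[N] = CN·c·(w + L)/L and
  CN̂ = N·L/(c·(w + L)). The estimator is exactly 1 at the single-copy
  expectation by construction. Reads are counted when they align at ≥ 90%
  identity anywhere on the target (partial, dangling alignments included,
  as the *w + L* window presumes); requiring full-length matches instead
  would shrink the effective window to roughly *w − 0.8L* and bias CN̂ down
  severely for short targets.
* **Overlap probability → cluster significance.** Under the null of a
  single-copy locus, read starts are a Poisson process of rate *a = N/G*;
  two reads chain when their starts differ by ≤ *t = L − T* (*T* = minimum
  overlap). The probability that any ≥ *k* reads chain is approximated by
  the island-size tail p_null = 1 − exp(−μ) with
  μ = N·e^(−a·t)·(1 − e^(−a·t))^(k−1). The implementation reports this
  closed form next to a direct Monte-Carlo estimate (uniform read drop,
  longest chained run per replicate) and the tests require agreement within
  two Monte-Carlo standard errors. Boundary effects (linear genome) and the
  Poissonization of island counts are the only approximations; at the
  scales exercised (G ≥ 10⁵, t ≪ G) they are below sampling noise.

## Repeat discovery

Reads are joined by an edge when **some ungapped offset** gives an overlap
(suffix/prefix or containment) of ≥ 14 bp whose identity over the full
intersection is ≥ 100%, in either orientation. This is deliberately strict:
an indel or any mismatch inside the intersection voids the edge. Candidate
offsets come from shared exact 14-mers, which makes detection exhaustive at
the 100% identity setting (any qualifying overlap contains such a word); at
lower identity thresholds a shorter seed is used and detection is heuristic.

Clusters are connected components with ≥ 3 reads. Layout is a greedy
maximum-spanning forest (strongest overlap first); edges closing a cycle are
dropped, which resolves any inconsistent placement in favour of the stronger
overlaps. Consensus is the per-column majority base with ties broken to the
alphabetically first base; columns supported by fewer than two reads are
trimmed from the ends only. One repeat family may legitimately yield several
clusters; no merging is attempted, and recovery statistics therefore ask
whether *some* cluster represents a family, not whether exactly one does.

## The aligner

A single seed-and-extend local aligner (word size 11, exact words, diagonal
banding, then affine-gap Smith–Waterman on the banded window) plays the
roles that full-scale pipelines split between a fast candidate finder and an
exact local aligner. Scores are integers on a ×100 scale: match +100,
mismatch −100, and a gap of length g costs 400 + 30·g. The DP is vectorised
per query row; horizontal (subject-side) gaps are handled by a prefix-max
scan, which is exact for this gap model because two abutting gaps always
cost more than one merged gap. `N` and IUPAC ambiguity codes never seed and
always score as mismatches. E-values use the ungapped Karlin–Altschul form
E = K·m·n·e^(−λS) with K = 0.711, λ = 1.37 and S the raw score in match
units; these constants gate contamination and classification calls at
E ≤ 10⁻⁶ and are not re-estimated per run. The minimum reported score
(default 30 match units) is a free calibration standing in for the external
tools' internal score scales.

Tests verify the top local score against Biopython's `PairwiseAligner`
(full Smith–Waterman with the identical gap model) on planted-core pairs;
agreement is exact in ≥ 95% of cases, with the residual cases caused by
optima lying outside any seeded band.

## Survey arithmetic and rounding

Printed survey quantities are only reproducible under per-quantity rounding
rules, which are therefore pinned: contamination percentages are
**truncated** to 2 decimals; the 3C genome size is rounded to the nearest
0.5 Gbp and the per-haploid size to 2 significant figures; the coding
percentage to 1 decimal (and the downstream base-pair and locus counts are
computed from the rounded percentage); per-subgenome locus counts to the
nearest 1,000; repeat genome fractions to 2 decimals.

The exon-space fraction f = E/(E + L − 2m) assumes each called-coding read
overlaps essentially one exon. Its Monte-Carlo counterpart — exonic bp among
reads with ≥ m bp exon overlap on an exon/intron mosaic — depends on intron
length: long introns (> L) push the true fraction toward ~0.63, short
introns raise it as reads span adjacent exons. The test mosaic uses 250-bp
exons and 130-bp introns (typical of grass gene models), where the closed
form is accurate to well under two percentage points; the formula should be
read as a geometry-dependent approximation, not an identity.

"Best hit" everywhere means maximum bit score, ties broken by higher
identity and then lexicographic subject id. The gene-space identity window
[94, 99] is inclusive at both ends and excludes 100% matches, which at
survey scale are dominated by non-full-length artefacts.

## Small RNA

Mapping is exhaustive by pigeonhole seeding: a signature with ≤ m
substitutions contains one of m + 1 equal pieces exactly, so exact-piece
lookups enumerate every candidate placement, each verified over the full
signature on both strands. One mismatch over an 18–32-mer subsumes a ≥ 94%
identity rule at 100% coverage; an indel breaks coverage and is a non-hit.
TPQ normalization is transcripts per **quarter-million** sequenced
signatures (× 250,000). For per-cluster counts a signature's abundance is
credited to every cluster it hits; for class shares it is split equally
among the distinct classes hit so shares sum to 100. Binned rates use the
bin's **minimum** copy number as the regressor, and the chi-square test
compares per-bin totals to a uniform expectation.

The simulator's per-class production rates (signatures per copy per kb) are
free parameters: no published per-class rates exist, and the defaults used
in tests are chosen to reflect the qualitative ordering seen in grass
surveys (rDNA highest, then MITEs, then DNA transposons, then
retrotransposons). Tests of proportionality therefore validate estimator
behaviour under the stated generative model, not any organism's true rates.

## rDNA parentage

Classification is nearest-haplotype by substitution distance over columns
where both the read and the haplotype carry an unambiguous base, with a
strict minimum required (ties → ambiguous). Quality filtering, in the
absence of quality scores, means dropping reads with any `N` inside the
block. Gap-column removal uses a strict > 95% threshold. Tree inference is
exported as NEXUS rather than re-implemented: the question answered here —
whether reads bipartition between two parental haplotypes — needs only the
distance classification, and the exported block feeds any external Bayesian
or likelihood tool.

## The synthetic-data generator

The generator emulates: i.i.d. background sequence at GC 0.44; repeat
families as mutated copies of a random master (i.i.d. substitutions at the
family divergence, ≤ 10%), dispersed non-overlapping or tandem-contiguous;
454-style reads (mean 229 bp, optional Gaussian length spread, substitution
errors, homopolymer-weighted indels with per-run probability rate × run
length); sRNA signatures as genomic substrings of planted copies with
Poisson counts proportional to rate × copies × kb and a configurable 24-nt
majority; and rDNA units carrying one of two ITS haplotypes. Placement is
largest-footprint-first with rejection sampling plus an exact free-gap
fallback, so densely packed specs remain feasible.

It does **not** emulate nested insertions, LTR/terminal structure, quality
scores, paired ends, isochore composition, or sequence-dependent sampling
bias. Passing recovery tests therefore demonstrate estimator correctness
under uniform sampling and simple divergence — the model the estimators
themselves assume — and say nothing about, e.g., cloning bias or chimeric
reads in real libraries.

## Problem sizes used by the acceptance suite

The property suites run on a 10-Mbp genome: repeat discovery with families
at copies {10, 100, 500, 2000} (units 0.4–1 kb; the 2000-copy family a
tandem 500-bp array), divergence 0.5% ("highly similar" copies), at
coverage 3 × 0.012 so a 100-copy family expects ≈ 16 reads, averaged over
three replicate read draws; copy-number recovery at c = 0.012 with counts
pooled over four replicate draws (median relative error over ≥ 100-copy
families ≤ 15%); sRNA proportionality with 620 families spanning copies
25–800 at 0.02 signatures/copy/kb across bin widths {25, 50, 100, 200};
parentage on 50 replicate 10:9 two-haplotype mixtures (6 diagnostic sites in
150 bp, 0.5% read error) with at most one misassigned read per replicate on
average. Replicate pooling is a design choice: single sub-percent-coverage
draws leave Poisson noise that would otherwise dominate the quantities under
test.

## Known limitations

* The strict 100%-identity overlap rule under-connects reads from families
  more diverged than ~2% or from error-rich reads; this mirrors the
  detection limit it models (high-copy, highly similar repeats) but means
  recovery claims do not extend to old, diverged families.
* The aligner is a desk-scale tool: seeding is exact-word only, statistics
  are ungapped Karlin–Altschul, and no attempt is made at chaining or
  protein-space alignment.
* Copy-number estimates inherit every bias of the uniform-sampling
  assumption; real 454 libraries show GC- and homopolymer-dependent
  sampling that the simulator deliberately omits.
* `cluster_significance` is computed once per run's parameters, not per
  cluster.
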