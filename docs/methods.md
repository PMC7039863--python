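# Methods

This note documents the models, parameter choices, and numerical behaviour
of sulfur-census, and what the synthetic-data validation does and does not
establish about real metagenomes.

## Profile models and scoring

Each gene family is a Plan7-style profile HMM built from an alignment of
ratified member proteins. An alignment column becomes a match state iff its
gap fraction is below 0.5 (majority occupancy); columns failing the rule
contribute insert-state counts instead. Match emissions are observed
residue frequencies blended with background-proportional pseudocounts of
total mass `pseudocount_weight` (default 1.0 — one pseudo-observation,
enough to avoid zero emissions without washing out small training sets).
Transitions are estimated from the alignment's gap structure with Dirichlet
priors (M→{M,I,D} prior counts 2.0/0.1/0.1, I→{M,I} and D→{M,D} 1.0/1.0);
the strong match prior keeps per-position transition cost near zero for
ungapped training alignments, so bit scores are dominated by emission
log-odds. The background is the Robinson–Robinson amino-acid frequency set.
I→D and D→I transitions are disallowed (standard Plan7 topology).

Scoring is best-path (Viterbi) local alignment in log₂-odds against the
background, with free entry into and free exit from any match state —
appropriate for partial genes from fragmented assemblies. Insert states
emit at background (zero emission score); the ambiguity residue X scores
zero in every state. The implementation is a vectorized dynamic programme
over (sequences × query positions) with the insert recurrence folded into
an affine running maximum; it is checked exactly against brute-force
enumeration of all state paths on small models. Scores are reported in
bits. Forward-sum scoring, glocal mode, and domain splitting are out of
scope.

## Cutoffs and E-values

Per-family bit-score cutoffs are derived from the training data: the
midpoint between the minimum leave-one-out positive score (each positive
scored against a profile rebuilt from the others) and the maximum score of
the different-function negatives. With no negatives the cutoff is the
minimum leave-one-out score minus a margin (default 10 bits). If negatives
overlap positives the cutoff conservatively equals the minimum positive
score and a warning is raised — ambiguous families should be curated, not
silently admitted.

E-values use the extreme-value law of optimal local alignment scores:
`decoy_count` i.i.d. background sequences (minimum 100; default 1000) are
scored and fit with a Gumbel distribution by maximum likelihood, giving
E(S) = N·exp(−λ(S−μ)) for a database of N sequences. The markers use the
conventional cutoffs E ≤ 10⁻⁵⁰ (recA) and E ≤ 10⁻⁶⁰ (β-actin); the "e−50"
notation in BLAST-style reports is read as 10⁻⁵⁰.

## Candidate verification

A profile hit becomes part of the census only if it aligns most closely to
the ratified enzymes: the candidate is Smith–Waterman-aligned (BLOSUM62,
gap open −11 / extend −1) against every positive and negative of its
family and must score strictly higher against a positive. Exact ties fail
(conservative). A gene hitting several family profiles is counted only for
its highest-scoring family. Families shipped without negatives fall back to
cutoff-only acceptance with a warning.

## Gene catalog and abundances

Contigs must exceed 500 bp (strict inequality). Clustering is greedy
incremental over genes sorted by decreasing nucleotide length (ties by
identifier): a gene joins the first cluster whose representative it matches
at ≥95% identity over ≥90% coverage of the shorter sequence, else founds a
cluster; under this order the founding (longest) member is the
representative. Identity and coverage are computed from a semi-global
alignment of the shorter sequence onto the longer (BLOSUM62, affine gaps,
free overhangs of the longer): identity = identical pairs / aligned residue
pairs, coverage = aligned residue pairs / length of the shorter. This is an
exact, testable stand-in for word-based clustering heuristics, whose
behaviour is unspecified at this granularity.

Abundance of gene g in sample s is counts(g,s) / nt_length(g) — reads per
base — with (gene, sample) entries under 2 mapped reads discarded, applied
per sample. The read-floor interacts with the lognormal tail of genome
abundances; see "Known limitations".

## Community fractions

fraction(family, s) = 100 × Σ abundance(verified family genes, s) /
Σ abundance(marker genes within the marker E-cutoff, s), with recA for
bacterial families and β-actin for the eukaryotic families (DSYB, Alma1) —
a static table shipped in `census.FAMILY_DOMAINS`. The quantity estimated
is the *abundance-weighted* fraction of cells whose genome carries the
family, assuming one marker copy per genome. Fractions above 100% (possible
for multi-copy families) are reported unclamped with a warning. Samples
with zero marker signal have undefined fractions for that domain; they are
excluded from group means, which are arithmetic means over samples.

## Taxonomic assignment

A gene's reference hits are filtered at `min_score` (default 50 bits, of
the same era as the default `top_fraction` = 0.10 and minimum support 1 in
MEGAN-style pipelines), then reduced to hits within 10% of the best bit
score, and the gene is assigned to the lowest common ancestor of the
retained taxa; best-hit-only assignment is available as a flag because the
band-then-LCA rule and best-hit selection are both defensible readings of
common practice. Taxon abundances are cumulative (a node includes its
descendants), so they are monotone along lineages and domain totals plus
the separately tracked unassigned mass conserve the table total. Reference
hits are generated with the same BLOSUM62 local aligner used elsewhere;
raw scores are converted to bits and crude E-values with standard gapped
Karlin–Altschul parameters (λ = 0.267, K = 0.041).

## DMSP quantification

Instrument response is regressed on known DMS amounts by ordinary least
squares (≥3 distinct standards; an eight-point ladder is typical). Sample
responses are inverted through the line; amounts under the 0.015 nmol
detection limit are censored and excluded from replicate summaries, which
report mean ± sample SD. Concentrations are nmol g⁻¹ (sediment,
polymetallic sulfide) or nmol L⁻¹ (seawater); the two units are never mixed
in a ratio without an explicit bridge flag, because a per-mass/per-volume
comparison is qualitative. No endogenous-DMS correction is applied — the
measured quantity is total DMSP plus endogenous DMS, and outputs should be
read as such. Environment ratios are ratios of arithmetic means of per-site
mean concentrations. The packaged station table carries per-site means ± SD
for the seven Bohai/Yellow Sea sediment sites and five Okinawa Trough
sediment/polymetallic-sulfide samples, plus three literature seawater
stations stored as dissolved + particulate totals (SD not reported, stored
as 0).

## Synthetic communities: what they emulate, and what they do not

The generator reproduces the *structural* assumptions of the census:
lognormal genome relative abundances (σ default 1.0, a realistic breadth
for marine communities); exactly one single-copy marker per genome; gene
families planted into exactly round(f × n_domain) genomes (deterministic
planting separates sampling noise from planting noise; the ground truth
records both the genome-count carriage and the abundance-weighted cell
fraction); planted sequences derived from the family reference by
substituting exactly round(divergence × length) positions (default 0.30)
with BLOSUM62-biased replacements, no indels by default; background genes
at background residue composition with lengths ~ Normal(200, 40) aa,
truncated at 60; and per-sample counts ~ Poisson(mean_depth ×
genome abundance × gene length / mean gene length). All randomness flows
from one seed through named substreams (community, mutation, counts), so
fixtures are byte-reproducible.

The bundled "ratified" training families are synthetic: random ancestors
(180–240 aa) with five aligned positives at 15% divergence and four
different-function negatives each. They are labelled synthetic throughout
and calibrate the *machinery*, not real enzyme discrimination.

What passing tests therefore show: the scorer, cutoff derivation,
verification, normalization and LCA logic are correct, and the estimator
recovers planted carriage under the stated noise model. What they do not
show: sensitivity at real inter-family divergences (real families share
folds and motifs in ways random ancestors do not), robustness to indels,
frameshifts, chimeric assembly, mapping bias, or contamination — all absent
from the simulator by construction.

## Validation problem sizes

The recovery study used throughout (tests and the acceptance script) plants
carriage truths of {1, 5, 10, 30, 50}% into 200-genome bacterial
communities at ~20 reads per gene, 10 replicate seeds per truth, and
compares estimates to the abundance-weighted truth; companion checks use
100-genome equal-abundance communities at ~50 reads/gene. Oracle
comparisons run ≥200 random tiny profiles (length ≤ 3) for the scorer and
100 random hit subsets of a ~200-node taxonomy for the LCA rule; decoy
control scores 1,000 background sequences per bundled family.

## Known limitations

- The 2-read floor slightly shrinks each gene's effective abundance by the
  factor (1 − e^(−λ)), λ the expected count. When marker and family genes
  differ in length their floors differ, leaving a small (sub-point at 20
  reads/gene) downward bias in fractions; with matched lengths the
  estimator is unbiased. At high coverage the effect vanishes.
- Cutoff derivation assumes the training negatives bracket the hardest
  confusable families; an unrepresented near-neighbour family could still
  cross a derived cutoff.
- The Gumbel fit uses maximum likelihood on full decoy score distributions;
  extreme-tail E-values (≪ decoy resolution) are extrapolations.
- Statistical comparison between environments (beyond descriptive ratios)
  is deliberately not implemented.
- Whether the sub-2-read discard should apply per sample or to counts
  summed across samples is ambiguous in common practice; per (gene, sample)
  is implemented.
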