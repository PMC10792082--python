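# Methods

## Data model and pairing

The interchange representation is long-format TSV (metadata, species
relative abundances in percent, marker values, marker→species map). Absent
(sample, species) combinations are exact zeros, matching MetaPhlAn output
semantics, and per-sample abundance sums are ≤ 100 (an unclassified fraction
may leave them below 100).

Samples are paired **within (subject, visit)**: one pair per subject, visit
and oral site, requiring both a stool and an oral-site sample. Collection
timestamps are not part of the interchange tables, so visit is the pairing
key; when a subject has several candidate samples of one type at the same
visit, the lexicographically smallest sample_id is chosen. This makes
pairing deterministic and permutation-invariant, at the cost of ignoring
collection proximity, which the tables cannot express.

## Overlap analysis

*Detection* is relative abundance strictly greater than a threshold
(default 0, i.e. detected at all). The *prevalence filter* keeps species
detected in at least max(3, ⌈0.10·N⌉) of the N pooled pair samples. The
"at least 3" floor and the 10% fraction coincide at N = 30; taking the max
keeps the rule well defined for small cohorts. Both constants are
configurable. Filtering pools both members of the pair set under analysis
rather than filtering per body site; per-site filtering would make the
retained set depend on which niche is treated as the reference, which the
pooled reading avoids.

The *pairwise overlap frequency* of a species is the fraction of pairs with
detection in both members; the retained "overlapping" set uses an inclusive
≥ 10% bound. The frequency is symmetric in the two niches, and raising the
detection threshold can only lower it (both properties are tested).

*Abundance comparison* uses the paired Wilcoxon signed-rank test over all
pairs, since samples are explicitly paired by subject; an unpaired rank-sum
fallback is exposed as configuration (`paired_test: false`) for sensitivity
analysis. Zero differences are dropped before ranking and tied absolute
differences receive midranks. The null is evaluated exactly — dynamic
programming over all 2^n sign assignments, which handles midranks — when the
effective n (pairs with nonzero difference) is at most 25, and by a
tie-corrected normal approximation with continuity correction above that.
The crossover at 25 keeps the exact path cheap (the DP state is O(n²))
while the approximation error at n > 25 is far below the decision
threshold. A species whose paired differences are all zero has an undefined
statistic; the pipeline reports it as non-significant with a `degenerate_test`
flag rather than failing the whole family.

p values are Benjamini–Hochberg adjusted (delegated to
`statsmodels.stats.multitest`), with one family per oral-site dataset — the
per-site species list — since each site's comparison stands alone.
Significance is strict q < 0.05. A significant species is called
**oral origin** when its oral median exceeds its fecal median, **fecal
origin** in the reverse case, and **indeterminate** otherwise.

Bray–Curtis dissimilarity (Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ), via
`scipy.spatial.distance`) and log10(x + pseudocount) transforms back the
heatmap/ordination outputs; the pseudocount is the smallest nonzero
abundance in the table, a scale-respecting choice when abundances span
orders of magnitude. Non-metric multidimensional scaling itself is treated
as visualization-layer machinery and delegated; only the distance matrix and
a deterministic (sorted) sample ordering are computed here.

## Strain consistency from marker presence/absence

For each species, a sample's *pattern* is the binary vector of its markers
with value strictly above a threshold (default 0 — upstream profiling has
already applied its own presence floor, so no second floor is imposed), over
the species' full marker set in sorted marker_id order. *Coverage* is the
present fraction; samples with coverage ≥ 0.9 (inclusive) are eligible, the
cutoff that separates genuine gene loss from low-depth missingness. The
coverage denominator is the species' full marker set as given by the
supplied marker map.

A subject is *consistent with same-strain colonization* for a species when
any eligible stool pattern is exactly identical to any eligible oral
pattern; every matching oral site is recorded, and individuals are counted
once across species and sites. With several eligible stool samples
(multi-visit subjects), each is tested and any match suffices; all eligible
within-subject stool/oral combinations are compared, without restricting to
same-visit pairs, since the pattern is a property of the colonizing strain
rather than of the visit. Exact identity is deliberately strict and
one-sided: identical patterns may still be different strains (SNPs are
invisible here), so calls are an upper bound on true strain sharing and the
wording is always "consistent with", never "same strain". The default
species list is the five frequently overlapping oral taxa
(*S. parasanguinis*, *H. parainfluenzae*, *S. salivarius*, *S. mitis*,
*V. parvula*); any list can be supplied.

## Synthetic cohort generator

The generator emulates the structure this analysis assumes, with ground
truth, so every stage is testable offline:

- **Design.** Each subject contributes one stool sample and one sample per
  configured oral site, single visit. Defaults: 125 subjects × 4 oral sites
  = 500 stool/oral pairs — the scale of the real multi-cohort dataset — with
  7 planted shared-strain subjects.
- **Composition.** Species pools are oral-adapted (40, including the five
  marker species), gut-adapted (60, never present in oral samples) and
  generalist (10, present in both niches at the niche-native rates; the
  occupancy model has three rates — oral-in-oral 0.9, gut-in-gut 0.95,
  oral-in-gut 0.3 — so generalists reuse the native ones). Presence is
  independent Bernoulli per species; a sample drawing no species at all is
  redrawn. Magnitudes are log-normal(μ = 0, σ = 2) — the standard
  heavy-tailed model for relative-abundance data — and renormalized to sum
  to 100 per sample. The oral-in-gut rate 0.3 puts pairwise overlap
  frequencies in the 10–70% band typical of frequently overlapping oral
  species.
- **Strains.** A strain repertoire starts from the all-present reference and
  loses each marker independently with `gene_loss_prob` (default 0.02 over
  100 markers); draws below the 90%-present floor are rejected, so every
  true repertoire passes the coverage filter, and repertoires of distinct
  strains are made pairwise distinct by rejection sampling, so pattern
  identity ⟺ same planted strain in the noise-free limit. Planted subjects
  get one species at one oral site forced present in both members with the
  identical repertoire; every other within-subject combination carries
  distinct strains.
- **Detection noise.** Each present marker is observed with probability
  1 − `marker_dropout_prob`; absent markers are never falsely detected
  (clade-specific markers are unique to their species by design, and
  one-sided noise keeps noise-free recovery exact). The default is 0: the
  ≥ 90% coverage filter models the post-depth-filter regime in which
  detection of present markers is near-certain, and dropout is an opt-in
  dial for sensitivity analyses. Note that exact pattern matching degrades
  quickly under symmetric dropout (a single missed marker on either side
  breaks identity), which is a property of the method itself, not of the
  simulator.
- **Determinism.** One `numpy` Generator seeded from `seed` drives every
  draw in fixed order; equal configs give bit-identical cohorts and TSVs.

What the generator does **not** emulate: read-level sequencing, unequal
per-site pair counts, per-species occupancy heterogeneity (all oral species
share one oral-in-gut rate, so overlap frequencies cluster instead of
spanning 10–70% within one cohort), gut species appearing at trace levels in
oral samples (so fecal-origin calls arise only from real or hand-built
tables), correlated abundances between niches, and SNP-level strain
variation. Passing tests therefore show the statistics and the caller are
correct under the stated model, not that the biological conclusions transfer
to any particular real cohort.

## Numerical choices and degenerate inputs

- Presence/eligibility boundaries: detection strict (>), overlap and
  coverage inclusive (≥), significance strict (<) — each matching the
  wording of the corresponding rule.
- Ties: equal overlap frequencies order lexicographically; equal absolute
  differences get midranks; pairing ties break to the smallest sample_id.
- Degenerate inputs: empty sample lists, empty pair sets, both-zero vectors
  for Bray–Curtis, and all-zero paired differences raise typed errors;
  empty marker files load with a warning; a species entirely absent from the
  table has overlap frequency 0 rather than erroring.
- Problem sizes in the test suite (pool sizes ~20–60 species, 40–100
  markers, cohorts of 12–500 subjects) were chosen as the smallest that
  exercise every structural feature; the calibration checks use 500 pairs
  and 100 seeds per occupancy level so the 99% binomial interval is
  informative.

## Known limitations

- Visit-based pairing cannot reproduce proximity-based pairing when a
  subject has several same-visit candidates; the tie-break is deterministic
  but arbitrary.
- The "≥ 3 occurrences" prevalence reading treats occurrence as presence in
  a sample; with relative abundances, a within-sample count reading is not
  computable.
- Whether the original per-site analyses used a paired or unpaired Wilcoxon
  is not recoverable from the statistics alone; both are implemented, paired
  by default.
- Strain-consistency calls are upper bounds by construction; they cannot
  confirm same-strain colonization, only fail to rule it out.
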