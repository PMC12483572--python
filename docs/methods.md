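# Methods

This note documents the statistical procedures implemented in `kinstruct`,
the conventions adopted where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Kin-type inventories

All statistics are computed over an explicit *inventory*: a set of kin types
split into G⁰ (Ego's siblings and cousins) and G⁺¹ (parents and parents'
siblings), plus a set of parent–child links. Links are data, never parsed
from the code strings. Two presets ship with the package:

- **`default`** — 10 G⁺¹ types (M, F, and aunts/uncles split by side ×
  gender × relative age), 20 G⁰ types (siblings by gender × relative age,
  plus a son and daughter per aunt/uncle), 24 links. Siblings link to both
  mother and father; each cousin links only to its connecting aunt/uncle.
  This is a documented approximation of the inventories used in large
  kinship databases (which distinguish up to 60 kin types over these two
  generations, with source-specific cleaning rules); the inventory is
  configuration-driven precisely so that a different catalogue can be
  declared without code changes.
- **`experiment16`** — the 16-referent space of the generalisation
  experiment: 6 G⁺¹ and 10 G⁰ referents, 12 links.

Affinal (in-law) relations are out of scope throughout; only consanguineal
meanings are modelled. Term forms are normalized as Unicode NFC plus
surrounding-whitespace trim; case is preserved, since orthographic case can
be contrastive in source transcriptions.

## Symmetric conditional entropy

The joint distribution p(T₀, T₁) places **uniform weight on each
parent–child link** whose two endpoints both carry a term; identical term
pairs accumulate. Uniform link weighting is the minimal assumption — no
usage frequencies are available for most languages — and reproduces the
endpoint behaviour (H_sym = 0 for one-to-one matchings, maximal for
independent uniform pairings). Entropies are in bits (log₂), with
0·log 0 := 0. The two marginals are role-indexed: a string used in both
generations is one label inside a joint cell, but conditioning is always on
the role (parent term vs child term), not on string identity across roles.

Missing data are handled by pairwise deletion: a link is dropped when either
endpoint lacks a term, and a system enters the analysis only if it assigns
at least one term in each generation (the *analysability filter*). This
mirrors corpus practice of computing predictive structure over whatever
terminology is documented.

## Permutation baselines

Each system is compared to its own null distribution: the multiset of G⁰
forms is shuffled uniformly over the *assigned* G⁰ kin types (missing slots
stay missing, G⁺¹ untouched), the statistic is recomputed, and the observed
value is z-scored against the baseline mean and population standard
deviation. Keeping missing slots fixed keeps the number of observed pairs
constant across permutations, so permuted systems are always analysable.

Conventions:

- 1,000 permutations by default; significance threshold |z| > 1.96
  (two-sided p = 0.05).
- **Degenerate spread**: when the baseline sd is 0 — e.g. a single G⁰ term,
  where every permutation is identical — z := 0. Such a system cannot beat
  its baseline. Baseline spread below 1e−12 is treated as summation jitter
  on identical values and handled the same way.
- An empirical-percentile classification (observed beyond the 5%/95% tails
  of the baseline sample) is reported alongside the z-based one; the two can
  disagree when the baseline is skewed, so both readings are exposed rather
  than resolved.
- Reproducibility: one root seed; per-system streams are derived as
  SHA-256(root seed, system id) mod 2³¹, so corpus runs are order-independent
  and individually re-runnable.

## Compositionality

Wordform similarity between the terms at the two ends of each link is
measured as Levenshtein distance (unit-cost insertions, deletions,
replacements over Unicode code points of the NFC-normalized strings — so
diacritics count as differences) divided by the length of the longer string.
The per-system statistic is the mean over observed links, weighted by link
multiplicity — consistent with the entropy distribution's link weighting; a
deduplicated (`unique_pairs`) mode is provided as an option. The same
G⁰-shuffling baseline classifies systems as compositional (significantly low
mean distance), anti-compositional (significantly high: form resemblance
sits on non-parent-child pairs), or neither. Orthographic rather than
phonemic forms are compared; the two are strongly correlated in practice,
but no segmentation or affix discovery is attempted.

The Levenshtein primitive is computed with `edlib`; the test suite verifies
it against an independent recursive oracle (exhaustively over all string
pairs of length ≤ 3 on a four-letter alphabet, plus a seeded random sample
of 5,000 longer pairs up to length 6 — sizes chosen to keep the exhaustive
check tractable while covering every short-string alignment case).

## Generalisation experiment

Trials present the `experiment16` tree with all six G⁺¹ labels and two G⁰
labels given; the remaining eight G⁰ referents are labelled one at a time,
in uniformly random order, from four candidates (the two given forms plus
two novel forms). Eight *system types* vary the partition of the four
aunts/uncles into term classes (mother and father always distinct):

| type | aunt/uncle classes |
|---|---|
| I | all four together |
| II_side | maternal vs paternal |
| II_gen | aunts vs uncles |
| II_opp | same-gender-as-parent vs opposite |
| III_fb / III_mz / III_mb / III_fz | one singled out vs the rest |

The exact partitions used in any particular published experiment are a
matter of configuration; these eight are the package defaults and are fully
reconstructible from the `SystemType` objects.

Trial construction samples a hidden predictive map from *child groups*
(G⁰ referents grouped by their parents' term classes; the two siblings
always form one group) to distinct unused forms, and reveals it on one
referent in each of two different groups — giving input consistent with a
maximally predictive system while leaving the remaining distinctions open.

**Choice coding.** A choice is *predictive* (1) iff it lies in the argmin of
partial-system H_sym over the four candidates, given the labels fixed so
far; partial systems use only links with both endpoints labelled (the same
pairwise deletion as the corpus analysis). Ties are resolved inclusively —
any member of the argmin set counts — and the argmin size is logged
(`n_argmin`) so analyses can restrict to uniquely-diagnostic choices, where
a uniform-random responder is predictive exactly 25% of the time.

**System scoring.** Completed systems are z-scored like corpus languages,
shuffling all ten G⁰ forms over the ten G⁰ referents; the given labels are
included in the shuffle by default (an exclude-given mode is provided).
`ideal_predictive_completion` finds the global H_sym minimum by exhaustive
search over the ≤ 4⁸ candidate assignments; for every default system type
the minimum is 1/3 bit — the irreducible uncertainty from mother and father
being distinct while sharing children.

Mixed-effects regression modelling of the coded choices is deliberately out
of scope: the module exports tidy coded tables (choice-level flags,
per-type proportions, co-occurrence long tables, gender-distinction coding,
per-participant z) for external model fitting.

## Synthetic data

`generate_system` plants controllable structure: G⁺¹ kin types are
partitioned into `n_g1_terms` classes (uniformly, with one anchor per class
to guarantee none is empty), each class maps injectively to a G⁰ base term,
and each G⁰ kin type takes its parent class's base term with probability ρ,
else a uniform draw from the G⁰ term pool; assignments are then erased
independently at the missingness rate. Defaults (8 terms per generation,
ρ = 1, no missingness) give corpora whose recovery behaviour brackets the
analysis: at ρ = 1 essentially every language is classified significantly
low, at ρ = 0 roughly the nominal 5%.

Where a G⁰ kin type has parents in two different classes (siblings link to
both mother and father), the first-listed link decides the class used for
the base term. The noise model is per-slot resampling — simple and monotone
in ρ; it is a stand-in for exercising the statistics, not a model of
historical kin-term change. Generated corpora therefore lack several
features of real data: no families or areal dependence between languages, no
synonymy, no orthographic noise, and wordforms that carry no morphological
structure (so synthetic corpora are non-compositional by construction).
Passing recovery tests shows the estimator and its baseline behave correctly
under the planted model, not that real corpora satisfy that model.

Ground-truth parameters are written to a separate file from the generated
corpus so the analysis path never sees them.

Simulated participants implement three policies: `random` (uniform over the
four candidates), `predictive_greedy` (uniform over the current H_sym argmin
set — by construction its completions attain the exhaustive-search minimum),
and `gender_biased` (with probability *g*, candidates matching the form of
the already-labelled opposite-gender counterpart are excluded before acting
predictively; at *g* = 1 every gender-paired duo ends up distinguished).

## Problem sizes and numerical choices

Default test and example runs use 12–100 languages per corpus, 100–1,000
permutations per system, and cohorts of up to 150 simulated participants;
the oracle-equivalence checks sweep 1,000 random small systems against a
direct grouped-summation entropy oracle (agreement to 1e−9). Entropy ties in
choice coding are compared at 1e−9; joint distributions are validated to sum
to 1 within 1e−9. All randomness flows from explicit seeds through
`numpy.random.Generator`.

## Known limitations

- The default inventory is an approximation, not a reproduction of any
  specific database's kin-type catalogue; corpus-level percentages depend on
  the inventory and cleaning rules used.
- Uniform link weighting ignores referent frequency; a frequency-weighted
  joint distribution would require usage data the package does not model.
- Synonym handling on read keeps the first listed form per (language, kin
  type) by default; alternative policies are configuration.
- The compositionality measure sees only parent–child form similarity;
  within-generation morphological structure registers, if at all, as
  *anti*-compositionality.
- No phylogenetic or areal correction is applied across languages; each
  system is tested against its own baseline and summaries are raw
  proportions.
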