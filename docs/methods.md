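# Methods

## The trait model

Denitrification potential is treated as a strain-level ecological trait
inferred purely from gene presence/absence: a genome *can* catalyze a
reduction step iff it encodes at least one complete enzyme complex for that
step. The model is a monotone boolean function per step — a disjunction of
conjunctions over gene symbols:

- nitrate → nitrite: `(narG ∧ narH ∧ narI) ∨ (napA ∧ napB)`
- nitrite → nitric oxide: `nirK ∨ nirS`
- nitric oxide → nitrous oxide: `(norB ∧ norC) ∨ (norV ∧ norW)`
- nitrous oxide → dinitrogen: `nosZ`

The complete-complex requirement is load-bearing: a genome carrying *norB*
without *norC* (e.g. the Haloferax volcanii DS2 pattern `110001010000`)
scores `0` on step 3, and *napB* without *napA* scores `0` on step 1. The
12 digits give 4096 possible enzyme patterns; because each step is
independently satisfiable and refutable, the rules map them onto all
2⁴ = 16 step codes. Preimage sizes follow from per-step inclusion–exclusion
(11/32 patterns satisfy step 1, 3/4 step 2, 7/16 step 3, 1/2 step 4; hence
11·3·7·1 = 231 patterns code as `1111` and 21·1·9·1 = 189 as `0000`), and
the test suite verifies the engine against an independently coded
truth-table oracle on all 4096 inputs.

Assumptions and limits of the model: annotation presence is taken at face
value (no homology search, no correction for draft-genome incompleteness);
regulation, expression and environmental modifiers of realized
denitrification rates are entirely outside scope; alternative subunits or
non-canonical reductases beyond the 12 catalog genes are not modelled.

## Trait names

Names are generated compositionally: the all-zero code is "Incomplete
Enzymes for Denitrification Steps", the all-one code "Complete
Denitrification", and every other code lists its satisfied step names
joined with commas and a final " and " (no Oxford comma), suffixed
" Reduction Only" — e.g. `1011` → "Nitrate, Nitric Oxide and Nitrous Oxide
Reduction Only". Name comparison downstream is case-insensitive. Generating
all 16 names from one rule keeps them injective and covers codes that are
rarely observed in real collections.

## Rulesets are data

A `TraitRuleSet` is an ordered list of steps, each a list of gene-symbol
sets (alternatives), validated against an `EnzymeCatalog` that fixes digit
order. Rulesets serialize to YAML, so new trait schemes need no code. The
packaged nitrogen-fixation instance (structural NifHDK, biosynthetic
NifENB) exercises this generality; its non-nifH KO identifiers are the
standard KEGG entries.

## Dataset assembly

Inputs are IMG/M-dialect per-KO genome lists (Domain / Status / Genome ID /
Genome Name; TSV preferred, CSV accepted) labelled `01_narG` … `12_nosZ`,
plus an optional metadata table. Design choices where the input contract is
loose:

- Genome identity is Genome ID; name conflicts between lists resolve
  first-seen-wins (catalog label order, then row order) with a logged
  warning.
- Duplicate rows within one KO list collapse to a single membership;
  presence is boolean.
- Genome names are whitespace-normalized (trim + collapse runs) before
  genus derivation and replicate detection.
- The genus is the literal text before the first space of the genome name.
  This mis-generalizes "Candidatus ..." names to "Candidatus"; that is the
  defined behaviour of the lexical rule, and the GTDB-Tk genus column is
  the taxonomic alternative.
- Genomes with an all-zero pattern are excluded at build time (inclusion
  criterion: at least one denitrifying enzyme) with the excluded count
  logged; the rule engine itself still maps the all-zero pattern to `0000`
  so the rule map stays total.
- Replicate strains are exact normalized-name matches with ≥ 2 genome
  records; culture-collection synonyms (e.g. a strain listed once under
  its isolate tag and once under a DSM number) are treated as distinct
  strains.
- Missing annotation stays as a true missing value in the table and is
  rendered as the explicit label "Null" only in grouped summaries.
- Pattern columns (4- and 12-digit) are typed as text in every export;
  spreadsheet numeric coercion would turn "0100" into 100.

Auxiliary-pathway annotation is generic over any KO list (nifH, glnA,
nasA, K01601 carbon fixation, ...): one boolean column per KO plus a count
table with an example genome per KO.

## Synthetic cohorts

The generator emulates the structure of the real inputs — per-KO list
files, a metadata table, replicate names, auxiliary carriers — with a
planted trait distribution, so end-to-end recovery can be asserted
exactly. Choices:

- `trait_weights` defaults to the uniform distribution over the 16 codes;
  within a code, patterns are drawn uniformly from the code's preimage.
  Uniformity maximizes coverage of rule-engine edge cases; it does not
  mimic any real collection's abundances (real collections concentrate on
  a few hundred of the 4096 patterns).
- The all-zero pattern is never emitted: such a genome appears in no KO
  list and could not be observed by the pipeline at all.
- `replicate_rate` (default 0.05) re-issues an existing genome name under
  a fresh Genome ID, mirroring strains with multiple sequenced genomes.
- `missing_ecosystem_rate` (default 0.2) plants genomes with no ecosystem
  annotation, exercising the "Null" rendering path; taxonomy and ecosystem
  pools are small realistic tuples (GTDB-style lineages, GOLD-style
  5-level habitats).
- All randomness flows from one mandatory integer seed through a single
  `numpy` generator; identical spec + seed yields byte-identical files.

What passing on synthetic cohorts does *not* show: robustness to real
IMG/M export quirks beyond the ones modelled (delimiter variation,
duplicate rows, name conflicts, missing annotation), or anything about
annotation quality in real genomes.

The packaged published reference records (nine archaeal trait-category
examples with their enzyme patterns; the 21 archaeal genomes carrying both
nirK and nirS) are byte-faithful transcriptions of printed tables and
serve as ground truth for the analytics operations: the 21-row
dual-reductase filter, 18 distinct strains, 7 genera, ecosystem tallies
(Aquatic 9, Terrestrial 8, Fish 2, Food production 2), and the three
replicate strain names.

## Problem sizes and numerics

Everything is exact integer/boolean computation; there are no tolerances,
no optimization and no floating-point sensitivity anywhere in the model.
Exhaustive enumeration over 4096 patterns runs in well under a second.
End-to-end recovery tests run at n = 300–1000 genomes and the trait
frequency sanity check (chi-square against planted weights, p > 1e-4) at
n = 10,000 — sizes chosen so the full suite completes in seconds while
every code path, including replicates and missing annotation, is
exercised.

## Reporting helpers

Scholar search texts are rendered, never executed: plain mode
`denitrification <symbol>`, negation mode `("<phrase> of <symbol>"
denitrification)` with the fixed negation vocabulary (absence, lack,
lacking, missing, no, not possess, not with, without). The genome-portal
URL for a KO is produced from the documented IMG/M find-KO-genome-list
template by substitution only; no network access is performed anywhere in
the package.
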