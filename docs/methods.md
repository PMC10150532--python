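# Methods

`pahtrait` implements a genome-mining pipeline for polycyclic aromatic
hydrocarbon (PAH) degradation capacity: a curated reference database of
17 catabolic gene families, profile hidden Markov models with calibrated
gathering thresholds, genome annotation by both similarity and HMM
search, catabolic gene-cluster completeness classification, and a
random-forest genotype→phenotype harness with group-consistency
filtering.  This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Reference database

The database models three catabolic cluster types distinguished by
degradation mechanism: `nah` (Gram-negative naphthalene pathway, 5
genes: nahAc, nahB, nahC, nahD, nahE), `nar` (Gram-positive
Rhodococcus-type pathway, 4 genes: narAa, narAb, narB, narC) and
`nid_phd` (Mycobacteriaceae pyrene/phenanthrene pathway, 8 genes: nidA,
nidB, nidD, phdE, phdF, phdG, phdI, phdJ).  nahE, phdJ and narC encode
the hydratase-aldolase superfamily — structurally conserved
N-acetylneuraminate-lyase-fold enzymes that cross-match between pathways
and serve as the degrader biomarker.  nahF and phdK are rejected at load
time: families without phylogenetic conservation admit no gathering
threshold that is simultaneously sensitive and specific.

The packaged "full" fixture is generated programmatically
(`fixtures.build_reference_database`).  Its per-cluster totals equal the
published ones (nah 843 = 71%, nid+phd 310 = 26%, nar 38 = 3%; 1,191
total); the per-family split within each cluster and all residues are
synthetic, as is the 95-strain / 42-genus catalog fixture.  Quantities
of record are the count tables, not the residues.

## Profile HMMs

Each family model is a standard match/insert/delete profile estimated
from a multiple alignment:

- **Alignment.** The built-in engine is a deterministic center-star
  aligner over unit-cost Needleman–Wunsch pairwise alignments (edlib);
  the center and merge schedule depend only on the sequence *set*, so
  profiles are invariant to input order.  MAFFT can be substituted
  (`align_family(..., engine="mafft")`); pre-computed alignments load
  verbatim.
- **Match states.** Columns with gap fraction ≤ 0.5.
- **Emissions and transitions.** Row-frequency estimates mixed with the
  background at a single pseudocount weight:
  `p = (f + w·bg) / (1 + w)` with default `w = 1`.  Using frequencies
  (not raw counts) makes duplicating every row a no-op.  Insert
  emissions are pooled over all insert columns; with no observed insert
  residues they default to the background.  The background is uniform
  (1/20) by default and overridable — no biological composition is
  assumed.
- **Scoring.** Viterbi (best-path) log₂-odds in local mode, reported in
  bits.  The local layer is fully specified so scores are reproducible
  to the bit: entry into match state *k* (0-based, length *L*) costs
  `log2(1/L)`; every continuation out of a match state is scaled by
  `1 − 1/(L−k)`; exit from *k* costs `log2(1/(L−k))`; flanking residues
  are emitted by the background at zero bits.  Unknown residues (X and
  mapped B/Z/U) emit at background everywhere, contributing zero bits.
  A numba kernel computes the recursion; the test suite checks it
  against exhaustive path enumeration on small profiles.

Forward/posterior scoring, E-values and multihit modes are out of scope;
the gathering-threshold logic is keyed only on bit scores and accepts
any engine exposing them.

## Gathering-threshold calibration

Per family: members and the negative pool are split 2:1 (seeded); the
profile is built on training members; the GA is the threshold maximizing
Youden's J = Sn + Sp − 1 over candidate cutoffs (the observed scores
plus one value above the maximum), ties broken toward the highest
threshold; held-out Sn/Sp are measured on the test halves; a model is
**retained** only when both strictly exceed 0.90.

Two choices deserve emphasis:

- **Negatives.**  The pool joins all members of the other families
  (cross-family discrimination — the hard case for the mutually
  homologous dioxygenase large subunits nahAc/nidA/narAa) with
  residue-shuffled permutations of the family's own members
  (composition-matched random decoys), 60 by default.
- **Jackknifed training scores.**  A member's own residues inflate the
  emission frequencies of a profile trained on it, so raw training
  scores are biased high; with clean separation the Youden-optimal GA is
  the *lowest training score*, and a biased minimum lands above much of
  the held-out distribution.  Training positives are therefore scored
  leave-self-out during GA optimization, making training and held-out
  scores exchangeable.  A consequence worth knowing: with GA at the
  training minimum, a family is retained only when no held-out member
  scores below it — under exchangeability roughly `n_train/(n_train +
  n_test)` ≈ 2/3 of calibrations per family at the default split.  The
  retention flag is doing its job: non-retained models are recalibrated
  or examined, not trusted.

**Leave-one-out curation** flags members whose removal improves Sn + Sp
by ≥ δ (default 0.05).  The validation used inside the loop is
split-free: each member is scored leave-self-out and counts as recovered
iff it clears the *negative ceiling* — the maximum negative score plus a
separation margin (30 bits).  The margin dominates the few-bit
fluctuation of the negative maximum while remaining far below the
hundreds of bits separating true members from decoys; an incoherent
member is then never self-admitted, its removal lifts Sn by exactly 1/n,
and a coherent member's removal changes nothing.  δ should stay below
1/n for the family size under curation.

**Expansion** scores a candidate pool against all calibrated models each
pass; candidates at or above a GA join their top-scoring family, models
are recalibrated, families falling out of retention revert, and the loop
stops when a pass adds nothing.

## Annotation

Two routes, mirroring field practice:

- **Similarity**: local pairwise alignment (BLOSUM62, gap open 11 /
  extend 1, via Biopython) against every reference; a hit needs identity
  > 0.70 (identical columns / alignment columns, gaps included) *and*
  hit-length ratio > 0.70 (alignment columns / reference length — the
  reference denominator guards against fragment matches).
- **HMM**: bit score ≥ the family's GA, all passing families recorded
  per protein.

A multi-family protein is assigned to its top-scoring family with the
runners-up kept as an ambiguity record; ambiguity *within* the
hydratase-aldolase superfamily raises an explicit flag rather than being
collapsed — the pipeline reports the confusion, it does not resolve it.
The per-genome feature vector is the maximum passing bit score per
family (0 when absent; the raw score, not a GA-relative one).  Group
tags come from the lineage: Mycobacteriaceae is its own stratum; else
phylum → Gram group via an overridable lookup.  Genomes arrive as
GenBank flat files (CDS translations, or table-11 translation from
coordinates; plasmid/chromosome from source features) or protein FASTA
(replicons unknown).  A naive ATG→stop ORF caller (table 11, both
strands, ≥100 aa) supports nucleotide-only simulations; gene calling
fidelity is not this package's contribution and pre-computed proteins
are the primary path.

## Completeness

Per cluster type: `complete` (all genes), `near_complete` (exactly one
missing), `partial`, `absent`.  Genes count anywhere in the genome
(chromosome or plasmid).  narAa/narAb co-occurring with nid/phd genes is
reported as a note, not merged into completeness.  The biomarker screen
flags any of nahE/phdJ/narC.  Ranking orders genomes by best status,
ties by summed bit score.

## Trait prediction

One random forest per stratum (scikit-learn learner inside a bespoke
harness): `n_tree` fixed at 2000; `m_try` swept 1–17 and selected as the
smallest value within 0.002 of the minimum out-of-bag error (a
reproducible reading of "levels off"); training negatives subsampled to
`round(ratio × n_positives × split)` with ratio ∈ [3, 8] (default 5),
test side untouched.  Metrics are Sn, Sp, Acc and MCC computed exactly
from the confusion matrix, with zero-denominator cases reported as
undefined (`None`), never silently 0.  "Mean decrease accuracy" is
permutation importance on the held-out split; "mean decrease Gini" is
the forest's impurity importance.  A positive call is *output* only when
group-consistent: Gram-negative requires nah evidence, Gram-positive nar
or nid/phd, Mycobacteriaceae nid/phd only.

## Synthetic data

Families: ancestor drawn from the background; members by per-site
substitutions (uniform over the 19 alternatives — controllable
divergence, not biological realism) and rare single-residue indels.
Defaults are the calibration study conditions: 30 members, 300 residues,
substitution rate 0.10 (expected pairwise identity
`(1−r)² + r²/19 ≈ 0.81`), indel rate 0.01.  Decoys are i.i.d. background
draws.  Genomes reverse-translate planted genes with fixed
most-frequent codons among random background ORFs; planted genes derive
from the family *ancestor* (default divergence 0.05), making them
statistically typical members that clear the GA.  Cohorts label
degraders (full cluster of an assigned type, group tag matching the
mechanism) against non-degraders (decoys only; a confounder fraction
carries one stray gene from a cluster mismatched with its group — the
case the consistency filter must suppress), with seeded label noise and
a recorded flip list.

What the generator does *not* emulate: phylogenetic structure and rate
heterogeneity within families, biased amino-acid composition, paralogs,
fragmented assemblies, and contamination.  Passing tests therefore
demonstrate the pipeline's correctness and its behaviour in a separable
regime, not performance on real genomes; in particular real families
have broader score distributions, which changes retention rates and GA
placement quantitatively.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale: 5–17 families of
8–30 members, cohorts of ~120 genomes with ≤ 13 proteins each — sizes
chosen so the full pipeline (including the 3 × 17-point m_try sweep at
2000 trees) completes in minutes on one core.  All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; reruns are
bit-identical.  Probability distributions are validated to sum to 1
within 1e-9; scores are float64 throughout; degenerate inputs (empty
sequences, single-class training sets, empty cohorts, all-gap columns,
zero-denominator metrics) raise typed errors rather than returning
sentinel numbers.

## Known limitations

- The built-in Viterbi scorer is not score-compatible with HMMER's
  (different pseudocounts, no entropy weighting, simplified local
  layer); GA values are meaningful only relative to the engine that
  produced them.
- Retention at the 2/3 split is an order statistic (see above); small
  families give coarse Sn/Sp resolution, and families under 3 members
  refuse automatic calibration.
- The similarity route scales as queries × references and is intended
  for focused panels, not genome-wide sweeps.
- Completeness treats gene presence as binary evidence and ignores
  synteny; cluster co-localization is not assessed.
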