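# Methods

## Model

`metlike` quantifies the *metabolite-likeness* of a drug as the Tanimoto
coefficient between binary substructure fingerprints:

    T_c(A, B) = C / (A + B - C)

with `A`, `B` the set-bit counts of the two fingerprints and `C` the
shared-bit count (the Jaccard index on bit sets). The working hypothesis
is that a drug strongly resembling an enzyme's substrate can occupy the
same binding site and modulate the enzyme — the mechanism of the
antimetabolite drug class, which is therefore used as the known-true
validation set.

The pipeline is: fingerprint everything → full drug × metabolite matrix →
(optionally) clustered-heat-map block detection → gold-standard selection
→ per-relation significance → ROC/Youden threshold calibration →
candidate enumeration. Each stage is a pure function of the similarity
matrix and small relation tables, so all downstream statistics are exactly
reproducible from the matrix alone.

## Fingerprints

* **Scheme.** The 166-key MACCS set, stored RDKit-style in a 167-slot
  vector with slot 0 unused. MACCS keys are the conventional public
  substructure key set for small-molecule similarity and the scheme under
  which the bundled reference similarities were computed.
* **Salt stripping** (default on). Database records often carry
  counter-ions; fingerprints are computed on the largest
  carbon-containing fragment. Reference values evidently refer to parent
  structures.
* **Empty pair convention.** `T_c` of two all-zero fingerprints is defined
  as 1.0 (identical, if empty, feature sets) with an explicit warning.
  This case cannot arise for MACCS keys of organic molecules but can for
  synthetic vectors.

## Similarity matrix and cluster highlights

The matrix is computed densely (integer dot products of the stacked bit
matrices); at the scale of a full approved-drug × metabolome screen
(~2 × 10⁶ cells) this is still a desk-size object.

Row and column dendrograms use **complete linkage** on
`d = 1 − Pearson r` between similarity profiles (`1 − cosine` available),
the standard choice for similarity heat maps; the source procedure names
the linkage but not the metric, so the metric is this package's choice.
Constant profiles, whose correlation is undefined, are assigned the
metric's maximal distance.

A *highlight* is a (row-subtree, column-subtree) pair satisfying all of:
more than 50 drugs, more than 100 metabolites, and a fraction ≥ 0.30 of
cells at `T_c ≥ 0.7` ("almost 30 %" is operationalised as ≥ 0.30 exactly,
configurable). All subtree pairs of the two dendrograms are scanned and
nested qualifying pairs are reduced to the maximal ones — a programmatic
formalisation of blocks that are usually read off a heat map visually.

## Gold-standard selection

For each curated (drug, enzyme) pair, the substrate with the highest
similarity to the drug is chosen among the enzyme's substrates (ubiquitous
co-substrates — water, cofactors — are excluded from substrate lists
upstream). The relation is kept only if that similarity is **strictly**
greater than 0.5; a weakly similar antimetabolite presumably acts through
a different mechanism. A drug may map to several enzymes (each pair
yields at most one relation); an exact similarity tie between substrates
keeps both with a warning rather than discarding information silently.

## Significance

For a metabolite, the similarity scores to the *entire* drug collection
(including the query drug itself) form the null distribution; a relation's
score is standardised (`z = (score − mean)/sd`, sample sd with the n − 1
denominator) and assigned the one-sided upper-tail normal probability.
A labelled empirical-percentile mode exists, but note its floor of 1/n —
strongly similar pairs have far smaller tail probabilities, which is why
the normal-tail form is the default. A constant similarity column raises
a typed degenerate-distribution error. No multiple-testing correction is
applied; the p-values are reported raw.

## Threshold calibration

Every (drug, gold-standard enzyme) relation is scored by the drug's
maximal similarity over the enzyme's gold-standard substrates and
labelled positive iff the relation itself is gold standard. The score
classifies via `score ≥ t ⇒ modulator`; the threshold grid is every
distinct observed score plus a sentinel above the maximum, so the ROC is
the exact step function. AUC is the trapezoidal area (equal to the
Mann–Whitney concordant-pair statistic, which the test suite verifies
against an independent pair-counting oracle). The operating threshold
maximises `J = Se + Sp − 1`; a tie resolves to the **higher** (more
specific) threshold. On a full-scale screen this calibration yields a
threshold of ~0.654; the bundled benchmark uses that published value when
enumerating reference candidates, since the 19-drug fixture universe is
itself almost entirely antimetabolites and cannot stand in for the
approved-drug background (its desk-scale AUC is ~0.83).

## Candidate prediction

Per enzyme, every drug whose max-substrate similarity is ≥ threshold
(inclusive — this keeps the gold-standard relations themselves above the
cutoff) is a candidate, minus two exclusions: the enzyme's own
gold-standard drugs, and the endogenous ligand (similarity 1.0 to the
substrate or an identical id). Candidates are ranked by descending
similarity with drug-id tie-breaks; an enzyme whose only passing relation
is its own gold-standard one yields an empty list (xanthine dehydrogenase
behaves this way on the bundled benchmark).

## Synthetic data

The generator emulates binary fingerprints only as **independent
Bernoulli(p) bit vectors** (default length 1024, density 0.2), which gives
a background expectation `E[T_c] ≈ p/(2 − p) ≈ 0.11` — comparable to the
low background of real drug–metabolite screens. A planted drug is derived
from its metabolite by flipping every bit independently at the
closed-form rate

    q = m(1 - t) / (t(L - m) + m)

(`m` = metabolite popcount, `L` = length, `t` = target similarity), chosen
so the ratio of expected shared to expected united bits equals `t`; the
Jensen bias of the realised ratio is O(1/L). Target 1.0 copies the vector
exactly; targets outside (0, 1] raise a typed infeasibility error.

What the generator does **not** emulate: the strong inter-bit correlations
of real substructure keys, size-dependent popcounts, or structural salt
and tautomer ambiguity. Passing synthetic tests therefore demonstrates the
correctness of the statistical machinery (selection, labelling, ROC,
Youden, enumeration), not chemical realism — that is what the bundled
real-structure benchmark is for.

## Numerical choices

* Similarities are reported to 2 decimals in human-readable tables
  (3 decimals for candidate reports), full precision in machine formats;
  matrix exports round-trip losslessly (`%.17g` + round-trip parsing).
* Determinism: fixed inputs give bit-identical matrices; all orderings
  have explicit tie-breaks (enzyme label, then score descending, then
  drug id); the synthetic generator is fully seeded.
* Degenerate inputs are typed errors (single-class ROC, constant
  similarity column, infeasible planted target) or warnings with defined
  behaviour (empty-fingerprint pair, substrate/candidate ties).

## Known limitations

* **Structure-form sensitivity.** MACCS-Tanimoto values shift by a few
  hundredths with protonation/tautomer choices. With the bundled neutral
  parent forms, most reference pairs reproduce exactly after rounding
  (including azacitidine–cytidine 0.97, decitabine–cytidine 0.88 and
  levoleucovorin–10-formyl-THF 0.969, and every best-candidate row); a
  handful deviate by 0.01–0.04 (pemetrexed and raltitrexed against the
  folates, capecitabine–dUMP, fludarabine–ADP), and allopurinol–
  hypoxanthine computes to 0.86 against a reference 0.69 under every
  tautomer combination tried. These discrepancies are reported as-is
  rather than tuned away. One knock-on effect: recomputed gold-standard
  selection picks tetrahydrofolate (0.871) rather than 7,8-dihydrofolate
  (0.844) as pemetrexed's best DHFR substrate, so the recomputed distinct
  substrate count is 14 where the reference relation table has 15.
* **Desk scale.** The bundled benchmark is a 19 × 15 matrix; full-scale
  quantities (global AUC, the 0.654 threshold, per-enzyme candidate
  counts, heat-map clusters) require the complete approved-drug and
  metabolome structure sets, which are not bundled. Cluster detection is
  exercised on simulated planted-block matrices (210 × 420 with a
  60 × 120 block); calibration properties on seeded synthetic universes
  (400 + 400 labelled scores; 20,000-draw null calibration).
* The curation chain from drug databases to enzyme substrate lists is the
  user's input (delimited tables), not automated retrieval.
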