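# metlike

Drug repositioning to enzyme modulators via **metabolite-likeness**.

Most endogenous metabolites have interaction partners among metabolic
enzymes, and a drug that structurally resembles an enzyme's substrate is a
plausible modulator of that enzyme — the mechanism that makes the
antimetabolite drug class work. `metlike` turns this idea into a screening
pipeline for cheminformaticians and drug-repositioning researchers:

1. **Similarity matrix** — encode every drug and metabolite as a 166-key
   MACCS substructure fingerprint and score all pairs with the Tanimoto
   coefficient
   *T<sub>c</sub>(A, B) = C / (A + B − C)*,
   where *A* and *B* are the set-bit counts of the two fingerprints and
   *C* the shared-bit count.
2. **Cluster highlights** — hierarchically cluster the matrix (complete
   linkage) and flag blocks of > 50 drugs × > 100 metabolites in which
   ≥ 30 % of cells reach T<sub>c</sub> ≥ 0.7.
3. **Gold standard** — validate the measure on curated antimetabolite →
   target-enzyme relations: for each pair keep the enzyme's most
   drug-similar substrate, requiring T<sub>c</sub> > 0.5.
4. **Significance** — standardise each relation's score against the
   substrate's similarity distribution over all drugs (z-score, one-sided
   normal tail p).
5. **Calibration** — treat the score as a binary classifier of
   gold-standard membership, build the ROC curve, and pick the threshold
   maximising Youden's index *J(x) = Sp(x) + Se(x) − 1*.
6. **Prediction** — per enzyme, report every drug at or above the
   calibrated threshold, excluding the enzyme's own gold-standard drugs
   and the endogenous ligand itself.

The package bundles parent structures (canonical SMILES) for the
17-antimetabolite / 11-enzyme / 15-substrate benchmark plus the extra
repositioning candidates, and a seeded synthetic fingerprint generator, so
every stage is testable offline.

## Worked example

```python
import metlike as ml

bundle = ml.load_fixture_bundle()
matrix = ml.build_matrix(bundle.drugs, bundle.metabolites)   # 19 x 15

print(round(ml.tanimoto(ml.fingerprint(bundle.drugs["azacitidine"]),
                        ml.fingerprint(bundle.metabolites["cytidine"])), 2))
# 0.97  -- azacitidine is almost indistinguishable from cytidine

gsp = ml.select_gsp(matrix, bundle.drug_enzyme_pairs(), bundle.enzymes)
print(ml.gsp_summary(bundle.gsp_relations()))
# GSPSummary(n_drugs=17, n_enzymes=11, n_substrates=15, n_relations=27)

cands = ml.predict_candidates(matrix, bundle.enzymes, gsp, threshold=0.654)
print(ml.top_candidate_report(cands,
                              enzymes=[e.label for e in bundle.enzymes]))
```

```
        enzyme        substrate           drug similarity
          TYMS    methylene-THF levoleucovorin      0.889
    POLA1,POLB             dCTP     decitabine      0.806
          DHFR tetrahydrofolate levoleucovorin      0.923
          RRM1              CDP     cytarabine      0.841
         DNMT1         cytidine    gemcitabine      0.875
      IMPDH1/2              IMP     nelarabine       0.77
         ENPP1      deamino-NAD     vidarabine      0.781
          ATIC       formyl-THF levoleucovorin      0.969
          GART       formyl-THF levoleucovorin      0.969
        NME1/2             dCDP     decitabine      0.806
           XDH                -              -          -
```

Each row is the single best repositioning proposal for one target enzyme:
e.g. levoleucovorin scores 0.969 against 10-formyl-tetrahydrofolate, the
substrate of ATIC and GART, so it is proposed as a possible modulator of
both folate enzymes. For xanthine dehydrogenase (XDH) no drug other than
its own gold-standard antimetabolite passes the 0.654 threshold, hence the
dash row.

The same pipeline is scriptable from the shell
(`metlike build-matrix | clusters | select-gsp | significance | calibrate |
predict`); see `metlike --help`.

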