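"""Repositioning-candidate enumeration above the calibrated threshold.

For each gold-standard enzyme, every drug whose maximal similarity to the
enzyme's gold-standard substrates reaches the calibrated threshold is
proposed as a possible modulator, after two exclusions: the enzyme's own
gold-standard (antimetabolite) drugs, and any drug structurally identical
to the substrate itself (the endogenous ligand is not a repositioning
candidate).  The comparison is inclusive (score >= threshold), which keeps
the gold-standard relations themselves above the cutoff; an enzyme whose
only passing relation is its own gold-standard one therefore yields an
empty candidate list rather than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .goldstandard import EnzymeRecord, GSPRelation
from .simmatrix import SimilarityMatrix


class CandidateTieWarning(UserWarning):
    """Two top candidates tie on similarity; drug id breaks the tie."""


@dataclass(frozen=True)
class CandidatePrediction:
    """A ranked (enzyme, substrate, drug) repositioning proposal."""

    enzyme_label: str
    substrate_id: str
    drug_id: str
    similarity: float
    rank: int


def predict_candidates(
    m: SimilarityMatrix,
    enzymes: Sequence[EnzymeRecord],
    gsp: Sequence[GSPRelation],
    threshold: float,
) -> list[CandidatePrediction]:
    """Enumerate per-enzyme candidates at ``threshold``.

    The candidate universe is the full drug set of the matrix (not just
    the gold-standard drugs).  Per enzyme, each drug is scored by its
    maximal similarity over the enzyme's gold-standard substrates (the
    best substrate is reported); drugs below the threshold, the enzyme's
    gold-standard drugs, and endogenous ligands (similarity 1.0 to the
    substrate, or the substrate's own id) are excluded.  Candidates are
    ranked per enzyme by descending similarity, ties broken by drug id.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")

    subs_by_enzyme: dict[str, set[str]] = {}
    gsp_drugs: dict[str, set[str]] = {}
    for r in gsp:
        subs_by_enzyme.setdefault(r.enzyme_label, set()).add(r.substrate_id)
        gsp_drugs.setdefault(r.enzyme_label, set()).add(r.drug_id)

    listed = {e.label for e in enzymes}
    out: list[CandidatePrediction] = []
    for enzyme_label in sorted(subs_by_enzyme):
        if enzyme_label not in listed:
            raise KeyError(f"no EnzymeRecord for label {enzyme_label!r}")
        subs = sorted(subs_by_enzyme[enzyme_label])
        block = np.column_stack([m.column(s) for s in subs])
        best_idx = block.argmax(axis=1)
        best_val = block.max(axis=1)
        rows = []
        for drug_id, j, score in zip(m.drug_ids, best_idx, best_val):
            if score < threshold:
                continue
            if drug_id in gsp_drugs[enzyme_label]:
                continue
            substrate = subs[j]
            if drug_id == substrate or score == 1.0:
                continue  # endogenous ligand, not a repositioning candidate
            rows.append((float(score), drug_id, substrate))
        rows.sort(key=lambda r: (-r[0], r[1]))
        for rank, (score, drug_id, substrate) in enumerate(rows, start=1):
            out.append(CandidatePrediction(enzyme_label, substrate, drug_id,
                                           score, rank))
    return out


def top_candidate_report(
    cands: Sequence[CandidatePrediction],
    enzymes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One best candidate per enzyme (columns: enzyme, substrate, drug, similarity).

    With ``enzymes`` given, enzymes without any candidate appear as a
    dash-filled row.  A similarity tie at the top resolves to the
    alphabetically first drug id, with a warning.
    """
    best: dict[str, CandidatePrediction] = {}
    for c in sorted(cands, key=lambda c: (c.enzyme_label, -c.similarity,
                                          c.drug_id)):
        cur = best.get(c.enzyme_label)
        if cur is None:
            best[c.enzyme_label] = c
        elif c.similarity == cur.similarity and c.drug_id != cur.drug_id:
            warnings.warn(
                f"top-candidate tie for {c.enzyme_label} at "
                f"{c.similarity:.3f}: keeping {cur.drug_id!r} over "
                f"{c.drug_id!r}",
                CandidateTieWarning,
                stacklevel=2,
            )

    labels = list(enzymes) if enzymes is not None else sorted(best)
    rows = []
    for label in labels:
        c = best.get(label)
        if c is None:
            rows.append({"enzyme": label, "substrate": "-", "drug": "-",
                         "similarity": "-"})
        else:
            rows.append({"enzyme": label, "substrate": c.substrate_id,
                         "drug": c.drug_id,
                         "similarity": round(c.similarity, 3)})
    return pd.DataFrame(rows, columns=["enzyme", "substrate", "drug",
                                       "similarity"])


def candidate_table(cands: Sequence[CandidatePrediction]) -> pd.DataFrame:
    """Full candidate list as a table."""
    return pd.DataFrame(
        [{"enzyme": c.enzyme_label, "substrate": c.substrate_id,
          "drug": c.drug_id, "similarity": c.similarity, "rank": c.rank}
         for c in cands],
        columns=["enzyme", "substrate", "drug", "similarity", "rank"],
    )
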