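"""Gold-standard positive (GSP) set construction.

Antimetabolite drugs mimic endogenous metabolites by definition, which
makes curated antimetabolite -> target-enzyme relations a natural
known-true set for validating metabolite-likeness.  For each curated
(drug, enzyme) pair the enzyme's most drug-similar substrate is selected
(ubiquitous co-substrates such as water and cofactors having been excluded
from the substrate lists beforehand), and the triple is retained only when
that maximal similarity exceeds ``min_sim`` (default 0.5): an
antimetabolite with only weak substrate resemblance presumably acts
through a different mechanism and would contaminate the standard.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .simmatrix import SimilarityMatrix

logger = logging.getLogger("metlike")


class UnknownCompoundError(KeyError):
    """A referenced drug or substrate is absent from the similarity matrix."""


class SubstrateTieWarning(UserWarning):
    """Two substrates attain the same maximal similarity; both are kept."""


@dataclass
class EnzymeRecord:
    """An enzyme (or slash/comma-grouped enzyme family) and its substrates.

    ``excluded_cosubstrates`` lists the ubiquitous reaction partners
    (water, cofactors, ...) removed from the substrate list; the two lists
    are kept disjoint.
    """

    label: str
    substrate_ids: list[str]
    ec_numbers: list[str] = field(default_factory=list)
    protein_accessions: list[str] = field(default_factory=list)
    excluded_cosubstrates: list[str] = field(default_factory=list)

    def __post_init__(self):
        excluded = set(self.excluded_cosubstrates)
        self.substrate_ids = [s for s in self.substrate_ids if s not in excluded]


@dataclass(frozen=True)
class GSPRelation:
    """A validated drug-enzyme-substrate triple with its similarity score."""

    drug_id: str
    enzyme_label: str
    substrate_id: str
    similarity: float


class GSPSummary(NamedTuple):
    n_drugs: int
    n_enzymes: int
    n_substrates: int
    n_relations: int


def select_gsp(
    matrix: SimilarityMatrix,
    drug_enzyme: Iterable[tuple[str, str]],
    enzymes: Sequence[EnzymeRecord],
    min_sim: float = 0.5,
) -> list[GSPRelation]:
    """Build the GSP set from curated drug->enzyme pairs.

    For each (drug, enzyme) pair the substrate with the highest similarity
    to the drug is chosen among the enzyme's substrates; the relation is
    kept iff that similarity is strictly greater than ``min_sim``.  A drug
    may map to several enzymes; each pair contributes at most one relation
    (two on an exact substrate tie, with a warning).  Output is sorted by
    enzyme label, then descending similarity, then drug id.
    """
    by_label = {e.label: e for e in enzymes}
    relations: list[GSPRelation] = []
    for drug_id, enzyme_label in drug_enzyme:
        if not matrix.has_drug(drug_id):
            raise UnknownCompoundError(f"drug {drug_id!r} not in matrix")
        enzyme = by_label.get(enzyme_label)
        if enzyme is None:
            raise KeyError(f"no EnzymeRecord for label {enzyme_label!r}")
        if not enzyme.substrate_ids:
            logger.warning(
                "skipping (%s, %s): no substrates after co-substrate exclusion",
                drug_id, enzyme_label,
            )
            continue
        scores = {}
        for sub in enzyme.substrate_ids:
            if not matrix.has_metabolite(sub):
                raise UnknownCompoundError(
                    f"substrate {sub!r} of {enzyme_label!r} not in matrix"
                )
            scores[sub] = matrix.loc(drug_id, sub)
        best = max(scores.values())
        if best <= min_sim:
            continue
        winners = sorted(s for s, v in scores.items() if v == best)
        if len(winners) > 1:
            warnings.warn(
                f"substrate tie at {best:.3f} for ({drug_id}, {enzyme_label}): "
                f"{winners}; keeping all",
                SubstrateTieWarning,
                stacklevel=2,
            )
        for sub in winners:
            relations.append(GSPRelation(drug_id, enzyme_label, sub, best))
    relations.sort(key=lambda r: (r.enzyme_label, -r.similarity, r.drug_id))
    return relations


def gsp_summary(relations: Sequence[GSPRelation]) -> GSPSummary:
    """Distinct drug / enzyme-label / substrate counts of a GSP set."""
    return GSPSummary(
        n_drugs=len({r.drug_id for r in relations}),
        n_enzymes=len({r.enzyme_label for r in relations}),
        n_substrates=len({r.substrate_id for r in relations}),
        n_relations=len(relations),
    )


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

def _split_list(cell) -> list[str]:
    if pd.isna(cell) or cell == "":
        return []
    return [part.strip() for part in str(cell).split(";") if part.strip()]


def load_enzyme_table(path: str | Path) -> list[EnzymeRecord]:
    """Read EnzymeRecords from a delimited table.

    Required columns: ``label``, ``substrate_ids`` (semicolon-separated);
    optional: ``ec_numbers``, ``protein_accessions``,
    ``excluded_cosubstrates`` (all semicolon-separated).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep)
    records = []
    for _, row in table.iterrows():
        records.append(
            EnzymeRecord(
                label=str(row["label"]),
                substrate_ids=_split_list(row["substrate_ids"]),
                ec_numbers=_split_list(row.get("ec_numbers", "")),
                protein_accessions=_split_list(row.get("protein_accessions", "")),
                excluded_cosubstrates=_split_list(row.get("excluded_cosubstrates", "")),
            )
        )
    return records


def load_drug_enzyme_table(path: str | Path) -> list[tuple[str, str]]:
    """Read curated (drug_id, enzyme_label) pairs from a delimited table."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep)
    return [(str(r["drug_id"]), str(r["enzyme_label"]))
            for _, r in table.iterrows()]


def gsp_table(relations: Sequence[GSPRelation], ndigits: int = 2) -> pd.DataFrame:
    """GSP set as a table (enzyme, substrate, drug, similarity).

    Similarity is rounded for the human-readable report; use the relation
    objects for full precision.
    """
    return pd.DataFrame(
        [
            {
                "enzyme": r.enzyme_label,
                "substrate": r.substrate_id,
                "drug": r.drug_id,
                "similarity": round(r.similarity, ndigits),
            }
            for r in relations
        ],
        columns=["enzyme", "substrate", "drug", "similarity"],
    )
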