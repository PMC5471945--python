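"""Bundled reference fixtures and a synthetic fingerprint generator.

Two ingredients make every pipeline stage testable without any database
download:

* a **fixture bundle** of the curated antimetabolite benchmark — parent
  structures (canonical SMILES) of the 17 antimetabolite drugs, their 11
  target-enzyme groups and 15 substrates, the two extra repositioning
  candidates (levoleucovorin, vidarabine), and the reference drug-enzyme
  relation table;

* a **synthetic universe generator** producing random binary fingerprints
  with planted drug-metabolite pairs of controlled expected similarity,
  for property and calibration tests at arbitrary scale.

Background fingerprints are independent Bernoulli(``bit_density``) bit
vectors.  A planted drug fingerprint is derived from its metabolite's by
flipping every bit independently with a rate ``q`` chosen in closed form
so that the ratio of expectations of shared to united bits equals the
target Tanimoto ``t``: with ``m`` bits on in the metabolite and length
``L``,

    E[C] = m(1-q),   E[|A u B|] = m + (L-m)q
    =>  q = m(1-t) / (t(L-m) + m).

For large ``L`` the realised similarity concentrates tightly around ``t``
(the Jensen bias of the ratio is O(1/L)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .chemcore import Compound, CompoundSet, Fingerprint, compound_from_smiles
from .goldstandard import EnzymeRecord, GSPRelation

_DATA = resources.files("metlike.data")


class FixtureError(RuntimeError):
    """The bundled fixture tables are inconsistent."""


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Parsed benchmark fixtures with verified referential integrity."""

    drugs: CompoundSet
    metabolites: CompoundSet
    enzymes: list[EnzymeRecord]
    relations: pd.DataFrame

    @property
    def gsp_drug_ids(self) -> list[str]:
        """Drugs of the curated relation table (the antimetabolites)."""
        seen: dict[str, None] = {}
        for d in self.relations["drug_id"]:
            seen.setdefault(d)
        return list(seen)

    def drug_enzyme_pairs(self) -> list[tuple[str, str]]:
        """Curated (drug, enzyme) pairs driving gold-standard selection."""
        seen: dict[tuple[str, str], None] = {}
        for _, row in self.relations.iterrows():
            seen.setdefault((row["drug_id"], row["enzyme_label"]))
        return list(seen)

    def gsp_relations(self) -> list[GSPRelation]:
        """The reference relation table as GSPRelation records.

        Similarities are the table's reported values; use
        :func:`metlike.goldstandard.select_gsp` on a freshly built matrix
        to recompute them from structures instead.
        """
        return [
            GSPRelation(
                drug_id=row["drug_id"],
                enzyme_label=row["enzyme_label"],
                substrate_id=row["substrate_id"],
                similarity=float(row["reported_similarity"]),
            )
            for _, row in self.relations.iterrows()
        ]


def load_fixture_bundle() -> FixtureBundle:
    """Load and integrity-check the bundled benchmark fixtures."""
    with resources.as_file(_DATA / "compounds.tsv") as p:
        compounds = pd.read_csv(p, sep="\t")
    with resources.as_file(_DATA / "enzymes.tsv") as p:
        enz_table = pd.read_csv(p, sep="\t")
    with resources.as_file(_DATA / "relations.tsv") as p:
        relations = pd.read_csv(p, sep="\t")

    def build_set(role: str) -> CompoundSet:
        rows = compounds[compounds["role"] == role]
        return CompoundSet(
            compound_from_smiles(r["id"], r["smiles"], role, name=r["name"])
            for _, r in rows.iterrows()
        )

    drugs = build_set("drug")
    metabolites = build_set("metabolite")
    if drugs.n_failed or metabolites.n_failed:
        raise FixtureError(
            "unparseable bundled structures: "
            + ", ".join(c.id for c in drugs.failures + metabolites.failures)
        )

    enzymes = []
    for _, row in enz_table.iterrows():
        def split(col):
            v = row.get(col)
            if pd.isna(v) or v == "":
                return []
            return str(v).split(";")
        enzymes.append(EnzymeRecord(
            label=row["label"],
            substrate_ids=split("substrate_ids"),
            ec_numbers=split("ec_numbers"),
            protein_accessions=split("protein_accessions"),
            excluded_cosubstrates=split("excluded_cosubstrates"),
        ))

    by_label = {e.label: set(e.substrate_ids) for e in enzymes}
    for _, row in relations.iterrows():
        if row["drug_id"] not in drugs:
            raise FixtureError(f"relation drug {row['drug_id']!r} not bundled")
        if row["substrate_id"] not in metabolites:
            raise FixtureError(
                f"relation substrate {row['substrate_id']!r} not bundled"
            )
        if row["substrate_id"] not in by_label.get(row["enzyme_label"], set()):
            raise FixtureError(
                f"substrate {row['substrate_id']!r} not listed for enzyme "
                f"{row['enzyme_label']!r}"
            )
    for e in enzymes:
        for s in e.substrate_ids:
            if s not in metabolites:
                raise FixtureError(f"enzyme substrate {s!r} not bundled")

    return FixtureBundle(drugs=drugs, metabolites=metabolites,
                         enzymes=enzymes, relations=relations)


# ---------------------------------------------------------------------------
# Synthetic fingerprint universes
# ---------------------------------------------------------------------------

class InfeasibleTargetError(ValueError):
    """A planted target similarity cannot be realised."""


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic fingerprint universe.

    ``planted_pairs`` are (drug index, metabolite index, target Tanimoto)
    triples; everything else is independent background.  A fixed seed
    yields a bit-identical universe.
    """

    n_drugs: int
    n_metabolites: int
    fp_length: int = 1024
    bit_density: float = 0.2
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.bit_density < 1.0):
            raise ValueError("bit_density must be in (0, 1)")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise must be in [0, 1]")
        for d, m, t in self.planted_pairs:
            if not (0 <= d < self.n_drugs and 0 <= m < self.n_metabolites):
                raise ValueError(f"planted pair ({d}, {m}) out of range")
            if not (0.0 < t <= 1.0):
                raise InfeasibleTargetError(
                    f"target similarity {t} outside (0, 1]"
                )

    @property
    def scheme(self) -> str:
        return f"synthetic-{self.fp_length}"


def _flip_rate(m: int, length: int, target: float) -> float:
    """Closed-form bit-flip rate for an expected Tanimoto of ``target``."""
    if m == 0:
        raise InfeasibleTargetError(
            "cannot plant a similarity on an empty metabolite fingerprint"
        )
    return m * (1.0 - target) / (target * (length - m) + m)


def generate_fingerprint_universe(
    cfg: SyntheticConfig,
) -> tuple[list[Fingerprint], list[Fingerprint], pd.DataFrame]:
    """Generate (drug fingerprints, metabolite fingerprints, truth table).

    Metabolites and non-planted drugs are independent
    Bernoulli(``bit_density``) vectors.  Each planted drug is derived from
    its metabolite by flipping bits at the closed-form rate for its target
    similarity (an exact copy for target 1.0), then perturbed by the extra
    symmetric ``noise`` flip rate.  The truth table records the planted
    (drug_idx, metabolite_idx, target) triples.
    """
    rng = np.random.default_rng(cfg.seed)
    mets = rng.random((cfg.n_metabolites, cfg.fp_length)) < cfg.bit_density
    drug_bits = rng.random((cfg.n_drugs, cfg.fp_length)) < cfg.bit_density

    for d, m, t in cfg.planted_pairs:
        base = mets[m]
        if t == 1.0:
            derived = base.copy()
        else:
            q = _flip_rate(int(base.sum()), cfg.fp_length, t)
            if not (0.0 <= q <= 1.0):  # pragma: no cover - q in [0,1] by form
                raise InfeasibleTargetError(
                    f"target {t} infeasible at density {cfg.bit_density}"
                )
            derived = base ^ (rng.random(cfg.fp_length) < q)
        drug_bits[d] = derived
        if cfg.noise > 0.0:
            drug_bits[d] ^= rng.random(cfg.fp_length) < cfg.noise

    drugs = [Fingerprint(bits=row, scheme=cfg.scheme) for row in drug_bits]
    metabolites = [Fingerprint(bits=row, scheme=cfg.scheme) for row in mets]
    truth = pd.DataFrame(
        cfg.planted_pairs, columns=["drug_idx", "metabolite_idx", "target"]
    )
    return drugs, metabolites, truth


def synthetic_matrix(cfg: SyntheticConfig):
    """Synthetic universe folded straight into a SimilarityMatrix.

    Drug ids are ``D000..``, metabolite ids ``M000..``; the truth table is
    returned alongside for label construction in tests.
    """
    from .simmatrix import SimilarityMatrix

    drugs, mets, truth = generate_fingerprint_universe(cfg)
    X = np.vstack([f.bits for f in drugs]).astype(np.int32)
    Y = np.vstack([f.bits for f in mets]).astype(np.int32)
    C = X @ Y.T
    union = X.sum(1)[:, None] + Y.sum(1)[None, :] - C
    values = np.where(union > 0, C / np.maximum(union, 1), 1.0)
    width = max(3, len(str(max(cfg.n_drugs, cfg.n_metabolites))))
    matrix = SimilarityMatrix(
        drug_ids=[f"D{i:0{width}d}" for i in range(cfg.n_drugs)],
        metabolite_ids=[f"M{j:0{width}d}" for j in range(cfg.n_metabolites)],
        values=values,
        scheme=cfg.scheme,
    )
    return matrix, truth
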