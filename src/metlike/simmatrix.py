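"""Drug x metabolite similarity matrix and high-similarity cluster blocks.

The matrix holds the pairwise Tanimoto score of every (drug, metabolite)
combination under one fingerprint scheme.  Hierarchical clustering of its
rows and columns (complete linkage on a correlation-derived distance, as is
standard for similarity heat maps) exposes rectangular blocks of mutually
metabolite-like compounds; a block is reported as a highlight when it holds
more than ``min_drugs`` drugs, more than ``min_metabolites`` metabolites,
and at least ``min_frac`` of its cells reach a high similarity (default
T_c >= 0.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .chemcore import CompoundSet, FingerprintError, fingerprint

logger = logging.getLogger("metlike")


@dataclass
class SimilarityMatrix:
    """Dense rectangle of Tanimoto scores: drugs as rows, metabolites as columns."""

    drug_ids: list[str]
    metabolite_ids: list[str]
    values: np.ndarray
    scheme: str = "maccs"
    _drug_idx: dict = field(init=False, repr=False)
    _met_idx: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.drug_ids), len(self.metabolite_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.metabolite_ids)} metabolites"
            )
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("similarity values must lie in [0, 1]")
        self._drug_idx = {d: i for i, d in enumerate(self.drug_ids)}
        self._met_idx = {m: j for j, m in enumerate(self.metabolite_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def loc(self, drug_id: str, metabolite_id: str) -> float:
        """Similarity of one (drug, metabolite) pair."""
        return float(self.values[self._drug_idx[drug_id],
                                 self._met_idx[metabolite_id]])

    def has_drug(self, drug_id: str) -> bool:
        return drug_id in self._drug_idx

    def has_metabolite(self, metabolite_id: str) -> bool:
        return metabolite_id in self._met_idx

    def column(self, metabolite_id: str) -> np.ndarray:
        """All drug similarities of one metabolite."""
        return self.values[:, self._met_idx[metabolite_id]].copy()

    def row(self, drug_id: str) -> np.ndarray:
        return self.values[self._drug_idx[drug_id], :].copy()

    # -- serialisation ------------------------------------------------------

    def to_wide(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids,
                            columns=self.metabolite_ids)

    def to_long(self) -> pd.DataFrame:
        long = self.to_wide().stack().rename("tc").reset_index()
        long.columns = ["drug_id", "metabolite_id", "tc"]
        return long

    def write_wide(self, path: str | Path) -> None:
        # repr-precision floats so the round-trip is lossless
        self.to_wide().to_csv(path, sep="\t", index_label="drug_id",
                              float_format="%.17g")

    @classmethod
    def read_wide(cls, path: str | Path, scheme: str = "maccs") -> "SimilarityMatrix":
        wide = pd.read_csv(path, sep="\t", index_col="drug_id",
                           float_precision="round_trip")
        return cls(drug_ids=[str(i) for i in wide.index],
                   metabolite_ids=[str(c) for c in wide.columns],
                   values=wide.to_numpy(dtype=float), scheme=scheme)


def build_matrix(
    drugs: CompoundSet,
    metabolites: CompoundSet,
    scheme: str = "maccs",
) -> SimilarityMatrix:
    """Compute the full rectangle of pairwise Tanimoto scores.

    Members that cannot be fingerprinted are excluded with a logged
    warning; the matrix dimensions reflect the exclusions.  The result is
    deterministic for fixed inputs.
    """
    def fp_block(cs: CompoundSet) -> tuple[list[str], np.ndarray]:
        ids, rows = [], []
        for c in cs:
            try:
                rows.append(fingerprint(c, scheme).bits)
            except FingerprintError:
                logger.warning("excluding %s: not fingerprintable", c.id)
                continue
            ids.append(c.id)
        if not ids:
            raise ValueError("no fingerprintable compounds in set")
        return ids, np.vstack(rows)

    drug_ids, X = fp_block(drugs)
    met_ids, Y = fp_block(metabolites)

    # Vectorised Tanimoto: C = X.Y^T, union = |A| + |B| - C
    Xi = X.astype(np.int32)
    Yi = Y.astype(np.int32)
    C = Xi @ Yi.T
    a = Xi.sum(axis=1)[:, None]
    b = Yi.sum(axis=1)[None, :]
    union = a + b - C
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(union > 0, C / np.maximum(union, 1), 1.0)
    return SimilarityMatrix(drug_ids=drug_ids, metabolite_ids=met_ids,
                            values=values, scheme=scheme)


# ---------------------------------------------------------------------------
# Highlight clusters
# ---------------------------------------------------------------------------

@dataclass
class ClusterHighlight:
    """A rectangular block of the clustered matrix rich in high similarities."""

    drug_members: list[str]
    metabolite_members: list[str]
    frac_high: float

    @property
    def n_cells(self) -> int:
        return len(self.drug_members) * len(self.metabolite_members)


def _subtree_leaf_sets(dist: np.ndarray, min_leaves: int) -> list[frozenset[int]]:
    """Leaf index sets of every complete-linkage subtree with > min_leaves leaves."""
    Z = linkage(dist, method="complete")
    _, nodes = to_tree(Z, rd=True)
    out = []
    for node in nodes:
        if node.get_count() > min_leaves:
            out.append(frozenset(node.pre_order(lambda leaf: leaf.id)))
    return out


def _profile_distance(X: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance between similarity profiles.

    ``correlation`` is 1 - Pearson r (standard heat-map practice, robust to
    the overall similarity level); ``cosine`` is the configurable
    alternative.  Constant profiles make the correlation undefined; those
    distances are set to the metric's maximum.
    """
    if metric not in ("correlation", "cosine"):
        raise ValueError(f"unsupported cluster metric: {metric!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pdist(X, metric=metric)
    return np.nan_to_num(d, nan=2.0 if metric == "correlation" else 1.0)


def find_highlight_clusters(
    m: SimilarityMatrix,
    min_drugs: int = 50,
    min_metabolites: int = 100,
    high_tc: float = 0.7,
    min_frac: float = 0.3,
    metric: str = "correlation",
) -> list[ClusterHighlight]:
    """Detect high-similarity blocks of the hierarchically clustered matrix.

    Rows and columns are clustered independently (complete linkage on the
    profile distance).  Every (row-subtree, column-subtree) pair whose block
    satisfies all three criteria — more than ``min_drugs`` drugs, more than
    ``min_metabolites`` metabolites, and a fraction >= ``min_frac`` of cells
    at T_c >= ``high_tc`` — qualifies; nested qualifying pairs are reduced
    to the maximal ones, returned largest block first.

    A matrix smaller than the thresholds yields an empty list.
    """
    n_d, n_m = m.shape
    high = m.values >= high_tc
    if n_d <= min_drugs or n_m <= min_metabolites or not high.any():
        return []

    row_sets = _subtree_leaf_sets(_profile_distance(m.values, metric), min_drugs)
    col_sets = _subtree_leaf_sets(_profile_distance(m.values.T, metric), min_metabolites)

    qualifying: list[tuple[frozenset[int], frozenset[int], float]] = []
    for rs in row_sets:
        ridx = np.fromiter(rs, dtype=int)
        sub = high[ridx]
        for cs in col_sets:
            cidx = np.fromiter(cs, dtype=int)
            frac = float(sub[:, cidx].mean())
            if frac >= min_frac:
                qualifying.append((rs, cs, frac))

    # keep only maximal (row, col) pairs: drop any block nested inside another
    qualifying.sort(key=lambda q: len(q[0]) * len(q[1]), reverse=True)
    maximal: list[tuple[frozenset[int], frozenset[int], float]] = []
    for rs, cs, frac in qualifying:
        if any(rs <= ks and cs <= kcs for ks, kcs, _ in maximal):
            continue
        maximal.append((rs, cs, frac))

    return [
        ClusterHighlight(
            drug_members=[m.drug_ids[i] for i in sorted(rs)],
            metabolite_members=[m.metabolite_ids[j] for j in sorted(cs)],
            frac_high=frac,
        )
        for rs, cs, frac in maximal
    ]


def plot_heatmap(m: SimilarityMatrix, path: str | Path) -> None:
    """Optional clustered heat-map rendering (cosmetic)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list

    row_order = leaves_list(linkage(_profile_distance(m.values, "correlation"),
                                    method="complete"))
    col_order = leaves_list(linkage(_profile_distance(m.values.T, "correlation"),
                                    method="complete"))
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(m.values[np.ix_(row_order, col_order)], aspect="auto",
                   cmap="viridis", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="Tanimoto similarity")
    ax.set_xlabel("metabolites (clustered)")
    ax.set_ylabel("drugs (clustered)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
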