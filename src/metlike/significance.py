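"""Statistical significance of a drug-metabolite similarity.

For a given metabolite, the similarity scores to the whole drug collection
form an empirical distribution; a particular drug's score is standardised
against it (z = (score - mean) / sd, sample-sd with the n-1 denominator)
and assigned a one-sided upper-tail normal probability.  An empirical
percentile mode is available as a labelled alternative, but note that an
empirical percentile can never fall below 1/n, whereas tail probabilities
of strongly similar pairs are far smaller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .goldstandard import GSPRelation
from .simmatrix import SimilarityMatrix


class DegenerateDistributionError(ValueError):
    """The similarity column is constant; no z-score can be formed."""


@dataclass(frozen=True)
class SimilarityDistribution:
    """Mean/sd summary of one metabolite's similarities over all drugs."""

    metabolite_id: str
    n: int
    mean: float
    sd: float
    scores: np.ndarray | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 drugs to form a distribution")
        if not (0.0 <= self.mean <= 1.0):
            raise ValueError(f"mean {self.mean} outside [0, 1]")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def fit_distribution(
    m: SimilarityMatrix,
    metabolite_id: str,
    keep_scores: bool = False,
) -> SimilarityDistribution:
    """Fit the similarity distribution of one metabolite's full drug column.

    The column deliberately includes every drug (a query drug's own score
    is not excluded).  A constant column raises
    :class:`DegenerateDistributionError`.
    """
    col = m.column(metabolite_id)
    if col.size < 2:
        raise ValueError("matrix must contain at least 2 drugs")
    sd = float(np.std(col, ddof=1))
    if sd == 0.0:
        raise DegenerateDistributionError(
            f"constant similarity column for {metabolite_id!r}"
        )
    return SimilarityDistribution(
        metabolite_id=metabolite_id,
        n=int(col.size),
        mean=float(np.mean(col)),
        sd=sd,
        scores=col if keep_scores else None,
    )


def zscore_pvalue(d: SimilarityDistribution, score: float) -> tuple[float, float]:
    """Standardised score and one-sided upper-tail normal probability.

    ``p`` is strictly decreasing in ``score`` and equals 0.5 at the mean.
    """
    z = (score - d.mean) / d.sd
    p = float(norm.sf(z))
    return float(z), p


def empirical_pvalue(d: SimilarityDistribution, score: float) -> float:
    """Empirical upper-tail percentile: fraction of drugs scoring >= score.

    Requires the raw scores (``fit_distribution(..., keep_scores=True)``).
    Bounded below by 1/n, unlike the normal-tail probability.
    """
    if d.scores is None:
        raise ValueError("raw scores not retained; refit with keep_scores=True")
    return float(np.mean(d.scores >= score))


def significance_report(
    m: SimilarityMatrix,
    relations: Sequence[GSPRelation],
) -> pd.DataFrame:
    """Per-relation significance table (drug, metabolite, similarity, z, p).

    ``p`` is formatted in scientific notation in the exported table; the
    returned frame keeps full precision.
    """
    cache: dict[str, SimilarityDistribution] = {}
    rows = []
    for r in relations:
        d = cache.get(r.substrate_id)
        if d is None:
            d = cache[r.substrate_id] = fit_distribution(m, r.substrate_id)
        z, p = zscore_pvalue(d, r.similarity)
        rows.append({
            "drug_id": r.drug_id,
            "metabolite_id": r.substrate_id,
            "similarity": r.similarity,
            "z": z,
            "p": p,
        })
    return pd.DataFrame(rows, columns=["drug_id", "metabolite_id",
                                       "similarity", "z", "p"])


def write_significance_report(report: pd.DataFrame, path) -> None:
    out = report.copy()
    out["p"] = out["p"].map(lambda v: f"{v:.2E}")
    out.to_csv(path, sep="\t", index=False)
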