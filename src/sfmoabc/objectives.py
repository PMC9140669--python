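"""Association scores for SNP combinations.

Two complementary objectives quantify the dependence between a SNP
combination S and the binary phenotype Y:

* mutual information MI(S;Y) = H(S) + H(Y) - H(S,Y), plug-in entropies in
  nats; larger means stronger association;
* the (negative log) K2 Bayesian network score
  K2log = -ln prod_i [(J-1)! / (n_i+J-1)!] prod_j n_ij!,
  computed via log-gamma; smaller means stronger association.

The scalarized fitness fit = MI / K2log combines the two: it is monotone
increasing in MI and decreasing in K2log, so larger fitness identifies the
more disease-associated combination.  A Pearson chi-square p-value is
provided for reporting only; it plays no role in the search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .genotype_data import GenotypeDataset

__all__ = [
    "ContingencyTable",
    "contingency_counts",
    "entropy",
    "mutual_information",
    "k2_log_score",
    "fitness",
    "association_p_value",
]

#: guard against division by zero in the fitness ratio
FITNESS_EPS = 1e-12


@dataclass
class ContingencyTable:
    """Genotype-combination x phenotype counts n_ij (J = 2 classes).

    Rows index the 3^k genotype combinations of a SNP combo in mixed-radix
    base-3 order (first SNP most significant); empty combinations keep
    their all-zero row.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError(f"counts must be I x 2, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def contingency_counts(ds: GenotypeDataset, combo: Sequence[int]) -> ContingencyTable:
    """Count samples per (genotype combination, phenotype) cell.

    ``combo`` holds distinct 0-based SNP column indices; row i of the
    result is the mixed-radix base-3 code of the genotype combination with
    the first SNP in ``combo`` most significant.
    """
    combo = [int(c) for c in combo]
    if len(set(combo)) != len(combo):
        raise ValueError(f"duplicate SNP index in combo {combo}")
    if any(not (0 <= c < ds.n_snps) for c in combo):
        raise IndexError(f"combo {combo} out of range [0, {ds.n_snps})")
    k = len(combo)
    code = np.zeros(ds.n_samples, dtype=np.int64)
    for c in combo:
        code = code * 3 + ds.genotypes[:, c]
    flat = np.bincount(code * 2 + ds.phenotype, minlength=2 * 3**k)
    return ContingencyTable(flat.reshape(3**k, 2))


def entropy(values) -> float:
    """Plug-in Shannon entropy in nats of counts or probabilities.

    Input is normalized internally; 0 * ln 0 is taken as 0.
    """
    v = np.asarray(values, dtype=float).ravel()
    if (v < 0).any():
        raise ValueError("negative weight in entropy input")
    total = v.sum()
    if total <= 0:
        raise ValueError("entropy of an all-zero input is undefined")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


def mutual_information(t: ContingencyTable) -> float:
    """MI(S;Y) in nats from the plug-in entropies of the table.

    Clipped to 0 from below (the plug-in estimate can be a few ulp
    negative on independent tables).
    """
    if t.total == 0:
        raise ValueError("mutual information of an empty table is undefined")
    h_s = entropy(t.counts.sum(axis=1))
    h_y = entropy(t.counts.sum(axis=0))
    h_sy = entropy(t.counts)
    return max(h_s + h_y - h_sy, 0.0)


def k2_log_score(t: ContingencyTable) -> float:
    """Negative log K2 score; lower means stronger association.

    For J = 2: sum_i [ lnGamma(n_i + 2) - sum_j lnGamma(n_ij + 1) ]; empty
    rows contribute 0.  Log-gamma avoids factorial overflow at any n.
    """
    if t.total == 0:
        raise ValueError("K2 score of an empty table is undefined")
    counts = t.counts
    j = counts.shape[1]
    n_i = counts.sum(axis=1)
    per_row = gammaln(n_i + j) - gammaln(j) - gammaln(counts + 1).sum(axis=1)
    return float(per_row.sum())


def fitness(mi: float, k2log: float) -> float:
    """Scalarized objective fit = MI / K2log (guarded against K2log = 0)."""
    if mi < 0:
        raise ValueError(f"mi must be nonnegative, got {mi}")
    if k2log < 0:
        raise ValueError(f"k2log must be nonnegative, got {k2log}")
    return mi / max(k2log, FITNESS_EPS)


def association_p_value(t: ContingencyTable) -> float:
    """Pearson chi-square upper-tail p-value over the nonzero rows.

    df = (number of nonzero rows - 1) * (J - 1).  Degenerate tables (fewer
    than two occupied rows, or a phenotype class absent) return p = 1.
    """
    if t.total == 0:
        raise ValueError("p-value of an empty table is undefined")
    obs = t.counts[t.row_margins > 0]
    if obs.shape[0] < 2:
        return 1.0
    col = obs.sum(axis=0)
    if (col == 0).any():
        return 1.0
    row = obs.sum(axis=1)
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(min(max(stats.chi2.sf(stat, df), np.finfo(float).tiny), 1.0))
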