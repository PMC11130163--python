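"""Exact contingency and cross-species concordance statistics.

Two statistics carry the inferential weight and are implemented from first
principles (with library cross-checks in the test suite):

* Fisher's exact two-sided test on a 2x2 table, by hypergeometric
  enumeration with the standard "small-p" rule (sum the probabilities of
  all outcomes no more likely than the observed table).
* The module concordance value: for each gene module, the percentage of
  genes whose log fold change has the same sign in two differential-
  expression comparisons (e.g. model-vs-control and human ASD-vs-control),
  with a one-sided binomial P against the 50% chance level.  Modules with
  fewer than 8 analyzable genes are omitted.

Figure legends in longitudinal-imaging studies usually print event counts
next to group totals ("k of N"); :func:`table_from_counts` forms the valid
2x2 table (k, N - k) per group so the total is not double counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "ModuleConcordance",
    "table_from_counts",
    "fisher_exact_2x2",
    "select_modulated_genes",
    "build_gene_pairs",
    "concordance",
    "logfc_correlation",
    "binomial_tail_p",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows are groups, columns are event / non-event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def table_from_counts(k1: int, n1: int, k2: int, n2: int) -> ContingencyTable2x2:
    """Build the 2x2 table from per-group event counts and group totals."""
    if k1 > n1 or k2 > n2:
        raise ValueError("event count exceeds group total")
    return ContingencyTable2x2(k1, n1 - k1, k2, n2 - k2)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Exact two-sided P by hypergeometric enumeration.

    With margins fixed, the first cell follows a hypergeometric law; the
    two-sided P sums the probabilities of all support points whose
    probability does not exceed that of the observed table (up to a relative
    tolerance guarding floating-point ties).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    return float(np.sum(pmf[pmf <= p_obs * (1 + 1e-7)]))


def binomial_tail_p(k: int, n: int, p: float = 0.5) -> float:
    """One-sided upper-tail binomial P(X >= k), exact.

    For the symmetric p = 1/2 case the tail is an exact rational
    ``sum_{i>=k} C(n, i) / 2^n``; otherwise it falls back to the regularized
    incomplete beta form via scipy.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if p == 0.5 and n <= 10_000:
        num = sum(math.comb(n, i) for i in range(k, n + 1))
        return float(Fraction(num, 2**n))
    return float(stats.binom.sf(k - 1, n, p))


def select_modulated_genes(
    model: pd.DataFrame, human: pd.DataFrame, p_adj_threshold: float = 0.1
) -> pd.Index:
    """Genes modulated in BOTH comparisons: p_adj strictly below threshold.

    Tables carry ``{gene_id, logfc, p_adj}``; returns the common gene ids.
    """
    if not 0 < p_adj_threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    m = model.loc[model["p_adj"] < p_adj_threshold, "gene_id"]
    h = human.loc[human["p_adj"] < p_adj_threshold, "gene_id"]
    return pd.Index(sorted(set(m) & set(h)))


def build_gene_pairs(
    model: pd.DataFrame,
    human: pd.DataFrame,
    module_map: pd.DataFrame,
    p_adj_threshold: float | None = 0.1,
) -> pd.DataFrame:
    """Join the two comparisons and the gene->module map into paired records.

    Returns columns ``{gene_id, logfc_model, logfc_human, module_id}``,
    restricted to commonly modulated genes when a threshold is given.
    """
    merged = model.merge(human, on="gene_id", suffixes=("_model", "_human")).merge(
        module_map, on="gene_id"
    )
    if p_adj_threshold is not None:
        keep = select_modulated_genes(model, human, p_adj_threshold)
        merged = merged[merged["gene_id"].isin(keep)]
    return merged[["gene_id", "logfc_model", "logfc_human", "module_id"]].reset_index(
        drop=True
    )


@dataclass(frozen=True)
class ModuleConcordance:
    module_id: str
    n_genes: int
    n_concordant: int
    concordance_pct: float
    p_binomial: float
    log10_p: float
    mean_direction: float  # mean sign of the model logFC among analyzed genes


def concordance(
    pairs: pd.DataFrame, min_genes: int = 8
) -> tuple[dict[str, ModuleConcordance], list[str]]:
    """Per-module concordance of logFC direction with a one-sided binomial P.

    A gene is concordant when its two logFC values share a sign (first or
    third quadrant).  Genes with either logFC exactly zero are excluded from
    the module's n (the quadrant rule is undefined on the axes).  Modules
    with fewer than ``min_genes`` analyzable genes are skipped and returned
    in the second element, mirroring blank cells in a concordance heat map.
    """
    results: dict[str, ModuleConcordance] = {}
    skipped: list[str] = []
    for module_id, sub in pairs.groupby("module_id"):
        lm = sub["logfc_model"].to_numpy(dtype=float)
        lh = sub["logfc_human"].to_numpy(dtype=float)
        nonzero = (lm != 0) & (lh != 0)
        lm, lh = lm[nonzero], lh[nonzero]
        n = lm.size
        if n < min_genes:
            skipped.append(str(module_id))
            continue
        k = int(np.sum(np.sign(lm) == np.sign(lh)))
        p = binomial_tail_p(k, n, 0.5)
        with np.errstate(divide="ignore"):
            log10_p = float(stats.binom.logsf(k - 1, n, 0.5) / math.log(10))
        results[str(module_id)] = ModuleConcordance(
            module_id=str(module_id),
            n_genes=n,
            n_concordant=k,
            concordance_pct=100.0 * k / n,
            p_binomial=p,
            log10_p=log10_p,
            mean_direction=float(np.mean(np.sign(lm))),
        )
    return results, skipped


def logfc_correlation(pairs: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of the paired logFC values and its P-value."""
    lm = pairs["logfc_model"].to_numpy(dtype=float)
    lh = pairs["logfc_human"].to_numpy(dtype=float)
    if lm.size < 3:
        raise ValueError("need at least 3 gene pairs")
    if np.std(lm) == 0 or np.std(lh) == 0:
        raise ValueError("zero variance in logFC values")
    r, p = stats.pearsonr(lm, lh)
    return float(r), float(p)
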