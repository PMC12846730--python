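"""ssGSEA immune-infiltration scores and taxa-score Spearman correlation.

Per sample, genes are ranked by expression (descending position order;
average ranks on ties, so the highest-expressed gene carries rank N).
For a gene set S the enrichment score is the sum over the ranked list
of the running difference between the cumulative normalized in-set rank
weight (weights rank^alpha, alpha = 0.25) and the cumulative uniform
out-of-set step:

    ES = sum_i ( sum_{j<=i, j in S} r_j^alpha / sum_{j in S} r_j^alpha
               - #{j<=i, j not in S} / (N - |S|) )

Scores are returned unnormalized: the downstream use is Spearman
correlation against taxa abundances, which is invariant to any common
monotone rescaling, and rank-based scoring makes a prior log transform
of FPKM values inert as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from cminet.datatypes import AbundanceTable, ExpressionMatrix, GeneSetCollection
from cminet.errors import ValidationError


@dataclass
class InfiltrationScores:
    """Samples x cell-type enrichment scores with scoring provenance."""

    scores: pd.DataFrame
    alpha_weight: float
    dropped_genes: dict[str, list[str]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class CorrelationMatrix:
    """Taxa x cell-type Spearman rho and two-sided p-values."""

    rho: pd.DataFrame
    p_value: pd.DataFrame

    def __post_init__(self) -> None:
        if self.rho.shape != self.p_value.shape:
            raise ValidationError("rho and p-value matrices must share shape")
        finite = self.rho.to_numpy()[np.isfinite(self.rho.to_numpy())]
        if len(finite) and (np.abs(finite) > 1 + 1e-12).any():
            raise ValidationError("Spearman rho must lie in [-1, 1]")


def _sample_enrichment(
    expr: pd.Series, in_set: np.ndarray, alpha_weight: float
) -> float:
    """Running-sum enrichment score for one sample (vector over genes)."""
    values = expr.to_numpy(dtype=float)
    n = len(values)
    ranks = rankdata(values)  # highest expression -> rank N; average ties
    # descending expression order; gene id as deterministic tie-break
    order = np.lexsort((expr.index.to_numpy(), -values))
    in_ordered = in_set[order]
    weights = np.where(in_ordered, ranks[order] ** alpha_weight, 0.0)
    total_in = weights.sum()
    n_out = n - int(in_set.sum())
    cum_in = np.cumsum(weights) / total_in
    if n_out > 0:
        cum_out = np.cumsum(~in_ordered) / n_out
    else:
        cum_out = np.zeros(n)
    return float((cum_in - cum_out).sum())


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha_weight: float = 0.25,
) -> InfiltrationScores:
    """Single-sample gene-set enrichment scores for every set and sample.

    Genes in a set but absent from the expression matrix are dropped
    with a warning; a set with no overlap at all is an error.
    """
    if expr.n_genes < 2:
        raise ValidationError("ssGSEA requires at least 2 genes")
    gene_index = pd.Index(expr.gene_ids)
    dropped: dict[str, list[str]] = {}
    membership: dict[str, np.ndarray] = {}
    for name in sets.names:
        members = sets[name]
        present = [g for g in members if g in gene_index]
        absent = [g for g in members if g not in gene_index]
        if not present:
            raise ValidationError(
                f"gene set {name!r} has no genes in the expression matrix"
            )
        if absent:
            dropped[name] = absent
        membership[name] = gene_index.isin(present)
    if dropped:
        n_abs = sum(len(v) for v in dropped.values())
        warnings.warn(
            f"dropped {n_abs} set genes absent from the expression matrix "
            f"(sets: {sorted(dropped)})",
            stacklevel=2,
        )

    data = expr.data
    scores = pd.DataFrame(
        {
            name: [
                _sample_enrichment(data[s], membership[name], alpha_weight)
                for s in expr.sample_ids
            ]
            for name in sets.names
        },
        index=expr.sample_ids,
    )
    return InfiltrationScores(scores, alpha_weight, dropped)


def spearman_correlation_matrix(
    abundance: AbundanceTable, scores: InfiltrationScores
) -> CorrelationMatrix:
    """Spearman rho and two-sided p per (taxon, cell type).

    Ties take average ranks.  Constant vectors have undefined rho and
    are reported as missing with a warning.
    """
    shared = [s for s in abundance.sample_ids if s in set(scores.sample_ids)]
    if len(shared) < 4:
        raise ValidationError(
            f"Spearman correlation requires >= 4 shared samples, found {len(shared)}"
        )
    a = abundance.data.loc[shared]
    s = scores.scores.loc[shared]
    taxa, cells = list(a.columns), list(s.columns)
    rho = pd.DataFrame(np.nan, index=taxa, columns=cells)
    pval = pd.DataFrame(np.nan, index=taxa, columns=cells)
    constant_seen = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on constant input
        for t in taxa:
            x = a[t].to_numpy()
            if np.all(x == x[0]):
                constant_seen = True
                continue
            for c in cells:
                y = s[c].to_numpy()
                if np.all(y == y[0]):
                    constant_seen = True
                    continue
                res = spearmanr(x, y)
                rho.loc[t, c] = res.statistic
                pval.loc[t, c] = res.pvalue
    if constant_seen:
        warnings.warn(
            "constant taxon or score vectors: rho undefined, reported as missing",
            stacklevel=2,
        )
    return CorrelationMatrix(rho, pval)
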