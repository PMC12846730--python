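"""Key-taxon selection funnel.

The funnel intersects three criteria over the gene-dependent microbes
(GDMs) of the dependency network:

1. differential enrichment between T and PT (two-sided paired Wilcoxon
   signed-rank test on per-pair relative abundances, p < alpha);
2. discriminative power — rank inside the top-k of a random-forest
   importance ranking (ntree = 100 by default; both mean decrease in
   accuracy and mean decrease in impurity are computed and combined by
   averaging their rank positions);
3. high tissue abundance — membership in the top-k taxa by mean
   relative abundance.

The intersection marks taxa with high tissue abundance, strong gene
dependency, and robust discriminative power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from cminet.datatypes import AbundanceTable, SampleMetadata
from cminet.errors import ConfigurationError, ValidationError
from cminet.preprocess import PhenotypeVector, relative_abundance


@dataclass
class ImportanceRanking:
    """Per-taxon random-forest importances and the combined rank.

    ``accuracy_decrease`` is the permutation importance (mean decrease
    in accuracy); ``impurity_decrease`` is the Gini importance.  Ranks
    are 1 = most important; the combined rank orders taxa by the mean
    of the two rank positions.
    """

    table: pd.DataFrame  # index: taxon; columns as documented above
    n_trees: int
    seed: int

    def __post_init__(self) -> None:
        ranks = np.sort(self.table["combined_rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.table) + 1)):
            raise ValidationError("combined ranks must be a permutation of 1..n_taxa")

    def top(self, k: int) -> set[str]:
        return set(self.table.nsmallest(k, "combined_rank").index)


@dataclass
class KeyTaxaResult:
    gdm_set: set[str]
    differential_gdm_set: set[str]
    rf_top_set: set[str]
    abundant_top_set: set[str]
    intersection: set[str]

    def __post_init__(self) -> None:
        expected = self.differential_gdm_set & self.rf_top_set & self.abundant_top_set
        if self.intersection != expected:
            raise ValidationError("intersection inconsistent with member sets")

    def membership_table(self) -> pd.DataFrame:
        taxa = sorted(
            self.gdm_set | self.differential_gdm_set | self.rf_top_set
            | self.abundant_top_set
        )
        return pd.DataFrame(
            {
                "gdm": [t in self.gdm_set for t in taxa],
                "differential_gdm": [t in self.differential_gdm_set for t in taxa],
                "rf_top": [t in self.rf_top_set for t in taxa],
                "abundant_top": [t in self.abundant_top_set for t in taxa],
                "key_taxon": [t in self.intersection for t in taxa],
            },
            index=pd.Index(taxa, name="taxon"),
        )


def _rank_descending(values: pd.Series) -> pd.Series:
    # 1 = largest importance; ties broken by taxon id for determinism
    order = values.to_frame("v").reset_index(names="taxon")
    order = order.sort_values(["v", "taxon"], ascending=[False, True])
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order["taxon"])
    return ranks.reindex(values.index)


def rank_rf_importance(
    abundance: AbundanceTable,
    phenotype: PhenotypeVector,
    n_trees: int = 100,
    seed: int = 0,
    n_permutation_repeats: int = 10,
) -> ImportanceRanking:
    """Random-forest taxon importance for discriminating the phenotype.

    The forest consumes relative abundances (binarization is specific
    to the CMI stage).  Mean decrease in accuracy is estimated by
    permutation importance with ``n_permutation_repeats`` shuffles per
    taxon; mean decrease in impurity is the built-in Gini importance.
    """
    if n_trees < 1:
        raise ConfigurationError("n_trees must be >= 1")
    y = phenotype.codes.reindex(abundance.sample_ids)
    if y.isna().any():
        raise ValidationError("phenotype missing for some samples")
    classes, counts = np.unique(y.to_numpy(), return_counts=True)
    if len(classes) < 2:
        raise ValidationError("phenotype has a single class")
    if (counts < 2).any():
        raise ValidationError("each phenotype class needs at least 2 samples")

    X = relative_abundance(abundance).data.to_numpy()
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y.to_numpy())
    impurity = pd.Series(forest.feature_importances_, index=abundance.taxon_ids)
    perm = permutation_importance(
        forest, X, y.to_numpy(), n_repeats=n_permutation_repeats, random_state=seed
    )
    accuracy = pd.Series(perm.importances_mean, index=abundance.taxon_ids)

    acc_rank = _rank_descending(accuracy)
    imp_rank = _rank_descending(impurity)
    combined = _rank_descending(-(acc_rank + imp_rank) / 2.0)
    table = pd.DataFrame(
        {
            "accuracy_decrease": accuracy,
            "impurity_decrease": impurity,
            "accuracy_rank": acc_rank,
            "impurity_rank": imp_rank,
            "combined_rank": combined,
        }
    )
    table.index.name = "taxon"
    return ImportanceRanking(table, n_trees=n_trees, seed=seed)


def top_abundant_taxa(abundance: AbundanceTable, k: int = 10) -> set[str]:
    """Top-k taxa by mean relative abundance across all samples.

    Ties are broken lexicographically by taxon id.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > abundance.n_taxa:
        warnings.warn(
            f"k={k} exceeds the {abundance.n_taxa} available taxa; returning all",
            stacklevel=2,
        )
        k = abundance.n_taxa
    means = relative_abundance(abundance).data.mean(axis=0)
    order = means.to_frame("mean").reset_index(names="taxon")
    order = order.sort_values(["mean", "taxon"], ascending=[False, True])
    return set(order["taxon"].head(k))


def differential_gdm_filter(
    gdms: set[str],
    abundance: AbundanceTable,
    metadata: SampleMetadata,
    alpha: float = 0.05,
) -> set[str]:
    """GDMs differentially enriched between T and PT.

    Uses a two-sided paired Wilcoxon signed-rank test on per-pair
    relative abundances, discarding zero differences (the classic
    convention); taxa with p < alpha are retained.  Taxa identical in
    every pair carry no signal and are removed.
    """
    if not gdms:
        return set()
    pairs = metadata.pairs()
    if pairs.shape[1] != 2:
        raise ValidationError("paired test requires exactly two phenotype levels")
    if len(pairs) < 3:
        raise ValidationError(
            f"paired test requires >= 3 complete pairs, found {len(pairs)}"
        )
    level_a, level_b = pairs.columns[0], pairs.columns[1]
    rel = relative_abundance(abundance).data
    kept = set()
    for taxon in sorted(gdms):
        if taxon not in rel.columns:
            raise ValidationError(f"GDM {taxon!r} absent from the abundance table")
        x = rel.loc[pairs[level_a], taxon].to_numpy()
        y = rel.loc[pairs[level_b], taxon].to_numpy()
        diffs = x - y
        if np.all(diffs == 0):
            continue
        res = wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
        if res.pvalue < alpha:
            kept.add(taxon)
    return kept


def intersect_key_taxa(
    differential_gdms: set[str],
    rf_ranking: ImportanceRanking,
    abundant: set[str],
    rf_k: int = 20,
    gdms: set[str] | None = None,
) -> KeyTaxaResult:
    """Intersect the three funnel criteria into the key-taxon set."""
    rf_top = rf_ranking.top(rf_k)
    intersection = set(differential_gdms) & rf_top & set(abundant)
    return KeyTaxaResult(
        gdm_set=set(gdms) if gdms is not None else set(differential_gdms),
        differential_gdm_set=set(differential_gdms),
        rf_top_set=rf_top,
        abundant_top_set=set(abundant),
        intersection=intersection,
    )
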