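"""In-memory containers for the three standard tables and gene sets.

All containers are thin, validated wrappers around pandas objects.
``AbundanceTable`` is oriented samples x taxa and ``ExpressionMatrix``
genes x samples, matching the conventions of microbiome and bulk RNA-seq
interchange files respectively; both expose a common samples-x-features
view so the preprocessing steps can treat them uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cminet.errors import ValidationError

PHENOTYPE_TUMOR = "T"
PHENOTYPE_PARACANCEROUS = "PT"


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


def _check_non_negative(df: pd.DataFrame, what: str) -> None:
    values = df.to_numpy()
    if not np.isfinite(values).all():
        raise ValidationError(f"{what} contains non-finite values")
    if (values < 0).any():
        row, col = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{what} contains a negative value at row {df.index[row]!r}, "
            f"column {df.columns[col]!r}"
        )


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of non-negative counts or relative abundances."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "taxon ids")
        _check_non_negative(self.data, "abundance table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def samples_by_features(self) -> pd.DataFrame:
        return self.data

    def with_data(self, data: pd.DataFrame) -> "AbundanceTable":
        return AbundanceTable(data)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression (FPKM or counts)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        _check_non_negative(self.data, "expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def samples_by_features(self) -> pd.DataFrame:
        return self.data.T

    def with_data(self, samples_by_features: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(samples_by_features.T)


@dataclass
class SampleMetadata:
    """Per-sample phenotype, pairing, clinical covariates and response label.

    ``data`` is indexed by sample id.  Required column: ``phenotype``
    (exactly two levels, e.g. T / PT).  Optional columns: ``pair_id``
    (each value occurring at most twice, once per phenotype),
    ``histology`` (e.g. LUAD / LUSC), ``response`` (CBR / NCB), and any
    number of named clinical covariates.  Missing clinical values stay
    missing (NaN); zero is a meaningful blood value and is never used to
    impute.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("metadata must be a DataFrame indexed by sample id")
        _check_unique(self.data.index, "sample ids")
        if "phenotype" not in self.data.columns:
            raise ValidationError("metadata requires a 'phenotype' column")
        levels = sorted(self.data["phenotype"].dropna().unique().tolist())
        if len(levels) != 2:
            raise ValidationError(
                f"phenotype must have exactly two levels, found {levels}"
            )
        if "pair_id" in self.data.columns:
            counts = self.data["pair_id"].dropna().value_counts()
            bad = counts[counts > 2]
            if len(bad):
                raise ValidationError(
                    f"pair_id values occurring more than twice: {list(bad.index)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def phenotype(self) -> pd.Series:
        return self.data["phenotype"]

    @property
    def phenotype_levels(self) -> list[str]:
        return sorted(self.data["phenotype"].dropna().unique().tolist())

    def pairs(self) -> pd.DataFrame:
        """Complete pairs as a frame with one row per pair_id and one
        column per phenotype level holding the member sample id."""
        if "pair_id" not in self.data.columns:
            raise ValidationError("metadata has no 'pair_id' column")
        wide = (
            self.data.reset_index(names="sample_id")
            .pivot_table(
                index="pair_id",
                columns="phenotype",
                values="sample_id",
                aggfunc="first",
            )
        )
        return wide.dropna()


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> member gene ids."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                # GMT files occasionally repeat members; keep first occurrence
                self.sets[name] = list(dict.fromkeys(members))

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]
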