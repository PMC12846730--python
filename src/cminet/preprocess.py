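"""Pre-processing for the dependency analysis.

Three steps precede CMI estimation: a prevalence filter keeping features
with nonzero abundance in at least ``min_samples`` samples (default 5),
per-feature median binarization (below the median -> 0, at or above ->
1), and a 0/1 encoding of the two-level phenotype.  Binarization uses
the conventional sample median (mean of the two middle order statistics
for even n), recorded per feature so the discretization is reproducible.

Features that are constant after binarization ("degenerate") carry no
information and make the permutation null degenerate; they are listed on
the result and excluded from network construction downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, TypeVar, Union

import numpy as np
import pandas as pd

from cminet.datatypes import AbundanceTable, ExpressionMatrix, SampleMetadata
from cminet.errors import ValidationError

TableT = TypeVar("TableT", bound=Union[AbundanceTable, ExpressionMatrix])


@dataclass
class BinaryMatrix:
    """Samples x features 0/1 matrix with its binarization provenance.

    ``medians`` records the per-feature threshold actually used;
    ``degenerate_features`` lists features whose binarized column is
    constant (all 0 or all 1).
    """

    data: pd.DataFrame
    medians: pd.Series
    degenerate_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("binary matrix entries must be 0 or 1")
        unknown = set(self.degenerate_features) - set(self.data.columns)
        if unknown:
            raise ValidationError(f"degenerate features not in matrix: {unknown}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def drop_degenerate(self) -> "BinaryMatrix":
        keep = [c for c in self.data.columns if c not in set(self.degenerate_features)]
        return BinaryMatrix(self.data[keep], self.medians[keep], [])


@dataclass
class PhenotypeVector:
    """Per-sample 0/1 phenotype codes plus the label -> code mapping."""

    codes: pd.Series
    mapping: dict[str, int]

    def __post_init__(self) -> None:
        if sorted(self.mapping.values()) != [0, 1]:
            raise ValidationError(
                f"phenotype mapping must assign codes 0 and 1, got {self.mapping}"
            )
        if not self.codes.isin([0, 1]).all():
            raise ValidationError("phenotype codes must be 0 or 1")

    @property
    def values(self) -> np.ndarray:
        return self.codes.to_numpy(dtype=np.int8)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.index)


def filter_prevalence(table: TableT, min_samples: int = 5) -> TableT:
    """Keep features with nonzero abundance in at least ``min_samples`` samples.

    Applied identically to taxa and genes.  Idempotent; preserves the
    input feature order and the full sample set.
    """
    if min_samples < 1:
        raise ValidationError("min_samples must be >= 1")
    sf = table.samples_by_features()
    prevalence = (sf > 0).sum(axis=0)
    keep = prevalence[prevalence >= min_samples].index
    if len(keep) == 0:
        warnings.warn(
            f"prevalence filter (min_samples={min_samples}) removed every feature",
            stacklevel=2,
        )
    return table.with_data(sf[keep])


def binarize_median(table: TableT | pd.DataFrame) -> BinaryMatrix:
    """Discretize each feature at its median across all samples.

    Values below the median map to 0; values equal to or above the
    median map to 1.  For an even number of samples the median is the
    mean of the two middle order statistics.
    """
    sf = table if isinstance(table, pd.DataFrame) else table.samples_by_features()
    if sf.shape[0] < 2:
        raise ValidationError(
            "median binarization requires at least 2 samples"
        )
    medians = sf.median(axis=0)
    binary = (sf >= medians).astype(np.int8)
    col_sums = binary.sum(axis=0)
    degenerate = binary.columns[
        (col_sums == 0) | (col_sums == binary.shape[0])
    ].tolist()
    return BinaryMatrix(binary, medians, degenerate)


def encode_phenotype(
    metadata: SampleMetadata, mapping: Mapping[str, int]
) -> PhenotypeVector:
    """Encode the two-level phenotype as 0/1 per an explicit mapping.

    The study convention is cancer=1 / control=0 for tumor status and
    LUAD=0 / LUSC=1 for histology; the mapping is always explicit and
    recorded on the result.
    """
    mapping = dict(mapping)
    labels = metadata.phenotype
    unmapped = sorted(set(labels.dropna()) - set(mapping))
    if unmapped:
        raise ValidationError(f"phenotype labels not in mapping: {unmapped}")
    codes = labels.map(mapping).astype(np.int8)
    return PhenotypeVector(codes, mapping)


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Normalise each sample row to sum to 1."""
    sums = table.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(
            f"samples with all-zero abundance cannot be normalised: "
            f"{list(zero.index)}"
        )
    return AbundanceTable(table.data.div(sums, axis=0))
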