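"""Alpha diversity, beta distances, PCoA and PERMANOVA.

Alpha indices follow the conventions of the classic community-ecology
toolkits: bias-corrected Chao1 (defined even when doubletons are
absent), Shannon entropy with the natural logarithm, and Simpson as
1 - sum(p_i^2).  Beta distances are Bray-Curtis, binary Jaccard on
presence/absence, and Euclidean.  Ordination is classical PCoA (Gower
double-centering); group separation is tested with one-way PERMANOVA
(pseudo-F on the distance partition, permutation p with the add-one
correction).

PERMANOVA is implemented in-package so that the permutation stream is
seeded and the R^2 partition is reported alongside the pseudo-F; the
statistic agrees with scikit-bio's implementation (checked in the test
suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.stats.distance import DistanceMatrix as SkbioDistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from cminet.datatypes import AbundanceTable
from cminet.errors import ValidationError

BETA_METRICS = ("bray_curtis", "binary_jaccard", "euclidean")


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample distance matrix with its metric name."""

    data: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.shape[0] != values.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(values, values.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if (values < 0).any():
            raise ValidationError("distances must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def to_skbio(self) -> SkbioDistanceMatrix:
        return SkbioDistanceMatrix(
            self.data.to_numpy(), ids=[str(s) for s in self.data.index]
        )


@dataclass
class OrdinationResult:
    """PCoA coordinates with eigenvalues and variance explained.

    Only axes with positive eigenvalues are embedded; negative
    eigenvalues (possible for non-Euclidean distances) are reported in
    ``all_eigenvalues`` but carry no coordinates.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    all_eigenvalues: np.ndarray


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1:
            raise ValidationError("R^2 must lie in [0, 1]")
        if not 0 < self.p_value <= 1:
            raise ValidationError("p-value must lie in (0, 1]")


def _as_abundance_vector(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("abundance vector must be one-dimensional")
    if (arr < 0).any():
        raise ValidationError("abundances must be non-negative")
    return arr


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the singleton and doubleton counts; the bias-corrected
    form stays defined when no doubletons are observed.  Requires
    integer counts — richness estimation is undefined for relative
    abundances.
    """
    arr = _as_abundance_vector(counts)
    if not np.all(arr == np.round(arr)):
        raise ValidationError("chao1 requires integer counts")
    return float(_skbio_chao1(arr.astype(np.int64), bias_corrected=True))


def shannon(abundances) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log, zeros ignored)."""
    arr = _as_abundance_vector(abundances)
    total = arr.sum()
    if total == 0:
        raise ValidationError("cannot compute Shannon entropy of an all-zero vector")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(abundances) -> float:
    """Gini-Simpson index 1 - sum p_i^2."""
    arr = _as_abundance_vector(abundances)
    total = arr.sum()
    if total == 0:
        raise ValidationError("cannot compute Simpson index of an all-zero vector")
    p = arr / total
    return float(1 - (p**2).sum())


def alpha_diversity_table(table: AbundanceTable, include_chao1: bool = True) -> pd.DataFrame:
    """Per-sample alpha diversity (chao1 where counts are integer)."""
    rows = {}
    for sample in table.sample_ids:
        vec = table.data.loc[sample].to_numpy()
        row = {"shannon": shannon(vec), "simpson": simpson(vec)}
        if include_chao1:
            row["chao1"] = chao1(vec)
        rows[sample] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def beta_distance(table: AbundanceTable, metric: str) -> DistanceMatrix:
    """Pairwise sample distances under one of the supported metrics."""
    if metric not in BETA_METRICS:
        raise ValidationError(f"metric must be one of {BETA_METRICS}, got {metric!r}")
    if table.n_samples < 2:
        raise ValidationError("beta diversity requires at least 2 samples")
    X = table.data.to_numpy(dtype=float)
    if metric == "bray_curtis":
        condensed = pdist(X, "braycurtis")
        if np.isnan(condensed).any():
            warnings.warn(
                "Bray-Curtis between all-zero samples defined as 0", stacklevel=2
            )
            condensed = np.nan_to_num(condensed, nan=0.0)
    elif metric == "binary_jaccard":
        condensed = pdist(X > 0, "jaccard")
        condensed = np.nan_to_num(condensed, nan=0.0)  # two empty samples
    else:
        condensed = pdist(X, "euclidean")
    dm = pd.DataFrame(
        squareform(condensed), index=table.sample_ids, columns=table.sample_ids
    )
    return DistanceMatrix(dm, metric)


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical principal coordinate analysis of a distance matrix."""
    with warnings.catch_warnings():
        # negative eigenvalues are reported explicitly on the result
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(d.to_skbio(), method="eigh", warn_neg_eigval=False)
    eigvals = res.eigvals.to_numpy()
    positive = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    n_positive = int(positive.sum())
    if n_axes is None:
        n_axes = n_positive
    elif n_axes > n_positive:
        warnings.warn(
            f"requested {n_axes} axes but only {n_positive} positive "
            f"eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_positive
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.index = d.sample_ids
    total = eigvals[positive].sum()
    proportion = eigvals[:n_axes] / total if total > 0 else eigvals[:n_axes] * 0.0
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eigvals[:n_axes],
        proportion_explained=proportion,
        all_eigenvalues=eigvals,
    )


def _permanova_ssw(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ssw = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ssw


def permanova(
    d: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA (pseudo-F on the among/within distance partition).

    The total sum of squares is partitioned following the standard
    distance-based ANOVA decomposition; significance comes from
    permuting the group labels, with the add-one correction
    p = (1 + #{F_perm >= F}) / (n_perm + 1).
    """
    labels = pd.Series(grouping)
    if len(labels) != len(d.sample_ids):
        raise ValidationError("grouping length must match the distance matrix")
    groups, counts = np.unique(labels.to_numpy(), return_counts=True)
    if len(groups) < 2:
        raise ValidationError("PERMANOVA requires at least 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise ValidationError(f"groups with fewer than 2 samples: {small}")

    d2 = d.data.to_numpy() ** 2
    n = d2.shape[0]
    a = len(groups)
    ss_total = d2.sum() / (2 * n)
    lab = labels.to_numpy()

    # one-hot label matrix lets the permuted within-group sums be a
    # single quadratic form per group
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)

    def pseudo_f(ssw: np.ndarray) -> np.ndarray:
        ssa = ss_total - ssw
        return (ssa / (a - 1)) / (ssw / (n - a))

    ssw_real = _permanova_ssw(d2, lab, groups)
    f_real = float(pseudo_f(np.array([ssw_real]))[0])

    ssw_perm = np.zeros(n_perm)
    for g, n_g in zip(groups, counts):
        member = (lab == g).astype(float)
        P = member[perms]                       # (n_perm, n) permuted indicators
        ssw_perm += ((P @ d2) * P).sum(axis=1) / (2 * n_g)
    f_perm = pseudo_f(ssw_perm)

    p_value = (1 + int((f_perm >= f_real - 1e-12).sum())) / (n_perm + 1)
    r_squared = float((ss_total - ssw_real) / ss_total) if ss_total > 0 else 0.0
    return PermanovaResult(
        pseudo_f=f_real,
        r_squared=min(max(r_squared, 0.0), 1.0),
        p_value=p_value,
        n_permutations=n_perm,
        seed=seed,
    )
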