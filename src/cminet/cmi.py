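"""Discrete conditional mutual information and the dependency network.

The dependency of a gene G on a microbe M in the context of a phenotype
P is quantified as the conditional mutual information I(G;M|P) of the
median-binarized variables, estimated by the plug-in over the empirical
2x2x2 contingency table:

    CMI = sum_{g,m,p} (n_gmp / n) * log2( n_gmp * n_p / (n_gp * n_mp) )

with the convention 0*log(0) = 0.  Base-2 logarithms are used so the
value is in bits and bounded by 1 for binary variables; the base does
not affect p-values or edge sets.

Significance is assessed by permuting the microbe vector: the real CMI
is compared against ``n_perm`` null CMI values from random permutations
of M (G and P held fixed).  Two p-value conventions are available:
``add_one`` (the default), p = (1 + #{null >= real}) / (n_perm + 1),
which is a valid permutation p-value; and ``literal_rank``, the
descending rank of the real value in the null distribution divided by
``n_perm``.  Ties between the real and null values count toward the
null (conservative).

Pairs with p below ``alpha`` form the edges of a bipartite microbe-gene
dependency network.  Each pair draws its permutations from a dedicated
substream derived from (seed, microbe index, gene index), so the network
is invariant to the order in which pairs are evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from cminet.errors import ConfigurationError, ValidationError
from cminet.preprocess import BinaryMatrix, PhenotypeVector

PMode = Literal["add_one", "literal_rank"]
Direction = Literal["gm_given_p", "gp_given_m"]

# numerical tolerance when comparing a null CMI with the real one; the
# two are produced by the same floating-point path, so anything within
# this band is a genuine tie
_TIE_EPS = 1e-12


@dataclass
class PermutationConfig:
    """Parameters of the permutation significance test."""

    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    p_mode: PMode = "add_one"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.p_mode not in ("add_one", "literal_rank"):
            raise ConfigurationError(f"unknown p_mode {self.p_mode!r}")


@dataclass
class DependencyPair:
    microbe_id: str
    gene_id: str
    cmi: float
    p_value: float
    significant: bool


@dataclass
class DependencyNetwork:
    """Bipartite microbe-gene network of significant dependency pairs.

    ``edges`` holds only the significant pairs; ``results`` is the full
    per-pair table (microbe, gene, cmi, p_value, significant) for all
    evaluated pairs.
    """

    edges: list[DependencyPair]
    microbes: list[str]
    genes: list[str]
    params: dict
    results: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        microbe_set, gene_set = set(self.microbes), set(self.genes)
        for e in self.edges:
            if e.microbe_id not in microbe_set or e.gene_id not in gene_set:
                raise ValidationError(
                    f"edge ({e.microbe_id}, {e.gene_id}) is not microbe-gene bipartite"
                )
            if not e.significant:
                raise ValidationError("network edges must all be significant")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.microbe_id, e.gene_id) for e in self.edges}


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0/1 entries")
    return arr.astype(np.float64)


def _cmi_rows_cond_fixed(M: np.ndarray, g: np.ndarray, p: np.ndarray) -> np.ndarray:
    """I(g ; M[r] | p) in bits for each row r of M (binary, shape k x n)."""
    n = g.shape[0]
    # joint (g, p) cell indicators; columns: (g=1,p=1), (1,0), (0,1), (0,0)
    W = np.stack([g * p, g * (1 - p), (1 - g) * p, (1 - g) * (1 - p)], axis=1)
    n_gp = W.sum(axis=0)                       # (4,) fixed margins
    C1 = M @ W                                 # (k, 4) cells with m=1
    C0 = n_gp[None, :] - C1                    # cells with m=0
    n_m1p1 = M @ p
    n_m1p0 = M @ (1 - p)
    n_p1 = p.sum()
    n_p0 = n - n_p1
    n_mp1 = np.stack([n_m1p1, n_m1p0, n_m1p1, n_m1p0], axis=1)
    n_mp0 = np.stack(
        [n_p1 - n_m1p1, n_p0 - n_m1p0, n_p1 - n_m1p1, n_p0 - n_m1p0], axis=1
    )
    n_c = np.array([n_p1, n_p0, n_p1, n_p0])

    def terms(cells: np.ndarray, n_mp: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = cells * n_c[None, :] / (n_gp[None, :] * n_mp)
            t = cells / n * np.log2(ratio)
        return np.where(cells > 0, t, 0.0).sum(axis=1)

    return terms(C1, n_mp1) + terms(C0, n_mp0)


def _cmi_rows_cond_rows(M: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """I(x ; y | M[r]) in bits for each row r of M (M is the conditioner)."""
    n = x.shape[0]
    W = np.stack([x * y, x * (1 - y), (1 - x) * y, (1 - x) * (1 - y)], axis=1)
    n_xy = W.sum(axis=0)
    C1 = M @ W                                  # cells with m=1
    C0 = n_xy[None, :] - C1
    n_x1m1 = M @ x
    n_y1m1 = M @ y
    n_m1 = M.sum(axis=1)
    n_m0 = n - n_m1
    n_x1 = x.sum()
    n_y1 = y.sum()
    # per column (x=a, y=b): margins n_{x=a, m} and n_{y=b, m}
    n_xm1 = np.stack([n_x1m1, n_x1m1, n_m1 - n_x1m1, n_m1 - n_x1m1], axis=1)
    n_ym1 = np.stack([n_y1m1, n_m1 - n_y1m1, n_y1m1, n_m1 - n_y1m1], axis=1)
    n_xm0 = np.stack(
        [n_x1 - n_x1m1, n_x1 - n_x1m1, n_m0 - (n_x1 - n_x1m1), n_m0 - (n_x1 - n_x1m1)],
        axis=1,
    )
    n_ym0 = np.stack(
        [n_y1 - n_y1m1, n_m0 - (n_y1 - n_y1m1), n_y1 - n_y1m1, n_m0 - (n_y1 - n_y1m1)],
        axis=1,
    )

    def terms(cells, n_xm, n_ym, n_m):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = cells * n_m[:, None] / (n_xm * n_ym)
            t = cells / n * np.log2(ratio)
        return np.where(cells > 0, t, 0.0).sum(axis=1)

    return terms(C1, n_xm1, n_ym1, n_m1) + terms(C0, n_xm0, n_ym0, n_m0)


def cmi_discrete(g, m, p) -> float:
    """Plug-in conditional mutual information I(g; m | p) in bits.

    All three vectors must be binary and of equal length >= 2.  The
    estimate is non-negative and is exactly 0 when g and m are
    conditionally independent in the empirical table.
    """
    g, m, p = _as_binary(g, "g"), _as_binary(m, "m"), _as_binary(p, "p")
    if not (g.shape == m.shape == p.shape):
        raise ValidationError("g, m, p must have equal length")
    if g.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    value = float(_cmi_rows_cond_fixed(m[None, :], g, p)[0])
    return max(value, 0.0)  # clip away -0.0 / rounding at the boundary


def permutation_test(
    g,
    m,
    p,
    config: PermutationConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
    direction: Direction = "gm_given_p",
) -> tuple[float, float]:
    """Real CMI of (g, m | p) and its permutation p-value.

    Only the microbe vector ``m`` is permuted; ``g`` and ``p`` stay
    fixed.  Degenerate (constant) g or m yields (0.0, 1.0) with a
    warning, since every permutation reproduces the same table.
    """
    config = config or PermutationConfig()
    g, m, p = _as_binary(g, "g"), _as_binary(m, "m"), _as_binary(p, "p")
    if not (g.shape == m.shape == p.shape):
        raise ValidationError("g, m, p must have equal length")
    if g.min() == g.max() or m.min() == m.max():
        warnings.warn(
            "degenerate (constant) variable: CMI defined as 0 with p = 1",
            stacklevel=2,
        )
        return 0.0, 1.0
    if rng is None:
        rng = np.random.default_rng(config.seed)
    null_m = rng.permuted(np.tile(m, (config.n_perm, 1)), axis=1)
    if direction == "gm_given_p":
        real = float(_cmi_rows_cond_fixed(m[None, :], g, p)[0])
        null = _cmi_rows_cond_fixed(null_m, g, p)
    elif direction == "gp_given_m":
        real = float(_cmi_rows_cond_rows(m[None, :], g, p)[0])
        null = _cmi_rows_cond_rows(null_m, g, p)
    else:
        raise ConfigurationError(f"unknown direction {direction!r}")
    real = max(real, 0.0)
    n_ge = int((null >= real - _TIE_EPS).sum())
    if config.p_mode == "add_one":
        p_value = (1 + n_ge) / (config.n_perm + 1)
    else:  # literal_rank: descending rank of the real value / n_perm
        p_value = min(1.0, (1 + n_ge) / config.n_perm)
    return real, p_value


def build_dependency_network(
    microbes: BinaryMatrix,
    genes: BinaryMatrix,
    phenotype: PhenotypeVector,
    config: PermutationConfig | None = None,
    *,
    direction: Direction = "gm_given_p",
    fdr: bool = False,
) -> DependencyNetwork:
    """Evaluate every microbe-gene pair and keep the significant edges.

    Each pair (i, j) uses an independent, deterministic permutation
    substream derived from (config.seed, i, j), so the edge set does not
    depend on evaluation order.  With ``fdr=True`` significance is
    decided on Benjamini-Hochberg adjusted p-values instead of the flat
    threshold.
    """
    config = config or PermutationConfig()
    shared = [s for s in microbes.sample_ids if s in set(genes.sample_ids)]
    if not shared:
        raise ValidationError("microbe and gene matrices share no samples")
    if len(shared) < len(microbes.sample_ids) or len(shared) < len(genes.sample_ids):
        warnings.warn(
            f"restricting to {len(shared)} shared samples", stacklevel=2
        )
    m_data = microbes.data.loc[shared]
    g_data = genes.data.loc[shared]
    p_codes = phenotype.codes.reindex(shared)
    if p_codes.isna().any():
        raise ValidationError("phenotype missing for some shared samples")
    p_vec = p_codes.to_numpy(dtype=np.float64)

    for bm, what in ((microbes, "microbe"), (genes, "gene")):
        if bm.degenerate_features:
            warnings.warn(
                f"excluding {len(bm.degenerate_features)} degenerate {what} "
                f"features from the network",
                stacklevel=2,
            )
    m_keep = [c for c in m_data.columns if c not in set(microbes.degenerate_features)]
    g_keep = [c for c in g_data.columns if c not in set(genes.degenerate_features)]
    m_arr = m_data[m_keep].to_numpy(dtype=np.float64)
    g_arr = g_data[g_keep].to_numpy(dtype=np.float64)

    rows = []
    for i, microbe_id in enumerate(m_keep):
        m_vec = m_arr[:, i]
        for j, gene_id in enumerate(g_keep):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(i, j))
            )
            cmi, p_value = permutation_test(
                g_arr[:, j], m_vec, p_vec, config, rng=rng, direction=direction
            )
            rows.append((microbe_id, gene_id, cmi, p_value))

    results = pd.DataFrame(rows, columns=["microbe", "gene", "cmi", "p_value"])
    if fdr and len(results):
        from statsmodels.stats.multitest import multipletests

        results["p_adjusted"] = multipletests(
            results["p_value"], method="fdr_bh"
        )[1]
        results["significant"] = results["p_adjusted"] < config.alpha
    else:
        results["significant"] = results["p_value"] < config.alpha

    edges = [
        DependencyPair(r.microbe, r.gene, r.cmi, r.p_value, True)
        for r in results[results["significant"]].itertuples()
    ]
    params = {
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "seed": config.seed,
        "p_mode": config.p_mode,
        "direction": direction,
        "fdr": fdr,
    }
    return DependencyNetwork(edges, m_keep, g_keep, params, results)


def gene_dependent_microbes(network: DependencyNetwork) -> dict[str, int]:
    """Microbes with at least one significant edge, with their edge counts.

    These are the gene-dependent microbes (GDMs) of the analysis; the
    returned mapping is ordered by decreasing edge count.
    """
    counts: dict[str, int] = {}
    for e in network.edges:
        counts[e.microbe_id] = counts.get(e.microbe_id, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
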