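"""Synthetic paired tumor/paracancerous cohorts with planted ground truth.

Real paired tissue-microbiome cohorts of this design are not publicly
deposited, so every downstream stage is exercised on a generator whose
signal is known exactly:

* microbial counts are zero-inflated negative binomial (dispersion
  fixed at 1.0) with per-taxon log-normal means across taxa; the
  paracancerous (PT) mean is ``pt_enrichment`` times the tumor (T)
  mean, reproducing the higher abundance and richness of paracancerous
  tissue;
* gene expression is log-normal;
* each planted dependency (taxon m, gene g, effect size delta) shifts
  the log-expression of g by +delta * sigma in the samples whose
  m-abundance is at or above the taxon's median across all samples.
  Planting thereby acts on the binarized microbe state — exactly the
  quantity the CMI stage measures, which discretizes at the
  across-sample median — so delta maps directly onto detection power.
  (A within-stratum median split would decouple the planted signal
  from the measured binarized state as soon as PT enrichment separates
  the strata, silently attenuating delta.)
  Planted taxa are drawn without structural zeros and with their mean
  abundance floored at the across-taxa log-normal median: a taxon
  absent from most samples has a constant binarized state, in which
  case the median-split shift applies to (almost) every sample and no
  dependency is actually planted.  Key taxa in this design are
  high-abundance taxa, so the exemption matches what the planted signal
  is meant to emulate;
* the immunotherapy-response generator draws routine blood covariates
  and a PT Prevotella abundance, forms a latent linear score with
  Gaussian noise, and labels a patient CBR (clinical benefit response)
  iff the latent score exceeds the cutoff.

All randomness flows from the single integer seed of the config through
one numpy Generator; identical configs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cminet.datatypes import (
    AbundanceTable,
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
)
from cminet.errors import ConfigurationError

# log-scale parameters of the per-taxon mean distribution and of gene
# expression; heavy-tailed low-biomass profiles without extra knobs
_TAXON_MEAN_LOG_MU = np.log(10.0)
_TAXON_MEAN_LOG_SIGMA = 1.0
_GENE_LOG_MU = 3.0
_GENE_LOG_SIGMA = 1.0
_NB_DISPERSION = 1.0


@dataclass
class CohortConfig:
    """Parameters of the paired-cohort generator."""

    n_pairs: int = 30
    n_taxa: int = 20
    n_genes: int = 50
    pt_enrichment: float = 2.0
    zero_inflation: float = 0.2
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 3:
            raise ConfigurationError("n_pairs must be >= 3")
        if self.n_taxa < 1 or self.n_genes < 1:
            raise ConfigurationError("n_taxa and n_genes must be >= 1")
        if self.pt_enrichment <= 0:
            raise ConfigurationError("pt_enrichment must be positive")
        if not 0 <= self.zero_inflation <= 1:
            raise ConfigurationError("zero_inflation must lie in [0, 1]")
        for m, g, delta in self.planted_pairs:
            if not 0 <= m < self.n_taxa:
                raise ConfigurationError(f"planted taxon index {m} out of range")
            if not 0 <= g < self.n_genes:
                raise ConfigurationError(f"planted gene index {g} out of range")
            if delta < 0:
                raise ConfigurationError("planted effect size delta must be >= 0")


@dataclass
class SyntheticCohort:
    abundance: AbundanceTable
    expression: ExpressionMatrix
    metadata: SampleMetadata
    truth_edges: list[tuple[int, int, float]]
    config: CohortConfig

    @property
    def taxon_name(self):
        return lambda i: self.abundance.taxon_ids[i]

    def truth_edge_ids(self) -> set[tuple[str, str]]:
        """Planted edges as (taxon id, gene id) pairs."""
        taxa = self.abundance.taxon_ids
        genes = self.expression.gene_ids
        return {(taxa[m], genes[g]) for m, g, _ in self.truth_edges}


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
    """NB draws parameterised by mean and fixed dispersion (size) k=1."""
    k = _NB_DISPERSION
    return rng.negative_binomial(k, k / (k + mean))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a paired T/PT cohort with planted microbe-gene dependencies."""
    rng = np.random.default_rng(config.seed)
    n_pairs, n_taxa, n_genes = config.n_pairs, config.n_taxa, config.n_genes
    n_samples = 2 * n_pairs

    sample_ids, pair_ids, phenotypes = [], [], []
    for k in range(n_pairs):
        for pheno in ("T", "PT"):
            sample_ids.append(f"P{k + 1:03d}_{pheno}")
            pair_ids.append(f"P{k + 1:03d}")
            phenotypes.append(pheno)
    phenotypes = np.array(phenotypes)
    is_pt = phenotypes == "PT"

    taxon_ids = [f"g__Taxon{i + 1:03d}" for i in range(n_taxa)]
    gene_ids = [f"GENE{j + 1:04d}" for j in range(n_genes)]

    # per-taxon T means, log-normal across taxa; PT scaled up
    base_mean = rng.lognormal(_TAXON_MEAN_LOG_MU, _TAXON_MEAN_LOG_SIGMA, size=n_taxa)
    planted_taxa = np.array(
        sorted({m for m, _, _ in config.planted_pairs}), dtype=int
    )
    if len(planted_taxa):
        # planted dependencies live on prevalent taxa: floor the mean at
        # the across-taxa log-normal median so the median split is real
        base_mean[planted_taxa] = np.maximum(
            base_mean[planted_taxa], np.exp(_TAXON_MEAN_LOG_MU)
        )
    mean = np.where(is_pt[:, None], config.pt_enrichment * base_mean, base_mean)
    counts = _negative_binomial(rng, mean)
    structural_zero = rng.random((n_samples, n_taxa)) < config.zero_inflation
    if len(planted_taxa):
        structural_zero[:, planted_taxa] = False
    counts = np.where(structural_zero, 0, counts)

    gene_mu = rng.normal(_GENE_LOG_MU, 1.0, size=n_genes)
    log_expr = rng.normal(gene_mu[None, :], _GENE_LOG_SIGMA, size=(n_samples, n_genes))

    # planting: samples whose planted taxon is at/above its median
    # across all samples get a +delta*sigma shift in the planted gene's
    # log-expression — the same split the CMI stage binarizes at
    for m, g, delta in config.planted_pairs:
        med = np.median(counts[:, m])
        high = counts[:, m] >= med
        log_expr[high, g] += delta * _GENE_LOG_SIGMA

    abundance = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxon_ids)
    )
    expression = ExpressionMatrix(
        pd.DataFrame(np.exp(log_expr).T, index=gene_ids, columns=sample_ids)
    )
    metadata = SampleMetadata(
        pd.DataFrame(
            {"pair_id": pair_ids, "phenotype": phenotypes},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return SyntheticCohort(
        abundance=abundance,
        expression=expression,
        metadata=metadata,
        truth_edges=list(config.planted_pairs),
        config=config,
    )


def generate_response_cohort(
    n_patients: int,
    coeffs: dict[str, float] | None = None,
    cutoff: float = 720.7,
    noise_sd: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Patients with blood covariates and a response label from a known score.

    Covariates are drawn from ranges typical of routine NSCLC clinical
    chemistry (Ca in mmol/L, Age in years, HGB in g/L, HCT as a
    fraction, ALT in U/L) plus a PT Prevotella relative abundance.  The
    latent score is the linear combination under ``coeffs`` plus
    N(0, noise_sd) noise; the label is CBR iff the latent score exceeds
    ``cutoff``, NCB otherwise.  The latent score is retained in the
    ``truth_score`` column.
    """
    if n_patients < 4:
        raise ConfigurationError("n_patients must be >= 4")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if coeffs is None:
        from cminet.predictor import PUBLISHED_PANEL

        coeffs = dict(PUBLISHED_PANEL.coefficients)
    rng = np.random.default_rng(seed)
    n = n_patients
    cov = pd.DataFrame(
        {
            "PT_Prevotella": rng.uniform(0.0, 0.2, n),
            "Ca": rng.normal(2.35, 0.15, n).clip(min=1.5),
            "Age": rng.integers(35, 81, n).astype(float),
            "HGB": rng.normal(135.0, 15.0, n).clip(min=60.0),
            "HCT": rng.normal(0.41, 0.04, n).clip(0.2, 0.6),
            "ALT": rng.lognormal(np.log(25.0), 0.45, n),
        },
        index=pd.Index([f"PT{k + 1:03d}" for k in range(n)], name="sample_id"),
    )
    missing = [name for name in coeffs if name not in cov.columns]
    if missing:
        raise ConfigurationError(f"coefficients without generated covariates: {missing}")
    linear = sum(coeffs[name] * cov[name] for name in coeffs)
    latent = linear + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else linear
    cov["truth_score"] = latent
    cov["response"] = np.where(latent > cutoff, "CBR", "NCB")
    return cov


def synthetic_immune_gene_sets(
    gene_ids: list[str],
    n_sets: int = 28,
    set_size: int = 8,
    seed: int = 0,
) -> GeneSetCollection:
    """Synthetic stand-in for an immune cell-type signature collection.

    Draws ``n_sets`` random, possibly overlapping gene sets from the
    supplied universe.  These are synthetic signatures for exercising
    the ssGSEA stage; they are not the published 28 immune cell-type
    marker sets.
    """
    rng = np.random.default_rng(seed)
    size = min(set_size, len(gene_ids))
    sets = {
        f"ImmuneSet{k + 1:02d}": sorted(
            rng.choice(gene_ids, size=size, replace=False).tolist()
        )
        for k in range(n_sets)
    }
    descriptions = {name: "synthetic immune signature" for name in sets}
    return GeneSetCollection(sets, descriptions)
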