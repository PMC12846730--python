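"""End-to-end orchestration: synthesize -> preprocess -> CMI network ->
key taxa -> diversity -> infiltration -> predictor, with a run manifest.

A run is described by a single flat :class:`RunConfig` (one
reproducibility artifact per run).  Stages execute in dependency order;
every output is a TSV under the run's output directory, and the
manifest records the config echo, per-output SHA-256 checksums,
captured warnings, package version and wall timestamps.  Identical
config and seed give byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import cminet
from cminet import io as cio
from cminet.cmi import PermutationConfig, build_dependency_network, gene_dependent_microbes
from cminet.datatypes import AbundanceTable, ExpressionMatrix, SampleMetadata
from cminet.diversity import (
    BETA_METRICS,
    alpha_diversity_table,
    beta_distance,
    pcoa,
    permanova,
)
from cminet.errors import ConfigurationError
from cminet.infiltration import spearman_correlation_matrix, ssgsea_scores
from cminet.predictor import (
    PUBLISHED_PANEL,
    classify_responder,
    combined_score,
    fit_response_glm,
    roc_auc,
    train_val_split,
)
from cminet.preprocess import binarize_median, encode_phenotype, filter_prevalence
from cminet.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_response_cohort,
    synthetic_immune_gene_sets,
)
from cminet.taxa import (
    differential_gdm_filter,
    intersect_key_taxa,
    rank_rf_importance,
    top_abundant_taxa,
)

ALL_STAGES = (
    "simulate",
    "preprocess",
    "cmi",
    "key_taxa",
    "diversity",
    "infiltration",
    "predict",
)

# stage -> stages that must also be enabled (or replaced by input files)
_REQUIRES = {
    "preprocess": ("simulate",),
    "cmi": ("preprocess",),
    "key_taxa": ("cmi",),
    "diversity": ("simulate",),
    "infiltration": ("simulate",),
}


@dataclass
class RunConfig:
    """Flat configuration of an end-to-end run (defaults mirror the
    study parameters: prevalence >= 5 samples, 1000 permutations at
    alpha 0.05, 100 trees, RF top 20, abundance top 10, 8:2 split)."""

    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # synthetic cohort
    n_pairs: int = 30
    n_taxa: int = 20
    n_genes: int = 50
    pt_enrichment: float = 2.0
    zero_inflation: float = 0.2
    planted_pairs: list = field(default_factory=lambda: [[0, 0, 2.0], [1, 1, 2.0], [2, 2, 2.0]])
    # external inputs (used instead of the simulate stage when given)
    abundance_path: str | None = None
    expression_path: str | None = None
    metadata_path: str | None = None
    gene_sets_path: str | None = None
    # stage parameters
    min_prevalence: int = 5
    n_perm: int = 1000
    alpha: float = 0.05
    p_mode: str = "add_one"
    cmi_direction: str = "gm_given_p"
    rf_trees: int = 100
    rf_top_k: int = 20
    abundance_top_k: int = 10
    beta_metric: str = "binary_jaccard"
    permanova_perms: int = 999
    n_immune_sets: int = 28
    split_ratio: float = 0.8
    response_n_patients: int = 100
    response_noise_sd: float = 50.0
    seed: int = 0
    outdir: str = "cminet_run"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if self.min_prevalence < 1:
            raise ConfigurationError("min_prevalence must be >= 1")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.rf_trees < 1:
            raise ConfigurationError("rf_trees must be >= 1")
        if self.rf_top_k < 1 or self.abundance_top_k < 1:
            raise ConfigurationError("top-k parameters must be >= 1")
        if self.beta_metric not in BETA_METRICS:
            raise ConfigurationError(f"beta_metric must be one of {BETA_METRICS}")
        if not 0 < self.split_ratio < 1:
            raise ConfigurationError("split_ratio must lie in (0, 1)")
        if self.permanova_perms < 1:
            raise ConfigurationError("permanova_perms must be >= 1")

    def has_inputs(self) -> bool:
        return self.abundance_path is not None

    def validate_dag(self) -> None:
        enabled = set(self.stages)
        for stage, deps in _REQUIRES.items():
            if stage not in enabled:
                continue
            for dep in deps:
                if dep in enabled:
                    continue
                if dep == "simulate" and self.has_inputs():
                    continue
                raise ConfigurationError(
                    f"stage {stage!r} requires stage {dep!r} (or input files)"
                )


def validate_config(path: str | Path) -> RunConfig:
    """Load, type and range-check a YAML run config.

    An empty file yields the full default configuration.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    config = RunConfig(**raw)
    config.validate_dag()
    return config


@dataclass
class RunManifest:
    config: dict
    stages: list[dict]
    warnings: list[str]
    version: str
    started: float
    finished: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.stage_records: list[dict] = []
        self.warnings: list[str] = []
        # shared state between stages
        self.cohort = None
        self.abundance: AbundanceTable | None = None
        self.expression: ExpressionMatrix | None = None
        self.metadata: SampleMetadata | None = None
        self.gene_sets = None
        self.microbes_bin = None
        self.genes_bin = None
        self.phenotype = None
        self.network = None
        self.gdm_counts = None

    def _write(self, name: str, writer) -> Path:
        path = self.outdir / name
        writer(path)
        return path

    def _record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stage_records.append(
            {
                "stage": stage,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "seconds": round(seconds, 3),
            }
        )

    # ----- stages -------------------------------------------------------

    def simulate(self) -> list[Path]:
        cfg = self.config
        cohort = generate_cohort(
            CohortConfig(
                n_pairs=cfg.n_pairs,
                n_taxa=cfg.n_taxa,
                n_genes=cfg.n_genes,
                pt_enrichment=cfg.pt_enrichment,
                zero_inflation=cfg.zero_inflation,
                planted_pairs=[tuple(p) for p in cfg.planted_pairs],
                seed=cfg.seed,
            )
        )
        self.cohort = cohort
        self.abundance = cohort.abundance
        self.expression = cohort.expression
        self.metadata = cohort.metadata
        self.gene_sets = synthetic_immune_gene_sets(
            cohort.expression.gene_ids, n_sets=cfg.n_immune_sets, seed=cfg.seed
        )
        truth = pd.DataFrame(
            [
                (cohort.abundance.taxon_ids[m], cohort.expression.gene_ids[g], d)
                for m, g, d in cohort.truth_edges
            ],
            columns=["microbe", "gene", "delta"],
        )
        return [
            self._write("abundance.tsv", lambda p: cio.write_abundance_table(self.abundance, p)),
            self._write("expression.tsv", lambda p: cio.write_expression(self.expression, p)),
            self._write("metadata.tsv", lambda p: cio.write_metadata(self.metadata, p)),
            self._write("gene_sets.gmt", lambda p: cio.write_gmt(self.gene_sets, p)),
            self._write("truth_edges.tsv", lambda p: truth.to_csv(p, sep="\t", index=False)),
        ]

    def _load_inputs(self) -> None:
        cfg = self.config
        self.abundance = cio.read_abundance_table(cfg.abundance_path)
        if cfg.expression_path:
            self.expression = cio.read_expression(cfg.expression_path)
        if cfg.metadata_path:
            self.metadata = cio.read_metadata(cfg.metadata_path)
        if cfg.gene_sets_path:
            self.gene_sets = cio.read_gmt(cfg.gene_sets_path)

    def preprocess(self) -> list[Path]:
        cfg = self.config
        abundance = filter_prevalence(self.abundance, cfg.min_prevalence)
        expression = filter_prevalence(self.expression, cfg.min_prevalence)
        self.microbes_bin = binarize_median(abundance).drop_degenerate()
        self.genes_bin = binarize_median(expression).drop_degenerate()
        levels = self.metadata.phenotype_levels
        if set(levels) == {"T", "PT"}:
            mapping = {"T": 1, "PT": 0}  # cancer = 1, control = 0
        else:
            mapping = {levels[0]: 0, levels[1]: 1}
        self.phenotype = encode_phenotype(self.metadata, mapping)
        return [
            self._write(
                "microbes_binary.tsv",
                lambda p: self.microbes_bin.data.to_csv(p, sep="\t", index_label="sample_id"),
            ),
            self._write(
                "genes_binary.tsv",
                lambda p: self.genes_bin.data.to_csv(p, sep="\t", index_label="sample_id"),
            ),
        ]

    def cmi(self) -> list[Path]:
        cfg = self.config
        perm = PermutationConfig(
            n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed, p_mode=cfg.p_mode
        )
        self.network = build_dependency_network(
            self.microbes_bin,
            self.genes_bin,
            self.phenotype,
            perm,
            direction=cfg.cmi_direction,
        )
        self.gdm_counts = gene_dependent_microbes(self.network)
        gdm = pd.DataFrame(
            list(self.gdm_counts.items()), columns=["microbe", "n_edges"]
        )
        return [
            self._write("network.tsv", lambda p: cio.write_network(self.network, p)),
            self._write(
                "cmi_all_pairs.tsv",
                lambda p: self.network.results.to_csv(p, sep="\t", index=False),
            ),
            self._write("gdm_counts.tsv", lambda p: gdm.to_csv(p, sep="\t", index=False)),
        ]

    def key_taxa(self) -> list[Path]:
        cfg = self.config
        gdms = set(self.gdm_counts)
        differential = differential_gdm_filter(gdms, self.abundance, self.metadata, cfg.alpha)
        ranking = rank_rf_importance(
            self.abundance, self.phenotype, n_trees=cfg.rf_trees, seed=cfg.seed
        )
        abundant = top_abundant_taxa(self.abundance, cfg.abundance_top_k)
        result = intersect_key_taxa(
            differential, ranking, abundant, rf_k=cfg.rf_top_k, gdms=gdms
        )
        return [
            self._write(
                "rf_importance.tsv", lambda p: ranking.table.to_csv(p, sep="\t")
            ),
            self._write(
                "key_taxa.tsv", lambda p: result.membership_table().to_csv(p, sep="\t")
            ),
        ]

    def diversity(self) -> list[Path]:
        cfg = self.config
        counts_ok = (self.abundance.data.to_numpy() % 1 == 0).all()
        alpha_tab = alpha_diversity_table(self.abundance, include_chao1=bool(counts_ok))
        dist = beta_distance(self.abundance, cfg.beta_metric)
        ordination = pcoa(dist, n_axes=2)
        perm = permanova(
            dist,
            self.metadata.phenotype.reindex(dist.sample_ids),
            n_perm=cfg.permanova_perms,
            seed=cfg.seed,
        )
        perm_tab = pd.DataFrame(
            [
                {
                    "pseudo_F": perm.pseudo_f,
                    "R2": perm.r_squared,
                    "p_value": perm.p_value,
                    "n_permutations": perm.n_permutations,
                }
            ]
        )
        return [
            self._write(
                "alpha_diversity.tsv",
                lambda p: alpha_tab.to_csv(p, sep="\t", index_label="sample_id"),
            ),
            self._write(
                f"distance_{cfg.beta_metric}.tsv",
                lambda p: dist.data.to_csv(p, sep="\t", index_label="sample_id"),
            ),
            self._write(
                "pcoa.tsv",
                lambda p: ordination.coordinates.to_csv(p, sep="\t", index_label="sample_id"),
            ),
            self._write(
                "permanova.tsv", lambda p: perm_tab.to_csv(p, sep="\t", index=False)
            ),
        ]

    def infiltration(self) -> list[Path]:
        scores = ssgsea_scores(self.expression, self.gene_sets)
        corr = spearman_correlation_matrix(self.abundance, scores)
        return [
            self._write(
                "infiltration_scores.tsv",
                lambda p: scores.scores.to_csv(p, sep="\t", index_label="sample_id"),
            ),
            self._write(
                "correlation_rho.tsv",
                lambda p: corr.rho.to_csv(p, sep="\t", index_label="taxon"),
            ),
            self._write(
                "correlation_p.tsv",
                lambda p: corr.p_value.to_csv(p, sep="\t", index_label="taxon"),
            ),
        ]

    def predict(self) -> list[Path]:
        cfg = self.config
        cohort = generate_response_cohort(
            cfg.response_n_patients,
            noise_sd=cfg.response_noise_sd,
            seed=cfg.seed,
        )
        covars = cohort[PUBLISHED_PANEL.covariate_names]
        scores = combined_score(covars, PUBLISHED_PANEL)
        predictions = pd.DataFrame(
            {
                "score": scores,
                "predicted": [classify_responder(s) for s in scores],
                "response": cohort["response"],
            },
            index=cohort.index,
        )
        or_table = fit_response_glm(covars, cohort["response"])
        train, val = train_val_split(
            cohort, ratio=cfg.split_ratio, seed=cfg.seed
        )
        outputs = [
            self._write(
                "response_cohort.tsv",
                lambda p: cohort.to_csv(p, sep="\t", index_label="sample_id"),
            ),
            self._write(
                "predictions.tsv",
                lambda p: predictions.to_csv(p, sep="\t", index_label="sample_id"),
            ),
            self._write(
                "odds_ratios.tsv", lambda p: or_table.table.to_csv(p, sep="\t")
            ),
        ]
        for part, name in ((train, "train"), (val, "validation")):
            if part["response"].nunique() < 2:
                self.warnings.append(f"ROC skipped for {name}: single outcome class")
                continue
            roc = roc_auc(combined_score(part[PUBLISHED_PANEL.covariate_names]), part["response"])
            pts = roc.points()
            pts.insert(0, "auc", roc.auc)
            outputs.append(
                self._write(
                    f"roc_{name}.tsv", lambda p, pts=pts: pts.to_csv(p, sep="\t", index=False)
                )
            )
        return outputs


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order and write a manifest."""
    config.validate_dag()
    run = _Run(config)
    started = time.time()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            if stage == "simulate" and config.has_inputs():
                run._load_inputs()
                continue
            t0 = time.time()
            try:
                outputs = getattr(run, stage)()
            except Exception as exc:
                manifest = RunManifest(
                    config=dataclasses.asdict(config),
                    stages=run.stage_records + [{"stage": stage, "failed": str(exc)}],
                    warnings=run.warnings + [str(w.message) for w in caught],
                    version=cminet.__version__,
                    started=started,
                    finished=time.time(),
                )
                (run.outdir / "manifest.json").write_text(manifest.to_json())
                raise CminetStageError(stage, exc) from exc
            run._record(stage, outputs, time.time() - t0)
    run.warnings.extend(str(w.message) for w in caught)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        stages=run.stage_records,
        warnings=run.warnings,
        version=cminet.__version__,
        started=started,
        finished=time.time(),
    )
    (run.outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


class CminetStageError(RuntimeError):
    """A pipeline stage failed; partial outputs and manifest are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
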