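"""The combined immunotherapy-response score, odds-ratio fits and ROC.

The published combined diagnostic panel for anti-PD-L1 response in
NSCLC is a linear score over the PT-resident Prevotella abundance and
five routine blood indicators, on raw clinical units:

    Score = 9.675*PT_Prevotella + 1.749*Ca + 8.086*Age
          + 3.332*HGB - 1.676*HCT - 5.930*ALT

Patients whose score is strictly above the optimal cutoff of 720.7 are
classified as likely responders (CBR); otherwise non-responders (NCB).

Per-biomarker associations are fit as binomial log-odds (logistic)
models — the source analysis labels this a GLMM but specifies no random
effect, so a plain fixed-effects logistic fit is what the machinery
implements — with odds ratio exp(coef), Wald two-sided p, and an OR > 1
flagged as positively associated with response.  Discrimination is
evaluated by ROC/AUC, with the cohort split 8:2 into training and
validation (stratified so both outcome classes reach the validation
fifth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

from cminet.errors import ConfigurationError, ValidationError

RESPONDER = "CBR"
NON_RESPONDER = "NCB"


@dataclass(frozen=True)
class ResponsePanel:
    """Named linear coefficients plus a decision cutoff."""

    coefficients: dict[str, float]
    cutoff: float

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ConfigurationError("panel needs at least one coefficient")
        if not np.isfinite(self.cutoff):
            raise ConfigurationError("cutoff must be finite")
        if not all(np.isfinite(v) for v in self.coefficients.values()):
            raise ConfigurationError("coefficients must be finite")

    @property
    def covariate_names(self) -> list[str]:
        return list(self.coefficients)


#: The published combined panel (raw clinical units) and its cutoff.
PUBLISHED_PANEL = ResponsePanel(
    coefficients={
        "PT_Prevotella": 9.675,
        "Ca": 1.749,
        "Age": 8.086,
        "HGB": 3.332,
        "HCT": -1.676,
        "ALT": -5.930,
    },
    cutoff=720.7,
)


@dataclass
class ORTable:
    """Per-biomarker logistic coefficients, odds ratios and Wald p-values."""

    table: pd.DataFrame  # index biomarker; columns coef, odds_ratio, p_value,
    #                      positive_association, separation_flag

    def __post_init__(self) -> None:
        converged = self.table[~self.table["separation_flag"]]
        if (converged["odds_ratio"] <= 0).any():
            raise ValidationError("odds ratios must be positive")


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValidationError("AUC must lie in [0, 1]")

    def points(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def combined_score(
    covariates: Mapping[str, float] | pd.Series | pd.DataFrame,
    panel: ResponsePanel = PUBLISHED_PANEL,
):
    """Evaluate the panel's linear score on raw covariate units.

    Accepts a single covariate mapping/Series (returns a float) or a
    DataFrame with one row per patient (returns a Series).
    """
    if isinstance(covariates, pd.DataFrame):
        missing = [c for c in panel.covariate_names if c not in covariates.columns]
        if missing:
            raise ValidationError(f"missing covariates: {missing}")
        return sum(
            panel.coefficients[name] * covariates[name]
            for name in panel.covariate_names
        )
    missing = [c for c in panel.covariate_names if c not in covariates]
    if missing:
        raise ValidationError(f"missing covariates: {missing}")
    return float(
        sum(panel.coefficients[n] * covariates[n] for n in panel.covariate_names)
    )


def classify_responder(score: float, panel: ResponsePanel = PUBLISHED_PANEL) -> str:
    """CBR iff the score is strictly above the panel cutoff, else NCB."""
    if not np.isfinite(score):
        raise ValidationError("score must be finite")
    return RESPONDER if score > panel.cutoff else NON_RESPONDER


def _as_binary_outcome(outcome) -> np.ndarray:
    y = pd.Series(outcome)
    if y.dtype == object or isinstance(y.dtype, pd.CategoricalDtype):
        y = y.map({RESPONDER: 1, NON_RESPONDER: 0, "1": 1, "0": 0})
        if y.isna().any():
            raise ValidationError(
                f"outcome labels must be {RESPONDER}/{NON_RESPONDER} or 0/1"
            )
    arr = y.to_numpy(dtype=float)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("outcome must be binary")
    if len(np.unique(arr)) < 2:
        raise ValidationError("outcome has a single class")
    return arr


def fit_response_glm(features: pd.DataFrame, outcome) -> ORTable:
    """Univariate binomial log-odds fit per biomarker with odds ratios.

    Each biomarker is fit separately (intercept + biomarker) by IRLS.
    Complete or quasi-complete separation is detected and flagged
    rather than reported as a converged estimate.
    """
    y = _as_binary_outcome(outcome)
    if len(features) <= features.shape[1] + 1:
        raise ValidationError("need n > number of features + 1")
    rows = {}
    for name in features.columns:
        x = sm.add_constant(features[[name]].to_numpy(dtype=float))
        separated = False
        coef = or_ = pval = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            try:
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
                coef = float(fit.params[1])
                or_ = float(np.exp(coef))
                pval = float(fit.pvalues[1])
                if not fit.mle_retvals.get("converged", True):
                    separated = True
            except Exception:
                # PerfectSeparationError / PerfectSeparationWarning /
                # convergence failure all land here
                separated = True
        rows[name] = {
            "coef": coef,
            "odds_ratio": or_,
            "p_value": pval,
            "positive_association": (or_ > 1) if np.isfinite(or_) else False,
            "separation_flag": separated,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "biomarker"
    return ORTable(table)


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC.

    The AUC equals the Mann-Whitney rank statistic — the fraction of
    (positive, negative) pairs ordered correctly, ties credited 1/2 —
    which is identical to the trapezoidal area under the empirical
    curve.
    """
    y = _as_binary_outcome(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValidationError("scores and labels must have equal length")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    return RocResult(
        auc=auc,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )


def train_val_split(
    cohort: pd.DataFrame,
    outcome_col: str = "response",
    ratio: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive 8:2 split stratified by outcome.

    Training size is round(ratio * n).  Stratification keeps both
    outcome classes in the validation fifth where counts allow; if a
    class is too small to stratify, the split falls back to unstratified
    with a warning.
    """
    if not 0 < ratio < 1:
        raise ConfigurationError("ratio must lie in (0, 1)")
    n = len(cohort)
    if n < 5:
        raise ValidationError("need at least 5 samples to split")
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    stratify = cohort[outcome_col] if outcome_col in cohort.columns else None
    try:
        train, val = train_test_split(
            cohort,
            train_size=n_train,
            random_state=seed,
            stratify=stratify,
            shuffle=True,
        )
    except ValueError:
        warnings.warn(
            "stratified split impossible at this size; falling back to "
            "unstratified (a class may be absent from a split)",
            stacklevel=2,
        )
        train, val = train_test_split(
            cohort, train_size=n_train, random_state=seed, shuffle=True
        )
    if stratify is not None:
        for part, which in ((train, "training"), (val, "validation")):
            if part[outcome_col].nunique() < cohort[outcome_col].nunique():
                warnings.warn(
                    f"an outcome class is absent from the {which} split",
                    stacklevel=2,
                )
    return train, val
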