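"""Gene-pair prognostic signatures: scoring, training and evaluation.

A :class:`SignatureModel` is a weighted sum of 0/1 gene-pair indicators
(a Cox linear predictor over pair flips) together with a risk cutoff.  The
published 10-pair autophagy index (ATGPI) for early-stage lung
adenocarcinoma ships as a frozen instance; :func:`train_signature` builds a
new signature from multi-cohort data by running the full pipeline:

    enumerate pairs → 0/1 pair matrix → cross-cohort constancy filter →
    per-pair log-rank screen (p < 0.05, unadjusted) → LASSO-Cox with 10-fold
    CV at the 1-SE penalty → unpenalized Cox refit on the selected pairs →
    risk cutoff by Youden's J on a time-dependent ROC at a reference horizon.

The clinical composite (ACPI) is a linear combination of the signature
score, coded tumor stage (I=1, II=2) and age in years, fit by multivariate
Cox regression; the published version is
``0.6657·ATGPI + 0.4445·stage + 0.0199·age`` with cutoff 1.31.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .io_cohorts import CohortCollection, ExpressionMatrix, harmonize_genes
from .pair_features import (
    GenePair,
    build_pair_matrix,
    enumerate_pairs,
    filter_informative_pairs,
    make_pair,
)
from . import survival as sv

__all__ = [
    "SignatureModel",
    "ACPIModel",
    "TrainConfig",
    "EvaluationReport",
    "published_atgpi",
    "published_acpi",
    "score_atgpi",
    "score_acpi",
    "classify_risk",
    "train_signature",
    "build_acpi",
    "evaluate_signature",
    "validate_model_dict",
]


@dataclass
class SignatureModel:
    pairs: list[GenePair]
    weights: np.ndarray
    cutoff: float
    provenance: str = "trained"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.pairs) != len(self.weights):
            raise ValueError("one weight per pair required")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("pairs must be unique")
        for p in self.pairs:
            if not p.gene1 < p.gene2:
                raise ValueError(f"pair {p} is not in canonical order")
        if self.provenance not in ("published", "trained"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def genes(self) -> list[str]:
        return sorted({g for p in self.pairs for g in p})

    def score_bounds(self) -> tuple[float, float]:
        """Attainable score range: [sum of negative, sum of positive] weights."""
        return (
            float(self.weights[self.weights < 0].sum()),
            float(self.weights[self.weights > 0].sum()),
        )

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "cutoff": self.cutoff,
            "pairs": [
                {"gene1": p.gene1, "gene2": p.gene2, "weight": float(w)}
                for p, w in zip(self.pairs, self.weights)
            ],
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        validate_model_dict(d)
        return cls(
            pairs=[make_pair(e["gene1"], e["gene2"]) for e in d["pairs"]],
            weights=np.array([e["weight"] for e in d["pairs"]], dtype=float),
            cutoff=float(d["cutoff"]),
            provenance=d["provenance"],
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SignatureModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def validate_model_dict(d: dict) -> None:
    """Structural validation of a serialized signature model."""
    for key in ("provenance", "cutoff", "pairs"):
        if key not in d:
            raise ValueError(f"model JSON lacks required key {key!r}")
    if d["provenance"] not in ("published", "trained"):
        raise ValueError(f"invalid provenance {d['provenance']!r}")
    if not isinstance(d["cutoff"], (int, float)):
        raise ValueError("cutoff must be a number")
    if not isinstance(d["pairs"], list) or not d["pairs"]:
        raise ValueError("pairs must be a non-empty list")
    for e in d["pairs"]:
        for key in ("gene1", "gene2", "weight"):
            if key not in e:
                raise ValueError(f"pair entry lacks {key!r}: {e}")


@dataclass
class ACPIModel:
    """Clinical composite: w_index·score + w_stage·stage + w_age·age."""

    w_index: float
    w_stage: float
    w_age: float
    cutoff: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in (self.w_index, self.w_stage, self.w_age, self.cutoff):
            if not np.isfinite(w):
                raise ValueError("ACPI weights and cutoff must be finite")

    def to_dict(self) -> dict:
        return {
            "w_index": self.w_index,
            "w_stage": self.w_stage,
            "w_age": self.w_age,
            "cutoff": self.cutoff,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ACPIModel":
        return cls(
            float(d["w_index"]),
            float(d["w_stage"]),
            float(d["w_age"]),
            float(d["cutoff"]),
            d.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ACPIModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def published_atgpi() -> SignatureModel:
    """The frozen published 10-pair index (15 unique genes, cutoff 1.35)."""
    text = resources.files("pairsig.data").joinpath("published_atgpi.json").read_text()
    return SignatureModel.from_dict(json.loads(text))


def published_acpi() -> ACPIModel:
    """The frozen published clinical composite (cutoff 1.31)."""
    return ACPIModel(w_index=0.6657, w_stage=0.4445, w_age=0.0199, cutoff=1.31)


def score_atgpi(
    expr: ExpressionMatrix | pd.DataFrame, model: SignatureModel
) -> pd.Series:
    """Per-sample signature score: Σ_k w_k · 1{expr[g1_k] ≤ expr[g2_k]}."""
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    missing = [g for g in model.genes if g not in data.index]
    if missing:
        raise KeyError(f"signature genes absent from expression matrix: {missing}")
    pm = build_pair_matrix(
        data, model.pairs, cohort_labels=["-"] * data.shape[1]
    )
    scores = model.weights @ pm.scores
    return pd.Series(scores, index=data.columns, name="score")


def score_acpi(atgpi, stage, age, model: ACPIModel):
    """The clinical composite, elementwise over scalars or arrays."""
    stage_arr = np.asarray(stage)
    if not np.isin(stage_arr, (1, 2)).all():
        raise ValueError("stage must be coded 1 (I) or 2 (II)")
    age_arr = np.asarray(age, dtype=float)
    if not (age_arr >= 0).all():
        raise ValueError("age must be non-negative")
    out = model.w_index * np.asarray(atgpi, dtype=float) + model.w_stage * stage_arr + model.w_age * age_arr
    return float(out) if np.isscalar(atgpi) or np.ndim(atgpi) == 0 else out


def classify_risk(score, cutoff: float) -> np.ndarray:
    """'high' iff score > cutoff (scores equal to the cutoff are low risk)."""
    arr = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(arr)) or not np.isfinite(cutoff):
        raise ValueError("scores and cutoff must be finite")
    out = np.where(arr > cutoff, "high", "low")
    return out if arr.ndim else str(out)


@dataclass
class TrainConfig:
    """Pipeline settings; every default is recorded in the trained model."""

    screen_p: float = 0.05
    fdr: bool = False  # Benjamini–Hochberg on the screen instead of raw p
    nfolds: int = 10
    lambda_rule: str = "1se"  # or "min"
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.05
    standardize: bool = False
    refit: bool = True  # unpenalized Cox refit on the selected pairs
    constancy_mode: str = "per_cohort"
    min_minority_freq: float | None = None
    horizon: float = 1825.0  # 5-year reference horizon for the cutoff
    span: float | None = None  # tdROC span; default 0.25·n^-0.2
    seed: int = 0


def _screen_pairs(pm, time, event, config):
    chi2, p = sv.logrank_screen(pm.scores.T, time, event)
    if config.fdr:
        from statsmodels.stats.multitest import multipletests

        ok = np.isfinite(p)
        reject = np.zeros_like(p, dtype=bool)
        reject[ok] = multipletests(p[ok], alpha=config.screen_p, method="fdr_bh")[0]
        keep = reject
    else:
        keep = np.nan_to_num(p, nan=1.0) < config.screen_p
    return [pr for pr, k in zip(pm.pairs, keep) if k]


def train_signature(
    train: CohortCollection, config: TrainConfig | None = None
) -> SignatureModel:
    """Build a gene-pair signature from harmonized training cohorts.

    Raises a ``ValueError`` advising the ``lambda_rule='min'`` fallback when
    the 1-SE penalty selects no pair.
    """
    config = config or TrainConfig()
    cohorts = harmonize_genes(train.cohorts)
    train = CohortCollection(cohorts, train.clinical)
    merged = train.merged_expression()
    clin = train.clinical_in_order()
    time = clin["time_days"].to_numpy(dtype=float)
    event = clin["event"].to_numpy()

    pairs = enumerate_pairs(merged.index)
    pm = build_pair_matrix(merged, pairs, cohort_labels=train.cohort_labels)
    informative = filter_informative_pairs(
        pm, mode=config.constancy_mode, min_minority_freq=config.min_minority_freq
    )
    pm_inf = pm.select(informative)
    screened = _screen_pairs(pm_inf, time, event, config)
    if not screened:
        raise ValueError(
            f"no pair passed the log-rank screen at p < {config.screen_p}"
        )
    pm_scr = pm_inf.select(screened)

    X = pd.DataFrame(
        pm_scr.scores.T.astype(float),
        index=pm_scr.sample_ids,
        columns=[p.label for p in screened],
    )
    data = sv.SurvivalData(time, event, covariates=X)
    cv = sv.cox_lasso_cv(
        data,
        nfolds=config.nfolds,
        seed=config.seed,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
        standardize=config.standardize,
    )
    lam = cv.lambda_1se if config.lambda_rule == "1se" else cv.lambda_min
    coef = cv.coef_at(lam)
    sel_idx = np.flatnonzero(coef != 0)
    if len(sel_idx) == 0:
        raise ValueError(
            "the LASSO selected no pair at lambda_1se; rerun with "
            "lambda_rule='min' to fall back to the CV-minimum penalty"
        )
    selected = [screened[i] for i in sel_idx]

    if config.refit:
        refit_data = sv.SurvivalData(
            time, event, covariates=X.iloc[:, sel_idx]
        )
        fit = sv.cox_fit(refit_data)
        weights = fit.beta
    else:
        weights = coef[sel_idx]

    scores = weights @ pm_scr.scores[sel_idx].astype(float)
    roc = sv.td_roc(
        scores,
        sv.SurvivalData(time, event),
        horizon=config.horizon,
        span=config.span,
    )
    cutoff = sv.optimal_cutoff(roc)
    metadata = {
        "seed": config.seed,
        "screen_p": config.screen_p,
        "fdr": config.fdr,
        "lambda_rule": config.lambda_rule,
        "lambda_min": cv.lambda_min,
        "lambda_1se": cv.lambda_1se,
        "nfolds": config.nfolds,
        "refit": config.refit,
        "horizon": config.horizon,
        "span": roc.span,
        "constancy_mode": config.constancy_mode,
        "n_candidate_pairs": len(pairs),
        "n_informative_pairs": len(informative),
        "n_screened_pairs": len(screened),
        "n_selected_pairs": len(selected),
        "cutoff_auc": roc.auc,
    }
    return SignatureModel(
        pairs=selected,
        weights=weights,
        cutoff=float(cutoff),
        provenance="trained",
        metadata=metadata,
    )


def build_acpi(
    train: CohortCollection,
    model: SignatureModel,
    tau_ref: float = 1825.0,
    span: float | None = None,
) -> ACPIModel:
    """Fit the clinical composite on training data.

    Weights are the multivariate Cox coefficients of (signature score, coded
    stage, age) in raw units; the cutoff maximizes Youden's J on the
    time-dependent ROC at ``tau_ref``.
    """
    merged = train.merged_expression()
    clin = train.clinical_in_order()
    scores = score_atgpi(merged, model)
    X = pd.DataFrame(
        {
            "index": scores.to_numpy(),
            "stage": clin["stage"].to_numpy(dtype=float),
            "age": clin["age"].to_numpy(dtype=float),
        },
        index=clin.index,
    )
    data = sv.SurvivalData(
        clin["time_days"].to_numpy(dtype=float), clin["event"].to_numpy(), X
    )
    fit = sv.cox_fit(data)
    acpi = ACPIModel(
        w_index=float(fit.beta[0]),
        w_stage=float(fit.beta[1]),
        w_age=float(fit.beta[2]),
        cutoff=0.0,
        metadata={"tau_ref": tau_ref, "se": [float(s) for s in fit.se]},
    )
    composite = score_acpi(
        scores.to_numpy(), clin["stage"].to_numpy(), clin["age"].to_numpy(), acpi
    )
    roc = sv.td_roc(
        composite,
        sv.SurvivalData(data.time, data.event),
        horizon=tau_ref,
        span=span,
    )
    acpi.cutoff = float(sv.optimal_cutoff(roc))
    return acpi


@dataclass
class EvaluationReport:
    cohort_label: str
    n: int
    n_events: int
    risk_groups: pd.Series  # 'low'/'high' per sample
    km_by_group: dict  # group -> KMCurve
    logrank: sv.LogRankResult
    cox_table: pd.DataFrame  # univariate + multivariate HR/CI/p per variable
    auc_by_horizon: dict  # horizon (days) -> AUC or None if not evaluable
    c_index: float
    acpi_c_index: float | None = None
    c_comparison: sv.ConcordanceComparison | None = None

    def summary_dict(self) -> dict:
        return {
            "cohort": self.cohort_label,
            "n": self.n,
            "n_events": self.n_events,
            "n_high_risk": int((self.risk_groups == "high").sum()),
            "logrank_chi2": self.logrank.chi_square,
            "logrank_p": self.logrank.p_value,
            "auc": {str(k): v for k, v in self.auc_by_horizon.items()},
            "c_index": self.c_index,
            "acpi_c_index": self.acpi_c_index,
            "c_difference_p": (
                self.c_comparison.p_value if self.c_comparison else None
            ),
        }


def _cox_row(fit: sv.CoxFit, name: str) -> dict:
    j = fit.names.index(name)
    return {
        "HR": fit.hazard_ratio[j],
        "CI_low": fit.ci_lower[j],
        "CI_high": fit.ci_upper[j],
        "p": fit.p_values[j],
    }


def evaluate_signature(
    model: SignatureModel,
    cohort: CohortCollection,
    acpi: ACPIModel | None = None,
    horizons: tuple = (365.0, 1095.0, 1825.0),
    span: float | None = None,
    label: str = "cohort",
) -> EvaluationReport:
    """Full prognostic evaluation of a signature on one cohort collection.

    Produces risk groups and their KM curves, the log-rank test, univariate
    Cox models per variable (risk group, sex, age, stage) and a multivariate
    model restricted to variables with univariate p < 0.05, time-dependent
    AUCs at the requested horizons, and the C-index of the continuous score
    (compared against the clinical composite when one is supplied).
    """
    merged = cohort.merged_expression()
    clin = cohort.clinical_in_order()
    for col in ("time_days", "event", "age", "stage", "sex"):
        if col not in clin.columns:
            raise ValueError(f"clinical table lacks required column {col!r}")
    time = clin["time_days"].to_numpy(dtype=float)
    event = clin["event"].to_numpy()
    outcome = sv.SurvivalData(time, event)

    scores = score_atgpi(merged, model)
    groups = pd.Series(
        classify_risk(scores.to_numpy(), model.cutoff), index=scores.index
    )
    high = (groups == "high").to_numpy()
    km_by_group = {}
    for g in ("low", "high"):
        mask = groups.to_numpy() == g
        if mask.any():
            km_by_group[g] = sv.km_fit(sv.SurvivalData(time[mask], event[mask]))
    if high.any() and (~high).any():
        lr = sv.logrank_test(outcome, high)
    else:
        lr = sv.LogRankResult(np.nan, 1, np.nan)

    variables = {
        "risk": high.astype(float),
        "sex": (clin["sex"] == "male").to_numpy(dtype=float),
        "age": clin["age"].to_numpy(dtype=float),
        "stage": clin["stage"].to_numpy(dtype=float),
    }
    rows = {}
    uni_p = {}
    for name, x in variables.items():
        if np.ptp(x) == 0:
            continue
        fit = sv.cox_fit(
            sv.SurvivalData(time, event, pd.DataFrame({name: x}, index=clin.index))
        )
        rows[name] = {"variable": name, "model": "univariate", **_cox_row(fit, name)}
        uni_p[name] = fit.p_values[0]
    multi_vars = [n for n, p in uni_p.items() if p < 0.05]
    multi_rows = []
    if len(multi_vars) >= 1:
        Xm = pd.DataFrame(
            {n: variables[n] for n in multi_vars}, index=clin.index
        )
        mfit = sv.cox_fit(sv.SurvivalData(time, event, Xm))
        for n in multi_vars:
            multi_rows.append(
                {"variable": n, "model": "multivariate", **_cox_row(mfit, n)}
            )
    cox_table = pd.DataFrame(list(rows.values()) + multi_rows)

    auc = {}
    for h in horizons:
        try:
            auc[h] = sv.td_roc(scores.to_numpy(), outcome, h, span=span).auc
        except ValueError:
            auc[h] = None

    c_index = sv.harrell_c(scores.to_numpy(), outcome)
    acpi_c = None
    comparison = None
    if acpi is not None:
        composite = score_acpi(
            scores.to_numpy(),
            clin["stage"].to_numpy(),
            clin["age"].to_numpy(),
            acpi,
        )
        acpi_c = sv.harrell_c(composite, outcome)
        comparison = sv.compare_concordance(
            composite, scores.to_numpy(), outcome
        )
    return EvaluationReport(
        cohort_label=label,
        n=len(clin),
        n_events=int(event.sum()),
        risk_groups=groups,
        km_by_group=km_by_group,
        logrank=lr,
        cox_table=cox_table,
        auc_by_horizon=auc,
        c_index=float(c_index),
        acpi_c_index=acpi_c,
        c_comparison=comparison,
    )
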