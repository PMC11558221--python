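"""Phenotype-outcome association models.

Four model families link the derived backspace phenotypes to clinical
measures collected at the baseline psychiatric evaluation:

* a linear mixed-effects model with subject random intercepts testing
  whether daily backspace rates differ between the healthy-control and
  mood-disorder groups on the continuous scale;
* ordinary least squares regressing depression severity (HAM-D totals)
  on phenotype (Low as reference), optionally adjusting for medication
  and diagnosis;
* a hurdle ("zero-inflated") gamma model for mania severity (YMRS
  totals): a logistic part for P(total > 0) and a log-link gamma GLM on
  the positive totals — identical likelihoods since a gamma density has
  no mass at zero;
* proportional-odds (cumulative-logit) regressions per symptom item,
  reporting odds ratios with Wald 95% CIs, with a structural-zero
  protocol: a phenotype group showing a single observed category for an
  item is dropped and the model refitted on the remaining groups.

Inference is Wald throughout (z statistics, exp(b +/- 1.96 SE) intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

# Clinical schema -----------------------------------------------------------

HAMD_ITEM_NAMES = {
    "hamd_1": "depressed_mood",
    "hamd_2": "guilt",
    "hamd_3": "suicide",
    "hamd_4": "initial_insomnia",
    "hamd_5": "middle_insomnia",
    "hamd_6": "terminal_insomnia",
    "hamd_7": "work_activities",
    "hamd_8": "retardation",
    "hamd_9": "agitation",
    "hamd_10": "psychic_anxiety",
    "hamd_11": "somatic_anxiety",
    "hamd_12": "gastrointestinal_somatic",
    "hamd_13": "general_somatic",
    "hamd_14": "genital",
    "hamd_15": "hypochondriasis",
    "hamd_16": "weight_loss",
    "hamd_17": "insight",
}
#: HAM-D items rated 0-4 (5-point); the remaining items are rated 0-2.
_HAMD_FIVE_POINT = {1, 2, 3, 7, 8, 9, 10, 11, 15}
HAMD_ITEM_LEVELS = {
    f"hamd_{i}": (5 if i in _HAMD_FIVE_POINT else 3) for i in range(1, 18)
}
YMRS_ITEM_NAMES = {
    "ymrs_1": "elevated_mood",
    "ymrs_2": "motor_activity",
    "ymrs_3": "sexual_interest",
    "ymrs_4": "sleep",
    "ymrs_5": "irritability",
    "ymrs_6": "speech",
    "ymrs_7": "language_thought",
    "ymrs_8": "content",
    "ymrs_9": "disruptive_aggressive",
    "ymrs_10": "appearance",
    "ymrs_11": "insight",
}
YMRS_ITEM_LEVELS = {f"ymrs_{i}": 5 for i in range(1, 12)}

HAMD_COLUMNS = list(HAMD_ITEM_NAMES)
YMRS_COLUMNS = list(YMRS_ITEM_NAMES)
CLINICAL_COLUMNS = ["subject_id", "group", "diagnosis", "medication"] + HAMD_COLUMNS + YMRS_COLUMNS


@dataclass(frozen=True)
class ClinicalRecord:
    """One subject's baseline clinical assessment."""

    subject_id: str
    group: str  # HC or MD
    diagnosis: str  # HC, unipolar, or bipolar
    medication: str  # yes or no
    hamd_items: tuple  # 17 ordinal scores
    ymrs_items: tuple  # 11 ordinal scores
    hamd_total: float | None = None
    ymrs_total: float | None = None

    def __post_init__(self) -> None:
        if len(self.hamd_items) != 17:
            raise ValueError("HAM-D has 17 items")
        if len(self.ymrs_items) != 11:
            raise ValueError("YMRS has 11 items")
        for col, v in zip(HAMD_COLUMNS, self.hamd_items):
            if not 0 <= v < HAMD_ITEM_LEVELS[col]:
                raise ValueError(f"{col} score {v} outside 0..{HAMD_ITEM_LEVELS[col] - 1}")
        for col, v in zip(YMRS_COLUMNS, self.ymrs_items):
            if not 0 <= v < YMRS_ITEM_LEVELS[col]:
                raise ValueError(f"{col} score {v} outside 0..{YMRS_ITEM_LEVELS[col] - 1}")


@dataclass
class AssociationResult:
    """A fitted association model: term table, convergence, and notes.

    ``table`` has one row per term with columns ``part, term, estimate,
    se, z, p`` and, for odds-ratio models, ``or_, ci_low, ci_high``.
    """

    model: str
    table: pd.DataFrame
    converged: bool = True
    notes: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical CSV; totals are computed from items, never read."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical file is missing columns {missing}")
    df = df[CLINICAL_COLUMNS].copy()
    df["hamd_total"] = df[HAMD_COLUMNS].sum(axis=1)
    df["ymrs_total"] = df[YMRS_COLUMNS].sum(axis=1)
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.loc[:, [c for c in df.columns if c in CLINICAL_COLUMNS]].to_csv(path, index=False)


# Design helpers ------------------------------------------------------------


def _labels_series(labels, subject_ids) -> pd.Series:
    """Align phenotype labels to subjects, by subject_id when the labels
    are keyed by it, positionally otherwise."""
    sids = pd.Index(subject_ids)
    if isinstance(labels, Mapping) and not isinstance(labels, pd.Series):
        labels = pd.Series(labels)
    if isinstance(labels, pd.Series):
        if sids.isin(labels.index).all():
            return pd.Series(labels.reindex(sids).to_numpy(), index=sids)
        labels = labels.to_numpy()
    arr = np.asarray(labels)
    if len(arr) != len(sids):
        raise ValueError("labels must be keyed by subject_id or align positionally")
    return pd.Series(arr, index=sids)


def _phenotype_dummies(pheno: pd.Series, reference: str) -> pd.DataFrame:
    levels = [g for g in ["Low", "Medium", "High"] if g in set(pheno)]
    if not levels:  # non-3-class labels: keep order of appearance
        levels = list(pd.unique(pheno))
    if reference not in levels:
        reference = levels[0]
    cols = {}
    for g in levels:
        if g != reference:
            cols[g] = (pheno == g).astype(float)
    return pd.DataFrame(cols, index=pheno.index)


def _covariate_design(clin: pd.DataFrame) -> pd.DataFrame:
    out = {"medication": (clin["medication"].astype(str) == "yes").astype(float)}
    for d in pd.unique(clin["diagnosis"]):
        if d != "HC":
            out[f"diagnosis[{d}]"] = (clin["diagnosis"] == d).astype(float)
    return pd.DataFrame(out, index=clin.index)


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop trailing columns that do not increase the design rank."""
    keep: list[str] = []
    for col in X.columns:
        trial = X[keep + [col]].to_numpy()
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(col)
        else:
            warnings.warn(f"dropping collinear design column {col!r}")
    return X[keep]


def _wald_table(names, params, bse, part: str = "", odds: bool = False) -> pd.DataFrame:
    params = np.asarray(params, float)
    bse = np.asarray(bse, float)
    z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    tab = pd.DataFrame(
        {"part": part, "term": list(names), "estimate": params, "se": bse, "z": z, "p": p}
    )
    if odds:
        tab["or_"] = np.exp(params)
        tab["ci_low"] = np.exp(params - 1.96 * bse)
        tab["ci_high"] = np.exp(params + 1.96 * bse)
    return tab


# Model families ------------------------------------------------------------


def lmm_group_test(
    daily: pd.DataFrame, clinical: pd.DataFrame, reml: bool = False
) -> AssociationResult:
    """Do daily backspace rates differ between HC and MD on the continuous
    scale? Random-intercept linear mixed model, fitted by ML (REML
    optional), Wald test on the group term. Falls back to OLS with
    cluster-robust SEs (flagged) when the random-intercept variance is
    degenerate.
    """
    merged = daily.merge(clinical[["subject_id", "group"]], on="subject_id", how="inner")
    if merged["group"].nunique() < 2:
        raise ValueError("need at least two groups")
    merged["md"] = (merged["group"] != "HC").astype(float)
    X = sm.add_constant(merged[["md"]])
    notes: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(merged["rate"], X, groups=merged["subject_id"])
            res = model.fit(reml=reml)
        if not res.converged or not np.isfinite(res.bse_fe).all():
            raise np.linalg.LinAlgError("mixed model did not converge")
        tab = _wald_table(["const", "group[MD]"], res.fe_params, res.bse_fe)
        extra = {"random_intercept_var": float(np.asarray(res.cov_re)[0, 0]),
                 "residual_var": float(res.scale)}
        converged = True
    except (np.linalg.LinAlgError, ValueError) as err:
        notes.append(f"mixed model singular ({err}); OLS with cluster-robust SEs")
        res = sm.OLS(merged["rate"], X).fit(
            cov_type="cluster", cov_kwds={"groups": merged["subject_id"]}
        )
        tab = _wald_table(["const", "group[MD]"], res.params, res.bse)
        extra = {}
        converged = False
    return AssociationResult("lmm_group", tab, converged=converged, notes=notes, extra=extra)


def severity_regression(
    clinical: pd.DataFrame,
    labels,
    outcome: str = "hamd_total",
    adjust: bool = False,
    reference: str = "Low",
) -> AssociationResult:
    """Least-squares regression of a severity total on phenotype.

    Coefficients are phenotype contrasts vs the reference (Low) group,
    optionally adjusted for medication and diagnosis. Collinear
    covariates are dropped with a warning.
    """
    pheno = _labels_series(labels, clinical["subject_id"]).set_axis(clinical.index)
    X = _phenotype_dummies(pheno, reference)
    if adjust:
        X = pd.concat([X, _covariate_design(clinical)], axis=1)
    X = sm.add_constant(X)
    X = _drop_collinear(X)
    res = sm.OLS(clinical[outcome].astype(float), X).fit()
    tab = _wald_table(X.columns, res.params, res.bse)
    return AssociationResult(
        f"severity[{outcome}]" + ("+covariates" if adjust else ""),
        tab,
        converged=True,
        extra={"nobs": int(res.nobs), "r_squared": float(res.rsquared)},
    )


def gamma_loglik(y: np.ndarray, mu: np.ndarray, shape: float) -> float:
    """Gamma log likelihood at mean mu and shape (mean parameterization)."""
    return float(stats.gamma.logpdf(y, a=shape, scale=mu / shape).sum())


def hurdle_log_likelihood(
    y: np.ndarray,
    X: np.ndarray,
    logit_params: np.ndarray,
    gamma_params: np.ndarray,
    gamma_shape: float,
) -> tuple[float, float, float]:
    """Hurdle-gamma log likelihood and its exact two-part decomposition.

    Returns ``(total, binary_part, positive_part)``; the total equals the
    sum of the parts because the gamma density has no atom at zero.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    d = (y > 0).astype(float)
    eta = X @ np.asarray(logit_params, float)
    binary = float(np.sum(d * eta - np.log1p(np.exp(eta))))
    pos = y > 0
    mu = np.exp(X[pos] @ np.asarray(gamma_params, float))
    positive = gamma_loglik(y[pos], mu, gamma_shape)
    return binary + positive, binary, positive


def hurdle_gamma(
    clinical: pd.DataFrame,
    labels,
    outcome: str = "ymrs_total",
    adjust: bool = False,
    reference: str = "Low",
) -> AssociationResult:
    """Two-part hurdle model for a zero-inflated nonnegative severity total.

    Part 1 ("nonzero"): logistic regression for P(total > 0). Part 2
    ("positive"): gamma GLM with log link on the positive totals. The two
    parts share the same design. An all-zero or all-positive outcome
    skips the corresponding part with a note.
    """
    pheno = _labels_series(labels, clinical["subject_id"]).set_axis(clinical.index)
    X = _phenotype_dummies(pheno, reference)
    if adjust:
        X = pd.concat([X, _covariate_design(clinical)], axis=1)
    X = _drop_collinear(sm.add_constant(X))
    y = clinical[outcome].astype(float)
    if (y < 0).any():
        raise ValueError("hurdle outcome must be nonnegative")
    d = (y > 0).astype(float)

    tables, notes, extra = [], [], {}
    converged = True
    if d.nunique() < 2:
        notes.append("outcome has no zero/positive contrast; nonzero part skipped")
        converged = False
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                logit = sm.Logit(d, X).fit(disp=0, maxiter=200)
            if not logit.mle_retvals.get("converged", True):
                # quasi-separation (e.g. a perfectly predicted small group):
                # keep the Wald estimates, whose SEs blow up accordingly
                notes.append(
                    "nonzero part: logistic MLE did not converge (perfectly "
                    "predicted group?); Wald estimates reported"
                )
                converged = False
            tables.append(_wald_table(X.columns, logit.params, logit.bse, part="nonzero"))
            extra["logit_params"] = np.asarray(logit.params)
            extra["logit_llf"] = float(logit.llf)
        except Exception as err:  # hard failure: singular design
            notes.append(f"nonzero part failed: {err}")
            converged = False

    pos = y > 0
    if pos.sum() < X.shape[1] + 1:
        notes.append("too few positive outcomes; positive part skipped")
        converged = False
    else:
        Xp = _drop_collinear(X[pos])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y[pos], Xp, family=sm.families.Gamma(sm.families.links.Log())).fit()
        tables.append(_wald_table(Xp.columns, glm.params, glm.bse, part="positive"))
        extra["gamma_params"] = np.asarray(glm.params)
        extra["gamma_shape"] = float(1.0 / glm.scale)  # MoM dispersion -> shape

    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["part", "term", "estimate", "se", "z", "p"])
    )
    return AssociationResult(
        f"hurdle_gamma[{outcome}]" + ("+covariates" if adjust else ""),
        table,
        converged=converged,
        notes=notes,
        extra=extra,
    )


def ordinal_item_model(
    item,
    labels,
    reference: str = "Low",
    item_name: str = "item",
) -> AssociationResult:
    """Proportional-odds model of one ordinal symptom item on phenotype.

    Cumulative-logit maximum likelihood with a common slope across
    thresholds; reported as odds ratios of higher ratings vs the
    reference (Low) group with Wald 95% CIs.

    Structural-zero protocol: a phenotype group in which only a single
    item category is observed makes its contrast inestimable; the model
    is marked non-convergent for that group, the group is dropped, the
    model refitted on the remaining groups, and a note recorded. An item
    constant across everyone yields a descriptive note only.
    """
    item = pd.Series(np.asarray(item, float))
    lab_values = np.asarray(labels.values if isinstance(labels, pd.Series) else labels)
    if len(lab_values) != len(item):
        raise ValueError("labels must align positionally with item scores")
    pheno = pd.Series(lab_values, index=item.index)
    if item.isna().any():
        raise ValueError("item scores must not be missing")

    if item.nunique() < 2:
        return AssociationResult(
            f"ordinal[{item_name}]",
            pd.DataFrame(columns=["part", "term", "estimate", "se", "z", "p"]),
            converged=False,
            notes=[f"{item_name}: constant item ({item.iloc[0]:g} for everyone); no model fitted"],
        )

    order = [g for g in ["Low", "Medium", "High"] if g in set(pheno)] or list(pd.unique(pheno))
    degenerate = [g for g in order if item[pheno == g].nunique() < 2]
    notes = []
    dropped: list[str] = []
    if degenerate:
        vals = {g: float(item[pheno == g].iloc[0]) for g in degenerate}
        notes.append(
            f"{item_name}: non-convergent — single observed category in "
            + ", ".join(f"{g} (all {vals[g]:g})" for g in degenerate)
            + "; group(s) dropped and model refitted"
        )
        keep = ~pheno.isin(degenerate)
        remaining = [g for g in order if g not in degenerate]
        if len(remaining) < 2:
            notes.append(f"{item_name}: fewer than two phenotype groups remain; no refit")
            return AssociationResult(
                f"ordinal[{item_name}]",
                pd.DataFrame(columns=["part", "term", "estimate", "se", "z", "p"]),
                converged=False,
                notes=notes,
            )
        refit = ordinal_item_model(
            item[keep].reset_index(drop=True),
            pheno[keep].reset_index(drop=True),
            reference=reference,
            item_name=item_name,
        )
        refit.notes = notes + refit.notes
        refit.converged = False
        refit.extra["dropped_groups"] = degenerate
        return refit

    X = _phenotype_dummies(pheno, reference)
    endog = pd.Series(
        pd.Categorical(item, categories=sorted(item.unique()), ordered=True), index=item.index
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(endog, X, distr="logit")
        res = model.fit(method="bfgs", disp=False, maxiter=1000, gtol=1e-10)
    k = X.shape[1]
    tab = _wald_table(X.columns, res.params[:k], res.bse[:k], odds=True)
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    return AssociationResult(
        f"ordinal[{item_name}]",
        tab,
        converged=bool(res.mle_retvals.get("converged", True)),
        notes=notes,
        extra={"thresholds": np.asarray(thresholds), "llf": float(res.llf)},
    )


def symptom_item_models(
    clinical: pd.DataFrame,
    labels,
    items: Sequence[str] | None = None,
    reference: str = "Low",
    adjust_pvalues: bool = False,
) -> dict[str, AssociationResult]:
    """Fit the proportional-odds model for each symptom item.

    ``items`` defaults to all 17 HAM-D and 11 YMRS item columns. No
    multiple-testing correction is applied by default; with
    ``adjust_pvalues`` a Benjamini-Hochberg adjusted p-value column is
    appended across all fitted terms.
    """
    names = dict(HAMD_ITEM_NAMES)
    names.update(YMRS_ITEM_NAMES)
    items = list(items) if items is not None else HAMD_COLUMNS + YMRS_COLUMNS
    pheno = _labels_series(labels, clinical["subject_id"]).set_axis(clinical.index)
    out: dict[str, AssociationResult] = {}
    for col in items:
        out[col] = ordinal_item_model(
            clinical[col].reset_index(drop=True),
            pheno.reset_index(drop=True),
            reference=reference,
            item_name=names.get(col, col),
        )
    if adjust_pvalues:
        keyed = [
            (col, i)
            for col, res in out.items()
            for i in range(len(res.table))
        ]
        pvals = [out[col].table["p"].iloc[i] for col, i in keyed]
        if pvals:
            adj = multipletests(pvals, method="fdr_bh")[1]
            for (col, i), q in zip(keyed, adj):
                out[col].table.loc[out[col].table.index[i], "p_bh"] = q
    return out
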