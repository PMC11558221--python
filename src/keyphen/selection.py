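"""Choosing the number of phenotype classes.

Internal fit is judged by DIC together with a minimum-class-size rule
(modal classes with fewer than 5 subjects are considered too small to be
substantively interpretable). External validity is judged by a Pearson
chi-square test of association between modal class membership and mood
disorder diagnosis (healthy control vs unipolar vs bipolar). Among the K
values that survive both screens, the lowest-DIC model wins, with a
parsimony tie-break (smaller K) when DICs are within 2 of each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import FitResult

#: DIC differences smaller than this are treated as ties (parsimony wins).
DIC_TIE_MARGIN = 2.0


class ChisqResult(NamedTuple):
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class SelectionCriteria:
    k_range: tuple[int, ...] = (2, 3, 4)
    min_class_size: int = 5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.k_range:
            raise ValueError("k_range must be nonempty")
        if self.min_class_size < 1:
            raise ValueError("min_class_size must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SelectionReport:
    per_k: dict  # K -> {dic, smallest_class_size, chisq, df, p, excluded, reason}
    chosen_k: int | None
    criteria: SelectionCriteria

    def to_dict(self) -> dict:
        return {
            "chosen_k": self.chosen_k,
            "criteria": {
                "k_range": list(self.criteria.k_range),
                "min_class_size": self.criteria.min_class_size,
                "alpha": self.criteria.alpha,
            },
            "per_k": {str(k): dict(v) for k, v in self.per_k.items()},
        }


def pearson_chisq(table) -> ChisqResult:
    """Pearson chi-square test of independence on a contingency table.

    statistic = sum (O - E)^2 / E with expected counts from the margins,
    df = (r - 1)(c - 1), p from the upper chi-square tail. No continuity
    correction. All-zero rows/columns are dropped with a warning; a table
    with fewer than 2 rows or columns after dropping is degenerate.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be nonnegative integers")
    keep_rows = t.sum(axis=1) > 0
    keep_cols = t.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping all-zero rows/columns from the contingency table")
        t = t[keep_rows][:, keep_cols]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError(f"degenerate contingency table of shape {t.shape}")
    res = stats.chi2_contingency(t, correction=False)
    return ChisqResult(float(res.statistic), int(res.dof), float(res.pvalue))


def class_by_diagnosis_table(fit: FitResult, diagnoses) -> pd.DataFrame:
    """Contingency table of diagnosis (rows) by modal class (columns).

    ``diagnoses`` maps subject_id to a diagnosis label (mapping or
    pandas Series indexed by subject).
    """
    if isinstance(diagnoses, pd.Series):
        diagnoses = diagnoses.to_dict()
    missing = [s for s in fit.subject_ids if s not in diagnoses]
    if missing:
        raise ValueError(f"diagnoses missing for subjects {missing[:5]}...")
    labels = [diagnoses[s] for s in fit.subject_ids]
    rows = pd.unique(pd.Series(labels))
    tab = pd.DataFrame(
        0, index=list(rows), columns=[f"class{k + 1}" for k in range(fit.K)]
    )
    for lab, k in zip(labels, fit.modal_class):
        tab.loc[lab, f"class{k + 1}"] += 1
    return tab


def select_model(
    fits: Sequence[FitResult],
    diagnoses,
    criteria: SelectionCriteria | None = None,
) -> SelectionReport:
    """Select K from per-K fits using internal fit and external validity.

    A K is excluded when any modal class has fewer than
    ``criteria.min_class_size`` subjects, or when the class-by-diagnosis
    chi-square is not significant at ``criteria.alpha``. Among survivors
    the lowest-DIC K is chosen; survivors within ``DIC_TIE_MARGIN`` of
    the best DIC are treated as ties and the smallest K wins. The result
    is invariant to the order fits are supplied. If no K survives,
    ``chosen_k`` is None and every K carries its exclusion reason.
    """
    criteria = criteria or SelectionCriteria()
    fits = sorted(fits, key=lambda f: f.K)
    ks = [f.K for f in fits]
    if len(set(ks)) != len(ks):
        raise ValueError("supply exactly one FitResult per K")

    per_k: dict[int, dict] = {}
    survivors: list[FitResult] = []
    for fit in fits:
        rec: dict = {
            "dic": fit.dic,
            "smallest_class_size": fit.smallest_class_size,
            "chisq": None,
            "df": None,
            "p": None,
            "excluded": False,
            "reason": None,
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                chi = pearson_chisq(class_by_diagnosis_table(fit, diagnoses).to_numpy())
            rec.update(chisq=chi.statistic, df=chi.df, p=chi.p)
        except ValueError as err:
            rec.update(excluded=True, reason=f"degenerate diagnosis table: {err}")
            per_k[fit.K] = rec
            continue
        if fit.smallest_class_size < criteria.min_class_size:
            rec.update(
                excluded=True,
                reason=(
                    f"smallest class has {fit.smallest_class_size} subjects "
                    f"(< {criteria.min_class_size})"
                ),
            )
        elif chi.p >= criteria.alpha:
            rec.update(
                excluded=True,
                reason=f"no external validity: chi-square p={chi.p:.3f} >= {criteria.alpha}",
            )
        else:
            survivors.append(fit)
        per_k[fit.K] = rec

    chosen: int | None = None
    if survivors:
        best_dic = min(f.dic for f in survivors)
        tied = [f.K for f in survivors if f.dic <= best_dic + DIC_TIE_MARGIN]
        chosen = min(tied)
    return SelectionReport(per_k=per_k, chosen_k=chosen, criteria=criteria)
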