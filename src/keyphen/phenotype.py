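"""Density-based phenotype classification.

Given fitted component means and the shared SD, a practitioner can score
a single observed backspace rate against each class: the unnormalized
score for class k is the plain normal density f(rate | mu_k, sigma)
(no mixture weight, no truncation normalizer), and normalized scores
divide by the sum. For a K = 3 fit the classes ordered by mean are named
Low, Medium, High. For whole cohorts with multi-day data, assignment
instead uses the MCMC posterior class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mixture import FitResult, MixtureParams


def class_labels(K: int) -> list[str]:
    """Class names ordered by ascending component mean."""
    if K == 3:
        return ["Low", "Medium", "High"]
    return [f"Class{k + 1}" for k in range(K)]


@dataclass
class PhenotypeAssignment:
    """Per-rate or per-subject class scores and the modal label."""

    subject_id: str | None
    rate: float | None
    unnormalized: np.ndarray
    normalized: np.ndarray
    label: str

    @property
    def labels(self) -> list[str]:
        return class_labels(len(self.normalized))


def class_density_scores(
    rate: float,
    params: MixtureParams,
    use_weights: bool = False,
    use_truncation: bool = False,
) -> PhenotypeAssignment:
    """Score one backspace rate against each fitted class.

    By default the score for class k is the untruncated, unweighted
    normal pdf f(rate | mu_k, sigma). ``use_weights`` multiplies by the
    mixture weights (giving, after normalization, the standard posterior
    class probability for a single observation); ``use_truncation``
    divides by the (0, 1) truncation normalizer. The label is the argmax
    class, ties resolving to the lower (smaller-mean) class.
    """
    if not 0 < rate < 1:
        raise ValueError("rate must lie strictly inside (0, 1)")
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    p = params.sorted()
    scores = stats.norm.pdf(rate, loc=p.means, scale=p.sigma)
    if use_truncation:
        scores = scores / (
            stats.norm.cdf((1 - p.means) / p.sigma) - stats.norm.cdf(-p.means / p.sigma)
        )
    if use_weights:
        scores = scores * p.weights
    total = scores.sum()
    if total <= 0:
        raise FloatingPointError("all class densities underflowed to zero")
    normalized = scores / total
    label = class_labels(p.K)[int(np.argmax(scores))]
    return PhenotypeAssignment(
        subject_id=None, rate=float(rate), unnormalized=scores, normalized=normalized, label=label
    )


def assign_subjects(fit: FitResult) -> list[PhenotypeAssignment]:
    """Assign every subject in a fit to its modal phenotype.

    Uses the MCMC posterior class probabilities (already on the simplex);
    the modal label breaks exact ties toward the lower class.
    """
    labels = class_labels(fit.K)
    out = []
    for sid, probs in zip(fit.subject_ids, fit.class_probs):
        k = int(np.argmax(probs))
        out.append(
            PhenotypeAssignment(
                subject_id=sid,
                rate=None,
                unnormalized=probs.copy(),
                normalized=probs / probs.sum(),
                label=labels[k],
            )
        )
    return out


def assignments_frame(assignments: list[PhenotypeAssignment]):
    """Tabulate assignments: one row per subject, score per class + label."""
    import pandas as pd

    rows = []
    for a in assignments:
        row = {"subject_id": a.subject_id, "rate": a.rate, "label": a.label}
        for name, u, p in zip(a.labels, a.unnormalized, a.normalized):
            row[f"score_{name}"] = u
            row[f"prob_{name}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
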