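"""Synthetic cohort generator.

Emulates the statistical structure of the study cohort — 128 community
adults (27 healthy controls, 101 with mood disorders) observed for ~23
days each, ~2948 subject-days in total — so that every pipeline stage is
testable without any raw keystroke export:

* a latent 3-class phenotype per subject, allocated within diagnosis
  from the observed class-by-diagnosis composition (HC 13/14/0,
  unipolar 27/54/6, bipolar 7/4/3 across Low/Medium/High);
* daily backspace rates drawn from the equal-variance truncated-normal
  mixture with component means 0.112 / 0.180 / 0.268 and shared SD 0.048
  on (0, 1);
* clinical outcomes generated from configurable effect truths: HAM-D
  totals from a linear phenotype-effect model, YMRS totals from a
  hurdle-gamma truth, and individual symptom items from proportional-
  odds truths honoring the study's structural zeros (e.g. nobody in the
  High group endorses guilt);
* optionally, raw keypress event streams whose daily aggregation
  reproduces the daily-rate table exactly.

Every latent value is returned in a truth record so recovery can be
checked against the generating parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date as _date, datetime, timedelta
from typing import Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from scipy import stats

from .events import CATEGORIES, DAILY_COLUMNS
from .associations import (
    CLINICAL_COLUMNS,
    HAMD_COLUMNS,
    HAMD_ITEM_LEVELS,
    YMRS_COLUMNS,
    YMRS_ITEM_LEVELS,
)
from .mixture import MixtureParams

CLASS_LABELS = ("Low", "Medium", "High")

# Threshold sets giving mild-symptom marginals in the reference group:
# 5-point items ~ (75, 13, 7, 3.5, 1.5)% and 3-point items ~ (80, 15, 5)%.
_T5 = (1.099, 1.992, 2.944, 4.180)
_T3 = (1.386, 2.944)
# Sparser thresholds for mania items (~85% zeros in the reference group).
_T5_SPARSE = (1.735, 2.586, 3.476, 4.595)


@dataclass(frozen=True)
class ItemSpec:
    """Proportional-odds truth for one ordinal symptom item.

    ``thresholds`` are the cumulative-logit cutpoints for the reference
    (Low) group; ``beta_medium``/``beta_high`` shift the latent logit for
    the other phenotypes (log odds ratios of higher ratings). Groups in
    ``zero_groups`` are structural zeros: every member scores 0.
    """

    column: str
    levels: int
    thresholds: tuple
    beta_medium: float = 0.0
    beta_high: float = 0.0
    zero_groups: tuple = ()

    def __post_init__(self) -> None:
        if len(self.thresholds) != self.levels - 1:
            raise ValueError(f"{self.column}: need {self.levels - 1} thresholds")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError(f"{self.column}: thresholds must be ascending")
        bad = set(self.zero_groups) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"{self.column}: unknown zero groups {sorted(bad)}")


def _ln(x: float) -> float:
    return math.log(x)


def default_hamd_items() -> tuple[ItemSpec, ...]:
    """HAM-D item truths: log odds ratios for the items with reported
    phenotype contrasts, structural zeros for the items that failed to
    converge in the source cohort."""
    return (
        ItemSpec("hamd_1", 5, _T5, _ln(1.58), _ln(0.49)),
        ItemSpec("hamd_2", 5, _T5, zero_groups=("High",)),
        ItemSpec("hamd_3", 5, _T5, zero_groups=("High",)),
        ItemSpec("hamd_4", 3, _T3, _ln(1.69), _ln(4.20)),
        ItemSpec("hamd_5", 3, _T3, _ln(2.12), _ln(6.82)),
        ItemSpec("hamd_6", 3, _T3, _ln(1.26), _ln(7.61)),
        ItemSpec("hamd_7", 5, _T5, _ln(1.51), _ln(0.65)),
        ItemSpec("hamd_8", 5, _T5, _ln(3.14), _ln(1.34)),
        ItemSpec("hamd_9", 5, _T5, _ln(0.93), _ln(6.87)),
        ItemSpec("hamd_10", 5, _T5, _ln(3.30), _ln(4.62)),
        ItemSpec("hamd_11", 5, _T5, _ln(3.64), _ln(2.08)),
        ItemSpec("hamd_12", 3, _T3, _ln(2.05), _ln(1.05)),
        ItemSpec("hamd_13", 3, _T3, _ln(2.78), _ln(0.58)),
        ItemSpec("hamd_14", 3, _T3, _ln(5.24), _ln(1.76)),
        ItemSpec("hamd_15", 5, _T5, zero_groups=("Low",)),
        ItemSpec("hamd_16", 3, _T3, zero_groups=("High",)),
        ItemSpec("hamd_17", 3, _T3, zero_groups=("Low", "High")),
    )


def default_ymrs_items() -> tuple[ItemSpec, ...]:
    return (
        ItemSpec("ymrs_1", 5, _T5_SPARSE, _ln(1.99), _ln(16.12)),
        ItemSpec("ymrs_2", 5, _T5_SPARSE, _ln(2.71), _ln(15.22)),
        ItemSpec("ymrs_3", 5, _T5_SPARSE, zero_groups=("Low",)),
        ItemSpec("ymrs_4", 5, _T5_SPARSE, _ln(1.09), _ln(4.74)),
        ItemSpec("ymrs_5", 5, _T5_SPARSE, _ln(6.61), _ln(12.83)),
        ItemSpec("ymrs_6", 5, _T5_SPARSE, zero_groups=("Low",)),
        ItemSpec("ymrs_7", 5, _T5_SPARSE, zero_groups=("Low", "Medium")),
        ItemSpec("ymrs_8", 5, _T5_SPARSE, zero_groups=("Low", "High")),
        ItemSpec("ymrs_9", 5, _T5_SPARSE, zero_groups=("Low", "Medium", "High")),
        ItemSpec("ymrs_10", 5, _T5_SPARSE, zero_groups=("Low", "Medium", "High")),
        ItemSpec("ymrs_11", 5, _T5_SPARSE, zero_groups=("Low", "Medium", "High")),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generating truths for a synthetic cohort.

    Defaults reproduce the study conditions: the diagnosis margins, the
    class-by-diagnosis composition, the fitted mixture (means
    0.112/0.180/0.268, SD 0.048), ~23 observation days per subject
    (Poisson), medication prevalence by group, and the reported severity
    and symptom effect sizes. Intercepts and dispersions the study does
    not print are set to values consistent with its descriptive table.
    """

    n_subjects: int = 128
    diagnosis_counts: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 27, "unipolar": 87, "bipolar": 14}
    )
    class_counts_by_diagnosis: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "HC": (13, 14, 0),
            "unipolar": (27, 54, 6),
            "bipolar": (7, 4, 3),
        }
    )
    class_assignment: str = "expected"  # or "sampled"
    means: tuple = (0.112, 0.180, 0.268)
    sigma: float = 0.048
    mean_days: float = 23.0
    medication_prob: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 6 / 27, "MD": 60 / 101}
    )
    # Depression severity truth (HAM-D total): linear effects, floored at 0.
    dep_intercept: float = 5.5
    dep_b_medium: float = 2.32
    dep_b_high: float = 1.0
    dep_sd: float = 4.0
    # Mania severity truth (YMRS total): hurdle gamma.
    mania_zero_intercept: float = -1.1
    mania_zero_b_medium: float = 0.5
    mania_zero_b_high: float = 1.91
    mania_pos_intercept: float = _ln(1.8)
    mania_pos_b_medium: float = 0.79
    mania_pos_b_high: float = 1.46
    mania_gamma_shape: float = 1.5
    integer_ymrs: bool = False
    hamd_items: tuple = field(default_factory=default_hamd_items)
    ymrs_items: tuple = field(default_factory=default_ymrs_items)
    # Daily keypress volume (log-normal, clipped).
    keypress_log_mean: float = _ln(400.0)
    keypress_log_sd: float = 0.5
    min_keypresses: int = 60
    max_keypresses: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.diagnosis_counts.values()) != self.n_subjects:
            raise ValueError("diagnosis counts must sum to n_subjects")
        for diag, counts in self.class_counts_by_diagnosis.items():
            if diag not in self.diagnosis_counts:
                raise ValueError(f"unknown diagnosis {diag!r} in class counts")
            if sum(counts) != self.diagnosis_counts[diag]:
                raise ValueError(f"class counts for {diag!r} do not sum to its margin")
            if len(counts) != len(self.means):
                raise ValueError("class counts must have one entry per component")
        if self.sigma <= 0 or self.dep_sd <= 0 or self.mania_gamma_shape <= 0:
            raise ValueError("scale parameters must be positive")
        if list(self.means) != sorted(self.means):
            raise ValueError("component means must be ascending")
        if self.class_assignment not in ("expected", "sampled"):
            raise ValueError("class_assignment must be 'expected' or 'sampled'")


def sample_truncated_rates(
    mu: float, sigma: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw from a normal(mu, sigma) truncated to (0, 1)."""
    a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _sample_ordinal(thresholds, shift, size, rng) -> np.ndarray:
    """Sample a proportional-odds item: P(Y <= j) = logistic(theta_j - shift)."""
    cum = 1.0 / (1.0 + np.exp(-(np.asarray(thresholds) - shift)))
    cum = np.append(cum, 1.0)
    u = rng.random(size)
    return np.searchsorted(cum, u, side="right").astype(int)


def _assign_classes(cfg: CohortConfig, diagnosis: np.ndarray, rng) -> np.ndarray:
    z = np.empty(len(diagnosis), dtype=int)
    for diag, counts in cfg.class_counts_by_diagnosis.items():
        idx = np.flatnonzero(diagnosis == diag)
        if cfg.class_assignment == "expected":
            pool = np.repeat(np.arange(len(counts)), counts)
            rng.shuffle(pool)
        else:
            probs = np.asarray(counts, float) / sum(counts)
            pool = rng.choice(len(counts), size=len(idx), p=probs)
        z[idx] = pool
    return z


def generate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a synthetic cohort.

    Returns ``(daily, clinical, truth)``: the per-subject-day rate table,
    the clinical table (items, covariates and severity totals), and a
    truth record holding every latent value (class assignments, realized
    weights, the generating config). Same config + seed is reproducible
    bit for bit.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_subjects
    width = len(str(n))
    subject_ids = [f"S{i + 1:0{width}d}" for i in range(n)]

    diagnosis = np.repeat(
        list(cfg.diagnosis_counts.keys()),
        list(cfg.diagnosis_counts.values()),
    ).astype(object)
    group = np.where(diagnosis == "HC", "HC", "MD").astype(object)
    z = _assign_classes(cfg, diagnosis, rng)
    label = np.asarray(CLASS_LABELS, object)[z]
    med_p = np.array([cfg.medication_prob[g] for g in group])
    medication = np.where(rng.random(n) < med_p, "yes", "no").astype(object)
    n_days = np.maximum(rng.poisson(cfg.mean_days, size=n), 1)

    # Daily backspace rates: truncated-normal mixture, realized as
    # backspace / keypress counts (integer rounding keeps rate in (0,1)).
    daily_rows = []
    start = _date(2023, 3, 6)
    for i, sid in enumerate(subject_ids):
        d = int(n_days[i])
        r = sample_truncated_rates(cfg.means[z[i]], cfg.sigma, d, rng)
        npress = np.clip(
            np.round(rng.lognormal(cfg.keypress_log_mean, cfg.keypress_log_sd, d)),
            cfg.min_keypresses,
            cfg.max_keypresses,
        ).astype(int)
        nback = np.clip(np.round(r * npress), 1, npress - 1).astype(int)
        for j in range(d):
            daily_rows.append(
                (sid, start + timedelta(days=j), int(npress[j]), int(nback[j]),
                 nback[j] / npress[j])
            )
    daily = pd.DataFrame(daily_rows, columns=DAILY_COLUMNS)

    # Severity totals.
    is_med = (label == "Medium").astype(float)
    is_high = (label == "High").astype(float)
    dep = (
        cfg.dep_intercept
        + cfg.dep_b_medium * is_med
        + cfg.dep_b_high * is_high
        + rng.normal(0.0, cfg.dep_sd, n)
    )
    hamd_total = np.clip(np.round(dep), 0, 52).astype(int)

    eta_zero = (
        cfg.mania_zero_intercept
        + cfg.mania_zero_b_medium * is_med
        + cfg.mania_zero_b_high * is_high
    )
    nonzero = rng.random(n) < 1.0 / (1.0 + np.exp(-eta_zero))
    eta_pos = (
        cfg.mania_pos_intercept
        + cfg.mania_pos_b_medium * is_med
        + cfg.mania_pos_b_high * is_high
    )
    gamma_draw = rng.gamma(cfg.mania_gamma_shape, np.exp(eta_pos) / cfg.mania_gamma_shape, n)
    if cfg.integer_ymrs:
        gamma_draw = np.maximum(np.round(gamma_draw), 1.0)
    ymrs_total = np.where(nonzero, gamma_draw, 0.0)

    # Symptom items from proportional-odds truths with structural zeros.
    clinical = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": group,
            "diagnosis": diagnosis,
            "medication": medication,
        }
    )
    for spec in tuple(cfg.hamd_items) + tuple(cfg.ymrs_items):
        shift = {"Low": 0.0, "Medium": spec.beta_medium, "High": spec.beta_high}
        vals = np.zeros(n, dtype=int)
        for g in CLASS_LABELS:
            idx = np.flatnonzero(label == g)
            if len(idx) == 0 or g in spec.zero_groups:
                continue
            vals[idx] = _sample_ordinal(spec.thresholds, shift[g], len(idx), rng)
        clinical[spec.column] = vals
    clinical["hamd_total"] = hamd_total
    clinical["ymrs_total"] = ymrs_total

    counts = np.bincount(z, minlength=len(cfg.means)).astype(float)
    truth = {
        "config": cfg,
        "subjects": pd.DataFrame(
            {
                "subject_id": subject_ids,
                "diagnosis": diagnosis,
                "group": group,
                "class_index": z,
                "label": label,
                "medication": medication,
                "n_days": n_days,
                "hamd_total": hamd_total,
                "ymrs_total": ymrs_total,
            }
        ),
        "mixture": MixtureParams(
            np.asarray(cfg.means, float), cfg.sigma, counts / counts.sum()
        ),
        "class_counts": counts.astype(int).tolist(),
    }
    return daily, clinical, truth


def generate_keystroke_events(
    daily: pd.DataFrame,
    seed: int = 0,
    timezone: str = "America/Chicago",
    start_hour: int = 8,
    session_gap_range: tuple = (30, 300),
    within_gap_range: tuple = (1, 2),
) -> pd.DataFrame:
    """Expand a daily-rate table into a raw keypress event stream.

    Each subject-day emits exactly ``n_keypresses`` events (of which
    exactly ``n_backspaces`` are backspace-category) in typing sessions:
    integer-second gaps of 1-2 s within a session and 30-300 s (always
    > 6 s) between sessions, starting at ``start_hour`` local time so the
    whole stream stays inside the local calendar day. Aggregating the
    events reproduces the daily table exactly; the emitted session_id
    column records the intended sessions for segmentation checks.
    """
    rng = np.random.default_rng(seed)
    tz = ZoneInfo(timezone)
    other = [c for c in CATEGORIES if c != "backspace"]
    other_p = np.array([0.75, 0.06, 0.08, 0.06, 0.05])
    rows = []
    for _, day in daily.iterrows():
        n, nb = int(day["n_keypresses"]), int(day["n_backspaces"])
        cats = np.array(
            ["backspace"] * nb + list(rng.choice(other, size=n - nb, p=other_p)),
            dtype=object,
        )
        rng.shuffle(cats)
        # Partition into sessions of 20-60 keypresses.
        bounds = [0]
        while bounds[-1] < n:
            bounds.append(min(n, bounds[-1] + int(rng.integers(20, 61))))
        t0 = datetime.combine(day["date"], datetime.min.time(), tzinfo=tz) + timedelta(
            hours=start_hour
        )
        offset = 0
        for s, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            if s > 0:
                offset += int(rng.integers(session_gap_range[0], session_gap_range[1] + 1))
            sid = f"{day['subject_id']}-{day['date'].isoformat()}-{s}"
            for j in range(lo, hi):
                if j > lo:
                    offset += int(rng.integers(within_gap_range[0], within_gap_range[1] + 1))
                ts = (t0 + timedelta(seconds=offset)).astimezone(ZoneInfo("UTC"))
                rows.append((day["subject_id"], sid, ts, timezone, cats[j]))
    return pd.DataFrame(
        rows, columns=["subject_id", "session_id", "timestamp_utc", "timezone", "category"]
    )
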