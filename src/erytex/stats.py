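"""Statistical layer: clinician-grade handling, agreement, treatment-energy
summaries, Friedman/Dunn longitudinal tests, Spearman correlation of grades
with face-level texture, and percent-change summaries.

All rank-based procedures use mid-ranks for ties.  Dunn pairwise p-values are
Bonferroni-adjusted over the three timepoint comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from erytex.pipeline import TIMEPOINTS, ZONES

RATERS = ("S1", "S2", "S3")
TIMEPOINT_PAIRS = (("T0", "T1"), ("T0", "T2"), ("T1", "T2"))

#: Grade bounds of the five-level clinician erythema scale.
GRADE_MIN, GRADE_MAX = 0, 4


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def load_energy_table() -> pd.DataFrame:
    """Per-volunteer energy densities (J/cm^2) for the three sessions."""
    with resources.files("erytex.data").joinpath("energy_densities.csv").open() as fh:
        return pd.read_csv(fh)


def load_reported_medians() -> pd.DataFrame:
    """Published per-region median texture values at the three timepoints."""
    with resources.files("erytex.data").joinpath("reported_medians.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    n: int
    rho: float
    t_stat: float
    p: float


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p: float
    posthoc: dict = field(default_factory=dict)  # "T0_vs_T1" -> adjusted p


# ---------------------------------------------------------------------------
# clinician grades
# ---------------------------------------------------------------------------

def mean_cea(grades: Mapping[str, int] | Sequence[int]) -> float:
    """Unrounded arithmetic mean of the rater grades for one assessment."""
    values = list(grades.values()) if isinstance(grades, Mapping) else list(grades)
    if not values:
        raise ValueError("no grades present")
    for g in values:
        if not (GRADE_MIN <= g <= GRADE_MAX):
            raise ValueError(f"grade {g} outside [{GRADE_MIN}, {GRADE_MAX}]")
    return float(np.mean(values))


def complete_agreement_fraction(cea: pd.DataFrame) -> tuple[int, int, float]:
    """Count assessments in which all three raters gave the identical grade.

    ``cea`` is long format with columns subject, timepoint, rater, grade.
    Returns (agree_count, total_assessments, percent).
    """
    required = {"subject", "timepoint", "rater", "grade"}
    if not required <= set(cea.columns):
        raise ValueError(f"CEA table needs columns {sorted(required)}")
    agree = total = 0
    for (_, _), grp in cea.groupby(["subject", "timepoint"], sort=True):
        raters = set(grp["rater"])
        if raters != set(RATERS):
            raise ValueError(f"assessment has raters {sorted(raters)}, expected {list(RATERS)}")
        total += 1
        if grp["grade"].nunique() == 1:
            agree += 1
    if total == 0:
        raise ValueError("no assessments in CEA table")
    return agree, total, 100.0 * agree / total


def mean_cea_table(cea: pd.DataFrame) -> pd.DataFrame:
    """Mean-of-raters grade per subject x timepoint (columns subject, timepoint, cea)."""
    out = (
        cea.groupby(["subject", "timepoint"], sort=True)["grade"]
        .mean()
        .rename("cea")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# treatment energies
# ---------------------------------------------------------------------------

def energy_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) per treatment session.

    ``records`` has columns subject, e1, e2, e3 (J/cm^2).
    """
    if records.empty:
        raise ValueError("no treatment records")
    for col in ("e1", "e2", "e3"):
        if col not in records.columns:
            raise ValueError(f"treatment table missing column {col!r}")
        if (records[col] <= 0).any():
            raise ValueError("energy densities must be positive")
    rows = [
        {
            "session": k,
            "mean": float(records[f"e{k}"].mean()),
            "sd": float(records[f"e{k}"].std(ddof=1)),
            "n": int(records[f"e{k}"].count()),
        }
        for k in (1, 2, 3)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# percent change
# ---------------------------------------------------------------------------

def percent_change(before: float, after: float, direction: str = "decrease") -> float:
    """Relative change in percent, unrounded.

    ``decrease`` reports 100*(before-after)/before; ``increase`` reports
    100*(after-before)/before.  Round only at presentation.
    """
    if before <= 0:
        raise ValueError(f"baseline value must be positive, got {before}")
    if direction == "decrease":
        return 100.0 * (before - after) / before
    if direction == "increase":
        return 100.0 * (after - before) / before
    raise ValueError(f"direction must be 'decrease' or 'increase', got {direction!r}")


# ---------------------------------------------------------------------------
# Spearman rank correlation with t(N-2)
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rho as Pearson correlation of mid-ranks, with t(N-2) p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant input vector")
    rx = sps.rankdata(x)  # mid-ranks on ties
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(abs(rho) - 1.0) < 1e-12:  # snap exact concordance past fp noise
        rho = float(np.sign(rho))
    if abs(rho) == 1.0:
        t_stat = np.inf * np.sign(rho)
        p = 0.0
    else:
        t_stat = rho * np.sqrt(n - 2) / np.sqrt(1.0 - rho * rho)
        p = 2.0 * sps.t.sf(abs(t_stat), df=n - 2)
    return CorrelationResult(n=n, rho=rho, t_stat=float(t_stat), p=float(p))


# ---------------------------------------------------------------------------
# Friedman + Dunn
# ---------------------------------------------------------------------------

def _friedman_ranks(values: np.ndarray) -> np.ndarray:
    """Within-subject mid-ranks, shape (n_subjects, k)."""
    return np.apply_along_axis(sps.rankdata, 1, values)


def friedman_statistic(values: np.ndarray) -> tuple[float, int]:
    """Tie-corrected Friedman chi-square for an (n_subjects, k) block table."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks = _friedman_ranks(values)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3.0 * n * (k + 1)
    # tie correction: sizes of tied groups within each subject's row
    tie_term = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    correction = 1.0 - tie_term / (n * (k**3 - k))
    if correction <= 0:  # every row constant: no information, statistic is 0
        return 0.0, k - 1
    return chi2 / correction, k - 1


def friedman_with_dunn(
    values: np.ndarray | pd.DataFrame,
    labels: Sequence[str] = TIMEPOINTS,
) -> FriedmanResult:
    """Friedman omnibus test plus Dunn pairwise z-tests (Bonferroni over 3).

    ``values`` is subjects x conditions with no missing cells (no imputation).
    """
    if isinstance(values, pd.DataFrame):
        values = values.to_numpy()
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D subjects x conditions table")
    if np.isnan(values).any():
        raise ValueError("missing cells are not allowed (no imputation)")
    n, k = values.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if k != len(labels):
        raise ValueError(f"expected {len(labels)} conditions, got {k}")

    stat, df = friedman_statistic(values)
    p = float(sps.chi2.sf(stat, df))

    ranks = _friedman_ranks(values)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_comparisons = k * (k - 1) // 2
    posthoc = {}
    for a, b in combinations(range(k), 2):
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        posthoc[f"{labels[a]}_vs_{labels[b]}"] = float(min(1.0, p_raw * n_comparisons))
    return FriedmanResult(statistic=float(stat), df=df, p=p, posthoc=posthoc)


def shapiro_normality(values: Sequence[float]) -> tuple[float, float]:
    """Library-backed Shapiro-Wilk screen (justificatory report line only)."""
    stat, p = sps.shapiro(np.asarray(values, dtype=float))
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# whole-study analysis
# ---------------------------------------------------------------------------

def _pivot_complete(study: pd.DataFrame, column: str) -> pd.DataFrame:
    wide = study.pivot(index="subject", columns="timepoint", values=column)
    missing_tp = [t for t in TIMEPOINTS if t not in wide.columns]
    if missing_tp:
        raise ValueError(f"study lacks timepoints {missing_tp} for {column}")
    wide = wide[list(TIMEPOINTS)]
    bad = wide[wide.isna().any(axis=1)].index.tolist()
    if bad:
        raise ValueError(f"subjects with incomplete timepoints for {column}: {bad}")
    return wide


def _metric_block(study: pd.DataFrame, column: str, alpha: float) -> dict:
    wide = _pivot_complete(study, column)
    medians = {t: float(wide[t].median()) for t in TIMEPOINTS}
    fried = friedman_with_dunn(wide.to_numpy())
    increases = column.startswith("homogeneity") or column == "face_homogeneity"
    direction = "increase" if increases else "decrease"
    return {
        "medians": medians,
        "percent_change": {
            "T0_to_T1": percent_change(medians["T0"], medians["T1"], direction),
            "T0_to_T2": percent_change(medians["T0"], medians["T2"], direction),
        },
        "direction": direction,
        "friedman": {
            "statistic": fried.statistic,
            "df": fried.df,
            "p": fried.p,
            "significant": fried.p < alpha,
            "posthoc": fried.posthoc,
        },
    }


def study_analysis(
    study: pd.DataFrame,
    cea: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Full results bundle over a feature StudyTable (plus optional CEA table).

    Per zone and for the face: per-timepoint medians, percent changes
    T0->T1 / T0->T2, Friedman omnibus + Dunn post hoc.  With a CEA table:
    complete-agreement stats and Spearman of mean grade vs face contrast and
    vs face homogeneity at each timepoint.
    """
    required = {"subject", "timepoint", "face_contrast", "face_homogeneity"}
    missing = required - set(study.columns)
    if missing:
        raise ValueError(f"study table missing columns {sorted(missing)}")
    bad_tp = sorted(set(study["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValueError(f"unknown timepoints in study table: {bad_tp}")
    if study["subject"].nunique() < 3:
        raise ValueError("need at least 3 subjects")

    metrics: dict[str, dict] = {}
    for zone in ZONES:
        for feat in ("contrast", "homogeneity"):
            col = f"{feat}_{zone}"
            if col in study.columns:
                metrics[col] = _metric_block(study, col, alpha)
    metrics["face_contrast"] = _metric_block(study, "face_contrast", alpha)
    metrics["face_homogeneity"] = _metric_block(study, "face_homogeneity", alpha)

    bundle: dict = {"alpha": alpha, "metrics": metrics}

    if cea is not None:
        agree, total, percent = complete_agreement_fraction(cea)
        bundle["agreement"] = {"unanimous": agree, "total": total, "percent": percent}
        means = mean_cea_table(cea)
        merged = means.merge(study, on=["subject", "timepoint"], how="inner")
        cea_wide = _pivot_complete(means.rename(columns={"cea": "mean_cea"}), "mean_cea")
        fried = friedman_with_dunn(cea_wide.to_numpy())
        bundle["cea"] = {
            "medians": {t: float(cea_wide[t].median()) for t in TIMEPOINTS},
            "friedman": {
                "statistic": fried.statistic,
                "df": fried.df,
                "p": fried.p,
                "significant": fried.p < alpha,
                "posthoc": fried.posthoc,
            },
        }
        correlations = {}
        for t in TIMEPOINTS:
            sub = merged[merged["timepoint"] == t]
            for col, key in (("face_contrast", "contrast"), ("face_homogeneity", "homogeneity")):
                try:
                    res = spearman(sub["cea"], sub[col])
                except ValueError as err:  # constant vector: correlation undefined
                    correlations[f"{t}_{key}"] = {"n": len(sub), "rho": None, "error": str(err)}
                    continue
                correlations[f"{t}_{key}"] = {
                    "n": res.n,
                    "rho": res.rho,
                    "t_stat": res.t_stat,
                    "p": res.p,
                }
        bundle["correlations"] = correlations
    return bundle
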