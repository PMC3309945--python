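"""Assessment statistics for relevance judgments.

Precision at two relevance levels with 95% confidence intervals,
generalized (Fleiss) kappa for multi-rater agreement, Spearman factor
correlations, a tie-corrected Friedman comparison of raters and a
chi-square comparison across query terms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import IO, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .terminology import DescriptorFeatures

__all__ = [
    "CATEGORIES",
    "JudgmentMatrix",
    "PrecisionEstimate",
    "KappaResult",
    "TestResult",
    "precision",
    "fleiss_kappa",
    "spearman_assoc",
    "compare_raters",
    "compare_terms",
]

#: Ordinal relevance categories, worst to best.
CATEGORIES = ("bad", "partial", "full")
_SCORE = {c: i for i, c in enumerate(CATEGORIES)}

_LEVELS = ("full", "partial_or_full")
_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class JudgmentMatrix:
    """Citations x raters table of three-category relevance ratings.

    Missing cells are allowed (NaN) and flagged; at least two raters and
    one rating per row are required.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.shape[1] < 2:
            raise ValueError("need ratings from at least 2 raters")
        values = frame.to_numpy(dtype=object)
        bad_cells = {
            v for v in values.ravel() if not (isinstance(v, float) and math.isnan(v)) and v not in CATEGORIES
        }
        if bad_cells:
            raise ValueError(f"ratings outside {CATEGORIES}: {sorted(map(str, bad_cells))}")
        if frame.notna().sum(axis=1).min() < 1:
            raise ValueError("every row needs at least one rating")
        self.frame = frame

    @property
    def raters(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def has_missing(self) -> bool:
        return bool(self.frame.isna().any().any())

    def complete_rows(self) -> pd.DataFrame:
        return self.frame.dropna()

    def ratings(self, rater: str) -> list[str]:
        if rater not in self.frame.columns:
            raise KeyError(f"unknown rater {rater!r}")
        return [v for v in self.frame[rater] if isinstance(v, str)]

    @classmethod
    def from_judgments(cls, table: Union[pd.DataFrame, IO[str], str]) -> "JudgmentMatrix":
        """Build from a long-format judgments table (CSV or DataFrame).

        Columns: term, rank, pmid, rater, rating.
        """
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, dtype=str)
        required = {"term", "rank", "pmid", "rater", "rating"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"judgments table missing columns {sorted(missing)}")
        wide = table.pivot_table(
            index=["term", "rank", "pmid"],
            columns="rater",
            values="rating",
            aggfunc="first",
        )
        wide.columns.name = None
        return cls(wide)


@dataclass(frozen=True)
class PrecisionEstimate:
    level: str
    p: float
    n: int
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.p <= self.ci_high <= 1.0):
            raise ValueError("confidence bounds must bracket p within [0, 1]")


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    n_subjects: int
    n_raters: int
    n_categories: int
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        if self.kappa > 1 + 1e-12:
            raise ValueError("kappa cannot exceed 1")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    warning: Optional[str] = None


def _wald_ci(p: float, n: int) -> tuple[float, float]:
    half = _Z95 * math.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def _wilson_ci(p: float, n: int) -> tuple[float, float]:
    z2 = _Z95**2
    denom = 1.0 + z2 / n
    centre = (p + z2 / (2 * n)) / denom
    half = _Z95 * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def precision(
    matrix: JudgmentMatrix,
    rater: Optional[str],
    level: str = "full",
    ci: str = "wald",
) -> PrecisionEstimate:
    """Fraction of a rater's citations judged at or above ``level``.

    ``level`` is ``"full"`` (only fully relevant counts) or
    ``"partial_or_full"``.  ``rater=None`` pools every rating from every
    rater.  The default interval is Wald (p +/- 1.96*sqrt(p(1-p)/n),
    clamped); pass ``ci="wilson"`` for the Wilson score interval.
    """
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}")
    if rater is None:
        ratings = [v for r in matrix.raters for v in matrix.ratings(r)]
    else:
        ratings = matrix.ratings(rater)
    if not ratings:
        raise ValueError("empty rating vector")
    threshold = _SCORE["full"] if level == "full" else _SCORE["partial"]
    n = len(ratings)
    hits = sum(1 for r in ratings if _SCORE[r] >= threshold)
    p = hits / n
    lo, hi = _wald_ci(p, n) if ci == "wald" else _wilson_ci(p, n)
    return PrecisionEstimate(level=level, p=p, n=n, ci_low=lo, ci_high=hi)


def fleiss_kappa(matrix: JudgmentMatrix) -> KappaResult:
    """Generalized (Fleiss) kappa over complete rows, nominal categories.

    Rows with any missing rating are dropped (the count is reported).
    If every rating falls in one category the chance-corrected
    denominator vanishes; agreement is perfect and kappa is defined as 1,
    with a warning.
    """
    complete = matrix.complete_rows()
    n_dropped = matrix.n_rows - len(complete)
    n = len(complete)
    if n < 2:
        raise ValueError("need at least 2 complete rows for kappa")
    m = complete.shape[1]

    counts = np.zeros((n, len(CATEGORIES)), dtype=float)
    for j, cat in enumerate(CATEGORIES):
        counts[:, j] = (complete == cat).sum(axis=1)

    p_j = counts.sum(axis=0) / (n * m)
    p_i = (np.square(counts).sum(axis=1) - m) / (m * (m - 1))
    p_bar = p_i.mean()
    p_e = float(np.square(p_j).sum())

    if 1.0 - p_e < 1e-15:
        warnings.warn("all ratings in a single category; kappa defined as 1", stacklevel=2)
        kappa = 1.0
    else:
        kappa = float((p_bar - p_e) / (1.0 - p_e))
    return KappaResult(
        kappa=kappa,
        n_subjects=n,
        n_raters=m,
        n_categories=len(CATEGORIES),
        n_dropped_rows=n_dropped,
    )


def spearman_assoc(
    features: Sequence[DescriptorFeatures], outcome: Sequence[float]
) -> dict[str, TestResult]:
    """Spearman rho of each recorded factor against an outcome vector.

    Factors: son count, entry-term count, UMLS-synonym count.  Ties get
    average ranks; p-values use the two-sided t approximation.  A
    constant factor has undefined rho (NaN statistic, flagged).
    """
    if len(features) != len(outcome):
        raise ValueError("features and outcome must have equal length")
    if len(features) < 3:
        raise ValueError("need at least 3 observations")
    out: dict[str, TestResult] = {}
    factors = {
        "n_sons": [f.n_sons for f in features],
        "n_mesh_synonyms": [f.n_mesh_synonyms for f in features],
        "n_umls_synonyms": [f.n_umls_synonyms for f in features],
    }
    y = np.asarray(outcome, dtype=float)
    for name, values in factors.items():
        x = np.asarray(values, dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[name] = TestResult(
                statistic=float("nan"),
                df=len(x) - 2,
                p_value=float("nan"),
                method="spearman",
                warning="undefined: constant vector",
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(x, y)
        out[name] = TestResult(statistic=float(rho), df=len(x) - 2, p_value=float(p), method="spearman")
    return out


def compare_raters(matrix: JudgmentMatrix) -> TestResult:
    """Friedman test of rater effects on ordinal scores (bad<partial<full).

    Rows are blocks, raters treatments; scores are coded 0/1/2 and ranked
    within rows with average ranks.  The statistic uses the tie-corrected
    chi-square form; with everything tied it is 0 with p = 1.
    """
    complete = matrix.complete_rows()
    n, k = complete.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 complete rows and 2 raters")
    scores = complete.apply(lambda col: col.map(_SCORE)).to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, scores)

    col_sums = ranks.sum(axis=0)
    a = float(np.square(ranks).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    numerator = (k - 1) * float(np.square(col_sums - n * (k + 1) / 2.0).sum())
    if a - c < 1e-12:
        return TestResult(statistic=0.0, df=k - 1, p_value=1.0, method="friedman")
    statistic = numerator / (a - c)
    p = float(stats.chi2.sf(statistic, k - 1))
    return TestResult(statistic=float(statistic), df=k - 1, p_value=p, method="friedman")


def compare_terms(table: Union[np.ndarray, Sequence[Sequence[int]]]) -> TestResult:
    """Pearson chi-square on a 2 x k relevant/non-relevant contingency table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if (obs < 0).any():
        raise ValueError("negative cell counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    statistic, p, df, expected = stats.chi2_contingency(obs, correction=False)
    warning = "expected count < 5 in some cell" if (expected < 5).any() else None
    return TestResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p),
        method="chi-square",
        warning=warning,
    )
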