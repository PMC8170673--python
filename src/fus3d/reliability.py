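"""Test-retest reliability statistics for pelvic landmark localization.

Each leg contributes one row (left and right sides treated as independent
observations).  For every localization method the landmark position is
measured in the sacrum-local pelvic frame in two sessions; reliability is
quantified per anatomical axis and for the Euclidean test-retest distance
by:

* ICC(2,1) -- single-measure, absolute-agreement intraclass correlation
  from the two-way (rows x sessions) ANOVA, with an F-based 95% CI and the
  conventional poor/moderate/good/excellent bands at 0.5 / 0.75 / 0.9;
* SEm -- the standard error of measurement, sqrt(MS_error) of the same
  two-way ANOVA (not the standard error of the mean);
* a Friedman test across methods per group with pairwise Mann-Whitney
  follow-ups (uncorrected, alpha 0.05);
* Pearson correlations of the Euclidean test-retest distance against
  torso fat mass (FMT, % body mass);
* a variation summary: SD of test-retest differences per group, with the
  obese-lean absolute difference (mm) and relative difference (% of the
  lean group).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import TooFewConditionsError, TooFewPointsError

__all__ = [
    "AXES",
    "METHODS",
    "TestRetestDataset",
    "IccResult",
    "SemResult",
    "FriedmanResult",
    "MannWhitneyResult",
    "PearsonResult",
    "GroupComparisonResult",
    "two_way_anova",
    "test_retest_differences",
    "icc_2_1",
    "rate_icc",
    "sem_from_anova",
    "friedman_test",
    "mann_whitney",
    "pearson_fmt",
    "compare_methods",
    "variation_summary",
    "variation_from_sds",
    "reliability_report",
]

logger = logging.getLogger(__name__)

#: anatomical axes of the pelvic frame plus the Euclidean distance channel
AXES = ("ant-post", "med-lat", "sup-inf")
_AXIS_COL = {"ant-post": "ap", "med-lat": "ml", "sup-inf": "si"}

METHODS = ("MMP", "IPT", "3DFUS", "3DFUS-HJC")

_POSITION_COLS = [f"{c}_{s}" for s in ("test", "retest") for c in ("ap", "ml", "si")]
_REQUIRED_COLS = ["subject_id", "side", "group", "method", "fmt"] + _POSITION_COLS


@dataclass(frozen=True)
class TestRetestDataset:
    """Tidy per-leg, per-method landmark table with both sessions.

    Columns: subject_id, side, group (lean|obese), method, fmt (% body
    mass), and ap/ml/si positions (mm, pelvic frame) suffixed ``_test``
    and ``_retest``.  Rows missing either session are excluded on
    construction and counted in ``n_dropped``.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        fmt = self.data["fmt"].to_numpy(dtype=float)
        valid = fmt[np.isfinite(fmt)]
        if valid.size and (valid.min() < 0 or valid.max() > 100):
            raise ValueError("fmt must lie in [0, 100] % body mass")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TestRetestDataset":
        """Build from a raw table, dropping rows with a missing session."""
        complete = df[_POSITION_COLS].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("dropped %d rows with a missing session", n_dropped)
        return cls(df.loc[complete].reset_index(drop=True), n_dropped)

    def method(self, method: str) -> pd.DataFrame:
        return self.data[self.data["method"] == method]

    @property
    def n_rows(self) -> int:
        return int(len(self.data))


def test_retest_differences(ds: TestRetestDataset) -> pd.DataFrame:
    """Signed per-axis (retest - test) differences and Euclidean distance.

    Returns the dataset table with ``d_ap``, ``d_ml``, ``d_si`` and
    ``eucl`` columns (mm) appended.
    """
    df = ds.data.copy()
    for col in _AXIS_COL.values():
        df[f"d_{col}"] = df[f"{col}_retest"] - df[f"{col}_test"]
    df["eucl"] = np.sqrt(df["d_ap"] ** 2 + df["d_ml"] ** 2 + df["d_si"] ** 2)
    return df


# ---------------------------------------------------------------------------
# two-way ANOVA machinery shared by ICC(2,1) and SEm


def two_way_anova(values: np.ndarray) -> dict[str, float]:
    """Mean squares of the two-way (rows x columns, one obs/cell) ANOVA."""
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be a 2-D rows x sessions array")
    n, k = X.shape
    if n < 3 or k < 2:
        raise TooFewPointsError(f"need >= 3 rows and >= 2 columns, got {n}x{k}")
    if not np.all(np.isfinite(X)):
        raise ValueError("values contain missing cells")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    # residual SS computed directly (not by subtraction) for stability
    resid = X - row_means[:, None] - col_means[None, :] + grand
    ss_err = float(np.sum(resid**2))
    return {
        "n": n,
        "k": k,
        "ms_rows": ss_rows / (n - 1),
        "ms_cols": ss_cols / (k - 1),
        "ms_error": max(ss_err, 0.0) / ((n - 1) * (k - 1)),
    }


def rate_icc(icc: float) -> str:
    """Conventional reliability bands: poor/moderate/good/excellent."""
    if math.isnan(icc):
        return "undefined"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    rating: str
    undefined: bool = False


def icc_2_1(values: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): single-measure absolute agreement from two-way ANOVA.

    ``values`` is an n x k matrix (rows = legs, columns = sessions).  The
    point estimate is ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)``
    and the confidence interval is the standard F-based interval with a
    Satterthwaite denominator-df approximation.  A matrix with no
    variability at all yields an undefined ICC (flagged, not an error).
    """
    ms = two_way_anova(values)
    n, k = ms["n"], ms["k"]
    msr, msc, mse = ms["ms_rows"], ms["ms_cols"], ms["ms_error"]

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    scale = max(msr, msc, mse)
    if scale == 0 or abs(denom) < 1e-12 * scale:
        return IccResult(float("nan"), float("nan"), float("nan"),
                         n, k, "undefined", undefined=True)
    icc = (msr - mse) / denom

    if mse <= 1e-12 * scale and msc <= 1e-12 * scale:
        # perfect agreement: degenerate CI
        return IccResult(1.0, 1.0, 1.0, n, k, rate_icc(1.0))

    a = k * icc / (n * (1 - icc)) if icc < 1 else float("inf")
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else float("inf")
    if not (math.isfinite(a) and math.isfinite(b)):
        return IccResult(icc, 1.0, 1.0, n, k, rate_icc(icc))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    lower = min(lower, icc)
    upper = max(upper, icc)
    return IccResult(float(icc), float(lower), float(upper), n, k, rate_icc(icc))


@dataclass(frozen=True)
class SemResult:
    sem: float  # mm, sqrt(MS_error)
    anova_mean_squares: dict[str, float]
    sem_from_icc: float | None = None  # secondary SD*sqrt(1-ICC) variant


def sem_from_anova(values: np.ndarray) -> SemResult:
    """Standard error of measurement: sqrt(MS_error) of the two-way ANOVA.

    The classical alternative ``SD * sqrt(1 - ICC)`` is reported as a
    labeled secondary value.
    """
    ms = two_way_anova(values)
    sem = float(np.sqrt(ms["ms_error"]))
    icc = icc_2_1(values)
    alt = None
    if not icc.undefined:
        sd = float(np.std(np.asarray(values, dtype=float), ddof=1))
        alt = float(sd * np.sqrt(max(1.0 - icc.icc, 0.0)))
    return SemResult(sem, {k: ms[k] for k in ("ms_rows", "ms_cols", "ms_error")}, alt)


# ---------------------------------------------------------------------------
# nonparametric battery


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float


def friedman_test(values: np.ndarray) -> FriedmanResult:
    """Friedman rank test across m >= 3 related conditions.

    Within-row average ranks with the standard tie correction; the
    statistic is referred to a chi-square with m-1 df.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be 2-D (rows x conditions)")
    n, m = X.shape
    if m < 3:
        raise TooFewConditionsError(f"need >= 3 conditions, got {m}")
    if n < 2:
        raise TooFewPointsError(f"need >= 2 rows, got {n}")
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * m * (m + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (m + 1)
    # tie correction
    tie_sum = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    c = 1.0 - tie_sum / (n * m * (m**2 - 1))
    if c <= 0:
        return FriedmanResult(0.0, m - 1, 1.0)
    chi2 /= c
    return FriedmanResult(float(chi2), m - 1, float(stats.chi2.sf(chi2, m - 1)))


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    z: float
    p: float


def mann_whitney(x: np.ndarray, y: np.ndarray, continuity: bool = False) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with normal approximation.

    U counts the pairs where x exceeds y plus half the ties.  The Z score
    uses the tie-corrected variance; the continuity correction is off by
    default (configurable).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise TooFewPointsError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    nt = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (nt * (nt - 1))
    var = n1 * n2 / 12.0 * ((nt + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(float(u), 0.0, 1.0)
    diff = u - mu
    if continuity and diff != 0:
        diff -= 0.5 * np.sign(diff)
    z = diff / math.sqrt(var)
    return MannWhitneyResult(float(u), float(z), float(2 * stats.norm.sf(abs(z))))


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int
    undefined: bool = False


def pearson_fmt(distances: np.ndarray, fmt: np.ndarray) -> PearsonResult:
    """Pearson correlation of test-retest distances against torso fat mass."""
    d = np.asarray(distances, dtype=float).ravel()
    f = np.asarray(fmt, dtype=float).ravel()
    if d.size != f.size:
        raise ValueError("distances and fmt must have equal length")
    if d.size < 3:
        raise TooFewPointsError("need >= 3 paired observations")
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(f))):
        raise ValueError("inputs must be finite")
    if np.std(d) == 0 or np.std(f) == 0:
        return PearsonResult(float("nan"), float("nan"), d.size, undefined=True)
    r, p = stats.pearsonr(d, f)
    return PearsonResult(float(r), float(p), int(d.size))


@dataclass(frozen=True)
class GroupComparisonResult:
    """Friedman omnibus across methods plus uncorrected pairwise follow-ups."""

    friedman: FriedmanResult
    pairwise: list[tuple[tuple[str, str], MannWhitneyResult]] = field(default_factory=list)
    alpha: float = 0.05
    corrected: bool = False


def compare_methods(
    per_method_distances: dict[str, np.ndarray],
    alpha: float = 0.05,
    always_posthoc: bool = False,
) -> GroupComparisonResult:
    """Friedman across methods; pairwise Mann-Whitney if significant.

    ``per_method_distances`` maps method name to the per-leg Euclidean
    test-retest distances of one group; rows must align across methods.
    Follow-up tests are not multiplicity-corrected.
    """
    names = list(per_method_distances)
    mat = np.column_stack([per_method_distances[m] for m in names])
    fr = friedman_test(mat)
    pairwise: list[tuple[tuple[str, str], MannWhitneyResult]] = []
    if fr.p < alpha or always_posthoc:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                res = mann_whitney(per_method_distances[names[i]],
                                   per_method_distances[names[j]])
                pairwise.append(((names[i], names[j]), res))
    return GroupComparisonResult(fr, pairwise, alpha=alpha, corrected=False)


# ---------------------------------------------------------------------------
# variation summary (group SDs and obese/lean contrasts)


def variation_from_sds(lean_sd: float, obese_sd: float) -> tuple[float, int]:
    """Obese-lean variation contrast from the two group SDs (mm).

    Returns the absolute difference ``obese - lean`` rounded to 0.1 mm and
    the relative difference ``100 * obese / lean`` rounded to integer
    percent.
    """
    if lean_sd < 0 or obese_sd < 0:
        raise ValueError("SDs must be non-negative")
    if lean_sd == 0:
        raise ValueError("lean SD must be positive for a relative difference")
    return round(obese_sd - lean_sd, 1), int(round(100.0 * obese_sd / lean_sd))


def variation_summary(ds: TestRetestDataset) -> pd.DataFrame:
    """Per method x axis SDs of test-retest differences by group.

    For each method and channel (three axes plus the Euclidean distance):
    SD of the signed per-axis differences (Euclidean: SD of the distances)
    within the lean and obese groups, the absolute difference in SD
    (obese - lean, mm) and the relative difference (100 * obese / lean, %
    of the lean group).  A missing group leaves NaNs and sets ``partial``.
    """
    diffs = test_retest_differences(ds)
    channels = {"ant-post": "d_ap", "med-lat": "d_ml", "sup-inf": "d_si",
                "Eucl. dist.": "eucl"}
    rows = []
    for method in diffs["method"].unique():
        sub = diffs[diffs["method"] == method]
        for axis, col in channels.items():
            sds = {}
            for grp in ("lean", "obese"):
                vals = sub.loc[sub["group"] == grp, col].to_numpy()
                sds[grp] = float(np.std(vals, ddof=1)) if vals.size >= 2 else float("nan")
            partial = any(math.isnan(v) for v in sds.values())
            if partial or sds["lean"] == 0:
                abs_d, rel_d = float("nan"), float("nan")
            else:
                abs_d, rel_d = variation_from_sds(sds["lean"], sds["obese"])
            rows.append({
                "method": method,
                "axis": axis,
                "lean_sd_mm": sds["lean"],
                "obese_sd_mm": sds["obese"],
                "abs_diff_mm": abs_d,
                "rel_diff_pct": rel_d,
                "partial": partial,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-level report


def _leg_key(df: pd.DataFrame) -> pd.Series:
    return df["subject_id"].astype(str) + "/" + df["side"].astype(str)


def reliability_report(ds: TestRetestDataset, alpha: float = 0.05) -> dict:
    """Full test-retest battery over a dataset.

    Returns a dict with:

    * ``icc`` -- per method x group x axis ICC(2,1), CI, rating;
    * ``sem`` -- per method x group x axis SEm (mm);
    * ``distances`` -- per method x group Euclidean distance descriptives;
    * ``variation`` -- the group-SD contrast table;
    * ``friedman`` -- per group omnibus + pairwise follow-ups across the
      methods, on legs present for every method;
    * ``pearson`` -- per method distance-vs-FMT correlation, groups pooled.
    """
    diffs = test_retest_differences(ds)
    icc_rows, sem_rows, dist_rows = [], [], []
    for method in diffs["method"].unique():
        for group in ("lean", "obese"):
            sub = ds.data[(ds.data["method"] == method) & (ds.data["group"] == group)]
            if len(sub) < 3:
                continue
            for axis in AXES:
                col = _AXIS_COL[axis]
                mat = sub[[f"{col}_test", f"{col}_retest"]].to_numpy()
                icc = icc_2_1(mat, alpha=alpha)
                sem = sem_from_anova(mat)
                icc_rows.append({
                    "method": method, "group": group, "axis": axis,
                    "icc": icc.icc, "ci_low": icc.ci_low, "ci_high": icc.ci_high,
                    "rating": icc.rating, "n": icc.n,
                })
                sem_rows.append({
                    "method": method, "group": group, "axis": axis,
                    "sem_mm": sem.sem, "sem_from_icc_mm": sem.sem_from_icc,
                })
            d = diffs[(diffs["method"] == method) & (diffs["group"] == group)]["eucl"]
            dist_rows.append({
                "method": method, "group": group, "n": int(len(d)),
                "median_mm": float(d.median()), "q1_mm": float(d.quantile(0.25)),
                "q3_mm": float(d.quantile(0.75)), "mean_mm": float(d.mean()),
            })

    friedman = {}
    for group in ("lean", "obese"):
        sub = diffs[diffs["group"] == group].copy()
        sub["leg"] = _leg_key(sub)
        wide = sub.pivot_table(index="leg", columns="method", values="eucl").dropna()
        if wide.shape[1] >= 3 and len(wide) >= 2:
            friedman[group] = compare_methods(
                {m: wide[m].to_numpy() for m in wide.columns}, alpha=alpha
            )

    pearson = {}
    for method in diffs["method"].unique():
        sub = diffs[diffs["method"] == method]
        if len(sub) >= 3:
            pearson[method] = pearson_fmt(sub["eucl"].to_numpy(), sub["fmt"].to_numpy())

    return {
        "icc": pd.DataFrame(icc_rows),
        "sem": pd.DataFrame(sem_rows),
        "distances": pd.DataFrame(dist_rows),
        "variation": variation_summary(ds),
        "friedman": friedman,
        "pearson": pearson,
        "n_dropped": ds.n_dropped,
    }
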