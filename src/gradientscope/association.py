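"""Brain–behaviour statistics: Spearman correlations, covariate-adjusted
linear models, the full network-pair × trait grid with Bonferroni control,
and median-split grouping.

The exploratory grid evaluates every unordered network pair (21 for seven
networks) against both traits (42 tests per pairwise metric family) and
flags cells surviving the Bonferroni-adjusted threshold α / n_tests —
0.05 / 42 ≈ 0.0012.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "spearman",
    "fit_covariate_model",
    "bonferroni_threshold",
    "median_split",
    "run_grid",
]

COVARIATES = ("aq_total", "gsq_total", "age", "gender", "fd", "dvars")


@dataclass(frozen=True)
class AssociationResult:
    """One metric–trait association: rank correlation and/or model betas."""

    n: int
    metric: str = ""
    trait: str = ""
    rho_s: float | None = None
    p: float | None = None
    beta: dict[str, float] = field(default_factory=dict)
    beta_p: dict[str, float] = field(default_factory=dict)


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    The p-value uses the t approximation (scipy default). Constant input has
    no defined rank correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Columns (beyond the first) lying in the span of the preceding ones."""
    bad = []
    x = design.to_numpy(dtype=float)
    for k in range(1, x.shape[1]):
        prev = x[:, :k]
        coef, *_ = np.linalg.lstsq(prev, x[:, k], rcond=None)
        resid = x[:, k] - prev @ coef
        scale = np.linalg.norm(x[:, k]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-10:
            bad.append(design.columns[k])
    return bad


def fit_covariate_model(metric, covariates: pd.DataFrame,
                        metric_name: str = "metric") -> AssociationResult:
    """OLS of a metric on AQ, GSQ, age, gender, FD and DVARS (raw units).

    An intercept is included; coefficients carry two-sided t-test p-values.
    A rank-deficient design raises, naming the collinear columns.
    """
    y = np.asarray(metric, dtype=float)
    missing = [c for c in COVARIATES if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table is missing columns {missing}")
    x = covariates.loc[:, list(COVARIATES)].astype(float)
    if y.ndim != 1 or y.size != len(x):
        raise ValueError("metric and covariates must have matching length")
    if y.size <= len(COVARIATES) + 1:
        raise ValueError("need more subjects than model parameters")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(f"collinear design columns: {_collinear_columns(design)}")
    fit = sm.OLS(y, design).fit()
    return AssociationResult(
        n=int(y.size),
        metric=metric_name,
        beta={c: float(fit.params[c]) for c in design.columns},
        beta_p={c: float(fit.pvalues[c]) for c in design.columns},
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted per-test threshold α / n_tests (full precision).

    Display at 4 decimals where a rounded value is reported
    (0.05 / 42 → 0.0012).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def median_split(values) -> tuple[np.ndarray, np.ndarray, float]:
    """Split subjects at the sample median; ties go to the low group.

    Returns (low indices, high indices, threshold), with membership rule
    value ≤ threshold → low, value > threshold → high.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    threshold = float(np.median(v))
    low = np.flatnonzero(v <= threshold)
    high = np.flatnonzero(v > threshold)
    return low, high, threshold


# ---------------------------------------------------------------------------
# exploratory grid

PAIRWISE_METRICS = ("median_distance", "peak_distance", "between_dispersion")
NETWORK_METRICS = ("eccentricity", "within_dispersion")
DEFAULT_TRAITS = ("aq_total", "gsq_total")


@dataclass(frozen=True)
class CorrelationGrid:
    """Tidy grid of metric × trait associations with Bonferroni flags.

    ``table`` columns: metric, network_a, network_b, trait, rho_s, p,
    n_tests, significant (raw p below α / n_tests for the metric family).
    """

    table: pd.DataFrame
    alpha: float

    def family(self, metric: str) -> pd.DataFrame:
        return self.table[self.table["metric"] == metric].reset_index(drop=True)


def run_grid(reports: pd.DataFrame, participants: pd.DataFrame,
             traits: tuple[str, ...] = DEFAULT_TRAITS,
             alpha: float = 0.05) -> CorrelationGrid:
    """Correlate every segregation metric with every trait across subjects.

    ``reports`` is the concatenation of per-subject tidy
    :func:`~gradientscope.seg_metrics.segregation_report` frames;
    ``participants`` carries one row per subject with the trait columns.
    Pairwise families test all K·(K−1)/2 pairs × len(traits); per-network
    families test each network (plus the global row for eccentricity).
    Each family is Bonferroni-controlled at its own test count.
    """
    if len(participants) < 4:
        raise ValueError("need at least 4 subjects")
    for t in traits:
        if t not in participants.columns:
            raise ValueError(f"missing trait column {t!r}")
    part_idx = participants.set_index("subject_id")
    rows: list[dict] = []
    for metric in (*PAIRWISE_METRICS, "gradient_range", "gradient_sd",
                   "variance_explained", *NETWORK_METRICS):
        fam = reports[reports["metric"] == metric]
        if fam.empty:
            continue
        cells = fam.groupby(["network_a", "network_b"], sort=False)
        n_tests = cells.ngroups * len(traits)
        threshold = bonferroni_threshold(alpha, n_tests)
        for (net_a, net_b), cell in cells:
            values = cell.set_index("subject")["value"]
            for trait in traits:
                aligned = part_idx.loc[values.index, trait]
                rho, p = spearman(values.to_numpy(), aligned.to_numpy())
                rows.append(dict(
                    metric=metric, network_a=net_a, network_b=net_b,
                    trait=trait, rho_s=rho, p=p, n=int(values.size),
                    n_tests=n_tests,
                    significant=bool(p < threshold),
                ))
    table = pd.DataFrame(rows)
    # Bonferroni flags never pass a cell whose raw p exceeds alpha/n_tests.
    assert not ((table["significant"]) &
                (table["p"] >= alpha / table["n_tests"])).any()
    return CorrelationGrid(table=table, alpha=alpha)


def grid_to_matrix(grid: CorrelationGrid, metric: str, trait: str,
                   network_order: tuple[str, ...]) -> pd.DataFrame:
    """Lower-triangular K × K view of one pairwise family (NaN above diagonal),
    with significance stars at 0.05 / 0.01 / 0.001 in a parallel table."""
    fam = grid.family(metric)
    fam = fam[fam["trait"] == trait]
    k = len(network_order)
    mat = pd.DataFrame(np.full((k, k), np.nan), index=network_order,
                       columns=network_order)
    for _, row in fam.iterrows():
        i = network_order.index(row["network_b"])
        j = network_order.index(row["network_a"])
        if i < j:
            i, j = j, i
        mat.iloc[i, j] = row["rho_s"]
    return mat


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
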