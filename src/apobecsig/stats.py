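"""Biomarker statistics for durable-clinical-benefit prediction.

Compares per-sample mutation counts (TCW/APOBEC count vs total count)
as predictors of durable clinical benefit (DCB) under anti-PD-1
therapy: univariate logistic regression, the Hosmer–Lemeshow
goodness-of-fit test, group summaries and fold changes,
quartile-based UP/DOWN expression grouping, two-group location tests,
Benjamini–Hochberg correction, immune-gene-module scores, and
exposure–score association.

The Hosmer–Lemeshow statistic bins samples by fitted probability into
``g`` near-equal groups (ties inseparable) and compares observed vs
expected events per bin:

    chi2 = sum_bins [(O1-E1)^2/E1 + (O0-E0)^2/E0],   df = g - 2.

Small p-values indicate poor calibration of the fitted model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)


@dataclass
class LogisticFit:
    """Univariate logistic fit logit P(y=1) = beta0 + beta1 * x."""

    predictor_name: str
    beta0: float
    beta1: float
    fitted_probabilities: np.ndarray
    converged: bool
    separation_detected: bool
    beta1_se: float = float("nan")


@dataclass
class HLTestResult:
    """Hosmer–Lemeshow calibration test result with its bin table."""

    g: int
    chi2: float
    df: int
    p_value: float
    bin_table: pd.DataFrame


@dataclass(frozen=True)
class GroupAssignment:
    """Quartile-based expression group for one sample."""

    sample_id: str
    group: str  # UP / DOWN / MID


class GroupCompareResult(NamedTuple):
    statistic: float
    p_value: float
    method: str


def fit_logistic(
    x: Sequence[float],
    y: Sequence[int],
    predictor_name: str = "x",
) -> LogisticFit:
    """Maximum-likelihood univariate logistic regression.

    Complete or quasi-complete separation (diverging coefficients with
    perfect classification) is detected and flagged rather than raised.
    Raises ``ValueError`` when the outcome has a single class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome y has a single class; logistic fit undefined")
    X = sm.add_constant(x)
    separation = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        params = np.asarray(res.params, dtype=float)
        fitted = np.asarray(res.fittedvalues, dtype=float)
        converged = bool(res.converged)
        se = float(np.asarray(res.bse, dtype=float)[1])
    except PerfectSeparationError:
        separation = True
        converged = False
        params = np.array([0.0, np.inf if np.corrcoef(x, y)[0, 1] >= 0 else -np.inf])
        fitted = np.where(y > 0.5, 1.0 - 1e-12, 1e-12)
        se = float("nan")
    if not separation:
        # quasi/complete separation: perfect classification with huge slope
        eta = params[0] + params[1] * x
        perfect = np.all((fitted > 1 - 1e-6) == (y > 0.5)) and np.all(
            (fitted < 1e-6) == (y < 0.5)
        )
        if np.max(np.abs(eta)) > 15 and perfect:
            separation = True
            logger.warning("separation detected for predictor %s", predictor_name)
    return LogisticFit(
        predictor_name=predictor_name,
        beta0=float(params[0]),
        beta1=float(params[1]),
        fitted_probabilities=fitted,
        converged=converged,
        separation_detected=separation,
        beta1_se=se,
    )


def hosmer_lemeshow(fit: LogisticFit, y: Sequence[int], g: int = 10) -> HLTestResult:
    """Hosmer–Lemeshow goodness-of-fit test on a logistic fit.

    Samples are sorted by fitted probability and cut at the g-quantiles
    of the fitted values; tied fitted values stay in one bin, so fewer
    than ``g`` bins can result. Bins with zero expected events or
    non-events are merged with their neighbor (recorded in the bin
    table). df = (number of bins) - 2.
    """
    p = np.asarray(fit.fitted_probabilities, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("y must match the fitted probabilities in length")
    n = len(y)
    if n < g:
        raise ValueError(f"need at least g={g} samples, got {n}")
    # quantile breaks on fitted probabilities, ties inseparable
    breaks = np.unique(np.quantile(p, np.linspace(0, 1, g + 1)[1:-1]))
    bin_idx = np.searchsorted(breaks, p, side="right")
    rows = []
    for b in np.unique(bin_idx):
        mask = bin_idx == b
        rows.append(
            {
                "n": int(mask.sum()),
                "observed_events": float(y[mask].sum()),
                "expected_events": float(p[mask].sum()),
                "observed_nonevents": float((1 - y[mask]).sum()),
                "expected_nonevents": float((1 - p[mask]).sum()),
                "merged": False,
            }
        )
    # merge bins with degenerate expectations into their neighbor
    i = 0
    while len(rows) > 1 and i < len(rows):
        if rows[i]["expected_events"] < 1e-12 or rows[i]["expected_nonevents"] < 1e-12:
            j = i - 1 if i > 0 else i + 1
            for key in ("n", "observed_events", "expected_events",
                        "observed_nonevents", "expected_nonevents"):
                rows[j][key] += rows[i][key]
            rows[j]["merged"] = True
            del rows[i]
            i = 0
        else:
            i += 1
    table = pd.DataFrame(rows)
    g_eff = len(rows)
    chi2 = float(
        (
            (table["observed_events"] - table["expected_events"]) ** 2
            / table["expected_events"]
            + (table["observed_nonevents"] - table["expected_nonevents"]) ** 2
            / table["expected_nonevents"]
        ).sum()
    )
    df = max(g_eff - 2, 1)
    p_value = float(sps.chi2.sf(chi2, df))
    return HLTestResult(g=g_eff, chi2=chi2, df=df, p_value=p_value, bin_table=table)


def compare_predictors(
    tcw: pd.DataFrame,
    labels: pd.DataFrame,
    g: int = 10,
) -> dict:
    """Compare TCW count vs total count as predictors of benefit.

    ``tcw`` is indexed by sample_id with columns ``tcw_count`` and
    ``total_count``; ``labels`` is indexed by sample_id with a
    ``benefit`` column in {DCB, NDB, NA}. NA samples are excluded with
    a logged count. For each predictor the report carries the logistic
    fit, the Hosmer–Lemeshow p-value, DCB/NDB group means and the
    fold change (DCB mean / NDB mean).
    """
    joined = tcw.join(labels, how="inner")
    if joined.empty:
        raise ValueError("no samples shared between the TCW table and the labels")
    n_na = int((joined["benefit"] == "NA").sum() + joined["benefit"].isna().sum())
    if n_na:
        logger.info("excluding %d sample(s) with NA benefit", n_na)
    joined = joined[joined["benefit"].isin(["DCB", "NDB"])]
    y = (joined["benefit"] == "DCB").to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both DCB and NDB samples after joining")
    report: dict = {
        "n_samples": int(len(joined)),
        "n_dcb": int(y.sum()),
        "n_ndb": int(len(y) - y.sum()),
        "n_excluded_na": n_na,
        "predictors": {},
    }
    for col in ("tcw_count", "total_count"):
        x = joined[col].to_numpy(dtype=float)
        fit = fit_logistic(x, y, predictor_name=col)
        hl = (
            hosmer_lemeshow(fit, y, g=g)
            if fit.converged and not fit.separation_detected
            else None
        )
        dcb_mean = float(x[y == 1].mean())
        ndb_mean = float(x[y == 0].mean())
        cohort_mean = float(x.mean())
        above = x > cohort_mean
        report["predictors"][col] = {
            "beta0": fit.beta0,
            "beta1": fit.beta1,
            "beta1_se": fit.beta1_se,
            "separation_detected": fit.separation_detected,
            "hl_chi2": hl.chi2 if hl else float("nan"),
            "hl_df": hl.df if hl else 0,
            "hl_p_value": hl.p_value if hl else float("nan"),
            "dcb_mean": dcb_mean,
            "ndb_mean": ndb_mean,
            "fold_change": dcb_mean / ndb_mean if ndb_mean else float("inf"),
            "cohort_mean": cohort_mean,
            "n_above_cohort_mean": int(above.sum()),
            "n_above_mean_with_dcb": int((above & (y == 1)).sum()),
        }
    return report


def quartile_groups(expression: pd.Series) -> pd.DataFrame:
    """Assign UP/DOWN/MID groups by expression quartiles.

    UP = strictly above the third quartile, DOWN = strictly below the
    first quartile, remainder MID. Quartiles use the linear-interpolation
    convention, so boundary membership depends on it.
    """
    values = expression.astype(float)
    if len(values) < 4:
        raise ValueError("quartile grouping needs at least 4 samples")
    q1, q3 = np.quantile(values.to_numpy(), [0.25, 0.75])
    group = pd.Series("MID", index=values.index, name="group")
    group[values > q3] = "UP"
    group[values < q1] = "DOWN"
    sizes = group.value_counts()
    if sizes.get("UP", 0) == 0 or sizes.get("DOWN", 0) == 0:
        warnings.warn("heavy ties left an empty UP or DOWN group", stacklevel=2)
    return group.to_frame()


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "auto",
) -> GroupCompareResult:
    """Two-group comparison: Student's t or Wilcoxon rank-sum.

    ``auto`` applies the convention that preprocessed expression data
    are approximately normal (t-test) while mutation counts are not
    (Wilcoxon): integer-valued inputs are treated as counts. The method
    actually used is recorded in the result.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        count_like = np.all(a == np.round(a)) and np.all(b == np.round(b))
        method = "wilcoxon" if count_like else "t"
    if method == "t":
        if np.var(a) == 0 and np.var(b) == 0 and a[0] == b[0]:
            warnings.warn("identical zero-variance groups; p set to 1", stacklevel=2)
            return GroupCompareResult(statistic=0.0, p_value=1.0, method="t")
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    elif method == "wilcoxon":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupCompareResult(statistic=float(stat), p_value=float(p), method=method)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, monotone, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def immune_score(
    expression: pd.DataFrame, gene_set: Sequence[str]
) -> pd.Series:
    """Per-sample mean log2 expression over an immune gene set.

    ``expression`` is genes x samples on the log2 scale. Genes of the
    set absent from the matrix are reported and skipped; an empty
    intersection raises.
    """
    present = [g for g in gene_set if g in expression.index]
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValueError("no gene of the set is present in the expression matrix")
    if missing:
        logger.info("immune_score: %d gene(s) missing from matrix: %s",
                    len(missing), ", ".join(missing[:10]))
    score = expression.loc[present].mean(axis=0)
    score.name = "immune_score"
    return score


def exposure_score_association(
    exposures: Sequence[float], score: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation between signature exposure and a score.

    Returns (rho, p). Constant input yields (nan, nan) with a warning.
    """
    exposures = np.asarray(exposures, dtype=float)
    score = np.asarray(score, dtype=float)
    if exposures.size < 10:
        raise ValueError("association requires at least 10 samples")
    if np.ptp(exposures) == 0 or np.ptp(score) == 0:
        warnings.warn("constant exposure or score; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(exposures, score)
    return float(rho), float(p)
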