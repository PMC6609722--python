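"""Per-metabolite longitudinal statistics.

Random-intercept mixed-model scans for drug-exposure effects (baseline vs a
treatment week) and for metabolite-symptom association over all visits,
Benjamini-Hochberg FDR control, and a two-step time-course regression that
separates responder and nonresponder trajectories (global polynomial fit,
then backward stepwise selection of group-difference terms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .preprocess import ProcessedMatrix
from .synthetic import TIME_POINTS

__all__ = [
    "DEFAULT_RATIOS",
    "MixedFit",
    "TimeCourseResult",
    "bh_adjust",
    "fit_random_intercept",
    "ratio_features",
    "exposure_scan",
    "symptom_association_scan",
    "timecourse_two_step",
]

#: Metabolite ratios analysed alongside single metabolites: serotonin
#: turnover (5HIAA/5HT), the indole shift (I3AA/TRP), catecholamine turnover
#: (MHPG/TYR), purine-pathway ratios, and the phenolic acid shift.
DEFAULT_RATIOS = [
    ("5HIAA", "5HT"),
    ("I3AA", "TRP"),
    ("MHPG", "TYR"),
    ("PXAN", "XAN"),
    ("URIC", "XAN"),
    ("XAN", "XANTH"),
    ("4HPAC", "TYR"),
]

ASSOCIATION_COLUMNS = [
    "feature_id", "effect", "standard_error", "statistic", "p_value", "q_value", "model_tag",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), original order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, _, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        dropped = [X.columns[i] for i in piv[rank:]]
        raise ValidationError(f"design matrix is singular; collinear columns: {dropped}")


@dataclass
class MixedFit:
    """Random-intercept mixed model fit (REML) with Wald z inference."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    var_subject: float
    var_resid: float
    converged: bool
    result: object | None = field(default=None, repr=False)


def fit_random_intercept(outcome, fixed_design: pd.DataFrame, subject_ids) -> MixedFit:
    """Fit outcome ~ fixed_design with a per-subject random intercept (REML).

    ``fixed_design`` must include any intercept column the caller wants.
    Degenerate outcomes with zero variance return a closed-form fit with all
    slopes and variance components zero.
    """
    y = np.asarray(outcome, dtype=float)
    groups = np.asarray(subject_ids)
    if len(np.unique(groups)) < 2:
        raise ValidationError("need at least 2 subjects")
    _check_full_rank(fixed_design)
    if np.ptp(y) == 0.0:
        params = pd.Series(0.0, index=fixed_design.columns)
        if "const" in fixed_design.columns:
            params["const"] = y[0]
        nan = pd.Series(np.nan, index=fixed_design.columns)
        return MixedFit(params=params, bse=nan, pvalues=nan,
                        var_subject=0.0, var_resid=0.0, converged=True)
    model = MixedLM(y, fixed_design, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    k = fixed_design.shape[1]
    return MixedFit(
        params=result.params.iloc[:k],
        bse=result.bse.iloc[:k],
        pvalues=result.pvalues.iloc[:k],
        var_subject=float(np.asarray(result.cov_re)[0, 0]),
        var_resid=float(result.scale),
        converged=bool(result.converged),
        result=result,
    )


def _sex_numeric(sex: pd.Series) -> pd.Series:
    if sex.dtype == object or str(sex.dtype) == "category":
        return (sex.astype(str) == "F").astype(float)
    return sex.astype(float)


def ratio_features(
    processed: dict[str, ProcessedMatrix],
    ratios: list[tuple[str, str]],
    time_points: tuple[str, ...] = TIME_POINTS,
) -> dict[str, dict[str, pd.Series]]:
    """Standardized log2-ratio features per time point.

    A ratio is the difference of log2 abundances (numerator minus
    denominator), computed before unit-variance scaling, then centered and
    scaled by constants pooled over the requested time points.  Ratios whose
    members are absent from the processed panel are skipped silently.
    """
    out: dict[str, dict[str, pd.Series]] = {}
    cols = set(processed[time_points[0]].log2_values.columns)
    for num, den in ratios:
        if num not in cols or den not in cols:
            continue
        name = f"{num}/{den}"
        raw = {tp: processed[tp].log2_values[num] - processed[tp].log2_values[den]
               for tp in time_points}
        pooled = pd.concat(raw.values())
        mu, sd = pooled.mean(), pooled.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        out[name] = {tp: (raw[tp] - mu) / sd for tp in time_points}
    return out


def _scan_features(
    processed: dict[str, ProcessedMatrix],
    ratios: list[tuple[str, str]] | None,
    time_points: tuple[str, ...],
):
    """Yield (feature_id, {tp: Series}) for metabolites then ratios."""
    for m in processed[time_points[0]].values.columns:
        yield m, {tp: processed[tp].values[m] for tp in time_points}
    if ratios:
        for name, series in ratio_features(processed, ratios, time_points).items():
            yield name, series


def exposure_scan(
    processed: dict[str, ProcessedMatrix],
    clinical: pd.DataFrame,
    week: int,
    ratios: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Drug-exposure scan: baseline vs week-4 or week-8 abundance.

    Per feature, fits a random-intercept mixed model of the (standardized)
    value on a time-point indicator plus age, sex, and baseline HRSD-17; the
    indicator coefficient is the exposure effect in pooled-SD units.
    Benjamini-Hochberg q-values are appended across features.
    """
    if week not in (4, 8):
        raise ValidationError("week must be 4 or 8")
    tw = f"t{week}"
    subjects = processed["t0"].subjects
    if processed[tw].subjects != subjects:
        raise ValidationError("baseline and target-week matrices must share subjects")
    base = pd.DataFrame(
        {
            "age": clinical.loc[subjects, "age"].to_numpy(dtype=float),
            "sex": _sex_numeric(clinical.loc[subjects, "sex"]).to_numpy(),
            "hrsd_baseline": clinical.loc[subjects, "hrsd_t0"].to_numpy(dtype=float),
        },
        index=subjects,
    )
    design = pd.concat([base.assign(week=0.0), base.assign(week=1.0)], axis=0)
    design.insert(0, "const", 1.0)
    design = design[["const", "week", "age", "sex", "hrsd_baseline"]]
    groups = np.concatenate([subjects, subjects])

    rows = []
    for fid, series in _scan_features(processed, ratios, ("t0", tw)):
        y = np.concatenate([series["t0"].to_numpy(), series[tw].to_numpy()])
        try:
            fit = fit_random_intercept(y, design, groups)
            rows.append((fid, fit.params["week"], fit.bse["week"],
                         fit.params["week"] / fit.bse["week"] if fit.bse["week"] > 0 else np.nan,
                         fit.pvalues["week"], f"exposure_week{week}"))
        except (ValidationError, np.linalg.LinAlgError):
            rows.append((fid, np.nan, np.nan, np.nan, np.nan, f"exposure_week{week}:failed"))
    return _finish_table(rows)


def symptom_association_scan(
    processed: dict[str, ProcessedMatrix],
    clinical: pd.DataFrame,
    ratios: list[tuple[str, str]] | None = None,
    regressor: str = "hrsd",
) -> pd.DataFrame:
    """Metabolite-symptom scan over all three visits.

    Per feature, fits a random-intercept model of the value on the
    time-varying HRSD-17 score (or, with ``regressor='change'``, its change
    from baseline) plus age and sex; reports the HRSD coefficient.  If the
    symptom regressor has no variance the feature is returned as NA with a
    ``degenerate`` tag.
    """
    if regressor not in ("hrsd", "change"):
        raise ValidationError("regressor must be 'hrsd' or 'change'")
    subjects = processed["t0"].subjects
    hrsd = {tp: clinical.loc[subjects, f"hrsd_{tp}"].to_numpy(dtype=float) for tp in TIME_POINTS}
    if regressor == "change":
        hrsd = {tp: hrsd[tp] - hrsd["t0"] for tp in TIME_POINTS}
    age = clinical.loc[subjects, "age"].to_numpy(dtype=float)
    sex = _sex_numeric(clinical.loc[subjects, "sex"]).to_numpy()

    hr = np.concatenate([hrsd[tp] for tp in TIME_POINTS])
    design = pd.DataFrame(
        {
            "const": 1.0,
            "hrsd": hr,
            "age": np.tile(age, 3),
            "sex": np.tile(sex, 3),
        }
    )
    groups = np.tile(np.asarray(subjects), 3)
    degenerate = np.ptp(hr) == 0.0

    rows = []
    for fid, series in _scan_features(processed, ratios, TIME_POINTS):
        if degenerate:
            rows.append((fid, np.nan, np.nan, np.nan, np.nan, "symptom:degenerate"))
            continue
        y = np.concatenate([series[tp].to_numpy() for tp in TIME_POINTS])
        try:
            fit = fit_random_intercept(y, design, groups)
            rows.append((fid, fit.params["hrsd"], fit.bse["hrsd"],
                         fit.params["hrsd"] / fit.bse["hrsd"] if fit.bse["hrsd"] > 0 else np.nan,
                         fit.pvalues["hrsd"], f"symptom_{regressor}"))
        except (ValidationError, np.linalg.LinAlgError):
            rows.append((fid, np.nan, np.nan, np.nan, np.nan, f"symptom_{regressor}:failed"))
    if degenerate:
        warnings.warn("symptom regressor has zero variance; returning NA coefficients")
    return _finish_table(rows)


def _finish_table(rows) -> pd.DataFrame:
    table = pd.DataFrame(rows, columns=[c for c in ASSOCIATION_COLUMNS if c != "q_value"])
    ok = table["p_value"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_adjust(table.loc[ok, "p_value"].to_numpy())
    table.insert(5, "q_value", q)
    return table


@dataclass
class TimeCourseResult:
    """Two-step time-course screen: global fits plus surviving group terms."""

    table: pd.DataFrame  # metabolite, global_fit_p, q_value, selected, r_squared
    group_difference_terms: dict[str, list[tuple[str, float, float]]]
    alpha: float
    fdr: float


def timecourse_two_step(
    processed: dict[str, ProcessedMatrix],
    groups: pd.Series,
    degree: int = 2,
    alpha: float = 0.05,
    fdr: float = 0.05,
) -> TimeCourseResult:
    """Two-step screen for group-divergent metabolite time courses.

    Step 1 fits, per metabolite, a least-squares regression of the value on
    polynomial time terms (degree <= 2 with three visits), a group dummy and
    group x time interactions; the global Wald F-test of all non-intercept
    terms (with subject-clustered covariance, since each subject contributes
    three visits) is FDR-adjusted and metabolites passing ``fdr`` are flagged
    selected.  Step 2 runs backward stepwise elimination at ``alpha`` on the
    selected metabolites and reports the surviving group-difference terms.
    """
    n_tp = len(TIME_POINTS)
    if degree >= n_tp:
        raise ValidationError(f"degree must be < number of time points ({n_tp})")
    subjects = processed["t0"].subjects
    g = groups.loc[subjects].astype(float).to_numpy()
    for val in (0.0, 1.0):
        if (g == val).sum() < 5:
            raise ValidationError("each group needs at least 5 subjects")

    t = np.concatenate([np.full(len(subjects), WEEK_CODE[tp]) for tp in TIME_POINTS])
    gg = np.tile(g, n_tp)
    cols = {"const": np.ones_like(t)}
    for d in range(1, degree + 1):
        cols["t" if d == 1 else f"t{d}"] = t**d
    cols["group"] = gg
    for d in range(1, degree + 1):
        cols["group:t" if d == 1 else f"group:t{d}"] = gg * t**d
    design = pd.DataFrame(cols)
    cluster = np.tile(np.asarray(subjects), n_tp)
    group_terms = [c for c in design.columns if c.startswith("group")]

    rows, survivors = [], {}
    for m in processed["t0"].values.columns:
        y = np.concatenate([processed[tp].values[m].to_numpy() for tp in TIME_POINTS])
        if np.ptp(y) == 0.0:
            rows.append((m, 1.0, np.nan, 0.0))
            continue
        res = _cluster_ols(y, design, cluster)
        terms = [c for c in design.columns if c != "const"]
        wald = res.wald_test(_restriction(design.columns, terms), use_f=True, scalar=True)
        # denominator df = clusters - 1, the standard choice for
        # cluster-robust Wald F (df_resid would be anti-conservative)
        n_clusters = len(np.unique(cluster))
        p_global = float(stats.f.sf(float(wald.statistic), len(terms), n_clusters - 1))
        rows.append((m, p_global, res.rsquared, np.nan))

    table = pd.DataFrame(rows, columns=["metabolite", "global_fit_p", "r_squared", "_pad"])
    table = table.drop(columns="_pad")
    table["q_value"] = bh_adjust(table["global_fit_p"].to_numpy())
    table["selected"] = table["q_value"] <= fdr

    for m in table.loc[table["selected"], "metabolite"]:
        y = np.concatenate([processed[tp].values[m].to_numpy() for tp in TIME_POINTS])
        kept = [c for c in design.columns if c != "const"]
        while kept:
            res = _cluster_ols(y, design[["const"] + kept], cluster)
            pvals = res.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] <= alpha:
                break
            kept.remove(worst)
        res = _cluster_ols(y, design[["const"] + kept], cluster)
        survivors[m] = [
            (c, float(res.params[c]), float(res.pvalues[c])) for c in kept if c in group_terms
        ]
    table = table[["metabolite", "global_fit_p", "q_value", "selected", "r_squared"]]
    return TimeCourseResult(table=table, group_difference_terms=survivors, alpha=alpha, fdr=fdr)


WEEK_CODE = {"t0": 0.0, "t4": 1.0, "t8": 2.0}


def _cluster_ols(y, X: pd.DataFrame, cluster):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": cluster})


def _restriction(columns, terms) -> np.ndarray:
    R = np.zeros((len(terms), len(columns)))
    for i, term in enumerate(terms):
        R[i, list(columns).index(term)] = 1.0
    return R
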