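"""Preprocessing: missingness QC, kNN imputation, log2/unit-variance scaling,
and HRSD-17 outcome labeling.

The pipeline order is fixed: metabolites with too many missing values are
dropped, remaining gaps are filled by k-nearest-neighbour imputation, then
abundances are log2 transformed and scaled to unit variance per metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .exceptions import ValidationError
from .synthetic import TIME_POINTS, CohortDataset

__all__ = [
    "ProcessedMatrix",
    "ResponseLabel",
    "qc_missingness",
    "knn_impute",
    "log2_scale",
    "classify_response",
    "label_cohort",
    "preprocess_cohort",
]


@dataclass
class ProcessedMatrix:
    """A complete subjects x metabolites matrix on the analysis scale.

    ``values`` holds log2-transformed, per-metabolite unit-variance-scaled
    (and, by default, centered) abundances.  ``log2_values`` keeps the log2
    matrix before scaling — metabolite ratio traits are differences of log2
    values, so they are built from this frame.  ``transform_log`` records the
    steps applied.
    """

    values: pd.DataFrame
    log2_values: pd.DataFrame
    transform_log: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ResponseLabel:
    subject_id: str
    responder: bool
    remitter: bool
    complete_nonresponder: bool
    pct_reduction: float


def qc_missingness(
    abundances: pd.DataFrame, threshold: float = 0.20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop metabolites with missing fraction strictly above ``threshold``.

    Returns the filtered matrix and a per-metabolite report with columns
    ``missing_fraction`` and ``retained``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must be in (0, 1]")
    frac = abundances.isna().mean(axis=0)
    retained = frac <= threshold
    if not retained.any():
        raise ValidationError("all metabolites exceed the missingness threshold")
    report = pd.DataFrame({"missing_fraction": frac, "retained": retained})
    return abundances.loc[:, retained], report


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing cells with the average over the k nearest subjects.

    Distances are Euclidean over mutually observed entries of per-metabolite
    standardized columns, rescaled by the fraction of observed coordinates;
    a missing cell becomes the mean of the metabolite's values among the k
    nearest subjects that observed it.  Observed cells are returned
    unchanged.  Because imputation averages standardized values and
    standardization is affine, imputing on the standardized scale and mapping
    back is exactly neighbour-mean imputation on the raw scale.
    """
    n = len(matrix)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of subjects ({n})")
    all_missing_cols = matrix.columns[matrix.isna().all(axis=0)]
    if len(all_missing_cols):
        raise ValidationError(
            f"metabolites with no observed values: {list(all_missing_cols)}"
        )
    all_missing_rows = matrix.index[matrix.isna().all(axis=1)]
    if len(all_missing_rows):
        raise ValidationError(
            f"subjects with all metabolites missing: {list(all_missing_rows)}"
        )
    if not matrix.isna().any().any():
        return matrix.copy()

    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1).replace(0.0, 1.0).fillna(1.0)
    standardized = (matrix - mu) / sd
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(standardized.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=matrix.index, columns=matrix.columns) * sd + mu
    return out.where(matrix.isna(), matrix)


def log2_scale(matrix: pd.DataFrame, center: bool = True) -> ProcessedMatrix:
    """log2 transform then scale each metabolite to unit sample variance.

    Uses the n-1 (sample) standard deviation.  Raises on non-positive
    abundances (naming the offending cell) and on zero-variance metabolites
    (naming the column).
    """
    arr = matrix.to_numpy(dtype=float)
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ValidationError(
            f"missing value at subject {matrix.index[i]!r}, metabolite {matrix.columns[j]!r}; "
            "impute before log2_scale"
        )
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValidationError(
            f"non-positive abundance at subject {matrix.index[i]!r}, "
            f"metabolite {matrix.columns[j]!r}"
        )
    log2 = pd.DataFrame(np.log2(arr), index=matrix.index, columns=matrix.columns)
    sd = log2.std(axis=0, ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()]
    if len(dead):
        raise ValidationError(f"zero-variance metabolites after log2: {list(dead)}")
    values = (log2 - log2.mean(axis=0)) / sd if center else log2 / sd
    return ProcessedMatrix(
        values=values,
        log2_values=log2,
        transform_log={"log2": True, "center": bool(center), "scale": "unit_variance_n_minus_1"},
    )


def classify_response(
    hrsd_baseline: float, hrsd_exit: float, subject_id: str = ""
) -> ResponseLabel:
    """Outcome labels from baseline and exit HRSD-17 scores.

    Responder: at least 50% reduction; remitter: exit score of 7 or less;
    complete non-responder: less than 30% reduction.  The labels are computed
    independently (a responder can also be a remitter).
    """
    if hrsd_baseline <= 0:
        raise ValidationError("baseline HRSD must be positive")
    if hrsd_exit < 0:
        raise ValidationError("exit HRSD must be non-negative")
    pct = 100.0 * (hrsd_baseline - hrsd_exit) / hrsd_baseline
    return ResponseLabel(
        subject_id=subject_id,
        responder=pct >= 50.0,
        remitter=hrsd_exit <= 7,
        complete_nonresponder=pct < 30.0,
        pct_reduction=pct,
    )


def label_cohort(clinical: pd.DataFrame, exit_col: str = "hrsd_t8") -> pd.DataFrame:
    """classify_response applied to every subject of a clinical table."""
    rows = [
        classify_response(r["hrsd_t0"], r[exit_col], subject_id=str(idx))
        for idx, r in clinical.iterrows()
    ]
    return pd.DataFrame(
        [(l.subject_id, l.responder, l.remitter, l.complete_nonresponder, l.pct_reduction) for l in rows],
        columns=["subject_id", "responder", "remitter", "complete_nonresponder", "pct_reduction"],
    ).set_index("subject_id")


def preprocess_cohort(
    dataset: CohortDataset,
    threshold: float = 0.20,
    k: int = 10,
    center: bool = True,
    pool_scaling: bool = True,
) -> dict[str, ProcessedMatrix]:
    """QC -> impute -> log2/scale, per time point.

    Imputation runs within each visit independently (no pooling across
    visits).  Metabolites must survive the missingness filter at every visit
    to stay in the panel, so the processed matrices remain aligned.

    With ``pool_scaling`` (the default) the centering/scaling constants are
    estimated once from the three visits pooled and applied to each visit,
    so between-visit mean differences — the drug-exposure signal the
    longitudinal scans estimate — survive standardization.  With
    ``pool_scaling=False`` each visit is standardized on its own, which
    removes visit-level mean shifts.
    """
    retained = None
    for tp in TIME_POINTS:
        _, report = qc_missingness(dataset.abundances[tp], threshold=threshold)
        keep = set(report.index[report["retained"]])
        retained = keep if retained is None else retained & keep
    keep_cols = [m for m in dataset.abundances["t0"].columns if m in retained]
    if not keep_cols:
        raise ValidationError("no metabolite survived missingness QC at all time points")
    complete = {}
    for tp in TIME_POINTS:
        filtered = dataset.abundances[tp].loc[:, keep_cols]
        complete[tp] = knn_impute(filtered, k=k)

    out = {}
    if pool_scaling:
        log2_frames = {}
        for tp in TIME_POINTS:
            arr = complete[tp].to_numpy(dtype=float)
            if (arr <= 0).any():
                raise ValidationError(f"non-positive abundance at time point {tp}")
            log2_frames[tp] = pd.DataFrame(
                np.log2(arr), index=complete[tp].index, columns=keep_cols
            )
        pooled = pd.concat([log2_frames[tp] for tp in TIME_POINTS], axis=0)
        mu = pooled.mean(axis=0)
        sd = pooled.std(axis=0, ddof=1)
        dead = sd.index[(sd == 0) | sd.isna()]
        if len(dead):
            raise ValidationError(f"zero-variance metabolites after log2: {list(dead)}")
        for tp in TIME_POINTS:
            values = (log2_frames[tp] - mu) / sd if center else log2_frames[tp] / sd
            out[tp] = ProcessedMatrix(
                values=values,
                log2_values=log2_frames[tp],
                transform_log={
                    "log2": True,
                    "center": bool(center),
                    "scale": "pooled_unit_variance_n_minus_1",
                    "missing_threshold": threshold,
                    "knn_k": k,
                    "time_point": tp,
                },
            )
    else:
        for tp in TIME_POINTS:
            pm = log2_scale(complete[tp], center=center)
            pm.transform_log.update(
                {"missing_threshold": threshold, "knn_k": k, "time_point": tp}
            )
            out[tp] = pm
    return out
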