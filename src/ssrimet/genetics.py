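"""Variant QC and covariate-adjusted association scans for metabolite ratio traits.

Hard genotype dosages (0/1/2, with missing) are filtered on call rate, minor
allele frequency and an exact Hardy-Weinberg test; population structure is
summarized by principal components of the standardized dosage matrix; and
standardized log-ratio traits of interacting metabolite pairs are scanned
for additive genetic association adjusting for age, sex, principal
components and optionally the symptom score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import gammaln

from .exceptions import ValidationError
from .preprocess import ProcessedMatrix

__all__ = [
    "GenotypeMatrix",
    "RatioTrait",
    "hwe_exact_test",
    "hwe_het_distribution",
    "variant_qc",
    "compute_pcs",
    "make_ratio_trait",
    "assoc_scan",
]


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix in {0, 1, 2} with NaN for missing."""

    dosages: pd.DataFrame
    variant_meta: pd.DataFrame
    _stats: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variant_meta.index):
            raise ValidationError("variant_meta index must match dosage columns")
        arr = self.dosages.to_numpy(dtype=float)
        observed = arr[~np.isnan(arr)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be 0, 1, 2 or missing")

    @property
    def n_subjects(self) -> int:
        return len(self.dosages)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_stats(self) -> pd.DataFrame:
        """Per-variant call_rate, maf (minor-allele oriented) and hwe_p."""
        if self._stats is not None:
            return self._stats
        arr = self.dosages.to_numpy(dtype=float)
        n = arr.shape[0]
        observed = ~np.isnan(arr)
        n_obs = observed.sum(axis=0)
        call_rate = n_obs / n
        with np.errstate(invalid="ignore"):
            alt_freq = np.nansum(arr, axis=0) / (2.0 * np.maximum(n_obs, 1))
        maf = np.minimum(alt_freq, 1.0 - alt_freq)
        maf[n_obs == 0] = 0.0
        hwe = np.empty(arr.shape[1])
        for j in range(arr.shape[1]):
            col = arr[observed[:, j], j]
            n_aa = int((col == 0).sum())
            n_het = int((col == 1).sum())
            n_bb = int((col == 2).sum())
            hwe[j] = hwe_exact_test(n_aa, n_het, n_bb) if (n_aa + n_het + n_bb) else np.nan
        self._stats = pd.DataFrame(
            {"call_rate": call_rate, "maf": maf, "hwe_p": hwe},
            index=self.dosages.columns,
        )
        return self._stats

    def subset_variants(self, keep: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages.loc[:, keep],
            variant_meta=self.variant_meta.loc[keep],
        )


@dataclass
class RatioTrait:
    """A standardized log-ratio of two metabolites, with outliers excluded."""

    values: pd.Series
    excluded_subjects: list[str]
    numerator: str
    denominator: str
    time_point: str | None = None

    @property
    def name(self) -> str:
        return f"{self.numerator}/{self.denominator}"


def hwe_het_distribution(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele counts.

    For ``n`` diploid individuals carrying ``n_minor`` copies of the minor
    allele, returns the attainable heterozygote counts (same parity as
    ``n_minor``) and their exact probabilities under Hardy-Weinberg
    equilibrium, computed in closed form with log-gamma arithmetic:

        P(h) = n! / (n_AA! h! n_aa!) * 2**h * n_minor! n_major! / (2n)!
    """
    if n < 1 or not 0 <= n_minor <= 2 * n:
        raise ValidationError("invalid allele configuration")
    n_major = 2 * n - n_minor
    h = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    n_aa = (n_minor - h) // 2  # minor homozygotes
    n_bb = (n_major - h) // 2
    logp = (
        gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(h + 1) - gammaln(n_bb + 1)
        + h * np.log(2.0)
        + gammaln(n_minor + 1) + gammaln(n_major + 1) - gammaln(2 * n + 1)
    )
    return h, np.exp(logp)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test conditional on allele counts.

    The p-value sums the probabilities of all heterozygote counts (with the
    observed allele counts) no more probable than the observed count.
    Monomorphic variants return 1.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValidationError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValidationError("total genotype count must be >= 1")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0
    hets, probs = hwe_het_distribution(n, n_minor)
    p_obs = probs[hets == n_Aa][0]
    # tolerance guards against ties lost to floating-point rounding
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def variant_qc(
    G: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    hwe_threshold: float = 1e-5,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants failing call-rate, MAF, or Hardy-Weinberg rules.

    Returns the filtered matrix and a report with per-variant stats, the
    per-rule failure flags, and per-rule / unique drop totals in
    ``report.attrs['summary']``.  An empty result is a warning, not an error.
    """
    stats = G.variant_stats().copy()
    stats["fail_call_rate"] = stats["call_rate"] < min_call_rate
    stats["fail_maf"] = stats["maf"] < min_maf
    stats["fail_hwe"] = stats["hwe_p"] < hwe_threshold
    stats["dropped"] = stats[["fail_call_rate", "fail_maf", "fail_hwe"]].any(axis=1)
    keep = list(stats.index[~stats["dropped"]])
    if not keep:
        import warnings

        warnings.warn("variant QC removed every variant")
    filtered = G.subset_variants(keep)
    stats.attrs["summary"] = {
        "n_input": G.n_variants,
        "n_retained": len(keep),
        "n_fail_call_rate": int(stats["fail_call_rate"].sum()),
        "n_fail_maf": int(stats["fail_maf"].sum()),
        "n_fail_hwe": int(stats["fail_hwe"].sum()),
        "n_dropped_unique": int(stats["dropped"].sum()),
    }
    return filtered, stats


def compute_pcs(G: GenotypeMatrix, k: int = 5) -> pd.DataFrame:
    """Principal component scores of the column-standardized dosage matrix.

    Missing dosages are mean-imputed per variant; zero-variance variants are
    ignored.  Scores are orthogonal and ordered by decreasing explained
    variance.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if k >= min(G.n_subjects, G.n_variants):
        raise ValidationError("k must be smaller than min(subjects, variants)")
    arr = G.dosages.to_numpy(dtype=float)
    mu = np.nanmean(arr, axis=0)
    arr = np.where(np.isnan(arr), mu, arr)
    sd = arr.std(axis=0, ddof=1)
    use = sd > 0
    Z = (arr[:, use] - mu[use]) / sd[use]
    Z = Z - Z.mean(axis=0)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * s[:k]
    return pd.DataFrame(scores, index=G.dosages.index, columns=[f"PC{i + 1}" for i in range(k)])


def make_ratio_trait(
    processed: ProcessedMatrix,
    numerator_id: str,
    denominator_id: str,
    sd_limit: float = 4.0,
    time_point: str | None = None,
) -> RatioTrait:
    """Standardized log2 ratio of two metabolites with outlier exclusion.

    ratio = log2(numerator) - log2(denominator) per subject, centered and
    scaled to unit variance; subjects beyond ``sd_limit`` standard deviations
    are excluded and the trait re-centered and re-scaled.
    """
    log2 = processed.log2_values
    for m in (numerator_id, denominator_id):
        if m not in log2.columns:
            raise ValidationError(f"metabolite {m!r} not in processed matrix")
    ratio = log2[numerator_id] - log2[denominator_id]
    sd = ratio.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValidationError(
            f"ratio {numerator_id}/{denominator_id} has zero variance"
        )
    z = (ratio - ratio.mean()) / sd
    excluded = list(z.index[z.abs() > sd_limit])
    kept = z.drop(index=excluded)
    sd2 = kept.std(ddof=1)
    if sd2 == 0 or np.isnan(sd2):
        raise ValidationError("ratio has zero variance after outlier exclusion")
    values = (kept - kept.mean()) / sd2
    return RatioTrait(
        values=values,
        excluded_subjects=[str(s) for s in excluded],
        numerator=numerator_id,
        denominator=denominator_id,
        time_point=time_point,
    )


def assoc_scan(
    trait: RatioTrait | pd.Series,
    G: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Additive association scan of a quantitative trait over all variants.

    Per variant, least-squares regression of the trait on dosage plus
    covariates; subjects with a missing dosage are dropped for that variant.
    Constant-dosage variants yield NA rows.  Returns one row per variant:
    variant_id, chrom, pos, beta, se, statistic, p_value, q_value, n.
    """
    values = trait.values if isinstance(trait, RatioTrait) else trait
    subjects = values.index.intersection(G.dosages.index)
    if len(subjects) < 3:
        raise ValidationError("too few subjects shared between trait and genotypes")
    y_all = values.loc[subjects].to_numpy(dtype=float)
    if covariates is not None:
        C = covariates.loc[subjects].to_numpy(dtype=float)
        full = np.column_stack([np.ones(len(subjects)), C])
        rank = np.linalg.matrix_rank(full)
        if rank < full.shape[1]:
            names = ["const"] + list(covariates.columns)
            _, _, piv = scipy.linalg.qr(full, mode="economic", pivoting=True)
            raise ValidationError(
                f"collinear covariates: {[names[i] for i in piv[rank:]]}"
            )
    else:
        C = np.empty((len(subjects), 0))

    dos = G.dosages.loc[subjects].to_numpy(dtype=float)
    meta = G.variant_meta
    rows = []
    for j, vid in enumerate(G.dosages.columns):
        d = dos[:, j]
        ok = ~np.isnan(d)
        n_used = int(ok.sum())
        chrom, pos = meta.loc[vid, "chrom"], meta.loc[vid, "pos"]
        if n_used < C.shape[1] + 3 or np.ptp(d[ok]) == 0.0:
            rows.append((vid, chrom, pos, np.nan, np.nan, np.nan, np.nan, n_used))
            continue
        X = np.column_stack([np.ones(n_used), d[ok], C[ok]])
        beta_hat, _, _, _ = np.linalg.lstsq(X, y_all[ok], rcond=None)
        resid = y_all[ok] - X @ beta_hat
        dof = n_used - X.shape[1]
        sigma2 = resid @ resid / dof
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        tstat = beta_hat[1] / se
        from scipy import stats as sps

        p = 2.0 * sps.t.sf(abs(tstat), dof)
        rows.append((vid, chrom, pos, beta_hat[1], se, tstat, p, n_used))
    table = pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "beta", "se", "statistic", "p_value", "n"],
    )
    ok = table["p_value"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        from .longitudinal import bh_adjust

        q[ok.to_numpy()] = bh_adjust(table.loc[ok, "p_value"].to_numpy())
    table.insert(7, "q_value", q)
    return table
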