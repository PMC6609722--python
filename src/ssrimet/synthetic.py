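"""Synthetic longitudinal pharmacometabolomics cohorts with known ground truth.

The generator emulates the statistical structure of an 8-week SSRI treatment
study: a panel of plasma metabolites measured at baseline, week 4 and week 8
on a few hundred depressed outpatients, HRSD-17 symptom scores with a
responder/nonresponder mixture, a sparse metabolite-metabolite partial
correlation structure organised in community blocks, optional
outcome-dependent (differential) edges, MCAR missingness, and biallelic
genotype dosages with planted effects on metabolite ratio traits.

Everything downstream (preprocessing, longitudinal scans, network inference,
genetic association) can therefore be tested against a known truth without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .panel import MetabolitePanel, default_panel, generic_panel

__all__ = [
    "TIME_POINTS",
    "WEEKS",
    "DEFAULT_HRSD_PARAMS",
    "DEFAULT_RESPONSE_RATE",
    "GroundTruth",
    "CohortDataset",
    "make_precision_matrix",
    "group_precision_matrices",
    "simulate_cohort",
    "inject_missing",
    "simulate_genotypes",
    "genetic_trait",
]

TIME_POINTS = ("t0", "t4", "t8")
WEEKS = {"t0": 0, "t4": 4, "t8": 8}

#: Observed response rate to citalopram/escitalopram after 8 weeks.
DEFAULT_RESPONSE_RATE = 0.693

#: HRSD-17 mean/sd per outcome group and visit, as reported for the cohort
#: the generator emulates (responders vs nonresponders at t0/t4/t8).
DEFAULT_HRSD_PARAMS = {
    "responder": {"t0": (21.86, 5.17), "t4": (10.10, 5.77), "t8": (5.79, 3.27)},
    "nonresponder": {"t0": (22.03, 4.28), "t4": (15.03, 6.58), "t8": (14.90, 4.15)},
}


@dataclass
class GroundTruth:
    """Planted generative structure for one synthetic cohort.

    precision_matrix is the baseline inverse covariance of the latent
    (log-scale, standardized) metabolite vector; community_labels assigns
    each metabolite to a block; exposure_effects holds the standardized mean
    shift added at week 4 and week 8; differential_edges lists
    (i, j, weight_low_group, weight_high_group) partial correlations that
    differ between the low- and high-outcome groups; genetic_effects lists
    (variant_index, trait_name, beta).
    """

    precision_matrix: np.ndarray
    community_labels: np.ndarray
    exposure_effects: dict[str, np.ndarray] = field(default_factory=dict)
    differential_edges: list[tuple[int, int, float, float]] = field(default_factory=list)
    genetic_effects: list[tuple[int, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        theta = np.asarray(self.precision_matrix, dtype=float)
        if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
            raise ConfigurationError("precision_matrix must be square")
        if not np.allclose(theta, theta.T, atol=1e-10):
            raise ConfigurationError("precision_matrix must be symmetric")
        if np.linalg.eigvalsh(theta).min() <= 0:
            raise ConfigurationError("precision_matrix must be positive definite")
        p = theta.shape[0]
        for i, j, *_ in self.differential_edges:
            if not (0 <= i < j < p):
                raise ConfigurationError(
                    f"differential edge ({i}, {j}) must satisfy 0 <= i < j < p={p}"
                )
        self.precision_matrix = theta
        self.community_labels = np.asarray(self.community_labels, dtype=int)

    @property
    def n_metabolites(self) -> int:
        return self.precision_matrix.shape[0]

    def partial_correlations(self) -> np.ndarray:
        """Planted baseline partial correlations implied by the precision matrix."""
        theta = self.precision_matrix
        d = np.sqrt(np.diag(theta))
        w = -theta / np.outer(d, d)
        np.fill_diagonal(w, 0.0)
        return w


@dataclass
class CohortDataset:
    """Longitudinal abundance matrices plus the clinical table.

    abundances maps time point -> subjects x metabolites DataFrame of
    positive raw abundances (NaN marks missing); clinical has one row per
    subject (age, sex, drug_arm, hrsd_t0/t4/t8, responder); latents keeps the
    generating standardized log-scale values for testability.
    """

    abundances: dict[str, pd.DataFrame]
    clinical: pd.DataFrame
    panel: MetabolitePanel
    latents: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        subj = None
        for tp in TIME_POINTS:
            if tp not in self.abundances:
                raise ConfigurationError(f"missing abundance matrix for time point {tp}")
            idx = list(self.abundances[tp].index)
            if subj is None:
                subj = idx
            elif idx != subj:
                raise ConfigurationError("subject ordering differs across time points")
        if list(self.clinical.index) != subj:
            raise ConfigurationError("clinical table subject ordering differs from abundances")

    @property
    def subjects(self) -> list:
        return list(self.clinical.index)

    @property
    def n_subjects(self) -> int:
        return len(self.clinical)


def _block_support(rng: np.random.Generator, nodes: np.ndarray, density: float) -> list[tuple[int, int]]:
    """Within-block edge support: a random cycle (connectivity) plus extras."""
    k = len(nodes)
    if k < 2 or density == 0.0:
        return []
    all_pairs = [(int(nodes[a]), int(nodes[b])) for a in range(k) for b in range(a + 1, k)]
    target = int(round(density * len(all_pairs)))
    if target == 0:
        return []
    edges: set[tuple[int, int]] = set()
    if k >= 3 and target >= k:
        order = rng.permutation(nodes)
        for a in range(k):
            i, j = int(order[a]), int(order[(a + 1) % k])
            edges.add((min(i, j), max(i, j)))
    remaining = [e for e in all_pairs if e not in edges]
    extra = target - len(edges)
    if extra > 0:
        pick = rng.choice(len(remaining), size=min(extra, len(remaining)), replace=False)
        edges.update(remaining[i] for i in np.atleast_1d(pick))
    return sorted(edges)


def make_precision_matrix(
    p: int,
    n_communities: int = 1,
    within_density: float = 0.3,
    edge_strength: float = 1.0,
    seed: int | None = None,
    between_density: float = 0.0,
    diagonal_margin: float = 0.5,
) -> GroundTruth:
    """Plant a block-structured sparse precision matrix.

    Metabolites are split into ``n_communities`` near-equal blocks.  Each
    block receives ``round(within_density * n_pairs)`` within-block edges of
    value ``-edge_strength`` (negative entries give positive partial
    correlations); whenever the budget allows, a random cycle through the
    block is laid down first so each community is connected.  Between-block
    pairs receive an edge independently with probability ``between_density``.
    The diagonal is set to ``diagonal_margin`` plus the absolute row sum,
    which makes the matrix strictly diagonally dominant and hence positive
    definite; a ridge is added in the (unreachable) event the smallest
    eigenvalue is still not positive.  With these defaults the planted
    partial correlations are roughly 1 / (node degree + margin), i.e. around
    0.2-0.4 at the default density.
    """
    if p < 2:
        raise ConfigurationError("p must be >= 2")
    if n_communities < 1:
        raise ConfigurationError("n_communities must be >= 1")
    if not 0.0 <= within_density <= 1.0:
        raise ConfigurationError("within_density must be in [0, 1]")
    if edge_strength <= 0:
        raise ConfigurationError("edge_strength must be positive")
    rng = np.random.default_rng(seed)

    blocks = np.array_split(np.arange(p), n_communities)
    labels = np.concatenate([np.full(len(block), c) for c, block in enumerate(blocks)])
    theta = np.zeros((p, p))
    for block in blocks:
        for i, j in _block_support(rng, block, within_density):
            theta[i, j] = theta[j, i] = -edge_strength
    if between_density > 0:
        for i in range(p):
            for j in range(i + 1, p):
                if labels[i] != labels[j] and rng.random() < between_density:
                    theta[i, j] = theta[j, i] = -edge_strength
    rowsum = np.abs(theta).sum(axis=1)
    theta[np.diag_indices(p)] = diagonal_margin + np.maximum(rowsum, edge_strength)
    mineig = np.linalg.eigvalsh(theta).min()
    if mineig <= 0:  # diagonally dominant construction cannot reach this
        theta[np.diag_indices(p)] += abs(mineig) + 1e-6
    return GroundTruth(precision_matrix=theta, community_labels=labels)


def group_precision_matrices(truth: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Low- and high-outcome-group precisions differing only at declared edges.

    Each differential edge (i, j, w_low, w_high) overwrites
    theta_ij = -w * sqrt(theta_ii * theta_jj) in the respective group's copy
    of the base precision; all other entries (including the diagonal) are
    bit-identical to the base matrix.
    """
    base = truth.precision_matrix
    low = base.copy()
    high = base.copy()
    for i, j, w_low, w_high in truth.differential_edges:
        scale = np.sqrt(base[i, i] * base[j, j])
        low[i, j] = low[j, i] = -w_low * scale
        high[i, j] = high[j, i] = -w_high * scale
    for name, theta in (("low", low), ("high", high)):
        if np.linalg.eigvalsh(theta).min() <= 0:
            raise ConfigurationError(
                f"{name}-group precision is not positive definite; "
                "reduce differential edge weights or increase the diagonal margin"
            )
    return low, high


def _draw_hrsd(rng: np.random.Generator, n: int, mean: float, sd: float, minimum: int = 0) -> np.ndarray:
    """Integer HRSD scores from a rounded normal, resampled until >= minimum."""
    out = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    bad = out < minimum
    while bad.any():
        out[bad] = np.rint(rng.normal(mean, sd, size=int(bad.sum()))).astype(int)
        bad = out < minimum
    return out


def simulate_cohort(
    n_subjects: int = 290,
    ground_truth: GroundTruth | None = None,
    response_rate: float = DEFAULT_RESPONSE_RATE,
    hrsd_params: dict | None = None,
    seed: int | None = None,
    rho: float = 0.6,
    subject_intercept_sd: float = 0.3,
    log2_location: float = 10.0,
    log2_scale: float = 1.0,
    hrsd_coupling: list[tuple[int, float]] | None = None,
    panel: MetabolitePanel | None = None,
) -> CohortDataset:
    """Simulate one longitudinal cohort from a planted ground truth.

    Baseline latent vectors are drawn from N(0, inverse(precision)); follow-up
    visits evolve by a stationary AR(1) carry-over (coefficient ``rho``) with
    fresh innovations from the same covariance, plus the per-visit
    standardized ``exposure_effects`` shift.  Latents map to positive raw
    abundances via 2**(location + scale * (latent + subject intercept)),
    where the intercept is a stable per-subject, per-metabolite level
    (sd ``subject_intercept_sd``) adding a visit-constant within-subject
    correlation component on top of the AR(1) carry-over.
    Responder labels are Bernoulli(response_rate); HRSD trajectories are drawn
    per group and visit from ``hrsd_params`` (rounded, floored at 0, baseline
    resampled until >= 14, the study inclusion rule).  Differential edges are
    realized by giving the low-outcome group (responders) and high-outcome
    group (nonresponders) precisions that differ only at the declared edges.

    ``hrsd_coupling`` optionally adds coef * zscore(HRSD_t) to the listed
    metabolite's latent at every visit, for testing the symptom scan.
    """
    if n_subjects < 10:
        raise ConfigurationError("n_subjects must be >= 10")
    if not 0.0 < response_rate < 1.0:
        raise ConfigurationError("response_rate must be in (0, 1)")
    if ground_truth is None:
        ground_truth = make_precision_matrix(31, n_communities=3, within_density=0.25, seed=seed)
    hrsd_params = DEFAULT_HRSD_PARAMS if hrsd_params is None else hrsd_params
    for grp in ("responder", "nonresponder"):
        if grp not in hrsd_params:
            raise ConfigurationError(f"hrsd_params missing group {grp!r}")
        for tp in TIME_POINTS:
            if tp not in hrsd_params[grp]:
                raise ConfigurationError(f"hrsd_params[{grp!r}] missing time point {tp!r}")

    rng = np.random.default_rng(seed)
    p = ground_truth.n_metabolites
    if panel is None:
        panel = default_panel() if p == 31 else generic_panel(p)
    if len(panel) != p:
        raise ConfigurationError("panel size does not match precision matrix")

    responder = rng.random(n_subjects) < response_rate
    prec_low, prec_high = group_precision_matrices(ground_truth)
    chol = {True: np.linalg.cholesky(np.linalg.inv(prec_low)),
            False: np.linalg.cholesky(np.linalg.inv(prec_high))}

    def innovations() -> np.ndarray:
        z = rng.standard_normal((n_subjects, p))
        out = np.empty_like(z)
        out[responder] = z[responder] @ chol[True].T
        out[~responder] = z[~responder] @ chol[False].T
        return out

    shifts = {
        tp: np.asarray(ground_truth.exposure_effects.get(tp, np.zeros(p)), dtype=float)
        for tp in TIME_POINTS
    }
    centered = {"t0": innovations()}
    centered["t4"] = rho * centered["t0"] + np.sqrt(1.0 - rho**2) * innovations()
    centered["t8"] = rho * centered["t4"] + np.sqrt(1.0 - rho**2) * innovations()
    latents = {tp: centered[tp] + shifts[tp] for tp in TIME_POINTS}

    hrsd = {}
    for tp in TIME_POINTS:
        scores = np.empty(n_subjects, dtype=int)
        minimum = 14 if tp == "t0" else 0
        for grp, mask in (("responder", responder), ("nonresponder", ~responder)):
            mean, sd = hrsd_params[grp][tp]
            scores[mask] = _draw_hrsd(rng, int(mask.sum()), mean, sd, minimum=minimum)
        hrsd[tp] = scores

    if hrsd_coupling:
        for idx, coef in hrsd_coupling:
            if not 0 <= idx < p:
                raise ConfigurationError(f"hrsd_coupling metabolite index {idx} out of range")
            for tp in TIME_POINTS:
                z = (hrsd[tp] - hrsd[tp].mean()) / max(hrsd[tp].std(), 1e-12)
                latents[tp][:, idx] = latents[tp][:, idx] + coef * z

    # stable per-subject, per-metabolite level differences (visit-constant)
    intercept = rng.normal(0.0, subject_intercept_sd, size=(n_subjects, p))
    subjects = [f"S{i + 1:04d}" for i in range(n_subjects)]
    abundances = {
        tp: pd.DataFrame(
            np.exp2(log2_location + log2_scale * (latents[tp] + intercept)),
            index=subjects,
            columns=panel.ids,
        )
        for tp in TIME_POINTS
    }

    clinical = pd.DataFrame(
        {
            "age": np.clip(rng.normal(39.8, 13.1, size=n_subjects), 18.0, 80.0).round(1),
            "sex": np.where(rng.random(n_subjects) < 0.66, "F", "M"),
            "drug_arm": np.where(rng.random(n_subjects) < 0.5, "citalopram", "escitalopram"),
            "hrsd_t0": hrsd["t0"],
            "hrsd_t4": hrsd["t4"],
            "hrsd_t8": hrsd["t8"],
            "responder": responder,
        },
        index=subjects,
    )
    return CohortDataset(abundances=abundances, clinical=clinical, panel=panel, latents=latents)


def inject_missing(dataset: CohortDataset, rate: float, seed: int | None = None) -> CohortDataset:
    """Set each abundance cell missing independently with probability ``rate`` (MCAR)."""
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    abundances = {}
    for tp in TIME_POINTS:
        df = dataset.abundances[tp].copy()
        if rate > 0:
            mask = rng.random(df.shape) < rate
            df = df.mask(mask)
        abundances[tp] = df
    return CohortDataset(
        abundances=abundances,
        clinical=dataset.clinical.copy(),
        panel=dataset.panel,
        latents=dataset.latents,
    )


def simulate_genotypes(
    n_subjects: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    causal: list[tuple[int, str, float]] | None = None,
    seed: int | None = None,
    missing_rate: float = 0.0,
    subjects: list[str] | None = None,
):
    """Biallelic dosages in {0,1,2} at Hardy-Weinberg proportions.

    Per-variant minor allele frequencies are uniform in ``maf_range``;
    dosages are Binomial(2, maf).  ``causal`` records planted
    (variant_index, trait_name, beta) effects; apply them to a phenotype with
    :func:`genetic_trait`.  ``missing_rate`` masks dosages MCAR so the
    call-rate QC rule can be exercised.
    """
    from .genetics import GenotypeMatrix

    low, high = maf_range
    if not (0.0 < low <= high <= 0.5):
        raise ConfigurationError("maf_range must satisfy 0 < low <= high <= 0.5")
    causal = causal or []
    for idx, _, _ in causal:
        if not 0 <= idx < n_variants:
            raise ConfigurationError(f"causal variant index {idx} out of range")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(low, high, size=n_variants)
    dosages = rng.binomial(2, maf, size=(n_subjects, n_variants)).astype(float)
    if missing_rate > 0:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan
    if subjects is None:
        subjects = [f"S{i + 1:04d}" for i in range(n_subjects)]
    ids = [f"rs{i + 1:06d}" for i in range(n_variants)]
    meta = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": np.repeat("1", n_variants),
            "pos": np.arange(1, n_variants + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "sim_maf": maf,
        }
    ).set_index("variant_id")
    G = GenotypeMatrix(dosages=pd.DataFrame(dosages, index=subjects, columns=ids), variant_meta=meta)
    return G, list(causal)


def genetic_trait(
    G,
    causal: list[tuple[int, str, float]],
    trait_name: str,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> pd.Series:
    """A quantitative trait = sum of planted additive effects + Gaussian noise.

    Missing dosages contribute their variant mean (the scan drops them
    per-variant anyway; this keeps the trait complete).
    """
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, size=G.n_subjects)
    for idx, name, beta in causal:
        if name != trait_name:
            continue
        dose = G.dosages.iloc[:, idx].to_numpy(dtype=float)
        dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
        values = values + beta * dose
    return pd.Series(values, index=G.dosages.index, name=trait_name)
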