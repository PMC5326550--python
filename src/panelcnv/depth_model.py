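"""Depth normalization and the negative-binomial emission model.

Read counts d_{i,j} at target i in sample j are modelled as

    d_{i,j} ~ NegBinom(mean = (c_{i,j}/2) * mu_i * mu_j, size = r_i)

where mu_i is the cross-sample median depth of target i, mu_j the median
per-sample scale factor, c the local copy number (2 = diploid) and r_i a
per-target dispersion (variance = mean + mean^2/r; r -> inf recovers
Poisson).  Normalization is strictly within one sequencing batch: the set
of samples run together is its own reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class DepthMatrix:
    """Integer read counts, targets x samples, for one normalization batch."""

    depths: np.ndarray
    target_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 2:
            raise ValueError("depths must be a 2-D targets x samples array")
        n_t, n_s = self.depths.shape
        if n_t < 1 or n_s < 1:
            raise ValueError("need at least one target and one sample")
        if len(self.target_ids) != n_t:
            raise ValueError("target_ids length does not match depth rows")
        if len(self.sample_ids) != n_s:
            raise ValueError("sample_ids length does not match depth columns")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample IDs")
        if len(set(self.target_ids)) != n_t:
            raise ValueError("duplicate target IDs")
        if np.any(self.depths < 0):
            raise ValueError("negative depths")

    @property
    def n_targets(self) -> int:
        return self.depths.shape[0]

    @property
    def n_samples(self) -> int:
        return self.depths.shape[1]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def reindex_targets(self, target_ids: list[str]) -> "DepthMatrix":
        """Reorder rows to ``target_ids``; error on any mismatch."""
        pos = {tid: k for k, tid in enumerate(self.target_ids)}
        missing = [tid for tid in target_ids if tid not in pos]
        extra = [tid for tid in self.target_ids if tid not in set(target_ids)]
        if missing or extra:
            raise ValueError(
                f"target IDs do not match panel: missing={missing[:5]} "
                f"extra={extra[:5]}"
            )
        order = [pos[tid] for tid in target_ids]
        return DepthMatrix(self.depths[order], list(target_ids), list(self.sample_ids))


@dataclass
class NormalizationFactors:
    mu_i: np.ndarray  # per-target central depth (reads)
    mu_j: np.ndarray  # per-sample scale factor (dimensionless)


@dataclass
class DispersionEstimates:
    r_i: np.ndarray  # per-target NB size parameter


def compute_target_medians(depths: DepthMatrix) -> np.ndarray:
    """mu_i: median depth of each target across the batch's samples.

    The median (not the mean) is used so that CNV-carrying samples in the
    batch do not shift the diploid reference level.
    """
    return np.median(depths.depths, axis=1)


def compute_sample_factors(depths: DepthMatrix, mu_i: np.ndarray) -> np.ndarray:
    """mu_j: per-sample median of d_{i,j}/mu_i over targets with mu_i > 0."""
    mu_i = np.asarray(mu_i, dtype=float)
    usable = mu_i > 0
    if not np.any(usable):
        raise ValueError("all targets have zero median depth; batch unusable")
    ratios = depths.depths[usable] / mu_i[usable, None]
    return np.median(ratios, axis=0)


def estimate_dispersion(
    depths: DepthMatrix,
    mu_i: np.ndarray,
    r_max: float = 1e8,
    default_r: float = 1e4,
    sample_factors: np.ndarray | None = None,
    robust: bool = False,
) -> DispersionEstimates:
    """Method-of-moments dispersion r_i = mu_i^2 / (Var_j[d_ij] - mu_i).

    Under-dispersed or degenerate targets (variance <= mean, zero median,
    or batches of one sample) fall back to the Poisson-like cap/default.
    The plain estimator uses the unbiased (n-1) sample variance of the raw
    counts.  When ``sample_factors`` is supplied the variance is taken on
    scale-corrected counts d_ij/mu_j (otherwise per-sample depth spread
    masquerades as target overdispersion), and ``robust=True`` swaps in a
    MAD-based variance so a CNV-carrying sample in the batch cannot
    deflate r at the very targets it affects.  The fitted emission model
    uses both corrections.
    """
    mu_i = np.asarray(mu_i, dtype=float)
    n = depths.n_targets
    if depths.n_samples < 2:
        return DispersionEstimates(np.full(n, default_r))
    d = depths.depths.astype(float)
    if sample_factors is not None:
        d = d / np.asarray(sample_factors, dtype=float)[None, :]
    if robust:
        med = np.median(d, axis=1, keepdims=True)
        mad = np.median(np.abs(d - med), axis=1)
        var = (1.4826 * mad) ** 2  # normal-consistent scale
    else:
        var = np.var(d, axis=1, ddof=1)
    r = np.full(n, r_max)
    ok = (mu_i > 0) & (var > mu_i)
    r[ok] = np.minimum(mu_i[ok] ** 2 / (var[ok] - mu_i[ok]), r_max)
    return DispersionEstimates(r)


def _lgamma_ratio_minus_dlogr(d: np.ndarray, r: np.ndarray) -> np.ndarray:
    """lgamma(d+r) - lgamma(r) - d*log(r), numerically stable for r >> d.

    Direct lgamma differencing loses ~|lgamma(r)|*eps absolute precision
    (about 2e-7 at r = 1e8), which would swamp the tiny Poisson-limit
    corrections; for large r the quantity equals sum_{k<d} log1p(k/r),
    expanded here in exact power sums with error below d^5/(5 r^4).
    """
    from scipy.special import gammaln

    d = d.astype(float)
    use_series = (r > 1e6) & (d < 1e-3 * r)
    with np.errstate(invalid="ignore"):
        direct = gammaln(d + r) - gammaln(r) - d * np.log(r)
    s1 = d * (d - 1) / 2
    s2 = (d - 1) * d * (2 * d - 1) / 6
    s3 = s1**2
    series = s1 / r - s2 / (2 * r**2) + s3 / (3 * r**3)
    return np.where(use_series, series, direct)


def nb_log_pmf(d, mean, r):
    """Negative-binomial log pmf in mean/size parameterization.

    Variance = mean + mean^2/r; as r -> inf this converges to
    Poisson(mean) with log-pmf deviation ((d-mean)^2 - d)/(2r) + O(1/r^2).
    Evaluated in a form that stays accurate in that limit (the dispersion
    cap R_MAX = 1e8 must be numerically indistinguishable from Poisson).
    """
    mean = np.asarray(mean, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(mean <= 0) or np.any(r <= 0):
        raise ValueError("mean and r must be positive")
    d_arr = np.asarray(d)
    if np.any(d_arr < 0) or not np.issubdtype(d_arr.dtype, np.integer) and np.any(d_arr != np.floor(d_arr)):
        raise ValueError("d must be a non-negative integer count")
    from scipy.special import gammaln

    d_f = np.asarray(d_arr, dtype=float)
    d_b, mean_b, r_b = np.broadcast_arrays(d_f, mean, r)
    out = (
        _lgamma_ratio_minus_dlogr(d_b, r_b)
        - gammaln(d_b + 1)
        - (r_b + d_b) * np.log1p(mean_b / r_b)
        + d_b * np.log(mean_b)
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class EmissionModel:
    """Fitted per-batch emission model: normalization + dispersion + states."""

    factors: NormalizationFactors
    dispersions: DispersionEstimates
    states: tuple[int, ...] = (0, 1, 2, 3)
    epsilon0: float = 0.01
    masked: np.ndarray = field(default=None)  # targets with mu_i == 0

    def __post_init__(self) -> None:
        if 2 not in self.states:
            raise ValueError("states must include diploid (2)")
        if not (0 < self.epsilon0 < 0.5):
            raise ValueError("epsilon0 must lie in (0, 0.5)")
        if self.masked is None:
            self.masked = self.factors.mu_i <= 0

    @classmethod
    def fit(cls, depths: DepthMatrix, config=None) -> "EmissionModel":
        from .config import DEFAULT_CONFIG

        cfg = config or DEFAULT_CONFIG
        mu_i = compute_target_medians(depths)
        mu_j = compute_sample_factors(depths, mu_i)
        disp = estimate_dispersion(
            depths,
            mu_i,
            r_max=cfg.r_max,
            default_r=cfg.default_r,
            sample_factors=mu_j,
            robust=True,
        )
        return cls(
            NormalizationFactors(mu_i, mu_j),
            disp,
            states=tuple(cfg.states),
            epsilon0=cfg.epsilon0,
        )

    def expected_depth(self, i: int, j: int, copy_number: int) -> float:
        """Expected reads at target i, sample j, for a given copy number.

        Diploid expectation is mu_i * mu_j (c/2 scaling); copy 0 keeps an
        epsilon0 background floor so the NB stays proper.
        """
        base = self.factors.mu_i[i] * self.factors.mu_j[j]
        scale = self.epsilon0 if copy_number == 0 else copy_number / 2.0
        return scale * base


def emission_log_likelihoods(
    depths: DepthMatrix, model: EmissionModel, sample: int | str
) -> np.ndarray:
    """Per-target x per-state log-likelihood table for one sample.

    Masked targets (mu_i == 0) get identical log-likelihood (0) across
    states: they carry no copy-number information.
    """
    j = depths.sample_index(sample) if isinstance(sample, str) else sample
    d = depths.depths[:, j]
    mu_i = model.factors.mu_i
    mu_j = model.factors.mu_j[j]
    r = model.dispersions.r_i
    out = np.zeros((depths.n_targets, len(model.states)))
    live = ~model.masked
    if np.any(live):
        for s_idx, c in enumerate(model.states):
            scale = model.epsilon0 if c == 0 else c / 2.0
            mean = np.maximum(scale * mu_i[live] * mu_j, 1e-12)
            out[live, s_idx] = nb_log_pmf(d[live], mean, r[live])
    return out


# ---------------------------------------------------------------------------
# sample QC gates
# ---------------------------------------------------------------------------


@dataclass
class SampleQcMetrics:
    contamination_fraction: float
    per_base_min_depth: float
    mean_depth: float
    roi_coverage_fraction: float


@dataclass
class QcResult:
    passed: bool
    reasons: list[str]


def apply_sample_qc(metrics: SampleQcMetrics, config=None) -> QcResult:
    """Evaluate the assay's printed post-sequencing gates.

    Contamination must stay below 5%, every targeted base needs >= 20
    reads, mean coverage must exceed 250x, and the ROI must be 100%
    covered.  All violated gates are reported, not just the first.
    """
    from .config import DEFAULT_CONFIG

    cfg = config or DEFAULT_CONFIG
    reasons: list[str] = []
    if metrics.contamination_fraction >= cfg.max_contamination:
        reasons.append(
            f"contamination {metrics.contamination_fraction:.3f} >= "
            f"{cfg.max_contamination}"
        )
    if metrics.per_base_min_depth < cfg.min_per_base_depth:
        reasons.append(
            f"per-base minimum depth {metrics.per_base_min_depth} < "
            f"{cfg.min_per_base_depth}"
        )
    if metrics.mean_depth <= cfg.min_mean_depth:
        reasons.append(
            f"mean depth {metrics.mean_depth} <= {cfg.min_mean_depth}"
        )
    if metrics.roi_coverage_fraction < cfg.min_roi_coverage:
        reasons.append(
            f"ROI coverage {metrics.roi_coverage_fraction} < "
            f"{cfg.min_roi_coverage}"
        )
    return QcResult(passed=not reasons, reasons=reasons)


def normalization_report(depths: DepthMatrix, model: EmissionModel):
    """Per-target normalization summary (target, mu_i, r_i, masked)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "target": depths.target_ids,
            "mu_i": model.factors.mu_i,
            "r_i": model.dispersions.r_i,
            "masked": model.masked,
        }
    )
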