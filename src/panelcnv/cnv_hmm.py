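"""Copy-number HMM: distance-aware transitions, Viterbi/posterior decoding,
segmentation into calls, reporting rules and the calling policy.

The hidden chain runs per base pair with two macro-states, wild-type
(diploid) and CNV, parameterized by the per-bp exit rate b = p_CNV->WT =
1/6200 (matching the mean CNV length observed in the population) and the
entry rate a = p_CNV * b with prior p_CNV = 0.001.  Emission nodes sit at
target regions only; the chain is advanced analytically across the
inter-target gap.  The CNV macro-state splits equally over the non-diploid
copy numbers, with no direct transitions between different CNV states
(a deletion cannot become a duplication without passing through diploid
sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .depth_model import DepthMatrix, EmissionModel, emission_log_likelihoods
from .panel import Panel, TargetRegion


@dataclass
class TransitionModel:
    p_cnv_to_wt_per_bp: float = 1.0 / 6200.0
    p_cnv_prior: float = 0.001
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not (0 < self.p_cnv_to_wt_per_bp < 1):
            raise ValueError("p_cnv_to_wt_per_bp must lie in (0, 1)")
        if self.p_cnv_prior <= 0:
            raise ValueError("p_cnv_prior must be positive")
        if self.p_wt_to_cnv_per_bp >= self.p_cnv_to_wt_per_bp:
            raise ValueError("entry rate must be below exit rate (prior < 1)")

    @property
    def p_wt_to_cnv_per_bp(self) -> float:
        return self.p_cnv_prior * self.p_cnv_to_wt_per_bp

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "TransitionModel":
        return cls(
            p_cnv_to_wt_per_bp=cfg.p_cnv_to_wt_per_bp,
            p_cnv_prior=cfg.p_cnv_prior,
            max_gap_bp=cfg.max_gap_bp,
        )


def transition_matrix(
    gap_bp: int,
    model: TransitionModel,
    states: tuple[int, ...] = (0, 1, 2, 3),
) -> np.ndarray:
    """Closed-form state transition matrix across ``gap_bp`` base pairs.

    The WT/CNV macro-chain with per-bp rates a (entry) and b (exit) has the
    exact g-step solution

        P(WT->CNV, g)  = (a/(a+b)) * (1 - (1-a-b)^g)
        P(CNV->WT, g)  = (b/(a+b)) * (1 - (1-a-b)^g)

    Within the CNV macro-state, mass that never exits stays in its own copy
    state with probability (1-b)^g; mass that exits and re-enters is split
    equally over the CNV states (re-entry from WT is uniform, and there are
    no direct CNV->CNV transitions), which makes the per-state closed form
    exact: it equals the gap-fold product of the per-bp matrix.
    """
    states = tuple(states)
    k = len(states)
    wt = states.index(2)
    n_cnv = k - 1
    if n_cnv < 1:
        raise ValueError("need at least one non-diploid state")
    g = min(int(gap_bp), model.max_gap_bp)
    if g < 0:
        raise ValueError("gap must be non-negative")
    if g == 0:
        return np.eye(k)

    a = model.p_wt_to_cnv_per_bp
    b = model.p_cnv_to_wt_per_bp
    # 1 - (1-a-b)^g via expm1/log1p: avoids cancellation so the g=1 matrix
    # is exact to 1 ulp and the closed form tracks repeated multiplication
    one_minus_decay = -np.expm1(g * np.log1p(-(a + b)))
    p_wt_cnv = (a / (a + b)) * one_minus_decay  # total WT -> CNV mass
    p_cnv_wt = (b / (a + b)) * one_minus_decay  # total CNV -> WT mass
    stay_own = np.exp(g * np.log1p(-b))  # never left the original CNV state
    reentered = max((1.0 - p_cnv_wt) - stay_own, 0.0)  # left, came back to CNV

    T = np.empty((k, k))
    for si in range(k):
        for sj in range(k):
            if si == wt and sj == wt:
                T[si, sj] = 1.0 - p_wt_cnv
            elif si == wt:
                T[si, sj] = p_wt_cnv / n_cnv
            elif sj == wt:
                T[si, sj] = p_cnv_wt
            elif si == sj:
                T[si, sj] = stay_own + reentered / n_cnv
            else:
                T[si, sj] = reentered / n_cnv
    return T


def per_bp_matrix(model: TransitionModel, states: tuple[int, ...] = (0, 1, 2, 3)) -> np.ndarray:
    """The elementary 1-bp transition matrix (for cross-checks)."""
    return transition_matrix(1, model, states)


def initial_distribution(
    model: TransitionModel, states: tuple[int, ...] = (0, 1, 2, 3)
) -> np.ndarray:
    """Stationary distribution of the per-bp macro-chain.

    P(CNV) = a/(a+b) = p_CNV/(1+p_CNV), split equally over the non-diploid
    states; used to (re)start each independent decoding block.
    """
    states = tuple(states)
    k = len(states)
    wt = states.index(2)
    a = model.p_wt_to_cnv_per_bp
    b = model.p_cnv_to_wt_per_bp
    p_cnv_total = a / (a + b)
    pi = np.full(k, p_cnv_total / (k - 1))
    pi[wt] = 1.0 - p_cnv_total
    return pi


@dataclass
class CopyStatePath:
    states: np.ndarray  # decoded copy number per target
    log_joint: float


def _preference_order(states: tuple[int, ...]) -> list[int]:
    """Tie-break order: diploid first, then lower copy numbers."""
    return sorted(range(len(states)), key=lambda i: (states[i] != 2, states[i]))


def _gap_log_transitions(
    gaps: np.ndarray, model: TransitionModel, states: tuple[int, ...]
) -> np.ndarray:
    k = len(states)
    if len(gaps) == 0:
        return np.zeros((0, k, k))
    mats = np.stack(
        [transition_matrix(max(int(g), 1), model, states) for g in gaps]
    )
    with np.errstate(divide="ignore"):
        return np.log(mats)


def viterbi(
    emissions: np.ndarray,
    gaps: np.ndarray,
    model: TransitionModel,
    states: tuple[int, ...] = (0, 1, 2, 3),
) -> CopyStatePath:
    """MAP copy-number path for one block (one gene) of ordered targets.

    ``emissions`` is targets x states log-likelihood; ``gaps`` holds the
    len(emissions)-1 inter-target distances in bp.  Ties are broken toward
    the diploid state, then toward the lower copy number.
    """
    states = tuple(states)
    n, k = emissions.shape
    if n == 0:
        return CopyStatePath(np.array([], dtype=int), 0.0)
    if len(gaps) != n - 1:
        raise ValueError("need one gap per adjacent target pair")
    pref = _preference_order(states)
    log_pi = np.log(initial_distribution(model, states))
    log_T = _gap_log_transitions(np.asarray(gaps), model, states)

    delta = np.empty((n, k))
    back = np.zeros((n, k), dtype=int)
    delta[0] = log_pi + emissions[0]
    for t in range(1, n):
        for j in range(k):
            best_i, best = pref[0], -np.inf
            for i in pref:
                score = delta[t - 1, i] + log_T[t - 1, i, j]
                if score > best:
                    best, best_i = score, i
            delta[t, j] = best + emissions[t, j]
            back[t, j] = best_i
    last, best = pref[0], -np.inf
    for i in pref:
        if delta[n - 1, i] > best:
            best, last = delta[n - 1, i], i
    path_idx = np.empty(n, dtype=int)
    path_idx[-1] = last
    for t in range(n - 1, 0, -1):
        path_idx[t - 1] = back[t, path_idx[t]]
    decoded = np.array([states[i] for i in path_idx])
    return CopyStatePath(decoded, float(best))


def posterior_decode(
    emissions: np.ndarray,
    gaps: np.ndarray,
    model: TransitionModel,
    states: tuple[int, ...] = (0, 1, 2, 3),
) -> np.ndarray:
    """Forward-backward posterior state probabilities (targets x states).

    Scaled (per-target normalized) recursion; emission rows are shifted by
    their maximum before exponentiation, which cancels in the posterior.
    Rows sum to 1.
    """
    states = tuple(states)
    n, k = emissions.shape
    if n == 0:
        return np.zeros((0, k))
    pi = initial_distribution(model, states)
    Ts = [transition_matrix(max(int(g), 1), model, states) for g in np.asarray(gaps)]
    e = np.exp(emissions - emissions.max(axis=1, keepdims=True))

    alpha = np.empty((n, k))
    c = np.empty(n)
    alpha[0] = pi * e[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ Ts[t - 1]) * e[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]

    beta = np.empty((n, k))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (Ts[t] @ (e[t + 1] * beta[t + 1])) / c[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


# ---------------------------------------------------------------------------
# segmentation, reporting, end-to-end calling
# ---------------------------------------------------------------------------


@dataclass
class CnvCall:
    sample_id: str
    gene: str
    first_region: TargetRegion
    last_region: TargetRegion
    event_type: str  # deletion | duplication
    copy_number: int
    n_targets: int
    confidence: float  # mean per-target P(c != 2) over the run
    min_posterior: float  # diagnostic: weakest target in the run
    status: str  # confident | retest | no_call
    exon_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = "deletion" if self.copy_number < 2 else "duplication"
        if self.event_type != expected:
            raise ValueError("event_type inconsistent with copy_number")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        if self.n_targets < 1:
            raise ValueError("a call spans at least one target")

    @property
    def chrom(self) -> str:
        return self.first_region.chrom

    @property
    def start(self) -> int:
        return self.first_region.start

    @property
    def end(self) -> int:
        return self.last_region.end


def segment_calls(
    path: CopyStatePath,
    posteriors: np.ndarray,
    block_targets: list[TargetRegion],
    config: PipelineConfig | None = None,
    sample_id: str = "",
    states: tuple[int, ...] = (0, 1, 2, 3),
) -> list[CnvCall]:
    """Turn a decoded path into calls: maximal runs of one non-diploid
    state, each scored by the mean (and min) per-target P(c != 2)."""
    cfg = config or DEFAULT_CONFIG
    states = tuple(states)
    wt = states.index(2)
    decoded = path.states
    if len(decoded) != len(block_targets):
        raise ValueError("path and targets misaligned")
    p_not_diploid = 1.0 - posteriors[:, wt]
    calls: list[CnvCall] = []
    t = 0
    n = len(decoded)
    while t < n:
        c = int(decoded[t])
        if c == 2:
            t += 1
            continue
        run_start = t
        while t < n and int(decoded[t]) == c:
            t += 1
        run = slice(run_start, t)
        conf = float(np.mean(p_not_diploid[run]))
        min_post = float(np.min(p_not_diploid[run]))
        if conf >= cfg.t_conf:
            status = "confident"
        elif conf >= cfg.t_retest:
            status = "retest"
        else:
            status = "no_call"
        regions = block_targets[run]
        calls.append(
            CnvCall(
                sample_id=sample_id,
                gene=regions[0].gene,
                first_region=regions[0],
                last_region=regions[-1],
                event_type="deletion" if c < 2 else "duplication",
                copy_number=c,
                n_targets=t - run_start,
                confidence=conf,
                min_posterior=min_post,
                status=status,
                exon_labels=[r.exon_label for r in regions],
            )
        )
    return calls


def filter_reportable(calls: list[CnvCall], panel: Panel) -> list[CnvCall]:
    """Drop calls that the panel's per-gene reporting rules exclude
    (EPCAM: only deletions including exon 9; GREM1: promoter duplications
    only; every other gene reports all events)."""
    kept = []
    for call in calls:
        rule = panel.rule_for(call.gene)
        if rule.allows(call.event_type, call.exon_labels):
            kept.append(call)
    return kept


def call_cnvs(
    depths: DepthMatrix,
    panel: Panel,
    config: PipelineConfig | None = None,
) -> list[CnvCall]:
    """End-to-end exon-level CNV calling for one batch.

    Fits the emission model on the batch, then decodes each sample's
    per-gene blocks independently (genes are separate chains restarted at
    the stationary distribution), segments runs of non-diploid states into
    calls, and applies the panel's reporting rules.  Deterministic given
    inputs.
    """
    cfg = config or DEFAULT_CONFIG
    if depths.n_samples < 2:
        raise ValueError(
            "cross-sample normalization needs at least 2 samples in the batch"
        )
    if depths.target_ids != panel.target_ids():
        depths = depths.reindex_targets(panel.target_ids())
    model = EmissionModel.fit(depths, cfg)
    tmodel = TransitionModel.from_config(cfg)
    states = tuple(cfg.states)
    regions = panel.regions

    calls: list[CnvCall] = []
    for j, sample_id in enumerate(depths.sample_ids):
        em_all = emission_log_likelihoods(depths, model, j)
        for gene, idxs in panel.gene_blocks():
            live = [i for i in idxs if not model.masked[i]]
            if not live:
                continue
            block_targets = [regions[i] for i in live]
            em = em_all[live]
            mids = np.array([r.midpoint for r in block_targets])
            gaps = np.maximum(np.diff(mids).astype(int), 1)
            path = viterbi(em, gaps, tmodel, states)
            if np.all(path.states == 2):
                continue
            post = posterior_decode(em, gaps, tmodel, states)
            calls.extend(
                segment_calls(
                    path,
                    post,
                    block_targets,
                    cfg,
                    sample_id=sample_id,
                    states=states,
                )
            )
    return filter_reportable(calls, panel)


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    """Tabular call representation matching the output TSV schema."""
    rows = [
        {
            "sample": c.sample_id,
            "gene": c.gene,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "first_exon": c.first_region.exon_label,
            "last_exon": c.last_region.exon_label,
            "event_type": c.event_type,
            "copy_number": c.copy_number,
            "n_targets": c.n_targets,
            "confidence": c.confidence,
            "min_posterior": c.min_posterior,
            "status": c.status,
        }
        for c in calls
    ]
    columns = [
        "sample", "gene", "chrom", "start", "end", "first_exon", "last_exon",
        "event_type", "copy_number", "n_targets", "confidence",
        "min_posterior", "status",
    ]
    return pd.DataFrame(rows, columns=columns)
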