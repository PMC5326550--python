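"""Synthetic-data generation with truth manifests.

Depth cohorts realize exactly the caller's generative model: per-target
baselines (lognormal spread around a 650x mean, emulating capture
efficiency variation), per-sample scale factors, and negative-binomial
counts drawn as a Gamma-Poisson mixture so the mean/size parameterization
is exact.  Spiked deletions/duplications scale the expected depth by c/2.
A separate generator emits read sets with Alu-junction soft clips, and a
third produces paired truth/test call tables for the validation
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alu import AluSite
from .cnv_hmm import CnvCall
from .depth_model import DepthMatrix
from .panel import AlignedRead, Panel
from .validation import CallRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Spike:
    """One synthetic CNV: ``first_target`` indexes within the gene's block."""

    sample: int
    gene: str
    first_target: int
    n_targets: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number not in (0, 1, 3):
            raise ValueError("spike copy_number must be 0, 1 or 3")
        if self.n_targets < 1 or self.first_target < 0:
            raise ValueError("invalid spike span")

    @property
    def event_type(self) -> str:
        return "deletion" if self.copy_number < 2 else "duplication"


@dataclass
class SimConfig:
    n_samples: int = 16
    mean_depth: float = 650.0  # assay's nominal mean coverage
    depth_spread: float = 0.3  # lognormal sigma of per-target baselines
    sample_factor_sigma: float = 0.1  # lognormal sigma of per-sample factors
    dispersion_r: float = 1e4  # NB size (near-Poisson at 650x)
    residual_fraction: float = 0.01  # background depth at copy 0
    spikes: list[Spike] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class SimTruth:
    spikes: list[Spike]
    spike_spans: list[tuple[int, int]]  # global panel index span per spike
    base_depths: np.ndarray  # true per-target baseline mu_i
    sample_factors: np.ndarray  # true per-sample factors
    sample_ids: list[str]
    dispersion_r: float


def _spike_global_span(panel: Panel, spike: Spike) -> tuple[int, int]:
    blocks = dict(panel.gene_blocks())
    if spike.gene not in blocks:
        raise ValueError(f"spike gene {spike.gene!r} not in panel")
    idxs = blocks[spike.gene]
    if spike.first_target + spike.n_targets > len(idxs):
        raise ValueError(
            f"spike {spike} exceeds {spike.gene}'s {len(idxs)} targets"
        )
    sub = idxs[spike.first_target : spike.first_target + spike.n_targets]
    return sub[0], sub[-1]


def simulate_cohort(panel: Panel, config: SimConfig) -> tuple[DepthMatrix, SimTruth]:
    """One flowcell-lane batch of NB depths with optional spiked CNVs."""
    rng = np.random.default_rng(config.seed)
    n_t = len(panel.regions)
    n_s = config.n_samples
    if config.n_samples < 2:
        raise ValueError("need at least 2 samples")

    base = np.exp(rng.normal(np.log(config.mean_depth), config.depth_spread, n_t))
    factors = np.exp(rng.normal(0.0, config.sample_factor_sigma, n_s))

    copy = np.full((n_t, n_s), 2, dtype=int)
    spans: list[tuple[int, int]] = []
    for spike in config.spikes:
        if not 0 <= spike.sample < n_s:
            raise ValueError(f"spike sample {spike.sample} outside cohort")
        lo, hi = _spike_global_span(panel, spike)
        spans.append((lo, hi))
        copy[lo : hi + 1, spike.sample] = spike.copy_number

    scale = np.where(copy == 0, config.residual_fraction, copy / 2.0)
    mean = scale * base[:, None] * factors[None, :]
    r = config.dispersion_r
    lam = rng.gamma(shape=r, scale=mean / r)
    depths = rng.poisson(lam).astype(np.int64)

    sample_ids = [f"S{j:02d}" for j in range(n_s)]
    dm = DepthMatrix(depths, panel.target_ids(), sample_ids)
    truth = SimTruth(
        spikes=list(config.spikes),
        spike_spans=spans,
        base_depths=base,
        sample_factors=factors,
        sample_ids=sample_ids,
        dispersion_r=r,
    )
    return dm, truth


def random_spike_set(
    panel: Panel,
    n_samples: int,
    rng: np.random.Generator,
    n_single: int = 13,
    n_multi: int = 37,
    copy_numbers: tuple[int, ...] = (1, 3),
    max_span: int = 10,
) -> list[Spike]:
    """Place spiked events on random (sample, gene) slots, one event per
    slot, avoiding the CNV-only genes whose reporting rules would mask a
    random event type.  Multi-target events span 2..max_span targets."""
    blocks = {
        g: idxs
        for g, idxs in panel.gene_blocks()
        if g not in panel.cnv_only_genes
    }
    spans = [1] * n_single + [
        int(rng.integers(2, max_span + 1)) for _ in range(n_multi)
    ]
    rng.shuffle(spans)
    used: set[tuple[int, str]] = set()
    spikes: list[Spike] = []
    for span in spans:
        eligible = [g for g, idxs in blocks.items() if len(idxs) >= span]
        for _ in range(10_000):
            sample = int(rng.integers(0, n_samples))
            gene = eligible[int(rng.integers(0, len(eligible)))]
            if (sample, gene) not in used:
                used.add((sample, gene))
                break
        else:
            raise RuntimeError("could not place spikes without collision")
        n_targets_gene = len(blocks[gene])
        first = int(rng.integers(0, n_targets_gene - span + 1))
        copy = int(copy_numbers[int(rng.integers(0, len(copy_numbers)))])
        spikes.append(Spike(sample, gene, first, span, copy))
    return spikes


def score_recovery(
    calls: list[CnvCall],
    truth: SimTruth,
    panel: Panel,
) -> tuple[int, int]:
    """(detected, false_confident): spikes overlapped by a confident call
    of the correct type in the right sample/gene, and confident calls that
    overlap no same-sample truth span."""
    index_of = {tid: i for i, tid in enumerate(panel.target_ids())}
    confident = [c for c in calls if c.status == "confident"]

    def call_span(call: CnvCall) -> tuple[int, int]:
        return (
            index_of[call.first_region.target_id],
            index_of[call.last_region.target_id],
        )

    detected = 0
    for spike, (lo, hi) in zip(truth.spikes, truth.spike_spans):
        sample_id = truth.sample_ids[spike.sample]
        for call in confident:
            if call.sample_id != sample_id or call.gene != spike.gene:
                continue
            if call.event_type != spike.event_type:
                continue
            c_lo, c_hi = call_span(call)
            if c_lo <= hi and c_hi >= lo:
                detected += 1
                break

    truth_by_sample: dict[str, list[tuple[int, int]]] = {}
    for spike, span in zip(truth.spikes, truth.spike_spans):
        truth_by_sample.setdefault(truth.sample_ids[spike.sample], []).append(span)
    false_calls = 0
    for call in confident:
        c_lo, c_hi = call_span(call)
        spans = truth_by_sample.get(call.sample_id, [])
        if not any(c_lo <= hi and c_hi >= lo for lo, hi in spans):
            false_calls += 1
    return detected, false_calls


# ---------------------------------------------------------------------------
# Alu read simulation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_alu_reads(
    site: AluSite,
    n_unique_matching: int,
    n_duplicates: int = 0,
    n_nonmatching: int = 0,
    read_len: int = 100,
    seed: int = 0,
) -> list[AlignedRead]:
    """Reads soft-clipped at the insertion site.

    Matching reads carry a clip equal to a prefix of the site's junction
    sequence (clip lengths vary so reads are unique under the dedup key);
    duplicates are exact copies of the matching reads (cycled); and
    non-matching reads carry random clip sequence at the same boundary.
    """
    rng = np.random.default_rng(seed)
    reads: list[AlignedRead] = []
    min_clip = 15
    max_clip = min(len(site.junction_seq), read_len - 20)
    if max_clip < min_clip:
        raise ValueError("read_len too short for a usable clip")

    matching: list[AlignedRead] = []
    for k in range(n_unique_matching):
        clip_len = min_clip + (k % (max_clip - min_clip + 1))
        m = read_len - clip_len
        pos = site.position - m
        seq = _random_seq(rng, m) + site.junction_seq[:clip_len]
        matching.append(
            AlignedRead(
                chrom=site.chrom,
                pos=pos,
                cigar=f"{m}M{clip_len}S",
                seq=seq,
                name=f"match{k}",
            )
        )
    reads.extend(matching)

    pool = matching or reads
    for k in range(n_duplicates):
        if not pool:
            break  # duplicates need a base read to copy
        src = pool[k % len(pool)]
        reads.append(
            AlignedRead(
                chrom=src.chrom,
                pos=src.pos,
                cigar=src.cigar,
                seq=src.seq,
                is_duplicate_flag=True,
                name=f"dup{k}",
            )
        )

    for k in range(n_nonmatching):
        clip_len = min_clip + (k % (max_clip - min_clip + 1))
        m = read_len - clip_len
        pos = site.position - m
        seq = _random_seq(rng, read_len)
        reads.append(
            AlignedRead(
                chrom=site.chrom,
                pos=pos,
                cigar=f"{m}M{clip_len}S",
                seq=seq,
                name=f"bg{k}",
            )
        )
    return reads


# ---------------------------------------------------------------------------
# validation-cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class ValidationSimConfig:
    n_samples: int = 10
    n_tp: int = 10
    n_fp: int = 0
    n_fn: int = 0
    n_nocall: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need >= 2 samples for reference backgrounds")


def simulate_validation_cohort(
    config: ValidationSimConfig,
) -> tuple[list[CallRecord], list[CallRecord]]:
    """Paired truth/test call tables with exact configured error counts.

    Each TP/FP/FN/no-call event occupies its own locus on the first
    sample; every other sample is concordant-reference there, so in site
    mode TN = (n_samples - 1) x number of event loci, exactly.
    """
    rng = np.random.default_rng(config.seed)
    truth: list[CallRecord] = []
    test: list[CallRecord] = []
    samples = [f"V{j:02d}" for j in range(config.n_samples)]
    carrier = samples[0]
    events = (
        [("variant", "variant")] * config.n_tp
        + [("reference", "variant")] * config.n_fp
        + [("variant", "reference")] * config.n_fn
        + [("variant", "no_call")] * config.n_nocall
    )
    for k, (truth_call, test_call) in enumerate(events):
        locus = f"L{k:03d}"
        payload = f"allele{int(rng.integers(0, 1000)):03d}"
        truth.append(
            CallRecord(carrier, locus, truth_call,
                       payload if truth_call == "variant" else None)
        )
        test.append(
            CallRecord(carrier, locus, test_call,
                       payload if test_call == "variant" else None)
        )
        for other in samples[1:]:
            truth.append(CallRecord(other, locus, "reference"))
            test.append(CallRecord(other, locus, "reference"))
    return truth, test
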