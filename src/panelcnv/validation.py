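"""Validation statistics: confusion counting, Clopper-Pearson-bounded
performance metrics and replicate concordance.

Definitions follow standard clinical assay validation practice:
Accuracy = (TP+TN)/(TP+FP+TN+FN), Sensitivity = TP/(TP+FN),
Specificity = TN/(TN+FP), FDR = FP/(TP+FP), each with an exact two-sided
Clopper-Pearson binomial confidence interval.  True negatives are counted
only where a negative is informative: at loci polymorphic in the cohort
(site mode) or in genes with at least one true CNV positive (gene mode).
No-calls are censored pairwise before counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

from scipy import stats

VALID_CALLS = ("variant", "reference", "no_call")


@dataclass(frozen=True)
class CallRecord:
    sample_id: str
    locus_id: str
    call: str  # variant | reference | no_call
    payload: str | None = None  # optional allele / copy-number text

    def __post_init__(self) -> None:
        if self.call not in VALID_CALLS:
            raise ValueError(f"call must be one of {VALID_CALLS}")


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0
    censored: int = 0  # pairs removed because either side was a no-call

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN, self.censored) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricWithCI:
    name: str
    numerator: int
    denominator: int
    estimate: float
    ci_low: float
    ci_high: float
    alpha: float

    def as_percent(self, decimals: int = 2) -> str:
        return (
            f"{round(self.estimate * 100, decimals)}% "
            f"({round(self.ci_low * 100, decimals)}-"
            f"{round(self.ci_high * 100, decimals)}%)"
        )


def _index(records: list[CallRecord], label: str) -> dict[tuple[str, str], CallRecord]:
    out: dict[tuple[str, str], CallRecord] = {}
    for rec in records:
        key = (rec.sample_id, rec.locus_id)
        if key in out:
            raise ValueError(f"duplicate (sample, locus) key in {label}: {key}")
        out[key] = rec
    return out


def count_confusion(
    truth: list[CallRecord],
    test: list[CallRecord],
    mode: str = "site",
) -> ConfusionCounts:
    """Confusion counts over paired truth/test calls.

    A pair is censored when either side is a no-call.  TP requires matching
    payload text when both sides carry one (call comparison, not just
    position).  TN counting is restricted to informative loci: in ``site``
    mode, loci where any sample carries a variant; in ``gene`` mode, loci
    (genes) with at least one true positive in the cohort.
    """
    if mode not in ("site", "gene"):
        raise ValueError("mode must be 'site' or 'gene'")
    truth_by_key = _index(truth, "truth")
    test_by_key = _index(test, "test")
    keys = sorted(set(truth_by_key) & set(test_by_key))

    pairs = [
        (truth_by_key[k], test_by_key[k])
        for k in keys
        if truth_by_key[k].call != "no_call" and test_by_key[k].call != "no_call"
    ]
    n_censored = len(keys) - len(pairs)

    tp = fp = fn = 0
    tn_loci: set[str] = set()
    concordant_ref_by_locus: dict[str, int] = {}
    polymorphic: set[str] = set()
    tp_loci: set[str] = set()

    for t_rec, s_rec in pairs:
        locus = t_rec.locus_id
        if t_rec.call == "variant" or s_rec.call == "variant":
            polymorphic.add(locus)
        if t_rec.call == "variant" and s_rec.call == "variant":
            if (
                t_rec.payload is not None
                and s_rec.payload is not None
                and t_rec.payload != s_rec.payload
            ):
                # right locus, wrong call: both a miss and a spurious call
                fp += 1
                fn += 1
            else:
                tp += 1
                tp_loci.add(locus)
        elif t_rec.call == "reference" and s_rec.call == "variant":
            fp += 1
        elif t_rec.call == "variant" and s_rec.call == "reference":
            fn += 1
        else:
            concordant_ref_by_locus[locus] = concordant_ref_by_locus.get(locus, 0) + 1

    tn_loci = polymorphic if mode == "site" else tp_loci
    tn = sum(
        count for locus, count in concordant_ref_by_locus.items() if locus in tn_loci
    )
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn, censored=n_censored)


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial CI via Beta quantiles.

    x = 0 gives (0, 1 - (alpha/2)^(1/n)); x = n gives ((alpha/2)^(1/n), 1).
    Conservative: coverage is at least 1 - alpha.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _metric(name: str, x: int, n: int, alpha: float) -> MetricWithCI | None:
    if n == 0:
        return None
    low, high = clopper_pearson(x, n, alpha)
    return MetricWithCI(name, x, n, x / n, low, high, alpha)


def compute_metrics(counts: ConfusionCounts, alpha: float = 0.05) -> list[MetricWithCI]:
    """Accuracy, sensitivity, specificity and FDR with exact CIs.

    Metrics whose denominator is zero are omitted rather than reported as
    NaN.
    """
    specs = [
        ("accuracy", counts.TP + counts.TN, counts.total),
        ("sensitivity", counts.TP, counts.TP + counts.FN),
        ("specificity", counts.TN, counts.TN + counts.FP),
        ("FDR", counts.FP, counts.TP + counts.FP),
    ]
    out = []
    for name, x, n in specs:
        m = _metric(name, x, n, alpha)
        if m is not None:
            out.append(m)
    return out


def concordance(replicate_calls: list[list[str]]) -> float:
    """Pooled pairwise concordance across aligned replicate call lists.

    Every replicate pair contributes one comparison per locus; the result
    is concordant comparisons / total comparisons.
    """
    if len(replicate_calls) < 2:
        raise ValueError("need at least two replicates")
    lengths = {len(r) for r in replicate_calls}
    if len(lengths) != 1:
        raise ValueError("replicates must be aligned (equal length)")
    agree = total = 0
    for rep_a, rep_b in combinations(replicate_calls, 2):
        for a, b in zip(rep_a, rep_b):
            total += 1
            if a == b:
                agree += 1
    if total == 0:
        raise ValueError("no comparable calls")
    return agree / total


# ---------------------------------------------------------------------------
# call table I/O
# ---------------------------------------------------------------------------


def read_call_table(path: str | Path) -> list[CallRecord]:
    """Truth/test call TSV: sample, locus, call, [payload]."""
    records: list[CallRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] in ("sample", "sample_id"):
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            payload = fields[3] if len(fields) > 3 and fields[3] else None
            records.append(CallRecord(fields[0], fields[1], fields[2], payload))
    return records


def write_metrics_report(
    counts: ConfusionCounts,
    metrics: list[MetricWithCI],
    path: str | Path,
    decimals: int = 2,
) -> None:
    with open(path, "w") as fh:
        fh.write("# TP\tFP\tTN\tFN\n")
        fh.write(f"# {counts.TP}\t{counts.FP}\t{counts.TN}\t{counts.FN}\n")
        fh.write("metric\tnumerator\tdenominator\testimate\tci_low\tci_high\n")
        for m in metrics:
            fh.write(
                f"{m.name}\t{m.numerator}\t{m.denominator}\t"
                f"{m.estimate:.6f}\t{m.ci_low:.6f}\t{m.ci_high:.6f}\n"
            )
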