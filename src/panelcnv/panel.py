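"""Panel model and file I/O: target intervals, BED/SAM/TSV readers.

Coordinates are 0-based half-open throughout (BED frame); SAM positions
are converted from 1-based on input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _tables
from .depth_model import DepthMatrix

log = logging.getLogger(__name__)

BUILTIN_PANELS = ("counsyl36",)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


@dataclass(frozen=True)
class TargetRegion:
    """One captured interval: the exon-level unit of CNV calling."""

    chrom: str
    start: int
    end: int
    gene: str
    exon_label: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def target_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.gene}"


@dataclass(frozen=True)
class ReportingRule:
    """Which CNV event types are reportable for a gene.

    ``must_overlap_exon`` restricts reportable events to those overlapping
    a named exon (EPCAM: only deletions including exon 9 silence MSH2 and
    are reported).
    """

    events: frozenset[str] = frozenset({"deletion", "duplication"})
    must_overlap_exon: str | None = None

    def allows(self, event_type: str, exon_labels: list[str]) -> bool:
        if event_type not in self.events:
            return False
        if self.must_overlap_exon is not None:
            return self.must_overlap_exon in exon_labels
        return True


DEFAULT_RULE = ReportingRule()


@dataclass
class Panel:
    """An ordered, validated collection of target regions plus per-gene
    reporting metadata."""

    name: str
    regions: list[TargetRegion]
    gene_roi_bp: dict[str, int] = field(default_factory=dict)
    reporting_rules: dict[str, ReportingRule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.regions = _sort_regions(self.regions)
        self._validate()

    def _validate(self) -> None:
        by_gene: dict[str, list[TargetRegion]] = {}
        for r in self.regions:
            by_gene.setdefault(r.gene, []).append(r)
        for gene, regs in by_gene.items():
            cnv_only = gene not in self.gene_roi_bp
            for a, b in zip(regs, regs[1:]):
                if a.chrom == b.chrom and b.start < a.end and not cnv_only:
                    raise ValueError(
                        f"overlapping targets in {gene}: "
                        f"{a.target_id} / {b.target_id}"
                    )

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.gene, None)
        return list(seen)

    @property
    def cnv_only_genes(self) -> list[str]:
        return [g for g in self.genes if g not in self.gene_roi_bp]

    def regions_for_gene(self, gene: str) -> list[TargetRegion]:
        return [r for r in self.regions if r.gene == gene]

    def gene_blocks(self) -> list[tuple[str, list[int]]]:
        """Panel indices grouped by gene, preserving panel order."""
        blocks: dict[str, list[int]] = {}
        for i, r in enumerate(self.regions):
            blocks.setdefault(r.gene, []).append(i)
        return list(blocks.items())

    def target_ids(self) -> list[str]:
        return [r.target_id for r in self.regions]

    def rule_for(self, gene: str) -> ReportingRule:
        return self.reporting_rules.get(gene, DEFAULT_RULE)


def _sort_regions(regions: list[TargetRegion]) -> list[TargetRegion]:
    """Sort by (chrom, start) keeping chromosome first-appearance order."""
    chrom_rank: dict[str, int] = {}
    for r in regions:
        chrom_rank.setdefault(r.chrom, len(chrom_rank))
    return sorted(regions, key=lambda r: (chrom_rank[r.chrom], r.start, r.end))


@dataclass(frozen=True)
class AlignedRead:
    """Minimal aligned-read record (SAM subset) for soft-clip analysis."""

    chrom: str
    pos: int  # 0-based leftmost aligned reference coordinate
    cigar: str
    seq: str
    is_duplicate_flag: bool = False
    name: str = ""

    def cigar_ops(self) -> list[tuple[int, str]]:
        ops = [(int(n), op) for n, op in _CIGAR_RE.findall(self.cigar)]
        if "".join(f"{n}{op}" for n, op in ops) != self.cigar:
            raise ValueError(f"malformed CIGAR {self.cigar!r}")
        return ops

    def query_consumed(self) -> int:
        return sum(n for n, op in self.cigar_ops() if op in _QUERY_OPS)

    def reference_end(self) -> int:
        return self.pos + sum(n for n, op in self.cigar_ops() if op in _REF_OPS)

    def validate(self) -> None:
        if self.seq and self.query_consumed() != len(self.seq):
            raise ValueError(
                f"CIGAR {self.cigar} consumes {self.query_consumed()} bases "
                f"but sequence has {len(self.seq)}"
            )


# ---------------------------------------------------------------------------
# builtin panel
# ---------------------------------------------------------------------------


def build_counsyl36() -> Panel:
    """The 36-gene hereditary-cancer panel fixture.

    Per-gene reportable ROI sizes and exon ranges are the assay's published
    values; the interval coordinates are synthetic (the commercial capture
    design is not public): each gene's exons are evenly sized blocks
    summing exactly to its ROI, separated by fixed 2-kb introns, with genes
    on a shared chromosome spaced 1 Mb apart.
    """
    regions: list[TargetRegion] = []
    gene_roi: dict[str, int] = {}
    chrom_cursor: dict[str, int] = {}

    for gene, (chrom, first_ex, last_ex, roi_bp) in _tables.PANEL_GENES.items():
        base = chrom_cursor.get(chrom, 0) + _tables.GENE_SPACING_BP
        chrom_cursor[chrom] = base

        if gene == "GREM1":
            for start1, end1, label in _tables.GREM1_INTERVALS:
                regions.append(
                    TargetRegion(chrom, start1 - 1, end1, gene, label)
                )
            continue
        if roi_bp is None:  # EPCAM: CNV-only single exon
            regions.append(
                TargetRegion(
                    chrom,
                    base,
                    base + _tables.EPCAM_EXON9_BP,
                    gene,
                    f"exon {first_ex}",
                )
            )
            continue

        gene_roi[gene] = roi_bp
        n_exons = last_ex - first_ex + 1
        size, extra = divmod(roi_bp, n_exons)
        pos = base
        for k in range(n_exons):
            exon_bp = size + (1 if k < extra else 0)
            regions.append(
                TargetRegion(chrom, pos, pos + exon_bp, gene, f"exon {first_ex + k}")
            )
            pos += exon_bp + _tables.INTRON_GAP_BP

    rules = {
        "EPCAM": ReportingRule(
            events=frozenset({"deletion"}), must_overlap_exon="exon 9"
        ),
        "GREM1": ReportingRule(events=frozenset({"duplication"})),
    }
    return Panel("counsyl36", regions, gene_roi_bp=gene_roi, reporting_rules=rules)


def load_panel(path_or_builtin: str | Path) -> Panel:
    """Load a panel from a BED-like file (chrom start end gene exon_label)
    or by builtin name (``"counsyl36"``)."""
    src = str(path_or_builtin)
    if src == "counsyl36":
        return build_counsyl36()
    path = Path(src)
    if not path.exists():
        raise ValueError(
            f"unknown builtin panel or missing file: {src!r} "
            f"(builtins: {', '.join(BUILTIN_PANELS)})"
        )
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            gene = fields[3]
            exon_label = fields[4] if len(fields) > 4 else f"target {lineno}"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from e
            try:
                regions.append(TargetRegion(chrom, start, end, gene, exon_label))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from e
    return Panel(path.stem, regions)


def roi_total(panel: Panel) -> int:
    """Total reportable SNV/indel ROI of the panel in bp (sum over genes)."""
    return sum(panel.gene_roi_bp.values())


# ---------------------------------------------------------------------------
# depth-matrix TSV
# ---------------------------------------------------------------------------


def read_depth_matrix(path: str | Path, panel: Panel | None = None) -> DepthMatrix:
    """Read a targets x samples integer depth TSV.

    First column holds target IDs (``chrom:start-end:gene``), the header
    row sample IDs.  ``#``-prefixed lines are comments.  When a panel is
    given, rows are required to match and are re-ordered to panel order.
    """
    path = Path(path)
    header: list[str] | None = None
    target_ids: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                if len(set(header)) != len(header):
                    dupes = sorted(
                        {s for s in header if header.count(s) > 1}
                    )
                    raise ValueError(
                        f"{path}: duplicate sample IDs in header: {dupes}"
                    )
                continue
            target_ids.append(fields[0])
            row: list[int] = []
            for col, cell in enumerate(fields[1:]):
                try:
                    value = int(cell)
                except ValueError as e:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer depth {cell!r} "
                        f"(target {fields[0]}, sample {header[col]})"
                    ) from e
                if value < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative depth {value} "
                        f"(target {fields[0]}, sample {header[col]})"
                    )
                row.append(value)
            rows.append(row)
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    dm = DepthMatrix(np.array(rows, dtype=np.int64), target_ids, header)
    if panel is not None:
        dm = dm.reindex_targets(panel.target_ids())
    return dm


def write_depth_matrix(dm: DepthMatrix, path: str | Path, comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("target\t" + "\t".join(dm.sample_ids) + "\n")
        for tid, row in zip(dm.target_ids, dm.depths):
            fh.write(tid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# SAM reading
# ---------------------------------------------------------------------------


def read_alignments(path: str | Path, region: TargetRegion | None = None) -> list[AlignedRead]:
    """Read aligned reads from a text SAM file, optionally restricted to
    those overlapping ``region``.

    A deliberately tolerant line reader: records whose CIGAR is
    inconsistent with the sequence length (or otherwise malformed) are
    skipped with a logged warning rather than aborting the file, so one
    corrupt record cannot take down a batch.  SAM POS is 1-based and
    converted to the 0-based internal frame.
    """
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                log.warning("%s:%d: fewer than 11 SAM fields, skipped", path, lineno)
                continue
            try:
                flag = int(fields[1])
                pos1 = int(fields[3])
            except ValueError:
                log.warning("%s:%d: non-integer FLAG/POS, skipped", path, lineno)
                continue
            cigar, seq = fields[5], fields[9]
            if flag & 0x4 or cigar == "*":  # unmapped
                continue
            read = AlignedRead(
                chrom=fields[2],
                pos=pos1 - 1,
                cigar=cigar,
                seq="" if seq == "*" else seq,
                is_duplicate_flag=bool(flag & 0x400),
                name=fields[0],
            )
            try:
                read.validate()
            except ValueError as e:
                log.warning("%s:%d: skipping read %s: %s", path, lineno, read.name, e)
                continue
            if region is not None:
                if read.chrom != region.chrom:
                    continue
                if read.reference_end() <= region.start or read.pos >= region.end:
                    continue
            reads.append(read)
    return reads


def write_sam(reads: list[AlignedRead], path: str | Path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write reads as minimal text SAM (used by the simulator)."""
    if chrom_lengths is None:
        chrom_lengths = {}
        for r in reads:
            end = r.reference_end() + 1000
            chrom_lengths[r.chrom] = max(chrom_lengths.get(r.chrom, 0), end)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for i, r in enumerate(reads):
            flag = 0x400 if r.is_duplicate_flag else 0
            name = r.name or f"read{i}"
            fh.write(
                f"{name}\t{flag}\t{r.chrom}\t{r.pos + 1}\t60\t{r.cigar}\t"
                f"*\t0\t0\t{r.seq}\t*\n"
            )
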