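"""Known-site Alu insertion detection from soft-clipped reads.

At the junction of an Alu insertion the aligner soft-clips the Alu-derived
portion of spanning reads.  Detection at a catalogued site proceeds as:
collect soft clips whose boundary falls at the site, discard duplicates,
count clips matching the known junction sequence, and call the site
positive when at least three unique matching reads remain.  Sites are
call-by-list only: each must have been orthogonally confirmed beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import _tables
from .config import DEFAULT_CONFIG, PipelineConfig
from .panel import AlignedRead, Panel, build_counsyl36


@dataclass(frozen=True)
class AluSite:
    chrom: str
    position: int  # 0-based between-base insertion coordinate
    name: str
    junction_seq: str  # known Alu-side sequence at this site

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be non-negative")
        if not self.junction_seq:
            raise ValueError("junction_seq must be non-empty")


@dataclass(frozen=True)
class ClipRecord:
    seq: str
    aligned_start: int  # reference start of the read's aligned portion
    side: str  # "left" (leading S) or "right" (trailing S)


@dataclass
class SoftClipEvidence:
    site: AluSite
    unique_reads: list[ClipRecord] = field(default_factory=list)
    n_unique: int = 0
    n_matching: int = 0


@dataclass
class AluCallResult:
    site: AluSite
    positive: bool
    n_unique: int
    n_matching: int
    evidence: SoftClipEvidence | None = None


def extract_soft_clips(
    reads: list[AlignedRead],
    site: AluSite,
    min_clip_len: int = 10,
    boundary_tolerance: int = 5,
) -> list[ClipRecord]:
    """Soft-clipped segments whose clip boundary coincides with the site.

    A leading S op clips at the read's aligned start; a trailing S op clips
    at its aligned end.  Clips shorter than ``min_clip_len`` or whose
    boundary sits more than ``boundary_tolerance`` bp from the insertion
    coordinate are discarded.
    """
    clips: list[ClipRecord] = []
    for read in reads:
        if read.chrom != site.chrom:
            continue
        ops = read.cigar_ops()
        if not ops:
            continue
        n_lead, op_lead = ops[0]
        if op_lead == "S" and n_lead >= min_clip_len:
            boundary = read.pos
            if abs(boundary - site.position) <= boundary_tolerance:
                clips.append(
                    ClipRecord(read.seq[:n_lead], read.pos, "left")
                )
        n_trail, op_trail = ops[-1]
        if len(ops) > 1 and op_trail == "S" and n_trail >= min_clip_len:
            boundary = read.reference_end()
            if abs(boundary - site.position) <= boundary_tolerance:
                clips.append(
                    ClipRecord(read.seq[-n_trail:], read.pos, "right")
                )
    return clips


def dedupe_clips(clips: list[ClipRecord]) -> list[ClipRecord]:
    """One representative per (aligned_start, side, sequence) key —
    a PCR-duplicate proxy in the absence of mate information.  Input order
    of first occurrences is preserved."""
    seen: set[tuple[int, str, str]] = set()
    unique: list[ClipRecord] = []
    for clip in clips:
        key = (clip.aligned_start, clip.side, clip.seq)
        if key not in seen:
            seen.add(key)
            unique.append(clip)
    return unique


def match_alu(
    clip_seq: str,
    site: AluSite,
    min_overlap: int = 10,
    min_identity: float = 0.9,
) -> bool:
    """Ungapped prefix comparison of a clip against the site's junction
    sequence (as aligned; no reverse complement).  True when the compared
    overlap is long enough and identical enough."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    overlap = min(len(clip_seq), len(site.junction_seq))
    if overlap < min_overlap:
        return False
    matches = sum(
        1 for a, b in zip(clip_seq[:overlap], site.junction_seq[:overlap]) if a == b
    )
    return matches / overlap >= min_identity


def call_alu_site(
    reads: list[AlignedRead],
    site: AluSite,
    config: PipelineConfig | None = None,
) -> AluCallResult:
    """Positive iff >= 3 unique soft-clipped reads match the junction
    sequence, after boundary filtering and duplicate removal."""
    cfg = config or DEFAULT_CONFIG
    clips = extract_soft_clips(
        reads, site,
        min_clip_len=cfg.min_clip_len,
        boundary_tolerance=cfg.clip_boundary_tolerance,
    )
    unique = dedupe_clips(clips)
    matching = [
        c for c in unique
        if match_alu(c.seq, site, cfg.min_overlap, cfg.min_identity)
    ]
    evidence = SoftClipEvidence(
        site=site,
        unique_reads=unique,
        n_unique=len(unique),
        n_matching=len(matching),
    )
    return AluCallResult(
        site=site,
        positive=len(matching) >= cfg.min_unique_reads,
        n_unique=len(unique),
        n_matching=len(matching),
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# site table I/O and builtin fixture
# ---------------------------------------------------------------------------


def read_alu_sites(path) -> list[AluSite]:
    """Sites TSV: chrom, position, name, junction_seq (tab-separated,
    '#' comments, no header required unless first line says 'chrom')."""
    sites: list[AluSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "chrom":
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            sites.append(
                AluSite(fields[0], int(fields[1]), fields[2], fields[3])
            )
    return sites


def write_alu_results(results: list[AluCallResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tn_unique\tn_matching\tcall\n")
        for r in results:
            call = "positive" if r.positive else "negative"
            fh.write(f"{r.site.name}\t{r.n_unique}\t{r.n_matching}\t{call}\n")


def builtin_alu_sites(panel: Panel | None = None) -> list[AluSite]:
    """The four unique Alu insertion variants confirmed in the assay's
    validation, anchored to the builtin panel's synthetic coordinates.

    Junction sequences are SYNTHETIC: the AluY consensus prefix stands in
    for the unpublished per-site junctions.  Exonic insertions sit at the
    midpoint of their exon target; intronic ones midway between the
    flanking exon targets.
    """
    panel = panel or build_counsyl36()
    junction = _tables.ALUY_CONSENSUS_PREFIX
    sites: list[AluSite] = []
    for var in _tables.ALU_VARIANTS:
        regs = {r.exon_label: r for r in panel.regions_for_gene(var["gene"])}
        if var["kind"] == "exon":
            r = regs[f"exon {var['exon']}"]
            pos = int(r.midpoint)
            chrom = r.chrom
        else:
            r1 = regs[f"exon {var['exon_before']}"]
            r2 = regs[f"exon {var['exon_after']}"]
            pos = (r1.end + r2.start) // 2
            chrom = r1.chrom
        sites.append(AluSite(chrom, pos, var["name"], junction))
    return sites
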