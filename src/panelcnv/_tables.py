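"""Built-in panel content for the 36-gene hereditary-cancer screen.

Per-gene reportable ROI sizes (bp) and sequenced exon ranges are those of
the commercial assay; the genomic intervals generated from them are
SYNTHETIC (evenly sized exon blocks separated by fixed introns) because the
assay's true capture coordinates are not public.  The GREM1 promoter
duplication intervals are the three published GRCh37 coordinates.
"""

from __future__ import annotations

# gene -> (chrom, first_exon, last_exon, snv_indel_roi_bp or None)
# EPCAM and GREM1 carry no SNV/indel ROI: they are CNV-only content.
# PMS2 exons 11-15 and RET exon 1 are absent by design (pseudogene homology
# and GC content, respectively).
PANEL_GENES: dict[str, tuple[str, int, int, int | None]] = {
    "APC": ("chr5", 2, 16, 9433),
    "ATM": ("chr11", 2, 63, 11853),
    "BARD1": ("chr2", 1, 11, 2776),
    "BMPR1A": ("chr10", 3, 13, 2046),
    "BRCA1": ("chr17", 2, 23, 7351),
    "BRCA2": ("chr13", 2, 27, 11652),
    "BRIP1": ("chr17", 2, 20, 4556),
    "CDH1": ("chr16", 1, 16, 3350),
    "CDK4": ("chr12", 2, 8, 1229),
    "CDKN2A": ("chr9", 1, 3, 1343),
    "CHEK2": ("chr22", 2, 15, 2199),
    "EPCAM": ("chr2", 9, 9, None),
    "GREM1": ("chr15", 0, 0, None),  # promoter intervals, see GREM1_INTERVALS
    "MEN1": ("chr11", 2, 10, 2306),
    "MLH1": ("chr3", 1, 19, 3295),
    "MRE11A": ("chr11", 2, 20, 2897),
    "MSH2": ("chr2", 1, 16, 3692),
    "MSH6": ("chr2", 1, 10, 4566),
    "MUTYH": ("chr1", 1, 16, 2321),
    "NBN": ("chr8", 1, 16, 2905),
    "PALB2": ("chr16", 1, 13, 4090),
    "PMS2": ("chr7", 1, 10, 1649),
    "POLD1": ("chr19", 2, 27, 4435),
    "POLE": ("chr12", 1, 49, 8823),
    "PTEN": ("chr10", 1, 9, 1866),
    "RAD50": ("chr5", 1, 25, 4944),
    "RAD51C": ("chr17", 1, 9, 1509),
    "RAD51D": ("chr17", 1, 10, 1862),
    "RET": ("chr10", 2, 20, 4167),
    "SDHA": ("chr5", 1, 15, 2606),
    "SDHB": ("chr1", 1, 8, 1188),
    "SDHC": ("chr1", 1, 6, 864),
    "SMAD4": ("chr18", 2, 12, 2148),
    "STK11": ("chr19", 1, 9, 1717),
    "TP53": ("chr17", 2, 11, 1818),
    "VHL": ("chr3", 1, 3, 789),
}

# Published GREM1 promoter duplication intervals (GRCh37, 1-based inclusive
# as printed; converted to 0-based half-open when the panel is built).
GREM1_INTERVALS: list[tuple[int, int, str]] = [
    (32_964_939, 33_004_759, "40kb promoter duplication"),
    (32_975_886, 33_033_276, "57kb promoter duplication"),
    (32_986_220, 33_002_449, "16kb promoter duplication"),
]

# Synthetic size of the single EPCAM exon-9 CNV target (bp); the assay
# reports only large deletions including this exon.
EPCAM_EXON9_BP = 200

# Spacing between consecutive synthetic exon targets of one gene (bp).
INTRON_GAP_BP = 2000

# Offset separating consecutive genes placed on the same chromosome (bp).
GENE_SPACING_BP = 1_000_000

# First ~120 bp of the AluY consensus; used to build synthetic junction
# sequences for the known insertion sites (the true junctions are not
# published).
ALUY_CONSENSUS_PREFIX = (
    "GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCGGGCGGA"
    "TCACGAGGTCAGGAGATCGAGACCATCCCGGCTAAAACGGTGAAACCCCGTCTCTACTAA"
)

# The four unique Alu insertion variants confirmed in the assay's
# validation (gene, anchoring exon(s), HGVS-style label).  Positions are
# resolved against the synthetic panel coordinates at build time.
ALU_VARIANTS: list[dict] = [
    {
        "gene": "ATM",
        "kind": "intron",
        "exon_before": 54,
        "exon_after": 55,
        "name": "ATM NM_000051.3:c.8010+13_8010+14insAlu (intron 54-55)",
    },
    {
        "gene": "BRCA2",
        "kind": "exon",
        "exon": 3,
        "name": "BRCA2 NM_000059.3:c.156_157insAlu (exon 3)",
    },
    {
        "gene": "BRCA2",
        "kind": "exon",
        "exon": 25,
        "name": "BRCA2 NM_000059.3:c.930_931insAlu (exon 25)",
    },
    {
        "gene": "MSH6",
        "kind": "intron",
        "exon_before": 2,
        "exon_after": 3,
        "name": "MSH6 NM_000179:c.458-19_458-18insAlu (intron 2-3)",
    },
]
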