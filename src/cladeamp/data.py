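"""Published gyrB primer sets and their sequencing performance summaries.

Two generations of clade-specific degenerate gyrB primers for three gut
bacterial families are bundled as reference inputs: the "Moeller"
short-read sets (MiSeq-scale amplicons, Illumina overhangs) and the
"Nichols" long-read sets (PacBio-scale amplicons, amine-modified PacBio
overhangs).  Overhang strings are adapter sequence only: they are
concatenated at report time and never take part in matching or degeneracy
scoring.  ``/5AmMC6/`` is a 5' amino modifier required for PacBio library
preparation, not nucleotide sequence.

``READ_SUMMARIES`` records the published per-primer-set read accounting
from sequencing eight samples (five human fecal, two murine cecal, one
mock community): ASV and read totals, on-/off-target splits, and the
off-target rate (percent of off-target reads among QC-passing reads).
"""

from __future__ import annotations

ILLUMINA_OVERHANG_FWD = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
ILLUMINA_OVERHANG_REV = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"
PACBIO_OVERHANG_FWD = "/5AmMC6/GCAGTCGAACATGTAGCTGACTCAGGTCAC"
PACBIO_OVERHANG_REV = "/5AmMC6/TGGATCACTTGTGCAAGCATCACATCGTAG"

FAMILIES = ("Bacteroidaceae", "Bifidobacteriaceae", "Lachnospiraceae")

#: Short-read gyrB primer pairs (band sizes in bp, including overhangs as
#: printed in the source table for these sets).
MOELLER_PRIMERS: dict[str, dict] = {
    "Bacteroidaceae": {
        "forward": "CGGAGGTAARTTCGAYAAAGG",
        "reverse": "GCRTATTTYTTCARHGTACGG",
        "overhang_fwd": ILLUMINA_OVERHANG_FWD,
        "overhang_rev": ILLUMINA_OVERHANG_REV,
        "amplicon_size": 608,
    },
    "Bifidobacteriaceae": {
        "forward": "GACRACGGNCGNGGCATYCC",
        "reverse": "AGNCCCTTGTTNAGGAAVGCC",
        "overhang_fwd": ILLUMINA_OVERHANG_FWD,
        "overhang_rev": ILLUMINA_OVERHANG_REV,
        "amplicon_size": 395,
    },
    "Lachnospiraceae": {
        "forward": "GGHGGAGGATAYAAGGTATCC",
        "reverse": "TRTANGAATCRTTRTGCTGC",
        "overhang_fwd": ILLUMINA_OVERHANG_FWD,
        "overhang_rev": ILLUMINA_OVERHANG_REV,
        "amplicon_size": 502,
    },
}

#: Long-read gyrB primer pairs designed with the 16S-identity-map /
#: codon-window consensus workflow this package implements.
NICHOLS_PRIMERS: dict[str, dict] = {
    "Bacteroidaceae": {
        "name": "NPB-Bacter",
        "forward": "TGTAYATYGGTGACATYAGYR",
        "reverse": "CCCATYARCATRGARAAGATR",
        "overhang_fwd": PACBIO_OVERHANG_FWD,
        "overhang_rev": PACBIO_OVERHANG_REV,
        "amplicon_size": 1800,
    },
    "Bifidobacteriaceae": {
        "name": "NPB-Bifido",
        "forward": "ATCGARGTSACGATTCTGCCG",
        "reverse": "GGATCCATGGTGGTYTCCCAC",
        "overhang_fwd": PACBIO_OVERHANG_FWD,
        "overhang_rev": PACBIO_OVERHANG_REV,
        "amplicon_size": 1678,
    },
    "Lachnospiraceae": {
        "name": "NPB-Lachno",
        "forward": "SAGRGGWCTBCATCATYTRGT",
        "reverse": "TCMGGATCCATDGTBGTCTCC",
        "overhang_fwd": PACBIO_OVERHANG_FWD,
        "overhang_rev": PACBIO_OVERHANG_REV,
        "amplicon_size": 1673,
    },
}

#: Design-stage parameters used for the published long-read sets: 16S
#: identity bounds defining each family in-group, seven-codon (21 nt)
#: windows, 90% single-base consensus, greedy whole-gene scan, and the
#: degeneracy ceiling applied when short-listing candidate pairs.
DESIGN_SETTINGS = {
    "idlow": {"Bacteroidaceae": 91.0, "Bifidobacteriaceae": 95.0, "Lachnospiraceae": 92.0},
    "idhigh": 100.0,
    "codons": 7,
    "consensus": 90.0,
    "greedy": True,
    "max_degeneracy": 96,
    "reference_ids": {
        "Bacteroidaceae": "NZ_CP036539",
        "Bifidobacteriaceae": "NC_008618.1",
        "Lachnospiraceae": "NZ_LR699005",
    },
}

#: Published read accounting per primer set, summed across the eight
#: samples.  ``off_target_rate_pct`` is the printed value,
#: 100 * off_target_reads / total_qc_reads rounded to two decimals.
READ_SUMMARIES: list[dict] = [
    {
        "primer_set": "Moeller Bacteroidaceae",
        "total_asvs": 82, "on_target_asvs": 55, "off_target_asvs": 27,
        "total_reads": 913_974, "total_qc_reads": 812_985,
        "on_target_reads": 804_113, "off_target_reads": 8_872,
        "off_target_rate_pct": 1.09,
    },
    {
        "primer_set": "Nichols Bacteroidaceae",
        "total_asvs": 31, "on_target_asvs": 31, "off_target_asvs": 0,
        "total_reads": 573_128, "total_qc_reads": 346_547,
        "on_target_reads": 346_547, "off_target_reads": 0,
        "off_target_rate_pct": 0.00,
    },
    {
        "primer_set": "Moeller Bifidobacteriaceae",
        "total_asvs": 256, "on_target_asvs": 28, "off_target_asvs": 228,
        "total_reads": 2_087_611, "total_qc_reads": 707_401,
        "on_target_reads": 610_610, "off_target_reads": 96_791,
        "off_target_rate_pct": 13.68,
    },
    {
        "primer_set": "Nichols Bifidobacteriaceae",
        "total_asvs": 66, "on_target_asvs": 26, "off_target_asvs": 40,
        "total_reads": 558_651, "total_qc_reads": 262_096,
        "on_target_reads": 259_754, "off_target_reads": 2_342,
        "off_target_rate_pct": 0.89,
    },
    {
        "primer_set": "Moeller Lachnospiraceae",
        "total_asvs": 367, "on_target_asvs": 250, "off_target_asvs": 117,
        "total_reads": 1_337_115, "total_qc_reads": 1_170_397,
        "on_target_reads": 898_401, "off_target_reads": 271_996,
        "off_target_rate_pct": 23.24,
    },
    {
        "primer_set": "Nichols Lachnospiraceae",
        "total_asvs": 456, "on_target_asvs": 326, "off_target_asvs": 130,
        "total_reads": 1_331_007, "total_qc_reads": 693_009,
        "on_target_reads": 620_713, "off_target_reads": 72_296,
        "off_target_rate_pct": 10.43,
    },
]
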