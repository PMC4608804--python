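"""VCF output for SNV calls.

Internal coordinates are 0-based half-open; VCF positions are emitted
1-based at this boundary only.  Output is deterministic (fixed ordering
and float formatting), and germline rows are excluded unless requested —
a somatic report filters out the germline SNPs.
"""
from __future__ import annotations

from .panel import ReferencePanel
from .snv import SnvCall

_HEADER = """\
##fileformat=VCFv4.2
##source=cfduplex
##INFO=<ID=AF,Number=A,Type=Float,Description="Mutant allele fraction (unique molecules)">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Unique molecule depth">
##INFO=<ID=MM,Number=A,Type=Integer,Description="Mutant unique molecules">
##INFO=<ID=MD,Number=A,Type=Integer,Description="Duplex-confirmed mutant molecules">
##INFO=<ID=CLS,Number=A,Type=String,Description="Classification (somatic/germline_het/germline_hom)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: list[SnvCall], panel: ReferencePanel, path,
              report_germline: bool = False) -> None:
    """Write calls as VCF v4.2; somatic-only unless ``report_germline``."""
    for c in calls:
        lut = panel.position_lookup(c.chrom)
        if c.position >= lut.size or lut[c.position] < 0:
            raise ValueError(f"call at {c.chrom}:{c.position} outside panel")
    rows = [c for c in calls
            if report_germline or c.classification == "somatic"]
    rows.sort(key=lambda c: (c.chrom, c.position, c.alt_base))
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for c in rows:
            info = (f"AF={c.maf:.6f};DP={c.total_molecules};"
                    f"MM={c.mutant_molecules};MD={c.mutant_duplex};"
                    f"CLS={c.classification}")
            fh.write(f"{c.chrom}\t{c.position + 1}\t.\t{c.ref_base}\t"
                     f"{c.alt_base}\t.\tPASS\t{info}\n")
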