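"""Target panel definition, reference sequences and panel I/O.

A panel is an ordered set of exon-level regions with gene labels, backed by
per-region reference sequences.  Internal coordinates are 0-based half-open
throughout; 1-based coordinates appear only at the VCF boundary.

The synthetic default panel emulates a pan-cancer liquid-biopsy design:
54 genes totalling 78 kbp, with complete exon coverage for a subset of
genes and critical-exon coverage for the remainder, plus focal-amplification
reporting for *EGFR*, *ERBB2* and *MET*.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._bases import decode_seq, encode_seq, random_reference

COVERAGE_CLASSES = ("complete_exon", "critical_exon")

#: Genes whose focal amplification is reported by the copy-number caller.
CNV_GENES = ("EGFR", "ERBB2", "MET")

# 54 recurrently altered cancer genes used for synthetic panels; the three
# copy-number genes lead so that small test panels always include them.
_GENE_NAMES = (
    "EGFR", "ERBB2", "MET", "ABL1", "AKT1", "ALK", "APC", "AR", "ARID1A",
    "ATM", "BRAF", "BRCA1", "BRCA2", "CCND1", "CDH1", "CDK4", "CDK6",
    "CDKN2A", "CTNNB1", "ESR1", "EZH2", "FBXW7", "FGFR1", "FGFR2", "FGFR3",
    "GATA3", "GNA11", "GNAQ", "GNAS", "HNF1A", "HRAS", "IDH1", "IDH2",
    "JAK2", "JAK3", "KIT", "KRAS", "MAP2K1", "MLH1", "MPL", "MYC", "NF1",
    "NOTCH1", "NPM1", "NRAS", "PDGFRA", "PIK3CA", "PTEN", "PTPN11", "RB1",
    "RET", "SMAD4", "SMO", "TP53",
)

#: Flank kept around every region so that simulated fragments (including
#: long genomic-DNA contaminants up to ~1.5 kb) never run off the reference.
FLANK = 1700


@dataclasses.dataclass(frozen=True)
class PanelRegion:
    """One targeted region (typically an exon) of the panel."""

    gene_symbol: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    exon_label: str = "e1"
    coverage_class: str = "complete_exon"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region end must exceed start: {self}")
        if self.start < 0:
            raise ValueError(f"negative region start: {self}")
        if self.coverage_class not in COVERAGE_CLASSES:
            raise ValueError(f"unknown coverage class {self.coverage_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class ReferencePanel:
    """Ordered panel regions plus their reference sequences.

    Parameters
    ----------
    regions
        Panel regions; stored sorted by (chrom, start).
    sequences
        One A/C/G/T string per region, same order as ``regions``.
    genome
        Optional dense reference per chromosome (uint8 base codes) covering
        every region plus flanks; built on demand for simulation.
    """

    def __init__(self, regions, sequences, genome=None):
        order = sorted(range(len(regions)),
                       key=lambda i: (regions[i].chrom, regions[i].start))
        self.regions: list[PanelRegion] = [regions[i] for i in order]
        self.sequences: list[str] = [sequences[i] for i in order]
        self.genome: dict[str, np.ndarray] | None = genome
        self._validate()
        self._lookup: dict[str, np.ndarray] = {}
        self._ref_codes: np.ndarray | None = None

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        if not self.regions:
            raise ValueError("panel must contain at least one region")
        for r, s in zip(self.regions, self.sequences):
            if len(s) != r.length:
                raise ValueError(
                    f"sequence length {len(s)} != region length {r.length} for {r}"
                )
        prev: PanelRegion | None = None
        for r in self.regions:
            if prev is not None and r.chrom == prev.chrom and r.start < prev.end:
                raise ValueError(
                    f"overlapping regions on {r.chrom}: {prev} and {r}"
                )
            prev = r

    # -- basic properties ------------------------------------------------
    @property
    def total_length_bp(self) -> int:
        return sum(r.length for r in self.regions)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.gene_symbol, None)
        return list(seen)

    def gene_regions(self, gene: str) -> list[PanelRegion]:
        out = [r for r in self.regions if r.gene_symbol == gene]
        if not out:
            raise KeyError(f"gene {gene!r} not on panel")
        return out

    def gene_length(self, gene: str) -> int:
        return sum(r.length for r in self.gene_regions(gene))

    def gene_gc(self, gene: str) -> float:
        """GC fraction over a gene's panel bases."""
        n_gc = n = 0
        for r, s in zip(self.regions, self.sequences):
            if r.gene_symbol == gene:
                n_gc += s.count("G") + s.count("C")
                n += len(s)
        return n_gc / n

    # -- coordinate mapping ----------------------------------------------
    def position_lookup(self, chrom: str) -> np.ndarray:
        """Dense genomic-position -> panel-index map for one chromosome.

        Entries outside the panel are -1.  Panel indices run 0..total_length
        in region-sorted order across all chromosomes.
        """
        if chrom not in self._lookup:
            offset = 0
            per_chrom: dict[str, list[tuple[int, int, int]]] = {}
            for r in self.regions:
                per_chrom.setdefault(r.chrom, []).append((r.start, r.end, offset))
                offset += r.length
            if chrom not in per_chrom:
                raise KeyError(f"chromosome {chrom!r} not on panel")
            extent = max(e for _, e, _ in per_chrom[chrom]) + 1
            lut = np.full(extent, -1, dtype=np.int64)
            for s, e, off in per_chrom[chrom]:
                lut[s:e] = np.arange(off, off + (e - s))
            self._lookup[chrom] = lut
        return self._lookup[chrom]

    def panel_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(chrom index array, genomic position array) per panel base."""
        chroms = []
        pos = []
        for i, r in enumerate(self.regions):
            chroms.append(np.full(r.length, i))
            pos.append(np.arange(r.start, r.end))
        return np.concatenate(chroms), np.concatenate(pos)

    def ref_codes(self) -> np.ndarray:
        """Reference base code per panel index."""
        if self._ref_codes is None:
            self._ref_codes = np.concatenate([encode_seq(s) for s in self.sequences])
        return self._ref_codes

    def region_of_panel_index(self) -> np.ndarray:
        """Region index per panel base (for per-gene aggregation)."""
        return np.repeat(np.arange(len(self.regions)),
                         [r.length for r in self.regions])

    # -- genome ----------------------------------------------------------
    def ensure_genome(self, seed: int = 0) -> dict[str, np.ndarray]:
        """Build (or return) a dense reference with random flank sequence.

        Region spans always carry the panel's own sequences; only the
        inter-region/flank filler is random (seeded, hence reproducible).
        """
        if self.genome is None:
            rng = np.random.default_rng(seed)
            genome: dict[str, np.ndarray] = {}
            for chrom in {r.chrom for r in self.regions}:
                extent = max(r.end for r in self.regions if r.chrom == chrom) + FLANK
                genome[chrom] = random_reference(extent, rng)
            for r, s in zip(self.regions, self.sequences):
                genome[r.chrom][r.start:r.end] = encode_seq(s)
            self.genome = genome
        return self.genome


# -- panel I/O (6-column BED-like TSV + FASTA) ---------------------------

def read_panel(bed_path: str | Path, fasta_path: str | Path) -> ReferencePanel:
    """Load a panel from a BED-like TSV and a companion FASTA.

    The TSV has six tab-separated columns and no header:
    chrom, start, end, gene_symbol, exon_label, coverage_class.
    FASTA records are named ``{chrom}:{start}-{end}``.
    """
    regions: list[PanelRegion] = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"expected 6 columns, got {len(fields)}: {line!r}")
            chrom, start, end, gene, exon, cls = fields
            regions.append(PanelRegion(gene, chrom, int(start), int(end), exon, cls))
    if not regions:
        raise ValueError(f"no records in {bed_path}")
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    sequences = []
    for r in regions:
        key = f"{r.chrom}:{r.start}-{r.end}"
        if key not in seqs:
            raise ValueError(f"missing FASTA record {key!r}")
        sequences.append(seqs[key])
    return ReferencePanel(regions, sequences)


def write_panel(panel: ReferencePanel, bed_path: str | Path, fasta_path: str | Path) -> None:
    """Write a panel back to the BED-like TSV + FASTA pair."""
    with open(bed_path, "w") as fh:
        for r in panel.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_symbol}"
                     f"\t{r.exon_label}\t{r.coverage_class}\n")
    records = [
        SeqRecord(Seq(s), id=f"{r.chrom}:{r.start}-{r.end}", description="")
        for r, s in zip(panel.regions, panel.sequences)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def synthetic_panel(
    n_genes: int = 54,
    total_bp: int = 78_000,
    n_complete: int = 18,
    seed: int = 0,
    gap: int = FLANK,
) -> ReferencePanel:
    """Build a synthetic target panel with an attached random reference.

    Defaults emulate the assay scale this package models: 54 genes and a
    78 kbp cumulative target, with complete-exon coverage for 18 genes.
    Gene symbols are real cancer genes so that the copy-number genes
    (EGFR/ERBB2/MET) are always present; exon structure is synthetic.
    Smaller ``n_genes``/``total_bp`` give fast desk-scale panels.
    """
    if not 1 <= n_genes <= len(_GENE_NAMES):
        raise ValueError(f"n_genes must be in [1, {len(_GENE_NAMES)}]")
    rng = np.random.default_rng(seed)
    base = total_bp // n_genes
    lengths = np.full(n_genes, base, dtype=int)
    lengths[: total_bp - base * n_genes] += 1  # exact total

    regions: list[PanelRegion] = []
    cursor = FLANK
    chrom = "chrS"
    for gi in range(n_genes):
        gene = _GENE_NAMES[gi]
        cls = "complete_exon" if gi < n_complete else "critical_exon"
        n_exons = min(1 + gi % 3, max(1, lengths[gi] // 60))
        cuts = np.linspace(0, lengths[gi], n_exons + 1).astype(int)
        for ei in range(n_exons):
            ex_len = int(cuts[ei + 1] - cuts[ei])
            regions.append(PanelRegion(gene, chrom, cursor, cursor + ex_len,
                                       f"e{ei + 1}", cls))
            cursor += ex_len + gap
    extent = cursor + FLANK
    genome = {chrom: random_reference(extent, rng)}
    sequences = [decode_seq(genome[chrom][r.start:r.end]) for r in regions]
    return ReferencePanel(regions, sequences, genome=genome)
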