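"""Synthetic cfDNA generator: duplex molecules, PCR, sequencing errors.

Models the statistical structure the duplex-consensus method relies on:

* double-stranded cfDNA fragments (~166 bp) drawn to a target unique-molecule
  depth per panel position;
* non-unique heptamer strand barcodes; molecule identity is the composite
  (barcode pair, start, end), so barcode collisions are possible and rare;
* germline SNPs (het/hom), low-fraction somatic SNVs, focal gene
  amplification via the germline/tumor mixture, and long (>500 bp)
  genomic-DNA contamination carrying germline alleles only;
* molecule-to-library conversion (default 80%), PCR duplication with
  per-strand read families, PCR-lineage ("jackpot") errors confined to one
  strand, uniform per-base sequencing errors and base qualities.

Reads are emitted in reference orientation; the Watson/Crick label records
which physical strand a read family derives from, which is all the duplex
comparison needs.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._bases import N_BARCODES, decode_seq
from .panel import ReferencePanel

#: Mass of one haploid genome copy in nanograms (3.3 pg).
HAPLOID_GENOME_MASS_NG = 0.0033

ORIGIN_GERMLINE, ORIGIN_TUMOR, ORIGIN_GDNA = 0, 1, 2
ORIGIN_NAMES = ("germline", "tumor", "gdna")

VARIANT_KINDS = ("germline_het", "germline_hom", "somatic")


def genome_copies_from_mass(mass_ng: float, rounded: bool = False) -> float:
    """Haploid genome copies equivalent to a cfDNA input mass.

    With ``rounded`` the value is reported to the nearest hundred copies,
    the convention used for assay input ranges (5 ng -> 1,500 copies).
    """
    if mass_ng <= 0:
        raise ValueError(f"input mass must be positive, got {mass_ng}")
    copies = mass_ng / HAPLOID_GENOME_MASS_NG
    if rounded:
        return float(round(copies / 100.0) * 100)
    return copies


@dataclasses.dataclass(frozen=True)
class GroundTruthVariant:
    """A truth SNV placed on the panel (genomic coordinates, 0-based)."""

    chrom: str
    position: int
    ref_base: str
    alt_base: str
    kind: str  # germline_het | germline_hom | somatic
    true_maf: float | None = None  # somatic only

    def __post_init__(self) -> None:
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")
        if self.kind == "somatic":
            if self.true_maf is None or not 0 < self.true_maf <= 0.5:
                raise ValueError("somatic true_maf must lie in (0, 0.5]")


@dataclasses.dataclass(frozen=True)
class GeneAmpTruth:
    """Truth focal amplification of one gene in the tumor compartment."""

    gene_symbol: str
    tumor_copy_number: float
    germline_copy_number: float = 2.0

    def __post_init__(self) -> None:
        if self.tumor_copy_number < self.germline_copy_number:
            raise ValueError("amplification requires tumor CN >= germline CN")


@dataclasses.dataclass
class SimParams:
    """Simulation parameters (study-condition defaults).

    molecules_per_position
        Target unique-molecule coverage (haploid genome equivalents
        overlapping each panel base); 3,000 matches the assay's minimum
        average unique coverage.
    fragment_length_mean / sd
        cfDNA fragment size law, centred on 166 bp.
    conversion_efficiency
        Probability a molecule is recovered in the library with both
        strands (default 0.80).
    pcr_duplicate_mean
        Mean reads per strand family, 1 + Poisson(mean-1); 1.7 reproduces
        an ~8,000x raw over ~4,800 strand-family depth ratio.
    per_base_error_rate
        Uniform sequencing error probability per read base (Q30-scale).
    pcr_lineage_error_rate
        Per base per strand family, probability of a PCR "jackpot" error
        shared by a subset of that strand's reads.
    low_quality_fraction
        Fraction of bases drawn below Q20 (masked by read filtering).
    gdna_ratio
        Mass ratio of long (>500 bp) genomic-DNA contaminant to cfDNA.
    region_efficiency
        Optional per-gene capture-efficiency multipliers (bias injection).
    """

    molecules_per_position: float = 3000.0
    tumor_fraction: float = 0.0
    fragment_length_mean: float = 166.0
    fragment_length_sd: float = 10.0
    conversion_efficiency: float = 0.80
    pcr_duplicate_mean: float = 1.7
    per_base_error_rate: float = 1e-3
    pcr_lineage_error_rate: float = 1e-5
    low_quality_fraction: float = 0.01
    gdna_ratio: float = 0.0
    gdna_length_range: tuple[float, float] = (600.0, 1500.0)
    region_efficiency: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name in ("tumor_fraction", "conversion_efficiency",
                     "per_base_error_rate", "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.molecules_per_position < 1:
            raise ValueError("molecules_per_position must be >= 1")
        if self.pcr_duplicate_mean < 1:
            raise ValueError("pcr_duplicate_mean must be >= 1")


@dataclasses.dataclass
class MoleculeBatch:
    """Ground-truth duplex molecules for one sample (array-of-columns)."""

    chrom: str
    start: np.ndarray          # int64 (n,)
    end: np.ndarray            # int64 (n,)
    origin: np.ndarray         # uint8 (n,)
    barcode_w: np.ndarray      # int32 (n,) heptamer codes
    barcode_c: np.ndarray      # int32 (n,)
    # truth substitutions: (genomic position, alt code, carrier mask over molecules)
    variants: list[tuple[int, int, np.ndarray]] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return self.start.size

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def barcode_collision_rate(self) -> float:
        """Fraction of molecules sharing (barcode pair, start, end) with another."""
        if len(self) == 0:
            return 0.0
        key = ((self.barcode_w.astype(np.int64) * N_BARCODES + self.barcode_c)
               * (self.end.max() + 1) + self.start) * (self.lengths.max() + 1) \
            + self.lengths
        _, counts = np.unique(key, return_counts=True)
        return float((counts > 1) @ counts / len(self))


@dataclasses.dataclass
class ReadBatch:
    """Sequenced reads in reference orientation (ragged CSR layout)."""

    chrom: str
    barcode_w: np.ndarray   # int32 (n,)
    barcode_c: np.ndarray   # int32 (n,)
    start: np.ndarray       # int64 (n,)
    end: np.ndarray         # int64 (n,)
    strand: np.ndarray      # uint8 (n,) 0=watson 1=crick
    bases: np.ndarray       # uint8 flat
    quals: np.ndarray       # uint8 flat (phred)
    offsets: np.ndarray     # int64 (n+1,)
    mol_index: np.ndarray | None = None  # truth provenance, None if file-loaded

    def __len__(self) -> int:
        return self.start.size

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def read_seq(self, i: int) -> str:
        return decode_seq(self.bases[self.offsets[i]:self.offsets[i + 1]])

    def read_quals(self, i: int) -> np.ndarray:
        return self.quals[self.offsets[i]:self.offsets[i + 1]]


def _csr_offsets(lengths: np.ndarray) -> np.ndarray:
    out = np.zeros(lengths.size + 1, dtype=np.int64)
    np.cumsum(lengths, out=out[1:])
    return out


def _ragged_ranges(first: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Concatenation of arange(first[i], first[i] + lengths[i]) for all i.

    Built with a single cumsum instead of ragged ``np.repeat`` (which is
    the dominant cost at tens of millions of bases).  Requires every
    length to be positive.
    """
    offsets = _csr_offsets(lengths)
    total = int(offsets[-1])
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    out[0] = first[0]
    out[offsets[1:-1]] = first[1:] - (first[:-1] + lengths[:-1] - 1)
    return np.cumsum(out)


def plasma_copy_number_expected(amp: GeneAmpTruth, tumor_fraction: float) -> float:
    """Expected plasma CN under the germline/tumor mixture."""
    f = tumor_fraction
    return (1 - f) * amp.germline_copy_number + f * amp.tumor_copy_number


def draw_molecules(
    panel: ReferencePanel,
    variants: Sequence[GroundTruthVariant],
    amps: Sequence[GeneAmpTruth],
    params: SimParams,
    rng: np.random.Generator,
) -> MoleculeBatch:
    """Draw ground-truth duplex cfDNA molecules over the panel.

    Fragment starts are uniform over each region's window so unique-molecule
    coverage is ~``molecules_per_position`` at every panel base.  Somatic
    variants are carried by cfDNA molecules covering their position with
    probability ``true_maf`` (those molecules become tumor-origin); germline
    het alleles split Binomial(n, 1/2) over all molecules including gDNA
    contaminants; amplified genes draw extra tumor-origin molecules so the
    expected plasma copy number is ``(1-f)·g + f·t``.
    """
    panel.ensure_genome()
    chroms = {r.chrom for r in panel.regions}
    if len(chroms) != 1:
        raise NotImplementedError("simulation supports single-chromosome panels")
    chrom = chroms.pop()
    for v in variants:
        lut = panel.position_lookup(v.chrom)
        if v.position >= lut.size or lut[v.position] < 0:
            raise ValueError(f"variant position {v.position} outside panel")
    amp_by_gene = {a.gene_symbol: a for a in amps}
    for g in amp_by_gene:
        panel.gene_regions(g)  # raises if absent

    fl = params.fragment_length_mean
    f = params.tumor_fraction
    starts_parts, ends_parts, origin_parts = [], [], []
    for r in panel.regions:
        eff = 1.0
        if params.region_efficiency:
            eff = params.region_efficiency.get(r.gene_symbol, 1.0)
        amp = amp_by_gene.get(r.gene_symbol)
        if amp is not None:
            plasma_cn = plasma_copy_number_expected(amp, f)
            cn_mult = plasma_cn / amp.germline_copy_number
            tumor_frac_mol = (f * amp.tumor_copy_number) / (
                (1 - f) * amp.germline_copy_number + f * amp.tumor_copy_number)
        else:
            cn_mult = 1.0
            tumor_frac_mol = f
        window = r.length + fl
        n_cf = int(round(params.molecules_per_position * window / fl * cn_mult * eff))
        lens = np.clip(np.round(rng.normal(fl, params.fragment_length_sd, n_cf)),
                       50, None).astype(np.int64)
        starts = rng.integers(r.start - int(fl), r.end, size=n_cf)
        origin = np.where(rng.random(n_cf) < tumor_frac_mol,
                          ORIGIN_TUMOR, ORIGIN_GERMLINE).astype(np.uint8)
        starts_parts.append(starts)
        ends_parts.append(starts + lens)
        origin_parts.append(origin)
        if params.gdna_ratio > 0:
            lo, hi = params.gdna_length_range
            mean_gdna = 0.5 * (lo + hi)
            n_gdna = int(round(params.gdna_ratio * n_cf * fl / mean_gdna))
            glens = rng.integers(int(lo), int(hi) + 1, size=n_gdna)
            gstarts = rng.integers(r.start - int(hi), r.end, size=n_gdna)
            starts_parts.append(gstarts)
            ends_parts.append(gstarts + glens)
            origin_parts.append(np.full(n_gdna, ORIGIN_GDNA, dtype=np.uint8))

    start = np.concatenate(starts_parts)
    end = np.concatenate(ends_parts)
    origin = np.concatenate(origin_parts)
    np.clip(start, 0, None, out=start)
    extent = panel.genome[chrom].size
    np.clip(end, None, extent, out=end)
    n = start.size

    mols = MoleculeBatch(
        chrom=chrom,
        start=start,
        end=end,
        origin=origin,
        barcode_w=rng.integers(0, N_BARCODES, size=n, dtype=np.int32),
        barcode_c=rng.integers(0, N_BARCODES, size=n, dtype=np.int32),
    )

    ref = panel.genome[chrom]
    base_code = {b: i for i, b in enumerate("ACGT")}
    for v in variants:
        if base_code[v.ref_base] != ref[v.position]:
            raise ValueError(
                f"truth ref {v.ref_base} != panel reference at {v.position}")
        covers = (start <= v.position) & (end > v.position)
        if v.kind == "germline_hom":
            carriers = covers
        elif v.kind == "germline_het":
            carriers = covers & (rng.random(n) < 0.5)
        else:  # somatic: cfDNA only, never the gDNA contaminant
            carriers = covers & (origin != ORIGIN_GDNA) \
                & (rng.random(n) < v.true_maf)
            origin[carriers] = ORIGIN_TUMOR
        mols.variants.append((v.position, base_code[v.alt_base], carriers))
    return mols


def amplify_and_sequence(
    panel: ReferencePanel,
    mols: MoleculeBatch,
    params: SimParams,
    rng: np.random.Generator,
) -> ReadBatch:
    """Convert, PCR-amplify and sequence a molecule batch into reads.

    Each molecule converts with probability ``conversion_efficiency``;
    converted molecules emit per-strand families of 1 + Poisson(mean-1)
    reads.  PCR-lineage errors hit a random subset of one strand's family;
    sequencing errors flip single bases uniformly; base qualities are
    two-valued with ``low_quality_fraction`` below Q20.
    """
    genome = panel.ensure_genome()[mols.chrom]
    n_mol = len(mols)
    converted = rng.random(n_mol) < params.conversion_efficiency
    fam = np.zeros((n_mol, 2), dtype=np.int64)
    k = int(converted.sum())
    extra = params.pcr_duplicate_mean - 1.0
    for s in (0, 1):
        fam[converted, s] = 1 + rng.poisson(extra, size=k)

    reads_per_mol = fam.sum(axis=1)
    n_reads = int(reads_per_mol.sum())
    read_mol = np.repeat(np.arange(n_mol), reads_per_mol)
    first_read = _csr_offsets(reads_per_mol)
    within = np.arange(n_reads) - np.repeat(first_read[:-1], reads_per_mol)
    strand = (within >= np.repeat(fam[:, 0], reads_per_mol)).astype(np.uint8)

    lengths = mols.lengths[read_mol]
    offsets = _csr_offsets(lengths)
    total = int(offsets[-1])
    pos_index = _ragged_ranges(mols.start[read_mol], lengths)
    bases = genome[pos_index]

    # truth substitutions (shared by every read of a carrier molecule)
    for vpos, valt, carriers in mols.variants:
        rows = np.flatnonzero(carriers[read_mol]
                              & (mols.start[read_mol] <= vpos)
                              & (mols.end[read_mol] > vpos))
        if rows.size:
            bases[offsets[rows] + (vpos - mols.start[read_mol[rows]])] = valt

    # PCR-lineage ("jackpot") errors: one strand, a random subset of its reads
    if params.pcr_lineage_error_rate > 0:
        lam = params.pcr_lineage_error_rate * mols.lengths[:, None] * (fam > 0)
        events = rng.poisson(lam)
        for m, s in zip(*np.nonzero(events)):
            for _ in range(events[m, s]):
                size = fam[m, s]
                j = int(rng.integers(0, mols.lengths[m]))
                lineage = 1 if size == 1 else 1 + int(rng.binomial(size - 1, 0.5))
                row0 = first_read[m] + (0 if s == 0 else fam[m, 0])
                rows = row0 + rng.permutation(size)[:lineage]
                idx = offsets[rows] + j
                bases[idx] = (bases[idx] + rng.integers(1, 4)) % 4

    # uniform sequencing errors
    if params.per_base_error_rate > 0:
        err = np.flatnonzero(rng.random(total) < params.per_base_error_rate)
        bases[err] = (bases[err] + rng.integers(1, 4, size=err.size)) % 4

    quals = np.where(rng.random(total) < params.low_quality_fraction, 11, 37) \
        .astype(np.uint8)

    return ReadBatch(
        chrom=mols.chrom,
        barcode_w=mols.barcode_w[read_mol],
        barcode_c=mols.barcode_c[read_mol],
        start=mols.start[read_mol],
        end=mols.end[read_mol],
        strand=strand,
        bases=bases,
        quals=quals,
        offsets=offsets,
        mol_index=read_mol,
    )


def simulate_sample(
    panel: ReferencePanel,
    variants: Sequence[GroundTruthVariant],
    amps: Sequence[GeneAmpTruth],
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[MoleculeBatch, ReadBatch]:
    """Convenience: draw molecules and sequence them in one call."""
    mols = draw_molecules(panel, variants, amps, params, rng)
    reads = amplify_and_sequence(panel, mols, params, rng)
    return mols, reads


def random_germline_variants(
    panel: ReferencePanel,
    rng: np.random.Generator,
    snps_range: tuple[int, int] = (12, 27),
    het_fraction: float = 2 / 3,
) -> list[GroundTruthVariant]:
    """Draw a donor's germline SNP set: 12-27 SNPs per sample by default."""
    panel.ensure_genome()
    _, pos = panel.panel_positions()
    ref = panel.ref_codes()
    chrom = panel.regions[0].chrom
    k = int(rng.integers(snps_range[0], snps_range[1] + 1))
    idx = rng.choice(pos.size, size=min(k, pos.size), replace=False)
    out = []
    for i in np.sort(idx):
        r = int(ref[i])
        alt = (r + int(rng.integers(1, 4))) % 4
        kind = "germline_het" if rng.random() < het_fraction else "germline_hom"
        out.append(GroundTruthVariant(chrom, int(pos[i]), "ACGT"[r],
                                      "ACGT"[alt], kind))
    return out


def make_validation_cohort(
    panel: ReferencePanel,
    params: SimParams,
    n_normal: int,
    rng: np.random.Generator,
    snps_range: tuple[int, int] = (12, 27),
) -> list[dict]:
    """Simulate a Normal Set: germline-only, diploid, no somatic content.

    Returns one dict per sample with ``variants`` (truth germline SNPs),
    ``molecules`` and ``reads``.
    """
    if n_normal < 2:
        raise ValueError("a normal cohort needs at least 2 samples")
    cohort = []
    for _ in range(n_normal):
        truth = random_germline_variants(panel, rng, snps_range)
        normal = dataclasses.replace(params, tumor_fraction=0.0)
        mols, reads = simulate_sample(panel, truth, [], normal, rng)
        cohort.append({"variants": truth, "molecules": mols, "reads": reads})
    return cohort


# -- read serialization --------------------------------------------------

def write_reads_tsv(reads: ReadBatch, path) -> None:
    """Write reads as an aligned-read TSV (documented dialect)."""
    from ._bases import barcode_to_str
    with open(path, "w") as fh:
        fh.write("barcode_w\tbarcode_c\tchrom\tstart\tend\tstrand\tseq\tqual\n")
        for i in range(len(reads)):
            q = "".join(chr(33 + int(x)) for x in reads.read_quals(i))
            fh.write(
                f"{barcode_to_str(int(reads.barcode_w[i]))}\t"
                f"{barcode_to_str(int(reads.barcode_c[i]))}\t"
                f"{reads.chrom}\t{reads.start[i]}\t{reads.end[i]}\t"
                f"{'WC'[reads.strand[i]]}\t{reads.read_seq(i)}\t{q}\n")


def read_reads_tsv(path) -> ReadBatch:
    """Load reads from the aligned-read TSV dialect."""
    from ._bases import barcode_from_str, encode_seq
    bw, bc, starts, ends, strands, base_parts, qual_parts = [], [], [], [], [], [], []
    chrom = None
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("barcode_w"):
            raise ValueError("not a cfduplex read TSV")
        for line in fh:
            w, c, ch, s, e, st, seq, q = line.rstrip("\n").split("\t")
            chrom = ch
            bw.append(barcode_from_str(w))
            bc.append(barcode_from_str(c))
            starts.append(int(s))
            ends.append(int(e))
            strands.append(0 if st == "W" else 1)
            base_parts.append(encode_seq(seq))
            qual_parts.append(np.frombuffer(q.encode(), dtype=np.uint8) - 33)
    lengths = np.array([b.size for b in base_parts], dtype=np.int64)
    return ReadBatch(
        chrom=chrom or "chrS",
        barcode_w=np.array(bw, dtype=np.int32),
        barcode_c=np.array(bc, dtype=np.int32),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands, dtype=np.uint8),
        bases=np.concatenate(base_parts) if base_parts else np.empty(0, np.uint8),
        quals=np.concatenate(qual_parts).astype(np.uint8) if qual_parts
        else np.empty(0, np.uint8),
        offsets=_csr_offsets(lengths),
    )


def write_fastq(reads: ReadBatch, path) -> None:
    """Write reads as annotated FASTQ: name carries barcodes/coordinates.

    Name dialect: ``cf|{bw}|{bc}|{chrom}|{start}|{end}|{W or C}|{serial}``.
    Sequences are stored in reference orientation.
    """
    from ._bases import barcode_to_str
    with open(path, "w") as fh:
        for i in range(len(reads)):
            name = (f"cf|{barcode_to_str(int(reads.barcode_w[i]))}"
                    f"|{barcode_to_str(int(reads.barcode_c[i]))}"
                    f"|{reads.chrom}|{reads.start[i]}|{reads.end[i]}"
                    f"|{'WC'[reads.strand[i]]}|{i}")
            q = "".join(chr(33 + int(x)) for x in reads.read_quals(i))
            fh.write(f"@{name}\n{reads.read_seq(i)}\n+\n{q}\n")


def read_fastq(path) -> ReadBatch:
    """Load reads from the annotated FASTQ dialect."""
    from ._bases import barcode_from_str, encode_seq
    bw, bc, starts, ends, strands, base_parts, qual_parts = [], [], [], [], [], [], []
    chrom = None
    with open(path) as fh:
        while True:
            name = fh.readline().strip()
            if not name:
                break
            seq = fh.readline().strip()
            fh.readline()
            q = fh.readline().strip()
            parts = name[1:].split("|")
            if len(parts) != 8 or parts[0] != "cf":
                raise ValueError(f"not a cfduplex FASTQ name: {name!r}")
            _, w, c, ch, s, e, st, _ = parts
            chrom = ch
            bw.append(barcode_from_str(w))
            bc.append(barcode_from_str(c))
            starts.append(int(s))
            ends.append(int(e))
            strands.append(0 if st == "W" else 1)
            base_parts.append(encode_seq(seq))
            qual_parts.append(np.frombuffer(q.encode(), dtype=np.uint8) - 33)
    lengths = np.array([b.size for b in base_parts], dtype=np.int64)
    return ReadBatch(
        chrom=chrom or "chrS",
        barcode_w=np.array(bw, dtype=np.int32),
        barcode_c=np.array(bc, dtype=np.int32),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands, dtype=np.uint8),
        bases=np.concatenate(base_parts) if base_parts else np.empty(0, np.uint8),
        quals=np.concatenate(qual_parts).astype(np.uint8) if qual_parts
        else np.empty(0, np.uint8),
        offsets=_csr_offsets(lengths),
    )
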