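"""Reconstruction of unique cfDNA molecules from barcoded reads.

The digitization stage turns raw reads back into the set of progenitor
double-stranded molecules: reads are quality-filtered, partitioned into
strand families by the exact composite key (barcode pair, start, end,
strand), each family is collapsed to a per-position supermajority
consensus, and the two strand consensi of a molecule are compared
position-by-position.  A base call survives as *duplex-confirmed* only if
both strands independently agree; a call seen on one strand only is kept
but flagged; disagreeing strands yield no call.  This duplex veto is what
removes PCR-lineage ("jackpot") errors and sequencing errors, which are
confined to a single strand.

Molecule identity is the composite key without the strand field.  Barcodes
are non-unique heptamers, so two distinct molecules with identical
coordinates can collide on the same key and merge; the collision rate is
measurable via :meth:`cfduplex.simulate.MoleculeBatch.barcode_collision_rate`
and is negligible at realistic depths.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from ._bases import MASK, N_BARCODES, decode_seq, encode_seq
from .panel import ReferencePanel
from .simulate import ReadBatch, _csr_offsets, _ragged_ranges

# per-position duplex status codes
DUPLEX_CONFIRMED, SINGLE_STRAND_ONLY, DISCORDANT_NO_CALL, NO_CALL = 0, 1, 2, 3
STATUS_NAMES = ("duplex_confirmed", "single_strand_only",
                "discordant_no_call", "no_call")

DEFAULT_SUPERMAJORITY = 0.75


def filter_reads(reads: ReadBatch, min_base_quality: int = 20,
                 max_masked_fraction: float = 0.5) -> ReadBatch:
    """Mask bases below the quality floor; drop mostly-masked reads.

    Bases under ``min_base_quality`` are set to the mask code and excluded
    from consensus voting.  Reads with more than ``max_masked_fraction``
    of their bases masked are removed entirely.
    """
    bases = reads.bases.copy()
    bases[reads.quals < min_base_quality] = MASK
    lengths = reads.lengths
    masked_per_read = np.add.reduceat(
        (bases == MASK).astype(np.int64), reads.offsets[:-1]) \
        if len(reads) else np.empty(0, np.int64)
    keep = masked_per_read <= max_masked_fraction * lengths
    if keep.all():
        return dataclasses.replace(reads, bases=bases)
    return _subset_reads(dataclasses.replace(reads, bases=bases),
                         np.flatnonzero(keep))


def _subset_reads(reads: ReadBatch, rows: np.ndarray) -> ReadBatch:
    """Row-subset a read batch, keeping the flat CSR layout consistent."""
    lengths = reads.lengths[rows]
    sel = _ragged_ranges(reads.offsets[:-1][rows], lengths)
    return ReadBatch(
        chrom=reads.chrom,
        barcode_w=reads.barcode_w[rows],
        barcode_c=reads.barcode_c[rows],
        start=reads.start[rows],
        end=reads.end[rows],
        strand=reads.strand[rows],
        bases=reads.bases[sel],
        quals=reads.quals[sel],
        offsets=_csr_offsets(lengths),
        mol_index=None if reads.mol_index is None else reads.mol_index[rows],
    )


@dataclasses.dataclass
class FamilySet:
    """Partition of reads into strand families by exact composite key."""

    family_of_read: np.ndarray  # int64 (n_reads,)
    barcode_w: np.ndarray       # per family
    barcode_c: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray
    sizes: np.ndarray

    @property
    def n_families(self) -> int:
        return self.start.size

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start


def _family_codes(reads: ReadBatch) -> np.ndarray:
    """Encode (bw, bc, start, end, strand) as one sortable int per read."""
    if len(reads) == 0:
        return np.empty(0, dtype=np.int64)
    span = int(reads.end.max()) + 1
    lmax = int(reads.lengths.max()) + 1
    code = reads.barcode_w.astype(np.int64)
    code = code * N_BARCODES + reads.barcode_c
    code = code * span + reads.start
    code = code * lmax + reads.lengths
    code = code * 2 + reads.strand
    return code


def group_families(reads: ReadBatch) -> FamilySet:
    """Partition reads by exact (barcode pair, start, end, strand) key.

    Families come out in deterministic lexicographic key order.
    """
    codes = _family_codes(reads)
    _, first, inverse, sizes = np.unique(
        codes, return_index=True, return_inverse=True, return_counts=True)
    return FamilySet(
        family_of_read=inverse.astype(np.int64),
        barcode_w=reads.barcode_w[first],
        barcode_c=reads.barcode_c[first],
        start=reads.start[first],
        end=reads.end[first],
        strand=reads.strand[first],
        sizes=sizes.astype(np.int64),
    )


def strand_consensus(member_seqs, q: float = DEFAULT_SUPERMAJORITY) -> str:
    """Collapse one read family to its per-position consensus.

    At each position the base carried by at least ``max(1, ceil(q * n))``
    of the ``n`` unmasked members is called; otherwise the position is
    masked (rendered ``N``).  Singleton families pass their base through
    (callers may treat them as low-confidence).
    """
    mat = np.stack([encode_seq(s) if isinstance(s, str) else np.asarray(s)
                    for s in member_seqs])
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # (4, L)
    n_unmasked = counts.sum(axis=0)
    top = counts.argmax(axis=0)
    topc = counts.max(axis=0)
    need = np.maximum(1, np.ceil(q * n_unmasked - 1e-9)).astype(np.int64)
    out = np.where((n_unmasked > 0) & (topc >= need), top, MASK).astype(np.uint8)
    return decode_seq(out)


# one-hot packed counters: 16 bits per base, mask contributes nothing;
# per-slot sums stay exact in float64 for family sizes < 2**16
_PACK_LUT = np.array([1.0, float(1 << 16), float(1 << 32), float(1 << 48), 0.0])


def _consensus_all(reads: ReadBatch, fams: FamilySet,
                   q: float = DEFAULT_SUPERMAJORITY,
                   clip_offset: np.ndarray | None = None,
                   clip_len: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-family consensus over every family at once.

    With ``clip_offset``/``clip_len`` (per family), consensus is computed
    only over the clipped sub-range of each family's span — used to skip
    off-panel flank bases.  Returns (flat consensus base codes, per-family
    CSR offsets over the clipped lengths).
    """
    fam_len = fams.lengths if clip_len is None else clip_len
    if clip_offset is None:
        clip_offset = np.zeros(fams.n_families, dtype=np.int64)
    fam_off = _csr_offsets(fam_len)
    n_slots = int(fam_off[-1])
    # reads sorted by family make the bincount scatter near-sequential
    order = np.argsort(fams.family_of_read, kind="stable")
    fam_sorted = fams.family_of_read[order]
    rl = fam_len[fam_sorted]
    gather = _ragged_ranges(reads.offsets[:-1][order] + clip_offset[fam_sorted], rl)
    slot = _ragged_ranges(fam_off[:-1][fam_sorted], rl)
    packed = np.bincount(slot, weights=_PACK_LUT[reads.bases[gather]],
                         minlength=n_slots).astype(np.int64)
    if packed.dtype.byteorder in ("=", "|") and np.little_endian:
        cnt = packed.view(np.uint16).reshape(-1, 4)
    else:  # pragma: no cover - big-endian fallback
        cnt = np.stack([(packed >> (16 * b)) & 0xFFFF for b in range(4)],
                       axis=1).astype(np.uint16)
    c0, c1, c2, c3 = cnt[:, 0], cnt[:, 1], cnt[:, 2], cnt[:, 3]
    # branchless argmax with first-index tie-break (A<C<G<T)
    b01 = c1 > c0
    m01 = np.where(b01, c1, c0)
    b23 = c3 > c2
    m23 = np.where(b23, c3, c2)
    hi = m23 > m01
    topc = np.where(hi, m23, m01)
    top = np.where(hi, b23.view(np.uint8) + 2, b01.view(np.uint8))
    n_unmasked = cnt.sum(axis=1, dtype=np.int32)
    max_n = int(fams.sizes.max()) if fams.sizes.size else 0
    need_lut = np.maximum(
        1, np.ceil(q * np.arange(max_n + 1) - 1e-9)).astype(np.int32)
    need = need_lut[n_unmasked]
    cons = np.where((n_unmasked > 0) & (topc >= need), top,
                    np.uint8(MASK))
    return cons, fam_off


def pair_duplex(watson: str, crick: str) -> tuple[str, list[str]]:
    """Compare the two strand consensi of one molecule.

    Returns the merged base string (``N`` where no call is possible) and
    the per-position status labels.  Equal calls are duplex-confirmed; a
    call present on one strand only is retained as single-strand-only;
    disagreeing calls are vetoed (discordant, no call).
    """
    w = encode_seq(watson)
    c = encode_seq(crick)
    if w.size != c.size:
        raise ValueError("strand consensi differ in length")
    bases, status = _pair_codes(w, c)
    return decode_seq(bases), [STATUS_NAMES[s] for s in status]


def _pair_codes(w: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w_called = w != MASK
    c_called = c != MASK
    both = w_called & c_called
    agree = both & (w == c)
    disagree = both & (w != c)
    single = w_called ^ c_called
    bases = np.where(agree, w, np.where(single, np.where(w_called, w, c),
                                        MASK)).astype(np.uint8)
    status = np.full(w.size, NO_CALL, dtype=np.uint8)
    status[single] = SINGLE_STRAND_ONLY
    status[disagree] = DISCORDANT_NO_CALL
    status[agree] = DUPLEX_CONFIRMED
    return bases, status


@dataclasses.dataclass
class ConsensusMolecules:
    """Reconstructed unique molecules with per-position duplex status."""

    chrom: str
    barcode_w: np.ndarray
    barcode_c: np.ndarray
    start: np.ndarray
    end: np.ndarray
    watson_size: np.ndarray   # reads in the Watson family (0 = strand absent)
    crick_size: np.ndarray
    bases: np.ndarray         # uint8 flat consensus codes
    status: np.ndarray        # uint8 flat duplex status codes
    offsets: np.ndarray       # int64 (n+1,)

    def __len__(self) -> int:
        return self.start.size

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def duplex_recovered(self) -> np.ndarray:
        """Molecules with both strand families present."""
        return (self.watson_size > 0) & (self.crick_size > 0)

    def molecule_seq(self, i: int) -> str:
        return decode_seq(self.bases[self.offsets[i]:self.offsets[i + 1]])

    def molecule_status(self, i: int) -> np.ndarray:
        return self.status[self.offsets[i]:self.offsets[i + 1]]


def _clip_ranges(fams: FamilySet, panel: ReferencePanel,
                 chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-family span clipped to the panel's region extent.

    Fragments extend past region boundaries; bases out there never enter a
    pileup, so consensus can skip them.  The clip is the range from the
    first to the last overlapped region (conservative: any inter-region
    gap inside a spanning fragment is retained).  Families overlapping no
    region clip to an empty range.
    """
    rs = np.array([r.start for r in panel.regions if r.chrom == chrom])
    re_ = np.array([r.end for r in panel.regions if r.chrom == chrom])
    if rs.size == 0:
        raise KeyError(f"chromosome {chrom!r} not on panel")
    i = np.searchsorted(re_, fams.start, side="right")
    j = np.searchsorted(rs, fams.end, side="left") - 1
    has = j >= i
    cstart = np.where(has, np.maximum(fams.start, rs[np.clip(i, 0, rs.size - 1)]),
                      fams.start)
    cend = np.where(has, np.minimum(fams.end, re_[np.clip(j, 0, rs.size - 1)]),
                    fams.start)  # empty range when no overlap
    return cstart, cend


def pair_duplex_families(reads: ReadBatch, fams: FamilySet,
                         q: float = DEFAULT_SUPERMAJORITY,
                         panel: ReferencePanel | None = None) -> ConsensusMolecules:
    """Pair Watson/Crick strand families into consensus molecules.

    With ``panel``, consensus spans are clipped to the panel regions
    (molecules that overlap no region are dropped); without it the full
    fragment span is reconstructed.
    """
    if panel is not None:
        cstart, cend = _clip_ranges(fams, panel, reads.chrom)
    else:
        cstart, cend = fams.start, fams.end
    clen = cend - cstart
    keep = clen > 0
    if not keep.all():
        kept = np.flatnonzero(keep)
        fmap = np.full(fams.n_families, -1, dtype=np.int64)
        fmap[kept] = np.arange(kept.size)
        rkeep = np.flatnonzero(keep[fams.family_of_read])
        reads = _subset_reads(reads, rkeep)
        fams = FamilySet(
            family_of_read=fmap[fams.family_of_read[rkeep]],
            barcode_w=fams.barcode_w[kept], barcode_c=fams.barcode_c[kept],
            start=fams.start[kept], end=fams.end[kept],
            strand=fams.strand[kept], sizes=fams.sizes[kept],
        )
        cstart, cend, clen = cstart[kept], cend[kept], clen[kept]
    cons, fam_off = _consensus_all(reads, fams, q,
                                   clip_offset=cstart - fams.start,
                                   clip_len=clen)
    # molecule key = family key without the strand bit
    span = int(fams.end.max()) + 1 if fams.n_families else 1
    lmax = int(fams.lengths.max()) + 1 if fams.n_families else 1
    mol_code = ((fams.barcode_w.astype(np.int64) * N_BARCODES + fams.barcode_c)
                * span + fams.start) * lmax + fams.lengths
    _, first, inverse = np.unique(mol_code, return_index=True, return_inverse=True)
    n_mol = first.size
    mol_len = clen[first]
    mol_off = _csr_offsets(mol_len)
    n_slots = int(mol_off[-1])

    strand_cons = np.full((2, n_slots), MASK, dtype=np.uint8)
    sizes = np.zeros((2, n_mol), dtype=np.int64)
    for s in (0, 1):
        rows = np.flatnonzero(fams.strand == s)
        if rows.size == 0:
            continue
        mols_of = inverse[rows]
        sizes[s, mols_of] = fams.sizes[rows]
        ln = clen[rows]
        src = _ragged_ranges(fam_off[rows], ln)
        dst = _ragged_ranges(mol_off[:-1][mols_of], ln)
        strand_cons[s, dst] = cons[src]

    bases, status = _pair_codes(strand_cons[0], strand_cons[1])
    # strand families that are truly absent (not just masked) stay single-strand
    return ConsensusMolecules(
        chrom=reads.chrom,
        barcode_w=fams.barcode_w[first],
        barcode_c=fams.barcode_c[first],
        start=cstart[first],
        end=cend[first],
        watson_size=sizes[0],
        crick_size=sizes[1],
        bases=bases,
        status=status,
        offsets=mol_off,
    )


def digitize_reads(reads: ReadBatch, min_base_quality: int = 20,
                   q: float = DEFAULT_SUPERMAJORITY,
                   panel: ReferencePanel | None = None) -> ConsensusMolecules:
    """Full digitization: filter -> group -> consensus -> duplex pairing."""
    filtered = filter_reads(reads, min_base_quality)
    fams = group_families(filtered)
    return pair_duplex_families(filtered, fams, q, panel=panel)


@dataclasses.dataclass
class Pileup:
    """Per-panel-position unique-molecule tallies by duplex status."""

    panel: ReferencePanel
    duplex: np.ndarray       # (P, 4) duplex-confirmed molecule count per base
    simplex: np.ndarray      # (P, 4) single-strand-only molecule count per base
    raw_depth: np.ndarray    # (P,) read-level depth

    @property
    def called_total(self) -> np.ndarray:
        """Unique molecules with a called base, per panel position."""
        return self.duplex.sum(axis=1) + self.simplex.sum(axis=1)

    @property
    def molecule_counts(self) -> np.ndarray:
        """(P, 4) unique-molecule count per base (duplex + single-strand)."""
        return self.duplex + self.simplex


def pileup(cons: ConsensusMolecules, panel: ReferencePanel,
           reads: ReadBatch | None = None) -> Pileup:
    """Tally unique molecules per panel position, by base and duplex status.

    Unique-molecule depth is bounded above by raw read depth (each molecule
    contributes at least one read).  Positions covered by zero molecules
    have empty tallies.
    """
    P = panel.total_length_bp
    lut = panel.position_lookup(cons.chrom)
    lengths = cons.lengths
    gpos = _ragged_ranges(cons.start, lengths)
    inside = gpos < lut.size
    pidx = np.where(inside, lut[np.clip(gpos, 0, lut.size - 1)], -1)
    duplex = np.zeros((P, 4), dtype=np.int64)
    simplex = np.zeros((P, 4), dtype=np.int64)
    for status_code, arr in ((DUPLEX_CONFIRMED, duplex),
                             (SINGLE_STRAND_ONLY, simplex)):
        sel = (pidx >= 0) & (cons.status == status_code) & (cons.bases < 4)
        if sel.any():
            flat = np.bincount(pidx[sel] * 4 + cons.bases[sel],
                               minlength=P * 4)
            arr += flat.reshape(P, 4)
    raw = np.zeros(P, dtype=np.int64)
    if reads is not None and len(reads):
        rlen = reads.lengths
        rpos = _ragged_ranges(reads.start, rlen)
        rin = rpos < lut.size
        ridx = lut[np.clip(rpos, 0, lut.size - 1)]
        sel = rin & (ridx >= 0)
        raw += np.bincount(ridx[sel], minlength=P)
    return Pileup(panel=panel, duplex=duplex, simplex=simplex, raw_depth=raw)


# -- molecule table serialization ----------------------------------------

def write_molecules_tsv(cons: ConsensusMolecules, path) -> None:
    """Persist consensus molecules as a TSV (seq uses N for no-call)."""
    from ._bases import barcode_to_str
    with open(path, "w") as fh:
        fh.write("barcode_w\tbarcode_c\tchrom\tstart\tend"
                 "\twatson_size\tcrick_size\tseq\tstatus\n")
        for i in range(len(cons)):
            st = "".join(str(int(s)) for s in cons.molecule_status(i))
            fh.write(
                f"{barcode_to_str(int(cons.barcode_w[i]))}\t"
                f"{barcode_to_str(int(cons.barcode_c[i]))}\t"
                f"{cons.chrom}\t{cons.start[i]}\t{cons.end[i]}\t"
                f"{cons.watson_size[i]}\t{cons.crick_size[i]}\t"
                f"{cons.molecule_seq(i)}\t{st}\n")


def write_pileup_tsv(pile: Pileup, path) -> None:
    """Persist a pileup as TSV: one row per panel position."""
    chrom_idx, gpos = pile.panel.panel_positions()
    regions = pile.panel.regions
    ref = pile.panel.ref_codes()
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\t" +
                 "\t".join(f"duplex_{b}" for b in "ACGT") + "\t" +
                 "\t".join(f"simplex_{b}" for b in "ACGT") +
                 "\traw_depth\n")
        for i in range(gpos.size):
            fh.write(f"{regions[chrom_idx[i]].chrom}\t{gpos[i]}\t"
                     f"{'ACGT'[ref[i]]}\t"
                     + "\t".join(str(x) for x in pile.duplex[i])
                     + "\t" + "\t".join(str(x) for x in pile.simplex[i])
                     + f"\t{pile.raw_depth[i]}\n")
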