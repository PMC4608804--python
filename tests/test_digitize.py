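import numpy as np
import pytest

import cfduplex as cf
from cfduplex import digitize as dg
from naive_consensus import naive_digitize


def _mini_reads(specs, chrom="chrS"):
    """Build a ReadBatch from (bw, bc, start, seq, strand, quals) tuples."""
    from cfduplex._bases import encode_seq
    from cfduplex.simulate import ReadBatch, _csr_offsets
    bases = [encode_seq(s[3]) for s in specs]
    lengths = np.array([b.size for b in bases], dtype=np.int64)
    quals = [np.full(b.size, 30, np.uint8) if len(s) < 6 else
             np.asarray(s[5], np.uint8) for s, b in zip(specs, bases)]
    return ReadBatch(
        chrom=chrom,
        barcode_w=np.array([s[0] for s in specs], np.int32),
        barcode_c=np.array([s[1] for s in specs], np.int32),
        start=np.array([s[2] for s in specs], np.int64),
        end=np.array([s[2] + len(s[3]) for s in specs], np.int64),
        strand=np.array([s[4] for s in specs], np.uint8),
        bases=np.concatenate(bases),
        quals=np.concatenate(quals),
        offsets=_csr_offsets(lengths),
    )


class TestFilterReads:
    def test_high_quality_reads_unchanged(self):
        reads = _mini_reads([(1, 2, 0, "ACGT", 0)])
        out = dg.filter_reads(reads)
        assert np.array_equal(out.bases, reads.bases)

    def test_low_quality_base_masked_read_kept(self):
        reads = _mini_reads([(1, 2, 0, "ACGT", 0, [30, 10, 30, 30])])
        out = dg.filter_reads(reads)
        assert len(out) == 1
        assert list(out.bases) == [0, 4, 2, 3]  # C masked

    def test_mostly_masked_read_dropped(self):
        reads = _mini_reads([(1, 2, 0, "ACGTA", 0, [10, 10, 10, 30, 30]),
                             (3, 4, 0, "ACGTA", 0)])
        out = dg.filter_reads(reads)  # 3/5 = 60% masked -> dropped
        assert len(out) == 1
        assert out.barcode_w[0] == 3


class TestGroupFamilies:
    def test_partition_by_exact_key(self):
        reads = _mini_reads([(1, 2, 0, "AAAA", 0)] * 3
                            + [(1, 2, 4, "CCCC", 0)] * 2)
        fams = dg.group_families(reads)
        assert fams.n_families == 2
        assert sorted(fams.sizes.tolist()) == [2, 3]

    def test_same_barcodes_different_start_split(self):
        reads = _mini_reads([(1, 2, 0, "AAAA", 0), (1, 2, 1, "AAAA", 0)])
        assert dg.group_families(reads).n_families == 2

    def test_strand_is_part_of_the_key(self):
        reads = _mini_reads([(1, 2, 0, "AAAA", 0), (1, 2, 0, "AAAA", 1)])
        assert dg.group_families(reads).n_families == 2


class TestStrandConsensus:
    @pytest.mark.parametrize("members,expected", [
        (["AAAA", "AAAA", "AAAA"], "AAAA"),        # unanimity
        (["AAAA", "AAAA", "GAAA"], "NAAA"),        # 2/3 < 0.75 -> mask
        (["AAAA", "AAAA", "AAAA", "GAAA"], "AAAA"),  # 3/4 >= 0.75
        (["ACGT"], "ACGT"),                        # singleton pass-through
        (["ANGT", "ACGT"], "ACGT"),                # mask excluded from vote
    ])
    def test_supermajority_vote(self, members, expected):
        assert dg.strand_consensus(members) == expected


class TestPairDuplex:
    def test_agreement_is_duplex_confirmed(self):
        bases, status = dg.pair_duplex("ACGT", "ACGT")
        assert bases == "ACGT"
        assert set(status) == {"duplex_confirmed"}

    def test_disagreement_is_vetoed(self):
        bases, status = dg.pair_duplex("ACGT", "AGGT")
        assert bases == "ANGT"
        assert status[1] == "discordant_no_call"

    def test_one_sided_call_is_single_strand(self):
        bases, status = dg.pair_duplex("ANGT", "ACGT")
        assert bases == "ACGT"
        assert status[1] == "single_strand_only"


def test_pcr_duplicate_invariance(tiny_panel):
    """Unique molecule count does not depend on the duplication factor."""
    counts = {}
    for dup in (1.0, 2.0, 5.0, 10.0):
        params = cf.SimParams(molecules_per_position=15,
                              pcr_duplicate_mean=dup,
                              conversion_efficiency=1.0,
                              per_base_error_rate=0.0,
                              low_quality_fraction=0.0,
                              pcr_lineage_error_rate=0.0)
        rng = np.random.default_rng(42)  # same molecule draw per dup factor
        mols = cf.draw_molecules(tiny_panel, [], [], params, rng)
        reads = cf.amplify_and_sequence(tiny_panel, mols, params, rng)
        cons = dg.digitize_reads(reads)
        counts[dup] = len(cons)
    assert len(set(counts.values())) == 1


def test_oracle_equivalence_on_small_instances(tiny_panel, noisy_params):
    """Vectorized reconstruction equals the by-definition reference."""
    rng = np.random.default_rng(7)
    checked = 0
    for _ in range(12):
        small = cf.SimParams(**{**noisy_params.__dict__,
                                "molecules_per_position": 3})
        _, reads = cf.simulate_sample(tiny_panel, [], [], small, rng)
        mine = dg.digitize_reads(reads)
        ref = naive_digitize(reads)
        assert len(mine) == len(ref)
        for i in range(len(mine)):
            key = (int(mine.barcode_w[i]), int(mine.barcode_c[i]),
                   int(mine.start[i]), int(mine.end[i]))
            rb, rs = ref[key]
            assert np.array_equal(rb, mine.bases[mine.offsets[i]:mine.offsets[i + 1]])
            assert np.array_equal(rs, mine.status[mine.offsets[i]:mine.offsets[i + 1]])
            checked += 1
    assert checked > 50


def test_duplex_veto_rejects_single_strand_errors(tiny_panel):
    """Errors injected on one strand never become duplex-confirmed calls."""
    params = cf.SimParams(molecules_per_position=300,
                          per_base_error_rate=0.0,
                          pcr_lineage_error_rate=0.0,
                          pcr_duplicate_mean=1.0,  # singletons pass errors through
                          low_quality_fraction=0.0)
    rng = np.random.default_rng(11)
    ref = tiny_panel.ref_codes()
    n_nonref_duplex = 0
    for _ in range(5):
        _, reads = cf.simulate_sample(tiny_panel, [], [], params, rng)
        # inject a heavy error load on Watson-strand reads only
        watson_base = np.repeat(reads.strand == 0, reads.lengths)
        hit = watson_base & (rng.random(reads.bases.size) < 0.02)
        reads.bases[hit] = (reads.bases[hit] + rng.integers(1, 4, hit.sum())) % 4
        cons = dg.digitize_reads(reads, panel=tiny_panel)
        pile = dg.pileup(cons, tiny_panel)
        nonref = pile.duplex.copy()
        nonref[np.arange(ref.size), ref] = 0
        n_nonref_duplex += int(nonref.sum())
        # errors did hit single strands: the veto shows up as discordance
        assert (cons.status == dg.DISCORDANT_NO_CALL).any()
    assert n_nonref_duplex == 0


def test_pcr_lineage_error_never_duplex_confirmed(tiny_panel):
    """A jackpot error dominating one strand family is always vetoed."""
    params = cf.SimParams(molecules_per_position=200,
                          per_base_error_rate=0.0,
                          pcr_lineage_error_rate=5e-3,
                          pcr_duplicate_mean=3.0,
                          low_quality_fraction=0.0)
    rng = np.random.default_rng(12)
    ref = tiny_panel.ref_codes()
    _, reads = cf.simulate_sample(tiny_panel, [], [], params, rng)
    cons = dg.digitize_reads(reads, panel=tiny_panel)
    pile = dg.pileup(cons, tiny_panel)
    nonref = pile.duplex.copy()
    nonref[np.arange(ref.size), ref] = 0
    assert nonref.sum() == 0


def test_conversion_accounting(lod_panel):
    """Recovered consensus molecules track the conversion efficiency."""
    params = cf.SimParams(molecules_per_position=500)
    rng = np.random.default_rng(13)
    mols, reads = cf.simulate_sample(lod_panel, [], [], params, rng)
    cons = dg.digitize_reads(reads, panel=lod_panel)
    recovered = len(cons) / len(mols)
    assert abs(recovered - params.conversion_efficiency) < 0.03
    assert cons.duplex_recovered.mean() > 0.95  # converted -> both strands


def test_pileup_tallies_and_depth_inequality(tiny_panel, noisy_params):
    rng = np.random.default_rng(14)
    _, reads = cf.simulate_sample(tiny_panel, [], [], noisy_params, rng)
    cons = dg.digitize_reads(reads, panel=tiny_panel)
    pile = dg.pileup(cons, tiny_panel, reads)
    assert (pile.called_total <= pile.raw_depth).all()
    assert pile.duplex.sum() > 0


def test_pileup_zero_coverage_position_is_empty(tiny_panel):
    params = cf.SimParams(molecules_per_position=1,
                          conversion_efficiency=1.0)
    rng = np.random.default_rng(15)
    _, reads = cf.simulate_sample(tiny_panel, [], [], params, rng)
    cons = dg.digitize_reads(reads, panel=tiny_panel)
    pile = dg.pileup(cons, tiny_panel)
    # with ~1 molecule per position some sites are empty; tallies stay zero
    empty = pile.called_total == 0
    assert pile.molecule_counts[empty].sum() == 0


def test_panel_clipped_and_full_reconstruction_agree(tiny_panel, noisy_params):
    """Clipping to the panel changes spans, not panel-base content."""
    rng = np.random.default_rng(16)
    _, reads = cf.simulate_sample(tiny_panel, [], [], noisy_params, rng)
    full = dg.pileup(dg.digitize_reads(reads), tiny_panel)
    clipped = dg.pileup(dg.digitize_reads(reads, panel=tiny_panel), tiny_panel)
    assert np.array_equal(full.duplex, clipped.duplex)
    assert np.array_equal(full.simplex, clipped.simplex)
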