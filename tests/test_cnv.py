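import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cfduplex as cf
from cfduplex import cnv
from cfduplex.cnv import (Z_AMPLIFICATION, NormalCnStats, call_amplification,
                          cnv_lod_surface, diploid_baseline, normalize_counts,
                          plasma_cn_mixture, tumor_cn_from_plasma)


class TestMixtureArithmetic:
    def test_worked_example_tumor_cn10_f5pct(self):
        assert plasma_cn_mixture(10.0, 0.05) == pytest.approx(2.4)

    def test_no_tumor_means_germline(self):
        assert plasma_cn_mixture(10.0, 0.0) == 2.0

    def test_inverse_round_trip(self):
        assert tumor_cn_from_plasma(2.4, 0.05) == pytest.approx(10.0)

    def test_inverse_undefined_at_zero_fraction(self):
        with pytest.raises(ValueError):
            tumor_cn_from_plasma(2.4, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=2.0, max_value=50.0),
           st.floats(min_value=1e-3, max_value=1.0))
    def test_mixture_identity(self, tumor_cn, f):
        plasma = plasma_cn_mixture(tumor_cn, f)
        assert tumor_cn_from_plasma(plasma, f) == pytest.approx(tumor_cn)


def test_amplification_threshold_is_995_normal_quantile():
    assert round(Z_AMPLIFICATION, 4) == 2.5758


def _counts_frame(values, lengths=None):
    genes = [f"G{i}" for i in range(len(values))]
    lengths = lengths or [100] * len(values)
    return pd.DataFrame({
        "unique_fragments": values,
        "length": lengths,
        "effective_length": [l + 166 for l in lengths],
        "gc": 0.5,
    }, index=pd.Index(genes, name="gene"))


class TestNormalization:
    def test_bias_free_is_count_over_mean(self):
        counts = _counts_frame([1000, 1010, 990, 1005, 995])
        norm = normalize_counts(counts)
        assert norm.mean() == pytest.approx(1.0)
        assert norm.max() - norm.min() < 0.03

    def test_injected_capture_bias_recovered(self):
        """A diploid gene with 2x capture efficiency returns to the median."""
        rng = np.random.default_rng(0)
        eff = rng.uniform(0.5, 2.5, size=24)
        eff[7] = 2.0
        counts = _counts_frame(np.round(3000 * eff).astype(int))
        cov = pd.DataFrame({"efficiency": eff}, index=counts.index)
        norm = normalize_counts(counts, cov)
        med = norm.median()
        assert abs(norm.iloc[7] - med) / med < 0.05

    def test_amplified_gene_not_shrunk(self):
        """The robust fit must not regress a real amplification away."""
        rng = np.random.default_rng(1)
        eff = rng.uniform(0.8, 1.2, size=24)
        vals = 3000 * eff
        vals[3] *= 1.5  # truly amplified gene (plasma CN 3)
        counts = _counts_frame(np.round(vals).astype(int))
        cov = pd.DataFrame({"efficiency": eff}, index=counts.index)
        norm = normalize_counts(counts, cov)
        others = norm.drop(index="G3")
        assert norm["G3"] / others.median() == pytest.approx(1.5, rel=0.05)

    def test_degenerate_covariate_falls_back_to_identity(self):
        counts = _counts_frame([1000, 1000, 1000, 1000, 1000])
        cov = pd.DataFrame({"efficiency": [1.0] * 5}, index=counts.index)
        norm = normalize_counts(counts, cov)
        assert np.allclose(norm, 1.0)


class TestDiploidBaseline:
    def test_all_diploid_gives_cn_two(self):
        norm = pd.Series(1.0 + 0.001 * np.arange(10),
                         index=[f"G{i}" for i in range(10)])
        cn, baseline = cnv.plasma_copy_numbers(norm)
        assert np.allclose(cn, 2.0, atol=0.05)

    def test_single_amplified_gene_leaves_mode_unmoved(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(1.0, 0.01, size=54)
        vals[5] = 1.5
        norm = pd.Series(vals, index=[f"G{i}" for i in range(54)])
        cn, _ = cnv.plasma_copy_numbers(norm)
        assert cn.drop(index="G5").max() < 2.2
        assert cn["G5"] == pytest.approx(3.0, rel=0.05)

    def test_majority_amplified_warns(self):
        vals = np.concatenate([np.full(8, 2.0), [1.0, 1.01, 0.99]])
        norm = pd.Series(vals, index=[f"G{i}" for i in range(11)])
        with pytest.warns(UserWarning, match="unreliable"):
            diploid_baseline(norm)

    def test_needs_three_genes(self):
        with pytest.raises(ValueError):
            diploid_baseline(pd.Series([1.0, 1.0], index=["A", "B"]))


class TestAmplificationCall:
    def _stats(self, genes, mean=1.0, sd=0.025):
        idx = pd.Index(genes)
        return NormalCnStats(mean=pd.Series(mean, index=idx),
                             sd=pd.Series(sd, index=idx), n_samples=10)

    def test_z_arithmetic_and_flags(self):
        genes = [f"G{i}" for i in range(10)]
        vals = np.full(10, 1.0)
        vals[0] = 1.2  # plasma CN 2.4 at sd 0.05 in CN units -> z = 8
        norm = pd.Series(vals, index=genes)
        calls = call_amplification(_counts_frame(vals * 1000), norm,
                                   self._stats(genes), genes=("G0", "G1"))
        g0, g1 = calls
        assert g0.z_score == pytest.approx(8.0, rel=0.05)
        assert g0.amplified and g0.reportable and g0.called
        assert g1.z_score == pytest.approx(0.0, abs=0.5)
        assert not g1.amplified

    def test_reportable_boundary_at_2_2(self):
        genes = [f"G{i}" for i in range(10)]
        vals = np.full(10, 1.0)
        vals[0] = 1.1  # plasma CN 2.2
        norm = pd.Series(vals, index=genes)
        calls = call_amplification(_counts_frame(vals * 1000), norm,
                                   self._stats(genes), genes=("G0",))
        assert calls[0].plasma_copy_number == pytest.approx(2.2, abs=0.02)
        assert calls[0].reportable

    def test_missing_gene_rejected(self):
        genes = ["G0", "G1", "G2"]
        norm = pd.Series(1.0, index=genes)
        with pytest.raises(KeyError):
            call_amplification(_counts_frame([1, 1, 1]), norm,
                               self._stats(genes), genes=("NOPE",))


class TestLodSurface:
    def _stats_sd_cn(self, sd_cn):
        idx = pd.Index(["EGFR"])
        return NormalCnStats(mean=pd.Series(1.0, index=idx),
                             sd=pd.Series(sd_cn / 2.0, index=idx),
                             n_samples=10)

    def test_lod_tracks_counting_noise(self):
        out = cnv_lod_surface("EGFR", self._stats_sd_cn(0.07))
        assert out["lod_extra_copies"] == pytest.approx(
            Z_AMPLIFICATION * 0.07, rel=1e-9)
        assert round(out["lod_extra_copies"], 1) == 0.2

    def test_lod_proportional_to_sd(self):
        a = cnv_lod_surface("EGFR", self._stats_sd_cn(0.07))
        b = cnv_lod_surface("EGFR", self._stats_sd_cn(0.07 * 2.5))
        assert b["lod_extra_copies"] == pytest.approx(
            2.5 * a["lod_extra_copies"])
        assert round(b["lod_extra_copies"], 1) == 0.5

    def test_low_excess_mixture_detectability(self):
        """CN 6 at 2% tumor fraction is a 0.08-copy excess: detectable only
        for genes with small counting noise."""
        out_quiet = cnv_lod_surface("EGFR", self._stats_sd_cn(0.02),
                                    tumor_cn_grid=np.array([6.0]),
                                    tumor_fraction_grid=np.array([0.02]))
        out_noisy = cnv_lod_surface("EGFR", self._stats_sd_cn(0.07),
                                    tumor_cn_grid=np.array([6.0]),
                                    tumor_fraction_grid=np.array([0.02]))
        assert out_quiet["detection_prob"][0, 0] > 0.9
        assert out_noisy["detection_prob"][0, 0] < 0.5


def test_count_gene_fragments_counts_and_halves(tiny_panel):
    params = cf.SimParams(molecules_per_position=200)
    rng = np.random.default_rng(3)
    from cfduplex import digitize as dg
    _, reads = cf.simulate_sample(tiny_panel, [], [], params, rng)
    cons = dg.digitize_reads(reads, panel=tiny_panel)
    counts = cnv.count_gene_fragments(cons, tiny_panel)
    assert (counts["unique_fragments"] > 0).all()
    assert (counts["watson_halves"] <= counts["unique_fragments"]).all()
    # balanced simulation: strand halves nearly even at depth
    assert (counts["half_imbalance"] < 0.05).all()


def test_molecule_spanning_two_genes_counted_for_both():
    from cfduplex.digitize import ConsensusMolecules
    from cfduplex.panel import PanelRegion, ReferencePanel
    regions = [PanelRegion("A", "chr1", 100, 200),
               PanelRegion("B", "chr1", 210, 310)]
    panel = ReferencePanel(regions, ["A" * 100, "C" * 100])
    cons = ConsensusMolecules(
        chrom="chr1",
        barcode_w=np.array([1]), barcode_c=np.array([2]),
        start=np.array([150]), end=np.array([260]),
        watson_size=np.array([1]), crick_size=np.array([1]),
        bases=np.zeros(110, np.uint8), status=np.zeros(110, np.uint8),
        offsets=np.array([0, 110]),
    )
    counts = cnv.count_gene_fragments(cons, panel)
    assert counts.loc["A", "unique_fragments"] == 1
    assert counts.loc["B", "unique_fragments"] == 1
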