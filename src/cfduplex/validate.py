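"""In-silico analytic-validation experiments and diagnostic statistics.

Every experiment here runs the complete pipeline — simulate molecules,
sequence, digitize to consensus molecules, train/apply the noise baseline,
call variants — and then measures the method's operating characteristics:
serial-dilution limit of detection, spike-in accuracy over a cumulative
target region, split-sample robustness, and gDNA-interference summaries.
The two-by-two diagnostic statistics use exact (Clopper-Pearson) binomial
confidence intervals.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .digitize import digitize_reads, pileup
from .noise import NoiseBaseline, train_baseline
from .panel import ReferencePanel
from .simulate import (
    GroundTruthVariant,
    SimParams,
    make_validation_cohort,
    random_germline_variants,
    simulate_sample,
)
from .snv import SnvCall, SnvCallParams, call_snvs

#: cfDNA fragment-length mean used by the amplicon-efficiency approximation.
CFDNA_FRAGMENT_BP = 166.0

#: Fragment-length boundary between cfDNA and genomic-DNA contamination.
GDNA_LENGTH_BP = 500.0


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Two-by-two tally of calls against truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency cells must be non-negative")


@dataclasses.dataclass(frozen=True)
class MetricWithCI:
    """A percentage metric with its exact binomial confidence interval."""

    value_pct: float
    ci_low_pct: float
    ci_high_pct: float
    numerator: int
    denominator: int


def _exact_metric(x: int, n: int, ci_level: float) -> MetricWithCI | None:
    if n == 0:
        return None
    lo, hi = proportion_confint(x, n, alpha=1 - ci_level, method="beta")
    return MetricWithCI(100.0 * x / n, 100.0 * lo, 100.0 * hi, x, n)


def diagnostic_metrics(table: ContingencyTable,
                       ci_level: float = 0.95) -> dict[str, MetricWithCI | None]:
    """Sensitivity, specificity and accuracy with Clopper-Pearson CIs.

    Metrics are percentages; a metric with an empty denominator is
    reported as None.  At the boundaries the exact interval collapses
    one-sided (e.g. the lower bound for x = n is (alpha/2)**(1/n)).
    """
    sens = _exact_metric(table.tp, table.tp + table.fn, ci_level)
    spec = _exact_metric(table.tn, table.tn + table.fp, ci_level)
    total = table.tp + table.fp + table.fn + table.tn
    acc = _exact_metric(table.tp + table.tn, total, ci_level)
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


@dataclasses.dataclass
class DilutionSeriesResult:
    """Detection fractions per dilution level and the >80% LOD."""

    levels: list[float]                 # MAF fractions, descending
    detection_fraction: dict[float, float]
    n_trials: dict[float, int]
    lod: float | None                   # lowest level with >80% detection

    def detection_pct(self, level: float) -> float:
        return 100.0 * self.detection_fraction[level]


#: Default dilution grid (MAF fractions).  The prepared titrations plus
#: 0.25% so the >80% rule can land on the validated limit of detection.
DEFAULT_DILUTION_LEVELS = (0.30, 0.10, 0.01, 0.005, 0.003, 0.0025, 0.001)

DETECTION_RULE = 0.80


def _lod_from_detections(levels: list[float],
                         detection: dict[float, float]) -> float | None:
    """Lowest level of the contiguous >80% prefix, scanning downwards."""
    lod = None
    for lv in sorted(levels, reverse=True):
        if detection[lv] > DETECTION_RULE:
            lod = lv
        else:
            break
    return lod


def _train_noise_on_normals(panel: ReferencePanel, params: SimParams,
                            n_normals: int, rng: np.random.Generator,
                            snps_range=(12, 27)) -> NoiseBaseline:
    cohort = make_validation_cohort(panel, params, n_normals, rng, snps_range)
    piles = []
    for sample in cohort:
        cons = digitize_reads(sample["reads"], panel=panel)
        piles.append(pileup(cons, panel, sample["reads"]))
    return train_baseline(piles, panel)


def _detected(calls: list[SnvCall], truth: GroundTruthVariant) -> bool:
    return any(c.position == truth.position and c.alt_base == truth.alt_base
               and c.classification == "somatic" for c in calls)


def run_dilution_series(
    panel: ReferencePanel,
    params: SimParams,
    levels=DEFAULT_DILUTION_LEVELS,
    n_variants: int = 29,
    n_replicates: int = 3,
    seed: int = 0,
    baseline: NoiseBaseline | None = None,
    n_normals: int = 5,
    snv_params: SnvCallParams = SnvCallParams(),
) -> DilutionSeriesResult:
    """Serial-dilution sensitivity study through the full pipeline.

    ``n_variants`` SNVs are placed at random panel positions; each is
    simulated in ``n_replicates`` independent samples per dilution level
    and counted as detected when the called somatic variant matches the
    truth site and allele.  The limit of detection is the lowest level at
    which more than 80% of variant-replicates are detected.
    """
    rng = np.random.default_rng(seed)
    panel.ensure_genome()
    if baseline is None:
        baseline = _train_noise_on_normals(panel, params, n_normals, rng)
    _, gpos = panel.panel_positions()
    ref = panel.ref_codes()
    chrom = panel.regions[0].chrom
    idx = rng.choice(gpos.size, size=n_variants, replace=False)
    sites = [(int(gpos[i]), int(ref[i]),
              (int(ref[i]) + int(rng.integers(1, 4))) % 4) for i in idx]

    levels = [float(l) for l in levels]
    detection: dict[float, float] = {}
    n_trials: dict[float, int] = {}
    for level in levels:
        hits = 0
        for pos, r, a in sites:
            truth = GroundTruthVariant(chrom, pos, "ACGT"[r], "ACGT"[a],
                                       "somatic", true_maf=level)
            for _ in range(n_replicates):
                _, reads = simulate_sample(panel, [truth], [], params, rng)
                cons = digitize_reads(reads, panel=panel)
                calls = call_snvs(pileup(cons, panel), baseline, snv_params)
                hits += _detected(calls, truth)
        n = n_variants * n_replicates
        detection[level] = hits / n
        n_trials[level] = n
    return DilutionSeriesResult(
        levels=sorted(levels, reverse=True),
        detection_fraction=detection,
        n_trials=n_trials,
        lod=_lod_from_detections(levels, detection),
    )


@dataclasses.dataclass
class SpecificityStudyResult:
    """Spike-in accuracy study tallies and derived metrics."""

    table: ContingencyTable
    metrics: dict[str, MetricWithCI | None]
    cumulative_bp: int
    n_samples: int


def run_specificity_study(
    panel: ReferencePanel,
    params: SimParams,
    n_samples: int = 20,
    seed: int = 0,
    spike_maf: tuple[float, float] = (0.025, 0.05),
    snps_range: tuple[int, int] = (12, 27),
    baseline: NoiseBaseline | None = None,
    n_normals: int = 5,
    snv_params: SnvCallParams = SnvCallParams(),
) -> SpecificityStudyResult:
    """Donor-into-host spike-in accuracy study over the whole panel.

    Each sample spikes one donor's germline SNP set into a host background
    at a few-percent MAF; calls classified somatic are tallied against the
    spiked truth over every panel base, giving the cumulative
    true-negative denominator (n_samples x panel bases).
    """
    rng = np.random.default_rng(seed)
    panel.ensure_genome()
    if baseline is None:
        baseline = _train_noise_on_normals(panel, params, n_normals, rng)
    tp = fp = fn = 0
    if n_samples == 0:
        table = ContingencyTable(0, 0, 0, 0)
        return SpecificityStudyResult(table, diagnostic_metrics(table), 0, 0)
    for _ in range(n_samples):
        host = random_germline_variants(panel, rng, snps_range)
        host_sites = {(v.position, v.alt_base) for v in host}
        donor = random_germline_variants(panel, rng, snps_range)
        spikes = []
        for v in donor:
            if (v.position, v.alt_base) in host_sites:
                continue  # indistinguishable from host background
            maf = float(rng.uniform(*spike_maf))
            spikes.append(GroundTruthVariant(v.chrom, v.position, v.ref_base,
                                             v.alt_base, "somatic", maf))
        _, reads = simulate_sample(panel, host + spikes, [], params, rng)
        cons = digitize_reads(reads, panel=panel)
        calls = call_snvs(pileup(cons, panel), baseline, snv_params)
        somatic = {(c.position, c.alt_base) for c in calls
                   if c.classification == "somatic"}
        truth = {(v.position, v.alt_base) for v in spikes}
        tp += len(somatic & truth)
        fp += len(somatic - truth)
        fn += len(truth - somatic)
    cumulative = n_samples * panel.total_length_bp
    tn = cumulative - tp - fp - fn
    table = ContingencyTable(tp, fp, fn, tn)
    return SpecificityStudyResult(table, diagnostic_metrics(table),
                                  cumulative, n_samples)


def split_sample_concordance(calls_a: list[SnvCall],
                             calls_b: list[SnvCall]) -> dict:
    """Paired-aliquot agreement: MAF R-squared and concordance by stratum.

    Variants are keyed by (position, alt); a variant missing from one
    aliquot contributes MAF 0 to the correlation.  Concordance within an
    MAF stratum is the fraction of variants (mean MAF above the stratum
    bound) detected in both aliquots.
    """
    a = {(c.position, c.alt_base): c.maf for c in calls_a}
    b = {(c.position, c.alt_base): c.maf for c in calls_b}
    keys = sorted(set(a) | set(b))
    if len(keys) < 2:
        raise ValueError("concordance needs >= 2 variants across aliquots")
    xa = np.array([a.get(k, 0.0) for k in keys])
    xb = np.array([b.get(k, 0.0) for k in keys])
    r2 = float(np.corrcoef(xa, xb)[0, 1] ** 2)
    out = {"r_squared": r2, "n_variants": len(keys), "concordance": {}}
    for bound in (0.003, 0.001):
        mean_maf = 0.5 * (xa + xb)
        sel = mean_maf > bound
        if sel.any():
            both = np.array([k in a and k in b for k in keys])
            out["concordance"][bound] = float(both[sel].mean())
        else:
            out["concordance"][bound] = float("nan")
    return out


def run_split_sample_study(
    panel: ReferencePanel,
    params: SimParams,
    n_variants: int = 24,
    maf_range: tuple[float, float] = (0.001, 0.30),
    seed: int = 0,
    baseline: NoiseBaseline | None = None,
    n_normals: int = 5,
) -> dict:
    """Two independent aliquots of one truth sample, compared by MAF.

    Truth MAFs are log-uniform over ``maf_range`` (spanning the dynamic
    range of a robustness study); both aliquots are fully independent
    simulations of the same truth.
    """
    rng = np.random.default_rng(seed)
    panel.ensure_genome()
    if baseline is None:
        baseline = _train_noise_on_normals(panel, params, n_normals, rng)
    _, gpos = panel.panel_positions()
    ref = panel.ref_codes()
    chrom = panel.regions[0].chrom
    idx = rng.choice(gpos.size, size=n_variants, replace=False)
    lo, hi = np.log(maf_range[0]), np.log(maf_range[1])
    truths = []
    for i in idx:
        r = int(ref[i])
        alt = (r + int(rng.integers(1, 4))) % 4
        maf = float(np.exp(rng.uniform(lo, hi)))
        truths.append(GroundTruthVariant(chrom, int(gpos[i]), "ACGT"[r],
                                         "ACGT"[alt], "somatic", maf))
    aliquots = []
    for _ in range(2):
        _, reads = simulate_sample(panel, truths, [], params, rng)
        cons = digitize_reads(reads, panel=panel)
        aliquots.append(call_snvs(pileup(cons, panel), baseline))
    result = split_sample_concordance(aliquots[0], aliquots[1])
    result["truth"] = truths
    result["calls"] = aliquots
    return result


def gdna_interference_report(fragment_lengths_per_sample: list[np.ndarray]) -> dict:
    """Per-sample gDNA mass ratio (>500 bp over <=500 bp) and summary.

    Mass is the summed fragment length on each side of the 500 bp
    boundary; a pure-cfDNA sample has ratio 0.
    """
    ratios = []
    for lengths in fragment_lengths_per_sample:
        lengths = np.asarray(lengths, dtype=float)
        long_mass = lengths[lengths > GDNA_LENGTH_BP].sum()
        short_mass = lengths[lengths <= GDNA_LENGTH_BP].sum()
        ratios.append(long_mass / short_mass if short_mass > 0 else np.inf)
    ratios_arr = np.array(ratios)
    q1, med, q3 = np.percentile(ratios_arr, [25, 50, 75])
    return {"ratios": ratios_arr, "median": float(med),
            "q1": float(q1), "q3": float(q3)}


def amplicon_conversion_efficiency(amplicon_length_bp: float) -> float:
    """Theoretical cfDNA conversion efficiency of an amplicon method, %.

    ``(1 - x/166) * 100`` for amplicon length x, floored at zero: the
    longer the amplicon relative to a 166 bp fragment, the fewer intact
    template molecules exist.  Integer rendering truncates (x=100 -> 39%).
    """
    if amplicon_length_bp <= 0:
        raise ValueError("amplicon length must be positive")
    return max(0.0, (1.0 - amplicon_length_bp / CFDNA_FRAGMENT_BP) * 100.0)


def expected_false_positives(fp_rate: float, target_bp: float) -> float:
    """Expected false-positive count = per-base rate x target size.

    A '99% specificity' assay (1% per-base false-positive rate) yields 780
    expected false positives over a 78 kbp target — the scale argument for
    requiring near-perfect per-base specificity on wide panels.
    """
    if not 0 <= fp_rate <= 1:
        raise ValueError("false-positive rate must lie in [0,1]")
    return fp_rate * target_bp
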