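"""Per-base background noise baselines trained on a normal cohort.

A separate noise model is kept for every (panel position, alternate base)
pair: the mean and dispersion of the duplex-confirmed minor-base fraction
observed across germline-only normal samples.  A candidate variant must
exceed its own site's threshold, so recurrent site-specific artifacts are
suppressed without raising the detection floor anywhere else.

The thresholding statistic is ``mean + k * sd`` with an absolute floor of
``min_support`` molecules over the local unique depth.  The default
``k = 10`` is a calibrated package default (chosen so that a fresh normal
sample essentially never exceeds threshold anywhere on the panel); it is
a package choice, not an externally specified constant.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .digitize import Pileup
from .panel import ReferencePanel

DEFAULT_K = 10.0
DEFAULT_MIN_SUPPORT = 2
GERMLINE_EXCLUDE_FRACTION = 0.25


@dataclasses.dataclass
class NoiseBaseline:
    """Trained per-(position, alt) background statistics.

    Arrays are (P, 4) over panel index x base code; the reference-base
    column of each site is invalid (NaN mean) and never queried.
    """

    panel: ReferencePanel
    mean: np.ndarray        # (P, 4) mean minor-base fraction
    sd: np.ndarray          # (P, 4)
    n_samples: np.ndarray   # (P, 4) samples contributing
    mean_depth: np.ndarray  # (P,) mean unique called depth in training
    k: float = DEFAULT_K
    min_support: int = DEFAULT_MIN_SUPPORT

    @property
    def stat_threshold(self) -> np.ndarray:
        """mean + k*sd part of the threshold, (P, 4)."""
        return self.mean + self.k * self.sd


def train_baseline(
    normal_pileups: list[Pileup],
    panel: ReferencePanel,
    k: float = DEFAULT_K,
    min_support: int = DEFAULT_MIN_SUPPORT,
    germline_exclude_fraction: float = GERMLINE_EXCLUDE_FRACTION,
) -> NoiseBaseline:
    """Train the per-base noise model from >=2 normal-sample pileups.

    Each sample contributes its duplex-confirmed minor-base fraction at
    every (site, alt).  A site/alt whose fraction in a given sample looks
    germline (above ``germline_exclude_fraction``) is excluded from that
    sample's contribution only, so one donor's SNPs cannot inflate the
    panel-wide baseline.
    """
    if len(normal_pileups) < 2:
        raise ValueError("noise training needs at least 2 normal samples")
    P = panel.total_length_bp
    ref = panel.ref_codes()
    ref_mask = np.zeros((P, 4), dtype=bool)
    ref_mask[np.arange(P), ref] = True

    total_frac = np.zeros((P, 4))
    total_sq = np.zeros((P, 4))
    n = np.zeros((P, 4), dtype=np.int64)
    depth_sum = np.zeros(P)
    for pile in normal_pileups:
        duplex_total = pile.duplex.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(duplex_total[:, None] > 0,
                            pile.duplex / np.maximum(duplex_total, 1)[:, None],
                            0.0)
        contrib = (~ref_mask) & (duplex_total[:, None] > 0) \
            & (frac <= germline_exclude_fraction)
        total_frac += np.where(contrib, frac, 0.0)
        total_sq += np.where(contrib, frac * frac, 0.0)
        n += contrib
        depth_sum += pile.called_total
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, total_frac / np.maximum(n, 1), np.nan)
        var = np.where(n > 1,
                       (total_sq - total_frac**2 / np.maximum(n, 1))
                       / np.maximum(n - 1, 1), 0.0)
    sd = np.sqrt(np.clip(var, 0.0, None))
    mean = np.where(ref_mask, np.nan, mean)
    return NoiseBaseline(
        panel=panel,
        mean=mean,
        sd=sd,
        n_samples=n,
        mean_depth=depth_sum / len(normal_pileups),
        k=k,
        min_support=min_support,
    )


def threshold_for(baseline: NoiseBaseline, position: int, alt: str,
                  chrom: str | None = None,
                  depth: float | None = None) -> float:
    """Site/alt-specific detection threshold (a molecule fraction).

    ``max(mean + k*sd, min_support / depth)``; with no explicit test-sample
    depth the mean training depth at the site is used for the floor.
    """
    panel = baseline.panel
    if chrom is None:
        chroms = {r.chrom for r in panel.regions}
        if len(chroms) != 1:
            raise ValueError("chrom required for multi-chromosome panels")
        chrom = chroms.pop()
    lut = panel.position_lookup(chrom)
    if position >= lut.size or lut[position] < 0:
        raise KeyError(f"position {chrom}:{position} not on panel")
    pidx = int(lut[position])
    alt_code = "ACGT".index(alt)
    if np.isnan(baseline.mean[pidx, alt_code]):
        if baseline.n_samples[pidx, alt_code] == 0:
            raise KeyError(
                f"site {chrom}:{position}>{alt} has no trained baseline")
    if depth is None:
        depth = float(baseline.mean_depth[pidx])
    if depth <= 0:
        raise ValueError("cannot compute a threshold floor at zero depth")
    stat = float(baseline.stat_threshold[pidx, alt_code])
    return max(stat, baseline.min_support / depth)


def write_baseline_tsv(baseline: NoiseBaseline, path) -> None:
    """Persist the baseline as TSV (position, alt, mean, sd, n, threshold)."""
    chrom_idx, gpos = baseline.panel.panel_positions()
    regions = baseline.panel.regions
    ref = baseline.panel.ref_codes()
    stat = baseline.stat_threshold
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tmean\tsd\tn\tthreshold_stat\n")
        for i in range(gpos.size):
            for b in range(4):
                if b == ref[i]:
                    continue
                fh.write(f"{regions[chrom_idx[i]].chrom}\t{gpos[i]}\t"
                         f"{'ACGT'[ref[i]]}\t{'ACGT'[b]}\t"
                         f"{baseline.mean[i, b]:.3e}\t{baseline.sd[i, b]:.3e}\t"
                         f"{baseline.n_samples[i, b]}\t{stat[i, b]:.3e}\n")
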