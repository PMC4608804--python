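"""Plasma copy-number estimation and focal-amplification calling.

Unique-fragment counts per gene (both strand halves of each parent
molecule) are normalized by a robust non-parametric regression on
region-level covariates (capture-efficiency proxy, GC, length) to remove
preparation/sequencing bias, scaled so the modal gene corresponds to two
copies, and z-scored against a cohort of normal samples.  Plasma copy
number is the tumor-fraction-weighted mixture of germline and tumor copy
numbers: ``plasma = (1-f)·g + f·t`` — e.g. tumor CN 10 at 5% tumor
fraction gives plasma CN 2.4 — so even strong tumor amplification shifts
the plasma value by fractions of a copy, and calling reduces to detecting
small shifts against tight counting noise.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .digitize import ConsensusMolecules
from .panel import CNV_GENES, ReferencePanel

#: Mean cfDNA fragment length used for effective capture length.
CFDNA_FRAGMENT_BP = 166.0

#: Inverse standard-normal CDF at the 99.5% confidence level.
Z_AMPLIFICATION = float(stats.norm.ppf(0.995))  # 2.5758...

#: Plasma CN at or above this is flagged as a reportable increase.
REPORTABLE_PLASMA_CN = 2.2


@dataclasses.dataclass
class GeneCnCall:
    """Per-gene plasma copy-number result."""

    gene_symbol: str
    unique_fragments: int
    normalized_fragments: float
    plasma_copy_number: float
    z_score: float
    amplified: bool      # z above threshold
    reportable: bool     # plasma CN >= 2.2

    @property
    def called(self) -> bool:
        """Reported amplification: statistically amplified and reportable."""
        return self.amplified and self.reportable


@dataclasses.dataclass
class NormalCnStats:
    """Per-gene normalized-count statistics over the Normal Set."""

    mean: pd.Series
    sd: pd.Series
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("normal CN stats need >= 2 samples")
        if (self.sd <= 0).any():
            raise ValueError("zero dispersion in normal CN stats")


def count_gene_fragments(cons: ConsensusMolecules,
                         panel: ReferencePanel) -> pd.DataFrame:
    """Count unique molecules overlapping each gene's regions.

    A molecule overlapping regions of two genes is counted once for each
    gene.  Per-strand-half counts and the half-imbalance statistic
    ``|watson - crick| / total`` are retained as QC covariates.
    """
    rows = []
    start, end = cons.start, cons.end
    has_w = cons.watson_size > 0
    has_c = cons.crick_size > 0
    for gene in panel.genes:
        regions = panel.gene_regions(gene)
        overlap = np.zeros(len(cons), dtype=bool)
        for r in regions:
            overlap |= (start < r.end) & (end > r.start)
        total = int(overlap.sum())
        w = int((overlap & has_w).sum())
        c = int((overlap & has_c).sum())
        rows.append({
            "gene": gene,
            "unique_fragments": total,
            "watson_halves": w,
            "crick_halves": c,
            "half_imbalance": abs(w - c) / total if total else np.nan,
            "length": panel.gene_length(gene),
            # a fragment overlaps a region if its start falls within
            # (region length + fragment length); per-fragment density must
            # use this effective capture length or multi-exon genes would
            # look over-covered
            "effective_length": sum(r.length + CFDNA_FRAGMENT_BP
                                    for r in regions),
            "gc": panel.gene_gc(gene),
        })
    return pd.DataFrame(rows).set_index("gene")


def normalize_counts(counts: pd.DataFrame,
                     covariates: pd.DataFrame | None = None,
                     frac: float = 0.7) -> pd.Series:
    """Remove preparation/sequencing bias from per-gene fragment counts.

    Fragment density (count / gene length) is regressed on each covariate
    in turn with robust locally-weighted regression (LOWESS, 3 robustifying
    iterations so genuinely amplified genes are not shrunk), and divided by
    the fit.  Degenerate covariates (no spread, or too few genes) fall back
    to identity.  The result is rescaled to mean 1 (dimensionless).
    """
    eff = counts.get("effective_length", counts["length"])
    density = (counts["unique_fragments"] / eff).astype(float)
    norm = density.to_numpy().copy()
    if covariates is not None:
        for name in covariates.columns:
            x = covariates[name].reindex(counts.index).to_numpy(dtype=float)
            if x.size < 5 or np.ptp(x) < 1e-9 or np.ptp(norm) == 0:
                continue
            fit = lowess(norm, x, frac=frac, it=3, return_sorted=False)
            if np.any(fit <= 0):
                continue
            norm = norm / fit
    if norm.mean() <= 0:
        raise ValueError("degenerate fragment counts")
    return pd.Series(norm / norm.mean(), index=counts.index,
                     name="normalized_fragments")


def diploid_baseline(normalized: pd.Series) -> float:
    """Kernel-density mode of the normalized counts = the two-copy level.

    The mode is robust to a minority of amplified genes.  Ties resolve to
    the lower mode (amplification inflates counts, rarely deflates them).
    A warning is emitted if most genes sit far above the mode — the
    baseline is then unreliable.
    """
    values = normalized.to_numpy(dtype=float)
    if values.size < 3:
        raise ValueError("diploid baseline needs >= 3 genes")
    if np.ptp(values) < 1e-12:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 1024)
    dens = kde(grid)
    mode = float(grid[np.argmax(dens)])  # argmax takes the lower tie
    # pathological panels: a second substantial cluster away from the mode
    # means the two-copy level is ambiguous (e.g. most genes amplified)
    if (np.mean(values > 1.1 * mode) > 0.5
            or np.mean(values < 0.9 * mode) > 0.2):
        warnings.warn("substantial gene cluster away from the modal level; "
                      "diploid baseline unreliable", stacklevel=2)
    return mode


def plasma_copy_numbers(normalized: pd.Series) -> tuple[pd.Series, float]:
    """Scale normalized counts so the modal gene sits at 2.0 copies."""
    baseline = diploid_baseline(normalized)
    cn = 2.0 * normalized / baseline
    cn.name = "plasma_copy_number"
    return cn, baseline


def train_cn_stats(normalized_cohort: list[pd.Series]) -> NormalCnStats:
    """Per-gene mean/sd of normalized fragment counts over normals."""
    mat = pd.concat(normalized_cohort, axis=1)
    return NormalCnStats(mean=mat.mean(axis=1), sd=mat.std(axis=1, ddof=1),
                         n_samples=mat.shape[1])


def call_amplification(
    counts: pd.DataFrame,
    normalized: pd.Series,
    stats_: NormalCnStats,
    z_threshold: float = Z_AMPLIFICATION,
    reportable_cn: float = REPORTABLE_PLASMA_CN,
    genes: tuple[str, ...] | None = CNV_GENES,
) -> list[GeneCnCall]:
    """z-score normalized counts against the Normal Set and call genes.

    z is computed on normalized fragment counts (not on copy number);
    amplified means z above the 99.5%-confidence threshold, and the call
    is additionally flagged reportable when plasma CN reaches 2.2.
    ``genes=None`` calls every panel gene.
    """
    cn, _ = plasma_copy_numbers(normalized)
    targets = list(normalized.index) if genes is None else list(genes)
    out = []
    for g in targets:
        if g not in stats_.mean.index or g not in normalized.index:
            raise KeyError(f"gene {g!r} missing from normal CN stats or sample")
        z = float((normalized[g] - stats_.mean[g]) / stats_.sd[g])
        out.append(GeneCnCall(
            gene_symbol=g,
            unique_fragments=int(counts.loc[g, "unique_fragments"]),
            normalized_fragments=float(normalized[g]),
            plasma_copy_number=float(cn[g]),
            z_score=z,
            amplified=z > z_threshold,
            reportable=float(cn[g]) >= reportable_cn,
        ))
    return out


def plasma_cn_mixture(tumor_cn: float, tumor_fraction: float,
                      germline_cn: float = 2.0) -> float:
    """Plasma CN of the germline/tumor cfDNA mixture: (1-f)·g + f·t."""
    if not 0 <= tumor_fraction <= 1:
        raise ValueError("tumor fraction must lie in [0,1]")
    return (1 - tumor_fraction) * germline_cn + tumor_fraction * tumor_cn


def tumor_cn_from_plasma(plasma_cn: float, tumor_fraction: float,
                         germline_cn: float = 2.0) -> float:
    """Invert the mixture for the tumor CN; undefined at f = 0."""
    if tumor_fraction <= 0 or tumor_fraction > 1:
        raise ValueError("inverse mixture requires tumor fraction in (0,1]")
    return (plasma_cn - (1 - tumor_fraction) * germline_cn) / tumor_fraction


def cnv_lod_surface(
    gene: str,
    stats_: NormalCnStats,
    z_threshold: float = Z_AMPLIFICATION,
    tumor_cn_grid: np.ndarray | None = None,
    tumor_fraction_grid: np.ndarray | None = None,
    germline_cn: float = 2.0,
) -> dict:
    """Detectability of amplification over (tumor CN, tumor fraction).

    The per-gene counting noise (normal-cohort sd, converted to copy
    units) sets the minimal detectable plasma-copy excess at the z
    threshold, ``lod = z_threshold * sd_cn``; the grid reports detection
    probability ``P(z > threshold)`` for each mixture.
    """
    if gene not in stats_.mean.index:
        raise KeyError(f"gene {gene!r} missing from normal CN stats")
    sd_cn = float(germline_cn * stats_.sd[gene] / stats_.mean[gene])
    lod_extra = z_threshold * sd_cn
    t = np.asarray(tumor_cn_grid if tumor_cn_grid is not None
                   else np.linspace(2, 20, 37), dtype=float)
    f = np.asarray(tumor_fraction_grid if tumor_fraction_grid is not None
                   else np.linspace(0, 0.3, 31), dtype=float)
    excess = f[:, None] * (t[None, :] - germline_cn)  # plasma-copy excess
    detect = 1.0 - stats.norm.cdf(z_threshold - excess / sd_cn)
    return {
        "gene": gene,
        "sd_copies": sd_cn,
        "lod_extra_copies": lod_extra,
        "tumor_cn_grid": t,
        "tumor_fraction_grid": f,
        "detection_prob": detect,
    }


def write_cnv_report_tsv(calls: list[GeneCnCall], path) -> None:
    """TSV report: gene, fragments, normalized, plasma CN, z, flags."""
    with open(path, "w") as fh:
        fh.write("gene\tunique_fragments\tnormalized\tplasma_cn\tz"
                 "\tamplified\treportable\n")
        for c in calls:
            fh.write(f"{c.gene_symbol}\t{c.unique_fragments}\t"
                     f"{c.normalized_fragments:.4f}\t"
                     f"{c.plasma_copy_number:.3f}\t{c.z_score:.3f}\t"
                     f"{int(c.amplified)}\t{int(c.reportable)}\n")
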