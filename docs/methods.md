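# Methods

## The problem

Circulating cell-free DNA (cfDNA) is mostly ~166 bp double-stranded
fragments, overwhelmingly leukocyte-derived. In a cancer patient, a small
fraction of those fragments (ctDNA) carries tumor variants, often well
below 1% mutant allele fraction (MAF). At such fractions, conventional
read-level calling fails: a per-base error rate of ~10⁻³ over a wide
(tens-of-kbp) panel produces hundreds of spurious non-reference positions
in exactly the 0.05–5% band where somatic signal lives, and a 1% per-base
false-positive rate alone would imply ~780 false calls over a 78 kbp
target. Wide-panel ctDNA calling therefore requires per-base specificity
on the order of 10⁻⁶ or better.

`cfduplex` implements the duplex-barcode "digital" strategy for this
problem: tag each strand of every input molecule, sequence redundantly,
reconstruct the original molecules in software, and only believe a base
that both strands of the same physical molecule report independently. It
also implements the matching per-base noise model, the MAF quantifier,
the unique-fragment copy-number caller, a synthetic cfDNA generator that
supplies ground truth for every stage, and the in-silico analytic
validation harness.

## Molecule reconstruction (digitization)

Reads carry a heptamer barcode per strand plus fragment coordinates.
Molecule identity is the composite key (barcode pair, start, end);
barcodes are deliberately non-unique (4⁷ = 16,384), so identity rests on
the combination with fragment endpoints. Collisions (two molecules with
identical coordinates and both barcodes) merge silently; the simulator
measures this rate (`MoleculeBatch.barcode_collision_rate`) and it is
negligible at the depths modelled here.

The stages:

1. **Quality filtering.** Bases below Q20 are masked; reads more than
   half masked are dropped.
2. **Family grouping.** Reads partition by the exact key (barcode pair,
   start, end, strand). No error-tolerant barcode matching is attempted.
3. **Strand consensus.** Per position, the base carried by at least
   `max(1, ceil(q·n))` of the `n` unmasked members is called, else the
   position is masked. The supermajority `q = 0.75` is a package choice
   (no published voting rule exists): it is the smallest threshold at
   which a single errored read can never flip a family of two or more,
   while singleton families still pass their base through. Ties are
   impossible above `q = 0.5` except in degenerate cases, where the
   alphabetically first base would win; in practice ties always fail the
   count test and mask.
4. **Duplex comparison.** The two strand consensi are compared
   position-wise: agreement → *duplex-confirmed*; one strand masked or
   absent → *single-strand-only* (kept, flagged); disagreement →
   *discordant, no call*. Sequencing errors, PCR "jackpot" errors and
   single-strand DNA damage all live on one strand, so the duplex veto
   removes them categorically rather than statistically.

For speed, consensus may be computed only over the panel-overlapping
span of each fragment (`digitize_reads(..., panel=...)`); off-panel
flank bases can never enter a pileup, and a regression test asserts the
clipped and full reconstructions give identical panel-base pileups.
Molecules overlapping no panel region are dropped in clipped mode.

## Per-base noise model

Every (panel position, alternate base) pair gets its own background
distribution: the mean and SD of the duplex-confirmed minor-base
fraction across a cohort of germline-only normal samples, excluding each
sample's own germline SNP sites (any site/alt above 25% minor fraction
in that sample). The detection threshold is

    max(mean + k·SD, min_support / unique_depth)

with `k = 10` and `min_support = 2`. Neither constant is externally
specified; they are calibrated package defaults chosen so that a fresh
simulated normal essentially never exceeds threshold at any site (the
analytic-specificity regime) while two duplex-confirmed mutant molecules
at a clean site always clear it. The floor comparison is inclusive
(`fraction ≥ threshold`): with a strict inequality the 2-molecule floor
would silently require 3 molecules, which would contradict the assay's
observed detection structure (see below).

## SNV calling and MAF

A site/alt is called when it has ≥ 2 supporting unique molecules, at
least 1 duplex-confirmed, and its molecule fraction reaches the site
threshold. MAF = mutant unique molecules / all unique molecules with a
called base at the position; it is a fraction in [0,1] internally and a
percent only in reports.

Calls in [35%, 65%] MAF classify as heterozygous germline, ≥ 85% as
homozygous germline, the rest somatic; an optional annotation table
(standing in for curated germline/somatic databases) overrides the
windows. The windows are deliberately wide — ctDNA fractions are
normally far below 35% — and are package choices.

Quantification uncertainty is assigned from an empirical bin table
(relative error 4% above 10% MAF down to 30% in the 0.25–0.5% stratum;
absolute error = relative × MAF). Bin-boundary membership follows the
two validated worked examples (10% MAF → ±0.4 points, 1% MAF → ±0.2
points); 0.25% MAF is the reporting floor, below which calls are kept
but flagged extrapolated.

### Why the limit of detection is 0.25%

At 3,000 unique molecules per position and 80% conversion, a variant at
true MAF *m* yields roughly Binomial(3000, 0.8·m) recoverable mutant
molecules. The 2-molecule rule then gives detection probability
P(X ≥ 2): ≈ 0.98 at m = 0.25% (λ = 6) but ≈ 0.69 at m = 0.1%
(λ = 2.4). The >80%-detection limit of detection therefore lands on
0.25%, while roughly a third of 0.1% variants are still detected — the
caller is conversion-limited, not noise-limited.

## Copy number

Unique fragments are counted per gene (a fragment spanning two genes
counts once for each). Counts are converted to densities using an
*effective capture length* Σ(region length + 166) per gene — a fragment
overlaps a region if its start falls anywhere in that window, so raw
per-bp density would overstate multi-exon genes. Densities are
normalized by robust LOWESS fits against available covariates
(capture-efficiency proxy, GC, length; 3 robustifying iterations so a
genuinely amplified gene is not regressed away; identity fallback for
degenerate covariates or < 5 genes). The per-strand-half counts and
their imbalance |W−C|/total are retained as a QC covariate; the
production formulation of half-imbalance correction is not public, so it
is not used in normalization here.

The two-copy level is the kernel-density mode (Silverman bandwidth) of
the normalized values — robust to a minority of amplified genes, with
ties resolved to the lower mode and a warning when a substantial cluster
sits away from the mode. Plasma CN = 2 × normalized / mode.

Plasma CN mixes germline and tumor compartments:
`plasma = (1−f)·g + f·t` (tumor CN 10 at f = 5% → 2.4 plasma copies), so
calling works on small shifts. A gene is *amplified* when its z-score —
computed on normalized fragment counts against a normal cohort — exceeds
2.5758 (the 99.5% normal quantile), and *reportable* when plasma CN ≥
2.2; the reported amplification call requires both. The minimal
detectable plasma-copy excess is `2.5758 × SD` in copy units
(`cnv_lod_surface`), and the detection-probability grid over
(tumor CN, tumor fraction) follows from the mixture.

## The synthetic generator

The generator emulates, per sample: fragment lengths N(166, 10) (gDNA
contaminants uniform 600–1500 bp, germline alleles only, mass-ratio
knob); uniform fragment starts giving a target unique-molecule coverage
per panel base (default 3,000); germline het/hom SNPs (Binomial(n, ½) /
all molecules) with 12–27 SNPs per donor (uniform, mean ≈ 18-19);
somatic carriers Binomial over covering cfDNA molecules at `true_maf`;
amplification via extra tumor-origin molecules matching the mixture
expectation; molecule-level conversion (default 0.80, both strands
recovered together); per-strand PCR families of 1 + Poisson(0.7) reads
(mean 1.7, consistent with ~8,000× raw over ~4,800 recovered strand
families at 3,000×/0.8 — no published family-size law exists); PCR
lineage errors shared by a random subset of one strand's family
(10⁻⁵/base/family); uniform sequencing errors at 10⁻³/base (a typical
Q30-scale platform rate, not a published value); and two-valued base
qualities with 1% below Q20.

Reads are emitted in reference orientation with the physical-strand
label retained; duplex comparison needs only the label, so
reverse-complement bookkeeping is omitted. One full-length read per
strand copy replaces 150 bp paired ends: consensus depends on
family/strand structure, not read pairing.

What the generator does **not** model: capture/GC bias beyond a
per-region multiplier, trinucleotide-context or oxidative damage
signatures, indels, fusions, barcode synthesis errors, and real
inter-donor variability. Passing tests therefore demonstrate the
*logic* of error suppression and quantification under the stated
statistical assumptions, not performance on real libraries —
position-correlated artifacts in real data are handled only insofar as
the per-site baseline absorbs recurrent ones.

## Validation harness and problem sizes

The harness reruns the analytic studies in silico at desk scale:

* **Dilution series**: 29 SNVs × 3 replicates per level on a
  single-region fragment-sized panel at full unique depth (3,000×);
  the level grid adds 0.25% between the prepared 0.3% and 0.1%
  titrations so the >80% rule can land on it.
* **Accuracy study**: donor germline SNP sets spiked at 2.5–5% MAF into
  host backgrounds; tallies over every panel base give the contingency
  table; scaled to 10 samples × 2 kbp at 1,000× in tests (the cumulative
  1.56 Mbp study shrinks proportionally).
* **Split-sample robustness**: 24 variants, log-uniform MAFs 0.1–30%,
  two independent aliquots, least-squares R² on paired MAFs plus
  concordance by MAF stratum.
* **CNV pools**: plasma CN {2.1, 2.2, 2.6, 3, 4} in duplicate at 5/15/30
  ng genome-equivalent inputs on a 10-gene desk panel; recovery asserted
  within ±0.1 copies on the per-level mean.

Exact binomial (Clopper–Pearson) intervals come from
`statsmodels.proportion_confint(method="beta")` and are cross-checked in
tests against an independent numeric inversion of the binomial tails.

## Numerical and degenerate-input choices

* All coordinates are 0-based half-open; 1-based only in VCF output,
  which is byte-deterministic (fixed ordering and float formats).
* Consensus voting uses exact integer counts (packed 16-bit counters);
  `ceil(q·n)` is evaluated with a 10⁻⁹ guard against float round-off.
* Zero-depth sites yield no call; empty panels, < 2 normals, < 3 genes
  for the CN mode, and inverse-mixture at f = 0 all raise.
* KDE degenerates (single point, zero spread) fall back to the point
  value; LOWESS falls back to identity normalization.
* Every stochastic function takes an explicit `numpy` Generator or seed.

## Known limitations

* Specificity claims at the 10⁻⁶/base scale are demonstrated on scaled
  panels (tests cover ~10⁴–10⁵ site-alt trials per run), not a full
  1.56 Mbp replication in a single test run.
* Strand-bias filtering beyond the duplex veto is not implemented (no
  public specification of it exists).
* Single-strand-only molecules support calls only through the
  `min_duplex` knob; with the default (≥1 duplex-confirmed) they add
  depth and MAF resolution but cannot create a call alone.
* The panel is a synthetic analog: real exon coordinates of the
  commercial assay are not reproduced, only the 54-gene / 78 kbp scale.
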