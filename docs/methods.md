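# Methods

`globtx` analyses non-genetic heterogeneity in the *global* transcription
rate of clonal mammalian cell populations — the gene-nonspecific, temporally
modulated component of transcription that scales all genes together. The
package contains (i) a stochastic simulator of multi-copy nascent-RNA
reporters under global modulation, (ii) synthetic-data generators with full
ground truth for every downstream stage, (iii) image-based quantification of
nascent transcription sites, (iv) PCNA-based cell-cycle annotation and
pseudotime alignment, (v) the noise and CV decomposition statistics, and
(vi) single-cell intron/exon count-matrix proxies. This note records the
models, parameter choices and numerical decisions.

## Two-state transcription model with global modulation

Each reporter locus follows the telegraph model

    OFF <-> ON   (k_on, k_off)
    ON -> ON + nascent        (rate k_m * m(t))
    nascent -> mature         (rate k_s per molecule)

with defaults `k_on = 1.5 h^-1`, `k_off = 0.75 h^-1`, `k_m = 0.15 min^-1`,
`k_s = 0.2 min^-1`, giving ON occupancy `p_on = 2/3` and a stationary
standing nascent count of `p_on * k_m / k_s = 0.5` per locus. The quantity
reported on the sampling grid is the *standing* nascent-molecule count,
because that is what a PP7/MS2 focus intensity reports; the per-interval
initiation count is exposed as a secondary channel. A two-step elongation
variant splits the maturation into two sequential stages at rate `2 k_s`
each, preserving the mean dwell time `1/k_s` and hence the stationary mean
of the standing total.

Global (gene-nonspecific) modulation multiplies `k_m` by
`m(t) = 1 + A s(t)` with `0 <= A < 1`: a sine (`s = sin(2 pi t / T +
phase)`), a constant, or a smoothed random series (seeded white noise on
the sample grid, moving-average smoothed over a 4 h window by default,
renormalized to mean 1 and scaled so its temporal SD equals `A / sqrt(2)`,
matching the sine; clipped at 0.05 before a final mean renormalization to
keep the multiplier positive). Within a simulated cell all reporters share
one realization of `m(t)` (the gene-nonspecific signal) while their
reaction randomness is independent (the gene-specific noise).

**Time-varying propensity.** `m(t)` is evaluated piecewise-constant on a
1-min subgrid (window midpoints). Event times are then drawn by inverting
the integrated total propensity across windows — exact for a
piecewise-constant signal and rejection-free. Each event consumes exactly
one uniform for the exponential target and one for the reaction choice
(order: promoter switch, initiation, stage-1 maturation, stage-2
maturation), which makes the trajectory reproducible draw-for-draw; the
test suite verifies sample-by-sample agreement with an independently coded
brute-force SSA on a frozen random stream. Thinning against a per-window
maximum would be an equally exact alternative; the inversion was chosen
because it avoids rejected draws and keeps the draw protocol fixed.

**Initial state.** The promoter starts in ON with probability `p_on` and
the nascent count is drawn Poisson at the conditional stationary mean, so
single-cell-cycle simulations start near stationarity. Long-horizon
statistics additionally discard a configurable burn-in (default 2 h).

## Reporter-design criterion

The minimum number of reporter copies needed to read out global
fluctuations is the smallest `n` such that the replicate-averaged temporal
CV² of the `n`-copy summed trace is below `2 CV_global²`, where
`CV_global` is the temporal CV of `m(t)` on the same sampling grid (the
empirical grid CV by default; the analytic `A/sqrt(2)` is available). The
scan is linear in `n` with 50 replicates per candidate by default, 48 h
horizon, 10-min sampling, 2 h burn-in. Under sinusoidal modulation at
`A = 0.7`, `T = 12 h` the answer is 10: the per-locus intrinsic CV² is
~2.4 and shrinks as 1/n in the sum, crossing the global CV² (~0.245)
near n = 10. A mean-field ODE mode (no reaction noise) is provided as an
oracle; it returns 1 because a noiseless reporter carries `m(t)` exactly.
The period for this headline scan defaults to 12 h — the periodicity the
imaging analyses measure — and is an exposed parameter, as is the
amplitude. Regulon variants scale both switching rates by 1/5 (label `X`)
or 5 (label `Y`).

## Noise statistics

For two co-measured traces `E1, E2` of one cell (expectations are temporal
means over the analysis window):

    eta_int² = <(E1-E2)²> / (2 <E1><E2>)
    eta_ext² = (<E1 E2> - <E1><E2>) / (<E1><E2>)
    eta_tot² = (<E1² + E2²> - 2 <E1><E2>) / (2 <E1><E2>)

`eta_int² + eta_ext² = eta_tot²` is an algebraic identity and is asserted
to 1e-12. All C(n,2) pairs of a cell are enumerated (45 pairs for 10
traces) and the RMS over pairs is the cell's fluctuation strength; a
slightly negative pair-mean extrinsic term (finite sampling) is kept as a
signed square root. Note a model property the simulator makes explicit:
because the global signal enters multiplicatively through `k_m`, the
extrinsic term is scale-free in the transcription level — raising `k_m`
lowers `eta_int` (Poisson-like 1/mean scaling) but leaves `eta_ext`
unchanged. Experimental observations that both terms fall with induction
therefore involve effects beyond a pure `k_m` change; the tests assert
only the intrinsic scaling.

## Static/dynamic CV decomposition

Given the pseudotime-aligned rate matrix `E_{t,c}` (cells with complete
M-to-M cycles, resampled to a 101-point 0-100% grid):

* `CV_total`: SD/mean over all `(t, c)`;
* `CV_dynamic`: CV over pseudotime of the cross-cell mean trajectory;
* `CV_static`: CV across cells of the per-cell time averages `E_c`;
* `CV_residual = sqrt(CV_total² - CV_dynamic² - CV_static²)`, clamped at 0
  with a flag when the radicand is negative (the decomposition is not a
  strict variance partition).

Population SDs (ddof = 0) are used throughout so degenerate cases resolve
exactly, and the output is invariant under global rescaling. The residual
term absorbs the intrinsic noise of the summed pseudo-reporter, which is
why it shrinks with reporter copy number — the package's recovery tests
assert `CV_residual(20 copies) < CV_residual(5 copies)` on 200-cell
synthetic populations and recovery of planted `CV_static = 0.3` (±0.03)
and `CV_dynamic = 0.2` (±15% relative).

The binomial null asks whether static heterogeneity could arise from
random, independent locus activation: with `N` loci active independently
with probability `p` (estimated as mean active sites / N), the null CV of
the time-averaged rate is `sqrt((1-p)/(N p))`; an observed static CV above
it indicates heterogeneity beyond random activation.

**Periodicity.** The unbiased sample autocorrelation of the mean-subtracted
trace is smoothed with a 7-lag moving average (suppressing the fast
intrinsic-noise shoulder and ACF sampling noise) and the lag of the first
local maximum above a 0.05 prominence, starting at lag 3, estimates the
period. On a noiseless 12 h sine sampled every 10 min over 48 h the
finite-window boundary term can shift the peak by one lag (12 h ± 10 min);
the replicate median on 20-copy simulated sums is accurate to one sample.
The 0.05 default suits strongly periodic reporter sums; discriminating pure
white noise at ~300 samples needs a higher bar (the ACF noise floor there
is ~0.06).

**Paired correlations versus scrambled identities.** Observed per-pair
Pearson correlations (traces: regulon pairs, fused-nuclei pairs) or the
cross-pair Pearson (scalars: mother/daughter time-averaged rates) are
compared to a null built from 1000 seeded random re-pairings. Heritability
is planted as a bivariate log-normal on the log scale, so recovery is also
measured there; the raw-scale Pearson of log-normal multipliers is
attenuated (~0.59 for a planted 0.6 at CV 0.3). Both daughters of a mother
are used by default, which makes the 200 "pairs" of a 100-mother population
mildly dependent.

## Synthetic populations and the two-pulse waveform

Per-cell mean multipliers `g_c` are log-normal with mean 1 and CV
`cv_static`; daughters inherit `log g` with correlation `rho`
(independent draws conditioned on the mother). Each traced cell is
simulated over exactly one cell cycle (24 h default, 10-min sampling) with
`k_m` scaled by `g_c` and modulated by a stylized two-pulse cell-cycle
waveform: two Gaussian bumps (centres at 15% and 70% of the cycle, widths
8% and 10%, second bump 0.9 relative weight) standardized so the
multiplier has mean 1 and temporal CV equal to the `dynamic_amplitude`
parameter (default 0.2). The shape — peaks in G1 and at late-S/G2, trough
in mid-S — is a stylized stand-in for the measured profile and is never
used as a numeric target; phase boundaries G1/S at 30%, S/G2 at 70% and M
at 95% of the cycle are the generator's conventions shared with the PCNA
renderer.

## Image rendering and quantification

The renderer produces a nuclei channel (uniform nuclear fluorophore),
a spot channel (pixel-sampled Gaussian PSFs, default sigma 1.5 px,
amplitude proportional to the instantaneous nascent count, on a 2nd-order
polynomial background, distributed over z slices), and a PCNA-like channel
(uniform in G1; puncta whose amplitude ramps through S, peaks at S/G2 and
dissipates in early G2; nucleus absent in M), all 16-bit with Gaussian
read noise and optional Poisson shot noise. Loci are laid out by rejection
sampling with a guaranteed minimum Euclidean separation of 6 PSF sigma
(the layout restarts rather than accept a violation). Ground truth records
masks, phases and per-spot intensities.

Quantification follows the standard chain: least-squares 2nd-order
polynomial background flattening; Sobel-edge segmentation (Otsu threshold
by default, 2 px dilation, hole filling, 200 px minimum area);
greedy nearest-centroid nucleus tracking with a displacement gate and
mask-disappearance division detection; per-slice background elimination,
maximum projection, LoG filtering and local-maxima detection at 5x the
MAD-based noise level; and the dimensionless spot statistic

    intensity = sum over the 3x3 signal square of (pixel - bg) / bg,

with `bg` the median of the 56 pixels of the centred 9x9 square minus the
centred 5x5 square. `sum(signal - bg)` is read as the sum of the nine
(pixel − bg) differences — the alternative `(sum pixel) − bg` differs by
`8 bg` and cannot vanish on uniform frames. Undetected loci contribute
intensity 0; the per-cell global transcription rate at a frame is the sum
over that cell's sites, with mean site intensity and active-site count as
companion statistics.

Because the measured `bg` annulus sees the PSF tails, the generator's
`true_intensity` is the noise-free expectation of the statistic itself,
`amp (K3 - 9 medG) / (bg + amp medG)` with `K3` the 3x3 PSF window sum and
`medG` the annulus-median PSF value — not the bare `amp K3 / bg`. Round
trips at SNR 10 achieve spot recall and precision ≥ 0.95 and per-frame
summed rates within 10% of truth.

## Cell-cycle annotation

`PCNA_var = (max - mean)/mean` over the nuclear pixels is scale-invariant,
zero for a uniform nucleus, and rises when replication foci form. Within
each inter-mitosis interval (M = absent mask) the trace is smoothed with a
5-frame moving median; G1/S is the first frame exceeding the
early-interval baseline (median of the first quartile) by 3 MADs, with the
MAD floored at 10% of the baseline so a flat-but-noisy G1 cannot trigger a
spurious call; S/G2 is the argmax after G1/S, accepted only if the signal
subsequently dissipates by at least 20% of the peak-minus-baseline (a
replication-block plateau therefore yields no S/G2 call). Pseudotime is
linear 0-100% between consecutive M events; rate traces are resampled onto
a 101-point percent grid by linear interpolation, which removes
cycle-duration differences while preserving time averages to <1% on smooth
traces. Cells never observed through mitosis enter only time-averaged
(static) statistics.

## Count-matrix generator and proxies

The generator emulates a plate-based, spike-in-normalized single-cell
protocol. Per cell: capture factor `s_c` (log-normal, CV 0.2), global-rate
factor `g_c` (log-normal, CV `global_rate_cv`), cell-cycle position
`phi_c` (uniform) entering through the two-pulse profile `m(phi)`.
Per gene: synthesis rate `alpha_g` (log-normal, sigma 1.2, scaled to a
20,000-count mean intron depth), degradation `delta_g` (log-normal, CV
0.3). Counts are Poisson with intron rate `s_c g_c m_gc alpha_g`, exon
rate `intron rate / delta_g * 5`, and spike-ins Poisson at `s_c * 300`
(so the default QC window of 100-600 retains most cells). The modulation
is applied per gene as `m_gc = 1 + w_g (m(phi_c) - 1)` with susceptibility
`w = 1 / 0.6 / 0.3` for low/medium/high expression tiers — low-expression
genes feel the full modulation while highly transcribing genes are
buffered, which is what produces the tier contrast in the binned profiles;
a `uniform` option applies `w = 1` everywhere. Options exist to decouple
exon counts from the global factor and to plant a single regulator gene
whose exon counts read out `g_c` (the ranking round-trip fixture).

Analyses: QC (spike-in totals within [100, 600]; genes detected in ≥ 100
cells — dataset parameters); spike-in normalization (counts scaled by
median-spike-in/spike-in; the spike-in column is scaled identically, making
the operation idempotent); per-cell proxies (total intron = transcription
rate, total exon = transcriptome size, intron/exon ratio = degradation
rate, valid under steady-state assumptions only); explanatory power as
squared Pearson correlation; 14 equal-occupancy pseudotime bins by
expression tier (bottom 30% / 30-70% / top 30% of mean exon expression);
a 50-bin Poisson counting null (`CV_null = 1/sqrt(mean total)`); a
GENIE3-style regulator ranking re-implemented from scratch as a single
extra-trees regression (200 trees, sqrt feature subsampling, seeded) of
the intron proxy on all genes' exon profiles, ranked by impurity
importance; and the modulation index (median expression of a marker-gene
module per sample).

## What the synthetic data does and does not show

The generators plant exactly the structures the statistics estimate
(log-normal static factors, a shared smooth cell-cycle modulation,
Poisson counting noise, Gaussian optics), so passing tests demonstrate
correctness of the estimators and the pipeline plumbing — not robustness
to real-data pathologies: segmentation of touching or irregular nuclei,
z-drift and photobleaching, transcriptome-wide gene-gene correlation
beyond a single global factor, empty droplets or doublets, or deviations
from the steady-state assumption behind the degradation proxy. The
rendered PCNA texture and the two-pulse waveform are stylized; their role
is to carry a known answer through the pipeline, not to mimic microscopy.

## Problem sizes and determinism

Default study sizes keep every stage at desk scale: the reporter-design
scan uses 50 replicates per candidate copy number; CV-decomposition
recovery uses 200 cells at 5 and 20 reporters over one 24 h cycle;
heritability uses 100 mothers with two daughters each; imaging round trips
render 5 nuclei on 256x256 frames for 10 frames; count-matrix studies use
a few hundred cells and 80-200 genes. Every stochastic component draws
from `numpy.random.default_rng` seeded explicitly; the pipeline derives
per-stage seeds from one global seed via `SeedSequence.spawn` in a fixed
stage order, and rerunning any configuration reproduces identical numbers.
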