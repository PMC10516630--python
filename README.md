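# globtx

Tools for detecting and decomposing **non-genetic heterogeneity in the
global transcription rate** — the gene-nonspecific modulation that scales
transcription of all genes in a cell together. Within a clonal population
this rate fluctuates along the cell cycle inside each cell (*dynamic*
heterogeneity) while its time average differs between cells and is
partially heritable (*static* heterogeneity). Because snapshot assays
cannot tell these modes apart, the package is built around temporal
reporters: many co-integrated nascent-RNA reporters (PP7/MS2-style) whose
summed focus intensity averages away gene-specific bursting noise and
leaves the shared global signal.

It is aimed at quantitative cell biologists and systems-biology modellers
who want to simulate such reporter systems, validate the estimators on
fully known ground truth, or apply the same statistics to their own trace
or count data.

## What is inside

* `globtx.twostate` — exact stochastic simulation of the two-state
  (telegraph) model, `OFF <-> ON -> nascent -> mature`, with the
  initiation rate `k_m` multiplied by a global signal
  `m(t) = 1 + A s(t)` (sine, constant, or smoothed random); reporter-design
  scans answering *how many summed copies make the global signal visible*
  under the criterion `CV²_sum < 2 CV²_global`.
* `globtx.synthetic` — ground-truth generators: cell populations with
  planted static CV, heritability and a two-pulse cell-cycle waveform;
  multi-channel time-lapse stacks (nuclei, PSF spots on a polynomial
  background, PCNA-like texture); spike-in-normalized intron/exon count
  matrices with a planted per-cell global-rate factor.
* `globtx.imaging` — background flattening, Sobel/Otsu nuclei
  segmentation, nearest-centroid tracking with division detection, LoG
  spot detection, the `sum(signal-bg)/bg` intensity statistic, and
  per-cell global transcription rates.
* `globtx.cellcycle` — `PCNA_var = (max-mean)/mean` phase annotation
  (G1/S = first rise, S/G2 = dissipating maximum, M = mask disappearance)
  and resampling of rate traces onto 0–100% cell-cycle pseudotime.
* `globtx.noise` — pairwise intrinsic/extrinsic noise
  (`η²_int = ⟨(E1−E2)²⟩ / 2⟨E1⟩⟨E2⟩`, `η²_ext = cov/⟨E1⟩⟨E2⟩`, RMS over all
  locus pairs per cell), the `CV_total / CV_dynamic / CV_static /
  CV_residual` decomposition, a binomial null for time-averaged rates,
  autocorrelation periodicity, and paired correlations versus
  scrambled-identity nulls.
* `globtx.scrna` — spike-in QC and normalization, total-intron
  transcription-rate proxy, intron/exon degradation proxy, explanatory
  power (R²), cell-cycle binning by expression tier, a Poisson CV null,
  tree-ensemble regulator ranking, and the module-median modulation index.
* `globtx.pipeline` / the `globtx` CLI — configuration, seeding and
  end-to-end orchestration.

See `docs/methods.md` for models, parameter defaults and numerical
decisions.

## Worked example

How many reporter copies are needed to see a 70%-amplitude, 12 h-period
sinusoidal global modulation through the bursting noise?

```python
from globtx.twostate import (TwoStateParams, GlobalWaveform, SimConfig,
                             min_reporters_for_detection)

n, scan = min_reporters_for_detection(
    TwoStateParams(),                     # k_on 1.5/h, k_off 0.75/h, k_m 0.15/min, k_s 0.2/min
    GlobalWaveform(kind="sine", amplitude=0.7, period_hr=12.0),
    SimConfig(duration_hr=48.0, dt_sample_min=10.0),
    max_n=15, n_replicates=50, seed=1234,
)
print(n)
print(scan.tail(3).to_string(index=False))
```

```
10
  n  mean_cv2  threshold  satisfied
  8  0.582124   0.511548      False
  9  0.541593   0.511548      False
 10  0.508635   0.511548       True
```

A single reporter's temporal CV² (~2.9) is dominated by gene-specific
bursting; summing `n` copies shrinks that part as `1/n`, and at 10 copies
the summed trace's CV² (0.509) drops below twice the global signal's CV²
(threshold 0.512), making the waveform readable.

Running the full synthetic pipeline (population → CV decomposition,
noise RMS, periodicity, heritability, count-matrix proxies):

```bash
globtx pipeline --seed 1 --out demo_out
```

prints, among others (planted values: static CV 0.3, dynamic CV 0.2,
mother–daughter correlation 0.6, 12 h period, global-rate CV 0.3 in the
count matrices):

```json
{
  "cv_decomposition": {"cv_total": 0.572, "cv_dynamic": 0.196,
                        "cv_static": 0.319, "cv_residual": 0.433},
  "period_hr": 11.83,
  "heritability": {"observed_r": 0.574, "null_mean_r": -0.004,
                    "p_value": 0.001, "n_pairs": 120},
  "scrna": {"r2_intron_proxy": 0.999, "r2_ratio_proxy": 0.0003}
}
```

The decomposition recovers the planted static and dynamic components; the
residual CV is the intrinsic noise of the summed pseudo-reporter and
shrinks with copy number. The total-intron proxy explains transcriptome
size almost completely while the intron/exon (degradation) proxy explains
almost none of it — the signature that transcriptome-size heterogeneity is
driven by the global transcription rate.

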