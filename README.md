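# circaturn

Circadian protein-turnover analysis for pulsed-SILAC/TMT proteomics.

## The problem

In non-dividing mammalian cells, global protein synthesis varies over
the ~24-h circadian cycle, yet total protein content barely changes.
The resolution of this apparent paradox is that protein **degradation
varies in phase with synthesis**: the two rhythms cancel in abundance
and instead produce a daily rhythm of protein **turnover** — the
proteome is renewed on a daily schedule without changing composition.
Detecting this requires measuring synthesis and abundance for the same
protein, simultaneously, across the cycle.

A pulsed-SILAC/TMT experiment does exactly that. At each timepoint a
culture is switched to medium with heavy arginine/lysine for a fixed
labelling window (6 h, or 1.5 h with a fully heavy *booster* channel to
aid MS detection), so newly made protein carries heavy mass. All
samples are TMT-multiplexed and quantified together: for every peptide,
the heavy form reports synthesis within the window and heavy + light
report total abundance.

`circaturn` implements the complete downstream analysis for such data,
from the MaxQuant `evidence.txt` peptide table to per-protein rhythm
calls, plus a ground-truth kinetic simulator that makes every stage
verifiable:

- **evidence** — read/validate evidence tables; classify peptides heavy
  (≥ 1 Arg10/Lys8 modification) vs light; collapse identical
  (sequence, label-state) entries by summing reporter intensities;
  exclude peptides with missing values.
- **quantify** — heavy-incorporation QC, sample-loading normalization
  (equalise summed intensity across TMT channels), heavy∧light pair
  filtering, roll-up to protein *synthesis* (Σ heavy) and *abundance*
  (Σ all) series, and relative turnover = mean over timepoints of
  heavy/total ∈ [0, 1].
- **rhythm** — three detectors at fixed period *p* (24 h default, 25 h
  selectable): a rank-based **umbrella test** in the spirit of RAIN
  (rise-to-peak-then-fall alternative, Jonckheere–Terpstra pair counts,
  exact permutation null at small n, Bonferroni over candidate peaks),
  one-way **ANOVA** on log values with the two sampling days as
  replicates, and a **damped cosine fit**
  y = (mx + c) + a·e^{kx}·cos((2πx − r)/p)
  compared against a straight line by the extra-sum-of-squares F test.
  Phase is reported as circadian time of the peak (reporter peak = 0);
  amplitude as the per-day peak/trough fold change, averaged.
- **classify** — four rhythmicity categories (both / synthesis-only /
  abundance-only / neither) at p < 0.05 per detector, Fisher's exact
  test for synthesis×abundance overlap, Mann–Whitney comparison of
  fold-change distributions, circular phase histograms.
- **complexes** — map proteins onto an annotated complex table, compute
  within-complex turnover SD (complexes with > 4 detected subunits),
  and test for coordination against a size-structure-preserving random
  resampling null.
- **assays** — closed-form bulk-label calculators:
  pulse-chase 100·(1 − chase/pulse), puromycin±bortezomib
  100·(1 − Puro/(Puro+BTZ)), natural-abundance-corrected heavy-UMP %,
  and eIF2α phosphorylation fold induction.
- **simulate** — kinetic generator
  dP/dt = s(t) − k(t)·P with s(t) = s₀(1 + A_s cos(2π(t − φ_s)/T)) and
  k(t) = k₀(1 + A_k cos(2π(t − φ_k)/T)); windowed heavy signal includes
  degradation of nascent protein within the window; peptide-level
  lognormal noise, missing values, decoys, booster channels, and
  complex-coordinated turnover, all with recorded ground truth.

## Worked example

`examples/rhythm_detection.py` simulates one protein with coupled
synthesis/degradation rhythms (synthesis fold change 2 peaking at hour
6, degradation in phase), samples it on the two-day design with 5%
noise, and runs the detectors:

```
synthesis (heavy)  umbrella p=0.0286 anova p=0.0001 phase=6 h fold-change=1.79
abundance (total)  umbrella p=1.0000 anova p=0.5534 phase=18 h fold-change=1.09
damped cosine vs line: F=42.3, p=5.93e-03, fitted peak at 6.0 h
```

The heavy (synthesis) series is called rhythmic by both detectors with
the correct peak phase and a fold change of ~1.8 (the 6-h labelling
window slightly attenuates the instantaneous fold change of 2), while
total abundance is flat — the coupled-rhythm signature. The other
examples cover quantification from raw evidence
(`simulate_and_quantify.py`), complex-coordination testing
(`complex_coordination.py`, coordinated complexes give within-complex
SDs ~9× below the random null), and the bulk calculators
(`bulk_assays.py`).

A thin CLI wraps the same library calls for shell use:

```bash
circaturn simulate --n-proteins 200 --seed 7 --n-complexes 10 --out fixture/
circaturn run-all --config config.yaml   # quantify -> rhythms -> classify -> complexes
```

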