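"""Bulk labelling calculators and their use in rhythm fitting.

Each calculator converts one pair of raw assay signals into a derived
percentage; a time series of such percentages can then be tested for a
circadian oscillation with the damped cosine fit.
"""

import numpy as np

from circaturn.assays import (
    degradation_pct_pulse_chase,
    degradation_pct_puro_btz,
    heavy_ump_pct,
    eif2a_fold_induction,
)
from circaturn.rhythm import fit_line, fit_damped_cosine, compare_fits_f_test
from circaturn.simulate import simulate_assay_series

# pulse-chase: 20% of nascent protein degraded within the 1-h chase
print("pulse-chase degradation:", round(degradation_pct_pulse_chase(100, 80), 1), "%")
# puromycin +/- bortezomib: 30% of nascent chains degraded by the proteasome
print("puro±BTZ degradation:", round(degradation_pct_puro_btz(70, 100), 1), "%")
# heavy uridine: 10% of UMP in assembled ribosomes is newly transcribed
print("heavy UMP:", heavy_ump_pct(10, 90, natural_heavy_fraction=0.0), "%")
# proteasome inhibition doubles relative eIF2alpha phosphorylation
print("eIF2a fold induction:", eif2a_fold_induction(0.6, 0.3))

# a degradation-% timecourse (12 timepoints over 2 days) tested for rhythm
times = np.arange(12) * 4.0
series = simulate_assay_series(
    times, c=25.0, a=6.0, peak_time_h=8.0, noise_sd=1.0, seed=3
)
cosine = fit_damped_cosine(times, series.values, period_h=24.0)
line = fit_line(times, series.values)
f_stat, p = compare_fits_f_test(line, cosine)
preferred = "damped cosine" if p < 0.05 else "straight line"
print(
    f"degradation timecourse: preferred fit = {preferred} "
    f"(F={f_stat:.1f}, p={p:.1e}), peak at {cosine.peak_time_h:.1f} h, "
    f"amplitude {cosine.a:.1f} %"
)
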