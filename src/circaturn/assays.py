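"""Closed-form calculators for bulk labelling readouts.

Each calculator turns a pair of raw signals from one of the bulk assays
into the derived percentage or ratio that is then analysed as a time
series:

* radioactive pulse-chase: percent of nascent protein degraded during
  the chase, ``100 * (1 - chase/pulse)``;
* puromycin +/- bortezomib: percent of nascent polypeptides degraded by
  the proteasome within the labelling window,
  ``100 * (1 - puro/(puro + BTZ))``;
* heavy-uridine (UMP) incorporation: percent of UMP that is heavy,
  corrected for the natural heavy-isotope background measured in
  unlabelled cells;
* eIF2alpha phosphorylation fold induction under proteasome inhibition.

Negative degradation estimates are preserved (with a warning) rather
than clipped — they flag normalization problems in the raw signals.
"""

from __future__ import annotations

import warnings

__all__ = [
    "degradation_pct_pulse_chase",
    "degradation_pct_puro_btz",
    "heavy_ump_pct",
    "eif2a_fold_induction",
]


def _check_nonneg(name: str, value: float) -> float:
    value = float(value)
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return value


def degradation_pct_pulse_chase(pulse_signal: float, chase_signal: float) -> float:
    """Percent of pulse-labelled protein lost during the chase.

    ``100 * (1 - chase/pulse)``; both signals should already be
    normalized to protein content. Requires pulse > 0; a chase larger
    than the pulse yields a negative percentage with a warning.
    """
    pulse = _check_nonneg("pulse_signal", pulse_signal)
    chase = _check_nonneg("chase_signal", chase_signal)
    if pulse == 0:
        raise ValueError("pulse signal is zero; degradation undefined")
    pct = 100.0 * (1.0 - chase / pulse)
    if pct < 0:
        warnings.warn(
            "chase exceeds pulse: negative degradation suggests a normalization problem",
            RuntimeWarning,
            stacklevel=2,
        )
    return pct


def degradation_pct_puro_btz(puro_signal: float, puro_btz_signal: float) -> float:
    """Percent of puromycylated peptides degraded when the proteasome is active.

    ``100 * (1 - Puro/(Puro+BTZ))``: the +BTZ condition measures all
    nascent chains, the -BTZ condition only those surviving degradation.
    """
    puro = _check_nonneg("puro_signal", puro_signal)
    puro_btz = _check_nonneg("puro_btz_signal", puro_btz_signal)
    if puro_btz == 0:
        raise ValueError("puro+BTZ signal is zero; degradation undefined")
    pct = 100.0 * (1.0 - puro / puro_btz)
    if pct < 0:
        warnings.warn(
            "puro exceeds puro+BTZ: negative degradation suggests a normalization problem",
            RuntimeWarning,
            stacklevel=2,
        )
    return pct


def heavy_ump_pct(
    heavy_abundance: float,
    light_abundance: float,
    natural_heavy_fraction: float = 0.0,
    renormalize: bool = False,
) -> float:
    """Corrected percentage of heavy UMP.

    Raw fraction = heavy / (heavy + light); the natural heavy-isotope
    fraction measured in unlabelled cells is subtracted and the result
    floored at 0. With ``renormalize=True`` the corrected fraction is
    (f - f0)/(1 - f0) instead — numerically indistinguishable at the
    ~1e-5 natural abundance of 15N2, provided for completeness.
    """
    heavy = _check_nonneg("heavy_abundance", heavy_abundance)
    light = _check_nonneg("light_abundance", light_abundance)
    f0 = float(natural_heavy_fraction)
    if not 0.0 <= f0 < 1.0:
        raise ValueError("natural_heavy_fraction must lie in [0, 1)")
    total = heavy + light
    if total == 0:
        raise ValueError("heavy and light abundances are both zero; fraction undefined")
    raw = heavy / total
    corrected = (raw - f0) / (1.0 - f0) if renormalize else raw - f0
    return 100.0 * max(0.0, corrected)


def eif2a_fold_induction(treated_ratio: float, control_ratio: float) -> float:
    """Fold increase in relative phosphorylation, treated over control.

    Ratios are phospho/total within each condition; requires a positive
    control ratio.
    """
    treated = _check_nonneg("treated_ratio", treated_ratio)
    control = _check_nonneg("control_ratio", control_ratio)
    if control == 0:
        raise ValueError("control ratio is zero; fold induction undefined")
    return treated / control
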