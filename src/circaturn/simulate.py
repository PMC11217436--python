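"""Ground-truth simulator for pulsed-SILAC/TMT circadian experiments.

The kinetic model couples a rhythmic synthesis rate to a rhythmic
degradation rate:

.. math::

    s(t) = s_0 (1 + A_s \\cos(2\\pi (t - \\varphi_s)/T)), \\qquad
    k(t) = k_0 (1 + A_k \\cos(2\\pi (t - \\varphi_k)/T)),

    dP/dt = s(t) - k(t) P(t).

When :math:`A_s = A_k` with equal phases, :math:`P \\equiv s_0/k_0`
solves the equation identically: synthesis and degradation rhythms
cancel, total abundance stays constant while the labelled (nascent)
signal oscillates — the coupled-turnover mechanism the analysis is
designed to detect.

For a labelling window :math:`[t_0, t_0+\\Delta]` the heavy signal is
the nascent protein surviving to the window end,
:math:`H = \\int_{t_0}^{t_0+\\Delta} s(u)\\, e^{-\\int_u^{t_0+\\Delta} k(v) dv}\\, du`
(equivalently :math:`dH/dt = s - kH` with :math:`H(t_0)=0`), total is
:math:`P(t_0+\\Delta)` and light is their difference. Trajectories are
integrated with a fixed-step RK4 solver after a quasi-steady-state
burn-in.

On top of the kinetics, :func:`emit_evidence` produces a MaxQuant-style
evidence table: several peptides per protein with lognormal response
factors, multiplicative lognormal reporter noise at a stated CV, random
missing cells, a fully heavy booster channel where the design has one,
and contaminant/reverse decoy rows. Every parameter is recorded in the
truth object so recovery can be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StudyDesign, whole_cell_design
from .complexes import ComplexAnnotation, write_complex_annotation
from .errors import SolverError, CircaturnError

__all__ = [
    "ProteinKinetics",
    "SyntheticTruth",
    "synthesis_rate",
    "degradation_rate",
    "simulate_trajectories",
    "generate_truth",
    "assign_complexes",
    "emit_evidence",
    "simulate_assay_series",
    "simulate_turnover_study",
    "TRUTH_LABELS",
]

TRUTH_LABELS = ("coupled_rhythmic", "synthesis_only_rhythmic", "abundance_rhythmic", "flat")

_MAX_DT = 0.05  # h; coarser steps are refused
_AA = "ACDEFGHILMNPQSTVWY"  # tryptic interiors: no K/R until the C-terminus


@dataclass
class ProteinKinetics:
    """Kinetic parameters of one simulated protein.

    ``s0`` basal synthesis rate (intensity/h), ``k0`` basal degradation
    rate (1/h); relative amplitudes in [0, 1) keep both rates positive;
    phases are peak times in hours.
    """

    s0: float
    a_s: float
    phi_s: float
    k0: float
    a_k: float
    phi_k: float
    complex_id: str | None = None
    truth_label: str = "flat"

    def __post_init__(self) -> None:
        if self.s0 <= 0 or self.k0 <= 0:
            raise CircaturnError("basal rates must be positive")
        if not (0 <= self.a_s < 1 and 0 <= self.a_k < 1):
            raise CircaturnError("relative amplitudes must lie in [0, 1)")
        if self.truth_label not in TRUTH_LABELS:
            raise CircaturnError(f"unknown truth label {self.truth_label!r}")


def synthesis_rate(kin: ProteinKinetics, t, period_h: float = 24.0):
    t = np.asarray(t, dtype=float)
    return kin.s0 * (1.0 + kin.a_s * np.cos(2.0 * np.pi * (t - kin.phi_s) / period_h))


def degradation_rate(kin: ProteinKinetics, t, period_h: float = 24.0):
    t = np.asarray(t, dtype=float)
    return kin.k0 * (1.0 + kin.a_k * np.cos(2.0 * np.pi * (t - kin.phi_k) / period_h))


# ---------------------------------------------------------------------------
# ODE core (vectorized over proteins)
# ---------------------------------------------------------------------------


def _rates(kins: list[ProteinKinetics], period_h: float):
    s0 = np.array([k.s0 for k in kins])
    a_s = np.array([k.a_s for k in kins])
    phi_s = np.array([k.phi_s for k in kins])
    k0 = np.array([k.k0 for k in kins])
    a_k = np.array([k.a_k for k in kins])
    phi_k = np.array([k.phi_k for k in kins])
    w = 2.0 * np.pi / period_h

    def s(t):
        return s0 * (1.0 + a_s * np.cos(w * (t - phi_s)))

    def k(t):
        return k0 * (1.0 + a_k * np.cos(w * (t - phi_k)))

    return s, k, k0


def _rk4(y, t0, t1, dt, deriv):
    """Fixed-step RK4 from t0 to t1 (vector state)."""
    n = max(1, int(np.ceil((t1 - t0) / dt)))
    h = (t1 - t0) / n
    t = t0
    for _ in range(n):
        k1 = deriv(t, y)
        k2 = deriv(t + h / 2.0, y + h / 2.0 * k1)
        k3 = deriv(t + h / 2.0, y + h / 2.0 * k2)
        k4 = deriv(t + h, y + h * k3)
        y = y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += h
    return y


def _simulate_many(
    kins: list[ProteinKinetics],
    design: StudyDesign,
    dt: float = _MAX_DT,
    include_nascent_degradation: bool = True,
):
    """Window quantities for many proteins at once.

    Returns (timepoints, heavy, light, total) with arrays shaped
    (n_proteins, n_timepoints). Labelling windows are centred on the
    design's timepoints (midpoint convention).
    """
    if dt > _MAX_DT:
        raise SolverError(f"dt={dt} h is too coarse; use dt <= {_MAX_DT} h")
    s, k, k0 = _rates(kins, design.period_h)
    tps = np.array(design.timepoints_h)
    half = design.label_window_h / 2.0
    starts, ends = tps - half, tps + half

    burn_in = float(min(500.0, 10.0 / k0.min()))
    t_start = starts.min() - burn_in
    # quasi-steady-state initialization; exact for coupled equal-amplitude rhythms
    p = s(t_start) / k(t_start)

    def dP(t, y):
        return s(t) - k(t) * y

    heavy = np.empty((len(kins), len(tps)))
    total = np.empty_like(heavy)
    t_cur = t_start
    for j in range(len(tps)):
        p = _rk4(p, t_cur, starts[j], dt, dP)
        t_cur = starts[j]
        if include_nascent_degradation:
            h_state = np.zeros_like(p)

            def dH(t, y):
                return s(t) - k(t) * y

            h_state = _rk4(h_state, starts[j], ends[j], dt, dH)
        else:
            grid = np.linspace(starts[j], ends[j], max(2, int(np.ceil(design.label_window_h / dt)) + 1))
            vals = np.stack([s(t) for t in grid], axis=1)
            h_state = np.trapezoid(vals, grid, axis=1)
        p = _rk4(p, t_cur, ends[j], dt, dP)
        t_cur = ends[j]
        heavy[:, j] = h_state
        total[:, j] = p
    light = total - heavy
    # solver round-off can leave tiny negatives for fully renewed proteins
    light = np.where(light < 0, np.maximum(light, -1e-9 * total), light)
    light = np.clip(light, 0.0, None)
    return tps, heavy, light, total


def simulate_trajectories(
    kinetics: ProteinKinetics,
    design: StudyDesign,
    dt: float = _MAX_DT,
    include_nascent_degradation: bool = True,
) -> pd.DataFrame:
    """Per-window heavy/light/total amounts for one protein.

    Returns a DataFrame indexed by timepoint (window midpoint, hours)
    with columns ``heavy``, ``light``, ``total``.
    """
    tps, heavy, light, total = _simulate_many(
        [kinetics], design, dt=dt, include_nascent_degradation=include_nascent_degradation
    )
    return pd.DataFrame(
        {"heavy": heavy[0], "light": light[0], "total": total[0]},
        index=pd.Index(tps, name="timepoint_h"),
    )


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a dataset: design, kinetics, noise, seed."""

    design: StudyDesign
    accessions: list
    kinetics: list
    n_peptides: list
    response_factors: list  # list of arrays, one per protein
    noise_cv: float
    missing_rate: float
    n_contaminants: int
    n_reverse: int
    seed: int
    complex_annotations: list = field(default_factory=list)

    def kinetics_by_accession(self) -> dict:
        return dict(zip(self.accessions, self.kinetics))

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "noise_cv": self.noise_cv,
            "missing_rate": self.missing_rate,
            "n_contaminants": self.n_contaminants,
            "n_reverse": self.n_reverse,
            "design": self.design.to_dict(),
            "proteins": [
                {
                    "accession": acc,
                    **asdict(kin),
                    "n_peptides": int(npep),
                    "response_factors": [float(x) for x in rfs],
                }
                for acc, kin, npep, rfs in zip(
                    self.accessions, self.kinetics, self.n_peptides, self.response_factors
                )
            ],
            "complexes": [
                {
                    "complex_id": a.complex_id,
                    "complex_name": a.complex_name,
                    "members": sorted(a.member_accessions),
                }
                for a in self.complex_annotations
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        kin_fields = {"s0", "a_s", "phi_s", "k0", "a_k", "phi_k", "complex_id", "truth_label"}
        prots = d["proteins"]
        return cls(
            design=StudyDesign.from_dict(d["design"]),
            accessions=[p["accession"] for p in prots],
            kinetics=[ProteinKinetics(**{k: v for k, v in p.items() if k in kin_fields}) for p in prots],
            n_peptides=[p["n_peptides"] for p in prots],
            response_factors=[np.array(p["response_factors"]) for p in prots],
            noise_cv=d["noise_cv"],
            missing_rate=d["missing_rate"],
            n_contaminants=d["n_contaminants"],
            n_reverse=d["n_reverse"],
            seed=d["seed"],
            complex_annotations=[
                ComplexAnnotation(c["complex_id"], c["complex_name"], frozenset(c["members"]))
                for c in d.get("complexes", [])
            ],
        )


def _phase_choices(design: StudyDesign) -> np.ndarray:
    return np.unique([design.circadian_time(t) for t in design.timepoints_h])


def generate_truth(
    n_proteins: int,
    design: StudyDesign | None = None,
    seed: int = 0,
    label_fractions: dict | None = None,
    amplitude: float = 1.0 / 3.0,
    noise_cv: float = 0.10,
    missing_rate: float = 0.02,
    n_contaminants: int = 10,
    n_reverse: int = 10,
    k0_median: float = 0.02,
    k0_sigma: float = 0.5,
    phases_on_grid: bool = True,
) -> SyntheticTruth:
    """Draw a population of protein kinetics forming the study conditions.

    Defaults embody the whole-cell design: synthesis relative amplitude
    1/3 (peak/trough fold change 2), 10% multiplicative peptide noise,
    2% missing cells, basal degradation lognormal around 0.02/h (about a
    35-h half-life, in line with the multi-day average half-life of
    mammalian proteins). Proteins of the ``abundance_rhythmic`` class
    get faster turnover (their abundance rhythm is degradation-driven,
    which requires a short half-life). Peak phases are drawn from the
    sampled circadian phase grid unless ``phases_on_grid=False``.
    """
    design = design or whole_cell_design()
    fractions = label_fractions or {
        "coupled_rhythmic": 0.25,
        "synthesis_only_rhythmic": 0.10,
        "abundance_rhythmic": 0.05,
        "flat": 0.60,
    }
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise CircaturnError("label fractions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = []
    for lbl, frac in fractions.items():
        labels += [lbl] * int(round(frac * n_proteins))
    while len(labels) < n_proteins:
        labels.append("flat")
    labels = labels[:n_proteins]
    rng.shuffle(labels)

    grid = _phase_choices(design)
    kinetics, accessions, n_peptides, rfs = [], [], [], []
    for i, lbl in enumerate(labels):
        s0 = float(rng.lognormal(np.log(50.0), 0.8))
        if lbl == "abundance_rhythmic":
            k0 = float(rng.lognormal(np.log(0.2), 0.3))
        else:
            k0 = float(rng.lognormal(np.log(k0_median), k0_sigma))
        phi = float(rng.choice(grid)) if phases_on_grid else float(rng.uniform(0, design.period_h))
        a_s = amplitude if lbl in ("coupled_rhythmic", "synthesis_only_rhythmic") else 0.0
        a_k = amplitude if lbl in ("coupled_rhythmic", "abundance_rhythmic") else 0.0
        kinetics.append(
            ProteinKinetics(
                s0=s0, a_s=a_s, phi_s=phi, k0=k0, a_k=a_k, phi_k=phi, truth_label=lbl
            )
        )
        accessions.append(f"SYN{i:05d}")
        npep = int(rng.integers(3, 9))
        n_peptides.append(npep)
        rfs.append(rng.lognormal(0.0, 0.5, size=npep))
    return SyntheticTruth(
        design=design,
        accessions=accessions,
        kinetics=kinetics,
        n_peptides=n_peptides,
        response_factors=rfs,
        noise_cv=noise_cv,
        missing_rate=missing_rate,
        n_contaminants=n_contaminants,
        n_reverse=n_reverse,
        seed=seed,
    )


def assign_complexes(
    truth: SyntheticTruth,
    n_complexes: int,
    size_range: tuple[int, int] = (5, 10),
    coordination: str = "coordinated",
    jitter: float = 0.05,
    seed: int | None = None,
) -> SyntheticTruth:
    """Assign disjoint complex memberships, optionally coordinating turnover.

    In ``coordinated`` mode one basal degradation rate is drawn per
    complex and members get that rate jittered by at most ``jitter``
    (relative); in ``uncoordinated`` mode members keep their
    independently drawn rates. Membership is recorded both on the
    kinetics and as a ComplexAnnotation list on the truth.
    """
    if coordination not in ("coordinated", "uncoordinated"):
        raise CircaturnError(f"unknown coordination mode {coordination!r}")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    lo, hi = size_range
    sizes = rng.integers(lo, hi + 1, size=n_complexes)
    if sizes.sum() > len(truth.accessions):
        raise CircaturnError("not enough proteins for the requested complex structure")
    order = rng.permutation(len(truth.accessions))
    annotations = []
    pos = 0
    for ci, size in enumerate(sizes):
        members = [truth.accessions[j] for j in order[pos : pos + size]]
        pos += size
        cid = f"CPX{ci:03d}"
        shared_k0 = float(rng.lognormal(np.log(0.02), 0.5))
        for acc in members:
            idx = truth.accessions.index(acc)
            kin = truth.kinetics[idx]
            kin.complex_id = cid
            if coordination == "coordinated":
                kin.k0 = shared_k0 * (1.0 + rng.uniform(-jitter, jitter))
        annotations.append(ComplexAnnotation(cid, f"synthetic complex {ci}", frozenset(members)))
    truth.complex_annotations = annotations
    return truth


# ---------------------------------------------------------------------------
# Evidence emission
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 15))
    body = "".join(rng.choice(list(_AA), size=length))
    return body + str(rng.choice(["K", "R"]))


def _lognormal_noise(rng, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise at the stated CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


_HEAVY_MODS = ["Arg10", "Lys8", "2 Arg10", "Oxidation (M);Lys8"]
_LIGHT_MODS = ["Unmodified", "Unmodified", "Unmodified", "Oxidation (M)"]


def emit_evidence(
    truth: SyntheticTruth,
    out_dir=None,
    dt: float = _MAX_DT,
    split_fraction: float = 0.25,
    include_nascent_degradation: bool = True,
) -> pd.DataFrame:
    """Produce the MaxQuant-style evidence table for a truth object.

    Each protein's peptides appear as one heavy and one light collapsed
    entry whose reporter intensities are ``response_factor x amount x
    lognormal noise``; a ``split_fraction`` of peptide entries is split
    into two evidence rows (with channel-wise conserved sums) to
    exercise collapsing. Booster channels carry fully heavy signal.
    Determinism: the same truth (seed included) gives a byte-identical
    table.

    When ``out_dir`` is given, writes ``evidence.txt``, ``design.yaml``,
    ``truth.json`` and (if complexes were assigned) ``complexes.tsv``.
    Returns the evidence DataFrame.
    """
    design = truth.design
    rng = np.random.default_rng(truth.seed)
    tps, heavy, light, _total = _simulate_many(
        truth.kinetics, design, dt=dt, include_nascent_degradation=include_nascent_degradation
    )
    tp_index = {tp: j for j, tp in enumerate(tps)}
    n_ch = design.n_channels
    mean_total = (heavy + light).mean(axis=1)

    rows = []
    used_sequences: set[str] = set()

    def fresh_sequence() -> str:
        while True:
            seq = _random_sequence(rng)
            if seq not in used_sequences:
                used_sequences.add(seq)
                return seq

    for p_idx, (acc, kin) in enumerate(zip(truth.accessions, truth.kinetics)):
        for pep in range(truth.n_peptides[p_idx]):
            rf = truth.response_factors[p_idx][pep]
            seq = fresh_sequence()
            for state, amounts, booster_amount in (
                ("heavy", heavy[p_idx], mean_total[p_idx]),
                ("light", light[p_idx], 0.0),
            ):
                noise = _lognormal_noise(rng, truth.noise_cv, n_ch)
                vals = np.empty(n_ch)
                for ci, ch in enumerate(design.channels):
                    base = booster_amount if ch.is_booster else amounts[tp_index[float(ch.timepoint_h)]]
                    vals[ci] = rf * base * noise[ci]
                if truth.missing_rate > 0:
                    vals[rng.random(n_ch) < truth.missing_rate] = np.nan
                mods = rng.choice(_HEAVY_MODS) if state == "heavy" else rng.choice(_LIGHT_MODS)
                if rng.random() < split_fraction:
                    u = rng.uniform(0.2, 0.8)
                    parts = [vals * u, vals * (1.0 - u)]
                else:
                    parts = [vals]
                for part in parts:
                    rows.append((seq, mods, acc, "", "", part))

    for d in range(truth.n_reverse):
        rows.append(
            (fresh_sequence(), "Unmodified", f"REV__Q{d:04d}", "+", "",
             rng.lognormal(3.0, 1.0, size=n_ch))
        )
    for d in range(truth.n_contaminants):
        rows.append(
            (fresh_sequence(), "Unmodified", f"CON__P{d:04d}", "", "+",
             rng.lognormal(3.0, 1.0, size=n_ch))
        )

    frame = pd.DataFrame(
        {
            "Sequence": [r[0] for r in rows],
            "Modifications": [r[1] for r in rows],
            "Leading razor protein": [r[2] for r in rows],
            "Reverse": [r[3] for r in rows],
            "Potential contaminant": [r[4] for r in rows],
        }
    )
    for ci in range(n_ch):
        frame[f"Reporter intensity corrected {ci + 1}"] = [r[5][ci] for r in rows]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "evidence.txt", sep="\t", index=False, float_format="%.17g")
        design.to_yaml(out_dir / "design.yaml")
        truth.to_json(out_dir / "truth.json")
        if truth.complex_annotations:
            write_complex_annotation(truth.complex_annotations, out_dir / "complexes.tsv")
    return frame


# ---------------------------------------------------------------------------
# Small-series simulators
# ---------------------------------------------------------------------------


def simulate_assay_series(
    times_h,
    m: float = 0.0,
    c: float = 10.0,
    a: float = 0.0,
    k: float = 0.0,
    peak_time_h: float = 0.0,
    period_h: float = 24.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    convention: str = "printed",
):
    """Draw a series from the damped-cosine model plus Gaussian noise.

    ``peak_time_h`` is converted to the phase parameter of the requested
    convention. Returns a :class:`circaturn.rhythm.TimeSeries`.
    """
    from .rhythm import TimeSeries

    x = np.asarray(times_h, dtype=float)
    if convention == "printed":
        angle = (2.0 * np.pi * x - 2.0 * np.pi * peak_time_h) / period_h
    else:
        angle = 2.0 * np.pi * (x - peak_time_h) / period_h
    y = m * x + c + a * np.exp(k * x) * np.cos(angle)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=x.size)
    return TimeSeries(times_h=x, values=y, period_h=period_h)


def simulate_turnover_study(
    n_proteins: int = 300,
    n_complexes: int = 20,
    size_range: tuple[int, int] = (5, 10),
    coordination: str = "coordinated",
    jitter: float = 0.05,
    measurement_cv: float = 0.05,
    design: StudyDesign | None = None,
    seed: int = 0,
):
    """Per-protein relative turnover with complex structure, without MS noise.

    For flat kinetics the window-relative turnover has the closed form
    ``1 - exp(-k0 * label_window)``, so coordination studies need no ODE
    integration; a small multiplicative measurement error (CV) mimics
    pipeline-level variability. Returns (turnover Series, annotations).
    """
    design = design or whole_cell_design()
    truth = generate_truth(
        n_proteins,
        design=design,
        seed=seed,
        label_fractions={"flat": 1.0},
        noise_cv=0.0,
        missing_rate=0.0,
    )
    assign_complexes(
        truth, n_complexes, size_range=size_range, coordination=coordination, jitter=jitter
    )
    rng = np.random.default_rng(seed + 1_000_003)
    k0 = np.array([kin.k0 for kin in truth.kinetics])
    turnover = (1.0 - np.exp(-k0 * design.label_window_h)) * _lognormal_noise(
        rng, measurement_cv, len(k0)
    )
    return pd.Series(turnover, index=truth.accessions, name="relative_turnover"), truth.complex_annotations
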