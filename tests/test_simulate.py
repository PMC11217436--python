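"""Kinetic simulator: analytic identities, noise model, determinism."""

import numpy as np
import pandas as pd
import pytest

from circaturn.design import whole_cell_design, mmc_design
from circaturn.errors import SolverError, CircaturnError
from circaturn.evidence import read_evidence, filter_artifacts, collapse_peptides
from circaturn.quantify import channel_incorporation
from circaturn.rhythm import fit_damped_cosine
from circaturn.simulate import (
    ProteinKinetics,
    simulate_trajectories,
    generate_truth,
    assign_complexes,
    emit_evidence,
    simulate_assay_series,
    SyntheticTruth,
)


def test_flat_kinetics_sit_at_steady_state():
    kin = ProteinKinetics(s0=1.0, a_s=0, phi_s=0, k0=0.02, a_k=0, phi_k=0)
    traj = simulate_trajectories(kin, whole_cell_design())
    assert np.allclose(traj["total"], 50.0, rtol=1e-9)
    # heavy has the closed form (s0/k0)(1 - e^{-k0 D}) at steady state
    expected = 50.0 * (1 - np.exp(-0.02 * 6.0))
    assert np.allclose(traj["heavy"], expected, rtol=1e-6)


def test_coupled_rhythms_cancel_in_total_abundance():
    """Equal-amplitude in-phase synthesis and degradation: P = s0/k0 identically."""
    kin = ProteinKinetics(
        s0=2.0, a_s=1 / 3, phi_s=6.0, k0=0.01, a_k=1 / 3, phi_k=6.0,
        truth_label="coupled_rhythmic",
    )
    traj = simulate_trajectories(kin, whole_cell_design())
    total = traj["total"].to_numpy()
    assert (total.max() - total.min()) / total.mean() < 1e-4
    heavy = traj["heavy"].to_numpy()
    assert heavy.max() / heavy.min() > 1.5  # nascent signal still oscillates


def test_synthesis_rhythm_matches_linear_ode_closed_form():
    """A_k = 0: forced linear ODE has a sinusoidal closed-form steady state."""
    s0, k0, amp, phi = 2.0, 0.05, 0.5, 6.0
    w = 2 * np.pi / 24.0
    kin = ProteinKinetics(
        s0=s0, a_s=amp, phi_s=phi, k0=k0, a_k=0.0, phi_k=0.0,
        truth_label="synthesis_only_rhythmic",
    )
    design = whole_cell_design()
    traj = simulate_trajectories(kin, design)
    t_end = traj.index.to_numpy() + design.label_window_h / 2.0  # window ends
    expected = s0 / k0 + s0 * amp / np.hypot(k0, w) * np.cos(w * (t_end - phi) - np.arctan2(w, k0))
    assert np.allclose(traj["total"].to_numpy(), expected, rtol=1e-4)


def test_mass_balance_and_solver_guard():
    kin = ProteinKinetics(s0=1.0, a_s=0.3, phi_s=3.0, k0=0.1, a_k=0.2, phi_k=9.0)
    traj = simulate_trajectories(kin, whole_cell_design())
    rel = np.abs(traj["heavy"] + traj["light"] - traj["total"]) / traj["total"]
    assert rel.max() < 1e-6
    with pytest.raises(SolverError):
        simulate_trajectories(kin, whole_cell_design(), dt=0.5)


def test_solver_step_halving_agreement():
    kin = ProteinKinetics(s0=1.0, a_s=0.4, phi_s=0.0, k0=0.05, a_k=0.4, phi_k=12.0)
    a = simulate_trajectories(kin, whole_cell_design(), dt=0.05)
    b = simulate_trajectories(kin, whole_cell_design(), dt=0.025)
    assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-6)


def test_longer_label_window_increases_incorporation(tmp_path):
    """6-h pulses incorporate more heavy label than 1.5-h pulses, same kinetics."""
    fracs = {}
    for window, factory in ((1.5, mmc_design), (6.0, whole_cell_design)):
        design = factory(label_window_h=window)
        truth = generate_truth(
            20, design=design, seed=3, noise_cv=0.0, missing_rate=0.0,
            n_contaminants=0, n_reverse=0,
        )
        out = tmp_path / f"w{window}"
        emit_evidence(truth, out_dir=out)
        table = filter_artifacts(read_evidence(out / "evidence.txt", design))
        pep = collapse_peptides(table)
        inc = channel_incorporation(pep)
        fracs[window] = inc.loc[~inc["is_booster"], "heavy_fraction"].to_numpy()
    assert (fracs[6.0] > fracs[1.5]).all()


def test_emit_evidence_deterministic(tmp_path):
    truth = generate_truth(15, seed=9, noise_cv=0.1, missing_rate=0.05)
    a = emit_evidence(truth, out_dir=tmp_path / "a")
    b = emit_evidence(truth, out_dir=tmp_path / "b")
    pd.testing.assert_frame_equal(a, b)
    assert (tmp_path / "a" / "evidence.txt").read_bytes() == (
        tmp_path / "b" / "evidence.txt"
    ).read_bytes()


def test_missingness_exclusions_match_binomial_expectation(tmp_path):
    """At missing rate 0.3, collapsed-peptide exclusions follow the binomial."""
    rate, n_ch = 0.3, 16
    truth = generate_truth(
        150, seed=21, noise_cv=0.0, missing_rate=rate, n_contaminants=0, n_reverse=0
    )
    emit_evidence(truth, out_dir=tmp_path, split_fraction=0.0)
    design = truth.design
    table = read_evidence(tmp_path / "evidence.txt", design)
    pep = collapse_peptides(table)
    n_groups = pep.provenance["collapsed_groups"]
    excluded = pep.provenance["missing_value_excluded"]
    p_excl = 1 - (1 - rate) ** n_ch  # a peptide survives only with all 16 cells present
    expect = n_groups * p_excl
    sigma = np.sqrt(n_groups * p_excl * (1 - p_excl))
    assert abs(excluded - expect) < 3 * sigma


def test_truth_json_round_trip(tmp_path):
    truth = generate_truth(10, seed=4)
    assign_complexes(truth, 2, size_range=(3, 4), coordination="coordinated")
    truth.to_json(tmp_path / "truth.json")
    back = SyntheticTruth.from_json(tmp_path / "truth.json")
    assert back.accessions == truth.accessions
    assert back.seed == truth.seed
    assert [k.k0 for k in back.kinetics] == pytest.approx([k.k0 for k in truth.kinetics])
    assert [sorted(a.member_accessions) for a in back.complex_annotations] == [
        sorted(a.member_accessions) for a in truth.complex_annotations
    ]


def test_assign_complexes_structure_and_coordination():
    truth = generate_truth(200, seed=6)
    assign_complexes(truth, 20, size_range=(5, 10), coordination="coordinated", jitter=0.0)
    sizes = sorted(len(a.member_accessions) for a in truth.complex_annotations)
    assert len(sizes) == 20 and all(5 <= s <= 10 for s in sizes)
    by_acc = truth.kinetics_by_accession()
    for a in truth.complex_annotations:
        k0s = [by_acc[m].k0 for m in a.member_accessions]
        assert np.std(k0s) == pytest.approx(0.0, abs=1e-12)  # jitter 0 -> identical rates
    # uncoordinated leaves the independently drawn rates in place
    truth2 = generate_truth(200, seed=6)
    k_before = [k.k0 for k in truth2.kinetics]
    assign_complexes(truth2, 20, coordination="uncoordinated")
    assert [k.k0 for k in truth2.kinetics] == k_before


def test_assay_series_model_and_recovery():
    times = np.arange(16) * 3.0
    line = simulate_assay_series(times, m=0.5, c=2.0, a=0.0, noise_sd=0.0)
    assert np.allclose(line.values, 0.5 * times + 2.0)
    osc = simulate_assay_series(
        times, m=0.0, c=10.0, a=2.5, k=-0.01, peak_time_h=9.0, noise_sd=0.0
    )
    fit = fit_damped_cosine(times, osc.values, 24.0)
    assert fit.a == pytest.approx(2.5, abs=1e-5)
    assert fit.k == pytest.approx(-0.01, abs=1e-5)


def test_kinetics_validation():
    with pytest.raises(CircaturnError):
        ProteinKinetics(s0=-1.0, a_s=0, phi_s=0, k0=0.1, a_k=0, phi_k=0)
    with pytest.raises(CircaturnError):
        ProteinKinetics(s0=1.0, a_s=1.2, phi_s=0, k0=0.1, a_k=0, phi_k=0)
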