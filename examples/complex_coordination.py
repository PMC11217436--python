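"""Test whether complex subunits share coordinated turnover.

Subunits of a stable macromolecular complex are made and removed
stoichiometrically, so their relative turnover values cluster. The test
compares the within-complex standard deviation of turnover (complexes
with more than four detected subunits) against pseudo-complexes of
identical sizes drawn at random from all detected proteins.
"""

from circaturn.complexes import (
    map_complexes,
    within_complex_sd,
    resample_null,
    coordination_test,
)
from circaturn.simulate import simulate_turnover_study

for mode in ("coordinated", "uncoordinated"):
    turnover, annotations = simulate_turnover_study(
        n_proteins=300, n_complexes=20, coordination=mode, seed=5
    )
    detected = map_complexes(turnover, annotations)
    observed_sds, structure = within_complex_sd(detected, min_subunits=5)
    null = resample_null(structure, turnover, n_iterations=999, seed=6)
    res = coordination_test(observed_sds, null)
    print(
        f"{mode:14s} complexes tested={len(observed_sds)} "
        f"median observed SD={observed_sds.mean():.4f} "
        f"median null SD={null.mean():.4f} "
        f"MW p={res.p_mannwhitney:.2e} empirical p={res.empirical_p:.4f}"
    )
# expected: coordinated complexes have much smaller within-complex SDs
# than the size-matched random null (both p-values small); uncoordinated
# complexes are indistinguishable from the null (p well above 0.05)
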