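"""Protein-complex turnover coordination.

Subunits of a stable complex tend to share turnover rates, since
stoichiometric assembly couples their synthesis and removal. The test
here quantifies that: for every annotated complex with more than four
detected subunits, compute the standard deviation of the members'
relative turnover; compare the collection of observed SDs against a
null built by drawing pseudo-complexes of identical sizes from the pool
of all detected proteins. Coordinated complexes have systematically
*smaller* SDs than the null.

Complex membership is an input table (complex id, name, member
accession), pre-mapped to the quantified accession namespace; ortholog
conversion is done upstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, CircaturnError

__all__ = [
    "ComplexAnnotation",
    "DetectedComplex",
    "CoordinationResult",
    "read_complex_annotation",
    "write_complex_annotation",
    "map_complexes",
    "within_complex_sd",
    "resample_null",
    "coordination_test",
    "complex_profiles",
]


@dataclass
class ComplexAnnotation:
    complex_id: str
    complex_name: str
    member_accessions: frozenset

    def __post_init__(self) -> None:
        self.member_accessions = frozenset(self.member_accessions)
        if not self.member_accessions:
            raise FormatError(f"complex {self.complex_id} has no members")


@dataclass
class DetectedComplex:
    """An annotated complex restricted to its quantified members."""

    complex_id: str
    complex_name: str
    n_annotated: int
    detected_members: list
    mean_turnover: float
    sd_turnover: float
    mean_fold_change: float

    @property
    def n_detected(self) -> int:
        return len(self.detected_members)

    @property
    def coverage(self) -> float:
        return self.n_detected / self.n_annotated


def read_complex_annotation(path) -> list[ComplexAnnotation]:
    """Read a TSV with columns complex_id, complex_name, member_accession."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"complex_id", "complex_name", "member_accession"}
    if not required.issubset(frame.columns):
        raise FormatError(f"complex annotation needs columns {sorted(required)}")
    out = []
    for cid, grp in frame.groupby("complex_id", sort=True):
        out.append(
            ComplexAnnotation(
                complex_id=str(cid),
                complex_name=str(grp["complex_name"].iloc[0]),
                member_accessions=frozenset(grp["member_accession"]),
            )
        )
    return out


def write_complex_annotation(annotations: list[ComplexAnnotation], path) -> None:
    rows = [
        {"complex_id": a.complex_id, "complex_name": a.complex_name, "member_accession": m}
        for a in annotations
        for m in sorted(a.member_accessions)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def map_complexes(
    turnover: pd.Series,
    annotations: list[ComplexAnnotation],
    min_coverage: float = 0.0,
    fold_change: pd.Series | None = None,
) -> list[DetectedComplex]:
    """Intersect complex annotations with the quantified proteins.

    ``turnover`` is the per-protein relative turnover indexed by
    accession (from :func:`circaturn.quantify.relative_turnover`). A
    complex is *present* when at least one member is detected; passing
    ``min_coverage=0.5`` keeps only complexes with half or more of
    their annotated subunits detected. A protein listed in several
    complexes contributes to each.
    """
    if not annotations:
        warnings.warn("empty complex annotation", RuntimeWarning, stacklevel=2)
        return []
    detected_set = set(turnover.dropna().index)
    out = []
    for ann in annotations:
        members = sorted(ann.member_accessions & detected_set)
        if not members:
            continue
        cov = len(members) / len(ann.member_accessions)
        if cov < min_coverage:
            continue
        vals = turnover.loc[members].to_numpy(dtype=float)
        fc = float("nan")
        if fold_change is not None:
            fc_vals = fold_change.reindex(members).dropna()
            if len(fc_vals):
                fc = float(fc_vals.mean())
        out.append(
            DetectedComplex(
                complex_id=ann.complex_id,
                complex_name=ann.complex_name,
                n_annotated=len(ann.member_accessions),
                detected_members=members,
                mean_turnover=float(vals.mean()),
                sd_turnover=float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                mean_fold_change=fc,
            )
        )
    return out


def within_complex_sd(
    complexes: list[DetectedComplex], min_subunits: int = 5
) -> tuple[np.ndarray, list[int]]:
    """Observed turnover SDs for complexes with > 4 detected subunits.

    Returns (sd array, matching subunit counts). ``min_subunits`` counts
    *detected* subunits (the members entering the SD), the default 5
    implementing the "more than four subunits" rule.
    """
    sds, sizes = [], []
    for c in complexes:
        if c.n_detected >= min_subunits:
            sds.append(c.sd_turnover)
            sizes.append(c.n_detected)
    return np.asarray(sds, dtype=float), sizes


def resample_null(
    structure: list[int],
    turnover_pool,
    n_iterations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Size-structure-preserving random null for within-complex SDs.

    Per iteration, for every complex size in ``structure``, draw that
    many proteins from the pool of all detected turnovers (without
    replacement within a pseudo-complex, with replacement across
    pseudo-complexes and iterations) and record the SD. Returns an
    (n_iterations, n_complexes) array; reproducible given the seed.
    """
    pool = np.asarray(list(turnover_pool), dtype=float)
    pool = pool[np.isfinite(pool)]
    if max(structure, default=0) > pool.size:
        raise CircaturnError("turnover pool smaller than the largest complex")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty((n_iterations, len(structure)))
    for it in range(n_iterations):
        for j, size in enumerate(structure):
            draw = rng.choice(pool, size=size, replace=False)
            out[it, j] = draw.std(ddof=1)
    return out


@dataclass
class CoordinationResult:
    observed_sds: np.ndarray
    null_sds: np.ndarray
    p_mannwhitney: float
    empirical_p: float
    n_iterations: int
    seed: int | None = None


def coordination_test(
    observed_sds: np.ndarray, null_sds: np.ndarray, seed: int | None = None
) -> CoordinationResult:
    """Are observed within-complex SDs smaller than the resampled null?

    Reports a one-sided Mann–Whitney p (observed stochastically smaller
    than the pooled null SDs) and an empirical p based on the median:
    (1 + #{iteration medians <= observed median}) / (1 + iterations).
    """
    observed = np.asarray(observed_sds, dtype=float)
    null = np.asarray(null_sds, dtype=float)
    if observed.size == 0 or null.size == 0:
        raise CircaturnError("coordination test needs non-empty observed and null SDs")
    if null.ndim == 1:
        null = null[None, :]
    res = stats.mannwhitneyu(observed, null.ravel(), alternative="less")
    obs_median = float(np.median(observed))
    null_medians = np.median(null, axis=1)
    emp = (1.0 + int(np.sum(null_medians <= obs_median))) / (1.0 + null.shape[0])
    return CoordinationResult(
        observed_sds=observed,
        null_sds=null,
        p_mannwhitney=float(res.pvalue),
        empirical_p=float(emp),
        n_iterations=null.shape[0],
        seed=seed,
    )


def complex_profiles(
    complexes: list[DetectedComplex], quant, per_timepoint: bool = True
) -> dict[str, pd.DataFrame]:
    """Per-complex normalized synthesis profiles for heatmap display.

    Each detected member's synthesis series (replicates averaged per
    timepoint) is scaled to its own mean = 1, so members of different
    absolute abundance become comparable; two appended rows give the
    complex mean and SEM per timepoint.
    """
    from .quantify import _per_timepoint_means  # local import to avoid a cycle

    synth_tp = _per_timepoint_means(quant, quant.synthesis_matrix())
    out = {}
    for c in complexes:
        members = [m for m in c.detected_members if m in synth_tp.index]
        block = synth_tp.loc[members].astype(float)
        means = block.mean(axis=1)
        norm = block.div(means.where(means > 0), axis=0)
        summary_mean = norm.mean(axis=0)
        sem = norm.std(axis=0, ddof=1) / math.sqrt(len(norm)) if len(norm) > 1 else norm.iloc[0] * 0.0
        prof = norm.copy()
        prof.loc["__complex_mean__"] = summary_mean
        prof.loc["__complex_sem__"] = sem
        out[c.complex_id] = prof
    return out
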