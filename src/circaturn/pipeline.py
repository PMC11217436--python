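"""End-to-end orchestration: evidence -> quantification -> rhythms -> complexes.

The stages compose pure library functions; this module adds
configuration, provenance (row counts at every filter), deterministic
output files and a summary JSON. The same config and inputs always
produce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .design import StudyDesign
from .errors import ConfigError, TransformError, InsufficientDesignError
from .evidence import read_evidence, filter_artifacts, collapse_peptides, write_peptides
from .quantify import (
    ProteinQuantTable,
    channel_incorporation,
    normalize_sample_loading,
    pair_filter,
    roll_up_proteins,
    relative_turnover,
    write_proteins,
)
from .rhythm import TimeSeries, umbrella_test, anova_rhythm_test, peak_trough_fold_change
from .classify import (
    classify_rhythmicity,
    category_percentages,
    overlap_fisher,
    compare_fold_change_distributions,
)
from .complexes import (
    read_complex_annotation,
    map_complexes,
    within_complex_sd,
    resample_null,
    coordination_test,
)

logger = logging.getLogger("circaturn")

__all__ = [
    "PipelineConfig",
    "quantify_evidence",
    "rhythm_analysis",
    "classification_summary",
    "complex_coordination_analysis",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Paths and stage toggles for a full run; serialized alongside outputs."""

    evidence_path: str
    design_path: str
    output_dir: str
    annotation_path: str | None = None
    normalize: bool = True
    apply_pair_filter: bool = True
    alpha: float = 0.05
    umbrella_mode: str = "pooled"
    n_iterations: int = 1000
    min_subunits: int = 5
    min_coverage: float = 0.0
    run_complexes: bool = False
    seed: int = 0
    version: str = __version__

    def validate(self) -> None:
        if not Path(self.evidence_path).exists():
            raise ConfigError(f"evidence file not found: {self.evidence_path}")
        if not Path(self.design_path).exists():
            raise ConfigError(f"design file not found: {self.design_path}")
        if self.run_complexes:
            if not self.annotation_path:
                raise ConfigError("complexes stage enabled but no annotation_path given")
            if not Path(self.annotation_path).exists():
                raise ConfigError(f"annotation file not found: {self.annotation_path}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.umbrella_mode not in ("pooled", "longitudinal"):
            raise ConfigError(f"unknown umbrella mode {self.umbrella_mode!r}")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"malformed pipeline config: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def quantify_evidence(
    evidence_path,
    design: StudyDesign,
    normalize: bool = True,
    apply_pair_filter: bool = True,
):
    """Evidence file to protein quantification.

    Runs the standard route: read, remove decoys, collapse by
    (sequence, labelling state), heavy-incorporation QC (before
    normalization), optional sample-loading normalization, optional
    both-forms pair filter, protein roll-up. Returns a dict with the
    intermediate tables and provenance.
    """
    table = read_evidence(evidence_path, design)
    table = filter_artifacts(table)
    peptides = collapse_peptides(table)
    incorporation = channel_incorporation(peptides)
    norm_report = None
    if normalize:
        peptides, norm_report = normalize_sample_loading(peptides)
    if apply_pair_filter:
        peptides = pair_filter(peptides)
    quant = roll_up_proteins(peptides)
    return {
        "quant": quant,
        "peptides": peptides,
        "incorporation": incorporation,
        "normalization": norm_report,
        "provenance": dict(peptides.provenance),
    }


def _bh(p: pd.Series) -> pd.Series:
    q = pd.Series(np.nan, index=p.index)
    mask = p.notna()
    if mask.any():
        q.loc[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def rhythm_analysis(quant: ProteinQuantTable, umbrella_mode: str = "pooled") -> pd.DataFrame:
    """Rhythm statistics for every protein's synthesis and abundance series.

    Returns one row per (accession, metric) with the umbrella and ANOVA
    p-values, phase (circadian hours, reference peak = 0), peak/trough
    fold change, and BH q-values computed per metric within each test.
    """
    times = quant.channel_times()
    timepoints = quant.channel_timepoints()
    reps = np.array([c.replicate for c in quant.design.non_booster_channels])
    period = quant.design.period_h
    rows = []
    for metric, matrix in (
        ("synthesis", quant.synthesis_matrix()),
        ("abundance", quant.total_matrix()),
    ):
        values = matrix.to_numpy(dtype=float)
        for acc, vals in zip(matrix.index, values):
            # fold change / day-splitting uses absolute time; tests use circadian folding
            circ = TimeSeries(times_h=times, values=vals, period_h=period, replicate_ids=reps)
            absolute = TimeSeries(times_h=timepoints, values=vals, period_h=period)
            try:
                umb = umbrella_test(circ, mode=umbrella_mode)
                p_u, phase = umb.p_value, umb.phase_h
            except InsufficientDesignError:
                p_u, phase = np.nan, np.nan
            try:
                p_a = anova_rhythm_test(circ).p_value
            except (TransformError, InsufficientDesignError):
                p_a = np.nan
            fc = peak_trough_fold_change(absolute)
            rows.append(
                {
                    "accession": acc,
                    "metric": metric,
                    "p_umbrella": p_u,
                    "p_anova": p_a,
                    "phase_h": phase,
                    "fold_change": fc,
                }
            )
    out = pd.DataFrame(rows)
    for col in ("p_umbrella", "p_anova"):
        out[f"q_{col[2:]}"] = (
            out.groupby("metric", group_keys=False)[col].apply(_bh).reindex(out.index)
        )
    return out


def classification_summary(rhythms: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Four-category classification per detector plus overlap/amplitude stats.

    Returns a dict with a per-protein frame (``table``) and a JSON-ready
    ``summary`` (category percentages per detector, Fisher overlap p,
    Mann–Whitney fold-change p).
    """
    wide_p = rhythms.pivot(index="accession", columns="metric", values="p_umbrella")
    wide_pa = rhythms.pivot(index="accession", columns="metric", values="p_anova")
    wide_fc = rhythms.pivot(index="accession", columns="metric", values="fold_change")
    wide_phase = rhythms.pivot(index="accession", columns="metric", values="phase_h")

    table = pd.DataFrame(index=wide_p.index)
    summary: dict = {"alpha": alpha, "n_excluded": 0}
    for test_name, wide in (("umbrella", wide_p), ("anova", wide_pa)):
        cats = []
        for acc in wide.index:
            ps, pa = wide.loc[acc, "synthesis"], wide.loc[acc, "abundance"]
            if not (np.isfinite(ps) and np.isfinite(pa)):
                cats.append("excluded")
                continue
            cats.append(classify_rhythmicity(ps, pa, alpha))
        table[f"category_{test_name}"] = cats
        valid = [c for c in cats if c != "excluded"]
        summary[f"category_pct_{test_name}"] = category_percentages(valid)
        ctab, fisher_p = overlap_fisher(valid)
        summary[f"fisher_table_{test_name}"] = ctab.tolist()
        summary[f"fisher_p_{test_name}"] = fisher_p
    summary["n_excluded"] = int((table["category_umbrella"] == "excluded").sum())

    table["fold_change_synthesis"] = wide_fc["synthesis"]
    table["fold_change_abundance"] = wide_fc["abundance"]
    table["phase_synthesis_h"] = wide_phase["synthesis"]
    table["phase_abundance_h"] = wide_phase["abundance"]

    # amplitude comparison: rhythmic-synthesis vs rhythmic-abundance sets (umbrella calls)
    synth_rhythmic = table["category_umbrella"].isin(["both", "synthesis_only"])
    abund_rhythmic = table["category_umbrella"].isin(["both", "abundance_only"])
    fc_s = table.loc[synth_rhythmic, "fold_change_synthesis"].dropna()
    fc_a = table.loc[abund_rhythmic, "fold_change_abundance"].dropna()
    if len(fc_s) and len(fc_a):
        summary["mannwhitney_fold_change_p"] = compare_fold_change_distributions(fc_s, fc_a)
    else:
        summary["mannwhitney_fold_change_p"] = None
    return {"table": table, "summary": summary}


def complex_coordination_analysis(
    quant: ProteinQuantTable,
    annotations,
    min_coverage: float = 0.0,
    min_subunits: int = 5,
    n_iterations: int = 1000,
    seed: int = 0,
    fold_change: pd.Series | None = None,
):
    """Detected complexes, observed turnover SDs, resampling null, and the test."""
    turnover = relative_turnover(quant)
    detected = map_complexes(turnover, annotations, min_coverage=min_coverage, fold_change=fold_change)
    observed, structure = within_complex_sd(detected, min_subunits=min_subunits)
    result = None
    null = None
    if len(observed):
        null = resample_null(structure, turnover.dropna(), n_iterations=n_iterations, seed=seed)
        result = coordination_test(observed, null, seed=seed)
    return {
        "detected": detected,
        "observed_sds": observed,
        "structure": structure,
        "null_sds": null,
        "result": result,
        "turnover": turnover,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the run directory.

    Writes the collapsed peptide table, protein quantification,
    incorporation QC, rhythm statistics, per-protein categories, the
    complex-coordination outputs when enabled, a provenance log and a
    summary JSON, plus a copy of the config. Identical config and
    inputs give identical outputs.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    design = StudyDesign.from_yaml(config.design_path)
    logger.info("quantify: %s", config.evidence_path)
    q = quantify_evidence(
        config.evidence_path,
        design,
        normalize=config.normalize,
        apply_pair_filter=config.apply_pair_filter,
    )
    write_peptides(q["peptides"], out / "peptides.tsv")
    write_proteins(q["quant"], out / "proteins.tsv")
    q["incorporation"].to_csv(out / "incorporation.tsv", sep="\t", index=False)
    if q["normalization"] is not None:
        q["normalization"].to_csv(out / "normalization.tsv", sep="\t", index=False)

    logger.info("rhythm analysis: %d proteins", len(q["quant"]))
    rhythms = rhythm_analysis(q["quant"], umbrella_mode=config.umbrella_mode)
    rhythms.to_csv(out / "rhythms.tsv", sep="\t", index=False)

    cls = classification_summary(rhythms, alpha=config.alpha)
    cls["table"].to_csv(out / "categories.tsv", sep="\t")
    summary = {
        "version": config.version,
        "seed": config.seed,
        "n_proteins": len(q["quant"]),
        **cls["summary"],
    }

    if config.run_complexes:
        annotations = read_complex_annotation(config.annotation_path)
        coord = complex_coordination_analysis(
            q["quant"],
            annotations,
            min_coverage=config.min_coverage,
            min_subunits=config.min_subunits,
            n_iterations=config.n_iterations,
            seed=config.seed,
        )
        rows = [
            {
                "complex_id": c.complex_id,
                "complex_name": c.complex_name,
                "n_annotated": c.n_annotated,
                "n_detected": c.n_detected,
                "coverage": c.coverage,
                "mean_turnover": c.mean_turnover,
                "sd_turnover": c.sd_turnover,
                "mean_fold_change": c.mean_fold_change,
            }
            for c in coord["detected"]
        ]
        pd.DataFrame(rows).to_csv(out / "complexes.tsv", sep="\t", index=False)
        if coord["null_sds"] is not None:
            pd.DataFrame(coord["null_sds"]).to_csv(out / "null_sds.tsv", sep="\t", index=False)
        if coord["result"] is not None:
            summary["coordination"] = {
                "n_complexes_tested": len(coord["observed_sds"]),
                "p_mannwhitney": coord["result"].p_mannwhitney,
                "empirical_p": coord["result"].empirical_p,
                "n_iterations": coord["result"].n_iterations,
            }

    provenance = {
        "version": config.version,
        "seed": config.seed,
        "filters": q["provenance"],
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return out
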