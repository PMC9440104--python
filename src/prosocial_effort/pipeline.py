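"""Seeded, configured pipeline: simulate -> exclude -> describe -> fit ->
compare -> decode -> report.

Every stage reads its inputs from, and writes tidy CSVs into, a single run
directory, so stages can be re-run individually from cached files. A single
global seed expands into per-stage seeds through a fixed scheme
(stage_seed = SeedSequence(global_seed, stage_index)), and a snapshot of the
validated config is written beside the outputs before anything runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .cohort import CohortModel
from .decoding import compare_decoders, covariate_correlation, decode_cohort, overlap_regression
from .design import TARGET_SELF, get_design
from .discounting import model_family, spec_from_name
from .fitting import fit_cohort, fits_to_frame
from .simulate import apply_exclusions, simulate_cohort
from .stats import choice_proportions, cohort_summary, two_stage_choice_regression

logger = logging.getLogger("prosocial_effort.pipeline")

_STAGE_INDEX = {
    "simulate": 0,
    "fit": 1,
    "decode": 2,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed or the configuration is invalid."""


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    study_id: int = 2
    n_participants: int = 94
    seed: int = 0
    cohort: CohortModel = field(default_factory=CohortModel)
    exclusion_hi: float = 0.85
    exclusion_lo: float = 0.15
    models: list[str] | None = None  # None = all 12
    n_starts: int = 10
    k_folds: int = 5
    include_decision_time: bool = True
    with_covariate: bool = True
    output_dir: str = "runs/run0"

    def validate(self) -> None:
        design = get_design(self.study_id)
        if self.n_participants < 1:
            raise PipelineError("n_participants must be >= 1")
        if not 0.0 <= self.exclusion_lo < self.exclusion_hi <= 1.0:
            raise PipelineError("exclusion cutoffs must satisfy 0 <= lo < hi <= 1")
        for name in self.models or []:
            try:
                spec_from_name(name, design.targets)
            except ValueError as err:
                raise PipelineError(str(err)) from err
        if self.n_starts < 1 or self.k_folds < 2:
            raise PipelineError("n_starts >= 1 and k_folds >= 2 required")

    def specs(self):
        design = get_design(self.study_id)
        if self.models is None:
            return model_family(design.targets)
        return [spec_from_name(n, design.targets) for n in self.models]

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, _STAGE_INDEX[stage]])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cohort_data = data.pop("cohort", None)
        cfg = cls(**data)
        if cohort_data:
            fs = cohort_data.pop("features_self", None)
            if fs is not None:
                from .simulate import FeatureModel

                cohort_data["features_self"] = FeatureModel(**fs)
            shrink = cohort_data.get("beta_other_shrink")
            if shrink is not None:
                cohort_data["beta_other_shrink"] = tuple(shrink)
            cfg.cohort = CohortModel(**cohort_data)
        cfg.validate()
        return cfg


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(config: PipelineConfig) -> Path:
    """Simulate the cohort; writes trials.csv and participants.csv."""
    out = _outdir(config)
    design = get_design(config.study_id)
    seed = config.stage_seed("simulate")
    sampler = lambda rng: config.cohort.sample(rng, design)  # noqa: E731
    trials, used = simulate_cohort(design, sampler, config.n_participants, seed=seed)
    pio.write_trials(trials, out / "trials.csv")

    rng_cov = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rows = []
    for i, params in enumerate(used):
        row = {"participant_id": f"p{i:03d}"}
        row.update({f"true_k_{t}": v for t, v in params.k.items()})
        row.update({f"true_beta_{t}": v for t, v in params.beta.items()})
        if config.with_covariate:
            row["covariate"] = config.cohort.covariate(rng_cov, params)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "participants.csv", index=False)
    logger.info("simulate: %d participants, %d trials -> %s", len(used), len(trials), out)
    return out / "trials.csv"


def stage_exclude(config: PipelineConfig) -> Path:
    out = _outdir(config)
    trials = pio.read_trials(out / "trials.csv")
    report = apply_exclusions(trials, hi=config.exclusion_hi, lo=config.exclusion_lo)
    report.as_frame().to_csv(out / "exclusions.csv", index=False)
    logger.info(
        "exclude: kept %d, excluded high %d, low %d",
        len(report.kept_ids),
        len(report.excluded_high_ids),
        len(report.excluded_low_ids),
    )
    return out / "exclusions.csv"


def _kept_trials(config: PipelineConfig) -> pd.DataFrame:
    out = _outdir(config)
    trials = pio.read_trials(out / "trials.csv")
    excl = pd.read_csv(out / "exclusions.csv")
    kept = excl.loc[excl["status"] == "kept", "participant_id"]
    return trials[trials["participant_id"].isin(kept)].reset_index(drop=True)


def stage_describe(config: PipelineConfig) -> Path:
    out = _outdir(config)
    trials = _kept_trials(config)
    choice_proportions(trials, by="effort").to_csv(out / "proportions_effort.csv", index=False)
    choice_proportions(trials, by="reward").to_csv(out / "proportions_reward.csv", index=False)
    covariate = None
    parts = pd.read_csv(out / "participants.csv")
    if "covariate" in parts.columns:
        covariate = parts.set_index("participant_id")["covariate"]
    summary = cohort_summary(trials, covariate=covariate)
    summary.to_csv(out / "cohort_summary.csv", index=False)
    two_stage = two_stage_choice_regression(trials)
    two_stage.group.to_csv(out / "choice_regression.csv", index=False)
    logger.info("describe: %d kept participants summarized", len(summary))
    return out / "cohort_summary.csv"


def stage_fit(config: PipelineConfig) -> Path:
    out = _outdir(config)
    trials = _kept_trials(config)
    fits = fit_cohort(
        trials, config.specs(), n_starts=config.n_starts, seed=config.stage_seed("fit")
    )
    fits_to_frame(fits).to_csv(out / "fits.csv", index=False)
    logger.info("fit: %d fits written", len(fits))
    return out / "fits.csv"


def stage_compare(config: PipelineConfig) -> Path:
    out = _outdir(config)
    df = pd.read_csv(out / "fits.csv")
    rows = []
    agg = (
        df.groupby("model")["bic"]
        .agg(summed_bic="sum", mean_bic="mean", median_bic="median")
        .reset_index()
    )
    winners = df.loc[df.groupby("participant_id")["bic"].idxmin(), "model"]
    agg["n_wins"] = agg["model"].map(winners.value_counts()).fillna(0).astype(int)
    agg = agg.sort_values("summed_bic", kind="stable").reset_index(drop=True)
    agg.to_csv(out / "model_comparison.csv", index=False)
    logger.info("compare: best summed-BIC model %s", agg.loc[0, "model"])
    return out / "model_comparison.csv"


def stage_decode(config: PipelineConfig) -> Path:
    out = _outdir(config)
    trials = _kept_trials(config)
    design = get_design(config.study_id)
    seed = config.stage_seed("decode")
    others = [t for t in design.targets if t != TARGET_SELF]
    acc_frames = [
        decode_cohort(
            trials,
            other,
            k_folds=config.k_folds,
            seed=seed,
            include_decision_time=config.include_decision_time,
        )
        for other in others
    ]
    acc = pd.concat(acc_frames, ignore_index=True)
    acc.to_csv(out / "decoding.csv", index=False)

    summary = pd.read_csv(out / "cohort_summary.csv").set_index("participant_id")
    rows = []
    for other, frame in zip(others, acc_frames):
        merged = frame.set_index("participant_id").join(summary, how="inner")
        reg = overlap_regression(merged[f"delta_{other}"], merged["accuracy_pct"])
        rows.append(
            {
                "analysis": f"overlap_vs_delta_{other}",
                "slope": reg.slope,
                "se": reg.se,
                "t": reg.t,
                "df": reg.df,
                "p": reg.p,
                "r": reg.r,
            }
        )
        if "covariate" in merged.columns:
            cov = covariate_correlation(merged["accuracy_pct"], merged["covariate"])
            rows.append(
                {
                    "analysis": f"covariate_vs_accuracy_{other}",
                    "slope": cov.slope,
                    "se": cov.se,
                    "t": cov.t,
                    "df": cov.df,
                    "p": cov.p,
                    "r": cov.r,
                }
            )
    if len(others) == 2:
        wide = acc.pivot(index="participant_id", columns="pair", values="accuracy_pct")
        cols = [f"{TARGET_SELF}_vs_{o}" for o in others]
        comp = compare_decoders(wide[cols[0]], wide[cols[1]])
        rows.append(
            {
                "analysis": f"decoder_{others[1]}_minus_{others[0]}",
                "slope": comp.mean_diff_pct,
                "se": float("nan"),
                "t": comp.t,
                "df": comp.df,
                "p": comp.p,
                "r": comp.r,
            }
        )
    pd.DataFrame(rows).to_csv(out / "decoding_summary.csv", index=False)
    logger.info("decode: %d accuracies, %d group analyses", len(acc), len(rows))
    return out / "decoding.csv"


def stage_report(config: PipelineConfig) -> Path:
    out = _outdir(config)
    excl = pd.read_csv(out / "exclusions.csv")
    comp = pd.read_csv(out / "model_comparison.csv")
    dec = pd.read_csv(out / "decoding_summary.csv")
    summary = pd.read_csv(out / "cohort_summary.csv")
    lines = [
        "# Pipeline report",
        "",
        f"Study {config.study_id}, {config.n_participants} simulated participants, "
        f"seed {config.seed}.",
        "",
        "## Exclusions",
        excl["status"].value_counts().to_string(),
        "",
        "## Effortful-choice rates (kept cohort)",
        summary.filter(like="rate_").mean().round(3).to_string(),
        "",
        "## Model comparison (by summed BIC)",
        comp.head(5).to_string(index=False),
        "",
        "## Decoding and overlap analyses",
        dec.round(4).to_string(index=False),
        "",
    ]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    logger.info("report -> %s", path)
    return path


STAGES = {
    "simulate": stage_simulate,
    "exclude": stage_exclude,
    "describe": stage_describe,
    "fit": stage_fit,
    "compare": stage_compare,
    "decode": stage_decode,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the run directory.

    The validated config snapshot and a log file are written into the run
    directory. A stage failure raises PipelineError; outputs of completed
    stages are retained.
    """
    config.validate()
    out = _outdir(config)
    config.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        for name, stage in STAGES.items():
            logger.info("stage %s starting", name)
            try:
                stage(config)
            except PipelineError:
                raise
            except Exception as err:  # noqa: BLE001 - wrap with stage context
                logger.error("stage %s failed: %s", name, err)
                raise PipelineError(f"stage {name!r} failed: {err}") from err
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
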