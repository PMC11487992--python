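"""End-to-end orchestration: generate or ingest a cohort, code it, and
write the descriptive, univariate and interaction-search artifacts.

SI and SA analyses use per-outcome complete cases: a record that
declined the suicide-attempt item is excluded from SA models but
retained for SI models, mirroring the per-variable Ns of the study's
univariate table.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .coding import (
    AGE_BANDS3,
    ERAS,
    GENDERS,
    RISK_LEVELS,
    code_records,
    filter_complete,
    read_cohort_csv,
    write_cohort_csv,
)
from .cohort import CohortGenerator, GeneratorConfig, default_config
from .descriptives import prevalence, risk_distribution
from .interaction_search import InteractionSearchLogit, SearchConfig
from .univariate import univariate_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES", "UNIVARIATE_LEVELS"]

#: Variables of the univariate analyses with ordered levels (reference first).
UNIVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": GENDERS,
    "age_band3": AGE_BANDS3,
    "era": ERAS,
    "risk": RISK_LEVELS,
}

ALL_STAGES: tuple[str, ...] = (
    "cohort", "coding", "descriptives", "univariate", "search",
)


@dataclass
class PipelineConfig:
    """Everything one run needs: input, outcomes, seeds, output dir."""

    out_dir: str = "suicohort_run"
    input_csv: str | None = None  # if None, generate synthetically
    generator: GeneratorConfig | None = None
    outcomes: tuple[str, ...] = ("si", "sa")
    search: SearchConfig = field(default_factory=SearchConfig)
    seed: int = 0
    write_plots: bool = False

    def content_hash(self) -> str:
        """Hash of the analysis configuration (output location and plot
        toggle excluded: they do not affect the computed numbers)."""
        def clean(o):
            if dataclasses.is_dataclass(o):
                o = dataclasses.asdict(o)
            if isinstance(o, dict):
                return {
                    str(k): clean(v)
                    for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))
                }
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            return o

        content = clean(self)
        content.pop("out_dir", None)
        content.pop("write_plots", None)
        payload = json.dumps(content, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _required_for(outcome: str) -> tuple[str, ...]:
    return ("gender", "age", "k10", outcome)


class _Stage:
    """Context manager tagging any stage failure with the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"[{self.name}] stage failed: {exc}") from exc


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the requested stages and write the artifact bundle.

    Returns a manifest dict (also written as ``manifest.json``) listing
    the seed, config hash, package version and produced files.  The
    cohort and coding stages always run; later stages only if named in
    ``stages``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def write_csv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        artifacts.append(name)

    with _Stage("cohort"):
        if config.input_csv:
            raw = read_cohort_csv(config.input_csv)
        else:
            gen = CohortGenerator(config.generator or default_config())
            gen.calibrate()
            raw = gen.generate(seed=config.seed)
            with open(out / "calibration.json", "w") as fh:
                json.dump(gen.calibration_, fh, indent=2)
            artifacts.append("calibration.json")
        write_cohort_csv(raw, out / "cohort.csv")
        artifacts.append("cohort.csv")

    with _Stage("coding"):
        coded = code_records(raw)
        complete = {}
        for outcome in config.outcomes:
            kept, tally = filter_complete(coded, required=_required_for(outcome))
            complete[outcome] = kept
            tally.to_json(out / f"exclusions_{outcome}.json")
            artifacts.append(f"exclusions_{outcome}.json")
        write_csv(coded, "coded.csv")

    if "descriptives" in stages:
        with _Stage("descriptives"):
            base = complete[config.outcomes[0]]
            t1 = pd.concat(
                [risk_distribution(base, "gender"), risk_distribution(base, "age_band3")],
                ignore_index=True,
            )
            write_csv(t1, "table1_risk_distribution.csv")
            trends = []
            for outcome in config.outcomes:
                tr = prevalence(complete[outcome], outcome, group_by="school_year")
                tr.insert(0, "outcome", outcome)
                trends.append(tr)
            write_csv(pd.concat(trends, ignore_index=True), "trend_prevalence.csv")
            write_csv(
                risk_distribution(base, "school_year"), "trend_risk_distribution.csv"
            )

    if "univariate" in stages:
        with _Stage("univariate"):
            for outcome in config.outcomes:
                parts = [
                    univariate_table(complete[outcome], var, outcome, levels).summary()
                    for var, levels in UNIVARIATE_LEVELS.items()
                ]
                write_csv(pd.concat(parts, ignore_index=True), f"table2_{outcome}.csv")

    if "search" in stages:
        with _Stage("search"):
            for outcome in config.outcomes:
                res = InteractionSearchLogit(
                    complete[outcome], outcome, config=config.search
                ).fit(seed=config.seed)
                write_csv(res.report.to_frame(), f"table3_{outcome}.csv")
                with open(out / f"search_log_{outcome}.jsonl", "w") as fh:
                    for entry in res.state.log:
                        fh.write(json.dumps(entry) + "\n")
                artifacts.append(f"search_log_{outcome}.jsonl")

    if config.write_plots and "descriptives" in stages:
        with _Stage("plots"):
            from .plotting import plot_prevalence_trend, plot_risk_trend

            trend = pd.read_csv(out / "trend_prevalence.csv")
            plot_prevalence_trend(trend, out / "fig1_prevalence.png")
            risk_trend = pd.read_csv(out / "trend_risk_distribution.csv")
            plot_risk_trend(risk_trend, out / "fig2_risk.png")
            artifacts += ["fig1_prevalence.png", "fig2_risk.png"]

    manifest = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "version": __version__,
        "n_records": int(len(raw)),
        "artifacts": sorted(artifacts),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
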