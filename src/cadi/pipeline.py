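"""Stage orchestration: simulate -> build-pod -> compute -> validate -> regress.

Each stage logs rows in/out and elapsed time to standard error, writes its
artifacts under ``config.out_dir``, and aborts the run with a stage-tagged
error on failure. Rerunning with the same config and inputs reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import index as index_mod
from .association import AssociationAnalysis
from .io import RunConfig, read_table, write_table
from .pod import PODBuilder
from .synthetic import ScenarioConfig, simulate_scenario
from .validation import correlation_suite, weighted_prevalence

__all__ = ["PipelineError", "run_pipeline"]

log = logging.getLogger("cadi")


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage=%s status=start", self.name)
        return self

    def done(self, rows_in=None, rows_out=None):
        log.info("stage=%s status=done rows_in=%s rows_out=%s elapsed=%.2fs",
                 self.name, rows_in, rows_out,
                 time.perf_counter() - self.t0)

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(self.name, str(exc)) from exc
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the in-memory artifacts.

    Inputs not pointed to by the config are generated by the synthetic
    scenario (seeded from ``config.seed``). Artifacts written: every input
    table used, pod.csv, cadi.csv, validation.json, regression table and
    JSON.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    with _Stage("simulate") as st:
        scenario = dict(config.scenario)
        scenario.setdefault("seed", config.seed)
        sc = ScenarioConfig.from_dict(scenario)
        needed = [n for n in ("corpus", "trends", "population", "penetration",
                              "covariates", "survey")
                  if getattr(config, n) is None]
        if needed:
            sim = simulate_scenario(sc)
            for name in needed:
                artifacts[name] = sim[name]
                write_table(sim[name], out / f"{name}.csv", name)
            write_table(sim["severity"], out / "severity.csv", "severity")
        for name in ("corpus", "trends", "population", "penetration",
                     "covariates", "survey"):
            if getattr(config, name) is not None:
                artifacts[name] = read_table(getattr(config, name), name)
        st.done(rows_out=sum(len(v) for v in artifacts.values()))

    with _Stage("build_pod") as st:
        builder = PODBuilder(
            min_chars=config.min_chars, min_char_len=config.min_char_len,
            min_frequency=config.min_frequency, dim=config.embedding_dim,
            window=config.embedding_window, epochs=config.embedding_epochs,
            stopwords=tuple(config.stopwords),
            alpha_threshold=config.alpha_threshold, top_k=config.top_k,
            seed=config.seed)
        builder.fit(artifacts["corpus"])
        pod = builder.pod_
        if pod.empty:
            raise ValueError("the Public Opinion Dictionary came out empty; "
                             "relax alpha_threshold/min_frequency")
        artifacts["pod"] = pod
        write_table(pod, out / "pod.csv", "pod")
        st.done(rows_in=len(artifacts["corpus"]), rows_out=len(pod))

    with _Stage("compute_index") as st:
        trends = artifacts["trends"]
        pod_words = set(artifacts["pod"]["word"])
        have = set(trends["word"].unique())
        usable = pod_words & have
        if not usable:
            raise ValueError("no POD word has a trend series")
        pod_used = artifacts["pod"][artifacts["pod"]["word"].isin(usable)]
        model = index_mod.CADIModel(tau=config.tau)
        model.fit(trends[trends["word"].isin(usable)], pod_used,
                  artifacts["population"], artifacts["penetration"])
        artifacts["cadi"] = model.cadi_
        artifacts["weights"] = model.weights_
        write_table(model.cadi_, out / "cadi.csv", "cadi")
        st.done(rows_in=len(trends), rows_out=len(model.cadi_))

    with _Stage("validate") as st:
        prev = weighted_prevalence(artifacts["survey"])
        # a synthetic survey is drawn at the scenario's (clipped) survey year
        survey_year = (config.survey_year if config.survey is not None
                       else sc.effective_survey_year)
        cadi_y = artifacts["cadi"]
        cadi_y = cadi_y[cadi_y["year"] == survey_year]
        merged = (cadi_y.set_index("region")["cadi"]
                  .to_frame().join(prev, how="inner"))
        report = correlation_suite(merged["cadi"], merged["prevalence"])
        artifacts["validation"] = report
        (out / "validation.json").write_text(
            json.dumps(report.to_dict(), indent=2), encoding="utf-8")
        st.done(rows_in=len(artifacts["survey"]), rows_out=report.n)

    with _Stage("regress") as st:
        panel = artifacts["covariates"].merge(
            artifacts["cadi"][["region", "year", "cadi"]],
            on=["region", "year"], how="inner")
        if panel.empty:
            raise ValueError("covariates and index share no (region, year)")
        analysis = AssociationAnalysis(
            quantile=config.quantile, n_boot=config.n_boot,
            subgroups=config.subgroups, seed=config.seed)
        analysis.fit(panel)
        artifacts["regression"] = analysis.results_
        artifacts["regression_table"] = analysis.table_
        analysis.table_.to_csv(out / "regression_table.csv",
                               encoding="utf-8")
        full = {f"{g}/{k}": (r.to_dict() if r is not None else None)
                for (g, k), r in analysis.results_.items()}
        (out / "regression.json").write_text(
            json.dumps(full, indent=2), encoding="utf-8")
        st.done(rows_in=len(panel), rows_out=len(analysis.table_))

    return artifacts
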