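"""Reproducible end-to-end runs: simulate -> detect -> score -> analyze.

A run is fully described by a :class:`RunConfig`; re-running the same config
produces byte-identical tables.  Every output file's SHA-256 goes into the
run manifest together with the seeds, parameters and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import headtrack, metrics, stats, synthetic

__all__ = ["RunConfig", "run_pipeline", "validate_run"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    n_subjects: int = 10
    seed: int = 0
    null_effects: bool = False        # zero out all factor effects in the generator
    traces: bool = False              # synthesize head traces and run the detector
    sample_rate_hz: float = 100.0
    noise_sd_deg: float = 0.5
    trace_duration_s: float = 4.5
    n_slow: int = 3

    # detector
    velocity_threshold_deg_s: float = 20.0
    min_supra_samples: int = 3
    min_sub_samples: int = 5
    onset_backtrack_threshold: float | None = 8.0

    # metrics
    error_convention: str = "circular"   # "circular" | "linear"
    printed_rau_variant: bool = False

    # stats
    responder_cutoff_s: float = 1.5
    drop_incomplete_subjects: bool = False

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["files"][path.name] = _sha256(path)


def _hyper(config: RunConfig) -> synthetic.CohortHyperparameters:
    if config.null_effects:
        return synthetic.CohortHyperparameters.null()
    return synthetic.CohortHyperparameters(n_slow=config.n_slow)


DVS = {"rau": "rau", "mae": "mae_deg", "promptness": "mean_promptness_inv_s"}


def _drop_incomplete(cells: pd.DataFrame, dv: str) -> tuple[pd.DataFrame, list[str]]:
    bad = cells.loc[cells[dv].isna(), "subject"].unique().tolist()
    return cells[~cells["subject"].isin(bad)], bad


def analyze_cells(cells: pd.DataFrame, responses: pd.DataFrame,
                  config: RunConfig) -> dict[str, pd.DataFrame]:
    """Statistical layer on a finished cell table: ANOVAs, follow-ups, correlations."""
    out: dict[str, pd.DataFrame] = {}
    for name, dv in DVS.items():
        table = cells
        if config.drop_incomplete_subjects:
            table, dropped = _drop_incomplete(cells, dv)
            if dropped:
                table = table.copy()
        out[f"anova_{name}"] = stats.rm_anova(table, dv)
        out[f"pairwise_condition_{name}"] = stats.bonferroni_pairwise(table, dv, "condition")
    out["correlations"] = stats.correlation_table(cells)
    out["responders"] = stats.classify_responders(responses,
                                                  cutoff_s=config.responder_cutoff_s)
    return out


def _report(results: dict[str, pd.DataFrame], config: RunConfig) -> str:
    lines = ["# Run report", "",
             f"{config.n_subjects} subjects, seed {config.seed}, "
             f"{'trace-level' if config.traces else 'record-level'} simulation",
             ""]
    for name in DVS:
        lines.append(f"## RM-ANOVA: {name}")
        for r in results[f"anova_{name}"].itertuples(index=False):
            lines.append(
                f"- {r.effect}: F({r.df_num},{r.df_den}) = {r.F:.2f}, "
                f"p = {r.p:.4g}, partial eta^2 = {r.partial_eta_sq:.3f} "
                f"(GG eps = {r.gg_epsilon:.3f}, p_GG = {r.p_gg:.4g})"
            )
        lines.append("")
    lines.append("## Responder split")
    for r in results["responders"].itertuples(index=False):
        lines.append(f"- {r.subject}: mean RT {r.mean_rt_s:.3f} s -> {r.responder_class}")
    lines.append("")
    lines.append("## Correlations (subject x condition aggregates)")
    for r in results["correlations"].itertuples(index=False):
        lines.append(f"- {r.x} vs {r.y}: r = {r.pearson_r:.3f}, p = {r.p:.4g} (n = {r.n})")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig, output_dir, force: bool = False) -> dict:
    """Execute the full pipeline into ``output_dir``; returns the run manifest."""
    out = Path(output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output dir {out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"config": asdict(config), "files": {},
                      "versions": {"numpy": np.__version__, "pandas": pd.__version__}}

    cohort = synthetic.simulate_cohort(
        n_subjects=config.n_subjects, seed=config.seed, hyper=_hyper(config),
        traces=config.traces, sample_rate=config.sample_rate_hz,
        noise_sd_deg=config.noise_sd_deg, duration_s=config.trace_duration_s,
    )
    responses = cohort.responses
    if config.traces:
        detected = headtrack.detect_batch(
            cohort.traces,
            threshold_deg_s=config.velocity_threshold_deg_s,
            min_supra=config.min_supra_samples,
            min_sub=config.min_sub_samples,
            onset_backtrack_threshold=config.onset_backtrack_threshold,
        )
        responses = responses.merge(detected, on="trial_id", validate="one_to_one")

    _write(cohort.trials, out / "trials.csv", manifest)
    _write(responses, out / "responses.csv", manifest)
    _write(cohort.truth, out / "truth.csv", manifest)

    cells = metrics.summarize_cells(cohort.trials, responses,
                                    convention=config.error_convention,
                                    printed_rau=config.printed_rau_variant)
    _write(cells, out / "cells.csv", manifest)

    results = analyze_cells(cells, responses, config)
    for name, df in results.items():
        _write(df, out / f"{name}.csv", manifest)

    (out / "report.md").write_text(_report(results, config))
    manifest["files"]["report.md"] = _sha256(out / "report.md")
    config.to_yaml(out / "config.yaml")
    manifest["files"]["config.yaml"] = _sha256(out / "config.yaml")
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest


def validate_run(output_dir) -> tuple[bool, list[str]]:
    """Re-check module invariants on a finished run; (ok, findings)."""
    out = Path(output_dir)
    findings: list[str] = []
    ok = True

    def check(cond: bool, msg: str):
        nonlocal ok
        status = "PASS" if cond else "FAIL"
        findings.append(f"[{status}] {msg}")
        ok = ok and cond

    required = ["trials.csv", "responses.csv", "cells.csv", "config.yaml",
                "manifest.yaml"] + [f"anova_{n}.csv" for n in DVS]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        return False, [f"[FAIL] missing artifacts: {missing}"]

    config = RunConfig.from_yaml(out / "config.yaml")
    trials = pd.read_csv(out / "trials.csv")
    cells = pd.read_csv(out / "cells.csv")

    n_subj = trials["subject"].nunique()
    check(len(trials) == 576 * n_subj, f"trial count = 576 x {n_subj} subjects")
    per_cond = trials.groupby(["subject", "condition"]).size()
    check((per_cond == 96).all(), "96 trials per subject x condition")
    per_snr = trials.groupby(["subject", "snr_db"]).size()
    check((per_snr == 288).all(), "288 trials per subject x SNR")
    hopper = sum(
        (trials[[f"s{i}_call_sign" for i in range(4)]] == "Hopper").sum(axis=1) == 1
    )
    check(hopper == len(trials), "exactly one 'Hopper' stream per trial")
    check(len(cells) == n_subj * 24, f"cell table has {n_subj} x 24 rows")

    manifest = yaml.safe_load((out / "manifest.yaml").read_text())
    stale = [name for name, digest in manifest["files"].items()
             if not (out / name).exists() or _sha256(out / name) != digest]
    check(not stale, f"checksums match recorded manifest{': ' + str(stale) if stale else ''}")

    try:
        resid = stats.decomposition_residual(cells, "rau")
        check(resid < 1e-8 * max(1.0, float(np.nanstd(cells["rau"]))),
              f"ANOVA decomposition identity (residual {resid:.2e})")
    except ValueError as exc:
        check(False, f"decomposition identity not checkable: {exc}")

    if (out / "truth.csv").exists() and (out / "responders.csv").exists():
        truth = pd.read_csv(out / "truth.csv")
        responders = pd.read_csv(out / "responders.csv")
        true_cls = truth.groupby("subject")["responder_class"].first()
        merged = responders.set_index("subject").join(true_cls, rsuffix="_true")
        check((merged["responder_class"] == merged["responder_class_true"]).all(),
              "responder classes recover the generator's archetypes")
    return ok, findings
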