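"""End-to-end orchestration: read -> segment -> metrics -> statistics -> report.

``analyze_traces`` turns traces into one row per trial (T, L, V and the
per-letter rho profile); ``run_analyses`` runs the Homothety ANOVA and the
Isochrony regressions on those rows, always separately per script — block
capitals and cursive are never pooled.  ``run_pipeline`` wires the stages
behind a config and writes machine-readable reports (JSON plus CSV tables)
with a provenance block.  Small and Slow trials are carried through the
per-trial stage but excluded from the statistics, with conservation of
counts reported.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .homothety import (anova_frame, bonferroni_posthoc,
                        build_homothety_table, mixed_anova)
from .isochrony import (loglog_fit, pairwise_r_comparisons, per_group_fits,
                        substitute_outliers)
from .kinematics import (SmoothingConfig, compute_speed,
                         relative_letter_durations, word_metrics)
from .segmentation import (SegmentationError, SegmentationParams,
                           extract_strokes, group_words, read_overrides,
                           segment_letters)
from .trace_io import ANALYZED_CONDITIONS, Trace, read_cohort

log = logging.getLogger("penrhythm")


@dataclass(frozen=True)
class PipelineConfig:
    manifest: str = ""
    out_dir: str = "penrhythm_out"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    velocity_definition: str = "L/T"
    overrides_path: str = ""
    outlier_threshold: float = 4.0
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        smo = SmoothingConfig(**raw.pop("smoothing", {}))
        return cls(segmentation=seg, smoothing=smo, **raw)

    def digest(self) -> str:
        """Hash of the analysis-relevant parameters (paths excluded, so the
        same analysis written elsewhere hashes identically)."""
        d = dataclasses.asdict(self)
        for key in ("manifest", "out_dir", "overrides_path"):
            d.pop(key)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def analyze_traces(
    traces: list[Trace],
    params: SegmentationParams = SegmentationParams(),
    smoothing: SmoothingConfig = SmoothingConfig(),
    velocity_definition: str = "L/T",
    overrides: dict[str, list[int]] | None = None,
) -> pd.DataFrame:
    """Segment every trace and compute per-trial word metrics and rho.

    Returns one row per trial with columns participant_id, group, script,
    condition, T, L, V, n_strokes, rho_<letter>..., source, error.  A trial
    that fails a stage gets its error message recorded instead of values.
    """
    overrides = overrides or {}
    rows = []
    for trace in traces:
        meta = trace.meta
        row = {
            "trial_id": meta.trial_id, "participant_id": meta.participant_id,
            "group": meta.group, "script": meta.script,
            "condition": meta.condition, "error": "",
        }
        try:
            strokes = extract_strokes(trace, params)
            words = group_words(strokes, trace, params)
            if not words:
                raise SegmentationError("no pen-down strokes")
            if len(words) > 1:
                log.debug("trial %s: %d word groups, analyzing the longest",
                          meta.trial_id, len(words))
            word_group = max(
                words, key=lambda w: sum(s.duration for s in w))
            speed = compute_speed(trace, smoothing)
            record = word_metrics(word_group, trace, velocity_definition,
                                  speed=speed)
            letters = segment_letters(
                word_group, trace, len(meta.word), speed, params,
                overrides=overrides.get(meta.trial_id))
            profile = relative_letter_durations(letters, record)
            row.update(T=record.T, L=record.L, V=record.V,
                       n_strokes=record.n_strokes,
                       source=letters[0].source)
            for letter, rho in zip(profile.letters, profile.rho):
                row[f"rho_{letter}"] = rho
        except (SegmentationError, ValueError) as exc:
            row["error"] = str(exc)
            log.warning("trial %s failed: %s", meta.trial_id, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _records_to_homothety(records: pd.DataFrame, word: str) -> pd.DataFrame:
    longf = records.melt(
        id_vars=["participant_id", "group", "condition"],
        value_vars=[f"rho_{ch}" for ch in word],
        var_name="letter", value_name="rho")
    longf["letter"] = longf["letter"].str.removeprefix("rho_")
    # preserve the word's letter order
    order = {ch: i for i, ch in enumerate(word)}
    return longf.sort_values(
        ["participant_id", "condition", "letter"],
        key=lambda col: col.map(order) if col.name == "letter" else col,
        kind="stable").reset_index(drop=True)


def _regression_dict(res) -> dict:
    return {"intercept": res.intercept, "slope": res.slope,
            "r": res.r, "p": res.p, "n": res.n}


def run_analyses(records: pd.DataFrame, word: str = "burle",
                 outlier_threshold: float = 4.0,
                 alpha: float = 0.05) -> dict:
    """Homothety + Isochrony statistics from the per-trial table, per script."""
    ok = records[records["error"] == ""] if "error" in records else records
    report: dict = {"scripts": {}, "counts": {
        "input_trials": int(len(records)),
        "analyzable_trials": int(len(ok)),
        "failed_trials": int(len(records) - len(ok)),
    }}
    for script, sub in ok.groupby("script", sort=True):
        analyzed = sub[sub["condition"].isin(ANALYZED_CONDITIONS)]
        excluded = sub[~sub["condition"].isin(ANALYZED_CONDITIONS)]

        entry: dict = {"counts": {
            "trials": int(len(sub)),
            "analyzed": int(len(analyzed)),
            "excluded_small_slow": int(len(excluded)),
        }}

        desc = (analyzed.groupby(["group", "condition"], observed=True)
                [["T", "L", "V"]].agg(["mean", "std"]))
        desc.columns = [f"{v}_{s}" for v, s in desc.columns]
        entry["descriptives"] = desc.reset_index().to_dict("records")

        # Homothety
        table = build_homothety_table(
            _records_to_homothety(analyzed, word))
        anova = mixed_anova(table)
        entry["homothety"] = {
            "excluded_participants": table.attrs["excluded_participants"],
            "anova": anova_frame(anova).to_dict("records"),
            "posthoc": {},
        }
        for eff in ("Condition x Letter", "Group x Letter"):
            comps = bonferroni_posthoc(table, eff, alpha=alpha)
            entry["homothety"]["posthoc"][eff] = [
                dataclasses.asdict(c) for c in comps]

        # Isochrony: outlier screen on (L, T), then both regressions on
        # the substituted dataset
        pairs = analyzed[["L", "T"]].to_numpy()
        pairs_sub, outlier_report = substitute_outliers(
            pairs, threshold=outlier_threshold)
        L_s, T_s = pairs_sub[:, 0], pairs_sub[:, 1]
        iso = analyzed.copy()
        iso["L"], iso["T"] = L_s, T_s
        iso["V"] = np.where(analyzed["V"].to_numpy()
                            == analyzed["L"].to_numpy() / analyzed["T"].to_numpy(),
                            L_s / T_s, analyzed["V"].to_numpy())
        fits_by_group = per_group_fits(iso, y_col="V", x_col="L")
        entry["isochrony"] = {
            "outliers": {
                "threshold": outlier_report.threshold,
                "n_substituted": outlier_report.n_substituted,
                "substituted": [dataclasses.asdict(s)
                                for s in outlier_report.substituted],
                "n_pairs_screened": int(len(pairs)),
            },
            "duration_vs_length": _regression_dict(loglog_fit(L_s, T_s)),
            "velocity_vs_length": _regression_dict(
                loglog_fit(L_s, iso["V"].to_numpy())),
            "per_group_velocity_vs_length": {
                g: _regression_dict(r) for g, r in fits_by_group.items()},
            "pairwise_r_comparisons":
                pairwise_r_comparisons(fits_by_group).to_dict("records"),
        }
        report["scripts"][script] = entry
    return report


def run_pipeline(config: PipelineConfig,
                 traces: list[Trace] | None = None) -> dict:
    """Run the full analysis and write the report bundle to out_dir.

    ``traces`` may be supplied directly (e.g. from the simulator);
    otherwise they are read from the manifest in the config.
    """
    if traces is None:
        if not config.manifest:
            raise ValueError("config.manifest is empty and no traces given")
        traces = read_cohort(config.manifest)
    overrides = (read_overrides(config.overrides_path)
                 if config.overrides_path else None)
    records = analyze_traces(
        traces, config.segmentation, config.smoothing,
        config.velocity_definition, overrides)
    word = traces[0].meta.word if traces else "burle"
    report = run_analyses(records, word=word,
                          outlier_threshold=config.outlier_threshold,
                          alpha=config.alpha)
    report["provenance"] = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "velocity_definition": config.velocity_definition,
        "smoothing": config.smoothing.describe(),
        "software_version": __version__,
    }

    os.makedirs(config.out_dir, exist_ok=True)
    records.to_csv(os.path.join(config.out_dir, "per_trial.csv"),
                   index=False)
    for script, entry in report["scripts"].items():
        pd.DataFrame(entry["homothety"]["anova"]).to_csv(
            os.path.join(config.out_dir, f"anova_{script}.csv"), index=False)
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


__all__ = ["PipelineConfig", "analyze_traces", "run_analyses",
           "run_pipeline"]
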