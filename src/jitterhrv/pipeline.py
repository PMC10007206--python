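"""End-to-end study orchestration: generate -> clean -> ladder -> features
-> evaluate -> bound -> report.

Each stage reads cached upstream artifacts from the run directory and writes
its own outputs there, so any stage can be re-run in isolation.  A run
manifest (JSON) records the config snapshot, package version, seeds and
output paths; config + seed determine every output byte.
"""

from __future__ import annotations

import copy
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import bound as bound_mod
from . import labels as labels_mod
from .hrv import WindowSpec, compute_features
from .jitter import JitterLadder, build_ladder, hbis_from_peaks, perturb_rpeaks
from .staging import EvalConfig, aggregate_confusion, ensemble_curve, evaluate_cohort, mean_sensitivity_slope
from .synthdata import (
    ValidationError,
    cohort_spec_from_dict,
    generate_beat_pairs,
    generate_cohort,
    hypnograms_from_csv,
    hypnograms_to_csv,
    rpeaks_from_csv,
    rpeaks_to_csv,
    stage_params_from_dict,
)

STAGES = ("simulate", "labels", "ladder", "features", "evaluate", "bound", "report")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "runs/default",
    "cohort": {"n_participants": 50},
    "stage_hrv_params": {},
    "labels": {"min_epochs": 4},
    "ladder": {"n_levels": 97, "target_mae_ms": 60.0},
    "window": {"width_s": 300.0, "step_s": 30.0, "min_beats": 60, "median_kernel": 5},
    "eval": {
        "classifier": "svm-gaussian-ovo",
        "k_folds": 10,
        "knn_k": 10,
        # levels to carry through features/evaluation; None means all + baseline
        "levels": None,
        "single_features": False,
    },
    "beat_pairs": {
        "n_participants": 27,
        "beats_per": 100,
        "rgi_mean_ms": 250.0,
        "rgi_sd_ms": 8.97,
        "ep_sd_ms": 11.0,
    },
}


def merge_config(overrides: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (overrides or {}).items():
        if key not in cfg:
            raise ValidationError(f"unknown config key: {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ValidationError(f"config key {key!r} must be a mapping")
            unknown = set(val) - set(cfg[key]) if key != "stage_hrv_params" and key != "cohort" else set()
            if unknown:
                raise ValidationError(f"unknown config keys under {key!r}: {sorted(unknown)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    # Validate eagerly so errors name the offending section.
    cohort = dict(cfg["cohort"])
    cohort.setdefault("seed", cfg["seed"])
    cohort_spec_from_dict(cohort)
    stage_params_from_dict(cfg["stage_hrv_params"])
    return cfg


class Runner:
    """Stage-by-stage executor over a run directory."""

    def __init__(self, config: dict | None = None):
        self.cfg = merge_config(config)
        self.out = Path(self.cfg["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "package": "jitterhrv",
            "version": __version__,
            "config": copy.deepcopy(self.cfg),
            "outputs": {},
            "timestamps": {},
        }

    # -- helpers -----------------------------------------------------------
    def _record(self, stage: str, **paths: Path) -> None:
        self.manifest["outputs"].setdefault(stage, {})
        for name, p in paths.items():
            self.manifest["outputs"][stage][name] = str(p)
        self.manifest["timestamps"][stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def _require(self, stage: str, path: Path) -> Path:
        if not path.exists():
            raise ValidationError(
                f"missing upstream artifact {path.name!r}; run stage {stage!r} first"
            )
        return path

    def _levels(self, ladder: JitterLadder) -> list[int]:
        sel = self.cfg["eval"]["levels"]
        if sel is None:
            return list(range(0, ladder.n_levels + 1))
        return sorted(set(int(x) for x in sel) | {0})

    # -- stages ------------------------------------------------------------
    def simulate(self) -> None:
        cohort = dict(self.cfg["cohort"])
        cohort.setdefault("seed", self.cfg["seed"])
        spec = cohort_spec_from_dict(cohort)
        params = stage_params_from_dict(self.cfg["stage_hrv_params"])
        hyps, streams = generate_cohort(spec, params)
        hypnograms_to_csv(hyps, self.out / "hypnogram.csv")
        rpeaks_to_csv(streams, self.out / "rpeaks.csv")
        bp = self.cfg["beat_pairs"]
        generate_beat_pairs(seed=self.cfg["seed"], **bp).to_csv(
            self.out / "beat_pairs.csv", index=False
        )
        self._record(
            "simulate",
            hypnogram=self.out / "hypnogram.csv",
            rpeaks=self.out / "rpeaks.csv",
            beat_pairs=self.out / "beat_pairs.csv",
        )

    def labels(self) -> None:
        raw = hypnograms_from_csv(self._require("simulate", self.out / "hypnogram.csv"))
        min_epochs = self.cfg["labels"]["min_epochs"]
        cleaned = [labels_mod.clean(h, min_epochs=min_epochs) for h in raw]
        macro = [labels_mod.to_macro(h) for h in cleaned]
        hypnograms_to_csv(cleaned, self.out / "hypnogram_micro.csv")
        hypnograms_to_csv(macro, self.out / "hypnogram_macro.csv")
        self._record(
            "labels",
            micro=self.out / "hypnogram_micro.csv",
            macro=self.out / "hypnogram_macro.csv",
        )

    def ladder(self) -> None:
        streams = rpeaks_from_csv(self._require("simulate", self.out / "rpeaks.csv"))
        lad = build_ladder(
            streams,
            n_levels=self.cfg["ladder"]["n_levels"],
            target_mae_ms=self.cfg["ladder"]["target_mae_ms"],
            seed=self.cfg["seed"],
        )
        lad.to_json(self.out / "ladder.json")
        self._record("ladder", ladder=self.out / "ladder.json")

    def features(self) -> None:
        streams = rpeaks_from_csv(self._require("simulate", self.out / "rpeaks.csv"))
        hyps = hypnograms_from_csv(
            self._require("labels", self.out / "hypnogram_micro.csv")
        )
        lad = JitterLadder.from_json(self._require("ladder", self.out / "ladder.json"))
        wspec = WindowSpec(**self.cfg["window"])
        levels = self._levels(lad)
        frames = []
        for i, (stream, hyp) in enumerate(zip(streams, hyps)):
            for lvl in levels:
                if lvl == 0:
                    pert = stream
                else:
                    pert = perturb_rpeaks(
                        stream, lad.sigmas_ms[lvl - 1], lad.seed, i, lvl
                    )
                hbis = hbis_from_peaks(pert, level=lvl)
                frames.append(compute_features(hbis, hyp, wspec))
        pd.concat(frames, ignore_index=True).to_csv(
            self.out / "features.csv", index=False
        )
        self._record("features", features=self.out / "features.csv")

    def evaluate(self) -> None:
        feats = pd.read_csv(self._require("features", self.out / "features.csv"))
        lad = JitterLadder.from_json(self._require("ladder", self.out / "ladder.json"))
        macro_hyps = {
            h.participant_id: h
            for h in hypnograms_from_csv(
                self._require("labels", self.out / "hypnogram_macro.csv"),
                scheme="macro",
            )
        }
        mae = {
            pid: {lvl: lad.mae_ms[i, lvl - 1] for lvl in range(1, lad.n_levels + 1)}
            for i, pid in enumerate(lad.participant_ids)
        }
        ev = self.cfg["eval"]
        all_results, curves, slope_rows = [], [], []
        for scheme in ("micro", "macro"):
            table = feats.copy()
            if scheme == "macro":
                table["stage"] = [
                    macro_hyps[pid].labels[int(e)]
                    for pid, e in zip(table["participant_id"], table["epoch_index"])
                ]
            cfg = EvalConfig(
                classifier=ev["classifier"],
                k_folds=ev["k_folds"],
                knn_k=ev["knn_k"],
                scheme=scheme,
                seed=self.cfg["seed"],
            )
            res = evaluate_cohort(table, mae, cfg)
            all_results.append(res.errors)
            curve = ensemble_curve(res.errors.dropna(subset=["error_pct"]))
            curve.insert(0, "scheme", scheme)
            curves.append(curve)
            level0 = [cm for (pid, lvl), cm in res.confusions.items() if lvl == 0]
            try:
                pooled, excluded = aggregate_confusion(level0)
                pd.DataFrame(
                    pooled, index=res.class_order, columns=res.class_order
                ).to_csv(self.out / f"confusion_{scheme}.csv")
            except ValidationError:
                excluded = len(level0)
            self.manifest.setdefault("confusion_excluded", {})[scheme] = excluded
            if ev["single_features"]:
                for feat in EvalConfig().feature_subset:
                    fcfg = EvalConfig(
                        classifier=ev["classifier"],
                        k_folds=ev["k_folds"],
                        knn_k=ev["knn_k"],
                        feature_subset=(feat,),
                        scheme=scheme,
                        seed=self.cfg["seed"],
                    )
                    fres = evaluate_cohort(table, mae, fcfg)
                    slope_rows.append(
                        {
                            "scheme": scheme,
                            "feature": feat,
                            "slope_pct_per_s": mean_sensitivity_slope(
                                fres.errors.dropna(subset=["error_pct"])
                            ),
                        }
                    )
        pd.concat(all_results, ignore_index=True).to_csv(
            self.out / "results.csv", index=False
        )
        pd.concat(curves, ignore_index=True).to_csv(self.out / "curves.csv", index=False)
        outs = {"results": self.out / "results.csv", "curves": self.out / "curves.csv"}
        if slope_rows:
            pd.DataFrame(slope_rows).to_csv(self.out / "slopes.csv", index=False)
            outs["slopes"] = self.out / "slopes.csv"
        self._record("evaluate", **outs)

    def bound(self) -> None:
        table = pd.read_csv(self._require("simulate", self.out / "beat_pairs.csv"))
        summary = bound_mod.total_bound(table)
        payload = {q: dict(summary.loc[q]) for q in summary.index}
        projection = {}
        curves_path = self.out / "curves.csv"
        if curves_path.exists():
            curves = pd.read_csv(curves_path)
            bound_ms = summary.loc["|RGI|+|ep|", "mean_ms"]
            for scheme, g in curves.groupby("scheme"):
                try:
                    projection[scheme] = bound_mod.project_error(bound_ms, g)
                except ValidationError:
                    projection[scheme] = None
        with open(self.out / "bound_summary.json", "w") as fh:
            json.dump({"summary_ms": payload, "projection_pct": projection}, fh, indent=1)
        self._record("bound", bound_summary=self.out / "bound_summary.json")

    def report(self) -> dict:
        missing = [
            s
            for s, p in (
                ("evaluate", self.out / "results.csv"),
                ("bound", self.out / "bound_summary.json"),
            )
            if not p.exists()
        ]
        if missing:
            raise ValidationError(f"incomplete run; missing stages: {missing}")
        results = pd.read_csv(self.out / "results.csv")
        curves = pd.read_csv(self.out / "curves.csv")
        with open(self.out / "bound_summary.json") as fh:
            bound_summary = json.load(fh)
        extremes = []
        for scheme, g in curves.groupby("scheme"):
            g = g.sort_values("level")
            extremes.append(
                {
                    "scheme": scheme,
                    "E0_pct": float(g.iloc[0]["mean_error_pct"]),
                    "Emax_pct": float(g.iloc[-1]["mean_error_pct"]),
                }
            )
        report = {
            "extremes": extremes,
            "bound": bound_summary,
            "n_results_rows": int(len(results)),
        }
        slopes_path = self.out / "slopes.csv"
        if slopes_path.exists():
            report["slopes"] = pd.read_csv(slopes_path).to_dict("records")
        with open(self.out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        self._record("report", report=self.out / "report.json")
        return report

    # -- entry point -------------------------------------------------------
    def run_all(self) -> dict:
        self.simulate()
        self.labels()
        self.ladder()
        self.features()
        self.evaluate()
        self.bound()
        self.report()
        return self.write_manifest()

    def write_manifest(self) -> dict:
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1)
        return self.manifest


def run_pipeline(config: dict | None = None) -> dict:
    """Execute every stage under the merged config; returns the manifest."""
    return Runner(config).run_all()
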