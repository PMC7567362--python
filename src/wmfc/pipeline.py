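"""End-to-end orchestration: simulate-or-load -> FCM -> statistics -> ML.

One declarative YAML config drives the full analysis; every stochastic
stage draws its seed from one master seed, so re-running a config
reproduces identical outputs.  Stage outputs are written as labelled TSV
(matrices, tract profiles, trend tables), JSON (metadata, staging
summaries) and a compressed array bundle for the subject-level FCM stacks;
a run manifest records the config hash, seeds, subject counts and every
exclusion with its reason.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_mod
from . import classify as classify_mod
from . import group_stats as gs
from .fcm import (TooFewRetainedFramesError, build_covariate_design,
                  partial_out_covariates, subject_fcms)
from .registry import RoiRegistry, load_registry, validate_registry
from .roi_extraction import (CleaningConfig, framewise_displacement,
                             read_motion_tsv, read_roi_timeseries_tsv)
from .synthetic import SCORE_COLUMNS, GROUP_ORDER, SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "main", "validate_registry"]

logger = logging.getLogger("wmfc")


@dataclass
class RunConfig:
    """Declarative run configuration.

    Statistical defaults are the pipeline's standard operating values:
    probability threshold 0.8, FD threshold 0.5 mm, 0.01-0.1 Hz band,
    10,000 permutations at alpha 0.05, 200 trees, 10 folds, selection
    chunk 5.
    """

    mode: str = "synthetic"  # synthetic | roi_timeseries
    output_dir: str = "wmfc_out"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    cleaning: dict = field(default_factory=dict)
    n_perm: int = 10_000
    alpha: float = 0.05
    min_retained_frames: int = 10
    fcm_kinds: tuple[str, ...] = ("WG", "WW")
    partial_covariates: bool = True
    compute_gg: bool = False
    n_trees: int = 200
    selection_chunk: int = 5
    n_folds: int = 10
    nested_cv: bool = False
    run_groupstats: bool = True
    run_behavior: bool = True
    run_regression: bool = False
    run_classification: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("synthetic", "roi_timeseries"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.n_perm < 1 or self.n_folds < 2 or self.n_trees < 1:
            raise ValueError("n_perm, n_folds and n_trees must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode == "roi_timeseries":
            for key in ("timeseries_dir", "cohort_table"):
                if key not in self.inputs:
                    raise ValueError(f"roi_timeseries mode requires inputs.{key}")
            for key, val in self.inputs.items():
                if key.endswith(("_dir", "_table", "_csv")) and not Path(val).exists():
                    raise FileNotFoundError(f"inputs.{key}: {val} does not exist")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_matrix(path: Path, values: np.ndarray, rows, cols) -> None:
    pd.DataFrame(values, index=rows, columns=cols).to_csv(
        path, sep="\t", float_format="%.8g")


def _load_inputs(config: RunConfig, seeds):
    """Returns (series dict, motion dict, cohort DataFrame, registry, truth|None)."""
    if config.mode == "synthetic":
        sim_kwargs = dict(config.synthetic)
        sim_kwargs.setdefault("seed", int(seeds["simulate"]))
        sim = SimulationConfig(**sim_kwargs)
        cohort = simulate_cohort(sim)
        return cohort.series, cohort.motion, cohort.cohort, cohort.registry, cohort.truth
    ts_dir = Path(config.inputs["timeseries_dir"])
    cohort = pd.read_csv(config.inputs["cohort_table"], sep="\t")
    registry = (load_registry(config.inputs["registry"])
                if config.inputs.get("registry") else load_registry())
    motion_dir = config.inputs.get("motion_dir")
    series, motion = {}, {}
    tr = float(config.inputs.get("tr_seconds", 3.0))
    for sid in cohort["subject_id"]:
        series[sid] = read_roi_timeseries_tsv(ts_dir / f"{sid}.tsv",
                                              tr_seconds=tr, subject=sid)
        if motion_dir:
            motion[sid] = read_motion_tsv(Path(motion_dir) / f"{sid}.tsv")
    # restrict the registry to the ROIs actually present in the series
    any_series = next(iter(series.values()))
    registry = registry.subset(any_series.roi_order)
    return series, motion, cohort, registry, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the run manifest (also
    written to ``<output_dir>/manifest.json``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    stage_names = ["simulate", "fcm", "groupstats", "behavior", "classify"]
    seeds = {name: int(ss.generate_state(1)[0] % (2**31))
             for name, ss in zip(stage_names, master.spawn(len(stage_names)))}
    cleaning = CleaningConfig(**config.cleaning) if config.cleaning else CleaningConfig()
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stage_seeds": seeds,
        "stages": [],
        "exclusions": [],
    }

    # ---- inputs -----------------------------------------------------------
    series, motion, cohort, registry, truth = _load_inputs(config, seeds)
    manifest["stages"].append({"name": "inputs", "n_subjects": len(series)})
    if truth is not None:
        (out / "ground_truth.json").write_text(truth.to_json())
        cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)

    # ---- subject FCMs -----------------------------------------------------
    kinds = tuple(config.fcm_kinds) + (("GG",) if config.compute_gg else ())
    stacks: dict[str, list[np.ndarray]] = {k: [] for k in kinds}
    kept_subjects: list[str] = []
    row_labels: dict[str, list] = {}
    col_labels: dict[str, list] = {}
    for sid in cohort["subject_id"]:
        ts = series[sid]
        m = motion.get(sid)
        try:
            fcms = subject_fcms(ts, registry, motion=m,
                                fd_threshold=cleaning.fd_threshold,
                                min_frames=config.min_retained_frames,
                                kinds=kinds)
        except TooFewRetainedFramesError as exc:
            manifest["exclusions"].append({"subject": sid, "reason": str(exc)})
            logger.warning("excluding %s: %s", sid, exc)
            continue
        kept_subjects.append(sid)
        for k in kinds:
            stacks[k].append(fcms[k].values)
            row_labels[k] = fcms[k].row_labels
            col_labels[k] = fcms[k].col_labels
    if not kept_subjects:
        raise RuntimeError("no subject survived frame censoring")
    cohort = cohort.set_index("subject_id").loc[kept_subjects].reset_index()
    arr_stacks = {k: np.stack(v) for k, v in stacks.items()}

    if config.partial_covariates:
        design = build_covariate_design(cohort)
        for k in config.fcm_kinds:  # GG stays raw unless requested as a kind
            arr_stacks[k] = partial_out_covariates(arr_stacks[k], design)

    np.savez_compressed(out / "fcm_stacks.npz",
                        subjects=np.array(kept_subjects),
                        **{k: v for k, v in arr_stacks.items()})
    for k in kinds:
        _write_matrix(out / f"mean_fcm_all_{k}.tsv", arr_stacks[k].mean(axis=0),
                      row_labels[k], col_labels[k])
    manifest["stages"].append({"name": "fcm", "kinds": list(kinds),
                               "n_subjects": len(kept_subjects),
                               "n_excluded": len(manifest["exclusions"]),
                               "outputs": ["fcm_stacks.npz"]})

    labels = cohort["group"].to_numpy()
    groups_present = [g for g in GROUP_ORDER if g in set(labels)]
    rng_stats = np.random.default_rng(seeds["groupstats"])

    # ---- group statistics -------------------------------------------------
    comparisons = {}
    for k in config.fcm_kinds if config.run_groupstats else ():
        for g in groups_present:
            if g == "CN" or (labels == g).sum() < 2 or (labels == "CN").sum() < 2:
                continue
            comp = gs.compare_groups(arr_stacks[k], labels, ("CN", g),
                                     n_perm=config.n_perm, alpha=config.alpha,
                                     seed=rng_stats)
            comparisons[(k, g)] = comp
            tag = f"{k}_CN_vs_{g}"
            _write_matrix(out / f"difference_{tag}.tsv", comp.difference,
                          row_labels[k], col_labels[k])
            _write_matrix(out / f"p_fdr_{tag}.tsv", comp.p_fdr,
                          row_labels[k], col_labels[k])
            _write_matrix(out / f"effect_size_{tag}.tsv", comp.effect_size,
                          row_labels[k], col_labels[k])
            _write_matrix(out / f"thresholded_difference_{tag}.tsv",
                          comp.thresholded_difference, row_labels[k], col_labels[k])

        tract_vals = np.stack([gs.tractwise_fc(s, kind=k) for s in arr_stacks[k]])
        profiles = []
        for g in groups_present:
            if g == "CN":
                continue
            prof = gs.tract_ttest(tract_vals, labels, ("CN", g),
                                  tract_names=row_labels[k])
            prof.insert(0, "contrast", f"CN_vs_{g}")
            profiles.append(prof)
        if profiles:
            pd.concat(profiles).to_csv(out / f"tract_profile_{k}.tsv",
                                       sep="\t", index=False)

        if "CN" in groups_present and "ADD" in groups_present:
            ofc = gs.overall_fc(arr_stacks[k])
            trend = gs.overall_fc_trend(ofc, labels, group_order=groups_present)
            trend.to_frame().to_csv(out / f"overall_fc_trend_{k}.tsv",
                                    sep="\t", index=False)
    if config.run_groupstats:
        manifest["stages"].append({
            "name": "groupstats", "n_perm": config.n_perm, "alpha": config.alpha,
            "contrasts": [f"{k}:CN_vs_{g}" for (k, g) in comparisons],
        })

    # ---- behavior ---------------------------------------------------------
    score_cols = [c for c in SCORE_COLUMNS if c in cohort.columns]
    if config.run_behavior and score_cols:
        scores = cohort[score_cols]
        for k in config.fcm_kinds:
            assocs = behavior_mod.score_associations(arr_stacks[k], scores, kind=k,
                                                     alpha=config.alpha)
            tract_rows = {}
            for name, assoc in assocs.items():
                _write_matrix(out / f"score_r_zeroed_{k}_{name}.tsv",
                              assoc.r_zeroed, row_labels[k], col_labels[k])
                tract_rows[name] = behavior_mod.tract_average_correlation(
                    assoc.r_zeroed, kind=k)
            pd.DataFrame(tract_rows, index=row_labels[k]).to_csv(
                out / f"score_tract_average_{k}.tsv", sep="\t")
        if config.run_regression:
            feats = np.hstack([arr_stacks[k].reshape(len(kept_subjects), -1)
                               for k in config.fcm_kinds])
            has_any = scores.notna().any(axis=1).to_numpy()
            reg_summaries = {}
            for name in score_cols:
                try:
                    res = behavior_mod.rf_score_regression(
                        feats[has_any], scores[name].to_numpy(dtype=float)[has_any],
                        score_name=name, seed=seeds["behavior"],
                        n_trees=config.n_trees, chunk=config.selection_chunk,
                        n_folds=config.n_folds)
                except ValueError as exc:
                    reg_summaries[name] = {"skipped": str(exc)}
                    continue
                reg_summaries[name] = {"r": res.r, "r2": res.r2, "p": res.p,
                                       "n": res.n,
                                       "n_features": int(len(res.selected_features))}
            (out / "score_regression.json").write_text(
                json.dumps(reg_summaries, indent=1))
        manifest["stages"].append({"name": "behavior", "scores": score_cols})

    # ---- classification ---------------------------------------------------
    if config.run_classification:
        feats = np.hstack([arr_stacks[k].reshape(len(kept_subjects), -1)
                           for k in config.fcm_kinds])
        results = classify_mod.stage_classification(
            feats, labels, seed=seeds["classify"], n_trees=config.n_trees,
            chunk=config.selection_chunk, n_folds=config.n_folds,
            nested=config.nested_cv)
        summary = []
        for res in results:
            pd.DataFrame({"fpr": res.fpr, "tpr": res.tpr,
                          "threshold": res.thresholds}).to_csv(
                out / f"roc_{res.contrast}.tsv", sep="\t", index=False)
            summary.append({
                "contrast": res.contrast, "C": res.C, "gamma": res.gamma,
                "class_weight_ratio": res.class_weight_ratio,
                "cv_error": res.cv_error, "auc": res.auc,
                "sensitivity": res.sensitivity, "specificity": res.specificity,
                "n_control": res.n_control, "n_patient": res.n_patient,
                "n_features": res.n_features, "protocol": res.protocol,
            })
        (out / "staging.json").write_text(json.dumps(summary, indent=1))
        manifest["stages"].append({"name": "classify",
                                   "contrasts": [s["contrast"] for s in summary],
                                   "outputs": ["staging.json"]})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

def _add_common(p: argparse.ArgumentParser) -> None:
    p.add_argument("--config", help="YAML run configuration")
    p.add_argument("--seed", type=int, default=None, help="master seed override")
    p.add_argument("--out", default=None, help="output directory override")


def _build_config(args, mode: str | None = None) -> RunConfig:
    overrides = {"seed": args.seed, "output_dir": args.out}
    if mode:
        overrides["mode"] = mode
    if args.config:
        return RunConfig.from_yaml(args.config, **overrides)
    cfg = RunConfig(**{k: v for k, v in overrides.items() if v is not None})
    cfg.validate()
    return cfg


def main(argv: list[str] | None = None) -> int:
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    parser = argparse.ArgumentParser(
        prog="wmfc",
        description="White-matter functional connectivity analysis pipeline")
    sub = parser.add_subparsers(dest="command", required=True)

    p_sim = sub.add_parser("simulate", help="write a synthetic cohort to disk")
    _add_common(p_sim)

    for name, help_text in [
        ("run", "full pipeline: inputs -> FCM -> stats -> behavior -> staging"),
        ("fcm", "inputs and FCM construction only"),
        ("groupstats", "FCM plus group statistics"),
        ("behavior", "FCM plus FC-score associations"),
        ("classify", "FCM plus staging classification"),
    ]:
        p = sub.add_parser(name, help=help_text)
        _add_common(p)

    p_val = sub.add_parser("validate-registry", help="check an ROI registry CSV")
    p_val.add_argument("path", nargs="?", default=None)

    args = parser.parse_args(argv)

    if args.command == "validate-registry":
        reg = validate_registry(args.path)
        print(f"registry OK: {len(reg.wm)} WM + {len(reg.gm)} GM ROIs")
        return 0

    if args.command == "simulate":
        cfg = _build_config(args, mode="synthetic")
        sim_kwargs = dict(cfg.synthetic)
        sim_kwargs.setdefault("seed", cfg.seed)
        cohort = simulate_cohort(SimulationConfig(**sim_kwargs))
        outdir = Path(cfg.output_dir)
        cohort.write(outdir)
        print(f"wrote {len(cohort.subjects)} subjects to {outdir}")
        return 0

    cfg = _build_config(args)
    if args.command == "fcm":
        cfg.run_groupstats = cfg.run_behavior = cfg.run_classification = False
    elif args.command == "groupstats":
        cfg.run_behavior = cfg.run_classification = False
    elif args.command == "behavior":
        cfg.run_groupstats = cfg.run_classification = False
        cfg.run_behavior = True
    elif args.command == "classify":
        cfg.run_groupstats = cfg.run_behavior = False
        cfg.run_classification = True
    manifest = run_pipeline(cfg)
    print(f"run complete: {len(manifest['stages'])} stages, "
          f"{len(manifest['exclusions'])} exclusion(s); "
          f"manifest at {Path(cfg.output_dir) / 'manifest.json'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
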