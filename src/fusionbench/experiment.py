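"""End-to-end experiment orchestration: simulate -> split -> train the
fusion family -> evaluate -> paired statistics.

An :class:`ExperimentConfig` fully determines a run; every stage is seeded
and idempotent, artifacts are written under one output directory, and a
partial previous run is resumed per (configuration, fold) unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .fusion import FusionConfig, enumerate_family
from .phantom import CONDITIONS, CohortManifest, PhantomParams, generate_cohort
from .preprocess import preprocess_pair
from .splits import SplitPlan, make_cv_splits
from .stats import EvalTable, StatReport, aggregate_folds, build_report
from .training import (TrainProtocol, evaluate_pairs, load_checkpoint,
                       save_checkpoint, train_model)

__all__ = ["ExperimentConfig", "run_experiment", "compare_architectures",
           "fusion_effect_experiment", "PRESETS"]

log = logging.getLogger("fusionbench")


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, with explicit seeds throughout."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    n_subjects: int = 24
    condition_proportions: dict = field(default_factory=lambda: {
        "control": 0.39, "t1d": 0.40, "aab": 0.13, "mody": 0.08})
    sessions_per_subject_range: tuple[int, int] = (1, 2)
    k_folds: int = 2
    split_seed: int = 0
    protocol: TrainProtocol = field(
        default_factory=lambda: TrainProtocol.desk())
    family_depth: int = 4
    family_base_channels: int = 8
    family_spatial_dims: int = 2
    family_skip_policy: str = "ref"
    family_members: list = field(default_factory=lambda: ["all"])
    stats_m: int = 6
    baseline_name: str = "baseline_ref"
    train_seed: int = 0

    def family(self) -> list[FusionConfig]:
        full = enumerate_family(
            self.family_depth, self.family_spatial_dims,
            self.family_base_channels, skip_policy=self.family_skip_policy)
        if self.family_members == ["all"]:
            members = full
        else:
            by_name = {c.name: c for c in full}
            try:
                members = [by_name[m] for m in self.family_members]
            except KeyError as e:
                raise ValueError(
                    f"unknown family member {e.args[0]!r}; choose from "
                    f"{sorted(by_name)}") from None
        if self.baseline_name not in {c.name for c in members}:
            raise ValueError(
                f"baseline {self.baseline_name!r} is not in the family list")
        return members

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            for key in ("grid_shape", "voxel_size", "target_radius_range"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            if "contrast_table" in ph:
                ph["contrast_table"] = {
                    k: {m: tuple(v) for m, v in d.items()}
                    for k, d in ph["contrast_table"].items()}
            d["phantom"] = PhantomParams(**ph)
        if "protocol" in d and isinstance(d["protocol"], dict):
            d["protocol"] = TrainProtocol(**d["protocol"])
        if "sessions_per_subject_range" in d:
            d["sessions_per_subject_range"] = tuple(
                d["sessions_per_subject_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _preset_smoke(seed: int) -> ExperimentConfig:
    return ExperimentConfig(
        phantom=PhantomParams(seed=seed),
        n_subjects=12,
        condition_proportions={"control": 0.5, "t1d": 0.5},
        k_folds=2, split_seed=seed,
        protocol=TrainProtocol.desk(seed=seed, total_batches=60),
        family_members=["baseline_ref", "input_concat"],
        stats_m=1, train_seed=seed)


def _preset_desk(seed: int) -> ExperimentConfig:
    return ExperimentConfig(
        phantom=PhantomParams(seed=seed),
        n_subjects=24, k_folds=2, split_seed=seed,
        protocol=TrainProtocol.desk(seed=seed),
        family_members=["all"], stats_m=6, train_seed=seed)


def _preset_paper_scale(seed: int) -> ExperimentConfig:
    """Full-scale analogue: 3D volumes, five folds, the full training
    schedule.  This is GPU-sized work; provided for completeness."""
    return ExperimentConfig(
        phantom=PhantomParams(grid_shape=(64, 64, 16), seed=seed),
        n_subjects=163,
        condition_proportions={"control": 63 / 163, "t1d": 66 / 163,
                               "aab": 22 / 163, "mody": 12 / 163},
        sessions_per_subject_range=(1, 4),
        k_folds=5, split_seed=seed,
        protocol=TrainProtocol(seed=seed),
        family_depth=4, family_spatial_dims=3,
        family_members=["all"], stats_m=6, train_seed=seed)


PRESETS = {"smoke": _preset_smoke, "desk": _preset_desk,
           "paper-scale": _preset_paper_scale}


# ---------------------------------------------------------------------------


def _load_split_pairs(manifest: CohortManifest, pairs, cache: dict):
    out = []
    for key in pairs:
        key = tuple(key)
        if key not in cache:
            df = manifest.frame
            row = df[(df["subject_id"] == key[0])
                     & (df["session_id"] == key[1])].iloc[0]
            cache[key] = preprocess_pair(manifest.load_pair(row))
        out.append(cache[key])
    return out


def run_experiment(config: ExperimentConfig, outdir,
                   force: bool = False) -> StatReport:
    """Run the full pipeline; returns the statistical report.

    Artifacts under ``outdir``: cohort volumes + manifest, split plan,
    per-(config, fold) checkpoints and train records, the aggregated
    evaluation table, the stats report (CSV + JSON) and ``summary.md``.
    Re-running with identical config and seeds reproduces the artifacts;
    existing (config, fold) checkpoints are reused unless ``force``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    t_start = time.time()
    log.info("run_experiment start config_hash=%s outdir=%s", chash, outdir)

    manifest_path = outdir / "cohort" / "manifest.csv"
    if manifest_path.exists() and not force:
        manifest = CohortManifest.read(manifest_path)
        log.info("stage=simulate reused existing cohort")
    else:
        manifest = generate_cohort(
            config.phantom, config.n_subjects, config.condition_proportions,
            config.sessions_per_subject_range, outdir / "cohort")
        log.info("stage=simulate wrote %d pairs", len(manifest.frame))

    plan = make_cv_splits(manifest, config.k_folds, config.split_seed)
    plan.save(outdir / "splits.json")

    family = config.family()
    cache: dict = {}
    fold_tables = []
    for f, fold in enumerate(plan.folds):
        train_pairs = _load_split_pairs(manifest, fold.train_pairs, cache)
        val_pairs = _load_split_pairs(manifest, fold.val_pairs, cache)
        test_pairs = _load_split_pairs(manifest, fold.test_pairs, cache)
        rows = []
        for cfg in family:
            ck_path = outdir / "models" / f"{cfg.name}_fold{f}.npz"
            if ck_path.exists() and not force:
                model, _ = load_checkpoint(ck_path)
                log.info("stage=train fold=%d config=%s resumed", f, cfg.name)
            else:
                t0 = time.time()
                model, record = train_model(
                    cfg, config.protocol, train_pairs, val_pairs,
                    seed=config.train_seed,
                    log_fn=lambda msg: log.debug("%s %s", cfg.name, msg))
                save_checkpoint(ck_path, model, record)
                (outdir / "models" / f"{cfg.name}_fold{f}.json").write_text(
                    record.to_json())
                log.info("stage=train fold=%d config=%s best=%.4f@%d "
                         "early=%s dt=%.1fs", f, cfg.name,
                         record.best_val_loss, record.best_batch,
                         record.stopped_early, time.time() - t0)
            for pair, dice in zip(test_pairs,
                                  evaluate_pairs(model, test_pairs)):
                rows.append(dict(subject_id=pair.subject_id,
                                 session_id=pair.session_id,
                                 config_name=cfg.name, dice=dice))
        fold_tables.append(EvalTable.from_rows(rows))

    table = aggregate_folds(fold_tables)
    table.write(outdir / "eval_table.csv")
    report = build_report(table, config.baseline_name, config.stats_m)
    report.write(outdir / "stats.csv", outdir / "stats.json")
    _write_summary(outdir / "summary.md", config, report, chash)
    log.info("run_experiment done dt=%.1fs", time.time() - t_start)
    return report


def _write_summary(path, config: ExperimentConfig, report: StatReport,
                   chash: str) -> None:
    lines = [
        "# Fusion experiment summary",
        "",
        f"config hash: `{chash}`  |  baseline: `{report.baseline_name}`  |  "
        f"Bonferroni m = {report.m}",
        "",
        "| config | n | median Dice | IQR | median residual | corrected p | |",
        "|---|---|---|---|---|---|---|",
    ]
    base_row = report.row(report.baseline_name)
    ordered = [base_row] + report.ranked()
    for r in ordered:
        lines.append(
            f"| {r['config_name']} | {r['n']} | {r['median_dice']:.3f} | "
            f"[{r['iqr_low']:.3f}, {r['iqr_high']:.3f}] | "
            f"{r['median_residual']:+.3f} | {r['corrected_p']:.3g} | "
            f"{r['stars']} |")
    Path(path).write_text("\n".join(lines) + "\n")


def fusion_effect_experiment(seed: int, n_train: int = 24, n_val: int = 6,
                             n_test: int = 60,
                             deform_amplitude_vox: float = 2.0,
                             modes: Sequence[str] = (
                                 "baseline_ref", "baseline_sec",
                                 "input_concat"),
                             protocol: Optional[TrainProtocol] = None,
                             m: int = 6) -> dict:
    """One seeded replicate of the core fusion-effect comparison.

    A misaligned phantom cohort is simulated in memory (training,
    validation and test drawn with independent sub-seeds), the requested
    family members are trained under the desk protocol, and each is
    evaluated on the ``n_test`` held-out pairs against the
    reference-modality baseline (Wilcoxon, Bonferroni over ``m``).  The
    secondary modality's complementary boundary signal and the residual
    misalignment are both active, so fusion configurations can profit from
    the second modality while the secondary-only baseline suffers from
    labels drawn in the reference frame.

    Returns per-mode Dice arrays, medians, residual medians, and
    raw/corrected p-values.
    """
    from .phantom import simulate_pairs

    if protocol is None:
        protocol = TrainProtocol.desk(seed=seed)
    props = ExperimentConfig().condition_proportions
    amp_mm = deform_amplitude_vox * 1.5
    make = lambda s, n, tag: [
        preprocess_pair(p) for p in simulate_pairs(
            PhantomParams(deform_amplitude=amp_mm, seed=s), n, props,
            id_prefix=tag)]
    train = make(seed, n_train, "tr")
    val = make(seed + 1000, n_val, "va")
    test = make(seed + 2000, n_test, "te")

    scores: dict[str, np.ndarray] = {}
    for mode in modes:
        cfg = FusionConfig(mode=mode)
        model, _ = train_model(cfg, protocol, train, val, seed=seed)
        scores[mode] = np.array(evaluate_pairs(model, test))
        log.info("fusion_effect seed=%d mode=%s median=%.3f", seed, mode,
                 np.median(scores[mode]))

    from .stats import bonferroni, median, wilcoxon_signed_rank

    out = {"seed": seed, "n_test": n_test, "scores": scores,
           "median": {k: median(v) for k, v in scores.items()},
           "residual_median": {}, "raw_p": {}, "corrected_p": {}}
    base = scores["baseline_ref"]
    for mode in modes:
        if mode == "baseline_ref":
            continue
        w = wilcoxon_signed_rank(scores[mode], base)
        cp, _ = bonferroni(w.p, m)
        out["residual_median"][mode] = median(scores[mode] - base)
        out["raw_p"][mode] = w.p
        out["corrected_p"][mode] = cp
    return out


def compare_architectures(config: ExperimentConfig, presets: Sequence[dict],
                          outdir, force: bool = False) -> dict:
    """Run the experiment under >= 2 architecture presets (depth/width
    overrides) and tabulate whether the best fusion block agrees.

    Returns ``{"presets": [...], "best_blocks": {...}, "agreement": bool}``
    and writes ``comparison.json``.
    """
    if len(presets) < 2:
        raise ValueError("need at least two presets to compare")
    outdir = Path(outdir)
    results = {}
    for i, overrides in enumerate(presets):
        sub = dataclasses.replace(
            config, **{k: v for k, v in overrides.items()
                       if not k.startswith("_")})
        name = overrides.get("_name", f"preset{i}")
        report = run_experiment(sub, outdir / name, force=force)
        block_rows = [r for r in report.ranked()
                      if r["config_name"].startswith("block_concat")]
        best = block_rows[0]["config_name"] if block_rows else None
        results[name] = {
            "depth": sub.family_depth,
            "base_channels": sub.family_base_channels,
            "best_block": best,
            "report": report.rows,
        }
    blocks = {k: v["best_block"] for k, v in results.items()}
    payload = {
        "presets": list(results),
        "best_blocks": blocks,
        "agreement": len(set(blocks.values())) == 1,
        "details": {k: {kk: vv for kk, vv in v.items() if kk != "report"}
                    for k, v in results.items()},
    }
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "comparison.json").write_text(json.dumps(payload, indent=1))
    return payload
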