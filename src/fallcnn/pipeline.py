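"""End-to-end experiment orchestration.

One :class:`ExperimentConfig` drives the full protocol exactly once:

    simulate (or load) → augment → split 80/20 → fit min–max on train →
    normalize both splits → train a CNN variant → evaluate five metrics

A single top-level seed fans out deterministically to per-stage seeds
(simulation, augmentation, split, training) via ``numpy.random.SeedSequence``
spawning, so a report is reproducible from its logged master seed alone.
Named profiles preconfigure the three study set-ups (URFD-style 500×3,
SmartWatch-style 25×3, Notch-style 118×3) with their augmentation
multipliers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augmentation import PRESET_PLANS, AugmentPlan, augment_dataset
from .cnn_models import TrainConfig, predict, save_model, train_model, build_stack
from .metrics import MetricsReport, evaluate
from .signal_io import (LabeledDataset, apply_min_max, fit_min_max,
                        read_dataset, split_dataset)
from .synthetic_data import SimConfig, gen_dataset

log = logging.getLogger("fallcnn")

_STAGES = ("simulate", "augment", "split", "train")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SimulatorSource:
    """Generate the input dataset with the bundled simulator."""

    n_fall: int = 30
    n_adl: int = 40
    window_length: int = 25


@dataclass
class ExperimentConfig:
    """Everything one experiment run needs; see profiles in :data:`PROFILES`."""

    source: SimulatorSource | str = field(default_factory=SimulatorSource)
    plan: AugmentPlan = field(default_factory=lambda: AugmentPlan(0, 0))
    train_fraction: float = 0.8
    variant: str = "CNN-1Conv"
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


#: Named study profiles: dataset shape + augmentation multipliers.
PROFILES: dict[str, dict] = {
    "urfd": {
        "source": {"n_fall": 30, "n_adl": 40, "window_length": 500},
        "plan": {"copies_per_fall": 60, "copies_per_adl": 80,
                 "include_originals": False},
        "variant": "CNN-3B3Conv",
    },
    "smartwatch": {
        "source": {"n_fall": 182, "n_adl": 1088, "window_length": 25},
        "plan": {"copies_per_fall": 5, "copies_per_adl": 0},
        "variant": "CNN-1Conv",
    },
    "notch": {
        "source": {"n_fall": 106, "n_adl": 568, "window_length": 118},
        "plan": {"copies_per_fall": 4, "copies_per_adl": 0},
        "variant": "CNN-3B3Conv",
    },
}


def profile_config(name: str, seed: int = 0, **overrides) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a named profile."""
    if name not in PROFILES:
        raise ValueError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
    p = PROFILES[name]
    cfg = ExperimentConfig(
        source=SimulatorSource(**p["source"]),
        plan=AugmentPlan(**p["plan"]),
        variant=p["variant"],
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def stage_seeds(master: int) -> dict[str, int]:
    """Deterministically fan the master seed out to one seed per stage."""
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        for stage, child in zip(_STAGES, children)
    }


@dataclass
class ExperimentReport:
    """Metrics plus the dataset bookkeeping and training history."""

    metrics: MetricsReport
    bookkeeping: dict
    history: list[dict]
    seeds: dict[str, int]
    config: dict

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "bookkeeping": self.bookkeeping,
            "history": self.history,
            "metrics": self.metrics.to_dict(),
            "metrics_formatted": self.metrics.formatted(),
        }


def _config_echo(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if isinstance(cfg.source, str):
        d["source"] = str(cfg.source)
    return d


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Execute the stage sequence exactly once and assemble the report.

    If ``cfg.output_dir`` is set, writes ``report.json`` and a model
    checkpoint there.  Any stage failure is re-raised as
    :class:`StageError` naming the stage.
    """
    seeds = stage_seeds(cfg.seed)
    log.info("stage seeds: %s", seeds)

    stage = "simulate"
    try:
        if isinstance(cfg.source, str):
            dataset = read_dataset(cfg.source)
            log.info("loaded %d windows from %s", len(dataset), cfg.source)
        else:
            sim = SimConfig(window_length=cfg.source.window_length,
                            seed=seeds["simulate"])
            dataset = gen_dataset(sim, cfg.source.n_fall, cfg.source.n_adl)
            log.info("simulated %d windows (L=%d)", len(dataset),
                     sim.window_length)
        n_fall0, n_adl0 = dataset.class_counts

        stage = "augment"
        plan = dataclasses.replace(cfg.plan, seed=seeds["augment"])
        augmented = augment_dataset(dataset, plan)
        n_fall_aug, n_adl_aug = augmented.class_counts
        log.info("augmented %d -> %d windows (%d fall / %d adl)",
                 len(dataset), len(augmented), n_fall_aug, n_adl_aug)

        stage = "split"
        train_set, test_set = split_dataset(augmented, cfg.train_fraction,
                                            seeds["split"])
        log.info("split %d -> %d train / %d test", len(augmented),
                 len(train_set), len(test_set))

        stage = "normalize"
        norm = fit_min_max(train_set)
        train_norm = apply_min_max(train_set, norm)
        test_norm = apply_min_max(test_set, norm)

        stage = "train"
        stack = build_stack(cfg.variant, train_norm.window_length)
        train_cfg = dataclasses.replace(cfg.train, seed=seeds["train"])
        model = train_model(stack, train_norm, train_cfg)
        log.info("trained %s for %d epochs; final train accuracy %.4f",
                 cfg.variant, train_cfg.epochs,
                 model.history[-1]["accuracy"] if model.history else float("nan"))

        stage = "evaluate"
        predictions = predict(model, test_norm)
        metrics = evaluate(test_norm.labels(), [p.label for p in predictions])
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    report = ExperimentReport(
        metrics=metrics,
        bookkeeping={
            "n_original": len(dataset),
            "original_class_counts": {"fall": n_fall0, "adl": n_adl0},
            "n_augmented": len(augmented),
            "augmented_class_counts": {"fall": n_fall_aug, "adl": n_adl_aug},
            "n_train": len(train_set),
            "n_test": len(test_set),
            "normalizer": norm.to_dict(),
        },
        history=model.history,
        seeds={"master": cfg.seed, **seeds},
        config=_config_echo(cfg),
    )

    if cfg.output_dir:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=1))
        save_model(model, outdir / "model")
        log.info("report and checkpoint written to %s", outdir)
    return report


def compare_arms(report_a: ExperimentReport | dict,
                 report_b: ExperimentReport | dict,
                 name_a: str = "A", name_b: str = "B") -> dict:
    """Side-by-side metric table for two experiment arms.

    Returns ``{"rows": [...], "table": str}`` with percentages to two
    decimals and MCC to four.
    """
    fa = (report_a.metrics.formatted() if isinstance(report_a, ExperimentReport)
          else report_a["metrics_formatted"])
    fb = (report_b.metrics.formatted() if isinstance(report_b, ExperimentReport)
          else report_b["metrics_formatted"])
    rows = []
    for key in ("accuracy", "precision", "sensitivity", "specificity", "mcc"):
        rows.append({"metric": key, name_a: fa[key], name_b: fb[key]})
    width = max(len(r["metric"]) for r in rows)
    lines = [f"{'Metric':<{width}}  {name_a:>10}  {name_b:>10}"]
    for r in rows:
        lines.append(f"{r['metric']:<{width}}  {r[name_a]:>10}  {r[name_b]:>10}")
    return {"rows": rows, "table": "\n".join(lines)}


def rotation_robustness_arms(seed: int, n_windows: int = 1000,
                             window_length: int = 25,
                             variant: str = "CNN-1Conv",
                             train_config: TrainConfig | None = None
                             ) -> dict[str, float]:
    """Equal-budget DA vs no-DA comparison on a rotation-perturbed test set.

    Simulates ``n_windows`` balanced windows, splits 80/20, then trains two
    arms with identical update budgets: the no-DA arm on all training
    originals, the DA arm on the first half of them plus one rotated copy
    each.  Both are evaluated on the held-out windows after a random rigid
    rotation — the deployment condition augmentation is meant to cover
    (a device worn at an unseen orientation).  Keeping the two training
    sets the same size isolates the value of rotation augmentation from
    the optimizer's sensitivity to the number of updates.

    Returns ``{"no_da": acc, "da": acc}`` test accuracies.
    """
    from .augmentation import rotate_window, sample_rotation

    sim = SimConfig(window_length=window_length, seed=seed)
    dataset = gen_dataset(sim, n_windows // 2, n_windows - n_windows // 2)
    train_set, test_set = split_dataset(dataset, 0.8, seed=seed)
    rng = np.random.default_rng(seed + 1000)
    test_rot = LabeledDataset(
        [rotate_window(w, sample_rotation(rng)) for w in test_set])

    half = LabeledDataset(train_set.windows[:len(train_set) // 2])
    arms = {
        "no_da": train_set,
        "da": augment_dataset(half, AugmentPlan(1, 1, seed=seed)),
    }
    accuracies: dict[str, float] = {}
    for name, arm_train in arms.items():
        norm = fit_min_max(arm_train)
        cfg = train_config or TrainConfig()
        model = train_model(build_stack(variant, window_length),
                            apply_min_max(arm_train, norm),
                            dataclasses.replace(cfg, seed=seed))
        preds = predict(model, apply_min_max(test_rot, norm))
        correct = sum(p.label == w.label for p, w in zip(preds, test_rot))
        accuracies[name] = correct / len(test_rot)
    return accuracies


# ---------------------------------------------------------------------------
# YAML experiment files

def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment YAML file (fields mirror ExperimentConfig; a
    top-level ``profile: <name>`` key applies a named profile first)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    profile = raw.pop("profile", None)
    cfg = profile_config(profile) if profile else ExperimentConfig()
    if "source" in raw:
        src = raw.pop("source")
        cfg.source = src if isinstance(src, str) else SimulatorSource(**src)
    if "plan" in raw:
        cfg.plan = AugmentPlan(**raw.pop("plan"))
    if "train" in raw:
        cfg.train = TrainConfig(**raw.pop("train"))
    for key in ("train_fraction", "variant", "seed", "output_dir"):
        if key in raw:
            setattr(cfg, key, raw.pop(key))
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return cfg
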