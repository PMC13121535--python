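"""Two-institution continual-learning benchmark.

For each random seed the benchmark generates two synthetic institutions
(A and B, differing in scanner style), trains the network on A, fine-tunes
on a 15-sample draw from B for 10 epochs under each consolidation mode
(none / EWC / vEWC), and measures, on institution A's held-out cases:

* the Task-1 test DSC before and after fine-tuning and their ratio (the
  retention score; 1 = no forgetting),
* the TZ/PZ silhouette of the fused-feature embeddings after fine-tuning,

plus the Task-2 (institution B) test DSC after fine-tuning.  ``both
directions`` runs A->B and B->A.  Aggregates are means over seeds.

Problem sizes are deliberately small (micro model on 32x32 slices, a
handful of phantom cases) so that a multi-seed run completes in minutes on
one CPU core.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom, preprocess
from .metrics import extract_embeddings, silhouette
from .model import ModelConfig, ZoneSegNet
from .training import (FinetuneConfig, TrainConfig, finetune_task,
                       mean_foreground_dice, train_task)

__all__ = ["BenchmarkConfig", "run_direction", "run_benchmark"]


@dataclasses.dataclass(frozen=True)
class BenchmarkConfig:
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    modes: tuple[str, ...] = ("none", "ewc", "vewc")
    n_cases_first: int = 7        # 3 train / 1 val / 3 test
    n_cases_second: int = 4       # 2 fine-tune pool / 2 test
    target_shape: tuple[int, int, int] = (10, 32, 32)
    task1_epochs: int = 30
    finetune_epochs: int = 10
    finetune_samples: int = 15
    finetune_lr: float = 1e-3     # desk-scale fine-tuning rate
    lr: float = 1e-3
    directions: tuple[str, ...] = ("A->B",)
    silhouette_slices: int = 30

    def validate(self) -> None:
        if self.n_cases_first < 5 or self.n_cases_second < 3:
            raise ValueError("too few cases to split train/val/test")


def _institution_pairs(style, seed, n_cases, target_shape):
    cfg = phantom.benchmark_config(style, seed=seed)
    ds = phantom.generate_institution_dataset(cfg, n_cases)
    pc = preprocess.PreprocessConfig(crop_ratio=4.0,
                                     target_shape=target_shape)
    pairs = preprocess.preprocess_dataset(ds, pc)
    # keep slices that contain prostate: background-only slices teach
    # nothing at these tiny sample sizes
    return [p for p in pairs if (p.mask > 0).any()]


def run_direction(config: BenchmarkConfig, seed: int, style_first,
                  style_second, label: str) -> list[dict]:
    """One seed, one direction: train on the first institution, fine-tune
    on the second under every mode.  Returns one record per mode."""
    first = _institution_pairs(style_first, 1000 + seed,
                               config.n_cases_first, config.target_shape)
    second = _institution_pairs(style_second, 2000 + seed,
                                config.n_cases_second, config.target_shape)
    n_tr = config.n_cases_first - 4
    train1 = [p for p in first if p.case_id < n_tr]
    val1 = [p for p in first if p.case_id == n_tr]
    test1 = [p for p in first if p.case_id > n_tr]
    n_pool = config.n_cases_second - 2
    pool2 = [p for p in second if p.case_id < n_pool]
    test2 = [p for p in second if p.case_id >= n_pool]

    input_size = config.target_shape[-1]
    model = ZoneSegNet(ModelConfig.micro(input_size, seed=seed))
    ck1 = train_task(model, train1, val1,
                     TrainConfig(epochs=config.task1_epochs, lr=config.lr,
                                 seed=seed))
    base_dice = mean_foreground_dice(ck1.build_model(), test1)

    records = []
    for mode in config.modes:
        fc = FinetuneConfig(n_samples=config.finetune_samples,
                            epochs=config.finetune_epochs,
                            lr=config.finetune_lr, mode=mode, seed=seed)
        ck2 = finetune_task(ck1, pool2, test2, fc)
        tuned = ck2.build_model()
        dice_first = mean_foreground_dice(tuned, test1)
        dice_second = mean_foreground_dice(tuned, test2)
        emb, lab = extract_embeddings(
            tuned, test1[:config.silhouette_slices])
        records.append({
            "direction": label, "seed": seed, "mode": mode,
            "task1_dice": base_dice,
            "task1_dice_after": dice_first,
            "retention": dice_first / base_dice,
            "task2_dice": dice_second,
            "silhouette": silhouette(emb, lab),
        })
    return records


def run_benchmark(config: BenchmarkConfig = BenchmarkConfig(),
                  out_dir=None) -> pd.DataFrame:
    """Full multi-seed benchmark over the configured directions; returns
    the per-run record table and optionally writes CSV/JSON reports."""
    config.validate()
    records = []
    for seed in config.seeds:
        for direction in config.directions:
            if direction == "A->B":
                styles = (phantom.INSTITUTION_A, phantom.INSTITUTION_B)
            elif direction == "B->A":
                styles = (phantom.INSTITUTION_B, phantom.INSTITUTION_A)
            else:
                raise ValueError(f"unknown direction {direction!r}")
            records.extend(run_direction(config, seed, *styles,
                                         label=direction))
    df = pd.DataFrame(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "benchmark_runs.csv", index=False)
        summary = (df.groupby(["direction", "mode"])
                   [["retention", "task1_dice", "task1_dice_after",
                     "task2_dice", "silhouette"]]
                   .mean().reset_index())
        summary.to_csv(out_dir / "benchmark_summary.csv", index=False)
        manifest = {"config": dataclasses.asdict(config),
                    "n_runs": len(df)}
        (out_dir / "manifest.json").write_text(json.dumps(manifest,
                                                          indent=2))
    return df
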