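"""End-to-end experiment orchestration: data -> train -> sample -> evaluate.

Every run directory is self-describing: resolved config, schedule and model
fingerprints, JSON-lines log, checkpoint, sample PNGs, and report.json.
Reruns with the same seed are bit-identical (single-threaded)."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np

from .conditioning import MaskSpec, Task
from .config import RunConfig, dump_config
from .diffusion import p_sample_loop
from .io_utils import write_image
from .metrics import accutance, psnr
from .nn.training import TrainConfig, train
from .nn.unet import build_reference_unet, save_checkpoint
from .phantoms import PhantomSpec, make_task_dataset
from .schedules import linear_beta_schedule

__all__ = ["run_experiment", "sample_pairs", "evaluate_task"]


def _build_dataset(cfg: RunConfig):
    data, task = cfg.data, cfg.task
    if data["kind"] != "synthetic":
        raise ValueError(f"unsupported data kind {data['kind']!r} (only 'synthetic')")
    spec = PhantomSpec(
        image_size=cfg.train["image_size"],
        style=data["style"],
        n_images=data["n_images"],
        seed=cfg.seed,
        texture_strength=data.get("texture_strength", 0.05),
    )
    mask = MaskSpec(seed=cfg.seed, **{k: v for k, v in task.get("mask", {}).items()})
    return make_task_dataset(
        spec,
        Task(task["name"]),
        sr_factor=task.get("sr_factor", 4.0),
        gauss_sigma=task.get("gauss_sigma", 0.1),
        sp_amount=task.get("sp_amount", 0.05),
        mask_spec=mask,
    )


def sample_pairs(model, pairs, schedule, seed: int, batch_size: int = 16):
    """Ancestral-sample one output per pair; batched for speed,
    deterministic given (pairs, seed, batch_size)."""
    outputs = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        ys = np.stack([p.y for p in chunk])
        xs = p_sample_loop(ys, model, schedule, rng_seed=seed * 1009 + start)
        outputs.extend(list(xs))
    return outputs


def evaluate_task(pairs, samples) -> dict:
    """Reference metrics of samples and of the raw condition, plus
    masked-region MSE for inpainting pairs."""
    rep = {
        "n": len(pairs),
        "psnr_sample": float(np.mean([psnr(p.x0, s) for p, s in zip(pairs, samples)])),
        "psnr_condition": float(np.mean([psnr(p.x0, p.y) for p in pairs])),
        "accutance_sample": float(np.mean([accutance(s) for s in samples])),
        "accutance_x0": float(np.mean([accutance(p.x0) for p in pairs])),
        "accutance_condition": float(np.mean([accutance(p.y) for p in pairs])),
    }
    masked = [p.mask for p in pairs if p.mask is not None]
    if len(masked) == len(pairs) and len(pairs) > 0:
        mse_s, mse_y = [], []
        for p, s in zip(pairs, samples):
            mse_s.append(float(np.mean((s[p.mask] - p.x0[p.mask]) ** 2)))
            mse_y.append(float(np.mean((p.y[p.mask] - p.x0[p.mask]) ** 2)))
        rep["masked_mse_sample"] = float(np.mean(mse_s))
        rep["masked_mse_condition"] = float(np.mean(mse_y))
    return rep


def run_experiment(cfg: RunConfig) -> dict:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "train_log.jsonl"
    try:
        dump_config(cfg, out_dir / "config.yaml")
        schedule = linear_beta_schedule(
            cfg.schedule["T"], cfg.schedule["beta_start"], cfg.schedule["beta_end"],
            sigma_mode=cfg.schedule.get("sigma_mode", "beta"),
        )
        dataset = _build_dataset(cfg)
        model = build_reference_unet(
            image_size=cfg.train["image_size"],
            base_channels=cfg.model["base_channels"],
            channel_mults=tuple(cfg.model["channel_mults"]),
            num_groups=cfg.model["num_groups"],
            in_channels=cfg.model["in_channels"],
            seed=cfg.seed,
        )
        tcfg = TrainConfig(
            iterations=cfg.train["iterations"],
            learning_rate=cfg.train["learning_rate"],
            batch_size=cfg.train["batch_size"],
            image_size=cfg.train["image_size"],
            seed=cfg.seed,
            T=cfg.schedule["T"],
            beta_start=cfg.schedule["beta_start"],
            beta_end=cfg.schedule["beta_end"],
            grad_clip=cfg.train.get("grad_clip", 0.0),
        )
        with open(log_path, "w") as log_fh:
            def log_fn(rec):
                log_fh.write(json.dumps(rec) + "\n")

            model, history = train(model, dataset.train, tcfg, schedule, log_fn=log_fn)
        save_checkpoint(out_dir / "checkpoint.npz", model, schedule.fingerprint(),
                        extra={"train_config": tcfg.to_dict()})
        samples = sample_pairs(model, dataset.test, schedule, seed=cfg.seed)
        samples_dir = out_dir / "samples"
        for i, (pair, s) in enumerate(zip(dataset.test, samples)):
            write_image(samples_dir / f"{i:04d}_sample.png", s)
            write_image(samples_dir / f"{i:04d}_condition.png", pair.y)
            write_image(samples_dir / f"{i:04d}_target.png", pair.x0)
        report = evaluate_task(dataset.test, samples)
        report.update({
            "task": cfg.task["name"],
            "seed": cfg.seed,
            "loss_first_100_mean": float(np.mean(history[:100])),
            "loss_last_100_mean": float(np.mean(history[-100:])),
            "schedule_fingerprint": schedule.fingerprint(),
            "model_fingerprint": model.fingerprint(),
            "python": platform.python_version(),
        })
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
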