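#!/usr/bin/env python
"""Train the anomaly model on normal phantom renders at study scale.

Trains the WGAN-GP (2000 generator steps, latent 32) and the izi_f encoder
(1000 steps) on 200 normal 64x64 phantom renders, then reports convergence
summaries.  Model weights go under scratch/ (binary); the training-loss
summary is written to results/.
"""

import json
import time
from pathlib import Path

import numpy as np

from anoscore.anogan import save_model
from anoscore.experiments import train_toy_model

ROOT = Path(__file__).resolve().parents[1]
MODEL_DIR = ROOT / "scratch" / "toy_model"
OUT = ROOT / "results"
SEED = 0


def main() -> None:
    t0 = time.time()
    model, train_images = train_toy_model(n_normal=200, seed=SEED)
    save_model(model, MODEL_DIR)
    np.save(MODEL_DIR / "train_images.npy", train_images)

    w = np.abs(model.training_log["wasserstein"])
    izi = model.training_log["encoder"]["loss_izi"]
    summary = {
        "seed": SEED,
        "n_train_images": len(train_images),
        "generator_steps": len(w),
        "encoder_steps": len(izi),
        "abs_wasserstein_first50_mean": float(np.mean(w[:50])),
        "abs_wasserstein_last50_mean": float(np.mean(w[-50:])),
        "loss_izi_first10pct_median": float(np.median(izi[:len(izi) // 10])),
        "loss_izi_last10pct_median": float(np.median(izi[-len(izi) // 10:])),
        "train_seconds": round(time.time() - t0, 1),
    }
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "training_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    print(f"model saved to {MODEL_DIR}")


if __name__ == "__main__":
    main()
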