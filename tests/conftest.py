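"""Shared fixtures: rendered scene batches and one small training run.

The training fixture is session-scoped and shared between the training
smoke tests and the segmentation-quality acceptance test so the suite
trains each network exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

import periomet as pm
from periomet.model import TrainConfig, build_model, downscale_mask, preprocess_image, train


def render_batch(master_seed: int, n: int):
    """Render n scenes; returns (params, images, truths) lists."""
    params, images, truths = [], [], []
    for i in range(n):
        p = pm.sample_scene_params(seed=pm.scene_seed(master_seed, i))
        img, truth = pm.render_scene(p)
        params.append(p)
        images.append(img)
        truths.append(truth)
    return params, images, truths


@pytest.fixture(scope="session")
def scene_small():
    """One deterministic scene (params, image, truth)."""
    p = pm.sample_scene_params(seed=pm.scene_seed(42, 0))
    img, truth = pm.render_scene(p)
    return p, img, truth


@pytest.fixture(scope="session")
def scene_batch20():
    """Twenty deterministic scenes for statistical checks."""
    return render_batch(21, 20)


@pytest.fixture(scope="session")
def training_run():
    """Train iris and brow segmenters on 200 scenes (held-out 20+20).

    240 scenes from master seed 0: 200 train, 20 validation, 20 test.
    Width-8 encoder, 30 epochs, the standard recipe (batch 16, Adam,
    lr 0.005 with plateau halving).  Returns arrays, models, histories.
    """
    xs, yi, yb = [], [], []
    for i in range(240):
        p = pm.sample_scene_params(seed=pm.scene_seed(0, i))
        img, truth = pm.render_scene(p)
        xs.append(preprocess_image(img)[0])
        yi.append(downscale_mask(truth.iris_mask)[None].astype(np.float32))
        yb.append(downscale_mask(truth.brow_mask)[None].astype(np.float32))
    x = np.stack(xs)
    y_iris = np.stack(yi)
    y_brow = np.stack(yb)

    out = {"x": x, "y": {"iris": y_iris, "brow": y_brow},
           "slices": {"train": slice(0, 200), "val": slice(200, 220),
                      "test": slice(220, 240)}}
    config = TrainConfig(max_epochs=30, seed=0)
    for task, y in (("iris", y_iris), ("brow", y_brow)):
        model = build_model(width=8, seed=0 if task == "iris" else 1)
        model, history = train(
            model, (x[:200], y[:200]), (x[200:220], y[200:220]), config)
        out[task] = {"model": model, "history": history}
    return out
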