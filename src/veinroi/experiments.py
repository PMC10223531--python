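"""Desk-scale study protocols: training, loss ablation, baseline contrast.

These functions define the package's reference experiments on synthetic
data.  The working resolution is 64 x 64 with a 2.5 px correctness threshold
(the same 3.9 %-of-height criterion as 40 px at 1080 or 5 px at 128); the
dataset is 300 mixed-condition images split 8:2.  Training runs 200 epochs
with batch size 4 — the small batch buys the optimizer enough update steps
(12,000) to converge on a single CPU at this problem size.
"""

from __future__ import annotations

import numpy as np

from . import synthetic as syn
from .baselines import (centroid_distance_keypoints, convexity_defect_keypoints,
                        match_to_labels)
from .evaluation import accuracy_from_distances, confidence_roc
from .network import NetworkConfig
from .training import TrainConfig, evaluate_accuracy, split_dataset, train

IMAGE_SIZE = 64
THRESHOLD_PX = 2.5          # 3.9 % of image height, the 40-px-at-1080 rule
N_IMAGES = 300
EPOCHS = 200
BATCH_SIZE = 4

# baselines run at higher resolution (contours need it); same relative threshold
BASELINE_SIZE = 256
BASELINE_THRESHOLD_PX = 10.0
CLEAN_CONDITION = {"occlusion_prob": 0.0}


def study_configs(seed: int, epochs: int = EPOCHS,
                  use_mse: bool = True, use_js: bool = True,
                  use_euclidean: bool = True):
    net = NetworkConfig(input_size=(IMAGE_SIZE, IMAGE_SIZE), seed=seed)
    cfg = TrainConfig(batch_size=BATCH_SIZE, epochs=epochs, seed=seed,
                      threshold_px=THRESHOLD_PX, eval_every=2,
                      use_mse=use_mse, use_js=use_js,
                      use_euclidean=use_euclidean)
    return net, cfg


def train_study_model(seed: int, n_images: int = N_IMAGES,
                      epochs: int = EPOCHS, **loss_flags):
    """Generate the study dataset, split 8:2 and train; returns
    (model, history, validation samples)."""
    samples = syn.make_samples(n_images, seed=seed,
                               image_size=(IMAGE_SIZE, IMAGE_SIZE))
    tr, va = split_dataset(samples, 0.8, seed=seed)
    net, cfg = study_configs(seed, epochs=epochs, **loss_flags)
    model, hist = train(tr, va, net, cfg)
    return model, hist, va


def loss_ablation(seed: int, n_images: int = 100, epochs: int = 20,
                  n_seeds: int = 3) -> dict[str, list[float]]:
    """Best validation accuracy per loss setting over several seeds at a
    small, equal budget (the supervision-ablation contrast)."""
    settings = {
        "combined": dict(),
        "mse": dict(use_js=False, use_euclidean=False),
        "js": dict(use_mse=False, use_euclidean=False),
        "euclidean": dict(use_mse=False, use_js=False),
    }
    out: dict[str, list[float]] = {k: [] for k in settings}
    for s in range(n_seeds):
        run_seed = seed + 1000 * s
        for name, flags in settings.items():
            _, hist, _ = train_study_model(run_seed, n_images=n_images,
                                           epochs=epochs, **flags)
            out[name].append(hist.best_val_accuracy)
    return out


def _baseline_distances(samples, method):
    dists = []
    for s in samples:
        res = method(s.image)
        if res.ok:
            matched = match_to_labels(res.keypoints, s.keypoints)
            dists.extend(np.linalg.norm(matched - s.keypoints, axis=1))
        else:
            dists.extend([np.inf] * 4)
    return np.asarray(dists)


def baseline_contrast(seed: int, n: int = 100) -> dict[str, float]:
    """Eq.-7 accuracy of both classical methods on clean vs cluttered sets."""
    clean = syn.make_samples(n, seed=seed, image_size=(BASELINE_SIZE,) * 2,
                             background_mode="clean",
                             distribution=CLEAN_CONDITION)
    clutter = syn.make_samples(n, seed=seed + 1,
                               image_size=(BASELINE_SIZE,) * 2,
                               background_mode="clutter")
    out = {}
    for name, fn in (("hull", convexity_defect_keypoints),
                     ("centroid", centroid_distance_keypoints)):
        for cond, samples in (("clean", clean), ("clutter", clutter)):
            d = _baseline_distances(samples, fn)
            out[f"{name}_{cond}"] = accuracy_from_distances(
                d, BASELINE_THRESHOLD_PX)
    return out


def network_condition_accuracy(model, seed: int, background_mode: str,
                               n: int = 100, return_details: bool = False):
    """Trained-detector accuracy on freshly generated images of one
    background condition."""
    dist = CLEAN_CONDITION if background_mode == "clean" else None
    samples = syn.make_samples(n, seed=seed, image_size=(IMAGE_SIZE,) * 2,
                               background_mode=background_mode,
                               distribution=dist)
    return evaluate_accuracy(model, samples, THRESHOLD_PX,
                             return_details=return_details)


def confidence_roc_analysis(model, seed: int, n: int = 100):
    """ROC of heatmap peak confidence vs keypoint correctness on a fresh
    mixed-condition set."""
    samples = syn.make_samples(n, seed=seed, image_size=(IMAGE_SIZE,) * 2)
    _, dists, confs = evaluate_accuracy(model, samples, THRESHOLD_PX,
                                        return_details=True)
    correct = dists < THRESHOLD_PX
    return confidence_roc(confs, correct)
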