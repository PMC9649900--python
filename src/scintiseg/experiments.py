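"""Phantom-scale experiment runners.

These functions reproduce, in miniature on synthetic phantoms, the study
design the method was evaluated with: the label-fraction sweep (does adding
manual labels to the semi-supervised loss improve test DSC?), the
feature-extractor ablation (plain convolutional baseline vs the full
dilated + inception + residual model), and the direct Chan–Vese recovery
check on a two-level image.  Problem sizes are desk-scale: 64x64 images,
200/60 train/test, 20 epochs for the sweep; 120/40 and 12 epochs for the
ablation.
"""

from __future__ import annotations

import numpy as np

from .losses import confusion_counts, fit_membership, metrics
from .network import ConvSpec, RecurrentSegmenter, conv_output_size
from .nn import Tensor
from .nn.autodiff import conv2d
from .phantom import PhantomSpec, generate_dataset
from .pipeline import (TrainConfig, TrainSample, desk_model_config,
                       evaluate_repeated, make_split, run_ablation,
                       train_semisupervised)
from .preprocess import normalize_for_network

__all__ = ["phantom_training_data", "label_fraction_sweep",
           "ablation_experiment", "chanvese_recovery",
           "conv_arithmetic_check"]


def phantom_training_data(n_images: int = 260, image_size: int = 64,
                          seed: int = 7) -> list[TrainSample]:
    """Generate normalized phantom samples ready for training.

    Each image gets its own patient key, so a patient-grouped split with
    train fraction f yields f * n_images training images exactly.
    """
    spec = PhantomSpec.for_size(image_size, n_patients=n_images, seed=seed)
    samples = generate_dataset(spec, n_images)
    return [TrainSample(s.sample_id, normalize_for_network(s.aggregated),
                        s.truth.mask, s.patient_key) for s in samples]


def _train_and_score(data: list[TrainSample], train_fraction: float,
                     label_fraction: float, seed: int, epochs: int,
                     image_size: int) -> float:
    plan = make_split(data, train_fraction=train_fraction,
                      label_fraction=label_fraction, seed=seed)
    model = RecurrentSegmenter(desk_model_config(image_size=image_size,
                                                 seed=seed))
    cfg = TrainConfig(epochs=epochs, batch_size=20, input_size=image_size,
                      label_fraction=label_fraction, seed=seed)
    model, _ = train_semisupervised(model, data, plan, cfg)
    test = [s for s in data if s.sample_id in set(plan.test_ids)]
    return evaluate_repeated(model, test, runs=1).mean["dsc"]


def label_fraction_sweep(fractions=(0.0, 0.1, 0.37, 0.7),
                         seeds=(0, 1, 2, 3, 4), n_train: int = 200,
                         n_test: int = 60, epochs: int = 20,
                         image_size: int = 64, data_seed: int = 7) -> dict:
    """Mean/sd test DSC per label fraction over several training seeds."""
    data = phantom_training_data(n_train + n_test, image_size, seed=data_seed)
    out = {}
    for frac in fractions:
        scores = [_train_and_score(data, n_train / (n_train + n_test), frac,
                                   seed, epochs, image_size)
                  for seed in seeds]
        out[frac] = {"mean": float(np.mean(scores)),
                     "sd": float(np.std(scores)),
                     "scores": [float(s) for s in scores]}
    return out


def ablation_experiment(seeds=(0, 1, 2), n_train: int = 120, n_test: int = 40,
                        epochs: int = 12, image_size: int = 64,
                        label_fraction: float = 0.37, data_seed: int = 7,
                        cases: dict | None = None) -> list[dict]:
    """Feature-extractor ablation on a shared phantom split."""
    if cases is None:
        cases = {
            "1#": dict(use_dilated=False, use_inception=False,
                       use_residual=False),
            "4#": dict(use_dilated=True, use_inception=True,
                       use_residual=True),
        }
    data = phantom_training_data(n_train + n_test, image_size, seed=data_seed)
    plan = make_split(data, train_fraction=n_train / (n_train + n_test),
                      label_fraction=label_fraction, seed=0)
    cfg = TrainConfig(epochs=epochs, batch_size=20, input_size=image_size,
                      label_fraction=label_fraction)
    return run_ablation(data, plan, cfg, cases=cases, seeds=tuple(seeds),
                        image_size=image_size)


def chanvese_recovery(size: int = 64, iters: int = 500,
                      v: float = 0.004) -> float:
    """DSC of direct region-energy descent on a noiseless two-level image."""
    g = np.full((size, size), 0.1)
    h0, h1 = size // 4, 3 * size // 4
    w0, w1 = size // 3, 7 * size // 8
    g[h0:h1, w0:w1] = 0.85
    truth = (g > 0.5).astype(np.uint8)
    m, _ = fit_membership(g, v=v, iters=iters)
    pred = (m > 0.5).astype(np.uint8)
    tp, fp, fn, _ = confusion_counts(pred, truth)
    return metrics(tp, fp, fn).dsc


def conv_arithmetic_check(seed: int = 0) -> tuple[int, int]:
    """Executed convolution output sizes vs the closed-form arithmetic.

    Returns (n_checked, n_agreeing) over a grid of >= 100 (i, k, d, p, s)
    combinations, including the zero-padding case i=10, k=3, d=2 -> o=6.
    """
    rng = np.random.default_rng(seed)
    checked = agree = 0
    combos = [(10, 3, 2, 0, 1)]
    for i in (7, 10, 16, 21, 32):
        for k in (1, 3, 5):
            for d in (1, 2, 3):
                for p in (0, 1, 2):
                    for s in (1, 2):
                        combos.append((i, k, d, p, s))
    for i, k, d, p, s in combos:
        spec = ConvSpec(kernel=k, dilation=d, padding=p, stride=s)
        if i + 2 * p < spec.effective_kernel:
            continue
        x = Tensor(rng.standard_normal((1, 1, i, i)))
        w = Tensor(rng.standard_normal((1, 1, k, k)))
        out = conv2d(x, w, stride=s, dilation=d, padding=p)
        checked += 1
        if out.shape[-2] == out.shape[-1] == conv_output_size(i, spec):
            agree += 1
    return checked, agree
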