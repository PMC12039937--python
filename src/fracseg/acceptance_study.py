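"""The desk-scale end-to-end training study.

Trains the tiny fracture network on single-bone crease/compression
phantoms — an FDM-weighted arm and a uniform-weighted arm per seed, three
seeds — and scores both on held-out phantoms.  Shared by the verification
script and the acceptance test so both report the same numbers.

Study conditions (see docs/methods.md): 40^3 grid at 1.4 mm isotropic
spacing so a 24^3 patch covers the whole bone, 16 training and 4 held-out
bones, 40 epochs, mirror + axis-permutation augmentation, mirror test-time
augmentation at evaluation.
"""

from __future__ import annotations

import os
import tempfile
from typing import Dict, List

import numpy as np
import pandas as pd

from fracseg.metrics import dsc, ldsc
from fracseg.network import (
    AugmentationPolicy,
    NetworkConfig,
    TrainConfig,
    _load_cases,
    predict,
    train,
)
from fracseg.phantom import PhantomSpec, generate_dataset

__all__ = ["run_desk_scale_study", "STUDY_EPOCHS", "STUDY_TRAIN_CASES"]

STUDY_EPOCHS = 40
STUDY_TRAIN_CASES = 16
STUDY_VAL_CASES = 4


def _study_cases(seed: int):
    spec = PhantomSpec(grid_shape=(40, 40, 40), spacing=(1.4, 1.4, 1.4), n_bones=1)
    n_half = STUDY_TRAIN_CASES // 2 + STUDY_VAL_CASES // 2
    with tempfile.TemporaryDirectory() as d:
        m1 = generate_dataset(n_half, spec, seed=seed * 11 + 1,
                              outdir=os.path.join(d, "a"), scenarios="crease")
        m2 = generate_dataset(n_half, spec, seed=seed * 11 + 2,
                              outdir=os.path.join(d, "b"), scenarios="compression")
        cases = _load_cases(m1, "frag") + _load_cases(m2, "frag")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(cases))
    train_cases = [cases[i] for i in idx[:STUDY_TRAIN_CASES]]
    val_cases = [cases[i] for i in idx[STUDY_TRAIN_CASES:
                                       STUDY_TRAIN_CASES + STUDY_VAL_CASES]]
    return train_cases, val_cases


def _evaluate(model, val_cases) -> Dict[str, float]:
    ds, ls = [], []
    for vc in val_cases:
        probs = predict(model, vc["image"], patch_size=(24, 24, 24),
                        tta_mirror=True)
        pred = np.argmax(probs, axis=0)
        gt = vc["labels"].data
        sp = vc["image"].spacing
        ds.append((dsc(pred == 1, gt == 1) + dsc(pred == 2, gt == 2)) / 2)
        ls.append((ldsc(pred == 1, gt == 1, vc["labels"], sp)
                   + ldsc(pred == 2, gt == 2, vc["labels"], sp)) / 2)
    return {"dsc": float(np.mean(ds)), "ldsc": float(np.mean(ls))}


def run_desk_scale_study(seed: int = 1, n_seeds: int = 3,
                         log=None) -> Dict[str, List[float]]:
    """Six trainings; returns per-seed held-out scores for both arms.

    Keys: ``dsc_fdm``, ``ldsc_fdm``, ``dsc_uniform``, ``ldsc_uniform``
    (lists of length ``n_seeds``).
    """
    aug = AugmentationPolicy.identity()
    aug.mirror_axes = (0, 1, 2)
    aug.ortho_rotations = True
    net_cfg = NetworkConfig(n_levels=4, base_channels=8, n_classes=3,
                            patch_size=(24, 24, 24))
    out: Dict[str, List[float]] = {"dsc_fdm": [], "ldsc_fdm": [],
                                   "dsc_uniform": [], "ldsc_uniform": []}
    for s in range(n_seeds):
        study_seed = (seed * 7919 + s * 104729) % (2 ** 31)
        train_cases, val_cases = _study_cases(study_seed)
        for arm, use_fdm in (("fdm", True), ("uniform", False)):
            tc = TrainConfig.tiny(epochs=STUDY_EPOCHS, seed=study_seed)
            tc.augment = True
            tc.foreground_oversample_p = 1.0
            tc.use_fdm = use_fdm
            ck = train(pd.DataFrame(), net_cfg, tc, task="frag",
                       cases=train_cases, augment_policy=aug)
            scores = _evaluate(ck["model"], val_cases)
            out[f"dsc_{arm}"].append(scores["dsc"])
            out[f"ldsc_{arm}"].append(scores["ldsc"])
            if log is not None:
                log(f"  seed {s} ({arm}): held-out DSC {scores['dsc']:.3f} "
                    f"LDSC {scores['ldsc']:.3f}")
    return out
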