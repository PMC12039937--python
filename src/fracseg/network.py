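"""Network construction, augmentation, and training for both stages.

The backbone is a compact numpy 3D UNet (:mod:`fracseg._nn`) with
multi-resolution supervision heads.  Two profiles exist:

``tiny``
    desk-scale settings (small patches, few channels, tens of epochs)
    meant for the synthetic phantoms and for CPU-only runs; this is what
    the test-suite exercises.
``full``
    the full-scale settings (five levels, 2000 epochs, 5-fold CV) for
    clinical data; structurally identical, just bigger.

The fracture network trains with the FDM-weighted deep-supervision loss;
the anatomical networks use the same machinery with uniform weights.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from fracseg._nn import Adam, UNet3D
from fracseg.fdm import DeepSupervisionConfig, multiscale_weights, downsample_labels
from fracseg.io_core import LabelMap, Volume, crop_to_bbox, read_volume, resample
from fracseg.losses import (
    LossConfig,
    TransitionSchedule,
    deep_supervision_loss,
    one_hot,
)

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "AugmentationPolicy",
    "build_unet",
    "augment_sample",
    "sample_patches",
    "train",
    "predict",
    "cascade_predict",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    n_levels: int = 5
    base_channels: int = 32
    n_classes: int = 3
    in_channels: int = 1
    deep_supervision: bool = True
    patch_size: Tuple[int, int, int] = (32, 32, 32)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        f = 2 ** (self.n_levels - 1)
        if any(p % f for p in self.patch_size):
            raise ValueError(f"patch size {self.patch_size} not divisible by 2^{self.n_levels - 1}")

    @classmethod
    def tiny(cls, n_classes: int = 3, in_channels: int = 1) -> "NetworkConfig":
        return cls(n_levels=3, base_channels=8, n_classes=n_classes,
                   in_channels=in_channels, patch_size=(32, 32, 32))


@dataclass
class AugmentationPolicy:
    """Spatial + intensity augmentation ranges (fractions/mm/degrees)."""

    elastic_scale: Tuple[float, float] = (0.8, 1.2)
    translation_mm: float = 20.0
    rotation_deg: float = 30.0
    noise_p: float = 0.15
    blur_sigma: Tuple[float, float] = (0.5, 1.0)
    brightness: Tuple[float, float] = (0.75, 1.25)
    contrast: Tuple[float, float] = (0.75, 1.25)
    gamma: Tuple[float, float] = (0.7, 1.5)
    mirror_axes: Tuple[int, ...] = ()          # fracture net: (0, 1, 2)
    #: random axis permutations (exact 90-degree rotations); only applied
    #: when spacing is isotropic
    ortho_rotations: bool = False
    copies_per_sample: int = 4                 # 4 anatomical / 8 fracture

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(elastic_scale=(1.0, 1.0), translation_mm=0.0, rotation_deg=0.0,
                   noise_p=0.0, blur_sigma=(0.0, 0.0), brightness=(1.0, 1.0),
                   contrast=(1.0, 1.0), gamma=(1.0, 1.0), mirror_axes=(),
                   copies_per_sample=1)

    @classmethod
    def fracture_default(cls) -> "AugmentationPolicy":
        return cls(mirror_axes=(0, 1, 2), copies_per_sample=8)


@dataclass
class TrainConfig:
    lr: float = 1e-4
    lr_decay: float = 0.99          # exponential, per epoch
    batch_size: int = 2
    epochs: int = 2000
    folds: int = 5
    fold: int = 0
    augment: bool = True
    use_fdm: bool = True
    foreground_oversample_p: float = 0.5
    patches_per_case: int = 1
    seed: int = 0
    # loss / schedule block
    lambda_dice: float = 1.0
    lambda_ce: float = 1.0
    lambda_back: float = 0.2
    lambda_fdm: float = 16.0
    tau_begin: float = 0.0
    tau_smooth: float = 1000.0
    epsilon: float = 1e-6
    time_unit: str = "epoch"

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.folds < 1:
            raise ValueError("folds must be >= 1")

    @classmethod
    def tiny(cls, epochs: int = 48, seed: int = 0) -> "TrainConfig":
        # tau_smooth scaled to the shortened run so the uniform->FDM hand-over
        # completes, as in the full-length schedule
        return cls(lr=3e-3, lr_decay=0.98, batch_size=2, epochs=epochs, folds=5,
                   augment=False, tau_begin=0.0, tau_smooth=max(1.0, epochs / 2),
                   seed=seed)


def build_unet(cfg: NetworkConfig, seed: int = 0) -> UNet3D:
    """Instantiate the UNet; raises on patch/level mismatch (see NetworkConfig)."""
    return UNet3D(in_channels=cfg.in_channels, n_classes=cfg.n_classes,
                  n_levels=cfg.n_levels, base_channels=cfg.base_channels,
                  deep_supervision=cfg.deep_supervision, seed=seed)


# ---------------------------------------------------------------------------
# Augmentation


def _affine_params(policy: AugmentationPolicy, spacing, rng):
    ang = np.deg2rad(rng.uniform(-policy.rotation_deg, policy.rotation_deg, size=3))
    scale = rng.uniform(*policy.elastic_scale, size=3) if policy.elastic_scale != (1.0, 1.0) else np.ones(3)
    shift_mm = rng.uniform(-policy.translation_mm, policy.translation_mm, size=3)
    return ang, scale, shift_mm


def _rotation_matrix(ang):
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def augment_sample(
    ct: Volume,
    labels: LabelMap,
    policy: AugmentationPolicy,
    seed: int,
) -> Tuple[Volume, LabelMap]:
    """One random augmented copy: shared spatial transform, image-only intensities.

    The spatial part is a rigid rotation/translation with anisotropic
    scaling (the "elastic distortion" range); the image interpolates
    linearly, labels nearest.  Intensity transforms (blur, brightness,
    contrast, gamma, additive noise with probability ``noise_p``) touch
    only the image.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    img = ct.data.astype(np.float32)
    lab = labels.data
    ang, scale, shift_mm = _affine_params(policy, ct.spacing, rng)
    if np.any(ang != 0) or np.any(scale != 1) or np.any(shift_mm != 0):
        R = _rotation_matrix(ang) * (1.0 / scale)[None, :]
        sp = np.asarray(ct.spacing)
        center = (np.asarray(img.shape) - 1) / 2.0
        # index-space affine: x_src = S^-1 R^-1 S (x_dst - c) + c - shift
        M = np.diag(1.0 / sp) @ np.linalg.inv(R) @ np.diag(sp)
        offset = center - M @ center - shift_mm / sp
        img = ndimage.affine_transform(img, M, offset=offset, order=1, mode="nearest")
        lab = ndimage.affine_transform(lab, M, offset=offset, order=0, mode="constant", cval=0)
    if policy.ortho_rotations and len(set(np.round(ct.spacing, 9))) == 1:
        perm = rng.permutation(3)
        img = np.transpose(img, perm)
        lab = np.transpose(lab, perm)
    for ax in policy.mirror_axes:
        if rng.random() < 0.5:
            img = np.flip(img, axis=ax)
            lab = np.flip(lab, axis=ax)
    if rng.random() < policy.noise_p:
        sigma = rng.uniform(*policy.blur_sigma)
        if sigma > 0:
            img = ndimage.gaussian_filter(img, sigma)
        img = img + rng.normal(0, 0.1 * (img.std() + 1e-6), size=img.shape).astype(np.float32)
    b = rng.uniform(*policy.brightness)
    c = rng.uniform(*policy.contrast)
    if b != 1.0 or c != 1.0:
        mu = img.mean()
        img = (img - mu) * c + mu * b
    g = rng.uniform(*policy.gamma)
    if g != 1.0:
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = ((img - lo) / (hi - lo)) ** g * (hi - lo) + lo
    out_ct = ct.with_data(np.ascontiguousarray(img, dtype=np.float32))
    out_lab = LabelMap(np.ascontiguousarray(lab).astype(np.int32), spacing=labels.spacing,
                       origin=labels.origin, direction=labels.direction, scheme=labels.scheme)
    return out_ct, out_lab


# ---------------------------------------------------------------------------
# Patch sampling


def _pad_to(data: np.ndarray, target: Sequence[int], fill) -> np.ndarray:
    pads = [(0, max(0, t - s)) for s, t in zip(data.shape, target)]
    if any(p[1] for p in pads):
        data = np.pad(data, pads, constant_values=fill)
    return data


def sample_patches(
    ct: Volume,
    labels: LabelMap,
    patch_size: Sequence[int],
    foreground_oversample_p: float = 0.5,
    seed: int = 0,
    n_patches: Optional[int] = None,
    fill_value: float = 0.0,
) -> Iterator[Tuple[np.ndarray, np.ndarray, Tuple[int, int, int]]]:
    """Yield (image patch, label patch, corner) pairs.

    With probability ``foreground_oversample_p`` the patch centre is drawn
    from foreground voxels; otherwise uniformly over the grid.  Inputs
    smaller than the patch are padded with ``fill_value`` (image) / 0
    (labels).
    """
    rng = np.random.default_rng(seed)
    patch = tuple(int(p) for p in patch_size)
    img = _pad_to(ct.data.astype(np.float32), patch, fill_value)
    lab = _pad_to(labels.data, patch, 0)
    shape = img.shape
    fg_idx = np.argwhere(lab > 0)
    count = 0
    while n_patches is None or count < n_patches:
        if foreground_oversample_p > 0 and len(fg_idx) and rng.random() < foreground_oversample_p:
            center = fg_idx[rng.integers(len(fg_idx))]
        else:
            center = np.array([rng.integers(n) for n in shape])
        corner = np.clip(center - np.array(patch) // 2, 0,
                         np.array(shape) - np.array(patch))
        sl = tuple(slice(c, c + p) for c, p in zip(corner, patch))
        yield img[sl], lab[sl], tuple(int(c) for c in corner)
        count += 1


# ---------------------------------------------------------------------------
# Dataset loading


def _load_cases(manifest: pd.DataFrame, task: str) -> List[Dict]:
    """Materialize training samples from a phantom manifest.

    ``frag``: one sample per (case, bone) — the cropped, z-scored bone
    with its fragment labels.  ``anat``: one sample per case — the
    z-scored full CT with anatomical labels.
    """
    from fracseg.io_core import zscore_normalize

    cases = []
    if task == "frag":
        for (cid, frag_path), grp in manifest.groupby(["case", "frag_path"], sort=True):
            row = grp.iloc[0]
            ct = read_volume(row["ct_path"])
            anat = read_volume(row["anat_path"], scheme="anatomical")
            frag = read_volume(frag_path, scheme="fragment")
            region = crop_to_bbox(ct, anat, int(row["bone_label"]), margin_vox=4)
            sl = tuple(slice(lo, hi) for lo, hi in region.bbox)
            frag_crop = LabelMap(frag.data[sl].copy(), spacing=frag.spacing,
                                 scheme="fragment")
            cases.append({"id": f"{cid}_b{int(row['bone_label'])}",
                          "image": region.volume, "labels": frag_crop})
    elif task == "anat":
        for cid, grp in manifest.groupby("case", sort=True):
            row = grp.iloc[0]
            ct = read_volume(row["ct_path"])
            anat = read_volume(row["anat_path"], scheme="anatomical")
            img = zscore_normalize(ct)
            cases.append({"id": cid, "image": img, "labels": anat})
    else:
        raise ValueError(f"unknown task {task!r}")
    return cases


def lowres_cases(cases: List[Dict], factor: float = 2.0) -> List[Dict]:
    """Resample training samples to ``factor``x the spacing for the coarse
    cascade stage (images linearly, labels nearest)."""
    out = []
    for c in cases:
        img = c["image"]
        target = tuple(s * factor for s in img.spacing)
        out.append({**c,
                    "image": resample(img, target, mode="linear"),
                    "labels": resample(c["labels"], target)})
    return out


def assign_folds(case_ids: Sequence[str], folds: int, seed: int) -> Dict[str, int]:
    """Deterministic shuffle-split: each case in exactly one validation fold."""
    rng = np.random.default_rng(seed)
    ids = sorted(set(case_ids))
    order = rng.permutation(len(ids))
    return {ids[order[i]]: i % folds for i in range(len(ids))}


# ---------------------------------------------------------------------------
# Training


def _level_targets(label_patch: np.ndarray, n_levels: int, n_classes: int):
    labs, hots = [], []
    cur = label_patch
    for n in range(n_levels):
        if n > 0:
            cur = downsample_labels(cur)
        labs.append(cur)
        hots.append(one_hot(cur, n_classes))
    return labs, hots


def _level_weights(label_patch: np.ndarray, spacing, cfg_ds: DeepSupervisionConfig,
                   lambda_back: float, use_fdm: bool):
    if not use_fdm:
        out = []
        cur = label_patch
        for n in range(cfg_ds.n_levels):
            if n > 0:
                cur = downsample_labels(cur)
            out.append(np.ones(cur.shape))
        return out
    lm = LabelMap(label_patch.astype(np.int32), spacing=spacing, scheme="fragment")
    if not (lm.data > 0).any():
        return [np.ones(s.shape) for s in _level_targets(label_patch, cfg_ds.n_levels, 2)[0]]
    levels = multiscale_weights(lm, cfg_ds, lambda_back=lambda_back)
    return [wm.W_hat for (_, wm) in levels]


def train(
    manifest: pd.DataFrame,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    task: str = "frag",
    out_dir: Optional[str] = None,
    cases: Optional[List[Dict]] = None,
    augment_policy: Optional[AugmentationPolicy] = None,
    resume: Optional[Dict] = None,
) -> Dict:
    """Train one network; returns a checkpoint dict and writes it if ``out_dir``.

    A "case" is one training sample (a cropped bone for ``frag``, a scene
    for ``anat``).  Per epoch every training case contributes
    ``patches_per_case`` patches; the loss is the FDM-weighted
    deep-supervision loss with the smooth-transition schedule evaluated at
    the current epoch.  The per-epoch mean training loss is logged.
    """
    if cases is None:
        cases = _load_cases(manifest, task)
    if len(cases) == 0:
        raise ValueError("empty dataset")
    if len(cases) < 2 and train_cfg.folds > 1:
        raise ValueError("need at least 2 cases for a cross-validation split")

    fold_of = assign_folds([c["id"] for c in cases], train_cfg.folds, train_cfg.seed)
    train_cases = [c for c in cases if fold_of[c["id"]] != train_cfg.fold] or cases

    model = build_unet(net_cfg, seed=train_cfg.seed)
    opt = Adam(model.params(), lr=train_cfg.lr)
    sched = TransitionSchedule(tau_begin=train_cfg.tau_begin,
                               tau_smooth=train_cfg.tau_smooth,
                               epsilon=train_cfg.epsilon,
                               time_unit=train_cfg.time_unit)
    loss_cfg = LossConfig(lambda_dice=train_cfg.lambda_dice, lambda_ce=train_cfg.lambda_ce)
    ds_cfg = DeepSupervisionConfig(n_levels=model.n_heads, lambda0=train_cfg.lambda_fdm)
    policy = augment_policy
    if policy is None:
        policy = AugmentationPolicy.fracture_default() if task == "frag" else AugmentationPolicy()

    rng = np.random.default_rng(train_cfg.seed)
    log_rows = []
    start_epoch = 0
    if resume is not None:
        model.load_state_dict(resume["model"].state_dict())
        opt.load_state(resume["opt_state"])
        rng.bit_generator.state = resume["rng_state"]
        start_epoch = int(resume["epoch_next"])
        log_rows = resume["log"].to_dict("records")
    patch = net_cfg.patch_size
    for epoch in range(start_epoch, train_cfg.epochs):
        opt.lr = train_cfg.lr * (train_cfg.lr_decay ** epoch)
        order = rng.permutation(len(train_cases))
        epoch_losses = []
        batch: List[Tuple[np.ndarray, np.ndarray]] = []

        def flush(batch):
            if not batch:
                return
            x = np.stack([
                b[0][None] if b[2] is None else np.concatenate([b[0][None], b[2]])
                for b in batch])
            model.zero_grad()
            probs = model.forward(x)
            n_heads = model.n_heads
            total = 0.0
            dprobs = [np.zeros_like(p) for p in probs]
            for bi, (_, lab_patch, _extra) in enumerate(batch):
                labs, hots = _level_targets(lab_patch, n_heads, net_cfg.n_classes)
                whats = _level_weights(lab_patch, (1.0, 1.0, 1.0), ds_cfg,
                                       train_cfg.lambda_back, train_cfg.use_fdm)
                preds = [probs[n][bi] for n in range(n_heads)]
                li, grads = deep_supervision_loss(
                    preds, hots, whats, t=epoch, sched=sched, cfg=loss_cfg,
                    return_grads=True)
                total += li
                for n in range(n_heads):
                    dprobs[n][bi] = grads[n] / len(batch)
            model.backward(dprobs)
            opt.step()
            epoch_losses.append(total / len(batch))

        for ci in order:
            case = train_cases[ci]
            img, lab = case["image"], case["labels"]
            if train_cfg.augment:
                img, lab = augment_sample(img, lab, policy,
                                          seed=int(rng.integers(2**31)))
            # extra input channels (the cascade's coarse one-hot labels):
            # teacher forcing derives them from the (augmented) ground truth,
            # a precomputed array is used as-is (valid with augment off)
            if case.get("extra_from_labels"):
                extra = one_hot(lab.data, net_cfg.in_channels - 1)
            else:
                extra = case.get("extra")
            if extra is not None:
                extra = np.stack([_pad_to(c.astype(np.float32), patch, 0.0)
                                  for c in extra])
            gen = sample_patches(img, lab, patch,
                                 foreground_oversample_p=train_cfg.foreground_oversample_p,
                                 seed=int(rng.integers(2**31)),
                                 n_patches=train_cfg.patches_per_case)
            for xp, lp, corner in gen:
                ep = None
                if extra is not None:
                    sl = tuple(slice(c, c + p) for c, p in zip(corner, patch))
                    ep = extra[(slice(None),) + sl]
                batch.append((xp, lp, ep))
                if len(batch) == train_cfg.batch_size:
                    flush(batch)
                    batch = []
        flush(batch)
        log_rows.append({"epoch": epoch, "loss": float(np.mean(epoch_losses)),
                         "lr": opt.lr})

    log = pd.DataFrame(log_rows)
    ckpt = {
        "model": model,
        "net_cfg": asdict(net_cfg),
        "train_cfg": asdict(train_cfg),
        "task": task,
        "fold_of": fold_of,
        "log": log,
        "opt_state": opt.state(),
        "rng_state": rng.bit_generator.state,
        "epoch_next": train_cfg.epochs,
    }
    if out_dir is not None:
        save_checkpoint(ckpt, out_dir)
    return ckpt


def save_checkpoint(ckpt: Dict, out_dir: str):
    os.makedirs(out_dir, exist_ok=True)
    ckpt["model"].save(os.path.join(out_dir, "model.npz"))
    meta = {k: ckpt[k] for k in ("net_cfg", "train_cfg", "task", "fold_of")}
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    ckpt["log"].to_csv(os.path.join(out_dir, "log.csv"), index=False)


def load_checkpoint(ckpt_dir: str) -> Dict:
    cfg_path = os.path.join(ckpt_dir, "config.json")
    if not os.path.exists(cfg_path):
        raise FileNotFoundError(f"no checkpoint at {ckpt_dir}")
    with open(cfg_path) as fh:
        meta = json.load(fh)
    model = UNet3D.load(os.path.join(ckpt_dir, "model.npz"))
    log_path = os.path.join(ckpt_dir, "log.csv")
    log = pd.read_csv(log_path) if os.path.exists(log_path) else None
    return {"model": model, "log": log, **meta}


# ---------------------------------------------------------------------------
# Inference


def _gaussian_window(patch: Sequence[int]) -> np.ndarray:
    grids = np.meshgrid(*[np.linspace(-1, 1, p) for p in patch], indexing="ij")
    r2 = sum(g ** 2 for g in grids)
    w = np.exp(-2.0 * r2).astype(np.float32)
    return np.maximum(w, 1e-3)


def predict(
    model: UNet3D,
    volume: Volume,
    patch_size: Optional[Sequence[int]] = None,
    overlap: float = 0.5,
    extra_channels: Optional[np.ndarray] = None,
    tta_mirror: bool = False,
) -> np.ndarray:
    """Sliding-window inference; returns (n_classes, *shape) probabilities.

    Windows overlap by ``overlap`` and are blended with a Gaussian
    importance map; volumes smaller than the patch are padded and cropped
    back.  ``extra_channels`` (C-1, *shape) are concatenated to the image
    (the cascade's coarse one-hot labels).  ``tta_mirror`` averages the
    probabilities over all eight mirror combinations (test-time
    augmentation).
    """
    if tta_mirror:
        import itertools

        acc = None
        for flips in itertools.product([False, True], repeat=3):
            axes = tuple(ax for ax, f in enumerate(flips) if f)
            img = np.flip(volume.data, axis=axes) if axes else volume.data
            ec = None
            if extra_channels is not None:
                ch_axes = tuple(a + 1 for a in axes)
                ec = np.flip(extra_channels, axis=ch_axes) if axes else extra_channels
            probs = predict(model, volume.with_data(np.ascontiguousarray(img)),
                            patch_size=patch_size, overlap=overlap,
                            extra_channels=ec, tta_mirror=False)
            if axes:
                probs = np.flip(probs, axis=tuple(a + 1 for a in axes))
            acc = probs if acc is None else acc + probs
        return acc / 8.0
    if patch_size is None:
        f = 2 ** (model.n_levels - 1)
        patch_size = tuple(min(64, int(np.ceil(s / f) * f)) for s in volume.shape)
    patch = tuple(int(p) for p in patch_size)
    img = volume.data.astype(np.float32)
    chans = [img]
    if extra_channels is not None:
        chans += [extra_channels[c].astype(np.float32) for c in range(extra_channels.shape[0])]
    if len(chans) != model.in_channels:
        raise ValueError(f"model expects {model.in_channels} channels, got {len(chans)}")
    x = np.stack(chans)
    shape = img.shape
    padded = tuple(max(s, p) for s, p in zip(shape, patch))
    x = np.stack([_pad_to(c, padded, 0.0) for c in x])
    acc = np.zeros((model.n_classes,) + padded, dtype=np.float32)
    wacc = np.zeros(padded, dtype=np.float32)
    win = _gaussian_window(patch)
    step = [max(1, int(p * (1 - overlap))) for p in patch]
    starts = [sorted(set(list(range(0, ps - p, st)) + [ps - p]))
              for ps, p, st in zip(padded, patch, step)]
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                sl = (slice(i, i + patch[0]), slice(j, j + patch[1]), slice(k, k + patch[2]))
                xin = x[(slice(None),) + sl][None]
                probs = model.forward(xin)[0][0]
                acc[(slice(None),) + sl] += probs * win[None]
                wacc[sl] += win
    probs = acc / wacc[None]
    return probs[(slice(None),) + tuple(slice(0, s) for s in shape)]


def cascade_predict(
    model_lowres: UNet3D,
    model_fullres: UNet3D,
    ct: Volume,
    lowres_factor: float = 2.0,
    patch_size: Optional[Sequence[int]] = None,
    return_probs: bool = False,
):
    """Coarse-to-fine anatomical segmentation.

    Stage 1 segments the CT resampled to ``lowres_factor`` x the native
    spacing; its one-hot labels are upsampled and concatenated
    channel-wise with the full-resolution CT as stage-2 input.
    """
    if model_fullres.in_channels != 1 + model_lowres.n_classes:
        raise ValueError(
            f"stage-2 input channels ({model_fullres.in_channels}) must equal "
            f"1 + stage-1 classes ({model_lowres.n_classes})")
    if model_lowres.n_classes != model_fullres.n_classes:
        raise ValueError("both stages must share the class set")
    low_spacing = tuple(s * lowres_factor for s in ct.spacing)
    ct_low = resample(ct, low_spacing, mode="linear")
    probs_low = predict(model_lowres, ct_low, patch_size=patch_size)
    coarse = np.argmax(probs_low, axis=0).astype(np.int32)
    coarse_lm = LabelMap(coarse, spacing=low_spacing, origin=ct_low.origin,
                         direction=ct_low.direction, scheme="anatomical")
    coarse_full = resample(coarse_lm, ct.spacing, mode="nearest")
    # pad/crop the upsampled coarse map to the exact full-res grid
    cf = np.zeros(ct.shape, dtype=np.int32)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(ct.shape, coarse_full.shape))
    cf[sl] = coarse_full.data[sl]
    onehot = one_hot(cf, model_lowres.n_classes).astype(np.float32)
    probs = predict(model_fullres, ct, patch_size=patch_size, extra_channels=onehot)
    out = np.argmax(probs, axis=0).astype(np.int32)
    labels = LabelMap(out, spacing=ct.spacing, origin=ct.origin,
                      direction=ct.direction, scheme="anatomical")
    if return_probs:
        return labels, probs
    return labels
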