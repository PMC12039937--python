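"""Synthetic fractured-bone CT phantoms with ground-truth labels.

Each scene contains one to three ellipsoidal "bones" (standing in for the
sacrum and the two hipbones) with a bright cortical shell around a darker
trabecular interior, embedded in soft tissue.  Every bone can be broken
into a main fragment and up to two minor fragments by smooth, randomly
oriented cut surfaces.  Four fracture appearances are modelled, matching
what fractured pelves show on CT:

``displaced_gap``
    minor fragments rigidly moved >= 3 mm away: a wide empty space.
``stable_gap``
    fragments separated by a thin (one-voxel) dark gap, no motion.
``crease``
    the cut runs over only 40-80 % of the cross-section; fragments stay
    connected and the fracture shows as a partial dark crease line.
``compression``
    fragments pushed into each other; overlap voxels belong to the main
    fragment and render brighter (density pile-up).

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from fracseg.io_core import LabelMap, Volume, write_volume

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "FracturedBone",
    "SCENARIOS",
    "make_bone_shape",
    "fracture_bone",
    "render_ct",
    "make_scene",
    "generate_dataset",
]

SCENARIOS = ("displaced_gap", "stable_gap", "crease", "compression")

#: anatomical label id per bone index in a scene
_BONE_LABELS = (1, 2, 3)  # sacrum, left hipbone, right hipbone


class GenerationError(RuntimeError):
    """Phantom construction failed (e.g. bones could not be placed)."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic scene.

    Intensity defaults are plausible adult CT values in HU: dense cortical
    bone around 1200, trabecular bone around 300, soft tissue around 40.
    """

    grid_shape: Tuple[int, int, int] = (96, 96, 96)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_bones: int = 3
    #: mean ellipsoid semi-axes in mm; each bone jitters them +-20 %
    semi_axes_mm: Tuple[float, float, float] = (14.0, 11.0, 12.0)
    shell_thickness_mm: float = 2.0
    scenario: str = "stable_gap"
    n_fragments: int = 2
    #: translation range for displaced fragments (mm)
    displacement_mm: Tuple[float, float] = (3.0, 6.0)
    #: translation range pushing fragments together under compression (mm)
    compression_mm: Tuple[float, float] = (1.0, 3.0)
    #: rotation range for displaced fragments (degrees)
    rotation_deg: Tuple[float, float] = (0.0, 8.0)
    #: minor fragment target fraction of the bone volume
    minor_fraction: Tuple[float, float] = (0.15, 0.35)
    cortical_hu: Tuple[float, float] = (1200.0, 100.0)
    trabecular_hu: Tuple[float, float] = (300.0, 80.0)
    soft_tissue_hu: Tuple[float, float] = (40.0, 20.0)
    noise_sd: float = 15.0
    #: minimum retained minor-fragment volume, cm^3
    min_minor_cm3: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if not (1 <= self.n_fragments <= 3):
            raise ValueError("n_fragments must be in 1..3")
        if not (1 <= self.n_bones <= 3):
            raise ValueError("n_bones must be in 1..3")
        if self.shell_thickness_mm >= min(self.semi_axes_mm):
            raise ValueError("shell thickness must be smaller than the smallest semi-axis")
        if min(self.semi_axes_mm) <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass
class FracturedBone:
    """One bone after fracturing: labels, moved cortical shell, truth record."""

    fragments: LabelMap        # fragment scheme: 0 bg, 1 main, 2 minor
    shell: np.ndarray          # bool, cortical voxels after displacement
    instance: np.ndarray       # int, 0 bg, 1 main, 2.. minor instances
    meta: Dict


@dataclass
class PhantomCase:
    """A full scene: CT, anatomical labels, per-bone fragment labels, truth."""

    ct: Volume
    anat: LabelMap
    fragments: Dict[int, LabelMap]   # anatomical label -> fragment LabelMap
    truth_meta: Dict


def _coords_mm(shape, spacing):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij")


def make_bone_shape(
    spec: PhantomSpec,
    bone_index: int = 0,
    center_vox: Optional[Tuple[int, int, int]] = None,
    rng: Optional[np.random.Generator] = None,
) -> LabelMap:
    """Build one ellipsoidal bone: label 1 = trabecular interior, 2 = cortical shell.

    The shell is the set of foreground voxels within ``shell_thickness_mm``
    of the bone surface (by Euclidean distance in mm).
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, 7919, bone_index])
    shape, spacing = spec.grid_shape, spec.spacing
    if center_vox is None:
        center_vox = tuple(n // 2 for n in shape)
    jitter = rng.uniform(0.8, 1.2, size=3)
    axes = np.asarray(spec.semi_axes_mm) * jitter
    if min(axes) <= spec.shell_thickness_mm:
        axes = np.maximum(axes, spec.shell_thickness_mm * 1.5)
    xs, ys, zs = _coords_mm(shape, spacing)
    cx, cy, cz = (c * s for c, s in zip(center_vox, spacing))
    q = ((xs - cx) / axes[0]) ** 2 + ((ys - cy) / axes[1]) ** 2 + ((zs - cz) / axes[2]) ** 2
    fg = q <= 1.0
    if not fg.any():
        raise ValueError("degenerate bone geometry: empty ellipsoid")
    depth = ndimage.distance_transform_edt(fg, sampling=spacing)
    shell = fg & (depth <= spec.shell_thickness_mm)
    data = np.zeros(shape, dtype=np.int32)
    data[fg] = 1
    data[shell] = 2
    lm = LabelMap(data=data, spacing=spacing, scheme="instance")
    return lm


def _smooth_field(coords_mm, extent_mm, rng, amplitude_mm, n_harmonics=3):
    """Low-frequency sinusoidal perturbation used to bend cut surfaces."""
    xs, ys, zs = coords_mm
    g = np.zeros_like(xs)
    for _ in range(n_harmonics):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        freq = rng.uniform(0.5, 1.5)
        phase = rng.uniform(0, 2 * np.pi)
        proj = (xs * d[0] + ys * d[1] + zs * d[2]) / max(extent_mm)
        g += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * freq * proj + phase)
    g *= amplitude_mm / max(1e-9, np.abs(g).max())
    return g


def _shift_mask(mask: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    """Integer-voxel translation of a boolean mask; voxels shifted off-grid vanish."""
    out = np.zeros_like(mask)
    src = []
    dst = []
    for ax, s in enumerate(shift_vox):
        n = mask.shape[ax]
        s = int(s)
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _rotate_mask(mask: np.ndarray, angle_deg: float, axes, center) -> np.ndarray:
    if abs(angle_deg) < 1e-6:
        return mask
    rot = ndimage.rotate(
        mask.astype(np.float32), angle_deg, axes=axes, reshape=False, order=0, mode="constant",
    )
    return rot > 0.5


def fracture_bone(
    bone: LabelMap,
    spec: PhantomSpec,
    rng: Optional[np.random.Generator] = None,
) -> FracturedBone:
    """Partition a bone into main + minor fragments and apply the scenario.

    The cut surface is a plane through the bone, bent by 2-3 low-frequency
    harmonics so the contact fracture surface is irregular rather than flat.
    Returns fragment labels (scheme ``fragment``), the displaced cortical
    shell and a truth record with per-fragment volumes and transforms.
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, 104729])
    fg = bone.data > 0
    if not fg.any():
        raise ValueError("cannot fracture an empty bone")
    spacing = np.asarray(bone.spacing)
    shell0 = bone.data == 2
    vox_cm3 = float(np.prod(spacing)) / 1000.0

    meta: Dict = {
        "scenario": spec.scenario,
        "warning": False,
        "transforms": [],
        "crease_mask": None,
        "overlap_mask": None,
    }

    if spec.n_fragments == 1:
        inst = np.where(fg, 1, 0).astype(np.int32)
        frag = LabelMap(np.where(fg, 1, 0).astype(np.int32), spacing=bone.spacing,
                        origin=bone.origin, direction=bone.direction, scheme="fragment")
        meta["fragment_volumes_cm3"] = [float(fg.sum() * vox_cm3)]
        return FracturedBone(frag, shell0.copy(), inst, meta)

    coords = _coords_mm(fg.shape, spacing)
    extent = [n * s for n, s in zip(fg.shape, spacing)]
    # signed distance to the bent cut plane, in mm
    normal = rng.normal(size=3)
    normal /= np.linalg.norm(normal)
    proj = coords[0] * normal[0] + coords[1] * normal[1] + coords[2] * normal[2]
    frac_target = rng.uniform(*spec.minor_fraction)
    thresh = np.quantile(proj[fg], 1.0 - frac_target)
    bend = _smooth_field(coords, extent, rng, amplitude_mm=2.0)
    signed = proj - thresh + bend

    pieces: List[np.ndarray] = []
    minor1 = fg & (signed > 0)
    main = fg & ~minor1
    min_vox = max(1, int(round(spec.min_minor_cm3 / vox_cm3)))
    if minor1.sum() < min_vox or main.sum() <= minor1.sum():
        meta["warning"] = True
        inst = np.where(fg, 1, 0).astype(np.int32)
        frag = LabelMap(inst.copy(), spacing=bone.spacing, origin=bone.origin,
                        direction=bone.direction, scheme="fragment")
        meta["fragment_volumes_cm3"] = [float(fg.sum() * vox_cm3)]
        return FracturedBone(frag, shell0.copy(), inst, meta)
    pieces.append(minor1)

    if spec.n_fragments == 3:
        normal2 = rng.normal(size=3)
        normal2 /= np.linalg.norm(normal2)
        proj2 = coords[0] * normal2[0] + coords[1] * normal2[1] + coords[2] * normal2[2]
        frac2 = rng.uniform(*spec.minor_fraction) * 0.7
        thresh2 = np.quantile(proj2[main], frac2)
        bend2 = _smooth_field(coords, extent, rng, amplitude_mm=2.0)
        minor2 = main & (proj2 - thresh2 + bend2 < 0)
        if minor2.sum() >= min_vox and (main.sum() - minor2.sum()) > max(minor1.sum(), minor2.sum()):
            main = main & ~minor2
            pieces.append(minor2)
        else:
            meta["warning"] = True

    # --- apply the scenario -------------------------------------------------
    shell = shell0.copy()
    gap_mm = float(min(spacing))
    instance = np.zeros(fg.shape, dtype=np.int32)
    instance[main] = 1

    moved_pieces: List[np.ndarray] = []
    for i, piece in enumerate(pieces):
        if spec.scenario == "stable_gap":
            # carve a one-voxel gap: the minor-side contact layer vanishes
            s26 = np.ones((3, 3, 3), dtype=bool)
            gap = piece & ndimage.binary_dilation(main, structure=s26)
            piece = piece & ~gap
            shell = shell & ~gap
            meta["transforms"].append({"shift_mm": [0.0, 0.0, 0.0], "rot_deg": 0.0})
        elif spec.scenario == "displaced_gap":
            d = rng.uniform(*spec.displacement_mm)
            shift_vox = np.rint(d * normal / spacing).astype(int)
            # ensure at least one voxel of motion
            if np.all(shift_vox == 0):
                shift_vox[np.argmax(np.abs(normal))] = 1 if normal[np.argmax(np.abs(normal))] >= 0 else -1
            ang = rng.uniform(*spec.rotation_deg) * rng.choice([-1.0, 1.0])
            piece_shell = piece & shell0
            piece = _rotate_mask(piece, ang, axes=(0, 1), center=None)
            piece_shell = _rotate_mask(piece_shell, ang, axes=(0, 1), center=None)
            piece = _shift_mask(piece, shift_vox)
            piece_shell = _shift_mask(piece_shell, shift_vox)
            shell = (shell & ~pieces[i]) | piece_shell
            piece = piece & ~main  # displacement never eats the main fragment
            meta["transforms"].append(
                {"shift_mm": list(shift_vox * spacing), "rot_deg": float(ang)}
            )
        elif spec.scenario == "compression":
            d = rng.uniform(*spec.compression_mm)
            shift_vox = np.rint(-d * normal / spacing).astype(int)
            if np.all(shift_vox == 0):
                shift_vox[np.argmax(np.abs(normal))] = -1 if normal[np.argmax(np.abs(normal))] >= 0 else 1
            piece_shell = piece & shell0
            moved = _shift_mask(piece, shift_vox)
            moved_shell = _shift_mask(piece_shell, shift_vox)
            overlap = moved & main
            meta["overlap_mask"] = overlap if meta["overlap_mask"] is None else (meta["overlap_mask"] | overlap)
            piece = moved & ~main  # overlap voxels belong to the central main fragment
            shell = (shell & ~pieces[i]) | (moved_shell & ~main)
            meta["transforms"].append({"shift_mm": list(shift_vox * spacing), "rot_deg": 0.0})
        else:  # crease: fragments stay connected, partial cut only affects rendering
            meta["transforms"].append({"shift_mm": [0.0, 0.0, 0.0], "rot_deg": 0.0})
        moved_pieces.append(piece)

    if spec.scenario == "crease":
        # the visible crease covers 40-80 % of the cut cross-section
        band = fg & (np.abs(signed) <= 0.6 * gap_mm + 1e-9)
        cover = rng.uniform(0.4, 0.8)
        h = _smooth_field(coords, extent, rng, amplitude_mm=1.0, n_harmonics=2)
        if band.any():
            cut_t = np.quantile(h[band], cover)
            meta["crease_mask"] = band & (h <= cut_t)

    # keep each minor a single 26-connected piece: splinters created by
    # displacement trimming merge back into the main fragment (they are
    # crushed slivers, physically part of the central mass)
    s26 = np.ones((3, 3, 3), dtype=bool)
    for i, piece in enumerate(moved_pieces):
        if not piece.any():
            continue
        comps, ncomp = ndimage.label(piece, structure=s26)
        if ncomp > 1:
            sizes = ndimage.sum_labels(np.ones_like(comps), comps,
                                       index=np.arange(1, ncomp + 1))
            largest = int(np.argmax(sizes)) + 1
            splinter = piece & (comps != largest)
            piece = piece & (comps == largest)
            if spec.scenario != "displaced_gap":
                main = main | splinter
            moved_pieces[i] = piece
    instance[main] = 1
    for i, piece in enumerate(moved_pieces):
        instance[piece] = 2 + i
    # a displaced piece may have been clipped away entirely
    kept = [i for i in range(len(moved_pieces)) if (instance == 2 + i).sum() >= min_vox]
    if len(kept) < len(moved_pieces):
        meta["warning"] = True
        relabel = np.zeros_like(instance)
        relabel[instance == 1] = 1
        nxt = 2
        for i in kept:
            relabel[instance == 2 + i] = nxt
            nxt += 1
        instance = relabel

    frag_data = np.where(instance >= 2, 2, instance).astype(np.int32)
    frag = LabelMap(frag_data, spacing=bone.spacing, origin=bone.origin,
                    direction=bone.direction, scheme="fragment")
    shell = shell & (instance > 0)
    meta["fragment_volumes_cm3"] = [
        float((instance == k).sum() * vox_cm3) for k in range(1, instance.max() + 1)
    ]
    return FracturedBone(frag, shell, instance, meta)


def render_ct(
    fragments: LabelMap,
    shell: np.ndarray,
    spec: PhantomSpec,
    rng: Optional[np.random.Generator] = None,
    crease_mask: Optional[np.ndarray] = None,
    overlap_mask: Optional[np.ndarray] = None,
) -> Volume:
    """Render a CT volume from fragment labels and a cortical-shell mask.

    Cortical voxels draw from N(cortical), interiors from N(trabecular),
    background from N(soft tissue); a global Gaussian noise field is added.
    Compression overlap voxels take the maximum of two draws (density
    pile-up); crease voxels are re-rendered as soft tissue (the dark line).
    """
    if fragments.data.shape != shell.shape:
        raise ValueError("fragment labels and shell mask shapes differ")
    if rng is None:
        rng = np.random.default_rng([spec.seed, 15485863])
    shape = fragments.data.shape
    fg = fragments.data > 0
    trab = fg & ~shell
    cm, cs = spec.cortical_hu
    tm, ts = spec.trabecular_hu
    sm, ss = spec.soft_tissue_hu
    ct = rng.normal(sm, ss, size=shape) if ss > 0 else np.full(shape, sm)
    draw_t = rng.normal(tm, ts, size=shape) if ts > 0 else np.full(shape, tm)
    draw_c = rng.normal(cm, cs, size=shape) if cs > 0 else np.full(shape, cm)
    ct[trab] = draw_t[trab]
    ct[fg & shell] = draw_c[fg & shell]
    if overlap_mask is not None and overlap_mask.any():
        second = rng.normal(tm, ts, size=shape) if ts > 0 else np.full(shape, tm)
        ct[overlap_mask] = np.maximum(ct[overlap_mask], second[overlap_mask] + (cm - tm) * 0.2)
    if crease_mask is not None and crease_mask.any():
        dark = rng.normal(sm, ss, size=shape) if ss > 0 else np.full(shape, sm)
        ct[crease_mask] = dark[crease_mask]
    if spec.noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.noise_sd, size=shape)
    return Volume(ct.astype(np.float32), spacing=fragments.spacing,
                  origin=fragments.origin, direction=fragments.direction)


def _cleanup_instance(inst: np.ndarray) -> np.ndarray:
    """Keep every instance a single 26-connected piece and compact ids.

    Splinters beyond an instance's largest component are dropped to
    background; emptied minor ids are removed and the rest renumbered.
    """
    s26 = np.ones((3, 3, 3), dtype=bool)
    out = np.zeros_like(inst)
    nxt = 1
    for k in range(1, int(inst.max()) + 1):
        mask = inst == k
        if not mask.any():
            continue
        comps, ncomp = ndimage.label(mask, structure=s26)
        if ncomp > 1:
            sizes = ndimage.sum_labels(np.ones_like(comps), comps,
                                       index=np.arange(1, ncomp + 1))
            mask = comps == (int(np.argmax(sizes)) + 1)
        out[mask] = nxt
        nxt += 1
    return out


def _bone_centers(spec: PhantomSpec, rng: np.random.Generator):
    """Default scene layout: sacrum posterior-centre, hipbones left/right."""
    nx, ny, nz = spec.grid_shape
    base = [
        (0.50, 0.62, 0.50),  # sacrum
        (0.26, 0.40, 0.50),  # left hipbone
        (0.74, 0.40, 0.50),  # right hipbone
    ]
    centers = []
    for bx, by, bz in base[: spec.n_bones]:
        j = rng.integers(-3, 4, size=3)
        centers.append((int(bx * nx) + int(j[0]), int(by * ny) + int(j[1]), int(bz * nz) + int(j[2])))
    return centers


def make_scene(spec: PhantomSpec) -> PhantomCase:
    """Build a full multi-bone scene: CT + anatomical + per-bone fragment labels.

    Deterministic given ``spec`` (including its seed).  Raises
    :class:`GenerationError` if non-overlapping bone placement fails after
    100 attempts.
    """
    master = np.random.default_rng([spec.seed, 32452843])
    for _attempt in range(100):
        rng = np.random.default_rng(master.integers(0, 2**31))
        centers = _bone_centers(spec, rng)
        bones = []
        ok = True
        occupied = np.zeros(spec.grid_shape, dtype=bool)
        for bi, c in enumerate(centers):
            bone = make_bone_shape(spec, bone_index=bi, center_vox=c, rng=rng)
            bfg = bone.data > 0
            if (occupied & bfg).any() or not bfg.any():
                ok = False
                break
            occupied |= bfg
            bones.append(bone)
        if ok:
            break
    else:
        raise GenerationError("could not place bones without overlap in 100 attempts")

    anat_data = np.zeros(spec.grid_shape, dtype=np.int32)
    frag_maps: Dict[int, LabelMap] = {}
    shell_all = np.zeros(spec.grid_shape, dtype=bool)
    occupied_frag = np.zeros(spec.grid_shape, dtype=bool)
    crease_all = None
    overlap_all = None
    vox_cm3 = float(np.prod(spec.spacing)) / 1000.0
    truth: Dict = {"bones": {}, "scenario": spec.scenario, "seed": spec.seed}
    for bi, bone in enumerate(bones):
        label = _BONE_LABELS[bi]
        fb = fracture_bone(bone, spec, rng=rng)
        inst = fb.instance
        shell = fb.shell
        # a displaced fragment may have collided with an earlier bone;
        # earlier bones keep their voxels, this bone's claim is trimmed
        clash = (inst > 0) & occupied_frag
        if clash.any():
            inst = inst.copy()
            shell = shell & ~clash
            inst[clash] = 0
            inst = _cleanup_instance(inst)
        frag_data = np.where(inst >= 2, 2, inst).astype(np.int32)
        frag = LabelMap(frag_data, spacing=fb.fragments.spacing,
                        origin=fb.fragments.origin,
                        direction=fb.fragments.direction, scheme="fragment")
        occupied_frag |= frag_data > 0
        anat_data[frag_data > 0] = label
        frag_maps[label] = frag
        shell_all |= shell
        if fb.meta["crease_mask"] is not None:
            crease_all = fb.meta["crease_mask"] if crease_all is None else (crease_all | fb.meta["crease_mask"])
        if fb.meta["overlap_mask"] is not None:
            overlap_all = fb.meta["overlap_mask"] if overlap_all is None else (overlap_all | fb.meta["overlap_mask"])
        truth["bones"][label] = {
            "fragment_volumes_cm3": [
                float((inst == k).sum() * vox_cm3)
                for k in range(1, int(inst.max()) + 1)],
            "transforms": fb.meta["transforms"],
            "warning": fb.meta["warning"],
            "instance": inst,
        }

    composite = LabelMap(
        np.where(anat_data > 0,
                 np.maximum.reduce([m.data for m in frag_maps.values()]), 0).astype(np.int32),
        spacing=spec.spacing, scheme="fragment",
    )
    ct = render_ct(composite, shell_all, spec, rng=rng,
                   crease_mask=crease_all, overlap_mask=overlap_all)
    anat = LabelMap(anat_data, spacing=spec.spacing, scheme="anatomical")
    return PhantomCase(ct=ct, anat=anat, fragments=frag_maps, truth_meta=truth)


def generate_dataset(
    n_cases: int,
    spec: PhantomSpec,
    seed: int,
    outdir: str | os.PathLike,
    scenarios: str = "all",
) -> pd.DataFrame:
    """Write ``n_cases`` phantom cases plus a ``manifest.csv`` to ``outdir``.

    With ``scenarios='all'`` the four fracture appearances are cycled so any
    dataset of >= 4 cases covers each at least once.  Case seeds derive
    deterministically from ``seed``.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    rows = []
    scen_list = SCENARIOS if scenarios == "all" else (scenarios,)
    for i in range(n_cases):
        scen = scen_list[i % len(scen_list)]
        case_seed = int((seed * 100003 + i * 7919) % (2**31))
        cspec = replace(spec, scenario=scen, seed=case_seed)
        case = make_scene(cspec)
        cid = f"case_{i:04d}"
        ct_path = os.path.join(outdir, f"{cid}_ct.nii.gz")
        anat_path = os.path.join(outdir, f"{cid}_anat.nii.gz")
        write_volume(case.ct, ct_path)
        write_volume(case.anat, anat_path)
        frag_paths = {}
        for label, fm in case.fragments.items():
            p = os.path.join(outdir, f"{cid}_frag_{label}.nii.gz")
            write_volume(fm, p)
            frag_paths[label] = p
        for label, info in case.truth_meta["bones"].items():
            for k, vol in enumerate(info["fragment_volumes_cm3"], start=1):
                rows.append({
                    "case": cid, "scenario": scen, "seed": case_seed,
                    "bone_label": label, "fragment_instance": k,
                    "volume_cm3": vol,
                    "ct_path": ct_path, "anat_path": anat_path,
                    "frag_path": frag_paths[label],
                })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    from fracseg.io_core import write_label_sidecar

    write_label_sidecar(os.path.join(outdir, "labels_anatomical.json"), "anatomical")
    write_label_sidecar(os.path.join(outdir, "labels_fragment.json"), "fragment")
    return manifest
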