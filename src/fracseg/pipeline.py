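"""The three-step inference chain: anatomy -> per-bone fragments -> instances.

Step 1 segments the sacrum and hipbones with the cascaded anatomical
networks.  Step 2 crops each present bone, z-scores it, and runs the
fracture network to split main from minor fragments.  Step 3 removes the
main fragment, enumerates the now-isolated minor components by connected
component analysis (26-connectivity), drops components below 1 cm^3, and
pastes everything back into a full-grid instance map with globally unique
ids.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from fracseg.io_core import (
    BoneRegion,
    LabelMap,
    Volume,
    crop_to_bbox,
    label_bbox,
    read_volume,
    write_volume,
)
from fracseg.network import cascade_predict, load_checkpoint, predict

__all__ = [
    "CaseResult",
    "segment_anatomy",
    "extract_bones",
    "segment_fragments",
    "postprocess_fragments",
    "assemble",
    "run_pipeline",
]


class ConfigurationError(RuntimeError):
    """Missing or incompatible model files."""


@dataclass
class CaseResult:
    anat: LabelMap
    instances: LabelMap
    per_bone: Dict[int, Dict]
    id_table: pd.DataFrame
    provenance: Dict


def segment_anatomy(
    ct: Volume,
    model_lowres,
    model_fullres,
    patch_size: Optional[Sequence[int]] = None,
    return_probs: bool = False,
):
    """Step 1: cascaded coarse-to-fine anatomical segmentation.

    The input is z-scored internally; the output label map shares the CT
    grid.  With ``return_probs`` the per-class stage-2 probabilities come
    along (used to resolve cross-bone overlaps in assembly).
    """
    from fracseg.io_core import zscore_normalize

    img = zscore_normalize(ct)
    return cascade_predict(model_lowres, model_fullres, img,
                           patch_size=patch_size, return_probs=return_probs)


def extract_bones(ct: Volume, anat: LabelMap, margin_vox: int = 8,
                  fill_hu: float = 0.0) -> List[BoneRegion]:
    """Step 1b: one cropped, z-scored region per anatomical label present."""
    if ct.data.shape != anat.data.shape:
        raise ValueError("CT and anatomical labels must share a grid")
    regions = []
    for label in sorted(int(l) for l in np.unique(anat.data) if l > 0):
        regions.append(crop_to_bbox(ct, anat, label, margin_vox=margin_vox, fill_hu=fill_hu))
    return regions


def segment_fragments(region: BoneRegion, model,
                      patch_size: Optional[Sequence[int]] = None) -> LabelMap:
    """Step 2: main/minor fragment labels over one cropped bone region."""
    if model.in_channels != 1:
        raise ConfigurationError("fracture model must take a single image channel")
    if model.n_classes != 3:
        raise ConfigurationError("fracture model must predict 3 classes (bg/main/minor)")
    probs = predict(model, region.volume, patch_size=patch_size)
    labels = np.argmax(probs, axis=0).astype(np.int32)
    return LabelMap(labels, spacing=region.volume.spacing,
                    origin=region.volume.origin,
                    direction=region.volume.direction, scheme="fragment")


def postprocess_fragments(
    frag: LabelMap,
    spacing: Optional[Sequence[float]] = None,
    min_volume_cm3: float = 1.0,
) -> LabelMap:
    """Step 3 per bone: instance labels with the small-fragment filter.

    The main class stays instance 1 (never removed — it is the reduction
    target).  Minor-class connected components (26-connectivity) become
    instances 2..K in decreasing volume order; components smaller than
    ``min_volume_cm3`` are set to background.  Ids are compacted after the
    filter.
    """
    if frag.scheme != "fragment":
        raise ValueError("postprocess_fragments expects fragment-scheme labels")
    sp = np.asarray(spacing if spacing is not None else frag.spacing, dtype=float)
    vox_cm3 = float(np.prod(sp)) / 1000.0
    out = np.zeros(frag.data.shape, dtype=np.int32)
    out[frag.data == 1] = 1
    minor = frag.data == 2
    struct = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    comps, n = ndimage.label(minor, structure=struct)
    sizes = ndimage.sum_labels(np.ones_like(comps), comps, index=np.arange(1, n + 1))
    order = np.argsort(-sizes)  # decreasing voxel count
    nxt = 2
    for ci in order:
        if sizes[ci] * vox_cm3 < min_volume_cm3:
            continue
        out[comps == ci + 1] = nxt
        nxt += 1
    return LabelMap(out, spacing=frag.spacing, origin=frag.origin,
                    direction=frag.direction, scheme="instance")


def assemble(
    full_shape: Sequence[int],
    per_bone_instances: Dict[int, LabelMap],
    bboxes: Dict[int, Tuple],
    spacing: Sequence[float],
    stage1_probs: Optional[np.ndarray] = None,
) -> Tuple[LabelMap, pd.DataFrame]:
    """Paste per-bone instance maps into one grid with globally unique ids.

    Returns the full-grid instance map and an id table (bone, role, local
    and global id, volume in cm^3).  Voxels claimed by two bones are
    resolved by the higher stage-1 probability when available, otherwise
    by paste order; the overlap count lands in the table attrs.
    """
    full_shape = tuple(int(n) for n in full_shape)
    canvas = np.zeros(full_shape, dtype=np.int32)
    owner = np.zeros(full_shape, dtype=np.int16)
    vox_cm3 = float(np.prod(spacing)) / 1000.0
    rows = []
    next_gid = 1
    overlap_total = 0
    for bone in sorted(per_bone_instances):
        inst = per_bone_instances[bone]
        bbox = bboxes[bone]
        sl = tuple(slice(lo, hi) for lo, hi in bbox)
        local_ids = [int(i) for i in np.unique(inst.data) if i > 0]
        gid_of = {}
        for lid in sorted(local_ids):
            gid_of[lid] = next_gid
            next_gid += 1
        sub_canvas = canvas[sl]
        sub_owner = owner[sl]
        fg = inst.data > 0
        clash = fg & (sub_canvas > 0)
        overlap_total += int(clash.sum())
        take = fg.copy()
        if clash.any() and stage1_probs is not None:
            mine = stage1_probs[bone][sl]
            prev_best = np.zeros_like(mine)
            for other in sorted(per_bone_instances):
                if other == bone:
                    continue
                prev_best = np.where(sub_owner == other, stage1_probs[other][sl], prev_best)
            take[clash] = mine[clash] > prev_best[clash]
        lut = np.zeros(max(local_ids, default=0) + 1, dtype=np.int32)
        for lid, gid in gid_of.items():
            lut[lid] = gid
        sub_canvas[take] = lut[inst.data[take]]
        sub_owner[take] = bone
        canvas[sl] = sub_canvas
        owner[sl] = sub_owner
        for lid, gid in gid_of.items():
            rows.append({
                "bone": bone,
                "role": "main" if lid == 1 else "minor",
                "local_id": lid,
                "instance_id": gid,
                "volume_cm3": float((inst.data == lid).sum() * vox_cm3),
            })
    table = pd.DataFrame(rows)
    table.attrs["overlap_voxels"] = overlap_total
    out = LabelMap(canvas, spacing=tuple(spacing), scheme="instance")
    # recount volumes on the assembled grid (overlap resolution may trim them)
    for i, row in table.iterrows():
        table.at[i, "volume_cm3"] = float((canvas == row["instance_id"]).sum() * vox_cm3)
    return out, table


def instances_from_truth(
    fragments: Dict[int, LabelMap],
    min_volume_cm3: float = 1.0,
) -> Tuple[LabelMap, pd.DataFrame]:
    """Run step 3 directly on ground-truth fragment labels (network bypass)."""
    per_bone = {}
    bboxes = {}
    spacing = None
    shape = None
    for bone, frag in fragments.items():
        spacing = frag.spacing
        shape = frag.data.shape
        per_bone[bone] = postprocess_fragments(frag, min_volume_cm3=min_volume_cm3)
        bboxes[bone] = tuple((0, n) for n in shape)
    return assemble(shape, per_bone, bboxes, spacing)


def run_pipeline(
    ct_path: str,
    model_dir: str,
    out_dir: str,
    min_volume_cm3: float = 1.0,
    keep_crops: bool = False,
    patch_size: Optional[Sequence[int]] = None,
) -> CaseResult:
    """Full chain on one CT: anatomy, fragments, instances, files on disk.

    ``model_dir`` must contain ``anat_lowres/``, ``anat_fullres/`` and
    ``frag/`` checkpoints.  Writes ``anat.nii.gz``, ``instances.nii.gz``,
    ``instances.csv`` and ``provenance.json`` to ``out_dir``.
    """
    t0 = time.time()
    for sub in ("anat_lowres", "anat_fullres", "frag"):
        if not os.path.isdir(os.path.join(model_dir, sub)):
            raise ConfigurationError(f"missing model checkpoint: {os.path.join(model_dir, sub)}")
    ct = read_volume(ct_path)
    m_low = load_checkpoint(os.path.join(model_dir, "anat_lowres"))["model"]
    m_full = load_checkpoint(os.path.join(model_dir, "anat_fullres"))["model"]
    m_frag = load_checkpoint(os.path.join(model_dir, "frag"))["model"]

    timings = {}
    t = time.time()
    anat, anat_probs = segment_anatomy(ct, m_low, m_full, patch_size=patch_size,
                                       return_probs=True)
    timings["anatomy_s"] = time.time() - t

    t = time.time()
    regions = extract_bones(ct, anat)
    per_bone: Dict[int, Dict] = {}
    inst_maps: Dict[int, LabelMap] = {}
    bboxes = {}
    for region in regions:
        frag = segment_fragments(region, m_frag, patch_size=patch_size)
        inst = postprocess_fragments(frag, min_volume_cm3=min_volume_cm3)
        per_bone[region.source_label] = {"fragments": frag, "instances": inst,
                                         "bbox": region.bbox}
        inst_maps[region.source_label] = inst
        bboxes[region.source_label] = region.bbox
    timings["fragments_s"] = time.time() - t

    t = time.time()
    stage1_probs = {bone: anat_probs[bone] for bone in inst_maps}
    instances, table = assemble(ct.shape, inst_maps, bboxes, ct.spacing,
                                stage1_probs=stage1_probs)
    timings["assemble_s"] = time.time() - t

    os.makedirs(out_dir, exist_ok=True)
    write_volume(anat, os.path.join(out_dir, "anat.nii.gz"))
    write_volume(instances, os.path.join(out_dir, "instances.nii.gz"))
    table.to_csv(os.path.join(out_dir, "instances.csv"), index=False)
    if keep_crops:
        for bone, info in per_bone.items():
            write_volume(info["fragments"], os.path.join(out_dir, f"frag_bone{bone}.nii.gz"))
    provenance = {
        "ct_path": os.path.abspath(ct_path),
        "model_dir": os.path.abspath(model_dir),
        "min_volume_cm3": min_volume_cm3,
        "timings_s": timings,
        "total_s": time.time() - t0,
        "n_instances": int(instances.data.max()),
    }
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2)
    return CaseResult(anat=anat, instances=instances, per_bone=per_bone,
                      id_table=table, provenance=provenance)
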