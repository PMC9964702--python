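"""End-to-end orchestration: NIfTI I/O, slice-wise inference, reassembly.

Volumes travel as :class:`~sdsseg.phantom.LabeledVolume`; prediction
runs the network slice by slice on preprocessed inputs, takes the final
head's per-pixel argmax, maps head classes back to BraTS label codes,
stacks the 2D results into a volume and inverts the preprocessing
geometry so the output matches the original scan extents exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time

import nibabel as nib
import numpy as np
from skimage.transform import resize

from .network import NetworkConfig, SegmentationNet
from .phantom import BRATS_LABELS, MODALITY_NAMES, LabeledVolume
from .preprocess import (CropRecord, PreprocessConfig, extract_sample,
                         preprocess_volume, uncrop_labels)
from .supervision import label_codes_from_classes

__version__ = "0.1.0"


def read_volume(modality_paths: list[str], label_path: str | None = None
                ) -> LabeledVolume:
    """Assemble one LabeledVolume from per-modality NIfTI files.

    Channel order follows the order of ``modality_paths`` (the BraTS
    convention is FLAIR, T1, T1ce, T2).  Label values must round to the
    BraTS codes {0, 1, 2, 4} within 1e-6.
    """
    imgs = []
    spacing = None
    shape = None
    for p in modality_paths:
        img = nib.load(p)
        data = np.asarray(img.dataobj, dtype=np.float32)
        if data.ndim != 3:
            raise ValueError(f"{p}: expected a 3D volume, got rank {data.ndim}")
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        if shape is None:
            shape, spacing = data.shape, zooms
        elif data.shape != shape:
            raise ValueError(f"{p}: shape {data.shape} differs from {shape}")
        imgs.append(data)
    intensities = np.stack(imgs, axis=-1)
    if label_path is not None:
        limg = nib.load(label_path)
        raw = np.asarray(limg.dataobj, dtype=np.float64)
        rounded = np.rint(raw)
        if np.abs(raw - rounded).max() > 1e-6:
            raise ValueError(f"{label_path}: label values are not integral")
        labels = rounded.astype(np.int16)
        bad = set(np.unique(labels)) - set(BRATS_LABELS)
        if bad:
            raise ValueError(f"{label_path}: unknown label code(s) {sorted(bad)}")
    else:
        labels = np.zeros(shape, dtype=np.int16)
    return LabeledVolume(intensities, labels, spacing)


def write_volume(vol: LabeledVolume, out_dir: str, stem: str,
                 modalities: bool = True) -> list[str]:
    """Write labels (and optionally per-modality intensities) as NIfTI."""
    os.makedirs(out_dir, exist_ok=True)
    aff = np.diag(list(vol.spacing) + [1.0])
    paths = []
    if modalities:
        for m in range(vol.n_modalities):
            name = MODALITY_NAMES[m] if m < len(MODALITY_NAMES) else f"mod{m}"
            p = os.path.join(out_dir, f"{stem}_{name}.nii.gz")
            nib.save(nib.Nifti1Image(vol.intensities[..., m].astype(np.float32), aff), p)
            paths.append(p)
    p = os.path.join(out_dir, f"{stem}_seg.nii.gz")
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), aff), p)
    paths.append(p)
    return paths


def predict_volume(model: SegmentationNet, vol: LabeledVolume,
                   pre_cfg: PreprocessConfig, batch_size: int = 8,
                   enforce_hierarchy: bool = False) -> np.ndarray:
    """Slice-wise inference reassembled into original volume geometry.

    Only the final head drives predictions.  With ``enforce_hierarchy``
    the nested-region consistency ET <= TC <= WT is imposed on the
    output by intersection (off by default).
    """
    prepped, zrec, crec = preprocess_volume(vol, pre_cfg)
    model.eval()
    Z = prepped.shape[0]
    class_slices = []
    for start in range(0, Z, batch_size):
        idx = range(start, min(start + batch_size, Z))
        samples = [extract_sample(prepped, n, pre_cfg) for n in idx]
        img = np.stack([s.image2d for s in samples])
        patch = np.stack([s.patch3d for s in samples])
        heads = model(img, patch)
        class_slices.append(np.argmax(heads[3].data, axis=1))
    classes = np.concatenate(class_slices, axis=0)  # (Z, H, W) at input_size
    codes = label_codes_from_classes(classes)
    # invert the in-plane resize back to the crop window size
    ch, cw = prepped.shape[1], prepped.shape[2]
    codes = resize(codes.astype(np.float32), (codes.shape[0], ch, cw), order=0,
                   anti_aliasing=False, preserve_range=True).astype(np.int16)
    full = uncrop_labels(codes, crec)
    if enforce_hierarchy:
        full = _enforce_hierarchy(full)
    return full


def _enforce_hierarchy(labels: np.ndarray) -> np.ndarray:
    """Impose ET <= TC <= WT by keeping inner labels only inside outer ones."""
    wt = np.isin(labels, (1, 2, 4))
    tc = np.isin(labels, (1, 4)) & wt
    et = (labels == 4) & tc
    out = np.zeros_like(labels)
    out[wt] = 2
    out[tc] = 1
    out[et] = 4
    return out


# ---------------------------------------------------------------------------
# checkpoints and run manifests
# ---------------------------------------------------------------------------

def _ckpt_path(path: str) -> str:
    return path if path.endswith(".npz") else path + ".npz"


def save_checkpoint(model: SegmentationNet, path: str, net_cfg: NetworkConfig,
                    extra: dict | None = None) -> None:
    path = _ckpt_path(path)
    np.savez(path, **model.state_arrays())
    manifest = {
        "network_config": dataclasses.asdict(net_cfg),
        "config_hash": config_hash(net_cfg),
        "tool_version": __version__,
    }
    manifest.update(extra or {})
    with open(path + ".json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def load_checkpoint(path: str) -> tuple[SegmentationNet, dict]:
    path = _ckpt_path(path)
    with open(path + ".json") as fh:
        manifest = json.load(fh)
    d = dict(manifest["network_config"])
    for key in ("in_plane", "head_classes"):
        d[key] = tuple(d[key])
    cfg = NetworkConfig(**d)
    model = SegmentationNet(cfg)
    with np.load(path) as state:
        model.load_state_arrays({k: state[k] for k in state.files})
    return model, manifest


def config_hash(cfg) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(out_dir: str, command: str, seeds: dict, configs: dict,
                   inputs: list[str], outputs: list[str],
                   crop_records: dict[str, CropRecord] | None = None) -> str:
    """Record everything needed to reproduce a run bit for bit."""
    manifest = {
        "tool_version": __version__,
        "command": command,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seeds": seeds,
        "config_hashes": {k: config_hash(v) for k, v in configs.items()},
        "configs": {k: dataclasses.asdict(v) for k, v in configs.items()},
        "inputs": inputs,
        "outputs": outputs,
    }
    if crop_records:
        manifest["crop_records"] = {k: json.loads(v.to_json())
                                    for k, v in crop_records.items()}
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "run_manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
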