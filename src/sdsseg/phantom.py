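"""Synthetic BraTS-like labeled volumes ("phantoms").

A phantom is a brain-shaped ellipsoid of elevated intensity in a zero
background, containing three nested tumor ellipsoids labeled with the
BraTS convention: 2 = peritumoral edema, 1 = necrotic/non-enhancing
core, 4 = GD-enhancing tumor (0 = everything else).  The nested regions
give the hierarchical evaluation targets

    WT (whole tumor)     = labels {1, 2, 4}
    TC (tumor core)      = labels {1, 4}
    ET (enhancing tumor) = label  {4}

with ET <= TC <= WT guaranteed by construction.  Each modality draws its
per-region mean intensity from ``PhantomSpec.region_means`` and adds
i.i.d. Gaussian noise, so regions are statistically separable but not
trivially so.  Identical spec (including seed) always yields an
identical volume.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

BRATS_LABELS = (0, 1, 2, 4)
REGIONS = ("background", "brain", "edema", "core", "enhancing")

#: Default per-region mean intensities for the four BraTS modalities
#: (FLAIR, T1, T1ce, T2).  Chosen to mimic the qualitative contrast of
#: real scans: edema bright on FLAIR/T2, enhancing rim bright on T1ce,
#: core dark on T1.
DEFAULT_REGION_MEANS: dict[str, tuple[float, ...]] = {
    "background": (0.0, 0.0, 0.0, 0.0),
    "brain": (0.30, 0.40, 0.35, 0.30),
    "edema": (0.75, 0.35, 0.40, 0.70),
    "core": (0.50, 0.20, 0.30, 0.50),
    "enhancing": (0.60, 0.55, 0.90, 0.55),
}

MODALITY_NAMES = ("flair", "t1", "t1ce", "t2")


class PhantomSpecError(ValueError):
    """Raised when a PhantomSpec violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic labeled volume.

    Fractional semi-axes are expressed as fractions of the half-extent
    of the volume along each axis, so ``brain_axes=(0.8, 0.8, 0.8)`` in
    a 32x64x64 volume gives a brain ellipsoid with semi-axes
    (12.8, 25.6, 25.6) voxels.
    """

    shape: tuple[int, int, int] = (20, 64, 64)
    n_modalities: int = 4
    brain_axes: tuple[float, float, float] = (0.85, 0.80, 0.80)
    tumor_axes: tuple[float, float, float] = (0.45, 0.40, 0.40)
    tc_scale: float = 0.65
    et_scale: float = 0.40
    region_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MEANS))
    noise_sigma: float = 0.04
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise PhantomSpecError(f"shape entries must be >= 8, got {self.shape}")
        if self.n_modalities < 1:
            raise PhantomSpecError("n_modalities must be >= 1")
        if not (0.0 < self.et_scale < self.tc_scale < 1.0):
            raise PhantomSpecError(
                f"need 0 < et_scale < tc_scale < 1 for strict nesting, "
                f"got et_scale={self.et_scale}, tc_scale={self.tc_scale}")
        for name, axes in (("brain_axes", self.brain_axes), ("tumor_axes", self.tumor_axes)):
            if any(not (0.0 < a <= 1.0) for a in axes):
                raise PhantomSpecError(f"{name} must lie in (0, 1], got {axes}")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be non-negative")
        for region in REGIONS:
            if region not in self.region_means:
                raise PhantomSpecError(f"region_means missing entry for '{region}'")
            if len(self.region_means[region]) < self.n_modalities:
                raise PhantomSpecError(
                    f"region_means['{region}'] has fewer entries than n_modalities")


@dataclass
class LabeledVolume:
    """Multi-channel intensity volume plus BraTS-coded integer labels."""

    intensities: np.ndarray  # (Z, Y, X, M) float
    labels: np.ndarray       # (Z, Y, X) int, codes {0, 1, 2, 4}
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        self.labels = np.asarray(self.labels)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be rank-4 (Z, Y, X, modality)")
        if self.intensities.shape[:3] != self.labels.shape:
            raise ValueError(
                f"intensities {self.intensities.shape[:3]} and labels "
                f"{self.labels.shape} disagree on (Z, Y, X) extents")
        bad = set(np.unique(self.labels)) - set(BRATS_LABELS)
        if bad:
            raise ValueError(f"labels contain unknown codes {sorted(bad)}; "
                             f"allowed: {BRATS_LABELS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_modalities(self) -> int:
        return self.intensities.shape[3]


@dataclass
class RegionMasks:
    """Binary masks for the three nested BraTS evaluation regions."""

    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Generate one labeled volume from ``spec`` (deterministic in seed).

    Tumor ellipsoids are concentric up to a small random center jitter.
    The jitter of each nested ellipsoid is bounded in the parent's
    normalized coordinates by (1 - scale), which guarantees strict
    geometric nesting ET < TC < WT.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    half = np.array(shape, dtype=np.float64) / 2.0
    center = half - 0.5

    brain_ax = np.array(spec.brain_axes) * half
    brain = _ellipsoid_mask(shape, center, brain_ax)

    # WT center jittered inside the brain so that WT stays within it.
    wt_ax = np.array(spec.tumor_axes) * half
    max_shift = np.maximum(brain_ax - wt_ax, 0.0)
    wt_center = center + rng.uniform(-0.5, 0.5, size=3) * max_shift
    wt = _ellipsoid_mask(shape, wt_center, wt_ax) & brain

    def _nested(parent_center, parent_ax, scale):
        ax = parent_ax * scale
        # shift bounded in parent-normalized coords: |A^-1 dc| <= 1 - scale
        u = rng.uniform(-1.0, 1.0, size=3)
        norm = np.linalg.norm(u)
        if norm > 0:
            u = u / norm
        r = rng.uniform(0.0, 0.9 * (1.0 - scale))
        return parent_center + u * r * parent_ax, ax

    tc_center, tc_ax = _nested(wt_center, wt_ax, spec.tc_scale)
    tc = _ellipsoid_mask(shape, tc_center, tc_ax) & wt
    et_center, et_ax = _nested(tc_center, tc_ax, spec.et_scale / spec.tc_scale)
    et = _ellipsoid_mask(shape, et_center, et_ax) & tc

    labels = np.zeros(shape, dtype=np.int16)
    labels[wt] = 2       # edema
    labels[tc] = 1       # necrotic / non-enhancing core
    labels[et] = 4       # enhancing

    means = {r: np.asarray(spec.region_means[r][:spec.n_modalities], dtype=np.float64)
             for r in REGIONS}
    region_of = np.zeros(shape, dtype=np.int8)          # index into REGIONS
    region_of[brain] = 1
    region_of[wt] = 2
    region_of[tc] = 3
    region_of[et] = 4
    mean_table = np.stack([means[r] for r in REGIONS])  # (5, M)
    intensities = mean_table[region_of]                 # (Z, Y, X, M)
    if spec.noise_sigma > 0:
        intensities = intensities + rng.normal(
            0.0, spec.noise_sigma, size=intensities.shape)
    return LabeledVolume(intensities.astype(np.float32), labels, spec.spacing)


def derive_region_masks(labels: np.ndarray) -> RegionMasks:
    """Map BraTS label codes to the nested WT/TC/ET masks."""
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - set(BRATS_LABELS)
    if bad:
        raise ValueError(f"unknown label code(s) {sorted(bad)}; allowed: {BRATS_LABELS}")
    wt = np.isin(labels, (1, 2, 4))
    tc = np.isin(labels, (1, 4))
    et = labels == 4
    return RegionMasks(wt=wt, tc=tc, et=et)


# ---------------------------------------------------------------------------
# NIfTI export (BraTS per-modality file layout)
# ---------------------------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_phantom(vol: LabeledVolume, out_dir: str, stem: str = "phantom") -> list[str]:
    """Write one NIfTI file per modality plus an integer label file."""
    os.makedirs(out_dir, exist_ok=True)
    aff = _affine(vol.spacing)
    paths = []
    for m in range(vol.n_modalities):
        name = MODALITY_NAMES[m] if m < len(MODALITY_NAMES) else f"mod{m}"
        p = os.path.join(out_dir, f"{stem}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(vol.intensities[..., m].astype(np.float32), aff), p)
        paths.append(p)
    p = os.path.join(out_dir, f"{stem}_seg.nii.gz")
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), aff), p)
    paths.append(p)
    return paths


def generate_cohort(n: int, base_seed: int = 0, **overrides) -> list[LabeledVolume]:
    """Generate ``n`` phantoms with varied geometry, seeded from ``base_seed``."""
    rng = np.random.default_rng(base_seed)
    vols = []
    for i in range(n):
        seed = int(rng.integers(0, 2**31 - 1))
        geo = np.random.default_rng(seed)
        spec = PhantomSpec(
            tumor_axes=tuple(geo.uniform(0.30, 0.55, size=3).round(3)),
            tc_scale=float(geo.uniform(0.55, 0.75)),
            et_scale=float(geo.uniform(0.30, 0.50)),
            seed=seed,
            **overrides,
        )
        vols.append(generate_phantom(spec))
    return vols
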