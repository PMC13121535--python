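"""Volume preprocessing: adaptive centre crop, resize, intensity
normalization, 3-D -> 2-D slicing and lossless flip/rotation augmentation.

The crop window is adaptive to the input size: a margin of ``floor(dim/r)``
voxels is removed from each in-plane side, with ``r`` the crop ratio
(default 4, so a 320x320 slice becomes 160x160).  Images are resized with
(tri)linear interpolation, label masks with nearest-neighbour so the class
set {0, 1, 2} is preserved.  Intensities are min-max mapped per volume onto
[0, 255]; a constant volume maps to all zeros.  Augmentation doubles the
sample count: each slice keeps its original plus one randomly chosen
lossless transform (horizontal/vertical flip or right-angle rotation).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .phantom import LabelVolume, Volume

__all__ = [
    "PreprocessConfig", "SlicePair", "adaptive_center_crop",
    "resize_to_target", "normalize_intensity", "slice_cases", "augment",
    "preprocess_dataset",
]

_FULL_TRANSFORMS = ("hflip", "vflip", "rot90", "rot180", "rot270")
_FLIP_TRANSFORMS = ("hflip", "vflip")


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    crop_ratio: float = 4.0
    target_shape: tuple[int, int, int] = (20, 128, 128)
    intensity_range: tuple[float, float] = (0.0, 255.0)
    augment: bool = False
    conservative_augment: bool = False  # flips only (few-shot fine-tuning)

    def validate(self) -> None:
        if self.crop_ratio <= 2:
            raise ValueError("crop_ratio must exceed 2 for a non-empty window")
        if not all(n > 0 for n in self.target_shape):
            raise ValueError("target_shape must be positive")


@dataclasses.dataclass
class SlicePair:
    """One 2-D training sample with provenance back to its volume."""
    image: np.ndarray                    # (H, W) float, [0, 255]
    mask: np.ndarray                     # (H, W) int, {0, 1, 2}
    case_id: int
    slice_index: int
    augmented: bool = False

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image/mask shape mismatch")


def adaptive_center_crop(volume: Volume, labels: LabelVolume,
                         crop_ratio: float = 4.0
                         ) -> tuple[Volume, LabelVolume]:
    """Symmetric in-plane crop with per-side margin floor(dim/ratio)."""
    if crop_ratio <= 2:
        raise ValueError("crop_ratio must exceed 2")
    _, H, W = volume.voxels.shape
    mh, mw = int(H // crop_ratio), int(W // crop_ratio)
    if H - 2 * mh <= 0 or W - 2 * mw <= 0:
        raise ValueError("crop window is empty")
    sl = (slice(None), slice(mh, H - mh), slice(mw, W - mw))
    return (Volume(volume.voxels[sl].copy(), volume.spacing),
            LabelVolume(labels.labels[sl].copy()))


def _resample_coords(in_shape, out_shape):
    """Pixel-centre aligned source coordinates for each output axis."""
    return np.meshgrid(
        *(((np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5)
          for n_in, n_out in zip(in_shape, out_shape)),
        indexing="ij")


def resize_to_target(volume: Volume, labels: LabelVolume,
                     target_shape: tuple[int, int, int] = (20, 128, 128)
                     ) -> tuple[Volume, LabelVolume]:
    """Linear resampling for the image, nearest-neighbour for the mask,
    both on the same pixel-centre aligned coordinate grid."""
    in_shape = volume.voxels.shape
    if tuple(in_shape) == tuple(target_shape):
        return (Volume(volume.voxels.copy(), volume.spacing),
                LabelVolume(labels.labels.copy()))
    coords = np.stack(_resample_coords(in_shape, target_shape))
    img = ndimage.map_coordinates(volume.voxels, coords, order=1,
                                  mode="nearest")
    lab = ndimage.map_coordinates(labels.labels, coords, order=0,
                                  mode="nearest")
    new_spacing = tuple(s * n_in / n_out for s, n_in, n_out in
                        zip(volume.spacing, in_shape, target_shape))
    return Volume(img, new_spacing), LabelVolume(lab.astype(labels.labels.dtype))


def normalize_intensity(volume: Volume,
                        out_range: tuple[float, float] = (0.0, 255.0)
                        ) -> Volume:
    """Affine per-volume min-max normalization; constant volumes map to the
    range minimum (zeros by default)."""
    v = volume.voxels
    lo, hi = float(v.min()), float(v.max())
    a, b = out_range
    if hi == lo:
        return Volume(np.full_like(v, a), volume.spacing)
    return Volume(a + (v - lo) * (b - a) / (hi - lo), volume.spacing)


def slice_cases(dataset: list[tuple[Volume, LabelVolume]]
                ) -> list[SlicePair]:
    """Split each 3-D case into its axial 2-D slices, in order."""
    pairs = []
    for case_id, (vol, lab) in enumerate(dataset):
        for k in range(vol.voxels.shape[0]):
            pairs.append(SlicePair(image=vol.voxels[k].copy(),
                                   mask=lab.labels[k].copy(),
                                   case_id=case_id, slice_index=k))
    return pairs


def _apply_transform(arr: np.ndarray, name: str) -> np.ndarray:
    if name == "hflip":
        return arr[:, ::-1].copy()
    if name == "vflip":
        return arr[::-1, :].copy()
    if name == "rot90":
        return np.rot90(arr, 1).copy()
    if name == "rot180":
        return np.rot90(arr, 2).copy()
    if name == "rot270":
        return np.rot90(arr, 3).copy()
    raise ValueError(f"unknown transform {name!r}")


def augment(pairs: list[SlicePair], seed: int = 0,
            conservative: bool = False) -> list[SlicePair]:
    """Return originals plus one lossless transformed copy each (doubling
    the sample count).  ``conservative`` restricts to flips, as used for
    small fine-tuning sets."""
    rng = np.random.default_rng(seed)
    choices = _FLIP_TRANSFORMS if conservative else _FULL_TRANSFORMS
    out = list(pairs)
    for p in pairs:
        t = choices[rng.integers(len(choices))]
        out.append(SlicePair(image=_apply_transform(p.image, t),
                             mask=_apply_transform(p.mask, t),
                             case_id=p.case_id, slice_index=p.slice_index,
                             augmented=True))
    return out


def preprocess_dataset(dataset: list[tuple[Volume, LabelVolume]],
                       config: PreprocessConfig = PreprocessConfig(),
                       seed: int = 0) -> list[SlicePair]:
    """Full chain: crop -> resize -> normalize -> slice (-> augment)."""
    config.validate()
    processed = []
    for vol, lab in dataset:
        vol, lab = adaptive_center_crop(vol, lab, config.crop_ratio)
        vol, lab = resize_to_target(vol, lab, config.target_shape)
        vol = normalize_intensity(vol, config.intensity_range)
        processed.append((vol, lab))
    pairs = slice_cases(processed)
    if config.augment:
        pairs = augment(pairs, seed=seed,
                        conservative=config.conservative_augment)
    return pairs
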