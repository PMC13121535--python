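"""Synthetic two-institution prostate phantom generator.

Real prostate-zone segmentation data (T2-weighted MRI with expert transition
zone / peripheral zone delineations) is proprietary or large; this module
emulates its essential structure at desk scale so the full pipeline —
preprocessing, training, continual fine-tuning, evaluation — can be
exercised end to end.

Each case is an ellipsoidal "prostate" near the grid centre: an inner
ellipsoid is the transition zone (label 1), the surrounding rim the
peripheral zone (label 2), everything else background (label 0).
Institutions differ in an :class:`InstitutionStyle` — class intensity means,
additive Gaussian noise level, and the amplitude of a smooth multiplicative
bias field (scanner shading).  Different styles are what create the
cross-institution domain shift that drives catastrophic forgetting.

Default geometry is 20x320x320 voxels so the adaptive-crop/resize
preprocessing path is exercised at the scale segmentation pipelines expect;
``benchmark_config`` returns a much smaller grid used by the training
benchmarks.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "InstitutionStyle", "PhantomConfig", "Volume", "LabelVolume",
    "generate_case", "generate_institution_dataset",
    "write_volume", "read_volume",
    "INSTITUTION_A", "INSTITUTION_B", "default_config", "benchmark_config",
]


@dataclasses.dataclass(frozen=True)
class InstitutionStyle:
    """Scanner/protocol fingerprint of one institution.

    Intensity means live on a nominal 0-255 scale; ``noise_sd`` is the
    additive Gaussian sigma, ``bias_amplitude`` the relative amplitude of the
    multiplicative low-order polynomial shading field.
    """
    contrast_tz: float
    contrast_pz: float
    background_level: float
    noise_sd: float
    bias_amplitude: float

    def validate(self) -> None:
        for v in (self.contrast_tz, self.contrast_pz, self.background_level):
            if not (0.0 <= v <= 255.0):
                raise ValueError("intensity means must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (20, 320, 320)
    prostate_axes: tuple[float, float, float] = (7.0, 60.0, 60.0)
    tz_fraction: float = 0.6
    institution_style: InstitutionStyle = dataclasses.field(
        default_factory=lambda: INSTITUTION_A)
    center_jitter: tuple[float, float, float] = (1.0, 8.0, 8.0)
    axes_jitter: float = 0.10  # relative
    seed: int = 0

    def validate(self) -> None:
        if not all(n > 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be strictly positive")
        if any(a <= 0 for a in self.prostate_axes):
            raise ValueError("prostate ellipsoid axes must be > 0")
        if not (0.0 < self.tz_fraction < 1.0):
            raise ValueError("tz_fraction must lie in (0, 1)")
        if self.axes_jitter < 0 or any(j < 0 for j in self.center_jitter):
            raise ValueError("jitter ranges must be >= 0")
        self.institution_style.validate()


# Style defaults are free parameters (no real cohort is emulated
# quantitatively).  A is a bright-PZ T2-like protocol; B is a brighter,
# noisier scanner whose TZ/PZ contrast ordering is reversed — a deliberately
# adversarial shift so that naive fine-tuning on B measurably damages what
# was learned on A.
INSTITUTION_A = InstitutionStyle(contrast_tz=105.0, contrast_pz=185.0,
                                 background_level=45.0, noise_sd=6.0,
                                 bias_amplitude=0.10)
INSTITUTION_B = InstitutionStyle(contrast_tz=175.0, contrast_pz=120.0,
                                 background_level=95.0, noise_sd=10.0,
                                 bias_amplitude=0.20)


@dataclasses.dataclass
class Volume:
    """A 3-D grayscale scan: ``voxels`` is (depth, height, width)."""
    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("Volume must be rank 3")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("Volume contains non-finite values")


@dataclasses.dataclass
class LabelVolume:
    """Zone mask aligned to a Volume: 0 background, 1 TZ, 2 PZ."""
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume must be rank 3")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        bad = set(np.unique(self.labels)) - {0, 1, 2}
        if bad:
            raise ValueError(f"labels outside {{0,1,2}}: {sorted(bad)}")


def default_config(style: InstitutionStyle = INSTITUTION_A,
                   seed: int = 0) -> PhantomConfig:
    return PhantomConfig(institution_style=style, seed=seed)


def benchmark_config(style: InstitutionStyle = INSTITUTION_A,
                     seed: int = 0) -> PhantomConfig:
    """Small grid used by the CPU training benchmarks (10x96x96 native,
    cropped and resized to 10x32x32 downstream)."""
    return PhantomConfig(grid_shape=(10, 96, 96),
                         prostate_axes=(3.6, 19.0, 19.0),
                         tz_fraction=0.6,
                         institution_style=style,
                         center_jitter=(0.5, 3.0, 3.0),
                         axes_jitter=0.10,
                         seed=seed)


def ellipsoid_mask(grid_shape, center, axes) -> np.ndarray:
    """Voxel-centre membership test for an axis-aligned ellipsoid."""
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in grid_shape),
                             indexing="ij")
    q = ((zz - center[0]) / axes[0]) ** 2 \
        + ((yy - center[1]) / axes[1]) ** 2 \
        + ((xx - center[2]) / axes[2]) ** 2
    return q <= 1.0


def _bias_field(grid_shape, amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """1 + amplitude * (low-order polynomial in normalized coordinates),
    mimicking smooth scanner shading."""
    if amplitude == 0:
        return np.ones(grid_shape)
    zn, yn, xn = np.meshgrid(
        *(np.linspace(-1.0, 1.0, n) for n in grid_shape), indexing="ij")
    c = rng.uniform(-1.0, 1.0, size=6)
    poly = (c[0] * zn + c[1] * yn + c[2] * xn
            + c[3] * yn * xn + c[4] * yn ** 2 + c[5] * xn ** 2)
    m = np.max(np.abs(poly))
    if m > 0:
        poly = poly / m
    return 1.0 + amplitude * poly


def generate_case(config: PhantomConfig,
                  case_seed: int) -> tuple[Volume, LabelVolume]:
    """Deterministically synthesize one (scan, zone-mask) pair."""
    config.validate()
    rng = np.random.default_rng(case_seed)
    shape = config.grid_shape
    center = np.array([(n - 1) / 2.0 for n in shape])
    center = center + rng.uniform(-1.0, 1.0, 3) * np.asarray(
        config.center_jitter)
    axes = np.asarray(config.prostate_axes, dtype=float)
    axes = axes * (1.0 + rng.uniform(-1.0, 1.0, 3) * config.axes_jitter)
    if np.any(axes <= 0):
        raise ValueError("jittered ellipsoid axes degenerate (<= 0)")

    prostate = ellipsoid_mask(shape, center, axes)
    tz = ellipsoid_mask(shape, center, axes * config.tz_fraction)
    labels = np.zeros(shape, dtype=np.int16)
    labels[prostate] = 2          # peripheral rim
    labels[tz] = 1                # inner transition zone (TZ subset wins)

    style = config.institution_style
    img = np.full(shape, style.background_level, dtype=np.float64)
    img[labels == 1] = style.contrast_tz
    img[labels == 2] = style.contrast_pz
    img = img * _bias_field(shape, style.bias_amplitude, rng)
    if style.noise_sd > 0:
        img = img + rng.normal(0.0, style.noise_sd, shape)
    return Volume(img), LabelVolume(labels)


def generate_institution_dataset(
        config: PhantomConfig,
        n_cases: int) -> list[tuple[Volume, LabelVolume]]:
    """Per-case seeds are config.seed + case index, so a dataset is a pure
    function of its config."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    return [generate_case(config, config.seed + i) for i in range(n_cases)]


# -- NIfTI I/O -------------------------------------------------------------

def write_volume(volume: Volume, labels: LabelVolume, path,
                 config: PhantomConfig | None = None) -> None:
    """Write image + mask as NIfTI; ``path`` is a stem, producing
    ``<stem>_img.nii.gz`` and ``<stem>_seg.nii.gz`` (plus a JSON sidecar
    with the generating config when given)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels, affine),
             str(path) + "_img.nii.gz")
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), affine),
             str(path) + "_seg.nii.gz")
    if config is not None:
        sidecar = dataclasses.asdict(config)
        Path(str(path) + "_config.json").write_text(
            json.dumps(sidecar, indent=2))


def read_volume(path) -> tuple[Volume, LabelVolume]:
    img_path = Path(str(path) + "_img.nii.gz")
    seg_path = Path(str(path) + "_seg.nii.gz")
    for p in (img_path, seg_path):
        if not p.exists():
            raise FileNotFoundError(p)
    img = nib.load(str(img_path))
    seg = nib.load(str(seg_path))
    spacing = tuple(float(s) for s in np.abs(np.diag(img.affine)[:3]))
    vox = np.asarray(img.dataobj, dtype=np.float64)
    lab = np.asarray(seg.dataobj)
    if not np.all(np.isin(lab, [0, 1, 2])):
        raise ValueError("label volume contains values outside {0, 1, 2}")
    return Volume(vox, spacing), LabelVolume(lab.astype(np.int16))
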