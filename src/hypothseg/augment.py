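"""On-the-fly augmentation for training pairs of MRI scans and label maps.

Each training pair is pushed through a stochastic chain that emulates the
variability expected across T1-weighted acquisitions:

1. a random smooth diffeomorphic deformation (a stationary velocity field
   sampled on a coarse grid, upsampled, and integrated by scaling-and-
   squaring) combined with a random affine transform, applied in a single
   trilinear resampling to both the image and the one-hot label channels;
2. a multiplicative smooth bias field (exponential of a coarse Gaussian
   field) mimicking scanner intensity inhomogeneity;
3. global brightness/contrast jitter;
4. a right-left flip with probability 0.5, swapping lateral labels;
5. a random crop that always retains the whole foreground;
6. min-max intensity normalisation to [0, 1].

All draws are taken from a caller-supplied numpy Generator, so a fixed seed
reproduces a sample bit for bit, while successive draws never repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import LabelMap, SoftLabelMap, Volume, one_hot_encode

__all__ = [
    "VelocityField",
    "DisplacementField",
    "AffineTransform",
    "DenseTransform",
    "BiasField",
    "AugmentConfig",
    "TrainingSample",
    "sample_svf",
    "integrate_svf",
    "compose_displacements",
    "sample_affine",
    "warp",
    "sample_bias_field",
    "apply_bias",
    "augment_intensity",
    "flip_pair",
    "random_flip_pair",
    "random_crop_pair",
    "minmax_normalize",
    "augment_pair",
]


@dataclass
class VelocityField:
    """Stationary velocity field, one 3-vector per voxel, in voxel units."""

    data: np.ndarray  # (D, H, W, 3)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(f"velocity field must be (D,H,W,3), got {self.data.shape}")

    def __neg__(self) -> "VelocityField":
        return VelocityField(-self.data)


@dataclass
class DisplacementField:
    """Displacement u mapping output voxel x to source location x + u(x)."""

    data: np.ndarray  # (D, H, W, 3)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(f"displacement must be (D,H,W,3), got {self.data.shape}")


@dataclass
class AffineTransform:
    """4x4 homogeneous matrix in voxel coordinates."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1]):
            raise ValueError("last row of an affine matrix must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))


@dataclass
class DenseTransform:
    """Target-to-source mapping x -> A.x + u(x), both on the output grid."""

    affine: AffineTransform
    displacement: DisplacementField | None = None


@dataclass
class BiasField:
    """Strictly positive multiplicative intensity field."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("bias field must be 3D")
        if np.any(self.data <= 0):
            raise ValueError("bias field must be strictly positive")


@dataclass
class AugmentConfig:
    """Sampling ranges of the augmentation chain.

    Grid sizes mirror the published configuration (coarse SVF grid 10^3,
    coarse bias grid 4^3, crop 160^3, flip probability 0.5); distribution
    widths are exposed here and default to visually moderate values.
    Per-sample noise scales (SVF sigma, bias log-sigma) are themselves drawn
    uniformly from [0, max], so the network sees a continuum from mild to
    strong corruption.
    """

    svf_grid: tuple[int, int, int] = (10, 10, 10)
    svf_std_max: float = 3.0  # voxels
    integration_steps: int = 7
    rotation_range: float = 15.0  # degrees, +/- per axis
    scaling_range: tuple[float, float] = (0.85, 1.15)  # per axis
    shear_range: float = 0.1  # +/- off-diagonal
    translation_range: float = 10.0  # voxels, +/- per axis
    bias_grid: tuple[int, int, int] = (4, 4, 4)
    bias_log_std_max: float = 0.3
    brightness_shift_range: float = 0.10  # fraction of intensity range, +/-
    contrast_factor_range: tuple[float, float] = (0.75, 1.25)
    flip_probability: float = 0.5
    crop_size: tuple[int, int, int] = (160, 160, 160)
    seed: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.crop_size, int):
            self.crop_size = (self.crop_size,) * 3
        self.svf_grid = tuple(int(g) for g in self.svf_grid)
        self.bias_grid = tuple(int(g) for g in self.bias_grid)
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")
        for lo, hi in (self.scaling_range, self.contrast_factor_range):
            if lo > hi:
                raise ValueError("ranges must be well ordered (lo <= hi)")
        if any(c <= 0 for c in self.crop_size):
            raise ValueError("crop_size must be positive")
        for name in ("svf_std_max", "bias_log_std_max", "rotation_range",
                     "shear_range", "translation_range", "brightness_shift_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def identity(self) -> "AugmentConfig":
        """A copy with every range collapsed to its identity value."""
        return replace(
            self,
            svf_std_max=0.0,
            rotation_range=0.0,
            scaling_range=(1.0, 1.0),
            shear_range=0.0,
            translation_range=0.0,
            bias_log_std_max=0.0,
            brightness_shift_range=0.0,
            contrast_factor_range=(1.0, 1.0),
            flip_probability=0.0,
        )


@dataclass
class TrainingSample:
    """An augmented image (intensities in [0,1]) with aligned soft labels."""

    image: Volume
    labels: SoftLabelMap
    flipped: bool = False  # whether a lateral flip was applied in this draw


# ---------------------------------------------------------------------------
# trilinear resampling core (shared by upsampling, SVF integration and warp)


def _trilinear_sample(field: np.ndarray, coords: np.ndarray, fill=None) -> np.ndarray:
    """Trilinearly sample a multi-channel 3D field at fractional coordinates.

    ``field`` is (D, H, W) or (D, H, W, C); ``coords`` is (3, ...) in voxel
    units.  With ``fill=None`` coordinates are edge-clamped; otherwise
    samples blend into the per-channel ``fill`` value within one voxel of
    the border and equal it beyond (matching linear interpolation against a
    constant exterior).  Channels share one set of interpolation weights.
    """
    squeeze = field.ndim == 3
    if squeeze:
        field = field[..., None]
    out_shape = coords.shape[1:]
    coords = coords.reshape(3, -1)
    if fill is not None:
        fills = np.broadcast_to(
            np.asarray(fill, dtype=np.float32), (field.shape[-1],)
        )
        padded = np.empty(
            tuple(s + 2 for s in field.shape[:3]) + (field.shape[-1],), dtype=np.float32
        )
        padded[...] = fills
        padded[1:-1, 1:-1, 1:-1] = field
        field = padded
        coords = coords + 1.0
    d, h, w = field.shape[:3]
    flat = field.reshape(-1, field.shape[-1])
    idx0, frac = [], []
    for axis, size in enumerate((d, h, w)):
        x = np.clip(coords[axis], 0.0, size - 1.0)
        i0 = np.minimum(x.astype(np.int64), size - 2) if size > 1 else np.zeros(
            x.shape, dtype=np.int64
        )
        idx0.append(i0)
        frac.append((x - i0).astype(np.float32))
    s1, s2 = h * w, w
    base = idx0[0] * s1 + idx0[1] * s2 + idx0[2]
    fx, fy, fz = frac
    gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz
    acc = (gx * gy * gz)[:, None] * flat[base]
    acc += (gx * gy * fz)[:, None] * flat[base + 1]
    acc += (gx * fy * gz)[:, None] * flat[base + s2]
    acc += (gx * fy * fz)[:, None] * flat[base + s2 + 1]
    acc += (fx * gy * gz)[:, None] * flat[base + s1]
    acc += (fx * gy * fz)[:, None] * flat[base + s1 + 1]
    acc += (fx * fy * gz)[:, None] * flat[base + s1 + s2]
    acc += (fx * fy * fz)[:, None] * flat[base + s1 + s2 + 1]
    out = acc.reshape(out_shape + (field.shape[-1],))
    return out[..., 0] if squeeze else out


# ---------------------------------------------------------------------------
# coarse-grid noise fields


def _upsample_trilinear(small: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Linearly interpolate a coarse 3D grid (optionally with a trailing
    component axis) to ``shape``, aligning the corner samples."""
    coords = np.meshgrid(
        *[
            np.linspace(0.0, g - 1.0, s) if g > 1 else np.zeros(s)
            for g, s in zip(small.shape[:3], shape)
        ],
        indexing="ij",
    )
    return _trilinear_sample(
        small.astype(np.float32), np.stack(coords).astype(np.float32)
    ).astype(np.float32)


def sample_svf(shape, cfg: AugmentConfig, rng: np.random.Generator) -> VelocityField:
    """Draw a smooth stationary velocity field on ``shape``.

    A coarse grid (cfg.svf_grid, 3 components) of N(0, sigma^2) noise is
    upsampled trilinearly; sigma is itself drawn uniformly from
    [0, cfg.svf_std_max] so successive samples span mild to strong
    deformations.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < g for s, g in zip(shape, cfg.svf_grid)):
        raise ValueError(f"image shape {shape} smaller than SVF grid {cfg.svf_grid}")
    sigma = rng.uniform(0.0, cfg.svf_std_max)
    small = rng.normal(0.0, 1.0, size=cfg.svf_grid + (3,)) * sigma
    return VelocityField(_upsample_trilinear(small.astype(np.float32), shape))


def _sample_vector_field(u: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinearly sample a (D,H,W,3) field at coords (3, ...), edge-clamped."""
    return _trilinear_sample(u, coords).astype(np.float32)


def integrate_svf(v: VelocityField, steps: int = 7) -> DisplacementField:
    """Integrate a stationary velocity field by scaling and squaring.

    u_0 = v / 2^steps, then u <- u + u(x + u(x)) applied ``steps`` times;
    the result approximates the flow exponential of v and is invertible
    (integrating -v gives the numerical inverse).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    u = v.data / (2.0 ** steps)
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=np.float32) for s in u.shape[:3]], indexing="ij")
    )
    for _ in range(steps):
        coords = grid + np.moveaxis(u, -1, 0)
        u = u + _sample_vector_field(u, coords)
    return DisplacementField(u)


def compose_displacements(u1: DisplacementField, u2: DisplacementField) -> DisplacementField:
    """Displacement of applying u2 first, then u1: u2(x) + u1(x + u2(x))."""
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=np.float32) for s in u2.data.shape[:3]], indexing="ij")
    )
    coords = grid + np.moveaxis(u2.data, -1, 0)
    return DisplacementField(u2.data + _sample_vector_field(u1.data, coords))


# ---------------------------------------------------------------------------
# affine sampling


def _rotation_matrix(axis: int, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    m = np.eye(4)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i], m[i, j], m[j, i], m[j, j] = c, -s, s, c
    return m


def sample_affine(
    cfg: AugmentConfig, rng: np.random.Generator, shape=None
) -> AffineTransform:
    """Random affine as the fixed product T . Rx . Ry . Rz . Sh . S.

    Rotation angles, per-axis scalings, shears and translations are uniform
    on their configured ranges.  When ``shape`` is given the linear part is
    conjugated so rotation/scaling/shear act about the volume centre.
    """
    angles = np.deg2rad(rng.uniform(-cfg.rotation_range, cfg.rotation_range, size=3))
    scales = rng.uniform(*cfg.scaling_range, size=3)
    shears = rng.uniform(-cfg.shear_range, cfg.shear_range, size=3)
    trans = rng.uniform(-cfg.translation_range, cfg.translation_range, size=3)

    s_mat = np.diag([scales[0], scales[1], scales[2], 1.0])
    sh_mat = np.eye(4)
    sh_mat[0, 1], sh_mat[0, 2], sh_mat[1, 2] = shears
    t_mat = np.eye(4)
    t_mat[:3, 3] = trans

    linear = (
        _rotation_matrix(0, angles[0])
        @ _rotation_matrix(1, angles[1])
        @ _rotation_matrix(2, angles[2])
        @ sh_mat
        @ s_mat
    )
    if shape is not None:
        centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
        to_c, from_c = np.eye(4), np.eye(4)
        to_c[:3, 3] = centre
        from_c[:3, 3] = -centre
        linear = to_c @ linear @ from_c
    return AffineTransform(t_mat @ linear)


# ---------------------------------------------------------------------------
# resampling


def warp(src, t: DenseTransform, fill: float = 0.0):
    """Resample with a single trilinear pass at source coords A.x + u(x).

    Volumes take ``fill`` outside the field of view; soft label maps take
    background probability 1 there, so warped channels remain a per-voxel
    probability simplex.
    """
    shape = src.shape
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=np.float32) for s in shape], indexing="ij")
    )
    a = t.affine.matrix.astype(np.float32)
    coords = np.einsum("ij,jdhw->idhw", a[:3, :3], grid) + a[:3, 3][:, None, None, None]
    if t.displacement is not None:
        if t.displacement.data.shape[:3] != shape:
            raise ValueError("displacement grid does not match the output grid")
        coords = coords + np.moveaxis(t.displacement.data, -1, 0)

    if isinstance(src, SoftLabelMap):
        bg = src.taxonomy.index_of(src.taxonomy.background)
        fills = np.zeros(src.data.shape[-1], dtype=np.float32)
        fills[bg] = 1.0
        out = _trilinear_sample(src.data.astype(np.float32), coords, fill=fills)
        np.clip(out, 0.0, 1.0, out=out)
        return SoftLabelMap(out, src.taxonomy, src.voxel_size, src.affine)
    if isinstance(src, Volume):
        data = _trilinear_sample(src.data.astype(np.float32), coords, fill=fill)
        return Volume(data.astype(np.float32), src.voxel_size, src.affine)
    raise TypeError(f"cannot warp object of type {type(src).__name__}")


# ---------------------------------------------------------------------------
# intensity corruption


def sample_bias_field(shape, cfg: AugmentConfig, rng: np.random.Generator) -> BiasField:
    """Exponential of an upsampled coarse Gaussian field; strictly positive."""
    shape = tuple(int(s) for s in shape)
    if any(s < g for s, g in zip(shape, cfg.bias_grid)):
        raise ValueError(f"image shape {shape} smaller than bias grid {cfg.bias_grid}")
    sigma = rng.uniform(0.0, cfg.bias_log_std_max)
    small = (rng.normal(0.0, 1.0, size=cfg.bias_grid) * sigma).astype(np.float32)
    return BiasField(np.exp(_upsample_trilinear(small, shape)))


def apply_bias(v: Volume, b: BiasField) -> Volume:
    """Voxel-wise product of the image with a multiplicative bias field."""
    if v.shape != b.data.shape:
        raise ValueError(f"shape mismatch: image {v.shape} vs bias {b.data.shape}")
    return v.with_data(v.data * b.data)


def augment_intensity(
    v: Volume, cfg: AugmentConfig, rng: np.random.Generator
) -> Volume:
    """Global contrast/brightness jitter: gain about the mean plus a shift.

    out = gain * (v - mean) + mean + shift, with the shift expressed as a
    fraction of the image intensity range.
    """
    gain = rng.uniform(*cfg.contrast_factor_range)
    span = float(v.data.max() - v.data.min())
    shift = rng.uniform(-cfg.brightness_shift_range, cfg.brightness_shift_range) * span
    mean = float(v.data.mean())
    return v.with_data((gain * (v.data - mean) + mean + shift).astype(np.float32))


# ---------------------------------------------------------------------------
# flip / crop / normalise


def flip_pair(img: Volume, labels: SoftLabelMap) -> tuple[Volume, SoftLabelMap]:
    """Mirror both along the right-left (first) axis and swap lateral labels."""
    perm = labels.taxonomy.swap_permutation()
    flipped = labels.data[::-1, ...][..., perm]
    return (
        img.with_data(img.data[::-1].copy()),
        SoftLabelMap(np.ascontiguousarray(flipped), labels.taxonomy,
                     labels.voxel_size, labels.affine),
    )


def random_flip_pair(
    img: Volume, labels: SoftLabelMap, cfg: AugmentConfig, rng: np.random.Generator
) -> tuple[Volume, SoftLabelMap, bool]:
    """Apply flip_pair with probability cfg.flip_probability."""
    if rng.uniform() < cfg.flip_probability:
        img, labels = flip_pair(img, labels)
        return img, labels, True
    return img, labels, False


def _foreground_bbox(labels: SoftLabelMap) -> tuple[np.ndarray, np.ndarray] | None:
    bg = labels.taxonomy.index_of(labels.taxonomy.background)
    fg = labels.data[..., bg] < 0.5
    if not fg.any():
        return None
    idx = np.nonzero(fg)
    return (np.array([a.min() for a in idx]), np.array([a.max() for a in idx]))


def random_crop_pair(
    img: Volume, labels: SoftLabelMap, cfg: AugmentConfig, rng: np.random.Generator
) -> tuple[Volume, SoftLabelMap]:
    """Crop to cfg.crop_size, keeping the whole foreground inside the crop.

    The crop origin is uniform over all positions whose window contains the
    foreground bounding box; with no foreground it is uniform over all valid
    positions.
    """
    shape = np.asarray(img.shape)
    crop = np.asarray(cfg.crop_size)
    if np.any(crop > shape):
        raise ValueError(f"crop size {tuple(crop)} exceeds image shape {tuple(shape)}")
    bbox = _foreground_bbox(labels)
    lo = np.zeros(3, dtype=int)
    hi = shape - crop  # inclusive upper bound of the origin
    if bbox is not None:
        bb_min, bb_max = bbox
        if np.any(bb_max - bb_min + 1 > crop):
            raise ValueError("foreground bounding box larger than the crop size")
        lo = np.maximum(lo, bb_max + 1 - crop)
        hi = np.minimum(hi, bb_min)
    origin = np.array([rng.integers(a, b + 1) for a, b in zip(lo, hi)])
    sl = tuple(slice(int(o), int(o + c)) for o, c in zip(origin, crop))
    return (
        img.with_data(img.data[sl].copy()),
        SoftLabelMap(labels.data[sl].copy(), labels.taxonomy,
                     labels.voxel_size, labels.affine),
    )


def minmax_normalize(v: Volume) -> Volume:
    """Rescale intensities to [0, 1]; a constant image maps to all zeros."""
    lo, hi = float(v.data.min()), float(v.data.max())
    if hi - lo == 0.0:
        return v.with_data(np.zeros_like(v.data, dtype=np.float32))
    return v.with_data(((v.data - lo) / (hi - lo)).astype(np.float32))


# ---------------------------------------------------------------------------
# the full chain


def augment_pair(
    img: Volume,
    lm: LabelMap | SoftLabelMap,
    cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
    stages: dict | None = None,
) -> TrainingSample:
    """Run the full augmentation chain on an aligned image/label pair.

    Order: spatial deformation (SVF + affine in one resampling) -> bias
    field -> brightness/contrast -> lateral flip -> foreground-safe crop ->
    min-max normalisation.  Labels undergo only the spatial steps.  Passing
    a dict as ``stages`` records the intermediate images under the keys
    'deformed', 'biased', 'intensity', 'flipped'.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = one_hot_encode(lm) if isinstance(lm, LabelMap) else lm
    if img.shape != labels.shape:
        raise ValueError(f"image shape {img.shape} != label shape {labels.shape}")

    if cfg.svf_std_max > 0:
        disp = integrate_svf(sample_svf(img.shape, cfg, rng), cfg.integration_steps)
    else:
        disp = None
    affine = sample_affine(cfg, rng, shape=img.shape)
    transform = DenseTransform(affine, disp)
    img = warp(img, transform)
    labels = warp(labels, transform)
    if stages is not None:
        stages["deformed"] = img

    img = apply_bias(img, sample_bias_field(img.shape, cfg, rng))
    if stages is not None:
        stages["biased"] = img
    img = augment_intensity(img, cfg, rng)
    if stages is not None:
        stages["intensity"] = img
    img, labels, flipped = random_flip_pair(img, labels, cfg, rng)
    if stages is not None:
        stages["flipped"] = img
    img, labels = random_crop_pair(img, labels, cfg, rng)
    img = minmax_normalize(img)
    return TrainingSample(img, labels, flipped)
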