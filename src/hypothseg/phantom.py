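"""Synthetic phantoms with the structural traits the method assumes.

Each phantom is a "brain" sphere in empty background containing two
mirrored ellipsoidal "hypothalami", one per hemisphere, each split into the
five subunits by two coronal planes (anterior / tubular / posterior thirds)
and one axial plane (superior / inferior halves of the anterior and tubular
thirds), mirroring the anatomical subdivision a-sHyp, a-iHyp, supTub,
infTub, posHyp.  Axes follow (right-left, anterior-posterior,
inferior-superior).

Intensities are per-class means plus Gaussian noise, lightly smoothed; the
structure-to-surroundings contrast gap is deliberately small by default to
emulate the low grey-matter contrast of the hypothalamic region that makes
the real task hard.  An optional per-label atrophy factor shrinks a subunit
to a chosen fraction of its volume (outermost voxels are removed first),
which lets cohorts with group-specific atrophy be simulated exactly.

Because the geometry is analytic, label volumes and boundaries are known,
so the generator doubles as an oracle for the metrics and study pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import HYPOTHALAMUS_TAXONOMY, LabelMap, LabelTaxonomy, Volume, write_volume

__all__ = ["PhantomConfig", "GroupSpec", "generate_phantom", "generate_cohort", "generate_dataset"]


@dataclass
class PhantomConfig:
    """Geometry and appearance of a synthetic head phantom."""

    size: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_mean: float = 10.0
    tissue_mean: float = 70.0
    contrast_gap: float = 6.0  # hypothalamus mean minus tissue mean; small on purpose
    noise_std: float = 4.0
    smoothing_sigma: float = 0.6
    brain_radius: float = 26.0
    semi_axes: tuple[float, float, float] = (4.5, 9.0, 6.5)
    lateral_offset: float = 6.5  # hypothalamus centre offset from midline, voxels
    centre_jitter: float = 0.0  # +/- voxels applied to the structure centre
    coronal_fractions: tuple[float, float] = (-1 / 3, 1 / 3)  # anterior/tubular/posterior
    atrophy: dict[int, float] = field(default_factory=dict)  # label code -> factor in (0,1]
    taxonomy: LabelTaxonomy = HYPOTHALAMUS_TAXONOMY
    seed: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.size, int):
            self.size = (self.size,) * 3
        self.size = tuple(int(s) for s in self.size)
        if any(s <= 0 for s in self.size):
            raise ValueError("size must be positive")
        for code, f in self.atrophy.items():
            if not 0.0 < f <= 1.0:
                raise ValueError(f"atrophy factor for label {code} must be in (0, 1]")
            if code not in self.taxonomy.foreground_codes:
                raise ValueError(f"atrophy refers to unknown foreground label {code}")
        if not np.all(np.isfinite([self.background_mean, self.tissue_mean,
                                   self.contrast_gap, self.noise_std])):
            raise ValueError("intensity parameters must be finite")

    @classmethod
    def desk(cls, size: int = 32, **overrides) -> "PhantomConfig":
        """Reduced configuration for fast CPU experiments.

        The structure is proportionally larger than at full scale so each
        subunit keeps a few dozen voxels, enough for surface metrics and
        learning to be meaningful on a 32^3 grid.
        """
        scale = size / 32.0
        base = cls(
            size=(size,) * 3,
            brain_radius=13.0 * scale,
            semi_axes=(3.0 * scale, 5.5 * scale, 4.0 * scale),
            lateral_offset=4.0 * scale,
        )
        return replace(base, **overrides)


@dataclass
class GroupSpec:
    """Two-group cohort description for generate_cohort/generate_dataset."""

    disease_fraction: float = 0.5
    disease_atrophy: dict[int, float] = field(default_factory=dict)
    scale_jitter: float = 0.10  # +/- fractional anatomy scale per subject
    centre_jitter: float = 1.5  # voxels
    age_range: tuple[float, float] = (50.0, 85.0)
    age_atrophy_per_year: float = 0.002  # mild global shrinkage with age


def _ellipsoid_norm2(shape, centre, semi_axes) -> np.ndarray:
    coords = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    r2 = np.zeros(shape, dtype=np.float64)
    for x, c, a in zip(coords, centre, semi_axes):
        r2 += ((x - c) / a) ** 2
    return r2


def _apply_atrophy(labels: np.ndarray, r2_by_side: dict, cfg_atrophy: dict[int, float]):
    """Shrink atrophied subunits to the requested volume fraction.

    Voxels of the subunit are ranked by their ellipsoidal radius and the
    outermost ones are relabelled as surrounding tissue (background code),
    so the retained count is round(factor * original count).
    """
    for code, f in cfg_atrophy.items():
        if f >= 1.0:
            continue
        voxels = np.nonzero(labels == code)
        n = voxels[0].size
        if n == 0:
            continue
        r2 = r2_by_side[code][voxels]
        keep = int(round(f * n))
        order = np.argsort(r2, kind="stable")
        drop = tuple(v[order[keep:]] for v in voxels)
        labels[drop] = 0


def generate_phantom(cfg: PhantomConfig, rng: np.random.Generator | None = None):
    """Build one (image, label map) pair; deterministic under cfg.seed.

    Raises if any subunit ends up empty (degenerate geometry).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    shape = cfg.size
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    if cfg.centre_jitter > 0:
        centre = centre + rng.uniform(-cfg.centre_jitter, cfg.centre_jitter, size=3)

    brain = _ellipsoid_norm2(shape, centre, (cfg.brain_radius,) * 3) <= 1.0
    labels = np.zeros(shape, dtype=np.int16)
    tax = cfg.taxonomy
    left_codes = [c for c in tax.foreground_codes if tax.lr_swap[c] > c]
    right_codes = [tax.lr_swap[c] for c in left_codes]

    coords = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    r2_by_side: dict[int, np.ndarray] = {}
    for side_codes, sign in ((left_codes, -1.0), (right_codes, +1.0)):
        c_side = centre + np.array([sign * cfg.lateral_offset, 0.0, 0.0])
        r2 = _ellipsoid_norm2(shape, c_side, cfg.semi_axes)
        inside = r2 <= 1.0
        # coronal position v in [-1, 1] along the anterior-posterior axis
        v = (coords[1] - c_side[1]) / cfg.semi_axes[1]
        superior = coords[2] >= c_side[2]
        lo, hi = cfg.coronal_fractions
        anterior, posterior = v < lo, v >= hi
        tubular = ~anterior & ~posterior
        a_s, a_i, sup_t, inf_t, pos = side_codes
        labels[inside & anterior & superior] = a_s
        labels[inside & anterior & ~superior] = a_i
        labels[inside & tubular & superior] = sup_t
        labels[inside & tubular & ~superior] = inf_t
        labels[inside & posterior] = pos
        for code in side_codes:
            r2_by_side[code] = r2

    _apply_atrophy(labels, r2_by_side, cfg.atrophy)

    present = set(np.unique(labels))
    missing = [c for c in tax.foreground_codes if c not in present]
    if missing:
        raise ValueError(
            f"degenerate phantom geometry: empty subunits {missing} "
            f"(size {shape}, semi-axes {cfg.semi_axes})"
        )

    image = np.full(shape, cfg.background_mean, dtype=np.float32)
    image[brain] = cfg.tissue_mean
    image[labels > 0] = cfg.tissue_mean + cfg.contrast_gap
    image += rng.normal(0.0, cfg.noise_std, size=shape).astype(np.float32)
    if cfg.smoothing_sigma > 0:
        image = gaussian_filter(image, cfg.smoothing_sigma)

    affine = np.diag(list(cfg.voxel_size) + [1.0])
    return (
        Volume(image.astype(np.float32), cfg.voxel_size, affine),
        LabelMap(labels, tax, cfg.voxel_size, affine),
    )


def _subject_config(
    cfg: PhantomConfig, spec: GroupSpec, group: str, age: float, rng
) -> PhantomConfig:
    scale = 1.0 + rng.uniform(-spec.scale_jitter, spec.scale_jitter)
    age_factor = float(np.clip(1.0 - spec.age_atrophy_per_year * (age - spec.age_range[0]),
                               0.5, 1.0))
    atrophy = {c: age_factor for c in cfg.taxonomy.foreground_codes}
    if group == "disease":
        for code, f in spec.disease_atrophy.items():
            atrophy[code] = atrophy[code] * f
    return replace(
        cfg,
        brain_radius=cfg.brain_radius * scale,
        semi_axes=tuple(a * scale for a in cfg.semi_axes),
        lateral_offset=cfg.lateral_offset * scale,
        centre_jitter=spec.centre_jitter,
        atrophy=atrophy,
    )


def generate_cohort(
    n: int,
    cfg: PhantomConfig,
    group_spec: GroupSpec | None = None,
    rng: np.random.Generator | None = None,
):
    """Generate n jittered subjects in memory.

    Returns (subjects, manifest): subjects is a list of (Volume, LabelMap)
    and manifest a table with subject id, group, age, icv (brain volume in
    mm^3 with 1% measurement noise) and the true per-label volumes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = group_spec or GroupSpec()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_disease = int(round(spec.disease_fraction * n))
    groups = ["disease"] * n_disease + ["control"] * (n - n_disease)
    rng.shuffle(groups)

    voxel_mm3 = float(np.prod(cfg.voxel_size))
    subjects, rows = [], []
    for i, group in enumerate(groups):
        age = float(rng.uniform(*spec.age_range))
        sub_cfg = _subject_config(cfg, spec, group, age, rng)
        img, lm = generate_phantom(sub_cfg, rng)
        brain_voxels = int((img.data > (cfg.background_mean + cfg.tissue_mean) / 2).sum())
        icv = brain_voxels * voxel_mm3 * float(1.0 + rng.normal(0.0, 0.01))
        row = {"subject": f"sub-{i:03d}", "group": group, "age": age, "icv": icv}
        for code in cfg.taxonomy.foreground_codes:
            row[f"vol_{cfg.taxonomy.name_of(code)}"] = float(
                (lm.data == code).sum() * voxel_mm3
            )
        subjects.append((img, lm))
        rows.append(row)
    return subjects, pd.DataFrame(rows)


def generate_dataset(
    n: int,
    cfg: PhantomConfig,
    group_spec: GroupSpec | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Write n phantom pairs plus a covariate manifest CSV to out_dir."""
    out_dir = Path(out_dir)
    if not out_dir.parent.exists():
        raise FileNotFoundError(f"cannot create dataset under {out_dir.parent}")
    out_dir.mkdir(exist_ok=True)
    subjects, manifest = generate_cohort(n, cfg, group_spec)
    image_paths, label_paths = [], []
    for (img, lm), subject in zip(subjects, manifest["subject"]):
        ipath = out_dir / f"{subject}_image.nii.gz"
        lpath = out_dir / f"{subject}_labels.nii.gz"
        write_volume(img, ipath)
        write_volume(lm, lpath)
        image_paths.append(ipath.name)
        label_paths.append(lpath.name)
    manifest = manifest.copy()
    manifest["image"] = image_paths
    manifest["labels"] = label_paths
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
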