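"""Volumes, label maps and the hypothalamic label taxonomy.

The segmentation target is the hypothalamus and its five subunits per side,
delineated on ~1 mm isotropic T1-weighted scans: anterior-superior (a-sHyp),
anterior-inferior (a-iHyp), superior tubular (supTub), inferior tubular
(infTub) and posterior (posHyp) hypothalamus.  Together with the background
this gives an 11-label taxonomy (5 subunits x 2 sides + background).

All spatial data is handled in voxel space; the NIfTI affine is carried
through unchanged and no reorientation or resampling is performed on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelTaxonomy",
    "LabelMap",
    "SoftLabelMap",
    "HYPOTHALAMUS_TAXONOMY",
    "read_volume",
    "read_label_map",
    "read_soft_label_map",
    "write_volume",
    "one_hot_encode",
    "hard_assign",
]


def _as_voxel_size(voxel_size) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be 3 positive floats, got {voxel_size!r}")
    return vs


@dataclass
class Volume:
    """A 3D scalar image with voxel size (mm) and world affine."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite voxels")
        self.voxel_size = _as_voxel_size(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass(frozen=True)
class LabelTaxonomy:
    """Ordered label codes with names and a left/right swap pairing.

    ``lr_swap`` maps each code to its contralateral twin (background to
    itself); it must be involutive.  Background is required and listed first.
    """

    codes: tuple[int, ...]
    names: tuple[str, ...]
    lr_swap: dict[int, int]

    def __post_init__(self) -> None:
        if len(self.codes) != len(set(self.codes)):
            raise ValueError("taxonomy codes must be unique")
        if len(self.codes) != len(self.names):
            raise ValueError("codes and names must have equal length")
        for a, b in self.lr_swap.items():
            if a not in self.codes or b not in self.codes:
                raise ValueError("lr_swap refers to unknown codes")
            if self.lr_swap.get(b) != a:
                raise ValueError("lr_swap must be its own inverse")
        if self.lr_swap[self.codes[0]] != self.codes[0]:
            raise ValueError("background (first code) must map to itself")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def background(self) -> int:
        return self.codes[0]

    @property
    def foreground_codes(self) -> tuple[int, ...]:
        return self.codes[1:]

    def index_of(self, code: int) -> int:
        return self.codes.index(code)

    def swap_permutation(self) -> np.ndarray:
        """Channel permutation realising lr_swap in one-hot space."""
        return np.array([self.index_of(self.lr_swap[c]) for c in self.codes])

    def name_of(self, code: int) -> str:
        return self.names[self.index_of(code)]

    def to_config(self) -> list[dict]:
        return [
            {"code": int(c), "name": n, "swap": int(self.lr_swap[c])}
            for c, n in zip(self.codes, self.names)
        ]

    @classmethod
    def from_config(cls, rows: list[dict]) -> "LabelTaxonomy":
        codes = tuple(int(r["code"]) for r in rows)
        names = tuple(str(r["name"]) for r in rows)
        swap = {int(r["code"]): int(r["swap"]) for r in rows}
        return cls(codes, names, swap)


_SUBUNITS = ("a-sHyp", "a-iHyp", "supTub", "infTub", "posHyp")

#: Default 11-label taxonomy: 0 background, 1-5 left subunits, 6-10 right.
HYPOTHALAMUS_TAXONOMY = LabelTaxonomy(
    codes=tuple(range(11)),
    names=("background",)
    + tuple(f"left {s}" for s in _SUBUNITS)
    + tuple(f"right {s}" for s in _SUBUNITS),
    lr_swap={0: 0, **{i: i + 5 for i in range(1, 6)}, **{i + 5: i for i in range(1, 6)}},
)


@dataclass
class LabelMap:
    """A 3D integer label image whose values are taxonomy codes."""

    data: np.ndarray
    taxonomy: LabelTaxonomy = HYPOTHALAMUS_TAXONOMY
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap data must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = self.data.astype(np.int32)
            if not np.array_equal(as_int, self.data):
                raise ValueError("LabelMap data must be integer-valued")
            self.data = as_int
        unknown = set(np.unique(self.data)) - set(self.taxonomy.codes)
        if unknown:
            raise ValueError(f"label codes outside taxonomy: {sorted(unknown)}")
        self.voxel_size = _as_voxel_size(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SoftLabelMap:
    """Per-voxel probability vector over the taxonomy (channels last).

    ``data`` has shape spatial + (n_labels,); channels are non-negative and
    sum to 1 per voxel (within 1e-5).  Both warped ground truth and the
    network softmax output are carried in this form.
    """

    data: np.ndarray
    taxonomy: LabelTaxonomy = HYPOTHALAMUS_TAXONOMY
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"SoftLabelMap data must be 4D, got {self.data.shape}")
        if self.data.shape[-1] != len(self.taxonomy):
            raise ValueError(
                f"channel count {self.data.shape[-1]} != taxonomy size {len(self.taxonomy)}"
            )
        if np.any(self.data < -1e-7):
            raise ValueError("SoftLabelMap has negative probabilities")
        sums = self.data.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > 1e-5):
            raise ValueError("SoftLabelMap channels do not sum to 1 per voxel")
        self.voxel_size = _as_voxel_size(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def _spacing_from_header(img) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_volume(path) -> Volume:
    """Read a 3D NIfTI scalar image; no resampling or reorientation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D image (shape {data.shape})")
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite voxels")
    return Volume(data, _spacing_from_header(img), np.asarray(img.affine))


def read_label_map(path, taxonomy: LabelTaxonomy = HYPOTHALAMUS_TAXONOMY) -> LabelMap:
    """Read a 3D NIfTI integer label image against a taxonomy."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label map: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D label map (shape {data.shape})")
    return LabelMap(
        np.rint(data).astype(np.int16), taxonomy, _spacing_from_header(img), np.asarray(img.affine)
    )


def read_soft_label_map(path, taxonomy: LabelTaxonomy = HYPOTHALAMUS_TAXONOMY) -> SoftLabelMap:
    """Read a 4D NIfTI probability image (channels in the 4th dimension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such soft label map: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D probability image (shape {data.shape})")
    return SoftLabelMap(data, taxonomy, _spacing_from_header(img), np.asarray(img.affine))


def write_volume(v, path) -> None:
    """Write a Volume, LabelMap or SoftLabelMap as NIfTI.

    Label maps are stored as integers; the header spacing and affine match
    the object.  The parent directory must exist.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, LabelMap):
        data = v.data.astype(np.int16)
    elif isinstance(v, SoftLabelMap):
        data = v.data.astype(np.float32)
    elif isinstance(v, Volume):
        data = v.data.astype(np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(v).__name__}")
    img = nib.Nifti1Image(data, v.affine)
    zooms = v.voxel_size + (1.0,) * (data.ndim - 3)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def one_hot_encode(lm: LabelMap) -> SoftLabelMap:
    """Indicator channels for each taxonomy code (per-voxel sum exactly 1)."""
    n = len(lm.taxonomy)
    code_to_idx = np.zeros(max(lm.taxonomy.codes) + 1, dtype=np.int64)
    for i, c in enumerate(lm.taxonomy.codes):
        code_to_idx[c] = i
    idx = code_to_idx[lm.data]
    out = np.zeros(lm.shape + (n,), dtype=np.float32)
    np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
    return SoftLabelMap(out, lm.taxonomy, lm.voxel_size, lm.affine)


def hard_assign(s: SoftLabelMap) -> LabelMap:
    """Most probable label per voxel; ties break to the lowest taxonomy index.

    np.argmax returns the first maximal index, which realises the tie-break
    because channels are stored in taxonomy order (background first).
    """
    idx = np.argmax(s.data, axis=-1)
    codes = np.asarray(s.taxonomy.codes, dtype=np.int16)
    return LabelMap(codes[idx], s.taxonomy, s.voxel_size, s.affine)
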