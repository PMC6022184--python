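"""Reading, writing, quantizing and masking tissue-probability volumes.

A subject is described by three co-registered 3D probability maps — grey
matter (GM), white matter (WM) and cerebrospinal fluid (CSF) — produced by a
unified-segmentation style preprocessing.  Volumes arrive either as floats in
[0, 1] or as 8-bit intensity maps in [0, 255]; all downstream feature
computation operates on the quantized (integer-level) representation
restricted to a brain mask.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

TISSUES = ("GM", "WM", "CSF")

MANIFEST_COLUMNS = [
    "subject_id",
    "label",
    "age",
    "gender",
    "gm_path",
    "wm_path",
    "csf_path",
]


@dataclasses.dataclass
class ProbabilityVolume:
    """One tissue's 3D probability map.

    ``data`` holds probabilities in [0, 1] while ``levels`` is None, or
    integer levels in [0, levels-1] once quantized.
    """

    data: np.ndarray
    tissue: str
    levels: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def voxel_count(self) -> int:
        return int(self.data.size)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def is_quantized(self) -> bool:
        return self.levels is not None


@dataclasses.dataclass
class BrainMask:
    """Boolean analysis mask over the subject grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def included_voxels(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class SubjectRecord:
    """Manifest entry: identity, diagnosis label, demographics, volume handles.

    Volumes may be held in memory (synthetic cohorts) or referenced by path.
    """

    subject_id: str
    label: str  # "AD" or "CN"
    age: float
    gender: str  # "M" or "F"
    gm_path: Optional[str] = None
    wm_path: Optional[str] = None
    csf_path: Optional[str] = None
    volumes: Optional[Mapping[str, ProbabilityVolume]] = None

    def __post_init__(self) -> None:
        if self.label not in ("AD", "CN"):
            raise ValueError(f"label must be AD or CN, got {self.label!r}")
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be M or F, got {self.gender!r}")

    def load_volumes(self) -> dict:
        """Return the three tissue volumes, reading from disk if necessary."""
        if self.volumes is not None:
            return dict(self.volumes)
        paths = {"GM": self.gm_path, "WM": self.wm_path, "CSF": self.csf_path}
        out = {}
        for tissue, path in paths.items():
            if path is None:
                raise ValueError(f"subject {self.subject_id}: no path for {tissue}")
            out[tissue] = read_probability_volume(path, tissue)
        return out


def read_probability_volume(path, tissue: str) -> ProbabilityVolume:
    """Read a 3D NIfTI volume as a :class:`ProbabilityVolume`.

    Float data are clipped to [0, 1] and left unquantized; integer data are
    clipped to [0, 255] and marked quantized at 256 levels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    if np.all(np.isnan(data)):
        raise ValueError(f"volume is all-NaN: {path}")
    if np.issubdtype(data.dtype, np.integer):
        data = np.clip(data, 0, 255).astype(np.int64)
        return ProbabilityVolume(data=data, tissue=tissue, levels=256)
    data = np.nan_to_num(data.astype(np.float64), nan=0.0)
    data = np.clip(data, 0.0, 1.0)
    return ProbabilityVolume(data=data, tissue=tissue)


def write_probability_volume(volume: ProbabilityVolume, path) -> None:
    """Write a volume as NIfTI (uint8 if quantized at <=256 levels)."""
    data = volume.data
    if volume.is_quantized and volume.levels <= 256:
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))


def quantize(volume: ProbabilityVolume, levels: int = 256) -> ProbabilityVolume:
    """Map probabilities in [0,1] to integer levels in [0, levels-1].

    The rule is round-half-up: v -> floor(v*(levels-1) + 0.5), so 0.5 at 256
    levels maps to 128 (0.5*255 = 127.5 rounds up).
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    if volume.is_quantized:
        raise ValueError("volume is already quantized")
    q = np.floor(volume.data * (levels - 1) + 0.5).astype(np.int64)
    np.clip(q, 0, levels - 1, out=q)
    return ProbabilityVolume(data=q, tissue=volume.tissue, levels=levels)


def build_brain_mask(
    gm: ProbabilityVolume,
    wm: ProbabilityVolume,
    csf: ProbabilityVolume,
    threshold: float = 0.0,
) -> BrainMask:
    """Include a voxel iff gm + wm + csf > threshold (any tissue signal)."""
    if not (gm.shape == wm.shape == csf.shape):
        raise ValueError(
            f"dimension mismatch: GM {gm.shape}, WM {wm.shape}, CSF {csf.shape}"
        )
    total = gm.data.astype(np.float64) + wm.data + csf.data
    return BrainMask(mask=total > threshold)


def read_manifest(path) -> list:
    """Read a subject manifest CSV into SubjectRecords.

    Columns: subject_id,label,age,gender,gm_path,wm_path,csf_path.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    base = Path(path).parent
    records = []
    for row in df.itertuples(index=False):
        def _resolve(p):
            p = str(p)
            return p if Path(p).is_absolute() else str(base / p)

        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                label=str(row.label),
                age=float(row.age),
                gender=str(row.gender),
                gm_path=_resolve(row.gm_path),
                wm_path=_resolve(row.wm_path),
                csf_path=_resolve(row.csf_path),
            )
        )
    return records


def write_manifest(subjects: Sequence[SubjectRecord], path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "label": s.label,
            "age": s.age,
            "gender": s.gender,
            "gm_path": s.gm_path,
            "wm_path": s.wm_path,
            "csf_path": s.csf_path,
        }
        for s in subjects
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
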