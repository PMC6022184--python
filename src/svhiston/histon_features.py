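"""Supervoxel-based volumetric histon features.

A histon is a contour laid on top of an intensity histogram: every voxel
contributes 1 to its intensity bin, plus 1 more if it sits inside a "similar
colour sphere" of its neighbourhood.  Here the neighbourhood is the supervoxel
containing the voxel, and the sphere radius per tissue channel is the expanse
threshold E_vi derived from supervoxel statistics.  A voxel is similar
(S2 = 1) iff, for every tissue channel, the absolute difference between its
intensity and its supervoxel's mean intensity is strictly below E_vi.

Per subject, three 256-bin histons (GM, WM, CSF) are concatenated into a
768-component feature vector; the plain 256-bin histograms are kept alongside
as a baseline representation.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .io_volumes import (
    BrainMask,
    ProbabilityVolume,
    SubjectRecord,
    build_brain_mask,
    quantize,
)
from .slic3d import SlicParams, SupervoxelLabeling, enforce_connectivity, slic_segment

EXPANSE_MODES = ("mean_of_sds", "mean_of_means")


@dataclasses.dataclass
class ExpanseThresholds:
    """Per-tissue similarity thresholds E_vi, channel order GM, WM, CSF.

    ``mean_of_sds`` (default) takes the mean over supervoxels of the
    per-supervoxel intensity standard deviation — the mean local deviation of
    the probability volume in the supervoxel-defined space.  ``mean_of_means``
    instead averages the supervoxel mean intensities.
    """

    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (3,):
            raise ValueError("expanse needs exactly three per-tissue entries")
        if np.any(self.values < 0):
            raise ValueError("expanse thresholds must be >= 0")
        if self.mode not in EXPANSE_MODES:
            raise ValueError(f"mode must be one of {EXPANSE_MODES}")


@dataclasses.dataclass
class SimilarityField:
    """Binary S2 field over the mask (0 outside the mask)."""

    s2: np.ndarray

    @property
    def n_similar(self) -> int:
        return int(self.s2.sum())


@dataclasses.dataclass
class HistonFeature:
    """Per-subject histon feature: 3 tissues x 256 levels = 768 components."""

    histons: np.ndarray  # (3, levels)
    histograms: np.ndarray  # (3, levels)
    levels: int
    tissue_order: tuple = ("GM", "WM", "CSF")

    @property
    def vector(self) -> np.ndarray:
        """Concatenated histon vector (GM, WM, CSF), length 3*levels."""
        return self.histons.reshape(-1)

    @property
    def histogram_vector(self) -> np.ndarray:
        """Concatenated plain-histogram vector, same layout as ``vector``."""
        return self.histograms.reshape(-1)


@dataclasses.dataclass
class HistonConfig:
    """End-to-end feature-extraction configuration."""

    levels: int = 256
    expanse_mode: str = "mean_of_sds"
    mask_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.expanse_mode not in EXPANSE_MODES:
            raise ValueError(f"expanse_mode must be one of {EXPANSE_MODES}")


def compute_expanse(
    labeling: SupervoxelLabeling, mode: str = "mean_of_sds"
) -> ExpanseThresholds:
    """Expanse threshold per tissue from supervoxel statistics.

    mean_of_sds:   E_vi = (1/N_s) sum_j sd_j(v_i)
    mean_of_means: E_vi = (1/N_s) sum_j mean_j(v_i)
    """
    if labeling.n_labels == 0:
        raise ValueError("labeling has zero supervoxels")
    if mode == "mean_of_sds":
        values = labeling.sds.mean(axis=0)
    elif mode == "mean_of_means":
        values = labeling.means.mean(axis=0)
    else:
        raise ValueError(f"mode must be one of {EXPANSE_MODES}")
    return ExpanseThresholds(values=values, mode=mode)


def compute_similarity_field(
    labeling: SupervoxelLabeling,
    volumes: Sequence[ProbabilityVolume],
    expanse: ExpanseThresholds,
) -> SimilarityField:
    """S2(x,y,z) = 1 iff |I(x,y,z,v_i) - mean_sv(v_i)| < E_vi for ALL tissues.

    The inequality is strict and the conjunction runs over the three channels,
    so one S2 field is shared by the three per-tissue histons.
    """
    if len(volumes) != 3:
        raise ValueError("expected three tissue volumes (GM, WM, CSF)")
    mask = labeling.labels >= 0
    s2 = mask.copy()
    lab = labeling.labels[mask]
    for c, vol in enumerate(volumes):
        if vol.data.shape != labeling.labels.shape:
            raise ValueError("volume/labeling dimension mismatch")
        dt = np.abs(vol.data[mask].astype(np.float64) - labeling.means[lab, c])
        inside = dt < expanse.values[c]
        cur = s2[mask]
        cur &= inside
        s2[mask] = cur
    return SimilarityField(s2=s2.astype(np.uint8))


def compute_histon(
    volume: ProbabilityVolume, s2: SimilarityField, mask: BrainMask
) -> tuple:
    """256-bin histon and plain histogram over the masked voxels.

    histon(g) = sum over masked voxels of (1 + S2) * [I == g].
    """
    if not volume.is_quantized:
        raise ValueError("compute_histon requires a quantized volume")
    levels = volume.levels
    m = mask.mask
    vals = volume.data[m]
    weights = 1.0 + s2.s2[m]
    histon = np.bincount(vals, weights=weights, minlength=levels).astype(np.int64)
    histogram = np.bincount(vals, minlength=levels).astype(np.int64)
    return histon, histogram


def extract_feature_vector(
    subject: SubjectRecord,
    slic_params: SlicParams,
    config: Optional[HistonConfig] = None,
) -> HistonFeature:
    """Full per-subject pipeline: mask -> quantize -> SLIC -> expanse ->
    similarity field -> three histons -> concatenation (GM, WM, CSF)."""
    config = config or HistonConfig()
    vols = subject.load_volumes()
    ordered = [vols["GM"], vols["WM"], vols["CSF"]]
    # mask is built on the probability scale before quantization
    if all(v.is_quantized for v in ordered):
        scale = [
            ProbabilityVolume(v.data / (v.levels - 1), v.tissue) for v in ordered
        ]
        mask = build_brain_mask(*scale, threshold=config.mask_threshold)
        quantized = ordered
    else:
        mask = build_brain_mask(*ordered, threshold=config.mask_threshold)
        quantized = [quantize(v, config.levels) for v in ordered]
    if mask.included_voxels == 0:
        raise ValueError(f"subject {subject.subject_id}: empty brain mask")

    labeling = slic_segment(*quantized, mask=mask, params=slic_params)
    labeling = enforce_connectivity(
        labeling, *quantized, min_region_frac=slic_params.min_region_frac
    )
    expanse = compute_expanse(labeling, mode=config.expanse_mode)
    s2 = compute_similarity_field(labeling, quantized, expanse)

    histons = np.zeros((3, config.levels), dtype=np.int64)
    histograms = np.zeros((3, config.levels), dtype=np.int64)
    for c, vol in enumerate(quantized):
        histons[c], histograms[c] = compute_histon(vol, s2, mask)
    return HistonFeature(histons=histons, histograms=histograms, levels=config.levels)


def classic_histon(
    image: np.ndarray,
    neighbourhood: Sequence[int],
    expanse: float,
    levels: int = 256,
) -> tuple:
    """Classic fixed-neighbourhood histon (reference mode).

    ``image`` is (..., channels) with 2 or 3 spatial dims and integer levels.
    For each element, dt is the sum over the P x Q (x R) neighbourhood and
    over channels of squared intensity differences; S = 1 iff dt < expanse.
    Returns (histons, histograms) of shape (channels, levels).  Out-of-bounds
    neighbours are skipped (the sum runs over in-image neighbours only).
    """
    image = np.asarray(image)
    if image.ndim == len(neighbourhood):  # single channel
        image = image[..., None]
    spatial = image.shape[:-1]
    if len(neighbourhood) != len(spatial):
        raise ValueError("neighbourhood rank must match image rank")
    if any(n > s for n, s in zip(neighbourhood, spatial)):
        raise ValueError("neighbourhood larger than image")
    if any(n % 2 == 0 for n in neighbourhood):
        raise ValueError("neighbourhood sizes must be odd")

    img = image.astype(np.float64)
    dt = np.zeros(spatial, dtype=np.float64)
    offsets = np.meshgrid(*[np.arange(-(n // 2), n // 2 + 1) for n in neighbourhood],
                          indexing="ij")
    for off in zip(*[o.ravel() for o in offsets]):
        if all(o == 0 for o in off):
            continue
        src = tuple(
            slice(max(0, -o), min(s, s - o)) for o, s in zip(off, spatial)
        )
        dst = tuple(
            slice(max(0, o), min(s, s + o)) for o, s in zip(off, spatial)
        )
        diff = img[dst] - img[src]
        dt[dst] += (diff**2).sum(axis=-1)
    s = (dt < expanse).astype(np.int64)

    n_chan = image.shape[-1]
    histons = np.zeros((n_chan, levels), dtype=np.int64)
    histograms = np.zeros((n_chan, levels), dtype=np.int64)
    for c in range(n_chan):
        vals = image[..., c].astype(np.int64).ravel()
        histograms[c] = np.bincount(vals, minlength=levels)[:levels]
        histons[c] = np.bincount(
            vals, weights=(1 + s).ravel(), minlength=levels
        )[:levels].astype(np.int64)
    return histons, histograms
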