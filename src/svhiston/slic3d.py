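"""3D SLIC supervoxel segmentation over three tissue channels.

SLIC is a spatially constrained k-means.  Cluster centres are seeded on a
regular grid with spacing ``I_n = round((masked_voxels / n_supervoxels)**(1/3))``
and voxels are assigned to the centre minimising

    D_w = sqrt((d_c / m)**2 + (d_s / I_n)**2)

where ``d_c`` is the Euclidean distance over the three tissue-intensity
channels (GM, WM, CSF on the quantized 0..levels-1 scale), ``d_s`` the 3D
Euclidean voxel distance, and ``m`` the compactness parameter (larger m
emphasises spatial proximity).  Assignment is restricted to a cube of side
2·I_n around each centre, as in standard SLIC.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
from scipy import ndimage

from .io_volumes import BrainMask, ProbabilityVolume

logger = logging.getLogger(__name__)

# 6-connectivity structuring element
STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


@dataclasses.dataclass
class SlicParams:
    """Parameters of the supervoxel segmentation."""

    n_supervoxels: int = 1000
    compactness: float = 10.0
    max_iterations: int = 10
    min_region_frac: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_supervoxels < 1:
            raise ValueError("n_supervoxels must be >= 1")
        if self.compactness <= 0:
            raise ValueError("compactness must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclasses.dataclass
class SupervoxelLabeling:
    """Partition of the masked volume into supervoxels, with statistics.

    ``labels`` is -1 outside the mask and in [0, n_labels-1] inside.
    ``means``/``sds`` are (n_labels, 3) arrays in channel order GM, WM, CSF;
    sds use the population divisor N_pj.
    """

    labels: np.ndarray
    n_labels: int
    sizes: np.ndarray
    centroids: np.ndarray  # (n_labels, 3) spatial
    means: np.ndarray  # (n_labels, 3) intensity per channel
    sds: np.ndarray  # (n_labels, 3) population sd per channel
    spacing: int  # seed spacing I_n

    def validate_partition(self, mask: np.ndarray) -> None:
        """Raise if labels do not exactly partition the mask."""
        inside = self.labels[mask]
        if inside.size and (inside.min() < 0 or inside.max() >= self.n_labels):
            raise ValueError("masked voxel with out-of-range label")
        if np.any(self.labels[~mask] != -1):
            raise ValueError("label assigned outside the mask")
        if np.any(np.bincount(inside, minlength=self.n_labels) == 0):
            raise ValueError("empty supervoxel label")


def init_centroids(mask: BrainMask, n_supervoxels: int) -> np.ndarray:
    """Seed positions on a regular 3D grid, snapped onto the mask.

    Grid spacing is I_n = round((masked_voxels / n_supervoxels)**(1/3)).
    Seeds landing outside the mask are moved to the nearest masked voxel;
    duplicate seeds after snapping are dropped.
    """
    m = mask.mask
    n_masked = mask.included_voxels
    if n_masked == 0:
        raise ValueError("empty mask")
    spacing = max(1, int(round((n_masked / n_supervoxels) ** (1.0 / 3.0))))
    shape = np.array(m.shape)
    grids = []
    for ax in range(3):
        n_ax = max(1, int(shape[ax] // spacing))
        # centre the grid within the axis extent
        offset = (shape[ax] - (n_ax - 1) * spacing - 1) // 2
        grids.append(offset + spacing * np.arange(n_ax))
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    seeds = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    off_mask = ~m[seeds[:, 0], seeds[:, 1], seeds[:, 2]]
    if np.any(off_mask):
        # EDT of the complement gives, per voxel, the nearest masked voxel
        _, nearest = ndimage.distance_transform_edt(~m, return_indices=True)
        bad = seeds[off_mask]
        seeds[off_mask] = nearest[:, bad[:, 0], bad[:, 1], bad[:, 2]].T
    seeds = np.unique(seeds, axis=0)
    return seeds


def _compute_spacing(n_masked: int, n_supervoxels: int) -> int:
    return max(1, int(round((n_masked / n_supervoxels) ** (1.0 / 3.0))))


def assign_voxels(
    intensity: np.ndarray,
    mask: np.ndarray,
    spatial_centres: np.ndarray,
    colour_centres: np.ndarray,
    spacing: int,
    compactness: float,
    windowed: bool = True,
) -> np.ndarray:
    """One SLIC assignment sweep: label each masked voxel by minimal D_w.

    With ``windowed=True`` only voxels inside the 2·I_n cube around a centre
    compete for it; voxels no centre reaches are assigned to the globally
    nearest centre under D_w (logged).  Ties go to the lower centre index.
    """
    shape = mask.shape
    best = np.full(shape, np.inf, dtype=np.float64)
    labels = np.full(shape, -1, dtype=np.int32)
    coords = [np.arange(s, dtype=np.float64) for s in shape]

    for k in range(len(spatial_centres)):
        c = spatial_centres[k]
        if windowed:
            lo = np.maximum(np.round(c).astype(int) - spacing, 0)
            hi = np.minimum(np.round(c).astype(int) + spacing + 1, shape)
        else:
            lo = np.zeros(3, dtype=int)
            hi = np.asarray(shape)
        sl = tuple(slice(lo[i], hi[i]) for i in range(3))
        sub_mask = mask[sl]
        if not sub_mask.any():
            continue
        dx = coords[0][sl[0]] - c[0]
        dy = coords[1][sl[1]] - c[1]
        dz = coords[2][sl[2]] - c[2]
        ds2 = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        diff = intensity[sl] - colour_centres[k]
        dc2 = np.einsum("xyzc,xyzc->xyz", diff, diff)
        dw = np.sqrt(dc2 / compactness**2 + ds2 / spacing**2)
        better = (dw < best[sl]) & sub_mask
        best_sub = best[sl]
        best_sub[better] = dw[better]
        best[sl] = best_sub
        lab_sub = labels[sl]
        lab_sub[better] = k
        labels[sl] = lab_sub

    unreached = mask & (labels == -1)
    if unreached.any():
        logger.info("%d masked voxels outside all centre windows; assigning globally",
                    int(unreached.sum()))
        pts = np.argwhere(unreached)
        vals = intensity[unreached]
        ds2 = ((pts[:, None, :] - spatial_centres[None, :, :]) ** 2).sum(axis=2)
        dc2 = ((vals[:, None, :] - colour_centres[None, :, :]) ** 2).sum(axis=2)
        dw = np.sqrt(dc2 / compactness**2 + ds2 / spacing**2)
        labels[unreached] = np.argmin(dw, axis=1).astype(np.int32)
    return labels


def _stack_intensity(gm, wm, csf) -> np.ndarray:
    return np.stack(
        [gm.data, wm.data, csf.data], axis=-1
    ).astype(np.float64)


def _labeling_from_labels(
    labels: np.ndarray, intensity: np.ndarray, mask: np.ndarray, spacing: int
) -> SupervoxelLabeling:
    """Relabel consecutively and compute per-supervoxel statistics."""
    inside = labels[mask]
    uniq, dense = np.unique(inside, return_inverse=True)
    n = len(uniq)
    out = np.full(labels.shape, -1, dtype=np.int32)
    out[mask] = dense.astype(np.int32)

    sizes = np.bincount(dense, minlength=n).astype(np.int64)
    pts = np.argwhere(mask).astype(np.float64)
    centroids = np.stack(
        [np.bincount(dense, weights=pts[:, ax], minlength=n) for ax in range(3)],
        axis=1,
    ) / sizes[:, None]
    vals = intensity[mask]
    means = np.stack(
        [np.bincount(dense, weights=vals[:, c], minlength=n) for c in range(3)],
        axis=1,
    ) / sizes[:, None]
    sq = np.stack(
        [np.bincount(dense, weights=vals[:, c] ** 2, minlength=n) for c in range(3)],
        axis=1,
    ) / sizes[:, None]
    var = np.maximum(sq - means**2, 0.0)
    sds = np.sqrt(var)
    return SupervoxelLabeling(
        labels=out, n_labels=n, sizes=sizes, centroids=centroids,
        means=means, sds=sds, spacing=spacing,
    )


def slic_segment(
    gm: ProbabilityVolume,
    wm: ProbabilityVolume,
    csf: ProbabilityVolume,
    mask: BrainMask,
    params: SlicParams,
) -> SupervoxelLabeling:
    """Segment the aggregate three-channel volume into supervoxels.

    Iterates assignment (windowed nearest centre under D_w) and centre
    updates (spatial + colour means) until ``max_iterations`` or until the
    total L1 centroid displacement falls below one voxel.  Connectivity is
    NOT enforced here; see :func:`enforce_connectivity`.
    """
    for vol in (gm, wm, csf):
        if not vol.is_quantized:
            raise ValueError("slic_segment requires quantized volumes")
    if not (gm.shape == wm.shape == csf.shape == mask.mask.shape):
        raise ValueError("volume/mask dimension mismatch")
    if mask.included_voxels == 0:
        raise ValueError("empty mask")

    m = mask.mask
    intensity = _stack_intensity(gm, wm, csf)
    seeds = init_centroids(mask, params.n_supervoxels)
    spacing = _compute_spacing(mask.included_voxels, params.n_supervoxels)

    spatial = seeds.astype(np.float64)
    colour = intensity[seeds[:, 0], seeds[:, 1], seeds[:, 2]]

    labels = None
    for _ in range(params.max_iterations):
        labels = assign_voxels(
            intensity, m, spatial, colour, spacing, params.compactness
        )
        inside = labels[m]
        n = len(spatial)
        sizes = np.bincount(inside, minlength=n)
        occupied = sizes > 0
        pts = np.argwhere(m).astype(np.float64)
        vals = intensity[m]
        new_spatial = spatial.copy()
        new_colour = colour.copy()
        for ax in range(3):
            s = np.bincount(inside, weights=pts[:, ax], minlength=n)
            new_spatial[occupied, ax] = s[occupied] / sizes[occupied]
            c = np.bincount(inside, weights=vals[:, ax], minlength=n)
            new_colour[occupied, ax] = c[occupied] / sizes[occupied]
        shift = np.abs(new_spatial - spatial).sum()
        spatial, colour = new_spatial, new_colour
        if shift < 1.0:
            break

    # final assignment with converged centres
    labels = assign_voxels(intensity, m, spatial, colour, spacing, params.compactness)
    return _labeling_from_labels(labels, intensity, m, spacing)


def enforce_connectivity(
    labeling: SupervoxelLabeling,
    gm: ProbabilityVolume,
    wm: ProbabilityVolume,
    csf: ProbabilityVolume,
    min_region_frac: float = 0.25,
) -> SupervoxelLabeling:
    """Make every supervoxel 6-connected.

    Connected components are found per label under 6-connectivity.  The
    largest component keeps its label.  Other components smaller than
    ``min_region_frac * I_n**3`` voxels are merged into the largest 6-adjacent
    neighbouring label; components at or above the threshold become new
    labels.  Statistics are recomputed.
    """
    mask = labeling.labels >= 0
    labels = labeling.labels.copy()
    intensity = _stack_intensity(gm, wm, csf)
    min_size = max(1, int(round(min_region_frac * labeling.spacing**3)))

    # give every connected component its own provisional label; the largest
    # component of each original label keeps that label, others >= min_size
    # become new labels, smaller ones are marked pending for merging
    next_label = labeling.n_labels
    pending = []  # (voxel index tuple, provisional label)
    objects = ndimage.find_objects(labels + 1)  # label l -> slot l (1-based)
    for lab in range(labeling.n_labels):
        sl = objects[lab]
        if sl is None:
            continue
        region = labels[sl] == lab
        comp, n_comp = ndimage.label(region, structure=STRUCTURE_6)
        if n_comp <= 1:
            continue
        comp_sizes = np.bincount(comp.ravel())[1:]
        order = np.argsort(comp_sizes)[::-1]
        for rank, ci in enumerate(order):
            if rank == 0:
                continue  # largest keeps the label
            comp_mask = comp == ci + 1
            idx = tuple(
                ax_idx + s.start for ax_idx, s in zip(np.nonzero(comp_mask), sl)
            )
            labels[idx] = next_label
            if comp_sizes[ci] < min_size:
                pending.append((idx, next_label))
            next_label += 1

    # merge pending islands into the largest 6-adjacent settled label; an
    # island whose only neighbours are themselves pending waits, and a group
    # isolated from every settled label promotes one member per round
    sizes = np.bincount(labels[mask], minlength=next_label).astype(np.int64)
    settled = np.ones(next_label, dtype=bool)
    for _, prov in pending:
        settled[prov] = False
    while pending:
        progressed = False
        still = []
        for idx, prov in pending:
            # work inside the island's bounding box (+1 voxel margin)
            lo = [max(int(a.min()) - 1, 0) for a in idx]
            hi = [min(int(a.max()) + 2, s) for a, s in zip(idx, labels.shape)]
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            island = np.zeros(tuple(h - l for l, h in zip(lo, hi)), dtype=bool)
            island[tuple(a - l for a, l in zip(idx, lo))] = True
            border = ndimage.binary_dilation(island, structure=STRUCTURE_6) & ~island
            neigh = np.unique(labels[sl][border & mask[sl]])
            neigh = neigh[neigh >= 0]
            neigh = neigh[settled[neigh]]
            if neigh.size == 0:
                still.append((idx, prov))
                continue
            target = int(neigh[np.argmax(sizes[neigh])])
            labels[idx] = target
            sizes[target] += len(idx[0])
            sizes[prov] = 0
            progressed = True
        if not progressed and still:
            settled[still[0][1]] = True  # promote one isolated island
            still = still[1:]
        pending = still

    return _labeling_from_labels(labels, intensity, mask, labeling.spacing)


def supervoxel_statistics(
    labeling: SupervoxelLabeling, volume: ProbabilityVolume
) -> tuple:
    """Per-supervoxel mean and population standard deviation for one channel."""
    mask = labeling.labels >= 0
    inside = labeling.labels[mask]
    vals = volume.data[mask].astype(np.float64)
    n = labeling.n_labels
    sizes = np.bincount(inside, minlength=n)
    if np.any(sizes == 0):
        raise ValueError("label with zero voxels")
    means = np.bincount(inside, weights=vals, minlength=n) / sizes
    sq = np.bincount(inside, weights=vals**2, minlength=n) / sizes
    sds = np.sqrt(np.maximum(sq - means**2, 0.0))
    return means, sds


def is_six_connected(labeling: SupervoxelLabeling) -> bool:
    """True iff every label's voxel set is a single 6-connected component."""
    labels = labeling.labels
    objects = ndimage.find_objects(labels + 1)
    for lab in range(labeling.n_labels):
        sl = objects[lab]
        if sl is None:
            return False
        region = labels[sl] == lab
        _, n_comp = ndimage.label(region, structure=STRUCTURE_6)
        if n_comp != 1:
            return False
    return True


def statistics_frame(labeling: SupervoxelLabeling):
    """Statistics table: label, size, centroid, per-channel mean and sd."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label": np.arange(labeling.n_labels),
            "size": labeling.sizes,
            "cx": labeling.centroids[:, 0],
            "cy": labeling.centroids[:, 1],
            "cz": labeling.centroids[:, 2],
            "mean_gm": labeling.means[:, 0],
            "mean_wm": labeling.means[:, 1],
            "mean_csf": labeling.means[:, 2],
            "sd_gm": labeling.sds[:, 0],
            "sd_wm": labeling.sds[:, 1],
            "sd_csf": labeling.sds[:, 2],
        }
    )
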