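"""Synthetic brain phantoms: GM/WM/CSF probability cohorts with class effects.

The phantom is three concentric smoothed ellipsoids — a white-matter core, a
grey-matter shell and a cerebrospinal-fluid rim — emulating the output of a
unified tissue segmentation.  Disease (AD) differs from control (CN) through
two orthogonal knobs:

* atrophy ``delta_gm`` — a fraction of GM probability mass shifted to CSF,
  emulating grey-matter volume loss;
* ambiguity ``omega`` — the width (voxels) of the sigmoidal transition
  between tissues, emulating the "ambiguous" partial-volume voxels that
  tissue segmentation produces around atrophic areas (AD uses a wider
  transition than CN).

Additive Gaussian noise (sd ``sigma``) is clipped to [0, 1], and voxels whose
tissue probabilities sum above 1 are renormalized.  Everything is
deterministic given the parameters and a seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np

from .io_volumes import (
    ProbabilityVolume,
    SubjectRecord,
    write_manifest,
    write_probability_volume,
)


@dataclasses.dataclass
class PhantomParams:
    """Geometry and effect sizes of the synthetic cohort.

    Radii are in voxels along the first axis; ``axis_ratios`` make the
    ellipsoid mildly anisotropic.  Defaults give a cohort that a single CPU
    processes in minutes: a 48-voxel grid with a clear three-tissue layering.
    """

    grid_size: int = 48
    wm_radius: float = 10.0
    gm_radius: float = 16.0
    csf_radius: float = 20.0
    axis_ratios: tuple = (1.0, 0.9, 0.95)
    delta_gm: float = 0.2  # GM mass fraction moved to CSF in AD
    omega_ad: float = 3.0  # transition width (voxels), AD
    omega_cn: float = 1.0  # transition width (voxels), CN
    sigma: float = 0.02  # additive Gaussian noise sd (probability units)
    jitter: float = 0.05  # per-subject radius jitter (fraction)

    def __post_init__(self) -> None:
        if not (self.csf_radius > self.gm_radius > self.wm_radius > 0):
            raise ValueError("radii must satisfy csf_radius > gm_radius > wm_radius > 0")
        if not (0.0 <= self.delta_gm <= 0.5):
            raise ValueError("delta_gm must be in [0, 0.5]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        max_extent = self.csf_radius * (1 + self.jitter) * max(self.axis_ratios)
        if max_extent >= self.grid_size / 2:
            raise ValueError("csf_radius (with jitter) exceeds the grid")


@dataclasses.dataclass
class SyntheticCohort:
    """Generated subjects with in-memory volumes and demographics."""

    subjects: list
    params: PhantomParams
    seed: int


def _soft_inside(r: np.ndarray, radius: float, omega: float) -> np.ndarray:
    """Sigmoidal indicator of being inside ``radius``; omega -> 0 is crisp."""
    if omega <= 0:
        return (r < radius).astype(np.float64)
    return 1.0 / (1.0 + np.exp((r - radius) / omega))


def generate_phantom(
    cls: str,
    params: PhantomParams,
    seed: int,
    radius_scale: tuple = (1.0, 1.0, 1.0),
) -> dict:
    """Generate the GM/WM/CSF probability volumes of one subject.

    ``radius_scale`` applies per-subject geometry jitter (scales the three
    radii).  Returns a dict tissue -> unquantized ProbabilityVolume.
    """
    if cls not in ("AD", "CN"):
        raise ValueError("cls must be AD or CN")
    n = params.grid_size
    centre = (n - 1) / 2.0
    ax = [np.arange(n, dtype=np.float64) - centre for _ in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    # elliptical radius, in voxels along the first axis
    r = np.sqrt(
        (gx / params.axis_ratios[0]) ** 2
        + (gy / params.axis_ratios[1]) ** 2
        + (gz / params.axis_ratios[2]) ** 2
    )

    omega = params.omega_ad if cls == "AD" else params.omega_cn
    r_wm = params.wm_radius * radius_scale[0]
    r_gm = params.gm_radius * radius_scale[1]
    r_csf = params.csf_radius * radius_scale[2]

    # the brain/background boundary is skull-stripped and stays crisp
    # (fixed width); omega widens only the inter-tissue transitions inside
    envelope = _soft_inside(r, r_csf, 0.5)
    inside_wm = _soft_inside(r, r_wm, omega)
    inside_gm = _soft_inside(r, r_gm, omega)
    wm = envelope * inside_wm
    gm = envelope * np.maximum(inside_gm - inside_wm, 0.0)
    csf = envelope * np.maximum(1.0 - inside_gm, 0.0)

    # segmentation output has an exact-zero background: cut the sigmoid tail
    background = envelope < 0.01
    for vol in (wm, gm, csf):
        vol[background] = 0.0

    if cls == "AD" and params.delta_gm > 0:
        shifted = params.delta_gm * gm
        gm = gm - shifted
        csf = csf + shifted

    rng = np.random.default_rng(seed)
    if params.sigma > 0:
        # noise only where there is any tissue signal, so background stays clean
        signal = (wm + gm + csf) > 1e-6
        for vol in (gm, wm, csf):
            noise = rng.normal(0.0, params.sigma, size=vol.shape)
            vol += noise * signal
    gm, wm, csf = (np.clip(v, 0.0, 1.0) for v in (gm, wm, csf))
    total = gm + wm + csf
    over = total > 1.0
    if np.any(over):
        for vol in (gm, wm, csf):
            vol[over] /= total[over]

    return {
        "GM": ProbabilityVolume(gm, "GM"),
        "WM": ProbabilityVolume(wm, "WM"),
        "CSF": ProbabilityVolume(csf, "CSF"),
    }


def generate_cohort(
    n_ad: int,
    n_cn: int,
    params: Optional[PhantomParams] = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a cohort of AD and CN subjects with demographics.

    Each subject gets an independent seed derived from the master seed, a
    ±jitter geometry perturbation, an age drawn uniformly from [60, 90] and a
    gender assigned to keep the cohort balanced within each class.
    """
    if n_ad < 1 or n_cn < 1:
        raise ValueError("need at least one subject per class")
    params = params or PhantomParams()
    master = np.random.default_rng(seed)
    subjects = []
    for cls, count in (("AD", n_ad), ("CN", n_cn)):
        for i in range(count):
            geom_seed = int(master.integers(0, 2**31 - 1))
            noise_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(geom_seed)
            scale = tuple(
                1.0 + rng.uniform(-params.jitter, params.jitter) for _ in range(3)
            )
            vols = generate_phantom(cls, params, seed=noise_seed, radius_scale=scale)
            subjects.append(
                SubjectRecord(
                    subject_id=f"{cls.lower()}{i:03d}",
                    label=cls,
                    age=float(np.round(60 + 30 * rng.uniform(), 1)),
                    gender="M" if i % 2 == 0 else "F",
                    volumes=vols,
                )
            )
    return SyntheticCohort(subjects=subjects, params=params, seed=seed)


def materialize_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write cohort volumes as NIfTI plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for s in cohort.subjects:
        paths = {}
        for tissue, vol in s.volumes.items():
            p = out_dir / f"{s.subject_id}_{tissue.lower()}.nii.gz"
            write_probability_volume(vol, p)
            # manifest-relative path: the manifest lives in the same directory
            paths[tissue] = p.name
        written.append(
            SubjectRecord(
                subject_id=s.subject_id,
                label=s.label,
                age=s.age,
                gender=s.gender,
                gm_path=paths["GM"],
                wm_path=paths["WM"],
                csf_path=paths["CSF"],
            )
        )
    manifest = out_dir / "manifest.csv"
    write_manifest(written, manifest)
    return manifest
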