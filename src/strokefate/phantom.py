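"""Two-hemisphere digital rat-brain phantoms with planted ischemic lesions.

The phantom is a coarse parcellated slab: a left and a right hemisphere that
are exact mirror images before lesion planting, containing cortex, striatum,
the contralateral reference territories (S1FL, S2, CPu), a ventricular CSF
compartment and a handful of arterial voxels used by AIF extraction.  A
lesion of known extent is planted in the right hemisphere and partitioned
into three tissue fates:

* lesion core — acutely ischemic tissue that proceeds to infarction,
* salvageable tissue — acutely ischemic tissue that recovers,
* delayed injury — tissue that infarcts only after recanalization.

The planted acute (diffusion) lesion is core + salvageable; the planted
subacute (T2) lesion is core + delayed.  These are precisely the set
identities the segmentation stage must reproduce, so every planted mask is
retained as ground truth.

Ground-truth ADC, T2, CBF, CBV and MTT maps are provided per imaging session
(during occlusion, 0.5 h after recanalization, day 4), with MTT = CBV/CBF
wherever CBF > 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import hemisphere_masks, mirror

__all__ = [
    "LABELS",
    "LesionSpec",
    "Phantom",
    "make_phantom",
    "TIMEPOINTS",
]

# Atlas label codes
LABELS = {
    "background": 0,
    "csf": 1,
    "cortex": 2,
    "striatum": 3,
    "s1fl": 4,
    "s2": 5,
    "cpu": 6,
    "vessel": 7,
}

#: Imaging sessions: during occlusion, 0.5 h after recanalization, day 4.
TIMEPOINTS = ("occlusion", "post_0.5h", "day4")

# Baseline tissue properties: ADC (mm^2/s), T2 (ms), CBF (arb/s), CBV (arb).
# MTT (s) follows from CBV/CBF.  Values are rodent-typical at 9.4 T.
_TISSUE_PROPS = {
    "cortex": (0.76e-3, 48.0, 2.00, 4.00),
    "s1fl": (0.74e-3, 47.0, 2.10, 4.20),
    "s2": (0.75e-3, 47.5, 2.05, 4.10),
    "striatum": (0.72e-3, 45.0, 1.80, 3.96),
    "cpu": (0.71e-3, 44.5, 1.75, 3.85),
    "csf": (2.60e-3, 150.0, 0.10, 0.12),
    "vessel": (0.90e-3, 60.0, 8.0, 4.80),
}

# Multiplicative lesion perturbations per session, per fate region.
# ADC drops acutely in ischemic tissue and pseudo-normalizes; T2 rises in the
# subacute infarct; perfusion falls during occlusion, delayed-injury tissue
# stays hypoperfused just after recanalization, and the lesion becomes
# hyperperfused by day 4.
_LESION_EFFECTS = {
    "occlusion": {
        "adc": {"core": 0.60, "salvageable": 0.65, "delayed": 0.95},
        "t2": {"core": 1.02, "salvageable": 1.0, "delayed": 1.0},
        "cbf": {"core": 0.22, "salvageable": 0.30, "delayed": 0.45},
        "cbv": {"core": 0.60, "salvageable": 0.70, "delayed": 0.80},
    },
    "post_0.5h": {
        "adc": {"core": 0.72, "salvageable": 0.90, "delayed": 0.97},
        "t2": {"core": 1.10, "salvageable": 1.02, "delayed": 1.03},
        "cbf": {"core": 1.00, "salvageable": 1.05, "delayed": 0.70},
        "cbv": {"core": 1.00, "salvageable": 1.02, "delayed": 0.85},
    },
    "day4": {
        "adc": {"core": 1.05, "salvageable": 1.00, "delayed": 0.90},
        "t2": {"core": 1.60, "salvageable": 1.02, "delayed": 1.55},
        "cbf": {"core": 1.30, "salvageable": 1.25, "delayed": 1.30},
        "cbv": {"core": 1.25, "salvageable": 1.20, "delayed": 1.22},
    },
}


@dataclass
class LesionSpec:
    """Geometry and fate composition of a planted right-hemisphere lesion.

    The lesion is an ellipsoid centred at ``center`` (voxel coordinates, must
    lie in the right hemisphere) with semi-axes ``radii`` (voxels).  Voxels
    with normalized radius <= ``core_fraction**(1/3)`` form the core; the
    remaining shell is split by anterior-posterior position into salvageable
    tissue (the fraction ``salvageable_shell_fraction`` with the lowest y)
    and delayed injury (the rest).
    """

    center: tuple[float, float, float] = (29.0, 20.0, 4.0)
    radii: tuple[float, float, float] = (7.0, 9.0, 3.2)
    core_fraction: float = 0.5
    salvageable_shell_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.core_fraction <= 1.0):
            raise ValueError("core_fraction must be in [0, 1]")
        if not (0.0 <= self.salvageable_shell_fraction <= 1.0):
            raise ValueError("salvageable_shell_fraction must be in [0, 1]")
        if any(r <= 0 for r in self.radii):
            raise ValueError("lesion radii must be positive")


@dataclass
class Phantom:
    """Parcellated two-hemisphere phantom with per-session ground truth."""

    label_volume: np.ndarray
    voxel_size: tuple[float, float, float]
    truth_maps: dict[str, dict[str, np.ndarray]]  # timepoint -> param -> map
    lesion_truth: dict[str, np.ndarray]  # acute/subacute/core/salvageable/delayed
    midline_axis: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_volume != LABELS["background"]

    @property
    def csf_mask(self) -> np.ndarray:
        return self.label_volume == LABELS["csf"]

    @property
    def arterial_mask(self) -> np.ndarray:
        return self.label_volume == LABELS["vessel"]

    @property
    def left_mask(self) -> np.ndarray:
        left, _ = hemisphere_masks(self.shape)
        return left

    @property
    def right_mask(self) -> np.ndarray:
        _, right = hemisphere_masks(self.shape)
        return right

    @property
    def voxel_volume_ul(self) -> float:
        return float(np.prod(self.voxel_size))

    def truth(self, timepoint: str) -> dict[str, np.ndarray]:
        return self.truth_maps[timepoint]

    def reference_labels_mask(self, contralateral: bool = True) -> np.ndarray:
        """Mask of the MCA-territory reference labels (S1FL, S2, CPu)."""
        lab = self.label_volume
        m = (
            (lab == LABELS["s1fl"])
            | (lab == LABELS["s2"])
            | (lab == LABELS["cpu"])
        )
        return m & (self.left_mask if contralateral else self.right_mask)

    def downsample(self, factors: tuple[int, int, int] = (2, 2, 1)) -> "Phantom":
        """Nearest-neighbour downsampled phantom (coarser perfusion grid)."""
        fx, fy, fz = factors
        sl = (slice(None, None, fx), slice(None, None, fy), slice(None, None, fz))
        truth = {
            tp: {k: v[sl].copy() for k, v in maps.items()}
            for tp, maps in self.truth_maps.items()
        }
        lesion = {k: v[sl].copy() for k, v in self.lesion_truth.items()}
        return Phantom(
            label_volume=self.label_volume[sl].copy(),
            voxel_size=(
                self.voxel_size[0] * fx,
                self.voxel_size[1] * fy,
                self.voxel_size[2] * fz,
            ),
            truth_maps=truth,
            lesion_truth=lesion,
            midline_axis=self.midline_axis,
        )


def _build_labels(shape: tuple[int, int, int]) -> np.ndarray:
    """Mirror-symmetric parcellation: construct the left half, reflect it."""
    nx, ny, nz = shape
    if nx % 2 != 0:
        raise ValueError("phantom requires an even left-right dimension")
    half = nx // 2
    left = np.zeros((half, ny, nz), dtype=np.int16)

    x = np.arange(half)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]

    brain = (x >= 1) & (y >= 2) & (y < ny - 2)
    lateral_cortex = brain & (x < max(2, half * 0.3))
    striatum = brain & (x >= max(2, half * 0.3)) & (x < half * 0.7)
    medial = brain & (x >= half * 0.7)

    left[np.broadcast_to(lateral_cortex, left.shape)] = LABELS["cortex"]
    left[np.broadcast_to(medial, left.shape)] = LABELS["cortex"]
    left[np.broadcast_to(striatum, left.shape)] = LABELS["striatum"]

    # Reference territories inside cortex/striatum
    s1fl = lateral_cortex & (y >= ny * 0.30) & (y < ny * 0.50)
    s2 = lateral_cortex & (y >= ny * 0.50) & (y < ny * 0.70)
    cpu = striatum & (y >= ny * 0.30) & (y < ny * 0.65)
    left[np.broadcast_to(s1fl, left.shape)] = LABELS["s1fl"]
    left[np.broadcast_to(s2, left.shape)] = LABELS["s2"]
    left[np.broadcast_to(cpu, left.shape)] = LABELS["cpu"]

    # Ventricle near the midline, central slices only
    vent = (
        (x >= half * 0.82)
        & (x < half * 0.95)
        & (y >= ny * 0.40)
        & (y < ny * 0.55)
        & (z >= nz * 0.25)
        & (z < nz * 0.75)
    )
    left[np.broadcast_to(vent, left.shape)] = LABELS["csf"]

    # A few lateral arterial voxels (MCA branches) for AIF extraction
    # Even x/y indices so the voxels survive nearest-neighbour downsampling
    # to the coarser perfusion grid.
    zm = nz // 2
    for yy in (ny // 2 - 6, ny // 2, ny // 2 + 6):
        yy -= yy % 2
        if 2 <= yy < ny - 2:
            left[2, yy, zm] = LABELS["vessel"]
            if nz > 2:
                left[2, yy, max(zm - 1, 0)] = LABELS["vessel"]

    labels = np.concatenate([left, np.flip(left, axis=0)], axis=0)
    return labels


def _lesion_masks(
    shape: tuple[int, int, int], spec: LesionSpec, labels: np.ndarray
) -> dict[str, np.ndarray]:
    nx, ny, nz = shape
    cx, cy, cz = spec.center
    rx, ry, rz = spec.radii
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    rho = np.sqrt(
        ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
    )
    tissue = (labels != LABELS["background"]) & (labels != LABELS["csf"])
    lesion = (rho <= 1.0) & tissue
    if not lesion.any():
        raise ValueError("lesion specification produced an empty lesion")
    if lesion[: nx // 2].any():
        raise ValueError("lesion crosses the hemispheric midline")

    core = lesion & (rho <= spec.core_fraction ** (1.0 / 3.0))
    shell_idx = np.argwhere(lesion & ~core)
    # Anterior (low-y) part of the shell becomes salvageable tissue.
    order = np.lexsort((shell_idx[:, 2], shell_idx[:, 0], shell_idx[:, 1]))
    shell_idx = shell_idx[order]
    n_salv = int(round(spec.salvageable_shell_fraction * len(shell_idx)))
    salvageable = np.zeros(shape, dtype=bool)
    delayed = np.zeros(shape, dtype=bool)
    if len(shell_idx):
        si = shell_idx[:n_salv]
        di = shell_idx[n_salv:]
        salvageable[si[:, 0], si[:, 1], si[:, 2]] = True
        delayed[di[:, 0], di[:, 1], di[:, 2]] = True

    return {
        "core": core,
        "salvageable": salvageable,
        "delayed": delayed,
        "acute": core | salvageable,
        "subacute": core | delayed,
    }


def make_phantom(
    shape: tuple[int, int, int] = (40, 40, 8),
    lesion_spec: LesionSpec | None = None,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (0.3, 0.3, 1.2),
    tissue_jitter: float = 0.03,
) -> Phantom:
    """Build a mirror-symmetric phantom and plant a right-hemisphere lesion.

    Parameters
    ----------
    shape : tuple of int
        Grid dimensions; the left-right axis (0) must be even.
    lesion_spec : LesionSpec
        Lesion geometry and fate composition; defaults to a mid-size lesion
        spanning lateral cortex and striatum.
    seed : int
        Seed for the per-voxel tissue heterogeneity fields.
    voxel_size : tuple of float
        Physical voxel dimensions in mm.
    tissue_jitter : float
        Relative SD of smooth within-tissue variability applied to ADC, T2
        and perfusion truth (MTT recomputed to preserve MTT = CBV/CBF).
    """
    if lesion_spec is None:
        lesion_spec = LesionSpec(
            center=(shape[0] * 0.725, shape[1] * 0.5, (shape[2] - 1) / 2.0),
            radii=(shape[0] * 0.175, shape[1] * 0.225, max(shape[2] * 0.4, 1.5)),
        )
    rng = np.random.default_rng(seed)
    labels = _build_labels(shape)
    lesion = _lesion_masks(shape, lesion_spec, labels)

    # Baseline (pre-stroke) property maps from the tissue table
    base = {p: np.zeros(shape, dtype=np.float64) for p in ("adc", "t2", "cbf", "cbv")}
    for name, (adc, t2, cbf, cbv) in _TISSUE_PROPS.items():
        m = labels == LABELS[name]
        base["adc"][m] = adc
        base["t2"][m] = t2
        base["cbf"][m] = cbf
        base["cbv"][m] = cbv

    # Smooth mirror-symmetric heterogeneity so reference statistics have
    # non-degenerate spread even on noiseless acquisitions.
    if tissue_jitter > 0:
        tissue = (labels != LABELS["background"]) & (labels != LABELS["csf"])
        half = shape[0] // 2
        for p in ("adc", "t2", "cbf", "cbv"):
            f_half = 1.0 + tissue_jitter * rng.standard_normal((half,) + shape[1:])
            f = np.concatenate([f_half, np.flip(f_half, axis=0)], axis=0)
            base[p][tissue] *= f[tissue]

    truth_maps: dict[str, dict[str, np.ndarray]] = {}
    for tp in TIMEPOINTS:
        eff = _LESION_EFFECTS[tp]
        maps = {p: base[p].copy() for p in base}
        for fate in ("core", "salvageable", "delayed"):
            m = lesion[fate]
            for p in ("adc", "t2", "cbf", "cbv"):
                maps[p][m] *= eff[p][fate]
        mtt = np.zeros(shape, dtype=np.float64)
        pos = maps["cbf"] > 0
        mtt[pos] = maps["cbv"][pos] / maps["cbf"][pos]
        maps["mtt"] = mtt
        truth_maps[tp] = maps

    return Phantom(
        label_volume=labels,
        voxel_size=voxel_size,
        truth_maps=truth_maps,
        lesion_truth=lesion,
    )
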