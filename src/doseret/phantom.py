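"""Synthetic thorax phantom cohorts for plan-retrieval experiments.

Real plan databases couple CT-derived anatomy with optimizer output and
cannot be shipped; this module generates parametric stand-ins with the
statistical structure the retrieval method relies on:

* anatomy masks (body, left/right lung, heart, spinal cord, GTV, PTV) on a
  regular grid, with ``total_lung = lungs \\ GTV``;
* plan-class-dependent clinical doses built from coplanar Gaussian-profile
  beams crossing at the PTV centroid plus a conformal target component,
  renormalized so that D95 of the PTV equals the prescription exactly;
* paired "virtual" doses emulating the error of a dose-prediction model
  (smoothing, a smooth multiplicative field, voxel noise), standing in for
  the mask-to-dose predictor that produces retrieval queries.

Each plan class uses a distinct coplanar beam arrangement (4–7 beams), so
between-class dose patterns differ far more than within-class ones — the
premise that makes nearest-neighbour retrieval of optimization parameters
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import DoseGrid, PlanDatabase, PlanRecord, StructureSet

__all__ = [
    "PhantomSpec",
    "VirtualizerSpec",
    "CohortSpec",
    "build_anatomy",
    "synthesize_clinical_dose",
    "emulate_virtual_dose",
    "generate_cohort",
]


@dataclass
class PhantomSpec:
    """Geometry of the synthetic thorax, as fractions of the grid extent."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    body_semiaxes: tuple[float, float, float] = (0.46, 0.40, 0.48)
    lung_semiaxes: tuple[float, float, float] = (0.15, 0.22, 0.30)
    lung_center_x: tuple[float, float] = (0.30, 0.70)  # left, right
    heart_center: tuple[float, float, float] = (0.42, 0.44, 0.42)
    heart_radius: float = 0.11
    cord_center_xy: tuple[float, float] = (0.50, 0.80)
    cord_radius: float = 0.035
    tumor_radius_vox: tuple[float, float] = (2.0, 4.0)
    ptv_margin_vox: int = 2
    tumor_jitter: float = 0.06  # placement jitter, fraction of extent

    def validate(self) -> None:
        if self.ptv_margin_vox < 1:
            raise ValueError("PTV margin must be at least 1 voxel")
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid too small for the organ geometry")


@dataclass
class VirtualizerSpec:
    """Error model of the virtual-dose predictor emulator.

    smooth_sigma_mm
        Gaussian blur width: predictors lose high-frequency dose detail.
    field_amplitude
        Amplitude of a smooth multiplicative error field (systematic
        regional over/under-prediction), as a fraction of the local dose.
    noise_sd_gy
        Independent voxel noise in Gy.
    """

    smooth_sigma_mm: float = 6.0
    field_amplitude: float = 0.05
    noise_sd_gy: float = 1.0

    def validate(self) -> None:
        if min(self.smooth_sigma_mm, self.field_amplitude, self.noise_sd_gy) < 0:
            raise ValueError("virtualizer parameters must be non-negative")


@dataclass
class CohortSpec:
    """A cohort of synthetic plans split across beam-geometry classes."""

    n_plans: int = 60
    n_classes: int = 3
    prescription_gy: float = 60.0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    virtualizer: VirtualizerSpec = field(default_factory=VirtualizerSpec)
    beam_sigma_vox: float = 4.5  # in-plane Gaussian beam profile width
    falloff_vox: float = 2.5  # conformal component exponential falloff
    beam_weight: float = 0.7  # beam-slab share of the unnormalized dose
    angle_jitter_deg: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_plans < 1 or self.n_classes < 1:
            raise ValueError("n_plans and n_classes must be positive")
        if self.n_classes > self.n_plans:
            raise ValueError("n_classes cannot exceed n_plans")
        self.phantom.validate()
        self.virtualizer.validate()

    def class_beam_angles(self, class_id: int) -> np.ndarray:
        """Beam gantry angles (degrees) for a plan class.

        Class ``c`` uses ``4 + (c mod 4)`` equally spaced coplanar beams
        (staying in the 4–7 beam range typical of lung IMRT) with a
        class-specific angular offset, so different classes have distinct,
        largely non-overlapping beam arrangements.
        """
        if class_id < 0 or class_id >= self.n_classes:
            raise ValueError(f"class_id {class_id} out of range [0, {self.n_classes})")
        n_beams = 4 + (class_id % 4)
        offset = 360.0 * class_id / (self.n_classes * max(n_beams, 1)) + 13.0 * class_id
        return (offset + np.arange(n_beams) * 360.0 / n_beams) % 360.0


def _ellipsoid(shape, center_frac, semiaxes_frac) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, n, c, a in zip(grids, shape, center_frac, semiaxes_frac):
        acc = acc + ((g - c * (n - 1)) / (a * n)) ** 2
    return acc <= 1.0


def _ball(radius_vox: float) -> np.ndarray:
    r = int(np.ceil(radius_vox))
    z, y, x = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return x * x + y * y + z * z <= radius_vox * radius_vox


def build_anatomy(spec: PhantomSpec, seed: int) -> StructureSet:
    """Generate one patient's structure masks; deterministic given *seed*.

    The tumor (GTV) is a sphere placed inside a randomly chosen lung with
    jittered position and radius; the PTV is the GTV dilated by the margin.
    Raises if the geometry degenerates to an empty PTV.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    shape = spec.grid_shape

    body = _ellipsoid(shape, (0.5, 0.5, 0.5), spec.body_semiaxes)
    lung_l = _ellipsoid(shape, (spec.lung_center_x[0], 0.48, 0.5), spec.lung_semiaxes)
    lung_r = _ellipsoid(shape, (spec.lung_center_x[1], 0.48, 0.5), spec.lung_semiaxes)
    heart = _ellipsoid(shape, spec.heart_center, (spec.heart_radius,) * 3)
    lung_l &= body & ~heart
    lung_r &= body & ~heart

    # spinal cord: cylinder along z at a fixed posterior position
    gx, gy = np.ogrid[0 : shape[0], 0 : shape[1]]
    cx, cy = (spec.cord_center_xy[0] * (shape[0] - 1), spec.cord_center_xy[1] * (shape[1] - 1))
    r_vox = spec.cord_radius * shape[0]
    cord2d = (gx - cx) ** 2 + (gy - cy) ** 2 <= max(r_vox, 1.0) ** 2
    lo, hi = int(0.1 * shape[2]), int(0.9 * shape[2])
    cord = np.zeros(shape, dtype=bool)
    cord[:, :, lo:hi] = cord2d[..., None]

    # tumor inside a random lung
    side = rng.integers(0, 2)
    lung = lung_l if side == 0 else lung_r
    center = np.array(ndimage.center_of_mass(lung))
    jitter = rng.uniform(-spec.tumor_jitter, spec.tumor_jitter, size=3) * np.array(shape)
    tumor_center = np.clip(center + jitter, 2, np.array(shape) - 3)
    radius = rng.uniform(*spec.tumor_radius_vox)
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, tumor_center))
    gtv = (dist2 <= radius**2) & body
    if not gtv.any():
        raise ValueError("degenerate geometry: GTV is empty")
    ptv = ndimage.binary_dilation(gtv, structure=_ball(spec.ptv_margin_vox)) & body
    if not ptv.any():
        raise ValueError("degenerate geometry: PTV is empty")

    ss = StructureSet(
        masks={
            "PTV": ptv,
            "GTV": gtv,
            "lung_L": lung_l,
            "lung_R": lung_r,
            "total_lung": np.zeros(shape, dtype=bool),
            "heart": heart,
            "spinal_cord": cord,
        }
    )
    ss.derive_total_lung()
    ss.validate()
    return ss


def _normalize_d95(values: np.ndarray, ptv: np.ndarray, rx: float) -> np.ndarray:
    """Scale so the dose received by 95% of PTV voxels equals *rx* exactly."""
    ptv_doses = np.sort(values[ptv])[::-1]
    rank = int(np.ceil(0.95 * ptv_doses.size))
    d95 = ptv_doses[rank - 1]
    if d95 <= 0:
        raise ValueError("cannot normalize: D95 of PTV is zero")
    return values * (rx / d95)


def synthesize_clinical_dose(
    structures: StructureSet,
    class_id: int,
    cohort: CohortSpec,
    seed: int,
) -> DoseGrid:
    """Class-dependent clinical dose: beam slabs + conformal PTV component.

    Each beam is a coplanar slab through the PTV centroid with a Gaussian
    profile perpendicular to its axis (in the axial plane) and a Gaussian
    extent in z matched to the PTV; the conformal component decays
    exponentially with distance from the PTV surface.  The sum is
    renormalized so D95(PTV) = prescription to within 1e-6 Gy.
    """
    cohort.validate()
    ptv = structures["PTV"]
    if not ptv.any():
        raise ValueError("empty PTV")
    rng = np.random.default_rng(seed)
    shape = structures.shape
    centroid = np.array(ndimage.center_of_mass(ptv))

    gx, gy, gz = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    dx, dy = gx - centroid[0], gy - centroid[1]
    ptv_extent_z = max(np.ptp(np.nonzero(ptv)[2]) / 2.0 + cohort.beam_sigma_vox, 2.0)
    z_profile = np.exp(-0.5 * ((gz - centroid[2]) / ptv_extent_z) ** 2)

    angles = cohort.class_beam_angles(class_id)
    angles = angles + rng.uniform(-cohort.angle_jitter_deg, cohort.angle_jitter_deg, angles.size)
    beams = np.zeros(shape, dtype=float)
    for theta in np.deg2rad(angles):
        # perpendicular distance (in-plane) from the beam's central axis
        u = -np.sin(theta) * dx + np.cos(theta) * dy
        beams += np.exp(-0.5 * (u / cohort.beam_sigma_vox) ** 2)
    beams = beams / angles.size * z_profile

    dist_out = ndimage.distance_transform_edt(~ptv)
    conformal = np.exp(-dist_out / max(cohort.falloff_vox, 1e-9))
    # small seeded intra-PTV ripple so same-class plans are not identical
    ripple = 1.0 + 0.02 * rng.standard_normal(shape)
    raw = (cohort.beam_weight * beams + (1.0 - cohort.beam_weight) * conformal) * ripple
    raw = np.clip(raw, 0.0, None)
    values = _normalize_d95(raw, ptv, cohort.prescription_gy)
    return DoseGrid(
        values=values.astype(np.float32),
        spacing_mm=cohort.phantom.spacing_mm,
    )


def emulate_virtual_dose(
    clinical: DoseGrid,
    structures: StructureSet,
    v: VirtualizerSpec,
    prescription: float,
    seed: int,
) -> DoseGrid:
    """Corrupt a clinical dose the way a dose predictor would.

    Gaussian smoothing at ``smooth_sigma_mm``, multiplication by a smooth
    random field ``1 ± field_amplitude``, additive voxel noise, clamping at
    zero, and D95 renormalization.  With all three parameters zero the
    output equals the clinical dose voxelwise.
    """
    v.validate()
    rng = np.random.default_rng(seed)
    values = np.asarray(clinical.values, dtype=float)
    if v.smooth_sigma_mm > 0:
        sigma_vox = [v.smooth_sigma_mm / s for s in clinical.spacing_mm]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    changed = v.smooth_sigma_mm > 0
    if v.field_amplitude > 0:
        white = rng.standard_normal(values.shape)
        fld = ndimage.gaussian_filter(white, sigma=max(values.shape) / 6.0)
        peak = np.abs(fld).max()
        if peak > 0:
            fld = fld / peak
        values = values * (1.0 + v.field_amplitude * fld)
        changed = True
    if v.noise_sd_gy > 0:
        values = values + v.noise_sd_gy * rng.standard_normal(values.shape)
        changed = True
    values = np.clip(values, 0.0, None)
    if changed:
        values = _normalize_d95(values, structures["PTV"], prescription)
    return DoseGrid(
        values=values.astype(np.float32),
        spacing_mm=clinical.spacing_mm,
        origin_mm=clinical.origin_mm,
    )


def generate_cohort(cohort: CohortSpec) -> PlanDatabase:
    """Generate a full synthetic plan database.

    Class labels are assigned round-robin; the OP payload records the class
    id, the beam angles and synthetic objective weights (it is treated as
    opaque downstream).  Fully reproducible from ``cohort.seed``.
    """
    cohort.validate()
    master = np.random.default_rng(cohort.seed)
    records = []
    for i in range(cohort.n_plans):
        class_id = i % cohort.n_classes
        s_anat, s_dose, s_virt, s_ops = master.integers(0, 2**31 - 1, size=4)
        structures = build_anatomy(cohort.phantom, int(s_anat))
        clinical = synthesize_clinical_dose(structures, class_id, cohort, int(s_dose))
        virtual = emulate_virtual_dose(
            clinical, structures, cohort.virtualizer, cohort.prescription_gy, int(s_virt)
        )
        ops_rng = np.random.default_rng(int(s_ops))
        ops = {
            "class_id": class_id,
            "beam_angles_deg": [round(float(a), 2) for a in cohort.class_beam_angles(class_id)],
            "objective_weights": {
                "ptv_uniformity": round(float(ops_rng.uniform(0.5, 1.0)), 4),
                "lung_sparing": round(float(ops_rng.uniform(0.1, 0.6)), 4),
                "cord_max": round(float(ops_rng.uniform(0.3, 0.9)), 4),
            },
        }
        records.append(
            PlanRecord(
                plan_id=f"plan_{i:03d}",
                prescription_gy=cohort.prescription_gy,
                clinical_dose=clinical,
                virtual_dose=virtual,
                structures=structures,
                ops_payload=ops,
                class_label=class_id,
            )
        )
    db = PlanDatabase(records=records)
    db.validate()
    return db
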