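"""Core domain types and I/O for dose volumes and plan databases.

A *plan* couples a clinically delivered 3D dose distribution, a predicted
("virtual") dose distribution, a set of binary structure masks on the same
voxel grid, a prescription dose, and an opaque optimization-parameter (OP)
payload destined for a treatment planning system's optimizer.  Volumes are
stored as compressed NIfTI, one file per volume, axis order (x, y, z);
databases are described by a JSON manifest.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "STRUCTURE_NAMES",
    "DoseGrid",
    "StructureSet",
    "PlanRecord",
    "PlanDatabase",
    "read_volume",
    "write_volume",
    "load_plan_database",
    "save_plan_database",
]

#: Canonical structure names expected on every plan.
STRUCTURE_NAMES = (
    "PTV",
    "GTV",
    "lung_L",
    "lung_R",
    "total_lung",
    "heart",
    "spinal_cord",
)

#: Negative voxel values smaller than this (in Gy) are treated as writer
#: round-off and clamped to zero; anything more negative is rejected.
NEGATIVE_CLAMP_GY = 1e-6


@dataclass
class DoseGrid:
    """A 3D scalar field of absorbed dose in Gy with grid metadata.

    Parameters
    ----------
    values : ndarray
        Dose in Gy, shape ``(nx, ny, nz)``, finite and non-negative.
    spacing_mm : tuple of float
        Per-axis voxel spacing, strictly positive.
    origin_mm : tuple of float
        Physical coordinate of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(
                f"dose volume must be 3D, got {self.values.ndim}D shape {self.values.shape}"
            )
        bad = ~np.isfinite(self.values)
        if bad.any():
            raise ValueError(
                f"dose volume contains {int(bad.sum())} non-finite voxel(s) (NaN/Inf)"
            )
        neg = self.values < 0
        if neg.any():
            if self.values.min() < -NEGATIVE_CLAMP_GY:
                raise ValueError(
                    f"dose volume contains {int(neg.sum())} negative voxel(s) "
                    f"below the {NEGATIVE_CLAMP_GY} Gy round-off tolerance"
                )
            self.values = np.clip(self.values, 0.0, None)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 strictly positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_grid(self, other: "DoseGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class StructureSet:
    """Co-registered binary masks for the PTV, GTV and organs at risk.

    ``total_lung`` is by definition the union of the two lungs with the
    gross tumor volume removed; :meth:`validate` enforces this voxelwise.
    """

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.masks.values())).shape  # type: ignore[return-value]

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"structure {name!r} missing; have {sorted(self.masks)}")
        return self.masks[name]

    def derive_total_lung(self) -> None:
        """(Re)compute ``total_lung = (lung_L | lung_R) & ~GTV``. Idempotent."""
        self.masks["total_lung"] = (
            (self["lung_L"] | self["lung_R"]) & ~self["GTV"]
        )

    def validate(self, grid_shape: tuple[int, int, int] | None = None) -> None:
        for name in STRUCTURE_NAMES:
            if name not in self.masks:
                raise ValueError(f"structure {name!r} missing from structure set")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError(f"structure masks disagree on grid shape: {shapes}")
        if grid_shape is not None and self.shape != tuple(grid_shape):
            raise ValueError(
                f"structure grid {self.shape} does not match dose grid {tuple(grid_shape)}"
            )
        if not self["PTV"].any():
            raise ValueError("PTV mask is empty")
        expected = (self["lung_L"] | self["lung_R"]) & ~self["GTV"]
        if not np.array_equal(self["total_lung"], expected):
            raise ValueError("total_lung != (lung_L | lung_R) \\ GTV voxelwise")


@dataclass
class PlanRecord:
    """One patient's plan: doses, structures, prescription and OP payload."""

    plan_id: str
    prescription_gy: float
    clinical_dose: DoseGrid
    structures: StructureSet
    virtual_dose: DoseGrid | None = None
    ops_payload: Any = None
    class_label: int | None = None

    def validate(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError(f"plan {self.plan_id}: prescription must be positive")
        try:
            self.structures.validate(grid_shape=self.clinical_dose.shape)
        except ValueError as exc:
            raise ValueError(f"plan {self.plan_id}: {exc}") from exc
        if self.virtual_dose is not None and not self.clinical_dose.same_grid(self.virtual_dose):
            raise ValueError(f"plan {self.plan_id}: clinical and virtual dose grids differ")


@dataclass
class PlanDatabase:
    """An ordered collection of plans with unique ids."""

    records: list[PlanRecord] = field(default_factory=list)
    manifest_path: Path | None = None

    def __post_init__(self) -> None:
        ids = [r.plan_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate plan id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PlanRecord]:
        return iter(self.records)

    def __getitem__(self, plan_id: str) -> PlanRecord:
        for r in self.records:
            if r.plan_id == plan_id:
                return r
        raise KeyError(f"plan id {plan_id!r} not in database")

    @property
    def plan_ids(self) -> list[str]:
        return [r.plan_id for r in self.records]

    def validate(self) -> None:
        for r in self.records:
            r.validate()


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def read_volume(path: str | Path) -> DoseGrid:
    """Read a 3D scalar volume from NIfTI into a :class:`DoseGrid`.

    Rejects non-3D images and volumes containing NaN/Inf voxels, naming
    the number of offending voxels.  Tiny negative round-off (< 1e-6 Gy)
    is clamped to zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: non-3D volume (got {data.ndim}D shape {data.shape})")
    data = np.asarray(data, dtype=np.float32)
    bad = ~np.isfinite(data)
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} invalid (NaN/Inf) voxel(s)")
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return DoseGrid(values=data, spacing_mm=spacing, origin_mm=origin)


def write_volume(grid: DoseGrid, path: str | Path) -> Path:
    """Write a :class:`DoseGrid` to compressed NIfTI (float32, lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(
        np.asarray(grid.values, dtype=np.float32),
        _affine(grid.spacing_mm, grid.origin_mm),
    )
    nib.save(img, str(path))
    return path


def _read_mask(path: str | Path, grid: DoseGrid, plan_id: str, name: str) -> np.ndarray:
    vol = read_volume(path)
    if vol.shape != grid.shape:
        raise ValueError(
            f"plan {plan_id}: mask {name!r} grid {vol.shape} does not match dose grid {grid.shape}"
        )
    return vol.values > 0.5


def load_plan_database(manifest: str | Path) -> PlanDatabase:
    """Load a plan database from a JSON manifest.

    The manifest lists, per plan: ``plan_id``, ``prescription_gy``, paths to
    the clinical (and optionally virtual) dose volumes, per-structure mask
    paths, the opaque ``ops_payload`` and an optional ``class_label``.
    Paths are resolved relative to the manifest's directory. ``total_lung``
    is derived from the lungs and GTV when absent.  All record invariants
    are verified on load.
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    spec = json.loads(manifest.read_text())
    base = manifest.parent
    records: list[PlanRecord] = []
    seen: set[str] = set()
    for entry in spec["plans"]:
        pid = entry["plan_id"]
        if pid in seen:
            raise ValueError(f"duplicate plan id {pid!r} in manifest")
        seen.add(pid)
        clinical = read_volume(base / entry["clinical_dose"])
        virtual = None
        if entry.get("virtual_dose"):
            virtual = read_volume(base / entry["virtual_dose"])
        masks = {
            name: _read_mask(base / p, clinical, pid, name)
            for name, p in entry["structures"].items()
        }
        structures = StructureSet(masks=masks)
        if "total_lung" not in structures.masks:
            structures.derive_total_lung()
        rec = PlanRecord(
            plan_id=pid,
            prescription_gy=float(entry["prescription_gy"]),
            clinical_dose=clinical,
            virtual_dose=virtual,
            structures=structures,
            ops_payload=copy.deepcopy(entry.get("ops_payload")),
            class_label=entry.get("class_label"),
        )
        rec.validate()
        records.append(rec)
    db = PlanDatabase(records=records, manifest_path=manifest)
    return db


def save_plan_database(db: PlanDatabase, out_dir: str | Path) -> Path:
    """Write all volumes plus a JSON manifest under ``out_dir``.

    Returns the manifest path. Round-trips through
    :func:`load_plan_database` preserving ids, prescriptions, OP payloads
    and voxel values to float32 precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in db.records:
        pdir = out_dir / rec.plan_id
        write_volume(rec.clinical_dose, pdir / "clinical_dose.nii.gz")
        entry: dict[str, Any] = {
            "plan_id": rec.plan_id,
            "prescription_gy": rec.prescription_gy,
            "clinical_dose": f"{rec.plan_id}/clinical_dose.nii.gz",
            "structures": {},
            "ops_payload": rec.ops_payload,
        }
        if rec.virtual_dose is not None:
            write_volume(rec.virtual_dose, pdir / "virtual_dose.nii.gz")
            entry["virtual_dose"] = f"{rec.plan_id}/virtual_dose.nii.gz"
        if rec.class_label is not None:
            entry["class_label"] = int(rec.class_label)
        for name, mask in rec.structures.masks.items():
            mgrid = DoseGrid(
                values=mask.astype(np.float32),
                spacing_mm=rec.clinical_dose.spacing_mm,
                origin_mm=rec.clinical_dose.origin_mm,
            )
            write_volume(mgrid, pdir / f"mask_{name}.nii.gz")
            entry["structures"][name] = f"{rec.plan_id}/mask_{name}.nii.gz"
        entries.append(entry)
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"plans": entries}, indent=2, sort_keys=True))
    db.manifest_path = manifest
    return manifest
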