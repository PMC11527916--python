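"""DVH construction and plan-quality metrics.

Implements the standard dosimetric vocabulary of IMRT plan evaluation:

* cumulative dose-volume histograms (DVH);
* Dx — the dose received by at least x% of a structure (descending-rank
  voxel percentile, no interpolation, so results are bit-reproducible and
  match counting oracles exactly);
* Vx — the percentage of a structure receiving over x Gy (strictly
  greater, per the usual "receiving over" wording);
* mean/max dose, mean lung dose (MLD) and mean heart dose (MHD);
* the conformity index CI = (V_T,ref / V_T) x (V_T,ref / V_ref), the
  product of target coverage and prescription-isodose selectivity (1 is
  perfect conformity);
* the homogeneity index HI = (D2 - D98) / D_P (0 is perfectly homogeneous).

Volumes entering CI are counted in voxels; on an equal-volume grid the
physical voxel volume cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DoseGrid, PlanRecord

__all__ = [
    "DVHCurve",
    "PlanMetrics",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "mean_max_dose",
    "conformity_index",
    "homogeneity_index",
    "plan_metrics",
    "metrics_table",
]


def _masked(dose: DoseGrid | np.ndarray, mask: np.ndarray) -> np.ndarray:
    values = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError(f"dose grid {values.shape} and mask {mask.shape} differ")
    if not mask.any():
        raise ValueError("empty structure mask")
    return values[mask].astype(float)


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= each edge."""

    structure: str
    bin_edges_gy: np.ndarray
    cum_volume_fraction: np.ndarray

    def volume_fraction_at(self, dose_gy: float) -> float:
        """Fraction of the structure receiving at least *dose_gy* (step lookup)."""
        idx = np.searchsorted(self.bin_edges_gy, dose_gy, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.cum_volume_fraction[idx])


def compute_dvh(
    dose: DoseGrid | np.ndarray,
    mask: np.ndarray,
    bin_width_gy: float = 0.1,
    structure: str = "",
) -> DVHCurve:
    """Cumulative >=-dose histogram over the masked voxels."""
    doses = _masked(dose, mask)
    top = float(doses.max()) + bin_width_gy
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    frac = (doses[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(structure=structure, bin_edges_gy=edges, cum_volume_fraction=frac)


def dose_at_volume(dose: DoseGrid | np.ndarray, mask: np.ndarray, x_percent: float) -> float:
    """Dx: the largest dose received by at least x% of the structure.

    Doses are sorted descending and the value at 1-based rank
    ceil(x/100 * N) is returned; x = 100 gives the minimum voxel dose.
    """
    if not 0 < x_percent <= 100:
        raise ValueError("x_percent must be in (0, 100]")
    doses = np.sort(_masked(dose, mask))[::-1]
    rank = int(np.ceil(x_percent / 100.0 * doses.size))
    return float(doses[rank - 1])


def volume_at_dose(dose: DoseGrid | np.ndarray, mask: np.ndarray, threshold_gy: float) -> float:
    """Vx: percentage of the structure receiving over *threshold_gy*."""
    doses = _masked(dose, mask)
    return float(100.0 * (doses > threshold_gy).sum() / doses.size)


def mean_max_dose(dose: DoseGrid | np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """(Dmean, Dmax) over the masked voxels, in Gy."""
    doses = _masked(dose, mask)
    return float(doses.mean()), float(doses.max())


def conformity_index(
    dose: DoseGrid | np.ndarray, ptv_mask: np.ndarray, prescription: float
) -> tuple[float, int, int, int]:
    """CI and its component volumes (in voxels).

    Returns ``(CI, V_T_ref, V_T, V_ref)`` where V_T,ref is the PTV volume
    covered by the prescription isodose, V_T the PTV volume and V_ref the
    volume of the prescription isodose (dose >= prescription).  If no voxel
    reaches the prescription, CI is defined as 0 with a warning.
    """
    values = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose)
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise ValueError("empty PTV mask")
    covered = values >= prescription
    v_t = int(ptv_mask.sum())
    v_ref = int(covered.sum())
    v_t_ref = int((covered & ptv_mask).sum())
    if v_ref == 0:
        import warnings

        warnings.warn("no voxel reaches the prescription dose; CI defined as 0")
        return 0.0, v_t_ref, v_t, v_ref
    ci = (v_t_ref / v_t) * (v_t_ref / v_ref)
    return float(ci), v_t_ref, v_t, v_ref


def homogeneity_index(d2: float, d98: float, prescription: float) -> float:
    """HI = (D2 - D98) / prescription."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    return (d2 - d98) / prescription


@dataclass
class PlanMetrics:
    """The per-plan metric bundle, one field per (structure, metric) pair.

    PTV: D2, D98, D99, Dmean, CI, HI; total lung: V5, V20, MLD;
    spinal cord: Dmax; heart: V30, V40, V45, V60, MHD.
    """

    plan_id: str
    ptv_d2: float
    ptv_d98: float
    ptv_d99: float
    ptv_dmean: float
    ptv_ci: float
    ptv_hi: float
    lung_v5: float
    lung_v20: float
    mld: float
    cord_dmax: float
    heart_v30: float
    heart_v40: float
    heart_v45: float
    heart_v60: float
    mhd: float
    ci_parts: tuple[int, int, int] = (0, 0, 0)  # (V_T,ref, V_T, V_ref)

    _FIELD_MAP = {
        ("PTV", "D2"): "ptv_d2",
        ("PTV", "D98"): "ptv_d98",
        ("PTV", "D99"): "ptv_d99",
        ("PTV", "Dmean"): "ptv_dmean",
        ("PTV", "CI"): "ptv_ci",
        ("PTV", "HI"): "ptv_hi",
        ("total_lung", "V5"): "lung_v5",
        ("total_lung", "V20"): "lung_v20",
        ("total_lung", "MLD"): "mld",
        ("spinal_cord", "Dmax"): "cord_dmax",
        ("heart", "V30"): "heart_v30",
        ("heart", "V40"): "heart_v40",
        ("heart", "V45"): "heart_v45",
        ("heart", "V60"): "heart_v60",
        ("heart", "MHD"): "mhd",
    }

    def value(self, structure: str, metric: str) -> float:
        key = (structure, metric)
        if key not in self._FIELD_MAP:
            raise KeyError(f"metric {metric!r} is not defined for structure {structure!r}")
        return getattr(self, self._FIELD_MAP[key])

    def as_dict(self) -> dict[str, float]:
        return {
            f"{s}_{m}": self.value(s, m) for (s, m) in self._FIELD_MAP
        } | {"plan_id": self.plan_id}


def plan_metrics(record: PlanRecord, which_dose: str = "clinical") -> PlanMetrics:
    """Compute the full metric bundle for one plan.

    ``which_dose`` selects the clinical or the virtual dose distribution.
    """
    if which_dose == "clinical":
        dose = record.clinical_dose
    elif which_dose == "virtual":
        if record.virtual_dose is None:
            raise ValueError(f"plan {record.plan_id} has no virtual dose")
        dose = record.virtual_dose
    else:
        raise ValueError("which_dose must be 'clinical' or 'virtual'")

    ss = record.structures
    for name in ("PTV", "total_lung", "spinal_cord", "heart"):
        if name not in ss.masks:
            raise ValueError(f"plan {record.plan_id}: structure {name!r} missing")

    rx = record.prescription_gy
    ptv = ss["PTV"]
    d2 = dose_at_volume(dose, ptv, 2)
    d98 = dose_at_volume(dose, ptv, 98)
    d99 = dose_at_volume(dose, ptv, 99)
    dmean, _ = mean_max_dose(dose, ptv)
    ci, v_t_ref, v_t, v_ref = conformity_index(dose, ptv, rx)
    mld, _ = mean_max_dose(dose, ss["total_lung"])
    _, cord_dmax = mean_max_dose(dose, ss["spinal_cord"])
    mhd, _ = mean_max_dose(dose, ss["heart"])
    return PlanMetrics(
        plan_id=record.plan_id,
        ptv_d2=d2,
        ptv_d98=d98,
        ptv_d99=d99,
        ptv_dmean=dmean,
        ptv_ci=ci,
        ptv_hi=homogeneity_index(d2, d98, rx),
        lung_v5=volume_at_dose(dose, ss["total_lung"], 5),
        lung_v20=volume_at_dose(dose, ss["total_lung"], 20),
        mld=mld,
        cord_dmax=cord_dmax,
        heart_v30=volume_at_dose(dose, ss["heart"], 30),
        heart_v40=volume_at_dose(dose, ss["heart"], 40),
        heart_v45=volume_at_dose(dose, ss["heart"], 45),
        heart_v60=volume_at_dose(dose, ss["heart"], 60),
        mhd=mhd,
        ci_parts=(v_t_ref, v_t, v_ref),
    )


def metrics_table(metrics_list: list[PlanMetrics]) -> pd.DataFrame:
    """One row per plan, one column per Table-style metric."""
    rows = [m.as_dict() for m in metrics_list]
    df = pd.DataFrame(rows)
    return df.set_index("plan_id")
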