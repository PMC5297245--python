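"""Hollow-cylinder model of the detergent belt around a membrane protein.

In solution a membrane protein carries a torus of detergent shielding its
transmembrane surface.  The belt is idealized as a hollow cylinder of
height H (the bilayer thickness), inner radius R_p (the protein's
effective cylinder radius) and outer radius R_t, whose volume equals the
summed molecular volume of the N bound detergent molecules:

    V_belt = N · V_det                       (belt volume from counting)
    V_belt = π (R_t² − R_p²) · H             (hollow-cylinder volume)
    R_t    = sqrt(V_belt / (π H) + R_p²)     (outer radius)
    R_belt = R_t − R_p                       (belt thickness)

N comes from internal-standard MALDI-TOF quantification (``ms_quant``),
V_det from a voxel-grid molecular volume of a detergent conformer, H and
R_p from the oriented structure (``structure_ahs``).  Across proteins the
belt volume grows roughly linearly with the membrane-restricted
accessible hydrophobic surface (AHS), so a fitted line V_belt = a·AHS + b
predicts how many detergent molecules a new protein will bind.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .structure_ahs import AtomRecord, MembraneSlab

__all__ = [
    "BeltGeometry",
    "AHSLinearModel",
    "NPrediction",
    "detergent_volume",
    "belt_volume",
    "cylinder_volume",
    "whole_radius",
    "belt_radius",
    "fit_ahs_model",
    "predict_n",
    "write_belt_pdb",
]


# --------------------------------------------------------------------------
# Molecular volume
# --------------------------------------------------------------------------


def detergent_volume(
    conformer: Sequence[AtomRecord], spacing: float = 0.25, probe: float = 0.0
) -> float:
    """Molecular volume V_det (Å³) of a detergent conformer on a voxel grid.

    Counts grid voxels whose center falls inside any sphere of radius
    r_i + probe and multiplies by spacing³.  With probe 0 this is the
    van-der-Waals volume; a positive probe gives a probe-inflated
    (solvent-excluded-like) volume.
    """
    if len(conformer) == 0:
        raise ValueError("empty conformer")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = np.array([a.coords for a in conformer], dtype=float)
    radii = np.array([a.radius for a in conformer], dtype=float)
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("all atoms need positive radii")
    radii = radii + probe

    lo = (coords - radii[:, None]).min(axis=0) - spacing
    hi = (coords + radii[:, None]).max(axis=0) + spacing
    axes = [np.arange(lo[d] + spacing / 2, hi[d], spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack((gx.ravel(), gy.ravel(), gz.ravel()))

    inside = np.zeros(pts.shape[0], dtype=bool)
    for c, r in zip(coords, radii):
        todo = ~inside
        if not todo.any():
            break
        d2 = np.einsum("ij,ij->i", pts[todo] - c, pts[todo] - c)
        inside[np.flatnonzero(todo)[d2 < r * r]] = True
    return float(inside.sum()) * spacing**3


# --------------------------------------------------------------------------
# Cylinder algebra
# --------------------------------------------------------------------------


def belt_volume(n_det: float, v_det: float) -> float:
    """V_belt = N · V_det (Å³)."""
    if n_det < 0:
        raise ValueError("n_det must be non-negative")
    if v_det <= 0:
        raise ValueError("v_det must be positive")
    return n_det * v_det


def cylinder_volume(r_t: float, r_p: float, h: float) -> float:
    """Hollow-cylinder volume π(R_t² − R_p²)·H (Å³)."""
    if r_p < 0 or r_t < r_p:
        raise ValueError("need r_t >= r_p >= 0")
    if h <= 0:
        raise ValueError("height must be positive")
    return math.pi * (r_t**2 - r_p**2) * h


def whole_radius(v_belt: float, h: float, r_p: float) -> float:
    """Outer cylinder radius R_t = sqrt(V_belt/(πH) + R_p²) (Å)."""
    if v_belt < 0:
        raise ValueError("v_belt must be non-negative")
    if h <= 0:
        raise ValueError("height must be positive")
    if r_p < 0:
        raise ValueError("r_p must be non-negative")
    return math.sqrt(v_belt / (math.pi * h) + r_p**2)


def belt_radius(r_t: float, r_p: float) -> float:
    """Belt thickness R_belt = R_t − R_p (Å)."""
    if r_t < r_p:
        raise ValueError("r_t must be at least r_p")
    if r_p < 0:
        raise ValueError("r_p must be non-negative")
    return r_t - r_p


@dataclass
class BeltGeometry:
    """Consistent hollow-cylinder belt parameters for one complex.

    The constructor enforces both volume identities (V_belt = N·V_det and
    V_belt = π(R_t²−R_p²)·H) to 1e-6 relative; build instances with
    :meth:`from_quantification` to get them by construction.
    """

    n_det: float
    v_det: float
    v_belt: float
    h: float
    r_p: float
    r_t: float
    r_belt: float

    def __post_init__(self) -> None:
        if self.r_p < 0 or self.r_t < self.r_p:
            raise ValueError("need r_t >= r_p >= 0")
        if self.h <= 0 or self.v_det <= 0 or self.n_det < 0:
            raise ValueError("invalid belt parameters")
        if not math.isclose(self.r_belt, self.r_t - self.r_p, rel_tol=1e-6, abs_tol=1e-9):
            raise ValueError("r_belt must equal r_t - r_p")
        if not math.isclose(
            self.v_belt, self.n_det * self.v_det, rel_tol=1e-6, abs_tol=1e-9
        ):
            raise ValueError("v_belt must equal n_det * v_det")
        if not math.isclose(
            self.v_belt, cylinder_volume(self.r_t, self.r_p, self.h),
            rel_tol=1e-6, abs_tol=1e-9,
        ):
            raise ValueError("v_belt must equal the hollow-cylinder volume")

    @classmethod
    def from_quantification(
        cls, n_det: float, v_det: float, h: float, r_p: float
    ) -> "BeltGeometry":
        """Belt geometry from measured N, V_det, H and R_p."""
        v_belt = belt_volume(n_det, v_det)
        r_t = whole_radius(v_belt, h, r_p)
        return cls(
            n_det=n_det,
            v_det=v_det,
            v_belt=v_belt,
            h=h,
            r_p=r_p,
            r_t=r_t,
            r_belt=belt_radius(r_t, r_p),
        )


# --------------------------------------------------------------------------
# V_belt vs AHS linear relation
# --------------------------------------------------------------------------


@dataclass
class AHSLinearModel:
    """Linear predictor V_belt = slope·AHS + intercept (Å³ vs Å²)."""

    slope: float
    intercept: float
    slope_se: float = 0.0
    intercept_se: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.slope_se < 0 or self.intercept_se < 0:
            raise ValueError("standard errors must be non-negative")

    def predict_volume(self, ahs: float) -> float:
        return self.slope * ahs + self.intercept

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "slope_se": self.slope_se,
                    "intercept_se": self.intercept_se,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AHSLinearModel":
        d = json.loads(Path(path).read_text())
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            slope_se=d.get("slope_se", 0.0),
            intercept_se=d.get("intercept_se", 0.0),
        )


def fit_ahs_model(points: Sequence[tuple[float, float]]) -> AHSLinearModel:
    """Ordinary least squares of V_belt on AHS with coefficient SEs."""
    if len(points) < 3:
        raise ValueError("need at least 3 (AHS, V_belt) points for standard errors")
    ahs = np.array([p[0] for p in points], dtype=float)
    vbelt = np.array([p[1] for p in points], dtype=float)
    if np.ptp(ahs) == 0:
        raise ValueError("degenerate design: all AHS values identical")
    res = sm.OLS(vbelt, sm.add_constant(ahs)).fit()
    intercept, slope = res.params
    intercept_se, slope_se = res.bse
    if not np.isfinite(slope_se):  # perfect fit has zero residual variance
        slope_se, intercept_se = 0.0, 0.0
    return AHSLinearModel(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
    )


class NPrediction(NamedTuple):
    raw: float
    rounded: int


def predict_n(ahs: float, model: AHSLinearModel, v_det: float) -> NPrediction:
    """Predicted number of bound detergent molecules at a given AHS.

    N = (slope·AHS + intercept)/V_det; a negative predicted belt volume
    (AHS below the fitted line's root, possible because the intercept is
    negative) maps to N = 0 with a warning.
    """
    if v_det <= 0:
        raise ValueError("v_det must be positive")
    v_pred = model.predict_volume(ahs)
    if v_pred < 0:
        warnings.warn(
            f"predicted belt volume {v_pred:.4g} Å³ is negative; returning N = 0",
            stacklevel=2,
        )
        v_pred = 0.0
    n = v_pred / v_det
    return NPrediction(raw=n, rounded=int(math.floor(n + 0.5)))


# --------------------------------------------------------------------------
# Belt visualization
# --------------------------------------------------------------------------


def write_belt_pdb(
    geom: BeltGeometry,
    slab: MembraneSlab,
    out: str | Path,
    center: tuple[float, float] = (0.0, 0.0),
    spacing: float = 2.0,
) -> int:
    """Write the belt annulus as HETATM pseudo-atoms for visualization.

    Pseudo-carbons on concentric rings fill the annulus R_p ≤ r ≤ R_t over
    z_lo ≤ z ≤ z_hi at ~``spacing`` Å; the file is fixed-column PDB and
    re-parses with :func:`detbelt.structure_ahs.read_pdb`.  Returns the
    number of atoms written.
    """
    out = Path(out)
    cx, cy = center
    lines: list[str] = []
    if geom.r_belt <= 0:
        warnings.warn("degenerate belt (r_t = r_p): writing empty model", stacklevel=2)
    else:
        radii = np.arange(geom.r_p, geom.r_t + 1e-9, spacing)
        if radii.size == 0 or radii[-1] < geom.r_t - 1e-9:
            radii = np.append(radii, geom.r_t)
        zs = np.arange(slab.z_lo, slab.z_hi + 1e-9, spacing)
        if zs.size == 0 or zs[-1] < slab.z_hi - 1e-9:
            zs = np.append(zs, slab.z_hi)
        serial = 1
        for z in zs:
            for r in radii:
                n_ring = max(1, int(round(2 * math.pi * r / spacing))) if r > 0 else 1
                for k in range(n_ring):
                    theta = 2 * math.pi * k / n_ring
                    x = cx + r * math.cos(theta)
                    y = cy + r * math.sin(theta)
                    lines.append(
                        f"HETATM{serial % 100000:5d}  C   BLT X{(serial % 9999) + 1:4d}"
                        f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                    )
                    serial += 1
    with open(out, "w") as fh:
        fh.write("REMARK   detergent belt pseudo-atom model\n")
        for line in lines:
            fh.write(line + "\n")
        fh.write("END\n")
    return len(lines)
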