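"""Membrane-restricted accessible surface of membrane proteins.

The surface a detergent's alkyl chain can reach is estimated as the
solvent-accessible surface area (Shrake–Rupley) computed with a 1.5 Å
probe — the C–C bond length, standing in for a detergent alkyl chain —
and then clipped to the membrane slab: only surface points whose z
coordinate lies between the two membrane boundary planes count toward the
accessible hydrophobic surface (AHS).  Structures are expected to be
membrane-oriented (e.g. as provided by the OPM database, whose files mark
the boundary planes with DUM pseudo-atoms); the membrane normal is the
z axis.

The module also estimates the protein's effective cylinder radius R_p by
sector-maximum averaging of atom positions at the two membrane
boundaries, which feeds the hollow-cylinder belt model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "MembraneSlab",
    "AHSResult",
    "DEFAULT_RADII",
    "read_pdb",
    "assign_radii",
    "sphere_points",
    "sasa",
    "membrane_ahs",
    "slab_from_opm_pdb",
    "estimate_rp",
    "transform",
]

#: United-atom van der Waals radii (Å), after the Chothia/Naccess
#: convention for protein heavy atoms.  Hydrogens are normally absent
#: from the structures handled here.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "H": 1.00,
    "SE": 1.90,
    "FE": 1.47,
    "ZN": 1.39,
    "MG": 1.18,
    "NA": 1.36,
    "CL": 1.81,
}

#: Fallback radius for elements not in the table (Å).
FALLBACK_RADIUS = 1.80

_TWO_LETTER_ELEMENTS = {
    "SE", "FE", "ZN", "MG", "NA", "CL", "BR", "MN", "CU", "NI", "CA", "CO", "CD",
}


@dataclass
class AtomRecord:
    """One heavy atom: element, Cartesian coordinates (Å) and vdW radius."""

    element: str
    coords: np.ndarray
    radius: Optional[float] = None
    is_hetero: bool = False
    name: str = ""
    chain: str = ""
    resid: int = 0
    resname: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class MembraneSlab:
    """Membrane boundary planes z = z_lo and z = z_hi (Å), z_hi > z_lo."""

    z_lo: float
    z_hi: float

    def __post_init__(self) -> None:
        if not self.z_hi > self.z_lo:
            raise ValueError("z_hi must exceed z_lo")

    @property
    def thickness(self) -> float:
        """Bilayer thickness H (Å)."""
        return self.z_hi - self.z_lo


@dataclass
class AHSResult:
    """Total SASA and its membrane-slab-restricted part (Å²)."""

    sasa_total: float
    ahs_membrane: float
    per_atom_total: np.ndarray
    per_atom_slab: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.ahs_membrane <= self.sasa_total * (1 + 1e-9) + 1e-9):
            raise ValueError("ahs_membrane must lie in [0, sasa_total]")


# --------------------------------------------------------------------------
# PDB input
# --------------------------------------------------------------------------


def _infer_element(name_field: str) -> str:
    """Infer the element from a PDB atom-name field (columns 13–16)."""
    stripped = name_field.strip(" 0123456789'\"")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name_field!r}")
    two = stripped[:2].upper()
    # two-letter elements are left-justified from column 13 in PDB format
    if name_field[:1].strip() and two in _TWO_LETTER_ELEMENTS:
        return two.capitalize().upper()
    return stripped[0].upper()


def read_pdb(
    path: str | Path,
    keep_hetero: bool = False,
    keep_waters: bool = False,
) -> list[AtomRecord]:
    """Parse ATOM/HETATM records from a fixed-column PDB file.

    Waters (HOH/WAT/DOD) and, by default, hetero compounds are excluded;
    OPM DUM membrane markers are always excluded (read them with
    :func:`slab_from_opm_pdb`).  The element is taken from columns 77–78
    when present, otherwise inferred from the atom name.  Malformed
    coordinate fields raise an error naming the offending line.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                continue
            resname = line[17:20].strip()
            if resname == "DUM":
                continue
            if resname in ("HOH", "WAT", "DOD") and not keep_waters:
                continue
            is_het = rec == "HETATM"
            if is_het and not keep_hetero and resname not in ("MSE",):
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinate field in {line.rstrip()!r}"
                ) from exc
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(line[12:16])
            element = element.upper()
            if element in ("D", "H") :
                continue  # hydrogens/deuteriums ignored for SASA
            try:
                resid = int(line[22:26])
            except ValueError:
                resid = 0
            atoms.append(
                AtomRecord(
                    element=element,
                    coords=(x, y, z),
                    is_hetero=is_het,
                    name=line[12:16].strip(),
                    chain=line[21:22].strip(),
                    resid=resid,
                    resname=resname,
                )
            )
    if not atoms:
        raise ValueError(f"{path}: no atoms after filtering")
    return atoms


def assign_radii(
    atoms: Sequence[AtomRecord],
    radii_set: Optional[dict[str, float]] = None,
) -> list[AtomRecord]:
    """Assign per-element vdW radii in place (returns the same list).

    Unknown elements get the 1.80 Å fallback with a warning.
    """
    table = DEFAULT_RADII if radii_set is None else radii_set
    unknown: set[str] = set()
    for atom in atoms:
        r = table.get(atom.element)
        if r is None:
            unknown.add(atom.element)
            r = FALLBACK_RADIUS
        atom.radius = r
    if unknown:
        warnings.warn(
            f"elements {sorted(unknown)} not in radii table; "
            f"using default {FALLBACK_RADIUS} Å",
            stacklevel=2,
        )
    return list(atoms)


def transform(
    atoms: Sequence[AtomRecord],
    rotation: Optional[np.ndarray] = None,
    translation: Optional[np.ndarray] = None,
) -> list[AtomRecord]:
    """Return rigidly transformed copies of the atoms (rotate then shift).

    Helper for re-orienting structures whose membrane normal is not z.
    """
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    tra = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    out = []
    for a in atoms:
        out.append(
            AtomRecord(
                element=a.element,
                coords=rot @ a.coords + tra,
                radius=a.radius,
                is_hetero=a.is_hetero,
                name=a.name,
                chain=a.chain,
                resid=a.resid,
                resname=a.resname,
            )
        )
    return out


# --------------------------------------------------------------------------
# Shrake–Rupley accessible surface
# --------------------------------------------------------------------------


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of ``n`` quasi-uniform points on
    the unit sphere (no RNG, so areas are bit-reproducible)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def _prepare(atoms: Sequence[AtomRecord]) -> tuple[np.ndarray, np.ndarray]:
    if len(atoms) == 0:
        raise ValueError("no atoms")
    coords = np.array([a.coords for a in atoms], dtype=float)
    radii = np.array(
        [a.radius if a.radius is not None else float("nan") for a in atoms]
    )
    if np.any(~np.isfinite(radii)):
        raise ValueError("all atoms need radii (run assign_radii first)")
    return coords, radii


def _accessible_area(
    coords: np.ndarray,
    inflated: np.ndarray,
    n_points: int,
    slab: Optional[MembraneSlab],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom accessible area, total and restricted to the slab.

    A lattice point on atom i's inflated sphere is accessible iff it lies
    outside every neighbor's inflated sphere (boundary contact counts as
    accessible); it contributes to the slab area additionally iff its z
    lies in [z_lo, z_hi] (closed interval).
    """
    n_atoms = coords.shape[0]
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    r_max = inflated.max()
    area_total = np.zeros(n_atoms)
    area_slab = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + inflated[i] * unit
        neighbors = tree.query_ball_point(coords[i], inflated[i] + r_max)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            # only spheres actually within reach can bury lattice points
            d = np.linalg.norm(coords[j] - coords[i])
            if d >= inflated[i] + inflated[j]:
                continue
            buried = np.einsum(
                "ij,ij->i", pts - coords[j], pts - coords[j]
            ) < inflated[j] ** 2
            accessible &= ~buried
            if not accessible.any():
                break
        sphere_area = 4.0 * math.pi * inflated[i] ** 2
        frac = accessible.sum() / n_points
        area_total[i] = sphere_area * frac
        if slab is not None and accessible.any():
            in_slab = accessible & (pts[:, 2] >= slab.z_lo) & (pts[:, 2] <= slab.z_hi)
            area_slab[i] = sphere_area * in_slab.sum() / n_points
    return area_total, area_slab


def sasa(
    atoms: Sequence[AtomRecord], probe: float = 1.5, n_points: int = 960
) -> np.ndarray:
    """Per-atom Shrake–Rupley solvent-accessible areas (Å²).

    The default 1.5 Å probe is the C–C bond length, modeling the alkyl
    chain of a detergent rather than a water molecule (1.4 Å).
    """
    if n_points < 32:
        raise ValueError("n_points must be at least 32")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    coords, radii = _prepare(atoms)
    total, _ = _accessible_area(coords, radii + probe, n_points, slab=None)
    return total


def membrane_ahs(
    atoms: Sequence[AtomRecord],
    slab: MembraneSlab,
    probe: float = 1.5,
    n_points: int = 960,
    apolar_only: bool = False,
) -> AHSResult:
    """Total SASA plus its part inside the membrane slab (the AHS).

    Identical point test as :func:`sasa`; a point contributes to the AHS
    only when accessible *and* z ∈ [z_lo, z_hi].  With ``apolar_only`` the
    slab contribution is restricted to carbon/sulfur atoms.
    """
    if n_points < 32:
        raise ValueError("n_points must be at least 32")
    coords, radii = _prepare(atoms)
    total, in_slab = _accessible_area(coords, radii + probe, n_points, slab)
    if apolar_only:
        apolar = np.array([a.element in ("C", "S") for a in atoms])
        in_slab = np.where(apolar, in_slab, 0.0)
    z = coords[:, 2]
    if (z + radii + probe).max() < slab.z_lo or (z - radii - probe).min() > slab.z_hi:
        warnings.warn("membrane slab lies entirely outside the structure", stacklevel=2)
    return AHSResult(
        sasa_total=float(total.sum()),
        ahs_membrane=float(in_slab.sum()),
        per_atom_total=total,
        per_atom_slab=in_slab,
    )


# --------------------------------------------------------------------------
# Membrane slab and protein radius
# --------------------------------------------------------------------------


def slab_from_opm_pdb(path: str | Path, tol: float = 0.1) -> MembraneSlab:
    """Membrane boundaries from the DUM marker atoms of an OPM-oriented PDB.

    OPM writes two planes of DUM pseudo-atoms at the hydrophobic
    boundaries; their two distinct z values (grouped within ``tol`` Å)
    give z_lo/z_hi and hence the bilayer thickness H.
    """
    path = Path(path)
    zs: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line[:6] not in ("ATOM  ", "HETATM"):
                continue
            if line[17:20].strip() != "DUM":
                continue
            try:
                zs.append(float(line[46:54]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed DUM coordinate"
                ) from exc
    if not zs:
        raise ValueError(
            f"{path}: no DUM membrane-marker atoms; supply the slab manually "
            "(z_lo/z_hi)"
        )
    planes: list[float] = []
    for z in sorted(zs):
        if not planes or abs(z - planes[-1]) > tol:
            planes.append(z)
    if len(planes) != 2:
        raise ValueError(
            f"{path}: expected 2 DUM planes, found {len(planes)}; supply the "
            "slab manually (z_lo/z_hi)"
        )
    return MembraneSlab(z_lo=planes[0], z_hi=planes[1])


def estimate_rp(
    atoms: Sequence[AtomRecord],
    slab: MembraneSlab,
    n_sectors: int = 8,
    band: float = 3.0,
) -> float:
    """Effective protein cylinder radius R_p (Å).

    Atoms within ``band`` Å of each membrane boundary plane are projected
    onto xy around the membrane-domain centroid; in each of ``n_sectors``
    azimuthal sectors the maximum radial distance is taken, and R_p is the
    mean of these sector maxima over both boundary bands.  This mirrors
    the practice of averaging several protein diameters measured parallel
    to the membrane plane at the two boundaries.
    """
    if n_sectors < 1:
        raise ValueError("n_sectors must be positive")
    coords = np.array([a.coords for a in atoms], dtype=float)
    z = coords[:, 2]
    dom = coords[(z >= slab.z_lo) & (z <= slab.z_hi)]
    if dom.size == 0:
        raise ValueError("no atoms inside the membrane slab")
    centroid = dom[:, :2].mean(axis=0)

    sector_maxima: list[float] = []
    for z0 in (slab.z_lo, slab.z_hi):
        sel = coords[np.abs(z - z0) <= band]
        if sel.shape[0] < n_sectors:
            raise ValueError(
                f"only {sel.shape[0]} atoms within {band} Å of z={z0}; "
                "widen the boundary band"
            )
        xy = sel[:, :2] - centroid
        r = np.hypot(xy[:, 0], xy[:, 1])
        theta = np.mod(np.arctan2(xy[:, 1], xy[:, 0]), 2 * math.pi)
        idx = np.minimum((theta / (2 * math.pi) * n_sectors).astype(int), n_sectors - 1)
        for s in range(n_sectors):
            rs = r[idx == s]
            if rs.size:
                sector_maxima.append(float(rs.max()))
    return float(np.mean(sector_maxima))
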