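"""Synthetic inputs and Monte-Carlo oracles for the detergent-belt toolkit.

Everything the other modules consume can be generated here without any
external download: MALDI profile spectra with planted concentrations
(emulating internal-standard acquisitions of detergent pairs), toy
structures with analytic geometry (sphere clusters, cylinder shells,
ideal helix bundles), Monte-Carlo estimators for accessible surface and
molecular volume used as independent oracles, and noisy samples of the
V_belt-vs-AHS linear relation.

All generators are pure functions of their parameters and an explicit
seed; the same seed yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .belt_model import AHSLinearModel
from .ms_quant import DetergentSpecies, Spectrum, isotope_pattern
from .structure_ahs import AtomRecord, MembraneSlab, sphere_points

__all__ = [
    "SpectrumSpec",
    "gen_spectrum",
    "gen_shape",
    "mc_sasa",
    "mc_volume",
    "MCEstimate",
    "gen_ahs_dataset",
    "load_table1",
    "write_fixtures",
]


# --------------------------------------------------------------------------
# Synthetic MALDI spectra
# --------------------------------------------------------------------------


@dataclass
class SpectrumSpec:
    """Recipe for one synthetic internal-standard acquisition.

    Each species desorbs with Gaussian isotopologue peaks whose total area
    is concentration × efficiency × ``area_scale``; ``efficiencies`` of 1
    model an ideally matched (e.g. deuterated) standard.  Defaults emulate
    a sugar-detergent acquisition: 0.08 Th peak width (reflectron MALDI at
    m/z ~500) and a few-count baseline noise, with areas placing a 0.1%
    (w/v) peak in the low-thousands of counts.
    """

    species: Sequence[DetergentSpecies]
    concentrations: Sequence[float]  # % (w/v)
    efficiencies: Optional[Sequence[float]] = None
    peak_width: float = 0.08  # Gaussian sigma, Th
    noise_sd: float = 0.0  # counts
    seed: int = 0
    grid_step: float = 0.02  # Th
    area_scale: float = 8000.0  # counts·Th per % (w/v) at efficiency 1
    max_offset: int = 8
    pad: float = 5.0  # Th margin around the envelopes

    def __post_init__(self) -> None:
        if len(self.species) != len(self.concentrations):
            raise ValueError("species and concentrations must have equal length")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if self.efficiencies is None:
            self.efficiencies = [1.0] * len(self.species)
        if len(self.efficiencies) != len(self.species):
            raise ValueError("efficiencies must match species")
        if self.peak_width <= 0 or self.grid_step <= 0:
            raise ValueError("peak_width and grid_step must be positive")


def gen_spectrum(spec: SpectrumSpec) -> Spectrum:
    """Synthesize a profile spectrum from a :class:`SpectrumSpec`.

    Peaks are Gaussians at each species' isotopologue m/z with areas
    proportional to concentration × efficiency × isotopologue probability,
    plus optional Gaussian baseline noise (clipped at zero counts).
    """
    rng = np.random.default_rng(spec.seed)
    centers: list[float] = []
    for sp in spec.species:
        mono = sp.monoisotopic_mz
        centers.extend(mono + k for k in range(spec.max_offset + 1))
    lo = min(centers) - spec.pad
    hi = max(centers) + spec.pad
    mz = np.arange(lo, hi, spec.grid_step)
    intensity = np.zeros_like(mz)

    norm = 1.0 / (spec.peak_width * math.sqrt(2.0 * math.pi))
    for sp, conc, eff in zip(spec.species, spec.concentrations, spec.efficiencies):
        if conc == 0:
            continue
        area = conc * eff * spec.area_scale
        pattern = isotope_pattern(sp, spec.max_offset)
        mono = sp.monoisotopic_mz
        for off, p in zip(pattern.offsets, pattern.probs):
            if p == 0:
                continue
            mu = mono + float(off)
            intensity += (
                area
                * p
                * norm
                * np.exp(-0.5 * ((mz - mu) / spec.peak_width) ** 2)
            )
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=mz.size)
    intensity = np.clip(intensity, 0.0, None)
    return Spectrum(mz, intensity)


# --------------------------------------------------------------------------
# Toy structures
# --------------------------------------------------------------------------


def gen_shape(kind: str, **params) -> list[AtomRecord]:
    """Deterministic toy structures with analytic geometry.

    ``sphere_cluster(n, cluster_radius, atom_radius=1.87)``
        n carbon atoms on a golden-spiral lattice of a sphere of the given
        radius (0 → all at the origin is rejected; use n=1 for one atom).
    ``cylinder_shell(radius, height, n_rings=10, atoms_per_ring=24,
    atom_radius=1.87)``
        rings of atoms, all centers exactly at the given radial distance,
        z from -height/2 to +height/2.
    ``helix_bundle(n_helices, length, bundle_radius=8.0, rise=1.5,
    helix_radius=2.3, twist_deg=100.0, atom_radius=1.87)``
        n ideal poly-carbon helices (one atom per residue) on a circle of
        the bundle radius, centered on z = 0; n_helices × length atoms.
    """
    if kind == "sphere_cluster":
        n = int(params["n"])
        cluster_radius = float(params.get("cluster_radius", 5.0))
        atom_radius = float(params.get("atom_radius", 1.87))
        if n < 1:
            raise ValueError("n must be at least 1")
        if n == 1:
            coords = np.zeros((1, 3))
        else:
            if cluster_radius <= 0:
                raise ValueError("cluster_radius must be positive for n > 1")
            coords = sphere_points(n) * cluster_radius
    elif kind == "cylinder_shell":
        radius = float(params["radius"])
        height = float(params["height"])
        n_rings = int(params.get("n_rings", 10))
        per_ring = int(params.get("atoms_per_ring", 24))
        atom_radius = float(params.get("atom_radius", 1.87))
        if radius <= 0 or height <= 0 or n_rings < 1 or per_ring < 1:
            raise ValueError("invalid cylinder_shell parameters")
        zs = np.linspace(-height / 2, height / 2, n_rings)
        rows = []
        for z in zs:
            for k in range(per_ring):
                theta = 2 * math.pi * k / per_ring
                rows.append((radius * math.cos(theta), radius * math.sin(theta), z))
        coords = np.array(rows)
    elif kind == "helix_bundle":
        n_hel = int(params["n_helices"])
        length = int(params["length"])
        bundle_radius = float(params.get("bundle_radius", 8.0))
        rise = float(params.get("rise", 1.5))
        helix_radius = float(params.get("helix_radius", 2.3))
        twist = math.radians(float(params.get("twist_deg", 100.0)))
        atom_radius = float(params.get("atom_radius", 1.87))
        if n_hel < 1 or length < 1:
            raise ValueError("invalid helix_bundle parameters")
        rows = []
        z0 = -(length - 1) * rise / 2
        for h in range(n_hel):
            phi = 2 * math.pi * h / n_hel
            cx, cy = bundle_radius * math.cos(phi), bundle_radius * math.sin(phi)
            for i in range(length):
                theta = i * twist
                rows.append(
                    (
                        cx + helix_radius * math.cos(theta),
                        cy + helix_radius * math.sin(theta),
                        z0 + i * rise,
                    )
                )
        coords = np.array(rows)
    else:
        raise ValueError(f"unknown shape kind {kind!r}")

    return [
        AtomRecord(element="C", coords=c, radius=atom_radius, name="C", resid=i + 1)
        for i, c in enumerate(coords)
    ]


# --------------------------------------------------------------------------
# Monte-Carlo oracles
# --------------------------------------------------------------------------


@dataclass
class MCEstimate:
    """A Monte-Carlo estimate with a 95% confidence half-width."""

    value: float
    ci95: float

    @property
    def low(self) -> float:
        return self.value - self.ci95

    @property
    def high(self) -> float:
        return self.value + self.ci95


def mc_sasa(
    atoms: Sequence[AtomRecord],
    probe: float = 1.5,
    slab: Optional[MembraneSlab] = None,
    n_samples: int = 100_000,
    seed: int = 0,
) -> MCEstimate:
    """Monte-Carlo accessible surface area (Å²), optionally slab-clipped.

    Uniform random points on each atom's probe-inflated sphere are tested
    with the same accessibility rule as the lattice method (outside every
    neighbor's inflated sphere; slab test on z when given), making this an
    independent stochastic oracle for ``structure_ahs``.
    """
    if n_samples < 10_000:
        raise ValueError("need at least 10^4 samples")
    rng = np.random.default_rng(seed)
    coords = np.array([a.coords for a in atoms], dtype=float)
    inflated = np.array([a.radius for a in atoms], dtype=float) + probe
    n_atoms = coords.shape[0]
    m = max(1, n_samples // n_atoms)

    total = 0.0
    var = 0.0
    for i in range(n_atoms):
        vec = rng.normal(size=(m, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        pts = coords[i] + inflated[i] * vec
        ok = np.ones(m, dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            ok &= d2 >= inflated[j] ** 2
        if slab is not None:
            ok &= (pts[:, 2] >= slab.z_lo) & (pts[:, 2] <= slab.z_hi)
        frac = ok.mean()
        sphere = 4.0 * math.pi * inflated[i] ** 2
        total += sphere * frac
        var += (sphere**2) * frac * (1 - frac) / m
    return MCEstimate(value=float(total), ci95=float(1.96 * math.sqrt(var)))


def mc_volume(
    atoms: Sequence[AtomRecord],
    probe: float = 0.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> MCEstimate:
    """Monte-Carlo molecular volume (Å³) by rejection sampling in the
    bounding box; independent oracle for the voxel-grid volume."""
    if n_samples < 10_000:
        raise ValueError("need at least 10^4 samples")
    rng = np.random.default_rng(seed)
    coords = np.array([a.coords for a in atoms], dtype=float)
    radii = np.array([a.radius for a in atoms], dtype=float) + probe
    lo = (coords - radii[:, None]).min(axis=0)
    hi = (coords + radii[:, None]).max(axis=0)
    box = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    inside = np.zeros(n_samples, dtype=bool)
    for c, r in zip(coords, radii):
        inside |= np.einsum("ij,ij->i", pts - c, pts - c) < r * r
    frac = inside.mean()
    return MCEstimate(
        value=float(box * frac),
        ci95=float(1.96 * box * math.sqrt(frac * (1 - frac) / n_samples)),
    )


# --------------------------------------------------------------------------
# V_belt vs AHS datasets
# --------------------------------------------------------------------------


def gen_ahs_dataset(
    model: AHSLinearModel,
    n_points: int,
    noise_sd: float,
    seed: int,
    ahs_range: tuple[float, float] = (8_000.0, 45_000.0),
) -> list[tuple[float, float]]:
    """Sample (AHS, V_belt) points from a linear model with Gaussian noise.

    AHS is uniform over ``ahs_range`` (default spans small 6-TMS bundles
    to large multimeric transporters); V_belt = slope·AHS + intercept +
    N(0, noise_sd).
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    ahs = rng.uniform(*ahs_range, size=n_points)
    v = model.slope * ahs + model.intercept
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n_points)
    return list(zip(ahs.tolist(), v.tolist()))


# --------------------------------------------------------------------------
# Packaged fixtures
# --------------------------------------------------------------------------


def load_table1() -> pd.DataFrame:
    """Published detergent:protein quantification table.

    Columns: protein, topology, detergent, purification step, protein
    concentration (μM), corrected detergent concentration (mM), and the
    printed mol/mol ratio with its uncertainty.
    """
    ref = resources.files("detbelt.data").joinpath("table1.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


def write_fixtures(outdir: str | Path, seed: int = 0) -> list[Path]:
    """Write all packaged/synthetic fixtures (spectra CSVs, toy PDBs,
    the stoichiometry table) into ``outdir``; returns the paths."""
    from .ms_quant import load_detergents

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    reg = load_detergents()
    pairs = [("DDM", "DDM-d25", 0.1), ("FC12", "FC12-d38", 0.1)]
    for meas, std, conc in pairs:
        spec = SpectrumSpec(
            species=[reg[meas], reg[std]],
            concentrations=[conc, 0.1],
            noise_sd=3.0,
            seed=seed,
        )
        s = gen_spectrum(spec)
        p = outdir / f"spectrum_{meas.lower()}.csv"
        np.savetxt(
            p,
            np.column_stack((s.mz, s.intensity)),
            delimiter=",",
            header="m/z,intensity",
            comments="# ",
            fmt="%.5f",
        )
        written.append(p)

    table = load_table1()
    p = outdir / "table1.csv"
    table.to_csv(p, index=False)
    written.append(p)

    bundle = gen_shape("helix_bundle", n_helices=4, length=20, bundle_radius=8.0)
    p = outdir / "helix_bundle.pdb"
    with open(p, "w") as fh:
        for i, a in enumerate(bundle, start=1):
            x, y, z = a.coords
            fh.write(
                f"ATOM  {i:5d}  C   ALA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        # membrane boundary markers spanning the central 30 Å
        for j, zd in enumerate((-15.0, 15.0), start=1):
            fh.write(
                f"HETATM{9000 + j:5d}  N   DUM X{j:4d}    "
                f"{0.0:8.3f}{0.0:8.3f}{zd:8.3f}  1.00  0.00           N\n"
            )
        fh.write("END\n")
    written.append(p)
    return written
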