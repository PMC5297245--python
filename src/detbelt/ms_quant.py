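"""Internal-standard MALDI-TOF MS quantification of detergents.

A sample containing the detergent to be measured is spiked with a known
amount of a chemically similar internal standard (ideally a deuterated
form of the same detergent) whose molecular ion is mass-resolved from the
analyte.  Because the two species desorb and ionize near-identically, the
ratio of their peak-cluster abundances maps linearly onto the analyte
concentration via a calibration curve acquired in parallel.

This module covers the full quantification path:

* spectrum I/O (two-column CSV/TSV, optional mzML adapter),
* isotope-envelope computation by elemental convolution,
* peak-cluster integration with signal-to-noise estimation,
* two-species isotopic unmixing (the deuterated standard's envelope can
  overlap the analyte's; a non-negative least-squares split recovers the
  two amplitudes),
* linear calibration, concentration conversion, baseline subtraction,
* detergent:protein stoichiometry, detection/quantification limits,
  automation QC windows, replicate CVs, and a small SEC molecular-weight
  calibration utility used to locate free micelles.

Concentrations are carried as % (w/v) internally; molar conversions happen
only at the interface (``pct_to_molar``).
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Spectrum",
    "DetergentSpecies",
    "IsotopePattern",
    "PeakCluster",
    "CalibrationCurve",
    "QuantResult",
    "StoichiometryRecord",
    "DetectionLimits",
    "parse_formula",
    "monoisotopic_mass",
    "read_spectrum",
    "read_spectrum_mzml",
    "isotope_pattern",
    "cluster_abundance",
    "unmix_ratio",
    "unmix_from_spectrum",
    "fit_calibration",
    "quantify",
    "pct_to_molar",
    "baseline_correct",
    "stoichiometry",
    "detection_limits",
    "qc_accept",
    "replicate_cv",
    "sec_mw",
    "load_detergents",
]

# --------------------------------------------------------------------------
# Elemental data
# --------------------------------------------------------------------------

#: Natural isotopic abundances on a unit-mass (nominal) grid, indexed by
#: integer mass offset from the lightest isotope.  IUPAC 2013 values.
#: "D" denotes a deuterium label (pure 2H, offset 0 within the labelled
#: molecule's own monoisotopic envelope).
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "D": (1.0,),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "F": (1.0,),
    "Na": (1.0,),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Cl": (0.7576, 0.0, 0.2424),
    "I": (1.0,),
}

#: Monoisotopic masses (u) of the lightest isotope (2H for the label "D").
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "D": 2.0141017781,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692809,
    "P": 30.9737615120,
    "S": 31.9720707300,
    "Cl": 34.9688527100,
    "I": 126.9044719,
}

PROTON_MASS = 1.00727646688

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style elemental formula such as ``C24H46O11`` or
    ``C24H21D25O11`` into an element → count mapping."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        element, num = m.group(1), m.group(2)
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    for element in counts:
        if element not in ISOTOPE_ABUNDANCES:
            raise ValueError(f"unknown element symbol {element!r} in {formula!r}")
    return counts


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class Spectrum:
    """One MALDI acquisition: paired m/z (Th) and intensity (counts) arrays.

    m/z is strictly increasing; intensities are non-negative.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size < 1:
            raise ValueError("spectrum must contain at least one point")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class DetergentSpecies:
    """A detergent (or its internal standard) as seen by the spectrometer.

    ``formula`` includes any heavy label, written with the pseudo-element
    ``D`` for deuterium (e.g. FC12-d38 is ``C17D38NO4P``).  ``adduct`` is
    the molecular-ion form, ``M+Na`` or ``M+H``.  ``v_det`` is the
    molecular volume in Å^3, optional until computed.
    """

    name: str
    formula: str
    adduct: str
    mw_avg: float
    v_det: Optional[float] = None
    matrix: Optional[str] = None

    def __post_init__(self) -> None:
        if self.adduct not in ("M+Na", "M+H"):
            raise ValueError(f"adduct must be 'M+Na' or 'M+H', got {self.adduct!r}")
        if self.mw_avg <= 0:
            raise ValueError("mw_avg must be positive")
        parse_formula(self.formula)  # validates

    @property
    def composition(self) -> dict[str, int]:
        return parse_formula(self.formula)

    @property
    def monoisotopic_mz(self) -> float:
        """m/z of the monoisotopic molecular ion, including the adduct."""
        mass = monoisotopic_mass(self.formula)
        if self.adduct == "M+Na":
            return mass + MONOISOTOPIC_MASS["Na"]
        return mass + PROTON_MASS


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (lightest-isotopologue) mass of a neutral formula, u."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in parse_formula(formula).items())


@dataclass
class IsotopePattern:
    """Relative isotopologue abundances on a unit-mass grid.

    ``offsets[i]`` is the integer mass offset from the monoisotopic peak;
    ``probs`` sums to 1.
    """

    offsets: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.offsets.shape != self.probs.shape:
            raise ValueError("offsets and probs must have equal length")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")


@dataclass
class PeakCluster:
    """Integrated isotopologue cluster of one species."""

    abundance: float
    sn: float
    peak_max: float = 0.0
    species: Optional[DetergentSpecies] = None

    def __post_init__(self) -> None:
        if self.abundance < 0 or self.sn < 0:
            raise ValueError("abundance and sn must be non-negative")


@dataclass
class CalibrationCurve:
    """Linear map from measured/standard abundance ratio to % (w/v)."""

    slope: float
    intercept: float
    r2: float
    standard_conc: float

    def __post_init__(self) -> None:
        if self.standard_conc <= 0:
            raise ValueError("standard_conc must be positive")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 must lie in [0, 1]")


@dataclass
class QuantResult:
    ratio: float
    conc_pct: float
    conc_mM: Optional[float] = None
    above_lod: Optional[bool] = None
    above_loq: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.above_loq and self.above_lod is False:
            raise ValueError("above_loq implies above_lod")


@dataclass
class StoichiometryRecord:
    """Detergent:protein molar ratio from corrected concentrations."""

    prot_conc: float  # μM
    det_conc_corrected: float  # mM
    ratio: float  # mol detergent / mol protein
    ratio_rounded: int

    def __post_init__(self) -> None:
        if self.prot_conc <= 0:
            raise ValueError("prot_conc must be positive")
        if self.ratio < 0:
            raise ValueError("ratio must be non-negative")


@dataclass
class DetectionLimits:
    """Lowest concentrations at S/N ≥ 3 (LOD) and ≥ 10 (LOQ); ``None``
    when no point in the dilution series meets the threshold."""

    lod: Optional[float]
    loq: Optional[float]


# --------------------------------------------------------------------------
# Spectrum I/O
# --------------------------------------------------------------------------


def read_spectrum(path: str | Path, fmt: Optional[str] = None) -> Spectrum:
    """Read a two-column (m/z, intensity) CSV or TSV spectrum.

    Lines beginning with ``#`` and blank lines are ignored.  The format is
    inferred from the extension when ``fmt`` is not given.  Points are
    sorted by m/z; duplicate m/z values are merged by summing intensity.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"format must be 'csv' or 'tsv', got {fmt!r}")
    sep = "," if fmt == "csv" else None  # None splits on any whitespace/tab

    mzs: list[float] = []
    ints: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep) if sep else line.split()
            if sep == "," and len(parts) == 1:
                parts = line.split()  # tolerate whitespace in .csv
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                mz = float(parts[0])
                inten = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
            if inten < 0:
                raise ValueError(f"{path}:{lineno}: negative intensity {inten}")
            mzs.append(mz)
            ints.append(inten)
    if not mzs:
        raise ValueError(f"{path}: no data rows")

    mz_arr = np.asarray(mzs)
    int_arr = np.asarray(ints)
    order = np.argsort(mz_arr, kind="stable")
    mz_arr, int_arr = mz_arr[order], int_arr[order]
    uniq, inverse = np.unique(mz_arr, return_inverse=True)
    merged = np.zeros_like(uniq)
    np.add.at(merged, inverse, int_arr)
    return Spectrum(uniq, merged)


def read_spectrum_mzml(path: str | Path, scan: int = 0) -> Spectrum:
    """Adapter: read one scan of an mzML file (requires ``pyteomics``)."""
    from pyteomics import mzml  # optional dependency

    with mzml.read(str(path)) as reader:
        for i, entry in enumerate(reader):
            if i == scan:
                return Spectrum(entry["m/z array"], entry["intensity array"])
    raise ValueError(f"{path}: scan {scan} not found")


# --------------------------------------------------------------------------
# Isotope envelopes
# --------------------------------------------------------------------------


def isotope_pattern(
    species: DetergentSpecies | str, max_offset: int = 8
) -> IsotopePattern:
    """Isotopologue abundance pattern of a species on a unit-mass grid.

    Per-element natural-abundance distributions are convolved (element
    count times each), truncated at ``max_offset`` and renormalized.  The
    adduct (Na or H) contributes its own distribution, which is
    monoisotopic for both and so does not alter the envelope shape.
    """
    if max_offset < 0:
        raise ValueError("max_offset must be non-negative")
    if isinstance(species, DetergentSpecies):
        counts = species.composition
    else:
        counts = parse_formula(species)

    pattern = np.array([1.0])
    for element, n in counts.items():
        dist = np.asarray(ISOTOPE_ABUNDANCES[element])
        for _ in range(n):
            pattern = np.convolve(pattern, dist)
            if pattern.size > max_offset + 1:
                pattern = pattern[: max_offset + 1]
    if pattern.size < max_offset + 1:
        pattern = np.pad(pattern, (0, max_offset + 1 - pattern.size))
    pattern = pattern / pattern.sum()
    return IsotopePattern(np.arange(max_offset + 1), pattern)


# --------------------------------------------------------------------------
# Peak integration and unmixing
# --------------------------------------------------------------------------


def _noise_scale(spec: Spectrum, noise_region: Optional[tuple[float, float]]) -> float:
    """Standard deviation of a signal-free region, floored at 1 count.

    With no region given, the 10% of points with lowest intensity stand in
    for baseline noise.
    """
    if noise_region is not None:
        lo, hi = noise_region
        mask = (spec.mz >= lo) & (spec.mz <= hi)
        if not np.any(mask):
            raise ValueError("noise_region contains no spectrum points")
        vals = spec.intensity[mask]
    else:
        k = max(1, spec.intensity.size // 10)
        vals = np.sort(spec.intensity)[:k]
    return max(float(np.std(vals)), 1.0)


def cluster_abundance(
    spec: Spectrum,
    center_mz: float,
    window: float = 0.5,
    noise_region: Optional[tuple[float, float]] = None,
    species: Optional[DetergentSpecies] = None,
) -> PeakCluster:
    """Integrate the peak cluster at ``center_mz`` ± ``window``.

    Abundance is the summed intensity inside the window; S/N is the window
    maximum divided by the noise scale (sd of a signal-free region, floor
    1 count).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if noise_region is not None:
        lo, hi = noise_region
        if lo <= center_mz + window and hi >= center_mz - window:
            raise ValueError("noise_region must be disjoint from the integration window")
    mask = np.abs(spec.mz - center_mz) <= window
    abundance = float(spec.intensity[mask].sum())
    peak_max = float(spec.intensity[mask].max()) if np.any(mask) else 0.0
    noise = _noise_scale(spec, noise_region)
    sn = peak_max / noise if peak_max > 0 else 0.0
    return PeakCluster(abundance=abundance, sn=sn, peak_max=peak_max, species=species)


def unmix_ratio(
    observed: Sequence[float],
    pattern_meas: IsotopePattern,
    pattern_std: IsotopePattern,
    offset_std: int,
) -> float:
    """Split an observed envelope into measured + standard amplitudes.

    ``observed`` holds intensities over consecutive unit-mass bins whose
    first bin is the measured species' monoisotopic peak; the standard's
    monoisotopic peak sits ``offset_std`` bins later (it may be negative
    if the standard is lighter).  The two normalized envelopes are placed
    at their offsets and the non-negative amplitudes ``A_meas``, ``A_std``
    solved by least squares (clipped at 0).  Returns ``A_meas / A_std``.
    """
    b = np.asarray(observed, dtype=float)
    n = b.size
    a_matrix = np.zeros((n, 2))
    for off, p in zip(pattern_meas.offsets, pattern_meas.probs):
        if 0 <= off < n:
            a_matrix[off, 0] += p
    for off, p in zip(pattern_std.offsets, pattern_std.probs):
        j = off + offset_std
        if 0 <= j < n:
            a_matrix[j, 1] += p
    sol, *_ = np.linalg.lstsq(a_matrix, b, rcond=None)
    a_meas, a_std = np.clip(sol, 0.0, None)
    if a_std <= 0:
        raise ValueError("standard not detected (zero standard amplitude)")
    return float(a_meas / a_std)


def unmix_from_spectrum(
    spec: Spectrum,
    measured: DetergentSpecies,
    standard: DetergentSpecies,
    max_offset: int = 8,
    window: float = 0.5,
) -> float:
    """Isotopically corrected abundance ratio from a raw spectrum.

    The spectrum is summed into ±``window`` bins centered on the two
    species' theoretical isotopologue positions (bins closer than
    ``window`` are merged, so unresolved isotopologues share a bin) and
    the envelope amplitudes are unmixed by non-negative least squares.
    """
    pat_meas = isotope_pattern(measured, max_offset)
    pat_std = isotope_pattern(standard, max_offset)
    positions: list[tuple[float, int, float]] = []
    for col, (sp, pat) in enumerate(
        ((measured, pat_meas), (standard, pat_std))
    ):
        mono = sp.monoisotopic_mz
        positions.extend(
            (mono + float(off), col, float(p))
            for off, p in zip(pat.offsets, pat.probs)
        )
    positions.sort(key=lambda t: t[0])

    # cluster peak positions closer than the integration window
    clusters: list[list[tuple[float, int, float]]] = []
    for entry in positions:
        if clusters and entry[0] - clusters[-1][-1][0] <= window:
            clusters[-1].append(entry)
        else:
            clusters.append([entry])

    observed = np.zeros(len(clusters))
    a_matrix = np.zeros((len(clusters), 2))
    for i, cluster in enumerate(clusters):
        center = float(np.mean([e[0] for e in cluster]))
        observed[i] = spec.intensity[np.abs(spec.mz - center) <= window].sum()
        for _, col, p in cluster:
            a_matrix[i, col] += p
    sol, *_ = np.linalg.lstsq(a_matrix, observed, rcond=None)
    a_meas, a_std = np.clip(sol, 0.0, None)
    if a_std <= 0:
        raise ValueError("standard not detected (zero standard amplitude)")
    return float(a_meas / a_std)


# --------------------------------------------------------------------------
# Calibration and quantification
# --------------------------------------------------------------------------


def fit_calibration(
    points: Sequence[tuple[float, float]], standard_conc: float
) -> CalibrationCurve:
    """Least-squares line through (abundance ratio, concentration) points.

    Concentration (% w/v) is regressed on ratio, matching how calibration
    plots are drawn: the ratio is the abscissa.
    """
    ratios = np.array([p[0] for p in points], dtype=float)
    concs = np.array([p[1] for p in points], dtype=float)
    if ratios.size < 2:
        raise ValueError("need at least 2 calibration points")
    if np.ptp(ratios) == 0:
        raise ValueError("degenerate design: all ratios identical")
    res = stats.linregress(ratios, concs)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=min(r2, 1.0),
        standard_conc=standard_conc,
    )


def quantify(
    ratio: float,
    curve: CalibrationCurve,
    mw: Optional[float] = None,
    sn: Optional[float] = None,
) -> QuantResult:
    """Convert a corrected abundance ratio to concentration.

    Negative back-calculated concentrations are clipped to 0 with a
    warning.  When ``mw`` is supplied the molarity is filled in; when
    ``sn`` is supplied the LOD (S/N ≥ 3) and LOQ (S/N ≥ 10) flags are set.
    """
    if ratio < 0:
        raise ValueError("abundance ratio must be non-negative")
    conc = curve.slope * ratio + curve.intercept
    if conc < 0:
        warnings.warn(
            f"negative back-calculated concentration {conc:.4g}% clipped to 0",
            stacklevel=2,
        )
        conc = 0.0
    conc_mm = pct_to_molar(conc, mw) if mw is not None else None
    above_lod = None if sn is None else sn >= 3.0
    above_loq = None if sn is None else sn >= 10.0
    return QuantResult(
        ratio=ratio,
        conc_pct=conc,
        conc_mM=conc_mm,
        above_lod=above_lod,
        above_loq=above_loq,
    )


def pct_to_molar(conc_pct: float, mw: float) -> float:
    """Convert % (w/v) to mM: 1% (w/v) = 10 g/L, so mM = pct·10/MW·1000."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    if conc_pct < 0:
        raise ValueError("concentration must be non-negative")
    return conc_pct * 10.0 / mw * 1000.0


def baseline_correct(sample_conc: float, buffer_conc: float) -> float:
    """Subtract the running-buffer detergent concentration (floor 0)."""
    if sample_conc < 0 or buffer_conc < 0:
        raise ValueError("concentrations must be non-negative")
    corrected = sample_conc - buffer_conc
    if corrected < 0:
        warnings.warn(
            f"buffer concentration exceeds sample ({buffer_conc} > {sample_conc}); "
            "corrected value floored at 0",
            stacklevel=2,
        )
        corrected = 0.0
    return corrected


def stoichiometry(det_conc_corrected: float, prot_conc: float) -> StoichiometryRecord:
    """Detergent:protein molar ratio.

    ``det_conc_corrected`` in mM, ``prot_conc`` in μM; the ratio is
    mol detergent per mol protein, reported raw and rounded
    (half away from zero, matching integer reporting conventions).
    """
    if prot_conc <= 0:
        raise ValueError("protein concentration must be positive")
    if det_conc_corrected < 0:
        raise ValueError("detergent concentration must be non-negative")
    ratio = det_conc_corrected * 1000.0 / prot_conc
    rounded = int(math.floor(ratio + 0.5))
    return StoichiometryRecord(
        prot_conc=prot_conc,
        det_conc_corrected=det_conc_corrected,
        ratio=ratio,
        ratio_rounded=rounded,
    )


def detection_limits(
    series: Sequence[tuple[float, float]],
    lod_sn: float = 3.0,
    loq_sn: float = 10.0,
) -> DetectionLimits:
    """LOD/LOQ from a dilution series of (concentration, S/N) points.

    The limit is the lowest concentration whose S/N meets the threshold
    (3 for detection, 10 for quantification); ``None`` when no point does.
    """
    lod = None
    loq = None
    for conc, sn in series:
        if sn >= lod_sn and (lod is None or conc < lod):
            lod = conc
        if sn >= loq_sn and (loq is None or conc < loq):
            loq = conc
    return DetectionLimits(lod=lod, loq=loq)


def qc_accept(
    cluster: PeakCluster | float, window: tuple[float, float]
) -> bool:
    """Automation acceptance test: peak maximum inside [low, high] counts.

    Bounds are inclusive.  Mirrors instrument auto-acquisition windows
    such as 1,000–30,000 counts for the DDM sodium adduct at m/z 533 and
    10,000–40,000 counts for FC12 at m/z 352.
    """
    low, high = window
    if low >= high:
        raise ValueError("QC window must satisfy low < high")
    peak = cluster.peak_max if isinstance(cluster, PeakCluster) else float(cluster)
    return low <= peak <= high


def replicate_cv(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Intra-day and inter-day coefficients of variation (%).

    ``groups`` holds replicate measurements grouped by day.  Intra-day CV
    is the per-day sd/mean (sample sd, ddof=1) averaged over days;
    inter-day CV is the sd/mean of the day means.
    """
    if any(len(g) < 2 for g in groups):
        raise ValueError("each day needs at least 2 replicates")
    intra = []
    means = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        m = arr.mean()
        if m == 0:
            raise ValueError("zero mean in replicate group")
        intra.append(arr.std(ddof=1) / m * 100.0)
        means.append(m)
    means_arr = np.asarray(means)
    if means_arr.mean() == 0:
        raise ValueError("zero grand mean")
    inter = (
        float(means_arr.std(ddof=1) / means_arr.mean() * 100.0)
        if means_arr.size > 1
        else 0.0
    )
    return float(np.mean(intra)), inter


def sec_mw(
    elution_volume: float, calibration: Sequence[tuple[float, float]]
) -> float:
    """Apparent MW (kDa) at a SEC elution volume from a log-linear fit.

    Standards are (elution volume mL, MW kDa); log10(MW) is fitted against
    volume by least squares.  Queries outside the calibrated volume range
    trigger an extrapolation warning.
    """
    if len(calibration) < 2:
        raise ValueError("need at least 2 SEC calibration standards")
    vols = np.array([c[0] for c in calibration], dtype=float)
    mws = np.array([c[1] for c in calibration], dtype=float)
    if np.any(mws <= 0):
        raise ValueError("standard MWs must be positive")
    res = stats.linregress(vols, np.log10(mws))
    if elution_volume < vols.min() or elution_volume > vols.max():
        warnings.warn(
            f"elution volume {elution_volume} mL outside calibration range "
            f"[{vols.min()}, {vols.max()}] mL; extrapolating",
            stacklevel=2,
        )
    return float(10 ** (res.slope * elution_volume + res.intercept))


# --------------------------------------------------------------------------
# Detergent registry
# --------------------------------------------------------------------------


def load_detergents() -> dict[str, DetergentSpecies]:
    """Packaged registry of common solubilization detergents.

    Keys are detergent names (e.g. ``DDM``, ``FC12``, deuterated standards
    ``DDM-d25`` / ``FC12-d38``); values carry the elemental formula,
    adduct, average MW and the optimal desorption-helper matrix.
    """
    registry: dict[str, DetergentSpecies] = {}
    ref = resources.files("detbelt.data").joinpath("detergents.csv")
    with ref.open() as fh:
        for row in csv.DictReader(filter(lambda l: not l.startswith("#"), fh)):
            registry[row["name"]] = DetergentSpecies(
                name=row["name"],
                formula=row["formula"],
                adduct=row["adduct"],
                mw_avg=float(row["mw_avg"]),
                matrix=row["matrix"] or None,
            )
    return registry
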