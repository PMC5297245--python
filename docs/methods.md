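# Methods

This note documents the models, numerical choices and limitations behind
`detbelt`, in the order the workflow runs.

## Internal-standard quantification model

The measured detergent M and its internal standard S are assumed to desorb
and ionize proportionally under MALDI, so the ratio of their molecular-ion
cluster abundances is linear in the concentration of M at fixed S. The
calibration design follows the standard protocol: S at 0.1% (w/v) mixed
with M at 0, 0.03, 0.1 and 0.3% (ratios 0, 0.3, 1, 3), concentration
regressed on ratio by unweighted least squares (ratio on the abscissa).
For a perfectly matched (deuterated) standard the slope equals the
standard concentration divided by unity efficiency, i.e. 0.1; a standard
that desorbs better than the analyte raises the slope proportionally (the
LMNG/DMNG pair, slope ≈ 0.143, corresponds to an efficiency ratio of
0.1/0.143 ≈ 0.7, which is how the synthetic generator models it).

### Isotope envelopes and unmixing

Isotopologue envelopes are computed on a unit-mass grid by convolving
per-element natural-abundance distributions (IUPAC 2013), truncating at a
configurable offset (default 8) and renormalizing. Deuterium labels are
treated as a separate monoisotopic pseudo-element `D`, so a deuterated
standard's envelope is the convolution over its *remaining* light
hydrogens — the reason its M+1/M+0 ratio differs from the protonated
analyte's and why a plain window-sum ratio is biased when envelopes
overlap.

Unmixing solves `A_M·pattern_M + A_S·pattern_S ≈ observed` by least
squares with amplitudes clipped at zero (physical abundances); a zero
standard amplitude is an error, not a zero division. Observation bins are
±0.5 Th windows centered on each species' theoretical isotopologue m/z;
bins closer than the window width are merged (unresolved isotopologues
share a bin). For non-overlapping envelopes this reduces exactly to the
ratio of summed window intensities.

### Peak integration and S/N

Spectra are treated as profile-or-centroid agnostic: cluster abundance is
a windowed sum (default ±0.5 Th per unit-mass bin — peak widths are
instrument-dependent and not assumed). The noise scale is the standard
deviation of a user-designated signal-free region, defaulting to the 10%
of points with lowest intensity, floored at 1 count; S/N is the window
maximum over that scale. LOD/LOQ are the lowest concentrations in a
dilution series with S/N ≥ 3 and ≥ 10 respectively. Automation QC uses
inclusive intensity windows (e.g. 1,000–30,000 counts for the DDM sodium
adduct at m/z 533; 10,000–40,000 counts for FC12 at m/z 352).

### Units

Concentrations are carried as % (w/v) internally; conversion to molarity
is `mM = pct × 10 / MW × 1000` (1% w/v = 10 g/L). Note that published
molarities for the detection-limit series (0.2% DDM quoted as 39.2 mM,
0.02% FC12 as 5.6 mM) are 10× this conversion (0.2% DDM at MW 510.6 is
3.92 mM); the implementation keeps the standard conversion. Stoichiometry
is `mol/mol = [Det]_mM × 1000 / [Prot]_μM`, reported raw and rounded half
away from zero to match integer reporting. Baseline correction subtracts
the running-buffer detergent concentration only (free-micelle overlap on
SEC is an experimental-design issue, not corrected numerically).

## Accessible hydrophobic surface

SASA uses the Shrake–Rupley construction: `n_points` (default 960)
quasi-uniform directions per atom on a deterministic golden-spiral
lattice (no RNG, so results are bit-reproducible); a point on the
probe-inflated sphere `r_i + probe` is accessible iff it lies outside
every neighbor's inflated sphere (boundary contact counts as accessible);
per-atom area is the accessible fraction of `4π(r_i+probe)²`. The default
probe is 1.5 Å — the C–C bond length, modeling a detergent alkyl chain
rather than water. Radii are united-atom values after the Chothia/Naccess
convention (C 1.87, N 1.65, O 1.40, S 1.85, P 1.90 Å); hydrogens are
ignored, waters and (by default) hetero-compounds excluded, unknown
elements get 1.80 Å with a warning.

The membrane-restricted AHS counts an accessible point only when its z
coordinate lies in the closed slab `[z_lo, z_hi]`. "Hydrophobic" is thus
implemented as *membrane-limited*, not chemistry-filtered — the slab is
what restricts the surface to the hydrophobic zone; an `apolar_only`
option additionally restricts to C/S atoms. Structures are assumed
membrane-oriented with the normal along z (OPM-style); `slab_from_opm_pdb`
reads the two DUM marker planes (grouped within 0.1 Å) and a `transform`
helper re-orients other inputs. Because slab membership partitions lattice
points, in-slab plus out-of-slab area equals total SASA exactly.

R_p is estimated from atoms within a 3 Å band of each boundary plane:
positions are projected onto xy about the membrane-domain centroid, the
maximum radius is taken in each of 8 azimuthal sectors, and R_p is the
mean of sector maxima over both bands — an automated version of averaging
several protein diameters measured parallel to the membrane plane. Bands
with fewer atoms than sectors raise an error suggesting a wider band.

## Belt model

The belt is an annular cylinder of height H (the slab thickness): its
volume must simultaneously equal `N·V_det` and `π(R_t²−R_p²)·H`, giving
`R_t = sqrt(V_belt/(πH) + R_p²)` and `R_belt = R_t − R_p`. The
`BeltGeometry` container enforces both identities to 1e-6 relative, so an
inconsistent parameter set cannot be constructed.

V_det is a voxel-grid volume (default spacing 0.25 Å): voxels whose
center falls inside any sphere `r_i + probe` count toward the volume. The
default probe is 0 (van-der-Waals volume) because the published workflow
defers to an external cavity program without stating the volume flavor; a
probe-inflated variant is exposed. Reported absolute R_t/R_belt values
therefore depend on the V_det convention chosen — the geometry algebra is
exact, but a ~10% change in V_det moves R_belt by several Å.

The V_belt-vs-AHS relation is fitted by ordinary least squares
(statsmodels) with coefficient standard errors; at least 3 points are
required. `predict_n` inverts the line at a given AHS and divides by
V_det; a negative predicted volume (AHS below the line's root — possible
because the fitted intercept is negative) maps to N = 0 with a warning
rather than an error. Belt visualization writes pseudo-carbon rings
filling the annulus at ~2 Å spacing as fixed-column HETATM records.

## Synthetic data and what it does(n't) show

`gen_spectrum` places Gaussian isotopologue peaks (default σ = 0.08 Th,
reflectron-like resolution at m/z ~500) with areas proportional to
concentration × desorption efficiency × isotopologue probability, plus
optional Gaussian baseline noise, on a 0.02 Th grid; the default area
scale puts a 0.1% (w/v) acquisition in the low-thousands of counts,
inside typical QC windows. Efficiency 1 models a deuterated standard;
0.7 the LMNG/DMNG mismatch. The generator does *not* model matrix
heterogeneity ("sweet spots"), detector saturation, chemical background,
or mass-dependent resolution — so passing recovery tests demonstrate the
correctness of the unmixing/calibration pipeline, not robustness to all
MALDI artifacts (the method's defense against spot heterogeneity is the
internal standard itself, which the generator bakes in as a shared
efficiency).

Toy structures (sphere clusters, cylinder shells, ideal poly-carbon
helix bundles with 1.5 Å rise and 2.3 Å helix radius) have analytic
geometry for oracle tests. Monte-Carlo estimators (`mc_sasa`,
`mc_volume`) implement the same accessibility/slab rules by rejection
sampling with binomial confidence intervals and serve as independent
stochastic oracles for the lattice and voxel methods. All generators are
pure functions of their parameters and an explicit seed.

## Problem sizes and numerical defaults

Test and acceptance runs use small, fixed problem sizes chosen for tight
oracle agreement at interactive speed: lattice SASA at 960–2000 points
(isolated-sphere error < 0.5%; ≤ 50-atom fixtures agree with ≥ 4·10⁵-sample
Monte Carlo within 1%), voxel volumes at 0.1–0.25 Å spacing (≤ 2% of the
analytic or Monte-Carlo value), calibration-recovery simulations at 200
seeds and end-to-end quantification at 50–100 seeded acquisitions.
Cylinder algebra round-trips to 1e-9 relative over 10⁴ random triples.

## Known limitations

* The belt is a right circular annulus of uniform thickness; real belts
  observed by cryo-EM can be irregular (15–20 Å variation), and
  non-cylindrical or micelle-shape analyses are out of scope.
* Absolute per-protein AHS values require the actual PDB structures and a
  conformer choice (published conformer-to-conformer spread is 1.5–9.5%);
  the package computes per-file values and leaves averaging to the user.
* Orientation is consumed, not computed: inputs must be membrane-oriented
  (OPM) or rotated with the provided helper.
* The two-species unmixing assumes exactly one analyte and one standard
  per envelope region; general deconvolution of detergent mixtures beyond
  pairwise windows is not attempted (mixtures are handled by quantifying
  each pair at its own m/z region).
* mzML input is a thin optional adapter; vendor raw formats are not read.
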