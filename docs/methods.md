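# Methods

This note documents the models, conventions and numerical choices behind
`pepmem`, and what the synthetic-data generators do and do not emulate.

## Trajectory model and membrane metrics

A `Trajectory` is a stack of frames of labelled coordinates (Å) with a
per-frame orthorhombic box. Every atom carries exactly one role —
`headgroup`, `acyl`, `peptide` or `solvent` — assigned on ingestion from a
residue/atom classification table. The acyl region of a lipid is defined
as the beads below the ester carbon; the ester carbon itself counts as
headgroup. GRO input (nm) is converted to Å when read; everything internal
is Å and Å².

**Bilayer centre of mass.** Computed per frame over lipid atoms only
(headgroup + acyl), with unit weights. Peptide and solvent atoms are
excluded so that asymmetric peptide binding does not shift the reference.

**Insertion depth.** Z^pos for a residue is the unsigned z-distance of its
Cβ bead from the bilayer COM, averaged over frames; chains bound to the
lower leaflet are folded onto the upper by the absolute value. The
"normalisation" of depths is exactly this folding — no scaling by leaflet
thickness is applied. Per-residue means and SDs are taken across chains
(the chains are the independent samples). The phosphate and ester-carbon
planes are reported with the same convention for visual reference.

**Thickness and area per lipid.** Thickness is the distance between the
mean phosphate z of the two leaflets; leaflets are assigned once, at frame
0, by the sign of z relative to the bilayer COM (tetrapeptide systems show
no lipid flip-flop on analysis timescales, so no tracking is attempted).
Area per lipid is L_x·L_y divided by the lipids in one leaflet. Both are
per-frame series summarised by block-averaged mean ± SE.

**Superposition and ensemble statistics.** RMSD is always computed after
optimal least-squares superposition (Kabsch via SVD); degenerate
reflection branches are resolved to the determinant-positive rotation. The
ensemble-average structure is computed self-consistently (superpose onto
the current average, re-average, iterate to convergence — a handful of
iterations for compact tetrapeptide ensembles). R_g uses unit weights
about each conformer's centroid. The "native-like fraction" metric counts
frames below a 3 Å heavy-atom RMSD threshold to a reference conformer,
the conventional cut-off for these tetrapeptides.

**SASA.** Shrake–Rupley sphere-point sampling with a deterministic
golden-spiral point set; the dot density (default 960 points/atom) and
probe radius (default 1.4 Å, water) are parameters. Atomic radii come from
a bundled element→radius table. Solvent atoms are excluded from the solute
set entirely. An atom's exposed area counts toward its own role group, so
component areas sum exactly to the total; tests verify the sampler against
an independent latitude–longitude grid quadrature to within 2%.

**Lateral RDF.** Pair distances use x–y separations only, with minimum
image in x and y. Counts per annulus are normalised by the ideal-gas
expectation (annulus area × mean target surface density per frame);
self-pairs are excluded and the target density corrected when the
selections overlap.

**Block averaging.** The SE of the mean is estimated from non-overlapping
block means over doubling block sizes; the chosen block is the first at
which the SE changes by less than 5% (configurable) between consecutive
sizes. If no plateau is reached the largest block is reported with a
warning, never silently.

## NOE ensemble/time averaging

NOE intensities scale as r⁻⁶, so a restraint applied to an ensemble of N
chains is scored by the r⁻⁶-weighted ensemble average r*(t), which is
dominated by the shortest chain distances; r*(t) always lies between the
ensemble minimum and maximum. Time averaging applies an r⁻³-weighted
forward window of (τ/Δt)+1 samples (defaults τ = 10 ps, Δt = 1 ps);
terminal windows are truncated and renormalised by the actual sample
count, so a constant series is a fixed point of both operators. The window
form follows the flat-window formula; an exponential-memory ("decay
time") variant is a documented alternative reading that this package does
not implement. A window counts as a violation when r̄* exceeds the
experimental upper bound plus a 0.3 Å buffer tolerance. The compliance
summary is the share of restraints violated in fewer than 20% of windows.
Restraint tables are expected pre-reduced for degenerate/methyl protons —
distances are taken to the provided coordinate as-is, with no intra-chain
r⁻⁶ sub-averaging. The ensemble size is taken from the data, not assumed.

## ITC one-site model

Geometry: peptide in the cell, lipid vesicles titrated in. Externally
added peptide reaches only the outer leaflet, so the binding axis is the
effective lipid concentration, total × outer-leaflet fraction. The default
fraction 0.5 is the symmetric-leaflet assumption appropriate for ~100 nm
LUVs; it is configurable for smaller, more asymmetric vesicles.

The model treats each peptide as n independent, identical lipid sites.
With S = n·[peptide], X = [lipid]eff and per-site dissociation constant
K_D, the bound site fraction is the closed-form quadratic root

    θ = ½ [ 1 + X/S + K_D/S − sqrt((1 + X/S + K_D/S)² − 4X/S) ],

the cell heat content is Q = θ·S·V₀·ΔH, and per-injection heats are
successive differences. The overfill perfusion cell uses the standard
displacement ladder — cell species diluted by (1 − v/2V₀)/(1 + v/2V₀),
titrant accumulating as (v/V₀)(1 − v/2V₀), and the injection heat
corrected by (dV/V₀)·(Qᵢ + Qᵢ₋₁)/2 — switchable to a plain growing-volume
model (`displacement="simple"`). The synthetic generator uses the same
forward model, so noiseless isotherms invert exactly; recovery under noise
is what the repeated-fit tests measure.

Fitting is nonlinear least squares (Levenberg–Marquardt) with n and K_D in
log space to enforce positivity; standard errors come from the Gauss–Newton
covariance mapped back by the delta method. Starting values are read off
the isotherm (stoichiometry from the half-heat molar ratio, ΔH from the
total heat, K_D from a c ≈ 10 guess). A c-value (n·[peptide]/K_D) outside
1–1000 triggers a warning, not a failure. ΔG = RT·ln K_D (molar scale),
TΔS = ΔH − ΔG exactly, temperatures default to 298.15 K, energies are
kJ/mol and K_D is reported in µM.

The membrane footprint is n × Σ (mole fraction × lipid cross-sectional
area); reports round to the nearest Å² while the library function returns
the exact value. Note that ΔG computed from first principles for the
published K_D range endpoints (≈ −26.0 kJ/mol at 27.5 µM, 298.15 K) can
differ in the last digit from independently rounded published ΔG values,
because K_D/ΔG pairings within a range are not recoverable from range
endpoints.

## Fluorescence titrations

Traces are normalised by the mean over a stated baseline window
(idempotent by construction). Plateaus are read deterministically as the
mean over the final 50% (configurable) of each inter-addition interval,
with the right edge exclusive so the next addition's first sample never
contaminates the read — a deterministic stand-in for reading steady
segments by eye. Saturation uses a one-site hyperbola R_max·d/(K + d); a
flat response is flagged unidentifiable rather than fitted. The ANEPPS
ratio reads each excitation intensity as a mean over ±2 nm. No conversion
of any probe response to millivolts is attempted: responses are reported
in probe units only. The PFG-NMR hydration radius uses
R_h = R_h,ref × D_ref/D_analyte, with DSS (3.34 Å) as the default internal
reference; viscosity cancels in the ratio.

## Sequence space

Enumeration is over L-residue codes only; stereochemistry is carried as
metadata because D-substitution enlarges the space combinatorially without
changing the register/charge bookkeeping this module does. Unnatural
residues (e.g. 2',6'-dimethyltyrosine) join via the extensible residue
registry. Net charge at physiological pH is +1 per basic side chain, +1
for the N-terminal amine, −1 for a free-acid C terminus (0 when amidated).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *study conditions*: 150 lipids (75 per
leaflet) at 20:80 TOCL:POPC, phosphate planes near ±19 Å (38 Å thickness),
a composition-weighted area per lipid of 81.8 Å², 20 surface-bound
tetrapeptides split across leaflets with per-residue target depths inside
the phosphate/ester band, 20-chain NOE ensembles at 1 ps spacing, and the
20 × 2.5 µl / 170 µl / 150 µM / 8 mM ITC protocol. Default ITC truth is
{n = 5, K_D = 30 µM, ΔH = −5 kJ/mol}, in the experimentally observed
range; titration traces use 10 nmol additions with a 20 nmol
half-saturation dose.

They are *not* simulations: lipids are 4–6-bead pseudo-atom templates,
peptide dynamics are independent Gaussian jitter about target depths (no
force field, no thermostat, no realistic lipid dynamics, no correlation
between frames except the piecewise-constant NOE segments), and box
fluctuations are uncorrelated Gaussian area noise. Consequently, passing
tests demonstrate that the *estimators* are correct — geometry is
recovered, averaging operators match their formulas, fits invert their
forward models under noise — not that the generators resemble real
membranes dynamically. Real-data features such as leaflet flip-flop,
correlated undulations, baseline drift in calorimetry, or photobleaching
in fluorescence are out of scope and untested.

All generators are pure functions of (parameters, seed); per-artifact
sub-streams are derived deterministically from the single seed, and every
emitted file embeds its generation parameters and seed in a provenance
header.

## Problem sizes and numerical tolerances

Test fixtures are sized for a single CPU: trajectories of 20–500 frames
and ~800 pseudo-atoms, NOE series of 10³–2×10⁴ frames × 20 chains, 50-seed
ITC recovery studies, and SASA clusters of ≤10 atoms against a dense grid
oracle. Equality checks on averaging operators use 1e-10 absolute
tolerance; designed NOE violation fractions are checked within 3 binomial
standard errors plus a 5-percentage-point allowance for window-boundary
mixing at segment edges; geometric recovery uses 3 standard errors from
the generated samples themselves. The block-average plateau tolerance is
5% relative change between doubling block sizes.

## Known limitations

- The NOE time average implements the flat forward window only, not an
  exponential-memory decay.
- PDB output stores a single CRYST1 record, so per-frame box fluctuations
  survive only in the frames text format.
- The Wiseman fit covers the single-site model only; multi-site,
  cooperative and surface-partitioning models are out of scope.
- Leaflet assignment is static (frame 0); systems with lipid flip-flop
  would need tracking.
- SASA uses fixed per-element radii; no united-atom or force-field
  specific radius sets are bundled.
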