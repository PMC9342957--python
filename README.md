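# pepmem

Quantitative analysis tools for the membrane biophysics of
mitochondria-targeted cationic-aromatic tetrapeptides (Szeto–Schiller-type
peptides such as SS-31, SS-20 and their sequence variants). These
tetrapeptides alternate basic (B) and aromatic (φ) residues, carry a
C-terminal amide (net charge +3), and act at the cardiolipin-rich inner
mitochondrial membrane. `pepmem` is written for biophysicists who study
such peptides with molecular-dynamics simulations, NMR distance restraints,
isothermal titration calorimetry (ITC), and fluorescence titrations — and
who want every analysis step testable on synthetic fixtures with known
ground truth.

## What it computes

**Membrane-trajectory metrics** (`pepmem.traj_analysis`) on role-tagged
coordinate trajectories of peptide/bilayer systems:

- per-residue insertion depth Z^pos = ⟨|z(Cβ) − z(bilayer COM)|⟩, with the
  lower leaflet folded onto the upper, plus phosphate/ester reference planes;
- bilayer thickness (phosphate-plane separation) and area per lipid
  (L_x·L_y divided by the lipids in one leaflet);
- ensemble statistics: radius of gyration R_g and RMSD to the ensemble
  average after optimal (Kabsch) superposition, and the fraction of
  simulation time within an RMSD threshold (default 3 Å) of a reference
  conformer;
- Shrake–Rupley solvent-accessible surface area (SASA) partitioned into
  headgroup, acyl and peptide components, with the acyl region defined as
  the beads below the ester carbon;
- lateral (x–y plane) radial distribution functions g(r) with minimum-image
  periodicity;
- block-averaged standard errors for correlated time series.

**NOE restraint compliance** (`pepmem.noe`): the r⁻⁶-weighted instantaneous
ensemble average over N chains,

    r*(t) = [ (1/N) Σᵢ rᵢ(t)⁻⁶ ]^(−1/6),

followed by an r⁻³-weighted forward time window (τ = 10 ps, Δt = 1 ps),

    r̄*(t) = [ (1/m) Σ_{j=t}^{t+τ/Δt} r*(j)⁻³ ]^(−1/3),

and violation statistics against the experimental upper bounds plus a
0.3 Å buffer tolerance, including the summary share of restraints violated
less than 20% of the time. Only i→i+2 and i→i+3 restraints pass the
long-range filter used for restrained simulations.

**ITC thermodynamics** (`pepmem.itc`): a statsmodels-style
`WisemanModel`/`WisemanResults` pair fits lipid-into-peptide isotherms to
the single-site (independent identical sites) binding model on the
effective-lipid axis, [lipid]eff = outer-leaflet fraction × total lipid.
The fit returns {n, K_D, ΔH} with standard errors and derives
ΔG = RT·ln K_D, TΔS = ΔH − ΔG, and the entropy/enthalpy balance TΔS/|ΔH|.
The per-peptide membrane footprint is n × (composition-weighted lipid
cross-sectional area); for the 80:20 POPC:TOCL bilayers used in the
titrations that area is 0.8×70 + 0.2×129 = 81.8 Å².

**Fluorescence titrations** (`pepmem.titration`): baseline normalisation of
probe time courses (1,8-ANS for surface potential ψ_s, TMRM for
transmembrane potential ΔΨ_m), plateau extraction and one-site hyperbolic
saturation fits (`SaturationModel`), the di-8-ANEPPS dual-excitation ratio
R = I(420 nm)/I(520 nm) for dipole potential ψ_d, and the PFG-NMR hydration
radius conversion against the DSS internal standard (R_h = 3.34 Å).

**Sequence space** (`pepmem.seqspace`): enumeration of the alternating
B-φ-B-φ / φ-B-φ-B tetrapeptide design space ({Arg, Lys} × {Phe, Tyr, Trp}
over both registers gives 3²×2²×2 = 72 permutations), register
classification and net-charge accounting.

**Synthetic data** (`pepmem.synthetic`): seeded generators for every input
above — a pseudo-atom lamellar bilayer (150 lipids, 20:80 TOCL:POPC, 20
surface-bound peptides), NOE distance ensembles with designed violation
fractions, one-site ITC isotherms with Gaussian noise, and saturable
titration traces — each recording its ground truth and seed for
provenance.

## Worked example

```python
from pepmem import SyntheticTruth, make_itc_isotherm, WisemanModel, footprint
from pepmem.itc import ITC_COMPOSITION

truth = SyntheticTruth(seed=42, itc_noise_sd_uJ=1.0)   # n=5, K_D=30 µM, ΔH=−5 kJ/mol
exp = make_itc_isotherm(truth)                          # 20 × 2.5 µl of 8 mM lipid
result = WisemanModel(exp).fit()                        # into 170 µl of 150 µM peptide
print(result.summary())
print(f"footprint: {footprint(result.params.n, ITC_COMPOSITION):.0f} A^2 per peptide")
```

prints

```
One-site ITC fit (lipid-into-peptide, effective lipid axis)
  injections: 20, cell 150 µM peptide, syringe 8 mM total lipid (outer fraction 0.5)
  T = 298.15 K, c-value = 25.7, RSS = 12.33 µJ²
  n (lipids/peptide)    5.02 ± 0.04
  K_D                   29.26 ± 2.32 µM
  ΔH                   -4.906 ± 0.0519 kJ/mol
  ΔG                   -25.88 kJ/mol
  TΔS                   20.97 kJ/mol
  TΔS/|ΔH|              4.275
```

The fitted stoichiometry (5.02 lipids per peptide) and K_D (29.3 µM)
recover the generator's ground truth within the noise; ΔG and TΔS are
derived from the fit, and the positive TΔS/|ΔH| ≈ 4.3 marks binding
dominated by entropy, as is typical for aromatic side-chain burial in the
membrane interface. The footprint line converts the stoichiometry into the
membrane area occluded per bound peptide (here 411 Å²).

A command-line pipeline wraps the same library:

```sh
pepmem all --outdir out --seed 1     # trajectory metrics, NOE, ITC, titration, seqspace
pepmem itc --outdir out --seed 1     # a single stage
```

Each report names the config hash and seed that produced it, and
`out/run.log` records parameters and overrides.

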