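# Methods

`curcumetry` implements, as a tested pipeline, a computational workflow
for explaining how curcuminoids interact with the amyloid-β fragment
Aβ(25–35): conformer-ensemble generation and folded/semi-folded/extended
classification of the ligands, Monte-Carlo/simulated-annealing docking to
the Aβ(25–35) helix, α-helix heptad-repeat mimicry analysis, and the two
spectroscopic quantifications that anchor the modelling to experiment
(outer hyperfine splitting 2A_max from spin-label EPR, and helix/sheet/coil
fractions from far-UV CD).

## Ligand model and energy function

Each curcuminoid tautomer (curcumin diketone and keto-enol,
demethoxy- and bisdemethoxycurcumin, cyclocurcumin, tetrahydrocurcumin) is
shipped as a SMILES template with the tautomer encoded explicitly; users
can supply SMILES or SDF instead.  A topology carries, per atom, Gasteiger
partial charges and UFF van-der-Waals parameters (x_ii, D_ii), and three
classes of torsions:

* **Rotatable torsions** — acyclic single bonds with two non-terminal heavy
  neighbours.  Bonds on the inter-ring bridge are labelled `tau1..tauN`
  (ordered from aryl ring X toward ring Y) and define conformer
  subfamilies; peripheral bonds (methoxy, aryl–O) are labelled `chi*` and
  are sampled but not subfamily-defining.
* **Constrained torsions** — acyclic C=C double bonds, restrained to the
  chain-trans arrangement (180°, k = 100 kcal/mol) so that 1000 K annealing
  cannot isomerize them.  Torsion reference atoms follow the bridge chain,
  so "180°" always means chain-trans while substituents such as the enol
  OH stay cis to the chain.
* **The β-ketoenol chelate** — in keto-enol tautomers the
  C(=O)–C(enol) single bond sits inside the resonance-assisted
  intramolecular H-bond ring (O=C–C=C–O–H).  It is configurationally
  locked s-Z (restrained at its chelated value, k = 100) and removed from
  the sampled set; the hydroxyl proton is oriented into the chelate at
  build time.  Rationale: the RAHB plus π delocalization give this bond a
  rotation barrier far above anything 1000 K annealing should cross, and
  the chelate is what makes the keto-enol bridge a rigid, fully conjugated
  unit.

Intramolecular energies are MMFF94 (RDKit implementation).  The medium
enters through the Coulomb dielectric: `polar` ε = 80·r (distance-dependent,
aqueous), `apolar` ε = 1 (constant, membrane-like), `docking` ε = 30·r
(80/20 fluorinated-alcohol/water mixture), `scoring` ε = 2·r.  "ε = k·r"
is the standard distance-dependent-dielectric reading: the effective
dielectric grows linearly with the interatomic distance in Å.

**Bridge planarity restraint.**  MMFF94's torsional barriers for the
conjugated acyclic sp²–sp² single bonds of the enone bridge (aryl–vinyl,
vinyl–carbonyl) are shallow enough that annealing finds twisted,
π-stacked folded minima which the fully delocalized bridge rules out
(keto-enol curcumin is planar in every published crystal form).  The
energy model therefore adds a twofold restraint `k·sin²τ`
(k = 10 kcal/mol, minima at 0° and 180°) on those bonds.  The restraint
leaves the s-cis/s-trans choice free — conformer diversity comes from
flips between planar states — and only suppresses out-of-plane twists.

**Ionization.**  Ionized fractions follow Henderson–Hasselbalch at
pH 7.2 by default (`100/(1+10^(pKa−pH))` for acids, mirrored for bases).
pKa values are user inputs (defaults: phenol 9.5, enol 8.5); the shipped
templates are the neutral forms, which are the dominant species for these
compounds at cytoplasmic pH with those pKa defaults.

## Conformational search

The annealing schedule is: heat 300 → 1000 K over 2000 fs (3 fs steps),
hold at 1000 K for 2000 fs, cool to 300 K over 1000 fs (1 fs steps);
200 cycles by default, one retained structure per cycle, each cycle
continuing from the previous minimized endpoint.  The sampler realizes
this schedule as Metropolis Monte Carlo in torsion space (one random
torsion perturbed per "timestep", uniform ±120°) rather than Cartesian
molecular dynamics — the sampled object is the torsional landscape, which
is what the classification consumes.

Two hybrid elements make the torsional walk sample the *relaxed* energy
surface, as Cartesian dynamics does continuously:

1. **Interleaved relaxations** — at the end of the hold phase and every
   100 cooling steps, a short Cartesian MMFF minimization (≤ 500 steps)
   drops the geometry into its local basin.
2. **Basin-hopping flip sweeps** — at each relaxation point, every bridge
   (`tau`) torsion in random order is offered a 180° flip followed by
   relaxation, accepted by Metropolis on the *relaxed* energies.  This
   equilibrates the populations of planar basins separated by the ~10
   kcal/mol conjugation barriers down to the 300 K cooling target;
   without it the walk freezes near 500 K and over-populates minor
   basins several kcal/mol above the global minimum.  Flip proposals are
   symmetric, so detailed balance holds at each temperature.

Every cycle ends with a full Cartesian minimization (RMS force below
0.001 kcal/(mol·Å), 10 000-step cap, non-convergence flagged).  The cap
mirrors the docking minimizer's stated iteration limit.  Ensembles are
deduplicated on the labelled torsions (identical within 30° across the
board keeps the lower energy) and sorted by energy; ΔE is measured from
the global minimum (GM).  The apolar stage re-minimizes every polar-stage
endpoint at constant ε = 1 — a molecular-mechanics stand-in for a
semi-empirical low-dielectric re-optimization, usable only qualitatively.

**Occurrence rates** are computed over all minimized cycle endpoints
(percentages in 1/n_cycles steps), not over unique minima: this is the
population whose family frequencies the occurrence-rate table reports.
A `count="unique"` option switches to deduplicated minima.

## Classification

d1 is the distance between the unweighted heavy-atom centroids of the two
terminal aryl rings.  Families: folded d1 ≤ 5 Å; semi-folded
5 < d1 < 9 Å; extended d1 ≥ 9 Å — applied strictly per conformer by
default.  Subfamilies (conf I, II, …) bin each `tau` torsion to the
nearest of {0°, ±60°, ±120°, 180°} (ties toward the lower absolute
angle).  Because conformer-family analyses conventionally label a torsionally
homogeneous subfamily with a single family even where individual members
cross a d1 boundary, a `family_override_by_subfamily` flag reassigns
threshold-crossing conformers to their subfamily's majority family, with
every reassignment logged; the default remains strict.

Intramolecular H-bonds use a geometric criterion: donor–acceptor
heavy-atom distance ≤ 3.5 Å and D–H⋯A angle ≥ 120°, with pairs fewer
than three bonds apart excluded.

"Low-energy" filtering, where requested, keeps ΔE ≤ 5 kcal/mol from the
GM.

## Peptide helix and heptad mimicry

Ideal α-helices (φ = −57°, ψ = −47°, ω = 180°, Engh–Huber-like backbone
geometry) are built from sequence by natural-extension (NeRF) placement;
side chains come from the Chemical Component Dictionary idealized
residues, superimposed on the local backbone frame — the CCD geometry is
the default rotamer.  Amide hydrogens are placed in the peptide plane.
The Aβ(25–35) stand-in is `build_ideal_helix("GSNKGAIIGLM")` numbered
25–35; its interior O(i)⋯N(i+4) distances are 3.09 Å.

The heptad scan returns all (i, i+4, i+7) triples whose three positions
are hydrophobic (A V L I M F W Y) except that one may be asparagine — on
Aβ(25–35) this selects Asn27/Ile31/Leu34.  Side-chain centroids are
unweighted heavy-atom means (glycine is an error).  Ligand
superimposition rigidly fits the three ligand pharmacophore centroids
(ring X, central moiety, ring Y) onto (i, i+4, i+7) with a proper-rotation
Kabsch fit; the central moiety is the dihydropyranone ring for
cyclocurcumin and the bridge heavy atoms for the open curcuminoids.

Frozen construction constants (used as no-download surrogates for
reference-structure measurements): ideal i→i+4 CA distance 6.40 Å;
poly-Leu i↔i+7 side-chain centroid distance 11.05 Å.  The corresponding
measurement on a real coiled-coil helix (8.20 Å) requires the reference
PDB entries and is reported by the heptad scan whenever such files are
supplied.

## Docking

The starting complex superimposes the cyclocurcumin GM conformer onto the
heptad triple of the helix.  The peptide is then held **rigid**: only the
ligand moves (torsions plus rigid-body translation/rotation).  This is a
deliberate narrowing — the observables of interest are ligand-geometry
quantities (d1 of the bound pose, pose stability), and a flexible peptide
would demand a full protein force field without changing those
observables' definitions.  The helix backbone H-bond distances of the
Asn27–Leu34 stretch (the structurally conserved region the protocol
restrains, target ≤ 2.5 Å donor–acceptor) are monitored and reported on every
complex instead of being enforced on a moving backbone.

Energies: ligand internal MMFF94 at ε = 30·r, plus ligand–peptide
Lennard-Jones (UFF parameters, geometric combining) and Coulomb terms
(Gasteiger ligand charges; a compact polar-atom charge set for the
peptide, residue-neutralized onto CA) with ε = 30·r while docking and
ε = 2·r for the reported interaction energy, group-based 100 Å cutoff
(groups: peptide residues vs. the whole ligand).  A soft-core floor at
r² = 0.4 Å² prevents singularities during random placement.

Monte-Carlo generation accepts up to 20 complexes: each attempt moves the
ligand from the last accepted structure by a random translation (≤ 3 Å),
rotation (≤ 180°) and torsion changes; pre-screens at 0.1-scaled
nonbonded terms against a 10⁶ kcal/mol tolerance (deliberately huge — it
exists to guarantee input variance); minimizes over rigid-body + torsion
coordinates (bounded L-BFGS with a 10 000-evaluation cap, standing in for
the conjugate-gradient Cartesian minimizer; translations are bounded by
MxRChange so a clashed start relaxes in place instead of being ejected
down the separation coordinate); then applies the 50 kcal/mol
energy-window test versus the best structure and a 0.3 Å ligand-RMS
dissimilarity test versus all previously accepted poses.  The "0.3"
similarity tolerance is read as 0.3 Å structural RMS.  The minimized
starting complex counts as the first accepted structure.

SA refinement anneals each complex 500 → 300 K over 50 stages of 100 fs
(Metropolis in the same coordinate space, move sizes annealed with
temperature) while the nonbonded scaling ramps 0.1 → 1.0, ending with an
unrestrained minimization.  A complex is **bound** if any ligand–peptide
heavy-atom contact is ≤ 4.5 Å, and **stable** if additionally the ligand
pose RMSD to its pre-annealing pose stays below 2.0 Å (the "same binding
mode" criterion; the threshold is this package's choice, as the source
protocol states the concept without a number).  Ranking sorts by
conformational energy (ligand internal + interaction; the rigid peptide's
internal energy is a constant); the representative is the complex that is
simultaneously lowest in conformational energy and most favorable in
interaction energy, falling back to the former with a logged note, and is
re-minimized without restraints before being reported.

## EPR: 2A_max extraction

The extractor smooths the first-derivative spectrum with a
Savitzky–Golay filter (~2 G window, cubic), locates the global maximum in
the low-field 40% of the sweep and the global minimum in the high-field
40%, refines both by a windowed least-squares parabola (±0.8 G; a 3-point
parabola would translate residual noise directly into position jitter),
and reports the difference.
The 40% windows (configurable) cover outer splittings down to 20 G on the
standard 100 G / 1024-point sweep.  Features must exceed three times the
noise floor (median absolute deviation of the smoothing residual), else
an `UnresolvedSplittingError` is raised — noise is an error, not a
number.  Intensities are never renormalized; only field positions enter
the result.  Values outside a 20–70 G plausibility window are flagged,
not rejected.

Δ2A_max is the signed difference (perturbed − reference) between spectra
of the same label; the perturbation table reports, per lipid system ×
label × ligand, the shift upon ligand inclusion and upon peptide
addition.

The generator models only what the extractor measures: three
derivative-Gaussian lines whose outer extrema are programmed at
B₀ ± splitting/2, with the order parameter mapping monotonically from
2·A_iso (32 G at A_iso = 16 G) to 55 G, plus white noise set by the SNR.
The generator's SNR is referenced to the smallest analyzed feature (the
high-field outer extremum), since resolvability of the outer lines — not
the dominant central line — is what limits the measurement; at SNR 20 the
extraction is unbiased within two grid steps with a random scatter well
under 0.5 G.
It is not a spin-physics simulation: no stochastic-Liouville lineshapes,
no A∥/A⊥ order-parameter decomposition, no field-dependent linewidths —
so passing round trips validate the extraction logic, not spectroscopic
fidelity on real spectrometer exports.

## CD: secondary-structure fractions

A spectrum is fit as a non-negative linear combination of three synthetic
reference curves (helix: minima 208/222 nm, maximum 192 nm; sheet:
minimum 218 nm, maximum 196 nm; coil: minimum 198 nm) by NNLS, and the
coefficients are renormalized to sum to one; the fit residual is
reported.  This documented stand-in deliberately does not reimplement
CONTIN/SELCON/K2D, and the three-class output matches the reported
helix/sheet/coil decomposition.  Absolute calibration to instrument
units is out of scope; only basis-relative fractions are meaningful.
`compare_conditions` reports signed per-class deltas and a
helix-stabilizing verdict when Δhelix exceeds +0.05 (configurable).

## Problem sizes and determinism

Default protocol scale is 200 SA cycles; the shipped acceptance script
uses 50 cycles per seed with three pooled seeds for the cyclocurcumin
ensembles, a 50-cycle run for keto-enol curcumin, and a docking run with
up to 10 complexes at 15 attempts each — sizes chosen so a complete
end-to-end run finishes in minutes on a single core while keeping every
protocol parameter (temperatures, durations, restraints, windows) at its
stated value.  All stochastic stages consume a `numpy` `Generator` seeded
from user input; identical seeds give bitwise-identical torsion tables,
accepted-complex lists and generated spectra.

## Known limitations

* CVFF and PM7 are replaced by MMFF94 (+ constant-ε re-minimization);
  absolute energies and the apolar-stage populations are comparable only
  qualitatively.  The diketone tautomers fold less readily under MMFF94
  with screened electrostatics than the original force field reports.
* The torsional sampler does not sample ring puckering; for
  cyclocurcumin the dihydropyranone half-chair flip is reached only
  through the interleaved Cartesian relaxations.
* The rigid-peptide docking cannot report induced-fit effects or
  peptide-side conformational strain; the survival statistic after
  annealing (how many complexes stay bound) is force-field dependent and
  treated as qualitative.
* The spectral generators are extraction-grade emulations; real
  spectrometer exports (baseline drift, phase errors, instrument units)
  are out of scope.
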