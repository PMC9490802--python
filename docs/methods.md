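# Methods

This note documents the models and procedures implemented in `aquagate`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Units, geometry and superposition

All lengths are nm, all times ns (frame periods in ps), angles in
degrees. PDB/GRO coordinates are converted from angstrom on read.
Superposition is the mass-unweighted Kabsch fit (orthogonal Procrustes
with a proper rotation) over a Calpha selection; the default fit
selection is the transmembrane bundle of one protomer (residues 7–35,
41–63, 69–79, 83–119, 145–167, 178–196, 204–217, 232–255). A portable
CSV trajectory format (`frame,time_ps,atom_id,x_nm,y_nm,z_nm`, six
decimals) is first class so that fixtures and synthetic data never need
binary MD formats; XTC/DCD/TRR are read through MDAnalysis when present.

## Permeation counting

Waters are labelled per frame against a counting cylinder (default 2.2 nm
long, 1.5 nm radius, axis along z, centred on the protomer's centre of
mass after superposition): `below`/`above` beyond the axial caps,
`inside` within the slab and radius, `outside_radius` within the slab but
radially beyond. A crossing is a cap → interior⁺ → opposite-cap sequence
with no `outside_radius` frame in between; touching `outside_radius`
resets the machine to the last cap visited, and re-entering the entry cap
restarts the transit clock. Events are timestamped at the first frame
beyond the exit cap, so half-open flux windows partition events uniquely.

The generous 1.5-nm cylinder admits waters that slip *around* the protein
rather than through the single-file pore. These are removed by a
configurable containment filter: an event is spurious if its path exceeds
`r_sf = 0.4 nm` radially anywhere in the single-file slab
`|z| <= z_sf = 0.8 nm`. The published analysis corrected such
misassignments with an unpublished script; the radial containment
criterion is this package's operationalization and the defaults are
package choices — both thresholds are exposed and recorded in outputs.

The flux outcome used by the statistics layer is the **total**
bidirectional crossing count per window. At equilibrium the net directed
flux is zero in expectation, and the magnitude of the reported per-window
counts is only consistent with event totals; a `net` mode is nevertheless
provided.

## Gating-state registry

Each of the nine modulating residues carries one descriptor:

| residue | descriptor | states (edges) | reference |
|---|---|---|---|
| W48 | torsion CA-CB-CG-CD1, [−180, 180) | blocked [−180,0), partial [0,70), open [70,180) | open |
| R206 | four-point torsion CA-CB-CG-CZ, [0, 360) | bins at 50, 115, 160, 210, 240, 290 | [290,360) |
| F200 | min side-chain distance to P196 | near < 0.37 nm ≤ far | far |
| A201 | min distance to W48 | blocking < 0.35 nm ≤ open | open |
| M202 | min distance to L21 | in_pore < 0.40 nm ≤ out | out |
| N203 | min distance to I187 | in_pore < 0.30 nm ≤ out | out |
| N68 | min distance to V52 | in_pore < 0.45 nm ≤ out | out |
| H66 | min distance to I183 | in_pore < 0.35 nm ≤ out | out |
| V173 | min distance to L75 | in_pore < 0.40 nm ≤ out | out |

Threshold semantics are strict ("less than"): a value exactly at a
threshold belongs to the upper bin; all bins are half-open `[lo, hi)`.
Torsions follow the IUPAC sign convention and need not connect bonded
atoms (R206's CA-CB-CG-CZ is the torsion of the four points). Minimum
distances use heavy side-chain atoms from Cbeta outward by default —
the crystal frame carries no hydrogens, so thresholds calibrated on it
must be hydrogen-free — with an `all` policy available since a
simulation-topology mindist that includes hydrogens can shift values by
roughly 0.05–0.1 nm. The registry is data driven (YAML round-trip) and
extensible.

### Reference frame

The deposited crystal coordinates are not bundled with the package; the
reference frame used in tests and the acceptance script is a **synthetic
stand-in** (`synthetic_reference_structure`), constructed from idealized
internal coordinates so that every published crystal descriptor value
holds by construction: W48 torsion 103°, R206 four-point torsion 311°,
M202–L21 minimum distance 0.82 nm, and all remaining descriptors in
their open reference states (their exact crystal separations are not
published; plausible above-threshold values are used). Checks against
this frame validate the descriptor and classification code end to end,
not the crystallographic coordinates themselves.

## Interval scheme

Property windows are 5 ns, flux windows 5 ns lagged by 3 ns (2 ns
overlap), advancing by a stride of 10/3 ns within the analysis range
(default [1000, 3000] ns — the first microsecond is treated as
equilibration). The stride is not stated in the source analysis; 10/3 ns
is back-computed so that 2,000 ns of analyzed time yields exactly 599
paired windows per pore, hence 14,376 rows for 24 pores. A pair is
emitted whenever its *property* window lies inside the analysis range;
the trailing flux windows may overhang the nominal end by up to the lag
(1.33 ns at the defaults), which the event series must cover. Overlapping
windows are used as-is: no autocorrelation correction is applied across
them, a known limitation of the interval design.

Phase fractions are computed per property window and per residue; the
reference-state column of each residue is dropped (k−1 encoding, since
fractions sum to one). A diagnostic mode keeps all columns.

## Count model

Negative binomial (NB2: variance mu + mu²/phi) with log link; linear
predictor = intercept + per-state phase-percentage effects + a varying
intercept per pore. Priors are weakly informative:
alpha ~ student-t(3, log mean(y), 2.5); beta ~ Normal(0, 2.5);
sigma_u ~ half-student-t(3, 0, 2.5); 1/sqrt(phi) ~ Exponential(1).
With ~14k rows these priors are dominated by the likelihood. With fewer
than two pores the varying intercept is dropped (it would be
unidentified against the intercept).

Sampling: affine-invariant ensemble MCMC (emcee) with
differential-evolution moves (80% DE, 20% snooker), vectorized across
walkers; the walker count defaults to max(4·ndim, 64). Two independent
ensembles are run for 2,000 iterations each, the first 1,000 discarded —
mirroring the study's two-chain budget. Scale parameters are sampled on
the log scale with Jacobians; a quadratic penalty outside a wide safe
range keeps the likelihood finite. A Poisson GLM point estimate
(statsmodels) seeds the walkers; it initializes, never replaces, the
Bayesian fit.

Diagnostics: each independent ensemble enters ArviZ as one chain, its
walkers pooled per iteration. Split-Rhat then compares the two
independent ensembles and each ensemble's early/late halves; bulk-ESS is
computed on the pooled series. Thresholds Rhat ≤ 1.01 and ESS ≥ 400
follow current MCMC practice (the source analysis names the measures but
not cutoffs).

Prediction: for a residue fully occupying a state, its predictors are set
to the state indicator (all zero for the reference state); other
residues are held at the dataset means by default (policy `reference`
zeroes them instead — the source does not state its conditioning); the
group effect defaults to the population level u = 0. Reported are the
posterior mean and 2.5/97.5 percentiles of mu, in waters per 5-ns flux
window.

Relative permeability across variants is the per-pore mean event count
per 100 ns, averaged per variant with SEM across pores, and ratios to the
wild type with standard error propagation.

## Synthetic data

The generators emulate the statistical structure the analysis consumes,
not the physics:

- **Gating traces**: independent continuous-time Markov chains per
  residue with exponential dwell times (uniform routing between states),
  sampled on the 10-ps frame grid. Default occupancies approximate the
  wild-type state populations; dwell scales are tens of nanoseconds,
  matching the observed temporary flipping events. Real gating is
  correlated across residues (e.g. F200 flipping is often compensated by
  A201); the generator's independence means recovery tests validate the
  statistical model, not the biology.
- **Flux counts**: the NB model run forward with known coefficients. The
  default truth sets the open-pore rate to 4.6 waters per 5 ns and each
  state's effect to the log-contrast of its published per-state rate
  against its residue's reference rate. The recovery configuration
  (`recovery_spec`) uses one two-state gate (open 4.6, blocked 1.0,
  12.5% blocked occupancy), sigma_u = 0.2, phi = 10, 24 pores × 2,000 ns.
  Counts in overlapping flux windows are drawn independently — a
  simplification relative to counting one event stream.
- **Toy trajectories**: single-file crossers ramp axially through the
  cylinder at small radius with planted entry/exit times; half-crossers
  retreat; radial escapees traverse the slab at 1.0 nm radius (outside
  `r_sf`, inside the counting radius) and must be removed by the filter;
  bulk decoys wander outside. Ground truth is derived from the
  construction, independently of the counter.

All generators are reproducible bit-for-bit given (seed, spec); seeds are
threaded through `numpy.random.default_rng` seed sequences.

## Ancillary metrics

Per-segment Calpha RMSD (fit on the TM bundle, measure per segment,
SEM across protomers), water dipole tilt to the membrane normal binned
along z (charge-weighted dipole when charges are supplied, otherwise the
H-H bisector), and water–residue hydrogen bonds under the standard
0.35 nm / 150° (D-H···A) geometric criterion — the source states no
criterion, so the convention is recorded in the output. Topologies
without hydrogens raise a capability error pointing to the distance-only
descriptors.

## Numerical choices and degenerate inputs

- Half-open conventions everywhere (windows, bins, compartment slabs);
  boundary values go to the upper bin, the axial/radial cylinder
  boundaries are inclusive on the inside.
- Angle wrap maps any input into the descriptor's domain; a rounding
  artefact that lands exactly on the upper domain edge wraps to the lower
  edge.
- Colinear torsion triples, empty side chains (glycine), empty event
  lists, empty windows and single-chain diagnostics raise typed errors
  rather than returning NaN.
- The linear predictor is clipped at ±30 before exponentiation during
  sampling to keep proposals finite.

## Validation scales and limitations

The test suite and the acceptance script run at the study's data scale
for the statistics layer (24 pores × 599 windows; five seeded recovery
replicates with 2 × 2,000 iterations) and at desk scale for the geometry
and counting layers (toy trajectories of ~23 waters × 30 ns). Recovery
coverage is a statistical statement: with correctly calibrated 95%
intervals, roughly one check in twenty fails by construction, and the
per-replicate realized mean of the pore intercepts shifts both state
predictions jointly.

Known limitations: no autocorrelation handling across overlapping
windows; residue-state generators are independent across residues; the
spurious-path filter is an operationalization of an unpublished
correction; the stand-in reference frame validates code paths, not
crystallographic geometry; no osmotic-permeability estimators and no
glycerol tracking.
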