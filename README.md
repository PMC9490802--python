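# aquagate

Gating-state and single-file water permeation analysis for aquaporin
molecular-dynamics trajectories, built around the *E. coli*
aquaglyceroporin GlpF.

Aquaporin water permeability is usually treated as a property of a
continuously open pore. In GlpF, however, several pore-lining residues —
the ar/R selectivity filter (W48, F200, R206), the NPA asparagines (N68,
N203) and their neighbours (A201, M202, H66, V173) — transiently rotate or
flip into the pore lumen and throttle the single-file water column.
`aquagate` quantifies this link: it counts complete water crossings
through a per-protomer cylinder, classifies each residue's side-chain
descriptor (a torsion or a minimum side-chain distance) into named gating
states, and fits a Bayesian count model that attributes flux differences
to those states. It is a library for structural-bioinformatics users,
with a thin `aquagate` CLI for end-to-end pipeline runs.

## The model

Time is cut into paired windows: a 5-ns *property* window followed, with
2 ns overlap, by a 5-ns *flux* window (conformation precedes transport).
For window *i* of pore *j* the number of waters crossing in the flux
window is modelled as negative binomial with a log link:

```
y_ij ~ NB(mu_ij, phi),     Var(y) = mu + mu^2/phi
log mu_ij = alpha + sum_{r, p != ref} beta_{r,p} x_{r,p,ij} + u_j
u_j ~ Normal(0, sigma_u)
```

where `x_{r,p,ij}` is the fraction of the property window that residue
*r* spends in state *p* (the reference state's column is dropped — k−1
encoding), and `u_j` is a varying intercept per pore. Posterior sampling
uses an ensemble MCMC (emcee, differential-evolution moves) with
split-Rhat/bulk-ESS diagnostics via ArviZ; `predict_state_flux` reports
the expected waters per 5 ns for a residue fully occupying one state,
with a 95% credible interval.

Because the underlying multi-microsecond trajectories are not publicly
deposited, the package ships a first-class synthetic-data module: Markov
gating traces with exponential dwell times, NB flux counts generated from
known coefficients, toy 3-D water trajectories with planted crossings,
and a synthetic stand-in reference frame realizing the published crystal
descriptor values.

## Worked example

```sh
python examples/fit_state_flux.py
```

generates 8 pores × 500 ns of gating/flux data from a known truth
(open 4.6, blocked 1.0 waters per 5 ns, sigma_u = 0.2, phi = 10), fits the
model and prints:

```
dataset: 1192 rows, mean flux count 4.26
converged: True (max Rhat 1.0058, min ESS 50496)

per-state predicted waters per 5 ns (95% CI) vs truth:
  open      4.72  [ 4.45,  4.99]   truth 4.60
  blocked   0.97  [ 0.82,  1.13]   truth 1.00
```

Both generating truths fall inside their 95% credible intervals; the
blocked state's ~4.6-fold flux reduction is recovered from ~1,200 noisy
interval counts. The other examples cover permeation counting against
planted ground truth (`count_permeation.py`), descriptor evaluation and
state classification (`gating_states.py`), and interval-dataset assembly
at study scale (`interval_dataset.py`). A full staged pipeline run:

```sh
aquagate run --config examples/pipeline.yaml --seed 3
```

## Layout

- `src/aquagate/structures.py` — structure/trajectory model, PDB/GRO and
  XTC/DCD/TRR readers (MDAnalysis), portable CSV trajectory, Kabsch fit
- `src/aquagate/permeation.py` — cylinder compartments, crossing state
  machine, spurious-path filter, windowed flux
- `src/aquagate/gating.py` — descriptor evaluation, state registry,
  classification, populations
- `src/aquagate/intervals.py` — paired property/flux windows, phase
  fractions, dataset assembly
- `src/aquagate/model.py` — NB multilevel model, diagnostics, prediction,
  relative permeability across variants
- `src/aquagate/synthetic.py` — generators with known ground truth
- `src/aquagate/metrics.py` — segment RMSD, water dipole tilt profile,
  hydrogen-bond counts
- `src/aquagate/pipeline.py`, `cli.py` — staged orchestration and CLI

See `docs/methods.md` for the modelling choices and their rationale.
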