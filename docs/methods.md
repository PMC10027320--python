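# Methods

## Model family

All models are mass-action-boundary / Michaelis–Menten-interior ODE systems
over pathway metabolites `M0..Mn` and cycled co-substrate pools. A pool is
two state variables (forms 0 and 1) linked to reactions through couplings:
a coupling with direction +1 converts ν molecules of form 0 to form 1 per
catalytic event. Because every reaction moves the two forms
antisymmetrically, `a0 + a1` is conserved exactly by construction whenever
pool synthesis/degradation is disabled; with it enabled the total relaxes
to `(ksyn0 + ksyn1)/kdeg` with rate `kdeg` (linear subsystem, closed form
used as a test oracle).

Rate laws act on composite concentration products. An uncoupled reaction
sees `m_sub`; a pool-coupled reaction sees `m_sub · a_consumed^ν`, with the
Michaelis constant stored as the composite constant dividing that product
(units mM^(1+ν)). A configuration switch (`km_interpretation:
per_substrate`) instead squares a per-substrate constant, covering both
readings of captioned KM values. The reversible law is the one-site form

    net = (Vf·sf/Kf − Vr·sr/Kr) / (1 + sf/Kf + sr/Kr),

which reduces pointwise to the irreversible law as the reverse terms
vanish (property-tested). No Haldane constraint is enforced between the
two directions; that is deliberate scope, not an oversight.

Internal units are mM and seconds everywhere; config files may declare µM
or minutes/hours and are converted once at the boundary.

## Motifs and their defaults

* **Single reaction** — primary enzyme on `a0·m0`, background turnover of
  `a1`, influx/outflux on `M0`/`M1`. Reference parameters (used throughout
  tests and the acceptance runs): Etot = 0.01 mM, kcat = 100 /s,
  KM = 0.05 (composite), kout = 0.1 /s, background enzyme at 1.2× (or
  0.7× for the turnover-limited regime) the primary Vmax. The 1.2× factor
  is applied once, to Vmax; the alternative reading (scaling both Etot and
  kcat, hence 1.44× Vmax) would only rescale the cycling limit.
* **Linear chain** — steps 1..n with intra-pathway cycling declared as
  (consume_step, regenerate_step, pool, ν) entries; multiple pools and
  ν > 1 are supported; a consume-only entry requires a background turnover
  enzyme, otherwise the pool cannot be stationary and construction fails.
  The blockage analyses use reversible chain enzymes (kcat_r = kcat,
  KM_r = KM): with irreversible steps only the cycling-limited step's own
  substrate accumulates, whereas reversibility propagates the blockage
  upstream, which is the behaviour the motif is meant to capture.
* **Branched** — two branches from `M0`, entry steps `M0 → M1,i`
  uncoupled, commit steps `M1,i → M2,i` consuming pool A or B, a fast
  pathway-independent background (Vmax = 10, KM = 1) regenerating each
  pool, all other parameters 1. The entry steps are reversible by default.
  This is a structural necessity, not a tuning choice: with identical
  irreversible entry steps the two branch fluxes are forced equal at any
  steady state and no pool-size regulation of the split is possible.
  Reversible entries let product back-pressure redistribute the flux, and
  reproduce the divergence pattern (`M0` plus the limited branch's `M1,i`)
  above threshold.
* **Coupled** — two pathways `M0,i → M1,i` sharing one pool, pathway 1
  converting form 1 → 0 and pathway 2 form 0 → 1; slow symmetric
  background turnover (Vmax = 0.01, KM = 1, set 0 to disable); all other
  parameters 1; reversible kinetics by default.

## Steady states and feasibility

The single irreversible motif has the closed form given in the README; the
two feasibility inequalities are independent (one involves only the
primary enzyme, the other only pool size and turnover kinetics).

Everything else is numeric: integrate in geometrically growing chunks
(LSODA, rtol 1e-8, atol 1e-10 by default), after each chunk attempt a
Powell-hybrid root polish on the conservation-reduced system (one free
form per conserved pool, so totals are enforced exactly; accepted only if
all species ≥ 0 and max |RHS| < 1e-8). Divergence is declared when a
species exceeds 10⁶× its initial scale (floored at 1e-3 mM) with positive
derivative — the finite proxy for "accumulates towards infinity" — or,
catching slow unbounded growth early, when it rises monotonically and
substantially over three consecutive chunks, sits well above its initial
scale, and no fixed point can be located. Remaining cases are `undecided`,
reported as a status, never an exception.

Two numerical safeguards matter near the feasibility boundary, where the
stiffness ratio blows up as one pool form approaches zero while an
upstream metabolite grows without bound: each chunk runs under a
wall-clock guard with a BDF retry (LSODA's corrector can stall there),
and chunk ends are clamped to the predicted cap-crossing time so
divergence is caught at a chunk boundary. With these in place a 50×50
(Atot, kin) grid classifies all 2500 cells in agreement with the analytic
region in about a minute; grid cells the solver cannot decide are flagged
with a three-valued status rather than forced into a class.

## Influx noise and trajectory statistics

The coupled-pathway noise process draws waiting times from an exponential
with mean τ; at each switch the log ratio of the two influxes is a
standard normal draw and the pair is rescaled to keep the arithmetic mean
at `mean_kin` (a geometric-mean variant is available; the arithmetic
reading is the default because only "the mean" is specified). Integration
restarts exactly at each switch; one seeded generator produces the whole
schedule, so a fixed seed gives bit-identical events. Output correlation
is Pearson on series resampled to a uniform grid after a 10% burn-in;
constant series yield an explicit undefined flag rather than NaN. The
acceptance runs use τ = 5 s against a pathway relaxation time of ~1 s
(kout = 1), t = 2000 s, 2000 sample points: long enough for several
hundred switches while keeping the full suite inside a few minutes on one
CPU.

Observed regimes (reproduced by the acceptance script): outputs
correlate at ≈ +1 for Atot ≲ 1 (the pool throughput couples the two
pathway fluxes; identical with background turnover 0.01 or 0), and
anti-correlate for Atot ≳ 10 (each output tracks its own influx, and the
influx pair is anti-correlated by construction). Symmetric influxes reach
steady state over at least two decades of magnitude, while the same total
split 0.9/0.1 diverges — the cycling limit binds the influx *difference*
against the background turnover capacity.

## Flux survey

The enzyme limit is `E·kcat·3600` in mmol gDW⁻¹ h⁻¹, the saturation limit
multiplies by `s/(KM+s)` and never exceeds it (asserted record-wise).
`v` strictly below the limit counts as below; ties do not. Fractions are
over records whose limit is computable; rows with missing mandatory
fields are retained but flagged. Flux–pool fits are OLS per reaction with
nRMSE = RMSE / mean(v) (mean-normalisation is a package convention; the
max−min alternative was considered and rejected as more sensitive to
single conditions). Significance is a two-sided Pearson p with
Benjamini–Hochberg adjustment within each flux source; measured and
FBA-derived records are never pooled in fits because FBA flux–pool
correlations can be confounded by flux–flux coupling. ΔrG′ is consumed as
an input column (provider convention: 1 mM reactants, pH 7), never
computed.

## Synthetic data

The survey generator emulates the structure of the condition-resolved
E. coli screen: 45 reactions × 7 conditions, ATP/NADH/NADPH labels cycled
across reactions, 7 reactions (49 records) measured and the rest
FBA-sourced, 80% of records below the enzyme limit. "Below" records are
placed uniformly under the saturation-corrected limit (so the planted
fraction is exact for both screening modes); "above" records sit 5–50%
over the raw limit. Three measured reactions carry a planted linear
flux–pool relation (slope 2, 2% relative noise) with enzyme levels raised
so the line is never clipped by the below assignment; these plants are
forced into the below quota, which the target fraction must accommodate.
Kinetic constants are drawn log-uniformly from ranges spanning roughly
two decades around the reference values (enzymes 1 µM–0.1 mM, kcat
1–1000 /s, KM 1 µM–1 mM, pools 10 µM–10 mM) — package conventions for a
physiological range. What the generator does **not** emulate: real
condition identities, absolute proteome scaling, measurement error
structure beyond independent relative noise, or flux–flux correlations
within FBA solutions. Passing the recovery tests therefore demonstrates
that the screening machinery is correct, not that the biological
conclusions hold on real tables.

## Known limitations

* Closed forms exist only for the single-reaction motif; chains with
  n > 3 are handled numerically by design.
* The divergence classification is a finite-horizon proxy; trajectories
  growing slower than the three-chunk rule at sub-cap levels are reported
  `undecided`.
* The branched motif's reversible entry steps are an inference from the
  motif's intended behaviour (see above); an all-irreversible variant
  builds and integrates but pins the flux ratio to 1.
* No SBML import/export, allosteric regulation, thermodynamic parameter
  constraints, or stochastic (Gillespie) kinetics.
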