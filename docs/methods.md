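# Methods

## Model

The package implements an empirical mass-action model of a cell-free
GDP-mannose synthesis/regeneration cascade. Five enzyme activities are
described: glucokinase phosphorylates mannose with ATP (irreversible,
bimolecular); 1-domain polyphosphate kinase 2 reversibly phosphorylates GDP
and ADP from inorganic polyphosphate (two independent linear reversible
laws); the phosphomannomutase/guanylyltransferase pair ManB/ManC is lumped
into a single reversible reaction man6P + GTP ⇌ GDP-man + PP plus a slow
first-order pyrophosphate-cleaving side activity; inorganic pyrophosphatase
hydrolyses PP to 2 Pi; and the transmembrane-deleted mannosyltransferase
Alg1 transfers mannose from GDP-man to the phytanyl-PP-(GlcNAc)₂ acceptor
with an empirical law quadratic in both substrate concentrations.

Key structural assumptions, all inherited from how the constants were
estimated:

- **Units.** Concentrations are mol/L, enzyme loadings g/L, time minutes.
  The constants are interpreted on this scale, consistent with their
  printed units (e.g. k₁ in L²/(min·g·mol)).
- **Lumping.** Mannose-1-phosphate is not a state variable; the
  mutase/guanylyltransferase sub-equilibrium is absorbed into the lumped
  r4. Michaelis–Menten or inhibition terms are deliberately absent — the
  data behind the constants were described by plain mass action.
- **Polyphosphate.** PolyP is tracked only as a phosphate-equivalent
  bookkeeping pool (4 mM of average chain length 14 → 56 mM equivalents);
  it enters no rate law because the kinase constants are only valid at the
  4 mM operating point (polyphosphate both activates and, above ~6 mM,
  inhibits the kinase). The simulator flags a pool that would go negative.
- **Pyrophosphatase idealisation.** Two realisations are provided:
  `fast_kinetic` (default) uses the fast first-order law with
  k₆ = 13.152 L/(min·g); `strict_instant` eliminates PP algebraically
  (initial PP converted up front, PP produced by r4 routed directly to
  2 Pi, [PP] ≡ 0). The printed law for the pyrophosphatase reaction carries
  an `e_man` factor in the source table; this is treated as a typesetting
  slip and the pyrophosphatase's own loading is used, since it is that
  enzyme's reaction. The two modes agree to ~1.6% in cascade GDP-man, not
  exactly: K_eq3 = 0.032 is small enough that the ~1.6 µM steady-state PP
  of the kinetic mode drives a noticeable reverse flux through r4.
- **Conservation.** Four moiety pools (adenine = ATP+ADP; guanine =
  GDP+GTP+GDP-man; mannose = man+man6P+GDP-man+Man1; lipid = Phyt+Man1)
  are conserved by construction, asserted at model build time and checked
  to relative 1e-9 on every trajectory. Man1 carries mannose and lipid but
  no guanine — the transferase releases GDP.

### Parameters

| name | value | units | role |
|------|-------|-------|------|
| k1 | 11.320 | L²/(min·g·mol) | glucokinase |
| k2, Keq1 | 0.519, 2.289 | L/(min·g), – | GDP phosphorylation |
| k3, Keq2 | 0.439, 1.816 | L/(min·g), – | ADP phosphorylation |
| k4, Keq3 | 18.163, 0.032 | L²/(min·g·mol), – | lumped GDP-man synthesis |
| k5 | 0.130 | L/(min·g) | ManB/ManC PP cleavage |
| k6 | 13.152 | L/(min·g) | pyrophosphatase |
| k7 | 8.1·10⁹ | L⁴/(min·g·mol³) | mannosyl transfer |
| k4_opt | 4.6·10⁻³ | L²/(min·g·mol) | cascade refit of k4 |
| k2_opt, k3_opt | 0.097, 0.041 | L/(min·g) | coupled-cascade kinase refit |

All constants must be strictly positive; reactions can instead be removed
outright via `disabled_reactions` (used, e.g., to study the pure r4
equilibrium without PP cleavage).

**The k4_opt caveat.** The source table reports a cascade-refit k4 of
4.6·10⁻³ — roughly 4000-fold *smaller* than the single-enzyme 18.163 —
while the accompanying narrative describes *enhanced* ManB/ManC activity
in the enzyme mixture. On the mol/L scale 4.6·10⁻³ produces negligible
flux, so it cannot be the constant behind the reported cascade agreement.
Our own simulations show that an enhanced k4 of roughly 30–50 would
reproduce the reported cascade titre; we therefore treat the printed
k4_opt value as unreliable, expose it unchanged as a configuration
alternative, and keep k4 = 18.163 as the default. Consequently the
simulated cascade *underestimates* the experimentally reported GDP-man
trajectory (≈367 µM vs 566 µM at 240 min; steady rate ≈2.0 vs 2.7 µM/min)
— the same underestimate the source describes for its own base model —
and the coupled cascade gives ≈24 µM Man1 against the reported ≈80 µM.
These discrepancies are properties of the printed constants, not of the
integration: the analytic equilibria, closed-form relaxations and
conservation laws are reproduced to ≤0.1%.

Similarly, the quadratic Alg1 law converts 90% of the acceptor in ~17 min
but — because the rate falls with [Phyt]² — needs ~255 min for 99%, so
"full conversion within 20 min" holds only at the ~90% level under this
law.

## Simulation

`solve_ivp` with LSODA (stiff-capable; the pyrophosphatase step is the
fast mode of the system), default rtol 1e-8 and atol 1e-12 mol/L. Dense
output on a 481-point grid merged with the design's sampling schedule.
Negative undershoots are clipped to zero inside rate evaluation only; the
raw solver state is preserved and clip events are counted in the solver
report. Halving the tolerances moves the 240-min cascade GDP-man titre by
<0.01%. Equilibrium ratios require |d[species]/dt| < 1e-9 mol/(L·min) at
the final time (printed equilibrium constants carry four significant
digits). The lag estimate is the earliest time after which the local
finite-difference slope stays within 20% of the window's least-squares
slope; the window, [60, 240] min by default, is configurable — the source
of the lag convention is a design choice, since no formal definition
accompanies the reported "60 min lag".

## Parameter estimation

The objective is Σ ((model − data)/scale)² over datasets, observed
species, times and replicates, with scale = max |data| per species per
dataset, so µM-scale nucleotides and mM-scale sugars weigh comparably.
(The original study names its optimisers but not its objective or
weighting; this normalisation is a declared choice.) Simulation failures
map to an `inf` sentinel. The search runs in log10 space within positive
bounds (default 1e-6…1e12 native units — the constants span >12 decades).
Two derivative-free algorithms are provided: multi-start Nelder-Mead
(scipy, adaptive simplex, incumbent polish; default 5 seeded starts) and a
particle-swarm pattern-search hybrid (20 particles, inertia 0.72,
cognitive/social 1.49, compass-search polish), implemented in-package and
deterministic per seed. Each experiment collection is fitted independently
by default; joint fits are a model built over several collections. The
cascade refits adjust exactly `k4` (plain cascade) or `k2`+`k3` (coupled
cascade) with everything else frozen.

Noiseless self-fits on the full design library recover every constant to
relative 1e-4; at 5% CV noise the glucokinase constant is recovered with
<5% median error over 20 seeds (both re-run by the acceptance suite).

## Synthetic data

The design library mirrors the six experiment collections of the study —
glucokinase 16, pyrophosphatase 13, polyphosphate kinase 25, ManB/ManC 42,
Alg1 8 and cascade 16 reactions (the cascade runs carry four replicates;
the Alg1-coupled fixture three). The exact concentration grids and time
schedules of the single-enzyme experiments are not published; the library
spans the reported ranges (glucokinase mannose ≤10 mM at 1.7 mM ATP;
kinase nucleotides 0.15–0.5 mM at 4 mM PolyP; ManB/ManC substrates
0.4–1.7 mM and enzyme 0.086–0.855 g/L; pyrophosphate 0.015–0.225 mM) on an
11-point schedule to 240 min (denser for the fast pyrophosphatase and
Alg1 reactions). Noise is multiplicative Gaussian (5% CV) plus an additive
2 µM floor, truncated at zero like a censoring detector — a conventional
precision class for a validated ion-chromatography assay, since the
original assay-validation figures are not published. What passing recovery
tests show is therefore identifiability under well-behaved, unbiased noise
on the model's own trajectories; they cannot speak to model misspecification,
peak-integration artefacts or run-to-run drift in real chromatography data.

## Diagnostics

Selwyn's test replots product curves measured at several enzyme loadings
against e₀·t; coincidence indicates the absence of enzyme inactivation.
The overlap statistic is the mean over a common 100-point e₀·t grid of the
across-curve range divided by the pointwise pooled mean (grid points with
negligible pooled mean are skipped); the verdict threshold defaults to
0.05, both configurable — the original test is graphical and defines no
numeric criterion. For simulated stable enzymes the statistic is ~1e-9
(every rate is linear in the loading, so superposition is exact); a
30-min enzyme half-life raises it far above threshold. The simulator
supports first-order enzyme decay for exactly this oracle.

## Known limitations

- No temperature, pH, MgCl₂ or polyphosphate-concentration dependence: the
  constants are valid at 30 °C, pH 7.5, 10 mM MgCl₂, 4 mM PolyP₁₄ only;
  conditions are carried as design metadata.
- The printed k4_opt inconsistency above; both values are exposed, neither
  silently corrected.
- The quadratic Alg1 law is mechanistically unusual and is implemented
  exactly as printed.
- Deterministic ODEs only — no stochastic simulation, no fed-batch or
  spatial effects, no confidence intervals on fits (recovery studies
  quantify estimator spread instead).
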