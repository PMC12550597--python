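# Methods

`reactbo` studies one question in silico: when a reaction-optimization
problem contains a categorical choice (here, the identity of a nucleophilic
catalyst), how should that choice be presented to a Bayesian optimizer?
The package implements three encodings, a kinetic ground-truth simulator,
single- and multi-objective acquisition loops, and a replicated comparison
harness. This note records the models, the defaults and the design choices.

## Catalyst descriptors

A catalyst carries Mayr's nucleophilicity parameter *N* (dimensionless, the
nucleophile-specific term of the linear free-energy relationship
log k = s·(N + E)), the Mayr sensitivity *s* (default 1.0 when a table omits
it), a molar mass (g/mol) and an abstract cost per gram. Every *N* value has
a provenance tag: `database`, `regression_estimate`, or `fixture`.

The fixture table shipped with the benchmarks is synthetic: six catalysts
(`cat01`…`cat06`) with *N* equally spaced from 12 to 27, the range spanned
by pyridine-type through bicyclic-guanidine organocatalysts. Real database
values are deliberately not hardcoded; users substitute their own CSV.

**Regression estimation.** For a catalyst absent from the databases, *N* is
back-estimated from a calibration screen: unweighted ordinary least squares
of yield on *N* over the known catalysts, inverted at the new catalyst's
observed yield, N̂ = (y − â)/b̂. The estimate is refused
(`NucleophilicityNotIdentifiable`) when fewer than two distinct *N* values
are available or when |b̂| < 1e-6 per *N* unit, below which the inversion
amplifies noise without bound. Weighted regression was considered and
rejected: the intended use is a handful of single-replicate screens with no
variance information.

## Encodings

All encodings place continuous parameters min-max scaled into [0, 1] and
differ only in the categorical block:

* **one_hot** — one standard basis vector per catalyst (k extra dimensions
  for k catalysts). Decoding takes the argmax component, which equals the
  nearest-basis-vector rule on [0, 1]^k.
* **label** — one dimension; the k catalysts receive a seeded random
  permutation of k equally spaced points in [0, 1]. The permutation seed is
  independent of the campaign seed so the same arbitrary order is held fixed
  across replicates — a comparison of encodings requires the label order to
  be a property of the encoding, not of the replicate.
* **chemistry** — one dimension; coordinates are min-max normalized *N*
  over the active catalyst set, so order and spacing carry reactivity
  information. A rank-only variant (`chemistry_rank`, equally spaced but
  *N*-ordered) is available but off by default.

Decoding snaps the optimizer's continuous suggestion to the nearest label
(Euclidean distance); exact ties resolve to the lowest catalyst index for
determinism. The [0, 1] range for the categorical coordinate keeps its GP
length-scale commensurate with the normalized continuous dimensions.

## Kinetic simulator

The ground truth is a two-channel kinetic model of nucleophile-catalysed
amide coupling:

    dS/dt = −k1·S − k2·S        k1 = k(T, N) · cat_equiv · S0
    dP/dt = +k1·S               (stops when P reaches amine_equiv · S0)
    dD/dt = +k2·S

with the catalytic rate constant following a Mayr-type log-linear coupling
and Arrhenius temperature dependence:

    k(T, N) = A · 10^(γ(N − N_ref)) · exp(−Ea/R · (1/T − 1/T_ref)),

T_ref = 298.15 K, γ = 0.25 decades per *N* unit, N_ref = 20. The catalyst
concentration is constant (catalytic); the amine is not integrated — a hard
stoichiometric cap on P correctly limits yield under sub-stoichiometric
amine while keeping the system two-channel and stiff-solver friendly.
Integration uses LSODA with rtol 1e-8 / atol 1e-10; the amine cap is an
integration event, after which only the decomposition channel continues.

**Calibration.** A = 4.5e-4 1/(M·min) and Ea = 50 kJ/mol were fixed from
the pseudo-first-order closed form so that, at the center of the wide
amidation benchmark's ranges, the N = 27 catalyst just clears 90% yield
(91.8%) while the N = 12 catalyst stays below 20% — and so that the
lowest-N catalysts cannot reach high yield anywhere in the space. The
second property is the important one: if time, temperature and loading
could fully compensate a poor catalyst, the categorical choice would be
irrelevant and all encodings would tie; A sits near the lowest value the
center-yield requirement allows, which keeps the problem as
catalyst-dominated as those constraints permit. The calibration is
asserted by a test. The narrower `model_reaction` ranges use A = 1.5e-3
so that mid-range conditions give the moderate (tens of percent) yields
typical of that reaction.

**Benchmarks.**

| name | T (°C) | t (min) | [S] (M) | amine (eq) | cat (eq) | decomposition |
|---|---|---|---|---|---|---|
| `amidation_sim` | 10–200 | 0.5–5 | 0.1–0.3 | 0.5–1.5 | 0.05–5 | none |
| `model_reaction` | 20–100 | 2–12 | 0.1–0.25 | 1.0–2.0 | 0.2–1.2 | none |
| `api_reaction` | 30–120 | 2–14 | 0.1–0.2 | 0.5–1.5 | 0.2–2.5 | A=3e-4 1/min, Ea=100 kJ/mol |

The API benchmark's uncatalysed substrate-decomposition channel has twice
the activation energy of the coupling, so heating first accelerates the
coupling and then burns substrate: yield versus temperature peaks in the
interior of the range (around 60–70 °C for the most nucleophilic catalyst
at mid-range settings) and declines toward 120 °C. Product/substrate/amine molar masses and the
solvent density (0.9 g/mL) are benchmark constants used only by the mass
objectives.

Optional multiplicative yield noise (relative sd ≤ 5%, matching the
reproducibility of slug-flow platforms) is off by default; the comparison
study is run noiseless.

**What the simulator does not emulate:** mechanistic acyl-intermediate
microkinetics, slug dispersion, pre-reaction in the liquid handler,
analytics error structure. Conclusions from passing tests are about the
relative merits of encodings under a smooth, catalyst-dominated response —
not about any specific laboratory reaction.

## Objectives

For 1 mL of reaction mixture: substrate, amine and catalyst masses follow
from concentration × equivalents × molar mass; solvent mass is
density × 1 mL (dissolved-species volumes ignored). Then

* yield (%) — maximized, never capped;
* base cost = catalyst mass × cost_per_g / product mass — minimized;
* PMI = total input mass / product mass — minimized.

Cost and PMI diverge as yield → 0, so both carry caps (defaults 100
currency/g and 500 g/g, configurable); capped values are set to the cap
exactly and flagged, which keeps the surrogate finite while recording the
loss of information. Only in-slug material is counted — the carrier-solvent
stream of a flow platform is not included in PMI.

## Surrogate and acquisitions

The GP uses a Matérn-5/2 kernel with ARD length-scales (encoded categorical
coordinate included — its length-scale is learned like any other), a fitted
constant signal variance and a fitted white-noise term. Targets are
standardized internally; signal variance is bounded in [1e-2, 1e2] and log
length-scales in [−3, 3], which keeps hyperparameters in a regime where the
spectral sampler below is well conditioned. Hyperparameters maximize the
marginal likelihood with 5 restarts (L-BFGS), deterministic under the seed.

**Expected improvement** (single-objective loop): closed form
EI(x) = Δ·Φ(Δ/σ) + σ·φ(Δ/σ), Δ = μ(x) − f_best, maximized by evaluating
1024 random candidates and polishing the 10 best with L-BFGS-B.

**Thompson sampling** (TS-EMO loop): an approximate posterior draw via
random Fourier features. Matérn-5/2 frequencies are multivariate-t with
5 degrees of freedom scaled by the inverse length-scales; 500 features by
default. The posterior over feature weights is the conjugate Bayesian
linear model, sampled exactly. Draws are deterministic functions of their
seed. Known limitation: with near-degenerate hyperparameters (huge signal
variance, near-zero noise) the finite-feature posterior can misestimate the
exact GP posterior variance; the tests therefore check the sampler against
its own analytic spectral posterior (law of total variance) and the exact
GP only within an approximation allowance.

**TS-EMO step**: one Thompson draw per objective, refined by a real-coded
NSGA-II (non-dominated sorting, crowding distance, binary tournament, SBX
η = 15, polynomial mutation η = 20; population 60 × 60 generations;
observed points warm-start the population). From the candidate front the
point with maximal hypervolume improvement over the observed front is
selected; the reference point is the componentwise worst of observed and
candidate values plus a 10% margin. Hypervolume is exact (recursive
slicing, ≤ 3 objectives). With one objective the step degenerates to
minimizing the single draw. One-hot suggestions live in the continuous
relaxation and are snapped at decode time; there is no mixed-integer
handling.

All campaign randomness derives from the single campaign seed through
`numpy.random.SeedSequence` spawning (one child per iteration, recorded in
the history), so histories are byte-identical across reruns and replayable
from their embedded config.

## Campaign harness and the comparison study

The initial design is a seeded Latin hypercube of size 2 × (n_continuous+1)
— 12 for the six-variable benchmarks — with catalysts assigned as evenly as
possible in seeded random order ("two per base" in the balanced 6-catalyst
case; round-robin floor/ceil otherwise). Failed integrations consume their
iteration, record capped objectives and a `failed` flag, and never abort a
campaign.

`compare_encodings` runs seed-paired replicates: every strategy sees the
same campaign seeds, so contrasts are paired. Reported statistics are the
per-record median and IQR of the best-so-far yield, the median final best,
and the median first record reaching a threshold, defaulting to 90% of the
benchmark optimum found by dense random search (4000 noiseless samples);
replicates that never reach it count as one past the last record. The
headline study is 10 replicates × 50 TS-EMO iterations × three encodings on
the 6-catalyst amidation benchmark, at the package defaults.

Desk-scale problem sizes used elsewhere (examples, fast tests): 150–200
spectral features, NSGA-II 24–30 × 15–25, 2–3 GP restarts. These settings
trade acquisition quality for speed and are always stated in the config
they run under.

## Known limitations

* The kinetic parameters are a documented stand-in, not a fit to any
  published SI data; absolute yields are not comparable to any wet-lab
  number, only the qualitative structure (catalyst dominance, interior
  temperature optimum) is designed in.
* Fixture *N*, molar masses and costs are placeholders with realistic
  magnitudes.
* The encoding comparison is a stochastic result: orderings hold in the
  median over seed-paired replicates, not per seed.
* Hypervolume is exact only to 3 objectives; more objectives would need a
  Monte-Carlo or WFG implementation.
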