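# reactbo

Bayesian optimization of chemical reaction conditions when one of the
variables is categorical — which nucleophilic catalyst to use — with the
categorical dimension encoded by a physicochemical descriptor rather than
by arbitrary labels.

## The problem

Closed-loop reaction optimizers (Gaussian-process surrogates with
expected-improvement or Thompson-sampling acquisition) want continuous
inputs. A catalyst choice is not continuous. The two standard workarounds
both discard chemistry: **one-hot encoding** gives each catalyst its own
dimension (an optimization problem in 5 continuous variables and 6
catalysts becomes 11-dimensional), while **label encoding** assigns
arbitrary numeric labels whose order and spacing mean nothing.
**Chemistry-based encoding** instead places each catalyst at its min-max
normalized Mayr nucleophilicity *N* — the nucleophile term of the
linear free-energy relationship log k = s·(N + E) — so the encoded
coordinate orders catalysts by reactivity and distances between them are
chemically meaningful. The optimizer's continuous suggestion is snapped to
the nearest catalyst label (Euclidean distance) at decode time.

`reactbo` provides:

* catalyst descriptor tables (CSV), including OLS back-estimation of a
  missing *N* from calibration yields;
* the three encoders with exact, deterministic snapping;
* kinetic ODE benchmark reactions whose catalytic rate constant follows
  k(T, N) = A · 10^(γ(N−N_ref)) · exp(−Ea/R·(1/T−1/T_ref)), including an
  API-style benchmark with a competing thermal decomposition that creates
  an interior temperature optimum;
* process objectives: yield, base cost per gram of product, and process
  mass intensity (PMI) normalized to 1 mL, with upper caps;
* a Matérn-5/2 ARD GP surrogate, closed-form expected improvement, and a
  TS-EMO-style multi-objective loop (spectral Thompson samples refined by
  NSGA-II, hypervolume-improvement selection);
* a fully seeded campaign harness with byte-replayable histories and a
  seed-paired encoding-comparison benchmark.

## Worked example

`examples/04_single_objective_campaign.py` runs one chemistry-encoded
TS-EMO campaign on the wide amidation benchmark (12 space-filling initial
experiments — twice the number of variables, two per base — then 10
algorithm iterations):

```text
record | provenance | catalyst | yield% | best-so-far%
     0 | init      | cat04  |    3.5 |    3.5
     1 | init      | cat03  |    0.0 |    3.5
     2 | init      | cat06  |   14.1 |   14.1
     3 | init      | cat05  |   24.4 |   24.4
     4 | init      | cat01  |    0.1 |   24.4
     5 | init      | cat06  |   93.9 |   93.9
    ...
    12 | algorithm | cat06  |    2.9 |   93.9
    13 | algorithm | cat06  |  100.0 |  100.0
    ...
    21 | algorithm | cat06  |  100.0 |  100.0

final best yield: 100.0%
```

The best-so-far column is the convergence diagnostic: after the initial
design the algorithm almost exclusively proposes the most nucleophilic
catalyst and pushes the continuous conditions, because the encoded
coordinate already tells the GP that reactivity increases along it. The
other examples cover descriptor regression (`01`), the encoders (`02`),
the simulator (`03`), multi-objective optimization with Pareto reporting
(`05`) and a desk-scale encoding comparison (`06`).

A thin CLI wraps the same functions: `reactbo simulate`, `reactbo campaign
run|replay`, `reactbo benchmark compare`, `reactbo report`.

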