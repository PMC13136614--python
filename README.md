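# chotwin

A hybrid digital-twin framework for fed-batch CHO cell culture. Given only
the initial state of a bioreactor and its feed schedule, `chotwin` predicts
the complete culture trajectory — viable cell density (VCD), product titer
and extracellular metabolite concentrations — by coupling five layers:

1. **Rate estimation** — concentration time series are corrected for
   feeding/sampling dilution events, fitted with logistic basis functions
   under a Bayesian noise model, and converted into posterior ensembles of
   specific metabolic rates (g·10⁻⁹ cells·d⁻¹).
2. **Growth network** — the specific growth rate μ(t) is a shared 4-sigmoid
   baseline plus a dense neural deviation, recurrent through the cumulative
   biomaterial variable γ_X = ∫X_v dt.
3. **Kinetic ODE models** — viable/dead/lysed cell pools with
   biomaterial-driven death (μ_d = k_d + k_Td·γ_X, μ_l = k_l + k_Tl·X_l) and
   a five-metabolite model of glucose, lactate, glutamine, glutamate and
   ammonium with saturation, overflow lactate metabolism and maintenance
   terms; parameters identified by multi-start Nelder–Mead.
4. **Network reduction** — a constraint-based metabolic model is reduced in
   four verified stages (feasibility demands, essential exchanges, pFBA
   pruning, loop removal) to a minimal model consistent with measured rates.
5. **PC-dFBA** — at each 0.1-day step a hybrid linear program

       min  c_v'v + 1'|s|
       s.t. S v = 0,  lb ≤ v ≤ ub,  hard bounds on growth + FLEX exchanges,
            med − RF·iqr ≤ S_e v − Load·s ≤ med + RF·iqr,  s in a score box

   couples stoichiometry with empirical flux correlations: `Load` holds
   PCA loading vectors predicted at run time by neural regressors from the
   current exchange rates, and a MOMA continuity stage keeps consecutive
   flux distributions close.

Who it is for: bioprocess modelers who want a working, fully tested
reference implementation of the PCA-constrained dynamic-FBA approach and of
the surrounding estimation/identification machinery, runnable end to end on
synthetic data with known ground truth.

No experimental dataset ships with the package; a first-class synthetic
module (`chotwin.synthetic`) generates fed-batch cohorts — daily sampling,
FMA/FMB bolus feeds from day 3, glucose maintenance feeding from day 5 —
whose latent dynamics follow the package's own kinetic equations, so every
layer can be validated against exact ground truth. See `docs/methods.md`
for the model details and design choices.

## Worked example

Recover kinetic parameters from a synthetic cohort:

```python
import numpy as np
from chotwin import kinetics as K
from chotwin.synthetic import SyntheticConfig, generate_cohort, flex_fit_batch

cohort = generate_cohort(SyntheticConfig(n_batches=4, n_media_groups=2,
                                         noise_cv=0.0))
batches = [flex_fit_batch(rec, truth) for rec, truth in cohort[:3]]

truth = K.KineticParameters()
rng = np.random.default_rng(0)
init = truth.with_values(**{n: getattr(truth, n) * (1 + 0.3 * rng.uniform(-1, 1))
                            for n in K.KineticParameters.FLEX_NAMES})
res = K.identify_flex(batches, K.OptimizerConfig(seed=0), init=init)
for name in ("mGlc", "vOx_max", "vGln_max"):
    print(name, round(getattr(res.params, name), 4),
          "true", round(getattr(truth, name), 4))
```

prints

```
mGlc 0.8826 true 0.8821
vOx_max 1.6473 true 1.6462
vGln_max 2.6776 true 2.6803
```

i.e. the glucose maintenance coefficient, the oxidative capacity and the
maximum glutamine uptake rate are re-identified to within a fraction of a
percent from a ±30% perturbed start, because the noise-free cohort was
generated by the same kinetic equations (generate-and-refit consistency).

The command-line interface mirrors the pipeline:

```
chotwin generate-data --out data/ --n-batches 6 --n-groups 2 --seed 0
chotwin estimate-rates --data data/ --out rates/
chotwin fit-ode        --data data/ --out kinetics/
chotwin train-growth   --data data/ --out growth/
chotwin reduce-network --model model.xml --out reduced/
chotwin train-loadings --data data/ --out loadings/
chotwin run-twin --init init.yaml --artifacts artifacts/ --out results/
```

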