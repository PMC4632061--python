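# Methods

## The kinetic model

`gsflux.pathway` implements a deterministic mass-action model of the two
glucosinolate branches.

**Topology.** Methionine-derived carbon enters an elongation chain
L2 → L3 → L4 → L5 (lumped `ELONG` step; each round adds one methylene, so
pool Ln feeds the aliphatic product of chain length n). At every pool the
entry enzyme CYP79F1 competes with further elongation; CYP79F2 provides a
second entry route restricted to the long-chain pools L4 and L5, matching
its known substrate preference. Entry is followed by CYP83A1, the shared
C-S lyase SUR1, and a lumped late segment (`LATE_ALI`:
glucosylation/sulfation) producing 3MSOP, 4MSOB, 5MSOP, 6MSOH from
L2…L5. The indolic branch runs TRP → CYP79B → CYP83B1 → SUR1 →
`LATE_IND` → I3M, with two parallel modifications of I3M: CYP81F2 →
4OHI3M and `MOD1M` → 1MOI3M.

**Kinetics.** Every step is first order in its substrate and degree-1 in
its enzyme level, except SUR1, which is competitive Michaelis–Menten with
all five of its substrates (four aliphatic, one indolic) sharing one
saturation denominator:

    v_i = k · E_SUR1 · (S_i/Km) / (1 + Σ_j S_j/Km)

This is the minimal mechanism by which a perturbation on one branch can
propagate to the other: knocking down an aliphatic enzyme relieves SUR1
competition and raises indolic output. All other steps being linear keeps
the model analytically transparent and the all-linear variant
(`sur1_kinetics="linear"`) exactly solvable, which validates the ODE path.

**Turnover and leaks.** The seven products turn over first order (`DEG`
pseudo-step, k_deg = 0.3), so a steady-state product pool is proportional
to its branch flux — concentration is the flux readout. Internal
intermediates additionally carry a smaller first-order background turnover
(k_leak = 0.3, also charged to the `DEG` level). This leak is a deliberate
design choice: in a strictly conserving irreversible network with constant
influx, total steady-state branch flux equals the influx no matter what the
enzymes do, so no biosynthetic enzyme could carry flux control and a
knockdown could never change total output. With leaks, slow consumption
lets intermediates accumulate and drain away, giving upstream enzymes
genuine, parameter-dependent control. Because leak rates are degree-1 in
the `DEG` level, the homogeneity needed by the summation theorems is
preserved and both theorems close over the complete step set (12
enzyme/pseudo steps + 2 influx pseudo-steps): flux control sums to 1,
concentration control to 0, each within 1e-3 by finite differences.

**Default parameters** (arbitrary units, frozen once; no claim of matching
measured concentrations):

| parameter | value | role |
|---|---|---|
| influx_met / influx_trp | 1.5 / 0.6 | precursor supply rates |
| k_elong | 1.0 | elongation vs entry competition |
| k_cyp79f1 / k_cyp79f2 | 0.35 / 1.2 | short-chain vs long-chain entry |
| k_sur1 / km_sur1 | 1.5 / 0.4 | shared-step saturation (branch crosstalk) |
| k_cyp81f2 / k_mod1m | 0.5 / 0.5 | I3M modification split |
| k_deg / k_leak | 0.3 / 0.3 | product turnover / intermediate leak |

They were calibrated once so that (a) wild-type product pools are of
comparable magnitude across the seven compounds (0.2–0.65 units), (b) the
first entry enzyme holds majority control over the short-chain aliphatics
(C ≈ 0.75 for 3MSOP) with CYP83A1 minor (≈ 0.11) and SUR1 intermediate
(≈ 0.42), and (c) the qualitative knockdown sign pattern holds: halving
CYP79F1 lowers 3MSOP/4MSOB, raises 5MSOP/6MSOH (elongation overflow into
the CYP79F2 entry), and raises the indolics (+2% I3M via SUR1 relief).
They were not revisited after the acceptance checks were written.

**Steady-state solver.** All-linear models are solved directly as
A·x = −b. Otherwise the ODEs are integrated (LSODA, rtol 1e-10) from empty
pools over doubling horizons, each chunk followed by a Newton polish
(`scipy.optimize.root`), until the relative rate norm max|dX/dt|/max(X)
drops below 1e-9 (default). Non-convergence within the horizon is flagged
on the result, not raised; the generator drops and counts such records.

## The MCA oracle

True coefficients are central finite differences on the log scale:
C = [ln X(E·e^δ) − ln X(E·e^−δ)]/(2δ) with δ = 0.01, accurate to O(δ²)
(Richardson-checked at δ = 0.005). Influx rates are perturbed the same way
as pseudo-steps so the summation theorems can be evaluated over the
complete step set.

**Estimator/oracle convention.** The log-ratio estimator applied to a
noise-free (WT, r·WT) pair is a symmetric secant in log–log space and thus
a second-order-accurate estimate of the slope at the *geometric midpoint*
enzyme level √r·E, not at E. For the saturable SUR1 step the true slope
itself moves ≈ 5% across a 5% enzyme change, so the equivalence test
evaluates the oracle on the midpoint model; agreement there is ~1e-4. At
the study's actual perturbation (r = 0.5) the finite-change estimate
deliberately differs from the infinitesimal coefficient (e.g. 0.55–0.66 vs
0.42 for SUR1); that gap is a property of finite-change estimation on a
curved response and is documented rather than asserted tight.

## The synthetic experiment

`generate_design` reproduces the factorial layout: 2⁴ combinations of
reduced water (W), leaf crushing (C), reduced soil nutrients (S) and methyl
jasmonate (J); WT vs HET; three insertion lines (*Cyp79f1*, *Cyp83a1*,
*Sur1*). Defaults are 8 WT and 15 HET per condition — 16 × 23 = 368 plants
per line ("approximately eight" is fixed at exactly 8 because that
reproduces the printed total). Flats are block labels assigned round-robin
*within* genotype so blocks are never confounded with the contrast of
interest.

Measured concentrations are lognormal around the condition-specific model
steady state: environment modifiers and (for HET) the line's expression
ratio (default r = 0.5, one null allele; always a configurable input) are
applied, and each compound drawn independently with log-SD σ = 0.35. A
cross-compound covariance hook exists but defaults off — no information on
real covariance is available. σ = 0.35 is a typical between-plant CV
(~36%) for leaf metabolite panels.

**Environment modifiers** are frozen multiplicative factors with only
qualitative authority: J induces every pathway enzyme ×1.5 except CYP81F2
×0.4 (repressed) and raises precursor influx (met ×1.3, trp ×1.8); C is a
milder jasmonate-like induction (×1.2, influxes ×1.15/×1.3) without the
CYP81F2 repression; W and S reduce precursor supply (S most strongly on
the sulfur-demanding aliphatic side, met ×0.7). The CYP81F2 factor is the
load-bearing one: it makes MeJA lower 4OHI3M while raising I3M and 1MOI3M.

**Herbivory.** Leaf area removed after 3 h (percent of leaf) for the
*Cyp79f1* line only: LR = baseline·exp(−β(c_3MSOP+c_4MSOB))·exp(flat+ε)
with β = 1.2, baseline = 12%, log-SD ε = 0.4, flat SD = 0.1. β is sized so
that the WT–HET difference in deterrent content (≈ 0.55 units) yields a
~2× feeding difference, giving the genotype term of the two-way ANOVA high
power at the assay's sample sizes.

**Expression fixtures.** Three synthetic treated/control median
experiments (stand-ins for public MeJA microarray studies; labelled
`synthetic-meja-exp*`) drawn around a true-fold profile: all pathway genes
×1.5, CYP81F2 ×0.4, with log-SD 0.15 per arm around a gene baseline of
~100 units.

What a green test does *not* establish: the generator draws compounds
independently (real glucosinolates covary), uses exact replicate counts
(the study's varied), has no germination loss, leaf-age or batch effects,
and its environment-modifier magnitudes are conventions. Green tests
establish the *machinery* — estimator calibration, CI coverage, test-size
of the MANOVA — under a stated world, not biological effect sizes.

## Estimation and inference

**λ estimator.** Default is the log-ratio form λ̂ = ln(G_HET/G_WT)/ln r
with geometric means (concentrations are log-transformed everywhere); the
fractional deviation-index form is behind a flag. The log form is exact
under a power-law response and symmetric in arm labels. r is a fixed known
constant; its measurement error is out of scope.

**Bootstrap.** Percentile CI (not BCa), 1000 resamples, plants resampled
with replacement within genotype arms, environments pooled (a
stratified-by-condition mode exists behind a flag); quantiles by linear
interpolation. CIs are reported on both the λ scale (default) and the
concentration-ratio scale, since either convention is defensible.
Empirical coverage at the pooled sample sizes (240 HET / 128 WT, σ = 0.35)
is 94–95% over 500 replicates (recomputed by `scripts/acceptance.py`).

**MANOVA.** The seven log concentrations against intercept + genotype +
W + C + S + J + four genotype×E + six E×E terms, sum-to-zero coding, Type
III hypothesis cross-products, Λ = det(E)/det(H+E), Rao's F (exact for
q = 1 terms). The implementation is in-package (the determinant identity
and a hand-computed toy value are part of the test surface);
`statsmodels.multivariate.MANOVA` serves as an independent cross-check in
the tests. Univariate follow-ups are gate-kept by the caller at α = 0.05
(no multiplicity correction, recorded in output metadata) and report
proportional change (T_C − U_C)/U_C on back-transformed geometric means.
Pooling directives (pool genotypes for environment effects / environments
for genotype effects) require all four genotype×E terms non-significant.

**Herbivory ANOVA.** LR = genotype + flat + genotype×flat, Type III with
sum contrasts via statsmodels, genotype tested against the residual. Flat
is fitted as a fixed blocking factor although it is conceptually a random
block — a two-way ANOVA table is what the assay reports; the docstring
flags the interpretation.

**Expression meta-analysis.** Proportional change of medians per gene per
experiment, averaged across available experiments with SE; missing
experiments reduce n, never imputed; single-experiment genes report SE as
missing.

## Numerical conventions

- Seeds: one run seed, expanded per stage via
  `SeedSequence(seed, spawn_key=(stage,))` with fixed stage indices
  (concentrations 0, herbivory 1, expression 2, bootstrap 3, acceptance
  coverage 4); skipping a stage never shifts another's stream.
- CSV: UTF-8, '.' decimal, floats at 12 significant digits; every writer's
  output is readable by its reader.
- Degenerate inputs: zero-variance bootstrap arms give zero-width CIs;
  fully-explained univariate responses report F as ∞/NaN rather than
  dividing by zero; solver non-convergence flags rather than raises.

## Known limitations

- No reversible/thermodynamic kinetics, no transcription-factor dynamics,
  no compartmentalization (chloroplast elongation vs cytosolic core).
- The leak/turnover constants set the overall "stiffness" of flux control;
  different defensible choices rescale all control coefficients.
- Rao's F is approximate for terms with q > 2 and p > 2; p-values on the
  simulated study are matched in kind, not digit-for-digit, to any
  particular commercial implementation.
- The finite-change λ at r = 0.5 is a biased estimate of the infinitesimal
  coefficient wherever the response is curved (saturable SUR1); the
  package reports the estimator the experiment supports, with the oracle
  available for calibration.
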