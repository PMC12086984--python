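# funmstate

Functional multistate models for bidirectional cognitive-state
transitions.

## The problem

Mild cognitive impairment (MCI) is not a one-way street: some people
progress to Alzheimer's disease (AD) dementia, others revert to normal
cognition (rNC) and may later deteriorate again. Characterizing these
bidirectional dynamics from observational cohorts is hard for two reasons:

1. **Panel observation.** Cognitive state is only known at irregular
   clinic visits; the exact transition instants are never observed.
2. **High-dimensional longitudinal markers.** Each subject carries sparse,
   noisy trajectories of ~11 neuropsychological scales and repeated
   116-region gray-matter density profiles from MRI, which cannot enter a
   regression as raw curves.

`funmstate` couples functional data analysis with a continuous-time
multistate model to address both. It is a library for biostatisticians:
the public face is the importable API plus the narrative scripts in
`examples/`.

## The model

States rNC (1), MCI (2), AD (3); MCI and rNC are transient, AD absorbing,
and allowed instantaneous moves are MCI→rNC, MCI→AD, rNC→MCI (reversion
routes back through MCI). Transition intensities are proportional:

    q_rs(i) = q_rs(0) · exp( γ₁ age_i + γ₂ sex_i + γ₃ education_i
                             + γ₄ marriage_i + γ₅ APOEε4_i + β_rsᵀ ρ_i )

where ρ_i are functional principal component (FPC) scores summarizing the
subject's longitudinal markers — the functional term ∫ g_i(s)B(s)ds with
the coefficient function B expanded in the eigenbasis, so it reduces to a
linear combination of scores. With generator Q(i), transition
probabilities are P_i(t) = exp(Q(i)·t), and the panel likelihood is the
product over consecutive visit pairs of the matching entries of
P_i(t_{k+1} − t_k). Scores come from:

- **sparse univariate FPCA** (`funmstate.fpca`): penalized-spline mean and
  covariance smoothing plus conditional-expectation (PACE) scores;
- **multivariate FPCA** (`funmstate.mvfpca`): joint eigendecomposition of
  the stacked univariate scores of the 11 scales;
- **multilevel FPCA** (`funmstate.mlfpca`): functional-ANOVA separation of
  subject-level and visit-level variation of the 116-region profiles, in
  traditional (grid) and fast (reduced spline basis, mixed-model scores)
  variants.

Fitted models provide intensities, probability curves, expected length of
stay over a horizon, MVN parametric-bootstrap confidence intervals,
AIC/likelihood-ratio comparison of the preplanned model suite
(FMSM 0–5, scalar-PCA MSM 1–3), and an observed-vs-expected assessment.
A seedable simulator (`funmstate.simulate`) generates cohorts with exactly
the structure the model assumes, so every estimator ships with parameter
recovery studies.

## Worked example

```python
from funmstate import fit_fmsm, length_of_stay, probability_curves
from funmstate.simulate import SimConfig, generate_cohort

subjects, _ = generate_cohort(SimConfig(n_subjects=1000), seed=1)
fit = fit_fmsm(subjects)
for (a, b), q in fit.intensities.items():
    print(f"{a.name} -> {b.name}: {q:.4f}")
```

prints (cohort simulated at the per-year intensity scale
0.035 / 0.120 / 0.117):

```
MCI -> RNC: 0.0376
MCI -> AD: 0.1243
RNC -> MCI: 0.1111
```

i.e. the instantaneous risk of re-progression for reverted subjects
(0.111/y) is close to the risk of MCI progressing to AD (0.124/y) and
about three times the reversion rate — reverted subjects remain at high
risk. Continuing,

```python
print(probability_curves(fit.spec, [5, 10]).round(3))
print(length_of_stay(fit, horizon=15.0)["percent"])
```

gives the occupancy probabilities from MCI at 5 and 10 years and the
expected share of a 15-year horizon spent in each state (about 9% rNC,
41% MCI, 50% AD under these intensities). `examples/01`–`06` walk through
every capability with the numbers they print.

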