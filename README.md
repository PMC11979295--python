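# moraltides

Opinion-dynamics modelling and statistical tests of argument-driven change
in moral norms.

## The problem

Across the world, norms on issues like divorce, homosexuality, soft drugs
or traditional gender roles have drifted in remarkably similar directions.
One account of this pattern is that moral arguments drive the drift:
*individualizing* arguments (harm, fairness, liberty) resonate with
everyone, while *binding* arguments (authority, loyalty, purity) resonate
only with moral conservatives. The opinion that is better justified by
individualizing arguments — the opinion with the *argument advantage* —
therefore spreads, first among moral liberals and, through them, in the
whole population. The package is for researchers in cultural evolution and
moral psychology who want to simulate this process, score its ingredients
from survey instruments, and test its predictions against longitudinal
opinion data.

## The model

A population has a proportion *q* of moral liberals. Each step an agent is
exposed with probability *d* to a random other agent's opinion;
conservatives switch to a differing opinion with probability *s* in either
direction, liberals with probability *s* toward the argument-advantaged
opinion but only (1 − *a*)*s* away from it, where *a* ∈ (0, 1] is the
advantage. Writing *l*ₜ, *c*ₜ for the advantaged opinion's popularity among
liberals and conservatives and *p*ₜ = *q*·*l*ₜ + (1 − *q*)·*c*ₜ:

```
l_{t+1} − l_t = d·s·[ a(1 − l_t)·p_t − (1 − a)(1 − q)(l_t − c_t) ]
c_{t+1} − c_t = d·s·q·(l_t − c_t)
```

Norms move toward the advantaged opinion, faster for larger *a* and larger
*q*. Around the model the package provides: a stochastic agent-based twin;
scoring of per-issue argument advantages from applicability-rating surveys
and of societies' moral liberalness (LIB) from moral-foundations
questionnaires; change-rate estimators (log odds per decade) for
longitudinal opinion panels, including a multilevel random-slope variant
and a three-way time × AA × LIB interaction model; mirrored-profile
correlation and resampling machinery for the five predictions the theory
makes; and a synthetic-world generator with known ground truth. A table of
published per-issue advantage scores and change rates for 33 moral issues
is packaged for fixture-only analyses. See `docs/methods.md` for the full
statistical account.

## Worked example

```python
import moraltides as mt

out = mt.table3_profile_correlation("alter", B=10_000, seed=0)
print(f"advantage-change correlation r = {out['stat']:.2f} "
      f"[{out['ci_low']:.2f}, {out['ci_high']:.2f}] over {out['n_issues']} issues")

prof = mt.accumulated_change_profile([0.6, 0.3, 0.0, -0.3, -0.6], q=2/3, d=0.1, s=0.5, T=100)
print(prof.round(3))
```

prints

```
advantage-change correlation r = 0.64 [0.37, 0.82] over 33 issues
     a  delta_p  delta_logodds
0  0.6    0.391          2.103
1  0.3    0.237          1.032
2  0.0    0.000          0.000
3 -0.3   -0.237         -1.032
4 -0.6   -0.391         -2.103
```

The first line correlates, over the 33 packaged issues, the
argument-advantage profile with the profile of estimated norm-change
rates; profiles are *mirrored* (each issue contributes its value and the
sign-flipped value for the opposite opinion) so the arbitrary coding of
issues cannot affect the result, and the CI resamples issues. A clearly
positive r means norms have been moving toward the opinions that
individualizing arguments favour. The table below it shows the model's
accumulated change over 100 steps for five issues with different signed
advantages in a two-thirds-liberal population: change grows with the
advantage and is exactly antisymmetric in its sign.

The same machinery is scriptable from a shell — `moraltides simulate`,
`score-aa`, `liberalness`, `estimate-change`, `test-predictions`, `synth`
and `run` — each a thin wrapper over the corresponding library function.

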