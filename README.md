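# rrtprev

Prevalence estimation for sensitive behaviours from **forced-response
randomized response (RRT) surveys** with detection of instruction
non-compliance (INC).

Asking people directly whether they dope, or use medication to boost
sporting performance, invites socially desirable underreporting. In a
forced-response RRT survey each respondent holds a private uniform random
number; depending on its last digit they either answer the sensitive
question truthfully or give a fixed "yes" or "no" forced by a harmless
side question. Because the forced-answer probabilities are known, the
population prevalence is identified even though no individual answer is
informative. Some respondents nevertheless ignore the instructions and
answer "no" regardless; splitting the sample into two subsamples with
*different* forced-answer probabilities makes this non-compliant class
estimable too.

## Model

With subsample *g* ∈ {1, 2} assigned forced-yes / forced-no probabilities
(p_gy, p_gn), the population splits into honest-yes carriers θ_y, honest-no
non-carriers θ_n and always-"no" non-compliers θ_inc (θ_y + θ_n + θ_inc = 1).
The observed yes-probability is

```
λ_g = θ_y (1 − p_gn) + θ_n p_gy ,      g = 1, 2
```

The two observed rates give a 2×2 linear system; its solution is the MLE
whenever it lies in the probability simplex. Otherwise the MLE sits on the
simplex boundary and is found by maximising the binomial likelihood with
one or two shares pinned to zero, keeping the case with the highest
likelihood. Boundary truncation makes the sampling distribution skewed
(with a point mass at 0 for rare traits), so inference uses a stratified
nonparametric bootstrap with percentile intervals. Because non-compliant
"no" answers may conceal the trait, the true prevalence is only bounded:
`θ_y ≤ prevalence ≤ θ_y + θ_inc`.

The package also implements the surrounding survey machinery: response-time
and plausibility quality control, per-question post-stratification weights
(country × gender × age, with a documented collapse ladder), sport
prioritisation and categorisation (Artistic / Combat / Games / CGS /
Other), the doper-vs-doping record selection, a bootstrap difference test
between groups, and a synthetic-survey generator for end-to-end testing.

## Worked example

```python
import numpy as np
from rrtprev import RRTPrevalenceEstimator, prevalence_bounds

# 1000 respondents per subsample; 150 / 250 answered "yes"
X = np.array([[1, 1]] * 150 + [[1, 0]] * 850 + [[2, 1]] * 250 + [[2, 0]] * 750)
est = RRTPrevalenceEstimator().fit(X)
print(est.theta_yes_, est.theta_no_, est.theta_inc_)
print(est.bounds_)
```

prints

```
0.125 0.5000000000000002 0.3749999999999998
(0.125, 0.5)
```

i.e. observed yes-rates of 15% and 25% decompose into 12.5% honest-yes,
50% honest-no and 37.5% non-compliant respondents; the trait prevalence
lies between 12.5% and 50%. The same decomposition with a yes-rate pair
that has no interior solution returns a boundary estimate with the pinned
shares recorded in `est.boundary_case_`.

A full survey analysis runs from the command line:

```sh
rrtprev simulate --preset otc --n 5700 --seed 1 --out survey.csv
rrtprev qc survey.csv --out kept.csv
rrtprev estimate kept.csv --question otc --b 2000 --seed 1
rrtprev report --config pipeline.yaml   # qc -> weights -> estimates -> contrasts
```

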