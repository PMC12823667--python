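# cctask

The Columbia Card Task (CCT) is a behavioral measure of risk-taking: in each
round a player faces a deck of `N = 32` face-down cards of which `m` are loss
cards, and reveals cards one at a time. Each revealed gain card pays `g`
points; the first loss card ends the round at a cost of `l` points. How many
cards a player tries to reveal indexes their risk tolerance. The task comes
in four "temperature" versions that differ in when commitments are made and
when feedback arrives — Cold (one blind commitment), Warm (one commitment,
feedback at the end of the round), Toasty (committed batches with feedback
and optional continuation), and Hot (card-by-card decisions). In the Hot and
Toasty versions a revealed loss ends the round before the player could stop,
so the observed count is a right-censored lower bound on intent.

`cctask` implements this task family end-to-end so task designs, censoring
biases, and version comparisons can be studied without human subjects:

- **design** — factorial round designs (the standard 2×2×2×3 = 24-round
  short form, the legacy 3×3×3 with 54 scored + 9 rigged rounds) and loss-card
  placement schemes (honest random placement vs. the historical deceptive
  stacked-at-end scheme with rigged rounds);
- **engine** — the four versions as explicit state machines with scoring,
  feedback-request accounting, censoring semantics, and the session bonus
  rule ($1 per 100 points, floored at zero);
- **strategy** — exact (rational-arithmetic) analysis of a round: the
  first-loss position follows the order-statistic form of sampling without
  replacement, `P(no loss in k draws) = C(N−m, k) / C(N, k)`, and the
  expected score of committing to `k` reveals is
  `EV(k) = g·k·P(no loss) + Σⱼ (g(j−1) − l)·P(first loss at j)`;
  the optimum `argmaxₖ EV(k)`, deviation scores, and loss-recovery counts
  derive from it;
- **agents** — synthetic players whose intended counts follow the linear
  mixed model `y* = x'β + z'bᵢ + ε`, plus a descriptive Toasty batching
  policy, for generating realistic trial data;
- **censored_model** — a right-censored multilevel Gaussian regression
  (random intercepts and within-subject slopes with full correlations,
  sum-to-zero coding so the intercept is the grand mean), fit by a conjugate
  data-augmentation Gibbs sampler with R-hat/ESS diagnostics, estimated
  marginal means, ICC, and marginal/conditional R²;
- **analysis** — descriptive tables: total scores, loss-card counts,
  deviation-from-optimal, and Toasty feedback-request profiles.

## Worked example

Exact optimal-stopping analysis of one parameter combination:

```python
>>> from cctask import RoundParams, ev_curve, optimal_reveal, deviation_score
>>> curve = ev_curve(RoundParams(gain_amount=30, loss_amount=250, n_loss_cards=1))
>>> curve.argmax_set, curve[23]
((23,), 251.5625)
>>> optimal_reveal(RoundParams(10, 250, 1))            # an exact tie
(6, 7)
>>> optimal_reveal(RoundParams(10, 250, 1), "published")
7
>>> deviation_score(12.3, RoundParams(10, 250, 1))     # +5.3 = over-revealing
5.3
```

Revealing 23 cards at (g=30, l=250, m=1) is worth 251.56 points in
expectation; at (g=10, l=250, m=1) the counts 6 and 7 tie exactly at 6.5625
points and the conventional published table reports 7. A group averaging
12.3 reveals there over-reveals by 5.3 cards.

Simulating a censored Hot-version study and recovering the generating
effects with the censored model:

```python
>>> import cctask.censored_model as cm
>>> from cctask import simulate_recovery_dataset
>>> trials = simulate_recovery_dataset(60, seed=7)   # 60 agents x 24 rounds
>>> trials.censored.mean()                           # half the rounds censored
0.512
>>> spec = cm.default_model_spec(trials).with_sampler(
...     chains=2, iterations=1500, warmup=750, seed=7)
>>> fit = cm.fit(trials, spec)
>>> fit.coef[["mean", "ci_lower", "ci_upper", "rhat"]].round(2)
                   mean  ci_lower  ci_upper  rhat
intercept         11.15     10.68     11.65  1.00
incentive[False]  -0.39     -0.87      0.09  1.00
gain[30]           1.24      1.02      1.48  1.00
loss[750]         -1.07     -1.30     -0.85  1.01
n_loss_cards[3]   -2.36     -2.54     -2.19  1.00
block[2]          -0.44     -0.68     -0.19  1.00
block[3]           0.01     -0.26      0.28  1.01
```

The generating values (grand mean 11.0, gain effect +1.24, loss effect
−1.19, loss-cards effect −2.51) sit inside the 95% intervals even though
half the rounds were cut short by a loss card; the raw mean of the same data
is ≈ 8 cards, badly attenuated. `cm.emm(fit, ["gain"])` then gives the
model-based marginal means per gain level, and `cm.r2_decomposition(fit)`
the marginal/conditional R².

A command-line surface mirrors the library:

```sh
cct design --reps 3 --seed 1 --out design.csv
cct ev --gain 30 --loss 250 --mloss 1
cct simulate --design design.csv --version toasty --participants 50 --seed 1 --out trials.csv
cct fit --data trials.csv --emm gain,loss --seed 1 --out fit.json
cct analyze --data trials.csv --out report/
```

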