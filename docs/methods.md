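# Methods

## The decision problem

Restoring an edentulous (toothless) maxilla with a bar-retained,
implant-supported overdenture can be done on six or on four implants.  Six
implants fail less often and keep the denture more stable, but cost more.
`overdent` quantifies this trade-off as an incremental cost-effectiveness
analysis from the perspective of a payer deciding between the two entry
treatments, with effectiveness measured in **satisfaction-years**: one year
lived at full denture satisfaction (satisfaction is a 0–1 scale per
remaining implant count).

## Model structure

A Markov cohort model over annual cycles (default horizon 10 years).  The
state is the number of implants still in place (0–6) plus a flag marking a
repair period.  Within a cycle, two failure events can occur independently
of each other:

* **implant failure** — probability depends on the current implant count;
  the count drops by exactly one (at most one loss per cycle; lost implants
  are never replaced), and a "repair after implant failure" is charged;
* **denture failure** — the overdenture itself needs repair ("repair
  without implant loss"); the denture is restored, there is no
  denture-replacement state.

Evidence reports failure rates for six and four implants only; rates for
the other counts lie on the straight line through those two anchors
(extrapolated below four).  That interpolation is carried out in exact
decimal arithmetic on the anchors' decimal representations, so a table
printed in decimals is reproduced digit for digit — naive binary float
arithmetic is off by one unit in the last place in several cells.  Implant
failure at count 0 is a structural zero; denture failure at count 0 has
its own assumed distribution.  Satisfaction is anchored at 6, 4, 2 and 0
implants and filled piecewise-linearly (arithmetic means at 5, 3, 1).

### Within-cycle timing

The source analysis was built in a cycle-tree tool whose Markov rewards
are state-based, and it does not spell out when within a cycle rewards
accrue.  `overdent` adopts the state-reward reading:

* a cycle accrues the satisfaction of the state occupied **during** the
  cycle (the start-of-cycle implant count); transitions happen at cycle
  end;
* a failure at the end of cycle *t* places the repair period in cycle
  *t+1*, whose satisfaction is multiplied **once** by the repair
  adjustment factor (once even if both failures occurred together);
* repair **costs** are charged in the cycle of the failure;
* the new-denture cost (labor + material) is charged once at entry;
* no discounting, no half-cycle correction (the source applies neither).

The plausible alternatives (satisfaction at the cycle-end count, penalty
inside the failure cycle) were evaluated against all eighteen thresholds
the reference analysis prints: the convention above reproduces every one
within ±5.5%, whereas the in-cycle readings miss the base case or the
pinned-adjustment grid by 14–17%.  A side effect of the lagged repair
period is that failures in the final cycle incur costs but no
satisfaction penalty; over a 10-year horizon this is a sub-percent effect.

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| annual failure rates | triangular (min/mode/max) per count | probability | sampled in PSA |
| satisfaction per count | point estimates, 0.63–0.89 | – | never sampled |
| repair adjustment | Triangular(0.8, 0.9, 0.99) | – | multiplies a repair cycle's satisfaction |
| cost factor | 1.0 / 2.3 / 3.5 | – | fee-schedule complexity multiplier on labor costs |
| horizon | 10 | years | annual cycles |
| draws | 50,000 | – | Monte Carlo repetitions |

Labor costs between the three printed factor anchors are piecewise-linear
in the factor; the printed columns are not scalar multiples of each other,
so multiplying the factor-1.0 column would misprice intermediate factors.
Material/laboratory costs are factor-independent.

## Probabilistic sensitivity analysis

Each draw samples every failure distribution and the repair adjustment
independently through the triangular inverse CDF (closed form, handling
the degenerate point mass; draws for different implant counts are sampled
independently rather than rank-correlated along the interpolation line —
the source specifies nothing).  Both strategies are evaluated on the same
realised parameters (common random parameters).  The cost factor is fixed
for acceptability curves (one panel per anchor) and sampled from
Triangular(1.0, 2.3, 3.5) for the cost-effectiveness-plane scatter.
Uniform deviates are consumed row-major from one `(n_draws, 15)` matrix,
so extending the draw count at a fixed seed leaves earlier draws
bit-identical.

## Threshold extraction

With two strategies and a strictly positive incremental effect in every
draw (which holds in the base case and is verified at run time), the
six-implant strategy's acceptability at willingness-to-pay λ is the
empirical CDF of the per-draw ICERs at λ; the two acceptability curves
cross 0.5 exactly at the **median per-draw ICER**.  The threshold is
computed as that median — grid-free and reproducible — with a bootstrap
(200 resamples) standard error; a CEAC grid scan (0–50,000 € in 250 €
steps by default) is retained as an independent cross-check in the test
suite.  NMB ties are split 0.5/0.5.

Per-draw effect dominance is not guaranteed outside the base case: when
the repair adjustment is pinned at 0, roughly one draw in 10⁵ realises a
six-implant denture-failure rate above the four-implant one and a
negative incremental effect.  The strict median-ICER extraction treats
such draws as an error by default; pipeline entry points instead use the
exact acceptability-curve crossing computed by an event sweep over the
per-draw win breakpoints (draws with ΔE < 0 and ΔC > 0 simply never
prefer six implants), which coincides with the median ICER whenever
dominance does hold.

In the one-way sensitivity suite every scenario × cost-factor cell is
simulated from the same seed (common random numbers), so cells that are
structurally insensitive to an override — notably the no-implant
denture-failure grid, whose state is almost never reached within 10
years — agree to the euro rather than to Monte Carlo noise.  The
no-implant grid rows pin that rate to a point mass at the stated value
(0.00/0.06/0.12); the pinned-adjustment rows replace the adjustment's
triangular distribution by a point mass.

## Synthetic model instances

`scenarios.random_instance(seed)` generates structurally valid random
configurations for property testing: failure modes strictly decreasing in
implant count (modes ≤ 0.2), shared relative min/max bounds along the
interpolation line (which keeps interpolated supports inside [0, 1]),
monotone satisfaction anchors in [0.5, 1], and cost schedules with
six-implant costs above four-implant costs.  These instances emulate the
*structure* of the evidence tables, not clinical reality: they do not
model correlated failure processes, patient heterogeneity, mortality or
re-implantation, so a green cohort-vs-microsimulation test establishes
that the recursion computes the stated model's expectation, not that the
model is clinically adequate.

## Numerical choices

* Triangular inverse CDF: closed form with the left branch for
  `u < F(mode)`; output clipped to the support to guard against roundoff
  at extreme parameter magnitudes.
* Table interpolation: exact rational arithmetic on shortest-repr
  decimals (see above); interpolated bounds leaving [0, 1] are an error,
  not clamped.
* Cohort recursion: dense mass vector over 7 counts × repair flag;
  probability conservation is exact to 1e-12 and asserted in tests.
* Reported thresholds are rounded to whole euros only at the reporting
  boundary.

## Known limitations

* The two in-cycle reward conventions rejected above remain defensible
  readings of the source; the ±15% acceptance band on stochastic
  thresholds reflects that residual ambiguity.
* Satisfaction uncertainty is not modelled (point estimates by design).
* No discounting; results at longer horizons than ~10 years would need it.
* The microsimulation oracle shares the model's structural assumptions;
  it guards against implementation errors, not specification errors.
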