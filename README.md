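# scalecraft

Goal-directed questionnaire construction under classical test theory
(CTT), for psychometricians and health-outcomes researchers shortening a
patient-reported outcome (PRO) instrument. A questionnaire can be built
for **measurement** — sum scores that represent the attribute precisely —
or for **prediction** — sum scores that forecast an external criterion
such as a gold-standard diagnosis. The two goals make opposite demands
on the items, and scalecraft makes both construction pipelines, and the
tension between them, computable from nothing more than a correlation
table.

## The statistics

For items *i* = 1..*n* with standard deviations σᵢ, inter-item
correlations ρᵢⱼ, and item–criterion correlations ρᵢY, the package
evaluates in closed form

- **coefficient alpha**
  α = n/(n−1) · (1 − Σσᵢ² / ΣΣ σᵢσⱼρᵢⱼ) — the internal-consistency
  lower bound to the reliability ρ²\_XT = σ²\_T/σ²\_X of the sum score;
- **predictive validity**
  ρ\_XY = Σσᵢρᵢ\_Y / √(ΣΣ σᵢσⱼρᵢⱼ) — the sum-score–criterion
  correlation, which *rises* as inter-item correlations fall;
- the corrected item–total correlation, α and ρ\_XY with an item
  deleted (the step statistics of stepwise backward selection), the
  Spearman–Brown prophecy, and the ceiling ρ\_XY ≤ √(reliability).

Item selection is provided as greedy backward elimination under either
objective and as exhaustive best-subset search (capped: an *n*-item pool
has 2ⁿ−1 candidate scales). A population true-score model module
exhibits the paradox that resolves the apparent conflict between the
formulas above: mutually uncorrelated but individually reliable items
give reliability 0.8 with α exactly 0 — alpha, not reliability, is what
low inter-item correlations destroy. A simulator of four-point Likert
items driven by correlated latent factors, with a binary criterion
thresholded at a target prevalence, closes the loop from population
design to sampled data to selection behavior.

## Worked example

The package bundles a published Pearson correlation table of ten
four-point depression-questionnaire items and a binary diagnostic
criterion (242 patients); only correlations were published, so it is
analyzed in standardized mode (unit SDs). `examples/01_worked_example.py`
scores the two published five-item scales:

```
measurement-based scale (2, 3, 5, 8, 10): alpha = 0.80, validity = 0.33
prediction-based scale (4, 6, 7, 9, 10): alpha = 0.63, validity = 0.39
```

Each scale wins on its own objective and loses on the other: relative to
the full 20-item instrument (α = 0.93, validity = 0.40), the
prediction-based scale gives up a third of alpha but almost no validity
(2%), while the measurement-based scale keeps alpha (down 14%) and drops
validity by 17%. Running the backward searches themselves
(`examples/02_item_selection.py`) shows the first deletions — item 9
under the measurement objective, item 2 under the prediction objective —
and that the two final scales share only two items: different goals
select different items. Because the published correlations are rounded
to two decimals, several deletion steps are near-ties; the trace flags
them, and final set membership (not the headline statistics) can differ
from the published sets at equal objective values.

The other examples print the paradox table
(`examples/03_paradox.py`) and a 20-replication simulation experiment
(`examples/04_simulation_experiment.py`) in which the measurement arm
averages the higher alpha and the prediction arm the higher validity —
the trade-off in expectation rather than in one sample.

A thin CLI mirrors the library: `scalecraft describe | select | compare
| count-subsets | paradox | simulate | experiment` (see `--help`).

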