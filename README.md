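# surrosim

Stochastic simulation of **surrogate-sire dissemination strategies** in a
two-part pig breeding program.

## The problem

Pig breeding programs improve a small elite *nucleus* by recurrent
genomic selection, but commercial animals receive that genetic progress
only after several years of *multiplication*: selected nucleus males are
mated through a multiplier layer whose unselected females dilute the
males' merit and add generations of lag.  An alternative is to identify a
handful of truly elite *donor* males by multi-stage testing (a genomic
screen followed by one or two progeny tests) and disseminate their
germline directly through surrogate sires — germline-ablated males
carrying donor spermatogonia — so that commercial-sire merit is the
donors' own, undiluted.

`surrosim` simulates both routes on a shared nucleus trajectory and asks:
**how many years' worth of genetic gain (YGG) does the surrogate-sire
strategy put commercial sires ahead of conventional multiplication?**

## The model in one paragraph

A 42-generation gene-drop nucleus (cohorts of 1,000 or 5,000; the 50 best
males by a noisy genomic pseudo-EBV and all females selected each year)
over a 10-chromosome genome founded from 400 base haplotypes, with a
purely additive trait.  Conventional dissemination takes the top
50/200/500 males, applies a 3.5-year multiplication lag and a printed
maternal-ancestor dilution recursion; surrogate-sire dissemination runs a
donor-testing pipeline (genomic screen, then progeny-test stages under a
fixed budget of 14,000 test progeny; lag 3.5 or 4.5 years) and passes
donor merit through undiluted.  Strategy merit is converted to years by
inverting the conventional top-50 reference trajectory over source
generations 11–20.  See [docs/methods.md](docs/methods.md) for the full
model, assumptions, and limitations.

## Worked example

One desk-scale replicate: run a small nucleus at genomic accuracy 0.5,
then compare the best three-stage surrogate-sire pipeline (S0 screen,
S1 = 100 candidates × 60 progeny, S2 = 20 × 400, one donor) against
conventional top-50 multiplication.

```python
import numpy as np

from surrosim import (
    NucleusConfig, StrategySpec, commercial_trajectory,
    generate_base_haplotypes, run_nucleus, sample_architecture, ygg,
)
from surrosim.metrics import prepare_reference

rng = np.random.default_rng(42)
panel = generate_base_haplotypes(loci_per_chromosome=200, seed=rng)
arch = sample_architecture(panel, 200, rng)
nucleus = run_nucleus(NucleusConfig.small(genomic_accuracy=0.5), panel, arch, seed=rng)

conv50 = commercial_trajectory(nucleus, StrategySpec.conventional(50), rng)
surrogate = commercial_trajectory(
    nucleus, StrategySpec.three_stage(100, 60, 20, 400), rng
)

reference = prepare_reference(conv50)
print("nucleus gain  :", round(nucleus.summary().male_mean_std.iloc[-1], 2), "base SD")
print("YGG conv50    :", round(ygg(conv50, reference), 2))
print("YGG surrogate :", round(ygg(surrogate, reference), 2))
```

Output:

```
nucleus gain  : 16.5 base SD
YGG conv50    : -0.0
YGG surrogate : 5.05
```

In this replicate the surrogate-sire strategy puts commercial sires about
5 years' worth of genetic gain ahead of the conventional program.

## Full experiments

The CLI orchestrates replicated experiments over the whole scenario grid
(3 conventional + 12 two-stage + 36 three-stage scenarios per nucleus
size and accuracy):

```bash
surrosim grid                                   # the scenario map as CSV
surrosim simulate --seed 1 --replicates 20 \
    --out results --size small --accuracy 0.5   # trajectories + YGG tables
surrosim ygg results/trajectories.csv           # recompute YGG summaries
```

`simulate` writes `trajectories.csv`, `ygg_summary.csv`, `manifest.json`,
and `run.log`; runs are resumable per replicate and byte-identical on
rerun.  A YAML config file (`--config`) can set any
`surrosim.scenario_runner.ExperimentConfig` field; flags override it.
The default `reduced` profile uses 200 loci per chromosome and 20
replicates; `--profile full` switches to 1,000 loci and 100 replicates.

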