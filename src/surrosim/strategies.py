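"""Dissemination strategies: conventional multiplication vs surrogate sires.

Conventional multiplication takes the top 50/200/500 nucleus males (by a
genomic pseudo-EBV), passes their merit through two rounds of
multiplication (3.5 years) and dilutes it by the lagged, unselected
females of the multiplier layer:

    diluted(t) = 0.5 a(t) + 0.5 * sum_{i=1..6} w_i a(t - i),

with w = (0.5, 0.25, ..., 0.015625) — the relationship between a
commercial sire and his maternal male ancestor i generations back.  The
weights are applied exactly as printed (they sum to 0.984375 and are not
renormalised).

The surrogate-sire strategy instead identifies one (or five) elite
donor(s) per male cohort through multi-stage testing — a genomic screen
(S0) followed by one (S1; 3.5-year lag) or two (S1 + S2; 4.5-year lag)
progeny tests under a fixed budget of 14,000 test progeny — and the
donor's own merit reaches the commercial layer undiluted through
germline transplantation into surrogate males.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .nucleus_engine import NucleusRun
from .testing_models import (
    DEFAULT_H2,
    Stage,
    TestSpec,
    progeny_test_accuracy,
    pseudo_ebv,
    select_top,
)

#: Relationship of a commercial sire to his maternal male ancestor i
#: generations back, i = 1..6.
DILUTION_WEIGHTS = (0.5, 0.25, 0.125, 0.0625, 0.03125, 0.015625)

#: Progeny available for the progeny-testing stages of every scenario.
PROGENY_BUDGET = 14000

LAG_CONVENTIONAL = 3.5
LAG_TWO_STAGE = 3.5
LAG_THREE_STAGE = 4.5

StrategyKind = Literal["conventional", "ss_two_stage", "ss_three_stage"]


@dataclass(frozen=True)
class StageAllocation:
    """Candidates entering a progeny-test stage and progeny per candidate."""

    n_candidates: int
    progeny_per_candidate: int

    @property
    def budget(self) -> int:
        return self.n_candidates * self.progeny_per_candidate

    def accuracy(self, h2: float = DEFAULT_H2) -> float:
        return progeny_test_accuracy(self.progeny_per_candidate, h2)


@dataclass(frozen=True)
class StrategySpec:
    """One scenario of the study grid."""

    kind: StrategyKind
    conventional_n_males: int | None = None
    s1: StageAllocation | None = None
    s2: StageAllocation | None = None
    n_donors: int = 1
    lag_years: float = LAG_CONVENTIONAL
    dilution: bool = False
    h2: float = DEFAULT_H2

    def __post_init__(self) -> None:
        if self.kind == "conventional":
            if self.conventional_n_males is None or self.conventional_n_males < 1:
                raise ValueError("conventional strategy needs a positive male count")
            if self.s1 is not None or self.s2 is not None:
                raise ValueError("conventional strategy takes no progeny-test stages")
        elif self.kind == "ss_two_stage":
            if self.s1 is None or self.s2 is not None:
                raise ValueError("two-stage testing needs s1 and forbids s2")
            self._check_pipeline(self.s1.n_candidates, self.n_donors)
        elif self.kind == "ss_three_stage":
            if self.s1 is None or self.s2 is None:
                raise ValueError("three-stage testing needs both s1 and s2")
            self._check_pipeline(self.s1.n_candidates, self.s2.n_candidates, self.n_donors)
        else:
            raise ValueError(f"unknown strategy kind {self.kind!r}")

    @staticmethod
    def _check_pipeline(*sizes: int) -> None:
        for a, b in zip(sizes, sizes[1:]):
            if b > a:
                raise ValueError(f"stage sizes must be non-increasing, got {sizes}")

    @property
    def progeny_budget(self) -> int:
        total = 0
        for alloc in (self.s1, self.s2):
            if alloc is not None:
                total += alloc.budget
        return total

    def validate_budget(self, budget: int = PROGENY_BUDGET) -> None:
        """Check the scenario spends the progeny budget.

        Progeny per candidate are whole animals, so a stage may deviate
        from an exact split by up to half a progeny per candidate (the
        printed study cells 224 x 63 and 448 x 31 round 62.5 and 31.25).
        """
        if self.kind == "conventional":
            return
        slack = sum(
            alloc.n_candidates / 2.0 for alloc in (self.s1, self.s2) if alloc is not None
        )
        if abs(self.progeny_budget - budget) > slack:
            raise ValueError(
                f"scenario {self.label()!r} uses {self.progeny_budget} test progeny, "
                f"budget is {budget}"
            )

    def label(self) -> str:
        if self.kind == "conventional":
            return f"conv{self.conventional_n_males}"
        parts = [f"s1_{self.s1.n_candidates}x{self.s1.progeny_per_candidate}"]
        if self.s2 is not None:
            parts.append(f"s2_{self.s2.n_candidates}x{self.s2.progeny_per_candidate}")
        parts.append(f"d{self.n_donors}")
        prefix = "ss2" if self.kind == "ss_two_stage" else "ss3"
        return prefix + "_" + "_".join(parts)

    # -- constructors -----------------------------------------------------

    @classmethod
    def conventional(cls, n_males: int) -> "StrategySpec":
        return cls(
            kind="conventional",
            conventional_n_males=n_males,
            lag_years=LAG_CONVENTIONAL,
            dilution=True,
        )

    @classmethod
    def two_stage(
        cls, n_candidates: int, progeny_per_candidate: int, n_donors: int = 1, h2: float = DEFAULT_H2
    ) -> "StrategySpec":
        return cls(
            kind="ss_two_stage",
            s1=StageAllocation(n_candidates, progeny_per_candidate),
            n_donors=n_donors,
            lag_years=LAG_TWO_STAGE,
            h2=h2,
        )

    @classmethod
    def three_stage(
        cls,
        s1_candidates: int,
        s1_progeny: int,
        s2_candidates: int,
        s2_progeny: int,
        n_donors: int = 1,
        h2: float = DEFAULT_H2,
    ) -> "StrategySpec":
        return cls(
            kind="ss_three_stage",
            s1=StageAllocation(s1_candidates, s1_progeny),
            s2=StageAllocation(s2_candidates, s2_progeny),
            n_donors=n_donors,
            lag_years=LAG_THREE_STAGE,
            h2=h2,
        )


@dataclass
class CommercialTrajectory:
    """Commercial-sire merit per calendar year for one scenario."""

    spec: StrategySpec
    table: pd.DataFrame  # columns: source_generation, year, merit_raw, merit_std

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy()

    @property
    def merit_std(self) -> np.ndarray:
        return self.table["merit_std"].to_numpy()

    def window(self, first_source_generation: int = 11, last_source_generation: int = 20):
        g = self.table["source_generation"]
        return self.table[(g >= first_source_generation) & (g <= last_source_generation)]


# ---------------------------------------------------------------------------
# conventional multiplication
# ---------------------------------------------------------------------------


def conventional_merit_series(
    nucleus_run: NucleusRun,
    n_males: int,
    rng: np.random.Generator,
    accuracy: float | None = None,
) -> pd.Series:
    """Mean TBV of the top-``n_males`` males per generation.

    Ranking uses a fresh genomic pseudo-EBV at the nucleus accuracy (the
    same testing device used for parent selection, drawn independently).
    """
    if accuracy is None:
        accuracy = nucleus_run.config.genomic_accuracy
    out = {}
    for g in nucleus_run.generations:
        tbvs = nucleus_run.male_tbvs[g]
        if n_males > tbvs.size:
            raise ValueError(f"n_males={n_males} exceeds male cohort size {tbvs.size}")
        test = pseudo_ebv(tbvs, accuracy, rng)
        top = select_top(test, n_males)
        out[int(g)] = float(tbvs[top].mean())
    return pd.Series(out, name=f"conv{n_males}")


def dilute(series: pd.Series, weights: tuple[float, ...] = DILUTION_WEIGHTS) -> pd.Series:
    """Apply the maternal-ancestor dilution recursion, exactly as printed.

    diluted(t) = 0.5 s(t) + 0.5 sum_i w_i s(t - i).  Only generations with
    a full len(weights) history are returned; the weights are not
    renormalised.
    """
    idx = series.index.to_numpy()
    if idx.size <= len(weights):
        raise ValueError("series too short for the dilution history")
    if not np.all(np.diff(idx) == 1):
        raise ValueError("series must be indexed by consecutive generations")
    vals = series.to_numpy(dtype=float)
    d = len(weights)
    w = np.asarray(weights)
    out_idx = idx[d:]
    lagged = np.stack([vals[d - i : vals.size - i] for i in range(1, d + 1)], axis=0)
    diluted = 0.5 * vals[d:] + 0.5 * (w @ lagged)
    return pd.Series(diluted, index=out_idx, name=series.name)


# ---------------------------------------------------------------------------
# surrogate-sire donor identification
# ---------------------------------------------------------------------------


def identify_donors(
    male_tbvs: np.ndarray,
    spec: StrategySpec,
    genomic_accuracy: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Run the multi-stage testing pipeline on one male cohort.

    S0 ranks all males with a genomic pseudo-EBV; survivors advance to the
    progeny-test stage(s), each ranked on that stage's test alone with the
    accuracy implied by its progeny allocation.  Returns the donor indices
    and their mean TBV.
    """
    if spec.kind not in ("ss_two_stage", "ss_three_stage"):
        raise ValueError("donor identification applies to surrogate-sire strategies")
    tbvs = np.asarray(male_tbvs, dtype=float)
    if spec.s1.n_candidates > tbvs.size:
        raise ValueError(
            f"S1 tests {spec.s1.n_candidates} candidates but only {tbvs.size} males exist"
        )

    ids = np.arange(tbvs.size)
    s0 = pseudo_ebv(tbvs, genomic_accuracy, rng, ids=ids, spec=TestSpec.genomic(genomic_accuracy))
    survivors = select_top(s0, spec.s1.n_candidates)

    s1_spec = TestSpec.progeny(spec.s1.progeny_per_candidate, spec.h2, Stage.S1_PROGENY)
    s1 = pseudo_ebv(tbvs[survivors], s1_spec.accuracy, rng, ids=survivors, spec=s1_spec)
    if spec.kind == "ss_three_stage":
        survivors = select_top(s1, spec.s2.n_candidates)
        s2_spec = TestSpec.progeny(spec.s2.progeny_per_candidate, spec.h2, Stage.S2_PROGENY)
        final = pseudo_ebv(tbvs[survivors], s2_spec.accuracy, rng, ids=survivors, spec=s2_spec)
    else:
        final = s1
    donors = select_top(final, spec.n_donors)
    return donors, float(tbvs[donors].mean())


def donor_merit_series(
    nucleus_run: NucleusRun,
    spec: StrategySpec,
    rng: np.random.Generator,
) -> pd.Series:
    """Mean donor TBV per source generation (one pipeline per male cohort)."""
    out = {}
    for g in nucleus_run.generations:
        _, mean_tbv = identify_donors(
            nucleus_run.male_tbvs[g], spec, nucleus_run.config.genomic_accuracy, rng
        )
        out[int(g)] = mean_tbv
    return pd.Series(out, name=spec.label())


# ---------------------------------------------------------------------------
# commercial trajectories
# ---------------------------------------------------------------------------


def commercial_trajectory(
    nucleus_run: NucleusRun,
    spec: StrategySpec,
    rng: np.random.Generator,
) -> CommercialTrajectory:
    """Commercial-sire merit trajectory for one scenario.

    The strategy's selected-male mean TBV from source generation t is
    reported at calendar year t + lag.  Conventional scenarios pass
    through the dilution recursion first, applied to merit expressed as
    deviation from the generation-0 nucleus mean (the point at which the
    multiplier pyramid is anchored); surrogate-sire donors reach the
    commercial layer undiluted.  Merit is standardised by the base scale.
    """
    if nucleus_run.base is None:
        raise ValueError("nucleus run has no base scale (degenerate trait)")
    if spec.kind == "conventional":
        series = conventional_merit_series(nucleus_run, spec.conventional_n_males, rng)
        if spec.dilution:
            anchored = series - nucleus_run.program_start_mean
            series = dilute(anchored) + nucleus_run.program_start_mean
    else:
        series = donor_merit_series(nucleus_run, spec, rng)

    years = series.index.to_numpy(dtype=float) + spec.lag_years
    merit_raw = series.to_numpy(dtype=float)
    merit_std = (merit_raw - nucleus_run.base.base_mean) / nucleus_run.base.base_sd
    table = pd.DataFrame(
        {
            "source_generation": series.index.to_numpy(),
            "year": years,
            "merit_raw": merit_raw,
            "merit_std": merit_std,
        }
    )
    return CommercialTrajectory(spec=spec, table=table)
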