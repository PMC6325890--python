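"""Pseudo-EBV testing devices and deterministic selection-theory utilities.

Breeding-value estimation is never modelled explicitly.  A test with
accuracy r (the correlation between estimated and true breeding value)
is emulated by adding Gaussian noise to the true breeding values with
variance sigma_A^2 (1 - r^2) / r^2, where sigma_A^2 is the variance of
the candidate group's TBVs, so that the expected correlation within that
group equals r.  Progeny-test accuracy follows the classical sire-model
formula r = sqrt(n / (n + (4 - h2)/h2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats


class Stage(str, Enum):
    S0_GENOMIC = "S0_genomic"
    S1_PROGENY = "S1_progeny"
    S2_PROGENY = "S2_progeny"


DEFAULT_H2 = 0.25


@dataclass(frozen=True)
class TestSpec:
    """One testing stage: a genomic screen or a progeny test."""

    stage: Stage
    accuracy: float
    n_progeny: int | None = None
    h2: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.accuracy <= 1.0:
            raise ValueError(f"accuracy must be in (0, 1], got {self.accuracy}")

    @classmethod
    def genomic(cls, accuracy: float) -> "TestSpec":
        return cls(stage=Stage.S0_GENOMIC, accuracy=accuracy)

    @classmethod
    def progeny(cls, n_progeny: int, h2: float = DEFAULT_H2, stage: Stage = Stage.S1_PROGENY) -> "TestSpec":
        return cls(
            stage=stage,
            accuracy=progeny_test_accuracy(n_progeny, h2),
            n_progeny=n_progeny,
            h2=h2,
        )


@dataclass
class TestResult:
    """Pseudo-EBVs for a candidate group under one test."""

    ids: np.ndarray
    ebv: np.ndarray
    spec: TestSpec
    realized_accuracy: float
    tbv: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ids,
                "stage": self.spec.stage.value,
                "ebv": self.ebv,
                "tbv": self.tbv if self.tbv is not None else np.nan,
                "realized_accuracy": self.realized_accuracy,
            }
        )


def pseudo_ebv(
    tbvs: np.ndarray,
    target_accuracy: float,
    rng: np.random.Generator,
    ids: np.ndarray | None = None,
    spec: TestSpec | None = None,
) -> TestResult:
    """Noisy breeding-value estimates at a targeted accuracy.

    ebv_i = tbv_i + e_i with e_i ~ Normal(0, sigma_A^2 (1 - r^2) / r^2),
    sigma_A^2 the candidate-group TBV variance.  r = 1 returns the TBVs
    exactly.  Fresh independent noise per invocation.
    """
    if not 0.0 < target_accuracy <= 1.0:
        raise ValueError(f"target accuracy must be in (0, 1], got {target_accuracy}")
    tbvs = np.asarray(tbvs, dtype=float)
    if ids is None:
        ids = np.arange(tbvs.size)
    if spec is None:
        spec = TestSpec.genomic(target_accuracy)

    if target_accuracy == 1.0:
        ebv = tbvs.copy()
    else:
        sigma2 = float(np.var(tbvs, ddof=1)) if tbvs.size > 1 else 0.0
        noise_sd = np.sqrt(sigma2 * (1.0 - target_accuracy**2) / target_accuracy**2)
        ebv = tbvs + rng.normal(0.0, noise_sd, size=tbvs.size)

    if tbvs.size > 1 and np.std(tbvs) > 0 and np.std(ebv) > 0:
        realized = float(np.corrcoef(tbvs, ebv)[0, 1])
    else:
        realized = np.nan
    return TestResult(ids=np.asarray(ids), ebv=ebv, spec=spec, realized_accuracy=realized, tbv=tbvs)


def progeny_test_accuracy(n_progeny: int, h2: float = DEFAULT_H2) -> float:
    """Classical sire progeny-test accuracy sqrt(n / (n + (4 - h2)/h2)).

    Strictly increasing in both arguments, tending to 1 as n grows.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"heritability must be in (0, 1], got {h2}")
    if n_progeny < 1:
        raise ValueError(f"need at least one progeny, got {n_progeny}")
    k = (4.0 - h2) / h2
    return float(np.sqrt(n_progeny / (n_progeny + k)))


def select_top(result: TestResult, k: int) -> np.ndarray:
    """Ids of the k largest EBVs, descending; ties broken by ascending id."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > result.ids.size:
        raise ValueError(f"k={k} exceeds candidate count {result.ids.size}")
    order = np.lexsort((result.ids, -result.ebv))
    return result.ids[order[:k]]


def selection_intensity(p: float) -> float:
    """Expected standardised mean of the selected upper fraction p.

    i(p) = phi(z_p) / p with z_p the upper-p standard-normal quantile;
    i(1) = 0 and i is strictly decreasing in p.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"selected proportion must be in (0, 1], got {p}")
    if p == 1.0:
        return 0.0
    z = stats.norm.isf(p)
    return float(stats.norm.pdf(z) / p)
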