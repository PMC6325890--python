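"""The recurrent-selection nucleus: 42 discrete generations of gene drop.

Generations run from -22 (founders drawn from the haplotype panel) through
-21..0 (historical genomic selection) to 1..20 (future phase).  Each
generation the 50 best males by a fresh genomic pseudo-EBV and all females
are selected as parents; every selected female is mated once to a sire
drawn uniformly at random from the selected males and contributes
cohort_size / n_females offspring, with sexes alternating so each cohort
splits exactly half male, half female.  One nucleus generation equals one
calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founder_genomes import (
    FEMALE,
    MALE,
    Cohort,
    HaplotypePanel,
    _meiosis_batch,
    sample_founder_cohort,
)
from .testing_models import pseudo_ebv, select_top
from .trait_architecture import (
    BaseScale,
    TraitArchitecture,
    base_scale,
    breeding_values,
    genic_variance,
)

BASE_GENERATION = -22
FINAL_GENERATION = 20


@dataclass(frozen=True)
class NucleusConfig:
    """Nucleus population structure and selection parameters."""

    cohort_size: int = 1000
    n_sires: int = 50
    genomic_accuracy: float = 0.5
    n_generations: int = 42
    base_generation: int = BASE_GENERATION

    def __post_init__(self) -> None:
        if self.cohort_size < 2 or self.cohort_size % 2:
            raise ValueError("cohort size must be a positive even number")
        if self.n_sires > self.cohort_size // 2:
            raise ValueError("cannot select more sires than there are males")
        n_females = self.cohort_size // 2
        if self.cohort_size % n_females:
            raise ValueError("cohort size must be a multiple of the female count")

    @classmethod
    def small(cls, genomic_accuracy: float = 0.5) -> "NucleusConfig":
        return cls(cohort_size=1000, genomic_accuracy=genomic_accuracy)

    @classmethod
    def big(cls, genomic_accuracy: float = 0.5) -> "NucleusConfig":
        return cls(cohort_size=5000, genomic_accuracy=genomic_accuracy)


@dataclass
class NucleusRun:
    """Per-generation records of one nucleus trajectory."""

    config: NucleusConfig
    generations: np.ndarray
    male_tbvs: dict[int, np.ndarray]
    cohort_mean: dict[int, float]
    male_mean: dict[int, float]
    male_sd: dict[int, float]
    sire_mean: dict[int, float]
    sire_ids: dict[int, np.ndarray]
    genic_var: dict[int, float]
    base: BaseScale | None
    program_start_mean: float
    seed: int | None = None
    cohorts: dict[int, Cohort] = field(default_factory=dict, repr=False)

    def summary(self) -> pd.DataFrame:
        """Per-generation merit statistics, standardised by the base scale."""
        gens = self.generations
        male_mean = np.array([self.male_mean[g] for g in gens])
        if self.base is not None:
            male_std = (male_mean - self.base.base_mean) / self.base.base_sd
        else:
            male_std = np.full(male_mean.shape, np.nan)
        return pd.DataFrame(
            {
                "generation": gens,
                "cohort_mean_tbv": [self.cohort_mean[g] for g in gens],
                "male_mean_tbv": male_mean,
                "male_sd_tbv": [self.male_sd[g] for g in gens],
                "male_mean_std": male_std,
                "sire_mean_tbv": [self.sire_mean[g] for g in gens],
                "genic_variance": [self.genic_var[g] for g in gens],
            }
        )


def advance_generation(
    cohort: Cohort,
    config: NucleusConfig,
    architecture: TraitArchitecture,
    rng: np.random.Generator,
    id_start: int = 0,
):
    """One round of selection and mating; returns (next cohort, sire ids).

    Sires are the ``config.n_sires`` best males by a fresh genomic
    pseudo-EBV at ``config.genomic_accuracy``; all females are dams.
    """
    if cohort.tbv is None:
        breeding_values(cohort, architecture)
    males = np.flatnonzero(cohort.is_male)
    females = np.flatnonzero(~cohort.is_male)
    if males.size < config.n_sires:
        raise ValueError(f"only {males.size} males available, need {config.n_sires} sires")
    if males.size != females.size:
        raise ValueError("cohort sex ratio is not half/half")

    test = pseudo_ebv(cohort.tbv[males], config.genomic_accuracy, rng, ids=males)
    sires = select_top(test, config.n_sires)

    n_off_per_dam = config.cohort_size // females.size
    dam_rows = np.repeat(females, n_off_per_dam)
    sire_of_dam = sires[rng.integers(0, sires.size, size=females.size)]
    sire_rows = np.repeat(sire_of_dam, n_off_per_dam)

    maternal = _meiosis_batch(cohort.maternal[dam_rows], cohort.paternal[dam_rows], cohort.gmap, rng)
    paternal = _meiosis_batch(cohort.maternal[sire_rows], cohort.paternal[sire_rows], cohort.gmap, rng)

    n = config.cohort_size
    sex = np.where(np.arange(n) % 2 == 0, MALE, FEMALE)
    nxt = Cohort(
        generation=cohort.generation + 1,
        ids=np.arange(id_start, id_start + n),
        sex=sex,
        maternal=maternal,
        paternal=paternal,
        gmap=cohort.gmap,
    )
    breeding_values(nxt, architecture)
    return nxt, sires


def run_nucleus(
    config: NucleusConfig,
    panel: HaplotypePanel,
    architecture: TraitArchitecture,
    seed: int | np.random.Generator,
    keep_cohorts: bool = False,
) -> NucleusRun:
    """Run the full nucleus trajectory from founders to generation 20.

    The base scale (mean and SD of TBVs) is frozen at the founder
    generation; the generation-0 cohort mean is recorded separately as the
    program-start anchor used when expressing multiplier-layer dilution.
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base_gen = config.base_generation
    cohort = sample_founder_cohort(panel, config.cohort_size, rng, generation=base_gen)
    breeding_values(cohort, architecture)
    try:
        scale = base_scale(cohort, architecture)
    except ValueError:
        # degenerate trait (e.g. all effects zero): raw merit is still
        # recorded, but standardised reporting is unavailable
        scale = None

    run = NucleusRun(
        config=config,
        generations=np.arange(base_gen, base_gen + config.n_generations + 1),
        male_tbvs={},
        cohort_mean={},
        male_mean={},
        male_sd={},
        sire_mean={},
        sire_ids={},
        genic_var={},
        base=scale,
        program_start_mean=np.nan,
        seed=seed if isinstance(seed, int) else None,
    )

    def record(c: Cohort) -> None:
        g = c.generation
        male_tbv = c.tbv[c.is_male]
        run.male_tbvs[g] = male_tbv
        run.cohort_mean[g] = float(c.tbv.mean())
        run.male_mean[g] = float(male_tbv.mean())
        run.male_sd[g] = float(male_tbv.std(ddof=1))
        run.genic_var[g] = genic_variance(c, architecture)
        if keep_cohorts:
            run.cohorts[g] = c

    record(cohort)
    id_start = config.cohort_size
    for _ in range(config.n_generations):
        nxt, sires = advance_generation(cohort, config, architecture, rng, id_start=id_start)
        # ``sires`` are row indices within the parent cohort
        run.sire_ids[cohort.generation] = cohort.ids[sires]
        run.sire_mean[cohort.generation] = float(cohort.tbv[sires].mean())
        cohort = nxt
        id_start += config.cohort_size
        record(cohort)
    run.sire_mean[cohort.generation] = np.nan
    run.sire_ids[cohort.generation] = np.array([], dtype=int)
    run.program_start_mean = run.cohort_mean.get(0, run.cohort_mean[max(run.cohort_mean)])
    return run
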