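"""Additive quantitative trait: causal loci, effects, and base scaling.

The trait is purely additive.  Causal loci are sampled uniformly without
replacement per chromosome and allele-substitution effects are i.i.d.
Normal(0, 1/sqrt(n_causal)) so that a trait with the reference 10,000
causal loci has effect standard deviation 0.01.  The true breeding value
of an animal is the sum of effects times its count of the "1" allele at
the causal loci.  No phenotypes are ever simulated; all testing noise is
introduced downstream by the pseudo-EBV device.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .founder_genomes import Cohort, HaplotypePanel, Individual


@dataclass
class TraitArchitecture:
    """Causal locus indices (per chromosome) and their additive effects."""

    causal_indices: list[np.ndarray]  # sorted, 0-based within chromosome
    effects: list[np.ndarray]  # trait units per copy of the "1" allele

    @property
    def n_causal(self) -> int:
        return sum(idx.size for idx in self.causal_indices)

    @property
    def n_chromosomes(self) -> int:
        return len(self.causal_indices)

    def global_columns(self, offsets: np.ndarray) -> np.ndarray:
        """Causal columns in the concatenated haplotype layout."""
        return np.concatenate(
            [offsets[c] + idx for c, idx in enumerate(self.causal_indices)]
        )

    def effect_vector(self) -> np.ndarray:
        return np.concatenate(self.effects)

    def export(self, path: str) -> None:
        """Write a 3-column table (chromosome, locus index, effect)."""
        with open(path, "w") as fh:
            fh.write("chromosome locus effect\n")
            for c, (idx, eff) in enumerate(zip(self.causal_indices, self.effects)):
                for j, e in zip(idx, eff):
                    fh.write(f"{c} {j} {float(e)!r}\n")

    @classmethod
    def from_file(cls, path: str) -> "TraitArchitecture":
        rows = np.loadtxt(path, skiprows=1, ndmin=2)
        chroms = rows[:, 0].astype(int)
        indices, effects = [], []
        for c in range(chroms.max() + 1):
            sel = chroms == c
            order = np.argsort(rows[sel, 1])
            indices.append(rows[sel, 1].astype(int)[order])
            effects.append(rows[sel, 2][order])
        return cls(indices, effects)


@dataclass(frozen=True)
class BaseScale:
    """Mean and SD of true breeding values in the base cohort.

    Frozen at the first simulated generation; all merit reporting is the
    affine transform (x - base_mean) / base_sd.
    """

    base_mean: float
    base_sd: float

    def __post_init__(self) -> None:
        if not self.base_sd > 0:
            raise ValueError("base SD must be positive")


def sample_architecture(
    panel: HaplotypePanel,
    n_causal_per_chromosome: int,
    rng: np.random.Generator,
) -> TraitArchitecture:
    """Sample causal loci (uniform, without replacement, per chromosome) and effects."""
    for c, n_loci in enumerate(panel.loci_per_chromosome):
        if n_loci < n_causal_per_chromosome:
            raise ValueError(
                f"chromosome {c} has {n_loci} loci, fewer than the requested "
                f"{n_causal_per_chromosome} causal loci"
            )
    indices = [
        np.sort(rng.choice(n_loci, size=n_causal_per_chromosome, replace=False))
        for n_loci in panel.loci_per_chromosome
    ]
    total = n_causal_per_chromosome * panel.n_chromosomes
    sd = 1.0 / np.sqrt(total)
    effects = [rng.normal(0.0, sd, size=n_causal_per_chromosome) for _ in indices]
    return TraitArchitecture(indices, effects)


def true_breeding_value(individual: Individual, architecture: TraitArchitecture) -> float:
    """Sum of effects times the allele-1 count at the causal loci."""
    tbv = 0.0
    for c in range(architecture.n_chromosomes):
        idx = architecture.causal_indices[c]
        dose = (
            individual.maternal_gamete.haplotypes[c][idx]
            + individual.paternal_gamete.haplotypes[c][idx]
        )
        tbv += float(dose @ architecture.effects[c])
    return tbv


def breeding_values(cohort: Cohort, architecture: TraitArchitecture) -> np.ndarray:
    """Vectorised TBVs for a whole cohort (also caches them on the cohort)."""
    cols = architecture.global_columns(cohort.gmap.offsets)
    if cols.size == cohort.maternal.shape[1]:
        # All loci are causal: skip the (large) column gather.
        dose = cohort.maternal + cohort.paternal
    else:
        dose = cohort.maternal[:, cols] + cohort.paternal[:, cols]
    tbv = dose.astype(np.float64) @ architecture.effect_vector()
    cohort.tbv = tbv
    return tbv


def genic_variance(cohort: Cohort, architecture: TraitArchitecture) -> float:
    """Genic (linkage-equilibrium) additive variance, 2 sum p q e^2."""
    cols = architecture.global_columns(cohort.gmap.offsets)
    freq = (cohort.maternal[:, cols].mean(axis=0) + cohort.paternal[:, cols].mean(axis=0)) / 2.0
    e = architecture.effect_vector()
    return float(np.sum(2.0 * freq * (1.0 - freq) * e**2))


def base_scale(base_cohort: Cohort, architecture: TraitArchitecture) -> BaseScale:
    """Mean/SD (n-1 denominator) of base-cohort TBVs, frozen for reporting."""
    tbv = base_cohort.tbv
    if tbv is None:
        tbv = breeding_values(base_cohort, architecture)
    sd = float(np.std(tbv, ddof=1))
    if sd == 0.0:
        raise ValueError("base cohort has zero TBV variance; scaling undefined")
    return BaseScale(base_mean=float(np.mean(tbv)), base_sd=sd)
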