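"""Founder haplotypes and gamete formation for the gene-drop simulation.

The base population is represented by a panel of phased biallelic
haplotypes (default 400 haplotypes on ten 1-Morgan chromosomes).  Allele
frequencies are drawn from a configurable site-frequency spectrum and
alleles are then assigned independently per haplotype; loci that come out
monomorphic are resampled so that every locus segregates in the panel.

Meiosis follows the classical no-interference model: the number of
crossovers per chromosome is Poisson with mean equal to the chromosome
length in Morgans, crossover positions are uniform on the genetic map, and
the starting parental strand is chosen with probability 1/2.  All heavy
operations are vectorised over individuals; the per-individual
:func:`make_gamete` / :func:`mate` API is a thin wrapper over the same
machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MALE = "M"
FEMALE = "F"

_MAX_LOCUS_RETRIES = 1000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Genetic positions (Morgans) of the loci, per chromosome."""

    positions: tuple[np.ndarray, ...]
    chromosome_length: float = 1.0

    def __post_init__(self) -> None:
        for c, pos in enumerate(self.positions):
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ValueError(f"genetic positions not strictly increasing on chromosome {c}")
            if pos.size and (pos[0] < 0 or pos[-1] > self.chromosome_length):
                raise ValueError(f"genetic positions outside [0, length] on chromosome {c}")

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    @property
    def loci_per_chromosome(self) -> tuple[int, ...]:
        return tuple(p.size for p in self.positions)

    @property
    def n_loci(self) -> int:
        return sum(self.loci_per_chromosome)

    @property
    def offsets(self) -> np.ndarray:
        """Start column of each chromosome in the concatenated layout."""
        return np.concatenate([[0], np.cumsum(self.loci_per_chromosome)])


@dataclass
class HaplotypePanel:
    """Phased founder haplotypes, one allele matrix per chromosome.

    ``alleles[c]`` has shape ``(n_haplotypes, n_loci_c)`` with entries in
    {0, 1}; every locus segregates (frequency strictly inside (0, 1)).
    """

    alleles: list[np.ndarray]
    gmap: GeneticMap
    metadata: dict = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles[0].shape[0]

    @property
    def n_chromosomes(self) -> int:
        return len(self.alleles)

    @property
    def loci_per_chromosome(self) -> tuple[int, ...]:
        return tuple(a.shape[1] for a in self.alleles)

    @property
    def n_loci(self) -> int:
        return sum(self.loci_per_chromosome)

    def concatenated(self) -> np.ndarray:
        """All chromosomes side by side, shape (n_haplotypes, n_loci)."""
        return np.concatenate(self.alleles, axis=1)

    def validate(self) -> None:
        n = self.n_haplotypes
        if self.n_chromosomes != self.gmap.n_chromosomes:
            raise ValueError("panel and map disagree on chromosome count")
        for c, a in enumerate(self.alleles):
            if a.shape[0] != n:
                raise ValueError("inconsistent haplotype count across chromosomes")
            if a.shape[1] != self.gmap.loci_per_chromosome[c]:
                raise ValueError(f"panel and map disagree on locus count for chromosome {c}")
            if not np.isin(a, (0, 1)).all():
                raise ValueError(f"non-biallelic allele code on chromosome {c}")
            freq = a.mean(axis=0)
            if np.any((freq <= 0) | (freq >= 1)):
                raise ValueError(f"monomorphic locus on chromosome {c}")


@dataclass(frozen=True)
class Gamete:
    """One haplotype per chromosome."""

    haplotypes: tuple[np.ndarray, ...]

    @property
    def n_chromosomes(self) -> int:
        return len(self.haplotypes)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.haplotypes)


@dataclass
class Individual:
    """A diploid animal with cached true breeding value."""

    id: int
    sex: str
    maternal_gamete: Gamete
    paternal_gamete: Gamete
    generation: int
    tbv: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"sex must be {MALE!r} or {FEMALE!r}, got {self.sex!r}")
        shapes_m = [h.shape for h in self.maternal_gamete.haplotypes]
        shapes_p = [h.shape for h in self.paternal_gamete.haplotypes]
        if shapes_m != shapes_p:
            raise ValueError("maternal and paternal gametes cover different loci sets")


class Cohort:
    """A generation of individuals stored as concatenated haplotype arrays.

    Haplotype matrices have shape ``(n, n_loci)`` (chromosomes side by
    side, boundaries given by ``gmap.offsets``), which keeps the gene-drop
    loop a handful of vectorised numpy operations per generation.
    """

    def __init__(
        self,
        generation: int,
        ids: np.ndarray,
        sex: np.ndarray,
        maternal: np.ndarray,
        paternal: np.ndarray,
        gmap: GeneticMap,
        tbv: np.ndarray | None = None,
    ) -> None:
        self.generation = int(generation)
        self.ids = np.asarray(ids)
        self.sex = np.asarray(sex)
        self.maternal = maternal
        self.paternal = paternal
        self.gmap = gmap
        self.tbv = tbv

    def __len__(self) -> int:
        return self.ids.size

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == MALE

    @property
    def n_males(self) -> int:
        return int(self.is_male.sum())

    @property
    def n_females(self) -> int:
        return len(self) - self.n_males

    def subset(self, index: np.ndarray) -> "Cohort":
        return Cohort(
            self.generation,
            self.ids[index],
            self.sex[index],
            self.maternal[index],
            self.paternal[index],
            self.gmap,
            None if self.tbv is None else self.tbv[index],
        )

    def _split(self, row: np.ndarray) -> Gamete:
        off = self.gmap.offsets
        return Gamete(tuple(row[off[c] : off[c + 1]] for c in range(self.gmap.n_chromosomes)))

    def individual(self, i: int) -> Individual:
        """Materialise row ``i`` as an :class:`Individual` view."""
        ind = Individual(
            id=int(self.ids[i]),
            sex=str(self.sex[i]),
            maternal_gamete=self._split(self.maternal[i]),
            paternal_gamete=self._split(self.paternal[i]),
            generation=self.generation,
            tbv=None if self.tbv is None else float(self.tbv[i]),
        )
        ind._gmap = self.gmap  # type: ignore[attr-defined]
        return ind

    @classmethod
    def from_individuals(cls, individuals: list[Individual], gmap: GeneticMap) -> "Cohort":
        if not individuals:
            raise ValueError("empty individual list")
        mat = np.stack([ind.maternal_gamete.concatenated() for ind in individuals])
        pat = np.stack([ind.paternal_gamete.concatenated() for ind in individuals])
        tbv = None
        if all(ind.tbv is not None for ind in individuals):
            tbv = np.array([ind.tbv for ind in individuals], dtype=float)
        return cls(
            generation=individuals[0].generation,
            ids=np.array([ind.id for ind in individuals]),
            sex=np.array([ind.sex for ind in individuals]),
            maternal=mat,
            paternal=pat,
            gmap=gmap,
            tbv=tbv,
        )


# ---------------------------------------------------------------------------
# founder panel generation
# ---------------------------------------------------------------------------


def _spectrum_sampler(frequency_model: str, n_haplotypes: int, rng: np.random.Generator):
    """Return a callable drawing allele frequencies from the named spectrum."""
    model = frequency_model.strip().lower()
    if model == "neutral-sfs":
        # density proportional to 1/x on the truncated grid i/n, i=1..n-1
        grid = np.arange(1, n_haplotypes) / n_haplotypes
        weights = 1.0 / grid
        weights /= weights.sum()
        return lambda size: rng.choice(grid, size=size, p=weights)
    if model == "uniform":
        return lambda size: rng.uniform(0.0, 1.0, size=size)
    if model.startswith("beta(") and model.endswith(")"):
        try:
            a, b = (float(x) for x in model[5:-1].split(","))
        except ValueError as exc:
            raise ValueError(f"cannot parse beta parameters from {frequency_model!r}") from exc
        return lambda size: rng.beta(a, b, size=size)
    raise ValueError(
        f"unknown frequency model {frequency_model!r}; "
        "expected 'neutral-sfs', 'uniform' or 'beta(a,b)'"
    )


def spectrum_density(frequency_model: str, n_haplotypes: int):
    """(grid, probability) arrays of the configured frequency spectrum.

    For continuous spectra the density is discretised on the i/n grid; used
    by calibration checks that compare empirical frequency histograms with
    the configured law.
    """
    grid = np.arange(1, n_haplotypes) / n_haplotypes
    model = frequency_model.strip().lower()
    if model == "neutral-sfs":
        w = 1.0 / grid
    elif model == "uniform":
        w = np.ones_like(grid)
    elif model.startswith("beta(") and model.endswith(")"):
        from scipy import stats

        a, b = (float(x) for x in model[5:-1].split(","))
        w = stats.beta.pdf(grid, a, b)
    else:
        raise ValueError(f"unknown frequency model {frequency_model!r}")
    return grid, w / w.sum()


def generate_base_haplotypes(
    n_haplotypes: int = 400,
    n_chromosomes: int = 10,
    loci_per_chromosome: int = 1000,
    frequency_model: str = "neutral-sfs",
    seed: int | np.random.Generator = 0,
    chromosome_length: float = 1.0,
) -> HaplotypePanel:
    """Generate the founder haplotype panel.

    Per locus an allele frequency is drawn from ``frequency_model`` and
    alleles are assigned independently per haplotype; monomorphic draws
    are resampled (bounded retries).  Genetic positions are uniform draws
    on (0, chromosome_length), sorted, per chromosome.  Deterministic for
    a given seed.
    """
    if n_haplotypes < 2 or n_chromosomes < 1 or loci_per_chromosome < 1:
        raise ValueError("need >=2 haplotypes and >=1 chromosome/locus")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sample_freqs = _spectrum_sampler(frequency_model, n_haplotypes, rng)

    alleles: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for _ in range(n_chromosomes):
        freqs = sample_freqs(loci_per_chromosome)
        chrom = (rng.random((n_haplotypes, loci_per_chromosome)) < freqs).astype(np.int8)
        counts = chrom.sum(axis=0)
        bad = np.flatnonzero((counts == 0) | (counts == n_haplotypes))
        retries = 0
        while bad.size:
            retries += 1
            if retries > _MAX_LOCUS_RETRIES:
                raise RuntimeError(
                    f"could not obtain segregating alleles at {bad.size} loci "
                    f"after {_MAX_LOCUS_RETRIES} retries"
                )
            freqs_bad = sample_freqs(bad.size)
            redraw = (rng.random((n_haplotypes, bad.size)) < freqs_bad).astype(np.int8)
            chrom[:, bad] = redraw
            counts = chrom[:, bad].sum(axis=0)
            bad = bad[(counts == 0) | (counts == n_haplotypes)]
        pos = np.sort(rng.uniform(0.0, chromosome_length, size=loci_per_chromosome))
        # nudge exact ties apart to keep positions strictly increasing
        while np.any(np.diff(pos) <= 0):  # pragma: no cover - astronomically rare
            pos = np.sort(rng.uniform(0.0, chromosome_length, size=loci_per_chromosome))
        alleles.append(chrom)
        positions.append(pos)

    panel = HaplotypePanel(
        alleles=alleles,
        gmap=GeneticMap(tuple(positions), chromosome_length),
        metadata={
            "frequency_model": frequency_model,
            # recorded for provenance only; the founder generator emulates a
            # livestock-like base population rather than running a coalescent
            "emulated_Ne_schedule": {"now": 100, "1e3_ya": 1256, "1e4_ya": 4350, "1e5_ya": 43500},
            "per_site_mutation_rate": 2.5e-8,
            "per_site_recombination_rate": 1.0e-8,
        },
    )
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# haplotype import / export
# ---------------------------------------------------------------------------


def export_haplotypes(panel: HaplotypePanel, path: str) -> None:
    """Write a panel as a whitespace 0/1 matrix plus a companion map file.

    The matrix file (``path``) has a header row of locus ids and one row
    per haplotype; the map file (``path + '.map'``) has three columns:
    chromosome, locus id, position in cM.
    """
    ids = [
        f"chr{c}_loc{j}"
        for c in range(panel.n_chromosomes)
        for j in range(panel.loci_per_chromosome[c])
    ]
    mat = panel.concatenated()
    with open(path, "w") as fh:
        fh.write(" ".join(ids) + "\n")
        for row in mat:
            fh.write(" ".join(str(int(x)) for x in row) + "\n")
    with open(path + ".map", "w") as fh:
        for c in range(panel.n_chromosomes):
            for j, pos in enumerate(panel.gmap.positions[c]):
                fh.write(f"{c} chr{c}_loc{j} {100.0 * pos:.10g}\n")


def _import_matrix(path: str, map_path: str | None) -> HaplotypePanel:
    if map_path is None:
        map_path = path + ".map"
    with open(path) as fh:
        header = fh.readline().split()
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}")
            try:
                rows.append(np.array(fields, dtype=np.int8))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer allele code") from exc
    mat = np.stack(rows)
    if not np.isin(mat, (0, 1)).all():
        bad = np.argwhere(~np.isin(mat, (0, 1)))[0]
        raise ValueError(f"{path}: allele code not in {{0,1}} at haplotype {bad[0]}, column {bad[1]}")

    chrom_of: dict[str, int] = {}
    cm_of: dict[str, float] = {}
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"{map_path}:{lineno}: expected 3 columns (chrom, id, cM)")
            chrom_of[fields[1]] = int(fields[0])
            cm_of[fields[1]] = float(fields[2])
    missing = [i for i in header if i not in chrom_of]
    if missing:
        raise ValueError(f"{map_path}: no map entry for locus {missing[0]!r}")

    chroms = sorted(set(chrom_of[i] for i in header))
    alleles, positions = [], []
    for c in chroms:
        cols = [k for k, i in enumerate(header) if chrom_of[i] == c]
        cols.sort(key=lambda k: cm_of[header[k]])
        alleles.append(np.ascontiguousarray(mat[:, cols]))
        positions.append(np.array([cm_of[header[k]] / 100.0 for k in cols]))
    length = max(1.0, max(p[-1] for p in positions if p.size))
    return HaplotypePanel(alleles, GeneticMap(tuple(positions), length))


def _import_vcf(path: str) -> HaplotypePanel:
    from cyvcf2 import VCF

    by_chrom: dict[str, list[tuple[float, np.ndarray]]] = {}
    for variant in VCF(path):
        gts = variant.genotypes  # [allele_a, allele_b, phased] per sample
        hap = []
        for s, gt in enumerate(gts):
            if len(gt) != 3:
                raise ValueError(
                    f"{path}: ploidy != 2 for sample {s} at {variant.CHROM}:{variant.POS}"
                )
            a, b, phased = gt
            if not phased:
                raise ValueError(
                    f"{path}: unphased genotype for sample {s} at {variant.CHROM}:{variant.POS}"
                )
            if a < 0 or b < 0:
                raise ValueError(
                    f"{path}: missing genotype for sample {s} at {variant.CHROM}:{variant.POS}"
                )
            hap.extend((a, b))
        # 1 cM per Mb: physical position to Morgans
        by_chrom.setdefault(variant.CHROM, []).append((variant.POS * 1e-8, np.array(hap, np.int8)))

    if not by_chrom:
        raise ValueError(f"{path}: no variant records")
    alleles, positions = [], []
    for chrom in by_chrom:
        recs = sorted(by_chrom[chrom], key=lambda r: r[0])
        positions.append(np.array([r[0] for r in recs]))
        alleles.append(np.stack([r[1] for r in recs], axis=1))
    length = max(1.0, max(p[-1] for p in positions))
    return HaplotypePanel(alleles, GeneticMap(tuple(positions), length))


def import_haplotypes(path: str, format: str = "matrix", map_path: str | None = None) -> HaplotypePanel:
    """Read a phased haplotype panel from a 0/1 matrix or a phased VCF.

    Loci that are monomorphic in the file are dropped (the number dropped
    is logged); remaining loci must satisfy all panel invariants.
    """
    if format == "matrix":
        panel = _import_matrix(path, map_path)
    elif format == "vcf":
        panel = _import_vcf(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'matrix' or 'vcf'")

    n = panel.n_haplotypes
    dropped = 0
    alleles, positions = [], []
    for a, pos in zip(panel.alleles, panel.gmap.positions):
        counts = a.sum(axis=0)
        keep = (counts > 0) & (counts < n)
        dropped += int((~keep).sum())
        alleles.append(np.ascontiguousarray(a[:, keep]))
        positions.append(pos[keep])
    if dropped:
        logger.info("import_haplotypes: dropped %d non-segregating locus/loci", dropped)
    panel = HaplotypePanel(alleles, GeneticMap(tuple(positions), panel.gmap.chromosome_length))
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# gamete formation
# ---------------------------------------------------------------------------


def _draw_crossovers(n: int, length: float, rng: np.random.Generator):
    """Poisson(length) crossover counts and flat uniform positions.

    Returns ``(counts, positions, meiosis_index)`` with one entry in
    ``positions`` per crossover and ``meiosis_index`` mapping it back to
    its meiosis.  No interference: positions are i.i.d. uniform.
    """
    counts = rng.poisson(length, size=n)
    total = int(counts.sum())
    positions = rng.uniform(0.0, length, size=total)
    return counts, positions, np.repeat(np.arange(n), counts)


def sample_crossover_positions(n: int, length: float, rng: np.random.Generator):
    """Crossover counts and positions for ``n`` meioses on one chromosome.

    Counts are Poisson(length in Morgans); positions are uniform on
    (0, length) with no interference.  Returns ``(counts, positions)``
    where ``positions`` is an ``(n, max_count)`` array padded with +inf.
    """
    counts, flat, midx = _draw_crossovers(n, length, rng)
    kmax = int(counts.max(initial=0))
    positions = np.full((n, kmax), np.inf)
    if kmax:
        within = np.concatenate([np.arange(k) for k in counts]) if flat.size else np.array([], int)
        positions[midx, within] = flat
    return counts, positions


def _meiosis_batch(
    maternal: np.ndarray,
    paternal: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete per row from (n, n_loci) parental haplotype arrays."""
    n = maternal.shape[0]
    out = np.empty_like(maternal)
    off = gmap.offsets
    for c in range(gmap.n_chromosomes):
        sl = slice(off[c], off[c + 1])
        pos = gmap.positions[c]
        n_loci = pos.size
        _, xo_pos, xo_row = _draw_crossovers(n, gmap.chromosome_length, rng)
        # a crossover at p flips the strand for all loci with position > p;
        # scatter counts into locus bins and cumulative-sum for the parity
        col = np.searchsorted(pos, xo_pos, side="left")
        delta = np.zeros((n, n_loci + 1), dtype=np.int8)
        np.add.at(delta, (xo_row, col), 1)
        n_left = delta[:, :n_loci].cumsum(axis=1, dtype=np.int8)
        start = rng.integers(0, 2, size=n).astype(np.int8)
        use_paternal = (start[:, None] + n_left) & 1
        out[:, sl] = np.where(use_paternal, paternal[:, sl], maternal[:, sl])
    return out


def make_gamete(parent: Individual, rng: np.random.Generator) -> Gamete:
    """Sample one gamete from ``parent`` by meiosis with recombination."""
    mat = parent.maternal_gamete.concatenated()[None, :]
    pat = parent.paternal_gamete.concatenated()[None, :]
    sizes = tuple(h.size for h in parent.maternal_gamete.haplotypes)
    gmap_like = getattr(parent, "_gmap", None)
    if gmap_like is None:
        raise ValueError("parent carries no genetic map; attach one or use cohort-level mating")
    row = _meiosis_batch(mat, pat, gmap_like, rng)[0]
    off = np.concatenate([[0], np.cumsum(sizes)])
    return Gamete(tuple(row[off[c] : off[c + 1]] for c in range(len(sizes))))


def attach_map(individual: Individual, gmap: GeneticMap) -> Individual:
    """Attach a genetic map to an individual so it can be used as a parent."""
    if tuple(h.size for h in individual.maternal_gamete.haplotypes) != gmap.loci_per_chromosome:
        raise ValueError("genetic map does not match the individual's loci")
    individual._gmap = gmap  # type: ignore[attr-defined]
    return individual


def mate(
    dam: Individual,
    sire: Individual,
    n_offspring: int,
    sex_assignment: str = "alternating",
    rng: np.random.Generator | None = None,
) -> list[Individual]:
    """Produce offspring of one dam x sire pair.

    Each offspring receives one recombinant gamete from each parent.  The
    ``alternating`` sex policy assigns male, female, male, ... so that an
    even number of offspring splits exactly half and half.
    """
    if dam.sex != FEMALE:
        raise ValueError(f"dam must be female, got sex {dam.sex!r}")
    if sire.sex != MALE:
        raise ValueError(f"sire must be male, got sex {sire.sex!r}")
    if sex_assignment not in ("alternating", "random"):
        raise ValueError(f"unknown sex policy {sex_assignment!r}")
    rng = rng if rng is not None else np.random.default_rng()

    gmap = getattr(dam, "_gmap", None) or getattr(sire, "_gmap", None)
    if gmap is None:
        raise ValueError("attach a genetic map to a parent first (attach_map)")

    dam_mat = np.broadcast_to(dam.maternal_gamete.concatenated(), (n_offspring, gmap.n_loci))
    dam_pat = np.broadcast_to(dam.paternal_gamete.concatenated(), (n_offspring, gmap.n_loci))
    sire_mat = np.broadcast_to(sire.maternal_gamete.concatenated(), (n_offspring, gmap.n_loci))
    sire_pat = np.broadcast_to(sire.paternal_gamete.concatenated(), (n_offspring, gmap.n_loci))
    from_dam = _meiosis_batch(np.ascontiguousarray(dam_mat), np.ascontiguousarray(dam_pat), gmap, rng)
    from_sire = _meiosis_batch(np.ascontiguousarray(sire_mat), np.ascontiguousarray(sire_pat), gmap, rng)

    if sex_assignment == "alternating":
        sexes = [MALE if i % 2 == 0 else FEMALE for i in range(n_offspring)]
    else:
        sexes = [MALE if b else FEMALE for b in rng.integers(0, 2, size=n_offspring)]

    off = gmap.offsets
    out = []
    for i in range(n_offspring):
        split = lambda row: Gamete(
            tuple(row[off[c] : off[c + 1]] for c in range(gmap.n_chromosomes))
        )
        child = Individual(
            id=i,
            sex=sexes[i],
            maternal_gamete=split(from_dam[i]),
            paternal_gamete=split(from_sire[i]),
            generation=dam.generation + 1,
        )
        child._gmap = gmap  # type: ignore[attr-defined]
        out.append(child)
    return out


# ---------------------------------------------------------------------------
# founder sampling
# ---------------------------------------------------------------------------


def sample_founder(
    panel: HaplotypePanel,
    id: int,
    sex: str,
    rng: np.random.Generator,
    generation: int = -22,
) -> Individual:
    """Draw a founder: per chromosome, two panel haplotypes with replacement."""
    if panel.n_haplotypes < 1:
        raise ValueError("empty haplotype panel")
    mat, pat = [], []
    for a in panel.alleles:
        mat.append(a[rng.integers(0, panel.n_haplotypes)].copy())
        pat.append(a[rng.integers(0, panel.n_haplotypes)].copy())
    ind = Individual(
        id=id, sex=sex, maternal_gamete=Gamete(tuple(mat)),
        paternal_gamete=Gamete(tuple(pat)), generation=generation,
    )
    ind._gmap = panel.gmap  # type: ignore[attr-defined]
    return ind


def sample_founder_cohort(
    panel: HaplotypePanel,
    n: int,
    rng: np.random.Generator,
    generation: int = -22,
    id_start: int = 0,
) -> Cohort:
    """Draw a founder cohort with exact alternating half/half sex ratio."""
    if n < 1:
        raise ValueError("cohort size must be positive")
    mat = np.empty((n, panel.n_loci), dtype=np.int8)
    pat = np.empty_like(mat)
    off = panel.gmap.offsets
    for c, a in enumerate(panel.alleles):
        sl = slice(off[c], off[c + 1])
        mat[:, sl] = a[rng.integers(0, panel.n_haplotypes, size=n)]
        pat[:, sl] = a[rng.integers(0, panel.n_haplotypes, size=n)]
    sex = np.where(np.arange(n) % 2 == 0, MALE, FEMALE)
    ids = np.arange(id_start, id_start + n)
    return Cohort(generation, ids, sex, mat, pat, panel.gmap)
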