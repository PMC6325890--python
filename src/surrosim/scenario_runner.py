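"""Experiment orchestration: configuration, replication, and output files.

An experiment runs ``n_replicates`` paired replicates for each nucleus
size and genomic-test accuracy: one nucleus run per replicate, against
which every scenario of the grid is evaluated, so that scenario contrasts
share Monte-Carlo noise.  The ``paper-grid`` preset expands to the full
study map — 3 conventional scenarios, 6 two-stage and 18 three-stage
surrogate-sire scenarios each with 1 or 5 donors, i.e. 51 scenarios per
nucleus size and accuracy (102 per accuracy over both sizes).

Outputs: ``trajectories.csv`` (replicate x scenario x year merit),
``ygg_summary.csv`` (YGG against the conventional top-50 reference),
``manifest.json`` and a plain-text log.  Runs are resumable per
(size, accuracy, replicate) unit and byte-identical on rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _version
from .founder_genomes import generate_base_haplotypes
from .metrics import WINDOW, aggregate, prepare_reference, ygg
from .nucleus_engine import NucleusConfig, run_nucleus
from .strategies import PROGENY_BUDGET, StrategySpec, commercial_trajectory
from .trait_architecture import sample_architecture

logger = logging.getLogger(__name__)

TWO_STAGE_ALLOCATIONS = [(14, 1000), (28, 500), (56, 250), (112, 125), (224, 63), (448, 31)]
THREE_STAGE_S1_BUDGETS = [2000, 4000, 6000]
THREE_STAGE_S1_CANDIDATES = [100, 200, 400]
THREE_STAGE_S2_CANDIDATES = [10, 20]
CONVENTIONAL_N_MALES = [50, 200, 500]
DONOR_COUNTS = [1, 5]

COHORT_SIZES = {"small": 1000, "big": 5000}

PROFILES = {
    "reduced": {"loci_per_chromosome": 200, "n_causal_per_chromosome": 200, "n_replicates": 20},
    "full": {"loci_per_chromosome": 1000, "n_causal_per_chromosome": 1000, "n_replicates": 100},
}


def paper_grid(h2: float = 0.25) -> list[StrategySpec]:
    """The study's scenario map for one nucleus size and accuracy level."""
    specs = [StrategySpec.conventional(n) for n in CONVENTIONAL_N_MALES]
    for donors in DONOR_COUNTS:
        for n_cand, progeny in TWO_STAGE_ALLOCATIONS:
            specs.append(StrategySpec.two_stage(n_cand, progeny, n_donors=donors, h2=h2))
    for donors in DONOR_COUNTS:
        for s1_budget in THREE_STAGE_S1_BUDGETS:
            s2_budget = PROGENY_BUDGET - s1_budget
            for s1_cand in THREE_STAGE_S1_CANDIDATES:
                for s2_cand in THREE_STAGE_S2_CANDIDATES:
                    specs.append(
                        StrategySpec.three_stage(
                            s1_cand,
                            s1_budget // s1_cand,
                            s2_cand,
                            s2_budget // s2_cand,
                            n_donors=donors,
                            h2=h2,
                        )
                    )
    return specs


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce an experiment bit-for-bit."""

    sizes: list[str] = field(default_factory=lambda: ["small"])
    accuracies: list[float] = field(default_factory=lambda: [0.5])
    scenarios: str | list[StrategySpec] = "paper-grid"
    n_replicates: int = 20
    seed: int = 1
    profile: str = "reduced"
    n_haplotypes: int = 400
    n_chromosomes: int = 10
    loci_per_chromosome: int | None = None
    n_causal_per_chromosome: int | None = None
    frequency_model: str = "neutral-sfs"
    h2: float = 0.25
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; choose from {sorted(PROFILES)}")
        prof = PROFILES[self.profile]
        if self.loci_per_chromosome is None:
            self.loci_per_chromosome = prof["loci_per_chromosome"]
        if self.n_causal_per_chromosome is None:
            self.n_causal_per_chromosome = prof["n_causal_per_chromosome"]
        for s in self.sizes:
            if s not in COHORT_SIZES:
                raise ValueError(f"unknown size {s!r}; choose from {sorted(COHORT_SIZES)}")
        if not self.sizes or not self.accuracies:
            raise ValueError("need at least one size and one accuracy")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if not isinstance(self.scenarios, str):
            d["scenarios"] = [s.label() for s in self.scenarios]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def expand_grid(config: ExperimentConfig) -> list[StrategySpec]:
    """Deduplicated, budget-validated scenario list for one size/accuracy."""
    if isinstance(config.scenarios, str):
        if config.scenarios != "paper-grid":
            raise ValueError(f"unknown scenario preset {config.scenarios!r}")
        specs = paper_grid(h2=config.h2)
    else:
        specs = list(config.scenarios)
    if not specs:
        raise ValueError("empty scenario list")
    seen: dict[str, StrategySpec] = {}
    for spec in specs:
        try:
            spec.validate_budget()
        except ValueError as exc:
            raise ValueError(f"budget violation in cell {spec.label()!r}: {exc}") from exc
        seen.setdefault(spec.label(), spec)
    return list(seen.values())


def _rep_rng(seed: int, size_idx: int, acc_idx: int, rep: int, stream: int = 0):
    """Deterministic, collision-free RNG stream for one unit of work."""
    return np.random.default_rng([seed, size_idx, acc_idx, rep, stream])


def run_replicate(
    config: ExperimentConfig,
    size: str,
    accuracy: float,
    rep: int,
    specs: list[StrategySpec],
) -> pd.DataFrame:
    """One replicate: nucleus run plus every scenario's trajectory (paired)."""
    size_idx = sorted(COHORT_SIZES).index(size)
    acc_idx = sorted(set(config.accuracies)).index(accuracy)
    rng = _rep_rng(config.seed, size_idx, acc_idx, rep)

    panel = generate_base_haplotypes(
        config.n_haplotypes,
        config.n_chromosomes,
        config.loci_per_chromosome,
        config.frequency_model,
        seed=rng,
    )
    arch = sample_architecture(panel, config.n_causal_per_chromosome, rng)
    nucleus = run_nucleus(
        NucleusConfig(cohort_size=COHORT_SIZES[size], genomic_accuracy=accuracy),
        panel,
        arch,
        seed=rng,
    )
    frames = []
    for i, spec in enumerate(specs):
        srng = _rep_rng(config.seed, size_idx, acc_idx, rep, stream=i + 1)
        traj = commercial_trajectory(nucleus, spec, srng)
        tab = traj.table.copy()
        tab.insert(0, "scenario", spec.label())
        tab.insert(0, "accuracy", accuracy)
        tab.insert(0, "size", size)
        tab.insert(0, "replicate", rep)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def summarize_ygg(
    trajectories: pd.DataFrame,
    reference: str = "conv50",
    window: tuple[int, int] = WINDOW,
) -> pd.DataFrame:
    """Aggregate per-replicate YGG against the reference scenario."""
    rows = []
    for (size, acc), block in trajectories.groupby(["size", "accuracy"], sort=True):
        per_scenario: dict[str, list[float]] = {}
        for rep, rep_block in block.groupby("replicate", sort=True):
            ref_tab = rep_block[rep_block["scenario"] == reference]
            if ref_tab.empty:
                raise ValueError(f"reference scenario {reference!r} missing from replicate {rep}")
            g = ref_tab["source_generation"]
            ref_win = ref_tab[(g >= window[0]) & (g <= window[1])]
            from .metrics import isotonize

            ref_series = pd.Series(
                isotonize(ref_win["merit_std"].to_numpy()), index=ref_win["year"].to_numpy()
            )
            for scenario, sc_tab in rep_block.groupby("scenario", sort=True):
                g = sc_tab["source_generation"]
                sc_win = sc_tab[(g >= window[0]) & (g <= window[1])]
                test = pd.Series(
                    sc_win["merit_std"].to_numpy(), index=sc_win["year"].to_numpy()
                )
                per_scenario.setdefault(scenario, []).append(ygg(test, ref_series, window))
        for scenario, values in sorted(per_scenario.items()):
            vals = np.asarray(values, dtype=float)
            if vals.size >= 2:
                res = aggregate(vals, scenario_id=scenario, window=window)
                mean, se = res.mean, res.se
            else:
                # single replicate (e.g. a partial, resumable run)
                mean, se = float(vals.mean()), float("nan")
            rows.append(
                {
                    "size": size,
                    "accuracy": acc,
                    "scenario": scenario,
                    "reference": reference,
                    "n_replicates": vals.size,
                    "ygg_mean": mean,
                    "ygg_se": se,
                }
            )
    return pd.DataFrame(rows)


def grid_table(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """The scenario map as a flat table (one row per scenario)."""
    specs = paper_grid() if config is None else expand_grid(config)
    rows = []
    for spec in specs:
        rows.append(
            {
                "scenario": spec.label(),
                "kind": spec.kind,
                "conventional_n_males": spec.conventional_n_males or "",
                "s1_candidates": spec.s1.n_candidates if spec.s1 else "",
                "s1_progeny_per_candidate": spec.s1.progeny_per_candidate if spec.s1 else "",
                "s2_candidates": spec.s2.n_candidates if spec.s2 else "",
                "s2_progeny_per_candidate": spec.s2.progeny_per_candidate if spec.s2 else "",
                "n_donors": spec.n_donors if spec.kind != "conventional" else "",
                "progeny_budget": spec.progeny_budget if spec.kind != "conventional" else "",
                "lag_years": spec.lag_years,
                "dilution": spec.dilution,
            }
        )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run (or resume) a full experiment and write all output files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("surrosim")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    specs = expand_grid(config)
    if not any(s.label() == "conv50" for s in specs):
        specs = [StrategySpec.conventional(50)] + specs
    logger.info(
        "experiment seed=%d profile=%s h2=%g sizes=%s accuracies=%s scenarios=%d",
        config.seed, config.profile, config.h2, config.sizes, config.accuracies, len(specs),
    )

    traj_path = out / "trajectories.csv"
    done: set[tuple[str, float, int]] = set()
    frames: list[pd.DataFrame] = []
    if traj_path.exists():
        prev = pd.read_csv(traj_path)
        frames.append(prev)
        done = {
            (r.size, float(r.accuracy), int(r.replicate))
            for r in prev[["size", "accuracy", "replicate"]].drop_duplicates().itertuples()
        }
        logger.info("resuming: %d completed replicate units found", len(done))

    completed = []
    try:
        for size in config.sizes:
            for accuracy in config.accuracies:
                for rep in range(config.n_replicates):
                    key = (size, float(accuracy), rep)
                    if key in done:
                        continue
                    t0 = time.time()
                    frames.append(run_replicate(config, size, accuracy, rep, specs))
                    completed.append(key)
                    logger.info(
                        "replicate size=%s accuracy=%.2f rep=%d done in %.1fs",
                        size, accuracy, rep, time.time() - t0,
                    )
    finally:
        trajectories = (
            pd.concat(frames, ignore_index=True)
            .sort_values(["size", "accuracy", "replicate", "scenario", "source_generation"])
            .reset_index(drop=True)
        )
        trajectories.to_csv(traj_path, index=False, float_format="%.10g")

        summary = summarize_ygg(trajectories)
        summary.to_csv(out / "ygg_summary.csv", index=False, float_format="%.10g")

        manifest = {
            "package_version": _version,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "root_seed": config.seed,
            "rng_scheme": "default_rng([seed, size_index, accuracy_index, replicate, scenario_stream])",
            "h2": config.h2,
            "lags_years": {"conventional": 3.5, "two_stage": 3.5, "three_stage": 4.5},
            "scenario_count_per_size_accuracy": len(specs),
            "profile": config.profile,
            "reduced": config.profile == "reduced",
            "completed_units": sorted(done | set(completed)),
            "outputs": ["trajectories.csv", "ygg_summary.csv", "run.log"],
            "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        root.removeHandler(handler)
        handler.close()
    return manifest
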