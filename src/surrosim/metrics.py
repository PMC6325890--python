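"""Merit standardisation and years'-worth-of-genetic-gain (YGG) conversion.

A strategy's commercial-sire merit is converted to years by asking when
the reference program — conventional multiplication with the top 50
males — delivers the same merit level: YGG at comparison year t is
t*(merit) - t, where t* inverts the reference trajectory by linear
interpolation (linear extrapolation with the reference's fitted trend
beyond its observed range).  The comparison window covers commercial
sires emerging from source generations 11-20, and YGG is averaged over
that window.  Replicates are paired: every scenario within a replicate is
evaluated against the same nucleus run and the same reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strategies import CommercialTrajectory
from .trait_architecture import BaseScale

WINDOW = (11, 20)


def standardize(series, base_scale: BaseScale):
    """(x - base_mean) / base_sd, elementwise."""
    return (series - base_scale.base_mean) / base_scale.base_sd


def _as_points(traj, window: tuple[int, int]):
    """(years, merits) arrays of a trajectory restricted to the window."""
    if isinstance(traj, CommercialTrajectory):
        tab = traj.window(*window)
        return tab["year"].to_numpy(dtype=float), tab["merit_std"].to_numpy(dtype=float)
    series = pd.Series(traj)
    return series.index.to_numpy(dtype=float), series.to_numpy(dtype=float)


def isotonize(values: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Non-decreasing pool-adjacent-violators fit, made strictly increasing.

    Numerical safeguard for sampled reference trajectories: Monte-Carlo
    noise can produce an occasional downtick that would otherwise break
    the inverse interpolation; pooling adjacent violators perturbs the
    points minimally while preserving their mean.
    """
    v = np.asarray(values, dtype=float).copy()
    # pool adjacent violators
    level = list(v)
    weight = [1.0] * len(level)
    out: list[float] = []
    wts: list[float] = []
    for x in level:
        out.append(x)
        wts.append(1.0)
        while len(out) > 1 and out[-2] > out[-1]:
            w = wts[-2] + wts[-1]
            m = (out[-2] * wts[-2] + out[-1] * wts[-1]) / w
            out[-2:] = [m]
            wts[-2:] = [w]
    fit = np.repeat(out, np.asarray(wts, dtype=int))
    # break ties so the fit is strictly increasing
    return fit + eps * np.arange(fit.size)


def reference_gain_rate(reference, window: tuple[int, int] = WINDOW) -> float:
    """Least-squares slope (merit per year) of the reference over the window."""
    years, merits = _as_points(reference, window)
    if years.size < 2:
        raise ValueError("need at least two reference points to fit a gain rate")
    slope = np.polyfit(years, merits, 1)[0]
    return float(slope)


def invert_reference(
    merit: np.ndarray,
    ref_years: np.ndarray,
    ref_merits: np.ndarray,
    slope: float,
) -> np.ndarray:
    """Year at which the reference attains each merit level.

    Linear interpolation inside the observed merit range; linear
    extrapolation with the fitted ``slope`` beyond either end.
    """
    merit = np.asarray(merit, dtype=float)
    t = np.interp(merit, ref_merits, ref_years)
    above = merit > ref_merits[-1]
    below = merit < ref_merits[0]
    t = np.where(above, ref_years[-1] + (merit - ref_merits[-1]) / slope, t)
    t = np.where(below, ref_years[0] + (merit - ref_merits[0]) / slope, t)
    return t


def ygg(test_trajectory, reference_trajectory, window: tuple[int, int] = WINDOW) -> float:
    """Mean years'-worth-of-genetic-gain of a trajectory over the reference.

    For each comparison year t of the test trajectory in the window, the
    reference is inverted to the year t* at which it attains the test's
    merit; YGG = mean(t* - t).  The reference must be strictly increasing
    over its fitted range (isotonize first if it carries sampling noise).
    """
    ref_years, ref_merits = _as_points(reference_trajectory, window)
    if np.any(np.diff(ref_merits) <= 0):
        raise ValueError("reference trajectory is not strictly increasing over the window")
    if np.any(np.diff(ref_years) <= 0):
        raise ValueError("reference years must be increasing")
    slope = np.polyfit(ref_years, ref_merits, 1)[0]
    if slope <= 0:
        raise ValueError("reference trajectory has non-positive fitted gain rate")

    test_years, test_merits = _as_points(test_trajectory, window)
    if test_years.size == 0:
        raise ValueError("test trajectory has no points in the comparison window")
    t_star = invert_reference(test_merits, ref_years, ref_merits, slope)
    return float(np.mean(t_star - test_years))


def ygg_advantage(test_trajectory, other_trajectory, reference_trajectory,
                  window: tuple[int, int] = WINDOW) -> float:
    """YGG lead of one strategy over another on the reference time axis."""
    return ygg(test_trajectory, reference_trajectory, window) - ygg(
        other_trajectory, reference_trajectory, window
    )


def prepare_reference(traj: CommercialTrajectory, window: tuple[int, int] = WINDOW) -> pd.Series:
    """Isotonized window points of a sampled reference, as a year-indexed series."""
    years, merits = _as_points(traj, window)
    return pd.Series(isotonize(merits), index=years)


@dataclass
class YGGResult:
    """Replicate-level YGG values and their aggregate for one scenario."""

    scenario_id: str
    values: np.ndarray
    mean: float
    se: float
    window: tuple[int, int] = WINDOW

    @property
    def n_replicates(self) -> int:
        return self.values.size


def aggregate(replicate_values, scenario_id: str = "", window: tuple[int, int] = WINDOW) -> YGGResult:
    """Mean and standard error of per-replicate YGG values."""
    values = np.asarray(list(replicate_values), dtype=float)
    if values.size < 2:
        raise ValueError("need at least two replicates to aggregate")
    return YGGResult(
        scenario_id=scenario_id,
        values=values,
        mean=float(values.mean()),
        se=float(values.std(ddof=1) / np.sqrt(values.size)),
        window=window,
    )


@dataclass
class ReplicateSet:
    """Paired per-replicate trajectories sharing a nucleus run per replicate."""

    seeds: list[int]
    trajectories: dict[tuple[str, int], CommercialTrajectory] = field(default_factory=dict)

    def add(self, scenario_id: str, replicate: int, traj: CommercialTrajectory) -> None:
        self.trajectories[(scenario_id, replicate)] = traj

    def scenario_ids(self) -> list[str]:
        return sorted({k[0] for k in self.trajectories})

    def ygg_table(self, reference_id: str, window: tuple[int, int] = WINDOW) -> pd.DataFrame:
        """Per-replicate YGG of every scenario against the named reference."""
        rows = []
        for rep, _ in enumerate(self.seeds):
            ref = self.trajectories.get((reference_id, rep))
            if ref is None:
                continue
            ref_series = prepare_reference(ref, window)
            for sid in self.scenario_ids():
                traj = self.trajectories.get((sid, rep))
                if traj is None:
                    continue
                rows.append(
                    {"scenario": sid, "replicate": rep, "ygg": ygg(traj, ref_series, window)}
                )
        return pd.DataFrame(rows)
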