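"""Exhaustive grid-search optimization of the Xi observer.

The corrected m-Tau observer has eight free parameters: the leakage mu,
the correction weight w, the two filter memories xi_theta and
xi_theta_dot, the offset kappa, the two noise levels p_theta and
p_theta_dot, and the averaging-window length n_avg.  The parameter space
is parsed with constant step widths; for every cell the observer's
proportion-of-later curves are simulated and compared against the
observed curves with two score measures, an unweighted root-mean-square
error (rmse) and an outlier-insensitive robust error (robe, by default
the median absolute residual).  Scores are sorted ascending and the best
set is assigned rank one.  A combined ranking averages the two sizes'
scores per parameter set, which naturally trades off against either
individual fit.  Monte-Carlo noise is common-random-number seeded across
cells, so ranking differences reflect the parameters, not the draws.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .functions import XiParams
from .noise import NoiseSpec
from .psychophysics import (
    ExperimentDesign,
    PsychometricPoint,
    TrialConfig,
    proportion_later,
)

__all__ = [
    "GridSpec",
    "ScoreEntry",
    "score_rmse",
    "score_robe",
    "grid_search",
    "combine_rank",
    "median_noise_by_rank",
]

#: Canonical searched-parameter order (deterministic enumeration).
PARAM_ORDER = (
    "mu",
    "w",
    "xi_theta",
    "xi_theta_dot",
    "kappa",
    "p_theta",
    "p_theta_dot",
    "n_avg",
)


@dataclass(frozen=True)
class GridSpec:
    """Per-parameter value lists, built from constant-step ranges.

    Parameters not listed stay at their base values; the grid is
    enumerated lexicographically in the canonical parameter order so that
    tie-breaks are reproducible.
    """

    values: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("empty grid")
        for name, vals in self.values.items():
            if name not in PARAM_ORDER:
                raise ValueError(f"unknown parameter {name!r}")
            if len(vals) == 0:
                raise ValueError(f"empty level list for {name!r}")

    @classmethod
    def from_ranges(cls, ranges: Mapping[str, tuple[float, float, float]]) -> "GridSpec":
        """Build from {name: (min, max, step)} with constant step widths."""
        values = {}
        for name, (lo, hi, step) in ranges.items():
            if step <= 0 or lo > hi:
                raise ValueError(f"invalid range for {name!r}")
            n = int(math.floor((hi - lo) / step + 1e-9)) + 1
            values[name] = tuple(lo + step * i for i in range(n))
        return cls(values)

    def cells(self) -> list[dict[str, float]]:
        """All grid cells in deterministic lexicographic order."""
        names = [n for n in PARAM_ORDER if n in self.values]
        combos = itertools.product(*(self.values[n] for n in names))
        return [dict(zip(names, combo)) for combo in combos]


@dataclass
class ScoreEntry:
    """One scored parameter set within a ranked table."""

    params: dict[str, float]
    rmse: float
    robe: float
    rank_rmse: int = 0
    rank_robe: int = 0
    size_label: str = ""
    order_index: int = field(default=0, repr=False)


def score_rmse(pred, obs) -> float:
    """Unweighted root mean square error between proportion curves."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def score_robe(pred, obs, kind: str = "median") -> float:
    """Outlier-insensitive robust error over absolute residuals.

    kind: 'median' (default, median absolute residual), 'mean_abs', or
    'trimmed' (20%-trimmed mean of absolute residuals).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    r = np.abs(pred - obs)
    if kind == "median":
        return float(np.median(r))
    if kind == "mean_abs":
        return float(np.mean(r))
    if kind == "trimmed":
        from scipy.stats import trim_mean

        return float(trim_mean(r, 0.2))
    raise ValueError(f"unknown robust aggregate {kind!r}")


def _apply_cell(
    cell: Mapping[str, float],
    base_params: XiParams,
    base_noise: NoiseSpec,
    base_cfg: TrialConfig,
) -> tuple[XiParams, NoiseSpec, TrialConfig]:
    xi_kw = {k: v for k, v in cell.items() if k in ("mu", "w", "xi_theta", "xi_theta_dot", "kappa")}
    nz_kw = {k: v for k, v in cell.items() if k in ("p_theta", "p_theta_dot")}
    params = replace(base_params, **xi_kw) if xi_kw else base_params
    noise = replace(base_noise, **nz_kw) if nz_kw else base_noise
    cfg = replace(base_cfg, n_avg=int(cell["n_avg"])) if "n_avg" in cell else base_cfg
    return params, noise, cfg


def _obs_lookup(obs: Sequence[PsychometricPoint]) -> dict[tuple[float, float], float]:
    return {(round(p.ttc, 9), round(p.presentation_time, 9)): p.proportion_later for p in obs}


def _curves_for_size(
    points: Sequence[PsychometricPoint], size_label: str
) -> dict[tuple[float, float], float]:
    return _obs_lookup([p for p in points if p.size_label == size_label])


def _rank_table(entries: list[ScoreEntry]) -> None:
    """Assign ascending ranks per score, ties broken by enumeration order."""
    for attr, rank_attr in (("rmse", "rank_rmse"), ("robe", "rank_robe")):
        order = sorted(entries, key=lambda e: (getattr(e, attr), e.order_index))
        for rank, e in enumerate(order, start=1):
            setattr(e, rank_attr, rank)


def grid_search(
    design: ExperimentDesign,
    obs_small: Sequence[PsychometricPoint],
    obs_big: Sequence[PsychometricPoint],
    grid: GridSpec,
    cfg: TrialConfig,
    base_params: XiParams = XiParams(),
    base_noise: NoiseSpec = NoiseSpec(),
    dt: float = 1e-3,
    robe_kind: str = "median",
) -> tuple[list[ScoreEntry], list[ScoreEntry]]:
    """Score every grid cell against the small- and big-size observations.

    Returns one ranked table per size.  The same noise seed (and hence
    the same underlying Gaussian deviates) is used in every cell.
    Non-finite scores are excluded with a warning.
    """
    cells = grid.cells()
    if not cells:
        raise ValueError("empty grid")
    look_small = _obs_lookup(obs_small)
    look_big = _obs_lookup(obs_big)
    table_small: list[ScoreEntry] = []
    table_big: list[ScoreEntry] = []
    for idx, cell in enumerate(cells):
        params, noise, cfg_c = _apply_cell(cell, base_params, base_noise, cfg)
        points = proportion_later(design, params, noise, cfg_c, dt=dt)
        for look, table, label in (
            (look_small, table_small, "small"),
            (look_big, table_big, "big"),
        ):
            pred_map = _curves_for_size(points, label)
            keys = sorted(look)
            missing = [k for k in keys if k not in pred_map]
            if missing:
                raise ValueError(f"design does not cover observed conditions {missing[:3]}")
            pred = [pred_map[k] for k in keys]
            obs = [look[k] for k in keys]
            rmse = score_rmse(pred, obs)
            robe = score_robe(pred, obs, kind=robe_kind)
            if not (math.isfinite(rmse) and math.isfinite(robe)):
                warnings.warn(f"non-finite score for cell {cell}; excluded")
                continue
            table.append(
                ScoreEntry(params=dict(cell), rmse=rmse, robe=robe, size_label=label, order_index=idx)
            )
    _rank_table(table_small)
    _rank_table(table_big)
    return table_small, table_big


def combine_rank(
    table_small: Sequence[ScoreEntry], table_big: Sequence[ScoreEntry]
) -> list[ScoreEntry]:
    """Average the two sizes' scores per parameter set and re-rank."""
    def key(e: ScoreEntry):
        return tuple(sorted(e.params.items()))

    big_by_key = {key(e): e for e in table_big}
    combined = []
    for e in table_small:
        k = key(e)
        if k not in big_by_key:
            raise ValueError("tables are not indexed by the same parameter sets")
        b = big_by_key[k]
        combined.append(
            ScoreEntry(
                params=dict(e.params),
                rmse=0.5 * (e.rmse + b.rmse),
                robe=0.5 * (e.robe + b.robe),
                size_label="combined",
                order_index=e.order_index,
            )
        )
    _rank_table(combined)
    return combined


def median_noise_by_rank(
    table: Sequence[ScoreEntry],
    k_values: Sequence[int],
    by: str = "rank_rmse",
) -> list[dict[str, float]]:
    """Median noise levels over the top-k ranked parameter sets.

    For each k, reports the median of p_theta and p_theta_dot across
    ranks 1..k together with a robust spread (median absolute deviation
    scaled by 1.4826 for normal consistency).
    """
    if not table:
        raise ValueError("empty table")
    ranked = sorted(table, key=lambda e: getattr(e, by))
    out = []
    for k in k_values:
        if not 1 <= k <= len(ranked):
            raise ValueError(f"k={k} outside 1..{len(ranked)}")
        top = ranked[:k]
        row: dict[str, float] = {"k": float(k)}
        for name in ("p_theta", "p_theta_dot"):
            vals = np.array([e.params.get(name, np.nan) for e in top], dtype=float)
            med = float(np.median(vals))
            mad = float(1.4826 * np.median(np.abs(vals - med)))
            row[f"median_{name}"] = med
            row[f"mad_{name}"] = mad
        out.append(row)
    return out
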