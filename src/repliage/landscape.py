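"""Fate maps and lifespan-prolonging strategies over the (k1, k2) plane.

The starvation bound confines viable rate parameters to k1 + k2 < g, so the
relevant plane is [0, g]^2.  ``scan`` classifies every grid point into one of
the four fates (starvation, immortality, ageing, clonal senescence) and
records the replicative lifespan of ageing cells; ``strategy_comparison``
asks, for each ageing cell, whether lowering damage formation (k1) or raising
repair (k2) by a relative step buys more lifespan.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lifespan import Fate, SimulationCaps, simulate_lineage
from .params import DivisionParameters, RateParameters

__all__ = [
    "LandscapeResult",
    "scan",
    "strategy_comparison",
    "compare_landscapes",
    "write_landscape",
    "read_landscape",
]

#: Strategy labels for ageing cells.
DOWN_K1 = "down_k1"
UP_K2 = "up_k2"
NEUTRAL = "neutral"


@dataclass
class LandscapeResult:
    """Grid over the (k1, k2) plane with per-cell fate, RLS and strategy.

    ``rls`` is -1 wherever the fate is not ageing; ``strategy`` is empty
    until :func:`strategy_comparison` fills it for ageing cells.
    """

    k1_grid: np.ndarray
    k2_grid: np.ndarray
    fate: np.ndarray  # dtype object of Fate values, shape (N, N)
    rls: np.ndarray  # int, -1 where undefined
    strategy: np.ndarray  # dtype object, '' where undefined
    meta: dict

    def mask(self, fate: Fate) -> np.ndarray:
        """Boolean grid mask of the cells with the given fate.

        (numpy coerces a str-backed enum to a plain string in elementwise
        comparisons, so ``self.fate == fate`` cannot be used directly.)
        """
        return np.frompyfunc(lambda f: f is fate, 1, 1)(self.fate).astype(bool)

    def fate_counts(self) -> dict[str, int]:
        counts = {f.value: 0 for f in Fate}
        values, n = np.unique(
            np.vectorize(lambda f: f.value)(self.fate), return_counts=True
        )
        counts.update(dict(zip(values.tolist(), n.tolist())))
        return counts

    def strategy_fractions(self) -> dict[str, float]:
        """Fractions of each strategy label over the ageing cells."""
        ageing = self.mask(Fate.AGEING)
        n = int(ageing.sum())
        if n == 0:
            return {DOWN_K1: math.nan, UP_K2: math.nan, NEUTRAL: math.nan}
        labels = self.strategy[ageing]
        return {
            lab: float(np.sum(labels == lab)) / n
            for lab in (DOWN_K1, UP_K2, NEUTRAL)
        }


def scan(
    g: float,
    Q: float,
    div: DivisionParameters,
    N: int = 50,
    caps: SimulationCaps = SimulationCaps(),
) -> LandscapeResult:
    """Classify every cell of the N x N grid over [0, g]^2.

    Grid values are i * g / N for i = 0..N-1 (spacing g/N, including the
    k = 0 axes).  Points with k1 + k2 >= g are starvation and the k1 = 0
    column is immortal, both assigned analytically; the rest are simulated
    from a damage-free daughter (1 - s, 0).  The scan is deterministic.
    """
    if N < 2:
        raise ValueError("mesh count N must be at least 2")
    grid = np.arange(N) * (g / N)
    fate = np.empty((N, N), dtype=object)
    rls = np.full((N, N), -1, dtype=int)
    n_censored = 0
    for i, k1 in enumerate(grid):
        for j, k2 in enumerate(grid):
            if k1 + k2 >= g:
                fate[i, j] = Fate.STARVATION
                continue
            if k1 == 0:
                fate[i, j] = Fate.IMMORTALITY
                continue
            rate = RateParameters(g=g, k1=float(k1), k2=float(k2), Q=Q)
            history = simulate_lineage(rate, div, caps=caps)
            fate[i, j] = history.fate
            if history.fate == Fate.AGEING:
                rls[i, j] = history.rls
            elif history.fate == Fate.CENSORED:
                n_censored += 1
    meta = {
        "g": g, "Q": Q, "s": div.s, "re": div.re, "N": N,
        "delta": None, "caps": dataclasses.asdict(caps),
        "n_censored": n_censored, "seed": None,
    }
    return LandscapeResult(
        k1_grid=grid, k2_grid=grid.copy(), fate=fate, rls=rls,
        strategy=np.full((N, N), "", dtype=object), meta=meta,
    )


def _rls_of(rate: RateParameters, div: DivisionParameters,
            caps: SimulationCaps) -> float:
    """RLS of a perturbed parameter point, as a float supporting infinity.

    Immortal and censored cells count as infinite lifespan (flagged by the
    caller); starving cells cannot grow and count as zero.
    """
    if rate.k1 + rate.k2 >= rate.g:
        return 0.0
    if rate.k1 == 0:
        return math.inf
    history = simulate_lineage(rate, div, caps=caps)
    if history.fate == Fate.AGEING:
        return float(history.rls)
    if history.fate == Fate.CLONAL_SENESCENCE:
        return 0.0
    return math.inf  # immortal or censored


def strategy_comparison(
    result: LandscapeResult,
    delta: float = 0.05,
    caps: SimulationCaps = SimulationCaps(),
    relative: bool = True,
) -> dict[str, float]:
    """Label each ageing cell by its better lifespan-prolonging strategy.

    For every ageing grid cell the lifespan gains
    dRLS_k1 = RLS(k1 - d_k1, k2) - RLS(k1, k2) and
    dRLS_k2 = RLS(k1, k2 + d_k2) - RLS(k1, k2) are compared, with
    d_k1 = delta * k1 and d_k2 = delta * k2 (multiplicative steps; set
    ``relative=False`` for absolute steps of size delta).  The cell is
    labelled ``down_k1`` when lowering damage formation gains more,
    ``up_k2`` when raising repair does, ``neutral`` on exact (integer)
    equality.  Perturbations landing on immortality count as an infinite
    gain.  Fills ``result.strategy`` in place and returns the label
    fractions over ageing cells.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    g, Q = result.meta["g"], result.meta["Q"]
    div = DivisionParameters(s=result.meta["s"], re=result.meta["re"])
    n_inf = 0
    for i, k1 in enumerate(result.k1_grid):
        for j, k2 in enumerate(result.k2_grid):
            if result.fate[i, j] != Fate.AGEING:
                continue
            base = float(result.rls[i, j])
            d_k1 = delta * k1 if relative else delta
            d_k2 = delta * k2 if relative else delta
            gain_k1 = _rls_of(
                RateParameters(g=g, k1=max(k1 - d_k1, 0.0), k2=k2, Q=Q),
                div, caps) - base
            gain_k2 = _rls_of(
                RateParameters(g=g, k1=k1, k2=k2 + d_k2, Q=Q),
                div, caps) - base
            if math.isinf(gain_k1) or math.isinf(gain_k2):
                n_inf += 1
            if gain_k1 > gain_k2:
                result.strategy[i, j] = DOWN_K1
            elif gain_k1 < gain_k2:
                result.strategy[i, j] = UP_K2
            else:
                result.strategy[i, j] = NEUTRAL
    result.meta["delta"] = delta
    result.meta["n_perturbed_immortal"] = n_inf
    return result.strategy_fractions()


def compare_landscapes(a: LandscapeResult, b: LandscapeResult) -> dict:
    """Per-fate cell counts of two scans on identical grids, with deltas.

    Compares RLS two ways: per cell over the cells ageing in both scans
    (``rls_higher_a`` / ``rls_higher_b`` / ``rls_equal``), and per region
    via the maximum and mean RLS over each scan's own ageing cells
    (``rls_max_a`` etc.).  The two views can disagree: a larger mother size
    share retains more damage and weakly shortens life at any common
    parameter point, yet shifts the ageing region toward the immortality
    boundary where far higher lifespans are attainable.
    """
    if a.k1_grid.shape != b.k1_grid.shape or not (
        np.allclose(a.k1_grid, b.k1_grid) and np.allclose(a.k2_grid, b.k2_grid)
    ):
        raise ValueError("landscapes have incompatible grids")
    if a.meta["g"] != b.meta["g"]:
        raise ValueError("landscapes use different growth factors")
    counts_a = a.fate_counts()
    counts_b = b.fate_counts()
    both_ageing = a.mask(Fate.AGEING) & b.mask(Fate.AGEING)
    rls_a = a.rls[both_ageing]
    rls_b = b.rls[both_ageing]
    own_a = a.rls[a.mask(Fate.AGEING)]
    own_b = b.rls[b.mask(Fate.AGEING)]
    return {
        "counts_a": counts_a,
        "counts_b": counts_b,
        "delta": {k: counts_a[k] - counts_b[k] for k in counts_a},
        "n_common_ageing": int(both_ageing.sum()),
        "rls_higher_a": int(np.sum(rls_a > rls_b)),
        "rls_higher_b": int(np.sum(rls_a < rls_b)),
        "rls_equal": int(np.sum(rls_a == rls_b)),
        "rls_max_a": int(own_a.max()) if own_a.size else 0,
        "rls_max_b": int(own_b.max()) if own_b.size else 0,
        "rls_mean_a": float(own_a.mean()) if own_a.size else math.nan,
        "rls_mean_b": float(own_b.mean()) if own_b.size else math.nan,
    }


def to_frame(result: LandscapeResult) -> pd.DataFrame:
    """Flatten a landscape to one grid cell per row."""
    k1_idx, k2_idx = np.meshgrid(
        np.arange(len(result.k1_grid)), np.arange(len(result.k2_grid)),
        indexing="ij",
    )
    return pd.DataFrame(
        {
            "k1": result.k1_grid[k1_idx.ravel()],
            "k2": result.k2_grid[k2_idx.ravel()],
            "fate": [f.value for f in result.fate.ravel()],
            "rls": result.rls.ravel(),
            "strategy": result.strategy.ravel(),
        }
    )


def write_landscape(result: LandscapeResult, path: str | Path) -> None:
    """Write a landscape as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    to_frame(result).to_csv(path, index=False)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(result.meta, indent=2, default=str)
    )


def read_landscape(path: str | Path) -> LandscapeResult:
    """Read a landscape written by :func:`write_landscape`."""
    path = Path(path)
    frame = pd.read_csv(path, keep_default_na=False)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    N = meta["N"]
    fate = np.array(
        [Fate(v) for v in frame["fate"]], dtype=object
    ).reshape(N, N)
    strategy = np.array(frame["strategy"], dtype=object).reshape(N, N)
    return LandscapeResult(
        k1_grid=frame["k1"].to_numpy().reshape(N, N)[:, 0],
        k2_grid=frame["k2"].to_numpy().reshape(N, N)[0, :],
        fate=fate,
        rls=frame["rls"].to_numpy().reshape(N, N),
        strategy=strategy,
        meta=meta,
    )
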