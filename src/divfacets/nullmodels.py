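"""Fixed-margin null communities (Curveball) and standardized effect sizes.

The Curveball algorithm randomizes a binary presence/absence matrix by
repeated "trades" between random pairs of species: the columns held by
exactly one of the two species are pooled and redealt at random, which
preserves every row sum (species occupancy) and column sum (cell richness)
exactly.  Each null replicate is an independent chain started from the
observed matrix.  The standardized effect size of a metric in a cell is

    SES = (obs - mean_null) / sd_null

with the sample (n-1) SD over replicates; |SES| > 1.96 flags over- or
under-dispersion.  Because the null preserves richness, any metric that is
a function of column sums alone has sd_null = 0 and an undefined SES.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .assembly import PresenceMatrix

#: metric evaluator: binary (S, C) array -> per-cell float vector
MetricFn = Callable[[np.ndarray], np.ndarray]


def default_trades(n_species: int) -> int:
    """Default chain length: 5 trades per species, floor of 1000."""
    return max(5 * n_species, 1000)


def _trade_inplace(data: np.ndarray, rng: np.random.Generator) -> None:
    i, j = rng.choice(data.shape[0], size=2, replace=False)
    a, b = data[i], data[j]
    only_a = np.flatnonzero((a == 1) & (b == 0))
    only_b = np.flatnonzero((a == 0) & (b == 1))
    if only_a.size == 0 or only_b.size == 0:
        return
    pool = np.concatenate([only_a, only_b])
    rng.shuffle(pool)
    a[pool] = 0
    b[pool] = 0
    a[pool[: only_a.size]] = 1
    b[pool[only_a.size :]] = 1


def curveball_trade(matrix: PresenceMatrix, rng: np.random.Generator) -> PresenceMatrix:
    """One Curveball trade; returns a new matrix with identical margins."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 species (rows) to trade")
    out = matrix.copy()
    _trade_inplace(out.data, rng)
    return out


def randomize(
    data: np.ndarray, n_trades: int, rng: np.random.Generator
) -> np.ndarray:
    """Apply ``n_trades`` Curveball trades to a copy of a binary array."""
    out = data.copy()
    for _ in range(n_trades):
        _trade_inplace(out, rng)
    return out


@dataclass
class NullEnsemble:
    """Per-replicate metric values for a set of null communities."""

    n_reps: int
    trades_per_rep: int
    seed: int
    cells: np.ndarray
    metrics: dict[str, np.ndarray]  # name -> (n_reps, n_cells)

    def to_json_meta(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "trades_per_rep": self.trades_per_rep,
            "seed": self.seed,
            "metrics": sorted(self.metrics),
        }


def generate_nulls(
    matrix: PresenceMatrix,
    metrics: dict[str, MetricFn],
    n_reps: int = 999,
    trades_per_rep: int | None = None,
    seed: int = 0,
    checkpoint: Path | None = None,
    checkpoint_every: int = 100,
    check_margins: bool = False,
) -> NullEnsemble:
    """Evaluate metrics on ``n_reps`` independent Curveball null matrices.

    Each replicate applies ``trades_per_rep`` trades (default
    ``max(5 * n_species, 1000)``) to a fresh copy of the observed matrix
    using a replicate-specific child seed, so replicates are reproducible
    and order-independent.  With ``checkpoint`` set, partial results are
    saved every ``checkpoint_every`` replicates and reloaded on restart.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if trades_per_rep is None:
        trades_per_rep = default_trades(matrix.shape[0])
    if trades_per_rep < 0:
        raise ValueError("trades_per_rep must be >= 0")

    n_cells = matrix.shape[1]
    values = {name: np.full((n_reps, n_cells), np.nan) for name in metrics}
    start = 0
    if checkpoint is not None and Path(checkpoint).exists():
        saved = np.load(checkpoint)
        if (
            int(saved["n_reps"]) == n_reps
            and int(saved["trades_per_rep"]) == trades_per_rep
            and int(saved["seed"]) == seed
            and sorted(saved["names"].tolist()) == sorted(metrics)
        ):
            start = int(saved["done"])
            for name in metrics:
                values[name][:start] = saved[f"metric_{name}"][:start]

    row_sums = matrix.data.sum(axis=1)
    col_sums = matrix.data.sum(axis=0)
    for rep in range(start, n_reps):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 7919, rep)))
        null = randomize(matrix.data, trades_per_rep, rng)
        if check_margins:
            assert np.array_equal(null.sum(axis=1), row_sums)
            assert np.array_equal(null.sum(axis=0), col_sums)
        for name, fn in metrics.items():
            values[name][rep] = fn(null)
        if checkpoint is not None and (rep + 1) % checkpoint_every == 0:
            _save_checkpoint(checkpoint, n_reps, trades_per_rep, seed, rep + 1, values)
    if checkpoint is not None:
        _save_checkpoint(checkpoint, n_reps, trades_per_rep, seed, n_reps, values)
    return NullEnsemble(
        n_reps=n_reps,
        trades_per_rep=trades_per_rep,
        seed=seed,
        cells=matrix.cells.copy(),
        metrics=values,
    )


def _save_checkpoint(path, n_reps, trades, seed, done, values) -> None:
    np.savez(
        path,
        n_reps=n_reps,
        trades_per_rep=trades,
        seed=seed,
        done=done,
        names=np.array(sorted(values)),
        **{f"metric_{k}": v for k, v in values.items()},
    )


@dataclass
class SESResult:
    """Per-cell standardized effect sizes and dispersion classes."""

    table: pd.DataFrame  # cell_id, obs, mean_null, sd_null, ses, dispersion
    threshold: float = 1.96

    @property
    def counts(self) -> dict[str, int]:
        return self.table["dispersion"].value_counts().to_dict()

    @property
    def fractions(self) -> dict[str, float]:
        defined = (self.table["dispersion"] != "undefined").sum()
        if defined == 0:
            return {}
        counts = self.table.loc[
            self.table["dispersion"] != "undefined", "dispersion"
        ].value_counts()
        return {k: v / defined for k, v in counts.items()}

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def compute_ses(
    obs: np.ndarray,
    null_values: np.ndarray,
    cells: np.ndarray | None = None,
    threshold: float = 1.96,
) -> SESResult:
    """Standardized effect sizes of an observed per-cell metric.

    ``null_values`` is (n_reps, n_cells).  SES is undefined (NaN, class
    "undefined") where the observed metric is NaN or the null SD is zero;
    the observed value is never pooled into the null distribution.
    """
    obs = np.asarray(obs, dtype=float)
    null_values = np.asarray(null_values, dtype=float)
    if null_values.ndim != 2 or null_values.shape[1] != obs.shape[0]:
        raise ValueError("null_values must be (n_reps, n_cells) matching obs")
    if cells is None:
        cells = np.arange(obs.shape[0])

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # all-NaN null columns (undefined metric) legitimately yield NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_null = np.nanmean(null_values, axis=0)
        sd_null = np.nanstd(null_values, axis=0, ddof=1)
    ses = np.full_like(obs, np.nan)
    ok = np.isfinite(obs) & np.isfinite(sd_null) & (sd_null > 0)
    ses[ok] = (obs[ok] - mean_null[ok]) / sd_null[ok]

    cls = np.where(
        ~np.isfinite(ses),
        "undefined",
        np.where(ses > threshold, "overdispersed",
                 np.where(ses < -threshold, "underdispersed", "neither")),
    )
    table = pd.DataFrame(
        {
            "cell_id": cells,
            "obs": obs,
            "mean_null": mean_null,
            "sd_null": sd_null,
            "ses": ses,
            "dispersion": cls,
        }
    )
    return SESResult(table=table, threshold=threshold)
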