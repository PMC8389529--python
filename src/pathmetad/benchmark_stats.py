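"""Benchmark statistics for computed-vs-experimental binding free energies.

Two reference tables ship with the package: the six cucurbit[8]uril
host-guest complexes ("cb8") and the eight ATP-competitive GSK-3β
inhibitors ("gsk3b"), each with the computed dG_b, the standard-state
correction dG_V, the standard binding free energy dG°_b and the
experimental reference (kcal/mol).  The same metrics apply to any user
table with ``dg_standard`` and ``dg_exp`` columns.

Conventions: mean error is experimental minus computed (positive = computed
overbinds); ranks are by ascending dG°_b (most negative = rank 1), ties
broken by row order with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

TABLE_FILES = {
    "cb8": "table_cb8.csv",
    "gsk3b": "table_gsk3b.csv",
    # aliases by table position in the benchmark write-up
    "table1": "table_cb8.csv",
    "table3": "table_gsk3b.csv",
}


@dataclass
class CorrelationStats:
    pearson: float
    spearman: float
    rmse: float  # kcal/mol
    mean_error: float  # kcal/mol, experimental - computed

    def rounded(self) -> tuple[float, float, float, float]:
        from .units import round_half_away
        return (round_half_away(self.pearson, 2),
                round_half_away(self.spearman, 1),
                round_half_away(self.rmse, 1),
                round_half_away(self.mean_error, 1))


def load_table(name_or_path: str) -> pd.DataFrame:
    """Load a packaged benchmark table by name, or any CSV by path."""
    if name_or_path in TABLE_FILES:
        ref = resources.files("pathmetad.data") / TABLE_FILES[name_or_path]
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(name_or_path)
    if not {"dg_standard", "dg_exp"}.issubset(df.columns):
        raise ValueError("table needs dg_standard and dg_exp columns")
    return df


def correlation_stats(table: pd.DataFrame) -> CorrelationStats:
    """Pearson, Spearman, RMSE and mean error of computed vs experimental."""
    comp = np.asarray(table["dg_standard"], dtype=float)
    exp = np.asarray(table["dg_exp"], dtype=float)
    if len(comp) != len(exp):
        raise ValueError("length mismatch")
    if len(comp) < 3:
        raise ValueError("need at least three pairs")
    if comp.std() == 0 or exp.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    pearson = float(stats.pearsonr(comp, exp)[0])
    spearman = float(stats.spearmanr(comp, exp)[0])
    rmse = float(np.sqrt(np.mean((comp - exp) ** 2)))
    mean_error = float(np.mean(exp - comp))
    return CorrelationStats(pearson, spearman, rmse, mean_error)


def bootstrap_pearson(table: pd.DataFrame, n_resamples: int = 10_000,
                      seed: int = 0) -> tuple[float, float, float]:
    """Bootstrap the Pearson correlation by resampling pairs.

    Degenerate resamples (a constant vector, non-negligible at n = 6) are
    redrawn.  Returns (mean of replicates, standard error of the bootstrap
    mean = replicate std / sqrt(n_resamples), replicate std).  Which of the
    last two the benchmark write-ups quote as "bootstrap standard error" is
    ambiguous, so both are reported.
    """
    comp = np.asarray(table["dg_standard"], dtype=float)
    exp = np.asarray(table["dg_exp"], dtype=float)
    n = len(comp)
    if n < 3:
        raise ValueError("need at least three pairs")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_resamples)
    filled = 0
    while filled < n_resamples:
        idx = rng.integers(0, n, n)
        c, e = comp[idx], exp[idx]
        if c.std() == 0 or e.std() == 0:
            continue
        reps[filled] = stats.pearsonr(c, e)[0]
        filled += 1
    rep_std = float(reps.std(ddof=1))
    return float(reps.mean()), rep_std / np.sqrt(n_resamples), rep_std


def rank_consistency(table: pd.DataFrame) -> pd.DataFrame:
    """Ranks by ascending dG°_b, computed and experimental.

    Most negative (strongest binder) gets rank 1.  Exact ties are broken by
    row order (first row wins) with a warning, which reproduces the printed
    rank columns of the packaged tables.
    """
    out = pd.DataFrame({"id": table.get("id", pd.RangeIndex(len(table)))})
    for col, name in (("dg_standard", "rank_comp"), ("dg_exp", "rank_exp")):
        vals = np.asarray(table[col], dtype=float)
        if len(np.unique(vals)) != len(vals):
            warnings.warn(f"ties in {col}; ranks broken by row order",
                          stacklevel=2)
        out[name] = stats.rankdata(vals, method="ordinal").astype(int)
    return out
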