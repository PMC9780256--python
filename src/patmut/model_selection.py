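"""Hyperparameter fitting by repeated 2-fold cross-validation.

Count tables are split by multivariate hypergeometric sampling: half of
the mutated events and, independently, half of the unmutated events are
allocated to fold 1 without replacement, the rest to fold 2, so the two
folds always sum back to the original table.  For each (alpha, c) grid
point a partition is trained on each fold and scored by the negative
binomial log-likelihood of the opposite fold under the trained rates;
the pair with the lowest mean out-of-sample NLL wins (ties go to the
stronger regularization: larger c, then larger alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import log_likelihood
from .kmer_counting import KmerCountTable
from .pattern_partition import Hyperparams, greedy_partition, optimal_partition

DEFAULT_ALPHA_GRID = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)
DEFAULT_C_GRID = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)


@dataclass
class CVConfig:
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_repeats: int = 5
    n_folds: int = 2
    seed: int = 0

    def __post_init__(self):
        if not self.alpha_grid or not self.c_grid:
            raise ValueError("grids must be non-empty")
        if self.n_folds != 2:
            raise ValueError("the procedure is defined for 2 folds")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CVResult:
    records: pd.DataFrame  # alpha, c, repeat, fold, test_nll
    means: pd.DataFrame    # alpha, c, mean_test_nll, valid
    selected: tuple[float, float]  # (alpha, c)

    @property
    def selected_hyperparams(self) -> Hyperparams:
        return Hyperparams(*self.selected)


def split_table(
    table: KmerCountTable, seed: int | np.random.Generator
) -> tuple[KmerCountTable, KmerCountTable]:
    """Hypergeometric 2-fold split; fold1 + fold2 reproduces the table."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if table.total_sites < 2:
        raise ValueError("table too small to split")
    f1 = table.copy_empty()
    f2 = table.copy_empty()
    for attr in ("m", "u"):
        counts = getattr(table, attr)
        half = int(counts.sum()) // 2
        take = rng.multivariate_hypergeometric(counts, half)
        getattr(f1, attr)[:] = take
        getattr(f2, attr)[:] = counts - take
    return f1, f2


def _fit(table: KmerCountTable, hp: Hyperparams, optimizer: str):
    if optimizer == "exact":
        return optimal_partition(table, hp)
    if optimizer == "greedy":
        return greedy_partition(table, hp)
    raise ValueError(f"unknown optimizer {optimizer!r}")


def grid_search(
    table: KmerCountTable,
    config: CVConfig | None = None,
    optimizer: str = "exact",
) -> CVResult:
    """Repeated 2-fold CV over the (alpha, c) grid.

    The same ``n_repeats`` seeded splits are reused for every grid point,
    so grid points are independent units of work and the result does not
    depend on evaluation order.
    """
    config = config or CVConfig()
    split_seeds = np.random.SeedSequence(config.seed).spawn(config.n_repeats)
    splits = [split_table(table, np.random.default_rng(ss)) for ss in split_seeds]

    rows = []
    for alpha in config.alpha_grid:
        for c in config.c_grid:
            hp = Hyperparams(alpha, c)
            for rep, (f1, f2) in enumerate(splits):
                for fold, (train, test) in enumerate([(f1, f2), (f2, f1)]):
                    try:
                        model = _fit(train, hp, optimizer)
                        nll = -log_likelihood(model, test)
                    except (ValueError, FloatingPointError) as exc:
                        warnings.warn(
                            f"grid point (alpha={alpha}, c={c}) failed on repeat "
                            f"{rep} fold {fold}: {exc}", stacklevel=2)
                        nll = np.nan
                    rows.append((alpha, c, rep, fold, nll))

    records = pd.DataFrame(rows, columns=["alpha", "c", "repeat", "fold", "test_nll"])
    means = (records.groupby(["alpha", "c"], as_index=False)
             .agg(mean_test_nll=("test_nll", "mean")))
    means["valid"] = np.isfinite(means["mean_test_nll"])
    usable = means[means["valid"]]
    if usable.empty:
        raise ValueError("every grid point failed")
    best = usable["mean_test_nll"].min()
    cand = usable[usable["mean_test_nll"] == best]
    # ties -> strongest regularization: larger c, then larger alpha
    cand = cand.sort_values(["c", "alpha"], ascending=False)
    sel = (float(cand.iloc[0]["alpha"]), float(cand.iloc[0]["c"]))
    return CVResult(records=records, means=means, selected=sel)


def fit_with_cv(
    table: KmerCountTable,
    config: CVConfig | None = None,
    optimizer: str = "exact",
):
    """Convenience: grid-search then refit on the full table."""
    cv = grid_search(table, config, optimizer)
    model = _fit(table, cv.selected_hyperparams, optimizer)
    return model, cv
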