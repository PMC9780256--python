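"""Out-of-sample scoring of pattern-partition models.

The model log-likelihood on a held-out count table is

    l_M = sum_i ( M_i log r_i + U_i log(1 - r_i) )

with pattern counts M_i, U_i recomputed from the test table and rates
r_i taken from the trained model.  Fit quality is summarized by
Nagelkerke's pseudo r-squared,

    r2 = (1 - exp(2 (l_0 - l_M) / n)) / (1 - exp(2 l_0 / n)),

the Cox-Snell ratio rescaled so that a perfect model reaches 1; l_0 is
the likelihood of a constant-rate null model and n the number of sites.
On test data l_M may fall below l_0, so r2 can be negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmer_counting import KmerCountTable
from .pattern_partition import PatternPartitionModel


@dataclass
class EvaluationResult:
    mut_class: str
    l_M: float
    l_0: float
    n: int
    r2: float


def log_likelihood(model: PatternPartitionModel, test_table: KmerCountTable) -> float:
    """Binomial log-likelihood of a held-out table under trained rates."""
    if model.k != test_table.k:
        raise ValueError("model and test table disagree on k")
    assign = model.assignment()
    m = test_table.m.astype(np.float64)
    u = test_table.u.astype(np.float64)
    hit = assign >= 0
    if ((m + u) > 0)[~hit].any():
        raise ValueError("test table has counts on k-mers outside the model's space")
    nM = int(len(model.patterns))
    M = np.bincount(assign[hit], weights=m[hit], minlength=nM)
    U = np.bincount(assign[hit], weights=u[hit], minlength=nM)
    r = np.array([p.r for p in model.patterns])

    ll = 0.0
    for Mi, Ui, ri in zip(M, U, r):
        if Mi > 0:
            if ri <= 0:
                warnings.warn("pattern with rate 0 has mutated test counts; "
                              "log-likelihood is -inf", stacklevel=2)
                return -math.inf
            ll += Mi * math.log(ri)
        if Ui > 0:
            if ri >= 1:
                warnings.warn("pattern with rate 1 has unmutated test counts; "
                              "log-likelihood is -inf", stacklevel=2)
                return -math.inf
            ll += Ui * math.log1p(-ri)
    return ll


def null_log_likelihood(table: KmerCountTable, mu: float | None = None) -> float:
    """Constant-rate log-likelihood; by default at the table's own mean rate."""
    mu = table.mu if mu is None else mu
    M = float(table.m.sum())
    U = float(table.u.sum())
    ll = 0.0
    if M > 0:
        ll += M * math.log(mu)
    if U > 0:
        ll += U * math.log1p(-mu)
    return ll


def nagelkerke_r2(l_M: float, l_0: float, n: int) -> float:
    """Nagelkerke's pseudo r-squared from two log-likelihoods and n sites."""
    if n <= 0:
        raise ValueError("n must be positive")
    if l_0 == 0:
        raise ValueError("null log-likelihood of 0 leaves r2 undefined")
    num = 1.0 - math.exp(2.0 * (l_0 - l_M) / n)
    den = 1.0 - math.exp(2.0 * l_0 / n)
    return num / den


def evaluate_model(
    model: PatternPartitionModel,
    test_table: KmerCountTable,
    null_mu: float | None = None,
) -> EvaluationResult:
    """Score one model on one held-out table.

    ``null_mu`` defaults to the test table's own mean rate, so r2 = 0
    means "no better than a constant fitted to the test data"; pass the
    training mu to compare against the training-derived constant instead.
    """
    l_M = log_likelihood(model, test_table)
    l_0 = null_log_likelihood(test_table, null_mu)
    n = test_table.total_sites
    return EvaluationResult(model.mut_class, l_M, l_0, n, nagelkerke_r2(l_M, l_0, n))


def evaluate_models(
    models: dict[str, PatternPartitionModel],
    test_tables: dict[str, KmerCountTable],
    null_mu: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-class scores plus a pooled joint row.

    The joint r2 pools l_M, l_0 and n across classes before applying the
    Nagelkerke formula.
    """
    rows = []
    tot_lM = tot_l0 = 0.0
    tot_n = 0
    for label, model in models.items():
        table = test_tables[label]
        if table.total_sites == 0:  # class without test data contributes nothing
            rows.append((label, 0.0, 0.0, 0, float("nan")))
            continue
        res = evaluate_model(model, table,
                             None if null_mu is None else null_mu.get(label))
        rows.append((label, res.l_M, res.l_0, res.n, res.r2))
        tot_lM += res.l_M
        tot_l0 += res.l_0
        tot_n += res.n
    rows.append(("joint", tot_lM, tot_l0, tot_n,
                 nagelkerke_r2(tot_lM, tot_l0, tot_n)))
    return pd.DataFrame(rows, columns=["type", "l_M", "l_0", "n", "r2"])
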