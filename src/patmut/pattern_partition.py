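"""The k-mer pattern partition optimizer.

A pattern partition is a set of IUPAC patterns matching every k-mer
exactly once.  Each pattern i pools the mutated/unmutated counts (M_i,
U_i) of its k-mers and carries a regularized rate

    r_i = (M_i + alpha) / (M_i + U_i + alpha / mu)

where mu is the table-wide mean rate and alpha a pseudo count.  The
partition chosen is the one minimizing the penalized binomial deviance

    loss = sum_i [ -2 (M_i log r_i + U_i log(1 - r_i)) + c ]

with a per-pattern complexity penalty c (at c = 2 the loss is the AIC of
the corresponding binomial model).  The exact optimizer solves the
recursion

    f(p) = min( loss({p}),
                min over positions i and two-partitions (x, y) of p[i]:
                    f(p with x at i) + f(p with y at i) )

bottom-up over all patterns reachable from the root, so every pattern's
optimum is computed once; the greedy variant commits to the single most
promising split of each pattern instead of exploring all of them.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .dna import kmer_index
from .iupac import (
    CODE_INDEX,
    CODES,
    IUPAC_SETS,
    MEMBER,
    TWO_PARTITIONS,
    pattern_match_mask,
    pattern_size,
    subset_codes,
)
from .kmer_counting import KmerCountTable


@dataclass(frozen=True)
class Hyperparams:
    """Regularizers of the partition loss: pseudo count and complexity penalty."""

    alpha: float
    c: float

    def __post_init__(self):
        if not (math.isfinite(self.alpha) and self.alpha >= 0):
            raise ValueError("alpha must be finite and >= 0")
        if not (math.isfinite(self.c) and self.c >= 0):
            raise ValueError("c must be finite and >= 0")


@dataclass
class PatternStats:
    pattern: str
    M: float
    U: float
    r: float


def regularized_rate(M: float, U: float, alpha: float, mu: float) -> float:
    """Rate estimate pulled toward the mean rate mu by the pseudo count."""
    denom = M + U + (alpha / mu if alpha > 0 else 0.0)
    if denom == 0:
        return mu  # empty pattern: the prior mean
    return (M + alpha) / denom


def _deviance(M: float, U: float, r: float) -> float:
    """-2 (M log r + U log(1-r)) with the 0 * log 0 = 0 convention."""
    ll = 0.0
    if M > 0:
        if r <= 0:
            return math.inf
        ll += M * math.log(r)
    if U > 0:
        if r >= 1:
            return math.inf
        ll += U * math.log1p(-r)
    return -2.0 * ll


def pattern_loss(stats: PatternStats, hp: Hyperparams, mu: float) -> float:
    """Loss contribution of one pattern: deviance at its regularized rate + c."""
    r = regularized_rate(stats.M, stats.U, hp.alpha, mu)
    return _deviance(stats.M, stats.U, r) + hp.c


@dataclass
class PatternPartitionModel:
    """A fitted pattern partition for one mutation class."""

    mut_class: str
    k: int
    patterns: list[PatternStats]
    hyperparams: Hyperparams
    mu: float
    loss: float

    def pattern_strings(self) -> list[str]:
        return [p.pattern for p in self.patterns]

    def assignment(self) -> np.ndarray:
        """Pattern row index for every k-mer index (-1 if unmatched)."""
        out = np.full(4 ** self.k, -1, dtype=np.int64)
        for i, p in enumerate(self.patterns):
            mask = pattern_match_mask(p.pattern, self.k)
            if (out[mask] != -1).any():
                raise ValueError("patterns overlap")
            out[mask] = i
        return out

    def rate_array(self) -> np.ndarray:
        """Per-k-mer regularized rate (NaN for unmatched k-mers)."""
        assign = self.assignment()
        rates = np.array([p.r for p in self.patterns])
        out = np.full(4 ** self.k, np.nan)
        hit = assign >= 0
        out[hit] = rates[assign[hit]]
        return out

    def rate_of(self, kmer: str) -> float:
        r = self.rate_array()[kmer_index(kmer)]
        if np.isnan(r):
            raise KeyError(f"k-mer {kmer} not matched by any pattern")
        return float(r)

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"#mut_class={self.mut_class}\n#k={self.k}\n")
            fh.write(f"#alpha={self.hyperparams.alpha!r}\n#c={self.hyperparams.c!r}\n")
            fh.write(f"#mu={self.mu!r}\n#loss={self.loss!r}\n")
            fh.write("pattern\tmutated_count\tbackground_count\trate\n")
            for p in self.patterns:
                fh.write(f"{p.pattern}\t{p.M:g}\t{p.U:g}\t{p.r!r}\n")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "PatternPartitionModel":
        meta, rows = {}, []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    meta[key] = val
                elif line and not line.startswith("pattern\t"):
                    pat, M, U, r = line.split("\t")
                    rows.append(PatternStats(pat, float(M), float(U), float(r)))
        return cls(
            mut_class=meta.get("mut_class", "?"),
            k=int(meta["k"]),
            patterns=rows,
            hyperparams=Hyperparams(float(meta["alpha"]), float(meta["c"])),
            mu=float(meta["mu"]),
            loss=float(meta["loss"]),
        )


def root_pattern(table: KmerCountTable) -> str:
    """The coarsest pattern covering a table's k-mer space.

    An SNV class is strand-collapsed with a fixed central reference base
    (A or C), so its k-mer space is the set of k-mers with that central
    base and the root's central code is that base itself (the 16 C-central
    3-mers of a C>* class, etc.).  Indel tables use the full all-N root.
    """
    k = table.k
    if ">" in table.mut_class:
        h = k // 2
        return "N" * h + table.mut_class[0] + "N" * (k - h - 1)
    return "N" * k


def _count_tensors(table: KmerCountTable):
    """Pattern counts M, U for every pattern, as (15,)*k tensors indexed by
    tuples of CODE_INDEX values; exploits additivity of counts over the
    bases each code matches."""
    k = table.k
    memberf = MEMBER.astype(np.float64)
    Mt = table.m.astype(np.float64).reshape((4,) * k)
    Ut = table.u.astype(np.float64).reshape((4,) * k)
    for ax in range(k):
        Mt = np.moveaxis(np.tensordot(memberf, Mt, axes=([1], [ax])), 0, ax)
        Ut = np.moveaxis(np.tensordot(memberf, Ut, axes=([1], [ax])), 0, ax)
    return Mt, Ut


def _check_table(table: KmerCountTable) -> float:
    mu = table.mu
    if math.isnan(mu) or not (0 < mu < 1):
        raise ValueError(
            f"table mean rate mu={mu} is degenerate; the partition loss is "
            "undefined without both mutated and unmutated counts")
    return mu


def optimal_partition(
    table: KmerCountTable,
    hp: Hyperparams,
    max_patterns_in_memory: float = 5e7,
) -> PatternPartitionModel:
    """Exact minimum-loss partition by bottom-up dynamic programming.

    Visits every pattern reachable from the root ordered by coarseness
    (number of matched k-mers, ascending), so both children of any split
    are solved before their parent.  Ties prefer not splitting, then the
    first split in canonical (position, Table-order) enumeration.
    """
    mu = _check_table(table)
    k = table.k
    root = root_pattern(table)
    per_pos = [subset_codes(c) for c in root]
    n_patterns = int(np.prod([len(p) for p in per_pos]))
    if n_patterns > max_patterns_in_memory:
        raise MemoryError(
            f"pattern space has {n_patterns} patterns; exact optimization "
            "refused - use greedy_partition for this k")

    Mt, Ut = _count_tensors(table)
    alpha, c = hp.alpha, hp.c
    aomu = alpha / mu if alpha > 0 else 0.0

    patterns = [
        tuple(CODE_INDEX[ch] for ch in combo)
        for combo in itertools.product(*per_pos)
    ]
    patterns.sort(key=lambda p: pattern_size("".join(CODES[i] for i in p)))

    splits_of = {CODE_INDEX[code]: [(CODE_INDEX[x], CODE_INDEX[y])
                                    for x, y in prs]
                 for code, prs in TWO_PARTITIONS.items()}

    F: dict[tuple, float] = {}
    choice: dict[tuple, tuple | None] = {}
    log, log1p, inf = math.log, math.log1p, math.inf
    for p in patterns:
        M = Mt[p]
        U = Ut[p]
        denom = M + U + aomu
        r = mu if denom == 0 else (M + alpha) / denom
        ll = 0.0
        bad = False
        if M > 0:
            if r <= 0:
                bad = True
            else:
                ll += M * log(r)
        if U > 0 and not bad:
            if r >= 1:
                bad = True
            else:
                ll += U * log1p(-r)
        best = inf if bad else -2.0 * ll + c
        best_split = None
        for i, ci in enumerate(p):
            sp = splits_of.get(ci)
            if not sp:
                continue
            left = p[:i]
            right = p[i + 1:]
            for x, y in sp:
                cand = F[left + (x,) + right] + F[left + (y,) + right]
                if cand < best:
                    best = cand
                    best_split = (i, x, y)
        F[p] = best
        choice[p] = best_split

    # reconstruct the optimal set of leaf patterns from the root
    root_t = tuple(CODE_INDEX[ch] for ch in root)
    leaves: list[tuple] = []
    stack = [root_t]
    while stack:
        p = stack.pop()
        ch = choice[p]
        if ch is None:
            leaves.append(p)
        else:
            i, x, y = ch
            stack.append(p[:i] + (x,) + p[i + 1:])
            stack.append(p[:i] + (y,) + p[i + 1:])

    stats = []
    for p in sorted(leaves):
        pat = "".join(CODES[i] for i in p)
        M, U = float(Mt[p]), float(Ut[p])
        stats.append(PatternStats(pat, M, U, regularized_rate(M, U, alpha, mu)))
    return PatternPartitionModel(table.mut_class, k, stats, hp, mu, float(F[root_t]))


def greedy_partition(table: KmerCountTable, hp: Hyperparams) -> PatternPartitionModel:
    """Heuristic partition: repeatedly apply the single most promising
    two-partition split of each pattern (by immediate loss of the two
    children) and stop when no split improves on keeping the pattern."""
    mu = _check_table(table)
    k = table.k
    Mt, Ut = _count_tensors(table)
    alpha = hp.alpha

    def loss1(p: tuple) -> float:
        M, U = float(Mt[p]), float(Ut[p])
        return _deviance(M, U, regularized_rate(M, U, alpha, mu)) + hp.c

    splits_of = {CODE_INDEX[code]: [(CODE_INDEX[x], CODE_INDEX[y]) for x, y in prs]
                 for code, prs in TWO_PARTITIONS.items()}

    root_t = tuple(CODE_INDEX[ch] for ch in root_pattern(table))
    leaves: list[tuple] = []
    stack = [root_t]
    while stack:
        p = stack.pop()
        keep = loss1(p)
        best = math.inf
        best_split = None
        for i, ci in enumerate(p):
            for x, y in splits_of.get(ci, ()):
                cand = loss1(p[:i] + (x,) + p[i + 1:]) + loss1(p[:i] + (y,) + p[i + 1:])
                if cand < best:
                    best = cand
                    best_split = (i, x, y)
        if best_split is not None and best < keep:
            i, x, y = best_split
            stack.append(p[:i] + (x,) + p[i + 1:])
            stack.append(p[:i] + (y,) + p[i + 1:])
        else:
            leaves.append(p)

    stats = []
    total = 0.0
    for p in sorted(leaves):
        pat = "".join(CODES[i] for i in p)
        M, U = float(Mt[p]), float(Ut[p])
        r = regularized_rate(M, U, alpha, mu)
        stats.append(PatternStats(pat, M, U, r))
        total += _deviance(M, U, r) + hp.c
    return PatternPartitionModel(table.mut_class, k, stats, hp, mu, total)


def model_total_loss(model: PatternPartitionModel) -> float:
    """Recompute the loss of a model from its own pattern stats."""
    return sum(pattern_loss(p, model.hyperparams, model.mu) for p in model.patterns)


def validate_partition(model: PatternPartitionModel, table: KmerCountTable | None = None) -> None:
    """Assert the exactly-one-match invariant (and count conservation if a
    table is given); raises ValueError on violation."""
    assign = model.assignment()
    root = root_pattern(table) if table is not None else None
    if table is not None:
        covered = pattern_match_mask(root, model.k)
        if (assign[covered] < 0).any():
            raise ValueError("some k-mers matched by no pattern")
        M = sum(p.M for p in model.patterns)
        U = sum(p.U for p in model.patterns)
        if not (math.isclose(M, table.m.sum()) and math.isclose(U, table.u.sum())):
            raise ValueError("pattern counts do not conserve table totals")
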