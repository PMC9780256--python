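"""Per-transcript expected mutation counts, burden tests and constraint.

Every possible coding point mutation of a transcript is enumerated and
classified into one of eight functional categories; each possible
mutation carries the per-generation probability of its context pattern,
rescaled so the genome-wide mean SNV rate is 1.28e-8 and the mean indel
rate 0.68e-9 per base per generation, and then converted into the
probability of having occurred in n_gen observed generations:

    r_scaled = 1 - (1 - r)^(2 * n_gen)

Expected category counts are sums of r_scaled.  Because every possible
mutation has its own probability, the null count distribution of a
transcript is Poisson-binomial; burden p-values and the 90% interval of
the expected count are obtained by sampling from it.  Loss-of-function
(LoF = nonsense + essential-splice + frameshift) constraint is reported
as the O/E ratio (obs + 0.5)/(exp + 0.5) and the conservative LOEUF
variant with the lower bound of the 90% interval in the denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dna import complement, kmer_index, position_digits, revcomp, revcomp_index_table
from .kmer_counting import SNV_CLASSES, _central_collapsed
from .dna import encode, window_indices
from .pattern_partition import PatternPartitionModel
from .sequence_io import (
    DEL,
    INS,
    SNV,
    MutationRecord,
    ReferenceGenome,
    RegionMask,
    TranscriptModel,
)

CATEGORIES = (
    "synonymous", "missense", "nonsense", "start_disruption",
    "stop_disruption", "splice_disruption", "inframe_indel", "frameshift_indel",
)
LOF_CATEGORIES = ("nonsense", "splice_disruption", "frameshift_indel")

STOP_CODONS = {"TAA", "TAG", "TGA"}


def _codon_table() -> dict[str, str]:
    from Bio.Data import CodonTable

    tab = CodonTable.unambiguous_dna_by_id[1]
    d = dict(tab.forward_table)
    for s in tab.stop_codons:
        d[s] = "*"
    return d


CODON_AA = _codon_table()


@dataclass
class ScalingConfig:
    """Rate-scaling constants and the generation exponent.

    ``snv_mean_rate`` / ``indel_mean_rate`` are the genome-wide average
    per-base per-generation rates the trained models are rescaled to;
    ``n_gen`` is the effective number of transmitted generations the
    observed variant set represents (given, or calibrated on synonymous
    counts).
    """

    snv_mean_rate: float = 1.28e-8
    indel_mean_rate: float = 0.68e-9
    n_gen: float | None = None

    def __post_init__(self):
        if self.snv_mean_rate <= 0 or self.indel_mean_rate <= 0:
            raise ValueError("mean rates must be positive")
        if self.n_gen is not None and self.n_gen < 0:
            raise ValueError("n_gen must be >= 0")


def generation_scale(r, n_gen: float):
    """Probability that a site with per-generation rate r mutated at least
    once in n_gen diploid generations: 1 - (1 - r)^(2 n_gen)."""
    r = np.asarray(r, dtype=np.float64)
    return -np.expm1(2.0 * n_gen * np.log1p(-r))


# --- rate rescaling --------------------------------------------------------


@dataclass
class SnvRateLookup:
    """Scaled per-generation SNV rates per collapsed k-mer, per class."""

    k: int
    rates: dict[str, np.ndarray]
    factor: float
    mean_unscaled: float
    n_sites: int

    def rate(self, label: str, kmer: str | int) -> float:
        idx = kmer_index(kmer) if isinstance(kmer, str) else int(kmer)
        r = self.rates[label][idx]
        if np.isnan(r):
            raise KeyError(f"k-mer index {idx} not in the {label} model's space")
        return float(r)

    def site_alt_rate(self, window: str, alt: str) -> float:
        """Rate of a specific substitution given its genomic-strand window."""
        h = self.k // 2
        ref = window[h]
        if ref in "GT":
            window, alt = revcomp(window), complement(alt)
        return self.rate(f"{window[h]}>{alt}", window)


def _site_kmer_counts(genome: ReferenceGenome, mask: RegionMask, k: int) -> np.ndarray:
    counts = np.zeros(4 ** k, dtype=np.int64)
    for _chrom, _centers, idx, _cbase, keep in _central_collapsed(genome, mask, k):
        if keep.any():
            counts += np.bincount(idx[keep], minlength=4 ** k)
    return counts


def _total_site_rate(rates: dict[str, np.ndarray], k: int) -> np.ndarray:
    """Per-collapsed-k-mer total substitution rate (sum over the 3 alts)."""
    h = k // 2
    central = position_digits(k, h)
    totA = sum(np.nan_to_num(rates[c]) for c in SNV_CLASSES if c[0] == "A")
    totC = sum(np.nan_to_num(rates[c]) for c in SNV_CLASSES if c[0] == "C")
    return np.where(central == 0, totA, totC)


def scale_snv_models(
    models: dict[str, PatternPartitionModel],
    genome: ReferenceGenome,
    mask: RegionMask,
    target: float = 1.28e-8,
) -> SnvRateLookup:
    """Rescale the six SNV models so the genome-wide (site-count weighted)
    mean per-base total substitution rate equals ``target``."""
    ks = {m.k for m in models.values()}
    if len(ks) != 1:
        raise ValueError("all SNV models must share one k")
    k = ks.pop()
    if set(models) != set(SNV_CLASSES):
        raise ValueError(f"need models for all classes {SNV_CLASSES}")
    raw = {lab: m.rate_array() for lab, m in models.items()}
    counts = _site_kmer_counts(genome, mask, k)
    if counts.sum() == 0:
        raise ValueError("mask covers no usable sites")
    tot = _total_site_rate(raw, k)
    mean = float((counts * tot).sum() / counts.sum())
    if mean <= 0:
        raise ValueError("models assign zero rate everywhere")
    factor = target / mean
    return SnvRateLookup(k, {lab: a * factor for lab, a in raw.items()},
                         factor, mean, int(counts.sum()))


def mean_scaled_snv_rate(lookup: SnvRateLookup, genome: ReferenceGenome,
                         mask: RegionMask) -> float:
    """Recompute the genome-wide mean scaled per-site substitution rate."""
    counts = _site_kmer_counts(genome, mask, lookup.k)
    tot = _total_site_rate(lookup.rates, lookup.k)
    return float((counts * tot).sum() / counts.sum())


@dataclass
class IndelRateLookup:
    """Scaled per-generation indel rates per breakpoint context k-mer."""

    k_ins: int
    k_del: int
    rates: dict[str, np.ndarray]
    factor: float
    mean_unscaled: float

    def ins_labels(self):
        return [lab for lab in self.rates if lab.startswith("INS")]

    def del_labels(self):
        return [lab for lab in self.rates if lab.startswith("DEL")]

    def rate(self, label: str, kmer: str | int) -> float:
        idx = kmer_index(kmer) if isinstance(kmer, str) else int(kmer)
        return float(self.rates[label][idx])


def _breakpoint_kmer_counts(genome, mask, k, at_breakpoint: bool):
    """Counts of context k-mers over masked breakpoints (even k, inter-base)
    or masked positions (odd k, base-centered)."""
    counts = np.zeros(4 ** k, dtype=np.int64)
    h = k // 2
    for chrom, seq in genome.items():
        codes = encode(seq)
        mb = mask.to_bool(chrom, len(codes))
        idx, valid = window_indices(codes, k)
        if not len(idx):
            continue
        anchor = np.arange(h, h + len(idx))
        sel = valid & mb[anchor]
        counts += np.bincount(idx[sel], minlength=4 ** k)
    return counts


def scale_indel_models(
    models: dict[str, PatternPartitionModel],
    genome: ReferenceGenome,
    mask: RegionMask,
    target: float = 0.68e-9,
) -> IndelRateLookup:
    """Rescale insertion + deletion models jointly so the mean combined
    per-breakpoint indel rate across the masked genome equals ``target``."""
    ins_labels = [lab for lab in models if lab.startswith("INS")]
    del_labels = [lab for lab in models if lab.startswith("DEL")]
    if not ins_labels or not del_labels:
        raise ValueError("need at least one INS and one DEL model")
    k_ins = {models[lab].k for lab in ins_labels}
    k_del = {models[lab].k for lab in del_labels}
    if len(k_ins) != 1 or len(k_del) != 1:
        raise ValueError("inconsistent k among indel models")
    k_ins, k_del = k_ins.pop(), k_del.pop()

    raw = {lab: np.nan_to_num(m.rate_array()) for lab, m in models.items()}
    mean = 0.0
    for k, labels in ((k_ins, ins_labels), (k_del, del_labels)):
        counts = _breakpoint_kmer_counts(genome, mask, k, k % 2 == 0)
        if counts.sum() == 0:
            raise ValueError("mask covers no usable breakpoints")
        tot = sum(raw[lab] for lab in labels)
        mean += float((counts * tot).sum() / counts.sum())
    if mean <= 0:
        raise ValueError("indel models assign zero rate everywhere")
    factor = target / mean
    return IndelRateLookup(k_ins, k_del,
                           {lab: a * factor for lab, a in raw.items()},
                           factor, mean)


def mean_scaled_indel_rate(lookup: IndelRateLookup, genome: ReferenceGenome,
                           mask: RegionMask) -> float:
    """Recompute the mean combined scaled per-breakpoint indel rate."""
    mean = 0.0
    for k, labels in ((lookup.k_ins, lookup.ins_labels()),
                      (lookup.k_del, lookup.del_labels())):
        counts = _breakpoint_kmer_counts(genome, mask, k, k % 2 == 0)
        tot = sum(lookup.rates[lab] for lab in labels)
        mean += float((counts * tot).sum() / counts.sum())
    return mean


# --- classification --------------------------------------------------------


class _TranscriptContext:
    """Precomputed coding map of one transcript against a genome."""

    def __init__(self, transcript: TranscriptModel, genome: ReferenceGenome):
        self.t = transcript
        self.genome = genome
        self.cds = transcript.coding_sequence(genome)
        pos = transcript.coding_positions()
        self.coding_pos = pos
        self.index = {int(p): i for i, p in enumerate(pos)}
        self.splice = set(transcript.splice_site_positions())
        self.n_codons = len(self.cds) // 3

    def classify(self, pos0: int, alt: str) -> str:
        if pos0 in self.splice:
            return "splice_disruption"
        i = self.index.get(pos0)
        if i is None:
            raise ValueError(
                f"position {pos0} outside transcript {self.t.transcript_id}")
        alt_c = complement(alt) if self.t.strand == "-" else alt
        ci, off = divmod(i, 3)
        codon = self.cds[3 * ci:3 * ci + 3]
        mutated = codon[:off] + alt_c + codon[off + 1:]
        if ci == 0 and codon == "ATG":
            return "start_disruption"
        aa_ref = CODON_AA[codon]
        aa_mut = CODON_AA[mutated]
        if aa_ref == "*":
            return "synonymous" if aa_mut == "*" else "stop_disruption"
        if aa_mut == "*":
            return "nonsense"
        return "synonymous" if aa_mut == aa_ref else "missense"


def classify_snv(
    transcript: TranscriptModel,
    genome: ReferenceGenome,
    pos0: int,
    ref: str,
    alt: str,
) -> str:
    """Functional category of a single-base substitution (0-based position)."""
    base = genome.fetch(transcript.chrom, pos0, pos0 + 1)
    if base != ref:
        raise ValueError(f"ref {ref!r} does not match genome base {base!r} at "
                         f"{transcript.chrom}:{pos0 + 1}")
    return _TranscriptContext(transcript, genome).classify(pos0, alt)


# --- site tables and expectations ------------------------------------------


@dataclass
class TranscriptSiteTable:
    """Every possible mutation of one transcript with its probability.

    ``df`` columns: pos (0-based genomic), kind (snv/ins/del), ref, alt,
    length, category, r (per-generation probability).
    """

    transcript_id: str
    df: pd.DataFrame

    def probabilities(self, category, n_gen: float) -> np.ndarray:
        """Generation-scaled probabilities of one category (or a group of
        categories, e.g. the LoF triple)."""
        cats = [category] if isinstance(category, str) else list(category)
        r = self.df.loc[self.df["category"].isin(cats), "r"].to_numpy()
        return generation_scale(r, n_gen)

    def expected(self, n_gen: float) -> dict[str, float]:
        """Expected count per category: sum of generation-scaled probabilities."""
        out = {c: 0.0 for c in CATEGORIES}
        for cat, grp in self.df.groupby("category"):
            out[str(cat)] = float(generation_scale(grp["r"].to_numpy(), n_gen).sum())
        return out


def build_site_table(
    transcript: TranscriptModel,
    genome: ReferenceGenome,
    snv_rates: SnvRateLookup,
    indel_rates: IndelRateLookup | None = None,
    del_lengths: tuple[int, ...] = (1, 2, 3),
) -> TranscriptSiteTable:
    """Enumerate all possible SNVs (and indel opportunities) of a transcript.

    Context k-mers are read from the genomic strand and strand-collapsed by
    the model's own convention.  Insertion opportunities are the inter-base
    breakpoints strictly inside coding exons; deletion opportunities are
    anchored at each coding base for each configured length.  Sites whose
    context window leaves the contig or contains N are dropped with a
    warning.
    """
    ctx = _TranscriptContext(transcript, genome)
    k = snv_rates.k
    h = k // 2
    chrom = transcript.chrom
    rows = []
    n_dropped = 0

    snv_positions = sorted(set(int(p) for p in ctx.coding_pos) | ctx.splice)
    for p in snv_positions:
        window = genome.fetch(chrom, p - h, p + h + 1)
        if len(window) != k or "N" in window:
            n_dropped += 1
            continue
        ref = window[h]
        for alt in "ACGT":
            if alt == ref:
                continue
            r = snv_rates.site_alt_rate(window, alt)
            cat = ctx.classify(p, alt)
            rows.append((p, "snv", ref, alt, 0, cat, r))

    if indel_rates is not None:
        need = {"INS_3n", "INS_non3n", "DEL_3n", "DEL_non3n"}
        if not need <= set(indel_rates.rates):
            raise ValueError("indel expectations need frame-split models "
                             "(INS_3n/INS_non3n/DEL_3n/DEL_non3n)")
        coding = set(int(p) for p in ctx.coding_pos)
        hi = indel_rates.k_ins // 2
        hd = indel_rates.k_del // 2
        for b in sorted(coding):
            # insertion breakpoint strictly inside a coding exon
            if b - 1 in coding:
                win = genome.fetch(chrom, b - hi, b + hi)
                if len(win) == indel_rates.k_ins and "N" not in win:
                    rows.append((b, "ins", "", "", 3, "inframe_indel",
                                 indel_rates.rate("INS_3n", win)))
                    rows.append((b, "ins", "", "", 1, "frameshift_indel",
                                 indel_rates.rate("INS_non3n", win)))
                else:
                    n_dropped += 1
            # deletions anchored at this coding base
            win = genome.fetch(chrom, b - hd, b + hd + 1)
            if len(win) == indel_rates.k_del and "N" not in win:
                for L in del_lengths:
                    lab = "DEL_3n" if L % 3 == 0 else "DEL_non3n"
                    cat = "inframe_indel" if L % 3 == 0 else "frameshift_indel"
                    rows.append((b, "del", "", "", L, cat,
                                 indel_rates.rate(lab, win)))
            else:
                n_dropped += 1

    if n_dropped:
        warnings.warn(f"{transcript.transcript_id}: dropped {n_dropped} site(s) "
                      "with undefined context", stacklevel=2)
    df = pd.DataFrame(rows, columns=["pos", "kind", "ref", "alt", "length",
                                     "category", "r"])
    return TranscriptSiteTable(transcript.transcript_id, df)


def expected_counts(
    transcript: TranscriptModel,
    genome: ReferenceGenome,
    snv_rates: SnvRateLookup,
    indel_rates: IndelRateLookup | None,
    scaling: ScalingConfig,
) -> tuple[dict[str, float], TranscriptSiteTable]:
    """Per-category expected mutation counts for one transcript."""
    if scaling.n_gen is None:
        raise ValueError("scaling.n_gen must be set (give it or calibrate it)")
    table = build_site_table(transcript, genome, snv_rates, indel_rates)
    return table.expected(scaling.n_gen), table


# --- Poisson-binomial burden test -------------------------------------------


@dataclass
class BurdenResult:
    p_value: float
    expected: float
    interval90: tuple[float, float]
    n_samples: int


def sample_poisson_binomial(
    probs: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    chunk_samples: int = 100_000,
) -> np.ndarray:
    """Sampled totals of independent Bernoulli trials with given probabilities.

    Sites sharing a probability are pooled into binomial draws, which is
    distributionally identical and much faster for pattern-derived rates.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    vals, cnts = np.unique(probs, return_counts=True)
    out = np.empty(n_samples, dtype=np.int64)
    done = 0
    while done < n_samples:
        s = min(chunk_samples, n_samples - done)
        if len(vals):
            out[done:done + s] = rng.binomial(cnts, vals, size=(s, len(vals))).sum(axis=1)
        else:
            out[done:done + s] = 0
        done += s
    return out


def burden_pvalue(
    site_table: TranscriptSiteTable,
    category,
    observed: int,
    n_gen: float,
    n_samples: int = 10_000_000,
    seed: int = 0,
) -> BurdenResult:
    """Monte-Carlo Poisson-binomial burden test for one category.

    p = (1 + #{samples >= observed}) / (1 + n_samples); the +1 keeps the
    p-value valid (never 0) under sampling.  The 90% interval is the
    empirical 5th-95th percentile of the sampled counts.
    """
    if observed < 0:
        raise ValueError("observed must be >= 0")
    probs = site_table.probabilities(category, n_gen)
    rng = np.random.default_rng(seed)
    samples = sample_poisson_binomial(probs, n_samples, rng)
    p = (1 + int((samples >= observed).sum())) / (1 + n_samples)
    lo, hi = np.quantile(samples, [0.05, 0.95])
    return BurdenResult(p, float(probs.sum()), (float(lo), float(hi)), n_samples)


# --- generation calibration -------------------------------------------------


def calibrate_ngen(
    site_tables: list[TranscriptSiteTable],
    observed_synonymous_total: float,
    rtol: float = 1e-6,
) -> float:
    """Solve for n_gen so total expected synonymous count matches observation.

    The expectation sum_i (1 - (1 - r_i)^(2 n)) is strictly increasing and
    bounded by the number of synonymous sites, so a bracketed root finder
    converges; the target must be reachable.
    """
    if observed_synonymous_total <= 0:
        raise ValueError("observed synonymous total must be > 0")
    rs = np.concatenate([
        t.df.loc[t.df["category"] == "synonymous", "r"].to_numpy()
        for t in site_tables
    ]) if site_tables else np.empty(0)
    rs = rs[rs > 0]
    if not len(rs):
        raise ValueError("no synonymous sites with positive rate; target unreachable")
    if observed_synonymous_total >= len(rs):
        raise ValueError("target exceeds the number of synonymous sites; unreachable")
    log1mr = np.log1p(-rs)

    def gap(n: float) -> float:
        return float(-np.expm1(2.0 * n * log1mr).sum()) - observed_synonymous_total

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e15:
            raise ValueError("calibration did not bracket a root")
    return float(brentq(gap, 0.0, hi, rtol=max(rtol * 1e-2, 1e-14), maxiter=200))


# --- coverage correction and constraint -------------------------------------


def coverage_correct(
    syn_oe,
    an,
    frac: float = 0.05,
    an_min: float = 50_000,
    min_transcripts: int = 20,
) -> pd.Series:
    """LOWESS correction factors for coverage-driven expectation bias.

    Fits a locally weighted regression of per-transcript synonymous O/E
    against mean allele number (AN, the coverage proxy), drops transcripts
    at or below ``an_min``, and returns the fitted factor at each kept
    transcript's AN; dividing a transcript's expected counts by its factor
    flattens the synonymous O/E trend.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    syn_oe = pd.Series(syn_oe, dtype=float)
    an = pd.Series(an, dtype=float)
    if not syn_oe.index.equals(an.index):
        an = pd.Series(np.asarray(an), index=syn_oe.index, dtype=float)
    keep = an > an_min
    if int(keep.sum()) < min_transcripts:
        raise ValueError(
            f"only {int(keep.sum())} transcripts above AN {an_min}; "
            f"need >= {min_transcripts}")
    y = syn_oe[keep].to_numpy()
    x = an[keep].to_numpy()
    if np.ptp(x) == 0:
        fit = np.full(len(x), y.mean())
    else:
        fit = lowess(y, x, frac=frac, return_sorted=False)
    return pd.Series(fit, index=syn_oe.index[keep], name="correction_factor")


@dataclass
class ConstraintScores:
    lof_observed: float
    lof_expected: float
    oe_ratio: float
    loeuf: float


def constraint_scores(
    lof_observed: float,
    lof_expected_corrected: float,
    interval90_lower: float,
) -> ConstraintScores:
    """O/E and LOEUF with the 0.5 pseudo score on both numerator and
    denominator (keeps zero-observation transcripts finite)."""
    if min(lof_observed, lof_expected_corrected, interval90_lower) < 0:
        raise ValueError("inputs must be >= 0")
    oe = (lof_observed + 0.5) / (lof_expected_corrected + 0.5)
    loeuf = (lof_observed + 0.5) / (interval90_lower + 0.5)
    return ConstraintScores(lof_observed, lof_expected_corrected, oe, loeuf)


# --- observed counts ---------------------------------------------------------


def observed_counts(
    transcript: TranscriptModel,
    genome: ReferenceGenome,
    mutations: list[MutationRecord],
) -> dict[str, int]:
    """Tally observed mutations of a transcript into the eight categories.

    SNVs at coding or essential-splice positions are classified by codon
    translation; an indel counts as frameshift/inframe when its affected
    bases touch the CDS, or splice_disruption when they only touch the
    essential splice sites.
    """
    ctx = _TranscriptContext(transcript, genome)
    coding = set(int(p) for p in ctx.coding_pos)
    counts = {c: 0 for c in CATEGORIES}
    for rec in mutations:
        if rec.chrom != transcript.chrom:
            continue
        cls = rec.mut_class
        if cls == SNV:
            if rec.pos0 in coding or rec.pos0 in ctx.splice:
                counts[ctx.classify(rec.pos0, rec.alt)] += 1
        elif cls == INS:
            b = rec.pos0 + 1  # insertion breakpoint
            if b in coding and b - 1 in coding:
                cat = ("inframe_indel" if rec.indel_length % 3 == 0
                       else "frameshift_indel")
                counts[cat] += 1
            elif b in ctx.splice or b - 1 in ctx.splice:
                counts["splice_disruption"] += 1
        elif cls == DEL:
            span = set(range(rec.pos0 + 1, rec.pos0 + 1 + rec.indel_length))
            if span & coding:
                cat = ("inframe_indel" if rec.indel_length % 3 == 0
                       else "frameshift_indel")
                counts[cat] += 1
            elif span & ctx.splice:
                counts["splice_disruption"] += 1
    return counts
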