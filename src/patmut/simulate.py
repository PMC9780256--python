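"""Seeded synthetic fixtures: genomes, mutation sets drawn from a known
pattern model, and toy transcriptomes.

The generator emulates the binomial site model the partition loss is
built on: every callable site (or indel breakpoint) mutates independently
with the rate of the ground-truth pattern matching its context, at most
once per site.  All randomness flows from one master seed through named
substreams so each fixture is individually reproducible, and parameter
recovery against the known truth is measurable end to end.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .dna import BASES, complement, revcomp
from .iupac import pattern_match_mask
from .kmer_counting import SNV_CLASSES, _central_collapsed
from .dna import encode, window_indices
from .sequence_io import MutationRecord, ReferenceGenome, RegionMask, TranscriptModel

_ALTS = {"A": "CGT", "C": "AGT"}

STOP_CODONS = ("TAA", "TAG", "TGA")
_NON_STOP = tuple(a + b + c for a in BASES for b in BASES for c in BASES
                  if a + b + c not in STOP_CODONS)


def _rate_array(patterns: list[tuple[str, float]], k: int) -> np.ndarray:
    out = np.full(4 ** k, np.nan)
    for pat, rate in patterns:
        if len(pat) != k:
            raise ValueError(f"pattern {pat} has wrong length")
        if not (0 <= rate < 1):
            raise ValueError(f"rate {rate} outside [0, 1)")
        mask = pattern_match_mask(pat, k)
        if not np.isnan(out[mask]).all():
            raise ValueError(f"pattern {pat} overlaps another pattern")
        out[mask] = rate
    return out


@dataclass
class GroundTruthModel:
    """A known pattern partition with true rates, per mutation class.

    SNV patterns partition the k-mers with the class's central reference
    base; insertion/deletion patterns partition all breakpoint-context
    k-mers (even/odd k respectively).
    """

    snv: dict[str, list[tuple[str, float]]]
    ins: list[tuple[str, float]] | None = None
    dele: list[tuple[str, float]] | None = None

    def __post_init__(self):
        ks = {len(p) for pats in self.snv.values() for p, _ in pats}
        if len(ks) != 1:
            raise ValueError("all SNV patterns must share one k")
        self.k = ks.pop()
        h = self.k // 2
        for label, pats in self.snv.items():
            arr = _rate_array(pats, self.k)
            space = pattern_match_mask("N" * h + label[0] + "N" * (self.k - h - 1),
                                       self.k)
            if np.isnan(arr[space]).any():
                raise ValueError(f"{label}: patterns do not cover the k-mer space")
        if self.ins is not None:
            self.k_ins = len(self.ins[0][0])
            arr = _rate_array(self.ins, self.k_ins)
            if np.isnan(arr).any():
                raise ValueError("INS patterns do not cover the k-mer space")
        if self.dele is not None:
            self.k_del = len(self.dele[0][0])
            arr = _rate_array(self.dele, self.k_del)
            if np.isnan(arr).any():
                raise ValueError("DEL patterns do not cover the k-mer space")

    def snv_rate_array(self, label: str) -> np.ndarray:
        return np.nan_to_num(_rate_array(self.snv[label], self.k))

    def ins_rate_array(self) -> np.ndarray:
        return np.nan_to_num(_rate_array(self.ins, self.k_ins))

    def del_rate_array(self) -> np.ndarray:
        return np.nan_to_num(_rate_array(self.dele, self.k_del))

    def save_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("class\tpattern\trate\n")
            for label, pats in self.snv.items():
                for p, r in pats:
                    fh.write(f"{label}\t{p}\t{r!r}\n")
            for label, pats in (("INS", self.ins), ("DEL", self.dele)):
                for p, r in pats or ():
                    fh.write(f"{label}\t{p}\t{r!r}\n")

    @classmethod
    def load_tsv(cls, path: str | os.PathLike) -> "GroundTruthModel":
        snv: dict[str, list] = {}
        ins: list = []
        dele: list = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                label, pat, rate = line.rstrip("\n").split("\t")
                if label == "INS":
                    ins.append((pat, float(rate)))
                elif label == "DEL":
                    dele.append((pat, float(rate)))
                else:
                    snv.setdefault(label, []).append((pat, float(rate)))
        return cls(snv, ins or None, dele or None)


def example_truth() -> GroundTruthModel:
    """A small, realistic ground truth: 3-mer SNV classes with a 4-pattern
    C->T partition (CpG effect dominating), single-pattern classes for
    the rest, and 2-pattern indel models.  Rates are per-site event
    probabilities on the scale of a large aggregated trio cohort."""
    return GroundTruthModel(
        snv={
            "C>T": [("NCG", 2.0e-2), ("SCH", 6.0e-3), ("ACH", 2.0e-3),
                    ("TCH", 5.0e-4)],
            "C>A": [("NCN", 1.0e-3)],
            "C>G": [("NCN", 8.0e-4)],
            "A>G": [("NAN", 1.2e-3)],
            "A>C": [("NAN", 3.0e-4)],
            "A>T": [("NAN", 4.0e-4)],
        },
        ins=[("NANN", 5.0e-4), ("NBNN", 1.5e-4)],
        dele=[("NAN", 6.0e-4), ("NBN", 2.0e-4)],
    )


def simulate_genome(
    length: int,
    gc_content: float = 0.41,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[ReferenceGenome, RegionMask]:
    """An i.i.d. random genome with the given GC fraction, fully callable."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0 <= gc_content <= 1:
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = "".join(BASES[c] for c in codes)
    genome = ReferenceGenome({chrom: seq})
    return genome, RegionMask.full(genome)


def simulate_snv_mutations(
    genome: ReferenceGenome,
    mask: RegionMask,
    truth: GroundTruthModel,
    seed: int = 0,
) -> list[MutationRecord]:
    """Draw at most one SNV per callable site, each alt with its true
    pattern rate (strand-collapsed), then shuffle the output."""
    rng = np.random.default_rng(seed)
    k = truth.k
    rateA = np.stack([truth.snv_rate_array(c) for c in SNV_CLASSES if c[0] == "A"])
    rateC = np.stack([truth.snv_rate_array(c) for c in SNV_CLASSES if c[0] == "C"])
    records: list[MutationRecord] = []
    for chrom, centers, idx, cbase, keep in _central_collapsed(genome, mask, k):
        idxs = idx[keep]
        cb = cbase[keep]
        pos = centers[keep]
        if not len(idxs):
            continue
        rmat = np.where((cb == 0)[:, None], rateA[:, idxs].T, rateC[:, idxs].T)
        cum = np.cumsum(rmat, axis=1)
        if (cum[:, -1] >= 1).any():
            raise ValueError("total per-site rate >= 1")
        u = rng.random(len(idxs))
        j = (u[:, None] >= cum).sum(axis=1)
        hit = j < 3
        seq = genome[chrom]
        for p, jj, c in zip(pos[hit], j[hit], cb[hit]):
            ref = seq[p]
            alt_coll = _ALTS["A" if c == 0 else "C"][jj]
            alt = complement(alt_coll) if ref in "GT" else alt_coll
            records.append(MutationRecord(chrom, int(p), ref, alt))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def simulate_indel_mutations(
    genome: ReferenceGenome,
    mask: RegionMask,
    truth: GroundTruthModel,
    seed: int = 0,
    ins_lengths: tuple[int, ...] = (1, 2, 3),
    del_lengths: tuple[int, ...] = (1, 2, 3),
) -> list[MutationRecord]:
    """Draw insertions per breakpoint and deletions per start position with
    the true context-pattern rates; lengths uniform over the given sets."""
    rng = np.random.default_rng(seed)
    records: list[MutationRecord] = []
    ins_rate = truth.ins_rate_array() if truth.ins is not None else None
    del_rate = truth.del_rate_array() if truth.dele is not None else None
    for chrom, seq in genome.items():
        codes = encode(seq)
        mb = mask.to_bool(chrom, len(codes))
        if ins_rate is not None:
            k = truth.k_ins
            h = k // 2
            idx, valid = window_indices(codes, k)
            bpos = np.arange(h, h + len(idx))
            sel = valid & mb[bpos] & (bpos >= 1)
            hit = np.zeros(len(idx), dtype=bool)
            hit[sel] = rng.random(int(sel.sum())) < ins_rate[idx[sel]]
            for b in bpos[hit]:
                b = int(b)
                L = int(rng.choice(ins_lengths))
                content = "".join(BASES[c] for c in rng.integers(0, 4, L))
                ref = seq[b - 1]
                if ref == "N":
                    continue
                records.append(MutationRecord(chrom, b - 1, ref, ref + content))
        if del_rate is not None:
            k = truth.k_del
            h = k // 2
            idx, valid = window_indices(codes, k)
            ppos = np.arange(h, h + len(idx))
            sel = valid & mb[ppos] & (ppos >= 1)
            hit = np.zeros(len(idx), dtype=bool)
            hit[sel] = rng.random(int(sel.sum())) < del_rate[idx[sel]]
            for p in ppos[hit]:
                p = int(p)
                L = int(rng.choice(del_lengths))
                if p + L > len(seq):
                    continue
                ref = seq[p - 1:p + L]
                if "N" in ref:
                    continue
                records.append(MutationRecord(chrom, p - 1, ref, seq[p - 1]))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def simulate_mutations(
    genome: ReferenceGenome,
    mask: RegionMask,
    truth: GroundTruthModel,
    seed: int = 0,
) -> list[MutationRecord]:
    """SNVs and indels from named substreams of one master seed."""
    ss = np.random.SeedSequence(seed).spawn(3)
    records = simulate_snv_mutations(genome, mask, truth, ss[0])
    if truth.ins is not None or truth.dele is not None:
        records += simulate_indel_mutations(genome, mask, truth, ss[1])
    rng = np.random.default_rng(ss[2])
    order = rng.permutation(len(records))
    return [records[i] for i in order]


# --- transcriptome ----------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[c] for c in rng.choice(4, size=n, p=p))


def simulate_transcriptome(
    n_transcripts: int = 8,
    seed: int = 0,
    codon_range: tuple[int, int] = (40, 90),
    exon_range: tuple[int, int] = (2, 4),
    intron_range: tuple[int, int] = (30, 80),
    gap_range: tuple[int, int] = (80, 160),
    gc: float = 0.45,
    chrom: str = "chr1",
) -> tuple[ReferenceGenome, RegionMask, list[TranscriptModel], str]:
    """Non-overlapping multi-exon transcripts with valid start/stop codons
    and GT-AG introns, embedded in a random genome.

    Returns (genome, full mask, transcript models, GTF text).
    """
    from .sequence_io import write_gtf

    rng = np.random.default_rng(seed)
    pieces: list[str] = [_random_seq(rng, int(rng.integers(*gap_range)), gc)]
    cursor = len(pieces[0])
    transcripts: list[TranscriptModel] = []

    for i in range(n_transcripts):
        n_cod = int(rng.integers(codon_range[0], codon_range[1] + 1))
        body = "".join(_NON_STOP[j] for j in rng.integers(0, len(_NON_STOP),
                                                          n_cod - 2))
        cds = "ATG" + body + STOP_CODONS[int(rng.integers(3))]
        n_ex = int(rng.integers(exon_range[0], exon_range[1] + 1))
        n_ex = min(n_ex, len(cds))
        cuts = np.sort(rng.choice(np.arange(1, len(cds)), size=n_ex - 1,
                                  replace=False)) if n_ex > 1 else np.empty(0, int)
        bounds = [0, *cuts.tolist(), len(cds)]
        exons = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
        introns = ["GT" + _random_seq(rng, int(rng.integers(*intron_range)) - 4, gc)
                   + "AG" for _ in range(n_ex - 1)]

        local: list[tuple[int, int]] = []
        parts: list[str] = []
        off = 0
        for j, ex in enumerate(exons):
            local.append((off, off + len(ex)))
            parts.append(ex)
            off += len(ex)
            if j < len(introns):
                parts.append(introns[j])
                off += len(introns[j])
        pre = "".join(parts)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            segment = pre
            iv = [(cursor + s, cursor + e) for s, e in local]
        else:
            segment = revcomp(pre)
            glen = len(pre)
            iv = [(cursor + glen - e, cursor + glen - s) for s, e in local]
            iv.sort()
        transcripts.append(TranscriptModel(f"T{i:04d}", chrom, strand, iv))
        pieces.append(segment)
        cursor += len(segment)
        gap = _random_seq(rng, int(rng.integers(*gap_range)), gc)
        pieces.append(gap)
        cursor += len(gap)

    genome = ReferenceGenome({chrom: "".join(pieces)})
    for t in transcripts:
        t.validate(genome)
    return genome, RegionMask.full(genome), transcripts, write_gtf(transcripts)


def simulate_gene_observations(site_table, n_gen: float, seed: int = 0) -> dict[str, int]:
    """Draw observed per-category counts from a transcript's own site
    probabilities (one Bernoulli per possible mutation): the null model
    of the burden test."""
    from .genic_expectation import CATEGORIES, generation_scale

    rng = np.random.default_rng(seed)
    out = {c: 0 for c in CATEGORIES}
    for cat, grp in site_table.df.groupby("category"):
        p = generation_scale(grp["r"].to_numpy(), n_gen)
        out[str(cat)] = int((rng.random(len(p)) < p).sum())
    return out
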