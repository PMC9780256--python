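"""Mutated / background k-mer count tables per mutation class.

For point mutations each callable position with an N-free k-mer window
contributes an *unmutated* count to the three substitution tables sharing
its central base; central purines are strand-collapsed (k-mer reverse
complemented, alleles complemented) so only the six classes with central
A or C remain.  An observed SNV moves one count from unmutated to mutated
in exactly one table.

Indels are represented by breakpoint context k-mers.  Because the exact
breakpoint of an indel is usually ambiguous (any placement that yields
the same alternative sequence is equivalent), we enumerate all equivalent
placements and pick one at random per event, with the choice derived from
the event itself so counting is independent of input order.  Insertion
contexts are the k/2 bases on each side of the inter-base breakpoint
(k even); deletion contexts are odd k-mers centered on the first and last
deleted base, and every context is counted together with its reverse
complement, which makes the start/end bookkeeping strand-symmetric.
"""

from __future__ import annotations

import os
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .dna import (
    BASES,
    complement,
    encode,
    index_to_kmer,
    kmer_index,
    revcomp,
    revcomp_index_table,
    window_indices,
)
from .sequence_io import DEL, INS, SNV, MutationRecord, ReferenceGenome, RegionMask

SNV_CLASSES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")
INDEL_CLASSES = ("INS", "DEL")
FRAME_CLASSES = ("INS_3n", "INS_non3n", "DEL_3n", "DEL_non3n")

MAX_SNV_K = 11


@dataclass
class KmerCountTable:
    """Counts of mutated (m) and background/unmutated (u) events per k-mer.

    ``m`` and ``u`` are dense int64 arrays over all 4**k k-mer indices;
    for SNV tables only indices whose central base is the class's
    (collapsed) reference base carry counts.
    """

    k: int
    mut_class: str
    m: np.ndarray = field(default=None)
    u: np.ndarray = field(default=None)

    def __post_init__(self):
        n = 4 ** self.k
        if self.m is None:
            self.m = np.zeros(n, dtype=np.int64)
        if self.u is None:
            self.u = np.zeros(n, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        self.u = np.asarray(self.u, dtype=np.int64)
        if self.m.shape != (n,) or self.u.shape != (n,):
            raise ValueError("count arrays must have length 4**k")
        if (self.m < 0).any() or (self.u < 0).any():
            raise ValueError("negative counts")

    @property
    def mu(self) -> float:
        """Overall mutation rate: sum(m) / sum(m + u)."""
        tot = int(self.m.sum() + self.u.sum())
        return float(self.m.sum()) / tot if tot else float("nan")

    @property
    def total_mutated(self) -> int:
        return int(self.m.sum())

    @property
    def total_sites(self) -> int:
        return int(self.m.sum() + self.u.sum())

    def items(self, nonzero_only: bool = True):
        """Yield (kmer, m, u) triples."""
        idx = np.nonzero(self.m + self.u)[0] if nonzero_only else range(4 ** self.k)
        for i in idx:
            yield index_to_kmer(int(i), self.k), int(self.m[i]), int(self.u[i])

    def copy_empty(self) -> "KmerCountTable":
        return KmerCountTable(self.k, self.mut_class)

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"#mut_class={self.mut_class}\n#k={self.k}\n")
            fh.write("kmer\tmutated_count\tbackground_count\n")
            for kmer, m, u in self.items():
                fh.write(f"{kmer}\t{m}\t{u}\n")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "KmerCountTable":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    meta[key] = val
                elif line and not line.startswith("kmer\t"):
                    kmer, m, u = line.split("\t")
                    rows.append((kmer, int(m), int(u)))
        k = int(meta["k"])
        t = cls(k, meta.get("mut_class", "?"))
        for kmer, m, u in rows:
            t.m[kmer_index(kmer)] = m
            t.u[kmer_index(kmer)] = u
        return t


def _central_collapsed(genome: ReferenceGenome, mask: RegionMask, k: int):
    """Per chromosome: collapsed k-mer index, collapsed central base code
    (0=A, 1=C) and validity for every maskable position."""
    h = k // 2
    rc = revcomp_index_table(k)
    for chrom, seq in genome.items():
        codes = encode(seq)
        idx, valid = window_indices(codes, k)
        if not len(idx):
            continue
        centers = np.arange(h, len(codes) - h)
        central = codes[centers]
        in_mask = mask.to_bool(chrom, len(codes))[centers]
        keep = valid & in_mask & (central < 4)
        idx = idx.copy()
        flip = (central == 2) | (central == 3)  # G or T -> reverse complement
        idx[flip] = rc[idx[flip]]
        cbase = np.where(flip, 3 - central, central)  # ->0 (A) or 1 (C)
        yield chrom, centers, idx, cbase, keep


def count_snv_kmers(
    mutations: list[MutationRecord],
    genome: ReferenceGenome,
    mask: RegionMask,
    k: int,
) -> dict[str, KmerCountTable]:
    """Build the six strand-collapsed SNV count tables.

    Every masked, N-free position contributes an unmutated count to each
    of the three tables for its collapsed central base; each observed SNV
    inside the mask adds a mutated count to its table and removes that
    site's unmutated contribution there (once per site and table).
    """
    if k % 2 == 0 or k < 1 or k > MAX_SNV_K:
        raise ValueError(f"k must be odd and 1 <= k <= {MAX_SNV_K}, got {k}")
    h = k // 2
    tables = {c: KmerCountTable(k, c) for c in SNV_CLASSES}

    bg = {0: np.zeros(4 ** k, dtype=np.int64), 1: np.zeros(4 ** k, dtype=np.int64)}
    for chrom, centers, idx, cbase, keep in _central_collapsed(genome, mask, k):
        for b in (0, 1):
            sel = keep & (cbase == b)
            if sel.any():
                bg[b] += np.bincount(idx[sel], minlength=4 ** k)
    for c in SNV_CLASSES:
        tables[c].u[:] = bg[0] if c[0] == "A" else bg[1]

    n_skipped = 0
    dec: dict[str, set[tuple[str, int]]] = {c: set() for c in SNV_CLASSES}
    for rec in mutations:
        if rec.mut_class != SNV:
            continue
        if not mask.contains(rec.chrom, rec.pos0):
            continue
        window = genome.fetch(rec.chrom, rec.pos0 - h, rec.pos0 + h + 1)
        if len(window) != k or "N" in window:
            n_skipped += 1
            continue
        if window[h] != rec.ref:
            warnings.warn(f"ref mismatch at {rec.chrom}:{rec.pos}; record skipped",
                          stacklevel=2)
            n_skipped += 1
            continue
        if rec.ref in "GT":
            kmer, alt = revcomp(window), complement(rec.alt)
        else:
            kmer, alt = window, rec.alt
        label = f"{kmer[h]}>{alt}"
        tables[label].m[kmer_index(kmer)] += 1
        dec[label].add((rec.chrom, rec.pos0))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} SNV(s) with unusable context",
                      stacklevel=2)

    # remove each mutated site's unmutated contribution (at most once per site)
    for label, sites in dec.items():
        t = tables[label]
        for chrom, pos0 in sites:
            window = genome.fetch(chrom, pos0 - h, pos0 + h + 1)
            kmer = revcomp(window) if window[h] in "GT" else window
            i = kmer_index(kmer)
            if t.u[i] > 0:
                t.u[i] -= 1
    return tables


# --- indels ----------------------------------------------------------------


def enumerate_indel_placements(rec: MutationRecord, genome: ReferenceGenome) -> list[int]:
    """Equivalent breakpoints of an indel on its chromosome.

    For deletions: all 0-based start positions s such that removing
    ``len`` bases at s yields the observed alternative sequence.  For
    insertions: all 0-based inter-base positions b (insertion before base
    b) that yield it.  Equivalent placements form a contiguous range; the
    left-aligned placement is always included.
    """
    seq = genome[rec.chrom]
    if rec.mut_class == DEL:
        L = rec.indel_length
        s = rec.pos0 + 1  # first deleted base
        lo = s
        while lo - 1 >= 0 and seq[lo - 1] == seq[lo + L - 1]:
            lo -= 1
        hi = s
        while hi + L < len(seq) and seq[hi] == seq[hi + L]:
            hi += 1
        return list(range(lo, hi + 1))
    if rec.mut_class == INS:
        ins = rec.alt[1:]
        b = rec.pos0 + 1  # insertion before this base
        lo, cur = b, ins
        while lo - 1 >= 0 and seq[lo - 1] == cur[-1]:
            cur = cur[-1] + cur[:-1]
            lo -= 1
        hi, cur = b, ins
        while hi < len(seq) and seq[hi] == cur[0]:
            cur = cur[1:] + cur[0]
            hi += 1
        return list(range(lo, hi + 1))
    raise ValueError("record is not an indel")


def _record_rng(seed: int, rec: MutationRecord) -> np.random.Generator:
    h = zlib.crc32(f"{rec.chrom}:{rec.pos0}:{rec.ref}:{rec.alt}".encode())
    return np.random.default_rng([int(seed), h])


def _indel_backgrounds(genome, mask, k_ins, k_del):
    """Background u arrays: every masked breakpoint context + its revcomp."""
    u_ins = np.zeros(4 ** k_ins, dtype=np.int64)
    u_del = np.zeros(4 ** k_del, dtype=np.int64)
    rc_i = revcomp_index_table(k_ins)
    rc_d = revcomp_index_table(k_del)
    hi = k_ins // 2
    hd = k_del // 2
    for chrom, seq in genome.items():
        codes = encode(seq)
        mb = mask.to_bool(chrom, len(codes))
        # insertions: window [b-hi, b+hi) around inter-base breakpoint b;
        # breakpoint b is in the mask iff base b is
        idx, valid = window_indices(codes, k_ins)
        if len(idx):
            b = np.arange(hi, hi + len(idx))  # breakpoint of window starting at b-hi
            sel = valid & mb[b]
            cnt = np.bincount(idx[sel], minlength=4 ** k_ins)
            u_ins += cnt + cnt[rc_i]  # rc is an involution: cnt[rc] adds each
            # window's reverse-complement contribution
        # deletions: odd window centered on each masked base
        idx, valid = window_indices(codes, k_del)
        if len(idx):
            centers = np.arange(hd, hd + len(idx))
            sel = valid & mb[centers]
            cnt = np.bincount(idx[sel], minlength=4 ** k_del)
            u_del += cnt + cnt[rc_d]
    return u_ins, u_del


def count_indel_kmers(
    mutations: list[MutationRecord],
    genome: ReferenceGenome,
    mask: RegionMask,
    k_ins: int = 4,
    k_del: int = 5,
    seed: int = 0,
    split_by_frame: bool = False,
    max_indel_length: int = 50,
) -> dict[str, KmerCountTable]:
    """Build insertion and deletion breakpoint k-mer tables.

    One equivalent placement per event is chosen at random; the choice is
    derived from (seed, chrom, pos, ref, alt) so results do not depend on
    input order.  Each insertion adds its breakpoint k-mer and reverse
    complement (2 mutated counts); each deletion adds start and end
    k-mers, each with its reverse complement (4 mutated counts).  With
    ``split_by_frame`` the same procedure is restricted to events whose
    length is / is not a multiple of 3.
    """
    if k_ins % 2 != 0 or k_ins < 2:
        raise ValueError("insertion context k must be even and >= 2")
    if k_del % 2 != 1 or k_del < 1:
        raise ValueError("deletion context k must be odd and >= 1")

    u_ins, u_del = _indel_backgrounds(genome, mask, k_ins, k_del)
    labels = FRAME_CLASSES if split_by_frame else INDEL_CLASSES
    tables: dict[str, KmerCountTable] = {}
    for lab in labels:
        k = k_ins if lab.startswith("INS") else k_del
        t = KmerCountTable(k, lab)
        t.u[:] = u_ins if lab.startswith("INS") else u_del
        tables[lab] = t

    hi, hd = k_ins // 2, k_del // 2
    n_skipped = 0
    for rec in mutations:
        cls = rec.mut_class
        if cls not in (INS, DEL):
            continue
        if rec.indel_length > max_indel_length:
            warnings.warn(f"indel at {rec.chrom}:{rec.pos} longer than "
                          f"{max_indel_length} bp skipped", stacklevel=2)
            continue
        if not mask.contains(rec.chrom, rec.pos0):
            continue
        placements = enumerate_indel_placements(rec, genome)
        rng = _record_rng(seed, rec)
        choice = int(placements[rng.integers(len(placements))])
        frame = "3n" if rec.indel_length % 3 == 0 else "non3n"
        if cls == INS:
            lab = f"INS_{frame}" if split_by_frame else "INS"
            if lab not in tables:
                continue
            ctx = genome.fetch(rec.chrom, choice - hi, choice + hi)
            if len(ctx) != k_ins or "N" in ctx:
                n_skipped += 1
                continue
            t = tables[lab]
            t.m[kmer_index(ctx)] += 1
            t.m[kmer_index(revcomp(ctx))] += 1
        else:
            lab = f"DEL_{frame}" if split_by_frame else "DEL"
            if lab not in tables:
                continue
            L = rec.indel_length
            start = genome.fetch(rec.chrom, choice - hd, choice + hd + 1)
            end = genome.fetch(rec.chrom, choice + L - 1 - hd, choice + L + hd)
            if len(start) != k_del or len(end) != k_del or "N" in start or "N" in end:
                n_skipped += 1
                continue
            t = tables[lab]
            for ctx in (start, end):
                t.m[kmer_index(ctx)] += 1
                t.m[kmer_index(revcomp(ctx))] += 1
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} indel(s) with unusable context",
                      stacklevel=2)
    return tables
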