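"""Reading and validating the standard inputs: FASTA genomes, BED masks,
VCF/TSV mutation lists and GTF/GFF3 transcript annotations.

Internally every coordinate is 0-based half-open, matching BED; 1-based
VCF/GTF positions are converted on read.  The callable-region mask
supports the interval algebra (union on read, subtraction, intersection)
needed to restrict k-mer counting to callable sites.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dna import revcomp  # noqa: F401  (re-exported convenience)

_VALID = set("ACGTN")


class ReferenceGenome:
    """An in-memory reference: chromosome name -> uppercase ACGTN string."""

    def __init__(self, sequences: dict[str, str]):
        norm = {}
        for name, seq in sequences.items():
            if name in norm:
                raise ValueError(f"duplicate chromosome name {name!r}")
            s = seq.upper()
            if set(s) - _VALID:
                # ambiguity letters in a reference are uncallable for our purposes
                s = "".join(b if b in _VALID else "N" for b in s)
            norm[name] = s
        self.sequences = norm

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    def items(self):
        return self.sequences.items()

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice, clipped to the chromosome."""
        seq = self.sequences[chrom]
        return seq[max(start, 0):min(end, len(seq))]

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ReferenceGenome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def write_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Sort and union a (n, 2) array of half-open intervals."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


@dataclass
class RegionMask:
    """Per-chromosome sorted, non-overlapping 0-based half-open intervals."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.intervals = {
            c: np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            for c, iv in self.intervals.items()
        }
        for c, iv in self.intervals.items():
            if len(iv) and not ((iv[:, 0] < iv[:, 1]).all()
                                and (iv[1:, 0] >= iv[:-1, 1]).all()):
                raise ValueError(f"intervals for {c} not sorted/non-overlapping")

    @property
    def total_size(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    @classmethod
    def from_intervals(cls, raw: dict[str, list[tuple[int, int]]]) -> "RegionMask":
        return cls({c: _merge_intervals(np.asarray(iv, dtype=np.int64).reshape(-1, 2))
                    for c, iv in raw.items() if len(iv)})

    @classmethod
    def from_bed(cls, path: str | os.PathLike) -> "RegionMask":
        raw: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 3:
                    raise ValueError(f"{path}: line {lineno}: expected >= 3 columns")
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
                if start < 0 or end <= start:
                    raise ValueError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
                raw.setdefault(chrom, []).append((start, end))
        return cls.from_intervals(raw)

    @classmethod
    def full(cls, genome: ReferenceGenome) -> "RegionMask":
        return cls({c: np.array([[0, len(s)]], dtype=np.int64)
                    for c, s in genome.items()})

    def write_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a single 0-based position."""
        iv = self.intervals.get(chrom)
        if iv is None or not len(iv):
            return False
        i = np.searchsorted(iv[:, 0], pos, side="right") - 1
        return i >= 0 and pos < iv[i, 1]

    def to_bool(self, chrom: str, length: int) -> np.ndarray:
        """Dense membership array for one chromosome."""
        out = np.zeros(length, dtype=bool)
        for s, e in self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64)):
            out[max(s, 0):min(e, length)] = True
        return out

    def intersect(self, other: "RegionMask") -> "RegionMask":
        out = {}
        for chrom in self.intervals:
            if chrom not in other.intervals:
                continue
            a, b = self.intervals[chrom], other.intervals[chrom]
            res, i, j = [], 0, 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    res.append((s, e))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if res:
                out[chrom] = np.asarray(res, dtype=np.int64)
        return RegionMask(out)

    def subtract(self, other: "RegionMask") -> "RegionMask":
        """Bases in self and not in other."""
        out = {}
        for chrom, a in self.intervals.items():
            b = other.intervals.get(chrom)
            if b is None or not len(b):
                if len(a):
                    out[chrom] = a.copy()
                continue
            res = []
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j, 1] <= cur:
                    j += 1
                jj = j
                while jj < len(b) and b[jj, 0] < e:
                    if b[jj, 0] > cur:
                        res.append((cur, b[jj, 0]))
                    cur = max(cur, b[jj, 1])
                    jj += 1
                if cur < e:
                    res.append((cur, e))
            if res:
                out[chrom] = np.asarray(res, dtype=np.int64)
        return RegionMask(out)


def subtract_mask(a: RegionMask, b: RegionMask) -> RegionMask:
    return a.subtract(b)


def read_mask(path: str | os.PathLike) -> RegionMask:
    return RegionMask.from_bed(path)


SNV, INS, DEL = "SNV", "INS", "DEL"


@dataclass(frozen=True)
class MutationRecord:
    """One normalized SNV or short indel (VCF anchor-base convention).

    ``pos0`` is the 0-based position of the first reference base; ``pos``
    exposes the familiar 1-based coordinate.
    """

    chrom: str
    pos0: int
    ref: str
    alt: str

    @property
    def pos(self) -> int:
        return self.pos0 + 1

    @property
    def mut_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNV
        if len(self.ref) == 1 and len(self.alt) > 1 and self.alt[0] == self.ref:
            return INS
        if len(self.alt) == 1 and len(self.ref) > 1 and self.ref[0] == self.alt:
            return DEL
        raise ValueError(f"unclassifiable record {self}")

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    def __post_init__(self):
        if self.pos0 < 0:
            raise ValueError("negative position")
        if not self.ref or not self.alt:
            raise ValueError("empty allele")
        if self.ref == self.alt:
            raise ValueError("ref == alt")


def _looks_like_vcf(path: str) -> bool:
    if str(path).endswith((".vcf", ".vcf.gz")):
        return True
    with open(path, "rb") as fh:
        head = fh.read(64)
    return head.startswith(b"##fileformat=VCF")


def _classifiable(ref: str, alt: str) -> bool:
    if len(ref) == 1 and len(alt) == 1:
        return ref != alt
    if len(ref) == 1 and len(alt) > 1:
        return alt[0] == ref
    if len(alt) == 1 and len(ref) > 1:
        return ref[0] == alt
    return False


def read_mutations(
    path: str | os.PathLike,
    genome: ReferenceGenome | None = None,
    normalize_chrom: bool = False,
) -> list[MutationRecord]:
    """Read SNVs and short indels from a VCF or headered TSV.

    Multi-allelic VCF records are split per alt.  Symbolic alleles,
    non-ACGT alleles and complex substitutions are skipped with a warning;
    when a genome is given, records whose ref does not match it are
    rejected and the rejection count reported.
    """
    rows: list[tuple[str, int, str, str]] = []
    if _looks_like_vcf(str(path)):
        import pysam

        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    rows.append((rec.chrom, rec.pos, rec.ref, alt))
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
        cols = {c.lower(): c for c in df.columns}
        try:
            cc, pc, rc, ac = (cols[x] for x in ("chrom", "pos", "ref", "alt"))
        except KeyError as exc:
            raise ValueError(f"{path}: TSV must have chrom/pos/ref/alt header") from exc
        for r in df.itertuples(index=False):
            rows.append((str(getattr(r, cc)), int(getattr(r, pc)),
                         str(getattr(r, rc)), str(getattr(r, ac))))

    records: list[MutationRecord] = []
    n_symbolic = n_nonacgt = n_complex = n_refmismatch = n_badchrom = 0
    for chrom, pos1, ref, alt in rows:
        if normalize_chrom and genome is not None and chrom not in genome:
            alias = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
            if alias in genome:
                chrom = alias
        if alt.startswith("<") or "[" in alt or "]" in alt or alt in (".", "*"):
            n_symbolic += 1
            continue
        ref, alt = ref.upper(), alt.upper()
        if set(ref) - set("ACGT") or set(alt) - set("ACGT"):
            n_nonacgt += 1
            continue
        if not _classifiable(ref, alt):
            n_complex += 1
            continue
        if genome is not None:
            if chrom not in genome:
                n_badchrom += 1
                continue
            if genome.fetch(chrom, pos1 - 1, pos1 - 1 + len(ref)) != ref:
                n_refmismatch += 1
                continue
        records.append(MutationRecord(chrom, pos1 - 1, ref, alt))

    for n, what in ((n_symbolic, "symbolic-allele"), (n_nonacgt, "non-ACGT"),
                    (n_complex, "complex/MNV"), (n_refmismatch, "reference-mismatch"),
                    (n_badchrom, "unknown-chromosome")):
        if n:
            warnings.warn(f"{path}: skipped {n} {what} record(s)", stacklevel=2)
    return records


def write_mutations(records: list[MutationRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\n")


def filter_mutations(records: list[MutationRecord], mask: RegionMask) -> list[MutationRecord]:
    """Keep records whose anchor base lies inside the mask."""
    return [r for r in records if mask.contains(r.chrom, r.pos0)]


# --- transcript annotation -------------------------------------------------

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptModel:
    """A protein-coding transcript: ordered genomic CDS intervals.

    ``cds_intervals`` are 0-based half-open and sorted by genomic start
    regardless of strand; coding order is derived from ``strand``.
    ``canonical`` is False when the translated CDS violates the
    start/stop-codon convention (a warning, not an error).
    """

    transcript_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    canonical: bool = True

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        iv = sorted((int(s), int(e)) for s, e in self.cds_intervals)
        for s, e in iv:
            if e <= s:
                raise ValueError("empty CDS interval")
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            if s2 < e1:
                raise ValueError("overlapping CDS intervals")
        self.cds_intervals = iv

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def coding_positions(self) -> np.ndarray:
        """Genomic positions of coding bases, in coding (5'->3') order."""
        parts = [np.arange(s, e) for s, e in self.cds_intervals]
        pos = np.concatenate(parts)
        return pos[::-1] if self.strand == "-" else pos

    def coding_sequence(self, genome: ReferenceGenome) -> str:
        seq = "".join(genome.fetch(self.chrom, s, e) for s, e in self.cds_intervals)
        return revcomp(seq) if self.strand == "-" else seq

    def splice_site_positions(self) -> list[int]:
        """Genomic positions of the 2 intronic bases on each side of every
        internal CDS junction (essential splice sites)."""
        out: list[int] = []
        for (s1, e1), (s2, e2) in zip(self.cds_intervals, self.cds_intervals[1:]):
            out.extend([e1, e1 + 1, s2 - 2, s2 - 1])
        return sorted(set(out))

    def footprint(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def validate(self, genome: ReferenceGenome) -> "TranscriptModel":
        """Check the coding invariants; flag non-canonical with warnings."""
        ok = True
        if self.cds_length % 3 != 0:
            warnings.warn(f"{self.transcript_id}: CDS length not a multiple of 3",
                          stacklevel=2)
            ok = False
        else:
            cds = self.coding_sequence(genome)
            if cds[:3] != "ATG":
                warnings.warn(f"{self.transcript_id}: CDS does not start with ATG",
                              stacklevel=2)
                ok = False
            if cds[-3:] not in STOP_CODONS:
                warnings.warn(f"{self.transcript_id}: CDS does not end with a stop codon",
                              stacklevel=2)
                ok = False
        self.canonical = ok
        return self


def read_transcripts(
    path: str | os.PathLike,
    genome: ReferenceGenome | None = None,
) -> list[TranscriptModel]:
    """Read transcript models from the CDS features of a GTF or GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        if "transcript_id" in feat.attributes:
            tid = feat.attributes["transcript_id"][0]
        elif "Parent" in feat.attributes:
            tid = feat.attributes["Parent"][0]
        else:
            raise ValueError(f"CDS feature without transcript_id/Parent at "
                             f"{feat.seqid}:{feat.start}")
        g = grouped.setdefault(tid, {"chrom": feat.seqid, "strand": feat.strand,
                                     "iv": []})
        g["iv"].append((feat.start - 1, feat.end))  # GTF is 1-based inclusive

    models = []
    for tid, g in grouped.items():
        t = TranscriptModel(tid, g["chrom"], g["strand"], g["iv"])
        if genome is not None:
            t.validate(genome)
        models.append(t)
    return models


def write_gtf(transcripts: list[TranscriptModel], path: str | os.PathLike | None = None) -> str:
    """Write transcripts as GTF CDS features; returns the text."""
    buf = io.StringIO()
    for t in transcripts:
        iv = t.cds_intervals if t.strand == "+" else t.cds_intervals[::-1]
        phase = 0
        for s, e in iv:
            attrs = f'gene_id "{t.transcript_id}"; transcript_id "{t.transcript_id}";'
            buf.write(f"{t.chrom}\tpatmut\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t{phase}\t{attrs}\n")
            phase = (3 - ((e - s) - phase) % 3) % 3
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
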