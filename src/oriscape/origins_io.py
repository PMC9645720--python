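"""Readers, writers and the origin-centered window coordinate frame.

Replication origins arrive as BED3+ intervals (optional name and per-origin
firing efficiency columns), variants as VCF, the genome as FASTA, and
numeric tracks as bedGraph.  Everything downstream works in one coordinate
convention: 0-based half-open internally, with VCF's 1-based positions
converted at the I/O boundary.

The central object is :class:`OriginDomainSet`: every origin midpoint anchors
a domain of ``2 * half_width`` bases split into fixed windows (200 windows of
100 bp at the defaults), and all profile machinery aggregates over that frame.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._seq import encode

log = logging.getLogger(__name__)

ORIGIN_CLASSES = ("stochastic", "core", "constitutive")
EFFICIENCY_BINS = ("low", "medium", "high")


class BedParseError(ValueError):
    """Raised for malformed BED lines; message names the line number."""


@dataclass
class OriginRecord:
    """A replication origin interval with optional firing efficiency.

    ``start``/``end`` are 0-based half-open; ``midpoint`` is the floor of the
    interval center and anchors the origin's windowed domain.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    origin_class: str = "constitutive"
    efficiency: Optional[float] = None
    efficiency_bin: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"origin {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.origin_class not in ORIGIN_CLASSES:
            raise ValueError(f"unknown origin class {self.origin_class!r}")
        if self.efficiency_bin is not None and self.efficiency is None:
            raise ValueError("efficiency_bin requires efficiency")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class VariantRecord:
    """A single SNV or simple indel; ``pos`` is the 1-based reference start."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) == 1 and len(self.alt) > 1:
            return "insertion"
        if len(self.alt) == 1 and len(self.ref) > 1:
            return "deletion"
        raise ValueError(f"unsupported allele pair {self.ref}>{self.alt}")


class Genome:
    """In-memory genome with 0-based half-open ``fetch``.

    Holds uppercase sequences; suitable for desk-scale assemblies (tens of
    megabases).  Use :meth:`from_fasta` for files.
    """

    def __init__(self, sequences: Dict[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}
        self._codes: Dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chroms(self) -> List[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][max(start, 0):end]

    def codes(self, chrom: str) -> np.ndarray:
        """Encoded chromosome (A=0,C=1,G=2,T=3; other=255), cached."""
        if chrom not in self._codes:
            self._codes[chrom] = encode(self._seqs[chrom])
        return self._codes[chrom]


@dataclass
class CoverageTrack:
    """Interval-valued track per chromosome (bedGraph semantics).

    ``intervals[chrom]`` is a (starts, ends, values) triple of aligned arrays,
    sorted and non-overlapping within each chromosome.
    """

    intervals: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for chrom, (s, e, v) in self.intervals.items():
            if len(s) and (np.any(e[:-1] > s[1:]) or np.any(s >= e)):
                raise ValueError(f"track intervals overlap or are empty on {chrom}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite track values on {chrom}")

    @classmethod
    def from_lists(cls, records: Iterable[Tuple[str, int, int, float]]) -> "CoverageTrack":
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        out = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            s = np.array([r[0] for r in rows], dtype=np.int64)
            e = np.array([r[1] for r in rows], dtype=np.int64)
            v = np.array([r[2] for r in rows], dtype=float)
            out[chrom] = (s, e, v)
        return cls(out)


@dataclass
class OriginDomainSet:
    """Origins plus the fixed window frame centered on their midpoints.

    Window ``w`` (0-based) of origin ``i`` covers
    ``[midpoint - half_width + w*window_size, ... + (w+1)*window_size)``.
    """

    origins: List[OriginRecord]
    half_width: int = 10_000
    window_size: int = 100
    _index: Dict[str, Tuple[List[int], List[int]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if (2 * self.half_width) % self.window_size:
            raise ValueError("2*half_width must be a multiple of window_size")
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for i, o in enumerate(self.origins):
            by_chrom.setdefault(o.chrom, []).append((o.midpoint, i))
        index = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            index[chrom] = ([m for m, _ in pairs], [i for _, i in pairs])
        self._index = index

    @property
    def n_windows(self) -> int:
        return 2 * self.half_width // self.window_size

    def __len__(self) -> int:
        return len(self.origins)

    def domain_bounds(self, i: int) -> Tuple[int, int]:
        m = self.origins[i].midpoint
        return m - self.half_width, m + self.half_width

    def window_offsets(self) -> np.ndarray:
        """Genomic offset of each window center relative to the midpoint."""
        w = np.arange(self.n_windows)
        return -self.half_width + w * self.window_size + self.window_size / 2

    def assign(self, chrom: str, pos: int) -> Optional[Tuple[int, int]]:
        """Map a 0-based position to (origin index, window index), or None.

        When domains overlap, the origin with the nearest midpoint wins.
        """
        entry = self._index.get(chrom)
        if entry is None:
            return None
        mids, idxs = entry
        j = bisect_left(mids, pos)
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(mids):
                d = abs(pos - mids[k])
                if best is None or d < best[0]:
                    best = (d, k)
        if best is None:
            return None
        _, k = best
        offset = pos - (mids[k] - self.half_width)
        if not 0 <= offset < 2 * self.half_width:
            return None
        return idxs[k], offset // self.window_size

    def assign_many(
        self, chrom: str, positions: np.ndarray
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Vectorized :meth:`assign`; unassigned positions get index -1."""
        entry = self._index.get(chrom)
        n = len(positions)
        if entry is None or n == 0:
            return np.full(n, -1), np.full(n, -1)
        mids = np.asarray(entry[0], dtype=np.int64)
        idxs = np.asarray(entry[1], dtype=np.int64)
        positions = np.asarray(positions, dtype=np.int64)
        j = np.searchsorted(mids, positions)
        left = np.clip(j - 1, 0, len(mids) - 1)
        right = np.clip(j, 0, len(mids) - 1)
        dl = np.abs(positions - mids[left])
        dr = np.abs(positions - mids[right])
        k = np.where(dl <= dr, left, right)
        offset = positions - (mids[k] - self.half_width)
        ok = (offset >= 0) & (offset < 2 * self.half_width)
        oi = np.where(ok, idxs[k], -1)
        wi = np.where(ok, offset // self.window_size, -1)
        return oi, wi


def assign_windows(domainset: OriginDomainSet, chrom: str, pos: int):
    """Functional form of :meth:`OriginDomainSet.assign` (0-based pos)."""
    return domainset.assign(chrom, pos)


# ---------------------------------------------------------------------------
# BED / bedGraph / VCF / FASTA I/O
# ---------------------------------------------------------------------------

def load_origins(path, origin_class: str = "constitutive") -> List[OriginRecord]:
    """Read a BED3+ origins file (col 4 = name, col 5 = efficiency)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            eff = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    eff = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad efficiency") from exc
            try:
                rec = OriginRecord(
                    fields[0], start, end, name=name,
                    origin_class=origin_class, efficiency=eff,
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.start))
    return records


def write_origins(records: Sequence[OriginRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            eff = "." if r.efficiency is None else repr(r.efficiency)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t{eff}\n")


def load_bedgraph(path) -> CoverageTrack:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return CoverageTrack.from_lists(rows)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            s, e, v = track.intervals[chrom]
            for i in range(len(s)):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")


def load_variants(path) -> Tuple[List[VariantRecord], Dict[str, int]]:
    """Read SNVs and simple indels from a VCF.

    Multi-allelic records and alleles containing non-ACGT characters are
    skipped; the second return value counts what was skipped and why.
    """
    import pysam

    skipped = {"multiallelic": 0, "non_acgt": 0, "complex": 0}
    out: List[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                skipped["multiallelic"] += 1
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if set(ref) - set("ACGT") or set(alt) - set("ACGT"):
                skipped["non_acgt"] += 1
                continue
            if len(ref) > 1 and len(alt) > 1:
                skipped["complex"] += 1
                continue
            out.append(VariantRecord(rec.chrom, rec.pos, ref, alt))
    if any(skipped.values()):
        log.info("load_variants skipped records: %s", skipped)
    return out, skipped


def write_vcf(variants: Sequence[VariantRecord], path, contigs=None) -> None:
    """Write a minimal valid VCF v4.2 (sites only)."""
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen = contigs if contigs is not None else sorted({v.chrom for v in variants})
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")


def write_fasta(sequences: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def load_config(path) -> Dict[str, str]:
    """Parse a flat ``key = value`` configuration file."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# Origin set operations
# ---------------------------------------------------------------------------

@dataclass
class MergeReport:
    shared: int
    a_only: int
    b_only: int
    pairs: List[Tuple[int, int]]


def _interval_gap(a: OriginRecord, b: OriginRecord) -> int:
    if a.chrom != b.chrom:
        return np.iinfo(np.int64).max
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def merge_same_origin(
    set_a: Sequence[OriginRecord],
    set_b: Sequence[OriginRecord],
    max_dist: int = 5_000,
) -> MergeReport:
    """Match origins across two maps that represent the same initiation site.

    Two origins are the same site iff the gap between their intervals is
    strictly below ``max_dist``.  Matching is nearest-first and one-to-one.
    """
    candidates = []
    b_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for j, b in enumerate(set_b):
        b_by_chrom.setdefault(b.chrom, []).append((b.start, j))
    for chrom in b_by_chrom:
        b_by_chrom[chrom].sort()
    for i, a in enumerate(set_a):
        entries = b_by_chrom.get(a.chrom, [])
        for s, j in entries:
            if s > a.end + max_dist:
                break
            d = _interval_gap(a, set_b[j])
            if d < max_dist:
                candidates.append((d, i, j))
    candidates.sort()
    used_a, used_b = set(), set()
    pairs = []
    for d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return MergeReport(
        shared=len(pairs),
        a_only=len(set_a) - len(pairs),
        b_only=len(set_b) - len(pairs),
        pairs=pairs,
    )


def select_isolated(
    origins: Sequence[OriginRecord], half_width: int = 10_000
) -> List[OriginRecord]:
    """Keep only origins whose domain contains no other midpoint of the set.

    An origin is dropped when another origin of the same set has a midpoint
    within ``half_width`` bases (inclusive) on the same chromosome.  The
    check is symmetric, so clustered origins remove each other.
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for i, o in enumerate(origins):
        by_chrom.setdefault(o.chrom, []).append((o.midpoint, i))
    keep = []
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        mids = [m for m, _ in pairs]
        for k, (m, i) in enumerate(pairs):
            lo = bisect_left(mids, m - half_width)
            hi = bisect_right(mids, m + half_width)
            if hi - lo == 1:  # only itself in range
                keep.append(i)
    return [origins[i] for i in sorted(keep)]


def efficiency_bins(
    origins: Sequence[OriginRecord], n_bins: int = 3
) -> List[OriginRecord]:
    """Assign low/medium/high efficiency tertiles by empirical quantiles.

    Boundary values go to the lower bin.  If every efficiency is identical
    the whole set falls in the lowest bin and a warning is emitted.
    """
    effs = np.array([o.efficiency for o in origins], dtype=float)
    if np.any(np.isnan(effs)):
        raise ValueError("efficiency_bins requires efficiencies on all origins")
    if n_bins != 3:
        raise ValueError("only tertile binning (n_bins=3) is supported")
    if np.all(effs == effs[0]):
        warnings.warn("all efficiencies identical; single bin assigned")
        return [replace(o, efficiency_bin="low") for o in origins]
    q1, q2 = np.quantile(effs, [1 / 3, 2 / 3])
    out = []
    for o in origins:
        if o.efficiency <= q1:
            b = "low"
        elif o.efficiency <= q2:
            b = "medium"
        else:
            b = "high"
        out.append(replace(o, efficiency_bin=b))
    return out


def drop_out_of_bounds(
    origins: Sequence[OriginRecord], genome: Genome, half_width: int = 10_000
) -> List[OriginRecord]:
    """Drop origins whose domain would overhang a chromosome end."""
    kept = []
    for o in origins:
        if o.chrom not in genome.chroms:
            log.warning("origin on unknown chromosome %s dropped", o.chrom)
            continue
        m = o.midpoint
        if m - half_width < 0 or m + half_width > genome.length(o.chrom):
            log.warning("origin %s:%d domain exceeds chromosome end; dropped",
                        o.chrom, m)
            continue
        kept.append(o)
    return kept
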