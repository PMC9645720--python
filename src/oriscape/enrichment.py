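"""Feature-anchored functional enrichment: TFBS scanning, QTL loads, KS.

Functional-variant density profiles around TSSs/splice sites partitioned by
origin presence, PWM scanning of variant contexts with dual-strand
log-odds scoring, per-motif 2x2 chi-square enrichment with a QQ report,
cis-QTL load ratios, and two-sample distribution comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import encode
from .landscape import ProfileMatrix, background_normalize, mutation_rate_profile
from .origins_io import OriginDomainSet, OriginRecord, VariantRecord

CONTEXT_FLANK = 12  # variant +/- 12 nt => 25-nt scanning context


@dataclass
class Pwm:
    """A position frequency matrix with log-odds scoring support."""

    motif_id: str
    counts: np.ndarray          # (4, L) rows A,C,G,T
    pseudocount: float = 0.8

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        c = self.counts + self.pseudocount / 4
        return c / c.sum(axis=0, keepdims=True)

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """Natural-log odds against the supplied background frequencies."""
        bg = np.asarray(background, dtype=float).reshape(4, 1)
        return np.log(self.probabilities() / bg)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.probabilities(), axis=0))

    @classmethod
    def from_jaspar_file(cls, path) -> List["Pwm"]:
        from Bio import motifs

        out = []
        with open(path) as fh:
            for m in motifs.parse(fh, "jaspar"):
                counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
                out.append(cls(m.matrix_id or m.name, counts))
        return out

    def to_jaspar(self) -> str:
        lines = [f">{self.motif_id}\t{self.motif_id}"]
        for i, b in enumerate("ACGT"):
            vals = " ".join(f"{v:g}" for v in self.counts[i])
            lines.append(f"{b}  [ {vals} ]")
        return "\n".join(lines) + "\n"


@dataclass
class TfbsHit:
    motif_id: str
    sequence_id: str
    offset: int
    strand: str
    rel_score: float
    raw_score: float
    overlaps_variant: bool
    had_n: bool = False


def _context_background(codes: np.ndarray) -> np.ndarray:
    counts = np.array([(codes == b).sum() for b in range(4)], dtype=float) + 1.0
    return counts / counts.sum()


def scan_pwm(
    context_sequence: str,
    pwm: Pwm,
    min_rel_score: float = 0.95,
    min_raw_score: float = 10.0,
    sequence_id: str = "",
    background: Optional[np.ndarray] = None,
) -> List[TfbsHit]:
    """Scan a variant context (variant +/- 12 nt) for motif matches.

    Both strands are scored at every offset (the minus strand via the
    reverse-complemented matrix, so reported offsets stay in sequence
    coordinates).  A hit is kept when its relative score reaches
    ``min_rel_score``, its natural-log odds score exceeds
    ``min_raw_score``, and the motif span covers the central (variant)
    position.  N bases contribute zero log-odds and flag the hit.
    """
    seq = context_sequence.upper()
    if len(seq) != 2 * CONTEXT_FLANK + 1:
        raise ValueError(f"context must be {2 * CONTEXT_FLANK + 1} nt")
    L = pwm.length
    if L > len(seq):
        return []
    codes = encode(seq)
    bg = background if background is not None else _context_background(codes)
    M = pwm.log_odds(bg)                      # (4, L)
    M_rc = M[::-1, ::-1]                      # reverse complement scoring
    col_min = {"+": M.min(axis=0), "-": M_rc.min(axis=0)}
    col_max = {"+": M.max(axis=0), "-": M_rc.max(axis=0)}
    center = CONTEXT_FLANK
    hits: List[TfbsHit] = []
    for strand, mat in (("+", M), ("-", M_rc)):
        min_possible = float(col_min[strand].sum())
        max_possible = float(col_max[strand].sum())
        for off in range(len(seq) - L + 1):
            window = codes[off:off + L]
            valid = window <= 3
            score = float(mat[window[valid], np.nonzero(valid)[0]].sum())
            rel = (score - min_possible) / (max_possible - min_possible)
            covers = off <= center < off + L
            if rel >= min_rel_score and score > min_raw_score and covers:
                hits.append(TfbsHit(pwm.motif_id, sequence_id, off, strand,
                                    rel, score, covers,
                                    had_n=not valid.all()))
    return hits


def best_relative_score(context_sequence: str, pwm: Pwm,
                        background: Optional[np.ndarray] = None) -> float:
    """Best relative score over all offsets and strands (no thresholds)."""
    seq = context_sequence.upper()
    codes = encode(seq)
    bg = background if background is not None else _context_background(codes)
    M = pwm.log_odds(bg)
    best = -np.inf
    for mat in (M, M[::-1, ::-1]):
        mn, mx = float(mat.min(axis=0).sum()), float(mat.max(axis=0).sum())
        for off in range(len(seq) - pwm.length + 1):
            window = codes[off:off + pwm.length]
            valid = window <= 3
            score = float(mat[window[valid], np.nonzero(valid)[0]].sum())
            best = max(best, (score - mn) / (mx - mn))
    return best


@dataclass
class MotifEnrichment:
    table: pd.DataFrame   # per-motif counts, odds ratio, chi2, p
    qq: pd.DataFrame      # observed vs expected -log10 p


def tfbs_enrichment(
    hits_marked: Sequence[TfbsHit],
    hits_unmarked: Sequence[TfbsHit],
) -> MotifEnrichment:
    """Per-motif 2x2 chi-square enrichment between two hit-pair lists.

    A "pair" is a unique (motif, variant context) hit.  For each motif the
    table contrasts that motif's pairs against all other pairs, marked
    versus unmarked group, without continuity correction.  Odds ratios are
    capped at infinity for empty cells; the QQ frame ranks observed
    -log10 p against uniform quantiles.
    """
    pairs_m = {(h.motif_id, h.sequence_id) for h in hits_marked}
    pairs_u = {(h.motif_id, h.sequence_id) for h in hits_unmarked}
    A, B = len(pairs_m), len(pairs_u)
    motifs = sorted({m for m, _ in pairs_m} | {m for m, _ in pairs_u})
    rows = []
    for motif in motifs:
        a = sum(1 for m, _ in pairs_m if m == motif)
        b = sum(1 for m, _ in pairs_u if m == motif)
        table = np.array([[a, A - a], [b, B - b]], dtype=float)
        if table.sum() == 0 or np.any(table.sum(axis=0) == 0) or np.any(
            table.sum(axis=1) == 0
        ):
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * (B - b)) / (b * (A - a)) if b * (A - a) > 0 else np.inf
        rows.append({"motif": motif, "n_marked": a, "n_unmarked": b,
                     "odds_ratio": float(odds), "chi2": float(chi2),
                     "p_value": float(p)})
    table = pd.DataFrame(rows)
    if len(table):
        obs = np.sort(table["p_value"].to_numpy())
        k = len(obs)
        expected = (np.arange(1, k + 1) - 0.5) / k
        qq = pd.DataFrame({
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(np.clip(obs, 1e-300, None)),
        })
    else:
        qq = pd.DataFrame(columns=["expected_neglog10", "observed_neglog10"])
    return MotifEnrichment(table, qq)


# ---------------------------------------------------------------------------
# Feature-anchored density profiles
# ---------------------------------------------------------------------------

@dataclass
class FeatureProfileResult:
    marked: Optional[ProfileMatrix]
    unmarked: Optional[ProfileMatrix]
    fold_change: float


def _features_to_domainset(
    positions: Sequence[Tuple[str, int]], half_width: int, window: int
) -> Optional[OriginDomainSet]:
    if not positions:
        return None
    origins = [OriginRecord(chrom, pos, pos + 1) for chrom, pos in positions]
    return OriginDomainSet(origins, half_width=half_width, window_size=window)


def feature_anchor_profile(
    variants: Sequence[VariantRecord],
    features_marked: Sequence[Tuple[str, int]],
    features_unmarked: Sequence[Tuple[str, int]],
    half_width: int = 2500,
    window: int = 100,
    n_edge_windows: int = 10,
    center_span: int = 500,
) -> FeatureProfileResult:
    """Normalized variant-density profiles anchored on genomic features.

    Features (e.g. TSSs or splice sites) are partitioned by origin
    presence; each group gets the standard windowed, background-normalized
    density profile, and the group fold-change is the ratio of mean
    normalized density within ``center_span`` bases of the anchors.
    """
    profiles = []
    for feats in (features_marked, features_unmarked):
        ds = _features_to_domainset(feats, half_width, window)
        if ds is None:
            warnings.warn("empty feature group; profile masked")
            profiles.append(None)
            continue
        prof = mutation_rate_profile(variants, ds)
        profiles.append(background_normalize(prof, n_edge_windows))
    marked, unmarked = profiles
    if marked is None or unmarked is None:
        return FeatureProfileResult(marked, unmarked, float("nan"))
    W = marked.n_windows
    offsets = (np.arange(W) + 0.5) * window - half_width
    center = np.abs(offsets) <= center_span
    num = np.nanmean(marked.aggregate[center])
    den = np.nanmean(unmarked.aggregate[center])
    fold = num / den if den > 0 else float("nan")
    return FeatureProfileResult(marked, unmarked, float(fold))


# ---------------------------------------------------------------------------
# QTL loads
# ---------------------------------------------------------------------------

@dataclass
class QtlRecord:
    chrom: str
    pos: int          # 1-based variant position
    gene: str
    tissue: str
    q_value: float

    def __post_init__(self):
        if not 0 <= self.q_value <= 1:
            raise ValueError("q_value must lie in [0, 1]")


@dataclass
class QtlLoadResult:
    load_marked: float
    load_unmarked: float
    fold: float
    chi2: float
    p_value: float
    n_marked: int
    n_unmarked: int
    bases_marked: int
    bases_unmarked: int


def _domain_bases(domains: Sequence[Tuple[str, int, int]]) -> int:
    return sum(e - s for _, s, e in domains)


def _count_in_domains(
    records: Iterable[QtlRecord], domains: Sequence[Tuple[str, int, int]]
) -> int:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in domains:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    n = 0
    for r in records:
        for s, e in by_chrom.get(r.chrom, ()):
            if s <= r.pos - 1 < e:
                n += 1
                break
    return n


def qtl_load(
    qtls: Sequence[QtlRecord],
    domains_marked: Sequence[Tuple[str, int, int]],
    domains_unmarked: Sequence[Tuple[str, int, int]],
    q_threshold: float = 0.05,
    significant_below: bool = True,
    tissue: Optional[str] = None,
) -> QtlLoadResult:
    """Significant cis-QTL load (count per base) per feature group.

    ``significant_below`` selects q <= threshold (the conventional
    direction); the comparison can be flipped for sensitivity checks.
    The chi-square contrasts QTL counts against the base totals of the two
    domain sets, without continuity correction.
    """
    if tissue is not None:
        qtls = [q for q in qtls if q.tissue == tissue]
    if significant_below:
        sig = [q for q in qtls if q.q_value <= q_threshold]
    else:
        sig = [q for q in qtls if q.q_value >= q_threshold]
    bases_m = _domain_bases(domains_marked)
    bases_u = _domain_bases(domains_unmarked)
    if bases_m == 0 or bases_u == 0:
        raise ValueError("each domain group must cover at least one base")
    n_m = _count_in_domains(sig, domains_marked)
    n_u = _count_in_domains(sig, domains_unmarked)
    load_m, load_u = n_m / bases_m, n_u / bases_u
    table = np.array([[n_m, n_u], [bases_m - n_m, bases_u - n_u]], dtype=float)
    if n_m + n_u == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    fold = load_m / load_u if load_u > 0 else float("inf")
    return QtlLoadResult(load_m, load_u, float(fold), float(chi2), float(p),
                         n_m, n_u, bases_m, bases_u)


def load_qtl_table(path, chrom_col="chrom", pos_col="pos", gene_col="gene",
                   tissue_col="tissue", q_col="q_value") -> List[QtlRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        QtlRecord(str(r[chrom_col]), int(r[pos_col]), str(r[gene_col]),
                  str(r[tissue_col]), float(r[q_col]))
        for _, r in df.iterrows()
    ]


def ks_compare(sample_a, sample_b) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (exact for small samples)."""
    res = stats.ks_2samp(np.asarray(sample_a, dtype=float),
                         np.asarray(sample_b, dtype=float), method="auto")
    return float(res.statistic), float(res.pvalue)
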