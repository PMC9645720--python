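"""Origin-centered profiles: mutation rates, strand bias, coverage, GERP.

All profile operations share one aggregation contract: per-origin,
per-window values with NaN marking masked windows, a per-window aggregate
vector, and background normalization by the mean of the first and last
``n_edge_windows`` aggregate values (the domain edges serve as the local
background, so a value of 1 means "no enrichment over flanks").
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._seq import A, C, G, T
from .origins_io import CoverageTrack, Genome, OriginDomainSet, VariantRecord

PYRIMIDINE_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ProfileMatrix:
    """Origins x windows aggregation with a per-window summary vector."""

    values: np.ndarray  # (n_origins, n_windows), NaN = masked
    metric: str
    aggregate: np.ndarray  # (n_windows,)
    normalized: bool = False
    n_contributing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.aggregate = np.asarray(self.aggregate, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.aggregate.shape[0]:
            raise ValueError("values/aggregate shape mismatch")

    @property
    def n_windows(self) -> int:
        return self.aggregate.shape[0]

    def to_frame(self, domainset: Optional[OriginDomainSet] = None):
        import pandas as pd

        offsets = (
            domainset.window_offsets()
            if domainset is not None
            else np.arange(self.n_windows, dtype=float)
        )
        ncontrib = (
            self.n_contributing
            if self.n_contributing is not None
            else np.sum(~np.isnan(self.values), axis=0)
        )
        return pd.DataFrame(
            {
                "window_index": np.arange(self.n_windows),
                "genomic_offset": offsets,
                "value": self.aggregate,
                "n_contributing": ncontrib,
            }
        )


def background_normalize(profile: ProfileMatrix, n_edge_windows: int = 20) -> ProfileMatrix:
    """Divide a profile by the mean of its first and last edge windows.

    Masked (NaN) windows are excluded from the background mean.  The result
    is scale-invariant: multiplying all inputs by k > 0 leaves it unchanged.
    """
    agg = profile.aggregate
    if profile.n_windows <= 2 * n_edge_windows:
        raise ValueError("profile too short for the requested edge windows")
    edges = np.concatenate([agg[:n_edge_windows], agg[-n_edge_windows:]])
    bg = np.nanmean(edges)
    if not np.isfinite(bg) or bg <= 0:
        raise ValueError(
            "background mean is zero or undefined; use a pseudocount or more data"
        )
    return replace(
        profile,
        values=profile.values / bg,
        aggregate=agg / bg,
        normalized=True,
    )


def mutation_rate_profile(
    variants: Sequence[VariantRecord],
    domainset: OriginDomainSet,
    kind: str = "all",
    indel_len_class: Optional[str] = None,
) -> ProfileMatrix:
    """Per-window mutation counts averaged over domains.

    ``aggregate[w]`` is the total number of in-domain variants falling in
    window ``w`` divided by the number of domains.  ``kind`` selects
    "all", "SNV", or "indel"; indels can be further restricted to the
    1-bp ("1") or >=2-bp ("2+") length class.
    """
    if len(domainset) == 0:
        raise ValueError("empty domain set")
    values = np.zeros((len(domainset), domainset.n_windows))
    for v in variants:
        vt = v.vtype
        if kind == "SNV" and vt != "SNV":
            continue
        if kind == "indel":
            if vt == "SNV":
                continue
            ilen = abs(len(v.ref) - len(v.alt))
            if indel_len_class == "1" and ilen != 1:
                continue
            if indel_len_class == "2+" and ilen < 2:
                continue
        hit = domainset.assign(v.chrom, v.pos0)
        if hit is not None:
            values[hit[0], hit[1]] += 1
    aggregate = values.sum(axis=0) / len(domainset)
    return ProfileMatrix(values, f"mutation_rate[{kind}]", aggregate)


def _window_base_counts(
    genome: Genome, domainset: OriginDomainSet
) -> np.ndarray:
    """Per-origin, per-window counts of A, C, G, T: shape (n, W, 4)."""
    n, W = len(domainset), domainset.n_windows
    ws = domainset.window_size
    out = np.zeros((n, W, 4), dtype=np.int64)
    for i, o in enumerate(domainset.origins):
        lo, hi = domainset.domain_bounds(i)
        codes = genome.codes(o.chrom)[max(lo, 0):hi]
        if lo < 0 or len(codes) < hi - lo:
            raise ValueError("domain exceeds chromosome; drop such origins first")
        wins = codes.reshape(W, ws)
        for b in range(4):
            out[i, :, b] = (wins == b).sum(axis=1)
    return out


def composition_corrected_rates(
    variants: Sequence[VariantRecord],
    genome: Genome,
    domainset: OriginDomainSet,
    normalize: bool = True,
) -> Dict[str, ProfileMatrix]:
    """Mutation rates per pyrimidine substitution class, corrected for
    window base composition.

    Purine-reference SNVs fold into the pyrimidine class by complementing
    both alleles.  C-class counts divide by the window's C+G bases, T-class
    by A+T bases; windows with no eligible bases are masked.  The corrected
    profiles are then background-normalized (disable with ``normalize``).
    """
    base_counts = _window_base_counts(genome, domainset)
    cg = (base_counts[:, :, C] + base_counts[:, :, G]).astype(float)
    at = (base_counts[:, :, A] + base_counts[:, :, T]).astype(float)
    cg[cg == 0] = np.nan
    at[at == 0] = np.nan

    counts = {t: np.zeros((len(domainset), domainset.n_windows)) for t in PYRIMIDINE_TYPES}
    for v in variants:
        if v.vtype != "SNV":
            continue
        ref, alt = v.ref, v.alt
        if ref in "AG":
            ref, alt = _COMP[ref], _COMP[alt]
        hit = domainset.assign(v.chrom, v.pos0)
        if hit is not None:
            counts[f"{ref}>{alt}"][hit[0], hit[1]] += 1

    out = {}
    for t in PYRIMIDINE_TYPES:
        denom = cg if t.startswith("C") else at
        values = counts[t] / denom
        with np.errstate(invalid="ignore"):
            agg_num = np.nansum(counts[t], axis=0)
            agg_den = np.nansum(denom, axis=0)
        aggregate = np.where(agg_den > 0, agg_num / agg_den, np.nan)
        prof = ProfileMatrix(values, f"corrected_rate[{t}]", aggregate)
        out[t] = background_normalize(prof) if normalize else prof
    return out


def interdistance_profile(
    variants: Sequence[VariantRecord],
    domainset: OriginDomainSet,
) -> ProfileMatrix:
    """Mean nearest-neighbour mutation distance per window.

    Each variant's value is the distance to the closest other variant on the
    same chromosome (genome-wide neighbours, not only in-domain ones);
    chromosomes carrying a single variant contribute nothing.
    """
    by_chrom: Dict[str, List[int]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v.pos0)
    sums = np.zeros((len(domainset), domainset.n_windows))
    nobs = np.zeros_like(sums)
    for chrom, positions in by_chrom.items():
        if len(positions) < 2:
            continue
        pos = np.array(sorted(positions), dtype=np.int64)
        gaps = np.diff(pos)
        nn = np.empty(len(pos), dtype=np.int64)
        nn[0] = gaps[0]
        nn[-1] = gaps[-1]
        if len(pos) > 2:
            nn[1:-1] = np.minimum(gaps[:-1], gaps[1:])
        oi, wi = domainset.assign_many(chrom, pos)
        ok = oi >= 0
        np.add.at(sums, (oi[ok], wi[ok]), nn[ok])
        np.add.at(nobs, (oi[ok], wi[ok]), 1)
    with np.errstate(invalid="ignore"):
        values = np.where(nobs > 0, sums / nobs, np.nan)
        agg_n = nobs.sum(axis=0)
        aggregate = np.where(agg_n > 0, sums.sum(axis=0) / agg_n, np.nan)
    return ProfileMatrix(values, "interdistance", aggregate, n_contributing=agg_n)


@dataclass
class RSBProfile:
    """Replication strand bias per pyrimidine substitution type and window.

    ``n_fwd[t, w]`` counts SNVs of type ``t`` whose reference base as written
    in the genome is the pyrimidine; ``n_rev`` counts the purine-written
    complement.  ``rsb = log2((n_fwd + c) / (n_rev + c))`` with pseudocount
    ``c``; swapping the two roles negates every value.
    """

    types: Tuple[str, ...]
    n_fwd: np.ndarray  # (6, n_windows)
    n_rev: np.ndarray
    pseudocount: float = 0.5

    @property
    def rsb(self) -> np.ndarray:
        c = self.pseudocount
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.log2((self.n_fwd + c) / (self.n_rev + c))

    def swapped(self) -> "RSBProfile":
        return RSBProfile(self.types, self.n_rev.copy(), self.n_fwd.copy(),
                          self.pseudocount)

    def p_forward(self) -> np.ndarray:
        """Empirical probability that the written reference is the pyrimidine."""
        c = self.pseudocount
        return (self.n_fwd + c) / (self.n_fwd + self.n_rev + 2 * c)

    def smoothed(self, span: float = 0.2) -> np.ndarray:
        return np.vstack([loess_smooth(row, span=span) for row in self.rsb])


def loess_smooth(y: np.ndarray, span: float = 0.2) -> np.ndarray:
    """Local linear (lowess) smoothing for display of windowed trends."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.arange(len(y), dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 5:
        return np.asarray(y, dtype=float)
    fitted = lowess(y[ok], x[ok], frac=span, return_sorted=False)
    out = np.full(len(y), np.nan)
    out[ok] = fitted
    return out


def replication_strand_bias(
    variants: Sequence[VariantRecord],
    genome: Genome,
    domainset: OriginDomainSet,
    pseudocount: float = 0.5,
) -> RSBProfile:
    """Count stranded SNVs per window and form the log2 bias profile."""
    n_fwd = np.zeros((6, domainset.n_windows))
    n_rev = np.zeros_like(n_fwd)
    tindex = {t: i for i, t in enumerate(PYRIMIDINE_TYPES)}
    for v in variants:
        if v.vtype != "SNV":
            continue
        hit = domainset.assign(v.chrom, v.pos0)
        if hit is None:
            continue
        written = genome.fetch(v.chrom, v.pos0, v.pos0 + 1)
        if written != v.ref or written not in "ACGT":
            continue
        if v.ref in "CT":
            n_fwd[tindex[f"{v.ref}>{v.alt}"], hit[1]] += 1
        else:
            n_rev[tindex[f"{_COMP[v.ref]}>{_COMP[v.alt]}"], hit[1]] += 1
    return RSBProfile(PYRIMIDINE_TYPES, n_fwd, n_rev, pseudocount)


def coverage_profile(
    tracks,
    domainset: OriginDomainSet,
    normalize: bool = True,
    n_edge_windows: int = 20,
) -> ProfileMatrix:
    """Overlap-weighted mean track value per window, background-normalized.

    ``tracks`` may be a single :class:`CoverageTrack` or a list, in which
    case per-track profiles are averaged (e.g. over cell lines) before
    normalization.  Windows with no covering interval are masked.
    """
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    stack = []
    for track in tracks:
        values = np.full((len(domainset), domainset.n_windows), np.nan)
        for i, o in enumerate(domainset.origins):
            entry = track.intervals.get(o.chrom)
            if entry is None:
                continue
            starts, ends, vals = entry
            lo, hi = domainset.domain_bounds(i)
            W, ws = domainset.n_windows, domainset.window_size
            w_start = lo + np.arange(W) * ws
            for w in range(W):
                a, b = w_start[w], w_start[w] + ws
                j0 = np.searchsorted(ends, a, side="right")
                j1 = np.searchsorted(starts, b, side="left")
                if j1 <= j0:
                    continue
                ov = np.minimum(ends[j0:j1], b) - np.maximum(starts[j0:j1], a)
                values[i, w] = np.sum(vals[j0:j1] * ov) / np.sum(ov)
        stack.append(values)
    values = np.nanmean(np.stack(stack), axis=0) if len(stack) > 1 else stack[0]
    with np.errstate(invalid="ignore"):
        aggregate = np.nanmean(values, axis=0)
    prof = ProfileMatrix(values, "coverage", aggregate)
    return background_normalize(prof, n_edge_windows) if normalize else prof


def gerp_profile(
    per_base_scores: CoverageTrack,
    domainset: OriginDomainSet,
    rolling: int = 100,
    normalize: bool = True,
    n_edge_windows: int = 20,
) -> ProfileMatrix:
    """Rolling-mean conservation scores aggregated to windows.

    Per-base scores are smoothed with a centered rolling mean of ``rolling``
    bases within each domain, then averaged per window and normalized to the
    domain-edge background.
    """
    values = np.full((len(domainset), domainset.n_windows), np.nan)
    W, ws = domainset.n_windows, domainset.window_size
    for i, o in enumerate(domainset.origins):
        entry = per_base_scores.intervals.get(o.chrom)
        if entry is None:
            continue
        starts, ends, vals = entry
        lo, hi = domainset.domain_bounds(i)
        base = np.full(hi - lo, np.nan)
        j0 = np.searchsorted(ends, lo, side="right")
        j1 = np.searchsorted(starts, hi, side="left")
        for j in range(j0, j1):
            a, b = max(starts[j], lo), min(ends[j], hi)
            base[a - lo:b - lo] = vals[j]
        ok = np.isfinite(base)
        if not ok.any():
            continue
        kernel = np.ones(rolling)
        num = np.convolve(np.where(ok, base, 0.0), kernel, mode="same")
        den = np.convolve(ok.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore"):
            smooth = np.where(den > 0, num / den, np.nan)
        wins = smooth.reshape(W, ws)
        with np.errstate(invalid="ignore"):
            values[i] = np.nanmean(wins, axis=1)
    with np.errstate(invalid="ignore"):
        aggregate = np.nanmean(values, axis=0)
    prof = ProfileMatrix(values, "gerp", aggregate)
    return background_normalize(prof, n_edge_windows) if normalize else prof


@dataclass
class BinnedAssociation:
    bin_edges: np.ndarray
    bin_sizes: np.ndarray
    bin_totals: np.ndarray
    chi2: float
    df: int
    p_value: float


def quantile_bin_association(
    per_origin_counts: np.ndarray,
    per_origin_covariate: np.ndarray,
    n_bins: int = 10,
) -> BinnedAssociation:
    """Test whether per-origin counts depend on a covariate.

    Origins are binned into ``n_bins`` covariate quantiles; total counts per
    bin are compared against a uniform expectation proportional to bin sizes
    with a chi-square test (df = n_bins - 1, no continuity correction).
    """
    counts = np.asarray(per_origin_counts, dtype=float)
    cov = np.asarray(per_origin_covariate, dtype=float)
    if counts.shape != cov.shape:
        raise ValueError("counts and covariate must align")
    n = len(counts)
    if n_bins > n:
        raise ValueError("more bins than origins")
    edges = np.quantile(cov, np.linspace(0, 1, n_bins + 1))
    # rank-based binning so ties cannot empty a bin
    order = np.argsort(cov, kind="stable")
    bin_of = np.empty(n, dtype=int)
    bin_of[order] = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1)
    sizes = np.bincount(bin_of, minlength=n_bins).astype(float)
    totals = np.bincount(bin_of, weights=counts, minlength=n_bins)
    expected = totals.sum() * sizes / sizes.sum()
    chi2, p = stats.chisquare(totals, expected)
    return BinnedAssociation(edges, sizes, totals, float(chi2), n_bins - 1, float(p))


def chi2_independence(table: np.ndarray) -> Tuple[float, int, float]:
    """Two-way chi-square of independence without continuity correction."""
    chi2, p, df, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), int(df), float(p)
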