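"""Mutational signature machinery: SBS96/ID83 channels, NMF, refitting.

Single-base substitutions are classified into the 96 canonical channels
(six pyrimidine substitution types x 16 flanking-base contexts); indels into
the 83 COSMIC channels (size, affected base, repeat context, microhomology).
Windowed count matrices are factorized de novo with a Kullback-Leibler
multiplicative-update NMF run many times from random seeds; the rank is
chosen from the cophenetic correlation of the run-consensus clustering.
Known catalogs are refit per window with non-negative least squares, with a
strict backward-elimination mode that discards signatures whose removal
costs less than ``max_delta`` in reconstruction cosine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import curve_fit, nnls
from scipy.spatial.distance import squareform

from ._seq import BASES, COMPLEMENT
from .origins_io import Genome, OriginDomainSet, VariantRecord

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SBS96_LABELS: Tuple[str, ...] = tuple(
    f"{l}[{sub}]{r}" for sub in SUBSTITUTIONS for l in BASES for r in BASES
)


def _id83_labels() -> Tuple[str, ...]:
    labels: List[str] = []
    for ref in ("C", "T"):
        labels += [f"1:Del:{ref}:{i}" for i in range(6)]
    for ref in ("C", "T"):
        labels += [f"1:Ins:{ref}:{i}" for i in range(6)]
    for ln in (2, 3, 4, 5):
        labels += [f"{ln}:Del:R:{i}" for i in range(6)]
    for ln in (2, 3, 4, 5):
        labels += [f"{ln}:Ins:R:{i}" for i in range(6)]
    for ln in (2, 3, 4, 5):
        upper = ln - 1 if ln < 5 else 5  # the "5" size class means 5+
        labels += [f"{ln}:Del:M:{i}" for i in range(1, upper + 1)]
    return tuple(labels)


ID83_LABELS: Tuple[str, ...] = _id83_labels()
assert len(SBS96_LABELS) == 96 and len(ID83_LABELS) == 83

_SBS_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}
_ID_INDEX = {lab: i for i, lab in enumerate(ID83_LABELS)}


class UnclassifiableVariant(ValueError):
    """Variant context cannot be classified (e.g. contains N)."""


def classify_sbs96(variant: VariantRecord, genome: Genome) -> int:
    """Channel index of an SNV in the canonical 96-channel order.

    Purine-reference substitutions are reverse-complemented so the reported
    reference is C or T; the genome base at the variant position must match
    the stated reference allele.
    """
    if variant.vtype != "SNV":
        raise ValueError("classify_sbs96 expects an SNV")
    p = variant.pos0
    ctx = genome.fetch(variant.chrom, p - 1, p + 2)
    if len(ctx) != 3:
        raise UnclassifiableVariant("variant at sequence end")
    if ctx[1] != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"genome={ctx[1]} vcf={variant.ref}"
        )
    ref, alt, l, r = variant.ref, variant.alt, ctx[0], ctx[2]
    if any(b not in "ACGT" for b in (ref, alt, l, r)):
        raise UnclassifiableVariant(f"ambiguous context {ctx}")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        l, r = COMPLEMENT[r], COMPLEMENT[l]
    return _SBS_INDEX[f"{l}[{ref}>{alt}]{r}"]


def _left_align(seq: str, pos0: int, genome: Genome, chrom: str) -> Tuple[str, int, bool]:
    """Shift an indel (anchored at pos0, event at pos0+1) maximally left."""
    moved = False
    while pos0 > 0:
        prev = genome.fetch(chrom, pos0, pos0 + 1)
        if prev != seq[-1]:
            break
        seq = seq[-1] + seq[:-1]
        pos0 -= 1
        moved = True
    return seq, pos0, moved


def _run_length(genome: Genome, chrom: str, start: int, base: str,
                step: int, limit: int) -> int:
    n, p = 0, start
    while n < limit:
        b = genome.fetch(chrom, p, p + 1)
        if b != base:
            break
        n += 1
        p += step
    return n


def _tandem_copies(genome: Genome, chrom: str, start: int, unit: str,
                   step: int, limit: int) -> int:
    """Count adjacent tandem copies of ``unit`` walking from ``start``."""
    n, L, p = 0, len(unit), start
    while n < limit:
        if step > 0:
            s = genome.fetch(chrom, p, p + L)
        else:
            s = genome.fetch(chrom, p - L + 1, p + 1)
        if s != unit:
            break
        n += 1
        p += step * L
    return n


def classify_id83(variant: VariantRecord, genome: Genome, scan: int = 50) -> int:
    """COSMIC ID83 channel index of a left-aligned simple indel.

    One-base events are classed by the affected base (pyrimidine-folded) and
    the reference homopolymer run; longer events by adjacent tandem-repeat
    copies, with microhomology classes for repeat-free deletions whose ends
    share sequence with the flanks.  Flank scanning is capped at ``scan`` bp,
    which is ample for channels capped at 5+/6+.
    """
    vt = variant.vtype
    if vt == "SNV":
        raise ValueError("classify_id83 expects an indel")
    is_del = vt == "deletion"
    seq = variant.ref[1:] if is_del else variant.alt[1:]
    if set(seq) - set("ACGT"):
        raise UnclassifiableVariant(f"indel sequence {seq} not ACGT")
    anchor = variant.pos0
    aligned_seq, aligned_anchor, moved = _left_align(seq, anchor, genome, variant.chrom)
    if moved:
        warnings.warn(
            f"indel at {variant.chrom}:{variant.pos} was not left-aligned; normalized"
        )
        seq, anchor = aligned_seq, aligned_anchor
    L = len(seq)
    ev_start = anchor + 1                     # first event base (0-based)
    ev_end = ev_start + (L if is_del else 0)  # first base after the event
    chrom = variant.chrom

    if L == 1:
        base = seq if seq in "CT" else COMPLEMENT[seq]
        right = _run_length(genome, chrom, ev_end, seq, +1, scan)
        left = _run_length(genome, chrom, ev_start - 1, seq, -1, scan)
        if is_del:
            run = 1 + left + right
            return _ID_INDEX[f"1:Del:{base}:{min(run, 6) - 1}"]
        run = left + right
        return _ID_INDEX[f"1:Ins:{base}:{min(run, 5)}"]

    lc = min(L, 5)
    fwd = _tandem_copies(genome, chrom, ev_end, seq, +1, scan // L + 1)
    bwd = _tandem_copies(genome, chrom, ev_start - 1, seq, -1, scan // L + 1)
    if is_del:
        copies = 1 + fwd + bwd
        if copies >= 2:
            return _ID_INDEX[f"{lc}:Del:R:{min(copies, 6) - 1}"]
        right_flank = genome.fetch(chrom, ev_end, ev_end + L)
        left_flank = genome.fetch(chrom, max(ev_start - L, 0), ev_start)
        pre = 0
        for a, b in zip(seq, right_flank):
            if a != b:
                break
            pre += 1
        suf = 0
        for a, b in zip(reversed(seq), reversed(left_flank)):
            if a != b:
                break
            suf += 1
        mh = min(max(pre, suf), lc - 1 if lc < 5 else 5, L - 1)
        if mh >= 1:
            return _ID_INDEX[f"{lc}:Del:M:{mh}"]
        return _ID_INDEX[f"{lc}:Del:R:0"]
    copies = fwd + bwd
    return _ID_INDEX[f"{lc}:Ins:R:{min(copies, 5)}"]


@dataclass
class SBSCountMatrix:
    counts: np.ndarray  # (n_windows, 96)
    channels: Tuple[str, ...] = SBS96_LABELS
    n_skipped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape[1] != len(self.channels):
            raise ValueError("channel dimension mismatch")


@dataclass
class IDCountMatrix:
    counts: np.ndarray  # (n_windows, 83)
    channels: Tuple[str, ...] = ID83_LABELS
    n_skipped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape[1] != len(self.channels):
            raise ValueError("channel dimension mismatch")


def build_count_matrix(
    variants: Sequence[VariantRecord],
    genome: Genome,
    domainset: OriginDomainSet,
    kind: str = "SBS",
):
    """Aggregate classified in-domain variants into a windows x channels matrix."""
    if kind == "SBS":
        nchan, classify = 96, classify_sbs96
        want = "SNV"
    elif kind == "ID":
        nchan, classify = 83, classify_id83
        want = "indel"
    else:
        raise ValueError("kind must be 'SBS' or 'ID'")
    counts = np.zeros((domainset.n_windows, nchan), dtype=np.int64)
    skipped = 0
    for v in variants:
        is_snv = v.vtype == "SNV"
        if (want == "SNV") != is_snv:
            continue
        hit = domainset.assign(v.chrom, v.pos0)
        if hit is None:
            continue
        try:
            ch = classify(v, genome)
        except UnclassifiableVariant:
            skipped += 1
            continue
        counts[hit[1], ch] += 1
    cls = SBSCountMatrix if kind == "SBS" else IDCountMatrix
    return cls(counts, n_skipped=skipped)


@dataclass
class SignatureSet:
    """Rows are probability vectors over channels."""

    matrix: np.ndarray  # (n_signatures, n_channels)
    names: Tuple[str, ...]
    channels: Tuple[str, ...] = SBS96_LABELS

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(self.matrix < 0):
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-9):
            raise ValueError("signature rows must sum to 1")
        self.names = tuple(self.names)

    @classmethod
    def from_matrix(cls, matrix, names, channels=SBS96_LABELS) -> "SignatureSet":
        m = np.asarray(matrix, dtype=float)
        sums = m.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return cls(m / sums, tuple(names), channels)

    def subset(self, names: Sequence[str]) -> "SignatureSet":
        idx = [self.names.index(n) for n in names]
        return SignatureSet(self.matrix[idx], tuple(names), self.channels)


@dataclass
class ExposureMatrix:
    """Per-window signature activities, absolute (mutation counts) or relative."""

    values: np.ndarray  # (n_windows, n_signatures)
    names: Tuple[str, ...]
    relative: bool = False
    recon_cosine: Optional[np.ndarray] = None
    residual: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("exposures must be non-negative")
        self.names = tuple(self.names)

    def to_relative(self) -> "ExposureMatrix":
        totals = self.values.sum(axis=1, keepdims=True)
        safe = np.where(totals > 0, totals, 1.0)
        return ExposureMatrix(self.values / safe, self.names, relative=True)


@dataclass
class StrictFitConfig:
    max_delta: float = 0.004

    def __post_init__(self):
        if not 0 <= self.max_delta < 1:
            raise ValueError("max_delta must lie in [0, 1)")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of two non-negative channel vectors; 0 for a zero vector."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# NMF (KL multiplicative updates) with consensus-based rank selection
# ---------------------------------------------------------------------------

def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    term = np.zeros_like(V)
    term[mask] = V[mask] * np.log(V[mask] / WH[mask])
    return float(np.sum(term - V + WH))


def _mu_kl_run(V, rank, rng, max_iter, tol):
    eps = 1e-12
    n, m = V.shape
    scale = np.sqrt(V.mean() / rank) + eps
    W = rng.uniform(0.5, 1.5, size=(n, rank)) * scale
    H = rng.uniform(0.5, 1.5, size=(rank, m)) * scale
    prev = None
    for it in range(max_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + eps)
        if it % 10 == 9 or it == max_iter - 1:
            div = _kl_divergence(V, W @ H + eps)
            if prev is not None and abs(prev - div) <= tol * max(prev, 1.0):
                break
            prev = div
    return W, H, _kl_divergence(V, W @ H + eps)


def kl_update_trace(V: np.ndarray, rank: int, seed: int = 0, n_iter: int = 50) -> np.ndarray:
    """KL divergence after each multiplicative update pass (diagnostic).

    The returned sequence is non-increasing up to floating-point noise; it
    exists so the monotonicity of the update rule can be verified directly.
    """
    eps = 1e-12
    rng = np.random.default_rng(seed)
    V = np.asarray(V, dtype=float)
    n, m = V.shape
    scale = np.sqrt(V.mean() / rank) + eps
    W = rng.uniform(0.5, 1.5, size=(n, rank)) * scale
    H = rng.uniform(0.5, 1.5, size=(rank, m)) * scale
    out = []
    for _ in range(n_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + eps)
        out.append(_kl_divergence(V, W @ H + eps))
    return np.array(out)


def _consensus_cophenetic(consensus: np.ndarray) -> float:
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if np.allclose(condensed, condensed[0] if len(condensed) else 0.0):
        return 1.0
    Z = linkage(condensed, method="average")
    coph = cophenet(Z)
    if np.std(coph) == 0 or np.std(condensed) == 0:
        return 1.0
    return float(np.corrcoef(condensed, coph)[0, 1])


@dataclass
class NMFResult:
    signatures: SignatureSet
    exposures: ExposureMatrix
    divergence: float
    divergences: np.ndarray
    consensus: np.ndarray
    cophenetic: float
    rank: int


def nmf_extract(
    counts,
    rank: int,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
    channels: Optional[Tuple[str, ...]] = None,
) -> NMFResult:
    """De novo signature extraction by seeded multi-run KL-NMF.

    Each run starts from an independent random non-negative initialization;
    the best-divergence run is reported.  A Brunet-style consensus matrix of
    channel co-clustering (each channel assigned to the signature giving it
    the highest probability, per run) yields the cophenetic correlation used
    for rank selection; channel assignments are stable up to the true rank
    and fragment beyond it, which window assignments do not resolve when one
    signature dominates most windows.
    """
    V = np.asarray(getattr(counts, "counts", counts), dtype=float)
    if channels is None:
        channels = getattr(counts, "channels", SBS96_LABELS)
    if np.any(V < 0):
        raise ValueError("counts must be non-negative")
    if rank >= min(V.shape):
        raise ValueError(f"rank {rank} too large for matrix {V.shape}")
    keep = V.sum(axis=1) > 0
    Vk = V[keep]
    n = Vk.shape[0]
    ss = np.random.SeedSequence(seed)
    best = None
    divs = []
    n_chan = Vk.shape[1]
    co = np.zeros((n_chan, n_chan))
    for child in ss.spawn(n_runs):
        rng = np.random.default_rng(child)
        W, H, div = _mu_kl_run(Vk, rank, rng, max_iter, tol)
        divs.append(div)
        h_norm = H / np.maximum(H.sum(axis=1, keepdims=True), 1e-300)
        labels = np.argmax(h_norm, axis=0)
        co += (labels[:, None] == labels[None, :]).astype(float)
        if best is None or div < best[2]:
            best = (W, H, div)
    consensus = co / n_runs
    W, H, div = best
    row_sums = H.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    signatures = SignatureSet(H / row_sums[:, None],
                              tuple(f"S{i + 1}" for i in range(rank)), channels)
    exposures_full = np.zeros((V.shape[0], rank))
    exposures_full[keep] = W * row_sums[None, :]
    exposures = ExposureMatrix(exposures_full, signatures.names)
    return NMFResult(
        signatures, exposures, div, np.array(divs), consensus,
        _consensus_cophenetic(consensus), rank,
    )


@dataclass
class RankSelection:
    rank: int
    cophenetics: Dict[int, float]
    decreasing_found: bool


def rank_from_cophenetics(cophenetics: Dict[int, float],
                          tol: float = 1e-6) -> RankSelection:
    """Apply the rank rule: smallest rank before the first cophenetic drop.

    Drops within ``tol`` count as ties so that a numerically flat plateau
    (e.g. 1.0 vs 1.0 - 1e-16) is traversed rather than truncated.
    """
    ranks = sorted(cophenetics)
    for r, r_next in zip(ranks, ranks[1:]):
        if cophenetics[r] - cophenetics[r_next] > tol:
            return RankSelection(r, cophenetics, True)
    warnings.warn("cophenetic correlation never decreased; returning max rank")
    return RankSelection(ranks[-1], cophenetics, False)


def select_rank(
    counts,
    rank_range: Sequence[int],
    n_runs: int = 30,
    seed: int = 0,
    **nmf_kwargs,
) -> RankSelection:
    """Smallest rank after which the cophenetic correlation starts to drop."""
    ranks = sorted(rank_range)
    if len(ranks) < 3:
        raise ValueError("rank_range needs at least 3 candidate ranks")
    V = np.asarray(getattr(counts, "counts", counts), dtype=float)
    if np.all(V == V.flat[0]):
        warnings.warn("constant count matrix; defaulting to rank 1")
        return RankSelection(1, {}, False)
    coph = {}
    for r in ranks:
        coph[r] = nmf_extract(counts, r, n_runs=n_runs, seed=seed + r,
                              **nmf_kwargs).cophenetic
    return rank_from_cophenetics(coph)


# ---------------------------------------------------------------------------
# Refitting against a reference catalog
# ---------------------------------------------------------------------------

def fit_exposures(counts, reference: SignatureSet) -> ExposureMatrix:
    """Per-window non-negative least squares against reference signatures."""
    V = np.asarray(getattr(counts, "counts", counts), dtype=float)
    channels = getattr(counts, "channels", None)
    if channels is not None and tuple(channels) != tuple(reference.channels):
        raise ValueError("count matrix channels do not match the reference")
    A = reference.matrix.T  # (channels, signatures)
    expo = np.zeros((V.shape[0], A.shape[1]))
    resid = np.zeros(V.shape[0])
    for i, row in enumerate(V):
        expo[i], resid[i] = nnls(A, row)
    recon = expo @ reference.matrix
    cosines = np.array([cosine_similarity(r, v) for r, v in zip(recon, V)])
    return ExposureMatrix(expo, reference.names, recon_cosine=cosines,
                          residual=resid)


@dataclass
class StrictFitResult:
    signatures: Tuple[str, ...]
    exposures: ExposureMatrix
    cosine_trace: List[Tuple[str, float]]
    final_cosine: float


def _overall_cosine(V, reference, names) -> Tuple[float, ExposureMatrix]:
    sub = reference.subset(names)
    expo = fit_exposures(V, sub)
    recon = expo.values @ sub.matrix
    return cosine_similarity(recon.ravel(), np.asarray(V, float).ravel()), expo


def strict_fit(
    counts,
    reference: SignatureSet,
    config: StrictFitConfig = StrictFitConfig(),
) -> StrictFitResult:
    """Backward-eliminate reference signatures that barely help the fit.

    Starting from the full catalog, the signature whose removal lowers the
    overall reconstruction cosine the least is dropped, as long as that drop
    does not exceed ``max_delta``; elimination stops otherwise (and always
    keeps at least one signature).  Ties break toward the signature with the
    smaller total exposure, then by name.
    """
    V = np.asarray(getattr(counts, "counts", counts), dtype=float)
    channels = getattr(counts, "channels", None)
    names = list(reference.names)
    base_cos, expo = _overall_cosine(V, reference, names)
    trace: List[Tuple[str, float]] = []
    while len(names) > 1:
        candidates = []
        for k, name in enumerate(names):
            trial = names[:k] + names[k + 1:]
            cos_k, _ = _overall_cosine(V, reference, trial)
            decrease = base_cos - cos_k
            total_expo = expo.values[:, expo.names.index(name)].sum()
            candidates.append((decrease, total_expo, name, cos_k))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        decrease, _, victim, new_cos = candidates[0]
        if decrease > config.max_delta:
            break
        names.remove(victim)
        trace.append((victim, decrease))
        base_cos, expo = _overall_cosine(V, reference, names)
    final_cos, expo = _overall_cosine(V, reference, names)
    return StrictFitResult(tuple(names), expo, trace, final_cos)


# ---------------------------------------------------------------------------
# Exposure profiles and polymerase attribution
# ---------------------------------------------------------------------------

DEFAULT_RINGS = ((0, 500), (500, 2000), (2000, 8000))


def exposure_profile(exposures: ExposureMatrix) -> ExposureMatrix:
    """Relative per-window contribution of each signature."""
    return exposures.to_relative()


def ring_aggregate(
    exposures: ExposureMatrix,
    offsets: np.ndarray,
    rings: Sequence[Tuple[float, float]] = DEFAULT_RINGS,
):
    """Relative signature contributions in nested origin-centered rings.

    ``offsets`` gives each window's center relative to the origin midpoint;
    ring (a, b) collects windows with a <= |offset| < b, so rings never
    overlap (1-kb core, 4-kb annulus, 16-kb annulus at the defaults).
    """
    import pandas as pd

    offsets = np.asarray(offsets, dtype=float)
    rows = []
    for a, b in rings:
        mask = (np.abs(offsets) >= a) & (np.abs(offsets) < b)
        total = exposures.values[mask].sum()
        contrib = (
            exposures.values[mask].sum(axis=0) / total
            if total > 0
            else np.full(len(exposures.names), np.nan)
        )
        rows.append({"ring": f"[{a},{b})", "n_windows": int(mask.sum()),
                     **dict(zip(exposures.names, contrib))})
    return pd.DataFrame(rows)


@dataclass
class SigmoidFit:
    floor: float
    ceiling: float
    midpoint: float
    slope: float


def fit_sigmoid(distance: np.ndarray, y: np.ndarray) -> SigmoidFit:
    """Four-parameter logistic fit of a profile against distance."""
    distance = np.asarray(distance, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    distance, y = distance[ok], y[ok]

    def f(d, floor, ceiling, mid, slope):
        from scipy.special import expit

        return floor + (ceiling - floor) * expit(-slope * (d - mid))

    span = y.max() - y.min() if len(y) else 1.0
    d_hi = float(distance.max()) if len(distance) else 1.0
    bounds = ([y.min() - span, y.min() - span, 0, -1],
              [y.max() + span, y.max() + span, d_hi * 2 + 1, 1])
    best = None
    # multistart over midpoint/slope: the 4PL surface has flat local optima
    for mid0 in np.quantile(distance, [0.2, 0.4, 0.6, 0.8]):
        for slope0 in (0.002, 0.02, -0.002, -0.02):
            p0 = [float(y.min()), float(y.max()), float(mid0), slope0]
            try:
                params, _ = curve_fit(f, distance, y, p0=p0, bounds=bounds,
                                      maxfev=20000)
            except RuntimeError:
                continue
            rss = float(np.sum((f(distance, *params) - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, params)
    if best is None:
        raise RuntimeError("sigmoid fit failed")
    return SigmoidFit(*map(float, best[1]))


@dataclass
class PolymeraseAttribution:
    exposures: ExposureMatrix       # absolute mutations per window
    surviving: Tuple[str, ...]
    fits: Dict[str, SigmoidFit]


def polymerase_attribution(
    counts,
    pol_reference: SignatureSet,
    offsets: np.ndarray,
    config: StrictFitConfig = StrictFitConfig(),
    fit_names: Optional[Sequence[str]] = None,
) -> PolymeraseAttribution:
    """Strict-fit restricted to polymerase-proofreading signatures.

    Returns absolute per-window attributions for each offered signature
    (zero where eliminated) plus four-parameter sigmoid fits of the named
    profiles against absolute distance from the origin midpoint.
    """
    res = strict_fit(counts, pol_reference, config)
    V = np.asarray(getattr(counts, "counts", counts), dtype=float)
    full = np.zeros((V.shape[0], len(pol_reference.names)))
    for j, name in enumerate(pol_reference.names):
        if name in res.signatures:
            full[:, j] = res.exposures.values[:, res.signatures.index(name)]
    expo = ExposureMatrix(full, pol_reference.names)
    fits = {}
    d = np.abs(np.asarray(offsets, dtype=float))
    for name in (fit_names if fit_names is not None else res.signatures):
        j = pol_reference.names.index(name)
        fits[name] = fit_sigmoid(d, full[:, j])
    return PolymeraseAttribution(expo, res.signatures, fits)


# ---------------------------------------------------------------------------
# Catalog I/O (COSMIC-style TSV layout)
# ---------------------------------------------------------------------------

def write_catalog(signatures: SignatureSet, path) -> None:
    import pandas as pd

    df = pd.DataFrame(signatures.matrix.T, columns=list(signatures.names))
    df.insert(0, "Type", list(signatures.channels))
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path, channels: Tuple[str, ...] = SBS96_LABELS) -> SignatureSet:
    """Read a channels-as-rows TSV catalog, reordering to canonical order."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    df = df.set_index(type_col)
    missing = set(channels) - set(df.index)
    if missing:
        raise ValueError(f"catalog missing channels, e.g. {sorted(missing)[:3]}")
    df = df.loc[list(channels)]
    return SignatureSet.from_matrix(df.to_numpy().T, tuple(df.columns), channels)
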