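"""In silico evolution of origin sequences under fitted mutational rules.

Three probability density functions distill the observed mutational
landscape of efficient replication origins:

* PDF-1 — where a base mutates, as a function of distance from the origin
  midpoint (baseline plus a multipeak Gaussian profile);
* PDF-2 — what it mutates to, given its pyrimidine-frame trinucleotide
  context and the positional activity of the operating signatures,
  corrected for the target library's own context composition;
* PDF-3 — on which strand the change is fixed (probability that the
  pyrimidine-frame substitution lands on the written strand).

A library of naive sequences is then mutated round by round; trajectories
of GC content, skews, and Shannon diversity are reported with RMSE against
observed target profiles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from ._seq import BASES, decode, encode
from .seqfeatures import shannon_diversity, skew_profile
from .signatures import SBS96_LABELS, SignatureSet, StrictFitConfig, strict_fit

# Pyrimidine-frame context space: center in (C, T), flanks in ACGT => 32.
N_CONTEXTS = 32
# Alternate bases per center, in ACGT order, as codes (A=0,C=1,G=2,T=3).
ALT_CODES = np.array([[0, 2, 3],   # C -> A, G, T
                      [0, 1, 2]])  # T -> A, C, G

_CHAN_LOOKUP = {lab: i for i, lab in enumerate(SBS96_LABELS)}


def context_channel_table() -> np.ndarray:
    """Map (context index, alternate slot) -> SBS96 channel index.

    Context index = center(0=C,1=T)*16 + 5'base*4 + 3'base.
    """
    tbl = np.zeros((N_CONTEXTS, 3), dtype=np.int64)
    for center_idx, center in enumerate("CT"):
        for l in range(4):
            for r in range(4):
                ctx = center_idx * 16 + l * 4 + r
                for slot in range(3):
                    alt = BASES[ALT_CODES[center_idx, slot]]
                    lab = f"{BASES[l]}[{center}>{alt}]{BASES[r]}"
                    tbl[ctx, slot] = _CHAN_LOOKUP[lab]
    return tbl


def context_frequencies(sequences: Sequence[str]) -> np.ndarray:
    """Pyrimidine-frame trinucleotide frequencies of a library (32-vector)."""
    counts = np.zeros(N_CONTEXTS, dtype=np.int64)
    for seq in sequences:
        codes = encode(seq)
        tri = np.lib.stride_tricks.sliding_window_view(codes, 3)
        ok = np.all(tri <= 3, axis=1)
        tri = tri[ok].astype(np.int64)
        l, mid, r = tri[:, 0], tri[:, 1], tri[:, 2]
        pur = (mid == 0) | (mid == 2)
        midp = np.where(pur, 3 - mid, mid)
        lp = np.where(pur, 3 - r, l)
        rp = np.where(pur, 3 - l, r)
        ctx = (midp == 3).astype(np.int64) * 16 + lp * 4 + rp
        counts += np.bincount(ctx, minlength=N_CONTEXTS)
    total = counts.sum()
    return counts / total if total else np.full(N_CONTEXTS, 1 / N_CONTEXTS)


# ---------------------------------------------------------------------------
# PDF-1: positional mutation probability
# ---------------------------------------------------------------------------

@dataclass
class Pdf1:
    baseline: float
    peaks: List[Tuple[float, float, float]]  # (amplitude, center, width)

    def evaluate(self, offsets: np.ndarray) -> np.ndarray:
        x = np.asarray(offsets, dtype=float)
        y = np.full_like(x, self.baseline)
        for a, c, w in self.peaks:
            y = y + a * np.exp(-((x - c) ** 2) / (2 * w ** 2))
        return np.clip(y, 0.0, None)


def _gauss_model(n_peaks: int) -> Callable:
    def f(x, *params):
        y = np.full_like(x, params[0], dtype=float)
        for i in range(n_peaks):
            a, c, w = params[1 + 3 * i: 4 + 3 * i]
            y = y + a * np.exp(-((x - c) ** 2) / (2 * w ** 2))
        return y
    return f


def fit_pdf1(
    profile: np.ndarray,
    offsets: np.ndarray,
    max_peaks: int = 4,
) -> Pdf1:
    """Fit baseline + multipeak Gaussians to a normalized rate profile.

    The number of peaks (1..max_peaks) is chosen by BIC; a flat profile
    collapses to near-zero amplitudes.  ``offsets`` are window centers
    relative to the origin midpoint.
    """
    x = np.asarray(offsets, dtype=float)
    y = np.asarray(profile, dtype=float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    span = x.max() - x.min()
    best = None
    for n_peaks in range(1, max_peaks + 1):
        f = _gauss_model(n_peaks)
        resid = y - np.median(y)
        p0 = [float(np.median(y))]
        lo = [-np.inf]
        hi = [np.inf]
        order = np.argsort(np.abs(resid))[::-1]
        centers = []
        for j in order:
            if all(abs(x[j] - c) > span / (2 * max_peaks) for c in centers):
                centers.append(x[j])
            if len(centers) == n_peaks:
                break
        while len(centers) < n_peaks:
            centers.append(0.0)
        for c in centers:
            p0 += [float(max(y.max() - np.median(y), 1e-3)), float(c), span / 10]
            lo += [-np.inf, float(x.min()), span / 200]
            hi += [np.inf, float(x.max()), span]
        try:
            params, _ = curve_fit(f, x, y, p0=p0, bounds=(lo, hi), maxfev=30000)
        except RuntimeError:
            continue
        rss = float(np.sum((f(x, *params) - y) ** 2))
        n, k = len(x), len(params)
        bic = n * np.log(max(rss / n, 1e-300)) + k * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, n_peaks, params)
    if best is None:
        raise RuntimeError("pdf1 fit failed at every peak count")
    _, n_peaks, params = best
    peaks = [tuple(map(float, params[1 + 3 * i: 4 + 3 * i])) for i in range(n_peaks)]
    return Pdf1(float(params[0]), peaks)


# ---------------------------------------------------------------------------
# Positional curves (shared by PDF-2 and PDF-3)
# ---------------------------------------------------------------------------

@dataclass
class PositionalCurve:
    """Either a Gaussian bump or a four-parameter sigmoid over offset."""

    kind: str  # "gaussian" | "sigmoid"
    params: Tuple[float, ...]

    def evaluate(self, offsets: np.ndarray) -> np.ndarray:
        x = np.asarray(offsets, dtype=float)
        if self.kind == "gaussian":
            b, a, c, w = self.params
            return b + a * np.exp(-((x - c) ** 2) / (2 * w ** 2))
        from scipy.special import expit

        floor, ceiling, mid, slope = self.params
        return floor + (ceiling - floor) * expit(slope * (x - mid))


def _fit_positional_curve(x: np.ndarray, y: np.ndarray,
                          weights: Optional[np.ndarray] = None
                          ) -> PositionalCurve:
    """Fit Gaussian and sigmoid candidates; keep the lower-residual model.

    ``weights`` (e.g. per-window observation counts) enter as inverse
    variances so sparsely observed windows do not drag the fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if weights is None:
        weights = np.ones_like(y)
    else:
        weights = np.asarray(weights, dtype=float)
    ok = np.isfinite(y) & (weights > 0)
    x, y, weights = x[ok], y[ok], weights[ok]
    sigma = 1.0 / np.sqrt(weights)
    span = x.max() - x.min()
    results = []

    def gauss(xx, b, a, c, w):
        return b + a * np.exp(-((xx - c) ** 2) / (2 * w ** 2))

    def sigm(xx, floor, ceiling, mid, slope):
        from scipy.special import expit

        return floor + (ceiling - floor) * expit(slope * (xx - mid))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            p0 = [float(np.median(y)), float(y.max() - np.median(y)),
                  float(x[np.argmax(y)]), span / 10]
            p, _ = curve_fit(gauss, x, y, p0=p0, sigma=sigma, maxfev=20000)
            rss = float(np.sum(weights * (gauss(x, *p) - y) ** 2))
            results.append((rss, PositionalCurve("gaussian", tuple(map(float, p)))))
        except RuntimeError:
            pass
        lo = float(np.mean(y[x <= np.quantile(x, 0.25)]))
        hi = float(np.mean(y[x >= np.quantile(x, 0.75)]))
        for slope0 in (4 / max(span, 1.0), 40 / max(span, 1.0)):
            for mid0 in (0.0, -span / 4, span / 4):
                try:
                    p0 = [lo, hi, mid0, slope0]
                    p, _ = curve_fit(sigm, x, y, p0=p0, sigma=sigma,
                                     maxfev=20000)
                    rss = float(np.sum(weights * (sigm(x, *p) - y) ** 2))
                    results.append(
                        (rss, PositionalCurve("sigmoid", tuple(map(float, p)))))
                except RuntimeError:
                    pass
    if not results:
        # constant fallback
        return PositionalCurve("gaussian", (float(np.mean(y)), 0.0, 0.0, 1.0))
    results.sort(key=lambda r: r[0])
    return results[0][1]


# ---------------------------------------------------------------------------
# PDF-2: substitution outcome given context and position
# ---------------------------------------------------------------------------

@dataclass
class Pdf2:
    signatures: SignatureSet
    curves: Dict[str, PositionalCurve]
    context_freq: np.ndarray  # (32,)

    def table(self, offsets: np.ndarray) -> np.ndarray:
        """P(alternate | position, context): shape (n_offsets, 32, 3).

        Assembled as sum over signatures of exposure_s(x) * sig_s(channel)
        divided by the context frequency, renormalized over the three
        alternates at each (position, context).
        """
        offsets = np.asarray(offsets, dtype=float)
        chan_tbl = context_channel_table()
        weights = np.stack(
            [np.clip(self.curves[n].evaluate(offsets), 0.0, None)
             for n in self.signatures.names]
        )  # (k, n_off)
        sig_probs = self.signatures.matrix[:, chan_tbl]  # (k, 32, 3)
        raw = np.einsum("ko,kca->oca", weights, sig_probs)
        freq = np.clip(self.context_freq, 1e-12, None)
        raw = raw / freq[None, :, None]
        totals = raw.sum(axis=2, keepdims=True)
        uniform = np.full_like(raw, 1 / 3)
        return np.where(totals > 0, raw / np.where(totals > 0, totals, 1.0), uniform)


def fit_pdf2(
    counts,
    reference: SignatureSet,
    offsets: np.ndarray,
    context_freq: Optional[np.ndarray] = None,
    config: StrictFitConfig = StrictFitConfig(),
) -> Pdf2:
    """Fit per-signature positional activity curves from a count matrix.

    A strict refit selects the operating signatures; each surviving
    signature's relative per-window exposure is fitted with a Gaussian or
    sigmoid curve (lower residual wins).  ``context_freq`` is the target
    library's pyrimidine-frame trinucleotide composition used for the
    composition correction (uniform if omitted).
    """
    res = strict_fit(counts, reference, config)
    sub = reference.subset(list(res.signatures))
    rel = res.exposures.to_relative()
    totals = res.exposures.values.sum(axis=1)
    curves = {}
    for j, name in enumerate(res.signatures):
        curves[name] = _fit_positional_curve(offsets, rel.values[:, j],
                                             weights=totals)
    if context_freq is None:
        context_freq = np.full(N_CONTEXTS, 1 / N_CONTEXTS)
    return Pdf2(sub, curves, np.asarray(context_freq, dtype=float))


# ---------------------------------------------------------------------------
# PDF-3: strand fixation probability
# ---------------------------------------------------------------------------

@dataclass
class Pdf3:
    """Per substitution type, P(pyrimidine fixed on the written strand)."""

    types: Tuple[str, ...]
    curves: Dict[str, PositionalCurve]

    def table(self, offsets: np.ndarray) -> np.ndarray:
        offsets = np.asarray(offsets, dtype=float)
        out = np.stack(
            [np.clip(self.curves[t].evaluate(offsets), 0.0, 1.0) for t in self.types]
        )
        return out.T  # (n_offsets, 6)

    @classmethod
    def neutral(cls, types=("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")) -> "Pdf3":
        return cls(tuple(types),
                   {t: PositionalCurve("gaussian", (0.5, 0.0, 0.0, 1.0))
                    for t in types})


def fit_pdf3(rsb, offsets: np.ndarray) -> Pdf3:
    """Fit strand-fixation curves from a replication strand bias profile.

    The raw empirical forward proportion per window,
    ``n_fwd / (n_fwd + n_rev)``, is fitted per substitution type with a
    Gaussian-or-sigmoid curve clipped to [0,1], weighting each window by
    its total count (binomial precision): pseudocounted ratios would bias
    sparse windows toward 1/2, and unweighted fits would let empty flanks
    drag the curve.
    """
    totals = rsb.n_fwd + rsb.n_rev
    with np.errstate(invalid="ignore"):
        p = np.where(totals > 0, rsb.n_fwd / np.maximum(totals, 1), np.nan)
    curves = {}
    for i, t in enumerate(rsb.types):
        if totals[i].sum() == 0:
            # no observations for this type: no evidence of bias
            curves[t] = PositionalCurve("gaussian", (0.5, 0.0, 0.0, 1.0))
            continue
        curves[t] = _fit_positional_curve(offsets, p[i], weights=totals[i])
    return Pdf3(tuple(rsb.types), curves)


# ---------------------------------------------------------------------------
# The evolution engine
# ---------------------------------------------------------------------------

@dataclass
class PdfBundle:
    pdf1: Pdf1
    pdf2: Pdf2
    pdf3: Pdf3

    def save(self, path) -> None:
        payload = {
            "pdf1": {"baseline": self.pdf1.baseline, "peaks": self.pdf1.peaks},
            "pdf2": {
                "signatures": {
                    "names": list(self.pdf2.signatures.names),
                    "matrix": self.pdf2.signatures.matrix.tolist(),
                    "channels": list(self.pdf2.signatures.channels),
                },
                "curves": {n: asdict(c) for n, c in self.pdf2.curves.items()},
                "context_freq": self.pdf2.context_freq.tolist(),
            },
            "pdf3": {
                "types": list(self.pdf3.types),
                "curves": {t: asdict(c) for t, c in self.pdf3.curves.items()},
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "PdfBundle":
        with open(path) as fh:
            d = json.load(fh)
        pdf1 = Pdf1(d["pdf1"]["baseline"],
                    [tuple(p) for p in d["pdf1"]["peaks"]])
        sigs = SignatureSet(
            np.array(d["pdf2"]["signatures"]["matrix"]),
            tuple(d["pdf2"]["signatures"]["names"]),
            tuple(d["pdf2"]["signatures"]["channels"]),
        )
        pdf2 = Pdf2(
            sigs,
            {n: PositionalCurve(c["kind"], tuple(c["params"]))
             for n, c in d["pdf2"]["curves"].items()},
            np.array(d["pdf2"]["context_freq"]),
        )
        pdf3 = Pdf3(
            tuple(d["pdf3"]["types"]),
            {t: PositionalCurve(c["kind"], tuple(c["params"]))
             for t, c in d["pdf3"]["curves"].items()},
        )
        return cls(pdf1, pdf2, pdf3)


@dataclass
class EvolutionConfig:
    library_size: int = 1000
    seq_length: int = 20_000
    mutations_per_round: int = 100
    max_rounds: int = 5000
    markov_order: int = 6
    window_size: int = 100
    plateau_tol: float = 1e-4
    plateau_patience: int = 3
    seed: int = 0
    per_library_selection: bool = False

    def __post_init__(self):
        if self.mutations_per_round > self.seq_length:
            raise ValueError("mutations_per_round must not exceed seq_length")
        for name in ("library_size", "seq_length", "max_rounds", "window_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SequenceLibrary:
    codes: np.ndarray  # (n_sequences, length) uint8 in {0..3}
    round: int = 0

    @classmethod
    def from_sequences(cls, sequences: Sequence[str]) -> "SequenceLibrary":
        codes = np.stack([encode(s) for s in sequences])
        if np.any(codes > 3):
            raise ValueError("library sequences must be pure ACGT")
        return cls(codes.astype(np.uint8))

    def sequences(self) -> List[str]:
        return [decode(row) for row in self.codes]

    @property
    def gc(self) -> float:
        return float(np.mean((self.codes == 1) | (self.codes == 2)))


@dataclass
class Trajectory:
    snapshots: Dict[int, np.ndarray]
    gc_trace: List[Tuple[int, float]]
    final_round: int
    stopped_early: bool
    window_size: int


def _dyadic_rounds(max_rounds: int) -> List[int]:
    rounds = []
    r = 1
    while r <= max_rounds:
        rounds.append(r)
        r *= 2
    if rounds and rounds[-1] != max_rounds:
        rounds.append(max_rounds)
    return rounds


def evolve(
    library: SequenceLibrary,
    pdfs: PdfBundle,
    config: EvolutionConfig,
) -> Trajectory:
    """Run rounds of in silico evolution over the library.

    Each round, for each sequence, ``mutations_per_round`` distinct
    positions are drawn with probability proportional to PDF-1 (sequence
    ends lacking a full trinucleotide context are excluded); each drawn
    site is mutated by sampling the pyrimidine-frame alternate from PDF-2
    and the fixation strand from PDF-3.  Snapshots are stored at dyadic
    rounds; the run stops early when the library GC plateaus.
    """
    codes = library.codes.copy()
    n, L = codes.shape
    if L % config.window_size:
        raise ValueError("seq_length must be a multiple of window_size")
    offsets_pos = np.arange(L, dtype=float) - L / 2
    p1 = pdfs.pdf1.evaluate(offsets_pos)
    p1[0] = p1[-1] = 0.0
    if p1.sum() <= 0:
        raise ValueError("pdf1 is zero everywhere over the sequence")
    with np.errstate(divide="ignore"):
        logp = np.where(p1 > 0, np.log(p1), -np.inf)

    W = L // config.window_size
    win_offsets = (np.arange(W) + 0.5) * config.window_size - L / 2
    tbl2 = pdfs.pdf2.table(win_offsets)            # (W, 32, 3)
    cum2 = np.cumsum(tbl2, axis=2)
    tbl3 = pdfs.pdf3.table(win_offsets)            # (W, 6)

    rng = np.random.default_rng(config.seed)
    m = config.mutations_per_round
    snap_rounds = set(_dyadic_rounds(config.max_rounds))
    snapshots: Dict[int, np.ndarray] = {}
    gc_trace: List[Tuple[int, float]] = []
    plateau_run = 0
    last_gc = None
    final_round = 0
    stopped_early = False

    for r in range(1, config.max_rounds + 1):
        if m > 0:
            gumbel = rng.gumbel(size=(n, L))
            scores = logp[None, :] + gumbel
            idx = np.argpartition(-scores, m - 1, axis=1)[:, :m]
            rows = np.repeat(np.arange(n), m)
            pos = idx.ravel()
            left = codes[rows, pos - 1].astype(np.int64)
            mid = codes[rows, pos].astype(np.int64)
            right = codes[rows, pos + 1].astype(np.int64)
            pur = (mid == 0) | (mid == 2)
            midp = np.where(pur, 3 - mid, mid)
            lp = np.where(pur, 3 - right, left)
            rp = np.where(pur, 3 - left, right)
            center_idx = (midp == 3).astype(np.int64)
            ctx = center_idx * 16 + lp * 4 + rp
            win = pos // config.window_size
            u = rng.random(len(pos))
            slot = (cum2[win, ctx] < u[:, None]).sum(axis=1)
            np.clip(slot, 0, 2, out=slot)
            alt_pyr = ALT_CODES[center_idx, slot]
            type_idx = center_idx * 3 + slot
            pfwd = tbl3[win, type_idx]
            fwd = rng.random(len(pos)) < pfwd
            new = np.where(fwd, alt_pyr, 3 - alt_pyr).astype(np.uint8)
            codes[rows, pos] = new
        final_round = r
        if r in snap_rounds:
            snapshots[r] = codes.copy()
            gc = float(np.mean((codes == 1) | (codes == 2)))
            gc_trace.append((r, gc))
            if last_gc is not None and abs(gc - last_gc) < config.plateau_tol:
                plateau_run += 1
            else:
                plateau_run = 0
            last_gc = gc
            if plateau_run >= config.plateau_patience:
                stopped_early = True
                break
    return Trajectory(snapshots, gc_trace, final_round, stopped_early,
                      config.window_size)


def rmse(computed: np.ndarray, observed: np.ndarray) -> float:
    a = np.asarray(computed, dtype=float)
    b = np.asarray(observed, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.sqrt(np.mean((a[ok] - b[ok]) ** 2)))


def snapshot_features(codes: np.ndarray, window: int = 100,
                      k: int = 6) -> Dict[str, np.ndarray]:
    """Windowed GC, skews, and Shannon diversity of a library snapshot."""
    seqs = [decode(row) for row in codes]
    sk = skew_profile(seqs, window=window)
    sdi = shannon_diversity(seqs, window=window, k=k)
    return {
        "gc": sk.gc_content,
        "at_skew": sk.at_skew,
        "gc_skew": sk.gc_skew,
        "sdi": sdi.sdi,
    }


def trajectory_report(
    trajectory: Trajectory,
    targets: Optional[Dict[str, np.ndarray]] = None,
    k: int = 6,
):
    """Per-snapshot feature profiles with RMSE against observed targets."""
    import pandas as pd

    rows = []
    features = {}
    for r in sorted(trajectory.snapshots):
        feats = snapshot_features(trajectory.snapshots[r],
                                  window=trajectory.window_size, k=k)
        features[r] = feats
        row = {"round": r, "mean_gc": float(np.nanmean(feats["gc"]))}
        if targets:
            for name, obs in targets.items():
                if name in feats:
                    row[f"rmse_{name}"] = rmse(feats[name], obs)
        rows.append(row)
    return pd.DataFrame(rows), features
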