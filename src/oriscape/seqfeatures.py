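"""Sequence statistics around origins and over evolving libraries.

GC content and AT/GC skews per window, G-quadruplex motif scanning on both
strands, CpG-island calling by the classic Gardiner-Garden rule, k-mer
Shannon diversity with rarefaction, and an order-k Markov sequence
generator used to build calibrated naive libraries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._seq import A, C, G, T, decode, encode, revcomp


@dataclass
class SkewProfile:
    """Per-window base counts with AT/GC skews and GC content."""

    base_counts: np.ndarray  # (n_windows, 4) in A,C,G,T order
    window_size: int

    @property
    def at_skew(self) -> np.ndarray:
        a, t = self.base_counts[:, A], self.base_counts[:, T]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(a + t > 0, (a - t) / (a + t), np.nan)

    @property
    def gc_skew(self) -> np.ndarray:
        g, c = self.base_counts[:, G], self.base_counts[:, C]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(g + c > 0, (g - c) / (g + c), np.nan)

    @property
    def gc_content(self) -> np.ndarray:
        tot = self.base_counts.sum(axis=1)
        gc = self.base_counts[:, C] + self.base_counts[:, G]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, gc / tot, np.nan)


def _pool_windows(sequences: Sequence[str], window: int) -> List[np.ndarray]:
    """Encode sequences and check equal lengths divisible into windows."""
    codes = [encode(s) for s in sequences]
    L = len(codes[0])
    if any(len(c) != L for c in codes):
        raise ValueError("sequences must have equal length")
    if L % window:
        raise ValueError("sequence length must be a multiple of the window")
    return codes


def skew_profile(sequences: Sequence[str], window: int = 100) -> SkewProfile:
    """Base counts pooled over all sequences in consecutive windows.

    N bases are excluded from all counts (and hence from skew denominators).
    """
    codes = _pool_windows(sequences, window)
    L = len(codes[0])
    W = L // window
    counts = np.zeros((W, 4), dtype=np.int64)
    for c in codes:
        wins = c.reshape(W, window)
        for b in range(4):
            counts[:, b] += (wins == b).sum(axis=1)
    return SkewProfile(counts, window)


def domain_sequences(genome, domainset) -> List[str]:
    """Extract the full domain sequence of every origin in the set."""
    out = []
    for i, o in enumerate(domainset.origins):
        lo, hi = domainset.domain_bounds(i)
        seq = genome.fetch(o.chrom, lo, hi)
        if len(seq) != hi - lo:
            raise ValueError("domain exceeds chromosome; drop such origins first")
        out.append(seq)
    return out


G4_REGEX = re.compile(r"G{3,}(?:[ACGT]{1,7}G{3,}){3}")


@dataclass
class G4Hit:
    start: int
    end: int
    strand: str


def find_g4(sequence: str) -> List[G4Hit]:
    """G-quadruplex motifs (four G3+ tracts, loops of 1-7 nt) on both strands.

    The plus strand is scanned with the G-motif; the minus strand is scanned
    by applying the same motif to the reverse complement (equivalently, the
    C-motif read 5'->3' on the complementary strand) with coordinates mapped
    back.  Matching is greedy leftmost in each scanning direction, and
    matches on a strand never overlap.
    """
    sequence = sequence.upper()
    n = len(sequence)
    hits = [G4Hit(m.start(), m.end(), "+") for m in G4_REGEX.finditer(sequence)]
    rc = revcomp(sequence)
    hits += [G4Hit(n - m.end(), n - m.start(), "-")
             for m in G4_REGEX.finditer(rc)]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def find_cpg_islands(
    sequence: str,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
    window: int = 200,
    step: int = 1,
) -> List[Tuple[int, int]]:
    """CpG islands by the Gardiner-Garden rule.

    Sliding windows meeting GC >= ``min_gc`` and observed/expected CpG >=
    ``min_obs_exp`` are merged into maximal regions, trimmed to their
    outermost CpG dinucleotides; regions shorter than ``min_length`` are
    discarded.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < window:
        return []
    codes = encode(seq)
    is_c = (codes == C).astype(np.int64)
    is_g = (codes == G).astype(np.int64)
    cpg = np.zeros(n, dtype=np.int64)
    cpg[:-1] = (codes[:-1] == C) & (codes[1:] == G)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cpg = np.concatenate([[0], np.cumsum(cpg)])
    starts = np.arange(0, n - window + 1, step)
    nc = cum_c[starts + window] - cum_c[starts]
    ng = cum_g[starts + window] - cum_g[starts]
    ncpg = cum_cpg[starts + window] - cum_cpg[starts]
    gc = (nc + ng) / window
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_exp = np.where(nc * ng > 0, ncpg * window / np.maximum(nc * ng, 1), 0.0)
    ok = (gc >= min_gc) & (obs_exp >= min_obs_exp)
    islands: List[Tuple[int, int]] = []
    cur: Optional[List[int]] = None
    for s, flag in zip(starts, ok):
        if flag:
            if cur is not None and s <= cur[1]:
                cur[1] = s + window
            else:
                if cur is not None:
                    islands.append((cur[0], cur[1]))
                cur = [int(s), int(s + window)]
    if cur is not None:
        islands.append((cur[0], cur[1]))
    # refine boundaries: sliding windows blur edges by up to the window
    # size, so trim each merged region to its outermost CpG dinucleotide
    refined = []
    for a, b in islands:
        b = min(b, n)
        region = seq[a:b]
        first = region.find("CG")
        last = region.rfind("CG")
        if first == -1:
            continue
        refined.append((a + first, a + last + 2))
    return [(a, b) for a, b in refined if b - a >= min_length]


@dataclass
class DiversityProfile:
    sdi: np.ndarray
    n_kmers_observed: np.ndarray
    k: int
    correction: str


def _window_kmer_counts(
    codes_list: Sequence[np.ndarray], w_start: int, w_end: int, k: int
) -> np.ndarray:
    """Counts over the 4^k k-mer space pooled over sequences, one window.

    k-mers are read with step 1 and must lie fully inside the window;
    any k-mer touching a non-ACGT base is skipped.
    """
    counts = np.zeros(4 ** k, dtype=np.int64)
    mult = 4 ** np.arange(k - 1, -1, -1)
    for codes in codes_list:
        seg = codes[w_start:w_end]
        if len(seg) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(seg, k)
        valid = np.all(windows <= 3, axis=1)
        if not valid.any():
            continue
        idx = (windows[valid].astype(np.int64) * mult).sum(axis=1)
        counts += np.bincount(idx, minlength=4 ** k)
    return counts


def _sdi_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_diversity(
    sequences: Sequence[str],
    window: int = 100,
    k: int = 6,
    correction: str = "none",
    depth: Optional[int] = None,
    n_repetitions: int = 20,
    seed: int = 0,
) -> DiversityProfile:
    """Windowed k-mer Shannon diversity over an aligned sequence library.

    Within each window the overlapping k-mers of all sequences are pooled
    and SDI = -sum p_i ln p_i is computed.  With ``correction='rarefy'``
    each window's k-mer multiset is subsampled to a common depth (the
    smallest window depth unless ``depth`` is given) and SDI is averaged
    over seeded repetitions, removing the sample-size dependence of the
    index.
    """
    if window < k:
        raise ValueError("window must be at least k")
    codes = _pool_windows(sequences, window)
    L = len(codes[0])
    W = L // window
    all_counts = [
        _window_kmer_counts(codes, w * window, (w + 1) * window, k)
        for w in range(W)
    ]
    n_obs = np.array([int((c > 0).sum()) for c in all_counts])
    if correction == "none":
        sdi = np.array([_sdi_from_counts(c) for c in all_counts])
        return DiversityProfile(sdi, n_obs, k, "none")
    if correction != "rarefy":
        raise ValueError("correction must be 'none' or 'rarefy'")
    totals = [int(c.sum()) for c in all_counts]
    if depth is None:
        depth = min(t for t in totals if t > 0)
    rng = np.random.default_rng(seed)
    sdi = np.full(W, np.nan)
    for w, cnts in enumerate(all_counts):
        total = totals[w]
        if total < depth or total == 0:
            continue
        vals = []
        p = cnts / total
        for _ in range(n_repetitions):
            sub = rng.multinomial(depth, p)
            vals.append(_sdi_from_counts(sub))
        sdi[w] = float(np.mean(vals))
    return DiversityProfile(sdi, n_obs, k, "rarefy")


# ---------------------------------------------------------------------------
# Markov sequence generation
# ---------------------------------------------------------------------------

@dataclass
class MarkovModel:
    """Order-k nucleotide transition model with add-one smoothing."""

    order: int
    transition: np.ndarray     # (4^order, 4) row-stochastic
    initial: np.ndarray        # (4^order,) distribution over starting states

    @classmethod
    def train(cls, sequences: Sequence[str], order: int = 6,
              pseudocount: float = 0.0) -> "MarkovModel":
        """Estimate transitions from k-mer counts.

        States never observed in training fall back to a uniform row (and
        ``pseudocount`` can additionally smooth observed rows); observed
        transitions are otherwise used exactly, so degenerate training text
        reproduces itself.
        """
        k = order
        counts = np.zeros((4 ** k, 4), dtype=np.float64)
        init = np.zeros(4 ** k, dtype=np.float64)
        mult = 4 ** np.arange(k - 1, -1, -1)
        for seq in sequences:
            codes = encode(seq)
            if len(codes) < k + 1:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(codes, k + 1)
            valid = np.all(windows <= 3, axis=1)
            if not valid.any():
                continue
            states = (windows[valid, :k].astype(np.int64) * mult).sum(axis=1)
            nxt = windows[valid, k].astype(np.int64)
            np.add.at(counts, (states, nxt), 1)
            init += np.bincount(states, minlength=4 ** k)
        counts += pseudocount
        row_sums = counts.sum(axis=1, keepdims=True)
        transition = np.divide(counts, row_sums,
                               out=np.full_like(counts, 0.25),
                               where=row_sums > 0)
        if init.sum() == 0:
            init[:] = 1.0
        return cls(k, transition, init / init.sum())

    def generate(self, n_sequences: int, length: int, seed: int = 0) -> List[str]:
        """Sample sequences; all randomness comes from ``seed``."""
        k = self.order
        if length < k:
            raise ValueError("length must be at least the model order")
        rng = np.random.default_rng(seed)
        states = rng.choice(len(self.initial), size=n_sequences, p=self.initial)
        out = np.empty((n_sequences, length), dtype=np.uint8)
        # unpack initial k-mer
        st = states.copy()
        for j in range(k - 1, -1, -1):
            out[:, j] = st % 4
            st //= 4
        cum = np.cumsum(self.transition, axis=1)
        mod = 4 ** (k - 1)
        for pos in range(k, length):
            u = rng.random(n_sequences)
            rows = cum[states]
            nxt = (rows < u[:, None]).sum(axis=1).astype(np.uint8)
            out[:, pos] = nxt
            states = (states % mod) * 4 + nxt
        return [decode(row) for row in out]


def markov_generate(
    training_sequences: Sequence[str],
    order: int = 6,
    n_sequences: int = 1,
    length: int = 20_000,
    seed: int = 0,
) -> List[str]:
    """Train an order-k model on the given text and sample a library."""
    model = MarkovModel.train(training_sequences, order=order)
    return model.generate(n_sequences, length, seed=seed)


def kmer_spectrum(sequences: Sequence[str], k: int = 6) -> np.ndarray:
    """Normalized k-mer frequency vector over a set of sequences."""
    counts = np.zeros(4 ** k, dtype=np.int64)
    for seq in sequences:
        codes = encode(seq)
        if len(codes) < k:
            continue
        counts += _window_kmer_counts([codes], 0, len(codes), k)
    total = counts.sum()
    return counts / total if total else counts.astype(float)
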