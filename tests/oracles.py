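"""Independent brute-force oracles used by the equivalence tests.

Everything here is implemented directly from the channel/scoring
definitions with plain string and arithmetic operations, independently of
the package's vectorized/genome-walking implementations.
"""

import numpy as np

from oriscape.signatures import SBS96_LABELS

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_sbs96(ref, alt, left, right):
    """Channel index by direct label construction with pyrimidine folding."""
    if ref in "AG":
        ref, alt = COMP[ref], COMP[alt]
        left, right = COMP[right], COMP[left]
    return SBS96_LABELS.index(f"{left}[{ref}>{alt}]{right}")


def _common_prefix_len(a, b):
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def oracle_id83(seq, p, ref, alt):
    """ID83 label by string slicing; left-aligns the event first.

    ``p`` is the 0-based anchor position (ref[0] == seq[p]).
    """
    is_del = len(ref) > len(alt)
    unit = ref[1:] if is_del else alt[1:]
    while p > 0 and seq[p] == unit[-1]:
        unit = unit[-1] + unit[:-1]
        p -= 1
    L = len(unit)
    ev_start = p + 1
    ev_end = ev_start + (L if is_del else 0)
    if L == 1:
        b = unit if unit in "CT" else COMP[unit]
        right = 0
        while seq[ev_end + right] == unit:
            right += 1
        left = 0
        while seq[ev_start - 1 - left] == unit:
            left += 1
        if is_del:
            return f"1:Del:{b}:{min(1 + left + right, 6) - 1}"
        return f"1:Ins:{b}:{min(left + right, 5)}"
    lc = min(L, 5)
    fwd = 0
    while seq[ev_end + fwd * L:ev_end + (fwd + 1) * L] == unit:
        fwd += 1
    bwd = 0
    while seq[ev_start - (bwd + 1) * L:ev_start - bwd * L] == unit:
        bwd += 1
    if not is_del:
        return f"{lc}:Ins:R:{min(fwd + bwd, 5)}"
    copies = 1 + fwd + bwd
    if copies >= 2:
        return f"{lc}:Del:R:{min(copies, 6) - 1}"
    right_flank = seq[ev_end:ev_end + L]
    left_flank = seq[ev_start - L:ev_start]
    pre = _common_prefix_len(unit, right_flank)
    suf = _common_prefix_len(unit[::-1], left_flank[::-1])
    mh = min(max(pre, suf), (lc - 1 if lc < 5 else 5), L - 1)
    if mh >= 1:
        return f"{lc}:Del:M:{mh}"
    return f"{lc}:Del:R:0"


def oracle_chi2_2x2(table):
    """Pearson chi-square of a 2x2 table from first principles."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    total = t.sum()
    expected = row @ col / total
    return float(np.sum((t - expected) ** 2 / expected))


def oracle_pwm_hits(ctx, log_odds, min_rel, min_raw, center=12):
    """Exhaustive-offset dual-strand PWM scan by direct summation."""
    L = log_odds.shape[1]
    hits = set()
    for mat, strand in ((log_odds, "+"), (log_odds[::-1, ::-1], "-")):
        mn = mat.min(axis=0).sum()
        mx = mat.max(axis=0).sum()
        for off in range(len(ctx) - L + 1):
            score = sum(mat["ACGT".index(b), i]
                        for i, b in enumerate(ctx[off:off + L]))
            rel = (score - mn) / (mx - mn)
            if rel >= min_rel and score > min_raw and off <= center < off + L:
                hits.add((off, strand))
    return hits


def oracle_window_assignment(origins, half_width, window_size, pos):
    """Scan every domain; nearest midpoint wins; None when outside all."""
    best = None
    for k, o in enumerate(origins):
        m = o.midpoint
        if m - half_width <= pos < m + half_width:
            d = abs(pos - m)
            if best is None or d < best[0]:
                best = (d, k, (pos - (m - half_width)) // window_size)
    return None if best is None else (best[1], best[2])
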