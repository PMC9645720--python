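"""Synthetic study inputs with known ground truth.

Emulates the statistical structure of the real inputs — replication
origins with firing efficiencies, origin-anchored SNV/indel mutagenesis
with distinct signatures per spatial component (flat background, a narrow
center peak, and a flanking "volcano" with a central dip), side-dependent
strand bias, efficiency-scaled coverage peaks, and feature tables with
planted functional-variant and QTL enrichments — so every pipeline stage
can be tested against configured truth without external downloads.

Determinism: every output is a pure function of a :class:`TruthConfig` and
a seed; each generator derives its own named random stream, so regenerating
any one output is byte-identical regardless of call order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._seq import decode
from .evolution import ALT_CODES, N_CONTEXTS, context_channel_table
from .origins_io import (
    CoverageTrack,
    Genome,
    OriginDomainSet,
    OriginRecord,
    VariantRecord,
    efficiency_bins,
)
from .signatures import SBS96_LABELS, SignatureSet

_PYR = (1, 3)  # codes of C, T


@dataclass
class TruthConfig:
    """All generator parameters; serializable and reloadable bit-exactly."""

    # genome
    chrom: str = "chr1"
    genome_length: int = 20_000_000
    gc_content: float = 0.41
    # origins
    n_origins: int = 400
    min_spacing: int = 25_000
    origin_half_size: int = 500
    efficiency_shape: float = 2.0
    efficiency_scale: float = 1.0
    origin_class: str = "constitutive"
    half_width: int = 10_000
    # SNV model
    n_snvs: int = 200_000
    component_weights: Dict[str, float] = field(
        default_factory=lambda: {"background": 0.5, "center": 0.25, "volcano": 0.25}
    )
    center_sigma: float = 400.0
    volcano_offset: float = 1500.0
    volcano_sigma: float = 600.0
    # per component: P(alt | pyrimidine center), alternates in ACGT order
    # (C -> A,G,T ; T -> A,C,G)
    component_substitutions: Dict[str, Dict[str, Tuple[float, float, float]]] = field(
        default_factory=lambda: {
            "background": {"C": (0.10, 0.10, 0.80), "T": (0.15, 0.70, 0.15)},
            "center": {"C": (0.15, 0.70, 0.15), "T": (0.10, 0.10, 0.80)},
            "volcano": {"C": (0.70, 0.15, 0.15), "T": (0.60, 0.20, 0.20)},
        }
    )
    p_pyr_left: float = 0.75  # P(written ref is the pyrimidine | left of origin)
    biased_components: Tuple[str, ...] = ("center", "volcano")
    # indel model
    n_indels: int = 20_000
    homopolymer_fraction: float = 0.7
    n_homopolymer_sites: int = 16_000
    homopolymer_min_run: int = 5
    homopolymer_max_run: int = 8
    n_mh_cassettes: int = 8000
    mh_deletion_length: int = 6
    mh_length: int = 5
    mh_center_sigma: float = 500.0
    # coverage model
    coverage_baseline: float = 1.0
    coverage_peak_scale: float = 2.0
    coverage_noise_sd: float = 0.1
    # feature tables
    n_features: int = 300
    marked_fraction: float = 0.5
    feature_half_width: int = 2500
    variants_per_feature: float = 40.0
    functional_rank_rate: float = 0.15
    functional_fold: float = 2.0
    qtl_rate_per_kb: float = 2.0
    qtl_fold: float = 2.0
    n_tissues: int = 3
    motif_plant_rate: float = 0.6
    seed: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "TruthConfig":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        d["component_substitutions"] = {
            k: {b: tuple(v) for b, v in sub.items()}
            for k, sub in d["component_substitutions"].items()
        }
        d["biased_components"] = tuple(d["biased_components"])
        return cls(**d)


def _rng(config: TruthConfig, stream: int, seed: Optional[int] = None):
    base = config.seed if seed is None else seed
    return np.random.default_rng([int(base) % (2 ** 31), stream])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _plant_indel_sites(codes: np.ndarray, config: TruthConfig, mids: np.ndarray,
                       rng) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Write homopolymer runs and microhomology cassettes into the genome.

    Returns (hp_starts, hp_lengths, mh_positions).  Cassettes copy the
    five bases at the deletion start to just past its end, so deleting
    ``mh_deletion_length`` bases leaves >= ``mh_length`` bp of
    microhomology without forming a full tandem repeat.
    """
    L = len(codes)
    margin = 200
    hp_starts = np.sort(rng.integers(margin, L - margin,
                                     size=config.n_homopolymer_sites))
    hp_lengths = rng.integers(config.homopolymer_min_run,
                              config.homopolymer_max_run + 1,
                              size=config.n_homopolymer_sites)
    hp_bases = rng.integers(0, 4, size=config.n_homopolymer_sites)
    for s, ln, b in zip(hp_starts, hp_lengths, hp_bases):
        # avoid extending the run accidentally on either side
        codes[s:s + ln] = b
        if codes[s - 1] == b:
            codes[s - 1] = (b + 1) % 4
        if codes[s + ln] == b:
            codes[s + ln] = (b + 1) % 4

    dlen, mh = config.mh_deletion_length, config.mh_length
    oi = rng.integers(0, len(mids), size=config.n_mh_cassettes)
    offs = rng.normal(0, config.mh_center_sigma, size=config.n_mh_cassettes)
    mh_pos = (mids[oi] + offs).astype(np.int64)
    mh_pos = np.clip(mh_pos, margin, L - margin)
    mh_pos = np.unique(mh_pos)
    keep = np.concatenate([[True], np.diff(mh_pos) > 2 * (dlen + mh)])
    mh_pos = mh_pos[keep]
    for p in mh_pos:
        codes[p + dlen:p + dlen + mh] = codes[p:p + mh]
        # break any full tandem copy of the deleted unit
        if np.array_equal(codes[p + dlen:p + 2 * dlen], codes[p:p + dlen]):
            codes[p + 2 * dlen - 1] = (codes[p + 2 * dlen - 1] + 1) % 4
    return hp_starts, hp_lengths, mh_pos


def simulate_genome(config: TruthConfig, seed: Optional[int] = None) -> np.ndarray:
    """Raw genome codes (before indel-site planting); seeded, A/C/G/T only."""
    rng = _rng(config, 1, seed)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=config.genome_length, p=p).astype(np.uint8)


def simulate_origins(config: TruthConfig, seed: Optional[int] = None) -> List[OriginRecord]:
    """Jittered-grid origin placement guaranteeing the minimum spacing."""
    rng = _rng(config, 2, seed)
    margin = config.half_width + 1000
    usable = config.genome_length - 2 * margin
    spacing = usable / config.n_origins
    if spacing < config.min_spacing:
        raise ValueError("genome too short for requested origin count/spacing")
    jitter = max(0.0, (spacing - config.min_spacing) / 2)
    mids = margin + spacing * (np.arange(config.n_origins) + 0.5)
    mids = (mids + rng.uniform(-jitter, jitter, size=config.n_origins)).astype(np.int64)
    effs = rng.gamma(config.efficiency_shape, config.efficiency_scale,
                     size=config.n_origins)
    origins = [
        OriginRecord(config.chrom, int(m - config.origin_half_size),
                     int(m + config.origin_half_size),
                     name=f"ori{i}", origin_class=config.origin_class,
                     efficiency=float(e))
        for i, (m, e) in enumerate(zip(mids, effs))
    ]
    return efficiency_bins(origins)


@dataclass
class SyntheticStudy:
    """Orchestrates all generators over one shared genome realization."""

    config: TruthConfig
    seed: Optional[int] = None

    def __post_init__(self):
        self._cache: Dict[str, object] = {}

    # -- lazily built shared state --------------------------------------
    @property
    def origins(self) -> List[OriginRecord]:
        if "origins" not in self._cache:
            self._cache["origins"] = simulate_origins(self.config, self.seed)
        return self._cache["origins"]

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([o.midpoint for o in self.origins], dtype=np.int64)

    @property
    def codes(self) -> np.ndarray:
        if "codes" not in self._cache:
            codes = simulate_genome(self.config, self.seed)
            rng = _rng(self.config, 3, self.seed)
            hp_s, hp_l, mh_p = _plant_indel_sites(codes, self.config,
                                                  self.midpoints, rng)
            self._cache["codes"] = codes
            self._cache["hp_sites"] = (hp_s, hp_l)
            self._cache["mh_sites"] = mh_p
        return self._cache["codes"]

    @property
    def genome(self) -> Genome:
        if "genome" not in self._cache:
            self._cache["genome"] = Genome({self.config.chrom: decode(self.codes)})
        return self._cache["genome"]

    def domainset(self, half_width: Optional[int] = None,
                  window_size: int = 100) -> OriginDomainSet:
        hw = half_width if half_width is not None else self.config.half_width
        return OriginDomainSet(self.origins, half_width=hw, window_size=window_size)

    # -- truth ----------------------------------------------------------
    def context_frequencies(self) -> np.ndarray:
        """Pyrimidine-frame trinucleotide frequencies of the genome."""
        if "ctx_freq" not in self._cache:
            codes = self.codes.astype(np.int64)
            l, mid, r = codes[:-2], codes[1:-1], codes[2:]
            pur = (mid == 0) | (mid == 2)
            midp = np.where(pur, 3 - mid, mid)
            lp = np.where(pur, 3 - r, l)
            rp = np.where(pur, 3 - l, r)
            ctx = (midp == 3).astype(np.int64) * 16 + lp * 4 + rp
            counts = np.bincount(ctx, minlength=N_CONTEXTS)
            self._cache["ctx_freq"] = counts / counts.sum()
        return self._cache["ctx_freq"]

    def _component_alt_probs(self, comp: str) -> np.ndarray:
        """(32, 3) P(alt slot | context) for a component (context-free in
        flanks, so rows repeat per center base)."""
        sub = self.config.component_substitutions[comp]
        out = np.zeros((N_CONTEXTS, 3))
        out[:16] = np.asarray(sub["C"]) / np.sum(sub["C"])
        out[16:] = np.asarray(sub["T"]) / np.sum(sub["T"])
        return out

    def effective_signatures(self) -> SignatureSet:
        """Exact channel distribution of each component's emitted SNVs.

        Positions are drawn independently of context, so the channel
        probability is the genome context frequency times the configured
        alternate probability.
        """
        freq = self.context_frequencies()
        chan_tbl = context_channel_table()
        names = tuple(self.config.component_weights)
        mat = np.zeros((len(names), 96))
        for i, comp in enumerate(names):
            q = self._component_alt_probs(comp)
            probs = freq[:, None] * q  # (32, 3)
            np.add.at(mat[i], chan_tbl.ravel(), probs.ravel())
        return SignatureSet.from_matrix(mat, names, SBS96_LABELS)

    # -- variants --------------------------------------------------------
    def _sample_component_positions(self, comp: str, n: int, rng
                                    ) -> Tuple[np.ndarray, np.ndarray]:
        """Positions and origin indices for one component, honouring the
        side-dependent written-strand orientation by rejection."""
        cfg = self.config
        codes = self.codes
        L = len(codes)
        mids = self.midpoints
        effs = np.array([o.efficiency for o in self.origins])
        effp = effs / effs.sum()
        hw = cfg.half_width
        biased = comp in cfg.biased_components
        pos = np.empty(n, dtype=np.int64)
        ori = np.empty(n, dtype=np.int64)
        todo = n
        while todo > 0:
            k = todo
            if comp == "background":
                o = np.full(k, -1, dtype=np.int64)
                p = rng.integers(1, L - 1, size=k)
                off = np.zeros(k)
            else:
                o = rng.choice(len(mids), size=k, p=effp)
                if comp == "center":
                    off = rng.normal(0, cfg.center_sigma, size=k)
                else:
                    sign = rng.choice([-1.0, 1.0], size=k)
                    off = sign * cfg.volcano_offset + rng.normal(
                        0, cfg.volcano_sigma, size=k)
                off = np.clip(off, -hw + 2, hw - 2)
                p = mids[o] + off.astype(np.int64)
            base = codes[p].astype(np.int64)
            ok = np.ones(k, dtype=bool)
            if biased:
                p_pyr = np.where(off < 0, cfg.p_pyr_left, 1 - cfg.p_pyr_left)
                desired = rng.random(k) < p_pyr
                is_pyr = (base == 1) | (base == 3)
                ok = is_pyr == desired
            n_ok = int(ok.sum())
            start = n - todo
            pos[start:start + n_ok] = p[ok]
            ori[start:start + n_ok] = o[ok]
            todo -= n_ok
        return pos, ori

    def snvs(self) -> Tuple[List[VariantRecord], pd.DataFrame]:
        """SNVs plus the per-variant truth sidecar."""
        if "snvs" in self._cache:
            return self._cache["snvs"]
        cfg = self.config
        rng = _rng(cfg, 4, self.seed)
        codes = self.codes
        names = list(cfg.component_weights)
        w = np.array([cfg.component_weights[c] for c in names], dtype=float)
        counts = rng.multinomial(cfg.n_snvs, w / w.sum())
        all_pos, all_ori, all_comp = [], [], []
        for comp, k in zip(names, counts):
            p, o = self._sample_component_positions(comp, int(k), rng)
            all_pos.append(p)
            all_ori.append(o)
            all_comp += [comp] * int(k)
        pos = np.concatenate(all_pos)
        ori = np.concatenate(all_ori)
        comp = np.array(all_comp)
        pos, keep = np.unique(pos, return_index=True)
        ori, comp = ori[keep], comp[keep]

        base = codes[pos].astype(np.int64)
        left = codes[pos - 1].astype(np.int64)
        right = codes[pos + 1].astype(np.int64)
        pur = (base == 0) | (base == 2)
        midp = np.where(pur, 3 - base, base)
        lp = np.where(pur, 3 - right, left)
        rp = np.where(pur, 3 - left, right)
        ctx = (midp == 3).astype(np.int64) * 16 + lp * 4 + rp
        alt_slot = np.empty(len(pos), dtype=np.int64)
        u = rng.random(len(pos))
        for c in names:
            mask = comp == c
            q = self._component_alt_probs(c)
            cum = np.cumsum(q[ctx[mask]], axis=1)
            alt_slot[mask] = (cum < u[mask, None]).sum(axis=1).clip(max=2)
        center_idx = (midp == 3).astype(np.int64)
        alt_pyr = ALT_CODES[center_idx, alt_slot]
        written_alt = np.where(pur, 3 - alt_pyr, alt_pyr)
        chan = context_channel_table()[ctx, alt_slot]

        bases = "ACGT"
        variants = [
            VariantRecord(cfg.chrom, int(p) + 1, bases[b], bases[a])
            for p, b, a in zip(pos, base, written_alt)
        ]
        truth = pd.DataFrame({
            "pos0": pos,
            "component": comp,
            "origin_index": ori,
            "written_pyr": ~pur,
            "channel": chan,
        })
        self._cache["snvs"] = (variants, truth)
        return self._cache["snvs"]

    def indels(self) -> Tuple[List[VariantRecord], pd.DataFrame]:
        """1-bp slippage events at homopolymers and MH deletions at centers."""
        if "indels" in self._cache:
            return self._cache["indels"]
        cfg = self.config
        _ = self.codes  # ensures planted sites exist
        hp_starts, hp_lengths = self._cache["hp_sites"]
        mh_pos = self._cache["mh_sites"]
        rng = _rng(cfg, 5, self.seed)
        codes = self.codes
        bases = "ACGT"
        n_hp = int(round(cfg.n_indels * cfg.homopolymer_fraction))
        n_mh = cfg.n_indels - n_hp
        variants: List[VariantRecord] = []
        kinds: List[str] = []

        idx = rng.choice(len(hp_starts), size=min(n_hp, len(hp_starts)),
                         replace=False)
        is_ins = rng.random(len(idx)) < 0.5
        for j, ins in zip(idx, is_ins):
            s = int(hp_starts[j])
            anchor = s - 1
            b = bases[codes[s]]
            if ins:
                variants.append(VariantRecord(cfg.chrom, anchor + 1,
                                              bases[codes[anchor]],
                                              bases[codes[anchor]] + b))
                kinds.append("homopolymer_ins")
            else:
                variants.append(VariantRecord(cfg.chrom, anchor + 1,
                                              bases[codes[anchor]] + b,
                                              bases[codes[anchor]]))
                kinds.append("homopolymer_del")

        take = rng.choice(len(mh_pos), size=min(n_mh, len(mh_pos)), replace=False)
        dlen = cfg.mh_deletion_length
        for p in np.sort(mh_pos[take]):
            anchor = int(p) - 1
            ref = bases[codes[anchor]] + decode(codes[p:p + dlen])
            variants.append(VariantRecord(cfg.chrom, anchor + 1, ref, ref[0]))
            kinds.append("mh_deletion")
        truth = pd.DataFrame({
            "pos": [v.pos for v in variants],
            "kind": kinds,
        })
        self._cache["indels"] = (variants, truth)
        return self._cache["indels"]

    def variants(self) -> Tuple[List[VariantRecord], pd.DataFrame]:
        snvs, t1 = self.snvs()
        indels, _ = self.indels()
        return snvs + indels, t1

    # -- coverage tracks -------------------------------------------------
    def tracks(self, window: int = 100) -> Dict[str, CoverageTrack]:
        """Center-peaked, volcano, and flat control tracks over all domains."""
        if "tracks" in self._cache:
            return self._cache["tracks"]
        cfg = self.config
        rng = _rng(cfg, 6, self.seed)
        mids = self.midpoints
        effs = np.array([o.efficiency for o in self.origins])
        scale = cfg.coverage_peak_scale / effs.mean()
        hw = cfg.half_width
        W = 2 * hw // window
        rel = (np.arange(W) + 0.5) * window - hw
        out = {}
        shapes = {
            "center": np.exp(-rel ** 2 / (2 * cfg.center_sigma ** 2)),
            "volcano": (np.exp(-(rel - cfg.volcano_offset) ** 2
                               / (2 * cfg.volcano_sigma ** 2))
                        + np.exp(-(rel + cfg.volcano_offset) ** 2
                                 / (2 * cfg.volcano_sigma ** 2))),
            "flat": np.zeros(W),
        }
        for name, shape in shapes.items():
            rows = []
            for m, e in zip(mids, effs):
                height = scale * e if name != "flat" else 0.0
                vals = (cfg.coverage_baseline + height * shape
                        + rng.normal(0, cfg.coverage_noise_sd, size=W))
                vals = np.clip(vals, 0.0, None)
                starts = m - hw + np.arange(W) * window
                rows += [(cfg.chrom, int(s), int(s) + window, float(v))
                         for s, v in zip(starts, vals)]
            out[name] = CoverageTrack.from_lists(rows)
        self._cache["tracks"] = out
        return out

    # -- feature tables ----------------------------------------------------
    def feature_tables(self) -> "FeatureTables":
        if "features" in self._cache:
            return self._cache["features"]
        self._cache["features"] = _simulate_feature_tables(self)
        return self._cache["features"]

    # -- serialization -----------------------------------------------------
    def write_all(self, outdir) -> Dict[str, str]:
        """Write every emulated input to standard text formats."""
        from pathlib import Path

        from .origins_io import write_bedgraph, write_fasta, write_origins, write_vcf
        from .signatures import write_catalog

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        cfg = self.config
        paths["config"] = str(outdir / "truth_config.json")
        cfg.to_json(paths["config"])
        paths["genome"] = str(outdir / "genome.fa")
        write_fasta({cfg.chrom: decode(self.codes)}, paths["genome"])
        paths["origins"] = str(outdir / "origins.bed")
        write_origins(self.origins, paths["origins"])
        variants, truth = self.variants()
        paths["variants"] = str(outdir / "variants.vcf")
        write_vcf(variants, paths["variants"], contigs=[cfg.chrom])
        paths["truth"] = str(outdir / "variant_truth.tsv")
        truth.to_csv(paths["truth"], sep="\t", index=False)
        for name, track in self.tracks().items():
            paths[f"track_{name}"] = str(outdir / f"track_{name}.bedGraph")
            write_bedgraph(track, paths[f"track_{name}"])
        paths["catalog"] = str(outdir / "reference_catalog.tsv")
        write_catalog(self.reference_catalog(), paths["catalog"])
        ft = self.feature_tables()
        paths.update(ft.write(outdir, cfg.chrom))
        return paths

    def reference_catalog(self, n_decoys: int = 2) -> SignatureSet:
        """Truth signatures plus smooth decoy signatures, catalog-style."""
        truth = self.effective_signatures()
        rng = _rng(self.config, 7, self.seed)
        freq = self.context_frequencies()
        chan_tbl = context_channel_table()
        mats = [truth.matrix]
        names = list(truth.names)
        for d in range(n_decoys):
            q = rng.dirichlet(np.ones(3), size=N_CONTEXTS)
            probs = freq[:, None] * q
            row = np.zeros(96)
            np.add.at(row, chan_tbl.ravel(), probs.ravel())
            mats.append(row[None, :])
            names.append(f"decoy{d + 1}")
        return SignatureSet.from_matrix(np.vstack(mats), names, SBS96_LABELS)


# ---------------------------------------------------------------------------
# Feature tables (TSS/splice sites, functional ranks, QTLs, PWMs)
# ---------------------------------------------------------------------------

SP1_LIKE_COUNTS = np.array([
    # A GC-box style GC-rich motif, length 10
    [2, 1, 1, 2, 5, 1, 2, 1, 1, 4],
    [5, 2, 2, 4, 60, 3, 3, 2, 5, 50],
    [88, 92, 92, 89, 25, 91, 90, 92, 85, 30],
    [5, 5, 5, 5, 10, 5, 5, 5, 9, 16],
], dtype=float)

AT_RICH_COUNTS = np.array([
    [70, 75, 5, 80, 70, 5, 75, 70],
    [10, 5, 5, 5, 10, 5, 5, 10],
    [10, 5, 5, 5, 10, 5, 5, 10],
    [10, 15, 85, 10, 10, 85, 15, 10],
], dtype=float)

MIXED_COUNTS = np.array([
    [25, 60, 10, 25, 10, 60, 25, 10, 25],
    [25, 10, 60, 25, 10, 10, 25, 60, 25],
    [25, 20, 20, 25, 70, 20, 25, 20, 25],
    [25, 10, 10, 25, 10, 10, 25, 10, 25],
], dtype=float)


@dataclass
class FeatureTables:
    tss: pd.DataFrame          # chrom, pos, gene, marked
    functional: pd.DataFrame   # chrom, pos, rank
    qtls: pd.DataFrame         # chrom, pos, gene, tissue, q_value
    expression: pd.DataFrame   # gene, tpm
    pwms: List                 # enrichment.Pwm objects

    def write(self, outdir, chrom: str) -> Dict[str, str]:
        from pathlib import Path

        outdir = Path(outdir)
        paths = {}
        paths["tss"] = str(outdir / "tss.bed")
        with open(paths["tss"], "w") as fh:
            for _, r in self.tss.iterrows():
                fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.gene}\t"
                         f"{int(r.marked)}\n")
        paths["functional"] = str(outdir / "functional_ranks.tsv")
        self.functional.to_csv(paths["functional"], sep="\t", index=False)
        paths["qtls"] = str(outdir / "qtls.tsv")
        self.qtls.to_csv(paths["qtls"], sep="\t", index=False)
        paths["expression"] = str(outdir / "expression.tsv")
        self.expression.to_csv(paths["expression"], sep="\t", index=False)
        paths["pwms"] = str(outdir / "motifs.pfm")
        with open(paths["pwms"], "w") as fh:
            for pwm in self.pwms:
                fh.write(pwm.to_jaspar())
        return paths


def _simulate_feature_tables(study: SyntheticStudy) -> FeatureTables:
    from .enrichment import Pwm

    cfg = study.config
    rng = _rng(cfg, 8, study.seed)
    codes = study.codes
    mids = study.midpoints
    L = len(codes)
    n_marked = int(round(cfg.n_features * cfg.marked_fraction))
    n_unmarked = cfg.n_features - n_marked

    # marked features sit near origin midpoints; unmarked in inter-origin gaps
    oi = rng.choice(len(mids), size=n_marked, replace=False) \
        if n_marked <= len(mids) else rng.choice(len(mids), size=n_marked)
    marked_pos = mids[oi] + rng.integers(-500, 501, size=n_marked)
    gaps = (mids[:-1] + mids[1:]) // 2
    gi = rng.choice(len(gaps), size=n_unmarked, replace=n_unmarked > len(gaps))
    unmarked_pos = gaps[gi] + rng.integers(-2000, 2001, size=n_unmarked)

    pwms = [Pwm("SP1LIKE", SP1_LIKE_COUNTS), Pwm("ATBOX", AT_RICH_COUNTS),
            Pwm("MIXED", MIXED_COUNTS)]
    gc_motif = pwms[0]
    consensus_codes = np.argmax(gc_motif.probabilities(), axis=0).astype(np.uint8)

    rows_tss, rows_func = [], []
    genes = []
    for i, (pos, marked) in enumerate(
        [(int(p), True) for p in marked_pos]
        + [(int(p), False) for p in unmarked_pos]
    ):
        pos = int(np.clip(pos, cfg.feature_half_width + 10,
                          L - cfg.feature_half_width - 10))
        gene = f"G{i:05d}"
        genes.append((gene, marked))
        rows_tss.append({"chrom": cfg.chrom, "pos": pos, "gene": gene,
                         "marked": marked})
        rate = cfg.functional_rank_rate * (cfg.functional_fold if marked else 1.0)
        n_var = rng.poisson(cfg.variants_per_feature)
        offsets = rng.integers(-cfg.feature_half_width, cfg.feature_half_width,
                               size=n_var)
        planted_motif = marked and rng.random() < cfg.motif_plant_rate
        if planted_motif:
            m0 = pos + int(rng.integers(-200, 200))
            codes[m0:m0 + len(consensus_codes)] = consensus_codes
        for j, off in enumerate(offsets):
            p = pos + int(off)
            functional = rng.random() < min(rate, 1.0)
            if planted_motif and j == 0:
                p = m0 + len(consensus_codes) // 2
                functional = True
            rank = int(rng.integers(1, 3)) if functional else int(rng.integers(3, 8))
            rows_func.append({"chrom": cfg.chrom, "pos": p + 1, "rank": rank})

    qtl_rows = []
    for t in range(cfg.n_tissues):
        tissue = f"tissue{t + 1}"
        for gene_pos, (gene, marked) in zip(rows_tss, genes):
            lam = (cfg.qtl_rate_per_kb * (2 * cfg.feature_half_width / 1000)
                   * (cfg.qtl_fold if marked else 1.0))
            n_sig = rng.poisson(lam)
            n_null = rng.poisson(lam)
            offs = rng.integers(-cfg.feature_half_width, cfg.feature_half_width,
                                size=n_sig + n_null)
            qs = np.concatenate([
                rng.uniform(0, 0.05, size=n_sig),
                rng.uniform(0.051, 1.0, size=n_null),
            ])
            for off, q in zip(offs, qs):
                qtl_rows.append({
                    "chrom": cfg.chrom,
                    "pos": int(gene_pos["pos"]) + int(off) + 1,
                    "gene": gene, "tissue": tissue, "q_value": float(q),
                })

    expr = pd.DataFrame({
        "gene": [g for g, _ in genes],
        "tpm": rng.lognormal(1.0, 1.5, size=len(genes)),
    })
    return FeatureTables(
        tss=pd.DataFrame(rows_tss),
        functional=pd.DataFrame(rows_func),
        qtls=pd.DataFrame(qtl_rows),
        expression=expr,
        pwms=pwms,
    )


def simulate_variants(config: TruthConfig, seed: Optional[int] = None):
    """Convenience wrapper: SNVs + indels + truth from a fresh study."""
    study = SyntheticStudy(config, seed)
    return study.variants()


def simulate_tracks(config: TruthConfig, seed: Optional[int] = None):
    return SyntheticStudy(config, seed).tracks()


def simulate_feature_tables(config: TruthConfig, seed: Optional[int] = None):
    return SyntheticStudy(config, seed).feature_tables()


def small_config(**overrides) -> TruthConfig:
    """A reduced configuration for quick exercises: 2-Mb genome, 40 origins."""
    base = dict(
        genome_length=2_000_000,
        n_origins=40,
        n_snvs=20_000,
        n_indels=2_000,
        n_homopolymer_sites=1_600,
        n_mh_cassettes=800,
        n_features=60,
    )
    base.update(overrides)
    return TruthConfig(**base)
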