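"""SBS96/ID83 classification, NMF extraction, rank selection, refitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oriscape.origins_io import Genome, OriginDomainSet, OriginRecord, VariantRecord
from oriscape.signatures import (
    ID83_LABELS,
    SBS96_LABELS,
    SignatureSet,
    StrictFitConfig,
    build_count_matrix,
    classify_id83,
    classify_sbs96,
    cosine_similarity,
    fit_exposures,
    kl_update_trace,
    nmf_extract,
    polymerase_attribution,
    rank_from_cophenetics,
    ring_aggregate,
    select_rank,
    strict_fit,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _genome_with(core, flank_n=60, pad="ACGTT"):
    """Embed `core` at a known offset inside deterministic flanks."""
    flank = (pad * (flank_n // len(pad) + 1))[:flank_n]
    return Genome({"chr1": flank + core + flank}), flank_n


def _oracle_sbs96(ref, alt, left, right):
    if ref in "AG":
        ref, alt = COMP[ref], COMP[alt]
        left, right = COMP[right], COMP[left]
    return SBS96_LABELS.index(f"{left}[{ref}>{alt}]{right}")


class TestClassifySbs96:
    def test_pyrimidine_reference_unchanged(self):
        genome, off = _genome_with("ACG")
        v = VariantRecord("chr1", off + 2, "C", "T")
        assert SBS96_LABELS[classify_sbs96(v, genome)] == "A[C>T]G"

    def test_purine_reference_strand_folded(self):
        genome, off = _genome_with("TGA")  # G with 5' T, 3' A; G>A -> T[C>T]A
        v = VariantRecord("chr1", off + 2, "G", "A")
        assert SBS96_LABELS[classify_sbs96(v, genome)] == "T[C>T]A"

    def test_reference_mismatch_rejected(self):
        genome, off = _genome_with("ACG")
        with pytest.raises(ValueError, match="mismatch"):
            classify_sbs96(VariantRecord("chr1", off + 2, "T", "G"), genome)

    def test_random_snvs_match_string_oracle(self, rng, random_genome):
        seq = random_genome.fetch("chr1", 0, 100_000)
        positions = rng.integers(10, 99_990, 10_000)
        alts = rng.integers(0, 3, 10_000)
        for p, a in zip(positions, alts):
            ref = seq[p]
            alt = [b for b in "ACGT" if b != ref][a]
            v = VariantRecord("chr1", int(p) + 1, ref, alt)
            assert classify_sbs96(v, random_genome) == _oracle_sbs96(
                ref, alt, seq[p - 1], seq[p + 1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"),
           st.sampled_from("ACGT"), st.integers(0, 2))
    def test_strand_fold_involution(self, left, ref, right, alt_i):
        alt = [b for b in "ACGT" if b != ref][alt_i]
        fwd = _oracle_sbs96(ref, alt, left, right)
        rev = _oracle_sbs96(COMP[ref], COMP[alt], COMP[right], COMP[left])
        assert fwd == rev


class TestClassifyId83:
    def test_homopolymer_deletion_run_of_five(self):
        genome, off = _genome_with("GTTTTTG")
        # delete one T from the TTTTT run: homopolymer length 5 => label digit 4
        v = VariantRecord("chr1", off + 1, "GT", "G")
        assert ID83_LABELS[classify_id83(v, genome)] == "1:Del:T:4"

    def test_homopolymer_deletion_capped_six_plus(self):
        genome, off = _genome_with("GTTTTTTTTG")
        v = VariantRecord("chr1", off + 1, "GT", "G")
        assert ID83_LABELS[classify_id83(v, genome)] == "1:Del:T:5"

    def test_single_base_insertion_no_run(self):
        genome, off = _genome_with("GAG")
        v = VariantRecord("chr1", off + 1, "G", "GC")
        assert ID83_LABELS[classify_id83(v, genome)] == "1:Ins:C:0"

    def test_purine_folding_for_one_base_events(self):
        genome, off = _genome_with("CAAAC")
        v = VariantRecord("chr1", off + 1, "CA", "C")  # A run of 3 -> T channel
        assert ID83_LABELS[classify_id83(v, genome)] == "1:Del:T:2"

    def test_tandem_repeat_deletion(self):
        genome, off = _genome_with("TACGACGACGT")
        # delete first ACG of three tandem copies
        v = VariantRecord("chr1", off + 1, "TACG", "T")
        assert ID83_LABELS[classify_id83(v, genome)] == "3:Del:R:2"

    def test_microhomology_five_bp(self):
        # deletion of 6 bp whose first 5 bases recur right after the deletion
        core = "T" + "GACTGA" + "GACTG" + "CCTTA"
        genome, off = _genome_with(core)
        v = VariantRecord("chr1", off + 1, "TGACTGA", "T")
        assert ID83_LABELS[classify_id83(v, genome)] == "5:Del:M:5"

    def test_repeat_free_long_deletion(self):
        genome, off = _genome_with("TACGTGCATT")
        v = VariantRecord("chr1", off + 1, "TACGTG", "T")
        # flanks share no sequence with the deleted unit's ends here?
        lab = ID83_LABELS[classify_id83(VariantRecord("chr1", off + 1,
                                                      "TACGTG", "T"), genome)]
        assert lab.startswith("5:Del:")

    def test_non_left_aligned_normalized_with_warning(self):
        genome, off = _genome_with("GTTTTTG")
        # same event described mid-run
        v = VariantRecord("chr1", off + 3, "TT", "T")
        with pytest.warns(UserWarning, match="left-aligned"):
            ch = classify_id83(v, genome)
        assert ID83_LABELS[ch] == "1:Del:T:4"

    def test_random_indels_match_string_oracle(self, rng, random_genome):
        seq = random_genome.fetch("chr1", 0, 100_000)
        n = 1500
        for _ in range(n):
            p = int(rng.integers(100, 99_800))
            L = int(rng.integers(1, 8))
            if rng.random() < 0.5:
                ref = seq[p:p + 1 + L]
                alt = ref[0]
            else:
                ins = "".join(rng.choice(list("ACGT"), L))
                ref = seq[p]
                alt = ref + ins
            v = VariantRecord("chr1", p + 1, ref, alt)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                got = classify_id83(v, random_genome)
            assert ID83_LABELS[got] == _oracle_id83(seq, p, ref, alt)


def _oracle_id83(seq, p, ref, alt):
    """Independent string-slicing ID83 oracle (left-aligns first)."""
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
    pre = len_common_prefix(unit, right_flank)
    suf = len_common_prefix(unit[::-1], left_flank[::-1])
    mh = min(max(pre, suf), (lc - 1 if lc < 5 else 5), L - 1)
    if mh >= 1:
        return f"{lc}:Del:M:{mh}"
    return f"{lc}:Del:R:0"


def len_common_prefix(a, b):
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


class TestBuildCountMatrix:
    def test_single_snv_single_cell(self, random_genome):
        ds = OriginDomainSet([OriginRecord("chr1", 49_500, 50_500)])
        seq = random_genome.fetch("chr1", 0, 100_000)
        ref = seq[40_050]
        alt = [b for b in "ACGT" if b != ref][0]
        v = [VariantRecord("chr1", 40_051, ref, alt)]
        m = build_count_matrix(v, random_genome, ds, kind="SBS")
        assert m.counts.sum() == 1
        assert m.counts[0].sum() == 1

    def test_additivity_over_disjoint_sets(self, small_study, small_domainset):
        variants, _ = small_study.snvs()
        half = len(variants) // 2
        a = build_count_matrix(variants[:half], small_study.genome,
                               small_domainset).counts
        b = build_count_matrix(variants[half:], small_study.genome,
                               small_domainset).counts
        both = build_count_matrix(variants, small_study.genome,
                                  small_domainset).counts
        assert np.array_equal(a + b, both)

    def test_channel_marginals_match_truth_mixture(self, small_study,
                                                   small_domainset):
        variants, truth = small_study.snvs()
        m = build_count_matrix(variants, small_study.genome, small_domainset)
        marginal = m.counts.sum(axis=0)
        # expected: mixture of effective signatures weighted by in-domain counts
        sigs = small_study.effective_signatures()
        oi, _ = small_domainset.assign_many(
            "chr1", truth.pos0.to_numpy())
        in_dom = truth[oi >= 0]
        weights = in_dom.component.value_counts()
        expected = np.zeros(96)
        for comp, n in weights.items():
            expected += n * sigs.matrix[sigs.names.index(comp)]
        assert cosine_similarity(marginal, expected) > 0.995


class TestNmfExtract:
    def test_rank_one_exact_recovery(self, rng):
        s = rng.dirichlet(np.ones(96))
        e = rng.gamma(5, 100, size=50)
        V = np.outer(e, s)
        res = nmf_extract(V, 1, n_runs=5, seed=0, channels=SBS96_LABELS)
        assert cosine_similarity(res.signatures.matrix[0], s) > 0.999
        # exposures recover row totals
        assert np.allclose(res.exposures.values[:, 0], V.sum(axis=1), rtol=0.01)

    def test_two_separated_signatures_recovered(self, rng):
        s1 = np.zeros(96)
        s1[:48] = rng.dirichlet(np.ones(48))
        s2 = np.zeros(96)
        s2[48:] = rng.dirichlet(np.ones(48))
        expo = rng.gamma(2, 300, size=(60, 2))
        V = rng.poisson(expo @ np.vstack([s1, s2]))
        res = nmf_extract(V, 2, n_runs=10, seed=1, channels=SBS96_LABELS)
        for s in (s1, s2):
            assert max(cosine_similarity(row, s)
                       for row in res.signatures.matrix) > 0.95

    def test_objective_non_increasing(self, rng):
        V = rng.poisson(5, size=(40, 96)).astype(float)
        trace = kl_update_trace(V, 3, seed=0, n_iter=60)
        assert np.all(np.diff(trace) <= 1e-8 * np.maximum(trace[:-1], 1.0))

    def test_agrees_with_sklearn_mu_kl(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        V = rng.poisson(20, size=(50, 96)).astype(float)
        res = nmf_extract(V, 3, n_runs=10, seed=0, max_iter=500,
                          channels=SBS96_LABELS)
        best = np.inf
        for rs in range(5):
            m = sklearn.NMF(3, init="random", solver="mu",
                            beta_loss="kullback-leibler", max_iter=800,
                            tol=1e-7, random_state=rs)
            W = m.fit_transform(V)
            H = m.components_
            WH = W @ H + 1e-12
            mask = V > 0
            div = float(np.sum(V[mask] * np.log(V[mask] / WH[mask]))
                        - V.sum() + WH.sum())
            best = min(best, div)
        assert res.divergence <= best * 1.02 + 1e-6

    def test_rank_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            nmf_extract(rng.poisson(3, (10, 96)).astype(float), 10)


class TestSelectRank:
    def test_rule_application(self):
        sel = rank_from_cophenetics({2: 0.99, 3: 0.99, 4: 0.90})
        assert sel.rank == 3 and sel.decreasing_found

    def test_monotone_returns_max_with_warning(self):
        with pytest.warns(UserWarning, match="never decreased"):
            sel = rank_from_cophenetics({2: 0.90, 3: 0.95, 4: 0.99})
        assert sel.rank == 4 and not sel.decreasing_found

    def test_constant_counts_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            sel = select_rank(np.full((30, 96), 2.0), [2, 3, 4])
        assert sel.rank == 1


class TestCosineSimilarity:
    def test_trivial_and_formula(self, rng):
        v = rng.random(96)
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        a = np.zeros(96)
        a[:10] = 1
        b = np.zeros(96)
        b[50:60] = 1
        assert cosine_similarity(a, b) == 0.0
        assert cosine_similarity(a, np.zeros(96)) == 0.0
        x, y = rng.random(96), rng.random(96)
        expected = float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
        assert cosine_similarity(x, y) == pytest.approx(expected)


@pytest.fixture
def three_signatures(rng):
    mat = rng.dirichlet(np.ones(96) * 0.3, size=3)
    return SignatureSet.from_matrix(mat, ("sigA", "sigB", "sigC"))


class TestFitExposures:
    def test_pure_row_recovered(self, three_signatures):
        V = 100 * three_signatures.matrix[[0]]
        expo = fit_exposures(V, three_signatures)
        assert expo.values[0, 0] == pytest.approx(100, rel=1e-6)
        assert expo.values[0, 1:] == pytest.approx(0, abs=1e-6)

    def test_zero_row_zero_exposures(self, three_signatures):
        expo = fit_exposures(np.zeros((1, 96)), three_signatures)
        assert np.all(expo.values == 0)

    def test_noisy_mixture_rmse(self, rng, three_signatures):
        truth = rng.gamma(2, 2000, size=(30, 3))
        V = rng.poisson(truth @ three_signatures.matrix)
        expo = fit_exposures(V, three_signatures)
        rel_rmse = np.sqrt(np.mean((expo.values - truth) ** 2)) / truth.mean()
        assert rel_rmse < 0.10


class TestStrictFit:
    def test_absent_signature_eliminated(self, rng, three_signatures):
        truth = rng.gamma(2, 1500, size=(40, 2))
        V = rng.poisson(truth @ three_signatures.matrix[:2])
        res = strict_fit(V, three_signatures, StrictFitConfig(0.004))
        assert set(res.signatures) == {"sigA", "sigB"}

    def test_max_delta_zero_keeps_informative(self, rng, three_signatures):
        truth = rng.gamma(2, 1500, size=(40, 3))
        V = rng.poisson(truth @ three_signatures.matrix)
        res = strict_fit(V, three_signatures, StrictFitConfig(0.0))
        assert set(res.signatures) == {"sigA", "sigB", "sigC"}

    def test_huge_max_delta_single_survivor(self, rng, three_signatures):
        truth = rng.gamma(2, 1500, size=(40, 3))
        V = rng.poisson(truth @ three_signatures.matrix)
        res = strict_fit(V, three_signatures, StrictFitConfig(0.999))
        assert len(res.signatures) == 1

    def test_cosine_lower_bound(self, rng, three_signatures):
        V = rng.poisson(rng.gamma(2, 800, size=(30, 3))
                        @ three_signatures.matrix)
        full = strict_fit(V, three_signatures, StrictFitConfig(0.0))
        res = strict_fit(V, three_signatures, StrictFitConfig(0.02))
        bound = full.final_cosine - len(res.cosine_trace) * 0.02
        assert res.final_cosine >= bound - 1e-9


class TestExposureProfile:
    def test_single_signature_constant_one(self, rng):
        from oriscape.signatures import ExposureMatrix, exposure_profile

        expo = ExposureMatrix(rng.gamma(2, 10, size=(20, 1)), ("only",))
        rel = exposure_profile(expo)
        assert np.allclose(rel.values, 1.0)

    def test_ring_partition_covers_160_of_200(self, rng):
        from oriscape.signatures import ExposureMatrix

        offsets = -10_000 + (np.arange(200) + 0.5) * 100
        expo = ExposureMatrix(rng.gamma(2, 10, size=(200, 2)), ("a", "b"))
        df = ring_aggregate(expo, offsets)
        assert df.n_windows.sum() == 160
        # no window in two rings: totals match a direct mask union
        masks = [(np.abs(offsets) >= a) & (np.abs(offsets) < b)
                 for a, b in ((0, 500), (500, 2000), (2000, 8000))]
        assert not np.any(np.logical_and.reduce([m.astype(int) for m in masks],
                                                axis=0) > 1)

    def test_center_signature_dominates_core_ring(self, rng):
        from oriscape.signatures import ExposureMatrix

        offsets = -10_000 + (np.arange(200) + 0.5) * 100
        center = 50 * np.exp(-offsets ** 2 / (2 * 400.0 ** 2))
        flank = np.full(200, 5.0)
        expo = ExposureMatrix(np.column_stack([center, flank]),
                              ("center", "flank"))
        df = ring_aggregate(expo, offsets)
        core = df[df.ring == "[0,500)"].iloc[0]
        assert core["center"] > 0.8


class TestPolymeraseAttribution:
    def test_step_profile_midpoint_recovered(self, rng):
        sigs = SignatureSet.from_matrix(
            rng.dirichlet(np.ones(96) * 0.3, size=4),
            ("SBS10a-like", "SBS10b-like", "SBS10c-like", "SBS10d-like"))
        offsets = -10_000 + (np.arange(200) + 0.5) * 100
        inside = np.abs(offsets) < 2_000
        truth = np.zeros((200, 4))
        truth[:, 2] = np.where(inside, 80.0, 2.0)   # delta-pol inside 2 kb
        truth[:, 1] = np.where(inside, 2.0, 40.0)   # epsilon outside
        V = rng.poisson(truth @ sigs.matrix)
        res = polymerase_attribution(V, sigs, offsets,
                                     fit_names=["SBS10c-like"])
        fit = res.fits["SBS10c-like"]
        assert abs(fit.midpoint - 2_000) < 300
        # conservation: attributed total tracks observed total (least-squares
        # refitting can overshoot the count total only within noise)
        assert res.exposures.values.sum() <= V.sum() * 1.05

    def test_zero_counts_zero_attribution(self, rng):
        sigs = SignatureSet.from_matrix(
            rng.dirichlet(np.ones(96), size=4), tuple("wxyz"))
        res = polymerase_attribution(np.zeros((20, 96)), sigs,
                                     np.linspace(-1000, 1000, 20),
                                     fit_names=[])
        assert np.all(res.exposures.values == 0)


class TestCatalogRoundTrip:
    def test_write_read_preserves_signatures(self, tmp_path, three_signatures):
        from oriscape.signatures import read_catalog, write_catalog

        path = tmp_path / "catalog.tsv"
        write_catalog(three_signatures, path)
        back = read_catalog(path)
        assert back.names == three_signatures.names
        assert np.allclose(back.matrix, three_signatures.matrix)
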