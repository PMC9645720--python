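"""Profiles, normalization, strand bias, coverage, and association tests."""

import numpy as np
import pytest
from scipy import stats

from oriscape.landscape import (
    ProfileMatrix,
    RSBProfile,
    background_normalize,
    chi2_independence,
    composition_corrected_rates,
    coverage_profile,
    gerp_profile,
    interdistance_profile,
    mutation_rate_profile,
    quantile_bin_association,
    replication_strand_bias,
)
from oriscape.origins_io import (
    CoverageTrack,
    Genome,
    OriginDomainSet,
    OriginRecord,
    VariantRecord,
)


def _profile(values):
    values = np.asarray(values, dtype=float)[None, :]
    return ProfileMatrix(values, "test", values[0])


class TestMutationRateProfile:
    def test_single_variant_single_domain(self, single_origin_domainset):
        v = [VariantRecord("chr1", 50_001, "A", "G")]  # 0-based 50,000 -> w=100
        prof = mutation_rate_profile(v, single_origin_domainset)
        assert prof.aggregate[100] == 1.0
        assert prof.aggregate.sum() == 1.0

    def test_denominator_counts_all_domains(self):
        ds = OriginDomainSet([OriginRecord("chr1", 49_500, 50_500),
                              OriginRecord("chr1", 149_500, 150_500)])
        v = [VariantRecord("chr1", 50_001, "A", "G")]
        prof = mutation_rate_profile(v, ds)
        assert prof.aggregate[100] == 0.5

    def test_conservation_of_in_domain_counts(self, small_study, small_domainset):
        variants, _ = small_study.snvs()
        prof = mutation_rate_profile(variants, small_domainset)
        in_domain = sum(
            1 for v in variants
            if small_domainset.assign(v.chrom, v.pos0) is not None
        )
        total = prof.aggregate.sum() * len(small_domainset)
        assert total == pytest.approx(in_domain)

    def test_uniform_poisson_flat_profile(self, rng):
        # 500 domains, lambda = 0.5 variants per window
        n_dom, lam = 500, 0.5
        origins = [OriginRecord("chr1", 50_000 + i * 30_000,
                                51_000 + i * 30_000) for i in range(n_dom)]
        ds = OriginDomainSet(origins, half_width=2_000, window_size=100)
        variants = []
        for i, o in enumerate(origins):
            lo, hi = ds.domain_bounds(i)
            n = rng.poisson(lam * ds.n_windows)
            for p in rng.integers(lo, hi, n):
                variants.append(VariantRecord("chr1", int(p) + 1, "A", "C"))
        prof = mutation_rate_profile(variants, ds)
        se = np.sqrt(lam / n_dom)
        assert np.all(np.abs(prof.aggregate - lam) < 5 * se)
        assert abs(prof.aggregate.mean() - lam) < 3 * se / np.sqrt(ds.n_windows)

    def test_empty_domainset_errors(self):
        with pytest.raises(ValueError):
            mutation_rate_profile([], OriginDomainSet([]))


class TestBackgroundNormalize:
    def test_flat_profile_becomes_ones(self):
        prof = _profile(np.full(200, 7.0))
        assert np.allclose(background_normalize(prof).aggregate, 1.0)

    def test_center_over_edges(self):
        vals = np.ones(200)
        vals[50:150] = 2.0
        out = background_normalize(_profile(vals))
        assert out.aggregate[100] == pytest.approx(2.0)

    def test_manual_recomputation(self, rng):
        vals = rng.gamma(2, 1, 200)
        out = background_normalize(_profile(vals))
        bg = np.mean(np.concatenate([vals[:20], vals[-20:]]))
        assert np.allclose(out.aggregate, vals / bg)

    def test_scale_invariance(self, rng):
        vals = rng.gamma(2, 1, 200) + 0.1
        a = background_normalize(_profile(vals)).aggregate
        b = background_normalize(_profile(vals * 37.0)).aggregate
        assert np.allclose(a, b)

    def test_zero_background_errors(self):
        vals = np.zeros(200)
        vals[100] = 5.0
        with pytest.raises(ValueError, match="pseudocount"):
            background_normalize(_profile(vals))


class TestCompositionCorrection:
    def test_strand_folding_and_raw_rate(self):
        # genome with known window composition around one origin
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=120_000))
        genome = Genome({"chr1": seq})
        ds = OriginDomainSet([OriginRecord("chr1", 49_500, 50_500)])
        # place a G>A at a G site: counted as C>T
        pos0 = next(p for p in range(50_000, 50_050) if seq[p] == "G")
        v = [VariantRecord("chr1", pos0 + 1, "G", "A")]
        out = composition_corrected_rates(v, genome, ds, normalize=False)
        w = ds.assign("chr1", pos0)[1]
        cg = sum(1 for b in seq[40_000 + w * 100:40_000 + (w + 1) * 100] if b in "CG")
        assert out["C>T"].aggregate[w] == pytest.approx(1 / cg)
        assert np.nansum(out["C>A"].aggregate) == 0

    def test_gc_gradient_removed(self, rng):
        # genome whose GC rises toward domain centers; uniform per-base
        # mutation probability => corrected profile flat, raw tracks GC
        n_dom, hw = 120, 2_000
        chrom_parts = []
        origins = []
        variants = []
        pos_cursor = 0
        for i in range(n_dom):
            L = 2 * hw
            x = np.arange(L)
            gc = 0.3 + 0.3 * np.exp(-((x - hw) ** 2) / (2 * 600.0 ** 2))
            u = rng.random(L)
            codes = np.where(u < gc / 2, 1,
                             np.where(u < gc, 2, np.where(u < gc + (1 - gc) / 2, 0, 3)))
            seq = "".join("ACGT"[c] for c in codes)
            start = pos_cursor
            chrom_parts.append(seq)
            origins.append(OriginRecord("chr1", start + hw - 100, start + hw + 100))
            # uniform mutation probability per base, type set by base
            n_mut = 120
            for p in rng.integers(0, L, n_mut):
                ref = seq[p]
                alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
                variants.append(VariantRecord("chr1", start + int(p) + 1, ref, alt))
            pos_cursor += L
        genome = Genome({"chr1": "".join(chrom_parts)})
        ds = OriginDomainSet(origins, half_width=hw, window_size=100)
        out = composition_corrected_rates(variants, genome, ds, normalize=False)
        # pooled corrected rate: C-class count / CG bases should not follow GC
        pooled = out["C>A"].aggregate + out["T>G"].aggregate
        x = np.arange(len(pooled))
        ok = np.isfinite(pooled)
        slope_corr = stats.linregress(
            np.abs(x[ok] - len(pooled) / 2), pooled[ok])
        assert slope_corr.pvalue > 0.01  # no residual spatial trend
        # uncorrected C-class counts do track the GC gradient
        raw = mutation_rate_profile(
            [v for v in variants if v.ref in "CG"], ds).aggregate
        slope_raw = stats.linregress(np.abs(x - len(raw) / 2), raw)
        assert slope_raw.pvalue < 1e-6 and slope_raw.slope < 0


class TestInterdistance:
    def test_three_variant_example(self):
        ds = OriginDomainSet([OriginRecord("chr1", 0, 1000)], half_width=500,
                             window_size=100)
        # positions 100, 200, 450 (0-based) -> distances 100, 100, 250
        vs = [VariantRecord("chr1", p + 1, "A", "C") for p in (100, 200, 450)]
        prof = interdistance_profile(vs, ds)
        assert prof.aggregate[ds.assign("chr1", 100)[1]] == 100
        assert prof.aggregate[ds.assign("chr1", 450)[1]] == 250

    def test_two_variants_symmetric(self):
        ds = OriginDomainSet([OriginRecord("chr1", 0, 1000)], half_width=500,
                             window_size=100)
        vs = [VariantRecord("chr1", 101, "A", "C"),
              VariantRecord("chr1", 431, "A", "C")]
        prof = interdistance_profile(vs, ds)
        vals = prof.aggregate[np.isfinite(prof.aggregate)]
        assert np.all(vals == 330)

    def test_single_variant_chromosome_masked(self):
        ds = OriginDomainSet([OriginRecord("chr1", 0, 1000)], half_width=500,
                             window_size=100)
        prof = interdistance_profile([VariantRecord("chr1", 101, "A", "C")], ds)
        assert np.all(np.isnan(prof.aggregate))

    def test_matches_all_pairs_oracle(self, rng):
        positions = np.unique(rng.integers(0, 1_000_000, 1000))
        ds = OriginDomainSet(
            [OriginRecord("chr1", m - 500, m + 500)
             for m in range(20_000, 1_000_000, 40_000)],
            half_width=10_000, window_size=100)
        vs = [VariantRecord("chr1", int(p) + 1, "A", "C") for p in positions]
        prof = interdistance_profile(vs, ds)
        # oracle: all-pairs minimum distance, then window means
        sums = np.zeros(ds.n_windows)
        ns = np.zeros(ds.n_windows)
        for p in positions:
            d = np.min(np.abs(positions[positions != p] - p))
            hit = ds.assign("chr1", int(p))
            if hit:
                sums[hit[1]] += d
                ns[hit[1]] += 1
        expected = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
        assert np.allclose(prof.aggregate, expected, equal_nan=True)


class TestReplicationStrandBias:
    def test_zero_and_log2_values(self):
        n_fwd = np.zeros((6, 10))
        n_rev = np.zeros((6, 10))
        n_fwd[0, 0] = n_rev[0, 0] = 8
        n_fwd[0, 1], n_rev[0, 1] = 10, 5
        prof = RSBProfile(("C>A",) * 6, n_fwd, n_rev, pseudocount=0.0)
        assert prof.rsb[0, 0] == 0.0
        assert prof.rsb[0, 1] == pytest.approx(1.0)

    def test_antisymmetry_under_swap(self, small_study, small_domainset):
        variants, _ = small_study.snvs()
        prof = replication_strand_bias(variants, small_study.genome,
                                       small_domainset)
        assert np.allclose(prof.swapped().rsb, -prof.rsb)

    def test_sign_flips_at_midpoint(self, small_study, small_domainset):
        variants, truth = small_study.snvs()
        biased = set(truth.loc[truth.component != "background", "pos0"])
        sel = [v for v in variants if v.pos0 in biased]
        prof = replication_strand_bias(sel, small_study.genome, small_domainset)
        pooled_left = prof.rsb[:, 80:100].mean()
        pooled_right = prof.rsb[:, 100:120].mean()
        assert pooled_left > 0.5 and pooled_right < -0.5


class TestCoverageProfile:
    def test_constant_track_normalizes_to_ones(self, single_origin_domainset):
        track = CoverageTrack.from_lists([("chr1", 0, 100_000, 5.0)])
        prof = coverage_profile(track, single_origin_domainset)
        assert np.allclose(prof.aggregate, 1.0)

    def test_single_hot_window(self, single_origin_domainset):
        rows = [("chr1", 0, 45_000, 1.0), ("chr1", 45_000, 45_100, 10.0),
                ("chr1", 45_100, 100_000, 1.0)]
        prof = coverage_profile(CoverageTrack.from_lists(rows),
                                single_origin_domainset, normalize=False)
        w = single_origin_domainset.assign("chr1", 45_000)[1]
        assert prof.aggregate[w] == pytest.approx(10.0)
        assert prof.aggregate[w + 1] == pytest.approx(1.0)

    def test_matches_interval_intersection_oracle(self, rng):
        edges = np.sort(rng.choice(np.arange(1, 20_000), 300, replace=False))
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [20_000]])
        vals = rng.gamma(2, 1, len(starts))
        track = CoverageTrack.from_lists(
            [("chr1", int(s), int(e), float(v))
             for s, e, v in zip(starts, ends, vals)])
        ds = OriginDomainSet([OriginRecord("chr1", 9_900, 10_100)],
                             half_width=5_000, window_size=100)
        prof = coverage_profile(track, ds, normalize=False)
        for w in range(0, ds.n_windows, 7):
            a = 5_000 + w * 100
            b = a + 100
            num = den = 0.0
            for s, e, v in zip(starts, ends, vals):
                ov = min(e, b) - max(s, a)
                if ov > 0:
                    num += v * ov
                    den += ov
            assert prof.aggregate[w] == pytest.approx(num / den)


class TestGerpProfile:
    def test_constant_scores_normalize_to_ones(self, single_origin_domainset):
        track = CoverageTrack.from_lists([("chr1", 0, 100_000, 2.5)])
        prof = gerp_profile(track, single_origin_domainset)
        assert np.allclose(prof.aggregate, 1.0)

    def test_spike_smoothed_by_rolling_mean(self, single_origin_domainset):
        rows = [("chr1", 0, 50_000, 1.0), ("chr1", 50_000, 50_001, 101.0),
                ("chr1", 50_001, 100_000, 1.0)]
        prof = gerp_profile(CoverageTrack.from_lists(rows),
                            single_origin_domainset, normalize=False)
        # one base of +100 excess spread over a 100-base rolling mean adds ~1
        w = single_origin_domainset.assign("chr1", 50_000)[1]
        assert prof.aggregate[w] > 1.5
        assert prof.aggregate[0] == pytest.approx(1.0)

    def test_matches_direct_rolling_oracle(self, rng):
        ds = OriginDomainSet([OriginRecord("chr1", 4_900, 5_100)],
                             half_width=2_000, window_size=100)
        scores = rng.normal(0, 1, 10_000)
        track = CoverageTrack.from_lists(
            [("chr1", i, i + 1, float(s)) for i, s in enumerate(scores)])
        prof = gerp_profile(track, ds, rolling=100, normalize=False)
        lo, hi = ds.domain_bounds(0)
        base = scores[lo:hi]
        kernel = np.ones(100)
        smooth = np.convolve(base, kernel, "same") / np.convolve(
            np.ones_like(base), kernel, "same")
        expected = smooth.reshape(ds.n_windows, 100).mean(axis=1)
        assert np.allclose(prof.aggregate, expected)


class TestQuantileBinAssociation:
    def test_identical_counts_give_zero_chi2(self, rng):
        counts = np.full(100, 3.0)
        cov = rng.random(100)
        res = quantile_bin_association(counts, cov, n_bins=10)
        assert res.chi2 == pytest.approx(0.0)
        assert res.df == 9

    def test_two_by_two_closed_form(self):
        chi2, df, p = chi2_independence([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(20 / 3, rel=1e-12)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(20 / 3, 1))

    def test_more_bins_than_origins_errors(self):
        with pytest.raises(ValueError):
            quantile_bin_association(np.ones(5), np.ones(5), n_bins=10)

    def test_null_p_values_uniform(self, rng):
        pvals = []
        for _ in range(400):
            counts = rng.poisson(5, 200).astype(float)
            cov = rng.random(200)
            pvals.append(quantile_bin_association(counts, cov, 10).p_value)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestParameterRecovery:
    def test_center_amplitude_recovered_within_ten_percent(self, rng):
        # planted enrichment: background rate 1, center amplitude a = 1.5
        n_dom, hw, a = 2000, 2_000, 1.5
        origins = [OriginRecord("chr1", 10_000 + i * 10_000, 10_200 + i * 10_000)
                   for i in range(n_dom)]
        ds = OriginDomainSet(origins, half_width=hw, window_size=100)
        lam0 = 0.5
        variants = []
        for i in range(n_dom):
            lo, hi = ds.domain_bounds(i)
            mid = (lo + hi) // 2
            x = np.arange(lo, hi)
            lam = lam0 / 100 * (1 + a * np.exp(-((x - mid) ** 2) / (2 * 300.0 ** 2)))
            hits = rng.random(hi - lo) < lam
            for p in x[hits]:
                variants.append(VariantRecord("chr1", int(p) + 1, "A", "C"))
        prof = background_normalize(mutation_rate_profile(variants, ds),
                                    n_edge_windows=5)
        peak = prof.aggregate[18:22].mean()
        assert abs(peak - (1 + a)) / (1 + a) < 0.10
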