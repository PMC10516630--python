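"""Count-matrix analyses: QC, normalization, proxies, bins, nulls, ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from globtx.scrna import (
    build_proxies,
    cellcycle_binned_rates,
    explanatory_power,
    modulation_index,
    poisson_cv_null,
    qc_filter,
    rank_regulators,
    spikein_normalize,
)
from globtx.synthetic import CountMatrices, generate_count_matrices


def _toy(spikeins, n_genes=4, seed=0):
    rng = np.random.default_rng(seed)
    n = len(spikeins)
    genes = [f"g{i}" for i in range(n_genes)]
    cols = [f"c{i}" for i in range(n)]
    intron = pd.DataFrame(rng.poisson(50, (n_genes, n)), index=genes, columns=cols)
    exon = pd.DataFrame(rng.poisson(200, (n_genes, n)), index=genes, columns=cols)
    return CountMatrices(
        intron=intron, exon=exon, spikein=pd.Series(spikeins, index=cols, dtype=float)
    )


class TestQcFilter:
    def test_all_cells_within_bounds_unchanged(self):
        cm = _toy([150, 300, 500])
        out = qc_filter(cm, min_cells_per_gene=1)
        assert out.intron.shape == cm.intron.shape

    def test_spikein_bounds_applied(self):
        cm = _toy([50, 150, 300, 600, 900])
        out = qc_filter(cm, spikein_min=100, spikein_max=600, min_cells_per_gene=1)
        assert out.intron.shape[1] == 3
        assert list(out.spikein) == [150, 300, 600]

    def test_undetected_gene_removed(self):
        cm = _toy([200, 300, 400])
        cm.intron.iloc[0] = 0
        cm.exon.iloc[0] = 0
        out = qc_filter(cm, min_cells_per_gene=1)
        assert "g0" not in out.intron.index

    def test_all_cells_removed_is_error(self):
        cm = _toy([10, 20])
        with pytest.raises(ValueError):
            qc_filter(cm)


class TestSpikeinNormalize:
    def test_equal_spikeins_identity(self):
        cm = _toy([300, 300, 300])
        out = spikein_normalize(cm)
        assert np.allclose(out.intron, cm.intron)

    def test_double_spikein_halves_counts(self):
        cm = _toy([300, 600])
        out = spikein_normalize(cm)
        # scale = median/spike; cell 1 has double spike-ins of the median ratio
        ratio = out.intron.iloc[:, 1] / cm.intron.iloc[:, 1]
        assert np.allclose(ratio, 450.0 / 600.0)

    def test_idempotent_after_qc(self):
        cm = generate_count_matrices(n_cells=100, n_genes=30, seed=3)
        once = spikein_normalize(qc_filter(cm, min_cells_per_gene=5))
        twice = spikein_normalize(qc_filter(once, min_cells_per_gene=5))
        assert np.allclose(once.intron, twice.intron)

    def test_capture_factor_removed(self):
        # normalization cancels the planted per-cell capture factor s_c
        cm = generate_count_matrices(
            n_cells=400, n_genes=80, capture_cv=0.4, global_rate_cv=0.0,
            modulation_amplitude=0.0, seed=4,
        )
        norm = spikein_normalize(cm)
        s_c = cm.truth["s_c"][norm.intron.columns]
        raw_r = np.corrcoef(cm.intron.sum(axis=0), cm.truth["s_c"])[0, 1]
        norm_r = np.corrcoef(norm.intron.sum(axis=0), s_c)[0, 1]
        assert raw_r > 0.9  # raw totals are dominated by capture
        assert abs(norm_r) < 3.0 / math.sqrt(400) + 0.05


class TestProxies:
    def test_ratio_arithmetic(self):
        cm = _toy([300])
        cm.intron.iloc[:, 0] = [50, 50, 50, 50]
        cm.exon.iloc[:, 0] = [250, 250, 250, 250]
        table = build_proxies(cm)
        assert table.total_intron.iloc[0] == 200
        assert table.total_exon.iloc[0] == 1000
        assert table.intron_exon_ratio.iloc[0] == pytest.approx(0.2)

    def test_linearity(self):
        cm = _toy([300, 400, 500])
        doubled = CountMatrices(intron=cm.intron * 2, exon=cm.exon, spikein=cm.spikein)
        assert np.allclose(build_proxies(doubled).total_intron, 2 * build_proxies(cm).total_intron)

    def test_gene_and_cell_order_invariance(self):
        cm = generate_count_matrices(n_cells=50, n_genes=20, seed=5)
        perm_genes = cm.intron.index[::-1]
        perm_cells = cm.intron.columns[::-1]
        shuffled = CountMatrices(
            intron=cm.intron.loc[perm_genes, perm_cells],
            exon=cm.exon.loc[perm_genes, perm_cells],
            spikein=cm.spikein[perm_cells],
        )
        a = build_proxies(cm).sort_index()
        b = build_proxies(shuffled).sort_index()
        assert np.allclose(a.total_intron, b.total_intron)


class TestExplanatoryPower:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        assert explanatory_power(x, 2 * x) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(6)
        r2s = [
            explanatory_power(rng.standard_normal(200), rng.standard_normal(200))
            for _ in range(20)
        ]
        assert np.mean(r2s) < 0.02

    def test_intron_proxy_beats_ratio_proxy_for_transcriptome_size(self):
        cm = generate_count_matrices(n_cells=400, n_genes=100, global_rate_cv=0.3, seed=7)
        proxies = build_proxies(spikein_normalize(qc_filter(cm, min_cells_per_gene=10)))
        r2_intron = explanatory_power(proxies.total_intron, proxies.total_exon)
        r2_ratio = explanatory_power(proxies.intron_exon_ratio, proxies.total_exon)
        assert r2_intron > r2_ratio

    def test_constant_predictor_flagged(self):
        assert math.isnan(explanatory_power(np.ones(10), np.arange(10.0)))


class TestBinnedRates:
    def test_flat_generator_flat_profile(self):
        cm = generate_count_matrices(
            n_cells=600, n_genes=100, modulation_amplitude=0.0, global_rate_cv=0.0,
            capture_cv=0.0, seed=8,
        )
        prof = cellcycle_binned_rates(cm, n_bins=14)
        rel = prof["low"] / prof["low"].mean()
        assert np.all(np.abs(rel - 1.0) < 0.1)

    def test_two_pulse_low_tier_peaks_high_tier_flatter(self):
        cm = generate_count_matrices(
            n_cells=800, n_genes=150, modulation_amplitude=0.25, global_rate_cv=0.0,
            capture_cv=0.0, seed=9,
        )
        prof = cellcycle_binned_rates(cm, n_bins=14, tiers=cm.truth["tiers"])
        low = prof["low"].to_numpy()
        peaks = [
            i for i in range(1, len(low) - 1) if low[i] > low[i - 1] and low[i] >= low[i + 1]
        ]
        assert len(peaks) == 2
        ptt_low = low.max() / low.min()
        high = prof["high"].to_numpy()
        ptt_high = high.max() / high.min()
        assert ptt_high < ptt_low

    def test_single_bin_is_population_mean(self):
        cm = generate_count_matrices(n_cells=100, n_genes=50, seed=10)
        prof = cellcycle_binned_rates(cm, n_bins=1, tiers=cm.truth["tiers"])
        genes = cm.truth["tiers"][cm.truth["tiers"] == "low"].index
        assert prof["low"].iloc[0] == pytest.approx(cm.intron.loc[genes].sum(axis=0).mean())


class TestPoissonCvNull:
    def test_null_cv_formula(self):
        out = poisson_cv_null(pd.Series(np.full(100, 40000.0)), bin_labels=np.zeros(100, dtype=int))
        assert out.null_cv.iloc[0] == pytest.approx(0.005, abs=1e-12)

    def test_poisson_totals_match_null(self):
        rng = np.random.default_rng(11)
        totals = pd.Series(rng.poisson(20000, 2000).astype(float))
        out = poisson_cv_null(totals, bin_labels=np.zeros(2000, dtype=int))
        null = out.null_cv.iloc[0]
        se = null / math.sqrt(2 * 1999)
        assert abs(out.observed_cv.iloc[0] - null) < 3 * se

    def test_planted_global_cv_exceeds_null_in_every_bin(self):
        cm = generate_count_matrices(
            n_cells=1000, n_genes=100, global_rate_cv=0.3, capture_cv=0.0,
            modulation_amplitude=0.0, seed=12,
        )
        totals = cm.intron.sum(axis=0)
        out = poisson_cv_null(totals, pseudotime=cm.pseudotime, n_bins=50)
        assert (out.observed_cv > 3 * out.null_cv).all()


class TestRankRegulators:
    def test_planted_regulator_ranked_first(self):
        for seed in range(3):
            cm = generate_count_matrices(
                n_cells=200, n_genes=40, global_rate_cv=0.4, capture_cv=0.0,
                exon_global_coupling=False, planted_regulator=True,
                modulation_amplitude=0.0, seed=20 + seed,
            )
            norm = spikein_normalize(cm)
            proxy = norm.intron.sum(axis=0)
            ranked = rank_regulators(norm.exon, proxy, n_top=10, seed=seed)
            assert ranked.index[0] == cm.truth["planted_regulator"]

    def test_independent_genes_no_dominant_importance(self):
        # no gene should beat the permutation null when none is coupled
        rng = np.random.default_rng(13)
        cm = generate_count_matrices(
            n_cells=120, n_genes=25, global_rate_cv=0.0, capture_cv=0.0,
            exon_global_coupling=False, modulation_amplitude=0.0, seed=21,
        )
        proxy = cm.intron.sum(axis=0)
        obs = rank_regulators(cm.exon, proxy, n_top=25, n_estimators=60, seed=0)
        null_max = [
            rank_regulators(
                cm.exon,
                pd.Series(rng.permutation(proxy.values), index=proxy.index),
                n_top=1,
                n_estimators=60,
                seed=i,
            ).importance.iloc[0]
            for i in range(10)
        ]
        assert obs.importance.iloc[0] <= np.percentile(null_max, 95) * 1.2

    def test_n_top_clipped_to_gene_count(self):
        cm = generate_count_matrices(n_cells=50, n_genes=10, seed=22)
        ranked = rank_regulators(cm.exon, cm.intron.sum(axis=0), n_top=100)
        assert len(ranked) == 10


class TestModulationIndex:
    def test_median_of_module(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [5.0, 6.0, 9.0]}, index=["a", "b", "c"]
        )
        idx = modulation_index(expr, ["a", "b", "c"])
        assert idx["s1"] == 2.0 and idx["s2"] == 6.0

    def test_single_gene_module(self):
        expr = pd.DataFrame({"s1": [4.0], "s2": [7.0]}, index=["a"])
        assert modulation_index(expr, ["a"]).tolist() == [4.0, 7.0]

    def test_empty_module_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            modulation_index(expr, ["zz"])

    def test_module_tracks_global_rate(self):
        cm = generate_count_matrices(
            n_cells=300, n_genes=60, global_rate_cv=0.4, capture_cv=0.0,
            modulation_amplitude=0.0, seed=23,
        )
        module = cm.exon.mean(axis=1).sort_values(ascending=False).index[:10]
        idx = modulation_index(cm.exon, module)
        r = np.corrcoef(idx, cm.truth["g_c"])[0, 1]
        assert r >= 0.9
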