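"""Ground-truth recoverability and determinism of the synthetic generators."""

import numpy as np
import pytest

from phostress import congruence, phobox, simulate
from phostress.exceptions import ConfigurationError


class TestGenome:
    def test_same_seed_same_genome(self):
        cfg = simulate.GenomeSimConfig(seed=11, length=20_000, n_genes=4)
        a, _ = simulate.simulate_genome(cfg)
        b, _ = simulate.simulate_genome(cfg)
        assert a.sequence == b.sequence

    def test_gc_content_close_to_configured(self):
        cfg = simulate.GenomeSimConfig(
            seed=3, length=100_000, n_genes=2, planted_fraction=0.0
        )
        ann, _ = simulate.simulate_genome(cfg)
        gc = (ann.sequence.count("G") + ann.sequence.count("C")) / len(ann)
        assert gc == pytest.approx(0.377, abs=0.01)

    def test_planted_box_recorded_at_configured_offset(self):
        cfg = simulate.GenomeSimConfig(
            seed=5, length=30_000, n_genes=6, planted_fraction=1.0, planted_offset=-63
        )
        ann, truth = simulate.simulate_genome(cfg)
        planted = truth["planted_boxes"]
        assert len(planted) == 6
        model = phobox.compile_motif()
        for gene, info in planted.items():
            assert info["offset"] == -63
            region = phobox.extract_promoter(ann, gene, 200)
            start = info["offset"] - region.offset_of_first_base
            observed = region.sequence[start : start + len(info["box"])]
            assert observed == info["box"].upper()
            # planted half-sites are consensus words
            assert model.mismatches(observed[: model.length]) == 0

    def test_planted_mismatch_distance_matches_request(self):
        model = phobox.compile_motif()
        cfg = simulate.GenomeSimConfig(
            seed=9,
            length=30_000,
            n_genes=4,
            planted_fraction=1.0,
            planted_mismatches=1,
        )
        _, truth = simulate.simulate_genome(cfg, model)
        for info in truth["planted_boxes"].values():
            halves, _ = _split_box(info["box"], model.length)
            for h in halves:
                # Hamming-to-set distance recomputed position by position
                dist = sum(b not in allowed for b, allowed in zip(h, model.half_site))
                assert dist == 1

    def test_offset_deeper_than_window_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate.simulate_genome(
                simulate.GenomeSimConfig(
                    seed=0, length=30_000, n_genes=4, promoter_window=50, planted_offset=-120
                )
            )

    def test_genes_must_fit(self):
        with pytest.raises(ConfigurationError):
            simulate.GenomeSimConfig(seed=0, length=1000, n_genes=10, gene_length=900)


def _split_box(box: str, L: int):
    halves = [box[:L].upper(), box[-L:].upper()]
    spacer = box[L:-L]
    return halves, spacer


class TestTreePair:
    def test_zero_noise_zero_transfer_trees_identical(self):
        core, gene, _ = simulate.simulate_tree_pair(
            simulate.TreeSimConfig(seed=21, n_leaves=12)
        )
        rf = congruence.robinson_foulds(core, gene)
        assert rf.unweighted == 0 and rf.weighted == pytest.approx(0.0, abs=1e-12)
        res = congruence.congruence_test(core, gene)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_transfers_preserve_leaf_set(self):
        core, gene, truth = simulate.simulate_tree_pair(
            simulate.TreeSimConfig(seed=22, n_leaves=15, transfer_events=5)
        )
        assert set(congruence.leaf_labels(core)) == set(congruence.leaf_labels(gene))
        assert truth["transfers"] == 5

    def test_transfers_degrade_mean_congruence(self):
        # Monte-Carlo under the generator: 0 vs 8 transfers on 20-leaf trees
        def mean_r(transfers: int) -> float:
            rs = []
            for seed in range(50):
                c, g, _ = simulate.simulate_tree_pair(
                    simulate.TreeSimConfig(
                        seed=1000 + seed,
                        n_leaves=20,
                        transfer_events=transfers,
                        length_noise_sd=0.1,
                    )
                )
                rs.append(congruence.congruence_test(c, g).pearson_r)
            return float(np.mean(rs))

        assert mean_r(8) < mean_r(0)

    def test_too_many_transfers_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate.TreeSimConfig(seed=0, n_leaves=5, transfer_events=5)


class TestCounts:
    def test_nb_moments_match_parameterization(self):
        rng = np.random.default_rng(42)
        mu, phi = 1000.0, 0.05
        draws = simulate.nb_draw(rng, np.full(100_000, mu), phi)
        assert draws.mean() == pytest.approx(mu, rel=0.03)
        assert draws.var() == pytest.approx(mu + phi * mu**2, rel=0.03)

    def test_poisson_limit_at_small_dispersion(self):
        rng = np.random.default_rng(43)
        draws = simulate.nb_draw(rng, np.full(100_000, 1000.0), 1e-8)
        assert draws.var() == pytest.approx(1000.0, rel=0.03)

    def test_no_planting_gives_empty_regulon(self):
        matrix, truth = simulate.simulate_counts(
            simulate.CountsSimConfig(seed=1, n_genes=50)
        )
        assert truth["regulon"] == []
        assert (truth["log2fc"] == 0).all()
        assert matrix.counts.shape == (50, 6)

    def test_planted_mean_ratio_across_simulations(self):
        # planted log2FC 1.33 at mu=500, n=3: mean deplete/replete count ratio
        # across 200 generator draws should sit near 2^1.33 ~ 2.51
        ratios = []
        for seed in range(200):
            cfg = simulate.CountsSimConfig(
                seed=seed,
                n_genes=10,
                mean_range=(500.0, 500.0),
                planted_log2fc={0: 1.33},
            )
            m, _ = simulate.simulate_counts(cfg)
            i1 = m.condition_columns("replete")
            i2 = m.condition_columns("deplete")
            ratios.append(m.counts[0, i2].mean() / m.counts[0, i1].mean())
        assert 2.3 <= np.mean(ratios) <= 2.8

    def test_determinism(self):
        cfg = simulate.regulon_counts_config(seed=9, n_genes=40)
        a, _ = simulate.simulate_counts(cfg)
        b, _ = simulate.simulate_counts(cfg)
        assert (a.counts == b.counts).all()

    def test_bad_dispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate.CountsSimConfig(seed=0, dispersion=0.0)


class TestCurves:
    def test_noiseless_replicates_identical(self):
        curves, _ = simulate.simulate_growth_curves(
            simulate.GrowthSimConfig(seed=1, noise_sd=0.0)
        )
        replete = [c for c in curves if c.condition == "replete" and c.infected]
        assert all(c.od == replete[0].od for c in replete)

    def test_infected_tracks_control_until_lysis(self):
        cfg = simulate.GrowthSimConfig(seed=2, noise_sd=0.0, interval=1.0)
        curves, truth = simulate.simulate_growth_curves(cfg)
        control = next(c for c in curves if c.condition == "deplete" and not c.infected)
        infected = next(c for c in curves if c.condition == "deplete" and c.infected)
        t_l = truth["lysis_times"]["deplete"]
        for t, odc, odi in zip(control.times, control.od, infected.od):
            if t <= t_l:
                assert odi == pytest.approx(odc, abs=1e-12)
            else:
                assert odi < odc

    def test_qpcr_noiseless_points_follow_configured_slope(self):
        cfg = simulate.QpcrSimConfig(seed=1, noise_sd=0.0, slope_replete=5.0)
        series, _ = simulate.simulate_qpcr(cfg)
        s = next(x for x in series if x.condition == "replete")
        values = dict(zip(s.times, s.percent))
        assert values[2.0] == pytest.approx(110.0)
        assert values[4.0] == pytest.approx(120.0)
        assert values[6.0] == pytest.approx(130.0)
        assert values[8.0] == pytest.approx(130.0)  # plateau after the window

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate.GrowthSimConfig(seed=0, noise_sd=-1.0)
        with pytest.raises(ConfigurationError):
            simulate.QpcrSimConfig(seed=0, noise_sd=-1.0)
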