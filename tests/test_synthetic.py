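"""Planted-structure guarantees and determinism of the data generators."""

import numpy as np
import pandas as pd
import pytest

from icenet.cerna import infer_cerna_pairs
from icenet.synthetic import (
    SyntheticConfig,
    gen_clinical,
    gen_expression,
    gen_mirna_target_map,
    gen_planted_cpm_graph,
    read_fixture_bundle,
    write_fixture_bundle,
)


def _cfg(**kw):
    base = dict(n_mirna=50, n_mrna=30, n_lncrna=5, target_density=0.1,
                n_samples=20, seed=42)
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_planted_sharing_beyond_pool_rejected(self):
        with pytest.raises(ValueError):
            _cfg(planted_pairs=[("G0001", "G0002", 60)])

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_mirna": 0},
            {"correlation_strength": 1.2},
            {"censoring_rate": 1.0},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)


class TestTargetMap:
    def test_planted_pair_shares_exactly_s(self):
        cfg = _cfg(planted_pairs=[("G0001", "G0002", 3), ("G0003", "L0001", 5)])
        tmap = gen_mirna_target_map(cfg)
        assert len(tmap.regulators_of("G0001") & tmap.regulators_of("G0002")) == 3
        assert len(tmap.regulators_of("G0003") & tmap.regulators_of("L0001")) == 5

    def test_exact_overlap_in_clique_of_pairs(self):
        mols = ["G0001", "G0002", "G0003", "G0004"]
        pairs = [(a, b, 4) for i, a in enumerate(mols) for b in mols[i + 1:]]
        tmap = gen_mirna_target_map(_cfg(n_mirna=100, planted_pairs=pairs))
        for a, b, s in pairs:
            assert len(tmap.regulators_of(a) & tmap.regulators_of(b)) == s

    def test_every_molecule_in_universe(self):
        tmap = gen_mirna_target_map(_cfg(target_density=0.0))
        assert len(tmap.molecules) == 35
        assert all(tmap.regulators_of(m) == set() for m in tmap.molecules)

    def test_same_seed_identical_tables(self):
        cfg = _cfg(planted_pairs=[("G0001", "G0002", 3)])
        t1 = gen_mirna_target_map(cfg).to_frame()
        t2 = gen_mirna_target_map(cfg).to_frame()
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_map_false_positive_rate_calibrated(self):
        # conservative discrete test: over 20 null replicates the >=-tail
        # rejects at most ~7% of candidate pairs at alpha = 0.05
        n_candidates = 0
        n_rejected = 0
        for rep in range(20):
            cfg = SyntheticConfig(
                n_mirna=50, n_mrna=180, n_lncrna=20, target_density=0.1,
                n_samples=10, seed=1000 + rep,
            )
            tmap = gen_mirna_target_map(cfg)
            expr = gen_expression(tmap, cfg)
            out = infer_cerna_pairs(tmap, expr, tail="ge")
            n_candidates += len(out)
            n_rejected += int((out["p"] < 0.05).sum())
        assert n_candidates >= 10_000
        assert n_rejected / n_candidates <= 0.07


class TestExpression:
    def test_noise_free_unit_strength_gives_perfect_correlation(self):
        cfg = _cfg(correlation_strength=1.0, noise_sd=0.0,
                   planted_pairs=[("G0001", "G0002", 3)])
        expr = gen_expression(gen_mirna_target_map(cfg), cfg)
        rho = np.corrcoef(expr.loc["G0001"], expr.loc["G0002"])[0, 1]
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_zero_strength_uncorrelated_on_average(self):
        rhos = []
        for rep in range(50):
            cfg = _cfg(correlation_strength=0.0, n_samples=100, seed=rep,
                       planted_pairs=[("G0001", "G0002", 3)])
            expr = gen_expression(gen_mirna_target_map(cfg), cfg)
            rhos.append(np.corrcoef(expr.loc["G0001"], expr.loc["G0002"])[0, 1])
        assert abs(np.mean(rhos)) < 0.1

    def test_cohort_scale_planted_pairs_pass_correlation_filter(self):
        pairs = [(f"G{2 * i:04d}", f"G{2 * i + 1:04d}", 3) for i in range(15)]
        cfg = SyntheticConfig(n_mirna=200, n_mrna=40, n_lncrna=2,
                              target_density=0.02, n_samples=109,
                              correlation_strength=0.9, planted_pairs=pairs, seed=5)
        expr = gen_expression(gen_mirna_target_map(cfg), cfg)
        frac = np.mean(
            [np.corrcoef(expr.loc[a], expr.loc[b])[0, 1] > 0.5 for a, b, _ in pairs]
        )
        assert frac > 0.9

    def test_too_few_samples_rejected(self):
        cfg = _cfg(n_samples=2)
        with pytest.raises(ValueError, match="n_samples"):
            gen_expression(gen_mirna_target_map(cfg), cfg)

    def test_same_seed_identical_matrix(self):
        cfg = _cfg(planted_pairs=[("G0001", "G0002", 3)])
        tmap = gen_mirna_target_map(cfg)
        pd.testing.assert_frame_equal(
            gen_expression(tmap, cfg), gen_expression(tmap, cfg)
        )


class TestClinical:
    def test_censoring_fraction_near_target(self):
        cfg = SyntheticConfig(n_mirna=20, n_mrna=10, n_lncrna=2, n_samples=1000,
                              censoring_rate=0.3, seed=8)
        expr = gen_expression(gen_mirna_target_map(cfg), cfg)
        clin = gen_clinical(expr, cfg)
        censored = 1.0 - clin["event"].mean()
        assert 0.25 <= censored <= 0.35

    def test_null_coefficients_give_calibrated_logrank(self):
        from icenet.survival import logrank_test

        rejections = 0
        for rep in range(40):
            cfg = _cfg(n_samples=60, censoring_rate=0.0, seed=300 + rep)
            expr = gen_expression(gen_mirna_target_map(cfg), cfg)
            clin = gen_clinical(expr, cfg)
            arbitrary = clin.index[:30]
            rest = clin.index[30:]
            _, p = logrank_test(
                (clin.loc[arbitrary, "dfs_months"], clin.loc[arbitrary, "event"]),
                (clin.loc[rest, "dfs_months"], clin.loc[rest, "event"]),
            )
            rejections += p < 0.05
        assert rejections / 40 <= 0.15

    def test_planted_module_must_exist_in_expression(self):
        cfg = _cfg(planted_module={"NOPE": 1.0})
        expr = gen_expression(gen_mirna_target_map(_cfg()), _cfg())
        with pytest.raises(ValueError, match="NOPE"):
            gen_clinical(expr, cfg)

    def test_age_and_grade_ranges(self):
        cfg = _cfg(n_samples=200)
        clin = gen_clinical(gen_expression(gen_mirna_target_map(cfg), cfg), cfg)
        assert clin["age"].between(40, 80).all()
        assert set(clin["grade"]) <= {"G1", "G2"}
        assert (clin["dfs_months"] > 0).all()


class TestPlantedCPMGraph:
    def test_merging_overlap_rejected(self):
        with pytest.raises(ValueError, match="merge"):
            gen_planted_cpm_graph(k=4, n_communities=2, overlap=3)

    def test_same_seed_identical_adjacency(self):
        g1 = gen_planted_cpm_graph(4, 3, 2, seed=5)
        g2 = gen_planted_cpm_graph(4, 3, 2, seed=5)
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_pairwise_intersections_equal_overlap(self):
        g = gen_planted_cpm_graph(k=5, n_communities=3, overlap=2, seed=1)
        cliques = [c for c in __import__("networkx").find_cliques(g) if len(c) >= 5]
        assert len(cliques) == 3
        for i in range(3):
            for j in range(i + 1, 3):
                assert len(set(cliques[i]) & set(cliques[j])) == 2


class TestFixtureBundle:
    def test_round_trip_exact(self, tmp_path):
        cfg = _cfg(planted_pairs=[("G0001", "G0002", 3)],
                   planted_module={"G0001": 0.5},
                   inflammatory_genes=["G0003"])
        write_fixture_bundle(cfg, tmp_path)
        bundle = read_fixture_bundle(tmp_path)
        tmap = gen_mirna_target_map(cfg)
        pd.testing.assert_frame_equal(bundle["interactions"], tmap.to_frame())
        pd.testing.assert_frame_equal(
            bundle["expression"], gen_expression(tmap, cfg), check_exact=True
        )
        assert bundle["inflammatory_genes"] == ["G0003"]
        assert bundle["config"] == cfg

    def test_manifest_rerun_reproduces_bundle(self, tmp_path):
        cfg = _cfg(planted_pairs=[("G0001", "G0002", 3)])
        write_fixture_bundle(cfg, tmp_path / "one")
        bundle = read_fixture_bundle(tmp_path / "one")
        write_fixture_bundle(bundle["config"], tmp_path / "two")
        for f in sorted((tmp_path / "one").iterdir()):
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()

    def test_empty_planted_section_valid(self, tmp_path):
        manifest = write_fixture_bundle(_cfg(), tmp_path)
        assert manifest.exists()
        assert read_fixture_bundle(tmp_path)["config"].planted_pairs == []
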