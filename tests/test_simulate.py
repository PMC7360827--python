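"""Synthetic collection generator: archetypes, mosaics, determinism, recovery."""

import numpy as np
import pytest
from scipy.stats import ks_2samp
from sklearn.metrics import adjusted_rand_score

from beandiv import (
    PoolArchetype,
    SimulationConfig,
    cut_dendrogram,
    default_archetypes,
    default_catalog,
    euclidean_distances,
    introgress,
    load_archetypes,
    sample_accession,
    save_archetypes,
    simulate_collection,
    standardize,
    upgma,
    validate_collection,
)


@pytest.fixture(scope="module")
def archetypes():
    return default_archetypes()


class TestArchetypes:
    def test_pools_differ_in_seed_size(self, archetypes):
        andean, meso = archetypes
        assert andean.quantitative_params["HSW"][0] > meso.quantitative_params["HSW"][0]

    def test_cover_all_29_traits_with_valid_levels(self, archetypes, catalog):
        for arch in archetypes:
            for d in catalog.qualitative:
                probs = arch.qualitative_params[d.code]
                assert set(probs) <= set(d.levels)
                assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
            for d in catalog.quantitative:
                mean, sd = arch.quantitative_params[d.code]
                assert sd > 0
        # diagnostic signals point the right way
        andean, meso = archetypes
        assert andean.qualitative_params["GH"][1] > 0.5  # mostly erect
        assert meso.qualitative_params["GH"][2] > 0.5  # mostly prostrate
        assert meso.qualitative_params["SSC"][0] > 0.5  # mostly speckle-free

    def test_roundtrip_through_parameter_file(self, archetypes, tmp_path):
        path = save_archetypes(*archetypes, tmp_path / "arch.yaml")
        back = load_archetypes(path)
        for orig, re_read in zip(archetypes, back):
            assert orig == re_read

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="distribution"):
            PoolArchetype("bad", {"HSW": (40.0, 5.0)}, {"GH": {1: 0.6, 2: 0.6}})


class TestSampleAccession:
    def test_near_zero_variance_reproduces_means(self, archetypes, catalog):
        andean, _ = archetypes
        tight = PoolArchetype(
            "tight",
            {k: (m, 1e-12) for k, (m, _) in andean.quantitative_params.items()},
            {k: {max(p, key=p.get): 1.0} for k, p in andean.qualitative_params.items()},
        )
        acc = sample_accession(tight, catalog, np.random.default_rng(0))
        for code, (mean, _) in tight.quantitative_params.items():
            if code == "LWS":
                continue
            assert acc.quantitative[code] == pytest.approx(mean, rel=1e-6)

    def test_empirical_mean_within_clt_bound(self, archetypes, catalog):
        andean, _ = archetypes
        rng = np.random.default_rng(12)
        draws = [sample_accession(andean, catalog, rng).quantitative["HSW"]
                 for _ in range(500)]
        mean, sd = andean.quantitative_params["HSW"]
        assert abs(np.mean(draws) - mean) < 3 * sd / np.sqrt(500)

    def test_lws_is_derived_ratio(self, archetypes, catalog):
        andean, _ = archetypes
        rng = np.random.default_rng(1)
        for _ in range(20):
            acc = sample_accession(andean, catalog, rng)
            assert acc.quantitative["LWS"] == pytest.approx(
                acc.quantitative["SL"] / acc.quantitative["SW"])

    def test_generated_accessions_are_valid(self, default_simulated):
        assert validate_collection(default_simulated.collection).ok


class TestIntrogress:
    def test_lambda_one_matches_pure_andean(self, archetypes, catalog):
        andean, meso = archetypes
        rng = np.random.default_rng(2)
        mosaic = [introgress(andean, meso, 1.0, catalog, rng).quantitative["HSW"]
                  for _ in range(300)]
        rng2 = np.random.default_rng(3)
        pure = [sample_accession(andean, catalog, rng2).quantitative["HSW"]
                for _ in range(300)]
        assert ks_2samp(mosaic, pure).pvalue > 0.01

    def test_lambda_zero_is_pure_mesoamerican(self, archetypes, catalog):
        andean, meso = archetypes
        rng = np.random.default_rng(4)
        draws = [introgress(andean, meso, 0.0, catalog, rng).quantitative["HSW"]
                 for _ in range(300)]
        mean, sd = meso.quantitative_params["HSW"]
        assert abs(np.mean(draws) - mean) < 3 * sd / np.sqrt(300) + 0.2

    def test_half_lambda_mixture_mean(self, archetypes, catalog):
        andean, meso = archetypes
        rng = np.random.default_rng(5)
        draws = np.array(
            [introgress(andean, meso, 0.5, catalog, rng).quantitative["HSW"]
             for _ in range(1000)])
        mu_a, sd_a = andean.quantitative_params["HSW"]
        mu_m, sd_m = meso.quantitative_params["HSW"]
        midpoint = (mu_a + mu_m) / 2
        mix_var = 0.5 * (sd_a ** 2 + sd_m ** 2) + 0.25 * (mu_a - mu_m) ** 2
        assert abs(draws.mean() - midpoint) < 3 * np.sqrt(mix_var / 1000)

    def test_invalid_lambda(self, archetypes, catalog):
        andean, meso = archetypes
        with pytest.raises(ValueError):
            introgress(andean, meso, 1.5, catalog, np.random.default_rng(0))


class TestSimulateCollection:
    def test_same_seed_identical_collections(self):
        a = simulate_collection(SimulationConfig(seed=9))
        b = simulate_collection(SimulationConfig(seed=9))
        assert a.true_pool == b.true_pool
        assert a.collection.to_frame().equals(b.collection.to_frame())

    def test_different_seeds_differ(self):
        a = simulate_collection(SimulationConfig(seed=1))
        b = simulate_collection(SimulationConfig(seed=2))
        assert not a.collection.to_frame().equals(b.collection.to_frame())

    def test_introgressed_count_arithmetic(self):
        config = SimulationConfig(
            n_per_pool={"Andean": 40, "Mesoamerican": 40},
            introgression_fraction=0.2, seed=0)
        labeled = simulate_collection(config)
        pools = list(labeled.true_pool.values())
        assert len(pools) == 100
        assert pools.count("Introgressed") == 20

    def test_default_study_conditions(self, default_simulated):
        pools = list(default_simulated.true_pool.values())
        assert len(pools) == 115
        assert pools.count("Andean") == 52
        assert pools.count("Mesoamerican") == 40
        assert pools.count("Introgressed") == 23
        regions = {a.region for a in default_simulated.collection}
        assert regions <= {"I", "II", "III", "IV"}


def _scaled_archetypes(alpha):
    """Pull both archetypes toward their midpoint; alpha=1 keeps defaults,
    alpha=0 collapses them to one distribution (chance-level clustering)."""
    andean, meso = default_archetypes()

    def blend(a, m):
        quant = {}
        for code in a.quantitative_params:
            ma, sa = a.quantitative_params[code]
            mm, _ = m.quantitative_params[code]
            mid = (ma + mm) / 2
            quant[code] = (mid + alpha * (ma - mid), sa)
        qual = {}
        for code in a.qualitative_params:
            pa = a.qualitative_params[code]
            pm = m.qualitative_params[code]
            levels = set(pa) | set(pm)
            mid = {lv: (pa.get(lv, 0) + pm.get(lv, 0)) / 2 for lv in levels}
            mixed = {lv: mid[lv] + alpha * (pa.get(lv, 0) - mid[lv]) for lv in levels}
            total = sum(mixed.values())
            qual[code] = {lv: p / total for lv, p in mixed.items() if p > 0}
        return PoolArchetype(a.name, quant, qual)

    return blend(andean, meso), blend(meso, andean)


def _recovery_ari(seed, archetypes=None):
    config = SimulationConfig(
        n_per_pool={"Andean": 23, "Mesoamerican": 23},
        introgression_fraction=0.0, seed=seed)
    labeled = simulate_collection(config, archetypes=archetypes)
    z = standardize(labeled.collection)
    tree_labels = cut_dendrogram(
        upgma(euclidean_distances(z), z.accession_ids), 2)
    truth = [labeled.true_pool[i] for i in z.accession_ids]
    found = [tree_labels[i] for i in z.accession_ids]
    return adjusted_rand_score(truth, found)


class TestPipelineRecovery:
    def test_cluster_cut_recovers_pools(self):
        aris = [_recovery_ari(seed) for seed in range(5)]
        assert all(a >= 0.9 for a in aris)

    def test_ari_decays_as_separation_shrinks(self):
        """Chance-level clustering when the pools coincide, perfect at full
        separation, with a decreasing trend in between."""
        mean_ari = []
        for alpha in (1.0, 0.75, 0.5, 0.25, 0.0):
            arch = _scaled_archetypes(alpha)
            mean_ari.append(np.mean([_recovery_ari(s, arch) for s in range(3)]))
        assert mean_ari[0] >= 0.9
        assert mean_ari[-1] <= 0.3
        # overall decreasing trend (pairwise, with stochastic slack)
        for hi, lo in zip(mean_ari, mean_ari[2:]):
            assert lo <= hi + 0.1
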