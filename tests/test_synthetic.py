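import filecmp
from dataclasses import replace
from math import comb

import numpy as np
import pytest
from scipy.stats import spearmanr

from cooccursig.cooccurrence import pair_probability
from cooccursig.io import read_ko_profile, read_metadata, read_pathway_annotation, read_taxonomic_profile
from cooccursig.preprocess import FilterCriteria, binarize, run_filter_cascade
from cooccursig.synthetic import (
    PlantedBlock,
    SimulationConfig,
    planted_truth,
    simulate_dataset,
    vary_block_strength,
    write_dataset,
)


class TestConfigValidation:
    def test_bad_block_probabilities(self):
        with pytest.raises(ValueError):
            PlantedBlock(phenotype="CD", q=0.3, p0=0.5)

    def test_block_too_small(self):
        with pytest.raises(ValueError):
            PlantedBlock(phenotype="CD", size=1)

    def test_pathway_smaller_than_block(self):
        # no single species may carry the whole pathway, so the KO count
        # must be at least the block size
        with pytest.raises(ValueError):
            PlantedBlock(phenotype="CD", size=5, n_kos=4)

    def test_block_without_samples(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                samples_per_phenotype=(("control", 10),),
                blocks=(PlantedBlock(phenotype="CD"),),
            )


class TestDeterminism:
    def test_fixture_files_byte_identical(self, tmp_path):
        config = SimulationConfig(seed=5)
        for rep in ("rep1", "rep2"):
            write_dataset(simulate_dataset(config, 0), tmp_path / rep)
        for name in ("taxonomic_profile.tsv", "ko_profile.tsv", "metadata.tsv",
                     "pathway_annotation.tsv"):
            assert filecmp.cmp(tmp_path / "rep1" / name, tmp_path / "rep2" / name,
                               shallow=False), name


class TestRoundTrip:
    def test_written_files_parse_back(self, tmp_path):
        config = SimulationConfig(seed=2)
        dataset = simulate_dataset(config, 0)
        paths = write_dataset(dataset, tmp_path)
        table = read_taxonomic_profile(paths["taxonomic"])
        assert sorted(table.species) == sorted(dataset.abundance.species)
        profile = read_ko_profile(paths["ko"])
        strat = profile.stratified()
        assert len(strat) == len(dataset.ko_profile.entries)
        metadata = read_metadata(paths["metadata"])
        assert len(metadata) == len(dataset.metadata)
        annotation = read_pathway_annotation(paths["annotation"])
        assert annotation.pathways == dataset.annotation.pathways


class TestPlantedStructure:
    def test_block_species_present_in_target_phenotype(self):
        config = SimulationConfig(seed=3)
        dataset = simulate_dataset(config, 0)
        table, metadata, _ = run_filter_cascade(
            dataset.abundance, dataset.metadata, FilterCriteria()
        )
        pm = binarize(table, "CD", metadata)
        for species in dataset.block_species["CD"]:
            assert species in pm.species
            assert pm.cells.loc[species].sum() > 0

    def test_perfect_block_gives_minimal_p(self):
        # no dropout: block species share the latent pattern exactly, so
        # N1 = N2 = j_obs and p_gt = 1 / C(N, N1)
        config = SimulationConfig(
            seed=4,
            blocks=(PlantedBlock(phenotype="CD", q=0.7, p0=0.0, pathway_id="map99001"),),
            dropout=1.0,
        )
        dataset = simulate_dataset(config, 0)
        pm = binarize(dataset.abundance, "CD", dataset.metadata)
        a, b = dataset.block_species["CD"][:2]
        N = len(pm.samples)
        n1 = int(pm.cells.loc[a].sum())
        n2 = int(pm.cells.loc[b].sum())
        obs = int((pm.cells.loc[a] & pm.cells.loc[b]).sum())
        assert 0 < n1 < N and n1 == n2 == obs
        p_gt, _, _ = pair_probability(N, n1, n2, obs)
        assert p_gt == pytest.approx(1 / comb(N, n1), rel=1e-9)

    def test_datasets_share_pathways_not_block_species(self):
        config = SimulationConfig(seed=6)
        truth = planted_truth(config)
        d1 = set(truth["block_species"]["dataset1"]["CD"])
        d2 = set(truth["block_species"]["dataset2"]["CD"])
        assert d1 & d2 == set()
        assert truth["planted_pathways"]["CD"] == "map99001"
        ds1 = simulate_dataset(config, 0)
        ds2 = simulate_dataset(config, 1)
        assert ds1.annotation.pathways == ds2.annotation.pathways

    def test_no_single_species_carries_whole_pathway(self):
        config = SimulationConfig(seed=7)
        dataset = simulate_dataset(config, 0)
        truth = planted_truth(config)
        strat = dataset.ko_profile.stratified()
        for phen, pathway in truth["planted_pathways"].items():
            planted = set(truth["planted_kos"][phen])
            per_species = strat[strat["ko"].isin(planted)].groupby("species")["ko"].nunique()
            assert (per_species < len(planted)).all()

    def test_truth_accessors(self):
        config = SimulationConfig(seed=0)
        truth = planted_truth(config)
        assert set(truth["planted_pathways"]) == {"CD", "UC"}
        assert len(truth["block_species"]) == config.n_datasets
        assert len(truth["planted_kos"]["CD"]) == 12


class TestSignalStrengthTrend:
    def test_block_p_gt_decreases_with_q_in_signal_regime(self):
        """Stronger latent co-presence yields smaller block-pair p_gt
        (geometric mean), monotonically across a q grid in the moderate-
        occupancy regime.  (At occupancy near 1 the hypergeometric null
        itself predicts near-total overlap, so the trend reverses there —
        which is why the generator's default q is moderate.)"""
        base = SimulationConfig(seed=9)
        grid = [0.15, 0.25, 0.35, 0.45]
        means = []
        for q in grid:
            config = vary_block_strength(base, q=q, p0=0.05)
            log_tails = []
            for seed in range(3):
                dataset = simulate_dataset(replace(config, seed=seed), 0)
                pm = binarize(dataset.abundance, "CD", dataset.metadata)
                block = dataset.block_species["CD"]
                cells = pm.cells.loc[block].to_numpy()
                N = cells.shape[1]
                for i in range(len(block)):
                    for j in range(i + 1, len(block)):
                        n1, n2 = int(cells[i].sum()), int(cells[j].sum())
                        obs = int((cells[i] & cells[j]).sum())
                        p_gt = pair_probability(N, n1, n2, obs)[0]
                        log_tails.append(np.log(max(p_gt, 1e-300)))
            means.append(np.mean(log_tails))
        rho, _ = spearmanr(grid, means)
        assert rho == -1.0
        assert all(a > b for a, b in zip(means, means[1:]))
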