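from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cooccursig.cooccurrence import (
    all_pairs,
    build_network,
    pair_probability,
    pairs_to_frame,
)
from cooccursig.preprocess import PresenceMatrix
from oracles import enumerate_pair_p_gt, exact_pair_tails


def presence(data, samples):
    return PresenceMatrix(
        cells=pd.DataFrame.from_dict(data, orient="index", columns=samples).astype("int8"),
        phenotype="CD",
    )


class TestPairProbability:
    def test_identical_half_occupancy(self):
        p_gt, p_lt, expected = pair_probability(10, 5, 5, 5)
        assert p_gt == pytest.approx(1 / 252, rel=1e-12)
        assert p_lt == pytest.approx(1.0, rel=1e-12)
        assert expected == 2.5

    def test_small_overlap_closed_form(self):
        p_gt, _, _ = pair_probability(4, 2, 2, 2)
        assert p_gt == pytest.approx(1 / 6, rel=1e-12)

    def test_lower_support_bound_gives_certainty(self):
        for N, N1, N2 in [(10, 3, 4), (6, 5, 4), (8, 8, 2)]:
            lo = max(0, N1 + N2 - N)
            p_gt, _, _ = pair_probability(N, N1, N2, lo)
            assert p_gt == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_full_occupancy(self):
        p_gt, p_lt, _ = pair_probability(7, 7, 3, 3)
        assert p_gt == pytest.approx(1.0) and p_lt == pytest.approx(1.0)

    def test_infeasible_observation_rejected(self):
        with pytest.raises(ValueError):
            pair_probability(10, 5, 5, 6)
        with pytest.raises(ValueError):
            pair_probability(10, 6, 6, 1)  # lo = 2

    def test_enumeration_oracle_spot_checks(self):
        for N, N1, N2, j in [(6, 3, 4, 2), (5, 2, 3, 1), (6, 2, 2, 2)]:
            p_gt, _, _ = pair_probability(N, N1, N2, j)
            assert p_gt == pytest.approx(float(enumerate_pair_p_gt(N, N1, N2, j)), abs=1e-12)

    @given(st.integers(2, 10), st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_symmetry_and_monotonicity(self, N, data):
        N1 = data.draw(st.integers(0, N))
        N2 = data.draw(st.integers(0, N))
        lo, hi = max(0, N1 + N2 - N), min(N1, N2)
        tails = [pair_probability(N, N1, N2, j)[0] for j in range(lo, hi + 1)]
        swapped = [pair_probability(N, N2, N1, j)[0] for j in range(lo, hi + 1)]
        assert tails == pytest.approx(swapped, abs=1e-12)
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))

    def test_large_panel_precision(self):
        # N = 5000: log-space evaluation stays in close agreement with an
        # exact per-term rational evaluation (float-accumulated)
        from fractions import Fraction
        from math import fsum

        N, N1, N2, j = 5000, 900, 1100, 230
        p_gt, p_lt, _ = pair_probability(N, N1, N2, j)
        lo, hi = max(0, N1 + N2 - N), min(N1, N2)
        denom = comb(N, N2)
        terms = {
            i: float(Fraction(comb(N1, i) * comb(N - N1, N2 - i), denom))
            for i in range(lo, hi + 1)
        }
        assert p_gt == pytest.approx(fsum(v for i, v in terms.items() if i >= j), rel=1e-10)
        assert p_lt == pytest.approx(fsum(v for i, v in terms.items() if i <= j), rel=1e-10)


class TestAllPairs:
    def test_identical_patterns_half_occupancy(self):
        row = [1] * 10 + [0] * 10
        pm = presence({"Species_a": row, "Species_b": row}, [f"S{i}" for i in range(20)])
        pairs = all_pairs(pm)
        assert len(pairs) == 1
        assert pairs[0].p_gt == pytest.approx(1 / comb(20, 10), rel=1e-9)
        assert pairs[0].significant

    def test_disjoint_patterns_not_significant(self):
        a = [1] * 8 + [0] * 8
        b = [0] * 8 + [1] * 8
        pm = presence({"Species_a": a, "Species_b": b}, [f"S{i}" for i in range(16)])
        pairs = all_pairs(pm)
        assert len(pairs) == 1
        assert pairs[0].obs == 0
        assert not pairs[0].significant
        assert pairs[0].p_gt == pytest.approx(1.0)

    def test_candidate_pair_count(self):
        rng = np.random.default_rng(7)
        data = {f"Species_{i:02d}": rng.integers(0, 2, 12).tolist() for i in range(6)}
        data = {k: v if sum(v) else [1] + v[1:] for k, v in data.items()}
        pm = presence(data, [f"S{i}" for i in range(12)])
        pairs = all_pairs(pm, expected_threshold=0.0)
        assert len(pairs) == comb(6, 2)

    def test_expected_threshold_screens_pairs(self):
        # occupancies 1 and 2 in 10 samples: expected 0.2 < 1 -> untested
        pm = presence(
            {"Species_a": [1] + [0] * 9, "Species_b": [1, 1] + [0] * 8},
            [f"S{i}" for i in range(10)],
        )
        assert all_pairs(pm, expected_threshold=1.0) == []
        assert len(all_pairs(pm, expected_threshold=0.0)) == 1

    def test_pair_ordering_lexicographic(self):
        rng = np.random.default_rng(0)
        data = {name: rng.integers(0, 2, 20).tolist() for name in ["Zeta_sp", "Alpha_sp", "Mid_sp"]}
        pm = presence(data, [f"S{i}" for i in range(20)])
        pairs = all_pairs(pm, expected_threshold=0.0)
        keys = [(p.species_a, p.species_b) for p in pairs]
        assert keys == sorted(keys)
        assert all(a < b for a, b in keys)


class TestBuildNetwork:
    def make_pairs(self, flags):
        rows = [1] * 6 + [0] * 6
        pm = presence(
            {name: rows for name in flags}, [f"S{i}" for i in range(12)]
        )
        return all_pairs(pm)

    def test_shared_species_star(self):
        pairs = self.make_pairs(["Sp_a", "Sp_b", "Sp_c", "Sp_d"])
        # identical patterns: all 6 pairs significant
        net = build_network(pairs, phenotype="CD", dataset="d1")
        assert net.number_of_nodes() == 4
        assert net.number_of_edges() == 6
        assert net.graph["phenotype"] == "CD"

    def test_no_significant_pairs_empty_network(self):
        a = [1] * 6 + [0] * 6
        b = [0] * 6 + [1] * 6
        pm = presence({"Sp_a": a, "Sp_b": b}, [f"S{i}" for i in range(12)])
        net = build_network(all_pairs(pm), phenotype="CD")
        assert net.number_of_nodes() == 0 and net.number_of_edges() == 0

    def test_edge_count_matches_significant_pairs(self):
        rng = np.random.default_rng(11)
        data = {f"Species_{i:02d}": (rng.random(30) < 0.5).astype(int).tolist() for i in range(8)}
        pm = presence(data, [f"S{i}" for i in range(30)])
        pairs = all_pairs(pm)
        net = build_network(pairs, phenotype="CD")
        assert net.number_of_edges() == sum(p.significant for p in pairs)
        assert set(net.nodes()) == {
            s for p in pairs if p.significant for s in (p.species_a, p.species_b)
        }

    def test_frame_columns(self):
        pairs = self.make_pairs(["Sp_a", "Sp_b"])
        frame = pairs_to_frame(pairs)
        assert list(frame.columns) == [
            "species_a", "species_b", "N", "N1", "N2",
            "obs", "expected", "p_gt", "p_lt", "significant",
        ]
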