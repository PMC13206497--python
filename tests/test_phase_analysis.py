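"""PCA, DP segmentation vs brute force, and phase assignments."""

import itertools

import numpy as np
import pandas as pd
import pytest

from syncom_core import (
    IndicatorSeries,
    assign_indicators,
    pca_scores,
    segment_phases,
)
from syncom_core.phase_analysis import (
    PhaseSegmentation,
    _segment_costs,
    segmentation_cost,
    taxa_phase_correspondence,
)


def brute_force_best_cost(scores, k):
    """Enumerate every contiguous k-split; return minimal total SSE."""
    t = scores.shape[0]
    best = np.inf
    for breaks in itertools.combinations(range(t - 1), k - 1):
        cost = 0.0
        start = 0
        for b in list(breaks) + [t - 1]:
            seg = scores[start : b + 1]
            cost += float(((seg - seg.mean(axis=0)) ** 2).sum())
            start = b + 1
        best = min(best, cost)
    return best


class TestPCA:
    def test_two_perfectly_correlated_variables(self, rng):
        x = rng.normal(size=20)
        res = pca_scores(np.column_stack([x, 3 * x + 1]))
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_orthogonal_noise_equal_fractions(self, rng):
        m = rng.normal(size=(4000, 4))
        res = pca_scores(m)
        assert np.allclose(res.variance_fractions, 0.25, atol=0.03)

    def test_reconstruction_identity(self, rng):
        m = rng.normal(size=(15, 6))
        res = pca_scores(m)
        z = (m - m.mean(axis=0)) / m.std(axis=0, ddof=1)
        assert np.allclose(res.reconstruct(), z, atol=1e-8)

    def test_constant_variable_dropped(self, rng):
        m = np.column_stack([rng.normal(size=10), np.full(10, 3.0), rng.normal(size=10)])
        res = pca_scores(m)
        assert res.kept == [0, 2]

    def test_orientation_first_observation_nonnegative(self, rng):
        m = rng.normal(size=(12, 5))
        res = pca_scores(m)
        assert res.scores[0, 0] >= 0


class TestSegmentation:
    def test_plateaus_recovered_exactly(self):
        # 4 distinct plateaus -> zero-cost segmentation at the changes
        levels = [0.0, 5.0, -3.0, 9.0]
        col = np.repeat(levels, [3, 2, 3, 4])
        m = np.column_stack([col, 2 * col])
        seg = segment_phases(m, k=4)
        assert seg.break_indices == [2, 4, 7]
        assert segmentation_cost(m, seg) == pytest.approx(0.0, abs=1e-12)

    def test_dp_cost_equals_brute_force(self, rng):
        from syncom_core.phase_analysis import pca_scores as _pca

        for _ in range(40):
            t = int(rng.integers(5, 13))
            m = rng.normal(size=(t, 3))
            seg = segment_phases(m, k=4)
            scores = _pca(m).scores[:, :2]
            assert segmentation_cost(m, seg) == pytest.approx(
                brute_force_best_cost(scores, 4), rel=1e-10, abs=1e-10
            )

    def test_invariant_to_uniform_rescaling(self, rng):
        m = rng.normal(size=(10, 4))
        a = segment_phases(m, k=3)
        b = segment_phases(m * 1000.0, k=3)
        assert a.break_indices == b.break_indices

    def test_too_many_phases_errors(self, rng):
        with pytest.raises(ValueError):
            segment_phases(rng.normal(size=(3, 2)), k=4)

    def test_boundaries_are_midpoints(self):
        seg = PhaseSegmentation(days=[0, 5, 10, 15], break_indices=[1],
                                labels=["a", "b"])
        assert seg.boundaries == [7.5]
        assert seg.assignment == {0: "a", 5: "a", 10: "b", 15: "b"}

    def test_generator_changepoints_recovered(self, default_dataset):
        abundance, _, _, truth = default_dataset
        tm = abundance.timepoint_means()
        matrix = np.log10(tm.loc[tm.mean(axis=1) > 0.005].T + 1e-6)
        seg = segment_phases(matrix, k=4)
        days = np.array(seg.days)
        for c in truth.changepoints:
            pos = np.searchsorted(days, c, side="right") - 1 + 0.5
            assert min(abs(b + 0.5 - pos) for b in seg.break_indices) <= 1.0


def _series(name, days, values):
    return IndicatorSeries(name, [(float(d), 1, float(v)) for d, v in zip(days, values)])


class TestAssignIndicators:
    @pytest.fixture()
    def seg(self):
        return PhaseSegmentation(
            days=[0, 5, 10, 15, 20, 25, 30, 35, 40],
            break_indices=[1, 3, 5],
            labels=["immediate_early", "early", "middle", "late"],
        )

    def test_generator_defaults_glutamate_early_4eg_late(self, default_dataset, seg):
        _, _, indicators, _ = default_dataset
        res = assign_indicators(indicators, seg)
        assert res.assignment["glutamic_acid"] == "early"
        assert res.assignment["4EG"] == "late"

    def test_constant_indicator_excluded(self, seg):
        days = seg.days
        inds = [
            _series("flat", days, [2.0] * 9),
            _series("rise_early", days, [0, 3, 6, 7, 7.5, 7.6, 7.7, 7.8, 7.9]),
            _series("rise_late", days, [0.1, 0.1, 0.1, 0.2, 0.2, 0.3, 2, 5, 9]),
        ]
        res = assign_indicators(inds, seg)
        assert "flat" in res.excluded
        assert "flat" not in res.assignment

    def test_mirrored_pair_opposite_assignments(self, seg):
        days = seg.days
        x = [0, 3, 6, 7, 7.5, 7.6, 7.7, 7.8, 7.9]
        inds = [
            _series("x", days, x),
            _series("neg_x", days, [-v for v in x]),
            _series("late_riser", days, [0, 0, 0, 0, 0, 0.2, 2, 5, 9]),
        ]
        res = assign_indicators(inds, seg)
        assert res.assignment["x"] != res.assignment["neg_x"]


class TestCorrespondence:
    def test_empty_core_empty_map(self, default_dataset):
        abundance, volatiles, indicators, _ = default_dataset
        seg = segment_phases(np.log10(abundance.timepoint_means().T + 1e-6), k=4)
        assert taxa_phase_correspondence(abundance, volatiles, indicators, set(), seg) == {}

    def test_identical_taxa_identical_phase_sets(self, default_dataset):
        abundance, volatiles, indicators, truth = default_dataset
        seg = segment_phases(np.log10(abundance.timepoint_means().T + 1e-6), k=4)
        core = set(sorted(truth.core_taxa)[:3])
        res1 = taxa_phase_correspondence(abundance, volatiles, indicators, core, seg)
        res2 = taxa_phase_correspondence(abundance, volatiles, indicators, core, seg)
        assert res1 == res2  # deterministic
        # a duplicated trajectory gets the same phases
        from syncom_core import AbundanceTable

        t0 = sorted(core)[0]
        idx = abundance.taxa.index(t0)
        taxa2 = abundance.taxa + ["clone"]
        values2 = np.vstack([abundance.values, abundance.values[idx]])
        ab2 = AbundanceTable(
            taxa=taxa2, samples=list(abundance.samples),
            values=values2 / values2.sum(axis=0), normalized=True,
        )
        res = taxa_phase_correspondence(ab2, volatiles, indicators, {t0, "clone"}, seg)
        assert res[t0] == res["clone"]

    def test_driver_of_early_rising_class_maps_early(self, rng):
        from syncom_core import AbundanceTable, SampleMeta, VolatileTable
        from scipy.special import expit

        days = np.linspace(0, 40, 9)
        samples = [SampleMeta(f"s{j}", float(d), 1) for j, d in enumerate(days)]
        driver = expit((days - 5) / 2)  # rises in the immediate-early phase
        noise_taxon = rng.uniform(0.8, 1.2, size=9)
        filler = np.ones((3, 9))
        values = np.vstack([driver, noise_taxon, filler])
        ab = AbundanceTable(
            taxa=["driver", "uncorrelated", "f1", "f2", "f3"],
            samples=samples,
            values=values / values.sum(axis=0),
            normalized=True,
        )
        ra = ab.values[0] / ab.values[0].mean()
        compounds, vols = [], []
        for i in range(5):  # an ester class the driver produces
            compounds.append((f"ester_{i}", "ester"))
            vols.append(100 * (1 + 2 * ra))
        for i in range(4):  # a null class
            compounds.append((f"ketone_{i}", "ketone"))
            vols.append(rng.uniform(40, 60, size=9))
        volatiles = VolatileTable(compounds=compounds, samples=samples,
                                  values=np.array(vols))
        seg = PhaseSegmentation(
            days=[float(d) for d in days], break_indices=[1, 3, 5],
            labels=["immediate_early", "early", "middle", "late"],
        )
        res = taxa_phase_correspondence(
            ab, volatiles, [], {"driver", "uncorrelated"}, seg
        )
        assert "immediate_early" in res["driver"] or "early" in res["driver"]
        assert res["uncorrelated"] == []
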