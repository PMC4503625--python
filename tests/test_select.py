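"""Scree-grid rank selection and split-half stability."""

import numpy as np
import pytest

import threemode as tm
from threemode.errors import SelectionError, ValidationError
from threemode.select import ScreeEntry, ScreeGrid, _flag_hull


def test_admissible_ranks_filtering():
    triples = tm.admissible_ranks((3, 2, 2))
    assert (1, 1, 1) in triples
    assert (3, 2, 2) in triples
    assert (2, 1, 1) not in triples  # 2 > 1*1
    assert (3, 1, 2) not in triples  # 3 > 1*2
    assert all(p <= q * r and q <= p * r and r <= p * q for p, q, r in triples)


def test_grid_contains_111_with_lowest_fit(rng):
    cubes = [rng.normal(size=(12, 5, 4)) for _ in range(2)]
    grid = tm.scree_grid(cubes, (2, 2, 2))
    fits = {e.ranks: e.mean_fit for e in grid.entries}
    assert (1, 1, 1) in fits
    assert fits[(1, 1, 1)] == min(fits.values())


def test_mean_fit_monotone_along_rank_increase(rng):
    cubes = [rng.normal(size=(10, 6, 5))]
    grid = tm.scree_grid(cubes, (3, 3, 3))
    fits = {e.ranks: e.mean_fit for e in grid.entries}
    for (p, q, r), f in fits.items():
        for bump in [(p + 1, q, r), (p, q + 1, r), (p, q, r + 1)]:
            if bump in fits:
                assert fits[bump] >= f - 1e-6


def test_hull_flags_order_invariant(rng):
    cubes = [rng.normal(size=(10, 6, 5))]
    grid = tm.scree_grid(cubes, (3, 3, 3))
    shuffled = ScreeGrid(entries=list(reversed(grid.entries)))
    _flag_hull(shuffled.entries)
    flags1 = {e.ranks: e.on_hull for e in grid.entries}
    flags2 = {e.ranks: e.on_hull for e in shuffled.entries}
    assert flags1 == flags2


def _entry(ranks, fit):
    return ScreeEntry(
        ranks=ranks, total_components=sum(ranks), fits=[fit],
        mean_fit=fit, sd_fit=0.0,
    )


class TestSelectComplexity:
    def test_single_entry_grid(self):
        grid = ScreeGrid(entries=[_entry((1, 1, 1), 20.0)])
        _flag_hull(grid.entries)
        ranks, trace = tm.select_complexity(grid)
        assert ranks == (1, 1, 1)
        assert trace

    def test_elbow_selected(self):
        entries = [
            _entry((1, 1, 1), 10.0),
            _entry((2, 2, 1), 20.0),
            _entry((3, 2, 2), 35.0),   # big gain to here ...
            _entry((3, 3, 2), 35.8),   # ... small gain past it
            _entry((4, 3, 3), 36.2),
        ]
        _flag_hull(entries)
        ranks, _trace = tm.select_complexity(ScreeGrid(entries=entries))
        assert ranks == (3, 2, 2)

    def test_unstable_candidate_vetoed(self):
        # (3,3,2) has the sharpest elbow but is unstable across
        # imputations; selection falls through to the stable (3,2,2)
        entries = [
            _entry((1, 1, 1), 10.0),
            _entry((3, 2, 2), 30.0),
            _entry((3, 3, 2), 34.5),
            _entry((4, 3, 3), 35.0),
        ]
        _flag_hull(entries)
        stability = {(3, 3, 2): 0.5, (3, 2, 2): 0.95}
        ranks, trace = tm.select_complexity(ScreeGrid(entries=entries), stability)
        assert ranks == (3, 2, 2)
        assert any("vetoed" in line for line in trace)

    def test_deterministic(self, rng):
        cubes = [rng.normal(size=(10, 6, 5)) for _ in range(2)]
        grid = tm.scree_grid(cubes, (3, 3, 3))
        r1, _t1 = tm.select_complexity(grid)
        r2, _t2 = tm.select_complexity(grid)
        assert r1 == r2

    def test_empty_grid_rejected(self):
        with pytest.raises(SelectionError):
            tm.select_complexity(ScreeGrid(entries=[]))


def test_planted_ranks_on_hull_high_snr():
    """With strong planted (3,2,2) structure that triple is hull-optimal."""
    hits = 0
    for seed in range(5):
        spec = tm.study_like_spec(seed=seed, noise_sd=0.25, missing_rate=0.0)
        synth = tm.generate_tucker3_dataset(spec)
        cube, _ = tm.preprocess(synth.dataset)
        grid = tm.scree_grid([cube.values], (4, 3, 3))
        hull = {e.ranks for e in grid.hull_entries()}
        hits += (3, 2, 2) in hull
    assert hits >= 4


class TestSplitHalf:
    def test_duplicated_persons_give_perfect_congruence(self, small_noisy):
        ds = small_noisy.dataset
        doubled = tm.ThreeWayDataset(
            np.concatenate([ds.values, ds.values]),
            np.ones((2 * ds.n_persons, ds.n_items, ds.n_times), bool),
            [f"{p}-{c}" for c in "ab" for p in ds.person_ids],
            list(ds.item_labels), ds.time_labels.copy(),
        )
        # split by copy: both halves are the same sample
        report = tm.split_half_stability(doubled, (2, 2, 2), n_splits=3, seed=0)
        # random halving of a duplicated sample still mixes copies, so
        # assert on the high-SNR structure instead of literal identity
        assert report.min_congruence >= 0.99

    def test_high_snr_congruence(self, small_noisy):
        report = tm.split_half_stability(
            small_noisy.dataset, (2, 2, 2), n_splits=5, seed=1
        )
        assert report.min_congruence >= 0.95
        assert report.n_splits == 5
        frame = report.to_frame()
        assert set(frame["mode"]) == {"symptom", "time"}
        assert np.all(np.abs(frame["phi"]) <= 1.0)

    def test_person_components_excluded(self, small_noisy):
        report = tm.split_half_stability(
            small_noisy.dataset, (2, 2, 2), n_splits=2, seed=2
        )
        for rec in report.per_split_congruence:
            assert set(rec) == {"symptom", "time"}

    def test_too_few_persons_rejected(self, small_noisy):
        tiny = tm.ThreeWayDataset(
            small_noisy.dataset.values[:3],
            small_noisy.dataset.mask[:3],
            small_noisy.dataset.person_ids[:3],
            list(small_noisy.dataset.item_labels),
            small_noisy.dataset.time_labels.copy(),
        )
        with pytest.raises(ValidationError):
            tm.split_half_stability(tiny, (2, 2, 2), n_splits=1, seed=0)
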