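"""Kennard-Stone partitioning and Mahalanobis outlier screening."""

import numpy as np
import pytest

from nircal.io import SpectraSet
from nircal.sampling import kennard_stone, mahalanobis_outliers
from nircal.synthetic import SyntheticConfig, simulate


def _points_1d(values):
    vals = np.asarray(values, dtype=float)
    # two identical columns so the 1-D geometry survives the 2-column matrix
    X = np.column_stack([vals, vals])
    return SpectraSet([1000.0, 1001.0], X, [f"S{i}" for i in range(len(vals))])


def _ks_oracle(X, n_cal):
    """Brute-force greedy max-min reference implementation (plain loops)."""
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] > best[0]:
                best = (D[i, j], [i, j])
    selected = best[1]
    while len(selected) < n_cal:
        cand, cand_d = None, -1.0
        for i in range(n):
            if i in selected:
                continue
            dmin = min(D[i, j] for j in selected)
            if dmin > cand_d:
                cand, cand_d = i, dmin
        selected.append(cand)
    return set(selected)


class TestKennardStone:
    def test_three_points_select_two(self):
        split = kennard_stone(_points_1d([0.0, 1.0, 10.0]), calibration_size=2)
        assert set(split.calibration_ids) == {"S0", "S2"}

    def test_select_all(self):
        split = kennard_stone(_points_1d([0.0, 1.0, 10.0]), calibration_size=3)
        assert set(split.calibration_ids) == {"S0", "S1", "S2"}
        assert split.prediction_ids == []

    def test_tie_breaks_to_lower_index(self):
        # after seeding {0, 10}, points 1 and 9 tie at min-distance 1
        split = kennard_stone(_points_1d([0.0, 1.0, 9.0, 10.0]), calibration_size=3)
        assert set(split.calibration_ids) == {"S0", "S3", "S1"}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        X = rng.normal(size=(n, 4))
        spectra = SpectraSet(
            1000.0 + np.arange(4.0), X, [f"S{i}" for i in range(n)]
        )
        n_cal = int(rng.integers(2, n))
        split = kennard_stone(spectra, calibration_size=n_cal)
        got = {int(s[1:]) for s in split.calibration_ids}
        assert got == _ks_oracle(X, n_cal)

    def test_permutation_covariant_id_set(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 6))
        lam = 1000.0 + np.arange(6.0)
        ids = [f"S{i}" for i in range(12)]
        base = kennard_stone(SpectraSet(lam, X, ids), calibration_size=7)
        perm = rng.permutation(12)
        shuffled = SpectraSet(lam, X[perm], [ids[i] for i in perm])
        other = kennard_stone(shuffled, calibration_size=7)
        assert set(base.calibration_ids) == set(other.calibration_ids)

    def test_default_fraction_round(self):
        spectra = _points_1d(np.linspace(0, 1, 111))
        split = kennard_stone(spectra, calibration_fraction=2.0 / 3.0)
        assert len(split.calibration_ids) == 74
        forced = kennard_stone(spectra, calibration_size=75)
        assert len(forced.calibration_ids) == 75

    def test_spread_beats_random_subsets(self, default_dataset):
        spectra, _, _ = default_dataset
        sub = spectra.subset_samples(spectra.sample_ids[:40])
        split = kennard_stone(sub, calibration_fraction=0.5)
        idx = {s: i for i, s in enumerate(sub.sample_ids)}
        rows = [idx[s] for s in split.calibration_ids]

        def min_pairwise(rows):
            X = sub.absorbance[rows]
            D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
            return D[np.triu_indices(len(rows), 1)].min()

        ks_min = min_pairwise(rows)
        rng = np.random.default_rng(0)
        beaten = sum(
            min_pairwise(rng.choice(40, size=len(rows), replace=False)) <= ks_min
            for _ in range(200)
        )
        assert beaten >= 195  # KS spread should beat almost every random subset

    def test_split_statistics_balanced(self, default_dataset):
        spectra, refs, _ = default_dataset
        split = kennard_stone(spectra, calibration_fraction=2.0 / 3.0)
        for analyte in ("abts", "frap", "dpph"):
            cal = refs.subset_samples(split.calibration_ids).values(analyte)
            pred = refs.subset_samples(split.prediction_ids).values(analyte)
            assert abs(cal.mean() - pred.mean()) < 0.5 * refs.values(analyte).std()


class TestMahalanobisOutliers:
    def test_clean_synthetic_has_no_outliers(self, default_dataset):
        spectra, _, _ = default_dataset
        report = mahalanobis_outliers(spectra)
        assert report.flagged == []
        assert np.all(report.distances >= 0)

    def test_planted_gross_outlier_flagged(self, default_dataset):
        spectra, _, _ = default_dataset
        X = spectra.absorbance.copy()
        X[17] = 10.0 * np.abs(X).max()
        poisoned = SpectraSet(spectra.wavelengths_nm, X, spectra.sample_ids)
        report = mahalanobis_outliers(poisoned)
        assert spectra.sample_ids[17] in report.flagged

    def test_quantile_rule_thresholds_distances(self, default_dataset):
        spectra, _, _ = default_dataset
        report = mahalanobis_outliers(spectra, rule="quantile95")
        assert all(
            report.distances[report.sample_ids.index(s)] > report.threshold
            for s in report.flagged
        )

    def test_exchangeable_spectra_unflagged(self):
        rng = np.random.default_rng(1)
        base = np.sin(np.linspace(0, 4, 60))
        X = base + rng.normal(0, 1e-4, size=(15, 60))
        spectra = SpectraSet(1000.0 + np.arange(60.0), X, [f"S{i}" for i in range(15)])
        report = mahalanobis_outliers(spectra)
        assert report.flagged == []
        spread = report.distances.max() - report.distances.min()
        assert spread < 3.0 * report.distances.mean()

    def test_preconditions(self, small_spectra):
        few = small_spectra.subset_samples(small_spectra.sample_ids[:4])
        with pytest.raises(ValueError):
            mahalanobis_outliers(few)
        with pytest.raises(ValueError):
            mahalanobis_outliers(small_spectra, variance_kept=1.5)
        with pytest.raises(ValueError):
            mahalanobis_outliers(small_spectra, rule="iqr")
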