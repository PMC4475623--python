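"""Per-study predictive factors: forced arithmetic and invariances."""

import numpy as np
import pytest

from exprbench.factors import (
    FACTOR_COLUMNS,
    compute_factors,
    compute_fc,
    compute_imbalance,
    compute_pdeg,
    compute_withincor,
    factors_table,
)
from exprbench.simulate import StudySimConfig, simulate_study
from exprbench.study import ExpressionStudy


def _study_from(matrix, labels, study_id="f"):
    matrix = np.asarray(matrix, float)
    return ExpressionStudy(
        study_id, matrix, np.asarray(labels),
        [f"g{i}" for i in range(matrix.shape[0])],
        [f"s{i}" for i in range(matrix.shape[1])],
    )


def _pair_with_exact_correlation(r, n, rng):
    """Two n-vectors whose sample correlation is exactly r."""
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    u = (u - u.mean()) / u.std(ddof=1)
    v = v - v.mean()
    v -= u * (u @ v) / (u @ u) * 1.0  # orthogonalize against u
    v = v / v.std(ddof=1)
    x2 = r * u + np.sqrt(1 - r**2) * v
    return u, x2


class TestFc:
    def test_zero_when_class_means_identical(self, rng):
        half = rng.standard_normal((5, 8))
        st = _study_from(np.hstack([half, half]), ["A"] * 8 + ["B"] * 8)
        assert compute_fc(st) == pytest.approx(0.0, abs=1e-12)

    def test_forced_arithmetic_mean_of_one_and_two(self):
        # per-probeset standardized differences exactly 1.0 and 2.0
        base = np.array([1.0, -1.0, 1.0, -1.0])
        sd_pooled = np.sqrt(8 / 6)  # pooled over both classes, n1=n2=4
        rows = []
        for d in (1.0, 2.0):
            rows.append(np.concatenate([base + d * sd_pooled, base]))
        st = _study_from(np.vstack(rows), ["A"] * 4 + ["B"] * 4)
        assert compute_fc(st) == pytest.approx(1.5, abs=1e-12)

    def test_generator_roundtrip_recovers_delta(self):
        st = simulate_study(
            StudySimConfig(
                study_id="d", n1=400, n2=400, p=300, n_de=300, delta=0.8, seed=3
            )
        )
        assert compute_fc(st) == pytest.approx(0.8, abs=0.05)

    def test_location_and_scale_invariance(self, rng):
        st = simulate_study(
            StudySimConfig(study_id="i", n1=10, n2=10, p=20, n_de=5, delta=1.0, seed=1)
        )
        base = compute_fc(st)
        mat = st.matrix.copy()
        mat[3] = mat[3] * 7.0 + 100.0
        st2 = _study_from(mat, st.labels)
        assert compute_fc(st2) == pytest.approx(base, abs=1e-12)


class TestWithincor:
    def test_full_shrinkage_gives_zero(self, rng):
        st = simulate_study(
            StudySimConfig(study_id="w", n1=6, n2=6, p=10, seed=2)
        )
        assert compute_withincor(st, shrinkage_intensity=1.0) == 0.0

    def test_forced_arithmetic_two_probesets(self, rng):
        a1, a2 = _pair_with_exact_correlation(0.6, 10, rng)
        b1, b2 = _pair_with_exact_correlation(-0.2, 12, rng)
        mat = np.vstack(
            [np.concatenate([a1, b1]), np.concatenate([a2, b2])]
        )
        st = _study_from(mat, ["A"] * 10 + ["B"] * 12)
        got = compute_withincor(st, shrinkage_intensity=0.0)
        assert got == pytest.approx((0.6 + 0.2) / 2, abs=1e-10)

    def test_block_structure_matches_monte_carlo_oracle(self):
        """Generator blocks of 50 at rho=0.4 in p=500: the average |r| should
        match a pair-count-weighted expectation estimated by brute force."""
        n = 150
        st = simulate_study(
            StudySimConfig(
                study_id="b", n1=n, n2=n, p=500, rho=0.4, block_size=50, seed=4
            )
        )
        got = compute_withincor(st, shrinkage_intensity=0.0)
        # oracle: E|r| for correlated (rho=0.4) and independent pairs at
        # sample size n, by direct bivariate-normal simulation
        orng = np.random.default_rng(99)
        def mean_abs_r(rho, reps=4000):
            x = orng.standard_normal((reps, n))
            y = rho * x + np.sqrt(1 - rho**2) * orng.standard_normal((reps, n))
            xc = x - x.mean(1, keepdims=True)
            yc = y - y.mean(1, keepdims=True)
            r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
            return np.abs(r).mean()
        n_within = 10 * (50 * 49 // 2)
        n_total = 500 * 499 // 2
        expected = (
            n_within * mean_abs_r(0.4) + (n_total - n_within) * mean_abs_r(0.0)
        ) / n_total
        assert got == pytest.approx(expected, abs=0.01)

    def test_analytic_intensity_shrinks_noise_floor(self):
        # independent probesets at modest n: shrinkage should push the
        # estimate well below the raw sampling floor
        st = simulate_study(
            StudySimConfig(study_id="n", n1=20, n2=20, p=100, seed=5)
        )
        raw = compute_withincor(st, shrinkage_intensity=0.0)
        shrunk = compute_withincor(st)
        assert shrunk < 0.5 * raw

    def test_invariant_to_sample_permutation_and_relabel(self, rng):
        st = simulate_study(
            StudySimConfig(study_id="p", n1=8, n2=9, p=12, rho=0.3, block_size=4, seed=6)
        )
        base = compute_withincor(st)
        perm = np.concatenate(
            [rng.permutation(np.flatnonzero(m)) for m in st.class_masks()]
        )
        st_perm = st.subset_samples(perm)
        assert compute_withincor(st_perm) == pytest.approx(base, abs=1e-12)
        st_flip = _study_from(st.matrix, np.where(st.labels == "A", "B", "A"))
        assert compute_withincor(st_flip) == pytest.approx(base, abs=1e-12)


class TestPdegAndImbalance:
    def test_null_study_pdeg_zero(self, null_study):
        pdeg, log2p = compute_pdeg(null_study)
        assert pdeg == 0 and log2p == 0.0

    def test_log2_transform_uses_plus_one(self):
        st = simulate_study(
            StudySimConfig(
                study_id="q", n1=30, n2=30, p=100, n_de=80, delta=3.0, seed=7
            )
        )
        pdeg, log2p = compute_pdeg(st)
        assert pdeg > 0
        assert log2p == pytest.approx(np.log2(pdeg + 1))

    def test_pdeg_monotone_in_delta(self):
        means = []
        for delta in (0.0, 0.8, 2.0):
            vals = [
                compute_pdeg(
                    simulate_study(
                        StudySimConfig(
                            study_id="m", n1=20, n2=20, p=300, n_de=60,
                            delta=delta, seed=s,
                        )
                    )
                )[0]
                for s in range(3)
            ]
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    @pytest.mark.parametrize(
        "n1,n2,expected", [(16, 8, 16 / 24), (20, 20, 0.5), (50, 33, 50 / 83)]
    )
    def test_imbalance_is_majority_fraction(self, n1, n2, expected):
        st = simulate_study(StudySimConfig(study_id="i", n1=n1, n2=n2, p=5, seed=1))
        assert compute_imbalance(st) == pytest.approx(expected)


class TestFactorsTable:
    def test_canonical_columns_and_reproducibility(self):
        st = simulate_study(
            StudySimConfig(
                study_id="t", n1=10, n2=12, p=80, n_de=10, delta=1.5, seed=9,
                medical_question="non-diagnostic", cell_type="blood",
            )
        )
        f1 = compute_factors(st)
        f2 = compute_factors(st)
        assert f1 == f2
        tab = factors_table([f1])
        assert list(tab.columns) == FACTOR_COLUMNS
        assert tab.loc[0, "medical_question"] == "non-diagnostic"
        assert tab.loc[0, "sample_size"] == 22
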