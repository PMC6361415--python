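import math

import numpy as np
import pandas as pd
import pytest

from otucensus import (
    FrequencyCounts,
    IncidenceMatrix,
    SampleCountTable,
    accumulation_curve,
    breakaway_ratio_regression,
    chao2,
    coverage_ratio_richness,
    detection_filter,
    frequency_counts,
    generate_census,
    ice,
    ichao2,
    ichao2split,
    incidence_from_counts,
    next_study_overlap,
    recapture_fraction,
    twlrm,
    CensusConfig,
)


# ---------------------------------------------------------------------------
# independent brute-force transcriptions of the closed-form estimators,
# written directly from the formulas, with no shared code with the package


def brute_chao2(q, T, s_obs):
    q1, q2 = q.get(1, 0), q.get(2, 0)
    if q2 > 0:
        return s_obs + (T - 1) / T * q1**2 / (2 * q2)
    return s_obs + (T - 1) / T * q1 * (q1 - 1) / 2


def brute_ichao2(q, T, s_obs):
    s = brute_chao2(q, T, s_obs)
    q1, q2, q3, q4 = (q.get(i, 0) for i in (1, 2, 3, 4))
    if q3 == 0:
        return s
    q4e = q4 if q4 > 0 else 1
    return s + (T - 3) / (4 * T) * (q3 / q4e) * max(
        q1 - (T - 3) / (2 * (T - 1)) * q2 * q3 / q4e, 0
    )


def brute_ice(q, T, s_obs, k=10, t_infr=None):
    s_infr = sum(q.get(i, 0) for i in range(1, k + 1))
    s_freq = s_obs - s_infr
    if s_infr == 0:
        return s_obs
    n_infr = sum(i * q.get(i, 0) for i in range(1, k + 1))
    q1 = q.get(1, 0)
    C = 1 - q1 / n_infr
    t = t_infr if t_infr is not None else T
    g2 = max(
        (s_infr / C) * (t / (t - 1)) * sum(i * (i - 1) * q.get(i, 0) for i in range(1, k + 1)) / n_infr**2 - 1,
        0,
    )
    return s_freq + s_infr / C + q1 / C * g2


def _fc(qdict, T):
    q = np.zeros(T, dtype=np.int64)
    for i, v in qdict.items():
        q[i - 1] = v
    return FrequencyCounts(q=q, n_units=T)


# ---------------------------------------------------------------------------


def _table(counts_by_sample, studies):
    df = pd.DataFrame(counts_by_sample, dtype=np.int64)
    return SampleCountTable(df, studies)


class TestDetectionFilter:
    def test_one_sample_per_study_removed(self):
        # OTU A in one sample of each of 3 studies -> no study has >=2 samples
        table = _table(
            {"s1": {"A": 5}, "s2": {"A": 3}, "s3": {"A": 1}},
            {"s1": "x", "s2": "y", "s3": "z"},
        )
        filtered, removed = detection_filter(table)
        assert removed == ["A"] and filtered.n_otus == 0

    def test_two_samples_same_study_kept(self):
        table = _table(
            {"s1": {"A": 4, "B": 2}, "s2": {"A": 1, "B": 0}},
            {"s1": "x", "s2": "x"},
        )
        filtered, removed = detection_filter(table)
        assert filtered.otu_ids == ["A"] and removed == ["B"]

    def test_two_reads_single_sample_removed(self):
        table = _table({"s1": {"A": 2}, "s2": {"A": 0}}, {"s1": "x", "s2": "x"})
        _, removed = detection_filter(table)
        assert removed == ["A"]


class TestIncidence:
    def test_presence_requires_two_samples_per_study(self):
        table = _table(
            {"s1": {"A": 4}, "s2": {"A": 1}, "s3": {"A": 9}},
            {"s1": "x", "s2": "x", "s3": "y"},
        )
        m = incidence_from_counts(table)
        assert m.presence.loc["A", "x"] == 1
        assert m.presence.loc["A", "y"] == 0  # only one sample in study y

    def test_matches_brute_force_on_census(self, census_factory):
        table, _ = census_factory(s_true=300, depth_per_sample=1000, seed=4)
        filtered, _ = detection_filter(table)
        m = incidence_from_counts(filtered)
        # two-pass brute force straight from the raw counts
        for otu in filtered.otu_ids[:60]:
            for study in m.presence.columns:
                samples = [s for s in filtered.sample_ids
                           if filtered.study_of_sample[s] == study]
                n_pos = sum(int(filtered.counts.loc[otu, s]) > 0 for s in samples)
                assert m.presence.loc[otu, study] == (1 if n_pos >= 2 else 0)


class TestFrequencyCounts:
    def test_row_sum_tally(self):
        m = IncidenceMatrix(pd.DataFrame(
            [[1, 0], [0, 1], [1, 1]], index=list("abc"), columns=["u", "v"]))
        fc = frequency_counts(m)
        assert list(fc.q) == [2, 1]
        assert fc.s_obs == 3 and fc.total_incidences == 4

    def test_all_ones_matrix(self):
        m = IncidenceMatrix(pd.DataFrame(np.ones((7, 5), dtype=np.int8)))
        fc = frequency_counts(m)
        assert fc.Q(5) == 7 and fc.s_obs == 7
        assert sum(fc.Q(i) for i in range(1, 5)) == 0

    def test_random_matrix_matches_exhaustive_recount(self, random_incidence):
        m = random_incidence(200, 12, seed=9)
        fc = frequency_counts(m)
        tally = {}
        arr = m.presence.to_numpy()
        for row in arr:
            tally[row.sum()] = tally.get(row.sum(), 0) + 1
        for i in range(1, 13):
            assert fc.Q(i) == tally.get(i, 0)


class TestChao2Family:
    def test_no_uniques_adds_nothing(self):
        fc = _fc({2: 3, 5: 7}, T=10)
        assert chao2(fc).s_hat == fc.s_obs

    def test_point_example(self):
        fc = _fc({1: 4, 2: 2, 5: 4}, T=10)  # S_obs = 10
        assert chao2(fc).s_hat == pytest.approx(13.6)

    def test_bias_corrected_branch(self):
        fc = _fc({1: 4, 5: 6}, T=10)  # Q2 = 0, S_obs = 10
        assert chao2(fc).s_hat == pytest.approx(15.4)

    def test_too_few_units(self):
        with pytest.raises(ValueError):
            chao2(_fc({1: 1}, T=1))

    def test_ichao2_reduces_to_chao2_when_q3_zero(self):
        fc = _fc({1: 4, 2: 2, 5: 4}, T=10)
        assert ichao2(fc).s_hat == chao2(fc).s_hat

    def test_ichao2_point_example(self):
        fc = _fc({1: 4, 2: 2, 3: 1, 4: 1, 6: 2}, T=10)  # S_obs = 10
        assert ichao2(fc).s_hat == pytest.approx(13.6 + 0.175 * (4 - 7 / 18 * 2), abs=1e-9)

    def test_ichao2_no_uniques(self):
        fc = _fc({5: 10}, T=10)
        assert ichao2(fc).s_hat == fc.s_obs

    def test_ichao2_q4_substitution_flagged(self):
        fc = _fc({1: 4, 2: 2, 3: 1, 6: 3}, T=10)
        est = ichao2(fc)
        assert est.diagnostics.get("q4_substituted")
        assert est.s_hat >= chao2(fc).s_hat

    def test_ichao2_requires_four_units(self):
        with pytest.raises(ValueError):
            ichao2(_fc({1: 1, 2: 1, 3: 1}, T=3))


class TestIce:
    def test_no_infrequent_otus(self):
        fc = _fc({11: 6}, T=12)
        assert ice(fc).s_hat == fc.s_obs

    def test_point_example(self):
        fc = _fc({1: 3, 2: 2, 11: 5}, T=12)  # S_freq=5 (incidence 11 > 10)
        assert ice(fc, t_infr=4).s_hat == pytest.approx(13.75)

    def test_all_uniques_inestimable(self):
        with pytest.raises(ValueError, match="inestimable"):
            ice(_fc({1: 9}, T=12))

    def test_t_infr_from_matrix(self, random_incidence):
        m = random_incidence(150, 12, seed=1)
        fc = frequency_counts(m)
        est = ice(fc, m)
        assert 2 <= est.diagnostics["T_infr"] <= 12


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_transcription(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(5, 16))
        qdict = {}
        for i in range(1, T + 1):
            if rng.random() < 0.7:
                qdict[i] = int(rng.integers(1, 40))
        qdict.setdefault(1, 5)
        qdict.setdefault(2, 3)
        fc = _fc(qdict, T)
        s_obs = fc.s_obs
        assert chao2(fc).s_hat == pytest.approx(brute_chao2(qdict, T, s_obs), rel=1e-9)
        if T >= 4:
            assert ichao2(fc).s_hat == pytest.approx(brute_ichao2(qdict, T, s_obs), rel=1e-9)
        assert ice(fc, t_infr=T).s_hat == pytest.approx(
            brute_ice(qdict, T, s_obs, k=min(10, T)), rel=1e-9)

    def test_ichao2_never_below_chao2(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            qdict = {i: int(rng.integers(0, 20)) for i in range(1, 8)}
            qdict = {i: v for i, v in qdict.items() if v}
            if not qdict:
                continue
            fc = _fc(qdict, T=10)
            assert ichao2(fc).s_hat >= chao2(fc).s_hat - 1e-12


def test_chao2_matches_vegan_specpool():
    """Independent oracle: vegan's specpool computes the same incidence-based
    chao estimate from a site-by-species matrix."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    rng = np.random.default_rng(5)
    mat = (rng.random((8, 60)) < 0.25).astype(int)  # sites x species
    mat[:, mat.sum(axis=0) == 0] = 0
    keep = mat.sum(axis=0) > 0
    mat = mat[:, keep]
    rows = ";".join(",".join(map(str, r)) for r in mat)
    script = (
        "suppressMessages(library(vegan));"
        f"m <- do.call(rbind, lapply(strsplit(strsplit('{rows}', ';')[[1]], ','), as.numeric));"
        "cat(specpool(m)$chao)"
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                         timeout=120)
    assert out.returncode == 0, out.stderr
    expected = float(out.stdout.strip())
    m = IncidenceMatrix(pd.DataFrame(mat.T))
    assert chao2(frequency_counts(m)).s_hat == pytest.approx(expected, rel=1e-6)


class TestRatioRegressions:
    def test_twlrm_geometric_decay_oracle(self):
        # Q_i = c * rho^i continues analytically to Q_0 = c
        c, rho, T = 1000.0, 0.6, 12
        q = np.round(c * rho ** np.arange(1, T + 1)).astype(int)
        fc = FrequencyCounts(q=q, n_units=T)
        est = twlrm(fc)
        assert est.diagnostics["Q0_hat"] == pytest.approx(c, rel=0.05)

    def test_twlrm_needs_three_classes(self):
        with pytest.raises(ValueError):
            twlrm(_fc({1: 5, 2: 3}, T=10))

    def test_breakaway_recovers_mixture_truth(self):
        """Two-component Poisson-mixture incidence, known S_true = 2000:
        estimate within 20% across seeds."""
        S, T = 2000, 30
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lam = np.where(rng.random(S) < 0.6, 0.08, 0.8)
            inc = rng.binomial(T, 1 - np.exp(-lam))
            inc = inc[inc > 0]
            fc = FrequencyCounts(q=np.bincount(inc, minlength=T + 1)[1:], n_units=T)
            est = breakaway_ratio_regression(fc)
            assert abs(est.s_hat / S - 1) < 0.20

    def test_breakaway_needs_four_classes(self):
        with pytest.raises(ValueError):
            breakaway_ratio_regression(_fc({1: 5, 2: 3, 3: 2}, T=10))


class TestIchao2Split:
    def test_saturated_matrix_gives_s_obs(self):
        m = IncidenceMatrix(pd.DataFrame(np.ones((9, 8), dtype=np.int8)))
        est = ichao2split(m, seed=0)
        assert est.s_hat == 9 and est.se == 0.0

    def test_deterministic_given_seed(self, random_incidence):
        m = random_incidence(100, 12, seed=2)
        a = ichao2split(m, n_repeats=20, seed=7)
        b = ichao2split(m, n_repeats=20, seed=7)
        assert a.s_hat == b.s_hat and a.se == b.se

    def test_group_count_floor(self, random_incidence):
        with pytest.raises(ValueError):
            ichao2split(random_incidence(10, 8), n_groups=3)

    def test_simulator_recovery_and_agreement_with_ichao2(self):
        table, truth = generate_census(
            CensusConfig(s_true=3000, sigma=1.5, n_studies=40, samples_per_study=10,
                         depth_per_sample=20_000, sample_noise_sigma=0.5, seed=17)
        )
        filtered, _ = detection_filter(table)
        m = incidence_from_counts(filtered)
        fc = frequency_counts(m)
        split = ichao2split(m, seed=17)
        plain = ichao2(fc)
        assert abs(split.s_hat / 3000 - 1) < 0.25
        assert abs(split.s_hat / plain.s_hat - 1) < 0.15


class TestCoverageRatioAndRecapture:
    def test_identity_rho(self):
        assert coverage_ratio_richness(100, 1.0).s_hat == 100

    def test_census_scale_division(self):
        est = coverage_ratio_richness(739_880, 0.96)
        assert round(est.s_hat) == 770_708

    def test_half_rho_doubles(self):
        assert coverage_ratio_richness(100, 0.5).s_hat == pytest.approx(200)

    def test_zero_rho_rejected(self):
        with pytest.raises(ValueError):
            coverage_ratio_richness(100, 0.0)

    def test_recapture_simple_fraction(self):
        ref = [f"r{i}" for i in range(100)]
        assert recapture_fraction(ref, ref[:93]) == pytest.approx(0.93)
        assert recapture_fraction(ref, ref) == 1.0

    def test_recapture_per_taxon(self):
        ref = [f"x{i}" for i in range(10)] + ["y0", "y1"]
        taxon = {r: ("X" if r.startswith("x") else "Y") for r in ref}
        mapped = [f"x{i}" for i in range(8)] + ["y0"]
        out = recapture_fraction(ref, mapped, taxon)
        assert out == {"X": pytest.approx(0.8), "Y": pytest.approx(0.5)}

    def test_recapture_guards(self):
        with pytest.raises(ValueError):
            recapture_fraction([], [])
        with pytest.raises(ValueError):
            recapture_fraction(["a"], ["b"])


class TestAccumulationCurve:
    def test_full_subset_is_exact(self, random_incidence):
        m = random_incidence(50, 6, seed=3)
        curve = accumulation_curve(m, n_repeats=10, seed=0)
        last = curve.iloc[-1]
        assert last["mean_otus"] == 50 and last["sd_otus"] == 0.0

    def test_disjoint_studies_are_additive(self):
        mat = np.kron(np.eye(4, dtype=np.int8), np.ones((5, 1), dtype=np.int8))
        m = IncidenceMatrix(pd.DataFrame(mat))
        curve = accumulation_curve(m, n_repeats=30, seed=1)
        assert np.allclose(curve["mean_otus"], 5 * curve["n_studies"])
        assert np.allclose(curve["sd_otus"], 0.0)

    def test_matches_hypergeometric_expectation(self, random_incidence):
        from scipy.special import comb

        m = random_incidence(500, 20, seed=4)
        reps = 200
        curve = accumulation_curve(m, n_repeats=reps, seed=5)
        t = m.row_sums()
        T = m.n_units
        for _, row in curve.iterrows():
            N = int(row["n_studies"])
            exact = np.sum(1.0 - comb(T - t, N) / comb(T, N))
            se = row["sd_otus"] / math.sqrt(reps)
            assert abs(row["mean_otus"] - exact) <= 5 * se + 1e-9


class TestNextStudyOverlap:
    def test_saturated(self):
        m = IncidenceMatrix(pd.DataFrame(np.ones((5, 4), dtype=np.int8)))
        assert next_study_overlap(m, seed=0) == 1.0

    def test_disjoint(self):
        m = IncidenceMatrix(pd.DataFrame(np.eye(4, dtype=np.int8)))
        assert next_study_overlap(m, seed=0) == 0.0

    def test_matches_exhaustive_leave_one_out(self, random_incidence):
        m = random_incidence(500, 20, seed=6)
        pres = m.presence.to_numpy().astype(bool)
        fracs = []
        for j in range(20):
            mem = pres[:, j]
            rest = np.delete(pres, j, axis=1).any(axis=1)
            fracs.append((mem & rest).sum() / mem.sum())
        exact = np.mean(fracs)
        est = next_study_overlap(m, n_repeats=2000, seed=7)
        assert abs(est - exact) < 0.02

    def test_needs_two_units(self):
        with pytest.raises(ValueError):
            next_study_overlap(IncidenceMatrix(pd.DataFrame(np.ones((3, 1), dtype=np.int8))))
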