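import numpy as np
import pytest
from scipy import stats

from camconverge import diel_screen as ds
from camconverge.core_io import (
    CANONICAL_TIMES,
    DielMatrix,
    DielProfile,
    OrthologGroup,
    TimeWindowScheme,
    ValidationError,
)
from camconverge.diel_screen import ExpressionThresholds

from conftest import TIMES, cosine_profile


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def periodic_spline_oracle(t, y, query, period=24.0):
    """Periodic natural cubic spline built from the cyclic tridiagonal system
    for the knot second derivatives (independent of scipy's implementation)."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = t.size
    h = np.empty(n)
    h[:-1] = np.diff(t)
    h[-1] = t[0] + period - t[-1]
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for i in range(n):
        im, ip = (i - 1) % n, (i + 1) % n
        A[i, im] += h[im] / 6.0
        A[i, i] += (h[im] + h[i]) / 3.0
        A[i, ip] += h[i] / 6.0
        rhs[i] = (y[ip] - y[i]) / h[i] - (y[i] - y[im]) / h[im]
    M = np.linalg.solve(A, rhs)
    out = []
    for q in np.atleast_1d(query):
        x = t[0] + (q - t[0]) % period
        i = int(np.searchsorted(t, x, side="right") - 1)
        i = max(0, min(i, n - 1))
        ip = (i + 1) % n
        t0, hi = t[i], h[i]
        t1 = t0 + hi
        s = (
            M[i] * (t1 - x) ** 3 / (6 * hi)
            + M[ip] * (x - t0) ** 3 / (6 * hi)
            + (y[i] - M[i] * hi**2 / 6) * (t1 - x) / hi
            + (y[ip] - M[ip] * hi**2 / 6) * (x - t0) / hi
        )
        out.append(s)
    return np.asarray(out)


def spearman_oracle(x, y):
    """Rank (average ties, hand-rolled) then Pearson."""

    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(v.size)
        i = 0
        while i < v.size:
            j = i
            while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def shift_oracle(a, b, grid_step=0.5):
    """Exhaustive search over all circular lags on the fine grid."""
    fine = np.arange(grid_step, 24.0 + grid_step / 2, grid_step)
    za = ds.periodic_spline_resample(a.times, ds.zscore(a).mean_series(), fine)
    zb = ds.periodic_spline_resample(b.times, ds.zscore(b).mean_series(), fine)
    half = int(round(12.0 / grid_step))
    cands = []
    for k in range(-(half - 1), half + 1):
        corr = np.corrcoef(za, np.roll(zb, -k))[0, 1]
        cands.append((k * grid_step, corr))
    best_corr = max(c for _, c in cands)
    ties = [(lag, c) for lag, c in cands if c >= best_corr - 1e-12]
    ties.sort(key=lambda lc: (abs(lc[0]), -np.sign(lc[0])))
    return ties[0][0]


def bh_oracle(p):
    """Step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


def naive_average_distance(dist, members_a, members_b):
    """Brute-force unweighted average linkage distance between two clusters."""
    return float(
        np.mean([dist[i, j] for i in members_a for j in members_b])
    )


def assert_valid_greedy_average_linkage(dist, Z, tol=1e-12):
    """Check a linkage matrix against O(n^3) recomputation: every merge joins
    a pair at the true minimum average distance, at the recomputed height.

    Ties in the minimum (common with rank-based distances) leave the merge
    partner ambiguous, so validity of the greedy sequence is the well-defined
    brute-force criterion.
    """
    n = dist.shape[0]
    members = {i: frozenset({i}) for i in range(n)}
    active = set(range(n))
    for row_idx, (a, b, h, size) in enumerate(Z):
        a, b = int(a), int(b)
        recomputed = naive_average_distance(dist, members[a], members[b])
        assert h == pytest.approx(recomputed, abs=tol)
        current_min = min(
            naive_average_distance(dist, members[i], members[j])
            for i in active
            for j in active
            if i < j
        )
        assert h == pytest.approx(current_min, abs=tol)
        new_id = n + row_idx
        members[new_id] = members[a] | members[b]
        assert size == len(members[new_id])
        active -= {a, b}
        active.add(new_id)


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------


class TestInterpolateToGrid:
    def test_constant_profile_preserved(self):
        prof = DielProfile("g", "At", [4, 8, 12, 16, 20, 24], np.full((6, 1), 5.0))
        out = ds.interpolate_to_grid(prof, 2.0)
        np.testing.assert_allclose(out.mean_series(), 5.0)
        assert out.times.size == 12

    def test_knot_reproduction_on_target_grid(self, rng):
        prof = DielProfile("g", "Kf", TIMES, rng.uniform(1, 10, size=(12, 3)))
        out = ds.interpolate_to_grid(prof, 2.0)
        np.testing.assert_allclose(out.mean_series(), prof.mean_series())

    def test_matches_independent_spline_oracle(self):
        t4 = np.asarray([4.0, 8.0, 12.0, 16.0, 20.0, 24.0])
        y = 3.0 + np.cos(2 * np.pi * t4 / 24.0)
        prof = DielProfile("g", "At", t4, y[:, None])
        out = ds.interpolate_to_grid(prof, 2.0)
        expected = periodic_spline_oracle(t4, y, np.asarray(TIMES))
        np.testing.assert_allclose(out.mean_series(), expected, atol=1e-10)

    def test_spline_oracle_agreement_many_random_profiles(self, rng):
        t4 = np.asarray([4.0, 8.0, 12.0, 16.0, 20.0, 24.0])
        query = np.linspace(0.5, 24.0, 48)
        for _ in range(30):
            y = rng.uniform(0.5, 10.0, size=6)
            mine = ds.periodic_spline_resample(t4, y, query)
            oracle = periodic_spline_oracle(t4, y, query)
            np.testing.assert_allclose(mine, oracle, atol=1e-9)

    def test_too_few_points_rejected(self):
        prof = DielProfile("g", "At", [8, 16, 24], np.ones((3, 1)))
        with pytest.raises(ValidationError):
            ds.interpolate_to_grid(prof, 2.0)


class TestZscore:
    def test_mean_zero_sd_one(self):
        prof = DielProfile("g", "Kf", TIMES, np.arange(1.0, 13.0)[:, None])
        z = ds.zscore(prof).mean_series()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_profile_rejected(self):
        prof = DielProfile("g", "Kf", TIMES, np.full((12, 1), 3.0))
        with pytest.raises(ValidationError):
            ds.zscore(prof)

    def test_affine_invariance(self, rng):
        x = rng.uniform(0, 10, size=12)
        p1 = DielProfile("g", "Kf", TIMES, x[:, None])
        p2 = DielProfile("g", "Kf", TIMES, (3.5 * x + 7.0)[:, None])
        np.testing.assert_allclose(
            ds.zscore(p1).mean_series(), ds.zscore(p2).mean_series(), atol=1e-12
        )


# ---------------------------------------------------------------------------
# Correlation and shifts
# ---------------------------------------------------------------------------


class TestDielSpearman:
    def test_self_correlation_is_one(self, rng):
        p = cosine_profile("g", "Kf", 6.0)
        assert ds.diel_spearman(p, p) == pytest.approx(1.0)

    def test_reversed_monotone_is_minus_one(self, rng):
        x = np.sort(rng.uniform(1, 10, size=12))
        a = DielProfile("a", "Kf", TIMES, x[:, None])
        b = DielProfile("b", "Ac", TIMES, (100.0 - x)[:, None])
        assert ds.diel_spearman(a, b) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(120):
            x = rng.integers(0, 6, size=12).astype(float)  # ties likely
            y = rng.integers(0, 6, size=12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            a = DielProfile("a", "Kf", TIMES, x[:, None])
            b = DielProfile("b", "Ac", TIMES, y[:, None])
            assert ds.diel_spearman(a, b) == pytest.approx(
                spearman_oracle(x, y), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(0.1, 5, size=12)
        y = rng.uniform(0.1, 5, size=12)
        a = DielProfile("a", "Kf", TIMES, x[:, None])
        b = DielProfile("b", "Ac", TIMES, y[:, None])
        b2 = DielProfile("b", "Ac", TIMES, np.exp(y)[:, None])
        assert ds.diel_spearman(a, b) == pytest.approx(ds.diel_spearman(a, b2))

    def test_mismatched_grid_rejected(self):
        a = cosine_profile("a", "Kf", 6.0)
        b = DielProfile("b", "At", [4, 8, 12, 16, 20, 24], np.arange(1.0, 7.0)[:, None])
        with pytest.raises(ValidationError):
            ds.diel_spearman(a, b)


class TestEstimateTimeShift:
    def test_identical_profiles_zero_shift(self):
        a = cosine_profile("a", "Kf", 6.0)
        est = ds.estimate_time_shift(a, a)
        assert est.shift == 0.0
        assert est.peak_correlation == pytest.approx(1.0, abs=1e-9)

    def test_six_hour_delay_recovered(self):
        a = cosine_profile("a", "Kf", 6.0)
        b = cosine_profile("b", "Ac", 12.0)  # peaks 6 h later
        assert ds.estimate_time_shift(a, b).shift == 6.0

    def test_rotation_recovery_all_half_hour_deltas(self):
        a = cosine_profile("a", "Kf", 6.0)
        for delta in np.arange(0.5, 12.5, 0.5):
            b = cosine_profile("b", "Ac", 6.0 + delta)
            assert ds.estimate_time_shift(a, b).shift == delta

    def test_matches_exhaustive_lag_oracle_on_noisy_pairs(self, rng):
        for _ in range(100):
            a = cosine_profile("a", "Kf", rng.uniform(0, 24), noise_sd=0.4, rng=rng)
            b = cosine_profile("b", "Ac", rng.uniform(0, 24), noise_sd=0.4, rng=rng)
            assert ds.estimate_time_shift(a, b).shift == shift_oracle(a, b)

    def test_antisymmetry_modulo_period(self, rng):
        for _ in range(50):
            a = cosine_profile("a", "Kf", rng.uniform(0, 24), noise_sd=0.3, rng=rng)
            b = cosine_profile("b", "Ac", rng.uniform(0, 24), noise_sd=0.3, rng=rng)
            s_ab = ds.estimate_time_shift(a, b).shift
            s_ba = ds.estimate_time_shift(b, a).shift
            assert (s_ab + s_ba) % 24.0 in (0.0, 24.0)

    def test_peak_correlation_at_least_zero_lag(self, rng):
        a = cosine_profile("a", "Kf", 3.0, noise_sd=0.5, rng=rng)
        b = cosine_profile("b", "Ac", 15.0, noise_sd=0.5, rng=rng)
        est = ds.estimate_time_shift(a, b)
        fine = np.arange(0.5, 24.25, 0.5)
        za = ds.periodic_spline_resample(a.times, ds.zscore(a).mean_series(), fine)
        zb = ds.periodic_spline_resample(b.times, ds.zscore(b).mean_series(), fine)
        r0 = np.corrcoef(za, zb)[0, 1]
        assert est.peak_correlation >= r0 - 1e-12


# ---------------------------------------------------------------------------
# Filters, window tests, FDR
# ---------------------------------------------------------------------------


class TestExpressionFilter:
    def _matrix(self, series):
        m = DielMatrix(species="Kf")
        for gid, vals in series.items():
            m.add(DielProfile(gid, "Kf", TIMES, np.asarray(vals)[:, None]))
        return m

    def test_filter_rules(self):
        always = [0.02] * 12
        five = [0.02] * 5 + [0.0] * 7
        boundary = [0.01] * 12
        m = self._matrix({"keep": always, "drop5": five, "dropEq": boundary})
        assert ds.expression_filter(m) == {"keep"}


class TestWindowEnrichment:
    def test_constructed_night_enrichment(self, rng):
        vals = np.ones((12, 3))
        night = [t in (16.0, 18.0, 20.0) for t in TIMES]
        vals[night] = 10.0
        vals += rng.normal(0, 0.01, size=vals.shape)
        prof = DielProfile("g", "Kf", TIMES, np.abs(vals))
        enr = ds.window_enrichment_test(prof)
        assert enr.pvalues["midday_vs_midnight"] < 0.01
        assert enr.larger_window["midday_vs_midnight"] == "midnight"

    def test_identical_windows_not_significant(self, rng):
        prof = DielProfile("g", "Kf", TIMES, np.full((12, 3), 5.0) + rng.normal(0, 1e-6, (12, 3)))
        enr = ds.window_enrichment_test(prof)
        ds.attach_qvalues([enr], 0.01)
        assert enr.enriched_window is None

    def test_welch_formula_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, size=18)
        y = rng.uniform(2, 12, size=18)
        scheme = TimeWindowScheme()
        mid = scheme.mask("midday", TIMES)
        night = scheme.mask("midnight", TIMES)
        m1, m2 = x.mean(), y.mean()
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        n1 = n2 = 18
        t_stat = (m1 - m2) / np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        p_oracle = 2 * stats.t.sf(abs(t_stat), df)
        # the window test pools 3 time points x 6 replicates per side
        vals2 = np.full((12, 6), 5.0)
        vals2[mid] = x.reshape(3, 6)
        vals2[night] = y.reshape(3, 6)
        prof = DielProfile("g", "Kf", TIMES, vals2)
        enr = ds.window_enrichment_test(prof)
        assert enr.pvalues["midday_vs_midnight"] == pytest.approx(p_oracle, rel=1e-10)


class TestBhFdr:
    def test_single_pvalue_identity(self):
        assert ds.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_matches_step_up_oracle(self, rng):
        np.testing.assert_allclose(
            ds.bh_fdr([0.01, 0.02, 0.03, 0.04]),
            bh_oracle([0.01, 0.02, 0.03, 0.04]),
            atol=1e-12,
        )
        for _ in range(100):
            p = rng.uniform(0, 1, size=rng.integers(1, 30))
            np.testing.assert_allclose(ds.bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_all_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(ds.bh_fdr([0.2] * 5), 0.2)

    def test_never_decreases_and_preserves_ranking(self, rng):
        p = rng.uniform(0, 1, size=50)
        q = ds.bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------


def _build_screen_inputs(rng, at_phase=18.0, ac_phase=6.2, extra_at=None):
    """A single ortholog group: Kf/Ac in phase at ~6 h, At elsewhere."""
    profiles = {
        "Kf": {"kf1": cosine_profile("kf1", "Kf", 6.0, amplitude=1.5, reps=3,
                                     noise_sd=0.05, rng=rng)},
        "Ac": {"ac1": cosine_profile("ac1", "Ac", ac_phase, amplitude=1.5, reps=3,
                                     noise_sd=0.05, rng=rng)},
        "At": {"at1": cosine_profile("at1", "At", at_phase, amplitude=1.5, reps=3,
                                     noise_sd=0.05, rng=rng)},
    }
    members = {"Kf": ["kf1"], "Ac": ["ac1"], "At": ["at1"]}
    if extra_at is not None:
        profiles["At"]["at2"] = extra_at
        members["At"].append("at2")
    group = OrthologGroup("OG1", members)
    enrichments = {}
    for sp in profiles:
        enr = [ds.window_enrichment_test(p) for p in profiles[sp].values()]
        ds.attach_qvalues(enr, 0.01)
        enrichments[sp] = {e.gene_id: e for e in enr}
    return group, profiles, enrichments


class TestClassifier:
    def test_planted_triple_is_convergent(self, rng):
        group, profiles, enr = _build_screen_inputs(rng)
        call = ds.classify_convergent_expression(group, profiles, enr, "kf1")
        assert call.criterion1 and call.criterion2 and call.criterion3
        assert call.convergent

    def test_in_phase_c3_ortholog_defeats_criterion1(self, rng):
        extra = cosine_profile("at2", "At", 6.0, amplitude=1.5, reps=3,
                               noise_sd=0.05, rng=rng)
        group, profiles, enr = _build_screen_inputs(rng, extra_at=extra)
        call = ds.classify_convergent_expression(group, profiles, enr, "kf1")
        assert call.r_kf_at_max > 0.8
        assert not call.criterion1
        assert not call.convergent

    def test_large_cam_shift_defeats_criterion3(self, rng):
        group, profiles, enr = _build_screen_inputs(rng, ac_phase=10.5)
        call = ds.classify_convergent_expression(group, profiles, enr, "kf1")
        assert abs(call.shift_kf_ac) > 3.0
        assert not call.criterion3
        assert not call.convergent

    def test_missing_species_not_evaluable(self, rng):
        group, profiles, enr = _build_screen_inputs(rng)
        del profiles["Ac"]["ac1"]
        call = ds.classify_convergent_expression(group, profiles, enr, "kf1")
        assert not call.evaluable
        assert not call.convergent

    def test_verdict_is_conjunction_of_criteria(self, rng):
        group, profiles, enr = _build_screen_inputs(rng)
        call = ds.classify_convergent_expression(group, profiles, enr, "kf1")
        assert call.convergent == (call.criterion1 and call.criterion2 and call.criterion3)


# ---------------------------------------------------------------------------
# Flat-line filter
# ---------------------------------------------------------------------------


class TestFlatlineTest:
    def test_constant_series_not_structured(self):
        assert ds.flatline_test(TIMES, np.full((12, 3), 4.0)) == 1.0

    def test_strong_sinusoid_structured(self):
        counts = np.exp(3 + 2 * np.cos(2 * np.pi * (TIMES - 6) / 24.0))
        assert ds.flatline_test(TIMES, np.tile(counts[:, None], (1, 3))) < 1e-6

    def test_matches_rss_formula_oracle(self, rng):
        counts = rng.uniform(0, 100, size=(12, 3))
        p = ds.flatline_test(TIMES, counts, degree=3)
        t_long = np.repeat(TIMES, 3)
        y = np.log2(counts + 1).ravel()
        coef = np.polyfit(t_long, y, 3)
        rss1 = float(np.sum((y - np.polyval(coef, t_long)) ** 2))
        rss0 = float(np.sum((y - y.mean()) ** 2))
        f = ((rss0 - rss1) / 3) / (rss1 / (36 - 4))
        assert p == pytest.approx(float(stats.f.sf(f, 3, 32)), rel=1e-9)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


class TestClusterProfiles:
    def test_antiphase_groups_separate(self, rng):
        profs = []
        for i in range(4):
            profs.append(cosine_profile(f"day{i}", "Kf", 6.0 + rng.normal(0, 0.3),
                                        noise_sd=0.05, rng=rng))
            profs.append(cosine_profile(f"night{i}", "Kf", 18.0 + rng.normal(0, 0.3),
                                        noise_sd=0.05, rng=rng))
        labels = ds.cluster_profiles(profs, k=2)
        day = {labels[f"day{i}"] for i in range(4)}
        night = {labels[f"night{i}"] for i in range(4)}
        assert len(day) == 1 and len(night) == 1 and day != night

    def test_k_equals_n_singletons(self, rng):
        profs = [cosine_profile(f"g{i}", "Kf", 3.0 * i + 1, noise_sd=0.1, rng=rng)
                 for i in range(5)]
        labels = ds.cluster_profiles(profs, k=5)
        assert len(set(labels.values())) == 5

    def test_k_larger_than_n_rejected(self, rng):
        profs = [cosine_profile(f"g{i}", "Kf", 6.0) for i in range(2)]
        with pytest.raises(ValidationError):
            ds.cluster_profiles(profs, k=3)

    def test_merge_order_matches_naive_linkage(self, rng):
        profs = [cosine_profile(f"g{i}", "Kf", rng.uniform(0, 24),
                                noise_sd=0.3, rng=rng) for i in range(5)]
        profs.sort(key=lambda p: p.gene_id)
        n = len(profs)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = 1 - ds.diel_spearman(profs[i], profs[j])
        Z = ds.linkage_matrix(profs)
        assert_valid_greedy_average_linkage(dist, Z)


# ---------------------------------------------------------------------------
# Triangle networks
# ---------------------------------------------------------------------------


def _call_with_windows(kf_w, ac_w, at_w):
    def enr(gene, sp, w):
        e = ds.WindowEnrichment(gene_id=gene, species=sp, window_means={},
                                pvalues={}, larger_window={})
        e.enriched_window = w
        return e

    call = ds.ExpressionConvergenceCall(kf_gene="kf1", group_id="OG1")
    call.best_ac_gene, call.best_at_gene = "ac1", "at1"
    call.shift_kf_ac, call.shift_kf_at, call.shift_ac_at = 1.0, 11.0, 10.0
    call.kf_enrichment = enr("kf1", "Kf", kf_w)
    call.ac_enrichment = enr("ac1", "Ac", ac_w)
    call.at_enrichment = enr("at1", "At", at_w)
    return call


class TestTriangleNetwork:
    def test_same_window_cam_opposite_c3_emits_triangle(self):
        edges = ds.build_triangle_network([_call_with_windows("midnight", "midnight", "midday")])
        assert len(edges) == 3
        assert {(e.species_a, e.species_b) for e in edges} == {
            ("Kf", "Ac"), ("Kf", "At"), ("Ac", "At")
        }

    def test_cam_window_mismatch_no_triangle(self):
        assert ds.build_triangle_network(
            [_call_with_windows("midnight", "dawn", "midday")]) == []

    def test_non_opposite_c3_window_no_triangle(self):
        assert ds.build_triangle_network(
            [_call_with_windows("midnight", "midnight", "dusk")]) == []
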