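"""Panel preparation, FastICA decomposition, canonicalization, restart
stability, and the participant-offset diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phenofuse.ica import (
    canonicalize,
    center_within_participant,
    component_offset_correlation,
    fit_ica,
    match_components,
    prepare_panel,
    restart_stability,
)


def make_panel(values, pids, dates, items=None):
    values = np.asarray(values, dtype=float)
    items = items or [f"item_{i+1:02d}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=items)
    df.insert(0, "participant_id", pids)
    df.insert(1, "date", dates)
    return df


def laplace_sources(q, n, rng):
    s = rng.laplace(0, 1 / np.sqrt(2), size=(q, n))
    return (s - s.mean(axis=1, keepdims=True)) / s.std(axis=1, keepdims=True)


def exhaustive_match(A_est, A_ref):
    """Independent oracle for small q: try every permutation and sign."""
    q = A_ref.shape[1]

    def col_corr(a, b):
        return np.corrcoef(a, b)[0, 1]

    best = None
    for perm in itertools.permutations(range(q)):
        corrs = [abs(col_corr(A_est[:, perm[j]], A_ref[:, j])) for j in range(q)]
        score = sum(corrs)
        if best is None or score > best[0]:
            best = (score, perm, corrs)
    return best[1], best[2]


class TestPreparePanel:
    def test_log_transform_and_concatenation(self):
        panel = make_panel(
            [[1, 2]] * 3 + [[4, 8]] * 3,
            pids=["A"] * 3 + ["B"] * 3,
            dates=pd.date_range("2023-01-02", periods=3).tolist() * 2,
        )
        conc = prepare_panel(panel)
        assert conc.X.shape == (2, 6)
        assert len(conc.index_map) == 6
        assert conc.X[0, 0] == pytest.approx(np.log(1)) == 0.0
        assert conc.X[1, 3] == pytest.approx(np.log(8))

    def test_incomplete_day_dropped(self):
        panel = make_panel(
            [[1, 2], [3, np.nan], [2, 2]],
            pids=["A"] * 3,
            dates=pd.date_range("2023-01-02", periods=3),
        )
        conc = prepare_panel(panel)
        assert conc.n == 2

    def test_nonpositive_value_located(self):
        panel = make_panel(
            [[1, 2], [0, 2]],
            pids=["A", "A"],
            dates=pd.date_range("2023-01-02", periods=2),
        )
        with pytest.raises(ValueError, match="item_01"):
            prepare_panel(panel)

    def test_duplicate_participant_day_rejected(self):
        panel = make_panel(
            [[1, 2], [1, 2]], pids=["A", "A"], dates=["2023-01-02"] * 2
        )
        with pytest.raises(ValueError, match="duplicate"):
            prepare_panel(panel)


class TestFitICA:
    def test_full_rank_decomposition_is_exact(self, rng):
        """With as many components as items the residual vanishes."""
        q = p = 5
        S = laplace_sources(q, 400, rng)
        A = rng.normal(size=(p, q))
        X = A @ S
        dec = fit_ica(X, q=p, seed=0)
        assert np.linalg.norm(dec.epsilon) < 1e-8
        assert np.allclose(dec.reconstruct(), X, atol=1e-8)

    def test_mixing_matrix_recovery_with_noise(self, rng):
        """10 items, 3 Laplace sources, n=2000, noise SD 0.1: every matched
        column correlates >= 0.95 with the truth (exhaustive-search match)."""
        p, q, n = 10, 3, 2000
        S = laplace_sources(q, n, rng)
        A = rng.normal(size=(p, q)) + np.sign(rng.normal(size=(p, q)))
        X = A @ S + rng.normal(0, 0.1, size=(p, n))
        dec = fit_ica(X, q=q, seed=1)
        _, corrs = exhaustive_match(dec.A, A)
        assert min(corrs) >= 0.95

    def test_hungarian_matcher_agrees_with_exhaustive_search(self, rng):
        A_ref = rng.normal(size=(8, 3))
        perm = [2, 0, 1]
        signs = np.array([1.0, -1.0, 1.0])
        A_est = A_ref[:, perm] * signs + rng.normal(0, 0.05, size=(8, 3))
        got_perm, _, got_corrs = match_components(A_est, A_ref)
        exp_perm, exp_corrs = exhaustive_match(A_est, A_ref)
        assert list(got_perm) == list(exp_perm)
        assert np.allclose(sorted(got_corrs), sorted(exp_corrs), atol=1e-12)

    def test_gaussian_data_still_returns_with_diagnostics(self, rng):
        X = rng.normal(size=(4, 300))
        dec = fit_ica(X, q=2, seed=0, max_iter=30)
        assert "converged" in dec.meta and "n_iter" in dec.meta

    def test_q_out_of_range_rejected(self, rng):
        X = rng.normal(size=(4, 50))
        with pytest.raises(ValueError, match="out of range"):
            fit_ica(X, q=5)

    def test_rank_deficient_data_rejected(self, rng):
        row = rng.normal(size=300)
        X = np.vstack([row, 2 * row, 3 * row])
        with pytest.raises(ValueError, match="rank"):
            fit_ica(X, q=3)

    def test_seeded_determinism(self, rng):
        X = laplace_sources(3, 500, rng)
        X = rng.normal(size=(6, 3)) @ X
        A1 = fit_ica(X, q=3, seed=42).A
        A2 = fit_ica(X, q=3, seed=42).A
        assert np.linalg.norm(A1 - A2) < 1e-8

    def test_residual_norm_nonincreasing_in_q(self, rng):
        p, n = 6, 800
        S = laplace_sources(p, n, rng)
        X = (rng.normal(size=(p, p)) + np.eye(p)) @ S
        norms = [
            np.linalg.norm(fit_ica(X, q=q, seed=0).epsilon) for q in range(2, p + 1)
        ]
        # tolerate optimizer noise but require the overall trend
        assert all(b <= a + 1e-6 * (1 + a) + 0.05 * norms[0] for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-8


class TestCanonicalize:
    def _dec(self, rng, q=3, p=6, n=400):
        S = laplace_sources(q, n, rng)
        X = rng.normal(size=(p, q)) @ S + rng.normal(0, 0.05, size=(p, n))
        return fit_ica(X, q=q, seed=0)

    def test_idempotent(self, rng):
        dec = self._dec(rng)
        again = canonicalize(dec)
        assert np.allclose(again.A, dec.A, atol=1e-10)
        assert np.allclose(again.S, dec.S, atol=1e-10)

    def test_sign_and_order_invariance(self, rng):
        dec = self._dec(rng)
        twisted = canonicalize(dec)
        twisted.A = twisted.A[:, ::-1].copy()
        twisted.S = twisted.S[::-1, :].copy()
        twisted.A[:, 1] *= -1
        twisted.S[1, :] *= -1
        back = canonicalize(twisted)
        assert np.allclose(back.A, dec.A, atol=1e-10)

    def test_product_unchanged_and_sources_unit_variance(self, rng):
        dec = self._dec(rng)
        assert np.allclose(dec.S.std(axis=1), 1.0, atol=1e-10)
        raw = dec.A @ dec.S
        again = canonicalize(dec)
        assert np.allclose(again.A @ again.S, raw, atol=1e-10)
        for col in range(dec.A.shape[1]):
            assert dec.A[np.argmax(np.abs(dec.A[:, col])), col] > 0


class TestRestartStability:
    def test_identical_seeds_fully_similar(self, rng):
        X = rng.normal(size=(5, 3)) @ laplace_sources(3, 600, rng)
        a = fit_ica(X, q=3, seed=9).A
        b = fit_ica(X, q=3, seed=9).A
        sim = np.abs(np.corrcoef(np.hstack([a, b]).T))
        for j in range(3):
            assert sim[j, 3 + j] == pytest.approx(1.0, abs=1e-8)

    def test_well_separated_sources_cluster_across_restarts(self, rng):
        q, n = 3, 1500
        S = laplace_sources(q, n, rng)
        A = np.array(
            [[1.0, 0.1, 0.0], [0.9, 0.0, 0.1], [0.0, 1.0, 0.1],
             [0.1, 0.9, 0.0], [0.0, 0.1, 1.0], [0.1, 0.0, 0.9]]
        )
        X = A @ S + rng.normal(0, 0.05, size=(6, n))
        rep = restart_stability(X, q=q, n_restarts=10, base_seed=0)
        sizes = sorted(rep.cluster_sizes().values(), reverse=True)
        assert len(rep.clusters) <= 10 * q
        assert len(sizes) >= 3
        assert all(s >= 9 for s in sizes[:3])
        big = [c for c, s in rep.cluster_sizes().items() if s >= 9]
        assert all(rep.cluster_tightness[c] > 0.9 for c in big)

    def test_requires_two_restarts(self, rng):
        X = rng.normal(size=(4, 100))
        with pytest.raises(ValueError):
            restart_stability(X, q=2, n_restarts=1)


class TestCentring:
    def _conc(self, rng, offsets=None, n_pid=6, days=30, p=5):
        pids, dates, rows = [], [], []
        for i in range(n_pid):
            off = 0.0 if offsets is None else offsets[i]
            for d in range(days):
                pids.append(f"P{i}")
                dates.append(pd.Timestamp("2023-01-02") + pd.Timedelta(days=d))
                rows.append(np.exp(off + rng.normal(0.5, 0.2, size=p)))
        return prepare_panel(make_panel(rows, pids, dates))

    def test_participant_item_series_sum_to_zero(self, rng):
        conc = self._conc(rng)
        cen = center_within_participant(conc)
        pids = cen.index_map["participant_id"].to_numpy()
        for pid in np.unique(pids):
            cols = np.flatnonzero(pids == pid)
            assert np.allclose(cen.X[:, cols].sum(axis=1), 0.0, atol=1e-10)

    def test_single_day_participant_becomes_zero(self, rng):
        conc = self._conc(rng, days=1)
        cen = center_within_participant(conc)
        assert np.allclose(cen.X, 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        conc = self._conc(rng)
        once = center_within_participant(conc)
        twice = center_within_participant(once)
        assert np.allclose(once.X, twice.X, atol=1e-12)

    def test_centring_removes_planted_offset_component(self, rng):
        """A component that encodes stable participant offsets must vanish
        once participants are mean-centred: no refit component should then
        correlate strongly with the participant mean-response pattern."""
        p, n_pid, days = 6, 12, 40
        offsets = rng.normal(0, 1.0, size=n_pid)
        pids, dates, rows = [], [], []
        daily = rng.laplace(0, 0.25, size=(n_pid, days, p))
        for i in range(n_pid):
            for d in range(days):
                log_vals = 1.0 + offsets[i] * 0.5 + daily[i, d]
                pids.append(f"P{i:02d}")
                dates.append(pd.Timestamp("2023-01-02") + pd.Timedelta(days=d))
                rows.append(np.exp(log_vals))
        conc = prepare_panel(make_panel(rows, pids, dates))
        dec = fit_ica(conc, q=3, seed=0)
        offset_corrs = [
            abs(component_offset_correlation(dec, conc, k)) for k in range(3)
        ]
        assert max(offset_corrs) > 0.9  # the offset component exists
        cen = center_within_participant(conc)
        dec2 = fit_ica(cen.X, q=3, seed=0)
        # correlate against the *uncentred* mean responses: the centred
        # panel's participant means are identically zero by construction
        centred_corrs = [
            abs(component_offset_correlation(dec2, conc, k)) for k in range(3)
        ]
        assert max(centred_corrs) < 0.5


class TestOffsetCorrelation:
    def _setup(self, rng):
        p, n_pid, days = 4, 8, 25
        pids, dates, rows = [], [], []
        for i in range(n_pid):
            for d in range(days):
                pids.append(f"P{i}")
                dates.append(pd.Timestamp("2023-01-02") + pd.Timedelta(days=d))
                rows.append(np.exp(rng.normal(0.6 + 0.3 * i / n_pid, 0.2, size=p)))
        conc = prepare_panel(make_panel(rows, pids, dates))
        dec = fit_ica(conc, q=2, seed=0)
        return conc, dec

    def test_self_correlation_is_one(self, rng):
        conc, dec = self._setup(rng)
        pids = conc.index_map["participant_id"].to_numpy()
        means = {p: conc.X[:, pids == p].mean() for p in np.unique(pids)}
        dec.S[0] = np.array([means[p] for p in pids])
        assert component_offset_correlation(dec, conc, 0) == pytest.approx(1.0)

    def test_sign_antisymmetry(self, rng):
        conc, dec = self._setup(rng)
        c = component_offset_correlation(dec, conc, 0)
        dec.S[0] *= -1
        assert component_offset_correlation(dec, conc, 0) == pytest.approx(-c)

    def test_orthogonalized_component_uncorrelated(self, rng):
        conc, dec = self._setup(rng)
        pids = conc.index_map["participant_id"].to_numpy()
        pattern = np.array(
            [conc.X[:, pids == p].mean() for p in pids]
        )
        s = dec.S[0] - np.polyval(np.polyfit(pattern, dec.S[0], 1), pattern)
        dec.S[0] = s
        assert abs(component_offset_correlation(dec, conc, 0)) < 0.15

    def test_too_few_participants_rejected(self, rng):
        p = 3
        panel = make_panel(
            np.exp(rng.normal(0.5, 0.2, size=(8, p))),
            pids=["A"] * 4 + ["B"] * 4,
            dates=list(pd.date_range("2023-01-02", periods=4)) * 2,
        )
        conc = prepare_panel(panel)
        dec = fit_ica(conc, q=2, seed=0)
        with pytest.raises(ValueError, match="participants"):
            component_offset_correlation(dec, conc, 0)
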