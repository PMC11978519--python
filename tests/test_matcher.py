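"""Threshold, drift estimation, naive Bayes classifier, full pipeline."""

import copy

import numpy as np
import pytest

from unitmatch.config import MatchConfig
from unitmatch.features import extract_all
from unitmatch.matching import (
    BayesModel,
    MatchingError,
    UnitMatcher,
    estimate_drift,
    find_threshold,
    fit_bayes_model,
    fit_from_features,
    match_probability,
    match_probability_matrix,
    putative_matches,
)
from unitmatch.similarity import ScoreMatrices


def make_total(self_vals, neigh_vals, positions=None):
    """Build a total-score matrix with given diagonal and neighbor values."""
    n = len(self_vals)
    total = np.zeros((n, n))
    np.fill_diagonal(total, self_vals)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            total[i, j] = total[j, i] = neigh_vals[k % len(neigh_vals)]
            k += 1
    return total


class TestFindThreshold:
    def test_separated_distributions(self):
        n = 12
        total = make_total([0.9] * n, [0.3])
        cdist = np.zeros((n, n))  # everyone is everyone's neighbor
        thr = find_threshold(total, cdist, np.zeros(n, dtype=int))
        assert 0.3 < thr.threshold < 0.9

    def test_mean_equalisation_adjustment(self):
        # within-session values fixed; across-session distribution shifted
        # down by exactly 0.1 -> threshold lowered by 0.1
        rng = np.random.default_rng(0)
        n = 40
        sids = np.array([0] * (n // 2) + [1] * (n // 2))
        total = np.zeros((n, n))
        within_vals = rng.uniform(0.4, 0.9, size=n)
        np.fill_diagonal(total, within_vals)
        same = sids[:, None] == sids[None, :]
        off = ~np.eye(n, dtype=bool)
        total[same & off] = 0.5
        total[~same] = 0.4  # across candidates shifted down
        cdist = np.zeros((n, n))
        thr = find_threshold(total, cdist, sids)
        within = np.concatenate([within_vals, total[same & off]])
        expect = -(within.mean() - 0.4)
        assert thr.adjustment == pytest.approx(expect)
        assert thr.threshold == pytest.approx(
            max(0.0, thr.base_threshold + expect)
        )
        assert thr.adjustment <= 0

    def test_no_neighbors_falls_back_to_quantile(self):
        n = 6
        total = np.eye(n) * 0.8
        cdist = np.full((n, n), 1e3)  # nobody within 50 um
        thr = find_threshold(total, cdist, np.zeros(n, dtype=int))
        assert "no_neighbor_pairs" in thr.flags
        assert thr.base_threshold == pytest.approx(0.8)

    def test_gap_midpoint_for_separated_histograms(self):
        # self mass at 1.0, neighbors at 0.40 -> threshold mid-gap, so a
        # stray pair at e.g. 0.6 cannot enter the putative-match class
        n = 30
        total = make_total([1.0] * n, [0.40])
        cdist = np.zeros((n, n))
        thr = find_threshold(total, cdist, np.zeros(n, dtype=int))
        assert 0.6 < thr.base_threshold < 1.0

    def test_matches_bin_scan_oracle_on_overlap(self):
        rng = np.random.default_rng(1)
        n = 60
        self_vals = rng.normal(0.8, 0.07, n).clip(0, 1)
        neigh_vals = rng.normal(0.45, 0.12, 300).clip(0, 1)
        total = make_total(self_vals, list(neigh_vals))
        cdist = np.zeros((n, n))
        cfg = MatchConfig()
        thr = find_threshold(total, cdist, np.zeros(n, dtype=int), cfg)
        # independent bin-scan on identically smoothed histograms
        edges = np.linspace(0, 1, cfg.n_bins + 1)
        neigh_mask = ~np.eye(n, dtype=bool)
        ds, _ = np.histogram(np.diag(total), bins=edges, density=True)
        dn, _ = np.histogram(total[neigh_mask], bins=edges, density=True)
        kernel = np.ones(cfg.smooth_bins) / cfg.smooth_bins
        ds = np.convolve(ds, kernel, "same")
        dn = np.convolve(dn, kernel, "same")
        expect = 0.0
        for b in range(cfg.n_bins - 1, -1, -1):
            if dn[b] > ds[b]:
                lower = edges[b + 1]
                upper = lower
                for g in range(b + 1, cfg.n_bins):
                    if ds[g] > 0:
                        upper = edges[g]
                        break
                expect = (lower + max(upper, lower)) / 2
                break
        assert thr.base_threshold == pytest.approx(expect)


class TestPutativeMatches:
    def test_strict_inequality_at_boundary(self):
        total = np.array([[0.5, 0.2], [0.2, 0.7]])
        m = putative_matches(total, 0.5)
        assert not m[0, 0] and m[1, 1]

    def test_elementwise_comparison(self, rng):
        total = rng.uniform(size=(15, 15))
        np.testing.assert_array_equal(putative_matches(total, 0.4), total > 0.4)


class TestDriftEstimate:
    def test_noisy_shift_matches_median_oracle(self, rng):
        n = 50
        early = rng.uniform(0, 500, size=(n, 2))
        shift = np.array([3.0, -12.0])
        late = early + shift + rng.normal(scale=2.0, size=(n, 2))
        centroids = np.vstack([early, late])
        sids = np.array([0] * n + [1] * n)
        putative = np.zeros((2 * n, 2 * n), dtype=bool)
        putative[np.arange(n), np.arange(n) + n] = True
        est = estimate_drift(centroids, sids, putative, [0, 1])
        expect = np.median(late - early, axis=0)
        np.testing.assert_allclose(est.displacement[(0, 1)], expect)
        assert est.n_matches[(0, 1)] == n

    def test_no_matches_flagged_zero(self):
        centroids = np.zeros((4, 2))
        sids = np.array([0, 0, 1, 1])
        est = estimate_drift(centroids, sids, np.zeros((4, 4), bool), [0, 1])
        np.testing.assert_array_equal(est.displacement[(0, 1)], 0.0)
        assert est.flags


def random_scores(rng, n):
    mats = {}
    for name in ("amplitude", "decay", "waveform", "centroid", "volatility", "route"):
        m = rng.uniform(size=(n, n))
        mats[name] = (m + m.T) / 2
    total = np.mean(list(mats.values()), axis=0)
    return ScoreMatrices(
        **mats, total=total, unit_ids=np.arange(n), session_ids=np.zeros(n, int)
    )


class TestBayesModel:
    def test_histogram_oracle(self, rng):
        cfg = MatchConfig()
        scores = random_scores(rng, 20)
        putative = rng.uniform(size=(20, 20)) > 0.6
        putative = putative | putative.T
        model = fit_bayes_model(scores, putative, cfg)
        iu = np.triu_indices(20)
        labels = putative[iu]
        edges = np.linspace(0, 1, 101)
        for name, mat in scores.as_dict().items():
            vals = mat[iu]
            for dens, mask in (
                (model.density_match[name], labels),
                (model.density_nonmatch[name], ~labels),
            ):
                counts, _ = np.histogram(vals[mask], bins=edges)
                smoothed = np.convolve(counts.astype(float), np.ones(3) / 3, "same")
                expect = smoothed / (smoothed.sum() * 0.01)
                expect = np.maximum(expect, 1e-6)
                expect = expect / (expect.sum() * 0.01)
                np.testing.assert_allclose(dens, expect)
                assert dens.min() > 0
                assert dens.sum() * 0.01 == pytest.approx(1.0)

    def test_empty_class_raises(self, rng):
        scores = random_scores(rng, 10)
        with pytest.raises(MatchingError):
            fit_bayes_model(scores, np.zeros((10, 10), bool))

    def test_prior_modes(self, rng):
        scores = random_scores(rng, 16)
        putative = np.eye(16, dtype=bool)
        emp = fit_bayes_model(scores, putative, MatchConfig(prior_mode="empirical"))
        iu = np.triu_indices(16)
        assert emp.prior_match == pytest.approx(16 / iu[0].size)
        flat = fit_bayes_model(scores, putative, MatchConfig(prior_mode="flat"))
        assert flat.prior_match == 0.5


def random_bayes_model(rng, n_bins=100):
    edges = np.linspace(0, 1, n_bins + 1)
    width = 1 / n_bins

    def dens():
        d = rng.uniform(0.01, 1, size=n_bins)
        return d / (d.sum() * width)

    names = ["amplitude", "decay", "waveform", "centroid", "volatility", "route"]
    return BayesModel(
        bin_edges=edges,
        density_match={k: dens() for k in names},
        density_nonmatch={k: dens() for k in names},
        prior_match=float(rng.uniform(0.05, 0.95)),
    )


class TestMatchProbability:
    def test_identical_densities_give_half(self, rng):
        model = random_bayes_model(rng)
        model.density_nonmatch = {k: v.copy() for k, v in model.density_match.items()}
        model.prior_match = 0.5
        assert match_probability(model, np.full(6, 0.37)) == pytest.approx(0.5)

    def test_likelihood_ratio_nine_gives_point_nine(self):
        edges = np.linspace(0, 1, 2 + 1)
        names = ["amplitude", "decay", "waveform", "centroid", "volatility", "route"]
        # per-score LR at the top bin: 9^(1/6); product over six scores = 9
        hi, lo = 9 ** (1 / 6), 1.0
        zm = np.array([2 - hi, hi])
        zn = np.array([2 - lo, lo])
        model = BayesModel(
            bin_edges=edges,
            density_match={k: zm.copy() for k in names},
            density_nonmatch={k: zn.copy() for k in names},
            prior_match=0.5,
        )
        assert match_probability(model, np.full(6, 0.9)) == pytest.approx(0.9)

    def test_transcription_oracle(self, rng):
        """Exact naive Bayes posterior over 1,000 random models/inputs."""
        for _ in range(1000):
            model = random_bayes_model(rng, n_bins=20)
            x = rng.uniform(size=6)
            got = match_probability(model, x)
            idx = np.minimum((x * 20).astype(int), 19)
            p1 = model.prior_match
            for name, i in zip(model.density_match, idx):
                p1 *= model.density_match[name][i]
            p0 = 1 - model.prior_match
            for name, i in zip(model.density_nonmatch, idx):
                p0 *= model.density_nonmatch[name][i]
            expect = p1 / (p1 + p0)
            assert abs(got - expect) < 1e-10

    def test_matrix_path_equals_scalar_path(self, rng):
        model = random_bayes_model(rng)
        scores = random_scores(rng, 8)
        mat = match_probability_matrix(model, scores)
        vec = {k: v[2, 5] for k, v in scores.as_dict().items()}
        assert mat[2, 5] == pytest.approx(match_probability(model, vec), abs=1e-12)

    def test_posterior_monotone_under_monotone_likelihood_ratio(self):
        """Sweep each score's bins: if every score's match/nonmatch density
        ratio increases with the score, the posterior must too."""
        n_bins = 20
        edges = np.linspace(0, 1, n_bins + 1)
        names = ["amplitude", "decay", "waveform", "centroid", "volatility", "route"]
        ramp_up = np.linspace(0.2, 2.0, n_bins)
        ramp_dn = ramp_up[::-1].copy()
        width = 1 / n_bins
        model = BayesModel(
            bin_edges=edges,
            density_match={k: ramp_up / (ramp_up.sum() * width) for k in names},
            density_nonmatch={k: ramp_dn / (ramp_dn.sum() * width) for k in names},
            prior_match=0.3,
        )
        centers = (edges[:-1] + edges[1:]) / 2
        for k in range(6):
            base = np.full(6, 0.5)
            post = []
            for c in centers:
                x = base.copy()
                x[k] = c
                post.append(match_probability(model, x))
            assert np.all(np.diff(post) >= -1e-12)


@pytest.fixture(scope="module")
def duplicated_fit(duplicated_session_set):
    ss = duplicated_session_set
    matcher = UnitMatcher(ss.all_records, ss.geometry, sessions=ss.sessions)
    return ss, matcher.fit()


class TestPipeline:
    def test_duplicated_session_recovers_every_unit(self, duplicated_fit):
        ss, res = duplicated_fit
        P = res.posteriors
        sids = res.session_ids
        u2n = {
            (r.session_id, r.unit_id): r.neuron_id
            for r in ss.truth.itertuples(index=False)
        }
        nid = np.array([u2n[(s, u)] for s, u in zip(sids, res.unit_ids)])
        same = nid[:, None] == nid[None, :]
        cross = sids[:, None] != sids[None, :]
        assert P[cross & same].min() > 0.5
        assert (P[cross & ~same] > 0.5).sum() == 0
        # well-separated units are never confused
        pos = {
            r.neuron_id: np.array([r.x, r.y])
            for r in ss.truth[ss.truth.session_id == 0].itertuples(index=False)
        }
        xy = np.array([pos[k] for k in nid])
        far = cross & ~same & (
            np.linalg.norm(xy[:, None] - xy[None, :], axis=2) > 50
        )
        assert P[far].max() < 0.5

    def test_summary_and_match_table(self, duplicated_fit):
        ss, res = duplicated_fit
        text = res.summary()
        assert "threshold" in text and "sessions: 2" in text
        table = res.match_table
        n = res.scores.n_units
        assert len(table) == n * (n + 1) // 2
        assert table["match_probability"].between(0, 1).all()

    def test_translation_equivariance_exact(self, duplicated_session_set):
        """Rigidly translating one session's positions changes no posterior
        after drift correction."""
        ss = duplicated_session_set
        feats = extract_all(ss.all_records, ss.geometry)
        uids = np.array([r.unit_id for r in ss.all_records])
        sids = np.array([r.session_id for r in ss.all_records])
        delta = np.array([0.0, 15.0])
        shifted = []
        for (f0, f1), s in zip(feats, sids):
            if s == 1:
                f0, f1 = copy.deepcopy(f0), copy.deepcopy(f1)
                for f in (f0, f1):
                    f.centroid_traj = f.centroid_traj + delta
                    f.avg_centroid = f.avg_centroid + delta
            shifted.append((f0, f1))
        r0 = fit_from_features(feats, uids, sids)
        r1 = fit_from_features(shifted, uids, sids)
        np.testing.assert_allclose(
            r1.drift.displacement[(0, 1)], delta, atol=1e-9
        )
        np.testing.assert_allclose(r1.posteriors, r0.posteriors, atol=1e-6)

    def test_single_session_runs(self, small_geometry, rng):
        from conftest import random_waveform
        from unitmatch.io import WaveformRecord

        records = []
        for u in range(6):
            wf = random_waveform(np.random.default_rng(u))
            noisy = np.stack([wf, wf], axis=2) + 0.2 * rng.standard_normal((82, 24, 2))
            records.append(
                WaveformRecord(unit_id=u, session_id=0, waveform=noisy)
            )
        res = UnitMatcher(records, small_geometry).fit()
        assert res.drift.displacement == {}
        assert res.posteriors.shape == (6, 6)
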