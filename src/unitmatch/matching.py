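"""Matching pipeline: threshold, drift correction, naive Bayes posterior.

The pipeline runs in five steps: (1) extract waveform features per half,
(2) score all pairs on six similarities, (3) find a putative-match
threshold on the total score from within-session cross-validation (same
unit across halves vs neighboring units), (4) estimate rigid
across-session drift from the putative matches and rescore/rethreshold
once, (5) fit per-score class-conditional densities for putative matches
and nonmatches and emit the naive Bayes posterior for every pair.

`UnitMatcher` is the model object (built from waveform records and probe
geometry); `UnitMatcher.fit()` returns a `MatchResults` carrying the
posterior matrix, the fitted threshold/drift/classifier and summary and
tracking methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import MatchConfig
from .features import WaveformFeatures, extract_all
from .io import (
    MATCH_COLUMNS,
    ProbeGeometry,
    SessionInfo,
    WaveformRecord,
    read_site_positions,
    read_waveform_store,
    write_results,
)
from .similarity import ScoreMatrices, centroid_distance_matrix, compute_scores


class MatchingError(RuntimeError):
    """Pipeline cannot proceed (e.g. an empty training class)."""


@dataclass
class ThresholdModel:
    """Putative-match threshold on the total similarity score."""

    threshold: float               # final threshold after adjustment
    base_threshold: float          # crossing-point estimate
    within_mean: float             # Gaussian-fit mean, within-session T
    across_mean: float             # Gaussian-fit mean, across-session T
    adjustment: float              # shift applied (<= 0)
    flags: set = field(default_factory=set)


@dataclass
class DriftEstimate:
    """Rigid per-session-pair displacement, later relative to earlier."""

    displacement: dict[tuple[int, int], np.ndarray]
    n_matches: dict[tuple[int, int], int]
    flags: set = field(default_factory=set)

    def get(self, key, default=None):
        return self.displacement.get(key, default)


@dataclass
class BayesModel:
    """Binned class-conditional score densities plus the match prior."""

    bin_edges: np.ndarray                       # shared, on [0, 1]
    density_match: dict[str, np.ndarray]        # per score, sums*width = 1
    density_nonmatch: dict[str, np.ndarray]
    prior_match: float

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1


def find_threshold(
    total: np.ndarray,
    centroid_dist: np.ndarray,
    session_ids: np.ndarray,
    config: MatchConfig | None = None,
) -> ThresholdModel:
    """Locate the total-score threshold separating same-unit from neighbor
    pairs within sessions, then lower it to equalise the within- and
    across-session score means (compensating mean across-day degradation,
    e.g. from uncorrected drift).

    The crossing point is found on shared (smoothed) histograms over
    [0, 1]: scanning from 1 downward, the crossing is the upper boundary
    of the first bin in which the neighbor-pair density exceeds the
    same-unit density.  When the two distributions are separated by a
    zero-density gap, every point of the gap is a crossing; the gap
    midpoint is taken.

    ``centroid_dist`` is the pairwise distance between average centroids
    (drift-corrected where a drift estimate is available), used both for
    the 50-um neighborhood and for across-session candidate pairs.
    """
    cfg = config or MatchConfig()
    flags: set = set()
    n = total.shape[0]
    session_ids = np.asarray(session_ids)
    cdist = np.asarray(centroid_dist)
    same_session = session_ids[:, None] == session_ids[None, :]
    off_diag = ~np.eye(n, dtype=bool)
    neighbor = same_session & off_diag & (cdist < cfg.neighbor_radius_um)

    self_T = np.diag(total)
    neigh_T = total[neighbor]
    if self_T.size == 0:
        raise MatchingError("no within-session self pairs")

    edges = np.linspace(0.0, 1.0, cfg.n_bins + 1)
    if neigh_T.size == 0:
        flags.add("no_neighbor_pairs")
        base = float(np.quantile(self_T, 0.05))
    else:
        dens_self, _ = np.histogram(self_T, bins=edges, density=True)
        dens_neigh, _ = np.histogram(neigh_T, bins=edges, density=True)
        if cfg.smooth_bins > 1:
            kernel = np.ones(cfg.smooth_bins) / cfg.smooth_bins
            dens_self = np.convolve(dens_self, kernel, mode="same")
            dens_neigh = np.convolve(dens_neigh, kernel, mode="same")
        base = float(edges[0])
        for b in range(cfg.n_bins - 1, -1, -1):
            if dens_neigh[b] > dens_self[b]:
                lower = float(edges[b + 1])
                upper = lower
                for g in range(b + 1, cfg.n_bins):
                    if dens_self[g] > 0:
                        upper = float(edges[g])
                        break
                base = (lower + max(upper, lower)) / 2.0
                break

    within_vals = np.concatenate([self_T, neigh_T])
    across = ~same_session & (cdist < cfg.neighbor_radius_um)
    across_vals = total[across]
    within_mean = float(stats.norm.fit(within_vals)[0])
    if across_vals.size:
        across_mean = float(stats.norm.fit(across_vals)[0])
        adjustment = -max(0.0, within_mean - across_mean)
    else:
        across_mean = np.nan
        adjustment = 0.0
        flags.add("no_across_candidates")

    return ThresholdModel(
        threshold=max(0.0, base + adjustment),
        base_threshold=base,
        within_mean=within_mean,
        across_mean=across_mean,
        adjustment=adjustment,
        flags=flags,
    )


def putative_matches(total: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean putative-match matrix: strictly above threshold."""
    return total > threshold


def estimate_drift(
    centroids: np.ndarray,
    session_ids: np.ndarray,
    putative: np.ndarray,
    session_order: list[int],
) -> DriftEstimate:
    """Median centroid displacement per ordered session pair.

    For each (earlier, later) session pair, the displacement is the
    componentwise median of ``c*_later - c*_earlier`` over putative
    across-session matches.  Pairs without any putative match get zero
    displacement and a flag.
    """
    session_ids = np.asarray(session_ids)
    displacement: dict[tuple[int, int], np.ndarray] = {}
    counts: dict[tuple[int, int], int] = {}
    flags: set = set()
    for a_idx in range(len(session_order)):
        for b_idx in range(a_idx + 1, len(session_order)):
            sa, sb = session_order[a_idx], session_order[b_idx]
            in_a = np.flatnonzero(session_ids == sa)
            in_b = np.flatnonzero(session_ids == sb)
            if in_a.size == 0 or in_b.size == 0:
                continue
            sub = putative[np.ix_(in_a, in_b)]
            ii, jj = np.nonzero(sub)
            if ii.size == 0:
                displacement[(sa, sb)] = np.zeros(2)
                counts[(sa, sb)] = 0
                flags.add(f"no_putative_matches_{sa}_{sb}")
                continue
            delta = centroids[in_b[jj]] - centroids[in_a[ii]]
            displacement[(sa, sb)] = np.median(delta, axis=0)
            counts[(sa, sb)] = int(ii.size)
    return DriftEstimate(displacement=displacement, n_matches=counts, flags=flags)


def _smooth_density(
    counts: np.ndarray, width: float, smooth_bins: int, floor: float
) -> np.ndarray:
    dens = counts.astype(float)
    if dens.sum() == 0:
        raise MatchingError("empty class for density estimation")
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        dens = np.convolve(dens, kernel, mode="same")
    dens = dens / (dens.sum() * width)
    dens = np.maximum(dens, floor)
    return dens / (dens.sum() * width)


def fit_bayes_model(
    scores: ScoreMatrices,
    putative: np.ndarray,
    config: MatchConfig | None = None,
) -> BayesModel:
    """Class-conditional densities of each score on shared [0, 1] bins.

    Histograms are smoothed with a short moving average, floored at a
    small positive value (so no likelihood is ever exactly zero), and
    renormalised to integrate to 1.  The match prior is the empirical
    fraction of putative matches among all scored pairs, or 0.5 in
    'flat' mode.  Raises if either class is empty — the threshold then
    needs adjusting.
    """
    cfg = config or MatchConfig()
    n = scores.n_units
    iu = np.triu_indices(n)
    labels = putative[iu]
    n_match = int(labels.sum())
    n_non = int(labels.size - n_match)
    if n_match == 0 or n_non == 0:
        raise MatchingError(
            f"degenerate putative classes (matches={n_match}, "
            f"nonmatches={n_non}); adjust the threshold"
        )
    edges = np.linspace(0.0, 1.0, cfg.n_bins + 1)
    width = edges[1] - edges[0]
    density_match: dict[str, np.ndarray] = {}
    density_nonmatch: dict[str, np.ndarray] = {}
    for name, mat in scores.as_dict().items():
        vals = mat[iu]
        cm, _ = np.histogram(vals[labels], bins=edges)
        cn, _ = np.histogram(vals[~labels], bins=edges)
        density_match[name] = _smooth_density(cm, width, cfg.smooth_bins, cfg.density_floor)
        density_nonmatch[name] = _smooth_density(cn, width, cfg.smooth_bins, cfg.density_floor)
    if cfg.prior_mode == "flat":
        prior = 0.5
    else:
        prior = n_match / labels.size
    return BayesModel(
        bin_edges=edges,
        density_match=density_match,
        density_nonmatch=density_nonmatch,
        prior_match=prior,
    )


def match_probability(model: BayesModel, score_vector: dict[str, float] | np.ndarray) -> float:
    """Naive Bayes posterior P(match | scores) for one pair.

    ``score_vector`` maps score names to values in [0, 1] (or is an array
    ordered as the model's densities).
    """
    if isinstance(score_vector, dict):
        names = list(model.density_match)
        vec = np.array([score_vector[k] for k in names])
    else:
        vec = np.asarray(score_vector, dtype=float)
        names = list(model.density_match)
    idx = np.minimum((vec * model.n_bins).astype(int), model.n_bins - 1)
    log_l1 = sum(
        np.log(model.density_match[name][i]) for name, i in zip(names, idx)
    )
    log_l0 = sum(
        np.log(model.density_nonmatch[name][i]) for name, i in zip(names, idx)
    )
    logit = (
        np.log(model.prior_match)
        - np.log1p(-model.prior_match)
        + log_l1
        - log_l0
    )
    return float(1.0 / (1.0 + np.exp(-logit)))


def match_probability_matrix(model: BayesModel, scores: ScoreMatrices) -> np.ndarray:
    """Posterior for every pair, vectorised over the score matrices."""
    n = scores.n_units
    log_odds = np.full(
        (n, n), np.log(model.prior_match) - np.log1p(-model.prior_match)
    )
    for name, mat in scores.as_dict().items():
        idx = np.minimum((mat * model.n_bins).astype(int), model.n_bins - 1)
        log_odds += np.log(model.density_match[name][idx])
        log_odds -= np.log(model.density_nonmatch[name][idx])
    return 1.0 / (1.0 + np.exp(-log_odds))


class UnitMatcher:
    """Model: match units across sessions from split-half average waveforms.

    Parameters
    ----------
    records : list of WaveformRecord
        One per unit, any number of sessions (waveforms must share one
        sampling rate so analysis windows are comparable).
    geometry : ProbeGeometry
        Site positions in micrometers.
    sessions : list of SessionInfo, optional
        Session order and day offsets; defaults to the distinct session
        ids in first-appearance order with day offsets equal to rank.
    config : MatchConfig, optional

    Examples
    --------
    >>> matcher = UnitMatcher(records, geometry)
    >>> res = matcher.fit()
    >>> res.match_table.head()
    """

    def __init__(
        self,
        records: list[WaveformRecord],
        geometry: ProbeGeometry,
        sessions: list[SessionInfo] | None = None,
        config: MatchConfig | None = None,
    ):
        if not records:
            raise ValueError("need at least one waveform record")
        for rec in records:
            rec.validate_geometry(geometry)
        self.records = records
        self.geometry = geometry
        self.config = config or MatchConfig()
        seen = list(dict.fromkeys(rec.session_id for rec in records))
        if sessions is None:
            sessions = [
                SessionInfo(session_id=s, day_offset=k) for k, s in enumerate(sorted(seen))
            ]
        self.sessions = sessions
        known = {s.session_id for s in sessions}
        missing = [s for s in seen if s not in known]
        if missing:
            raise ValueError(f"records reference unknown sessions {missing}")

    @classmethod
    def from_stores(
        cls,
        store_paths: list[str | Path],
        geometry: ProbeGeometry | str | Path,
        sessions: list[SessionInfo] | None = None,
        config: MatchConfig | None = None,
    ) -> "UnitMatcher":
        """Build from one waveform-store directory per session."""
        if not isinstance(geometry, ProbeGeometry):
            geometry = read_site_positions(geometry)
        records: list[WaveformRecord] = []
        for path in store_paths:
            records.extend(read_waveform_store(path, geometry))
        return cls(records, geometry, sessions=sessions, config=config)

    def fit(self) -> "MatchResults":
        """Run the full five-step pipeline; deterministic given inputs."""
        features = extract_all(self.records, self.geometry, self.config)
        unit_ids = np.array([rec.unit_id for rec in self.records])
        session_ids = np.array([rec.session_id for rec in self.records])
        session_order = [s.session_id for s in self.sessions]
        results = fit_from_features(
            features, unit_ids, session_ids, session_order, self.config
        )
        results.model = self
        return results


def fit_from_features(
    features: list[tuple[WaveformFeatures, WaveformFeatures]],
    unit_ids: np.ndarray,
    session_ids: np.ndarray,
    session_order: list[int] | None = None,
    config: MatchConfig | None = None,
) -> "MatchResults":
    """Steps 2-5 of the pipeline from already-extracted features."""
    cfg = config or MatchConfig()
    log: list[str] = []
    unit_ids = np.asarray(unit_ids)
    session_ids = np.asarray(session_ids)
    if session_order is None:
        session_order = sorted(set(session_ids.tolist()))
    centroids = np.stack(
        [(f0.avg_centroid + f1.avg_centroid) / 2.0 for f0, f1 in features]
    )

    scores = compute_scores(features, unit_ids, session_ids, cfg)
    cdist = centroid_distance_matrix(centroids, session_ids)
    thr_initial = find_threshold(scores.total, cdist, session_ids, cfg)
    log.append(
        f"initial threshold {thr_initial.threshold:.4f} "
        f"(base {thr_initial.base_threshold:.4f}, "
        f"adjustment {thr_initial.adjustment:+.4f})"
    )
    putative = putative_matches(scores.total, thr_initial.threshold)

    n_sessions = len(set(session_ids.tolist()))
    drift = DriftEstimate(displacement={}, n_matches={})
    thr = thr_initial
    if cfg.drift_correction and n_sessions > 1:
        drift = estimate_drift(centroids, session_ids, putative, session_order)
        for key, d in drift.displacement.items():
            log.append(
                f"drift {key}: ({d[0]:+.2f}, {d[1]:+.2f}) um "
                f"from {drift.n_matches[key]} putative matches"
            )
        if any(np.any(d != 0) for d in drift.displacement.values()):
            scores = compute_scores(
                features, unit_ids, session_ids, cfg, drift=drift.displacement
            )
            cdist = centroid_distance_matrix(
                centroids, session_ids, drift=drift.displacement
            )
            thr = find_threshold(scores.total, cdist, session_ids, cfg)
            log.append(
                f"post-drift threshold {thr.threshold:.4f} "
                f"(base {thr.base_threshold:.4f}, "
                f"adjustment {thr.adjustment:+.4f})"
            )
            putative = putative_matches(scores.total, thr.threshold)

    bayes = fit_bayes_model(scores, putative, cfg)
    iu = np.triu_indices(len(features))
    log.append(
        f"classifier classes: {int(putative[iu].sum())} putative matches, "
        f"{int((~putative[iu]).sum())} nonmatches; "
        f"prior P(match) = {bayes.prior_match:.4f}"
    )
    posteriors = match_probability_matrix(bayes, scores)
    return MatchResults(
        model=None,
        features=features,
        scores=scores,
        threshold_model=thr,
        initial_threshold_model=thr_initial,
        drift=drift,
        bayes_model=bayes,
        posteriors=posteriors,
        centroids=centroids,
        log=log,
        config=cfg,
        session_order=list(session_order),
    )


@dataclass
class MatchResults:
    """Fitted matching results: posteriors, diagnostics and accessors."""

    model: UnitMatcher | None
    features: list[tuple[WaveformFeatures, WaveformFeatures]]
    scores: ScoreMatrices
    threshold_model: ThresholdModel
    initial_threshold_model: ThresholdModel
    drift: DriftEstimate
    bayes_model: BayesModel
    posteriors: np.ndarray
    centroids: np.ndarray
    log: list[str]
    config: MatchConfig = field(default_factory=MatchConfig)
    session_order: list[int] = field(default_factory=list)

    @property
    def unit_ids(self) -> np.ndarray:
        return self.scores.unit_ids

    @property
    def session_ids(self) -> np.ndarray:
        return self.scores.session_ids

    @property
    def match_table(self) -> pd.DataFrame:
        """One row per unordered pair (diagonal = own cross-half pair)."""
        n = self.scores.n_units
        ii, jj = np.triu_indices(n)
        sd = self.scores
        return pd.DataFrame(
            {
                "unit_i": self.unit_ids[ii],
                "session_i": self.session_ids[ii],
                "unit_j": self.unit_ids[jj],
                "session_j": self.session_ids[jj],
                "amplitude_score": sd.amplitude[ii, jj],
                "decay_score": sd.decay[ii, jj],
                "waveform_score": sd.waveform[ii, jj],
                "centroid_score": sd.centroid[ii, jj],
                "volatility_score": sd.volatility[ii, jj],
                "route_score": sd.route[ii, jj],
                "total_score": sd.total[ii, jj],
                "match_probability": self.posteriors[ii, jj],
            },
            columns=MATCH_COLUMNS,
        )

    def matched_pairs(self, cutoff: float | None = None) -> pd.DataFrame:
        """Cross-session pairs whose posterior exceeds the cutoff (0.5)."""
        cutoff = self.config.match_probability_cutoff if cutoff is None else cutoff
        table = self.match_table
        cross = table["session_i"] != table["session_j"]
        return table[cross & (table["match_probability"] > cutoff)].reset_index(drop=True)

    def track(self, mode: str = "default") -> pd.DataFrame:
        """Assign persistent global ids; see `unitmatch.tracking`."""
        from .tracking import assign_global_ids

        return assign_global_ids(
            self.posteriors,
            self.unit_ids,
            self.session_ids,
            self.session_order,
            mode=mode,
        )

    def summary(self) -> str:
        n = self.scores.n_units
        lines = [
            "UnitMatch results",
            "=" * 54,
            f"units: {n}    sessions: {len(self.session_order)}",
            f"threshold (total score): {self.threshold_model.threshold:.4f}",
            f"  crossing point: {self.threshold_model.base_threshold:.4f}",
            f"  mean-equalisation adjustment: {self.threshold_model.adjustment:+.4f}",
            f"prior P(match): {self.bayes_model.prior_match:.4f}",
        ]
        for key, d in self.drift.displacement.items():
            lines.append(
                f"drift {key[0]}->{key[1]}: ({d[0]:+.2f}, {d[1]:+.2f}) um "
                f"[{self.drift.n_matches[key]} matches]"
            )
        matched = self.matched_pairs()
        lines.append(f"cross-session matches (P > 0.5): {len(matched)}")
        diag = np.diag(self.posteriors)
        lines.append(
            f"split-half self-match posteriors: median {np.median(diag):.3f}, "
            f"min {diag.min():.3f}"
        )
        return "\n".join(lines)

    def save(self, path: str | Path, tracks: pd.DataFrame | None = None) -> dict:
        written = write_results(self.match_table, tracks, path)
        log_path = Path(path) / "unitmatch.log"
        log_path.write_text("\n".join(self.log) + "\n")
        written["log"] = log_path
        return written

    def plot_score_distributions(self, ax=None):
        """Class-conditional densities of each score (diagnostic plot)."""
        import matplotlib.pyplot as plt

        names = list(self.bayes_model.density_match)
        fig, axes = plt.subplots(2, 3, figsize=(10, 5), sharex=True)
        centers = (self.bayes_model.bin_edges[:-1] + self.bayes_model.bin_edges[1:]) / 2
        for name, ax_ in zip(names, axes.ravel()):
            ax_.plot(centers, self.bayes_model.density_match[name], "k", label="match")
            ax_.plot(centers, self.bayes_model.density_nonmatch[name], "0.6", label="nonmatch")
            ax_.set_title(name)
        axes[0, 0].legend(frameon=False)
        fig.tight_layout()
        return fig
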