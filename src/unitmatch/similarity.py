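"""Pairwise similarity scores between unit waveform halves.

Every unit (across all sessions) is compared with every other unit by
pairing the first-half features of one with the second-half features of
the other; the reported score for a pair is the mean of the two
orientations, which makes each matrix symmetric.  The diagonal therefore
holds each unit's own cross-half (split-half) comparison — the
within-session "same unit" reference the classifier is trained on.

Six scores are produced, each in [0, 1] with 1 = most similar:

* amplitude (A): sqrt of the weighted-amplitude difference;
* decay (D): difference in spatial-decay slope;
* waveform (W): mean of a normalised-waveform RMS distance term and a
  Fisher-transformed waveform-correlation term;
* centroid (C): mean centroid-trajectory distance mapped to 0 at
  ``d_max = 100 um``;
* volatility (V): stability of the centroid difference once each unit's
  average centroid is subtracted — invariant to a rigid displacement of
  one unit's whole trajectory (uncorrected drift);
* route (R): difference in travel direction plus difference in per-step
  travel distance.

Raw distances are turned into similarities by "0-99 scaling": the pooled
minimum maps to 1, the pooled 99th percentile to 0, and values beyond the
percentile clip to 0.  All pairs (within- and across-session) share one
pool so scores are mutually comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import MatchConfig
from .features import WaveformFeatures


@dataclass
class ScoreMatrices:
    """Six symmetric (n_units x n_units) similarity matrices plus total."""

    amplitude: np.ndarray
    decay: np.ndarray
    waveform: np.ndarray
    centroid: np.ndarray
    volatility: np.ndarray
    route: np.ndarray
    total: np.ndarray
    unit_ids: np.ndarray
    session_ids: np.ndarray
    flags: set = field(default_factory=set)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "amplitude": self.amplitude,
            "decay": self.decay,
            "waveform": self.waveform,
            "centroid": self.centroid,
            "volatility": self.volatility,
            "route": self.route,
        }

    @property
    def n_units(self) -> int:
        return self.total.shape[0]


def scale_0_99(raw: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Map pooled raw distances to similarities in [0, 1].

    ``(P99 - X) / (P99 - P0)`` with ``P0`` the pooled minimum and ``P99``
    the pooled upper percentile, clipped into [0, 1] (so raw values beyond
    the percentile — the most dissimilar pairs — score 0).  Constant input
    has zero spread and is treated as perfectly similar everywhere.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw scores must be finite")
    p0 = raw.min()
    p99 = np.percentile(raw, percentile)
    if p99 == p0:
        return np.ones_like(raw)
    return np.clip((p99 - raw) / (p99 - p0), 0.0, 1.0)


def total_score(matrices: dict[str, np.ndarray]) -> np.ndarray:
    """Elementwise mean of the six similarity matrices."""
    arrays = list(matrices.values())
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("score matrices must share one shape")
    return np.mean(arrays, axis=0)


def _pair_shift(
    session_ids: np.ndarray,
    drift: dict[tuple[int, int], np.ndarray] | None,
    session_order: dict[int, int],
) -> np.ndarray | None:
    """Per-pair rigid correction (n, n, 2) added to centroid differences.

    ``drift[(sa, sb)]`` (sa earlier) is the displacement of session sb
    relative to sa; comparing a pair removes it from the later unit, which
    amounts to adding it to ``c_i - c_j`` when j is the later unit.
    """
    if not drift:
        return None
    n = session_ids.size
    shift = np.zeros((n, n, 2))
    for (sa, sb), d in drift.items():
        d = np.asarray(d, dtype=float)
        if session_order[sb] < session_order[sa]:
            sa, sb, d = sb, sa, d  # caller passes ordered keys; be safe
        in_a = session_ids == sa
        in_b = session_ids == sb
        # j in later session sb: diff c_i - (c_j - d) = diff + d
        shift[np.ix_(in_a, in_b)] = d
        shift[np.ix_(in_b, in_a)] = -d
    return shift


def centroid_distance_matrix(
    centroids: np.ndarray,
    session_ids: np.ndarray,
    drift: dict[tuple[int, int], np.ndarray] | None = None,
) -> np.ndarray:
    """Pairwise distance between per-unit average centroids.

    When a drift estimate is supplied, the displacement of the later
    session is removed from each cross-session pair before the distance
    is taken.
    """
    session_ids = np.asarray(session_ids)
    diff = centroids[:, None, :] - centroids[None, :, :]
    order = {s: k for k, s in enumerate(dict.fromkeys(session_ids.tolist()))}
    shift = _pair_shift(session_ids, drift, order)
    if shift is not None:
        diff = diff + shift
    return np.linalg.norm(diff, axis=2)


def compute_scores(
    features: list[tuple[WaveformFeatures, WaveformFeatures]],
    unit_ids: np.ndarray,
    session_ids: np.ndarray,
    config: MatchConfig | None = None,
    drift: dict[tuple[int, int], np.ndarray] | None = None,
) -> ScoreMatrices:
    """All six similarity matrices over every (unit, unit) pair.

    ``drift`` optionally supplies per-session-pair rigid displacements
    (later relative to earlier session) that are removed from centroid
    positions before the position-dependent scores are computed.
    """
    cfg = config or MatchConfig()
    n = len(features)
    unit_ids = np.asarray(unit_ids)
    session_ids = np.asarray(session_ids)
    flags: set = set()

    lengths = {f.weighted_waveform.size for pair in features for f in pair}
    if len(lengths) != 1:
        raise ValueError(
            "all waveform halves must share one analysis-window length "
            f"(got {sorted(lengths)}); check sampling rates"
        )

    def stack(attr, half):
        return np.stack([getattr(pair[half], attr) for pair in features])

    amp = np.stack([[pair[0].amplitude, pair[1].amplitude] for pair in features])
    dec = np.stack([[pair[0].decay_slope, pair[1].decay_slope] for pair in features])
    what = [stack("normalized_waveform", h) for h in (0, 1)]   # (n, Tw)
    wbar = [stack("weighted_waveform", h) for h in (0, 1)]
    traj = [stack("centroid_traj", h) for h in (0, 1)]          # (n, Tw, 2)
    cstar = [stack("avg_centroid", h) for h in (0, 1)]          # (n, 2)
    theta = [stack("travel_dir", h) for h in (0, 1)]            # (n, Tw-1)
    steps = [stack("step_dist", h) for h in (0, 1)]

    order = {s: k for k, s in enumerate(dict.fromkeys(session_ids.tolist()))}
    shift = _pair_shift(session_ids, drift, order)

    # --- raw (oriented) distance matrices: first half of i vs second of j
    raw_amp = np.sqrt(np.abs(amp[:, 0][:, None] - amp[:, 1][None, :]))
    raw_dec = np.abs(dec[:, 0][:, None] - dec[:, 1][None, :])

    d_hat = what[0][:, None, :] - what[1][None, :, :]
    raw_eucl = np.sqrt(np.mean(d_hat**2, axis=2))

    v0 = wbar[0] - wbar[0].mean(axis=1, keepdims=True)
    v1 = wbar[1] - wbar[1].mean(axis=1, keepdims=True)
    n0 = np.sqrt((v0**2).mean(axis=1))
    n1 = np.sqrt((v1**2).mean(axis=1))
    zero0, zero1 = n0 == 0, n1 == 0
    if zero0.any() or zero1.any():
        flags.add("zero_variance_waveform")
        n0 = np.where(zero0, 1.0, n0)
        n1 = np.where(zero1, 1.0, n1)
    rho = (v0 @ v1.T) / v0.shape[1] / np.outer(n0, n1)
    rho[zero0, :] = 0.0
    rho[:, zero1] = 0.0
    rho = np.clip(rho, -1.0 + cfg.rho_clip, 1.0 - cfg.rho_clip)
    raw_fisher = 1.0 - np.log((1.0 + rho) / (1.0 - rho))

    diff = traj[0][:, None, :, :] - traj[1][None, :, :, :]       # (n, n, Tw, 2)
    if shift is not None:
        diff = diff + shift[:, :, None, :]
    dist_t = np.linalg.norm(diff, axis=3)                        # (n, n, Tw)
    raw_cdist = dist_t.mean(axis=2)
    raw_std = np.sqrt(np.mean((dist_t - raw_cdist[:, :, None]) ** 2, axis=2))

    rel0 = traj[0] - cstar[0][:, None, :]
    rel1 = traj[1] - cstar[1][:, None, :]
    rel_diff = rel0[:, None, :, :] - rel1[None, :, :, :]
    raw_vol = np.linalg.norm(rel_diff, axis=3).mean(axis=2)

    raw_theta = np.abs(
        (theta[0][:, None, :] - theta[1][None, :, :]).mean(axis=2)
    )
    raw_path = np.sqrt(
        np.abs(steps[0][:, None, :] - steps[1][None, :, :]).sum(axis=2)
    )

    # --- scale into similarities, pooling every pair
    pct = cfg.percentile
    A = scale_0_99(raw_amp, pct)
    D = scale_0_99(raw_dec, pct)
    E = scale_0_99(raw_eucl, pct)
    Z = scale_0_99(raw_fisher, pct)
    W = (E + Z) / 2.0

    d_min = raw_cdist.min()
    if d_min >= cfg.d_max_um:
        flags.add("all_centroids_beyond_dmax")
        C = np.zeros_like(raw_cdist)
    else:
        C = np.clip(
            (cfg.d_max_um - raw_cdist) / (cfg.d_max_um - d_min), 0.0, 1.0
        )

    F = scale_0_99(raw_vol, pct)
    S = scale_0_99(raw_std, pct)
    V = (F + S) / 2.0

    TH = scale_0_99(raw_theta, pct)
    P = scale_0_99(raw_path, pct)
    R = (TH + P) / 2.0

    # --- symmetrise: average the two half orientations
    def sym(m):
        return (m + m.T) / 2.0

    A, D, W, C, V, R = (sym(m) for m in (A, D, W, C, V, R))
    T = total_score(
        {"A": A, "D": D, "W": W, "C": C, "V": V, "R": R}
    )
    return ScoreMatrices(
        amplitude=A, decay=D, waveform=W, centroid=C, volatility=V, route=R,
        total=T, unit_ids=unit_ids, session_ids=session_ids, flags=flags,
    )
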