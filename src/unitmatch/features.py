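"""Per-half waveform attribute extraction.

Each unit contributes two average waveforms (one per recording half); each
is summarised independently by:

* the spatial footprint ``w*_s`` (per-site max absolute amplitude inside
  the peak window) and the max site ``s*``;
* an exponential spatial-decay fit ``w*_s ~ A exp(-lambda * dist)`` giving
  the 10%-amplitude distance ``d10 = ln(10)/lambda``, which (capped at
  150 um) defines the unit's site neighborhood;
* the decay slope ``d`` — the mean amplitude drop per micrometer over the
  selected sites;
* the amplitude-weighted centroid trajectory ``c_t``, the footprint-
  weighted average centroid ``c*``, the per-step travel direction
  ``theta_t`` and step distance;
* the proximity-weighted average waveform ``w_bar_t``, its amplitude
  ``a = max_t |w_bar_t|`` and its min-max normalisation ``w_hat_t``.

The analysis window runs from 0.23 ms before the global waveform peak to
0.50 ms after it (inclusive, rounded to samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import MatchConfig
from .io import ProbeGeometry, WaveformRecord


class WindowError(ValueError):
    """Peak window cannot be placed (peak near edge, or no peak)."""


class DegenerateWaveformError(ValueError):
    """Waveform too degenerate to summarise (zero proximity mass etc.)."""


@dataclass
class WaveformFeatures:
    """The extracted attributes of one waveform half."""

    footprint: np.ndarray          # (S,) w*_s, uV
    max_site: int                  # s*
    decay_lambda: float            # 1/um
    amplitude_fit: float           # uV, fitted A
    d10: float                     # um
    selected_sites: np.ndarray     # site indices (int)
    decay_slope: float             # d, uV/um
    proximity: np.ndarray          # (S,) f_s in [0, 1]
    weighted_waveform: np.ndarray  # (Tw,) w_bar_t, uV
    amplitude: float               # a = max_t |w_bar_t|, uV
    normalized_waveform: np.ndarray  # (Tw,) w_hat_t in [0, 1]
    centroid_traj: np.ndarray      # (Tw, 2) um
    avg_centroid: np.ndarray       # (2,) um
    travel_dir: np.ndarray         # (Tw-1,) radians
    step_dist: np.ndarray          # (Tw-1,) um
    peak_sample: int
    window: tuple[int, int]        # inclusive sample range in the full trace
    noise_level: float = np.nan    # baseline RMS on the max-site trace, uV
    flags: set = field(default_factory=set)


def locate_peak_window(
    waveform_half: np.ndarray,
    sampling_rate: float,
    pre_peak_ms: float = 0.23,
    post_peak_ms: float = 0.50,
) -> tuple[int, tuple[int, int]]:
    """Locate the global peak and the inclusive analysis window around it.

    The peak is the sample where the largest absolute amplitude across all
    sites occurs; window bounds are rounded to the nearest sample.
    """
    wf = np.asarray(waveform_half, dtype=float)
    envelope = np.max(np.abs(wf), axis=1)
    if np.max(envelope) == 0:
        raise WindowError("all-zero waveform: no unambiguous peak")
    peak = int(np.argmax(envelope))
    pre = int(round(pre_peak_ms * 1e-3 * sampling_rate))
    post = int(round(post_peak_ms * 1e-3 * sampling_rate))
    lo, hi = peak - pre, peak + post
    if lo < 0 or hi >= wf.shape[0]:
        raise WindowError(
            f"peak at sample {peak} too close to edge for window "
            f"[-{pre}, +{post}] in a {wf.shape[0]}-sample trace"
        )
    return peak, (lo, hi)


def compute_footprint(windowed: np.ndarray) -> tuple[np.ndarray, int]:
    """Spatial footprint ``w*_s = max_t |w_{s,t}|`` and max site ``s*``.

    Ties in the footprint maximum are broken toward the lowest site index
    (numpy argmax convention).
    """
    footprint = np.max(np.abs(windowed), axis=0)
    max_site = int(np.argmax(footprint))
    return footprint, max_site


def fit_spatial_decay(
    footprint: np.ndarray,
    positions: np.ndarray,
    max_site: int,
    max_radius_um: float = 150.0,
    amp_floor_uv: float = 0.1,
) -> tuple[float, float, float, np.ndarray, set]:
    """Fit ``w*_s ~ A exp(-lambda dist)`` and derive d10 and the site set.

    The fit is ordinary least squares in log-amplitude space over sites
    within ``max_radius_um`` of the max site, with amplitudes floored at
    ``amp_floor_uv``.  ``d10 = ln(10)/lambda``.  Selected sites are those
    closer than ``min(d10, max_radius_um)``, always including the max
    site.  A non-decaying fit (lambda <= 0) falls back to the capped
    radius and is flagged.
    """
    flags: set = set()
    dist = np.linalg.norm(positions - positions[max_site], axis=1)
    fit_mask = dist <= max_radius_um
    if np.count_nonzero(fit_mask) < 3 or len(np.unique(dist[fit_mask])) < 3:
        raise DegenerateWaveformError(
            "need >= 3 sites at distinct distances for the decay fit"
        )
    # sites at the amplitude floor carry no decay information and would
    # flatten the log-space fit; drop them unless too few sites remain
    informative = fit_mask & (footprint > amp_floor_uv)
    if np.count_nonzero(informative) >= 3 and len(np.unique(dist[informative])) >= 3:
        fit_mask = informative
    log_amp = np.log(np.maximum(footprint[fit_mask], amp_floor_uv))
    slope, intercept = np.polyfit(dist[fit_mask], log_amp, 1)
    lam = -slope
    amplitude_fit = float(np.exp(intercept))
    if lam <= 1e-9:
        flags.add("decay_fallback")
        d10 = np.inf
    else:
        d10 = float(np.log(10.0) / lam)
    radius = min(d10, max_radius_um)
    selected = np.flatnonzero(dist < radius)
    if max_site not in selected:
        selected = np.union1d(selected, [max_site]).astype(int)
    return float(lam), amplitude_fit, d10, selected.astype(int), flags


def compute_centroid_features(
    windowed: np.ndarray,
    positions: np.ndarray,
    selected_sites: np.ndarray,
    footprint: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, set]:
    """Centroid trajectory, average centroid, travel direction, step size.

    The trajectory weights each selected site's position by the absolute
    waveform value at that time; the average centroid weights by the
    footprint.  The travel direction folds into one quadrant,
    ``theta_t = atan(|x_t - x_{t+1}| / |y_t - y_{t+1}|)``, with zero-length
    steps assigned direction 0.
    """
    flags: set = set()
    sel = np.asarray(selected_sites, dtype=int)
    if sel.size == 0:
        raise DegenerateWaveformError("no selected sites")
    pos = positions[sel]                       # (k, 2)
    w_abs = np.abs(windowed[:, sel])           # (Tw, k)
    fp = footprint[sel]

    avg_centroid = (fp[:, None] * pos).sum(axis=0) / fp.sum()

    mass = w_abs.sum(axis=1)                   # (Tw,)
    traj = np.empty((windowed.shape[0], 2))
    ok = mass > 0
    traj[ok] = (w_abs[ok] @ pos) / mass[ok, None]
    if not np.all(ok):
        traj[~ok] = avg_centroid
        flags.add("zero_mass_frame")

    diff = traj[:-1] - traj[1:]                # c_t - c_{t+1}
    travel_dir = np.arctan2(np.abs(diff[:, 0]), np.abs(diff[:, 1]))
    step_dist = np.linalg.norm(traj[1:] - traj[:-1], axis=1)
    # steps below numerical resolution are zero-length: direction 0
    tiny = step_dist < 1e-9
    travel_dir[tiny] = 0.0
    step_dist[tiny] = 0.0
    return traj, avg_centroid, travel_dir, step_dist, flags


def compute_weighted_waveform(
    windowed: np.ndarray,
    positions: np.ndarray,
    avg_centroid: np.ndarray,
    d10: float,
    selected_sites: np.ndarray,
    footprint: np.ndarray,
    max_site: int,
    max_radius_um: float = 150.0,
) -> tuple[np.ndarray, float, np.ndarray, float, np.ndarray]:
    """Proximity weights, decay slope, weighted waveform, amplitude, norm.

    * ``f_s = max(0, 1 - |p_s - c*| / r)`` with ``r = min(d10, 150 um)``;
    * ``d`` = mean over selected sites (excluding the max site) of the
      amplitude drop from the max site divided by the distance;
    * ``w_bar_t`` = proximity-weighted average of the per-site waveforms;
    * ``a = max_t |w_bar_t|``; ``w_hat_t`` min-max normalised to [0, 1].
    """
    radius = min(d10, max_radius_um)
    prox = np.maximum(0.0, 1.0 - np.linalg.norm(positions - avg_centroid, axis=1) / radius)
    total = prox.sum()
    if total == 0:
        raise DegenerateWaveformError("all proximity weights are zero")

    sel = np.asarray(selected_sites, dtype=int)
    others = sel[sel != max_site]
    if others.size:
        drops = footprint[max_site] - footprint[others]
        dists = np.linalg.norm(positions[others] - positions[max_site], axis=1)
        decay_slope = float(np.mean(drops / dists))
    else:
        decay_slope = 0.0

    weighted = (windowed * prox[None, :]).sum(axis=1) / total
    amplitude = float(np.max(np.abs(weighted)))
    span = weighted.max() - weighted.min()
    if span == 0:
        raise DegenerateWaveformError("flat weighted waveform")
    normalized = (weighted - weighted.min()) / span
    return prox, decay_slope, weighted, amplitude, normalized


def extract_features(
    waveform_half: np.ndarray,
    geometry: ProbeGeometry,
    sampling_rate: float,
    config: MatchConfig | None = None,
) -> WaveformFeatures:
    """Extract every attribute of one waveform half (shape (T, S))."""
    cfg = config or MatchConfig()
    positions = geometry.site_positions
    wf = np.asarray(waveform_half, dtype=float)
    if wf.shape[1] != positions.shape[0]:
        raise ValueError(
            f"waveform has {wf.shape[1]} sites, geometry has {positions.shape[0]}"
        )
    peak, (lo, hi) = locate_peak_window(
        wf, sampling_rate, cfg.pre_peak_ms, cfg.post_peak_ms
    )
    windowed = wf[lo : hi + 1]
    footprint, max_site = compute_footprint(windowed)
    lam, amp_fit, d10, selected, flags = fit_spatial_decay(
        footprint, positions, max_site, cfg.max_radius_um, cfg.amp_floor_uv
    )
    traj, avg_centroid, travel_dir, step_dist, cflags = compute_centroid_features(
        windowed, positions, selected, footprint
    )
    prox, decay_slope, weighted, amplitude, normalized = compute_weighted_waveform(
        windowed, positions, avg_centroid, d10, selected, footprint,
        max_site, cfg.max_radius_um,
    )
    # Baseline noise on the max-site trace, in a window of the same
    # duration ending well before the peak window; stored for diagnostics
    # only — the matcher does not use it.
    width = hi - lo + 1
    base_hi = lo - int(round(1.33e-3 * sampling_rate)) + width
    if base_hi - width >= 0:
        noise_level = float(np.sqrt(np.mean(wf[base_hi - width : base_hi, max_site] ** 2)))
    else:
        noise_level = np.nan

    return WaveformFeatures(
        footprint=footprint,
        max_site=max_site,
        decay_lambda=lam,
        amplitude_fit=amp_fit,
        d10=d10,
        selected_sites=selected,
        decay_slope=decay_slope,
        proximity=prox,
        weighted_waveform=weighted,
        amplitude=amplitude,
        normalized_waveform=normalized,
        centroid_traj=traj,
        avg_centroid=avg_centroid,
        travel_dir=travel_dir,
        step_dist=step_dist,
        peak_sample=peak,
        window=(lo, hi),
        noise_level=noise_level,
        flags=flags | cflags,
    )


def extract_all(
    records: list[WaveformRecord],
    geometry: ProbeGeometry,
    config: MatchConfig | None = None,
) -> list[tuple[WaveformFeatures, WaveformFeatures]]:
    """Features for both halves of every record, independently per half."""
    out = []
    for rec in records:
        halves = tuple(
            extract_features(rec.waveform[:, :, h], geometry, rec.sampling_rate, config)
            for h in (0, 1)
        )
        out.append(halves)
    return out
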