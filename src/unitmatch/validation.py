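"""Functional-fingerprint validation of tracking.

Matching never uses activity; these fingerprints provide an independent
check.  Three fingerprints are computed per unit and recording half:

* ISI — histogram of consecutive-spike intervals on log-spaced bins up
  to 5 s;
* population coupling — Pearson correlations between a unit's 10-ms
  binned spike counts and those of a tracked reference population;
* stimulus response — trial-averaged PSTHs locked to natural-image onset
  (-0.3 to 0.5 s) and offset (0 to 0.5 s) at 5 ms, reduced to an average
  time course (mean over stimuli) concatenated with a per-image tuning
  curve (mean over time).

Fingerprint similarity between two unit-days is the correlation of their
fingerprints computed on *different* halves, which for a unit against
itself on one day gives the fingerprint's split-half reliability.  ROC
analysis (AUC, Mann-Whitney form) then quantifies how well fingerprint
similarity separates matched from nonmatched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ValidationError(ValueError):
    pass


DEFAULT_ISI_BINS = 50
ISI_MIN_S = 1e-3
ISI_MAX_S = 5.0
COUPLING_BIN_S = 0.010
PSTH_BIN_S = 0.005
ONSET_WINDOW_S = (-0.3, 0.5)
OFFSET_WINDOW_S = (0.0, 0.5)


def isi_bin_edges(n_bins: int = DEFAULT_ISI_BINS) -> np.ndarray:
    """Logarithmically spaced interval-histogram edges from 1 ms to 5 s."""
    return np.logspace(np.log10(ISI_MIN_S), np.log10(ISI_MAX_S), n_bins + 1)


def isi_fingerprint(
    spike_times: np.ndarray,
    t_range: tuple[float, float] | None = None,
    n_bins: int = DEFAULT_ISI_BINS,
) -> np.ndarray:
    """Normalised log-binned inter-spike-interval histogram.

    Intervals longer than 5 s are discarded.  Fewer than two spikes give
    an all-zero vector (degenerate, nothing to histogram).
    """
    t = np.asarray(spike_times, dtype=float)
    if t_range is not None:
        t = t[(t >= t_range[0]) & (t < t_range[1])]
    if t.size < 2:
        return np.zeros(n_bins)
    intervals = np.diff(np.sort(t))
    counts, _ = np.histogram(intervals, bins=isi_bin_edges(n_bins))
    total = counts.sum()
    if total == 0:
        return np.zeros(n_bins)
    return counts / total


def binned_counts(
    spike_times: np.ndarray,
    t_range: tuple[float, float],
    bin_s: float = COUPLING_BIN_S,
) -> np.ndarray:
    edges = np.arange(t_range[0], t_range[1] + bin_s / 2, bin_s)
    counts, _ = np.histogram(np.asarray(spike_times, float), bins=edges)
    return counts


def coupling_fingerprint(
    trains: dict[int, np.ndarray],
    reference_units: list[int],
    t_range: tuple[float, float],
    bin_s: float = COUPLING_BIN_S,
) -> dict[int, np.ndarray]:
    """Per-unit correlation vector with a tracked reference population.

    Returns, for every unit in ``trains``, the Pearson correlation of its
    binned counts with each reference unit's counts (reference order as
    given).  A unit's correlation with itself, and any correlation
    involving a zero-variance binned train, is NaN.
    """
    units = list(trains)
    counts = np.stack([binned_counts(trains[u], t_range, bin_s) for u in units])
    sd = counts.std(axis=1)
    centered = counts - counts.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * counts.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered @ centered.T) / denom
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    row_of = {u: k for k, u in enumerate(units)}
    out: dict[int, np.ndarray] = {}
    for u in units:
        vec = np.array(
            [
                np.nan
                if (ref == u or ref not in row_of)
                else corr[row_of[u], row_of[ref]]
                for ref in reference_units
            ]
        )
        out[u] = vec
    return out


def image_fingerprint(
    spike_times: np.ndarray,
    stimuli: pd.DataFrame,
    t_range: tuple[float, float] | None = None,
    bin_s: float = PSTH_BIN_S,
) -> np.ndarray:
    """Natural-image response fingerprint.

    ``stimuli`` needs columns stimulus_id, onset_s and offset_s.  For each
    stimulus, spike counts are averaged over presentations in onset- and
    offset-locked windows; the mean-over-stimuli time course and the
    mean-over-time tuning curve are concatenated (length
    n_onset_bins + n_offset_bins + n_stimuli; 160 + 100 + 112 = 372 for
    the 112-image protocol).
    """
    t = np.asarray(spike_times, dtype=float)
    stim = stimuli
    if t_range is not None:
        stim = stimuli[
            (stimuli["onset_s"] >= t_range[0]) & (stimuli["onset_s"] < t_range[1])
        ]
    if "offset_s" not in stim.columns:
        raise ValidationError("stimulus table needs an offset_s column")
    on_edges = np.arange(ONSET_WINDOW_S[0], ONSET_WINDOW_S[1] + bin_s / 2, bin_s)
    off_edges = np.arange(OFFSET_WINDOW_S[0], OFFSET_WINDOW_S[1] + bin_s / 2, bin_s)
    n_on, n_off = on_edges.size - 1, off_edges.size - 1

    stim_ids = sorted(stimuli["stimulus_id"].unique())
    R = np.zeros((n_on + n_off, len(stim_ids)))
    for k, sid in enumerate(stim_ids):
        rows = stim[stim["stimulus_id"] == sid]
        if rows.empty:
            raise ValidationError(
                f"stimulus {sid} has no presentation in the requested half"
            )
        psth = np.zeros(n_on + n_off)
        for row in rows.itertuples(index=False):
            on_counts, _ = np.histogram(t - row.onset_s, bins=on_edges)
            off_counts, _ = np.histogram(t - row.offset_s, bins=off_edges)
            psth += np.concatenate([on_counts, off_counts])
        R[:, k] = psth / len(rows)

    time_course = R.mean(axis=1)   # mean over stimuli
    tuning = R.mean(axis=0)        # mean over time bins
    return np.concatenate([time_course, tuning])


def fingerprint_similarity(
    vec_a: np.ndarray, vec_b: np.ndarray, min_overlap: int = 3
) -> float:
    """Pearson correlation across entries, dropping NaNs pairwise."""
    a = np.asarray(vec_a, float)
    b = np.asarray(vec_b, float)
    if a.shape != b.shape:
        raise ValidationError("fingerprints must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_overlap:
        return np.nan
    aa, bb = a[ok], b[ok]
    if aa.std() == 0 or bb.std() == 0:
        return np.nan
    return float(np.corrcoef(aa, bb)[0, 1])


def pair_similarity(
    fp_i: tuple[np.ndarray, np.ndarray], fp_j: tuple[np.ndarray, np.ndarray]
) -> float:
    """Cross-half fingerprint similarity of two unit-days.

    Mean of the two half crossings (half1 of i vs half2 of j and vice
    versa); for i == j on one day this is the split-half reliability.
    """
    s1 = fingerprint_similarity(fp_i[0], fp_j[1])
    s2 = fingerprint_similarity(fp_i[1], fp_j[0])
    return float(np.nanmean([s1, s2]))


def roc_auc(similarities_match, similarities_nonmatch) -> float:
    """Area under the ROC curve separating match from nonmatch values.

    Equals the Mann-Whitney U statistic normalised by n1*n2, with ties
    counted one half.
    """
    x = np.asarray(similarities_match, float)
    y = np.asarray(similarities_nonmatch, float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    return float(u / (x.size * y.size))


@dataclass
class FingerprintSet:
    """Fingerprints for one session: unit -> (half1 vector, half2 vector)."""

    kind: str
    session_id: int
    vectors: dict[int, tuple[np.ndarray, np.ndarray]]


def auc_report(
    fingerprints: dict[int, FingerprintSet],
    matches: pd.DataFrame,
    day_offsets: dict[int, int],
    min_matched_units: int = 20,
    reliability_cutoff: float | None = None,
    exclude_units: dict[int, set] | None = None,
) -> pd.DataFrame:
    """AUC per session pair plus the AUC-vs-day-gap slope.

    ``matches`` holds the cross-session matched pairs (columns unit_i,
    session_i, unit_j, session_j).  Session pairs with fewer than
    ``min_matched_units`` matched units are excluded.  If
    ``reliability_cutoff`` is set (image fingerprints), only units whose
    earlier-day split-half reliability exceeds it enter the analysis.
    ``exclude_units`` optionally removes units per session (e.g. units
    with a within-recording match).  The slope is the OLS fit of AUC
    against day gap over the retained session pairs.
    """
    exclude_units = exclude_units or {}
    sessions = sorted(fingerprints, key=lambda s: day_offsets[s])
    rows = []
    for a_idx in range(len(sessions)):
        for b_idx in range(a_idx + 1, len(sessions)):
            sa, sb = sessions[a_idx], sessions[b_idx]
            fa, fb = fingerprints[sa], fingerprints[sb]
            pair_rows = matches[
                (matches["session_i"] == sa) & (matches["session_j"] == sb)
            ]
            matched = {
                (int(r.unit_i), int(r.unit_j)) for r in pair_rows.itertuples(index=False)
            }
            if len(matched) < min_matched_units:
                continue

            def usable(unit, fset, sess):
                if unit in exclude_units.get(sess, set()):
                    return False
                if reliability_cutoff is not None and sess == sa:
                    rel = pair_similarity(fset.vectors[unit], fset.vectors[unit])
                    if not (rel > reliability_cutoff):
                        return False
                return True

            units_a = [u for u in fa.vectors if usable(u, fa, sa)]
            units_b = [u for u in fb.vectors if usable(u, fb, sb)]
            sims_match, sims_non = [], []
            for ua in units_a:
                for ub in units_b:
                    s = pair_similarity(fa.vectors[ua], fb.vectors[ub])
                    if not np.isfinite(s):
                        continue
                    if (ua, ub) in matched:
                        sims_match.append(s)
                    else:
                        sims_non.append(s)
            if not sims_match or not sims_non:
                continue
            rows.append(
                {
                    "session_i": sa,
                    "session_j": sb,
                    "delta_days": day_offsets[sb] - day_offsets[sa],
                    "auc": roc_auc(sims_match, sims_non),
                    "n_matched": len(matched),
                    "n_match_pairs": len(sims_match),
                    "n_nonmatch_pairs": len(sims_non),
                }
            )
    report = pd.DataFrame(
        rows,
        columns=[
            "session_i", "session_j", "delta_days", "auc",
            "n_matched", "n_match_pairs", "n_nonmatch_pairs",
        ],
    )
    if len(report) >= 2 and report["delta_days"].nunique() > 1:
        slope = float(np.polyfit(report["delta_days"], report["auc"], 1)[0])
    elif len(report) >= 1:
        slope = 0.0
    else:
        slope = np.nan
    report.attrs["auc_slope_per_day"] = slope
    return report


def normalized_response(
    rate: np.ndarray,
    time_bins: np.ndarray,
    baseline_window: tuple[float, float] = (-0.2, 0.0),
) -> np.ndarray:
    """Baseline-normalised response (R - <R>_baseline) / <R>_baseline.

    ``rate`` is a trial-averaged firing-rate trace on ``time_bins`` (bin
    centers, seconds, stimulus onset at 0).  A zero baseline makes the
    normalisation undefined; the trace is then all-NaN.
    """
    rate = np.asarray(rate, float)
    centers = np.asarray(time_bins, float)
    base_mask = (centers >= baseline_window[0]) & (centers < baseline_window[1])
    if not base_mask.any():
        raise ValidationError("baseline window contains no time bins")
    base = rate[base_mask].mean()
    if base == 0:
        return np.full_like(rate, np.nan)
    return (rate - base) / base


def cross_day_discrepancy(
    resp_day1: np.ndarray, resp_day2: np.ndarray, true_rms: bool = False
) -> float:
    """Across-day discrepancy of normalised responses.

    By default the plain sum over time bins of squared differences; with
    ``true_rms`` the square root of the mean squared difference instead.
    """
    a = np.asarray(resp_day1, float)
    b = np.asarray(resp_day2, float)
    if a.shape != b.shape:
        raise ValidationError("responses must share time bins")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        return np.nan
    sq = (a - b) ** 2
    return float(np.sqrt(sq.mean())) if true_rms else float(sq.sum())


def learning_stats(
    trains: dict[int, dict[int, np.ndarray]],
    stimuli: dict[int, pd.DataFrame],
    window: tuple[float, float] = (-0.2, 0.5),
    bin_s: float = 0.01,
    baseline_window: tuple[float, float] = (-0.2, 0.0),
    true_rms: bool = False,
) -> tuple[dict[int, dict[int, np.ndarray]], pd.DataFrame]:
    """Per-unit baseline-normalised stimulus responses and cross-day RMS.

    ``trains[day][unit]`` are spike times, ``stimuli[day]`` the stimulus
    table for that day.  Returns the normalised trial-averaged response
    trace per unit and day, and a table of pairwise cross-day
    discrepancies per unit.
    """
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    responses: dict[int, dict[int, np.ndarray]] = {}
    for day, day_trains in trains.items():
        onsets = stimuli[day]["onset_s"].to_numpy()
        responses[day] = {}
        for unit, t in day_trains.items():
            t = np.asarray(t, float)
            counts = np.zeros(centers.size)
            for onset in onsets:
                c, _ = np.histogram(t - onset, bins=edges)
                counts += c
            rate = counts / (len(onsets) * bin_s)
            responses[day][unit] = normalized_response(rate, centers, baseline_window)
    days = sorted(trains)
    rows = []
    for i in range(len(days)):
        for j in range(i + 1, len(days)):
            d1, d2 = days[i], days[j]
            for unit in set(responses[d1]) & set(responses[d2]):
                rows.append(
                    {
                        "unit_id": unit,
                        "day_1": d1,
                        "day_2": d2,
                        "rms": cross_day_discrepancy(
                            responses[d1][unit], responses[d2][unit], true_rms
                        ),
                    }
                )
    return responses, pd.DataFrame(rows, columns=["unit_id", "day_1", "day_2", "rms"])
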