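"""Seedable multi-session simulator with ground-truth correspondences.

Emulates the data the matcher assumes: each neuron has a biphasic
temporal spike template whose amplitude decays exponentially with
distance from its (fixed) position near a two-column probe; each session
applies a rigid positional drift to every neuron, multiplicative
amplitude jitter, survival draws (with optional replacement by newly
appearing neurons), and independent additive noise per recording half.
Spike trains are gamma-renewal processes with unit-specific shape and
rate, modulated by a shared population rate fluctuation; stimulus
sessions add natural-image responses with unit-specific per-image gains.

Everything is reproducible from the seed, and a ground-truth table maps
every session's unit ids back to persistent neuron identities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ProbeGeometry,
    SessionInfo,
    WaveformRecord,
    write_sessions_table,
    write_site_positions,
    write_spike_table,
    write_stimulus_table,
    write_waveform_store,
)


@dataclass
class SimConfig:
    """Synthetic study conditions.

    Defaults describe a desk-scale chronic recording: 60 neurons on a
    96-site two-column probe (32 um pitch), three sessions one day
    apart, 80% per-session survival, rigid drift up to 15 um per
    session, 10% amplitude jitter and per-unit waveform SNR of 20.
    """

    n_neurons: int = 60
    n_sessions: int = 3
    n_columns: int = 2
    n_rows: int = 72
    row_pitch_um: float = 20.0        # along the probe axis (Neuropixels-like)
    col_pitch_um: float = 32.0
    survival: float = 0.8
    replace_lost: bool = True
    drift_max_um: float = 15.0
    drifts: list[tuple[float, float]] | None = None  # explicit per-session
    amplitude_jitter: float = 0.1
    snr: float | None = 20.0          # per-spike SNR at the max site; None = noiseless
    amp_range_uv: tuple[float, float] = (80.0, 300.0)
    lambda_range: tuple[float, float] = (0.02, 0.08)
    sampling_rate: float = 30000.0
    n_samples: int = 82
    peak_sample: int = 40
    days_between: int = 1
    # spike trains
    with_spikes: bool = False
    duration_s: float = 1200.0
    rate_range_hz: tuple[float, float] = (0.5, 20.0)
    shape_range: tuple[float, float] = (0.5, 4.0)
    coupling_strength: float = 0.3
    # stimulus responses
    with_stimuli: bool = False
    n_images: int = 112
    n_repeats: int = 5
    stim_duration_s: float = 0.5
    intertrial_s: float = 0.8
    image_gain_range: tuple[float, float] = (0.2, 3.0)
    response_spikes_mean: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.survival <= 1:
            raise ValueError("survival must be a probability")
        if self.n_sessions < 1 or self.n_neurons < 1:
            raise ValueError("need at least one session and one neuron")
        if self.peak_sample <= 0 or self.peak_sample >= self.n_samples:
            raise ValueError("peak_sample must lie inside the trace")
        if self.drifts is not None and len(self.drifts) != self.n_sessions:
            raise ValueError("drifts must list one (dx, dy) per session")


def default_geometry(config: SimConfig) -> ProbeGeometry:
    """Column site grid with Neuropixels-like pitch (20 um along the axis)."""
    xs = np.arange(config.n_columns) * config.col_pitch_um
    ys = np.arange(config.n_rows) * config.row_pitch_um
    grid = np.array([(x, y) for y in ys for x in xs])
    return ProbeGeometry(grid)


@dataclass
class SessionSet:
    """In-memory simulated session set plus ground truth."""

    config: SimConfig
    geometry: ProbeGeometry
    sessions: list[SessionInfo]
    records: dict[int, list[WaveformRecord]]
    spike_tables: dict[int, pd.DataFrame]
    stimulus_tables: dict[int, pd.DataFrame]
    truth: pd.DataFrame
    neuron_params: pd.DataFrame

    @property
    def all_records(self) -> list[WaveformRecord]:
        out: list[WaveformRecord] = []
        for s in self.sessions:
            out.extend(self.records[s.session_id])
        return out

    def write(self, path: str | Path) -> None:
        """Write a self-contained directory consumable by the matcher CLI."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_site_positions(self.geometry, path / "site_positions.txt")
        write_sessions_table(self.sessions, path / "sessions.tsv")
        for s in self.sessions:
            sdir = path / f"session{s.session_id}"
            write_waveform_store(self.records[s.session_id], sdir)
            if s.session_id in self.spike_tables:
                write_spike_table(
                    self.spike_tables[s.session_id], sdir / "spikes.tsv"
                )
            if s.session_id in self.stimulus_tables:
                write_stimulus_table(
                    self.stimulus_tables[s.session_id], sdir / "stimuli.tsv"
                )
        self.truth.to_csv(path / "ground_truth.csv", index=False)
        self.neuron_params.to_csv(path / "neuron_params.csv", index=False)


def _template_params(rng: np.random.Generator, config: SimConfig) -> dict:
    """Random spike-shape parameters: three Gaussian lobes plus propagation.

    Shapes span the diversity of real average waveforms: narrow to broad
    troughs, variable repolarisation delay/width/height, an optional
    pre-peak positive deflection (tri-phasic shapes), and a signed
    conduction velocity that delays the waveform at sites away from the
    soma along the probe axis (what makes the spatial centroid travel
    during the spike).
    """
    params = {
        "t0": float(config.peak_sample),
        "trough_width": rng.uniform(1.5, 6.0),
        "bump_delay": rng.uniform(4.0, 18.0),
        "bump_width": rng.uniform(3.0, 12.0),
        "bump_frac": rng.uniform(0.1, 0.9),
        "pre_frac": rng.uniform(0.0, 0.35),
        "pre_lead": rng.uniform(3.0, 8.0),
        "pre_width": rng.uniform(1.5, 5.0),
        # samples of delay per micrometer along the axis (signed):
        # ~0.3-1.5 m/s conduction, toward either probe end
        "prop_slope": rng.choice([-1.0, 1.0]) * rng.uniform(0.02, 0.08),
    }
    base = _eval_template(params, np.arange(config.n_samples, dtype=float))
    trough_mag = -base.min()
    pos_max = base.max()
    # keep the trough the global extreme (as in real extracellular spikes)
    params["pos_scale"] = (
        0.95 * trough_mag / pos_max if pos_max > 0.95 * trough_mag else 1.0
    )
    base = _eval_template(params, np.arange(config.n_samples, dtype=float))
    params["norm"] = float(np.max(np.abs(base)))
    return params


def _eval_template(params: dict, t: np.ndarray) -> np.ndarray:
    """Evaluate the (unnormalised) spike shape at sample times ``t``."""
    t0 = params["t0"]
    out = -np.exp(-((t - t0) ** 2) / (2 * params["trough_width"] ** 2))
    pos = params["bump_frac"] * np.exp(
        -((t - t0 - params["bump_delay"]) ** 2) / (2 * params["bump_width"] ** 2)
    )
    pos += params["pre_frac"] * np.exp(
        -((t - t0 + params["pre_lead"]) ** 2) / (2 * params["pre_width"] ** 2)
    )
    out += params.get("pos_scale", 1.0) * pos
    return out / params.get("norm", 1.0)


def _spatiotemporal_signal(
    params: dict, positions: np.ndarray, pos: np.ndarray, lam: float,
    amplitude: float, n_samples: int,
) -> np.ndarray:
    """Noise-free waveform (T, S): delayed template scaled by spatial decay."""
    dist = np.linalg.norm(positions - pos, axis=1)
    site_amp = amplitude * np.exp(-lam * dist)
    delay = params["prop_slope"] * (positions[:, 1] - pos[1])
    tgrid = np.arange(n_samples, dtype=float)[:, None] - delay[None, :]
    return _eval_template(params, tgrid) * site_amp[None, :]


def _population_modulation(
    rng: np.random.Generator, n_points: int, smooth_bins: int = 20
) -> np.ndarray:
    """Smooth shared log-rate fluctuation with zero mean and unit sd."""
    z = rng.standard_normal(n_points + 2 * smooth_bins)
    kernel = np.ones(smooth_bins) / smooth_bins
    z = np.convolve(z, kernel, mode="same")[smooth_bins:-smooth_bins]
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def _gamma_renewal_train(
    rng: np.random.Generator,
    rate_hz: float,
    shape: float,
    duration_s: float,
    modulation: np.ndarray | None = None,
    coupling: float = 0.0,
    grid_dt: float = 0.01,
) -> np.ndarray:
    """Gamma-renewal spike train, optionally warped by a shared modulation.

    The train is generated in operational time (unit-rate gamma renewal
    with the requested shape) and mapped through the cumulative intensity
    of ``rate * exp(coupling * z)`` (normalised to preserve the mean
    rate), which couples all units sharing ``z``.
    """
    if modulation is None or coupling == 0.0:
        n_expect = int(rate_hz * duration_s * 1.5) + 20
        isis = rng.gamma(shape, 1.0 / (shape * rate_hz), size=n_expect)
        times = np.cumsum(isis)
        while times.size and times[-1] < duration_s:
            more = rng.gamma(shape, 1.0 / (shape * rate_hz), size=n_expect)
            times = np.concatenate([times, times[-1] + np.cumsum(more)])
        return times[times < duration_s]
    grid = np.arange(modulation.size) * grid_dt
    intensity = np.exp(coupling * modulation)
    intensity = intensity / intensity.mean() * rate_hz
    cum = np.concatenate([[0.0], np.cumsum(intensity) * grid_dt])
    total_mass = cum[-1]
    n_expect = int(total_mass * 1.5) + 20
    isis = rng.gamma(shape, 1.0 / shape, size=n_expect)
    ops = np.cumsum(isis)
    while ops.size and ops[-1] < total_mass:
        more = rng.gamma(shape, 1.0 / shape, size=n_expect)
        ops = np.concatenate([ops, ops[-1] + np.cumsum(more)])
    ops = ops[ops < total_mass]
    grid_edges = np.concatenate([grid, [modulation.size * grid_dt]])
    times = np.interp(ops, cum, grid_edges)
    return times[times < duration_s]


def _stimulus_table(
    rng: np.random.Generator, config: SimConfig
) -> pd.DataFrame:
    """Block-randomised image sequence: each repeat block permutes all images."""
    order = np.concatenate(
        [rng.permutation(config.n_images) for _ in range(config.n_repeats)]
    )
    period = config.stim_duration_s + config.intertrial_s
    onsets = 5.0 + np.arange(order.size) * period
    if onsets[-1] + config.stim_duration_s > config.duration_s:
        raise ValueError(
            "session too short for the stimulus protocol; increase duration_s"
        )
    return pd.DataFrame(
        {
            "stimulus_id": order.astype(int),
            "onset_s": onsets,
            "offset_s": onsets + config.stim_duration_s,
        }
    )


def generate_session_set(config: SimConfig) -> SessionSet:
    """Simulate waveform stores (and optionally spikes/stimuli) per session."""
    rng = np.random.default_rng(config.seed)
    geometry = default_geometry(config)
    positions = geometry.site_positions
    y_max = positions[:, 1].max()

    # --- persistent neuron population
    neurons: list[dict] = []

    def new_neuron(entry_session: int) -> dict:
        nid = len(neurons)
        margin = 60.0
        neuron = {
            "neuron_id": nid,
            "entry_session": entry_session,
            "x": rng.uniform(positions[:, 0].min(), positions[:, 0].max()),
            "y": rng.uniform(margin, y_max - margin),
            "amplitude": rng.uniform(*config.amp_range_uv),
            "decay_lambda": rng.uniform(*config.lambda_range),
            "template": _template_params(rng, config),
            "rate_hz": float(np.exp(rng.uniform(*np.log(config.rate_range_hz)))),
            "shape": rng.uniform(*config.shape_range),
            "coupling": rng.uniform(0.0, 2.0 * config.coupling_strength),
            "image_gains": np.exp(
                rng.uniform(*np.log(config.image_gain_range), size=config.n_images)
            ),
        }
        neurons.append(neuron)
        return neuron

    for _ in range(config.n_neurons):
        new_neuron(0)

    # --- per-session drift and survival
    if config.drifts is not None:
        step_drifts = [np.asarray(d, float) for d in config.drifts]
    else:
        # drift is predominantly axial (along the probe / depth axis), as
        # in chronic recordings; transverse drift is a small fraction
        step_drifts = [np.zeros(2)]
        for _ in range(1, config.n_sessions):
            mag = rng.uniform(0.3, 1.0) * config.drift_max_um
            sign = rng.choice([-1.0, 1.0])
            dx = rng.uniform(-0.15, 0.15) * mag
            step_drifts.append(np.array([dx, sign * mag]))
    cum_drift = np.cumsum(step_drifts, axis=0)

    alive = {n["neuron_id"]: True for n in neurons}
    presence: dict[int, list[int]] = {}
    for s in range(config.n_sessions):
        if s > 0:
            died = []
            for nid, ok in list(alive.items()):
                if ok and rng.uniform() > config.survival:
                    alive[nid] = False
                    died.append(nid)
            if config.replace_lost:
                for _ in died:
                    fresh = new_neuron(s)
                    alive[fresh["neuron_id"]] = True
        presence[s] = [nid for nid, ok in alive.items() if ok]

    sessions = [
        SessionInfo(session_id=s, day_offset=s * config.days_between)
        for s in range(config.n_sessions)
    ]

    records: dict[int, list[WaveformRecord]] = {}
    truth_rows = []
    spike_tables: dict[int, pd.DataFrame] = {}
    stimulus_tables: dict[int, pd.DataFrame] = {}

    for s in range(config.n_sessions):
        present = presence[s]
        unit_order = rng.permutation(len(present))
        unit_of = {nid: int(unit_order[k]) for k, nid in enumerate(present)}
        session_records = []
        for nid in present:
            neuron = neurons[nid]
            pos = np.array([neuron["x"], neuron["y"]]) + cum_drift[s]
            jitter = 1.0 + config.amplitude_jitter * rng.standard_normal()
            jitter = max(jitter, 0.2)
            amp_sess = neuron["amplitude"] * jitter
            dist = np.linalg.norm(positions - pos, axis=1)
            site_amp = amp_sess * np.exp(-neuron["decay_lambda"] * dist)
            signal = _spatiotemporal_signal(
                neuron["template"], positions, pos, neuron["decay_lambda"],
                amp_sess, config.n_samples,
            )
            sampled_amp = np.abs(signal).max(axis=0)  # per-site, on the grid
            wf = np.repeat(signal[:, :, None], 2, axis=2)
            if config.snr is not None and np.isfinite(config.snr):
                # The store holds a per-half *average* over that half's
                # spikes: residual noise is the per-spike noise (max-site
                # amplitude / snr) attenuated by sqrt(n spikes averaged).
                n_half = max(25, int(rng.poisson(neuron["rate_hz"] * config.duration_s / 2)))
                noise_sd = site_amp.max() / config.snr / np.sqrt(n_half)
                wf = wf + noise_sd * rng.standard_normal(wf.shape)
            max_site = int(np.argmax(sampled_amp))
            session_records.append(
                WaveformRecord(
                    unit_id=unit_of[nid],
                    session_id=s,
                    waveform=wf,
                    sampling_rate=config.sampling_rate,
                )
            )
            truth_rows.append(
                {
                    "neuron_id": nid,
                    "session_id": s,
                    "present": 1,
                    "unit_id": unit_of[nid],
                    "x": pos[0],
                    "y": pos[1],
                    "decay_lambda": neuron["decay_lambda"],
                    "amplitude": amp_sess,
                    "max_site": max_site,
                    "max_site_amplitude": float(sampled_amp[max_site]),
                    "drift_x": cum_drift[s][0],
                    "drift_y": cum_drift[s][1],
                }
            )
        # manifest order follows unit id for readability
        session_records.sort(key=lambda r: r.unit_id)
        records[s] = session_records

        if config.with_stimuli:
            stimulus_tables[s] = _stimulus_table(rng, config)
        if config.with_spikes:
            n_grid = int(np.ceil(config.duration_s / 0.01))
            z = _population_modulation(rng, n_grid)
            rows = []
            for nid in present:
                neuron = neurons[nid]
                times = _gamma_renewal_train(
                    rng,
                    neuron["rate_hz"],
                    neuron["shape"],
                    config.duration_s,
                    modulation=z,
                    coupling=neuron["coupling"],
                )
                if config.with_stimuli:
                    times = np.sort(
                        np.concatenate(
                            [times, _stimulus_spikes(rng, neuron, stimulus_tables[s], config)]
                        )
                    )
                rows.append(
                    pd.DataFrame({"unit_id": unit_of[nid], "spike_time_s": times})
                )
            spike_tables[s] = (
                pd.concat(rows, ignore_index=True)
                if rows
                else pd.DataFrame(columns=["unit_id", "spike_time_s"])
            )

    truth = pd.DataFrame(truth_rows)
    neuron_params = pd.DataFrame(
        [
            {
                "neuron_id": n["neuron_id"],
                "entry_session": n["entry_session"],
                "x": n["x"],
                "y": n["y"],
                "amplitude": n["amplitude"],
                "decay_lambda": n["decay_lambda"],
                "rate_hz": n["rate_hz"],
                "shape": n["shape"],
                "coupling": n["coupling"],
            }
            for n in neurons
        ]
    )
    return SessionSet(
        config=config,
        geometry=geometry,
        sessions=sessions,
        records=records,
        spike_tables=spike_tables,
        stimulus_tables=stimulus_tables,
        truth=truth,
        neuron_params=neuron_params,
    )


def _stimulus_spikes(
    rng: np.random.Generator,
    neuron: dict,
    stimuli: pd.DataFrame,
    config: SimConfig,
) -> np.ndarray:
    """Added stimulus-locked spikes with per-image gains (gamma latency)."""
    out = []
    gains = neuron["image_gains"]
    for row in stimuli.itertuples(index=False):
        mean_count = config.response_spikes_mean * gains[int(row.stimulus_id)]
        n = rng.poisson(mean_count)
        if n == 0:
            continue
        latencies = rng.gamma(2.0, 0.05, size=n)
        latencies = latencies[latencies < config.stim_duration_s]
        out.append(row.onset_s + latencies)
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def true_pairs(truth: pd.DataFrame, session_a: int, session_b: int) -> set:
    """Ground-truth unit-id correspondences between two sessions."""
    a = truth[truth["session_id"] == session_a].set_index("neuron_id")["unit_id"]
    b = truth[truth["session_id"] == session_b].set_index("neuron_id")["unit_id"]
    shared = a.index.intersection(b.index)
    return {(int(a[nid]), int(b[nid])) for nid in shared}


def score_against_truth(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    kind: str = "probability",
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Precision/recall of predicted correspondences per session pair.

    ``predicted`` is either a match table (kind='probability': pairs with
    match_probability > cutoff count as predicted matches) or a track
    table (kind='tracks': shared global_id counts).  Recall is measured
    over neurons present in both sessions; precision over the emitted
    pairs (NaN when none are emitted).
    """
    sessions = sorted(truth["session_id"].unique())
    rows = []
    for i in range(len(sessions)):
        for j in range(i + 1, len(sessions)):
            sa, sb = sessions[i], sessions[j]
            actual = true_pairs(truth, sa, sb)
            if kind == "probability":
                hit = predicted["match_probability"] > cutoff
                fwd = predicted[
                    hit & (predicted["session_i"] == sa) & (predicted["session_j"] == sb)
                ]
                rev = predicted[
                    hit & (predicted["session_i"] == sb) & (predicted["session_j"] == sa)
                ]
                emitted = {
                    (int(r.unit_i), int(r.unit_j)) for r in fwd.itertuples(index=False)
                } | {
                    (int(r.unit_j), int(r.unit_i)) for r in rev.itertuples(index=False)
                }
            elif kind == "tracks":
                ta = predicted[predicted["session_id"] == sa].set_index("global_id")["unit_id"]
                tb = predicted[predicted["session_id"] == sb].set_index("global_id")["unit_id"]
                shared = ta.index.intersection(tb.index)
                emitted = {(int(ta[g]), int(tb[g])) for g in shared}
            else:
                raise ValueError("kind must be 'probability' or 'tracks'")
            units_a = set(
                truth.loc[truth["session_id"] == sa, "unit_id"].astype(int)
            )
            units_b = set(
                truth.loc[truth["session_id"] == sb, "unit_id"].astype(int)
            )
            unknown = {
                (ua, ub) for ua, ub in emitted if ua not in units_a or ub not in units_b
            }
            if unknown:
                raise ValueError(f"predicted pairs reference unknown units: {unknown}")
            tp = len(emitted & actual)
            fp = len(emitted - actual)
            fn = len(actual - emitted)
            rows.append(
                {
                    "session_i": sa,
                    "session_j": sb,
                    "tp": tp,
                    "fp": fp,
                    "fn": fn,
                    "precision": tp / (tp + fp) if (tp + fp) else np.nan,
                    "recall": tp / (tp + fn) if (tp + fn) else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["session_i", "session_j", "tp", "fp", "fn", "precision", "recall"],
    )
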