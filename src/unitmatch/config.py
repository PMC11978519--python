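"""Pipeline configuration with the published default parameters."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class MatchConfig:
    """Tunable parameters of the matching pipeline.

    Attributes
    ----------
    pre_peak_ms, post_peak_ms : float
        Analysis window around the waveform peak, in milliseconds.  All
        waveform attributes are computed inside this window.
    max_radius_um : float
        Hard cap on the site-selection radius around the max site; sites
        further than this never contribute, even when the fitted 10%-decay
        distance ``d10`` is larger.
    amp_floor_uv : float
        Floor applied to per-site amplitudes before the log-space
        exponential-decay fit (keeps the log finite on noisy sites).
    d_max_um : float
        Centroid distance at which centroid similarity reaches 0.
    neighbor_radius_um : float
        Radius defining "neighboring units" for threshold estimation.
    percentile : float
        Upper percentile used by the 0-99 similarity rescaling.
    n_bins : int
        Number of histogram bins (on [0, 1]) for both the threshold scan
        and the naive-Bayes score densities.
    smooth_bins : int
        Moving-average width (bins) applied to the Bayes densities.
    density_floor : float
        Positive floor on the Bayes densities; prevents zero likelihoods.
    prior_mode : str
        'empirical' (fraction of putative matches) or 'flat' (0.5).
    rho_clip : float
        Correlations are clipped to ``±(1 - rho_clip)`` before the Fisher
        transform, which diverges at ``|rho| = 1``.
    match_probability_cutoff : float
        Posterior above which a pair is called a match.
    """

    pre_peak_ms: float = 0.23
    post_peak_ms: float = 0.50
    max_radius_um: float = 150.0
    amp_floor_uv: float = 0.1
    d_max_um: float = 100.0
    neighbor_radius_um: float = 50.0
    percentile: float = 99.0
    n_bins: int = 100
    smooth_bins: int = 3
    density_floor: float = 1e-6
    prior_mode: str = "empirical"
    rho_clip: float = 1e-6
    match_probability_cutoff: float = 0.5
    drift_correction: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.prior_mode not in ("empirical", "flat"):
            raise ValueError(f"unknown prior_mode {self.prior_mode!r}")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")

    @classmethod
    def from_file(cls, path: str | Path) -> "MatchConfig":
        """Read a flat ``key = value`` text file; unknown keys go to .extra."""
        known = {f.name: f.type for f in fields(cls) if f.name != "extra"}
        kwargs: dict = {}
        extra: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"cannot parse config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in known:
                kwargs[key] = _coerce(value, known[key])
            else:
                extra[key] = value
        return cls(**kwargs, extra=extra)


def _coerce(value: str, typ: str):
    if typ == "float":
        return float(value)
    if typ == "int":
        return int(value)
    if typ == "bool":
        return value.lower() in ("1", "true", "yes")
    return value
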