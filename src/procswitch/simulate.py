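"""Synthetic constant-force hairpin-unwinding traces and first-passage data.

The generative model has two layers.  A four-state continuous-time Markov
chain (low-processivity, high-processivity, dissociated, past-threshold)
simulated by the Gillespie direct method decides burst-level outcomes: the
helicase starts every unwinding attempt in the low state, may switch to the
high state (rate k1, set by the ssDNA-binding-protein concentration), cross
the 25 bp classification threshold from there (rate k2), or dissociate from
the low state (rate k_off).  A stepping layer then renders each attempt as a
piecewise-constant base-pairs-unwound trajectory built from 1 bp steps with
a slowdown in the GC-rich stall region near 10-15 bp: low-processivity
bursts stall there and backslide to the hairpin base, high-processivity
bursts push through and unwind up to the full 89 bp stem.

Transient protein-mediated duplex melting is superimposed as rectangular
+5 bp excursions arriving as a Poisson process of rate k_on * c with
exponentially distributed lifetimes (~20 ms), and i.i.d. Gaussian sensor
noise is added at the sampling rate.  Every injected step, melting pulse
and burst is returned in an injection log so detectors downstream can be
scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STATE_LOW = "low"
STATE_HIGH = "high"
STATE_OFF = "off"
STATE_CROSSED = "crossed"

#: bp threshold past which a molecule is scored high-processivity.
THRESHOLD_BP = 25.0
#: full hairpin stem, bp.
STEM_BP = 89


class ConfigurationError(ValueError):
    """Raised when a kinetic scheme has a transient state with no exit."""


@dataclass(frozen=True)
class KineticRates:
    """Rate constants of the four-state processivity-switch scheme, s^-1.

    k1 : low -> high (concentration dependent)
    k_minus1 : high -> low
    k2 : threshold crossing from high
    k_off : dissociation from low
    k_off_prime : dissociation from high (0 in the reference model)
    """

    k1: float
    k_minus1: float
    k2: float
    k_off: float
    k_off_prime: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2", "k_off", "k_off_prime"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SteppingParams:
    """Stepping-layer phenomenology of the rendered trajectories.

    The helicase unwinds in 1 bp steps; a fraction of steps are backsteps
    (sizes in [-2, 0) bp) or backslides (< -2 bp).  The stall region is the
    GC-rich section of the stem where forward stepping slows; low-
    processivity bursts terminate there.
    """

    step_size: float = 1.0
    forward_rate: float = 9.0            # stepping events / s off-stall
    backstep_prob: float = 0.20          # fraction of steps in [-2, 0)
    backslide_prob: float = 0.18         # fraction of steps < -2 bp
    stall_region: tuple[float, float] = (10.0, 15.0)
    stall_factor_low: float = 0.15       # rate multiplier in stall, low state
    stall_factor_high: float = 0.60      # rate multiplier in stall, high state
    stall_dwell_mean_s: float = 2.0      # extra dwell at the stall point
    rezip_rate: float = 25.0             # backslide events / s while rezipping
    backslide_size: float = 3.0          # bp per rezip backslide event
    release_recapture_size: float = 5.0  # nt, -5/+5 step pairs
    release_recapture_rate: float = 0.05  # events / s during unwinding
    bursts_per_molecule_mean: float = 5.0
    bursts_per_molecule_sd: float = 1.0
    interburst_pause_mean_s: float = 1.5

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        for p in (self.backstep_prob, self.backslide_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("step-type probabilities must be in [0, 1]")
        if self.backstep_prob + self.backslide_prob > 1.0:
            raise ValueError("step-type probabilities exceed 1")


@dataclass(frozen=True)
class MeltingParams:
    """Poisson arrival model for transient duplex-melting excursions."""

    k_on: float = 1.2e8        # M^-1 s^-1 effective second-order on-rate
    concentration: float = 0.0  # M
    amplitude: float = 5.0     # bp opened per event
    lifetime: float = 0.020    # s, mean of exponential event duration

    @property
    def event_rate(self) -> float:
        """Poisson arrival rate k_on * c, s^-1."""
        return self.k_on * self.concentration

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.lifetime <= 0:
            raise ValueError("amplitude and lifetime must be positive")
        if self.k_on < 0 or self.concentration < 0:
            raise ValueError("k_on and concentration must be non-negative")


@dataclass
class Trace:
    """A sampled constant-force trace of base pairs unwound vs. time."""

    time: np.ndarray           # s, uniform grid
    position: np.ndarray       # bp unwound
    force: float               # pN
    sampling_rate: float       # Hz
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.time.shape != self.position.shape:
            raise ValueError("time and position must have equal length")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate


@dataclass
class InjectionLog:
    """Ground truth for a simulated trace: what was actually injected."""

    steps: pd.DataFrame        # time_s, size_bp, kind
    melt_events: pd.DataFrame  # t_start_s, t_end_s, amplitude_bp, resolvable
    bursts: pd.DataFrame       # t_start_s, t_end_s, category, max_bp


@dataclass
class FirstPassageDataset:
    """Per-molecule threshold-crossing times grouped by concentration.

    ``frame`` columns: molecule_id, conc_nM, t_cross_s (NaN when censored),
    t_max_s.  A molecule that dissociated or ran out of observation time
    without crossing contributes a censored record.
    """

    frame: pd.DataFrame

    COLUMNS = ["molecule_id", "conc_nM", "t_cross_s", "t_max_s"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.frame["conc_nM"].unique())

    def empirical_fraction_crossed(self, conc_nM: float,
                                   t_grid: np.ndarray) -> np.ndarray:
        """Fraction of molecules at ``conc_nM`` that crossed by each time."""
        sub = self.frame[self.frame["conc_nM"] == conc_nM]
        times = sub["t_cross_s"].dropna().to_numpy()
        n = len(sub)
        if n == 0:
            return np.zeros_like(np.asarray(t_grid, dtype=float))
        return np.searchsorted(np.sort(times), t_grid, side="right") / n

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out["t_cross_s"] = out["t_cross_s"].map(
            lambda v: "censored" if pd.isna(v) else f"{v:.6f}")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FirstPassageDataset":
        df = pd.read_csv(path, sep="\t", comment="#")
        df["t_cross_s"] = pd.to_numeric(df["t_cross_s"], errors="coerce")
        return cls(df)


def _check_scheme(rates: KineticRates) -> None:
    if rates.k1 + rates.k_off == 0:
        raise ConfigurationError("low state has no exit (k1 = k_off = 0)")
    if rates.k1 > 0 and rates.k_minus1 + rates.k2 + rates.k_off_prime == 0:
        raise ConfigurationError(
            "high state is reachable but has no exit "
            "(k_minus1 = k2 = k_off_prime = 0)")


def simulate_state_path(rates: KineticRates, t_max: float,
                        seed_or_rng) -> list[tuple[str, float]]:
    """Gillespie direct-method path of the four-state scheme.

    Starts in the low-processivity state at t = 0; 'off' and 'crossed' are
    absorbing.  Returns the sequence of (state, entry_time) pairs, truncated
    at ``t_max`` (a path still transient at t_max simply ends there,
    representing censoring).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    _check_scheme(rates)
    rng = np.random.default_rng(seed_or_rng)
    t = 0.0
    state = STATE_LOW
    path = [(state, 0.0)]
    while t < t_max and state in (STATE_LOW, STATE_HIGH):
        if state == STATE_LOW:
            channels = [(rates.k1, STATE_HIGH), (rates.k_off, STATE_OFF)]
        else:
            channels = [(rates.k_minus1, STATE_LOW),
                        (rates.k2, STATE_CROSSED),
                        (rates.k_off_prime, STATE_OFF)]
        total = sum(r for r, _ in channels)
        t += rng.exponential(1.0 / total)
        if t >= t_max:
            break
        u = rng.uniform(0, total)
        acc = 0.0
        for r, nxt in channels:
            acc += r
            if u < acc:
                state = nxt
                break
        path.append((state, t))
    return path


def first_passage_time(rates: KineticRates, t_max: float,
                       seed_or_rng) -> float:
    """First time the path enters 'crossed', or NaN if censored by t_max
    or by dissociation."""
    path = simulate_state_path(rates, t_max, seed_or_rng)
    for state, t in path:
        if state == STATE_CROSSED:
            return t
    return np.nan


def simulate_first_passage(rates_by_conc: dict[float, KineticRates],
                           n_molecules: int, t_max: float,
                           seed) -> FirstPassageDataset:
    """Simulate ``n_molecules`` per concentration and record each molecule's
    threshold-crossing time (censored at dissociation or at ``t_max``).

    ``rates_by_conc`` maps concentration in nM to the rate set used there.
    The global seed is expanded into independent per-molecule substreams so
    per-molecule reproducibility survives reordering of concentrations.
    """
    records = []
    for conc in sorted(rates_by_conc):
        rates = rates_by_conc[conc]
        child_seeds = np.random.SeedSequence(
            [int(seed), int(round(conc * 1000))]).spawn(n_molecules)
        for i in range(n_molecules):
            t_cross = first_passage_time(
                rates, t_max, np.random.default_rng(child_seeds[i]))
            records.append({"molecule_id": f"c{conc:g}_m{i:04d}",
                            "conc_nM": conc, "t_cross_s": t_cross,
                            "t_max_s": t_max})
    frame = pd.DataFrame(records, columns=FirstPassageDataset.COLUMNS)
    return FirstPassageDataset(frame)


# ---------------------------------------------------------------------------
# stepping layer


def _walk_up(rng, stepping: SteppingParams, start: float, target: float,
             t0: float, rate_factor) -> tuple[list, float]:
    """Biased 1 bp random walk from start to target, reflecting at 0.

    Within the unwinding portion, steps are forward (+step_size) or
    backsteps (-step_size) with the backstep share of the configured
    step-type mix; backslides belong to the rezipping phase.  Returns
    (events, end_time) where events are (t, size, kind).
    """
    p_back = stepping.backstep_prob / (
        stepping.backstep_prob + (1.0 - stepping.backstep_prob
                                  - stepping.backslide_prob))
    pos, t = start, t0
    events = []
    lo, hi = stepping.stall_region
    while pos < target:
        rate = stepping.forward_rate * (
            rate_factor if lo <= pos <= hi else 1.0)
        t += rng.exponential(1.0 / rate)
        if rng.random() < p_back and pos > 0:
            size = -stepping.step_size
            kind = "backstep"
        else:
            size = stepping.step_size
            kind = "forward"
        pos += size
        events.append((t, size, kind))
    return events, t


def _rezip(rng, stepping: SteppingParams, start: float,
           t0: float) -> tuple[list, float]:
    """Rapid rezipping to the hairpin base through backslide steps."""
    pos, t = start, t0
    events = []
    while pos > 0:
        t += rng.exponential(1.0 / stepping.rezip_rate)
        size = -min(stepping.backslide_size, pos)
        pos += size
        events.append((t, size, "backslide"))
    return events, t


def _sample_melt_events(rng, melting: MeltingParams, duration: float,
                        dt: float) -> pd.DataFrame:
    rate = melting.event_rate
    rows = []
    if rate > 0:
        t = rng.exponential(1.0 / rate)
        while t < duration:
            lifetime = rng.exponential(melting.lifetime)
            t_end = min(t + lifetime, duration)
            # resolvable iff the pulse spans at least one sample instant
            resolvable = np.floor(t_end / dt) > np.floor(t / dt)
            rows.append({"t_start_s": t, "t_end_s": t_end,
                         "amplitude_bp": melting.amplitude,
                         "resolvable": bool(resolvable)})
            t += rng.exponential(1.0 / rate)
    return pd.DataFrame(
        rows, columns=["t_start_s", "t_end_s", "amplitude_bp", "resolvable"])


def _render(step_events, melt_frame, duration, sampling_rate,
            noise_sd, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample the piecewise-constant step path + melt pulses on the grid."""
    n = int(np.floor(duration * sampling_rate))
    t_grid = np.arange(n) / sampling_rate
    pos = np.zeros(n)
    if step_events:
        times = np.array([e[0] for e in step_events])
        sizes = np.array([e[1] for e in step_events])
        order = np.argsort(times, kind="stable")
        cum = np.cumsum(sizes[order])
        idx = np.searchsorted(times[order], t_grid, side="right")
        pos = np.where(idx > 0, cum[np.clip(idx - 1, 0, None)], 0.0)
    for _, ev in melt_frame.iterrows():
        mask = (t_grid >= ev.t_start_s) & (t_grid < ev.t_end_s)
        pos = pos + np.where(mask, ev.amplitude_bp, 0.0)
    pos = np.clip(pos, -2.0, STEM_BP + 3.0)
    if noise_sd > 0:
        pos = pos + rng.normal(0.0, noise_sd, size=n)
    return t_grid, pos


def simulate_trace(rates: KineticRates,
                   stepping: SteppingParams = SteppingParams(),
                   melting: MeltingParams = MeltingParams(),
                   force: float = 12.0,
                   duration: float = 120.0,
                   noise_sd: float = 0.3,
                   sampling_rate: float = 89.0,
                   seed=0) -> tuple[Trace, InjectionLog]:
    """Render one molecule's constant-force unwinding trace.

    Bursts are attempted sequentially (their number drawn from the
    configured per-molecule distribution); each attempt runs a fresh
    Gillespie path of the switch scheme truncated at the attempt's natural
    low-state duration, so an attempt during which the path reaches
    'crossed' is rendered as a high-processivity burst that pushes through
    the stall region, and all others stall near 10-15 bp and backslide to
    the hairpin base.  Melting pulses and Gaussian noise are superimposed.

    Returns the sampled trace and the injection log of ground-truth steps,
    melting events and bursts.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    dt = 1.0 / sampling_rate

    n_bursts = max(1, int(round(rng.normal(
        stepping.bursts_per_molecule_mean, stepping.bursts_per_molecule_sd))))
    step_events: list = []
    burst_rows = []
    t = rng.exponential(stepping.interburst_pause_mean_s)
    for _ in range(n_bursts):
        if t >= duration:
            break
        t_start = t
        target = rng.uniform(*stepping.stall_region)
        up, t = _walk_up(rng, stepping, 0.0, target, t,
                         stepping.stall_factor_low)
        t += rng.exponential(stepping.stall_dwell_mean_s)
        low_duration = t - t_start
        # burst-level outcome from the switch kinetics over this attempt
        crossed = not np.isnan(
            first_passage_time(rates, low_duration, rng)) if (
                rates.k1 > 0 and rates.k2 > 0) else False
        if crossed:
            # high-processivity attempt: the stall region is traversed at
            # the elevated rate with no terminal stall (re-rendered in
            # place of the low-phase walk)
            high_target = (float(STEM_BP) if rng.random() < 0.5
                           else float(rng.integers(int(THRESHOLD_BP) + 1,
                                                   STEM_BP)))
            events, t = _walk_up(rng, stepping, 0.0, high_target, t_start,
                                 stepping.stall_factor_high)
            peak = high_target
            category = "high"
        else:
            events = list(up)
            peak = target
            category = "low"
        down, t = _rezip(rng, stepping, peak, t)
        events += down
        # occasional release/recapture -5/+5 pairs during the burst
        n_rr = rng.poisson(stepping.release_recapture_rate * (t - t_start))
        for _ in range(n_rr):
            t_rr = rng.uniform(t_start, t_start + max(low_duration, dt))
            events.append((t_rr, -stepping.release_recapture_size,
                           "release"))
            events.append((t_rr + 5 * dt, stepping.release_recapture_size,
                           "recapture"))
        step_events += events
        burst_rows.append({"t_start_s": t_start, "t_end_s": t,
                           "category": category, "max_bp": peak,
                           "window_s": low_duration})
        t += rng.exponential(stepping.interburst_pause_mean_s)

    melt_frame = _sample_melt_events(rng, melting, duration, dt)
    t_grid, pos = _render(step_events, melt_frame, duration,
                          sampling_rate, noise_sd, rng)

    conc_nM = melting.concentration * 1e9
    trace = Trace(time=t_grid, position=pos, force=force,
                  sampling_rate=sampling_rate,
                  metadata={"rpa2_nM": conc_nM, "seed": int(seed),
                            "noise_sd_bp": noise_sd, "units": "bp"})
    steps = pd.DataFrame(
        sorted(step_events), columns=["time_s", "size_bp", "kind"]) \
        if step_events else pd.DataFrame(
            columns=["time_s", "size_bp", "kind"])
    log = InjectionLog(steps=steps, melt_events=melt_frame,
                       bursts=pd.DataFrame(
                           burst_rows, columns=["t_start_s", "t_end_s",
                                                "category", "max_bp",
                                                "window_s"]))
    return trace, log


def simulate_bare_hairpin(melting: MeltingParams,
                          duration: float = 500.0,
                          noise_sd: float = 0.3,
                          sampling_rate: float = 89.0,
                          seed=0,
                          force: float = 12.0) -> tuple[Trace, InjectionLog]:
    """Trace of a hairpin with no helicase bound: baseline zero plus
    transient melting excursions only."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    dt = 1.0 / sampling_rate
    melt_frame = _sample_melt_events(rng, melting, duration, dt)
    t_grid, pos = _render([], melt_frame, duration, sampling_rate,
                          noise_sd, rng)
    conc_nM = melting.concentration * 1e9
    trace = Trace(time=t_grid, position=pos, force=force,
                  sampling_rate=sampling_rate,
                  metadata={"rpa2_nM": conc_nM, "seed": int(seed),
                            "noise_sd_bp": noise_sd, "units": "bp"})
    empty_steps = pd.DataFrame(columns=["time_s", "size_bp", "kind"])
    empty_bursts = pd.DataFrame(
        columns=["t_start_s", "t_end_s", "category", "max_bp", "window_s"])
    return trace, InjectionLog(steps=empty_steps, melt_events=melt_frame,
                               bursts=empty_bursts)
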