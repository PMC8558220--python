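"""Synthetic two-pacemaker atrial excitation and downstream data generators.

The heart of this module is an event-driven lattice model of atrial
excitation driven by competing pacemakers.  Each pacemaker (e.g. the
sinoatrial region, SAR, and the atrioventricular canal, AVC) carries a
phase clock that fires when it reaches the pacemaker's intrinsic period;
a wavefront arriving at the pacemaker site first resets the clock, which
is the minimal mechanism of overdrive suppression: the fastest site
dictates the rhythm, and silencing it reveals the slower escape rhythm
of the latent pacemaker.

Wave propagation follows a straight-line eikonal rule (arrival time =
firing time + distance / conduction velocity) with an absolute
refractory period per pixel.  The emitted fluorescence emulates a
FRET-based voltage sensor (Mermaid-like): donor emission drops and
acceptor emission rises with depolarization, imaged on a split-frame
16-bit camera at 52 Hz.

All distances are in µm, times in ms, pixel coordinates are 0-based
(row, col).
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

LAYOUT_SPLIT = "left_donor_right_acceptor"
LAYOUT_SEPARATE = "separate_stacks"


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass
class PacemakerSpec:
    """A point source of automaticity on the lattice.

    Parameters
    ----------
    site : (row, col) pixel coordinate of the pacemaker.
    intrinsic_period : ms between spontaneous firings.
    period_jitter_sd : Gaussian SD (ms) added to each inter-firing period.
    pause_probability : per-scheduled-firing probability that the firing
        is skipped (a sinus pause).
    pause_duration : quiescent interval (ms) after a skipped firing before
        the phase clock restarts.
    enabled : disabled pacemakers never fire (but their site can still be
        excited by passing wavefronts).
    phase_offset_ms : time of the first scheduled firing.  Latent
        pacemakers should start mid-diastole (offset larger than the
        propagation time from the dominant site) so the first wave of the
        dominant pacemaker resets them before they ever fire.
    """

    site: tuple[int, int]
    intrinsic_period: float
    period_jitter_sd: float = 0.0
    pause_probability: float = 0.0
    pause_duration: float = 0.0
    enabled: bool = True
    phase_offset_ms: float = 0.0

    def validate(self) -> None:
        if self.intrinsic_period <= 0:
            raise ValueError("intrinsic_period must be > 0")
        if not 0.0 <= self.pause_probability <= 1.0:
            raise ValueError("pause_probability must be in [0, 1]")
        if self.period_jitter_sd < 0 or self.pause_duration < 0:
            raise ValueError("negative durations are not allowed")


@dataclass
class FretParams:
    donor_baseline: float = 30000.0      # counts (~half well depth, 16-bit)
    acceptor_baseline: float = 30000.0   # counts
    donor_fractional_drop: float = 0.05
    acceptor_fractional_rise: float = 0.05


@dataclass
class NoiseModel:
    shot_noise_scale: float = 1.0   # 0 disables shot noise
    gaussian_read_sd: float = 20.0  # counts; 0 disables read noise


@dataclass
class SimConfig:
    """Full description of one simulated optical-mapping acquisition."""

    grid_shape: tuple[int, int] = (128, 64)  # per-channel (rows, cols)
    pixel_size: float = 10.0                 # µm / pixel
    frame_rate: float = 52.0                 # Hz
    duration: float = 10.0                   # s
    pacemakers: list[PacemakerSpec] = field(default_factory=list)
    conduction_velocity: float = 10.0        # µm / ms (~1 cm/s, immature myocardium)
    refractory_period: float = 200.0         # ms
    ap_upstroke_duration: float = 20.0       # ms
    ap_duration: float = 150.0               # ms
    fret_params: FretParams = field(default_factory=FretParams)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    camera_bit_depth: int = 16

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.conduction_velocity <= 0:
            raise ValueError("conduction_velocity must be > 0")
        if self.refractory_period < self.ap_upstroke_duration:
            raise ValueError("refractory_period must be >= ap_upstroke_duration")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if min(self.grid_shape) < 1:
            raise ValueError("grid must be non-empty")
        fp = self.fret_params
        if fp.donor_baseline <= 0 or fp.acceptor_baseline <= 0:
            raise ValueError("channel baselines must be > 0")
        for beta in (fp.donor_fractional_drop, fp.acceptor_fractional_rise):
            if not 0.0 <= beta < 1.0:
                raise ValueError("fractional changes must be in [0, 1)")
        for pm in self.pacemakers:
            pm.validate()
            r, c = pm.site
            if not (0 <= r < self.grid_shape[0] and 0 <= c < self.grid_shape[1]):
                raise ValueError(f"pacemaker site {pm.site} outside grid")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Truth container produced by :func:`simulate_activation_events`.

    ``firing_events`` is ordered by time; ``activation_times`` holds one
    2D array (ms; NaN where a pixel was refractory and never excited by
    that beat) per realized beat, aligned with ``realized_beat_times``.
    """

    firing_events: list[tuple[float, int, tuple[int, int]]]
    activation_times: list[np.ndarray]
    realized_beat_times: np.ndarray


@dataclass
class TwoChannelMovie:
    """Raw camera frames plus the metadata needed to un-pack them.

    For the split layout ``frames`` has shape (T, rows, 2*cols) with the
    donor on the left half; for ``separate_stacks`` it has shape
    (2, T, rows, cols) with channel 0 = donor.
    """

    frames: np.ndarray
    frame_rate: float
    layout: str = LAYOUT_SPLIT
    bit_depth: int = 16


# ---------------------------------------------------------------------------
# event-driven excitation model
# ---------------------------------------------------------------------------

def simulate_activation_events(config: SimConfig, seed: int) -> GroundTruth:
    """Run the two-pacemaker lattice model and return the full ground truth.

    Discrete-event simulation over two event kinds: pacemaker firings and
    wavefront arrivals at pixels.  A firing at site *s*, time *t* excites
    pixel *p* at ``t + dist(p, s) / v`` unless *p* fired within the
    refractory period; concurrent waves race, and each pixel takes the
    earliest admissible arrival.  An admissible arrival at a latent
    pacemaker's site resets its phase clock (overdrive suppression).
    """
    config.validate()
    enabled = [i for i, pm in enumerate(config.pacemakers) if pm.enabled]
    if not enabled:
        raise ValueError("silent heart: no enabled pacemaker")

    rng = np.random.default_rng(seed)
    nrow, ncol = config.grid_shape
    duration_ms = config.duration * 1000.0
    v = config.conduction_velocity
    refr = config.refractory_period

    rr, cc = np.mgrid[0:nrow, 0:ncol]
    site_of = {config.pacemakers[i].site: i for i in enabled}

    last_excited = np.full((nrow, ncol), -np.inf)
    generation = {i: 0 for i in enabled}

    FIRE, ARRIVE = 0, 1
    counter = itertools.count()
    heap: list[tuple] = []

    def draw_period(pm: PacemakerSpec) -> float:
        p = pm.intrinsic_period
        if pm.period_jitter_sd > 0:
            p += rng.normal(0.0, pm.period_jitter_sd)
        return max(p, 1.0)

    def schedule_fire(i: int, t: float) -> None:
        generation[i] += 1
        if t < duration_ms:
            heapq.heappush(heap, (t, FIRE, next(counter), i, generation[i]))

    for i in enabled:
        pm = config.pacemakers[i]
        schedule_fire(i, pm.phase_offset_ms)

    firing_events: list[tuple[float, int, tuple[int, int]]] = []
    activation_maps: list[np.ndarray] = []

    while heap:
        item = heapq.heappop(heap)
        t, kind = item[0], item[1]
        if kind == FIRE:
            _, _, _, i, gen = item
            if gen != generation[i]:
                continue  # superseded by a reset
            pm = config.pacemakers[i]
            if pm.pause_probability > 0 and rng.random() < pm.pause_probability:
                # sinus pause: skip, stay quiescent, then restart the clock
                schedule_fire(i, t + pm.pause_duration + draw_period(pm))
                continue
            r0, c0 = pm.site
            if t - last_excited[r0, c0] < refr:
                schedule_fire(i, t + draw_period(pm))
                continue
            beat_id = len(firing_events)
            firing_events.append((t, i, pm.site))
            activation_maps.append(np.full((nrow, ncol), np.nan))
            dist = np.hypot(rr - r0, cc - c0) * config.pixel_size
            arrivals = t + dist / v
            for r in range(nrow):
                for c in range(ncol):
                    heapq.heappush(
                        heap, (arrivals[r, c], ARRIVE, next(counter), r, c, beat_id, i)
                    )
            schedule_fire(i, t + draw_period(pm))
        else:
            _, _, _, r, c, beat_id, origin_pm = item
            if t - last_excited[r, c] >= refr:
                last_excited[r, c] = t
                activation_maps[beat_id][r, c] = t
                j = site_of.get((r, c))
                if j is not None and j != origin_pm:
                    pm_j = config.pacemakers[j]
                    schedule_fire(j, t + draw_period(pm_j))

    # keep beats that excited at least one pixel (always true for the origin)
    keep = [b for b, m in enumerate(activation_maps) if np.isfinite(m).any()]
    return GroundTruth(
        firing_events=[firing_events[b] for b in keep],
        activation_times=[activation_maps[b] for b in keep],
        realized_beat_times=np.array([firing_events[b][0] for b in keep]),
    )


# ---------------------------------------------------------------------------
# action-potential waveform and fluorescence rendering
# ---------------------------------------------------------------------------

def ap_template(tau: np.ndarray, upstroke_ms: float, apd_ms: float) -> np.ndarray:
    """Normalized action-potential waveform evaluated at ``tau`` ms after
    activation: logistic upstroke (max slope at ``upstroke_ms/2``) rising
    0→1 over ``upstroke_ms``, a plateau, then exponential repolarization,
    zero outside ``[0, apd_ms]``.

    The logistic steepness is set so the 10–90% rise time is ~80% of
    ``upstroke_ms``, i.e. the nominal upstroke duration describes the
    actual rise of the waveform."""
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    u, apd = float(upstroke_ms), float(apd_ms)
    k = 5.5 / u

    def logistic(x):
        return 1.0 / (1.0 + np.exp(-k * (x - u / 2.0)))

    s0, s1 = logistic(0.0), logistic(u)
    m = (tau >= 0) & (tau < u)
    out[m] = (logistic(tau[m]) - s0) / (s1 - s0)
    plateau_end = u + 0.3 * (apd - u)
    out[(tau >= u) & (tau < plateau_end)] = 1.0
    tau_rep = 0.7 * (apd - u) / 3.0
    m = (tau >= plateau_end) & (tau < apd)
    out[m] = np.exp(-(tau[m] - plateau_end) / tau_rep)
    return out


def render_voltage(gt: GroundTruth, config: SimConfig) -> np.ndarray:
    """Per-pixel membrane-voltage stack (T, rows, cols), normalized 0–1.

    Each beat contributes ``template(t - t_act(p))``; overlapping beats
    superpose by maximum (the simulator's refractory rule guarantees no
    two activations of one pixel are closer than the refractory period).
    """
    t_ms = np.arange(config.n_frames) / config.frame_rate * 1000.0
    volt = np.zeros((config.n_frames,) + tuple(config.grid_shape))
    for act in gt.activation_times:
        tau = t_ms[:, None, None] - act[None, :, :]
        with np.errstate(invalid="ignore"):
            contrib = ap_template(np.nan_to_num(tau, nan=-1.0),
                                  config.ap_upstroke_duration, config.ap_duration)
        contrib[:, ~np.isfinite(act)] = 0.0
        np.maximum(volt, contrib, out=volt)
    return volt


def render_fret_movie(voltage: np.ndarray, config: SimConfig, seed: int,
                      layout: str = LAYOUT_SPLIT) -> TwoChannelMovie:
    """Turn a 0–1 voltage stack into noisy two-channel camera counts.

    Donor dims and acceptor brightens with depolarization:
    ``donor = D0 (1 - βD V)``, ``acceptor = A0 (1 + βA V)``; Poisson shot
    noise (scaled) plus Gaussian read noise, quantized and clipped to the
    camera bit depth.
    """
    if np.nanmin(voltage) < -1e-9 or np.nanmax(voltage) > 1 + 1e-9:
        raise ValueError("voltage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fp, nm = config.fret_params, config.noise_model
    donor = fp.donor_baseline * (1.0 - fp.donor_fractional_drop * voltage)
    acceptor = fp.acceptor_baseline * (1.0 + fp.acceptor_fractional_rise * voltage)

    def add_noise(mean):
        x = mean
        if nm.shot_noise_scale > 0:
            x = rng.poisson(mean / nm.shot_noise_scale) * nm.shot_noise_scale
        if nm.gaussian_read_sd > 0:
            x = x + rng.normal(0.0, nm.gaussian_read_sd, size=mean.shape)
        return x

    max_count = 2 ** config.camera_bit_depth - 1
    donor_n = add_noise(donor)
    acceptor_n = add_noise(acceptor)
    clipped_low = (donor_n <= 0).mean() + (acceptor_n <= 0).mean()
    if clipped_low / 2 > 0.01:
        warnings.warn("more than 1% of pixels clipped at zero; baselines too low")
    donor_q = np.clip(np.rint(donor_n), 0, max_count)
    acceptor_q = np.clip(np.rint(acceptor_n), 0, max_count)
    dtype = np.uint16 if config.camera_bit_depth <= 16 else np.uint32
    if layout == LAYOUT_SPLIT:
        frames = np.concatenate([donor_q, acceptor_q], axis=2).astype(dtype)
    elif layout == LAYOUT_SEPARATE:
        frames = np.stack([donor_q, acceptor_q]).astype(dtype)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return TwoChannelMovie(frames=frames, frame_rate=config.frame_rate,
                           layout=layout, bit_depth=config.camera_bit_depth)


def simulate_fret_movie(config: SimConfig, seed: int,
                        layout: str = LAYOUT_SPLIT
                        ) -> tuple[TwoChannelMovie, GroundTruth]:
    """Convenience: events → voltage → noisy two-channel movie."""
    gt = simulate_activation_events(config, seed)
    voltage = render_voltage(gt, config)
    movie = render_fret_movie(voltage, config, seed + 1, layout=layout)
    return movie, gt


# ---------------------------------------------------------------------------
# trace- and table-level generators
# ---------------------------------------------------------------------------

def simulate_voltage_trace(period_ms: float, duration_s: float = 20.0,
                           frame_rate: float = 52.0, snr: float = 20.0,
                           seed: int = 0, jitter_sd_ms: float = 0.0,
                           upstroke_ms: float = 20.0,
                           apd_ms: float = 150.0,
                           start_ms: float = 100.0) -> np.ndarray:
    """Single-pixel ratiometric-like voltage trace: a periodic train of
    action potentials sampled at ``frame_rate`` with additive Gaussian
    noise of SD ``1/snr`` (signal amplitude is 1).  The first beat sits
    ``start_ms`` into the recording so its upstroke is not clipped by
    the trace boundary."""
    rng = np.random.default_rng(seed)
    t_ms = np.arange(int(round(duration_s * frame_rate))) / frame_rate * 1000.0
    beat_times = []
    t = float(start_ms)
    while t < duration_s * 1000.0:
        beat_times.append(t)
        step = period_ms + (rng.normal(0, jitter_sd_ms) if jitter_sd_ms > 0 else 0.0)
        t += max(step, 1.0)
    trace = np.zeros_like(t_ms)
    for tb in beat_times:
        np.maximum(trace, ap_template(t_ms - tb, upstroke_ms, apd_ms), out=trace)
    if snr > 0:
        trace = trace + rng.normal(0.0, 1.0 / snr, size=trace.shape)
    return trace


def simulate_contraction_video(beat_times: np.ndarray, config: SimConfig,
                               seed: int, pulse_width_ms: float = 150.0,
                               noise_sd: float = 0.05,
                               frame_shape: tuple[int, int] = (32, 32)
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Videography stand-in: a single-channel frame stack of a contracting
    disc plus the scalar area/intensity trace (one smooth raised-cosine
    pulse per beat, additive noise).  Returns ``(frames, trace)``."""
    beat_times = np.asarray(beat_times, dtype=float)
    if np.any(np.diff(beat_times) < 0):
        raise ValueError("beat_times must be sorted")
    frame_interval_ms = 1000.0 / config.frame_rate
    if beat_times.size >= 2 and np.min(np.diff(beat_times)) < 2 * frame_interval_ms:
        raise ValueError("beat spacing below the Nyquist limit of the frame rate")
    rng = np.random.default_rng(seed)
    t_ms = np.arange(config.n_frames) / config.frame_rate * 1000.0
    w = min(pulse_width_ms,
            0.8 * np.min(np.diff(beat_times)) if beat_times.size >= 2 else pulse_width_ms)
    pulse = np.zeros_like(t_ms)
    for tb in beat_times:
        tau = t_ms - tb
        m = (tau >= 0) & (tau < w)
        pulse[m] += 0.5 * (1.0 - np.cos(2.0 * np.pi * tau[m] / w))
    trace = pulse + rng.normal(0.0, noise_sd, size=pulse.shape)
    h, wd = frame_shape
    yy, xx = np.mgrid[0:h, 0:wd]
    disc = (np.hypot(yy - h / 2, xx - wd / 2) < min(h, wd) / 3).astype(float)
    frames = (1.0 - 0.3 * trace)[:, None, None] * disc[None, :, :]
    frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return frames, trace


def simulate_rate_groups(group_specs: list[tuple[float, float, int]], seed: int,
                         labels: list[str] | None = None) -> pd.DataFrame:
    """Per-embryo heart-rate samples for groups given as (mean bpm, SEM, n).

    Values are drawn from Normal(mean, sd = SEM·√n), i.e. the population
    whose sampling distribution of the mean has the stated SEM.
    """
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(group_specs))]
    rows = []
    for label, (mean, sem, n) in zip(labels, group_specs):
        if n < 2:
            raise ValueError("each group needs n >= 2")
        if sem <= 0:
            raise ValueError("SEM must be > 0")
        values = rng.normal(mean, sem * np.sqrt(n), size=n)
        for j, bpm in enumerate(values):
            rows.append({"embryo_id": f"{label}_{j + 1}", "group": label,
                         "bpm": float(bpm)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential-expression tables with planted truth
# ---------------------------------------------------------------------------

DEFAULT_EFFECT_PARAMS = {
    "lfc_lo": 2.5, "lfc_hi": 6.0,       # |log2FC| range of true effects
    "null_lfc_sd": 1.0,
    "lincrna_fraction": 0.10, "other_fraction": 0.05,
}


def generate_de_table(n_genes: int, enriched_fraction: float,
                      depleted_fraction: float,
                      effect_size_params: dict | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """DESeq2-like result table with truth labels.

    Truth-enriched genes get log2FC strictly above 2 and padj below 0.05
    by construction; truth-null genes deliberately straddle the two
    thresholds one at a time (large fold change with non-significant padj,
    and vice versa) so that threshold filters are exercised at their
    boundaries.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if enriched_fraction + depleted_fraction > 1:
        raise ValueError("fractions must sum to <= 1")
    p = dict(DEFAULT_EFFECT_PARAMS, **(effect_size_params or {}))
    rng = np.random.default_rng(seed)
    n_enr = int(round(n_genes * enriched_fraction))
    n_dep = int(round(n_genes * depleted_fraction))
    n_null = n_genes - n_enr - n_dep

    def effect_lfc(size, sign):
        return sign * rng.uniform(p["lfc_lo"], p["lfc_hi"], size)

    lfc = np.concatenate([
        effect_lfc(n_enr, +1),
        effect_lfc(n_dep, -1),
        rng.normal(0.0, p["null_lfc_sd"], n_null),
    ])
    padj = np.concatenate([
        10 ** rng.uniform(-8, np.log10(0.049), n_enr),
        10 ** rng.uniform(-8, np.log10(0.049), n_dep),
        rng.uniform(0.05, 1.0, n_null),
    ])
    # make a third of nulls straddle one threshold each
    if n_null >= 6:
        third = n_null // 3
        base = n_enr + n_dep
        sl = slice(base, base + third)
        lfc[sl] = rng.uniform(2.1, 4.0, third) * rng.choice([-1, 1], third)
        padj[sl] = rng.uniform(0.06, 1.0, third)          # big FC, not significant
        sl2 = slice(base + third, base + 2 * third)
        lfc[sl2] = rng.uniform(-1.5, 1.5, third)
        padj[sl2] = rng.uniform(1e-4, 0.049, third)       # significant, small FC
    truth = (["enriched"] * n_enr + ["depleted"] * n_dep + ["null"] * n_null)
    biotype = rng.choice(
        ["protein_coding", "lincRNA", "other"], size=n_genes,
        p=[1 - p["lincrna_fraction"] - p["other_fraction"],
           p["lincrna_fraction"], p["other_fraction"]])
    tpm_neg = rng.lognormal(2.0, 1.0, n_genes)
    tpm_pos = tpm_neg * 2.0 ** lfc
    table = pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
        "biotype": biotype,
        "log2FC": lfc,
        "padj": padj,
        "tpm_gfp_pos": tpm_pos,
        "tpm_gfp_neg": tpm_neg,
        "truth_label": truth,
    })
    return table.sample(frac=1.0, random_state=int(rng.integers(2**31))
                        ).reset_index(drop=True)


def make_marker_set(members: set[str], n_overlap: int, n_novel: int,
                    seed: int = 0, prefix: str = "marker") -> set[str]:
    """Marker list planting an overlap of exactly ``n_overlap`` genes with
    ``members`` plus ``n_novel`` ids absent from it."""
    if n_overlap > len(members):
        raise ValueError("n_overlap exceeds the source set size")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(sorted(members), size=n_overlap, replace=False)
    novel = {f"{prefix}_novel{i:04d}" for i in range(n_novel)}
    return set(chosen) | novel


def make_ortholog_map(genes: list[str], seed: int = 0,
                      mapped_fraction: float = 0.9,
                      multi_fraction: float = 0.1) -> pd.DataFrame:
    """Zebrafish→human ortholog pairs: a ``mapped_fraction`` of genes get a
    unique symbol, of which ``multi_fraction`` get a second symbol
    (many-to-many)."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        if rng.random() > mapped_fraction:
            continue
        sym = "HS_" + g.upper()
        rows.append({"zebrafish_id": g, "human_symbol": sym})
        if rng.random() < multi_fraction:
            rows.append({"zebrafish_id": g, "human_symbol": sym + "B"})
    return pd.DataFrame(rows, columns=["zebrafish_id", "human_symbol"])


def make_disease_table(orthomap: pd.DataFrame, terms: list[str],
                       target_genes: list[str], seed: int = 0) -> pd.DataFrame:
    """Disease-term annotations planting hits for exactly ``target_genes``:
    every listed zebrafish gene gets ≥1 of ``terms`` through one of its
    orthologs (a random subset get several terms, exercising the
    count-once-per-gene rule)."""
    rng = np.random.default_rng(seed)
    by_gene = orthomap.groupby("zebrafish_id")["human_symbol"].apply(list)
    rows = []
    for g in target_genes:
        if g not in by_gene.index:
            raise ValueError(f"gene {g} has no ortholog in the map")
        syms = by_gene[g]
        n_terms = 1 + int(rng.random() < 0.3)
        for term in rng.choice(terms, size=n_terms, replace=False):
            rows.append({"human_symbol": syms[int(rng.integers(len(syms)))],
                         "term": term})
    return pd.DataFrame(rows, columns=["human_symbol", "term"]).drop_duplicates()


# ---------------------------------------------------------------------------
# study-condition factories
# ---------------------------------------------------------------------------

SAR_PERIOD_WT_48HPF = 60000.0 / 176.0   # ms, control rate at 48 hpf
AVC_PERIOD_DEFAULT = 600.0              # ms; escape rate is not quantified
                                        # in vivo — placeholder default


def two_pacemaker_config(grid_shape: tuple[int, int] = (64, 64),
                         sar_period_ms: float = SAR_PERIOD_WT_48HPF,
                         avc_period_ms: float = AVC_PERIOD_DEFAULT,
                         duration_s: float = 10.0,
                         sar_enabled: bool = True,
                         sar_pause_probability: float = 0.0,
                         sar_pause_duration_ms: float = 800.0,
                         jitter_sd_ms: float = 0.0,
                         **overrides) -> SimConfig:
    """Canonical SAR-vs-AVC sheet: SAR at the top edge (venous pole), AVC
    at the bottom edge.  The AVC starts mid-diastole so the SAR's first
    wave resets it before its own first firing."""
    nrow, ncol = grid_shape
    sar = PacemakerSpec(site=(2, ncol // 2), intrinsic_period=sar_period_ms,
                        period_jitter_sd=jitter_sd_ms,
                        pause_probability=sar_pause_probability,
                        pause_duration=sar_pause_duration_ms,
                        enabled=sar_enabled)
    avc = PacemakerSpec(site=(nrow - 3, ncol // 2), intrinsic_period=avc_period_ms,
                        period_jitter_sd=jitter_sd_ms,
                        phase_offset_ms=avc_period_ms / 2.0)
    return SimConfig(grid_shape=grid_shape, duration=duration_s,
                     pacemakers=[sar, avc], **overrides)
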