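"""Synthetic multi-channel EEG cohorts for the two acquisition protocols.

The generator emulates what the identification pipeline actually measures:
between-channel correlation structure that is stable within a subject and
different between subjects.  Each subject is a linear spatial-mixing model —
a fixed ``channels x sources`` mixing matrix applied to a small set of latent
sources (alpha-band oscillators plus 1/f "pink" background processes) with
independent per-channel sensor noise on top.  The eyes-closed (EC) protocol
records that background alone; the visual-stimulation (VS) protocol adds
stimulus-locked event-related potential (ERP) deflections, modelled as
Gaussian-windowed bumps with a per-subject latency, width, amplitude and
scalp topography.  Ocular (blink) artifacts are stereotyped low-frequency
transients weighted toward the frontal channels and can be injected on
demand with their ground-truth onsets recorded for downstream tests.

All amplitudes are in microvolts.  Every draw is a pure function of the
parameter set's ``rng_seed`` (plus a fixed protocol tag), so recordings are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from eegauth.exceptions import EmptyInputError

#: Electrode montage of a 14-channel consumer headset, International 10-20 positions.
CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Channels dominated by ocular activity; blink artifacts load here.
FRONTAL_CHANNELS: tuple[str, ...] = ("AF3", "AF4", "F7", "F8")

N_CHANNELS = len(CHANNELS)

# Latent source layout: two alpha oscillators + four 1/f background processes.
N_ALPHA_SOURCES = 2
N_NOISE_SOURCES = 4
N_SOURCES = N_ALPHA_SOURCES + N_NOISE_SOURCES

# Protocol tags folded into the RNG stream so EC and VS backgrounds differ.
_EC_STREAM = 11
_VS_STREAM = 12
_BLINK_STREAM = 13

_BLINK_DURATION_S = 0.3

# Lead-in / tail around the stimulus schedule so the widest epoch window
# ([-1.0, +1.0] s in the alternative convention) fits around every onset.
VS_LEAD_IN_S = 2.0
VS_TAIL_S = 2.0


@dataclass(frozen=True)
class ErpComponent:
    """One stimulus-locked deflection: a Gaussian bump in time with a scalp map.

    ``width_ms`` is the Gaussian standard deviation.  ``topography`` holds one
    unitless weight per channel; the bump added to channel ``c`` is
    ``amplitude_uv * topography[c] * exp(-(t - latency)^2 / (2 width^2))``.
    """

    latency_ms: float
    width_ms: float
    amplitude_uv: float
    topography: np.ndarray

    def __post_init__(self) -> None:
        topo = np.asarray(self.topography, dtype=float)
        if topo.shape != (N_CHANNELS,):
            raise ValueError(
                f"topography must have {N_CHANNELS} weights, got {topo.shape}"
            )
        object.__setattr__(self, "topography", topo)
        if self.amplitude_uv < 0:
            raise ValueError("amplitude_uv must be >= 0")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")


@dataclass(frozen=True)
class SubjectGenParams:
    """Generative parameters of one subject (their spatial/temporal fingerprint)."""

    subject_id: str
    mixing_matrix: np.ndarray  # channels x sources, unitless spatial fingerprint
    alpha_peak_hz: float
    alpha_amplitude_uv: float
    erp_components: tuple[ErpComponent, ...]
    noise_exponent: float  # 1/f^exponent spectral slope of background sources
    background_amplitude_uv: float
    sensor_noise_uv: float  # per-channel white noise RMS
    blink_rate_hz: float
    blink_amplitude_uv: float
    rng_seed: int
    #: spread of the per-stimulus ERP amplitude/latency jitter (single-trial
    #: response variability); fraction for amplitude, scaled ms for latency
    erp_trial_jitter: float = 0.1

    def __post_init__(self) -> None:
        mix = np.asarray(self.mixing_matrix, dtype=float)
        if mix.ndim != 2 or mix.shape[0] != N_CHANNELS:
            raise ValueError(f"mixing_matrix must be {N_CHANNELS} x sources")
        if np.linalg.matrix_rank(mix) < mix.shape[1]:
            raise ValueError("mixing_matrix must have full column rank")
        object.__setattr__(self, "mixing_matrix", mix)
        for name in (
            "alpha_amplitude_uv", "background_amplitude_uv",
            "sensor_noise_uv", "blink_rate_hz", "blink_amplitude_uv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.alpha_peak_hz <= 0:
            raise ValueError("alpha_peak_hz must be > 0")

    def generative_fields(self) -> dict:
        """The statistical parameters, excluding identity (subject_id, rng_seed).

        Two subjects with equal generative fields are draws from the same
        distribution — the ``separation = 0`` degenerate cohort.
        """
        return {
            "mixing_matrix": self.mixing_matrix,
            "alpha_peak_hz": self.alpha_peak_hz,
            "alpha_amplitude_uv": self.alpha_amplitude_uv,
            "erp_components": self.erp_components,
            "noise_exponent": self.noise_exponent,
            "background_amplitude_uv": self.background_amplitude_uv,
            "sensor_noise_uv": self.sensor_noise_uv,
            "blink_rate_hz": self.blink_rate_hz,
            "blink_amplitude_uv": self.blink_amplitude_uv,
            "erp_trial_jitter": self.erp_trial_jitter,
        }


@dataclass(frozen=True)
class EventSchedule:
    """Timed stimulus presentation: 1 s word on screen, 1 s black screen."""

    onsets_s: np.ndarray
    stimulus_duration_s: float = 1.0
    gap_duration_s: float = 1.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        if onsets.ndim != 1 or onsets.size == 0:
            raise EmptyInputError("schedule must contain at least one onset")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        object.__setattr__(self, "onsets_s", onsets)

    @property
    def n_stimuli(self) -> int:
        return int(self.onsets_s.size)

    @property
    def total_duration_s(self) -> float:
        """Presentation time: each stimulus plus its following black screen."""
        return self.n_stimuli * (self.stimulus_duration_s + self.gap_duration_s)


@dataclass
class Recording:
    """Continuous multi-channel EEG with protocol metadata.

    ``signal`` is channels x samples in microvolts; ``events`` holds stimulus
    onset sample indices (empty for EC).  ``meta`` carries generator ground
    truth (e.g. injected blink onsets) for oracle use in tests.
    """

    signal: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    protocol: str  # "EC" or "VS"
    events: np.ndarray
    subject_id: str
    session_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError("channel count must equal label count")
        if self.protocol not in ("EC", "VS"):
            raise ValueError("protocol must be 'EC' or 'VS'")
        if self.events.size and np.any(np.diff(self.events) <= 0):
            raise ValueError("events must be strictly increasing")
        if self.events.size and (
            self.events[0] < 0 or self.events[-1] >= self.signal.shape[1]
        ):
            raise ValueError("events must lie within the signal")

    @property
    def n_samples(self) -> int:
        return int(self.signal.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(
            signal=self.signal.copy(),
            fs=self.fs,
            channel_labels=self.channel_labels,
            protocol=self.protocol,
            events=self.events.copy(),
            subject_id=self.subject_id,
            session_id=self.session_id,
            meta=dict(self.meta),
        )


def _channel_weights(weights: dict[str, float], default: float = 0.0) -> np.ndarray:
    out = np.full(N_CHANNELS, default, dtype=float)
    for label, w in weights.items():
        out[CHANNELS.index(label)] = w
    return out

# Base scalp maps for the two canonical ERP components.  Posterior/occipital
# loading for the early visual component, centro-parietal for the late one.
_N170_TOPO = _channel_weights(
    {"O1": 1.0, "O2": 1.0, "P7": 0.8, "P8": 0.8, "T7": 0.3, "T8": 0.3}, default=0.1
)
_P300_TOPO = _channel_weights(
    {"P7": 1.0, "P8": 1.0, "O1": 0.5, "O2": 0.5, "FC5": 0.4, "FC6": 0.4}, default=0.2
)

_BLINK_TOPO = _channel_weights(
    {"AF3": 1.0, "AF4": 1.0, "F7": 0.7, "F8": 0.7, "F3": 0.4, "F4": 0.4}, default=0.05
)


def make_cohort(
    n_subjects: int,
    seed: int,
    separation: float = 1.0,
    *,
    alpha_amplitude_uv: float = 10.0,
    background_amplitude_uv: float = 5.0,
    sensor_noise_uv: float = 2.0,
    blink_rate_hz: float = 0.2,
    blink_amplitude_uv: float = 150.0,
    erp_trial_jitter: float = 0.1,
) -> list[SubjectGenParams]:
    """Draw a cohort of subject parameter sets.

    ``separation`` scales every between-subject deviation from the shared
    base parameters.  The spatial fingerprint interpolates between a common
    base matrix and a fully independent per-subject draw — ``mix =
    normalize((1 - separation) * base + separation * delta)`` — so
    ``separation = 0`` gives all subjects identical generative parameters
    (only their noise seeds differ; the pipeline's identification accuracy
    collapses to chance) and ``separation = 1`` gives completely independent
    spatial fingerprints, the natural meaning of a well-separated cohort.
    Alpha peak frequency spreads over the typical 8-12 Hz range at
    ``separation = 1``; alpha amplitude, 1/f slope and the ERP parameters
    spread proportionally around their base values.

    Deterministic for a fixed ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if separation < 0:
        raise ValueError("separation must be >= 0")

    base_rng = np.random.default_rng([int(seed), 0])
    # Shared base spatial fingerprint; column-scaled so source amplitudes are
    # carried by the amplitude parameters, not the mixing weights.
    base_mix = base_rng.normal(size=(N_CHANNELS, N_SOURCES))
    base_mix /= np.linalg.norm(base_mix, axis=0, keepdims=True)

    cohort: list[SubjectGenParams] = []
    for i in range(n_subjects):
        rng = np.random.default_rng([int(seed), 1, i])
        delta = rng.normal(size=(N_CHANNELS, N_SOURCES))
        delta /= np.linalg.norm(delta, axis=0, keepdims=True)
        mix = (1.0 - separation) * base_mix + separation * delta
        mix /= np.linalg.norm(mix, axis=0, keepdims=True)

        erp = (
            ErpComponent(
                latency_ms=170.0 + separation * rng.uniform(-30.0, 30.0),
                width_ms=30.0 * (1.0 + separation * rng.uniform(-0.2, 0.2)),
                amplitude_uv=5.0 * (1.0 + separation * rng.uniform(-0.4, 0.4)),
                topography=np.clip(
                    _N170_TOPO + separation * 0.3 * rng.normal(size=N_CHANNELS),
                    0.0, None,
                ),
            ),
            ErpComponent(
                latency_ms=320.0 + separation * rng.uniform(-40.0, 40.0),
                width_ms=60.0 * (1.0 + separation * rng.uniform(-0.2, 0.2)),
                amplitude_uv=5.0 * (1.0 + separation * rng.uniform(-0.4, 0.4)),
                topography=np.clip(
                    _P300_TOPO + separation * 0.3 * rng.normal(size=N_CHANNELS),
                    0.0, None,
                ),
            ),
        )

        cohort.append(
            SubjectGenParams(
                subject_id=f"S{i + 1:02d}",
                mixing_matrix=mix,
                alpha_peak_hz=10.0 + separation * rng.uniform(-2.0, 2.0),
                alpha_amplitude_uv=alpha_amplitude_uv
                * (1.0 + separation * rng.uniform(-0.3, 0.3)),
                erp_components=erp,
                noise_exponent=1.0 + separation * rng.uniform(-0.2, 0.2),
                background_amplitude_uv=background_amplitude_uv,
                sensor_noise_uv=sensor_noise_uv,
                blink_rate_hz=blink_rate_hz,
                blink_amplitude_uv=blink_amplitude_uv,
                rng_seed=int(
                    np.random.default_rng([int(seed), 2, i]).integers(2**31)
                ),
                erp_trial_jitter=erp_trial_jitter,
            )
        )
    return cohort


def session_params(
    params: SubjectGenParams,
    session: int,
    intra_subject_var: float | None = None,
) -> SubjectGenParams:
    """Derive one recording session's parameters from a subject's.

    Session-to-session (morning vs afternoon) variability is modelled as
    fresh realizations: a new noise seed, hence new background draws and new
    per-stimulus ERP amplitude/latency jitter (see ``erp_trial_jitter``,
    overridable here via ``intra_subject_var``).  The subject's parameters
    themselves — spatial fingerprint, rhythm and mean ERP shape — are
    treated as fixed traits.  Keeping the session effect at the realization
    level (rather than a session-constant parameter offset) is deliberate:
    with one recording per subject and session, any session-constant offset
    would be a recording-identity watermark that makes even an
    identical-parameter (zero-separation) cohort identifiable, destroying
    the pipeline's chance-level null calibration.
    """
    rng = np.random.default_rng([params.rng_seed, 3, int(session)])
    return replace(
        params,
        erp_trial_jitter=(
            params.erp_trial_jitter if intra_subject_var is None
            else intra_subject_var
        ),
        rng_seed=int(rng.integers(2**31)),
    )


def build_schedule(
    n_stimuli: int,
    stimulus_duration_s: float = 1.0,
    gap_duration_s: float = 1.0,
) -> EventSchedule:
    """Equally spaced word-presentation schedule: onsets at 0, 2, 4, ... s."""
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    spacing = stimulus_duration_s + gap_duration_s
    return EventSchedule(
        onsets_s=np.arange(n_stimuli) * spacing,
        stimulus_duration_s=stimulus_duration_s,
        gap_duration_s=gap_duration_s,
    )


#: Gaussian spectral width of the resting-rhythm band (Hz); the sub-second
#: envelope/phase coherence this implies keeps neighbouring analysis frames
#: of one recording from acting as near-duplicates of each other, while the
#: band stays narrow enough for subjects' peak frequencies to be resolvable.
ALPHA_BANDWIDTH_HZ = 1.5

#: Low-frequency corner of the 1/f background (Hz): the spectrum is flat
#: below it, as an acquisition high-pass would leave it.  It bounds the
#: correlation time of the background to well under a second.
PINK_CORNER_HZ = 3.0


def _source_shapes(params: SubjectGenParams, freqs: np.ndarray) -> np.ndarray:
    """Target magnitude spectrum of each latent source on the given bins."""
    shapes = np.zeros((N_SOURCES, freqs.size))
    for k in range(N_ALPHA_SOURCES):
        # second oscillator sits 0.5 Hz above the peak: a finite-width alpha band
        f_k = params.alpha_peak_hz + 0.5 * k
        shapes[k] = np.exp(-0.5 * ((freqs - f_k) / ALPHA_BANDWIDTH_HZ) ** 2)
    for k in range(N_NOISE_SOURCES):
        shapes[N_ALPHA_SOURCES + k] = (
            np.maximum(freqs, PINK_CORNER_HZ) ** (-params.noise_exponent / 2.0)
        )
    shapes[:, 0] = 0.0  # no DC in the sources; electrode drift is added separately
    return shapes


def _deterministic_rms(mag: np.ndarray, n: int) -> float:
    """Exact RMS of ``irfft(mag * exp(i*phase), n)`` — independent of phases."""
    if n % 2 == 0:
        total = mag[0] ** 2 + 2.0 * np.sum(mag[1:-1] ** 2) + mag[-1] ** 2
    else:
        total = mag[0] ** 2 + 2.0 * np.sum(mag[1:] ** 2)
    return float(np.sqrt(total)) / n


def _source_bank(
    params: SubjectGenParams, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS latent sources with exact spectra, whitened per recording.

    Each source is synthesised from its target magnitude spectrum with
    uniformly random phases, so every recording realises its ensemble power
    spectrum exactly (only the phases are random).  The bank is then ZCA
    whitened — the realised source covariance is mapped to the exact
    identity, which barely perturbs each source (off-diagonal realised
    correlations are O(1/sqrt(n))) but removes them entirely.  Net effect:
    a recording's second-order statistics are pinned to the ensemble values
    instead of fluctuating around them, leaving the between-channel
    correlation structure to the mixing matrix alone.  This exactness is
    what the zero-separation null calibration of the downstream pipeline
    rests on: realised deviations of band power or source cross-covariance
    would act as recording-identity fingerprints that a cross-validation
    splitting trials of the same recording could exploit even when all
    subjects share identical parameters.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    n_bins = freqs.size
    shapes = _source_shapes(params, freqs)
    sources = np.empty((N_SOURCES, n))
    for k in range(N_SOURCES):
        mag = shapes[k]
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_bins)
        phases[0] = 0.0
        if n % 2 == 0:
            phases[-1] = 0.0  # Nyquist coefficient must be real
        source = np.fft.irfft(mag * np.exp(1j * phases), n)
        rms = _deterministic_rms(mag, n)
        sources[k] = source / rms if rms > 0 else source

    # ZCA whitening: realised covariance -> exact identity
    cov = sources @ sources.T / n
    vals, vecs = np.linalg.eigh(cov)
    inv_sqrt = vecs @ np.diag(1.0 / np.sqrt(np.maximum(vals, 1e-12))) @ vecs.T
    return inv_sqrt @ sources


def _background(
    params: SubjectGenParams, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Spatially mixed alpha + 1/f sources plus sensor noise and DC drift."""
    if params.alpha_peak_hz >= fs / 2.0:
        raise ValueError("alpha_peak_hz must be below the Nyquist frequency")
    sources = _source_bank(params, n, fs, rng)
    amps = np.concatenate([
        np.full(N_ALPHA_SOURCES, params.alpha_amplitude_uv),
        np.full(N_NOISE_SOURCES, params.background_amplitude_uv),
    ])
    signal = params.mixing_matrix @ (amps[:, None] * sources)
    if params.sensor_noise_uv > 0:
        signal += params.sensor_noise_uv * rng.normal(size=signal.shape)
        # slow electrode drift: a per-channel DC offset the band-pass removes
        signal += 5.0 * params.sensor_noise_uv * rng.normal(size=(N_CHANNELS, 1))
    return signal


def simulate_ec(
    params: SubjectGenParams,
    duration_s: float = 30.0,
    fs: float = 256.0,
    session_id: str = "S1",
) -> Recording:
    """Simulate an eyes-closed resting recording (default 30 s at 256 Hz)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng([params.rng_seed, _EC_STREAM])
    signal = _background(params, n, fs, rng)
    return Recording(
        signal=signal,
        fs=fs,
        channel_labels=CHANNELS,
        protocol="EC",
        events=np.array([], dtype=int),
        subject_id=params.subject_id,
        session_id=session_id,
    )


def simulate_vs(
    params: SubjectGenParams,
    schedule: EventSchedule,
    fs: float = 256.0,
    session_id: str = "S1",
) -> Recording:
    """Simulate a visual-stimulation recording with stimulus-locked ERPs.

    The recording spans a lead-in, the full presentation schedule, and a
    tail, so that every epoch window around every onset fits within the
    signal.  Each stimulus adds the subject's ERP components with
    per-stimulus amplitude and latency jitter of spread
    ``params.erp_trial_jitter`` — the single-trial response variability seen
    in time-locked averaging.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    duration_s = VS_LEAD_IN_S + schedule.total_duration_s + VS_TAIL_S
    n = int(round(duration_s * fs))
    rng = np.random.default_rng([params.rng_seed, _VS_STREAM])
    signal = _background(params, n, fs, rng)

    events = np.round((VS_LEAD_IN_S + schedule.onsets_s) * fs).astype(int)
    jitter = params.erp_trial_jitter
    for component in params.erp_components:
        width_s = component.width_ms / 1000.0
        # window generously covers latency + jitter + 4 sigma of the bump
        half = int(np.ceil((abs(component.latency_ms) / 1000.0
                            + 4.0 * width_s + 0.05) * fs))
        rel = np.arange(-half, half + 1) / fs
        topo = component.topography[:, None]
        for onset in events:
            amp = component.amplitude_uv * (1.0 + jitter * rng.uniform(-1.0, 1.0))
            lat_s = (component.latency_ms + jitter * rng.uniform(-20.0, 20.0)) / 1000.0
            bump = amp * np.exp(-0.5 * ((rel - lat_s) / width_s) ** 2)
            lo, hi = onset - half, onset + half + 1
            src_lo = max(0, -lo)
            src_hi = bump.size - max(0, hi - n)
            signal[:, max(0, lo) : min(n, hi)] += (
                topo * bump[None, src_lo:src_hi]
            )

    return Recording(
        signal=signal,
        fs=fs,
        channel_labels=CHANNELS,
        protocol="VS",
        events=events,
        subject_id=params.subject_id,
        session_id=session_id,
    )


def inject_blinks(recording: Recording, params: SubjectGenParams) -> Recording:
    """Add stereotyped ocular artifacts; ground-truth onsets go into ``meta``.

    Blinks are a homogeneous Poisson process at ``blink_rate_hz``; each blink
    is a 300 ms raised-cosine transient of ``blink_amplitude_uv`` peak
    amplitude, loaded on the frontal channels.  With a zero rate the recording
    is returned unchanged (a copy).
    """
    if params.blink_rate_hz < 0:
        raise ValueError("blink_rate_hz must be >= 0")
    out = recording.copy()
    out.meta.setdefault("blink_onsets", np.array([], dtype=int))
    if params.blink_rate_hz == 0 or params.blink_amplitude_uv == 0:
        return out

    fs = recording.fs
    n = recording.n_samples
    rng = np.random.default_rng(
        [params.rng_seed, _BLINK_STREAM, 0 if recording.protocol == "EC" else 1]
    )
    width = int(round(_BLINK_DURATION_S * fs))
    # raised cosine over [0, 300 ms]: smooth onset and offset, peak mid-blink
    blink = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(width) / width))
    waveform = params.blink_amplitude_uv * _BLINK_TOPO[:, None] * blink[None, :]

    n_blinks = rng.poisson(params.blink_rate_hz * n / fs)
    onsets = np.sort(rng.integers(0, max(1, n - width), size=n_blinks))
    for onset in onsets:
        out.signal[:, onset : onset + width] += waveform
    out.meta["blink_onsets"] = onsets.astype(int)
    out.meta["blink_duration_samples"] = width
    return out
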