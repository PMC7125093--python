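"""Synthetic EEG-like epoch sets with controllable subject signatures.

The generator emulates the shape of the study data — by default 26 subjects,
56 channels, two sessions of 25 one-second epochs sampled at 200 Hz — without
claiming biophysical realism.  Each subject owns a signature: a small set of
carrier oscillations (frequencies drawn from the 6-30 Hz band, subject-
specific amplitudes) projected onto the informative channels through
subject-specific loadings, plus an ERP-like transient bump peaking near
300 ms after epoch onset.  Every channel additionally receives independent
1/f ("pink") background noise, the spectral shape typical of EEG, which
stresses EMD more realistically than white noise would.  Session-to-session
amplitude jitter models non-stationarity between recording days.

Non-informative channels carry only background noise, giving ground-truth
"informative" channels against which channel-selection recovery can be
scored — the real study has no such ground truth, so this synthetic hook is
the only way to test selection behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import DEFAULT_MONTAGE_56, EpochSet, SubjectSplit

__all__ = ["SyntheticSpec", "generate_epochset", "make_benchmark_instance"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic EEG generator.

    Amplitudes are in microvolts.  ``informative_channels`` lists the 0-based
    channel indices carrying subject signatures; all other channels receive
    background noise only.  ``session_jitter`` is the relative standard
    deviation of the per-session amplitude perturbation.
    """

    n_subjects: int = 26
    n_sessions: int = 2
    epochs_per_session: int = 25
    n_channels: int = 56
    sampling_rate: float = 200.0
    epoch_seconds: float = 1.0
    informative_channels: tuple[int, ...] = tuple(range(10))
    n_carriers: int = 3
    carrier_freq_range: tuple[float, float] = (6.0, 30.0)
    signature_amplitude: float = 8.0
    erp_amplitude: float = 6.0
    erp_latency: float = 0.3
    erp_width: float = 0.05
    noise_exponent: float = 1.0
    noise_level: float = 2.0
    session_jitter: float = 0.1
    distinct_signatures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_sessions, self.epochs_per_session,
               self.n_channels) < 1:
            raise ValueError("all counts must be >= 1")
        if self.sampling_rate <= 0 or self.epoch_seconds <= 0:
            raise ValueError("sampling_rate and epoch_seconds must be > 0")
        bad = [c for c in self.informative_channels
               if not 0 <= c < self.n_channels]
        if bad:
            raise ValueError(f"informative channels out of range: {bad}")
        if not self.informative_channels:
            raise ValueError("need at least one informative channel")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.epoch_seconds))


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                exponent: float, level: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit-free level."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    spectrum = (rng.standard_normal((n_channels, len(freqs)))
                + 1j * rng.standard_normal((n_channels, len(freqs)))) * shaping
    noise = np.fft.irfft(spectrum, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(noise ** 2, axis=1, keepdims=True))
    return level * noise / np.maximum(rms, 1e-12)


def _montage_for(n_channels: int) -> tuple[str, ...]:
    if n_channels <= len(DEFAULT_MONTAGE_56):
        return DEFAULT_MONTAGE_56[:n_channels]
    extra = tuple(f"X{i}" for i in range(n_channels - len(DEFAULT_MONTAGE_56)))
    return DEFAULT_MONTAGE_56 + extra


def generate_epochset(spec: SyntheticSpec) -> EpochSet:
    """Generate a reproducible :class:`EpochSet` following ``spec``.

    Epoch model per subject s, session r, epoch e, channel c:

        x[c, t] = loading[s, c] * (sum_k A[s, k] * sin(2 pi f[s, k] t + phase)
                  + ERP bump) * (1 + session jitter[r]) + pink noise

    with loadings nonzero only on informative channels.  With
    ``distinct_signatures`` (the default) the subject parameters are assigned
    by stratified slots — each carrier band, the amplitude scale and the
    spatial loading profile are divided into one slot per subject and dealt
    out by independent random permutations — so any two subjects are
    guaranteed to differ in several signature coordinates at once, the way
    distinct individuals do.  Without it all parameters are free random
    draws, which deliberately allows near-collisions between subjects (the
    "hard" regime).  The same seed always produces a bitwise-identical set.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_samples
    t = np.arange(n_samples) / spec.sampling_rate
    informative = np.array(sorted(spec.informative_channels))
    montage = _montage_for(spec.n_channels)

    bump = np.exp(-0.5 * ((t - spec.erp_latency) / spec.erp_width) ** 2)

    lo, hi = spec.carrier_freq_range

    # a subject's own carriers should sit at least half an octave apart so
    # EMD resolves them as stable modes; narrow carrier ranges (as in the
    # "hard" benchmark) cannot honour that, so the requirement is capped at
    # what the band geometrically allows
    if spec.n_carriers > 1:
        min_ratio = min(1.5, 0.8 * (hi / lo) ** (1.0 / (spec.n_carriers - 1)))
    else:
        min_ratio = 1.0

    def draw_carriers() -> np.ndarray:
        while True:
            f = np.sort(rng.uniform(lo, hi, size=spec.n_carriers))
            if spec.n_carriers == 1 or np.all(f[1:] / f[:-1] >= min_ratio):
                return f

    n_subj, n_carr = spec.n_subjects, spec.n_carriers
    subj_freqs = np.empty((n_subj, n_carr))
    subj_amps = np.empty((n_subj, n_carr))
    subj_loadings = np.zeros((n_subj, spec.n_channels))
    if spec.distinct_signatures:
        log_edges = np.log(np.geomspace(lo, hi, n_carr + 1))
        freq_perms = [rng.permutation(n_subj) for _ in range(n_carr)]
        amp_perms = [rng.permutation(n_subj) for _ in range(n_carr)]
        amp_levels = np.linspace(0.4, 1.6, n_subj)
        load_profile = np.linspace(0.4, 1.0, len(informative))
        for s in range(n_subj):
            for k in range(n_carr):
                pos = (freq_perms[k][s] + rng.uniform(0.3, 0.7)) / n_subj
                width = log_edges[k + 1] - log_edges[k]
                subj_freqs[s, k] = np.exp(log_edges[k] + pos * width)
                subj_amps[s, k] = (spec.signature_amplitude
                                   * amp_levels[amp_perms[k][s]]
                                   * rng.uniform(0.95, 1.05))
            subj_loadings[s, informative] = rng.permutation(load_profile)
    else:
        for s in range(n_subj):
            subj_freqs[s] = draw_carriers()
            subj_amps[s] = spec.signature_amplitude * rng.uniform(
                0.4, 1.6, size=n_carr)
            subj_loadings[s, informative] = rng.uniform(
                0.5, 1.0, size=len(informative))

    epochs: dict[tuple[str, str], np.ndarray] = {}
    for s in range(spec.n_subjects):
        subject = f"S{s + 1:02d}"
        freqs = subj_freqs[s]
        amps = subj_amps[s]
        erp_amp = spec.erp_amplitude * rng.uniform(0.5, 1.5)
        loadings = subj_loadings[s]
        for r in range(spec.n_sessions):
            session = str(r + 1)
            jitter = 1.0 + spec.session_jitter * rng.standard_normal()
            block = np.empty((spec.epochs_per_session, spec.n_channels, n_samples))
            for e in range(spec.epochs_per_session):
                phases = rng.uniform(0, 2 * np.pi, size=spec.n_carriers)
                carrier = np.sum(
                    amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :]
                                           + phases[:, None]),
                    axis=0,
                )
                signature = carrier + erp_amp * bump
                block[e] = loadings[:, None] * signature[None, :] * jitter
                block[e] += _pink_noise(rng, spec.n_channels, n_samples,
                                        spec.noise_exponent, spec.noise_level)
            epochs[(subject, session)] = block
    return EpochSet(montage=montage, sampling_rate=spec.sampling_rate, epochs=epochs)


#: Frozen benchmark generator settings.  "easy" has well-separated subject
#: signatures and low noise, so the full pipeline should approach perfect
#: metrics; "hard" crowds the carrier band and raises noise and session
#: jitter so the metrics stay clearly below 1.  Sizes are kept small enough
#: that feature extraction and optimization run in minutes on one CPU.
_BENCHMARK_SPECS: dict[str, SyntheticSpec] = {
    "easy": SyntheticSpec(
        n_subjects=8, n_sessions=2, epochs_per_session=25, n_channels=16,
        informative_channels=tuple(range(5)), n_carriers=3,
        carrier_freq_range=(6.0, 30.0), signature_amplitude=10.0,
        erp_amplitude=8.0, noise_level=1.2, session_jitter=0.04,
    ),
    "hard": SyntheticSpec(
        n_subjects=8, n_sessions=2, epochs_per_session=12, n_channels=16,
        informative_channels=tuple(range(5)), n_carriers=2,
        carrier_freq_range=(9.0, 12.0), signature_amplitude=2.5,
        erp_amplitude=1.5, noise_level=4.0, session_jitter=0.4,
        distinct_signatures=False,
    ),
}


def make_benchmark_instance(difficulty: str, seed: int = 0
                            ) -> tuple[EpochSet, SubjectSplit, frozenset[int]]:
    """A ready-made (EpochSet, SubjectSplit, informative channel set) triple.

    The split enrols the first half of the subjects as non-intruders and
    casts the second half as intruders, mirroring the manual 50/50 subject
    subdivision protocol.
    """
    try:
        base = _BENCHMARK_SPECS[difficulty]
    except KeyError:
        raise ValueError(f"unknown difficulty {difficulty!r}; "
                         f"choose from {sorted(_BENCHMARK_SPECS)}") from None
    spec = replace(base, seed=seed)
    epochset = generate_epochset(spec)
    subjects = epochset.subjects
    half = len(subjects) // 2
    split = SubjectSplit(non_intruders=subjects[:half], intruders=subjects[half:])
    return epochset, split, frozenset(spec.informative_channels)
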