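"""Synthetic raw signals and feature-level cohorts with known ground truth.

Two generators back the test oracles downstream:

* :func:`simulate_oscillatory_channel` builds a single-channel recording as a
  1/f background plus band-limited carriers under boxcar burst envelopes, with
  optional 60 Hz line tone and spike artifacts. Boxcar envelopes keep the true
  burst intervals exact, so burst detection can be scored against them.
* :func:`simulate_feature_cohort` builds a subjects x features cohort in which
  a sparse rank-1 latent factor couples the morphometric and physiological
  blocks at a controllable correlation, with optional confound couplings.

Ground truth is returned alongside every output and is never consumed by
estimation code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signals import Recording, FeatureConfig, physio_feature_names
from .morph import morph_feature_names

__all__ = [
    "BurstSpec",
    "ArtifactSpec",
    "SignalSimConfig",
    "LatentCohortConfig",
    "GroundTruth",
    "simulate_oscillatory_channel",
    "simulate_coupled_channels",
    "simulate_feature_cohort",
    "inject_artifacts",
    "one_over_f_noise",
]


@dataclass(frozen=True)
class BurstSpec:
    """Amplitude-modulated carrier: boxcar bursts on a constant baseline."""

    band: str
    carrier_hz: float
    rate_hz: float = 0.0  # bursts per second
    duration_s: float = 0.3
    amplitude: float = 1.0
    baseline: float = 0.0


@dataclass(frozen=True)
class ArtifactSpec:
    """Triangular voltage slews: ``width_samples`` up, ``width_samples`` down.

    A ramp (rather than a square step) keeps the elevated first derivative
    sustained over several samples, as real movement/electrical transients do;
    a single-sample step would be erased by the 5-point median filter stage of
    the repair pipeline and is not what that detector targets.
    """

    count: int = 3
    amplitude_mad: float = 50.0  # peak height as a multiple of the signal MAD
    width_samples: int = 5


@dataclass
class SignalSimConfig:
    """Configuration for one synthetic resting-state channel.

    ``min_duration_s`` encodes the minimum usable resting epoch (15 s for the
    recordings this emulates); fixtures that need a different burst time
    fraction may lower it explicitly.
    """

    duration_s: float = 60.0
    fs: float = 1000.0
    background_slope: float = 1.0
    background_scale: float = 0.05
    line_hz: float = 60.0
    line_amplitude: float = 0.0
    bursts: tuple[BurstSpec, ...] = ()
    artifacts: ArtifactSpec | None = None
    seed: int = 0
    min_duration_s: float = 15.0
    max_analyzed_hz: float = 110.0

    def validate(self) -> None:
        if self.duration_s < self.min_duration_s:
            raise ValueError(
                f"duration_s={self.duration_s} below minimum resting epoch {self.min_duration_s}"
            )
        top = max([self.max_analyzed_hz] + [b.carrier_hz for b in self.bursts])
        if self.fs <= 2 * top:
            raise ValueError(f"fs={self.fs} too low for highest analyzed frequency {top} Hz")
        for b in self.bursts:
            if b.rate_hz > 0 and b.duration_s < 1.0 / b.carrier_hz:
                raise ValueError(f"burst duration {b.duration_s}s below one carrier cycle ({b.band})")


@dataclass
class LatentCohortConfig:
    """Planted sparse rank-1 cross-block structure at correlation ``rho_true``."""

    n_subjects: int = 100
    p_physio: int = 84
    q_morph: int = 36
    support_u: int = 5  # nonzero physio weights
    support_v: int = 5  # nonzero morph weights
    rho_true: float = 0.7
    noise_sd: float = 0.5
    confound_age: float = 0.0
    confound_updrs: float = 0.0
    confound_years: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= abs(self.rho_true) <= 1):
            raise ValueError(f"rho_true must lie in [-1, 1], got {self.rho_true}")
        if self.support_u > self.p_physio or self.support_v > self.q_morph:
            raise ValueError("sparse support exceeds feature count")
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")


@dataclass
class GroundTruth:
    """Planted structure; consumed only by tests and scoring, never by estimators."""

    burst_intervals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    artifact_mask: np.ndarray | None = None
    band_msc: dict[str, float] = field(default_factory=dict)
    u_true: np.ndarray | None = None  # physio weights
    v_true: np.ndarray | None = None  # morph weights
    z_scores: np.ndarray | None = None  # physio-side latent
    w_scores: np.ndarray | None = None  # morph-side latent


def one_over_f_noise(rng: np.random.Generator, n: int, fs: float, slope: float, scale: float) -> np.ndarray:
    """Stationary 1/f^slope background by spectral shaping of white noise."""
    if scale == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    spectrum = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-slope / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spectrum * shape, n)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def _place_bursts(
    rng: np.random.Generator, n_bursts: int, duration_s: float, total_s: float,
    margin_s: float = 0.25, gap_s: float = 0.2, max_tries: int = 10_000,
) -> list[tuple[float, float]]:
    """Non-overlapping boxcar intervals with a minimum inter-burst gap."""
    need = n_bursts * (duration_s + gap_s) + 2 * margin_s
    if need > total_s:
        raise ValueError(f"cannot place {n_bursts} bursts of {duration_s}s in {total_s}s")
    for _ in range(max_tries):
        starts = np.sort(rng.uniform(margin_s, total_s - margin_s - duration_s, n_bursts))
        if n_bursts < 2 or np.all(np.diff(starts) >= duration_s + gap_s):
            return [(s, s + duration_s) for s in starts]
    raise RuntimeError("burst placement failed; lower the rate or duration")


def simulate_oscillatory_channel(
    cfg: SignalSimConfig, label: str = "M1"
) -> tuple[Recording, GroundTruth]:
    """One channel of 1/f background + per-band boxcar-modulated carriers.

    Burst intervals are recorded exactly in the ground truth; a spec whose burst
    amplitude equals its baseline plants no bursts (pure modulation-free carrier).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = one_over_f_noise(rng, n, cfg.fs, cfg.background_slope, cfg.background_scale)
    truth = GroundTruth()
    for spec in cfg.bursts:
        amp = np.full(n, spec.baseline)
        intervals: list[tuple[float, float]] = []
        n_bursts = int(round(spec.rate_hz * cfg.duration_s))
        if n_bursts > 0 and spec.amplitude != spec.baseline:
            intervals = _place_bursts(rng, n_bursts, spec.duration_s, cfg.duration_s)
            for s, e in intervals:
                amp[int(round(s * cfg.fs)) : int(round(e * cfg.fs))] = spec.amplitude
        phase = rng.uniform(0, 2 * np.pi)
        x = x + amp * np.sin(2 * np.pi * spec.carrier_hz * t + phase)
        truth.burst_intervals.setdefault(spec.band, []).extend(intervals)
    if cfg.line_amplitude > 0:
        x = x + cfg.line_amplitude * np.sin(2 * np.pi * cfg.line_hz * t + rng.uniform(0, 2 * np.pi))
    rec = Recording(samples=x[None, :], fs=cfg.fs, labels=[label])
    if cfg.artifacts is not None and cfg.artifacts.count > 0:
        rec, mask = inject_artifacts(rec, cfg.artifacts, rng)
        truth.artifact_mask = mask
    return rec, truth


def simulate_coupled_channels(
    cfg: SignalSimConfig, mix: float, labels: tuple[str, str] = ("M1", "PM")
) -> tuple[Recording, GroundTruth]:
    """Two channels sharing a band-limited source with controllable coherence.

    Channel 1 is the band-limited source s; channel 2 = mix*s + (1-mix)*n with n
    an independent noise of identical spectrum, so the in-band magnitude-squared
    coherence is analytically mix^2 / (mix^2 + (1-mix)^2), recorded in the truth.
    """
    if not (0.0 <= mix <= 1.0):
        raise ValueError("mix must lie in [0, 1]")
    cfg.validate()
    if not cfg.bursts:
        raise ValueError("a band spec (carrier/band) is required to define the source band")
    from scipy import signal as sps

    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    spec = cfg.bursts[0]
    from .signals import DEFAULT_BANDS

    band = next((b for b in DEFAULT_BANDS if b.name == spec.band), None)
    if band is None:
        raise ValueError(f"unknown band {spec.band!r} for coupled-channel source")
    sos = sps.butter(4, [band.f_lo, band.f_hi], btype="bandpass", fs=cfg.fs, output="sos")
    source = sps.sosfilt(sos, rng.standard_normal(n))
    noise = sps.sosfilt(sos, rng.standard_normal(n))
    scale = spec.amplitude / max(source.std(), 1e-12)
    source *= scale
    noise *= scale
    ch1 = source
    ch2 = mix * source + (1.0 - mix) * noise
    denom = mix**2 + (1.0 - mix) ** 2
    truth = GroundTruth(band_msc={spec.band: (mix**2 / denom) if denom > 0 else 0.0})
    rec = Recording(samples=np.vstack([ch1, ch2]), fs=cfg.fs, labels=list(labels))
    return rec, truth


def inject_artifacts(
    rec: Recording, spec: ArtifactSpec, rng: np.random.Generator | int | None = None
) -> tuple[Recording, np.ndarray]:
    """Add non-overlapping square spikes of ``amplitude_mad`` x MAD to each channel."""
    if spec.width_samples < 1:
        raise ValueError("spike width must be at least 1 sample")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    samples = rec.samples.copy()
    mask = np.zeros(samples.shape, dtype=bool)
    n = rec.n_samples
    margin = spec.width_samples + int(0.01 * rec.fs)
    if spec.count * 3 * margin > n:
        raise ValueError("more spikes than fit without overlap")
    for ch in range(rec.n_channels):
        x = samples[ch]
        mad = np.median(np.abs(x - np.median(x)))
        height = spec.amplitude_mad * (mad if mad > 0 else x.std() or 1.0)
        placed: list[int] = []
        tries = 0
        while len(placed) < spec.count:
            pos = int(rng.integers(margin, n - margin))
            if all(abs(pos - p) > 3 * margin for p in placed):
                placed.append(pos)
            tries += 1
            if tries > 100_000:
                raise ValueError("could not place non-overlapping spikes")
        w = spec.width_samples
        shape = np.concatenate([np.linspace(0, 1, w + 1)[1:], np.linspace(1, 0, w + 1)[1:]])
        for pos in sorted(placed):
            sl = slice(pos, pos + shape.size)
            x[sl] += height * shape
            mask[ch, sl] = True
    out = Recording(samples=samples, fs=rec.fs, labels=list(rec.labels))
    return out, mask


def _sparse_weights(rng: np.random.Generator, dim: int, support: int) -> np.ndarray:
    """Unit-L2 weight vector with ``support`` equal-magnitude, random-sign entries."""
    w = np.zeros(dim)
    idx = rng.choice(dim, size=support, replace=False)
    w[idx] = rng.choice([-1.0, 1.0], size=support) / np.sqrt(support)
    return w


def simulate_feature_cohort(
    cfg: LatentCohortConfig,
    physio_cfg: FeatureConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Feature-level cohort with a planted sparse rank-1 cross-block factor.

    X = z u' + noise (physio block), Y = w v' + noise (morph block) with
    corr(z, w) = rho_true; confounds are linear in the latent scores with the
    configured coefficients (zero by default). Feature names follow the
    canonical physio/morph orderings when the dimensions match the defaults.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    cov = np.array([[1.0, cfg.rho_true], [cfg.rho_true, 1.0]])
    zw = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    z, w = zw[:, 0], zw[:, 1]
    u = _sparse_weights(rng, cfg.p_physio, cfg.support_u)
    v = _sparse_weights(rng, cfg.q_morph, cfg.support_v)
    X = np.outer(z, u) + cfg.noise_sd * rng.standard_normal((n, cfg.p_physio))
    Y = np.outer(w, v) + cfg.noise_sd * rng.standard_normal((n, cfg.q_morph))

    for M in (X, Y):  # no constant columns (vanishingly unlikely; jitter if so)
        const = M.std(axis=0) == 0
        if const.any():
            M[:, const] += 1e-9 * rng.standard_normal((n, const.sum()))

    phys_names = (
        physio_feature_names(physio_cfg)
        if cfg.p_physio == len(physio_feature_names(physio_cfg))
        else [f"phys_{i:03d}" for i in range(cfg.p_physio)]
    )
    morph_names = (
        morph_feature_names()
        if cfg.q_morph == len(morph_feature_names())
        else [f"morph_{i:03d}" for i in range(cfg.q_morph)]
    )
    subjects = [f"S{i:03d}" for i in range(n)]
    physio = pd.DataFrame(X, index=subjects, columns=phys_names)
    morph = pd.DataFrame(Y, index=subjects, columns=morph_names)
    physio.index.name = morph.index.name = "subject"

    shared = 0.5 * (z + w)
    age = np.clip(64.0 + 8.0 * rng.standard_normal(n) + cfg.confound_age * shared, 19.0, 99.0)
    updrs = np.clip(38.0 + 12.0 * rng.standard_normal(n) + cfg.confound_updrs * shared, 3.0, 108.0)
    years = np.clip(8.0 + 4.0 * rng.standard_normal(n) + cfg.confound_years * shared, 0.5, 40.0)
    sex = rng.choice(["M", "F"], size=n, p=[0.74, 0.26])
    covars = pd.DataFrame(
        {"age": age, "years_since_diagnosis": years, "updrs_iii": updrs, "sex": sex},
        index=subjects,
    )
    covars.index.name = "subject"

    truth = GroundTruth(u_true=u, v_true=v, z_scores=z, w_scores=w)
    return physio, morph, covars, truth
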