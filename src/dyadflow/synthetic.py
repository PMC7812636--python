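"""Synthetic dyad sessions with a known coupling graph.

The generative model lives at the 1 Hz analysis grid: a 6-node stable VAR
(SCL, RR, NEURO per subject) with within-subject links always on and
between-subject links (SCL->RR, RR->SCL, NEURO->SCL, both directions)
switched on, with a per-dyad gain, only in the cooperative conditions.
Latent node series are then rendered *upward* into raw signals:

* EEG -- 25-channel band-limited noise whose frontal beta power per second
  tracks the latent neurometric; eyes-closed baseline carries a 10 Hz alpha
  rhythm for IAF estimation; large spikes are injected at a configurable
  rate to exercise artifact rejection.
* ECG -- a QRS pulse train whose interbeat intervals follow the latent RR
  series (affine-mapped into the physiologic 0.3-2.0 s range).
* EDA -- the latent SCL series double-integrated into a slowly wandering
  tonic level plus phasic bumps, so the pipeline's double differencing
  recovers a stationary series.

Behavioural scores increase with the dyad's coupling gain, giving the
correlation analysis a known positive ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .behavior import TrialOutcome, compute_score
from .io import CHANNELS_25, Montage, Recording, SessionManifest, default_montage
from .neurometrics import BandScheme, define_bands

__all__ = [
    "CouplingSpec",
    "GroundTruth",
    "SyntheticSession",
    "SyntheticCohort",
    "make_coupling_spec",
    "simulate_latent_var",
    "render_eeg",
    "render_ecg",
    "render_eda",
    "simulate_session",
    "simulate_cohort",
    "write_session",
]

CONDITIONS = ("Alone", "CoopNT", "CoopT")

# session layout (seconds on the shared clock)
EYES_CLOSED = (0.0, 60.0)
REST = (60.0, 120.0)
TASK_START = 120.0

# default within-subject dynamics, node order (SCL, RR, NEURO);
# rows are targets, columns drivers
WITHIN_BLOCK = np.array(
    [
        [0.70, 0.00, 0.20],  # SCL: slow, driven by the neurometric
        [0.10, 0.50, 0.00],  # RR: driven by arousal (SCL)
        [0.00, 0.00, 0.50],  # NEURO
    ]
)

# between-subject template, scaled by the coupling gain
BETWEEN_BLOCK = np.array(
    [
        [0.0, 1.0, 1.0],  # SCL <- other's RR and NEURO
        [1.0, 0.0, 0.0],  # RR  <- other's SCL
        [0.0, 0.0, 0.0],
    ]
)

BURN_IN = 500


@dataclass
class CouplingSpec:
    """Latent VAR specification for one dyad/condition."""

    order: int
    coeffs: np.ndarray  # (p, 6, 6)
    innovation_cov: np.ndarray  # (6, 6)
    gain: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.order, 6, 6):
            raise ValueError("coefficient tensor must be (p, 6, 6)")

    def spectral_radius(self) -> float:
        p = self.order
        comp = np.zeros((6 * p, 6 * p))
        comp[:6, :] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            comp[6:, :-6] = np.eye(6 * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    @property
    def between_adjacency(self) -> np.ndarray:
        """True 6x6 directed adjacency restricted to between-subject links."""
        adj = np.zeros((6, 6), dtype=bool)
        strength = np.abs(self.coeffs).sum(axis=0)
        adj[3:, :3] = strength[3:, :3] > 1e-12
        adj[:3, 3:] = strength[:3, 3:] > 1e-12
        # adjacency[i, j] convention: link i -> j (driver row)
        return adj.T


@dataclass
class GroundTruth:
    latent: np.ndarray  # (n, 6) at 1 Hz
    between_adjacency: np.ndarray
    gain: float
    seed: int


@dataclass
class SyntheticSession:
    manifest: SessionManifest
    recordings: dict  # recordings[subject][modality] -> Recording
    ground_truth: GroundTruth


@dataclass
class SyntheticCohort:
    sessions: dict  # (dyad_id, condition) -> SyntheticSession
    gains: dict  # dyad_id -> coupling gain
    behaviour: list  # rows: dict(dyad_id, condition, t_el, w, m, score)
    master_seed: int

    @property
    def dyads(self) -> list[str]:
        return sorted(self.gains)


def make_coupling_spec(gain: float, seed: int = 0, sigma: float = 1.0) -> CouplingSpec:
    """Build the default 6-node VAR(1) with the given between-subject gain."""
    if gain < 0:
        raise ValueError("gain must be nonnegative")
    A = np.zeros((6, 6))
    A[:3, :3] = WITHIN_BLOCK
    A[3:, 3:] = WITHIN_BLOCK
    A[:3, 3:] = gain * BETWEEN_BLOCK
    A[3:, :3] = gain * BETWEEN_BLOCK
    spec = CouplingSpec(
        order=1,
        coeffs=A[None],
        innovation_cov=np.eye(6) * sigma**2,
        gain=gain,
        seed=seed,
    )
    if spec.spectral_radius() >= 1.0:
        raise ValueError(f"unstable latent VAR (gain {gain})")
    return spec


def simulate_latent_var(spec: CouplingSpec, n: int, seed: int | None = None) -> GroundTruth:
    """Draw n samples of the latent 6-node series after a 500-sample burn-in."""
    if spec.spectral_radius() >= 1.0:
        raise ValueError("unstable latent VAR specification")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    p = spec.order
    total = n + BURN_IN
    chol = np.linalg.cholesky(spec.innovation_cov)
    innov = rng.standard_normal((total, 6)) @ chol.T
    Y = np.zeros((total, 6))
    for t in range(p, total):
        acc = innov[t].copy()
        for k in range(p):
            acc += spec.coeffs[k] @ Y[t - 1 - k]
        Y[t] = acc
    return GroundTruth(
        latent=Y[BURN_IN:],
        between_adjacency=spec.between_adjacency,
        gain=spec.gain,
        seed=spec.seed if seed is None else seed,
    )


# ---------------------------------------------------------------------------
# raw-signal rendering


def _band_noise(rng, n_samples: int, fs: float, band: tuple[float, float], n_ch: int) -> np.ndarray:
    """Zero-phase band-limited Gaussian noise, unit variance per channel.

    Synthesized in the frequency domain (white-noise spectrum masked to the
    band, raised-cosine edges) — equivalent to sharp zero-phase filtering but
    much cheaper for long multichannel records.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    lo, hi = band
    roll = max(0.25, 0.05 * (hi - lo))  # soft edges avoid ringing
    gain = np.clip((freqs - (lo - roll)) / roll, 0.0, 1.0) * np.clip(
        ((hi + roll) - freqs) / roll, 0.0, 1.0
    )
    keep = np.flatnonzero(gain > 0)
    spec = np.zeros((freqs.size, n_ch), dtype=np.complex64)
    draws = rng.standard_normal((keep.size, n_ch, 2)).astype(np.float32)
    spec[keep] = (draws[..., 0] + 1j * draws[..., 1]) * gain[keep, None].astype(np.float32)
    x = np.fft.irfft(spec, n=n_samples, axis=0)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


#: channels whose beta amplitude is modulated by the latent neurometric
MODULATED_CHANNELS = ("F3", "F4", "F7", "F8", "Fz")


def render_eeg(
    latent_neuro: np.ndarray,
    montage: Montage | None = None,
    fs: float = 256.0,
    band_scheme: BandScheme | None = None,
    seed: int = 0,
    base_uv: float = 4.0,
    beta_uv: float = 3.0,
    modulation: float = 0.25,
    artifact_rate: float = 0.02,
    subject_id: str = "synthetic",
) -> Recording:
    """Task-window EEG whose frontal beta power tracks the latent series.

    Per second k the frontal beta amplitude is scaled by
    exp(modulation * latent_k), so band power is log-linear (hence rank
    monotone) in the latent neurometric.
    """
    montage = montage or default_montage()
    band_scheme = band_scheme or define_bands(10.0)
    latent = np.asarray(latent_neuro, dtype=float)
    n_sec = latent.size
    spe = int(round(fs))
    n_samp = n_sec * spe
    rng = np.random.default_rng(seed)
    channels = list(montage.channels)
    n_ch = len(channels)

    data = base_uv * _band_noise(rng, n_samp, fs, (1.0, 35.0), n_ch)
    data += 1.5 * _band_noise(rng, n_samp, fs, band_scheme.alpha, n_ch)

    beta = _band_noise(rng, n_samp, fs, band_scheme.beta, len(MODULATED_CHANNELS))
    amp = beta_uv * np.exp(modulation * latent)
    gain = np.repeat(amp, spe)[:, None]
    for col, name in enumerate(MODULATED_CHANNELS):
        data[:, channels.index(name)] += gain[:, 0] * beta[:, col]

    if artifact_rate > 0:
        hit = rng.random((n_sec, n_ch)) < artifact_rate
        for ep, ch in zip(*np.nonzero(hit)):
            pos = ep * spe + rng.integers(2, spe - 2)
            data[pos - 1 : pos + 2, ch] += rng.choice([-1.0, 1.0]) * 160.0
    return Recording(subject_id, "EEG", fs, channels, data, t0=TASK_START)


def _rest_eeg(
    duration_s: int,
    fs: float,
    iaf: float,
    seed: int,
    base_uv: float = 4.0,
    alpha_uv: float = 8.0,
) -> np.ndarray:
    """Eyes-closed style baseline with a clear posterior alpha rhythm."""
    rng = np.random.default_rng(seed)
    spe = int(round(fs))
    n = duration_s * spe
    channels = list(CHANNELS_25)
    data = base_uv * _band_noise(rng, n, fs, (1.0, 35.0), len(channels))
    t = np.arange(n) / fs
    alpha = np.sin(2 * np.pi * iaf * t + rng.uniform(0, 2 * np.pi))
    for name in ("Pz", "P3", "P4", "PO3", "PO4", "P7", "P8"):
        jitter = 1.0 + 0.1 * rng.standard_normal()
        data[:, channels.index(name)] += alpha_uv * jitter * alpha
    return data


def render_ecg(
    latent_rr: np.ndarray,
    fs: float = 256.0,
    seed: int = 0,
    rr_base: float = 0.85,
    rr_scale: float = 0.05,
    noise_mv: float = 0.02,
    subject_id: str = "synthetic",
) -> Recording:
    """QRS pulse train whose interbeat intervals integrate the latent RR.

    The latent series is affine-mapped to rr(t) = rr_base + rr_scale *
    latent(t); the mapping must stay inside the physiologic [0.3, 2.0] s
    range.
    """
    latent = np.asarray(latent_rr, dtype=float)
    rr_target = rr_base + rr_scale * latent
    if rr_target.min() < 0.3 or rr_target.max() > 2.0:
        raise ValueError("mapped RR intervals leave the physiologic [0.3, 2.0] s range")
    rng = np.random.default_rng(seed)
    n_sec = latent.size
    n_samp = n_sec * int(round(fs))

    beat_times = []
    t = float(rng.uniform(0.1, 0.5))
    while t < n_sec:
        beat_times.append(t)
        idx = min(int(t), n_sec - 1)
        t += rr_target[idx]

    # triphasic QRS template, ~100 ms wide, 1 mV R-wave
    width = int(round(0.1 * fs))
    tt = np.linspace(-1.5, 1.5, width)
    template = (1.0 - 4.0 * tt**2) * np.exp(-2 * tt**2)  # Mexican-hat-like
    template /= template.max()

    ecg = noise_mv * rng.standard_normal(n_samp)
    ecg += 0.1 * np.sin(2 * np.pi * 0.15 * np.arange(n_samp) / fs)  # baseline wander
    half = width // 2
    for bt in beat_times:
        pos = int(round(bt * fs))
        lo, hi = pos - half, pos - half + width
        if lo >= 0 and hi <= n_samp:
            ecg[lo:hi] += template
    return Recording(subject_id, "ECG", fs, ["ECG"], ecg[:, None], t0=TASK_START)


def render_eda(
    latent_scl: np.ndarray,
    fs: float = 64.0,
    seed: int = 0,
    scale: float = 3e-3,
    base_us: float = 8.0,
    n_phasic: int = 8,
    noise_us: float = 0.01,
    subject_id: str = "synthetic",
) -> Recording:
    """Tonic EDA whose second difference at 1 Hz equals the latent SCL series.

    The latent series is scaled and double-integrated (so the pipeline's
    double differencing recovers it), upsampled smoothly to the EDA rate,
    and decorated with exponential-decay phasic bumps and sensor noise.
    """
    latent = np.asarray(latent_scl, dtype=float)
    rng = np.random.default_rng(seed)
    n_sec = latent.size
    tonic_1hz = base_us + np.cumsum(np.cumsum(scale * latent))
    lo = tonic_1hz.min()
    if lo < 0.5:  # keep conductance physical; a constant shift is harmless
        tonic_1hz = tonic_1hz - lo + 0.5

    spe = int(round(fs))
    n_samp = n_sec * spe
    t_hi = np.arange(n_samp) / fs
    tonic = np.interp(t_hi, np.arange(n_sec, dtype=float), tonic_1hz)

    eda = tonic + noise_us * rng.standard_normal(n_samp)
    # sparse skin-conductance responses riding on the tonic level
    for _ in range(n_phasic):
        onset = rng.uniform(0, max(1.0, n_sec - 10))
        amp = rng.uniform(0.05, 0.2)
        tau = rng.uniform(1.5, 4.0)
        rise = 0.75
        dt = t_hi - onset
        bump = np.where(dt > 0, (1 - np.exp(-dt / rise)) * np.exp(-dt / tau), 0.0)
        eda += amp * bump
    eda = np.maximum(eda, 0.0)
    return Recording(subject_id, "EDA", fs, ["EDA"], eda[:, None], t0=TASK_START)


# ---------------------------------------------------------------------------
# sessions and cohorts


def _seed_for(master_seed: int, *keys: int) -> int:
    """Stable derived seed below 2**31."""
    ss = np.random.SeedSequence([master_seed, *keys])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_session(
    dyad_id: str,
    condition: str,
    gain: float,
    seed: int,
    duration: int = 240,
    iaf: float = 10.0,
    artifact_rate: float = 0.02,
) -> SyntheticSession:
    """One dyad/condition session: latent dynamics plus full raw rendering.

    Recordings cover 60 s eyes-closed + 60 s rest baselines followed by the
    task window; only the task window carries the latent dynamics.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    spec = make_coupling_spec(gain if condition != "Alone" else 0.0, seed=seed)
    truth = simulate_latent_var(spec, duration, seed=seed)
    bands = define_bands(iaf)
    fs_eeg, fs_ecg, fs_eda = 256.0, 256.0, 64.0
    recordings: dict = {}
    for si, subj in enumerate("ab"):
        cols = slice(0, 3) if subj == "a" else slice(3, 6)
        scl, rr, neuro = truth.latent[:, cols].T
        sid = f"{dyad_id}{subj}"
        s = _seed_for(seed, si)

        task_eeg = render_eeg(
            neuro, fs=fs_eeg, band_scheme=bands, seed=s + 1,
            artifact_rate=artifact_rate, subject_id=sid,
        )
        base_eeg = np.vstack(
            [
                _rest_eeg(60, fs_eeg, iaf, s + 2),
                _rest_eeg(60, fs_eeg, iaf, s + 3, alpha_uv=4.0),
            ]
        )
        eeg = Recording(sid, "EEG", fs_eeg, task_eeg.channel_names,
                        np.vstack([base_eeg, task_eeg.data]), t0=0.0)

        task_ecg = render_ecg(rr, fs=fs_ecg, seed=s + 4, subject_id=sid)
        base_rr = np.zeros(int(TASK_START))
        base_ecg = render_ecg(base_rr, fs=fs_ecg, seed=s + 5, subject_id=sid)
        ecg = Recording(sid, "ECG", fs_ecg, ["ECG"],
                        np.vstack([base_ecg.data, task_ecg.data]), t0=0.0)

        task_eda = render_eda(scl, fs=fs_eda, seed=s + 6, subject_id=sid)
        rng = np.random.default_rng(s + 7)
        base_level = task_eda.data[0, 0]
        base_eda = base_level + 0.01 * rng.standard_normal((int(TASK_START * fs_eda), 1))
        eda = Recording(sid, "EDA", fs_eda, ["EDA"],
                        np.vstack([np.maximum(base_eda, 0.0), task_eda.data]), t0=0.0)

        recordings[sid] = {"EEG": eeg, "ECG": ecg, "EDA": eda}

    manifest = SessionManifest(
        dyad_id=dyad_id,
        condition=condition,
        duration=float(duration),
        eyes_closed=EYES_CLOSED,
        rest=REST,
        files={sid: {} for sid in recordings},
    )
    return SyntheticSession(manifest=manifest, recordings=recordings, ground_truth=truth)


def _behaviour_for(gain: float, condition: str, rng) -> TrialOutcome:
    """Behavioural outcome whose score grows with the coupling gain."""
    if condition == "Alone":
        frac = np.clip(0.5 + 0.15 * rng.standard_normal(), 0.0, 1.0)
    else:
        frac = np.clip(1.05 - 3.0 * gain + 0.08 * rng.standard_normal(), 0.0, 1.0)
    missing = min(15, max(0, int(round(15 * frac))))
    return TrialOutcome(t_el=240.0, w=0, m=missing)


def simulate_cohort(
    n_dyads: int = 14,
    duration: int = 240,
    master_seed: int = 0,
    gain_range: tuple[float, float] = (0.15, 0.3),
    coupled_conditions: tuple[str, ...] = ("CoopNT", "CoopT"),
    artifact_rate: float = 0.02,
) -> SyntheticCohort:
    """A full study cohort: every dyad runs Alone, CoopNT and CoopT.

    Per-dyad coupling gains are drawn once from ``gain_range`` and applied
    only in ``coupled_conditions`` (pass an empty tuple for a fully
    uncoupled null cohort).  All randomness derives from ``master_seed``.
    """
    if n_dyads < 3:
        raise ValueError("need at least 3 dyads")
    rng = np.random.default_rng(master_seed)
    gains = {f"d{i:02d}": float(rng.uniform(*gain_range)) for i in range(n_dyads)}
    sessions: dict = {}
    behaviour: list = []
    for di, dyad_id in enumerate(sorted(gains)):
        for ci, condition in enumerate(CONDITIONS):
            seed = _seed_for(master_seed, di, ci)
            gain = gains[dyad_id] if condition in coupled_conditions else 0.0
            sessions[(dyad_id, condition)] = simulate_session(
                dyad_id, condition, gain, seed, duration=duration,
                artifact_rate=artifact_rate,
            )
            out = _behaviour_for(gains[dyad_id], condition, np.random.default_rng(seed + 1))
            behaviour.append(
                {
                    "dyad_id": dyad_id,
                    "condition": condition,
                    "t_el": out.t_el,
                    "w": out.w,
                    "m": out.m,
                    "score": compute_score(out),
                }
            )
    return SyntheticCohort(sessions=sessions, gains=gains, behaviour=behaviour, master_seed=master_seed)


def write_session(session: SyntheticSession, out_dir) -> None:
    """Persist one session as EDF recordings plus a YAML manifest."""
    from pathlib import Path

    from . import edf as edfmod
    from .io import write_manifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = session.manifest
    files: dict = {}
    for sid, mods in session.recordings.items():
        files[sid] = {}
        for modality, rec in mods.items():
            fname = f"{manifest.dyad_id}_{manifest.condition}_{sid}_{modality}.edf"
            dim = {"EEG": "uV", "ECG": "mV", "EDA": "uS"}[modality]
            edfmod.write_edf(out / fname, rec.data, rec.fs, rec.channel_names, physical_dim=dim)
            files[sid][modality] = fname
    manifest.files = files
    write_manifest(manifest, out / f"{manifest.dyad_id}_{manifest.condition}.yaml")
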