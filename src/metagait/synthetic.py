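"""Synthetic multimodal gait cohort generator.

Emulates a treadmill/overground walking acquisition with four hard-synchronized
streams per trial:

* ``image`` — RGB frames (default 30 Hz, 64x64) of a sagittal stick figure whose
  thigh/shank/foot segments are driven by the ground-truth joint angles;
* ``emg`` — 6-channel surface EMG (default 1111.111 Hz): per-muscle activation
  envelopes phase-locked to the gait cycle, multiplied by a 20-450 Hz
  band-limited Gaussian carrier (the standard surrogate for interference-pattern
  EMG), plus additive sensor noise;
* ``vio`` — pelvis pose at 200 Hz (3-D position on a circular walking path with
  step-frequency vertical oscillation, plus a heading-aligned unit quaternion);
* ``angles`` — the ground-truth 6-angle trajectory (L/R hip, knee, ankle;
  degrees; 100 Hz), an exact deterministic function of the subject and speed.

Joint kinematics follow a truncated Fourier series per joint,

    theta_j(t) = offset_j + sum_h a_jh * cos(2*pi*h*f0*t + phi_jh),  h = 1..3,

with stride frequency ``f0`` increasing with belt speed and scaled by a
per-subject cadence multiplier.  Subjects differ in baseline offsets, harmonic
amplitudes/phases, cadence, and EMG gains, which is what makes few-shot
intra-subject adaptation measurable downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .errors import ConfigurationError, DomainError

JOINT_NAMES = ("L-hip", "L-knee", "L-ankle", "R-hip", "R-knee", "R-ankle")
EMG_CHANNELS = ("L-RF", "L-BF", "L-GA", "R-RF", "R-BF", "R-GA")
SPEED_CLASSES = {"slow": 3.5, "moderate": 4.5, "fast": 6.0}
MODALITIES = ("image", "emg", "vio", "angles")

# Per-joint-type Fourier templates (degrees / radians), 3 harmonics.
_TEMPLATES = {
    "hip": dict(offset=15.0, amps=(12.0, 4.0, 1.5), phases=(0.2, 1.2, 0.5)),
    "knee": dict(offset=25.0, amps=(15.0, 10.0, 4.0), phases=(2.6, -0.9, 1.0)),
    "ankle": dict(offset=2.0, amps=(7.0, 5.0, 2.0), phases=(1.5, 0.3, -1.0)),
}
_JOINT_TYPES = ("hip", "knee", "ankle")

# EMG activation-bump centres as gait-cycle fractions (left leg; right leg +0.5):
# RF fires around terminal swing/loading, BF in late swing, GA in late stance.
_EMG_BUMPS = {"RF": 0.98, "BF": 0.85, "GA": 0.45}
_EMG_BUMP_WIDTH = 0.06
_EMG_BASELINE = 0.10


def speed_class(speed_kmh: float) -> str:
    """Map a belt speed to the nearest protocol speed class."""
    return min(SPEED_CLASSES, key=lambda c: abs(SPEED_CLASSES[c] - speed_kmh))


@dataclass
class GeneratorConfig:
    """Distribution ranges and acquisition settings for the simulator.

    All ``*_range`` fields are (low, high) uniform-sampling bounds; a zero-width
    range pins the value.  Rates follow the acquisition hardware being emulated.
    """

    image_rate: float = 30.0
    emg_rate: float = 1111.111
    vio_rate: float = 200.0
    angle_rate: float = 100.0
    image_size: int = 64
    image_channels: int = 3
    duration_s: float = 60.0
    speeds_kmh: tuple = (3.5, 4.5, 6.0)

    # stride frequency (Hz) = stride_freq_base + stride_freq_slope * speed_kmh
    stride_freq_base: float = 0.55
    stride_freq_slope: float = 0.09
    # stance fraction of the gait cycle = base + slope * speed_kmh, clipped to band
    stance_frac_base: float = 0.72
    stance_frac_slope: float = -0.026
    stance_band: tuple = (0.55, 0.65)

    # inter-subject variability: wide enough that subject identity dominates
    # trial-to-trial variation (anatomical zero offsets of this order are
    # typical across individuals), which is what makes intra-subject
    # adaptation a measurable effect
    offset_halfwidth_deg: float = 12.0
    amp_scale_range: tuple = (0.7, 1.3)
    phase_jitter_rad: float = 0.4
    cadence_scale_range: tuple = (0.85, 1.15)
    emg_gain_range: tuple = (0.7, 1.3)
    emg_units_scale: float = 1.0
    emg_band_hz: tuple = (20.0, 450.0)

    vio_radius_m: float = 2.0
    pelvis_height_m: float = 0.9
    vertical_osc_m: float = 0.02

    image_noise_sd: float = 0.02     # on the 0-1 pixel scale
    emg_noise_sd: float = 0.05       # additive, relative to unit envelope scale
    vio_pos_noise_m: float = 0.005
    vio_rot_noise_rad: float = 0.01

    def __post_init__(self):
        for name in ("amp_scale_range", "cadence_scale_range", "emg_gain_range",
                     "stance_band", "emg_band_hz"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: min {lo} > max {hi}")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")

    def stride_freq(self, speed_kmh: float, cadence_scale: float = 1.0) -> float:
        return (self.stride_freq_base + self.stride_freq_slope * speed_kmh) * cadence_scale

    def stance_fraction(self, speed_kmh: float) -> float:
        lo, hi = self.stance_band
        return float(np.clip(self.stance_frac_base + self.stance_frac_slope * speed_kmh, lo, hi))

    def to_yaml(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        d = yaml.safe_load(text) or {}
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class SubjectProfile:
    """Per-subject gait pattern parameters sampled from a GeneratorConfig."""

    subject_id: int
    baseline_offsets: np.ndarray      # (6,) degrees
    fourier_amps: np.ndarray          # (6, 3) degrees, non-negative
    fourier_phases: np.ndarray        # (6, 3) radians
    cadence_scale: float
    emg_gain: np.ndarray              # (6,) dimensionless
    noise_levels: dict                # modality -> SD

    def validate(self):
        if not np.all(np.isfinite(self.fourier_amps)) or np.any(self.fourier_amps < 0):
            raise DomainError("fourier_amps must be finite and non-negative")
        if self.cadence_scale <= 0:
            raise DomainError("cadence_scale must be positive")
        if any(v < 0 for v in self.noise_levels.values()):
            raise DomainError("noise levels must be non-negative")
        return self

    def to_json(self) -> str:
        return json.dumps({
            "subject_id": self.subject_id,
            "baseline_offsets": self.baseline_offsets.tolist(),
            "fourier_amps": self.fourier_amps.tolist(),
            "fourier_phases": self.fourier_phases.tolist(),
            "cadence_scale": self.cadence_scale,
            "emg_gain": self.emg_gain.tolist(),
            "noise_levels": self.noise_levels,
        })

    @classmethod
    def from_json(cls, text: str) -> "SubjectProfile":
        d = json.loads(text)
        return cls(
            subject_id=d["subject_id"],
            baseline_offsets=np.asarray(d["baseline_offsets"]),
            fourier_amps=np.asarray(d["fourier_amps"]),
            fourier_phases=np.asarray(d["fourier_phases"]),
            cadence_scale=d["cadence_scale"],
            emg_gain=np.asarray(d["emg_gain"]),
            noise_levels=d["noise_levels"],
        )


@dataclass
class ModalityStream:
    """One modality's samples for a trial or clip, with rate metadata."""

    modality: str
    samples: np.ndarray     # (T, D) or (T, H, W, C) for images
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise DomainError(f"unknown modality {self.modality!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class TrialMeta:
    subject_id: int
    trial_index: int
    speed_kmh: float
    speed_class: str
    direction: str
    duration_s: float
    seed: int
    stride_freq: float
    stance_frac: float


@dataclass
class RawTrial:
    streams: dict            # modality -> ModalityStream (incl. "angles")
    phase_stance: np.ndarray  # bool at the angle rate; True during stance
    meta: TrialMeta


@dataclass
class MultimodalClip:
    """A synchronized window across all modalities — the few-shot 'shot' unit."""

    streams: dict            # image/emg/vio -> ModalityStream
    angles: np.ndarray       # (T_a, 6) degrees
    angle_rate: float
    phase_stance: np.ndarray  # (T_a,) bool
    subject_id: int
    speed_class: str
    speed_kmh: float
    trial_index: int
    clip_index: int
    duration_s: float


def make_subject(seed: int, config: GeneratorConfig | None = None) -> SubjectProfile:
    """Sample a subject-specific gait profile. Deterministic in (seed, config)."""
    if seed < 0:
        raise DomainError("seed must be non-negative")
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    offsets = np.empty(6)
    amps = np.empty((6, 3))
    phases = np.empty((6, 3))
    hw = config.offset_halfwidth_deg
    for side in range(2):                      # 0 = left, 1 = right
        for jt, jtype in enumerate(_JOINT_TYPES):
            j = side * 3 + jt
            tpl = _TEMPLATES[jtype]
            offsets[j] = tpl["offset"] + rng.uniform(-hw, hw)
            for h in range(3):
                amps[j, h] = tpl["amps"][h] * rng.uniform(*config.amp_scale_range)
                jit = rng.uniform(-config.phase_jitter_rad, config.phase_jitter_rad)
                # right leg lags by half a gait cycle: harmonic h+1 shifts by (h+1)*pi
                phases[j, h] = tpl["phases"][h] + jit + side * (h + 1) * np.pi
    profile = SubjectProfile(
        subject_id=int(seed),
        baseline_offsets=offsets,
        fourier_amps=amps,
        fourier_phases=phases,
        cadence_scale=float(rng.uniform(*config.cadence_scale_range)),
        emg_gain=rng.uniform(*config.emg_gain_range, size=6),
        noise_levels={"image": config.image_noise_sd,
                      "emg": config.emg_noise_sd,
                      "vio": config.vio_pos_noise_m},
    )
    return profile.validate()


def joint_angles(profile: SubjectProfile, stride_freq: float, t: np.ndarray) -> np.ndarray:
    """Evaluate the truncated Fourier gait model at times ``t`` -> (len(t), 6) deg."""
    h = np.arange(1, 4)
    arg = 2 * np.pi * stride_freq * t[:, None, None] * h[None, None, :] \
        + profile.fourier_phases[None, :, :]
    return profile.baseline_offsets[None, :] + (
        profile.fourier_amps[None, :, :] * np.cos(arg)
    ).sum(axis=2)


def emg_envelope(profile: SubjectProfile, stride_freq: float, t: np.ndarray) -> np.ndarray:
    """Phase-locked activation envelope, (len(t), 6); exactly 1/stride_freq periodic."""
    env = np.empty((len(t), 6))
    for ch, name in enumerate(EMG_CHANNELS):
        side, muscle = name.split("-")
        phase = (stride_freq * t + (0.5 if side == "R" else 0.0)) % 1.0
        d = phase - _EMG_BUMPS[muscle]
        d = d - np.round(d)                      # circular distance in cycles
        bump = np.exp(-0.5 * (d / _EMG_BUMP_WIDTH) ** 2)
        env[:, ch] = profile.emg_gain[ch] * (_EMG_BASELINE + bump)
    return env


def _bandlimited_carrier(rng: np.random.Generator, n: int, fs: float,
                         band: tuple) -> np.ndarray:
    """Zero-mean unit-RMS Gaussian noise band-limited to ``band`` Hz, (n, 6)."""
    lo, hi = band
    hi = min(hi, 0.49 * fs)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal((n, 6)), axis=0)
    return x / x.std(axis=0, keepdims=True)


def _render_stick_frames(angles_deg: np.ndarray, bob_px: np.ndarray,
                         size: int) -> np.ndarray:
    """Render sagittal stick-figure frames (F, size, size, 3) uint8.

    Left-leg segments draw into the red channel, right-leg into blue, the
    trunk into green; the fixed camera looks along the mediolateral axis.
    """
    f = angles_deg.shape[0]
    s = size / 64.0
    img = np.zeros((f, size, size, 3), dtype=np.uint8)
    hip_x = np.full(f, 32.0 * s)
    hip_y = 22.0 * s + bob_px * s
    l_th, l_sh, l_ft, l_tr = 14 * s, 13 * s, 5 * s, 12 * s
    rad = np.deg2rad(angles_deg)

    def draw(x0, y0, x1, y1, ch):
        npts = max(int(16 * s), 8)
        u = np.linspace(0.0, 1.0, npts)
        xs = x0[:, None] + (x1 - x0)[:, None] * u
        ys = y0[:, None] + (y1 - y0)[:, None] * u
        px = np.clip(np.round(xs).astype(int), 0, size - 1)
        py = np.clip(np.round(ys).astype(int), 0, size - 1)
        fr = np.broadcast_to(np.arange(f)[:, None], px.shape)
        img[fr.ravel(), py.ravel(), px.ravel(), ch] = 255

    draw(hip_x, hip_y, hip_x, hip_y - l_tr, 1)     # trunk
    for side, ch in ((0, 0), (1, 2)):              # left -> R channel, right -> B
        hip, knee, ankle = rad[:, 3 * side: 3 * side + 3].T
        a_th = hip                                  # from vertical, + = forward
        knee_x = hip_x + l_th * np.sin(a_th)
        knee_y = hip_y + l_th * np.cos(a_th)
        a_sh = a_th - knee
        ank_x = knee_x + l_sh * np.sin(a_sh)
        ank_y = knee_y + l_sh * np.cos(a_sh)
        a_ft = a_sh + np.pi / 2 + ankle
        toe_x = ank_x + l_ft * np.sin(a_ft)
        toe_y = ank_y + l_ft * np.cos(a_ft)
        draw(hip_x, hip_y, knee_x, knee_y, ch)
        draw(knee_x, knee_y, ank_x, ank_y, ch)
        draw(ank_x, ank_y, toe_x, toe_y, ch)
    return img


def simulate_trial(profile: SubjectProfile, speed_kmh: float, duration_s: float,
                   direction: str = "ccw", seed: int = 0,
                   config: GeneratorConfig | None = None,
                   trial_index: int = 0) -> RawTrial:
    """Simulate one synchronized walking trial. Deterministic in all arguments."""
    if speed_kmh <= 0 or duration_s <= 0:
        raise DomainError("speed_kmh and duration_s must be positive")
    if direction not in ("cw", "ccw"):
        raise DomainError(f"direction must be 'cw' or 'ccw', got {direction!r}")
    config = config or GeneratorConfig()
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=3)
    r_img, r_emg, r_vio = (np.random.default_rng(int(s)) for s in seeds)

    f0 = config.stride_freq(speed_kmh, profile.cadence_scale)
    stance = config.stance_fraction(speed_kmh)

    # ---- ground-truth angles (exact; never noised)
    n_a = round(config.angle_rate * duration_s)
    t_a = np.arange(n_a) / config.angle_rate
    ang = joint_angles(profile, f0, t_a)
    phase_stance = (f0 * t_a) % 1.0 < stance

    # ---- sEMG
    n_e = round(config.emg_rate * duration_s)
    t_e = np.arange(n_e) / config.emg_rate
    env = emg_envelope(profile, f0, t_e)
    carrier = _bandlimited_carrier(r_emg, n_e, config.emg_rate, config.emg_band_hz)
    emg = env * carrier
    if profile.noise_levels["emg"] > 0:
        emg = emg + r_emg.normal(0.0, profile.noise_levels["emg"], emg.shape)
    emg = (emg * config.emg_units_scale).astype(np.float32)

    # ---- VIO (pelvis pose on a circular path)
    n_v = round(config.vio_rate * duration_s)
    t_v = np.arange(n_v) / config.vio_rate
    v_ms = speed_kmh / 3.6
    sign = 1.0 if direction == "ccw" else -1.0
    theta = sign * (v_ms / config.vio_radius_m) * t_v
    pos = np.stack([
        config.vio_radius_m * np.cos(theta),
        config.vio_radius_m * np.sin(theta),
        config.pelvis_height_m + config.vertical_osc_m * np.sin(2 * np.pi * 2 * f0 * t_v),
    ], axis=1)
    if profile.noise_levels["vio"] > 0:
        pos = pos + r_vio.normal(0.0, profile.noise_levels["vio"], pos.shape)
    yaw = theta + sign * np.pi / 2
    if config.vio_rot_noise_rad > 0:
        yaw = yaw + r_vio.normal(0.0, config.vio_rot_noise_rad, yaw.shape)
    quat = np.stack([np.cos(yaw / 2), np.zeros_like(yaw),
                     np.zeros_like(yaw), np.sin(yaw / 2)], axis=1)
    vio = np.concatenate([pos, quat], axis=1)

    # ---- images
    n_i = round(config.image_rate * duration_s)
    t_i = np.arange(n_i) / config.image_rate
    ang_i = joint_angles(profile, f0, t_i)
    bob = 1.5 * np.sin(2 * np.pi * 2 * f0 * t_i)
    frames = _render_stick_frames(ang_i, bob, config.image_size)
    if profile.noise_levels["image"] > 0:
        noise = r_img.standard_normal(frames.shape, dtype=np.float32)
        noise *= profile.noise_levels["image"] * 255.0
        noise += frames
        frames = np.clip(noise, 0, 255, out=noise).astype(np.uint8)

    streams = {
        "image": ModalityStream("image", frames, config.image_rate),
        "emg": ModalityStream("emg", emg, config.emg_rate),
        "vio": ModalityStream("vio", vio, config.vio_rate),
        "angles": ModalityStream("angles", ang.astype(np.float64), config.angle_rate),
    }
    meta = TrialMeta(profile.subject_id, trial_index, float(speed_kmh),
                     speed_class(speed_kmh), direction, float(duration_s),
                     int(seed), float(f0), float(stance))
    return RawTrial(streams=streams, phase_stance=phase_stance, meta=meta)


def segment_clips(trial: RawTrial, clip_s: float = 10.0,
                  overlap: float = 0.0) -> list[MultimodalClip]:
    """Cut a trial into consecutive clips; a trailing remainder is dropped."""
    if clip_s <= 0:
        raise DomainError("clip_s must be positive")
    if not 0.0 <= overlap < 1.0:
        raise DomainError("overlap must lie in [0, 1)")
    duration = trial.meta.duration_s
    step = clip_s * (1.0 - overlap)
    n_clips = int(np.floor((duration - clip_s) / step + 1e-9)) + 1 if duration >= clip_s else 0
    if n_clips <= 0:
        warnings.warn(
            f"trial shorter than clip length ({duration} s < {clip_s} s): no clips",
            stacklevel=2,
        )
        return []
    clips = []
    ang_stream = trial.streams["angles"]
    for k in range(n_clips):
        start_s = k * step
        streams = {}
        for mod in ("image", "emg", "vio"):
            st = trial.streams[mod]
            i0 = round(st.rate * start_s)
            n = round(st.rate * clip_s)
            streams[mod] = ModalityStream(mod, st.samples[i0:i0 + n], st.rate,
                                          t0=start_s)
        a0 = round(ang_stream.rate * start_s)
        na = round(ang_stream.rate * clip_s)
        clips.append(MultimodalClip(
            streams=streams,
            angles=ang_stream.samples[a0:a0 + na],
            angle_rate=ang_stream.rate,
            phase_stance=trial.phase_stance[a0:a0 + na],
            subject_id=trial.meta.subject_id,
            speed_class=trial.meta.speed_class,
            speed_kmh=trial.meta.speed_kmh,
            trial_index=trial.meta.trial_index,
            clip_index=k,
            duration_s=clip_s,
        ))
    return clips


# ----------------------------------------------------------------- cohort I/O
class CohortDataset:
    """A cohort of simulated trials, in memory or backed by an HDF5 file.

    HDF5 layout: ``/subject_<id>/trial_<k>/{image,emg,vio,angles,phase}`` with
    per-dataset ``rate`` attributes, per-trial acquisition attributes, and the
    generator config embedded verbatim as a file attribute for provenance.
    """

    def __init__(self, config: GeneratorConfig, profiles: dict | None = None,
                 trials: list | None = None, path=None):
        self.config = config
        self.profiles = profiles or {}
        self._trials = trials or []          # in-memory RawTrial list
        self._index = []                     # list of TrialMeta
        self.path = path
        if trials:
            self._index = [t.meta for t in trials]

    # ---------------------------------------------------------------- queries
    @property
    def trial_metas(self) -> list[TrialMeta]:
        return list(self._index)

    @property
    def subject_ids(self) -> list[int]:
        return sorted({m.subject_id for m in self._index})

    def __len__(self) -> int:
        return len(self._index)

    def load_trial(self, i: int) -> RawTrial:
        if self._trials:
            return self._trials[i]
        meta = self._index[i]
        with h5py.File(self.path, "r") as f:
            grp = f[f"subject_{meta.subject_id}/trial_{meta.trial_index}"]
            streams = {
                mod: ModalityStream(mod, grp[mod][...], float(grp[mod].attrs["rate"]))
                for mod in MODALITIES
            }
            phase = grp["phase"][...].astype(bool)
        return RawTrial(streams=streams, phase_stance=phase, meta=meta)

    def iter_trials(self):
        for i in range(len(self._index)):
            yield self.load_trial(i)

    def clips(self, clip_s: float = 10.0) -> list[MultimodalClip]:
        out = []
        for trial in self.iter_trials():
            out.extend(segment_clips(trial, clip_s=clip_s))
        return out

    # -------------------------------------------------------------------- I/O
    def write(self, path) -> "CohortDataset":
        with h5py.File(path, "w") as f:
            f.attrs["config_yaml"] = self.config.to_yaml()
            f.attrs["profiles_json"] = json.dumps(
                {str(k): json.loads(v.to_json()) for k, v in self.profiles.items()}
            )
            for i, meta in enumerate(self._index):
                trial = self.load_trial(i)
                _write_trial(f, trial)
        return CohortDataset.open(path)

    @staticmethod
    def open(path) -> "CohortDataset":
        with h5py.File(path, "r") as f:
            config = GeneratorConfig.from_yaml(f.attrs["config_yaml"])
            profiles = {
                int(k): SubjectProfile.from_json(json.dumps(v))
                for k, v in json.loads(f.attrs["profiles_json"]).items()
            }
            index = []
            for sname in sorted(f.keys(), key=lambda s: int(s.split("_")[1])):
                sgrp = f[sname]
                for tname in sorted(sgrp.keys(), key=lambda s: int(s.split("_")[1])):
                    a = sgrp[tname].attrs
                    index.append(TrialMeta(
                        subject_id=int(a["subject_id"]),
                        trial_index=int(a["trial_index"]),
                        speed_kmh=float(a["speed_kmh"]),
                        speed_class=str(a["speed_class"]),
                        direction=str(a["direction"]),
                        duration_s=float(a["duration_s"]),
                        seed=int(a["seed"]),
                        stride_freq=float(a["stride_freq"]),
                        stance_frac=float(a["stance_frac"]),
                    ))
        ds = CohortDataset(config, profiles=profiles, path=path)
        ds._index = index
        return ds

    def export_angles_csv(self, path):
        """Tidy CSV of ground-truth angles: time_s, joint, side, angle_deg."""
        rows = []
        for trial in self.iter_trials():
            st = trial.streams["angles"]
            t = np.arange(st.n_samples) / st.rate
            for j, name in enumerate(JOINT_NAMES):
                side, joint = name.split("-")
                rows.append(pd.DataFrame({
                    "subject_id": trial.meta.subject_id,
                    "trial_index": trial.meta.trial_index,
                    "time_s": t,
                    "joint": joint,
                    "side": side,
                    "angle_deg": st.samples[:, j],
                }))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _write_trial(f: h5py.File, trial: RawTrial):
    meta = trial.meta
    grp = f.require_group(f"subject_{meta.subject_id}").create_group(
        f"trial_{meta.trial_index}"
    )
    for mod, st in trial.streams.items():
        comp = dict(compression="lzf") if mod == "image" else {}
        d = grp.create_dataset(mod, data=st.samples, **comp)
        d.attrs["rate"] = st.rate
    grp.create_dataset("phase", data=trial.phase_stance.astype(np.uint8))
    for k, v in asdict(meta).items():
        grp.attrs[k] = v


def make_cohort(n_subjects: int, trials_per_speed: int = 4, seed: int = 0,
                config: GeneratorConfig | None = None, path=None,
                duration_s: float | None = None) -> CohortDataset:
    """Simulate a full cohort: per subject, ``trials_per_speed`` trials at each
    of the three protocol speeds, alternating walking direction.

    With ``path`` given, trials are streamed to HDF5 as generated (memory stays
    bounded); otherwise the cohort is held in memory.
    """
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    if trials_per_speed < 1:
        raise DomainError("trials_per_speed must be >= 1")
    config = config or GeneratorConfig()
    duration = duration_s if duration_s is not None else config.duration_s
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    profiles = {}
    f = h5py.File(path, "w") if path is not None else None
    trials = [] if f is None else None
    index = []
    try:
        for s in range(n_subjects):
            profile = make_subject(int(subject_seeds[s]), config)
            profile.subject_id = s          # sequential cohort-local id
            profiles[profile.subject_id] = profile
            k = 0
            for speed in config.speeds_kmh:
                for _ in range(trials_per_speed):
                    tseed = int(master.integers(0, 2**31 - 1))
                    direction = "ccw" if k % 2 == 0 else "cw"
                    trial = simulate_trial(profile, speed, duration, direction,
                                           seed=tseed, config=config, trial_index=k)
                    index.append(trial.meta)
                    if f is not None:
                        _write_trial(f, trial)
                    else:
                        trials.append(trial)
                    k += 1
        if f is not None:
            f.attrs["config_yaml"] = config.to_yaml()
            f.attrs["profiles_json"] = json.dumps(
                {str(k): json.loads(v.to_json()) for k, v in profiles.items()}
            )
    finally:
        if f is not None:
            f.close()
    if path is not None:
        return CohortDataset.open(path)
    ds = CohortDataset(config, profiles=profiles, trials=trials)
    return ds
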