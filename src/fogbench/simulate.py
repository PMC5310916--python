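"""Synthetic waist-accelerometer cohorts with ground-truth FoG episodes.

The original home recordings are not publicly deposited, so this module
generates a stand-in cohort that realises exactly the signal properties the
detection methods rely on, and nothing more:

* walking concentrates spectral energy in the walking band (0.5–3 Hz):
  a step-frequency sinusoid with one harmonic, oscillating mainly along the
  gravity direction so the modulus channel sees it;
* FoG trembling concentrates energy in the freezing band (3–8 Hz) with the
  walking-band content attenuated tenfold;
* rest is gravity plus sensor noise;
* false-positive activities (tooth-brushing-like arm/trunk oscillation)
  place energy in the same 3–8 Hz band — indistinguishable from FoG by a
  spectral band ratio — but in a different posture (rotated gravity vector)
  and with a different cross-axis correlation structure, which the
  55-feature classifier can exploit.

Each of the ~21 simulated subjects is recorded in two sessions on one time
axis: an OFF-like session with frequent, longer FoG episodes and an ON-like
session with fewer episodes plus the false-positive activity block.
Episode durations are log-normal with mean 5.14 s (minimum 1 s).  Oscillation
amplitudes are calibrated so the power index of default walking sits near 2
of the dimensionless threshold-grid units, which makes the printed 0–4
threshold grid meaningful; the classifiers z-score features, so this choice
of absolute scale is immaterial to them.

Two cohort flavours exist.  In the default ``separable`` cohort, FoG and
false-positive signatures are cohort-consistent, so a single generic model
can separate them.  In the ``heterogeneous`` cohort every subject freezes
in a subject-specific posture and tremor direction, and the false-positive
activity is drawn from the same distribution — there is no cohort-level cue
separating the two, only a within-subject one, which is exactly the regime
in which personalised training should pay off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EpisodeSet
from .preprocess import Recording

SIM_FS = 200.0

# Amplitude calibration (g).  4096·a² is the raw-PSD power of a unit-aligned
# sinusoid of amplitude a in a 128-sample window, so walking at 0.022 g
# yields a power index near 2 grid units.  Trembling is ~4x the walking
# amplitude: with the walk-band content of a freeze attenuated tenfold,
# the freeze index of a clean fog window then reaches the 10^3 range.
WALK_AMP_G = 0.022
TREMOR_AMP_G = 0.09
FP_AMP_G = 0.09
NOISE_SD_G = 0.004
FOG_WALK_ATTENUATION = 0.1

EPISODE_MEAN_S = 5.14
EPISODE_SIGMA_LOG = 0.45
EPISODE_MIN_S = 1.0

SESSION_GAP_S = 60.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    axis = _unit(axis)
    return (
        v * np.cos(angle_rad)
        + np.cross(axis, v) * np.sin(angle_rad)
        + axis * np.dot(axis, v) * (1 - np.cos(angle_rad))
    )


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector orthogonal to v."""
    r = rng.normal(size=3)
    r -= r.dot(v) * v
    return _unit(r)


@dataclass
class SubjectProfile:
    """Per-subject signal parameters; all directions are unit vectors."""

    subject_id: str
    step_freq: float            # Hz, walking cadence fundamental
    walk_amp: float             # g
    tremor_freq: float          # Hz, 3–8 band
    tremor_amp: float           # g
    noise_sd: float             # g
    gravity_dir: np.ndarray     # resting posture
    fog_posture_dir: np.ndarray
    fog_tremor_dir: np.ndarray
    fp_posture_dir: np.ndarray
    fp_tremor_dir1: np.ndarray
    fp_tremor_dir2: np.ndarray
    fp_freq: float
    fp_amp: float
    fp_quadrature: bool         # circular (True) vs linear oscillation

    def __post_init__(self) -> None:
        if not 0.5 <= self.step_freq <= 3.0:
            raise ValueError("step frequency must lie in the walking band")
        if not 3.0 <= self.tremor_freq <= 8.0:
            raise ValueError("tremor frequency must lie in the freezing band")
        if min(self.walk_amp, self.tremor_amp, self.fp_amp) <= 0:
            raise ValueError("amplitudes must be positive")


@dataclass
class Segment:
    kind: str       # rest | walk | fog | fp_activity
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")


@dataclass
class ProtocolTemplate:
    """Session structure: FoG-containing and FoG-free walk/rest cycles.

    The OFF-like session uses ``n_fog_off`` episodes and no false-positive
    block; the ON-like session uses ``n_fog_on`` episodes plus
    ``fp_block_s`` seconds of false-positive activity.  Defaults target
    roughly 20-minute sessions; shorter studies scale the cycle counts and
    bout lengths down.
    """

    n_fog_off: int = 16
    n_fog_on: int = 5
    n_filler_off: int = 4
    n_filler_on: int = 10
    walk_s: float = 18.0
    rest_s: float = 14.0
    fp_block_s: float = 40.0
    n_fp_blocks_on: int = 2
    jitter: float = 0.2

    def reduced(self, scale: float) -> "ProtocolTemplate":
        """A proportionally smaller template.

        Cycle counts scale down (floored so every subject keeps at least
        two OFF and one ON episode, enough for the personal split) and bout
        durations shrink with floors of a few windows each, so the same
        activity structure fits a much shorter recording.
        """
        bout = max(scale, 0.28)
        return ProtocolTemplate(
            n_fog_off=max(2, round(self.n_fog_off * scale)),
            n_fog_on=max(1, round(self.n_fog_on * scale)),
            n_filler_off=max(1, round(self.n_filler_off * scale)),
            n_filler_on=max(2, round(self.n_filler_on * scale)),
            walk_s=max(5.0, self.walk_s * bout),
            rest_s=max(4.0, self.rest_s * bout),
            fp_block_s=max(10.0, self.fp_block_s * bout),
            n_fp_blocks_on=max(1, round(self.n_fp_blocks_on * scale * 4)),
            jitter=self.jitter,
        )


@dataclass
class SimOutput:
    """One simulated subject: two sessions on a single time axis."""

    subject_id: str
    recordings: dict           # {"OFF": Recording, "ON": Recording}
    episodes: EpisodeSet       # ground truth, global time
    segments: pd.DataFrame     # session, kind, start_s, end_s (global time)
    profile: SubjectProfile
    seed: int

    @property
    def session_spans(self) -> list[tuple[float, float]]:
        return [
            (rec.t0, rec.t0 + rec.duration_s)
            for rec in (self.recordings["OFF"], self.recordings["ON"])
        ]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir) / self.subject_id
        out.mkdir(parents=True, exist_ok=True)
        for session, rec in self.recordings.items():
            rec.to_csv(out / f"signal_{session}.csv")
        self.episodes.to_csv(out / "labels.csv")
        self.segments.to_csv(out / "segments.csv", index=False)
        manifest = {
            "subject_id": self.subject_id,
            "seed": self.seed,
            "fs": SIM_FS,
            "session_spans": self.session_spans,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _envelope(n: int, fs: float, ramp_s: float = 0.25) -> np.ndarray:
    """Raised-cosine on/off ramp limiting segment-edge spectral splatter."""
    env = np.ones(n)
    k = min(int(ramp_s * fs), n // 2)
    if k > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
        env[:k] = ramp
        env[-k:] = ramp[::-1]
    return env


def generate_segment(
    kind: str,
    duration: float,
    profile: SubjectProfile,
    rng: np.random.Generator,
    fs: float = SIM_FS,
) -> np.ndarray:
    """Synthesise one activity segment as an (n, 3) acceleration block in g."""
    if duration < 0.5:
        raise ValueError(f"segment duration must be >= 0.5 s, got {duration}")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    env = _envelope(n, fs)
    noise = rng.normal(0.0, profile.noise_sd, size=(n, 3))
    g = profile.gravity_dir

    if kind == "rest":
        return g[None, :] + noise

    if kind == "walk":
        f = profile.step_freq
        a = profile.walk_amp
        ph = rng.uniform(0, 2 * np.pi, size=3)
        lateral = _perpendicular(g, rng)
        osc = (
            np.outer(a * np.sin(2 * np.pi * f * t + ph[0]), g)
            + np.outer(0.3 * a * np.sin(4 * np.pi * f * t + ph[1]), g)
            + np.outer(0.3 * a * np.sin(2 * np.pi * f * t + ph[2]), lateral)
        )
        return g[None, :] + env[:, None] * osc + noise

    if kind == "fog":
        posture = profile.fog_posture_dir
        ph = rng.uniform(0, 2 * np.pi, size=2)
        tremor = np.outer(
            profile.tremor_amp * np.sin(2 * np.pi * profile.tremor_freq * t + ph[0]),
            profile.fog_tremor_dir,
        )
        residual_walk = np.outer(
            FOG_WALK_ATTENUATION
            * profile.walk_amp
            * np.sin(2 * np.pi * profile.step_freq * t + ph[1]),
            posture,
        )
        return posture[None, :] + env[:, None] * (tremor + residual_walk) + noise

    if kind == "fp_activity":
        posture = profile.fp_posture_dir
        ph = rng.uniform(0, 2 * np.pi)
        omega = 2 * np.pi * profile.fp_freq
        if profile.fp_quadrature:
            # per-axis sinusoids 120 deg apart: pairwise correlations are
            # +-1/2 (unlike the +-1 of a linear tremor) while the signed
            # weights keep the oscillation visible on the modulus channel
            weights, phases = _fp_phase_design(posture)
            osc = profile.fp_amp * np.sin(
                omega * t[:, None] + ph + phases[None, :]
            ) * weights[None, :]
        else:
            s = profile.fp_amp * np.sin(omega * t + ph)
            osc = np.outer(s, profile.fp_tremor_dir1)
        return posture[None, :] + env[:, None] * osc + noise

    raise ValueError(f"unknown segment kind {kind!r}")


def _fp_phase_design(posture: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis weights and 120-deg-spaced phases for the fp oscillation.

    Axis signs are chosen (4 candidates) to maximise the oscillation's
    projection onto the posture direction, so the modulus channel always
    carries enough freeze-band power for the band-ratio detector to fire.
    """
    phases = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    w = np.maximum(np.abs(posture), 0.35)
    w = w / np.linalg.norm(w)
    best_signs, best_r = None, -1.0
    for s2 in (1.0, -1.0):
        for s3 in (1.0, -1.0):
            signs = np.array([1.0, s2, s3])
            r = np.abs(np.sum(posture * signs * w * np.exp(1j * phases)))
            if r > best_r:
                best_signs, best_r = signs, r
    return best_signs * w, phases


def _draw_episode_duration(rng: np.random.Generator) -> float:
    mu = np.log(EPISODE_MEAN_S) - EPISODE_SIGMA_LOG**2 / 2
    return max(EPISODE_MIN_S, float(rng.lognormal(mu, EPISODE_SIGMA_LOG)))


def draw_profile(
    subject_id: str,
    rng: np.random.Generator,
    heterogeneity: str = "separable",
) -> SubjectProfile:
    """Draw one subject's signal parameters.

    ``separable``: cohort-consistent FoG signature (upright tremor along a
    gravity/sagittal mix) and false-positive signature (leaning posture,
    circular oscillation).  ``heterogeneous``: subject-specific postures and
    tremor directions for both, drawn from the same distribution, plus a
    wide tremor-frequency spread.
    """
    tilt_axis = _unit(rng.normal(size=3))
    g_dir = _rotate(np.array([0.0, 0.0, 1.0]), tilt_axis, rng.uniform(0, np.deg2rad(8)))

    if heterogeneity == "separable":
        # cohort-consistent body-frame directions: every subject trembles
        # along the same gravity/sagittal mix and leans the same way during
        # the false-positive activity, so a generic model can separate them
        x_hat = np.array([1.0, 0.0, 0.0])
        sagittal = _unit(x_hat - x_hat.dot(g_dir) * g_dir)
        tremor_freq = rng.uniform(6.0, 7.8)
        fog_posture = g_dir
        fog_tremor = _unit(0.9 * g_dir + 0.44 * sagittal)
        fp_posture = _rotate(g_dir, np.array([0.0, 1.0, 0.0]), np.deg2rad(rng.uniform(48, 62)))
        fp_sag = _unit(sagittal - sagittal.dot(fp_posture) * fp_posture)
        e1 = _unit(0.8 * fp_posture + 0.6 * fp_sag)
        e2 = _unit(np.cross(fp_posture, e1))
        fp_quadrature = True
        fp_freq = rng.uniform(4.0, 7.0)
    elif heterogeneity == "heterogeneous":
        tremor_freq = rng.uniform(3.3, 7.8)
        ax1, ax2 = _perpendicular(g_dir, rng), _perpendicular(g_dir, rng)
        fog_posture = _rotate(g_dir, ax1, np.deg2rad(rng.uniform(5, 60)))
        fog_tremor = _unit(0.7 * fog_posture + 0.7 * _perpendicular(fog_posture, rng))
        fp_posture = _rotate(g_dir, ax2, np.deg2rad(rng.uniform(5, 60)))
        e1 = _unit(0.7 * fp_posture + 0.7 * _perpendicular(fp_posture, rng))
        e2 = _perpendicular(e1, rng)
        fp_quadrature = False
        fp_freq = rng.uniform(3.3, 7.8)
    else:
        raise ValueError(f"unknown heterogeneity mode {heterogeneity!r}")

    return SubjectProfile(
        subject_id=subject_id,
        step_freq=rng.uniform(0.9, 1.4),
        walk_amp=WALK_AMP_G * rng.uniform(0.85, 1.2),
        tremor_freq=tremor_freq,
        tremor_amp=TREMOR_AMP_G * rng.uniform(0.85, 1.2),
        noise_sd=NOISE_SD_G * rng.uniform(0.8, 1.25),
        gravity_dir=g_dir,
        fog_posture_dir=fog_posture,
        fog_tremor_dir=fog_tremor,
        fp_posture_dir=fp_posture,
        fp_tremor_dir1=e1,
        fp_tremor_dir2=e2,
        fp_freq=fp_freq,
        fp_amp=FP_AMP_G * rng.uniform(0.85, 1.2),
        fp_quadrature=fp_quadrature,
    )


def build_session_segments(
    session: str, template: ProtocolTemplate, rng: np.random.Generator
) -> list[Segment]:
    """Assemble one session's ordered activity segments.

    Each FoG cycle is walk → fog → walk → rest so episodes are always
    adjacent to gait; filler cycles are walk → rest.  The ON-like session
    interleaves false-positive activity blocks between cycles.
    """
    def jit(x: float) -> float:
        return max(2.0, x * rng.uniform(1 - template.jitter, 1 + template.jitter))

    n_fog = template.n_fog_off if session == "OFF" else template.n_fog_on
    n_filler = template.n_filler_off if session == "OFF" else template.n_filler_on
    cycles = []
    for _ in range(n_fog):
        cycles.append(
            [
                Segment("walk", jit(template.walk_s)),
                Segment("fog", _draw_episode_duration(rng)),
                Segment("walk", jit(template.walk_s / 2)),
                Segment("rest", jit(template.rest_s)),
            ]
        )
    for _ in range(n_filler):
        cycles.append(
            [Segment("walk", jit(template.walk_s)), Segment("rest", jit(template.rest_s))]
        )
    order = rng.permutation(len(cycles))
    segments = [Segment("rest", jit(template.rest_s))]
    fp_positions = set()
    if session == "ON" and template.n_fp_blocks_on > 0:
        step = max(1, len(cycles) // (template.n_fp_blocks_on + 1))
        fp_positions = {step * (i + 1) for i in range(template.n_fp_blocks_on)}
    for pos, ci in enumerate(order):
        segments.extend(cycles[ci])
        if pos in fp_positions:
            segments.append(Segment("fp_activity", jit(template.fp_block_s)))
            segments.append(Segment("rest", jit(template.rest_s)))
    return segments


def generate_subject(
    subject_id: str,
    template: ProtocolTemplate,
    seed: int,
    heterogeneity: str = "separable",
) -> SimOutput:
    """Simulate both sessions for one subject on a shared time axis."""
    rng = np.random.default_rng(seed)
    profile = draw_profile(subject_id, rng, heterogeneity)
    recordings: dict[str, Recording] = {}
    episode_rows: list[tuple[float, float]] = []
    seg_rows = []
    t0 = 0.0
    for session in ("OFF", "ON"):
        segments = build_session_segments(session, template, rng)
        blocks, cursor = [], t0
        for seg in segments:
            block = generate_segment(seg.kind, seg.duration, profile, rng)
            actual = len(block) / SIM_FS
            if seg.kind == "fog":
                episode_rows.append((cursor, cursor + actual))
            seg_rows.append(
                {"session": session, "kind": seg.kind, "start_s": cursor,
                 "end_s": cursor + actual}
            )
            blocks.append(block)
            cursor += actual
        recordings[session] = Recording(
            subject_id=subject_id,
            session=session,
            fs=SIM_FS,
            t0=t0,
            samples=np.vstack(blocks),
        )
        t0 = cursor + SESSION_GAP_S
    return SimOutput(
        subject_id=subject_id,
        recordings=recordings,
        episodes=EpisodeSet(episode_rows),
        segments=pd.DataFrame(seg_rows),
        profile=profile,
        seed=seed,
    )


def generate_cohort(
    n_subjects: int = 21,
    template: ProtocolTemplate | None = None,
    seed: int = 0,
    heterogeneity: str = "separable",
) -> list[SimOutput]:
    """Simulate a cohort; fully reproducible from the master seed."""
    if n_subjects < 2:
        raise ValueError("cohort needs at least 2 subjects")
    template = template or ProtocolTemplate()
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        generate_subject(
            f"subj{i + 1:02d}",
            template,
            seed=int(children[i].generate_state(1)[0] % (2**31)),
            heterogeneity=heterogeneity,
        )
        for i in range(n_subjects)
    ]
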