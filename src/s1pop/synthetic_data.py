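"""Synthetic GCaMP6s-like population recordings with known ground truth.

No raw recordings are distributed with the experiments this package
emulates, so every pipeline stage is exercised on simulated data.  The
generator produces raw-fluorescence traces of the form

    F_i(t) = F0_i * (1 + sum_events a_ijk * kernel(t - onset)) + noise

where the kernel is a difference of exponentials (rise tau 0.18 s, decay
tau 1.5 s — a slow GCaMP6s-like transient sampled at the 0.229 s frame
period), a_ijk is the trial amplitude drawn lognormally around a
class-determined per-stimulus mean, and the noise is frame-wise Gaussian
proportional to the baseline (photon noise scales with brightness).

Population factories reproduce the archetypes of the emulated experiments:

* ``three_stimulus_population`` — Brush / Press / Pinch sessions with the
  seven Venn tuning subsets (default mixture: 17.0% brush-specific, 13.4%
  press-and-pinch, 50.2% broadly tuned among responders, ...).
* ``texture_dynamics_population`` — the 2x2 B-stroke / B-press / F-stroke /
  F-press design with texture-discriminative cells far outnumbering
  dynamics-discriminative ones (20% vs 3%).
* ``graded_pinch_population`` — P0..P3 graded pinches with intensity-coding
  (21.93%), invariant (15.30%), inverse (1.53%) and irregular (61.24%)
  responders.
* ``feature_coding_population`` — a four-stimulus session covering the
  noxiousness / dynamics / texture pairs, mixing texture-exclusive cells
  with forceps-responsive cells whose amplitudes co-vary across forceps
  stimuli (tightly between press and pinch, more loosely between stroke and
  press).

Every function is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .trace_processing import (
    FluorescenceRecording,
    StimulusEvent,
    StimulusProtocol,
)

FRAME_PERIOD_S = 0.229
RISE_TAU_S = 0.18
DECAY_TAU_S = 1.5

#: Default measurement-noise sigma (fraction of F0 per frame).
NOISE_SIGMA = 0.1
#: Default trial-to-trial amplitude coefficient of variation.
TRIAL_CV = 0.3


@dataclass(frozen=True)
class StimulusSpec:
    label: str
    texture: str
    dynamics: str
    noxiousness: str
    intensity_g: float | None = None
    duration_s: float = 5.0


@dataclass(frozen=True)
class ProtocolSpec:
    """Session layout: which stimuli, how many trials, what timing."""

    stimuli: tuple[StimulusSpec, ...]
    n_trials: int = 5
    isi_range_s: tuple[float, float] = (15.0, 20.0)
    frame_period_s: float = FRAME_PERIOD_S
    lead_in_s: float = 10.0
    post_window_s: float = 2.0

    def __post_init__(self):
        if not self.stimuli:
            raise ContractError("need at least one stimulus")
        if self.n_trials < 1:
            raise ContractError("n_trials must be >= 1")
        lo, hi = self.isi_range_s
        if not (0 < lo <= hi):
            raise ContractError("isi_range_s must satisfy 0 < lo <= hi")


#: Brush / Press / Pinch sessions (all 5 s, ISI 15-20 s).
THREE_STIMULI = ProtocolSpec(
    stimuli=(
        StimulusSpec("Brush", "brush", "stroke", "innocuous"),
        StimulusSpec("Press", "forceps", "press", "innocuous"),
        StimulusSpec("Pinch", "forceps", "press", "noxious", intensity_g=300.0),
    )
)

#: The 2x2 texture x dynamics design (all 5 s, ISI 15-20 s).
TEXTURE_DYNAMICS = ProtocolSpec(
    stimuli=(
        StimulusSpec("B-stroke", "brush", "stroke", "innocuous"),
        StimulusSpec("B-press", "brush", "press", "innocuous"),
        StimulusSpec("F-stroke", "forceps", "stroke", "innocuous"),
        StimulusSpec("F-press", "forceps", "press", "innocuous"),
    )
)

#: Graded forceps pinches: P0 < 2 g innocuous; P1-P3 100/200/300 g noxious
#: (3 s stimuli, fixed 20 s ISI).
GRADED_PINCH = ProtocolSpec(
    stimuli=(
        StimulusSpec("P0", "forceps", "press", "innocuous", 2.0, duration_s=3.0),
        StimulusSpec("P1", "forceps", "press", "noxious", 100.0, duration_s=3.0),
        StimulusSpec("P2", "forceps", "press", "noxious", 200.0, duration_s=3.0),
        StimulusSpec("P3", "forceps", "press", "noxious", 300.0, duration_s=3.0),
    ),
    isi_range_s=(20.0, 20.0),
)

#: One session covering the three single-feature contrasts:
#: noxiousness (F-press vs F-pinch), dynamics (F-stroke vs F-press),
#: texture (B-press vs F-press).
FEATURE_CODING = ProtocolSpec(
    stimuli=(
        StimulusSpec("B-press", "brush", "press", "innocuous"),
        StimulusSpec("F-stroke", "forceps", "stroke", "innocuous"),
        StimulusSpec("F-press", "forceps", "press", "innocuous"),
        StimulusSpec("F-pinch", "forceps", "press", "noxious", 300.0, duration_s=3.0),
    )
)


@dataclass(frozen=True)
class GroundTruth:
    """Known per-cell classes and evoked amplitudes behind a simulation."""

    cell_classes: np.ndarray  # per-cell class label
    amplitudes: np.ndarray  # cells x stimuli mean evoked dF/F0
    stimulus_labels: tuple[str, ...]
    f0: np.ndarray  # per-cell baseline fluorescence (a.u.)
    noise_sigma: float = NOISE_SIGMA
    trial_cv: float = TRIAL_CV
    rise_tau_s: float = RISE_TAU_S
    decay_tau_s: float = DECAY_TAU_S
    seed: int = 0
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        classes = np.asarray(self.cell_classes, dtype=object)
        f0 = np.asarray(self.f0, dtype=float)
        if amps.ndim != 2 or amps.shape[1] != len(self.stimulus_labels):
            raise ContractError("amplitudes must be cells x stimuli")
        if classes.shape != (amps.shape[0],) or f0.shape != (amps.shape[0],):
            raise ContractError("per-cell arrays must align")
        if np.any(amps < 0):
            raise ContractError("amplitudes must be >= 0")
        if np.any(f0 <= 0):
            raise ContractError("f0 must be > 0")
        if not (0 < self.rise_tau_s < self.decay_tau_s):
            raise ContractError("need decay_tau > rise_tau > 0")
        if self.noise_sigma < 0 or self.trial_cv < 0:
            raise ContractError("noise parameters must be >= 0")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "cell_classes", classes)
        object.__setattr__(self, "f0", f0)

    @property
    def n_cells(self) -> int:
        return self.amplitudes.shape[0]


def build_protocol(spec: ProtocolSpec, seed: int | None = 0) -> StimulusProtocol:
    """Randomized-order stimulus schedule converted to frames.

    Stimuli are shuffled within each trial block; inter-stimulus intervals
    are drawn uniformly from the configured range; times are converted to
    frames by rounding down.
    """
    rng = np.random.default_rng(seed)
    fp = spec.frame_period_s
    events = []
    t = spec.lead_in_s
    for block in range(1, spec.n_trials + 1):
        order = rng.permutation(len(spec.stimuli))
        for idx in order:
            s = spec.stimuli[idx]
            events.append(
                StimulusEvent(
                    label=s.label,
                    texture=s.texture,
                    dynamics=s.dynamics,
                    noxiousness=s.noxiousness,
                    intensity_g=s.intensity_g,
                    trial=block,
                    onset_frame=int(math.floor(t / fp)),
                    duration_frames=int(math.floor(s.duration_s / fp)),
                )
            )
            t += s.duration_s + float(rng.uniform(*spec.isi_range_s))
    return StimulusProtocol(
        events=tuple(events),
        post_window_frames=int(math.floor(spec.post_window_s / fp)),
    )


def gcamp_kernel(
    rise_tau: float = RISE_TAU_S,
    decay_tau: float = DECAY_TAU_S,
    frame_period: float = FRAME_PERIOD_S,
    duration_s: float = 10.0,
) -> np.ndarray:
    """Unit-peak difference-of-exponentials transient sampled at frames."""
    if not (0 < rise_tau < decay_tau):
        raise ContractError("need decay_tau > rise_tau > 0")
    t = np.arange(0.0, duration_s, frame_period)
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    peak = k.max()
    if peak <= 0:
        raise ContractError("kernel degenerate; lengthen duration_s")
    return k / peak


def simulate_population(
    truth: GroundTruth,
    protocol: StimulusProtocol,
    tail_s: float = 10.0,
    frame_period: float = FRAME_PERIOD_S,
) -> FluorescenceRecording:
    """Render raw fluorescence traces for a ground-truth population.

    Trial amplitudes are lognormal around the class mean (mean-preserving,
    cv = ``truth.trial_cv``); frame noise is Gaussian with s.d.
    ``noise_sigma * F0``.  Traces are clipped at 0 to respect the
    non-negativity of fluorescence.
    """
    rng = np.random.default_rng(truth.seed)
    kernel = gcamp_kernel(truth.rise_tau_s, truth.decay_tau_s, frame_period)
    n_frames = protocol.n_frames_required + int(math.floor(tail_s / frame_period))
    n_cells = truth.n_cells
    labels = list(truth.stimulus_labels)

    signal = np.zeros((n_cells, n_frames))
    # draw all trial gains in one deterministic block: cells x events
    if truth.trial_cv > 0:
        log_sd = math.sqrt(math.log(1.0 + truth.trial_cv**2))
        gains = rng.lognormal(-0.5 * log_sd**2, log_sd, size=(n_cells, len(protocol.events)))
    else:
        gains = np.ones((n_cells, len(protocol.events)))
    for e_idx, event in enumerate(protocol.events):
        j = labels.index(event.label)
        amps = truth.amplitudes[:, j] * gains[:, e_idx]
        stop = min(n_frames, event.onset_frame + len(kernel))
        seg = kernel[: stop - event.onset_frame]
        signal[:, event.onset_frame:stop] += amps[:, None] * seg[None, :]

    f = truth.f0[:, None] * (1.0 + signal)
    if truth.noise_sigma > 0:
        f = f + rng.normal(0.0, truth.noise_sigma, size=f.shape) * truth.f0[:, None]
    np.clip(f, 0.0, None, out=f)
    return FluorescenceRecording(fluor=f, frame_period_s=frame_period)


def _class_counts(n_cells: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder rounding of proportions to integer cell counts."""
    total = sum(proportions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ContractError(f"proportions must sum to 1 (got {total})")
    raw = {k: v * n_cells for k, v in proportions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n_cells - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _base_amplitudes(rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-cell evoked-amplitude scale: uniform 0.6-2.0 dF/F0 at the peak."""
    return rng.uniform(0.6, 2.0, size=n)


def _jitter(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Mean-1 lognormal multiplicative jitter."""
    if sd <= 0:
        return np.ones(n)
    return rng.lognormal(-0.5 * sd**2, sd, size=n)


def _assemble(
    rng: np.random.Generator,
    stimulus_labels,
    class_rows: list[tuple[str, np.ndarray]],
    noise_sigma: float,
    trial_cv: float,
    seed: int,
    extra: dict | None = None,
) -> GroundTruth:
    classes = np.array([c for c, _ in class_rows], dtype=object)
    amps = np.vstack([a for _, a in class_rows]) if class_rows else np.empty((0, 0))
    order = rng.permutation(len(classes))
    return GroundTruth(
        cell_classes=classes[order],
        amplitudes=amps[order],
        stimulus_labels=tuple(stimulus_labels),
        f0=rng.uniform(80.0, 120.0, size=len(classes)),
        noise_sigma=noise_sigma,
        trial_cv=trial_cv,
        seed=seed,
        extra=extra or {},
    )


#: Venn-subset mixture among responders for Brush/Press/Pinch sessions.
#: Five subsets follow the reported population (brush-specific 17.0%,
#: press-specific 0.92%, pinch-specific 5.99%, press-and-pinch 13.4%,
#: broadly tuned 50.2%); the two unreported subsets split the remainder.
THREE_STIMULUS_MIXTURE = {
    "Brush": 0.170,
    "Press": 0.0092,
    "Pinch": 0.0599,
    "Brush+Press": 0.0625,
    "Brush+Pinch": 0.0624,
    "Press+Pinch": 0.134,
    "Brush+Press+Pinch": 0.502,
}


def three_stimulus_population(
    n_cells: int = 217,
    seed: int = 0,
    mixture: dict[str, float] | None = None,
    non_responder_fraction: float = 0.1,
    noise_sigma: float = NOISE_SIGMA,
    trial_cv: float = TRIAL_CV,
) -> GroundTruth:
    """Brush/Press/Pinch population with known Venn tuning subsets.

    ``mixture`` gives subset proportions among responders; an additional
    ``non_responder_fraction`` of silent cells is appended on top.
    """
    mixture = dict(THREE_STIMULUS_MIXTURE if mixture is None else mixture)
    rng = np.random.default_rng(seed)
    labels = ("Brush", "Press", "Pinch")
    n_resp = int(round(n_cells * (1 - non_responder_fraction)))
    counts = _class_counts(n_resp, mixture)
    rows: list[tuple[str, np.ndarray]] = []
    for subset, count in counts.items():
        members = subset.split("+")
        tuned = np.array([lab in members for lab in labels])
        for _ in range(count):
            amp = float(_base_amplitudes(rng, 1)[0])
            row = np.where(tuned, amp * _jitter(rng, 3, 0.1), 0.0)
            rows.append((subset, row))
    for _ in range(n_cells - n_resp):
        rows.append(("non_responder", np.zeros(3)))
    return _assemble(rng, labels, rows, noise_sigma, trial_cv, seed)


#: Discriminative-class mixture among responders for the 2x2 design:
#: texture-discriminative cells far outnumber dynamics-discriminative ones.
TEXTURE_DYNAMICS_MIXTURE = {
    "texture": 0.20,
    "dynamics": 0.03,
    "broad": 0.50,
    "other": 0.27,
}


def texture_dynamics_population(
    n_cells: int = 208,
    seed: int = 0,
    mixture: dict[str, float] | None = None,
    non_responder_fraction: float = 0.1,
    noise_sigma: float = NOISE_SIGMA,
    trial_cv: float = TRIAL_CV,
) -> GroundTruth:
    """B-stroke/B-press/F-stroke/F-press population with known classes.

    Texture-discriminative cells respond to both same-texture stimuli
    (half prefer brush, half forceps); dynamics-discriminative cells to both
    same-dynamics stimuli; broad cells to all four; "other" cells to exactly
    one or exactly three stimuli.
    """
    mixture = dict(TEXTURE_DYNAMICS_MIXTURE if mixture is None else mixture)
    rng = np.random.default_rng(seed)
    labels = ("B-stroke", "B-press", "F-stroke", "F-press")
    texture_sets = (np.array([1, 1, 0, 0], bool), np.array([0, 0, 1, 1], bool))
    dynamics_sets = (np.array([1, 0, 1, 0], bool), np.array([0, 1, 0, 1], bool))
    n_resp = int(round(n_cells * (1 - non_responder_fraction)))
    counts = _class_counts(n_resp, mixture)
    rows: list[tuple[str, np.ndarray]] = []
    for cls, count in counts.items():
        for i in range(count):
            amp = float(_base_amplitudes(rng, 1)[0])
            if cls == "texture":
                tuned = texture_sets[i % 2]
            elif cls == "dynamics":
                tuned = dynamics_sets[i % 2]
            elif cls == "broad":
                tuned = np.ones(4, bool)
            else:  # other: exactly 1 or exactly 3 stimuli
                tuned = np.zeros(4, bool)
                if i % 2 == 0:
                    tuned[rng.integers(4)] = True
                else:
                    tuned[:] = True
                    tuned[rng.integers(4)] = False
            row = np.where(tuned, amp * _jitter(rng, 4, 0.1), 0.0)
            rows.append((cls, row))
    for _ in range(n_cells - n_resp):
        rows.append(("non_responder", np.zeros(4)))
    return _assemble(rng, labels, rows, noise_sigma, trial_cv, seed)


#: Intensity-response mixture among responders for graded pinches.
GRADED_PINCH_MIXTURE = {
    "intensity_coding": 0.2193,
    "invariant": 0.1530,
    "inverse": 0.0153,
    "irregular": 0.6124,
}

#: Relative gain per intensity level for intensity-coding cells.  Chosen so
#: that, with evoked amplitudes spanning 0.6-2.0 dF/F0, cells cross the
#: 0.30 response threshold at different levels: none respond at the
#: innocuous P0 and progressively more are recruited at each stronger
#: pinch, reproducing the rising recruitment curve alongside rising
#: amplitude and fidelity.
INTENSITY_GAINS = np.array([0.12, 0.2, 0.32, 0.5])

#: Gain multiset for irregular cells (shuffled per cell, monotone orders
#: rejected).  Kept well above threshold at every level so the irregular
#: majority contributes amplitude scatter, not recruitment noise.
IRREGULAR_GAINS = np.array([0.55, 0.7, 0.85, 1.0])


def graded_pinch_population(
    n_cells: int = 197,
    seed: int = 0,
    mixture: dict[str, float] | None = None,
    non_responder_fraction: float = 0.1,
    noise_sigma: float = NOISE_SIGMA,
    trial_cv: float = TRIAL_CV,
) -> GroundTruth:
    """P0..P3 graded-pinch population with known intensity-response classes.

    Intensity-coding cells rise monotonically with the level (crossing the
    response threshold at level-dependent forces), invariant cells keep a
    flat supra-threshold profile, inverse cells fall with intensity, and
    irregular cells use a random non-monotonic gain order that stays
    supra-threshold at every level.
    """
    mixture = dict(GRADED_PINCH_MIXTURE if mixture is None else mixture)
    rng = np.random.default_rng(seed)
    labels = ("P0", "P1", "P2", "P3")
    n_resp = int(round(n_cells * (1 - non_responder_fraction)))
    counts = _class_counts(n_resp, mixture)
    rows: list[tuple[str, np.ndarray]] = []
    for cls, count in counts.items():
        for _ in range(count):
            amp = float(_base_amplitudes(rng, 1)[0])
            if cls == "intensity_coding":
                gains = INTENSITY_GAINS
            elif cls == "invariant":
                gains = np.ones(4)
            elif cls == "inverse":
                gains = INTENSITY_GAINS[::-1]
            else:  # irregular: shuffled gains, rejected if monotone
                while True:
                    gains = rng.permutation(IRREGULAR_GAINS)
                    d = np.diff(gains)
                    if not (np.all(d > 0) or np.all(d < 0)):
                        break
            rows.append((cls, amp * gains))
    for _ in range(n_cells - n_resp):
        rows.append(("non_responder", np.zeros(4)))
    return _assemble(rng, labels, rows, noise_sigma, trial_cv, seed)


#: Mixture for the single-feature-contrast session.
FEATURE_CODING_MIXTURE = {
    "brush_selective": 0.20,
    "forceps_broad": 0.52,
    "broadly_tuned": 0.28,
}

#: Amplitude co-variation of forceps-responsive cells across forceps
#: stimuli: pinch amplitudes track press tightly (small jitter) but run
#: uniformly higher (press-responsive cells respond to pinch with larger
#: transients), stroke tracks press more loosely — so noxiousness is the
#: least and dynamics the next-least exclusive contrast, while texture is
#: carried by a dedicated exclusive population.  The pinch gain and the
#: per-cell stroke jitter are what make both contrasts decodable from the
#: population pattern despite low single-cell selectivity.
FORCEPS_PINCH_JITTER = 0.1
FORCEPS_PINCH_GAIN = 1.5
FORCEPS_STROKE_JITTER = 0.3


def feature_coding_population(
    n_cells: int = 120,
    seed: int = 0,
    mixture: dict[str, float] | None = None,
    non_responder_fraction: float = 0.1,
    noise_sigma: float = NOISE_SIGMA,
    trial_cv: float = TRIAL_CV,
) -> GroundTruth:
    """Session covering noxiousness / dynamics / texture stimulus pairs.

    Brush-selective cells respond only to B-press (texture-exclusive);
    forceps-responsive cells respond to F-stroke, F-press and F-pinch with
    correlated per-cell amplitudes; broadly tuned cells respond to all four
    and are filtered out of selectivity analyses downstream.
    """
    mixture = dict(FEATURE_CODING_MIXTURE if mixture is None else mixture)
    rng = np.random.default_rng(seed)
    labels = ("B-press", "F-stroke", "F-press", "F-pinch")
    n_resp = int(round(n_cells * (1 - non_responder_fraction)))
    counts = _class_counts(n_resp, mixture)
    rows: list[tuple[str, np.ndarray]] = []
    for cls, count in counts.items():
        for _ in range(count):
            amp = float(_base_amplitudes(rng, 1)[0])
            if cls == "brush_selective":
                row = np.array([amp, 0.0, 0.0, 0.0])
            elif cls == "forceps_broad":
                press = amp
                stroke = amp * float(_jitter(rng, 1, FORCEPS_STROKE_JITTER)[0])
                pinch = (
                    FORCEPS_PINCH_GAIN
                    * amp
                    * float(_jitter(rng, 1, FORCEPS_PINCH_JITTER)[0])
                )
                row = np.array([0.0, stroke, press, pinch])
            else:  # broadly_tuned
                row = amp * _jitter(rng, 4, 0.15)
            rows.append((cls, row))
    for _ in range(n_cells - n_resp):
        rows.append(("non_responder", np.zeros(4)))
    return _assemble(rng, labels, rows, noise_sigma, trial_cv, seed)


def simulate_cohort(
    factory,
    protocol_spec: ProtocolSpec,
    n_mice: int,
    cells_per_mouse: int,
    seed: int = 0,
    **factory_kwargs,
):
    """Simulate one session per mouse with independent seeds.

    Returns a list of ``(recording, protocol, truth)`` triples; each mouse
    gets its own randomized stimulus order and population draw, all derived
    deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    sessions = []
    for child in ss.spawn(n_mice):
        child_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        truth = factory(n_cells=cells_per_mouse, seed=child_seed, **factory_kwargs)
        protocol = build_protocol(protocol_spec, seed=child_seed + 1)
        recording = simulate_population(truth, protocol)
        sessions.append((recording, protocol, truth))
    return sessions
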