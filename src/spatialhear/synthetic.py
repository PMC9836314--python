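"""Ground-truthed synthetic listeners: head traces and response records.

The generator is phenomenological: it does not model acoustics, only the
statistical structure the analysis assumes.  Per trial it draws

* item correctness (color, number) from a per-subject logistic model with
  additive logit effects of SNR, hemifield, listening condition and a
  hemifield-by-SNR interaction,
* a localization endpoint = target azimuth + wrapped-normal error, with a
  front-back reversal (mirror about the interaural axis) at some probability,
* a reaction time from a lognormal whose median shifts with hemifield and
  SNR; "slow responder" subjects (median RT > 1.5 s, no condition effects)
  emulate listeners who wait for the color/number before orienting,
* optionally a head trace: fixation at 0 deg, a single minimum-jerk saccade
  of monophasic velocity starting at the RT, amplitude-dependent duration
  (main-sequence-like), plus white position noise.

Every trial's true onset/endpoint/correctness is emitted on a separate truth
channel that analysis modules never read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import COLORS, CONDITIONS, NUMBERS, generate_schedule, wrap_angle
from .headtrack import HeadTrace

__all__ = [
    "ListenerModel", "CohortHyperparameters", "SimulatedCohort",
    "simulate_responses", "make_saccade_trace", "make_two_step_trace",
    "simulate_trial", "cohort_trials", "draw_models", "simulate_cohort",
]

RESPONDER_CUTOFF_S = 1.5


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def mirror_front_back(az_deg):
    """Reflect an azimuth about the interaural (left-right) axis."""
    az = np.asarray(az_deg, dtype=float)
    return wrap_angle(np.where(az >= 0, 180.0 - az, -180.0 - az))


@dataclass(frozen=True)
class ListenerModel:
    """Per-subject behavioral parameters.

    Intelligibility is per item (color or number) on the logit scale; the
    reference cell is condition NH, front hemifield, +5 dB SNR.  Localization
    error SD multiplies a base dispersion by condition/hemifield/SNR factors.
    RT is lognormal: ``median * back_factor^[back] * snr5_factor^[+5] *
    exp(sigma * z)``.
    """

    base_logit: float = 1.2
    effect_snr10: float = 1.1          # +10 dB advantage (logit)
    effect_back: float = -0.8          # rear-hemifield penalty (logit)
    effect_back_snr5: float = -0.45    # extra rear penalty at +5 dB (logit)
    effect_condition: dict = field(default_factory=lambda: {
        "NH": 0.0, "NH-LPF": -0.10, "OTE": -0.30,
        "OTE-LPF": -0.35, "ITE": -0.50, "ITE-LPF": -0.65,
    })

    loc_base_sd_deg: float = 6.0
    loc_sd_condition: dict = field(default_factory=lambda: {
        "NH": 1.0, "NH-LPF": 1.15, "OTE": 1.8,
        "OTE-LPF": 1.9, "ITE": 1.3, "ITE-LPF": 1.4,
    })
    loc_sd_back_factor: float = 1.9
    loc_sd_snr5_factor: float = 1.5
    fb_confusion_prob: float = 0.05

    rt_median_s: float = 0.9
    rt_sigma: float = 0.25
    rt_back_factor: float = 1.25
    rt_snr5_factor: float = 1.2
    responder_class: str = "fast"      # "fast" | "slow"

    def __post_init__(self):
        if not 0.0 <= self.fb_confusion_prob <= 1.0:
            raise ValueError("fb_confusion_prob must be a probability")
        if self.loc_base_sd_deg <= 0 or self.rt_sigma <= 0 or self.rt_median_s <= 0:
            raise ValueError("dispersions and RT median must be positive")
        if self.responder_class not in ("fast", "slow"):
            raise ValueError("responder_class must be 'fast' or 'slow'")
        if self.responder_class == "slow" and self.rt_median_s <= RESPONDER_CUTOFF_S:
            raise ValueError("slow responder requires median RT > 1.5 s")

    def p_item_correct(self, condition: str, snr_db: int, hemifield: str) -> float:
        logit = (self.base_logit
                 + (self.effect_snr10 if snr_db == 10 else 0.0)
                 + (self.effect_back if hemifield == "back" else 0.0)
                 + (self.effect_back_snr5 if (hemifield == "back" and snr_db == 5) else 0.0)
                 + self.effect_condition[condition])
        return float(_sigmoid(logit))

    def loc_error_sd(self, condition: str, snr_db: int, hemifield: str) -> float:
        sd = self.loc_base_sd_deg * self.loc_sd_condition[condition]
        if hemifield == "back":
            sd *= self.loc_sd_back_factor
        if snr_db == 5:
            sd *= self.loc_sd_snr5_factor
        return sd

    def rt_median(self, snr_db: int, hemifield: str) -> float:
        m = self.rt_median_s
        if hemifield == "back":
            m *= self.rt_back_factor
        if snr_db == 5:
            m *= self.rt_snr5_factor
        return m


def _slow_variant() -> dict:
    # slow responders wait out the sentence; behavior insensitive to condition/SNR
    return dict(rt_median_s=1.9, rt_sigma=0.15, rt_back_factor=1.0, rt_snr5_factor=1.0,
                responder_class="slow")


@dataclass(frozen=True)
class CohortHyperparameters:
    """Population distribution the per-subject :class:`ListenerModel` is drawn from.

    Means are the :class:`ListenerModel` defaults; ``*_sd`` are between-subject
    normal SDs on the logit effects and lognormal SDs on the positive scales.
    """

    mean: ListenerModel = field(default_factory=ListenerModel)
    base_logit_sd: float = 0.4
    effect_snr10_sd: float = 0.20
    effect_back_sd: float = 0.20
    effect_back_snr5_sd: float = 0.10
    effect_condition_sd: float = 0.10
    loc_base_sd_logsd: float = 0.20
    rt_median_logsd: float = 0.15
    n_slow: int = 3

    @classmethod
    def null(cls, base_logit: float = 1.2, **kwargs) -> "CohortHyperparameters":
        """All factor effects zero: cells differ only through the subject."""
        mean = ListenerModel(
            base_logit=base_logit, effect_snr10=0.0, effect_back=0.0,
            effect_back_snr5=0.0,
            effect_condition={c: 0.0 for c in CONDITIONS},
            loc_sd_condition={c: 1.0 for c in CONDITIONS},
            loc_sd_back_factor=1.0, loc_sd_snr5_factor=1.0,
            rt_back_factor=1.0, rt_snr5_factor=1.0,
        )
        defaults = dict(mean=mean, effect_snr10_sd=0.0, effect_back_sd=0.0,
                        effect_back_snr5_sd=0.0, effect_condition_sd=0.0, n_slow=0)
        defaults.update(kwargs)
        return cls(**defaults)


def draw_models(n_subjects: int, hyper: CohortHyperparameters,
                rng: np.random.Generator) -> list[ListenerModel]:
    """Draw per-subject models; the first ``min(n_slow, n_subjects)`` get the slow archetype."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    n_slow = min(hyper.n_slow, n_subjects)
    m = hyper.mean
    models = []
    for i in range(n_subjects):
        cond = {c: m.effect_condition[c]
                + (rng.normal(0.0, hyper.effect_condition_sd) if c != "NH" else 0.0)
                for c in CONDITIONS}
        kwargs = dict(
            base_logit=rng.normal(m.base_logit, hyper.base_logit_sd),
            effect_snr10=rng.normal(m.effect_snr10, hyper.effect_snr10_sd),
            effect_back=rng.normal(m.effect_back, hyper.effect_back_sd),
            effect_back_snr5=rng.normal(m.effect_back_snr5, hyper.effect_back_snr5_sd),
            effect_condition=cond,
            loc_base_sd_deg=m.loc_base_sd_deg * np.exp(rng.normal(0.0, hyper.loc_base_sd_logsd)),
            loc_sd_condition=dict(m.loc_sd_condition),
            loc_sd_back_factor=m.loc_sd_back_factor,
            loc_sd_snr5_factor=m.loc_sd_snr5_factor,
            fb_confusion_prob=m.fb_confusion_prob,
            # fast archetype: bounded so the class stays on its side of the
            # 1.5 s cutoff (the cohort's fast/slow split is bimodal, not graded)
            rt_median_s=min(1.1, m.rt_median_s * np.exp(rng.normal(0.0, hyper.rt_median_logsd))),
            rt_sigma=m.rt_sigma,
            rt_back_factor=m.rt_back_factor,
            rt_snr5_factor=m.rt_snr5_factor,
        )
        if i < n_slow:
            kwargs.update(_slow_variant())
            # jittered around the waiting-listener median, kept above the class cutoff
            kwargs["rt_median_s"] = max(
                1.6, 1.9 * np.exp(rng.normal(0.0, hyper.rt_median_logsd / 2)))
        models.append(ListenerModel(**kwargs))
    return models


def cohort_trials(n_subjects: int, seed: int, **schedule_kwargs) -> pd.DataFrame:
    """Full factorial schedules for a cohort, with globally unique trial ids."""
    frames = []
    offset = 0
    for i in range(n_subjects):
        arm = "OTE-first" if i % 2 == 0 else "ITE-first"
        sched = generate_schedule(f"S{i + 1:02d}", arm, seed=seed + i, **schedule_kwargs)
        df = sched.to_frame()
        df["trial_id"] = df["trial_id"] + offset
        offset += len(df)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_responses(trials: pd.DataFrame, models: dict[str, ListenerModel],
                       rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized record-level simulation: (responses, truth) tables.

    The responses table is what a perfectly reviewed detection pass would
    yield (reported color/number, RT, endpoint, promptness, empty QC flags);
    the truth table carries the generating values for recovery tests.
    """
    n = len(trials)
    subj = trials["subject"].to_numpy()
    cond = trials["condition"].to_numpy()
    snr = trials["snr_db"].to_numpy()
    hemi = trials["target_hemifield"].to_numpy()
    target_az = trials["target_azimuth_deg"].to_numpy(dtype=float)
    target_color = trials["target_color"].to_numpy()
    target_number = trials["target_number"].to_numpy()

    p = np.empty(n)
    sd = np.empty(n)
    rt_med = np.empty(n)
    rt_sigma = np.empty(n)
    fb_p = np.empty(n)
    for s, model in models.items():
        for c in CONDITIONS:
            for q in (5, 10):
                for h in ("front", "back"):
                    m = (subj == s) & (cond == c) & (snr == q) & (hemi == h)
                    if not m.any():
                        continue
                    p[m] = model.p_item_correct(c, q, h)
                    sd[m] = model.loc_error_sd(c, q, h)
                    rt_med[m] = model.rt_median(q, h)
                    rt_sigma[m] = model.rt_sigma
                    fb_p[m] = model.fb_confusion_prob

    color_correct = rng.random(n) < p
    number_correct = rng.random(n) < p
    reversed_ = rng.random(n) < fb_p
    err = rng.normal(0.0, 1.0, n) * sd
    base = np.where(reversed_, mirror_front_back(target_az), target_az)
    endpoint = wrap_angle(base + err)
    rt = rt_med * np.exp(rng.normal(0.0, 1.0, n) * rt_sigma)

    # wrong reports drawn uniformly from the remaining alternatives
    color_pos = pd.Series(target_color).map({c: i for i, c in enumerate(COLORS)}).to_numpy()
    rep_color = np.array(target_color, dtype=object)
    wrong = ~color_correct
    shift = rng.integers(1, len(COLORS), size=n)
    rep_color[wrong] = np.array(COLORS, dtype=object)[(color_pos[wrong] + shift[wrong]) % len(COLORS)]
    rep_number = target_number.astype(int).copy()
    wrongn = ~number_correct
    shiftn = rng.integers(1, len(NUMBERS), size=n)
    rep_number[wrongn] = ((target_number[wrongn].astype(int) - 1 + shiftn[wrongn]) % len(NUMBERS)) + 1

    responses = pd.DataFrame({
        "trial_id": trials["trial_id"].to_numpy(),
        "subject": subj,
        "reported_color": rep_color,
        "reported_number": rep_number,
        "onset_s": rt,
        "offset_s": rt + 0.2 + 0.0025 * np.abs(endpoint),
        "endpoint_deg": endpoint,
        "rt_s": rt,
        "promptness_inv_s": 1.0 / rt,
        "qc_flags": "",
    })
    truth = pd.DataFrame({
        "trial_id": trials["trial_id"].to_numpy(),
        "subject": subj,
        "true_onset_s": rt,
        "true_endpoint_deg": endpoint,
        "fb_reversed": reversed_,
        "color_correct": color_correct,
        "number_correct": number_correct,
        "responder_class": [models[s].responder_class for s in subj],
    })
    return responses, truth


def make_saccade_trace(
    onset_s: float,
    endpoint_deg: float,
    sample_rate: float = 100.0,
    duration_s: float = 4.5,
    noise_sd_deg: float = 0.5,
    rng: np.random.Generator | None = None,
    start_deg: float = 0.0,
    main_seq_intercept_s: float = 0.2,
    main_seq_slope_s_per_deg: float = 0.0025,
    trial_id: int | None = None,
) -> HeadTrace:
    """Single minimum-jerk saccade from fixation to ``endpoint_deg``.

    Position follows ``s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5`` over a
    movement duration that grows linearly with amplitude (main-sequence-like),
    so the velocity profile is smooth, bell-shaped and monophasic.
    """
    if sample_rate < 50:
        raise ValueError("sample_rate must be >= 50 Hz")
    t = np.arange(0.0, duration_s, 1.0 / sample_rate)
    amp = wrap_angle(endpoint_deg - start_deg)
    move_dur = main_seq_intercept_s + main_seq_slope_s_per_deg * abs(amp)
    tau = np.clip((t - onset_s) / move_dur, 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    pos = start_deg + amp * s
    if noise_sd_deg > 0:
        if rng is None:
            rng = np.random.default_rng()
        pos = pos + rng.normal(0.0, noise_sd_deg, len(pos))
    return HeadTrace(time_s=t, azimuth_deg=wrap_angle(pos), trial_id=trial_id)


def make_two_step_trace(onsets_s, endpoints_deg, sample_rate: float = 100.0,
                        duration_s: float = 4.5, noise_sd_deg: float = 0.0,
                        rng: np.random.Generator | None = None,
                        trial_id: int | None = None) -> HeadTrace:
    """Detector stress trace: consecutive saccades (e.g. corrective search)."""
    t = np.arange(0.0, duration_s, 1.0 / sample_rate)
    pos = np.zeros_like(t)
    start = 0.0
    for onset, endpoint in zip(onsets_s, endpoints_deg):
        amp = wrap_angle(endpoint - start)
        move_dur = 0.2 + 0.0025 * abs(amp)
        tau = np.clip((t - onset) / move_dur, 0.0, 1.0)
        pos = pos + amp * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
        start = endpoint
    if noise_sd_deg > 0:
        if rng is None:
            rng = np.random.default_rng()
        pos = pos + rng.normal(0.0, noise_sd_deg, len(pos))
    return HeadTrace(time_s=t, azimuth_deg=wrap_angle(pos), trial_id=trial_id)


def simulate_trial(spec, model: ListenerModel, sample_rate: float = 100.0,
                   seed: int | None = None, noise_sd_deg: float = 0.5,
                   duration_s: float = 4.5):
    """Simulate one trial with a head trace; returns (trace, response row, truth row)."""
    rng = np.random.default_rng(seed)
    trials = pd.DataFrame([{
        "trial_id": spec.trial_id, "subject": spec.subject_id,
        "condition": spec.condition, "snr_db": spec.snr_db,
        "target_hemifield": spec.target_hemifield,
        "target_azimuth_deg": spec.target_azimuth_deg,
        "target_color": spec.target_sentence.color,
        "target_number": spec.target_sentence.number,
    }])
    responses, truth = simulate_responses(trials, {spec.subject_id: model}, rng)
    rec, tru = responses.iloc[0], truth.iloc[0]
    trace = make_saccade_trace(
        float(tru["true_onset_s"]), float(tru["true_endpoint_deg"]),
        sample_rate=sample_rate, duration_s=duration_s,
        noise_sd_deg=noise_sd_deg, rng=rng, trial_id=spec.trial_id,
    )
    return trace, rec, tru


@dataclass
class SimulatedCohort:
    trials: pd.DataFrame
    responses: pd.DataFrame
    truth: pd.DataFrame
    traces: list[HeadTrace] | None
    models: dict[str, ListenerModel]
    manifest: dict


def simulate_cohort(
    n_subjects: int = 10,
    seed: int = 0,
    hyper: CohortHyperparameters | None = None,
    traces: bool = False,
    sample_rate: float = 100.0,
    noise_sd_deg: float = 0.5,
    duration_s: float = 4.5,
    **schedule_kwargs,
) -> SimulatedCohort:
    """Simulate a full cohort: schedules, responses, truth and (optionally) traces.

    With ``traces=True`` the responses table omits the movement columns; they
    are meant to be filled by running the detector on the emitted traces.
    Deterministic given ``seed``.
    """
    hyper = hyper or CohortHyperparameters()
    ss = np.random.SeedSequence(seed)
    model_rng, resp_rng, trace_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    trials = cohort_trials(n_subjects, seed=int(ss.generate_state(1)[0] % 2**31),
                           **schedule_kwargs)
    model_list = draw_models(n_subjects, hyper, model_rng)
    models = {f"S{i + 1:02d}": m for i, m in enumerate(model_list)}
    responses, truth = simulate_responses(trials, models, resp_rng)

    trace_list = None
    if traces:
        trace_list = [
            make_saccade_trace(float(o), float(e), sample_rate=sample_rate,
                               duration_s=duration_s, noise_sd_deg=noise_sd_deg,
                               rng=trace_rng, trial_id=int(tid))
            for tid, o, e in zip(truth["trial_id"], truth["true_onset_s"],
                                 truth["true_endpoint_deg"])
        ]
        responses = responses[["trial_id", "subject", "reported_color",
                               "reported_number"]].copy()

    manifest = {
        "n_subjects": n_subjects, "seed": seed, "traces": traces,
        "sample_rate": sample_rate, "noise_sd_deg": noise_sd_deg,
        "duration_s": duration_s, "n_slow": hyper.n_slow,
        "schedule_kwargs": {k: repr(v) for k, v in schedule_kwargs.items()},
    }
    return SimulatedCohort(trials=trials, responses=responses, truth=truth,
                           traces=trace_list, models=models, manifest=manifest)
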