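"""Experimental design: CRM sentence space, speaker array, trial schedules.

The listening experiment presents four simultaneous coordinate-response-measure
(CRM) sentences, one from each quadrant of a horizontal 12-speaker ring
(30 deg spacing).  The target stream carries the call sign "Hopper"; the
listener reports the target's color/number and orients the head toward it.
Six listening conditions (bare ears and two hearing-protection devices, each
with and without a low-pass "simulated hearing loss" filter) are crossed with
two signal-to-noise ratios (+5/+10 dB) and run as 96-trial blocks (576 trials
per subject).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CALL_SIGNS",
    "COLORS",
    "NUMBERS",
    "TALKERS",
    "CONDITIONS",
    "SNRS_DB",
    "TARGET_CALL_SIGN",
    "CRMSentence",
    "SpeakerArray",
    "TrialSpec",
    "Schedule",
    "enumerate_corpus",
    "build_speaker_array",
    "generate_schedule",
    "wrap_angle",
]

CALL_SIGNS: tuple[str, ...] = (
    "Arrow", "Baron", "Charlie", "Eagle", "Hopper", "Laker", "Ringo", "Tiger",
)
COLORS: tuple[str, ...] = ("blue", "red", "green", "white")
NUMBERS: tuple[int, ...] = tuple(range(1, 9))
TALKERS: tuple[int, ...] = tuple(range(1, 9))

#: Block order of the six listening conditions is fixed up to the HPD
#: counterbalance arm: bare-ear blocks first, each low-pass-filtered block
#: anchored directly after its unfiltered partner.
CONDITIONS: tuple[str, ...] = ("NH", "NH-LPF", "OTE", "OTE-LPF", "ITE", "ITE-LPF")
SNRS_DB: tuple[int, int] = (5, 10)
TARGET_CALL_SIGN = "Hopper"

QUADRANTS: tuple[str, ...] = ("front-left", "front-right", "back-left", "back-right")

_TEXT_RE = re.compile(
    r"^ready (?P<cs>\w+) go to (?P<color>\w+) (?P<num>\d) now$", re.IGNORECASE
)


def wrap_angle(deg):
    """Wrap an angle (degrees) into (-180, 180]."""
    wrapped = np.asarray(deg, dtype=float) % 360.0
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    if np.ndim(deg) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class CRMSentence:
    """One sentence of the CRM corpus: "ready <call-sign> go to <color> <number> now"."""

    talker: int
    call_sign: str
    color: str
    number: int

    def __post_init__(self):
        if self.talker not in TALKERS:
            raise ValueError(f"talker must be in 1..8, got {self.talker}")
        if self.call_sign not in CALL_SIGNS:
            raise ValueError(f"unknown call sign {self.call_sign!r}")
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")
        if self.number not in NUMBERS:
            raise ValueError(f"number must be in 1..8, got {self.number}")

    @property
    def text(self) -> str:
        return f"ready {self.call_sign} go to {self.color} {self.number} now"

    @classmethod
    def from_text(cls, text: str, talker: int) -> "CRMSentence":
        m = _TEXT_RE.match(text.strip())
        if m is None:
            raise ValueError(f"not a CRM sentence: {text!r}")
        cs = m.group("cs").capitalize()
        return cls(talker=talker, call_sign=cs, color=m.group("color").lower(),
                   number=int(m.group("num")))


def enumerate_corpus() -> list[CRMSentence]:
    """The full factorial CRM sentence set: 8 talkers x 8 call signs x 4 colors x 8 numbers."""
    return [
        CRMSentence(t, cs, c, n)
        for t, cs, c, n in itertools.product(TALKERS, CALL_SIGNS, COLORS, NUMBERS)
    ]


@dataclass(frozen=True)
class SpeakerArray:
    """Twelve loudspeaker azimuths at 30 deg spacing on the horizontal ring.

    Azimuth convention: degrees in (-180, 180], 0 = straight ahead, positive =
    rightward (clockwise from above).  The front hemifield is |azimuth| < 90;
    quadrants are the four front/back x left/right sectors.  No speaker may sit
    exactly on a quadrant boundary (0, +/-90, 180).
    """

    azimuths_deg: tuple[float, ...]

    def __post_init__(self):
        az = np.sort(np.asarray(self.azimuths_deg, dtype=float))
        if len(az) != 12:
            raise ValueError("speaker array must have exactly 12 azimuths")
        on_boundary = np.isclose(np.abs(az), 0) | np.isclose(np.abs(az), 90) | np.isclose(np.abs(az), 180)
        if on_boundary.any():
            bad = az[on_boundary]
            raise ValueError(
                f"speakers {bad.tolist()} lie on a quadrant boundary (0, +/-90, 180); "
                "choose an offset that keeps all speakers strictly inside a quadrant"
            )
        ring = np.diff(np.concatenate([az, [az[0] + 360.0]]))
        if not np.allclose(ring, 30.0):
            raise ValueError("adjacent speaker spacing must be exactly 30 deg")

    @staticmethod
    def hemifield_of(azimuth_deg: float) -> str:
        return "front" if abs(wrap_angle(azimuth_deg)) < 90.0 else "back"

    @staticmethod
    def quadrant_of(azimuth_deg: float) -> str:
        a = wrap_angle(azimuth_deg)
        fb = "front" if abs(a) < 90.0 else "back"
        lr = "right" if a > 0 else "left"
        return f"{fb}-{lr}"

    def by_quadrant(self) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {q: [] for q in QUADRANTS}
        for a in self.azimuths_deg:
            out[self.quadrant_of(a)].append(a)
        return out


def build_speaker_array(offset_deg: float = 15.0) -> SpeakerArray:
    """Place 12 speakers at ``offset + k*30`` deg, wrapped to (-180, 180].

    The default 15 deg offset gives azimuths +/-15, +/-45, ..., +/-165 so that
    every speaker is unambiguously inside one quadrant (3 per quadrant).
    """
    az = wrap_angle(offset_deg + 30.0 * np.arange(12))
    return SpeakerArray(azimuths_deg=tuple(sorted(az)))


@dataclass(frozen=True)
class TrialSpec:
    """One trial: four simultaneous CRM streams, one per quadrant, one target."""

    trial_id: int
    subject_id: str
    condition: str
    snr_db: int
    streams: tuple[tuple[CRMSentence, float], ...]  # (sentence, azimuth_deg) x 4
    target_index: int

    @property
    def target_sentence(self) -> CRMSentence:
        return self.streams[self.target_index][0]

    @property
    def target_azimuth_deg(self) -> float:
        return self.streams[self.target_index][1]

    @property
    def target_hemifield(self) -> str:
        return SpeakerArray.hemifield_of(self.target_azimuth_deg)


@dataclass
class Schedule:
    """An ordered per-subject trial list plus its counterbalance arm."""

    subject_id: str
    counterbalance_arm: str  # "OTE-first" | "ITE-first"
    trials: list[TrialSpec] = field(default_factory=list)

    @property
    def condition_order(self) -> list[str]:
        seen: list[str] = []
        for t in self.trials:
            if t.condition not in seen:
                seen.append(t.condition)
        return seen

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            row: dict = {
                "trial_id": t.trial_id,
                "subject": t.subject_id,
                "condition": t.condition,
                "snr_db": t.snr_db,
                "target_index": t.target_index,
                "target_azimuth_deg": t.target_azimuth_deg,
                "target_hemifield": t.target_hemifield,
                "target_color": t.target_sentence.color,
                "target_number": t.target_sentence.number,
            }
            for i, (s, az) in enumerate(t.streams):
                row[f"s{i}_talker"] = s.talker
                row[f"s{i}_call_sign"] = s.call_sign
                row[f"s{i}_color"] = s.color
                row[f"s{i}_number"] = s.number
                row[f"s{i}_azimuth_deg"] = az
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, counterbalance_arm: str = "OTE-first") -> "Schedule":
        trials = []
        for _, r in df.iterrows():
            streams = tuple(
                (
                    CRMSentence(int(r[f"s{i}_talker"]), r[f"s{i}_call_sign"],
                                r[f"s{i}_color"], int(r[f"s{i}_number"])),
                    float(r[f"s{i}_azimuth_deg"]),
                )
                for i in range(4)
            )
            trials.append(TrialSpec(int(r["trial_id"]), str(r["subject"]), r["condition"],
                                    int(r["snr_db"]), streams, int(r["target_index"])))
        return cls(subject_id=str(df["subject"].iloc[0]), counterbalance_arm=counterbalance_arm,
                   trials=trials)


def _condition_order(arm: str) -> list[str]:
    if arm == "OTE-first":
        return ["NH", "NH-LPF", "OTE", "OTE-LPF", "ITE", "ITE-LPF"]
    if arm == "ITE-first":
        return ["NH", "NH-LPF", "ITE", "ITE-LPF", "OTE", "OTE-LPF"]
    raise ValueError(f"counterbalance_arm must be 'OTE-first' or 'ITE-first', got {arm!r}")


def _interleave_snr_targets(targets: list[tuple[int, float]], rng: np.random.Generator,
                            max_run: int = 4, max_tries: int = 10_000) -> list[tuple[int, float]]:
    """Shuffle (snr, azimuth) pairs until no more than ``max_run`` equal SNRs run consecutively."""
    arr = list(targets)
    for _ in range(max_tries):
        rng.shuffle(arr)
        run, longest = 1, 1
        for a, b in itertools.pairwise(arr):
            run = run + 1 if a[0] == b[0] else 1
            longest = max(longest, run)
        if longest <= max_run:
            return arr
    raise RuntimeError("could not interleave SNRs within the run-length constraint")


def _sample_trial_streams(target_az: float, array: SpeakerArray, rng: np.random.Generator,
                          talker_pool: tuple[int, ...], distinct_color_number: bool,
                          allow_repeat_talker: bool) -> tuple[tuple[tuple[CRMSentence, float], ...], int]:
    by_quad = array.by_quadrant()
    target_quad = array.quadrant_of(target_az)

    azimuths: dict[str, float] = {target_quad: target_az}
    for q in QUADRANTS:
        if q != target_quad:
            azimuths[q] = float(rng.choice(by_quad[q]))

    if allow_repeat_talker:
        talkers = [int(rng.choice(talker_pool)) for _ in range(4)]
    else:
        talkers = [int(t) for t in rng.choice(talker_pool, size=4, replace=False)]
    if distinct_color_number:
        colors = [COLORS[i] for i in rng.permutation(len(COLORS))]
        numbers = [int(n) for n in rng.choice(NUMBERS, size=4, replace=False)]
    else:
        colors = [COLORS[i] for i in rng.integers(0, len(COLORS), size=4)]
        numbers = [int(n) for n in rng.choice(NUMBERS, size=4, replace=True)]
    masker_signs = [cs for cs in CALL_SIGNS if cs != TARGET_CALL_SIGN]

    streams = []
    target_index = -1
    for i, q in enumerate(QUADRANTS):
        if q == target_quad:
            cs = TARGET_CALL_SIGN
            target_index = i
        else:
            cs = masker_signs[int(rng.integers(0, len(masker_signs)))]
        streams.append((CRMSentence(talkers[i], cs, colors[i], numbers[i]), azimuths[q]))
    return tuple(streams), target_index


def generate_schedule(
    subject_id: str,
    counterbalance_arm: str,
    seed: int,
    *,
    speaker_offset_deg: float = 15.0,
    trials_per_condition: int = 96,
    stratify_targets: bool = True,
    distinct_color_number: bool = True,
    talker_pool: tuple[int, ...] = TALKERS,
    allow_repeat_talker: bool = False,
    max_snr_run: int = 4,
) -> Schedule:
    """Generate one subject's randomized, counterbalanced 576-trial schedule.

    Within each condition the two SNRs are interleaved (288 of each over the
    session) and, by default, the target azimuth is stratified uniformly over
    the 12 speakers within every condition x SNR cell.
    """
    if trials_per_condition % (2 * 12) != 0 and stratify_targets:
        raise ValueError("trials_per_condition must be a multiple of 24 for stratified targets")
    array = build_speaker_array(speaker_offset_deg)
    rng = np.random.default_rng(seed)
    order = _condition_order(counterbalance_arm)

    schedule = Schedule(subject_id=subject_id, counterbalance_arm=counterbalance_arm)
    trial_id = 0
    for condition in order:
        targets: list[tuple[int, float]] = []
        if stratify_targets:
            reps = trials_per_condition // (2 * 12)
            for snr in SNRS_DB:
                for az in array.azimuths_deg:
                    targets.extend([(snr, az)] * reps)
        else:
            half = trials_per_condition // 2
            snrs = [SNRS_DB[0]] * half + [SNRS_DB[1]] * (trials_per_condition - half)
            targets = [(s, float(rng.choice(array.azimuths_deg))) for s in snrs]
        targets = _interleave_snr_targets(targets, rng, max_run=max_snr_run)

        for snr, az in targets:
            streams, tgt = _sample_trial_streams(
                az, array, rng, tuple(talker_pool), distinct_color_number, allow_repeat_talker
            )
            schedule.trials.append(
                TrialSpec(trial_id, subject_id, condition, snr, streams, tgt)
            )
            trial_id += 1
    return schedule
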