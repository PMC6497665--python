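"""Domain types and I/O for per-second scored dyadic encounters.

One-on-one behaviour assays (typically staged ant worker encounters in a
neutral arena) are coded second by second on an ordinal scale from −4 to +5:
negative scores are peaceful behaviours (trophallaxis −4, allogrooming −3,
antennation −2, sitting next to each other −1), 0 is ignoring, and positive
scores are aggressive behaviours (avoiding 1, mandible threatening 2,
fighting without / with gaster flexion 3 / 4, killing 5). Killing is
absorbing: once one opponent is dead the observation stops and all remaining
seconds are attributed to score 5.

The sufficient statistic for every downstream index is the
:class:`DurationProfile` — the total number of seconds spent at each score —
so most of this module is plumbing between second-by-second series, duration
profiles and the long-format CSV exchange file.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

SCORE_MIN = -4
SCORE_MAX = 5
KILLING = 5
#: default scored encounter length in seconds (acclimatisation already removed)
T_OBS = 170

VALID_ENCOUNTER_TYPES = ("intranest", "internest")


class EthogramError(ValueError):
    """Raised when an ethogram file or series violates the domain contract."""


def _normalise_minus(s: str) -> str:
    # typographic minus signs (U+2212, U+2013) appear in published tables
    return s.replace("−", "-").replace("–", "-")


@dataclass(frozen=True)
class ScoringScale:
    """An ordered ordinal scoring scale, optionally with a translation map.

    ``entries`` are (score, label) pairs in strictly increasing score order.
    ``translation`` maps scores of *this* scale onto another scale (used to
    bring legacy data sets onto the adapted −4…+5 scale). ``killing_score``
    marks the absorbing score, if the scale has one.
    """

    entries: tuple[tuple[int, str], ...]
    translation: Mapping[int, int] | None = None
    killing_score: int | None = None

    def __post_init__(self) -> None:
        scores = [s for s, _ in self.entries]
        if sorted(set(scores)) != scores:
            raise ValueError("scale scores must be strictly increasing and unique")
        if self.translation is not None:
            missing = set(scores) - set(self.translation)
            if missing:
                raise ValueError(f"translation not total: missing {sorted(missing)}")
        if self.killing_score is not None and self.killing_score not in scores:
            raise ValueError("killing_score must be on the scale")

    @property
    def scores(self) -> frozenset[int]:
        return frozenset(s for s, _ in self.entries)

    def label(self, score: int) -> str:
        for s, lab in self.entries:
            if s == score:
                return lab
        raise KeyError(score)


#: Adapted −4…+5 scale used for scoring (and as the common scale after
#: translation of legacy data).
ADAPTED_SCALE = ScoringScale(
    entries=(
        (-4, "Trophallaxis"),
        (-3, "Allogrooming"),
        (-2, "Antennation"),
        (-1, "Being next to each other without touching"),
        (0, "Ignoring"),
        (1, "Avoiding"),
        (2, "Mandible threatening"),
        (3, "Fighting without gaster flexion"),
        (4, "Fighting with gaster flexion"),
        (5, "Killing"),
    ),
    killing_score=KILLING,
)

#: Legacy 0–7 scale of the oldest data set, with its translation onto the
#: adapted scale. The legacy scale collapses allogrooming and trophallaxis
#: into one category (3), so adapted −4 is unreachable from it.
DS3_SCALE = ScoringScale(
    entries=(
        (0, "Ignoring"),
        (1, "Being next to each other without touching"),
        (2, "Antennation"),
        (3, "Allogrooming and trophallaxis"),
        (4, "Avoiding"),
        (5, "Mandible threatening"),
        (6, "Biting"),
        (7, "Fighting"),
    ),
    translation={0: 0, 1: -1, 2: -2, 3: -3, 4: 1, 5: 2, 6: 3, 7: 4},
)


@dataclass(frozen=True)
class SecondSeries:
    """One worker's score for every second of an encounter.

    Scores are validated against ``scale`` (the adapted −4…+5 scale by
    default); if the scale has a killing score, it must be absorbing.
    """

    scores: tuple[int, ...]
    worker: str = "w1"
    scale: ScoringScale = ADAPTED_SCALE

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", tuple(int(s) for s in self.scores))
        valid = self.scale.scores
        for i, s in enumerate(self.scores):
            if s not in valid:
                raise EthogramError(
                    f"worker {self.worker}, second {i + 1}: score {s} not on "
                    "the scoring scale"
                )
        kill = self.scale.killing_score
        if kill is not None and kill in self.scores:
            k = self.scores.index(kill)
            if any(s != kill for s in self.scores[k:]):
                raise EthogramError(
                    f"worker {self.worker}: killing at second {k + 1} is not "
                    "absorbing (later seconds carry other scores)"
                )

    def __len__(self) -> int:
        return len(self.scores)


def translate_scale(
    series: SecondSeries,
    translation: Mapping[int, int],
    target_scale: ScoringScale = ADAPTED_SCALE,
) -> SecondSeries:
    """Map every score of ``series`` through ``translation`` (element-wise)."""
    unmapped = set(series.scores) - set(translation)
    if unmapped:
        raise EthogramError(f"scores {sorted(unmapped)} not in translation domain")
    return replace(
        series,
        scores=tuple(translation[s] for s in series.scores),
        scale=target_scale,
    )


@dataclass(frozen=True)
class DurationProfile:
    """Total seconds spent at each score; sufficient statistic for all indices."""

    durations: Mapping[int, int]

    def __post_init__(self) -> None:
        d = {int(s): int(v) for s, v in self.durations.items()}
        if any(v < 0 for v in d.values()):
            raise EthogramError("durations must be non-negative")
        object.__setattr__(self, "durations", d)

    @property
    def total_seconds(self) -> int:
        return sum(self.durations.values())

    def present_scores(self) -> list[int]:
        """Scores observed for at least one second, ascending."""
        return sorted(s for s, v in self.durations.items() if v > 0)

    @classmethod
    def from_series(cls, series: SecondSeries) -> "DurationProfile":
        return cls(collections.Counter(series.scores))

    def to_series(self, worker: str = "w1") -> SecondSeries:
        """Expand to a block-ordered series (killing last, so it is absorbing)."""
        scores: list[int] = []
        for s in self.present_scores():
            if s != KILLING:
                scores.extend([s] * self.durations[s])
        scores.extend([KILLING] * self.durations.get(KILLING, 0))
        return SecondSeries(scores=tuple(scores), worker=worker)


def to_profile(series: SecondSeries) -> DurationProfile:
    """Collapse a second-by-second series to its duration profile."""
    return DurationProfile.from_series(series)


@dataclass(frozen=True)
class Encounter:
    """One staged meeting; 2 scored workers for observed data, 1 for simulated."""

    encounter_id: str
    pairing_id: str
    replicate: int
    encounter_type: str
    series: tuple[SecondSeries, ...]
    day: int | None = None

    def __post_init__(self) -> None:
        if self.encounter_type not in VALID_ENCOUNTER_TYPES:
            raise EthogramError(
                f"encounter {self.encounter_id}: encounter_type must be one of "
                f"{VALID_ENCOUNTER_TYPES}, got {self.encounter_type!r}"
            )
        if not 1 <= len(self.series) <= 2:
            raise EthogramError(
                f"encounter {self.encounter_id}: expected 1 or 2 workers, "
                f"got {len(self.series)}"
            )
        lengths = {len(s) for s in self.series}
        if len(lengths) > 1:
            raise EthogramError(
                f"encounter {self.encounter_id}: workers scored for unequal "
                f"numbers of seconds {sorted(lengths)}"
            )

    @property
    def t_obs(self) -> int:
        return len(self.series[0])


@dataclass(frozen=True)
class PairingGroup:
    """All replicate encounters of one colony pairing."""

    pairing_id: str
    encounters: tuple[Encounter, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "encounters", tuple(self.encounters))
        if not self.encounters:
            raise EthogramError(f"pairing {self.pairing_id}: no encounters")
        for e in self.encounters:
            if e.pairing_id != self.pairing_id:
                raise EthogramError(
                    f"pairing {self.pairing_id}: encounter {e.encounter_id} "
                    f"belongs to pairing {e.pairing_id}"
                )
        types = {e.encounter_type for e in self.encounters}
        if len(types) > 1:
            raise EthogramError(
                f"pairing {self.pairing_id}: mixed encounter types {sorted(types)}"
            )

    @property
    def encounter_type(self) -> str:
        return self.encounters[0].encounter_type


ETHOGRAM_COLUMNS = [
    "pairing_id",
    "encounter_id",
    "replicate",
    "encounter_type",
    "day",
    "worker",
    "second",
    "score",
]

PROFILE_COLUMNS = [
    "pairing_id",
    "encounter_id",
    "replicate",
    "encounter_type",
    "worker",
    "score",
    "seconds",
]


def read_ethogram(
    path: str | Path,
    scale: ScoringScale = ADAPTED_SCALE,
    repair_kill: bool = False,
) -> list[PairingGroup]:
    """Read a long-format ethogram CSV into validated pairing groups.

    One row per scored second. Validates score domain against ``scale``,
    contiguous 1-based seconds per worker, and absorbing killing;
    ``repair_kill`` forward-fills score 5 after the first killing second
    instead of rejecting.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ETHOGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise EthogramError(f"{path}: missing columns {missing}")
    if df.empty:
        return []

    def _int(raw: str, row: int, what: str) -> int:
        try:
            return int(_normalise_minus(raw.strip()))
        except ValueError:
            raise EthogramError(f"{path}, row {row}: {what} {raw!r} is not an integer")

    records: dict[tuple, dict[int, int]] = {}
    meta: dict[tuple, dict] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based with header line
        score = _int(row["score"], rowno, "score")
        if score not in scale.scores:
            raise EthogramError(
                f"{path}, row {rowno}: score {score} not on the scoring scale"
            )
        second = _int(row["second"], rowno, "second")
        key = (row["pairing_id"], row["encounter_id"], row["worker"])
        series = records.setdefault(key, {})
        if second in series:
            raise EthogramError(
                f"{path}, row {rowno}: duplicate second {second} for encounter "
                f"{row['encounter_id']}, worker {row['worker']}"
            )
        series[second] = score
        meta.setdefault(
            key,
            {
                "replicate": _int(row["replicate"], rowno, "replicate"),
                "encounter_type": row["encounter_type"],
                "day": _int(row["day"], rowno, "day") if row["day"] != "" else None,
            },
        )

    # assemble series, checking second coverage 1..T
    encounters: dict[tuple[str, str], dict] = {}
    for (pairing, encounter, worker), seconds in records.items():
        T = max(seconds)
        absent = sorted(set(range(1, T + 1)) - set(seconds))
        if absent:
            raise EthogramError(
                f"{path}: encounter {encounter}, worker {worker}: missing "
                f"seconds {absent[:5]}{'...' if len(absent) > 5 else ''}"
            )
        scores = [seconds[t] for t in range(1, T + 1)]
        kill = scale.killing_score
        if repair_kill and kill is not None and kill in scores:
            k = scores.index(kill)
            scores[k:] = [kill] * (T - k)
        try:
            series = SecondSeries(scores=tuple(scores), worker=worker, scale=scale)
        except EthogramError as err:
            raise EthogramError(f"{path}: encounter {encounter}: {err}") from None
        enc = encounters.setdefault((pairing, encounter), {"series": []})
        enc["series"].append(series)
        enc.update(meta[(pairing, encounter, worker)])

    groups: dict[str, list[Encounter]] = collections.defaultdict(list)
    for (pairing, encounter), enc in encounters.items():
        groups[pairing].append(
            Encounter(
                encounter_id=encounter,
                pairing_id=pairing,
                replicate=enc["replicate"],
                encounter_type=enc["encounter_type"],
                day=enc["day"],
                series=tuple(sorted(enc["series"], key=lambda s: s.worker)),
            )
        )
    return [
        PairingGroup(pairing_id=p, encounters=tuple(sorted(es, key=lambda e: e.replicate)))
        for p, es in sorted(groups.items())
    ]


def write_ethogram(groups: Iterable[PairingGroup], path: str | Path) -> None:
    """Write pairing groups as a long-format ethogram CSV (read_ethogram inverse)."""
    rows = []
    for g in groups:
        for e in g.encounters:
            for s in e.series:
                for sec, score in enumerate(s.scores, start=1):
                    rows.append(
                        (
                            g.pairing_id,
                            e.encounter_id,
                            e.replicate,
                            e.encounter_type,
                            "" if e.day is None else e.day,
                            s.worker,
                            sec,
                            score,
                        )
                    )
    pd.DataFrame(rows, columns=ETHOGRAM_COLUMNS).to_csv(path, index=False)


def profiles_frame(groups: Iterable[PairingGroup]) -> pd.DataFrame:
    """Wide score→seconds table, one row per (encounter, worker, score)."""
    rows = []
    for g in groups:
        for e in g.encounters:
            for s in e.series:
                prof = DurationProfile.from_series(s)
                for score in sorted(prof.durations):
                    rows.append(
                        (
                            g.pairing_id,
                            e.encounter_id,
                            e.replicate,
                            e.encounter_type,
                            s.worker,
                            score,
                            prof.durations[score],
                        )
                    )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def load_scale(path: str | Path) -> ScoringScale:
    """Load a scale config (YAML or JSON): entries + optional translation."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = tuple((int(s), str(lab)) for s, lab in raw["entries"])
    translation = raw.get("translation")
    if translation is not None:
        translation = {int(k): int(v) for k, v in translation.items()}
    killing = raw.get("killing_score")
    return ScoringScale(
        entries=entries,
        translation=translation,
        killing_score=None if killing is None else int(killing),
    )
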