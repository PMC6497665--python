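"""The five dyadic behaviour indices and their aggregation.

Per worker and encounter:

* **AI** (Aggression Index) — duration-weighted mean score over seconds of
  interaction, ``AI = Σ s·t_s / T`` where ``T`` sums the durations of all
  nonzero-score seconds (ignoring is excluded from both numerator and
  denominator; non-contact behaviours such as avoiding and sitting nearby are
  included).
* **MMAI** — the maximum score displayed for at least one second.
* **MMPI** — the minimum score displayed for at least one second (the
  peaceful counterpart of MMAI).
* **MBI** (Mean Behaviour Index) — a cascade on the aggregate aggressive and
  peaceful durations against a time threshold ``t``: killing dominates (5);
  aggression dominating returns MMAI; peace dominating returns MMPI;
  neither exceeding ``t`` returns 0; both exceeding ``t`` returns the
  midrange (MMAI + MMPI)/2. ``MBI_agg`` and ``MBI_pcf`` are MBI at two
  empirically chosen thresholds (see :mod:`ethoindex.thresholds`).

Worker values are averaged with equal weight to the encounter level, and
encounter values averaged with equal weight over replicates to the pairing
level. An all-ignoring worker has no defined AI; it propagates as NaN and is
dropped from means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .ethogram import (
    KILLING,
    DurationProfile,
    Encounter,
    PairingGroup,
    SecondSeries,
)

ProfileLike = Union[DurationProfile, SecondSeries]


def _profile(x: ProfileLike) -> DurationProfile:
    if isinstance(x, SecondSeries):
        return DurationProfile.from_series(x)
    return x


@dataclass(frozen=True)
class DurationSummary:
    """Aggregate durations by behaviour class (seconds)."""

    d_agg: int
    d_pcf: int
    d_ignore: int
    killed: bool

    @property
    def total_seconds(self) -> int:
        return self.d_agg + self.d_pcf + self.d_ignore


@dataclass(frozen=True)
class IndexVector:
    """The five index values at one aggregation level.

    Listed from most aggressive to most peaceful pole, mirroring how the
    indices order on typical data: mmai ≥ ai ≥ mmpi always holds per
    encounter (over nonzero-score support).
    """

    mmai: float
    mbi_agg: float
    ai: float
    mbi_pcf: float
    mmpi: float
    level: str = "encounter"

    def as_dict(self) -> dict[str, float]:
        return {
            "mmai": self.mmai,
            "mbi_agg": self.mbi_agg,
            "ai": self.ai,
            "mbi_pcf": self.mbi_pcf,
            "mmpi": self.mmpi,
        }


def ai(profile: ProfileLike) -> float:
    """Duration-weighted mean score over nonzero-score seconds.

    Returns NaN (a distinct missing marker, not 0) when the encounter is
    ignoring throughout, i.e. no second with a nonzero score exists.
    """
    prof = _profile(profile)
    num = sum(s * d for s, d in prof.durations.items() if s != 0)
    den = sum(d for s, d in prof.durations.items() if s != 0)
    if den == 0:
        return math.nan
    return num / den


def mmai(profile: ProfileLike) -> int:
    """Maximum score displayed for at least one second (may be negative)."""
    present = _profile(profile).present_scores()
    if not present:
        raise ValueError("empty profile has no maximum score")
    return present[-1]


def mmpi(profile: ProfileLike) -> int:
    """Minimum score displayed for at least one second (may be positive)."""
    present = _profile(profile).present_scores()
    if not present:
        raise ValueError("empty profile has no minimum score")
    return present[0]


def duration_summary(profile: ProfileLike) -> DurationSummary:
    prof = _profile(profile)
    return DurationSummary(
        d_agg=sum(d for s, d in prof.durations.items() if s > 0),
        d_pcf=sum(d for s, d in prof.durations.items() if s < 0),
        d_ignore=prof.durations.get(0, 0),
        killed=prof.durations.get(KILLING, 0) > 0,
    )


def mbi(profile: ProfileLike, t: int) -> float:
    """Mean Behaviour Index of one worker at time threshold ``t``.

    Decision cascade, with strict "duration larger than t" comparisons:

    i.   killing occurred                      → 5
    iv.  d_agg > t and d_pcf ≤ t               → MMAI
    v.   d_agg ≤ t and d_pcf ≤ t               → 0
    vi.  d_pcf > t and d_agg ≤ t               → MMPI
    vii. d_agg > t and d_pcf > t               → (MMAI + MMPI) / 2
    """
    prof = _profile(profile)
    if not 0 <= t <= prof.total_seconds:
        raise ValueError(f"threshold t={t} outside [0, {prof.total_seconds}]")
    d = duration_summary(prof)
    if d.killed:
        return float(KILLING)
    agg, pcf = d.d_agg > t, d.d_pcf > t
    if agg and not pcf:
        return float(mmai(prof))
    if pcf and not agg:
        return float(mmpi(prof))
    if agg and pcf:
        return (mmai(prof) + mmpi(prof)) / 2.0
    return 0.0


def worker_vector(profile: ProfileLike, t_agg: int, t_pcf: int) -> IndexVector:
    """All five indices for a single worker."""
    prof = _profile(profile)
    return IndexVector(
        mmai=float(mmai(prof)),
        mbi_agg=mbi(prof, t_agg),
        ai=ai(prof),
        mbi_pcf=mbi(prof, t_pcf),
        mmpi=float(mmpi(prof)),
        level="worker",
    )


def _mean_vectors(vectors: Sequence[IndexVector], level: str) -> IndexVector:
    # NaN AIs (all-ignoring workers/encounters) are dropped from the mean;
    # a mean over only-NaN values stays NaN.
    arrays = {
        k: np.array([v.as_dict()[k] for v in vectors], dtype=float)
        for k in ("mmai", "mbi_agg", "ai", "mbi_pcf", "mmpi")
    }
    with np.errstate(invalid="ignore"):
        means = {
            k: float(np.nanmean(a)) if not np.all(np.isnan(a)) else math.nan
            for k, a in arrays.items()
        }
    return IndexVector(level=level, **means)


def index_vector(encounter: Encounter, t_agg: int, t_pcf: int) -> IndexVector:
    """Encounter-level indices: equal-weight mean over the scored workers."""
    vecs = [worker_vector(s, t_agg, t_pcf) for s in encounter.series]
    return _mean_vectors(vecs, level="encounter")


def pairing_means(group: PairingGroup, t_agg: int, t_pcf: int) -> IndexVector:
    """Pairing-level indices: equal-weight mean over replicate encounters."""
    vecs = [index_vector(e, t_agg, t_pcf) for e in group.encounters]
    return _mean_vectors(vecs, level="pairing_mean")


def index_report(
    groups: Sequence[PairingGroup],
    t_agg: int,
    t_pcf: int,
    include_encounters: bool = False,
) -> pd.DataFrame:
    """Tabulate index values per pairing (and optionally per encounter)."""
    rows = []
    for g in groups:
        if include_encounters:
            for e in g.encounters:
                v = index_vector(e, t_agg, t_pcf)
                rows.append(
                    {"pairing_id": g.pairing_id, "level": "encounter", **v.as_dict(),
                     "n_replicates": 1, "t_agg": t_agg, "t_pcf": t_pcf}
                )
        v = pairing_means(g, t_agg, t_pcf)
        rows.append(
            {"pairing_id": g.pairing_id, "level": "pairing_mean", **v.as_dict(),
             "n_replicates": len(g.encounters), "t_agg": t_agg, "t_pcf": t_pcf}
        )
    cols = ["pairing_id", "level", "mmai", "mbi_agg", "ai", "mbi_pcf", "mmpi",
            "n_replicates", "t_agg", "t_pcf"]
    return pd.DataFrame(rows, columns=cols)


def near_tie_fraction(
    encounters: Iterable[Union[Encounter, ProfileLike]], delta: int = 10
) -> float:
    """Fraction of encounters whose aggressive and peaceful aggregate
    durations differ by less than ``delta`` seconds (strict).

    Near-ties are where AI is least informative: equal amounts of aggression
    and peace cancel to a value near 0.
    """
    items = list(encounters)
    if not items:
        raise ValueError("no encounters given")
    n_tie = 0
    for item in items:
        if isinstance(item, Encounter):
            d_agg = d_pcf = 0
            for s in item.series:
                d = duration_summary(s)
                d_agg += d.d_agg
                d_pcf += d.d_pcf
        else:
            d = duration_summary(item)
            d_agg, d_pcf = d.d_agg, d.d_pcf
        if abs(d_agg - d_pcf) < delta:
            n_tie += 1
    return n_tie / len(items)
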