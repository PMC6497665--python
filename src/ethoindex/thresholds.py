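"""Empirical time-threshold selection for the Mean Behaviour Index.

The MBI cascade needs a time threshold ``t`` saying how long aggressive or
peaceful behaviour must last to count as dominating. Two thresholds are
chosen empirically from the internest encounters of a data set: MBI is
computed for every integer ``t`` in ``0 … T_obs`` and each encounter is
classified by sign (``> 0`` aggressive, ``< 0`` peaceful, ``0`` neutral).
The threshold for MBI_agg is the lowest ``t`` at which the count of
aggressive encounters reaches its maximum over the scan; analogously the
threshold for MBI_pcf on the peaceful count. Counts are not monotone in
``t`` — past the inflection point they stay constant or decrease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ethogram import Encounter
from .indices import duration_summary, mmai, mmpi


def classify(mbi_value: float) -> str:
    """Sign classification of an index value: aggressive / peaceful / neutral."""
    if mbi_value > 0:
        return "aggressive"
    if mbi_value < 0:
        return "peaceful"
    return "neutral"


@dataclass(frozen=True)
class ThresholdCurve:
    """Counts of aggressive / peaceful encounters for each scanned ``t``."""

    t_values: np.ndarray
    n_aggressive: np.ndarray
    n_peaceful: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t_values,
                "n_aggressive": self.n_aggressive,
                "n_peaceful": self.n_peaceful,
            }
        )


@dataclass(frozen=True)
class ThresholdChoice:
    t_agg: int
    t_pcf: int
    max_n_agg: int
    max_n_pcf: int


def _worker_stats(encounters: Sequence[Encounter]):
    """Flat per-worker summary arrays plus the owning encounter index."""
    enc_idx, killed, d_agg, d_pcf, vmax, vmin = [], [], [], [], [], []
    for i, enc in enumerate(encounters):
        for s in enc.series:
            d = duration_summary(s)
            enc_idx.append(i)
            killed.append(d.killed)
            d_agg.append(d.d_agg)
            d_pcf.append(d.d_pcf)
            vmax.append(mmai(s))
            vmin.append(mmpi(s))
    return (
        np.array(enc_idx),
        np.array(killed, dtype=bool),
        np.array(d_agg),
        np.array(d_pcf),
        np.array(vmax, dtype=float),
        np.array(vmin, dtype=float),
    )


def scan(encounters: Sequence[Encounter], t_max: int | None = None) -> ThresholdCurve:
    """Classify encounter-level MBI for every integer ``t`` in ``0 … t_max``.

    Workers are averaged to the encounter level before classification;
    replicates are *not* averaged (the scan counts encounters, not pairings).
    """
    encounters = list(encounters)
    if not encounters:
        raise ValueError("scan requires at least one encounter")
    if t_max is None:
        t_max = max(e.t_obs for e in encounters)

    enc_idx, killed, d_agg, d_pcf, vmax, vmin = _worker_stats(encounters)
    t = np.arange(t_max + 1)

    # worker MBI for every t, vectorised: shape (n_workers, n_t)
    agg = d_agg[:, None] > t[None, :]
    pcf = d_pcf[:, None] > t[None, :]
    m = np.zeros((len(enc_idx), len(t)))
    m = np.where(agg & ~pcf, vmax[:, None], m)
    m = np.where(pcf & ~agg, vmin[:, None], m)
    m = np.where(agg & pcf, (vmax + vmin)[:, None] / 2.0, m)
    m[killed, :] = 5.0

    # equal-weight worker average per encounter
    n_enc = len(encounters)
    sums = np.zeros((n_enc, len(t)))
    np.add.at(sums, enc_idx, m)
    counts = np.bincount(enc_idx, minlength=n_enc)
    enc_mbi = sums / counts[:, None]

    return ThresholdCurve(
        t_values=t,
        n_aggressive=(enc_mbi > 0).sum(axis=0),
        n_peaceful=(enc_mbi < 0).sum(axis=0),
    )


def select(curve: ThresholdCurve) -> ThresholdChoice:
    """Lowest ``t`` attaining the maximum count, per behaviour class.

    If a class never occurs (maximum count 0, e.g. no aggressive encounter
    in a purely peaceful data set) the threshold falls back to 0 with a
    warning; every downstream MBI is insensitive to the choice in that case.
    """
    choices = {}
    for name, counts in (("agg", curve.n_aggressive), ("pcf", curve.n_peaceful)):
        peak = int(counts.max())
        if peak == 0:
            warnings.warn(
                f"no {'aggressive' if name == 'agg' else 'peaceful'} encounter "
                "in the scan; falling back to t=0",
                stacklevel=2,
            )
            t_star = 0
        else:
            t_star = int(curve.t_values[np.argmax(counts)])  # first argmax
        choices[name] = (t_star, peak)
    return ThresholdChoice(
        t_agg=choices["agg"][0],
        t_pcf=choices["pcf"][0],
        max_n_agg=choices["agg"][1],
        max_n_pcf=choices["pcf"][1],
    )


def choose_thresholds(
    encounters: Iterable[Encounter], t_max: int | None = None
) -> ThresholdChoice:
    """Convenience: ``select(scan(internest encounters))``."""
    return select(scan(list(encounters), t_max=t_max))
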