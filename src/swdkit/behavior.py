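"""Behavioral and metabolic assay metrics.

Small, pure table-in/value-out formulas used alongside the EEG pipeline:

* :func:`ppi` — pre-pulse inhibition of the acoustic startle response,
  ``(1 - mean prepulse response / mean startle response) x 100`` per
  prepulse level (74/78/82 dB prepulses, 120 dB startle stimulus).
* :func:`resting_metabolic_rate` — mean of the two lowest
  energy-expenditure samples measured 4–8 h (half-open window) into a
  fast.
* :func:`repetitive_poke_runs` — number of maximal runs of >= 2
  consecutive nose-pokes into the same hole of a 16-hole board
  (repetitive-behavior index).
* :func:`footslips_per_distance` — footslip count normalized by distance
  traveled.
* :func:`charge_transfer` — total synaptic charge over a 120-s
  voltage-clamp trace: the time integral of |current - baseline|
  (pA·s = pC).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ppi",
    "resting_metabolic_rate",
    "repetitive_poke_runs",
    "footslips_per_distance",
    "charge_transfer",
]

STARTLE_TRIAL = "startle_120dB"
PREPULSE_LEVELS = (74, 78, 82)


def ppi(session: pd.DataFrame, levels: Sequence[int] = PREPULSE_LEVELS) -> dict[int, float]:
    """Percent pre-pulse inhibition per prepulse level.

    ``session`` needs columns ``trial_type`` (one of ``startle_120dB``,
    ``prepulse_74dB``, ``prepulse_78dB``, ``prepulse_82dB``) and
    ``response`` (startle magnitude, arbitrary force units). For each
    level, PPI = (1 - mean prepulse response / mean startle response)
    x 100; values can be negative (facilitation) and at most 100.
    """
    responses = session["response"].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")
    startle = session.loc[session["trial_type"] == STARTLE_TRIAL, "response"]
    if startle.empty:
        raise ValueError(f"no {STARTLE_TRIAL} trials in session")
    mean_startle = float(startle.mean())
    if mean_startle == 0:
        raise ZeroDivisionError("mean startle response is 0; PPI undefined")
    out: dict[int, float] = {}
    for level in levels:
        trial = f"prepulse_{level}dB"
        pre = session.loc[session["trial_type"] == trial, "response"]
        if pre.empty:
            raise ValueError(f"no {trial} trials in session")
        out[level] = (1.0 - float(pre.mean()) / mean_startle) * 100.0
    return out


def resting_metabolic_rate(
    time_h: np.ndarray,
    energy_expenditure: np.ndarray,
    window: tuple[float, float] = (4.0, 8.0),
) -> float:
    """RMR (kcal/h): mean of the two lowest energy-expenditure values
    whose timestamps fall in the half-open ``[window[0], window[1])``
    hours after the start of the fast.
    """
    t = np.asarray(time_h, dtype=np.float64)
    ee = np.asarray(energy_expenditure, dtype=np.float64)
    if t.shape != ee.shape:
        raise ValueError("time and energy-expenditure arrays differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    inside = ee[(t >= window[0]) & (t < window[1])]
    if inside.size < 2:
        raise ValueError(
            f"need >= 2 samples in [{window[0]}, {window[1]}) h, got {inside.size}"
        )
    lowest_two = np.partition(inside, 1)[:2]
    return float(lowest_two.mean())


def repetitive_poke_runs(pokes: Sequence[int], n_holes: int = 16) -> int:
    """Count maximal runs of >= 2 consecutive pokes into the same hole.

    A run of three pokes into one hole counts once; two separated runs on
    the same hole count twice ("continuously poke the same hole no less
    than twice").
    """
    seq = list(pokes)
    if any(not (1 <= h <= n_holes) for h in seq):
        raise ValueError(f"hole identifiers must be in 1..{n_holes}")
    count = 0
    i = 0
    while i < len(seq):
        j = i
        while j + 1 < len(seq) and seq[j + 1] == seq[i]:
            j += 1
        if j > i:
            count += 1
        i = j + 1
    return count


def repetitive_holes(pokes: Sequence[int], n_holes: int = 16) -> int:
    """Variant: number of *distinct holes* that received >= 2 sequential
    pokes at least once (each hole counts at most once)."""
    seq = list(pokes)
    holes: set[int] = set()
    i = 0
    while i < len(seq):
        j = i
        while j + 1 < len(seq) and seq[j + 1] == seq[i]:
            j += 1
        if j > i:
            holes.add(seq[i])
        i = j + 1
    return len(holes)


def footslips_per_distance(footslips: int, distance_m: float) -> float:
    """Footslips normalized to distance traveled (slips per meter)."""
    if distance_m <= 0:
        raise ValueError("distance must be > 0")
    if footslips < 0:
        raise ValueError("footslip count must be >= 0")
    return footslips / distance_m


def charge_transfer(
    time_s: np.ndarray,
    current_pA: np.ndarray,
    baseline_pA: float = 0.0,
    duration: float = 120.0,
    signed: bool = False,
) -> float:
    """Total charge of synaptic responses over ``duration`` seconds (pC).

    Trapezoidal integral of ``|current - baseline|`` (or the signed
    deviation with ``signed=True``) over ``[0, duration)`` relative to the
    first sample. pA x s = pC.
    """
    t = np.asarray(time_s, dtype=np.float64)
    i = np.asarray(current_pA, dtype=np.float64)
    if t.shape != i.shape:
        raise ValueError("time and current arrays differ in length")
    t = t - t[0]
    if t[-1] < duration:
        raise ValueError(f"trace covers only {t[-1]:.3f} s < required {duration} s")
    mask = t <= duration
    dev = i[mask] - baseline_pA
    if not signed:
        dev = np.abs(dev)
    return float(np.trapezoid(dev, t[mask]))
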