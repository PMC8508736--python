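"""Exercise-induced gene expression: early and delayed transcriptional
responses.

Early-response genes (NR4A2, NR4A3) and the intermediate transcription
factor X are driven by the product of active CREB1 (phospho-Ser133) and its
coactivator CRTC (dephospho-Ser171) -- coactivator logic, hence a
multiplicative drive.  The delayed-response gene PPARGC1A is driven by the
protein of factor X, itself translated from the early-induced X transcript;
this two-step relay is what delays the PPARGC1A peak to hours after the
signaling kinases have already returned to baseline.  Every gene also has a
constitutive transcription rate independent of these factors, so the
resting fold change is exactly 1.

mRNA is baseline-normalized (resting level 1 when k0/kdeg = 1); rates are
per minute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneParams",
    "TFActivity",
    "GENES",
    "hill",
    "transcription_rate",
    "fold_change",
    "peak_timing",
]

GENES = ("NR4A2", "NR4A3", "X", "PPARGC1A")


def hill(x: float, K: float, n: float = 1.0) -> float:
    """Saturating Hill response of a nonnegative drive."""
    x = max(x, 0.0)
    if x == 0.0:
        return 0.0
    xn = x ** n
    return xn / (K ** n + xn)


@dataclass(frozen=True)
class TFActivity:
    """Transcription-factor inputs to the gene level."""

    creb_active: float
    crtc_active: float
    x_protein: float = 0.0


@dataclass(frozen=True)
class GeneParams:
    """One gene's transcription kinetics.

    ``k0``: constitutive transcription rate; ``vmax``: maximal activated
    rate on top of k0; ``K``/``n``: Hill constants of the drive; ``kdeg``:
    mRNA degradation rate (per min; ln2/kdeg is the half-life).  ``ref`` is
    the resting value of the drive input (CREB*CRTC product, or X protein),
    subtracted so the activated term vanishes exactly at rest.  For factor
    X, ``k_translate``/``k_prot_deg`` govern its protein.
    """

    k0: float = 0.02
    vmax: float = 0.3
    K: float = 0.5
    n: float = 2.0
    kdeg: float = 0.02
    ref: float = 0.0
    k_translate: float = 0.0
    k_prot_deg: float = 0.0


def transcription_rate(gene: str, tf: TFActivity, p: GeneParams,
                       direct_creb_regulation: bool = False) -> float:
    """Transcription rate of ``gene`` given TF activities.

    Early genes and X respond to the CREB1*CRTC product above its resting
    reference; PPARGC1A responds to factor-X protein above its resting
    reference (or, in the alternative model variant, directly to the
    CREB1*CRTC product).  At baseline the rate is exactly ``k0``.
    """
    if gene == "PPARGC1A" and not direct_creb_regulation:
        drive = max(tf.x_protein - p.ref, 0.0)
    else:
        drive = max(tf.creb_active * tf.crtc_active - p.ref, 0.0)
    return p.k0 + p.vmax * hill(drive, p.K, p.n)


def fold_change(times: np.ndarray, values: np.ndarray,
                baseline_time: float) -> np.ndarray:
    """Trajectory divided by its pre-exercise steady value.

    ``baseline_time`` marks the end of the resting segment (exercise
    onset); the baseline is the value at the last sample at or before it.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    idx = np.nonzero(times <= baseline_time + 1e-12)[0]
    if len(idx) == 0:
        raise ValueError("trajectory has no baseline segment")
    base = values[idx[-1]]
    if base <= 0:
        raise ValueError("baseline expression is nonpositive")
    return values / base


def peak_timing(times: np.ndarray, values: np.ndarray,
                exercise_end: float) -> float:
    """Time of the maximal value after exercise, in hours relative to
    exercise end; ties break to the earliest time.

    Requires the trajectory to span at least 6 h past ``exercise_end``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    post = times >= exercise_end - 1e-12
    if not post.any() or times[post][-1] - exercise_end < 360.0 - 1e-9:
        raise ValueError("trajectory must span at least 6 h post-exercise")
    t_post = times[post]
    v_post = values[post]
    i = int(np.argmax(v_post))  # argmax returns the first maximum
    return (t_post[i] - exercise_end) / 60.0
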