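"""Lorenz-curve / Gini quantification of chemical-probing signal.

The Gini index over the DMS reactivities of the A/C residues of a region
measures how unevenly the signal is distributed: a region whose A/C bases are
uniformly reactive (unstructured RNA) has Gini near 0, while a region where
most signal concentrates on a few unprotected bases (structured RNA) has a
high Gini.  The index is the ratio a/(a+b) of the area between the diagonal
and the Lorenz curve (a) to the whole area below the diagonal (a+b), computed
with trapezoidal areas from the ascending-sorted signal; this is identical to
the pairwise mean-absolute-difference form  sum_ij |x_i - x_j| / (2 n^2 mu).

Gini is invariant to positive rescaling, so raw counts and normalized
reactivities give the same index; callers pass raw (coverage-scaled) counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ReactivityProfile


class GiniUndefinedError(ValueError):
    """Raised when the Gini index is undefined (all-zero or too-short input)."""


@dataclass
class GiniResult:
    gini: float
    n_positions: int
    lorenz: np.ndarray  # (n+1, 2) points: cumulative position/signal fraction

    def areas(self) -> tuple[float, float]:
        """(a, b): area between diagonal and Lorenz curve, area under curve."""
        x, y = self.lorenz[:, 0], self.lorenz[:, 1]
        b = float(np.trapezoid(y, x))
        return 0.5 - b, b


def gini(values: np.ndarray, min_positions: int = 2) -> GiniResult:
    """Gini index of a non-negative signal vector (already A/C-restricted)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("gini expects a 1-D vector")
    if v.size < min_positions:
        raise GiniUndefinedError(f"need >= {min_positions} positions, got {v.size}")
    if (v < 0).any():
        raise ValueError("negative signal values")
    total = v.sum()
    if total == 0:
        raise GiniUndefinedError("all-zero signal")
    s = np.sort(v)
    n = s.size
    cum = np.concatenate([[0.0], np.cumsum(s)]) / total
    x = np.arange(n + 1) / n
    lorenz = np.column_stack([x, cum])
    b = float(np.trapezoid(cum, x))
    g = (0.5 - b) / 0.5
    return GiniResult(gini=g, n_positions=n, lorenz=lorenz)


def gini_value(values: np.ndarray, min_positions: int = 2) -> float:
    """Gini as a bare float; NaN where undefined."""
    try:
        return gini(values, min_positions=min_positions).gini
    except GiniUndefinedError:
        return math.nan


def ac_gini(profile: ReactivityProfile, min_positions: int = 2) -> float:
    """Gini over the A/C positions of a profile; NaN where undefined."""
    return gini_value(profile.ac_values(), min_positions=min_positions)


def orf_half_ginis(profile: ReactivityProfile, min_positions: int = 2) -> tuple[float, float]:
    """Gini of the first and second halves of an ORF profile.

    Halves split at floor(L/2) nucleotides in transcript coordinates (the
    first half gets the shorter piece on odd lengths).  A half with fewer
    than ``min_positions`` scored A/C bases, or no signal, yields NaN.
    """
    L = profile.values.size
    mid = L // 2
    ac = profile.is_ac
    first = profile.values[:mid][ac[:mid]]
    second = profile.values[mid:][ac[mid:]]
    return (
        gini_value(first, min_positions=min_positions),
        gini_value(second, min_positions=min_positions),
    )


def windowed_gini(
    values: np.ndarray,
    window: int,
    step: int = 1,
    ac_mask: np.ndarray | None = None,
    min_positions: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Rolling-window Gini series over a region.

    Returns ``(centers, ginis)`` with each value reported at the window
    center (offset ``start + window // 2``).  Windows that would extend past
    the region ends are dropped, not shrunk, so every reported value scores
    the same number of nucleotides.  When ``ac_mask`` is given only masked-in
    (A/C) positions are scored; otherwise every position is.
    """
    v = np.asarray(values, dtype=float)
    if window > v.size:
        raise ValueError(f"window {window} exceeds region length {v.size}")
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    starts = np.arange(0, v.size - window + 1, step)
    centers = starts + window // 2
    out = np.empty(starts.size)
    for k, s in enumerate(starts):
        w = v[s : s + window]
        if ac_mask is not None:
            w = w[ac_mask[s : s + window]]
        out[k] = gini_value(w, min_positions=min_positions)
    return centers, out


def delta_gini(g_untranslated: float, g_translated: float) -> float:
    """Translation-dependent structure change, normalized by the mean.

    ``(g_u - g_t) / ((g_u + g_t) / 2)``; NaN when both indices are zero
    (or either is NaN).
    """
    if math.isnan(g_untranslated) or math.isnan(g_translated):
        return math.nan
    mean = (g_untranslated + g_translated) / 2.0
    if mean == 0:
        return math.nan
    return (g_untranslated - g_translated) / mean
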