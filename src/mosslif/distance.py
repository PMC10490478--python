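"""Histogram distances: intersection density difference and dynamic time warping.

Two complementary measures of how far a trial image's color distribution has
moved from a control image's:

* ``density_difference`` — one minus the histogram intersection, i.e.
  ``1 - sum_v min(x_v, y_v)`` over the 256 code values.  Bounded in [0, 1];
  0 for identical curves, 1 for disjoint supports.

* ``dtw_distance`` — the minimal cumulative alignment cost between two curves
  under monotone index warping, anchored at both curve ends, with step
  directions (i+1, j), (i+1, j+1), (i, j+1).  Unbounded above; 0 iff a
  perfect alignment exists.

DTW is also applied jointly to two channels at once (``two_color_dtw``): the
local cost is the Euclidean distance between the 2-vectors of channel
densities, so a color shift common to both channels can be absorbed by the
warp while a *relative* shift between the channels cannot.  The three
two-color combinations considered are RvG, GvB and RvB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .errors import ValidationError
from .histogram import ChannelHistogram, HistogramSet
from .imaging import ImageMeta

#: |sum - 1| tolerance accepted by density_difference.
INPUT_SUM_TOL = 1e-6

PAIR_COMBO_NAMES = ("RvG", "GvB", "RvB")
SINGLE_COMBO_NAMES = ("R", "G", "B")
METRICS = ("density_difference", "dtw")


@dataclass(frozen=True)
class ChannelCombo:
    """A single channel (R, G, B) or a two-color combination (RvG, GvB, RvB)."""

    kind: str  # "single" | "pair"
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind == "single":
            if len(self.channels) != 1 or self.channels[0] not in SINGLE_COMBO_NAMES:
                raise ValidationError(f"invalid single-channel combo {self.channels}")
        elif self.kind == "pair":
            if self.name not in PAIR_COMBO_NAMES:
                raise ValidationError(
                    f"pair combos are limited to {PAIR_COMBO_NAMES}, got {self.channels}"
                )
        else:
            raise ValidationError(f"combo kind must be 'single' or 'pair', got {self.kind!r}")

    @property
    def name(self) -> str:
        return self.channels[0] if self.kind == "single" else "v".join(self.channels)

    @classmethod
    def parse(cls, name: str) -> "ChannelCombo":
        if name in SINGLE_COMBO_NAMES:
            return cls(kind="single", channels=(name,))
        if name in PAIR_COMBO_NAMES:
            return cls(kind="pair", channels=tuple(name.split("v")))
        raise ValidationError(f"unknown channel combo {name!r}")


ALL_COMBOS = tuple(ChannelCombo.parse(n) for n in SINGLE_COMBO_NAMES + PAIR_COMBO_NAMES)


@dataclass(frozen=True)
class DifferenceSample:
    """One trial-image-vs-control-image distance under a chosen metric."""

    trial_meta: ImageMeta
    control_meta: ImageMeta
    combo: ChannelCombo
    metric: str
    value: float


def density_difference(x: ChannelHistogram | np.ndarray, y: ChannelHistogram | np.ndarray) -> float:
    """Intersection density difference between two normalized density curves.

    Returns ``1 - sum_v min(x_v, y_v)``; symmetric, in [0, 1], and 0 iff the
    curves are bin-wise equal.  Raises :class:`ValidationError` if either
    input does not sum to 1 within ``INPUT_SUM_TOL``.
    """
    xv = x.densities if isinstance(x, ChannelHistogram) else np.asarray(x, dtype=np.float64)
    yv = y.densities if isinstance(y, ChannelHistogram) else np.asarray(y, dtype=np.float64)
    for name, v in (("x", xv), ("y", yv)):
        if abs(float(v.sum()) - 1.0) > INPUT_SUM_TOL:
            raise ValidationError(
                f"{name} is not a normalized density curve (sum={float(v.sum())!r})"
            )
    # clamp away float residue so the result honors its documented [0, 1] range
    return float(min(1.0, max(0.0, 1.0 - np.minimum(xv, yv).sum())))


@njit(cache=True)
def _dtw_kernel(x: np.ndarray, y: np.ndarray) -> float:
    """Boundary-anchored DTW dynamic program over (n, k) / (m, k) sequences.

    Local cost is |x_i - y_j| for k = 1 and the Euclidean norm of the
    difference vector for k > 1.  No warping window, no slope constraint.
    """
    n, m, k = x.shape[0], y.shape[0], x.shape[1]
    D = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            if k == 1:
                c = abs(x[i, 0] - y[j, 0])
            else:
                s = 0.0
                for d in range(k):
                    t = x[i, d] - y[j, d]
                    s += t * t
                c = math.sqrt(s)
            if i == 0 and j == 0:
                prev = 0.0
            elif i == 0:
                prev = D[0, j - 1]
            elif j == 0:
                prev = D[i - 1, 0]
            else:
                prev = min(D[i - 1, j], D[i - 1, j - 1], D[i, j - 1])
            D[i, j] = c + prev
    return D[n - 1, m - 1]


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Univariate best-alignment distance between two nonempty sequences."""
    xv = np.ascontiguousarray(np.asarray(x, dtype=np.float64).reshape(-1, 1))
    yv = np.ascontiguousarray(np.asarray(y, dtype=np.float64).reshape(-1, 1))
    if xv.shape[0] == 0 or yv.shape[0] == 0:
        raise ValidationError("DTW requires nonempty sequences")
    return float(_dtw_kernel(xv, yv))


def two_color_dtw(a: HistogramSet, b: HistogramSet, combo: ChannelCombo) -> float:
    """Joint DTW over the 2-vector density curves of a two-color combination."""
    if combo.kind != "pair":
        raise ValidationError(f"two_color_dtw requires a pair combo, got {combo.name}")
    c1, c2 = combo.channels
    xa = np.ascontiguousarray(
        np.column_stack([a.channel(c1).densities, a.channel(c2).densities])
    )
    xb = np.ascontiguousarray(
        np.column_stack([b.channel(c1).densities, b.channel(c2).densities])
    )
    return float(_dtw_kernel(xa, xb))


def combo_distance(a: HistogramSet, b: HistogramSet, metric: str, combo: ChannelCombo) -> float:
    """Dispatch a metric/combo pair to the right distance function."""
    if metric == "density_difference":
        if combo.kind != "single":
            raise ValidationError("density_difference is defined for single channels only")
        return density_difference(a.channel(combo.name), b.channel(combo.name))
    if metric == "dtw":
        if combo.kind == "single":
            return dtw_distance(a.channel(combo.name).densities, b.channel(combo.name).densities)
        return two_color_dtw(a, b, combo)
    raise ValidationError(f"unknown metric {metric!r}")


def samples_to_frame(samples: list[DifferenceSample]) -> pd.DataFrame:
    """Long-format export of difference samples."""
    rows = []
    for s in samples:
        t, c = s.trial_meta, s.control_meta
        rows.append(
            {
                "trial_id": t.trial_id,
                "day": t.day,
                "session": t.session,
                "trial_position": t.position,
                "trial_side": t.side,
                "control_image_id": f"{c.trial_id}/day{c.day}/{c.session}/{c.position}_{c.side}",
                "metric": s.metric,
                "combo": s.combo.name,
                "value": s.value,
            }
        )
    return pd.DataFrame(rows)
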