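"""Per-channel density histograms ("percent abundance curves").

Each color channel of a frame is reduced to a 256-bin histogram of decimal
code values, normalized by the total pixel count so the bins sum to one.
These density curves are the sole input to every downstream comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .imaging import ImageMeta, RgbImage

CHANNELS = ("R", "G", "B")

#: Bins-sum tolerance for a valid density curve.
NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class ChannelHistogram:
    """Normalized 256-bin density curve for one color channel of one image."""

    densities: np.ndarray
    pixel_count: int
    channel: str

    def __post_init__(self) -> None:
        d = self.densities
        if d.shape != (256,):
            raise ValidationError(f"densities must be a 256-vector, got shape {d.shape}")
        if self.pixel_count < 1:
            raise ValidationError("pixel_count must be >= 1")
        if self.channel not in CHANNELS:
            raise ValidationError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if np.any(d < 0) or np.any(d > 1):
            raise ValidationError("densities must lie in [0, 1]")
        if abs(float(d.sum()) - 1.0) > NORMALIZATION_TOL:
            raise ValidationError(f"densities must sum to 1, got {float(d.sum())!r}")


@dataclass(frozen=True)
class HistogramSet:
    """The three channel histograms of one image, plus its metadata."""

    r: ChannelHistogram
    g: ChannelHistogram
    b: ChannelHistogram
    meta: ImageMeta

    def __post_init__(self) -> None:
        if not (self.r.pixel_count == self.g.pixel_count == self.b.pixel_count):
            raise ValidationError("all three channel histograms must share pixel_count")

    def channel(self, name: str) -> ChannelHistogram:
        try:
            return {"R": self.r, "G": self.g, "B": self.b}[name]
        except KeyError:
            raise ValidationError(f"unknown channel {name!r}") from None


def compute_histograms(image: RgbImage) -> HistogramSet:
    """Tally decimal code values per channel and normalize by pixel count."""
    n = image.width * image.height
    hists = {}
    for idx, name in enumerate(CHANNELS):
        counts = np.bincount(image.pixels[:, :, idx].ravel(), minlength=256)
        hists[name] = ChannelHistogram(
            densities=counts.astype(np.float64) / n, pixel_count=n, channel=name
        )
    return HistogramSet(r=hists["R"], g=hists["G"], b=hists["B"], meta=image.meta)


def histograms_to_frame(hset: HistogramSet) -> pd.DataFrame:
    """Long-format export: code, r_density, g_density, b_density + metadata."""
    m = hset.meta
    return pd.DataFrame(
        {
            "code": np.arange(256),
            "r_density": hset.r.densities,
            "g_density": hset.g.densities,
            "b_density": hset.b.densities,
            "trial_id": m.trial_id,
            "day": m.day,
            "session": m.session,
            "position": m.position,
            "side": m.side,
        }
    )
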