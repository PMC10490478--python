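"""Synthetic LIF-like image batches for exercising the full pipeline.

Real acquisitions are 8-bit RGB frames of a fluorescing moss tray: a
textured target whose channel intensities drift between imaging sessions,
carry pixel-level noise, and share a fixed brightness gradient caused by the
camera sitting close to the laser.  The generator reproduces those features
with a controllable, fully seeded model:

``pixel = clip(base_mean + day-scaled channel shift + session offset
             + image offset + gradient(x, y) + Gaussian noise)``

* the *gradient* is a corner-to-corner linear ramp, identical in every frame
  of a run — so, exactly as with the physical artifact, it cancels from any
  comparison made over a shared ROI and inflates comparisons made over
  mismatched ROIs;
* *session offsets* (one draw per channel per imaging session) model the
  drift in laser power, moisture and tray placement that makes the control's
  own session means vary — the natural variation the control band measures;
* *image offsets* model frame-to-frame brightness jitter within a session;
* *channel shifts* are the planted treatment effect, applied on the dosing
  calendar (days 2, 4, 6 by default, matching a 7-day experiment with
  treatments every 48 h).

Scenario presets mimic the qualitative response classes seen in LIF moss
data: metal-like stress shifts G and B strongly, environmental-like stress
shifts mainly B (with a weaker G response), photoperiod-like stress shifts
mainly G (with a weaker B response).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigError
from .imaging import MANIFEST_COLUMNS, ImageMeta, RgbImage

#: Treatment-effect presets: (dR, dG, dB) intensity-code shifts on dosing days.
#: Signs follow the response classes the generator emulates: metal-like
#: stress quenches green fluorescence while raising blue; environmental
#: stress expresses mainly as a blue rise; photoperiod change mainly as a
#: green drop.
SCENARIO_SHIFTS: dict[str, tuple[float, float, float]] = {
    "control": (0.0, 0.0, 0.0),
    "metal_like": (0.0, -28.0, 22.0),
    "environmental_like": (0.0, 11.0, 22.0),
    "photoperiod_like": (0.0, -28.0, -10.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the seed fully determines every generated byte.

    Defaults mirror the source study's design: a 7-day experiment imaged
    twice daily (am/pm) with ten frames per session and treatments applied
    on days 2, 4 and 6.  Base channel means place a strong red/green
    fluorescence signal over a weak blue one; 64x64 frames keep histogram
    sampling noise realistic while staying cheap to generate.
    """

    width: int = 64
    height: int = 64
    base_means: tuple[float, float, float] = (105.0, 175.0, 40.0)
    channel_shifts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    treatment_days: tuple[int, ...] = (2, 4, 6)
    noise_sd: float = 8.0
    session_sd: float = 2.0
    image_sd: float = 1.0
    gradient_amplitude: float = 10.0
    images_per_session: int = 10
    days: int = 7
    sessions_per_day: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.session_sd < 0 or self.image_sd < 0:
            raise ConfigError("noise/session/image SDs must be nonnegative")
        if self.width < 1 or self.height < 1:
            raise ConfigError("image dimensions must be positive")
        if self.images_per_session < 1 or self.days < 1:
            raise ConfigError("images_per_session and days must be positive")
        if self.sessions_per_day not in (1, 2):
            raise ConfigError("sessions_per_day must be 1 (am) or 2 (am/pm)")

    @property
    def sessions(self) -> tuple[str, ...]:
        return ("am", "pm")[: self.sessions_per_day]


def gradient_field(config: SyntheticConfig) -> np.ndarray:
    """The fixed acquisition ramp: 0 at pixel (0, 0), rising linearly to
    ``gradient_amplitude`` at the opposite corner, identical in all channels
    and all images of a run."""
    xs = np.arange(config.width) / max(config.width - 1, 1)
    ys = np.arange(config.height) / max(config.height - 1, 1)
    return config.gradient_amplitude * (xs[None, :] + ys[:, None]) / 2.0


def day_shift(config: SyntheticConfig, day: int) -> np.ndarray:
    """Channel shift in effect on ``day``: full amplitude on treatment days,
    zero otherwise."""
    scale = 1.0 if day in config.treatment_days else 0.0
    return scale * np.asarray(config.channel_shifts, dtype=np.float64)


def generate_image(
    config: SyntheticConfig,
    day: int,
    rng: np.random.Generator,
    meta: ImageMeta | None = None,
    channel_offset: tuple[float, float, float] | np.ndarray = (0.0, 0.0, 0.0),
) -> RgbImage:
    """Draw one frame: base means + day-scaled shift + offsets + gradient + noise,
    rounded and clipped to 8-bit codes."""
    if meta is None:
        meta = ImageMeta(trial_id="synthetic", day=day, session="am", position=1, side="front")
    base = (
        np.asarray(config.base_means, dtype=np.float64)
        + day_shift(config, day)
        + np.asarray(channel_offset, dtype=np.float64)
    )
    field = base[None, None, :] + gradient_field(config)[:, :, None]
    noisy = field + rng.normal(0.0, config.noise_sd, size=(config.height, config.width, 3))
    codes = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return RgbImage(pixels=codes, meta=meta)


def _trial_rng(config: SyntheticConfig, trial_id: str) -> np.random.Generator:
    # Stable per-trial stream: independent trials from one study seed.
    return np.random.default_rng([config.seed, zlib.crc32(trial_id.encode("utf-8"))])


def _session_layout(config: SyntheticConfig) -> list[tuple[int, str]]:
    n_front = (config.images_per_session + 1) // 2
    layout = []
    for i in range(config.images_per_session):
        if i < n_front:
            layout.append((i + 1, "front"))
        else:
            layout.append((i - n_front + 1, "back"))
    return layout


def generate_trial(
    config: SyntheticConfig,
    trial_id: str,
    shifts: tuple[float, float, float] | None = None,
) -> list[RgbImage]:
    """Generate every frame of one trial, in (day, session, position) order."""
    if shifts is not None:
        config = replace(config, channel_shifts=shifts)
    rng = _trial_rng(config, trial_id)
    images: list[RgbImage] = []
    for day in range(1, config.days + 1):
        for session in config.sessions:
            session_off = rng.normal(0.0, config.session_sd, size=3)
            for position, side in _session_layout(config):
                image_off = rng.normal(0.0, config.image_sd, size=3)
                meta = ImageMeta(
                    trial_id=trial_id, day=day, session=session, position=position, side=side
                )
                images.append(
                    generate_image(
                        config, day, rng, meta=meta, channel_offset=session_off + image_off
                    )
                )
    return images


def generate_experiment(
    config: SyntheticConfig,
    scenario: str,
    out_dir: str | Path,
    trial_id: str | None = None,
) -> Path:
    """Write one scenario trial as PNG files plus a manifest CSV.

    Files follow ``<out>/<trial_id>/day<D>/<session>/<position>_<side>.png``;
    rows are appended to ``<out>/manifest.csv`` (created if absent) with
    paths relative to the manifest.  Returns the manifest path.
    """
    if scenario not in SCENARIO_SHIFTS:
        raise ConfigError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIO_SHIFTS)}")
    trial_id = trial_id or scenario
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = generate_trial(config, trial_id, shifts=SCENARIO_SHIFTS[scenario])
    rows = []
    for img in images:
        m = img.meta
        rel = Path(m.trial_id) / f"day{m.day}" / m.session / f"{m.position}_{m.side}.png"
        full = out_dir / rel
        full.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img.pixels, mode="RGB").save(full)
        rows.append(
            {
                "path": rel.as_posix(),
                "trial_id": m.trial_id,
                "day": m.day,
                "session": m.session,
                "position": m.position,
                "side": m.side,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    new = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest_path.exists():
        old = pd.read_csv(manifest_path)
        merged = pd.concat([old[old["trial_id"] != trial_id], new], ignore_index=True)
    else:
        merged = new
    merged.to_csv(manifest_path, index=False)
    return manifest_path
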