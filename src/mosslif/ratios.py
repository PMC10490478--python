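"""Color-ratio decomposition and rule-based stressor classification.

The three single-channel difference values of a session are reduced to the
fraction each channel contributes to the total color change
(``R_D / (R_D + G_D + B_D)`` and likewise for G and B).  Separately, the
pattern of control-band deviations across channel combinations is mapped to
a stressor class:

* metals move the color distribution broadly — two or more two-color
  combinations deviate;
* environmental stress (watering, nutrients) expresses mainly through the
  blue channel — a single deviating combination that contains B;
* photoperiod changes express through the green channel — a single deviating
  combination that contains G (after the blue rule, so a lone GvB deviation
  is attributed to environmental stress by declared rule order).

The rules are an explicit ordered table so the mapping is total and
deterministic over every flag pattern; each call reports which rules fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .distance import PAIR_COMBO_NAMES, SINGLE_COMBO_NAMES
from .errors import ValidationError

ALL_COMBO_NAMES = SINGLE_COMBO_NAMES + PAIR_COMBO_NAMES

STRESSOR_LABELS = ("metal", "environmental", "photoperiod", "none", "ambiguous")


@dataclass(frozen=True)
class ColorRatioTriple:
    """Per-channel fractions of the total color difference; sums to 1."""

    r_frac: float
    g_frac: float
    b_frac: float

    def __post_init__(self) -> None:
        total = self.r_frac + self.g_frac + self.b_frac
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"fractions must sum to 1, got {total!r}")
        for f in (self.r_frac, self.g_frac, self.b_frac):
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"fractions must lie in [0, 1], got {f!r}")


@dataclass(frozen=True)
class DeviationPattern:
    """Control-band deviation flags for all six channel combinations.

    ``flags`` maps combo name (R, G, B, RvG, GvB, RvB) to a boolean;
    ``metric_by_combo`` records which metric produced each flag.
    """

    flags: dict[str, bool]
    metric_by_combo: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ALL_COMBO_NAMES if c not in self.flags]
        if missing:
            raise ValidationError(f"deviation pattern incomplete; missing combos {missing}")

    @property
    def flagged_pairs(self) -> tuple[str, ...]:
        return tuple(c for c in PAIR_COMBO_NAMES if self.flags[c])

    @property
    def any_flag(self) -> bool:
        return any(self.flags[c] for c in ALL_COMBO_NAMES)


@dataclass(frozen=True)
class StressorCall:
    """Rule-based attribution of a deviation pattern to a stressor class."""

    label: str
    rationale: tuple[str, ...]


def color_ratios(r_d: float, g_d: float, b_d: float) -> ColorRatioTriple:
    """Fraction of total color difference contributed by each channel."""
    for name, v in (("r_d", r_d), ("g_d", g_d), ("b_d", b_d)):
        if v < 0:
            raise ValidationError(f"{name} must be nonnegative, got {v}")
    total = r_d + g_d + b_d
    if total <= 0:
        raise ValidationError("total color difference is zero; ratios are undefined")
    return ColorRatioTriple(r_frac=r_d / total, g_frac=g_d / total, b_frac=b_d / total)


def classify_stressor(pattern: DeviationPattern) -> StressorCall:
    """Map a deviation pattern to a stressor label via the ordered rule table.

    Rule order: (a) >= 2 deviating two-color combinations -> metal;
    (b) exactly one deviating combination, containing B -> environmental;
    (c) exactly one deviating combination, containing G -> photoperiod;
    (d) no deviation anywhere -> none; (e) otherwise -> ambiguous.
    """
    pairs = pattern.flagged_pairs
    fired: list[str] = []
    if len(pairs) >= 2:
        fired.append(f"(a) {len(pairs)} two-color combinations deviate ({', '.join(pairs)})")
        return StressorCall(label="metal", rationale=tuple(fired))
    if len(pairs) == 1:
        combo = pairs[0]
        if "B" in combo:
            fired.append(f"(b) single deviating combination {combo} contains B")
            return StressorCall(label="environmental", rationale=tuple(fired))
        if "G" in combo:
            fired.append(f"(c) single deviating combination {combo} contains G")
            return StressorCall(label="photoperiod", rationale=tuple(fired))
    if not pattern.any_flag:
        fired.append("(d) no combination deviates from control")
        return StressorCall(label="none", rationale=tuple(fired))
    singles = [c for c in SINGLE_COMBO_NAMES if pattern.flags[c]]
    fired.append(
        "(e) deviation pattern matches no attribution rule "
        f"(single-channel flags: {', '.join(singles) if singles else 'none'}; "
        f"two-color flags: {', '.join(pairs) if pairs else 'none'})"
    )
    return StressorCall(label="ambiguous", rationale=tuple(fired))
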