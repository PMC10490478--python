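"""Batch comparison statistics and control-band decision rules.

The unit of analysis is the imaging *session* (am/pm of one day): every image
of a trial session is compared against every image of the control pool, and
the resulting per-pair distance values are summarized as mean, sample SD and
SE.  A control trial compared against its own pool excludes identical-image
self-pairs, which would otherwise bias the null toward zero.

Deviation from control is decided against a *control band*: the control
pool's own session means define a t-based interval at the configured
confidence level (default 99%) plus a 3-sigma envelope.  A trial session is
flagged only if its mean falls strictly outside the band, so a flag carries
high statistical certainty that the session does not belong to the control
population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .distance import ChannelCombo, DifferenceSample, combo_distance
from .errors import DegenerateVarianceError, InsufficientDataError, ValidationError
from .histogram import HistogramSet


@dataclass(frozen=True)
class SessionSummary:
    """Mean / SD / SE of difference samples for one trial session and combo."""

    trial_id: str
    day: int
    session: str
    combo: ChannelCombo
    metric: str
    mean: float
    sd: float
    se: float
    n: int


@dataclass(frozen=True)
class WelchResult:
    """Welch's unequal-variance t statistic with Satterthwaite dof."""

    t: float
    dof: float
    p: float


@dataclass(frozen=True)
class ControlBand:
    """Control-population band for one combo/metric.

    ``ci99_lo``/``ci99_hi`` bound the region a new control session mean falls
    in with the configured probability (t-based prediction interval on the
    control session means); ``sigma3_lo``/``sigma3_hi`` is the wider
    3-sigma envelope around the same center.
    """

    combo: ChannelCombo
    metric: str
    center: float
    ci99_lo: float
    ci99_hi: float
    sigma3_lo: float
    sigma3_hi: float
    n_sessions: int
    level: float


def _meta_id(meta) -> tuple:
    return (meta.trial_id, meta.day, meta.session, meta.position, meta.side)


def all_pairs_differences(
    trial_images: list[HistogramSet],
    control_images: list[HistogramSet],
    metric: str,
    combo: ChannelCombo,
    exclude: str = "self",
) -> list[DifferenceSample]:
    """One sample per ordered (trial image, control image) pair.

    With ``exclude="self"`` (default), self-pairs — a control image compared
    with itself during control self-comparison, identified by identical
    acquisition metadata — are excluded, giving
    ``|trial| * |control| - n_shared`` samples.  With ``exclude="session"``,
    every pair sharing the same (trial, day, session) is dropped, so a
    control session is compared only against images *outside* its own
    session; this makes control session means exchangeable with those of an
    independent trial, whose sessions never appear in the control pool.
    """
    if not trial_images or not control_images:
        raise InsufficientDataError("all_pairs_differences requires nonempty image lists")
    if exclude not in ("self", "session"):
        raise ValidationError(f"exclude must be 'self' or 'session', got {exclude!r}")
    samples: list[DifferenceSample] = []
    for t in trial_images:
        tid = _meta_id(t.meta)
        for c in control_images:
            if exclude == "self" and tid == _meta_id(c.meta):
                continue
            if exclude == "session" and t.meta.session_key == c.meta.session_key:
                continue
            samples.append(
                DifferenceSample(
                    trial_meta=t.meta,
                    control_meta=c.meta,
                    combo=combo,
                    metric=metric,
                    value=combo_distance(t, c, metric, combo),
                )
            )
    return samples


def summarize_session(samples: list[DifferenceSample]) -> SessionSummary:
    """Mean, sample SD (n-1 denominator) and SE over one session's samples.

    All samples must share trial session, combo and metric.
    """
    if len(samples) < 2:
        raise InsufficientDataError("summarize_session requires at least 2 samples")
    keys = {(s.trial_meta.session_key, s.combo.name, s.metric) for s in samples}
    if len(keys) != 1:
        raise ValidationError("samples mix trial sessions, combos or metrics")
    values = np.array([s.value for s in samples], dtype=np.float64)
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    first = samples[0]
    return SessionSummary(
        trial_id=first.trial_meta.trial_id,
        day=first.trial_meta.day,
        session=first.trial_meta.session,
        combo=first.combo,
        metric=first.metric,
        mean=mean,
        sd=sd,
        se=sd / math.sqrt(n),
        n=n,
    )


def welch_t(a, b, two_sided: bool = True) -> WelchResult:
    """Welch's t-test for unequal variances.

    ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with
    Welch–Satterthwaite degrees of freedom.  Raises
    :class:`DegenerateVarianceError` when both samples are constant.
    """
    av = np.asarray(a, dtype=np.float64)
    bv = np.asarray(b, dtype=np.float64)
    if av.size < 2 or bv.size < 2:
        raise InsufficientDataError("welch_t requires at least 2 observations per sample")
    na, nb = av.size, bv.size
    va = float(av.var(ddof=1))
    vb = float(bv.var(ddof=1))
    if va == 0.0 and vb == 0.0:
        raise DegenerateVarianceError("both samples are constant; Welch's t is undefined")
    sa, sb = va / na, vb / nb
    t = (float(av.mean()) - float(bv.mean())) / math.sqrt(sa + sb)
    dof = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    if two_sided:
        p = 2.0 * float(sps.t.sf(abs(t), dof))
    else:
        p = float(sps.t.sf(t, dof))
    return WelchResult(t=t, dof=dof, p=min(p, 1.0))


def control_band(control_summaries: list[SessionSummary], level: float = 0.99) -> ControlBand:
    """Band of plausible control session means for one combo/metric.

    The interval is the t-based prediction interval for a *new* session mean,
    ``center ± t_{(1+level)/2, n-1} * s * sqrt(1 + 1/n)`` where ``s`` is the
    SD of the control session means — i.e. the region a held-out control
    session falls in with probability ``level``.  The 3-sigma envelope is
    ``center ± 3 s``.
    """
    if len(control_summaries) < 2:
        raise InsufficientDataError("control_band requires >= 2 control session summaries")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    keys = {(s.combo.name, s.metric) for s in control_summaries}
    if len(keys) != 1:
        raise ValidationError("control summaries mix combos or metrics")
    means = np.array([s.mean for s in control_summaries], dtype=np.float64)
    n = means.size
    center = float(means.mean())
    s = float(means.std(ddof=1))
    tcrit = float(sps.t.ppf((1.0 + level) / 2.0, n - 1))
    half = tcrit * s * math.sqrt(1.0 + 1.0 / n)
    first = control_summaries[0]
    return ControlBand(
        combo=first.combo,
        metric=first.metric,
        center=center,
        ci99_lo=center - half,
        ci99_hi=center + half,
        sigma3_lo=center - 3.0 * s,
        sigma3_hi=center + 3.0 * s,
        n_sessions=n,
        level=level,
    )


def exceeds_band(summary: SessionSummary, band: ControlBand) -> bool:
    """True iff the session mean lies strictly outside the band's interval.

    A mean exactly on a bound is *not* a deviation (strict exceedance).
    """
    if summary.combo.name != band.combo.name or summary.metric != band.metric:
        raise ValidationError(
            f"summary ({summary.combo.name}, {summary.metric}) does not match "
            f"band ({band.combo.name}, {band.metric})"
        )
    return summary.mean < band.ci99_lo or summary.mean > band.ci99_hi
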