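"""Log-ratio fluctuation statistics and per-subject feature assembly.

The fluctuation of a latency series is summarised as the sample standard
deviation of the natural log of the quotient of two consecutive intervals:

    X_SD = SD{ ln(I_{n+1} / I_n) }

This is a scale-free, sequential dispersion measure: multiplying every
interval by a constant leaves it unchanged, while permuting the series
generally changes it.  For intervals with iid Normal(mu, sigma^2)
logarithms the consecutive log-ratios are Normal(0, 2 sigma^2), so the
statistic converges to sqrt(2)*sigma — the closed form used to calibrate
the synthetic cohorts.

Two variants are computed per subject: the all-keystroke statistic for each
of HL/IL/PL/RL, and a restricted-key variant of the HL statistic that keeps
only alphanumeric, symbol and space-bar keystrokes (the construction used
by earlier hold-time work, reported as the "SD" feature).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np

from .io import SubjectMetadata, TypingSession
from .latency import LatencySeries, extract_latencies, typing_speed_and_words
from .outliers import MIN_SERIES_LENGTH, OutlierPolicy, OutlierRecord, clean_series

__all__ = [
    "SubjectFeatureRecord",
    "FLUCTUATION_FEATURES",
    "log_ratio_sd",
    "restricted_key_filter",
    "build_feature_record",
]

FLUCTUATION_FEATURES = ("hl_sd", "il_sd", "pl_sd", "rl_sd", "sd_restricted")

#: key classes admitted by the restricted filter: letters, digits, printable
#: punctuation/symbols, and the space bar; specials (backspace, enter,
#: shift, arrows, ...) are excluded
_ALLOWED_SINGLE = set(string.ascii_lowercase) | set(string.digits) | set(string.punctuation)


def _key_allowed(key_id: str) -> bool:
    return key_id == "space" or (len(key_id) == 1 and key_id in _ALLOWED_SINGLE)


def log_ratio_sd(
    values, original_index=None, pair_policy: str = "compact"
) -> float:
    """Sample SD of ln(v_{i+1}/v_i) over consecutive survivor pairs.

    Parameters
    ----------
    values
        Cleaned interval values in original order.  Non-positive values
        (possible when negative removal was disabled upstream) are outside
        the logarithm's domain; they are excluded and both ratios adjacent
        to them dropped.
    original_index
        Positions of ``values`` in the pre-cleaning series; required by the
        strict pair policy, ignored otherwise.
    pair_policy
        ``"compact"`` (default): cleaning compacts the series, so ratios are
        taken between all adjacent survivors — this maximises retained
        pairs.  ``"strict"``: a ratio is kept only when its two values were
        adjacent before cleaning, i.e. pairs spanning a removed value are
        discarded.

    Returns
    -------
    float
        The statistic, or ``nan`` when fewer than 2 valid ratios remain
        (so a missing value is representable and never rendered as zero).
    """
    v = np.asarray(values, dtype=float)
    if pair_policy not in ("compact", "strict"):
        raise ValueError(f"unknown pair_policy {pair_policy!r}")
    if v.size < MIN_SERIES_LENGTH:
        return math.nan
    keep = np.flatnonzero(v > 0)
    if keep.size < 2:
        return math.nan
    kept = v[keep]
    # log of the quotient (not difference of logs): equal quotients give
    # bit-identical ratios, so constant-ratio series yield exactly 0
    ratios = np.log(kept[1:] / kept[:-1])
    ok = np.diff(keep) == 1  # never bridge an excluded non-positive value
    if pair_policy == "strict":
        if original_index is None:
            raise ValueError("strict pair_policy requires original_index")
        orig = np.asarray(original_index, dtype=int)[keep]
        ok &= np.diff(orig) == 1
    ratios = ratios[ok]
    if ratios.size < 2:
        return math.nan
    if np.ptp(ratios) == 0.0:
        return 0.0
    return float(np.std(ratios, ddof=1))


def restricted_key_filter(series: LatencySeries, session: TypingSession) -> LatencySeries:
    """Keep only values whose source events are all allowed-class keys."""
    allowed = np.array([_key_allowed(k) for k in session.key_ids], dtype=bool)
    mask = allowed[series.pair_index].all(axis=1)
    return series.take(np.flatnonzero(mask))


@dataclass(frozen=True)
class SubjectFeatureRecord:
    """Per-subject scalar features plus pass-through clinical metadata.

    Fluctuation statistics are unitless; ``typing_speed`` is words/min;
    ``stap``/``aftap`` are msec.  A statistic that could not be computed
    (cleaned series too short) is ``nan``, never zero.
    """

    subject_id: str
    group: str
    hl_sd: float = math.nan
    il_sd: float = math.nan
    pl_sd: float = math.nan
    rl_sd: float = math.nan
    sd_restricted: float = math.nan
    typing_speed: float = math.nan
    word_count: float = math.nan
    updrs3: float = math.nan
    stap: float = math.nan
    aftap: float = math.nan
    nqi: float = math.nan


def build_feature_record(
    session: TypingSession,
    metadata: SubjectMetadata | None = None,
    policy: OutlierPolicy = OutlierPolicy(),
    word_convention: str = "space_plus_one",
    pair_policy: str = "compact",
) -> tuple[SubjectFeatureRecord, list[OutlierRecord]]:
    """Extract, clean and summarise one session into a feature record.

    Pipeline: latency extraction -> per-kind cleaning -> log-ratio SD per
    kind over all keystrokes -> restricted-key HL statistic (key filter
    applied before cleaning, as in the original hold-time construction) ->
    typing speed and word count -> metadata merge.
    """
    series = extract_latencies(session)
    stats: dict[str, float] = {}
    records: list[OutlierRecord] = []
    for kind, s in series.items():
        cleaned, rec = clean_series(s, policy, subject_id=session.subject_id)
        records.append(rec)
        stats[f"{kind.lower()}_sd"] = log_ratio_sd(
            cleaned.values, cleaned.pair_index[:, 0], pair_policy
        )

    restricted = restricted_key_filter(series["HL"], session)
    cleaned_r, _ = clean_series(restricted, policy, subject_id=session.subject_id)
    stats["sd_restricted"] = log_ratio_sd(
        cleaned_r.values, cleaned_r.pair_index[:, 0], pair_policy
    )

    speed, words = typing_speed_and_words(session, convention=word_convention)

    meta = metadata or SubjectMetadata(subject_id=session.subject_id, group="control")
    record = SubjectFeatureRecord(
        subject_id=session.subject_id,
        group=meta.group,
        typing_speed=speed,
        word_count=float(words),
        updrs3=meta.updrs3,
        stap=meta.stap,
        aftap=meta.aftap,
        nqi=meta.nqi,
        **stats,
    )
    return record, records
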