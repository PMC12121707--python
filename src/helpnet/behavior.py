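"""Behavioral classification and statistics for the helping behavior test.

A free rat is classified as an "opener" if it opened the restrainer door at
least twice on the last three testing days; non-opening days are scored at
the 40 min session maximum when averaging latencies. Role assignment in the
boldness test gives the "free" role to the rat that peeked first on at least
3 of 5 days.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from helpnet.data_model import (
    HBT_MAX_LATENCY_MIN,
    BoldnessRecord,
    DegenerateInputError,
    OpenerCall,
    RoleAssignment,
    SessionRecord,
    SocialInteractionSummary,
    ValidationError,
)

__all__ = [
    "assign_roles",
    "classify_opener",
    "opening_rate_by_day",
    "latency_series",
    "fisher_exact_2x2",
    "pearson_with_p",
    "si_latency_association",
]


class UnresolvedRoleError(ValidationError):
    """Neither rat of a pair attains 3 first-peeks and no tie rule applies."""


def assign_roles(
    log: Sequence[BoldnessRecord], tie_rule: str = "lower_mean_latency"
) -> RoleAssignment:
    """Assign free/trapped roles from a pair's 5-day boldness log.

    The rat that peeked first on >= 3 of the 5 days becomes the free rat.
    Days where both rats share the same latency (including double censoring
    at 300 s) count as ties and credit neither rat. If neither rat reaches
    3 first-peeks, ``tie_rule='lower_mean_latency'`` falls back to the rat
    with the lower mean peek latency; ``tie_rule='error'`` raises.
    """
    if tie_rule not in ("lower_mean_latency", "error"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    pair_ids = {r.pair_id for r in log}
    if len(pair_ids) != 1:
        raise ValidationError(f"assign_roles expects one pair, got {sorted(pair_ids)}")
    (pair_id,) = pair_ids
    rats = sorted({r.rat_id for r in log})
    if len(rats) != 2:
        raise ValidationError(f"pair {pair_id}: expected exactly 2 rats, got {rats}")
    by_day: dict[int, dict[str, BoldnessRecord]] = {}
    for rec in log:
        if rec.rat_id in by_day.setdefault(rec.day, {}):
            raise ValidationError(f"pair {pair_id}: duplicate record day {rec.day}")
        by_day[rec.day][rec.rat_id] = rec
    if sorted(by_day) != [1, 2, 3, 4, 5] or any(len(v) != 2 for v in by_day.values()):
        raise ValidationError(f"pair {pair_id}: need complete 5 days x 2 rats coverage")

    days_first = {r: 0 for r in rats}
    for day in range(1, 6):
        a, b = (by_day[day][r] for r in rats)
        if a.peek_latency < b.peek_latency:
            days_first[rats[0]] += 1
        elif b.peek_latency < a.peek_latency:
            days_first[rats[1]] += 1
        # equal latencies: tie day, no credit
    mean_latency = {
        r: float(np.mean([by_day[d][r].peek_latency for d in range(1, 6)]))
        for r in rats
    }
    qualified = [r for r in rats if days_first[r] >= 3]
    if qualified:
        free = qualified[0]
    elif tie_rule == "lower_mean_latency":
        free = min(rats, key=lambda r: (mean_latency[r], r))
    else:
        raise UnresolvedRoleError(
            f"pair {pair_id}: neither rat peeked first on 3 of 5 days"
        )
    trapped = rats[1] if free == rats[0] else rats[0]
    return RoleAssignment(
        pair_id=pair_id,
        free_rat=free,
        trapped_rat=trapped,
        days_first={r: days_first[r] for r in rats},
        mean_latency={r: mean_latency[r] for r in rats},
        delta_latency=abs(mean_latency[free] - mean_latency[trapped]),
    )


def _validated_days(log: Sequence[SessionRecord]) -> dict[int, SessionRecord]:
    pair_ids = {r.pair_id for r in log}
    if len(pair_ids) != 1:
        raise ValidationError(f"expected one pair, got {sorted(pair_ids)}")
    by_day: dict[int, SessionRecord] = {}
    for rec in log:
        if rec.day in by_day:
            raise ValidationError(f"pair {rec.pair_id}: duplicate day {rec.day}")
        by_day[rec.day] = rec
    n_days = len(by_day)
    if n_days < 3:
        raise ValidationError("opener classification needs at least 3 testing days")
    if sorted(by_day) != list(range(1, n_days + 1)):
        raise ValidationError("session log must cover contiguous days 1..D")
    return by_day


def classify_opener(
    log: Sequence[SessionRecord], alt_rule_consecutive_plus_final: bool = False
) -> OpenerCall:
    """Classify a pair's free rat as opener/nonopener from its session log.

    The rule is >= 2 openings by the free rat on the last 3 days. The
    optional alternative rule additionally accepts a rat that opened on 2
    consecutive days and on the final day (a documented exception used for
    one animal in the c-Fos cohort).
    """
    by_day = _validated_days(log)
    n_days = len(by_day)
    opened = [by_day[d].opened_by_free for d in range(1, n_days + 1)]
    total = int(sum(opened))
    last3 = int(sum(opened[-3:]))
    is_opener = last3 >= 2
    if not is_opener and alt_rule_consecutive_plus_final:
        consecutive = any(opened[i] and opened[i + 1] for i in range(n_days - 1))
        is_opener = consecutive and opened[-1]
    latencies, mean_lat = latency_series(log)
    return OpenerCall(
        pair_id=by_day[1].pair_id,
        is_opener=is_opener,
        total_openings=total,
        openings_last3=last3,
        mean_latency=mean_lat,
    )


def latency_series(log: Sequence[SessionRecord]) -> tuple[np.ndarray, float]:
    """Per-day opening latencies (minutes) with non-openings scored at 40."""
    by_day = _validated_days(log)
    n_days = len(by_day)
    out = np.empty(n_days)
    for d in range(1, n_days + 1):
        rec = by_day[d]
        out[d - 1] = rec.latency if rec.opened_by_free else HBT_MAX_LATENCY_MIN
    return out, float(out.mean())


def opening_rate_by_day(
    logs: Mapping[str, Sequence[SessionRecord]]
) -> pd.Series:
    """Fraction of a group's free rats that opened the door on each day."""
    if not logs:
        raise ValidationError("opening_rate_by_day requires a non-empty group")
    per_pair = {pid: _validated_days(log) for pid, log in logs.items()}
    day_ranges = {max(d) for d in per_pair.values()}
    if len(day_ranges) != 1:
        raise ValidationError("all pairs must share the same day range")
    n_days = day_ranges.pop()
    counts = np.zeros(n_days)
    for by_day in per_pair.values():
        for d in range(1, n_days + 1):
            counts[d - 1] += by_day[d].opened_by_free
    return pd.Series(
        counts / len(per_pair), index=pd.RangeIndex(1, n_days + 1, name="day")
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability method).

    The two-sided p sums the hypergeometric probabilities of every table
    with the same margins whose point probability does not exceed that of
    the observed table.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValidationError("table cells must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DegenerateInputError("all margins of the 2x2 table must be positive")
    _, p = scipy.stats.fisher_exact(arr.astype(int), alternative="two-sided")
    return float(min(p, 1.0))


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("constant input has undefined correlation")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def si_latency_association(
    si: Sequence[SocialInteractionSummary],
    calls: Sequence[OpenerCall],
) -> pd.DataFrame:
    """Correlate social-interaction measures with mean opening latency.

    Returns one row per (session, measure) with Pearson r and p over pairs
    present in both inputs; used to ask whether affiliative behavior before
    or at the start of testing predicts subsequent helping.
    """
    lat = {c.pair_id: c.mean_latency for c in calls}
    rows = []
    df = pd.DataFrame(
        [
            {
                "pair_id": s.pair_id,
                "session": s.session,
                "si_count": s.si_count,
                "si_duration": s.si_duration,
            }
            for s in si
            if s.pair_id in lat
        ]
    )
    if df.empty or df.groupby("session").size().max() < 3:
        raise ValidationError("need at least 3 matched pairs per session")
    for session, grp in df.groupby("session", sort=False):
        if len(grp) < 3:
            raise ValidationError(f"session {session}: fewer than 3 matched pairs")
        y = np.array([lat[p] for p in grp["pair_id"]])
        for measure in ("si_count", "si_duration"):
            r, p = pearson_with_p(grp[measure].to_numpy(dtype=float), y)
            rows.append(
                {"session": session, "measure": measure, "r": r, "p": p, "n": len(grp)}
            )
    return pd.DataFrame(rows)
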