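"""Effect decomposition from joint path draws.

All quantities are computed per draw and only then summarized, so deltas and
totals respect the joint posterior.  Significance is interval exclusion of
zero at the report's level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hapath.errors import IntegrityError
from hapath.ham_model import PathDraws

#: Composed quantities, in report order.
QUANTITIES = (
    "direct",
    "indirect_via_performance",
    "indirect_via_referee",
    "serial_indirect",
    "total_on_outcome",
    "indirect_on_referee_via_performance",
    "total_on_referee",
)

#: Raw path symbols also reportable per period.
PATHS = ("a1", "a2", "d", "b1", "b2", "c")


def _period_quantities(
    draws: PathDraws, period: str, include_serial_in_total: bool
) -> dict[str, np.ndarray]:
    a1 = draws.period_value("a1", period)
    a2 = draws.period_value("a2", period)
    d = draws.period_value("d", period)
    b1 = draws.period_value("b1", period)
    b2 = draws.period_value("b2", period)
    c = draws.period_value("c", period)
    n = {len(x) for x in (a1, a2, d, b1, b2, c)}
    if len(n) != 1:
        raise IntegrityError("mismatched draw lengths across paths")
    q = {
        "direct": c,
        "indirect_via_performance": a1 * b1,
        "indirect_via_referee": a2 * b2,
        "serial_indirect": a1 * d * b2,
        "indirect_on_referee_via_performance": a1 * d,
        "total_on_referee": a2 + a1 * d,
    }
    q["total_on_outcome"] = (
        c
        + q["indirect_via_performance"]
        + q["indirect_via_referee"]
        + (q["serial_indirect"] if include_serial_in_total else 0.0)
    )
    for s, arr in zip(("a1", "a2", "d", "b1", "b2", "c"), (a1, a2, d, b1, b2, c)):
        q[s] = arr
    return q


def _summarize(x: np.ndarray, level: float) -> dict:
    lo_q = (1 - level) / 2
    lo, hi = float(np.quantile(x, lo_q)), float(np.quantile(x, 1 - lo_q))
    return {
        "estimate": float(np.median(x)),
        "lower": lo,
        "upper": hi,
        "significant": bool(lo > 0 or hi < 0),
    }


def compose_effects(
    draws: PathDraws,
    include_serial_in_total: bool = False,
    interval_level: float | None = None,
) -> pd.DataFrame:
    """Direct, indirect and total effects per period, with paired deltas.

    By default the serial three-path channel is reported separately and not
    folded into ``total_on_outcome``; pass ``include_serial_in_total=True``
    to fold it in.  Returns a tidy frame with one row per (quantity, period)
    where period is ``pre``, ``post`` or ``delta`` (post minus pre).
    """
    level = interval_level if interval_level is not None else draws.interval_level
    per = {
        p: _period_quantities(draws, p, include_serial_in_total)
        for p in ("pre", "post")
    }
    rows = []
    for name in QUANTITIES + PATHS:
        for period in ("pre", "post"):
            rows.append(
                {"quantity": name, "period": period, **_summarize(per[period][name], level)}
            )
        diff = per["post"][name] - per["pre"][name]
        rows.append({"quantity": name, "period": "delta", **_summarize(diff, level)})
    return pd.DataFrame(rows)


def delta(source, quantity: str | None = None, interval_level: float = 0.95) -> dict:
    """Summarized post-minus-pre difference of one quantity.

    ``source`` is either a :class:`PathDraws` (then ``quantity`` names a
    composed quantity or path symbol) or a mapping with ``pre`` and ``post``
    point values/arrays.  The difference is taken per draw (paired), then
    summarized.
    """
    if isinstance(source, PathDraws):
        if quantity is None:
            raise ValueError("quantity is required with PathDraws input")
        known = set(QUANTITIES) | set(PATHS)
        if quantity not in known:
            raise KeyError(f"unknown quantity {quantity!r}")
        pre = _period_quantities(source, "pre", False)
        post = _period_quantities(source, "post", False)
        diff = post[quantity] - pre[quantity]
        level = interval_level
    else:
        pre = np.atleast_1d(np.asarray(source["pre"], dtype=float))
        post = np.atleast_1d(np.asarray(source["post"], dtype=float))
        if pre.shape != post.shape:
            raise IntegrityError("pre/post arrays have mismatched lengths")
        diff = post - pre
        level = interval_level
    return _summarize(diff, level)


def format_report(report: pd.DataFrame, digits: int = 2) -> str:
    """Fixed-width text rendering of an effect report."""
    lines = [f"{'quantity':38s} {'period':6s} {'est':>8s} {'interval':>18s} sig"]
    for _, row in report.iterrows():
        sig = "*" if row.get("significant") else " "
        interval = f"[{row['lower']:.{digits}f}, {row['upper']:.{digits}f}]" if \
            np.isfinite(row.get("lower", np.nan)) else ""
        lines.append(
            f"{row['quantity']:38s} {row['period']:6s} "
            f"{row['estimate']:8.{digits}f} {interval:>18s} {sig}"
        )
    return "\n".join(lines)
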