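"""Maximum Monthly Mean (MMM) climatology baseline.

The MMM is the long-term mean temperature of the climatologically hottest
month and is the reference against which daily HotSpots are measured.  It
can be supplied as a configured constant (which takes precedence) or
computed from a multi-year daily series by month-wise averaging.
"""

from __future__ import annotations

import logging

import pandas as pd

from .types import Climatology, ConfigError, InsufficientClimatologyError

log = logging.getLogger(__name__)


def compute_mmm(
    daily: pd.DataFrame,
    reference_period: tuple[int, int] | None = None,
) -> Climatology:
    """Compute the MMM from a daily summary series.

    ``monthly_means[m]`` is the mean of ``st_mean`` over every day falling
    in calendar month ``m`` within ``reference_period`` (inclusive year
    range; default: all years present); the MMM is the maximum of the 12
    monthly means.  Every calendar month must be represented by at least
    one day, otherwise :class:`InsufficientClimatologyError` is raised.
    """
    if daily.empty:
        raise InsufficientClimatologyError("empty daily series")
    df = daily
    if reference_period is not None:
        y0, y1 = reference_period
        df = df[(df["date"].dt.year >= y0) & (df["date"].dt.year <= y1)]
    by_month = df.groupby(df["date"].dt.month)["st_mean"].mean()
    missing = sorted(set(range(1, 13)) - set(by_month.index))
    if missing:
        raise InsufficientClimatologyError(
            f"calendar month(s) {missing} have no days in the reference period"
        )
    monthly = [float(by_month.loc[m]) for m in range(1, 13)]
    return Climatology(
        mmm_c=max(monthly),
        source="computed",
        reference_period=reference_period,
        monthly_means_c=monthly,
    )


def load_mmm(
    config: dict,
    daily: pd.DataFrame | None = None,
) -> Climatology:
    """Resolve the climatology from configuration.

    A numeric ``mmm_c`` key wins over a ``reference_period`` (logged if
    both are present); with only a reference period, the MMM is computed
    from ``daily``.  Anything else is a :class:`ConfigError`.
    """
    mmm = config.get("mmm_c")
    period = config.get("reference_period")
    if mmm is not None:
        if not isinstance(mmm, (int, float)) or isinstance(mmm, bool):
            raise ConfigError(f"climatology.mmm_c must be numeric, got {mmm!r}")
        if period is not None:
            log.info("configured mmm_c=%.3f takes precedence over reference_period", mmm)
        return Climatology(mmm_c=float(mmm), source="configured")
    if period is not None:
        if daily is None:
            raise ConfigError("reference_period given but no daily series to compute MMM from")
        return compute_mmm(daily, reference_period=(int(period[0]), int(period[1])))
    raise ConfigError("climatology config needs either mmm_c or reference_period")
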