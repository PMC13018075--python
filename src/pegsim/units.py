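"""Time-unit constants. Hours are the internal time unit everywhere."""

WEEK_H = 168.0          # weekly dosing interval, exact
YEAR_H = 8766.0         # 365.25 d
MONTH_H = YEAR_H / 12.0  # 730.5 h


def months_to_hours(months: float) -> float:
    return months * MONTH_H


def hours_to_years(hours: float):
    return hours / YEAR_H
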