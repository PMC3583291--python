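"""Time-unit conventions.

All kinetic rate constants are per second; all ages in the public API are
expressed in calendar years.  The conversion constant is a 365-day year.
"""

#: Seconds in one simulated calendar year (365 days).
YEAR_SECONDS: float = 3.1536e7


def years_to_seconds(years: float) -> float:
    return years * YEAR_SECONDS


def seconds_to_years(seconds: float) -> float:
    return seconds / YEAR_SECONDS
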