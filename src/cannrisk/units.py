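"""Single choke point for µg/day ↔ mg/day conversion.

All TTC limits are tabulated in µg/day while safety limits and exposures are
carried in mg/day; every crossing between the two scales goes through these
two functions so a silent 1000× error cannot creep in ad hoc.
"""

UG_PER_MG = 1000.0


def ug_per_day_to_mg_per_day(value_ug_per_day: float) -> float:
    return value_ug_per_day / UG_PER_MG


def mg_per_day_to_ug_per_day(value_mg_per_day: float) -> float:
    return value_mg_per_day * UG_PER_MG
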