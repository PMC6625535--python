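"""Brute-force transcription of the five plausibility rules.

Deliberately independent of the package: rules are written as literal
predicates over string-valued points, and the first-error choice is an
explicit argmin over (anchor, priority). Tests compare the rule engine
against this transcription over all 3^7 point assignments.
"""

import itertools

POINT_NAMES = ["diverted", "detained", "petitioned", "adjudicated", "probation", "confined", "waived"]
PRIORITY = [
    "INCONSISTENT_PETITION",
    "IMPLAUSIBLE_CASE",
    "EXCESS_INFORMATION",
    "INCONSISTENT_ADJUDICATION",
    "INCONSISTENT_WAIVER",
]


def oracle_fired(p):
    """Map rule name -> anchor position for one assignment (dict of tokens)."""
    fired = {}
    if p["diverted"] == "yes" and p["petitioned"] == "yes":
        fired["INCONSISTENT_PETITION"] = 3
    if p["diverted"] == "no" and p["petitioned"] == "no":
        fired["IMPLAUSIBLE_CASE"] = 3
    if p["diverted"] == "yes":
        offs = [pos for name, pos in
                (("adjudicated", 4), ("probation", 5), ("confined", 6), ("waived", 7))
                if p[name] == "yes"]
        if offs:
            fired["EXCESS_INFORMATION"] = min(offs)
    if p["waived"] == "yes":
        if any(p[n] == "yes" for n in ("adjudicated", "probation", "confined")):
            fired["INCONSISTENT_WAIVER"] = 7
    if p["adjudicated"] == "no":
        offs = [pos for name, pos in (("probation", 5), ("confined", 6)) if p[name] == "yes"]
        if offs:
            fired["INCONSISTENT_ADJUDICATION"] = min(offs)
    return fired


def oracle_first(p):
    fired = oracle_fired(p)
    if not fired:
        return None
    return min(fired, key=lambda rule: (fired[rule], PRIORITY.index(rule)))


def all_assignments():
    """All 3^7 = 2187 decision-point assignments."""
    for combo in itertools.product(["yes", "no", "missing"], repeat=7):
        yield dict(zip(POINT_NAMES, combo))
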