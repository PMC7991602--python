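"""Derived neurotologic measures and deficit classification.

Caloric asymmetry follows the Jongkees formula on the slow-phase
velocities of the four irrigations (30 degC and 44 degC, each ear); an
asymmetry above 35% defines vestibular paresis.  VEMP amplitude asymmetry
uses the (larger - smaller) / (larger + smaller) ratio.  The deficit
classification reconstructs the category columns of the association
tables: a cochlear deficit when any side's pure-tone average reaches the
hearing-loss threshold, a vestibular deficit when the caloric asymmetry,
any VEMP amplitude asymmetry, or the vHIT gain is abnormal; both together
make a vestibulocochlear deficit.  Laterality is the implicated side, or
bilateral when both sides are implicated.  VEMP latencies are recorded but
do not enter the classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import NeurotologyRecord

__all__ = [
    "CaloricResponses",
    "DeficitThresholds",
    "DeficitClassification",
    "caloric_asymmetry",
    "is_vestibular_paresis",
    "vemp_ar",
    "classify_deficits",
    "classify_record",
]


@dataclass
class CaloricResponses:
    """Slow-phase velocities (deg/s) of caloric nystagmus: right/left ear,
    30 degC cold and 44 degC warm irrigation."""

    r30: float
    r44: float
    l30: float
    l44: float

    def __post_init__(self) -> None:
        if min(self.r30, self.r44, self.l30, self.l44) < 0:
            raise ValueError("slow-phase velocities must be non-negative")


def caloric_asymmetry(c: CaloricResponses) -> float:
    """Jongkees caloric asymmetry in %, signed (positive favors right).

    100 * [(R30 + R44) - (L30 + L44)] / [(R30 + R44) + (L30 + L44)].
    """
    right = c.r30 + c.r44
    left = c.l30 + c.l44
    total = right + left
    if total == 0:
        raise ValueError("bilateral areflexia, AR undefined")
    return 100.0 * (right - left) / total


def is_vestibular_paresis(ar_pct: float) -> bool:
    """Vestibular paresis: asymmetry strictly above 35%."""
    if ar_pct < 0:
        raise ValueError("pass the absolute asymmetry ratio")
    return ar_pct > 35.0


def vemp_ar(larger: float, smaller: float) -> float:
    """VEMP amplitude asymmetry ratio in %: 100 (larger - smaller) / (sum)."""
    if not larger >= smaller >= 0:
        raise ValueError("expected larger >= smaller >= 0")
    if larger == 0:
        raise ValueError("both responses absent, AR undefined")
    return 100.0 * (larger - smaller) / (larger + smaller)


@dataclass
class DeficitThresholds:
    """Cut-offs for abnormality, each independently configurable."""

    caloric_ar_pct: float = 35.0  # abnormal when |AR| > this
    vemp_ar_pct: float = 40.0  # abnormal when amplitude AR >= this
    pta_db: float = 25.0  # cochlear deficit when PTA >= this
    vhit_gain_low: float = 0.80  # abnormal gain when below (2 SD reference band)


@dataclass
class DeficitClassification:
    category: str  # normal | vestibular | cochlear | vestibulocochlear
    laterality: str  # normal | right | left | bilateral

    def __post_init__(self) -> None:
        if (self.category == "normal") != (self.laterality == "normal"):
            raise ValueError("category 'normal' iff laterality 'normal'")


def _laterality(sides: set[str]) -> str:
    if not sides:
        return "normal"
    if sides == {"right"}:
        return "right"
    if sides == {"left"}:
        return "left"
    return "bilateral"


def classify_deficits(
    pta_r: float,
    pta_l: float,
    caloric: CaloricResponses,
    cvemp_amp_r: float,
    cvemp_amp_l: float,
    ovemp_amp_r: float,
    ovemp_amp_l: float,
    vhit_gain_r: float,
    vhit_gain_l: float,
    thresholds: DeficitThresholds | None = None,
) -> DeficitClassification:
    """Pure function from a complete scalar record to a deficit category."""
    th = thresholds or DeficitThresholds()
    missing = [
        name
        for name, v in (
            ("pta_r", pta_r), ("pta_l", pta_l),
            ("cvemp_amp_r", cvemp_amp_r), ("cvemp_amp_l", cvemp_amp_l),
            ("ovemp_amp_r", ovemp_amp_r), ("ovemp_amp_l", ovemp_amp_l),
            ("vhit_gain_r", vhit_gain_r), ("vhit_gain_l", vhit_gain_l),
        )
        if v is None or (isinstance(v, float) and np.isnan(v))
    ]
    if missing:
        raise ValueError(f"missing fields: {', '.join(missing)}")

    cochlear_sides = {s for s, pta in (("right", pta_r), ("left", pta_l)) if pta >= th.pta_db}

    vestibular_sides: set[str] = set()
    ar = caloric_asymmetry(caloric)
    if abs(ar) > th.caloric_ar_pct:
        # the weaker (deficit) side is the one with the smaller response
        vestibular_sides.add("left" if ar > 0 else "right")
    for amp_r, amp_l in ((cvemp_amp_r, cvemp_amp_l), (ovemp_amp_r, ovemp_amp_l)):
        larger, smaller = max(amp_r, amp_l), min(amp_r, amp_l)
        if larger > 0 and vemp_ar(larger, smaller) >= th.vemp_ar_pct:
            vestibular_sides.add("left" if amp_l < amp_r else "right")
    for side, gain in (("right", vhit_gain_r), ("left", vhit_gain_l)):
        if gain < th.vhit_gain_low:
            vestibular_sides.add(side)

    has_c, has_v = bool(cochlear_sides), bool(vestibular_sides)
    if has_c and has_v:
        category = "vestibulocochlear"
    elif has_c:
        category = "cochlear"
    elif has_v:
        category = "vestibular"
    else:
        category = "normal"
    return DeficitClassification(category, _laterality(cochlear_sides | vestibular_sides))


def classify_record(
    rec: NeurotologyRecord, thresholds: DeficitThresholds | None = None
) -> DeficitClassification:
    """Classify a cohort record."""
    return classify_deficits(
        rec.pta_r,
        rec.pta_l,
        CaloricResponses(rec.r30, rec.r44, rec.l30, rec.l44),
        rec.cvemp_p13_amp_r,
        rec.cvemp_p13_amp_l,
        rec.ovemp_n10_amp_r,
        rec.ovemp_n10_amp_l,
        rec.vhit_gain_r,
        rec.vhit_gain_l,
        thresholds,
    )
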