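"""Ionization-class assignment from reported pKa values.

A molecule is assigned one of four ionization classes — acid, basic,
neutral, zwitterion — from its strongest-acidic and strongest-basic pKa at
a reference environment pH. The molecule is taken to carry at least one
ionized acidic group when its strongest-acidic pKa is strictly below the
pH, and at least one ionized basic group when its strongest-basic pKa is
strictly above the pH. The class follows the truth table over those two
booleans: acid = acidic group only, basic = basic group only, neutral =
neither, zwitterion = both.

A missing pKa means the corresponding group is absent — no imputation from
structure is attempted. Boundary equality (pKa == pH) does not create a
group (strict inequalities).

Named pH presets cover different regions of the intestine: 6.0 (duodenum),
6.4 (caecum), 7.0 (descending colon, jejunum) and 7.4 (sigmoid, rectum,
ileum; the default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Mapping, Optional, Sequence

from .records import CompoundRecord

#: pH presets for intestinal regions.
PH_PRESETS: Mapping[str, float] = {
    "duodenum": 6.0,
    "caecum": 6.4,
    "descending_colon": 7.0,
    "jejunum": 7.0,
    "sigmoid": 7.4,
    "rectum": 7.4,
    "ileum": 7.4,
}

DEFAULT_PH = 7.4


class IonClass(str, Enum):
    ACID = "acid"
    BASIC = "basic"
    NEUTRAL = "neutral"
    ZWITTERION = "zwitterion"


@dataclass(frozen=True)
class IonizationCall:
    ion_class: IonClass
    ph: float
    has_acid_group: bool
    has_basic_group: bool


def assign_ionization_class(
    pka_acid: Optional[float], pka_base: Optional[float], ph: float = DEFAULT_PH
) -> IonizationCall:
    """Classify a molecule as acid/basic/neutral/zwitterion at ``ph``."""
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"ph must be in [0, 14], got {ph}")
    for name, v in (("pka_acid", pka_acid), ("pka_base", pka_base)):
        if v is not None and not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    has_acid = pka_acid is not None and pka_acid < ph
    has_base = pka_base is not None and pka_base > ph
    if has_acid and has_base:
        cls = IonClass.ZWITTERION
    elif has_acid:
        cls = IonClass.ACID
    elif has_base:
        cls = IonClass.BASIC
    else:
        cls = IonClass.NEUTRAL
    return IonizationCall(cls, ph, has_acid, has_base)


def ionization_distribution(
    records: Sequence[CompoundRecord],
    ph: float = DEFAULT_PH,
    *,
    group_by: Callable[[CompoundRecord], Optional[str]] = lambda r: r.compartment_set,
) -> dict[str, dict[IonClass, float]]:
    """Per-set proportions of the four ionization classes.

    ``group_by`` extracts the set label (default: compartment set). Records
    mapping to ``None`` are ignored; empty sets are omitted with a warning.
    Proportions within each returned set sum to 1.
    """
    counts: dict[str, dict[IonClass, int]] = {}
    for r in records:
        label = group_by(r)
        if label is None:
            continue
        call = assign_ionization_class(r.pka_strongest_acidic, r.pka_strongest_basic, ph)
        counts.setdefault(label, {c: 0 for c in IonClass})[call.ion_class] += 1
    out: dict[str, dict[IonClass, float]] = {}
    for label, c in counts.items():
        total = sum(c.values())
        if total == 0:
            warnings.warn(f"set {label!r} is empty; omitted from distribution")
            continue
        out[label] = {cls: n / total for cls, n in c.items()}
    return out
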