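"""Reversed oral-absorption rules as gut-permanence baselines.

The classical Lipinski rule-of-five and Veber rule describe molecules
likely to be orally absorbed. Read in reverse, a molecule that *violates*
them is predicted to remain in the gut lumen (a *Lingerer*, the positive
class here):

* reversed Lipinski: Lingerer iff two or more of {mw > 500 Da, logp > 5,
  hba > 10, hbd > 5};
* reversed Veber: Lingerer iff tpsa > 140 Å² or rb > 10.

All inequalities are strict; the thresholds are fixed baselines, not
calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

from .descriptors import DescriptorVector
from .set_assembly import LINGERER, TRAVERSER

#: Immutable default thresholds.
RULE_THRESHOLDS = MappingProxyType(
    {
        "lipinski": MappingProxyType(
            {"mw_gt": 500.0, "logp_gt": 5.0, "hba_gt": 10, "hbd_gt": 5, "min_violations": 2}
        ),
        "veber": MappingProxyType({"tpsa_gt": 140.0, "rb_gt": 10}),
    }
)


@dataclass(frozen=True)
class RuleCall:
    label: str  # Lingerer or Traverser
    violations: int


def reversed_lipinski(d: DescriptorVector) -> RuleCall:
    """Lingerer iff >= 2 Lipinski violations; also returns the violation count."""
    t = RULE_THRESHOLDS["lipinski"]
    violations = sum(
        (
            d.mw > t["mw_gt"],
            d.logp > t["logp_gt"],
            d.hba > t["hba_gt"],
            d.hbd > t["hbd_gt"],
        )
    )
    label = LINGERER if violations >= t["min_violations"] else TRAVERSER
    return RuleCall(label, violations)


def reversed_veber(d: DescriptorVector) -> RuleCall:
    """Lingerer iff tpsa > 140 or rb > 10."""
    t = RULE_THRESHOLDS["veber"]
    violations = int(d.tpsa > t["tpsa_gt"]) + int(d.rb > t["rb_gt"])
    label = LINGERER if violations >= 1 else TRAVERSER
    return RuleCall(label, violations)
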