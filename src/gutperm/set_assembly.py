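"""Assembly of the gut compound sets and permanence labels.

Deduplicated records are first partitioned into four compartment sets by
provenance and biospecimen flags: drug-set records form ``DrugBank``;
metabolites detected in both gut and serum form ``GutSerum``; gut-only
records form ``Gut``; serum-only records form ``Serum``.

"Fatty lipid" (FL) chemical classes — Glycerolipids, Glycerophospholipids,
Fatty acyls, Sphingolipids — are hydrolyzed by lipases in the gut lumen and
cannot cross the gut wall intact, so their presence in serum reflects de
novo synthesis rather than absorption. Every GutSerum record in an FL class
is therefore reassigned to Gut. The Gut set is then split into Gut-FL and
Gut-noFL by the same class list.

Finally the binary gut-permanence label is attached: records in DrugBank or
the updated GutSerum are *Traversers* (cross the gut wall), records in
Gut-FL or Gut-noFL are *Lingerers* (remain in the lumen; the positive class
for modeling). Serum-only records receive no permanence label and are
excluded from modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .records import CompoundRecord, Source

logger = logging.getLogger(__name__)

#: The four "fatty lipid" chemical classes.
FL_CLASSES = frozenset(
    {"Glycerolipids", "Glycerophospholipids", "Fatty acyls", "Sphingolipids"}
)

#: Closed chemical-class vocabulary (17 named classes + "Other").
CHEM_CLASSES = (
    "Benzenoids",
    "Endocannabinoids",
    "Fatty acyls",
    "Glycerolipids",
    "Glycerophospholipids",
    "Hydrocarbons",
    "Nucleosides, nucleotides, and analogues",
    "Organic acids and derivatives",
    "Organic nitrogen compounds",
    "Organic oxygen compounds",
    "Organoheterocyclic compounds",
    "Organosulfur compounds",
    "Phenylpropanoids and polyketides",
    "Prenol lipids",
    "Saccharolipids",
    "Sphingolipids",
    "Steroids and steroid derivatives",
    "Other",
)

GUT = "Gut"
GUT_SERUM = "GutSerum"
SERUM = "Serum"
DRUGBANK = "DrugBank"
TRAVERSER = "Traverser"
LINGERER = "Lingerer"


@dataclass
class AssemblyReport:
    """Bookkeeping from the assembly stages."""

    moved_fl: int = 0
    sizes: dict = field(default_factory=dict)
    n_rejected: int = 0


def coerce_chem_class(label: str) -> str:
    """Map a raw class label into the closed vocabulary (unknown -> "Other")."""
    if label in CHEM_CLASSES:
        return label
    logger.warning("unknown chemical class %r mapped to 'Other'", label)
    return "Other"


def assign_compartment_sets(
    records: Sequence[CompoundRecord], report: AssemblyReport | None = None
) -> list[CompoundRecord]:
    """Attach the compartment set to each record (in place); returns kept records.

    Metabolite records with neither biospecimen flag are rejected with a
    warning.
    """
    report = report if report is not None else AssemblyReport()
    kept = []
    for r in records:
        r.chem_class = coerce_chem_class(r.chem_class)
        if r.source is Source.DRUGBANK:
            r.compartment_set = DRUGBANK
        elif r.in_gut and r.in_serum:
            r.compartment_set = GUT_SERUM
        elif r.in_gut:
            r.compartment_set = GUT
        elif r.in_serum:
            r.compartment_set = SERUM
        else:
            logger.warning("record %s has no biospecimen flag; rejected", r.id)
            report.n_rejected += 1
            continue
        kept.append(r)
    _count_sizes(kept, report)
    return kept


def reassign_fl(
    records: Sequence[CompoundRecord], report: AssemblyReport | None = None
) -> AssemblyReport:
    """Move FL-class GutSerum records to Gut; returns the report with ``moved_fl``."""
    report = report if report is not None else AssemblyReport()
    moved = 0
    for r in records:
        if r.compartment_set == GUT_SERUM and r.chem_class in FL_CLASSES:
            r.compartment_set = GUT
            moved += 1
    report.moved_fl = moved
    _count_sizes(records, report)
    return report


def split_fl(records: Sequence[CompoundRecord]) -> None:
    """Set ``fl_flag`` on every record: True iff its class is a fatty-lipid class."""
    for r in records:
        r.fl_flag = r.chem_class in FL_CLASSES


def build_permanence_labels(records: Sequence[CompoundRecord]) -> None:
    """Attach Traverser/Lingerer labels; serum-only records stay unlabeled."""
    for r in records:
        if r.compartment_set in (DRUGBANK, GUT_SERUM):
            r.permanence_label = TRAVERSER
        elif r.compartment_set == GUT:
            r.permanence_label = LINGERER
        else:
            r.permanence_label = None


def assemble(
    records: Sequence[CompoundRecord],
) -> tuple[list[CompoundRecord], AssemblyReport]:
    """Run all assembly stages in order; idempotent on its own output."""
    report = AssemblyReport()
    kept = assign_compartment_sets(records, report)
    reassign_fl(kept, report)
    split_fl(kept)
    build_permanence_labels(kept)
    _count_sizes(kept, report)
    return kept, report


def _count_sizes(records: Sequence[CompoundRecord], report: AssemblyReport) -> None:
    sizes: dict[str, int] = {}
    for r in records:
        if r.compartment_set:
            sizes[r.compartment_set] = sizes.get(r.compartment_set, 0) + 1
        if r.compartment_set == GUT and r.fl_flag is not None:
            key = "Gut-FL" if r.fl_flag else "Gut-noFL"
            sizes[key] = sizes.get(key, 0) + 1
        if r.permanence_label:
            sizes[r.permanence_label] = sizes.get(r.permanence_label, 0) + 1
    report.sizes = sizes
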