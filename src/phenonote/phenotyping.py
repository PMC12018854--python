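"""Per-patient phenotype fusion of structured records and text extractions.

For each configured concept group (an antibody assay or a drug treatment,
identified by a set of codes) and each patient, two booleans are derived:

* structured hit — any structured record with a code in the group that is
  positive (labs: explicit interpretation flag when present, otherwise
  reference-range exceedance) or simply exists (drugs);
* unstructured hit — any retained text mention (certain and not negated)
  normalized to a group code that is positive (labs) or present (drugs).

The two booleans give a four-way provenance flag, and the cohort table
reports, per group, how many patients are evidenced by structured data, by
either source, and by text alone (the "benefit" of the unstructured data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .documents import (
    Entity,
    Measurement,
    StructuredDrugRecord,
    StructuredLabRecord,
)

logger = logging.getLogger(__name__)

FLAGS = ("absent", "structured_only", "unstructured_only", "both")


@dataclass(frozen=True)
class ConceptGroup:
    name: str
    kind: str  # lab | drug
    codes: frozenset[str]
    titer_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("lab", "drug"):
            raise ValueError(f"unknown group kind {self.kind!r}")
        if not self.codes:
            raise ValueError("concept group needs at least one code")


@dataclass
class PatientPhenotype:
    patient_id: str
    flags: dict[str, str]  # group name -> flag

    def __post_init__(self) -> None:
        for g, f in self.flags.items():
            if f not in FLAGS:
                raise ValueError(f"unknown flag {f!r} for group {g}")


def read_concept_groups(text: str) -> list[ConceptGroup]:
    """Parse a YAML group file::

        - name: antinuclear antibody
          kind: lab
          codes: [C0003243]
          titer_threshold: 80
    """
    raw = yaml.safe_load(text)
    groups = []
    for item in raw:
        groups.append(
            ConceptGroup(
                name=str(item["name"]),
                kind=str(item["kind"]),
                codes=frozenset(str(c) for c in item["codes"]),
                titer_threshold=(
                    float(item["titer_threshold"])
                    if item.get("titer_threshold") is not None
                    else None
                ),
            )
        )
    return groups


def write_concept_groups(groups: list[ConceptGroup]) -> str:
    return yaml.safe_dump(
        [
            {
                "name": g.name,
                "kind": g.kind,
                "codes": sorted(g.codes),
                **(
                    {"titer_threshold": g.titer_threshold}
                    if g.titer_threshold is not None
                    else {}
                ),
            }
            for g in groups
        ],
        sort_keys=False,
        allow_unicode=True,
    )


# ---------------------------------------------------------------------------
# filtering and positivity
# ---------------------------------------------------------------------------


def filter_entities(entities: Iterable[Entity]) -> list[Entity]:
    """Keep only entities explicitly qualified as certain and not negated.

    Lab entities are never qualified, so they pass with the default (keep)
    qualifiers; a drug_name entity without qualifiers means qualification
    was skipped upstream, which is a contract violation.
    """
    kept = []
    for ent in entities:
        if ent.label == "drug_name" and ent.qualifiers is None:
            raise ValueError(
                f"drug entity {ent.entity_id} is unqualified; run qualification first"
            )
        q = ent.effective_qualifiers()
        if q.certainty == "certain" and not q.negation:
            kept.append(ent)
    return kept


def lab_is_positive(
    m: Measurement, group: ConceptGroup, ref_high: Optional[float] = None
) -> bool:
    """Positivity of a lab result: explicit interpretation when qualitative,
    reference-range exceedance for numeric values, titer-threshold comparison
    for titers.  Numeric values with neither a reference nor a group
    threshold are conservatively non-positive."""
    if m.is_qualitative:
        return m.value == 1.0
    if m.unit == "titer" and group.titer_threshold is not None:
        return m.value >= group.titer_threshold
    if ref_high is not None:
        return m.value > ref_high
    return False


def structured_lab_is_positive(rec: StructuredLabRecord) -> bool:
    """Positivity of a structured lab row: the interpretation flag wins when
    present, otherwise upper-reference exceedance."""
    if rec.positive_flag is not None:
        return rec.positive_flag
    if rec.ref_high is not None:
        return rec.value > rec.ref_high
    return False


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _entity_code(ent: Entity) -> Optional[str]:
    if ent.concept is not None:
        return ent.concept.code
    values = ent.code_values()
    return values[0] if values else None


def aggregate_patients(
    structured_labs: list[StructuredLabRecord],
    structured_drugs: list[StructuredDrugRecord],
    entities_by_patient: Mapping[str, list[Entity]],
    groups: list[ConceptGroup],
    patient_ids: Optional[Iterable[str]] = None,
) -> list[PatientPhenotype]:
    """Fuse both sources into one provenance flag per patient per group.

    ``entities_by_patient`` must contain only retained (filtered) entities
    that already carry concept codes; lab entities additionally carry their
    measurement.  Entities without a code are skipped and counted in a
    diagnostics log.  The patient universe is the union of both sources
    unless ``patient_ids`` is given explicitly.
    """
    # reference ranges seen in the structured system, per (patient, code)
    ref_high: dict[tuple[str, str], float] = {}
    for rec in structured_labs:
        if rec.ref_high is not None:
            ref_high.setdefault((rec.patient_id, rec.concept_code), rec.ref_high)

    if patient_ids is None:
        universe = (
            {r.patient_id for r in structured_labs}
            | {r.patient_id for r in structured_drugs}
            | set(entities_by_patient)
        )
    else:
        universe = set(patient_ids)

    labs_by_patient: dict[str, list[StructuredLabRecord]] = {}
    for rec in structured_labs:
        labs_by_patient.setdefault(rec.patient_id, []).append(rec)
    drugs_by_patient: dict[str, list[StructuredDrugRecord]] = {}
    for rec in structured_drugs:
        drugs_by_patient.setdefault(rec.patient_id, []).append(rec)

    skipped = 0
    phenotypes = []
    for pid in sorted(universe):
        flags: dict[str, str] = {}
        for group in groups:
            structured_hit = False
            if group.kind == "lab":
                structured_hit = any(
                    rec.concept_code in group.codes and structured_lab_is_positive(rec)
                    for rec in labs_by_patient.get(pid, [])
                )
            else:
                structured_hit = any(
                    rec.atc_code in group.codes
                    for rec in drugs_by_patient.get(pid, [])
                )

            unstructured_hit = False
            for ent in entities_by_patient.get(pid, []):
                code = _entity_code(ent)
                if group.kind == "lab":
                    if ent.measurement is None:
                        continue
                    if code is None:
                        skipped += 1
                        continue
                    if code in group.codes and lab_is_positive(
                        ent.measurement, group, ref_high.get((pid, code))
                    ):
                        unstructured_hit = True
                        break
                else:
                    if ent.label != "drug_name":
                        continue
                    if code is None:
                        skipped += 1
                        continue
                    if code in group.codes:
                        unstructured_hit = True
                        break

            if structured_hit and unstructured_hit:
                flags[group.name] = "both"
            elif structured_hit:
                flags[group.name] = "structured_only"
            elif unstructured_hit:
                flags[group.name] = "unstructured_only"
            else:
                flags[group.name] = "absent"
        phenotypes.append(PatientPhenotype(pid, flags))
    if skipped:
        logger.info("aggregate_patients: %d uncoded entities skipped", skipped)
    return phenotypes


def cohort_table(
    phenotypes: list[PatientPhenotype],
    groups: list[ConceptGroup],
    cohort_size: int,
) -> pd.DataFrame:
    """Three-column benefit accounting per group.

    ``n_structured`` counts patients evidenced by structured data (alone or
    with text), ``n_combined`` adds text-only patients, and
    ``n_benefit = n_combined − n_structured`` is the contribution of the
    unstructured data.  Percentages are over the cohort size, two decimals.
    """
    rows = []
    for group in groups:
        flags = [p.flags[group.name] for p in phenotypes]
        n_structured = sum(f in ("structured_only", "both") for f in flags)
        n_unstructured_only = sum(f == "unstructured_only" for f in flags)
        n_combined = n_structured + n_unstructured_only
        if n_combined > cohort_size:
            raise ValueError(
                f"group {group.name}: {n_combined} positives exceed cohort size"
            )
        def pct(n: int) -> float:
            return round(100.0 * n / cohort_size, 2) if cohort_size else 0.0

        rows.append(
            {
                "group": group.name,
                "kind": group.kind,
                "n_structured": n_structured,
                "n_combined": n_combined,
                "n_benefit": n_unstructured_only,
                "cohort_size": cohort_size,
                "pct_structured": pct(n_structured),
                "pct_combined": pct(n_combined),
                "pct_benefit": pct(n_unstructured_only),
            }
        )
    return pd.DataFrame(rows)
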