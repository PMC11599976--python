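"""Typed model of the clinical cohort tables packaged with femur3d.

The package ships two delimited-text fixtures transcribed from the study
tables of a 41-dog / 47-limb patellar-luxation cohort:

* ``table1.tsv`` — per-dog demographics, preoperative lameness and the
  direction/grade of every luxated limb (including non-included
  contralateral low-grade limbs);
* ``table2.tsv`` — per-included-limb surgeries, follow-up, postoperative
  patellar position, lameness, outcome label and complications.

Cells holding several limb entries (e.g. ``R MPL 2/4;L MPL 1/4``) are
split into separate limb records.  A limb is *included* (one of the 47)
exactly when it has a row in table 2; for unilateral table-2 rows the
operated side is inferred from table 1 as the higher-grade luxation entry
(ties resolved by the lame side, then right).

Some counts printed in the study narrative do not equal a recount of its
own tables under any inclusion rule (luxation-grade distribution, the
acceptable-outcome count, the demographic medians).  Those claims are
*flagged* by :func:`discrepancies` rather than reproduced; summary counts
here are always honest recounts of the fixture rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import IncompleteRecordError, RecordParseError

SEVERITY_ORDER = {"none": 0, "minor": 1, "major": 2, "catastrophic": 3}

#: complication label -> severity class; recurrent patellar luxation was
#: the only major complication observed in the cohort
COMPLICATION_SEVERITY = {
    "Patellar luxation": "major",
    "Delayed bone union": "minor",
    "Periarticular fibrosis": "minor",
    "Kirschner wire migration": "minor",
    "Seroma": "minor",
    "Screw fracture": "minor",
    "Patellar tendon tendinitis": "minor",
    "Incisional seroma": "minor",
}


@dataclass
class DogRecord:
    case_id: int
    breed: str
    age_years: float
    body_weight_kg: float
    additional_diseases: list = field(default_factory=list)


@dataclass
class LimbRecord:
    case_id: int
    limb: str                      # "R" | "L"
    luxation_direction: str        # "MPL" | "LPL"
    luxation_grade: int            # 1..4
    preop_lameness: int | None
    included_in_47: bool
    laterality_of_case: str | None = None   # unilateral | bilateral
    surgeries: list = field(default_factory=list)
    followup_months: float | None = None
    postop_patella: str | None = None       # in_situ | MPL | LPL
    postop_lameness: int | None = None
    outcome_label: str | None = None        # full | acceptable | unacceptable
    complications: list = field(default_factory=list)  # (label, severity)


@dataclass
class CohortSummary:
    n_dogs: int
    n_limbs: int
    n_bilateral_cases: int
    direction_counts_raw: dict
    direction_counts_included: dict
    grade_counts_raw: dict
    grade_counts_included: dict
    breed_counts: dict
    surgery_counts: dict
    outcome_counts: dict
    complication_severity_counts: dict   # limbs with >= 1 of each severity
    age_median: float
    age_range: tuple
    weight_median: float
    weight_range: tuple

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# fixture parsing

_LUX_RE = re.compile(r"^([RL])\s+(MPL|LPL)\s+([1-4])/4$")
_LAME_RE = re.compile(r"^([RL])\s+([0-5])/5$")


def fixture_path(name: str):
    return resources.files("femur3d.data") / name


def _read_tsv(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    rows = [r + [""] * (len(header) - len(r)) for r in rows]
    return pd.DataFrame(rows, columns=header)


def load_fixture(table1=None, table2=None) -> tuple[list[DogRecord], list[LimbRecord]]:
    """Parse the packaged (or user-supplied) cohort tables.

    Returns (dogs, limbs) where ``limbs`` contains one record per luxation
    entry of table 1 — included limbs are enriched with table-2 data and
    carry ``included_in_47=True``.  Malformed rows raise
    :class:`RecordParseError` naming the case id.
    """
    t1 = _read_tsv(table1 or fixture_path("table1.tsv"))
    t2 = _read_tsv(table2 or fixture_path("table2.tsv"))

    dogs: list[DogRecord] = []
    limb_entries: dict[tuple[int, str], LimbRecord] = {}
    lameness_by_case: dict[int, dict[str, int]] = {}

    for _, row in t1.iterrows():
        raw_id = row["case_id"]
        try:
            case_id = int(raw_id)
        except ValueError:
            raise RecordParseError(raw_id, "non-integer case id")
        try:
            age = float(row["age_years"])
            weight = float(row["body_weight_kg"])
        except ValueError as exc:
            raise RecordParseError(case_id, f"bad numeric cell: {exc}")
        if age <= 0 or weight <= 0:
            raise RecordParseError(case_id, "age and weight must be positive")
        diseases = [d.strip() for d in row["additional_diseases"].split(";")
                    if d.strip()]
        dogs.append(DogRecord(case_id, row["breed"].strip(), age, weight,
                              diseases))

        lame = {}
        for cell in row["lameness"].split(";"):
            cell = cell.strip()
            if not cell:
                continue
            m = _LAME_RE.match(cell)
            if not m:
                raise RecordParseError(case_id, f"bad lameness cell {cell!r}")
            lame[m.group(1)] = int(m.group(2))
        lameness_by_case[case_id] = lame

        for cell in row["luxation"].split(";"):
            cell = cell.strip()
            if not cell:
                continue
            m = _LUX_RE.match(cell)
            if not m:
                raise RecordParseError(case_id, f"bad luxation cell {cell!r}")
            side, direction, grade = m.group(1), m.group(2), int(m.group(3))
            if (case_id, side) in limb_entries:
                raise RecordParseError(case_id, f"duplicate limb entry {side}")
            limb_entries[(case_id, side)] = LimbRecord(
                case_id=case_id, limb=side,
                luxation_direction=direction, luxation_grade=grade,
                preop_lameness=lame.get(side), included_in_47=False,
            )

    if len({d.case_id for d in dogs}) != len(dogs):
        raise RecordParseError("-", "duplicate case ids in table 1")

    # table 2: one row per included limb
    for _, row in t2.iterrows():
        try:
            case_id = int(row["case_id"])
        except ValueError:
            raise RecordParseError(row["case_id"], "non-integer case id")
        side = row["limb"].strip()
        entries = {s: rec for (c, s), rec in limb_entries.items()
                   if c == case_id}
        if not entries:
            raise RecordParseError(case_id, "table-2 row without table-1 limb")
        if side:
            if side not in entries:
                raise RecordParseError(case_id, f"no table-1 entry for limb {side}")
            rec = entries[side]
        else:
            # unilateral row: operated limb = highest-grade entry, ties by
            # the lame side, then right
            lame = lameness_by_case.get(case_id, {})
            rec = sorted(
                entries.values(),
                key=lambda r: (-r.luxation_grade,
                               -(lame.get(r.limb, -1)),
                               r.limb != "R"),
            )[0]
        if rec.included_in_47:
            raise RecordParseError(case_id, f"limb {rec.limb} listed twice in table 2")
        rec.included_in_47 = True
        rec.laterality_of_case = row["laterality"].strip() or None
        rec.surgeries = [s.strip() for s in row["surgeries"].split(";")
                         if s.strip()]
        fu = row["followup_months"].strip()
        rec.followup_months = float(fu) if fu else None
        patella = row["postop_patella"].strip()
        if patella:
            # revision rows record the final position after revision
            rec.postop_patella = patella.split("revision:")[-1].strip(";") \
                if "revision:" in patella else patella
        lame_post = row["postop_lameness"].strip()
        rec.postop_lameness = int(lame_post) if lame_post else None
        outcome = row["outcome"].strip()
        if outcome:
            if outcome not in ("full", "acceptable", "unacceptable"):
                raise RecordParseError(case_id, f"bad outcome {outcome!r}")
            rec.outcome_label = outcome
        comps = []
        for label in row["complications"].split(";"):
            label = label.strip()
            if not label:
                continue
            sev = COMPLICATION_SEVERITY.get(label)
            if sev is None:
                raise RecordParseError(case_id, f"unknown complication {label!r}")
            comps.append((label, sev))
        rec.complications = comps

    limbs = list(limb_entries.values())
    return dogs, limbs


# ---------------------------------------------------------------------------
# summaries


def _count(values) -> dict:
    out: dict = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return dict(sorted(out.items(), key=lambda kv: (-kv[1], str(kv[0]))))


def summarize(dogs: list[DogRecord], limbs: list[LimbRecord]) -> CohortSummary:
    """Deterministic descriptive counts over the cohort records.

    Direction and grade counts are offered both over all table-1 luxation
    entries (*raw*) and over the 47 included limbs only, because the two
    denominators genuinely differ for bilateral low-grade cases.
    """
    included = [r for r in limbs if r.included_in_47]
    bilateral_cases = {r.case_id for r in included
                       if r.laterality_of_case == "bilateral"}
    ages = sorted(d.age_years for d in dogs)
    weights = sorted(d.body_weight_kg for d in dogs)

    surgery_counts: dict = {}
    for r in included:
        for s in r.surgeries:
            key = s.split(":")[-1] if s.startswith("revision:") else s
            surgery_counts[key] = surgery_counts.get(key, 0) + 1

    sev_counts = {"minor": 0, "major": 0, "catastrophic": 0}
    for r in included:
        present = {sev for _, sev in r.complications}
        for sev in present:
            sev_counts[sev] += 1

    s_ages = pd.Series(ages)
    s_w = pd.Series(weights)
    return CohortSummary(
        n_dogs=len(dogs),
        n_limbs=len(included),
        n_bilateral_cases=len(bilateral_cases),
        direction_counts_raw=_count(r.luxation_direction for r in limbs),
        direction_counts_included=_count(
            r.luxation_direction for r in included),
        grade_counts_raw=_count(r.luxation_grade for r in limbs),
        grade_counts_included=_count(r.luxation_grade for r in included),
        breed_counts=_count(d.breed for d in dogs),
        surgery_counts=dict(sorted(surgery_counts.items(),
                                   key=lambda kv: (-kv[1], kv[0]))),
        outcome_counts=_count(r.outcome_label for r in included
                              if r.outcome_label is not None),
        complication_severity_counts=sev_counts,
        age_median=float(s_ages.median()),
        age_range=(float(s_ages.min()), float(s_ages.max())),
        weight_median=float(s_w.median()),
        weight_range=(float(s_w.min()), float(s_w.max())),
    )


def classify_outcome(postop_patella: str | None,
                     postop_lameness: int | None,
                     complications: list) -> str:
    """Re-derive the functional outcome label from the stated rule cascade.

    * full: patella in situ, lameness 0/5 or 1/5, complications at worst
      minor;
    * acceptable: patella in situ, lameness 1/5 or 2/5, complications at
      worst major;
    * unacceptable: otherwise (lameness >= 3/5, or a luxated patella with
      complications beyond the acceptable band).

    A limb with lameness 1/5 and at most minor complications satisfies
    both the full and the acceptable definition; the cascade returns
    ``full`` in that overlap.
    """
    if postop_patella is None or postop_lameness is None or complications is None:
        raise IncompleteRecordError(
            "postop_patella, postop_lameness and complications are all required"
        )
    worst = max((SEVERITY_ORDER[sev] for _, sev in complications), default=0)
    in_situ = postop_patella == "in_situ"
    if in_situ and postop_lameness <= 1 and worst <= SEVERITY_ORDER["minor"]:
        return "full"
    if in_situ and postop_lameness in (1, 2) and worst <= SEVERITY_ORDER["major"]:
        return "acceptable"
    return "unacceptable"


def recount_outcomes(limbs: list[LimbRecord]) -> list[dict]:
    """Apply :func:`classify_outcome` to every included limb with complete
    postoperative data and report rows whose stored label disagrees."""
    out = []
    for r in limbs:
        if not r.included_in_47 or r.outcome_label is None:
            continue
        if r.postop_patella is None or r.postop_lameness is None:
            continue
        derived = classify_outcome(r.postop_patella, r.postop_lameness,
                                   r.complications)
        if derived != r.outcome_label:
            out.append({
                "case_id": r.case_id, "limb": r.limb,
                "stored": r.outcome_label, "derived": derived,
            })
    return out


#: counts printed in the study narrative, checked against fixture recounts
PRINTED_CLAIMS = {
    "n_dogs": 41,
    "n_limbs": 47,
    "lpl_limbs": 9,
    "mpl_limbs": 38,
    "mixed_breed_dogs": 13,
    "grade_2_limbs": 18,
    "grade_3_limbs": 22,
    "grade_4_limbs": 7,
    "full_outcomes": 34,
    "acceptable_outcomes": 11,
    "unacceptable_outcomes": 2,
    "major_complication_limbs": 5,
    "minor_complication_limbs": 11,
    "age_median": 7.5,
    "weight_median": 13.8,
}


def discrepancies(dogs: list[DogRecord], limbs: list[LimbRecord]) -> list[dict]:
    """Printed cohort claims that do not match a recount of the tables.

    Each entry carries the claim name, the printed value and the recounted
    value(s); recounts are attempted against both the raw-entry and the
    included-only denominators, and a claim is flagged only when it
    matches neither.
    """
    s = summarize(dogs, limbs)
    checks = {
        "n_dogs": (s.n_dogs,),
        "n_limbs": (s.n_limbs,),
        "lpl_limbs": (s.direction_counts_raw.get("LPL", 0),
                      s.direction_counts_included.get("LPL", 0)),
        "mpl_limbs": (s.direction_counts_raw.get("MPL", 0),
                      s.direction_counts_included.get("MPL", 0)),
        "mixed_breed_dogs": (s.breed_counts.get("Mixed-breed", 0),),
        "grade_2_limbs": (s.grade_counts_raw.get(2, 0),
                          s.grade_counts_included.get(2, 0)),
        "grade_3_limbs": (s.grade_counts_raw.get(3, 0),
                          s.grade_counts_included.get(3, 0)),
        "grade_4_limbs": (s.grade_counts_raw.get(4, 0),
                          s.grade_counts_included.get(4, 0)),
        "full_outcomes": (s.outcome_counts.get("full", 0),),
        "acceptable_outcomes": (s.outcome_counts.get("acceptable", 0),),
        "unacceptable_outcomes": (s.outcome_counts.get("unacceptable", 0),),
        "major_complication_limbs": (
            s.complication_severity_counts["major"],),
        "minor_complication_limbs": (
            s.complication_severity_counts["minor"],),
        "age_median": (s.age_median,),
        "weight_median": (s.weight_median,),
    }
    flagged = []
    for name, recounts in checks.items():
        printed = PRINTED_CLAIMS[name]
        if printed not in recounts:
            flagged.append({
                "claim": name,
                "printed": printed,
                "recounted": list(recounts),
            })
    return flagged
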