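"""Rule-based surgical planning from measured femoral angles.

Physiological bands used in veterinary patellar-luxation planning:

* aLDFA strictly between 90 and 102 degrees is normal-to-mild; values at
  or outside the band indicate frontal malalignment and trigger a distal
  femoral osteotomy (DFO) recommendation.
* FTA between 18 and 35 degrees (inclusive) is physiological; torsion
  below 18 or above 35 degrees triggers a femoral detorsional osteotomy
  (FDO) recommendation.
* FNA has no published decision threshold and is carried through reports
  without gating any recommendation.

When neither band is violated, traditional techniques (trochleoplasty,
tibial tuberosity transposition, fascia imbrication) are considered
sufficient.  Correction magnitudes are reported as measured minus a
configurable target (band midpoints by default; a ``paper-postop``
profile presets the achieved post-operative means instead).  Cases within
2 degrees of any band edge carry a ``borderline`` annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

BORDERLINE_MARGIN = 2.0  # degrees


@dataclass(frozen=True)
class PlannerConfig:
    """Decision bands and correction targets (degrees)."""

    aldfa_low: float = 90.0
    aldfa_high: float = 102.0
    fta_low: float = 18.0
    fta_high: float = 35.0
    target_aLDFA: float = 96.0
    target_FTA: float = 26.5

    def __post_init__(self):
        if not (self.aldfa_low < self.target_aLDFA < self.aldfa_high):
            raise ValueError("require aldfa_low < target_aLDFA < aldfa_high")
        if not (self.fta_low < self.target_FTA < self.fta_high):
            raise ValueError("require fta_low < target_FTA < fta_high")

    @classmethod
    def profile(cls, name: str) -> "PlannerConfig":
        """Named presets: ``default`` (band midpoints) or ``paper-postop``
        (achieved post-operative cohort means as correction targets)."""
        if name == "default":
            return cls()
        if name == "paper-postop":
            return cls(target_aLDFA=94.6, target_FTA=25.7)
        raise ValueError(f"unknown planner profile {name!r}")


@dataclass
class SurgicalRecommendation:
    """Per-limb planning decision with rule provenance."""

    frontal_osteotomy: bool           # DFO
    torsional_osteotomy: bool         # FDO
    traditional_only: bool
    frontal_correction: float         # degrees, measured - target; 0 if no DFO
    torsional_correction: float       # degrees, measured - target; 0 if no FDO
    rationale: list = field(default_factory=list)
    borderline: bool = False

    @property
    def any_osteotomy(self) -> bool:
        return self.frontal_osteotomy or self.torsional_osteotomy

    def to_dict(self) -> dict:
        return {
            "DFO": self.frontal_osteotomy,
            "FDO": self.torsional_osteotomy,
            "traditional_only": self.traditional_only,
            "frontal_correction": round(self.frontal_correction, 2),
            "torsional_correction": round(self.torsional_correction, 2),
            "rationale": list(self.rationale),
            "borderline": self.borderline,
        }


def classify(aldfa: float, fta: float,
             cfg: PlannerConfig | None = None) -> SurgicalRecommendation:
    """Classify a measured (aLDFA, FTA) pair against the decision bands.

    Band semantics follow the clinical rules exactly: the aLDFA band is
    exclusive (pathologic when aLDFA < low or > high, and also flagged at
    the boundary values since 'normal' requires strict inequality), the
    FTA band is inclusive (pathologic strictly below low or above high).
    A pure function: identical inputs give identical outputs.
    """
    cfg = cfg or PlannerConfig()
    rationale = []

    # normal frontal alignment requires aldfa_low < aLDFA < aldfa_high
    dfo = not (cfg.aldfa_low < aldfa < cfg.aldfa_high)
    if dfo:
        side = "valgus" if aldfa <= cfg.aldfa_low else "varus"
        rationale.append(
            f"aLDFA {aldfa:.1f} outside ({cfg.aldfa_low:g}, "
            f"{cfg.aldfa_high:g}) [{side}]"
        )

    # physiological torsion is fta_low <= FTA <= fta_high
    fdo = fta < cfg.fta_low or fta > cfg.fta_high
    if fdo:
        kind = "retrotorsion" if fta < cfg.fta_low else "excessive antetorsion"
        rationale.append(
            f"FTA {fta:.1f} outside [{cfg.fta_low:g}, {cfg.fta_high:g}] "
            f"[{kind}]"
        )

    borderline = (
        min(abs(aldfa - cfg.aldfa_low), abs(aldfa - cfg.aldfa_high))
        <= BORDERLINE_MARGIN
        or min(abs(fta - cfg.fta_low), abs(fta - cfg.fta_high))
        <= BORDERLINE_MARGIN
    )
    if borderline:
        rationale.append("within 2 deg of a band edge (borderline)")

    return SurgicalRecommendation(
        frontal_osteotomy=dfo,
        torsional_osteotomy=fdo,
        traditional_only=not (dfo or fdo),
        frontal_correction=(aldfa - cfg.target_aLDFA) if dfo else 0.0,
        torsional_correction=(fta - cfg.target_FTA) if fdo else 0.0,
        rationale=rationale,
        borderline=borderline,
    )


def batch_plan(measurements, cfg: PlannerConfig | None = None) -> pd.DataFrame:
    """Plan a batch of measurements.

    ``measurements`` is an iterable of mappings with at least ``aLDFA``
    and ``FTA`` keys (extra keys such as ``label`` or ``FNA`` are carried
    through).  Returns a DataFrame with one row per limb; the number of
    limbs flagged for any osteotomy is available as
    ``df["any_osteotomy"].sum()``.
    """
    cfg = cfg or PlannerConfig()
    rows = []
    for m in measurements:
        rec = classify(float(m["aLDFA"]), float(m["FTA"]), cfg)
        row = {k: m[k] for k in m}
        row.update(rec.to_dict())
        row["any_osteotomy"] = rec.any_osteotomy
        rows.append(row)
    columns = ["label", "aLDFA", "FNA", "FTA", "DFO", "FDO",
               "traditional_only", "any_osteotomy", "frontal_correction",
               "torsional_correction", "borderline", "rationale"]
    df = pd.DataFrame(rows)
    if len(df):
        df = df[[c for c in columns if c in df.columns]
                + [c for c in df.columns if c not in columns]]
    return df
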