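"""In vivo dose bookkeeping: minimal effective doses, therapeutic windows,
conditioned-place-preference scores.

The therapeutic window of an analgesic is the ratio of the smallest dose
producing a side-effect phenotype (catalepsy, sedation, hypolocomotion) to
the smallest dose producing the analgesic phenotype.  Significance flags
are *inputs* here — they come from the primary statistics of the behavioral
study (ANOVA + post-hoc), which this module deliberately does not redo.
When a side effect never reaches significance up to the highest tested
dose, the window is reported as a lower bound ("> max tested / min
analgesic"), kept distinct from point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorError",
    "CPPRecord",
    "DoseOutcomeTable",
    "WindowResult",
    "cpp_score",
    "min_effective_dose",
    "therapeutic_window",
    "window_matrix",
]


class BehaviorError(ValueError):
    pass


@dataclass
class DoseOutcomeTable:
    """Rows of (assay, phenotype_class, dose, significant_vs_control)."""

    rows: pd.DataFrame

    REQUIRED = ("assay", "phenotype_class", "dose_mg_kg", "significant")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise BehaviorError(f"dose-outcome table missing columns: {sorted(missing)}")
        if (self.rows["dose_mg_kg"] <= 0).any():
            raise BehaviorError("doses must be positive")
        bad = set(self.rows["phenotype_class"]) - {"analgesic", "side_effect"}
        if bad:
            raise BehaviorError(f"unknown phenotype classes: {sorted(bad)}")

    @classmethod
    def from_records(cls, records) -> "DoseOutcomeTable":
        return cls(pd.DataFrame.from_records(records, columns=cls.REQUIRED))

    def assays(self) -> list[str]:
        return sorted(self.rows["assay"].unique())

    def phenotype_of(self, assay: str) -> str:
        sub = self.rows[self.rows["assay"] == assay]
        if sub.empty:
            raise BehaviorError(f"unknown assay {assay!r}")
        return sub["phenotype_class"].iloc[0]


def min_effective_dose(table: DoseOutcomeTable, assay: str) -> float | None:
    """Smallest dose flagged significant vs control; None when none is."""
    sub = table.rows[table.rows["assay"] == assay]
    if sub.empty:
        raise BehaviorError(f"unknown assay {assay!r}")
    sig = sub[sub["significant"].astype(bool)]
    if sig.empty:
        return None
    return float(sig["dose_mg_kg"].min())


@dataclass
class WindowResult:
    """A therapeutic window: a point value, a lower bound, or undefined."""

    analgesic_assay: str
    side_effect_assay: str
    value: float | None
    kind: str  # "point" | "lower_bound" | "undefined"
    detail: str = ""

    def __str__(self):
        if self.kind == "point":
            return f"{self.value:g}"
        if self.kind == "lower_bound":
            return f"> {self.value:g}"
        return f"undefined ({self.detail})"


def therapeutic_window(
    table: DoseOutcomeTable,
    analgesic_assay: str,
    side_effect_assay: str,
) -> WindowResult:
    """Min side-effect dose over min analgesic dose.

    If the side-effect assay never reaches significance, the highest dose
    actually tested bounds the window from below.  Without a significant
    analgesic dose no window exists.
    """
    med_analg = min_effective_dose(table, analgesic_assay)
    med_side = min_effective_dose(table, side_effect_assay)
    if med_analg is None:
        return WindowResult(analgesic_assay, side_effect_assay, None, "undefined",
                            detail="no significant analgesic dose")
    if med_side is None:
        top = float(
            table.rows.loc[table.rows["assay"] == side_effect_assay, "dose_mg_kg"].max()
        )
        return WindowResult(
            analgesic_assay, side_effect_assay, top / med_analg, "lower_bound",
            detail=f"side effect not significant up to {top:g} mg/kg",
        )
    return WindowResult(analgesic_assay, side_effect_assay, med_side / med_analg,
                        "point")


def window_matrix(table: DoseOutcomeTable) -> pd.DataFrame:
    """Window for every (analgesic assay x side-effect assay) pair.

    Lets any stated pair be recovered without guessing which one a summary
    number referred to.  Cells hold the window's string form ("20", "> 5",
    "undefined (...)").
    """
    analgesic = [a for a in table.assays() if table.phenotype_of(a) == "analgesic"]
    side = [a for a in table.assays() if table.phenotype_of(a) == "side_effect"]
    mat = pd.DataFrame(index=analgesic, columns=side, dtype=object)
    for a in analgesic:
        for s in side:
            mat.loc[a, s] = str(therapeutic_window(table, a, s))
    mat.index.name = "analgesic_assay"
    mat.columns.name = "side_effect_assay"
    return mat


@dataclass
class CPPRecord:
    """Per-chamber occupancy times (s) on test and pretest days."""

    time_in_chamber_test: dict[str, float]
    time_in_chamber_pretest: dict[str, float]

    def __post_init__(self):
        for d in (self.time_in_chamber_test, self.time_in_chamber_pretest):
            if any(v < 0 for v in d.values()):
                raise BehaviorError("chamber times must be >= 0")


def cpp_score(r: CPPRecord) -> dict[str, float]:
    """CPP score per chamber: test-day time minus pretest-day time."""
    if set(r.time_in_chamber_test) != set(r.time_in_chamber_pretest):
        raise BehaviorError(
            "chamber mismatch between test and pretest: "
            f"{sorted(r.time_in_chamber_test)} vs {sorted(r.time_in_chamber_pretest)}"
        )
    return {
        ch: r.time_in_chamber_test[ch] - r.time_in_chamber_pretest[ch]
        for ch in sorted(r.time_in_chamber_test)
    }
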