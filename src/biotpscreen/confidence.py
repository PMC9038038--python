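"""Schymanski confidence-level assignment and the final report table.

The evidence collected for each surviving suspect is mapped onto the
Schymanski scale:

* CL 1 — confirmed structure: MS2 match to an authentic reference standard
  (similarity >= threshold, default 0.90, *at* threshold counts) with a
  matching retention time.
* CL 2 — probable structure: library / in-silico spectral match at threshold
  without a standard.
* CL 3–4 — tentative candidate to unequivocal formula: MS2 present with
  consistent but partial evidence (fragment annotations or sub-threshold
  similarity).
* CL 5 — exact mass of interest only (no usable MS2).

Detection in the dosing medium or an in-source-fragment flag marks the
assignment tentative: the structure is reported in parentheses, whatever the
level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["EvidenceBundle", "ConfidenceAssignment", "assign_confidence", "render_report"]

_LEVEL_ORDER = {"1": 1, "2": 2, "2-3": 2.5, "3": 3, "3-4": 3.5, "4": 4, "5": 5}


class EvidenceError(ValueError):
    """Internally contradictory evidence bundle."""


@dataclass(frozen=True)
class EvidenceBundle:
    """Everything known about one suspect when the level is assigned.

    Optional fields are None iff the corresponding evidence was never
    collected (no standard run, no library hit, ...).
    """

    name: str
    has_ms2: bool = False
    similarity_to_standard: float | None = None
    rt_delta_to_standard_min: float | None = None
    similarity_to_library_or_insilico: float | None = None
    fish_fraction: float | None = None
    in_dosing_medium: bool = False
    in_source_flag: bool = False

    def __post_init__(self) -> None:
        if self.similarity_to_standard is not None and not self.has_ms2:
            raise EvidenceError(
                f"{self.name}: a standard similarity score requires MS2 data"
            )
        if self.similarity_to_library_or_insilico is not None and not self.has_ms2:
            raise EvidenceError(
                f"{self.name}: a library/in-silico similarity score requires MS2 data"
            )


@dataclass(frozen=True)
class ConfidenceAssignment:
    level: str  # "1", "2", "3-4", "5", ...
    rationale: tuple[str, ...] = ()
    tentative: bool = False

    @property
    def numeric_level(self) -> float:
        return _LEVEL_ORDER[self.level]


def assign_confidence(
    e: EvidenceBundle,
    sim_threshold: float = 0.90,
    rt_window_min: float = 0.1,
) -> ConfidenceAssignment:
    """Map an evidence bundle to a confidence level.

    Rules fire in order; similarity exactly at the threshold counts as a
    match.  Strengthening the evidence can only improve (never worsen) the
    level.
    """
    rationale: list[str] = []
    level: str

    std_ok = (
        e.similarity_to_standard is not None
        and e.similarity_to_standard >= sim_threshold
        and e.rt_delta_to_standard_min is not None
        and abs(e.rt_delta_to_standard_min) <= rt_window_min
    )
    lib_ok = (
        e.similarity_to_library_or_insilico is not None
        and e.similarity_to_library_or_insilico >= sim_threshold
    )
    partial = e.has_ms2 and (
        (e.fish_fraction is not None and e.fish_fraction > 0)
        or (e.similarity_to_standard is not None)
        or (e.similarity_to_library_or_insilico is not None)
    )

    if std_ok:
        level = "1"
        rationale.append(
            f"standard MS2 match (similarity {e.similarity_to_standard:.3f} >= "
            f"{sim_threshold:g}) with RT delta "
            f"{abs(e.rt_delta_to_standard_min):.3f} min <= {rt_window_min:g}"
        )
    elif lib_ok:
        level = "2"
        rationale.append(
            f"library/in-silico MS2 match (similarity "
            f"{e.similarity_to_library_or_insilico:.3f} >= {sim_threshold:g})"
        )
    elif partial:
        level = "3-4"
        if e.fish_fraction is not None and e.fish_fraction > 0:
            rationale.append(
                f"partial fragment annotation ({100 * e.fish_fraction:.0f}% of peaks)"
            )
        else:
            rationale.append("MS2 present but similarity below threshold")
    elif e.has_ms2:
        level = "3-4"
        rationale.append("MS2 acquired but no candidate evidence scored")
    else:
        level = "5"
        rationale.append("exact-mass suspect match only; no MS2 spectra")

    tentative = e.in_dosing_medium or e.in_source_flag
    if e.in_dosing_medium:
        rationale.append("also detected in dosing medium: reported tentative")
    if e.in_source_flag:
        rationale.append("possible in-source fragment of the parent: reported tentative")
    return ConfidenceAssignment(
        level=level, rationale=tuple(rationale), tentative=tentative
    )


@dataclass
class ReportRow:
    name: str
    formula: str
    exact_mass: float
    rt_min: float
    dppm: float
    similarity: float | None
    datasets: str
    level: str
    tentative: bool
    comment: str = ""


def render_report(
    rows: Sequence[ReportRow],
) -> tuple[pd.DataFrame, str]:
    """Final identification table: one row per (tentatively) identified
    bioTP, sorted by confidence level then mass.  The dPPM column is the
    magnitude of the measured-vs-theoretical deviation.  Returns the
    machine-readable frame and a human-readable rendering."""
    recs = []
    for r in rows:
        recs.append(
            {
                "bioTP": f"({r.name})" if r.tentative else r.name,
                "formula": r.formula,
                "exact_mass": round(r.exact_mass, 5),
                "rt_min": round(r.rt_min, 3),
                "dPPM": round(abs(r.dppm), 2),
                "similarity": "" if r.similarity is None else round(r.similarity, 3),
                "datasets": r.datasets,
                "CL": r.level,
                "comment": r.comment,
            }
        )
    df = pd.DataFrame(
        recs,
        columns=[
            "bioTP",
            "formula",
            "exact_mass",
            "rt_min",
            "dPPM",
            "similarity",
            "datasets",
            "CL",
            "comment",
        ],
    )
    if len(df):
        df = df.sort_values(
            by=["CL", "exact_mass"],
            key=lambda col: col.map(_LEVEL_ORDER) if col.name == "CL" else col,
            kind="stable",
        ).reset_index(drop=True)
    text = df.to_string(index=False) if len(df) else "(no bioTPs identified)"
    return df, text
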