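"""The prioritization funnel: suspect matching and the two blank filters.

Stages, applied to a feature table after replicate exclusion:

1. *suspect* — ppm-match feature neutral masses against the expected-bioTP
   mass list from :mod:`.transform_rules`.
2. *filter 1 (control presence)* — remove features detected in more than one
   sample to which no test compound was added (negative + positive controls).
   The limit of one tolerates noise in a single control sample.
3. *filter 2 (enrichment factor)* — EF = mean area in the highest-dose group
   over mean area in negative controls (non-detect = 0 on both sides); features
   with EF <= 10 are removed.  A blank control denominator with signal in the
   top dose gives EF = +inf (retained); all-zero features give EF = 0.

An in-source-fragment flag demotes suspects that co-elute with the parent
compound and match a known fragment mass; they are retained but reported as
tentative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_model import FeatureTable, SampleSheet
from .transform_rules import PredictedBioTP

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningParams",
    "SuspectHit",
    "ScreeningResult",
    "ScreeningOutcome",
    "exclude_replicates",
    "match_suspects",
    "control_detect_counts",
    "filter_controls",
    "enrichment_factor",
    "enrichment_factors",
    "flag_in_source_fragments",
    "screen",
]

FUNNEL_STAGES = ("raw", "suspect", "post_filter1", "post_filter2")


@dataclass(frozen=True)
class ScreeningParams:
    tol_ppm: float = 5.0          # suspect-match tolerance
    presence_threshold: float = 0.0  # area > threshold counts as a signal
    max_control_detects: int = 1  # filter 1: "more than 1 sample" rule
    ef_cutoff: float = 10.0       # filter 2: EF <= cutoff removed
    rt_window_min: float = 0.2    # co-elution window for in-source flagging


@dataclass(frozen=True)
class SuspectHit:
    """One (feature, predicted product) ppm match."""

    feature_id: str
    product_formula: str
    predicted_mass: float
    feature_mass: float
    ppm_error: float
    rule_chains: tuple[tuple[str, ...], ...]
    ambiguous: bool = False
    in_source_fragment: bool = False

    @property
    def best_rule_chain(self) -> tuple[str, ...]:
        return min(self.rule_chains, key=lambda c: (len(c), c))


@dataclass(frozen=True)
class ScreeningResult:
    """Per-feature filter trail."""

    feature_id: str
    is_suspect: bool
    control_detect_count: int
    passed_filter1: bool
    ef: float
    passed_filter2: bool
    funnel_stage: str
    in_source_fragment: bool = False


@dataclass
class ScreeningOutcome:
    results: list[ScreeningResult]
    hits: list[SuspectHit]
    funnel: dict[str, int]
    surviving_counts: dict[str, int] = field(default_factory=dict)

    def survivors(self) -> list[str]:
        return [r.feature_id for r in self.results if r.funnel_stage == "post_filter2"]

    def hits_for(self, feature_id: str) -> list[SuspectHit]:
        return [h for h in self.hits if h.feature_id == feature_id]

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_id": r.feature_id,
                    "is_suspect": r.is_suspect,
                    "control_detect_count": r.control_detect_count,
                    "passed_filter1": r.passed_filter1,
                    "EF": r.ef,
                    "passed_filter2": r.passed_filter2,
                    "funnel_stage": r.funnel_stage,
                    "in_source_fragment": r.in_source_fragment,
                }
                for r in self.results
            ]
        )


def exclude_replicates(
    table: FeatureTable, metadata: SampleSheet
) -> tuple[FeatureTable, dict[float, int]]:
    """Drop all areas of samples flagged excluded (lethal / severe
    morphological endpoints).  Returns the reduced table and surviving
    replicate counts per dose group."""
    excluded = [s.sample_id for s in metadata if s.excluded]
    surviving: dict[float, int] = {}
    for s in metadata:
        if s.group == "dose" and not s.excluded:
            surviving[s.dose] = surviving.get(s.dose, 0) + 1
    for dose in metadata.doses():
        if surviving.get(dose, 0) == 0:
            logger.warning(
                "all replicates excluded in dose group %g; group absent downstream",
                dose,
            )
    out = table.drop_samples(excluded) if excluded else table
    return out, surviving


def match_suspects(
    table: FeatureTable,
    predicted: Sequence[PredictedBioTP],
    tol_ppm: float,
) -> list[SuspectHit]:
    """ppm-match every feature mass against every predicted product mass.

    A feature may match several predictions; all matches are kept and flagged
    ambiguous.  Deterministic order: (feature_id, predicted mass).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if not predicted:
        return []
    pred_masses = np.array([p.neutral_mass for p in predicted])
    feat_masses = table.meta["neutral_mass"].to_numpy()
    # ppm relative to the predicted (theoretical) mass
    ppm = 1e6 * (feat_masses[:, None] - pred_masses[None, :]) / pred_masses[None, :]
    fi, pi = np.nonzero(np.abs(ppm) <= tol_ppm)
    ids = table.meta.index
    n_matches = np.bincount(fi, minlength=len(ids))
    hits = [
        SuspectHit(
            feature_id=str(ids[f]),
            product_formula=predicted[p].product_formula.hill(),
            predicted_mass=predicted[p].neutral_mass,
            feature_mass=float(feat_masses[f]),
            ppm_error=float(ppm[f, p]),
            rule_chains=predicted[p].rule_chains,
            ambiguous=bool(n_matches[f] > 1),
        )
        for f, p in zip(fi, pi)
    ]
    hits.sort(key=lambda h: (h.feature_id, h.predicted_mass))
    return hits


def control_detect_counts(
    table: FeatureTable, metadata: SampleSheet, presence_threshold: float = 0.0
) -> pd.Series:
    """Number of non-excluded control samples (negative + positive) in which
    each feature produced a signal (area > threshold)."""
    controls = [c for c in metadata.control_ids() if c in table.areas.columns]
    if not metadata.control_ids(include_excluded=True):
        raise ValueError("sample metadata contains no control samples")
    sub = table.areas[controls]
    return (sub > presence_threshold).sum(axis=1).astype(int)


def filter_controls(
    feature_areas: pd.Series | dict,
    metadata: SampleSheet,
    presence_threshold: float = 0.0,
    max_control_detects: int = 1,
) -> tuple[int, bool]:
    """Filter 1 for one feature: (control detect count, passed)."""
    if not metadata.control_ids(include_excluded=True):
        raise ValueError("sample metadata contains no control samples")
    areas = dict(feature_areas)
    count = sum(
        1
        for c in metadata.control_ids()
        if areas.get(c) is not None
        and not pd.isna(areas.get(c))
        and areas[c] > presence_threshold
    )
    return count, count <= max_control_detects


def enrichment_factors(table: FeatureTable, metadata: SampleSheet) -> pd.Series:
    """Filter 2 statistic for every feature (vectorized).

    EF = mean(highest-dose areas) / mean(negative-control areas); non-detects
    count as 0 in both means over non-excluded replicates.  Blank denominator
    with positive numerator -> +inf; both zero -> 0.
    """
    top = metadata.highest_dose
    top_ids = [
        s for s in metadata.ids(("dose",), dose=top) if s in table.areas.columns
    ]
    neg_ids = [
        s for s in metadata.ids(("negative_control",)) if s in table.areas.columns
    ]
    if not top_ids:
        logger.warning("no highest-dose samples remain; EF undefined (set to NaN)")
        return pd.Series(np.nan, index=table.areas.index)
    num = table.areas[top_ids].fillna(0.0).mean(axis=1).to_numpy()
    den = (
        table.areas[neg_ids].fillna(0.0).mean(axis=1).to_numpy()
        if neg_ids
        else np.zeros(len(table))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = num / den
    ef[(den == 0) & (num > 0)] = np.inf
    ef[(den == 0) & (num == 0)] = 0.0
    return pd.Series(ef, index=table.areas.index)


def enrichment_factor(
    feature_areas: pd.Series | dict, metadata: SampleSheet
) -> float:
    """EF for a single feature (see :func:`enrichment_factors`)."""
    areas = {k: v for k, v in dict(feature_areas).items() if not pd.isna(v)}
    top = metadata.highest_dose
    top_ids = metadata.ids(("dose",), dose=top)
    neg_ids = metadata.ids(("negative_control",))
    if not top_ids:
        raise ValueError("no non-excluded highest-dose samples; EF undefined")
    num = np.mean([areas.get(s, 0.0) for s in top_ids])
    den = np.mean([areas.get(s, 0.0) for s in neg_ids]) if neg_ids else 0.0
    if den == 0:
        return np.inf if num > 0 else 0.0
    return float(num / den)


def flag_in_source_fragments(
    hits: Sequence[SuspectHit],
    table: FeatureTable,
    parent_rt_min: float,
    known_fragment_masses: Sequence[float],
    rt_window_min: float = 0.2,
    tol_ppm: float = 5.0,
) -> list[SuspectHit]:
    """Flag hits that co-elute with the parent compound AND match a supplied
    in-source fragment mass; flagged hits are retained but demoted."""
    if not known_fragment_masses:
        return list(hits)
    frags = np.asarray(known_fragment_masses, dtype=float)
    out = []
    for h in hits:
        rt = float(table.meta.loc[h.feature_id, "rt_min"])
        coelutes = abs(rt - parent_rt_min) <= rt_window_min
        matches = np.any(
            np.abs(1e6 * (h.feature_mass - frags) / frags) <= tol_ppm
        )
        if coelutes and matches:
            h = SuspectHit(**{**h.__dict__, "in_source_fragment": True})
        out.append(h)
    return out


def screen(
    table: FeatureTable,
    metadata: SampleSheet,
    predicted: Sequence[PredictedBioTP],
    params: ScreeningParams = ScreeningParams(),
    *,
    parent_rt_min: float | None = None,
    known_fragment_masses: Sequence[float] = (),
) -> ScreeningOutcome:
    """Run the full funnel: replicate exclusion, suspect matching, filter 1,
    filter 2, in-source flagging.  Filters 1 and 2 are independent predicates,
    so their application order cannot change the surviving set."""
    table, surviving = exclude_replicates(table, metadata)

    hits = match_suspects(table, predicted, params.tol_ppm)
    if parent_rt_min is not None and known_fragment_masses:
        hits = flag_in_source_fragments(
            hits,
            table,
            parent_rt_min,
            known_fragment_masses,
            rt_window_min=params.rt_window_min,
            tol_ppm=params.tol_ppm,
        )
    suspect_ids = {h.feature_id for h in hits}
    flagged_ids = {h.feature_id for h in hits if h.in_source_fragment}

    counts = control_detect_counts(table, metadata, params.presence_threshold)
    efs = enrichment_factors(table, metadata)

    results = []
    for fid in table.meta.index:
        fid = str(fid)
        is_suspect = fid in suspect_ids
        c = int(counts.loc[fid])
        p1 = c <= params.max_control_detects
        ef = float(efs.loc[fid])
        p2 = bool(ef > params.ef_cutoff)
        if not is_suspect:
            stage = "raw"
        elif not p1:
            stage = "suspect"
        elif not p2:
            stage = "post_filter1"
        else:
            stage = "post_filter2"
        results.append(
            ScreeningResult(
                feature_id=fid,
                is_suspect=is_suspect,
                control_detect_count=c,
                passed_filter1=p1,
                ef=ef,
                passed_filter2=p2,
                funnel_stage=stage,
                in_source_fragment=fid in flagged_ids,
            )
        )

    order = {s: i for i, s in enumerate(FUNNEL_STAGES)}
    funnel = {
        stage: sum(1 for r in results if order[r.funnel_stage] >= i)
        for i, stage in enumerate(FUNNEL_STAGES)
    }
    return ScreeningOutcome(
        results=results, hits=hits, funnel=funnel, surviving_counts=surviving
    )
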