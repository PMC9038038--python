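"""Post-filter corroboration: dose gradients, cross-dataset linking, MS2
similarity, fragment-annotation fractions, and inter-individual variability.

Rank statistics are Spearman throughout.  rs is Pearson's correlation on
midranks; the p-value is two-sided, computed by exhaustive enumeration of
rank permutations for n <= 8 and by seeded Monte-Carlo permutation (9999
draws) above that.

Spectral similarity is a sqrt-intensity-weighted cosine over greedily matched
peak pairs (nearest pair first, each peak used at most once).  It is bounded
in [0, 1], symmetric, equals 1 on self-comparison, and is invariant to
uniform intensity scaling.  Comparisons between spectra whose retention times
differ by more than the configured window are rejected outright — a rejection
is distinct from a score of 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .feature_model import SampleSheet, Spectrum

__all__ = [
    "CorroborationStats",
    "ComparisonRejected",
    "InsufficientData",
    "spearman_rs",
    "dose_gradient_check",
    "link_cross_dataset",
    "spectral_similarity",
    "fish_fraction",
    "group_rsd",
]


class InsufficientData(ValueError):
    """Fewer complete pairs / replicates than the statistic requires."""


class ComparisonRejected(RuntimeError):
    """Spectra are outside the retention-time window; no score is defined."""


@dataclass
class CorroborationStats:
    """Evidence collected for one suspect feature."""

    gradient_rs: float = math.nan
    gradient_pass: bool = False
    crossdataset_rs: float = math.nan
    crossdataset_p: float = math.nan
    linked: bool = False
    similarity: float | None = None
    fish_matched: int | None = None
    fish_total: int | None = None
    fish_fraction: float | None = None
    rsd_by_group: dict = None


def _rs_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return math.nan
    return float(rx @ ry) / denom


def spearman_rs(
    x: Sequence[float],
    y: Sequence[float],
    *,
    seed: int = 0,
    n_perm: int = 9999,
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Spearman rank correlation with a permutation/exact p-value.

    Pairs with a missing (NaN) member are dropped; fewer than 3 complete
    pairs raises :class:`InsufficientData`.  Zero variance in either vector
    yields (nan, nan).  For n <= ``exact_max_n`` the two-sided p is computed
    by full enumeration of the n! pairings; above that by ``n_perm`` seeded
    random pairings with the +1 correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InsufficientData(f"need >= 3 complete pairs, have {n}")
    rx = rankdata(x)  # midranks for ties
    ry = rankdata(y)
    rs = _rs_from_ranks(rx, ry)
    if math.isnan(rs):
        return math.nan, math.nan

    # permutation distribution of rs under pairing exchangeability; rank sets
    # are fixed so only the pairing is permuted
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    tol = 1e-12
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        stats = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(stats) >= abs(rs) - tol))
    else:
        rng = np.random.default_rng(seed)
        perm_matrix = np.tile(ryc, (n_perm, 1))
        perm_matrix = rng.permuted(perm_matrix, axis=1)
        stats = (perm_matrix @ rxc) / denom
        p = float((np.sum(np.abs(stats) >= abs(rs) - tol) + 1) / (n_perm + 1))
    return rs, p


def dose_gradient_check(
    feature_areas: Mapping[str, float] | pd.Series,
    metadata: SampleSheet,
    min_rs: float = 0.6,
    *,
    seed: int = 0,
) -> tuple[bool, float]:
    """Does the feature's abundance increase with dose?

    rs is computed over (dose, area) pairs across all non-excluded dosed
    samples, with non-detects as zero areas; pass iff rs >= ``min_rs``.  The
    0.6 default quantifies a qualitative "logical gradient" judgement and is
    flagged as heuristic in reports.
    """
    areas = dict(feature_areas)
    dosed = metadata.ids(("dose",))
    if len({metadata[s].dose for s in dosed}) < 3:
        raise InsufficientData("need >= 3 dose groups with surviving replicates")
    doses = np.array([metadata[s].dose for s in dosed])
    vals = np.array(
        [0.0 if pd.isna(areas.get(s, np.nan)) else float(areas[s]) for s in dosed]
    )
    rs, _ = spearman_rs(doses, vals, seed=seed)
    if math.isnan(rs):
        return False, rs
    return bool(rs >= min_rs), rs


def link_cross_dataset(
    areas_a: Mapping[str, float] | pd.Series,
    areas_b: Mapping[str, float] | pd.Series,
    metadata: SampleSheet,
    min_rs: float = 0.83,
    max_p: float = 0.005,
    *,
    seed: int = 0,
    always_compute_p: bool = False,
) -> tuple[bool, float, float]:
    """Do two features from different analytical datasets track the same
    substance?

    Areas are paired by sample id over all non-excluded samples (non-detect =
    0).  Linked iff rs >= ``min_rs`` AND p <= ``max_p`` (defaults 0.83 and
    0.005).  When rs already fails the threshold, the permutation p cannot
    change the verdict and is skipped (NaN) unless ``always_compute_p``.
    """
    a = dict(areas_a)
    b = dict(areas_b)
    shared = [s for s in metadata.ids() if s in a or s in b]
    if not shared:
        raise InsufficientData("features share no samples")

    def val(d, s):
        v = d.get(s, 0.0)
        return 0.0 if pd.isna(v) else float(v)

    va = np.array([val(a, s) for s in shared])
    vb = np.array([val(b, s) for s in shared])
    rx, ry = rankdata(va), rankdata(vb)
    rs = _rs_from_ranks(rx, ry)
    if math.isnan(rs) or (rs < min_rs and not always_compute_p):
        return False, rs, math.nan
    rs, p = spearman_rs(va, vb, seed=seed)
    return bool(rs >= min_rs and p <= max_p), rs, p


def _greedy_peak_matching(
    mz_a: np.ndarray, mz_b: np.ndarray, frag_tol_da: float
) -> list[tuple[int, int]]:
    """Nearest-pair-first greedy matching; each peak used at most once."""
    diffs = np.abs(mz_a[:, None] - mz_b[None, :])
    ia, ib = np.nonzero(diffs <= frag_tol_da)
    order = np.argsort(diffs[ia, ib], kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for k in order:
        i, j = int(ia[k]), int(ib[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    return matches


def spectral_similarity(
    query: Spectrum,
    reference: Spectrum,
    frag_tol_da: float = 0.01,
    rt_window_min: float = 0.2,
) -> float:
    """MS2 similarity score in [0, 1] between two centroided spectra.

    score = sum over matched pairs of sqrt(I_q * I_r), divided by
    sqrt(sum I_q) * sqrt(sum I_r) over all peaks — the cosine of the
    sqrt-intensity peak vectors under greedy nearest matching.
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("cannot score an empty spectrum")
    if abs(query.rt_min - reference.rt_min) > rt_window_min:
        raise ComparisonRejected(
            f"retention times differ by {abs(query.rt_min - reference.rt_min):.3f} "
            f"min (> {rt_window_min} min window)"
        )
    qa, qi = query.mz, np.sqrt(query.intensities)
    ra, ri = reference.mz, np.sqrt(reference.intensities)
    denom = math.sqrt(float(qi @ qi) * float(ri @ ri))
    if denom == 0:
        return 0.0
    matches = _greedy_peak_matching(qa, ra, frag_tol_da)
    score = sum(float(qi[i] * ri[j]) for i, j in matches) / denom
    return min(1.0, score)


def fish_fraction(
    spectrum: Spectrum,
    candidate_fragment_masses: Sequence[float],
    frag_tol_da: float = 0.01,
) -> tuple[int, int, float]:
    """Fraction of observed MS2 peaks explained by a candidate structure's
    fragment mass list (fragment-ion-search style annotation)."""
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    if not len(candidate_fragment_masses):
        raise ValueError("empty candidate fragment list")
    cands = np.asarray(candidate_fragment_masses, dtype=float)
    mz = spectrum.mz
    matched = np.any(np.abs(mz[:, None] - cands[None, :]) <= frag_tol_da, axis=1)
    n_matched = int(matched.sum())
    n_total = len(mz)
    return n_matched, n_total, n_matched / n_total


def group_rsd(
    feature_areas: Mapping[str, float] | pd.Series,
    metadata: SampleSheet,
    groups: Sequence[tuple[str, float | None]] | None = None,
) -> dict[str, float]:
    """Percent relative standard deviation of replicate areas per group.

    ``groups`` is a list of (group, dose) selectors; default = every dose
    level plus the controls.  Only explicit (detected) areas enter; groups
    with < 2 such replicates are skipped, zero-mean groups are NaN.
    """
    areas = dict(feature_areas)
    if groups is None:
        groups = [("dose", d) for d in metadata.doses()]
        groups += [("negative_control", None), ("positive_control", None)]
    out: dict[str, float] = {}
    for group, dose in groups:
        ids = metadata.ids((group,), dose=dose)
        vals = np.array(
            [float(areas[s]) for s in ids if s in areas and not pd.isna(areas[s])]
        )
        label = f"{group}@{dose:g}" if dose is not None else group
        if len(vals) < 2:
            continue
        mean = vals.mean()
        out[label] = math.nan if mean == 0 else float(100.0 * vals.std(ddof=1) / mean)
    return out
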