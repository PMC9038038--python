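import math

import numpy as np
import pandas as pd
import pytest

from biotpscreen.chemformula import parse_formula
from biotpscreen.screening import (
    ScreeningParams,
    control_detect_counts,
    enrichment_factor,
    enrichment_factors,
    exclude_replicates,
    filter_controls,
    flag_in_source_fragments,
    match_suspects,
    screen,
)
from biotpscreen.transform_rules import default_rule_set, enumerate_biotps

from conftest import make_sheet, make_table

PPL = parse_formula("C16H21NO2")
PREDICTED = enumerate_biotps(PPL, default_rule_set(), 2, max_phase2=1, phase2_terminal=True)


# ---------------------------------------------------------------- replicate exclusion

def test_exclude_replicates_counts():
    excluded = {"D6_R01", "D6_R02", "D6_R03"}
    sheet = make_sheet(excluded=excluded)
    table = make_table({"f1": {s: 1.0 for s in sheet.sample_ids}}, sheet=sheet)
    out, surviving = exclude_replicates(table, sheet)
    assert surviving[46540.0] == 9
    assert surviving[4550.0] == 12
    assert len(out) == len(table)
    assert not any(c in out.areas.columns for c in excluded)


def test_exclude_replicates_identity_without_flags(sheet96):
    table = make_table({"f1": {s: 1.0 for s in sheet96.sample_ids}}, sheet=sheet96)
    out, surviving = exclude_replicates(table, sheet96)
    assert out.areas.shape == table.areas.shape
    assert set(surviving.values()) == {12}


def test_exclude_all_in_group_warns(caplog):
    sheet = make_sheet(
        doses=(1.0, 10.0, 100.0),
        replicates=2,
        n_controls=2,
        excluded={"D3_R01", "D3_R02"},
    )
    table = make_table({"f1": {s: 1.0 for s in sheet.sample_ids}}, sheet=sheet)
    with caplog.at_level("WARNING"):
        _, surviving = exclude_replicates(table, sheet)
    assert surviving.get(100.0, 0) == 0
    assert "100" in caplog.text


# ---------------------------------------------------------------- suspect matching

def test_match_observed_glucuronide(small_sheet):
    table = make_table(
        {"f1": {"D3_R01": 100.0}},
        masses={"f1": 435.18913},
        sheet=None,
    )
    hits = match_suspects(table, PREDICTED, tol_ppm=5.0)
    glu = [h for h in hits if h.product_formula == "C22H29NO8"]
    assert len(glu) == 1
    assert abs(glu[0].ppm_error) == pytest.approx(0.43, abs=0.1)
    assert ("glucuronidation",) in glu[0].rule_chains
    # tolerance monotonicity down to exclusion
    assert match_suspects(table, PREDICTED, tol_ppm=0.1) == []


def test_match_count_nondecreasing_in_tolerance():
    rng = np.random.default_rng(7)
    masses = {f"f{i}": float(m) for i, m in enumerate(rng.uniform(80, 800, 200))}
    table = make_table({f: {"D1_R01": 1.0} for f in masses}, masses=masses)
    counts = [
        len(match_suspects(table, PREDICTED, tol))
        for tol in (0.5, 2.0, 5.0, 20.0, 100.0)
    ]
    assert counts == sorted(counts)


# ---------------------------------------------------------------- filter 1

@pytest.mark.parametrize("n_controls_with_signal,passed", [(0, True), (1, True), (2, False)])
def test_control_presence_boundary(sheet96, n_controls_with_signal, passed):
    controls = sheet96.control_ids()[:n_controls_with_signal]
    areas = {s: 100.0 for s in controls}
    count, ok = filter_controls(areas, sheet96)
    assert count == n_controls_with_signal
    assert ok is passed


def test_positive_controls_count_toward_filter1(sheet96):
    # one signal in a positive control + one in a negative control -> removed
    areas = {"PC_R01": 50.0, "NC_R01": 50.0}
    count, ok = filter_controls(areas, sheet96)
    assert count == 2 and not ok


def test_presence_threshold_configurable(sheet96):
    areas = {"NC_R01": 5.0, "NC_R02": 5.0}
    assert filter_controls(areas, sheet96, presence_threshold=10.0) == (0, True)


def test_no_controls_is_configuration_error():
    sheet = make_sheet(doses=(1.0,), replicates=2, n_controls=0)
    with pytest.raises(ValueError):
        filter_controls({"D1_R01": 1.0}, sheet)


# ---------------------------------------------------------------- filter 2 (EF)

def _ef_table(sheet, dose_area, control_area):
    top = sheet.ids(("dose",), dose=sheet.highest_dose)
    neg = sheet.ids(("negative_control",))
    areas = {s: dose_area for s in top}
    areas.update({s: control_area for s in neg})
    return areas


def test_ef_equality_removed(sheet96):
    areas = _ef_table(sheet96, 100.0, 100.0)
    assert enrichment_factor(areas, sheet96) == pytest.approx(1.0)


def test_ef_eleven_retained(sheet96):
    areas = _ef_table(sheet96, 1100.0, 100.0)
    ef = enrichment_factor(areas, sheet96)
    assert ef == pytest.approx(11.0)
    assert ef > 10.0


def test_ef_blank_controls_is_infinite(sheet96):
    areas = {s: 500.0 for s in sheet96.ids(("dose",), dose=sheet96.highest_dose)}
    assert enrichment_factor(areas, sheet96) == math.inf


def test_ef_all_zero_fails(sheet96):
    assert enrichment_factor({}, sheet96) == 0.0


def test_ef_positive_controls_not_in_denominator(sheet96):
    # huge areas in positive controls must not deflate the EF
    areas = _ef_table(sheet96, 1100.0, 100.0)
    areas.update({s: 1e9 for s in sheet96.ids(("positive_control",))})
    assert enrichment_factor(areas, sheet96) == pytest.approx(11.0)


def test_ef_scale_invariance(sheet96):
    rng = np.random.default_rng(3)
    areas = {s: float(a) for s, a in zip(sheet96.sample_ids, rng.uniform(1, 100, 96))}
    ef1 = enrichment_factor(areas, sheet96)
    ef2 = enrichment_factor({s: 137.5 * a for s, a in areas.items()}, sheet96)
    assert ef2 == pytest.approx(ef1, rel=1e-12)


def test_vectorized_ef_matches_scalar(sheet96):
    rng = np.random.default_rng(11)
    feats = {
        f"f{i}": {
            s: float(a)
            for s, a in zip(sheet96.sample_ids, rng.uniform(0, 50, 96))
            if a > 5.0
        }
        for i in range(20)
    }
    table = make_table(feats, sheet=sheet96)
    vec = enrichment_factors(table, sheet96)
    for fid, areas in feats.items():
        assert vec.loc[fid] == pytest.approx(enrichment_factor(areas, sheet96))


# ---------------------------------------------------------------- in-source flags

def test_in_source_flagging(sheet96):
    # two features with the same suspect mass: one co-elutes with the parent
    # and matches a known in-source fragment mass, one elutes far away
    table = make_table(
        {"frag": {"D6_R01": 10.0}, "far": {"D6_R01": 10.0}},
        masses={"frag": 133.1101, "far": 133.1102},
        rts={"frag": 3.41, "far": 3.83},
    )
    hits = match_suspects(table, PREDICTED, tol_ppm=5.0)
    flagged = flag_in_source_fragments(
        hits, table, parent_rt_min=3.43, known_fragment_masses=[133.11014],
        rt_window_min=0.1,
    )
    by_id = {h.feature_id: h for h in flagged}
    assert by_id["frag"].in_source_fragment
    assert not by_id["far"].in_source_fragment
    # empty fragment list flags nothing
    assert not any(
        h.in_source_fragment
        for h in flag_in_source_fragments(hits, table, 3.43, [])
    )


# ---------------------------------------------------------------- full funnel

def _random_study(seed, sheet, n=150):
    rng = np.random.default_rng(seed)
    masses = {}
    feats = {}
    for i in range(n):
        fid = f"f{i}"
        if i % 7 == 0:  # plant some suspect-mass features
            p = PREDICTED[rng.integers(len(PREDICTED))]
            masses[fid] = p.neutral_mass * (1 + 1e-6 * rng.uniform(-3, 3))
        else:
            masses[fid] = float(rng.uniform(80, 800))
        present = rng.random(len(sheet)) < rng.uniform(0.2, 1.0)
        feats[fid] = {
            s: float(rng.lognormal(8, 1))
            for s, keep in zip(sheet.sample_ids, present)
            if keep
        }
    return make_table(feats, masses=masses, sheet=sheet)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_funnel_monotone(sheet96, seed):
    table = _random_study(seed, sheet96)
    out = screen(table, sheet96, PREDICTED)
    f = out.funnel
    assert f["raw"] >= f["suspect"] >= f["post_filter1"] >= f["post_filter2"]
    assert f["raw"] == len(table)
    # stage monotonicity per feature: post_filter2 implies all earlier stages
    for r in out.results:
        if r.funnel_stage == "post_filter2":
            assert r.is_suspect and r.passed_filter1 and r.passed_filter2


@pytest.mark.parametrize("seed", [0, 5])
def test_filter_order_invariance(sheet96, seed):
    """Applying filter 1 then 2 must select the same features as 2 then 1."""
    table = _random_study(seed, sheet96)
    counts = control_detect_counts(table, sheet96)
    efs = enrichment_factors(table, sheet96)
    f1 = set(counts[counts <= 1].index)
    f2 = set(efs[efs > 10].index)
    ids = set(table.meta.index)
    assert (ids & f1) & f2 == (ids & f2) & f1
    survivors = {
        r.feature_id for r in screen(table, sheet96, PREDICTED).results
        if r.funnel_stage == "post_filter2"
    }
    suspect_ids = {h.feature_id for h in match_suspects(table, PREDICTED, 5.0)}
    assert survivors == suspect_ids & f1 & f2


def test_spiked_feature_survives(sheet96):
    """A suspect-mass feature absent from controls with dose/control mean
    ratio > 10 must survive both filters."""
    top = sheet96.ids(("dose",), dose=sheet96.highest_dose)
    table = make_table(
        {"spike": {s: 1000.0 for s in top}},
        masses={"spike": 435.18932},
        sheet=sheet96,
    )
    out = screen(table, sheet96, PREDICTED)
    assert out.survivors() == ["spike"]
    r = out.results[0]
    assert r.control_detect_count == 0 and r.ef == math.inf
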