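"""End-to-end orchestration: generate/load -> screen -> corroborate -> report.

A single :class:`RunConfig` carries every threshold explicitly; when a run
directory is written, the resolved config is serialized into it verbatim so
any output can be reproduced from the directory alone.  Identical config and
seed give byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import corroborate as corr
from .chemformula import parse_formula, ppm_error
from .confidence import ConfidenceAssignment, EvidenceBundle, ReportRow, assign_confidence, render_report
from .feature_model import FeatureTable, SampleSheet, Spectrum
from .screening import ScreeningOutcome, ScreeningParams, SuspectHit, screen
from .synthetic_data import SyntheticConfig, SyntheticData, generate
from .transform_rules import (
    DEFAULT_MAX_PHASE2,
    DEFAULT_MAX_STEPS,
    DEFAULT_PHASE2_TERMINAL,
    PredictedBioTP,
    default_rule_set,
    enumerate_biotps,
    load_rules,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_synthetic"]


@dataclass(frozen=True)
class RunConfig:
    """All thresholds of one screening run, explicit and serializable."""

    parent: str = "C16H21NO2"
    rules_file: str | None = None
    max_steps: int = DEFAULT_MAX_STEPS
    max_phase2: int = DEFAULT_MAX_PHASE2
    phase2_terminal: bool = DEFAULT_PHASE2_TERMINAL
    tol_ppm: float = 5.0
    presence_threshold: float = 0.0
    max_control_detects: int = 1
    ef_cutoff: float = 10.0
    gradient_min_rs: float = 0.6
    link_min_rs: float = 0.83
    link_max_p: float = 0.005
    sim_threshold: float = 0.90
    frag_tol_da: float = 0.01
    ms2_rt_window_min: float = 0.2
    standard_rt_window_min: float = 0.1
    insource_rt_window_min: float = 0.2
    seed: int = 0

    def screening_params(self) -> ScreeningParams:
        return ScreeningParams(
            tol_ppm=self.tol_ppm,
            presence_threshold=self.presence_threshold,
            max_control_detects=self.max_control_detects,
            ef_cutoff=self.ef_cutoff,
            rt_window_min=self.insource_rt_window_min,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    config: RunConfig
    predicted: list[PredictedBioTP]
    screening: dict[str, ScreeningOutcome]
    corroboration: pd.DataFrame
    assignments: dict[str, ConfidenceAssignment]  # keyed by (ds, feature_id) string
    report: pd.DataFrame
    report_text: str
    truth: pd.DataFrame | None = None

    @property
    def funnels(self) -> dict[str, dict[str, int]]:
        return {ds: out.funnel for ds, out in self.screening.items()}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(outdir / "config.yaml")
        funnel_rows = [
            {"dataset": ds, "stage": stage, "n_features": n}
            for ds, funnel in self.funnels.items()
            for stage, n in funnel.items()
        ]
        pd.DataFrame(funnel_rows).to_csv(
            outdir / "funnel_summary.tsv", sep="\t", index=False
        )
        for ds, out in self.screening.items():
            out.results_frame().to_csv(
                outdir / f"screening_{ds}.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
        self.corroboration.to_csv(
            outdir / "corroboration.tsv", sep="\t", index=False, float_format="%.6g"
        )
        self.report.to_csv(outdir / "report.tsv", sep="\t", index=False)
        (outdir / "report.txt").write_text(self.report_text + "\n")


def _predicted_products(config: RunConfig) -> list[PredictedBioTP]:
    rules = load_rules(config.rules_file) if config.rules_file else default_rule_set()
    return enumerate_biotps(
        parse_formula(config.parent),
        rules,
        config.max_steps,
        max_phase2=config.max_phase2,
        phase2_terminal=config.phase2_terminal,
    )


def _best_hit(hits: Sequence[SuspectHit]) -> SuspectHit:
    return min(hits, key=lambda h: abs(h.ppm_error))


def run_pipeline(
    config: RunConfig,
    samples: dict[str, SampleSheet],
    tables: dict[str, FeatureTable],
    spectra: dict[str, list[Spectrum]] | None = None,
    standards: dict[str, dict[str, Spectrum]] | None = None,
    fragment_candidates: dict[str, list[float]] | None = None,
    medium_masses: Sequence[float] = (),
    truth: pd.DataFrame | None = None,
) -> PipelineResult:
    """Screen every dataset, corroborate the survivors, assign confidence
    levels, and assemble the identification report."""
    spectra = spectra or {}
    standards = standards or {}
    fragment_candidates = fragment_candidates or {}
    predicted = _predicted_products(config)
    params = config.screening_params()
    parent_mass = parse_formula(config.parent).mass

    screening: dict[str, ScreeningOutcome] = {}
    for ds, table in tables.items():
        # the parent's own feature (if present) anchors in-source RT checks
        parent_rt = None
        near_parent = (table.meta["neutral_mass"] - parent_mass).abs() < 1e-3
        if near_parent.any():
            parent_rt = float(table.meta.loc[near_parent, "rt_min"].iloc[0])
        out = screen(
            table,
            samples[ds],
            predicted,
            params,
            parent_rt_min=parent_rt,
            known_fragment_masses=list(fragment_candidates.get("__parent__", ())),
        )
        screening[ds] = out
        logger.info("dataset %s funnel: %s", ds, out.funnel)

    # ---- corroboration over survivors -----------------------------------
    corr_rows = []
    survivor_info: dict[tuple[str, str], dict] = {}
    spectra_by_feature = {
        ds: {s.feature_id: s for s in spectra.get(ds, [])} for ds in tables
    }
    for ds, out in screening.items():
        table = tables[ds]
        sheet = samples[ds]
        for fid in out.survivors():
            hits = out.hits_for(fid)
            best = _best_hit(hits)
            areas = table.areas.loc[fid]
            gr_pass, gr_rs = corr.dose_gradient_check(
                areas, sheet, config.gradient_min_rs, seed=config.seed
            )
            rsds = corr.group_rsd(areas, sheet)
            spec = spectra_by_feature[ds].get(fid)
            info = {
                "dataset": ds,
                "feature_id": fid,
                "formula": best.product_formula,
                "rule_chain": ">".join(best.best_rule_chain),
                "ppm_error": best.ppm_error,
                "gradient_rs": gr_rs,
                "gradient_pass": gr_pass,
                "has_ms2": spec is not None,
                "in_source_fragment": best.in_source_fragment,
            }
            survivor_info[(ds, fid)] = dict(info, spectrum=spec, rsds=rsds, hit=best)
            corr_rows.append(info)

    # cross-dataset linking: survivors matched to the same product formula
    links: dict[tuple[str, str], tuple[bool, float, float]] = {}
    ds_list = list(tables)
    for i, ds_a in enumerate(ds_list):
        for ds_b in ds_list[i + 1 :]:
            a_by_formula: dict[str, str] = {
                v["formula"]: key[1]
                for key, v in survivor_info.items()
                if key[0] == ds_a
            }
            for (ds, fid), v in list(survivor_info.items()):
                if ds != ds_b or v["formula"] not in a_by_formula:
                    continue
                fid_a = a_by_formula[v["formula"]]
                linked, rs, p = corr.link_cross_dataset(
                    tables[ds_a].areas.loc[fid_a],
                    tables[ds_b].areas.loc[fid],
                    samples[ds_a],
                    config.link_min_rs,
                    config.link_max_p,
                    seed=config.seed,
                )
                links[(ds_a, fid_a)] = (linked, rs, p)
                links[(ds_b, fid)] = (linked, rs, p)

    for row in corr_rows:
        linked, rs, p = links.get(
            (row["dataset"], row["feature_id"]), (False, math.nan, math.nan)
        )
        row["crossdataset_rs"] = rs
        row["crossdataset_p"] = p
        row["linked"] = linked

    # ---- evidence -> confidence -----------------------------------------
    assignments: dict[str, ConfidenceAssignment] = {}
    report_rows: list[ReportRow] = []
    for (ds, fid), v in survivor_info.items():
        spec = v["spectrum"]
        best: SuspectHit = v["hit"]
        sim_std = rt_delta = None
        if spec is not None and standards.get(ds, {}).get(v["formula"]) is not None:
            std = standards[ds][v["formula"]]
            rt_delta = spec.rt_min - std.rt_min
            try:
                sim_std = corr.spectral_similarity(
                    spec, std, config.frag_tol_da, config.ms2_rt_window_min
                )
            except corr.ComparisonRejected:
                sim_std = None
        fish = None
        if spec is not None and v["formula"] in fragment_candidates:
            _, _, fish = corr.fish_fraction(
                spec, fragment_candidates[v["formula"]], config.frag_tol_da
            )
        in_medium = any(
            abs(ppm_error(best.feature_mass, m)) <= config.tol_ppm
            for m in medium_masses
        )
        bundle = EvidenceBundle(
            name=v["rule_chain"] or v["formula"],
            has_ms2=spec is not None,
            similarity_to_standard=sim_std,
            rt_delta_to_standard_min=rt_delta,
            fish_fraction=fish,
            in_dosing_medium=in_medium,
            in_source_flag=v["in_source_fragment"],
        )
        assignment = assign_confidence(
            bundle, config.sim_threshold, config.standard_rt_window_min
        )
        assignments[f"{ds}:{fid}"] = assignment
        report_rows.append(
            ReportRow(
                name=v["rule_chain"] or v["formula"],
                formula=v["formula"],
                exact_mass=best.predicted_mass,
                rt_min=float(tables[ds].meta.loc[fid, "rt_min"]),
                dppm=best.ppm_error,
                similarity=sim_std,
                datasets=ds,
                level=assignment.level,
                tentative=assignment.tentative,
                comment="; ".join(assignment.rationale[1:]),
            )
        )

    # merge rows describing the same product seen in several datasets
    merged: dict[str, ReportRow] = {}
    for r in report_rows:
        if r.formula in merged:
            m = merged[r.formula]
            m.datasets = " & ".join(sorted(set(m.datasets.split(" & ")) | {r.datasets}))
            if _LEVEL_BETTER(r.level, m.level):
                m.level, m.similarity, m.rt_min, m.dppm = (
                    r.level,
                    r.similarity,
                    r.rt_min,
                    r.dppm,
                )
            m.tentative = m.tentative or r.tentative
        else:
            merged[r.formula] = r
    report_df, report_text = render_report(list(merged.values()))

    corr_df = pd.DataFrame(
        corr_rows,
        columns=[
            "dataset",
            "feature_id",
            "formula",
            "rule_chain",
            "ppm_error",
            "gradient_rs",
            "gradient_pass",
            "crossdataset_rs",
            "crossdataset_p",
            "linked",
            "has_ms2",
            "in_source_fragment",
        ],
    )
    return PipelineResult(
        config=config,
        predicted=predicted,
        screening=screening,
        corroboration=corr_df,
        assignments=assignments,
        report=report_df,
        report_text=report_text,
        truth=truth,
    )


def _LEVEL_BETTER(a: str, b: str) -> bool:
    from .confidence import _LEVEL_ORDER

    return _LEVEL_ORDER[a] < _LEVEL_ORDER[b]


def run_synthetic(
    run_config: RunConfig, synth_config: SyntheticConfig | None = None
) -> tuple[PipelineResult, SyntheticData]:
    """Generate a synthetic study (seeded from the run config unless an
    explicit synthetic config is given) and push it through the pipeline."""
    if synth_config is None:
        synth_config = SyntheticConfig(seed=run_config.seed)
    data = generate(synth_config)
    result = run_pipeline(
        run_config,
        data.samples,
        data.tables,
        data.spectra,
        data.standards,
        data.fragment_candidates,
        data.medium_masses,
        truth=data.truth,
    )
    return result, data


def spike_recovery(result: PipelineResult, data: SyntheticData) -> dict:
    """Recall/precision of spiked bioTPs against the generator truth table.

    A spike is recovered when its feature survives both filters and its true
    rule chain is among the chains of the matched product formula."""
    truth = data.truth
    spikes = truth[truth["class"] == "spike"]
    n_spikes = len(spikes)
    recovered = 0
    for _, row in spikes.iterrows():
        ds, fid = row["dataset"], row["feature_id"]
        out = result.screening.get(ds)
        if out is None or fid not in out.survivors():
            continue
        chains = {
            c for h in out.hits_for(fid) for c in h.rule_chains
        }
        if tuple(row["rule_chain"].split(">")) in chains:
            recovered += 1
    survivors_all = {
        (ds, fid) for ds, out in result.screening.items() for fid in out.survivors()
    }
    truth_idx = truth.set_index(["dataset", "feature_id"])["class"]
    false_pos = [
        key for key in survivors_all if truth_idx.get(key, "") != "spike"
    ]
    return {
        "n_spikes": n_spikes,
        "n_recovered": recovered,
        "recall": recovered / n_spikes if n_spikes else math.nan,
        "n_false_positives": len(false_pos),
        "false_positive_ids": sorted(false_pos),
        "precision": (
            recovered / (recovered + len(false_pos))
            if recovered + len(false_pos)
            else math.nan
        ),
    }
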