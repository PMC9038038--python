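"""Synthetic single-embryo exposure datasets for exercising the screening
pipeline end to end.

The generator emulates the study design the screening procedure assumes: six
exposure doses plus one positive- and one negative-control group, 12
replicate embryos per group, thousands of background features with no dose
structure, a handful of spiked biotransformation products whose mean areas
scale as dose**gamma with log-normal replicate noise, dosing-medium
contaminants, control-only contaminants, and replicate dropout modelling
lethal endpoints.  Two analytical datasets (HILIC positive / C18 negative)
share the embryos, so paired spikes carry correlated abundances for
cross-dataset linking.

Every feature's ground-truth class is recorded in a truth table, which makes
spike recall / false-positive rates measurable for any pipeline
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .chemformula import MolecularFormula, mz_from_neutral, parse_formula
from .feature_model import (
    FeatureTable,
    SampleMetadata,
    SampleSheet,
    Spectrum,
    write_mgf,
)
from .transform_rules import apply_chain, default_rule_set, rules_by_name

__all__ = ["SyntheticConfig", "SyntheticData", "generate"]

#: The six exposure doses (ug/L) of the emulated design.
DEFAULT_DOSES = (0.050, 0.49, 12.0, 62.0, 4550.0, 46540.0)

#: Spiked-bioTP rule chains (defaults mirror the products such a screen is
#: designed to recover: phase I oxidations/dealkylations and terminal
#: conjugates).
DEFAULT_SPIKE_CHAINS: tuple[tuple[str, ...], ...] = (
    ("hydroxylation",),
    ("desisopropylation",),
    ("o_dearylation",),
    ("hydration",),
    ("hydroxylation", "hydration"),
    ("glucuronidation",),
    ("hydroxylation", "glucuronidation"),
    ("hydroxylation", "sulfation"),
)

#: Chains for which an authentic reference standard is emitted (five, as for
#: a typical standards shelf covering the major expected metabolites).
DEFAULT_STANDARD_CHAINS: tuple[tuple[str, ...], ...] = (
    ("hydroxylation",),
    ("desisopropylation",),
    ("glucuronidation",),
    ("hydroxylation", "glucuronidation"),
    ("hydroxylation", "sulfation"),
)

_ADDUCT_FOR_DATASET = {"HILIC_pos": "[M+H]+", "C18_neg": "[M-H]-"}


def _sigma_from_cv(cv: float) -> float:
    """Log-normal sigma giving a multiplicative coefficient of variation cv."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    doses: tuple[float, ...] = DEFAULT_DOSES
    replicates: int = 12
    n_background: int = 2000
    parent: str = "C16H21NO2"
    spike_chains: tuple[tuple[str, ...], ...] = DEFAULT_SPIKE_CHAINS
    standard_chains: tuple[tuple[str, ...], ...] = DEFAULT_STANDARD_CHAINS
    no_ms2_chains: tuple[tuple[str, ...], ...] = (("hydration",),)
    gamma: float = 1.0            # dose-response exponent for spikes
    cv: float = 0.3               # biological replicate CV (shared by datasets)
    technical_cv: float = 0.1     # per-dataset measurement CV
    top_area: float = 1.0e6       # spike mean area at the highest dose
    background_median_area: float = 5.0e4
    background_sigma: float = 1.0   # log-normal sigma of background base levels
    background_cell_cv: float = 0.4
    detect_prob: float = 0.97     # per-cell detection prob for non-spikes
    n_control_contaminants: int = 20
    n_medium_contaminants: int = 5
    # lethality: per-replicate Bernoulli dropout probability by dose; the two
    # top doses default to 3/12 and 4/12
    dropout_rates: tuple[tuple[float, float], ...] = (
        (46540.0, 3 / 12),
        (4550.0, 4 / 12),
    )
    datasets: tuple[str, ...] = ("HILIC_pos", "C18_neg")
    mass_jitter_ppm: float = 1.0  # instrument mass error on spiked features
    mass_range: tuple[float, float] = (80.0, 800.0)
    rt_range: tuple[float, float] = (0.5, 10.0)
    parent_rt_min: float = 3.4
    n_fragments: int = 8
    n_noise_peaks: int = 8

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.n_background < 0:
            raise ValueError("counts must be nonnegative (replicates >= 1)")
        if self.cv < 0 or self.technical_cv < 0:
            raise ValueError("CVs must be >= 0")
        for _, p in self.dropout_rates:
            if not 0 <= p <= 1:
                raise ValueError("dropout probabilities must be in [0, 1]")
        unknown = [c for c in self.no_ms2_chains if c not in self.spike_chains]
        unknown += [c for c in self.standard_chains if c not in self.spike_chains]
        if unknown:
            raise ValueError(f"chains not among spike_chains: {unknown}")


@dataclass
class SyntheticData:
    """Everything one generated run produces, in memory."""

    config: SyntheticConfig
    samples: dict[str, SampleSheet]
    tables: dict[str, FeatureTable]
    spectra: dict[str, list[Spectrum]]
    standards: dict[str, dict[str, Spectrum]]  # dataset -> formula -> spectrum
    truth: pd.DataFrame
    fragment_candidates: dict[str, list[float]]  # formula -> fragment m/z
    medium_masses: list[float]
    spike_products: dict[tuple[str, ...], MolecularFormula]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frames = [s.to_frame() for s in self.samples.values()]
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "samples.csv", index=False
        )
        for ds, table in self.tables.items():
            table.to_csv(outdir / f"features_{ds}.csv")
            if self.spectra[ds]:
                write_mgf(self.spectra[ds], outdir / f"spectra_{ds}.mgf")
            if self.standards[ds]:
                write_mgf(
                    list(self.standards[ds].values()),
                    outdir / f"standards_{ds}.mgf",
                )
        self.truth.to_csv(outdir / "truth.csv", index=False)
        pd.DataFrame(
            {
                "formula": list(self.fragment_candidates),
                "fragment_mz": [
                    ";".join(f"{m:.5f}" for m in v)
                    for v in self.fragment_candidates.values()
                ],
            }
        ).to_csv(outdir / "fragments.csv", index=False)
        pd.DataFrame({"neutral_mass": self.medium_masses}).to_csv(
            outdir / "medium_blank.csv", index=False
        )


def _make_samples(cfg: SyntheticConfig, rng: np.random.Generator) -> list[SampleMetadata]:
    dropout = dict(cfg.dropout_rates)
    samples = []
    for di, dose in enumerate(cfg.doses):
        rate = dropout.get(dose, 0.0)
        for r in range(cfg.replicates):
            samples.append(
                SampleMetadata(
                    sample_id=f"D{di + 1}_R{r + 1:02d}",
                    group="dose",
                    dose=dose,
                    replicate=r + 1,
                    excluded=bool(rng.random() < rate),
                )
            )
    for prefix, group in (("PC", "positive_control"), ("NC", "negative_control")):
        for r in range(cfg.replicates):
            samples.append(
                SampleMetadata(
                    sample_id=f"{prefix}_R{r + 1:02d}",
                    group=group,
                    dose=0.0,
                    replicate=r + 1,
                )
            )
    return samples


def _spike_fragments(
    rng: np.random.Generator, neutral_mass: float, n: int
) -> list[float]:
    """Candidate fragment m/z values for one product: random cuts below the
    protonated mass, deterministic given the generator state."""
    lo, hi = 50.0, max(60.0, neutral_mass - 10.0)
    return sorted(float(m) for m in rng.uniform(lo, hi, size=n))


def generate(config: SyntheticConfig) -> SyntheticData:
    """Generate metadata, feature tables, spectra, standards and the truth
    table for every configured dataset.  Bit-reproducible for a given config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rules = rules_by_name(default_rule_set())
    parent = parse_formula(cfg.parent)

    # spiked products
    spike_products: dict[tuple[str, ...], MolecularFormula] = {}
    for chain in cfg.spike_chains:
        missing = [r for r in chain if r not in rules]
        if missing:
            raise ValueError(f"unknown rule(s) in spike chain {chain}: {missing}")
        spike_products[chain] = apply_chain(parent, [rules[r] for r in chain])

    sample_meta = _make_samples(cfg, rng)
    n_samples = len(sample_meta)
    sample_ids = [s.sample_id for s in sample_meta]
    doses = np.array([s.dose for s in sample_meta])
    is_dosed = np.array([s.group == "dose" for s in sample_meta])
    is_control = ~is_dosed
    max_dose = max(cfg.doses)

    sigma_bio = _sigma_from_cv(cfg.cv)
    sigma_tech = _sigma_from_cv(cfg.technical_cv)
    sigma_cell = _sigma_from_cv(cfg.background_cell_cv)

    # biological spike abundances, shared across datasets (same embryos)
    rel_dose = np.where(is_dosed, doses / max_dose, 0.0)
    spike_bio = {}
    for chain in cfg.spike_chains:
        level = np.exp(rng.normal(0.0, sigma_bio, size=n_samples))
        spike_bio[chain] = cfg.top_area * rel_dose**cfg.gamma * level

    # fragment candidate lists per product formula
    fragment_candidates = {
        spike_products[c].hill(): _spike_fragments(
            rng, spike_products[c].mass, cfg.n_fragments
        )
        for c in cfg.spike_chains
    }

    # medium contaminants: present in dosed samples (scaling with dose) and
    # recorded in the medium-blank mass list
    lo, hi = cfg.mass_range
    medium_masses = sorted(float(m) for m in rng.uniform(lo, hi, cfg.n_medium_contaminants))

    samples: dict[str, SampleSheet] = {}
    tables: dict[str, FeatureTable] = {}
    spectra: dict[str, list[Spectrum]] = {}
    standards: dict[str, dict[str, Spectrum]] = {}
    truth_rows = []

    spike_rts = {
        chain: float(rng.uniform(1.0, 8.0)) for chain in cfg.spike_chains
    }

    for ds in cfg.datasets:
        adduct = _ADDUCT_FOR_DATASET.get(ds, "[M+H]+")
        sheet = SampleSheet(
            SampleMetadata(
                sample_id=s.sample_id,
                group=s.group,
                dose=s.dose,
                replicate=s.replicate,
                excluded=s.excluded,
                dataset=ds,
            )
            for s in sample_meta
        )
        samples[ds] = sheet

        meta_rows = []
        area_rows = []
        ds_spectra: list[Spectrum] = []
        ds_standards: dict[str, Spectrum] = {}
        ds_scale = float(np.exp(rng.normal(0.0, 0.2)))

        def add_feature(fid, mass, rt, areas, klass, formula="", chain=""):
            meta_rows.append((fid, mass, rt))
            area_rows.append(areas)
            truth_rows.append(
                {
                    "dataset": ds,
                    "feature_id": fid,
                    "class": klass,
                    "formula": formula,
                    "rule_chain": chain,
                    "true_neutral_mass": mass if not formula else parse_formula(formula).mass,
                }
            )

        # parent compound feature (matches no product; anchors in-source RT)
        parent_areas = np.where(
            is_dosed,
            10.0 * cfg.top_area * rel_dose * np.exp(rng.normal(0, sigma_bio, n_samples)),
            np.nan,
        )
        add_feature(
            f"{ds}_parent",
            parent.mass * (1 + 1e-6 * cfg.mass_jitter_ppm * rng.uniform(-1, 1)),
            cfg.parent_rt_min,
            parent_areas,
            "parent",
            formula=cfg.parent,
        )

        # spiked bioTPs: dose-monotone, absent in all controls
        for k, chain in enumerate(cfg.spike_chains):
            product = spike_products[chain]
            true_mass = product.mass
            jitter = 1e-6 * cfg.mass_jitter_ppm * rng.uniform(-1, 1)
            tech = np.exp(rng.normal(0.0, sigma_tech, size=n_samples))
            areas = np.where(is_dosed, spike_bio[chain] * tech * ds_scale, np.nan)
            fid = f"{ds}_spike{k:02d}"
            rt = spike_rts[chain]
            add_feature(
                fid,
                true_mass * (1 + jitter),
                rt,
                areas,
                "spike",
                formula=product.hill(),
                chain=">".join(chain),
            )

            # MS2: candidate fragments + uniform-random noise peaks
            if chain in cfg.no_ms2_chains:
                continue
            frags = np.array(fragment_candidates[product.hill()])
            frag_int = np.exp(rng.normal(np.log(1e4), 0.5, size=len(frags)))
            noise_mz = rng.uniform(50.0, true_mass, size=cfg.n_noise_peaks)
            noise_int = rng.uniform(0.0, 0.03 * float(np.median(frag_int)), cfg.n_noise_peaks)
            mzs = np.concatenate([frags, noise_mz])
            ints = np.concatenate([frag_int, noise_int])
            ds_spectra.append(
                Spectrum(
                    precursor_mz=mz_from_neutral(true_mass, adduct),
                    rt_min=rt,
                    peaks=tuple(zip(mzs, ints)),
                    sample_id=f"D{len(cfg.doses)}_pool",
                    feature_id=fid,
                )
            )
            if chain in cfg.standard_chains:
                std_int = frag_int * np.exp(rng.normal(0.0, 0.2, size=len(frags)))
                ds_standards[product.hill()] = Spectrum(
                    precursor_mz=mz_from_neutral(true_mass, adduct),
                    rt_min=rt + float(rng.uniform(-0.02, 0.02)),
                    peaks=tuple(zip(frags, std_int)),
                    sample_id="standard",
                    feature_id=product.hill(),
                )

        # background features: i.i.d. log-normal, no dose structure
        bg_mass = rng.uniform(lo, hi, size=cfg.n_background)
        bg_rt = rng.uniform(*cfg.rt_range, size=cfg.n_background)
        bg_base = np.exp(
            rng.normal(np.log(cfg.background_median_area), cfg.background_sigma, cfg.n_background)
        )
        bg_noise = np.exp(rng.normal(0.0, sigma_cell, size=(cfg.n_background, n_samples)))
        bg_detect = rng.random((cfg.n_background, n_samples)) < cfg.detect_prob
        bg_areas = np.where(bg_detect, bg_base[:, None] * bg_noise, np.nan)
        for i in range(cfg.n_background):
            add_feature(
                f"{ds}_bg{i:04d}", float(bg_mass[i]), float(bg_rt[i]), bg_areas[i], "background"
            )

        # control-only contaminants
        for i in range(cfg.n_control_contaminants):
            base = np.exp(rng.normal(np.log(cfg.background_median_area), 1.0))
            areas = np.where(
                is_control, base * np.exp(rng.normal(0, sigma_cell, n_samples)), np.nan
            )
            add_feature(
                f"{ds}_ctl{i:02d}",
                float(rng.uniform(lo, hi)),
                float(rng.uniform(*cfg.rt_range)),
                areas,
                "control_contaminant",
            )

        # dosing-medium contaminants: scale with dose, absent in controls
        for i, m in enumerate(medium_masses):
            base = np.exp(rng.normal(np.log(cfg.background_median_area), 1.0))
            areas = np.where(
                is_dosed,
                base * rel_dose**cfg.gamma * np.exp(rng.normal(0, sigma_cell, n_samples)),
                np.nan,
            )
            add_feature(
                f"{ds}_med{i:02d}",
                m * (1 + 1e-6 * cfg.mass_jitter_ppm * rng.uniform(-1, 1)),
                float(rng.uniform(*cfg.rt_range)),
                areas,
                "medium_contaminant",
            )

        fids = [r[0] for r in meta_rows]
        meta = pd.DataFrame(
            {
                "neutral_mass": [r[1] for r in meta_rows],
                "rt_min": [r[2] for r in meta_rows],
            },
            index=pd.Index(fids, name="feature_id"),
        )
        areas = pd.DataFrame(np.vstack(area_rows), index=meta.index, columns=sample_ids)
        dead = [s.sample_id for s in sample_meta if s.excluded]
        areas[dead] = np.nan  # lethal endpoints: no usable measurement
        tables[ds] = FeatureTable(meta, areas, dataset=ds)
        spectra[ds] = ds_spectra
        standards[ds] = ds_standards

    truth = pd.DataFrame(truth_rows)
    return SyntheticData(
        config=cfg,
        samples=samples,
        tables=tables,
        spectra=spectra,
        standards=standards,
        truth=truth,
        fragment_candidates=fragment_candidates,
        medium_masses=medium_masses,
        spike_products=spike_products,
    )
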