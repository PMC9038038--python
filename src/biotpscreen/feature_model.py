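"""Data model and I/O for feature tables, sample metadata, and MS2 spectra.

A *feature* is a picked LC-HRMS peak: neutral monoisotopic mass, retention
time (minutes), and one area per sample.  An absent/blank area cell means "no
detected signal" and is distinct from an explicit 0; both count as no-signal
for presence tests, but only explicit values enter plain table statistics
(the screening module's enrichment factor defines its own zero-fill
convention).

Tables are CSV/TSV (pandas); spectra are MGF (pyteomics) with optional MSP
ingestion (matchms).  m/z columns are normalized to neutral mass on load via
the adduct rules in :mod:`.chemformula`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .chemformula import neutral_from_mz, mz_from_neutral

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "SampleMetadata",
    "SampleSheet",
    "Feature",
    "FeatureTable",
    "Spectrum",
    "read_feature_table",
    "read_sample_sheet",
    "read_spectra",
    "write_mgf",
]

GROUPS = ("dose", "negative_control", "positive_control")

_META_COLUMNS = ["sample_id", "group", "dose", "replicate", "excluded", "dataset"]


class FormatError(ValueError):
    """Malformed or inconsistent input table/spectrum file."""


@dataclass(frozen=True)
class SampleMetadata:
    """One sample: exposure group, dose (ug/L, 0 for controls), replicate
    index, exclusion flag (lethal / severe morphological endpoint)."""

    sample_id: str
    group: str
    dose: float
    replicate: int
    excluded: bool = False
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if (self.dose > 0) != (self.group == "dose"):
            raise ValueError(
                f"sample {self.sample_id}: dose > 0 iff group == 'dose' "
                f"(group={self.group}, dose={self.dose})"
            )


class SampleSheet:
    """Ordered collection of :class:`SampleMetadata` with unique ids."""

    def __init__(self, samples: Iterable[SampleMetadata]):
        self.samples: list[SampleMetadata] = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in sample sheet")
        self._by_id = {s.sample_id: s for s in self.samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleMetadata]:
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> SampleMetadata:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def ids(
        self,
        groups: Sequence[str] | None = None,
        *,
        include_excluded: bool = False,
        dose: float | None = None,
    ) -> list[str]:
        out = []
        for s in self.samples:
            if groups is not None and s.group not in groups:
                continue
            if s.excluded and not include_excluded:
                continue
            if dose is not None and s.dose != dose:
                continue
            out.append(s.sample_id)
        return out

    def control_ids(self, *, include_excluded: bool = False) -> list[str]:
        """All samples to which no test compound was added (negative +
        positive controls)."""
        return self.ids(
            ("negative_control", "positive_control"),
            include_excluded=include_excluded,
        )

    def doses(self) -> list[float]:
        return sorted({s.dose for s in self.samples if s.group == "dose"})

    @property
    def highest_dose(self) -> float:
        doses = self.doses()
        if not doses:
            raise ValueError("sample sheet has no dose-group samples")
        return doses[-1]

    def with_exclusions(self, excluded_ids: Iterable[str]) -> "SampleSheet":
        excluded = set(excluded_ids)
        return SampleSheet(
            replace(s, excluded=True) if s.sample_id in excluded else s
            for s in self.samples
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                [s.sample_id, s.group, s.dose, s.replicate, s.excluded, s.dataset]
                for s in self.samples
            ],
            columns=_META_COLUMNS,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSheet":
        missing = set(_META_COLUMNS[:3]) - set(df.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        samples = []
        for _, row in df.iterrows():
            dataset = row.get("dataset", "")
            samples.append(
                SampleMetadata(
                    sample_id=str(row["sample_id"]),
                    group=str(row["group"]),
                    dose=float(row["dose"]),
                    replicate=int(row.get("replicate", 0)),
                    excluded=bool(row.get("excluded", False)),
                    dataset="" if pd.isna(dataset) else str(dataset),
                )
            )
        return cls(samples)


def read_sample_sheet(path) -> SampleSheet:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return SampleSheet.from_frame(pd.read_csv(path, sep=sep))


@dataclass(frozen=True)
class Feature:
    """One picked LC-HRMS peak with per-sample areas (absent = no signal)."""

    feature_id: str
    neutral_mass: float
    rt_min: float
    areas: dict[str, float] = field(default_factory=dict)
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"{self.feature_id}: neutral_mass must be > 0")
        if self.rt_min < 0:
            raise ValueError(f"{self.feature_id}: retention_time must be >= 0")


class FeatureTable:
    """A set of features over a fixed sample panel.

    Internally a pandas layout: ``meta`` (feature_id, neutral_mass, rt_min)
    and ``areas`` (features x samples, NaN = not detected), which keeps the
    screening filters vectorized.
    """

    def __init__(self, meta: pd.DataFrame, areas: pd.DataFrame, dataset: str = ""):
        if not meta.index.equals(areas.index):
            raise ValueError("meta and areas must share the feature index")
        if (meta["neutral_mass"] <= 0).any():
            raise FormatError("neutral_mass must be positive")
        if (meta["rt_min"] < 0).any():
            raise FormatError("retention_time must be nonnegative")
        if (areas.to_numpy(dtype=float) < 0).any():
            raise FormatError("negative area encountered")
        self.meta = meta
        self.areas = areas.astype(float)
        self.dataset = dataset

    # -- construction -----------------------------------------------------
    @classmethod
    def from_features(cls, features: Sequence[Feature], dataset: str = "") -> "FeatureTable":
        ids = [f.feature_id for f in features]
        meta = pd.DataFrame(
            {
                "neutral_mass": [f.neutral_mass for f in features],
                "rt_min": [f.rt_min for f in features],
            },
            index=pd.Index(ids, name="feature_id"),
        )
        areas = pd.DataFrame(
            [f.areas for f in features], index=meta.index, dtype=float
        )
        return cls(meta, areas, dataset=dataset)

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.meta.index)

    def feature(self, feature_id: str) -> Feature:
        row = self.meta.loc[feature_id]
        areas = self.areas.loc[feature_id].dropna().to_dict()
        return Feature(
            feature_id=feature_id,
            neutral_mass=float(row["neutral_mass"]),
            rt_min=float(row["rt_min"]),
            areas=areas,
            dataset=self.dataset,
        )

    def features(self) -> Iterator[Feature]:
        for fid in self.meta.index:
            yield self.feature(fid)

    def drop_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        keep = [c for c in self.areas.columns if c not in set(sample_ids)]
        return FeatureTable(self.meta, self.areas[keep], dataset=self.dataset)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path, *, adduct: str | None = None) -> None:
        """Write a delimited table; with ``adduct`` the mass is written as an
        m/z column instead of neutral mass."""
        df = self.meta.copy()
        if adduct is not None:
            df.insert(0, "mz", [mz_from_neutral(m, adduct) for m in df["neutral_mass"]])
            df.insert(1, "adduct", adduct)
            df = df.drop(columns="neutral_mass")
        out = pd.concat([df, self.areas], axis=1)
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        out.to_csv(path, sep=sep, float_format="%.10g")


def read_feature_table(path, metadata: SampleSheet, dataset: str = "") -> FeatureTable:
    """Read a delimited feature table.

    Required columns: ``feature_id``, ``rt_min``, and either ``neutral_mass``
    or ``mz`` + ``adduct``; every remaining column must name a sample in
    ``metadata``.  Blank cells are non-detections.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "feature_id" not in df.columns:
        raise FormatError("missing required column 'feature_id'")
    if "rt_min" not in df.columns:
        raise FormatError("missing required column 'rt_min'")
    df = df.set_index("feature_id")

    if "neutral_mass" in df.columns:
        mass = df["neutral_mass"].astype(float)
        known = {"neutral_mass", "rt_min"}
    elif "mz" in df.columns and "adduct" in df.columns:
        mass = pd.Series(
            [neutral_from_mz(float(m), str(a)) for m, a in zip(df["mz"], df["adduct"])],
            index=df.index,
        )
        known = {"mz", "adduct", "rt_min"}
    else:
        raise FormatError(
            "need a 'neutral_mass' column or 'mz' + 'adduct' columns"
        )

    sample_cols = [c for c in df.columns if c not in known]
    unknown = [c for c in sample_cols if c not in metadata]
    if unknown:
        raise FormatError(
            f"area columns not present in sample metadata: {unknown}"
        )
    meta = pd.DataFrame({"neutral_mass": mass, "rt_min": df["rt_min"].astype(float)})
    areas = df[sample_cols].astype(float)
    return FeatureTable(meta, areas, dataset=dataset)


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS2 spectrum: peaks sorted by m/z, with precursor info."""

    precursor_mz: float
    rt_min: float
    peaks: tuple[tuple[float, float], ...]
    sample_id: str = ""
    feature_id: str = ""

    def __post_init__(self) -> None:
        peaks = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        for (m1, _), (m2, _) in zip(peaks, peaks[1:]):
            if abs(m2 - m1) < 1e-6:
                raise ValueError(f"duplicate peak m/z near {m1}")
        if any(i < 0 for _, i in peaks):
            raise ValueError("negative peak intensity")
        object.__setattr__(self, "peaks", peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def _spectrum_from_block(params: dict, mz, intensities, index: int) -> Spectrum | None:
    if len(mz) == 0:
        logger.warning("dropping empty spectrum block #%d", index)
        return None
    pepmass = params.get("pepmass", (0.0,))
    precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
    rt = params.get("rtinseconds")
    rt_min = float(rt) / 60.0 if rt is not None else float(params.get("rt_min", 0.0))
    return Spectrum(
        precursor_mz=precursor,
        rt_min=rt_min,
        peaks=tuple(zip(map(float, mz), map(float, intensities))),
        sample_id=str(params.get("sample_id", params.get("title", ""))),
        feature_id=str(params.get("feature_id", "")),
    )


def read_spectra(path) -> list[Spectrum]:
    """Read MS2 spectra from an MGF (or MSP) file.

    Peak lists are sorted on load; blocks with empty peak lists are dropped
    with a logged warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".msp":
        return _read_msp(path)
    from pyteomics import mgf

    spectra: list[Spectrum] = []
    try:
        with mgf.MGF(str(path)) as reader:
            for i, block in enumerate(reader):
                spec = _spectrum_from_block(
                    block["params"], block["m/z array"], block["intensity array"], i
                )
                if spec is not None:
                    spectra.append(spec)
    except Exception as exc:  # pyteomics raises various auxiliary errors
        raise FormatError(f"malformed MGF {path}: {exc}") from exc
    return spectra


def _read_msp(path) -> list[Spectrum]:
    from matchms.importing import load_from_msp

    spectra = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, ms in enumerate(load_from_msp(str(path))):
            if ms is None or len(ms.peaks.mz) == 0:
                logger.warning("dropping empty spectrum block #%d", i)
                continue
            meta = ms.metadata
            rt = meta.get("retention_time", meta.get("rt_min", 0.0)) or 0.0
            spectra.append(
                Spectrum(
                    precursor_mz=float(meta.get("precursor_mz", 0.0) or 0.0),
                    rt_min=float(rt),
                    peaks=tuple(zip(ms.peaks.mz, ms.peaks.intensities)),
                    sample_id=str(meta.get("sample_id", "")),
                    feature_id=str(meta.get("feature_id", "")),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    from pyteomics import mgf

    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensities,
                "params": {
                    "pepmass": s.precursor_mz,
                    "rtinseconds": s.rt_min * 60.0,
                    "title": s.sample_id,
                    "feature_id": s.feature_id,
                    "sample_id": s.sample_id,
                },
            }
        )
    mgf.write(entries, str(path), file_mode="w")
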