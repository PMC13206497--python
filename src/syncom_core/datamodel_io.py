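"""Shared data model and table I/O for the fermentation analysis pipeline.

Defines the in-memory containers used by every downstream stage — taxon
abundance tables, volatile-compound tables, physicochemical indicator
series, and the analysis configuration — plus TSV/JSON readers and writers
and the two closed-form quantification utilities (internal-standard
volatile quantification and protein relative utilization rate).

Conventions
-----------
* Abundance and volatile matrices are TSV: first column(s) identify the
  row (taxon, or compound + class), remaining columns are sample ids.
* Per-sample metadata (sample_id, day, replicate, group) lives in a
  sidecar TSV named ``<table>.meta.tsv`` so the matrix stays rectangular.
* Units are fixed: days for time, g/L for acids/sugars/nitrogen, and
  μg/L for volatile compounds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("syncom_core")

#: Controlled vocabulary of volatile compound classes.
VOLATILE_CLASSES = (
    "alcohol",
    "phenol",
    "pyrazine",
    "aldehyde",
    "ketone",
    "ester",
    "acid",
)

#: Known physicochemical indicators and their units.
INDICATOR_UNITS = {
    "glutamic_acid": "g/L",
    "umami_AA": "g/L",
    "4EG": "ug/L",
    "lactic_acid": "g/L",
    "reducing_sugar": "g/L",
    "amino_N": "g/L",
    "total_N": "g/L",
    "pH": "unitless",
}

_NORMALIZATION_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: time point, replicate and experimental group."""

    sample_id: str
    day: float
    replicate: int
    group: str = "control"

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"sample {self.sample_id!r}: day must be >= 0, got {self.day}")
        if self.replicate < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


def _check_samples(samples: Sequence[SampleMeta]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")


@dataclass
class AbundanceTable:
    """Taxon-by-sample abundance matrix (counts or relative abundances).

    ``level`` tags the taxonomic rank ("species" or "genus"); the core
    identification criteria run at species level while succession
    summaries use genus level.
    """

    taxa: list[str]
    samples: list[SampleMeta]
    values: np.ndarray  # shape (n_taxa, n_samples)
    level: str = "species"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxa), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        _check_samples(self.samples)
        if np.any(self.values < 0):
            t, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance for taxon {self.taxa[t]!r} in sample "
                f"{self.samples[s].sample_id!r}"
            )
        if self.normalized:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=_NORMALIZATION_TOL, rtol=0):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"normalized table but sample {self.samples[bad].sample_id!r} "
                    f"sums to {sums[bad]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def days(self) -> np.ndarray:
        return np.array([s.day for s in self.samples], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.sample_ids)

    def row(self, taxon: str) -> np.ndarray:
        return self.values[self.taxa.index(taxon)]

    def timepoint_means(self) -> pd.DataFrame:
        """Taxon-by-day matrix of replicate-averaged abundances."""
        df = self.to_dataframe()
        days = self.days
        out = {}
        for d in np.unique(days):
            out[float(d)] = df.loc[:, days == d].mean(axis=1)
        return pd.DataFrame(out)


@dataclass
class VolatileTable:
    """Volatile-compound-by-sample concentration matrix (μg/L)."""

    compounds: list[tuple[str, str]]  # (name, class)
    samples: list[SampleMeta]
    values: np.ndarray  # shape (n_compounds, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compounds), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.compounds)} compounds x {len(self.samples)} samples"
            )
        names = [n for n, _ in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compound names")
        for name, cls in self.compounds:
            if cls not in VOLATILE_CLASSES:
                raise ValueError(
                    f"compound {name!r} has unknown class {cls!r}; "
                    f"expected one of {VOLATILE_CLASSES}"
                )
        _check_samples(self.samples)
        if np.any(self.values < 0):
            c, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative concentration for compound {self.compounds[c][0]!r} "
                f"in sample {self.samples[s].sample_id!r}"
            )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.compounds]

    @property
    def classes(self) -> list[str]:
        return [c for _, c in self.compounds]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.sample_ids)


@dataclass
class IndicatorSeries:
    """Time series of one physicochemical indicator.

    Observations are (day, replicate, value) triples; the indicator name
    keys into :data:`INDICATOR_UNITS` when it is one of the standard
    fermentation indicators.
    """

    name: str
    observations: list[tuple[float, int, float]]
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError(f"indicator {self.name!r}: at least one observation required")
        if not self.unit:
            self.unit = INDICATOR_UNITS.get(self.name, "")
        if self.name == "pH":
            vals = [v for _, _, v in self.observations]
            if min(vals) <= 0 or max(vals) >= 14:
                raise ValueError(f"pH values must lie in (0, 14); got range "
                                 f"[{min(vals)}, {max(vals)}]")

    @property
    def days(self) -> np.ndarray:
        return np.unique([d for d, _, _ in self.observations])

    def timepoint_means(self) -> pd.Series:
        """Replicate-averaged value per day, indexed by day."""
        df = pd.DataFrame(self.observations, columns=["day", "replicate", "value"])
        return df.groupby("day")["value"].mean()


@dataclass
class AnalysisConfig:
    """Thresholds for every stage of the core-identification pipeline.

    Defaults encode the selection criteria: dominant microbes have mean
    relative abundance > 1% and are present in >= 80% of samples; hub
    microbes have more than 9 links in the q-controlled co-occurrence
    network (edges require |rho| > 0.6 and q < 0.05, with a stricter
    |rho| > 0.8, p < 0.01 rule for display networks); flavor-associated
    microbes correlate (|rho| > 0.5, p < 0.05, q < 0.05) with at least
    five volatile compounds.
    """

    dominance_abundance_threshold: float = 0.01
    dominance_prevalence_threshold: float = 0.8
    presence_epsilon: float = 0.0
    edge_r_threshold: float = 0.6
    edge_q_threshold: float = 0.05
    display_r_threshold: float = 0.8
    display_p_threshold: float = 0.01
    hub_degree_threshold: int = 9  # strict: hub iff degree > threshold
    flavor_r_threshold: float = 0.5
    flavor_p_threshold: float = 0.05
    flavor_q_threshold: float = 0.05
    flavor_min_volatiles: int = 5
    n_phases: int = 4
    omission_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dominance_abundance_threshold",
            "dominance_prevalence_threshold",
            "edge_q_threshold",
            "display_p_threshold",
            "flavor_p_threshold",
            "flavor_q_threshold",
            "omission_alpha",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("edge_r_threshold", "display_r_threshold", "flavor_r_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.presence_epsilon < 0:
            raise ValueError("presence_epsilon must be >= 0")
        if int(self.hub_degree_threshold) != self.hub_degree_threshold or self.hub_degree_threshold < 0:
            raise ValueError("hub_degree_threshold must be a non-negative integer")
        if self.flavor_min_volatiles < 1:
            raise ValueError("flavor_min_volatiles must be >= 1")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Quantification utilities
# ---------------------------------------------------------------------------


def quantify_volatile(peak_area: float, istd_area: float, istd_conc: float) -> float:
    """Internal-standard quantification of a volatile compound (μg/L).

    concentration = peak area of compound × internal-standard
    concentration / peak area of the internal standard.
    """
    if istd_area <= 0:
        raise ValueError(f"internal standard peak area must be > 0, got {istd_area}")
    return peak_area * istd_conc / istd_area


def protein_utilization(amino_acid_content: float, total_nitrogen: float) -> float:
    """Protein relative utilization rate (%) = (AA / TN) × 100."""
    if total_nitrogen <= 0:
        raise ValueError(f"total nitrogen must be > 0, got {total_nitrogen}")
    return amino_acid_content / total_nitrogen * 100.0


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Close each sample column to relative abundances summing to 1.

    Idempotent on already-normalized tables; preserves within-sample rank
    order of taxa. An all-zero sample cannot be closed and is an error.
    """
    sums = table.values.sum(axis=0)
    if np.any(sums <= 0):
        bad = int(np.argmax(sums <= 0))
        raise ValueError(
            f"sample {table.samples[bad].sample_id!r} has no positive abundance; "
            "cannot normalize"
        )
    return AbundanceTable(
        taxa=list(table.taxa),
        samples=list(table.samples),
        values=table.values / sums,
        level=table.level,
        normalized=True,
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.tsv")


def _write_meta(samples: Sequence[SampleMeta], path: Path) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.day, s.replicate, s.group) for s in samples],
        columns=["sample_id", "day", "replicate", "group"],
    )
    df.to_csv(path, sep="\t", index=False)


def _read_meta(path: Path, sample_ids: Iterable[str]) -> list[SampleMeta]:
    if not path.exists():
        raise FileNotFoundError(f"sample metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    by_id = {row.sample_id: row for row in df.itertuples(index=False)}
    metas = []
    for sid in sample_ids:
        if sid not in by_id:
            raise ValueError(f"no metadata for sample {sid!r} in {path}")
        r = by_id[sid]
        metas.append(SampleMeta(sample_id=sid, day=float(r.day),
                                replicate=int(r.replicate), group=str(r.group)))
    return metas


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    df = table.to_dataframe()
    df.index.name = f"taxon[{table.level}]" + ("|normalized" if table.normalized else "")
    df.to_csv(path, sep="\t", float_format="%.17g")
    _write_meta(table.samples, _meta_path(path))


def read_abundance_table(
    path: str | Path,
    level: str | None = None,
    metadata_path: str | Path | None = None,
) -> AbundanceTable:
    """Read a taxon-by-sample TSV plus its ``.meta.tsv`` sidecar.

    ``level`` overrides the level tag embedded in the header by
    :func:`write_abundance_table`; defaults to "species" when neither is
    available.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    header = df.index.name or ""
    normalized = header.endswith("|normalized")
    if level is None:
        if header.startswith("taxon[") and "]" in header:
            level = header[len("taxon["):header.index("]")]
        else:
            level = "species"
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value for taxon {df.index[r]!r} in sample {df.columns[c]!r}"
        )
    meta = _read_meta(
        Path(metadata_path) if metadata_path else _meta_path(path),
        [str(c) for c in df.columns],
    )
    return AbundanceTable(
        taxa=[str(i) for i in df.index],
        samples=meta,
        values=df.to_numpy(dtype=float),
        level=level,
        normalized=normalized,
    )


def write_volatile_table(table: VolatileTable, path: str | Path) -> None:
    path = Path(path)
    df = table.to_dataframe()
    df.insert(0, "class", table.classes)
    df.index.name = "compound"
    df.to_csv(path, sep="\t", float_format="%.17g")
    _write_meta(table.samples, _meta_path(path))


def read_volatile_table(
    path: str | Path, metadata_path: str | Path | None = None
) -> VolatileTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if "class" not in df.columns:
        raise ValueError(f"{path}: expected a 'class' column of compound classes")
    classes = df.pop("class")
    meta = _read_meta(
        Path(metadata_path) if metadata_path else _meta_path(path),
        [str(c) for c in df.columns],
    )
    return VolatileTable(
        compounds=[(str(n), str(c)) for n, c in zip(df.index, classes)],
        samples=meta,
        values=df.to_numpy(dtype=float),
    )


def write_indicator_series(series: Sequence[IndicatorSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for day, rep, value in s.observations:
            rows.append((s.name, s.unit, day, rep, value))
    pd.DataFrame(
        rows, columns=["indicator", "unit", "day", "replicate", "value"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_indicator_series(path: str | Path) -> list[IndicatorSeries]:
    df = pd.read_csv(path, sep="\t", dtype={"indicator": str, "unit": str},
                     float_precision="round_trip")
    df["unit"] = df["unit"].fillna("")
    out = []
    for name, grp in df.groupby("indicator", sort=False):
        obs = [
            (float(d), int(r), float(v))
            for d, r, v in zip(grp["day"], grp["replicate"], grp["value"])
        ]
        unit = str(grp["unit"].iloc[0])
        out.append(IndicatorSeries(name=str(name), observations=obs, unit=unit))
    return out


def write_omission_table(df: pd.DataFrame, path: str | Path) -> None:
    expected = ["group", "indicator", "replicate", "value"]
    if list(df.columns) != expected:
        raise ValueError(f"omission table must have columns {expected}")
    df.to_csv(path, sep="\t", index=False)


def read_omission_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "indicator": str},
                     float_precision="round_trip")
    expected = ["group", "indicator", "replicate", "value"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: omission table must have columns {expected}")
    return df


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_JSONEncoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
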