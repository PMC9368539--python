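"""Core record and scenario types plus their on-disk formats.

Concentration tables are plain UTF-8 CSV with a required header
``sample_id,source,region,tissue,concentration_ug_kg`` (decimal point, comma
separator).  Scenario configuration is YAML with flat, documented keys; absent
keys fall back to the study defaults (intake rate 10.54 g/day, body weights
70/20 kg, RfD 0.7 and TDI 0.3 μg/kg bw/day, 1000 iterations).
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .distributions import DistributionSpec, lognormal_from_moments, spec_from_moments

__all__ = [
    "Source",
    "Tissue",
    "ConcentrationRecord",
    "RatioSpec",
    "ExposureScenario",
    "SchemaError",
    "RecordError",
    "CSV_COLUMNS",
    "read_concentration_table",
    "write_concentration_table",
    "records_to_dataframe",
    "load_scenario",
]

CSV_COLUMNS = ["sample_id", "source", "region", "tissue", "concentration_ug_kg"]


class SchemaError(ValueError):
    """The table is missing a required column."""


class RecordError(ValueError):
    """A data row failed validation; the message names the 1-based row."""


class Source(str, enum.Enum):
    cultivated = "cultivated"
    market = "market"


class Tissue(str, enum.Enum):
    whole = "whole"
    abdominal_muscle = "abdominal_muscle"
    exoskeleton_head = "exoskeleton_head"
    exoskeleton_back = "exoskeleton_back"
    hepatopancreas = "hepatopancreas"
    other = "other"


class ConcentrationRecord(BaseModel):
    """One measured perchlorate concentration for one tissue of one sample.

    ``concentration`` is μg/kg wet weight.  When ``below_lod`` is true the
    stored concentration is the limit of detection, not a measurement;
    downstream statistics substitute LOD/2 for such records.
    """

    model_config = ConfigDict(frozen=True)

    sample_id: str
    source: Source
    region: str
    tissue: Tissue
    concentration: float = Field(ge=0)
    below_lod: bool = False

    @property
    def effective_concentration(self) -> float:
        """Value used in statistics: LOD/2 for censored records."""
        return self.concentration / 2.0 if self.below_lod else self.concentration


def read_concentration_table(
    path: str | Path, lod: float | None = None
) -> list[ConcentrationRecord]:
    """Read a concentration CSV into records, in file order.

    When ``lod`` (μg/kg, > 0) is given, rows whose concentration falls below
    it are flagged ``below_lod`` and carry the LOD as stored value.
    """
    if lod is not None and lod <= 0:
        raise ValueError("lod must be positive")
    df = pd.read_csv(path, dtype=str)
    for column in CSV_COLUMNS:
        if column not in df.columns:
            raise SchemaError(f"missing required column {column!r}")
    records: list[ConcentrationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            concentration = float(getattr(row, "concentration_ug_kg"))
        except (TypeError, ValueError) as exc:
            raise RecordError(f"row {i}: unparseable concentration") from exc
        if concentration < 0:
            raise RecordError(f"row {i}: negative concentration {concentration}")
        below_lod = lod is not None and concentration < lod
        try:
            records.append(
                ConcentrationRecord(
                    sample_id=str(row.sample_id),
                    source=row.source,
                    region=str(row.region),
                    tissue=row.tissue,
                    concentration=lod if below_lod else concentration,
                    below_lod=below_lod,
                )
            )
        except pydantic.ValidationError as exc:
            raise RecordError(f"row {i}: {exc.errors()[0]['msg']}") from exc
    return records


def write_concentration_table(
    records: Sequence[ConcentrationRecord], path: str | Path
) -> None:
    """Write records to the canonical CSV dialect (round-trips with reader)."""
    records_to_dataframe(records)[CSV_COLUMNS].to_csv(path, index=False)


def records_to_dataframe(records: Sequence[ConcentrationRecord]) -> pd.DataFrame:
    """Tabular view; includes the ``below_lod`` flag and effective values."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "source": [r.source.value for r in records],
            "region": [r.region for r in records],
            "tissue": [r.tissue.value for r in records],
            "concentration_ug_kg": [r.concentration for r in records],
            "below_lod": [r.below_lod for r in records],
            "effective_ug_kg": [r.effective_concentration for r in records],
        }
    )


class RatioSpec(BaseModel):
    """Tissue-to-body mass fraction, mean and SD (dimensionless)."""

    model_config = ConfigDict(frozen=True)

    mean: float = Field(gt=0, lt=1)
    sd: float = Field(ge=0)


def _default_cs_distributions() -> dict[Tissue, DistributionSpec]:
    # Edible-tissue concentrations (μg/kg): lognormals moment-matched to the
    # measured tissue means and SDs.
    return {
        Tissue.abdominal_muscle: lognormal_from_moments(20.98, 10.49),
        Tissue.hepatopancreas: lognormal_from_moments(10.21, 3.30),
    }


class ExposureScenario(BaseModel):
    """Every deterministic and stochastic input to the EDI simulation.

    Defaults encode the study conditions: adult per-capita crayfish
    consumption 10.54 g/day wet weight, abdominal-muscle and hepatopancreas
    mass fractions 20.00 ± 5.01% and 11.96 ± 1.93%, body weights 70 kg
    (adults) and 20 kg (children), RfD 0.7 and TDI 0.3 μg/kg bw/day, and
    1000 Latin-hypercube iterations.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    ir_total: float = Field(default=10.54, gt=0)
    ratio_muscle: RatioSpec = RatioSpec(mean=0.2000, sd=0.0501)
    ratio_hepatopancreas: RatioSpec = RatioSpec(mean=0.1196, sd=0.0193)
    bw: dict[str, float] = Field(default_factory=lambda: {"adults": 70.0, "children": 20.0})
    rfd: float = Field(default=0.7, gt=0)
    tdi: float = Field(default=0.3, gt=0)
    n_iterations: int = Field(default=1000, ge=2)
    seed: int = 0
    cs_distributions: dict[Tissue, DistributionSpec] = Field(
        default_factory=_default_cs_distributions
    )
    aggregation: str = "per_tissue_sum"
    single_tissue: Tissue = Tissue.hepatopancreas
    stochastic_ratios: bool = False

    @field_validator("bw")
    @classmethod
    def _positive_bw(cls, value: dict[str, float]) -> dict[str, float]:
        if not value:
            raise ValueError("bw: at least one population required")
        for population, weight in value.items():
            if weight <= 0:
                raise ValueError(f"bw.{population}: body weight must be positive")
        return value

    @field_validator("aggregation")
    @classmethod
    def _known_aggregation(cls, value: str) -> str:
        if value not in {"per_tissue_sum", "single_tissue"}:
            raise ValueError("aggregation: must be per_tissue_sum or single_tissue")
        return value

    @model_validator(mode="after")
    def _specs_available(self) -> "ExposureScenario":
        if self.aggregation == "single_tissue" and self.single_tissue not in self.cs_distributions:
            raise ValueError(
                f"cs_distributions: missing spec for single tissue {self.single_tissue.value}"
            )
        return self

    def tissue_ratio(self, tissue: Tissue) -> RatioSpec:
        if tissue == Tissue.abdominal_muscle:
            return self.ratio_muscle
        if tissue == Tissue.hepatopancreas:
            return self.ratio_hepatopancreas
        raise KeyError(f"no mass-fraction ratio for tissue {tissue.value}")


def _merge_bw(user: Mapping[str, float] | None) -> dict[str, float]:
    merged = {"adults": 70.0, "children": 20.0}
    if user:
        merged.update({str(k): float(v) for k, v in user.items()})
    return merged


def _parse_ratio(value: Any, default: RatioSpec) -> RatioSpec:
    if value is None:
        return default
    if isinstance(value, Mapping):
        return RatioSpec(mean=value.get("mean", default.mean), sd=value.get("sd", default.sd))
    return RatioSpec(mean=float(value), sd=default.sd)


def _parse_cs(value: Mapping[str, Any] | None) -> dict[Tissue, DistributionSpec]:
    if not value:
        return _default_cs_distributions()
    specs: dict[Tissue, DistributionSpec] = {}
    for tissue_label, entry in value.items():
        tissue = Tissue(tissue_label)
        family = entry.get("family", "lognormal")
        specs[tissue] = spec_from_moments(
            family, float(entry["mean"]), float(entry.get("sd", 0.0))
        )
    return specs


def load_scenario(path: str | Path) -> ExposureScenario:
    """Load a YAML scenario config; absent keys take the study defaults.

    Recognised keys: ``ir_total``, ``ratio_muscle`` / ``ratio_hepatopancreas``
    (mean/sd mappings), ``bw`` (population → kg), ``rfd``, ``tdi``,
    ``n_iterations``, ``seed``, ``aggregation``, ``single_tissue``,
    ``stochastic_ratios``, and ``cs_distributions`` (tissue → family/mean/sd).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ValueError("scenario config must be a mapping of keys to values")
    known = {
        "ir_total",
        "ratio_muscle",
        "ratio_hepatopancreas",
        "bw",
        "rfd",
        "tdi",
        "n_iterations",
        "seed",
        "aggregation",
        "single_tissue",
        "stochastic_ratios",
        "cs_distributions",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {
        "bw": _merge_bw(raw.get("bw")),
        "ratio_muscle": _parse_ratio(raw.get("ratio_muscle"), RatioSpec(mean=0.2000, sd=0.0501)),
        "ratio_hepatopancreas": _parse_ratio(
            raw.get("ratio_hepatopancreas"), RatioSpec(mean=0.1196, sd=0.0193)
        ),
        "cs_distributions": _parse_cs(raw.get("cs_distributions")),
    }
    for key in ("ir_total", "rfd", "tdi", "n_iterations", "seed", "aggregation",
                "single_tissue", "stochastic_ratios"):
        if key in raw:
            kwargs[key] = raw[key]
    try:
        return ExposureScenario(**kwargs)
    except pydantic.ValidationError as exc:
        first = exc.errors()[0]
        location = ".".join(str(part) for part in first["loc"])
        raise ValueError(f"invalid scenario config at {location}: {first['msg']}") from exc
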