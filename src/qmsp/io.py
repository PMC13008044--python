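"""CT-table and configuration I/O.

File dialect: comma-separated, UTF-8, dot decimal, header row
``sample_id,assay_id,replicate,ct,input_mass_pg,group``.  Undetermined
CTs (threshold never crossed) are serialized as the literal ``NA`` and
are never imputed.  Run configuration is a YAML document (see
:class:`RunConfig`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml

from .simulate import WellRecord

logger = logging.getLogger("qmsp")

CT_TABLE_COLUMNS = ["sample_id", "assay_id", "replicate", "ct", "input_mass_pg", "group"]
NA_LITERAL = "NA"


class CtTableError(ValueError):
    """Structurally invalid CT table (missing column, duplicate well, ...)."""


@dataclass
class CtTable:
    """An ordered collection of qPCR wells plus file-level metadata.

    (sample_id, assay_id, replicate) is unique; rows that failed
    validation on read are kept in ``rejects`` with a reason, never
    silently dropped.
    """

    records: list[WellRecord]
    run_id: str = ""
    notes: str = ""
    rejects: list[tuple[dict, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for r in self.records:
            key = (r.sample_id, r.assay_id, r.replicate)
            if key in seen:
                raise CtTableError(f"duplicate well {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_undetermined(self) -> int:
        return sum(r.ct is None for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "assay_id": [r.assay_id for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "ct": [math.nan if r.ct is None else r.ct for r in self.records],
                "input_mass_pg": [r.input_mass_pg for r in self.records],
                "group": [r.group for r in self.records],
            }
        )

    def wells(self, sample_id: str | None = None, assay_id: str | None = None) -> list[WellRecord]:
        out = self.records
        if sample_id is not None:
            out = [r for r in out if r.sample_id == sample_id]
        if assay_id is not None:
            out = [r for r in out if r.assay_id == assay_id]
        return out


def _parse_row(row: dict) -> WellRecord:
    ct_raw = str(row["ct"]).strip()
    if ct_raw == NA_LITERAL or ct_raw == "":
        ct: float | None = None
    else:
        ct = float(ct_raw)  # ValueError propagates to reject handling
        if ct <= 0:
            raise ValueError(f"CT must be positive, got {ct}")
    replicate = int(row["replicate"])
    if replicate < 1:
        raise ValueError(f"replicate must be >= 1, got {replicate}")
    mass = float(row["input_mass_pg"])
    if mass <= 0:
        raise ValueError(f"input_mass_pg must be positive, got {mass}")
    return WellRecord(
        sample_id=str(row["sample_id"]),
        assay_id=str(row["assay_id"]),
        replicate=replicate,
        ct=ct,
        input_mass_pg=mass,
        group=str(row["group"]),
    )


def read_ct_table(path: str | Path, run_id: str = "") -> CtTable:
    """Read and validate a CT table CSV.

    Missing required columns and duplicate (sample, assay, replicate)
    keys are hard errors; rows with unparseable or out-of-range fields
    go to ``table.rejects`` with a reason.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CtTableError(f"missing required column(s): {', '.join(missing)}")
    records: list[WellRecord] = []
    rejects: list[tuple[dict, str]] = []
    for row in df.to_dict(orient="records"):
        try:
            records.append(_parse_row(row))
        except (ValueError, KeyError) as exc:
            rejects.append((row, str(exc)))
    table = CtTable(records=records, run_id=run_id or path.stem, rejects=rejects)
    logger.info(
        "read %s: %d wells (%d undetermined, %d rejected)",
        path, len(records), table.n_undetermined, len(rejects),
    )
    return table


def write_ct_table(table: CtTable | Iterable[WellRecord], path: str | Path) -> None:
    """Write wells as CSV; undetermined CTs become the literal NA."""
    records = table.records if isinstance(table, CtTable) else list(table)
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "assay_id": r.assay_id,
                "replicate": r.replicate,
                "ct": NA_LITERAL if r.ct is None else repr(float(r.ct)),
                "input_mass_pg": repr(float(r.input_mass_pg)),
                "group": r.group,
            }
        )
    pd.DataFrame(rows, columns=CT_TABLE_COLUMNS).to_csv(path, index=False)


@dataclass(frozen=True)
class AssayConfig:
    """Declared properties of one assay as used by the pipeline."""

    assay_id: str
    role: str  # MSP | MIP
    element: str  # LINE1 | ALU
    efficiency: float | None = None  # fractional E from a standard curve
    ct_cutoff: float | None = None


@dataclass
class RunConfig:
    """Pipeline run configuration.

    ``formula`` maps element name to AUTO | LIVAK | PFAFFL; AUTO defers
    to the dilution-series selection rule and therefore requires
    standard-curve data.
    """

    assays: list[AssayConfig]
    calibrator_sample_id: str = "calibrator"
    formula: dict[str, str] = field(default_factory=lambda: {"LINE1": "AUTO", "ALU": "AUTO"})
    mixture_levels_pct: list[float] = field(default_factory=lambda: [0.0, 12.5, 25.0, 50.0, 75.0, 100.0])
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate assay ids in config")
        for el, f in self.formula.items():
            if f.upper() not in ("AUTO", "LIVAK", "PFAFFL"):
                raise ValueError(f"unknown formula {f!r} for element {el}")

    def assay(self, assay_id: str) -> AssayConfig:
        for a in self.assays:
            if a.assay_id == assay_id:
                return a
        raise KeyError(f"assay {assay_id!r} not declared in config")

    def assays_by(self, role: str | None = None, element: str | None = None) -> list[AssayConfig]:
        out = self.assays
        if role is not None:
            out = [a for a in out if a.role.upper() == role.upper()]
        if element is not None:
            out = [a for a in out if a.element.upper() == element.upper()]
        return out

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        assays = [AssayConfig(**a) for a in doc.pop("assays")]
        return cls(assays=assays, **doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _format_value(v: Any) -> Any:
    if isinstance(v, float):
        if math.isnan(v):
            return NA_LITERAL
        return float(f"{v:.6g}")
    return v


def results_to_dataframe(results: Sequence[Any]) -> pd.DataFrame:
    """Dataclass results -> DataFrame with deterministic column order."""
    if len(results) == 0:
        raise ValueError("results must be non-empty")
    rows = [dataclasses.asdict(r) for r in results]
    cols = list(rows[0].keys())
    df = pd.DataFrame(rows, columns=cols)
    return df


def write_results(results: Sequence[Any], path: str | Path, format: str = "tsv") -> None:
    """Serialize result records as TSV or JSON.

    Floats are written at 6 significant digits for diffability; both
    formats encode identical content.
    """
    df = results_to_dataframe(results)
    rows = [{k: _format_value(v) for k, v in row.items()} for row in df.to_dict(orient="records")]
    path = Path(path)
    if format == "tsv":
        pd.DataFrame(rows, columns=df.columns).to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}; expected tsv or json")
    logger.info("wrote %d result rows to %s (%s)", len(rows), path, format)
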