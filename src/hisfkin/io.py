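"""File formats, run configuration and reports.

CSV dialect: '#'-prefixed ``key: value`` metadata header lines (values are
JSON where they are structured), then a comma-separated table with a header
row and '.' decimals. The ``kind`` metadata key selects the object type:
``trace``, ``progress`` or ``titration``. Reports are deterministic JSON
(sorted keys) plus per-trace residual CSVs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .titration import TitrationSeries
from .traces import Trace
from .turnover import ProgressCurve
from .util import ValidationError

__all__ = ["RunConfig", "read_trace_csv", "write_trace_csv", "write_report"]

_JSON_KEYS = {"mix", "totals", "extra", "corrections"}


@dataclass
class RunConfig:
    """Declarative description of one analysis run (fit or generation)."""

    task: str
    seed: int
    inputs: list[str] = field(default_factory=list)
    scheme: str | None = None
    parameters: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "seed" not in doc:
            raise ValidationError("config must set an explicit seed")
        return cls(**doc)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "task": self.task,
                "seed": self.seed,
                "inputs": list(self.inputs),
                "scheme": self.scheme,
                "parameters": self.parameters,
                "options": self.options,
                "output_dir": self.output_dir,
            },
            sort_keys=False,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _meta_lines(meta: dict) -> list[str]:
    lines = []
    for k, v in meta.items():
        if v is None:
            continue
        if k in _JSON_KEYS or isinstance(v, (dict, list)):
            v = json.dumps(v, sort_keys=True)
        lines.append(f"# {k}: {v}")
    return lines


def _parse_header(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" not in body:
                continue
            k, v = body.split(":", 1)
            k, v = k.strip(), v.strip()
            if k in _JSON_KEYS or v[:1] in "[{":
                try:
                    meta[k] = json.loads(v)
                    continue
                except json.JSONDecodeError:
                    pass
            for cast in (int, float):
                try:
                    meta[k] = cast(v)
                    break
                except ValueError:
                    continue
            else:
                meta[k] = {"true": True, "false": False}.get(v.lower(), v)
    return meta, n_header


def write_trace_csv(obj, path: str | Path) -> None:
    """Serialize a Trace, ProgressCurve or TitrationSeries to the CSV dialect."""
    path = Path(path)
    if isinstance(obj, Trace):
        meta = {
            "kind": "trace",
            "label": obj.label,
            "observable": obj.observable,
            "dead_time_s": obj.dead_time,
            "sigma": obj.sigma,
            "dead_time_obscured": obj.dead_time_obscured,
            "totals": obj.totals,
            "mix": obj.mix,
            "extra": obj.extra or None,
        }
        df = pd.DataFrame({"time_s": obj.time, "signal": obj.signal})
    elif isinstance(obj, ProgressCurve):
        meta = {
            "kind": "progress",
            "label": obj.label,
            "E_tot_uM": obj.e_tot,
            "S0_uM": obj.s0,
            "mode": obj.mode,
            "ammonia": obj.ammonia_present,
            "unit": obj.unit,
        }
        col = "A300" if obj.unit == "A300" else "conc_uM"
        df = pd.DataFrame({"time_s": obj.time, col: obj.values})
    elif isinstance(obj, TitrationSeries):
        meta = {
            "kind": "titration",
            "label": obj.label,
            "ligand": obj.ligand,
            "protein_uM": obj.protein_conc,
            "co_ligand": obj.co_ligand,
            "co_ligand_uM": obj.co_ligand_conc,
            "corrections": obj.corrections,
        }
        cols = {"conc_uM": obj.conc, "F": obj.fluorescence}
        if obj.added_volume is not None:
            cols["added_volume_uL"] = obj.added_volume
        df = pd.DataFrame(cols)
    else:
        raise ValidationError(f"cannot serialize {type(obj).__name__}")
    with open(path, "w") as fh:
        fh.write("\n".join(_meta_lines(meta)) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_trace_csv(path: str | Path):
    """Read a CSV in the package dialect back into its typed object."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, n_header = _parse_header(path)
    kind = meta.get("kind")
    if kind is None:
        raise ValidationError(f"{path}: missing required metadata key 'kind'")
    df = pd.read_csv(path, skiprows=n_header)

    if kind == "trace":
        t = df["time_s"].to_numpy()
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValidationError(
                f"{path}: time not strictly increasing at data row {bad[0] + 2}"
            )
        known = {
            "kind", "label", "observable", "dead_time_s", "sigma",
            "dead_time_obscured", "totals", "mix", "extra",
        }
        extra = dict(meta.get("extra") or {})
        extra.update({k: v for k, v in meta.items() if k not in known})
        return Trace(
            time=t,
            signal=df["signal"].to_numpy(),
            totals=dict(meta.get("totals") or {}),
            observable=meta.get("observable", "fluorescence"),
            mix=meta.get("mix"),
            dead_time=float(meta.get("dead_time_s", 0.0)),
            sigma=meta.get("sigma"),
            dead_time_obscured=bool(meta.get("dead_time_obscured", False)),
            label=str(meta.get("label", "")),
            extra=extra,
        )
    if kind == "progress":
        for key in ("E_tot_uM", "S0_uM", "mode"):
            if key not in meta:
                raise ValidationError(f"{path}: missing required metadata key {key!r}")
        unit = meta.get("unit", "A300")
        col = "A300" if unit == "A300" else "conc_uM"
        return ProgressCurve(
            time=df["time_s"].to_numpy(),
            values=df[col].to_numpy(),
            e_tot=float(meta["E_tot_uM"]),
            s0=float(meta["S0_uM"]),
            mode=str(meta["mode"]),
            ammonia_present=bool(meta.get("ammonia", True)),
            unit=unit,
            label=str(meta.get("label", "")),
        )
    if kind == "titration":
        return TitrationSeries(
            ligand=str(meta.get("ligand", "")),
            conc=df["conc_uM"].to_numpy(),
            fluorescence=df["F"].to_numpy(),
            protein_conc=float(meta.get("protein_uM", 0.0)),
            co_ligand=meta.get("co_ligand") or None,
            co_ligand_conc=float(meta.get("co_ligand_uM", 0.0)),
            added_volume=(
                df["added_volume_uL"].to_numpy() if "added_volume_uL" in df else None
            ),
            corrections=list(meta.get("corrections") or []),
            label=str(meta.get("label", "")),
        )
    raise ValidationError(f"{path}: unknown kind {kind!r}")


def write_report(results: dict, path: str | Path, config: RunConfig | None = None) -> Path:
    """Write a deterministic JSON report (+ residual CSVs for fit results).

    ``results`` maps section names to result objects exposing ``to_dict``
    (or plain JSON-serializable values). Returns the report path.
    """
    if not results:
        raise ValidationError("empty results: nothing to report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "software": {"name": "hisfkin", "version": __version__},
        "config_hash": config.config_hash() if config else None,
        "results": {},
    }
    for name, obj in results.items():
        doc["results"][name] = obj.to_dict() if hasattr(obj, "to_dict") else obj
        residuals = getattr(obj, "residuals", None)
        if residuals is not None:
            res_path = path.with_name(path.stem + f".{name}.residuals.csv")
            if isinstance(residuals, list):
                frames = [
                    pd.DataFrame({"trace": i, "residual": r})
                    for i, r in enumerate(residuals)
                ]
                pd.concat(frames).to_csv(res_path, index=False)
            else:
                pd.DataFrame({"residual": np.asarray(residuals)}).to_csv(
                    res_path, index=False
                )
    path.write_text(json.dumps(doc, indent=2, sort_keys=True, default=float) + "\n")
    return path
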