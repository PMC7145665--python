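"""File formats: trace CSV, gel TSV, analogue TSV, YAML scenario configs.

All tabular files are UTF-8 with a header row; metadata travels in leading
``# key: value`` comment lines. Time is always in seconds; concentrations
are μM internally, with nM inputs accepted via a ``units: nM`` metadata
key (converted on read).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .observables import Trace, ProductTimeCourse
from .transient import GelTable
from .lfer import AnalogueRecord

__all__ = [
    "write_trace",
    "read_trace_table",
    "write_product_course",
    "read_product_table",
    "read_gel_table",
    "write_gel_table",
    "read_analogue_table",
    "write_analogue_table",
    "load_scenario",
]

PathLike = Union[str, Path]

# metadata keys holding concentrations, scaled on nM→μM conversion
_CONC_KEYS = ("dntp_conc", "enzyme_total", "dna_total")


def _format_meta(meta: dict) -> list[str]:
    lines = []
    for k, v in meta.items():
        lines.append(f"# {k}: {json.dumps(v) if isinstance(v, (dict, list)) else v}")
    return lines


def _parse_header(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    n_skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if ":" not in body:
                continue
            k, v = body.split(":", 1)
            v = v.strip()
            try:
                meta[k.strip()] = json.loads(v)
            except (json.JSONDecodeError, ValueError):
                meta[k.strip()] = v
    return meta, n_skip


def _convert_units(meta: dict) -> dict:
    units = str(meta.pop("units", "uM")).lower()
    if units in ("um", "μm", "micromolar"):
        return meta
    if units in ("nm", "nanomolar"):
        for key in _CONC_KEYS:
            if key in meta:
                meta[key] = float(meta[key]) * 1e-3
        return meta
    raise ValueError(f"unsupported concentration units {units!r} (use uM or nM)")


def _check_time(t: np.ndarray, path: Path) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: time not strictly increasing at table row {int(bad[0]) + 3} "
            f"(t={float(t[bad[0] + 1])!r} after t={float(t[bad[0]])!r})"
        )


def write_trace(trace: Trace, path: PathLike) -> None:
    path = Path(path)
    lines = _format_meta(trace.meta) + ["time_s,signal"]
    for t, s in zip(trace.time, trace.signal):
        lines.append(f"{float(t)!r},{float(s)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace_table(path: PathLike) -> Trace:
    path = Path(path)
    meta, n_skip = _parse_header(path)
    df = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
    if "time_s" not in df.columns or "signal" not in df.columns:
        raise ValueError(f"{path}: expected columns time_s, signal; got {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    _check_time(t, path)
    return Trace(time=t, signal=df["signal"].to_numpy(dtype=float), meta=_convert_units(meta))


def write_product_course(tc: ProductTimeCourse, path: PathLike) -> None:
    path = Path(path)
    lines = _format_meta(tc.meta) + ["time_s,fraction_product"]
    for t, f in zip(tc.time, tc.fraction_product):
        lines.append(f"{float(t)!r},{float(f)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_product_table(path: PathLike) -> ProductTimeCourse:
    path = Path(path)
    meta, n_skip = _parse_header(path)
    df = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
    if "time_s" not in df.columns or "fraction_product" not in df.columns:
        raise ValueError(
            f"{path}: expected columns time_s, fraction_product; got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    _check_time(t, path)
    return ProductTimeCourse(
        time=t,
        fraction_product=df["fraction_product"].to_numpy(dtype=float),
        meta=_convert_units(meta),
    )


def write_gel_table(gel: GelTable, path: PathLike) -> None:
    df = gel.bands.copy()
    df.insert(0, "time_s", gel.time)
    df["substrate"] = gel.substrate
    Path(path).write_text(df.to_csv(sep="\t", index=False), encoding="utf-8")


def read_gel_table(path: PathLike) -> GelTable:
    """TSV layout: time_s, then one column per product band, last column substrate."""
    path = Path(path)
    meta, n_skip = _parse_header(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_skip, float_precision="round_trip")
    if df.columns[0] != "time_s" or df.columns[-1] != "substrate":
        raise ValueError(
            f"{path}: expected first column time_s and last column substrate, got {list(df.columns)}"
        )
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need at least one band column")
    t = df["time_s"].to_numpy(dtype=float)
    _check_time(t, path)
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if (values < 0).any():
        row = int(np.argwhere(values < 0)[0, 0]) + 2
        raise ValueError(f"{path}: negative intensity at data row {row}")
    return GelTable(
        time=t,
        bands=df.iloc[:, 1:-1],
        substrate=df["substrate"].to_numpy(dtype=float),
    )


def write_analogue_table(records, path: PathLike) -> None:
    lines = ["label\tpKa4\tkpol\tkpol_se"]
    for r in records:
        se = "" if r.kpol_se is None else repr(float(r.kpol_se))
        lines.append(f"{r.label}\t{float(r.pKa4)!r}\t{float(r.kpol)!r}\t{se}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_analogue_table(path: PathLike) -> list[AnalogueRecord]:
    """TSV layout: label, pKa4, kpol and optionally kpol_se."""
    path = Path(path)
    _, n_skip = _parse_header(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_skip, float_precision="round_trip")
    required = {"label", "pKa4", "kpol"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    records = []
    for i, row in df.iterrows():
        se = row.get("kpol_se")
        se = None if se is None or pd.isna(se) else float(se)
        try:
            records.append(
                AnalogueRecord(
                    label=str(row["label"]), pKa4=float(row["pKa4"]),
                    kpol=float(row["kpol"]), kpol_se=se,
                )
            )
        except ValueError as e:
            raise ValueError(f"{path}: data row {i + 2}: {e}") from e
    return records


def load_scenario(path: PathLike) -> dict:
    """Load a YAML scenario config for the CLI pipeline."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "run" not in cfg:
        raise ValueError(f"{path}: scenario config must be a mapping with a 'run' key")
    return cfg
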