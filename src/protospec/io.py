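"""Reading and writing titration tables, model files and run configs.

Titration files are delimited text with a header row, columns
``volume_mL`` then exactly one of ``emf_mV`` or ``pH``.  Metadata (the
solution state) travels in one of two equivalent dialects:

* **header dialect** — ``#key=value`` comment lines at the top of the
  data file itself;
* **sidecar dialect** — a YAML file next to the data holding the same
  keys.

Both dialects round-trip bit-exactly: floats are serialized with
``repr``, which is the shortest digit string that recovers the value.
Model and composition files are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .calibrate import ElectrodeModel
from .errors import DialectError, MalformedFileError
from .groups import NmrComposition
from .speciation import AcidSite, ProtonationModel, SolutionState, TitrationDataset

__all__ = [
    "read_titration",
    "write_titration",
    "read_model",
    "write_model",
    "read_electrode",
    "write_electrode",
    "read_composition",
    "write_composition",
]

_STATE_KEYS = {
    "v0": float,
    "sbo_conc": float,
    "c_strong_acid": float,
    "titrant_conc": float,
    "titrant_sign": int,
    "pKw": float,
    "temperature_C": float,
    "ionic_strength": float,
}


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# titration files


def write_titration(
    dataset: TitrationDataset,
    path: str | Path,
    dialect: str = "header",
    column: str | None = None,
) -> Path:
    """Write a dataset in the canonical text layout.

    ``column`` picks which reading to store when both are present
    (``"emf_mV"`` or ``"pH"``); default prefers EMF.
    """
    path = Path(path)
    if column is None:
        column = "emf_mV" if dataset.emf_mV is not None else "pH"
    values = dataset.emf_mV if column == "emf_mV" else dataset.ph
    if values is None:
        raise DialectError(f"dataset has no {column} readings")

    state = dataset.state
    meta_items = {k: getattr(state, k) for k in _STATE_KEYS}
    prov = dataset.meta.get("provenance")

    lines = []
    if dialect == "header":
        for k, v in meta_items.items():
            lines.append(f"#{k}={_fmt(v) if isinstance(v, float) else v}")
        if prov is not None:
            lines.append(f"#provenance_json={json.dumps(prov, sort_keys=True)}")
    elif dialect == "sidecar":
        side = {k: v for k, v in meta_items.items()}
        if prov is not None:
            side["provenance"] = prov
        path.with_suffix(path.suffix + ".meta.yaml").write_text(
            yaml.safe_dump(side, sort_keys=True)
        )
    else:
        raise DialectError(f"unknown dialect {dialect!r}")

    lines.append(f"volume_mL,{column}")
    for v, y in zip(dataset.volume_mL, values):
        lines.append(f"{_fmt(v)},{_fmt(y)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_titration(path: str | Path, sidecar: str | Path | None = None) -> TitrationDataset:
    """Parse a titration file in either metadata dialect.

    When ``sidecar`` is omitted a ``<name>.meta.yaml`` neighbor is used
    if present; otherwise metadata comes from ``#key=value`` lines.
    """
    path = Path(path)
    meta: dict = {}
    prov = None

    if sidecar is None:
        candidate = path.with_suffix(path.suffix + ".meta.yaml")
        sidecar = candidate if candidate.exists() else None
    if sidecar is not None:
        side = yaml.safe_load(Path(sidecar).read_text()) or {}
        prov = side.pop("provenance", None)
        meta.update(side)

    header: list[str] | None = None
    volumes: list[float] = []
    readings: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key == "provenance_json":
                    prov = json.loads(val)
                elif key in _STATE_KEYS and key not in meta:
                    try:
                        meta[key] = _STATE_KEYS[key](val)
                    except ValueError as err:
                        raise MalformedFileError(f"bad value for {key}: {val!r}", lineno) from err
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            if len(header) != 2 or header[0] != "volume_mL":
                raise DialectError(
                    f"{path}: header must be 'volume_mL,<emf_mV|pH>', got {line!r}"
                )
            if header[1] not in ("emf_mV", "pH"):
                raise DialectError(f"{path}: unknown reading column {header[1]!r}")
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise MalformedFileError(f"{path}: expected 2 fields, got {len(parts)}", lineno)
        try:
            v, y = float(parts[0]), float(parts[1])
        except ValueError as err:
            raise MalformedFileError(f"{path}: non-numeric row {line!r}", lineno) from err
        if volumes and v <= volumes[-1]:
            raise MalformedFileError(
                f"{path}: volume {v} not strictly increasing after {volumes[-1]}", lineno
            )
        volumes.append(v)
        readings.append(y)

    if header is None:
        raise DialectError(f"{path}: no header row found")
    state = SolutionState(**{k: meta[k] for k in _STATE_KEYS if k in meta})
    ds_meta = {"source": str(path)}
    if prov is not None:
        ds_meta["provenance"] = prov
    kwargs = {"ph": np.array(readings)} if header[1] == "pH" else {"emf_mV": np.array(readings)}
    return TitrationDataset(
        volume_mL=np.array(volumes), state=state, meta=ds_meta, **kwargs
    )


# ---------------------------------------------------------------------------
# model / electrode / composition files


def write_model(model: ProtonationModel, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "name": model.name,
        "sites": [
            {
                "id": s.site_id,
                "logbeta": [float(x) for x in s.cum_logbeta],
                "conc_mmol_per_g": float(s.conc_per_gram),
            }
            for s in model.sites
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_model(path: str | Path) -> ProtonationModel:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        sites = tuple(
            AcidSite(s["id"], tuple(s["logbeta"]), s["conc_mmol_per_g"])
            for s in doc["sites"]
        )
        return ProtonationModel(doc["name"], sites)
    except (KeyError, TypeError) as err:
        raise MalformedFileError(f"{path}: invalid model file ({err})") from err


def write_electrode(electrode: ElectrodeModel, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "e0": float(electrode.e0),
        "slope": float(electrode.slope),
        "j_a": float(electrode.j_a),
        "pKw": float(electrode.pKw),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def read_electrode(path: str | Path) -> ElectrodeModel:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return ElectrodeModel(**doc)
    except TypeError as err:
        raise MalformedFileError(f"{path}: invalid electrode file ({err})") from err


def write_composition(comp: NmrComposition, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "name": comp.name,
        "ash_pct": comp.ash_pct,
        "pct_C": comp.pct_C,
        "pct_N": comp.pct_N,
        "mole_fractions": dict(comp.mole_fractions),
        "cmc_g_per_L": comp.cmc,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_composition(path: str | Path) -> NmrComposition:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return NmrComposition(
            name=doc["name"],
            pct_C=doc["pct_C"],
            pct_N=doc["pct_N"],
            mole_fractions=dict(doc.get("mole_fractions", {})),
            ash_pct=doc.get("ash_pct", 0.0),
            cmc=doc.get("cmc_g_per_L"),
        )
    except (KeyError, TypeError) as err:
        raise MalformedFileError(f"{path}: invalid composition file ({err})") from err
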