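"""Readers, writers and run configuration for the analysis pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .curves import ScatteringCurve, WindowRules

__all__ = [
    "read_fasta",
    "read_sans_curve",
    "write_sans_curve",
    "CurveEntry",
    "RunConfig",
    "load_config",
    "dump_config",
    "config_hash",
]


def read_fasta(path: str) -> dict[str, str]:
    """Minimal FASTA reader: returns {record id: sequence}."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before any FASTA header")
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def read_sans_curve(
    path: str,
    f_d2o: float = 0.0,
    conc: float = 1.0,
    label: str = "",
    q_unit: str = "1/A",
) -> ScatteringCurve:
    """Read a reduced 1-D SANS curve from 3-4 column text.

    Whitespace- or comma-delimited, ``#`` comment lines; columns are
    q, I, sigma [, dq].  q in inverse Angstrom by default; pass
    ``q_unit="1/nm"`` to convert on read.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{ln}: expected 3-4 columns, got {len(parts)}")
            try:
                rows.append([float(x) for x in parts[:3]])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric value ({exc})") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    q = arr[:, 0]
    if q_unit == "1/nm":
        q = q / 10.0
    elif q_unit != "1/A":
        raise ValueError(f"unknown q unit {q_unit!r}")
    return ScatteringCurve(q=q, I=arr[:, 1], sigma=arr[:, 2],
                           f_D2O=f_d2o, conc=conc, label=label)


def write_sans_curve(curve: ScatteringCurve, path: str) -> None:
    """Write q/I/sigma as whitespace text with a metadata comment header."""
    with open(path, "w") as fh:
        fh.write(f"# f_D2O = {curve.f_D2O}\n# conc = {curve.conc} mg/ml\n")
        fh.write(f"# label = {curve.label}\n# q(1/A)  I  sigma\n")
        for q, i, s in zip(curve.q, curve.I, curve.sigma):
            fh.write(f"{q:.6e} {i:.6e} {s:.6e}\n")


@dataclass(frozen=True)
class CurveEntry:
    path: str
    f_d2o: float
    conc: float
    label: str = ""


_KNOWN_KEYS = {
    "curves", "output_dir", "seed", "guinier_qmin_rg", "guinier_qmax_rg",
    "guinier_qmax_rg_tolerance", "stuhrmann_linear_margin", "labile_exchange",
    "q_unit", "structure", "sequences",
}
_CURVE_KEYS = {"path", "f_d2o", "conc", "label"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    curves: list[CurveEntry]
    output_dir: str = "results"
    seed: int = 0
    guinier_qmin_rg: tuple[float, float] = (0.15, 0.57)
    guinier_qmax_rg: tuple[float, float] = (0.39, 1.3)
    guinier_qmax_rg_tolerance: float = 1.4
    stuhrmann_linear_margin: float = 0.02
    labile_exchange: float = 0.95
    q_unit: str = "1/A"
    structure: str | None = None
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def window_rules(self) -> WindowRules:
        return WindowRules(
            qmin_rg=tuple(self.guinier_qmin_rg),
            qmax_rg=tuple(self.guinier_qmax_rg),
            qmax_rg_tolerance=self.guinier_qmax_rg_tolerance,
        )


def load_config(path: str, check_files: bool = True) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected exhaustively; referenced files must exist
    (disable with ``check_files=False`` for round-trip tests).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    errors = [f"unknown key {k!r}" for k in raw if k not in _KNOWN_KEYS]
    entries: list[CurveEntry] = []
    for i, item in enumerate(raw.get("curves", [])):
        bad = [k for k in item if k not in _CURVE_KEYS]
        errors.extend(f"curves[{i}]: unknown key {k!r}" for k in bad)
        missing = [k for k in ("path", "f_d2o", "conc") if k not in item]
        errors.extend(f"curves[{i}]: missing key {k!r}" for k in missing)
        if not bad and not missing:
            entries.append(CurveEntry(path=str(item["path"]),
                                      f_d2o=float(item["f_d2o"]),
                                      conc=float(item["conc"]),
                                      label=str(item.get("label", ""))))
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    cfg = RunConfig(curves=entries)
    for key in _KNOWN_KEYS - {"curves"}:
        if key in raw:
            val = raw[key]
            if key in ("guinier_qmin_rg", "guinier_qmax_rg"):
                val = tuple(float(x) for x in val)
            setattr(cfg, key, val)
    if not (0 <= cfg.labile_exchange <= 1):
        raise ValueError(f"{path}: labile_exchange outside [0, 1]")
    if check_files:
        missing = [e.path for e in cfg.curves if not Path(e.path).exists()]
        if cfg.structure and not Path(cfg.structure).exists():
            missing.append(cfg.structure)
        missing += [p for p in cfg.sequences.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError("missing input files: " + ", ".join(missing))
    return cfg


def dump_config(cfg: RunConfig, path: str) -> None:
    data = {
        "curves": [asdict(e) for e in cfg.curves],
        "output_dir": cfg.output_dir,
        "seed": cfg.seed,
        "guinier_qmin_rg": list(cfg.guinier_qmin_rg),
        "guinier_qmax_rg": list(cfg.guinier_qmax_rg),
        "guinier_qmax_rg_tolerance": cfg.guinier_qmax_rg_tolerance,
        "stuhrmann_linear_margin": cfg.stuhrmann_linear_margin,
        "labile_exchange": cfg.labile_exchange,
        "q_unit": cfg.q_unit,
    }
    if cfg.structure:
        data["structure"] = cfg.structure
    if cfg.sequences:
        data["sequences"] = cfg.sequences
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the configuration for output provenance."""
    blob = yaml.safe_dump({
        "curves": [asdict(e) for e in cfg.curves],
        "output_dir": cfg.output_dir, "seed": cfg.seed,
        "guinier_qmin_rg": list(cfg.guinier_qmin_rg),
        "guinier_qmax_rg": list(cfg.guinier_qmax_rg),
        "guinier_qmax_rg_tolerance": cfg.guinier_qmax_rg_tolerance,
        "stuhrmann_linear_margin": cfg.stuhrmann_linear_margin,
        "labile_exchange": cfg.labile_exchange, "q_unit": cfg.q_unit,
        "structure": cfg.structure, "sequences": cfg.sequences,
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
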