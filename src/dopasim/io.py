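"""Readers, writers and run configuration for the simulation pipeline.

Coupling matrices and BOLD panels travel as delimited text (tab or comma,
header optional), region manifests as two-column text plus named roles, and
run configurations as YAML whose blocks mirror the pipeline stages.  All
readers validate; all writers round-trip to full printed precision.
"""

from __future__ import annotations

import json
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hemodynamics import BoldSignal
from .params import CouplingMatrix, ModelParameters, ParameterError, RegionSet
from .synthetic_inputs import ExperimentConfig

__all__ = [
    "read_matrix", "write_matrix",
    "read_manifest", "write_manifest",
    "read_bold", "write_bold",
    "load_run_config", "save_run_config", "RunConfigError",
]


class RunConfigError(ParameterError):
    """A run configuration file is malformed."""


def _detect_delimiter(line: str) -> str:
    return "," if line.count(",") >= line.count("\t") else "\t"


def read_matrix(path) -> CouplingMatrix:
    """Read a square nonnegative matrix from delimited text.

    A non-numeric first row is treated as a header and ignored for values.
    Ragged rows, non-numeric cells, non-square shapes and negative entries
    are rejected with row/column context.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coupling matrix file not found: {path}")
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ParameterError(f"{path}: empty matrix file")
    delim = _detect_delimiter(lines[0])

    def parse(ln: str):
        return [cell.strip() for cell in ln.split(delim)]

    start = 0
    try:
        [float(c) for c in parse(lines[0])]
    except ValueError:
        start = 1  # header row
    rows = []
    width = None
    for r, ln in enumerate(lines[start:], start=start + 1):
        cells = parse(ln)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ParameterError(
                f"{path}: ragged row {r} ({len(cells)} cells, expected {width})")
        row = []
        for c, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise ParameterError(
                    f"{path}: non-numeric cell at row {r}, column {c}: "
                    f"{cell!r}") from None
        rows.append(row)
    m = np.array(rows)
    if m.shape[0] != m.shape[1]:
        raise ParameterError(f"{path}: matrix is {m.shape[0]}x{m.shape[1]}, "
                             "expected square")
    if np.any(m < 0):
        i, j = np.argwhere(m < 0)[0]
        raise ParameterError(
            f"{path}: negative entry at row {i + 1}, column {j + 1}")
    return CouplingMatrix(weights=m, largest_row_sum=float(m.sum(axis=1).max()))


def write_matrix(C: CouplingMatrix, path, labels=None) -> None:
    """Write a coupling matrix as tab-delimited text (header = labels)."""
    path = Path(path)
    header = "\t".join(labels) + "\n" if labels is not None else ""
    body = "\n".join("\t".join(f"{v:.17g}" for v in row)
                     for row in C.weights)
    path.write_text(header + body + "\n")


def write_manifest(regions: RegionSet, path) -> None:
    roles = {regions.lmc_left: "lmc_left", regions.lmc_right: "lmc_right",
             regions.snc_left: "snc_left", regions.snc_right: "snc_right"}
    lines = ["index\tlabel\trole"]
    for i, lab in enumerate(regions.labels):
        lines.append(f"{i}\t{lab}\t{roles.get(i, '-')}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path) -> RegionSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"region manifest not found: {path}")
    df = pd.read_csv(path, sep="\t")
    for col in ("index", "label", "role"):
        if col not in df.columns:
            raise ParameterError(f"{path}: missing column {col!r}")
    df = df.sort_values("index")
    if not (df["index"].to_numpy() == np.arange(len(df))).all():
        raise ParameterError(f"{path}: region indices must be 0..N-1")
    roles = {}
    for _, row in df.iterrows():
        if row["role"] != "-":
            roles[row["role"]] = int(row["index"])
    missing = {"lmc_left", "lmc_right", "snc_left", "snc_right"} - roles.keys()
    if missing:
        raise ParameterError(f"{path}: missing roles {sorted(missing)}")
    return RegionSet(labels=[str(x) for x in df["label"]], **roles)


def write_bold(bold: BoldSignal, path, labels=None) -> None:
    """BOLD panel as TSV: time_s column then one column per region."""
    n_t, n_r = bold.values.shape
    cols = list(labels) if labels is not None else \
        [f"R{k:02d}" for k in range(n_r)]
    df = pd.DataFrame(bold.values, columns=cols)
    df.insert(0, "time_s", np.arange(n_t) * bold.tr_s)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_bold(path) -> BoldSignal:
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ParameterError(f"{path}: expected a time_s column plus regions")
    t = df["time_s"].to_numpy()
    tr = float(t[1] - t[0]) if t.size > 1 else 1.0
    return BoldSignal(values=df.drop(columns="time_s").to_numpy(), tr_s=tr)


# ---------------------------------------------------------------------------
# run configuration (YAML)

_BLOCKS = {
    "paths": {"coupling_matrix", "manifest", "output_dir"},
    "parameters": {f.name for f in fields(ModelParameters)},
    "experiment": {"n_regions", "n_cycles", "cycle_s", "speech_s", "h",
                   "stride", "drive_bin_ms", "tr_rest_s", "tr_task_s",
                   "discard_cycles", "density"},
    "analysis": {"bins", "n_null", "n_perm", "alpha"},
}


def load_run_config(path) -> dict:
    """Load and validate a YAML run configuration.

    Returns a dict with keys ``seed``, ``paths``, ``experiment_config``
    (an :class:`ExperimentConfig` with parameter overrides applied).
    Unknown keys anywhere are rejected; referenced input files must exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    unknown = set(raw) - (set(_BLOCKS) | {"seed"})
    if unknown:
        raise RunConfigError(f"unknown top-level keys: {sorted(unknown)}")
    for block, allowed in _BLOCKS.items():
        got = set(raw.get(block) or {})
        extra = got - allowed
        if extra:
            raise RunConfigError(f"unknown keys in {block!r}: {sorted(extra)}")
    paths = dict(raw.get("paths") or {})
    for key in ("coupling_matrix", "manifest"):
        if paths.get(key) and not Path(paths[key]).exists():
            raise RunConfigError(f"referenced file does not exist: "
                                 f"{block_path(paths[key])}")
    params = ModelParameters().with_overrides(**(raw.get("parameters") or {}))
    kwargs = dict(raw.get("experiment") or {})
    kwargs.update(raw.get("analysis") or {})
    cfg = ExperimentConfig(params=params, seed=int(raw.get("seed", 0)),
                           **kwargs)
    return {"seed": cfg.seed, "paths": paths, "experiment_config": cfg,
            "raw": raw}


def block_path(p) -> str:
    return str(Path(p))


def save_run_config(cfg_dict: dict, path) -> None:
    """Serialize a loaded configuration back to YAML (round-trip identity)."""
    Path(path).write_text(yaml.safe_dump(cfg_dict["raw"], sort_keys=True))


def provenance_record(cfg_dict: dict, extra: dict | None = None) -> str:
    """JSON provenance blob: config content, seed, package version."""
    from . import __version__

    rec = {"seed": cfg_dict["seed"], "config": cfg_dict["raw"],
           "dopasim_version": __version__}
    rec.update(extra or {})
    return json.dumps(rec, indent=2, sort_keys=True, default=str)
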