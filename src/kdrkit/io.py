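"""Readers and writers for the package's plain-text interchange formats.

- concentration-mortality tables: CSV with columns concentration, n_exposed,
  n_dead, strain, stage, insecticide, synergist;
- current traces: two-column CSV (time_ms, current_uA) with a structured
  '# key = json' header block carrying the protocol and metadata (a paired
  pre-drug recording goes to a sibling *.pre.csv file);
- sequences: FASTA via Biopython;
- results: JSON with an optional provenance header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ephys import CurrentTrace, VoltageProtocol

MORTALITY_COLUMNS = ["concentration", "n_exposed", "n_dead"]


def write_mortality_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    missing = [c for c in MORTALITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"mortality table missing columns {missing}")
    table.to_csv(path, index=False)
    return path


def read_mortality_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in MORTALITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: not a mortality table (missing {missing})")
    return table


def _trace_header(trace: CurrentTrace) -> list:
    head = {
        "sample_interval_ms": trace.sample_interval,
        "protocol": dataclasses.asdict(trace.protocol),
        "meta": trace.meta,
    }
    return [f"# {k} = {json.dumps(v)}" for k, v in head.items()]


def write_trace(trace: CurrentTrace, path, write_pre: bool = True) -> Path:
    """Write a trace as two-column text; the pre-drug pair goes to *.pre.csv."""
    path = Path(path)
    t = trace.times

    def _dump(p, current):
        lines = _trace_header(trace) + ["time_ms,current_uA"]
        body = "\n".join(f"{ti:.6g},{ci:.8g}" for ti, ci in zip(t, current))
        p.write_text("\n".join(lines) + "\n" + body + "\n")

    _dump(path, trace.current)
    if write_pre and trace.pre_current is not None:
        _dump(path.with_suffix(".pre.csv"), trace.pre_current)
    return path


def read_trace(path) -> CurrentTrace:
    path = Path(path)
    head = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].partition("=")
            head[key.strip()] = json.loads(value)
    data = np.loadtxt(path, delimiter=",", skiprows=n_header + 1)
    protocol = VoltageProtocol(**head["protocol"])
    pre_path = path.with_suffix(".pre.csv")
    pre = None
    if pre_path.exists():
        pre = np.loadtxt(pre_path, delimiter=",", skiprows=n_header + 1)[:, 1]
    return CurrentTrace(
        sample_interval=head["sample_interval_ms"],
        current=data[:, 1],
        protocol=protocol,
        meta=head.get("meta", {}),
        pre_current=pre,
    )


def write_fasta(sequences: dict, path) -> Path:
    """Write {id: sequence string} as FASTA."""
    path = Path(path)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def config_hash(config: dict) -> str:
    """Stable short hash of the semantically meaningful config fields."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path, provenance: dict | None = None) -> Path:
    path = Path(path)
    payload = _jsonable(obj)
    if provenance is not None:
        payload = {"provenance": _jsonable(provenance), **payload} if isinstance(
            payload, dict
        ) else {"provenance": _jsonable(provenance), "result": payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
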