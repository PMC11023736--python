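"""Plain-text file formats.

Everything the pipeline reads or writes is delimited text (CSV) or YAML with
a small ``# key=value`` comment header carrying provenance (format version,
config hash, seed).  No binary formats: none of the instruments involved has
a community-standard container, and text keeps runs diffable and
reproducible byte-for-byte.
"""

from __future__ import annotations

import io as _io
import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .cmj import ForceTrace
from .pca import PCAModel

FORMAT_VERSION = "courtwatch-v1"


def _header_lines(meta: Mapping) -> str:
    lines = [f"# format={FORMAT_VERSION}"]
    lines += [f"# {k}={v}" for k, v in meta.items()]
    return "\n".join(lines) + "\n"


def read_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_table(frame: pd.DataFrame, path, meta: Optional[Mapping] = None,
                index: bool = False, float_format: str = "%.10g") -> None:
    """Write a tidy CSV with a commented provenance header."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_header_lines(meta or {}))
        frame.to_csv(fh, index=index, float_format=float_format)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_trace(trace: ForceTrace, path, meta: Optional[Mapping] = None) -> None:
    """Trace file: time, f_left, f_right columns; body mass and sample rate in
    the header."""
    head = {"body_mass_kg": repr(trace.body_mass),
            "sample_rate_hz": repr(trace.sample_rate)}
    head.update(meta or {})
    frame = pd.DataFrame({"time_s": trace.time, "f_left_n": trace.f_left,
                          "f_right_n": trace.f_right})
    write_table(frame, path, head)


def read_trace(path) -> ForceTrace:
    meta = read_header(path)
    try:
        body_mass = float(meta["body_mass_kg"])
        sample_rate = float(meta["sample_rate_hz"])
    except KeyError as exc:
        raise ValueError(f"{path}: trace header missing {exc}") from exc
    frame = read_table(path)
    return ForceTrace(time=frame["time_s"].to_numpy(),
                      f_left=frame["f_left_n"].to_numpy(),
                      f_right=frame["f_right_n"].to_numpy(),
                      body_mass=body_mass, sample_rate=sample_rate,
                      meta={k: v for k, v in meta.items()
                            if k not in ("body_mass_kg", "sample_rate_hz",
                                         "format")})


def save_model(model: PCAModel, path, meta: Optional[Mapping] = None) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    payload = model.to_dict()
    payload["meta"] = dict(meta or {})
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_model(path) -> PCAModel:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return PCAModel.from_dict(payload)
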