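"""File I/O: assessment panels, score reports and model artifacts.

Panels and reports are plain CSV with a comment header (lines starting with
``#``) that embeds the tool version, the run seed and a SHA-256 digest of
every input file, so any output can be traced to the exact inputs that
produced it.  Floats are written with 10 significant digits and columns in
a fixed order, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

__all__ = [
    "file_digest",
    "write_report",
    "read_report",
    "read_panel",
    "write_panel",
    "load_config_file",
    "dump_config_file",
]

FLOAT_FORMAT = "%.10g"
MISSING_TOKEN = ""  # empty cell


def file_digest(path) -> str:
    """First 12 hex digits of the SHA-256 of a file's bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _header_lines(seed, inputs: dict | None) -> str:
    lines = [f"# nhqi {__version__}", f"# seed={seed}"]
    for name, path in (inputs or {}).items():
        lines.append(f"# input {name} sha256={file_digest(path)}")
    return "\n".join(lines) + "\n"


def write_report(df: pd.DataFrame, path, seed=0, inputs: dict | None = None) -> None:
    """Write a CSV report with the provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_header_lines(seed, inputs))
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT, na_rep=MISSING_TOKEN)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_panel(panel: pd.DataFrame, path, seed=0, inputs: dict | None = None) -> None:
    """Write an assessment panel; ``new_admission`` is stored as 0/1."""
    out = panel.copy()
    if "new_admission" in out.columns:
        out["new_admission"] = out["new_admission"].astype(int)
    write_report(out, path, seed=seed, inputs=inputs)


def read_panel(path) -> pd.DataFrame:
    """Read a panel CSV (empty cell = missing; header comments ignored)."""
    panel = pd.read_csv(path, comment="#")
    required = {"resident_id", "facility_id", "quarter"}
    missing = sorted(required - set(panel.columns))
    if missing:
        raise ValueError(f"panel {path} lacks required column(s) {missing}")
    if "new_admission" in panel.columns:
        panel["new_admission"] = panel["new_admission"].fillna(0).astype(int).astype(bool)
    else:
        panel["new_admission"] = False
    dup = panel.duplicated(["resident_id", "quarter"])
    if dup.any():
        first = panel.loc[dup, ["resident_id", "quarter"]].iloc[0]
        raise ValueError(
            f"panel {path}: duplicate (resident_id, quarter) starting at "
            f"({first['resident_id']}, {first['quarter']})"
        )
    return panel


def load_config_file(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config_file(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
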