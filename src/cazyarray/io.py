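"""Shared table I/O: TSV with a provenance comment line.

Every table the toolkit writes starts with a single ``#``-prefixed comment
recording the tool version, seed and a config digest, followed by a header
row. Readers skip comment lines, so the files remain plain TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__


def config_digest(params: Mapping[str, Any] | None) -> str:
    """Short stable digest of a parameter mapping (for provenance lines)."""
    payload = json.dumps(dict(params or {}), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_line(seed: int | None = None, params: Mapping[str, Any] | None = None) -> str:
    parts = [f"cazyarray v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.append(f"config={config_digest(params)}")
    return "# " + " ".join(parts)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    params: Mapping[str, Any] | None = None,
) -> Path:
    """Write *df* as TSV with a leading provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_line(seed=seed, params=params) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


def read_table(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
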