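"""Output writers and reproducibility manifest.

Every simulation output directory receives exactly one ``manifest.json``
recording the resolved parameter set, seeds, time step, protocol, software
version and a content hash of the written files, so any run can be
replayed bit-identically.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd

from .params import ParameterSet

SCHEMA_VERSION = 1


def write_csv(df: pd.DataFrame, path) -> Path:
    """CSV writer: comma-separated, '.' decimal, UTF-8, no index column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        try:
            import numpy as np
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
        except ImportError:
            pass
        raise TypeError(f"not JSON serialisable: {type(o)!r}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path


def content_hash(paths) -> str:
    """Stable SHA-256 over the byte content of the given files."""
    h = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        h.update(p.encode())
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, params: ParameterSet, *, seed: int, dt: float,
                   protocol: str, outputs=(), extra=None) -> Path:
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "software": {"name": "boutonsim", "version": __version__},
        "started_utc": datetime.datetime.now(datetime.timezone.utc)
        .isoformat(),
        "seed": int(seed),
        "dt_ms": float(dt),
        "protocol": protocol,
        "unit_conventions": {
            "time": "ms", "concentration": "uM", "voltage": "mV",
            "conductance": "pS", "volume": "L",
            "ip3_metabolism_rates":
                params.ip3_metabolism.rate_unit_scale,
        },
        "parameters": params.to_dict(),
        "outputs": [str(Path(p).name) for p in outputs],
        "content_hash": content_hash(outputs) if outputs else None,
    }
    return write_json(manifest, out_dir / "manifest.json")
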