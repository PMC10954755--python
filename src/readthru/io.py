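"""Tabular output with metadata headers, and run manifests.

All tables are tab-separated with leading ``# key: value`` metadata lines
(readers skip ``#``).  Every run directory gets a ``manifest.json``
recording package version, subcommand, seed, configuration echo, and
input checksums — no timestamps, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def checksum(path) -> str:
    digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return digest[:12]


def write_manifest(out_dir, subcommand: str, seed: int, config: dict,
                   inputs: dict) -> None:
    manifest = {
        "version": __version__,
        "subcommand": subcommand,
        "seed": seed,
        "config": config,
        "inputs": {str(k): checksum(v) for k, v in inputs.items()},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
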