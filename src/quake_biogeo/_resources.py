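"""Loaders for the plain-text constant tables shipped with the package."""
from __future__ import annotations

import hashlib
from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

_DATA_PACKAGE = "quake_biogeo.data"


def data_path(name: str) -> Path:
    """Filesystem path of a shipped constant table."""
    return Path(resources.files(_DATA_PACKAGE) / name)


@lru_cache(maxsize=None)
def load_table(name: str) -> pd.DataFrame:
    """Read a shipped keyed TSV (``#`` comment lines, ``NA`` missing)."""
    return pd.read_csv(data_path(name), sep="\t", comment="#", na_values="NA")


def data_file_hashes() -> dict[str, str]:
    """sha256 of every shipped constant file, for run manifests."""
    out = {}
    root = resources.files(_DATA_PACKAGE)
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".tsv"):
            out[entry.name] = hashlib.sha256(entry.read_bytes()).hexdigest()
    return out
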