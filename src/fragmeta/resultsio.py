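"""Tabular result files: CSV with a '#'-prefixed metadata header.

All experiment outputs are plain CSV preceded by comment lines of the form
``# key: value`` carrying at least the config hash, the seed and the
package version, so any file can be traced back to the run that made it.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["write_results", "read_results"]


def write_results(path, table: pd.DataFrame, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, index=False)


def read_results(path) -> tuple[pd.DataFrame, dict]:
    """Read a result file back; returns (table, metadata).

    A file without a metadata header still parses, with a warning.
    """
    metadata: dict = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            key, sep, value = body.partition(":")
            if sep:
                metadata[key.strip()] = value.strip()
    if not metadata:
        warnings.warn(f"result file {path} has no metadata header")
    table = pd.read_csv(path, skiprows=n_header)
    return table, metadata
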