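"""TSV/JSON serialization of results.

TSV files are tab-separated with '.' decimals and start with a single
'#'-prefixed header line carrying the resolved parameters as key=value
pairs, so every output is self-describing and round-trippable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_tsv", "read_tsv", "write_json"]


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_tsv(path, columns: dict[str, np.ndarray], params: dict | None = None) -> None:
    """Write named columns to a TSV file with a '#' parameter header."""
    path = Path(path)
    names = list(columns)
    arrays = [np.asarray(columns[n]) for n in names]
    n_rows = len(arrays[0])
    if any(len(a) != n_rows for a in arrays):
        raise ValueError("all columns must have equal length")
    with path.open("w", encoding="utf-8") as fh:
        kv = " ".join(f"{k}={_fmt(v)}" for k, v in (params or {}).items())
        fh.write(f"# {kv}\n" if kv else "#\n")
        fh.write("\t".join(names) + "\n")
        for i in range(n_rows):
            fh.write("\t".join(_fmt(a[i].item() if hasattr(a[i], "item") else a[i]) for a in arrays) + "\n")


def read_tsv(path) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Read a TSV written by :func:`write_tsv`; returns (columns, params)."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().strip()
        params = {}
        for tok in header.lstrip("#").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                params[k] = v
        names = fh.readline().strip().split("\t")
        rows = [line.strip().split("\t") for line in fh if line.strip()]
    cols = {}
    for j, name in enumerate(names):
        vals = [r[j] for r in rows]
        try:
            cols[name] = np.array([float(v) for v in vals])
        except ValueError:
            cols[name] = np.array(vals)
    return cols, params


def write_json(path, obj: dict) -> None:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n", encoding="utf-8")
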