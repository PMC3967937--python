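"""Serialization: the SFS TSV dialect and JSON documents.

The TSV dialect is two tab-separated columns ``i`` and ``xi`` for
``i = 1..n-1``, preceded by comment lines of which one must declare the
sample size, e.g.::

    # n=100
    # any other metadata lines
    1\t103.2
    2\t51.7
    ...

JSON documents carry ``{"n": ..., "xi": [...]}`` plus optional statistics
and run metadata.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .sfs import (
    SiteFrequencySpectrum,
    SummaryStats,
    UndefinedStatisticError,
    summary_stats,
)

__all__ = ["read_sfs", "write_sfs", "sfs_to_json", "sfs_from_json", "SfsParseError"]


class SfsParseError(ValueError):
    """Malformed SFS file (message names the offending line)."""


def write_sfs(path: str | Path, sfs: SiteFrequencySpectrum, **metadata: Any) -> None:
    """Write an SFS to the TSV dialect (deterministic formatting)."""
    path = Path(path)
    lines = [f"# n={sfs.n}"]
    for k, v in sorted(metadata.items()):
        lines.append(f"# {k}={v}")
    for i, x in zip(sfs.freqs, sfs.xi):
        lines.append(f"{i}\t{x:.12g}")
    path.write_text("\n".join(lines) + "\n")


def read_sfs(path: str | Path) -> SiteFrequencySpectrum:
    """Read an SFS from the TSV dialect, validating the header."""
    path = Path(path)
    n = None
    header_lines = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith("#"):
            break
        header_lines += 1
        m = re.match(r"#\s*n\s*=\s*(\d+)\s*$", line)
        if m:
            n = int(m.group(1))
    if n is None:
        raise SfsParseError(f"{path}: no '# n=<int>' header line found")
    table = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["i", "xi"]
    )
    if len(table) != n - 1:
        raise SfsParseError(
            f"{path}: header declares n={n} but found {len(table)} rows "
            f"(expected {n - 1}; first data line is line {header_lines + 1})"
        )
    idx = table["i"].to_numpy()
    expected = np.arange(1, n)
    if not (idx == expected).all():
        bad = int(np.nonzero(idx != expected)[0][0]) + header_lines + 1
        raise SfsParseError(f"{path}: unexpected frequency index at line {bad}")
    return SiteFrequencySpectrum(n, table["xi"].to_numpy(dtype=float))


def sfs_to_json(sfs: SiteFrequencySpectrum, with_stats: bool = True) -> dict:
    doc: dict[str, Any] = {"n": sfs.n, "xi": [float(x) for x in sfs.xi]}
    if with_stats:
        try:
            st: SummaryStats = summary_stats(sfs)
            doc["stats"] = {
                "pi": st.pi,
                "tajimas_d": st.tajimas_d,
                "mean_maf": st.mean_maf,
                "ushape": st.ushape,
                "segregating_sites": st.segregating_sites,
            }
        except UndefinedStatisticError:
            doc["stats"] = None
    return doc


def sfs_from_json(doc: dict | str) -> SiteFrequencySpectrum:
    if isinstance(doc, str):
        doc = json.loads(doc)
    return SiteFrequencySpectrum(int(doc["n"]), doc["xi"])
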