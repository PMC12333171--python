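"""Report assembly: volcano-style summaries and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd


def make_volcano_summary(diff_results: pd.DataFrame,
                         fold_changes: pd.Series | None = None,
                         p_cut: float = 0.05,
                         fc_cut: float = 1.5,
                         p_col: str = "p") -> pd.DataFrame:
    """Classify proteins as up / down / ns for a volcano-style display.

    ``up``: log2 fold change >= log2(fc_cut) and p < p_cut; ``down``: the
    mirror image; anything else ``ns``.  ``diff_results`` needs columns
    ``protein`` and ``p_col``; fold changes come either from a matched Series
    (indexed by protein) or a ``log2fc`` column.
    """
    frame = diff_results.copy()
    if fold_changes is not None:
        missing = [p for p in frame["protein"] if p not in fold_changes.index]
        if missing:
            raise ValueError(f"fold changes missing for proteins: {missing}")
        frame["log2fc"] = frame["protein"].map(fold_changes)
    if "log2fc" not in frame.columns:
        raise ValueError("need fold_changes or a 'log2fc' column")
    cut = float(np.log2(fc_cut))
    sig = frame[p_col] < p_cut
    frame["volcano"] = np.where(sig & (frame["log2fc"] >= cut), "up",
                                np.where(sig & (frame["log2fc"] <= -cut),
                                         "down", "ns"))
    return frame


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir, subcommand: str, parameters: dict,
                   inputs: list | None = None, seed: int | None = None) -> Path:
    """Write a machine-readable run manifest next to the stage outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "parameters": parameters,
        "seed": seed,
        "version": __version__,
        "python": platform.python_version(),
        "inputs": [{"path": str(p), "sha256": _checksum(Path(p))}
                   for p in (inputs or []) if Path(p).exists()],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
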