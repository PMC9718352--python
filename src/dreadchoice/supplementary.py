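"""Optional loader for the original study's deposited raw data.

The published dataset ("Extended Data 1", a ZIP of data and analysis
scripts) is not redistributed with this package.  When a copy is available
locally, :func:`load_supplementary_percentages` reads per-animal choice
percentages from it so the published experimental statistics can be
recomputed; everything that depends on it degrades gracefully (returns
None / tests skip) when the archive is absent.

Expected layout (documented mapping, not enforced): one CSV per experiment
matching ``experiment<j>*.csv`` — either inside the ZIP or in an unpacked
directory — with one row per animal and either a ``percent`` column (percent
choices of the reported option) or ``k``/``n`` count columns.
"""

from __future__ import annotations

import io
import re
import zipfile
from pathlib import Path
from typing import Optional

import pandas as pd

DEFAULT_LOCATIONS = (
    Path("data/extended_data_1.zip"),
    Path("data/extended_data_1"),
)


def _frame_to_percent(df: pd.DataFrame) -> list[float]:
    cols = {c.lower(): c for c in df.columns}
    if "percent" in cols:
        return [float(v) for v in df[cols["percent"]]]
    if "k" in cols and "n" in cols:
        return [100.0 * k / n for k, n in zip(df[cols["k"]], df[cols["n"]])]
    raise ValueError("supplementary CSV needs a 'percent' column or 'k'/'n' columns")


def find_supplementary(root: str | Path = ".") -> Optional[Path]:
    """First existing default location under ``root``, else None."""
    root = Path(root)
    for loc in DEFAULT_LOCATIONS:
        if (root / loc).exists():
            return root / loc
    return None


def load_supplementary_percentages(path: str | Path) -> dict[int, list[float]]:
    """Per-experiment per-animal choice percentages from the deposited data.

    ``path`` may be the ZIP archive or an unpacked directory.  Returns a
    mapping experiment id -> list of percentages.
    """
    path = Path(path)
    pattern = re.compile(r"experiment([123])[^/]*\.csv$", re.IGNORECASE)
    out: dict[int, list[float]] = {}
    if path.is_dir():
        for f in sorted(path.rglob("*.csv")):
            m = pattern.search(f.name)
            if m:
                out[int(m.group(1))] = _frame_to_percent(pd.read_csv(f))
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                m = pattern.search(name)
                if m:
                    with zf.open(name) as fh:
                        out[int(m.group(1))] = _frame_to_percent(pd.read_csv(io.TextIOWrapper(fh)))
    else:
        raise FileNotFoundError(f"{path} is neither a directory nor a ZIP archive")
    if not out:
        raise ValueError(f"no experiment CSVs found under {path}")
    return out


def convert_ethovision_export(path: str | Path):  # pragma: no cover - documented stub
    """Converter stub for raw video-tracking exports.

    The original apparatus logs (Ethovision trial exports) would map to the
    trial CSV schema as: trial number -> (session, trial_index) via the
    6-forced/16-free session layout; arm entered -> ``chosen`` through the
    session's side contingency; early-departure flag -> ``omission``.
    Parsing those exports is out of scope; use the trial CSV schema directly.
    """
    raise NotImplementedError("Ethovision export parsing is not implemented")
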