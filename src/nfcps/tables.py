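"""Delimited-table readers and writers with provenance headers.

All pipeline tables are plain UTF-8 CSV with a header row, '.' decimal
separator, and a single leading comment line carrying tool version, seed and
config hash (no timestamps, so identical runs are byte-identical).  The
external-feature reader is deliberately tolerant: comma or tab delimiters,
Greek or Latin feature column names, and a few label spellings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .features import COMBINATIONS, LABELS, normalize_combination

logger = logging.getLogger(__name__)

_COLUMN_SYNONYMS = {
    "α": "alpha", "a": "alpha", "alpha": "alpha",
    "β": "beta", "b": "beta", "beta": "beta",
    "γ": "gamma", "g": "gamma", "gamma": "gamma",
    "δ": "delta", "d": "delta", "delta": "delta",
    "label": "label", "class": "label", "type": "label", "y": "label",
    "edema_type": "label",
    "subject_id": "subject_id", "subject": "subject_id", "rabbit": "subject_id",
    "t0_h": "t0_h", "t0": "t0_h", "time_h": "t0_h", "hour": "t0_h",
}

_LABEL_SYNONYMS = {
    "CE": "CE", "C": "CE", "CYTOTOXIC": "CE", "-1": "CE", "0": "CE",
    "VE": "VE", "V": "VE", "VASOGENIC": "VE", "1": "VE", "+1": "VE",
}


def provenance_line(seed: int | None = None, config_hash: str | None = None) -> str:
    parts = [f"nfcps v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return "# " + " | ".join(parts)


def write_table(df: pd.DataFrame, path: str | Path,
                seed: int | None = None, config_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(provenance_line(seed, config_hash) + "\n")
        df.to_csv(fh, index=False)
    logger.info("wrote %d rows to %s", len(df), path)


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    logger.info("read %d rows from %s", len(df), path)
    return df


def read_external_features(path: str | Path, combination: str) -> pd.DataFrame:
    """Read a feature table in an external (supplementary-style) layout.

    Delimiter is sniffed (comma/tab/semicolon); column headers may use Greek
    letters or single-letter names; the label column accepts CE/VE and common
    synonyms.  Returns a frame with canonical feature columns and a 'label'
    column, ready for :func:`nfcps.features.build_dataset`.
    """
    comb = normalize_combination(combination)
    needed = list(COMBINATIONS[comb])
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        key = _COLUMN_SYNONYMS.get(key, _COLUMN_SYNONYMS.get(str(col).strip(), key))
        rename[col] = key
    df = df.rename(columns=rename)
    missing = [c for c in needed + ["label"] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: could not map column(s) {missing}; found columns "
            f"{list(df.columns)}"
        )
    for c in needed:
        numeric = pd.to_numeric(df[c], errors="coerce")
        bad = numeric.isna() & df[c].notna()
        if df[c].isna().any() or bad.any():
            row = int((numeric.isna() | df[c].isna()).idxmax())
            raise ValueError(
                f"{path}: non-numeric or missing value in column {c!r} at row {row}"
            )
        df[c] = numeric.astype(float)
    labels = df["label"].astype(str).str.strip().str.upper().map(_LABEL_SYNONYMS)
    if labels.isna().any():
        row = int(labels.isna().idxmax())
        raise ValueError(
            f"{path}: unmappable label {df['label'].iloc[row]!r} at row {row}; "
            f"expected one of {sorted(set(_LABEL_SYNONYMS))}"
        )
    df["label"] = labels
    assert set(df["label"]) <= set(LABELS)
    logger.info("read %d external feature rows from %s (combination %s)",
                len(df), path, comb)
    keep = [c for c in ("subject_id", "t0_h") if c in df.columns]
    return df[keep + needed + ["label"]]
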