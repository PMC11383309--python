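"""Ranking and threshold classification of structure-prediction screens.

A receptor/ipTM score table (one row per candidate WIPI-binding receptor,
ipTM in [0, 1]) is classified with a strict ``iptm > threshold`` hit rule
(default 0.5) and ranked by descending ipTM.  Records within a small margin
of the threshold are annotated ``borderline`` — an annotation only, never a
hit — to flag near-misses worth experimental follow-up.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 0.5
DEFAULT_BORDERLINE_MARGIN = 0.05

SCREEN_COLUMNS = ["receptor", "uniprot_id", "iptm", "oligomeric_state"]


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV screen table (receptor, optional uniprot_id, iptm, optional state)."""
    df = pd.read_csv(path, sep="\t")
    if "receptor" not in df.columns or "iptm" not in df.columns:
        raise ValueError("screen table needs 'receptor' and 'iptm' columns")
    if "uniprot_id" not in df.columns:
        df["uniprot_id"] = ""
    if "oligomeric_state" not in df.columns:
        df["oligomeric_state"] = "monomer"
    return df[SCREEN_COLUMNS].copy()


def _check_iptm(df: pd.DataFrame) -> None:
    iptm = df["iptm"].to_numpy(dtype=float)
    if np.any((iptm < 0) | (iptm > 1) | ~np.isfinite(iptm)):
        bad = df.loc[(df["iptm"] < 0) | (df["iptm"] > 1), "receptor"].tolist()
        raise ValueError(f"ipTM outside [0, 1] for {bad}")
    states = set(df.get("oligomeric_state", pd.Series(dtype=str)).dropna())
    unknown = states - {"monomer", "dimer"}
    if unknown:
        raise ValueError(f"unknown oligomeric_state value(s) {sorted(unknown)}")


def classify_hits(
    records: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    borderline_margin: float = DEFAULT_BORDERLINE_MARGIN,
) -> pd.DataFrame:
    """Set ``is_hit = iptm > threshold`` (strict) and a ``borderline`` annotation.

    ``borderline`` marks records with |iptm - threshold| <= margin; a score of
    exactly the threshold is not a hit.
    """
    out = records.copy()
    if len(out) == 0:
        out["is_hit"] = pd.Series(dtype=bool)
        out["borderline"] = pd.Series(dtype=bool)
        return out
    _check_iptm(out)
    iptm = out["iptm"].to_numpy(dtype=float)
    out["is_hit"] = iptm > threshold
    out["borderline"] = np.abs(iptm - threshold) <= borderline_margin
    return out


def rank_screen(records: pd.DataFrame) -> pd.DataFrame:
    """Sort by ipTM descending; ties broken lexicographically by receptor."""
    if len(records) == 0:
        return records.copy()
    _check_iptm(records)
    return records.sort_values(
        ["iptm", "receptor"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
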