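"""Reading, writing and curating Ct matrices and sample annotations.

The pipeline's native currency is a *Ct matrix*: a features x samples grid
of qPCR cycle-threshold values held as a :class:`pandas.DataFrame` with
feature IDs on the index, sample IDs on the columns, and ``NaN`` marking
missing ("Undetermined") wells.  Sample metadata travels alongside it as an
annotation table indexed by sample ID with columns ``case_id``,
``tissue_class`` (``normal``/``malignant``), ``gleason_score``,
``tumor_pct``, ``who_grade`` and a boolean ``paired`` flag maintained by
:func:`exclude_samples`.

All on-disk formats are plain delimited text so that round-trips are
bit-exact and files are diff-able.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MISSING_TOKENS",
    "read_ct_table",
    "write_ct_table",
    "read_annotation",
    "write_annotation",
    "exclude_samples",
    "drop_controls",
    "collapse_duplicate_features",
    "complete_pairs",
    "validate_ct_matrix",
    "validate_annotation",
]

#: Cell contents interpreted as a missing well on input.
MISSING_TOKENS = {"", "NA", "NaN", "nan", "Undetermined", "undetermined"}

ANNOTATION_COLUMNS = [
    "case_id",
    "tissue_class",
    "gleason_score",
    "tumor_pct",
    "who_grade",
]


class FormatError(ValueError):
    """Raised when an input file violates the tabular contracts."""


def _find_duplicates(ids: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


def validate_ct_matrix(m: pd.DataFrame) -> None:
    """Check the Ct-matrix invariants, raising :class:`FormatError` on violation."""
    dups = _find_duplicates(m.index)
    if dups:
        raise FormatError(f"duplicate feature IDs: {dups}")
    dups = _find_duplicates(m.columns)
    if dups:
        raise FormatError(f"duplicate sample IDs: {dups}")
    vals = m.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if np.any(np.isinf(vals)):
        raise FormatError("Ct matrix contains infinite values")
    if np.any(vals[finite] <= 0):
        bad = np.argwhere(finite & (vals <= 0))[0]
        raise FormatError(
            f"non-positive Ct at feature {m.index[bad[0]]!r}, sample {m.columns[bad[1]]!r}"
        )


def read_ct_table(path: str | os.PathLike, sep: str = ",") -> pd.DataFrame:
    """Read a delimited Ct table (first column feature IDs, header sample IDs).

    Cells equal to any of :data:`MISSING_TOKENS` become ``NaN``.  Duplicate
    feature or sample IDs and non-numeric cells raise :class:`FormatError`
    naming the offender.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    def convert(cell: str, fid: str, sid: str) -> float:
        cell = cell.strip()
        if cell in MISSING_TOKENS:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise FormatError(
                f"non-numeric Ct value {cell!r} at feature {fid!r}, sample {sid!r}"
            ) from None

    out = pd.DataFrame(
        [
            [convert(raw.iat[i, j], raw.index[i], raw.columns[j]) for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index.copy(),
        columns=raw.columns.copy(),
        dtype=float,
    )
    validate_ct_matrix(out)
    return out


def write_ct_table(m: pd.DataFrame, path: str | os.PathLike, sep: str = ",") -> None:
    """Write a Ct matrix; missing wells become ``NA``."""
    m.to_csv(path, sep=sep, na_rep="NA", index_label="feature_id")


def read_annotation(path: str | os.PathLike, sep: str = ",") -> pd.DataFrame:
    """Read a sample-annotation table indexed by ``sample_id``."""
    a = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "case_id": str})
    if "sample_id" not in a.columns:
        raise FormatError("annotation file lacks a 'sample_id' column")
    a = a.set_index("sample_id")
    for col in ANNOTATION_COLUMNS:
        if col not in a.columns:
            a[col] = np.nan
    if "paired" not in a.columns:
        a["paired"] = True
    validate_annotation(a)
    return a


def write_annotation(a: pd.DataFrame, path: str | os.PathLike, sep: str = ",") -> None:
    a.to_csv(path, sep=sep, na_rep="NA", index_label="sample_id")


def validate_annotation(a: pd.DataFrame) -> None:
    dups = _find_duplicates(a.index)
    if dups:
        raise FormatError(f"duplicate sample IDs in annotation: {dups}")
    bad = set(a["tissue_class"]) - {"normal", "malignant"}
    if bad:
        raise FormatError(f"unknown tissue_class values: {sorted(bad)}")
    gs = pd.to_numeric(a["gleason_score"], errors="coerce").dropna()
    if len(gs) and ((gs < 6) | (gs > 10)).any():
        raise FormatError("gleason_score outside [6, 10]")


def exclude_samples(
    m: pd.DataFrame, a: pd.DataFrame, sample_ids: Iterable[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples from matrix and annotation, flagging orphaned pair partners.

    If removing a sample breaks its (normal, malignant) pair, the surviving
    partner stays in the matrix (it can still be clustered) but its
    ``paired`` flag is set False so paired statistics skip it.
    """
    sample_ids = list(sample_ids)
    unknown = [s for s in sample_ids if s not in a.index or s not in m.columns]
    if unknown:
        raise KeyError(f"unknown sample IDs: {unknown}")
    keep = [s for s in m.columns if s not in sample_ids]
    m2 = m[keep].copy()
    a2 = a.loc[keep].copy()
    if "paired" not in a2.columns:
        a2["paired"] = True
    dropped_cases = set(a.loc[sample_ids, "case_id"])
    for case in dropped_cases:
        members = a2.index[a2["case_id"] == case]
        classes = set(a2.loc[members, "tissue_class"])
        if classes != {"normal", "malignant"}:
            a2.loc[members, "paired"] = False
    return m2, a2


def drop_controls(m: pd.DataFrame, roles: Mapping[str, str]) -> pd.DataFrame:
    """Keep only features whose role is ``target``.

    ``roles`` maps feature ID -> ``"target"`` / ``"control"``; features absent
    from the mapping are treated as targets.
    """
    keep = [f for f in m.index if roles.get(f, "target") == "target"]
    return m.loc[keep].copy()


def collapse_duplicate_features(m: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicated feature rows by per-well mean Ct.

    Arrays spotting the same miRNA on both cards yield duplicate rows; the
    reader rejects them, and this helper merges them (mean of non-missing
    replicate wells) before entry into the pipeline.
    """
    return m.groupby(level=0, sort=False).mean()


def complete_pairs(a: pd.DataFrame) -> list[tuple[str, str, str]]:
    """Return ``(case_id, normal_sample, malignant_sample)`` for intact pairs.

    Only samples with ``paired`` unset or True participate.
    """
    out = []
    flag = a["paired"] if "paired" in a.columns else pd.Series(True, index=a.index)
    usable = a[flag.astype(bool)]
    for case, grp in usable.groupby("case_id", sort=False):
        normals = grp.index[grp["tissue_class"] == "normal"]
        maligns = grp.index[grp["tissue_class"] == "malignant"]
        if len(normals) == 1 and len(maligns) == 1:
            out.append((case, normals[0], maligns[0]))
    return out
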