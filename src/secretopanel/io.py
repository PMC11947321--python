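"""Tabular input/output for the secreted-proteome pipeline.

Everything is plain tab-separated UTF-8 text with ``.`` as the decimal
separator.  The central container is :class:`QuantMatrix`: a proteins × runs
intensity table plus per-run metadata (sample, group, technical replicate).
Missing and zero are distinct states end-to-end — an empty field means the
protein was not identified in that run, a written ``0`` is a detected zero —
because the downstream coverage rules are defined on identification, not on
abundance.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Allowed subcellular-localization labels (UniProt-derived, collapsed).
LOCALIZATIONS = ("extracellular", "membrane", "intracellular", "unknown")

#: Tokens parsed as "not identified" in quantification tables.
MISSING_TOKENS = ("", "NA", "NaN", "nan")


@dataclass
class QuantMatrix:
    """Protein quantification matrix with run metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id, one column per run; entries are
        nonnegative intensities or NaN (not identified).
    runs
        DataFrame indexed by run name with columns ``sample_id``, ``group``
        and ``tech_rep`` (positive integer replicate index).
    """

    values: pd.DataFrame
    runs: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate protein id {dup!r}")
        if not self.values.columns.is_unique:
            raise ValidationError("duplicate run names in quantification matrix")
        missing_meta = set(self.values.columns) - set(self.runs.index)
        if missing_meta:
            raise ValidationError(
                f"runs without metadata: {sorted(missing_meta)}"
            )
        for col in ("sample_id", "group", "tech_rep"):
            if col not in self.runs.columns:
                raise ValidationError(f"run metadata lacks column {col!r}")
        # align metadata to the matrix columns
        self.runs = self.runs.loc[list(self.values.columns)]
        if self.runs.duplicated(subset=["sample_id", "tech_rep"]).any():
            raise ValidationError("(sample_id, tech_rep) pairs must be unique")
        if (self.runs["tech_rep"].astype(int) < 1).any():
            raise ValidationError("tech_rep indices must be ≥ 1")
        by_sample = self.runs.groupby("sample_id")["group"].nunique()
        if (by_sample > 1).any():
            bad = by_sample[by_sample > 1].index[0]
            raise ValidationError(f"sample {bad!r} assigned to more than one group")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            r, c = np.argwhere(np.nan_to_num(vals, nan=0.0) < 0)[0]
            raise ValidationError(
                f"negative intensity at protein {self.values.index[r]!r}, "
                f"run {self.values.columns[c]!r}"
            )

    # -- convenience views -------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.runs["sample_id"]))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.runs["group"]))

    def sample_groups(self) -> pd.Series:
        """Map sample_id → group, in first-appearance order."""
        return self.runs.drop_duplicates("sample_id").set_index("sample_id")["group"]


def read_quant_table(path: str | Path, metadata: str | Path) -> QuantMatrix:
    """Read a wide protein × run intensity table and its run-metadata file.

    The matrix file has a ``protein_id`` first column; empty fields, ``NA``
    and ``NaN`` are missing.  The metadata file has columns ``run``,
    ``sample_id``, ``group``, ``tech_rep``.  Malformed numbers, negative
    intensities and duplicate protein rows raise :class:`ParseError` naming
    the offending cell.
    """
    path, metadata = Path(path), Path(metadata)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "protein_id":
        raise ParseError(f"{path}: first column must be 'protein_id'")
    raw = raw.set_index("protein_id")
    if not raw.index.is_unique:
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate protein id {dup!r}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        text = raw[col].str.strip()
        is_missing = text.isin(MISSING_TOKENS)
        numeric = pd.to_numeric(text.where(~is_missing), errors="coerce")
        bad = ~is_missing & numeric.isna()
        if bad.any():
            row = raw.index[bad][0]
            raise ParseError(
                f"{path}: malformed number {text[bad].iloc[0]!r} at "
                f"protein {row!r}, run {col!r}"
            )
        neg = numeric < 0
        if neg.any():
            row = raw.index[neg.fillna(False)][0]
            raise ParseError(
                f"{path}: negative intensity at protein {row!r}, run {col!r}"
            )
        values[col] = numeric

    meta = pd.read_csv(metadata, sep="\t", dtype={"run": str, "sample_id": str, "group": str})
    for col in ("run", "sample_id", "group", "tech_rep"):
        if col not in meta.columns:
            raise ParseError(f"{metadata}: missing column {col!r}")
    meta = meta.set_index("run")
    unknown = set(values.columns) - set(meta.index)
    if unknown:
        raise ParseError(f"{metadata}: no metadata for run(s) {sorted(unknown)}")
    return QuantMatrix(values=values, runs=meta)


def write_quant_table(
    qm: QuantMatrix, path: str | Path, metadata: str | Path | None = None
) -> None:
    """Write a :class:`QuantMatrix` (and optionally its metadata) to TSV.

    Missing values are written as empty fields so identification state
    round-trips exactly.
    """
    out = qm.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="", float_format="%.10g")
    if metadata is not None:
        meta = qm.runs.copy()
        meta.index.name = "run"
        meta.to_csv(metadata, sep="\t")


def read_localization_table(path: str | Path) -> pd.Series:
    """Read a ``protein_id → localization`` table.

    Labels must be one of :data:`LOCALIZATIONS`.  Proteins absent from the
    table are treated downstream as ``unknown``.  Duplicate entries with
    conflicting labels are rejected; consistent duplicates are collapsed.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "localization"):
        if col not in table.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    bad = ~table["localization"].isin(LOCALIZATIONS)
    if bad.any():
        raise ValidationError(
            f"{path}: invalid localization {table['localization'][bad].iloc[0]!r}; "
            f"allowed labels are {', '.join(LOCALIZATIONS)}"
        )
    per_protein = table.groupby("protein_id")["localization"].nunique()
    if (per_protein > 1).any():
        dup = per_protein[per_protein > 1].index[0]
        raise ValidationError(
            f"{path}: protein {dup!r} has conflicting localization labels"
        )
    dedup = table.drop_duplicates("protein_id").set_index("protein_id")["localization"]
    dedup.name = "localization"
    return dedup


def write_localization_table(loc: pd.Series, path: str | Path) -> None:
    out = loc.rename("localization").to_frame()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


def localization_of(loc: pd.Series, proteins: Iterable[str]) -> pd.Series:
    """Look up labels for ``proteins``, defaulting unlisted ones to unknown."""
    idx = pd.Index(proteins)
    return loc.reindex(idx).fillna("unknown")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, pd.Index)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if isinstance(obj, float) and math.isnan(obj) else float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_report(
    panels,
    de: Mapping[str, pd.DataFrame],
    path: str | Path,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write DE tables, panel membership tables and a JSON run manifest.

    One TSV per DE contrast (``de_<contrast>.tsv``), one TSV per panel
    (``panel_<name>.tsv``) listing members with the criterion values that
    admitted them, and ``manifest.json`` with configuration echo, package
    version and stage counts.  Data files are byte-deterministic for
    identical inputs; only the manifest carries free-form metadata.
    """
    from . import __version__

    outdir = Path(path)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    written: dict[str, Path] = {}
    for name, table in de.items():
        p = outdir / f"de_{name}.tsv"
        out = table.copy()
        out.index.name = "protein_id"
        out.to_csv(p, sep="\t", na_rep="NA", float_format="%.10g")
        written[f"de_{name}"] = p
    for panel in panels:
        p = outdir / f"panel_{panel.name}.tsv"
        members = panel.members.copy()
        members.index.name = "protein_id"
        members.to_csv(p, sep="\t", na_rep="NA", float_format="%.10g")
        written[f"panel_{panel.name}"] = p

    info = {
        "package": "secretopanel",
        "version": __version__,
        "counts": {
            **{f"de_{name}": int(len(t)) for name, t in de.items()},
            **{f"panel_{panel.name}": int(len(panel.members)) for panel in panels},
        },
    }
    if manifest:
        info.update(_jsonable(manifest))
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(info, indent=2, sort_keys=True) + "\n")
    written["manifest"] = mp
    return written
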