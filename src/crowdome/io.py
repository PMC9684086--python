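"""Tabular I/O, prevalence filtering, and the compositional transformation.

Profile tables follow the MetaPhlAn convention: first column a pipe-delimited
clade string (``k__...|p__...|...|s__Species_name``), one column per sample,
percentage values. Only species-rank rows enter the analyses by default.
Metadata travels as CSV with a JSON sidecar declaring each variable's kind
(binary / ordinal / nominal / continuous).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_KINDS = frozenset({"binary", "ordinal", "nominal", "continuous"})

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__")


class FormatError(ValueError):
    """Raised when an input table violates the expected format."""


@dataclass
class AbundanceTable:
    """Samples x taxa fractional composition.

    ``data`` holds fractions in [0, 1] with sample IDs on the index and short
    taxon names (clade-string leaf without the rank prefix) on the columns;
    ``lineages`` maps each short name back to its full clade string.
    """

    data: pd.DataFrame
    lineages: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample IDs")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate taxon IDs")
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            raise FormatError("negative abundance value")
        sums = values.sum(axis=1)
        if (sums > 1 + 1e-6).any():
            raise FormatError("per-sample fractions sum above 1")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    def lineage_of(self, taxon: str) -> str:
        return self.lineages.get(taxon, f"k__Bacteria|s__{taxon}")

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), dict(self.lineages))


@dataclass
class MetadataTable:
    """Samples x mixed-kind host variables; values may be missing.

    ``kinds`` declares every column as binary, ordinal, nominal, or
    continuous.
    """

    data: pd.DataFrame
    kinds: dict

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample IDs")
        undeclared = [c for c in self.data.columns if c not in self.kinds]
        if undeclared:
            raise FormatError(f"variables without a declared kind: {undeclared}")
        bad = {k: v for k, v in self.kinds.items() if v not in VALID_KINDS}
        if bad:
            raise FormatError(f"unknown variable kinds: {bad}")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def copy(self) -> "MetadataTable":
        return MetadataTable(self.data.copy(), dict(self.kinds))


def _clade_rank(clade: str) -> str:
    leaf = clade.split("|")[-1]
    for prefix in _RANK_PREFIXES:
        if leaf.startswith(prefix):
            return prefix[0]
    return "?"


def _short_name(clade: str) -> str:
    leaf = clade.split("|")[-1]
    return leaf[3:] if leaf[:3] in {p for p in _RANK_PREFIXES} else leaf


def read_profile_table(path, rank: str = "s", percent: bool | None = None) -> AbundanceTable:
    """Read a MetaPhlAn-style TSV profile into an :class:`AbundanceTable`.

    Parameters
    ----------
    path : path-like
        TSV with clade strings in the first column and one column per sample.
    rank : str
        Single-letter rank to extract (default ``"s"`` for species).
    percent : bool or None
        Whether values are percentages. ``None`` auto-detects: if the mean
        per-sample sum over the selected rank exceeds 1.5 the table is taken
        as percentages and divided by 100.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise FormatError("duplicate sample column")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.has_duplicates:
        raise FormatError("duplicate clade row")
    values = raw.to_numpy(dtype=float)
    if (values < 0).any():
        raise FormatError("negative value in profile table")

    clades = raw.index.astype(str)
    unknown = clades.str.contains("UNKNOWN", case=False) | clades.str.contains("unclassified")
    if unknown.any():
        logger.info("dropping %d UNKNOWN/unclassified rows", int(unknown.sum()))
        raw = raw.loc[~unknown]
        clades = raw.index.astype(str)

    keep = [c for c in clades if _clade_rank(c) == rank]
    sub = raw.loc[keep]
    mat = sub.to_numpy(dtype=float)
    if percent is None:
        percent = bool(mat.sum(axis=0).mean() > 1.5) if mat.size else False
    if percent:
        mat = mat / 100.0

    short = [_short_name(c) for c in keep]
    data = pd.DataFrame(mat.T, index=raw.columns, columns=short)
    lineages = dict(zip(short, keep))
    return AbundanceTable(data, lineages)


def write_profile_table(table: AbundanceTable, path) -> None:
    """Write an :class:`AbundanceTable` as MetaPhlAn-style percentages."""
    out = pd.DataFrame(
        table.data.to_numpy(dtype=float).T * 100.0,
        index=[table.lineage_of(t) for t in table.taxon_ids],
        columns=table.sample_ids,
    )
    out.index.name = "clade_name"
    out.to_csv(path, sep="\t", float_format="%.10g", encoding="utf-8")


def read_metadata(path, kinds_path=None) -> MetadataTable:
    """Read a metadata CSV plus its JSON kind-declaration sidecar."""
    path = Path(path)
    if kinds_path is None:
        kinds_path = path.with_suffix(".kinds.json")
    data = pd.read_csv(path, index_col=0)
    with open(kinds_path, encoding="utf-8") as fh:
        kinds = json.load(fh)
    for col, kind in kinds.items():
        if kind != "nominal" and col in data.columns:
            data[col] = data[col].astype(float)
    return MetadataTable(data, kinds)


def write_metadata(meta: MetadataTable, path, kinds_path=None) -> None:
    path = Path(path)
    if kinds_path is None:
        kinds_path = path.with_suffix(".kinds.json")
    meta.data.to_csv(path, float_format="%.10g", encoding="utf-8")
    with open(kinds_path, "w", encoding="utf-8") as fh:
        json.dump(meta.kinds, fh, indent=1, sort_keys=True)


def prevalence_filter(table: AbundanceTable, min_prevalence: float = 0.10) -> AbundanceTable:
    """Retain taxa with nonzero abundance in >= min_prevalence of samples.

    The boundary is inclusive: with 100 samples and ``min_prevalence=0.10``,
    presence in exactly 10 samples retains the taxon. Prevalence counts
    strictly positive entries.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    n = len(table.data)
    need = int(np.ceil(min_prevalence * n))
    counts = (table.data.to_numpy(dtype=float) > 0).sum(axis=0)
    keep = [t for t, c in zip(table.taxon_ids, counts) if c >= need]
    if not keep:
        logger.warning("prevalence_filter removed every taxon")
    data = table.data.loc[:, keep]
    lineages = {t: table.lineages[t] for t in keep if t in table.lineages}
    return AbundanceTable(data, lineages)


def arcsine_sqrt(x):
    """Elementwise arcsine-square-root transform of fractions.

    Values must lie in [0, 1]; values in (1, 1 + 1e-9] are clamped to 1,
    anything further outside raises. Output lies in [0, pi/2]. Accepts and
    returns either a DataFrame or an ndarray.
    """
    frame = isinstance(x, pd.DataFrame)
    arr = x.to_numpy(dtype=float) if frame else np.asarray(x, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("arcsine_sqrt input contains NaN")
    if (arr < -1e-9).any() or (arr > 1 + 1e-9).any():
        raise ValueError("arcsine_sqrt input outside [0, 1]")
    arr = np.clip(arr, 0.0, 1.0)
    out = np.arcsin(np.sqrt(arr))
    if frame:
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out
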