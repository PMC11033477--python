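"""Ct-table data model, CSV readers/writers, replicate aggregation, and the
Ct -> relative-quantity transform shared by the stability methods.

A :class:`CtTable` is a rectangular gene x sample matrix of cycle-threshold
values with per-sample group labels.  Missing measurements are stored as NaN
and every downstream statistic documents how it treats them
(pairwise-complete by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "RelativeQuantityTable",
    "CtTableError",
    "read_ct_table",
    "write_ct_table",
    "aggregate_replicates",
    "to_relative_quantities",
]

#: Ct values must lie in (0, CT_MAX] cycles.
CT_MAX = 45.0


class CtTableError(ValueError):
    """Raised when a Ct table violates its contract."""


@dataclass
class CtTable:
    """Gene x sample matrix of cycle-threshold values.

    Parameters
    ----------
    genes : list of str
        Unique gene identifiers (row order of ``ct``).
    samples : list of str
        Unique sample identifiers (column order of ``ct``).
    ct : ndarray, shape (n_genes, n_samples)
        Ct values in cycles; NaN marks a missing cell.
    groups : dict
        Mapping sample -> group label; every sample must be present.
    replicate_of : dict, optional
        Mapping sample -> biological-unit id.  ``None`` when each column
        already represents one biological unit.
    meta : dict
        Free-form provenance (condition name, source file, warnings).
    """

    genes: list[str]
    samples: list[str]
    ct: np.ndarray
    groups: dict[str, str]
    replicate_of: dict[str, str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.ct = np.asarray(self.ct, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if len(self.genes) < 2:
            raise CtTableError("a Ct table needs >=2 genes")
        if len(self.samples) < 2:
            raise CtTableError("a Ct table needs >=2 samples")
        if len(set(self.genes)) != len(self.genes):
            raise CtTableError("gene identifiers must be unique")
        if len(set(self.samples)) != len(self.samples):
            raise CtTableError("sample identifiers must be unique")
        if self.ct.shape != (len(self.genes), len(self.samples)):
            raise CtTableError(
                f"ct matrix shape {self.ct.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        missing_groups = [s for s in self.samples if s not in self.groups]
        if missing_groups:
            raise CtTableError(f"samples without group label: {missing_groups}")
        finite = self.ct[np.isfinite(self.ct)]
        if finite.size and (np.any(finite <= 0) or np.any(finite > CT_MAX)):
            bad = finite[(finite <= 0) | (finite > CT_MAX)]
            raise CtTableError(
                f"Ct values outside (0, {CT_MAX:g}] cycles: {bad[:5].tolist()}"
            )
        if self.replicate_of is not None:
            extra = set(self.replicate_of) - set(self.samples)
            if extra:
                raise CtTableError(f"replicate_of references unknown samples: {sorted(extra)}")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise CtTableError(f"unknown gene {gene!r}") from None

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance (sample) order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def row(self, gene: str) -> np.ndarray:
        return self.ct[self.gene_index(gene)]

    def missing_cells(self) -> list[tuple[str, str]]:
        gi, sj = np.nonzero(~np.isfinite(self.ct))
        return [(self.genes[i], self.samples[j]) for i, j in zip(gi, sj)]

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame, genes as rows and samples as columns."""
        return pd.DataFrame(self.ct, index=self.genes, columns=self.samples)

    def copy_with(self, **kwargs) -> "CtTable":
        base = dict(
            genes=list(self.genes),
            samples=list(self.samples),
            ct=self.ct.copy(),
            groups=dict(self.groups),
            replicate_of=None if self.replicate_of is None else dict(self.replicate_of),
            meta=dict(self.meta),
        )
        base.update(kwargs)
        return CtTable(**base)


@dataclass
class RelativeQuantityTable:
    """Linear-scale relative quantities q_ij = base_i ** (anchor_i - Ct_ij).

    With the default per-gene minimum-Ct anchor every gene's maximum q is 1,
    so q lies in (0, 1].  ``base`` is the per-gene amplification base
    (2 at 100% efficiency) and ``anchor`` the per-gene anchoring Ct.
    """

    genes: list[str]
    samples: list[str]
    q: np.ndarray
    groups: dict[str, str]
    base: dict[str, float]
    anchor: dict[str, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        finite = self.q[np.isfinite(self.q)]
        if finite.size and np.any(finite <= 0):
            raise CtTableError("relative quantities must be strictly positive")

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def log2_matrix(self) -> np.ndarray:
        """log2 of q; NaN cells propagate."""
        return np.log2(self.q)


# ----------------------------------------------------------------------
# CSV I/O
# ----------------------------------------------------------------------

_LONG_COLUMNS = ["sample", "group", "gene", "replicate", "ct"]


def _parse_ct(value, row: int) -> float:
    if pd.isna(value) or (isinstance(value, str) and value.strip() in {"", "NA", "NaN"}):
        return math.nan
    try:
        ct = float(value)
    except (TypeError, ValueError):
        raise CtTableError(f"non-numeric Ct value {value!r} at data row {row}") from None
    if not (0 < ct <= CT_MAX):
        raise CtTableError(
            f"Ct value {ct} at data row {row} outside the (0, {CT_MAX:g}] cycle contract"
        )
    return ct


def read_ct_table(path, layout: str = "long", group_map=None, meta: dict | None = None) -> CtTable:
    """Read a Ct table from CSV.

    ``layout='long'`` expects columns ``sample, group, gene, replicate, ct``;
    one column per (sample, replicate) pair is created and ``replicate_of``
    maps it back to its biological unit.  ``layout='wide'`` expects gene rows
    by sample columns (first column = gene id) plus a ``group_map`` — either a
    mapping sample -> group or a path to a two-column CSV (sample, group).
    """
    if layout == "long":
        return _read_long(path, meta)
    if layout == "wide":
        return _read_wide(path, group_map, meta)
    raise CtTableError(f"unknown layout {layout!r}; expected 'long' or 'wide'")


def _read_long(path, meta: dict | None) -> CtTable:
    df = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CtTableError(f"long CSV missing required columns: {missing_cols}")

    dup = df.duplicated(subset=["gene", "sample", "replicate"], keep=False)
    if dup.any():
        g, s, r = df.loc[dup.idxmax(), ["gene", "sample", "replicate"]]
        raise CtTableError(f"duplicate record for (gene={g!r}, sample={s!r}, replicate={r!r})")

    cts = [_parse_ct(v, i + 2) for i, v in enumerate(df["ct"])]  # +2: header is row 1
    df = df.assign(_ct=cts)

    # column key = (sample, replicate); collapse the suffix when redundant
    reps_per_sample = df.groupby("sample")["replicate"].nunique()
    multi = set(reps_per_sample[reps_per_sample > 1].index)

    columns: list[str] = []
    replicate_of: dict[str, str] = {}
    groups: dict[str, str] = {}
    col_of: dict[tuple[str, str], str] = {}
    for _, rec in df.iterrows():
        key = (rec["sample"], rec["replicate"])
        if key in col_of:
            continue
        col = f"{rec['sample']}.{rec['replicate']}" if rec["sample"] in multi else rec["sample"]
        col_of[key] = col
        columns.append(col)
        replicate_of[col] = rec["sample"]
        groups[col] = rec["group"]

    # consistent group labels per biological unit
    for (sample, _), col in col_of.items():
        lbls = set(df.loc[df["sample"] == sample, "group"])
        if len(lbls) > 1:
            raise CtTableError(f"sample {sample!r} carries conflicting group labels {sorted(lbls)}")

    genes = list(dict.fromkeys(df["gene"]))
    ct = np.full((len(genes), len(columns)), np.nan)
    gi = {g: i for i, g in enumerate(genes)}
    ci = {c: j for j, c in enumerate(columns)}
    for _, rec in df.iterrows():
        ct[gi[rec["gene"]], ci[col_of[(rec["sample"], rec["replicate"])]]] = rec["_ct"]

    m = {"source": str(path), "layout": "long"}
    m.update(meta or {})
    return CtTable(genes=genes, samples=columns, ct=ct, groups=groups,
                   replicate_of=replicate_of, meta=m)


def _read_wide(path, group_map, meta: dict | None) -> CtTable:
    if group_map is None:
        raise CtTableError("wide layout requires a group_map (mapping or CSV path)")
    if not isinstance(group_map, Mapping):
        gm = pd.read_csv(group_map, dtype=str)
        if not {"sample", "group"} <= set(gm.columns):
            raise CtTableError("group-map CSV must have columns sample, group")
        group_map = dict(zip(gm["sample"], gm["group"]))

    df = pd.read_csv(path, index_col=0)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    ct = np.full(df.shape, np.nan)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            ct[i, j] = _parse_ct(df.iat[i, j], i + 2)
    m = {"source": str(path), "layout": "wide"}
    m.update(meta or {})
    return CtTable(genes=genes, samples=samples, ct=ct,
                   groups={s: group_map[s] for s in samples}, meta=m)


def write_ct_table(t: CtTable, path, layout: str = "long", precision: int = 6) -> None:
    """Write a Ct table to CSV (the formats :func:`read_ct_table` accepts).

    Wide layout writes only the matrix; persist the group map separately.
    """
    fmt = f"{{:.{precision}g}}"
    if layout == "long":
        rows = []
        for j, s in enumerate(t.samples):
            unit = t.replicate_of.get(s, s) if t.replicate_of else s
            for i, g in enumerate(t.genes):
                v = t.ct[i, j]
                rows.append({
                    "sample": unit,
                    "group": t.groups[s],
                    "gene": g,
                    "replicate": s if (t.replicate_of and unit != s) else "1",
                    "ct": "" if not np.isfinite(v) else fmt.format(v),
                })
        pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)
    elif layout == "wide":
        df = t.to_frame().map(lambda v: "" if not np.isfinite(v) else fmt.format(v))
        df.to_csv(path, index_label="gene")
    else:
        raise CtTableError(f"unknown layout {layout!r}")


# ----------------------------------------------------------------------
# Replicate aggregation and the relative-quantity transform
# ----------------------------------------------------------------------

def aggregate_replicates(t: CtTable, how: str = "mean") -> CtTable:
    """Collapse replicate columns into one column per biological unit.

    ``how`` is ``'mean'`` (default) or ``'median'``; missing replicates are
    ignored.  A unit with zero non-missing Ct for some gene keeps that cell
    missing and a warning is recorded in ``meta['warnings']``.
    """
    if t.replicate_of is None:
        raise CtTableError("aggregate_replicates requires replicate_of")
    if how not in {"mean", "median"}:
        raise CtTableError(f"unknown aggregation {how!r}")

    units: list[str] = list(dict.fromkeys(t.replicate_of[s] for s in t.samples))
    cols: dict[str, list[int]] = {u: [] for u in units}
    for j, s in enumerate(t.samples):
        cols[t.replicate_of[s]].append(j)

    groups: dict[str, str] = {}
    for u in units:
        lbls = {t.groups[t.samples[j]] for j in cols[u]}
        if len(lbls) > 1:
            raise CtTableError(f"replicates of unit {u!r} have conflicting groups {sorted(lbls)}")
        groups[u] = lbls.pop()

    reducer = np.nanmean if how == "mean" else np.nanmedian
    warnings: list[str] = []
    ct = np.full((t.n_genes, len(units)), np.nan)
    for k, u in enumerate(units):
        block = t.ct[:, cols[u]]
        valid = np.isfinite(block).sum(axis=1)
        reduced = np.full(t.n_genes, np.nan)
        has_data = valid > 0
        if has_data.any():
            reduced[has_data] = reducer(block[has_data], axis=1)
        ct[:, k] = reduced
        for i in np.nonzero(valid == 0)[0]:
            warnings.append(f"unit {u!r}, gene {t.genes[i]!r}: no non-missing replicate")
        for i in np.nonzero((valid > 0) & (valid < block.shape[1]))[0]:
            warnings.append(f"unit {u!r}, gene {t.genes[i]!r}: aggregated {valid[i]}/{block.shape[1]} replicates")

    meta = dict(t.meta)
    meta["replicates_aggregated"] = {u: len(cols[u]) for u in units}
    meta["aggregation"] = how
    if warnings:
        meta.setdefault("warnings", []).extend(warnings)
    return CtTable(genes=list(t.genes), samples=units, ct=ct, groups=groups,
                   replicate_of=None, meta=meta)


def to_relative_quantities(
    t: CtTable,
    efficiencies: Mapping[str, float] | None = None,
) -> RelativeQuantityTable:
    """Transform Ct to linear relative quantities q = base ** (anchor - Ct).

    ``efficiencies`` maps gene -> efficiency percent (100 = perfect
    doubling); genes absent from the mapping, or all genes when it is None,
    use base 2.  The anchor is the per-gene minimum observed Ct, so the
    maximum q of every gene is exactly 1.
    """
    efficiencies = dict(efficiencies or {})
    for g, e in efficiencies.items():
        if not (50.0 <= e <= 150.0):
            raise CtTableError(
                f"implausible amplification efficiency {e}% for gene {g!r} (allowed 50-150%)"
            )

    base = {g: 1.0 + efficiencies.get(g, 100.0) / 100.0 for g in t.genes}
    anchor: dict[str, float] = {}
    q = np.full_like(t.ct, np.nan)
    for i, g in enumerate(t.genes):
        row = t.ct[i]
        if not np.isfinite(row).any():
            raise CtTableError(f"gene {g!r} has no non-missing Ct")
        a = float(np.nanmin(row))
        anchor[g] = a
        with np.errstate(invalid="ignore"):
            q[i] = np.power(base[g], a - row)
    return RelativeQuantityTable(genes=list(t.genes), samples=list(t.samples), q=q,
                                 groups=dict(t.groups), base=base, anchor=anchor,
                                 meta=dict(t.meta))


def validation_report(t: CtTable) -> dict:
    """JSON-serializable validation summary (missing cells, warnings)."""
    return {
        "n_genes": t.n_genes,
        "n_samples": t.n_samples,
        "groups": {g: len(t.samples_in_group(g)) for g in t.group_labels()},
        "missing_cells": [list(c) for c in t.missing_cells()],
        "warnings": list(t.meta.get("warnings", [])),
    }
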