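"""Pipeline orchestration and report assembly.

``run_pipeline`` wires read -> aggregate -> transform -> stability methods
-> consensus and writes TSV/JSON outputs with a stable column order;
``render_report`` produces a plain-text summary.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io
from .consensus import ConsensusResult, build_rank_table, geomean_consensus
from .core_io import CtTable, CtTableError
from .stability import (
    StabilityResult,
    bestkeeper,
    delta_ct_stability,
    genorm,
    normfinder,
)

__all__ = ["RunConfig", "PipelineBundle", "run_pipeline", "render_report", "ALL_METHODS"]

ALL_METHODS = ("delta_ct", "genorm", "normfinder", "bestkeeper")


@dataclass
class RunConfig:
    input_path: str
    layout: str = "long"
    group_map: str | None = None
    methods: tuple[str, ...] = ALL_METHODS
    efficiency_table: str | None = None
    grouped: bool = True
    dispersion: str = "sample_sd"
    aggregate: str | None = "mean"       # None = keep replicates as samples
    out_dir: str | None = None
    verbose: bool = False

    def validate(self) -> None:
        if not self.methods:
            raise CtTableError("methods list must be non-empty")
        unknown = [m for m in self.methods if m not in ALL_METHODS]
        if unknown:
            raise CtTableError(f"unknown methods {unknown}; allowed: {list(ALL_METHODS)}")
        if self.layout not in {"long", "wide"}:
            raise CtTableError(f"unknown layout {self.layout!r}")
        if not Path(self.input_path).exists():
            raise CtTableError(f"input path does not exist: {self.input_path}")
        for p in (self.group_map, self.efficiency_table):
            if p is not None and not Path(p).exists():
                raise CtTableError(f"referenced path does not exist: {p}")


@dataclass
class PipelineBundle:
    table: CtTable
    results: dict[str, StabilityResult]
    consensus: ConsensusResult
    warnings: list[str] = field(default_factory=list)


def read_efficiency_table(path) -> dict[str, float]:
    """Two-column table gene -> efficiency percent (TSV or CSV by suffix)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "efficiency_percent" not in cols:
        raise CtTableError("efficiency table needs columns gene, efficiency_percent")
    return dict(zip(df[cols["gene"]], df[cols["efficiency_percent"]].astype(float)))


def compute_stability(
    t: CtTable,
    methods=ALL_METHODS,
    efficiencies=None,
    grouped: bool = True,
    dispersion: str = "sample_sd",
) -> dict[str, StabilityResult]:
    """Run the selected stability methods on an aggregated Ct table."""
    results: dict[str, StabilityResult] = {}
    for m in methods:
        if m == "delta_ct":
            results[m] = delta_ct_stability(t)
        elif m == "genorm":
            rq = core_io.to_relative_quantities(t, efficiencies)
            results[m] = genorm(rq)
        elif m == "normfinder":
            results[m] = normfinder(t, use_groups=grouped, efficiencies=efficiencies)
        elif m == "bestkeeper":
            results[m] = bestkeeper(t, dispersion=dispersion)
        else:
            raise CtTableError(f"unknown method {m!r}")
    return results


def run_pipeline(config: RunConfig) -> PipelineBundle:
    config.validate()
    t = core_io.read_ct_table(config.input_path, layout=config.layout,
                              group_map=config.group_map)
    warnings: list[str] = []
    if config.aggregate and t.replicate_of is not None:
        units = set(t.replicate_of.values())
        if len(units) < len(t.samples):
            t = core_io.aggregate_replicates(t, how=config.aggregate)
            warnings.extend(t.meta.get("warnings", []))

    efficiencies = (read_efficiency_table(config.efficiency_table)
                    if config.efficiency_table else None)
    results = compute_stability(t, methods=config.methods, efficiencies=efficiencies,
                                grouped=config.grouped, dispersion=config.dispersion)
    for r in results.values():
        warnings.extend(f"{r.method}: {w}" for w in r.warnings)

    if len(results) >= 2:
        cons = geomean_consensus(build_rank_table(list(results.values())))
    else:
        only = next(iter(results.values()))
        ordering = only.ordering()
        cons = ConsensusResult(
            rank_table=pd.DataFrame({only.method: [only.ranks[g] for g in sorted(only.ranks)]},
                                    index=sorted(only.ranks)),
            geomean={g: float(only.ranks[g]) for g in only.ranks},
            ordering=ordering,
            recommended_pair=(ordering[0], ordering[1]),
            methods_used=[only.method],
        )

    bundle = PipelineBundle(table=t, results=results, consensus=cons, warnings=warnings)
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


# ----------------------------------------------------------------------
# Output writing
# ----------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    if isinstance(o, (set, frozenset, tuple)):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_bundle(bundle: PipelineBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for name, res in bundle.results.items():
        genes = sorted(res.values, key=lambda g: (res.ranks[g], g))
        df = pd.DataFrame({
            "gene": genes,
            "stability": [res.values[g] for g in genes],
            "rank": [res.ranks[g] for g in genes],
        })
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")

    if "genorm" in bundle.results:
        detail = bundle.results["genorm"].details
        vdf = pd.DataFrame({
            "n": list(detail.v_series),
            "v": [detail.v_series[n] for n in detail.v_series],
            "below_threshold": [bool(np.isfinite(detail.v_series[n]) and detail.v_series[n] < detail.v_threshold)
                                for n in detail.v_series],
        })
        vdf.to_csv(out / "genorm_v.tsv", sep="\t", index=False, float_format="%.6g")

    cons = bundle.consensus.to_frame().reset_index(names="gene")
    cons.to_csv(out / "consensus.tsv", sep="\t", index=False, float_format="%.6g")

    report = {
        "methods": list(bundle.results),
        "recommended_pair": list(bundle.consensus.recommended_pair),
        "ordering": bundle.consensus.ordering,
        "geomean": bundle.consensus.geomean,
        "warnings": bundle.warnings,
        "details": {m: r.details for m, r in bundle.results.items()},
        "validation": core_io.validation_report(bundle.table),
    }
    (out / "report.json").write_text(json.dumps(report, default=_json_default, indent=1))


def render_report(bundle: PipelineBundle) -> str:
    """Plain-text summary: per-method ranks, geomean ordering, V series."""
    if not bundle.results:
        raise CtTableError("empty bundle: no stability results")
    lines: list[str] = []
    lines.append("Reference-gene stability report")
    lines.append("=" * 31)
    table = bundle.consensus.to_frame().reset_index(names="gene")
    lines.append(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    lines.append("")
    pair = bundle.consensus.recommended_pair
    lines.append(f"Recommended reference pair: {pair[0]} + {pair[1]}")
    if "genorm" in bundle.results:
        d = bundle.results["genorm"].details
        vtxt = ", ".join(
            f"V{n}/{n + 1}={d.v_series[n]:.4g}" + ("" if d.v_series[n] < d.v_threshold else " (>=0.15)")
            for n in d.v_series if math.isfinite(d.v_series[n])
        )
        lines.append(f"geNorm pairwise variation: {vtxt}")
        lines.append(f"Optimal number of reference genes (first V<{d.v_threshold:g}, min 2): {d.recommended_n}")
    ties = [m for m, r in bundle.results.items() if len(set(r.ranks.values())) < len(r.ranks)]
    if ties:
        lines.append(f"Tied ranks present in: {', '.join(ties)} (dense ranking; deterministic tie-breaks)")
    if bundle.warnings:
        lines.append("")
        lines.append("Warnings:")
        lines.extend(f"  - {w}" for w in bundle.warnings)
    return "\n".join(lines) + "\n"
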