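"""Synthetic Ct generator with known ground truth.

The generative model per gene i, group g, biological sample j, technical
replicate r is

    Ct = mu_i + L_j + delta_i * u_{ig} + eps_{ijr}

with L_j ~ N(0, loading_sd^2) a per-sample loading shift shared by all
genes, u_{ig} ~ N(0, 1) a per-(gene, group) biological effect scaled by
delta_i, and eps ~ N(0, sigma_i^2) technical noise.  All randomness flows
from a single seed through one generator, so outputs are bit-reproducible.

The recorded truth ranks genes by total disturbance
sqrt(sigma_i^2 + delta_i^2 * var(u_{i,.})), using the realized group
effects, and carries per-group fold changes for an optional target gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import CtTable, CtTableError

__all__ = [
    "GeneSpec",
    "GroupSpec",
    "TargetSpec",
    "SimulationSpec",
    "SimulationTruth",
    "simulate_ct",
    "paper_like_design",
    "CONDITIONS",
]


@dataclass(frozen=True)
class GeneSpec:
    name: str
    baseline: float            # mean Ct, cycles
    noise_sd: float            # sigma_i, cycles
    group_effect_sd: float     # delta_i, cycles

    def validate(self) -> None:
        if not (5.0 < self.baseline < 40.0):
            raise CtTableError(f"gene {self.name!r}: baseline {self.baseline} outside (5, 40)")
        if self.noise_sd < 0:
            raise CtTableError(f"gene {self.name!r}: noise_sd must be >= 0")
        if self.group_effect_sd < 0:
            raise CtTableError(f"gene {self.name!r}: group_effect_sd must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_biological: int = 3
    n_technical: int = 1

    def validate(self) -> None:
        if self.n_biological < 1:
            raise CtTableError(f"group {self.label!r}: n_biological must be >= 1")
        if self.n_technical < 1:
            raise CtTableError(f"group {self.label!r}: n_technical must be >= 1")


@dataclass(frozen=True)
class TargetSpec:
    """Optional target gene with true per-group fold changes (linear scale)."""
    name: str
    baseline: float
    noise_sd: float
    fold_changes: dict[str, float] = field(default_factory=dict)  # group -> fold, default 1


@dataclass
class SimulationSpec:
    genes: list[GeneSpec]
    groups: list[GroupSpec]
    loading_sd: float = 0.0
    seed: int = 0
    target_spec: TargetSpec | None = None
    condition: str = "custom"

    def validate(self) -> None:
        if len(self.genes) < 2:
            raise CtTableError("simulation needs >=2 genes")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise CtTableError("gene names must be unique")
        total = sum(g.n_biological * g.n_technical for g in self.groups)
        if total < 2:
            raise CtTableError("simulation needs >=2 samples in total")
        if self.loading_sd < 0:
            raise CtTableError("loading_sd must be >= 0")
        for g in self.genes:
            g.validate()
        for gr in self.groups:
            gr.validate()
        if self.target_spec is not None:
            unknown = set(self.target_spec.fold_changes) - {g.label for g in self.groups}
            if unknown:
                raise CtTableError(f"target fold changes for unknown groups: {sorted(unknown)}")


@dataclass
class SimulationTruth:
    disturbance: dict[str, float]
    ordering: list[str]                       # ascending disturbance (most stable first)
    loading_shifts: dict[str, float]          # biological sample -> L_j
    group_effects: dict[str, dict[str, float]]  # gene -> group -> delta_i * u_{ig}
    target_fold_changes: dict[str, float] | None

    def top(self, k: int) -> set[str]:
        return set(self.ordering[:k])


def simulate_ct(spec: SimulationSpec) -> tuple[CtTable, SimulationTruth]:
    """Draw one Ct table (plus truth) from the generative model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    genes = list(spec.genes)
    gene_names = [g.name for g in genes]
    target = spec.target_spec

    # per-(gene, group) effects
    u = rng.standard_normal((len(genes), len(spec.groups)))
    group_effects = {
        g.name: {gr.label: g.group_effect_sd * u[i, k] for k, gr in enumerate(spec.groups)}
        for i, g in enumerate(genes)
    }

    samples: list[str] = []
    groups_map: dict[str, str] = {}
    replicate_of: dict[str, str] = {}
    loading: dict[str, float] = {}
    columns: list[tuple[str, str]] = []  # (biological unit, column id)
    any_tech = any(gr.n_technical > 1 for gr in spec.groups)
    for gr in spec.groups:
        for b in range(1, gr.n_biological + 1):
            unit = f"{gr.label}_b{b}"
            # scaled standard normal keeps the rng stream identical across
            # parameter settings (same seed -> same underlying draws)
            loading[unit] = spec.loading_sd * rng.standard_normal()
            for r in range(1, gr.n_technical + 1):
                col = f"{unit}_t{r}" if any_tech else unit
                samples.append(col)
                groups_map[col] = gr.label
                replicate_of[col] = unit
                columns.append((unit, col))

    all_names = gene_names + ([target.name] if target else [])
    ct = np.zeros((len(all_names), len(samples)))
    for i, g in enumerate(genes):
        for j, (unit, col) in enumerate(columns):
            lab = groups_map[col]
            eps = g.noise_sd * rng.standard_normal()
            ct[i, j] = g.baseline + loading[unit] + group_effects[g.name][lab] + eps
    if target:
        ti = len(gene_names)
        for j, (unit, col) in enumerate(columns):
            lab = groups_map[col]
            fold = target.fold_changes.get(lab, 1.0)
            eps = target.noise_sd * rng.standard_normal()
            ct[ti, j] = target.baseline + loading[unit] - math.log2(fold) + eps

    np.clip(ct, 1.0, 44.0, out=ct)

    table = CtTable(
        genes=all_names,
        samples=samples,
        ct=ct,
        groups=groups_map,
        replicate_of=replicate_of if any_tech else None,
        meta={"condition": spec.condition, "seed": spec.seed,
              "target": target.name if target else None},
    )

    disturbance = {}
    for g in genes:
        effects = np.array([group_effects[g.name][gr.label] for gr in spec.groups])
        disturbance[g.name] = math.sqrt(g.noise_sd ** 2 + float(np.var(effects)))
    ordering = sorted(gene_names, key=lambda n: (disturbance[n], n))

    truth = SimulationTruth(
        disturbance=disturbance,
        ordering=ordering,
        loading_shifts=loading,
        group_effects=group_effects,
        target_fold_changes=dict(target.fold_changes) if target else None,
    )
    return table, truth


# ----------------------------------------------------------------------
# Ready-made designs mirroring a 10-gene candidate panel under four
# experimental conditions (ages / tissues / temperature / sex).
# ----------------------------------------------------------------------

PANEL = ["ACT", "ARF1", "AK", "EF1a", "GAPDH", "aTUB", "RPL6", "RPL13", "RPS3", "RPS18"]

CONDITIONS: dict[str, list[str]] = {
    "ages": ["age_3d", "age_10d", "age_20d"],
    "tissues": ["epidermis", "foregut", "midgut", "hindgut", "trachea", "antenna"],
    "temperature": ["4C", "15C", "20C", "26C", "35C"],
    "sex": ["male", "female"],
}

# default disturbance profile: ribosomal-protein genes most stable, the
# classic metabolic genes least; >=3x separation between the top-2 and the rest
_DEFAULT_PROFILE: dict[str, tuple[float, float, float]] = {
    # name: (baseline Ct, noise_sd, group_effect_sd)
    "RPL6":  (18.0, 0.08, 0.05),
    "RPL13": (18.5, 0.10, 0.06),
    "RPS18": (19.0, 0.35, 0.25),
    "RPS3":  (19.5, 0.40, 0.30),
    "EF1a":  (20.0, 0.45, 0.35),
    "ARF1":  (23.0, 0.50, 0.40),
    "AK":    (21.0, 0.55, 0.45),
    "aTUB":  (24.0, 0.60, 0.50),
    "GAPDH": (22.0, 0.70, 0.70),
    "ACT":   (20.5, 0.75, 0.80),
}


def paper_like_design(
    condition: str,
    seed: int = 0,
    n_biological: int = 3,
    n_technical: int = 1,
    loading_sd: float = 0.3,
    with_target: bool = False,
) -> SimulationSpec:
    """A ready 10-gene design for one of the four study-like conditions.

    Groups follow the condition (3 ages / 6 tissues / 5 temperatures /
    2 sexes) with 3 biological replicates by default.  The disturbance
    profile makes RPL6 and RPL13 the most stable genes and GAPDH/ACT the
    least.  ``with_target`` adds a 4-fold up-regulated target gene in the
    first group for normalization fixtures.
    """
    if condition not in CONDITIONS:
        raise CtTableError(
            f"unknown condition {condition!r}; expected one of {sorted(CONDITIONS)}"
        )
    labels = CONDITIONS[condition]
    genes = [GeneSpec(n, *_DEFAULT_PROFILE[n]) for n in PANEL]
    groups = [GroupSpec(lab, n_biological=n_biological, n_technical=n_technical) for lab in labels]
    target = None
    if with_target:
        target = TargetSpec(name="UAP", baseline=26.0, noise_sd=0.1,
                            fold_changes={labels[0]: 4.0})
    return SimulationSpec(genes=genes, groups=groups, loading_sd=loading_sd,
                          seed=seed, target_spec=target, condition=condition)
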