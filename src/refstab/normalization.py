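"""Target-gene relative quantification by 2^-ddCt against a multi-gene
reference set, with one-way ANOVA + Tukey HSD group comparison.

The reference aggregate per sample is the arithmetic mean of the reference
Ct values (equivalently the geometric mean of their relative quantities at
base 2).  ddCt is re-centered on the mean dCt of the calibrator group, so
the calibrator group's mean ddCt is zero by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import CtTable, CtTableError

__all__ = ["RelativeExpression", "relative_expression", "group_anova", "compact_letter_display"]


@dataclass
class RelativeExpression:
    target: str
    reference_set: list[str]
    calibrator: str
    samples: list[str]
    groups: dict[str, str]
    delta_ct: dict[str, float]
    delta_delta_ct: dict[str, float]
    rq: dict[str, float]
    group_summary: pd.DataFrame          # group, mean_rq, se, n
    letters: dict[str, str] | None = None
    anova_p: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.samples,
            "group": [self.groups[s] for s in self.samples],
            "delta_ct": [self.delta_ct[s] for s in self.samples],
            "delta_delta_ct": [self.delta_delta_ct[s] for s in self.samples],
            "rq": [self.rq[s] for s in self.samples],
        })


def relative_expression(
    t: CtTable,
    target: str,
    refs: Sequence[str],
    calibrator: str,
) -> RelativeExpression:
    """Per-sample 2^-ddCt of ``target`` against the mean Ct of ``refs``.

    ``calibrator`` is a group label; samples with any missing Ct among the
    target or references are dropped with a warning.
    """
    refs = list(refs)
    if not refs:
        raise CtTableError("reference set must be non-empty")
    if target in refs:
        raise CtTableError(f"target {target!r} cannot be in the reference set")
    for g in [target, *refs]:
        t.gene_index(g)  # raises for unknown genes
    if calibrator not in t.group_labels():
        raise CtTableError(f"unknown calibrator group {calibrator!r}")

    warnings: list[str] = []
    ti = t.gene_index(target)
    ri = [t.gene_index(g) for g in refs]

    used: list[str] = []
    dct: dict[str, float] = {}
    for j, s in enumerate(t.samples):
        vals = t.ct[[ti, *ri], j]
        if not np.isfinite(vals).all():
            warnings.append(f"sample {s!r} dropped: incomplete target/reference Ct")
            continue
        used.append(s)
        dct[s] = float(t.ct[ti, j] - np.mean(t.ct[ri, j]))

    cal_samples = [s for s in used if t.groups[s] == calibrator]
    if not cal_samples:
        raise CtTableError(f"calibrator group {calibrator!r} has no complete samples")
    cal_mean = float(np.mean([dct[s] for s in cal_samples]))

    ddct = {s: dct[s] - cal_mean for s in used}
    rq = {s: 2.0 ** (-ddct[s]) for s in used}

    rows = []
    groups = {s: t.groups[s] for s in used}
    for lab in dict.fromkeys(groups[s] for s in used):
        vals = np.array([rq[s] for s in used if groups[s] == lab])
        se = float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan
        rows.append({"group": lab, "mean_rq": float(vals.mean()), "se": se, "n": int(vals.size)})
    summary = pd.DataFrame(rows)

    return RelativeExpression(
        target=target, reference_set=refs, calibrator=calibrator,
        samples=used, groups=groups, delta_ct=dct, delta_delta_ct=ddct,
        rq=rq, group_summary=summary, warnings=warnings,
    )


def compact_letter_display(
    groups: Sequence[str],
    different: set[frozenset[str]],
) -> dict[str, str]:
    """Assign letters so two groups share one iff not significantly different.

    Insert-and-absorb: start from one all-inclusive letter set, split on
    each significant pair, drop subsets, then label sets a, b, c, ... in
    group order.
    """
    sets: list[set[str]] = [set(groups)]
    for pair in different:
        a, b = tuple(pair)
        for s in list(sets):
            if a in s and b in s:
                sets.remove(s)
                for drop in (a, b):
                    new = s - {drop}
                    if new and not any(new <= other for other in sets):
                        sets.append(new)
    sets = [s for s in sets if not any(s < other for other in sets)]
    # stable ordering: sets sorted by earliest member in group order
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in groups:
            if g in s:
                letters[g] += letter
    return letters


def group_anova(re: RelativeExpression, alpha: float = 0.05) -> RelativeExpression:
    """One-way ANOVA on rq across groups plus Tukey HSD letters.

    Groups with fewer than 2 replicates are excluded with a warning; if all
    values are identical the p-value is reported as 1 with a single shared
    letter.  Mutates and returns ``re`` with ``anova_p`` and ``letters``.
    """
    by_group: dict[str, list[float]] = {}
    for s in re.samples:
        by_group.setdefault(re.groups[s], []).append(re.rq[s])

    usable = {g: np.array(v) for g, v in by_group.items() if len(v) >= 2}
    for g in by_group:
        if g not in usable:
            re.warnings.append(f"group {g!r} excluded from ANOVA (<2 replicates)")
    if len(usable) < 2:
        raise CtTableError("ANOVA needs >=2 groups with >=2 replicates")

    labels = list(usable)
    allvals = np.concatenate([usable[g] for g in labels])
    if np.allclose(allvals, allvals[0]):
        re.anova_p = 1.0
        re.letters = {g: "a" for g in labels}
        return re

    re.anova_p = float(sps.f_oneway(*[usable[g] for g in labels]).pvalue)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    flat_groups = np.concatenate([[g] * len(usable[g]) for g in labels])
    tukey = pairwise_tukeyhsd(allvals, flat_groups, alpha=alpha)
    different: set[frozenset[str]] = set()
    for (g1, g2), reject in zip(
        ((tukey.groupsunique[i], tukey.groupsunique[j]) for i, j in zip(*np.triu_indices(len(tukey.groupsunique), 1))),
        tukey.reject,
    ):
        if reject:
            different.add(frozenset((str(g1), str(g2))))
    re.letters = compact_letter_display(labels, different)
    return re
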