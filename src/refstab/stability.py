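"""The four reference-gene stability statistics.

* ``delta_ct_stability`` — mean over partner genes of the sample SD of
  pairwise Ct differences.
* ``genorm`` — average pairwise variation M with stepwise elimination and
  the V_n/n+1 series for choosing how many references to use.
* ``normfinder`` — variance-decomposition stability after removing
  per-sample loading, with optional group structure and shrunken
  intergroup deviations.
* ``bestkeeper`` — descriptive dispersion of raw Ct plus the per-sample
  geometric-mean index and gene-vs-index correlations.

All four report "lower = more stable" values and dense integer ranks
(1 = most stable, ties share a rank).  Missing cells are handled
pairwise-complete; dropped pairs/samples are recorded as warnings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .core_io import CtTable, CtTableError, RelativeQuantityTable

__all__ = [
    "StabilityResult",
    "GeNormDetail",
    "NormFinderDetail",
    "BestKeeperDetail",
    "delta_ct_stability",
    "genorm",
    "normfinder",
    "bestkeeper",
    "dense_ranks",
    "V_THRESHOLD",
]

#: conventional pairwise-variation cut-off: V_n/n+1 below this means n genes suffice
V_THRESHOLD = 0.15

_TIE_DECIMALS = 10  # values equal after rounding here share a rank


def dense_ranks(values: Mapping[str, float]) -> dict[str, int]:
    """Dense ranking, 1 = smallest value; ties (to 1e-10) share a rank."""
    rounded = {g: round(float(v), _TIE_DECIMALS) for g, v in values.items()}
    distinct = sorted(set(rounded.values()))
    level = {v: r + 1 for r, v in enumerate(distinct)}
    return {g: level[rounded[g]] for g in values}


@dataclass
class StabilityResult:
    method: str
    values: dict[str, float]
    ranks: dict[str, int]
    details: object = None
    warnings: list[str] = field(default_factory=list)

    def ordering(self) -> list[str]:
        """Genes from most to least stable (value, then id for ties)."""
        return sorted(self.values, key=lambda g: (self.values[g], g))


def _finish(method: str, values: dict[str, float], details, warnings) -> StabilityResult:
    return StabilityResult(method=method, values=values, ranks=dense_ranks(values),
                           details=details, warnings=list(warnings))


# ----------------------------------------------------------------------
# Comparative delta-Ct method
# ----------------------------------------------------------------------

def _pairwise_sd_matrix(mat: np.ndarray, genes: list[str], warnings: list[str]) -> np.ndarray:
    """SD (n-1 denominator) of per-sample differences for every gene pair.

    Entry [i, k] is NaN when fewer than 2 pairwise-complete samples exist.
    """
    K = len(genes)
    out = np.full((K, K), np.nan)
    for i in range(K):
        for k in range(i + 1, K):
            d = mat[i] - mat[k]
            d = d[np.isfinite(d)]
            if d.size < 2:
                warnings.append(
                    f"pair ({genes[i]}, {genes[k]}): only {d.size} complete sample(s); excluded"
                )
                continue
            out[i, k] = out[k, i] = float(np.std(d, ddof=1))
    return out


def delta_ct_stability(t: CtTable) -> StabilityResult:
    """Comparative delta-Ct stability: mean pairwise SD of Ct differences.

    For each ordered gene pair the per-sample Ct differences are reduced to
    their sample standard deviation; a gene's stability is the mean of those
    SDs over all partners.  Per-sample loading shifts cancel in the
    differences, so the statistic is loading-invariant.
    """
    if t.n_genes < 2:
        raise CtTableError("delta-Ct method needs >=2 genes")
    warnings: list[str] = []
    sd = _pairwise_sd_matrix(t.ct, t.genes, warnings)
    values: dict[str, float] = {}
    for i, g in enumerate(t.genes):
        partners = np.delete(sd[i], i)
        partners = partners[np.isfinite(partners)]
        if partners.size == 0:
            raise CtTableError(f"gene {g!r} has no valid partner pair")
        values[g] = float(np.mean(partners))
    details = {"pairwise_sd": sd, "genes": list(t.genes)}
    return _finish("delta_ct", values, details, warnings)


# ----------------------------------------------------------------------
# geNorm
# ----------------------------------------------------------------------

@dataclass
class GeNormDetail:
    initial_m: dict[str, float]
    stepwise_m: list[dict[str, float]]
    elimination_order: list[str]
    final_pair: tuple[str, str]
    v_series: dict[int, float]
    v_threshold: float
    recommended_n: int
    stability_order: list[str]


def _genorm_m(log2q: np.ndarray, genes: list[str], warnings: list[str]) -> dict[str, float]:
    """Average pairwise variation M for the given panel."""
    sd = _pairwise_sd_matrix(log2q, genes, warnings)
    m: dict[str, float] = {}
    for i, g in enumerate(genes):
        partners = np.delete(sd[i], i)
        partners = partners[np.isfinite(partners)]
        if partners.size == 0:
            raise CtTableError(f"gene {g!r} has no valid partner pair for geNorm M")
        m[g] = float(np.mean(partners))
    return m


def genorm(rq: RelativeQuantityTable) -> StabilityResult:
    """geNorm stability: M values, stepwise elimination, and V_n/n+1.

    Pairwise variation V_ik is the sample SD across samples of
    log2(q_i / q_k); M_i is the mean V_ik over partners.  The gene with the
    largest M is removed and M recomputed until two genes remain; those two
    share rank 1 and both carry their mutual V from the final 2-gene panel.
    Ties for the largest M are broken by removing the lexicographically
    last gene id.

    The V series compares normalization factors built from the n and n+1
    most stable genes: NF_n is the per-sample geometric mean of q over the
    top n genes and V_n/n+1 = SD across samples of log2(NF_n / NF_{n+1}).
    The recommended panel size is the first n with V below 0.15 (minimum 2).
    """
    if rq.q.shape[0] < 2:
        raise CtTableError("geNorm needs >=2 genes")
    warnings: list[str] = []
    log2q = rq.log2_matrix()
    genes = list(rq.genes)

    initial_m = _genorm_m(log2q, genes, warnings)

    panel = list(genes)
    idx = {g: i for i, g in enumerate(genes)}
    stepwise: list[dict[str, float]] = []
    elimination: list[str] = []
    values: dict[str, float] = {}
    current_m = dict(initial_m)
    while len(panel) > 2:
        stepwise.append(dict(current_m))
        worst = max(current_m.values())
        tied = sorted(g for g, v in current_m.items() if math.isclose(v, worst, abs_tol=10 ** -_TIE_DECIMALS))
        out = tied[-1]  # lexicographically last among ties
        if len(tied) > 1:
            warnings.append(f"elimination tie at M={worst:.6g}: removed {out!r} among {tied}")
        values[out] = current_m[out]
        elimination.append(out)
        panel.remove(out)
        sub = np.stack([log2q[idx[g]] for g in panel])
        current_m = _genorm_m(sub, panel, warnings)
    stepwise.append(dict(current_m))

    final_pair = tuple(sorted(panel))
    # in a 2-gene panel both M values equal the mutual pairwise SD
    for g in final_pair:
        values[g] = current_m[g]

    stability_order = list(final_pair) + elimination[::-1]

    v_series: dict[int, float] = {}
    K = len(genes)
    for n in range(2, K):
        top_n = [idx[g] for g in stability_order[:n]]
        top_n1 = [idx[g] for g in stability_order[: n + 1]]
        nf_n = np.nanmean(log2q[top_n], axis=0)     # log2 of geometric mean of q
        nf_n1 = np.nanmean(log2q[top_n1], axis=0)
        d = nf_n - nf_n1
        d = d[np.isfinite(d)]
        if d.size < 2:
            warnings.append(f"V_{n}/{n + 1}: fewer than 2 complete samples; undefined")
            v_series[n] = math.nan
            continue
        v_series[n] = float(np.std(d, ddof=1))

    recommended_n = 2
    for n in sorted(v_series):
        if np.isfinite(v_series[n]) and v_series[n] < V_THRESHOLD:
            recommended_n = max(n, 2)
            break
    else:
        if v_series:
            recommended_n = max(v_series) + 1
            warnings.append(f"no V_n/n+1 below {V_THRESHOLD}; recommending all {recommended_n} genes")

    detail = GeNormDetail(
        initial_m=initial_m,
        stepwise_m=stepwise,
        elimination_order=elimination + list(final_pair[::-1]),
        final_pair=final_pair,
        v_series=v_series,
        v_threshold=V_THRESHOLD,
        recommended_n=recommended_n,
        stability_order=stability_order,
    )
    return _finish("genorm", values, detail, warnings)


# ----------------------------------------------------------------------
# NormFinder
# ----------------------------------------------------------------------

@dataclass
class NormFinderDetail:
    grouped: bool
    z: np.ndarray                    # gene x sample, sample-centered log2 expression
    group_means: dict[str, dict[str, float]] | None
    group_vars: dict[str, dict[str, float]] | None
    raw_deviation: dict[str, dict[str, float]] | None
    shrunken_deviation: dict[str, dict[str, float]] | None
    tau2: dict[str, float] | None


def normfinder(
    t: CtTable,
    use_groups: bool = True,
    efficiencies: Mapping[str, float] | None = None,
) -> StabilityResult:
    """Model-based stability after removing per-sample loading.

    Ct is mapped to log2 expression y = -Ct * log2(base) (base 2 by default,
    so y = -Ct) and centered per sample across genes, giving z.  Ungrouped,
    a gene's stability is the sample SD of its z row.  Grouped, per-group
    means and variances of z yield raw intergroup deviations d (weighted to
    zero across groups), a between-group variance tau^2 estimated by a
    moment estimator truncated at zero, shrunken deviations
    d * tau^2 / (tau^2 + s^2/n), and stability
    S = mean over groups of |shrunken d| + sqrt(s^2/n).
    """
    if t.n_genes < 3:
        raise CtTableError("NormFinder needs >=3 genes for per-sample centering")
    warnings: list[str] = []

    efficiencies = dict(efficiencies or {})
    base = np.array([1.0 + efficiencies.get(g, 100.0) / 100.0 for g in t.genes])
    y = -t.ct * np.log2(base)[:, None]

    complete = np.isfinite(y).all(axis=0)
    if not complete.all():
        dropped = [t.samples[j] for j in np.nonzero(~complete)[0]]
        warnings.append(f"samples dropped (incomplete across genes): {dropped}")
    if complete.sum() < 2:
        raise CtTableError("NormFinder needs >=2 complete samples")
    y = y[:, complete]
    samples = [s for s, c in zip(t.samples, complete) if c]

    z = y - y.mean(axis=0, keepdims=True)

    group_of = [t.groups[s] for s in samples]
    labels = list(dict.fromkeys(group_of))

    if use_groups and len(labels) < 2:
        warnings.append("single group: falling back to ungrouped NormFinder")
        use_groups = False

    if not use_groups:
        values = {g: float(np.std(z[i], ddof=1)) for i, g in enumerate(t.genes)}
        detail = NormFinderDetail(grouped=False, z=z, group_means=None, group_vars=None,
                                  raw_deviation=None, shrunken_deviation=None, tau2=None)
        return _finish("normfinder", values, detail, warnings)

    cols = {g: [j for j, lab in enumerate(group_of) if lab == g] for g in labels}
    for lab in labels:
        if len(cols[lab]) < 2:
            raise CtTableError(f"group {lab!r} has a single sample; variance undefined")
    n_g = {lab: len(cols[lab]) for lab in labels}
    n_tot = sum(n_g.values())
    G = len(labels)

    group_means: dict[str, dict[str, float]] = {}
    group_vars: dict[str, dict[str, float]] = {}
    raw_dev: dict[str, dict[str, float]] = {}
    shrunk_dev: dict[str, dict[str, float]] = {}
    tau2: dict[str, float] = {}
    values: dict[str, float] = {}

    for i, gene in enumerate(t.genes):
        m = {lab: float(np.mean(z[i, cols[lab]])) for lab in labels}
        s2 = {lab: float(np.var(z[i, cols[lab]], ddof=1)) for lab in labels}
        grand = sum(n_g[lab] * m[lab] for lab in labels) / n_tot
        d = {lab: m[lab] - grand for lab in labels}
        t2 = max(
            0.0,
            sum(d[lab] ** 2 for lab in labels) / (G - 1)
            - float(np.mean([s2[lab] / n_g[lab] for lab in labels])),
        )
        dt = {
            lab: (d[lab] * t2 / (t2 + s2[lab] / n_g[lab]) if t2 > 0 else 0.0)
            for lab in labels
        }
        values[gene] = float(np.mean([abs(dt[lab]) + math.sqrt(s2[lab] / n_g[lab]) for lab in labels]))
        group_means[gene], group_vars[gene] = m, s2
        raw_dev[gene], shrunk_dev[gene], tau2[gene] = d, dt, t2

    detail = NormFinderDetail(grouped=True, z=z, group_means=group_means,
                              group_vars=group_vars, raw_deviation=raw_dev,
                              shrunken_deviation=shrunk_dev, tau2=tau2)
    return _finish("normfinder", values, detail, warnings)


# ----------------------------------------------------------------------
# BestKeeper
# ----------------------------------------------------------------------

@dataclass
class BestKeeperDetail:
    descriptives: dict[str, dict[str, float]]   # gene -> mean/geo_mean/min/max/sd/cv
    index: dict[str, float]                     # sample -> geometric-mean Ct
    correlations: dict[str, tuple[float, float]]  # gene -> (pearson r, p)
    dispersion: str


def bestkeeper(t: CtTable, dispersion: str = "sample_sd") -> StabilityResult:
    """BestKeeper descriptives on raw Ct.

    The stability value is the chosen dispersion of a gene's raw Ct values —
    sample SD (n-1) by default, mean absolute deviation from the mean with
    ``dispersion='mean_abs_dev'``.  The per-sample index (geometric mean of
    Ct across genes) and each gene's Pearson correlation with it are
    reported in the details but never used for ranking.
    """
    if dispersion not in {"sample_sd", "mean_abs_dev"}:
        raise CtTableError(f"unknown dispersion estimator {dispersion!r}")
    if t.n_samples < 2:
        raise CtTableError("BestKeeper needs >=2 samples")
    warnings: list[str] = []

    desc: dict[str, dict[str, float]] = {}
    values: dict[str, float] = {}
    for i, g in enumerate(t.genes):
        row = t.ct[i]
        row = row[np.isfinite(row)]
        if row.size < 2:
            raise CtTableError(f"gene {g!r} has fewer than 2 Ct values")
        sd = float(np.std(row, ddof=1))
        mad = float(np.mean(np.abs(row - row.mean())))
        mean = float(row.mean())
        desc[g] = {
            "mean": mean,
            "geo_mean": float(sps.gmean(row)),
            "min": float(row.min()),
            "max": float(row.max()),
            "sd": sd,
            "mean_abs_dev": mad,
            "cv_percent": 100.0 * sd / mean,
            "n": int(row.size),
        }
        values[g] = sd if dispersion == "sample_sd" else mad

    if not np.isfinite(t.ct).all():
        warnings.append("missing cells: index computed over available genes per sample")
    with np.errstate(invalid="ignore"):
        log_ct = np.log(t.ct)
        index_arr = np.exp(np.nanmean(log_ct, axis=0))
    index = {s: float(v) for s, v in zip(t.samples, index_arr)}

    correlations: dict[str, tuple[float, float]] = {}
    for i, g in enumerate(t.genes):
        mask = np.isfinite(t.ct[i]) & np.isfinite(index_arr)
        x, yv = t.ct[i, mask], index_arr[mask]
        if x.size < 3 or np.isclose(np.std(x), 0) or np.isclose(np.std(yv), 0):
            correlations[g] = (math.nan, math.nan)
            warnings.append(f"correlation vs index undefined for gene {g!r}")
            continue
        r, p = sps.pearsonr(x, yv)
        correlations[g] = (float(r), float(p))

    detail = BestKeeperDetail(descriptives=desc, index=index,
                              correlations=correlations, dispersion=dispersion)
    return _finish("bestkeeper", values, detail, warnings)
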