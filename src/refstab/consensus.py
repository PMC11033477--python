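"""Rank-aggregation consensus across stability methods.

Each method contributes dense integer ranks; genes are ordered by the
geometric mean of their ranks (lower = more stable) and the two smallest
geometric means form the recommended reference pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import CtTableError
from .stability import StabilityResult

__all__ = ["ConsensusResult", "build_rank_table", "geomean_consensus"]


@dataclass
class ConsensusResult:
    rank_table: pd.DataFrame            # genes x methods, integer ranks
    geomean: dict[str, float]
    ordering: list[str]                 # ascending geometric mean
    recommended_pair: tuple[str, str]
    methods_used: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = self.rank_table.copy()
        df["geomean"] = [self.geomean[g] for g in df.index]
        df["overall_rank"] = [self.ordering.index(g) + 1 for g in df.index]
        return df.loc[self.ordering]


def build_rank_table(results: list[StabilityResult]) -> pd.DataFrame:
    """Assemble a gene x method table of dense ranks.

    All results must cover the identical gene set; a mismatch raises with
    the symmetric difference listed.
    """
    if len(results) < 2:
        raise CtTableError("consensus needs >=2 stability results")
    ref_genes = set(results[0].ranks)
    for r in results[1:]:
        if set(r.ranks) != ref_genes:
            diff = sorted(set(r.ranks) ^ ref_genes)
            raise CtTableError(
                f"gene sets differ between methods ({r.method}): symmetric difference {diff}"
            )
    genes = sorted(ref_genes)
    data = {r.method: [r.ranks[g] for g in genes] for r in results}
    if len(data) != len(results):
        raise CtTableError("duplicate method names in consensus input")
    return pd.DataFrame(data, index=genes)


def geomean_consensus(rank_table: pd.DataFrame) -> ConsensusResult:
    """Order genes by the geometric mean of their per-method ranks.

    Ties are broken by arithmetic mean rank, then gene id.  The recommended
    pair is the first two genes of the ordering.
    """
    if rank_table.empty:
        raise CtTableError("empty rank table")
    arr = rank_table.to_numpy(dtype=float)
    if np.any(arr < 1) or np.any(arr != np.round(arr)):
        raise CtTableError("ranks must be integers >= 1")

    geomean = {g: float(sps.gmean(arr[i])) for i, g in enumerate(rank_table.index)}
    mean_rank = {g: float(np.mean(arr[i])) for i, g in enumerate(rank_table.index)}
    ordering = sorted(rank_table.index, key=lambda g: (geomean[g], mean_rank[g], g))
    if len(ordering) < 2:
        raise CtTableError("consensus needs >=2 genes to recommend a pair")
    return ConsensusResult(
        rank_table=rank_table,
        geomean=geomean,
        ordering=ordering,
        recommended_pair=(ordering[0], ordering[1]),
        methods_used=list(rank_table.columns),
    )
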