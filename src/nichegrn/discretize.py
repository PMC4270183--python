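"""Quartile-expression discretization and differential calls.

The cross-platform comparison rests on relative abundance only: per region,
each gene's (median-summarized) expression is assigned a quartile 1-4 by
equal-frequency discretization (EFD), and a gene is differentially expressed
between two regions when its quartile changes by at least +/-2. Because the
assignment is rank-based, it is invariant to any monotone rescaling of one
platform's values, which is what makes microarray intensities and RNA-seq
FPKM comparable at all.

Ties receive equal quartiles; bin occupancies then deviate from n/k as
little as possible (globally minimal total deviation, computed by dynamic
programming over tie blocks). Among equally good assignments the
lexicographically smallest one in value order is returned, which keeps the
operation deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDistributionError, FormatError
from .io import ExpressionMatrix, ProbeMap, SampleSheet

logger = logging.getLogger("nichegrn.discretize")

_INF = 1 << 60


@dataclass
class GeneConditionSummary:
    """Median-summarized expression: one value per (gene, region)."""

    values: pd.DataFrame  # genes x regions

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def regions(self) -> list:
        return list(self.values.columns)

    def value(self, gene: str, region: str) -> float:
        return float(self.values.at[gene, region])

    def log2(self) -> "GeneConditionSummary":
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("log2 summarization requires strictly positive values")
        return GeneConditionSummary(np.log2(self.values))


@dataclass
class QuartileProfile:
    """Per-gene quartile expression (1..k) per region."""

    qe: pd.DataFrame  # genes x regions, ints
    k: int = 4

    def region(self, region: str) -> pd.Series:
        return self.qe[region]


@dataclass
class DifferentialTable:
    """Signed quartile differences QDE = QE(X) - QE(Y) with significance calls."""

    table: pd.DataFrame  # gene_id, qe_x, qe_y, qde, significant
    region_x: str
    region_y: str
    threshold: int = 2

    @property
    def n_up_in_x(self) -> int:
        return int((self.table["qde"] >= self.threshold).sum())

    @property
    def n_up_in_y(self) -> int:
        return int((self.table["qde"] <= -self.threshold).sum())

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_genes(self) -> list:
        return list(self.table.loc[self.table["significant"], "gene_id"])


@dataclass
class DistributionStats:
    """Per-region sample moments and quartile boundaries of pooled expression."""

    table: pd.DataFrame  # region, skewness, kurtosis, mean, median, q25, q50, q75
    excess_kurtosis: bool = False


def summarize_to_gene(
    matrix: ExpressionMatrix, probemap: ProbeMap, sheet: SampleSheet
) -> GeneConditionSummary:
    """Median over a gene's probes per sample, then median over replicates.

    Genes with no mapped probe in the matrix are absent from the result and
    logged. Regions are taken from the sample sheet restricted to this
    matrix's samples; a probe map may cover several platforms, only the
    features present here are used.
    """
    sheet.validate_against(matrix)
    df = matrix.to_frame()
    mapped = [f for f in matrix.feature_ids if f in probemap.mapping]
    if not mapped:
        raise FormatError("probe map covers no feature of this matrix")
    n_dropped = len(matrix.feature_ids) - len(mapped)
    if n_dropped:
        logger.info("dropping %d unmapped features", n_dropped)
    missing_genes = probemap.genes() - {probemap.mapping[f] for f in mapped}
    if missing_genes:
        logger.info("%d genes have no probe in this matrix", len(missing_genes))

    per_gene = df.loc[mapped].groupby(
        pd.Index([probemap.mapping[f] for f in mapped]), sort=True
    ).median()

    sub = sheet.table[sheet.table["sample_id"].isin(matrix.sample_ids)]
    regions = sorted(sub["region"].unique())
    if not regions:
        raise FormatError("no region of the sheet has samples in this matrix")
    out = {}
    for region in regions:
        samples = list(sub.loc[sub["region"] == region, "sample_id"])
        if not samples:
            raise FormatError(f"region {region!r} has zero samples")
        out[region] = per_gene[samples].median(axis=1)
    return GeneConditionSummary(pd.DataFrame(out))


def _efd_assign_blocks(counts: np.ndarray, k: int) -> np.ndarray:
    """Optimal monotone assignment of tie blocks to k bins.

    Minimizes sum over bins of |bin count - n/k| (computed in integer
    arithmetic scaled by k); among optima returns the lexicographically
    smallest assignment in value order. O(k * m) via a sliding-window
    minimum over the cost-to-go recursion.
    """
    m = len(counts)
    n = int(counts.sum())
    P = np.zeros(m + 1, dtype=np.int64)
    P[1:] = k * np.cumsum(counts)

    # G[j][h]: minimal cost of covering blocks h.. with bins j..k
    G = np.full((k + 2, m + 1), _INF, dtype=np.int64)
    G[k + 1, m] = 0
    for j in range(k, 0, -1):
        nxt = G[j + 1]
        B = np.where(nxt >= _INF, _INF, nxt + P)      # for P[i] >= T_h
        A = np.where(nxt >= _INF, _INF, nxt - P)      # for P[i] <  T_h
        suf_b = np.minimum.accumulate(B[::-1])[::-1]
        dq: list = []  # indices with increasing A (monotone deque)
        prev_s = 0
        for h in range(m + 1):
            t = P[h] + n
            s = int(np.searchsorted(P, t, side="left"))
            for i in range(max(prev_s, h), s):
                while dq and A[dq[-1]] >= A[i]:
                    dq.pop()
                dq.append(i)
            prev_s = max(prev_s, s)
            while dq and dq[0] < h:
                dq.pop(0)
            best = _INF
            if dq and A[dq[0]] < _INF:
                best = t + A[dq[0]]
            if s <= m and suf_b[s] < _INF:
                best = min(best, suf_b[s] - t)
            G[j, h] = best

    # forward reconstruction: longest feasible segment per bin, lowest bin first
    assign = np.empty(m, dtype=np.int64)
    h = 0
    for j in range(1, k + 1):
        target = G[j, h]
        chosen = h
        for i in range(h, m + 1):
            cost = abs(int(P[i]) - int(P[h]) - n)
            if G[j + 1, i] < _INF and cost + G[j + 1, i] == target:
                chosen = i
        assign[h:chosen] = j
        h = chosen
    assert h == m, "reconstruction must consume all blocks"
    return assign


def quartile_expression(values, k: int = 4) -> pd.Series:
    """Equal-frequency discretization of one region's summarized values.

    Returns an integer Series (1..k) indexed like the input. Requires at
    least k distinct values; ties always receive equal quartiles.
    """
    s = pd.Series(values, dtype=float)
    if s.isna().any():
        raise FormatError("NaN in values for quartile expression")
    if len(s) < k:
        raise DegenerateDistributionError(f"need at least {k} values, got {len(s)}")
    uniq, inverse, counts = np.unique(s.to_numpy(), return_inverse=True, return_counts=True)
    if len(uniq) < k:
        raise DegenerateDistributionError(
            f"degenerate distribution: only {len(uniq)} distinct values for k={k}"
        )
    block_qe = _efd_assign_blocks(counts, k)
    return pd.Series(block_qe[inverse], index=s.index, dtype=int)


def quartile_profile(summary: GeneConditionSummary, k: int = 4) -> QuartileProfile:
    """Apply EFD per region over all summarized genes of that region."""
    qe = pd.DataFrame(
        {region: quartile_expression(summary.values[region], k=k)
         for region in summary.regions}
    )
    return QuartileProfile(qe, k=k)


def differential_qe(qe_x, qe_y, region_x: str = "X", region_y: str = "Y",
                    threshold: int = 2) -> DifferentialTable:
    """QDE = QE(X) - QE(Y) on the shared gene universe; |QDE| >= threshold is called."""
    sx = pd.Series(qe_x, dtype=int)
    sy = pd.Series(qe_y, dtype=int)
    shared = sx.index.intersection(sy.index)
    if len(shared) == 0:
        raise FormatError("empty gene intersection between quartile profiles")
    dropped = len(sx.index.union(sy.index)) - len(shared)
    if dropped:
        logger.info("dropping %d genes absent from one profile", dropped)
    qde = sx.loc[shared] - sy.loc[shared]
    table = pd.DataFrame(
        {
            "gene_id": shared,
            "qe_x": sx.loc[shared].to_numpy(),
            "qe_y": sy.loc[shared].to_numpy(),
            "qde": qde.to_numpy(),
            "significant": (qde.abs() >= threshold).to_numpy(),
        }
    ).reset_index(drop=True)
    return DifferentialTable(table, region_x, region_y, threshold)


def distribution_stats(matrix: ExpressionMatrix, sheet: SampleSheet,
                       excess: bool = False) -> DistributionStats:
    """Sample skewness/kurtosis and quartile boundaries of each region's pooled values.

    Kurtosis is raw (non-excess) by default. Used to check that two platforms
    have comparable distribution shapes before rank-based discretization.
    """
    sheet.validate_against(matrix)
    df = matrix.to_frame()
    sub = sheet.table[sheet.table["sample_id"].isin(matrix.sample_ids)]
    rows = []
    for region in sorted(sub["region"].unique()):
        samples = list(sub.loc[sub["region"] == region, "sample_id"])
        pooled = df[samples].to_numpy().ravel()
        if len(pooled) < 4:
            raise DegenerateDistributionError(f"region {region!r}: fewer than 4 values")
        if np.ptp(pooled) == 0:
            raise DegenerateDistributionError(
                f"region {region!r}: constant values, moments undefined"
            )
        q25, q50, q75 = np.percentile(pooled, [25, 50, 75])
        rows.append(
            {
                "region": region,
                "n_values": len(pooled),
                "skewness": sps.skew(pooled),
                "kurtosis": sps.kurtosis(pooled, fisher=excess),
                "mean": pooled.mean(),
                "median": q50,
                "q25": q25,
                "q75": q75,
            }
        )
    return DistributionStats(pd.DataFrame(rows), excess_kurtosis=excess)
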