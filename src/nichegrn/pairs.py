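"""Rival cell-fate determinant TF pair discovery.

A stem/progenitor state is modelled as a balance between two rival
lineage-specifier TFs; differentiation breaks the balance. For a pair of
genes the disbalance statistic is

    D = (gene1_diff - gene2_diff) - (gene1_stem - gene2_stem)

with every term a log2 median expression value, so D is the log2 change of
the pair's expression ratio upon differentiation. D is computed for all TF
pairs; significance comes from a robust z-test (location/scale estimated on
the central mass after trimming 2.5% of values on each side, the same
linear transform then extrapolated to all values), Benjamini-Hochberg
adjusted. Four criteria coupled to the network's SCC then narrow the
significant pairs to cell-fate determinant candidates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDistributionError, FormatError
from .discretize import GeneConditionSummary
from .io import BaselineReference, PriorNetwork


@dataclass(frozen=True)
class PairStatistic:
    """Disbalance of one TF pair between stem and differentiated states."""

    gene1: str
    gene2: str
    g1_stem: float
    g1_diff: float
    g2_stem: float
    g2_diff: float

    @property
    def d(self) -> float:
        return (self.g1_diff - self.g2_diff) - (self.g1_stem - self.g2_stem)


def pair_statistic(summary: GeneConditionSummary, gene1: str, gene2: str,
                   stem_region: str, diff_region: str) -> PairStatistic:
    """D for one pair, from log2-scale summarized expression."""
    vals = {}
    for gene in (gene1, gene2):
        for region in (stem_region, diff_region):
            if gene not in summary.values.index:
                raise FormatError(f"gene {gene!r} missing from summary")
            if region not in summary.values.columns:
                raise FormatError(f"region {region!r} missing from summary")
            v = summary.value(gene, region)
            if not math.isfinite(v):
                raise FormatError(f"non-finite value for gene {gene!r}, region {region!r}")
            vals[(gene, region)] = v
    return PairStatistic(
        gene1, gene2,
        g1_stem=vals[(gene1, stem_region)], g1_diff=vals[(gene1, diff_region)],
        g2_stem=vals[(gene2, stem_region)], g2_diff=vals[(gene2, diff_region)],
    )


def all_pair_statistics(summary: GeneConditionSummary, tf_list,
                        stem_region: str, diff_region: str) -> pd.DataFrame:
    """One row per unordered TF pair, canonical orientation gene1 < gene2."""
    tfs = list(tf_list)
    if len(set(tfs)) != len(tfs):
        dup = sorted({t for t in tfs if tfs.count(t) > 1})
        raise FormatError(f"duplicate ids in TF list: {dup}")
    if len(tfs) < 2:
        raise FormatError("need at least two TFs")
    missing = [t for t in tfs if t not in summary.values.index]
    if missing:
        raise FormatError(f"TFs missing from summary: {sorted(missing)[:10]}")
    stem = summary.values[stem_region]
    diff = summary.values[diff_region]
    rows = []
    for g1, g2 in itertools.combinations(sorted(tfs), 2):
        rows.append(
            (g1, g2, stem[g1], diff[g1], stem[g2], diff[g2],
             (diff[g1] - diff[g2]) - (stem[g1] - stem[g2]))
        )
    return pd.DataFrame(
        rows, columns=["gene1", "gene2", "g1_stem", "g1_diff",
                       "g2_stem", "g2_diff", "d"]
    )


def _trim_consistency_factor(alpha: float) -> float:
    """SD of a standard normal truncated to its central (1-2*alpha) mass.

    Dividing a trimmed SD by this factor makes it a consistent scale
    estimate under normality, so the z-test is calibrated on null data.
    """
    if alpha <= 0:
        return 1.0
    a = norm.ppf(1.0 - alpha)
    var = 1.0 - 2.0 * a * norm.pdf(a) / (1.0 - 2.0 * alpha)
    return math.sqrt(var)


def robust_z_test(values, trim_fraction: float = 0.025,
                  normal_consistency: bool = True):
    """Robust z-scores and two-sided normal p-values for every value.

    Location and scale are the mean and SD of the values remaining after
    trimming ``trim_fraction`` of the sorted values on each side; the same
    linear transform is then applied to all values, including the trimmed
    ones. With ``normal_consistency`` the trimmed SD is rescaled to be
    unbiased for the full SD under normality.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 20:
        raise FormatError(f"need at least 20 values, got {len(x)}")
    if not 0 <= trim_fraction < 0.25:
        raise ValueError("trim_fraction must be in [0, 0.25)")
    k = int(math.floor(trim_fraction * len(x)))
    core = np.sort(x)[k: len(x) - k] if k else np.sort(x)
    loc = core.mean()
    scale = core.std(ddof=1)
    if scale == 0:
        raise DegenerateDistributionError("constant central mass; zero scale")
    if normal_consistency:
        scale /= _trim_consistency_factor(k / len(x))
    z = (x - loc) / scale
    p = 2.0 * norm.sf(np.abs(z))
    return z, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise FormatError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def evaluate_pairs(summary: GeneConditionSummary, tf_list, stem_region: str,
               diff_region: str, trim_fraction: float = 0.025,
               alpha: float = 0.05, stem_ratio_normalize: bool = False,
               eps: float = 1e-6) -> pd.DataFrame:
    """All-pairs D with robust z, p, BH-adjusted p, and significance flag.

    ``stem_ratio_normalize`` enables the alternative normalization reading
    (divide D by |gene1_stem - gene2_stem|, guarded against near-zero
    denominators); by default the stem ratio enters only subtractively,
    exactly as in the pair formula.
    """
    table = all_pair_statistics(summary, tf_list, stem_region, diff_region)
    d = table["d"].to_numpy()
    if stem_ratio_normalize:
        denom = np.maximum(np.abs(table["g1_stem"] - table["g2_stem"]), eps)
        d = d / denom
        table["d_normalized"] = d
    z, p = robust_z_test(d, trim_fraction=trim_fraction)
    table["z"] = z
    table["p"] = p
    table["p_adj"] = bh_adjust(p)
    table["significant"] = table["p_adj"] < alpha
    return table


def filter_candidates(results: pd.DataFrame, qe_stem, qe_diff,
                      baseline: BaselineReference, scc, prior: PriorNetwork,
                      alpha: float = 0.05, qde_threshold: int = 2,
                      baseline_relative: bool = True) -> pd.DataFrame:
    """Apply the four SCC-coupled criteria to significant pairs.

    c1: at least one gene differentially up in the differentiated state
        (QE(diff) - QE(baseline) >= +threshold);
    c2: neither gene differentially down in the stem state
        (QE(stem) - QE(baseline) <= -threshold excluded);
    c3: both genes inside the designated SCC and directly linked;
    c4: exactly one gene inside the SCC, the pair directly linked in the
        prior network.
    A pair is kept iff adjusted p < alpha and c1 and c2 and (c3 or c4).
    With ``baseline_relative=False`` c1/c2 use stem-vs-differentiated QDE
    calls instead of the baseline reference. The reported orientation puts
    the differentiated-up gene first.
    """
    if baseline_relative and baseline.quartiles is None:
        raise FormatError("baseline reference has no quartile assignment")
    scc = frozenset(scc)
    qe_stem = pd.Series(qe_stem, dtype=int)
    qe_diff = pd.Series(qe_diff, dtype=int)

    def up_in_diff(g: str) -> bool:
        ref = baseline.quartiles[g] if baseline_relative else qe_stem[g]
        return bool(qe_diff[g] - ref >= qde_threshold)

    def down_in_stem(g: str) -> bool:
        ref = baseline.quartiles[g] if baseline_relative else qe_diff[g]
        return bool(qe_stem[g] - ref <= -qde_threshold)

    out = []
    for row in results.itertuples(index=False):
        if row.p_adj >= alpha:
            continue
        g1, g2 = row.gene1, row.gene2
        for g in (g1, g2):
            if g not in qe_stem.index or g not in qe_diff.index:
                raise FormatError(f"gene {g!r} missing from quartile profiles")
            if baseline_relative and g not in baseline.quartiles:
                raise FormatError(f"gene {g!r} missing from baseline reference")
        c1 = up_in_diff(g1) or up_in_diff(g2)
        c2 = not (down_in_stem(g1) or down_in_stem(g2))
        linked = prior.adjacent(g1, g2)
        in1, in2 = g1 in scc, g2 in scc
        c3 = in1 and in2 and linked
        c4 = (in1 != in2) and linked
        passes = c1 and c2 and (c3 or c4)
        if not passes:
            continue
        d, z = row.d, row.z
        if up_in_diff(g2) and not up_in_diff(g1):
            g1, g2 = g2, g1
            d, z = -d, -z
        out.append(
            {"gene1": g1, "gene2": g2, "d": d, "z": z, "p": row.p,
             "p_adj": row.p_adj, "c1_up_in_differentiated": c1,
             "c2_not_down_in_stem": c2, "c3_both_in_scc_connected": c3,
             "c4_one_in_scc_partner_interacts": c4, "passes": passes}
        )
    return pd.DataFrame(
        out, columns=["gene1", "gene2", "d", "z", "p", "p_adj",
                      "c1_up_in_differentiated", "c2_not_down_in_stem",
                      "c3_both_in_scc_connected",
                      "c4_one_in_scc_partner_interacts", "passes"]
    )
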