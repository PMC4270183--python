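"""Seeded synthetic data with known ground truth.

The generator emulates the structure of the study design this package
analyzes: two neurogenic sites profiled on different platforms — site A
(stem region ``stemA`` vs differentiated ``diffA``) with microarray-like
intensities, multiple probes per gene and saturated high-intensity probes,
and site B (``stemB``/``diffB``) with FPKM-like values on a very different
absolute scale but a similar rank distribution — plus a basal-expression
reference panel and a signed prior interaction network.

Planted, self-verifying ground truth drives every downstream test:

* differential genes with a known quartile shift between the two sites,
* a strongly connected core network admitting the two observed Boolean
  phenotype states as fixed points, contaminated with spurious edges that
  each break at least one state, and with a fraction of signs published as
  "unassigned",
* rival TF pairs balanced in the stem state and split by a known log2
  magnitude upon differentiation, wired to the core SCC so they satisfy
  the candidate filter criteria.

Intensity model: gene base values are a stratified sample (quantile grid)
of an upper-truncated lognormal; stratification keeps the pooled sample
skewness/kurtosis stable across seeds. Site A probes above the saturation
quantile are noise-free single-probe features (scanner saturation); site B
values are capped at a dynamic-range ceiling. Replicate noise is
multiplicative lognormal on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import boolean, discretize
from .errors import FormatError, NicheGRNError
from .io import (ACTIVATION, BINDING, INHIBITION, TRANSCRIPTION, UNASSIGNED,
                 BaselineReference, Edge, ExpressionMatrix, PriorNetwork,
                 ProbeMap, SampleSheet)

logger = logging.getLogger("nichegrn.synthetic")


@dataclass
class SynthConfig:
    """Generator settings; every default is a declared study condition."""

    seed: int
    n_genes: int = 6000
    replicates: dict = field(default_factory=lambda: {
        "stemA": 4, "diffA": 4, "stemB": 3, "diffB": 3})
    # site A: microarray-intensity-like
    a_sigma: float = 1.63            # lognormal shape, ln units
    a_umax: float = 0.9986           # upper quantile truncation
    a_saturation_quantile: float = 0.99
    a_scale: float = 120.0
    probe_weights: dict = field(default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    probe_jitter_sd: float = 0.1     # per-probe affinity, log2 units
    # site B: RNA-seq FPKM-like
    b_sigma: float = 1.55
    b_cap_quantile: float = 0.978    # dynamic-range ceiling
    b_scale: float = 8.0
    # shared replicate noise, log2 units
    noise_sd: float = 0.25
    # planted cross-site differential genes
    de_fraction: float = 0.10
    de_shift: int = 2
    # planted prior network
    n_network_genes: int = 30
    spurious_fraction: float = 0.2   # fraction of the prior's edges
    unassigned_fraction: float = 0.2
    binding_fraction: float = 0.2
    # planted rival TF pairs
    n_tfs: int = 100
    n_planted_pairs: int = 2
    pair_magnitude: float = 2.0      # log2 units of D
    # moment calibration bands (site A: printed; site B: relaxed around printed)
    a_skew_band: tuple = (6.4, 7.18)
    a_kurt_band: tuple = (64.1, 76.9)
    b_skew_band: tuple = (2.38, 3.38)
    b_kurt_band: tuple = (8.7, 12.7)
    strict_b_bands: bool = False
    check_moments: bool = True

    def __post_init__(self):
        for name in ("de_fraction", "spurious_fraction", "unassigned_fraction",
                     "binding_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_network_genes < 4:
            raise ValueError("need at least 4 network genes (two groups of >= 2)")
        if self.strict_b_bands:
            self.b_skew_band = (2.87, 2.89)
            self.b_kurt_band = (10.6, 10.8)

    def effective_b_bands(self):
        return self.b_skew_band, self.b_kurt_band


@dataclass
class GroundTruth:
    """Planted facts, all re-verifiable through the analysis modules."""

    gene_ids: list = field(default_factory=list)
    de_genes: dict = field(default_factory=dict)       # gene -> QDE(stemA - stemB)
    network_genes: list = field(default_factory=list)
    core_edges: tuple = ()                              # true-signed core
    spurious_edges: tuple = ()
    unassigned_true_signs: dict = field(default_factory=dict)  # edge key -> sign
    states: dict = field(default_factory=dict)          # label -> BooleanState
    scc_nodes: frozenset = frozenset()
    tf_list: list = field(default_factory=list)
    planted_pairs: list = field(default_factory=list)   # (up_gene, partner, magnitude)


@dataclass
class SyntheticDataset:
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    sheet: SampleSheet
    probemap: ProbeMap
    baseline: BaselineReference
    prior: PriorNetwork
    truth: GroundTruth
    config: SynthConfig


# ---------------------------------------------------------------------------
# network plan


@dataclass
class _NetworkPlan:
    genes: list
    group_p: list
    group_q: list
    core_edges: list
    spurious_edges: list
    unassigned_keys: set
    state_stem: dict
    state_diff: dict


def _plan_network(config: SynthConfig, gene_ids) -> _NetworkPlan:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    m = config.n_network_genes
    genes = gene_ids[:m]
    half = m // 2
    group_p, group_q = genes[:half], genes[half:]

    def itype():
        return BINDING if rng.random() < config.binding_fraction else TRANSCRIPTION

    core = []
    for group in (group_p, group_q):
        for i, g in enumerate(group):
            core.append(Edge(g, group[(i + 1) % len(group)], itype(), ACTIVATION))
    core.append(Edge(group_p[0], group_q[0], itype(), INHIBITION))
    core.append(Edge(group_q[0], group_p[0], itype(), INHIBITION))

    pred = {}  # cycle predecessor (the target's single activator)
    for e in core:
        if e.sign == ACTIVATION:
            pred[e.target] = e.source

    n_core = len(core)
    f = config.spurious_fraction
    n_spur = int(round(f / (1.0 - f) * n_core)) if f < 1.0 else n_core
    taken = {(e.source, e.target) for e in core}
    spurious = []
    guard = 0
    while len(spurious) < n_spur:
        guard += 1
        if guard > 10000:
            raise NicheGRNError("could not place the requested spurious edges")
        if rng.random() < 0.5:  # same-group inhibitor: tie -> OFF in the ON state
            group = group_p if rng.random() < 0.5 else group_q
            t = group[rng.integers(len(group))]
            s = group[rng.integers(len(group))]
            if s == t or s == pred[t] or (s, t) in taken:
                continue
            e = Edge(s, t, itype(), INHIBITION)
        else:  # cross-group activator: forces an OFF hold-state gene ON
            sgroup, tgroup = (group_p, group_q) if rng.random() < 0.5 else (group_q, group_p)
            s = sgroup[rng.integers(len(sgroup))]
            t = tgroup[rng.integers(1, len(tgroup))]  # skip tgroup[0] (has an inhibitor)
            if (s, t) in taken:
                continue
            e = Edge(s, t, itype(), ACTIVATION)
        taken.add((e.source, e.target))
        spurious.append(e)

    n_un = int(round(config.unassigned_fraction * n_core))
    unassigned_keys = {core[i].key for i in rng.choice(n_core, size=n_un, replace=False)}

    state_stem = {g: 1 for g in group_p} | {g: 0 for g in group_q}
    state_diff = {g: 0 for g in group_p} | {g: 1 for g in group_q}
    plan = _NetworkPlan(genes, group_p, group_q, core, spurious,
                        unassigned_keys, state_stem, state_diff)
    _verify_plan(plan)
    return plan


def _verify_plan(plan: _NetworkPlan) -> None:
    """Ground truth is self-verifying: states are fixed points of the core,
    and each spurious edge alone breaks at least one state."""
    core_net = PriorNetwork(tuple(plan.core_edges))
    states = [boolean.BooleanState(plan.state_stem, "stem"),
              boolean.BooleanState(plan.state_diff, "diff")]
    for st in states:
        ok, violators = boolean.is_fixed_point(st, core_net)
        if not ok:
            raise NicheGRNError(f"planted state {st.label} is not a fixed point: {violators}")
    for e in plan.spurious_edges:
        net = PriorNetwork(tuple(plan.core_edges) + (e,))
        rep = boolean.consistency_score(net, states)
        if rep.overall >= 1.0:
            raise NicheGRNError(f"spurious edge {e.key} does not violate any state")


def generate_prior_network(config: SynthConfig):
    """The 30-gene default prior: consistent core + spurious + unassigned signs."""
    gene_ids = _gene_ids(config)
    plan = _plan_network(config, gene_ids)
    prior_edges = [
        replace(e, sign=UNASSIGNED) if e.key in plan.unassigned_keys else e
        for e in plan.core_edges
    ] + list(plan.spurious_edges)
    prior = PriorNetwork(tuple(prior_edges))
    truth = GroundTruth(
        gene_ids=gene_ids,
        network_genes=plan.genes,
        core_edges=tuple(plan.core_edges),
        spurious_edges=tuple(plan.spurious_edges),
        unassigned_true_signs={e.key: e.sign for e in plan.core_edges
                               if e.key in plan.unassigned_keys},
        states={
            "stem": boolean.BooleanState(plan.state_stem, "stem"),
            "diff": boolean.BooleanState(plan.state_diff, "diff"),
        },
        scc_nodes=frozenset(plan.genes),
    )
    return prior, truth


# ---------------------------------------------------------------------------
# expression


def _gene_ids(config: SynthConfig):
    return [f"G{i:05d}" for i in range(1, config.n_genes + 1)]


def _quantile_value(u, sigma, scale):
    return scale * np.exp(sigma * norm.ppf(u))


def _central_u(frac: float, quartile: int) -> float:
    """A position inside the central 60% of the given quartile.

    ``frac`` in [0, 1) picks the spot deterministically; planted genes use
    an evenly spaced grid so the pooled value composition (and with it the
    sample moments) does not drift from seed to seed.
    """
    lo = (quartile - 1) * 0.25
    return lo + 0.25 * (0.2 + 0.6 * frac)


def generate_expression(config: SynthConfig) -> SyntheticDataset:
    """Expression matrices for both sites + sheet, probe map, baseline, prior.

    Planted differential genes and network-gene phenotype states are wired
    in; rival pairs are added by :func:`plant_disbalanced_pairs` (see
    :func:`generate_dataset` for the composed default).
    """
    n = config.n_genes
    gene_ids = _gene_ids(config)
    plan = _plan_network(config, gene_ids)

    ss = np.random.SeedSequence([config.seed, 1])
    r_assign, r_a, r_b, r_base = [np.random.default_rng(s) for s in ss.spawn(4)]

    # stratified base quantile positions, shared across regions and sites
    u_base = (np.arange(n) + 0.5) / n * config.a_umax
    u_base = u_base[r_assign.permutation(n)]

    gi = {g: i for i, g in enumerate(gene_ids)}
    n_reserved = config.n_network_genes + 2 * max(config.n_planted_pairs, 0)
    tf_flat_end = n_reserved + config.n_tfs  # flat TFs fill up the TF quota

    # genes whose positions get overridden (network, pair, DE) must not hold
    # upper-tail slots: vacating a tail slot would change the pooled tail
    # composition from seed to seed and with it the sample moments
    protected = u_base >= 0.95
    bad = np.where(protected[:n_reserved])[0]
    free_pool = np.where(~protected & (np.arange(n) >= tf_flat_end))[0]
    swap_with = r_assign.choice(free_pool, size=len(bad), replace=False)
    u_base[bad], u_base[swap_with] = u_base[swap_with].copy(), u_base[bad].copy()
    protected = u_base >= 0.95
    u = {region: u_base.copy() for region in config.replicates}

    # planted cross-site differential genes (flat within each site)
    n_de = int(round(config.de_fraction * n))
    eligible = np.where(~protected & (np.arange(n) >= tf_flat_end))[0]
    if n_de > len(eligible):
        raise NicheGRNError("de_fraction too large for the reserved gene layout")
    de_idx = r_assign.choice(eligible, size=n_de, replace=False)
    de_genes = {}
    hi_choices = list(range(1 + config.de_shift, 5))
    for j, idx in enumerate(de_idx):
        up_in_a = j % 2 == 0
        q_hi = hi_choices[j % len(hi_choices)]  # shift fits below
        q_lo = q_hi - config.de_shift
        frac = ((j * 0.381966) % 1.0)  # low-discrepancy spacing in the band
        u_hi = _central_u(frac, q_hi)
        u_lo = _central_u(frac, q_lo)
        g = gene_ids[idx]
        if up_in_a:
            u["stemA"][idx] = u["diffA"][idx] = u_hi
            u["stemB"][idx] = u["diffB"][idx] = u_lo
            de_genes[g] = config.de_shift
        else:
            u["stemA"][idx] = u["diffA"][idx] = u_lo
            u["stemB"][idx] = u["diffB"][idx] = u_hi
            de_genes[g] = -config.de_shift

    # network genes follow their planted Boolean states in every region
    for g in plan.genes:
        idx = gi[g]
        for region in config.replicates:
            state = plan.state_stem if region.startswith("stem") else plan.state_diff
            if state[g] == 1:
                u[region][idx] = 0.55 + 0.40 * r_assign.random()
            else:
                u[region][idx] = 0.05 + 0.40 * r_assign.random()

    # --- site A: probes, affinities, saturation
    planted_idx = set(gi[g] for g in plan.genes) | set(int(i) for i in de_idx)
    sat = (u_base >= config.a_saturation_quantile)
    sat[list(planted_idx)] = False
    # probe multiplicity follows the configured weights but is assigned
    # cyclically along the intensity rank, so the pooled tail composition
    # (which dominates skewness/kurtosis) is identical across seeds
    counts = np.array(list(config.probe_weights.keys()))
    weights = np.array(list(config.probe_weights.values()), dtype=float)
    weights = weights / weights.sum()
    cycle = np.concatenate([
        np.full(max(int(round(w * 10)), 0), c) for c, w in zip(counts, weights)
    ])
    rank = np.argsort(np.argsort(u_base))
    probe_n = cycle[rank % len(cycle)]
    probe_n[sat] = 1

    probe_gene = np.repeat(np.arange(n), probe_n)
    feature_ids_a = [f"{gene_ids[g]}_p{j + 1}"
                     for g, c in zip(range(n), probe_n) for j in range(c)]
    # measurement CV shrinks with intensity (and vanishes at saturation)
    noise_scale = np.ones(n)
    noise_scale[u_base >= 0.9] = 0.4
    noise_scale[sat] = 0.0
    affinity = 2.0 ** (r_a.normal(0.0, config.probe_jitter_sd, size=len(probe_gene))
                       * noise_scale[probe_gene])

    regions_a = [r for r in config.replicates if r.endswith("A")]
    cols_a, mats_a = [], []
    for region in regions_a:
        vals = _quantile_value(u[region], config.a_sigma, config.a_scale)
        base = vals[probe_gene] * affinity
        nrep = config.replicates[region]
        noise = r_a.normal(0.0, config.noise_sd, size=(len(base), nrep)) \
            * noise_scale[probe_gene, None]
        mats_a.append(base[:, None] * 2.0 ** noise)
        cols_a += [f"{region}_r{i + 1}" for i in range(nrep)]
    expr_a = ExpressionMatrix(feature_ids_a, cols_a, np.hstack(mats_a),
                              platform_tag="microarray")

    # --- site B: gene-level, dynamic-range cap
    cap = _quantile_value(config.b_cap_quantile, config.b_sigma, config.b_scale)
    regions_b = [r for r in config.replicates if r.endswith("B")]
    cols_b, mats_b = [], []
    for region in regions_b:
        vals = _quantile_value(u[region], config.b_sigma, config.b_scale)
        nrep = config.replicates[region]
        noise = r_b.normal(0.0, config.noise_sd, size=(n, nrep))
        mats_b.append(np.minimum(vals[:, None] * 2.0 ** noise, cap))
        cols_b += [f"{region}_r{i + 1}" for i in range(nrep)]
    expr_b = ExpressionMatrix(gene_ids, cols_b, np.hstack(mats_b),
                              platform_tag="rnaseq-fpkm")

    sheet = SampleSheet(pd.DataFrame(
        [{"sample_id": f"{region}_r{i + 1}", "region": region, "replicate": i + 1}
         for region in config.replicates for i in range(config.replicates[region])]
    ))
    probemap = ProbeMap({**dict(zip(feature_ids_a, (gene_ids[g] for g in probe_gene))),
                         **{g: g for g in gene_ids}})

    base_vals = _quantile_value(u_base, config.a_sigma, config.a_scale) \
        * 2.0 ** r_base.normal(0.0, 0.1, size=n)
    baseline_series = pd.Series(base_vals, index=gene_ids)
    baseline = BaselineReference(
        baseline_series.to_dict(),
        discretize.quartile_expression(baseline_series).to_dict(),
    )

    prior_edges = [
        replace(e, sign=UNASSIGNED) if e.key in plan.unassigned_keys else e
        for e in plan.core_edges
    ] + list(plan.spurious_edges)
    prior = PriorNetwork(tuple(prior_edges))

    truth = GroundTruth(
        gene_ids=gene_ids,
        de_genes=de_genes,
        network_genes=plan.genes,
        core_edges=tuple(plan.core_edges),
        spurious_edges=tuple(plan.spurious_edges),
        unassigned_true_signs={e.key: e.sign for e in plan.core_edges
                               if e.key in plan.unassigned_keys},
        states={
            "stem": boolean.BooleanState(plan.state_stem, "stem"),
            "diff": boolean.BooleanState(plan.state_diff, "diff"),
        },
        scc_nodes=frozenset(plan.genes),
        tf_list=[],
    )
    ds = SyntheticDataset(expr_a, expr_b, sheet, probemap, baseline, prior,
                          truth, config)
    _check_moments(ds)
    return ds


def _check_moments(ds: SyntheticDataset) -> None:
    config = ds.config
    if not config.check_moments or config.n_genes < 5000:
        return
    stats = discretize.distribution_stats(ds.expr_a, ds.sheet)
    stem_a = stats.table.set_index("region").loc["stemA"]
    lo, hi = config.a_skew_band
    klo, khi = config.a_kurt_band
    if not (lo <= stem_a["skewness"] <= hi and klo <= stem_a["kurtosis"] <= khi):
        raise NicheGRNError(
            f"site A moments outside the configured bands "
            f"(skew {stem_a['skewness']:.2f}, kurt {stem_a['kurtosis']:.1f}); "
            f"adjust a_sigma / a_umax / a_saturation_quantile"
        )
    stats_b = discretize.distribution_stats(ds.expr_b, ds.sheet)
    stem_b = stats_b.table.set_index("region").loc["stemB"]
    (blo, bhi), (bklo, bkhi) = config.effective_b_bands()
    if not (blo <= stem_b["skewness"] <= bhi and bklo <= stem_b["kurtosis"] <= bkhi):
        raise NicheGRNError(
            f"site B moments outside the configured bands "
            f"(skew {stem_b['skewness']:.2f}, kurt {stem_b['kurtosis']:.1f}); "
            f"adjust b_sigma / b_cap_quantile"
        )


def plant_disbalanced_pairs(ds: SyntheticDataset,
                            config: SynthConfig | None = None) -> SyntheticDataset:
    """Plant rival TF pairs: balanced in stem, split by ``pair_magnitude`` in diff.

    One gene of each pair belongs to the planted SCC (it is a core-network
    gene of the ON-in-diff group); the partner is a new out-of-SCC node
    linked by a direct (inhibiting) prior edge, so the pair satisfies the
    candidate criteria by construction. Also fills in the TF universe.
    """
    config = config or ds.config
    n_pairs = config.n_planted_pairs
    gene_ids = ds.truth.gene_ids
    gi = {g: i for i, g in enumerate(gene_ids)}
    m = config.n_network_genes
    group_q = ds.truth.network_genes[m // 2:]
    if n_pairs > min(len(group_q) - 1, config.n_tfs // 2):
        raise NicheGRNError("requested more planted pairs than available TFs")

    # in-SCC up-genes: ON-in-diff core genes, skipping the inhibited anchor
    up_genes = [group_q[1 + 2 * i] for i in range(n_pairs)]
    partners = [gene_ids[m + i] for i in range(n_pairs)]
    flat_tfs = [g for g in gene_ids[m + n_pairs: m + n_pairs + config.n_tfs]
                if g not in partners][: config.n_tfs - 2 * n_pairs]
    tf_list = sorted(up_genes + partners + flat_tfs)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    expr_a = ds.expr_a.to_frame()
    expr_b = ds.expr_b.to_frame()
    regions = {r: [c for c in expr_a.columns if c.startswith(r)]
               for r in ("stemA", "diffA")}
    regions_b = {r: [c for c in expr_b.columns if c.startswith(r)]
                 for r in ("stemB", "diffB")}

    features_of = {}
    for f, g in ds.probemap.mapping.items():
        if f != g:
            features_of.setdefault(g, []).append(f)

    baseline_values = dict(ds.baseline.values)
    planted = []
    states = {k: dict(v.values) for k, v in ds.truth.states.items()}
    new_edges = []
    for i, (up, partner) in enumerate(zip(up_genes, partners)):
        u_stem = 0.33 + 0.04 * i           # central Q2, distinct per pair
        v_stem = float(_quantile_value(u_stem, config.a_sigma, config.a_scale))
        v_diff = v_stem * 2.0 ** config.pair_magnitude

        def fill(df, gene, value_by_region, region_cols, jitter=True):
            for f in features_of.get(gene, [gene]) if df is expr_a else [gene]:
                aff = 2.0 ** rng.normal(0.0, config.probe_jitter_sd) if jitter else 1.0
                for region, cols in region_cols.items():
                    v = value_by_region[region]
                    noise = 2.0 ** rng.normal(0.0, config.noise_sd, size=len(cols))
                    df.loc[f, cols] = v * aff * noise

        fill(expr_a, up, {"stemA": v_stem, "diffA": v_diff}, regions)
        fill(expr_a, partner, {"stemA": v_stem, "diffA": v_stem}, regions)
        # site B: partner stays low/flat so the partner edge is consistent
        vb = float(_quantile_value(0.36 + 0.04 * i, config.b_sigma, config.b_scale))
        fill(expr_b, partner, {"stemB": vb, "diffB": vb}, regions_b, jitter=False)

        baseline_values[up] = float(_quantile_value(0.08 + 0.03 * i,
                                                    config.a_sigma, config.a_scale))
        baseline_values[partner] = float(_quantile_value(0.36 + 0.04 * i,
                                                         config.a_sigma, config.a_scale))
        new_edges.append(Edge(up, partner, TRANSCRIPTION, INHIBITION))
        planted.append((up, partner, config.pair_magnitude))
        for label in states:
            states[label][partner] = 0

    baseline_series = pd.Series(baseline_values).loc[gene_ids]
    baseline = BaselineReference(
        baseline_series.to_dict(),
        discretize.quartile_expression(baseline_series).to_dict(),
    )
    prior = PriorNetwork(tuple(ds.prior.edges) + tuple(new_edges))
    truth = replace(
        ds.truth,
        tf_list=tf_list,
        planted_pairs=planted,
        states={k: boolean.BooleanState(v, k) for k, v in states.items()},
    )
    return SyntheticDataset(
        ExpressionMatrix.from_frame(expr_a, ds.expr_a.platform_tag),
        ExpressionMatrix.from_frame(expr_b, ds.expr_b.platform_tag),
        ds.sheet, ds.probemap, baseline, prior, truth, config,
    )


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Expression + network + pairs: the composed default synthetic study."""
    return plant_disbalanced_pairs(generate_expression(config), config)
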