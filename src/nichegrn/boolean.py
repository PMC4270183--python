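"""Boolean network semantics and prior-network contextualization.

Each cellular phenotype is treated as a stable steady state (attractor) of
the gene regulatory network under a synchronous threshold rule: for every
gene, the number of activating and inhibiting edges whose source is ON are
compared and the larger count dominates; on a tie inhibition dominates
(the gene switches OFF); a gene with no ON regulator holds its current value
(configurable to decay instead). Contextualization prunes and sign-assigns
a prior knowledge network so the observed Booleanized expression states
become fixed points, using a genetic algorithm over one keep/remove bit per
edge plus one sign bit per originally unassigned edge. Fitness is the mean
per-state consistency minus a parsimony penalty on the fraction of removed
edges, so the algorithm keeps as much prior knowledge as the data allows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ContextualizationError, FormatError
from .io import ACTIVATION, INHIBITION, TRANSCRIPTION, UNASSIGNED, PriorNetwork

logger = logging.getLogger("nichegrn.boolean")

HOLD = "hold"
DECAY = "decay"


@dataclass(frozen=True)
class BooleanState:
    """Gene -> {0,1} phenotype vector used as an attractor target."""

    values: dict
    label: str = ""

    def __post_init__(self):
        bad = {g: v for g, v in self.values.items() if v not in (0, 1)}
        if bad:
            raise FormatError(f"non-Boolean state values: {bad}")

    def vector(self, nodes) -> np.ndarray:
        missing = [n for n in nodes if n not in self.values]
        if missing:
            raise FormatError(
                f"state {self.label!r} missing genes: {sorted(missing)[:10]}"
            )
        return np.array([self.values[n] for n in nodes], dtype=np.int8)


@dataclass(frozen=True)
class ContextualizedNetwork(PriorNetwork):
    """A prior network after pruning and sign assignment.

    Every remaining edge carries a fixed sign; ``removed_edges`` and
    ``assigned_signs`` record the provenance relative to the prior.
    """

    removed_edges: tuple = ()
    assigned_signs: tuple = ()  # edge keys whose sign was chosen during search

    def __post_init__(self):
        super().__post_init__()
        unassigned = [e for e in self.edges if e.sign == UNASSIGNED]
        if unassigned:
            raise FormatError(
                f"contextualized network has unassigned signs: "
                f"{[e.key for e in unassigned][:5]}"
            )


@dataclass
class GAParams:
    """Genetic-algorithm settings; the seed is recorded in every report."""

    seed: int
    population: int = 200
    generations: int = 500
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1/chromosome-length
    elitism: int = 2
    removal_penalty: float = 0.1  # lambda, per fraction of removed edges

    def __post_init__(self):
        if self.population <= 0 or self.generations <= 0:
            raise ValueError("population and generations must be positive")
        if self.elitism < 0 or not 0 <= self.crossover_rate <= 1:
            raise ValueError("invalid GA parameters")


@dataclass
class ConsistencyReport:
    """Per-state consistency of a network against observed Boolean states."""

    per_state: dict  # label -> fraction of genes reproduced by one update
    inconsistent: dict  # label -> tuple of violating genes
    overall: float
    edges_removed: tuple = ()
    signs_assigned: tuple = ()
    seed: int | None = None
    params: GAParams | None = None

    def __post_init__(self):
        for lab, f in self.per_state.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"consistency fraction out of [0,1] for {lab!r}")


def booleanize(qe, genes=None, on_threshold: int = 3, label: str = "") -> BooleanState:
    """ON iff quartile expression >= on_threshold (default: upper two quartiles)."""
    s = pd.Series(qe, dtype=int)
    if genes is not None:
        missing = [g for g in genes if g not in s.index]
        if missing:
            raise FormatError(f"genes missing from quartile profile: {sorted(missing)}")
        s = s.loc[list(genes)]
    return BooleanState({g: int(v >= on_threshold) for g, v in s.items()}, label=label)


# ---------------------------------------------------------------------------
# compiled representation


class _Compiled:
    """Index-based edge arrays for fast synchronous updates."""

    def __init__(self, net, transcription_only: bool = False):
        self.nodes = sorted(net.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        edges = [e for e in net.edges
                 if not transcription_only or e.interaction == TRANSCRIPTION]
        self.edges = edges
        self.src = np.array([self.index[e.source] for e in edges], dtype=np.int64)
        self.tgt = np.array([self.index[e.target] for e in edges], dtype=np.int64)
        # +1 activation, -1 inhibition, 0 unassigned (must be resolved by search)
        self.sign = np.array(
            [1 if e.sign == ACTIVATION else (-1 if e.sign == INHIBITION else 0)
             for e in edges], dtype=np.int64)
        n, m = len(self.nodes), len(edges)
        self.tmat = np.zeros((m, n), dtype=np.float64)
        if m:
            self.tmat[np.arange(m), self.tgt] = 1.0

    def step(self, current: np.ndarray, no_input: str = HOLD) -> np.ndarray:
        if np.any(self.sign == 0):
            raise FormatError("cannot simulate a network with unassigned signs")
        if len(self.src) == 0:
            return current.copy() if no_input == HOLD else np.zeros_like(current)
        src_on = current[self.src] == 1
        act = (src_on & (self.sign == 1)).astype(np.float64) @ self.tmat
        inh = (src_on & (self.sign == -1)).astype(np.float64) @ self.tmat
        nxt = np.where(act > inh, 1, 0).astype(np.int8)
        tie_off = (act == inh) & (act + inh > 0)
        nxt[tie_off] = 0
        silent = (act + inh) == 0
        if no_input == HOLD:
            nxt[silent] = current[silent]
        else:
            nxt[silent] = 0
        return nxt


def majority_update(state: BooleanState, net, no_input: str = HOLD,
                    transcription_only: bool = False) -> BooleanState:
    """One synchronous step of the majority rule over all genes."""
    comp = _Compiled(net, transcription_only)
    cur = state.vector(comp.nodes)
    nxt = comp.step(cur, no_input=no_input)
    return BooleanState(dict(zip(comp.nodes, (int(v) for v in nxt))),
                        label=state.label)


def is_fixed_point(state: BooleanState, net, no_input: str = HOLD,
                   transcription_only: bool = False):
    """True iff one majority update reproduces the state; violators listed."""
    comp = _Compiled(net, transcription_only)
    cur = state.vector(comp.nodes)
    nxt = comp.step(cur, no_input=no_input)
    violators = [comp.nodes[i] for i in np.nonzero(nxt != cur)[0]]
    return len(violators) == 0, violators


@dataclass
class Trajectory:
    """Synchronous trajectory until state repetition (or truncation)."""

    states: list
    kind: str  # "fixed_point" | "limit_cycle" | "truncated"
    period: int | None = None


def simulate(state: BooleanState, net, max_steps: int = 1000,
             no_input: str = HOLD, transcription_only: bool = False) -> Trajectory:
    """Iterate synchronous updates, classifying the terminal behavior.

    By pigeonhole the trajectory of an n-node network must repeat within
    2^n steps; ``max_steps`` only truncates earlier.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    comp = _Compiled(net, transcription_only)
    cur = state.vector(comp.nodes)
    seen = {cur.tobytes(): 0}
    visited = [cur]
    for step in range(1, max_steps + 1):
        cur = comp.step(cur, no_input=no_input)
        key = cur.tobytes()
        if key in seen:
            period = step - seen[key]
            kind = "fixed_point" if period == 1 else "limit_cycle"
            states = [
                BooleanState(dict(zip(comp.nodes, map(int, v))), label=state.label)
                for v in visited
            ]
            return Trajectory(states, kind, period)
        seen[key] = step
        visited.append(cur)
    states = [BooleanState(dict(zip(comp.nodes, map(int, v))), label=state.label)
              for v in visited]
    return Trajectory(states, "truncated", None)


def consistency_score(net, states, no_input: str = HOLD,
                      transcription_only: bool = False) -> ConsistencyReport:
    """Fraction of genes whose update reproduces each observed state."""
    if not states:
        raise ValueError("need at least one state")
    comp = _Compiled(net, transcription_only)
    per_state, inconsistent = {}, {}
    for i, st in enumerate(states):
        label = st.label or f"state_{i}"
        if label in per_state:
            label = f"{label}_{i}"
        cur = st.vector(comp.nodes)
        nxt = comp.step(cur, no_input=no_input)
        ok = nxt == cur
        per_state[label] = float(ok.mean()) if len(ok) else 1.0
        inconsistent[label] = tuple(comp.nodes[i] for i in np.nonzero(~ok)[0])
    removed = getattr(net, "removed_edges", ())
    assigned = getattr(net, "assigned_signs", ())
    return ConsistencyReport(
        per_state=per_state,
        inconsistent=inconsistent,
        overall=float(np.mean(list(per_state.values()))),
        edges_removed=tuple(removed),
        signs_assigned=tuple(assigned),
    )


# ---------------------------------------------------------------------------
# genetic-algorithm contextualization


class _FitnessEvaluator:
    """Vectorized fitness of keep/sign chromosomes against observed states."""

    def __init__(self, prior: PriorNetwork, states, no_input: str = HOLD,
                 removal_penalty: float = 0.1):
        self.comp = _Compiled(prior)
        self.n_edges = len(self.comp.edges)
        self.unassigned_idx = np.nonzero(self.comp.sign == 0)[0]
        self.n_bits = self.n_edges + len(self.unassigned_idx)
        self.removal_penalty = removal_penalty
        self.no_input = no_input
        self.obs = [st.vector(self.comp.nodes) for st in states]
        self.src_on = [obs[self.comp.src] == 1 for obs in self.obs]

    def split(self, pop: np.ndarray):
        keep = pop[:, : self.n_edges].astype(bool)
        signbits = pop[:, self.n_edges:].astype(bool)
        return keep, signbits

    def _sign_act(self, signbits: np.ndarray) -> np.ndarray:
        """Per-chromosome activation mask over edges (sign bit 1 = activation)."""
        p = signbits.shape[0]
        act = np.broadcast_to(self.comp.sign == 1, (p, self.n_edges)).copy()
        if len(self.unassigned_idx):
            act[:, self.unassigned_idx] = signbits
        return act

    def consistency(self, pop: np.ndarray) -> np.ndarray:
        keep, signbits = self.split(pop)
        act_mask = self._sign_act(signbits)
        total = np.zeros(pop.shape[0])
        for obs, src_on in zip(self.obs, self.src_on):
            act = (keep & act_mask & src_on).astype(np.float64) @ self.comp.tmat
            inh = (keep & ~act_mask & src_on).astype(np.float64) @ self.comp.tmat
            nxt = (act > inh).astype(np.int8)
            silent = (act + inh) == 0
            if self.no_input == HOLD:
                nxt = np.where(silent, obs[None, :], nxt)
            total += (nxt == obs[None, :]).mean(axis=1)
        return total / len(self.obs)

    def fitness(self, pop: np.ndarray) -> np.ndarray:
        keep, _ = self.split(pop)
        removed = self.n_edges - keep.sum(axis=1)
        penalty = self.removal_penalty * removed / max(self.n_edges, 1)
        return self.consistency(pop) - penalty

    def build(self, prior: PriorNetwork, chrom: np.ndarray) -> ContextualizedNetwork:
        keep = chrom[: self.n_edges].astype(bool)
        signbits = chrom[self.n_edges:].astype(bool)
        signs = self.comp.sign.copy()
        if len(self.unassigned_idx):
            signs[self.unassigned_idx] = np.where(signbits, 1, -1)
        kept_edges, removed, assigned = [], [], []
        for i, e in enumerate(self.comp.edges):
            new_sign = ACTIVATION if signs[i] == 1 else INHIBITION
            if keep[i]:
                kept_edges.append(replace(e, sign=new_sign))
                if e.sign == UNASSIGNED:
                    assigned.append(e.key)
            else:
                removed.append(e)
        return ContextualizedNetwork(
            edges=tuple(kept_edges),
            nodes=frozenset(prior.nodes),
            removed_edges=tuple(removed),
            assigned_signs=tuple(assigned),
        )


def _ga_search(ev: _FitnessEvaluator, params: GAParams, seed_individual=None):
    """Plain generational GA: tournament selection, uniform crossover, elitism."""
    rng = np.random.default_rng(params.seed)
    nbits = ev.n_bits
    pop = rng.integers(0, 2, size=(params.population, nbits), dtype=np.int8)
    pop[0, :] = 1  # keep-everything individual: optimal when the prior is consistent
    if seed_individual is not None:
        pop[min(1, params.population - 1), :] = seed_individual
    mut = params.mutation_rate if params.mutation_rate is not None else 1.0 / max(nbits, 1)
    fit = ev.fitness(pop)
    best_idx = int(np.argmax(fit))
    best = (fit[best_idx], pop[best_idx].copy())
    for _ in range(params.generations):
        order = np.argsort(fit)[::-1]
        elite = pop[order[: params.elitism]].copy()
        # tournament selection (size 3)
        cand = rng.integers(0, params.population, size=(params.population, 3))
        winners = cand[np.arange(params.population), np.argmax(fit[cand], axis=1)]
        parents = pop[winners]
        # uniform crossover on consecutive pairs
        children = parents.copy()
        do_cx = rng.random(params.population // 2) < params.crossover_rate
        mask = rng.integers(0, 2, size=(params.population // 2, nbits), dtype=bool)
        a = children[0::2][: len(do_cx)]
        b = children[1::2][: len(do_cx)]
        swap = mask & do_cx[:, None]
        a_swapped = np.where(swap, b, a)
        b_swapped = np.where(swap, a, b)
        children[0::2][: len(do_cx)] = a_swapped
        children[1::2][: len(do_cx)] = b_swapped
        # per-bit mutation
        flips = rng.random((params.population, nbits)) < mut
        children = np.where(flips, 1 - children, children)
        children[: params.elitism] = elite
        pop = children.astype(np.int8)
        fit = ev.fitness(pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best[0]:
            best = (fit[gen_best], pop[gen_best].copy())
    return best


def contextualize(prior: PriorNetwork, states, params: GAParams,
                  no_input: str = HOLD):
    """Prune/sign-assign the prior so the observed states become fixed points.

    Chromosome: one keep/remove bit per edge plus one sign bit per
    originally unassigned edge. Fitness: mean consistency across states
    minus ``removal_penalty`` times the fraction of removed edges. The seed
    makes the result bit-reproducible.
    """
    if not prior.edges:
        raise FormatError("prior network has no edges")
    ev = _FitnessEvaluator(prior, states, no_input=no_input,
                           removal_penalty=params.removal_penalty)
    best_fit, best_chrom = _ga_search(ev, params)
    net = ev.build(prior, best_chrom)
    report = consistency_score(net, states, no_input=no_input)
    report.seed = params.seed
    report.params = params
    logger.info("contextualization: fitness %.4f, %d/%d edges removed, overall "
                "consistency %.4f", best_fit, len(net.removed_edges),
                len(prior.edges), report.overall)
    return net, report


def contextualize_focused(prior: PriorNetwork, states, focus_gene: str,
                          params: GAParams, no_input: str = HOLD):
    """Contextualize only edges incident to ``focus_gene``.

    The focus gene and its first neighbors (in the prior) must be perfectly
    consistent in every state; all other edges pass through unchanged. The
    incident keep/sign space is searched exhaustively up to 2^18
    assignments, by seeded GA beyond that. Raises ContextualizationError
    (carrying the best report) when no assignment achieves a perfectly
    consistent neighborhood.
    """
    if focus_gene not in prior.nodes:
        raise FormatError(f"focus gene {focus_gene!r} not in the prior network")
    incident = [i for i, e in enumerate(sorted(prior.edges,
                key=lambda e: (e.source, e.target, e.interaction)))
                if e.source == focus_gene or e.target == focus_gene]
    edges_sorted = sorted(prior.edges, key=lambda e: (e.source, e.target, e.interaction))
    outside_unassigned = [e for i, e in enumerate(edges_sorted)
                          if i not in incident and e.sign == UNASSIGNED]
    if outside_unassigned:
        raise FormatError(
            "focused contextualization requires assigned signs outside the focus "
            f"neighborhood; unassigned: {[e.key for e in outside_unassigned][:5]}"
        )
    neighborhood = {focus_gene}
    for i in incident:
        neighborhood.add(edges_sorted[i].source)
        neighborhood.add(edges_sorted[i].target)

    ev = _FitnessEvaluator(prior, states, no_input=no_input,
                           removal_penalty=params.removal_penalty)
    unassigned_incident = [j for j, i in enumerate(ev.unassigned_idx) if i in incident]
    n_keep_bits = len(incident)
    n_sign_bits = len(unassigned_incident)
    nbits = n_keep_bits + n_sign_bits

    comp_nodes = ev.comp.nodes
    hood_mask = np.array([n in neighborhood for n in comp_nodes])

    def expand(local: np.ndarray) -> np.ndarray:
        """Local incident bits -> full chromosomes (others kept, signs moot)."""
        p = local.shape[0]
        full = np.ones((p, ev.n_bits), dtype=np.int8)
        full[:, incident] = local[:, :n_keep_bits]
        for j, uj in enumerate(unassigned_incident):
            full[:, ev.n_edges + uj] = local[:, n_keep_bits + j]
        return full

    def neighborhood_ok(full: np.ndarray) -> np.ndarray:
        keep, signbits = ev.split(full)
        act_mask = ev._sign_act(signbits)
        ok = np.ones(full.shape[0], dtype=bool)
        for obs, src_on in zip(ev.obs, ev.src_on):
            act = (keep & act_mask & src_on).astype(np.float64) @ ev.comp.tmat
            inh = (keep & ~act_mask & src_on).astype(np.float64) @ ev.comp.tmat
            nxt = (act > inh).astype(np.int8)
            silent = (act + inh) == 0
            if no_input == HOLD:
                nxt = np.where(silent, obs[None, :], nxt)
            ok &= ((nxt == obs[None, :]) | ~hood_mask[None, :]).all(axis=1)
        return ok

    if nbits <= 18:
        codes = np.arange(2 ** nbits, dtype=np.int64)
        local = ((codes[:, None] >> np.arange(nbits)[None, :]) & 1).astype(np.int8)
        best_local, best_key = None, None
        chunk = 4096
        for lo in range(0, len(local), chunk):
            block = local[lo: lo + chunk]
            full = expand(block)
            feas = neighborhood_ok(full)
            if not feas.any():
                continue
            fit = ev.fitness(full[feas])
            removed = (~full[feas][:, : ev.n_edges].astype(bool)).sum(axis=1)
            sub = np.nonzero(feas)[0]
            for r, (f, rm) in enumerate(zip(fit, removed)):
                key = (-f, rm, tuple(block[sub[r]]))
                if best_key is None or key < best_key:
                    best_key, best_local = key, block[sub[r]]
        if best_local is None:
            # report the least-bad assignment for diagnostics
            full = expand(local)
            fit = ev.fitness(full)
            net = ev.build(prior, full[int(np.argmax(fit))])
            rep = consistency_score(net, states, no_input=no_input)
            raise ContextualizationError("no perfectly consistent neighborhood",
                                         report=rep)
        chrom = expand(best_local[None, :])[0]
    else:  # large neighborhoods: seeded GA with feasibility bonus
        rng = np.random.default_rng(params.seed)
        pop = rng.integers(0, 2, size=(params.population, nbits), dtype=np.int8)
        pop[0, :] = 1
        best = None
        for _ in range(params.generations):
            full = expand(pop)
            score = ev.fitness(full) + neighborhood_ok(full).astype(float) * 10.0
            order = np.argsort(score)[::-1]
            if best is None or score[order[0]] > best[0]:
                best = (score[order[0]], pop[order[0]].copy())
            elite = pop[order[: params.elitism]]
            cand = rng.integers(0, params.population, size=(params.population, 3))
            winners = cand[np.arange(params.population), np.argmax(score[cand], axis=1)]
            children = pop[winners].copy()
            flips = rng.random((params.population, nbits)) < 1.0 / nbits
            children = np.where(flips, 1 - children, children).astype(np.int8)
            children[: params.elitism] = elite
            pop = children
        chrom = expand(best[1][None, :])[0]
        if not neighborhood_ok(chrom[None, :])[0]:
            net = ev.build(prior, chrom)
            rep = consistency_score(net, states, no_input=no_input)
            raise ContextualizationError("no perfectly consistent neighborhood",
                                         report=rep)

    net = ev.build(prior, chrom)
    report = consistency_score(net, states, no_input=no_input)
    report.seed = params.seed
    report.params = params
    return net, report
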