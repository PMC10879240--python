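"""Agent-based 2D lattice membrane with raft detection and mobility.

The membrane is an L x L periodic square lattice whose sites each hold
one agent from seven lipid groups: cholesterol (CHO), sterol esters
(SE), DHA, n-6 LCPUFA, monounsaturates (MUFA), saturates (SFA) and
sphingolipids (SL).  Nearest-neighbour pairs carry interaction energies
from a symmetric 7x7 matrix J (negative = attractive); the defaults
encode textbook raft physics — cholesterol-sphingolipid and
cholesterol-saturate affinity, cholesterol-PUFA aversion, sterol esters
as a packing disruptor — with all values configuration-exposed.

Because the bulk composition is the model *input*, dynamics must
conserve it: we use Kawasaki (conservative) Metropolis exchanges.  Each
sweep attempts L^2 moves; a move picks a random site and a random
4-neighbour and swaps the two agents with probability
min(1, exp(-dE/T)).  At J = 0 every move is accepted and the lattice is
an ideal mixture.

Rafts are detected geometrically: a site is raft-like when the fraction
of raft-forming lipids {CHO, SL, SFA} in its 9-site Moore neighbourhood
(centre included) reaches ``raft_theta``; rafts are 4-connected
components of raft-like sites of at least ``raft_min_size`` sites,
with components merged across the periodic boundary.  Mobility is the
tracer mean squared displacement per sweep of tagged agents, reported
separately for agents that started the measurement window inside vs
outside a raft.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy import ndimage

from .lipid_core import FattyAcidProfile, LipidClassProfile

__all__ = [
    "LipidGroup",
    "AbmConfig",
    "MembraneState",
    "RaftSummary",
    "default_interaction_matrix",
    "composition_from_profiles",
    "init_membrane",
    "step_kawasaki",
    "detect_rafts",
    "mobility_stats",
    "simulate_group",
    "total_energy",
    "RAFT_FORMING",
]


class LipidGroup(IntEnum):
    CHO = 0
    SE = 1
    DHA = 2
    N6LCPUFA = 3
    MUFA = 4
    SFA = 5
    SL = 6


N_GROUPS = len(LipidGroup)

#: groups whose local density defines a raft-like site
RAFT_FORMING = (LipidGroup.CHO, LipidGroup.SL, LipidGroup.SFA)


def default_interaction_matrix() -> np.ndarray:
    """Default symmetric interaction energies (energy units).

    CHO-SL, SL-SL and CHO-SFA attract (-1); CHO repels both PUFA groups
    (+0.8); SE repels everything (+0.4, packing disruptor); all other
    pairs are neutral.
    """
    J = np.zeros((N_GROUPS, N_GROUPS))
    J[LipidGroup.CHO, LipidGroup.SL] = J[LipidGroup.SL, LipidGroup.CHO] = -1.0
    J[LipidGroup.SL, LipidGroup.SL] = -1.0
    J[LipidGroup.CHO, LipidGroup.SFA] = J[LipidGroup.SFA, LipidGroup.CHO] = -1.0
    J[LipidGroup.CHO, LipidGroup.DHA] = J[LipidGroup.DHA, LipidGroup.CHO] = 0.8
    J[LipidGroup.CHO, LipidGroup.N6LCPUFA] = J[LipidGroup.N6LCPUFA, LipidGroup.CHO] = 0.8
    for g in LipidGroup:
        if g != LipidGroup.SE:
            J[LipidGroup.SE, g] = J[g, LipidGroup.SE] = 0.4
    J[LipidGroup.SE, LipidGroup.SE] = 0.4
    return J


@dataclass
class AbmConfig:
    composition: dict[LipidGroup, float]
    lattice_size: int = 64
    interaction: np.ndarray = field(default_factory=default_interaction_matrix)
    temperature: float = 1.0
    sweeps_burnin: int = 500
    sweeps_measure: int = 200
    raft_theta: float = 0.5
    raft_min_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_size < 16:
            raise ValueError(f"lattice_size must be >= 16, got {self.lattice_size}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {total!r}, expected 1")
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("negative composition fraction")
        J = np.asarray(self.interaction, dtype=float)
        if J.shape != (N_GROUPS, N_GROUPS) or not np.allclose(J, J.T):
            raise ValueError("interaction must be a symmetric 7x7 matrix")
        self.interaction = J
        if not (0.0 < self.raft_theta <= 1.0):
            raise ValueError(f"raft_theta must lie in (0, 1], got {self.raft_theta}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def composition_vector(self) -> np.ndarray:
        v = np.zeros(N_GROUPS)
        for g, f in self.composition.items():
            v[int(g)] = f
        return v


@dataclass
class MembraneState:
    lattice: np.ndarray  # (L, L) int8 group codes
    agent_at: np.ndarray  # (L, L) int32 agent ids
    disp: np.ndarray  # (N, 2) int64 unwrapped displacement per agent
    group_of: np.ndarray  # (N,) int8
    rng: np.random.Generator
    sweep: int = 0
    accepted: int = 0
    attempted: int = 0
    accepted_by_group: np.ndarray = field(default_factory=lambda: np.zeros(N_GROUPS, np.int64))

    @property
    def L(self) -> int:
        return self.lattice.shape[0]

    def counts(self) -> np.ndarray:
        return np.bincount(self.lattice.ravel(), minlength=N_GROUPS)


@dataclass
class RaftSummary:
    n_rafts: int
    mean_size: float
    size_distribution: list[int]
    area_fraction: float
    raft_composition: dict[str, float]
    raft_enrichment: dict[str, float]
    mobility_raft: float = float("nan")
    mobility_nonraft: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "n_rafts": self.n_rafts,
            "mean_size": self.mean_size,
            "size_distribution": list(self.size_distribution),
            "area_fraction": self.area_fraction,
            "raft_composition": dict(self.raft_composition),
            "raft_enrichment": dict(self.raft_enrichment),
            "mobility_raft": self.mobility_raft,
            "mobility_nonraft": self.mobility_nonraft,
        }


# ---------------------------------------------------------------------------
# Composition mapping
# ---------------------------------------------------------------------------

_GLYCEROPHOSPHOLIPIDS = ("PC", "PE", "PS", "PI", "PG")


def composition_from_profiles(
    fa: FattyAcidProfile, lc: LipidClassProfile
) -> dict[LipidGroup, float]:
    """Map the two measured tables onto the seven simulated groups.

    CHO, SE and the sphingolipid pool come straight from the class
    table.  The acyl-chain groups (DHA, n-6 LCPUFA, MUFA, SFA) take the
    fatty-acid mol% scaled into the glycerophospholipid share of the
    class table (fatty-acid composition describes the phospholipid acyl
    chains, which occupy that mass share of the membrane).  The seven
    fractions are renormalized to 1.
    """
    from .lipid_core import SPHINGOLIPID_CLASSES

    phospho_share = sum(lc.get(t) for t in _GLYCEROPHOSPHOLIPIDS) / 100.0
    comp = {
        LipidGroup.CHO: lc.get("CHO"),
        LipidGroup.SE: lc.get("SE"),
        LipidGroup.SL: sum(lc.get(t) for t in SPHINGOLIPID_CLASSES),
        LipidGroup.DHA: 0.0,
        LipidGroup.N6LCPUFA: 0.0,
        LipidGroup.MUFA: 0.0,
        LipidGroup.SFA: 0.0,
    }
    for sp in fa.species():
        v = fa.values[sp.name] * phospho_share
        if sp.is_dma:
            continue
        if sp.name == "22:6n-3":
            comp[LipidGroup.DHA] += v
        elif sp.series == "n-6" and sp.carbons >= 20 and sp.double_bonds >= 2:
            comp[LipidGroup.N6LCPUFA] += v
        elif sp.double_bonds == 1:
            comp[LipidGroup.MUFA] += v
        elif sp.double_bonds == 0:
            comp[LipidGroup.SFA] += v
    total = sum(comp.values())
    if total <= 0:
        raise ValueError("profiles map to an all-zero composition")
    return {g: v / total for g, v in comp.items()}


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing exactly to ``total`` (largest remainder)."""
    raw = fractions * total
    counts = np.floor(raw).astype(np.int64)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def init_membrane(config: AbmConfig) -> MembraneState:
    """Allocate agents by largest-remainder rounding and shuffle onto the lattice."""
    L = config.lattice_size
    counts = _largest_remainder_counts(config.composition_vector(), L * L)
    groups = np.repeat(np.arange(N_GROUPS, dtype=np.int8), counts)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(L * L)
    lattice = np.empty(L * L, dtype=np.int8)
    lattice[perm] = groups  # agent k sits at site perm[k]
    agent_at = np.empty(L * L, dtype=np.int32)
    agent_at[perm] = np.arange(L * L, dtype=np.int32)
    return MembraneState(
        lattice=lattice.reshape(L, L),
        agent_at=agent_at.reshape(L, L),
        disp=np.zeros((L * L, 2), dtype=np.int64),
        group_of=groups.copy(),
        rng=rng,
    )


# ---------------------------------------------------------------------------
# Kawasaki dynamics
# ---------------------------------------------------------------------------

_DI = np.array([-1, 1, 0, 0], dtype=np.int64)
_DJ = np.array([0, 0, -1, 1], dtype=np.int64)


@njit(cache=True)
def _kawasaki_kernel(lattice, agent_at, disp, J, T, sites, dirs, us, acc_by_group):
    L = lattice.shape[0]
    di = np.array([-1, 1, 0, 0], dtype=np.int64)
    dj = np.array([0, 0, -1, 1], dtype=np.int64)
    accepted = 0
    for m in range(sites.shape[0]):
        s = sites[m]
        i = s // L
        j = s - i * L
        d = dirs[m]
        ni = (i + di[d]) % L
        nj = (j + dj[d]) % L
        a = lattice[i, j]
        b = lattice[ni, nj]
        if a == b:
            dE = 0.0
        else:
            dE = 0.0
            for k in range(4):
                pi = (i + di[k]) % L
                pj = (j + dj[k]) % L
                if pi == ni and pj == nj:
                    continue
                c = lattice[pi, pj]
                dE += J[b, c] - J[a, c]
                qi = (ni + di[k]) % L
                qj = (nj + dj[k]) % L
                if qi == i and qj == j:
                    continue
                c2 = lattice[qi, qj]
                dE += J[a, c2] - J[b, c2]
        if dE <= 0.0 or us[m] < np.exp(-dE / T):
            lattice[i, j] = b
            lattice[ni, nj] = a
            ida = agent_at[i, j]
            idb = agent_at[ni, nj]
            agent_at[i, j] = idb
            agent_at[ni, nj] = ida
            disp[ida, 0] += di[d]
            disp[ida, 1] += dj[d]
            disp[idb, 0] -= di[d]
            disp[idb, 1] -= dj[d]
            accepted += 1
            acc_by_group[a] += 1
            acc_by_group[b] += 1
    return accepted


def step_kawasaki(state: MembraneState, config: AbmConfig, n_sweeps: int) -> MembraneState:
    """Run ``n_sweeps`` sweeps of L^2 attempted Metropolis exchanges each.

    Mutates and returns ``state``.  Per-group counts are conserved
    exactly; acceptance counters accumulate on the state.
    """
    L = state.L
    J = np.ascontiguousarray(config.interaction)
    chunk = 64  # sweeps per RNG batch, keeps random buffers small
    done = 0
    while done < n_sweeps:
        n = min(chunk, n_sweeps - done)
        moves = n * L * L
        sites = state.rng.integers(0, L * L, size=moves)
        dirs = state.rng.integers(0, 4, size=moves)
        us = state.rng.random(size=moves)
        state.accepted += int(
            _kawasaki_kernel(
                state.lattice, state.agent_at, state.disp, J,
                float(config.temperature), sites, dirs, us, state.accepted_by_group,
            )
        )
        state.attempted += moves
        done += n
    state.sweep += n_sweeps
    return state


def total_energy(state: MembraneState, config: AbmConfig) -> float:
    """Sum of nearest-neighbour pair energies (each pair counted once)."""
    lat = state.lattice
    J = config.interaction
    right = J[lat, np.roll(lat, -1, axis=1)]
    down = J[lat, np.roll(lat, -1, axis=0)]
    return float(right.sum() + down.sum())


# ---------------------------------------------------------------------------
# Raft detection
# ---------------------------------------------------------------------------

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _raft_mask(lattice: np.ndarray, theta: float) -> np.ndarray:
    """Sites whose 9-site Moore neighbourhood is >= theta raft-forming."""
    is_raft_lipid = np.isin(lattice, [int(g) for g in RAFT_FORMING]).astype(np.int64)
    counts = np.zeros_like(is_raft_lipid)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            counts += np.roll(np.roll(is_raft_lipid, di, axis=0), dj, axis=1)
    # integer comparison avoids float threshold jitter at exact multiples
    return counts >= 9.0 * theta - 1e-9


def _periodic_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """4-connected labelling with components merged across the periodic seam."""
    labels, n = ndimage.label(mask, structure=_FOUR_CONN)
    if n == 0:
        return labels, 0
    parent = np.arange(n + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    top, bottom = labels[0, :], labels[-1, :]
    for a, b in zip(top, bottom):
        if a and b:
            union(int(a), int(b))
    left, right = labels[:, 0], labels[:, -1]
    for a, b in zip(left, right):
        if a and b:
            union(int(a), int(b))
    roots = np.array([find(k) for k in range(n + 1)])
    # compress root ids to 1..m
    uniq = np.unique(roots[1:])
    remap = np.zeros(n + 1, dtype=np.int64)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[roots[labels]], len(uniq)


def detect_rafts(state: MembraneState, config: AbmConfig) -> RaftSummary:
    """Static raft summary: count, sizes, area fraction, composition."""
    mask = _raft_mask(state.lattice, config.raft_theta)
    labels, n = _periodic_components(mask)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    keep = np.flatnonzero(sizes >= config.raft_min_size) + 1
    raft_sites = np.isin(labels, keep)
    kept_sizes = sorted(int(sizes[k - 1]) for k in keep)
    area = float(raft_sites.mean())
    comp: dict[str, float] = {}
    enrich: dict[str, float] = {}
    overall = np.bincount(state.lattice.ravel(), minlength=N_GROUPS) / state.lattice.size
    if raft_sites.any():
        inside = np.bincount(state.lattice[raft_sites], minlength=N_GROUPS)
        inside = inside / inside.sum()
        for g in LipidGroup:
            comp[g.name] = float(inside[g])
            enrich[g.name] = float(inside[g] / overall[g]) if overall[g] > 0 else float("nan")
    else:
        for g in LipidGroup:
            comp[g.name] = 0.0
            enrich[g.name] = float("nan")
    return RaftSummary(
        n_rafts=len(kept_sizes),
        mean_size=float(np.mean(kept_sizes)) if kept_sizes else 0.0,
        size_distribution=kept_sizes,
        area_fraction=area if kept_sizes else 0.0,
        raft_composition=comp,
        raft_enrichment=enrich,
    )


# ---------------------------------------------------------------------------
# Mobility
# ---------------------------------------------------------------------------

def mobility_stats(
    state: MembraneState, config: AbmConfig, n_sweeps: int
) -> tuple[float, float]:
    """Tracer MSD per sweep for raft vs non-raft agents.

    Agents are classified by raft membership at the window start; the
    window must be at least 10 sweeps.  Returns (mobility_raft,
    mobility_nonraft) in lattice units^2 per sweep; a population with no
    members reports NaN.
    """
    if n_sweeps < 10:
        raise ValueError(f"mobility window must be >= 10 sweeps, got {n_sweeps}")
    mask = _raft_mask(state.lattice, config.raft_theta)
    labels, n = _periodic_components(mask)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    keep = np.flatnonzero(sizes >= config.raft_min_size) + 1
    raft_sites = np.isin(labels, keep)
    in_raft = np.zeros(state.L * state.L, dtype=bool)
    in_raft[state.agent_at[raft_sites]] = True
    state.disp[:] = 0
    step_kawasaki(state, config, n_sweeps)
    sq = (state.disp.astype(float) ** 2).sum(axis=1)
    mob_raft = float(sq[in_raft].mean() / n_sweeps) if in_raft.any() else float("nan")
    mob_non = float(sq[~in_raft].mean() / n_sweeps) if (~in_raft).any() else float("nan")
    return mob_raft, mob_non


# ---------------------------------------------------------------------------
# Replicated group simulation
# ---------------------------------------------------------------------------

def simulate_group(
    composition: Mapping[LipidGroup, float],
    config: AbmConfig | None = None,
    n_replicates: int = 5,
    seed: int | None = None,
    **config_overrides,
) -> dict:
    """Run seeded replicate simulations for one composition.

    Each replicate draws its own seed from a ``SeedSequence`` spawned
    from the master seed, equilibrates for ``sweeps_burnin`` sweeps,
    detects rafts, then measures mobility over ``sweeps_measure``
    sweeps.  Returns per-replicate summaries plus mean/sd aggregates.
    """
    base = config or AbmConfig(composition=dict(composition), **config_overrides)
    master = base.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(n_replicates)
    replicates: list[RaftSummary] = []
    for child in children:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = AbmConfig(
            composition=dict(composition),
            lattice_size=base.lattice_size,
            interaction=base.interaction.copy(),
            temperature=base.temperature,
            sweeps_burnin=base.sweeps_burnin,
            sweeps_measure=base.sweeps_measure,
            raft_theta=base.raft_theta,
            raft_min_size=base.raft_min_size,
            seed=rep_seed,
        )
        state = init_membrane(cfg)
        step_kawasaki(state, cfg, cfg.sweeps_burnin)
        summary = detect_rafts(state, cfg)
        mob_r, mob_n = mobility_stats(state, cfg, cfg.sweeps_measure)
        summary.mobility_raft, summary.mobility_nonraft = mob_r, mob_n
        replicates.append(summary)

    def agg(vals: Sequence[float]) -> dict[str, float]:
        arr = np.asarray(vals, dtype=float)
        ok = arr[~np.isnan(arr)]
        if len(ok) == 0:
            return {"mean": float("nan"), "sd": float("nan")}
        return {"mean": float(ok.mean()), "sd": float(ok.std(ddof=1)) if len(ok) > 1 else 0.0}

    aggregate = {
        "n_rafts": agg([r.n_rafts for r in replicates]),
        "mean_size": agg([r.mean_size for r in replicates]),
        "area_fraction": agg([r.area_fraction for r in replicates]),
        "mobility_raft": agg([r.mobility_raft for r in replicates]),
        "mobility_nonraft": agg([r.mobility_nonraft for r in replicates]),
        "raft_composition": {
            g.name: agg([r.raft_composition[g.name] for r in replicates]) for g in LipidGroup
        },
    }
    return {"replicates": [r.as_dict() for r in replicates], "aggregate": aggregate}
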