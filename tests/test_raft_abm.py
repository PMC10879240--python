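"""Lattice membrane: conservation, raft detection vs brute force, mobility."""

import numpy as np
import pytest

from raftscape.lipid_core import FattyAcidProfile, LipidClassProfile
from raftscape.raft_abm import (
    AbmConfig,
    LipidGroup,
    composition_from_profiles,
    default_interaction_matrix,
    detect_rafts,
    init_membrane,
    mobility_stats,
    simulate_group,
    step_kawasaki,
    total_energy,
    _largest_remainder_counts,
)

RAFT_CODES = {int(LipidGroup.CHO), int(LipidGroup.SL), int(LipidGroup.SFA)}


def brute_force_rafts(lattice, theta, min_size):
    """Independent reference: per-pixel Moore scan + periodic flood fill."""
    L = lattice.shape[0]
    mask = np.zeros((L, L), dtype=bool)
    for i in range(L):
        for j in range(L):
            cnt = 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if int(lattice[(i + di) % L, (j + dj) % L]) in RAFT_CODES:
                        cnt += 1
            mask[i, j] = cnt >= 9 * theta - 1e-9
    seen = np.zeros((L, L), dtype=bool)
    comps = []
    for i in range(L):
        for j in range(L):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                comp = []
                while stack:
                    a, b = stack.pop()
                    comp.append((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        na, nb = (a + da) % L, (b + db) % L
                        if mask[na, nb] and not seen[na, nb]:
                            seen[na, nb] = True
                            stack.append((na, nb))
                comps.append(comp)
    kept = [c for c in comps if len(c) >= min_size]
    raft_sites = np.zeros((L, L), dtype=bool)
    for c in kept:
        for a, b in c:
            raft_sites[a, b] = True
    return raft_sites, sorted(len(c) for c in kept)


def uniform_config(**kw):
    comp = {g: 1.0 / 7.0 for g in LipidGroup}
    comp[LipidGroup.SL] = 1.0 - 6.0 / 7.0
    return AbmConfig(composition=comp, **kw)


def test_composition_from_profiles_classes_only():
    fa = FattyAcidProfile("s", {"16:0": 100.0})
    lc = LipidClassProfile("s", {"CHO": 50.0, "SM": 50.0})
    comp = composition_from_profiles(fa, lc)
    # no glycerophospholipid share: acyl-chain groups get zero weight
    assert comp[LipidGroup.CHO] == pytest.approx(0.5)
    assert comp[LipidGroup.SL] == pytest.approx(0.5)
    assert comp[LipidGroup.SFA] == pytest.approx(0.0)


def test_composition_equal_shares_is_uniform():
    fa = FattyAcidProfile(
        "s", {"22:6n-3": 25.0, "20:4n-6": 25.0, "18:1n-9": 25.0, "16:0": 25.0}
    )
    c = 100.0 / 7.0
    lc = LipidClassProfile("s", {"CHO": c, "SE": c, "SM": c, "PC": 4 * c})
    comp = composition_from_profiles(fa, lc)
    for g in LipidGroup:
        assert comp[g] == pytest.approx(1.0 / 7.0, abs=1e-9)


def test_composition_sums_to_one(small_cohort):
    for rec in small_cohort[:4]:
        comp = composition_from_profiles(rec.fatty_acids, rec.lipid_classes)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in comp.values())


def test_largest_remainder_counts():
    counts = _largest_remainder_counts(np.array([0.5, 0.3, 0.2]), 100)
    assert counts.tolist() == [50, 30, 20]
    fr = np.array([0.333, 0.333, 0.334])
    assert _largest_remainder_counts(fr, 16 * 16).sum() == 256


def test_init_membrane_pure_and_counts():
    comp = {g: 0.0 for g in LipidGroup}
    comp[LipidGroup.SL] = 1.0
    cfg = AbmConfig(composition=comp, lattice_size=16, seed=0)
    st = init_membrane(cfg)
    assert (st.lattice == int(LipidGroup.SL)).all()
    cfg2 = uniform_config(lattice_size=16, seed=0)
    st2 = init_membrane(cfg2)
    assert st2.counts().sum() == 16 * 16
    assert st2.counts().tolist() == _largest_remainder_counts(
        cfg2.composition_vector(), 256
    ).tolist()


def test_kawasaki_conserves_counts_and_j0_accepts_all():
    cfg = uniform_config(
        lattice_size=24, interaction=np.zeros((7, 7)), seed=2
    )
    st = init_membrane(cfg)
    c0 = st.counts().copy()
    step_kawasaki(st, cfg, 1000)
    assert (st.counts() == c0).all()
    assert st.accepted == st.attempted  # dE == 0 everywhere at J = 0


def test_low_temperature_energy_decreases():
    cfg = uniform_config(lattice_size=24, temperature=0.2, seed=3)
    st = init_membrane(cfg)
    e0 = total_energy(st, cfg)
    step_kawasaki(st, cfg, 300)
    e1 = total_energy(st, cfg)
    step_kawasaki(st, cfg, 300)
    e2 = total_energy(st, cfg)
    assert e1 < e0
    assert e2 <= e1 + 1e-9


def test_detect_rafts_pure_membranes():
    comp = {g: 0.0 for g in LipidGroup}
    comp[LipidGroup.SL] = 1.0
    cfg = AbmConfig(composition=comp, lattice_size=16, seed=0)
    s = detect_rafts(init_membrane(cfg), cfg)
    assert s.n_rafts == 1
    assert s.area_fraction == 1.0
    assert s.raft_composition["SL"] == pytest.approx(1.0)

    comp2 = {g: 0.0 for g in LipidGroup}
    comp2[LipidGroup.MUFA] = 1.0
    cfg2 = AbmConfig(composition=comp2, lattice_size=16, seed=0)
    s2 = detect_rafts(init_membrane(cfg2), cfg2)
    assert s2.n_rafts == 0
    assert s2.area_fraction == 0.0


@pytest.mark.parametrize("seed", range(8))
def test_detector_matches_brute_force_flood_fill(seed):
    """Detection is bit-identical to the reference on random 16x16 lattices."""
    rng = np.random.default_rng(seed)
    lattice = rng.integers(0, 7, size=(16, 16)).astype(np.int8)
    cfg = uniform_config(lattice_size=16, seed=seed)
    st = init_membrane(cfg)
    st.lattice = lattice
    ours = detect_rafts(st, cfg)
    ref_sites, ref_sizes = brute_force_rafts(lattice, cfg.raft_theta, cfg.raft_min_size)
    assert ours.size_distribution == ref_sizes
    assert ours.n_rafts == len(ref_sizes)
    assert ours.area_fraction == pytest.approx(ref_sites.mean())


def test_mobility_j0_homogeneous():
    cfg = uniform_config(lattice_size=32, interaction=np.zeros((7, 7)), seed=5)
    st = init_membrane(cfg)
    mr, mn = mobility_stats(st, cfg, 200)
    assert mr == pytest.approx(mn, rel=0.05)


def test_mobility_trapped_clusters_at_low_temperature():
    comp = {g: 0.0 for g in LipidGroup}
    comp[LipidGroup.CHO] = 0.3
    comp[LipidGroup.SL] = 0.3
    comp[LipidGroup.MUFA] = 0.4
    cfg = AbmConfig(
        composition=comp, lattice_size=32, temperature=0.3, seed=4, sweeps_burnin=800
    )
    st = init_membrane(cfg)
    step_kawasaki(st, cfg, cfg.sweeps_burnin)
    mr, mn = mobility_stats(st, cfg, 100)
    assert mr < mn


def test_mobility_window_validation():
    cfg = uniform_config(lattice_size=16, seed=0)
    st = init_membrane(cfg)
    with pytest.raises(ValueError, match="10 sweeps"):
        mobility_stats(st, cfg, 5)


def test_simulate_group_deterministic():
    comp = {g: 1.0 / 7.0 for g in LipidGroup}
    comp[LipidGroup.SL] = 1.0 - 6.0 / 7.0
    kw = dict(n_replicates=2, seed=9, lattice_size=16, sweeps_burnin=30, sweeps_measure=10)
    a = simulate_group(comp, **kw)
    b = simulate_group(comp, **kw)
    assert a == b


def test_simulate_group_single_species_degenerate():
    comp = {g: 0.0 for g in LipidGroup}
    comp[LipidGroup.SFA] = 1.0
    res = simulate_group(
        comp, n_replicates=2, seed=1, lattice_size=16, sweeps_burnin=20, sweeps_measure=10
    )
    for rep in res["replicates"]:
        assert rep["n_rafts"] in (0, 1)


def test_j0_relaxation_is_indistinguishable_from_fresh_shuffle():
    """With J = 0 the chain's occupancy statistics stay ideal-mixture."""
    from scipy.stats import chi2_contingency

    cfg = uniform_config(lattice_size=32, interaction=np.zeros((7, 7)), seed=6)
    pvals = []
    for seed in range(10):
        cfg.seed = seed
        st = init_membrane(cfg)
        step_kawasaki(st, cfg, 200)
        # per-row group counts vs a fresh shuffle of the same membrane
        rows_a = np.stack([np.bincount(r, minlength=7) for r in st.lattice[:8]])
        fresh = init_membrane(cfg)
        rows_b = np.stack([np.bincount(r, minlength=7) for r in fresh.lattice[:8]])
        p = chi2_contingency(np.vstack([rows_a.sum(0), rows_b.sum(0)]))[1]
        pvals.append(p)
    assert np.mean(np.array(pvals) > 0.01) >= 0.9


def test_stronger_raft_attraction_does_not_shrink_rafts():
    """Area fraction is non-decreasing as CHO-SL attraction strengthens."""
    comp = {g: 0.0 for g in LipidGroup}
    comp[LipidGroup.CHO] = 0.25
    comp[LipidGroup.SL] = 0.25
    comp[LipidGroup.MUFA] = 0.5
    areas = []
    for j_att in (0.0, -1.0, -2.0):
        vals = []
        for seed in range(3):
            J = np.zeros((7, 7))
            J[LipidGroup.CHO, LipidGroup.SL] = J[LipidGroup.SL, LipidGroup.CHO] = j_att
            cfg = AbmConfig(
                composition=comp, lattice_size=24, interaction=J, seed=seed,
                sweeps_burnin=300,
            )
            st = init_membrane(cfg)
            step_kawasaki(st, cfg, cfg.sweeps_burnin)
            vals.append(detect_rafts(st, cfg).area_fraction)
        areas.append(np.mean(vals))
    assert areas[1] >= areas[0] - 0.02
    assert areas[2] >= areas[1] - 0.02


def test_config_validation():
    comp = {g: 1.0 / 7.0 for g in LipidGroup}
    with pytest.raises(ValueError, match="sums to"):
        AbmConfig(composition={LipidGroup.CHO: 0.5})
    with pytest.raises(ValueError, match="lattice_size"):
        AbmConfig(composition={**comp, LipidGroup.SL: 1 - 6 / 7}, lattice_size=8)
    bad_j = default_interaction_matrix()
    bad_j[0, 1] = 5.0  # breaks symmetry
    with pytest.raises(ValueError, match="symmetric"):
        AbmConfig(composition={**comp, LipidGroup.SL: 1 - 6 / 7}, interaction=bad_j)
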