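"""Encoder semantics: worked examples, oracles and invariances."""

import itertools
import math
import random
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from conftest import random_molecule
from graphfp.atom_typing import LabelScheme, assign_ppps, label_atoms
from graphfp.chem_model import build_molecule
from graphfp.encoders import (
    DEFAULT_CONFIGS,
    ENCODINGS,
    PAIR_BLOCKS,
    EncodingConfig,
    FixedVector,
    Metric,
    cats_flat_index,
    encode,
    encode_asp,
    encode_atom_pairs,
    encode_atom_triplets,
    encode_cats,
    encode_dfs,
    encode_ecfp,
    encode_lstar,
    encode_pharm_pairs,
    encode_radial_shells,
    encode_shed,
    get_config,
)
from graphfp.fixtures import BOND_LENGTH, make_chain, make_ring, permute_molecule

EN = LabelScheme.ELEMENT_NEIGHBOR


def nx_distances(mol):
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from((b.i, b.j) for b in mol.bonds)
    return dict(nx.all_pairs_shortest_path_length(g))


# ---------------------------------------------------------------------------
# DFS / ASP

def test_dfs_single_atom_empty():
    assert encode(make_chain(1), "DFS", d=2) == Counter()


def test_dfs_propane_worked_example():
    features = encode(make_chain(3), "DFS", d=2)
    assert features == Counter({"C.2-C.1": 4, "C.1-C.2-C.1": 2})


def test_asp_equals_dfs_on_trees():
    rng = random.Random(41)
    for _ in range(25):
        mol = random_molecule(rng, p_extra_edge=0.0, with_coords=False)
        cfg = EncodingConfig("DFS", d=6, scheme=EN)
        assert encode_dfs(mol, cfg) == encode_asp(mol, cfg)


def test_asp_drops_around_the_ring_paths_on_cyclobutane():
    ring = make_ring(4)
    cfg = EncodingConfig("ASP", d=3, scheme=EN)
    dfs = encode_dfs(ring, cfg)
    asp = encode_asp(ring, cfg)
    long_path = "C.2-C.2-C.2-C.2"
    assert long_path in dfs
    assert long_path not in asp


def test_asp_feature_ids_subset_of_dfs():
    rng = random.Random(43)
    for _ in range(50):
        mol = random_molecule(rng, with_coords=False)
        cfg = EncodingConfig("x", d=5, scheme=EN)
        assert set(encode_asp(mol, cfg)) <= set(encode_dfs(mol, cfg))


# ---------------------------------------------------------------------------
# pairs / triplets vs brute-force oracles

def brute_force_pairs(mol, labels, d, dmat):
    out = Counter()
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            dist = dmat[i].get(j, math.inf) if isinstance(dmat, dict) else dmat[i, j]
            if 1 <= dist <= d:
                a = f"{labels[i]}-{int(dist)}-{labels[j]}"
                b = f"{labels[j]}-{int(dist)}-{labels[i]}"
                out[max(a, b)] += 1
    return out


def brute_force_triplets(mol, labels, d, dmat):
    def dist(i, j):
        return dmat[i].get(j, math.inf) if isinstance(dmat, dict) else dmat[i, j]

    out = Counter()
    for i, j, k in itertools.combinations(range(mol.n_atoms), 3):
        ds = (dist(i, j), dist(j, k), dist(i, k))
        if not all(1 <= x <= d for x in ds):
            continue
        candidates = []
        for a, b, c in itertools.permutations((i, j, k)):
            candidates.append(
                f"{labels[a]}-{int(dist(a, b))}-{labels[b]}-"
                f"{int(dist(b, c))}-{labels[c]}-{int(dist(c, a))}"
            )
        out[max(candidates)] += 1
    return out


def test_pair_encoder_examples():
    assert encode(make_chain(1), "AP2D") == Counter()
    assert encode(make_chain(3), "AP2D") == Counter({"C.2-1-C.1": 2, "C.1-2-C.1": 1})


def test_triplet_encoder_propane_single_triple():
    features = encode(make_chain(3), "AT2D", d=2)
    assert sum(features.values()) == 1
    assert len(features) == 1


def test_two_atom_molecule_has_no_triplets():
    assert encode(make_chain(2), "AT2D") == Counter()


def test_pair_and_triplet_encoders_match_brute_force():
    rng = random.Random(47)
    for _ in range(30):
        mol = random_molecule(rng, n_max=8, with_coords=True)
        labels = label_atoms(mol, EN)
        topo = nx_distances(mol)
        cfg = EncodingConfig("x", d=4, scheme=EN)
        assert encode_atom_pairs(mol, cfg, Metric.TOPO) == brute_force_pairs(
            mol, labels, 4, topo
        )
        assert encode_atom_triplets(mol, cfg, Metric.TOPO) == brute_force_triplets(
            mol, labels, 4, topo
        )
        from graphfp.graph_core import geom_matrix

        g = geom_matrix(mol, 1.0)
        assert encode_atom_pairs(mol, cfg, Metric.GEOM) == brute_force_pairs(
            mol, labels, 4, g
        )
        assert encode_atom_triplets(mol, cfg, Metric.GEOM) == brute_force_triplets(
            mol, labels, 4, g
        )


def test_geometric_encoders_require_coordinates():
    mol = build_molecule(["C", "C"], [(0, 1)])
    for name in ("AP3D", "AT3D", "RAD3D", "CATS3D"):
        with pytest.raises(ValueError, match="no 3D information"):
            encode(mol, name)


# ---------------------------------------------------------------------------
# CATS

def test_cats_flat_index_dn_distance_six_is_76():
    assert cats_flat_index("DN", 6, 9) == 76


def test_cats_vector_length_and_dn_bit():
    # donor-negative pair at topological distance 6 increments flat index 76
    mol = build_molecule(
        ["O"] + ["C"] * 6,
        [(i, i + 1) for i in range(6)],
        charges=[0, 0, 0, 0, 0, 0, -1],
    )
    vec = encode(mol, "CATS2D")
    assert len(vec) == 150
    assert vec[76] == 1


def test_cats_zero_vector_without_ppps():
    vec = encode(make_chain(1), "CATS2D", d=9)  # methane: no PPP atoms
    assert len(vec) == 150
    assert not vec.values.any()


def test_cats_conservation_of_pair_observations():
    rng = random.Random(53)
    for _ in range(20):
        mol = random_molecule(rng, with_coords=False)
        d = 9
        vec = encode(mol, "CATS2D", d=d)
        ppps = assign_ppps(mol)
        dmat = nx_distances(mol)
        expected = 0
        for i in range(mol.n_atoms):
            for j in range(i + 1, mol.n_atoms):
                dist = dmat[i].get(j, math.inf)
                if 1 <= dist <= d:
                    expected += len(ppps[i]) * len(ppps[j])
        distance_cells = np.delete(
            vec.values, [b * (d + 1) for b in range(15)]
        )
        assert distance_cells.sum() == expected


# ---------------------------------------------------------------------------
# SHED

def test_shed_has_15_entries_and_blocks_enumerate_ppp_pairs():
    assert len(PAIR_BLOCKS) == 15
    pairs = {
        "".join(sorted(p))
        for p in itertools.combinations_with_replacement("ADLNP", 2)
    }
    assert set(PAIR_BLOCKS) == pairs
    vec = encode(make_chain(3), "SHED")
    assert len(vec) == 15


def test_shed_single_distance_scores_one():
    # one acceptor/donor against one lipophilic carbon at a single distance
    mol = build_molecule(["O", "C", "C", "C"], [(0, 1), (1, 2), (2, 3)])
    vec = encode(mol, "SHED")
    # L atoms: 2 and 3?  atom 1 has O neighbor -> not L; atoms 2,3 all-C -> L
    # AL distances: O-2 = 2, O-3 = 3 -> two distances, equal counts
    assert vec.block("AL")[0] == pytest.approx(2.0)
    # DD / AA: single-atom pair types never observed -> 0
    assert vec.block("DD")[0] == 0.0


def test_shed_uniform_distance_distribution_scores_k():
    # O capping a 5-carbon chain: lipophilic carbons at distances 2..5 from O,
    # one pair per distance -> perplexity 4 for both AL and DL
    mol = build_molecule(["C"] * 5 + ["O"], [(i, i + 1) for i in range(5)])
    vec = encode(mol, "SHED")
    assert vec.block("AL")[0] == pytest.approx(4.0)
    assert vec.block("DL")[0] == pytest.approx(4.0)


def test_shed_entries_bounded_by_number_of_distances():
    rng = random.Random(59)
    for _ in range(25):
        mol = random_molecule(rng, with_coords=False)
        d = 8
        vec = encode(mol, "SHED", d=d)
        assert (vec.values >= 0).all()
        assert (vec.values <= d).all()


# ---------------------------------------------------------------------------
# ECFP

def test_ecfp_depth_zero_counts_initial_identifiers(oxa):
    features = encode(oxa, "ECFP", d=0, scheme=LabelScheme.ELEMENT)
    assert features == Counter({"C": 7, "O": 4, "N": 1})


def test_ecfp_ethane_by_hand():
    features = encode(make_chain(2), "ECFP", d=1, scheme=LabelScheme.ELEMENT)
    assert features == Counter({"C": 2, "C(-C)": 2})


def test_ecfp_growth_saturates():
    features = encode(make_chain(3), "ECFP", d=6, scheme=LabelScheme.ELEMENT)
    # iterations stop once the sphere covers the whole chain
    assert features == Counter(
        {"C": 3, "C(-C([*]))": 2, "C(-C(-C))": 2, "C(-C)(-C)": 1}
    )


def test_ecfp_ring_closure_marks_are_paired():
    ring = make_ring(6)
    features = encode(ring, "ECFP", d=3, scheme=LabelScheme.ELEMENT)
    closures = [f for f in features if "%1" in f]
    assert closures, "ring sphere must contain a closure marker"
    for f in closures:
        assert f.count("%1") == 2


# ---------------------------------------------------------------------------
# radial shells and LSTAR

def test_radial_shell_isolated_atom_keeps_empty_shell():
    features = encode(make_chain(1), "RAD2D", d=1)
    assert features == Counter({"0[C.0]1[]": 1})


def test_radial_shells_oxaceprol_topological(oxa):
    features = encode(oxa, "RAD2D", scheme=LabelScheme.ELEMENT)
    assert features["0[N]1[C C C]"] == 1
    assert features["0[N]1[C C C]2[C C C C O]"] == 1
    assert sum(features.values()) == oxa.n_atoms * 3  # n*d features


def test_radial_shells_oxaceprol_geometric(oxa):
    features = encode(oxa, "RAD3D")
    assert any(f.startswith("0[N.3]1[C.2 C.3 C.3]") for f in features)


def test_lstar_isolated_atom_empty():
    assert encode(make_chain(1), "LSTAR") == Counter()


def test_lstar_propane_terminal_shell():
    features = encode(make_chain(3), "LSTAR", d=1)
    assert features["[C.1-C.2]"] == 2  # both terminal roots
    assert features["[C.2-C.1, C.2-C.1]"] == 1  # middle root


def test_lstar_oxaceprol_shells(oxa):
    features = encode(oxa, "LSTAR")
    assert features["[N.3-C.2, N.3-C.3, N.3-C.3]"] == 1
    assert (
        features[
            "[N.3-C.2-C.3, N.3-C.3-C.1, N.3-C.3-C.2, N.3-C.3-C.3, N.3-C.3=O.1]"
        ]
        == 1
    )


# ---------------------------------------------------------------------------
# cross-cutting invariants

@pytest.mark.parametrize("name", sorted(ENCODINGS))
def test_every_encoder_invariant_under_atom_permutation(name, oxa):
    rng = random.Random(61)
    mols = [oxa, random_molecule(rng, n_max=8, with_coords=True)]
    for mol in mols:
        ref = encode(mol, name)
        for _ in range(3):
            perm = list(range(mol.n_atoms))
            rng.shuffle(perm)
            out = encode(permute_molecule(mol, perm), name)
            if isinstance(ref, FixedVector):
                assert np.allclose(out.values, ref.values)
            else:
                assert out == ref


@pytest.mark.parametrize(
    "pair", [("AP2D", "AP3D"), ("AT2D", "AT3D"), ("CATS2D", "CATS3D"),
             ("PHAP2PT2D", "PHAP2PT3D"), ("RAD2D", "RAD3D")]
)
def test_2d_and_3d_variants_coincide_on_calibrated_chain(pair):
    # chain laid out so floor(scaled Euclidean distance) == topological distance
    topo_name, geom_name = pair
    mol = make_chain(7)
    s = 1.0 / BOND_LENGTH
    d = 5
    a = encode(mol, topo_name, d=d)
    b = encode(mol, geom_name, d=d, s=s)
    if isinstance(a, FixedVector):
        assert np.array_equal(a.values, b.values)
    else:
        assert a == b


def test_default_configs_cover_all_encodings():
    assert set(DEFAULT_CONFIGS) == set(ENCODINGS)
    assert DEFAULT_CONFIGS["DFS"].d == 8
    assert DEFAULT_CONFIGS["ECFP"].scheme is LabelScheme.DAYLIGHT_INVARIANT
    with pytest.raises(KeyError):
        get_config("UNKNOWN")
    with pytest.raises(ValueError):
        EncodingConfig("DFS", d=0)
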