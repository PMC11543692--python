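"""Disulfides, layer contacts, ion pairs, hydrophobic clusters, SASA burial."""

import itertools
import warnings

import numpy as np
import pytest

from fibrilkit import (
    GeneratorSpec,
    HelicalParams,
    apply_symmetry,
    classify_exposure,
    detect_disulfides,
    find_ion_pairs,
    hydrophobic_clusters,
    layer_contacts,
    make_fibril,
)
from fibrilkit.contacts import shrake_rupley, vdw_radius
from fibrilkit.model import FibrilModel
from conftest import make_point_model


def _cys_layer():
    """One layer with two Cys whose SG atoms are 2.0 A apart (one bridge)."""
    specs = [
        ("CA", "C", "CYS", 1, (0, 0, 0)),
        ("SG", "S", "CYS", 1, (1.5, 0, 0)),
        ("CA", "C", "CYS", 2, (5.0, 0, 0)),
        ("SG", "S", "CYS", 2, (3.5, 0, 0)),
        ("CA", "C", "ALA", 3, (10.0, 0, 0)),
    ]
    return make_point_model(specs)


class TestDisulfides:
    def test_single_bridge(self):
        bonds = detect_disulfides(_cys_layer())
        assert len(bonds) == 1
        b = bonds[0]
        assert {b.residue_a[1], b.residue_b[1]} == {1, 2}
        assert b.sg_distance == pytest.approx(2.0)
        assert b.intra_chain

    def test_above_cutoff_excluded(self):
        m = make_point_model(
            [("SG", "S", "CYS", 1, (0, 0, 0)), ("SG", "S", "CYS", 2, (3.5, 0, 0))]
        )
        assert detect_disulfides(m) == []
        assert len(detect_disulfides(m, cutoff=4.0)) == 1

    def test_no_cysteines(self, six_layer_stack):
        assert detect_disulfides(six_layer_stack) == []

    def test_per_layer_count_invariant_under_expansion(self):
        """A layer with one bridge expands to n layers with n intra-chain bridges."""
        layer = _cys_layer().layers[0]
        stack = apply_symmetry(layer, HelicalParams(-1.4, 20.0), 9)
        bonds = detect_disulfides(stack)
        assert len(bonds) == 9
        assert all(b.intra_chain for b in bonds)

    def test_missing_sg_warns(self):
        m = make_point_model([("CA", "C", "CYS", 1, (0, 0, 0))])
        with pytest.warns(UserWarning, match="SG"):
            assert detect_disulfides(m) == []


def _brute_force_contacts(model, center, cutoff):
    cpts = [a.xyz for a in model.layer(center).heavy_atoms()]
    out = {}
    for lay in model.layers:
        if lay.layer_index == center:
            continue
        n = 0
        mind = np.inf
        for a in lay.heavy_atoms():
            for c in cpts:
                d = float(np.linalg.norm(a.xyz - c))
                if d <= cutoff:
                    n += 1
                    mind = min(mind, d)
        if n:
            out[lay.layer_index] = (n, mind)
    return out


class TestLayerContacts:
    def test_matches_brute_force(self):
        """Spatial-index contact counting equals exhaustive pair enumeration."""
        model = make_fibril(GeneratorSpec(sequence=20, n_layers=5, rise=4.8,
                                          noise_sigma=0.3, seed=7))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            edges = layer_contacts(model, 2, cutoff=4.5)
        truth = _brute_force_contacts(model, 2, 4.5)
        assert {e.layer_j for e in edges} == set(truth)
        for e in edges:
            n, mind = truth[e.layer_j]
            assert e.n_atom_pairs == n
            assert e.min_distance == pytest.approx(mind)

    def test_well_separated_layers_touch_neighbors_only(self):
        """Flat compact layers at rise 20 A contact at most the adjacent layers."""
        model = make_fibril(GeneratorSpec(sequence=12, n_layers=5, rise=20.0, twist=0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            edges = layer_contacts(model, 2, cutoff=4.5)
        assert {e.layer_j for e in edges} <= {1, 3}

    def test_single_layer_empty(self):
        model = make_fibril(GeneratorSpec(sequence=12, n_layers=1))
        assert layer_contacts(model, 0) == []

    def test_contact_graph_symmetric(self):
        model = make_fibril(GeneratorSpec(sequence=16, n_layers=6, seed=2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adj = {i: {e.layer_j for e in layer_contacts(model, i)} for i in range(6)}
        for i, j in itertools.permutations(range(6), 2):
            assert (j in adj[i]) == (i in adj[j])

    def test_edge_layer_warns(self):
        model = make_fibril(GeneratorSpec(sequence=16, n_layers=4))
        with pytest.warns(UserWarning, match="edge"):
            layer_contacts(model, 0)


class TestIonPairs:
    def test_asp_arg_within_cutoff(self):
        m = make_point_model(
            [
                ("OD1", "O", "ASP", 1, (0, 0, 0)),
                ("OD2", "O", "ASP", 1, (-1.0, 1.0, 0)),
                ("NH1", "N", "ARG", 2, (3.0, 0, 0)),
            ]
        )
        pairs = find_ion_pairs(m)
        assert len(pairs) == 1
        assert pairs[0].acidic[2] == "ASP" and pairs[0].basic[2] == "ARG"
        assert pairs[0].distance == pytest.approx(3.0)
        assert pairs[0].same_layer

    def test_asp_his_counts_as_pair(self):
        """His imidazole N pairs with carboxylate O (buried Asp-His geometry)."""
        m = make_point_model(
            [("OD1", "O", "ASP", 67, (0, 0, 0)), ("NE2", "N", "HIS", 78, (3.5, 0, 0))]
        )
        pairs = find_ion_pairs(m)
        assert len(pairs) == 1
        assert {pairs[0].acidic[1], pairs[0].basic[1]} == {67, 78}

    def test_beyond_cutoff_excluded(self):
        m = make_point_model(
            [("OD1", "O", "ASP", 1, (0, 0, 0)), ("NH1", "N", "ARG", 2, (5.5, 0, 0))]
        )
        assert find_ion_pairs(m) == []

    def test_cross_layer_annotation(self):
        a = make_point_model(
            [("OD1", "O", "ASP", 53, (0, 0, 0))], chain_id="A"
        ).layers[0]
        b = make_point_model(
            [("NH1", "N", "ARG", 41, (0, 0, 3.0))], chain_id="B"
        ).layers[0]
        a.layer_index, b.layer_index = 0, 1
        pairs = find_ion_pairs(FibrilModel([a, b]))
        assert len(pairs) == 1
        assert not pairs[0].same_layer

    def test_all_ala_empty(self, six_layer_stack):
        m = make_point_model([("CB", "C", "ALA", i, (4.0 * i, 0, 0)) for i in range(1, 6)])
        assert find_ion_pairs(m) == []


class TestHydrophobicClusters:
    def test_chain_of_three_leucines(self):
        m = make_point_model(
            [("CD1", "C", "LEU", i, (4.0 * (i - 1), 0, 0)) for i in (1, 2, 3)]
        )
        clusters = hydrophobic_clusters(m, cutoff=5.0, min_size=3)
        assert clusters == [{("A", 1), ("A", 2), ("A", 3)}]

    def test_distant_residues_no_cluster(self):
        m = make_point_model(
            [("CD1", "C", "LEU", i, (10.0 * i, 0, 0)) for i in (1, 2, 3)]
        )
        assert hydrophobic_clusters(m) == []

    def test_polar_residues_excluded(self):
        m = make_point_model(
            [("OG", "O", "SER", 1, (0, 0, 0)),
             ("CD1", "C", "LEU", 2, (3, 0, 0)),
             ("CD1", "C", "LEU", 3, (6, 0, 0)),
             ("CG", "C", "LEU", 4, (9, 0, 0))]
        )
        clusters = hydrophobic_clusters(m, min_size=3)
        assert clusters == [{("A", 2), ("A", 3), ("A", 4)}]

    def test_matches_brute_force_components(self):
        """Union-find clustering equals brute-force graph components."""
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 25, size=(30, 3))
        m = make_point_model(
            [("CD1", "C", "LEU", i + 1, tuple(p)) for i, p in enumerate(pts)]
        )
        clusters = hydrophobic_clusters(m, cutoff=5.0, min_size=1)
        # brute force: adjacency + BFS
        adj = {i: set() for i in range(30)}
        for i in range(30):
            for j in range(i + 1, 30):
                if np.linalg.norm(pts[i] - pts[j]) <= 5.0:
                    adj[i].add(j)
                    adj[j].add(i)
        seen, comps = set(), []
        for i in range(30):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k] - comp)
            seen |= comp
            comps.append({("A", k + 1) for k in comp})
        assert sorted(map(sorted, clusters)) == sorted(map(sorted, comps))


class TestExposure:
    def test_isolated_residue_is_exposed(self):
        m = make_point_model(
            [("N", "N", "ALA", 1, (-1.45, 0, 0)), ("CA", "C", "ALA", 1, (0, 0, 0)),
             ("C", "C", "ALA", 1, (1.5, 0, 0)), ("O", "O", "ALA", 1, (2.0, 1.1, 0)),
             ("CB", "C", "ALA", 1, (0, 1.2, 1.0))]
        )
        res = classify_exposure(m, 1)
        assert res.label == "exposed"
        assert res.relative_sasa > 0.9

    def test_caged_residue_is_buried(self):
        """A residue enclosed in a tight shell of atoms has ~zero SASA."""
        n = 120
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        th = np.pi * (1 + 5**0.5) * i
        cage = 4.5 * np.column_stack(
            [np.cos(th) * np.sin(phi), np.sin(th) * np.sin(phi), np.cos(phi)]
        )
        specs = [("CA", "C", "ALA", 1, (0.0, 0.0, 0.0))]
        specs += [("C", "C", "GLY", k + 2, tuple(p)) for k, p in enumerate(cage)]
        m = make_point_model(specs)
        res = classify_exposure(m, 1)
        assert res.label == "buried"
        assert res.relative_sasa < 0.02

    def test_shrake_rupley_matches_biotite(self):
        """Our Shrake-Rupley agrees with an independent SASA implementation."""
        import biotite.structure as struc

        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 12, size=(40, 3))
        radii = np.full(40, vdw_radius("C"))
        ours = shrake_rupley(coords, radii, probe=1.4, n_points=960)
        arr = struc.AtomArray(40)
        arr.coord = coords.astype(np.float32)
        arr.atom_name = np.array(["C"] * 40)
        arr.element = np.array(["C"] * 40)
        arr.res_id = np.arange(1, 41)
        arr.res_name = np.array(["ALA"] * 40)
        arr.chain_id = np.array(["A"] * 40)
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=radii)
        assert np.sum(ours) == pytest.approx(np.sum(theirs), rel=0.02)
        assert np.abs(ours - theirs).max() < 0.05 * max(ours.max(), 1.0)
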