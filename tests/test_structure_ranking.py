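import numpy as np
import pytest

import hdxamend as hx
from hdxamend.structure_ranking import (
    DecoySet,
    Structure,
    backbone_rmsd,
    label_decoys,
    make_synthetic_structure,
    perturb_decoys,
    protection_from_structure,
    rank_and_auc,
    read_structure,
    write_structure,
)

SEQ40 = "AKVLGSTIEDMNQRHWYFCAAKVLGSTIEDMNQRHWYFCA"


@pytest.fixture(scope="module")
def helix_hairpin():
    return make_synthetic_structure(SEQ40, "ref")


def extended_chain(n=10):
    """Straight chain with 10 A between residues: nothing within any cutoff."""
    names, resi, resn, xyz, elem = [], [], [], [], []
    for i in range(n):
        base = np.array([10.0 * i, 0.0, 0.0])
        for j, name in enumerate(("N", "CA", "C", "O")):
            names.append(name)
            resi.append(i + 1)
            resn.append("ALA")
            xyz.append(base + [j * 1.2, 0.0, 0.0])
            elem.append(name[0])
    return Structure("ext", np.array(names), np.array(resi), np.array(resn),
                     np.array(xyz), np.array(elem))


class TestProtectionFromStructure:
    def test_isolated_chain_has_zero_lnp(self):
        prof = protection_from_structure(extended_chain())
        ok = ~prof.mask
        assert np.all(prof.lnp[ok] == 0.0)

    def test_beta_linearity(self, helix_hairpin):
        a = protection_from_structure(helix_hairpin, 0.35, 2.0)
        b = protection_from_structure(helix_hairpin, 0.70, 4.0)
        ok = ~a.mask
        assert np.allclose(b.lnp[ok], 2.0 * a.lnp[ok])

    def test_hand_built_contact_and_hbond_counts(self):
        """4-residue toy with one placed contact atom and one N...O pair;
        counts verified by brute-force pairwise distance enumeration."""
        s = extended_chain(4)
        # move residue 4's O within both cutoffs of residue 2's amide N
        n2 = s.coords[(s.res_indices == 2) & (s.atom_names == "N")][0]
        idx = np.flatnonzero((s.res_indices == 4) & (s.atom_names == "O"))[0]
        coords = s.coords.copy()
        coords[idx] = n2 + np.array([2.0, 0.0, 0.0])
        toy = s.with_coords(coords, "toy")
        bc, bh = 0.35, 2.0
        prof = protection_from_structure(toy, bc, bh, contact_cutoff=6.5,
                                         hbond_cutoff=2.4)
        # brute force: count heavy atoms within 6.5 A of each amide N
        for i in (1, 2, 3):  # residues 2-4 (0-based)
            n_pos = toy.coords[(toy.res_indices == i + 1) & (toy.atom_names == "N")][0]
            keep = np.abs(toy.res_indices - (i + 1)) > 1
            d = np.linalg.norm(toy.coords[keep] - n_pos, axis=1)
            n_c = int(np.sum(d <= 6.5))
            o_mask = keep & (toy.atom_names == "O")
            d_o = np.linalg.norm(toy.coords[o_mask] - n_pos, axis=1)
            n_h = int(np.sum(d_o <= 2.4))
            assert prof.lnp[i] == pytest.approx(bc * n_c + bh * n_h)
        assert prof.lnp[1] == pytest.approx(bc * 1 + bh * 1)  # the placed O

    def test_pdb_round_trip(self, tmp_path, helix_hairpin):
        path = tmp_path / "ref.pdb"
        write_structure(helix_hairpin, path)
        back = read_structure(path)
        assert back.sequence == SEQ40
        assert np.allclose(back.coords, helix_hairpin.coords, atol=1e-2)


class TestBackboneRmsd:
    def test_identity(self, helix_hairpin):
        assert backbone_rmsd(helix_hairpin, helix_hairpin) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed(self, helix_hairpin):
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = helix_hairpin.with_coords(helix_hairpin.coords @ R.T + [5, -3, 8], "m")
        assert backbone_rmsd(helix_hairpin, moved) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, helix_hairpin):
        decoy = perturb_decoys(helix_hairpin, 2, [0.0, 2.0], seed=1).structures[1]
        assert backbone_rmsd(helix_hairpin, decoy) == pytest.approx(
            backbone_rmsd(decoy, helix_hairpin), abs=1e-9)

    def test_matches_rotation_grid_search(self):
        """Optimal superposition beats (to tolerance) a brute-force search
        over sampled rotations about z after centroid alignment."""
        toy = extended_chain(3)
        rng = np.random.default_rng(2)
        noisy = toy.with_coords(toy.coords + rng.normal(0, 0.3, toy.coords.shape), "n")
        got = backbone_rmsd(toy, noisy)
        x = toy.backbone_coords()
        y = noisy.backbone_coords()
        xc, yc = x - x.mean(0), y - y.mean(0)
        best = np.inf
        for theta in np.linspace(0, 2 * np.pi, 3600, endpoint=False):
            R = np.array([[np.cos(theta), -np.sin(theta), 0],
                          [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
            best = min(best, np.sqrt(np.mean(np.sum((xc - yc @ R.T) ** 2, axis=1))))
        # full 3-D superposition can only do better than the z-axis grid
        assert got <= best + 1e-9

    def test_size_mismatch_raises(self, helix_hairpin):
        with pytest.raises(hx.AlignmentError):
            backbone_rmsd(helix_hairpin, extended_chain(10))


class TestLabels:
    def test_reference_among_decoys_is_native(self, helix_hairpin):
        decoys = perturb_decoys(helix_hairpin, 3, [0.0, 1.0, 4.0], seed=3)
        label_decoys(decoys)
        assert decoys.labels[0]
        assert decoys.rmsd[0] == pytest.approx(0.0, abs=1e-9)

    def test_threshold_is_strict(self, helix_hairpin):
        decoys = perturb_decoys(helix_hairpin, 2, [0.0, 1.0], seed=4)
        decoys.rmsd = np.array([2.5, 1.0])
        decoys.labels = decoys.rmsd < 2.5
        assert not decoys.labels[0] and decoys.labels[1]

    def test_label_counts_on_controlled_perturbations(self, helix_hairpin):
        decoys = perturb_decoys(helix_hairpin, 5, [0.0, 0.5, 1.0, 4.0, 5.0], seed=5)
        label_decoys(decoys)
        assert np.array_equal(decoys.labels, decoys.rmsd < 2.5)
        assert decoys.labels[0] and not decoys.labels[-1]


class TestAuc:
    def test_perfect_separation(self):
        from sklearn.metrics import roc_auc_score
        labels = np.array([True, True, False, False])
        scores = np.array([0.01, 0.02, 0.3, 0.4])
        assert roc_auc_score(labels, -scores) == 1.0

    def test_shuffled_labels_null(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(6)
        scores = rng.uniform(0, 1, 50)
        labels = np.array([True] * 20 + [False] * 30)
        aucs = []
        for _ in range(2000):
            rng.shuffle(labels)
            aucs.append(roc_auc_score(labels, -scores))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)

    def test_auc_equals_pair_counting(self, helix_hairpin):
        """AUC from the ranking equals the brute-force fraction of correctly
        ordered (native, non-native) pairs on a 10-decoy set."""
        decoys = perturb_decoys(helix_hairpin, 10, np.linspace(0, 5, 10), seed=7)
        label_decoys(decoys)
        cond = hx.ExchangeConditions(7.0, 293.15)
        rates = hx.compute_kint(SEQ40, cond)
        pmap = hx.generate_peptide_map(SEQ40, seed=8, n_peptides=15)
        prof = protection_from_structure(helix_hairpin)
        ref_uptake = hx.simulate_dataset(pmap, prof, rates,
                                         [15.0, 600.0, 3600.0, 28800.0])
        decoys, auc, roc = rank_and_auc(ref_uptake, decoys, rates)
        nat = decoys.scores[decoys.labels]
        non = decoys.scores[~decoys.labels]
        wins = sum((a < b) + 0.5 * (a == b) for a in nat for b in non)
        assert auc == pytest.approx(wins / (len(nat) * len(non)), abs=1e-9)
        assert roc.shape[1] == 2

    def test_auc_invariant_under_monotone_transform(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(9)
        scores = rng.uniform(0.01, 1, 30)
        labels = rng.uniform(size=30) < 0.4
        a = roc_auc_score(labels, -scores)
        b = roc_auc_score(labels, -np.log(scores))
        assert a == pytest.approx(b, abs=1e-12)


class TestPerturbDecoys:
    def test_zero_scale_duplicates_reference(self, helix_hairpin):
        decoys = perturb_decoys(helix_hairpin, 2, [0.0, 1.0], seed=10)
        assert np.allclose(decoys.structures[0].coords, helix_hairpin.coords)

    def test_rmsd_grows_with_scale_on_average(self, helix_hairpin):
        decoys = perturb_decoys(helix_hairpin, 30, seed=11)
        label_decoys(decoys)
        scales = decoys.meta["scales"]
        slope = np.polyfit(scales, decoys.rmsd, 1)[0]
        assert slope > 0

    def test_seeded_determinism(self, helix_hairpin):
        a = perturb_decoys(helix_hairpin, 4, seed=12)
        b = perturb_decoys(helix_hairpin, 4, seed=12)
        for sa, sb in zip(a.structures, b.structures):
            assert np.array_equal(sa.coords, sb.coords)
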