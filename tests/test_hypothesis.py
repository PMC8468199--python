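"""Common-feature enumeration and receptor-derived pharmacophores."""

import itertools

import numpy as np
import pytest

from pharmscreen.chem import FeatureKind, Hypothesis, PharmacophoreFeature, \
    rigid_transform_features
from pharmscreen.geometry import random_rotation
from pharmscreen.hypothesis import (
    GenerationConfig,
    InteractionGeometryRules,
    TrainingMember,
    TrainingSetSpec,
    classify_contacts,
    derive_receptor_hypothesis,
    enumerate_common_pharmacophores,
    rank_score,
)
from pharmscreen import synthetic as syn
from pharmscreen.chem import Atom, Molecule3D


def _feat(kind, xyz, tol=1.0):
    return PharmacophoreFeature(kind=kind, centroid=tuple(map(float, xyz)),
                                tolerance=tol)


def _training_set(spec):
    lib = syn.gen_planted_library(spec)
    return TrainingSetSpec(members=[
        TrainingMember(id=c.id, conformers=c.conformers, principal=2,
                       max_omit=0)
        for c in lib
    ])


class TestEnumeration:
    def test_single_member_self_maps_direct(self):
        spec = syn.PlantedPharmacophoreSpec(jitter_sd=0.0, n_actives=1,
                                            tolerance=1.0, seed=0)
        ts = _training_set(spec)
        results = enumerate_common_pharmacophores(
            ts, GenerationConfig(match_tolerance=1.0, min_features=4,
                                 max_features=4)
        )
        assert results
        for h, rep in results:
            assert rep.direct_hit_string == "1"
            assert rep.partial_hit_string == "0"

    def test_planted_arrangement_recovered(self):
        spec = syn.PlantedPharmacophoreSpec(
            jitter_sd=0.2, n_actives=4, n_extra_features=2,
            tolerance=1.0, seed=7,
        )
        ts = _training_set(spec)
        results = enumerate_common_pharmacophores(
            ts, GenerationConfig(match_tolerance=1.0, min_features=4,
                                 max_features=4)
        )
        top = results[0][0]
        planted = syn.planted_hypothesis(spec)
        assert sorted(f.kind.value for f in top.features) == \
            sorted(f.kind.value for f in planted.features)
        # all kinds distinct -> match features by kind and compare geometry
        tmap = {f.kind: f.xyz for f in top.features}
        pmap = {f.kind: f.xyz for f in planted.features}
        for a, b in itertools.combinations(pmap, 2):
            d_top = np.linalg.norm(tmap[a] - tmap[b])
            d_pl = np.linalg.norm(pmap[a] - pmap[b])
            assert abs(d_top - d_pl) <= 0.5

    def test_agrees_with_brute_force_retention(self):
        """The clique-based retention matches exhaustive correspondence
        enumeration on a small instance (the defining equivalence)."""
        spec = syn.PlantedPharmacophoreSpec(
            jitter_sd=0.15, n_actives=3, n_extra_features=1,
            tolerance=1.0, seed=3,
        )
        lib = syn.gen_planted_library(spec)
        members = [c.conformers[0] for c in lib]
        tol = 1.0
        size = 4

        def maps_brute(candidate, feats):
            cpts = np.array([f.xyz for f in candidate])
            ckinds = [f.kind for f in candidate]
            for perm in itertools.permutations(range(len(feats)), len(candidate)):
                if any(feats[j].kind is not ckinds[i]
                       for i, j in enumerate(perm)):
                    continue
                ok = True
                for i in range(len(candidate)):
                    for j in range(i + 1, len(candidate)):
                        dc = np.linalg.norm(cpts[i] - cpts[j])
                        dl = np.linalg.norm(feats[perm[i]].xyz -
                                            feats[perm[j]].xyz)
                        if abs(dc - dl) > tol:
                            ok = False
                            break
                    if not ok:
                        break
                if ok:
                    return True
            return False

        ref_feats = members[0]
        brute_retained = set()
        for subset in itertools.combinations(range(len(ref_feats)), size):
            cand = [ref_feats[i] for i in subset]
            if all(maps_brute(cand, m) for m in members):
                brute_retained.add(
                    tuple(sorted(f.kind.value for f in cand))
                )

        ts = _training_set(spec)
        results = enumerate_common_pharmacophores(
            ts, GenerationConfig(match_tolerance=tol, min_features=size,
                                 max_features=size, max_hypotheses=100)
        )
        pkg_retained = {
            tuple(sorted(f.kind.value for f in h.features))
            for h, _ in results
        }
        assert pkg_retained == brute_retained

    def test_geometry_error_shrinks_with_jitter(self):
        """Recovered geometry converges to the planted one as jitter -> 0
        (averaged over seeds)."""
        def mean_err(jitter):
            errs = []
            for seed in range(8):
                spec = syn.PlantedPharmacophoreSpec(
                    jitter_sd=jitter, n_actives=4, tolerance=1.0, seed=seed
                )
                ts = _training_set(spec)
                res = enumerate_common_pharmacophores(
                    ts, GenerationConfig(match_tolerance=1.0, min_features=4,
                                         max_features=4)
                )
                top = res[0][0]
                planted = syn.planted_hypothesis(spec)
                tmap = {f.kind: f.xyz for f in top.features}
                pmap = {f.kind: f.xyz for f in planted.features}
                errs.append(np.mean([
                    abs(np.linalg.norm(tmap[a] - tmap[b]) -
                        np.linalg.norm(pmap[a] - pmap[b]))
                    for a, b in itertools.combinations(pmap, 2)
                ]))
            return np.mean(errs)

        errs = [mean_err(j) for j in (0.05, 0.1, 0.2)]
        assert errs[0] < errs[1] < errs[2]

    def test_max_hypotheses_and_feature_bounds_respected(self):
        spec = syn.PlantedPharmacophoreSpec(
            jitter_sd=0.1, n_actives=3, n_extra_features=3,
            tolerance=1.0, seed=5,
        )
        ts = _training_set(spec)
        cfg = GenerationConfig(match_tolerance=1.0, min_features=3,
                               max_features=4, max_hypotheses=10)
        results = enumerate_common_pharmacophores(ts, cfg)
        assert len(results) <= 10
        for h, _ in results:
            assert 3 <= h.max_fit <= 4
            h.validate()

    def test_no_principal_member_is_error(self):
        spec = syn.PlantedPharmacophoreSpec(jitter_sd=0.0, n_actives=2, seed=0)
        lib = syn.gen_planted_library(spec)
        with pytest.raises(ValueError, match="principal"):
            TrainingSetSpec(members=[
                TrainingMember(id=c.id, conformers=c.conformers, principal=1)
                for c in lib
            ])

    def test_featureless_member_is_hard_error(self):
        with pytest.raises(ValueError, match="perception"):
            TrainingMember(id="empty", conformers=[[]])


class TestRankScore:
    def test_unmappable_hypothesis_scores_zero(self):
        spec = syn.PlantedPharmacophoreSpec(jitter_sd=0.0, n_actives=3, seed=0)
        ts = _training_set(spec)
        far = Hypothesis(id="far", features=[
            _feat(FeatureKind.NI, (0, 0, 0)),
            _feat(FeatureKind.NI, (30, 0, 0)),
            _feat(FeatureKind.NI, (0, 30, 0)),
            _feat(FeatureKind.NI, (0, 0, 30)),
        ], provenance="ligand_based")
        assert rank_score(far, ts, GenerationConfig()) == 0.0

    def test_perfect_self_map_scores_members_times_features(self):
        m, k = 3, 4
        spec = syn.PlantedPharmacophoreSpec(jitter_sd=0.0, n_actives=m, seed=0)
        ts = _training_set(spec)
        h = syn.planted_hypothesis(spec)
        assert rank_score(h, ts, GenerationConfig()) == pytest.approx(m * k)

    def test_full_arrangement_outranks_sub_hypothesis(self):
        spec = syn.PlantedPharmacophoreSpec(jitter_sd=0.0, n_actives=3, seed=0)
        ts = _training_set(spec)
        full = syn.planted_hypothesis(spec)
        sub = Hypothesis(id="sub", features=full.features[:3],
                         provenance="ligand_based")
        cfg = GenerationConfig()
        assert rank_score(full, ts, cfg) > rank_score(sub, ts, cfg)


class TestReceptorHypothesis:
    def test_distant_ligand_gives_empty_hypothesis(self):
        lig = Molecule3D(id="lig", atoms=[
            Atom("N", (0.0, 0.0, 0.0)), Atom("H", (0.0, 1.0, 0.0)),
        ], bonds=[(0, 1, 1.0)])
        rec = Molecule3D(id="rec", atoms=[Atom("O", (0.0, 20.0, 0.0))])
        h = derive_receptor_hypothesis(rec, lig)
        assert h.features == [] and h.provenance == "structure_based"

    def test_angled_hbond_detected(self):
        """Ligand N-H aimed at a carbonyl O: 2.9 Å heavy-atom distance,
        165 deg donor angle -> exactly one HBD feature on the N."""
        n = np.array([0.0, 0.0, 0.0])
        h_at = np.array([0.0, 1.0, 0.0])
        # ray from H making a 165 deg angle with the H->N direction
        direction = np.array([np.sin(np.radians(15.0)),
                              np.cos(np.radians(15.0)), 0.0])
        lo, hi = 0.0, 5.0
        for _ in range(60):  # bisect on distance along the angled ray from H
            mid = 0.5 * (lo + hi)
            o = h_at + mid * direction
            if np.linalg.norm(o - n) < 2.9:
                lo = mid
            else:
                hi = mid
        o = h_at + 0.5 * (lo + hi) * direction
        lig = Molecule3D(id="lig", atoms=[
            Atom("N", tuple(n)), Atom("H", tuple(h_at)),
        ], bonds=[(0, 1, 1.0)])
        rec = Molecule3D(id="rec", atoms=[
            Atom("O", tuple(o)),
            Atom("C", tuple(o + np.array([0.0, 1.23, 0.0]))),
        ], bonds=[(0, 1, 2.0)])
        feats = derive_receptor_hypothesis(rec, lig).features
        assert [f.kind for f in feats] == [FeatureKind.HBD]
        assert feats[0].source_atoms == (0,)

    def test_table_shaped_contact_request(self):
        rec, lig = syn.gen_toy_complex([
            "hbond_acceptor", "hbond_acceptor", "hbond_donor",
            "hydrophobic", "hydrophobic", "hydrophobic",
        ])
        h = derive_receptor_hypothesis(rec, lig)
        assert sorted(f.kind.value for f in h.features) == \
            ["HBA", "HBA", "HBD", "HYP", "HYP", "HYP"]
        h.validate()

    def test_joint_rigid_invariance(self, rng):
        rec, lig = syn.gen_toy_complex(["hbond_donor", "hydrophobic",
                                        "aromatic_stack"])
        h0 = derive_receptor_hypothesis(rec, lig)
        R = random_rotation(rng)
        t = rng.uniform(-7, 7, 3)

        def move(mol):
            atoms = [
                Atom(element=a.element,
                     coords=tuple(float(x) for x in R @ np.array(a.coords) + t),
                     formal_charge=a.formal_charge, aromatic=a.aromatic,
                     res_name=a.res_name, res_id=a.res_id)
                for a in mol.atoms
            ]
            return Molecule3D(id=mol.id, atoms=atoms, bonds=list(mol.bonds))

        h1 = derive_receptor_hypothesis(move(rec), move(lig))
        assert [f.kind for f in h0.features] == [f.kind for f in h1.features]
        for a, b in zip(h0.features, h1.features):
            assert np.allclose(R @ a.xyz + t, b.xyz, atol=1e-9)

    def test_missing_coordinates_guarded_by_types(self):
        with pytest.raises(ValueError):
            Molecule3D(id="bad", atoms=[Atom("C", (np.nan, 0.0, 0.0))])


class TestClassifyContacts:
    def test_single_hbond_complex(self):
        rec, lig = syn.gen_toy_complex(["hbond_donor"])
        tab = classify_contacts(rec, lig)
        assert (tab["contact_class"] == "hydrogen_bond").sum() == 1
        assert len(tab) == 1

    def test_empty_complex(self):
        rec, lig = syn.gen_toy_complex([])
        assert classify_contacts(rec, lig).empty

    def test_small_apolar_contact_never_hydrogen_bond(self):
        # lone CH3 carbon 3.8 Å from a receptor CH2: below the minimum
        # cluster size, so vdW, and under no rule a hydrogen bond
        lig = Molecule3D(id="lig", atoms=[
            Atom("C", (0.0, 0.0, 0.0)),
            Atom("H", (0.6, 0.8, 0.0)), Atom("H", (-0.6, 0.8, 0.0)),
            Atom("H", (0.0, -1.0, 0.2)),
        ], bonds=[(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])
        rec = Molecule3D(id="rec", atoms=[
            Atom("C", (3.8, 0.0, 0.0), res_name="LEU", res_id=5),
            Atom("H", (4.4, 0.8, 0.0)),
        ], bonds=[(0, 1, 1.0)])
        tab = classify_contacts(rec, lig)
        classes = set(tab["contact_class"])
        assert classes == {"van_der_waals"}

    def test_aromatic_stack_detected_with_priority(self):
        rec, lig = syn.gen_toy_complex(["aromatic_stack"])
        tab = classify_contacts(rec, lig)
        assert "aromatic_stack" in set(tab["contact_class"])
        # stacked ring pairs are consumed: no hydrophobic double count
        assert "hydrophobic" not in set(tab["contact_class"])

    def test_priority_hbond_over_vdw(self):
        rec, lig = syn.gen_toy_complex(["hbond_donor"])
        tab = classify_contacts(rec, lig)
        # the donor-acceptor pair is within vdW range but must be classed
        # as a hydrogen bond only
        assert list(tab["contact_class"]) == ["hydrogen_bond"]
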