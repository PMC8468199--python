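"""Binding-energy aggregation, toy-system energy terms, and ranking."""

import math

import numpy as np
import pytest

from pharmscreen.energetics import (
    COULOMB_CONSTANT,
    BindingSummary,
    EnergyComponents,
    ForceFieldParams,
    NonpolarModel,
    SnapshotEnergies,
    born_polar_energy,
    delta_g,
    delta_g_components,
    lj_coulomb_energy,
    rank_candidates,
    read_snapshot_table,
    sasa,
    sum_components,
    summarize,
    write_snapshot_table,
)
from pharmscreen.synthetic import SnapshotSpec, gen_snapshots

# printed component means and dG (kJ/mol) for the six tabulated systems
ENERGY_ROWS = {
    "Hit1": ((-191.19, -309.22, 355.74, -25.34), -170.01),
    "Hit2": ((-164.36, -47.28, 128.50, -20.02), -103.17),
    "Hit3": ((-167.45, -22.27, 115.57, -20.50), -94.66),
    "Hit4": ((-147.54, -17.71, 91.10, -16.44), -90.59),
    "THZ1": ((-151.40, -22.06, 98.27, -16.29), -91.48),
    "CT7001": ((-181.13, -44.09, 154.73, -20.09), -90.58),
}


def _snap(t, comp, prot=None, lig=None):
    if prot is None:
        return SnapshotEnergies(time_ps=t,
                                interaction=EnergyComponents(*comp))
    return SnapshotEnergies(time_ps=t, complex=EnergyComponents(*comp),
                            protein=EnergyComponents(*prot),
                            ligand=EnergyComponents(*lig))


class TestDeltaG:
    def test_zero_when_complex_equals_parts(self):
        s = _snap(0.0, (1, 2, 3, 4), (0.5, 1, 2, 3), (0.5, 1, 1, 1))
        assert delta_g(s) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        s = _snap(0.0, (-10, -5, 8, -1), (-4, -2, 3, 0), (-1, -1, 1, 0))
        assert delta_g_components(s).as_array() == pytest.approx([-5, -2, 4, -1])
        assert delta_g(s) == pytest.approx(-4.0)

    def test_linear_in_scaling(self):
        s1 = _snap(0.0, (-10, -5, 8, -1), (-4, -2, 3, 0), (-1, -1, 1, 0))
        s3 = _snap(0.0, (-30, -15, 24, -3), (-12, -6, 9, 0), (-3, -3, 3, 0))
        assert delta_g(s3) == pytest.approx(3 * delta_g(s1))

    def test_mixed_representation_is_error(self):
        series = [_snap(0.0, (1, 1, 1, 1)),
                  _snap(1.0, (1, 1, 1, 1), (0, 0, 0, 0), (0, 0, 0, 0))]
        with pytest.raises(ValueError, match="mixed"):
            summarize(series, window=(0.0, 1.0))


class TestSummarize:
    def test_constant_series(self):
        series = [_snap(float(t), (-5, -3, 7, -1)) for t in range(10)]
        s = summarize(series, window=(0, 9))
        assert s.sd.as_array() == pytest.approx([0, 0, 0, 0])
        assert s.dg_mean == pytest.approx(-2.0)
        assert s.dg_sd == 0.0

    def test_window_excludes_early_frames(self):
        series = [_snap(float(t), (t, 0, 0, 0)) for t in range(10)]
        s = summarize(series, window=(5, 9))
        assert s.n == 5
        assert s.mean.vdw == pytest.approx(7.0)

    def test_default_window_is_final_10ns(self):
        series = [_snap(t * 1000.0, (1, 1, 1, 1)) for t in range(51)]
        s = summarize(series)
        assert s.n == 11  # 40-50 ns inclusive

    def test_empty_window_is_error(self):
        series = [_snap(float(t), (1, 1, 1, 1)) for t in range(5)]
        with pytest.raises(ValueError):
            summarize(series, window=(100.0, 200.0))

    def test_gaussian_recovery_within_sampling_error(self):
        spec = SnapshotSpec(seed=12)
        s = summarize(gen_snapshots(spec))
        mu = sum(m for m, _ in spec.moments.values())
        sd = math.sqrt(sum(v**2 for _, v in spec.moments.values()))
        assert abs(s.dg_mean - mu) < 3 * sd / math.sqrt(spec.n)

    def test_mean_of_dg_equals_dg_of_means(self):
        """delta_g and summarize commute (linearity, exact)."""
        series = gen_snapshots(SnapshotSpec(seed=3))
        s = summarize(series)
        per_snapshot = np.mean([delta_g(x) for x in series])
        assert s.dg_mean == pytest.approx(per_snapshot, abs=1e-9)


class TestSumComponents:
    @pytest.mark.parametrize("name", sorted(ENERGY_ROWS))
    def test_component_sum_matches_tabulated_dg(self, name):
        comps, dg = ENERGY_ROWS[name]
        assert sum_components(EnergyComponents(*comps)) == \
            pytest.approx(dg, abs=0.02)

    def test_exact_rows(self):
        assert sum_components(EnergyComponents(*ENERGY_ROWS["Hit1"][0])) == \
            pytest.approx(-170.01, abs=1e-9)
        assert sum_components(EnergyComponents(*ENERGY_ROWS["THZ1"][0])) == \
            pytest.approx(-91.48, abs=1e-9)


class TestLJCoulomb:
    def test_single_atom_is_zero(self):
        v, e = lj_coulomb_energy(np.zeros((1, 3)),
                                 ForceFieldParams([1.0], [3.0], [0.5]))
        assert (v, e) == (0.0, 0.0)

    def test_lj_minimum_closed_form(self):
        sigma, eps = 3.0, 0.5
        r = 2 ** (1 / 6) * sigma
        v, _ = lj_coulomb_energy(
            np.array([[0, 0, 0], [r, 0, 0]], float),
            ForceFieldParams([0, 0], [sigma, sigma], [eps, eps]),
        )
        assert v == pytest.approx(-eps, abs=1e-12)

    def test_coulomb_closed_form_at_1nm(self):
        _, e = lj_coulomb_energy(
            np.array([[0, 0, 0], [10.0, 0, 0]]),
            ForceFieldParams([1.0, 1.0], [0, 0], [0, 0]),
        )
        assert e == pytest.approx(COULOMB_CONSTANT, abs=1e-3)

    def test_bonded_exclusions(self):
        coords = np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]], float)
        params = ForceFieldParams([1, 1, 1], [0, 0, 0], [0, 0, 0])
        _, e = lj_coulomb_energy(coords, params, bonds=[(0, 1), (1, 2)])
        assert e == 0.0  # 1-2 and 1-3 all excluded

    def test_missing_params_is_error(self):
        with pytest.raises(ValueError):
            lj_coulomb_energy(np.zeros((2, 3)),
                              ForceFieldParams([1.0], [3.0], [0.5]))

    def test_agrees_with_all_pairs_brute_force(self, rng):
        n = 40
        coords = rng.uniform(0, 15, size=(n, 3))
        params = ForceFieldParams(
            rng.uniform(-0.5, 0.5, n),
            rng.uniform(2.5, 3.5, n),
            rng.uniform(0.1, 0.8, n),
        )
        v, e = lj_coulomb_energy(coords, params, cutoff=1e9)
        bv = be = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                r = np.linalg.norm(coords[i] - coords[j])
                s = 0.5 * (params.sigma[i] + params.sigma[j])
                eps = math.sqrt(params.epsilon[i] * params.epsilon[j])
                bv += 4 * eps * ((s / r) ** 12 - (s / r) ** 6)
                be += COULOMB_CONSTANT * params.charges[i] * \
                    params.charges[j] / (r / 10.0)
        assert v == pytest.approx(bv, abs=1e-9)
        assert e == pytest.approx(be, abs=1e-9)


def _two_sphere_analytic(r1, r2, d, probe):
    """Accessible area of two overlapping solvent-extended spheres."""
    e1, e2 = r1 + probe, r2 + probe
    if d >= e1 + e2:
        return 4 * math.pi * (e1**2 + e2**2)
    h1 = e1 - (d**2 + e1**2 - e2**2) / (2 * d)
    h2 = e2 - (d**2 + e2**2 - e1**2) / (2 * d)
    return (4 * math.pi * e1**2 - 2 * math.pi * e1 * h1 +
            4 * math.pi * e2**2 - 2 * math.pi * e2 * h2)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        areas, total, energy = sasa(
            np.zeros((1, 3)), np.array([1.5]), NonpolarModel(n_points=960)
        )
        exact = 4 * math.pi * 2.9**2
        assert total == pytest.approx(exact, rel=0.01)
        model = NonpolarModel(n_points=960)
        assert energy == pytest.approx(model.gamma * total + model.offset)

    def test_disjoint_additivity(self):
        coords = np.array([[0, 0, 0], [50, 0, 0]], float)
        radii = np.array([1.5, 1.2])
        _, total, _ = sasa(coords, radii)
        singles = sum(
            sasa(np.zeros((1, 3)), np.array([r]))[1] for r in radii
        )
        assert total == pytest.approx(singles, abs=1e-9)

    def test_total_decreases_with_overlap(self):
        radii = np.array([1.5, 1.5])
        totals = [
            sasa(np.array([[0, 0, 0], [d, 0, 0]], float), radii)[1]
            for d in (6.0, 4.0, 2.5, 1.0)
        ]
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_quadrature_convergence_halves_error(self):
        coords = np.array([[0, 0, 0], [2.5, 0, 0]], float)
        radii = np.array([1.5, 1.2])
        exact = _two_sphere_analytic(1.5, 1.2, 2.5, 1.4)
        errs = {
            n: abs(sasa(coords, radii, NonpolarModel(n_points=n))[1] - exact)
            for n in (960, 3840)
        }
        assert errs[3840] <= errs[960] / 2 + 1e-9

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), np.array([0.0]))


def test_born_polar_energy_sign_and_scale():
    # a single buried charge is stabilized by solvent screening
    e = born_polar_energy(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]))
    exact = -0.5 * COULOMB_CONSTANT * (1 - 1 / 78.5) / 0.2
    assert e == pytest.approx(exact, rel=1e-9)
    assert e < 0


class TestRanking:
    def _summaries(self):
        out = []
        for name, (comps, _) in ENERGY_ROWS.items():
            series = [
                SnapshotEnergies(time_ps=float(t),
                                 interaction=EnergyComponents(*comps))
                for t in range(4)
            ]
            out.append(summarize(series, window=(0, 3), summary_id=name))
        return out

    def test_tabulated_ordering(self):
        ranked = rank_candidates(self._summaries(),
                                 reference_ids=["CT7001", "THZ1"])
        order = [r.summary.id for r in ranked]
        # ascending dG: the second reference binds slightly tighter than Hit4
        assert order == ["Hit1", "Hit2", "Hit3", "THZ1", "Hit4", "CT7001"]

    def test_gate_uses_primary_reference_only(self):
        """A candidate between the two references passes the headline gate
        (vs the primary) while losing to the secondary."""
        ranked = rank_candidates(self._summaries(),
                                 reference_ids=["CT7001", "THZ1"])
        hit4 = next(r for r in ranked if r.summary.id == "Hit4")
        assert hit4.better_than["CT7001"] is True   # -90.59 vs -90.58
        assert hit4.better_than["THZ1"] is False    # -90.59 vs -91.48
        assert hit4.passes_gate is True

    def test_equal_dg_keeps_input_order(self):
        series = [
            SnapshotEnergies(time_ps=float(t),
                             interaction=EnergyComponents(-1, -1, 0, 0))
            for t in range(3)
        ]
        sums = [summarize(series, window=(0, 2), summary_id=f"c{i}")
                for i in range(3)]
        ranked = rank_candidates(sums, reference_ids=["c0"])
        assert [r.summary.id for r in ranked] == ["c0", "c1", "c2"]

    def test_missing_reference_is_error(self):
        with pytest.raises(ValueError, match="reference"):
            rank_candidates(self._summaries(), reference_ids=["nope"])


class TestIO:
    def test_snapshot_table_round_trip(self, tmp_path):
        series = gen_snapshots(SnapshotSpec(n=5, seed=9))
        path = tmp_path / "snaps.tsv"
        write_snapshot_table(series, path)
        back = read_snapshot_table(path)
        assert len(back) == 5
        for a, b in zip(series, back):
            assert delta_g(a) == pytest.approx(delta_g(b), abs=1e-9)

    def test_kcal_conversion(self, tmp_path):
        path = tmp_path / "snaps.tsv"
        path.write_text("time_ps\tvdw\telec\tpolar\tsasa\n0\t-1\t0\t0\t0\n")
        (s,) = read_snapshot_table(path, units="kcal/mol")
        assert s.interaction.vdw == pytest.approx(-4.184)
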