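"""RMSF profiles, B-factor conversion, distance monitors, snapshot RMSD."""

import numpy as np
import pytest

from loopdyn.demo import build_toy_receptor, demo_loop_specs
from loopdyn.ensembles import (Ensemble, SelectionMask, resolve_loops,
                               superpose)
from loopdyn.fluctuations import (B_FROM_MSF, bfactor_from_rmsf,
                                  distance_series, groove_width, rmsf,
                                  rmsf_from_bfactor, running_mean,
                                  snapshot_rmsd_matrix)
from loopdyn.synthetic import GaussianEnsembleSpec, gaussian_ensemble


def static_ensemble(n_res=5, n_frames=4):
    ens = gaussian_ensemble(
        GaussianEnsembleSpec(n_res, np.zeros(n_res), n_frames=n_frames, seed=1)
    )
    return ens


class TestRmsf:
    def test_rigid_ensemble_is_zero(self):
        ens = static_ensemble()
        prof = rmsf(ens, SelectionMask.alpha_carbons(ens.topology))
        assert np.allclose(prof.rmsf, 0.0)

    def test_two_frame_displacement_gives_half_span(self):
        ens = static_ensemble(n_frames=2)
        coords = ens.coords.copy()
        ca0 = np.where(ens.topology.atoms.atom_name == "CA")[0][0]
        coords[1, ca0, 0] += 2.0
        moved = Ensemble(ens.topology, coords)
        prof = rmsf(moved, SelectionMask.alpha_carbons(moved.topology))
        assert prof.rmsf[0] == pytest.approx(1.0)
        assert np.allclose(prof.rmsf[1:], 0.0)

    def test_invariant_under_global_rigid_motion(self, rng):
        ens = gaussian_ensemble(
            GaussianEnsembleSpec(6, np.full(6, 0.6), n_frames=500, seed=2)
        )
        mask = SelectionMask.alpha_carbons(ens.topology)
        base = rmsf(ens, mask).rmsf
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = Ensemble(ens.topology, ens.coords @ rot.T + [1.0, -2.0, 3.0])
        assert np.allclose(rmsf(moved, mask).rmsf, base, atol=1e-10)

    def test_loop_mobility_ranking_recovers_planted_sigma_order(self):
        model, _ = build_toy_receptor("A6")
        loops = resolve_loops(model, demo_loop_specs("A6"))
        n_res = len({(c, r) for c, r, _ in
                     SelectionMask.alpha_carbons(model).references})
        rng_sigma = np.full(n_res, 0.3)
        index = {ref[:2]: k for k, ref in
                 enumerate(SelectionMask.alpha_carbons(model).references)}
        planted = {"CDR3b": 1.5, "CDR3a": 0.9, "CDR1a": 0.2}
        for name, s in planted.items():
            loop = next(l for l in loops if l.name == name)
            for r in loop.res_ids:
                rng_sigma[index[(loop.chain_id, int(r))]] = s
        ens = gaussian_ensemble(GaussianEnsembleSpec(
            n_res, rng_sigma, n_frames=3000, seed=5, template=model
        ))
        mask = SelectionMask.alpha_carbons(ens.topology)
        ens = superpose(ens, mask, 0)
        prof = rmsf(ens, mask)
        by_res = dict(zip([r[:2] for r in prof.references], prof.rmsf))
        maxima = {
            l.name: max(by_res[(l.chain_id, int(r))] for r in l.res_ids)
            for l in loops
        }
        ranked = sorted(planted, key=planted.get, reverse=True)
        measured = sorted(planted, key=maxima.get, reverse=True)
        assert ranked == measured


class TestBfactorConversion:
    def test_closed_form(self):
        from loopdyn.fluctuations import FluctuationProfile

        prof = bfactor_from_rmsf(
            FluctuationProfile([("A", 1, "CA")], np.array([1.0]))
        )
        assert prof.bfactor[0] == pytest.approx(8 * np.pi**2 / 3)

    def test_round_trip_is_identity(self, rng):
        values = rng.uniform(0, 3, size=50)
        from loopdyn.fluctuations import FluctuationProfile

        prof = bfactor_from_rmsf(
            FluctuationProfile([("A", i, "CA") for i in range(50)], values)
        )
        assert np.allclose(rmsf_from_bfactor(prof.bfactor), values, atol=1e-14)

    def test_monotone_bijection(self, rng):
        x = np.sort(rng.uniform(0, 5, size=20))
        b = B_FROM_MSF * x**2
        assert np.all(np.diff(b) > 0)


class TestDistanceSeries:
    def test_constant_separation(self):
        ens = static_ensemble()
        refs = SelectionMask.alpha_carbons(ens.topology).references
        d = distance_series(ens, refs[0], refs[1])
        assert np.allclose(d.distances, d.distances[0])
        assert d.smoothed == pytest.approx(d.distances)

    def test_running_mean_window_two(self):
        x = np.array([10.0, 12.0, 10.0, 12.0, 10.0, 12.0])
        sm = running_mean(x, 2)
        # interior values average adjacent 10/12 pairs; the trailing edge
        # truncates to the lone final sample
        assert np.allclose(sm[:-1], 11.0) and sm[-1] == 12.0

    def test_oversized_window_falls_back_to_global_mean(self, caplog):
        x = np.array([10.0, 12.0])
        with caplog.at_level("WARNING"):
            sm = running_mean(x, 10)
        assert np.allclose(sm, 11.0)
        assert "window" in caplog.text

    def test_groove_width_mixture_mean(self):
        ens = static_ensemble(n_frames=4)
        coords = ens.coords.copy()
        ca = np.where(ens.topology.atoms.atom_name == "CA")[0]
        for f in range(4):
            coords[f, ca[0]] = [0.0, 0.0, 0.0]
            coords[f, ca[1]] = [13.0 if f < 2 else 15.0, 0.0, 0.0]
        moved = Ensemble(ens.topology, coords)
        d = groove_width(moved, ("A", 1), ("A", 2))
        assert d.mean == pytest.approx(14.0)

    def test_single_frame_series(self):
        ens = static_ensemble(n_frames=1)
        refs = SelectionMask.alpha_carbons(ens.topology).references
        assert len(distance_series(ens, refs[0], refs[1]).distances) == 1


class TestSnapshotRmsdMatrix:
    def test_identical_frames_give_zero_matrix(self):
        ens = static_ensemble(n_frames=3)
        mask = SelectionMask.alpha_carbons(ens.topology)
        mat = snapshot_rmsd_matrix([("sim", ens)], mask)
        assert np.allclose(mat.matrix, 0.0, atol=1e-8)

    def test_rigid_body_motions_are_removed(self, rng):
        ens = static_ensemble(n_frames=2)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        other = Ensemble(ens.topology, ens.coords @ rot.T + [4.0, 0.0, -2.0])
        mask = SelectionMask.alpha_carbons(ens.topology)
        mat = snapshot_rmsd_matrix([("a", ens), ("b", other)], mask)
        assert np.allclose(mat.matrix, 0.0, atol=1e-8)

    def test_block_means_match_brute_force(self, rng):
        ens_a = gaussian_ensemble(
            GaussianEnsembleSpec(4, np.full(4, 1.0), n_frames=2, seed=10)
        )
        ens_b = gaussian_ensemble(
            GaussianEnsembleSpec(4, np.full(4, 1.0), n_frames=2, seed=11)
        )
        mask = SelectionMask.alpha_carbons(ens_a.topology)
        mat = snapshot_rmsd_matrix([("a", ens_a), ("b", ens_b)], mask)

        from loopdyn.fluctuations import _pairwise_rmsd

        snaps = [ens_a.coords[f][mask.indices] for f in range(2)] + \
                [ens_b.coords[f][mask.indices] for f in range(2)]
        cross = np.mean([
            _pairwise_rmsd(snaps[i], snaps[j])
            for i in (0, 1) for j in (2, 3)
        ])
        got = mat.block_means
        row = got[(got.source_a == "a") & (got.source_b == "b")]
        assert row.mean_rmsd_A.iloc[0] == pytest.approx(cross)
        diag = got[(got.source_a == "a") & (got.source_b == "a")]
        assert diag.mean_rmsd_A.iloc[0] == pytest.approx(
            _pairwise_rmsd(snaps[0], snaps[1])
        )
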