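import numpy as np
import pytest

from rigidpmf import dilution_stability as ds
from rigidpmf import synthetic_data as sd
from rigidpmf.synthetic_data import PlantedBond, split_dimer_truth, stiffen_backbone


def stability_of(truth, schedule):
    return ds.stability_map(
        truth["model"], schedule, hbonds=truth["hbonds"], tethers=truth["tethers"]
    )


def dimer_difference(truth, schedule):
    dimer = stability_of(truth, schedule)
    monos = []
    for cid in ("A", "B"):
        sub, hb, te = split_dimer_truth(truth, cid)
        monos.append(ds.stability_map(sub, schedule, hbonds=hb, tethers=te))
    return ds.difference_stability_map(dimer, monos[0], monos[1])


class TestSchedule:
    def test_paper_schedule_has_sixty_states(self, schedule):
        states = schedule.states
        assert len(states) == 60
        assert states[0] == pytest.approx(-0.1)
        assert states[-1] == pytest.approx(-6.0)
        assert np.all(np.diff(states) < 0)

    @pytest.mark.parametrize("bad", [dict(step=0.0), dict(step=-0.1), dict(e_start=-6.0, e_end=-0.1)])
    def test_invalid_schedules_rejected(self, bad):
        with pytest.raises(ValueError):
            ds.DilutionSchedule(**{**dict(e_start=-0.1, e_end=-6.0, step=0.1), **bad})


class TestStabilityMap:
    def test_contact_held_by_planted_bond_vanishes_past_its_energy(self, schedule):
        _, truth = sd.toy_structure(n_res=3, planted=[PlantedBond("hbond", "A", 1, "A", 3, -2.3)])
        smap = stability_of(truth, schedule)
        i, j = smap.residues.index(("A", 1)), smap.residues.index(("A", 3))
        assert smap.status[i, j] == ds.NUMERIC
        assert smap.values[i, j] == pytest.approx(-2.4)

    def test_contact_below_dilution_end_is_persistent(self, schedule):
        _, truth = sd.toy_structure(n_res=3, planted=stiffen_backbone("A", 1, 3, energy=-8.0))
        smap = stability_of(truth, schedule)
        i, j = smap.residues.index(("A", 1)), smap.residues.index(("A", 3))
        assert smap.status[i, j] == ds.PERSISTENT

    def test_unconstrained_pair_is_never_rigid(self, schedule):
        _, truth = sd.toy_structure(n_res=4)
        smap = stability_of(truth, schedule)
        i, j = smap.residues.index(("A", 1)), smap.residues.index(("A", 4))
        assert smap.status[i, j] == ds.NEVER

    def test_no_hbonds_means_identical_states(self, schedule):
        _, truth = sd.toy_structure(n_res=3)
        decomps = ds.constraint_dilution(truth["model"], schedule, hbonds=[], tethers=[])
        first = decomps[0].labels
        assert all(np.array_equal(d.labels, first) for d in decomps)

    def test_monotone_contact_loss_along_dilution(self, schedule):
        planted = [
            PlantedBond("hbond", "A", 1, "A", 3, -1.2),
            PlantedBond("hbond", "A", 2, "A", 4, -3.7),
            PlantedBond("hbond", "A", 3, "A", 5, -5.9),
        ]
        _, truth = sd.toy_structure(n_res=5, planted=planted)
        residues, contacts = ds.contact_history(
            truth["model"], schedule, hbonds=truth["hbonds"], tethers=truth["tethers"]
        )
        # once a contact is lost it must stay lost at all deeper cutoffs
        lost = ~contacts
        assert np.all(lost[:-1] <= lost[1:])

    def test_rerun_determinism(self, schedule):
        _, truth = sd.toy_structure(n_res=4, planted=[PlantedBond("hbond", "A", 1, "A", 4, -2.0)])
        a = stability_of(truth, schedule)
        b = stability_of(truth, schedule)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.status, b.status)


class TestEnsembleAverage:
    def _map_with(self, value, status, schedule):
        residues = [("A", 1), ("A", 2)]
        vals = np.full((2, 2), value)
        stat = np.full((2, 2), status)
        np.fill_diagonal(vals, 0.0)
        np.fill_diagonal(stat, ds.PERSISTENT)
        return ds.StabilityMap(residues, vals, stat, schedule)

    def test_identical_maps_average_to_themselves(self, schedule):
        m = self._map_with(-1.5, ds.NUMERIC, schedule)
        avg = ds.ensemble_average_map([m, m])
        assert avg.values[0, 1] == pytest.approx(-1.5)

    def test_mean_of_two_values(self, schedule):
        a = self._map_with(-1.0, ds.NUMERIC, schedule)
        b = self._map_with(-3.0, ds.NUMERIC, schedule)
        assert ds.ensemble_average_map([a, b]).values[0, 1] == pytest.approx(-2.0)

    def test_never_maps_resolve_to_e_start(self, schedule):
        m = self._map_with(0.0, ds.NEVER, schedule)
        avg = ds.ensemble_average_map([m, m])
        assert avg.values[0, 1] == pytest.approx(schedule.e_start)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ds.ensemble_average_map([])


class TestDifferenceMap:
    def test_zero_interface_identical_conformations_gives_zero(self, schedule):
        _, truth = sd.toy_structure(
            n_res=5, kind="dimer",
            planted=stiffen_backbone("A", 1, 5) + stiffen_backbone("B", 1, 5),
        )
        diff = dimer_difference(truth, schedule)
        assert np.abs(diff.values).max() == 0.0

    def test_interface_bond_stabilizes_remote_pairs(self, schedule):
        planted = (
            stiffen_backbone("A", 1, 6)
            + stiffen_backbone("B", 1, 6)
            + [
                PlantedBond("hbond", "A", 6, "B", 1, -2.0),
                PlantedBond("hydrophobic", "A", 5, "B", 2, anchor="CA"),
            ]
        )
        _, truth = sd.toy_structure(n_res=6, kind="dimer", planted=planted)
        diff = dimer_difference(truth, schedule)
        res = diff.residues

        def delta(ci, ri, cj, rj):
            return diff.values[res.index((ci, ri)), res.index((cj, rj))]

        assert delta("A", 6, "B", 1) == pytest.approx(-2.1)
        # long-range percolation: remote pair, far from the interface bond
        assert delta("A", 1, "B", 6) == pytest.approx(-2.1)
        # intra-chain stability unchanged; all signal is intermolecular
        intra = [
            diff.values[i, j]
            for i, (ci, _) in enumerate(res)
            for j, (cj, _) in enumerate(res)
            if ci == cj
        ]
        assert np.abs(intra).max() == 0.0

    def test_indexing_mismatch_is_error(self, schedule):
        _, truth = sd.toy_structure(n_res=4, kind="dimer")
        dimer = stability_of(truth, schedule)
        _, t_other = sd.toy_structure(n_res=6, kind="dimer")
        sub, hb, te = split_dimer_truth(t_other, "A")
        mono = ds.stability_map(sub, schedule, hbonds=hb, tethers=te)
        with pytest.raises(ValueError):
            ds.difference_stability_map(dimer, mono, mono)


class TestDomainBlocks:
    def _constant_diff(self, value=-1.0):
        residues = [("A", i) for i in range(1, 5)] + [("B", i) for i in range(1, 5)]
        vals = np.full((8, 8), value)
        np.fill_diagonal(vals, 0.0)
        return ds.DifferenceStabilityMap(residues, vals)

    def test_constant_map_block_mean(self):
        diff = self._constant_diff(-1.0)
        domains = {"nbdA": [("A", 1, 2)], "pbdA": [("A", 3, 4)], "nbdB": [("B", 1, 2)]}
        out = ds.domain_block_summary(diff, domains)
        row = out[(out.domain_i == "nbdA") & (out.domain_j == "pbdA")].iloc[0]
        assert row.mean_delta_rc == pytest.approx(-1.0)

    def test_overlapping_domains_rejected(self):
        diff = self._constant_diff()
        with pytest.raises(ValueError, match="both"):
            ds.domain_block_summary(diff, {"x": [("A", 1, 3)], "y": [("A", 3, 4)]})

    def test_interface_only_fixture_confines_signal_to_interface_block(self, schedule):
        planted = (
            stiffen_backbone("A", 1, 6)
            + stiffen_backbone("B", 1, 6)
            + [
                PlantedBond("hbond", "A", 6, "B", 1, -2.0),
                PlantedBond("hydrophobic", "A", 5, "B", 2, anchor="CA"),
            ]
        )
        _, truth = sd.toy_structure(n_res=6, kind="dimer", planted=planted)
        diff = dimer_difference(truth, schedule)
        domains = {"coreA": [("A", 1, 6)], "coreB": [("B", 1, 6)]}
        out = ds.domain_block_summary(diff, domains, stabilized_below=-0.05)
        inter = out[(out.domain_i == "coreA") & (out.domain_j == "coreB")].iloc[0]
        intraA = out[(out.domain_i == "coreA") & (out.domain_j == "coreA")].iloc[0]
        assert inter.n_stabilized > 0
        assert intraA.n_stabilized == 0
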