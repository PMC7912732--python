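"""Cavity extraction, relaxation, funnel selection and population stats."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from emip.cavity import (Cavity, CavityError, FunnelSpec, binding_energy,
                         extract_first_shell, funnel_select, interval_share,
                         population_frame, population_report, relax_cavity,
                         shell_cutoff_from_rdf)
from emip.mc import pair_energy
from emip.topology import (Configuration, MoleculePose, MoleculeTopology,
                           SiteParams, TrajectoryFrame)


def _random_frame(rng, toy_topologies, n_monomer=25, n_solvent=10,
                  box=28.0):
    poses = [MoleculePose("tmdpv", rng.uniform(0, box, 3),
                          Rotation.random(rng=rng).as_quat())]
    for _ in range(n_monomer):
        poses.append(MoleculePose("topd", rng.uniform(0, box, 3),
                                  Rotation.random(rng=rng).as_quat()))
    for _ in range(n_solvent):
        poses.append(MoleculePose("twat", rng.uniform(0, box, 3)))
    cfg = Configuration(box=[box] * 3, poses=poses,
                        topologies=toy_topologies)
    return TrajectoryFrame(0, 0, cfg, 0.0, cfg.volume)


def brute_force_shell(frame, cutoff):
    """Independent O(N²) membership oracle with per-site minimum image."""
    cfg = frame.configuration
    t_idx = cfg.template_index()
    t_sites = cfg.site_positions(t_idx)
    members = []
    for i in range(cfg.n_molecules):
        if i == t_idx or cfg.topology_of(i).role != "monomer":
            continue
        dmin = math.inf
        for ms in cfg.site_positions(i):
            for ts in t_sites:
                d = ms - ts
                d = d - cfg.box * np.round(d / cfg.box)
                dmin = min(dmin, float(np.linalg.norm(d)))
        if dmin <= cutoff:
            members.append(i)
    return members


class TestExtraction:
    def test_all_monomers_far_gives_empty_cavity(self, toy_topologies):
        poses = [MoleculePose("tmdpv", [5, 5, 5]),
                 MoleculePose("topd", [25, 25, 25])]
        cfg = Configuration(box=[50] * 3, poses=poses,
                            topologies=toy_topologies)
        frame = TrajectoryFrame(0, 0, cfg, 0.0, cfg.volume)
        cavity = extract_first_shell(frame, 4.0)
        assert cavity.n_monomers == 0
        assert cavity.stage == "extracted"

    def test_membership_matches_brute_force_on_100_frames(
            self, rng, toy_topologies):
        for _ in range(100):
            frame = _random_frame(rng, toy_topologies)
            cavity = extract_first_shell(frame, 4.0)
            assert cavity.n_monomers == len(brute_force_shell(frame, 4.0))

    def test_solvent_never_included(self, rng, toy_topologies):
        # pack solvent right next to the template
        poses = [MoleculePose("tmdpv", [10, 10, 10]),
                 MoleculePose("twat", [10, 10, 13.5])]
        cfg = Configuration(box=[30] * 3, poses=poses,
                            topologies=toy_topologies)
        frame = TrajectoryFrame(0, 0, cfg, 0.0, cfg.volume)
        assert extract_first_shell(frame, 6.0).n_monomers == 0

    def test_no_template_raises(self, toy_topologies):
        poses = [MoleculePose("topd", [5, 5, 5])]
        cfg = Configuration(box=[20] * 3, poses=poses,
                            topologies=toy_topologies)
        frame = TrajectoryFrame(0, 0, cfg, 0.0, cfg.volume)
        with pytest.raises(Exception, match="template"):
            extract_first_shell(frame, 4.0)


class TestRdfCutoff:
    def _frames_from_distances(self, distances, toy_topologies):
        """Single-monomer frames placing the monomer ring site at a given
        min distance from the nearest template site."""
        frames = []
        template = toy_topologies["tmdpv"]
        for k, r in enumerate(distances):
            # approach along +x through the O1 site
            o1 = template.sites[1].local_position
            u = o1 / np.linalg.norm(o1)
            # ring site sits exactly r from the nearest template site (O1)
            pos = np.array([40.0, 40, 40]) + o1 + u * r
            poses = [MoleculePose("tmdpv", [40, 40, 40]),
                     MoleculePose("topd", pos)]
            cfg = Configuration(box=[80] * 3, poses=poses,
                                topologies=toy_topologies)
            frames.append(TrajectoryFrame(0, k, cfg, 0.0, cfg.volume))
        return frames

    def test_bimodal_distances_recover_trough(self, rng, toy_topologies):
        near = rng.normal(3.0, 0.35, 700)
        far = rng.normal(6.5, 0.55, 700)
        dists = np.clip(np.concatenate([near, far]), 1.8, 9.0)
        frames = self._frames_from_distances(dists, toy_topologies)
        cutoff = shell_cutoff_from_rdf(frames)
        # generator trough lies between the two modes
        assert 3.8 <= cutoff <= 5.4

    def test_too_few_frames_rejected(self, toy_topologies):
        frames = self._frames_from_distances([3.0] * 5, toy_topologies)
        with pytest.raises(CavityError, match="10 frames"):
            shell_cutoff_from_rdf(frames)

    def test_unimodal_histogram_rejected(self, rng, toy_topologies):
        dists = rng.normal(4.0, 0.3, 300)
        frames = self._frames_from_distances(dists, toy_topologies)
        with pytest.raises(CavityError, match="minimum|cutoff"):
            shell_cutoff_from_rdf(frames)


def _lj_dimer_cavity(r0, sigma=3.4, epsilon=0.5):
    template = MoleculeTopology(
        "t", "template",
        [SiteParams("T", "C", sigma, epsilon, 0.0, [0, 0, 0])])
    monomer = MoleculeTopology(
        "m", "monomer",
        [SiteParams("M", "C", sigma, epsilon, 0.0, [0, 0, 0])])
    topos = {"t": template, "m": monomer}
    return Cavity(provenance=(0, 0),
                  template_pose=MoleculePose("t", [0.0, 0.0, 0.0]),
                  monomer_poses=[MoleculePose("m", [r0, 0.0, 0.0])],
                  topologies=topos)


class TestRelaxation:
    def test_lj_dimer_relaxes_to_known_minimum(self):
        sigma = 3.4
        cavity = _lj_dimer_cavity(1.5 * sigma, sigma=sigma)
        relaxed = relax_cavity(cavity, "stage1")
        relaxed = relax_cavity(relaxed, "stage2")
        r = np.linalg.norm(relaxed.monomer_poses[0].position
                           - relaxed.template_pose.position)
        assert r == pytest.approx(2 ** (1 / 6) * sigma, abs=1e-3 * sigma)
        assert relaxed.binding_energy == pytest.approx(-0.5, abs=1e-4)

    def test_already_minimal_dimer_unchanged(self):
        sigma = 3.4
        cavity = _lj_dimer_cavity(2 ** (1 / 6) * sigma, sigma=sigma)
        relaxed = relax_cavity(cavity, "stage1")
        assert relaxed.binding_energy == pytest.approx(-0.5, abs=1e-4)

    def test_energy_never_increases(self, rng, toy_topologies):
        frame = _random_frame(rng, toy_topologies, n_monomer=12,
                              n_solvent=0, box=24.0)
        cavity = extract_first_shell(frame, 6.0)
        if cavity.n_monomers == 0:
            pytest.skip("random frame produced an empty shell")
        e0 = binding_energy(cavity)
        relaxed = relax_cavity(cavity, "stage1", max_iterations=30)
        assert relaxed.binding_energy <= e0 + 1e-9
        tighter = relax_cavity(relaxed, "stage2", max_iterations=30)
        assert tighter.binding_energy <= relaxed.binding_energy + 1e-9

    def test_stage_order_enforced(self):
        cavity = _lj_dimer_cavity(5.0)
        with pytest.raises(CavityError, match="stage1"):
            relax_cavity(cavity, "stage2")


class TestBindingEnergy:
    def test_empty_cavity_is_zero(self, toy_topologies):
        cavity = Cavity(provenance=(0, 0),
                        template_pose=MoleculePose("tmdpv", [0, 0, 0]),
                        monomer_poses=[], topologies=toy_topologies)
        assert binding_energy(cavity) == 0.0

    def test_two_monomer_additivity(self, toy_topologies):
        poses = [MoleculePose("tmdpv", [20.0, 20, 20]),
                 MoleculePose("topd", [24.5, 20, 20]),
                 MoleculePose("topd", [20, 24.5, 20])]
        cfg = Configuration(box=[200] * 3, poses=poses,
                            topologies=toy_topologies)
        expected = (pair_energy(cfg, 0, 1) + pair_energy(cfg, 0, 2)
                    + pair_energy(cfg, 1, 2))
        cavity = Cavity(provenance=(0, 0), template_pose=poses[0],
                        monomer_poses=poses[1:], topologies=toy_topologies)
        assert binding_energy(cavity) == pytest.approx(expected, abs=1e-10)

    def test_matches_brute_force_on_random_cavities(self, rng,
                                                    toy_topologies):
        for _ in range(5):
            frame = _random_frame(rng, toy_topologies, n_monomer=10,
                                  n_solvent=0, box=26.0)
            cavity = extract_first_shell(frame, 6.0)
            cluster = cavity.as_cluster()
            expected = sum(
                pair_energy(cluster, a, b)
                for a in range(cluster.n_molecules)
                for b in range(a + 1, cluster.n_molecules))
            assert binding_energy(cavity) == pytest.approx(expected,
                                                           abs=1e-10)


def _energy_cavities(energies_by_group, topologies):
    """Cavities with preset energies; geometry is irrelevant because the
    funnel is driven through an injected identity relaxer."""
    cavities = []
    step = 0
    for n, energies in energies_by_group.items():
        for e in energies:
            step += 1
            cavities.append(Cavity(
                provenance=(0, step),
                template_pose=MoleculePose("tmdpv", [0, 0, 0]),
                monomer_poses=[MoleculePose("topd", [10.0 + 5 * k, 0, 0])
                               for k in range(n)],
                topologies=topologies,
                binding_energy=e, stage="extracted"))
    return cavities


def _identity_relaxer(cavity, scorer):
    out = cavity.copy()
    out.stage = ("relaxed_stage1" if scorer == "stage1"
                 else "relaxed_stage2")
    return out


def _identity_rescore(cavity):
    return cavity.binding_energy


class TestFunnel:
    def test_threshold_is_inclusive(self, toy_topologies):
        cavities = _energy_cavities({3: [0.0, 9.9, 10.1]}, toy_topologies)
        spec = FunnelSpec(stage1_cutoff=10.0, stage2_cutoff=5.0,
                          group_range=(1, 10))
        report = funnel_select(cavities, spec, relaxer=_identity_relaxer,
                               rescorer=_identity_rescore)
        assert report.groups[0].n_stage1 == 2

    def test_all_close_energies_survive_both_cuts(self, toy_topologies):
        cavities = _energy_cavities({2: [-3.0, -2.5], 3: [-2.8, -2.2]},
                                    toy_topologies)
        spec = FunnelSpec(group_range=(1, 10))
        report = funnel_select(cavities, spec, relaxer=_identity_relaxer,
                               rescorer=_identity_rescore)
        assert report.total_stage1_survivors == 4
        assert report.total_stage2_survivors == 4

    def test_stage2_uses_overall_minimum(self, toy_topologies):
        # group 2's minimum is 6 above the global minimum: with a stage-2
        # window of 5 the whole group is cut even though it passed stage 1
        cavities = _energy_cavities({2: [-10.0, -9.0], 3: [-4.0, -3.5]},
                                    toy_topologies)
        spec = FunnelSpec(stage1_cutoff=10.0, stage2_cutoff=5.0,
                          group_range=(1, 10))
        report = funnel_select(cavities, spec, relaxer=_identity_relaxer,
                               rescorer=_identity_rescore)
        by_n = {g.n_monomers: g for g in report.groups}
        assert by_n[2].n_stage2 == 2
        assert by_n[3].n_stage2 == 0

    def test_group_range_restriction(self, toy_topologies):
        cavities = _energy_cavities({1: [0.0], 5: [0.0]}, toy_topologies)
        spec = FunnelSpec(group_range=(4, 6))
        report = funnel_select(cavities, spec, relaxer=_identity_relaxer,
                               rescorer=_identity_rescore)
        assert [g.n_monomers for g in report.groups] == [5]

    def test_engineered_stage1_survivor_total_46(self, toy_topologies):
        # six groups engineered so the stage-1 cut keeps 46 cavities in
        # total, the head-count a real funnel reports after its coarse cut
        energies = {
            18: [0.0] * 5 + [20.0] * 10,
            19: [-1.0] * 8 + [15.0] * 10,
            20: [-2.0] * 10 + [12.0] * 10,
            21: [-1.5] * 9 + [30.0] * 5,
            22: [-4.0] * 8 + [11.0] * 4,
            23: [-5.0] * 6 + [40.0] * 2,
        }
        assert sum(len([e for e in v if e < 10]) for v in
                   energies.values()) == 46
        cavities = _energy_cavities(energies, toy_topologies)
        spec = FunnelSpec(stage1_cutoff=10.0, stage2_cutoff=5.0,
                          group_range=(18, 23))
        report = funnel_select(cavities, spec, relaxer=_identity_relaxer,
                               rescorer=_identity_rescore)
        assert report.total_stage1_survivors == 46

    @given(energies=st.lists(st.floats(-50, 50), min_size=1, max_size=30))
    def test_survivor_counts_monotone_and_minimum_kept(self, toy_topologies,
                                                       energies):
        cavities = _energy_cavities({4: energies}, toy_topologies)
        spec = FunnelSpec(group_range=(1, 10))
        report = funnel_select(cavities, spec, relaxer=_identity_relaxer,
                               rescorer=_identity_rescore)
        g = report.groups[0]
        assert g.n_extracted >= g.n_stage1 >= g.n_stage2
        # the group minimum always survives stage 1
        assert g.n_stage1 >= 1
        assert min(energies) >= g.best.binding_energy - 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(CavityError):
            funnel_select([], FunnelSpec())

    def test_real_relaxation_end_to_end(self, rng, toy_topologies):
        # small but genuine pipeline: extraction → relax → funnel
        frames = [_random_frame(rng, toy_topologies, n_monomer=6,
                                n_solvent=0, box=22.0) for _ in range(4)]
        cavities = [extract_first_shell(f, 6.0) for f in frames]
        cavities = [c for c in cavities if c.n_monomers > 0]
        if not cavities:
            pytest.skip("no shells in random frames")
        sizes = [c.n_monomers for c in cavities]
        spec = FunnelSpec(group_range=(min(sizes), max(sizes)))
        report = funnel_select(cavities, spec)
        assert report.survivors
        for c in report.survivors:
            assert c.stage == "final_scored"
            assert math.isfinite(c.binding_energy)


class TestPopulation:
    def test_single_cavity_is_100_percent(self, toy_topologies):
        cavities = _energy_cavities({7: [0.0]}, toy_topologies)
        report = population_report(cavities)
        assert len(report) == 1
        assert report[0].population_fraction == 1.0

    def test_fractions_match_hand_oracle(self, rng, toy_topologies):
        counts = {2: 7, 3: 13, 5: 5}
        cavities = _energy_cavities(
            {n: [0.0] * c for n, c in counts.items()}, toy_topologies)
        report = population_report(cavities)
        total = sum(counts.values())
        for group in report:
            assert group.population_fraction == pytest.approx(
                counts[group.n_monomers] / total)
        assert sum(g.population_fraction for g in report) == pytest.approx(
            1.0, abs=1e-9)

    def test_printed_fraction_fixture(self, toy_topologies):
        # the authored 616-cavity distribution: 19/20/21-monomer shares
        counts = {18: 80, 19: 126, 20: 140, 21: 114, 22: 88, 23: 68}
        cavities = _energy_cavities(
            {n: [0.0] * c for n, c in counts.items()}, toy_topologies)
        report = population_report(cavities)
        frame = population_frame(report).set_index("n_monomers")
        assert frame.loc[19, "percent"] == pytest.approx(20.5, abs=0.05)
        assert frame.loc[20, "percent"] == pytest.approx(22.7, abs=0.05)
        assert frame.loc[21, "percent"] == pytest.approx(18.5, abs=0.05)
        assert interval_share(report, 19, 21) > 0.60

    def test_interval_share_equals_member_sum(self, toy_topologies):
        counts = {1: 3, 2: 4, 3: 5, 9: 8}
        cavities = _energy_cavities(
            {n: [0.0] * c for n, c in counts.items()}, toy_topologies)
        report = population_report(cavities)
        assert interval_share(report, 2, 3) == pytest.approx(9 / 20)

    def test_empty_input_rejected(self):
        with pytest.raises(CavityError):
            population_report([])
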