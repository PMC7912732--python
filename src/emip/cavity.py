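"""First-solvation-shell cavity extraction, relaxation and funnel selection.

A *cavity* (pre-polymerization complex) is the template molecule together
with the functional monomers of its first solvation shell.  The pipeline
mirrors a coarse→fine conformer funnel: extract shells from trajectory
frames, group by monomer count, relax every member with a coarse
tolerance and keep those within a stage-1 energy window of the group
minimum, re-relax survivors with a tight tolerance and keep those within
a stage-2 window of the overall minimum, then rescore.

Relaxation is classical rigid-body coordinate descent on the isolated
cluster (no periodic images, untruncated LJ + Coulomb); the two stages
differ only in their convergence tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .mc import System
from .topology import (Configuration, MoleculePose, MoleculeTopology,
                       TrajectoryFrame)

STAGES = ("extracted", "relaxed_stage1", "relaxed_stage2", "final_scored")

#: per-cycle energy tolerances (kcal mol⁻¹) of the two relaxation stages
STAGE_TOLERANCES = {"stage1": 1e-2, "stage2": 1e-4}

#: default shell membership cutoff, Å (min site–site distance); can be
#: replaced by an RDF-derived value, see :func:`shell_cutoff_from_rdf`
DEFAULT_SHELL_CUTOFF = 4.0


class CavityError(ValueError):
    pass


@dataclass
class Cavity:
    """One template + first-shell monomer cluster with its energy."""

    provenance: tuple[int, int]            # (run_id, step)
    template_pose: MoleculePose
    monomer_poses: list[MoleculePose]
    topologies: Mapping[str, MoleculeTopology] = field(repr=False)
    binding_energy: float = math.nan
    stage: str = "extracted"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise CavityError(f"unknown stage {self.stage!r}")

    @property
    def n_monomers(self) -> int:
        return len(self.monomer_poses)

    def as_cluster(self) -> Configuration:
        """The isolated cluster as a large non-interacting-walls box.

        The box is a formality (poses are used unwrapped relative to each
        other); energies are always computed without periodic images.
        """
        poses = [self.template_pose] + list(self.monomer_poses)
        coords = np.concatenate([
            p.site_positions(self.topologies[p.topology_ref]) for p in poses])
        span = coords.max(axis=0) - coords.min(axis=0)
        edge = float(span.max()) * 4 + 100.0
        shifted = [MoleculePose(p.topology_ref,
                                p.position - coords.min(axis=0) + edge / 4,
                                p.orientation.copy()) for p in poses]
        return Configuration(box=np.array([edge] * 3), poses=shifted,
                             topologies=self.topologies)

    def copy(self) -> "Cavity":
        return Cavity(
            provenance=self.provenance,
            template_pose=MoleculePose(self.template_pose.topology_ref,
                                       self.template_pose.position.copy(),
                                       self.template_pose.orientation.copy()),
            monomer_poses=[MoleculePose(p.topology_ref, p.position.copy(),
                                        p.orientation.copy())
                           for p in self.monomer_poses],
            topologies=self.topologies,
            binding_energy=self.binding_energy,
            stage=self.stage,
        )


@dataclass
class CavityGroup:
    """All cavities of one monomer count, with population statistics."""

    n_monomers: int
    members: list[Cavity]
    population_fraction: float
    best: Cavity | None = None


@dataclass
class FunnelSpec:
    """Two-stage energy funnel: windows in kcal mol⁻¹ above the minimum."""

    stage1_cutoff: float = 10.0
    stage2_cutoff: float = 5.0
    group_range: tuple[int, int] = (16, 25)

    def __post_init__(self) -> None:
        if self.stage1_cutoff <= 0 or self.stage2_cutoff <= 0:
            raise CavityError("funnel cutoffs must be > 0")
        if self.group_range[0] > self.group_range[1]:
            raise CavityError("group_range must be a nonempty interval")


# ---------------------------------------------------------------------------
# shell extraction
# ---------------------------------------------------------------------------

def extract_first_shell(frame: TrajectoryFrame,
                        shell_cutoff: float = DEFAULT_SHELL_CUTOFF) -> Cavity:
    """Extract the template's first monomer shell from one frame.

    A monomer belongs to the shell when its minimum-image minimum
    site–site distance to any template site is at most ``shell_cutoff``.
    Solvent molecules are never included.  An empty shell is a valid
    cavity with zero monomers.
    """
    if shell_cutoff <= 0:
        raise CavityError("shell_cutoff must be > 0")
    cfg = frame.configuration
    t_idx = cfg.template_index()
    t_sites = cfg.site_positions(t_idx)
    box = cfg.box
    members: list[MoleculePose] = []
    for i, pose in enumerate(cfg.poses):
        if i == t_idx:
            continue
        topo = cfg.topology_of(i)
        if topo.role != "monomer":
            continue
        m_sites = cfg.site_positions(i)
        d = m_sites[:, None, :] - t_sites[None, :, :]
        d -= box * np.round(d / box)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        if r2.min() <= shell_cutoff * shell_cutoff:
            # keep the monomer in the template's image so the cluster is
            # geometrically contiguous
            cog_shift = -box * np.round(
                (m_sites.mean(axis=0) - t_sites.mean(axis=0)) / box)
            members.append(MoleculePose(pose.topology_ref,
                                        pose.position + cog_shift,
                                        pose.orientation.copy()))
    template_pose = MoleculePose(cfg.poses[t_idx].topology_ref,
                                 cfg.poses[t_idx].position.copy(),
                                 cfg.poses[t_idx].orientation.copy())
    return Cavity(provenance=(frame.run_id, frame.step),
                  template_pose=template_pose,
                  monomer_poses=members,
                  topologies=cfg.topologies)


def shell_cutoff_from_rdf(frames: Sequence[TrajectoryFrame],
                          bin_width: float = 0.1,
                          r_max: float = 12.0,
                          smooth_window: int = 5) -> float:
    """Derive the shell cutoff from the template–monomer distance histogram.

    Histograms the per-monomer minimum site–site distance to the template
    over all frames, smooths with a moving average, and returns the first
    local minimum after the first peak, refined by a parabolic fit over
    the three bins around the minimum.
    """
    if len(frames) < 10:
        raise CavityError("need at least 10 frames for an RDF-based cutoff")
    dists: list[float] = []
    for frame in frames:
        cfg = frame.configuration
        t_idx = cfg.template_index()
        t_sites = cfg.site_positions(t_idx)
        box = cfg.box
        for i in range(cfg.n_molecules):
            if i == t_idx or cfg.topology_of(i).role != "monomer":
                continue
            d = cfg.site_positions(i)[:, None, :] - t_sites[None, :, :]
            d -= box * np.round(d / box)
            r = math.sqrt(np.einsum("ijk,ijk->ij", d, d).min())
            if r < r_max:
                dists.append(r)
    if not dists:
        raise CavityError("no template–monomer distances below r_max")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist, _ = np.histogram(dists, bins=edges)
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(hist.astype(float), kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    # first peak: first interior local maximum with nonzero counts
    peak = None
    for k in range(1, len(smooth) - 1):
        if smooth[k] > 0 and smooth[k] >= smooth[k - 1] and \
                smooth[k] > smooth[k + 1]:
            peak = k
            break
    if peak is None:
        raise CavityError(
            "distance histogram has no interior peak; supply a manual cutoff")
    trough = None
    for k in range(peak + 1, len(smooth) - 1):
        if smooth[k] <= smooth[k - 1] and smooth[k] < smooth[k + 1]:
            trough = k
            break
    if trough is None:
        raise CavityError(
            "no interior minimum after the first peak; supply a manual cutoff")
    y0, y1, y2 = smooth[trough - 1: trough + 2]
    denom = y0 - 2 * y1 + y2
    offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(centers[trough] + offset * bin_width)


# ---------------------------------------------------------------------------
# energies and relaxation
# ---------------------------------------------------------------------------

def binding_energy(cavity: Cavity) -> float:
    """Total intermolecular interaction energy of the isolated cluster.

    Defined as E(complex) − E(template) − Σ E(monomer); with rigid
    molecules the isolated terms vanish, leaving the pairwise
    intermolecular sum (untruncated LJ + Coulomb, no periodic images).
    """
    if cavity.n_monomers == 0:
        return 0.0
    system = System(cavity.as_cluster(), cutoff=None)
    return system.total_U


_AXES = np.eye(3)


def relax_cavity(cavity: Cavity, scorer: str = "stage1",
                 max_iterations: int = 200,
                 initial_translation: float = 0.3,
                 initial_rotation: float = 0.25,
                 min_translation: float = 1e-4) -> Cavity:
    """Greedy rigid-body coordinate descent on the isolated cavity.

    Cycles over molecules trying axis-aligned translations and rotations,
    keeping only energy-lowering moves, halving the step sizes whenever a
    full cycle improves the energy by less than the stage tolerance, and
    stopping once the translation step has shrunk below
    ``min_translation`` Å (or at ``max_iterations`` cycles).  The output
    energy is never above the input energy.
    """
    if scorer not in STAGE_TOLERANCES:
        raise CavityError(f"scorer must be one of {tuple(STAGE_TOLERANCES)}")
    if scorer == "stage2" and cavity.stage == "extracted":
        raise CavityError("stage1 relaxation must precede stage2")
    out = cavity.copy()
    new_stage = "relaxed_stage1" if scorer == "stage1" else "relaxed_stage2"
    if out.n_monomers == 0:
        out.binding_energy = 0.0
        out.stage = new_stage
        return out
    tol = STAGE_TOLERANCES[scorer]
    system = System(out.as_cluster(), cutoff=None)
    if not math.isfinite(system.total_U):
        raise CavityError("non-finite cavity energy at relaxation start")
    h, theta = initial_translation, initial_rotation

    def try_move(i: int, new_pos: np.ndarray | None,
                 new_quat: np.ndarray | None) -> bool:
        old_pos = system.positions[i].copy()
        old_quat = system.quats[i].copy()
        old_sites = system.mol_sites(i).copy()
        old_cog = system.cogs[i].copy()
        e_old = system.mol_energy(i)
        if new_pos is not None:
            system.positions[i] = new_pos
        if new_quat is not None:
            system.quats[i] = new_quat
        system._rebuild_sites(i)
        system._update_cog(i)
        try:
            e_new = system.mol_energy(i)
        except Exception:
            e_new = math.inf
        if e_new < e_old:
            system.total_U += e_new - e_old
            return True
        system.positions[i] = old_pos
        system.quats[i] = old_quat
        system.site_pos[system.mol_slice(i)] = old_sites
        system.cogs[i] = old_cog
        return False

    for _ in range(max_iterations):
        e_start = system.total_U
        for i in range(system.n):
            for axis in _AXES:
                for sign in (1.0, -1.0):
                    while try_move(i, system.positions[i] + sign * h * axis,
                                   None):
                        pass
            if system.site_start[i + 1] - system.site_start[i] > 1:
                for axis in _AXES:
                    for sign in (1.0, -1.0):
                        rot = Rotation.from_rotvec(sign * theta * axis)
                        while try_move(
                                i, None,
                                (rot * Rotation.from_quat(system.quats[i])
                                 ).as_quat()):
                            rot = Rotation.from_rotvec(sign * theta * axis)
                        # quaternion renormalization guard
                        system.quats[i] /= np.linalg.norm(system.quats[i])
                        system._rebuild_sites(i)
                        system._update_cog(i)
        if e_start - system.total_U < tol:
            if h <= min_translation:
                break
            h *= 0.5
            theta *= 0.5
    if not math.isfinite(system.total_U):
        raise CavityError("non-finite cavity energy during relaxation")
    poses = system.to_configuration().poses
    out.template_pose = poses[0]
    out.monomer_poses = poses[1:]
    out.binding_energy = system.total_U
    out.stage = new_stage
    return out


# ---------------------------------------------------------------------------
# funnel selection
# ---------------------------------------------------------------------------

def _stability_key(c: Cavity) -> tuple[float, int, int]:
    """Sort key: lowest energy, ties to fewer monomers then earlier step."""
    return (c.binding_energy, c.n_monomers, c.provenance[1])


@dataclass
class FunnelGroupReport:
    n_monomers: int
    n_extracted: int
    n_stage1: int
    n_stage2: int
    best: Cavity | None


@dataclass
class FunnelReport:
    groups: list[FunnelGroupReport]
    survivors: list[Cavity]

    @property
    def total_stage1_survivors(self) -> int:
        return sum(g.n_stage1 for g in self.groups)

    @property
    def total_stage2_survivors(self) -> int:
        return sum(g.n_stage2 for g in self.groups)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"n_monomers": g.n_monomers,
             "n_extracted": g.n_extracted,
             "n_stage1": g.n_stage1,
             "n_stage2": g.n_stage2,
             "best_energy": (math.nan if g.best is None
                             else g.best.binding_energy)}
            for g in self.groups])


def funnel_select(cavities: Sequence[Cavity], spec: FunnelSpec,
                  relaxer: Callable[[Cavity, str], Cavity] = relax_cavity,
                  rescorer: Callable[[Cavity], float] = binding_energy,
                  ) -> FunnelReport:
    """Apply the two-stage energy funnel and report per-group survivors.

    Stage 1: groups are restricted to ``spec.group_range``; every member
    is relaxed with the coarse scorer and kept when its energy lies
    within ``stage1_cutoff`` (inclusive) of its *group* minimum.  Stage
    2: survivors are relaxed with the tight scorer and kept within
    ``stage2_cutoff`` (inclusive) of the *overall* minimum.  Survivors
    get a final single-point rescoring.  ``relaxer``/``rescorer`` are
    injectable so constructed energy sets can exercise the threshold
    logic directly.
    """
    if not cavities:
        raise CavityError("funnel_select needs at least one cavity")
    lo, hi = spec.group_range
    groups: dict[int, list[Cavity]] = {}
    for c in cavities:
        groups.setdefault(c.n_monomers, []).append(c)
    in_range = {n: g for n, g in groups.items() if lo <= n <= hi}
    report_groups: list[FunnelGroupReport] = []
    stage1_survivors: dict[int, list[Cavity]] = {}
    for n in sorted(in_range):
        relaxed = [relaxer(c, "stage1") for c in in_range[n]]
        gmin = min(c.binding_energy for c in relaxed)
        kept = [c for c in relaxed
                if c.binding_energy <= gmin + spec.stage1_cutoff]
        stage1_survivors[n] = kept
    all_stage2: list[Cavity] = []
    for n in sorted(stage1_survivors):
        all_stage2.extend(relaxer(c, "stage2") for c in stage1_survivors[n])
    final_survivors: list[Cavity] = []
    if all_stage2:
        overall_min = min(c.binding_energy for c in all_stage2)
        for c in all_stage2:
            if c.binding_energy <= overall_min + spec.stage2_cutoff:
                scored = c.copy()
                scored.binding_energy = rescorer(c)
                scored.stage = "final_scored"
                final_survivors.append(scored)
    for n in sorted(in_range):
        stage2_members = [c for c in final_survivors if c.n_monomers == n]
        candidates = stage2_members or stage1_survivors[n]
        best = min(candidates, key=_stability_key) if candidates else None
        report_groups.append(FunnelGroupReport(
            n_monomers=n,
            n_extracted=len(in_range[n]),
            n_stage1=len(stage1_survivors[n]),
            n_stage2=len(stage2_members),
            best=best))
    return FunnelReport(groups=report_groups, survivors=final_survivors)


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

def population_report(cavities: Sequence[Cavity]) -> list[CavityGroup]:
    """Group cavities by monomer count with population fractions.

    Fractions use all extracted cavities as the denominator and sum to 1.
    The ``best`` member is only defined for cavities with finite energy.
    """
    if not cavities:
        raise CavityError("population_report needs at least one cavity")
    total = len(cavities)
    groups: dict[int, list[Cavity]] = {}
    for c in cavities:
        groups.setdefault(c.n_monomers, []).append(c)
    out = []
    for n in sorted(groups):
        members = groups[n]
        finite = [c for c in members if math.isfinite(c.binding_energy)]
        best = min(finite, key=_stability_key) if finite else None
        out.append(CavityGroup(n_monomers=n, members=members,
                               population_fraction=len(members) / total,
                               best=best))
    return out


def population_frame(report: Sequence[CavityGroup]) -> pd.DataFrame:
    return pd.DataFrame([
        {"n_monomers": g.n_monomers,
         "count": len(g.members),
         "fraction": g.population_fraction,
         "percent": 100.0 * g.population_fraction}
        for g in report])


def interval_share(report: Sequence[CavityGroup], lo: int, hi: int) -> float:
    """Cumulative population fraction of monomer counts in [lo, hi]."""
    return sum(g.population_fraction for g in report
               if lo <= g.n_monomers <= hi)
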