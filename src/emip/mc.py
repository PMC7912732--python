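"""Metropolis Monte Carlo sampling of rigid molecules in the NPT ensemble.

The interaction model is a classical site–site pair potential:
Lennard-Jones with geometric-mean combining rules for both σ and ε plus
point-charge Coulomb.  Molecules interact as whole units: a pair is
inside the cutoff when the minimum-image distance between the two site
centroids is at most the cutoff, in which case every site pair
contributes (LJ truncated and shifted at the cutoff distance, Coulomb
plainly truncated; no lattice sums).  This molecule-based cutoff avoids
split-molecule artifacts in downstream cavity energies.

Volume moves are uniform in ln V with the (N+1)·ln(V′/V) Jacobian and
scale molecule centers; displacement moves translate a uniformly chosen
molecule inside a cube or rotate it about a uniform random axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import ATM_TO_KCAL_PER_A3, COULOMB_KCAL, KB_KCAL
from .topology import (Configuration, MoleculePose, MoleculeTopology,
                       TrajectoryFrame)

OVERLAP_R2 = 1e-12  # squared Å; closer site pairs are an error


class OverlapError(ValueError):
    """Two interaction sites closer than the overlap threshold."""


@dataclass
class SimulationSpec:
    """Parameters of one NPT Monte Carlo run.

    Move amplitudes default to values giving roughly 30–50 % acceptance
    for the toy layered systems this package ships.
    """

    temperature: float = 298.0          # K
    pressure: float = 1.0               # atm
    cutoff: float = 10.0                # Å, molecule-centroid based
    max_translation: float = 1.0        # Å, half-width of the proposal cube
    max_rotation: float = 0.8           # rad
    max_ln_volume_step: float = 0.1     # half-width of the ln V proposal
    n_thermalization: int = 0
    n_production: int = 0
    snapshot_stride: int = 1
    n_parallel_runs: int = 1
    rng_seed: int = 0
    volume_move_frequency: float = 0.02

    def __post_init__(self) -> None:
        if self.n_thermalization < 0 or self.n_production < 0:
            raise ValueError("step counts must be >= 0")
        if self.snapshot_stride < 1:
            raise ValueError("snapshot_stride must be >= 1")
        if self.n_parallel_runs < 1:
            raise ValueError("n_parallel_runs must be >= 1")
        if not 0.0 <= self.volume_move_frequency < 1.0:
            raise ValueError("volume_move_frequency must lie in [0, 1)")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")

    @property
    def frames_per_run(self) -> int:
        return self.n_production // self.snapshot_stride

    @property
    def total_frames(self) -> int:
        """Recorded frames over all parallel runs."""
        return self.n_parallel_runs * self.frames_per_run


@dataclass
class MoveRecord:
    step: int
    move_kind: str                     # translate | rotate | volume
    accepted: bool
    delta_energy: float = 0.0


# ---------------------------------------------------------------------------
# vectorized system state
# ---------------------------------------------------------------------------

class System:
    """Flattened, cached state of a configuration for fast energy updates.

    ``box=None`` means an isolated (non-periodic) cluster and
    ``cutoff=None`` disables truncation and the LJ shift — the form used
    for cavity energies.
    """

    def __init__(self, config: Configuration, cutoff: float | None):
        self.topologies = config.topologies
        self.temperature = config.temperature
        self.pressure = config.pressure
        self.cutoff = cutoff
        self.box: np.ndarray | None = config.box.copy()
        self.names = [p.topology_ref for p in config.poses]
        self.positions = np.array([p.position for p in config.poses])
        self.quats = np.array([p.orientation for p in config.poses])
        self.n = len(config.poses)

        starts, locals_, ssig, seps, chg = [], [], [], [], []
        cursor = 0
        for name in self.names:
            topo = self.topologies[name]
            starts.append(cursor)
            cursor += topo.n_sites
            locals_.append(topo.local_coords)
            ssig.append(np.sqrt(topo.sigmas))
            seps.append(np.sqrt(topo.epsilons))
            chg.append(topo.charges)
        self.site_start = np.array(starts + [cursor])
        self.local_coords = locals_
        self.ssig = np.concatenate(ssig)
        self.seps = np.concatenate(seps)
        self.charge = np.concatenate(chg)
        self.n_sites = cursor
        self.site_mol = np.repeat(np.arange(self.n),
                                  np.diff(self.site_start))
        self.site_pos = np.empty((cursor, 3))
        for i in range(self.n):
            self._rebuild_sites(i)
        self.cogs = np.array([self.mol_sites(i).mean(axis=0)
                              for i in range(self.n)])
        self.total_U = self.recompute_total()

    # -- geometry -----------------------------------------------------------

    def mol_slice(self, i: int) -> slice:
        return slice(self.site_start[i], self.site_start[i + 1])

    def mol_sites(self, i: int) -> np.ndarray:
        return self.site_pos[self.mol_slice(i)]

    def _rebuild_sites(self, i: int) -> None:
        rot = Rotation.from_quat(self.quats[i])
        self.site_pos[self.mol_slice(i)] = (
            self.positions[i] + rot.apply(self.local_coords[i]))

    def _update_cog(self, i: int) -> None:
        self.cogs[i] = self.mol_sites(i).mean(axis=0)

    # -- energies -----------------------------------------------------------

    def mol_energy(self, i: int) -> float:
        """Interaction energy of molecule ``i`` with all other molecules."""
        if self.n <= 1:
            return 0.0
        d = self.cogs - self.cogs[i]
        if self.box is not None:
            shift = -self.box * np.round(d / self.box)
        else:
            shift = np.zeros_like(d)
        dmin = d + shift
        r2 = np.einsum("ij,ij->i", dmin, dmin)
        mask = np.ones(self.n, dtype=bool)
        mask[i] = False
        if self.cutoff is not None:
            mask &= r2 <= self.cutoff * self.cutoff
        site_idx = np.nonzero(mask[self.site_mol])[0]
        if site_idx.size == 0:
            return 0.0
        other = self.site_pos[site_idx] + shift[self.site_mol[site_idx]]
        mine = self.mol_sites(i)
        diff = mine[:, None, :] - other[None, :, :]
        r2p = np.einsum("ijk,ijk->ij", diff, diff)
        if np.any(r2p < OVERLAP_R2):
            raise OverlapError(
                f"overlapping sites while evaluating molecule {i}")
        sij = self.ssig[self.mol_slice(i)][:, None] * self.ssig[site_idx][None, :]
        eij = self.seps[self.mol_slice(i)][:, None] * self.seps[site_idx][None, :]
        qq = self.charge[self.mol_slice(i)][:, None] * self.charge[site_idx][None, :]
        s6 = (sij * sij / r2p) ** 3
        lj = 4.0 * eij * (s6 * s6 - s6)
        if self.cutoff is not None:
            sc6 = (sij * sij / (self.cutoff * self.cutoff)) ** 3
            lj -= 4.0 * eij * (sc6 * sc6 - sc6)
        coul = COULOMB_KCAL * qq / np.sqrt(r2p)
        return float(np.sum(lj + coul))

    def recompute_total(self) -> float:
        """Full O(N²) recomputation of the potential energy."""
        if self.n <= 1:
            return 0.0
        if self.n_sites * self.n_sites > 4_000_000:
            # large systems: per-molecule passes to bound memory
            return 0.5 * sum(self.mol_energy(i) for i in range(self.n))
        d = self.cogs[:, None, :] - self.cogs[None, :, :]
        if self.box is not None:
            shift = -self.box * np.round(d / self.box)
        else:
            shift = np.zeros_like(d)
        dmin = d + shift
        mol_r2 = np.einsum("ijk,ijk->ij", dmin, dmin)
        pair_mask = ~np.eye(self.n, dtype=bool)
        if self.cutoff is not None:
            pair_mask &= mol_r2 <= self.cutoff * self.cutoff
        site_mask = pair_mask[self.site_mol[:, None], self.site_mol[None, :]]
        diff = (self.site_pos[:, None, :] - self.site_pos[None, :, :]
                + shift[self.site_mol[:, None], self.site_mol[None, :]])
        r2p = np.einsum("ijk,ijk->ij", diff, diff)
        if np.any(r2p[site_mask] < OVERLAP_R2):
            raise OverlapError("overlapping sites in total-energy pass")
        r2p = np.where(site_mask, r2p, 1.0)   # dummy distances off-mask
        sij = self.ssig[:, None] * self.ssig[None, :]
        eij = self.seps[:, None] * self.seps[None, :]
        qq = self.charge[:, None] * self.charge[None, :]
        s6 = (sij * sij / r2p) ** 3
        lj = 4.0 * eij * (s6 * s6 - s6)
        if self.cutoff is not None:
            sc6 = (sij * sij / (self.cutoff * self.cutoff)) ** 3
            lj -= 4.0 * eij * (sc6 * sc6 - sc6)
        coul = COULOMB_KCAL * qq / np.sqrt(r2p)
        return 0.5 * float(np.sum((lj + coul)[site_mask]))

    # -- moves --------------------------------------------------------------

    def _wrap_position(self, i: int) -> None:
        assert self.box is not None
        self.positions[i] -= self.box * np.floor(self.positions[i] / self.box)

    def try_displacement(self, i: int, rng: np.random.Generator,
                         max_translation: float, max_rotation: float,
                         ) -> tuple[str, bool, float]:
        """Attempt a translation or rotation of molecule ``i``."""
        beta = 1.0 / (KB_KCAL * self.temperature)
        multi_site = self.site_start[i + 1] - self.site_start[i] > 1
        rotate = multi_site and rng.random() < 0.5
        kind = "rotate" if rotate else "translate"
        old_pos = self.positions[i].copy()
        old_quat = self.quats[i].copy()
        old_sites = self.mol_sites(i).copy()
        old_cog = self.cogs[i].copy()
        u_old = self.mol_energy(i)
        if rotate:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(-max_rotation, max_rotation)
            rot = Rotation.from_rotvec(axis * angle)
            self.quats[i] = (rot * Rotation.from_quat(self.quats[i])).as_quat()
        else:
            self.positions[i] = self.positions[i] + rng.uniform(
                -max_translation, max_translation, 3)
            if self.box is not None:
                self._wrap_position(i)
        self._rebuild_sites(i)
        self._update_cog(i)
        try:
            u_new = self.mol_energy(i)
        except OverlapError:
            u_new = math.inf
        du = u_new - u_old
        if du <= 0 or rng.random() < math.exp(-beta * du):
            self.total_U += du
            return kind, True, du
        self.positions[i] = old_pos
        self.quats[i] = old_quat
        self.site_pos[self.mol_slice(i)] = old_sites
        self.cogs[i] = old_cog
        return kind, False, du

    def try_volume_move(self, rng: np.random.Generator,
                        max_ln_volume_step: float, cutoff_check: float,
                        ) -> tuple[bool, float]:
        """Attempt a ln-V volume move; returns (accepted, ΔU)."""
        assert self.box is not None
        beta = 1.0 / (KB_KCAL * self.temperature)
        v_old = float(np.prod(self.box))
        ln_v_new = math.log(v_old) + rng.uniform(-max_ln_volume_step,
                                                 max_ln_volume_step)
        v_new = math.exp(ln_v_new)
        scale = (v_new / v_old) ** (1.0 / 3.0)
        new_box = self.box * scale
        if cutoff_check >= new_box.min() / 2.0:
            return False, 0.0  # auto-reject: cutoff invariant would break
        old_box = self.box
        old_positions = self.positions
        old_sites = self.site_pos
        old_cogs = self.cogs
        old_U = self.total_U
        self.box = new_box
        self.positions = old_positions * scale
        delta = self.positions - old_positions
        self.site_pos = old_sites + np.repeat(delta, np.diff(self.site_start),
                                              axis=0)
        self.cogs = old_cogs + delta
        try:
            u_new = self.recompute_total()
        except OverlapError:
            u_new = math.inf
        du = u_new - old_U
        p_kcal = self.pressure * ATM_TO_KCAL_PER_A3
        arg = (-beta * (du + p_kcal * (v_new - v_old))
               + (self.n + 1) * math.log(v_new / v_old))
        if arg >= 0 or rng.random() < math.exp(arg):
            self.total_U = u_new
            return True, du
        self.box = old_box
        self.positions = old_positions
        self.site_pos = old_sites
        self.cogs = old_cogs
        self.total_U = old_U
        return False, du

    def step(self, spec: SimulationSpec, rng: np.random.Generator,
             step_index: int = 0) -> MoveRecord:
        if spec.volume_move_frequency > 0 and \
                rng.random() < spec.volume_move_frequency:
            accepted, du = self.try_volume_move(
                rng, spec.max_ln_volume_step, spec.cutoff)
            return MoveRecord(step_index, "volume", accepted, du)
        i = int(rng.integers(self.n))
        kind, accepted, du = self.try_displacement(
            i, rng, spec.max_translation, spec.max_rotation)
        return MoveRecord(step_index, kind, accepted, du)

    # -- export -------------------------------------------------------------

    def to_configuration(self) -> Configuration:
        poses = [MoleculePose(self.names[i], self.positions[i].copy(),
                              self.quats[i].copy()) for i in range(self.n)]
        return Configuration(
            box=self.box.copy(), poses=poses, topologies=self.topologies,
            temperature=self.temperature, pressure=self.pressure)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def pair_energy(config: Configuration, a: int, b: int,
                cutoff: float | None = None) -> float:
    """Interaction energy between molecules ``a`` and ``b``, kcal mol⁻¹.

    LJ (geometric combining) + Coulomb over all site pairs, with the
    minimum image taken on the site-centroid separation so that both
    molecules stay whole.  With ``cutoff`` set, the pair contributes
    nothing beyond the centroid cutoff and the LJ part is shifted to
    vanish at the cutoff distance; Coulomb is plainly truncated.
    """
    if a == b:
        raise ValueError("pair_energy requires two distinct molecules")
    ta, tb = config.topology_of(a), config.topology_of(b)
    pa = config.site_positions(a)
    pb = config.site_positions(b)
    cog_a, cog_b = pa.mean(axis=0), pb.mean(axis=0)
    d = cog_b - cog_a
    shift = -config.box * np.round(d / config.box)
    if cutoff is not None and np.linalg.norm(d + shift) > cutoff:
        return 0.0
    pb = pb + shift
    diff = pa[:, None, :] - pb[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.any(r2 < OVERLAP_R2):
        raise OverlapError(f"overlapping sites between molecules {a} and {b}")
    sij = np.sqrt(ta.sigmas)[:, None] * np.sqrt(tb.sigmas)[None, :]
    eij = np.sqrt(ta.epsilons)[:, None] * np.sqrt(tb.epsilons)[None, :]
    qq = ta.charges[:, None] * tb.charges[None, :]
    s6 = (sij * sij / r2) ** 3
    lj = 4.0 * eij * (s6 * s6 - s6)
    if cutoff is not None:
        sc6 = (sij * sij / (cutoff * cutoff)) ** 3
        lj -= 4.0 * eij * (sc6 * sc6 - sc6)
    coul = COULOMB_KCAL * qq / np.sqrt(r2)
    return float(np.sum(lj + coul))


def total_energy(config: Configuration, cutoff: float | None = None) -> float:
    """Sum of :func:`pair_energy` over all unordered molecule pairs."""
    return System(config, cutoff).total_U


def metropolis_step(config: Configuration, spec: SimulationSpec,
                    rng: np.random.Generator
                    ) -> tuple[Configuration, MoveRecord]:
    """One Metropolis move on a standalone configuration.

    Convenience wrapper: builds the cached system, applies one move and
    exports the result.  Long runs should use :func:`run_simulation` (or
    :class:`System` directly), which keeps the cache alive.
    """
    system = System(config, spec.cutoff)
    record = system.step(spec, rng)
    out = system.to_configuration() if record.accepted else config
    return out, record


def run_simulation(initial: Configuration, spec: SimulationSpec,
                   collect_records: bool = False,
                   ) -> tuple[list[TrajectoryFrame], list[MoveRecord]]:
    """Run ``n_parallel_runs`` independent chains and record frames.

    Each chain gets a deterministic RNG derived from ``(rng_seed, run)``,
    performs ``n_thermalization`` unrecorded steps, then ``n_production``
    steps with a frame recorded every ``snapshot_stride`` steps; the
    total frame count is ``n_parallel_runs * (n_production // stride)``.
    With ``collect_records`` the full per-move log is returned, otherwise
    only per-run acceptance summaries are kept as sentinel records.
    """
    if spec.cutoff >= initial.box.min() / 2.0:
        raise ValueError(
            f"cutoff {spec.cutoff} must be below half the smallest box edge "
            f"({initial.box.min() / 2.0})")
    frames: list[TrajectoryFrame] = []
    records: list[MoveRecord] = []
    for run in range(spec.n_parallel_runs):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.rng_seed, run]))
        system = System(initial.copy(), spec.cutoff)
        for s in range(spec.n_thermalization):
            rec = system.step(spec, rng, s)
            if collect_records:
                records.append(rec)
        for s in range(spec.n_production):
            rec = system.step(spec, rng, spec.n_thermalization + s)
            if collect_records:
                records.append(rec)
            if (s + 1) % spec.snapshot_stride == 0:
                cfg = system.to_configuration()
                frames.append(TrajectoryFrame(
                    run_id=run, step=s + 1, configuration=cfg,
                    potential_energy=system.total_U, volume=cfg.volume))
    return frames, records


# ---------------------------------------------------------------------------
# initial configuration builder
# ---------------------------------------------------------------------------

def build_layered_initial(template: MoleculeTopology,
                          monomer: MoleculeTopology,
                          solvent: MoleculeTopology,
                          n_monomer: int, n_solvent: int,
                          target_density: float,
                          temperature: float = 298.0,
                          pressure: float = 1.0,
                          seed: int = 0,
                          min_sep_factor: float = 0.85,
                          max_attempts: int = 200) -> Configuration:
    """Build the layered starting box: monomer slab below, solvent above,
    template centered on the dividing plane.

    The cubic box edge comes from the total molar mass and
    ``target_density`` (g cm⁻³).  Molecules sit on jittered lattices with
    random orientations; the build is rejected and re-jittered until no
    two sites are closer than ``min_sep_factor · σ_ij``.
    """
    if n_monomer < 0 or n_solvent < 0:
        raise ValueError("molecule counts must be >= 0")
    if target_density <= 0:
        raise ValueError("target_density must be > 0")
    from .constants import A3_PER_GMOL_PER_GCM3
    total_mass = (template.mass + n_monomer * monomer.mass
                  + n_solvent * solvent.mass)
    volume = total_mass * A3_PER_GMOL_PER_GCM3 / target_density
    edge = volume ** (1.0 / 3.0)
    box = np.array([edge, edge, edge])
    topologies = {t.name: t for t in (template, monomer, solvent)}
    rng = np.random.default_rng(seed)

    def random_quat() -> np.ndarray:
        return Rotation.random(rng=rng).as_quat()

    center = np.array([edge / 2, edge / 2, edge / 2])
    t_extent = float(np.linalg.norm(template.local_coords, axis=1).max())

    def lattice(n: int, z_lo: float, z_hi: float, other_sigma_max: float
                ) -> tuple[np.ndarray, float]:
        """Jittered-lattice anchors, skipping the template's midplane zone."""
        if n == 0:
            return np.empty((0, 3)), 0.0
        height = z_hi - z_lo
        r_excl = (t_extent + min_sep_factor
                  * math.sqrt(template.sigmas.max() * other_sigma_max))
        nz = max(1, round((n * height * height / (edge * edge)) ** (1.0 / 3.0)))
        nxy = math.ceil(math.sqrt(n / nz))
        while True:
            pts = []
            for k in range(nxy * nxy * nz):
                iz, rem = divmod(k, nxy * nxy)
                iy, ix = divmod(rem, nxy)
                pts.append([(ix + 0.5) * edge / nxy,
                            (iy + 0.5) * edge / nxy,
                            z_lo + (iz + 0.5) * height / nz])
            pts = np.array(pts)
            keep = np.linalg.norm(pts - center, axis=1) > r_excl
            if keep.sum() >= n:
                cell = min(edge / nxy, height / nz)
                return pts[keep][:n], cell
            # grow the roomier dimension so no spacing collapses below
            # the contact distance
            if edge / nxy >= height / nz:
                nxy += 1
            else:
                nz += 1

    # sequential placement with per-molecule re-jitter/re-orientation
    placed_pos: list[np.ndarray] = []
    placed_ssig: list[np.ndarray] = []
    poses: list[MoleculePose] = []

    def try_place(topo: MoleculeTopology, anchor: np.ndarray,
                  jitter: float) -> None:
        local = topo.local_coords
        ssig = np.sqrt(topo.sigmas)
        for _ in range(max_attempts):
            pos = anchor + rng.uniform(-jitter, jitter, 3)
            quat = random_quat()
            sites = pos + Rotation.from_quat(quat).apply(local)
            if placed_pos:
                other = np.concatenate(placed_pos)
                d = sites[:, None, :] - other[None, :, :]
                d -= box * np.round(d / box)
                r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
                limit = min_sep_factor * (
                    ssig[:, None] * np.concatenate(placed_ssig)[None, :])
                if np.any(r < limit):
                    continue
            placed_pos.append(sites)
            placed_ssig.append(ssig)
            poses.append(MoleculePose(topo.name, pos, quat))
            return
        raise RuntimeError(
            f"could not place a {topo.name} molecule without overlaps "
            f"after {max_attempts} attempts; lower the target density")

    def layer_jitter(cell: float, topo: MoleculeTopology) -> float:
        # keep the jitter inside the slack between the lattice spacing
        # and the same-species contact distance, so dense layers (e.g.
        # the aqueous slab near liquid density) still place cleanly
        extent = float(np.linalg.norm(topo.local_coords, axis=1).max())
        slack = cell - min_sep_factor * topo.sigmas.max() - 2.0 * extent
        return float(np.clip(0.45 * slack, 0.02, 0.18 * cell))

    try_place(template, center, 0.0)
    mono_pts, mono_cell = lattice(n_monomer, 0.0, edge / 2,
                                  monomer.sigmas.max())
    for anchor in mono_pts:
        try_place(monomer, anchor, layer_jitter(mono_cell, monomer))
    solv_pts, solv_cell = lattice(n_solvent, edge / 2, edge,
                                  solvent.sigmas.max())
    for anchor in solv_pts:
        try_place(solvent, anchor, layer_jitter(solv_cell, solvent))
    config = Configuration(box=box, poses=poses, topologies=topologies,
                           temperature=temperature, pressure=pressure)
    if not _min_separation_ok(config, min_sep_factor):
        raise RuntimeError(
            "placement consistency check failed; lower the target density")
    return config


def _min_separation_ok(config: Configuration, factor: float) -> bool:
    """Check every inter-molecular site pair against 0.85·σ_ij via a KD-tree."""
    from scipy.spatial import cKDTree
    all_pos, all_sig, all_mol = [], [], []
    for i in range(config.n_molecules):
        topo = config.topology_of(i)
        all_pos.append(config.site_positions(i))
        all_sig.append(topo.sigmas)
        all_mol.append(np.full(topo.n_sites, i))
    box = config.box
    pos = np.concatenate(all_pos) % box  # wrap sites for a periodic query
    sig = np.concatenate(all_sig)
    mol = np.concatenate(all_mol)
    tree = cKDTree(pos, boxsize=box)
    r_max = factor * sig.max()
    for a, b in tree.query_pairs(r_max):
        if mol[a] == mol[b]:
            continue
        sij = math.sqrt(sig[a] * sig[b])
        d = np.abs(pos[a] - pos[b])
        d = np.minimum(d, box - d)
        if np.linalg.norm(d) < factor * sij:
            return False
    return True
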