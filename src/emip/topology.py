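"""Rigid-molecule topologies, configurations and trajectory I/O.

Molecules are rigid bodies: a topology carries the body-frame site
geometry together with OPLS-style nonbonded parameters (LJ σ/ε, partial
charge), and a pose places one instance in a periodic orthorhombic box
through a position (body-frame origin) and a unit quaternion.

File formats are plain text of this package's own design:

* topology files — a documented key/value header plus a site table
  (see :func:`write_topology` for the exact layout);
* trajectories — an extended-XYZ dialect, one block per frame, whose
  comment line carries ``run_id``, ``step``, box edges, potential energy
  and the ordered molecule composition.  Poses are reconstructed from
  site coordinates on read by rigid superposition (Kabsch).
"""

from __future__ import annotations

import shlex
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import ATOMIC_MASSES, DEFAULT_MASS

ROLES = ("template", "monomer", "solvent")

IDENTITY_QUAT = np.array([0.0, 0.0, 0.0, 1.0])


class TopologyError(ValueError):
    """Raised for invalid topology definitions or files."""


class TrajectoryError(ValueError):
    """Raised for invalid trajectory frames or files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SiteParams:
    """One interaction site of a rigid molecule.

    Parameters
    ----------
    label : str
        Short site label, unique within its molecule.
    element : str
        Element symbol (or coarse-site pseudo-element) used for masses
        and XYZ output.
    sigma : float
        Lennard-Jones diameter, Å.  Must be positive.
    epsilon : float
        Lennard-Jones well depth, kcal mol⁻¹.  Must be non-negative.
    charge : float
        Partial charge, elementary charge units.
    local_position : (3,) array_like
        Site position in the molecule's body frame, Å.
    """

    label: str
    element: str
    sigma: float
    epsilon: float
    charge: float
    local_position: np.ndarray

    def __post_init__(self) -> None:
        self.local_position = np.asarray(self.local_position, dtype=float)
        if self.local_position.shape != (3,):
            raise TopologyError(
                f"site {self.label!r}: local_position must be a 3-vector")
        if not np.all(np.isfinite(self.local_position)):
            raise TopologyError(
                f"site {self.label!r}: local_position must be finite")
        if not self.sigma > 0:
            raise TopologyError(f"site {self.label!r}: sigma must be > 0")
        if self.epsilon < 0:
            raise TopologyError(f"site {self.label!r}: epsilon must be >= 0")

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element, DEFAULT_MASS)


@dataclass
class MoleculeTopology:
    """A rigid molecule: named, role-tagged, with an ordered site list."""

    name: str
    role: str
    sites: list[SiteParams]
    net_charge: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TopologyError(
                f"molecule {self.name!r}: role must be one of {ROLES}, "
                f"got {self.role!r}")
        if len(self.sites) < 1:
            raise TopologyError(f"molecule {self.name!r}: needs >= 1 site")
        total = sum(s.charge for s in self.sites)
        if abs(total - self.net_charge) > 1e-6:
            raise TopologyError(
                f"molecule {self.name!r}: site charges sum to {total:.8f} "
                f"but net_charge is {self.net_charge:.8f}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def local_coords(self) -> np.ndarray:
        return np.array([s.local_position for s in self.sites])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([s.sigma for s in self.sites])

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([s.epsilon for s in self.sites])

    @property
    def charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.sites])

    @property
    def mass(self) -> float:
        return sum(s.mass for s in self.sites)


@dataclass
class MoleculePose:
    """Placement of one molecule instance: origin position + orientation.

    The orientation quaternion uses scipy's ``(x, y, z, w)`` ordering and
    must have unit norm to 1e-9.
    """

    topology_ref: str
    position: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: IDENTITY_QUAT.copy())

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.position.shape != (3,):
            raise TopologyError("pose position must be a 3-vector")
        if self.orientation.shape != (4,):
            raise TopologyError("pose orientation must be a 4-vector")
        norm = float(np.linalg.norm(self.orientation))
        if abs(norm - 1.0) > 1e-9:
            raise TopologyError(
                f"pose orientation must be a unit quaternion (norm {norm!r})")

    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.orientation)

    def site_positions(self, topology: MoleculeTopology) -> np.ndarray:
        """World-frame site coordinates of this instance, (n_sites, 3)."""
        return self.position + self.rotation().apply(topology.local_coords)


@dataclass
class Configuration:
    """A periodic orthorhombic box full of molecule poses.

    ``topologies`` maps topology names to :class:`MoleculeTopology`; every
    pose's ``topology_ref`` must resolve.  Pose origins are stored wrapped
    into ``[0, box_edge)`` with the box origin at a corner.
    """

    box: np.ndarray
    poses: list[MoleculePose]
    topologies: Mapping[str, MoleculeTopology]
    temperature: float = 298.0
    pressure: float = 1.0

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise TopologyError("box must be 3 positive edge lengths")
        for p in self.poses:
            if p.topology_ref not in self.topologies:
                raise TopologyError(
                    f"pose refers to unknown topology {p.topology_ref!r}")
        n_templates = sum(
            1 for p in self.poses
            if self.topologies[p.topology_ref].role == "template")
        if n_templates > 1:
            raise TopologyError(
                f"configuration has {n_templates} template molecules; "
                "at most one is allowed")
        self.wrap()

    @property
    def n_molecules(self) -> int:
        return len(self.poses)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrap(self) -> "Configuration":
        """Wrap pose origins into [0, box); idempotent."""
        for p in self.poses:
            w = p.position - self.box * np.floor(p.position / self.box)
            # fp rounding can land exactly on the upper box face
            p.position = np.where(w >= self.box, w - self.box, w)
        return self

    def topology_of(self, i: int) -> MoleculeTopology:
        return self.topologies[self.poses[i].topology_ref]

    def site_positions(self, i: int) -> np.ndarray:
        return self.poses[i].site_positions(self.topology_of(i))

    def template_index(self) -> int:
        idx = [i for i, p in enumerate(self.poses)
               if self.topologies[p.topology_ref].role == "template"]
        if not idx:
            raise TopologyError("configuration contains no template molecule")
        return idx[0]

    def copy(self) -> "Configuration":
        return Configuration(
            box=self.box.copy(),
            poses=[MoleculePose(p.topology_ref, p.position.copy(),
                                p.orientation.copy()) for p in self.poses],
            topologies=self.topologies,
            temperature=self.temperature,
            pressure=self.pressure,
        )


@dataclass
class TrajectoryFrame:
    """One recorded snapshot of a simulation run."""

    run_id: int
    step: int
    configuration: Configuration
    potential_energy: float
    volume: float

    def __post_init__(self) -> None:
        if self.step < 0:
            raise TrajectoryError("frame step must be >= 0")
        box_volume = self.configuration.volume
        if abs(self.volume - box_volume) > 1e-6 * max(1.0, abs(box_volume)):
            raise TrajectoryError(
                f"frame volume {self.volume} inconsistent with box volume "
                f"{box_volume}")


# ---------------------------------------------------------------------------
# topology file I/O
# ---------------------------------------------------------------------------

_TOPOLOGY_MAGIC = "# emip topology v1"


def write_topology(topology: MoleculeTopology, path) -> None:
    """Write a topology file.

    Layout (fixed formatting, so ``read → write`` is byte-identical)::

        # emip topology v1
        name = <name>
        role = <template|monomer|solvent>
        net_charge = <%.6f>
        nsites = <int>
        # label element sigma epsilon charge x y z
        <label> <element> <%.6f ×6>
    """
    lines = [
        _TOPOLOGY_MAGIC,
        f"name = {topology.name}",
        f"role = {topology.role}",
        f"net_charge = {topology.net_charge:.6f}",
        f"nsites = {topology.n_sites}",
        "# label element sigma epsilon charge x y z",
    ]
    for s in topology.sites:
        x, y, z = s.local_position
        lines.append(
            f"{s.label} {s.element} {s.sigma:.6f} {s.epsilon:.6f} "
            f"{s.charge:.6f} {x:.6f} {y:.6f} {z:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_topology(path) -> MoleculeTopology:
    """Read and validate a topology file written by :func:`write_topology`."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    header: dict[str, str] = {}
    site_lines: list[tuple[int, str]] = []
    in_sites = False
    for lineno, line in enumerate(raw, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if not in_sites:
            if "=" not in stripped:
                raise TopologyError(
                    f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = stripped.partition("=")
            header[key.strip()] = value.strip()
            if key.strip() == "nsites":
                in_sites = True
        else:
            site_lines.append((lineno, stripped))
    for key in ("name", "role", "net_charge", "nsites"):
        if key not in header:
            raise TopologyError(f"{path}: missing header field {key!r}")
    try:
        nsites = int(header["nsites"])
        net_charge = float(header["net_charge"])
    except ValueError as exc:
        raise TopologyError(f"{path}: bad numeric header field: {exc}") from exc
    if len(site_lines) != nsites:
        raise TopologyError(
            f"{path}: header declares {nsites} sites but found "
            f"{len(site_lines)} site lines")
    sites = []
    for lineno, line in site_lines:
        parts = line.split()
        if len(parts) != 8:
            raise TopologyError(
                f"{path}:{lineno}: site line needs 8 fields "
                "(label element sigma epsilon charge x y z)")
        label, element = parts[0], parts[1]
        try:
            nums = [float(v) for v in parts[2:]]
        except ValueError as exc:
            raise TopologyError(
                f"{path}:{lineno}: non-numeric site field: {exc}") from exc
        sites.append(SiteParams(label, element, nums[0], nums[1], nums[2],
                                np.array(nums[3:6])))
    return MoleculeTopology(header["name"], header["role"], sites, net_charge)


# ---------------------------------------------------------------------------
# trajectory I/O (extended-XYZ dialect)
# ---------------------------------------------------------------------------

def _compress_composition(poses: Sequence[MoleculePose]) -> str:
    runs: list[tuple[str, int]] = []
    for p in poses:
        if runs and runs[-1][0] == p.topology_ref:
            runs[-1] = (p.topology_ref, runs[-1][1] + 1)
        else:
            runs.append((p.topology_ref, 1))
    return ",".join(f"{name}:{count}" for name, count in runs)


def _expand_composition(text: str) -> list[str]:
    names: list[str] = []
    for token in text.split(","):
        name, _, count = token.partition(":")
        if not count:
            raise TrajectoryError(f"malformed mols token {token!r}")
        names.extend([name] * int(count))
    return names


def _pose_from_sites(topology: MoleculeTopology,
                     world: np.ndarray) -> MoleculePose:
    """Recover a rigid pose from world-frame site coordinates (Kabsch)."""
    local = topology.local_coords
    if topology.n_sites == 1:
        return MoleculePose(topology.name, world[0], IDENTITY_QUAT.copy())
    c_local = local.mean(axis=0)
    c_world = world.mean(axis=0)
    with warnings.catch_warnings():
        # collinear molecules: any rotation in the degenerate subspace is
        # valid; site coordinates still round-trip
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(world - c_world, local - c_local)
    position = c_world - rot.apply(c_local)
    quat = rot.as_quat()
    quat = quat / np.linalg.norm(quat)
    return MoleculePose(topology.name, position, quat)


def write_trajectory(frames: Sequence[TrajectoryFrame], path) -> None:
    """Write frames as one extended-XYZ block per frame.

    Requires a nonempty frame list with strictly increasing step indices
    within each ``run_id``.
    """
    frames = list(frames)
    if not frames:
        raise TrajectoryError("cannot write an empty trajectory")
    last_step: dict[int, int] = {}
    for f in frames:
        if f.run_id in last_step and f.step <= last_step[f.run_id]:
            raise TrajectoryError(
                f"non-monotone step indices in run {f.run_id}: "
                f"{last_step[f.run_id]} then {f.step}")
        last_step[f.run_id] = f.step
    with open(path, "w") as fh:
        for f in frames:
            cfg = f.configuration
            natoms = sum(cfg.topology_of(i).n_sites
                         for i in range(cfg.n_molecules))
            bx, by, bz = cfg.box
            comment = (
                f'run_id={f.run_id} step={f.step} '
                f'box="{bx:.12f} {by:.12f} {bz:.12f}" '
                f'energy={f.potential_energy:.12g} '
                f'temperature={cfg.temperature:.6f} '
                f'pressure={cfg.pressure:.6f} '
                f'mols="{_compress_composition(cfg.poses)}"')
            fh.write(f"{natoms}\n{comment}\n")
            for i in range(cfg.n_molecules):
                topo = cfg.topology_of(i)
                coords = cfg.site_positions(i)
                for s, (x, y, z) in zip(topo.sites, coords):
                    fh.write(f"{s.element} {x:.12f} {y:.12f} {z:.12f}\n")


def read_trajectory(path, topologies: Mapping[str, MoleculeTopology]
                    ) -> list[TrajectoryFrame]:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`.

    ``topologies`` must contain every molecule name referenced in the
    per-frame composition metadata; poses are rebuilt from the site
    coordinates by rigid superposition.
    """
    frames: list[TrajectoryFrame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise TrajectoryError(
                f"{path}:{pos + 1}: expected atom count, got "
                f"{lines[pos]!r}") from exc
        if pos + 1 >= len(lines):
            raise TrajectoryError(f"{path}: truncated frame at line {pos + 1}")
        meta = dict(
            token.partition("=")[::2]
            for token in shlex.split(lines[pos + 1]))
        for key in ("run_id", "step", "box", "energy", "mols"):
            if key not in meta:
                raise TrajectoryError(
                    f"{path}:{pos + 2}: frame comment missing {key!r}")
        box = np.array([float(v) for v in meta["box"].split()])
        names = _expand_composition(meta["mols"])
        body = lines[pos + 2: pos + 2 + natoms]
        if len(body) != natoms:
            raise TrajectoryError(
                f"{path}: frame at line {pos + 1} declares {natoms} atoms "
                f"but only {len(body)} lines remain")
        coords = np.empty((natoms, 3))
        for k, line in enumerate(body):
            parts = line.split()
            if len(parts) != 4:
                raise TrajectoryError(
                    f"{path}:{pos + 3 + k}: malformed atom line {line!r}")
            coords[k] = [float(v) for v in parts[1:]]
        poses: list[MoleculePose] = []
        cursor = 0
        for name in names:
            if name not in topologies:
                raise TrajectoryError(
                    f"{path}: unknown topology {name!r} in frame composition")
            topo = topologies[name]
            poses.append(_pose_from_sites(
                topo, coords[cursor:cursor + topo.n_sites]))
            cursor += topo.n_sites
        if cursor != natoms:
            raise TrajectoryError(
                f"{path}: composition accounts for {cursor} atoms but frame "
                f"has {natoms}")
        cfg = Configuration(
            box=box,
            poses=poses,
            topologies=topologies,
            temperature=float(meta.get("temperature", 298.0)),
            pressure=float(meta.get("pressure", 1.0)),
        )
        frames.append(TrajectoryFrame(
            run_id=int(meta["run_id"]),
            step=int(meta["step"]),
            configuration=cfg,
            potential_energy=float(meta["energy"]),
            volume=cfg.volume,
        ))
        pos += 2 + natoms
    return frames
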