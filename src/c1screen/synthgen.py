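"""Synthetic bilayer + ligand trajectory generator with known ground truth.

The generator emulates, at reduced scale, the assay-mimicking membrane
system used for candidate screening — an anionic bilayer patch with water,
K⁺ counterions, and four copies of the ligand candidate placed with lateral
separation — so the whole analysis pipeline can be exercised and validated
without running molecular dynamics. Frames are independent draws from
configured tilt/depth distributions, not dynamics: every downstream
observable is a time average of configurational quantities, so an emulator
with exactly known per-frame ground truth is the right test substrate.

Components per frame:

* pseudo-lipids — three-bead chains, head bead at the ±phosphate-plane
  height with small jitter, two tail beads stacked toward the bilayer
  center;
* waters — three-site molecules uniform in the two slabs outside the
  membrane, randomly oriented;
* ions — K⁺ scattered through the water slabs;
* ligand copies — a rigid toy template (aromatic core ring, hydroxymethyl
  arm, two carbonyl-type oxygens) rotated to a tilt drawn per frame from
  the configured distribution (inverted with ``flip_probability``) and
  translated so its hydroxy-group COM sits at the drawn depth;
* hydrogen-bond events — with probability ``hbond_rate`` per copy per
  frame a probe water is teleported to ideal acceptor geometry against the
  hydroxy group (r = 0.30 nm, H-D-A angle 0°);
* cluster episodes — for the configured fraction of frames, copy 1 is
  re-placed as a laterally shifted image of copy 0 at 0.3 nm, forming a
  transient dimer.

The ground-truth record stores every drawn angle, depth, and event, so
tests can compare recovered observables against exact inputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ConfigError
from .geometry import LigandSpec
from .trajio import AtomTable, Frame, SelectionGroups, Trajectory

__all__ = [
    "LigandTemplate",
    "ScenarioConfig",
    "generate_scenario",
    "reference_scenarios",
    "paper_scale",
    "HMI_LIKE_TEMPLATE",
    "NO_OH_TEMPLATE",
]


@dataclass
class LigandTemplate:
    """Rigid toy ligand in local coordinates (molecular axis = local +z)."""

    names: list[str]
    coords: np.ndarray  # (n, 3) nm
    bonds: list[tuple[int, int]]  # local indices
    tail: list[int]  # core-ring atoms (axis tail)
    head: list[int]  # hydroxy oxygen (axis head)
    oh: list[int] | None  # hydroxy O + H
    oono: list[int] | None  # carbonyl-type oxygens
    donors: list[tuple[int, int]]  # (D, H) local pairs
    acceptors: list[int]

    @property
    def n_atoms(self) -> int:
        return len(self.names)


def _hexagon(radius: float) -> np.ndarray:
    ang = np.radians(np.arange(6) * 60.0)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def _make_hmi_like_template() -> LigandTemplate:
    ring = _hexagon(0.14)
    coords = np.vstack(
        [
            ring,  # 0..5 core ring
            [0.0, 0.0, 0.30],  # 6 C7 hydroxymethyl carbon
            [0.0, 0.0, 0.43],  # 7 O1 hydroxy oxygen
            [0.0, 0.0, 0.53],  # 8 HO1 hydroxy hydrogen
            [0.25, 0.0, 0.05],  # 9 OE1 carbonyl oxygen
            [-0.25, 0.0, 0.05],  # 10 OE2 carbonyl oxygen
        ]
    )
    names = ["C1", "C2", "C3", "C4", "C5", "C6", "C7", "O1", "HO1", "OE1", "OE2"]
    bonds = [(i, (i + 1) % 6) for i in range(6)] + [
        (0, 6),
        (6, 7),
        (7, 8),
        (1, 9),
        (4, 10),
    ]
    return LigandTemplate(
        names=names,
        coords=coords,
        bonds=bonds,
        tail=list(range(6)),
        head=[7],
        oh=[7, 8],
        oono=[9, 10],
        donors=[(7, 8)],
        acceptors=[7, 9, 10],
    )


def _make_no_oh_template() -> LigandTemplate:
    """Control-compound analog lacking the hydroxymethyl oxygen/hydrogen."""
    full = _make_hmi_like_template()
    keep = [0, 1, 2, 3, 4, 5, 6, 9, 10]
    remap = {g: i for i, g in enumerate(keep)}
    return LigandTemplate(
        names=[full.names[i] for i in keep],
        coords=full.coords[keep],
        bonds=[(remap[a], remap[b]) for a, b in full.bonds if a in remap and b in remap],
        tail=list(range(6)),
        head=[remap[6]],  # hydroxymethyl carbon stands in as the axis head
        oh=None,
        oono=[remap[9], remap[10]],
        donors=[],
        acceptors=[remap[9], remap[10]],
    )


HMI_LIKE_TEMPLATE = _make_hmi_like_template()
NO_OH_TEMPLATE = _make_no_oh_template()


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic trajectory.

    Defaults are a reduced-scale patch (16 pseudo-lipids, 400 waters, 8 K⁺,
    4 ligand copies) whose 200 frames at 7.5 ns spacing span 1500 ns, so the
    standard 5-block statistics use 300 ns blocks. ``paper_scale`` swaps in
    the full assay-mimicking counts (128 lipids, 6400 waters, 128 K⁺).
    """

    name: str = "custom"
    n_lipids: int = 16
    n_waters: int = 400
    n_ions: int = 8
    n_ligand_copies: int = 4
    box_xy: float = 4.0  # nm lateral edge
    box_z: float = 7.0  # nm
    phosphate_plane: float = 2.0  # nm, head-bead height above/below center
    tilt_mean: float = 30.0  # degrees
    tilt_sd: float = 8.0
    depth_mean: float = 1.65  # nm
    depth_sd: float = 0.08
    flip_probability: float = 0.0
    hbond_rate: float = 0.0  # per copy per frame
    cluster_episode: bool = False
    cluster_fraction: float = 0.0  # fraction of frames with the 0-1 dimer
    has_oh: bool = True
    n_frames: int = 200
    frame_dt: float = 7500.0  # ps (7.5 ns)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_lipids", "n_waters", "n_ions", "n_ligand_copies", "n_frames"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be >= 0")
        for f in ("flip_probability", "hbond_rate", "cluster_fraction"):
            if not (0.0 <= getattr(self, f) <= 1.0):
                raise ConfigError(f"{f} must be in [0, 1]")
        if self.n_lipids % 2:
            raise ConfigError("n_lipids must be even (half per leaflet)")
        if self.tilt_sd <= 0 or self.depth_sd <= 0:
            raise ConfigError("distribution SDs must be positive")
        if self.phosphate_plane * 2 + 0.8 > self.box_z:
            raise ConfigError("box_z too small for the requested phosphate planes")

    def template(self) -> LigandTemplate:
        return HMI_LIKE_TEMPLATE if self.has_oh else NO_OH_TEMPLATE


def paper_scale(cfg: ScenarioConfig) -> ScenarioConfig:
    """The same scenario at the full assay-mimicking system size."""
    d = asdict(cfg)
    d.update(
        n_lipids=128, n_waters=6400, n_ions=128, n_ligand_copies=4,
        box_xy=6.4, box_z=9.0,
    )
    return ScenarioConfig(**d)


def _grid_sites(n: int, edge: float) -> np.ndarray:
    """n approximately uniform lateral sites on a square grid."""
    side = int(np.ceil(np.sqrt(n)))
    xs = (np.arange(side) + 0.5) * edge / side
    pts = np.array([(x, y) for y in xs for x in xs])
    return pts[:n]


def _rotation(alpha: float, phi: float, psi: float) -> np.ndarray:
    """Rz(phi) @ Ry(alpha) @ Rz(psi)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cf, sf = np.cos(phi), np.sin(phi)
    cp, sp = np.cos(psi), np.sin(psi)
    ry = np.array([[ca, 0, sa], [0, 1, 0], [-sa, 0, ca]])
    rz_f = np.array([[cf, -sf, 0], [sf, cf, 0], [0, 0, 1]])
    rz_p = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]])
    return rz_f @ ry @ rz_p


def _random_water_frame(rng: np.random.Generator) -> np.ndarray:
    """Random rigid orientation of a 3-site water (O at origin), O-H 0.1 nm."""
    half = np.radians(104.5 / 2.0)
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.1 * np.sin(half), 0.0, 0.1 * np.cos(half)],
            [-0.1 * np.sin(half), 0.0, 0.1 * np.cos(half)],
        ]
    )
    a, b, c = rng.uniform(0, 2 * np.pi, 3)
    return local @ _rotation(b, a, c).T


def _build_atom_table(cfg: ScenarioConfig) -> tuple[AtomTable, dict]:
    tpl = cfg.template()
    names, resnames, resids = [], [], []
    resid = 0
    layout: dict = {}

    start = 0
    for _ in range(cfg.n_lipids):
        resid += 1
        names += ["OP", "C1", "C2"]
        resnames += ["LIP"] * 3
        resids += [resid] * 3
    layout["lipids"] = np.arange(start, start + 3 * cfg.n_lipids)
    start += 3 * cfg.n_lipids

    for _ in range(cfg.n_waters):
        resid += 1
        names += ["OW", "HW1", "HW2"]
        resnames += ["SOL"] * 3
        resids += [resid] * 3
    layout["water"] = np.arange(start, start + 3 * cfg.n_waters)
    start += 3 * cfg.n_waters

    for _ in range(cfg.n_ions):
        resid += 1
        names.append("K")
        resnames.append("K")
        resids.append(resid)
    layout["ions"] = np.arange(start, start + cfg.n_ions)
    start += cfg.n_ions

    lig_starts = []
    for _ in range(cfg.n_ligand_copies):
        resid += 1
        lig_starts.append(start)
        names += tpl.names
        resnames += ["LIG"] * tpl.n_atoms
        resids += [resid] * tpl.n_atoms
        start += tpl.n_atoms
    layout["ligand_starts"] = lig_starts
    layout["ligands"] = (
        np.concatenate([np.arange(s, s + tpl.n_atoms) for s in lig_starts])
        if lig_starts
        else np.empty(0, dtype=int)
    )
    return AtomTable.from_names(names, resnames, resids), layout


def ligand_spec_from_config(cfg: ScenarioConfig, layout: dict) -> LigandSpec:
    tpl = cfg.template()
    starts = layout["ligand_starts"]

    def g(local) -> list[np.ndarray]:
        return [np.asarray(local, dtype=int) + s for s in starts]

    return LigandSpec(
        resname="LIG",
        n_copies=cfg.n_ligand_copies,
        all_atoms=g(range(tpl.n_atoms)),
        axis_tail=g(tpl.tail),
        axis_head=g(tpl.head),
        oh_group=g(tpl.oh) if tpl.oh is not None else None,
        oono_group=g(tpl.oono) if tpl.oono is not None else None,
        donors=[[(d + s, h + s) for d, h in tpl.donors] for s in starts],
        acceptors=g(tpl.acceptors),
        bonds=[[(a + s, b + s) for a, b in tpl.bonds] for s in starts],
    )


def generate_scenario(cfg: ScenarioConfig):
    """Generate (Trajectory, SelectionGroups, ground_truth) for a scenario.

    Deterministic given ``cfg.seed``. The ground-truth dict records the
    drawn tilt (degrees, measured from the leaflet outward normal), depth
    (nm), leaflet, flip flags, injected H-bond events, and dimer frames.
    """
    if cfg.n_ligand_copies < 1:
        raise ConfigError("need at least one ligand copy")
    if cfg.cluster_episode and cfg.n_ligand_copies < 2:
        raise ConfigError("cluster episodes need at least two ligand copies")
    rng = np.random.default_rng(cfg.seed)
    tpl = cfg.template()
    atoms, layout = _build_atom_table(cfg)
    masses = atoms.mass

    box = np.array([cfg.box_xy, cfg.box_xy, cfg.box_z])
    z_mid = cfg.box_z / 2.0
    water_gap = cfg.phosphate_plane + 0.2  # waters only outside |z| > gap
    half_lip = cfg.n_lipids // 2
    lip_sites = _grid_sites(half_lip, cfg.box_xy)

    n_up = (cfg.n_ligand_copies + 1) // 2
    lig_leaflet = ["upper" if c < n_up else "lower" for c in range(cfg.n_ligand_copies)]
    upper_sites = _grid_sites(max(n_up, 1), cfg.box_xy) * [1.0, 0.5] + [0.0, cfg.box_xy * 0.0]
    lower_sites = _grid_sites(max(cfg.n_ligand_copies - n_up, 1), cfg.box_xy) * [1.0, 0.5] + [
        0.0,
        cfg.box_xy * 0.5,
    ]
    lig_sites = [
        upper_sites[c] if c < n_up else lower_sites[c - n_up]
        for c in range(cfg.n_ligand_copies)
    ]

    # mass-weighted local COM of the placement group (OH if present, else all)
    place_local = np.asarray(tpl.oh if tpl.oh is not None else range(tpl.n_atoms), dtype=int)
    tpl_masses = masses[layout["ligand_starts"][0] : layout["ligand_starts"][0] + tpl.n_atoms]
    pm = tpl_masses[place_local]
    local_place_com = (tpl.coords[place_local] * pm[:, None]).sum(axis=0) / pm.sum()

    n_frames = cfg.n_frames
    gt_theta = np.zeros((n_frames, cfg.n_ligand_copies))
    gt_depth = np.zeros((n_frames, cfg.n_ligand_copies))
    gt_flip = np.zeros((n_frames, cfg.n_ligand_copies), dtype=bool)
    gt_hbond = np.zeros((n_frames, cfg.n_ligand_copies), dtype=bool)
    gt_dimer = np.zeros(n_frames, dtype=bool)

    frames: list[Frame] = []
    n_atoms = atoms.n_atoms
    for f in range(n_frames):
        coords = np.zeros((n_atoms, 3))

        # lipids: half per leaflet, head bead at ±phosphate_plane, tails inward
        for leaf, zsign in (("upper", 1.0), ("lower", -1.0)):
            for li in range(half_lip):
                idx = layout["lipids"][
                    3 * (li + (0 if leaf == "upper" else half_lip)) : 3
                    * (li + (0 if leaf == "upper" else half_lip))
                    + 3
                ]
                xy = lip_sites[li] + rng.normal(0, 0.05, 2)
                zs = z_mid + zsign * (
                    np.array([cfg.phosphate_plane, cfg.phosphate_plane * 2 / 3,
                              cfg.phosphate_plane / 3])
                    + rng.normal(0, 0.03, 3)
                )
                coords[idx, 0] = xy[0] + rng.normal(0, 0.02, 3)
                coords[idx, 1] = xy[1] + rng.normal(0, 0.02, 3)
                coords[idx, 2] = zs

        # waters: uniform in the two slabs outside the membrane
        if cfg.n_waters:
            w_idx = layout["water"].reshape(cfg.n_waters, 3)
            half_slab = cfg.box_z / 2.0 - water_gap
            off = rng.uniform(0, half_slab, cfg.n_waters)
            side = np.where(rng.random(cfg.n_waters) < 0.5, 1.0, -1.0)
            oz = z_mid + side * (water_gap + off)
            oxy = rng.uniform(0, cfg.box_xy, (cfg.n_waters, 2))
            for w in range(cfg.n_waters):
                mol = _random_water_frame(rng) + np.array([oxy[w, 0], oxy[w, 1], oz[w]])
                coords[w_idx[w]] = mol

        # ions among the waters
        if cfg.n_ions:
            half_slab = cfg.box_z / 2.0 - water_gap
            ioff = rng.uniform(0, half_slab, cfg.n_ions)
            iside = np.where(rng.random(cfg.n_ions) < 0.5, 1.0, -1.0)
            coords[layout["ions"], 0] = rng.uniform(0, cfg.box_xy, cfg.n_ions)
            coords[layout["ions"], 1] = rng.uniform(0, cfg.box_xy, cfg.n_ions)
            coords[layout["ions"], 2] = z_mid + iside * (water_gap + ioff)

        # ligand copies: draw tilt/depth, rotate rigid template, translate.
        # depths are placed relative to the realized lipid COM of this frame
        # so the recorded ground truth is exact, not jittered.
        if cfg.n_lipids:
            from .geometry import pbc_com_z

            z_ref = pbc_com_z(
                coords[layout["lipids"], 2], masses[layout["lipids"]], cfg.box_z
            )
        else:
            z_ref = z_mid
        dimer = bool(cfg.cluster_episode and rng.random() < cfg.cluster_fraction)
        gt_dimer[f] = dimer
        copy_R = []
        copy_t = []
        for c in range(cfg.n_ligand_copies):
            theta = float(np.clip(rng.normal(cfg.tilt_mean, cfg.tilt_sd), 0.0, 180.0))
            flipped = bool(rng.random() < cfg.flip_probability)
            if flipped:
                theta = 180.0 - theta
            depth = float(
                np.clip(rng.normal(cfg.depth_mean, cfg.depth_sd), 0.3, cfg.box_z / 2 - 0.2)
            )
            phi, psi = rng.uniform(0, 2 * np.pi, 2)
            leaf = lig_leaflet[c]
            alpha = np.radians(theta if leaf == "upper" else 180.0 - theta)
            R = _rotation(alpha, phi, psi)
            zsign = 1.0 if leaf == "upper" else -1.0
            target = np.array(
                [lig_sites[c][0], lig_sites[c][1], z_ref + zsign * depth]
            )
            t = target - R @ local_place_com

            if dimer and c == 1:
                # copy 1 becomes a laterally shifted image of copy 0 at 0.3 nm
                R = copy_R[0]
                t = copy_t[0] + np.array([0.3, 0.0, 0.0])
                theta = gt_theta[f, 0]
                depth = gt_depth[f, 0]
                flipped = gt_flip[f, 0]

            start = layout["ligand_starts"][c]
            coords[start : start + tpl.n_atoms] = tpl.coords @ R.T + t
            copy_R.append(R)
            copy_t.append(t)
            gt_theta[f, c] = theta
            gt_depth[f, c] = depth
            gt_flip[f, c] = flipped

            # ideal-geometry H-bond event: probe water teleported onto the OH
            if tpl.oh is not None and cfg.n_waters > cfg.n_ligand_copies:
                if rng.random() < cfg.hbond_rate:
                    gt_hbond[f, c] = True
                    o1 = start + tpl.oh[0]
                    h1 = start + tpl.oh[1]
                    u = coords[h1] - coords[o1]
                    u /= np.linalg.norm(u)
                    w = np.array([1.0, 0.0, 0.0])
                    if abs(u @ w) > 0.9:
                        w = np.array([0.0, 1.0, 0.0])
                    perp = np.cross(u, w)
                    perp /= np.linalg.norm(perp)
                    ow = coords[o1] + 0.30 * u
                    ang = np.radians(104.5)
                    widx = layout["water"].reshape(cfg.n_waters, 3)[c]
                    coords[widx[0]] = ow
                    coords[widx[1]] = ow + 0.1 * u
                    coords[widx[2]] = ow + 0.1 * (np.cos(ang) * u + np.sin(ang) * perp)

        coords = np.mod(coords, box)  # wrap into the primary cell (GRO convention)
        frames.append(Frame(time=f * cfg.frame_dt, box=box.copy(), coords=coords))

    traj = Trajectory(atoms=atoms, frames=frames)
    spec = ligand_spec_from_config(cfg, layout)
    groups: SelectionGroups = {
        "lipids": layout["lipids"],
        "water": layout["water"],
        "ions": layout["ions"],
        "ligands": layout["ligands"],
    }
    groups.update(spec.to_selection_groups())

    ground_truth = {
        "config": asdict(cfg),
        "leaflet": lig_leaflet,
        "theta": gt_theta,
        "depth": gt_depth,
        "flipped": gt_flip,
        "hbond_event": gt_hbond,
        "dimer_frame": gt_dimer,
    }
    return traj, groups, ground_truth


def reference_scenarios(seed: int = 0) -> dict[str, ScenarioConfig]:
    """Built-in reference scenarios.

    ``hmi_like`` emulates the positive-control population (hydroxy group
    near the headgroups, small tilt), ``pyr_like`` the internally
    hydrogen-bonded negative control (flipped, deep), ``ambiguous`` sits in
    the classifier's gap, and ``no_hydroxymethyl`` exercises the
    control-compound path lacking the hydroxy group.
    """
    return {
        "hmi_like": ScenarioConfig(
            name="hmi_like",
            tilt_mean=30.0,
            tilt_sd=8.0,
            depth_mean=1.65,
            depth_sd=0.08,
            flip_probability=0.05,
            hbond_rate=0.8,
            cluster_episode=True,
            cluster_fraction=0.2,
            seed=seed,
        ),
        "pyr_like": ScenarioConfig(
            name="pyr_like",
            tilt_mean=150.0,
            tilt_sd=8.0,
            depth_mean=1.00,
            depth_sd=0.08,
            flip_probability=0.05,
            hbond_rate=0.3,
            seed=seed,
        ),
        "ambiguous": ScenarioConfig(
            name="ambiguous",
            tilt_mean=90.0,
            tilt_sd=10.0,
            depth_mean=1.30,
            depth_sd=0.10,
            hbond_rate=0.5,
            seed=seed,
        ),
        "no_hydroxymethyl": ScenarioConfig(
            name="no_hydroxymethyl",
            tilt_mean=30.0,
            tilt_sd=8.0,
            depth_mean=1.65,
            depth_sd=0.08,
            has_oh=False,
            seed=seed,
        ),
    }
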