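"""Synthetic amorphous ensembles with known ground truth.

Real inputs to the pipeline are force-field MD ensembles of a
flexible drug-like molecule plus machine-learned shift predictions;
neither carries ground truth.  This module generates toy analogues
with every answer known in advance: a 12-atom model molecule with a
hydroxyl donor (O1-H1), a rigid 4-atom ring, a flexible 4-torsion
linker and an intramolecular nitrogen acceptor (N53); a two-basin
torsion mixture planting a known fraction of molecules in the
H-bond-closed conformation; a closed-form geometry -> shift surrogate
with Gaussian noise; and "experimental" distributions derived from
the planted subpopulation.  Every pipeline stage can then be tested
for recovery of the planted signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import Atom, Frame, Molecule, dihedral
from .scoring import EnvironmentShifts
from .spectra import ShiftDistribution, nucleus_of

__all__ = [
    "ToyMolecule",
    "SyntheticConfig",
    "GroundTruth",
    "build_molecule",
    "generate_toy_ensemble",
    "surrogate_shifts",
    "plant_experimental_distributions",
    "make_benchmark_case",
    "TORSION_NAMES",
    "CLOSED_BASIN",
    "OPEN_BASIN",
]

#: Rotatable torsions of the linker, named by their defining atom quadruples.
TORSION_NAMES = (
    "O1-C2-C7-C8",    # tau1
    "C2-C7-C8-C9",    # tau2 - the reporter torsion locking the H-bond
    "C7-C8-C9-N53",   # tau3
    "H1-O1-C2-C7",    # tau4 - hydroxyl rotation
)

# Torsion basin centres (degrees).  The closed basin folds the linker so
# the O1-H1 donor points at N53 with r(H1...N53) = 1.90 Angstrom and a
# near-linear O1-H1...N53 angle of 163 deg (solved once from the template
# geometry); the open basin is all-trans with r(H1...N53) = 6.81 Angstrom.
# With the default 5 deg basin width and 2.3-sigma jitter truncation the
# closed basin stays below 2.44 Angstrom and the open basin above 6.7.
CLOSED_BASIN = (4.95, 43.36, -127.06, -17.55)
OPEN_BASIN = (180.0, 180.0, 180.0, 180.0)

#: Torsion jitter is truncated at this many basin widths so basin
#: membership implies a hard geometric bound on r(H1...N53).
JITTER_TRUNCATION = 2.3


@dataclass(frozen=True)
class ToyMolecule:
    """Internal-coordinate template of the 12-atom model molecule.

    Each atom after the third is placed from (parent, ref, ref2) by
    bond length (Angstrom), bond angle and torsion (degrees); the four
    linker torsions are the free parameters, everything else is rigid.
    """

    # (label, element, parent, ref, ref2, bond, angle, torsion)
    # torsion is a fixed number or the name of a free torsion
    zmatrix: tuple = (
        ("O1", "O", None, None, None, 0.0, 0.0, 0.0),
        ("C2", "C", "O1", None, None, 1.36, 0.0, 0.0),
        ("C7", "C", "C2", "O1", None, 1.50, 120.0, 0.0),
        ("C8", "C", "C7", "C2", "O1", 1.50, 112.0, "O1-C2-C7-C8"),
        ("C9", "C", "C8", "C7", "C2", 1.50, 112.0, "C2-C7-C8-C9"),
        ("N53", "N", "C9", "C8", "C7", 1.47, 112.0, "C7-C8-C9-N53"),
        ("H1", "H", "O1", "C2", "C7", 0.97, 105.0, "H1-O1-C2-C7"),
        ("C3", "C", "C2", "C7", "O1", 1.40, 120.0, 180.0),
        ("C4", "C", "C3", "C2", "C7", 1.40, 120.0, 180.0),
        ("C5", "C", "C4", "C3", "C2", 1.40, 120.0, 0.0),
        ("C50", "C", "N53", "C9", "C8", 1.47, 112.0, 180.0),
        ("O49", "O", "C50", "N53", "C9", 1.23, 120.0, 0.0),
    )

    @property
    def labels(self):
        return tuple(row[0] for row in self.zmatrix)

    @property
    def elements(self):
        return tuple(row[1] for row in self.zmatrix)


DEFAULT_TEMPLATE = ToyMolecule()

#: Ring carbons whose surrogate shift couples to the reporter torsion.
RING_CARBONS = ("C3", "C4", "C5")

#: Baseline shifts delta0 (ppm) of the sites carrying predictions.
DEFAULT_BASELINES = {
    "H1": 5.0,
    "C2": 155.0,
    "C3": 120.0,
    "C4": 128.0,
    "C5": 126.0,
    "C7": 35.0,
    "C8": 30.0,
    "C9": 28.0,
    "C50": 45.0,
    "N53": 250.0,
}

#: Sites whose "experimental" distributions are fitted and scored.
DEFAULT_SCORED_SITES = ("H1", "N53", "C3", "C4", "C5", "C7")


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom X with |X-a| = bond, angle(X,a,b) = angle, dih(X,a,b,c) = torsion."""
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    u = a - b
    u = u / np.linalg.norm(u)
    w = c - b
    wp = w - np.dot(w, u) * u
    m = wp / np.linalg.norm(wp)
    nvec = np.cross(m, u)
    return a + bond * (-math.cos(theta) * u
                       + math.sin(theta) * (math.cos(phi) * m + math.sin(phi) * nvec))


def build_molecule(torsions, template=DEFAULT_TEMPLATE, index=0):
    """Reconstruct Cartesian geometry from the four linker torsions.

    Parameters
    ----------
    torsions : dict or sequence
        Mapping torsion-name -> degrees, or the four values in
        ``TORSION_NAMES`` order.

    Returns
    -------
    Molecule
    """
    if not isinstance(torsions, dict):
        torsions = dict(zip(TORSION_NAMES, torsions))
    pos = {}
    rows = template.zmatrix
    # first three atoms define the frame
    pos[rows[0][0]] = np.zeros(3)
    pos[rows[1][0]] = np.array([rows[1][5], 0.0, 0.0])
    th = math.radians(rows[2][6])
    pos[rows[2][0]] = pos[rows[1][0]] + rows[2][5] * np.array(
        [-math.cos(th), math.sin(th), 0.0]
    )
    for label, el, parent, ref, ref2, bond, angle, tors in rows[3:]:
        phi = torsions[tors] if isinstance(tors, str) else tors
        pos[label] = _place_atom(pos[parent], pos[ref], pos[ref2], bond, angle, phi)
    atoms = [Atom(label=row[0], element=row[1], xyz=tuple(pos[row[0]]))
             for row in rows]
    return Molecule(index=index, atoms=atoms)


def donor_acceptor_distance(mol):
    """r(H1...N53) in Angstrom."""
    return float(np.linalg.norm(mol.position("H1") - mol.position("N53")))


def reporter_torsion(mol):
    """The C2-C7-C8-C9 dihedral (degrees)."""
    return dihedral(*(mol.position(l) for l in ("C2", "C7", "C8", "C9")))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic benchmark.

    Defaults give 4 runs x 50 frames x 25 molecules = 5,000
    environments in a 40 Angstrom cubic box, a 0.40 closed-basin
    fraction, and the closed-form shift surrogate with 0.2 ppm noise.
    """

    n_runs: int = 4
    n_frames: int = 50
    molecules_per_frame: int = 25
    box_edge: float = 40.0  # Angstrom
    min_center_distance: float = 9.0  # Angstrom, placement exclusion
    bias_fraction: float = 0.40
    closed_center: tuple = CLOSED_BASIN
    open_center: tuple = OPEN_BASIN
    basin_width: float = 5.0  # degrees, common to all torsions
    # shift surrogate
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    hbond_amplitude: float = 8.0   # ppm, on H1
    hbond_amplitude_n: float = 15.0  # ppm, on N53
    decay_length: float = 1.0      # Angstrom
    torsion_amplitude: float = 3.0  # ppm, on ring carbons
    noise_sigma: float = 0.2       # ppm
    scored_sites: tuple = DEFAULT_SCORED_SITES
    seed: int = 0
    max_placement_retries: int = 2000

    def __post_init__(self):
        if not 0.0 <= self.bias_fraction <= 1.0:
            raise ValueError("bias_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted per-environment truth, recomputable from emitted geometry."""

    basin: dict            # env_id -> "closed" | "open"
    torsions: dict         # env_id -> tuple of 4 degrees
    hbond_distance: dict   # env_id -> r(H1...N53), Angstrom
    bias_fraction: float

    def closed_fraction(self, env_ids=None):
        ids = list(self.basin) if env_ids is None else env_ids
        if not ids:
            raise ValueError("no environments")
        return sum(self.basin[e] == "closed" for e in ids) / len(ids)

    def to_json(self, path):
        obj = {
            "bias_fraction": self.bias_fraction,
            "environments": [
                {
                    "env_id": list(e),
                    "basin": self.basin[e],
                    "torsions": list(self.torsions[e]),
                    "hbond_distance": self.hbond_distance[e],
                }
                for e in self.basin
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _random_rotation(rng):
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _wrap180(x):
    return (x + 180.0) % 360.0 - 180.0


def generate_toy_ensemble(config: SyntheticConfig):
    """Generate the synthetic periodic ensemble and its ground truth.

    Each molecule's linker torsions are drawn from a two-basin wrapped
    Gaussian mixture ("closed", probability ``bias_fraction``, versus
    "open"); molecules are rigidly rotated and placed at non-overlapping
    random positions in a periodic cubic box.  Fully reproducible for a
    fixed seed.

    Returns
    -------
    (frames, truth) : (dict, GroundTruth)
        ``frames`` maps run_id -> list of Frame; environments are
        addressed (run_id, frame_index, molecule_index).
    """
    master = np.random.default_rng(config.seed)
    cell = np.eye(3) * config.box_edge
    frames = {}
    basin, torsions, hbond_dist = {}, {}, {}
    for run in range(config.n_runs):
        run_id = f"run{run}"
        rng = np.random.default_rng(master.integers(2**31))
        run_frames = []
        for fidx in range(config.n_frames):
            centers = _place_centers(rng, config)
            mols = []
            for midx in range(config.molecules_per_frame):
                closed = bool(rng.random() < config.bias_fraction)
                center = config.closed_center if closed else config.open_center
                bound = JITTER_TRUNCATION * config.basin_width
                jitter = np.clip(rng.normal(scale=config.basin_width, size=4),
                                 -bound, bound)
                taus = tuple(_wrap180(c + j) for c, j in zip(center, jitter))
                mol = build_molecule(taus, index=midx)
                coords = mol.coords()
                coords = coords - coords.mean(axis=0)
                coords = coords @ _random_rotation(rng).T + centers[midx]
                mol = Molecule(
                    index=midx,
                    atoms=[
                        Atom(label=a.label, element=a.element, xyz=tuple(xyz))
                        for a, xyz in zip(mol.atoms, coords)
                    ],
                )
                mols.append(mol)
                env = (run_id, fidx, midx)
                basin[env] = "closed" if closed else "open"
                torsions[env] = taus
                hbond_dist[env] = donor_acceptor_distance(mol)
            run_frames.append(Frame(molecules=mols, cell=cell.copy()))
        frames[run_id] = run_frames
    truth = GroundTruth(basin=basin, torsions=torsions,
                        hbond_distance=hbond_dist,
                        bias_fraction=config.bias_fraction)
    return frames, truth


def _place_centers(rng, config):
    """Random molecule centres with a minimum-image pairwise exclusion."""
    L = config.box_edge
    centers = []
    for _ in range(config.molecules_per_frame):
        for attempt in range(config.max_placement_retries):
            cand = rng.random(3) * L
            ok = True
            for c in centers:
                d = cand - c
                d -= L * np.round(d / L)
                if np.linalg.norm(d) < config.min_center_distance:
                    ok = False
                    break
            if ok:
                centers.append(cand)
                break
        else:
            raise RuntimeError(
                "could not place molecules without overlap; increase box_edge "
                "or lower min_center_distance"
            )
    return centers


def surrogate_shifts(frame, molecule_index, config, rng, env_id=None):
    """Closed-form geometry -> shift surrogate for one environment.

    delta(H1)  = delta0 + A_hb  * exp(-r(H1...N53)/r0) + eps
    delta(N53) = delta0 + A_hbN * exp(-r(H1...N53)/r0) + eps
    delta(ring C) = delta0 + B * cos(tau_reporter) + eps
    delta(other site) = delta0 + eps,   eps ~ N(0, noise_sigma^2)

    ``rng`` drives the noise; pass a seeded generator for determinism.
    """
    mol = frame.molecule(molecule_index)
    expected = set(DEFAULT_TEMPLATE.labels)
    if not expected.issubset(set(mol.labels)):
        raise ValueError("molecule does not follow the toy template")
    r = donor_acceptor_distance(mol)
    tau = math.radians(reporter_torsion(mol))
    decay = math.exp(-r / config.decay_length)
    shifts = {}
    for label, delta0 in config.baselines.items():
        val = delta0
        if label == "H1":
            val += config.hbond_amplitude * decay
        elif label == "N53":
            val += config.hbond_amplitude_n * decay
        elif label in RING_CARBONS:
            val += config.torsion_amplitude * math.cos(tau)
        if config.noise_sigma > 0:
            val += rng.normal(scale=config.noise_sigma)
        shifts[label] = val
    return EnvironmentShifts(env_id=env_id or (None, None, molecule_index),
                             shifts=shifts)


def predict_ensemble(frames, config, seed=None):
    """Surrogate shifts for every environment, in (run, frame, molecule) order."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = []
    for run_id in sorted(frames):
        for fidx, frame in enumerate(frames[run_id]):
            for mol in frame.molecules:
                out.append(
                    surrogate_shifts(frame, mol.index, config, rng,
                                     env_id=(run_id, fidx, mol.index))
                )
    return out


def plant_experimental_distributions(predictions, truth, config,
                                     subensemble="closed", sigma_floor=0.01):
    """Derive "experimental" shift distributions from a designated subensemble.

    For each scored site, mu and sigma are the sample mean and standard
    deviation of the surrogate shifts over the subensemble: "closed"
    (default, emulating an experimentally biased solid), "open", or
    "all".  sigma is floored at ``sigma_floor`` ppm.
    """
    if subensemble == "all":
        keep = [p for p in predictions]
    else:
        keep = [p for p in predictions if truth.basin[p.env_id] == subensemble]
    if not keep:
        raise ValueError(f"subensemble {subensemble!r} is empty")
    dists = []
    for site in config.scored_sites:
        vals = np.array([p.shifts[site] for p in keep])
        sigma = max(float(vals.std(ddof=0)), sigma_floor)
        dists.append(
            ShiftDistribution(atom_label=site, nucleus=nucleus_of(site),
                              mu=float(vals.mean()), sigma=sigma,
                              source=f"synthetic:{subensemble}")
        )
    return dists


@dataclass
class BenchmarkCase:
    """A complete synthetic fixture: ensemble, predictions, distributions, truth."""

    preset: str
    config: SyntheticConfig
    frames: dict
    truth: GroundTruth
    predictions: list
    distributions: list
    n_select: int

    def environments(self):
        """(env_id, Frame, molecule_index) triples in scoring order."""
        out = []
        for run_id in sorted(self.frames):
            for fidx, frame in enumerate(self.frames[run_id]):
                for mol in frame.molecules:
                    out.append(((run_id, fidx, mol.index), frame, mol.index))
        return out


PRESETS = ("null", "planted_hbond", "planted_torsion")


def make_benchmark_case(preset, seed=0, out_dir=None, config=None):
    """Build a named end-to-end benchmark fixture.

    Presets
    -------
    planted_hbond
        40% of molecules in the H-bond-closed basin; experimental
        distributions fitted to the closed subpopulation.  Selection
        should strongly enrich the closed basin.
    planted_torsion
        Same ensemble, but only the ring-carbon torsion coupling is
        informative (H-bond amplitudes off); the closed reporter-torsion
        basin should be promoted.
    null
        Geometry -> shift couplings switched off and distributions
        fitted to the whole ensemble: selection is structure-blind and
        no feature may be promoted beyond sampling noise.

    When ``out_dir`` is given the fixture is written to disk in the
    standard formats (extended-XYZ, predictions CSV, distributions CSV,
    ground_truth.json).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    base = config or SyntheticConfig()
    base = replace(base, seed=seed)
    if preset == "null":
        cfg = replace(base, hbond_amplitude=0.0, hbond_amplitude_n=0.0,
                      torsion_amplitude=0.0)
        subensemble = "all"
    elif preset == "planted_torsion":
        cfg = replace(base, hbond_amplitude=0.0, hbond_amplitude_n=0.0)
        subensemble = "closed"
    else:
        cfg = base
        subensemble = "closed"
    frames, truth = generate_toy_ensemble(cfg)
    predictions = predict_ensemble(frames, cfg)
    dists = plant_experimental_distributions(predictions, truth, cfg,
                                             subensemble=subensemble)
    n_select = max(1, (cfg.n_runs * cfg.n_frames * cfg.molecules_per_frame) // 10)
    case = BenchmarkCase(preset=preset, config=cfg, frames=frames, truth=truth,
                         predictions=predictions, distributions=dists,
                         n_select=n_select)
    if out_dir is not None:
        _write_case(case, out_dir)
    return case


def _write_case(case, out_dir):
    import os

    import pandas as pd

    from .io import write_extxyz
    from .spectra import write_distributions

    os.makedirs(out_dir, exist_ok=True)
    for run_id in sorted(case.frames):
        write_extxyz(
            os.path.join(out_dir, f"{run_id}.extxyz"),
            case.frames[run_id],
            info={"run_id": run_id},
        )
    rows = []
    for p in case.predictions:
        for label, val in p.shifts.items():
            rows.append({"run_id": p.env_id[0], "frame": p.env_id[1],
                         "molecule": p.env_id[2], "atom_label": label,
                         "shift_ppm": val})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "predictions.csv"), index=False)
    write_distributions(case.distributions,
                        os.path.join(out_dir, "distributions.csv"),
                        header_lines=[f"preset={case.preset} seed={case.config.seed}"])
    case.truth.to_json(os.path.join(out_dir, "ground_truth.json"))
    with open(os.path.join(out_dir, "case.json"), "w") as fh:
        json.dump({"preset": case.preset, "seed": case.config.seed,
                   "n_select": case.n_select,
                   "bias_fraction": case.config.bias_fraction}, fh, indent=1)
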