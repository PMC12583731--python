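"""Cluster formation energies of local molecular environments.

A local environment is a central molecule plus every molecule with at
least one atom within a cutoff (default 7 Angstrom) of it, unwrapped
to the central molecule's minimum-image frame.  Its relative formation
energy comes from three energy evaluations on a pluggable backend:
the cluster with the central molecule (e_with), without it
(e_without), and the central molecule alone (e_central); the
difference e_with - e_without estimates the conformational plus
intermolecular interaction energy, and subtracting e_central isolates
the interaction part when the backend carries intramolecular terms.

The repository ships two backends: a toy pairwise potential
(Lennard-Jones between intermolecular heavy atoms plus a Gaussian
donor-acceptor well for intermolecular H...N/O contacts) and a
file-based backend reading precomputed per-cluster energies, the
route used with external quantum-chemistry energies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import Frame, _min_image_vector

__all__ = [
    "Cluster",
    "ClusterEnergies",
    "BinnedEnergyProfile",
    "PairwiseBackend",
    "FileBackend",
    "extract_cluster",
    "formation_energy",
    "sample_md_environments",
    "binned_energy_profile",
    "write_cluster_xyz",
]


@dataclass
class Cluster:
    """A central molecule and its unwrapped neighbour shell."""

    env_id: tuple
    central: int  # molecule index
    members: list  # neighbour molecule indices
    # per molecule index: (elements, labels, coords) with coords shifted
    # to the central molecule's minimum-image frame
    geometry: dict


@dataclass
class ClusterEnergies:
    """The three backend energies (kJ/mol) and derived formation energies."""

    env_id: tuple
    e_with: float
    e_without: float
    e_central: float

    @property
    def delta(self):
        """Formation energy e_with - e_without - e_central (kJ/mol)."""
        return self.e_with - self.e_without - self.e_central

    @property
    def delta_env(self):
        """Alternative reading e_with - e_without (kJ/mol): conformational
        energy of the central molecule plus its interaction with the shell."""
        return self.e_with - self.e_without


class PairwiseBackend:
    """Toy intermolecular pair potential (kJ/mol).

    Heavy-atom pairs in different molecules interact through a 12-6
    Lennard-Jones term 4*eps*((sig/r)**12 - (sig/r)**6); intermolecular
    H...{N,O} contacts additionally feel a Gaussian donor-acceptor well
    -depth*exp(-(r - r0)**2 / (2*width**2)).  Strictly intermolecular
    and strictly pairwise, so cluster formation energies reduce exactly
    to the central<->member pair sum.  Interactions beyond ``cutoff``
    are zero, making the energy local.
    """

    def __init__(self, eps=0.4, sigma=3.4, hb_depth=20.0, hb_r0=1.9,
                 hb_width=0.25, cutoff=10.0):
        self.eps = eps
        self.sigma = sigma
        self.hb_depth = hb_depth
        self.hb_r0 = hb_r0
        self.hb_width = hb_width
        self.cutoff = cutoff

    def pair_energy(self, el1, el2, r):
        """Closed-form energy of one intermolecular atom pair at distance r."""
        if r > self.cutoff:
            return 0.0
        e = 0.0
        if el1 != "H" and el2 != "H":
            sr6 = (self.sigma / r) ** 6
            e += 4.0 * self.eps * (sr6 * sr6 - sr6)
        pair = {el1, el2}
        if "H" in pair and pair & {"N", "O"} and el1 != el2:
            e += -self.hb_depth * math.exp(-((r - self.hb_r0) ** 2)
                                           / (2.0 * self.hb_width ** 2))
        return e

    def energy(self, elements, coords, mol_ids):
        """Total energy of an atom set: sum over intermolecular pairs."""
        coords = np.asarray(coords, dtype=float)
        mol_ids = np.asarray(mol_ids)
        e = 0.0
        n = len(elements)
        for i in range(n):
            for j in range(i + 1, n):
                if mol_ids[i] == mol_ids[j]:
                    continue
                r = float(np.linalg.norm(coords[i] - coords[j]))
                e += self.pair_energy(elements[i], elements[j], r)
        return e


class FileBackend:
    """Backend serving precomputed per-cluster energies from a CSV table.

    Expected header: run_id,frame,molecule,e_with,e_without,e_central
    (kJ/mol), one row per cluster.
    """

    def __init__(self, path_or_buf):
        df = pd.read_csv(path_or_buf, comment="#")
        self._table = {
            (r.run_id, int(r.frame), int(r.molecule)):
                (float(r.e_with), float(r.e_without), float(r.e_central))
            for r in df.itertuples()
        }

    def energies_for(self, env_id):
        try:
            e_with, e_without, e_central = self._table[env_id]
        except KeyError:
            raise KeyError(f"no precomputed energies for environment {env_id}") from None
        return ClusterEnergies(env_id=env_id, e_with=e_with,
                               e_without=e_without, e_central=e_central)


def _shortest_cell_height(cell):
    # height along each axis = |det| / area of the opposite face
    vol = abs(np.linalg.det(cell))
    heights = []
    for k in range(3):
        a, b = cell[(k + 1) % 3], cell[(k + 2) % 3]
        heights.append(vol / np.linalg.norm(np.cross(a, b)))
    return min(heights)


def extract_cluster(frame: Frame, central: int, cutoff: float = 7.0,
                    env_id=None) -> Cluster:
    """Extract the local environment of one molecule.

    Membership: every other molecule with at least one atom within
    ``cutoff`` (inclusive) of any central-molecule atom, with
    intermolecular distances measured under the minimum image.  Member
    coordinates are shifted by the lattice translation bringing them
    nearest the central molecule.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if frame.cell is not None:
        half = 0.5 * _shortest_cell_height(frame.cell)
        if cutoff >= half - 1e-9:
            raise ValueError(
                f"cutoff {cutoff} Angstrom exceeds half the shortest cell "
                f"height ({half:.2f} Angstrom); minimum-image neighbour "
                f"search would be ambiguous"
            )
    cmol = frame.molecule(central)
    ccoords = cmol.coords()
    geometry = {central: (cmol.elements, cmol.labels, ccoords)}
    members = []
    for other in frame.molecules:
        if other.index == central:
            continue
        ocoords = other.coords()
        if frame.cell is None:
            d = np.linalg.norm(ccoords[:, None, :] - ocoords[None, :, :], axis=-1)
            if d.min() <= cutoff:
                members.append(other.index)
                geometry[other.index] = (other.elements, other.labels, ocoords)
            continue
        # candidate whole-molecule lattice shifts around the minimum-image
        # displacement of the molecule centroids
        delta = ocoords.mean(axis=0) - ccoords.mean(axis=0)
        frac = delta @ np.linalg.inv(frame.cell)
        base = -np.round(frac)
        best_min = np.inf
        best_coords = None
        for shift in itertools.product((-1, 0, 1), repeat=3):
            t = (base + shift) @ frame.cell
            d = np.linalg.norm(ccoords[:, None, :] - (ocoords + t)[None, :, :], axis=-1)
            dmin = float(d.min())
            if dmin < best_min:
                best_min = dmin
                best_coords = ocoords + t
        if best_min <= cutoff:
            members.append(other.index)
            geometry[other.index] = (other.elements, other.labels, best_coords)
    return Cluster(env_id=env_id or (None, None, central), central=central,
                   members=members, geometry=geometry)


def formation_energy(cluster: Cluster, backend) -> ClusterEnergies:
    """Three-energy decomposition of one cluster on ``backend``.

    The backend is called on (i) the full cluster, (ii) the shell
    without the central molecule and (iii) the central molecule alone;
    ``delta`` is e_with - e_without - e_central.
    """
    def collect(indices):
        elements, coords, mol_ids = [], [], []
        for idx in indices:
            els, _, xyz = cluster.geometry[idx]
            elements.extend(els)
            coords.extend(xyz)
            mol_ids.extend([idx] * len(els))
        return elements, np.asarray(coords, dtype=float).reshape(-1, 3), mol_ids

    try:
        e_with = backend.energy(*collect([cluster.central] + cluster.members))
        e_without = backend.energy(*collect(cluster.members))
        e_central = backend.energy(*collect([cluster.central]))
    except Exception as err:
        raise RuntimeError(f"energy backend failed on cluster {cluster.env_id}: {err}") from err
    return ClusterEnergies(env_id=cluster.env_id, e_with=e_with,
                           e_without=e_without, e_central=e_central)


def sample_md_environments(run_envs, per_run=1500, seed=0):
    """Uniformly sample ``per_run`` environments from each MD run.

    Parameters
    ----------
    run_envs : dict
        run_id -> list of env_ids belonging to that run.
    per_run : int
        Environments drawn (without replacement) per run.
    seed : int
        Reproducibility seed.

    Returns
    -------
    list of env_id
    """
    rng = np.random.default_rng(seed)
    sample = []
    for run_id in sorted(run_envs, key=str):
        envs = run_envs[run_id]
        if len(envs) < per_run:
            raise ValueError(
                f"run {run_id} has only {len(envs)} environments, "
                f"cannot sample {per_run}"
            )
        idx = rng.choice(len(envs), size=per_run, replace=False)
        sample.extend(envs[i] for i in sorted(idx))
    return sample


@dataclass
class BinnedEnergyProfile:
    """Mean relative formation energy along a geometric feature, per bin."""

    bin_edges: np.ndarray
    mean: np.ndarray      # kJ/mol, relative to the reference zero; NaN if empty
    spread: np.ndarray    # within-bin standard deviation, kJ/mol
    count: np.ndarray
    reference_energy: float  # absolute energy (kJ/mol) subtracted from all bins


def binned_energy_profile(features, energies, bin_edges, *, reference_zero=None,
                          spread="std"):
    """Bin formation energies along a feature and reference them to a zero.

    Parameters
    ----------
    features : dict
        env_id -> feature value.
    energies : dict
        env_id -> formation energy delta (kJ/mol).
    bin_edges : array
    reference_zero : float, optional
        Absolute energy subtracted from every bin mean.  Omitted, the
        minimum bin mean of this profile is used (so its lowest bin sits
        at 0); pass the MD-sample reference to put an NMR-set profile on
        the same scale.
    spread : "std" or "sem"
        Within-bin standard deviation of environment energies
        (default) or standard error of the bin mean.

    Returns
    -------
    BinnedEnergyProfile
    """
    env_ids = [e for e in features if e in energies]
    if not env_ids:
        raise ValueError("features and energies share no environments")
    vals = np.array([features[e] for e in env_ids], dtype=float)
    ergs = np.array([energies[e] for e in env_ids], dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    nbins = len(edges) - 1
    idx = np.digitize(vals, edges) - 1
    inside = (idx >= 0) & (idx < nbins)
    # values exactly on the last edge belong to the last bin
    on_top = np.isclose(vals, edges[-1])
    idx[on_top] = nbins - 1
    inside |= on_top

    mean = np.full(nbins, np.nan)
    sd = np.full(nbins, np.nan)
    count = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        sel = ergs[inside & (idx == b)]
        count[b] = sel.size
        if sel.size:
            mean[b] = sel.mean()
            sd[b] = sel.std(ddof=0)
            if spread == "sem":
                sd[b] /= math.sqrt(sel.size)
    if reference_zero is None:
        reference_zero = np.nanmin(mean)
    return BinnedEnergyProfile(bin_edges=edges, mean=mean - reference_zero,
                               spread=sd, count=count,
                               reference_energy=float(reference_zero))


def write_cluster_xyz(cluster: Cluster, path):
    """Write one cluster as plain XYZ, central molecule first."""
    lines = []
    order = [cluster.central] + cluster.members
    natoms = sum(len(cluster.geometry[i][0]) for i in order)
    lines.append(str(natoms))
    lines.append(f"cluster env_id={cluster.env_id} central={cluster.central} "
                 f"members={cluster.members}")
    for idx in order:
        els, labels, coords = cluster.geometry[idx]
        for el, xyz in zip(els, coords):
            lines.append(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
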