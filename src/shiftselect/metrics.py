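"""Geometric features of periodic molecular ensembles.

Computes dihedral angles, (minimum-image) distances and hydrogen
bonds over multi-frame periodic ensembles, and compares feature
distributions between the full MD set and the selected NMR set:
1D/2D normalized histograms, per-bin promotion ratios, and a
hydrogen-bond acceptor census per donor.

Conventions: coordinates in Angstrom, angles in degrees, dihedral
sign per the IUPAC rule (cis = 0; looking from atom 2 to atom 3,
clockwise positive), molecules stored whole (unwrapped), and all
intermolecular geometry evaluated under the minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "Frame",
    "FeatureSpec",
    "HBondCriterion",
    "FeatureHistogram",
    "HBondCensus",
    "dihedral",
    "min_image_distance",
    "detect_hbond",
    "feature_values",
    "histogram1d",
    "make_feature_histogram",
    "promotion_map",
    "correlation2d",
    "hbond_census",
]

#: Reference dihedrals (degrees) of the protein-bound conformation
#: (PDB 6HAX) and of proline backbone statistics, for histogram
#: annotation only.
BOUND_STATE_DIHEDRALS = {
    "C2-C7-C8-C9": (-177.0,),
    "C44-N58-C39-C38": (-60.0,),   # phi
    "N58-C39-C38-N37": (150.0,),   # psi
    "O38-C38-C44-O44": (-102.0,),
}
PROLINE_DIHEDRALS = {
    "C44-N58-C39-C38": (-65.0,),          # phi
    "N58-C39-C38-N37": (-35.0, 150.0),    # psi
}


@dataclass(frozen=True)
class Atom:
    label: str
    element: str
    xyz: tuple  # Angstrom


@dataclass
class Molecule:
    index: int
    atoms: list  # of Atom

    def __post_init__(self):
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate atom labels in molecule {self.index}")
        self._by_label = {a.label: a for a in self.atoms}

    def position(self, label):
        try:
            return np.asarray(self._by_label[label].xyz, dtype=float)
        except KeyError:
            raise KeyError(f"atom label {label!r} not in molecule {self.index}") from None

    def coords(self):
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def labels(self):
        return [a.label for a in self.atoms]

    @property
    def elements(self):
        return [a.element for a in self.atoms]


@dataclass
class Frame:
    """One snapshot: an optional periodic cell and whole molecules."""

    molecules: list  # of Molecule
    cell: np.ndarray | None = None  # 3x3 rows = lattice vectors, Angstrom

    def __post_init__(self):
        if self.cell is not None:
            cell = np.asarray(self.cell, dtype=float)
            if cell.shape != (3, 3):
                raise ValueError("cell must be a 3x3 matrix of lattice vectors")
            if abs(np.linalg.det(cell)) < 1e-10:
                raise ValueError("cell is singular")
            self.cell = cell
        self._by_index = {m.index: m for m in self.molecules}

    def molecule(self, index):
        return self._by_index[index]


@dataclass(frozen=True)
class FeatureSpec:
    """A named geometric feature: dihedral, distance, or H-bond acceptor class.

    ``atom_labels`` holds 4 labels for a dihedral, 2 for a distance and
    1 (the donor hydrogen) for an H-bond feature.  ``scope`` restricts
    distance evaluation (intra uses the plain in-molecule geometry).
    """

    kind: str  # dihedral | distance | hbond_acceptor
    atom_labels: tuple
    scope: str = "intra"
    name: str = ""
    donor_heavy: str = ""  # hbond_acceptor only

    def __post_init__(self):
        expected = {"dihedral": 4, "distance": 2, "hbond_acceptor": 1}
        if self.kind not in expected:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if len(self.atom_labels) != expected[self.kind]:
            raise ValueError(
                f"{self.kind} needs {expected[self.kind]} atom labels, got "
                f"{len(self.atom_labels)}"
            )
        if not self.name:
            object.__setattr__(self, "name", "-".join(self.atom_labels))


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition: H...A cutoff and D-H...A angle."""

    max_ha_distance: float = 2.5  # Angstrom
    min_dha_angle: float = 120.0  # degrees
    acceptor_elements: tuple = ("N", "O")

    def __post_init__(self):
        if not self.max_ha_distance > 0:
            raise ValueError("max_ha_distance must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("min_dha_angle must lie in (0, 180]")


def dihedral(p1, p2, p3, p4):
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-10:
        raise ValueError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("three consecutive points are collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def _min_image_vector(delta, cell):
    """Minimum-image displacement for a raw Cartesian delta in a triclinic cell."""
    diag = np.diag(np.diag(cell))
    if np.allclose(cell, diag):
        # orthorhombic: the rounded image is exact
        d = np.diag(cell)
        return delta - d * np.round(delta / d)
    inv = np.linalg.inv(cell)
    frac = delta @ inv
    frac -= np.round(frac)
    best = None
    best_d2 = np.inf
    # the rounded image is optimal for near-orthorhombic cells; scanning
    # the 27 neighbours makes the result exact for skewed ones
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                cand = (frac + (sx, sy, sz)) @ cell
                d2 = float(cand @ cand)
                if d2 < best_d2:
                    best_d2 = d2
                    best = cand
    return best


def min_image_distance(a, b, cell=None):
    """Shortest distance between ``a`` and any periodic image of ``b`` (Angstrom)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if cell is None:
        return float(np.linalg.norm(b - a))
    cell = np.asarray(cell, dtype=float)
    if abs(np.linalg.det(cell)) < 1e-10:
        raise ValueError("cell is singular")
    return float(np.linalg.norm(_min_image_vector(b - a, cell)))


def _angle_deg(v1, v2):
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbond(frame, molecule_index, donor_h, donor_heavy,
                 criterion=None, acceptor_class_map=None):
    """Classify the H-bond acceptor of one donor hydrogen, or "none".

    Scans every acceptor-element atom in the frame (excluding the
    donor's own heavy atom), applying the distance and D-H...A angle
    criterion; intermolecular contacts use the minimum image.  When
    several acceptors pass, the one with the shortest H...A distance
    wins.

    Returns
    -------
    (acceptor_class, scope) : (str, str)
        ``scope`` is "intra" or "inter"; for "none" the scope is "".
        Intramolecular acceptors are classed by their atom label;
        intermolecular ones through ``acceptor_class_map`` (label ->
        chemical class, default the element).
    """
    if criterion is None:
        criterion = HBondCriterion()
    mol = frame.molecule(molecule_index)
    h_pos = mol.position(donor_h)
    d_pos = mol.position(donor_heavy)
    if np.linalg.norm(h_pos - d_pos) > 1.3:
        raise ValueError(
            f"{donor_h} and {donor_heavy} are not covalently associated "
            f"(>1.3 Angstrom apart)"
        )

    best = None  # (distance, class, scope)
    for other in frame.molecules:
        intra = other.index == molecule_index
        for atom in other.atoms:
            if atom.element not in criterion.acceptor_elements:
                continue
            if intra and atom.label in (donor_heavy, donor_h):
                continue
            a_pos = np.asarray(atom.xyz, dtype=float)
            if intra or frame.cell is None:
                vec = a_pos - h_pos
            else:
                vec = _min_image_vector(a_pos - h_pos, frame.cell)
            r = float(np.linalg.norm(vec))
            if r > criterion.max_ha_distance:
                continue
            # D-H...A angle at the hydrogen: 180 deg = linear bond
            ang = _angle_deg(d_pos - h_pos, vec)
            if ang < criterion.min_dha_angle:
                continue
            if intra:
                cls, scope = atom.label, "intra"
            else:
                cls = (acceptor_class_map or {}).get(atom.label, atom.element)
                scope = "inter"
            if best is None or r < best[0]:
                best = (r, cls, scope)
    if best is None:
        return "none", ""
    return best[1], best[2]


def feature_values(environments, spec, criterion=None, acceptor_class_map=None):
    """Evaluate one feature over an ensemble of environments.

    Parameters
    ----------
    environments : iterable of (env_id, Frame, molecule_index)
    spec : FeatureSpec

    Returns
    -------
    (env_ids, values) : (list, list)
        Dihedrals in degrees, distances in Angstrom, or H-bond
        acceptor-class strings, one per environment in input order.
    """
    env_ids, values = [], []
    for env_id, frame, mol_index in environments:
        mol = frame.molecule(mol_index)
        if spec.kind == "dihedral":
            pts = [mol.position(lbl) for lbl in spec.atom_labels]
            values.append(dihedral(*pts))
        elif spec.kind == "distance":
            a, b = (mol.position(lbl) for lbl in spec.atom_labels)
            cell = frame.cell if spec.scope == "inter" else None
            values.append(min_image_distance(a, b, cell))
        else:  # hbond_acceptor
            cls, scope = detect_hbond(
                frame, mol_index, spec.atom_labels[0], spec.donor_heavy,
                criterion, acceptor_class_map,
            )
            values.append(cls if cls == "none" else f"{cls}:{scope}")
        env_ids.append(env_id)
    return env_ids, values


def histogram1d(values, bin_width, periodic=False, range_=None, edge_offset=0.0):
    """Probability-density histogram of one feature over one set.

    Periodic histograms live on (-180, 180] with edges symmetric about
    zero by default; ``edge_offset`` shifts the edge grid (e.g. half a
    bin width to centre a bin on 180 deg, so -179 and +179 share the
    wrap-around bin).

    Returns
    -------
    (edges, density) : (ndarray, ndarray)
        ``density`` integrates to 1 over the binned range.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to histogram")
    if periodic:
        lo = -180.0 + edge_offset
        values = (values - lo) % 360.0 + lo
        nbins = int(round(360.0 / bin_width))
        if not np.isclose(nbins * bin_width, 360.0):
            raise ValueError("bin_width must divide 360 for periodic histograms")
        edges = lo + bin_width * np.arange(nbins + 1)
    else:
        if range_ is None:
            range_ = (float(values.min()), float(values.max()) + bin_width)
        lo, hi = range_
        nbins = int(np.ceil((hi - lo) / bin_width))
        edges = lo + bin_width * np.arange(nbins + 1)
    density, edges = np.histogram(values, bins=edges, density=True)
    return edges, density


@dataclass
class FeatureHistogram:
    """Paired MD-set / NMR-set densities of one feature with promotion ratios."""

    name: str
    bin_edges: np.ndarray
    density_md: np.ndarray
    density_nmr: np.ndarray
    periodic: bool = False
    promoted_threshold: float = 1.25
    demoted_threshold: float = 0.8
    annotations: dict = field(default_factory=dict)  # label -> reference values

    def __post_init__(self):
        if len(self.density_md) != len(self.density_nmr):
            raise ValueError("MD and NMR histograms must share binning")

    @property
    def promotion(self):
        """Per-bin density_nmr / density_md; NaN where density_md = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(self.density_md > 0,
                             self.density_nmr / self.density_md, np.nan)
        return ratio

    @property
    def classification(self):
        """Per-bin labels: promoted / demoted / unchanged / undefined."""
        out = []
        for r in self.promotion:
            if np.isnan(r):
                out.append("undefined")
            elif r > self.promoted_threshold:
                out.append("promoted")
            elif r < self.demoted_threshold:
                out.append("demoted")
            else:
                out.append("unchanged")
        return out

    @property
    def bin_centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def make_feature_histogram(values_md, values_nmr, bin_width, *, periodic=False,
                           range_=None, edge_offset=0.0, name="",
                           annotations=None, **thresholds):
    """Build a FeatureHistogram from MD-set and NMR-set feature values."""
    if not periodic and range_ is None:
        both = np.concatenate([np.asarray(values_md, float),
                               np.asarray(values_nmr, float)])
        range_ = (float(both.min()), float(both.max()) + bin_width)
    edges, dmd = histogram1d(values_md, bin_width, periodic, range_, edge_offset)
    _, dnmr = histogram1d(values_nmr, bin_width, periodic, range_, edge_offset)
    return FeatureHistogram(
        name=name, bin_edges=edges, density_md=dmd, density_nmr=dnmr,
        periodic=periodic, annotations=annotations or {}, **thresholds,
    )


def promotion_map(hist: FeatureHistogram):
    """Per-bin promotion ratios and classifications of a paired histogram.

    Returns a list of (bin_left, bin_right, ratio, label) tuples; bins
    where the MD density is zero carry ratio NaN and label "undefined".
    """
    return list(zip(hist.bin_edges[:-1], hist.bin_edges[1:],
                    hist.promotion, hist.classification))


def correlation2d(values_a, values_b, edges_a, edges_b):
    """Joint probability density of two features paired by environment.

    Returns a 2D grid normalized to unit integral; marginalizing over
    either axis reproduces the corresponding 1D density.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.shape != values_b.shape:
        raise ValueError("feature value lists must have equal length")
    H, ea, eb = np.histogram2d(values_a, values_b, bins=[edges_a, edges_b],
                               density=True)
    return H, ea, eb


@dataclass
class HBondCensus:
    """Acceptor-class occurrence fractions per donor, MD set vs NMR set."""

    fractions: dict  # donor_h -> {acceptor_class -> (fraction_md, fraction_nmr)}


def hbond_census(md_environments, nmr_environments, donors, criterion=None,
                 acceptor_class_map=None):
    """Census of H-bond acceptor classes for each donor in both sets.

    Parameters
    ----------
    md_environments, nmr_environments : lists of (env_id, Frame, molecule_index)
    donors : list of (donor_h_label, donor_heavy_label)

    Returns
    -------
    HBondCensus
        Fractions over each set sum to 1 per donor (class "none"
        included).
    """
    result = {}
    for donor_h, donor_heavy in donors:
        spec = FeatureSpec(kind="hbond_acceptor", atom_labels=(donor_h,),
                           donor_heavy=donor_heavy)
        per_set = []
        for envs in (md_environments, nmr_environments):
            _, classes = feature_values(envs, spec, criterion, acceptor_class_map)
            n = len(classes)
            counts = {}
            for c in classes:
                counts[c] = counts.get(c, 0) + 1
            per_set.append({c: k / n for c, k in counts.items()})
        all_classes = sorted(set(per_set[0]) | set(per_set[1]))
        result[donor_h] = {
            c: (per_set[0].get(c, 0.0), per_set[1].get(c, 0.0)) for c in all_classes
        }
    return HBondCensus(fractions=result)
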