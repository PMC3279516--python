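"""Structural geometry of tandem-domain filament models.

Tools to assemble and characterize composite filament models built from
overlapping fragment structures: least-squares superposition on a shared
domain, per-domain centroids and their distance spectra, tilt/twist
angles between consecutive domains, the pair distance distribution p(r)
with Rg and Dmax, and a synthetic superhelix builder used as a
well-posed fixture for angle-recovery checks.

Conventions (fixed, documented):

* centroids are unweighted means of Calpha positions by default
  (mass-weighted all-atom centroids behind ``use_masses=True``);
* each domain's internal frame comes from the eigenvectors of its
  Calpha covariance tensor; the long axis is the largest-variance
  eigenvector with its sign fixed N->C;
* tilt is the angle between the long axes of the two domains; twist is
  the rotation about the inter-centroid axis obtained by swing-twist
  decomposition of the frame-to-frame rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

__all__ = [
    "Domain",
    "StructureModel",
    "DomainArrangement",
    "DistanceDistribution",
    "RigidTransform",
    "read_pdb",
    "write_pdb",
    "superpose_shared_domain",
    "domain_centroids",
    "neighbor_distance_stats",
    "tilt_twist",
    "pair_distance_distribution",
    "build_synthetic_superhelix",
]

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "SE": 78.97}


@dataclass(frozen=True)
class Domain:
    """Half-open-free residue range of one domain: [first, last] inclusive."""

    label: str
    chain_id: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.last_residue < self.first_residue:
            raise ValueError(f"domain {self.label!r}: last < first residue")


@dataclass(frozen=True)
class StructureModel:
    """Labeled atomic or bead coordinates with optional domain boundaries.

    Coordinates are in Angstrom.  ``domain_boundaries`` is an ordered
    list following the filament N->C direction (across the dimer for
    tail-to-tail filaments).
    """

    coords: np.ndarray  # (N, 3) float, Angstrom
    chain_ids: np.ndarray  # (N,) str
    residue_indices: np.ndarray  # (N,) int, author numbering (1-based)
    atom_names: np.ndarray  # (N,) str
    elements: np.ndarray  # (N,) str
    domain_boundaries: tuple[Domain, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "domain_boundaries", tuple(self.domain_boundaries))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        n = len(coords)
        for name in ("chain_ids", "residue_indices", "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            object.__setattr__(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"{name} length does not match coords")
        for dom in self.domain_boundaries:
            idx = self.domain_atom_indices(dom.label)
            res = np.unique(self.residue_indices[idx])
            if not np.array_equal(res, np.arange(res.min(), res.max() + 1)):
                raise ValueError(
                    f"domain {dom.label!r}: residue indices are not contiguous"
                )

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def domain_labels(self) -> list[str]:
        return [d.label for d in self.domain_boundaries]

    def _domain(self, label: str) -> Domain:
        for d in self.domain_boundaries:
            if d.label == label:
                return d
        raise KeyError(f"no domain labeled {label!r}")

    def domain_atom_indices(self, label: str) -> np.ndarray:
        d = self._domain(label)
        mask = (
            (self.chain_ids == d.chain_id)
            & (self.residue_indices >= d.first_residue)
            & (self.residue_indices <= d.last_residue)
        )
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"domain {d.label!r} selects no atoms")
        return idx

    def domain_ca(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(residue indices, Calpha coordinates) of one domain, residue-sorted."""
        idx = self.domain_atom_indices(label)
        ca = idx[self.atom_names[idx] == "CA"]
        if ca.size == 0:
            raise ValueError(f"domain {label!r} has no CA atoms")
        res = self.residue_indices[ca]
        order = np.argsort(res, kind="stable")
        return res[order], self.coords[ca[order]]

    def with_domains(self, domains) -> "StructureModel":
        return replace(self, domain_boundaries=tuple(domains))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        return replace(self, coords=self.coords @ np.asarray(rotation).T + translation)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class DomainArrangement:
    """Tilt/twist/centroid-distance description of a domain pair."""

    pair: tuple[str, str]
    tilt: float  # degrees in [0, 180]
    twist: float  # degrees in (-180, 180]
    centroid_distance: float  # Angstrom

    def __post_init__(self) -> None:
        if not (0.0 <= self.tilt <= 180.0):
            raise ValueError("tilt must lie in [0, 180] degrees")
        if not (-180.0 < self.twist <= 180.0):
            raise ValueError("twist must lie in (-180, 180] degrees")
        if self.centroid_distance < 0:
            raise ValueError("centroid_distance must be >= 0")


@dataclass(frozen=True)
class DistanceDistribution:
    """Binned pair-distance histogram p(r) with Rg and Dmax (Angstrom)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    rg: float
    dmax: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if len(edges) != len(counts) + 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be ascending with len(counts)+1 entries")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        beyond = edges[:-1] > self.dmax
        if np.any(counts[beyond] > 0):
            raise ValueError("counts must vanish beyond dmax")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def maxima(self, min_r: float = 0.0, prominence_fraction: float = 0.02) -> np.ndarray:
        """Positions (bin centers) of local maxima of p(r) with r >= min_r."""
        peaks, _ = signal.find_peaks(
            self.counts, prominence=prominence_fraction * self.counts.max()
        )
        r = self.bin_centers[peaks]
        return r[r >= min_r]


# ---------------------------------------------------------------------------
# PDB reading / writing


def _validate_pdb_lines(path: str) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.startswith("ATOM"):
                continue
            if len(line) >= 27 and line[26] not in (" ", ""):
                raise ValueError(
                    f"{path}:{i}: insertion codes are not supported "
                    f"(found {line[26]!r})"
                )
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{i}: malformed coordinate fields in ATOM record"
                ) from exc


def read_pdb(path) -> StructureModel:
    """Read all ATOM records of the first model of a standard PDB file.

    HETATM records and altlocs other than blank/'A' are dropped; author
    (1-based) residue numbering is preserved; insertion codes are
    rejected with an error naming the offending line.
    """
    import gemmi

    path = str(path)
    _validate_pdb_lines(path)
    structure = gemmi.read_pdb(path)
    if len(structure) == 0:
        raise ValueError(f"{path}: no ATOM records")
    model = structure[0]
    coords, chains, resseq, names, elems = [], [], [], [], []
    for chain in model:
        for residue in chain:
            if residue.het_flag != "A":  # 'A' marks ATOM records in gemmi
                continue
            for atom in residue:
                if atom.altloc not in ("", "A", " ", "\x00"):
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                chains.append(chain.name)
                resseq.append(residue.seqid.num)
                names.append(atom.name)
                elems.append(atom.element.name.upper())
    if not coords:
        raise ValueError(f"{path}: no ATOM records")
    return StructureModel(
        coords=np.asarray(coords, dtype=float),
        chain_ids=np.asarray(chains),
        residue_indices=np.asarray(resseq, dtype=int),
        atom_names=np.asarray(names),
        elements=np.asarray(elems),
    )


def write_pdb(model: StructureModel, path) -> None:
    """Write the model as a minimal standard PDB file (ATOM records only)."""
    import gemmi

    # group atoms by (chain, residue); gemmi copies on add_*, so each
    # object must be complete before it is added to its parent
    order: list[tuple[str, int]] = []
    atoms_by_res: dict[tuple[str, int], list[int]] = {}
    for i in range(len(model)):
        key = (str(model.chain_ids[i]), int(model.residue_indices[i]))
        if key not in atoms_by_res:
            atoms_by_res[key] = []
            order.append(key)
        atoms_by_res[key].append(i)

    st = gemmi.Structure()
    st.name = "model"
    md = gemmi.Model("1")
    chain_keys: list[str] = []
    chains: dict[str, gemmi.Chain] = {}
    for cid, resnum in order:
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
            chain_keys.append(cid)
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(resnum, " ")
        res.het_flag = "A"
        for i in atoms_by_res[(cid, resnum)]:
            atom = gemmi.Atom()
            atom.name = str(model.atom_names[i])
            atom.element = gemmi.Element(str(model.elements[i]))
            atom.pos = gemmi.Position(*model.coords[i])
            res.add_atom(atom)
        chains[cid].add_residue(res)
    for cid in chain_keys:
        md.add_chain(chains[cid])
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Superposition


def superpose_shared_domain(
    mobile: StructureModel,
    reference: StructureModel,
    selection: str,
) -> tuple[RigidTransform, float, StructureModel]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Calpha atoms of the ``selection`` domain are matched by residue
    index (>= 3 shared positions required); the optimal rotation and
    translation (Kabsch/SVD) are applied to all mobile atoms.  The RMSD
    is reported on the matched Calpha set.  Collinear point sets are
    rejected as degenerate.
    """
    from Bio.SVDSuperimposer import SVDSuperimposer

    res_m, ca_m = mobile.domain_ca(selection)
    res_r, ca_r = reference.domain_ca(selection)
    shared = np.intersect1d(res_m, res_r)
    if shared.size < 3:
        raise ValueError(
            f"selection {selection!r}: only {shared.size} shared CA positions "
            "(need >= 3)"
        )
    xm = ca_m[np.searchsorted(res_m, shared)]
    xr = ca_r[np.searchsorted(res_r, shared)]

    for pts, which in ((xm, "mobile"), (xr, "reference")):
        centered = pts - pts.mean(axis=0)
        svals = np.linalg.svd(centered, compute_uv=False)
        if svals[1] < 1e-8 * max(svals[0], 1.0):
            raise ValueError(
                f"selection {selection!r}: {which} CA set is collinear "
                "(degenerate superposition)"
            )

    sup = SVDSuperimposer()
    sup.set(xr, xm)  # rotate mobile (second) onto reference (first)
    sup.run()
    rot, tran = sup.get_rotran()
    rmsd = float(sup.get_rms())
    transform = RigidTransform(rotation=rot.T, translation=tran)
    transformed = mobile.transformed(transform.rotation, transform.translation)
    return transform, rmsd, transformed


# ---------------------------------------------------------------------------
# Centroids and distance spectra


def domain_centroids(
    model: StructureModel,
    use_masses: bool = False,
    merge_pairs: tuple[tuple[str, str], ...] = (),
) -> list[tuple[str, np.ndarray]]:
    """Centroid per domain, in the order of ``domain_boundaries``.

    Default: unweighted mean of Calpha positions.  ``use_masses=True``
    switches to the mass-weighted all-atom centroid.  ``merge_pairs``
    merges labeled pairs (e.g. the two copies of a central dimerization
    domain) into one centroid placed at their combined mean, keeping the
    position of the first label of the pair in the ordering.
    """
    if not model.domain_boundaries:
        raise ValueError("model has no domain boundaries")

    def one(label: str) -> tuple[np.ndarray, float]:
        if use_masses:
            idx = model.domain_atom_indices(label)
            masses = np.array(
                [_MASSES.get(str(e).upper(), 12.011) for e in model.elements[idx]]
            )
            return (masses[:, None] * model.coords[idx]).sum(axis=0), masses.sum()
        _, ca = model.domain_ca(label)
        return ca.sum(axis=0), float(len(ca))

    merged_with: dict[str, str] = {}
    for a, b in merge_pairs:
        merged_with[b] = a
    out: list[tuple[str, np.ndarray]] = []
    partner = {a: b for a, b in merge_pairs}
    for dom in model.domain_boundaries:
        if dom.label in merged_with:
            continue
        vec, w = one(dom.label)
        if dom.label in partner:
            vec2, w2 = one(partner[dom.label])
            vec, w = vec + vec2, w + w2
        out.append((dom.label, vec / w))
    return out


def neighbor_distance_stats(
    centroids: list[tuple[str, np.ndarray]],
    order: int = 1,
) -> tuple[float, float, int]:
    """Mean, SD and count of centroid distances between k-th neighbours.

    Pools all pairs (i, i+k) in filament order, intra- and
    inter-molecular alike.  SD is the population standard deviation.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    pts = np.asarray([c for _, c in centroids], dtype=float)
    n = len(pts)
    if order > n - 1:
        raise ValueError(f"order {order} too large for {n} centroids")
    d = np.linalg.norm(pts[order:] - pts[:-order], axis=1)
    return float(d.mean()), float(d.std()), int(len(d))


# ---------------------------------------------------------------------------
# Tilt / twist


def _domain_frame(model: StructureModel, label: str) -> tuple[np.ndarray, np.ndarray]:
    """(orthonormal frame with columns e1,e2,e3; centroid) of a domain.

    e1 is the long axis (largest-variance eigenvector of the Calpha
    covariance), sign-fixed from the N- to the C-terminal Calpha; e2 is
    the second eigenvector, sign-fixed towards the N-terminal Calpha;
    e3 completes the right-handed frame.
    """
    res, ca = model.domain_ca(label)
    if len(ca) < 3:
        raise ValueError(f"domain {label!r} has fewer than 3 CA atoms")
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    cov = centered.T @ centered / len(ca)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if (evals[2] - evals[1]) < 1e-9 * max(evals[2], 1e-12) or evals[2] <= 0:
        raise ValueError(
            f"domain {label!r}: degenerate inertia tensor (no unique long axis)"
        )
    e1 = evecs[:, 2]
    nc = ca[-1] - ca[0]  # N -> C direction in residue order
    if np.dot(e1, nc) < 0:
        e1 = -e1
    e2 = evecs[:, 1]
    ref = centered[0]
    if np.dot(e2, ref) < 0:
        e2 = -e2
    # re-orthogonalize the sign-fixed pair and complete right-handed
    e2 = e2 - np.dot(e2, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3]), centroid


def tilt_twist(
    model: StructureModel,
    domain_a: str,
    domain_b: str,
    axis: np.ndarray | None = None,
) -> DomainArrangement:
    """Tilt and twist angles between two domains of the filament.

    Tilt is the angle between the two long axes.  Twist is the
    swing-twist component, about ``axis``, of the rotation carrying
    domain A's internal frame onto domain B's.  ``axis`` defaults to
    the inter-centroid direction A->B; for a filament whose modules
    advance mostly along the filament axis this closely approximates
    the twist about that axis.  A domain paired with itself has tilt
    and twist both zero.
    """
    frame_a, cen_a = _domain_frame(model, domain_a)
    frame_b, cen_b = _domain_frame(model, domain_b)
    dvec = cen_b - cen_a
    dist = float(np.linalg.norm(dvec))

    cos_tilt = float(np.clip(np.dot(frame_a[:, 0], frame_b[:, 0]), -1.0, 1.0))
    tilt = math.degrees(math.acos(cos_tilt))

    if axis is None:
        if dist < 1e-9:
            return DomainArrangement((domain_a, domain_b), tilt, 0.0, dist)
        u = dvec / dist
    else:
        u = np.asarray(axis, dtype=float)
        u = u / np.linalg.norm(u)

    R = frame_b @ frame_a.T
    quat = Rotation.from_matrix(R).as_quat()  # (x, y, z, w)
    proj = float(np.dot(quat[:3], u))
    twist = math.degrees(2.0 * math.atan2(proj, quat[3]))
    if twist <= -180.0:
        twist += 360.0
    elif twist > 180.0:
        twist -= 360.0
    return DomainArrangement((domain_a, domain_b), tilt, twist, dist)


# ---------------------------------------------------------------------------
# Pair distance distribution


def pair_distance_distribution(
    model: StructureModel | np.ndarray,
    bin_width: float = 2.0,
    atoms: str = "ca",
) -> DistanceDistribution:
    """Histogram of all unordered pairwise distances, with Rg and Dmax.

    Uses Calpha positions by default (``atoms="all"`` for every atom).
    Counts are unnormalized; Rg is the root mean square distance from
    the centroid; Dmax is the largest pairwise distance.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if isinstance(model, StructureModel):
        if atoms == "ca":
            pts = model.coords[model.atom_names == "CA"]
        else:
            pts = model.coords
    else:
        pts = np.asarray(model, dtype=float)
    if len(pts) < 2:
        raise ValueError("p(r) undefined for fewer than 2 points")
    d = pdist(pts)
    dmax = float(d.max())
    edges = np.arange(0.0, dmax + bin_width, bin_width)
    if edges[-1] <= dmax:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(d, bins=edges)
    centroid = pts.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
    return DistanceDistribution(
        bin_edges=edges, counts=counts.astype(float), rg=rg, dmax=dmax
    )


# ---------------------------------------------------------------------------
# Synthetic superhelix fixture


def build_synthetic_superhelix(
    n_modules: int,
    rise: float = 49.8,
    twist: float = 26.0,
    radius: float = 5.0,
    points_per_module: int = 30,
    seed: int = 0,
) -> StructureModel:
    """Bead model of a superhelical filament of identical modules.

    Module centroids lie on a helix of the given per-module ``rise``
    (A), ``twist`` (degrees) and ``radius`` (A); every module is one
    shared anisotropic random point cloud (so per-module frames are
    well-posed), rotated by the cumulative twist about the helix axis z.
    Beads are emitted as CA pseudo-atoms; modules are labeled M1..Mn.

    The consecutive-centroid distance is exactly
    sqrt(rise**2 + (2 radius sin(twist/2))**2).
    """
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if points_per_module < 3:
        raise ValueError("points_per_module must be >= 3")
    rng = np.random.default_rng(seed)
    template = rng.normal(size=(points_per_module, 3)) * np.array([12.0, 4.0, 2.0])
    template -= template.mean(axis=0)

    theta = math.radians(twist)
    coords = []
    domains = []
    res_counter = 0
    for k in range(n_modules):
        ang = k * theta
        c, s = math.cos(ang), math.sin(ang)
        Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        center = np.array([radius * c, radius * s, k * rise])
        coords.append(template @ Rz.T + center)
        domains.append(
            Domain(
                label=f"M{k + 1}",
                chain_id="A",
                first_residue=res_counter + 1,
                last_residue=res_counter + points_per_module,
            )
        )
        res_counter += points_per_module
    pts = np.vstack(coords)
    n = len(pts)
    return StructureModel(
        coords=pts,
        chain_ids=np.array(["A"] * n),
        residue_indices=np.arange(1, n + 1),
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        domain_boundaries=tuple(domains),
    )
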