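"""Structure parsing and the geometry underlying the feature encoding.

A PDZ domain is represented as a flat list of atoms grouped into chains of
sequentially indexed residues.  From that model this module computes the
raw geometric quantities the predictor's structure features are built on:

* backbone phi dihedrals (the positive-phi binary feature),
* side-chain hydrogen bonds, classified as side chain -> main-chain amide,
  side chain -> main-chain carbonyl, or side chain -> side chain,
* solvent-accessible surface area (Shrake-Rupley), both per residue and as
  exposed surface points reused for surface-property sampling,
* the core binding-site positions: alignment columns whose residues lie
  within a contact cutoff (default < 4.5 A, heavy atoms, strict) of a
  bound peptide chain in a sufficient number of complexes.
"""
from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .tables import (
    AA3_TO_1,
    BACKBONE_ATOMS,
    GXG_REFERENCE_AREA,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    VDW_RADII,
)

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Base class for structure-model failures."""


class StructureParseError(StructureError):
    """Malformed PDB input; the message names the offending line."""


class EmptyStructureError(StructureError):
    """No standard amino-acid residues after filtering."""


class EmptyBindingSiteError(StructureError):
    """Contact derivation produced no binding-site positions."""


@dataclass(frozen=True)
class Atom:
    """One heavy (or hydrogen) atom of a parsed model."""

    serial: int
    name: str
    element: str
    residue_index: int  # 0-based, sequential within the chain
    residue_name: str  # 3-letter code, standard amino acids only
    chain_id: str
    coords: np.ndarray  # shape (3,), Angstrom

    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    index: int
    name: str  # 3-letter
    chain_id: str
    atoms: dict = field(default_factory=dict)  # atom name -> Atom
    author_id: str = ""  # original PDB numbering, reporting only

    @property
    def one_letter(self) -> str:
        return AA3_TO_1[self.name]

    def sidechain_atoms(self) -> list:
        return [a for a in self.atoms.values() if not a.is_backbone()]


class DomainStructure:
    """Atomic model of one domain, optionally with a bound peptide chain.

    Residue indices are 0-based and contiguous per chain; original PDB
    author numbering is retained on each :class:`Residue` for reporting.
    """

    def __init__(self, atoms: list[Atom], model_index: int = 0):
        if not atoms:
            raise EmptyStructureError("structure contains no standard residues")
        self.atoms = list(atoms)
        self.model_index = model_index
        self._residues: dict[str, list[Residue]] = {}
        for atom in self.atoms:
            chain = self._residues.setdefault(atom.chain_id, [])
            if not chain or chain[-1].index != atom.residue_index:
                if chain and atom.residue_index != chain[-1].index + 1:
                    raise StructureError(
                        f"non-contiguous residue index {atom.residue_index} "
                        f"in chain {atom.chain_id}"
                    )
                chain.append(Residue(atom.residue_index, atom.residue_name, atom.chain_id))
            chain[-1].atoms[atom.name] = atom
        if not any(len(c) >= 3 for c in self._residues.values()):
            logger.warning("no chain with >= 3 residues")

    @property
    def chains(self) -> dict[str, int]:
        return {cid: len(res) for cid, res in self._residues.items()}

    def residues(self, chain_id: str) -> list[Residue]:
        return self._residues[chain_id]

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self._residues[chain_id])

    def first_chain(self) -> str:
        return next(iter(self._residues))

    def chain_coords(self, chain_id: str, heavy_only: bool = True) -> np.ndarray:
        atoms = [a for a in self.atoms if a.chain_id == chain_id
                 and (a.is_heavy() or not heavy_only)]
        return np.array([a.coords for a in atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "DomainStructure":
        """Return a copy under the rigid motion x -> R x + t."""
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_index, a.residue_name,
                 a.chain_id, rotation @ a.coords + translation)
            for a in self.atoms
        ]
        return DomainStructure(atoms, self.model_index)


@dataclass(frozen=True)
class HBond:
    """A donor->acceptor hydrogen bond, classified for feature encoding."""

    donor: tuple  # (chain_id, residue_index, atom name)
    acceptor: tuple
    kind: str  # sidechain_mainchain_amide | sidechain_mainchain_carbonyl | sidechain_sidechain
    distance: float


HB_SC_MC_AMIDE = "sidechain_mainchain_amide"
HB_SC_MC_CARBONYL = "sidechain_mainchain_carbonyl"
HB_SC_SC = "sidechain_sidechain"


@dataclass
class BindingSiteDefinition:
    """Ordered core binding-site positions (alignment columns or residue
    indices; default length 10)."""

    positions: list[int]
    provenance: str = "configured"  # derived | configured

    def __post_init__(self):
        if len(self.positions) < 1:
            raise ValueError("binding site needs at least one position")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("binding-site positions must be unique")

    def __len__(self) -> int:
        return len(self.positions)

    def to_tsv(self) -> str:
        lines = ["position\tprovenance"]
        lines += [f"{p}\t{self.provenance}" for p in self.positions]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "BindingSiteDefinition":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        return cls([int(r[0]) for r in rows], rows[0][1] if rows else "configured")


# ---------------------------------------------------------------------------
# parsing


def _validate_atom_records(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise StructureParseError(
                    f"line {lineno}: ATOM record shorter than coordinate fields"
                )
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise StructureParseError(
                    f"line {lineno}: unparseable coordinates in ATOM record"
                ) from None


def _pick_altloc(children) -> object:
    # highest occupancy wins; ties broken by alphabetical altloc id
    return min(children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))


def parse_structure(pdb_text: str, model_index: int = 0) -> DomainStructure:
    """Parse PDB text into a :class:`DomainStructure`.

    Only the requested model is kept (default: the first, matching the
    convention of using only the first model of NMR ensembles).  HETATM
    records, waters and non-standard residues are discarded; alternate
    locations are resolved by highest occupancy, then alphabetical id.
    """
    _validate_atom_records(pdb_text)
    parser = PDBParser(QUIET=True)
    bio_structure = parser.get_structure("domain", io.StringIO(pdb_text))
    models = list(bio_structure)
    if not models:
        raise EmptyStructureError("no models in PDB input")
    if model_index >= len(models):
        raise StructureError(
            f"model_index {model_index} out of range ({len(models)} models)"
        )
    model = models[model_index]

    atoms: list[Atom] = []
    author_ids: dict[tuple[str, int], str] = {}
    for chain in model:
        residue_index = -1
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag.strip():
                continue  # HETATM / waters
            if residue.resname in WATER_NAMES or residue.resname not in AA3_TO_1:
                logger.info("discarding non-standard residue %s", residue.resname)
                continue
            residue_index += 1
            author_ids[(chain.id, residue_index)] = f"{resseq}{icode}".strip()
            for bio_atom in residue:
                if bio_atom.is_disordered():
                    bio_atom = _pick_altloc(bio_atom.disordered_get_list())
                coords = np.asarray(bio_atom.get_coord(), dtype=float)
                if not np.all(np.isfinite(coords)):
                    raise StructureParseError(
                        f"non-finite coordinates for atom {bio_atom.get_serial_number()}"
                    )
                element = (bio_atom.element or "").strip() or bio_atom.get_name()[0]
                atoms.append(
                    Atom(
                        serial=bio_atom.get_serial_number() or 0,
                        name=bio_atom.get_name(),
                        element=element.upper(),
                        residue_index=residue_index,
                        residue_name=residue.resname,
                        chain_id=chain.id,
                        coords=coords,
                    )
                )
    if not atoms:
        raise EmptyStructureError("no standard amino-acid residues in model")
    structure = DomainStructure(atoms, model_index=model_index)
    for (cid, idx), author in author_ids.items():
        structure.residues(cid)[idx].author_id = author
    return structure


# ---------------------------------------------------------------------------
# dihedrals


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    angle = math.degrees(math.atan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))
    return 180.0 if angle <= -180.0 + 1e-12 else angle


def compute_phi(structure: DomainStructure, chain_id: str) -> list[float | None]:
    """Backbone phi per residue; ``None`` where undefined (first residue,
    missing backbone atoms) — undefined is flagged, never silently zero."""
    residues = structure.residues(chain_id)
    phi: list[float | None] = [None] * len(residues)
    for i in range(1, len(residues)):
        prev, cur = residues[i - 1], residues[i]
        try:
            phi[i] = dihedral(
                prev.atoms["C"].coords,
                cur.atoms["N"].coords,
                cur.atoms["CA"].coords,
                cur.atoms["C"].coords,
            )
        except KeyError as missing:
            logger.info(
                "phi undefined for %s:%d (missing backbone atom %s)",
                chain_id, i, missing,
            )
    return phi


# ---------------------------------------------------------------------------
# hydrogen bonds


def _angle_deg(a, b, c) -> float:
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(
    structure: DomainStructure,
    max_distance: float = 3.5,
    min_angle: float = 90.0,
) -> list[HBond]:
    """Detect side-chain-involving hydrogen bonds with geometric criteria.

    A donor-acceptor pair forms a bond when the donor-acceptor distance is
    <= ``max_distance`` and (hydrogens being absent from most inputs) the
    antecedent-donor-acceptor angle is >= ``min_angle``.  Bonds are
    classified by which partner is a side-chain atom; main-chain/main-chain
    pairs are not reported because the encoding does not use them.
    """
    donors = []  # (Atom, antecedent Atom|None, is_sidechain)
    acceptors = []  # (Atom, is_sidechain, kind-if-mainchain)
    for chain_id, residues in structure._residues.items():
        for res in residues:
            if "N" in res.atoms and res.name != "PRO":
                donors.append((res.atoms["N"], res.atoms.get("CA"), False))
            if "O" in res.atoms:
                acceptors.append((res.atoms["O"], False))
            for (rname, aname), antecedent in SIDECHAIN_DONORS.items():
                if rname == res.name and aname in res.atoms:
                    ante = res.atoms.get(antecedent) or res.atoms.get("CA")
                    donors.append((res.atoms[aname], ante, True))
            for rname, aname in SIDECHAIN_ACCEPTORS:
                if rname == res.name and aname in res.atoms:
                    acceptors.append((res.atoms[aname], True))

    if not donors or not acceptors:
        return []
    acc_tree = cKDTree(np.array([a.coords for a, _ in acceptors]))
    bonds: list[HBond] = []
    for donor, antecedent, donor_sc in donors:
        for j in acc_tree.query_ball_point(donor.coords, max_distance):
            acceptor, acc_sc = acceptors[j]
            if (acceptor.chain_id == donor.chain_id
                    and acceptor.residue_index == donor.residue_index):
                continue
            if not donor_sc and not acc_sc:
                continue  # backbone-backbone, not encoded
            dist = float(np.linalg.norm(donor.coords - acceptor.coords))
            if dist > max_distance:
                continue
            if antecedent is not None and _angle_deg(
                    antecedent.coords, donor.coords, acceptor.coords) < min_angle:
                continue
            if donor_sc and acc_sc:
                kind = HB_SC_SC
            elif donor_sc:  # side-chain donor to backbone carbonyl O
                kind = HB_SC_MC_CARBONYL
            else:  # backbone amide N donating to a side-chain acceptor
                kind = HB_SC_MC_AMIDE
            bonds.append(HBond(
                donor=(donor.chain_id, donor.residue_index, donor.name),
                acceptor=(acceptor.chain_id, acceptor.residue_index, acceptor.name),
                kind=kind,
                distance=dist,
            ))
    return bonds


def sidechain_hbond_flags(structure: DomainStructure, bonds: list[HBond] | None = None):
    """Per-residue booleans (amide, carbonyl, sidechain) saying whether the
    residue's side chain takes part in a bond of each encoded kind."""
    if bonds is None:
        bonds = detect_hbonds(structure)
    flags: dict[tuple[str, int], dict[str, bool]] = {}

    def _mark(chain_id, idx, kind):
        flags.setdefault((chain_id, idx), {
            HB_SC_MC_AMIDE: False, HB_SC_MC_CARBONYL: False, HB_SC_SC: False,
        })[kind] = True

    for bond in bonds:
        d_chain, d_idx, d_name = bond.donor
        a_chain, a_idx, a_name = bond.acceptor
        if bond.kind == HB_SC_SC:
            _mark(d_chain, d_idx, HB_SC_SC)
            _mark(a_chain, a_idx, HB_SC_SC)
        elif bond.kind == HB_SC_MC_CARBONYL:  # side chain is the donor
            _mark(d_chain, d_idx, HB_SC_MC_CARBONYL)
        else:  # amide donates; the side chain is the acceptor
            _mark(a_chain, a_idx, HB_SC_MC_AMIDE)
    return flags


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)


def sphere_points(n: int) -> np.ndarray:
    """n approximately uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def canonical_transform(coords: np.ndarray):
    """Deterministic molecule frame anchored on the first three
    non-collinear atoms (Gram-Schmidt, right-handed).  Computing sphere
    exposure in this frame makes areas and surface points exactly
    invariant under rigid motion of the input coordinates."""
    coords = np.asarray(coords, float)
    origin = coords[0]
    e1 = e2 = None
    for i in range(1, len(coords)):
        v = coords[i] - origin
        if np.linalg.norm(v) > 1e-6:
            e1 = v / np.linalg.norm(v)
            break
    if e1 is not None:
        for j in range(i + 1, len(coords)):
            w = coords[j] - origin
            w = w - (w @ e1) * e1
            if np.linalg.norm(w) > 1e-6:
                e2 = w / np.linalg.norm(w)
                break
    if e1 is None or e2 is None:  # < 3 non-collinear atoms: identity frame
        return np.eye(3), origin
    axes = np.column_stack([e1, e2, np.cross(e1, e2)])
    return axes, origin


@dataclass
class SasaResult:
    atom_areas: np.ndarray  # per atom, Angstrom^2
    residue_areas: dict  # (chain_id, residue_index) -> Angstrom^2
    relative: dict  # (chain_id, residue_index) -> area / Gly-X-Gly reference
    total: float
    exposed_points: np.ndarray | None = None  # (m, 3) surface points
    exposed_owner: np.ndarray | None = None  # (m,) atom index owning each point


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
    return_points: bool = False,
):
    """Shrake-Rupley areas for a set of spheres; optionally the exposed
    surface points themselves (reused for surface-property sampling)."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    unit = sphere_points(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.zeros(len(coords))
    points_out, owners_out = [], []
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= d >= expanded[j]
        frac = exposed.sum() / n_points
        areas[i] = 4.0 * math.pi * expanded[i] ** 2 * frac
        if return_points and exposed.any():
            points_out.append(pts[exposed])
            owners_out.append(np.full(int(exposed.sum()), i))
    if return_points:
        pts = np.vstack(points_out) if points_out else np.empty((0, 3))
        own = np.concatenate(owners_out) if owners_out else np.empty(0, int)
        return areas, pts, own
    return areas


def compute_sasa(
    structure: DomainStructure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    return_points: bool = False,
) -> SasaResult:
    """Per-residue solvent-accessible area and relative accessibility.

    Relative accessibility divides the residue area by its extended
    Gly-X-Gly reference; values are reported uncapped (may exceed 1).
    """
    heavy = [a for a in structure.atoms if a.is_heavy()]
    for atom in heavy:
        if atom.element not in VDW_RADII:
            raise StructureError(
                f"no van der Waals radius for element {atom.element!r} "
                f"(atom {atom.name} in {atom.residue_name})"
            )
    coords = np.array([a.coords for a in heavy])
    radii = np.array([VDW_RADII[a.element] for a in heavy])
    axes, centroid = canonical_transform(coords)
    out = shrake_rupley((coords - centroid) @ axes, radii,
                        probe_radius, n_points, return_points)
    if return_points:
        areas, pts, own = out
        pts = pts @ axes.T + centroid  # back to the input frame
    else:
        areas, pts, own = out, None, None

    residue_areas: dict = {}
    for atom, area in zip(heavy, areas):
        key = (atom.chain_id, atom.residue_index)
        residue_areas[key] = residue_areas.get(key, 0.0) + float(area)
    relative = {}
    for (chain_id, idx), area in residue_areas.items():
        one = structure.residues(chain_id)[idx].one_letter
        relative[(chain_id, idx)] = area / GXG_REFERENCE_AREA[one]
    return SasaResult(
        atom_areas=areas,
        residue_areas=residue_areas,
        relative=relative,
        total=float(areas.sum()),
        exposed_points=pts,
        exposed_owner=own,
    )


# ---------------------------------------------------------------------------
# core binding-site derivation


def contacting_residues(
    structure: DomainStructure,
    domain_chain: str,
    peptide_chain: str,
    contact_cutoff: float = 4.5,
) -> set[int]:
    """Domain residue indices with any heavy atom strictly closer than
    ``contact_cutoff`` to any peptide heavy atom."""
    pep = structure.chain_coords(peptide_chain, heavy_only=True)
    if len(pep) == 0:
        return set()
    tree = cKDTree(pep)
    hits: set[int] = set()
    for atom in structure.atoms:
        if atom.chain_id != domain_chain or not atom.is_heavy():
            continue
        d, _ = tree.query(atom.coords)
        if d < contact_cutoff:  # strict, boundary excluded
            hits.add(atom.residue_index)
    return hits


def derive_core_positions(
    complexes: list[tuple[DomainStructure, str, str]],
    alignments: list[dict[int, int]] | None = None,
    contact_cutoff: float = 4.5,
    min_structures: int | None = None,
) -> BindingSiteDefinition:
    """Derive the core binding-site columns from domain-peptide complexes.

    Each complex is (structure, domain_chain, peptide_chain); ``alignments``
    maps each complex's domain residue index to a shared alignment column
    (identity if omitted).  A column is kept when it contacts the peptide
    (< ``contact_cutoff``, heavy atoms) in at least ``min_structures``
    complexes (default: a majority).  Output is ordered by column index.
    """
    if not complexes:
        raise ValueError("need at least one complex")
    if min_structures is None:
        min_structures = len(complexes) // 2 + 1
    counts: dict[int, int] = {}
    for k, (structure, domain_chain, peptide_chain) in enumerate(complexes):
        mapping = alignments[k] if alignments is not None else None
        columns = {
            mapping[idx] if mapping is not None else idx
            for idx in contacting_residues(structure, domain_chain, peptide_chain,
                                           contact_cutoff)
        }
        for column in columns:  # one vote per structure per column
            counts[column] = counts.get(column, 0) + 1
    positions = sorted(c for c, n in counts.items() if n >= min_structures)
    if not positions:
        raise EmptyBindingSiteError(
            f"no columns contact the peptide in >= {min_structures} complexes"
        )
    return BindingSiteDefinition(positions=positions, provenance="derived")
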