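"""Feature encoding for domains and C-terminal pentapeptides.

A domain is encoded as 240 values over its ten core binding-site
positions, in a fixed block layout:

* 50 binaries (5 per position): solvent accessible, side chain H-bonded
  to a main-chain amide, to a main-chain carbonyl, to another side chain,
  positive phi angle;
* 10 solvent-accessible areas (A^2, one per position);
* 90 electrostatic-potential samples (9 surface points per position);
* 90 hydrophobicity samples (9 surface points per position).

A pentapeptide is a 100-bit sparse vector: per residue a 20-bit one-hot
block over the alphabet A,C,D,...,Y (alphabetical 1-letter codes),
positions ordered -4..0 with 0 the C-terminus.

Surface properties are desk-scale physical stand-ins: a Coulomb potential
with distance-dependent dielectric (eps = 4r) over a bundled partial-charge
table, and the Kyte-Doolittle index of the residue owning each exposed
surface point.  Both are pluggable via the ``potential_fn`` hook.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
import io as _io

from .structure import (
    BindingSiteDefinition,
    DomainStructure,
    compute_phi,
    compute_sasa,
    sidechain_hbond_flags,
)
from .tables import (
    AA3_TO_1,
    AA_INDEX,
    ALPHABET,
    COULOMB_KCAL,
    KYTE_DOOLITTLE,
    PARTIAL_CHARGES,
)

logger = logging.getLogger(__name__)

N_STRUCTURE_FEATURES = 240
N_PEPTIDE_FEATURES = 100
PEPTIDE_LENGTH = 5
DEFAULT_SURFACE_SAMPLES = 9
ACCESSIBLE_THRESHOLD = 0.07  # relative accessibility >= 7% -> accessible

# block slices of the 240-vector
JOY_SLICE = slice(0, 50)
AREA_SLICE = slice(50, 60)
ELEC_SLICE = slice(60, 150)
HYDRO_SLICE = slice(150, 240)


class EncodingError(ValueError):
    pass


class UnsupportedDomainError(EncodingError):
    """A binding-site position cannot be resolved in the structure (gap)."""


@dataclass
class StructureFeatureVector:
    values: np.ndarray  # length 240
    domain_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != (N_STRUCTURE_FEATURES,):
            raise EncodingError(
                f"structure vector must have {N_STRUCTURE_FEATURES} values"
            )

    @property
    def joy(self) -> np.ndarray:
        return self.values[JOY_SLICE]

    @property
    def area(self) -> np.ndarray:
        return self.values[AREA_SLICE]

    @property
    def electrostatic(self) -> np.ndarray:
        return self.values[ELEC_SLICE]

    @property
    def hydrophobicity(self) -> np.ndarray:
        return self.values[HYDRO_SLICE]


@dataclass
class PeptideFeatureVector:
    bits: np.ndarray  # length 100, uint8
    peptide: str

    def __post_init__(self):
        self.bits = np.asarray(self.bits, np.uint8)
        if self.bits.shape != (N_PEPTIDE_FEATURES,):
            raise EncodingError(f"peptide vector must have {N_PEPTIDE_FEATURES} bits")


def _site_residues(structure: DomainStructure, site: BindingSiteDefinition,
                   chain_id: str):
    residues = structure.residues(chain_id)
    out = []
    for pos in site.positions:
        if pos < 0 or pos >= len(residues):
            raise UnsupportedDomainError(
                f"binding-site position {pos} not present in chain {chain_id} "
                f"({len(residues)} residues): domain unsupported (gap)"
            )
        out.append(residues[pos])
    return out


def encode_joy_block(
    structure: DomainStructure,
    site: BindingSiteDefinition,
    chain_id: str | None = None,
    sasa=None,
    hbond_flags=None,
    phi=None,
) -> np.ndarray:
    """5 binaries per core position: [accessible, sc->mc-amide,
    sc->mc-carbonyl, sc->sc, positive phi].  Undefined phi encodes 0."""
    from .structure import HB_SC_MC_AMIDE, HB_SC_MC_CARBONYL, HB_SC_SC

    chain_id = chain_id or structure.first_chain()
    residues = _site_residues(structure, site, chain_id)
    if sasa is None:
        sasa = compute_sasa(structure)
    if hbond_flags is None:
        hbond_flags = sidechain_hbond_flags(structure)
    if phi is None:
        phi = compute_phi(structure, chain_id)
    bits = np.zeros(5 * len(site), dtype=float)
    for k, res in enumerate(residues):
        key = (chain_id, res.index)
        flags = hbond_flags.get(key, {})
        angle = phi[res.index]
        bits[5 * k:5 * k + 5] = [
            1.0 if sasa.relative.get(key, 0.0) >= ACCESSIBLE_THRESHOLD else 0.0,
            1.0 if flags.get(HB_SC_MC_AMIDE) else 0.0,
            1.0 if flags.get(HB_SC_MC_CARBONYL) else 0.0,
            1.0 if flags.get(HB_SC_SC) else 0.0,
            1.0 if (angle is not None and angle > 0.0) else 0.0,
        ]
    return bits


def encode_area_block(
    structure: DomainStructure,
    site: BindingSiteDefinition,
    chain_id: str | None = None,
    sasa=None,
) -> np.ndarray:
    """Per-position solvent-accessible area (A^2), in site order."""
    chain_id = chain_id or structure.first_chain()
    residues = _site_residues(structure, site, chain_id)
    if sasa is None:
        sasa = compute_sasa(structure)
    return np.array(
        [sasa.residue_areas.get((chain_id, r.index), 0.0) for r in residues]
    )


def coulomb_potential(points: np.ndarray, structure: DomainStructure) -> np.ndarray:
    """Electrostatic potential at surface points: Coulomb sum over the
    bundled partial charges with distance-dependent dielectric eps = 4r,
    i.e. V(p) = k * sum_j q_j / (4 d_pj^2), in kcal/(mol e)."""
    charged = [
        (a.coords, PARTIAL_CHARGES[(a.residue_name, a.name)])
        for a in structure.atoms
        if (a.residue_name, a.name) in PARTIAL_CHARGES
    ]
    if not charged:
        return np.zeros(len(points))
    pos = np.array([c for c, _ in charged])
    q = np.array([v for _, v in charged])
    d2 = ((points[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    d2 = np.maximum(d2, 1e-6)
    return COULOMB_KCAL * (q[None, :] / (4.0 * d2)).sum(axis=1)


def sample_surface_values(
    structure: DomainStructure,
    site: BindingSiteDefinition,
    field: str,
    chain_id: str | None = None,
    n_samples: int = DEFAULT_SURFACE_SAMPLES,
    sasa=None,
    potential_fn=None,
) -> np.ndarray:
    """``n_samples`` surface-property values per core position.

    The molecular surface is the set of exposed Shrake-Rupley sphere
    points; per position the ``n_samples`` points nearest the residue's
    side-chain centroid are taken, ordered by distance (deterministic).
    A position whose residue exposes no surface at all yields zeros.
    """
    if field not in ("electrostatic", "hydrophobicity"):
        raise ValueError(f"unknown surface field {field!r}")
    chain_id = chain_id or structure.first_chain()
    residues = _site_residues(structure, site, chain_id)
    if sasa is None or sasa.exposed_points is None:
        sasa = compute_sasa(structure, return_points=True)
    points = sasa.exposed_points
    owners = sasa.exposed_owner
    heavy = [a for a in structure.atoms if a.is_heavy()]

    if field == "electrostatic":
        fn = potential_fn or coulomb_potential
        point_values = fn(points, structure) if len(points) else np.empty(0)
    else:
        kd = np.array([KYTE_DOOLITTLE[AA3_TO_1[a.residue_name]] for a in heavy])
        point_values = kd[owners] if len(points) else np.empty(0)

    out = np.zeros(len(site) * n_samples)
    for k, res in enumerate(residues):
        key = (chain_id, res.index)
        if sasa.residue_areas.get(key, 0.0) <= 0.0 or len(points) == 0:
            logger.info("position %d (%s:%d) has no exposed surface; zeros",
                        k, chain_id, res.index)
            continue
        side = res.sidechain_atoms()
        anchor_atoms = side if side else [res.atoms["CA"]] if "CA" in res.atoms \
            else list(res.atoms.values())
        centroid = np.mean([a.coords for a in anchor_atoms], axis=0)
        # distances rounded so that float noise from rigid motions cannot
        # reorder the stable sort (ties fall back to point index)
        dists = np.round(np.linalg.norm(points - centroid, axis=1), 6)
        order = np.argsort(dists, kind="stable")[:n_samples]
        vals = point_values[order]
        out[k * n_samples:k * n_samples + len(vals)] = vals
    return out


def encode_domain(
    structure: DomainStructure,
    site: BindingSiteDefinition,
    chain_id: str | None = None,
    scaler: "FeatureScaler | None" = None,
    domain_id: str = "",
    n_samples: int = DEFAULT_SURFACE_SAMPLES,
) -> StructureFeatureVector:
    """Full 240-value structure encoding, optionally min-max scaled."""
    chain_id = chain_id or structure.first_chain()
    sasa = compute_sasa(structure, return_points=True)
    values = np.concatenate([
        encode_joy_block(structure, site, chain_id, sasa=sasa),
        encode_area_block(structure, site, chain_id, sasa=sasa),
        sample_surface_values(structure, site, "electrostatic", chain_id,
                              n_samples, sasa=sasa),
        sample_surface_values(structure, site, "hydrophobicity", chain_id,
                              n_samples, sasa=sasa),
    ])
    if scaler is not None:
        values = scaler.transform(values)
    return StructureFeatureVector(values=values, domain_id=domain_id)


# ---------------------------------------------------------------------------
# peptides


def encode_peptide(peptide: str) -> PeptideFeatureVector:
    """Sparse binary encoding: 5 positions x 20 amino-acid indicator bits."""
    if len(peptide) != PEPTIDE_LENGTH:
        raise EncodingError(
            f"peptide must have exactly {PEPTIDE_LENGTH} residues, got {peptide!r}"
        )
    bits = np.zeros(N_PEPTIDE_FEATURES, dtype=np.uint8)
    for i, letter in enumerate(peptide.upper()):
        if letter not in AA_INDEX:
            raise EncodingError(
                f"non-standard amino acid {letter!r} in peptide {peptide!r}"
            )
        bits[20 * i + AA_INDEX[letter]] = 1
    return PeptideFeatureVector(bits=bits, peptide=peptide.upper())


def decode_peptide(vector: PeptideFeatureVector | np.ndarray) -> str:
    bits = vector.bits if isinstance(vector, PeptideFeatureVector) else np.asarray(vector)
    letters = []
    for i in range(PEPTIDE_LENGTH):
        block = bits[20 * i:20 * (i + 1)]
        (idx,) = np.flatnonzero(block == 1)
        letters.append(ALPHABET[idx])
    return "".join(letters)


# ---------------------------------------------------------------------------
# C-termini extraction


@dataclass
class CTermini:
    """Unique C-terminal peptides of a proteome plus the id -> peptide map."""

    pairs: list  # (protein id, peptide)
    by_peptide: dict  # peptide -> sorted list of protein ids

    @property
    def unique_peptides(self) -> list[str]:
        return sorted(self.by_peptide)

    def __len__(self) -> int:
        return len(self.by_peptide)


def extract_ctermini(fasta_text: str, length: int = PEPTIDE_LENGTH) -> CTermini:
    """Last ``length`` residues of every FASTA record.

    Records shorter than ``length`` or whose tail contains non-standard
    letters are skipped with a log message.  Duplicate tails collapse into
    one unique peptide while retaining every protein id that carries it.
    """
    pairs = []
    by_peptide: dict[str, list[str]] = {}
    for record in SeqIO.parse(_io.StringIO(fasta_text), "fasta"):
        seq = str(record.seq).upper().rstrip("*")
        if len(seq) < length:
            logger.info("skipping %s: shorter than %d residues", record.id, length)
            continue
        tail = seq[-length:]
        if any(c not in AA_INDEX for c in tail):
            logger.info("skipping %s: non-standard letters in tail %s",
                        record.id, tail)
            continue
        pairs.append((record.id, tail))
        by_peptide.setdefault(tail, []).append(record.id)
    for ids in by_peptide.values():
        ids.sort()
    return CTermini(pairs=pairs, by_peptide=by_peptide)


# ---------------------------------------------------------------------------
# scaling


@dataclass
class FeatureScaler:
    """Per-dimension min-max scaler to [0, 1] on the fitting set.

    Dimensions with max == min map to 0.  Values outside the fitted range
    are NOT clamped: an unseen value of 20 after fitting on {0, 10} scales
    to 2.0.  Fit on training vectors only; transform everything else with
    the stored parameters.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    @classmethod
    def fit(cls, vectors) -> "FeatureScaler":
        matrix = np.asarray(
            [v.values if isinstance(v, StructureFeatureVector) else v
             for v in vectors], float)
        if matrix.ndim != 2 or len(matrix) < 1:
            raise EncodingError("need at least one vector to fit a scaler")
        return cls(minimum=matrix.min(axis=0), maximum=matrix.max(axis=0))

    def transform(self, vector: np.ndarray) -> np.ndarray:
        vector = np.asarray(vector, float)
        if vector.shape[-1] != self.minimum.shape[0]:
            raise EncodingError(
                f"dimension mismatch: scaler has {self.minimum.shape[0]}, "
                f"vector has {vector.shape[-1]}"
            )
        span = self.maximum - self.minimum
        safe = np.where(span > 0, span, 1.0)
        return np.where(span > 0, (vector - self.minimum) / safe, 0.0)

    def to_text(self) -> str:
        lines = ["dim\tmin\tmax"]
        lines += [f"{i}\t{float(lo):.17g}\t{float(hi):.17g}"
                  for i, (lo, hi) in enumerate(zip(self.minimum, self.maximum))]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "FeatureScaler":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        return cls(minimum=np.array([float(r[1]) for r in rows]),
                   maximum=np.array([float(r[2]) for r in rows]))


def feature_names(site_length: int = 10,
                  n_samples: int = DEFAULT_SURFACE_SAMPLES) -> list[str]:
    """Column names for the 340 dimensions of a domain+peptide pair."""
    names = []
    joy = ["accessible", "hb_mc_amide", "hb_mc_carbonyl", "hb_sc_sc", "pos_phi"]
    for p in range(site_length):
        names += [f"joy_p{p}_{b}" for b in joy]
    names += [f"area_p{p}" for p in range(site_length)]
    for block in ("elec", "hydro"):
        for p in range(site_length):
            names += [f"{block}_p{p}_s{s}" for s in range(n_samples)]
    for p in range(PEPTIDE_LENGTH):
        names += [f"pep_p{p - 4}_{a}" for a in ALPHABET]
    return names
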