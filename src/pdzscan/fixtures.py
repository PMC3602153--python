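"""Synthetic fixtures: toy structures, interaction sets and proteomes.

Everything the pipeline consumes can be generated here with no downloads:

* toy domain structures with idealized secondary structure (alpha-helix
  phi = -57 / psi = -47, beta-strand phi = -120 / psi = +120), single
  pseudo-atom side chains at Cbeta-extended geometry, and optionally a
  bound pentapeptide chain placed within contact distance of the binding
  site;
* interaction sets with a planted position-specific binding preference
  (one PWM per domain archetype) over the 5 C-terminal positions, plus
  low-scoring uniform-background negatives;
* toy proteomes whose C-terminal tails are a seeded mixture of
  planted-PWM binders and uniform background.

Fixtures exercise the package's contracts; they do not attempt realistic
PDZ folds.  Two archetypes differ in binding-site residue chemistry
(charged/polar vs hydrophobic), so domain feature vectors carry a
learnable class signal alongside the peptide bits.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .structure import BindingSiteDefinition, DomainStructure, parse_structure
from .tables import AA1_TO_3, ALPHABET, REPRESENTATIVE_SIDECHAIN_ATOM
from .training import PWM, InteractionRecord, score_peptide

# idealized backbone geometry (bond lengths in Angstrom, angles in degrees)
BOND_N_CA, BOND_CA_C, BOND_C_N, BOND_C_O = 1.458, 1.525, 1.329, 1.231
ANGLE_C_N_CA, ANGLE_N_CA_C, ANGLE_CA_C_N, ANGLE_CA_C_O = 121.7, 111.2, 116.2, 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 120.0

ARCHETYPE_CONSENSUS = ("RETQV", "NFDVL")  # class I-like, class II-like
ARCHETYPE_SITE_POOL = ("KDERSNQT", "LIVFAMYW")


@dataclass
class FixtureSpec:
    """Fully determines every fixture output given the seed."""

    seed: int = 0
    n_domains: int = 20
    n_archetypes: int = 2
    site_length: int = 10
    n_pos: int = 30
    n_neg: int = 60
    proteome_size: int = 300
    binder_fraction: float = 0.25
    strand_length: int = 10
    helix_length: int = 12
    consensus_weight: float = 0.6  # planted PWM mass on the consensus letter
    n_site_mutations: int = 2  # per-domain within-archetype site variation

    @property
    def chain_length(self) -> int:
        return self.strand_length + self.helix_length

    @property
    def site_positions(self) -> list[int]:
        # evenly spread residue indices, avoiding the chain termini
        step = max(1, (self.chain_length - 2) // self.site_length)
        return [1 + i * step for i in range(self.site_length)]

    def binding_site(self) -> BindingSiteDefinition:
        return BindingSiteDefinition(self.site_positions, provenance="configured")

    def archetype_of(self, index: int) -> int:
        return index % self.n_archetypes

    def domain_id(self, index: int) -> str:
        return f"D{index:03d}"

    def planted_pwm(self, archetype: int) -> PWM:
        consensus = ARCHETYPE_CONSENSUS[archetype % len(ARCHETYPE_CONSENSUS)]
        w = self.consensus_weight
        matrix = np.full((20, 5), (1.0 - w) / 19.0)
        for j, letter in enumerate(consensus):
            matrix[ALPHABET.index(letter), j] = w
        return PWM(matrix=matrix, n_sequences=0)


def _stable_tag(tag) -> int:
    if isinstance(tag, int):
        return tag & 0x7FFFFFFF
    return zlib.crc32(str(tag).encode()) & 0x7FFFFFFF


def _rng(spec: FixtureSpec, *tags) -> np.random.Generator:
    return np.random.default_rng(
        [spec.seed & 0x7FFFFFFF, *(_stable_tag(t) for t in tags)]
    )


# ---------------------------------------------------------------------------
# geometry construction


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF placement: the point d with |cd| = bond, angle(b,c,d) = angle
    and dihedral(a,b,c,d) = dihedral."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta, chi = math.radians(angle_deg), math.radians(dihedral_deg)
    local = bond * np.array([
        -math.cos(theta),
        math.sin(theta) * math.cos(chi),
        math.sin(theta) * math.sin(chi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    return c + np.column_stack([bc, m, n]) @ local


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict]:
    """Backbone atom positions (N, CA, C, O per residue) for given
    (phi, psi) targets; phi of the first residue is unrealized."""
    residues: list[dict] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    alpha = math.radians(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-math.cos(alpha), math.sin(alpha), 0.0])
    for i, (phi, psi) in enumerate(phi_psi):
        if i > 0:
            prev = residues[-1]
            n = place_atom(prev["N"], prev["CA"], prev["C"],
                           BOND_C_N, ANGLE_CA_C_N, psi_prev)
            ca = place_atom(prev["CA"], prev["C"], n,
                            BOND_N_CA, ANGLE_C_N_CA, 180.0)  # omega trans
            c = place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        residues.append({"N": n, "CA": ca, "C": c, "O": o})
        psi_prev = psi
    return residues


def _sidechain_pseudoatom(res: dict, extension: float = 2.4):
    """Cbeta-extended single pseudo-atom direction from ideal geometry."""
    cb = place_atom(res["N"], res["C"], res["CA"], 1.53, 110.5, -122.5)
    direction = cb - res["CA"]
    direction /= np.linalg.norm(direction)
    return res["CA"] + extension * direction


def _format_pdb_atom(serial, name, resname, chain, resseq, coords, element):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} {chain}{resseq:4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def chain_to_pdb_lines(sequence: str, residues: list[dict], chain_id: str,
                       serial_start: int = 1, with_sidechains: bool = True):
    lines = []
    serial = serial_start
    for i, (letter, res) in enumerate(zip(sequence, residues)):
        resname = AA1_TO_3[letter]
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            lines.append(_format_pdb_atom(serial, name, resname, chain_id,
                                          i + 1, res[name], element))
            serial += 1
        rep = REPRESENTATIVE_SIDECHAIN_ATOM[resname]
        if with_sidechains and rep is not None:
            name, element = rep
            lines.append(_format_pdb_atom(serial, name, resname, chain_id, i + 1,
                                          _sidechain_pseudoatom(res), element))
            serial += 1
    return lines, serial


def domain_sequence(spec: FixtureSpec, index: int) -> str:
    """Poly-Ala scaffold with archetype-specific binding-site residues and
    a couple of seeded within-archetype site mutations."""
    archetype = spec.archetype_of(index)
    pool = ARCHETYPE_SITE_POOL[archetype % len(ARCHETYPE_SITE_POOL)]
    rng = _rng(spec, "domain-seq", index)
    letters = ["A"] * spec.chain_length
    for k, pos in enumerate(spec.site_positions):
        letters[pos] = pool[k % len(pool)]
    for pos in rng.choice(spec.site_positions, size=min(
            spec.n_site_mutations, spec.site_length), replace=False):
        letters[pos] = pool[rng.integers(len(pool))]
    return "".join(letters)


def make_toy_domain(spec: FixtureSpec, index: int,
                    with_peptide: bool = False) -> str:
    """PDB text for one toy domain: a beta-strand segment followed by an
    alpha-helix.  With ``with_peptide``, a pentapeptide chain B (the
    archetype consensus) is placed so that at least one binding-site
    residue lies within 4.0 A of it.  Byte-identical for a given seed."""
    sequence = domain_sequence(spec, index)
    phi_psi = (
        [(STRAND_PHI, STRAND_PSI)] * spec.strand_length
        + [(HELIX_PHI, HELIX_PSI)] * spec.helix_length
    )
    residues = build_backbone(phi_psi)
    lines, serial = chain_to_pdb_lines(sequence, residues, "A")
    lines.append("TER")
    if with_peptide:
        consensus = ARCHETYPE_CONSENSUS[spec.archetype_of(index)]
        pep_residues = build_backbone([(STRAND_PHI, STRAND_PSI)] * 5)
        anchor_pos = spec.site_positions[0]
        anchor = _sidechain_pseudoatom(residues[anchor_pos])
        centroid = np.mean([r["CA"] for r in residues], axis=0)
        outward = anchor - centroid
        outward /= np.linalg.norm(outward)
        target = anchor + 4.0 * outward
        shift = target - pep_residues[2]["CA"]
        pep_residues = [{k: v + shift for k, v in r.items()} for r in pep_residues]
        pep_lines, _ = chain_to_pdb_lines(consensus, pep_residues, "B",
                                          serial_start=serial)
        lines += pep_lines
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_domain_structures(spec: FixtureSpec, with_peptide: bool = False):
    """{domain_id: DomainStructure} for all domains of the spec."""
    return {
        spec.domain_id(i): parse_structure(make_toy_domain(spec, i, with_peptide))
        for i in range(spec.n_domains)
    }


def site_sequence(spec: FixtureSpec, index: int) -> str:
    seq = domain_sequence(spec, index)
    return "".join(seq[p] for p in spec.site_positions)


# ---------------------------------------------------------------------------
# interaction sets


def sample_peptide(pwm: PWM, rng: np.random.Generator) -> str:
    cols = [rng.choice(20, p=pwm.matrix[:, j]) for j in range(5)]
    return "".join(ALPHABET[c] for c in cols)


def make_interactions(spec: FixtureSpec):
    """Interaction records with a planted specificity per domain.

    Positives are sampled from the domain archetype's planted PWM;
    negatives are uniform-background pentapeptides rejected whenever their
    planted-PWM score reaches the lowest positive's score.  Returns
    (records, {archetype: planted PWM}).
    """
    records: list[InteractionRecord] = []
    planted = {a: spec.planted_pwm(a) for a in range(spec.n_archetypes)}
    for index in range(spec.n_domains):
        domain_id = spec.domain_id(index)
        archetype = spec.archetype_of(index)
        pwm = planted[archetype]
        rng = _rng(spec, "interactions", index)
        # smoothed copy for scoring so degenerate (one-hot) planted PWMs
        # can still rank background peptides
        score_pwm = PWM(matrix=(pwm.matrix + 1e-6)
                        / (pwm.matrix + 1e-6).sum(axis=0, keepdims=True))
        positives: list[str] = []
        seen: set[str] = set()
        attempts = 0
        while len(positives) < spec.n_pos:
            attempts += 1
            if attempts > 200 * spec.n_pos:
                raise RuntimeError(
                    "rejection sampling stalled while drawing positives"
                )
            pep = sample_peptide(pwm, rng)
            if pep not in seen:
                seen.add(pep)
                positives.append(pep)
        min_pos_score = min(score_peptide(score_pwm, p) for p in positives)
        negatives: set[str] = set()
        attempts = 0
        while len(negatives) < spec.n_neg:
            attempts += 1
            if attempts > 200 * spec.n_neg:
                raise RuntimeError(
                    "rejection sampling stalled while drawing negatives"
                )
            pep = "".join(ALPHABET[i] for i in rng.integers(0, 20, size=5))
            if pep in seen or score_peptide(score_pwm, pep) > min_pos_score:
                continue
            negatives.add(pep)
        records += [InteractionRecord(domain_id, p, +1) for p in positives]
        records += [InteractionRecord(domain_id, p, -1)
                    for p in sorted(negatives)]
    return records, planted


# ---------------------------------------------------------------------------
# toy proteome


def make_toy_proteome(spec: FixtureSpec, protein_length: int = 30) -> str:
    """FASTA text: ``binder_fraction`` of the tails are sampled from the
    planted PWMs (cycling archetypes), the rest are uniform background
    (never equal to a planted consensus)."""
    rng = _rng(spec, "proteome")
    consensi = {ARCHETYPE_CONSENSUS[a % len(ARCHETYPE_CONSENSUS)]
                for a in range(spec.n_archetypes)}
    planted = [spec.planted_pwm(a) for a in range(spec.n_archetypes)]
    n_binders = round(spec.binder_fraction * spec.proteome_size)
    entries = []
    for i in range(spec.proteome_size):
        body = "".join(ALPHABET[j]
                       for j in rng.integers(0, 20, size=protein_length - 5))
        if i < n_binders:
            tail = sample_peptide(planted[i % len(planted)], rng)
        else:
            tail = "".join(ALPHABET[j] for j in rng.integers(0, 20, size=5))
            while tail in consensi:
                tail = "".join(ALPHABET[j] for j in rng.integers(0, 20, size=5))
        entries.append(f">P{i:04d} synthetic\n{body}{tail}")
    return "\n".join(entries) + "\n"


# ---------------------------------------------------------------------------
# one-call pipeline inputs


def encode_fixture_domains(spec: FixtureSpec, structures=None):
    """Raw (unscaled) 240-vectors and binding-site sequences per domain."""
    from .features import encode_domain

    structures = structures or make_domain_structures(spec)
    site = spec.binding_site()
    vectors, sequences = {}, {}
    for index in range(spec.n_domains):
        domain_id = spec.domain_id(index)
        vec = encode_domain(structures[domain_id], site, "A",
                            domain_id=domain_id)
        vectors[domain_id] = vec.values
        sequences[domain_id] = site_sequence(spec, index)
    return vectors, sequences
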