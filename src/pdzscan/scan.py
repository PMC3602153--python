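"""Proteome scanning with a trained model, and binding-specificity
summaries of the hits.

Scanning predicts every (domain, unique C-terminal pentapeptide) pair
once, then expands hits back to all proteins carrying that C-terminus.
Per-domain hit counts are the over-prediction diagnostic the
semi-supervised expansion loop acts on.  Hits per domain are summarized
as a PWM over ligand positions -4..0 (0 = C-terminus) and compared to
reference specificities by a normalized Euclidean similarity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import CTermini
from .svm import TrainedModel, predict
from .tables import ALPHABET
from .training import PWM, build_pwm

logger = logging.getLogger(__name__)


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class ScanHit:
    domain_id: str
    protein_id: str
    peptide: str
    decision_value: float

    def __post_init__(self):
        if self.decision_value < 0:
            raise ScanError("hits must have non-negative decision values")


def scan_peptides(model: TrainedModel, domain_vectors: dict, peptides) -> dict:
    """Predict each unique peptide against each domain; return
    {domain_id: [(peptide, decision_value), ...]} for predicted binders."""
    peptides = sorted(set(peptides))
    hits: dict[str, list] = {}
    for domain_id in sorted(domain_vectors):
        vec = domain_vectors[domain_id]
        preds = predict(model, [(domain_id, p, vec) for p in peptides])
        hits[domain_id] = [(p.peptide, p.decision_value)
                           for p in preds if p.label == +1]
    return hits


def scan_proteome(
    model: TrainedModel,
    domain_vectors: dict,
    ctermini: CTermini,
    min_decision: float = 0.0,
) -> tuple[list[ScanHit], dict]:
    """Scan a C-terminal proteome for predicted binders of each domain.

    Each (domain, unique peptide) pair is predicted once; hits (decision
    value >= ``min_decision``, default the sign threshold 0) are expanded
    to every protein id carrying that C-terminus.  Returns the hits plus
    per-domain unique-peptide hit counts.
    """
    peptide_hits = scan_peptides(model, domain_vectors, ctermini.unique_peptides)
    hits: list[ScanHit] = []
    counts: dict[str, int] = {}
    for domain_id in sorted(peptide_hits):
        kept = [(pep, dv) for pep, dv in peptide_hits[domain_id]
                if dv >= min_decision]
        counts[domain_id] = len(kept)
        for peptide, decision in kept:
            for protein_id in ctermini.by_peptide[peptide]:
                hits.append(ScanHit(domain_id, protein_id, peptide, decision))
    return hits, counts


def predicted_pwm(hits, pseudocount: float = 0.0, min_peptides: int = 4) -> PWM:
    """PWM over ligand positions -4..0 from one domain's scan hits.

    Refuses to summarize fewer than ``min_peptides`` hit peptides (too few
    to define a specificity); repeated peptides count with multiplicity.
    """
    peptides = [h.peptide if isinstance(h, ScanHit) else h for h in hits]
    if len(peptides) < min_peptides:
        raise ScanError(
            f"only {len(peptides)} hit peptides; "
            f"need >= {min_peptides} to summarize a binding specificity"
        )
    return build_pwm(peptides, pseudocount=pseudocount)


def pwm_similarity(pwm_a: PWM, pwm_b: PWM) -> float:
    """Normalized Euclidean similarity between probability matrices.

    similarity = 1 - D / D_max with D the Euclidean (Frobenius) distance
    and D_max = sqrt(2 * n_columns), the largest distance two
    column-stochastic matrices of that shape can achieve (disjoint
    one-hot columns).  1 iff identical, 0 for fully disjoint consensi.
    """
    if pwm_a.matrix.shape != pwm_b.matrix.shape:
        raise ScanError("PWM shapes differ")
    d = float(np.linalg.norm(pwm_a.matrix - pwm_b.matrix))
    d_max = float(np.sqrt(2.0 * pwm_a.matrix.shape[1]))
    return 1.0 - d / d_max


def information_content(pwm: PWM, background: float = 0.05) -> np.ndarray:
    """Per-position information content (bits), Schneider-Stephens style."""
    p = np.maximum(pwm.matrix, 1e-12)
    return np.sum(p * np.log2(p / background), axis=0)


def hits_to_tsv(hits) -> str:
    lines = ["domain_id\tprotein_id\tpeptide\tdecision_value"]
    lines += [f"{h.domain_id}\t{h.protein_id}\t{h.peptide}\t{h.decision_value:.6g}"
              for h in hits]
    return "\n".join(lines) + "\n"


def render_logo(pwm: PWM, path=None, ax=None, title: str = ""):
    """Render a sequence logo (information-content letter stacks) from a
    PWM; a reporting convenience for eyeballing binding specificities."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import transforms
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath

    colors = {aa: ("#2c7fb8" if aa in "STCNQY" else
                   "#d7301f" if aa in "DE" else
                   "#225ea8" if aa in "KRH" else
                   "#35978f" if aa in "G P".replace(" ", "") else "#555555")
              for aa in ALPHABET}
    if ax is None:
        _fig, ax = plt.subplots(figsize=(4, 2.2))
    ic = information_content(pwm)
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for col in range(pwm.matrix.shape[1]):
        stack = sorted(
            ((pwm.matrix[i, col], ALPHABET[i]) for i in range(20)
             if pwm.matrix[i, col] > 0.01),
        )
        y = 0.0
        for prob, aa in stack:
            height = prob * ic[col]
            if height <= 1e-3:
                continue
            tp = TextPath((0, 0), aa, size=1.0, prop=font)
            bbox = tp.get_extents()
            scale_x = 0.8 / bbox.width
            scale_y = height / bbox.height
            offset = transforms.Affine2D() \
                .translate(-bbox.x0, -bbox.y0) \
                .scale(scale_x, scale_y) \
                .translate(col + 0.1, y)
            ax.add_patch(PathPatch(tp, transform=offset + ax.transData,
                                   facecolor=colors[aa], edgecolor="none"))
            y += height
    ax.set_xlim(0, pwm.matrix.shape[1])
    ax.set_ylim(0, max(np.log2(20.0), float(ic.max()) if len(ic) else 1.0))
    ax.set_xticks(np.arange(pwm.matrix.shape[1]) + 0.5)
    ax.set_xticklabels([str(p - 4) for p in range(pwm.matrix.shape[1])])
    ax.set_ylabel("bits")
    ax.set_xlabel("ligand position")
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
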