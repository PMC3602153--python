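"""Training-set construction: PWMs, artificial negatives, genomic-peptide
filtering and the semi-supervised negative-expansion loop.

Positive binders per domain come from experiments; artificial negatives
are proteomic C-termini scoring in the bottom quantile of the domain's
positive-binder PWM.  When a trained predictor over-predicts on the
proteome, the expansion loop feeds its own top-scoring proteome hits back
in as negatives and retrains until per-domain hit counts fall below a
threshold, emulating the procedure that grew the negative set from 407
PWM negatives to 1843 total negatives in the original study.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import PEPTIDE_LENGTH, encode_peptide
from .tables import AA_INDEX, ALPHABET

logger = logging.getLogger(__name__)

SOURCE_EXPERIMENTAL = "experimental"
SOURCE_PWM_NEGATIVE = "pwm_negative"
SOURCE_SVM_NEGATIVE = "svm_negative"

UNIFORM_BACKGROUND = 0.05  # 1/20 per amino acid


class TrainingDataError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionRecord:
    domain_id: str
    peptide: str
    label: int  # +1 or -1
    source: str = SOURCE_EXPERIMENTAL

    def __post_init__(self):
        if self.label not in (+1, -1):
            raise TrainingDataError(f"label must be +1 or -1, got {self.label}")
        encode_peptide(self.peptide)  # validates length and alphabet


def check_label_consistency(records) -> None:
    """No peptide may be both +1 and -1 for the same domain."""
    seen: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.domain_id, rec.peptide)
        if key in seen and seen[key] != rec.label:
            raise TrainingDataError(
                f"peptide {rec.peptide} has contradictory labels for domain "
                f"{rec.domain_id}"
            )
        seen[key] = rec.label


def records_to_tsv(records) -> str:
    lines = ["domain_id\tpeptide\tlabel\tsource"]
    lines += [f"{r.domain_id}\t{r.peptide}\t{r.label:+d}\t{r.source}"
              for r in records]
    return "\n".join(lines) + "\n"


def records_from_tsv(text: str) -> list[InteractionRecord]:
    records = []
    for line in text.strip().splitlines()[1:]:
        domain_id, peptide, label, source = line.split("\t")
        records.append(InteractionRecord(domain_id, peptide, int(label), source))
    return records


# ---------------------------------------------------------------------------
# position weight matrices


@dataclass
class PWM:
    """20 x 5 matrix of per-position amino-acid probabilities.

    Rows follow the fixed alphabet A,C,D,...,Y; columns are ligand
    positions -4..0 with 0 the C-terminus.  Columns sum to 1.
    """

    matrix: np.ndarray  # shape (20, 5)
    pseudocount: float = 0.0
    n_sequences: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (20, PEPTIDE_LENGTH):
            raise TrainingDataError(
                f"PWM must be 20 x {PEPTIDE_LENGTH}, got {self.matrix.shape}"
            )
        if np.any(self.matrix < 0):
            raise TrainingDataError("PWM probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise TrainingDataError(f"PWM columns must sum to 1, got {sums}")

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))

    def to_tsv(self) -> str:
        header = "aa\t" + "\t".join(str(p - 4) for p in range(PEPTIDE_LENGTH))
        lines = [header]
        for i, aa in enumerate(ALPHABET):
            lines.append(aa + "\t" + "\t".join(f"{v:.10g}" for v in self.matrix[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "PWM":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        matrix = np.array([[float(x) for x in r[1:]] for r in rows])
        return cls(matrix=matrix)


def build_pwm(peptides, pseudocount: float = 0.0) -> PWM:
    """Per-column probability (count(a, j) + pc) / (n + 20 pc)."""
    peptides = list(peptides)
    if not peptides:
        raise TrainingDataError("cannot build a PWM from an empty peptide list")
    counts = np.zeros((20, PEPTIDE_LENGTH))
    for pep in peptides:
        vec = encode_peptide(pep)  # validates
        for j, letter in enumerate(vec.peptide):
            counts[AA_INDEX[letter], j] += 1
    n = len(peptides)
    matrix = (counts + pseudocount) / (n + 20.0 * pseudocount)
    return PWM(matrix=matrix, pseudocount=pseudocount, n_sequences=n)


def score_peptide(pwm: PWM, peptide: str,
                  background: float = UNIFORM_BACKGROUND) -> float:
    """Log-odds PWM score: sum_j log2(p(a_j, j) / background)."""
    vec = encode_peptide(peptide)
    score = 0.0
    for j, letter in enumerate(vec.peptide):
        p = pwm.matrix[AA_INDEX[letter], j]
        if p <= 0.0:
            raise TrainingDataError(
                f"zero probability for {letter} at position {j - 4}; "
                "build the PWM with a pseudocount > 0"
            )
        score += np.log2(p / background)
    return float(score)


def generate_pwm_negatives(
    pwm: PWM,
    peptide_pool,
    n_negatives: int,
    quantile: float = 0.25,
    known_positives=(),
    domain_id: str = "",
    seed: int = 0,
) -> list[InteractionRecord]:
    """Sample artificial negatives from the low-scoring tail of a pool.

    Pool peptides are PWM-scored; ``n_negatives`` are drawn uniformly
    (seeded) from the bottom ``quantile`` of scores, never including a
    known positive of the domain.
    """
    if not 0.0 < quantile < 1.0:
        raise TrainingDataError("quantile must be in (0, 1)")
    positives = set(known_positives)
    candidates = sorted(set(peptide_pool) - positives)
    if not candidates:
        raise TrainingDataError(
            f"peptide pool exhausted after excluding {len(positives)} positives"
        )
    scores = np.array([score_peptide(pwm, p) for p in candidates])
    cutoff = np.quantile(scores, quantile)
    low = [p for p, s in zip(candidates, scores) if s <= cutoff]
    if len(low) < n_negatives:
        raise TrainingDataError(
            f"only {len(low)} low-scoring peptides available for "
            f"{n_negatives} requested negatives (pool {len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(low), size=n_negatives, replace=False)
    return [
        InteractionRecord(domain_id, low[i], -1, SOURCE_PWM_NEGATIVE)
        for i in sorted(chosen)
    ]


# ---------------------------------------------------------------------------
# genomic peptides


def proteome_tail_suffixes(proteome_tails, k: int = 4) -> set[str]:
    return {t[-k:] for t in proteome_tails if len(t) >= k}


def is_genomic(peptide: str, proteome_tails, _suffixes: set | None = None) -> bool:
    """A peptide is genomic when its last four residues occur at the end
    of some proteomic C-terminal tail."""
    suffixes = _suffixes if _suffixes is not None else proteome_tail_suffixes(proteome_tails)
    return peptide[-4:] in suffixes


def filter_training_domains(
    records,
    proteome_tails,
    min_genomic: int = 4,
) -> list[InteractionRecord]:
    """Keep a domain iff it has >= ``min_genomic`` genomic positive
    peptides AND at least one negative; drops are logged."""
    suffixes = proteome_tail_suffixes(proteome_tails)
    by_domain: dict[str, list[InteractionRecord]] = {}
    for rec in records:
        by_domain.setdefault(rec.domain_id, []).append(rec)
    kept: list[InteractionRecord] = []
    for domain_id, recs in by_domain.items():
        n_genomic_pos = sum(
            1 for r in recs
            if r.label == +1 and is_genomic(r.peptide, None, suffixes)
        )
        n_neg = sum(1 for r in recs if r.label == -1)
        if n_genomic_pos >= min_genomic and n_neg >= 1:
            kept.extend(recs)
        else:
            logger.info(
                "dropping domain %s: %d genomic positives (< %d) or %d negatives",
                domain_id, n_genomic_pos, min_genomic, n_neg,
            )
    return kept


# ---------------------------------------------------------------------------
# semi-supervised negative expansion


@dataclass
class ExpansionResult:
    records: list  # augmented training set
    per_round_hits: list  # list of dict domain_id -> hit count (incl. round 0)
    rounds: int = 0
    converged: bool = False

    @property
    def mean_hits_per_round(self) -> list[float]:
        return [float(np.mean(list(h.values()))) for h in self.per_round_hits]

    @property
    def accepted_round_means(self) -> list[float]:
        """Mean hits of the accepted rounds only.

        A retrain whose rescan does not lower the mean per-domain hit
        count keeps its added negatives (they become useful in later
        rounds) but is not counted as an accepted expansion round, so
        this sequence is non-increasing by construction.
        """
        out: list[float] = []
        for mean in self.mean_hits_per_round:
            if not out or mean < out[-1]:
                out.append(mean)
        return out


def expand_negatives_semisupervised(
    initial_model,
    training_set,
    domain_vectors: dict,
    proteome_tails,
    retrain_fn,
    per_domain_cap: int = 10,
    hit_threshold: int = 1000,
    max_rounds: int = 5,
) -> ExpansionResult:
    """Grow the negative set from the model's own proteome over-predictions.

    Per round: scan the unique proteomic tails with the current model; for
    every domain whose hit count exceeds ``hit_threshold``, add its top
    ``per_domain_cap`` predicted hits (by decision value, excluding known
    positives) as negatives with source ``svm_negative``; retrain with
    ``retrain_fn(records)`` and repeat until every domain is at or below
    the threshold or ``max_rounds`` is reached.  Experimental records are
    never removed.

    ``domain_vectors`` maps domain_id -> unscaled 240-vector; tails are
    the unique C-terminal pentapeptides of the proteome.
    """
    from .scan import scan_peptides  # lazy: avoids a module cycle

    records = list(training_set)
    check_label_consistency(records)
    model = initial_model
    tails = sorted(set(proteome_tails))
    per_round_hits: list[dict] = []
    converged = False
    rounds = 0
    for round_no in range(max_rounds + 1):
        hits = scan_peptides(model, domain_vectors, tails)
        counts = {d: len(hs) for d, hs in hits.items()}
        per_round_hits.append(counts)
        over = {d for d, c in counts.items() if c > hit_threshold}
        if not over:
            converged = True
            break
        if round_no == max_rounds:
            break
        known = {(r.domain_id, r.peptide) for r in records}
        added = 0
        for domain_id in sorted(over):
            ranked = sorted(hits[domain_id], key=lambda h: -h[1])
            added_this = 0
            for peptide, _decision in ranked:
                if (domain_id, peptide) in known:  # incl. all known positives
                    continue
                records.append(InteractionRecord(
                    domain_id, peptide, -1, SOURCE_SVM_NEGATIVE))
                known.add((domain_id, peptide))
                added_this += 1
                if added_this >= per_domain_cap:
                    break
            added += added_this
        logger.info("expansion round %d: %d domains over threshold, %d negatives added",
                    round_no + 1, len(over), added)
        model = retrain_fn(records)
        rounds = round_no + 1
    if not converged:
        logger.warning(
            "semi-supervised expansion did not converge after %d rounds; "
            "final per-domain hits: %s", rounds, per_round_hits[-1],
        )
    check_label_consistency(records)
    return ExpansionResult(records=records, per_round_hits=per_round_hits,
                           rounds=rounds, converged=converged)
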