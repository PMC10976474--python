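"""Local-alignment presence/absence calling of phage AMG homologues.

Whether a phage genome carries a PstS-like auxiliary metabolic gene is
decided by optimal local alignment (Smith–Waterman with a linear gap
penalty) of a query protein against each protein of the phage proteome,
with a conservative dual presence rule: identity >= 35% over >= 50% of the
query length, or score >= half the query's self-alignment score.  The
association between genotype (pstS absent) and phenotype (delayed lysis) is
formalized as Fisher's exact test on the 2x2 panel table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from .exceptions import DegenerateInputError, FormatError

DNA_SCORING = (2, -1, -2)  # match, mismatch, gap
DEFAULT_MIN_IDENTITY = 0.35
DEFAULT_MIN_COVERAGE = 0.50
DEFAULT_SELF_SCORE_FRACTION = 0.5

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class AlignmentScore:
    """Best local alignment: score, 1-based inclusive spans, identity."""

    score: int
    query_span: tuple[int, int] | None
    target_span: tuple[int, int] | None
    identity: float
    aligned_columns: int


def _substitution(scoring) -> tuple:
    """Normalize scoring to (lookup(a, b), gap_penalty)."""
    if scoring is None:
        mat = _BLOSUM62

        def lookup(x: str, y: str) -> float:
            try:
                return mat[x, y]
            except KeyError:
                return float(mat.min())

        return lookup, -11  # classic BLOSUM62 open-ish penalty, linear here
    if isinstance(scoring, tuple) and len(scoring) == 3:
        match, mismatch, gap = scoring
        if gap >= 0:
            raise FormatError("gap penalty must be negative")
        return (lambda x, y: match if x == y else mismatch), gap
    raise FormatError("scoring must be None (protein) or (match, mismatch, gap)")


def smith_waterman(a: str, b: str, scoring=DNA_SCORING) -> AlignmentScore:
    """Optimal local alignment of ``a`` (query) and ``b`` (target).

    Linear gap penalty; ``scoring`` is a ``(match, mismatch, gap)`` triple or
    None for BLOSUM62 protein scoring with gap −11.  Traceback is
    deterministic with tie order diagonal > up (gap in b) > left (gap in a),
    anchored at the first maximal cell in row-major order.  A score of 0
    means no positive-scoring local alignment exists.
    """
    if not a or not b:
        raise FormatError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    sub, gap = _substitution(scoring)
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        Hi, Hp = H[i], H[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            Hi[j] = max(
                0.0,
                Hp[j - 1] + sub(ai, b[j - 1]),
                Hp[j] + gap,
                Hi[j - 1] + gap,
            )
    best = float(H.max())
    if best <= 0:
        return AlignmentScore(0, None, None, 0.0, 0)
    end_i, end_j = np.unravel_index(int(np.argmax(H)), H.shape)
    i, j = int(end_i), int(end_j)
    matches = columns = 0
    while H[i, j] > 0:
        if i > 0 and j > 0 and np.isclose(H[i, j], H[i - 1, j - 1] + sub(a[i - 1], b[j - 1])):
            matches += a[i - 1] == b[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(H[i, j], H[i - 1, j] + gap):
            columns += 1
            i -= 1
        elif j > 0 and np.isclose(H[i, j], H[i, j - 1] + gap):
            columns += 1
            j -= 1
        else:  # pragma: no cover - defensive; DP table guarantees a move
            break
    return AlignmentScore(
        score=int(round(best)),
        query_span=(i + 1, int(end_i)),
        target_span=(j + 1, int(end_j)),
        identity=matches / columns if columns else 0.0,
        aligned_columns=columns,
    )


def call_presence(
    proteome: dict[str, str],
    query: str,
    scoring=None,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    self_score_fraction: float = DEFAULT_SELF_SCORE_FRACTION,
) -> tuple[bool, AlignmentScore]:
    """Is a homologue of ``query`` present in the proteome?

    Present iff some protein aligns with identity >= ``min_identity`` over
    >= ``min_coverage`` of the query length, OR with score >= ``self_score_fraction``
    × the query self-alignment score.  An empty proteome is absence with
    score 0.
    """
    if not proteome:
        return False, AlignmentScore(0, None, None, 0.0, 0)
    self_score = smith_waterman(query, query, scoring).score
    best = AlignmentScore(0, None, None, 0.0, 0)
    present = False
    for seq in proteome.values():
        aln = smith_waterman(query, seq, scoring)
        if aln.score > best.score:
            best = aln
        coverage = (
            (aln.query_span[1] - aln.query_span[0] + 1) / len(query)
            if aln.query_span
            else 0.0
        )
        if (aln.identity >= min_identity and coverage >= min_coverage) or (
            self_score > 0 and aln.score >= self_score_fraction * self_score
        ):
            present = True
    return present, best


def presence_absence_matrix(
    proteomes: dict[str, dict[str, str]], queries: dict[str, str], scoring=None
) -> pd.DataFrame:
    """Taxa × gene presence flags (one row per taxon, one column per query)."""
    rows = {
        taxon: {
            gene: call_presence(prot, q, scoring)[0] for gene, q in queries.items()
        }
        for taxon, prot in proteomes.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class AssociationResult:
    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_direction: int
    fisher_p_one_sided: float
    fisher_p_two_sided: float


def association_test(table) -> AssociationResult:
    """Fisher's exact test on a 2x2 genotype-by-phenotype table.

    One-sided p in the direction of the observed association (sign of the
    cross-product ad − bc); two-sided p by the point-probability rule
    (sum of hypergeometric probabilities <= that of the observed table).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise FormatError("need a 2x2 table of non-negative integers")
    if t.sum() == 0:
        raise DegenerateInputError("all-zero contingency table")
    (a, b), (c, d) = t
    direction = int(np.sign(a * d - b * c))
    alternative = "less" if direction < 0 else "greater"
    _, p_one = stats.fisher_exact(t, alternative=alternative)
    _, p_two = stats.fisher_exact(t, alternative="two-sided")
    return AssociationResult(
        contingency=((int(a), int(b)), (int(c), int(d))),
        odds_direction=direction,
        fisher_p_one_sided=float(p_one),
        fisher_p_two_sided=float(p_two),
    )
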