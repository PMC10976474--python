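"""Promoter extraction and Pho box motif scanning.

The PhoB response regulator of the phosphate-stress two-component system
binds a degenerate tandem-repeat motif ("Pho box").  The cyanobacterial
consensus half-site is ``PyTTAAPyPyT/A`` (8 positions; Py = pyrimidine,
``T/A`` = one position allowing T or A).  Functional boxes are typically two
or more half-sites separated by short (3 nt) spacers in the promoter of the
regulated gene.

This module extracts strand-aware upstream regions from a genome annotation
and scans them for half-sites within a mismatch budget, assembling tandem
boxes from half-site runs.  Position convention: the first base of the start
codon is +1, upstream positions are negative, there is no position 0; a
reported box position is the offset of its first base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .formats import GenomeAnnotation, reverse_complement

DEFAULT_CONSENSUS = "PyTTAAPyPyT/A"
DEFAULT_WINDOW = 200
DEFAULT_MAX_MISMATCH = 1
DEFAULT_SPACERS = frozenset({3})

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class PromoterRegion:
    """Upstream region of a gene, in coding-strand orientation.

    ``offset_of_first_base`` is the signed offset of the region's first base
    relative to the start codon (+1); the last base of a full window sits at
    offset −1, immediately 5′ of the start codon.
    """

    gene_id: str
    sequence: str
    genome_span: tuple[int, int, str]
    offset_of_first_base: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifModel:
    """Compiled degenerate half-site with tandem-architecture parameters."""

    half_site: tuple[frozenset[str], ...]
    spacer_lengths: frozenset[int] = DEFAULT_SPACERS
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    architecture: str = "tandem"

    def __post_init__(self) -> None:
        if self.architecture not in ("single", "tandem"):
            raise FormatError(f"unknown architecture {self.architecture!r}")
        if self.max_mismatch >= len(self.half_site):
            raise FormatError("max_mismatch must be smaller than the half-site")
        if self.architecture == "tandem" and not self.spacer_lengths:
            raise FormatError("tandem architecture needs allowed spacer lengths")
        for allowed in self.half_site:
            if not allowed or not allowed <= {"A", "C", "G", "T"}:
                raise FormatError("half-site positions must be non-empty ACGT subsets")

    @property
    def length(self) -> int:
        return len(self.half_site)

    def mismatches(self, word: str) -> int:
        """Hamming-to-set distance of an 8-mer against the allowed sets."""
        if len(word) != self.length:
            raise FormatError("word length does not match the half-site")
        return sum(b not in allowed for b, allowed in zip(word.upper(), self.half_site))


@dataclass(frozen=True)
class MotifHit:
    """A located (half-)site or assembled tandem box in a promoter."""

    gene_id: str
    matched_sequence: str
    position: int  # signed offset of the first matched base; negative upstream
    mismatches: int
    architecture: str
    half_site_count: int


_TWO_LETTER = {"Py": frozenset("CT"), "Pu": frozenset("AG")}
_ONE_LETTER = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "N": frozenset("ACGT"),
}


def compile_motif(
    consensus: str = DEFAULT_CONSENSUS,
    *,
    spacer_lengths: frozenset[int] | set[int] = DEFAULT_SPACERS,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    architecture: str = "tandem",
) -> MotifModel:
    """Compile a degenerate consensus string into a :class:`MotifModel`.

    Recognized codes: literal ``A C G T``, ``N``, ``Py`` (pyrimidine), ``Pu``
    (purine), and slash alternatives such as ``T/A`` (one position).  The
    default consensus compiles to 8 positions with pyrimidine degeneracy at
    positions 1, 6 and 7 and T-or-A at position 8.
    """
    sets: list[frozenset[str]] = []
    i = 0
    while i < len(consensus):
        if consensus[i : i + 2] in _TWO_LETTER:
            sets.append(_TWO_LETTER[consensus[i : i + 2]])
            i += 2
        elif consensus[i] in _ONE_LETTER:
            alternatives = {consensus[i]}
            i += 1
            while i + 1 < len(consensus) + 1 and consensus[i : i + 1] == "/":
                nxt = consensus[i + 1 : i + 2]
                if nxt not in _ONE_LETTER or nxt == "N":
                    raise FormatError(f"bad slash alternative at {consensus[i:]!r}")
                alternatives.add(nxt)
                i += 2
            sets.append(frozenset().union(*(_ONE_LETTER[a] for a in alternatives)))
        else:
            raise FormatError(f"unknown consensus code at {consensus[i:]!r}")
    return MotifModel(
        half_site=tuple(sets),
        spacer_lengths=frozenset(spacer_lengths),
        max_mismatch=max_mismatch,
        architecture=architecture,
    )


def extract_promoter(
    annotation: GenomeAnnotation, gene_id: str, window: int = DEFAULT_WINDOW
) -> PromoterRegion:
    """Extract the upstream region of a gene in coding-strand orientation.

    For a + strand gene starting at ``s`` the genomic span is
    ``[max(1, s−window), s−1]``; for a − strand gene ending at ``e`` it is
    ``[e+1, min(L, e+window)]``, reverse-complemented.  The window is silently
    truncated at contig ends; a gene flush against the edge yields an empty
    region.
    """
    if window < 1:
        raise FormatError("window must be >= 1")
    f = annotation.feature(gene_id)
    L = len(annotation)
    if f.strand == "+":
        lo, hi = max(1, f.start - window), f.start - 1
        seq = annotation.sequence[lo - 1 : hi] if hi >= lo else ""
        span = (lo, hi, "+") if hi >= lo else (f.start, f.start - 1, "+")
    else:
        lo, hi = f.stop + 1, min(L, f.stop + window)
        seq = reverse_complement(annotation.sequence[lo - 1 : hi]) if hi >= lo else ""
        span = (lo, hi, "-") if hi >= lo else (f.stop + 1, f.stop, "-")
    return PromoterRegion(
        gene_id=gene_id,
        sequence=seq,
        genome_span=span,
        offset_of_first_base=-len(seq) if seq else 0,
    )


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise FormatError(f"non-ACGTN base {exc.args[0]!r} in sequence") from None


def half_site_mismatch_counts(sequence: str, model: MotifModel) -> np.ndarray:
    """Mismatch count of every half-site-length window of ``sequence``.

    Returns an array of length ``len(sequence) − L + 1`` (empty when the
    sequence is shorter than the half-site).  N counts as a mismatch at every
    position.
    """
    L = model.length
    n = len(sequence)
    if n < L:
        return np.zeros(0, dtype=np.int64)
    codes = _encode(sequence.upper())
    # allowed[k, c] — is base code c acceptable at half-site position k
    allowed = np.zeros((L, 5), dtype=bool)
    for k, s in enumerate(model.half_site):
        for b in s:
            allowed[k, _BASE_INDEX[b]] = True
    mm = np.zeros(n - L + 1, dtype=np.int64)
    for k in range(L):
        mm += ~allowed[k][codes[k : k + n - L + 1]]
    return mm


def scan_sequence(region: PromoterRegion, model: MotifModel) -> list[MotifHit]:
    """Report every half-site window within the mismatch budget.

    Hits are sorted by position; overlapping hits are all reported.  An empty
    region yields an empty list.
    """
    mm = half_site_mismatch_counts(region.sequence, model)
    hits = []
    for idx in np.flatnonzero(mm <= model.max_mismatch):
        idx = int(idx)
        hits.append(
            MotifHit(
                gene_id=region.gene_id,
                matched_sequence=region.sequence[idx : idx + model.length],
                position=region.offset_of_first_base + idx,
                mismatches=int(mm[idx]),
                architecture="single",
                half_site_count=1,
            )
        )
    return hits


def assemble_tandem_boxes(
    region: PromoterRegion, model: MotifModel, half_sites: list[MotifHit]
) -> list[MotifHit]:
    """Chain half-site hits separated by allowed spacers into tandem boxes.

    Maximal runs of >= 2 half-sites are reported as one box whose position is
    the first base of the first half-site; the rendered sequence shows
    half-sites upper case and spacers lower case.
    """
    L = model.length
    idx_of = {h.position: i for i, h in enumerate(half_sites)}
    successors: dict[int, list[int]] = {i: [] for i in range(len(half_sites))}
    has_predecessor = set()
    for i, h in enumerate(half_sites):
        for sp in model.spacer_lengths:
            j = idx_of.get(h.position + L + sp)
            if j is not None:
                successors[i].append(j)
                has_predecessor.add(j)

    boxes: list[MotifHit] = []

    def walk(chain: list[int]) -> None:
        nxt = successors[chain[-1]]
        if not nxt:
            if len(chain) >= 2:
                boxes.append(_render_box(region, model, [half_sites[i] for i in chain]))
            return
        for j in nxt:
            walk(chain + [j])

    for i in range(len(half_sites)):
        if i not in has_predecessor:
            walk([i])
    boxes.sort(key=lambda b: b.position)
    return boxes


def _render_box(
    region: PromoterRegion, model: MotifModel, chain: list[MotifHit]
) -> MotifHit:
    first = chain[0].position - region.offset_of_first_base
    parts = []
    for k, h in enumerate(chain):
        start = h.position - region.offset_of_first_base
        parts.append(h.matched_sequence.upper())
        if k + 1 < len(chain):
            nxt = chain[k + 1].position - region.offset_of_first_base
            parts.append(region.sequence[start + model.length : nxt].lower())
    return MotifHit(
        gene_id=region.gene_id,
        matched_sequence="".join(parts),
        position=chain[0].position,
        mismatches=sum(h.mismatches for h in chain),
        architecture="tandem",
        half_site_count=len(chain),
    )


def find_pho_boxes(
    annotation: GenomeAnnotation,
    model: MotifModel | None = None,
    window: int = DEFAULT_WINDOW,
    *,
    both_strands: bool = False,
) -> pd.DataFrame:
    """Scan every annotated gene's promoter for Pho boxes.

    Returns a table with columns ``gene_id, box, position, mismatches,
    half_site_count, architecture, strand`` (one row per reported box; genes
    without hits are absent).  With tandem architecture only runs of >= 2
    half-sites are reported; with single architecture every half-site is.
    ``both_strands=True`` additionally scans the reverse complement of each
    promoter (positions still refer to the coding strand first base of the
    hit).
    """
    model = model or compile_motif()
    rows = []
    for f in annotation.features:
        region = extract_promoter(annotation, f.cds_id, window)
        if not region.sequence:
            continue
        for strand, region_variant in _strand_variants(region, both_strands):
            half_hits = scan_sequence(region_variant, model)
            if model.architecture == "tandem":
                found = assemble_tandem_boxes(region_variant, model, half_hits)
            else:
                found = half_hits
            for h in found:
                rows.append(
                    {
                        "gene_id": h.gene_id,
                        "box": h.matched_sequence,
                        "position": h.position,
                        "mismatches": h.mismatches,
                        "half_site_count": h.half_site_count,
                        "architecture": h.architecture,
                        "strand": strand,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "box",
            "position",
            "mismatches",
            "half_site_count",
            "architecture",
            "strand",
        ],
    )


def _strand_variants(region: PromoterRegion, both: bool):
    yield "coding", region
    if both:
        yield (
            "template",
            PromoterRegion(
                gene_id=region.gene_id,
                sequence=reverse_complement(region.sequence),
                genome_span=region.genome_span,
                offset_of_first_base=region.offset_of_first_base,
            ),
        )


def hits_to_bed(annotation: GenomeAnnotation, hits: pd.DataFrame) -> str:
    """Render promoter hits as BED lines (0-based half-open genomic coords)."""
    lines = []
    for row in hits.itertuples(index=False):
        f = annotation.feature(row.gene_id)
        length = len(row.box)
        if f.strand == "+":
            # position -k means k bases upstream of start codon base f.start
            g_start = f.start + row.position  # 1-based first base of the box
            lo0, hi0 = g_start - 1, g_start - 1 + length
        else:
            g_end = f.stop - row.position  # 1-based genomic end of the box
            lo0, hi0 = g_end - length, g_end
        lines.append(
            f"{annotation.contig_id}\t{lo0}\t{hi0}\t{row.gene_id}_phobox\t{row.mismatches}\t{f.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
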