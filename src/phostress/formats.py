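"""Readers/writers for the formats the pipeline touches, plus packaged fixtures.

Conventions
-----------
* Genomic coordinates are 1-based inclusive throughout (GenBank style);
  ``start <= stop`` always, strand carries orientation.
* TSV dialect: tab-separated, ``#`` comment lines, UTF-8, ``.`` decimal point.
* Newick branch lengths default to 0.0 when absent.

Two fixtures ship with the package: the table of differentially expressed
S-PM2d genes (17 CDS with coordinates, log2 fold change and FDR, three of
them flagged as likely misannotations) and the table of putative Pho boxes
found upstream of those genes (half-sites upper case, spacers lower case,
signed offsets relative to the start codon).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import pandas as pd
from Bio import SeqIO

from .exceptions import CoordinateError, FormatError, NewickError, UnknownGeneError

_VALID_BASES = set("ACGTN")
_STRANDS = {"+", "-"}

DE_GENES_FIXTURE = "spm2d_de_genes.tsv"
PHO_BOX_FIXTURE = "spm2d_pho_boxes.tsv"


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature on a contig, 1-based inclusive coordinates."""

    cds_id: str
    start: int
    stop: int
    strand: str
    product: str = ""
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise FormatError(f"unknown strand symbol {self.strand!r} for {self.cds_id}")
        if self.start < 1 or self.stop < self.start:
            raise CoordinateError(
                f"{self.cds_id}: invalid span [{self.start}, {self.stop}]"
            )

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass
class GenomeAnnotation:
    """A contig sequence plus its strand-aware CDS features, sorted by start."""

    contig_id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
        ids = [f.cds_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate feature ids in annotation")
        for f in self.features:
            if f.stop > len(self.sequence):
                raise CoordinateError(
                    f"{f.cds_id}: stop {f.stop} beyond contig length {len(self.sequence)}"
                )
        self.features.sort(key=lambda f: f.start)
        self._by_id = {f.cds_id: f for f in self.features}

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, cds_id: str) -> CdsFeature:
        try:
            return self._by_id[cds_id]
        except KeyError:
            raise UnknownGeneError(cds_id) from None

    def feature_sequence(self, cds_id: str) -> str:
        """Feature sequence in coding-strand orientation."""
        f = self.feature(cds_id)
        seq = self.sequence[f.start - 1 : f.stop]
        return reverse_complement(seq) if f.strand == "-" else seq


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# genome tables


def read_genome_table(sequence_source: str, feature_source: str) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from FASTA text and a feature TSV.

    The TSV needs columns ``id, start, stop, strand`` (1-based inclusive) and
    may carry optional ``product`` and ``gene`` columns; ``#`` lines are
    comments.  The first FASTA record is used as the contig.
    """
    records = list(SeqIO.parse(io.StringIO(sequence_source), "fasta"))
    if not records:
        raise FormatError("no FASTA record in sequence source")
    rec = records[0]
    table = _read_tsv(feature_source)
    required = {"id", "start", "stop", "strand"}
    if not required.issubset(table.columns):
        raise FormatError(f"feature table needs columns {sorted(required)}")
    feats = []
    for row in table.itertuples(index=False):
        feats.append(
            CdsFeature(
                cds_id=str(row.id),
                start=int(row.start),
                stop=int(row.stop),
                strand=str(row.strand),
                product=str(getattr(row, "product", "") or ""),
                gene=(str(row.gene) if getattr(row, "gene", None) else None),
            )
        )
    return GenomeAnnotation(contig_id=rec.id, sequence=str(rec.seq), features=feats)


def write_genome_table(annotation: GenomeAnnotation) -> tuple[str, str]:
    """Serialize back to (FASTA text, feature TSV text); round-trips exactly."""
    fasta = f">{annotation.contig_id}\n"
    seq = annotation.sequence
    fasta += "\n".join(seq[i : i + 70] for i in range(0, len(seq), 70)) + "\n"
    lines = ["id\tstart\tstop\tstrand\tproduct\tgene"]
    for f in annotation.features:
        lines.append(
            f"{f.cds_id}\t{f.start}\t{f.stop}\t{f.strand}\t{f.product}\t{f.gene or ''}"
        )
    return fasta, "\n".join(lines) + "\n"


def _read_tsv(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree.

    Missing branch lengths become 0.0.  Duplicate leaf labels and malformed
    syntax raise :class:`NewickError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"cannot parse Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        raise NewickError("duplicate leaf labels in Newick tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
        elif edge.length < 0:
            raise NewickError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# packaged fixtures


def _fixture_text(name: str) -> str:
    return resources.files("phostress").joinpath("data", name).read_text(encoding="utf-8")


def load_de_gene_table() -> pd.DataFrame:
    """The packaged table of differentially expressed phage genes.

    17 rows with columns ``cds_id, accession, product, gene, start, stop,
    strand, log2fc, pvalue, fdr, presence_pct, misannotated``.  Exactly three
    rows carry the misannotation flag; FDR >= p holds row-wise.
    """
    df = _read_tsv(_fixture_text(DE_GENES_FIXTURE))
    df = df.astype(
        {
            "start": int,
            "stop": int,
            "log2fc": float,
            "pvalue": float,
            "fdr": float,
            "presence_pct": float,
        }
    )
    df["misannotated"] = df["misannotated"].astype(int).astype(bool)
    if len(df) != 17:
        raise FormatError(f"DE fixture must have 17 rows, found {len(df)}")
    if int(df["misannotated"].sum()) != 3:
        raise FormatError("DE fixture must flag exactly 3 misannotated rows")
    if not (df["fdr"] >= df["pvalue"]).all():
        raise FormatError("DE fixture violates fdr >= p")
    return df


_HALF_SITE_RE = re.compile(r"[ACGT]{8,9}")
_SPACER_RE = re.compile(r"[acgt]{1,3}")


def decompose_box(box: str) -> tuple[list[str], list[str]]:
    """Split a recorded box into (half_sites, spacers) by letter case.

    Half-sites are upper case (8 nt in the consensus; one printed box leads
    with a 9-mer and is accepted as recorded), spacers lower case, <= 3 nt.
    """
    tokens = re.findall(r"[ACGT]+|[acgt]+", box)
    if "".join(tokens) != box:
        raise FormatError(f"box contains non-nucleotide symbols: {box!r}")
    half_sites = [t for t in tokens if t.isupper()]
    spacers = [t for t in tokens if t.islower()]
    if not half_sites or len(spacers) != len(half_sites) - 1:
        raise FormatError(f"box does not alternate half-site/spacer: {box!r}")
    for h in half_sites:
        if not _HALF_SITE_RE.fullmatch(h):
            raise FormatError(f"half-site of unexpected length in {box!r}")
    for s in spacers:
        if not _SPACER_RE.fullmatch(s):
            raise FormatError(f"spacer longer than 3 nt in {box!r}")
    return half_sites, spacers


def load_pho_box_table() -> pd.DataFrame:
    """The packaged table of putative Pho boxes upstream of phage genes.

    Columns ``gene_id, annotation, box, position``; ``box``/``position`` are
    missing (NA) for genes without a reported box.  Every recorded box
    decomposes into half-sites separated by <=3-nt spacers.
    """
    df = _read_tsv(_fixture_text(PHO_BOX_FIXTURE))
    df["position"] = pd.to_numeric(df["position"].replace("NA", pd.NA)).astype("Int64")
    df["box"] = df["box"].replace("NA", pd.NA)
    for box in df["box"].dropna():
        decompose_box(box)
    return df
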