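"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates one input class of the study system — an AT-rich
(GC 37.7%) ~200 kb phage genome with tandem Pho boxes planted at known
promoter offsets; a core/gene tree pair related by vertical descent plus
discrete leaf-transfer events; negative-binomial count matrices with a
planted up-regulated regulon; logistic OD750 growth curves whose infected
replicates lyse at condition-dependent times; and linear-phase qPCR series
of intracellular phage DNA.  Every call takes a config carrying its own
seed, draws from a single ``numpy.random.default_rng`` stream in a fixed
documented order, and returns the ground truth needed to check recovery.

Defaults mirror the study conditions where stated (GC fraction, planted
log2 fold change 1.33 on the pyrophosphatase-like regulon gene, OD sampling
every 2 h, a 3 h lysis delay on top of a 9 h replete latent period, a 2–6 h
qPCR slope window with no true between-condition difference); the remaining
magnitudes are chosen as realistic for a slow-growing marine *Synechococcus*
culture and are documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import dendropy
import numpy as np

from .de import CountMatrix
from .exceptions import ConfigurationError
from .formats import GenomeAnnotation, CdsFeature, reverse_complement
from .kinetics import GrowthCurve, QPCRSeries
from .phobox import MotifModel, compile_motif


@dataclass
class GroundTruth:
    """Planted truth recorded by a generator, keyed by coordinates/labels."""

    data: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.data[key]


# ---------------------------------------------------------------------------
# genome + planted Pho boxes


@dataclass(frozen=True)
class GenomeSimConfig:
    seed: int = 0
    length: int = 200_000
    gc: float = 0.377
    n_genes: int = 20
    gene_length: int = 900
    promoter_window: int = 200
    planted_offset: int = -63
    planted_fraction: float = 0.5
    planted_mismatches: int = 0
    spacer_length: int = 3
    alternate_strands: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ConfigurationError("GC fraction must be in (0, 1)")
        if self.n_genes * (self.gene_length + self.promoter_window) > self.length:
            raise ConfigurationError("genes + promoters do not fit in the genome")
        if self.planted_offset >= 0:
            raise ConfigurationError("planted offset must be negative (upstream)")


def _consensus_word(rng: np.random.Generator, model: MotifModel, mismatches: int) -> str:
    bases = [rng.choice(sorted(s)) for s in model.half_site]
    if mismatches:
        pos = rng.choice(len(bases), size=mismatches, replace=False)
        for k in pos:
            forbidden = sorted({"A", "C", "G", "T"} - model.half_site[k])
            bases[k] = rng.choice(forbidden)
    return "".join(bases)


def simulate_genome(
    config: GenomeSimConfig, model: MotifModel | None = None
) -> tuple[GenomeAnnotation, GroundTruth]:
    """I.i.d. background genome with genes and planted tandem Pho boxes.

    Genes are laid out left to right, each preceded by its promoter window;
    strands alternate (+, −, ...) when ``alternate_strands``.  A tandem box
    (two consensus half-sites, ``spacer_length`` nt apart, each carrying
    ``planted_mismatches`` mismatches) is written at ``planted_offset`` on
    the coding strand of the first ``planted_fraction`` × n_genes genes
    (every other gene).  Truth records per-gene offsets and box sequences.
    """
    model = model or compile_motif()
    box_len = 2 * model.length + config.spacer_length
    if config.planted_offset < -config.promoter_window:
        raise ConfigurationError("planted offset deeper than the promoter window")
    if config.planted_offset + box_len > 0:
        raise ConfigurationError("planted box would overlap the start codon")
    rng = np.random.default_rng(config.seed)
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    seq = rng.choice(np.array(list("ACGT")), size=config.length, p=p)

    slot = config.length // config.n_genes
    features, planted = [], {}
    n_planted = int(round(config.planted_fraction * config.n_genes))
    plant_every = max(1, config.n_genes // max(1, n_planted)) if n_planted else 0
    for g in range(config.n_genes):
        strand = "-" if (config.alternate_strands and g % 2) else "+"
        slot_start = g * slot + 1
        if strand == "+":
            start = slot_start + config.promoter_window
            stop = start + config.gene_length - 1
        else:
            start = slot_start
            stop = start + config.gene_length - 1
        gene_id = f"gene{g + 1:03d}"
        features.append(CdsFeature(gene_id, start, stop, strand, product="simulated"))
        if plant_every and g % plant_every == 0 and len(planted) < n_planted:
            half1 = _consensus_word(rng, model, config.planted_mismatches)
            half2 = _consensus_word(rng, model, config.planted_mismatches)
            spacer = "".join(rng.choice(list("ACGT"), size=config.spacer_length))
            box = half1 + spacer.lower() + half2
            _write_box(seq, box, start, stop, strand, config.planted_offset)
            planted[gene_id] = {"offset": config.planted_offset, "box": box}
    annotation = GenomeAnnotation("sim_contig", "".join(seq), features)
    return annotation, GroundTruth({"planted_boxes": planted, "config": config})


def _write_box(
    seq: np.ndarray, box: str, start: int, stop: int, strand: str, offset: int
) -> None:
    flat = box.upper()
    if strand == "+":
        first = start + offset  # 1-based genomic position of the box first base
        seq[first - 1 : first - 1 + len(flat)] = list(flat)
    else:
        last = stop - offset  # genomic position pairing with coding offset
        rc = reverse_complement(flat)
        seq[last - len(flat) : last] = list(rc)


# ---------------------------------------------------------------------------
# tree pairs


@dataclass(frozen=True)
class TreeSimConfig:
    seed: int = 0
    n_leaves: int = 20
    transfer_events: int = 0
    length_noise_sd: float = 0.0
    branch_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_leaves < 4:
            raise ConfigurationError("need >= 4 leaves")
        if self.transfer_events < 0 or self.transfer_events >= self.n_leaves:
            raise ConfigurationError("transfer_events must be in [0, n_leaves)")
        if self.length_noise_sd < 0:
            raise ConfigurationError("length_noise_sd must be >= 0")


def _random_binary_tree(rng: np.random.Generator, config: TreeSimConfig) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(config.n_leaves):
        nd = dendropy.Node(taxon=tns.new_taxon(f"L{i + 1}"))
        nd.edge.length = float(rng.exponential(config.branch_scale))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(config.branch_scale))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = 0.0
    return tree


def _regraft_leaf(rng: np.random.Generator, tree: dendropy.Tree) -> None:
    leaves = [lf for lf in tree.leaf_node_iter()]
    leaf = leaves[int(rng.integers(len(leaves)))]
    parent = leaf.parent_node
    if parent is None:
        return
    parent.remove_child(leaf)
    # suppress the unifurcation left behind
    sibling = parent.child_nodes()[0]
    grand = parent.parent_node
    if grand is None:
        parent.remove_child(sibling)
        sibling.edge.length = 0.0
        tree.seed_node = sibling
    else:
        grand.remove_child(parent)
        grand.add_child(sibling)
        sibling.edge.length = (sibling.edge.length or 0.0) + (parent.edge.length or 0.0)
    # choose a target edge (any non-seed node) and split it
    candidates = [
        nd
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and nd is not leaf
    ]
    target = candidates[int(rng.integers(len(candidates)))]
    t_parent = target.parent_node
    mid = dendropy.Node()
    frac = float(rng.uniform(0.2, 0.8))
    total = target.edge.length or 0.0
    t_parent.remove_child(target)
    t_parent.add_child(mid)
    mid.edge.length = total * frac
    mid.add_child(target)
    target.edge.length = total * (1 - frac)
    mid.add_child(leaf)


def simulate_tree_pair(
    config: TreeSimConfig,
) -> tuple[dendropy.Tree, dendropy.Tree, GroundTruth]:
    """A core tree and a gene tree related by noise plus leaf transfers.

    The core tree has a random binary topology with exponential branch
    lengths (mean ``branch_scale``).  The gene tree is a copy whose branch
    lengths are multiplied by lognormal noise (sigma ``length_noise_sd``),
    then ``transfer_events`` random leaf regrafts are applied — the simplest
    event that erodes leaf-distance correlation, emulating horizontal gene
    transfer of an AMG between phages.
    """
    rng = np.random.default_rng(config.seed)
    core = _random_binary_tree(rng, config)
    gene = dendropy.Tree(core)  # deep clone with its own namespace view
    for edge in gene.preorder_edge_iter():
        if edge.length and config.length_noise_sd > 0:
            edge.length *= float(rng.lognormal(0.0, config.length_noise_sd))
    for _ in range(config.transfer_events):
        _regraft_leaf(rng, gene)
    return core, gene, GroundTruth({"transfers": config.transfer_events, "config": config})


# ---------------------------------------------------------------------------
# counts


@dataclass(frozen=True)
class CountsSimConfig:
    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 3
    mean_range: tuple[float, float] = (50.0, 2000.0)
    dispersion: float = 0.05
    planted_log2fc: dict[int, float] = field(default_factory=dict)
    gene_length_range: tuple[int, int] = (120, 2500)
    library_size_range: tuple[float, float] = (0.7, 1.3)

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.n_replicates < 2:
            raise ConfigurationError("need >= 2 replicates per condition")


def regulon_counts_config(seed: int = 0, **overrides) -> CountsSimConfig:
    """The study-like default: one planted regulon gene at log2FC 1.33."""
    overrides.setdefault("planted_log2fc", {0: 1.33})
    return CountsSimConfig(seed=seed, **overrides)


def nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """NB draws parameterized by (mean, dispersion): Var = mean + phi·mean²."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + mean))


def simulate_counts(config: CountsSimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Gene-by-sample NB counts with a planted deplete-condition regulon.

    Per gene g: baseline mean mu_g ~ log-uniform over ``mean_range``; the
    deplete-condition mean is ``mu_g · 2^log2fc_g`` (0 for non-regulon
    genes).  Per sample: a library-size multiplier ~ uniform over
    ``library_size_range`` scales every gene mean.  Draw order: gene means,
    gene lengths, library sizes, then counts sample by sample (replete
    first).
    """
    rng = np.random.default_rng(config.seed)
    G, n = config.n_genes, config.n_replicates
    lo, hi = config.mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), G))
    lengths = rng.integers(*config.gene_length_range, size=G)
    lfc = np.zeros(G)
    for idx, value in config.planted_log2fc.items():
        lfc[idx] = value
    lib = rng.uniform(*config.library_size_range, size=2 * n)
    samples, conditions, cols = [], [], []
    for j in range(2 * n):
        condition = "replete" if j < n else "deplete"
        mean_j = mu * (2.0**lfc if condition == "deplete" else 1.0) * lib[j]
        cols.append(nb_draw(rng, mean_j, config.dispersion))
        samples.append(f"{condition}_{j % n + 1}")
        conditions.append(condition)
    counts = np.column_stack(cols)
    matrix = CountMatrix(
        genes=[f"gene{g + 1:04d}" for g in range(G)],
        lengths=lengths,
        samples=samples,
        conditions=conditions,
        totals=counts.sum(axis=0),
        counts=counts,
    )
    truth = GroundTruth(
        {
            "log2fc": lfc,
            "regulon": sorted(matrix.genes[i] for i in config.planted_log2fc),
            "library_sizes": lib,
            "config": config,
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# growth curves and qPCR


@dataclass(frozen=True)
class GrowthSimConfig:
    seed: int = 0
    interval: float = 2.0
    horizon: float = 24.0
    n_replicates: int = 3
    latent_period_replete: float = 9.0
    delay: float = 3.0
    od0: float = 0.25
    capacity: float = 1.0
    growth_rate: float = 0.08
    lysis_rate: float = 1.0
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.interval <= 0 or self.horizon <= 0:
            raise ConfigurationError("interval and horizon must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")


def simulate_growth_curves(
    config: GrowthSimConfig,
) -> tuple[list[GrowthCurve], GroundTruth]:
    """Logistic control curves plus infected curves lysing per condition.

    The uninfected control follows logistic growth; each infected replicate
    tracks its control until the condition's lysis time (replete latent
    period, plus ``delay`` under depletion), then declines exponentially at
    ``lysis_rate``.  Additive Gaussian noise (sd ``noise_sd``) is clipped at
    0.  Draw order: replete noise then deplete noise, control before
    infected, replicate by replicate.
    """
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.horizon + 1e-9, config.interval)
    lysis = {
        "replete": config.latent_period_replete,
        "deplete": config.latent_period_replete + config.delay,
    }
    curves = []
    for condition in ("replete", "deplete"):
        control = config.capacity / (
            1
            + (config.capacity - config.od0)
            / config.od0
            * np.exp(-config.growth_rate * times)
        )
        t_l = lysis[condition]
        infected = np.where(
            times <= t_l,
            control,
            np.interp(t_l, times, control) * np.exp(-config.lysis_rate * (times - t_l)),
        )
        for rep in range(config.n_replicates):
            for flag, base in ((False, control), (True, infected)):
                noisy = base + rng.normal(0.0, config.noise_sd, size=times.shape)
                curves.append(
                    GrowthCurve(
                        replicate=f"r{rep + 1}",
                        condition=condition,
                        infected=flag,
                        times=tuple(times),
                        od=tuple(np.clip(noisy, 0.0, None)),
                    )
                )
    return curves, GroundTruth({"lysis_times": lysis, "config": config})


@dataclass(frozen=True)
class QpcrSimConfig:
    seed: int = 0
    interval: float = 2.0
    horizon: float = 18.0
    n_replicates: int = 3
    slope_replete: float = 25.0
    slope_deplete: float = 25.0
    window: tuple[float, float] = (2.0, 6.0)
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")
        if self.interval <= 0:
            raise ConfigurationError("interval must be positive")


def simulate_qpcr(config: QpcrSimConfig) -> tuple[list[QPCRSeries], GroundTruth]:
    """Linear-rise qPCR series: 100% at t=0, configured slope, plateau after.

    Each series rises linearly at the condition's slope (percent per hour)
    from t = 0 until the end of the slope window, then plateaus; Gaussian
    noise (sd ``noise_sd``) is added and values are clipped at 0.  The first
    point is pinned to 100 (the normalization reference).  Draw order:
    replete replicates then deplete replicates.
    """
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.horizon + 1e-9, config.interval)
    slopes = {"replete": config.slope_replete, "deplete": config.slope_deplete}
    series = []
    for condition in ("replete", "deplete"):
        base = 100.0 + slopes[condition] * np.minimum(times, config.window[1])
        for rep in range(config.n_replicates):
            noisy = base + rng.normal(0.0, config.noise_sd, size=times.shape)
            noisy[0] = 100.0
            series.append(
                QPCRSeries(
                    replicate=f"r{rep + 1}",
                    condition=condition,
                    times=tuple(times),
                    percent=tuple(np.clip(noisy, 0.0, None)),
                )
            )
    return series, GroundTruth({"slopes": slopes, "config": config})
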