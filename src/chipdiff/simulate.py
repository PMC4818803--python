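"""Synthetic four-sample ChIP-seq tag generator with known promoter truth.

The generator emulates the statistical structure of a two-condition
H3K4me3 promoter-profiling experiment: a treated and a control chromatin
immunoprecipitation, each paired with a sequenced-input control.  Input
samples are uniform Poisson background over the genome.  ChIP samples carry,
on top of background, promoter-proximal enrichment at a configurable subset
of genes; a fraction of the enriched promoters change their enrichment fold
between conditions ("up" and "down" classes).

Occupancy model
---------------
Each enriched promoter occupies the window ``[tss - half_width,
tss + half_width)``.  The expected tag count of a promoter window in a
sample with ``N`` total tags is ``fold * (N / G) * 2 * half_width`` where
``G`` is the genome size, i.e. the fold is expressed relative to the
depth-normalized genome-average tag rate.  The uniform background fills the
complement of the promoter windows with the remaining tags.  Defined this
way, the configured alteration fold equals the true expected treated/control
count ratio at a promoter once the two ChIP samples are equalized in depth,
so truth classes and true folds are exact, not approximate.

Each sampled event is a chromatin fragment: a midpoint is drawn from the
occupancy distribution, a fragment length uniformly from the configured
range, a strand at random, and the fragment contributes one 5' tag
(fragment start on ``+``, fragment end - 1 on ``-``), mirroring single-end
sequencing of sonicated fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, NamedTuple, Sequence, Tuple

import numpy as np

from chipdiff.genomic import GeneModel, GenomeLayout, TagCollection

__all__ = [
    "SimulationConfig",
    "PromoterTruth",
    "SampleSet",
    "simulate_genes",
    "simulate_tags",
    "simulate_term_annotation",
    "write_truth_tsv",
    "read_truth_tsv",
]

# stream indices for deriving per-stage RNGs from the single config seed
_STREAM_GENES = 0
_STREAM_TAGS = 1
_STREAM_TERMS = 2

SAMPLE_NAMES = ("treated_chip", "treated_input", "control_chip", "control_input")

#: minimum distance enforced between simulated TSSs, chosen so the +/-2 kb
#: promoter-annotation windows of distinct genes never overlap.
_TSS_MIN_SPACING = 4100
_TSS_EDGE_MARGIN = 2500


def _default_genome() -> GenomeLayout:
    return GenomeLayout({"chr1": 5_000_000, "chr2": 5_000_000})


@dataclass
class SimulationConfig:
    """Configuration of the four-sample synthetic experiment.

    Defaults are the desk-scale study conditions: two 5 Mb chromosomes,
    1,000 genes of which 60% carry promoter enrichment (base fold 8 over the
    depth-normalized average rate), 10% of genes gain signal in the treated
    condition (fold 4) and 10% lose it (fold 0.25); fragments are 100-300 bp;
    the four samples have unequal depths between 200k and 400k tags.
    """

    genome: GenomeLayout = field(default_factory=_default_genome)
    n_genes: int = 1000
    frac_up: float = 0.10
    frac_down: float = 0.10
    frac_enriched: float = 0.60
    base_fold: float = 8.0
    fold_up: float = 4.0
    fold_down: float = 0.25
    tss_half_width: int = 500
    frag_min: int = 100
    frag_max: int = 300
    n_treated_chip: int = 230_000
    n_treated_input: int = 200_000
    n_control_chip: int = 250_000
    n_control_input: int = 380_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.frac_up < 0 or self.frac_down < 0:
            raise ValueError("class fractions must be non-negative")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if not (0 <= self.frac_enriched <= 1):
            raise ValueError("frac_enriched must be in [0, 1]")
        if min(self.base_fold, self.fold_up, self.fold_down) <= 0:
            raise ValueError("folds must be positive")
        if self.tss_half_width <= 0:
            raise ValueError("tss_half_width must be positive")
        if not (50 <= self.frag_min <= self.frag_max <= 1000):
            raise ValueError("fragment range must satisfy 50 <= min <= max <= 1000")
        for name in SAMPLE_NAMES:
            if self.total_for(name) <= 0:
                raise ValueError(f"tag count for {name} must be positive")
        n_up, n_down, n_enr = self.class_counts()
        if n_up + n_down > n_enr:
            raise ValueError(
                "altered promoters must be enriched: "
                "frac_up + frac_down exceeds frac_enriched after rounding"
            )

    def class_counts(self) -> Tuple[int, int, int]:
        """(n_up, n_down, n_enriched) after rounding."""
        n_up = int(round(self.frac_up * self.n_genes))
        n_down = int(round(self.frac_down * self.n_genes))
        n_enr = int(round(self.frac_enriched * self.n_genes))
        return n_up, n_down, n_enr

    def total_for(self, sample: str) -> int:
        return {
            "treated_chip": self.n_treated_chip,
            "treated_input": self.n_treated_input,
            "control_chip": self.n_control_chip,
            "control_input": self.n_control_input,
        }[sample]

    def background_rate(self, sample: str) -> float:
        """Depth-implied genome-average tag rate per bp for a sample.

        For input samples this is exactly ``total / genome_size``; ChIP
        samples share the same average rate, with promoter occupancy
        expressed as folds of it.
        """
        return self.total_for(sample) / self.genome.total_size

    def rng_for(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[stream])


class PromoterTruth:
    """Ground-truth promoter classes for recovery testing.

    Maps gene id to class (``up`` / ``down`` / ``unchanged``), true
    treated/control fold, and whether the promoter is enriched over
    background in the control condition.
    """

    def __init__(
        self,
        classes: Dict[str, str],
        true_fold: Dict[str, float],
        enriched_in_control: Dict[str, bool],
    ):
        if set(classes) != set(true_fold) or set(classes) != set(enriched_in_control):
            raise ValueError("truth maps must cover the same gene ids")
        for gid, cls in classes.items():
            if cls not in ("up", "down", "unchanged"):
                raise ValueError(f"unknown class {cls!r} for {gid}")
            if cls == "unchanged" and true_fold[gid] != 1.0:
                raise ValueError(f"unchanged gene {gid} must have fold 1")
        self.classes = dict(classes)
        self.true_fold = dict(true_fold)
        self.enriched_in_control = dict(enriched_in_control)

    def genes_in_class(self, cls: str) -> List[str]:
        return sorted(g for g, c in self.classes.items() if c == cls)

    def __len__(self) -> int:
        return len(self.classes)


class SampleSet(NamedTuple):
    treated_chip: TagCollection
    treated_input: TagCollection
    control_chip: TagCollection
    control_input: TagCollection

    def as_dict(self) -> Dict[str, TagCollection]:
        return dict(zip(SAMPLE_NAMES, self))


def _allocate_counts(total: int, weights: Sequence[int]) -> List[int]:
    """Largest-remainder apportionment of ``total`` across weights."""
    weights = np.asarray(weights, dtype=float)
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    if remainder:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts.tolist()


def simulate_genes(config: SimulationConfig) -> Tuple[List[GeneModel], PromoterTruth]:
    """Place gene TSSs and assign truth classes; deterministic given the seed.

    TSSs are spaced so that +/-2 kb promoter windows of distinct genes never
    overlap; strands are random.  Classes are assigned by the configured
    fractions (after rounding), with altered promoters drawn from the
    enriched subset.
    """
    rng = config.rng_for(_STREAM_GENES)
    layout = config.genome
    chroms = layout.chromosomes
    per_chrom = _allocate_counts(config.n_genes, [layout[c] for c in chroms])

    genes: List[GeneModel] = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        usable = layout[chrom] - 2 * _TSS_EDGE_MARGIN - (n - 1) * _TSS_MIN_SPACING
        if usable <= 0:
            raise ValueError(
                f"genome too small: cannot place {n} non-overlapping promoters "
                f"on {chrom} (length {layout[chrom]})"
            )
        offsets = np.sort(rng.random(n)) * usable
        tss = (_TSS_EDGE_MARGIN + offsets + np.arange(n) * _TSS_MIN_SPACING).astype(
            np.int64
        )
        strands = rng.choice(["+", "-"], size=n)
        for t, s in zip(tss, strands):
            gid += 1
            genes.append(GeneModel(f"GENE{gid:05d}", chrom, str(s), int(t)))

    n_up, n_down, n_enr = config.class_counts()
    order = rng.permutation(len(genes))
    classes: Dict[str, str] = {}
    true_fold: Dict[str, float] = {}
    enriched: Dict[str, bool] = {}
    for rank, idx in enumerate(order):
        g = genes[idx]
        if rank < n_up:
            cls, fold, enr = "up", config.fold_up, True
        elif rank < n_up + n_down:
            cls, fold, enr = "down", config.fold_down, True
        elif rank < n_enr:
            cls, fold, enr = "unchanged", 1.0, True
        else:
            cls, fold, enr = "unchanged", 1.0, False
        classes[g.gene_id] = cls
        true_fold[g.gene_id] = fold
        # "enriched" means above background in control, which requires base_fold > 1
        enriched[g.gene_id] = bool(enr and config.base_fold > 1.0)
    return genes, PromoterTruth(classes, true_fold, enriched)


def _occupancy_folds(
    config: SimulationConfig, truth: PromoterTruth, genes: Sequence[GeneModel], sample: str
) -> np.ndarray:
    """Per-gene occupancy fold (relative to the average rate) for a sample."""
    folds = np.ones(len(genes))
    if sample.endswith("input"):
        return folds
    for i, g in enumerate(genes):
        cls = truth.classes[g.gene_id]
        # altered promoters belong to the enriched subset by construction;
        # silent promoters sit at background level (fold 1)
        member = truth.enriched_in_control[g.gene_id] or cls in ("up", "down")
        if not member:
            continue
        fold = config.base_fold
        if sample == "treated_chip":
            if cls == "up":
                fold *= config.fold_up
            elif cls == "down":
                fold *= config.fold_down
        folds[i] = fold
    return folds


def _background_space(
    layout: GenomeLayout, promoter_windows: Dict[str, np.ndarray]
) -> Tuple[List[Tuple[str, int, int]], np.ndarray]:
    """Complement of the promoter windows as (chrom, start, end) segments."""
    segments: List[Tuple[str, int, int]] = []
    for chrom in layout:
        cursor = 0
        for start, end in promoter_windows.get(chrom, np.empty((0, 2), dtype=np.int64)):
            if start > cursor:
                segments.append((chrom, cursor, int(start)))
            cursor = max(cursor, int(end))
        if cursor < layout[chrom]:
            segments.append((chrom, cursor, layout[chrom]))
    lengths = np.array([e - s for _, s, e in segments], dtype=np.int64)
    return segments, lengths


def simulate_tags(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: PromoterTruth,
) -> SampleSet:
    """Draw the four tag collections; totals exactly match the configured depths."""
    layout = config.genome
    G = layout.total_size
    h = config.tss_half_width
    width = 2 * h

    # promoter windows, clipped to chromosomes, grouped per chromosome, sorted
    windows: Dict[str, List[Tuple[int, int]]] = {}
    for g in genes:
        start = max(0, g.tss - h)
        end = min(layout[g.chrom], g.tss + h)
        windows.setdefault(g.chrom, []).append((start, end))
    win_arrays = {
        c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2) for c, v in windows.items()
    }
    bg_segments, bg_lengths = _background_space(layout, win_arrays)
    bg_total = int(bg_lengths.sum())
    bg_cum = np.concatenate([[0], np.cumsum(bg_lengths)])

    rng = config.rng_for(_STREAM_TAGS)
    samples: List[TagCollection] = []
    for sample in SAMPLE_NAMES:
        N = config.total_for(sample)
        folds = _occupancy_folds(config, truth, genes, sample)
        probs = folds * width / G
        bg_prob = 1.0 - probs.sum()
        if bg_prob <= 0.05:
            raise ValueError(
                "promoter occupancy exhausts the genome: reduce n_genes, "
                "folds or tss_half_width"
            )
        counts = rng.multinomial(N, np.concatenate([probs, [bg_prob]]))

        mids_list: List[np.ndarray] = []
        chrom_ids: List[np.ndarray] = []
        chrom_index = {c: i for i, c in enumerate(layout)}
        for g, c in zip(genes, counts[:-1]):
            if c == 0:
                continue
            lo = max(0, g.tss - h)
            hi = min(layout[g.chrom], g.tss + h)
            mids_list.append(lo + (rng.random(c) * (hi - lo)).astype(np.int64))
            chrom_ids.append(np.full(c, chrom_index[g.chrom], dtype=np.int32))
        n_bg = counts[-1]
        if n_bg:
            u = (rng.random(n_bg) * bg_total).astype(np.int64)
            seg_idx = np.searchsorted(bg_cum, u, side="right") - 1
            offsets = u - bg_cum[seg_idx]
            bg_mids = np.empty(n_bg, dtype=np.int64)
            bg_chrom = np.empty(n_bg, dtype=np.int32)
            seg_starts = np.array([s for _, s, _ in bg_segments], dtype=np.int64)
            seg_chrom = np.array(
                [chrom_index[c] for c, _, _ in bg_segments], dtype=np.int32
            )
            bg_mids = seg_starts[seg_idx] + offsets
            bg_chrom = seg_chrom[seg_idx]
            mids_list.append(bg_mids)
            chrom_ids.append(bg_chrom)

        mids = np.concatenate(mids_list) if mids_list else np.empty(0, dtype=np.int64)
        cids = np.concatenate(chrom_ids) if chrom_ids else np.empty(0, dtype=np.int32)
        frag_len = rng.integers(config.frag_min, config.frag_max + 1, size=len(mids))
        strands = np.where(rng.random(len(mids)) < 0.5, 1, -1).astype(np.int8)
        frag_start = mids - frag_len // 2
        frag_end = frag_start + frag_len
        five_prime = np.where(strands > 0, frag_start, frag_end - 1)

        positions: Dict[str, np.ndarray] = {}
        strand_map: Dict[str, np.ndarray] = {}
        for chrom, idx in chrom_index.items():
            mask = cids == idx
            if not mask.any():
                continue
            p = np.clip(five_prime[mask], 0, layout[chrom] - 1)
            positions[chrom] = p
            strand_map[chrom] = strands[mask]
        tc = TagCollection(positions, strand_map)
        assert tc.total_tags == N
        samples.append(tc)
    return SampleSet(*samples)


def simulate_term_annotation(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: PromoterTruth,
    n_terms: int = 50,
    term_size: Tuple[int, int] = (10, 40),
    planted_term_size: int = 15,
) -> Tuple[List["TermAnnotation"], str]:
    """Random term->genes annotation with one term planted inside the up class.

    Returns the annotation and the planted term's id.  Used to validate the
    enrichment statistics end to end: the planted term should dominate the
    enrichment ranking of the recovered up-regulated gene list.
    """
    from chipdiff.enrich import TermAnnotation

    rng = config.rng_for(_STREAM_TERMS)
    gene_ids = [g.gene_id for g in genes]
    up_genes = truth.genes_in_class("up")
    terms: List[TermAnnotation] = []
    planted_id = "TERM_PLANTED"
    if up_genes:
        k = min(planted_term_size, len(up_genes))
        members = rng.choice(up_genes, size=k, replace=False)
        terms.append(
            TermAnnotation(planted_id, "planted up-class term", "GO", frozenset(members))
        )
    for i in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        members = rng.choice(gene_ids, size=size, replace=False)
        terms.append(
            TermAnnotation(f"TERM{i + 1:04d}", f"random term {i + 1}", "GO", frozenset(members))
        )
    return terms, planted_id


def write_truth_tsv(truth: PromoterTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\ttrue_fold\tenriched_in_control\n")
        for gid in sorted(truth.classes):
            fh.write(
                f"{gid}\t{truth.classes[gid]}\t{truth.true_fold[gid]:g}\t"
                f"{int(truth.enriched_in_control[gid])}\n"
            )


def read_truth_tsv(path) -> PromoterTruth:
    classes: Dict[str, str] = {}
    fold: Dict[str, float] = {}
    enriched: Dict[str, bool] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            gid, cls, f, enr = line.rstrip("\n").split("\t")
            classes[gid] = cls
            fold[gid] = float(f)
            enriched[gid] = bool(int(enr))
    return PromoterTruth(classes, fold, enriched)
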