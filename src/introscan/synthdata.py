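"""Synthetic data generation for the addition-line transcriptome pipeline.

Generates gene annotations, negative-binomial count matrices with injected
regional effects (deletions, logFC gradients, fixed shifts), cross-genome
homology hit tables with a controllable collinear fraction, and small
single-rooted ontologies with gene annotations.  Every generator is
deterministic for a fixed seed, and counts come with a ground-truth table so
downstream calls can be scored.

The per-gene baseline is drawn log-normally — a documented stand-in (no
empirical per-gene expression distribution is assumed) chosen so the FPKM
bins the analysis reports on are all populated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ANNOTATION_COLUMNS, BLAST6_COLUMNS

EFFECT_KINDS = ("deletion", "up_gradient", "down_gradient", "fixed_logFC")


class SpecError(ValueError):
    """Raised when a generator spec fails validation."""


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of one synthetic (sub)genome.

    Parameters
    ----------
    chromosomes:
        ``(name, length_bp)`` pairs.
    genes_per_chromosome:
        Number of non-overlapping genes placed on each chromosome.
    label:
        Genome tag used as a gene-id prefix (e.g. ``"wheat"`` or ``"donor"``).
    gene_length_range:
        Uniform sampling range for gene lengths in bp.
    gene_regions:
        Optional per-chromosome ``(start, end)`` window outside which no gene
        is placed — e.g. a donor telosome occupying only part of its
        pseudomolecule.
    """

    chromosomes: tuple
    genes_per_chromosome: int
    label: str = "genome"
    gene_length_range: tuple = (500, 5000)
    gene_regions: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.chromosomes:
            raise SpecError("chromosomes: at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise SpecError(f"chromosomes: length of {name!r} must be > 0")
        if self.genes_per_chromosome <= 0:
            raise SpecError("genes_per_chromosome: must be > 0")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise SpecError("gene_length_range: need 0 < lo <= hi")
        names = {name for name, _ in self.chromosomes}
        for chrom, (rlo, rhi) in self.gene_regions.items():
            if chrom not in names:
                raise SpecError(f"gene_regions: unknown chromosome {chrom!r}")
            if not (1 <= rlo < rhi):
                raise SpecError(f"gene_regions[{chrom!r}]: need 1 <= start < end")
        for name, length in self.chromosomes:
            rlo, rhi = self.gene_regions.get(name, (1, length))
            if rhi > length:
                raise SpecError(f"gene_regions[{name!r}]: end exceeds chromosome length")
            if self.genes_per_chromosome * hi >= rhi - rlo + 1:
                raise SpecError(
                    f"genes_per_chromosome: {self.genes_per_chromosome} genes of up to "
                    f"{hi} bp cannot fit on {name!r} ({rhi - rlo + 1} bp available)"
                )


@dataclass(frozen=True)
class EffectRegion:
    """A regional transcriptional effect injected into the test group."""

    chromosome: str
    start: int
    end: int
    kind: str
    magnitude: float = 0.0

    def validate(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise SpecError(f"kind: {self.kind!r} not in {EFFECT_KINDS}")
        if self.end <= self.start:
            raise SpecError(f"effect region on {self.chromosome}: end <= start")


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design of the simulated count matrix.

    ``groups`` are the genotype labels; ``test_group`` (default: the last
    label) is the one that receives the injected effects — in the addition-line
    design this is the line carrying the donor arm, contrasted against each
    of the other two groups.  ``chromosome_groups`` optionally restricts a chromosome's
    genes to a subset of groups (donor chromosomes are absent from the host
    genotype and vice versa); unlisted chromosomes are present everywhere.
    """

    groups: tuple = ("CS", "B", "CS+7HL")
    replicates: int = 6
    library_size_mean: float = 2.0e7
    library_size_cv: float = 0.1
    dispersion: float = 0.2
    baseline_log_mean: float = 5.3
    baseline_log_sd: float = 1.0
    effect_regions: tuple = ()
    test_group: str | None = None
    chromosome_groups: dict = field(default_factory=dict)

    @property
    def resolved_test_group(self) -> str:
        return self.test_group if self.test_group is not None else self.groups[-1]

    def validate(self, chromosome_lengths: dict | None = None) -> None:
        if len(self.groups) < 2:
            raise SpecError("groups: at least two genotype groups required")
        if len(set(self.groups)) != len(self.groups):
            raise SpecError("groups: labels must be unique")
        if self.replicates < 2:
            raise SpecError("replicates: must be >= 2")
        if self.dispersion < 0:
            raise SpecError("dispersion: must be >= 0")
        if self.library_size_mean <= 0:
            raise SpecError("library_size_mean: must be > 0")
        if self.resolved_test_group not in self.groups:
            raise SpecError(f"test_group: {self.resolved_test_group!r} not in groups")
        for region in self.effect_regions:
            region.validate()
            if chromosome_lengths is not None:
                if region.chromosome not in chromosome_lengths:
                    raise SpecError(
                        f"effect_regions: unknown chromosome {region.chromosome!r}"
                    )
                if region.start > chromosome_lengths[region.chromosome]:
                    raise SpecError(
                        f"effect_regions: region {region.start}-{region.end} starts "
                        f"beyond {region.chromosome!r}"
                    )
        for chrom, groups in self.chromosome_groups.items():
            for g in groups:
                if g not in self.groups:
                    raise SpecError(
                        f"chromosome_groups[{chrom!r}]: unknown group {g!r}"
                    )


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(spec: GenomeSpec, seed: int) -> pd.DataFrame:
    """Place sorted, non-overlapping genes on each chromosome of ``spec``.

    Returns a table with columns ``gene_id, chromosome, start, end, length``
    (1-based inclusive coordinates).  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, chrom_len in spec.chromosomes:
        n = spec.genes_per_chromosome
        lo, hi = spec.gene_length_range
        region_lo, region_hi = spec.gene_regions.get(chrom, (1, chrom_len))
        lengths = rng.integers(lo, hi + 1, size=n)
        free = (region_hi - region_lo + 1) - int(lengths.sum())
        # distribute the free space among the n+1 inter-gene gaps
        weights = rng.random(n + 1)
        gaps = np.floor(free * weights / weights.sum()).astype(np.int64)
        starts = (
            region_lo + gaps[:-1].cumsum() + np.concatenate(([0], lengths[:-1].cumsum()))
        )
        ends = starts + lengths - 1
        for i in range(n):
            rows.append(
                {
                    "gene_id": f"{spec.label}_{chrom}_g{i + 1:05d}",
                    "chromosome": chrom,
                    "start": int(starts[i]),
                    "end": int(ends[i]),
                    "length": int(lengths[i]),
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


# ---------------------------------------------------------------------------
# counts


def _effect_profile(annotation: pd.DataFrame, design: DesignSpec):
    """Per-gene true log2FC in the test group and deletion membership."""
    logfc = np.zeros(len(annotation))
    deleted = np.zeros(len(annotation), dtype=bool)
    pos = annotation["start"].to_numpy()
    chrom = annotation["chromosome"].to_numpy()
    for region in design.effect_regions:
        mask = (chrom == region.chromosome) & (pos >= region.start) & (pos <= region.end)
        if region.kind == "deletion":
            deleted |= mask
            continue
        span = region.end - region.start
        frac = (pos[mask] - region.start) / span
        if region.kind == "fixed_logFC":
            logfc[mask] += region.magnitude
        elif region.kind == "up_gradient":
            # strongest at the proximal (start) edge, fading to zero distally
            logfc[mask] += region.magnitude * (1.0 - frac)
        elif region.kind == "down_gradient":
            # fades in from zero at the start to -magnitude at the distal edge
            logfc[mask] += -region.magnitude * frac
    return logfc, deleted


def generate_counts(
    annotation: pd.DataFrame, design: DesignSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an NB count matrix plus sample metadata and a truth table.

    Counts follow a gamma–Poisson mixture with mean
    ``baseline x library-factor x 2**logFC`` (logFC applied in the test group
    only) and the design's dispersion; genes inside a ``deletion`` region have
    mean exactly 0 in the test group (structural zeros).  Genes on a
    chromosome restricted by ``chromosome_groups`` have mean 0 in the absent
    groups.

    Returns
    -------
    counts : DataFrame, genes x samples
    samples : DataFrame indexed by sample id, columns ``group, replicate``
    truth : DataFrame keyed by gene with true logFC, class and deletion flag
    """
    chrom_lengths = {
        c: int(annotation.loc[annotation["chromosome"] == c, "end"].max())
        for c in annotation["chromosome"].unique()
    }
    design.validate(chromosome_lengths=chrom_lengths)
    rng = np.random.default_rng(seed)
    n_genes = len(annotation)
    test_group = design.resolved_test_group

    sample_ids, sample_group, sample_rep = [], [], []
    for group in design.groups:
        for rep in range(1, design.replicates + 1):
            sample_ids.append(f"{group}_r{rep}")
            sample_group.append(group)
            sample_rep.append(rep)
    samples = pd.DataFrame(
        {"group": sample_group, "replicate": sample_rep},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    sigma2 = np.log1p(design.library_size_cv**2)
    lib_sizes = rng.lognormal(
        np.log(design.library_size_mean) - sigma2 / 2.0,
        np.sqrt(sigma2),
        size=len(samples),
    )
    lib_factor = lib_sizes / design.library_size_mean

    baseline = rng.lognormal(
        design.baseline_log_mean, design.baseline_log_sd, size=n_genes
    )
    logfc, deleted = _effect_profile(annotation, design)

    presence = np.ones((n_genes, len(samples)), dtype=bool)
    chrom_arr = annotation["chromosome"].to_numpy()
    for chrom, present_groups in design.chromosome_groups.items():
        gmask = chrom_arr == chrom
        smask = ~samples["group"].isin(present_groups).to_numpy()
        presence[np.ix_(gmask, smask)] = False

    is_test = (samples["group"] == test_group).to_numpy()
    mean = baseline[:, None] * lib_factor[None, :]
    mean[:, is_test] *= 2.0 ** logfc[:, None]
    mean[np.ix_(deleted, is_test)] = 0.0
    mean[~presence] = 0.0

    if design.dispersion > 0:
        shape = 1.0 / design.dispersion
        lam = rng.gamma(shape, design.dispersion * mean)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(
        counts, index=pd.Index(annotation["gene_id"], name="gene_id"), columns=samples.index
    )

    true_class = np.where(
        deleted, "deleted", np.where(logfc > 0, "up", np.where(logfc < 0, "down", "null"))
    )
    truth = pd.DataFrame(
        {
            "gene_id": annotation["gene_id"].to_numpy(),
            "chromosome": chrom_arr,
            "start": annotation["start"].to_numpy(),
            "true_logFC": np.where(deleted, -np.inf, logfc),
            "true_class": true_class,
            "in_deletion": deleted,
        }
    ).set_index("gene_id")
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# homology hits


def generate_homology_hits(
    annotation_a: pd.DataFrame,
    annotation_b: pd.DataFrame,
    collinear_fraction: float,
    seed: int,
    noise_fraction: float = 0.3,
) -> pd.DataFrame:
    """Simulate a BLAST-tabular hit table between two annotated gene sets.

    A ``collinear_fraction`` of ``min(nA, nB)`` genes form order-preserving
    pairs with strong E-values (< 1e-20); ``noise_fraction x min(nA, nB)``
    random pairs are added with E-values spanning both sides of the 1e-5
    filtering threshold.
    """
    if not 0.0 <= collinear_fraction <= 1.0:
        raise SpecError("collinear_fraction: must lie in [0, 1]")
    if noise_fraction < 0:
        raise SpecError("noise_fraction: must be >= 0")
    rng = np.random.default_rng(seed)
    a_ids = annotation_a.sort_values(["chromosome", "start"])["gene_id"].to_numpy()
    b_ids = annotation_b.sort_values(["chromosome", "start"])["gene_id"].to_numpy()
    n = min(len(a_ids), len(b_ids))
    k = int(round(collinear_fraction * n))

    rows = []
    if k > 0:
        ia = np.sort(rng.choice(len(a_ids), size=k, replace=False))
        ib = np.sort(rng.choice(len(b_ids), size=k, replace=False))
        evalues = 10.0 ** (-rng.uniform(20, 60, size=k))
        bits = rng.uniform(300, 900, size=k)
        for qa, sb, ev, bit in zip(a_ids[ia], b_ids[ib], evalues, bits):
            rows.append((qa, sb, ev, bit))
    n_noise = int(round(noise_fraction * n))
    if n_noise > 0:
        qa = a_ids[rng.integers(0, len(a_ids), size=n_noise)]
        sb = b_ids[rng.integers(0, len(b_ids), size=n_noise)]
        evalues = 10.0 ** (-rng.uniform(0, 10, size=n_noise))
        bits = rng.uniform(40, 80, size=n_noise)
        rows.extend(zip(qa, sb, evalues, bits))

    aln_len = rng.integers(100, 500, size=len(rows))
    hits = pd.DataFrame(
        {
            "qseqid": [r[0] for r in rows],
            "sseqid": [r[1] for r in rows],
            "pident": np.round(rng.uniform(70, 99, size=len(rows)), 2),
            "length": aln_len,
            "mismatch": rng.integers(0, 30, size=len(rows)),
            "gapopen": rng.integers(0, 5, size=len(rows)),
            "qstart": 1,
            "qend": aln_len,
            "sstart": 1,
            "send": aln_len,
            "evalue": [r[2] for r in rows],
            "bitscore": np.round([r[3] for r in rows], 1),
        },
        columns=BLAST6_COLUMNS,
    )
    return hits


# ---------------------------------------------------------------------------
# ontology


def generate_ontology(
    n_terms: int,
    seed: int,
    gene_ids=None,
    n_genes: int = 100,
    terms_per_gene: tuple = (1, 3),
) -> tuple[dict, dict]:
    """Build a single-rooted random DAG and direct gene->term annotations.

    Each non-root term draws one or two parents among previously created
    terms, which guarantees acyclicity and root reachability.  Annotations
    are direct (un-propagated); run :func:`introscan.enrichment.propagate`
    to apply the true-path rule.

    Returns ``(parents, annotations)`` where ``parents`` maps term id to a
    tuple of parent ids (empty for the root) and ``annotations`` maps gene id
    to a set of directly annotated terms.
    """
    if n_terms < 3:
        raise SpecError("n_terms: must be >= 3")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    parents: dict[str, tuple] = {terms[0]: ()}
    for i in range(1, n_terms):
        n_parents = 1 if i == 1 else int(rng.integers(1, 3))
        chosen = rng.choice(i, size=min(n_parents, i), replace=False)
        parents[terms[i]] = tuple(terms[j] for j in sorted(chosen))
    if gene_ids is None:
        gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    lo, hi = terms_per_gene
    non_root = terms[1:]
    annotations: dict[str, set] = {}
    for gene in gene_ids:
        count = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(non_root), size=min(count, len(non_root)), replace=False)
        annotations[gene] = {non_root[j] for j in chosen}
    return parents, annotations
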