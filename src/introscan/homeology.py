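"""Synteny-block detection, 1:1 homeolog pairing and compensation scoring.

Consumes a BLAST-style tabular hit table between two annotated gene sets.
Hits are E-value filtered, chained into collinear blocks by dynamic
programming over gene-order ranks (both orientations), reduced to exclusive
1:1 pairs, and — for pairs whose host gene falls in a deleted interval —
scored for transcriptional compensation by the donor copy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_EVALUE = 1e-5
DEFAULT_MIN_BLOCK = 10
DEFAULT_MAX_RANK_GAP = 25


def gene_ranks(annotation: pd.DataFrame) -> pd.Series:
    """0-based gene-order rank along each chromosome (by start position)."""
    ann = annotation.sort_values(["chromosome", "start"])
    rank = ann.groupby("chromosome").cumcount()
    return pd.Series(rank.to_numpy(), index=ann["gene_id"].to_numpy(), name="rank")


def filter_hits(hits: pd.DataFrame, e_threshold: float = DEFAULT_EVALUE) -> pd.DataFrame:
    """Keep hits with E-value <= threshold; drop self-hits."""
    keep = (hits["evalue"] <= e_threshold) & (hits["qseqid"] != hits["sseqid"])
    return hits[keep].reset_index(drop=True)


@dataclass
class SyntenyBlock:
    """A run of order-conserved cross-genome gene pairs."""

    query_chromosome: str
    subject_chromosome: str
    orientation: str  # "same" or "inverted"
    pairs: pd.DataFrame  # hit rows in chain order

    @property
    def size(self) -> int:
        return len(self.pairs)


def _chain_once(qr: np.ndarray, sr: np.ndarray, max_gap: int) -> list:
    """Longest chain with increasing ranks and bounded gaps in both genomes.

    O(n^2) DP over hits sorted by (query rank, subject rank); returns the
    indices of the best chain.
    """
    n = len(qr)
    best_len = np.ones(n, dtype=np.int64)
    prev = np.full(n, -1, dtype=np.int64)
    for j in range(n):
        for i in range(j):
            if (
                0 < qr[j] - qr[i] <= max_gap
                and 0 < sr[j] - sr[i] <= max_gap
                and best_len[i] + 1 > best_len[j]
            ):
                best_len[j] = best_len[i] + 1
                prev[j] = i
    end = int(np.argmax(best_len))
    chain = []
    while end != -1:
        chain.append(end)
        end = int(prev[end])
    return chain[::-1]


def chain_collinear_blocks(
    hits: pd.DataFrame,
    ranks_a: pd.Series,
    ranks_b: pd.Series,
    chrom_a: pd.Series,
    chrom_b: pd.Series,
    min_block: int = DEFAULT_MIN_BLOCK,
    max_rank_gap: int = DEFAULT_MAX_RANK_GAP,
) -> list:
    """Extract collinear blocks per chromosome pair and orientation.

    Within each (query chromosome, subject chromosome) pair, hits are chained
    when both rank gaps are positive and <= ``max_rank_gap``, with the
    subject ranks monotone increasing ("same" orientation) or decreasing
    ("inverted", handled by rank reflection).  Maximal chains are extracted
    greedily without hit reuse; chains shorter than ``min_block`` are
    discarded.

    ``ranks_*`` / ``chrom_*`` map gene ids to order ranks and chromosomes in
    the two genomes (see :func:`gene_ranks`).
    """
    hits = hits.copy()
    hits["q_rank"] = hits["qseqid"].map(ranks_a)
    hits["s_rank"] = hits["sseqid"].map(ranks_b)
    hits["q_chrom"] = hits["qseqid"].map(chrom_a)
    hits["s_chrom"] = hits["sseqid"].map(chrom_b)
    if hits[["q_rank", "s_rank"]].isna().any().any():
        missing = hits.loc[hits[["q_rank", "s_rank"]].isna().any(axis=1), ["qseqid", "sseqid"]]
        raise ValueError(f"hits reference genes absent from the annotations: {missing.head().values.tolist()}")

    blocks = []
    for (qc, sc), group in hits.groupby(["q_chrom", "s_chrom"], sort=True):
        for orientation in ("same", "inverted"):
            available = group.sort_values(
                ["q_rank", "s_rank"], kind="mergesort"
            ).reset_index(drop=True)
            while True:
                if len(available) < min_block:
                    break
                qr = available["q_rank"].to_numpy(dtype=np.int64)
                sr = available["s_rank"].to_numpy(dtype=np.int64)
                if orientation == "inverted":
                    sr = sr.max() - sr
                chain = _chain_once(qr, sr, max_rank_gap)
                if len(chain) < min_block:
                    break
                blocks.append(
                    SyntenyBlock(
                        query_chromosome=qc,
                        subject_chromosome=sc,
                        orientation=orientation,
                        pairs=available.iloc[chain].reset_index(drop=True),
                    )
                )
                available = available.drop(available.index[chain]).reset_index(
                    drop=True
                )
    return blocks


def one_to_one(blocks: list) -> pd.DataFrame:
    """Reduce block-supported pairs to an exclusive 1:1 homeolog set.

    All pairs from all blocks are pooled; for each gene only its best pair
    survives (highest bit score, then lowest E-value).  A gene still tied
    between several equally supported partners occurs in more than one pair
    and is dropped entirely.  The retained pairs are those that are the
    unique best for both of their genes.
    """
    if not blocks:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "block_id", "evalue", "bitscore"]
        )
    frames = []
    for bid, block in enumerate(blocks):
        sub = block.pairs[["qseqid", "sseqid", "evalue", "bitscore"]].copy()
        sub["block_id"] = bid
        frames.append(sub)
    pairs = pd.concat(frames, ignore_index=True)
    pairs = pairs.drop_duplicates(subset=["qseqid", "sseqid"])

    def best_of(group: pd.DataFrame) -> pd.DataFrame:
        top = group[group["bitscore"] == group["bitscore"].max()]
        return top[top["evalue"] == top["evalue"].min()]

    by_q = pairs.groupby("qseqid", group_keys=False)[pairs.columns].apply(best_of)
    by_s = by_q.groupby("sseqid", group_keys=False)[by_q.columns].apply(best_of)
    # exclusivity: both genes must appear exactly once in the surviving set
    q_counts = by_s["qseqid"].value_counts()
    s_counts = by_s["sseqid"].value_counts()
    keep = by_s[
        by_s["qseqid"].map(q_counts).eq(1) & by_s["sseqid"].map(s_counts).eq(1)
    ]
    out = keep.rename(columns={"qseqid": "gene_a", "sseqid": "gene_b"})
    return (
        out[["gene_a", "gene_b", "block_id", "evalue", "bitscore"]]
        .sort_values(["gene_a", "gene_b"])
        .reset_index(drop=True)
    )


def class_distribution(
    pairs: pd.DataFrame,
    dt_coords: pd.DataFrame,
    chromosome: str,
    start: int,
    end: int,
    paired_side: str = "gene_b",
) -> pd.DataFrame:
    """DT-class counts for All / homeolog / nonhomeolog genes of a region.

    The region is taken on the genome whose genes appear in
    ``pairs[paired_side]``; a transcribed gene is a homeolog iff it occurs in
    the 1:1 set.  Percentages are per column (of that column's transcribed
    total).
    """
    region = dt_coords[
        (dt_coords["chromosome"] == chromosome)
        & (dt_coords["start"] >= start)
        & (dt_coords["start"] <= end)
    ]
    homeologs = set(pairs[paired_side])
    is_homeo = region.index.isin(homeologs)
    rows = []
    for label, mask in (
        ("All", np.ones(len(region), dtype=bool)),
        ("homeolog", is_homeo),
        ("nonhomeolog", ~is_homeo),
    ):
        sub = region[mask]
        n = len(sub)
        for cls in ("not_DT", "up", "down"):
            k = int((sub["dt_class"] == cls).sum())
            rows.append(
                {
                    "set": label,
                    "dt_class": cls,
                    "count": k,
                    "pct": 100.0 * k / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def compensation(
    pairs: pd.DataFrame,
    fpkm_host_ref: pd.Series,
    fpkm_donor_test: pd.Series,
    host_annotation: pd.DataFrame,
    deletion_chromosome: str,
    deletion_start: int,
    deletion_end: int,
    ratio_threshold: float = 0.5,
    high_fpkm_threshold: float = 20.0,
) -> tuple[pd.DataFrame, dict]:
    """Score donor-copy compensation for host genes in a deleted interval.

    For each 1:1 pair whose host gene (``gene_a``) starts inside the deletion
    interval: ratio = donor-gene mean FPKM in the addition genotype over
    host-gene mean FPKM in the host genotype.  A pair partially compensates
    iff ratio >= ``ratio_threshold``; donor genes with mean FPKM >=
    ``high_fpkm_threshold`` are flagged highly transcribed.  Host genes with
    zero reference FPKM give an undefined ratio and are excluded from the
    summary denominator.

    Returns the annotated pair table and a summary dict.
    """
    ann = host_annotation.set_index("gene_id")
    sub = pairs.copy()
    sub["host_chrom"] = sub["gene_a"].map(ann["chromosome"])
    sub["host_start"] = sub["gene_a"].map(ann["start"])
    sub = sub[
        (sub["host_chrom"] == deletion_chromosome)
        & (sub["host_start"] >= deletion_start)
        & (sub["host_start"] <= deletion_end)
    ].copy()

    host_fpkm = fpkm_host_ref.reindex(sub["gene_a"]).to_numpy(dtype=float)
    donor_fpkm = fpkm_donor_test.reindex(sub["gene_b"]).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(host_fpkm > 0, donor_fpkm / host_fpkm, np.nan)
    sub["host_fpkm_ref"] = host_fpkm
    sub["donor_fpkm_test"] = donor_fpkm
    sub["compensation_ratio"] = ratio
    sub["partial_compensation"] = (ratio >= ratio_threshold) & ~np.isnan(ratio)
    sub["donor_highly_transcribed"] = donor_fpkm >= high_fpkm_threshold

    defined = sub[~sub["compensation_ratio"].isna()]
    summary = {
        "n_pairs_in_deletion": int(len(sub)),
        "n_ratio_defined": int(len(defined)),
        "n_partial_compensation": int(defined["partial_compensation"].sum()),
        "n_donor_highly_transcribed": int(sub["donor_highly_transcribed"].sum()),
        "n_undefined_ratio": int(sub["compensation_ratio"].isna().sum()),
    }
    return sub.reset_index(drop=True), summary
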