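"""Readers and writers for the plain-text formats used across the pipeline.

All tables are TSV; genomic intervals are written both as BED (0-based,
half-open) and GFF3 (1-based, inclusive); homology hits use the 12-column
BLAST tabular layout; ontologies use a minimal OBO subset ([Term] stanzas
with ``id``, ``name`` and ``is_a`` lines only).
"""

from __future__ import annotations

import pandas as pd

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

ANNOTATION_COLUMNS = ["gene_id", "chromosome", "start", "end", "length"]


# ---------------------------------------------------------------------------
# gene annotation


def write_bed(annotation: pd.DataFrame, path) -> None:
    """Write a gene annotation table as 4-column BED (0-based, half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": annotation["chromosome"],
            "chromStart": annotation["start"] - 1,
            "chromEnd": annotation["end"],
            "name": annotation["gene_id"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Write a gene annotation table as GFF3 (1-based, inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\tintroscan\tgene\t{row.start}\t{row.end}"
                f"\t.\t+\t.\tID={row.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read gene records from a GFF3 file into the internal annotation layout."""
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            start, end = int(fields[3]), int(fields[4])
            records.append(
                {
                    "gene_id": attrs.get("ID", f"{fields[0]}:{start}-{end}"),
                    "chromosome": fields[0],
                    "start": start,
                    "end": end,
                    "length": end - start + 1,
                }
            )
    return pd.DataFrame(records, columns=ANNOTATION_COLUMNS)


def read_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "chromStart", "chromEnd", "name"]
    )
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chromosome": bed["chrom"],
            "start": bed["chromStart"] + 1,
            "end": bed["chromEnd"],
            "length": bed["chromEnd"] - bed["chromStart"],
        }
    )


# ---------------------------------------------------------------------------
# count matrices


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ---------------------------------------------------------------------------
# homology hits


def write_blast6(hits: pd.DataFrame, path) -> None:
    hits[BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_blast6(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)


# ---------------------------------------------------------------------------
# ontology


def write_obo(parents: dict, path, names: dict | None = None) -> None:
    """Write a term->parents mapping as a minimal OBO document."""
    names = names or {}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(parents):
            fh.write(f"\n[Term]\nid: {term}\n")
            fh.write(f"name: {names.get(term, term)}\n")
            for parent in sorted(parents[term]):
                fh.write(f"is_a: {parent}\n")


def read_obo(path) -> dict:
    """Parse a minimal OBO file into a term -> tuple-of-parents mapping."""
    parents: dict[str, tuple[str, ...]] = {}
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                current = None
            elif line.startswith("id:"):
                current = line.split(":", 1)[1].strip()
                parents.setdefault(current, ())
            elif line.startswith("is_a:") and current is not None:
                target = line.split(":", 1)[1].split("!")[0].strip()
                parents[current] = parents[current] + (target,)
    return parents


def write_gene2term(annotations: dict, path) -> None:
    """Write direct gene->term annotations as a 2-column TSV."""
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_gene2term(path) -> dict:
    annotations: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            gene, term = line.rstrip("\n").split("\t")[:2]
            annotations.setdefault(gene, set()).add(term)
    return annotations


# ---------------------------------------------------------------------------
# tracks


def write_bedgraph(track, path) -> None:
    """Write one WindowTrack as bedGraph; windows without data are skipped."""
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{track.metric}" description="{track.chromosome}"\n'
        )
        for start, end, value in zip(track.starts, track.ends, track.values):
            if value == value:  # not NaN
                fh.write(f"{track.chromosome}\t{start}\t{end}\t{value:.6g}\n")
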