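"""End-to-end orchestration: simulate -> DT -> scan -> homeology -> enrichment.

A single YAML config drives a reproducible run; every intermediate table is
written (the interesting quantities of this analysis all live in
intermediates), and a manifest records the config hash, seed and row counts
so a run can be replayed and compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chromoscan, diffexpr, enrichment, homeology, io, synthdata

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "cpm": 1.0,
    "fdr": 0.05,
    "window": 10_000_000,
    "step": 1_000_000,
    "penalty": "MBIC",
    "min_segment": 2,
    "evalue": 1.0e-5,
    "min_block": 10,
    "max_rank_gap": 25,
    "r_down_min": 0.9,
    "r_up_max": 0.0,
    "deletion_fpkm_max": 1.0,
    "compensation_ratio": 0.5,
    "high_fpkm": 20.0,
    "enrichment_alpha": 0.05,
    "logfc_pseudo": 0.125,
    "prior_df": 20.0,
}

DEFAULT_CONFIG = {
    "seed": 1,
    "simulation": {
        "host": {
            "label": "wheat",
            "chromosomes": [["7A", 740_000_000], ["1B", 600_000_000]],
            "genes_per_chromosome": 1500,
        },
        "donor": {
            "label": "barley",
            "chromosomes": [["7H", 656_000_000]],
            "genes_per_chromosome": 900,
            "gene_regions": {"7H": [339_000_000, 656_000_000]},
        },
        "design": {
            "groups": ["CS", "B", "CS+7HL"],
            "replicates": 6,
            "library_size_mean": 2.0e7,
            "library_size_cv": 0.1,
            "dispersion": 0.2,
            "baseline_log_mean": 5.3,
            "baseline_log_sd": 1.0,
            "test_group": "CS+7HL",
            "host_groups": ["CS", "CS+7HL"],
            "donor_groups": ["B", "CS+7HL"],
            "effect_regions": [
                {"chromosome": "7A", "start": 700_000_000, "end": 736_000_000,
                 "kind": "deletion"},
                {"chromosome": "7H", "start": 339_000_000, "end": 500_000_000,
                 "kind": "up_gradient", "magnitude": 1.5},
                {"chromosome": "7H", "start": 500_000_000, "end": 656_000_000,
                 "kind": "down_gradient", "magnitude": 1.5},
            ],
        },
        "homology": {
            "host_chromosome": "7A",
            "donor_chromosome": "7H",
            "collinear_fraction": 0.8,
            "noise_fraction": 0.3,
        },
        "ontology": {"n_terms": 50},
    },
    "contrasts": [
        {"name": "host_vs_addition", "reference": "CS", "test": "CS+7HL",
         "chromosomes": ["7A", "1B"]},
        {"name": "donor_vs_addition", "reference": "B", "test": "CS+7HL",
         "chromosomes": ["7H"]},
    ],
    "thresholds": dict(DEFAULT_THRESHOLDS),
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged in)."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = _deep_merge(DEFAULT_CONFIG, self.raw or {})
        self.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def thresholds(self) -> dict:
        return self.raw["thresholds"]

    @property
    def contrasts(self) -> list:
        return self.raw["contrasts"]

    def validate(self) -> None:
        groups = self.raw["simulation"]["design"]["groups"]
        for contrast in self.raw["contrasts"]:
            for key in ("reference", "test"):
                if contrast[key] not in groups:
                    raise ValueError(
                        f"contrast {contrast.get('name', '?')!r}: group "
                        f"{contrast[key]!r} not among design groups {groups}"
                    )
        for key in self.raw["thresholds"]:
            if key not in DEFAULT_THRESHOLDS:
                raise ValueError(f"unknown threshold {key!r}")

    def config_hash(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# simulation stage


def simulate(config: RunConfig, outdir: Path, seed: int | None = None) -> dict:
    """Generate annotations, counts, hits and ontology; write them to disk."""
    sim = config.raw["simulation"]
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def genome_spec(section: dict) -> synthdata.GenomeSpec:
        return synthdata.GenomeSpec(
            chromosomes=tuple((c, int(l)) for c, l in section["chromosomes"]),
            genes_per_chromosome=int(section["genes_per_chromosome"]),
            label=section.get("label", "genome"),
            gene_regions={
                c: tuple(map(int, r))
                for c, r in section.get("gene_regions", {}).items()
            },
        )

    host_spec = genome_spec(sim["host"])
    donor_spec = genome_spec(sim["donor"])
    host_ann = synthdata.generate_annotation(host_spec, seed)
    donor_ann = synthdata.generate_annotation(donor_spec, seed + 1)
    annotation = pd.concat([host_ann, donor_ann], ignore_index=True)

    d = sim["design"]
    chromosome_groups = {}
    for chrom, _ in host_spec.chromosomes:
        chromosome_groups[chrom] = list(d.get("host_groups", d["groups"]))
    for chrom, _ in donor_spec.chromosomes:
        chromosome_groups[chrom] = list(d.get("donor_groups", d["groups"]))
    design = synthdata.DesignSpec(
        groups=tuple(d["groups"]),
        replicates=int(d["replicates"]),
        library_size_mean=float(d["library_size_mean"]),
        library_size_cv=float(d["library_size_cv"]),
        dispersion=float(d["dispersion"]),
        baseline_log_mean=float(d["baseline_log_mean"]),
        baseline_log_sd=float(d["baseline_log_sd"]),
        effect_regions=tuple(
            synthdata.EffectRegion(
                chromosome=r["chromosome"],
                start=int(r["start"]),
                end=int(r["end"]),
                kind=r["kind"],
                magnitude=float(r.get("magnitude", 0.0)),
            )
            for r in d.get("effect_regions", [])
        ),
        test_group=d.get("test_group"),
        chromosome_groups=chromosome_groups,
    )
    counts, samples, truth = synthdata.generate_counts(annotation, design, seed + 2)

    hom = sim["homology"]
    hits = synthdata.generate_homology_hits(
        host_ann[host_ann["chromosome"] == hom["host_chromosome"]],
        donor_ann[donor_ann["chromosome"] == hom["donor_chromosome"]],
        collinear_fraction=float(hom["collinear_fraction"]),
        seed=seed + 3,
        noise_fraction=float(hom.get("noise_fraction", 0.3)),
    )
    parents, gene2term = synthdata.generate_ontology(
        int(sim["ontology"]["n_terms"]),
        seed + 4,
        gene_ids=list(annotation["gene_id"]),
    )

    io.write_gff3(annotation, outdir / "annotation.gff3")
    io.write_bed(annotation, outdir / "annotation.bed")
    io.write_counts(counts, outdir / "counts.tsv")
    io.write_samples(samples, outdir / "samples.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    io.write_blast6(hits, outdir / "hits.blast6")
    io.write_obo(parents, outdir / "ontology.obo")
    io.write_gene2term(gene2term, outdir / "gene2term.tsv")

    chrom_lengths = {c: int(l) for c, l in list(host_spec.chromosomes) + list(donor_spec.chromosomes)}
    return {
        "annotation": annotation,
        "host_annotation": host_ann,
        "donor_annotation": donor_ann,
        "counts": counts,
        "samples": samples,
        "truth": truth,
        "hits": hits,
        "ontology": parents,
        "gene2term": gene2term,
        "chromosome_lengths": chrom_lengths,
    }


# ---------------------------------------------------------------------------
# analysis stages


def run_contrast(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    annotation: pd.DataFrame,
    reference: str,
    test: str,
    chromosomes: list,
    thresholds: dict,
) -> dict:
    """Filter, normalize and test one genotype contrast on a chromosome set."""
    genes = annotation[annotation["chromosome"].isin(chromosomes)]["gene_id"]
    matrix = diffexpr.CountMatrix(counts.loc[genes], samples).subset_groups(
        [reference, test]
    )
    factors = diffexpr.tmm_factors(matrix)
    transcribed = diffexpr.filter_transcribed(
        matrix, factors, reference, test, threshold=thresholds["cpm"]
    )
    tested = matrix.subset_genes(transcribed)
    dispersions = diffexpr.estimate_dispersion(tested, prior_df=thresholds["prior_df"])
    dt = diffexpr.test_dt(
        tested,
        factors,
        dispersions,
        reference,
        test,
        alpha=thresholds["fdr"],
        logfc_pseudo=thresholds["logfc_pseudo"],
    )
    lengths = annotation.set_index("gene_id")["length"]
    fpkm_table = diffexpr.fpkm(tested, factors, lengths)
    fpkm_groups = diffexpr.group_means(fpkm_table, tested.samples)
    dt_coords = chromoscan.attach_coordinates(dt, annotation)
    dt_coords[f"fpkm_{reference}"] = fpkm_groups[reference]
    dt_coords[f"fpkm_{test}"] = fpkm_groups[test]
    return {
        "matrix": tested,
        "factors": factors,
        "dispersions": dispersions,
        "dt": dt_coords,
        "fpkm": fpkm_table,
        "fpkm_groups": fpkm_groups,
        "summary": diffexpr.summarize_contrast(dt),
    }


def scan_chromosome(
    dt_coords: pd.DataFrame,
    chromosome: str,
    chrom_length: int,
    fpkm_test: pd.Series,
    thresholds: dict,
) -> dict:
    """Window metrics, per-metric PELT segmentation and deletion calls."""
    tracks = chromoscan.window_metrics(
        dt_coords,
        chromosome,
        chrom_length,
        window=int(thresholds["window"]),
        step=int(thresholds["step"]),
    )
    segments = {
        name: chromoscan.pelt_segment(
            track,
            penalty=thresholds["penalty"],
            min_size=int(thresholds["min_segment"]),
        )
        for name, track in tracks.items()
    }
    profile = chromoscan.classify_segments(
        segments["R_Down_Trans"], dt_coords, fpkm_test=fpkm_test
    )
    deletions = chromoscan.call_deletions(
        profile,
        dt_coords,
        fpkm_test,
        r_down_min=thresholds["r_down_min"],
        r_up_max=thresholds["r_up_max"],
        fpkm_max=thresholds["deletion_fpkm_max"],
    )
    return {"tracks": tracks, "segments": segments, "profile": profile,
            "deletions": deletions}


def run_all(config: RunConfig, outdir) -> Path:
    """Execute every stage in order and write a run manifest.

    Re-running with the same config and seed reproduces identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "tables": {},
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.raw, fh, sort_keys=True)

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"started": time.time()}

    def done(name, **rows):
        manifest["stages"][name]["seconds"] = round(
            time.time() - manifest["stages"][name].pop("started"), 3
        )
        manifest["tables"].update(rows)

    stage("simulate")
    sim = simulate(config, outdir / "inputs")
    done("simulate", genes=len(sim["annotation"]), samples=len(sim["samples"]),
         hits=len(sim["hits"]))

    annotation = sim["annotation"]
    chrom_lengths = sim["chromosome_lengths"]
    results = {}
    all_deletions = []
    for contrast in config.contrasts:
        name = contrast["name"]
        stage(f"dt:{name}")
        try:
            res = run_contrast(
                sim["counts"], sim["samples"], annotation,
                contrast["reference"], contrast["test"],
                contrast["chromosomes"], thresholds,
            )
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise RuntimeError(f"stage dt:{name} failed: {exc}") from exc
        results[name] = res
        cdir = outdir / name
        cdir.mkdir(exist_ok=True)
        res["dt"].to_csv(cdir / "dt.tsv", sep="\t", index_label="gene_id")
        pd.DataFrame([res["summary"]]).to_csv(cdir / "summary.tsv", sep="\t", index=False)
        norm = pd.DataFrame(
            {"lib_size": res["factors"].lib_size, "tmm": res["factors"].factor,
             "effective": res["factors"].effective}
        )
        norm.to_csv(cdir / "norm_factors.tsv", sep="\t", index_label="sample_id")
        done(f"dt:{name}", **{f"{name}/dt": len(res["dt"])})

        stage(f"scan:{name}")
        fpkm_test = res["fpkm_groups"][contrast["test"]]
        seg_frames, del_rows = [], []
        for chrom in contrast["chromosomes"]:
            scan = scan_chromosome(
                res["dt"], chrom, chrom_lengths[chrom], fpkm_test, thresholds
            )
            for metric, track in scan["tracks"].items():
                io.write_bedgraph(track, cdir / f"track_{chrom}_{metric}.bedgraph")
            seg_frames.extend(s.to_frame() for s in scan["segments"].values())
            scan["profile"].to_csv(
                cdir / f"segments_profile_{chrom}.tsv", sep="\t", index=False
            )
            for call in scan["deletions"]:
                del_rows.append({**call.__dict__, "contrast": name})
        pd.concat(seg_frames, ignore_index=True).to_csv(
            cdir / "segments.tsv", sep="\t", index=False
        )
        deletions = pd.DataFrame(
            del_rows,
            columns=["contrast", "chromosome", "start", "end", "n_transcribed",
                     "n_down", "n_not_DT", "n_up", "mean_fpkm_test", "mean_logFC"],
        )
        deletions.to_csv(cdir / "deletions.tsv", sep="\t", index=False)
        all_deletions.append(deletions)
        done(f"scan:{name}", **{f"{name}/deletions": len(deletions)})

    # homeology + compensation: host deletion vs donor arm
    stage("homeology")
    hom_cfg = config.raw["simulation"]["homology"]
    host_contrast = config.contrasts[0]
    donor_contrast = config.contrasts[1] if len(config.contrasts) > 1 else None
    hits = homeology.filter_hits(sim["hits"], e_threshold=thresholds["evalue"])
    ranks_a = homeology.gene_ranks(sim["host_annotation"])
    ranks_b = homeology.gene_ranks(sim["donor_annotation"])
    chrom_a = sim["host_annotation"].set_index("gene_id")["chromosome"]
    chrom_b = sim["donor_annotation"].set_index("gene_id")["chromosome"]
    blocks = homeology.chain_collinear_blocks(
        hits, ranks_a, ranks_b, chrom_a, chrom_b,
        min_block=int(thresholds["min_block"]),
        max_rank_gap=int(thresholds["max_rank_gap"]),
    )
    pairs = homeology.one_to_one(blocks)
    hdir = outdir / "homeology"
    hdir.mkdir(exist_ok=True)
    if blocks:
        block_table = pd.concat(
            [b.pairs.assign(block_id=i, orientation=b.orientation)
             for i, b in enumerate(blocks)],
            ignore_index=True,
        )
    else:
        block_table = pd.DataFrame(columns=["qseqid", "sseqid", "block_id", "orientation"])
    block_table.to_csv(hdir / "blocks.tsv", sep="\t", index=False)
    pairs.to_csv(hdir / "pairs.tsv", sep="\t", index=False)

    non_empty = [d for d in all_deletions if not d.empty]
    deletion_df = (
        pd.concat(non_empty, ignore_index=True) if non_empty else all_deletions[0]
    )
    comp_summary = {"available": False}
    if (
        donor_contrast is not None
        and not deletion_df.empty
        and not pairs.empty
    ):
        first = deletion_df.iloc[0]
        host_res = results[host_contrast["name"]]
        donor_res = results[donor_contrast["name"]]
        comp, comp_summary = homeology.compensation(
            pairs,
            host_res["fpkm_groups"][host_contrast["reference"]],
            donor_res["fpkm_groups"][donor_contrast["test"]],
            sim["host_annotation"],
            first["chromosome"],
            int(first["start"]),
            int(first["end"]),
            ratio_threshold=thresholds["compensation_ratio"],
            high_fpkm_threshold=thresholds["high_fpkm"],
        )
        comp.to_csv(hdir / "compensation.tsv", sep="\t", index=False)
        comp_summary["available"] = True
    with open(hdir / "compensation_summary.json", "w") as fh:
        json.dump(comp_summary, fh, indent=2, sort_keys=True)
    done("homeology", blocks=len(blocks), pairs=len(pairs))

    # enrichment of up/down sets of the host contrast
    stage("enrichment")
    parents = sim["ontology"]
    propagated = enrichment.propagate(parents, sim["gene2term"])
    edir = outdir / "enrichment"
    edir.mkdir(exist_ok=True)
    host_res = results[host_contrast["name"]]
    population = set(host_res["dt"].index)
    for direction in ("up", "down"):
        study = set(host_res["dt"].index[host_res["dt"]["dt_class"] == direction])
        if study:
            res = enrichment.parent_child_union_test(
                study, population, parents, propagated
            )
        else:
            res = pd.DataFrame()
        res.to_csv(edir / f"{direction}_terms.tsv", sep="\t", index=False)
        enrichment.enriched_terms(res, alpha=thresholds["enrichment_alpha"]).to_csv(
            edir / f"{direction}_enriched.tsv", sep="\t", index=False
        )
    done("enrichment")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# reporting


def report(run_dir, with_plots: bool = True) -> Path:
    """Summarize a completed run into ``report.md`` (plus track plots)."""
    run_dir = Path(run_dir)
    lines = ["# introscan run report", ""]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"seed: {manifest['seed']}  config: {manifest['config_hash']}")
        lines.append("")

    for cdir in sorted(p for p in run_dir.iterdir() if (p / "summary.tsv").exists()):
        summary = pd.read_csv(cdir / "summary.tsv", sep="\t").iloc[0]
        lines += [
            f"## Contrast {cdir.name}",
            "",
            "| class | count | % of transcribed |",
            "|---|---|---|",
            f"| transcribed | {summary['transcribed']} | 100.00 |",
            f"| not_DT | {summary['not_DT']} | {summary['pct_not_DT']:.2f} |",
            f"| DT | {summary['DT']} | {summary['pct_DT']:.2f} |",
            f"| up | {summary['up']} | {summary['pct_up']:.2f} |",
            f"| down | {summary['down']} | {summary['pct_down']:.2f} |",
            "",
        ]
        dels = pd.read_csv(cdir / "deletions.tsv", sep="\t")
        if len(dels):
            lines.append("Deletion calls:")
            for row in dels.itertuples(index=False):
                lines.append(
                    f"- {row.chromosome}:{row.start}-{row.end} "
                    f"({row.n_down}/{row.n_transcribed} down, "
                    f"test FPKM {row.mean_fpkm_test:.2f}, "
                    f"mean logFC {row.mean_logFC:.2f})"
                )
        else:
            lines.append("Deletion calls: none")
        lines.append("")
        if with_plots:
            try:
                _plot_contrast_tracks(cdir)
                lines.append(f"Track plots: see `{cdir.name}/tracks_*.png`")
                lines.append("")
            except Exception as exc:  # plotting must never sink a report
                logger.warning("plotting failed for %s: %s", cdir, exc)

    comp_path = run_dir / "homeology" / "compensation_summary.json"
    lines.append("## Compensation")
    lines.append("")
    if comp_path.exists():
        comp = json.loads(comp_path.read_text())
        if comp.get("available"):
            lines.append(
                f"- 1:1 pairs with host gene in deletion: {comp['n_pairs_in_deletion']}"
            )
            lines.append(
                f"- partially compensated (ratio >= threshold): "
                f"{comp['n_partial_compensation']} of {comp['n_ratio_defined']} defined"
            )
            lines.append(
                f"- donor copies highly transcribed: {comp['n_donor_highly_transcribed']}"
            )
        else:
            lines.append("section absent (no deletion call or no 1:1 pairs)")
    else:
        lines.append("section absent (homeology stage did not run)")
    lines.append("")

    edir = run_dir / "enrichment"
    lines.append("## Enrichment")
    lines.append("")
    for direction in ("up", "down"):
        path = edir / f"{direction}_enriched.tsv"
        if path.exists():
            table = pd.read_csv(path, sep="\t") if path.stat().st_size > 1 else pd.DataFrame()
            lines.append(f"- {direction}: {len(table)} enriched terms")
        else:
            lines.append(f"- {direction}: section absent")

    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out


def _plot_contrast_tracks(cdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tracks = sorted(cdir.glob("track_*_R_Down_Trans.bedgraph"))
    segments = pd.read_csv(cdir / "segments.tsv", sep="\t")
    for track_path in tracks:
        chrom = track_path.name.split("_")[1]
        metrics = ["R_notDT_Trans", "R_Up_Trans", "R_Down_Trans", "mean_logFC"]
        fig, axes = plt.subplots(len(metrics), 1, figsize=(10, 8), sharex=True)
        for ax, metric in zip(axes, metrics):
            path = cdir / f"track_{chrom}_{metric}.bedgraph"
            data = pd.read_csv(
                path, sep="\t", skiprows=1, header=None,
                names=["chrom", "start", "end", "value"],
            )
            ax.plot(data["start"] / 1e6, data["value"], lw=0.8)
            segs = segments[
                (segments["chromosome"] == chrom) & (segments["metric"] == metric)
            ]
            for row in segs.itertuples(index=False):
                ax.hlines(
                    row.mean, row.start / 1e6, row.end / 1e6,
                    color="crimson", lw=2,
                )
            ax.set_ylabel(metric, fontsize=7)
        axes[-1].set_xlabel("position (Mbp)")
        fig.suptitle(f"{cdir.name} {chrom}")
        fig.tight_layout()
        fig.savefig(cdir / f"tracks_{chrom}.png", dpi=110)
        plt.close(fig)
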