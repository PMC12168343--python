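"""End-to-end orchestration of the two-condition ChIP + expression analysis.

``make_fixture`` writes a fully synthetic dataset (genome, genes, IP/input
reads for two conditions, spike-in-bearing counts, target gene list,
polysome traces) with a ground-truth JSON sidecar.  ``run_pipeline``
consumes such a dataset: per-condition peak calling, condition-1 gene
association, difference track, DE-stratified profiles, the target-set
resampling test, spike-in normalisation/classification and category
enrichment, all recorded in a manifest with parameters, seeds and input
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GenomeSpec
from .expression import (
    EnrichmentParams,
    ExpressionTable,
    category_enrichment,
    classify_de,
    spikein_normalize,
)
from .genomic_io import (
    read_gene_sets,
    read_genes,
    read_genome,
    read_reads,
    write_genes,
    write_genome,
    write_reads,
    write_track,
)
from .peakcall import PeakCallParams, call_peaks
from .profiles import (
    ProfileParams,
    associate_genes,
    differential_track,
    metagene,
    polysome_ratio,
    tss_profile,
)
from .resampling import ResamplingParams, resample_null
from .simulate import (
    ChipSimParams,
    ExprSimParams,
    make_genes,
    simulate_chip,
    simulate_expression,
    simulate_polysome_trace,
)

__all__ = ["PipelineConfig", "make_fixture", "run_pipeline", "FIXTURE_SCALES"]


@dataclass
class PipelineConfig:
    """Paths and parameter blocks for one pipeline run.

    Condition 1 is the reference (nutrient-replete-like) condition; gene
    association and heat-map ordering are defined from its peak calls.
    """

    genome: str
    genes: str
    ip_cond1: str
    input_cond1: str
    ip_cond2: str
    input_cond2: str
    counts: str
    target_genes: str
    categories: str | None = None
    out_dir: str = "pipeline_out"
    seed: int = 0
    peakcall: PeakCallParams = field(default_factory=PeakCallParams)
    profile: ProfileParams = field(default_factory=ProfileParams)
    resampling: ResamplingParams = field(default_factory=ResamplingParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    fold_cutoff: float = 2.0
    min_expr: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, klass in (
            ("peakcall", PeakCallParams),
            ("profile", ProfileParams),
            ("resampling", ResamplingParams),
            ("enrichment", EnrichmentParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("genome", "genes", "ip_cond1", "input_cond1",
                     "ip_cond2", "input_cond2", "counts", "target_genes"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.categories is not None and not Path(self.categories).exists():
            raise FileNotFoundError(f"categories: {self.categories} does not exist")


FIXTURE_SCALES = {
    # chrom_len, n_genes, n_reads, n_target, min_len, max_len
    "tiny": dict(chrom_len=500_000, n_genes=20, n_reads=20_000, n_target=5,
                 min_len=2_000, max_len=10_000),
    "demo": dict(chrom_len=5_000_000, n_genes=200, n_reads=500_000, n_target=50,
                 min_len=2_000, max_len=10_000),
}

# The demo enrichment structure: a gene-body mark at 8x in condition 1,
# reduced by 40% at every gene in condition 2, plus (for the promoter-factor
# read sets) a 4x promoter gain restricted to the target genes in condition 2.
BODY_ENRICH_COND1 = 8.0
BODY_REDUCTION = 0.4
PROMOTER_GAIN = 4.0


def make_fixture(out_dir, scale: str = "tiny", seed: int = 0) -> dict:
    """Write a synthetic two-condition dataset plus ground truth to disk.

    Returns the ground-truth dictionary (also stored as truth.json).
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(FIXTURE_SCALES)}")
    cfg = FIXTURE_SCALES[scale]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    genome = GenomeSpec(("chr1",), (cfg["chrom_len"],))
    genes = make_genes(genome, cfg["n_genes"], cfg["min_len"], cfg["max_len"],
                       seed=seed)
    write_genome(genome, out / "genome.json")
    write_genes(genes, out / "genes.bed12")

    gene_ids = [g.gene_id for g in genes]
    target = sorted(rng.choice(gene_ids, size=cfg["n_target"], replace=False))
    (out / "target_genes.txt").write_text("\n".join(target) + "\n")

    body1 = {gid: BODY_ENRICH_COND1 for gid in gene_ids}
    body2 = {gid: BODY_ENRICH_COND1 * (1 - BODY_REDUCTION) for gid in gene_ids}
    promoter2 = {gid: PROMOTER_GAIN for gid in target}

    specs = {
        "ip_cond1": ChipSimParams(body_enrichment=body1, n_reads=cfg["n_reads"],
                                  seed=seed * 10 + 1),
        "ip_cond2": ChipSimParams(body_enrichment=body2,
                                  promoter_enrichment=promoter2,
                                  n_reads=cfg["n_reads"], seed=seed * 10 + 3),
    }
    specs["input_cond1"] = specs["ip_cond1"].as_input()
    specs["input_cond2"] = specs["ip_cond2"].as_input()
    for name, sp in specs.items():
        write_reads(simulate_chip(genome, genes, sp), out / f"{name}.bed")

    log2fc = rng.choice([-2.0, 0.0, 2.0], size=len(genes), p=(0.25, 0.5, 0.25))
    expr = simulate_expression(
        ExprSimParams(
            n_genes=len(genes),
            n_spikeins=10,
            base_mean=200.0,
            fold_changes=2.0 ** log2fc,
            library_scale=(1.0, 2.0),
            seed=seed * 10 + 5,
        )
    )
    expr.to_csv(out / "counts.tsv", sep="\t")

    categories = {"target_like": target,
                  "other": [gid for gid in gene_ids if gid not in target]}
    with open(out / "categories.tsv", "w") as fh:
        for cat, members in categories.items():
            for gid in members:
                fh.write(f"{cat}\t{gid}\n")

    for name, (mono, poly) in {
        "polysome_plusAA": (1.0, 3.0),
        "polysome_minusAA": (1.0, 1.2),
        "polysome_readd": (1.0, 2.4),
    }.items():
        tr = simulate_polysome_trace(mono, poly, seed=seed * 10 + 7)
        pd.DataFrame({"position": np.arange(len(tr.absorbance)) * tr.dx,
                      "absorbance": tr.absorbance}).to_csv(
            out / f"{name}.tsv", sep="\t", index=False)

    truth = {
        "scale": scale,
        "seed": seed,
        "genome": genome.sizes,
        "n_genes": len(genes),
        "target_genes": list(target),
        "body_enrichment_cond1": BODY_ENRICH_COND1,
        "body_enrichment_cond2": BODY_ENRICH_COND1 * (1 - BODY_REDUCTION),
        "promoter_gain_cond2_targets": PROMOTER_GAIN,
        "n_reads": cfg["n_reads"],
        "log2_fold_changes": {gid: float(v) for gid, v in zip(gene_ids, log2fc)},
        "library_scale": [1.0, 2.0],
        "polysome_true_ratios": {"polysome_plusAA": 3.0,
                                 "polysome_minusAA": 1.2,
                                 "polysome_readd": 2.4},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _asdict(params) -> dict:
    d = dataclasses.asdict(params)
    return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in d.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full two-condition analysis; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    try:
        genome = read_genome(config.genome)
        genes = read_genes(config.genes)
        gene_by_id = {g.gene_id: g for g in genes}
        target_ids = [
            l.strip() for l in Path(config.target_genes).read_text().splitlines()
            if l.strip()
        ]

        results: dict = {}
        tracks = {}
        peaks_by_cond = {}
        for cond in ("cond1", "cond2"):
            stage = f"peakcall_{cond}"
            ip = read_reads(getattr(config, f"ip_{cond}"), genome=genome)
            inp = read_reads(getattr(config, f"input_{cond}"), genome=genome)
            peaks, ip_track, in_track, sig = call_peaks(
                ip, inp, genome, config.peakcall
            )
            peaks_by_cond[cond] = peaks
            tracks[cond] = ip_track
            with open(out / f"peaks_{cond}.bed", "w") as fh:
                for p in peaks:
                    score = -np.log10(max(p.min_p, 1e-300))
                    fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak\t{score:.3f}\t.\n")
            write_track(ip_track, out / f"ip_{cond}.bedgraph")
            results[f"n_peaks_{cond}"] = len(peaks)

        stage = "associate_genes"
        associated = sorted(
            associate_genes(peaks_by_cond["cond1"], genes, config.profile)
        )
        (out / "associated_genes_cond1.txt").write_text(
            "\n".join(associated) + "\n"
        )
        results["n_associated_cond1"] = len(associated)

        stage = "difference_track"
        diff = differential_track(tracks["cond2"], tracks["cond1"])
        write_track(diff, out / "difference_cond2_minus_cond1.bedgraph")

        stage = "expression"
        frame = pd.read_csv(config.counts, sep="\t", index_col=0)
        frame["is_spikein"] = frame["is_spikein"].astype(bool)
        table = spikein_normalize(ExpressionTable.from_frame(frame))
        labels = classify_de(table, config.fold_cutoff, config.min_expr)
        table.adjusted.to_csv(out / "adjusted_rpkm.tsv", sep="\t")
        labels.to_frame().to_csv(out / "de_labels.tsv", sep="\t")
        results["de_counts"] = labels.value_counts().to_dict()

        stage = "stratified_profiles"
        strata = {}
        for label in ("up", "down", "unchanged"):
            ids = [gid for gid in labels.index[labels == label]
                   if gid in gene_by_id]
            if not ids:
                continue
            sub = [gene_by_id[g] for g in ids]
            pos, prof = tss_profile(diff, sub, config.profile)
            mpos, mprof, skipped = metagene(diff, sub, config.profile)
            pd.DataFrame({"position": pos, "mean_diff": prof}).to_csv(
                out / f"tss_profile_{label}.tsv", sep="\t", index=False)
            pd.DataFrame({"position": mpos, "mean_diff": mprof}).to_csv(
                out / f"metagene_{label}.tsv", sep="\t", index=False)
            strata[label] = {"n_genes": len(sub),
                             "mean_tss_diff": float(prof.mean()),
                             "metagene_skipped": skipped}
        results["strata"] = strata

        stage = "resampling"
        target = [gene_by_id[g] for g in target_ids if g in gene_by_id]
        universe = [g for g in genes if g.gene_id not in set(target_ids)]
        rr = resample_null(diff, target, universe, config.resampling)
        pd.DataFrame(
            {
                "position": rr.positions,
                "observed": rr.observed_profile,
                "null_mean": rr.null_mean_profile,
                "null_min": rr.null_min_profile,
                "null_max": rr.null_max_profile,
            }
        ).to_csv(out / "resampling_profiles.tsv", sep="\t", index=False)
        results["resampling"] = {
            "observed_summary": rr.observed_summary,
            "null_max_summary": float(rr.null_summaries.max()),
            "empirical_p": rr.empirical_p,
            "n_trials": rr.n_trials,
        }

        if config.categories is not None:
            stage = "category_enrichment"
            cats = read_gene_sets(config.categories)
            gene_universe = [g.gene_id for g in genes]
            enrich = {}
            for label in ("up", "down"):
                sel = set(labels.index[labels == label]) & set(gene_universe)
                res = category_enrichment(sel, cats, gene_universe,
                                          config.enrichment)
                res.to_csv(out / f"enrichment_{label}.tsv", sep="\t",
                           index=False)
                enrich[label] = res["category"][res["significant"]].tolist()
            results["significant_categories"] = enrich

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                "peakcall": _asdict(config.peakcall),
                "profile": _asdict(config.profile),
                "resampling": _asdict(config.resampling),
                "enrichment": _asdict(config.enrichment),
                "fold_cutoff": config.fold_cutoff,
                "min_expr": config.min_expr,
            },
            "inputs": {
                name: {"path": str(getattr(config, name)),
                       "sha256": _sha256(getattr(config, name))}
                for name in ("genome", "genes", "ip_cond1", "input_cond1",
                             "ip_cond2", "input_cond2", "counts",
                             "target_genes")
            },
            "results": results,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def polysome_ratios_from_fixture(fixture_dir) -> dict[str, float]:
    """AUC polysome/monosome ratios for every trace TSV in a fixture."""
    fixture_dir = Path(fixture_dir)
    ratios = {}
    for path in sorted(fixture_dir.glob("polysome_*.tsv")):
        df = pd.read_csv(path, sep="\t")
        y = df["absorbance"].to_numpy()
        n = len(y)
        tr = simulate_polysome_trace(1.0, 1.0, n_points=n)  # region layout only
        ratios[path.stem] = polysome_ratio(
            y, tr.mono_region, tr.poly_region, dx=tr.dx
        )
    return ratios
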