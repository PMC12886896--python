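"""Pipeline orchestration: configuration, stages, demo scenario, manifest.

``run_pipeline`` executes tracks -> enrich -> windows -> smallrna -> de ->
integrate on the files named in a YAML config, skipping stages whose
inputs are absent, and writes a manifest with content hashes so identical
config + seed reruns are verifiable byte-for-byte.  ``make_demo`` emits a
complete synthetic scenario with recorded ground truth plus a ready-to-run
config.

Result tables are serialized with 6 significant digits — a presentation
choice for hash-stable text outputs; internal computation is full
precision.  bedGraph tracks use exact (repr) floats so track round trips
are lossless.
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

from germ_epimem import metagene, nbstats, smallrna, synth, tracks, windows
from germ_epimem.core_io import (
    CountMatrix,
    Genome,
    GenomeAnnotation,
    read_counts_tsv,
    read_fasta,
    read_fastq,
    read_gff3,
    read_reads_bed,
    write_bedgraph,
    write_counts_tsv,
    write_fasta,
    write_gff3,
    write_fastq,
    write_reads_bed,
)
from germ_epimem.integrate import build_crosstab, overlap_sets

log = logging.getLogger("germ_epimem")

FLOAT_FORMAT = "%.6g"

DEFAULT_PARAMS = {
    "bin_size": 10,
    "fragment_length": 200,
    "pseudocount": 1.0,
    "halfwidth": 500,
    "fraction": 0.8,
    "upstream": 1000,
    "downstream": 1000,
    "window_size": 200,
    "step": 10,
    "window_max_fdr": 0.05,
    "sr_min_fold_change": 2.0,
    "sr_max_fdr": 0.05,
    "mrna_min_fold_change": 1.0,
    "mrna_max_fdr": 0.01,
}

_PARAM_RANGES = {
    "bin_size": (1, 10_000),
    "fragment_length": (1, 100_000),
    "pseudocount": (1e-9, 1e6),
    "halfwidth": (10, 1_000_000),
    "fraction": (1e-9, 1.0),
    "window_size": (1, 1_000_000),
    "step": (1, 1_000_000),
    "window_max_fdr": (0.0, 1.0),
    "sr_min_fold_change": (1.0, 1e6),
    "sr_max_fdr": (0.0, 1.0),
    "mrna_min_fold_change": (1.0, 1e6),
    "mrna_max_fdr": (0.0, 1.0),
}


@dataclass
class SampleSpec:
    path: str
    genotype: str
    replicate: int
    role: str = ""  # IP/input for ChIP; empty for small RNA


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    genome: str
    annotation: str
    chip_samples: list[SampleSpec] = field(default_factory=list)
    smallrna_samples: list[SampleSpec] = field(default_factory=list)
    mrna_counts: str | None = None
    mrna_condition: dict[str, str] | None = None
    reference_lists: dict[str, str] = field(default_factory=dict)
    truth: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        base = Path(path).parent

        def resolve(p):
            return str((base / p) if not Path(p).is_absolute() else Path(p))

        chip = [
            SampleSpec(resolve(s["path"]), s["genotype"], int(s["replicate"]), s["role"])
            for s in raw.get("chip_samples", [])
        ]
        sr = [
            SampleSpec(resolve(s["path"]), s["genotype"], int(s["replicate"]))
            for s in raw.get("smallrna_samples", [])
        ]
        refs = {k: resolve(v) for k, v in raw.get("reference_lists", {}).items()}
        return cls(
            seed=int(raw["seed"]),
            output_dir=resolve(raw["output_dir"]),
            genome=resolve(raw["genome"]),
            annotation=resolve(raw["annotation"]),
            chip_samples=chip,
            smallrna_samples=sr,
            mrna_counts=resolve(raw["mrna_counts"]) if raw.get("mrna_counts") else None,
            mrna_condition=raw.get("mrna_condition"),
            reference_lists=refs,
            truth=resolve(raw["truth"]) if raw.get("truth") else None,
            params=raw.get("params", {}),
        )

    def validate(self) -> None:
        missing = []
        for p in [self.genome, self.annotation, self.mrna_counts, self.truth]:
            if p is not None and not Path(p).exists():
                missing.append(p)
        for s in self.chip_samples + self.smallrna_samples:
            if not Path(s.path).exists():
                missing.append(s.path)
        for p in self.reference_lists.values():
            if not Path(p).exists():
                missing.append(p)
        if missing:
            raise FileNotFoundError(f"config references missing paths: {missing}")
        for key, (lo, hi) in _PARAM_RANGES.items():
            value = self.params[key]
            if not (lo <= value <= hi):
                raise ValueError(f"parameter {key}={value} outside [{lo}, {hi}]")


def _write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def _check_chrom_names(genome: Genome, annotation: GenomeAnnotation) -> None:
    genome_chroms = set(genome.lengths)
    ann_chroms = {g.interval.chrom for g in annotation}
    if not ann_chroms <= genome_chroms:
        raise ValueError(
            "annotation chromosomes absent from genome: "
            f"{sorted(ann_chroms - genome_chroms)} (genome has {sorted(genome_chroms)})"
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_tracks(genome, chip_samples, params, outdir: Path):
    """Per-genotype CPM / enrichment / fold-change tracks from ChIP BEDs."""
    by_group: dict[tuple[str, str], list] = {}
    for sample in chip_samples:
        rs = read_reads_bed(sample.path)
        cov = tracks.bin_coverage(
            rs, genome, bin_size=params["bin_size"], fragment_length=params["fragment_length"]
        )
        cpm = tracks.cpm_normalize(cov, rs.library_size)
        by_group.setdefault((sample.genotype, sample.role), []).append(cpm)
    enrich = {}
    for genotype in ("wild_type", "mutant"):
        ip = by_group.get((genotype, "IP"))
        inp = by_group.get((genotype, "input"))
        if not ip or not inp:
            continue
        enr = tracks.enrichment_ratio(
            tracks.mean_tracks(ip),
            tracks.mean_tracks(inp),
            pseudocount=params["pseudocount"],
        )
        enrich[genotype] = enr
        write_bedgraph(enr, outdir / f"enrichment_{genotype}.bedgraph")
    fc = None
    if "wild_type" in enrich and "mutant" in enrich:
        fc = tracks.fold_change_track(enrich["mutant"], enrich["wild_type"])
        write_bedgraph(fc, outdir / "fold_change_mut_vs_wt.bedgraph")
    return enrich, fc


def stage_enrich(enrich, annotation, params, outdir: Path):
    """TSS score table, cumulative-80% selection and metagene profiles."""
    table = metagene.build_score_table(
        enrich["wild_type"], enrich["mutant"], annotation, halfwidth=params["halfwidth"]
    )
    selected = metagene.select_enriched_genes(table, fraction=params["fraction"])
    _write_table(table, outdir / "tss_scores.tsv")
    (outdir / "enriched_genes.txt").write_text("".join(f"{g}\n" for g in selected))
    profiles = {}
    for genotype, track in enrich.items():
        mat = metagene.metagene_matrix(
            track, annotation, upstream=params["upstream"], downstream=params["downstream"]
        )
        profiles[genotype] = metagene.average_profile(mat)
        heat = pd.DataFrame(mat.values, index=mat.gene_ids, columns=mat.offsets)
        _write_table(heat, outdir / f"metagene_matrix_{genotype}.tsv", index_label="gene_id")
    prof = pd.DataFrame(profiles, index=mat.offsets)
    prof.index.name = "offset"
    _write_table(prof, outdir / "metagene_profile.tsv")
    stats = metagene.compare_scores(table.loc[selected] if selected else table)
    pd.Series(stats).to_json(outdir / "tss_score_test.json")
    return table, selected


def stage_windows(genome, chip_samples, params, outdir: Path):
    """Sliding-window differential binding over the IP libraries."""
    grid = windows.make_windows(
        genome, window_size=params["window_size"], step=params["step"]
    )
    read_sets, condition = {}, {}
    for sample in chip_samples:
        if sample.role != "IP":
            continue
        name = f"{sample.genotype}_{sample.replicate}"
        read_sets[name] = read_reads_bed(sample.path)
        condition[name] = sample.genotype
    if len(set(condition.values())) != 2:
        return None, set()
    counts = windows.window_counts(
        grid, read_sets, fragment_length=params["fragment_length"], condition=condition
    )
    res = windows.window_differential(counts, group_order=("wild_type", "mutant"))
    _write_table(res, outdir / "window_differential.tsv")
    sig = res[res["q_value"] <= params["window_max_fdr"]]
    with open(outdir / "significant_windows.bed", "w") as handle:
        for wid, row in sig.iterrows():
            iv = windows._parse_window_id(wid)
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{wid}\t"
                f"{row['log2fc']:.6g}\t{row['q_value']:.6g}\n"
            )
    return res, list(sig.index)


def stage_smallrna(genome, annotation, sr_samples, seed, outdir: Path):
    """Filter/map/count each small-RNA library into one count matrix."""
    index = smallrna.ExactMatchIndex(genome)
    columns, condition, reports = {}, {}, []
    for sample in sr_samples:
        name = f"{sample.genotype}_{sample.replicate}"
        reads = read_fastq(sample.path)
        kept, report = smallrna.filter_22g(reads)
        alignments = smallrna.map_exact(kept, genome, seed=seed, index=index)
        columns[name] = smallrna.count_per_gene(alignments, annotation)
        condition[name] = sample.genotype
        rep = report.as_frame()
        rep.insert(0, "sample", name)
        rep["n_mapped"] = len(alignments)
        reports.append(rep)
    pd.concat(reports).to_csv(outdir / "sr22g_filter_report.tsv", sep="\t", index=False)
    matrix = CountMatrix(pd.DataFrame(columns), condition=condition)
    write_counts_tsv(matrix, outdir / "sr22g_counts.tsv")
    return matrix


def stage_de(matrix: CountMatrix, min_fold_change, max_fdr, outdir: Path, label: str):
    """Shared NB differential stage: results TSV + up/down call lists."""
    factors = nbstats.size_factors(matrix)
    dispersions = nbstats.estimate_dispersion(matrix, factors)
    res = nbstats.add_q_values(
        nbstats.nb_wald_test(
            matrix, factors, dispersions, group_order=("wild_type", "mutant")
        )
    )
    calls = nbstats.call_de(res, min_fold_change=min_fold_change, max_fdr=max_fdr)
    _write_table(res, outdir / f"{label}_de_results.tsv")
    (outdir / f"{label}_up.txt").write_text("".join(f"{g}\n" for g in sorted(calls.up)))
    (outdir / f"{label}_down.txt").write_text(
        "".join(f"{g}\n" for g in sorted(calls.down))
    )
    return res, calls


def stage_integrate(selected, calls22g, callsmrna, universe, reference_lists, outdir: Path):
    """Crosstab + pairwise overlaps of the integrated gene sets."""
    crosstab = build_crosstab(
        selected,
        calls22g if calls22g is not None else nbstats.DECallSet(set(), set()),
        callsmrna if callsmrna is not None else nbstats.DECallSet(set(), set()),
    )
    pd.Series(crosstab.as_dict()).to_frame("count").to_csv(
        outdir / "crosstab.tsv", sep="\t", index_label="category"
    )
    sets = {"enriched": set(selected)}
    if calls22g is not None:
        sets["sr22g_up"], sets["sr22g_down"] = calls22g.up, calls22g.down
    if callsmrna is not None:
        sets["mrna_up"], sets["mrna_down"] = callsmrna.up, callsmrna.down
    for name, path in reference_lists.items():
        sets[name] = {
            line.strip() for line in Path(path).read_text().splitlines() if line.strip()
        } & universe
    rows = []
    names = sorted(sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            row = overlap_sets(sets[a], sets[b], universe)
            rows.append({"set_a": a, "set_b": b, **row})
    pd.DataFrame(rows).to_csv(
        outdir / "pairwise_overlaps.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    venn = {name: sorted(s) for name, s in sets.items()}
    (outdir / "venn_sets.json").write_text(json.dumps(venn, indent=1))
    return crosstab


# ---------------------------------------------------------------------------
# run + manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages whose inputs are present; return the manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage_names: list[str] = []
    current = "load"
    try:
        t0 = time.time()
        genome = read_fasta(config.genome)
        annotation = read_gff3(config.annotation)
        _check_chrom_names(genome, annotation)
        log.info("loaded genome (%d chrom) and %d genes in %.1fs",
                 len(genome.lengths), len(annotation), time.time() - t0)

        enrich = {}
        selected: list[str] = []
        calls22g = callsmrna = None
        if config.chip_samples:
            current = "tracks"
            t = time.time()
            enrich, _ = stage_tracks(genome, config.chip_samples, config.params, outdir)
            stage_names.append("tracks")
            log.info("tracks done in %.1fs", time.time() - t)
            if len(enrich) == 2:
                current = "enrich"
                t = time.time()
                _, selected = stage_enrich(enrich, annotation, config.params, outdir)
                stage_names.append("enrich")
                log.info("enrich done in %.1fs (%d genes selected)", time.time() - t, len(selected))
                current = "windows"
                t = time.time()
                stage_windows(genome, config.chip_samples, config.params, outdir)
                stage_names.append("windows")
                log.info("windows done in %.1fs", time.time() - t)
        if config.smallrna_samples:
            current = "smallrna"
            t = time.time()
            matrix = stage_smallrna(
                genome, annotation, config.smallrna_samples, config.seed, outdir
            )
            stage_names.append("smallrna")
            log.info("smallrna done in %.1fs", time.time() - t)
            if matrix.condition and len(set(matrix.condition.values())) == 2:
                current = "de"
                _, calls22g = stage_de(
                    matrix,
                    config.params["sr_min_fold_change"],
                    config.params["sr_max_fdr"],
                    outdir,
                    "sr22g",
                )
                stage_names.append("de_sr22g")
        if config.mrna_counts:
            current = "de_mrna"
            mrna = read_counts_tsv(config.mrna_counts, condition=config.mrna_condition)
            if mrna.condition is None:
                # infer genotype from "<genotype>_<replicate>" sample names
                mrna = read_counts_tsv(
                    config.mrna_counts,
                    condition={s: s.rsplit("_", 1)[0] for s in mrna.sample_ids},
                )
            _, callsmrna = stage_de(
                mrna,
                config.params["mrna_min_fold_change"],
                config.params["mrna_max_fdr"],
                outdir,
                "mrna",
            )
            stage_names.append("de_mrna")
        if selected:
            current = "integrate"
            universe = set(annotation.gene_ids)
            stage_integrate(
                selected, calls22g, callsmrna, universe, config.reference_lists, outdir
            )
            stage_names.append("integrate")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {current}: {exc}\n")
        log.removeHandler(handler)
        raise RuntimeError(f"pipeline failed at stage {current}: {exc}") from exc

    current = "manifest"
    files = sorted(
        p for p in outdir.rglob("*")
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    )
    manifest = {
        "stages": stage_names,
        "seed": config.seed,
        "params": config.params,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.removeHandler(handler)
    return manifest


# ---------------------------------------------------------------------------
# demo scenario
# ---------------------------------------------------------------------------

DEMO = {
    "n_chrom": 2,
    "chrom_length": 500_000,
    "n_genes": 300,
    "gene_length": 500,
    "spacing": 2000,
    "n_enriched": 30,
    "enrichment_multiplier": 3.0,
    "n_chip_replicates": 2,
    "n_sr_replicates": 4,
    "sr_n_reads": 50_000,
    "sr_frac_valid": 0.8,
    "sr_log2fc": 2.0,
    "n_sr_up": 15,
    "n_sr_down": 15,
    "n_sr_up_in_enriched": 10,
    "n_sr_down_in_enriched": 10,
    "mrna_base_mean": 200.0,
    "mrna_dispersion": 0.05,
    "mrna_log2fc": 2.0,
    "n_mrna_up_in_enriched": 5,
    "n_mrna_down_in_enriched": 1,
    "n_mrna_de_other": 10,
}


def make_demo(output_dir, seed: int) -> Path:
    """Write a complete synthetic scenario plus a ready-to-run config.

    The scenario: a 2 x 0.5 Mb genome with 300 genes; 30 genes planted
    with a 3x mutant H3K4me3 gain (2 IP + 2 input ChIP replicates per
    genotype); 15 genes with 22G up and 15 with 22G down at |log2fc| = 2
    (10 of each inside the enriched set; 4 small-RNA replicates per
    genotype); and an mRNA count matrix with a handful of planted changes,
    12-up-to-1-down biased inside the enriched set.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = DEMO
    genome = synth.simulate_genome(d["n_chrom"], d["chrom_length"], seed)
    annotation = synth.simulate_annotation(
        genome, d["n_genes"], d["gene_length"], d["spacing"], seed
    )
    rng = synth._rng_for(seed, "demo_truth")
    gene_ids = annotation.gene_ids
    enriched = sorted(rng.choice(gene_ids, d["n_enriched"], replace=False))
    non_enriched = [g for g in gene_ids if g not in set(enriched)]
    enr_pool = list(rng.permutation(enriched))
    other_pool = list(rng.permutation(non_enriched))
    sr_up = sorted(
        enr_pool[: d["n_sr_up_in_enriched"]]
        + other_pool[: d["n_sr_up"] - d["n_sr_up_in_enriched"]]
    )
    sr_down = sorted(
        enr_pool[d["n_sr_up_in_enriched"] : d["n_sr_up_in_enriched"] + d["n_sr_down_in_enriched"]]
        + other_pool[
            d["n_sr_up"] - d["n_sr_up_in_enriched"] : d["n_sr_up"]
            - d["n_sr_up_in_enriched"]
            + d["n_sr_down"]
            - d["n_sr_down_in_enriched"]
        ]
    )
    used = d["n_sr_up_in_enriched"] + d["n_sr_down_in_enriched"]
    mrna_up = enr_pool[used : used + d["n_mrna_up_in_enriched"]]
    mrna_down = enr_pool[
        used + d["n_mrna_up_in_enriched"] : used
        + d["n_mrna_up_in_enriched"]
        + d["n_mrna_down_in_enriched"]
    ]
    offset = d["n_sr_up"] - d["n_sr_up_in_enriched"] + d["n_sr_down"] - d["n_sr_down_in_enriched"]
    mrna_other = other_pool[offset : offset + d["n_mrna_de_other"]]

    truth = synth.SyntheticTruth(
        enriched_genes={g: d["enrichment_multiplier"] for g in enriched},
        sr_up_genes={g: d["sr_log2fc"] for g in sr_up},
        sr_down_genes={g: -d["sr_log2fc"] for g in sr_down},
        de_genes={
            **{g: d["mrna_log2fc"] for g in mrna_up},
            **{g: -d["mrna_log2fc"] for g in mrna_down},
            **{g: d["mrna_log2fc"] for g in mrna_other},
        },
        params={"seed": seed, **d},
    )

    write_fasta(genome, outdir / "genome.fa")
    write_gff3(annotation, outdir / "annotation.gff3")
    truth.save_tsv(outdir / "truth.tsv")

    chip_params = synth.ChipSimParams(seed=seed)
    chip_entries = []
    for genotype in ("wild_type", "mutant"):
        for role in ("IP", "input"):
            for rep in range(1, d["n_chip_replicates"] + 1):
                rs = synth.simulate_chip_library(
                    annotation, truth, chip_params, genome, genotype, role, rep
                )
                name = f"chip_{genotype}_{role}_{rep}.bed"
                write_reads_bed(rs, outdir / name)
                chip_entries.append(
                    {"path": name, "genotype": genotype, "role": role, "replicate": rep}
                )
    sr_entries = []
    for genotype in ("wild_type", "mutant"):
        for rep in range(1, d["n_sr_replicates"] + 1):
            reads, _ = synth.simulate_smallrna_fastq(
                genome,
                annotation,
                truth,
                n_reads=d["sr_n_reads"],
                frac_valid=d["sr_frac_valid"],
                seed=seed * 1000 + rep,
                genotype=genotype,
                library_label=f"{genotype}_{rep}",
            )
            name = f"sr_{genotype}_{rep}.fastq"
            write_fastq(reads, outdir / name)
            sr_entries.append({"path": name, "genotype": genotype, "replicate": rep})
    # bookkept valid counts per library, for exactness tests
    pd.DataFrame(
        [
            {"library": lib, "n_valid": rec["n_valid"]}
            for lib, rec in truth.sr_valid_counts.items()
        ]
    ).to_csv(outdir / "sr_valid_counts.tsv", sep="\t", index=False)

    mrna = _demo_mrna_counts(gene_ids, truth, d, seed)
    write_counts_tsv(mrna, outdir / "mrna_counts.tsv")

    config = {
        "seed": seed,
        "output_dir": "results",
        "genome": "genome.fa",
        "annotation": "annotation.gff3",
        "chip_samples": chip_entries,
        "smallrna_samples": sr_entries,
        "mrna_counts": "mrna_counts.tsv",
        "truth": "truth.tsv",
        "params": {},
    }
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path


def _demo_mrna_counts(gene_ids, truth, d, seed) -> CountMatrix:
    rng = synth._rng_for(seed, "demo_mrna")
    reps = 4
    base = rng.lognormal(np.log(d["mrna_base_mean"]), 0.6, size=len(gene_ids))
    mu = np.tile(base[:, None], (1, 2 * reps))
    for i, gid in enumerate(gene_ids):
        if gid in truth.de_genes:
            mu[i, reps:] *= 2.0 ** truth.de_genes[gid]
    r = 1.0 / d["mrna_dispersion"]
    counts = rng.negative_binomial(r, r / (r + mu))
    samples = [f"{g}_{i + 1}" for g in ("wild_type", "mutant") for i in range(reps)]
    return CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=samples),
        condition={s: s.rsplit("_", 1)[0] for s in samples},
    )
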