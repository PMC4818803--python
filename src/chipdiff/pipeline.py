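"""End-to-end pipeline: simulate/load -> peaks -> differential -> genes -> enrichment.

A run is driven by a validated configuration (YAML file or plain dict) and
writes all outputs under a run directory together with the resolved
configuration, a plain-text log, a machine-readable JSON summary and a
manifest of SHA-256 file hashes.  Identical configuration and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from chipdiff import diffmod, enrich, genomic, normalize, peakcall, profiles, promoters, simulate

__all__ = ["ConfigError", "PipelineError", "load_config", "run_pipeline", "RunResult"]

FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad type or value)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_CONFIG: Dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "chromosomes": {"chr1": 5_000_000, "chr2": 5_000_000},
        "n_genes": 1000,
        "frac_up": 0.10,
        "frac_down": 0.10,
        "frac_enriched": 0.60,
        "base_fold": 8.0,
        "fold_up": 4.0,
        "fold_down": 0.25,
        "tss_half_width": 500,
        "frag_min": 100,
        "frag_max": 300,
        "n_treated_chip": 230_000,
        "n_treated_input": 200_000,
        "n_control_chip": 250_000,
        "n_control_input": 380_000,
        "write_tags": True,
    },
    "inputs": {
        "treated_chip": None,
        "treated_input": None,
        "control_chip": None,
        "control_input": None,
        "genome": None,
        "genes": None,
        "terms": None,
        "truth": None,
    },
    "normalize": {"subsample_inputs": False},
    "peaks": {
        "window_size": 100,
        "alpha": 0.05,
        "fragment_length": 200,
        "merge_gap": None,
        "min_background_lambda": 0.1,
    },
    "diff": {"alpha": 0.05, "n_top": 2000, "pseudocount": 1.0},
    "promoter": {"window": 2000, "require_both": True},
    "enrich": {"method": "ease", "universe": "assigned"},
    "profile": {"flank": 2000, "bin_size": 50, "write_tracks": False},
}

_POSITIVE_INT_KEYS = {
    ("peaks", "window_size"),
    ("peaks", "fragment_length"),
    ("promoter", "window"),
    ("diff", "n_top"),
    ("profile", "flank"),
    ("profile", "bin_size"),
    ("simulate", "n_genes"),
    ("simulate", "tss_half_width"),
    ("simulate", "n_treated_chip"),
    ("simulate", "n_treated_input"),
    ("simulate", "n_control_chip"),
    ("simulate", "n_control_input"),
}
_UNIT_INTERVAL_KEYS = {("peaks", "alpha"), ("diff", "alpha")}


def _merge(defaults: Dict[str, Any], user: Dict[str, Any], path: str = "") -> Dict[str, Any]:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and key != "chromosomes":
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def _validate(cfg: Dict[str, Any]) -> None:
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed: expected an integer")
    for section, key in _POSITIVE_INT_KEYS:
        v = cfg[section][key]
        if not isinstance(v, int) or v <= 0:
            raise ConfigError(f"{section}.{key}: expected a positive integer, got {v!r}")
    for section, key in _UNIT_INTERVAL_KEYS:
        v = cfg[section][key]
        if not (isinstance(v, (int, float)) and 0 < v < 1):
            raise ConfigError(f"{section}.{key}: expected a value in (0, 1), got {v!r}")
    if cfg["enrich"]["method"] not in ("fisher", "ease"):
        raise ConfigError("enrich.method: expected 'fisher' or 'ease'")
    if cfg["enrich"]["universe"] not in ("assigned", "annotation"):
        raise ConfigError("enrich.universe: expected 'assigned' or 'annotation'")
    if cfg["profile"]["flank"] % cfg["profile"]["bin_size"] != 0:
        raise ConfigError("profile.flank must be a multiple of profile.bin_size")
    paths = cfg["inputs"]
    given = [k for k in ("treated_chip", "treated_input", "control_chip", "control_input") if paths[k]]
    if given and len(given) != 4:
        raise ConfigError(
            "inputs: either all four tag files or none must be given "
            f"(got only {given})"
        )
    if given and not paths["genome"]:
        raise ConfigError("inputs.genome is required when tag files are given")
    if given and not paths["genes"]:
        raise ConfigError("inputs.genes is required when tag files are given")


def load_config(path: Optional[str | Path] = None, overrides: Optional[Dict[str, Any]] = None) -> Dict[str, Any]:
    """Load and validate a YAML run configuration; unknown keys are rejected.

    An empty/missing file yields all defaults.  ``overrides`` (a nested dict)
    is merged on top of the file, useful for programmatic runs.
    """
    user: Dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration root must be a mapping")
        user = loaded
    cfg = _merge(DEFAULT_CONFIG, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    _validate(cfg)
    return cfg


@dataclass
class RunResult:
    outdir: Path
    summary: Dict[str, Any]
    gene_table: pd.DataFrame
    regions: List[diffmod.MatchedRegion]
    metrics: Optional[profiles.RecoveryMetrics] = None
    files: Dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _derived_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def _peaks_to_frame(peaks: List[peakcall.Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "tag_count": p.tag_count,
                "fold_vs_input": p.fold_vs_input,
                "best_pvalue": p.best_pvalue,
                "qvalue": p.qvalue,
            }
            for p in peaks
        ],
        columns=["chrom", "start", "end", "tag_count", "fold_vs_input", "best_pvalue", "qvalue"],
    )


def _regions_to_frame(regions: List[diffmod.MatchedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "in_control": int(r.in_control),
                "in_treated": int(r.in_treated),
                "count_control": r.count_control,
                "count_treated": r.count_treated,
                "fold_change": r.fold_change,
                "log2_fold": r.log2_fold,
                "pvalue": r.pvalue,
                "qvalue": r.qvalue,
                "direction": r.direction,
            }
            for r in regions
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "in_control",
            "in_treated",
            "count_control",
            "count_treated",
            "fold_change",
            "log2_fold",
            "pvalue",
            "qvalue",
            "direction",
        ],
    )


def run_pipeline(config: Dict[str, Any], outdir: str | Path) -> RunResult:
    """Execute the full analysis chain and write all outputs under ``outdir``."""
    cfg = _merge(DEFAULT_CONFIG, config)
    _validate(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: Dict[str, Path] = {}
    log_lines: List[str] = []

    def register(name: str, path: Path) -> Path:
        files[name] = path
        return path

    def log(msg: str) -> None:
        log_lines.append(msg)

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage '{name}': {exc}") from exc
                return False

        return _Stage()

    seed = cfg["seed"]
    simulate_mode = not cfg["inputs"]["treated_chip"]

    # -- stage: inputs ------------------------------------------------------
    truth = None
    terms = None
    with stage("inputs"):
        if simulate_mode:
            sim = cfg["simulate"]
            sim_config = simulate.SimulationConfig(
                genome=genomic.GenomeLayout(sim["chromosomes"]),
                n_genes=sim["n_genes"],
                frac_up=sim["frac_up"],
                frac_down=sim["frac_down"],
                frac_enriched=sim["frac_enriched"],
                base_fold=sim["base_fold"],
                fold_up=sim["fold_up"],
                fold_down=sim["fold_down"],
                tss_half_width=sim["tss_half_width"],
                frag_min=sim["frag_min"],
                frag_max=sim["frag_max"],
                n_treated_chip=sim["n_treated_chip"],
                n_treated_input=sim["n_treated_input"],
                n_control_chip=sim["n_control_chip"],
                n_control_input=sim["n_control_input"],
                seed=seed,
            )
            layout = sim_config.genome
            genes, truth = simulate.simulate_genes(sim_config)
            samples = simulate.simulate_tags(sim_config, genes, truth).as_dict()
            terms, _planted = simulate.simulate_term_annotation(sim_config, genes, truth)
            genomic.write_gene_annotation(genes, register("genes", outdir / "genes.tsv"))
            simulate.write_truth_tsv(truth, register("truth", outdir / "truth.tsv"))
            enrich.write_gmt(terms, register("terms", outdir / "terms.gmt"))
            genomic.write_genome_tsv(layout, register("genome", outdir / "genome.tsv"))
            if sim["write_tags"]:
                for name, tc in samples.items():
                    genomic.write_tags_bed(
                        tc, register(f"tags_{name}", outdir / f"tags_{name}.bed")
                    )
            log("mode: simulate")
        else:
            paths = cfg["inputs"]
            layout = genomic.read_genome_tsv(paths["genome"])
            genes = genomic.read_gene_annotation(paths["genes"])
            samples = {
                name: genomic.read_tags_bed(paths[name])
                for name in simulate.SAMPLE_NAMES
            }
            for tc in samples.values():
                tc.validate_against(layout)
            if paths["truth"]:
                truth = simulate.read_truth_tsv(paths["truth"])
            if paths["terms"]:
                terms = enrich.read_gmt(paths["terms"])
            log("mode: file inputs")
        for name in simulate.SAMPLE_NAMES:
            log(f"tags {name}: {samples[name].total_tags}")

    # -- stage: normalization -----------------------------------------------
    with stage("normalize"):
        sub_seed = _derived_seed(seed, 101)
        norm_control, norm_treated, depth_ratio = normalize.normalize_pair(
            samples["control_chip"], samples["treated_chip"], sub_seed
        )
        log(
            f"normalization: ChIP depth ratio {depth_ratio:.4f}, "
            f"subsample seed {sub_seed}, normalized depth "
            f"{norm_control.total_tags}"
        )
        if cfg["normalize"]["subsample_inputs"]:
            ni_c, ni_t, input_ratio = normalize.normalize_pair(
                samples["control_input"], samples["treated_input"], _derived_seed(seed, 102)
            )
            samples["control_input"], samples["treated_input"] = ni_c, ni_t
            log(f"normalization: input depth ratio {input_ratio:.4f} (subsampled)")

    # -- stage: peak calling ------------------------------------------------
    with stage("peakcall"):
        params = peakcall.PeakCallParams(
            window_size=cfg["peaks"]["window_size"],
            alpha=cfg["peaks"]["alpha"],
            fragment_length=cfg["peaks"]["fragment_length"],
            merge_gap=cfg["peaks"]["merge_gap"],
            min_background_lambda=cfg["peaks"]["min_background_lambda"],
        )
        log(
            f"peak calling: window {params.window_size} bp, "
            f"p-value threshold {params.alpha}, fragment {params.fragment_length} bp"
        )
        peaks = {}
        for cond, chip, inp in (
            ("control", "control_chip", "control_input"),
            ("treated", "treated_chip", "treated_input"),
        ):
            peaks[cond] = peakcall.call_peaks(samples[chip], samples[inp], layout, params)
            log(
                f"peaks {cond}: {len(peaks[cond])} "
                f"(chip/input depth ratio "
                f"{samples[chip].total_tags / samples[inp].total_tags:.3f})"
            )
            frame = _peaks_to_frame(peaks[cond])
            frame.to_csv(
                register(f"peaks_{cond}", outdir / f"peaks_{cond}.tsv"),
                sep="\t",
                index=False,
                float_format=FLOAT_FMT,
            )
            genomic.write_intervals_bed(
                [(p.interval, p.best_pvalue) for p in peaks[cond]],
                register(f"peaks_{cond}_bed", outdir / f"peaks_{cond}.bed"),
            )

    # -- stage: differential -------------------------------------------------
    with stage("diffmod"):
        regions = diffmod.match_peaks(peaks["control"], peaks["treated"])
        scored = diffmod.score_regions(
            regions,
            norm_control,
            norm_treated,
            fragment_length=cfg["peaks"]["fragment_length"],
            pseudocount=cfg["diff"]["pseudocount"],
        )
        log(f"matched regions: {len(scored)}")
        rframe = _regions_to_frame(scored)
        rframe.to_csv(
            register("regions", outdir / "regions.tsv"),
            sep="\t",
            index=False,
            float_format=FLOAT_FMT,
        )
        genomic.write_intervals_bed(
            [(r.interval, r.pvalue) for r in scored],
            register("regions_bed", outdir / "regions.bed"),
        )

    # -- stage: promoter annotation -------------------------------------------
    with stage("promoter_annot"):
        window = cfg["promoter"]["window"]
        require_both = cfg["promoter"]["require_both"]
        log(
            f"promoter annotation: TSS window {window} bp, "
            f"matched-in-both-conditions only: {require_both}"
        )
        # genes are qualified by matched peak regions; regions arising from a
        # peak in a single condition are selected by their own extreme counts,
        # which biases the differential test, so they are excluded by default
        qualifying = (
            [r for r in scored if r.in_control and r.in_treated]
            if require_both
            else scored
        )
        assignments = promoters.assign_regions_to_genes(qualifying, genes, window=window)
        gene_table = promoters.gene_level_table(assignments)
        gene_table.to_csv(
            register("gene_table", outdir / "gene_table.tsv"),
            sep="\t",
            index=False,
            float_format=FLOAT_FMT,
        )
        alpha = cfg["diff"]["alpha"]
        n_top = cfg["diff"]["n_top"]
        sig = gene_table[gene_table["pvalue"] < alpha]
        up_genes = sig[sig["direction"] == "up"]["gene_id"].tolist()
        down_genes = sig[sig["direction"] == "down"]["gene_id"].tolist()
        log(
            f"genes: {len(gene_table)} with promoter regions, "
            f"{len(up_genes)} up / {len(down_genes)} down at p < {alpha}, "
            f"top-N cap {n_top}"
        )

    # -- stage: enrichment -----------------------------------------------------
    enrichment: Dict[str, pd.DataFrame] = {}
    with stage("enrich"):
        if terms is not None:
            if cfg["enrich"]["universe"] == "assigned":
                universe = set(gene_table["gene_id"])
            else:
                universe = set().union(*(t.genes for t in terms))
            heat = profiles.heatmap_matrix(gene_table, top_n=n_top, alpha=alpha)
            ranked_up = heat[heat["direction"] == "up"]["gene_id"].tolist()
            ranked_down = heat[heat["direction"] == "down"]["gene_id"].tolist()
            for label, gene_list in (("up", ranked_up), ("down", ranked_down)):
                table = enrich.enrich_terms(
                    gene_list, terms, universe, method=cfg["enrich"]["method"]
                )
                table.to_csv(
                    register(f"enrichment_{label}", outdir / f"enrichment_{label}.tsv"),
                    sep="\t",
                    index=False,
                    float_format=FLOAT_FMT,
                )
                log(f"enrichment {label}: {len(table)} terms tested")
        else:
            log("enrichment: skipped (no term annotation)")

    # -- stage: report ---------------------------------------------------------
    metrics = None
    with stage("report"):
        heat = profiles.heatmap_matrix(gene_table, top_n=n_top, alpha=alpha)
        heat.to_csv(
            register("heatmap", outdir / "heatmap.tsv"),
            sep="\t",
            index=False,
            float_format=FLOAT_FMT,
        )
        flank = cfg["profile"]["flank"]
        bin_size = cfg["profile"]["bin_size"]
        _, prof_control = profiles.tss_density_profile(
            norm_control, genes, flank=flank, bin_size=bin_size,
            fragment_length=cfg["peaks"]["fragment_length"],
        )
        _, prof_treated = profiles.tss_density_profile(
            norm_treated, genes, flank=flank, bin_size=bin_size,
            fragment_length=cfg["peaks"]["fragment_length"],
        )
        offsets = [-flank + bin_size * i for i in range(2 * flank // bin_size)]
        pd.DataFrame(
            {"offset": offsets, "control": prof_control, "treated": prof_treated}
        ).to_csv(
            register("tss_profile", outdir / "tss_profile.tsv"),
            sep="\t",
            index=False,
            float_format=FLOAT_FMT,
        )
        if cfg["profile"]["write_tracks"]:
            for label, tc in (("control", norm_control), ("treated", norm_treated)):
                profiles.write_density_bedgraph(
                    tc,
                    layout,
                    register(f"track_{label}", outdir / f"density_{label}.bedgraph"),
                    window_size=cfg["peaks"]["window_size"],
                    fragment_length=cfg["peaks"]["fragment_length"],
                )
        if truth is not None:
            metrics = profiles.recovery_metrics(gene_table, truth, alpha=alpha)
            with open(register("metrics", outdir / "metrics.json"), "w") as fh:
                json.dump(metrics.as_dict(), fh, indent=2, sort_keys=True)
            log(
                "recovery: sensitivity up "
                f"{metrics.sensitivity_up:.3f}, down {metrics.sensitivity_down:.3f}, "
                f"FDR {metrics.observed_fdr:.3f}, direction accuracy "
                f"{metrics.direction_accuracy:.3f}"
            )

    # -- summary / manifest -----------------------------------------------------
    summary: Dict[str, Any] = {
        "seed": seed,
        "parameters": {
            "window_size": cfg["peaks"]["window_size"],
            "peak_alpha": cfg["peaks"]["alpha"],
            "diff_alpha": cfg["diff"]["alpha"],
            "promoter_window": cfg["promoter"]["window"],
            "n_top": cfg["diff"]["n_top"],
            "fragment_length": cfg["peaks"]["fragment_length"],
        },
        "tag_totals": {n: samples_total for n, samples_total in
                       ((name, samples[name].total_tags) for name in simulate.SAMPLE_NAMES)},
        "chip_depth_ratio": depth_ratio,
        "subsample_seed": sub_seed,
        "n_peaks": {"control": len(peaks["control"]), "treated": len(peaks["treated"])},
        "n_matched_regions": len(scored),
        "n_genes_with_regions": int(len(gene_table)),
        "n_genes_up": len(up_genes),
        "n_genes_down": len(down_genes),
    }
    if metrics is not None:
        summary["recovery"] = metrics.as_dict()
    with open(register("summary", outdir / "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(register("config", outdir / "config_resolved.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    with open(register("log", outdir / "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    manifest = {p.name: _sha256(p) for p in sorted(files.values())}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files["manifest"] = outdir / "manifest.json"

    return RunResult(
        outdir=outdir,
        summary=summary,
        gene_table=gene_table,
        regions=scored,
        metrics=metrics,
        files=files,
    )
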