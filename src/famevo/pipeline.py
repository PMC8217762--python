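"""End-to-end orchestration of the analysis stages from one config.

Stages run in dependency order — membership scan, physicochemical
properties, tandem detection, tree building, phylostratigraphy,
mirror-tree co-evolution, expression classification — skipping any stage
whose inputs are absent from the config.  Every reported statistic lands
in a machine-readable JSON summary together with the exact parameters
used; the reporter never recomputes anything.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import (
    coevolution,
    expression,
    family_props,
    genome_map,
    io_formats,
    phylo,
    phylostrat,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Input paths and thresholds for a pipeline run.

    ``inputs`` maps stage input names (``domtbl``, ``fasta``, ``genes``,
    ``alignment``, ``orthologs``, ``background``, ``family_a_dir``,
    ``family_b_dir``, ``expression``, ``sample_groups``) to file paths;
    absent keys skip the dependent stage.
    """

    inputs: dict[str, str] = field(default_factory=dict)
    e_max: float = 1e-5
    score_min: float = 0.0
    family: str = "Wnt"
    distance_model: str = "poisson"
    bootstrap_reps: int = 1000
    min_common_species: int = coevolution.DEFAULT_MIN_COMMON
    lfc_min: float = 1.0
    alpha: float = 0.05
    de_mode: str = "fc_only"
    group_case: str = "case"
    group_control: str = "control"
    seed: int = 0
    outdir: str = "famevo_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.e_max:
            raise ValueError("e_max must be positive")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.distance_model not in ("p", "poisson"):
            raise ValueError(f"unknown distance model {self.distance_model!r}")
        if self.de_mode not in ("fc_only", "welch"):
            raise ValueError(f"unknown DE mode {self.de_mode!r}")
        for name, path in self.inputs.items():
            if not Path(path).exists():
                raise ValueError(f"input {name!r} does not exist: {path}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("scan")
def _run_scan(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    rows = io_formats.read_domtbl(cfg.inputs["domtbl"])
    kept = family_props.filter_hits(rows, cfg.e_max, cfg.score_min)
    out = outdir / "membership.tsv"
    with open(out, "w") as fh:
        fh.write("target_id\tquery_accession\tevalue\tscore\n")
        for r in kept:
            fh.write(
                f"{r.target_id}\t{r.query_accession}\t"
                f"{r.full_seq_evalue:g}\t{r.full_seq_score:g}\n"
            )
    return {
        "n_hits_in": len(rows),
        "n_hits_kept": len(kept),
        "members": sorted({r.target_id for r in kept}),
        "output": str(out),
    }


@_stage("props")
def _run_props(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    seqs = io_formats.read_fasta(cfg.inputs["fasta"])
    out = outdir / "protein_props.tsv"
    rows = []
    with open(out, "w") as fh:
        fh.write("gene_id\tlength\tmw_da\tpi\n")
        for rec in seqs:
            mw = family_props.molecular_weight(rec.sequence)
            pi = family_props.isoelectric_point(rec.sequence)
            fh.write(f"{rec.id}\t{len(rec.sequence)}\t{mw:.2f}\t{pi:.2f}\n")
            rows.append({"gene_id": rec.id, "length": len(rec.sequence),
                         "mw_da": round(mw, 2), "pi": round(pi, 2)})
    return {"n_proteins": len(rows), "proteins": rows, "output": str(out)}


@_stage("tandem")
def _run_tandem(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    loci = io_formats.read_gene_table(cfg.inputs["genes"])
    groups = genome_map.detect_tandem(loci, cfg.family)
    summary = genome_map.chromosome_summary(loci, cfg.family)
    out = outdir / "tandem_groups.tsv"
    with open(out, "w") as fh:
        fh.write("group_id\tchromosome\tmembers\n")
        for i, g in enumerate(groups, 1):
            fh.write(f"{i}\t{g.chromosome}\t{','.join(g.members)}\n")
    n_tandem = sum(len(g) for g in groups)
    return {
        "n_groups": len(groups),
        "n_tandem_genes": n_tandem,
        "tandem_fraction": n_tandem / summary.total,
        "chromosome_counts": summary.counts,
        "top_k_fraction": summary.top_k_fraction,
        "output": str(out),
    }


@_stage("tree")
def _run_tree(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    aln = io_formats.read_alignment(cfg.inputs["alignment"])
    tree = phylo.bootstrap_support(
        aln, cfg.distance_model, cfg.bootstrap_reps, cfg.seed
    )
    out = outdir / "tree.nwk"
    io_formats.write_newick(tree, out)
    supports = [
        node.support
        for node in tree.preorder_node_iter()
        if getattr(node, "support", None) is not None
    ]
    return {
        "n_taxa": aln.n_taxa,
        "n_sites": aln.n_sites,
        "bootstrap_reps": cfg.bootstrap_reps,
        "mean_support": sum(supports) / len(supports) if supports else None,
        "output": str(out),
    }


@_stage("strata")
def _run_strata(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    presence = io_formats.read_ortholog_table(cfg.inputs["orthologs"])
    patterns = phylostrat.classify_presence(presence)
    summary = phylostrat.stratum_proportions(patterns.values())
    result: dict[str, Any] = {
        "n_genes": summary.n_genes,
        "counts": summary.counts,
        "proportions": summary.proportions,
        "post_vertebrate_split": summary.post_vertebrate_split,
        "non_nested_genes": sorted(
            g for g, p in patterns.items() if p.non_nested
        ),
    }
    if "background" in cfg.inputs:
        bg = io_formats.read_ortholog_table(cfg.inputs["background"])
        bg_summary = phylostrat.stratum_proportions(
            phylostrat.classify_presence(bg).values()
        )
        cmp_df = phylostrat.compare_to_background(
            summary.counts, bg_summary.counts
        )
        out = outdir / "strata_vs_background.tsv"
        cmp_df.to_csv(out, sep="\t")
        result["background_comparison"] = {
            lab: {
                "ratio": None if not _finite(row["ratio"]) else row["ratio"],
                "fisher_p": row["fisher_p"],
            }
            for lab, row in cmp_df.iterrows()
        }
        result["background_output"] = str(out)
    return result


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def _read_member_dir(path: str) -> dict[str, io_formats.AlignmentSet]:
    files = sorted(Path(path).glob("*.fasta")) + sorted(Path(path).glob("*.aln"))
    if not files:
        raise ValueError(f"no member alignments (*.fasta, *.aln) in {path}")
    return {f.stem: io_formats.read_alignment(f) for f in files}


@_stage("mirrortree")
def _run_mirrortree(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    fam_a = _read_member_dir(cfg.inputs["family_a_dir"])
    fam_b = _read_member_dir(cfg.inputs["family_b_dir"])
    result = coevolution.family_coevolution(
        fam_a, fam_b, cfg.distance_model, cfg.min_common_species
    )
    out = outdir / "coevolution_matrix.tsv"
    result.matrix.to_csv(out, sep="\t")
    return {
        "n_pairs": result.n_pairs,
        "n_missing": result.n_missing,
        "mean_r": result.mean_r,
        "output": str(out),
    }


@_stage("de")
def _run_de(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    groups = None
    if "sample_groups" in cfg.inputs:
        import pandas as pd

        gdf = pd.read_csv(cfg.inputs["sample_groups"], sep="\t")
        for col in ("sample", "group"):
            if col not in gdf.columns:
                raise ValueError(
                    f"{cfg.inputs['sample_groups']}: missing column {col!r}"
                )
        groups = dict(zip(gdf["sample"], gdf["group"]))
    mat = io_formats.read_expression_tsv(cfg.inputs["expression"], groups)
    calls = expression.classify_de(
        mat, cfg.group_case, cfg.group_control,
        cfg.lfc_min, cfg.alpha, cfg.de_mode,
    )
    props = expression.de_proportions(calls)
    out = outdir / "de_calls.tsv"
    with open(out, "w") as fh:
        fh.write("gene_id\tlog2fc\tp_value\tclass\n")
        for c in calls:
            p = "" if c.p_value is None else f"{c.p_value:.4g}"
            fh.write(f"{c.gene_id}\t{c.log2fc:.4f}\t{p}\t{c.label}\n")
    heat = expression.heatmap_matrix(mat)
    heat_out = outdir / "heatmap_matrix.tsv"
    heat.to_csv(heat_out, sep="\t", index_label="gene_id")
    return {
        "n_genes": len(calls),
        "proportions": props,
        "output": str(out),
        "heatmap_output": str(heat_out),
    }


_STAGES = [
    ("scan", ("domtbl",), _run_scan),
    ("props", ("fasta",), _run_props),
    ("tandem", ("genes",), _run_tandem),
    ("tree", ("alignment",), _run_tree),
    ("strata", ("orthologs",), _run_strata),
    ("mirrortree", ("family_a_dir", "family_b_dir"), _run_mirrortree),
    ("de", ("expression",), _run_de),
]


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run all stages whose inputs are configured; write summary.json.

    The summary is deterministic for a fixed config (no timestamps).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "parameters": {
            "e_max": cfg.e_max,
            "score_min": cfg.score_min,
            "family": cfg.family,
            "distance_model": cfg.distance_model,
            "bootstrap_reps": cfg.bootstrap_reps,
            "min_common_species": cfg.min_common_species,
            "lfc_min": cfg.lfc_min,
            "alpha": cfg.alpha,
            "de_mode": cfg.de_mode,
            "seed": cfg.seed,
        },
        "stages": {},
        "skipped": [],
    }
    for name, required, runner in _STAGES:
        if all(key in cfg.inputs for key in required):
            logger.info("running stage %s", name)
            report["stages"][name] = runner(cfg, outdir)
        else:
            logger.info("skipping stage %s (no input)", name)
            report["skipped"].append(name)
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report["summary_path"] = str(summary_path)
    return report
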