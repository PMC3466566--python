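"""End-to-end orchestration: load -> smooth -> signal -> Mantel -> reports.

The bundle mirrors the published analysis: per-operon complexity profile,
a two-arm (with/without plasmids) signal table, the differential-K report,
Mantel congruence between the rate-smoothed gene tree and the species tree,
trait co-occurrence matrices, the plasmid-bias regression, and a
machine-readable JSON summary. All randomness flows from one master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import chronos, matrixstats, physignal, traits, treeio

log = logging.getLogger("merphylo.pipeline")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults mirror the published run parameters
    (smoothing lambda 0.8 over 1000 iterations, 1000 permutations)."""

    gene_tree: str = ""
    operon_table: str = ""
    outdir: str = "results"
    species_tree: str | None = None
    smoothing_lambda: float = 0.8
    smoothing_iterations: int = 1000
    n_perm: int = 1000
    seed: int = 0
    replicon_arm: str = "all"  # arm used for co-occurrence / complexity
    bh_correction: bool = False
    two_sided: bool = False
    mantel_subsets: dict = field(default_factory=dict)

    def smoothing(self) -> chronos.SmoothingConfig:
        return chronos.SmoothingConfig(
            lambda_=self.smoothing_lambda, max_iterations=self.smoothing_iterations
        )


def load_config(path) -> RunConfig:
    """Read a RunConfig from a plain key-value YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _bh(p: pd.Series) -> pd.Series:
    mask = p.notna()
    out = p.copy()
    if mask.sum():
        out[mask] = stats.false_discovery_control(p[mask].to_numpy(), method="bh")
    return out


def _smooth_arm(tree: treeio.Tree, keep, cfg: RunConfig) -> chronos.Chronogram:
    sub = tree if set(keep) == set(tree.tip_labels) else treeio.prune(tree, keep)
    sub = sub if sub.is_binary() else treeio.resolve_polytomies(sub, epsilon=0.0)
    return chronos.rate_smooth(sub, cfg.smoothing())


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.outdir``.

    Returns the JSON-ready summary dict. Raises on the first failing stage
    (the CLI converts that into a non-zero exit with a structured log line).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(cfg), "stages": {}}

    def run_stage(name, fn):
        log.info("stage=%s seed=%s start", name, cfg.seed)
        try:
            result = fn()
        except Exception as exc:
            log.error("stage=%s FAILED: %s", name, exc)
            summary["stages"][name] = {"status": "failed", "error": str(exc)}
            (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
            raise
        summary["stages"][name] = {"status": "ok"}
        return result

    def _load():
        gene = treeio.read_newick_file(cfg.gene_tree)
        catalog = traits.read_operon_table(cfg.operon_table)
        missing = set(gene.tip_labels) - set(catalog.taxa)
        if missing:
            log.warning("%d tree tips absent from catalog", len(missing))
        return gene, catalog

    gene, catalog = run_stage("load", _load)

    def _smooth():
        chrom_taxa = [
            t
            for t in gene.tip_labels
            if t in set(traits.subset_by_replicon(catalog, "chromosome").taxa)
        ]
        chrono_all = _smooth_arm(gene, gene.tip_labels, cfg)
        chrono_chrom = (
            _smooth_arm(gene, chrom_taxa, cfg) if len(chrom_taxa) >= 3 else chrono_all
        )
        treeio.write_newick_file(chrono_all.tree, outdir / "gene_chronogram.nwk")
        chrono_all.age_table().to_csv(
            outdir / "gene_chronogram_ages.tsv", sep="\t", index=False
        )
        return chrono_all, chrono_chrom

    chrono_all, chrono_chrom = run_stage("smooth", _smooth)

    def _complexity():
        prof = traits.complexity_profile(
            traits.subset_by_replicon(catalog, cfg.replicon_arm)
        )
        prof.to_csv(outdir / "complexity_profile.tsv", sep="\t", index=False)
        return prof

    run_stage("complexity", _complexity)

    def _signal():
        arm_all = physignal.multi_signal(
            chrono_all.tree, catalog, n_perm=cfg.n_perm, seed=cfg.seed
        )
        chrom = traits.subset_by_replicon(catalog, "chromosome")
        arm_chrom = physignal.multi_signal(
            chrono_chrom.tree, chrom, n_perm=cfg.n_perm, seed=cfg.seed
        )
        if cfg.bh_correction:
            arm_all["p_bh"] = _bh(arm_all["p"])
            arm_chrom["p_bh"] = _bh(arm_chrom["p"])
        table = arm_all.merge(
            arm_chrom, on="trait", suffixes=("_with_plasmids", "_without_plasmids")
        )
        table.to_csv(
            outdir / "signal_table.tsv", sep="\t", index=False, float_format="%.3f"
        )
        return table

    run_stage("signal", _signal)

    def _differential():
        report = physignal.plasmid_differential(
            chrono_all.tree, chrono_chrom.tree, catalog, n_perm=cfg.n_perm, seed=cfg.seed
        )
        report.to_csv(
            outdir / "differential_k.tsv", sep="\t", index=False, float_format="%.3f"
        )
        (outdir / "differential_k.json").write_text(
            report.to_json(orient="records", indent=2)
        )
        return report

    run_stage("differential", _differential)

    if cfg.species_tree:

        def _mantel():
            species = treeio.read_newick_file(cfg.species_tree)
            shared = [
                t for t in chrono_chrom.tree.tip_labels if t in set(species.tip_labels)
            ]
            d_gene = treeio.patristic_matrix(
                treeio.prune(chrono_chrom.tree, shared)
            ).submatrix(shared)
            d_sp = treeio.patristic_matrix(treeio.prune(species, shared)).submatrix(
                shared
            )
            alt = "two-sided" if cfg.two_sided else "greater"
            rows = [
                {"subset": "all", **asdict(matrixstats.mantel(
                    d_gene, d_sp, n_perm=cfg.n_perm, seed=cfg.seed, alternative=alt
                ))}
            ]
            for name, labels in cfg.mantel_subsets.items():
                labs = [t for t in labels if t in shared]
                if len(labs) >= 4:
                    rows.append(
                        {
                            "subset": name,
                            **asdict(
                                matrixstats.mantel_subset(
                                    d_gene, d_sp, labs, n_perm=cfg.n_perm,
                                    seed=cfg.seed, alternative=alt,
                                )
                            ),
                        }
                    )
            out = pd.DataFrame(rows)
            out.to_csv(outdir / "mantel.tsv", sep="\t", index=False)
            return out

        run_stage("mantel", _mantel)

    def _cooccur():
        arm = traits.subset_by_replicon(catalog, cfg.replicon_arm)
        res = matrixstats.cooccurrence_matrix(arm, n_perm=cfg.n_perm, seed=cfg.seed)
        with open(outdir / "cooccurrence.tsv", "w") as fh:
            fh.write("# Pearson R\n")
            res.r.round(3).to_csv(fh, sep="\t")
            fh.write("# permutation p\n")
            res.p.round(3).to_csv(fh, sep="\t")
        return res

    run_stage("cooccurrence", _cooccur)

    def _bias():
        try:
            slope, intercept, pairs = matrixstats.plasmid_bias_regression(catalog)
        except ValueError as exc:
            log.warning("bias regression skipped: %s", exc)
            return None
        pairs.to_csv(outdir / "plasmid_bias_pairs.tsv", sep="\t", index=False)
        summary["bias_regression"] = {"slope": slope, "intercept": intercept}
        return slope

    run_stage("bias_regression", _bias)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
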