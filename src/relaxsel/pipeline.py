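"""End-to-end orchestration on synthetic inputs.

``run_pipeline`` wires the stages together in dependency order: simulate
gene families -> branch dN/dS tests with Bonferroni significance ->
orthogroup consolidation and the duplication-confound filter -> SNP panel
with RVIS/DRVIS and MK alpha -> GO enrichment of the surviving gene set.
Every stage's table is written as TSV beside a JSON run manifest carrying
the config hash and seed; identical config + seed reproduces identical
bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from .codon_model import DNDS_CAP, branch_test, cap_dnds
from .io import write_tsv
from .popgen import MAF_COMMON, MAF_DELETERIOUS, MAF_MK, MAX_MISSING, MIN_MAC, RATE_CUT, SIFT_CUT, intolerance_scores, mk_alpha
from .synthetic_data import (
    SimulationConfig,
    SnpPanelConfig,
    simulate_gene_family,
    simulate_go_universe,
    simulate_snp_panel,
)

logger = logging.getLogger("relaxsel")


class PipelineConfigError(ValueError):
    """Raised before any compute when enabled stages have unmet dependencies."""


@dataclass
class PipelineConfig:
    """Stage toggles, synthetic-data conditions, and analysis thresholds.

    Threshold defaults mirror the study design: homolog coverage >= 0.90,
    >= 4 aligned genomes, dN/dS reporting cap 2, common-variant MAF 0.01,
    MK MAF 0.10, missingness < 0.20, MAC >= 3, deleterious rule
    (rate < 0.5, SIFT <= 0.05, MAF < 0.20), top fraction 5%, alpha 0.05.
    """

    seed: int = 0
    # stage toggles
    simulate: bool = True
    branch_tests: bool = True
    variants: bool = True
    scores: bool = True
    mk: bool = True
    consolidate: bool = True
    enrich: bool = True
    # synthetic gene families
    n_genes: int = 20
    n_taxa: int = 8
    n_codons: int = 300
    kappa: float = 2.0
    omega_background: float = 0.2
    omega_relaxed: float = 1.5
    relaxed_fraction: float = 0.2
    branch_length_mean: float = 0.1
    duplicate_fraction: float = 0.3
    # synthetic SNP panel
    total_mean: float = 50.0
    snp_slope: float = 0.3
    snp_noise_sd: float = 2.0
    outlier_fraction: float = 0.05
    outlier_shift: float = 20.0
    deleterious_fraction: float = 0.15
    # synthetic GO universe
    n_terms: int = 40
    planted_term_size: int = 8
    enrichment_factor: float = 8.0
    # thresholds
    min_aligned_fraction: float = 0.90
    min_taxa: int = 4
    dnds_cap: float = DNDS_CAP
    maf_common: float = MAF_COMMON
    maf_mk: float = MAF_MK
    max_missing: float = MAX_MISSING
    min_mac: int = MIN_MAC
    rate_cut: float = RATE_CUT
    sift_cut: float = SIFT_CUT
    maf_del: float = MAF_DELETERIOUS
    top_fraction: float = 0.05
    alpha: float = 0.05

    def __post_init__(self) -> None:
        checks = {
            "min_aligned_fraction": (self.min_aligned_fraction, 0.0, 1.0),
            "relaxed_fraction": (self.relaxed_fraction, 0.0, 1.0),
            "duplicate_fraction": (self.duplicate_fraction, 0.0, 1.0),
            "outlier_fraction": (self.outlier_fraction, 0.0, 1.0),
            "maf_common": (self.maf_common, 0.0, 0.5),
            "maf_mk": (self.maf_mk, 0.0, 0.5),
            "max_missing": (self.max_missing, 0.0, 1.0),
            "maf_del": (self.maf_del, 0.0, 0.5),
            "top_fraction": (self.top_fraction, 0.0, 1.0),
            "alpha": (self.alpha, 0.0, 1.0),
        }
        for name, (value, lo, hi) in checks.items():
            if not lo <= value <= hi:
                raise PipelineConfigError(f"{name}={value} outside [{lo}, {hi}]")
        if self.scores and not self.variants:
            raise PipelineConfigError("scores stage requires the variants stage")
        if self.mk and not (self.variants and self.branch_tests):
            raise PipelineConfigError("mk stage requires variants and branch_tests")
        if self.consolidate and not self.branch_tests:
            raise PipelineConfigError("consolidate stage requires branch_tests")
        if self.enrich and not self.branch_tests:
            raise PipelineConfigError("enrich stage requires branch_tests")
        if self.branch_tests and not self.simulate:
            raise PipelineConfigError(
                "branch_tests requires simulated inputs (simulate stage)"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _gene_seed(base: int, index: int) -> int:
    return int(
        np.random.SeedSequence(entropy=base, spawn_key=(index,)).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Execute the enabled stages and write the report bundle to ``outdir``.

    Returns the stage tables keyed by name ('branch_tests', 'orthogroups',
    'scores', 'mk', 'enrichment', 'gene_summary').
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    bundle: dict[str, pd.DataFrame] = {}
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]

    n_relaxed = int(round(config.relaxed_fraction * config.n_genes))
    relaxed = set(
        gene_ids[i] for i in rng.choice(config.n_genes, size=n_relaxed, replace=False)
    )

    branch_df = pd.DataFrame()
    if config.branch_tests:
        rows = []
        for i, gid in enumerate(gene_ids):
            omega_fg = (
                config.omega_relaxed if gid in relaxed else config.omega_background
            )
            sim = simulate_gene_family(
                SimulationConfig(
                    seed=_gene_seed(config.seed, i),
                    n_taxa=config.n_taxa,
                    n_codons=config.n_codons,
                    kappa=config.kappa,
                    omega_background=config.omega_background,
                    omega_foreground=omega_fg,
                    branch_length_mean=config.branch_length_mean,
                )
            )
            res = branch_test(sim.alignment, sim.tree, gene_id=gid)
            logger.debug("branch test %s: p=%.3g flags=%s", gid, res.p_value, res.flags)
            rows.append(
                {
                    "gene_id": gid,
                    "lnl_one_ratio": res.lnl_one_ratio,
                    "lnl_two_ratio": res.lnl_two_ratio,
                    "omega_tree": res.omega_tree,
                    "omega_background": res.omega_background,
                    "omega_foreground": res.omega_foreground,
                    "omega_tree_capped": cap_dnds(res.omega_tree, config.dnds_cap),
                    "omega_foreground_capped": cap_dnds(
                        res.omega_foreground, config.dnds_cap
                    ),
                    "delta_dnds": res.delta_dnds,
                    "lrt_stat": res.lrt_stat,
                    "p_value": res.p_value,
                    "n_taxa": res.n_taxa,
                    "n_codons": res.n_codons,
                    "converged": res.converged,
                    "flags": ";".join(res.flags),
                    "simulated_relaxed": gid in relaxed,
                }
            )
        branch_df = pd.DataFrame(rows)
        threshold = enr.bonferroni_threshold(config.alpha, len(branch_df))
        branch_df["significant"] = (branch_df["p_value"] < threshold) & (
            branch_df["delta_dnds"] < 0
        )
        bundle["branch_tests"] = branch_df
        write_tsv(branch_df, outdir / "branch_tests.tsv")
        logger.info(
            "branch tests: %d genes, %d significant at Bonferroni %.3g",
            len(branch_df), int(branch_df["significant"].sum()), threshold,
        )

    kept_genes: set[str] = set()
    if config.consolidate and config.branch_tests:
        orthogroups: dict[str, list[str]] = {}
        n_dup_pairs = int(config.duplicate_fraction * config.n_genes / 2)
        i = 0
        og = 0
        while i < config.n_genes:
            og += 1
            if og <= n_dup_pairs and i + 1 < config.n_genes:
                orthogroups[f"og{og:05d}"] = [gene_ids[i], gene_ids[i + 1]]
                i += 2
            else:
                orthogroups[f"og{og:05d}"] = [gene_ids[i]]
                i += 1
        sig = dict(zip(branch_df["gene_id"], branch_df["significant"]))
        metrics = {
            r.gene_id: (r.delta_dnds, r.p_value) for r in branch_df.itertuples()
        }
        og_rows = []
        for og_id, members in orthogroups.items():
            summary = enr.consolidate_orthogroup(
                og_id, {g: metrics[g] for g in members}
            )
            og_rows.append(
                {
                    "orthogroup_id": og_id,
                    "gene_ids": ",".join(summary.gene_ids),
                    "n_members": len(members),
                    "delta_dnds": summary.delta_dnds,
                    "p_value": summary.p_value,
                }
            )
        og_df = pd.DataFrame(og_rows)
        kept_genes = enr.duplication_confound_filter(orthogroups, sig)
        bundle["orthogroups"] = og_df
        write_tsv(og_df, outdir / "orthogroups.tsv")
        logger.info(
            "consolidation: %d orthogroups, %d genes kept after duplication filter",
            len(og_df), len(kept_genes),
        )
    elif config.branch_tests:
        kept_genes = set(branch_df.loc[branch_df["significant"], "gene_id"])

    scores_df = pd.DataFrame()
    if config.variants:
        panel, outliers = simulate_snp_panel(
            SnpPanelConfig(
                seed=_gene_seed(config.seed, 10_000),
                n_genes=config.n_genes,
                total_mean=config.total_mean,
                slope=config.snp_slope,
                noise_sd=config.snp_noise_sd,
                outlier_fraction=config.outlier_fraction,
                outlier_shift=config.outlier_shift,
                deleterious_fraction=config.deleterious_fraction,
            )
        )
        panel["planted_outlier"] = panel["gene_id"].isin(outliers)
        bundle["snp_panel"] = panel
        write_tsv(panel, outdir / "snp_panel.tsv")
        if config.scores:
            rvis = intolerance_scores(
                panel["gene_id"], panel["n_total_snps"], panel["n_nonsyn_common"],
                top_fraction=config.top_fraction,
            ).rename(columns={c: f"rvis_{c}" for c in ("residual", "percentile", "top5", "bottom5")})
            drvis = intolerance_scores(
                panel["gene_id"], panel["n_total_snps"], panel["n_deleterious"],
                top_fraction=config.top_fraction,
            ).rename(columns={c: f"drvis_{c}" for c in ("residual", "percentile", "top5", "bottom5")})
            scores_df = rvis.merge(drvis, on="gene_id")
            bundle["scores"] = scores_df
            write_tsv(scores_df, outdir / "scores.tsv")

    mk_df = pd.DataFrame()
    if config.mk and config.variants and config.branch_tests:
        panel = bundle["snp_panel"]
        omega_fg = dict(zip(branch_df["gene_id"], branch_df["omega_foreground"]))
        rows = []
        for r in panel.itertuples():
            pn = float(r.n_nonsyn_common)
            ps = float(r.n_total_snps - r.n_nonsyn_common)
            result = mk_alpha(pn, ps, omega_fg.get(r.gene_id, 0.0), 1.0, gene_id=r.gene_id)
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "pN": pn,
                    "pS": ps,
                    "dnds": omega_fg.get(r.gene_id, float("nan")),
                    "alpha": result.alpha if result.defined else float("nan"),
                    "defined": result.defined,
                    "reason": result.reason or "",
                }
            )
        mk_df = pd.DataFrame(rows)
        bundle["mk"] = mk_df
        write_tsv(mk_df, outdir / "mk_alpha.tsv")

    if config.enrich and config.branch_tests:
        study = sorted(kept_genes)
        go = simulate_go_universe(
            n_genes=config.n_genes,
            n_terms=config.n_terms,
            planted_term_size=min(config.planted_term_size, config.n_genes),
            study_set=study,
            enrichment_factor=config.enrichment_factor,
            seed=_gene_seed(config.seed, 20_000),
        )
        gene_terms = {
            g: set(sub["term_id"])
            for g, sub in go.gene_terms.groupby("gene_id")
        }
        parents = {
            t: set(sub["parent_id"])
            for t, sub in go.term_parents.groupby("term_id")
        }
        propagated = enr.propagate_annotations(gene_terms, parents)
        term_genes: dict[str, set[str]] = {}
        for g, terms in propagated.items():
            for t in terms:
                term_genes.setdefault(t, set()).add(g)
        universe = set(propagated)
        study_in = set(study) & universe
        enr_df = enr.fisher_enrichment(study_in, universe, term_genes)
        enr_df["planted"] = enr_df["term_id"] == go.planted_term
        enr_df["bonferroni_threshold"] = enr.bonferroni_threshold(
            config.alpha, len(enr_df)
        ) if len(enr_df) else float("nan")
        bundle["enrichment"] = enr_df
        write_tsv(enr_df, outdir / "enrichment.tsv")

    if config.branch_tests:
        summary = branch_df[
            ["gene_id", "delta_dnds", "p_value", "significant", "simulated_relaxed"]
        ].copy()
        summary["kept_after_duplication_filter"] = summary["gene_id"].isin(kept_genes)
        if not scores_df.empty:
            summary = summary.merge(
                scores_df[["gene_id", "rvis_residual", "drvis_residual"]],
                on="gene_id", how="left",
            )
        if not mk_df.empty:
            summary = summary.merge(mk_df[["gene_id", "alpha"]], on="gene_id", how="left")
        bundle["gene_summary"] = summary
        write_tsv(summary, outdir / "gene_summary.tsv")

    manifest = {
        "seed": config.seed,
        "config_sha256": config.digest(),
        "config": config.to_dict(),
        "tables": {name: len(df) for name, df in bundle.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return bundle
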