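"""End-to-end pipeline orchestration.

``run_pipeline`` wires the stages together over a fixture bundle on disk:
preprocessing -> trait-stratified differential expression and consensus ->
planar co-expression network with multiscale modules and hubs -> module
enrichment and ranking -> genotype-primed causal network with key driver
analysis -> (optionally) cross-cell-type pseudobulk correlations and GSEA.
Every stage output is written as TSV/GMT next to a JSON manifest recording
seeds, parameters, and row counts; a rerun with the same config and seed
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import causalnet, coexnet, crosscell, diffexpr, io, modulechar, preprocess

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "expression", "metadata", "genotypes", "signatures", "counts", "out_dir",
    "seed", "covariates", "max_missing", "impute_k", "traits", "dep_preset",
    "coex_fdr", "min_module_size", "n_null", "n_hub_perm", "n_causal_features",
    "n_networks", "n_mcmc_iter", "max_parents", "consensus_freq", "kda_h",
    "kda_min_neighborhood", "crosscell_rho", "crosscell_fdr", "cerad_coding",
}


@dataclass
class PipelineConfig:
    """Paths and stage parameters; unknown keys are rejected at load."""

    expression: str
    metadata: str
    out_dir: str
    genotypes: str | None = None
    signatures: str | None = None
    counts: str | None = None
    seed: int = 0
    covariates: list[str] = field(
        default_factory=lambda: ["AgeAtDeath", "Sex", "PMI", "Race", "Batch"]
    )
    max_missing: float = 0.5
    impute_k: int = 10
    traits: list[str] = field(
        default_factory=lambda: ["CDR", "Braak", "CERAD", "PlaqueMean"]
    )
    cerad_coding: str = "msbb"
    dep_preset: str = "msbb-protein"
    coex_fdr: float = 0.05
    min_module_size: int = 10
    n_null: int = 20
    n_hub_perm: int = 1000
    n_causal_features: int = 100
    n_networks: int = 100
    n_mcmc_iter: int = 2000
    max_parents: int = 3
    consensus_freq: float = 0.3
    kda_h: int = 2
    kda_min_neighborhood: int = 10
    crosscell_rho: float = 0.2
    crosscell_fdr: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def validate(self) -> None:
        for key in ("expression", "metadata", "genotypes", "signatures", "counts"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the report manifest."""
    t0 = time.time()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, int] = {}

    logger.info("[preprocess] loading and residualizing expression")
    expr = io.read_matrix(config.expression)
    meta = pd.read_csv(config.metadata, sep="\t", index_col=0)
    expr = preprocess.filter_missing(expr, config.max_missing)
    expr = preprocess.impute_missing(expr, k=config.impute_k)
    covs = [c for c in config.covariates if c in meta.columns]
    resid = preprocess.adjust_covariates(expr, meta, covs)
    io.write_matrix(resid, out / "residuals.tsv", index_label="feature")
    outputs["residuals.tsv"] = len(resid)

    logger.info("[dep] trait-stratified differential expression")
    comparisons = []
    for trait in config.traits:
        groups = diffexpr.stratify_samples(meta, trait, config.cerad_coding)
        hi, lo = groups.extreme_contrast
        res, _ = diffexpr.moderated_ttest(
            resid, groups.samples(hi), groups.samples(lo)
        )
        res.to_csv(out / f"dep_{trait}.tsv", sep="\t", index_label="feature")
        outputs[f"dep_{trait}.tsv"] = len(res)
        up, down = diffexpr.call_deps(res, preset=config.dep_preset)
        comparisons.append((up, down, res["p"].to_dict()))
    consensus = diffexpr.consensus_signature(comparisons)
    consensus.to_csv(out / "consensus.tsv", sep="\t")
    outputs["consensus.tsv"] = len(consensus)
    dep_sets = {
        "consensus_up": set(consensus.index[consensus["direction"] == "up"]),
        "consensus_down": set(consensus.index[consensus["direction"] == "down"]),
    }
    io.write_gmt(dep_sets, out / "dep_sets.gmt")

    logger.info("[network] planar co-expression network and modules")
    pairs = coexnet.significant_pairs(resid, fdr=config.coex_fdr)
    pfn = coexnet.build_pfn(pairs)
    io.write_edge_list(pfn.edge_table(), out / "edges.tsv")
    outputs["edges.tsv"] = pfn.n_edges
    hier = coexnet.multiscale_cluster(
        pfn, min_size=config.min_module_size, n_null=config.n_null,
        seed=config.seed,
    )
    io.write_gmt({m: s for m, s in hier.modules.items()}, out / "modules.gmt")
    pd.DataFrame(
        [(c, p) for c, p in hier.parent.items()], columns=["child", "parent"]
    ).to_csv(out / "module_parents.tsv", sep="\t", index=False)
    outputs["modules.gmt"] = len(hier.modules)
    hub_frames = []
    for mid, members in sorted(hier.modules.items()):
        ht = coexnet.detect_hubs(pfn, members, n_perm=config.n_hub_perm,
                                 seed=config.seed)
        if len(ht):
            ht.insert(0, "module", mid)
            hub_frames.append(ht)
    hubs = (
        pd.concat(hub_frames, ignore_index=True)
        if hub_frames
        else pd.DataFrame(columns=["module", "node", "degree", "hub_p"])
    )
    hubs.to_csv(out / "hubs.tsv", sep="\t", index=False)
    outputs["hubs.tsv"] = len(hubs)

    logger.info("[modules] enrichment and ranking")
    background = set(resid.index)
    signature_panel = dict(dep_sets)
    if config.signatures:
        signature_panel.update(io.read_gmt(config.signatures))
    recs = []
    for mid, members in sorted(hier.modules.items()):
        for sid, sig in sorted(signature_panel.items()):
            recs.append(
                modulechar.hypergeometric_enrichment(
                    members, sig & background, background,
                    module_id=mid, signature_id=sid,
                )
            )
    recs = modulechar.adjust_enrichments(recs)
    rank = modulechar.rank_modules(recs)
    rank.to_csv(out / "module_rank.tsv", sep="\t", index=False)
    outputs["module_rank.tsv"] = len(rank)

    kda = None
    if config.genotypes:
        logger.info("[causal] eQTL -> CIT -> MCMC ensemble -> consensus -> KDA")
        geno = io.read_matrix(config.genotypes)
        # desk-scale causal subset: top-variance features
        nv = resid.var(axis=1).sort_values(ascending=False)
        causal_feats = sorted(nv.index[: config.n_causal_features])
        sub = resid.loc[causal_feats]
        eqtls = causalnet.compute_eqtls(geno, sub)
        eqtls.to_csv(out / "eqtls.tsv", sep="\t", index=False)
        outputs["eqtls.tsv"] = len(eqtls)
        cits = []
        sig_eq = eqtls[eqtls["significant"]]
        for snp, grp in sig_eq.groupby("snp"):
            feats = sorted(grp["feature"])
            dose = geno.loc[snp, sub.columns]
            for i in range(len(feats)):
                for j in range(i + 1, len(feats)):
                    a, b = feats[i], feats[j]
                    cits.append(
                        causalnet.cit_test(dose, sub.loc[a], sub.loc[b],
                                           snp=snp, a_id=a, b_id=b)
                    )
        pd.DataFrame(
            [
                (c.snp, c.a, c.b, *c.p_components, c.omnibus_p, c.direction)
                for c in cits
            ],
            columns=["snp", "a", "b", "p1", "p2", "p3", "p4", "omnibus_p",
                     "direction"],
        ).to_csv(out / "cit.tsv", sep="\t", index=False)
        outputs["cit.tsv"] = len(cits)
        priors = causalnet.assemble_priors(cits)
        ensemble = causalnet.sample_ensemble(
            sub, priors, n_networks=config.n_networks,
            n_iter=config.n_mcmc_iter, max_parents=config.max_parents,
            seed=config.seed, max_features=max(config.n_causal_features, 300),
        )
        cons = causalnet.consensus_network(ensemble, config.consensus_freq)
        dag = causalnet.deloop(cons)
        io.write_edge_list(dag.edge_table(), out / "consensus_dag.tsv")
        outputs["consensus_dag.tsv"] = dag.graph.number_of_edges()
        kda_sig = dep_sets["consensus_up"] | dep_sets["consensus_down"]
        if not kda_sig:
            kda_sig = set(causal_feats)
        kda = causalnet.key_driver_analysis(
            dag, kda_sig, h=config.kda_h,
            min_neighborhood=config.kda_min_neighborhood,
        )
        kda.to_csv(out / "kda.tsv", sep="\t", index=False)
        outputs["kda.tsv"] = len(kda)

    if config.counts:
        logger.info("[crosscell] pseudobulk and cross-cell-type correlations")
        cells = pd.read_csv(config.counts, sep="\t", index_col=0)
        raw = crosscell.pseudobulk_aggregate(cells)
        pb = crosscell.normalize_pseudobulk(raw)
        edges = crosscell.cross_celltype_correlations(
            pb, rho_thresh=config.crosscell_rho, fdr_thresh=config.crosscell_fdr
        )
        edges.to_csv(out / "crosscell.tsv", sep="\t", index=False)
        outputs["crosscell.tsv"] = len(edges)

    from . import __version__

    manifest = {
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(),
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "outputs": outputs,
        "runtime_s": round(time.time() - t0, 2),
    }
    io.write_manifest(manifest, out / "manifest.json")
    return manifest
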