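"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure of a postmortem-brain proteomic cohort:
~185 donors, isoform-aware features (1-3 isoforms per gene), correlated
co-expression modules built from latent factors, trait-linked differential
abundance, covariate confounding (age, sex, batch), missing values, cis-eQTL
driven driver proteins with linear-Gaussian downstream fan-outs, and
donor-level cross-cell-type couplings in single-nucleus-style count data.

Every planted effect is recorded in :class:`SyntheticTruth` so that each
downstream stage of the pipeline can be scored against known structure.

The module signal model is a latent factor construction::

    x_ij = sqrt(r) * f_mj + sqrt(1 - r) * e_ij

so the expected correlation between two module members from different genes
is exactly ``r``.  Isoforms of one gene additionally share a configurable
fraction of their noise variance (default 0.5), mimicking correlated
isoforms.  Missingness is inserted completely at random.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_pseudobulk_counts",
    "write_fixture_bundle",
]

# trait strata proportions for the case-control (CERAD-like) axis:
# NL, possible, probable, definite
_CERAD_PROPS = (60 / 185, 25 / 185, 24 / 185, 76 / 185)
# MSBB CERAD coding in increasing severity order: NL=1, possible=4,
# probable=3, definite=2
_CERAD_CODES = (1, 4, 3, 2)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``within_module_cor`` is the expected pairwise correlation between module
    members (cross-gene pairs).  ``de_effect`` is the standardized mean shift
    per unit of the latent disease-severity score.  ``eqtl_beta`` is the
    per-allele effect on each driver feature; descendants follow their causal
    parent with coefficient ``causal_beta`` and Gaussian noise
    ``causal_noise_sd``.
    """

    n_samples: int = 185
    n_genes: int = 200
    isoform_rate: tuple[float, float, float] = (0.8, 0.15, 0.05)
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (30, 30, 30)
    within_module_cor: float = 0.6
    isoform_shared_var: float = 0.5
    de_frac: float = 0.15
    de_effect: float = 0.8
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.3, "batch": 0.2}
    )
    missing_frac: float = 0.0
    n_snps: int = 2
    eqtl_beta: float = 1.0
    snp_maf: float = 0.3
    n_drivers: int = 1
    n_descendants_per_driver: int = 10
    causal_depth: int = 2
    causal_beta: float = 1.0
    causal_noise_sd: float = 0.7
    cdr_cerad_cor: float = 0.6
    # pseudobulk block
    n_donors: int = 30
    cell_types: tuple[str, ...] = ("Ast", "Mic", "Neu", "Oli")
    cells_per_donor_type: int = 20
    n_pb_genes: int = 60
    n_coupled_pairs: int = 5
    coupling_strength: float = 0.8
    nb_dispersion: float = 0.5
    pb_base_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0 <= self.missing_frac <= 0.6:
            raise ValueError("missing_frac must be in [0, 0.6]")
        if abs(sum(self.isoform_rate) - 1.0) > 1e-9:
            raise ValueError("isoform_rate must sum to 1")
        if not 0 <= self.within_module_cor < 1:
            raise ValueError("within_module_cor must be in [0, 1)")
        if any(s < 10 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 10")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")


@dataclass
class SyntheticTruth:
    """Planted structure: the acceptance oracle for every pipeline stage."""

    module_of: dict[str, str] = field(default_factory=dict)
    de_direction: dict[str, dict[str, str]] = field(default_factory=dict)
    causal_edges: list[tuple[str, str]] = field(default_factory=list)
    drivers: list[str] = field(default_factory=list)
    eqtl_pairs: list[tuple[str, str]] = field(default_factory=list)
    crosscell_pairs: list[tuple[tuple[str, str], tuple[str, str]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        sources = {a for a, _ in self.causal_edges}
        if self.causal_edges and not set(self.drivers) <= sources | {
            b for _, b in self.causal_edges
        }:
            raise ValueError("drivers must appear in causal_edges")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["causal_edges"] = [tuple(e) for e in d.get("causal_edges", [])]
        d["eqtl_pairs"] = [tuple(e) for e in d.get("eqtl_pairs", [])]
        d["crosscell_pairs"] = [
            (tuple(a), tuple(b)) for a, b in d.get("crosscell_pairs", [])
        ]
        return cls(**d)


def _feature_ids(cfg: CohortConfig, rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Feature ids GENE<g>.<k> and the parallel list of gene names."""
    counts = rng.choice([1, 2, 3], size=cfg.n_genes, p=np.asarray(cfg.isoform_rate))
    feats, genes = [], []
    for g, c in enumerate(counts):
        gene = f"G{g:04d}"
        for k in range(1, int(c) + 1):
            feats.append(f"{gene}.{k}" if c > 1 else gene)
            genes.append(gene)
    return feats, genes


def _traits(cfg: CohortConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Clinical metadata from a latent severity score.

    CDR, Braak and plaque density are monotone in the severity latent; the
    case-control axis uses a second latent with configurable correlation
    (default 0.6, a modest inter-trait correlation)."""
    n = cfg.n_samples
    z = rng.standard_normal(n)
    rho = cfg.cdr_cerad_cor
    z2 = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)

    def to_levels(latent: np.ndarray, levels: list, probs: list[float]) -> np.ndarray:
        qs = np.quantile(latent, np.cumsum(probs)[:-1])
        idx = np.searchsorted(qs, latent, side="right")
        return np.asarray(levels, dtype=object)[idx]

    cdr = to_levels(z, [0, 0.5, 1, 2, 3, 4, 5],
                    [0.30, 0.12, 0.10, 0.10, 0.14, 0.14, 0.10])
    braak = to_levels(z, list(range(7)), [0.14] * 6 + [0.16])
    plaque = np.clip(np.round(12 * np.exp(0.8 * z) / (1 + np.exp(0.8 * z)) *
                              rng.uniform(0.6, 1.4, n) - 3.0, 2), 0, None)
    cerad = to_levels(z2, list(_CERAD_CODES), list(_CERAD_PROPS))

    meta = pd.DataFrame(
        {
            "CDR": cdr.astype(float),
            "Braak": braak.astype(int),
            "CERAD": cerad.astype(int),
            "PlaqueMean": plaque,
            "Sex": rng.choice(["F", "M"], n, p=[116 / 185, 69 / 185]),
            "APOE": rng.choice(["33", "34", "44"], n, p=[0.6, 0.3, 0.1]),
            "AgeAtDeath": np.round(np.clip(rng.normal(84.5, 8, n), 61, 108), 1),
            "PMI": np.round(np.clip(rng.normal(6, 2.5, n), 0.5, None), 1),
            "Race": rng.choice(["W", "B", "H"], n, p=[0.8, 0.12, 0.08]),
            "Batch": rng.choice([f"b{i}" for i in range(1, 5)], n),
        },
        index=[f"S{i:03d}" for i in range(n)],
    )
    return meta, z


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression, metadata, genotypes, truth).

    Expression is features x samples on a log2-like scale with unit-variance
    noise.  Identical config (including seed) yields identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    feats, genes = _feature_ids(cfg, rng)
    n_feat, n = len(feats), cfg.n_samples
    if sum(cfg.module_sizes) > n_feat:
        raise ValueError("module_sizes exceed the number of features")

    meta, z = _traits(cfg, rng)
    samples = list(meta.index)

    # unit-variance noise with isoform sharing: isoforms of a gene share a
    # gene-level noise component of variance isoform_shared_var
    s = cfg.isoform_shared_var
    gene_names = sorted(set(genes))
    gene_noise = {g: rng.standard_normal(n) for g in gene_names}
    N = np.empty((n_feat, n))
    for i, (f, g) in enumerate(zip(feats, genes)):
        N[i] = np.sqrt(s) * gene_noise[g] + np.sqrt(1 - s) * rng.standard_normal(n)

    truth = SyntheticTruth()

    # module factors and per-feature shared-variance fraction r_i
    r = cfg.within_module_cor
    r_i = np.zeros(n_feat)
    F = np.zeros((n_feat, n))
    pos = 0
    for m, size in enumerate(cfg.module_sizes, start=1):
        factor = rng.standard_normal(n)
        for i in range(pos, pos + size):
            F[i] = factor
            r_i[i] = r
            truth.module_of[feats[i]] = f"M{m}"
        pos += size

    # covariate confounding with per-feature random loadings, budgeted so
    # that each feature keeps unit total variance (within-module correlation
    # stays exact in expectation)
    cov = cfg.covariate_effects
    C_cols = []
    load_sd = []
    if cov.get("age"):
        age_c = meta["AgeAtDeath"].to_numpy() - meta["AgeAtDeath"].mean()
        C_cols.append(age_c / max(age_c.std(), 1e-12))
        load_sd.append(cov["age"] * max(age_c.std(), 1e-12))
    if cov.get("sex"):
        male = (meta["Sex"] == "M").to_numpy(float)
        mc = male - male.mean()
        C_cols.append(mc / max(mc.std(), 1e-12))
        load_sd.append(cov["sex"] * max(mc.std(), 1e-12))
    if cov.get("batch"):
        for b in sorted(meta["Batch"].unique()):
            ind = (meta["Batch"] == b).to_numpy(float)
            ic = ind - ind.mean()
            C_cols.append(ic / max(ic.std(), 1e-12))
            load_sd.append(cov["batch"] * max(ic.std(), 1e-12))
    if C_cols:
        C = np.vstack(C_cols)  # q x samples, unit-variance rows
        L = rng.normal(0, 1, size=(n_feat, len(C_cols))) * np.asarray(load_sd)
        w_raw = (L**2).sum(axis=1)
        w_cap = np.minimum(w_raw, 0.5 * (1 - r_i))
        scale = np.sqrt(np.where(w_raw > 0, w_cap / np.maximum(w_raw, 1e-300), 0.0))
        Cov = (L * scale[:, None]) @ C
        w_i = w_cap
    else:
        Cov = np.zeros((n_feat, n))
        w_i = np.zeros(n_feat)

    X = (
        np.sqrt(r_i)[:, None] * F
        + Cov
        + np.sqrt(1 - r_i - w_i)[:, None] * N
    )

    # genotypes and eQTL-driven causal fan-outs
    snp_ids = [f"rs{i:05d}" for i in range(cfg.n_snps)]
    G = rng.binomial(2, cfg.snp_maf, size=(cfg.n_snps, n)).astype(float)
    geno = pd.DataFrame(G, index=snp_ids, columns=samples)

    # causal features occupy the tail of the feature list (outside modules)
    module_feat_count = sum(cfg.module_sizes)
    per_driver = 1 + cfg.n_descendants_per_driver
    need = cfg.n_drivers * per_driver
    start = n_feat - need
    if start < module_feat_count:
        raise ValueError("not enough features for the causal block")

    # trait-linked differential abundance on a random feature subset,
    # excluding the causal block so planted effects do not collide
    zs = (z - z.mean()) / z.std()
    n_de = min(int(round(cfg.de_frac * n_feat)), start)
    de_idx = rng.choice(start, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    for trait in ("CDR", "Braak", "CERAD", "PlaqueMean"):
        truth.de_direction[trait] = {}
    for i, sg in zip(de_idx, signs):
        X[i] += sg * cfg.de_effect * zs
        d = "up" if sg > 0 else "down"
        for trait in truth.de_direction:
            truth.de_direction[trait][feats[i]] = d
    for d in range(cfg.n_drivers):
        block = list(range(start + d * per_driver, start + (d + 1) * per_driver))
        drv = block[0]
        snp = snp_ids[d % cfg.n_snps]
        dose = geno.loc[snp].to_numpy()
        X[drv] = cfg.eqtl_beta * (dose - dose.mean()) + rng.standard_normal(n)
        truth.drivers.append(feats[drv])
        truth.eqtl_pairs.append((snp, feats[drv]))
        # split descendants across causal_depth layers, chaining parents
        desc = block[1:]
        layers = np.array_split(desc, max(cfg.causal_depth, 1))
        prev_layer = [drv]
        for layer in layers:
            for i in layer:
                parent = prev_layer[rng.integers(len(prev_layer))]
                xp = X[parent]
                xp = (xp - xp.mean()) / xp.std()
                X[i] = cfg.causal_beta * xp + cfg.causal_noise_sd * rng.standard_normal(n)
                truth.causal_edges.append((feats[parent], feats[i]))
            prev_layer = [i for i in layer] or prev_layer

    # MCAR missingness
    if cfg.missing_frac > 0:
        mask = rng.random(X.shape) < cfg.missing_frac
        X = np.where(mask, np.nan, X)

    expr = pd.DataFrame(X, index=feats, columns=samples)
    return expr, meta, geno, truth


def generate_pseudobulk_counts(
    config: CohortConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Cell-labeled negative-binomial count matrix with planted donor-level
    cross-cell-type couplings.

    Returns a cells x (donor, celltype, genes...) DataFrame.  Coupled gene
    pairs share a donor-level latent factor scaled by ``coupling_strength``
    acting on the log-mean of each member in its own cell type.
    """
    cfg = config
    if len(cfg.cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    if cfg.n_donors < 2:
        raise ValueError("need at least 2 donors")
    rng = np.random.default_rng(cfg.seed + 1)
    donors = [f"D{i:03d}" for i in range(cfg.n_donors)]
    genes = [f"PG{i:03d}" for i in range(cfg.n_pb_genes)]

    truth = SyntheticTruth()
    # pick disjoint gene pairs across distinct cell types
    perm = rng.permutation(cfg.n_pb_genes)
    for p in range(cfg.n_coupled_pairs):
        ga, gb = genes[perm[2 * p]], genes[perm[2 * p + 1]]
        cts = rng.choice(len(cfg.cell_types), size=2, replace=False)
        truth.crosscell_pairs.append(
            ((ga, cfg.cell_types[cts[0]]), (gb, cfg.cell_types[cts[1]]))
        )

    base_log_mu = rng.normal(np.log(cfg.pb_base_mean), 0.4, cfg.n_pb_genes)
    donor_latent = rng.standard_normal(cfg.n_donors)

    rows, labels = [], []
    disp = cfg.nb_dispersion  # NB size parameter = 1/disp
    size = 1.0 / disp
    for di, donor in enumerate(donors):
        for ct in cfg.cell_types:
            log_mu = base_log_mu.copy()
            # donor-level random shift (library/biology variation)
            log_mu = log_mu + rng.normal(0, 0.1)
            for (ga, cta), (gb, ctb) in truth.crosscell_pairs:
                if ct == cta:
                    log_mu[genes.index(ga)] += cfg.coupling_strength * donor_latent[di]
                if ct == ctb:
                    log_mu[genes.index(gb)] += cfg.coupling_strength * donor_latent[di]
            mu = np.exp(log_mu)
            ncells = cfg.cells_per_donor_type
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p[None, :].repeat(ncells, 0))
            for c in range(ncells):
                rows.append(counts[c])
                labels.append((donor, ct))

    df = pd.DataFrame(np.asarray(rows), columns=genes)
    df.insert(0, "celltype", [ct for _, ct in labels])
    df.insert(0, "donor", [d for d, _ in labels])
    df.index = [f"cell{i:06d}" for i in range(len(df))]
    return df, truth


def write_fixture_bundle(
    dir_path: str | Path,
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    genotypes: pd.DataFrame,
    truth: SyntheticTruth,
    config: CohortConfig,
    counts: pd.DataFrame | None = None,
) -> dict:
    """Write the cohort as TSV/GMT files plus a JSON manifest.

    The manifest records each file's role and the generator seed; files
    round-trip bit-exactly through :mod:`proteoscale.io`.
    """
    if expression.empty:
        raise ValueError("empty cohort")
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    io.write_matrix(expression, d / "expression.tsv", index_label="feature")
    metadata.to_csv(d / "metadata.tsv", sep="\t", index_label="sample")
    io.write_matrix(genotypes, d / "genotypes.tsv", index_label="snp")
    truth.to_json(d / "truth.json")

    # signatures: planted module memberships and DE direction sets
    sigs: dict[str, set[str]] = {}
    for f, m in truth.module_of.items():
        sigs.setdefault(f"module_{m}", set()).add(f)
    for trait, dirs in truth.de_direction.items():
        for f, dr in dirs.items():
            sigs.setdefault(f"de_{trait}_{dr}", set()).add(f)
    io.write_gmt(sigs, d / "signatures.gmt")

    manifest = {
        "seed": config.seed,
        "files": {
            "expression.tsv": "features x samples expression matrix",
            "metadata.tsv": "per-sample clinical metadata",
            "genotypes.tsv": "snp x sample dosage matrix",
            "truth.json": "planted ground truth",
            "signatures.gmt": "planted module and DE signatures",
        },
        "config": dataclasses.asdict(config),
    }
    if counts is not None:
        counts.to_csv(d / "counts.tsv", sep="\t", index_label="cell")
        manifest["files"]["counts.tsv"] = "cell-labeled count matrix"
    io.write_manifest(manifest, d / "manifest.json")
    return manifest
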