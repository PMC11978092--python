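"""Synthetic multi-omics / drug-response data with planted, known structure.

The generator emulates the statistical shape of the real inputs the
pipeline is designed for — pathway-coherent expression shifts,
pathway-enriched damaging mutations, ploidy-scaled copy-number
categories, valid drug SMILES, and responses driven by drug-specific
target pathways plus noise — so every stage of the pipeline can be
exercised and tested without any downloads.

The response surface is wired through the *computed* expression
pathway-difference feature of each drug's target pathway (not the raw
planted shift), so the full feature pipeline sits on the causal path from
data to response:

    y(c, d) = intercept + offset_d − β · feature_expr(c, target_d) + ε,
    ε ~ N(0, noise_sd²).

Classifier labels are Bernoulli draws from a logistic transform of −y
(lower LN IC50 — more sensitive — means higher response probability).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureConfig, PathwayFeatureMatrix, compute_pathway_features
from .genesets import GeneSetCollection, write_gmt
from .omics import OmicsMatrix, write_omics_csv, write_ploidy

#: Hand-checked valid SMILES spanning rings, halogens, bracket atoms,
#: charges, stereocenters and %nn ring closures, to exercise every
#: tokenizer class.
SMILES_LIBRARY: tuple[str, ...] = (
    "CCO", "CC(=O)O", "CCN", "CCOCC", "CC(C)O", "C1CCCCC1", "C1CCCC1", "C1CC1",
    "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1", "Nc1ccccc1", "Clc1ccccc1",
    "Brc1ccccc1", "Fc1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1c[nH]cn1",
    "c1cn[nH]c1", "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1",
    "CC(=O)Oc1ccccc1C(=O)O", "CC(=O)Nc1ccc(O)cc1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CN1CCC[C@H]1c1cccnc1", "O=[N+]([O-])c1ccccc1", "C[N+](C)(C)C",
    "[O-]C(=O)c1ccccc1", "OC[C@H](O)[C@@H](O)CO", "N[C@@H](C)C(=O)O",
    "N[C@@H](Cc1ccccc1)C(=O)O", "CSCC[C@H](N)C(=O)O", "OC(=O)CCC(=O)O",
    "C/C=C/C(=O)O", "C#N", "CC#N", "C#Cc1ccccc1", "CC(=O)c1ccccc1",
    "COc1ccccc1", "CCOC(=O)c1ccccc1", "NS(=O)(=O)c1ccccc1", "CS(=O)(=O)N",
    "O=C1CCCCC1", "O=C1CCCN1", "C%10CCCCC%10", "c1ccc2c(c1)oc1ccccc12",
    "OCC1OC(O)C(O)C(O)C1O", "CC1=CC(=O)CC(C)(C)C1", "[Na+].[Cl-]", "ClCCl",
    "ClC(Cl)Cl", "BrCCBr",
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle."""

    n_genes: int = 1000
    n_pathways: int = 50
    set_size_min: int = 10
    set_size_max: int = 50
    n_cell_lines: int = 200
    n_drugs: int = 30
    expression_shift: float = 1.0       # δ, in baseline-sd units
    pathway_active_rate: float = 0.3    # P(pathway active in a cell line)
    mutation_base_rate: float = 0.02
    mutation_enriched_rate: float = 0.2
    mutation_high_freq_rate: float = 0.1  # P(status 2 | mutated)
    cnv_alteration_rate: float = 0.05
    cnv_enriched_rate: float = 0.3      # alteration rate in active pathways
    ploidy_min: float = 1.8
    ploidy_max: float = 4.2
    response_intercept: float = 2.5
    drug_offset_sd: float = 1.0
    effect_size: float = 1.0            # β on the target-pathway feature
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.pathway_active_rate, self.mutation_base_rate,
            self.mutation_enriched_rate, self.mutation_high_freq_rate,
            self.cnv_alteration_rate, self.cnv_enriched_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must be in [0, 1]")
        if self.set_size_max > self.n_genes:
            raise ValueError("set sizes cannot exceed the number of genes")
        if self.n_drugs > len(SMILES_LIBRARY):
            raise ValueError(
                f"n_drugs={self.n_drugs} exceeds the bundled SMILES library "
                f"({len(SMILES_LIBRARY)})"
            )


@dataclass
class SimTruth:
    """The planted ground truth, sufficient to regenerate every response."""

    active_pathways: dict[str, list[str]]     # cell line -> pathway names
    drug_targets: dict[str, str]              # drug -> target pathway
    drug_offsets: dict[str, float]
    intercept: float
    effect_size: float
    noise_sd: float
    noise: dict[str, float]                   # "cell|drug" -> drawn noise
    target_features: dict[str, float]         # "cell|drug" -> feature used

    def noise_free_response(self, cell_line: str, drug: str) -> float:
        key = f"{cell_line}|{drug}"
        return (
            self.intercept
            + self.drug_offsets[drug]
            - self.effect_size * self.target_features[key]
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=0, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimBundle:
    """Everything simulate() produces, in pipeline-native containers."""

    config: SimConfig
    gene_sets: GeneSetCollection
    expression: OmicsMatrix
    mutation: OmicsMatrix
    cnv: OmicsMatrix
    drugs: list[tuple[str, str]]              # (drug_id, smiles)
    responses: pd.DataFrame                   # cell_line, drug, response, label
    truth: SimTruth
    expression_features: PathwayFeatureMatrix


def simulate(config: SimConfig | None = None) -> SimBundle:
    """Generate a complete synthetic bundle under the given conditions."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    cell_lines = [f"CL{i:03d}" for i in range(config.n_cell_lines)]
    pathway_names = [f"PATHWAY_{i:02d}" for i in range(config.n_pathways)]

    sets: dict[str, list[str]] = {}
    for name in pathway_names:
        size = int(rng.integers(config.set_size_min, config.set_size_max + 1))
        members = rng.choice(config.n_genes, size=size, replace=False)
        sets[name] = [genes[i] for i in sorted(members)]
    collection = GeneSetCollection(sets, universe=list(genes))
    member_idx = {
        name: np.array([genes.index(g) for g in sets[name]]) for name in pathway_names
    }

    # Active (cell line, pathway) pairs drive all three planted omics signals.
    active = rng.random((config.n_cell_lines, config.n_pathways)) < config.pathway_active_rate
    active_pathways = {
        c: [pathway_names[k] for k in np.flatnonzero(active[i])]
        for i, c in enumerate(cell_lines)
    }

    # Expression: standard-normal baseline + δ on active-pathway genes.
    expr = rng.normal(0.0, 1.0, size=(config.n_cell_lines, config.n_genes))
    for i in range(config.n_cell_lines):
        for k in np.flatnonzero(active[i]):
            expr[i, member_idx[pathway_names[k]]] += config.expression_shift
    expression = OmicsMatrix("expression", cell_lines, genes, expr)

    # Mutations: Bernoulli at the base rate, enriched inside active pathways;
    # a mutated gene gets status 2 with a small conditional probability.
    mut_rate = np.full((config.n_cell_lines, config.n_genes), config.mutation_base_rate)
    for i in range(config.n_cell_lines):
        for k in np.flatnonzero(active[i]):
            mut_rate[i, member_idx[pathway_names[k]]] = config.mutation_enriched_rate
    mutated = rng.random(mut_rate.shape) < mut_rate
    high = rng.random(mut_rate.shape) < config.mutation_high_freq_rate
    mut = np.where(mutated, np.where(high, 2.0, 1.0), 0.0)
    mutation = OmicsMatrix("mutation", cell_lines, genes, mut)

    # Copy number: ratios near 2/ploidy (absolute copy number 2) with
    # amplified/deleted blocks, enriched inside active pathways.
    ploidy = {
        c: float(rng.uniform(config.ploidy_min, config.ploidy_max)) for c in cell_lines
    }
    alt_rate = np.full((config.n_cell_lines, config.n_genes), config.cnv_alteration_rate)
    for i in range(config.n_cell_lines):
        for k in np.flatnonzero(active[i]):
            alt_rate[i, member_idx[pathway_names[k]]] = config.cnv_enriched_rate
    altered = rng.random(alt_rate.shape) < alt_rate
    amplified = rng.random(alt_rate.shape) < 0.5
    absolute = np.where(altered, np.where(amplified, 4.0, 1.0), 2.0)
    pl = np.array([ploidy[c] for c in cell_lines])[:, None]
    ratios = absolute / pl * (1.0 + rng.normal(0.0, 0.02, size=absolute.shape))
    ratios = np.clip(ratios, 0.0, None)
    cnv = OmicsMatrix("cnv_ratio", cell_lines, genes, ratios, ploidy=ploidy)

    # Drugs: sampled from the bundled library; one target pathway each.
    lib = rng.permutation(len(SMILES_LIBRARY))[: config.n_drugs]
    drugs = [(f"D{j:02d}", SMILES_LIBRARY[i]) for j, i in enumerate(lib)]
    drug_targets = {
        d: pathway_names[int(rng.integers(config.n_pathways))] for d, _ in drugs
    }
    drug_offsets = {
        d: float(rng.normal(0.0, config.drug_offset_sd)) for d, _ in drugs
    }

    # Responses wired through the computed expression pathway feature.
    expr_features = compute_pathway_features(expression, collection, FeatureConfig())
    path_col = {p: k for k, p in enumerate(pathway_names)}
    rows = []
    noise_store: dict[str, float] = {}
    feature_store: dict[str, float] = {}
    for i, c in enumerate(cell_lines):
        for d, _ in drugs:
            feat = float(expr_features.values[i, path_col[drug_targets[d]]])
            eps = float(rng.normal(0.0, config.noise_sd))
            y = (
                config.response_intercept
                + drug_offsets[d]
                - config.effect_size * feat
                + eps
            )
            key = f"{c}|{d}"
            noise_store[key] = eps
            feature_store[key] = feat
            rows.append({"cell_line": c, "drug": d, "response": y})
    responses = pd.DataFrame(rows)
    # Classifier labels: logistic transform of -y (sensitive -> responder).
    y = responses["response"].to_numpy()
    prob = 1.0 / (1.0 + np.exp((y - y.mean()) / max(y.std(), 1e-12)))
    responses["label"] = (rng.random(len(y)) < prob).astype(int)

    truth = SimTruth(
        active_pathways=active_pathways,
        drug_targets=drug_targets,
        drug_offsets=drug_offsets,
        intercept=config.response_intercept,
        effect_size=config.effect_size,
        noise_sd=config.noise_sd,
        noise=noise_store,
        target_features=feature_store,
    )
    return SimBundle(
        config=config,
        gene_sets=collection,
        expression=expression,
        mutation=mutation,
        cnv=cnv,
        drugs=drugs,
        responses=responses,
        truth=truth,
        expression_features=expr_features,
    )


def write_fixture_bundle(bundle: SimBundle, path: str | Path) -> dict:
    """Write the bundle as GMT + CSVs + truth JSON; return a manifest.

    The manifest records a sha256 checksum per file, so identical seeds
    can be verified to produce identical bundles.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
    write_omics_csv(bundle.expression, out / "expression.csv")
    write_omics_csv(bundle.mutation, out / "mutation.csv")
    write_omics_csv(bundle.cnv, out / "cnv_ratio.csv")
    write_ploidy(bundle.cnv.ploidy, out / "ploidy.csv")
    pd.DataFrame(bundle.drugs, columns=["drug_id", "smiles"]).to_csv(
        out / "drugs.csv", index=False
    )
    bundle.responses.to_csv(out / "responses.csv", index=False)
    bundle.truth.to_json(out / "truth.json")
    bundle.expression_features.write_csv(out / "expression_features.csv")
    manifest = {"seed": bundle.config.seed, "files": {}}
    for f in sorted(out.iterdir()):
        if f.name == "manifest.json":
            continue
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
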