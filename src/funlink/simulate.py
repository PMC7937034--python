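"""Synthetic benchmark bundles with planted functional-module structure.

The generator emulates the statistical structure that multi-evidence
functional-association inference assumes: genes are partitioned into
functional modules, and every evidence category carries a module signal —

* a dense within-module / sparse between-module "truth" interactome;
* expression with a block-exchangeable correlation structure (Gaussian
  one-factor-per-module model: within-module Pearson correlation
  ``rho_within``, between-module ``rho_between``);
* module-characteristic annotation terms, subcellular compartments,
  protein domains (with interacting domain pairs seeded within module
  domain pools) and phylogenetic presence patterns, each corrupted by a
  per-category noise rate;
* interolog evidence as a second, independently drawn module-structured
  pair set (deliberately *not* a copy of the truth edges, so evidence is
  informative about labels only through module membership — and exactly
  uninformative in the no-structure null bundle);
* gold-standard interactions sampled from the truth edges with study
  counts and throughput flags covering both branches of the quality
  filter;
* an annotation corpus split per gene into "old" and "new" layers for
  the guilt-by-association benchmark.

``null_bundle`` equalises the within/between rates, removing all planted
structure; it backs the type-I-error and AUC-0.5 property tests.
All outputs are deterministic functions of the config (including seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import GoldInteraction, read_gold_table, write_gold_table
from .errors import ConfigError
from .evidence import EvidenceBundle, pair_key
from .gba import (
    AnnotationCorpus,
    read_annotation_table,
    write_annotation_table,
)
from .gsla import GeneSet, GeneSetCollection, read_gmt, write_gmt
from .interactome import (
    Interactome,
    read_edge_list_with_isolated,
    write_edge_list,
)


@dataclasses.dataclass(frozen=True)
class FixtureConfig:
    """Generator settings; defaults give a desk-scale planted benchmark.

    ``rho_*`` are pairwise expression correlations, ``p_edge_*`` the truth
    interactome edge probabilities, within and between modules.  Noise
    rates are per-category corruption probabilities in [0, 1].
    """

    n_genes: int = 1000
    n_modules: int = 200
    module_size_range: tuple[int, int] = (4, 6)
    n_conditions: int = 30
    rho_within: float = 0.7
    rho_between: float = 0.05
    p_edge_within: float = 0.5
    p_edge_between: float = 0.0001
    terms_per_module: int = 3
    compartments_per_module: int = 2
    domains_per_module: int = 4
    n_species: int = 25
    annotation_noise: float = 0.1
    localization_noise: float = 0.1
    domain_noise: float = 0.1
    phylo_flip: float = 0.1
    interolog_p_within: float = 0.15
    interolog_p_between: float = 0.0005
    n_gold: int = 70
    new_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.module_size_range
        if not (self.n_modules * lo <= self.n_genes <= self.n_modules * hi):
            raise ConfigError(
                f"{self.n_genes} genes cannot be split into {self.n_modules} "
                f"modules of size {lo}..{hi}"
            )
        # equality allowed so that null_bundle (no planted structure) is a
        # valid configuration; planted bundles should use strict inequality
        if self.rho_within < self.rho_between:
            raise ConfigError("rho_within must be >= rho_between")
        if self.p_edge_within < self.p_edge_between:
            raise ConfigError("p_edge_within must be >= p_edge_between")
        for name in (
            "rho_within", "rho_between", "p_edge_within", "p_edge_between",
            "annotation_noise", "localization_noise", "domain_noise",
            "phylo_flip", "interolog_p_within", "interolog_p_between",
            "new_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_conditions < 2 or self.n_species < 2:
            raise ConfigError("need >= 2 conditions and >= 2 species")
        if self.n_gold < 0:
            raise ConfigError("n_gold must be non-negative")


@dataclasses.dataclass
class FixtureBundle:
    """Everything the other modules consume, generated from one config."""

    truth: Interactome
    evidence: EvidenceBundle
    gold: list[GoldInteraction]
    corpus: AnnotationCorpus
    sets: GeneSetCollection
    module_of: dict[str, int]
    manifest: dict


def _module_sizes(cfg: FixtureConfig, rng: np.random.Generator) -> list[int]:
    lo, hi = cfg.module_size_range
    sizes = [cfg.n_genes // cfg.n_modules] * cfg.n_modules
    for i in range(cfg.n_genes % cfg.n_modules):
        sizes[i] += 1
    # random transfers inside the allowed range
    for _ in range(cfg.n_modules * 4):
        i, j = rng.integers(0, cfg.n_modules, size=2)
        if i != j and sizes[i] < hi and sizes[j] > lo:
            sizes[i] += 1
            sizes[j] -= 1
    return sizes


def generate(cfg: FixtureConfig) -> FixtureBundle:
    """Generate a planted-module benchmark bundle (deterministic per config)."""
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]

    sizes = _module_sizes(cfg, rng)
    module_of: dict[str, int] = {}
    modules: list[list[str]] = []
    pos = 0
    for m, s in enumerate(sizes):
        block = genes[pos:pos + s]
        modules.append(block)
        for g in block:
            module_of[g] = m
        pos += s

    # ---- truth interactome + interolog evidence (independent draws) ----
    truth = Interactome(genes=genes)
    interologs: set[tuple[str, str]] = set()
    mod_idx = np.array([module_of[g] for g in genes])
    for i in range(cfg.n_genes):
        same = mod_idx[i + 1:] == mod_idx[i]
        p_edge = np.where(same, cfg.p_edge_within, cfg.p_edge_between)
        p_olog = np.where(same, cfg.interolog_p_within, cfg.interolog_p_between)
        draw_e = rng.random(p_edge.size) < p_edge
        draw_o = rng.random(p_olog.size) < p_olog
        for off in np.nonzero(draw_e)[0]:
            j = i + 1 + int(off)
            truth.add_edge(genes[i], genes[j], score=round(float(rng.uniform(0.5, 1.0)), 6))
        for off in np.nonzero(draw_o)[0]:
            j = i + 1 + int(off)
            interologs.add(pair_key(genes[i], genes[j]))

    # ---- expression: one global + one per-module factor -----------------
    rb, rw = cfg.rho_between, cfg.rho_within
    z_global = rng.standard_normal(cfg.n_conditions)
    z_module = rng.standard_normal((cfg.n_modules, cfg.n_conditions))
    eps = rng.standard_normal((cfg.n_genes, cfg.n_conditions))
    expr = (
        np.sqrt(rb) * z_global
        + np.sqrt(max(rw - rb, 0.0)) * z_module[mod_idx]
        + np.sqrt(max(1.0 - rw, 0.0)) * eps
    )
    expression = pd.DataFrame(
        np.round(expr, 6), index=pd.Index(genes, name="gene"),
        columns=[f"cond{k + 1:02d}" for k in range(cfg.n_conditions)],
    )

    # ---- annotations (full corpus; old/new split afterwards) ------------
    module_terms = [
        [f"T{m:02d}_{k}" for k in range(cfg.terms_per_module)]
        for m in range(cfg.n_modules)
    ]
    noise_terms = [f"TN_{k}" for k in range(2 * cfg.n_modules)]
    annotations: dict[str, set[str]] = {}
    for g in genes:
        terms = {
            t for t in module_terms[module_of[g]]
            if rng.random() >= cfg.annotation_noise
        }
        if rng.random() < cfg.annotation_noise:
            terms.add(noise_terms[int(rng.integers(0, len(noise_terms)))])
        annotations[g] = terms

    old: dict[str, set[str]] = {}
    new: dict[str, set[str]] = {}
    for g in genes:
        for t in sorted(annotations[g]):
            (new if rng.random() < cfg.new_fraction else old).setdefault(g, set()).add(t)
    corpus = AnnotationCorpus(old=old, new=new)

    # ---- localizations ---------------------------------------------------
    module_comps = [
        [f"C{m:02d}_{k}" for k in range(cfg.compartments_per_module)]
        for m in range(cfg.n_modules)
    ]
    noise_comps = [f"CN_{k}" for k in range(cfg.n_modules)]
    localizations: dict[str, set[str]] = {}
    for g in genes:
        comps = {
            c for c in module_comps[module_of[g]]
            if rng.random() >= cfg.localization_noise
        }
        if rng.random() < cfg.localization_noise:
            comps.add(noise_comps[int(rng.integers(0, len(noise_comps)))])
        localizations[g] = comps

    # ---- domains + interacting domain pairs ------------------------------
    module_domains = [
        [f"D{m:02d}_{k}" for k in range(cfg.domains_per_module)]
        for m in range(cfg.n_modules)
    ]
    all_domains = [d for pool in module_domains for d in pool]
    domains: dict[str, set[str]] = {}
    for g in genes:
        pool = module_domains[module_of[g]]
        k = int(rng.integers(1, min(3, len(pool)) + 1))
        chosen = set(rng.choice(pool, size=k, replace=False).tolist())
        if rng.random() < cfg.domain_noise:
            chosen.add(all_domains[int(rng.integers(0, len(all_domains)))])
        domains[g] = chosen
    domain_interactions: dict[tuple[str, str], float] = {}
    for m, pool in enumerate(module_domains):
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if rng.random() < 0.8:
                    domain_interactions[pair_key(pool[i], pool[j])] = round(
                        float(rng.uniform(0.5, 1.0)), 6
                    )
    for i in range(len(all_domains)):
        for j in range(i + 1, len(all_domains)):
            p = pair_key(all_domains[i], all_domains[j])
            if p not in domain_interactions and rng.random() < 0.01:
                domain_interactions[p] = round(float(rng.uniform(0.05, 0.5)), 6)

    # ---- phylogenetic profiles ------------------------------------------
    patterns = rng.integers(0, 2, size=(cfg.n_modules, cfg.n_species))
    flips = rng.random((cfg.n_genes, cfg.n_species)) < cfg.phylo_flip
    prof = np.where(flips, 1 - patterns[mod_idx], patterns[mod_idx])
    phylo = pd.DataFrame(
        prof.astype(int), index=pd.Index(genes, name="gene"),
        columns=[f"sp{k + 1:02d}" for k in range(cfg.n_species)],
    )

    evidence = EvidenceBundle(
        expression=expression,
        annotations={g: set(t) for g, t in old.items()},  # "known" layer only
        localizations=localizations,
        domains=domains,
        domain_interactions=domain_interactions,
        phylo_profiles=phylo,
        interologs=interologs,
    )

    # ---- gold standard ----------------------------------------------------
    edges = sorted(truth.edge_pairs())
    n_gold = min(cfg.n_gold, len(edges))
    gold: list[GoldInteraction] = []
    if n_gold:
        picked = rng.choice(len(edges), size=n_gold, replace=False)
        for k in sorted(int(x) for x in picked):
            a, b = edges[k]
            gold.append(
                GoldInteraction(
                    a, b,
                    n_studies=int(rng.integers(1, 4)),
                    has_low_throughput=bool(rng.random() < 0.5),
                )
            )

    # ---- gene sets ---------------------------------------------------------
    sets = GeneSetCollection(
        GeneSet(
            f"module_{m + 1:02d}",
            f"planted functional module {m + 1}",
            frozenset(block),
        )
        for m, block in enumerate(modules)
    )

    manifest = {
        "config": {**dataclasses.asdict(cfg),
                   "module_size_range": list(cfg.module_size_range)},  # JSON-clean
        "n_truth_edges": truth.n_edges,
        "n_gold": len(gold),
        "n_interologs": len(interologs),
        "module_sizes": sizes,
    }
    return FixtureBundle(
        truth=truth,
        evidence=evidence,
        gold=gold,
        corpus=corpus,
        sets=sets,
        module_of=module_of,
        manifest=manifest,
    )


def null_bundle(cfg: FixtureConfig) -> FixtureBundle:
    """As :func:`generate` but with the within-module rates equalised to the
    between-module rates: no planted structure relating evidence to edges."""
    flat = dataclasses.replace(
        cfg,
        rho_within=cfg.rho_between,
        p_edge_within=cfg.p_edge_between,
        interolog_p_within=cfg.interolog_p_between,
    )
    return generate(flat)


# ---------------------------------------------------------------------
# Bundle IO (all plain TSV / GMT / JSON; deterministic bytes)
# ---------------------------------------------------------------------

def _write_pairs(pairs, path: Path, cols: tuple[str, str]) -> None:
    with path.open("w") as fh:
        fh.write(f"{cols[0]}\t{cols[1]}\n")
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> None:
    """Write every artefact of the bundle as plain text under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_list(bundle.truth, out / "truth_edges.tsv")
    ev = bundle.evidence
    ev.expression.to_csv(out / "expression.tsv", sep="\t", float_format="%.6f")
    ev.phylo_profiles.to_csv(out / "phylo_profiles.tsv", sep="\t")
    write_annotation_table(bundle.corpus.old, out / "annotations_old.tsv")
    write_annotation_table(bundle.corpus.new, out / "annotations_new.tsv")
    write_annotation_table(ev.localizations, out / "localizations.tsv")  # gene/term cols
    write_annotation_table(ev.domains, out / "domains.tsv")
    with (out / "domain_interactions.tsv").open("w") as fh:
        fh.write("domainA\tdomainB\tscore\n")
        for (a, b), s in sorted(ev.domain_interactions.items()):
            fh.write(f"{a}\t{b}\t{s:.6f}\n")
    _write_pairs(ev.interologs, out / "interologs.tsv", ("geneA", "geneB"))
    write_gold_table(bundle.gold, out / "gold_standard.tsv")
    write_gmt(bundle.sets, out / "gene_sets.gmt")
    with (out / "modules.tsv").open("w") as fh:
        fh.write("gene\tmodule\n")
        for g in sorted(bundle.module_of):
            fh.write(f"{g}\t{bundle.module_of[g]}\n")
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n"
    )


def load_bundle(indir: str | Path) -> FixtureBundle:
    """Reconstruct a bundle from :func:`write_bundle` output."""
    ind = Path(indir)
    manifest = json.loads((ind / "manifest.json").read_text())
    truth = read_edge_list_with_isolated(ind / "truth_edges.tsv")
    expression = pd.read_csv(ind / "expression.tsv", sep="\t", index_col="gene")
    phylo = pd.read_csv(ind / "phylo_profiles.tsv", sep="\t", index_col="gene")
    old = read_annotation_table(ind / "annotations_old.tsv")
    new = read_annotation_table(ind / "annotations_new.tsv")
    localizations = read_annotation_table(ind / "localizations.tsv")
    domains = read_annotation_table(ind / "domains.tsv")
    di_df = pd.read_csv(ind / "domain_interactions.tsv", sep="\t", dtype={"score": float})
    domain_interactions = {
        pair_key(r.domainA, r.domainB): float(r.score)
        for r in di_df.itertuples(index=False)
    }
    il_df = pd.read_csv(ind / "interologs.tsv", sep="\t")
    interologs = {pair_key(r.geneA, r.geneB) for r in il_df.itertuples(index=False)}
    gold = read_gold_table(ind / "gold_standard.tsv")
    sets = read_gmt(ind / "gene_sets.gmt")
    mod_df = pd.read_csv(ind / "modules.tsv", sep="\t")
    module_of = {r.gene: int(r.module) for r in mod_df.itertuples(index=False)}
    evidence = EvidenceBundle(
        expression=expression,
        annotations=old,
        localizations=localizations,
        domains=domains,
        domain_interactions=domain_interactions,
        phylo_profiles=phylo,
        interologs=interologs,
    )
    return FixtureBundle(
        truth=truth,
        evidence=evidence,
        gold=gold,
        corpus=AnnotationCorpus(old=old, new=new),
        sets=sets,
        module_of=module_of,
        manifest=manifest,
    )
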