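"""Ground-truth-known synthetic microbiome worlds.

The generator emulates the statistical structure the modeling pipeline
assumes, at desk scale:

* sparse compositional samples — presence/absence driven by co-occurrence
  *blocks* (guilds of taxa that tend to appear together), abundances drawn
  log-normal and renormalized to sum 1;
* a taxonomy whose phyla contain whole blocks, so block-driven contextual
  structure should cluster by phylum;
* binary pathway annotations correlated with blocks;
* vocabulary embeddings built as block mean + noise (structured inputs for
  the frozen embedding layer, analogous to co-occurrence-trained vectors);
* planted phenotype effects — a set of taxa whose presence probability
  differs between positive and negative patients — plus patient structure
  (multiple samples per patient sharing the patient's label).

World-level structure (taxa, blocks, taxonomy, pathways, embeddings) is
derived from ``structure_seed`` so that distribution-shifted worlds over
the same vocabulary can be generated by varying the sampling parameters
and ``seed`` only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import (
    TAXONOMY_RANKS,
    AbundanceTable,
    EmbeddingMatrix,
    TaxonomyMap,
    TaxonVocabulary,
    write_abundance_table,
    write_embedding_matrix,
    write_labels,
    write_pathway_matrix,
    write_taxonomy,
)

PHYLUM_NAMES = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
                "Fusobacteria", "Verrucomicrobia")


@dataclass
class SyntheticConfig:
    n_taxa: int = 300
    n_samples: int = 1000
    n_blocks: int = 10
    n_phyla: int = 4
    block_activation_prob: float = 0.25
    within_block_presence: float = 0.35
    base_prevalence: float = 0.02
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    n_pathways: int = 25
    pathway_in_block: float = 0.8
    pathway_out_block: float = 0.05
    n_planted: int = 6
    planted_prevalence_positive: float = 0.8
    planted_prevalence_negative: float = 0.1
    planted_taxa: list[str] | None = None
    positive_fraction: float = 0.35
    samples_per_patient: int = 2
    embed_dim: int = 100
    embedding_noise: float = 0.5
    genus_missing_prob: float = 0.2
    seed: int = 0
    structure_seed: int | None = None  # defaults to seed

    def __post_init__(self):
        for name in ("block_activation_prob", "within_block_presence",
                     "base_prevalence", "planted_prevalence_positive",
                     "planted_prevalence_negative", "positive_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_blocks > self.n_taxa:
            raise ValueError("n_blocks must be <= n_taxa")
        if self.n_phyla > self.n_blocks:
            raise ValueError("n_phyla must be <= n_blocks")
        if self.n_planted > self.n_taxa:
            raise ValueError("n_planted must be <= n_taxa")
        if self.base_prevalence == 0 and self.block_activation_prob == 0:
            raise ValueError("infeasible config: samples would contain no taxa")


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    abundance: AbundanceTable
    labels: pd.DataFrame  # index sample_id; columns label, patient_id
    taxonomy: TaxonomyMap
    pathways: pd.DataFrame
    embeddings: EmbeddingMatrix
    truth: dict = field(default_factory=dict)

    def vocabulary(self) -> TaxonVocabulary:
        return TaxonVocabulary(self.abundance.taxon_ids)

    def label_array(self) -> np.ndarray:
        return self.labels["label"].to_numpy()

    def patient_array(self) -> np.ndarray:
        return self.labels["patient_id"].to_numpy()

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_abundance_table(self.abundance, outdir / "abundance.tsv")
        write_labels(self.labels, outdir / "labels.tsv")
        write_taxonomy(self.taxonomy, outdir / "taxonomy.tsv")
        write_pathway_matrix(self.pathways, outdir / "pathways.tsv")
        write_embedding_matrix(self.embeddings, outdir / "embeddings.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str)


def _structure(cfg: SyntheticConfig):
    """World-level structure from structure_seed: taxa, blocks, taxonomy,
    pathways, embeddings."""
    srng = np.random.Generator(np.random.PCG64(
        cfg.seed if cfg.structure_seed is None else cfg.structure_seed))
    taxon_ids = [f"ASV{i:04d}" for i in range(cfg.n_taxa)]
    per_block = cfg.n_taxa // cfg.n_blocks
    blocks = np.minimum(np.arange(cfg.n_taxa) // max(per_block, 1), cfg.n_blocks - 1)

    # taxonomy: phyla contain whole blocks; ranks nest below the block
    blocks_per_phylum = int(np.ceil(cfg.n_blocks / cfg.n_phyla))
    phylum_of_block = np.minimum(np.arange(cfg.n_blocks) // blocks_per_phylum,
                                 cfg.n_phyla - 1)
    tax_rows = []
    for i in range(cfg.n_taxa):
        b = blocks[i]
        genus = f"Genus_b{b}_{i % 3}"
        if srng.random() < cfg.genus_missing_prob:
            genus = np.nan
        tax_rows.append({
            "phylum": PHYLUM_NAMES[phylum_of_block[b] % len(PHYLUM_NAMES)],
            "class": f"Class_b{b}",
            "order": f"Order_b{b}",
            "family": f"Family_b{b}_{i % 2}",
            "genus": genus,
        })
    taxonomy = TaxonomyMap(pd.DataFrame(tax_rows, index=taxon_ids,
                                        columns=list(TAXONOMY_RANKS)))

    # pathways: each pathway tied to 1-2 blocks
    pw = np.zeros((cfg.n_taxa, cfg.n_pathways), dtype=np.int8)
    pathway_blocks = []
    for j in range(cfg.n_pathways):
        k = int(srng.integers(1, 3))
        chosen = srng.choice(cfg.n_blocks, size=k, replace=False)
        pathway_blocks.append(sorted(int(b) for b in chosen))
        in_block = np.isin(blocks, chosen)
        p = np.where(in_block, cfg.pathway_in_block, cfg.pathway_out_block)
        pw[:, j] = srng.random(cfg.n_taxa) < p
    pathways = pd.DataFrame(pw, index=taxon_ids,
                            columns=[f"pathway{j:03d}" for j in range(cfg.n_pathways)])

    # embeddings: block mean + noise
    means = srng.standard_normal((cfg.n_blocks, cfg.embed_dim))
    emb = means[blocks] + cfg.embedding_noise * srng.standard_normal(
        (cfg.n_taxa, cfg.embed_dim))
    embeddings = EmbeddingMatrix(pd.DataFrame(emb, index=taxon_ids))

    # planted effect taxa: spread across blocks unless given explicitly
    if cfg.planted_taxa is not None:
        planted = [taxon_ids.index(t) for t in cfg.planted_taxa]
        if any(t not in taxon_ids for t in cfg.planted_taxa):
            raise ValueError("planted taxon not in world")
    else:
        # spread planted taxa across blocks, wrapping within blocks if
        # there are more planted taxa than blocks
        planted = [
            (b % cfg.n_blocks) * per_block + (b // cfg.n_blocks)
            for b in range(cfg.n_planted)
        ]
    return taxon_ids, blocks, taxonomy, pathways, pathway_blocks, embeddings, planted


def generate_world(cfg: SyntheticConfig) -> SyntheticWorld:
    """Draw a complete world: tables, labels, taxonomy, pathways, embeddings,
    and the ground-truth record that recovery tests compare against."""
    (taxon_ids, blocks, taxonomy, pathways, pathway_blocks, embeddings,
     planted) = _structure(cfg)
    rng = np.random.Generator(np.random.PCG64(cfg.seed))

    n_patients = int(np.ceil(cfg.n_samples / cfg.samples_per_patient))
    patient_labels = (rng.random(n_patients) < cfg.positive_fraction).astype(int)
    patient_of_sample = np.repeat(np.arange(n_patients),
                                  cfg.samples_per_patient)[: cfg.n_samples]

    planted_mask = np.zeros(cfg.n_taxa, dtype=bool)
    planted_mask[planted] = True
    presence = np.zeros((cfg.n_samples, cfg.n_taxa), dtype=bool)
    values = np.zeros((cfg.n_samples, cfg.n_taxa))
    for i in range(cfg.n_samples):
        label = patient_labels[patient_of_sample[i]]
        active = rng.random(cfg.n_blocks) < cfg.block_activation_prob
        p = np.where(active[blocks], cfg.within_block_presence, cfg.base_prevalence)
        p = np.where(planted_mask,
                     cfg.planted_prevalence_positive if label
                     else cfg.planted_prevalence_negative, p)
        pres = rng.random(cfg.n_taxa) < p
        if not pres.any():  # degenerate sample: force one taxon
            pres[rng.integers(cfg.n_taxa)] = True
        raw = np.zeros(cfg.n_taxa)
        raw[pres] = rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma,
                                  int(pres.sum()))
        values[i] = raw / raw.sum()
        presence[i] = pres

    sample_ids = [f"S{i:05d}" for i in range(cfg.n_samples)]
    abundance = AbundanceTable(pd.DataFrame(values, index=sample_ids,
                                            columns=taxon_ids))
    labels = pd.DataFrame({
        "label": patient_labels[patient_of_sample],
        "patient_id": [f"P{p:05d}" for p in patient_of_sample],
    }, index=pd.Index(sample_ids, name="sample_id"))
    abundance.patient_ids = labels["patient_id"]

    truth = {
        "blocks": {taxon_ids[i]: int(blocks[i]) for i in range(cfg.n_taxa)},
        "planted_taxa": [taxon_ids[i] for i in planted],
        "planted_prevalences": [cfg.planted_prevalence_positive,
                                cfg.planted_prevalence_negative],
        "pathway_blocks": {f"pathway{j:03d}": pathway_blocks[j]
                           for j in range(cfg.n_pathways)},
        "positive_fraction": cfg.positive_fraction,
        "config": dataclasses.asdict(cfg),
    }
    return SyntheticWorld(cfg, abundance, labels, taxonomy, pathways,
                          embeddings, truth)


def shifted_config(cfg: SyntheticConfig, seed_offset: int = 1) -> SyntheticConfig:
    """A distribution-shifted study over the same vocabulary and taxa.

    Keeps ``structure_seed`` (same taxa/taxonomy/pathways/embeddings) but
    changes community statistics and weakens — without flipping — the
    planted effects, emulating an independent cohort.
    """
    return dataclasses.replace(
        cfg,
        seed=cfg.seed + seed_offset,
        structure_seed=cfg.seed if cfg.structure_seed is None else cfg.structure_seed,
        block_activation_prob=min(1.0, cfg.block_activation_prob + 0.15),
        within_block_presence=max(0.0, cfg.within_block_presence - 0.10),
        base_prevalence=cfg.base_prevalence * 1.5,
        lognormal_sigma=cfg.lognormal_sigma * 1.5,
        planted_prevalence_positive=0.7,
        planted_prevalence_negative=0.15,
        positive_fraction=min(1.0, cfg.positive_fraction + 0.2),
    )


def null_config(cfg: SyntheticConfig, seed_offset: int = 2) -> SyntheticConfig:
    """Same world shape but label-independent presence (no planted signal)."""
    return dataclasses.replace(
        cfg,
        seed=cfg.seed + seed_offset,
        structure_seed=cfg.seed if cfg.structure_seed is None else cfg.structure_seed,
        planted_prevalence_positive=0.3,
        planted_prevalence_negative=0.3,
    )


def cooccurrence_odds_ratios(presence: np.ndarray, blocks: np.ndarray,
                             haldane: float = 0.5) -> dict[str, float]:
    """Mean log odds ratio of pairwise co-occurrence, within vs between blocks."""
    presence = presence.astype(np.int64)
    n = presence.shape[0]
    c = presence.T @ presence
    ni = np.diag(c)
    a = c.astype(float)
    b = ni[:, None] - a
    cc = ni[None, :] - a
    d = n - ni[:, None] - ni[None, :] + a
    log_or = np.log(((a + haldane) * (d + haldane)) / ((b + haldane) * (cc + haldane)))
    same = blocks[:, None] == blocks[None, :]
    upper = np.triu(np.ones_like(same, dtype=bool), k=1)
    return {
        "mean_log_or_within": float(log_or[same & upper].mean()),
        "mean_log_or_between": float(log_or[~same & upper].mean()),
    }


def world_report(world: SyntheticWorld) -> dict:
    """Summary statistics to compare against the generating configuration."""
    presence = world.abundance.values.to_numpy() > 0
    labels = world.label_array()
    blocks = np.array([world.truth["blocks"][t] for t in world.abundance.taxon_ids])
    prevalence = presence.mean(axis=0)
    planted = world.truth["planted_taxa"]
    col = {t: j for j, t in enumerate(world.abundance.taxon_ids)}
    pos, neg = labels == 1, labels == 0
    planted_prev = {
        t: {"positive": float(presence[pos, col[t]].mean()),
            "negative": float(presence[neg, col[t]].mean())}
        for t in planted
    }
    report = {
        "n_samples": int(presence.shape[0]),
        "n_taxa": int(presence.shape[1]),
        "class_balance": float(labels.mean()),
        "mean_taxa_per_sample": float(presence.sum(axis=1).mean()),
        "prevalence_min": float(prevalence.min()),
        "prevalence_max": float(prevalence.max()),
        "planted_prevalence": planted_prev,
    }
    report.update(cooccurrence_odds_ratios(presence, blocks))
    return report
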