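"""End-to-end orchestration of the synthetic study.

simulate -> round-1 pairwise search -> align/trim/filter -> gene trees +
paralog screen -> profile build -> profile re-search -> six-frame genome
rescue -> presence/absence assembly -> Dollo losses -> phi + Ward-D2
clustering -> two-group conservation + motif scan.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import numpy as np
import pandas as pd

from . import seqio
from .alphabet import blosum62
from .containers import ProteomeSet
from .coevolution import assemble_matrix, phi_matrix, ward_cluster
from .conservation_motifs import (column_conservation, logo_counts,
                                  motif_hits_to_bed, scan_caim, scan_saim,
                                  twogroup_score)
from .homology_search import (SearchHit, build_profile, calibrate_profile,
                              profile_search, search_round1, six_frame_rescue)
from .msa_processing import (GroupedMSA, filter_fragments, progressive_align,
                             trim_columns)
from .phylo import (UndefinedDistanceError, dollo_losses, neighbor_joining,
                    pairwise_distance, screen_paralogs)
from .synthetic_data import Dataset, generate_dataset, write_fixture

log = logging.getLogger("phyloprof")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_taxa: int = 12
    out_dir: Optional[str] = None
    evalue_threshold: float = 1e-5
    trim_gap_threshold: float = 0.3
    profile_trim_gap_threshold: float = 0.1
    fragment_min_data: float = 0.5
    min_orf: int = 30
    n_shuffles: int = 200
    write_fixture_files: bool = True

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("E-value threshold must be positive")
        for v in (self.trim_gap_threshold, self.profile_trim_gap_threshold,
                  self.fragment_min_data):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must be in [0, 1]")


@dataclass
class StudyResult:
    dataset: Dataset
    hits: List[SearchHit]
    screens: Dict[str, Set[str]]
    presence: pd.DataFrame
    provenance: pd.DataFrame
    losses: Dict[str, "object"]
    phi: pd.DataFrame
    dendrogram_newick: str
    twogroup: "object"
    conservation: "object"
    motif_bed: pd.DataFrame
    manifest: dict


def _family_candidates(hits: List[SearchHit], family: str,
                       proteomes: ProteomeSet) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    for h in hits:
        if h.family == family and h.target_id not in seqs:
            seqs[h.target_id] = proteomes.sequence(h.taxon, h.target_id)
    return seqs


def _best_per_taxon(hits: List[SearchHit], family: str) -> Set[str]:
    best: Dict[str, SearchHit] = {}
    for h in hits:
        if h.family != family:
            continue
        cur = best.get(h.taxon)
        if cur is None or h.raw_score > cur.raw_score:
            best[h.taxon] = h
    return {h.target_id for h in best.values()}


def _screen_family(hits: List[SearchHit], family: str, proteomes: ProteomeSet,
                   config: PipelineConfig, scoring) -> dict:
    """Align candidates, trim/filter, build a gene tree and screen paralogs.

    Returns the retained (ortholog) id set and, when buildable, the trimmed
    alignment used for profile construction. Fragment-filtered rows were
    never paralog-labelled, so they stay in the retained set.
    """
    seqs = _family_candidates(hits, family, proteomes)
    if len(seqs) < 3:
        return {"retained": set(seqs), "profile_msa": None}
    msa = progressive_align(seqs, scoring)
    msa = trim_columns(msa, config.trim_gap_threshold)
    msa = filter_fragments(msa, config.fragment_min_data)
    if msa.n_rows < 3:
        return {"retained": set(seqs), "profile_msa": None}
    references = _best_per_taxon(hits, family) & set(msa.ids)
    try:
        dm = pairwise_distance(msa)
        gene_tree = neighbor_joining(dm)
        retained = screen_paralogs(gene_tree, references or set(msa.ids))
    except UndefinedDistanceError:
        retained = set(msa.ids)
    profile_msa = msa.subset(sorted(retained & set(msa.ids)))
    profile_msa = trim_columns(profile_msa, config.profile_trim_gap_threshold)
    if profile_msa.n_rows < 2 or profile_msa.n_columns < 20:
        profile_msa = None
    return {"retained": retained | (set(seqs) - set(msa.ids)),
            "profile_msa": profile_msa}


def run_study(config: PipelineConfig,
              dataset: Optional[Dataset] = None) -> StudyResult:
    """Execute the full analysis; returns all stage outputs in memory and,
    when ``config.out_dir`` is set, writes them as plain-text files."""
    scoring = blosum62()
    if dataset is None:
        dataset = generate_dataset(n_taxa=config.n_taxa, seed=config.seed)
    proteomes = dataset.proteomes
    families = sorted(dataset.queries)
    taxa = proteomes.taxa()
    log.info("stage=simulate taxa=%d families=%d sequences=%d",
             len(taxa), len(families), proteomes.n_sequences())

    hits: List[SearchHit] = list(search_round1(
        dataset.queries, proteomes, threshold=config.evalue_threshold,
        scoring=scoring))
    log.info("stage=round1 hits=%d", len(hits))

    profiles = {}
    for family in families:
        screened = _screen_family(hits, family, proteomes, config, scoring)
        msa = screened["profile_msa"]
        if msa is None:
            continue
        profile = build_profile(msa)
        calibrate_profile(profile, proteomes, n_shuffles=config.n_shuffles,
                          seed=config.seed)
        profiles[family] = profile
    log.info("stage=profile-build families_with_profiles=%d", len(profiles))

    for family, profile in sorted(profiles.items()):
        hits.extend(profile_search(profile, proteomes,
                                   threshold=config.evalue_threshold,
                                   family=family, seed=config.seed))
    log.info("stage=profile total_hits=%d", len(hits))

    # Final paralog screen over the union of round-1 and profile candidates,
    # mirroring the re-screening after the second search iteration.
    screens: Dict[str, Set[str]] = {}
    for family in families:
        screened = _screen_family(hits, family, proteomes, config, scoring)
        screens[family] = screened["retained"]
    log.info("stage=screen families=%d", len(screens))

    for taxon, genome in sorted(proteomes.genomes.items()):
        for family, profile in sorted(profiles.items()):
            _, rescue_hits = six_frame_rescue(
                profile, genome, taxon=taxon, min_orf=config.min_orf,
                threshold=config.evalue_threshold, family=family,
                seed=config.seed)
            hits.extend(rescue_hits)
    log.info("stage=rescue total_hits=%d", len(hits))

    presence, provenance = assemble_matrix(hits, taxa, families, screens)
    log.info("stage=matrix present_entries=%d", int(presence.to_numpy().sum()))

    losses = {}
    for family in families:
        col = presence[family]
        if col.sum() == 0:
            losses[family] = None
            continue
        losses[family] = dollo_losses(dataset.tree,
                                      col.to_dict(), family=family)
    log.info("stage=losses mapped=%d", sum(v is not None for v in losses.values()))

    phi_df = phi_matrix(presence)
    dendro = ward_cluster(phi_df)
    newick = dendro.to_newick()

    msa = dataset.receptor_alignment
    tg = twogroup_score(msa, scoring)
    pos_group = msa.group_rows("ubl+")
    cons = column_conservation(pos_group if pos_group.n_rows >= 2 else msa, scoring)
    motif_hits = []
    for taxon in taxa:
        sid = f"{taxon}|receptor"
        seq = proteomes.find(sid)
        if seq:
            motif_hits.extend(scan_saim(seq, sid))
            motif_hits.extend(scan_caim(seq, sid))
    motif_bed = motif_hits_to_bed(motif_hits)
    log.info("stage=conservation columns=%d motif_hits=%d",
             msa.n_columns, len(motif_hits))

    manifest = {
        "config": dataclasses.asdict(config),
        "dataset": dataset.config,
        "n_hits": len(hits),
        "families": families,
        "taxa": taxa,
    }

    result = StudyResult(dataset=dataset, hits=hits, screens=screens,
                         presence=presence, provenance=provenance,
                         losses=losses, phi=phi_df, dendrogram_newick=newick,
                         twogroup=tg, conservation=cons, motif_bed=motif_bed,
                         manifest=manifest)
    if config.out_dir:
        write_outputs(result, config)
    return result


def write_outputs(result: StudyResult, config: PipelineConfig) -> None:
    out = seqio.ensure_dir(config.out_dir)
    if config.write_fixture_files:
        write_fixture(result.dataset, os.path.join(out, "fixture"))
    seqio.write_table(result.presence.reset_index(),
                      os.path.join(out, "presence.tsv"))
    seqio.write_table(result.provenance.reset_index(),
                      os.path.join(out, "provenance.tsv"))
    hits_df = pd.DataFrame([dataclasses.asdict(h) for h in result.hits])
    seqio.write_table(hits_df, os.path.join(out, "hits.tsv"))
    loss_rows = []
    for family, lm in sorted(result.losses.items()):
        if lm is None:
            continue
        loss_rows.append({"family": family, "gain_node": lm.gain_node,
                          "n_losses": lm.n_losses,
                          "loss_branches": ",".join(lm.loss_branches)})
    seqio.write_table(pd.DataFrame(loss_rows), os.path.join(out, "losses.tsv"))
    seqio.write_table(result.phi.reset_index().rename(columns={"index": "family"}),
                      os.path.join(out, "phi.tsv"))
    with open(os.path.join(out, "dendrogram.nwk"), "w") as fh:
        fh.write(result.dendrogram_newick + "\n")
    seqio.write_table(result.twogroup.to_frame(),
                      os.path.join(out, "twogroup_conservation.tsv"))
    seqio.write_table(result.conservation.to_frame(),
                      os.path.join(out, "column_conservation.tsv"))
    seqio.write_table(result.motif_bed, os.path.join(out, "motifs.tsv"))
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
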