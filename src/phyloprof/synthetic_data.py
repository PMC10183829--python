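"""Seeded generation of a complete synthetic study.

Produces a rooted species tree, per-taxon proteomes (orthologs, inflated-rate
paralogs, composition-matched decoys, truncated fragments), one hidden
ortholog encoded only in a nucleotide genome, receptor sequences whose
disordered region carries shuffled-AIM motifs only in taxa that retain the
ubiquitin-like modifier family, and a ground-truth table the downstream
pipeline is scored against.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .alphabet import AA, ScoringMatrix, background_frequencies, blosum62, rng_for
from .containers import ProteomeSet
from .msa_processing import GroupedMSA
from . import seqio

# Residue pools that cannot spawn AIM/sAIM motifs by accident:
# no aromatics (cAIM anchor), no I/L/V (cAIM tail, sAIM anchor).
SAFE_POOL = "ACDEGHKMNPQRST"
# Safe pool restricted to residues scoring negative (BLOSUM62) against every
# motif residue {I, D, S, W, G}; used opposite planted sAIM columns so the
# two-group score there is negative by construction.
ANTI_MOTIF_POOL = "CHPR"

GROUP_POSITIVE = "ubl+"
GROUP_NEGATIVE = "ubl-"


@dataclass
class FamilySpec:
    """Generator parameters for one gene family."""

    family_id: str
    root_sequence: str
    loss_probability: float = 0.0
    correlation_partner: Optional[str] = None
    paralog_count: int = 0
    decoy_count: int = 0
    fragment_taxa: Tuple[str, ...] = ()
    rate_scale: Dict[str, float] = field(default_factory=dict)
    min_losses: int = 0
    max_losses: int = 10**9

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_probability <= 1.0:
            raise ValueError("loss probability must be in [0, 1]")
        if len(self.root_sequence) < 30:
            raise ValueError("root sequence must be at least 30 residues")


@dataclass
class GroundTruth:
    presence: pd.DataFrame                      # taxa x families, {0,1}
    loss_branches: Dict[str, List[str]]         # family -> child-node ids
    motifs: pd.DataFrame                        # seq_id, pattern, start, end
    hidden: Optional[dict] = None               # family/taxon/strand/coords
    fragments: List[str] = field(default_factory=list)
    paralogs: List[str] = field(default_factory=list)
    decoys: List[str] = field(default_factory=list)


@dataclass
class Dataset:
    tree: dendropy.Tree
    proteomes: ProteomeSet
    groups: Dict[str, str]                      # taxon -> group label
    truth: GroundTruth
    queries: Dict[str, str]                     # family -> reference sequence
    receptor_alignment: GroupedMSA              # constructed true alignment
    column_classes: List[str]                   # per alignment column
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Species tree

def simulate_tree(n_taxa: int, seed: int,
                  mean_branch_length: float = 0.25) -> dendropy.Tree:
    """Random rooted binary tree; branch lengths ~ Exponential(mean)."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = rng_for(seed, "species-tree")
    ns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_taxa):
        taxon = dendropy.Taxon(label=f"t{i + 1:02d}")
        ns.add_taxon(taxon)
        nodes.append(dendropy.Node(taxon=taxon))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.exponential(mean_branch_length))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[0])
    tree.is_rooted = True
    from .phylo import label_internal_nodes

    label_internal_nodes(tree)
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution

def _transition_rows(scoring: ScoringMatrix, temperature: float = 2.0) -> np.ndarray:
    """Replacement distributions: P(b | a) ∝ exp(S(a,b)/T), b != a."""
    w = np.exp(scoring.scores / temperature).astype(float)
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def mutate_sequence(seq: str, branch_length: float, rng: np.random.Generator,
                    trans: Optional[np.ndarray] = None,
                    pool: Optional[str] = None) -> str:
    """Per-site Poisson(branch_length) substitutions.

    Replacements follow the exponentiated-BLOSUM62 rows unless ``pool`` is
    given, in which case replacements are uniform over the pool (used for
    motif-safe regions).
    """
    if trans is None:
        trans = _transition_rows(blosum62())
    out = list(seq)
    n_subs = rng.poisson(branch_length, size=len(seq))
    for i, k in enumerate(n_subs):
        for _ in range(int(k)):
            cur = out[i]
            if pool is not None:
                choices = [c for c in pool if c != cur]
                out[i] = choices[int(rng.integers(len(choices)))]
            else:
                a = AA.index(cur) if cur in AA else None
                if a is None:
                    continue
                out[i] = AA[int(rng.choice(20, p=trans[a]))]
    return "".join(out)


def random_sequence(length: int, rng: np.random.Generator,
                    composition: Optional[np.ndarray] = None) -> str:
    if composition is None:
        composition = background_frequencies()
    return "".join(np.array(list(AA))[rng.choice(20, size=length, p=composition)])


def _composition_of(seq: str) -> np.ndarray:
    v = np.zeros(20)
    for ch in seq:
        k = AA.find(ch)
        if k >= 0:
            v[k] += 1
    return v / v.sum()


def _sample_losses(tree: dendropy.Tree, p: float, rng: np.random.Generator,
                   protect: Sequence[str]) -> List[str]:
    """Sample per-branch losses, never severing the protected taxa.

    Returns the canonical (maximal-subtree) loss-branch set; sampling skips
    subtrees that are already lost.
    """
    from .phylo import _node_id

    protected = set(protect)
    lost_state: Dict[int, bool] = {}
    sampled: List[str] = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            lost_state[id(node)] = False
            continue
        if lost_state[id(parent)]:
            lost_state[id(node)] = True
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below & protected:
            lost_state[id(node)] = False
            continue
        lost = bool(rng.random() < p)
        lost_state[id(node)] = lost
        if lost:
            sampled.append(_node_id(node))
    # Canonicalise: merge sibling losses into their parent branch.
    presence = {lf.taxon.label: 0 if lost_state[id(lf)] else 1
                for lf in tree.leaf_node_iter()}
    return _canonical_losses(tree, presence), presence


def _canonical_losses(tree: dendropy.Tree, presence: Mapping[str, int]) -> List[str]:
    """Maximal all-absent subtrees (the generative definition of a loss)."""
    from .phylo import _node_id

    all_absent: Dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            all_absent[id(node)] = not presence[node.taxon.label]
        else:
            all_absent[id(node)] = all(all_absent[id(c)] for c in node.child_nodes())
    losses = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if all_absent[id(node)] and not all_absent[id(node.parent_node)]:
            losses.append(_node_id(node))
    return sorted(losses)


def evolve_family(spec: FamilySpec, tree: dendropy.Tree, seed: int,
                  copy_losses: Optional[List[str]] = None,
                  protect: Sequence[str] = ("t01",),
                  paralog_rate_factor: float = 3.0,
                  ) -> Tuple[Dict[str, str], Dict[str, int], List[str]]:
    """Evolve one family down the species tree.

    Returns (sequences keyed by sequence id, presence by taxon, canonical
    loss-branch list). Paralog and decoy ids carry ``_par``/``_decoy``
    suffixes; fragment taxa get orthologs truncated to <50% length.
    """
    rng = rng_for(seed, f"family-{spec.family_id}")
    trans = _transition_rows(blosum62())
    from .phylo import apply_losses

    if copy_losses is not None:
        losses = sorted(copy_losses)
        presence = apply_losses(tree, losses)
    else:
        for _ in range(200):
            losses, presence = _sample_losses(tree, spec.loss_probability, rng, protect)
            if spec.min_losses <= len(losses) <= spec.max_losses:
                break
        else:
            raise RuntimeError(
                f"could not sample a loss pattern for {spec.family_id} "
                f"within [{spec.min_losses}, {spec.max_losses}] losses")

    lost = set(losses)
    sequences: Dict[str, str] = {}
    seqs_at: Dict[int, str] = {id(tree.seed_node): spec.root_sequence}
    from .phylo import _node_id

    alive: Dict[int, bool] = {id(tree.seed_node): True}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        alive[id(node)] = alive[id(parent)] and _node_id(node) not in lost
        if not alive[id(node)]:
            continue
        bl = float(node.edge.length or 0.0)
        if node.is_leaf():
            bl *= spec.rate_scale.get(node.taxon.label, 1.0)
        seqs_at[id(node)] = mutate_sequence(seqs_at[id(parent)], bl, rng, trans)
        if node.is_leaf():
            taxon = node.taxon.label
            seq = seqs_at[id(node)]
            if taxon in spec.fragment_taxa:
                seq = seq[: max(10, int(0.4 * len(seq)))]
            sequences[f"{taxon}|{spec.family_id}"] = seq

    present_taxa = sorted(t for t, v in presence.items() if v)
    for k in range(spec.paralog_count):
        host = present_taxa[int(rng.integers(len(present_taxa)))]
        seq = spec.root_sequence
        node = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == host)
        path = []
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        for step in reversed(path):
            bl = float(step.edge.length or 0.0) * paralog_rate_factor
            seq = mutate_sequence(seq, bl, rng, trans)
        sequences[f"{host}|{spec.family_id}_par{k + 1}"] = seq

    comp = _composition_of(spec.root_sequence)
    all_taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    for k in range(spec.decoy_count):
        host = all_taxa[int(rng.integers(len(all_taxa)))]
        seq = random_sequence(len(spec.root_sequence), rng, comp)
        sequences[f"{host}|{spec.family_id}_decoy{k + 1}"] = seq

    return sequences, presence, losses


# ---------------------------------------------------------------------------
# Receptor (C53-like) construction

_BLOCKS = (
    ("helix1", 40), ("idr", 12), ("saim1", 4), ("idr", 6), ("saim2", 4),
    ("idr", 6), ("saim3", 4), ("idr", 4), ("caim", 4), ("idr_plus", 20),
    ("idr", 8), ("helix2", 40),
)
_MOTIF_SEQ = {"saim1": "IDWD", "saim2": "IDWD", "saim3": "ISWD", "caim": "WELV"}


def build_c53_alignment(presence_of_ubl: Mapping[str, int], seed: int,
                        helix_divergence: float = 0.03,
                        ) -> Tuple[GroupedMSA, List[str], pd.DataFrame]:
    """Construct the receptor alignment column-by-column.

    Taxa retaining the modifier (group ``ubl+``) carry three sAIMs and one
    cAIM inside a long disordered region; the others (``ubl-``) keep the
    conserved helical flanks and the cAIM but a shortened, sAIM-free IDR.
    Returns (grouped alignment, per-column class labels, motif truth with
    1-based coordinates on the de-gapped sequences).
    """
    if not presence_of_ubl:
        raise ValueError("presence map must be non-empty")
    rng = rng_for(seed, "receptor")
    taxa = sorted(presence_of_ubl)
    helices = {
        "helix1": "".join(rng.choice(list(SAFE_POOL), size=40)),
        "helix2": "".join(rng.choice(list(SAFE_POOL), size=40)),
    }
    rows: Dict[str, List[str]] = {t: [] for t in taxa}
    classes: List[str] = []
    for block, width in _BLOCKS:
        for pos in range(width):
            classes.append(block)
        for t in taxa:
            positive = bool(presence_of_ubl[t])
            if block in ("helix1", "helix2"):
                chars = list(helices[block])
                for i, ch in enumerate(chars):
                    if rng.random() < helix_divergence:
                        choices = [c for c in SAFE_POOL if c != ch]
                        chars[i] = choices[int(rng.integers(len(choices)))]
                rows[t].append("".join(chars))
            elif block == "caim":
                rows[t].append(_MOTIF_SEQ["caim"])
            elif block in ("saim1", "saim2", "saim3"):
                if positive:
                    rows[t].append(_MOTIF_SEQ[block])
                else:
                    rows[t].append("".join(rng.choice(list(ANTI_MOTIF_POOL), size=4)))
            elif block == "idr_plus":
                if positive:
                    rows[t].append("".join(rng.choice(list(SAFE_POOL), size=width)))
                else:
                    rows[t].append("-" * width)
            else:  # shared IDR
                rows[t].append("".join(rng.choice(list(SAFE_POOL), size=width)))
    aligned = {t: "".join(rows[t]) for t in taxa}
    groups = {t: (GROUP_POSITIVE if presence_of_ubl[t] else GROUP_NEGATIVE)
              for t in taxa}
    msa = GroupedMSA(ids=taxa, rows=[aligned[t] for t in taxa], groups=groups)

    records = []
    for t in taxa:
        row = aligned[t]
        col = 0
        residue = 0
        for block, width in _BLOCKS:
            chunk = row[col: col + width]
            start = residue + 1
            residue += sum(1 for ch in chunk if ch != "-")
            if block in _MOTIF_SEQ and chunk == _MOTIF_SEQ[block]:
                pattern = "cAIM" if block == "caim" else "sAIM"
                records.append({"seq_id": t, "block": block, "pattern": pattern,
                                "start": start, "end": start + 3})
            col += width
    return msa, classes, pd.DataFrame(records)


def build_c53_sequences(presence_of_ubl: Mapping[str, int], seed: int,
                        ) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Per-taxon receptor sequences (de-gapped rows of the built alignment)."""
    msa, _, motifs = build_c53_alignment(presence_of_ubl, seed)
    seqs = {t: msa.rows[i].replace("-", "") for i, t in enumerate(msa.ids)}
    return seqs, motifs


# ---------------------------------------------------------------------------
# Whole-study assembly

def default_family_specs(seed: int) -> List[FamilySpec]:
    rng = rng_for(seed, "roots")

    def root(length: int) -> str:
        return random_sequence(length, rng)

    return [
        FamilySpec("ubl", root(110), loss_probability=0.16,
                   min_losses=2, max_losses=4),
        FamilySpec("e1_act", root(140), correlation_partner="ubl",
                   paralog_count=2, decoy_count=2),
        FamilySpec("e2_conj", root(130), loss_probability=0.10,
                   min_losses=1, max_losses=3, decoy_count=2),
        FamilySpec("e3_lig", root(150), loss_probability=0.10,
                   min_losses=1, max_losses=3),
        FamilySpec("adaptor", root(120), loss_probability=0.08,
                   min_losses=1, max_losses=3, fragment_taxa=("t03",)),
        FamilySpec("receptor", "X" * 30, loss_probability=0.0),   # built separately
        FamilySpec("ribosomal", root(120), loss_probability=0.0, decoy_count=2),
    ]


def generate_dataset(n_taxa: int = 12, seed: int = 0,
                     mean_branch_length: float = 0.13,
                     specs: Optional[List[FamilySpec]] = None,
                     reference_taxon: str = "t01",
                     hidden_family: str = "e3_lig",
                     genome_pad: int = 900) -> Dataset:
    """Generate the default synthetic study."""
    tree = simulate_tree(n_taxa, seed, mean_branch_length)
    if specs is None:
        specs = default_family_specs(seed)
    spec_by_id = {s.family_id: s for s in specs}

    proteomes: Dict[str, Dict[str, str]] = {
        lf.taxon.label: {} for lf in tree.leaf_node_iter()}
    presence_cols: Dict[str, Dict[str, int]] = {}
    loss_map: Dict[str, List[str]] = {}
    fragments: List[str] = []
    paralog_ids: List[str] = []
    decoy_ids: List[str] = []

    loss_sets: Dict[str, List[str]] = {}
    used_patterns: set = set()
    ordered = sorted(specs, key=lambda s: (s.correlation_partner is not None,
                                           s.family_id))
    for spec in ordered:
        if spec.family_id == "receptor":
            continue
        copy = None
        if spec.correlation_partner is not None:
            copy = loss_sets[spec.correlation_partner]
        # Resample on collision so no two independently-evolving families
        # share a loss pattern by accident (only the declared correlation
        # partner may duplicate one).
        for attempt in range(50):
            seqs, presence, losses = evolve_family(
                spec, tree, seed + 7919 * attempt, copy_losses=copy,
                protect=(reference_taxon,))
            if copy is not None or spec.loss_probability == 0.0 \
                    or tuple(losses) not in used_patterns:
                break
        if copy is None and spec.loss_probability > 0.0:
            used_patterns.add(tuple(losses))
        loss_sets[spec.family_id] = losses
        loss_map[spec.family_id] = losses
        presence_cols[spec.family_id] = presence
        for sid, s in seqs.items():
            taxon = sid.split("|", 1)[0]
            proteomes[taxon][sid] = s
            if "_par" in sid:
                paralog_ids.append(sid)
            elif "_decoy" in sid:
                decoy_ids.append(sid)
        for taxon in spec.fragment_taxa:
            if presence.get(taxon):
                fragments.append(f"{taxon}|{spec.family_id}")

    # Receptor family: present everywhere, motif content tracks ubl presence.
    ubl_presence = presence_cols["ubl"]
    receptor_msa, column_classes, motifs = build_c53_alignment(ubl_presence, seed)
    receptor_seqs, _ = build_c53_sequences(ubl_presence, seed)
    for taxon, seq in receptor_seqs.items():
        proteomes[taxon][f"{taxon}|receptor"] = seq
    presence_cols["receptor"] = {t: 1 for t in receptor_seqs}
    loss_map["receptor"] = []
    motifs = motifs.assign(seq_id=[f"{t}|receptor" for t in motifs["seq_id"]])
    receptor_msa = GroupedMSA(
        ids=[f"{t}|receptor" for t in receptor_msa.ids],
        rows=list(receptor_msa.rows),
        groups={f"{t}|receptor": g for t, g in receptor_msa.groups.items()})

    # Hide one ortholog inside a genome (reverse strand, single exon).
    rng = rng_for(seed, "hidden-genome")
    hidden = None
    genomes: Dict[str, str] = {}
    candidates = [t for t, v in presence_cols[hidden_family].items()
                  if v and t != reference_taxon]
    if candidates:
        taxon = sorted(candidates)[int(rng.integers(len(candidates)))]
        sid = f"{taxon}|{hidden_family}"
        protein = proteomes[taxon].pop(sid)
        cds = _reverse_translate(protein, rng)
        left = _random_dna(genome_pad, rng)
        right = _random_dna(genome_pad, rng)
        genome_fwd = left + _revcomp(cds) + right
        start = len(left) + 1
        end = len(left) + len(cds)
        genomes[taxon] = genome_fwd
        hidden = {"family": hidden_family, "taxon": taxon, "seq_id": sid,
                  "strand": "-", "start": start, "end": end, "protein": protein}

    taxa = sorted(proteomes)
    presence = pd.DataFrame(
        {fam: [presence_cols[fam][t] for t in taxa] for fam in sorted(presence_cols)},
        index=pd.Index(taxa, name="taxon"))
    groups = {t: (GROUP_POSITIVE if ubl_presence[t] else GROUP_NEGATIVE)
              for t in taxa}
    queries = {}
    for fam in sorted(presence_cols):
        sid = f"{reference_taxon}|{fam}"
        if sid in proteomes[reference_taxon]:
            queries[fam] = proteomes[reference_taxon][sid]
    truth = GroundTruth(presence=presence, loss_branches=loss_map, motifs=motifs,
                        hidden=hidden, fragments=fragments,
                        paralogs=paralog_ids, decoys=decoy_ids)
    config = {"n_taxa": n_taxa, "seed": seed,
              "mean_branch_length": mean_branch_length,
              "reference_taxon": reference_taxon, "hidden_family": hidden_family}
    return Dataset(tree=tree, proteomes=ProteomeSet(proteomes=proteomes, genomes=genomes),
                   groups=groups, truth=truth, queries=queries,
                   receptor_alignment=receptor_msa, column_classes=column_classes,
                   config=config)


_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_CODON_ALT = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG", "N": "AAC", "P": "CCG",
    "Q": "CAG", "R": "CGC", "S": "AGC", "T": "ACC", "V": "GTG", "Y": "TAC",
    "M": "ATG", "W": "TGG",
}


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join((_CODON if rng.random() < 0.5 else _CODON_ALT)[aa]
                   for aa in protein)


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=length)])


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# Fixture serialisation

def write_fixture(dataset: Dataset, out_dir: str) -> None:
    """Write the dataset as plain-text files that round-trip through seqio."""
    import os

    seqio.ensure_dir(out_dir)
    seqio.ensure_dir(os.path.join(out_dir, "proteomes"))
    seqio.ensure_dir(os.path.join(out_dir, "genomes"))
    for taxon in dataset.proteomes.taxa():
        seqio.write_fasta(dataset.proteomes.proteomes[taxon],
                          os.path.join(out_dir, "proteomes", f"{taxon}.fasta"))
    for taxon, genome in dataset.proteomes.genomes.items():
        seqio.write_fasta({f"{taxon}_genome": genome},
                          os.path.join(out_dir, "genomes", f"{taxon}.fasta"))
    seqio.write_tree(dataset.tree, os.path.join(out_dir, "species_tree.nwk"))
    groups = pd.DataFrame({"taxon": sorted(dataset.groups),
                           "group": [dataset.groups[t] for t in sorted(dataset.groups)]})
    seqio.write_table(groups, os.path.join(out_dir, "groups.tsv"))
    seqio.write_table(dataset.truth.presence.reset_index(),
                      os.path.join(out_dir, "truth_presence.tsv"))
    losses = pd.DataFrame(
        [{"family": fam, "branch": b}
         for fam, branches in sorted(dataset.truth.loss_branches.items())
         for b in branches])
    if losses.empty:
        losses = pd.DataFrame(columns=["family", "branch"])
    seqio.write_table(losses, os.path.join(out_dir, "truth_losses.tsv"))
    seqio.write_table(dataset.truth.motifs, os.path.join(out_dir, "truth_motifs.tsv"))
    seqio.write_fasta(dict(zip(dataset.receptor_alignment.ids,
                               dataset.receptor_alignment.rows)),
                      os.path.join(out_dir, "receptor_alignment.fasta"))
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        manifest = dict(dataset.config)
        manifest["hidden"] = dataset.truth.hidden
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_fixture_proteomes(out_dir: str) -> ProteomeSet:
    import glob
    import os

    proteomes = {}
    for path in sorted(glob.glob(os.path.join(out_dir, "proteomes", "*.fasta"))):
        taxon = os.path.splitext(os.path.basename(path))[0]
        proteomes[taxon] = seqio.read_fasta(path)
    genomes = {}
    for path in sorted(glob.glob(os.path.join(out_dir, "genomes", "*.fasta"))):
        taxon = os.path.splitext(os.path.basename(path))[0]
        genomes[taxon] = next(iter(seqio.read_fasta(path).values()))
    return ProteomeSet(proteomes=proteomes, genomes=genomes)
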