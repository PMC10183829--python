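"""Shared data containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional


@dataclass
class ProteomeSet:
    """Per-taxon protein collections, with optional nucleotide genomes.

    ``proteomes`` maps taxon -> {sequence id -> protein sequence};
    ``genomes`` maps taxon -> nucleotide sequence (only taxa that have one).
    """

    proteomes: Dict[str, Dict[str, str]] = field(default_factory=dict)
    genomes: Dict[str, str] = field(default_factory=dict)

    def taxa(self) -> List[str]:
        return sorted(self.proteomes)

    def total_residues(self) -> int:
        return sum(len(s) for p in self.proteomes.values() for s in p.values())

    def n_sequences(self) -> int:
        return sum(len(p) for p in self.proteomes.values())

    def sequence(self, taxon: str, seq_id: str) -> str:
        return self.proteomes[taxon][seq_id]

    def find(self, seq_id: str) -> Optional[str]:
        """Locate a sequence id across taxa; returns the sequence or None."""
        for prot in self.proteomes.values():
            if seq_id in prot:
                return prot[seq_id]
        return None
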