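"""Run configuration for the refinement pipeline.

A single dataclass holds every tunable so a run is fully reproducible from
one serialized file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class Config:
    """Pipeline parameters with their package-wide defaults.

    il_equivalent
        Treat I and L as interchangeable during peptide matching (MS/MS
        cannot distinguish them).
    min_peptides
        Minimum unambiguous peptide hits required to support a novel exon.
    identity_threshold
        Minimum alignment identity for fragment placement and for accepting
        a reconstructed model against its evidence protein.
    fragment_overlap_tol
        Residues two fragment placements may overlap (signal-peptide /
        propeptide fuzz).
    splice_window
        Window (nt) searched for canonical splice sites around a
        peptide-supported interval.
    max_merge_gap
        Maximum genomic distance (nt) for two fragments on one contig to be
        considered adjacent merge candidates.
    missed_cleavages, peptide_min_len, peptide_max_len
        In-silico tryptic digestion parameters (search-engine defaults).
    min_orf_len
        Shortest six-frame ORF retained as peptide search space.
    min_block
        Minimum exact-match block (nt) in transcript-to-genome chaining.
    exhaustive
        Search the genome even for peptides that already map to the
        annotated proteome.
    """

    il_equivalent: bool = True
    min_peptides: int = 1
    identity_threshold: float = 0.95
    fragment_overlap_tol: int = 5
    splice_window: int = 300
    max_merge_gap: int = 50_000
    missed_cleavages: int = 2
    peptide_min_len: int = 7
    peptide_max_len: int = 35
    min_orf_len: int = 8
    min_block: int = 20
    exhaustive: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")
        if self.peptide_min_len < 5 or self.peptide_max_len < self.peptide_min_len:
            raise ValueError("bad peptide length range")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Config":
        with open(path) as fh:
            return cls(**json.load(fh))
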