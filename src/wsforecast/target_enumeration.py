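"""Mutational target sizes: per-gene, per-class counts of WS-enabling events.

Target sizes are event counts over the sequence (real-valued only to allow
weighted indel models); mutation-class rates are applied downstream in
:mod:`wsforecast.pathway_model`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import DataValidationError, ModelError
from .gene_models import (
    CODON_TABLE,
    STOP_CODONS,
    GeneModel,
    GeneModelSet,
    Region,
    codon_to_positions,
)

__all__ = [
    "IndelModel",
    "RepeatDeletion",
    "TargetSizeTable",
    "count_stop_gain_sites",
    "count_frameshift_sites",
    "scan_direct_repeats",
    "restricted_missense_target",
    "lof_target",
    "build_target_table",
    "CONSTRAINT_LABELS",
]

_BASES = "ACGT"

CONSTRAINT_LABELS = ("any_lof", "inframe_only", "regions_only", "none")


@dataclass(frozen=True)
class IndelModel:
    """Per-site weights for +-1 bp indel events.

    Every CDS position carries weight 1; positions inside homopolymer runs
    of length >= ``min_run`` are weighted ``homopolymer_multiplier`` instead.
    """

    homopolymer_multiplier: float = 1.0
    min_run: int = 4

    def __post_init__(self) -> None:
        if self.homopolymer_multiplier < 0:
            raise DataValidationError("indel weights must be non-negative")
        if self.min_run < 2:
            raise DataValidationError("min_run must be >= 2")

    def site_weights(self, seq: str) -> list[float]:
        weights = [1.0] * len(seq)
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i >= self.min_run:
                for k in range(i, j):
                    weights[k] = self.homopolymer_multiplier
            i = j
        return weights


@dataclass(frozen=True)
class RepeatDeletion:
    """A deletion between two exact direct repeats.

    Deleting ``deletion_len = right_start - left_start`` bases starting at
    ``left_start`` leaves the sequence with a single copy of the repeat.
    """

    repeat_seq: str
    repeat_len: int
    left_start: int  # 1-based CDS position of the left copy
    right_start: int
    deletion_len: int
    frame_preserving: bool

    def __post_init__(self) -> None:
        if self.deletion_len < 1:
            raise DataValidationError("deletion_len must be >= 1")


def _interior_codons(cds: str) -> Iterable[tuple[int, str]]:
    """(codon_index, codon) for codons 2..L-1 (start and stop excluded)."""
    n_codons = len(cds) // 3
    for idx in range(2, n_codons):
        yield idx, cds[3 * (idx - 1) : 3 * idx]


def count_stop_gain_sites(cds: str) -> tuple[int, dict[int, int]]:
    """Single-nucleotide substitutions creating a premature stop.

    Counts over interior codons only (the start codon and the annotated stop
    are excluded).  Returns the total and a per-codon breakdown.
    """
    breakdown: dict[int, int] = {}
    for idx, codon in _interior_codons(cds):
        n = 0
        for offset in range(3):
            for base in _BASES:
                if base == codon[offset]:
                    continue
                mutant = codon[:offset] + base + codon[offset + 1 :]
                if mutant in STOP_CODONS:
                    n += 1
        if n:
            breakdown[idx] = n
    return sum(breakdown.values()), breakdown


def count_frameshift_sites(
    cds: str, indel_model: Optional[IndelModel] = None
) -> float:
    """Weighted count of frame-breaking +-1 bp indel sites over the CDS."""
    model = indel_model or IndelModel()
    return float(sum(model.site_weights(cds)))


def scan_direct_repeats(
    seq: str, min_repeat_len: int = 6, max_deletion_len: int = 500
) -> list[RepeatDeletion]:
    """All maximal exact direct-repeat pairs in ``seq``.

    A pair (i, j) with ``seq[i:i+k] == seq[j:j+k]`` is maximal when it cannot
    be extended left or right.  Overlapping and nested pairs are all
    reported; output is sorted by (left_start, deletion_len).
    """
    if min_repeat_len < 4:
        raise DataValidationError("min_repeat_len must be >= 4")
    seq = seq.upper()
    n = len(seq)
    hits: list[RepeatDeletion] = []
    # one maximal match per (left, separation) diagonal
    for sep in range(1, min(max_deletion_len, n - min_repeat_len) + 1):
        i = 0
        while i + sep < n:
            if seq[i] != seq[i + sep]:
                i += 1
                continue
            start = i
            while i + sep < n and seq[i] == seq[i + sep]:
                i += 1
            run = i - start
            if run >= min_repeat_len:
                hits.append(
                    RepeatDeletion(
                        repeat_seq=seq[start : start + run],
                        repeat_len=run,
                        left_start=start + 1,
                        right_start=start + sep + 1,
                        deletion_len=sep,
                        frame_preserving=(sep % 3 == 0),
                    )
                )
    hits.sort(key=lambda h: (h.left_start, h.deletion_len))
    return hits


def _aa_regions(regions: Sequence[Region], mclass: str) -> list[Region]:
    return [
        r
        for r in regions
        if r.kind == "aa_range" and (not r.allowed_classes or mclass in r.allowed_classes)
    ]


def restricted_missense_target(
    cds: str, regions: Sequence[Region]
) -> int:
    """Non-synonymous, non-nonsense single-nt substitutions within regions.

    ``regions`` are aa ranges; overlapping regions count each codon once.
    """
    n_codons = len(cds) // 3
    residues: set[int] = set()
    for region in _aa_regions(regions, "missense"):
        if region.end > n_codons:
            raise DataValidationError(
                f"region {region.region_id} extends beyond protein length {n_codons}"
            )
        residues.update(range(region.start, region.end + 1))
    total = 0
    for idx in sorted(residues):
        a, _, c = codon_to_positions(idx)
        codon = cds[a - 1 : c]
        aa = CODON_TABLE[codon]
        for offset in range(3):
            for base in _BASES:
                if base == codon[offset]:
                    continue
                mutant = codon[:offset] + base + codon[offset + 1 :]
                new_aa = CODON_TABLE[mutant]
                if new_aa != aa and new_aa != "*":
                    total += 1
    return total


def _inframe_repeat_target(
    cds: str,
    regions: Optional[Sequence[Region]],
    min_repeat_len: int,
    max_deletion_len: int,
) -> int:
    """Frame-preserving repeat deletions, optionally restricted to regions."""
    hits = [
        h
        for h in scan_direct_repeats(cds, min_repeat_len, max_deletion_len)
        if h.frame_preserving
    ]
    if regions is None:
        return len(hits)
    spans = []
    for r in _aa_regions(regions, "inframe_indel"):
        nt_start, _, _ = codon_to_positions(r.start)
        _, _, nt_end = codon_to_positions(r.end)
        spans.append((nt_start, nt_end))
    if not spans:
        return 0
    kept = 0
    for h in hits:
        del_start, del_end = h.left_start, h.left_start + h.deletion_len - 1
        if any(s <= del_start and del_end <= e for s, e in spans):
            kept += 1
    return kept


def lof_target(
    gene: GeneModel,
    constraint: str,
    regions: Sequence[Region] = (),
    indel_model: Optional[IndelModel] = None,
    min_repeat_len: int = 6,
    max_deletion_len: int = 500,
) -> dict[str, float]:
    """Per-class WS-enabling targets for one gene under a constraint set.

    * ``any_lof``: nonsense + frameshift over the whole CDS, in-frame repeat
      deletions anywhere, plus region-restricted missense.
    * ``inframe_only``: only frame-preserving events (in-frame repeat
      deletions anywhere plus region-restricted missense); nonsense and
      frameshift contribute 0.
    * ``regions_only``: missense and in-frame deletions within the listed
      regions only.
    * ``none``: all targets 0.
    """
    if constraint not in CONSTRAINT_LABELS:
        raise ModelError(f"unknown constraint label {constraint!r}")
    cds = gene.cds_seq
    gene_regions = [r for r in regions if r.gene_name == gene.gene_name]
    out: dict[str, float] = {
        "nonsense": 0.0,
        "frameshift_indel": 0.0,
        "inframe_indel": 0.0,
        "missense": 0.0,
    }
    if constraint == "none":
        return out
    if constraint == "any_lof":
        out["nonsense"] = float(count_stop_gain_sites(cds)[0])
        out["frameshift_indel"] = count_frameshift_sites(cds, indel_model)
        out["inframe_indel"] = float(
            _inframe_repeat_target(cds, None, min_repeat_len, max_deletion_len)
        )
        out["missense"] = float(restricted_missense_target(cds, gene_regions))
    elif constraint == "inframe_only":
        out["inframe_indel"] = float(
            _inframe_repeat_target(cds, None, min_repeat_len, max_deletion_len)
        )
        out["missense"] = float(restricted_missense_target(cds, gene_regions))
    elif constraint == "regions_only":
        out["inframe_indel"] = float(
            _inframe_repeat_target(cds, gene_regions, min_repeat_len, max_deletion_len)
        )
        out["missense"] = float(restricted_missense_target(cds, gene_regions))
    return out


@dataclass
class TargetSizeTable:
    """(gene, mutation class) -> target size, with per-gene constraint notes."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    constraints: dict[str, str] = field(default_factory=dict)

    def get(self, gene: str, mclass: str) -> float:
        return self.entries.get((gene, mclass), 0.0)

    def gene_total(self, gene: str) -> float:
        return sum(v for (g, _), v in self.entries.items() if g == gene)

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.entries})

    def to_json(self) -> str:
        return json.dumps(
            {
                "constraints": self.constraints,
                "targets": [
                    {"gene": g, "mclass": c, "target": v}
                    for (g, c), v in sorted(self.entries.items())
                ],
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["gene_name\tmclass\ttarget"]
        for (g, c), v in sorted(self.entries.items()):
            lines.append(f"{g}\t{c}\t{v:g}")
        return "\n".join(lines) + "\n"


def build_target_table(
    genes: GeneModelSet,
    constraints: dict[str, str],
    regions: Sequence[Region] = (),
    indel_model: Optional[IndelModel] = None,
    min_repeat_len: int = 6,
    max_deletion_len: int = 500,
) -> TargetSizeTable:
    """Compute the full target table for a gene set.

    ``constraints`` maps gene_name -> constraint label; genes not listed get
    ``none`` (zero targets).
    """
    table = TargetSizeTable()
    for gene in genes:
        constraint = constraints.get(gene.gene_name, "none")
        table.constraints[gene.gene_name] = constraint
        per_class = lof_target(
            gene,
            constraint,
            regions,
            indel_model,
            min_repeat_len,
            max_deletion_len,
        )
        for mclass, value in per_class.items():
            if value < 0:
                raise ModelError(
                    f"negative target for {gene.gene_name}/{mclass}"
                )
            table.entries[(gene.gene_name, mclass)] = value
    return table
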