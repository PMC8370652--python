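"""Observed mutations: records, effect classification and spectra.

This is a deliberately small variant-effect annotator: single-nucleotide
substitutions are classified by translating the affected codon before and
after, indels by frame arithmetic, and upstream events by the promoter
convention of :mod:`wsforecast.gene_models`.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import DataValidationError
from .gene_models import (
    CODON_TABLE,
    START_CODONS,
    GeneModel,
    GeneModelSet,
    position_to_codon,
    translate_cds,
)

log = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "MutationEffect",
    "ObservedSpectrum",
    "MUTATION_CLASSES",
    "CODING_CLASSES",
    "classify_mutation",
    "build_spectrum",
    "top_recurrent",
    "load_mutant_table",
]

MUTATION_CLASSES = (
    "missense",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
    "synonymous",
    "promoter_point",
    "promoter_capture",
    "intergenic_other",
)

#: classes that disrupt a protein's coding sequence
CODING_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel"}
)

COORD_SYSTEMS = ("cds_nt", "upstream_nt", "protein_aa")


@dataclass
class MutationRecord:
    """One observed or simulated mutation.

    ``position`` is interpreted per ``coord_system``: 1-based CDS nucleotide
    (``cds_nt``), <=0 upstream offset (``upstream_nt``) or 1-based protein
    residue (``protein_aa``).  ``ref_allele``/``alt_allele`` may be empty for
    pure insertions/deletions.
    """

    isolate_id: str
    gene_name: str
    coord_system: str
    position: int
    ref_allele: str = ""
    alt_allele: str = ""
    structural_flag: Optional[str] = None
    experiment: str = "wt"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.coord_system not in COORD_SYSTEMS:
            raise DataValidationError(
                f"isolate {self.isolate_id}: unknown coord_system "
                f"{self.coord_system!r}"
            )
        self.ref_allele = (self.ref_allele or "").upper().replace("-", "")
        self.alt_allele = (self.alt_allele or "").upper().replace("-", "")
        if self.structural_flag not in (None, "", "promoter_capture"):
            raise DataValidationError(
                f"isolate {self.isolate_id}: unknown structural_flag "
                f"{self.structural_flag!r}"
            )
        self.structural_flag = self.structural_flag or None

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def net_length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    def change_key(self) -> str:
        """Exact allele description used to detect identical mutations."""
        return (
            f"{self.gene_name}:{self.coord_system}:{self.position}:"
            f"{self.ref_allele or '-'}>{self.alt_allele or '-'}"
            + (f":{self.structural_flag}" if self.structural_flag else "")
        )


@dataclass
class MutationEffect:
    """A classified mutation."""

    record: MutationRecord
    mclass: str
    protein_change: Optional[str] = None
    frame_preserving: Optional[bool] = None
    disrupts_downstream: bool = False
    #: 1-based residue of the affected codon, for coding effects
    aa_position: Optional[int] = None

    @property
    def gene_name(self) -> str:
        return self.record.gene_name

    def change_label(self) -> str:
        """Human-readable label, e.g. ``"WspF V271G"``."""
        gene = self.record.gene_name
        display = gene[0].upper() + gene[1:] if gene[0].islower() else gene
        if self.protein_change:
            return f"{display} {self.protein_change}"
        return self.record.change_key()


def _check_ref(record: MutationRecord, gene: GeneModel) -> None:
    if record.coord_system != "cds_nt" or not record.ref_allele:
        return
    start = record.position - 1
    observed = gene.cds_seq[start : start + len(record.ref_allele)]
    if observed != record.ref_allele:
        raise DataValidationError(
            f"isolate {record.isolate_id}: ref allele {record.ref_allele} does "
            f"not match {gene.gene_name} CDS at position {record.position} "
            f"(found {observed or 'end of CDS'})"
        )


def classify_mutation(
    record: MutationRecord, gene_models: GeneModelSet
) -> MutationEffect:
    """Deterministically assign a mutation class to one record."""
    gene = gene_models.get(record.gene_name)

    if record.structural_flag == "promoter_capture":
        return MutationEffect(record, "promoter_capture")

    if record.coord_system == "upstream_nt":
        if record.position > 0:
            raise DataValidationError(
                f"isolate {record.isolate_id}: upstream position must be <= 0"
            )
        if record.position < -gene.upstream_window:
            warnings.warn(
                f"isolate {record.isolate_id}: position {record.position} is "
                f"outside the {gene.upstream_window}-bp upstream window of "
                f"{gene.gene_name}; classified intergenic_other",
                stacklevel=2,
            )
            return MutationEffect(record, "intergenic_other")
        return MutationEffect(record, "promoter_point")

    if record.coord_system == "protein_aa":
        if not (1 <= record.position <= gene.protein_length):
            raise DataValidationError(
                f"isolate {record.isolate_id}: residue {record.position} outside "
                f"{gene.gene_name} protein"
            )
        ref_aa, alt_aa = record.ref_allele, record.alt_allele
        if len(ref_aa) != 1 or len(alt_aa) != 1:
            raise DataValidationError(
                f"isolate {record.isolate_id}: protein_aa records must carry "
                "single-residue ref/alt"
            )
        expected = translate_cds(gene.cds_seq)[record.position - 1]
        if ref_aa != expected:
            raise DataValidationError(
                f"isolate {record.isolate_id}: ref residue {ref_aa} does not "
                f"match {gene.gene_name} position {record.position} ({expected})"
            )
        if alt_aa == ref_aa:
            mclass = "synonymous"
        elif alt_aa == "*":
            mclass = "nonsense"
        else:
            mclass = "missense"
        return MutationEffect(
            record,
            mclass,
            protein_change=f"{ref_aa}{record.position}{alt_aa}",
            aa_position=record.position,
            disrupts_downstream=(mclass == "nonsense" and gene.polar_partner is not None),
        )

    # cds_nt
    if not (1 <= record.position <= len(gene.cds_seq)):
        warnings.warn(
            f"isolate {record.isolate_id}: position {record.position} outside "
            f"the CDS and upstream window of {gene.gene_name}; classified "
            "intergenic_other",
            stacklevel=2,
        )
        return MutationEffect(record, "intergenic_other")
    _check_ref(record, gene)

    if record.is_indel:
        frame_ok = record.net_length_change % 3 == 0
        mclass = "inframe_indel" if frame_ok else "frameshift_indel"
        codon_index, _ = position_to_codon(record.position, len(gene.cds_seq))
        return MutationEffect(
            record,
            mclass,
            frame_preserving=frame_ok,
            aa_position=codon_index,
            disrupts_downstream=(not frame_ok and gene.polar_partner is not None),
        )

    if len(record.ref_allele) != 1 or len(record.alt_allele) != 1:
        raise DataValidationError(
            f"isolate {record.isolate_id}: multi-nucleotide substitutions are "
            "not supported"
        )
    codon_index, offset = position_to_codon(record.position, len(gene.cds_seq))
    codon = gene.codon(codon_index)
    mutant_codon = codon[: offset - 1] + record.alt_allele + codon[offset:]
    old_aa = CODON_TABLE[codon]
    new_aa = CODON_TABLE[mutant_codon]
    if codon_index == 1:
        # the annotated initiator reads M; a switch to another valid start
        # codon preserves it
        old_aa = "M"
        if mutant_codon in START_CODONS:
            new_aa = "M"
    if new_aa == old_aa:
        mclass = "synonymous"
    elif new_aa == "*":
        mclass = "nonsense"
    else:
        # stop-loss and start-loss substitutions are folded into missense
        mclass = "missense"
    return MutationEffect(
        record,
        mclass,
        protein_change=f"{old_aa}{codon_index}{new_aa}",
        aa_position=codon_index,
        disrupts_downstream=(mclass == "nonsense" and gene.polar_partner is not None),
    )


@dataclass
class ObservedSpectrum:
    """Integer mutation counts over (gene, class), with marginals."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    n_total: int = 0

    def gene_marginals(self) -> dict[str, int]:
        out: Counter[str] = Counter()
        for (gene, _), n in self.counts.items():
            out[gene] += n
        return dict(out)

    def coding_gene_marginals(self) -> dict[str, int]:
        """Gene counts restricted to within-CDS effects (promoter events excluded)."""
        out: Counter[str] = Counter()
        for (gene, mclass), n in self.counts.items():
            if mclass in CODING_CLASSES:
                out[gene] += n
        return dict(out)

    def class_marginals(self) -> dict[str, int]:
        out: Counter[str] = Counter()
        for (_, mclass), n in self.counts.items():
            out[mclass] += n
        return dict(out)

    def pathway_marginals(self, gene_models: GeneModelSet) -> dict[str, int]:
        out: Counter[str] = Counter()
        for (gene, _), n in self.counts.items():
            out[gene_models.get(gene).pathway] += n
        return dict(out)

    def to_json(self, gene_models: Optional[GeneModelSet] = None, **provenance) -> str:
        payload = {
            "n_total": self.n_total,
            "counts": [
                {"gene": g, "mclass": c, "count": n}
                for (g, c), n in sorted(self.counts.items())
            ],
            "gene_marginals": self.gene_marginals(),
            "class_marginals": self.class_marginals(),
        }
        if gene_models is not None:
            payload["pathway_marginals"] = self.pathway_marginals(gene_models)
        if provenance:
            payload["provenance"] = provenance
        return json.dumps(payload, indent=2, sort_keys=True)


def build_spectrum(
    effects: Iterable[MutationEffect],
    gene_models: GeneModelSet,
    *,
    include_nonadaptive: bool = False,
) -> ObservedSpectrum:
    """Aggregate classified mutations into an :class:`ObservedSpectrum`.

    Synonymous and intergenic effects are non-adaptive and are excluded from
    WS spectra unless ``include_nonadaptive`` is set; ``n_total`` counts the
    retained effects.
    """
    spectrum = ObservedSpectrum()
    for eff in effects:
        if not include_nonadaptive and eff.mclass in {"synonymous", "intergenic_other"}:
            continue
        gene_models.get(eff.gene_name)  # raises on unknown gene
        key = (eff.gene_name, eff.mclass)
        spectrum.counts[key] = spectrum.counts.get(key, 0) + 1
        spectrum.n_total += 1
    return spectrum


def top_recurrent(
    effects: Sequence[MutationEffect],
) -> list[tuple[str, int]]:
    """Counts of exactly identical mutations, sorted descending.

    Identity is the protein change when available (e.g. two isolates with
    V271G via different codon changes still differ) combined with the exact
    allele description; ties break lexicographically by label.
    """
    counter: Counter[str] = Counter()
    labels: dict[str, str] = {}
    for eff in effects:
        key = eff.record.change_key()
        counter[key] += 1
        labels[key] = eff.change_label()
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], labels[kv[0]]))
    return [(labels[k], n) for k, n in ranked]


_MUTANT_COLUMNS = {
    "isolate_id",
    "experiment",
    "gene_name",
    "coord_system",
    "position",
    "ref",
    "alt",
    "structural_flag",
}


def load_mutant_table(
    tsv_path: str | Path,
    gene_models: Optional[GeneModelSet] = None,
    *,
    experiment: Optional[str] = None,
) -> list[MutationRecord]:
    """Load mutation records from the strict TSV dialect.

    Columns: isolate_id, experiment, gene_name, coord_system, position, ref,
    alt, structural_flag, notes.  '#' lines are comments; unknown columns are
    ignored with a warning.  ``experiment`` filters rows when given.
    """
    records: list[MutationRecord] = []
    with open(tsv_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        fields = set(reader.fieldnames or [])
        missing = _MUTANT_COLUMNS - fields
        if missing:
            raise DataValidationError(
                f"{tsv_path}: missing mutant-table columns {sorted(missing)}"
            )
        extra = fields - _MUTANT_COLUMNS - {"notes", "provenance"}
        if extra:
            warnings.warn(
                f"{tsv_path}: ignoring unknown columns {sorted(extra)}",
                stacklevel=2,
            )
        for lineno, row in enumerate(reader, 2):
            try:
                record = MutationRecord(
                    isolate_id=row["isolate_id"],
                    gene_name=row["gene_name"],
                    coord_system=row["coord_system"],
                    position=int(row["position"]),
                    ref_allele=row["ref"],
                    alt_allele=row["alt"],
                    structural_flag=row["structural_flag"] or None,
                    experiment=row["experiment"],
                    notes=row.get("notes", ""),
                )
            except (KeyError, ValueError, DataValidationError) as exc:
                raise DataValidationError(f"{tsv_path}:{lineno}: {exc}") from exc
            if gene_models is not None:
                if record.gene_name not in gene_models:
                    raise DataValidationError(
                        f"{tsv_path}:{lineno}: unknown gene_name {record.gene_name!r}"
                    )
                _check_ref(record, gene_models.get(record.gene_name))
            if experiment is None or record.experiment == experiment:
                records.append(record)
    return records
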