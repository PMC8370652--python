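"""Gene/operon models: loading, validation, translation and coordinate math.

Conventions
-----------
* All coordinates are 1-based inclusive.
* ``cds_seq`` is always stored on the coding strand, so CDS positions equal
  positions in the stored string.
* Upstream (promoter) positions are <= 0 relative to the first CDS base;
  the regulatory window attributed to a gene/operon is ``upstream_window``
  bp (default 300, configurable per gene).
* Translation uses the bacterial genetic code (NCBI table 11).  GTG/TTG are
  accepted as start codons but rendered as the annotated initiator 'M'.
  Ambiguity codes are rejected outright: downstream target counting needs
  exact sequences.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import DataValidationError, GeneModelError

__all__ = [
    "GeneModel",
    "GeneModelSet",
    "Region",
    "START_CODONS",
    "STOP_CODONS",
    "CODON_TABLE",
    "translate_cds",
    "position_to_codon",
    "codon_to_positions",
    "load_gene_models",
    "load_gene_table",
    "load_regions",
]

_NCBI11 = CodonTable.unambiguous_dna_by_id[11]

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset(_NCBI11.stop_codons)

#: codon -> one-letter amino acid, stops as '*'
CODON_TABLE: dict[str, str] = dict(_NCBI11.forward_table)
CODON_TABLE.update({c: "*" for c in STOP_CODONS})

PATHWAYS = frozenset({"Wsp", "Aws", "Mws", "DgcH", "PFL_3078", "other"})
ROLES = frozenset(
    {"negative_regulator", "dgc", "interacting", "promoter_only", "structural"}
)

_DNA = frozenset("ACGT")


def translate_cds(cds_seq: str, *, first_codon_as_met: bool = True) -> str:
    """Translate a CDS with NCBI table 11; terminal stop rendered as '*'.

    Raises
    ------
    DataValidationError
        If the length is not a multiple of 3 or the sequence contains
        characters outside {A,C,G,T} (no IUPAC expansion).
    """
    seq = cds_seq.upper()
    if len(seq) % 3 != 0:
        raise DataValidationError(
            f"CDS length {len(seq)} is not a multiple of 3"
        )
    bad = set(seq) - _DNA
    if bad:
        raise DataValidationError(
            f"CDS contains non-ACGT characters: {sorted(bad)}"
        )
    aas = []
    for i in range(0, len(seq), 3):
        aas.append(CODON_TABLE[seq[i : i + 3]])
    if first_codon_as_met and aas and seq[:3] in START_CODONS:
        aas[0] = "M"
    return "".join(aas)


def position_to_codon(cds_position: int, cds_length: Optional[int] = None) -> tuple[int, int]:
    """Map a 1-based CDS nucleotide position to (codon_index, offset).

    Both outputs are 1-based; ``cds_position == 3*(codon_index-1) + offset``.
    """
    if cds_position < 1:
        raise DataValidationError(f"CDS position {cds_position} < 1")
    if cds_length is not None and cds_position > cds_length:
        raise DataValidationError(
            f"CDS position {cds_position} exceeds CDS length {cds_length}"
        )
    return (cds_position - 1) // 3 + 1, (cds_position - 1) % 3 + 1


def codon_to_positions(codon_index: int) -> tuple[int, int, int]:
    """Inverse of :func:`position_to_codon`: the three nt positions of a codon."""
    if codon_index < 1:
        raise DataValidationError(f"codon index {codon_index} < 1")
    first = 3 * (codon_index - 1) + 1
    return first, first + 1, first + 2


@dataclass
class GeneModel:
    """One coding sequence with pathway/role annotation."""

    gene_name: str
    cds_seq: str
    locus_tag: Optional[str] = None
    strand: str = "+"
    genomic_start: Optional[int] = None
    genomic_end: Optional[int] = None
    operon: str = ""
    pathway: str = "other"
    role: str = "structural"
    upstream_window: int = 300
    #: downstream operon partner whose expression depends on this gene's
    #: reading frame (polar effects; e.g. awsX -> awsR)
    polar_partner: Optional[str] = None

    def __post_init__(self) -> None:
        self.cds_seq = self.cds_seq.upper()

    # -- derived quantities -------------------------------------------------
    @property
    def protein(self) -> str:
        return translate_cds(self.cds_seq)

    @property
    def protein_length(self) -> int:
        """Residue count including the terminal stop symbol's codon."""
        return len(self.cds_seq) // 3

    def codon(self, codon_index: int) -> str:
        a, _, c = codon_to_positions(codon_index)
        if c > len(self.cds_seq):
            raise DataValidationError(
                f"{self.gene_name}: codon {codon_index} outside CDS"
            )
        return self.cds_seq[a - 1 : c]

    # -- validation ---------------------------------------------------------
    def violations(self) -> list[str]:
        """All invariant violations (empty list means valid)."""
        problems: list[str] = []
        seq = self.cds_seq
        bad = set(seq) - _DNA
        if bad:
            problems.append(f"non-ACGT characters {sorted(bad)}")
        if len(seq) % 3 != 0:
            problems.append(f"length {len(seq)} not divisible by 3")
        if self.strand not in {"+", "-"}:
            problems.append(f"strand {self.strand!r} not in {{+,-}}")
        if self.pathway not in PATHWAYS:
            problems.append(f"unknown pathway {self.pathway!r}")
        if self.role not in ROLES:
            problems.append(f"unknown role {self.role!r}")
        if problems:
            return problems
        if len(seq) < 6:
            problems.append("CDS shorter than two codons")
            return problems
        if seq[:3] not in START_CODONS:
            problems.append(f"start codon {seq[:3]} not in {sorted(START_CODONS)}")
        if seq[-3:] not in STOP_CODONS:
            problems.append(f"final codon {seq[-3:]} is not a stop codon")
        for i in range(3, len(seq) - 3, 3):
            if seq[i : i + 3] in STOP_CODONS:
                problems.append(
                    f"internal stop codon {seq[i:i+3]} at codon {i // 3 + 1}"
                )
        return problems

    def validate(self) -> "GeneModel":
        problems = self.violations()
        if problems:
            raise GeneModelError(
                f"gene {self.gene_name}: " + "; ".join(problems)
            )
        return self


@dataclass
class Region:
    """A predicted mutational region of a gene.

    ``kind`` selects the coordinate system: ``aa_range`` (protein residues),
    ``nt_range`` (CDS nucleotides) or ``upstream`` (positions <= 0 relative
    to the first CDS base).
    """

    gene_name: str
    kind: str
    start: int
    end: int
    allowed_classes: frozenset[str] = frozenset()
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {"aa_range", "nt_range", "upstream"}:
            raise DataValidationError(f"unknown region kind {self.kind!r}")
        if self.start > self.end:
            raise DataValidationError(
                f"region {self.region_id or self.gene_name}: start > end"
            )
        if self.kind == "upstream" and self.end > 0:
            raise DataValidationError(
                f"upstream region {self.region_id or self.gene_name} must end <= 0"
            )
        if not isinstance(self.allowed_classes, frozenset):
            self.allowed_classes = frozenset(self.allowed_classes)
        if not self.region_id:
            self.region_id = f"{self.gene_name}:{self.kind}:{self.start}-{self.end}"

    def contains_aa(self, residue: int) -> bool:
        return self.kind == "aa_range" and self.start <= residue <= self.end

    def validate_against(self, gene: GeneModel) -> "Region":
        if self.kind == "aa_range" and self.end > gene.protein_length:
            raise DataValidationError(
                f"region {self.region_id}: aa range exceeds protein length "
                f"{gene.protein_length} of {gene.gene_name}"
            )
        if self.kind == "nt_range" and self.end > len(gene.cds_seq):
            raise DataValidationError(
                f"region {self.region_id}: nt range exceeds CDS length of "
                f"{gene.gene_name}"
            )
        return self


class GeneModelSet:
    """Indexed collection of gene models (unique by name and locus tag)."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_name: dict[str, GeneModel] = {}
        self._by_tag: dict[str, GeneModel] = {}
        for g in genes:
            g.validate()
            if g.gene_name in self._by_name:
                raise DataValidationError(f"duplicate gene_name {g.gene_name}")
            self._by_name[g.gene_name] = g
            if g.locus_tag:
                if g.locus_tag in self._by_tag:
                    raise DataValidationError(f"duplicate locus_tag {g.locus_tag}")
                self._by_tag[g.locus_tag] = g

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name or name in self._by_tag

    def get(self, name: str) -> GeneModel:
        if name in self._by_name:
            return self._by_name[name]
        if name in self._by_tag:
            return self._by_tag[name]
        raise KeyError(f"unknown gene or locus tag: {name}")

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def by_pathway(self, pathway: str) -> list[GeneModel]:
        return [g for g in self if g.pathway == pathway]


# ---------------------------------------------------------------------------
# loaders


_GENE_TSV_COLUMNS = {
    "gene_name",
    "locus_tag",
    "operon",
    "pathway",
    "role",
    "cds_seq",
    "upstream_window",
}


def load_gene_table(tsv_path: str | Path) -> GeneModelSet:
    """Load gene models from the bundled TSV dialect.

    Columns: gene_name, locus_tag, operon, pathway, role, cds_seq,
    upstream_window and optionally polar_partner. '#'-prefixed lines are
    comments.
    """
    genes: list[GeneModel] = []
    with open(tsv_path, newline="", encoding="utf-8") as fh:
        rows = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        if rows.fieldnames is None or not _GENE_TSV_COLUMNS.issubset(rows.fieldnames):
            missing = _GENE_TSV_COLUMNS - set(rows.fieldnames or [])
            raise DataValidationError(
                f"{tsv_path}: missing gene-table columns {sorted(missing)}"
            )
        for row in rows:
            genes.append(
                GeneModel(
                    gene_name=row["gene_name"],
                    locus_tag=row["locus_tag"] or None,
                    operon=row["operon"],
                    pathway=row["pathway"],
                    role=row["role"],
                    cds_seq=row["cds_seq"],
                    upstream_window=int(row["upstream_window"] or 300),
                    polar_partner=row.get("polar_partner") or None,
                )
            )
    return GeneModelSet(genes)


def _parse_gff3_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for item in attr_field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def load_gene_models(
    fasta_path: str | Path, annotation_path: str | Path
) -> GeneModelSet:
    """Load gene models from FASTA sequences plus a GFF3 or bundled TSV.

    FASTA records are joined to annotation entries by ``gene`` /
    ``locus_tag`` attribute (GFF3) or by ``gene_name`` (TSV with empty
    cds_seq column, in which case sequences come from the FASTA).
    """
    annotation_path = Path(annotation_path)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    if annotation_path.suffix.lower() in {".gff", ".gff3"}:
        genes: list[GeneModel] = []
        with open(annotation_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise DataValidationError(
                        f"{annotation_path}:{lineno}: expected 9 GFF3 columns"
                    )
                if fields[2] not in {"CDS", "gene"}:
                    continue
                attrs = _parse_gff3_attributes(fields[8])
                name = attrs.get("gene") or attrs.get("Name")
                tag = attrs.get("locus_tag")
                key = name or tag
                if key is None:
                    raise DataValidationError(
                        f"{annotation_path}:{lineno}: CDS without gene=/locus_tag="
                    )
                seq = seqs.get(key) or (tag and seqs.get(tag)) or (name and seqs.get(name))
                if not seq:
                    raise DataValidationError(
                        f"missing FASTA sequence for annotated gene {key}"
                    )
                genes.append(
                    GeneModel(
                        gene_name=name or key,
                        locus_tag=tag,
                        strand=fields[6] if fields[6] in "+-" else "+",
                        genomic_start=int(fields[3]),
                        genomic_end=int(fields[4]),
                        operon=attrs.get("operon", ""),
                        pathway=attrs.get("pathway", "other"),
                        role=attrs.get("role", "structural"),
                        cds_seq=seq,
                    )
                )
        return GeneModelSet(genes)

    # TSV annotation: sequences may come from the TSV itself or the FASTA
    gene_set = load_gene_table(annotation_path)
    missing = [g.gene_name for g in gene_set if not g.cds_seq and g.gene_name not in seqs]
    if missing:
        raise DataValidationError(
            f"missing FASTA sequence for annotated genes: {missing}"
        )
    return gene_set


def load_regions(tsv_path: str | Path, genes: Optional[GeneModelSet] = None) -> list[Region]:
    """Load region definitions (TSV: gene_name, kind, start, end, allowed_classes[, region_id])."""
    regions: list[Region] = []
    with open(tsv_path, newline="", encoding="utf-8") as fh:
        rows = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        for lineno, row in enumerate(rows, 2):
            try:
                region = Region(
                    gene_name=row["gene_name"],
                    kind=row["kind"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    allowed_classes=frozenset(
                        c for c in row["allowed_classes"].replace("|", ",").split(",") if c
                    ),
                    region_id=row.get("region_id", "") or "",
                )
            except (KeyError, ValueError) as exc:
                raise DataValidationError(f"{tsv_path}:{lineno}: {exc}") from exc
            if genes is not None:
                region.validate_against(genes.get(region.gene_name))
            regions.append(region)
    return regions
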