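"""Synthetic-data generators and the bundled reference fixtures.

Every generator is a pure function of its parameters and seed, and every
output passes the validators of the module that consumes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import DataValidationError
from .fitness import CompetitionCounts
from .gene_models import (
    START_CODONS,
    STOP_CODONS,
    GeneModelSet,
    Region,
    load_gene_table,
    load_regions,
    translate_cds,
)
from .mutation_catalog import MutationRecord, load_mutant_table

__all__ = [
    "gen_cds",
    "plant_repeat",
    "gen_competition_counts",
    "Pf5Fixtures",
    "pf5_fixtures",
    "fixture_path",
]

_BASES = np.array(list("ACGT"))
_STOPS = sorted(STOP_CODONS)


def _codon_pool(gc_content: float) -> tuple[list[str], np.ndarray]:
    """All 61 sense codons with weights matching the target GC content."""
    p = {
        "A": (1 - gc_content) / 2,
        "T": (1 - gc_content) / 2,
        "G": gc_content / 2,
        "C": gc_content / 2,
    }
    codons, weights = [], []
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                codon = a + b + c
                if codon in STOP_CODONS:
                    continue
                codons.append(codon)
                weights.append(p[a] * p[b] * p[c])
    w = np.asarray(weights)
    return codons, w / w.sum()


def gen_cds(n_codons: int, gc_content: float = 0.5, seed: int = 0) -> str:
    """A valid random CDS: ATG start, stop end, no internal in-frame stops."""
    if n_codons < 2:
        raise DataValidationError("a CDS needs at least 2 codons (start + stop)")
    if not (0.0 < gc_content < 1.0):
        raise DataValidationError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    codons, weights = _codon_pool(gc_content)
    body = rng.choice(codons, size=n_codons - 2, p=weights)
    stop = rng.choice(_STOPS)
    return "ATG" + "".join(body) + stop


def _cds_valid(seq: str) -> bool:
    if len(seq) % 3 != 0 or len(seq) < 6:
        return False
    if seq[:3] not in START_CODONS or seq[-3:] not in STOP_CODONS:
        return False
    return all(
        seq[i : i + 3] not in STOP_CODONS for i in range(3, len(seq) - 3, 3)
    )


def plant_repeat(
    cds: str,
    repeat_len: int,
    separation: int,
    position: int,
    seed: int = 0,
    max_attempts: int = 100,
) -> str:
    """Copy the ``repeat_len``-bp substring at ``position`` (1-based) to
    ``position + separation``, so a direct-repeat deletion of length
    ``separation`` becomes available there.

    The result must remain a valid CDS; the source window is re-drawn at
    random (seeded) for a bounded number of attempts before failing.
    """
    if position < 1 or position + separation + repeat_len - 1 > len(cds):
        raise DataValidationError("planting region outside the CDS")
    if separation < repeat_len:
        raise DataValidationError(
            "overlapping repeats (separation < repeat_len) cannot be planted"
        )
    rng = np.random.default_rng(seed)
    codons, weights = _codon_pool(0.5)

    def attempt(repeat: str) -> Optional[str]:
        left = position - 1
        right = left + separation
        out = cds[:left] + repeat + cds[left + repeat_len : right] + repeat + cds[right + repeat_len :]
        return out if _cds_valid(out) and len(out) == len(cds) else None

    candidate = attempt(cds[position - 1 : position - 1 + repeat_len])
    if candidate is not None:
        return candidate
    for _ in range(max_attempts):
        repeat = "".join(
            rng.choice(list("ACGT"), size=repeat_len)
        )
        candidate = attempt(repeat)
        if candidate is not None:
            return candidate
    raise DataValidationError(
        f"could not plant a {repeat_len}-bp repeat at position {position} "
        f"without breaking CDS validity after {max_attempts} attempts"
    )


def gen_competition_counts(
    true_s: float,
    initial_ratio: float,
    generations: float,
    sampling_depth: int,
    n_replicates: int,
    seed: int = 0,
    assay: str = "competition",
    noise: bool = True,
    strain_id: str = "synthetic",
    reference_id: str = "reference",
) -> list[CompetitionCounts]:
    """Replicated CFU counts around an exponential ratio trajectory.

    The true trajectory is R(t) = R(0) * exp(s*t); plating draws
    ``sampling_depth`` colonies per timepoint multinomially between mutant
    and reference.  With ``noise=False`` the expected (real-valued) counts
    are returned, so the estimator inverts the generator exactly.
    """
    if sampling_depth < 1:
        raise DataValidationError("sampling_depth must be >= 1")
    if initial_ratio <= 0:
        raise DataValidationError("initial_ratio must be positive")
    rng = np.random.default_rng(seed)
    r0 = initial_ratio
    r1 = r0 * math.exp(true_s * generations)
    f0 = r0 / (1 + r0)
    f1 = r1 / (1 + r1)
    out = []
    for rep in range(1, n_replicates + 1):
        if noise:
            m0 = int(rng.binomial(sampling_depth, f0))
            m1 = int(rng.binomial(sampling_depth, f1))
            t0_m, t0_r = float(m0), float(sampling_depth - m0)
            t1_m, t1_r = float(m1), float(sampling_depth - m1)
        else:
            t0_m, t0_r = sampling_depth * f0, sampling_depth * (1 - f0)
            t1_m, t1_r = sampling_depth * f1, sampling_depth * (1 - f1)
        out.append(
            CompetitionCounts(
                strain_id=strain_id,
                reference_id=reference_id,
                assay=assay,
                replicate=rep,
                t0_mutant=t0_m,
                t0_reference=t0_r,
                t1_mutant=t1_m,
                t1_reference=t1_r,
                generations=generations,
            )
        )
    return out


# ---------------------------------------------------------------------------
# bundled fixtures


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(resources.files("wsforecast").joinpath("data", name)))


@dataclass
class Pf5Fixtures:
    """The transcribed reference dataset.

    ``expectations`` records the printed summary counts the fixtures were
    transcribed against, each tagged with its provenance.
    """

    gene_models: GeneModelSet
    wt_mutants: list[MutationRecord]
    triple_deletion_mutants: list[MutationRecord]
    regions: list[Region]
    expectations: dict
    competition_counts: dict[str, list[CompetitionCounts]]


_EXPECTATIONS = {
    "wt_total": {"value": 43, "provenance": "main text"},
    "triple_deletion_total": {"value": 7, "provenance": "main text"},
    "triple_deletion_pfl0087": {"value": 6, "provenance": "main text"},
    "pathway_counts": {
        "value": {"Wsp": 16, "Aws": 14, "Mws": 10, "PFL_3078": 3},
        "provenance": "main text",
    },
    "gene_counts": {
        "value": {"wspF": 15, "awsX": 9, "wspE": 1, "awsR": 3, "mwsR": 10},
        "provenance": "main text",
    },
    "top_recurrent": {"value": ["WspF V271G", 11], "provenance": "main text"},
    "negative_regulation_coding": {"value": 38, "provenance": "main text"},
    "in_three_pathways": {"value": 40, "provenance": "main text"},
    "region_coverage": {"value": [16, 22], "provenance": "main text"},
    "predicted_pathway_percent": {
        "value": {"Wsp": 54.0, "Aws": 30.0, "Mws": 16.0},
        "provenance": "main text",
    },
    "competition_lowest_s": {
        "value": {"strain": "PFL_3078_promoter", "s": -0.1},
        "provenance": "main text (approximate printed value)",
    },
}


def pf5_fixtures() -> Pf5Fixtures:
    """Load the bundled transcription of the reference mutant dataset.

    Nucleotide-level coordinates not printed in the source tables are
    placeholder values consistent with the gene-level mutation classes; each
    fixture row carries a provenance note distinguishing transcribed from
    reconstructed fields.
    """
    genes = load_gene_table(fixture_path("pf5_genes.tsv"))
    wt = load_mutant_table(fixture_path("pf5_mutants.tsv"), genes, experiment="wt")
    triple = load_mutant_table(
        fixture_path("pf5_mutants.tsv"), genes, experiment="triple_deletion"
    )
    regions = load_regions(fixture_path("pf5_regions.tsv"), genes)
    from .fitness import load_cfu_table  # local import to avoid a cycle

    competition = load_cfu_table(fixture_path("pf5_competition.tsv"))
    return Pf5Fixtures(
        gene_models=genes,
        wt_mutants=wt,
        triple_deletion_mutants=triple,
        regions=regions,
        expectations=_EXPECTATIONS,
        competition_counts=competition,
    )
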