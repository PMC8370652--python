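"""Selection-coefficient estimation from competition-assay CFU counts.

The estimator is s = ln(R(t)/R(0)) / t with R the dilution-corrected ratio
of mutant to reference CFU; s = 0 means equal fitness and positive s means
the mutant is fitter than the reference.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DataValidationError

__all__ = [
    "CompetitionCounts",
    "SelectionEstimate",
    "StrainSummary",
    "selection_coefficient",
    "estimate_replicates",
    "summarize_fitness",
    "invasion_check",
    "load_cfu_table",
]


@dataclass
class CompetitionCounts:
    """CFU counts of one replicate of a pairwise competition."""

    strain_id: str
    reference_id: str
    assay: str  # invasion | competition
    replicate: int
    t0_mutant: float
    t0_reference: float
    t1_mutant: float
    t1_reference: float
    generations: float
    dilution_t0: float = 1.0
    dilution_t1: float = 1.0

    def __post_init__(self) -> None:
        if self.assay not in {"invasion", "competition"}:
            raise DataValidationError(f"unknown assay {self.assay!r}")
        for name in ("t0_mutant", "t0_reference", "t1_mutant", "t1_reference"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"{name} must be >= 0")
        if self.t0_reference <= 0 or self.t1_reference <= 0:
            raise DataValidationError(
                f"{self.strain_id} rep {self.replicate}: reference counts must be "
                "positive at both timepoints"
            )
        if self.generations <= 0:
            raise DataValidationError("generations must be positive")
        if self.dilution_t0 <= 0 or self.dilution_t1 <= 0:
            raise DataValidationError("dilution factors must be positive")


def selection_coefficient(
    counts: CompetitionCounts, *, pseudocount: float = 0.0
) -> tuple[float, bool]:
    """Per-generation selection coefficient for one replicate.

    Returns ``(s, censored)``.  A zero mutant count at t1 is left-censored:
    the value returned is a lower bound computed with half a count and the
    flag is set.  A zero mutant count at t0 leaves s undefined and raises.
    ``pseudocount`` (optional, e.g. 0.5) is added to both mutant counts; no
    correction is applied by default.
    """
    m0 = counts.t0_mutant + pseudocount
    m1 = counts.t1_mutant + pseudocount
    if m0 <= 0:
        raise DataValidationError(
            f"{counts.strain_id} rep {counts.replicate}: zero mutant count at t0; "
            "selection coefficient undefined"
        )
    censored = False
    if m1 <= 0:
        m1 = 0.5
        censored = True
    r0 = (m0 * counts.dilution_t0) / (counts.t0_reference * counts.dilution_t0)
    r1 = (m1 * counts.dilution_t1) / (counts.t1_reference * counts.dilution_t1)
    return math.log(r1 / r0) / counts.generations, censored


@dataclass
class SelectionEstimate:
    """Replicate-averaged selection coefficient for one strain/assay."""

    strain_id: str
    assay: str
    s: float
    sd: Optional[float]
    se: Optional[float]
    ci: Optional[tuple[float, float]]
    n: int
    replicate_values: tuple[float, ...] = ()
    any_censored: bool = False


def estimate_replicates(
    counts: Sequence[CompetitionCounts],
    *,
    alpha: float = 0.05,
    pseudocount: float = 0.0,
) -> SelectionEstimate:
    """Combine replicates of one strain/assay into a mean with a t-based CI."""
    if not counts:
        raise DataValidationError("no replicates supplied")
    strain = counts[0].strain_id
    assay = counts[0].assay
    if any(c.strain_id != strain or c.assay != assay for c in counts):
        raise DataValidationError("replicates mix strains or assays")
    values, censored_flags = [], []
    for c in counts:
        s, cen = selection_coefficient(c, pseudocount=pseudocount)
        values.append(s)
        censored_flags.append(cen)
    arr = np.asarray(values)
    n = len(arr)
    mean = float(arr.mean())
    if n < 2:
        return SelectionEstimate(
            strain, assay, mean, None, None, None, n, tuple(values),
            any_censored=any(censored_flags),
        )
    sd = float(arr.std(ddof=1))
    se = sd / math.sqrt(n)
    tcrit = float(stats.t.ppf(1 - alpha / 2, n - 1))
    ci = (mean - tcrit * se, mean + tcrit * se)
    return SelectionEstimate(
        strain, assay, mean, sd, se, ci, n, tuple(values),
        any_censored=any(censored_flags),
    )


@dataclass
class StrainSummary:
    estimate: SelectionEstimate
    vs_reference_p: Optional[float] = None
    vs_reference_p_holm: Optional[float] = None
    significant: Optional[bool] = None


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    order = sorted(range(len(pvals)), key=lambda i: pvals[i])
    adjusted = [0.0] * len(pvals)
    running = 0.0
    m = len(pvals)
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def summarize_fitness(
    counts_by_strain: dict[str, Sequence[CompetitionCounts]],
    reference_strain: Optional[str] = None,
    *,
    alpha: float = 0.05,
    pseudocount: float = 0.0,
) -> dict[str, StrainSummary]:
    """Per-strain estimates plus pairwise two-sided t-tests vs a reference.

    Comparisons follow the uncorrected per-pair procedure at the stated
    alpha (the default reproduction mode) but Holm-adjusted p-values are
    reported alongside.
    """
    estimates = {
        strain: estimate_replicates(reps, alpha=alpha, pseudocount=pseudocount)
        for strain, reps in counts_by_strain.items()
    }
    summaries = {s: StrainSummary(est) for s, est in estimates.items()}
    if reference_strain is not None:
        if reference_strain not in estimates:
            raise DataValidationError(
                f"reference strain {reference_strain!r} not in the table"
            )
        ref_values = estimates[reference_strain].replicate_values
        tested = []
        for strain, summary in summaries.items():
            if strain == reference_strain:
                continue
            vals = summary.estimate.replicate_values
            if len(vals) < 2 or len(ref_values) < 2:
                continue
            _, p = stats.ttest_ind(vals, ref_values, equal_var=False)
            summary.vs_reference_p = float(p)
            tested.append(strain)
        holm = _holm([summaries[s].vs_reference_p for s in tested])
        for strain, p_adj in zip(tested, holm):
            summaries[strain].vs_reference_p_holm = p_adj
            summaries[strain].significant = summaries[strain].vs_reference_p < alpha
    return summaries


def invasion_check(estimate: SelectionEstimate) -> str:
    """{adaptive, neutral, deleterious} from the CI's position relative to 0."""
    if estimate.ci is None:
        raise DataValidationError(
            "invasion_check needs a CI (>= 2 replicates)"
        )
    lo, hi = estimate.ci
    if lo > 0:
        return "adaptive"
    if hi < 0:
        return "deleterious"
    return "neutral"


_CFU_COLUMNS = {
    "strain_id",
    "reference_id",
    "assay",
    "replicate",
    "t0_mutant",
    "t0_reference",
    "t1_mutant",
    "t1_reference",
    "dilution_t0",
    "dilution_t1",
    "generations",
}


def load_cfu_table(tsv_path: str | Path) -> dict[str, list[CompetitionCounts]]:
    """Load a CFU TSV grouped by (strain, assay) key ``strain_id/assay``."""
    grouped: dict[str, list[CompetitionCounts]] = {}
    with open(tsv_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        missing = _CFU_COLUMNS - set(reader.fieldnames or [])
        if missing:
            raise DataValidationError(
                f"{tsv_path}: missing CFU columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, 2):
            try:
                counts = CompetitionCounts(
                    strain_id=row["strain_id"],
                    reference_id=row["reference_id"],
                    assay=row["assay"],
                    replicate=int(row["replicate"]),
                    t0_mutant=float(row["t0_mutant"]),
                    t0_reference=float(row["t0_reference"]),
                    t1_mutant=float(row["t1_mutant"]),
                    t1_reference=float(row["t1_reference"]),
                    dilution_t0=float(row["dilution_t0"]),
                    dilution_t1=float(row["dilution_t1"]),
                    generations=float(row["generations"]),
                )
            except (ValueError, KeyError, DataValidationError) as exc:
                raise DataValidationError(f"{tsv_path}:{lineno}: {exc}") from exc
            grouped.setdefault(f"{counts.strain_id}/{counts.assay}", []).append(counts)
    return grouped
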