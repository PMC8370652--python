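"""Scoring forecasts against observations.

Goodness-of-fit of spectra (G test and exact multinomial), rank agreement,
mutated-region coverage, and the machine-readable scoreboard for the eight
hierarchical predictions.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DataValidationError, ModelError
from .gene_models import GeneModelSet, Region
from .mutation_catalog import (
    CODING_CLASSES,
    MutationEffect,
    ObservedSpectrum,
)
from .pathway_model import PredictedSpectrum, rank_genes

__all__ = [
    "GoodnessOfFit",
    "PredictionScore",
    "RegionCoverage",
    "g_test",
    "exact_multinomial_p",
    "rank_agreement",
    "region_coverage",
    "evaluate_predictions",
    "render_report",
]


@dataclass
class GoodnessOfFit:
    statistic: str  # "G" | "exact_multinomial"
    value: float
    df: Optional[int]
    p: float
    expected: Optional[list[float]] = None
    mc_se: Optional[float] = None
    infinite: bool = False


def g_test(
    observed_counts: Sequence[int], predicted_probs: Sequence[float]
) -> GoodnessOfFit:
    """Log-likelihood-ratio goodness of fit: G = 2 sum O_i ln(O_i/E_i).

    Zero observed cells contribute 0; a zero-probability cell with a
    positive observation sets the infinite-G flag instead of raising.
    """
    obs = np.asarray(observed_counts, dtype=float)
    probs = np.asarray(predicted_probs, dtype=float)
    if obs.shape != probs.shape:
        raise DataValidationError("observed and predicted lengths differ")
    n = obs.sum()
    if n <= 0:
        raise DataValidationError("need at least one observation")
    if not math.isclose(probs.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise DataValidationError("predicted probabilities must sum to 1")
    expected = n * probs
    df = len(obs) - 1
    if np.any((probs == 0) & (obs > 0)):
        return GoodnessOfFit("G", math.inf, df, 0.0, list(expected), infinite=True)
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    g = max(g, 0.0)
    p = float(stats.chi2.sf(g, df))
    return GoodnessOfFit("G", g, df, p, list(expected))


def _compositions(n: int, k: int) -> Iterable[tuple[int, ...]]:
    """All k-part compositions of n (ordered, parts >= 0)."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def exact_multinomial_p(
    observed: Sequence[int],
    probs: Sequence[float],
    max_enumeration: int = 200_000,
    mc_reps: int = 100_000,
    seed: int = 0,
) -> GoodnessOfFit:
    """Exact multinomial test: mass of outcomes no more probable than observed.

    Falls back to Monte Carlo (with a binomial standard error on the
    estimate) when the outcome space exceeds ``max_enumeration``.
    """
    obs = tuple(int(x) for x in observed)
    probs = np.asarray(probs, dtype=float)
    if len(obs) != len(probs):
        raise DataValidationError("observed and probs lengths differ")
    if not math.isclose(probs.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise DataValidationError("probs must sum to 1")
    n = sum(obs)
    if n <= 0:
        raise DataValidationError("need at least one observation")
    k = len(obs)
    n_outcomes = math.comb(n + k - 1, k - 1)
    dist = stats.multinomial(n, probs)
    p_obs = float(dist.pmf(obs))

    if n_outcomes <= max_enumeration:
        total = 0.0
        for outcome in _compositions(n, k):
            mass = float(dist.pmf(outcome))
            if mass <= p_obs * (1 + 1e-9):
                total += mass
        return GoodnessOfFit("exact_multinomial", p_obs, None, min(total, 1.0))

    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=mc_reps)
    masses = dist.pmf(draws)
    hits = int(np.sum(masses <= p_obs * (1 + 1e-9)))
    p_hat = hits / mc_reps
    se = math.sqrt(max(p_hat * (1 - p_hat), 1.0 / mc_reps) / mc_reps)
    return GoodnessOfFit("exact_multinomial", p_obs, None, p_hat, mc_se=se)


def rank_agreement(
    predicted: Mapping[str, float], observed: Mapping[str, int]
) -> dict:
    """Order concordance over shared categories (exact match + Kendall tau-b)."""
    shared = sorted(set(predicted) & set(observed))
    if len(shared) < 2:
        raise DataValidationError(
            "rank agreement needs >= 2 shared categories"
        )
    pred = [predicted[c] for c in shared]
    obs = [observed[c] for c in shared]
    pred_order = [c for _, c in sorted(zip(pred, shared), key=lambda t: (-t[0], t[1]))]
    obs_order = [c for _, c in sorted(zip(obs, shared), key=lambda t: (-t[0], t[1]))]
    tau, tau_p = stats.kendalltau(pred, obs, variant="b")
    return {
        "categories": shared,
        "predicted_order": pred_order,
        "observed_order": obs_order,
        "exact_order_match": pred_order == obs_order,
        "kendall_tau": float(tau),
        "kendall_p": float(tau_p),
    }


@dataclass
class RegionCoverage:
    covered_count: int
    total_distinct_sites: int
    groups: list[dict] = field(default_factory=list)

    @property
    def fraction(self) -> float:
        return (
            self.covered_count / self.total_distinct_sites
            if self.total_distinct_sites
            else 0.0
        )


def _matching_region(
    effect: MutationEffect, regions: Sequence[Region]
) -> Optional[Region]:
    if effect.aa_position is None:
        return None
    for region in regions:
        if region.gene_name != effect.gene_name:
            continue
        if effect.mclass not in region.allowed_classes:
            continue
        if region.contains_aa(effect.aa_position):
            return region
    return None


def region_coverage(
    effects: Sequence[MutationEffect], regions: Sequence[Region]
) -> RegionCoverage:
    """Coverage of distinct mutated protein sites/regions by predictions.

    Only protein-coding effects enter (promoter and structural events are
    not protein sites).  Identical changes collapse to one site; distinct
    changes within the same gene additionally collapse when they fall inside
    one contiguous predicted region matching their class.  A site is covered
    iff it lies inside a matching predicted region of its gene.
    """
    coding = [e for e in effects if e.mclass in CODING_CLASSES]
    genes_without_regions = {
        e.gene_name for e in coding
    } - {r.gene_name for r in regions}
    if genes_without_regions:
        warnings.warn(
            "no region definitions for gene(s) "
            f"{sorted(genes_without_regions)}; their sites count uncovered",
            stacklevel=2,
        )
    group_of: dict[str, dict] = {}
    for eff in coding:
        region = _matching_region(eff, regions)
        key = region.region_id if region is not None else eff.record.change_key()
        entry = group_of.setdefault(
            key,
            {
                "gene": eff.gene_name,
                "covered": region is not None,
                "region_id": region.region_id if region else None,
                "members": [],
                "n_isolates": 0,
            },
        )
        entry["members"].append(eff.change_label())
        entry["n_isolates"] += 1
    groups = sorted(group_of.values(), key=lambda g: (g["gene"], str(g["region_id"])))
    covered = sum(1 for g in groups if g["covered"])
    return RegionCoverage(covered, len(groups), groups)


@dataclass
class PredictionScore:
    prediction_id: int
    status: str  # supported | partially_supported | failed | not_computable
    evidence: dict = field(default_factory=dict)

    STATUSES = ("supported", "partially_supported", "failed", "not_computable")

    def __post_init__(self) -> None:
        if self.status not in self.STATUSES:
            raise ModelError(f"unknown prediction status {self.status!r}")
        if self.status != "not_computable" and not self.evidence:
            raise ModelError("a computed status requires evidence")


def _class_frequency_order(
    spectrum: ObservedSpectrum, gene_models: GeneModelSet
) -> dict:
    """Counts of LOF vs promoter vs activating mutation groups."""
    lof = promoter = activating = 0
    for (gene, mclass), n in spectrum.counts.items():
        if mclass in {"promoter_point", "promoter_capture"}:
            promoter += n
        elif mclass in CODING_CLASSES:
            role = gene_models.get(gene).role
            if role == "negative_regulator" or mclass in {
                "nonsense",
                "frameshift_indel",
            }:
                lof += n
            else:
                activating += n
    return {"loss_of_function": lof, "promoter": promoter, "activating": activating}


def evaluate_predictions(
    observed: Optional[ObservedSpectrum],
    gene_models: GeneModelSet,
    predicted: Optional[PredictedSpectrum] = None,
    effects: Sequence[MutationEffect] = (),
    regions: Sequence[Region] = (),
    fitness_by_strain: Optional[Mapping[str, float]] = None,
    rare_predicted_strains: Sequence[str] = (),
    phenotype_tables: Optional[Mapping] = None,
    coverage_threshold: float = 0.5,
) -> list[PredictionScore]:
    """Score the eight hierarchical predictions from available inputs.

    Missing inputs degrade individual predictions to ``not_computable``.
    """
    scores: list[PredictionScore] = []

    # P1-P3 are phenotype-level (interface colonization, EPS morphology,
    # motility) and need phenotype tables.
    for pid in (1, 2, 3):
        if phenotype_tables and pid in phenotype_tables:
            table = phenotype_tables[pid]
            ok = bool(table.get("supported"))
            scores.append(
                PredictionScore(pid, "supported" if ok else "failed", dict(table))
            )
        else:
            scores.append(PredictionScore(pid, "not_computable"))

    if observed is None or observed.n_total == 0:
        for pid in (4, 5, 6, 7, 8):
            scores.append(PredictionScore(pid, "not_computable"))
        return scores

    # P4: class frequency order LOF > promoter > activating
    order = _class_frequency_order(observed, gene_models)
    ok4 = (
        order["loss_of_function"] > order["promoter"] > order["activating"]
    )
    partial4 = order["loss_of_function"] > order["promoter"]
    scores.append(
        PredictionScore(
            4,
            "supported" if ok4 else ("partially_supported" if partial4 else "failed"),
            order,
        )
    )

    # P5: majority of mutations in the Wsp/Aws/Mws pathways
    marginals = observed.pathway_marginals(gene_models)
    in_three = sum(marginals.get(p, 0) for p in ("Wsp", "Aws", "Mws"))
    scores.append(
        PredictionScore(
            5,
            "supported" if in_three > observed.n_total / 2 else "failed",
            {
                "in_three_pathways": in_three,
                "n_total": observed.n_total,
                "pathway_marginals": marginals,
            },
        )
    )

    # P6: pathway order matches the predicted spectrum; per-gene top set
    if predicted is None:
        scores.append(PredictionScore(6, "not_computable"))
    else:
        agreement = rank_agreement(
            predicted.pathway_probs,
            {p: marginals.get(p, 0) for p in predicted.pathway_probs},
        )
        top_pred = set(rank_genes(predicted)[:6])
        observed_genes = set(observed.gene_marginals())
        missing = sorted(top_pred - observed_genes)
        status = "supported" if agreement["exact_order_match"] else (
            "partially_supported" if agreement["kendall_tau"] > 0 else "failed"
        )
        evidence = dict(agreement)
        evidence["top6_predicted_genes"] = sorted(top_pred)
        evidence["predicted_genes_without_observations"] = missing
        scores.append(PredictionScore(6, status, evidence))

    # P7: region coverage of distinct mutated sites
    if effects and regions:
        cov = region_coverage(effects, regions)
        scores.append(
            PredictionScore(
                7,
                "supported" if cov.fraction >= coverage_threshold else "failed",
                {
                    "covered": cov.covered_count,
                    "total": cov.total_distinct_sites,
                    "fraction": cov.fraction,
                },
            )
        )
    else:
        scores.append(PredictionScore(7, "not_computable"))

    # P8: rare predicted mutants have lower competition fitness
    if fitness_by_strain and rare_predicted_strains:
        rare = [s for s in rare_predicted_strains if s in fitness_by_strain]
        common = [
            s for s in fitness_by_strain if s not in rare_predicted_strains
        ]
        if rare and common:
            rare_mean = float(np.mean([fitness_by_strain[s] for s in rare]))
            common_mean = float(np.mean([fitness_by_strain[s] for s in common]))
            scores.append(
                PredictionScore(
                    8,
                    "supported" if rare_mean < common_mean else "failed",
                    {
                        "rare_strains": rare,
                        "rare_mean_s": rare_mean,
                        "common_mean_s": common_mean,
                    },
                )
            )
        else:
            scores.append(PredictionScore(8, "not_computable"))
    else:
        scores.append(PredictionScore(8, "not_computable"))

    return scores


def render_report(scores: Sequence[PredictionScore]) -> str:
    lines = ["Prediction scoreboard", "=" * 21]
    for score in sorted(scores, key=lambda s: s.prediction_id):
        lines.append(f"P{score.prediction_id}: {score.status}")
        for key, value in score.evidence.items():
            lines.append(f"    {key}: {value}")
    return "\n".join(lines) + "\n"


def scores_to_json(scores: Sequence[PredictionScore]) -> str:
    return json.dumps(
        [
            {
                "prediction_id": s.prediction_id,
                "status": s.status,
                "evidence": s.evidence,
            }
            for s in sorted(scores, key=lambda s: s.prediction_id)
        ],
        indent=2,
        default=str,
    )
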