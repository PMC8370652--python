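"""Stochastic simulation of static-well experimental evolution.

Resident growth is deterministic exponential (doubling per generation up to
the final population size); stochasticity enters only through mutant
arrivals, Poisson per generation with mean mu_k * N_i (the standard
Luria-Delbruck approximation at these population sizes).  Each mutant
lineage grows with a per-generation factor 2*exp(s_k).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import DataValidationError, ModelError

__all__ = [
    "MicrocosmParams",
    "WellOutcome",
    "ExperimentResult",
    "generations_elapsed",
    "simulate_well",
    "simulate_experiment",
    "knockout",
    "estimate_total_rate",
]


def generations_elapsed(n0: float, nf: float) -> float:
    """Whole-population generations of growth from ``n0`` to ``nf`` cells."""
    if n0 <= 0 or nf <= 0:
        raise DataValidationError("population sizes must be positive")
    if nf <= n0:
        raise DataValidationError("final size must exceed initial size")
    return math.log2(nf / n0)


@dataclass
class MicrocosmParams:
    """Parameters of one static-well evolution experiment.

    ``mu`` maps a mutant class label (here: gene names) to its absolute
    per-cell, per-generation mutation rate; ``s`` to its per-generation
    Malthusian selection coefficient; ``pathway_of`` to its pathway label
    (used by :func:`knockout`).
    """

    mu: dict[str, float] = field(default_factory=dict)
    s: dict[str, float] = field(default_factory=dict)
    pathway_of: dict[str, str] = field(default_factory=dict)
    n0: float = 1e3
    nf: float = 4e8
    f_detect: float = 0.01
    wells: int = 60  # 30 central wells x 2 occasions

    def __post_init__(self) -> None:
        if not (0 < self.n0 < self.nf):
            raise DataValidationError("require 0 < N0 < Nf")
        if not (0 < self.f_detect <= 1):
            raise DataValidationError("require 0 < f_detect <= 1")
        if any(m < 0 for m in self.mu.values()):
            raise DataValidationError("mutation rates must be >= 0")

    @property
    def classes(self) -> list[str]:
        return sorted(self.mu)

    def selection(self, label: str) -> float:
        return self.s.get(label, 0.0)


@dataclass
class WellOutcome:
    """Endpoint state of one well."""

    frequencies: dict[str, float]
    detected: list[str]
    sampled_mutant: Optional[str]


@dataclass
class ExperimentResult:
    """Aggregate over wells: one sampled mutant per detecting well."""

    sampled_counts: dict[str, int]
    n_wells: int
    n_detecting: int

    @property
    def detection_fraction(self) -> float:
        return self.n_detecting / self.n_wells if self.n_wells else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "sampled_counts": dict(sorted(self.sampled_counts.items())),
                "n_wells": self.n_wells,
                "n_detecting": self.n_detecting,
                "detection_fraction": self.detection_fraction,
            },
            indent=2,
        )


def _simulate_wells(
    params: MicrocosmParams, n_wells: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Endpoint frequency matrix (n_wells x n_classes) for all wells."""
    labels = params.classes
    k = len(labels)
    n_gen = math.ceil(generations_elapsed(params.n0, params.nf))
    freqs = np.zeros((n_wells, max(k, 1)))
    if k == 0:
        return freqs, labels
    mu = np.array([params.mu[c] for c in labels])
    growth = np.array([2.0 * math.exp(params.selection(c)) for c in labels])

    # resident size at the start of each generation, capped at Nf
    n_i = np.minimum(params.n0 * np.power(2.0, np.arange(n_gen)), params.nf)
    # arrivals[w, i, c] ~ Poisson(mu_c * N_i)
    lam = np.broadcast_to(n_i[:, None] * mu[None, :], (n_gen, k))
    arrivals = rng.poisson(np.broadcast_to(lam, (n_wells, n_gen, k)))
    # lineage founded in generation i grows for (n_gen - i) generations
    expansion = growth[None, :] ** np.arange(n_gen, 0, -1)[:, None]
    mutant_sizes = (arrivals * expansion[None, :, :]).sum(axis=1)

    total = params.nf + mutant_sizes.sum(axis=1, keepdims=True)
    freqs = mutant_sizes / total
    return freqs, labels


def _outcome_from_freqs(
    freqs: np.ndarray, labels: list[str], f_detect: float, rng: np.random.Generator
) -> WellOutcome:
    detected = [labels[j] for j in range(len(labels)) if freqs[j] >= f_detect]
    sampled = None
    if detected:
        # a single divergent colony is picked at random from the plate, so
        # classes are sampled proportional to their endpoint frequency
        w = np.array([freqs[labels.index(c)] for c in detected])
        sampled = detected[rng.choice(len(detected), p=w / w.sum())]
    return WellOutcome(
        frequencies={c: float(f) for c, f in zip(labels, freqs)},
        detected=detected,
        sampled_mutant=sampled,
    )


def simulate_well(params: MicrocosmParams, rng: np.random.Generator) -> WellOutcome:
    """Simulate a single well with the generation-stepped scheme."""
    freqs, labels = _simulate_wells(params, 1, rng)
    return _outcome_from_freqs(freqs[0], labels, params.f_detect, rng)


def simulate_experiment(
    params: MicrocosmParams, n_wells: Optional[int] = None, seed: int = 0
) -> ExperimentResult:
    """Simulate ``n_wells`` independent wells; bit-reproducible for a fixed seed."""
    n_wells = params.wells if n_wells is None else n_wells
    rng = np.random.default_rng(seed)
    freqs, labels = _simulate_wells(params, n_wells, rng)
    counts: dict[str, int] = {}
    n_detecting = 0
    for w in range(n_wells):
        outcome = _outcome_from_freqs(freqs[w], labels, params.f_detect, rng)
        if outcome.sampled_mutant is not None:
            n_detecting += 1
            counts[outcome.sampled_mutant] = counts.get(outcome.sampled_mutant, 0) + 1
    return ExperimentResult(sampled_counts=counts, n_wells=n_wells, n_detecting=n_detecting)


def knockout(params: MicrocosmParams, pathways: Iterable[str]) -> MicrocosmParams:
    """Zero the mutation rates of all classes belonging to ``pathways``."""
    pathways = set(pathways)
    known = set(params.pathway_of.values())
    unknown = pathways - known
    if unknown:
        raise ModelError(f"unknown pathway label(s): {sorted(unknown)}")
    new_mu = {
        c: (0.0 if params.pathway_of.get(c) in pathways else m)
        for c, m in params.mu.items()
    }
    return replace(params, mu=new_mu)


def _analytic_detection_probability(
    params: MicrocosmParams, scale: float
) -> float:
    """Poisson approximation of P(any class reaches f_detect at endpoint).

    A lineage founded at generation i reaches endpoint frequency
    (2 e^s)^(G-i) / Nf; it is detectable iff i <= i_max(s).  Detection
    happens unless no detectable lineage ever arises, so P = 1 - exp(-Lambda)
    with Lambda the expected number of detectable arrivals.
    """
    n_gen = math.ceil(generations_elapsed(params.n0, params.nf))
    lam_total = 0.0
    for label in params.classes:
        mu = params.mu[label] * scale
        if mu <= 0:
            continue
        growth = 2.0 * math.exp(params.selection(label))
        if growth <= 1.0:
            continue
        # (growth)^(G-i) >= f_detect * Nf  <=>  i <= G - log(f Nf)/log(growth)
        need = math.log(params.f_detect * params.nf) / math.log(growth)
        i_max = math.floor(n_gen - need)
        if i_max < 0:
            continue
        for i in range(0, min(i_max, n_gen - 1) + 1):
            n_i = min(params.n0 * 2.0**i, params.nf)
            lam_total += mu * n_i
    return 1.0 - math.exp(-lam_total)


def estimate_total_rate(
    observed_detection_fraction: float,
    params: MicrocosmParams,
    precision: float = 1e-3,
) -> tuple[float, tuple[float, float]]:
    """Invert the detection probability for the total mutation rate.

    Bisection on a common scale factor applied to ``params.mu`` against the
    analytic Poisson-approximate detection probability (monotone in the
    rate).  Returns (mu_total estimate, bracketing interval on mu_total).
    """
    if not (0 < observed_detection_fraction < 1):
        raise DataValidationError("detection fraction must be in (0, 1)")
    base_total = sum(params.mu.values())
    if base_total <= 0:
        raise ModelError("params.mu must contain at least one positive rate")

    lo, hi = 0.0, 1.0
    while _analytic_detection_probability(params, hi) < observed_detection_fraction:
        hi *= 2.0
        if hi > 1e12:
            raise ModelError(
                "observed detection fraction unreachable under these parameters"
            )
    while hi - lo > precision * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if _analytic_detection_probability(params, mid) < observed_detection_fraction:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return mid * base_total, (lo * base_total, hi * base_total)
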