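"""c-di-GMP network logic and the rate-weighted null spectrum.

The model operates at the level of mutation-class logic plus mutational
target sizes: a (gene, class) pair contributes to the predicted spectrum
only when perturbing that component switches the pathway output to ``high``
(:func:`ws_output`), and its weight is the class rate times the target size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import DataValidationError, ModelError, UndefinedSpectrumError
from .gene_models import GeneModelSet
from .target_enumeration import TargetSizeTable

__all__ = [
    "PathwayComponent",
    "PathwaySpec",
    "NullModelParams",
    "PredictedSpectrum",
    "COMPONENT_STATES",
    "default_pathway_specs",
    "ws_output",
    "predict_spectrum",
    "rank_genes",
]

#: base states; ``lof_frameshift`` distinguishes frame-breaking loss of
#: function, which is polar onto a downstream operon partner
COMPONENT_STATES = ("wildtype", "lof", "lof_frameshift", "activating", "absent")


@dataclass(frozen=True)
class PathwayComponent:
    gene_name: str
    role: str  # negative_regulator | dgc | interacting
    #: frame-breaking LOF in this component silences the pathway's DGC
    polar_onto_dgc: bool = False


@dataclass
class PathwaySpec:
    """Ordered components of one c-di-GMP pathway."""

    name: str
    components: tuple[PathwayComponent, ...]
    deleted: bool = False

    def __post_init__(self) -> None:
        roles = [c.role for c in self.components]
        if roles.count("dgc") != 1:
            raise ModelError(f"pathway {self.name} must have exactly one DGC")

    @property
    def dgc(self) -> PathwayComponent:
        return next(c for c in self.components if c.role == "dgc")

    @property
    def gene_names(self) -> list[str]:
        return [c.gene_name for c in self.components]


def default_pathway_specs() -> list[PathwaySpec]:
    """The Wsp, Aws and Mws pathway wirings.

    Wsp: WspA receptor feeds the WspE kinase which activates the WspR DGC;
    WspF is the negative regulator.  Aws: AwsO sensor, AwsX inhibitor
    (upstream of AwsR in the operon, hence polar), AwsR DGC.  Mws: MwsR is a
    fused DGC-phosphodiesterase; its regulatory PDE moiety is modelled as a
    negative-regulator pseudo-component of the same protein.
    """
    return [
        PathwaySpec(
            "Wsp",
            (
                PathwayComponent("wspA", "interacting"),
                PathwayComponent("wspB", "interacting"),
                PathwayComponent("wspC", "interacting"),
                PathwayComponent("wspD", "interacting"),
                PathwayComponent("wspE", "interacting"),
                PathwayComponent("wspF", "negative_regulator"),
                PathwayComponent("wspR", "dgc"),
            ),
        ),
        PathwaySpec(
            "Aws",
            (
                PathwayComponent("awsX", "negative_regulator", polar_onto_dgc=True),
                PathwayComponent("awsR", "dgc"),
                PathwayComponent("awsO", "interacting"),
            ),
        ),
        PathwaySpec(
            "Mws",
            (
                PathwayComponent("mwsR_pde", "negative_regulator"),
                PathwayComponent("mwsR", "dgc"),
            ),
        ),
    ]


def ws_output(
    pathway_spec: PathwaySpec, component_states: Mapping[str, str]
) -> str:
    """Pathway output {basal, high, none} for an assignment of states.

    Rules: a dead or absent DGC silences the pathway; an activating DGC
    mutation yields high; loss of function in a negative regulator yields
    high unless the regulator sits upstream of the DGC in the operon and the
    event breaks the reading frame (polar suppression); activating mutations
    in interacting components yield high; all-wildtype is basal.
    """
    unknown = set(component_states.values()) - set(COMPONENT_STATES)
    if unknown:
        raise ModelError(f"unknown component state(s): {sorted(unknown)}")
    if pathway_spec.deleted:
        return "none"
    states = {
        c.gene_name: component_states.get(c.gene_name, "wildtype")
        for c in pathway_spec.components
    }
    dgc = pathway_spec.dgc
    dgc_state = states[dgc.gene_name]
    if dgc_state in {"lof", "lof_frameshift", "absent"}:
        return "none"
    for comp in pathway_spec.components:
        if comp.polar_onto_dgc and states[comp.gene_name] in {"lof_frameshift", "absent"}:
            return "none"
    if dgc_state == "activating":
        return "high"
    for comp in pathway_spec.components:
        state = states[comp.gene_name]
        if comp.role == "negative_regulator" and state in {"lof", "lof_frameshift", "absent"}:
            return "high"
        if comp.role == "interacting" and state == "activating":
            return "high"
    return "basal"


@dataclass
class NullModelParams:
    """Mutation-class rates and normalization options.

    Rates are relative (events per site per generation in arbitrary common
    units); only ratios matter for the predicted spectrum.
    """

    rates: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 1.0,
            "nonsense": 1.0,
            "frameshift_indel": 1.0,
            "inframe_indel": 1.0,
            "promoter_point": 0.0,
        }
    )
    hot_spot_multipliers: dict[str, float] = field(default_factory=dict)
    normalization_scope: str = "three_pathways"
    mu_total: Optional[float] = None
    calibration: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates.values()):
            raise DataValidationError("class rates must be >= 0")
        if not any(r > 0 for r in self.rates.values()):
            raise DataValidationError("at least one class rate must be positive")
        if self.normalization_scope not in {"three_pathways", "all_targets"}:
            raise DataValidationError(
                f"unknown normalization scope {self.normalization_scope!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "NullModelParams":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            rates={k: float(v) for k, v in (raw.get("rates") or {}).items()},
            hot_spot_multipliers=raw.get("hot_spot_multipliers") or {},
            normalization_scope=raw.get("normalization_scope", "three_pathways"),
            mu_total=raw.get("mu_total"),
            calibration=raw.get("calibration") or {},
        )


@dataclass
class PredictedSpectrum:
    """Normalized per-gene probabilities with pathway marginals."""

    gene_probs: dict[str, float]
    pathway_probs: dict[str, float]
    mu_total: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_probs": dict(sorted(self.gene_probs.items())),
                "pathway_probs": dict(sorted(self.pathway_probs.items())),
                "mu_total": self.mu_total,
            },
            indent=2,
        )


_CLASS_TO_STATE = {
    # negative regulators
    ("negative_regulator", "nonsense"): "lof_frameshift",  # truncation: polar
    ("negative_regulator", "frameshift_indel"): "lof_frameshift",
    ("negative_regulator", "inframe_indel"): "lof",
    ("negative_regulator", "missense"): "lof",
    # DGCs and interacting proteins: region-restricted events are activating
    ("dgc", "missense"): "activating",
    ("dgc", "inframe_indel"): "activating",
    ("interacting", "missense"): "activating",
    ("interacting", "inframe_indel"): "activating",
    ("dgc", "nonsense"): "lof",
    ("dgc", "frameshift_indel"): "lof_frameshift",
    ("interacting", "nonsense"): "lof",
    ("interacting", "frameshift_indel"): "lof_frameshift",
}

# Special case: for WspF-like regulators not upstream of the DGC, nonsense
# is not polar.  The distinction only matters for polar components, and the
# polar flag is consulted inside ws_output, so mapping truncations to
# lof_frameshift is conservative and correct for both.


def _component_for_gene(
    specs: Sequence[PathwaySpec], gene_name: str
) -> Optional[tuple[PathwaySpec, PathwayComponent]]:
    for spec in specs:
        for comp in spec.components:
            if comp.gene_name == gene_name:
                return spec, comp
    return None


def ws_enabling(
    specs: Sequence[PathwaySpec], gene_name: str, mclass: str
) -> bool:
    """Whether a mutation of ``mclass`` in ``gene_name`` switches its pathway high."""
    hit = _component_for_gene(specs, gene_name)
    if hit is None:
        return False
    spec, comp = hit
    state = _CLASS_TO_STATE.get((comp.role, mclass))
    if state is None:
        return False
    return ws_output(spec, {comp.gene_name: state}) == "high"


def predict_spectrum(
    target_table: TargetSizeTable,
    params: NullModelParams,
    pathway_specs: Optional[Sequence[PathwaySpec]] = None,
    gene_models: Optional[GeneModelSet] = None,
) -> PredictedSpectrum:
    """Rate-weighted, normalized spectrum over WS-enabling (gene, class) pairs.

    P(g) = sum_c r_c T_c(g) / sum_g' sum_c r_c T_c(g'), restricted to pairs
    for which :func:`ws_output` returns ``high``; deleted pathways are
    excluded before normalization.
    """
    specs = list(pathway_specs) if pathway_specs is not None else default_pathway_specs()
    active = [s for s in specs if not s.deleted]
    pathway_of: dict[str, str] = {}
    for spec in active:
        for comp in spec.components:
            pathway_of.setdefault(comp.gene_name, spec.name)

    weights: dict[str, float] = {}
    for (gene, mclass), target in target_table.entries.items():
        if target <= 0:
            continue
        rate = params.rates.get(mclass, 0.0)
        if rate <= 0:
            continue
        if not ws_enabling(active, gene, mclass):
            continue
        multiplier = params.hot_spot_multipliers.get(f"{gene}:{mclass}", 1.0)
        weights[gene] = weights.get(gene, 0.0) + rate * target * multiplier

    if params.normalization_scope == "three_pathways":
        scope_pathways = {"Wsp", "Aws", "Mws"}
        weights = {
            g: w for g, w in weights.items() if pathway_of.get(g) in scope_pathways
        }

    total = sum(weights.values())
    if total <= 0:
        raise UndefinedSpectrumError(
            "all rate-weighted targets are zero under the chosen scope"
        )
    gene_probs = {g: w / total for g, w in sorted(weights.items())}
    pathway_probs: dict[str, float] = {}
    for gene, p in gene_probs.items():
        pw = pathway_of.get(gene, "other")
        pathway_probs[pw] = pathway_probs.get(pw, 0.0) + p
    return PredictedSpectrum(
        gene_probs=gene_probs,
        pathway_probs=dict(sorted(pathway_probs.items())),
        mu_total=params.mu_total,
    )


def rank_genes(spectrum: PredictedSpectrum) -> list[str]:
    """Genes by decreasing probability; ties break alphabetically (stable)."""
    return [
        g
        for g, _ in sorted(
            spectrum.gene_probs.items(), key=lambda kv: (-kv[1], kv[0])
        )
    ]
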