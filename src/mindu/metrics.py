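"""Candidate macroinvertebrate metrics and their registry.

A metric is a scalar summary of one composite sample (one station on one
sampling date): an absolute group abundance, a percent composition, a
richness or diversity measure, or a fuzzy-coded trait metric.  Every
metric carries a predicted *direction* of response to increasing urban
pollution (tolerant-group metrics increase; sensitive-group, diversity
and large-body-size metrics decrease), which the quartile scorer needs.

The built-in registry ships the fifteen seasonally stable metrics of the
Niger Delta urban index pool plus the four classical diversity measures
and taxa richness; generic builders (``group_abundance_metric`` etc.)
let users extend the candidate pool to their own taxon groups or trait
modalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceTable, TraitAffinityTable, ValidationError

__all__ = [
    "MetricDefinition",
    "DEFAULT_TAXONOMY",
    "MINDU_METRICS",
    "MINDU_DIRECTIONS",
    "group_abundance",
    "percent_composition",
    "richness",
    "diversity_indices",
    "trait_log_relative_abundance",
    "default_registry",
    "compute_metric_matrix",
    "group_abundance_metric",
    "percent_group_metric",
    "trait_metric",
]

#: Family -> higher taxon groups (order/class) for common Afrotropical
#: river macroinvertebrates.  Free-text family names outside this map are
#: still valid taxa; they simply match no group metric.
DEFAULT_TAXONOMY: dict[str, frozenset[str]] = {
    # Diptera
    "Chironomidae": frozenset({"Diptera"}),
    "Culicidae": frozenset({"Diptera"}),
    "Simuliidae": frozenset({"Diptera"}),
    "Syrphidae": frozenset({"Diptera"}),
    "Tipulidae": frozenset({"Diptera"}),
    "Tabanidae": frozenset({"Diptera"}),
    # Oligochaeta (worm families)
    "Tubificidae": frozenset({"Oligochaeta"}),
    "Naididae": frozenset({"Oligochaeta"}),
    "Lumbricidae": frozenset({"Oligochaeta"}),
    # Hemiptera
    "Naucoridae": frozenset({"Hemiptera"}),
    "Notonectidae": frozenset({"Hemiptera"}),
    "Belostomatidae": frozenset({"Hemiptera"}),
    "Nepidae": frozenset({"Hemiptera"}),
    "Gerridae": frozenset({"Hemiptera"}),
    "Corixidae": frozenset({"Hemiptera"}),
    "Veliidae": frozenset({"Hemiptera"}),
    # Coleoptera
    "Dytiscidae": frozenset({"Coleoptera"}),
    "Gyrinidae": frozenset({"Coleoptera"}),
    "Hydrophilidae": frozenset({"Coleoptera"}),
    "Elmidae": frozenset({"Coleoptera"}),
    # Mollusca
    "Thiaridae": frozenset({"Mollusca"}),
    "Physidae": frozenset({"Mollusca"}),
    "Planorbidae": frozenset({"Mollusca"}),
    "Lymnaeidae": frozenset({"Mollusca"}),
    "Bulinidae": frozenset({"Mollusca"}),
    "Unionidae": frozenset({"Mollusca"}),
    # EPT orders
    "Baetidae": frozenset({"Ephemeroptera", "EPT"}),
    "Caenidae": frozenset({"Ephemeroptera", "EPT"}),
    "Heptageniidae": frozenset({"Ephemeroptera", "EPT"}),
    "Perlidae": frozenset({"Plecoptera", "EPT"}),
    "Hydropsychidae": frozenset({"Trichoptera", "EPT"}),
    "Leptoceridae": frozenset({"Trichoptera", "EPT"}),
    # Odonata
    "Libellulidae": frozenset({"Odonata"}),
    "Coenagrionidae": frozenset({"Odonata"}),
    "Gomphidae": frozenset({"Odonata"}),
    # Crustacea
    "Atyidae": frozenset({"Decapoda"}),
    "Palaemonidae": frozenset({"Decapoda"}),
    # Hirudinea
    "Hirudinidae": frozenset({"Hirudinea"}),
    "Glossiphoniidae": frozenset({"Hirudinea"}),
}


@dataclass(frozen=True)
class MetricDefinition:
    """A registered candidate metric.

    ``direction`` is the predicted response to increasing urban
    pollution and decides which arm of the 5/3/1 scorer applies.
    """

    name: str
    family: str  # abundance | composition | richness | diversity | trait
    direction: str  # increase | decrease
    formula_id: str
    taxon_groups: tuple[str, ...] = ()
    trait_modality: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ValidationError(
                f"metric {self.name!r}: direction must be increase/decrease"
            )


def _in_group(taxon: str, groups, taxonomy) -> bool:
    if taxon in groups:
        return True
    return bool(taxonomy.get(taxon, frozenset()) & set(groups))


def group_abundance(sample: dict, groups, taxonomy=DEFAULT_TAXONOMY) -> float:
    """Total count over taxa that are, or belong to, any of ``groups``."""
    return float(
        sum(c for t, c in sample.items() if _in_group(t, groups, taxonomy))
    )


def percent_composition(sample: dict, groups, taxonomy=DEFAULT_TAXONOMY) -> float:
    """Percent of individuals in ``groups``; NaN for an empty sample."""
    total = sum(sample.values())
    if total <= 0:
        return math.nan
    return 100.0 * group_abundance(sample, groups, taxonomy) / total


def richness(sample: dict) -> float:
    """Number of taxa with at least one individual."""
    return float(sum(1 for c in sample.values() if c > 0))


def diversity_indices(sample: dict) -> dict[str, float]:
    """Shannon H' (natural log), Simpson 1-D, Margalef and Pielou J'.

    Margalef is undefined (NaN) at N = 1 and evenness at S = 1; an empty
    sample yields all-NaN.
    """
    counts = np.array([c for c in sample.values() if c > 0], dtype=float)
    n = counts.sum()
    s = len(counts)
    if s == 0 or n <= 0:
        return {k: math.nan for k in ("shannon", "simpson", "margalef", "evenness")}
    p = counts / n
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    margalef = math.nan if n == 1 else float((s - 1) / math.log(n))
    evenness = math.nan if s == 1 else shannon / math.log(s)
    return {
        "shannon": shannon,
        "simpson": simpson,
        "margalef": margalef,
        "evenness": evenness,
    }


def trait_log_relative_abundance(
    sample: dict, traits: TraitAffinityTable, modality: str
) -> float:
    """log10(1 + relative abundance weighted by fuzzy affinity to a modality).

    Each taxon's 0-3 affinities are normalized across the modalities of
    the owning trait to weights summing to one (all-zero profiles weigh
    nothing); the weighted abundance A of the modality is summed over
    taxa and the metric is log10(1 + A/N), bounded in [0, log10 2].
    """
    weights = traits.modality_weights(modality)
    total = sum(sample.values())
    if total <= 0:
        return math.nan
    weighted = sum(c * weights.get(t, 0.0) for t, c in sample.items())
    return math.log10(1.0 + weighted / total)


# ---------------------------------------------------------------------------
# Registry

#: The five metrics of the packaged Niger Delta urban index (MINDU).
MINDU_METRICS = (
    "Hemiptera abundance",
    "%Coleoptera + Hemiptera",
    "%Chironomidae + Oligochaeta",
    "Evenness index",
    "Log very large body size",
)

MINDU_DIRECTIONS = {
    "Hemiptera abundance": "decrease",
    "%Coleoptera + Hemiptera": "decrease",
    "%Chironomidae + Oligochaeta": "increase",
    "Evenness index": "decrease",
    "Log very large body size": "decrease",
}

#: Modality name the packaged trait metric expects in trait tables:
#: very large body size (>40-80 mm).
VERY_LARGE_BODY = "very_large"


def group_abundance_metric(name, groups, direction) -> MetricDefinition:
    return MetricDefinition(name, "abundance", direction, "group_abundance",
                            tuple(groups))


def percent_group_metric(name, groups, direction) -> MetricDefinition:
    return MetricDefinition(name, "composition", direction, "percent_group",
                            tuple(groups))


def trait_metric(name, modality, direction) -> MetricDefinition:
    return MetricDefinition(name, "trait", direction, "trait_log_rel_abundance",
                            trait_modality=modality)


def default_registry(include_extras: bool = True) -> list[MetricDefinition]:
    """The shipped candidate-metric pool.

    The fifteen seasonally stable metrics (abundance, composition,
    evenness and the very-large-body trait metric), plus — when
    ``include_extras`` — Shannon, Simpson, Margalef and taxa richness.
    """
    ga, pg = group_abundance_metric, percent_group_metric
    reg = [
        ga("Chironomidae abundance", ["Chironomidae"], "increase"),
        ga("Chironomidae + Oligochaeta abundance",
           ["Chironomidae", "Oligochaeta"], "increase"),
        ga("Oligochaeta abundance", ["Oligochaeta"], "increase"),
        ga("Hemiptera abundance", ["Hemiptera"], "decrease"),
        ga("Diptera abundance", ["Diptera"], "increase"),
        ga("Mollusca + Diptera abundance", ["Mollusca", "Diptera"], "increase"),
        pg("%Chironomidae + Oligochaeta",
           ["Chironomidae", "Oligochaeta"], "increase"),
        pg("%Oligochaeta", ["Oligochaeta"], "increase"),
        pg("%Diptera", ["Diptera"], "increase"),
        pg("%Hemiptera", ["Hemiptera"], "decrease"),
        pg("%Coleoptera", ["Coleoptera"], "decrease"),
        pg("%Coleoptera + Hemiptera", ["Coleoptera", "Hemiptera"], "decrease"),
        pg("%Mollusca + Diptera", ["Mollusca", "Diptera"], "increase"),
        MetricDefinition("Evenness index", "diversity", "decrease", "evenness"),
        trait_metric("Log very large body size", VERY_LARGE_BODY, "decrease"),
    ]
    if include_extras:
        reg += [
            MetricDefinition("Shannon diversity", "diversity", "decrease",
                             "shannon"),
            MetricDefinition("Simpson diversity", "diversity", "decrease",
                             "simpson"),
            MetricDefinition("Margalef index", "diversity", "decrease",
                             "margalef"),
            MetricDefinition("Taxa richness", "richness", "decrease",
                             "richness"),
        ]
    return reg


_DIVERSITY_KEYS = {"shannon", "simpson", "margalef", "evenness"}
_FORMULAE = (
    {"group_abundance", "percent_group", "richness", "total_abundance",
     "trait_log_rel_abundance"} | _DIVERSITY_KEYS
)


def evaluate_metric(
    defn: MetricDefinition,
    sample: dict,
    traits: TraitAffinityTable | None,
    taxonomy=DEFAULT_TAXONOMY,
) -> float:
    if defn.formula_id == "group_abundance":
        return group_abundance(sample, defn.taxon_groups, taxonomy)
    if defn.formula_id == "percent_group":
        return percent_composition(sample, defn.taxon_groups, taxonomy)
    if defn.formula_id == "richness":
        return richness(sample)
    if defn.formula_id == "total_abundance":
        return float(sum(sample.values()))
    if defn.formula_id in _DIVERSITY_KEYS:
        return diversity_indices(sample)[defn.formula_id]
    if defn.formula_id == "trait_log_rel_abundance":
        if traits is None:
            raise ValidationError(
                f"metric {defn.name!r} needs a trait affinity table"
            )
        return trait_log_relative_abundance(sample, traits, defn.trait_modality)
    raise ValidationError(f"unknown formula_id {defn.formula_id!r}")


def compute_metric_matrix(
    table: AbundanceTable,
    registry: list[MetricDefinition],
    traits: TraitAffinityTable | None = None,
    taxonomy=DEFAULT_TAXONOMY,
) -> pd.DataFrame:
    """Evaluate every registered metric on every sampling occasion.

    Returns a frame indexed by (station, date, season) with one column
    per metric; undefined values propagate as NaN, never as zero.
    """
    if not registry:
        raise ValidationError("empty metric registry")
    names = [d.name for d in registry]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate metric names in registry")
    for d in registry:  # fail before any computation
        if d.formula_id not in _FORMULAE:
            raise ValidationError(f"unknown formula_id {d.formula_id!r}")
        if d.formula_id == "trait_log_rel_abundance" and traits is None:
            raise ValidationError(
                f"metric {d.name!r} needs a trait affinity table"
            )
    rows, keys = [], []
    for key, sample in table.samples():
        keys.append(key)
        rows.append(
            [evaluate_metric(d, sample, traits, taxonomy) for d in registry]
        )
    idx = pd.MultiIndex.from_tuples(keys, names=["station", "date", "season"])
    return pd.DataFrame(rows, index=idx, columns=names)
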