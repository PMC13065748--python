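"""Seeded fixture generators: mock registries and multi-facility catalogs.

Real international terminologies are licensed and real hospital rate lists
are not redistributable, so every other module is exercised against
synthetic stand-ins built here:

* :func:`generate_mock_registry` — a registry whose source codes imitate
  each classification's surface shape (7-character alphanumerics for the
  ICD-10-PCS mock, ``NNNNN-N`` for the LOINC mock, ...) without using any
  real code, plus dot-suffixed extension families and operational codes.
* :func:`generate_catalogs` — multi-facility billing catalogs that realize
  requested disharmony rates (label divergence, duplicate entries, code
  reuse across services) and a requested coverage split by EXACT planted
  counts, together with the ground-truth key that lets the assessment
  module recover those rates (the closed-loop property).

All randomness flows from ``FixtureConfig.seed``; the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .assessment import (
    CatalogItem,
    FacilityCatalog,
    MappingHint,
    MatchStatus,
    normalize_label,
    round_pct,
)
from .registry import DEFAULT_CLASSIFICATIONS, DOMAINS, Concept, Registry

__all__ = [
    "FixtureConfig",
    "GroundTruth",
    "FixtureError",
    "generate_mock_registry",
    "generate_catalogs",
    "write_ground_truth",
    "read_ground_truth",
]


class FixtureError(ValueError):
    """Invalid or infeasible fixture configuration."""


@dataclass
class FixtureConfig:
    """Generator settings.

    The defaults emulate the study conditions: five facilities; one third
    of services consistently labelled across all of them while every
    cross-facility service is coded or labelled at least two different
    ways; 11% duplicate entries and 9% code reuse; and a coverage split of
    91% direct, 6.7% national extensions, 2.3% operational-only.
    """

    seed: int = 0
    n_concepts_per_domain: Dict[str, int] = field(
        default_factory=lambda: {d: 10 for d in DOMAINS}
    )
    n_extension_families: int = 3
    n_extensions_per_family: int = 4
    n_operational: int = 5
    n_facilities: int = 5
    n_clusters: int = 100
    rate_consistent: float = 0.33
    rate_duplicate_within: float = 0.11
    rate_multi_coded: float = 1.0
    rate_code_reuse: float = 0.09
    coverage_split: Dict[str, float] = field(
        default_factory=lambda: {
            MatchStatus.DIRECT: 0.91,
            MatchStatus.EXTENSION_REQUIRED: 0.067,
            MatchStatus.OPERATIONAL_ONLY: 0.023,
            MatchStatus.HEADER_MAPPED: 0.0,
            MatchStatus.UNMATCHED: 0.0,
        }
    )

    def validate(self) -> None:
        rates = {
            "rate_consistent": self.rate_consistent,
            "rate_duplicate_within": self.rate_duplicate_within,
            "rate_multi_coded": self.rate_multi_coded,
            "rate_code_reuse": self.rate_code_reuse,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise FixtureError(f"{name} must be in [0, 1], got {value}")
        unknown = set(self.coverage_split) - set(MatchStatus.ALL)
        if unknown:
            raise FixtureError(f"unknown coverage classes {sorted(unknown)}")
        total = sum(self.coverage_split.values())
        if abs(total - 1.0) > 1e-9:
            raise FixtureError(f"coverage_split must sum to 1, got {total}")
        if any(v < 0 for v in self.coverage_split.values()):
            raise FixtureError("coverage_split fractions must be non-negative")
        if self.n_facilities < 1:
            raise FixtureError("n_facilities must be >= 1")
        if self.n_clusters < 1:
            raise FixtureError("n_clusters must be >= 1")
        for d in self.n_concepts_per_domain:
            if d not in DOMAINS:
                raise FixtureError(f"unknown domain {d!r}")


# ---------------------------------------------------------------------------
# Mock registry
# ---------------------------------------------------------------------------

# surface shapes of mock source codes, one per classification prefix
_ICD_CHARS = "0123456789BCDFGHJKLMNPQRSTVWXYZ"

_ORGANS = [
    "mastoid sinus", "peritoneal cavity", "knee joint", "shoulder", "liver",
    "lower extremity", "cervical spine", "thorax", "abdomen", "skull",
    "pelvis", "femur", "wrist", "ankle", "elbow",
]
_ORGANS_FR = [
    "sinus mastoidien", "cavite peritoneale", "articulation du genou",
    "epaule", "foie", "membre inferieur", "rachis cervical", "thorax",
    "abdomen", "crane", "bassin", "femur", "poignet", "cheville", "coude",
]
_ACTIONS = {
    "PROC": ("Drainage of", "Drainage du"),
    "IMG": ("Plain radiography of", "Radiographie simple du"),
    "RXT": ("Radiation therapy of", "Radiotherapie du"),
    "PHY": ("Physical rehabilitation of", "Reeducation physique du"),
    "MENT": ("Psychotherapy session for", "Seance de psychotherapie pour"),
    "EVAL": ("Evaluation and management visit for", "Visite d'evaluation pour"),
    "LAB": ("Blood assay of", "Dosage sanguin de"),
    "MED": ("Tablet of", "Comprime de"),
    "CONS": ("Sterile supply for", "Fourniture sterile pour"),
    "PROT": ("Prosthetic device for", "Prothese pour"),
    "TRANS": ("Ambulance transport for", "Transport en ambulance pour"),
    "LOG": ("Hospital accommodation for", "Hebergement hospitalier pour"),
}


def _mock_source_code(prefix: str, rng: random.Random, used: set) -> str:
    """A plausible-looking but fictitious source code for one classification."""
    makers = {
        "I": lambda: "".join(rng.choice(_ICD_CHARS) for _ in range(7)),
        "C": lambda: f"{rng.randrange(10000, 100000)}",
        "H": lambda: rng.choice("ABCDEGJKLPQSTV") + f"{rng.randrange(1000, 10000)}",
        "L": lambda: f"{rng.randrange(1000, 100000)}-{rng.randrange(10)}",
        "R": lambda: f"{rng.randrange(100000, 1000000)}",
        "U": lambda: f"{rng.randrange(100, 1000):04d}",
    }
    maker = makers[prefix]
    while True:
        code = maker()
        if (prefix, code) not in used:
            used.add((prefix, code))
            return code


def generate_mock_registry(config: FixtureConfig) -> Registry:
    """Build a registry of mock concepts per domain, with extension
    families and operational codes, that passes the full audit."""
    config.validate()
    rng = random.Random(config.seed)
    registry = Registry(DEFAULT_CLASSIFICATIONS)
    by_domain = {
        d: cls for cls in DEFAULT_CLASSIFICATIONS for d in cls.domains
    }
    used_sources: set = set()
    used_labels: set = set()
    img_parents: List[Concept] = []

    for domain in DOMAINS:
        count = config.n_concepts_per_domain.get(domain, 0)
        cls = by_domain[domain]
        verb_en, verb_fr = _ACTIONS[domain]
        for k in range(count):
            organ = _ORGANS[(k + rng.randrange(len(_ORGANS))) % len(_ORGANS)]
            organ_fr = _ORGANS_FR[_ORGANS.index(organ)]
            label_en = f"{verb_en} {organ}"
            if normalize_label(label_en) in used_labels:
                label_en = f"{label_en}, level {k + 1}"
                organ_fr = f"{organ_fr}, niveau {k + 1}"
            used_labels.add(normalize_label(label_en))
            concept = registry.register_concept(
                source_code=_mock_source_code(cls.prefix, rng, used_sources),
                classification=cls,
                domain=domain,
                labels={"en": label_en, "fr": f"{verb_fr} {organ_fr}"},
            )
            if domain == "IMG":
                img_parents.append(concept)

    views = ["front view", "front and profile views", "profile view", "other view"]
    parents = img_parents or registry.concepts
    for f in range(min(config.n_extension_families, len(parents))):
        parent = parents[f]
        for j in range(config.n_extensions_per_family):
            view = views[j % len(views)]
            label = f"{parent.labels['en']} - {view}"
            if j >= len(views):
                label += f" (variant {j + 1})"
            registry.add_extension(parent.code, {"en": label})

    areas = ["larynx and trachea", "neck", "nose and sinuses", "pharynx",
             "oral cavity", "scalp", "outer ear"]
    for k in range(config.n_operational):
        area = areas[k % len(areas)]
        suffix = "" if k < len(areas) else f" ({k // len(areas) + 1})"
        registry.add_operational(
            "PROC", {"en": f"Services related to the {area}{suffix}"}
        )
    return registry


# ---------------------------------------------------------------------------
# Catalog generation with planted rates
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything needed to recover the planted rates through the
    assessment module, plus the rates actually achieved by the integer
    planting (identical to the requested rates whenever the counts divide
    evenly)."""

    concept_key: Dict[Tuple[str, int], str]
    hints: Dict[str, Dict[int, MappingHint]]
    domains: Dict[Tuple[str, int], str]
    intended_status: Dict[Tuple[str, int], str]
    achieved_consistency: Dict[str, float]
    achieved_coverage_counts: Dict[str, int]

    @property
    def n_items(self) -> int:
        return len(self.intended_status)


def _largest_remainder_counts(split: Mapping[str, float], total: int) -> Dict[str, int]:
    """Integer counts per class summing exactly to ``total``, apportioned by
    the largest-remainder method (deterministic tie-break on class name)."""
    exact = {s: split.get(s, 0.0) * total for s in MatchStatus.ALL}
    counts = {s: int(exact[s]) for s in exact}
    short = total - sum(counts.values())
    order = sorted(exact, key=lambda s: (counts[s] - exact[s], s))
    for s in order[:short]:
        counts[s] += 1
    return counts


def _best_merge_count(d0: int, rate: float) -> int:
    """Number of code merges m so that m / (d0 - m) best approximates rate."""
    target = rate * d0 / (1.0 + rate)
    candidates = {max(0, int(target)), min(d0 - 1, int(target) + 1)}
    return min(candidates, key=lambda m: (abs(m / (d0 - m) - rate), m))


def _best_copy_count(n0: int, rate: float) -> int:
    """Number of duplicate copies a so that 2a / (n0 + a) best approximates rate."""
    target = rate * n0 / (2.0 - rate) if rate < 2.0 else n0
    candidates = {max(0, int(target)), int(target) + 1}
    return min(candidates, key=lambda a: (abs(2 * a / (n0 + a) - rate), a))


def _corrupt_label(label: str, rng: random.Random) -> str:
    """A deterministic 'locally divergent' version of a label: synonym swap,
    word shuffle, or abbreviation; always differs from the input."""
    synonyms = {
        "consultation": "visit", "service": "act", "tariff": "fee",
        "standard": "ordinary", "package": "bundle", "care": "treatment",
    }
    words = label.split()
    choice = rng.randrange(3)
    if choice == 0:
        swapped = [synonyms.get(w.lower(), w) for w in words]
        if swapped != words:
            return " ".join(swapped)
    if choice == 1 and len(words) >= 2:
        shuffled = words[:]
        rng.shuffle(shuffled)
        if shuffled != words:
            return " ".join(shuffled)
    abbreviated = " ".join(w[:4] + "." if len(w) > 5 else w for w in words)
    if abbreviated != label:
        return abbreviated
    return label + " (local)"


_LOCAL_SERVICES = [
    "consultation", "dressing change", "injection", "day observation",
    "minor suture", "plaster cast", "oxygen therapy", "screening test",
    "delivery package", "emergency admission", "follow-up visit",
    "health certificate", "vaccination session", "nutrition advice",
]
_LOCAL_QUALIFIERS = [
    "standard", "pediatric", "adult", "night tariff", "weekend tariff",
    "insured patient", "private ward", "general ward", "referred case",
    "chronic care",
]


def generate_catalogs(
    config: FixtureConfig,
    registry: Registry,
) -> Tuple[List[FacilityCatalog], GroundTruth]:
    """Generate ``n_facilities`` catalogs over ``n_clusters`` local services
    realizing the configured disharmony rates and coverage split by exact
    integer counts; returns the catalogs and the ground-truth key.

    Raises :class:`FixtureError` for infeasible rate combinations, e.g. a
    consistency rate below ``1 - rate_multi_coded`` (a service realized a
    single way everywhere is necessarily consistently labelled).
    """
    config.validate()
    rng = random.Random(config.seed + 1)
    K, F = config.n_clusters, config.n_facilities
    facilities = [f"HOSP{f + 1:02d}" for f in range(F)]

    n_single = round((1.0 - config.rate_multi_coded) * K)
    n_consistent = round(config.rate_consistent * K)
    if n_consistent < n_single:
        raise FixtureError(
            f"infeasible rates: rate_consistent={config.rate_consistent} implies "
            f"{n_consistent} label-consistent services, but rate_multi_coded="
            f"{config.rate_multi_coded} forces at least {n_single} services with a "
            "single realization, which are label-consistent by construction"
        )

    # cluster labels: synthetic local-billing vocabulary, never colliding
    # with registry labels (coverage must stay hint-controlled)
    registry_labels = set(registry.labels_index(normalizer=normalize_label))
    cluster_labels: List[str] = []
    seen = set(registry_labels)
    i = 0
    while len(cluster_labels) < K:
        base = _LOCAL_SERVICES[i % len(_LOCAL_SERVICES)]
        qual = _LOCAL_QUALIFIERS[(i // len(_LOCAL_SERVICES)) % len(_LOCAL_QUALIFIERS)]
        serial = i // (len(_LOCAL_SERVICES) * len(_LOCAL_QUALIFIERS))
        label = f"{base.capitalize()}, {qual}" + (f", series {serial + 1}" if serial else "")
        key = normalize_label(label)
        if key not in seen:
            seen.add(key)
            cluster_labels.append(label)
        i += 1

    order = list(range(K))
    rng.shuffle(order)
    single_set = set(order[:n_single])
    consistent_set = set(order[:n_consistent])  # includes the single clusters

    # per-(cluster, facility) codes and labels
    codes: Dict[Tuple[int, str], str] = {}
    labels: Dict[Tuple[int, str], str] = {}
    for cid in range(K):
        base_label = cluster_labels[cid]
        divergent_at = (
            rng.randrange(F) if (cid not in consistent_set and F > 1) else None
        )
        for f, facility in enumerate(facilities):
            if cid in single_set:
                codes[(cid, facility)] = f"S{cid:04d}"
            else:
                codes[(cid, facility)] = f"{facility}-{cid:04d}"
            if cid in consistent_set or F == 1:
                labels[(cid, facility)] = base_label
            elif divergent_at is not None and f == divergent_at:
                labels[(cid, facility)] = _corrupt_label(base_label, rng)
            else:
                labels[(cid, facility)] = base_label
    # F == 1 makes every cluster trivially consistent; reject incompatible asks
    if F == 1 and n_consistent < K:
        raise FixtureError(
            "infeasible rates: with a single facility every service is "
            "label-consistent; rate_consistent must be 1.0"
        )

    # code reuse: merge codes of disjoint pairs of multi clusters
    multi_clusters = [cid for cid in range(K) if cid not in single_set]
    d0 = K * F
    m = _best_merge_count(d0, config.rate_code_reuse) if config.rate_code_reuse else 0
    if 2 * m > len(multi_clusters):
        raise FixtureError(
            f"infeasible rates: code reuse needs {2 * m} multi-coded services "
            f"but only {len(multi_clusters)} exist"
        )
    merge_pool = multi_clusters[:]
    rng.shuffle(merge_pool)
    merged: set = set()
    for j in range(m):
        a, b = merge_pool[2 * j], merge_pool[2 * j + 1]
        facility = facilities[j % F]
        codes[(b, facility)] = codes[(a, facility)]
        merged.update((a, b))

    # duplicate entries: extra copies of items in unmerged clusters
    n0 = K * F
    a_copies = (
        _best_copy_count(n0, config.rate_duplicate_within)
        if config.rate_duplicate_within
        else 0
    )
    copy_pool = [
        (cid, facility)
        for cid in range(K) if cid not in merged
        for facility in facilities
    ]
    if a_copies > len(copy_pool):
        raise FixtureError(
            f"infeasible rates: {a_copies} duplicate entries requested but only "
            f"{len(copy_pool)} items are available to duplicate"
        )
    rng.shuffle(copy_pool)
    copies = copy_pool[:a_copies]

    # materialize the catalogs, cluster-major so coverage statuses sliced
    # over this order stay nearly cluster-homogeneous
    item_refs: List[Tuple[str, int, int]] = []  # (facility, index, cluster)
    catalogs = {facility: FacilityCatalog(facility) for facility in facilities}

    def _emit(cid: int, facility: str) -> None:
        catalog = catalogs[facility]
        index = len(catalog.items)
        catalog.items.append(
            CatalogItem(
                local_code=codes[(cid, facility)],
                label=labels[(cid, facility)],
                price=float(500 * (1 + cid % 40)),
            )
        )
        item_refs.append((facility, index, cid))

    copy_counts = {ref: 0 for ref in copies}
    for cid in range(K):
        for facility in facilities:
            _emit(cid, facility)
            if copy_counts.get((cid, facility), None) == 0:
                copy_counts[(cid, facility)] += 1
                _emit(cid, facility)

    n_items = len(item_refs)

    # coverage planting: exact counts over the cluster-major item order
    counts = _largest_remainder_counts(config.coverage_split, n_items)
    status_sequence: List[str] = []
    for status in MatchStatus.ALL:
        status_sequence.extend([status] * counts[status])

    # one target registry concept per cluster supplies codes and domains
    plain = [c for c in registry.concepts if c.parent is None and not c.operational]
    if not plain:
        raise FixtureError("registry holds no plain concepts to map against")
    target_concept = {cid: plain[cid % len(plain)] for cid in range(K)}

    concept_key: Dict[Tuple[str, int], str] = {}
    hints: Dict[str, Dict[int, MappingHint]] = {facility: {} for facility in facilities}
    domains: Dict[Tuple[str, int], str] = {}
    intended: Dict[Tuple[str, int], str] = {}
    for (facility, index, cid), status in zip(item_refs, status_sequence):
        ref = (facility, index)
        concept_key[ref] = f"SVC{cid:05d}"
        concept = target_concept[cid]
        domains[ref] = concept.domain
        intended[ref] = status
        relation = _STATUS_TO_RELATION.get(status)
        if relation == "operational":
            hints[facility][index] = MappingHint(relation, domain=concept.domain)
        elif relation is not None:
            hints[facility][index] = MappingHint(
                relation, code=concept.code, domain=concept.domain
            )
        # unmatched: no hint; the synthetic labels cannot match the registry

    achieved = {
        "pct_consistent_across_facilities": round_pct(n_consistent, K),
        "pct_duplicate_within_facility": round_pct(2 * a_copies, n_items),
        "pct_multiple_codes_across_facilities": round_pct(K - n_single, K) if F > 1
        else 0.0,
        "pct_code_reuse_for_different_services": round_pct(m, d0 - m),
    }
    truth = GroundTruth(
        concept_key=concept_key,
        hints=hints,
        domains=domains,
        intended_status=intended,
        achieved_consistency=achieved,
        achieved_coverage_counts=counts,
    )
    return [catalogs[facility] for facility in facilities], truth


# ---------------------------------------------------------------------------
# Ground-truth persistence (CSV, mirrors the in-memory structure)
# ---------------------------------------------------------------------------

_GT_HEADER = [
    "facility_id", "item_index", "cluster_key", "domain",
    "intended_status", "relation", "hint_code",
]

_STATUS_TO_RELATION = {
    MatchStatus.DIRECT: "direct",
    MatchStatus.EXTENSION_REQUIRED: "extension",
    MatchStatus.HEADER_MAPPED: "header",
    MatchStatus.OPERATIONAL_ONLY: "operational",
}


def write_ground_truth(truth: GroundTruth, path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_GT_HEADER)
        for (facility, index) in sorted(truth.intended_status):
            status = truth.intended_status[(facility, index)]
            hint = truth.hints.get(facility, {}).get(index)
            writer.writerow([
                facility, index, truth.concept_key[(facility, index)],
                truth.domains[(facility, index)], status,
                hint.relation if hint else "",
                (hint.code or "") if hint else "",
            ])


def read_ground_truth(path) -> GroundTruth:
    concept_key: Dict[Tuple[str, int], str] = {}
    hints: Dict[str, Dict[int, MappingHint]] = {}
    domains: Dict[Tuple[str, int], str] = {}
    intended: Dict[Tuple[str, int], str] = {}
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _GT_HEADER:
            raise FixtureError(f"{path}:1: bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_GT_HEADER):
                raise FixtureError(f"{path}:{lineno}: expected {len(_GT_HEADER)} fields")
            facility, index_text, key, domain, status, relation, code = row
            index = int(index_text)
            ref = (facility, index)
            concept_key[ref] = key
            domains[ref] = domain
            intended[ref] = status
            if relation:
                hints.setdefault(facility, {})[index] = MappingHint(
                    relation, code=code or None, domain=domain or None
                )
    return GroundTruth(
        concept_key=concept_key,
        hints=hints,
        domains=domains,
        intended_status=intended,
        achieved_consistency={},
        achieved_coverage_counts={},
    )
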