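"""Doddington Zoo labeling of individuals within one modality.

Each valid individual is assigned exactly one menagerie label:

* **goats** — large intra-class dispersion (hard to match against
  themselves): individuals whose mean pairwise distance between their own
  training samples ranks above the goat percentile (default 70th);
* **lambs** — small inter-class separation (easy to imitate): individuals
  whose one-against-all mean distance to everyone else's training samples
  ranks in the lower lamb percentile (default 30th);
* **sheep** — everyone else; by construction the majority.

Percentile ranks use the fractional 1-based index ``p/100 * N + 1/2``.
Goat candidates are the individuals whose ascending-dispersion rank lies
strictly above that index; lamb candidates are those whose ascending
separation rank is at or below the round-half-up of the index. From each
candidate list a seeded random permutation selects a fixed fraction
(default 10%) of the valid population, so every build of a chimeric dataset
draws a fresh—but reproducible—menagerie. Individuals missing a session are
discarded before labeling; all statistics use training-session data only
(first session in the declared order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ConstraintViolationError,
    EmptyInputError,
    InsufficientPopulationError,
    InsufficientSamplesError,
    IntegrityError,
    ValidationError,
)
from .matching_fusion import METRICS, cross_distances, pairwise_distances
from .modality_store import ModalityDataset

LABELS = ("sheep", "goat", "lamb")


@dataclass(frozen=True)
class ZooConfig:
    """Selection percentiles and final menagerie fraction."""

    goat_percentile: float = 70.0
    lamb_percentile: float = 30.0
    final_fraction: float = 0.10
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if not (0 < self.lamb_percentile < self.goat_percentile < 100):
            raise ValidationError(
                "percentiles must satisfy 0 < lamb < goat < 100, got "
                f"lamb={self.lamb_percentile}, goat={self.goat_percentile}"
            )
        if not (0 < self.final_fraction < 0.5):
            raise ValidationError("final_fraction must lie in (0, 0.5)")
        if self.metric not in METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}")


@dataclass
class ZooLabelMap:
    """Final label per individual plus the candidate provenance."""

    labels: dict[str, str]
    goat_candidates: list[tuple[str, float]]
    lamb_candidates: list[tuple[str, float]]
    discarded: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        bad = set(self.labels.values()) - set(LABELS)
        if bad:
            raise IntegrityError(f"unknown labels {bad}")

    def ids_with(self, label: str) -> list[str]:
        return sorted(i for i, l in self.labels.items() if l == label)

    def counts(self) -> dict[str, int]:
        return {label: len(self.ids_with(label)) for label in LABELS}


def percentile_index(p: float, n: int) -> float:
    """Fractional 1-based rank of the p-th percentile in a population of n.

    index = p/100 * n + 1/2, returned exactly (no rounding).
    """
    if n < 1:
        raise EmptyInputError("percentile of an empty population")
    if not (0 <= p <= 100):
        raise ValidationError(f"percentile must be in [0, 100], got {p}")
    return p / 100.0 * n + 0.5


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (for x >= 0)."""
    return int(math.floor(x + 0.5))


def filter_valid_individuals(dataset: ModalityDataset) -> list[str]:
    """Individuals having at least one sample in *every* declared session."""
    if not dataset.session_order:
        raise IntegrityError("dataset declares no sessions")
    valid = [
        ind
        for ind in dataset.individual_ids
        if all(dataset.sample_count(ind, sess) >= 1 for sess in dataset.session_order)
    ]
    if not valid:
        raise EmptyInputError("no individual has samples in every session")
    return valid


def _training_session(dataset: ModalityDataset) -> str:
    return dataset.session_order[0]


def intra_class_dispersion(
    dataset: ModalityDataset, individual_id: str, metric: str = "euclidean"
) -> float:
    """Mean pairwise distance among one individual's training samples."""
    X = dataset.features_of(individual_id, _training_session(dataset))
    if X.shape[0] < 2:
        raise InsufficientSamplesError(
            f"{individual_id!r}: needs >= 2 training samples, has {X.shape[0]}"
        )
    return float(pairwise_distances(X, metric).mean())


def mean_inter_class_distance(
    dataset: ModalityDataset, individual_id: str, metric: str = "euclidean"
) -> float:
    """Mean one-against-all distance from an individual's training samples
    to every other individual's training samples."""
    if dataset.n_individuals < 2:
        raise InsufficientPopulationError("need >= 2 individuals")
    sess = _training_session(dataset)
    X = dataset.features_of(individual_id, sess)
    others = [i for i in dataset.individual_ids if i != individual_id]
    Y = np.vstack([dataset.features_of(i, sess) for i in others])
    return float(cross_distances(X, Y, metric).mean())


def _ranked(stats: Mapping[str, float]) -> list[tuple[str, float]]:
    # ascending by statistic, ties broken by id for determinism
    return sorted(stats.items(), key=lambda kv: (kv[1], kv[0]))


def identify_goats(
    dispersions: Mapping[str, float], cfg: ZooConfig = ZooConfig()
) -> list[tuple[str, float]]:
    """Goat candidates: ascending-dispersion ranks strictly above the
    goat-percentile index."""
    if not dispersions:
        raise EmptyInputError("no dispersion statistics")
    ranked = _ranked(dispersions)
    idx = percentile_index(cfg.goat_percentile, len(ranked))
    return [(i, v) for rank, (i, v) in enumerate(ranked, start=1) if rank > idx]


def identify_lambs(
    separations: Mapping[str, float], cfg: ZooConfig = ZooConfig()
) -> list[tuple[str, float]]:
    """Lamb candidates: ascending-separation ranks at or below the
    round-half-up of the lamb-percentile index."""
    if not separations:
        raise EmptyInputError("no separation statistics")
    ranked = _ranked(separations)
    k = round_half_up(percentile_index(cfg.lamb_percentile, len(ranked)))
    return ranked[:k]


def _permuted(ids: Sequence[str], rng: np.random.Generator) -> list[str]:
    ids = list(ids)
    return [ids[i] for i in rng.permutation(len(ids))]


def finalize_labels(
    goat_candidates: Sequence[tuple[str, float]] | Sequence[str],
    lamb_candidates: Sequence[tuple[str, float]] | Sequence[str],
    valid_ids: Iterable[str],
    cfg: ZooConfig = ZooConfig(),
    seed: int | None = None,
) -> ZooLabelMap:
    """Draw the final menagerie from the candidate lists.

    Individuals qualifying as both goat and lamb become goats. Per animal a
    seeded permutation of its candidates is drawn and the first
    round-half-up(final_fraction * N) kept (capped at the candidate count);
    everyone else is a sheep. Raises if sheep would not be the majority.
    """
    def _pairs(cands):
        return [c if isinstance(c, tuple) else (c, float("nan")) for c in cands]

    goat_pairs = _pairs(goat_candidates)
    lamb_pairs = _pairs(lamb_candidates)
    valid = sorted(valid_ids)
    goat_ids = [i for i, _ in goat_pairs]
    lamb_ids = [i for i, _ in lamb_pairs if i not in set(goat_ids)]
    unknown = (set(goat_ids) | set(lamb_ids)) - set(valid)
    if unknown:
        raise IntegrityError(f"candidates outside the valid population: {sorted(unknown)}")
    target = round_half_up(cfg.final_fraction * len(valid))
    rng = np.random.default_rng(seed)
    goats = _permuted(goat_ids, rng)[:target]
    lambs = _permuted(lamb_ids, rng)[:target]
    labels = {i: "sheep" for i in valid}
    labels.update({i: "goat" for i in goats})
    labels.update({i: "lamb" for i in lambs})
    n_sheep = sum(1 for l in labels.values() if l == "sheep")
    if not (n_sheep > len(goats) and n_sheep > len(lambs)):
        raise ConstraintViolationError(
            f"sheep must be the majority: {n_sheep} sheep vs "
            f"{len(goats)} goats / {len(lambs)} lambs"
        )
    return ZooLabelMap(
        labels=labels,
        goat_candidates=goat_pairs,
        lamb_candidates=lamb_pairs,
        seed=seed,
    )


def label_modality(
    dataset: ModalityDataset, cfg: ZooConfig = ZooConfig(), seed: int | None = None
) -> ZooLabelMap:
    """Full labeling pipeline for one modality: filter, compute statistics,
    select candidates, draw the seeded final menagerie."""
    valid = filter_valid_individuals(dataset)
    if len(valid) < 2:
        raise InsufficientPopulationError("need >= 2 valid individuals to label")
    dispersions = {i: intra_class_dispersion(dataset, i, cfg.metric) for i in valid}
    separations = {i: mean_inter_class_distance_among(dataset, i, valid, cfg.metric) for i in valid}
    goat_cands = identify_goats(dispersions, cfg)
    lamb_cands = identify_lambs(separations, cfg)
    out = finalize_labels(goat_cands, lamb_cands, valid, cfg, seed)
    out.discarded = sorted(set(dataset.individual_ids) - set(valid))
    return out


def mean_inter_class_distance_among(
    dataset: ModalityDataset,
    individual_id: str,
    population: Sequence[str],
    metric: str = "euclidean",
) -> float:
    """One-against-all mean distance restricted to a given valid population."""
    others = [i for i in population if i != individual_id]
    if not others:
        raise InsufficientPopulationError("need >= 2 individuals")
    sess = _training_session(dataset)
    X = dataset.features_of(individual_id, sess)
    if X.shape[0] == 0:
        raise InsufficientSamplesError(f"{individual_id!r} has no training samples")
    Y = np.vstack([dataset.features_of(i, sess) for i in others])
    return float(cross_distances(X, Y, metric).mean())


def reconcile_shared_labels(
    maps: Sequence[ZooLabelMap],
    cfg: ZooConfig = ZooConfig(),
    seed: int | None = None,
) -> ZooLabelMap:
    """Merge per-modality labelings of the *same* individuals into one.

    When modalities come from one source population the chimeric individual
    must carry a single label. Ids labeled identically everywhere keep that
    label. If a minority category (goat/lamb) then falls short of its target
    count, the divergently-labeled ids are pooled, permuted with the seed,
    and the first ones fill the category; everyone else is a sheep.
    """
    if len(maps) < 2:
        raise IntegrityError("reconciliation needs >= 2 label maps")
    id_set = set(maps[0].labels)
    for m in maps[1:]:
        if set(m.labels) != id_set:
            raise IntegrityError("label maps cover different individual sets")
    n = len(id_set)
    target = round_half_up(cfg.final_fraction * n)
    agreed: dict[str, str] = {}
    divergent: list[str] = []
    for i in sorted(id_set):
        labs = {m.labels[i] for m in maps}
        if len(labs) == 1:
            agreed[i] = labs.pop()
        else:
            divergent.append(i)
    rng = np.random.default_rng(seed)
    labels = {i: "sheep" for i in id_set}
    used: set[str] = set()
    for cat in ("goat", "lamb"):
        members = sorted(i for i, l in agreed.items() if l == cat)[:target]
        shortfall = target - len(members)
        if shortfall > 0:
            pool = [i for i in _permuted(divergent, rng) if i not in used]
            members = members + pool[:shortfall]
        for i in members:
            labels[i] = cat
            used.add(i)
    n_sheep = sum(1 for l in labels.values() if l == "sheep")
    counts = {c: sum(1 for l in labels.values() if l == c) for c in ("goat", "lamb")}
    if not all(n_sheep > counts[c] for c in counts):
        raise ConstraintViolationError("sheep must remain the majority after reconciliation")
    return ZooLabelMap(labels=labels, goat_candidates=[], lamb_candidates=[], seed=seed)
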