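"""Pair enumeration, score distributions, decidability, DET curve, EER.

Three evaluation scenarios are supported for a two-session protocol:

* ``train_intra`` — all unordered sample pairs within the training session;
* ``test_intra``  — all unordered sample pairs within the test session;
* ``inter``       — the full cross-product of test (probe) x training
  (gallery) samples, so every pair spans sessions.

A pair is *genuine* when both samples belong to the same chimeric
individual, *impostor* otherwise. Scores are distances (genuine low). The
decidability index

    d = |mu_E - mu_I| / sqrt((sigma_I^2 + sigma_E^2) / 2)

measures the separation of the genuine (intra-class, ``I``) and impostor
(inter-class, ``E``) score distributions; the DET curve traces (FAR, FRR)
over all thresholds, and the EER is the rate at the FAR = FRR crossing
(linear interpolation between adjacent thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import matching_fusion as mf
from .chimera_builder import ChimericDataset
from .errors import (
    EmptyInputError,
    IntegrityError,
    UndefinedDecidabilityError,
)
from .modality_store import ModalityDataset

SCENARIOS = ("train_intra", "test_intra", "inter")


@dataclass
class PairManifest:
    """Sample pairs for one scenario.

    ``probe_samples``/``gallery_samples`` are lists of (individual index,
    sample position) into a :class:`ChimericDataset`; ``pair_idx`` holds row
    indices into those lists. For intra scenarios the two lists coincide.
    """

    scenario: str
    probe_samples: list[tuple[int, int]]
    gallery_samples: list[tuple[int, int]]
    pair_idx: np.ndarray  # (n_pairs, 2) int
    genuine: np.ndarray  # (n_pairs,) bool
    seed: int | None = None
    limits: tuple[int, int] | None = None

    @property
    def n_genuine(self) -> int:
        return int(self.genuine.sum())

    @property
    def n_impostor(self) -> int:
        return int((~self.genuine).sum())


@dataclass
class ScoreSet:
    """Genuine and impostor distance scores for one scenario/method."""

    genuine: np.ndarray
    impostor: np.ndarray
    scenario: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        self.genuine = np.asarray(self.genuine, dtype=float)
        self.impostor = np.asarray(self.impostor, dtype=float)
        if self.genuine.size == 0 or self.impostor.size == 0:
            raise EmptyInputError("both genuine and impostor scores are required")

    @property
    def mu_i(self) -> float:
        return float(self.genuine.mean())

    @property
    def sigma_i(self) -> float:
        return float(self.genuine.std(ddof=1))

    @property
    def mu_e(self) -> float:
        return float(self.impostor.mean())

    @property
    def sigma_e(self) -> float:
        return float(self.impostor.std(ddof=1))


@dataclass
class DETCurve:
    """(threshold, FAR, FRR) triples over all distinct score thresholds.

    With distance scores and accept-if-below-threshold, FAR is
    non-decreasing and FRR non-increasing in the threshold; the curve
    includes the degenerate endpoints (FAR=0, FRR=1) and (FAR=1, FRR=0).
    """

    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray


def enumerate_pairs(
    chimeric: ChimericDataset,
    scenario: str,
    session_order: Sequence[str],
    limits: tuple[int, int] | None = None,
    seed: int | None = None,
) -> PairManifest:
    """Enumerate genuine/impostor pairs for a scenario.

    ``limits = (n_genuine, n_impostor)`` subsamples each class uniformly
    with the given seed when more pairs are available than requested.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if len(session_order) < 2:
        raise IntegrityError("two sessions (train, test) are required")
    train_sess, test_sess = session_order[0], session_order[1]

    if scenario == "inter":
        probe = chimeric.session_samples(test_sess)
        gallery = chimeric.session_samples(train_sess)
        if not probe or not gallery:
            raise IntegrityError("a required session has no chimeric samples")
        pi, gi = np.meshgrid(np.arange(len(probe)), np.arange(len(gallery)), indexing="ij")
        pair_idx = np.column_stack([pi.ravel(), gi.ravel()])
        p_ind = np.array([s[0] for s in probe])
        g_ind = np.array([s[0] for s in gallery])
        genuine = p_ind[pair_idx[:, 0]] == g_ind[pair_idx[:, 1]]
    else:
        sess = train_sess if scenario == "train_intra" else test_sess
        probe = gallery = chimeric.session_samples(sess)
        if len(probe) < 2:
            raise IntegrityError(f"session {sess!r} has fewer than two samples")
        iu = np.triu_indices(len(probe), k=1)
        pair_idx = np.column_stack(iu)
        ind = np.array([s[0] for s in probe])
        genuine = ind[pair_idx[:, 0]] == ind[pair_idx[:, 1]]

    if limits is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for flag, cap in ((True, limits[0]), (False, limits[1])):
            rows = np.where(genuine == flag)[0]
            if len(rows) > cap:
                rows = rng.choice(rows, size=cap, replace=False)
            keep.append(np.sort(rows))
        sel = np.concatenate(keep)
        pair_idx, genuine = pair_idx[sel], genuine[sel]

    return PairManifest(
        scenario=scenario,
        probe_samples=list(probe),
        gallery_samples=list(gallery),
        pair_idx=pair_idx,
        genuine=genuine,
        seed=seed,
        limits=limits,
    )


def _sample_features(
    chimeric: ChimericDataset,
    modalities: Mapping[str, ModalityDataset],
    sample_refs: Sequence[tuple[int, int]],
    which: Sequence[str],
) -> dict[str, np.ndarray]:
    """Feature matrix (one row per chimeric sample reference) per modality."""
    out: dict[str, np.ndarray] = {}
    for mod in which:
        ds = modalities[mod]
        rows = []
        for ind_idx, pos in sample_refs:
            ind = chimeric.individuals[ind_idx]
            sess, idx = ind.samples[pos][mod]
            rows.append(ds.lookup(ind.sources[mod], sess, idx).features)
        out[mod] = np.vstack(rows)
    return out


def score_pairs(
    manifest: PairManifest,
    chimeric: ChimericDataset,
    modalities: Mapping[str, ModalityDataset],
    metrics: Mapping[str, str] | str,
    modality_subset: Sequence[str] | None = None,
    fusion: str | None = None,
    train_session: str | None = None,
) -> ScoreSet:
    """Compute the genuine/impostor score distributions for one method.

    * single modality, ``fusion=None`` — raw metric distances;
    * ``fusion in {sum, min, mult}`` — per-modality distances, min-max
      normalized over this run's pairs, then fused;
    * ``fusion="concat"`` — per-modality features min-max scaled with
      training-session statistics, concatenated in declared order, and
      matched with a single metric.
    """
    order = list(modality_subset) if modality_subset is not None else list(modalities)
    if isinstance(metrics, str):
        metrics = {mod: metrics for mod in order}
    name = "+".join(order) + (f"/{fusion}" if fusion else "")

    if fusion == "concat":
        train_session = train_session or modalities[order[0]].session_order[0]
        train_refs = chimeric.session_samples(train_session)
        train_feats = _sample_features(chimeric, modalities, train_refs, order)
        scalers = {mod: mf.feature_scaler(train_feats[mod]) for mod in order}
        probe_f = _sample_features(chimeric, modalities, manifest.probe_samples, order)
        gal_f = _sample_features(chimeric, modalities, manifest.gallery_samples, order)
        P = np.hstack([mf.scale_features(probe_f[m], scalers[m]) for m in order])
        G = np.hstack([mf.scale_features(gal_f[m], scalers[m]) for m in order])
        metric = metrics[order[0]]
        scores = mf.rowwise_distances(
            P[manifest.pair_idx[:, 0]], G[manifest.pair_idx[:, 1]], metric
        )
    else:
        probe_f = _sample_features(chimeric, modalities, manifest.probe_samples, order)
        gal_f = _sample_features(chimeric, modalities, manifest.gallery_samples, order)
        per_mod = {
            mod: mf.rowwise_distances(
                probe_f[mod][manifest.pair_idx[:, 0]],
                gal_f[mod][manifest.pair_idx[:, 1]],
                metrics[mod],
            )
            for mod in order
        }
        if fusion is None:
            if len(order) != 1:
                raise IntegrityError("multiple modalities require a fusion rule")
            scores = per_mod[order[0]]
        else:
            normed = mf.normalize_scores(per_mod)
            scores = mf.fuse_scores(np.vstack([normed[m] for m in order]), fusion)

    return ScoreSet(
        genuine=scores[manifest.genuine],
        impostor=scores[~manifest.genuine],
        scenario=manifest.scenario,
        method=name,
    )


def decidability(scores: ScoreSet) -> float:
    """Separation index d between genuine and impostor distributions."""
    if scores.genuine.size < 2 or scores.impostor.size < 2:
        raise EmptyInputError("decidability needs >= 2 scores per class")
    si, se = scores.sigma_i, scores.sigma_e
    num = abs(scores.mu_e - scores.mu_i)
    den = np.sqrt((si**2 + se**2) / 2.0)
    if den == 0.0:
        if num == 0.0:
            raise UndefinedDecidabilityError("both classes constant and equal (0/0)")
        return float("inf")
    return float(num / den)


def det_curve(scores: ScoreSet) -> DETCurve:
    """DET curve with thresholds at every distinct score plus a sentinel.

    FAR(t) = fraction of impostor scores < t (falsely accepted);
    FRR(t) = fraction of genuine scores >= t (falsely rejected).
    """
    all_scores = np.concatenate([scores.genuine, scores.impostor])
    uniq = np.unique(all_scores)
    thresholds = np.concatenate([uniq, [np.inf]])
    gen = np.sort(scores.genuine)
    imp = np.sort(scores.impostor)
    far = np.searchsorted(imp, thresholds, side="left") / imp.size
    frr = 1.0 - np.searchsorted(gen, thresholds, side="left") / gen.size
    return DETCurve(thresholds=thresholds, far=far, frr=frr)


def equal_error_rate(curve: DETCurve) -> float:
    """Rate where FAR = FRR, linearly interpolated between adjacent points."""
    diff = curve.far - curve.frr
    if diff[0] >= 0:  # already crossed at the lowest threshold
        return float((curve.far[0] + curve.frr[0]) / 2.0)
    i = int(np.argmax(diff >= 0))
    if diff[i] == 0:
        return float(curve.far[i])
    d0, d1 = diff[i - 1], diff[i]
    alpha = -d0 / (d1 - d0)
    return float(curve.far[i - 1] + alpha * (curve.far[i] - curve.far[i - 1]))


def eer_from_scores(scores: ScoreSet) -> float:
    return equal_error_rate(det_curve(scores))


def det_table(curve: DETCurve):
    """DET points as a DataFrame (threshold, far, frr) for export."""
    import pandas as pd

    return pd.DataFrame(
        {"threshold": curve.thresholds, "far": curve.far, "frr": curve.frr}
    )


def plot_det(curve: DETCurve, ax=None, **kwargs):
    """Thin optional plotting layer (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.far, curve.frr, **kwargs)
    ax.set_xlabel("False acceptance rate")
    ax.set_ylabel("False rejection rate")
    return ax
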