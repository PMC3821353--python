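"""Verification and identification protocols and their metrics.

Verification collects genuine (same-class) and imposter (cross-class)
similarity scores and reduces them to an ROC curve, the equal error rate
(EER), the false rejection rate at 0.1% false acceptance rate, and the
false acceptance rate at 0.1% false rejection rate.  Identification ranks
every probe against one template per class and reports the cumulative match
characteristic (CMC), the rank-one recognition rate, and the lowest rank at
which recognition is perfect.

Protocol conventions
--------------------
* A pair (x, y) with x drawn from class A's samples in the enrolled role is
  scored with class A's weight map (the weighted similarity is asymmetric).
* Genuine scores: all unordered pairs among each class's test samples.
* Imposter scores: each class's first ``n_test_imposter`` test samples
  against every *other* class's first ``n_test_imposter`` test samples,
  ordered class pairs (both directions counted), so with C classes there
  are ``C * (C - 1) * n_test_imposter**2`` imposter scores.
* Acceptance is strict (similarity > threshold), so FAR(t) counts imposter
  scores ``> t`` and FRR(t) counts genuine scores ``<= t``; the EER and the
  fixed-rate operating points are read off the swept curve by linear
  interpolation.
* Identification ties are pessimistic: a probe's rank is the worst position
  consistent with score ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, ProtocolViolationError
from .features import BinaryCode

__all__ = [
    "Gallery",
    "ScoreSet",
    "VerificationResult",
    "IdentificationResult",
    "verification_protocol",
    "compute_eer",
    "identification_protocol",
    "random_split_repetitions",
    "training_size_sweep",
]

logger = logging.getLogger(__name__)


@dataclass
class Gallery:
    """Ordered samples per class plus a training/test role split.

    ``classes`` maps class id to the class's ordered list of codes; sample
    order is stable because protocols index by position ("the first ten",
    "the last six").  ``train_idx`` / ``test_idx`` give the per-class role
    split as index lists into each class's sample list.
    """

    classes: dict[str, list[BinaryCode]]
    train_idx: dict[str, list[int]] = field(default_factory=dict)
    test_idx: dict[str, list[int]] = field(default_factory=dict)

    @property
    def class_ids(self) -> list[str]:
        return list(self.classes)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def train_codes(self, cid: str) -> list[BinaryCode]:
        return [self.classes[cid][i] for i in self.train_idx.get(cid, [])]

    def test_codes(self, cid: str) -> list[BinaryCode]:
        return [self.classes[cid][i] for i in self.test_idx.get(cid, [])]

    def training(self) -> dict[str, list[BinaryCode]]:
        return {cid: self.train_codes(cid) for cid in self.classes}

    def with_split_first(self, k_train: int) -> "Gallery":
        """Train on the first ``k_train`` samples, test on the rest."""
        train, test = {}, {}
        for cid, samples in self.classes.items():
            if len(samples) < k_train + 1:
                raise ProtocolViolationError(
                    f"class {cid!r} has {len(samples)} samples, "
                    f"needs at least {k_train + 1}"
                )
            train[cid] = list(range(k_train))
            test[cid] = list(range(k_train, len(samples)))
        return Gallery(self.classes, train, test)

    def with_split_last_test(self, k_train: int, n_test: int) -> "Gallery":
        """Train on the first ``k_train``, test on the *last* ``n_test``."""
        train, test = {}, {}
        for cid, samples in self.classes.items():
            if len(samples) < k_train + n_test:
                raise ProtocolViolationError(
                    f"class {cid!r} has {len(samples)} samples, "
                    f"needs at least {k_train + n_test}"
                )
            train[cid] = list(range(k_train))
            test[cid] = list(range(len(samples) - n_test, len(samples)))
        return Gallery(self.classes, train, test)

    def with_random_split(self, k_train: int, rng: np.random.Generator) -> "Gallery":
        """Train on a uniform random ``k_train``-subset per class, test on
        the remainder (in original sample order)."""
        train, test = {}, {}
        for cid, samples in self.classes.items():
            n = len(samples)
            if n < k_train + 2:
                raise ProtocolViolationError(
                    f"class {cid!r} has {n} samples, needs at least {k_train + 2}"
                )
            chosen = np.sort(rng.choice(n, size=k_train, replace=False))
            train[cid] = chosen.tolist()
            test[cid] = [i for i in range(n) if i not in set(chosen.tolist())]
        return Gallery(self.classes, train, test)


@dataclass
class ScoreSet:
    """Labeled genuine/imposter similarity scores."""

    genuine: list[tuple[str, float]]
    imposter: list[tuple[str, str, float]]

    @property
    def genuine_scores(self) -> np.ndarray:
        return np.array([s for _, s in self.genuine], dtype=np.float64)

    @property
    def imposter_scores(self) -> np.ndarray:
        return np.array([s for _, _, s in self.imposter], dtype=np.float64)


@dataclass
class VerificationResult:
    """EER, fixed-rate operating points, and the full swept ROC curve.

    ``roc`` is an (n, 3) array of (FAR, FRR, threshold) rows ordered by
    ascending threshold, so FAR is non-increasing and FRR non-decreasing
    down the rows.
    """

    eer: float
    frr_at_far: float  # FRR at FAR = far_level
    far_at_frr: float  # FAR at FRR = frr_level
    roc: np.ndarray = field(repr=False)
    far_level: float = 0.001
    frr_level: float = 0.001

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.roc, columns=["far", "frr", "threshold"])


@dataclass
class IdentificationResult:
    """CMC curve and its headline numbers."""

    cmc: np.ndarray = field(repr=False)  # cmc[r-1] = rate at rank r
    rank_one: float = 0.0
    lowest_perfect_rank: int = 0
    n_probes: int = 0

    def cmc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": np.arange(1, len(self.cmc) + 1), "rate": self.cmc}
        )


def verification_protocol(
    gallery: Gallery,
    matcher,
    n_test_all: int = 10,
    n_test_imposter: int = 2,
) -> ScoreSet:
    """Collect genuine and imposter scores under the verification protocol.

    Genuine: all unordered pairs among each class's first ``n_test_all``
    test samples (``C * C(n_test_all, 2)`` scores).  Imposter: first
    ``n_test_imposter`` test samples of every ordered pair of distinct
    classes (``C * (C - 1) * n_test_imposter**2`` scores); the first class
    of the pair plays the enrolled role.
    """
    for cid in gallery.class_ids:
        n = len(gallery.test_codes(cid))
        if n < n_test_all:
            raise ProtocolViolationError(
                f"class {cid!r} has {n} test samples, protocol needs {n_test_all}"
            )
    if gallery.n_classes == 1:
        logger.warning("single-class gallery: no imposter comparisons possible")
    genuine: list[tuple[str, float]] = []
    imposter: list[tuple[str, str, float]] = []
    test = {cid: gallery.test_codes(cid)[:n_test_all] for cid in gallery.class_ids}
    for cid, codes in test.items():
        for i in range(len(codes)):
            for j in range(i + 1, len(codes)):
                genuine.append((cid, matcher.score(cid, codes[i], codes[j])))
    for cid_a in gallery.class_ids:
        heads_a = test[cid_a][:n_test_imposter]
        for cid_b in gallery.class_ids:
            if cid_b == cid_a:
                continue
            for x in heads_a:
                for y in test[cid_b][:n_test_imposter]:
                    imposter.append((cid_a, cid_b, matcher.score(cid_a, x, y)))
    return ScoreSet(genuine=genuine, imposter=imposter)


def compute_eer(
    scores: ScoreSet, far_level: float = 0.001, frr_level: float = 0.001
) -> VerificationResult:
    """Sweep thresholds over the observed scores and reduce to EER and the
    fixed-rate operating points, all by linear interpolation."""
    gen = scores.genuine_scores
    imp = scores.imposter_scores
    if gen.size == 0 or imp.size == 0:
        raise InvalidInputError("need both genuine and imposter scores")
    thresholds = np.unique(np.concatenate([gen, imp]))
    # a threshold below every score anchors the (FAR=1, FRR=0) corner
    thresholds = np.concatenate([[thresholds[0] - 1.0], thresholds])
    far = (imp[None, :] > thresholds[:, None]).mean(axis=1)
    frr = (gen[None, :] <= thresholds[:, None]).mean(axis=1)
    roc = np.column_stack([far, frr, thresholds])

    d = far - frr  # non-increasing along the sweep; starts >= 0 at the anchor
    cross = np.nonzero(d <= 0)[0]
    if cross.size == 0:  # FAR never falls to FRR (cannot happen with anchor + max)
        eer = float(min(far[-1], 1.0))
    else:
        j = cross[0]
        if d[j] == 0 or j == 0:
            eer = float((far[j] + frr[j]) / 2)
        else:
            alpha = d[j - 1] / (d[j - 1] - d[j])
            eer_far = far[j - 1] + alpha * (far[j] - far[j - 1])
            eer_frr = frr[j - 1] + alpha * (frr[j] - frr[j - 1])
            eer = float((eer_far + eer_frr) / 2)

    # FAR is non-increasing with threshold: reverse for np.interp
    frr_at_far = float(np.interp(far_level, far[::-1], frr[::-1]))
    far_at_frr = float(np.interp(frr_level, frr, far))
    return VerificationResult(
        eer=eer,
        frr_at_far=frr_at_far,
        far_at_frr=far_at_frr,
        roc=roc,
        far_level=far_level,
        frr_level=frr_level,
    )


def identification_protocol(
    gallery: Gallery, matcher, template_index: int = 0
) -> IdentificationResult:
    """Rank every probe against one template per class.

    Each class contributes the test sample at ``template_index`` as its
    template; its remaining test samples are probes.  A probe is scored
    against every template with that template's class weight map, templates
    are sorted by descending similarity, and the probe's rank is the worst
    position consistent with ties.
    """
    class_ids = gallery.class_ids
    templates: dict[str, BinaryCode] = {}
    probes: list[tuple[str, BinaryCode]] = []
    for cid in class_ids:
        test = gallery.test_codes(cid)
        if len(test) < template_index + 1:
            raise ProtocolViolationError(
                f"class {cid!r} has no test sample at template index {template_index}"
            )
        if len(test) < 2:
            raise ProtocolViolationError(f"class {cid!r} has no probe samples")
        templates[cid] = test[template_index]
        probes.extend(
            (cid, code) for i, code in enumerate(test) if i != template_index
        )
    n_templates = len(templates)
    ranks = np.empty(len(probes), dtype=np.int64)
    for p, (true_cid, probe) in enumerate(probes):
        sims = np.array(
            [matcher.score(cid, templates[cid], probe) for cid in class_ids]
        )
        own = sims[class_ids.index(true_cid)]
        worse = int((sims > own).sum())
        tied = int((sims == own).sum()) - 1  # excluding the true class itself
        ranks[p] = 1 + worse + tied
    cmc = np.array(
        [(ranks <= r).mean() for r in range(1, n_templates + 1)], dtype=np.float64
    )
    lowest = int(np.argmax(cmc >= 1.0)) + 1 if cmc[-1] >= 1.0 else n_templates
    return IdentificationResult(
        cmc=cmc,
        rank_one=float(cmc[0]),
        lowest_perfect_rank=lowest,
        n_probes=len(probes),
    )


def random_split_repetitions(
    gallery: Gallery,
    matcher_kind: str,
    k_train: int,
    reps: int,
    seed: int,
    n_test_imposter: int = 2,
) -> tuple[list[VerificationResult], dict[str, float]]:
    """Repeat verification over ``reps`` random training/test splits.

    Each repetition draws a fresh uniform ``k_train``-subset per class
    (reproducibly from ``seed``), trains the matcher on it, and evaluates on
    the remaining samples.  Returns all per-repetition results plus the
    min/max/mean/variance summary of the EER (sample variance for
    ``reps > 1``).
    """
    from .pwm import make_matcher

    if reps < 1:
        raise InvalidInputError("reps must be >= 1")
    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    results = []
    for rep in range(reps):
        rng = np.random.default_rng(child_seeds[rep])
        split = gallery.with_random_split(k_train, rng)
        matcher = make_matcher(matcher_kind, split.training())
        n_test = min(len(split.test_codes(cid)) for cid in split.class_ids)
        scores = verification_protocol(
            split, matcher, n_test_all=n_test,
            n_test_imposter=min(n_test_imposter, n_test),
        )
        results.append(compute_eer(scores))
    eers = np.array([r.eer for r in results])
    summary = {
        "min": float(eers.min()),
        "max": float(eers.max()),
        "mean": float(eers.mean()),
        "variance": float(eers.var(ddof=1)) if reps > 1 else 0.0,
    }
    return results, summary


def training_size_sweep(
    gallery: Gallery,
    k_values: list[int],
    n_test: int,
    matcher_kinds: tuple[str, ...] = ("plain", "pbbm", "pwm"),
    n_test_imposter: int = 2,
    template_index: int = 0,
) -> pd.DataFrame:
    """Evaluate verification and identification for each training-set size.

    The *last* ``n_test`` samples of every class are fixed as the test set;
    for each ``k`` in ``k_values`` the *first* ``k`` samples train the
    matchers.  Returns one row per (k, matcher) with EER, the fixed-rate
    operating points, rank-one rate and lowest perfect rank.
    """
    from .pwm import make_matcher

    rows = []
    for k in sorted(k_values):
        split = gallery.with_split_last_test(k, n_test)
        for kind in matcher_kinds:
            matcher = make_matcher(kind, split.training())
            scores = verification_protocol(
                split, matcher, n_test_all=n_test,
                n_test_imposter=min(n_test_imposter, n_test),
            )
            ver = compute_eer(scores)
            ident = identification_protocol(split, matcher, template_index)
            rows.append(
                {
                    "k_train": k,
                    "matcher": kind,
                    "eer": ver.eer,
                    "frr_at_far": ver.frr_at_far,
                    "far_at_frr": ver.far_at_frr,
                    "rank_one": ident.rank_one,
                    "lowest_perfect_rank": ident.lowest_perfect_rank,
                }
            )
    return pd.DataFrame(rows)
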