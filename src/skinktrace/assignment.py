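"""Source assignment for intercepted specimens.

Each detection carries a haplotype and a locality.  The decision cascade
mirrors how an invasion biologist reads the genetics:

1. haplotype identical to one known from the established invaded-range
   populations -> the animal is of local origin;
2. haplotype within a small tolerance (default 0.3% corrected distance) of
   the established set -> still local origin, read as a previously
   undetected haplotype from the same original source region;
3. otherwise a new arrival from the native range, whose source region is
   the locality of the nearest native-range haplotype (all ties reported).

Local-origin animals detected at a locality outside the established range
are instances of human-assisted jump dispersal within the invaded country;
inside the range they are local residents.

The cascade is packaged as :class:`HaplotypeSourceClassifier`, a
scikit-learn style estimator (``fit`` on a :class:`ReferencePanel`,
``predict`` categories for query detections); the module-level functions
are thin wrappers over it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .alignment import AlignedSequenceSet, HaplotypeTable, InputError
from .distances import (
    BaseComposition,
    base_composition,
    count_site_patterns,
    jc_distance,
    k2p_distance,
    trn_distance,
)

__all__ = [
    "LocalityError",
    "UnassignableError",
    "NativeHaplotype",
    "ReferencePanel",
    "AssignmentThresholds",
    "RegionEquivalence",
    "ClassificationResult",
    "HaplotypeSourceClassifier",
    "normalize_locality",
    "base_locality",
    "nearest_reference",
    "classify_detection",
    "score_prediction",
    "batch_classify",
]

LOCAL_RESIDENT = "local-resident"
WITHIN_COUNTRY = "within-country-movement"
NEW_ARRIVAL = "new-arrival"
CATEGORIES = (LOCAL_RESIDENT, WITHIN_COUNTRY, NEW_ARRIVAL)


class LocalityError(InputError):
    """A detection locality cannot be resolved against the panel."""


class UnassignableError(ValueError):
    """Query is saturated against every reference haplotype."""


@dataclass(frozen=True)
class NativeHaplotype:
    label: str
    sequence: str
    locality: str
    clade: str


@dataclass(frozen=True)
class ReferencePanel:
    """Native-range haplotypes plus the established invaded-range set.

    ``established_localities`` are the places where the invasive
    population is self-sustaining; a local-origin detection outside them is
    jump dispersal.  ``known_localities`` optionally enumerates resolvable
    out-of-range places — when given, a locality in neither set raises
    :class:`LocalityError` instead of being silently treated as outside.
    ``source_region_label`` names the native region the established
    population came from, reported for tier-2 (closely related) matches.
    """

    native_haplotypes: tuple[NativeHaplotype, ...]
    established_haplotypes: tuple[tuple[str, str], ...]
    established_localities: frozenset[str]
    source_region_label: str = "original source region"
    known_localities: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.established_localities:
            raise InputError("established_localities must be non-empty")
        labels = [h.label for h in self.native_haplotypes] + [
            lab for lab, _ in self.established_haplotypes
        ]
        if len(labels) != len(set(labels)):
            raise InputError("haplotype labels must be unique across the panel")
        lengths = {len(h.sequence) for h in self.native_haplotypes} | {
            len(s) for _, s in self.established_haplotypes
        }
        if len(lengths) > 1:
            raise InputError("panel sequences must share one alignment length")

    def all_sequences(self) -> list[tuple[str, str]]:
        return [(h.label, h.sequence) for h in self.native_haplotypes] + list(
            self.established_haplotypes
        )


@dataclass(frozen=True)
class AssignmentThresholds:
    """Distance tolerances of the cascade (substitutions/site).

    ``identical_tol`` bounds tier 1 (default 0: exact haplotype match);
    ``close_tol`` bounds tier 2, defaulting to 0.003 — the upper end of the
    divergence observed between established-range haplotypes and the
    previously undetected variants attributed to the same source region.
    """

    identical_tol: float = 0.0
    close_tol: float = 0.003

    def __post_init__(self) -> None:
        if not (0 <= self.identical_tol <= self.close_tol):
            raise InputError("need 0 <= identical_tol <= close_tol")


_PUNCT = re.compile(r"[?.,'\"]")
_WS = re.compile(r"\s+")


def normalize_locality(name: str) -> str:
    """Case-fold, strip punctuation (keeping parentheses, hyphens and
    slashes) and collapse whitespace."""
    name = _PUNCT.sub("", str(name))
    return _WS.sub(" ", name).strip().lower()


def base_locality(name: str) -> str:
    """Locality with any parenthetical sub-region qualifier removed, so
    'Brisbane (North)' and 'Brisbane (South)' share the base 'brisbane'."""
    return _WS.sub(" ", re.sub(r"\([^)]*\)", "", normalize_locality(name))).strip()


def _pair(a: str, b: str) -> frozenset[str]:
    return frozenset((a, b))


@dataclass(frozen=True)
class RegionEquivalence:
    """Named-locality equivalences used when scoring origin predictions.

    ``exact_pairs`` are treated as the same region (e.g. a town bordering
    the named suburb); ``near_pairs`` as the same broad region (localities
    roughly within 100 km).  Matching is by name, not geodesic — the
    equivalences encode documented geography.
    """

    exact_pairs: frozenset[frozenset[str]] = frozenset()
    near_pairs: frozenset[frozenset[str]] = frozenset()

    def __post_init__(self) -> None:
        if self.exact_pairs & self.near_pairs:
            raise InputError("a locality pair cannot be both exact and near")

    @classmethod
    def from_pairs(
        cls,
        exact: Iterable[tuple[str, str]] = (),
        near: Iterable[tuple[str, str]] = (),
    ) -> "RegionEquivalence":
        return cls(
            exact_pairs=frozenset(
                _pair(normalize_locality(a), normalize_locality(b)) for a, b in exact
            ),
            near_pairs=frozenset(
                _pair(normalize_locality(a), normalize_locality(b)) for a, b in near
            ),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionEquivalence":
        """Load from a delimited table with columns locality_a, locality_b, tier."""
        df = pd.read_csv(path)
        required = {"locality_a", "locality_b", "tier"}
        if not required <= set(df.columns):
            raise InputError(f"equivalence table needs columns {sorted(required)}")
        exact = [
            (r.locality_a, r.locality_b) for r in df.itertuples() if r.tier == "exact"
        ]
        near = [
            (r.locality_a, r.locality_b) for r in df.itertuples() if r.tier == "near"
        ]
        bad = df.loc[~df.tier.isin(["exact", "near"]), "tier"].unique()
        if len(bad):
            raise InputError(f"unknown equivalence tiers {list(bad)}")
        return cls.from_pairs(exact=exact, near=near)


@dataclass(frozen=True)
class ClassificationResult:
    detection_id: str
    category: str
    tier: str  # identical | close | divergent
    matched_haplotypes: tuple[str, ...]
    min_distance: float
    inferred_source: str
    ties: tuple[tuple[str, str], ...] = ()  # (haplotype label, locality)
    caveat: str = ""


def _tier_single(pred: str, conf: str, eq: RegionEquivalence) -> str:
    np_, nc = normalize_locality(pred), normalize_locality(conf)
    bp, bc = base_locality(pred), base_locality(conf)
    if np_ == nc or _pair(np_, nc) in eq.exact_pairs:
        return "exact"
    if bp == bc and (np_ == bp or nc == bc):
        # a bare name matches any of its own sub-regions exactly;
        # two *different* sub-regions of one base are only 'near'
        return "exact"
    for x in (np_, bp):
        for y in (nc, bc):
            if _pair(x, y) in eq.near_pairs:
                return "near"
    if bp == bc:
        return "near"
    return "far"


def score_prediction(
    result: "ClassificationResult | str",
    recorded_prediction: str | None,
    eq: RegionEquivalence | None = None,
) -> str:
    """Tier at which a recorded origin prediction matches the confirmed one.

    Returns ``exact``, ``near``, ``far`` or ``no-prediction``.  The
    prediction may list alternatives joined by ' or '; the best-matching
    alternative counts.  A missing/'Unknown' prediction is
    ``no-prediction``.
    """
    eq = eq or RegionEquivalence()
    confirmed = (
        result.inferred_source if isinstance(result, ClassificationResult) else result
    )
    if recorded_prediction is None or (
        isinstance(recorded_prediction, float) and math.isnan(recorded_prediction)
    ):
        return "no-prediction"
    pred = str(recorded_prediction).strip()
    if not pred or normalize_locality(pred) == "unknown":
        return "no-prediction"
    order = {"exact": 0, "near": 1, "far": 2}
    tiers = []
    for alt in re.split(r"\s+or\s+", pred, flags=re.IGNORECASE):
        # confirmed sources may themselves carry tied alternatives
        tiers.extend(
            _tier_single(alt, conf_alt, eq) for conf_alt in str(confirmed).split("|")
        )
    return min(tiers, key=order.__getitem__)


class HaplotypeSourceClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-haplotype source classifier for intercepted specimens.

    Parameters
    ----------
    model : {"tn93", "k2p", "jc", "p"}
        Pairwise distance model.  TN93 (the default) suits skewed mtDNA
        composition; its base frequencies are pooled over the reference
        panel at fit time.
    identical_tol, close_tol : float
        Cascade tolerances, see :class:`AssignmentThresholds`.

    After ``fit(panel)`` the fitted attributes are ``panel_``,
    ``composition_`` and ``classes_``.  ``predict`` takes an iterable of
    ``(sequence, locality)`` pairs (or a DataFrame with ``sequence`` and
    ``locality`` columns) and returns the category per detection.
    """

    def __init__(
        self,
        model: str = "tn93",
        identical_tol: float = 0.0,
        close_tol: float = 0.003,
    ):
        self.model = model
        self.identical_tol = identical_tol
        self.close_tol = close_tol

    # -- sklearn plumbing -------------------------------------------------
    def fit(self, X: ReferencePanel, y=None) -> "HaplotypeSourceClassifier":
        if not isinstance(X, ReferencePanel):
            raise InputError("fit expects a ReferencePanel")
        if self.model not in ("tn93", "k2p", "jc", "p"):
            raise InputError(f"unknown distance model {self.model!r}")
        AssignmentThresholds(self.identical_tol, self.close_tol)  # validates
        self.panel_ = X
        records = tuple(X.all_sequences())
        self.composition_: BaseComposition | None = (
            base_composition(AlignedSequenceSet(records))
            if self.model == "tn93"
            else None
        )
        self._established_norm_ = frozenset(
            normalize_locality(loc) for loc in X.established_localities
        )
        self._known_norm_ = (
            None
            if X.known_localities is None
            else frozenset(normalize_locality(loc) for loc in X.known_localities)
        )
        self.classes_ = np.array(CATEGORIES)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "panel_"):
            raise InputError("classifier is not fitted; call fit(panel) first")

    # -- distances --------------------------------------------------------
    def _distance(self, a: str, b: str) -> float:
        counts = count_site_patterns(a, b)
        if self.model == "p":
            return counts.p
        if self.model == "jc":
            d, flag = jc_distance(counts.p)
        elif self.model == "k2p":
            d, flag = k2p_distance(counts.P1 + counts.P2, counts.Q)
        else:
            d, flag = trn_distance(counts, self.composition_)
        return math.inf if flag == "saturated" else d

    # -- core operations ---------------------------------------------------
    def nearest_reference(
        self, query: str
    ) -> list[tuple[str, str, str, float]]:
        """Rank native-range haplotypes by distance to the query.

        Returns (label, locality, clade, distance) ascending; every
        haplotype tied at the minimum appears before the rest.  Raises
        :class:`UnassignableError` if the query is saturated against the
        entire panel.
        """
        self._check_fitted()
        ranked = sorted(
            (
                (h.label, h.locality, h.clade, self._distance(query, h.sequence))
                for h in self.panel_.native_haplotypes
            ),
            key=lambda item: (item[3], item[0]),
        )
        if not ranked or math.isinf(ranked[0][3]):
            raise UnassignableError("query saturated against every reference haplotype")
        return [r for r in ranked if not math.isinf(r[3])]

    def _resolve_outside(self, locality: str) -> bool:
        norm = normalize_locality(locality)
        if norm in self._established_norm_:
            return False
        if self._known_norm_ is not None and norm not in self._known_norm_:
            raise LocalityError(
                f"locality {locality!r} is in neither the established-range "
                "nor the known out-of-range list"
            )
        return True

    def classify(
        self,
        query: str,
        detection_locality: str,
        detection_id: str = "query",
    ) -> ClassificationResult:
        """Run the three-tier cascade for one detection."""
        self._check_fitted()
        outside = self._resolve_outside(detection_locality)
        est = self.panel_.established_haplotypes
        est_d = [(lab, self._distance(query, seq)) for lab, seq in est]
        d_min = min((d for _, d in est_d), default=math.inf)

        if d_min <= self.identical_tol:
            tier = "identical"
        elif d_min <= self.close_tol:
            tier = "close"
        else:
            tier = "divergent"

        if tier in ("identical", "close"):
            matched = tuple(lab for lab, d in est_d if d <= max(d_min, 1e-300))
            category = WITHIN_COUNTRY if outside else LOCAL_RESIDENT
            source = (
                self.panel_.source_region_label
                if tier == "close"
                else "established range"
            )
            return ClassificationResult(
                detection_id=detection_id,
                category=category,
                tier=tier,
                matched_haplotypes=matched,
                min_distance=d_min,
                inferred_source=source,
                caveat="local-or-same-source",
            )

        ranked = self.nearest_reference(query)
        best_d = ranked[0][3]
        ties = tuple(
            (label, locality)
            for label, locality, _, d in ranked
            if math.isclose(d, best_d, rel_tol=0.0, abs_tol=1e-12)
        )
        localities = list(dict.fromkeys(loc for _, loc in ties))
        return ClassificationResult(
            detection_id=detection_id,
            category=NEW_ARRIVAL,
            tier="divergent",
            matched_haplotypes=tuple(label for label, _ in ties),
            min_distance=best_d,
            inferred_source="|".join(localities),
            ties=ties,
        )

    def predict(self, X) -> np.ndarray:
        """Category per detection; X is (sequence, locality) pairs or a
        DataFrame with ``sequence``/``locality`` columns."""
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            pairs = list(zip(X["sequence"], X["locality"]))
        else:
            pairs = list(X)
        return np.array(
            [self.classify(seq, loc).category for seq, loc in pairs], dtype=object
        )


def nearest_reference(
    query: str, panel: ReferencePanel, model: str = "tn93"
) -> list[tuple[str, str, str, float]]:
    return HaplotypeSourceClassifier(model=model).fit(panel).nearest_reference(query)


def classify_detection(
    query: str,
    detection_locality: str,
    panel: ReferencePanel,
    thresholds: AssignmentThresholds | None = None,
    model: str = "tn93",
    detection_id: str = "query",
) -> ClassificationResult:
    thresholds = thresholds or AssignmentThresholds()
    clf = HaplotypeSourceClassifier(
        model=model,
        identical_tol=thresholds.identical_tol,
        close_tol=thresholds.close_tol,
    ).fit(panel)
    return clf.classify(query, detection_locality, detection_id=detection_id)


def batch_classify(
    queries: HaplotypeTable | Sequence[tuple[str, str]],
    localities: pd.DataFrame,
    panel: ReferencePanel,
    thresholds: AssignmentThresholds | None = None,
    eq: RegionEquivalence | None = None,
    model: str = "tn93",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify a batch of detections; per-row errors never abort the batch.

    ``localities`` needs columns ``detection_id`` and ``locality`` and may
    carry ``predicted_origin`` for prediction scoring.  Returns the
    per-detection table (stable column order) and category counts.
    """
    thresholds = thresholds or AssignmentThresholds()
    clf = HaplotypeSourceClassifier(
        model=model,
        identical_tol=thresholds.identical_tol,
        close_tol=thresholds.close_tol,
    ).fit(panel)
    if isinstance(queries, HaplotypeTable):
        items = [(h.label, h.sequence) for h in queries]
    else:
        items = list(queries)
    loc_map = dict(zip(localities["detection_id"], localities["locality"]))
    pred_map = (
        dict(zip(localities["detection_id"], localities["predicted_origin"]))
        if "predicted_origin" in localities.columns
        else {}
    )
    rows = []
    counts: dict[str, int] = {}
    for det_id, seq in items:
        row = {
            "detection_id": det_id,
            "locality": loc_map.get(det_id),
            "category": None,
            "tier": None,
            "matched_haplotypes": None,
            "min_distance": None,
            "inferred_source": None,
            "predicted_origin": pred_map.get(det_id),
            "prediction_tier": None,
            "caveat": None,
            "error": None,
        }
        try:
            if det_id not in loc_map:
                raise LocalityError(f"no locality row for detection {det_id!r}")
            res = clf.classify(seq, loc_map[det_id], detection_id=det_id)
            row.update(
                category=res.category,
                tier=res.tier,
                matched_haplotypes="|".join(res.matched_haplotypes),
                min_distance=res.min_distance,
                inferred_source=res.inferred_source,
                caveat=res.caveat or None,
            )
            if det_id in pred_map and res.category == NEW_ARRIVAL:
                row["prediction_tier"] = score_prediction(res, pred_map[det_id], eq)
            counts[res.category] = counts.get(res.category, 0) + 1
        except (InputError, UnassignableError) as exc:
            row["error"] = str(exc)
            counts["error"] = counts.get("error", 0) + 1
        rows.append(row)
    columns = [
        "detection_id", "locality", "category", "tier", "matched_haplotypes",
        "min_distance", "inferred_source", "predicted_origin",
        "prediction_tier", "caveat", "error",
    ]
    return pd.DataFrame(rows, columns=columns), counts
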