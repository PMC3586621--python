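"""Synthetic reference panels, detections and recovery experiments.

The generator emulates the statistical structure the assignment pipeline
assumes: a native-range panel of equal-length mtDNA haplotypes partitioned
into geographically labelled clades whose between-clade divergence sits in
a configured band (default 1.8-8.3% — deep, long-isolated mitochondrial
clades), with shallow within-region variation (default <= 0.3%), plus an
established invaded-range haplotype set drawn from a single source
locality, and detections of all three true categories.

Mutations follow a discrete Tamura–Nei-flavoured process: substitutions hit
distinct random sites and the replacement base is drawn proportionally to
a rate built from the stationary composition and separate purine-transition,
pyrimidine-transition and transversion weights.  Divergence targets are
checked empirically on the generated sequences and topped up where random
overlap pulls a pair under its band.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedSequenceSet, InputError
from .assignment import (
    NEW_ARRIVAL,
    AssignmentThresholds,
    NativeHaplotype,
    ReferencePanel,
    batch_classify,
)

__all__ = [
    "SimulationConfig",
    "simulate_reference_panel",
    "simulate_detections",
    "recovery_experiment",
    "RecoveryResult",
]

_BASES = "ACGT"
_PURINES = {0, 2}  # A, G indices in _BASES
_MITO_STOPS = {"TAA", "TAG", "AGA", "AGG"}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults mirror the study system.

    ``composition`` is the stationary (A, C, G, T) proportion vector;
    the default is the skewed mtDNA composition of the study alignment.
    ``detection_mix`` gives the counts of true local residents,
    within-country movements and new arrivals to simulate.
    """

    seed: int = 0
    seq_length: int = 1221
    n_clades: int = 9
    localities_per_clade: int = 2
    haplotypes_per_locality: int = 3
    inter_clade_divergence: tuple[float, float] = (0.018, 0.083)
    intra_region_divergence: tuple[float, float] = (0.0, 0.003)
    inter_locality_divergence: float = 0.010
    established_clade: int = 0
    n_established_haplotypes: int = 6
    composition: tuple[float, float, float, float] = (0.326, 0.310, 0.120, 0.244)
    purine_transition_weight: float = 20.0
    pyrimidine_transition_weight: float = 10.0
    transversion_weight: float = 1.0
    detection_mix: tuple[int, int, int] = (5, 5, 5)
    query_mutations_max: int | None = None  # default: just under the intra band
    prediction_error_rate: float = 0.0
    n_in_range_localities: int = 3
    n_out_range_localities: int = 5
    coding_frame: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.inter_clade_divergence
        ilo, ihi = self.intra_region_divergence
        if not (0 <= ilo <= ihi <= lo <= hi):
            raise InputError("divergence bands must be ordered: intra <= inter")
        if hi > 0.25:
            raise InputError(
                "inter-clade divergence target too high: the distance "
                "correction would saturate"
            )
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise InputError("composition must sum to 1")
        if min(self.detection_mix) < 0:
            raise InputError("detection mix counts must be >= 0")
        if self.n_clades < 1 or self.seq_length < 10:
            raise InputError("need at least 1 clade and 10 sites")
        if not 0 <= self.prediction_error_rate <= 1:
            raise InputError("prediction_error_rate must be in [0, 1]")
        if not 0 <= self.established_clade < self.n_clades:
            raise InputError("established_clade out of range")


def _substitution_weights(cfg: SimulationConfig) -> np.ndarray:
    """4x4 replacement weights: rate(x->y) ~ class_weight(x,y) * pi_y."""
    pi = np.asarray(cfg.composition)
    w = np.full((4, 4), cfg.transversion_weight)
    w[0, 2] = w[2, 0] = cfg.purine_transition_weight  # A<->G
    w[1, 3] = w[3, 1] = cfg.pyrimidine_transition_weight  # C<->T
    np.fill_diagonal(w, 0.0)
    return w * pi[None, :]


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


def _is_stop(codon: np.ndarray) -> bool:
    return _decode(codon) in _MITO_STOPS


def _remove_stops(seq: np.ndarray, frame: int, rng: np.random.Generator) -> None:
    for pos in range(frame, len(seq) - 2, 3):
        while _is_stop(seq[pos : pos + 3]):
            seq[pos + 2] = rng.integers(0, 4)


def _mutate_distinct(
    seq: np.ndarray,
    n_mutations: int,
    weights: np.ndarray,
    rng: np.random.Generator,
    coding_frame: int | None = None,
) -> np.ndarray:
    """Copy `seq` with substitutions at `n_mutations` distinct sites.

    In coding mode only third codon positions mutate and a replacement
    recreating a (vertebrate-mitochondrial) stop codon is redrawn.
    """
    out = seq.copy()
    length = len(seq)
    if coding_frame is None:
        candidate_sites = np.arange(length)
    else:
        candidate_sites = np.arange(coding_frame + 2, length, 3)
    if n_mutations > len(candidate_sites):
        raise InputError("more mutations requested than mutable sites")
    sites = rng.choice(candidate_sites, size=n_mutations, replace=False)
    for site in sites:
        current = out[site]
        p = weights[current].copy()
        for _ in range(64):
            p_norm = p / p.sum()
            new = rng.choice(4, p=p_norm)
            if coding_frame is not None:
                codon_start = site - 2
                codon = out[codon_start : codon_start + 3].copy()
                codon[2] = new
                if _is_stop(codon):
                    p[new] = 0.0
                    continue
            out[site] = new
            break
    return out


def _p_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float((a != b).mean())


def simulate_reference_panel(
    cfg: SimulationConfig,
) -> tuple[ReferencePanel, dict]:
    """Generate a clade-structured native panel plus the established set.

    Clade ancestors are produced by mutating a common root until every
    between-clade pairwise p-distance reaches the lower band edge, with
    per-clade targets drawn so pairs land inside the configured band.
    Localities within a clade are separated by ``inter_locality_divergence``
    and haplotypes within a locality differ by at most the intra-region
    band.  The established haplotypes are shallow variants of one source
    locality of the established clade.

    Returns the panel and a truth map (clade and locality per label, the
    source locality, and the root/clade ancestor sequences).
    """
    rng = np.random.default_rng(cfg.seed)
    weights = _substitution_weights(cfg)
    L = cfg.seq_length
    lo, hi = cfg.inter_clade_divergence
    ilo, ihi = cfg.intra_region_divergence

    root = rng.choice(4, size=L, p=np.asarray(cfg.composition))
    if cfg.coding_frame is not None:
        _remove_stops(root, cfg.coding_frame, rng)

    # Clade ancestors: half the band per branch, then top up underdiverged pairs.
    ancestors: list[np.ndarray] = []
    for _ in range(cfg.n_clades):
        target = rng.uniform(lo / 2, hi / 2)
        anc = _mutate_distinct(root, round(target * L), weights, rng, cfg.coding_frame)
        for prev in ancestors:
            guard = 0
            while _p_distance(anc, prev) < lo and guard < L:
                anc = _mutate_distinct(anc, 1, weights, rng, cfg.coding_frame)
                guard += 1
        ancestors.append(anc)

    intra_max_mut = max(int(ihi * L / 2), 0)
    loc_mut = max(round(cfg.inter_locality_divergence * L / 2), intra_max_mut + 1)

    natives: list[NativeHaplotype] = []
    truth_clades: dict[str, str] = {}
    truth_localities: dict[str, str] = {}
    founders: dict[str, np.ndarray] = {}
    for ci, anc in enumerate(ancestors):
        for lj in range(cfg.localities_per_clade):
            locality = f"Clade{ci + 1}-Loc{lj + 1}"
            founder = _mutate_distinct(anc, loc_mut, weights, rng, cfg.coding_frame)
            founders[locality] = founder
            for hk in range(cfg.haplotypes_per_locality):
                n_mut = int(rng.integers(0, intra_max_mut + 1))
                hap = _mutate_distinct(founder, n_mut, weights, rng, cfg.coding_frame)
                label = f"NAT-C{ci + 1}L{lj + 1}H{hk + 1}"
                natives.append(
                    NativeHaplotype(
                        label=label,
                        sequence=_decode(hap),
                        locality=locality,
                        clade=f"Clade{ci + 1}",
                    )
                )
                truth_clades[label] = f"Clade{ci + 1}"
                truth_localities[label] = locality

    source_locality = f"Clade{cfg.established_clade + 1}-Loc1"
    established = []
    for ei in range(cfg.n_established_haplotypes):
        n_mut = int(rng.integers(0, intra_max_mut + 1))
        hap = _mutate_distinct(
            founders[source_locality], n_mut, weights, rng, cfg.coding_frame
        )
        established.append((f"EST{ei + 1:02d}", _decode(hap)))

    in_range = frozenset(f"Invaded-In{i + 1}" for i in range(cfg.n_in_range_localities))
    out_range = frozenset(
        f"Invaded-Out{i + 1}" for i in range(cfg.n_out_range_localities)
    )
    panel = ReferencePanel(
        native_haplotypes=tuple(natives),
        established_haplotypes=tuple(established),
        established_localities=in_range,
        source_region_label=source_locality,
        known_localities=out_range,
    )
    truth = {
        "clades": truth_clades,
        "localities": truth_localities,
        "source_locality": source_locality,
        "root": _decode(root),
        "clade_ancestors": [_decode(a) for a in ancestors],
        "in_range": in_range,
        "out_range": out_range,
    }
    return panel, truth


def _panel_alignment(panel: ReferencePanel) -> AlignedSequenceSet:
    return AlignedSequenceSet(tuple(panel.all_sequences()))


def simulate_detections(
    panel: ReferencePanel, cfg: SimulationConfig
) -> pd.DataFrame:
    """Simulate detections with known truth.

    Local residents and within-country movements carry haplotypes at most
    ``query_mutations_max`` substitutions from an established haplotype
    (so at or under the close-match tolerance for the default 1221 bp) and
    differ only in locality: in range for residents, beyond it for
    movements.  New arrivals descend from native haplotypes outside the
    established clade.  Synthetic predicted origins are correct except
    with probability ``prediction_error_rate``.

    Returns a DataFrame with detection_id, sequence, locality,
    true_category, true_source and predicted_origin columns.
    """
    if sum(cfg.detection_mix) == 0:
        raise InputError("empty detection mix")
    rng = np.random.default_rng([cfg.seed, 1723])
    weights = _substitution_weights(cfg)
    n_local, n_within, n_new = cfg.detection_mix
    if cfg.query_mutations_max is not None:
        query_mut_max = cfg.query_mutations_max
    else:
        # queries are same-region variants: keep their divergence strictly
        # inside the intra-region band
        ihi = cfg.intra_region_divergence[1]
        query_mut_max = max(int(np.ceil(ihi * cfg.seq_length)) - 1, 0)

    est_clade = f"Clade{cfg.established_clade + 1}"
    est_arrs = [
        (lab, np.array([_BASES.index(c) for c in seq], dtype=np.int64))
        for lab, seq in panel.established_haplotypes
    ]
    native_pool = [
        h
        for h in panel.native_haplotypes
        if h.clade != est_clade
    ]
    if n_new > 0 and not native_pool:
        raise InputError("no native haplotypes outside the established clade")
    in_range = sorted(panel.established_localities)
    out_range = sorted(panel.known_localities or {"beyond-range"})
    all_localities = sorted({h.locality for h in panel.native_haplotypes})

    rows = []

    def _query_from(arr: np.ndarray) -> str:
        n_mut = int(rng.integers(0, query_mut_max + 1))
        return _decode(_mutate_distinct(arr, n_mut, weights, rng, cfg.coding_frame))

    for i in range(n_local):
        lab, arr = est_arrs[rng.integers(0, len(est_arrs))]
        rows.append(
            {
                "true_category": "local-resident",
                "sequence": _query_from(arr),
                "locality": in_range[int(rng.integers(0, len(in_range)))],
                "true_source": "established range",
                "predicted_origin": "local",
            }
        )
    for i in range(n_within):
        lab, arr = est_arrs[rng.integers(0, len(est_arrs))]
        rows.append(
            {
                "true_category": "within-country-movement",
                "sequence": _query_from(arr),
                "locality": out_range[int(rng.integers(0, len(out_range)))],
                "true_source": "established range",
                "predicted_origin": "local",
            }
        )
    for i in range(n_new):
        src = native_pool[int(rng.integers(0, len(native_pool)))]
        arr = np.array([_BASES.index(c) for c in src.sequence], dtype=np.int64)
        predicted = src.locality
        if rng.random() < cfg.prediction_error_rate:
            others = [loc for loc in all_localities if loc != src.locality]
            predicted = others[int(rng.integers(0, len(others)))]
        rows.append(
            {
                "true_category": NEW_ARRIVAL,
                "sequence": _query_from(arr),
                "locality": (in_range + out_range)[
                    int(rng.integers(0, len(in_range) + len(out_range)))
                ],
                "true_source": src.locality,
                "predicted_origin": predicted,
            }
        )

    df = pd.DataFrame(rows)
    df.insert(0, "detection_id", [f"DET{i + 1:04d}" for i in range(len(df))])
    return df


@dataclass(frozen=True)
class RecoveryResult:
    confusion: pd.DataFrame  # true category x assigned category
    category_accuracy: float
    source_accuracy: float  # new arrivals with the true source among the call
    n_detections: int
    results: pd.DataFrame


def recovery_experiment(
    cfg: SimulationConfig, thresholds: AssignmentThresholds | None = None
) -> RecoveryResult:
    """Simulate a panel plus detections and score the assignment cascade.

    Category accuracy is over all detections; source accuracy is over true
    new arrivals, counting a hit when the true source locality is among
    the (possibly tied) inferred sources.  Per-row classification errors
    are carried in the result table, never raised.
    """
    panel, _ = simulate_reference_panel(cfg)
    detections = simulate_detections(panel, cfg)
    if detections.empty:
        return RecoveryResult(
            confusion=pd.DataFrame(),
            category_accuracy=float("nan"),
            source_accuracy=float("nan"),
            n_detections=0,
            results=pd.DataFrame(),
        )
    queries = list(zip(detections["detection_id"], detections["sequence"]))
    loc_table = detections[["detection_id", "locality", "predicted_origin"]]
    table, _counts = batch_classify(queries, loc_table, panel, thresholds)
    merged = table.merge(
        detections[["detection_id", "true_category", "true_source"]],
        on="detection_id",
    )
    confusion = pd.crosstab(merged["true_category"], merged["category"])
    category_accuracy = float((merged["category"] == merged["true_category"]).mean())
    new_mask = merged["true_category"] == NEW_ARRIVAL
    if new_mask.any():
        hits = [
            str(row.true_source) in str(row.inferred_source).split("|")
            for row in merged[new_mask].itertuples()
        ]
        source_accuracy = float(np.mean(hits))
    else:
        source_accuracy = float("nan")
    return RecoveryResult(
        confusion=confusion,
        category_accuracy=category_accuracy,
        source_accuracy=source_accuracy,
        n_detections=len(merged),
        results=merged,
    )
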