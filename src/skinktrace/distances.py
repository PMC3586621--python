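"""Base composition, site patterns and corrected genetic distances.

The workhorse model is the Tamura–Nei (TN93) correction, which allows
unequal base frequencies and distinct purine (A<->G) and pyrimidine (C<->T)
transition rates — the regime typical of vertebrate mitochondrial DNA,
where composition is skewed (G-poor light strand) and transitions dominate.
Jukes–Cantor and Kimura two-parameter distances are provided both as user
options and as limiting cases of TN93 for validation.

All pairwise site counting uses pairwise deletion: a column is compared for
a pair of sequences only when both carry an unambiguous A/C/G/T at it.
Complete deletion (drop a column for everyone if anyone is ambiguous/gapped)
is available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .alignment import AlignedSequenceSet, HaplotypeTable, InputError, UNAMBIGUOUS

__all__ = [
    "BaseComposition",
    "SubstitutionCounts",
    "ChiSquareResult",
    "SiteSummary",
    "DistanceMatrix",
    "SaturationError",
    "base_composition",
    "composition_homogeneity_test",
    "count_site_patterns",
    "p_distance",
    "jc_distance",
    "k2p_distance",
    "trn_distance",
    "distance_matrix",
    "site_summary",
    "write_distance_matrix",
    "read_distance_matrix",
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)
SATURATED = float("nan")


class SaturationError(ValueError):
    """A corrected distance is undefined (log argument <= 0)."""


@dataclass(frozen=True)
class BaseComposition:
    """Pooled nucleotide proportions with purine/pyrimidine totals."""

    freq_A: float
    freq_C: float
    freq_G: float
    freq_T: float
    counted_sites: int

    def __post_init__(self) -> None:
        total = self.freq_A + self.freq_C + self.freq_G + self.freq_T
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise InputError(f"base proportions sum to {total}, not 1")

    @property
    def g_R(self) -> float:
        return self.freq_A + self.freq_G

    @property
    def g_Y(self) -> float:
        return self.freq_C + self.freq_T

    def as_dict(self) -> dict[str, float]:
        return {"A": self.freq_A, "C": self.freq_C, "G": self.freq_G, "T": self.freq_T}


@dataclass(frozen=True)
class SubstitutionCounts:
    """Observed pairwise substitution proportions under pairwise deletion.

    P1: A<->G (purine transition) proportion; P2: C<->T (pyrimidine
    transition) proportion; Q: transversion proportion.  Proportions are
    over `compared_sites`, the columns where both sequences are
    unambiguous.
    """

    P1: float
    P2: float
    Q: float
    compared_sites: int

    def __post_init__(self) -> None:
        if self.compared_sites < 1:
            raise InputError("no comparable sites between sequences")
        if min(self.P1, self.P2, self.Q) < 0 or self.P1 + self.P2 + self.Q > 1 + 1e-12:
            raise InputError("substitution proportions out of range")

    @property
    def p(self) -> float:
        """Total proportion of differing sites (uncorrected p-distance)."""
        return self.P1 + self.P2 + self.Q


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class SiteSummary:
    total_sites: int
    variable_sites: int
    parsimony_informative_sites: int

    @property
    def variable_proportion(self) -> float:
        return self.variable_sites / self.total_sites

    @property
    def parsimony_informative_proportion(self) -> float:
        return self.parsimony_informative_sites / self.total_sites


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair saturation flags."""

    labels: tuple[str, ...]
    values: np.ndarray
    flags: np.ndarray  # bool, True where the pair is saturated

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n) or self.flags.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0):
            raise InputError("distance matrix diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if self.flags[i, j]:
                    out.append((self.labels[i], self.labels[j]))
        return out


def _unambiguous_counts(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.array([(arr == b).sum() for b in _ACGT], dtype=np.int64)


def _complete_deletion_columns(aln: AlignedSequenceSet) -> np.ndarray:
    arr = aln.to_array()
    unamb = np.zeros_like(arr, dtype=bool)
    for b in _ACGT:
        unamb |= arr == b
    return unamb.all(axis=0)


def base_composition(
    aln: AlignedSequenceSet, deletion: str = "pairwise-n/a"
) -> BaseComposition:
    """Pooled A/C/G/T proportions over the whole alignment.

    With ``deletion="complete"`` only columns that are unambiguous in every
    sequence are counted; the default counts every unambiguous character
    wherever it occurs.
    """
    arr = aln.to_array()
    if deletion == "complete":
        keep = _complete_deletion_columns(aln)
        arr = arr[:, keep]
    elif deletion != "pairwise-n/a":
        raise InputError(f"unknown deletion mode {deletion!r}")
    counts = np.array([(arr == b).sum() for b in _ACGT], dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        raise InputError("alignment has no unambiguous A/C/G/T characters")
    fA, fC, fG, fT = (counts / total).tolist()
    return BaseComposition(fA, fC, fG, fT, counted_sites=total)


def composition_homogeneity_test(aln: AlignedSequenceSet) -> ChiSquareResult:
    """Chi-square test of base-frequency homogeneity among sequences.

    Builds the N x 4 table of per-sequence base counts, takes expected
    counts from the pooled proportions scaled by each sequence's total, and
    sums (obs - exp)^2 / exp.  Degrees of freedom are 3(N - 1); the p-value
    is the upper tail of the chi-square distribution.
    """
    if len(aln) < 2:
        raise InputError("homogeneity test needs at least 2 sequences")
    table = np.stack([_unambiguous_counts(seq) for seq in aln.sequences])
    row_totals = table.sum(axis=1)
    if (row_totals == 0).any():
        bad = aln.identifiers[int(np.argmin(row_totals))]
        raise InputError(f"sequence {bad!r} has no countable characters")
    pooled = table.sum(axis=0) / table.sum()
    expected = row_totals[:, None] * pooled[None, :]
    mask = expected > 0
    statistic = float(((table - expected) ** 2 / np.where(mask, expected, 1.0))[mask].sum())
    df = 3 * (len(aln) - 1)
    p_value = float(stats.chi2.sf(statistic, df))
    return ChiSquareResult(statistic=statistic, df=df, p_value=p_value)


def count_site_patterns(a: str, b: str, deletion: str = "pairwise") -> SubstitutionCounts:
    """Classify the differing columns of a sequence pair.

    Returns the proportions of purine transitions (P1), pyrimidine
    transitions (P2) and transversions (Q) over the columns where both
    sequences carry an unambiguous base (pairwise deletion).
    """
    if deletion != "pairwise":
        raise InputError(f"unknown deletion mode {deletion!r}")
    if len(a) != len(b):
        raise InputError("sequences differ in length")
    xa = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)
    unamb_a = np.zeros(len(xa), dtype=bool)
    unamb_b = np.zeros(len(xb), dtype=bool)
    for base in _ACGT:
        unamb_a |= xa == base
        unamb_b |= xb == base
    both = unamb_a & unamb_b
    n = int(both.sum())
    if n == 0:
        raise InputError("no comparable sites between sequences")
    ya, yb = xa[both], xb[both]
    diff = ya != yb
    A, C, G, T = (ord(c) for c in "ACGT")
    purine_a = (ya == A) | (ya == G)
    purine_b = (yb == A) | (yb == G)
    p1 = int((diff & purine_a & purine_b).sum())
    pyrimidine_a = (ya == C) | (ya == T)
    pyrimidine_b = (yb == C) | (yb == T)
    p2 = int((diff & pyrimidine_a & pyrimidine_b).sum())
    q = int(diff.sum()) - p1 - p2
    return SubstitutionCounts(P1=p1 / n, P2=p2 / n, Q=q / n, compared_sites=n)


def p_distance(counts: SubstitutionCounts) -> float:
    return counts.p


def jc_distance(p: float) -> tuple[float, str]:
    """Jukes–Cantor distance: d = -(3/4) ln(1 - 4p/3)."""
    w = 1.0 - 4.0 * p / 3.0
    if w <= 0:
        return SATURATED, "saturated"
    return -0.75 * math.log(w), "ok"


def k2p_distance(P: float, Q: float) -> tuple[float, str]:
    """Kimura two-parameter distance: d = -ln(1-2P-Q)/2 - ln(1-2Q)/4."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return SATURATED, "saturated"
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), "ok"


def trn_distance(
    counts: SubstitutionCounts, comp: BaseComposition
) -> tuple[float, str]:
    """Tamura–Nei (TN93) corrected distance.

    d = -k1 ln(w1) - k2 ln(w2) - k3 ln(w3) with

        k1 = 2 gA gG / gR          w1 = 1 - gR P1 / (2 gA gG) - Q / (2 gR)
        k2 = 2 gT gC / gY          w2 = 1 - gY P2 / (2 gT gC) - Q / (2 gY)
        k3 = 2 (gR gY - gA gG gY / gR - gT gC gR / gY)
                                   w3 = 1 - Q / (2 gR gY)

    where gR = gA + gG and gY = gC + gT.  When substitutions are too
    numerous for the correction (any log argument <= 0) the pair is flagged
    ``saturated`` and the value is NaN.

    Degenerate compositions: a term with a zero denominator is evaluated
    only if its substitution class was actually observed, in which case the
    distance is undefined and an error is raised; if the class proportion
    is 0 the term contributes 0 and is skipped.
    """
    gA, gC, gG, gT = comp.freq_A, comp.freq_C, comp.freq_G, comp.freq_T
    gR, gY = comp.g_R, comp.g_Y
    P1, P2, Q = counts.P1, counts.P2, counts.Q

    terms: list[tuple[float, float]] = []  # (k, w)

    if gA * gG > 0 and gR > 0:
        terms.append((2 * gA * gG / gR, 1 - gR * P1 / (2 * gA * gG) - Q / (2 * gR)))
    elif P1 > 0:
        raise InputError("purine transitions observed but composition has gA*gG = 0")

    if gT * gC > 0 and gY > 0:
        terms.append((2 * gT * gC / gY, 1 - gY * P2 / (2 * gT * gC) - Q / (2 * gY)))
    elif P2 > 0:
        raise InputError("pyrimidine transitions observed but composition has gT*gC = 0")

    if gR * gY > 0:
        k3 = 2 * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0)
                  - (gT * gC * gR / gY if gY > 0 else 0))
        terms.append((k3, 1 - Q / (2 * gR * gY)))
    elif Q > 0:
        raise InputError("transversions observed but composition has gR*gY = 0")

    d = 0.0
    for k, w in terms:
        if w <= 0:
            return SATURATED, "saturated"
        d -= k * math.log(w)
    # correction may be fractionally below 0 from float rounding at d ~ 0
    return max(d, 0.0), "ok"


def distance_matrix(
    table: HaplotypeTable | AlignedSequenceSet,
    model: str = "tn93",
    composition_scope: str = "pooled",
) -> DistanceMatrix:
    """All-pairs corrected distances over a haplotype table or alignment.

    The TN93 correction uses the composition pooled over all input
    sequences by default (``composition_scope="pooled"``); with
    ``"per-pair"`` each pair's own pooled composition is used.  Saturated
    pairs are flagged, never silently replaced.
    """
    if isinstance(table, HaplotypeTable):
        aln = table.as_alignment()
    else:
        aln = table
    labels = tuple(aln.identifiers)
    seqs = aln.sequences
    n = len(labels)
    if n < 2:
        raise InputError("need at least 2 sequences for a distance matrix")
    if model not in ("p", "jc", "k2p", "tn93"):
        raise InputError(f"unknown distance model {model!r}")
    if composition_scope not in ("pooled", "per-pair"):
        raise InputError(f"unknown composition scope {composition_scope!r}")

    pooled = base_composition(aln) if model == "tn93" else None
    values = np.zeros((n, n), dtype=float)
    flags = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            counts = count_site_patterns(seqs[i], seqs[j])
            if model == "p":
                d, flag = counts.p, "ok"
            elif model == "jc":
                d, flag = jc_distance(counts.p)
            elif model == "k2p":
                d, flag = k2p_distance(counts.P1 + counts.P2, counts.Q)
            else:
                comp = pooled
                if composition_scope == "per-pair":
                    comp = base_composition(
                        AlignedSequenceSet(((labels[i], seqs[i]), (labels[j], seqs[j])))
                    )
                d, flag = trn_distance(counts, comp)
            values[i, j] = values[j, i] = d
            flags[i, j] = flags[j, i] = flag == "saturated"
    return DistanceMatrix(labels=labels, values=values, flags=flags)


def site_summary(aln: AlignedSequenceSet) -> SiteSummary:
    """Count variable and parsimony-informative columns.

    A column is variable if it shows >= 2 distinct unambiguous states, and
    parsimony informative if >= 2 states are each carried by >= 2
    sequences.  Gaps and ambiguity codes are ignored when tallying states.
    """
    arr = aln.to_array()
    variable = 0
    informative = 0
    for col in arr.T:
        state_counts = [int((col == b).sum()) for b in _ACGT]
        present = [c for c in state_counts if c > 0]
        if len(present) >= 2:
            variable += 1
            if sum(1 for c in present if c >= 2) >= 2:
                informative += 1
    return SiteSummary(
        total_sites=aln.length,
        variable_sites=variable,
        parsimony_informative_sites=informative,
    )


def write_distance_matrix(dm: DistanceMatrix, path: str | Path, precision: int = 8) -> None:
    """Square tab-delimited matrix with a label header row."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(("",) + dm.labels) + "\n")
        for i, label in enumerate(dm.labels):
            row = "\t".join(
                "saturated" if dm.flags[i, j] else f"{dm.values[i, j]:.{precision}f}"
                for j in range(len(dm.labels))
            )
            fh.write(f"{label}\t{row}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square matrix written by :func:`write_distance_matrix`.

    A PHYLIP-style square matrix (leading line holding the taxon count) is
    also accepted.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).open() if ln.strip()]
    if not lines:
        raise InputError(f"empty matrix file: {path}")
    first = lines[0].split()
    if len(first) == 1 and first[0].isdigit():  # PHYLIP square
        n = int(first[0])
        body = [ln.split() for ln in lines[1 : 1 + n]]
        labels = tuple(row[0] for row in body)
        raw = [row[1:] for row in body]
    else:
        labels = tuple(lines[0].split("\t")[1:])
        n = len(labels)
        body = [ln.split("\t") for ln in lines[1 : 1 + n]]
        raw = [row[1:] for row in body]
    values = np.zeros((n, n), dtype=float)
    flags = np.zeros((n, n), dtype=bool)
    for i, row in enumerate(raw):
        for j, cell in enumerate(row):
            if cell == "saturated":
                values[i, j] = SATURATED
                flags[i, j] = True
            else:
                values[i, j] = float(cell)
    return DistanceMatrix(labels=labels, values=values, flags=flags)
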