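"""Kimura 2-parameter distances and barcoding-gap statistics.

The K2P distance corrects observed divergence for multiple hits while
distinguishing transitions (purine<->purine, pyrimidine<->pyrimidine;
proportion P) from transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Columns containing a gap or an IUPAC ambiguity code in either sequence
are excluded pair by pair (pairwise deletion).  A pair with no shared
unambiguous columns, or one whose observed proportions saturate a
logarithm, has no defined distance; such entries are *masked*, never
silently zeroed, and downstream consumers must consult the mask.

The barcoding gap is the separation between the distributions of
intraspecific and interspecific distances; it is summarised here with
the two-sample tests used in barcode surveys (Mood's median test and
the Wilcoxon rank-sum test) applied, as in those surveys, to the pooled
pairwise distances even though pairwise distances are not independent
observations — the caveat is inherited from the procedure, not hidden.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .alignments import MarkerAlignment

__all__ = [
    "K2PResult",
    "DistanceMatrix",
    "GapSummary",
    "WilcoxonResult",
    "MedianTestResult",
    "PVALUE_FLOOR",
    "encode_sequences",
    "k2p_distance",
    "build_distance_matrix",
    "distance_matrix_from_encoded",
    "partition_distances",
    "wilcoxon_rank_sum",
    "median_test",
    "gap_summary",
    "format_pvalue",
]

#: Reporting floor for vanishingly small p-values ("< 2.2e-16").
PVALUE_FLOOR = 2.2e-16

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_BASE_CODE[ord("U")] = _BASE_CODE[ord("u")] = 3


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode sequences as a (n, L) uint8 matrix: A,C,G,T -> 0..3, other -> 4."""
    n = len(seqs)
    length = len(seqs[0])
    out = np.empty((n, length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        out[i] = _BASE_CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    return out


class K2PResult(NamedTuple):
    """Outcome of one pairwise K2P computation."""

    distance: float  # nan when undefined
    p_transition: float
    q_transversion: float
    n_sites: int
    defined: bool
    reason: str | None  # 'no-overlap' or 'saturated' when undefined


def _k2p_from_codes(a: np.ndarray, b: np.ndarray) -> K2PResult:
    both = (a < 4) & (b < 4)
    n = int(both.sum())
    if n == 0:
        return K2PResult(math.nan, math.nan, math.nan, 0, False, "no-overlap")
    x = a[both]
    y = b[both]
    diff = x != y
    xor = x ^ y
    ts = int((diff & (xor == 2)).sum())  # A<->G, C<->T
    tv = int(diff.sum()) - ts
    p = ts / n
    q = tv / n
    # integer numerators of 1-2P-Q and 1-2Q: saturation is detected
    # exactly, immune to float rounding at the log-domain boundary
    num1 = n - 2 * ts - tv
    num2 = n - 2 * tv
    if num1 <= 0 or num2 <= 0:
        return K2PResult(math.nan, p, q, n, False, "saturated")
    d = -0.5 * math.log(num1 / n) - 0.25 * math.log(num2 / n)
    # guard against -0.0 from rounding at p=q=0
    return K2PResult(max(d, 0.0), p, q, n, True, None)


def k2p_distance(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance between two equal-length gapped DNA strings.

    Pairwise deletion: only columns where both residues are in
    {A,C,G,T} are compared.  Undefined outcomes (zero overlap or
    saturation, 1-2P-Q <= 0 or 1-2Q <= 0) are signalled via
    ``defined=False``; no exception is raised.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal (aligned) lengths")
    codes = encode_sequences([seq_a, seq_b])
    return _k2p_from_codes(codes[0], codes[1])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with masking of undefined entries.

    ``values[i, j]`` is nan wherever ``defined[i, j]`` is False;
    ``sites[i, j]`` is the number of columns compared for the pair.
    """

    labels: list[str]
    values: np.ndarray
    defined: np.ndarray
    sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def all_defined(self) -> bool:
        return bool(self.defined.all())

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = self.n
        for i in range(n):
            for j in range(i + 1, n):
                if not self.defined[i, j]:
                    out.append((self.labels[i], self.labels[j]))
        return out


def distance_matrix_from_encoded(
    codes: np.ndarray, labels: Sequence[str]
) -> DistanceMatrix:
    """Build a DistanceMatrix from pre-encoded sequences (see encode_sequences).

    Vectorized over all pairs via one-hot count matrices; per-pair
    transition/transversion counts are exact integers, so the result
    is bit-identical to applying :func:`k2p_distance` pair by pair.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two sequences")
    onehot = [(codes == b).astype(np.float64) for b in range(4)]
    valid = (codes < 4).astype(np.float64)
    sites_f = valid @ valid.T
    match = sum(x @ x.T for x in onehot)
    m_ag = onehot[0] @ onehot[2].T
    m_ct = onehot[1] @ onehot[3].T
    ts = m_ag + m_ag.T + m_ct + m_ct.T
    tv = sites_f - match - ts

    # integer numerators (exact in float64) for saturation detection
    num1 = sites_f - 2.0 * ts - tv
    num2 = sites_f - 2.0 * tv
    with np.errstate(divide="ignore", invalid="ignore"):
        values = -0.5 * np.log(num1 / sites_f) - 0.25 * np.log(num2 / sites_f)
    defined = (sites_f > 0) & (num1 > 0) & (num2 > 0)
    values = np.where(defined, values, np.nan)
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(defined, True)
    values[defined] = np.maximum(values[defined], 0.0)
    sites = sites_f.astype(np.int64)
    np.fill_diagonal(sites, codes.shape[1])
    return DistanceMatrix(list(labels), values, defined, sites)


def build_distance_matrix(alignment: MarkerAlignment) -> DistanceMatrix:
    """All-pairs K2P distances for one alignment (pairwise deletion)."""
    if len(alignment) < 2:
        raise ValueError("need at least two records to build a distance matrix")
    codes = encode_sequences([rec.residues for rec in alignment])
    return distance_matrix_from_encoded(codes, alignment.accession_ids)


def partition_distances(
    dm: DistanceMatrix, species_of: Mapping[str, str]
) -> tuple[list[float], list[float]]:
    """Split defined off-diagonal distances into intra-/inter-specific lists.

    Every defined unordered pair lands in exactly one list; masked pairs
    are in neither.
    """
    intra: list[float] = []
    inter: list[float] = []
    species = [species_of[label] for label in dm.labels]
    n = dm.n
    for i in range(n):
        for j in range(i + 1, n):
            if not dm.defined[i, j]:
                continue
            (intra if species[i] == species[j] else inter).append(
                float(dm.values[i, j])
            )
    return intra, inter


# ---------------------------------------------------------------------------
# Two-sample tests


class WilcoxonResult(NamedTuple):
    W: float  # rank sum of the first sample
    p: float
    exact: bool


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 12
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact p by full enumeration of rank assignments when
    ``len(x) + len(y) <= exact_limit``; tie-corrected normal
    approximation with continuity correction otherwise.  The statistic
    W is the rank sum of ``x`` in the pooled mid-rank ranking.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    total = n + m
    ranks = stats.rankdata(x + y)
    w_obs = float(ranks[:n].sum())
    mu = n * (total + 1) / 2.0

    if total <= exact_limit:
        dev = abs(w_obs - mu)
        count = 0
        n_assign = 0
        for combo in itertools.combinations(range(total), n):
            w = ranks[list(combo)].sum()
            n_assign += 1
            if abs(w - mu) >= dev - 1e-9:
                count += 1
        return WilcoxonResult(w_obs, count / n_assign, True)

    # tie-corrected normal approximation
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    sigma2 = n * m / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    if sigma2 <= 0:
        return WilcoxonResult(w_obs, 1.0, False)
    z = (w_obs - mu - math.copysign(0.5, w_obs - mu)) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(w_obs, max(p, math.ulp(0.0)), False)


class MedianTestResult(NamedTuple):
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: x,y; cols: >median, <median
    p: float
    method: str  # 'fisher', 'chi2', or 'degenerate'


def median_test(x: Sequence[float], y: Sequence[float]) -> MedianTestResult:
    """Mood's median test on the grand median.

    Values equal to the grand median are dropped.  Fisher's exact
    two-sided p is used when any expected cell count is below 5, the
    1-df chi-square statistic otherwise.  If no values remain on either
    side of the median the test is degenerate and p = 1.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    grand = float(np.median(x + y))
    ax = sum(1 for v in x if v > grand)
    bx = sum(1 for v in x if v < grand)
    ay = sum(1 for v in y if v > grand)
    by = sum(1 for v in y if v < grand)
    table = ((ax, bx), (ay, by))
    tab = np.array(table, dtype=float)
    total = tab.sum()
    if total == 0 or tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
        return MedianTestResult(table, 1.0, "degenerate")
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    if expected.min() < 5:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return MedianTestResult(table, float(p), "fisher")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return MedianTestResult(table, float(p), "chi2")


def format_pvalue(p: float | None, floor: float = PVALUE_FLOOR) -> str:
    """Render a p-value, flooring tiny values as '< 2.2e-16'."""
    if p is None:
        return "NA"
    if p < floor:
        return f"< {floor:g}"
    return f"{p:.4g}"


# ---------------------------------------------------------------------------
# Barcoding-gap summary


@dataclass
class GapSummary:
    """Distributional summary of intra- vs interspecific K2P distances."""

    n_inter: int
    n_intra: int
    mean_intra: float | None
    mean_inter: float
    range_intra: tuple[float, float] | None
    range_inter: tuple[float, float]
    median_p: float | None
    wilcoxon_W: float | None
    wilcoxon_p: float | None
    bin_width: float
    histogram_intra: np.ndarray
    histogram_inter: np.ndarray
    bin_edges: np.ndarray

    @property
    def tests_applicable(self) -> bool:
        return self.median_p is not None


def _histogram(values: Sequence[float], bin_width: float, n_bins: int) -> np.ndarray:
    # half-open bins [k*w, (k+1)*w)
    if not len(values):
        return np.zeros(n_bins, dtype=np.int64)
    idx = np.floor(np.asarray(values, dtype=float) / bin_width).astype(np.int64)
    return np.bincount(idx, minlength=n_bins).astype(np.int64)


def gap_summary(
    intra: Sequence[float], inter: Sequence[float], bin_width: float = 0.005
) -> GapSummary:
    """Summarise the barcoding gap between two distance pools.

    Runs both two-sample tests (intra vs inter) when the intraspecific
    pool is non-empty; otherwise the tests are marked not applicable.
    """
    inter = list(map(float, inter))
    intra = list(map(float, intra))
    if not inter:
        raise ValueError("interspecific pool must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = max(inter + intra)
    n_bins = int(math.floor(top / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width

    if intra:
        med = median_test(intra, inter)
        wil = wilcoxon_rank_sum(intra, inter)
        summary = GapSummary(
            n_inter=len(inter),
            n_intra=len(intra),
            mean_intra=float(np.mean(intra)),
            mean_inter=float(np.mean(inter)),
            range_intra=(min(intra), max(intra)),
            range_inter=(min(inter), max(inter)),
            median_p=med.p,
            wilcoxon_W=wil.W,
            wilcoxon_p=wil.p,
            bin_width=bin_width,
            histogram_intra=_histogram(intra, bin_width, n_bins),
            histogram_inter=_histogram(inter, bin_width, n_bins),
            bin_edges=edges,
        )
    else:
        summary = GapSummary(
            n_inter=len(inter),
            n_intra=0,
            mean_intra=None,
            mean_inter=float(np.mean(inter)),
            range_intra=None,
            range_inter=(min(inter), max(inter)),
            median_p=None,
            wilcoxon_W=None,
            wilcoxon_p=None,
            bin_width=bin_width,
            histogram_intra=_histogram([], bin_width, n_bins),
            histogram_inter=_histogram(inter, bin_width, n_bins),
            bin_edges=edges,
        )
    return summary
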