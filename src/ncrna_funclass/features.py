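"""Global-information encoders: k-mer statistics (KM), sequence-pattern class
propensities (SP), and instance-based alignment propensities (IB).

All three summarize a whole sequence into one fixed-size vector that is fed
to the dense branch of the hybrid network, complementing the position-local
view of the convolutional branch.  U is folded to T throughout; k-mer windows
and patterns containing any symbol outside {A, C, G, T} are excluded from
counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LabeledDataset

__all__ = [
    "KmerVector",
    "PatternPropensityTable",
    "AlignmentParams",
    "kmer_vector",
    "kmer_presence_prob",
    "count_occurr",
    "build_pattern_table",
    "pattern_propensity",
    "align_global",
    "instance_propensity",
    "KmerFrequencyEncoder",
    "PatternPropensityEncoder",
    "InstancePropensityEncoder",
]

# A < C < G < T lexicographic channel codes; the k-mer with code c is the
# base-4 representation of c over this alphabet.
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _BASE_CODE[ord(_c)] = _i
    _BASE_CODE[ord(_c.lower())] = _i
_BASE_CODE[ord("U")] = 3
_BASE_CODE[ord("u")] = 3

_U_TO_T = str.maketrans("Uu", "Tt")


def _codes(seq: str) -> np.ndarray:
    """Residues as integers 0-3 (A,C,G,T with U==T); -1 for other symbols."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Base-4 integer codes of every valid (all-ACGT) k-window, in order."""
    codes = _codes(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows[valid] @ powers


@dataclass(frozen=True)
class KmerVector:
    """Normalized k-mer spectrum: 4^k floats summing to 1 (or all zero)."""

    values: np.ndarray
    k: int


def kmer_vector(seq: str, k: int) -> KmerVector:
    """Overlapping k-mer frequency spectrum of a sequence.

    Every contiguous window whose residues are all in {A,C,G,T} (U folded to
    T) is counted; windows containing other symbols are skipped.  Counts are
    divided by their total, so the vector sums to 1 whenever at least one
    valid window exists, and is all-zero otherwise (e.g. k > len(seq)).
    """
    if not 1 <= k <= 8:
        raise ValueError("k must be in [1, 8]")
    if not seq:
        raise ValueError("sequence must be non-empty")
    idx = _window_codes(seq, k)
    counts = np.bincount(idx, minlength=4**k).astype(np.float64)
    total = counts.sum()
    if total > 0:
        counts /= total
    return KmerVector(values=counts, k=k)


def kmer_presence_prob(len_s: int, k: int) -> float:
    """Probability a fixed k-mer occurs in an i.i.d.-uniform sequence.

    ``1 - (1 - 4**-k) ** (len_s - k + 1)``, where ``len_s - k + 1`` is the
    number of contiguous overlapping windows.  Strictly within (0, 1) and
    monotone increasing in ``len_s``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len_s < k:
        raise ValueError(f"len_s ({len_s}) must be >= k ({k})")
    return 1.0 - (1.0 - 4.0 ** (-k)) ** (len_s - k + 1)


def count_occurr(p: str, s: str) -> int:
    """Number of (possibly overlapping) occurrences of pattern p within s."""
    if not p or len(p) > len(s):
        return 0
    count = 0
    start = s.find(p)
    while start != -1:
        count += 1
        start = s.find(p, start + 1)
    return count


@dataclass
class PatternPropensityTable:
    """Per-class propensities of length-L patterns seen in a training set.

    For each stored pattern p, ``counts[p]`` holds N(c,p) = the number of
    training sequences of class c containing p at least once; the propensity
    row is N(c,p)/N(p), which sums to 1.
    """

    L: int
    classes: list[str]
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def n_total(self, p: str) -> int:
        return int(self.counts[p].sum())

    def propensity(self, p: str) -> np.ndarray:
        c = self.counts[p]
        return c / c.sum()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pattern\tn_total\t" + "\t".join(self.classes) + "\n")
            for p in sorted(self.counts):
                c = self.counts[p]
                fh.write(f"{p}\t{int(c.sum())}\t" + "\t".join(str(int(x)) for x in c) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PatternPropensityTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            classes = header[2:]
            counts: dict[str, np.ndarray] = {}
            L = 0
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                counts[parts[0]] = np.array([int(x) for x in parts[2:]], dtype=np.int64)
                L = len(parts[0])
        return cls(L=L, classes=classes, counts=counts)


def _valid_window_strings(seq: str, L: int) -> list[str]:
    """All length-L windows of seq over {A,C,G,T} (U folded to T), in order."""
    t = seq.upper().translate(_U_TO_T)
    codes = _codes(t)
    n = len(t) - L + 1
    if n <= 0:
        return []
    bad = codes < 0
    # windows containing an invalid residue, via prefix sums of the bad mask
    csum = np.concatenate([[0], np.cumsum(bad)])
    ok = (csum[L:] - csum[:-L]) == 0
    return [t[i : i + L] for i in np.nonzero(ok)[0]]


def build_pattern_table(
    train: LabeledDataset, L: int, min_support: int = 2
) -> PatternPropensityTable:
    """Tabulate class propensities of every recurrent length-L pattern.

    A pattern enters the table when it occurs (as a substring, counted at
    sequence level) in at least ``min_support`` training sequences.  Longer
    support thresholds combat the sparsity of medium-length patterns.
    """
    if L < 2:
        raise ValueError("pattern length L must be >= 2")
    labels = train.labels()
    if any(lab is None for lab in labels):
        raise ValueError("training dataset must be fully labeled")
    classes = list(train.classes)
    class_idx = {c: i for i, c in enumerate(classes)}
    counts: dict[str, np.ndarray] = {}
    for rec in train.records:
        ci = class_idx[rec.label]  # type: ignore[index]
        for p in set(_valid_window_strings(rec.seq, L)):
            row = counts.get(p)
            if row is None:
                row = counts[p] = np.zeros(len(classes), dtype=np.int64)
            row[ci] += 1
    if min_support > 1:
        counts = {p: c for p, c in counts.items() if c.sum() >= min_support}
    if not counts:
        import warnings

        warnings.warn(
            f"no length-{L} pattern reaches min_support={min_support}; table is empty",
            stacklevel=2,
        )
    return PatternPropensityTable(L=L, classes=classes, counts=counts)


def pattern_propensity(seq: str, table: PatternPropensityTable) -> np.ndarray:
    """Occurrence-weighted mean of the propensity rows of matched patterns.

    Every window position of ``seq`` whose pattern is in the table
    contributes that pattern's row once, which realizes occurrence-count
    weighting.  If nothing matches (or the table is empty) the uniform
    vector 1/|C| is returned, the maximally non-informative propensity.
    """
    n_classes = len(table.classes)
    acc = np.zeros(n_classes, dtype=np.float64)
    matched = 0
    for w in _valid_window_strings(seq, table.L):
        row = table.counts.get(w)
        if row is not None:
            acc += row / row.sum()
            matched += 1
    if matched == 0:
        return np.full(n_classes, 1.0 / n_classes)
    return acc / matched


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for end-to-end global alignment: identity matrix, linear gaps."""

    match_score: float = 1.0
    mismatch_score: float = 0.0
    gap_penalty: float = -1.0

    def __post_init__(self) -> None:
        if self.match_score <= self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_penalty
    aligner.extend_gap_score = params.gap_penalty
    return aligner


def align_global(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Optimal Needleman-Wunsch global alignment score of two sequences.

    Default scoring: match 1, mismatch 0, linear gap -1.  U is folded to T
    before scoring so RNA and DNA spellings align identically.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    params = params or AlignmentParams()
    aligner = _make_aligner(params)
    return float(
        aligner.score(a.upper().translate(_U_TO_T), b.upper().translate(_U_TO_T))
    )


def _normalized_hit_propensity(
    scores: np.ndarray, class_indices: np.ndarray, n_classes: int, top_n: int
) -> np.ndarray:
    """Score-proportional class propensity from the top_n alignment hits."""
    order = np.argsort(-scores, kind="stable")[:top_n]
    weights = np.maximum(scores[order], 0.0)
    total = weights.sum()
    if total <= 0:
        return np.full(n_classes, 1.0 / n_classes)
    acc = np.zeros(n_classes)
    np.add.at(acc, class_indices[order], weights)
    return acc / total


def instance_propensity(
    seq: str,
    reference: LabeledDataset,
    params: AlignmentParams | None = None,
    top_n: int = 5,
    seed_k: int = 11,
    candidate_pool: int = 50,
    use_prefilter: bool = True,
) -> np.ndarray:
    """Class propensity transferred from the most similar training sequences.

    Candidate references are pre-filtered by the number of shared ``seed_k``-mers
    (a fast seed stage standing in for a heuristic database search), the best
    ``candidate_pool`` candidates are scored by exact global alignment, and the
    ``top_n`` hits vote for their classes with weight max(score, 0).  Set
    ``use_prefilter=False`` to align against every reference sequence.
    """
    enc = InstancePropensityEncoder(
        top_n=top_n,
        seed_k=seed_k,
        candidate_pool=candidate_pool,
        use_prefilter=use_prefilter,
        match_score=(params or AlignmentParams()).match_score,
        mismatch_score=(params or AlignmentParams()).mismatch_score,
        gap_penalty=(params or AlignmentParams()).gap_penalty,
    )
    labels = reference.labels()
    if len(reference) == 0:
        raise ValueError("reference dataset is empty")
    if any(lab is None for lab in labels):
        raise ValueError("reference dataset must be fully labeled")
    enc.fit(reference.sequences(), np.asarray(labels, dtype=object))
    return enc.transform([seq])[0]


class KmerFrequencyEncoder(TransformerMixin, BaseEstimator):
    """KM channel: normalized overlapping k-mer spectra, one row per sequence.

    Output dimension is 4**k (4096 at the default k=6).
    """

    def __init__(self, k: int = 6):
        self.k = k

    def fit(self, X: Sequence[str], y=None) -> "KmerFrequencyEncoder":
        self.n_features_out_ = 4**self.k
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        return np.stack([kmer_vector(s, self.k).values for s in X])


class PatternPropensityEncoder(TransformerMixin, BaseEstimator):
    """SP channel: class propensities from medium-length pattern occurrences.

    ``fit`` tabulates, over the training set, how often each length-L pattern
    occurs per class; ``transform`` averages the matched rows per query,
    weighted by occurrence count.
    """

    def __init__(self, L: int = 11, min_support: int = 2):
        self.L = L
        self.min_support = min_support

    def fit(self, X: Sequence[str], y: Sequence[str]) -> "PatternPropensityEncoder":
        y = np.asarray(y, dtype=object)
        self.classes_ = np.unique(y)
        ds = _as_dataset(X, y, self.classes_)
        self.table_ = build_pattern_table(ds, L=self.L, min_support=self.min_support)
        self.n_features_out_ = len(self.classes_)
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        return np.stack([pattern_propensity(s, self.table_) for s in X])


class InstancePropensityEncoder(TransformerMixin, BaseEstimator):
    """IB channel: class propensities from global-alignment nearest instances.

    Stores the training instances at ``fit``; at ``transform`` each query is
    seeded against them by shared ``seed_k``-mer counts, the top
    ``candidate_pool`` candidates are aligned exactly (match 1 / mismatch 0 /
    gap -1 by default) and the best ``top_n`` scores vote, score-weighted,
    for their classes.  ``transform_loo`` re-encodes the fitted instances
    themselves with the self-hit excluded, which keeps the channel free of
    label leakage when used on the training split.
    """

    def __init__(
        self,
        top_n: int = 5,
        seed_k: int = 11,
        candidate_pool: int = 50,
        use_prefilter: bool = True,
        match_score: float = 1.0,
        mismatch_score: float = 0.0,
        gap_penalty: float = -1.0,
    ):
        self.top_n = top_n
        self.seed_k = seed_k
        self.candidate_pool = candidate_pool
        self.use_prefilter = use_prefilter
        self.match_score = match_score
        self.mismatch_score = mismatch_score
        self.gap_penalty = gap_penalty

    def _params(self) -> AlignmentParams:
        return AlignmentParams(self.match_score, self.mismatch_score, self.gap_penalty)

    def fit(self, X: Sequence[str], y: Sequence[str]) -> "InstancePropensityEncoder":
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        y = np.asarray(y, dtype=object)
        if len(X) == 0:
            raise ValueError("reference dataset is empty")
        self.classes_ = np.unique(y)
        class_idx = {c: i for i, c in enumerate(self.classes_)}
        self.ref_seqs_ = [s.upper().translate(_U_TO_T) for s in X]
        self.ref_class_idx_ = np.array([class_idx[lab] for lab in y], dtype=np.int64)
        self.ref_kmer_sets_ = [
            frozenset(_window_codes(s, self.seed_k).tolist()) for s in self.ref_seqs_
        ]
        self.n_features_out_ = len(self.classes_)
        return self

    def _encode_one(self, seq: str, exclude: int | None = None) -> np.ndarray:
        aligner = _make_aligner(self._params())
        n_ref = len(self.ref_seqs_)
        candidates = np.arange(n_ref)
        if exclude is not None:
            candidates = candidates[candidates != exclude]
        if self.use_prefilter and len(candidates) > self.candidate_pool:
            qset = frozenset(_window_codes(seq, self.seed_k).tolist())
            shared = np.array(
                [len(qset & self.ref_kmer_sets_[i]) for i in candidates], dtype=np.int64
            )
            keep = np.argsort(-shared, kind="stable")[: self.candidate_pool]
            candidates = candidates[keep]
        scores = np.array(
            [aligner.score(seq, self.ref_seqs_[i]) for i in candidates], dtype=np.float64
        )
        return _normalized_hit_propensity(
            scores, self.ref_class_idx_[candidates], len(self.classes_), self.top_n
        )

    def transform(self, X: Sequence[str]) -> np.ndarray:
        queries = [s.upper().translate(_U_TO_T) for s in X]
        return np.stack([self._encode_one(q) for q in queries])

    def transform_loo(self) -> np.ndarray:
        """Encode the fitted reference sequences, excluding each self-hit."""
        return np.stack(
            [self._encode_one(s, exclude=i) for i, s in enumerate(self.ref_seqs_)]
        )


def _as_dataset(X: Sequence[str], y: np.ndarray, classes: np.ndarray) -> LabeledDataset:
    from .io import SequenceRecord

    records = [
        SequenceRecord(id=f"q{i}", seq=s, label=str(lab)) for i, (s, lab) in enumerate(zip(X, y))
    ]
    return LabeledDataset(records=records, classes=[str(c) for c in classes])
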