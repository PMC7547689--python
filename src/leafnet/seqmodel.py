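"""Bag-of-k-mers discriminative sequence models.

Sequences are tokenized into canonical (strand-collapsed) k-mers, weighted
by TF-IDF, and classified with L2-regularized logistic regression under
5-fold cross-validation; the reported model averages the fold coefficients.
Per-base importance comes from occlusion (mask one base with N) and
saturation mutagenesis (substitute each alternative base). Models are
compared across TFs by Spearman distance of their weight vectors, and top
k-mers are matched against PWMs with an exact log-odds null distribution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .types import GenomeBundle, GenomicInterval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASE_ORDER = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def tokenize(sequence: str, k: int = 7) -> Counter:
    """Counts of canonical k-mers over all windows; windows with N skipped."""
    sequence = sequence.upper()
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} shorter than k={k}")
    counts: Counter = Counter()
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        if "N" in window:
            continue
        counts[canonical_kmer(window)] += 1
    return counts


def gc_content(seq: str) -> float:
    seq = seq.upper()
    n = sum(1 for b in seq if b != "N")
    if n == 0:
        return 0.0
    return sum(1 for b in seq if b in "GC") / n


def extract_training_set(
    loci: list[GenomicInterval],
    genome: GenomeBundle,
    gc_tolerance: float = 0.02,
    seed: int = 0,
    max_retries: int = 500,
) -> tuple[list[str], np.ndarray]:
    """Positive locus sequences plus GC-matched non-overlapping controls.

    One control per positive: a random genomic interval of identical length
    whose GC is within ``gc_tolerance`` of its matched positive and which
    overlaps none of the input loci. Returns (sequences, labels).
    """
    rng = np.random.default_rng(seed)
    sizes = genome.chrom_sizes
    chroms = sorted(sizes)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for iv in loci:
        occupied[iv.chrom].append((iv.start, iv.end))
    for c in occupied:
        occupied[c].sort()

    def overlaps_locus(chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in occupied[chrom])

    sequences: list[str] = []
    labels: list[int] = []
    for iv in loci:
        pos_seq = genome.fetch(iv)
        sequences.append(pos_seq)
        labels.append(1)
        target_gc = gc_content(pos_seq)
        length = len(iv)
        for attempt in range(max_retries):
            chrom = chroms[rng.integers(len(chroms))]
            if sizes[chrom] <= length:
                continue
            start = int(rng.integers(0, sizes[chrom] - length))
            if overlaps_locus(chrom, start, start + length):
                continue
            ctrl = genome.sequences[chrom][start : start + length]
            if abs(gc_content(ctrl) - target_gc) <= gc_tolerance:
                sequences.append(ctrl)
                labels.append(0)
                break
        else:
            raise ValueError(
                f"no GC-matched control found for locus {iv.chrom}:{iv.start}-{iv.end}"
            )
    return sequences, np.array(labels)


def build_count_matrix(
    documents: list[Counter], vocabulary: dict[str, int] | None = None
) -> tuple[sparse.csr_matrix, dict[str, int]]:
    """Documents x k-mers sparse count matrix with a shared vocabulary."""
    if vocabulary is None:
        vocab_terms = sorted({t for doc in documents for t in doc})
        vocabulary = {t: i for i, t in enumerate(vocab_terms)}
    rows, cols, vals = [], [], []
    for d, doc in enumerate(documents):
        for term, count in doc.items():
            j = vocabulary.get(term)
            if j is not None:
                rows.append(d)
                cols.append(j)
                vals.append(count)
    X = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(documents), len(vocabulary)), dtype=float
    )
    return X, vocabulary


def tfidf_transform(
    counts: sparse.csr_matrix,
    df: np.ndarray | None = None,
    n_docs: int | None = None,
) -> tuple[sparse.csr_matrix, np.ndarray, int]:
    """weight(d, t) = count(d, t) * ln(N / df(t)); rows L2-normalized.

    ``df``/``n_docs`` fix the collection statistics when transforming new
    documents with a trained model's vocabulary.
    """
    if counts.shape[0] < 2 and df is None:
        raise ValueError("need at least 2 documents to define collection frequency")
    if df is None:
        df = np.asarray((counts > 0).sum(axis=0)).ravel()
        n_docs = counts.shape[0]
    assert n_docs is not None
    idf = np.zeros(df.size)
    present = df > 0
    idf[present] = np.log(n_docs / df[present])
    X = counts.multiply(idf[np.newaxis, :]).tocsr()
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    norms[norms == 0] = 1.0
    X = sparse.diags(1.0 / norms) @ X
    return X.tocsr(), df, n_docs


@dataclass
class SequenceModel:
    """Averaged k-mer logistic model plus the collection statistics needed
    to embed new sequences."""

    tf: str
    k: int
    vocabulary: dict[str, int]
    weights: np.ndarray
    intercept: float
    cv_accuracy: float
    cv_auroc: float
    df: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    n_docs: int = 0

    def top_kmers(self, top_percent: float = 1.0) -> list[str]:
        n_top = max(1, int(np.ceil(len(self.vocabulary) * top_percent / 100.0)))
        inv = {i: t for t, i in self.vocabulary.items()}
        order = np.argsort(self.weights)[::-1][:n_top]
        return [inv[i] for i in order]


def train_kmer_model(
    sequences: list[str],
    labels: np.ndarray,
    tf: str = "",
    k: int = 7,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> SequenceModel:
    """Fit per-fold L2 logistic models; report fold-averaged coefficients."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    docs = [tokenize(s, k) for s in sequences]
    counts, vocabulary = build_count_matrix(docs)
    X, df, n_docs = tfidf_transform(counts)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    coefs, intercepts, accs, aucs = [], [], [], []
    for train_idx, test_idx in skf.split(X, labels):
        clf = LogisticRegression(C=C, max_iter=2000)  # L2 penalty
        clf.fit(X[train_idx], labels[train_idx])
        proba = clf.predict_proba(X[test_idx])[:, 1]
        accs.append(float(np.mean((proba >= 0.5) == (labels[test_idx] == 1))))
        aucs.append(float(roc_auc_score(labels[test_idx], proba)))
        coefs.append(clf.coef_.ravel())
        intercepts.append(float(clf.intercept_[0]))
    return SequenceModel(
        tf=tf,
        k=k,
        vocabulary=vocabulary,
        weights=np.mean(coefs, axis=0),
        intercept=float(np.mean(intercepts)),
        cv_accuracy=float(np.mean(accs)),
        cv_auroc=float(np.mean(aucs)),
        df=df,
        n_docs=n_docs,
    )


def _embed(model: SequenceModel, sequence: str) -> np.ndarray:
    """TF-IDF vector of one sequence under the model's collection statistics.

    Tokens outside the training vocabulary are ignored.
    """
    vec = np.zeros(len(model.vocabulary))
    for term, count in tokenize(sequence, model.k).items():
        j = model.vocabulary.get(term)
        if j is not None and model.df[j] > 0:
            vec[j] = count * np.log(model.n_docs / model.df[j])
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


def score_sequence(model: SequenceModel, sequence: str) -> float:
    """Probability of label 1 (binding) for a sequence."""
    x = _embed(model, sequence)
    logit = float(model.weights @ x + model.intercept)
    return float(1.0 / (1.0 + np.exp(-logit)))


@dataclass
class ImportanceTrack:
    sequence_id: str
    occlusion: np.ndarray
    mutagenesis: np.ndarray | None = None  # positions x 3 (alternative bases)
    mutagenesis_bases: list[list[str]] | None = None


def occlusion_map(model: SequenceModel, sequence: str,
                  sequence_id: str = "") -> ImportanceTrack:
    """score(i) = P(original) - P(sequence with position i masked to N)."""
    sequence = sequence.upper()
    if len(sequence) < model.k:
        raise ValueError("sequence shorter than k")
    base = score_sequence(model, sequence)
    scores = np.empty(len(sequence))
    for i in range(len(sequence)):
        masked = sequence[:i] + "N" + sequence[i + 1 :]
        scores[i] = base - score_sequence(model, masked)
    return ImportanceTrack(sequence_id=sequence_id, occlusion=scores)


def mutagenesis_map(model: SequenceModel, sequence: str,
                    sequence_id: str = "") -> ImportanceTrack:
    """score(i, b) = P(original) - P(position i substituted by base b)."""
    sequence = sequence.upper()
    if len(sequence) < model.k:
        raise ValueError("sequence shorter than k")
    base = score_sequence(model, sequence)
    n = len(sequence)
    scores = np.empty((n, 3))
    alt_bases: list[list[str]] = []
    for i in range(n):
        ref = sequence[i]
        # 3 alternative bases; an N reference yields 4 candidates, keep 3
        alts = [b for b in BASE_ORDER if b != ref][:3]
        alt_bases.append(alts)
        for j, b in enumerate(alts):
            mutated = sequence[:i] + b + sequence[i + 1 :]
            scores[i, j] = base - score_sequence(model, mutated)
    return ImportanceTrack(
        sequence_id=sequence_id,
        occlusion=np.empty(0),
        mutagenesis=scores,
        mutagenesis_bases=alt_bases,
    )


def tf_similarity_clustering(
    models: list[SequenceModel],
) -> tuple[np.ndarray, dict[str, int]]:
    """Ward dendrogram on 1 - Spearman distance plus a dynamic gap cut.

    Returns the scipy linkage matrix and a TF -> cluster-label map. The cut
    height is placed at the largest gap between consecutive merge heights
    (a simplified dynamic tree cut).
    """
    if len(models) < 3:
        raise ValueError("need at least 3 models")
    vocab = models[0].vocabulary
    for m in models[1:]:
        if m.vocabulary != vocab:
            raise ValueError("models must share a vocabulary")
    W = np.vstack([m.weights for m in models])
    rho = spearmanr(W, axis=1).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = hierarchy.ward(squareform(dist, checks=False))
    heights = Z[:, 2]
    if len(heights) >= 2:
        gaps = np.diff(heights)
        cut = float((heights[np.argmax(gaps)] + heights[np.argmax(gaps) + 1]) / 2)
    else:
        cut = float(heights[-1] / 2)
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    return Z, {m.tf: int(lbl) for m, lbl in zip(models, labels)}


@dataclass
class PWM:
    """Position weight matrix: 4 x width base probabilities (rows = ACGT)."""

    matrix: np.ndarray
    name: str
    family: str = "unknown"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x width")
        colsums = self.matrix.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def _log_odds(pwm: PWM, pseudocount: float = 1e-3) -> np.ndarray:
    m = pwm.matrix + pseudocount
    m = m / m.sum(axis=0, keepdims=True)
    return np.log2(m / 0.25)


_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


def _best_alignment(
    kmer: str, lo: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Best ungapped log-odds score of kmer against the matrix (both strands).

    Returns (score, aligned base indices, matrix column indices).
    """
    width = lo.shape[1]
    k = len(kmer)
    best_score = -np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    for candidate in (kmer, reverse_complement(kmer)):
        idx = np.array([_BASE_INDEX[b] for b in candidate])
        if width >= k:
            for off in range(width - k + 1):
                cols = np.arange(off, off + k)
                score = float(lo[idx, cols].sum())
                if score > best_score:
                    best_score, best = score, (idx, cols)
        else:
            for off in range(k - width + 1):
                cols = np.arange(width)
                sub = idx[off : off + width]
                score = float(lo[sub, cols].sum())
                if score > best_score:
                    best_score, best = score, (sub, cols)
    assert best is not None
    return best_score, best[0], best[1]


def _exact_pvalue(
    lo_cols: np.ndarray, observed_idx: np.ndarray, grid: float = 1e-3
) -> float:
    """P(aligned score of a uniform random word >= the observed word's score).

    Exact dynamic programming over columns on a discretized score grid; the
    observed score is discretized the same way, so the comparison is exact
    on the grid (the observed word itself is always counted).
    """
    keys = np.round(lo_cols / grid).astype(np.int64)  # 4 x ncols
    obs_key = int(keys[observed_idx, np.arange(keys.shape[1])].sum())
    dist: dict[int, float] = {0: 1.0}
    for j in range(keys.shape[1]):
        nxt: dict[int, float] = {}
        for s, p in dist.items():
            for v in keys[:, j]:
                key = s + int(v)
                nxt[key] = nxt.get(key, 0.0) + p * 0.25
        dist = nxt
    return float(sum(p for s, p in dist.items() if s >= obs_key))


@dataclass
class PWMMatch:
    kmer: str
    pwm: str
    family: str
    score_bits: float
    p: float


def match_kmers_to_pwms(
    model: SequenceModel,
    pwms: list[PWM],
    top_percent: float = 1.0,
    min_bits: float = 13.28,
    max_p: float = 1e-4,
) -> tuple[str | None, list[PWMMatch]]:
    """Match the model's top k-mers against a PWM collection.

    A hit requires best ungapped log2-odds score > ``min_bits`` and exact
    null p < ``max_p``. The reported family is the one collecting most hits
    (``None`` if there are no hits).
    """
    if not pwms:
        raise ValueError("empty PWM collection")
    hits: list[PWMMatch] = []
    for kmer in model.top_kmers(top_percent):
        for pwm in pwms:
            lo = _log_odds(pwm)
            score, idx, cols = _best_alignment(kmer, lo)
            if score <= min_bits:
                continue
            p = _exact_pvalue(lo[:, cols], idx)
            if p < max_p:
                hits.append(
                    PWMMatch(kmer=kmer, pwm=pwm.name, family=pwm.family,
                             score_bits=score, p=p)
                )
    if not hits:
        return None, []
    families = Counter(h.family for h in hits)
    return families.most_common(1)[0][0], hits
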