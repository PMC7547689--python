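"""TF co-localization modelling.

For a focus TF, each of its peaks becomes a row and each partner TF a
column holding the normalized signal rank of the partner peak whose summit
falls inside the focus peak (0 when none). Column-permuted copies serve as
negatives for a rule-ensemble classifier (gradient-boosted shallow trees ->
extracted threshold rules -> L1 logistic), from which relative importance
(RI, 0-100 per partner) and proximal-vs-distal differential importance (DI)
are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .peaks import distance_to_gene
from .types import GeneModel, Locus, PeakSet


def normalized_ranks(peakset: PeakSet) -> np.ndarray:
    """(R - r) / (R - 1) per peak; strongest signal -> 1, weakest -> 0.

    Ties receive the average rank. A single peak gets 1.
    """
    R = len(peakset.peaks)
    if R == 0:
        raise ValueError("empty peak set")
    if R == 1:
        return np.array([1.0])
    signals = np.array([p.signal for p in peakset.peaks])
    rank_desc = stats.rankdata(-signals, method="average")  # strongest -> 1
    return (R - rank_desc) / (R - 1)


@dataclass
class ColocMatrix:
    focus: str
    partners: list[str]
    matrix: np.ndarray  # focus peaks x partners, values in [0, 1]
    row_class: list[str]  # 'proximal' | 'distal' per focus peak

    def __post_init__(self) -> None:
        if self.matrix.size and (
            self.matrix.min() < 0 or self.matrix.max() > 1
        ):
            raise ValueError("co-localization values must lie in [0, 1]")

    def subset(self, row_label: str) -> "ColocMatrix":
        keep = [i for i, lbl in enumerate(self.row_class) if lbl == row_label]
        return ColocMatrix(
            focus=self.focus,
            partners=self.partners,
            matrix=self.matrix[keep],
            row_class=[row_label] * len(keep),
        )


def build_coloc_matrix(
    focus: PeakSet,
    partners: list[PeakSet],
    genes: list[GeneModel],
    proximal_cutoff: int = 2000,
) -> ColocMatrix:
    """Overlap partner summits with focus peaks into a normalized-rank matrix.

    Cell (i, p) is the normalized rank of the partner-p peak whose summit
    lies inside focus peak i; 0 when none, the maximum when several. Rows
    are annotated proximal/distal at ``proximal_cutoff`` from the nearest
    gene (genic counts as proximal).
    """
    if not focus.peaks:
        raise ValueError("empty focus peak set")
    if any(ps.tf == focus.tf for ps in partners):
        raise ValueError("focus TF must not appear among partners")
    n = len(focus.peaks)
    matrix = np.zeros((n, len(partners)))
    for j, partner in enumerate(partners):
        if not partner.peaks:
            continue
        ranks = normalized_ranks(partner)
        by_chrom: dict[str, list[tuple[int, float]]] = {}
        for p, r in zip(partner.peaks, ranks):
            by_chrom.setdefault(p.chrom, []).append((p.summit, r))
        for c in by_chrom:
            by_chrom[c].sort()
        for i, fp in enumerate(focus.peaks):
            entries = by_chrom.get(fp.chrom)
            if not entries:
                continue
            positions = [s for s, _ in entries]
            lo = np.searchsorted(positions, fp.start, side="left")
            hi = np.searchsorted(positions, fp.end - 1, side="right")
            if hi > lo:
                matrix[i, j] = max(r for _, r in entries[lo:hi])
    loci = [Locus(interval=p.interval, member_tfs=frozenset({focus.tf}))
            for p in focus.peaks]
    dists = distance_to_gene(loci, genes, proximal_cutoff)
    row_class = [
        "proximal" if d.label in ("proximal", "genic") else "distal" for d in dists
    ]
    return ColocMatrix(
        focus=focus.tf, partners=[ps.tf for ps in partners],
        matrix=matrix, row_class=row_class,
    )


def randomize_matrix(
    matrix: ColocMatrix, n: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Independent per-column permutations: marginals kept, joint structure lost."""
    if matrix.matrix.size == 0:
        raise ValueError("empty co-localization matrix")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        X = matrix.matrix.copy()
        for j in range(X.shape[1]):
            rng.shuffle(X[:, j])
        out.append(X)
    return out


@dataclass
class Rule:
    """Conjunction of interval conditions over partner columns."""

    conditions: list[tuple[str, str, float]]  # (partner, '>' | '<=', threshold)
    coefficient: float = 0.0
    support: float = 0.0

    @property
    def variables(self) -> list[str]:
        return sorted({name for name, _, _ in self.conditions})

    def evaluate(self, X: np.ndarray, partners: list[str]) -> np.ndarray:
        mask = np.ones(X.shape[0], dtype=bool)
        col = {p: i for i, p in enumerate(partners)}
        for name, op, thr in self.conditions:
            if op == ">":
                mask &= X[:, col[name]] > thr
            else:
                mask &= X[:, col[name]] <= thr
        return mask

    def render(self) -> str:
        # collapse to one interval per variable, in the (lo < TF <= hi) form
        bounds: dict[str, list[float]] = {}
        for name, op, thr in self.conditions:
            lo, hi = bounds.setdefault(name, [0.0, 1.0])
            if op == ">":
                bounds[name][0] = max(lo, thr)
            else:
                bounds[name][1] = min(hi, thr)
        parts = [
            f"({lo:.2g} < {name} <= {hi:.2g})" for name, (lo, hi) in sorted(bounds.items())
        ]
        return " AND ".join(parts)


@dataclass
class RuleEnsemble:
    focus: str
    partners: list[str]
    rules: list[Rule]
    linear_coef: np.ndarray  # per partner (winsorized linear terms)
    linear_scale: np.ndarray  # std of the winsorized columns
    intercept: float = 0.0
    auroc: float = float("nan")
    auroc_per_randomization: list[float] = field(default_factory=list)


def _extract_rules(
    gbc: GradientBoostingClassifier, partners: list[str]
) -> list[Rule]:
    """Every root-to-node path of every tree becomes a candidate rule."""
    rules: list[Rule] = []
    seen: set[tuple] = set()
    for est in gbc.estimators_.ravel():
        tree = est.tree_

        def walk(node: int, conds: list[tuple[str, str, float]]) -> None:
            if conds:
                key = tuple(sorted(conds))
                if key not in seen:
                    seen.add(key)
                    rules.append(Rule(conditions=list(conds)))
            if tree.children_left[node] == -1:
                return
            name = partners[tree.feature[node]]
            thr = float(tree.threshold[node])
            walk(tree.children_left[node], conds + [(name, "<=", thr)])
            walk(tree.children_right[node], conds + [(name, ">", thr)])

        walk(0, [])
    return rules


def _winsorize(X: np.ndarray, lo_q: float = 0.05, hi_q: float = 0.95) -> np.ndarray:
    lo = np.quantile(X, lo_q, axis=0)
    hi = np.quantile(X, hi_q, axis=0)
    return np.clip(X, lo, hi)


def learn_rules(
    true_matrix: ColocMatrix,
    randomized_matrices: list[np.ndarray],
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: int = 3,
    l1_C: float = 1.0,
) -> RuleEnsemble:
    """Rule-ensemble discrimination of true vs column-permuted rows.

    Per randomization, a held-out third of rows yields an AUROC; the
    reported ensemble is refit on the pooled true-vs-all-randomized data and
    carries the averaged AUROC.
    """
    if len(true_matrix.partners) < 2:
        raise ValueError("need >= 2 partner columns to learn combinatorial rules")
    partners = true_matrix.partners
    rng = np.random.default_rng(seed)

    def fit_once(X_true: np.ndarray, X_rand: np.ndarray, rseed: int):
        X = np.vstack([X_true, X_rand])
        y = np.concatenate([np.ones(len(X_true)), np.zeros(len(X_rand))])
        idx = np.random.default_rng(rseed).permutation(len(X))
        n_test = len(X) // 3
        test, train = idx[:n_test], idx[n_test:]
        gbc = GradientBoostingClassifier(
            n_estimators=n_estimators, max_depth=max_depth, random_state=rseed
        )
        gbc.fit(X[train], y[train])
        rules = _extract_rules(gbc, partners)
        R_train = np.column_stack(
            [r.evaluate(X[train], partners).astype(float) for r in rules]
        ) if rules else np.empty((len(train), 0))
        L_train = _winsorize(X[train])
        F_train = np.hstack([R_train, L_train])
        clf = LogisticRegression(  # L1 penalty
            l1_ratio=1, solver="liblinear", C=l1_C, max_iter=2000,
            random_state=rseed,
        )
        clf.fit(F_train, y[train])
        R_test = np.column_stack(
            [r.evaluate(X[test], partners).astype(float) for r in rules]
        ) if rules else np.empty((len(test), 0))
        F_test = np.hstack([R_test, _winsorize(X[test])])
        proba = clf.predict_proba(F_test)[:, 1]
        auc = float(roc_auc_score(y[test], proba))
        return rules, clf, auc, X, y

    aurocs = []
    for X_rand in randomized_matrices:
        _, _, auc, _, _ = fit_once(
            true_matrix.matrix, X_rand, int(rng.integers(2**31))
        )
        aurocs.append(auc)

    X_all_rand = np.vstack(randomized_matrices)
    rules, clf, _, X_pool, y_pool = fit_once(
        true_matrix.matrix, X_all_rand, int(rng.integers(2**31))
    )
    coefs = clf.coef_.ravel()
    n_rules = len(rules)
    for r, c in zip(rules, coefs[:n_rules]):
        r.coefficient = float(c)
        r.support = float(np.mean(r.evaluate(X_pool, partners)))
    W = _winsorize(X_pool)
    return RuleEnsemble(
        focus=true_matrix.focus,
        partners=partners,
        rules=[r for r in rules if r.coefficient != 0.0],
        linear_coef=coefs[n_rules:],
        linear_scale=W.std(axis=0),
        intercept=float(clf.intercept_[0]),
        auroc=float(np.mean(aurocs)),
        auroc_per_randomization=aurocs,
    )


def relative_importance(ensemble: RuleEnsemble) -> dict[str, float]:
    """Partner RI on a 0-100 scale.

    Rule importance is |coef| * sqrt(support * (1 - support)), shared
    equally among the rule's variables; a linear term adds
    |coef| * std(winsorized column). The maximum partner is scaled to 100.
    """
    raw = {p: 0.0 for p in ensemble.partners}
    for rule in ensemble.rules:
        if not 0.0 < rule.support < 1.0:
            continue
        imp = abs(rule.coefficient) * np.sqrt(rule.support * (1 - rule.support))
        for var in rule.variables:
            raw[var] += imp / len(rule.variables)
    for p, c, s in zip(ensemble.partners, ensemble.linear_coef, ensemble.linear_scale):
        raw[p] += abs(c) * s
    top = max(raw.values())
    if top == 0:
        return {p: 0.0 for p in ensemble.partners}
    return {p: 100.0 * v / top for p, v in raw.items()}


def context_importance(
    matrix: ColocMatrix,
    n_randomizations: int = 10,
    seed: int = 0,
    **learn_kwargs,
) -> tuple[RuleEnsemble, dict[str, float]]:
    """Randomize, learn rules and score RI for one focus-TF context."""
    randomized = randomize_matrix(matrix, n=n_randomizations, seed=seed)
    ensemble = learn_rules(matrix, randomized, seed=seed, **learn_kwargs)
    return ensemble, relative_importance(ensemble)


MIN_SUBSET_ROWS = 30


def differential_importance(
    matrix: ColocMatrix,
    n_randomizations: int = 10,
    seed: int = 0,
    **learn_kwargs,
) -> dict[str, float] | None:
    """DI per partner: RI on proximal rows minus RI on distal rows.

    Returns None (with a warning) when either subset has < 30 rows.
    """
    prox = matrix.subset("proximal")
    dist = matrix.subset("distal")
    if len(prox.matrix) < MIN_SUBSET_ROWS or len(dist.matrix) < MIN_SUBSET_ROWS:
        warnings.warn(
            f"context {matrix.focus}: proximal/distal subset below "
            f"{MIN_SUBSET_ROWS} rows; skipped"
        )
        return None
    _, ri_prox = context_importance(
        prox, n_randomizations=n_randomizations, seed=seed, **learn_kwargs
    )
    _, ri_dist = context_importance(
        dist, n_randomizations=n_randomizations, seed=seed + 1, **learn_kwargs
    )
    return {p: ri_prox[p] - ri_dist[p] for p in matrix.partners}


def average_importance(per_context: dict[str, dict[str, float]]) -> dict[str, float]:
    """Average RI (or DI) of each partner across contexts; absent -> 0."""
    partners = sorted({p for scores in per_context.values() for p in scores})
    return {
        p: float(np.mean([scores.get(p, 0.0) for scores in per_context.values()]))
        for p in partners
    }


def cluster_ri_matrix(
    ri: np.ndarray, row_names: list[str], col_names: list[str]
) -> dict:
    """Independent Ward/Euclidean clusterings of contexts and partners."""
    if ri.shape[0] < 3 or ri.shape[1] < 3:
        raise ValueError("need >= 3 rows and columns")
    row_Z = hierarchy.ward(ri)
    col_Z = hierarchy.ward(ri.T)
    row_order = hierarchy.leaves_list(row_Z)
    col_order = hierarchy.leaves_list(col_Z)

    def gap_cut(Z: np.ndarray) -> np.ndarray:
        heights = Z[:, 2]
        if heights.size >= 2:
            gaps = np.diff(heights)
            i = int(np.argmax(gaps))
            t = float((heights[i] + heights[i + 1]) / 2)
        else:
            t = float(heights[-1] / 2)
        return hierarchy.fcluster(Z, t=t, criterion="distance")

    return {
        "row_linkage": row_Z,
        "col_linkage": col_Z,
        "row_order": [row_names[i] for i in row_order],
        "col_order": [col_names[i] for i in col_order],
        "row_clusters": dict(zip(row_names, map(int, gap_cut(row_Z)))),
        "col_clusters": dict(zip(col_names, map(int, gap_cut(col_Z)))),
    }
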