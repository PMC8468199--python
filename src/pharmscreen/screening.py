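"""Ligand-to-hypothesis mapping, library screening, and hypothesis validation.

Mapping places a ligand's perceived features onto a hypothesis by solving a
kind-respecting correspondence problem (clique search on a distance-
compatibility graph), superposing the matched centroids, and scoring the
placement with a sphere-penalty fit value

    fit = sum_i max(0, 1 - (d_i / t_i)^2)

where ``d_i`` is the residual deviation of matched feature i after rigid
superposition and ``t_i`` its tolerance radius.  Validation covers ROC
analysis and the Güner–Henry decoy-set statistics, with the composite
goodness-of-fit score

    GF = [Ha (3A + Ht) / (4 Ht A)] * [1 - (Ht - Ha) / (D - A)]

reported both at full precision and truncated (floor) to two decimals, the
convention used when such tables are printed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .chem import FeatureKind, Hypothesis, PharmacophoreFeature
from .geometry import SuperpositionResult, kabsch

__all__ = [
    "Compound", "MappingResult", "ScreenRecord", "DecoyEvaluation", "RocResult",
    "map_conformer", "screen_library", "gh_statistics", "evaluate_decoy_set",
    "roc_curve", "truncate2", "fit_value",
]


def truncate2(x: float) -> float:
    """Truncate toward zero to two decimals (floor of |x|), guarding the
    binary representation of values that are exact hundredths."""
    return math.trunc(x * 100 + math.copysign(1e-9, x)) / 100


@dataclass
class Compound:
    """A library entry: one or more conformers, each a list of features."""

    id: str
    conformers: list[list[PharmacophoreFeature]]
    active: Optional[bool] = None
    molecule: object = None

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("compound must carry at least one conformer")


@dataclass
class MappingResult:
    """Best correspondence of a ligand conformer onto a hypothesis."""

    pairs: list[tuple[int, int]]  # (hypothesis feature idx, ligand feature idx)
    omitted_count: int
    deviations: np.ndarray  # per matched pair, Å, after superposition
    fit: float
    transform: SuperpositionResult


@dataclass
class ScreenRecord:
    compound_id: str
    best_fit: Optional[float]
    hypothesis_id: str
    passed: bool


def _correspondence_graph(
    h_feats: Sequence[PharmacophoreFeature],
    l_feats: Sequence[PharmacophoreFeature],
    tolerance: float,
) -> nx.Graph:
    """Nodes are same-kind (hypothesis, ligand) feature pairs; edges connect
    pairs whose interfeature distances agree within ``tolerance``."""
    hc = np.array([f.xyz for f in h_feats])
    lc = np.array([f.xyz for f in l_feats])
    nodes = [
        (i, j)
        for i, hf in enumerate(h_feats)
        for j, lf in enumerate(l_feats)
        if hf.kind is lf.kind
    ]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a in range(len(nodes)):
        i1, j1 = nodes[a]
        for b in range(a + 1, len(nodes)):
            i2, j2 = nodes[b]
            if i1 == i2 or j1 == j2:
                continue
            dh = np.linalg.norm(hc[i1] - hc[i2])
            dl = np.linalg.norm(lc[j1] - lc[j2])
            if abs(dh - dl) <= tolerance:
                g.add_edge(nodes[a], nodes[b])
    return g


def fit_value(deviations, tolerances) -> float:
    """Sphere-penalty fit: sum_i max(0, 1 - (d_i/t_i)^2).

    Each matched feature contributes 1 at zero deviation, 0 at or beyond its
    tolerance radius; an exact self-map therefore scores max_fit.
    """
    total = 0.0
    for d, t in zip(deviations, tolerances, strict=True):
        total += max(0.0, 1.0 - (d / t) ** 2)
    return total


def _score_correspondence(
    h_feats: Sequence[PharmacophoreFeature],
    l_feats: Sequence[PharmacophoreFeature],
    pairs: Sequence[tuple[int, int]],
) -> tuple[float, np.ndarray, SuperpositionResult]:
    H = np.array([h_feats[i].xyz for i, _ in pairs])
    L = np.array([l_feats[j].xyz for _, j in pairs])
    sup = kabsch(L, H)
    moved = sup.apply(L)
    devs = np.linalg.norm(moved - H, axis=1)
    fit = fit_value(devs, [h_feats[i].tolerance for i, _ in pairs])
    return fit, devs, sup


def map_conformer(
    h: Hypothesis,
    ligand_features: Sequence[PharmacophoreFeature],
    allow_omit: int = 0,
    match_tolerance: float = 1.0,
) -> Optional[MappingResult]:
    """Find the best placement of a ligand conformer onto a hypothesis.

    Enumerates kind-respecting correspondences of size at least
    ``max_fit - allow_omit`` (cliques on the distance-compatibility graph,
    including sub-cliques of maximal cliques), superposes each candidate by
    least-squares rigid alignment, and keeps the correspondence maximizing
    fit; ties prefer fewer omissions, then the lexicographically smallest
    index pairing.  Returns ``None`` when no large-enough correspondence
    exists.
    """
    if h.max_fit == 0:
        raise ValueError("cannot map onto an empty hypothesis")
    if allow_omit >= h.max_fit:
        raise ValueError("allow_omit must be smaller than the feature count")
    required = h.max_fit - allow_omit
    if not ligand_features or len(ligand_features) < required:
        return None

    g = _correspondence_graph(h.features, ligand_features, match_tolerance)
    if g.number_of_nodes() == 0:
        return None

    best = None  # (fit, -size, sorted pairs, devs, sup)
    seen: set[frozenset] = set()
    for clique in nx.find_cliques(g):
        if len(clique) < required:
            continue
        for size in range(required, len(clique) + 1):
            for sub in itertools.combinations(sorted(clique), size):
                key = frozenset(sub)
                if key in seen:
                    continue
                seen.add(key)
                pairs = sorted(sub)
                fit, devs, sup = _score_correspondence(
                    h.features, ligand_features, pairs
                )
                cand = (-fit, h.max_fit - len(pairs), pairs)
                if best is None or cand < (-best[0], best[1], best[2]):
                    best = (fit, h.max_fit - len(pairs), pairs, devs, sup)
    if best is None:
        return None
    fit, omitted, pairs, devs, sup = best
    return MappingResult(
        pairs=list(pairs), omitted_count=omitted, deviations=devs,
        fit=fit, transform=sup,
    )


def screen_library(
    h: Hypothesis,
    library: Sequence[Compound],
    allow_omit: int = 0,
    match_tolerance: float = 1.0,
    min_fit: Optional[float] = None,
) -> list[ScreenRecord]:
    """Screen a compound library against one hypothesis.

    Each compound's best fit over its conformers is reported; a compound
    passes when any conformer maps under the configured omission allowance
    (and, optionally, reaches ``min_fit``).  Output order follows input
    order.
    """
    if not library:
        raise ValueError("library must be non-empty")
    records = []
    for comp in library:
        best_fit = None
        for conf in comp.conformers:
            res = map_conformer(h, conf, allow_omit, match_tolerance)
            if res is not None and (best_fit is None or res.fit > best_fit):
                best_fit = res.fit
        passed = best_fit is not None and (min_fit is None or best_fit >= min_fit)
        records.append(
            ScreenRecord(
                compound_id=comp.id, best_fit=best_fit,
                hypothesis_id=h.id, passed=passed,
            )
        )
    return records


# --------------------------------------------------------------------------
# Güner–Henry decoy-set statistics
# --------------------------------------------------------------------------

class UndefinedGFError(ValueError):
    pass


@dataclass
class DecoyEvaluation:
    """Retrieval quality of a hypothesis on a labeled decoy library.

    D: library size; A: actives in it; Ht: hits retrieved; Ha: actives among
    hits.  Derived: percentage yield of actives (Ha/Ht), percentage ratio of
    actives retrieved (Ha/A), false negatives/positives, and the composite
    goodness-of-fit GF (1 only at perfect retrieval).  ``*_trunc`` fields are
    floor-truncated to two decimals.
    """

    D: int
    A: int
    Ht: int
    Ha: int
    yield_pct: float = field(init=False)
    ratio_pct: float = field(init=False)
    false_negatives: int = field(init=False)
    false_positives: int = field(init=False)
    GF: float = field(init=False)
    yield_pct_trunc: float = field(init=False)
    ratio_pct_trunc: float = field(init=False)
    GF_trunc: float = field(init=False)

    def __post_init__(self) -> None:
        D, A, Ht, Ha = self.D, self.A, self.Ht, self.Ha
        if not (D > A > 0):
            raise ValueError(f"need D > A > 0, got D={D}, A={A}")
        if Ht > D:
            raise ValueError("Ht cannot exceed D")
        if Ha > Ht or Ha > A or Ha < 0:
            raise ValueError(
                f"inconsistent confusion counts: Ha={Ha}, Ht={Ht}, A={A}"
            )
        if Ht == 0:
            raise UndefinedGFError("GF undefined when no hits are retrieved")
        self.yield_pct = 100.0 * Ha / Ht
        self.ratio_pct = 100.0 * Ha / A
        self.false_negatives = A - Ha
        self.false_positives = Ht - Ha
        self.GF = (Ha * (3 * A + Ht) / (4 * Ht * A)) * (1 - (Ht - Ha) / (D - A))
        self.yield_pct_trunc = truncate2(self.yield_pct)
        self.ratio_pct_trunc = truncate2(self.ratio_pct)
        self.GF_trunc = truncate2(self.GF)

    def to_dict(self) -> dict:
        return {
            "D": self.D, "A": self.A, "Ht": self.Ht, "Ha": self.Ha,
            "yield_pct": self.yield_pct, "ratio_pct": self.ratio_pct,
            "false_negatives": self.false_negatives,
            "false_positives": self.false_positives,
            "GF": self.GF, "GF_trunc": self.GF_trunc,
            "yield_pct_trunc": self.yield_pct_trunc,
            "ratio_pct_trunc": self.ratio_pct_trunc,
        }


def gh_statistics(D: int, A: int, Ht: int, Ha: int) -> DecoyEvaluation:
    """Güner–Henry statistics from the raw confusion counts."""
    return DecoyEvaluation(D=D, A=A, Ht=Ht, Ha=Ha)


def evaluate_decoy_set(
    h: Hypothesis,
    labeled_library: Sequence[Compound],
    allow_omit: int = 0,
    match_tolerance: float = 1.0,
) -> DecoyEvaluation:
    """Screen a labeled decoy library and derive the Güner–Henry statistics."""
    if any(c.active is None for c in labeled_library):
        raise ValueError("every compound must carry an active/inactive label")
    records = screen_library(h, labeled_library, allow_omit, match_tolerance)
    D = len(labeled_library)
    A = sum(1 for c in labeled_library if c.active)
    Ht = sum(1 for r in records if r.passed)
    Ha = sum(
        1 for r, c in zip(records, labeled_library) if r.passed and c.active
    )
    return gh_statistics(D=D, A=A, Ht=Ht, Ha=Ha)


def gh_report_table(evaluations: dict[str, DecoyEvaluation]):
    """Validation summary, one hypothesis per column, rows in the customary
    order (D, A, Ht, Ha, %yield, %ratio, FN, FP, GF)."""
    import pandas as pd

    rows = [
        ("Total compounds in database (D)", lambda e: e.D),
        ("Total actives in database (A)", lambda e: e.A),
        ("Total hits retrieved (Ht)", lambda e: e.Ht),
        ("Actives in hit list (Ha)", lambda e: e.Ha),
        ("% Yield of actives", lambda e: e.yield_pct_trunc),
        ("% Ratio of actives", lambda e: e.ratio_pct_trunc),
        ("False negatives (A-Ha)", lambda e: e.false_negatives),
        ("False positives (Ht-Ha)", lambda e: e.false_positives),
        ("Goodness of fit score (GF)", lambda e: e.GF_trunc),
    ]
    return pd.DataFrame(
        {name: [fn(e) for _, fn in rows] for name, e in evaluations.items()},
        index=[r[0] for r in rows],
    ).T


# --------------------------------------------------------------------------
# ROC validation
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    """ROC curve with AUC; higher scores are treated as more active."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    scores: np.ndarray
    labels: np.ndarray

    def sensitivity_at(self, threshold: float) -> float:
        """Fraction of actives scoring at or above the threshold."""
        pos = self.labels == 1
        return float((self.scores[pos] >= threshold).mean())

    def specificity_at(self, threshold: float) -> float:
        """Fraction of inactives correctly rejected (scoring below)."""
        neg = self.labels == 0
        return float((self.scores[neg] < threshold).mean())


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC analysis of screening scores against binary activity labels.

    The AUC equals the probability that a random active outscores a random
    inactive, with ties counted one half (the rank-sum identity).
    """
    from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thr = _sk_roc(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
                     scores=scores, labels=labels)
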