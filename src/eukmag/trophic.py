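"""Trophic-mode prediction and heterotrophy-index scoring from KEGG
ortholog (KO) presence/absence.

Two complementary outputs are produced for a transcriptome or MAG:

1. a trinary Random Forest classification (phototroph / heterotroph /
   mixotroph) trained on labelled reference transcriptomes, restricted to
   KOs chosen by hold-out permutation-importance feature selection
   ("vita" selection: cross-validated per-tree permutation importance with
   an empirical null built by mirroring the negative importances); and

2. a composite heterotrophy index.  Each selected KO k receives one score
   per mode from its occurrence ratio a = K_mode/n_mode among that mode's
   references, through the piecewise transform

       g(a) = a            if a > 0.5
       g(a) = -(0.5 - a)   otherwise,

   so KOs characteristic of a mode score high and KOs typically absent
   score mildly negative.  An evaluated entity sums, over all selected
   KOs, s_k * g(a) with s_k = +1 when the KO is present and -1 when it is
   absent (absence of a typically-absent KO is evidence *for* the mode).
   The three sums H, P, M collapse to the index

       H_ind = H - P          if M - max(H, P) < 50
       H_ind = (H - P) / M    otherwise,

   negative for phototroph-like and positive for heterotroph-like entities,
   damped when mixotrophy signal dominates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

MODES = ("heterotroph", "phototroph", "mixotroph")
KO_PATTERN = re.compile(r"^K\d{5}$")

DEFAULT_MIN_KOS = 500
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_N_TREES = 500
DEFAULT_TEST_FRACTION = 0.25
DEFAULT_MIXO_MARGIN = 50.0


@dataclass
class KOProfile:
    """KO presence set for one reference transcriptome or MAG."""

    entity_id: str
    present_kos: set[str]
    label: str | None = None

    def __post_init__(self) -> None:
        self.present_kos = set(self.present_kos)
        bad = [k for k in self.present_kos if not KO_PATTERN.match(k)]
        if bad:
            raise ValueError(
                f"{self.entity_id}: invalid KO identifiers (expect K#####): {sorted(bad)[:5]}"
            )
        if self.label is not None and self.label not in MODES:
            raise ValueError(f"{self.entity_id}: unknown trophic label {self.label!r}")


def profiles_from_long(df: pd.DataFrame, labels: pd.DataFrame | None = None) -> list[KOProfile]:
    """Build profiles from a long annotation table (entity_id, ko_id) plus an
    optional label table (entity_id, trophic_mode)."""
    label_map: dict[str, str] = {}
    if labels is not None:
        label_map = labels.set_index("entity_id")["trophic_mode"].to_dict()
    out = []
    for entity, group in df.groupby("entity_id", sort=True):
        out.append(
            KOProfile(str(entity), set(group["ko_id"]), label_map.get(entity))
        )
    return out


def profiles_from_wide(df: pd.DataFrame, labels: pd.DataFrame | None = None) -> list[KOProfile]:
    """Build profiles from a wide presence/absence matrix (entity x KO)."""
    label_map: dict[str, str] = {}
    if labels is not None:
        label_map = labels.set_index("entity_id")["trophic_mode"].to_dict()
    kos = np.asarray(df.columns)
    return [
        KOProfile(str(entity), set(kos[df.loc[entity].values > 0]), label_map.get(entity))
        for entity in df.index
    ]


def profiles_to_matrix(
    profiles: Sequence[KOProfile], kos: Sequence[str] | None = None
) -> pd.DataFrame:
    """0/1 entity x KO matrix over the union of KOs (or a fixed KO list)."""
    if kos is None:
        kos = sorted(set().union(*(p.present_kos for p in profiles)))
    kos = list(kos)
    ko_index = {k: j for j, k in enumerate(kos)}
    mat = np.zeros((len(profiles), len(kos)), dtype=np.int8)
    for i, p in enumerate(profiles):
        for k in p.present_kos:
            j = ko_index.get(k)
            if j is not None:
                mat[i, j] = 1
    return pd.DataFrame(mat, index=[p.entity_id for p in profiles], columns=kos)


def filter_references(
    profiles: Sequence[KOProfile], min_kos: int = DEFAULT_MIN_KOS
) -> tuple[list[KOProfile], list[str]]:
    """Drop sparsely annotated references (fewer than ``min_kos`` present
    KOs; a profile with exactly ``min_kos`` is retained).  Returns
    (retained, removed ids); removing everything is an error."""
    kept = [p for p in profiles if len(p.present_kos) >= min_kos]
    removed = [p.entity_id for p in profiles if len(p.present_kos) < min_kos]
    if not kept:
        raise ValueError(
            f"no reference profiles with >= {min_kos} KOs remain after filtering"
        )
    if removed:
        logger.info("filter_references removed %d profiles", len(removed))
    return kept, removed


# ---------------------------------------------------------------------------
# vita-style feature selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureSelectionResult:
    importances: pd.Series       # per KO, cross-validated permutation importance
    p_values: pd.Series          # per KO, empirical p against the mirrored null
    selected: list[str]
    p_threshold: float

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _holdout_importance(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_trees: int,
    rng: np.random.Generator,
    seed: int,
) -> np.ndarray:
    """Per-tree hold-out permutation importance: each tree of a forest grown
    on the training fold is scored on the held-out fold; for every feature
    the tree actually splits on, the feature column is permuted and the
    drop in that tree's hold-out accuracy recorded.  Importance of a
    feature is its mean drop over all trees (zero for trees not using it).
    """
    n_features = X_train.shape[1]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X_train, y_train)
    classes = forest.classes_
    Xf = np.ascontiguousarray(X_test, dtype=np.float32)
    n_test = Xf.shape[0]
    drops = np.zeros(n_features)

    def _tree_acc(tree) -> float:
        proba = tree.predict(Xf)
        if proba.ndim == 3:
            proba = proba[:, 0, :]
        return float(np.mean(classes[np.argmax(proba, axis=1)] == y_test))

    for est in forest.estimators_:
        tree = est.tree_
        used = np.unique(tree.feature[tree.feature >= 0])
        if used.size == 0:
            continue
        base_acc = _tree_acc(tree)
        for j in used:
            saved = Xf[:, j].copy()
            Xf[:, j] = saved[rng.permutation(n_test)]
            acc = _tree_acc(tree)
            Xf[:, j] = saved
            drops[j] += base_acc - acc
    return drops / len(forest.estimators_)


def vita_select(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> FeatureSelectionResult:
    """Select predictive KOs by two-fold cross-validated permutation
    importance with a mirrored-null empirical p-value.

    The samples are split into two stratified folds; a forest grown on
    each fold is scored by per-tree permutation importance on the other,
    and the two estimates are averaged.  Under the null a feature's
    importance is symmetric around zero, so the non-positive importances,
    mirrored to the positive side, form the null distribution; a KO is
    selected when its empirical upper-tail p falls below ``p_threshold``.
    Deterministic for a fixed seed.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection requires at least 2 classes")
    if len(y) != matrix.shape[0]:
        raise ValueError("labels length does not match matrix rows")
    X = matrix.values
    rng = np.random.default_rng(seed)
    splitter = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed % (2**31))
    fold_a, fold_b = (idx for _, idx in splitter.split(X, y))
    imp = np.zeros(X.shape[1])
    for train_idx, test_idx in ((fold_a, fold_b), (fold_b, fold_a)):
        imp += _holdout_importance(
            X[train_idx], y[train_idx], X[test_idx], y[test_idx],
            n_trees, rng, seed=int(rng.integers(2**31)),
        )
    imp /= 2.0
    nonpos = imp[imp <= 0]
    null = np.concatenate([nonpos, -nonpos])
    if null.size == 0:
        logger.warning("no non-positive importances; null distribution empty")
        p = np.where(imp > 0, 0.0, 1.0)
    else:
        # upper-tail empirical p with add-one smoothing
        p = (1.0 + np.sum(null[None, :] >= imp[:, None], axis=1)) / (1.0 + null.size)
    importances = pd.Series(imp, index=matrix.columns, name="importance")
    p_values = pd.Series(p, index=matrix.columns, name="p")
    selected = list(matrix.columns[p < p_threshold])
    return FeatureSelectionResult(importances, p_values, selected, p_threshold)


# ---------------------------------------------------------------------------
# Random Forest classifier
# ---------------------------------------------------------------------------

@dataclass
class TrophicModel:
    forest: RandomForestClassifier
    kos: list[str]
    holdout_accuracy: float
    classes: list[str]

    def predict(self, profiles: Sequence[KOProfile]) -> pd.Series:
        X = profiles_to_matrix(profiles, self.kos).values
        return pd.Series(
            self.forest.predict(X), index=[p.entity_id for p in profiles], name="rf_class"
        )


def train_trophic_rf(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    split_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    tune_max_features: bool = False,
) -> TrophicModel:
    """Train the trophic-mode Random Forest on a (selected-KO) presence
    matrix with a class-stratified hold-out split and report held-out
    accuracy.  ``tune_max_features`` runs a coarse out-of-bag grid over the
    number of candidate features per split instead of sqrt(n_features).
    """
    y = np.asarray(labels)
    X = matrix.values
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=split_fraction, stratify=y, random_state=seed % (2**31)
    )
    if len(np.unique(y_tr)) < len(np.unique(y)):
        raise ValueError("a class is absent from the training split")
    max_features: float | str = "sqrt"
    if tune_max_features:
        n_feat = X.shape[1]
        sqrt_f = max(1, int(np.sqrt(n_feat)))
        grid = sorted({max(1, sqrt_f // 2), sqrt_f, min(n_feat, sqrt_f * 2)})
        best_oob = -np.inf
        for mf in grid:
            probe = RandomForestClassifier(
                n_estimators=n_trees, max_features=mf, oob_score=True,
                bootstrap=True, random_state=seed % (2**31), n_jobs=1,
            ).fit(X_tr, y_tr)
            if probe.oob_score_ > best_oob:
                best_oob, max_features = probe.oob_score_, mf
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=max_features,
        random_state=seed % (2**31), n_jobs=1,
    ).fit(X_tr, y_tr)
    acc = float(np.mean(forest.predict(X_te) == y_te))
    return TrophicModel(forest, list(matrix.columns), acc, list(forest.classes_))


# ---------------------------------------------------------------------------
# h/p/m scores and the heterotrophy index
# ---------------------------------------------------------------------------

def g_transform(a: float | np.ndarray) -> float | np.ndarray:
    """Occurrence-ratio transform: a when a > 0.5, else -(0.5 - a)."""
    a = np.asarray(a, dtype=float)
    out = np.where(a > 0.5, a, -(0.5 - a))
    return float(out) if out.ndim == 0 else out


@dataclass
class TrophicScoreTable:
    """Per-KO mode scores h/p/m with their occurrence ratios and counts."""

    table: pd.DataFrame  # index KO; columns h, p, m, a_het, a_photo, a_mixo
    n_refs: dict[str, int] = field(default_factory=dict)

    @property
    def kos(self) -> list[str]:
        return list(self.table.index)


def ko_mode_scores(
    profiles: Sequence[KOProfile], selected_kos: Sequence[str]
) -> TrophicScoreTable:
    """Compute per-KO h/p/m scores from labelled reference profiles.

    For each selected KO and each mode, a = (references of that mode
    containing the KO) / (references of that mode); the score is g(a).
    Every mode must have at least one reference.
    """
    counts = {m: 0 for m in MODES}
    for p in profiles:
        if p.label in counts:
            counts[p.label] += 1
    empty = [m for m, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"modes without reference profiles: {empty}")
    kos = list(selected_kos)
    rows = {}
    for mode in MODES:
        members = [p for p in profiles if p.label == mode]
        k_counts = np.array(
            [sum(1 for p in members if k in p.present_kos) for k in kos], dtype=float
        )
        rows[mode] = k_counts / counts[mode]
    df = pd.DataFrame(
        {
            "h": g_transform(rows["heterotroph"]),
            "p": g_transform(rows["phototroph"]),
            "m": g_transform(rows["mixotroph"]),
            "a_het": rows["heterotroph"],
            "a_photo": rows["phototroph"],
            "a_mixo": rows["mixotroph"],
        },
        index=pd.Index(kos, name="ko"),
    )
    return TrophicScoreTable(df, dict(counts))


@dataclass
class SampleTrophicScores:
    entity_id: str
    H: float
    P: float
    M: float
    H_ind: float
    band: str


def score_entity(
    profile: KOProfile, table: TrophicScoreTable,
    mixo_margin: float = DEFAULT_MIXO_MARGIN, quadratic: bool = False,
) -> SampleTrophicScores:
    """Sum signed per-KO scores over all selected KOs: a present KO
    contributes +g(a) per mode, an absent KO contributes -g(a), then
    collapse H, P, M to the heterotrophy index.  KOs present in the entity
    but missing from the score table (never seen in any reference) are
    ignored with a warning."""
    if table.table.empty:
        raise ValueError("empty score table")
    df = table.table
    sign = np.array([1.0 if k in profile.present_kos else -1.0 for k in df.index])
    unknown = profile.present_kos - set(df.index)
    if unknown:
        logger.warning(
            "%s: %d present KOs absent from score table ignored",
            profile.entity_id, len(unknown),
        )
    H = float(np.sum(sign * df["h"].values))
    P = float(np.sum(sign * df["p"].values))
    M = float(np.sum(sign * df["m"].values))
    hind = h_index(H, P, M, mixo_margin=mixo_margin, quadratic=quadratic)
    return SampleTrophicScores(profile.entity_id, H, P, M, hind, classify_with_index(hind))


def h_index(
    H: float, P: float, M: float,
    mixo_margin: float = DEFAULT_MIXO_MARGIN, quadratic: bool = False,
) -> float:
    """Composite heterotrophy index.

    Base term sign(H-P)*sqrt((H-P)^2) = H - P; when the mixotrophy score
    dominates both (M - max(H, P) >= ``mixo_margin``) the base is divided
    by M.  ``quadratic=True`` switches the base to sign(H-P)*(H-P)^2, an
    alternative algebraic reading of the same composite."""
    base = np.sign(H - P) * (H - P) ** 2 if quadratic else H - P
    if M - max(H, P) < mixo_margin:
        return float(base)
    return float(base / M)


def classify_with_index(
    H_ind: float, cutoffs: tuple[float, float] = (-50.0, 50.0)
) -> str:
    """Descriptive band for reporting (never overrides the forest class):
    below the lower cutoff phototroph-like, above the upper heterotroph-like,
    otherwise intermediate."""
    lo, hi = cutoffs
    if H_ind < lo:
        return "phototroph-like"
    if H_ind > hi:
        return "heterotroph-like"
    return "intermediate"


def score_entities(
    profiles: Sequence[KOProfile], table: TrophicScoreTable,
    model: TrophicModel | None = None,
    mixo_margin: float = DEFAULT_MIXO_MARGIN, quadratic: bool = False,
) -> pd.DataFrame:
    """Score many entities; returns a DataFrame (entity, H, P, M, H_ind,
    band[, rf_class])."""
    rows = [
        score_entity(p, table, mixo_margin=mixo_margin, quadratic=quadratic)
        for p in profiles
    ]
    df = pd.DataFrame(
        {
            "entity_id": [r.entity_id for r in rows],
            "H": [r.H for r in rows],
            "P": [r.P for r in rows],
            "M": [r.M for r in rows],
            "H_ind": [r.H_ind for r in rows],
            "band": [r.band for r in rows],
        }
    ).set_index("entity_id")
    if model is not None:
        df["rf_class"] = model.predict(list(profiles))
    return df
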