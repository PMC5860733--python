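"""Pairwise polynomial SVMs, Platt calibration, posterior coupling, LOSO.

A K-class problem is decomposed into K(K-1)/2 two-class soft-margin SVMs
with a degree-2 polynomial kernel.  Class imbalance is handled by penalty
weights inversely proportional to class frequency (the "margin calibration"
for unbalanced data).  Each SVM's decision values are mapped to pairwise
posterior probabilities Pr_ij with Platt's sigmoid, fitted on out-of-fold
decision values from a 3-fold internal split to avoid optimistic
calibration.  Per-class posteriors are obtained by pairwise coupling

    Pr(C_i | x) = 1 / ( sum_{j != i} 1/Pr_ij - (K - 2) )

followed by an explicit normalization to sum to one (the raw coupled values
need not; for K = 2 the formula reduces to Pr_12 exactly).

Generalization is estimated by leave-one-subject-out (LOSO)
cross-validation: for each held-out subject, feature standardization,
feature selection and all SVM/Platt fits use the remaining subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .recording import GROUPS
from .select import fold_feature_matrices, probe_select

__all__ = [
    "SVMConfig",
    "SelectionConfig",
    "PairwiseModel",
    "train_pairwise",
    "combine_pairwise",
    "ConfusionMatrix",
    "LOSOResult",
    "loso_evaluate",
]

_CLIP = 1e-6


@dataclass
class SVMConfig:
    C: float = 1.0
    degree: int = 2
    coef0: float = 1.0
    gamma: str | float = "auto"  # "auto" = 1/n_features
    platt_folds: int = 3
    seed: int = 0


@dataclass
class SelectionConfig:
    """How features are chosen inside the evaluation.

    mode "nested": random-probe selection re-run inside every LOSO training
    fold (no leakage; the default).  mode "global": one selection on the full
    data set before LOSO — reproduces a single reported feature list but is
    optimistically biased.  mode "none": use all provided columns.
    """

    mode: str = "nested"
    risk: float = 0.10
    n_probes: int = 100
    probe_kind: str = "permute"
    seed: int = 0


def _platt_fit(decision: np.ndarray, positive: np.ndarray) -> tuple[float, float]:
    """Platt's sigmoid P(pos|f) = 1/(1+exp(A f + B)) by regularized MLE.

    Targets use Platt's Bayes-corrected values (N+1)/(N+2) to keep the fit
    finite on separable data, and samples are weighted inversely to class
    frequency — the same calibration-for-imbalance stance as the SVM's
    penalty weighting, so a majority class cannot drag the intercept.
    """
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(positive, hi, lo)
    w = np.where(positive, 0.5 / n_pos, 0.5 / n_neg) * positive.size

    def nll(ab):
        a, b = ab
        z = a * decision + b
        # -sum w * (t*log(p) + (1-t)*log(1-p)), stable via logaddexp
        return float(np.sum(w * (np.logaddexp(0.0, z) - (1.0 - t) * z)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead")
    return float(res.x[0]), float(res.x[1])


@dataclass
class PairwiseModel:
    """SVM + Platt sigmoid separating one class pair (ci, cj)."""

    class_i: str
    class_j: str
    svm: SVC
    platt_a: float
    platt_b: float
    feature_names: list[str] = field(default_factory=list)

    def decision(self, X: np.ndarray) -> np.ndarray:
        d = self.svm.decision_function(np.asarray(X, dtype=float))
        # sklearn's positive decision side is classes_[1]; flip so that
        # positive always means class_i
        return d if self.svm.classes_[1] == self.class_i else -d

    def proba_i(self, X: np.ndarray) -> np.ndarray:
        """Pr_ij: probability of class_i, Platt-mapped, clipped to (0, 1)."""
        p = expit(-(self.platt_a * self.decision(X) + self.platt_b))
        return np.clip(p, _CLIP, 1.0 - _CLIP)


def train_pairwise(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    class_i: str,
    class_j: str,
    cfg: SVMConfig | None = None,
) -> PairwiseModel:
    """Fit one margin-calibrated pairwise SVM with Platt probability mapping.

    Penalty weights are inversely proportional to class frequencies
    (sklearn's "balanced" mode), so the minority class is not sacrificed on
    unbalanced cohorts.  The Platt sigmoid is fitted on decision values
    obtained out-of-fold from a stratified internal split.
    """
    cfg = cfg or SVMConfig()
    names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y)
    classes, counts = np.unique(ya, return_counts=True)
    if set(classes) != {class_i, class_j}:
        raise ValueError(f"y must contain exactly classes {class_i!r} and {class_j!r}")
    if counts.min() < 3:
        raise ValueError("need at least 3 subjects per class")

    def make_svm() -> SVC:
        return SVC(
            kernel="poly",
            degree=cfg.degree,
            coef0=cfg.coef0,
            gamma=cfg.gamma,
            C=cfg.C,
            class_weight="balanced",
            random_state=cfg.seed,
        )

    # out-of-fold decision values for calibration
    n_folds = min(cfg.platt_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
    dec = np.empty(len(ya))
    for tr, te in skf.split(Xa, ya):
        sub = make_svm().fit(Xa[tr], ya[tr])
        d = sub.decision_function(Xa[te])
        dec[te] = d if sub.classes_[1] == class_i else -d
    a, b = _platt_fit(dec, ya == class_i)
    svm = make_svm().fit(Xa, ya)
    return PairwiseModel(
        class_i=class_i, class_j=class_j, svm=svm, platt_a=a, platt_b=b,
        feature_names=names,
    )


def combine_pairwise(
    prs: dict[tuple[str, str], float], classes: list[str]
) -> dict[str, float]:
    """Couple pairwise posteriors Pr_ij into per-class posteriors.

    ``prs[(ci, cj)]`` is the probability of ``ci`` from the (ci, cj) SVM;
    either orientation of each unordered pair must be present (the other is
    inferred as the complement).  Raw coupled values are normalized to sum
    to one.
    """
    K = len(classes)
    def pr(i: str, j: str) -> float:
        if (i, j) in prs:
            return float(np.clip(prs[(i, j)], _CLIP, 1 - _CLIP))
        if (j, i) in prs:
            return float(np.clip(1.0 - prs[(j, i)], _CLIP, 1 - _CLIP))
        raise KeyError(f"missing pairwise probability for ({i}, {j})")

    raw = {}
    for ci in classes:
        s = sum(1.0 / pr(ci, cj) for cj in classes if cj != ci)
        raw[ci] = 1.0 / (s - (K - 2))
    total = sum(raw.values())
    return {c: v / total for c, v in raw.items()}


@dataclass
class ConfusionMatrix:
    """Row-normalized confusion matrix with the study's summary metrics."""

    labels: list[str]
    counts: np.ndarray  # (K, K) integer counts, rows = true class
    reference: str = "SCI"

    @property
    def percent(self) -> np.ndarray:
        row = self.counts.sum(axis=1, keepdims=True)
        return 100.0 * self.counts / np.maximum(row, 1)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / max(self.counts.sum(), 1))

    @property
    def sensitivity(self) -> dict[str, float]:
        """Per-class proportion of correctly classified subjects."""
        diag = np.diag(self.counts)
        rows = self.counts.sum(axis=1)
        return {
            lab: float(diag[i] / rows[i]) if rows[i] else float("nan")
            for i, lab in enumerate(self.labels)
        }

    @property
    def specificity(self) -> float:
        """Proportion of correctly classified reference-group subjects."""
        ref = self.reference if self.reference in self.labels else self.labels[0]
        return self.sensitivity[ref]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.percent, index=self.labels, columns=self.labels)

    def pretty(self) -> str:
        return self.to_frame().round(1).to_string()


@dataclass
class LOSOResult:
    predictions: pd.DataFrame  # subject_id, true, predicted, per-class posterior
    confusion: ConfusionMatrix
    fold_info: list[dict]

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy


def _class_order(labels) -> list[str]:
    seen = list(dict.fromkeys(labels))
    known = [g for g in GROUPS if g in seen]
    return known + [g for g in seen if g not in known]


def loso_evaluate(
    primary: pd.DataFrame,
    groups: pd.Series,
    svm_cfg: SVMConfig | None = None,
    sel_cfg: SelectionConfig | None = None,
) -> LOSOResult:
    """Leave-one-subject-out evaluation of the pairwise-SVM classifier.

    ``primary`` holds the raw (unstandardized) primary features, one row per
    subject; ``groups`` the diagnostic labels.  For every held-out subject
    the pipeline re-runs from scratch on the training fold: standardization
    statistics, squared secondary features, per-pair feature selection and
    SVM/Platt fits never see the held-out row.
    """
    svm_cfg = svm_cfg or SVMConfig()
    sel_cfg = sel_cfg or SelectionConfig()
    groups = groups.loc[primary.index]
    classes = _class_order(groups)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if groups.value_counts().min() < 2:
        raise ValueError("every class needs at least 2 subjects")
    pairs = [(classes[a], classes[b]) for a in range(len(classes)) for b in range(a + 1, len(classes))]

    global_selection: dict[tuple[str, str], list[str]] | None = None
    if sel_cfg.mode == "global":
        full32 = fold_feature_matrices(primary, primary)[0]
        global_selection = {}
        for ci, cj in pairs:
            mask = groups.isin([ci, cj])
            sel = probe_select(
                full32[mask],
                np.where(groups[mask] == ci, 1.0, -1.0),
                n_probes=sel_cfg.n_probes,
                risk=sel_cfg.risk,
                seed=sel_cfg.seed,
                probe_kind=sel_cfg.probe_kind,
            )
            global_selection[(ci, cj)] = sel.accepted_names() or [full32.columns[0]]

    rows = []
    fold_info = []
    for held in primary.index:
        train_idx = primary.index.drop(held)
        tr32, te32 = fold_feature_matrices(
            primary.loc[train_idx], primary.loc[[held]]
        )
        g_tr = groups.loc[train_idx]
        prs: dict[tuple[str, str], float] = {}
        fold_selected: dict[str, list[str]] = {}
        for ci, cj in pairs:
            mask = g_tr.isin([ci, cj]).to_numpy()
            if g_tr[mask].nunique() < 2:
                continue  # vanished class in this fold
            Xp = tr32.loc[mask]
            yp = g_tr[mask].to_numpy()
            if sel_cfg.mode == "nested":
                sel = probe_select(
                    Xp,
                    np.where(yp == ci, 1.0, -1.0),
                    n_probes=sel_cfg.n_probes,
                    risk=sel_cfg.risk,
                    seed=sel_cfg.seed,
                    probe_kind=sel_cfg.probe_kind,
                )
                feats = sel.accepted_names() or [tr32.columns[0]]
            elif sel_cfg.mode == "global":
                feats = global_selection[(ci, cj)]
            elif sel_cfg.mode == "none":
                feats = list(tr32.columns)
            else:
                raise ValueError(f"unknown selection mode {sel_cfg.mode!r}")
            model = train_pairwise(Xp[feats], yp, ci, cj, svm_cfg)
            prs[(ci, cj)] = float(model.proba_i(te32[feats].to_numpy())[0])
            fold_selected[f"{ci}|{cj}"] = feats
        post = combine_pairwise(prs, classes)
        pred = max(classes, key=lambda c: post[c])  # ties -> class order
        rows.append(
            {"subject_id": held, "true": groups.loc[held], "predicted": pred,
             **{f"P({c})": post[c] for c in classes}}
        )
        fold_info.append(
            {"held_out": held, "train_ids": list(train_idx),
             "train_means": primary.loc[train_idx].mean(axis=0).to_dict(),
             "selected": fold_selected}
        )
    pred_df = pd.DataFrame(rows).set_index("subject_id")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for _, r in pred_df.iterrows():
        counts[classes.index(r["true"]), classes.index(r["predicted"])] += 1
    return LOSOResult(
        predictions=pred_df,
        confusion=ConfusionMatrix(labels=classes, counts=counts),
        fold_info=fold_info,
    )
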