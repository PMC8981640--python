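"""Block-level DNA-methylation classification of tumor tissue of origin.

Targeted bisulfite sequencing yields per-CpG beta values (methylated
fraction in [0, 1]). Neighboring CpGs are highly correlated, so sites are
aggregated into *methylation blocks* and each sample is represented by its
vector of block-mean betas — the "MBS" matrix (samples x blocks).

For each extrathoracic organ (stomach, colon/rectum, cervix) a binary
soft-margin linear SVM separates lung-origin (label 0) from organ-origin
(label 1) tumors. The misclassification penalty is chosen by stratified
fivefold cross-validation on AUC; out-of-fold decision values are mapped to
[0, 1] by a Platt-style sigmoid, giving the *Methyl Score* — a calibrated
probability of non-lung origin. The operating cutoff is the Youden-index
maximizer on the calibrated out-of-fold scores (0.5 for well-separated
training data). A query sample scoring below the cutoff is called
lung-origin; above, non-lung-origin.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .integrate import (
    DiagnosisRelationship,
    EvidenceSource,
    LesionLabel,
    PatientDiagnosis,
)
from .cgp import TOO
from .profiles import Site

__all__ = [
    "MethylationBlock",
    "MBSMatrix",
    "SigmoidCalibration",
    "BinaryTOOModel",
    "OriginCall",
    "MethylScoreResult",
    "DegenerateROCError",
    "ScoringError",
    "build_blocks",
    "select_differential_blocks",
    "train_model",
    "youden_cutoff",
    "methyl_score",
    "call_from_score",
    "infer_patient_from_scores",
    "pca_projection",
    "roc_auc",
    "DEFAULT_PENALTY_GRID",
]

DEFAULT_PENALTY_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_MAX_GAP = 500
DEFAULT_MIN_SITES = 3
DEFAULT_TOP_M = 200


class DegenerateROCError(ValueError):
    """All scores identical: no ROC threshold can be chosen."""


class ScoringError(ValueError):
    """A query sample is missing blocks required by the model."""


@dataclass(frozen=True)
class MethylationBlock:
    """A run of nearby CpG sites summarized by their mean beta."""

    block_id: str
    chrom: str
    start: int
    end: int
    member_sites: tuple[int, ...]

    def __post_init__(self):
        if any(not self.start <= p <= self.end for p in self.member_sites):
            raise ValueError(f"{self.block_id}: member sites outside [start, end]")


@dataclass
class MBSMatrix:
    """Samples x blocks matrix of block-mean betas, optionally labeled.

    ``labels``: 0 = lung-cancer origin, 1 = non-lung; ``tissue``: anatomical
    site per sample (used to derive contrast-specific labels).
    """

    values: pd.DataFrame  # index: sample_id, columns: block_id
    blocks: list[MethylationBlock]
    labels: Optional[pd.Series] = None
    tissue: Optional[pd.Series] = None

    def __post_init__(self):
        block_ids = [b.block_id for b in self.blocks]
        if list(self.values.columns) != block_ids:
            raise ValueError("values columns must match block ids, in order")
        vals = self.values.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("block betas must lie in [0, 1]")
        for series_name in ("labels", "tissue"):
            s = getattr(self, series_name)
            if s is not None and not s.index.equals(self.values.index):
                raise ValueError(f"{series_name} index must match sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def block_ids(self) -> list[str]:
        return list(self.values.columns)

    def contrast_view(self, organ: Site | str) -> "MBSMatrix":
        """Subset to lung + one organ, with labels 0 (lung) / 1 (organ)."""
        organ = Site(organ)
        if self.tissue is None:
            raise ValueError("contrast_view requires per-sample tissue annotations")
        mask = self.tissue.isin([Site.LUNG.value, organ.value])
        values = self.values.loc[mask]
        tissue = self.tissue.loc[mask]
        labels = (tissue != Site.LUNG.value).astype(int)
        return MBSMatrix(values=values, blocks=self.blocks, labels=labels, tissue=tissue)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


def build_blocks(
    sites: pd.DataFrame,
    max_gap: int = DEFAULT_MAX_GAP,
    min_sites: int = DEFAULT_MIN_SITES,
) -> tuple[list[MethylationBlock], MBSMatrix]:
    """Group CpG sites into blocks and average betas within each block.

    ``sites`` is a tidy table with columns ``chrom, pos, sample_id, beta``
    (the BED-like TSV layout); every sample must report the same site set.
    Consecutive sites on one chromosome join a block while the inter-site
    gap is <= ``max_gap`` bp; blocks with fewer than ``min_sites`` sites are
    dropped.
    """
    required = {"chrom", "pos", "sample_id", "beta"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing column(s): {', '.join(sorted(missing))}")
    if ((sites["beta"] < 0) | (sites["beta"] > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")

    wide = sites.pivot_table(index="sample_id", columns=["chrom", "pos"], values="beta")
    if wide.isna().any().any():
        bad = sorted(wide.index[wide.isna().any(axis=1)])
        raise ValueError(f"samples with mismatched site sets: {', '.join(map(str, bad))}")

    coords = sorted(wide.columns, key=lambda cp: (cp[0], cp[1]))
    blocks: list[MethylationBlock] = []
    runs: list[list[tuple[str, int]]] = []
    current: list[tuple[str, int]] = []
    for chrom, pos in coords:
        if current and (chrom != current[-1][0] or pos - current[-1][1] > max_gap):
            runs.append(current)
            current = []
        current.append((chrom, pos))
    if current:
        runs.append(current)

    col_groups = []
    for run in runs:
        if len(run) < min_sites:
            continue
        chrom = run[0][0]
        positions = tuple(p for _, p in run)
        block_id = f"{chrom}:{positions[0]}-{positions[-1]}"
        blocks.append(
            MethylationBlock(
                block_id=block_id,
                chrom=chrom,
                start=positions[0],
                end=positions[-1],
                member_sites=positions,
            )
        )
        col_groups.append(run)

    data = {
        b.block_id: wide[cols].mean(axis=1) for b, cols in zip(blocks, col_groups)
    }
    values = pd.DataFrame(data, index=wide.index)
    return blocks, MBSMatrix(values=values, blocks=blocks)


def _require_both_labels(labels: np.ndarray) -> None:
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError(f"both labels must be present, got {present.tolist()}")


def _rank_blocks(values: pd.DataFrame, labels: pd.Series) -> np.ndarray:
    """Column indices sorted by |group-mean difference| desc, genomic order
    (column order) breaking ties."""
    v = values.to_numpy()
    y = labels.to_numpy()
    delta = np.abs(v[y == 0].mean(axis=0) - v[y == 1].mean(axis=0))
    return np.argsort(-delta, kind="stable")


def select_differential_blocks(mbs: MBSMatrix, top_m: int) -> list[str]:
    """Top ``top_m`` blocks by absolute between-group mean-beta difference."""
    if mbs.labels is None:
        raise ValueError("select_differential_blocks requires labels")
    y = mbs.labels.to_numpy()
    _require_both_labels(y)
    for lab in (0, 1):
        if (y == lab).sum() < 2:
            raise ValueError(f"need >= 2 samples with label {lab}")
    if top_m > mbs.values.shape[1]:
        raise ValueError(f"top_m={top_m} exceeds number of blocks {mbs.values.shape[1]}")
    order = _rank_blocks(mbs.values, mbs.labels)
    return [mbs.block_ids[i] for i in order[:top_m]]


@dataclass(frozen=True)
class SigmoidCalibration:
    """Platt-style sigmoid mapping SVM decision values to [0, 1].

    ``P(label=1 | f) = 1 / (1 + exp(a * f + b))`` with ``a < 0`` whenever
    larger decision values indicate label 1, so the map is monotone
    increasing in the decision value.
    """

    a: float
    b: float

    def __call__(self, decision: np.ndarray | float) -> np.ndarray | float:
        z = self.a * np.asarray(decision, dtype=float) + self.b
        return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


def fit_sigmoid(decisions: np.ndarray, labels: np.ndarray) -> SigmoidCalibration:
    """Fit the sigmoid by maximum likelihood with Platt's smoothed targets.

    Target smoothing (t1 = (n1+1)/(n1+2), t0 = 1/(n0+2)) keeps the fit
    finite even when the decision values separate the classes perfectly.
    """
    decisions = np.asarray(decisions, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _require_both_labels(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    t = np.where(labels == 1, (n1 + 1.0) / (n1 + 2.0), 1.0 / (n0 + 2.0))

    def nll(params):
        a, b = params
        z = np.clip(a * decisions + b, -500, 500)
        p = 1.0 / (1.0 + np.exp(z))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(t * np.log(p) + (1 - t) * np.log(1 - p))

    x0 = np.array([-1.0, np.log((n0 + 1.0) / (n1 + 1.0))])
    res = minimize(nll, x0, method="BFGS")
    return SigmoidCalibration(a=float(res.x[0]), b=float(res.x[1]))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: probability a random label-1 score exceeds a random
    label-0 score, ties counted half."""
    labels = np.asarray(labels, dtype=int)
    _require_both_labels(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def youden_cutoff(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC-optimal threshold maximizing J = sensitivity + specificity - 1.

    Label 1 is the positive class; a sample is called positive when its
    score strictly exceeds the threshold. Candidates are the midpoints
    between adjacent distinct sorted scores, plus 0.5 itself; ties on J are
    broken toward the candidate closest to 0.5 (then the smaller one), so a
    signal-free ROC returns 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _require_both_labels(labels)
    distinct = np.unique(scores)
    if len(distinct) < 2:
        raise DegenerateROCError("all scores identical; ROC is degenerate")
    candidates = np.unique(np.concatenate([(distinct[:-1] + distinct[1:]) / 2.0, [0.5]]))

    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    best = None
    for c in candidates:
        pos = scores > c
        sens = (pos & (labels == 1)).sum() / n1
        spec = (~pos & (labels == 0)).sum() / n0
        j = sens + spec - 1.0
        key = (-j, abs(c - 0.5), c)
        if best is None or key < best[0]:
            best = (key, c)
    return float(best[1])


class OriginCall(str, enum.Enum):
    LC_ORIGIN = "LC_origin"
    NON_LC_ORIGIN = "non_LC_origin"
    INDETERMINATE = "indeterminate"


@dataclass
class MethylScoreResult:
    sample_id: str
    score: float
    call: OriginCall
    model_organ: Optional[Site] = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "score": self.score,
            "call": self.call.value,
            "model_organ": None if self.model_organ is None else self.model_organ.value,
        }


@dataclass
class BinaryTOOModel:
    """Trained lung-vs-organ classifier with calibration and cutoff."""

    contrast_organ: Site
    selected_blocks: list[str]
    weights: np.ndarray
    intercept: float
    penalty: float
    calibration: SigmoidCalibration
    cutoff: float
    cv_auc: float
    seed: int
    cv_scores: Optional[np.ndarray] = None   # calibrated out-of-fold scores
    cv_labels: Optional[np.ndarray] = None

    def decision(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.weights + self.intercept

    def to_json(self, path: str | Path) -> None:
        payload = {
            "contrast_organ": self.contrast_organ.value,
            "selected_blocks": self.selected_blocks,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "penalty": self.penalty,
            "calibration": {"a": self.calibration.a, "b": self.calibration.b},
            "cutoff": self.cutoff,
            "cv_auc": self.cv_auc,
            "seed": self.seed,
            "cv_scores": None if self.cv_scores is None else self.cv_scores.tolist(),
            "cv_labels": None if self.cv_labels is None else self.cv_labels.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "BinaryTOOModel":
        raw = json.loads(Path(path).read_text())
        return cls(
            contrast_organ=Site(raw["contrast_organ"]),
            selected_blocks=list(raw["selected_blocks"]),
            weights=np.asarray(raw["weights"], dtype=float),
            intercept=float(raw["intercept"]),
            penalty=float(raw["penalty"]),
            calibration=SigmoidCalibration(**raw["calibration"]),
            cutoff=float(raw["cutoff"]),
            cv_auc=float(raw["cv_auc"]),
            seed=int(raw["seed"]),
            cv_scores=None if raw["cv_scores"] is None else np.asarray(raw["cv_scores"]),
            cv_labels=None if raw["cv_labels"] is None else np.asarray(raw["cv_labels"]),
        )


def train_model(
    mbs: MBSMatrix,
    contrast_organ: Site | str,
    penalty_grid: Sequence[float] = DEFAULT_PENALTY_GRID,
    folds: int = 5,
    top_m: int = DEFAULT_TOP_M,
    seed: int = 0,
) -> BinaryTOOModel:
    """Train a lung-vs-organ model with penalty chosen by stratified CV.

    Differential-block selection is re-done inside every CV fold (training
    folds only) so cv_auc is a leak-free estimate of the full pipeline;
    the shipped ``selected_blocks`` come from the complete training panel.
    Calibration and the Youden cutoff are fit on out-of-fold decision
    values of the winning penalty.
    """
    contrast_organ = Site(contrast_organ)
    if mbs.labels is None:
        mbs = mbs.contrast_view(contrast_organ)
    y = mbs.labels.to_numpy().astype(int)
    _require_both_labels(y)
    class_sizes = [(y == 0).sum(), (y == 1).sum()]
    if folds > min(class_sizes):
        raise ValueError(f"folds={folds} exceeds smallest class size {min(class_sizes)}")
    X = mbs.values.to_numpy()
    top_m = min(top_m, X.shape[1])

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    oof = {c: np.zeros(len(y)) for c in penalty_grid}
    for train_idx, test_idx in splits:
        train_vals = mbs.values.iloc[train_idx]
        train_lab = mbs.labels.iloc[train_idx]
        order = _rank_blocks(train_vals, train_lab)[:top_m]
        Xtr, Xte = X[np.ix_(train_idx, order)], X[np.ix_(test_idx, order)]
        for c in penalty_grid:
            svm = SVC(kernel="linear", C=c)
            svm.fit(Xtr, y[train_idx])
            oof[c][test_idx] = svm.decision_function(Xte)

    cv_aucs = {c: roc_auc(oof[c], y) for c in penalty_grid}
    best_c = max(penalty_grid, key=lambda c: (cv_aucs[c], -c))

    selected_idx = _rank_blocks(mbs.values, mbs.labels)[:top_m]
    selected_blocks = [mbs.block_ids[i] for i in selected_idx]
    final = SVC(kernel="linear", C=best_c)
    final.fit(X[:, selected_idx], y)

    calibration = fit_sigmoid(oof[best_c], y)
    cv_scores = np.asarray(calibration(oof[best_c]), dtype=float)
    cutoff = youden_cutoff(cv_scores, y)

    return BinaryTOOModel(
        contrast_organ=contrast_organ,
        selected_blocks=selected_blocks,
        weights=final.coef_.ravel().copy(),
        intercept=float(final.intercept_[0]),
        penalty=float(best_c),
        calibration=calibration,
        cutoff=cutoff,
        cv_auc=float(cv_aucs[best_c]),
        seed=seed,
        cv_scores=cv_scores,
        cv_labels=y.copy(),
    )


def call_from_score(
    score: float,
    cutoff: float = 0.5,
    sample_id: str = "",
    model_organ: Optional[Site] = None,
) -> MethylScoreResult:
    """Apply the cutoff rule: < cutoff lung-origin, > cutoff non-lung-origin,
    exactly at the cutoff indeterminate."""
    if score < cutoff:
        call = OriginCall.LC_ORIGIN
    elif score > cutoff:
        call = OriginCall.NON_LC_ORIGIN
    else:
        call = OriginCall.INDETERMINATE
    return MethylScoreResult(sample_id=sample_id, score=float(score), call=call, model_organ=model_organ)


def methyl_score(model: BinaryTOOModel, sample: pd.Series) -> MethylScoreResult:
    """Score one sample (a row of an MBS matrix indexed by block id)."""
    missing = [b for b in model.selected_blocks if b not in sample.index]
    if missing:
        raise ScoringError(
            f"sample {sample.name!r} missing {len(missing)} model block(s): "
            + ", ".join(missing[:5])
            + ("..." if len(missing) > 5 else "")
        )
    x = sample.loc[model.selected_blocks].to_numpy(dtype=float)
    score = float(model.calibration(model.decision(x)))
    return call_from_score(
        score,
        cutoff=model.cutoff,
        sample_id=str(sample.name),
        model_organ=model.contrast_organ,
    )


def infer_patient_from_scores(
    lung_result: Optional[MethylScoreResult],
    extra_result: Optional[MethylScoreResult],
    extra_organ: Site | str,
) -> PatientDiagnosis:
    """Patient-level diagnosis from per-lesion Methyl Score calls.

    A lung-site sample called lung-origin is the primary (P), non-lung
    origin a metastasis (M); the polarity flips for the extrathoracic
    sample. (P,P) -> independent multiple primaries; (P,M) -> metastatic
    from the lung; (M,P) -> metastatic from the extrathoracic organ;
    (M,M) is self-contradictory -> indeterminate. With a single scored
    sample only its lesion label is set.
    """
    if lung_result is None and extra_result is None:
        raise ValueError("at least one lesion result is required")
    extra_organ = Site(extra_organ)

    def lesion(result: Optional[MethylScoreResult], is_lung: bool) -> LesionLabel:
        if result is None or result.call is OriginCall.INDETERMINATE:
            return LesionLabel.UNAVAILABLE
        lc = result.call is OriginCall.LC_ORIGIN
        return LesionLabel.P if lc == is_lung else LesionLabel.M

    lung_label = lesion(lung_result, is_lung=True)
    extra_label = lesion(extra_result, is_lung=False)
    pid = (lung_result or extra_result).sample_id

    if LesionLabel.UNAVAILABLE in (lung_label, extra_label):
        relationship = DiagnosisRelationship.NOT_EVALUABLE
        too = TOO.INCONCLUSIVE
    elif lung_label is LesionLabel.P and extra_label is LesionLabel.P:
        relationship = DiagnosisRelationship.MULTIPLE_PRIMARY
        too = TOO.NOT_APPLICABLE
    elif lung_label is LesionLabel.P:
        relationship = DiagnosisRelationship.METASTATIC
        too = TOO.LUNG
    elif extra_label is LesionLabel.P:
        relationship = DiagnosisRelationship.METASTATIC
        too = TOO(extra_organ.value)
    else:
        relationship = DiagnosisRelationship.INDETERMINATE
        too = TOO.INCONCLUSIVE

    return PatientDiagnosis(
        patient_id=pid,
        lung_label=lung_label,
        extra_label=extra_label,
        extra_site=extra_organ,
        relationship=relationship,
        too=too,
        evidence_source=EvidenceSource.METHYLATION,
    )


def pca_projection(mbs: MBSMatrix, n_components: int = 2) -> pd.DataFrame:
    """Mean-centered projection onto the top principal axes (QC view)."""
    X = mbs.values.to_numpy()
    if X.shape[0] < 2:
        raise ValueError("PCA requires >= 2 samples")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds data rank bound {max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return pd.DataFrame(
        coords,
        index=mbs.values.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
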