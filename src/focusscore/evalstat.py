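"""Splitting, classification metrics, trial summaries, and the assay-level
promotion-activity decision rule.

The assay protocol evaluates a focus classifier with a stratified
train/validation/test split (70/10/20 in the main design; 90/10 plus an
external test set when transferring to other chemicals), accuracy and recall
at threshold 0.5, and the ROC/AUC.  At the plate level, a chemical is called
a tumor promoter when the focus count rises significantly above the vehicle
control — one-way ANOVA plus Dunnett many-to-one comparisons — at two
consecutive tested concentrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .synthgen import DatasetManifest

__all__ = [
    "SplitSpec",
    "EvalReport",
    "PromotionInput",
    "PromotionResult",
    "stratified_split",
    "confusion_at_threshold",
    "roc_auc",
    "evaluate_scores",
    "summarize_trials",
    "promotion_call",
]


@dataclass(frozen=True)
class SplitSpec:
    """Stratified split fractions; the main protocol uses (0.7, 0.1, 0.2)."""

    fractions: tuple[float, ...] = (0.7, 0.1, 0.2)
    names: tuple[str, ...] = ("train", "val", "test")
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.names):
            raise ValueError("one name per fraction")
        if any(not (0 < f <= 1) for f in self.fractions):
            raise ValueError("fractions must be in (0, 1]")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> np.ndarray:
    """Allocate n items proportionally; remainders go to the largest fractional
    parts (ties to the earlier split)."""
    exact = np.asarray(fractions) * n
    base = np.floor(exact).astype(int)
    rem = n - base.sum()
    if rem > 0:
        frac = exact - base
        order = np.argsort(-frac, kind="stable")
        base[order[:rem]] += 1
    return base


def stratified_split(manifest: DatasetManifest, spec: SplitSpec) -> DatasetManifest:
    """Assign split labels per-class: shuffle with the spec seed, then allocate
    with largest-remainder rounding so each split's class ratio is within one
    sample of the overall ratio."""
    df = manifest.records.copy().reset_index(drop=True)
    rng = np.random.default_rng(spec.seed)
    assign = np.empty(len(df), dtype=object)
    groups = [df.index.to_numpy()] if not spec.stratified else [
        df.index[df["label"] == lab].to_numpy() for lab in sorted(df["label"].unique())
    ]
    for idx in groups:
        if len(idx) < len(spec.fractions):
            raise ValueError(
                f"class with {len(idx)} samples cannot fill {len(spec.fractions)} splits")
        perm = rng.permutation(len(idx))
        sizes = _largest_remainder(len(idx), spec.fractions)
        start = 0
        for name, size in zip(spec.names, sizes):
            assign[idx[perm[start:start + size]]] = name
            start += size
    df["split"] = assign
    return DatasetManifest(df)


def confusion_at_threshold(scores, labels, threshold: float = 0.5) -> dict[str, int]:
    """2x2 confusion counts with positive prediction at score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size == 0:
        raise ValueError("empty input")
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    pred = s >= threshold
    pos = y == 1
    return {
        "TP": int(np.sum(pred & pos)),
        "FP": int(np.sum(pred & ~pos)),
        "FN": int(np.sum(~pred & pos)),
        "TN": int(np.sum(~pred & ~pos)),
    }


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all distinct score thresholds and the
    trapezoidal AUC.

    With tied scores the trapezoid over tie-grouped points equals the
    Mann-Whitney concordance probability with ties counted 1/2, so AUC is
    0.5 for pure ties and 1.0 for a perfect separator.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for ROC")
    fpr, tpr, _ = _roc_curve(y, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(_trapezoid_auc(fpr, tpr))


@dataclass(frozen=True)
class EvalReport:
    """Classification metrics of one model on one dataset."""

    confusion: dict[str, int]
    accuracy: float
    recall: float
    roc: np.ndarray
    auc: float
    n: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"confusion": self.confusion, "accuracy": self.accuracy,
                   "recall": self.recall, "auc": self.auc, "n": self.n,
                   "roc": self.roc.tolist()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def roc_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.roc, columns=["FPR", "TPR"]).to_csv(path, index=False)


def evaluate_scores(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Full report: confusion at the threshold, accuracy, recall (sensitivity
    on the positive, transformed-focus class), ROC and AUC."""
    conf = confusion_at_threshold(scores, labels, threshold)
    n = sum(conf.values())
    acc = (conf["TP"] + conf["TN"]) / n
    denom = conf["TP"] + conf["FN"]
    rec = conf["TP"] / denom if denom else float("nan")
    roc, auc_val = roc_auc(scores, labels)
    return EvalReport(confusion=conf, accuracy=acc, recall=rec, roc=roc,
                      auc=auc_val, n=n)


def summarize_trials(reports: list[EvalReport]) -> dict[str, dict[str, float]]:
    """Mean and sample SD (ddof=1) of accuracy, recall and AUC over trials.

    A single report yields SD 0 with ``n=1`` flagged.
    """
    if not reports:
        raise ValueError("need at least one report")
    out: dict[str, dict[str, float]] = {}
    single = len(reports) == 1
    for name in ("accuracy", "recall", "auc"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        sd = 0.0 if single else float(np.std(vals, ddof=1))
        out[name] = {"mean": float(np.mean(vals)), "sd": sd,
                     "n": len(reports), "n1_flag": single}
    return out


# ---------------------------------------------------------------------------
# Promotion-activity decision rule

@dataclass(frozen=True)
class PromotionInput:
    """Per-well focus counts by chemical concentration.

    ``counts`` maps concentration -> list of nonnegative integer well counts;
    ``control`` names the vehicle-control concentration (typically 0).
    Concentrations are compared on their numeric order.
    """

    counts: dict[float, list[int]]
    control: float = 0.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.control not in self.counts:
            raise ValueError("control concentration missing from counts")
        for conc, wells in self.counts.items():
            if len(wells) < 2:
                raise ValueError(f"concentration {conc}: need >= 2 wells")
            if any((w < 0 or int(w) != w) for w in wells):
                raise ValueError("well counts must be nonnegative integers")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_csv(cls, path: str | Path, control: float = 0.0,
                 alpha: float = 0.05) -> "PromotionInput":
        df = pd.read_csv(path)
        counts = {float(c): g["count"].astype(int).tolist()
                  for c, g in df.groupby("concentration")}
        return cls(counts=counts, control=control, alpha=alpha)


@dataclass(frozen=True)
class PromotionResult:
    """Outcome of the promotion rule for one chemical."""

    positive: bool
    anova_p: float
    dunnett_p: dict[float, float]      # per non-control concentration
    significant: dict[float, bool]
    flagged_pairs: list[tuple[float, float]]
    degenerate: bool = False
    anova_gated: bool = False
    alternative: str = "two-sided"


def promotion_call(data: PromotionInput, anova_gate: bool = False,
                   alternative: str = "two-sided") -> PromotionResult:
    """Apply the assay decision rule to per-well focus counts.

    One-way ANOVA across all groups is reported alongside Dunnett
    many-to-one comparisons against the control.  The chemical is called a
    promoter when two adjacent members of the concentration ladder are both
    significant at ``alpha`` (optionally only if the ANOVA is also
    significant, ``anova_gate=True``).

    ``alternative`` is ``"two-sided"`` (default) or ``"greater"``; promotion
    screens for an *increase* in focus frequency, and published
    per-concentration summaries of the reference promoter plate are
    consistent with the one-sided test, so ``"greater"`` is offered as a
    first-class mode.

    Degenerate plates with zero variance everywhere cannot support the test;
    groups are then flagged significant iff their mean differs from the
    control, and the result carries ``degenerate=True``.
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    concs = sorted(c for c in data.counts if c != data.control)
    control = np.asarray(data.counts[data.control], dtype=float)
    groups = [np.asarray(data.counts[c], dtype=float) for c in concs]

    all_groups = [control] + groups
    pooled_var = sum(np.sum((g - g.mean()) ** 2) for g in all_groups)
    if pooled_var == 0:
        if alternative == "greater":
            sig = {c: bool(g.mean() > control.mean()) for c, g in zip(concs, groups)}
        else:
            sig = {c: bool(g.mean() != control.mean()) for c, g in zip(concs, groups)}
        anova_p = 1.0 if len({g.mean() for g in all_groups}) == 1 else 0.0
        dunnett_p = {c: (0.0 if s else 1.0) for c, s in sig.items()}
    else:
        anova_p = float(stats.f_oneway(*all_groups).pvalue)
        res = stats.dunnett(*groups, control=control, alternative=alternative)
        dunnett_p = {c: float(p) for c, p in zip(concs, res.pvalue)}
        sig = {c: dunnett_p[c] < data.alpha for c in concs}

    gate_ok = (anova_p < data.alpha) if anova_gate else True
    pairs = [(concs[i], concs[i + 1]) for i in range(len(concs) - 1)
             if sig[concs[i]] and sig[concs[i + 1]]]
    return PromotionResult(positive=bool(pairs) and gate_ok,
                           anova_p=anova_p, dunnett_p=dunnett_p,
                           significant=sig, flagged_pairs=pairs,
                           degenerate=(pooled_var == 0),
                           anova_gated=anova_gate, alternative=alternative)
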