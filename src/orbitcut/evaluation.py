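"""Accuracy and reliability statistics for segmentation validation.

Covers the standard battery for volumetric segmentation studies: Jaccard
similarity (JS) and Dice coefficient (DC) for spatial overlap, two-way
mixed-effects intraclass correlation (ICC) for intra-/inter-observer
agreement of repeated volume measurements, paired and independent Student
t tests for mean comparisons, and percentage difference versus a known
ground-truth volume. p-values are two-sided throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["RatingMatrix", "MetricsReport", "jaccard", "dice", "icc_two_way_mixed",
           "paired_t", "independent_t", "percentage_difference"]


@dataclass
class RatingMatrix:
    """Subjects x raters matrix of repeated volume measurements (cm^3)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("rating matrix must be 2-D (subjects x raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 subjects and >= 2 raters, got {n}x{k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rating matrix contains non-finite cells")


def _as_masks(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def jaccard(a, b) -> float:
    """Jaccard similarity |A∩B| / |A∪B|.

    0 means completely dissimilar, 1 identical; two empty masks are
    identical and score 1.
    """
    a, b = _as_masks(a, b)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def dice(a, b) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1 for two empty masks."""
    a, b = _as_masks(a, b)
    denom = np.count_nonzero(a) + np.count_nonzero(b)
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom


def icc_two_way_mixed(m: RatingMatrix | np.ndarray, kind: str = "consistency") -> float:
    """Two-way mixed-effects, single-measure ICC.

    ``kind='consistency'`` is ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E),
    the usual reading for a fixed set of raters; ``kind='agreement'`` adds
    the rater variance term (absolute agreement). Mean squares come from
    the two-way ANOVA decomposition of the subjects x raters table.
    """
    if not isinstance(m, RatingMatrix):
        m = RatingMatrix(np.asarray(m))
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msc = ss_cols / (k - 1)
    if kind == "consistency":
        denom = msr + (k - 1) * mse
    elif kind == "agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    else:
        raise ValueError(f"unknown ICC kind {kind!r}")
    if denom == 0:
        raise ValueError("ICC undefined: zero between-subject variance and zero error (0/0)")
    return float((msr - mse) / denom)


def paired_t(x, y) -> tuple[float, float]:
    """Paired-sample Student t test; returns (t, two-sided p), df = n-1."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired t test needs two equal-length 1-D samples of size >= 2")
    d = x - y
    if np.var(d, ddof=1) == 0:
        raise ValueError("paired t undefined: zero variance of the differences")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def independent_t(x, y) -> tuple[float, float]:
    """Independent-sample Student t (pooled variance), df = n1+n2-2."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.size < 2 or y.size < 2:
        raise ValueError("independent t test needs two 1-D samples of size >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("independent t undefined: both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def percentage_difference(measured: float, truth: float) -> float:
    """|truth - measured| / truth x 100, versus a known ground-truth volume."""
    if truth <= 0:
        raise ValueError(f"truth volume must be positive, got {truth}")
    return abs(truth - measured) / truth * 100.0


@dataclass
class MetricsReport:
    """Structured evaluation results for one prediction/truth comparison."""

    per_label: dict[int, dict[str, float]] = field(default_factory=dict)
    icc: float | None = None
    icc_kind: str | None = None
    t: float | None = None
    p: float | None = None
    label_names: dict[int, str] = field(default_factory=dict)

    @classmethod
    def from_label_maps(cls, pred, truth) -> "MetricsReport":
        """Per-tissue JS/DC between a predicted and a truth label map."""
        if pred.shape != truth.shape:
            raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
        labels = sorted(set(np.unique(truth.labels)) | set(np.unique(pred.labels)))
        per_label = {}
        for lab in labels:
            a, b = pred.mask(lab), truth.mask(lab)
            per_label[int(lab)] = {"JS": jaccard(a, b), "DC": dice(a, b)}
        names = dict(truth.label_names)
        names.update(pred.label_names)
        return cls(per_label=per_label, label_names=names)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "per_label": {
                self.label_names.get(l, f"label_{l}"): {k: round(v, 6) for k, v in d.items()}
                for l, d in sorted(self.per_label.items())
            },
        }
        if self.icc is not None:
            obj["icc"] = {"value": self.icc, "kind": self.icc_kind}
        if self.t is not None:
            obj["t_test"] = {"t": self.t, "p": self.p}
        Path(path).write_text(json.dumps(obj, indent=2))

    def to_csv(self) -> str:
        lines = ["label,name,metric,value"]
        for lab, d in sorted(self.per_label.items()):
            for metric, value in sorted(d.items()):
                lines.append(f"{lab},{self.label_names.get(lab, f'label_{lab}')},{metric},{value:.6f}")
        return "\n".join(lines) + "\n"
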