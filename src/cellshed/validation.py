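"""Segmentation accuracy against per-cell ground truth.

The headline per-image score is the fraction of annotated cells whose
mask is recovered by the segmentation, expressed in percent:

    agreement_i = 100 * (sum_j B_j) / N

where ``B_j`` is 1 when truth cell ``j`` is matched by a predicted
region and 0 otherwise.  The strict reading of "matched" — pixel-exact
identity of the two masks — is available as ``criterion="exact"``; the
default is an IoU >= 0.5 overlay criterion, with greedy one-to-one
assignment so a single merged region cannot claim two cells.  The
complementary quantity ``error = 100 - agreement`` is reported as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellMask",
    "GroundTruth",
    "MatchReport",
    "SuiteSummary",
    "mask_agreement",
    "count_mae",
    "suite_summary",
]


@dataclass
class CellMask:
    """One annotated cell, stored bbox-cropped for memory economy."""

    row: int
    col: int
    mask: np.ndarray = field(repr=False)  # local boolean patch

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.mask))

    def to_full(self, shape: tuple[int, int]) -> np.ndarray:
        full = np.zeros(shape, dtype=bool)
        h, w = self.mask.shape
        full[self.row: self.row + h, self.col: self.col + w] = self.mask
        return full

    @classmethod
    def from_full(cls, full: np.ndarray) -> "CellMask":
        full = np.asarray(full, dtype=bool)
        rows, cols = np.nonzero(full)
        if rows.size == 0:
            return cls(0, 0, np.zeros((0, 0), dtype=bool))
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
        return cls(r0, c0, full[r0:r1, c0:c1].copy())


@dataclass
class GroundTruth:
    """Annotated cells of one frame."""

    shape: tuple[int, int]
    cells: list[CellMask]

    @property
    def n(self) -> int:
        return len(self.cells)


@dataclass
class MatchReport:
    """Per-image agreement between prediction and ground truth."""

    agreement: float          # percent of truth cells matched
    matched: list[bool]       # indicator B_j per truth cell
    criterion: str
    iou_threshold: float
    n_truth: int
    n_pred: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    # (truth index, predicted label, IoU) of each accepted match

    @property
    def error(self) -> float:
        return 100.0 - self.agreement


def _pred_census(pred: np.ndarray) -> np.ndarray:
    flat = pred.ravel()
    top = int(flat.max(initial=0))
    return np.bincount(flat[flat > 0], minlength=top + 1)


def mask_agreement(
    pred: np.ndarray,
    truth: GroundTruth,
    criterion: str = "iou",
    iou_threshold: float = 0.5,
) -> MatchReport:
    """Score a predicted label map against annotated cell masks.

    Every candidate (truth cell, predicted region) pair with non-zero
    overlap is ranked by descending IoU (ties broken by smaller predicted
    label, then smaller truth index) and assigned greedily one-to-one.
    ``B_j`` is 1 when the assigned pair satisfies the criterion.
    """
    if criterion not in ("iou", "exact"):
        raise ValueError("criterion must be 'iou' or 'exact'")
    if truth.n == 0:
        raise ValueError("ground truth has no cells; agreement undefined")
    pred = np.asarray(pred)
    if pred.shape != tuple(truth.shape):
        raise ValueError("prediction and ground truth shapes differ")
    pred_areas = _pred_census(pred)

    candidates: list[tuple[float, int, int]] = []  # (-iou, label, truth idx)
    pair_iou: dict[tuple[int, int], float] = {}
    for j, cell in enumerate(truth.cells):
        h, w = cell.mask.shape
        window = pred[cell.row: cell.row + h, cell.col: cell.col + w]
        inside = window[cell.mask]
        inter = np.bincount(inside[inside > 0], minlength=pred_areas.size)
        t_area = cell.area
        for lab in np.nonzero(inter)[0]:
            iou = inter[lab] / (t_area + pred_areas[lab] - inter[lab])
            if criterion == "exact" and not (
                inter[lab] == t_area == pred_areas[lab]
            ):
                continue
            pair_iou[(j, int(lab))] = float(iou)
            candidates.append((-float(iou), int(lab), j))

    candidates.sort()
    matched = [False] * truth.n
    used_labels: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for neg_iou, lab, j in candidates:
        if matched[j] or lab in used_labels:
            continue
        iou = -neg_iou
        if criterion == "iou" and iou < iou_threshold:
            continue
        matched[j] = True
        used_labels.add(lab)
        pairs.append((j, lab, iou))

    agreement = 100.0 * sum(matched) / truth.n
    return MatchReport(
        agreement=agreement,
        matched=matched,
        criterion=criterion,
        iou_threshold=iou_threshold,
        n_truth=truth.n,
        n_pred=int(np.count_nonzero(pred_areas)),
        pairs=sorted(pairs),
    )


def count_mae(pred_counts, true_counts) -> float:
    """Mean absolute error between predicted and reference cell counts."""
    pred = np.asarray(pred_counts, dtype=float)
    true = np.asarray(true_counts, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("count lists must be equal-length and non-empty")
    return float(np.mean(np.abs(pred - true)))


@dataclass
class SuiteSummary:
    """Mean and sample standard deviation of per-image agreement."""

    mean_agreement: float
    std_agreement: float
    n_images: int

    @property
    def mean_error(self) -> float:
        return 100.0 - self.mean_agreement

    @property
    def std_error(self) -> float:
        return self.std_agreement


def suite_summary(reports: list[MatchReport]) -> SuiteSummary:
    """Summarize per-image agreement over a validation suite (n >= 2)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports for a mean and std")
    vals = np.array([r.agreement for r in reports], dtype=float)
    return SuiteSummary(
        mean_agreement=float(vals.mean()),
        std_agreement=float(vals.std(ddof=1)),
        n_images=len(reports),
    )
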