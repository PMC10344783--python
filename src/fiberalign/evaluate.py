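"""Scoring machinery: alignment error taxonomy, karyotype accuracy, distance
matrices, contact-matrix correlation and the exact binomial preference test.

The error taxonomy compares each selected spot against simulator ground
truth, per fiber and per locus:

* true coverage  -- the fiber's true spot was detected and selected (TP->TP);
* Type I   -- the fiber's spot was dropped, yet a false candidate was
  selected in its place (TN->FP);
* Type II  -- the fiber's spot was detected, but a different spot was
  selected (TP->FP);
* Type III -- the fiber's spot was detected and omitted (TP->FN).

Coverage + Type II + Type III account exactly for every detected true spot,
so the error budget closes by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .karyotype import KaryotypeResult
from .reference import ReferenceMap
from .simulate import SimulatedCell

__all__ = ["ClassificationReport", "classify_selections", "karyotype_accuracy",
           "median_distance_matrix", "match_bins", "contact_comparison",
           "binomial_preference_test"]


@dataclass
class ClassificationReport:
    """Per-chromosome selection-error bookkeeping (counts, not rates)."""

    chromosome: str
    cell_id: object
    n_loci: int
    copies: int
    n_detected: int        # true spots surviving dropout
    n_covered: int         # TP -> TP
    n_type2: int           # TP -> FP
    n_type3: int           # TP -> FN
    n_type1: int           # TN -> FP
    n_type1_den: int       # dropped loci with >= 1 false candidate present

    @property
    def n_fiber_loci(self) -> int:
        return self.n_loci * self.copies

    @property
    def coverage_rate(self) -> float:
        return self.n_covered / self.n_fiber_loci if self.n_fiber_loci else float("nan")

    @property
    def type2_rate(self) -> float:
        return self.n_type2 / self.n_fiber_loci if self.n_fiber_loci else float("nan")

    @property
    def type3_rate(self) -> float:
        return self.n_type3 / self.n_fiber_loci if self.n_fiber_loci else float("nan")

    @property
    def type1_rate(self) -> float:
        """Type I rate over dropped loci that offered a false candidate."""
        return self.n_type1 / self.n_type1_den if self.n_type1_den else float("nan")

    @property
    def type1_rate_global(self) -> float:
        """Type I rate over all fiber loci (alternate denominator)."""
        return self.n_type1 / self.n_fiber_loci if self.n_fiber_loci else float("nan")


def classify_selections(traces, cell: SimulatedCell, chrom: str) -> ClassificationReport:
    """Compare aligned traces with simulator ground truth for one chromosome.

    ``traces`` may be a list of PolymerTraces or a :class:`KaryotypeResult`.
    Each trace is attributed to the ground-truth fiber contributing the
    majority of its selected true spots; at most one trace per fiber (the one
    with the most own-fiber selections) enters the per-locus comparison.
    """
    if isinstance(traces, KaryotypeResult):
        traces = traces.traces
    spots = cell.chromosome_spots(chrom)
    copies = cell.copy_numbers[chrom]
    if copies and chrom not in cell.truth_xyz:
        raise ValueError(f"cell carries no ground truth for {chrom}")
    T = cell.truth_xyz[chrom].shape[1] if copies else _infer_n_loci(traces, spots)

    detected = np.zeros((copies, T), dtype=bool)
    tp = spots[spots["label"] == "TP"]
    detected[tp["fiber_id"].to_numpy(dtype=int), tp["locus_order"].to_numpy(dtype=int) - 1] = True
    # candidates per locus (any spot), and per (fiber, locus) own-spot ids
    cand_count = np.zeros(T, dtype=int)
    for t, n in spots["locus_order"].value_counts().items():
        cand_count[int(t) - 1] = n

    # trace -> fiber attribution by majority vote over selected true spots
    claims: dict[int, tuple[int, object]] = {}
    for tr in traces:
        sel = spots.loc[tr.spot_ids]
        own = sel[sel["label"] == "TP"]
        if len(own) == 0:
            continue
        fiber = int(own["fiber_id"].value_counts().idxmax())
        n_own = int((own["fiber_id"] == fiber).sum())
        if fiber not in claims or n_own > claims[fiber][0]:
            claims[fiber] = (n_own, tr)

    n_covered = n_type2 = n_type3 = n_type1 = n_type1_den = 0
    for f in range(copies):
        tr = claims.get(f, (0, None))[1]
        sel_fiber = np.full(T, -2, dtype=int)   # -2 = locus not assigned, -1 = stray
        if tr is not None:
            sel = spots.loc[tr.spot_ids]
            sel_fiber[sel["locus_order"].to_numpy(dtype=int) - 1] = \
                sel["fiber_id"].to_numpy(dtype=int)
        for t in range(T):
            if detected[f, t]:
                # true signal present for this fiber: the taxonomy grades the
                # *type* of spot its trace selected (a true spot from a sister
                # fiber still counts TP->TP; cross-fiber misselection is the
                # chromatid module's concern)
                if sel_fiber[t] >= 0:
                    n_covered += 1
                elif sel_fiber[t] == -1:
                    n_type2 += 1
                else:
                    n_type3 += 1
            else:
                # fiber's own signal dropped: selecting a stray here is the
                # Type I error
                if cand_count[t] > 0:
                    n_type1_den += 1
                    if sel_fiber[t] == -1:
                        n_type1 += 1
    return ClassificationReport(chrom, cell.cell_id, T, copies,
                                int(detected.sum()), n_covered, n_type2, n_type3,
                                n_type1, n_type1_den)


def _infer_n_loci(traces, spots) -> int:
    if traces:
        return traces[0].n_loci
    if len(spots):
        return int(spots["locus_order"].max())
    return 0


def karyotype_accuracy(predicted, truth, max_ploidy: int = 4):
    """Confusion matrix over true x predicted ploidy plus under/overcounts.

    ``predicted`` and ``truth`` are aligned sequences of per-chromosome copy
    numbers.  Returns a dict with the confusion matrix (DataFrame), the
    per-ploidy detection fraction (diagonal / row sum) and the counts of
    undercounted and overcounted chromosomes.
    """
    pred = np.asarray(list(predicted), dtype=int)
    true = np.asarray(list(truth), dtype=int)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    hi = max(max_ploidy, pred.max(initial=0), true.max(initial=0))
    mat = np.zeros((hi + 1, hi + 1), dtype=int)
    np.add.at(mat, (true, pred), 1)
    confusion = pd.DataFrame(mat,
                             index=pd.Index(range(hi + 1), name="true"),
                             columns=pd.Index(range(hi + 1), name="predicted"))
    row_sums = mat.sum(axis=1)
    with np.errstate(invalid="ignore"):
        detection = np.where(row_sums > 0, np.diag(mat) / np.maximum(row_sums, 1), np.nan)
    return {
        "confusion": confusion,
        "detection_fraction": pd.Series(detection, index=confusion.index),
        "n_undercount": int((pred < true).sum()),
        "n_overcount": int((pred > true).sum()),
    }


def median_distance_matrix(traces, n_loci: int | None = None) -> np.ndarray:
    """Untabulated median pairwise distance matrix over single-fiber traces.

    Entry (a, b) is the median over traces of |pos_a - pos_b| restricted to
    traces where both loci were assigned; gap loci are excluded pairwise.
    Pairs never co-assigned are NaN.  Symmetric with a zero diagonal.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    T = n_loci or traces[0].n_loci
    stack = np.full((len(traces), T, T), np.nan)
    for k, tr in enumerate(traces):
        pos = tr.positions()
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        stack[k] = d
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        med = np.nanmedian(stack, axis=0)
    idx = np.arange(T)
    med[idx, idx] = np.where(np.isnan(med[idx, idx]), med[idx, idx], 0.0)
    return med


def match_bins(ref: ReferenceMap, bin_size_bp: float):
    """Map imaged loci onto integer genomic bins for contact comparison.

    For every integer bin the imaged locus (ordered 5'->3') closest to the
    bin coordinate is kept and all other loci are dropped; the same bins are
    retained on the contact-matrix side.  Returns ``(locus_idx, bin_idx)``,
    0-based arrays of equal length.
    """
    pos = ref.positions_bp
    bins = np.arange(0, pos[-1] + bin_size_bp, bin_size_bp)
    locus_idx, bin_idx, seen = [], [], set()
    for b, edge in enumerate(bins):
        i = int(np.argmin(np.abs(pos - edge)))
        if i not in seen:
            seen.add(i)
            locus_idx.append(i)
            bin_idx.append(b)
    return np.asarray(locus_idx), np.asarray(bin_idx)


def contact_comparison(dist_matrix, contact_matrix, bin_map=None,
                       threshold_nm: float | None = None) -> float:
    """Spearman correlation between imaging distances and contact frequencies.

    With ``threshold_nm`` unset, correlates log median distances with log
    contact counts over the valid upper-triangle pairs.  With it set,
    ``dist_matrix`` must be a (traces, T, T) stack; the imaging side becomes
    the fraction of traces with distance below the threshold (a pseudo
    contact frequency).  ``bin_map = (locus_idx, contact_idx)`` restricts
    both matrices to matched bins before comparison.
    """
    dist = np.asarray(dist_matrix, dtype=float)
    contacts = np.asarray(contact_matrix, dtype=float)
    if threshold_nm is not None:
        if dist.ndim != 3:
            raise ValueError("threshold mode needs a (traces, T, T) distance stack")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            img = np.nanmean(dist < threshold_nm, axis=0)
        log_transform = False
    else:
        if dist.ndim != 2:
            raise ValueError("expected a 2-D median distance matrix")
        img = dist
        log_transform = True
    if bin_map is not None:
        li, ci = bin_map
        img = img[np.ix_(li, li)]
        contacts = contacts[np.ix_(ci, ci)]
    if img.shape != contacts.shape:
        raise ValueError("distance and contact matrices disagree after bin matching")
    n = img.shape[0]
    iu = np.triu_indices(n, k=1)
    x, y = img[iu], contacts[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    if log_transform:
        ok &= (x > 0) & (y > 0)
        x, y = np.log(x[ok]), np.log(y[ok])
    else:
        x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("not enough valid pairs for a correlation")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def binomial_preference_test(k: int, n: int, p: float = 0.5) -> float:
    """One-sided exact binomial tail P(X >= k | n, p) by direct summation."""
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if p == 0.5:
        total = sum(math.comb(n, i) for i in range(k, n + 1))
        return total / 2.0**n
    return float(sum(math.comb(n, i) * p**i * (1 - p) ** (n - i)
                     for i in range(k, n + 1)))
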