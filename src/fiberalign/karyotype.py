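"""Polymer fiber karyotyping: copy numbers by iterative path subtraction.

All physically plausible fibers of a chromosome are discovered one at a time:
the shortest (most likely) path is extracted, its nodes are subtracted from
the graph, and the search repeats until no path can be extended or the next
path's score exceeds a physical-likelihood threshold.  The threshold is the
score a polymer achieves when the observed spatial distances no longer abide
by the genomic intervals separating the loci -- estimated by permuting the
reference's interval sequence (a scrambled null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aligner import PolymerTrace, align
from .model import (ChainParams, expected_variance, gap_extension_cost,
                    gap_scaled_cost, neg_log_bond)
from .reference import ReferenceMap
from .simulate import (DEFAULT_LOC_JITTER_NM, DEFAULT_NUCLEAR_RADIUS_NM,
                       fiber_spot_table, inject_noise, simulate_polymer)

__all__ = ["KaryotypeResult", "scramble_threshold", "karyotype", "karyotype_cell",
           "stringent_trisomy_filter"]


@dataclass
class KaryotypeResult:
    """Copy-number call for one chromosome in one cell."""

    chromosome: str
    cell_id: object
    traces: list            # accepted, node-disjoint PolymerTraces, discovery order
    residual_spot_ids: np.ndarray
    threshold: float | None
    rejected_scores: list = field(default_factory=list)

    @property
    def copy_number(self) -> int:
        return len(self.traces)

    @property
    def scores(self) -> list:
        return [t.score for t in self.traces]


def _trace_statistic(trace: PolymerTrace, params: ChainParams) -> float:
    if params.score_threshold_mode == "raw":
        return trace.score
    return trace.normalized_score


def _forced_path_score(spots: pd.DataFrame, ref: ReferenceMap,
                       params: ChainParams) -> float | None:
    """Per-locus score of the path through the first candidate of every
    detected locus, with no optimization.

    This is the likelihood of the polymer *as laid down*, the statistic the
    scrambled null is built from: re-optimizing the alignment would let the
    null adaptively skip its worst-fitting loci and deflate the threshold.
    When a locus offers several candidates (stray localizations), the one
    nearest the previously selected spot is taken -- the chain-following
    choice a real fiber's spots dominate -- so strays do not inflate the
    null.
    """
    srt = spots.sort_values("locus_order", kind="stable")
    all_orders = srt["locus_order"].to_numpy(dtype=int)
    all_xyz = srt[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    uniq = np.unique(all_orders)
    if uniq.size < 2:
        return None
    orders_sel, xyz_sel = [], []
    prev = None
    for t in uniq:
        cand = all_xyz[all_orders == t]
        if prev is None or len(cand) == 1:
            pick = cand[0]
        else:
            pick = cand[np.argmin(np.linalg.norm(cand - prev, axis=1))]
        orders_sel.append(int(t))
        xyz_sel.append(pick)
        prev = pick
    orders = np.asarray(orders_sel, dtype=int)
    xyz = np.asarray(xyz_sel, dtype=float)
    L = np.abs(np.diff(ref.positions_bp[orders - 1]))
    R = np.linalg.norm(np.diff(xyz, axis=0), axis=1) / params.pixel_nm
    sig = params.sigma_default_nm
    s2 = expected_variance(L, sig, sig, params)
    w = neg_log_bond(R, s2, params.spherical_term)
    c = np.diff(orders)
    if params.gap_mode == "affine":
        gap_ext = gap_extension_cost(float(np.median(ref.intervals())), sig, params)
        w = w + (c - 1.0) * gap_ext
    else:
        w = gap_scaled_cost(w, c, params)
    total = float(np.maximum(w, 0.0).sum())
    if params.score_threshold_mode == "raw":
        return total
    return total / len(orders)


def scramble_threshold(ref: ReferenceMap, params: ChainParams, n_perm: int = 20,
                       seed=None, fnr: float = 0.0, fpr: float = 0.0,
                       radius_nm: float | None = None,
                       nuclear_radius_nm: float = DEFAULT_NUCLEAR_RADIUS_NM,
                       null_percentile: float = 50.0) -> float:
    """Physical-likelihood score cutoff from a scrambled-interval null.

    For each permutation a Gaussian-chain polymer is simulated under the
    *true* reference (with the analysis compaction scale ``params.tau``, and
    optionally confined to ``radius_nm``), degraded with the same dropout
    and stray rates as the data being thresholded, and *scored as laid
    down* against a reference whose interval sequence has been permuted:
    its observed spatial distances no longer abide by the genomic intervals
    separating the loci.  The threshold is the ``null_percentile``
    percentile of the null scores (default the median): paths scoring below
    it fit their genomic intervals better than a typical interval-scrambled
    polymer.  Structurally invalid paths (unbridgeable gaps, too few
    assigned loci) are already rejected by the aligner itself, so the
    threshold's role is to cut egregious, physically unlikely paths rather
    than to perform fine discrimination.

    Scores are normalized per assigned locus unless
    ``params.score_threshold_mode == "raw"``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if ref.n_loci < 3:
        raise ValueError("scramble threshold needs at least 3 reference loci")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    radius = np.inf if radius_nm is None else radius_nm
    scores = []
    for _ in range(n_perm):
        chain = simulate_polymer(ref, params, radius, rng)
        truth = fiber_spot_table(ref.chromosome, None, chain, 0, DEFAULT_LOC_JITTER_NM, rng)
        noisy = inject_noise(truth, ref, fnr, fpr, nuclear_radius_nm, rng,
                             center=chain.mean(axis=0))
        forced = _forced_path_score(noisy, ref.scrambled(rng), params)
        if forced is not None:
            scores.append(forced)
    if not scores:
        raise RuntimeError("no scrambled-null score could be computed")
    return float(np.percentile(scores, null_percentile))


def karyotype(cell_spots: pd.DataFrame, ref: ReferenceMap, params: ChainParams,
              threshold: float | None, cell_id=None) -> KaryotypeResult:
    """Count chromosome copies by iterative shortest-path subtraction.

    Repeats align -> accept -> subtract until no path can be extended or the
    next path scores above the effective threshold
    (``threshold * params.threshold_headroom``).  The search is greedy: the
    first fiber discovered selects as many loci as it sees fit, and a spot
    once selected cannot be re-selected by subsequent fibers, so traces are
    node-disjoint by construction.
    """
    traces: list[PolymerTrace] = []
    rejected: list[float] = []
    remaining = cell_spots
    effective = None if threshold is None else threshold * params.threshold_headroom
    for _ in range(params.max_fibers):
        if len(remaining) == 0:
            break
        trace = align(remaining, ref, params, cell_id=cell_id)
        if trace is None:
            break
        stat = _trace_statistic(trace, params)
        if effective is not None and stat > effective:
            rejected.append(stat)
            break
        traces.append(trace)
        remaining = remaining.drop(index=trace.spot_ids)
    return KaryotypeResult(ref.chromosome, cell_id, traces,
                           remaining.index.to_numpy(), effective, rejected)


def karyotype_cell(spots: pd.DataFrame, refs: dict[str, ReferenceMap],
                   params, thresholds=None, cell_id=None) -> dict[str, KaryotypeResult]:
    """Karyotype every chromosome of one cell.

    ``params`` and ``thresholds`` may be single values or per-chromosome
    dicts (compaction scales are chromosome specific).
    """
    results = {}
    for chrom, ref in refs.items():
        p = params[chrom] if isinstance(params, dict) else params
        thr = thresholds.get(chrom) if isinstance(thresholds, dict) else thresholds
        sub = spots[spots["chromosome"] == chrom]
        results[chrom] = karyotype(sub, ref, p, thr, cell_id=cell_id)
    return results


def stringent_trisomy_filter(result: KaryotypeResult) -> bool:
    """True iff a 3N+ call is routed through three separate detections per
    locus for at least three different loci.

    Traces are node-disjoint, so three traces assigning the same locus order
    necessarily selected three distinct detections there.
    """
    if result.copy_number < 3:
        return False
    counts = np.zeros(result.traces[0].n_loci, dtype=int)
    for t in result.traces:
        counts[t.orders - 1] += 1
    return int((counts >= 3).sum()) >= 3
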