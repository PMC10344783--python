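"""Post-tracing biology: chromosome territories, sister/homolog pairing,
cis/trans distance profiles and the sliding-window misselection scan.

Sister chromatids are the two identical copies of a replicated chromosome;
in imaging they spatially "shadow" each other, and because the probes do not
discriminate copies a tracer may inadvertently cross over between them.  The
misselection scan quantifies this by exchanging three-locus blocks between
paired fibers and asking whether the swap improves the Gaussian-chain bond
likelihood of both fibers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .aligner import PolymerTrace
from .model import ChainParams, expected_variance, neg_log_bond
from .reference import ReferenceMap

__all__ = ["SisterAssignment", "MisselectionScan", "cluster_territories",
           "assign_sisters", "cis_trans_profiles", "misselection_scan",
           "interpolate_trace"]

_MATCHINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def cluster_territories(traces, eps_nm: float = 2_000.0, min_pts: int = 1) -> np.ndarray:
    """DBSCAN cluster label per trace (-1 = noise), traces summarized by
    their centroid.  Separate chromosome territories appear as separate
    density clusters; a "compact" multi-copy state collapses into one."""
    if not traces:
        raise ValueError("need at least one trace")
    X = np.stack([np.nanmean(t.positions(), axis=0) for t in traces])
    if len(traces) == 1:
        return np.zeros(1, dtype=int)
    return DBSCAN(eps=eps_nm, min_samples=min_pts).fit_predict(X)


@dataclass
class SisterAssignment:
    """Sister pairings of four traces under all three perfect matchings.

    SA pairs the closest centromeric starts, EA the closest telomeric ends;
    alt1/alt2 are the remaining matchings ranked by start-distance.  The
    same-fiber start-to-end distance serves as the unpaired control.
    """

    matchings: tuple                 # the 3 perfect matchings of trace indices
    start_sums: np.ndarray           # summed start-start distance per matching
    end_sums: np.ndarray             # summed end-end distance per matching
    sa: tuple                        # matching minimizing start distances
    ea: tuple                        # matching minimizing end distances
    alt1: tuple
    alt2: tuple
    control_nm: np.ndarray           # per-trace start-to-end distance

    def pair_distances(self, matching, where: str = "start") -> np.ndarray:
        col = 0 if where == "start" else 1
        return np.array([np.linalg.norm(self._ends[i, col] - self._ends[j, col])
                         for i, j in matching])

    _ends: np.ndarray = field(default=None, repr=False)


def assign_sisters(traces) -> SisterAssignment:
    """Enumerate all three perfect matchings of four traces.

    Ties between matchings are broken toward the lexicographically first
    matching in the fixed enumeration order, which is deterministic in the
    trace ordering supplied.
    """
    traces = list(traces)
    if len(traces) != 4:
        raise ValueError("sister assignment requires exactly four traces")
    ends = np.stack([[t.coords_nm[0], t.coords_nm[-1]] for t in traces])  # (4,2,3)
    start_sums, end_sums = [], []
    for m in _MATCHINGS:
        start_sums.append(sum(np.linalg.norm(ends[i, 0] - ends[j, 0]) for i, j in m))
        end_sums.append(sum(np.linalg.norm(ends[i, 1] - ends[j, 1]) for i, j in m))
    start_sums = np.asarray(start_sums)
    end_sums = np.asarray(end_sums)
    order = np.argsort(start_sums, kind="stable")
    sa, alt1, alt2 = (_MATCHINGS[i] for i in order)
    ea = _MATCHINGS[int(np.argmin(end_sums))]
    control = np.linalg.norm(ends[:, 0] - ends[:, 1], axis=1)
    out = SisterAssignment(_MATCHINGS, start_sums, end_sums, sa, ea, alt1, alt2,
                           control)
    out._ends = ends
    return out


def cis_trans_profiles(pairs, ref: ReferenceMap,
                       bin_size_bp: float = 1e6, max_sep_bp: float | None = None):
    """Distance versus genomic-separation curves for paired sister fibers.

    ``pairs`` is a sequence of (trace_a, trace_b).  *cis* compares loci on
    the same fiber, *trans* loci across the two fibers (including the
    same-locus "shadowing" distance at zero separation).  Returns a tidy
    DataFrame (kind, bin_mid_bp, mean_nm, sem_nm, n) and the array of trans
    same-locus distances.
    """
    pos_bp = ref.positions_bp
    recs = {"cis": ([], []), "trans": ([], [])}
    shadow = []
    for a, b in pairs:
        pa, pb = a.positions(), b.positions()
        for kind, (p1, p2) in (("cis", (pa, pa)), ("cis", (pb, pb)), ("trans", (pa, pb))):
            d = np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=-1)
            sep = np.abs(pos_bp[:, None] - pos_bp[None, :])
            if kind == "cis":
                iu = np.triu_indices(len(pos_bp), k=1)
                dd, ss = d[iu], sep[iu]
            else:
                dd, ss = d.ravel(), sep.ravel()
                same = np.isclose(sep, 0).ravel()
                shadow.extend(d.ravel()[same & np.isfinite(d.ravel())])
            ok = np.isfinite(dd)
            if max_sep_bp is not None:
                ok &= ss <= max_sep_bp
            recs[kind][0].extend(ss[ok])
            recs[kind][1].extend(dd[ok])
    rows = []
    for kind, (seps, dists) in recs.items():
        seps = np.asarray(seps)
        dists = np.asarray(dists)
        if seps.size == 0:
            continue
        bins = (seps // bin_size_bp).astype(int)
        for b in np.unique(bins):
            vals = dists[bins == b]
            rows.append({"kind": kind, "bin_mid_bp": (b + 0.5) * bin_size_bp,
                         "mean_nm": float(vals.mean()),
                         "sem_nm": float(vals.std(ddof=1) / np.sqrt(vals.size))
                         if vals.size > 1 else np.nan,
                         "n": int(vals.size)})
    return pd.DataFrame(rows), np.asarray(shadow)


def interpolate_trace(trace: PolymerTrace) -> np.ndarray:
    """(T, 3) coordinates with gap loci filled by linear 3D interpolation
    between the nearest assigned flanking loci (ends held constant)."""
    pos = trace.positions()
    T = pos.shape[0]
    assigned = ~np.isnan(pos[:, 0])
    if assigned.sum() < 2:
        raise ValueError("interpolation needs at least two assigned loci")
    idx = np.arange(T)
    out = pos.copy()
    for ax in range(3):
        out[:, ax] = np.interp(idx, idx[assigned], pos[assigned, ax])
    return out


@dataclass
class MisselectionScan:
    """Result of the sliding-window sister misselection scan."""

    window_starts: np.ndarray        # 1-based first locus of each exchanged block
    flagged: np.ndarray              # bool per window: swap improved both fibers
    crossover_events: list           # (first_start, last_start) of maximal runs

    @property
    def n_misselections(self) -> int:
        return int(self.flagged.sum())

    @property
    def n_crossovers(self) -> int:
        return len(self.crossover_events)

    @property
    def misselection_rate(self) -> float:
        return float(self.flagged.mean()) if self.flagged.size else float("nan")


def misselection_scan(trace_a: PolymerTrace, trace_b: PolymerTrace,
                      ref: ReferenceMap, params: ChainParams,
                      window: int = 3) -> MisselectionScan:
    """Scan a sister pair for loci plausibly selected from the wrong fiber.

    Missing loci are first interpolated.  A window of ``window`` loci is slid
    from locus ``window`` to ``T - window + 1``; at each position the window
    coordinates are exchanged between the fibers and the bond probabilities
    linking the (up to) ``window`` upstream loci through the exchanged block
    are recomputed on both fibers.  The position is a misselection iff both
    fibers' recomputed bond products improve strictly; maximal runs of
    consecutive misselections are cross-over events.
    """
    T = ref.n_loci
    if T < 2 * window:
        raise ValueError("traces must span at least twice the window length")
    if trace_a.n_loci != T or trace_b.n_loci != T:
        raise ValueError("traces and reference disagree on locus count")
    A = interpolate_trace(trace_a)
    B = interpolate_trace(trace_b)
    pos = ref.positions_bp
    sig = params.sigma_default_nm

    def _segment_cost(xyz: np.ndarray, lo: int, hi: int) -> float:
        """Sum of consecutive-locus bond costs over loci lo..hi (0-based)."""
        L = np.diff(pos[lo:hi + 1])
        R = np.linalg.norm(np.diff(xyz[lo:hi + 1], axis=0), axis=1) / params.pixel_nm
        s2 = expected_variance(L, sig, sig, params)
        return float(np.sum(neg_log_bond(R, s2, params.spherical_term)))

    starts = np.arange(window, T - window + 2)  # 1-based first locus of block
    flagged = np.zeros(starts.size, dtype=bool)
    for w, s in enumerate(starts):
        blk_lo, blk_hi = s - 1, s - 1 + window - 1          # 0-based block span
        up_lo = max(0, blk_lo - window)
        before = (_segment_cost(A, up_lo, blk_hi), _segment_cost(B, up_lo, blk_hi))
        A2, B2 = A.copy(), B.copy()
        A2[blk_lo:blk_hi + 1], B2[blk_lo:blk_hi + 1] = (B[blk_lo:blk_hi + 1].copy(),
                                                        A[blk_lo:blk_hi + 1].copy())
        after = (_segment_cost(A2, up_lo, blk_hi), _segment_cost(B2, up_lo, blk_hi))
        flagged[w] = after[0] < before[0] and after[1] < before[1]

    events = []
    run_start = None
    for w, f in enumerate(flagged):
        if f and run_start is None:
            run_start = int(starts[w])
        elif not f and run_start is not None:
            events.append((run_start, int(starts[w - 1])))
            run_start = None
    if run_start is not None:
        events.append((run_start, int(starts[-1])))
    return MisselectionScan(starts, flagged, events)
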