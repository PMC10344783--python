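"""Gaussian-chain bond model underlying every edge of the alignment graph.

A chromatin fiber between two imaged loci separated by ``L`` base pairs is
modeled as a freely jointed (Gaussian) chain with persistence length ``l_p``
(in bp) and a compaction scale ``tau`` (nm per bp) that converts genomic to
spatial distance.  The displacement between the two loci is then Gaussian per
axis with variance

    S^2 = (sigma_i^2 + sigma_j^2) + (2/3) * tau^2 * l_p * L

where ``sigma_i``/``sigma_j`` are the localization uncertainties of the two
spots.  ``tau`` scales both the contour length and the persistence length, so
the chain variance carries tau squared.  All costs are computed in *pixel*
units (coordinates and S divided by ``pixel_nm``, natural logs); this is the
convention that makes the additive entropic prefactor (3/2)*ln(2*pi*S^2)
comparable across implementations, and it is the convention under which a
1-Mb segment evaluated at its full contour length costs 5013.34 and a 2-Mb
segment 10014.38 (tau = 0.34 nm/bp, l_p = 150 bp, 100-nm pixels).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import digamma

__all__ = [
    "ChainParams",
    "expected_variance",
    "neg_log_bond",
    "gap_scaled_cost",
    "gap_extension_cost",
    "terminal_pseudo_cost",
    "fit_tau",
]

# Geometric mean of a 3-dof chi variable: exp(E[ln chi_3]).  Used to convert a
# log-log fit of scalar distances into the per-axis Gaussian scale.
_CHI3_GEOM_MEAN = math.exp(0.5 * (digamma(1.5) + math.log(2.0)))


@dataclass
class ChainParams:
    """Physical and algorithmic parameters of the spatial genome aligner.

    Parameters
    ----------
    l_p:
        Persistence length in bp (fixed at 150 bp in the reference analysis).
    tau:
        Genomic-to-spatial compaction scale in nm per bp.  Fit per chromosome
        in practice (see :func:`fit_tau`); the default 0.34 nm/bp is the bare
        B-DNA contour scale used in the worked examples.
    pixel_nm:
        Nanometers per pixel; all bond costs are computed in pixel units.
    gamma:
        Multiplicative gap penalty base (``gap_mode = "geometric"``).  A
        skip edge spanning ``c`` locus intervals is charged ``gamma**(c-1)``
        times its bond cost.  The default 2.0 enforces the
        no-preferential-skip condition at *typical* chain displacements (see
        docs/methods.md); the often-quoted bound ~1.0012 holds only for
        fully stretched chains.
    gap_mode:
        "affine" (default) charges each skipped locus the expected cost of
        the honest edge it avoided plus ``skip_margin`` expected exponents;
        "geometric" uses the multiplicative ``gamma`` scaling.  For
        diffusive chain statistics (observed distance growing like sqrt of
        genomic separation) only the affine form can simultaneously forbid
        preferential skipping and keep the long bridges demanded by heavy
        signal dropout affordable; see docs/methods.md.
    skip_margin:
        Reluctance to skip a detected locus, in units of the expected edge
        exponent (3/2).  Zero means cost-indifference between visiting and
        skipping a typical locus; the default 1.0 skips only loci whose
        local fit is roughly one expected exponent worse than typical.
    C:
        Maximum locus intervals a single edge may span (so up to ``C - 1``
        consecutive missing loci can be bridged).  Sized from run-length
        statistics: at 50% detection efficiency the longest dropout run of
        a T-locus chromosome exceeds C-1 with probability ~T/2**C, so
        C = 11 keeps even a ~175-locus chromosome traceable ~95% of the
        time.  Affine gap charges grow only linearly in C, so a wide
        lookahead does not destabilize the path costs.
    K:
        Maximum loci skippable at the chromosome start and end via terminal
        pseudo-bonds (P(terminal run > K) = 0.5**(K+1) ~ 0.4% per end at
        50% detection).
    alpha:
        Stretch factor of the imaginary terminal segment; terminal skips are
        charged the bond cost at ``alpha`` times the RMS displacement.
    sigma_default_nm:
        Per-axis localization uncertainty assumed when a spot table carries
        none (~50 nm for drift- and chromatic-corrected data).
    spherical_term:
        If True, include the spherical differential-volume factor 4*pi*R^2 in
        the bond probability (off in the reference analysis).
    min_assigned_fraction:
        A trace must assign at least this fraction of the reference loci to
        be considered a valid polymer.
    score_threshold_mode:
        "per_locus" compares trace score / assigned loci against the
        karyotype threshold; "raw" compares total scores.
    threshold_headroom:
        Multiplier applied to the scrambled-null threshold before
        acceptance.  Genuine fibers in confined nuclei carry finite model
        misfit (compaction heterogeneity, confinement compression, fitted-
        scale error) that places them near the null's scale, while junk
        paths score several-fold above it; the default 1.5 puts the cutoff
        between those regimes.
    max_fibers:
        Iteration cap of the karyotyper per chromosome.
    """

    l_p: float = 150.0
    tau: float = 0.34
    pixel_nm: float = 100.0
    gamma: float = 2.0
    gap_mode: str = "affine"
    skip_margin: float = 1.0
    C: int = 11
    K: int = 7
    alpha: float = 2.0
    sigma_default_nm: float = 50.0
    spherical_term: bool = False
    min_assigned_fraction: float = 0.25
    score_threshold_mode: str = "per_locus"
    threshold_headroom: float = 1.5
    max_fibers: int = 8

    def __post_init__(self) -> None:
        if self.l_p <= 0:
            raise ValueError("l_p must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.gap_mode not in ("affine", "geometric"):
            raise ValueError("gap_mode must be 'affine' or 'geometric'")
        if self.skip_margin < 0:
            raise ValueError("skip_margin must be >= 0")
        if self.C < 1:
            raise ValueError("C must be >= 1")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.score_threshold_mode not in ("per_locus", "raw"):
            raise ValueError("score_threshold_mode must be 'per_locus' or 'raw'")

    def with_tau(self, tau: float) -> "ChainParams":
        """Return a copy with a different compaction scale."""
        return replace(self, tau=float(tau))


def expected_variance(L, sigma_i, sigma_j, params: ChainParams):
    """Per-axis variance S^2 (in pixel^2) of the chain displacement.

    ``L`` is the genomic separation in bp, ``sigma_i``/``sigma_j`` the
    per-axis localization uncertainties of the two spots in nm.  Accepts
    scalars or numpy arrays.
    """
    L = np.asarray(L, dtype=float)
    sigma_i = np.asarray(sigma_i, dtype=float)
    sigma_j = np.asarray(sigma_j, dtype=float)
    if np.any(L < 0):
        raise ValueError("genomic separation L must be >= 0")
    if np.any(sigma_i < 0) or np.any(sigma_j < 0):
        raise ValueError("localization uncertainties must be >= 0")
    px2 = params.pixel_nm**2
    s2 = (sigma_i**2 + sigma_j**2) / px2 + (2.0 / 3.0) * params.tau**2 * params.l_p * L / px2
    return s2 if s2.ndim else float(s2)


def neg_log_bond(R, S2, spherical_term: bool = False):
    """Negative log of the Gaussian bond probability.

    ``R`` is the observed spatial separation and ``S2`` the per-axis variance,
    both in pixel units.  Without the spherical term this is
    (3/2)*ln(2*pi*S^2) + R^2/(2*S^2); with it, ln(4*pi*R^2) is subtracted.
    """
    R = np.asarray(R, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    if np.any(S2 <= 0):
        raise ValueError("S2 must be > 0")
    if np.any(R < 0):
        raise ValueError("R must be >= 0")
    cost = 1.5 * np.log(2.0 * np.pi * S2) + R * R / (2.0 * S2)
    if spherical_term:
        with np.errstate(divide="ignore"):
            cost = cost - np.log(4.0 * np.pi * R * R)
    return cost if cost.ndim else float(cost)


def gap_scaled_cost(cost, c, params: ChainParams):
    """Apply the geometric gap penalty gamma**(c-1) to an edge cost.

    ``c`` is the number of locus intervals the edge spans; adjacent loci
    (c = 1) are not penalized.
    """
    c = np.asarray(c)
    if np.any(c < 1):
        raise ValueError("skip count c must be >= 1")
    out = np.asarray(cost, dtype=float) * params.gamma ** (np.asarray(c, dtype=float) - 1.0)
    return out if out.ndim else float(out)


def gap_extension_cost(L_med, sigma_nm, params: ChainParams) -> float:
    """Affine charge per skipped locus.

    A skipped locus is charged the expected cost of the honest edge it
    avoided -- the bond cost at the RMS displacement of a typical (median)
    imaged interval, whose exponent is exactly 3/2 -- plus ``skip_margin``
    expected exponents of reluctance.  With margin zero the aligner is
    cost-indifferent between visiting and skipping a typical locus.
    """
    s2 = expected_variance(L_med, sigma_nm, sigma_nm, params)
    base = neg_log_bond(math.sqrt(3.0 * s2), s2, params.spherical_term)
    return float(base + params.skip_margin * 1.5)


def terminal_pseudo_cost(L, k, sigma_nm, params: ChainParams,
                         gap_extension: float = 0.0):
    """Cost of a terminal pseudo-bond skipping ``k`` loci over ``L`` bp.

    The pseudo-bond links an imaginary chromosome start (or end) to an
    observed spot, modeling an imaginary genomic segment stretched by the
    factor ``alpha``: the bond cost is evaluated at ``alpha`` times the RMS
    3D displacement of a chain of length ``L``, and carries the same gap
    penalty as an internal skip (geometric ``gamma**k`` scaling, or
    ``(k-1) * gap_extension`` in affine mode).  ``k = 0`` (no skipped
    locus) is free, so alignments that start at locus 1 and end at locus T
    incur no terminal cost.
    """
    if k == 0:
        return 0.0
    if L <= 0:
        raise ValueError("terminal pseudo-bond requires L > 0 when k > 0")
    s2 = expected_variance(L, sigma_nm, 0.0, params)
    r_eff = params.alpha * math.sqrt(3.0 * s2)
    bond = neg_log_bond(r_eff, s2, params.spherical_term)
    if params.gap_mode == "affine":
        return float(bond + (k - 1) * gap_extension)
    return float(params.gamma**k * bond)


def fit_tau(pair_distances, pair_intervals, params: ChainParams | None = None,
            reference_interval: float | None = None):
    """Estimate the compaction scale tau (nm/bp) from pairwise distances.

    Fits the power law d = A * L**beta by ordinary least squares in log-log
    space through (genomic interval, spatial distance) pairs, evaluates the
    fitted distance at a reference interval (the median interval by default),
    and converts it to the per-bp scale implied by the Gaussian chain,
    E[d^2] = 2 * l_p * tau^2 * L.  The log-log fit estimates the geometric
    mean of the chi_3-distributed distances, which is corrected back to the
    per-axis Gaussian scale.

    Returns ``(tau, beta)``.
    """
    params = params or ChainParams()
    d = np.asarray(pair_distances, dtype=float)
    L = np.asarray(pair_intervals, dtype=float)
    if d.shape != L.shape or d.ndim != 1:
        raise ValueError("pair_distances and pair_intervals must be 1-D and equal length")
    keep = (d > 0) & (L > 0)
    d, L = d[keep], L[keep]
    if d.size < 2:
        raise ValueError("need at least two positive (distance, interval) pairs")
    L_ref = float(reference_interval) if reference_interval else float(np.median(L))

    uniq = np.unique(L)
    if uniq.size < 2:
        warnings.warn("single distinct genomic interval; falling back to d/L ratio",
                      RuntimeWarning, stacklevel=2)
        d_ref = float(np.exp(np.mean(np.log(d))))
        beta = float("nan")
    else:
        logL, logd = np.log(L), np.log(d)
        if np.allclose(logd, logd[0]):
            warnings.warn("all distances equal; power-law slope is degenerate (beta = 0)",
                          RuntimeWarning, stacklevel=2)
        beta, logA = np.polyfit(logL, logd, 1)
        d_ref = math.exp(logA + beta * math.log(L_ref))
        beta = float(beta)
    sigma_axis = d_ref / _CHI3_GEOM_MEAN  # geometric-mean -> per-axis Gaussian scale
    tau = sigma_axis * math.sqrt(1.5 / (params.l_p * L_ref))
    return tau, beta


def fit_tau_quantile(pair_distances, pair_intervals,
                     params: ChainParams | None = None, q: float = 0.25) -> float:
    """Censoring-robust compaction scale by quantile matching.

    Matches the ``q`` quantile of the observed squared-distance-to-interval
    ratios d^2 / ((4/3) l_p L) against the same quantile of the chi-square
    (3 dof) half-distribution it should follow under the Gaussian chain.
    Because the aligner preferentially *skips* poorly fitting (long-step)
    loci, traced step samples are censored in their upper tail; a low
    quantile is untouched by that censoring where mean- or geometric-mean-
    based fits are dragged down.
    """
    params = params or ChainParams()
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    d = np.asarray(pair_distances, dtype=float)
    L = np.asarray(pair_intervals, dtype=float)
    keep = (d > 0) & (L > 0)
    d, L = d[keep], L[keep]
    if d.size < 2:
        raise ValueError("need at least two positive (distance, interval) pairs")
    from scipy.stats import chi2
    obs = np.quantile(d * d / ((4.0 / 3.0) * params.l_p * L), q)
    return float(math.sqrt(obs / (chi2.ppf(q, df=3) / 2.0)))


def tau_pairs_from_spots(spots, ref, trim_factor: float | None = 4.0):
    """(distances, intervals) pairs for :func:`fit_tau` from a raw spot table.

    For every adjacent pair of imaged locus orders within each cell, the
    *nearest* candidate-to-candidate distance is taken, which approximates
    the same-fiber distance when several chromosome copies (or strays) are
    present.  Pairs farther than ``trim_factor`` times the median distance
    are discarded: under signal dropout the nearest candidate is sometimes a
    spot of another chromosome territory microns away, which would otherwise
    inflate the fit.  ``spots`` is a per-chromosome table with cell_id,
    locus_order and x/y/z_nm columns; ``ref`` supplies the genomic intervals.

    This estimator is a rough first pass (nearest-candidate selection biases
    it low when sister territories overlap); refine it with
    :func:`tau_pairs_from_traces` after a threshold-free alignment pass.
    """
    pos = ref.positions_bp
    dists, intervals = [], []
    for _, cell in spots.groupby("cell_id", sort=False):
        orders = cell["locus_order"].to_numpy(dtype=int)
        xyz = cell[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        by_order = {}
        for t in np.unique(orders):
            by_order[int(t)] = xyz[orders == t]
        ts = sorted(by_order)
        for a, b in zip(ts[:-1], ts[1:]):
            if b - a != 1:
                continue  # adjacent imaged orders only
            A, B = by_order[a], by_order[b]
            d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
            dists.append(float(d.min()))
            intervals.append(float(pos[b - 1] - pos[a - 1]))
    dists = np.asarray(dists)
    intervals = np.asarray(intervals)
    if trim_factor is not None and dists.size:
        keep = dists <= trim_factor * np.median(dists)
        dists, intervals = dists[keep], intervals[keep]
    return dists, intervals


def tau_pairs_from_traces(traces, ref, max_span: int = 1):
    """(distances, genomic spans) from consecutive assigned loci of traces.

    Distances between consecutively assigned loci within one trace are
    same-fiber by construction, removing the cross-territory and
    nearest-candidate biases of the raw-spot estimator.  Pairs spanning up
    to ``max_span`` locus intervals are used -- under the Gaussian chain
    their variance is proportional to the genomic span regardless of the
    number of loci bridged, and including spans softens the censoring bias
    introduced when the aligner skips a poorly fitting locus (the flanking
    spanning pair remains in the sample).
    """
    pos = ref.positions_bp
    dists, intervals = [], []
    for tr in traces:
        orders = np.asarray(tr.orders)
        c = np.diff(orders)
        keep = c <= max_span
        if not keep.any():
            continue
        d = np.linalg.norm(np.diff(tr.coords_nm, axis=0), axis=1)[keep]
        span = (pos[orders[1:] - 1] - pos[orders[:-1] - 1])[keep]
        dists.extend(d.tolist())
        intervals.extend(span.tolist())
    return np.asarray(dists), np.asarray(intervals)
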