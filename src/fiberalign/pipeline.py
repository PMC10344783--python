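"""End-to-end cohort analysis: calibrate, threshold, karyotype, score.

The compaction scale tau is chromosome specific and must be estimated from
the data themselves.  The pipeline does this in two passes: a rough
power-law fit through nearest-candidate distances of adjacent imaged loci,
then a threshold-free alignment pass whose traced consecutive segments are
same-fiber by construction and yield an unbiased re-fit.  Karyotype
acceptance thresholds are then derived per chromosome from the scrambled-
interval null, condition-matched to the cohort's dropout and stray rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aligner import align
from .evaluate import ClassificationReport, classify_selections, karyotype_accuracy
from .karyotype import KaryotypeResult, karyotype_cell, scramble_threshold
from .model import (ChainParams, fit_tau, fit_tau_quantile, tau_pairs_from_spots,
                    tau_pairs_from_traces)
from .reference import ReferenceMap
from .simulate import MOUSE_CHROM_LENGTHS_BP, SimulatedCell, territory_radius_nm

__all__ = ["estimate_taus", "cohort_thresholds", "CohortResult", "karyotype_cohort"]


def _looks_single_copy(table: pd.DataFrame, n_loci: int,
                       max_multi_fraction: float = 0.15,
                       min_occupancy: float = 0.3) -> bool:
    """Heuristic: does this cell's chromosome carry exactly one fiber?

    Single-copy chromosomes offer at most one candidate per locus, so the
    aligner has no spot-selection freedom there and traced step lengths are
    unbiased.  Multi-copy chromosomes are excluded from the refit because
    the aligner preferentially selects shorter steps when two fibers offer
    candidates, biasing the fitted scale low.
    """
    counts = table["locus_order"].value_counts()
    if len(counts) < min_occupancy * n_loci:
        return False
    return (counts >= 2).mean() <= max_multi_fraction


def estimate_taus(spot_tables, refs: dict[str, ReferenceMap],
                  base_params: ChainParams, refine: bool = True,
                  max_cells: int = 30) -> dict[str, float]:
    """Per-chromosome compaction scales from a cohort of spot tables.

    ``spot_tables`` is an iterable of per-cell spot DataFrames.  Pass one
    pools nearest-candidate adjacent-locus distances (cross-territory pairs
    trimmed) into a log-log power-law fit.  With ``refine``, a threshold-free
    alignment pass over *single-copy-looking* chromosomes re-fits tau from
    within-trace consecutive segments, which are same-fiber by construction
    and carry no spot-selection bias.
    """
    cells = list(spot_tables)[:max_cells]
    taus: dict[str, float] = {}
    for chrom, ref in refs.items():
        pooled = [c[c["chromosome"] == chrom] for c in cells]
        pooled = [p for p in pooled if len(p)]
        if not pooled:
            taus[chrom] = base_params.tau
            continue
        spots = pd.concat(pooled)
        d, L = tau_pairs_from_spots(spots, ref)
        try:
            tau0, _ = fit_tau(d, L, base_params)
        except ValueError:
            taus[chrom] = base_params.tau
            continue
        if not refine:
            taus[chrom] = tau0
            continue
        singles, others = [], []
        for p in pooled:
            for _, grp in p.groupby("cell_id", sort=False):
                (singles if _looks_single_copy(grp, ref.n_loci) else others).append(grp)
        tau_ref = None
        for groups in (singles, singles + others):
            if not groups:
                continue
            # self-consistent refit: a low scale inflates exponents and makes
            # the aligner skip-censor long steps, so iterate to a fixed point
            tau_it = tau0
            ok = False
            for _ in range(3):
                rough = base_params.with_tau(tau_it)
                traces = [tr for grp in groups
                          if (tr := align(grp, ref, rough)) is not None]
                d2, L2 = tau_pairs_from_traces(traces, ref)
                if d2.size < 10:
                    break
                try:
                    # quantile matching resists the skip-censoring of traced
                    # step lengths that drags moment fits low
                    tau_new = fit_tau_quantile(d2, L2, base_params)
                except ValueError:
                    break
                ok = abs(tau_new - tau_it) <= 0.01 * tau_it
                tau_it = tau_new
                if ok:
                    break
            if ok or (tau_it != tau0):
                tau_ref = tau_it
                break
        taus[chrom] = tau_ref if tau_ref is not None else tau0
    return taus


def cohort_thresholds(refs: dict[str, ReferenceMap], params_by_chrom: dict,
                      fnr: float, fpr: float, n_perm: int = 20,
                      seed=None) -> dict[str, float]:
    """Scrambled-null karyotype threshold per chromosome.

    The null is condition-matched: same dropout and stray rates as the
    cohort, with chains generated at the fitted compaction scale so the
    null carries the same edge statistics as the data it gates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return {chrom: scramble_threshold(ref, params_by_chrom[chrom], n_perm=n_perm,
                                      seed=rng, fnr=fnr, fpr=fpr)
            for chrom, ref in refs.items()}


@dataclass
class CohortResult:
    """Everything the karyotyping pipeline produced for a cohort of cells."""

    taus: dict
    thresholds: dict
    karyotypes: list                  # per cell: chromosome -> KaryotypeResult
    reports: list = field(default_factory=list)   # ClassificationReports (simulated input)
    predicted: list = field(default_factory=list)
    truth: list = field(default_factory=list)

    def accuracy(self):
        return karyotype_accuracy(self.predicted, self.truth)

    def mean_rate(self, attr: str) -> float:
        """Mean of a ClassificationReport rate over chromosomes with >= 1 copy."""
        vals = [getattr(r, attr) for r in self.reports if r.copies > 0]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def detection_fraction(self, ploidy: int) -> float:
        """Fraction of true-``ploidy`` chromosomes called at exactly that ploidy."""
        hits = [p == t for p, t in zip(self.predicted, self.truth) if t == ploidy]
        return float(np.mean(hits)) if hits else float("nan")


def karyotype_cohort(cells, refs: dict[str, ReferenceMap],
                     base_params: ChainParams, fnr: float, fpr: float,
                     n_perm: int = 20, seed=None,
                     taus: dict | None = None) -> CohortResult:
    """Run the full pipeline over a cohort.

    ``cells`` may be :class:`SimulatedCell` objects (ground-truth error
    taxonomy is then computed) or raw per-cell spot DataFrames.  ``fnr`` and
    ``fpr`` describe the cohort's noise condition and are matched by the
    scrambled null.
    """
    cells = list(cells)
    simulated = cells and isinstance(cells[0], SimulatedCell)
    tables = [c.spots if simulated else c for c in cells]
    if taus is None:
        taus = estimate_taus(tables, refs, base_params)
    params = {c: base_params.with_tau(t) for c, t in taus.items()}
    thresholds = cohort_thresholds(refs, params, fnr, fpr, n_perm=n_perm, seed=seed)
    out = CohortResult(taus, thresholds, [])
    for k, table in enumerate(tables):
        cell_id = cells[k].cell_id if simulated else k
        res = karyotype_cell(table, refs, params, thresholds, cell_id=cell_id)
        out.karyotypes.append(res)
        for chrom, r in res.items():
            if simulated:
                out.reports.append(classify_selections(r, cells[k], chrom))
                out.predicted.append(r.copy_number)
                out.truth.append(cells[k].copy_numbers[chrom])
    return out
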