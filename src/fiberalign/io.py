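"""File formats: spot tables (CSV), reference maps (BED), trace tables
(FOF-CT-core-style CSV), karyotype summaries and dense contact matrices.

Coordinates are stored in nm everywhere; conversion to pixel units happens
only inside the bond model.  Trace tables follow the 4D Nucleome FISH-omics
chromatin-tracing core convention: one row per locus of one trace, gaps
written explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .aligner import PolymerTrace
from .karyotype import KaryotypeResult
from .model import ChainParams
from .reference import ReferenceMap

__all__ = ["read_spots", "read_reference", "write_traces", "read_traces",
           "write_karyotype", "read_contact_matrix", "load_params", "save_params"]

logger = logging.getLogger("fiberalign")

_REQUIRED_SPOT_COLS = ["cell_id", "chromosome", "locus_order", "x_nm", "y_nm", "z_nm"]
_SIGMA_COLS = ["sigma_x_nm", "sigma_y_nm", "sigma_z_nm"]


def read_spots(path, sigma_default_nm: float = 50.0) -> pd.DataFrame:
    """Read a candidate-spot table (CSV with header).

    Required columns: cell_id, chromosome, locus_order (1-based, 5'->3'),
    x_nm, y_nm, z_nm.  The per-axis uncertainty trio sigma_{x,y,z}_nm is
    optional; when absent, ``sigma_default_nm`` (~50 nm for corrected data)
    is filled in with a logged warning.  Malformed rows raise with their
    line numbers.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_SPOT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    numeric = ["locus_order", "x_nm", "y_nm", "z_nm"] + \
        [c for c in _SIGMA_COLS if c in df.columns]
    bad_lines = []
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(coerced.to_numpy(dtype=float))
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[col] = coerced
    if bad_lines:
        raise ValueError(f"{path}: malformed numeric values on lines "
                         f"{sorted(set(bad_lines))}")
    if (df["locus_order"] < 1).any():
        raise ValueError(f"{path}: locus_order must be >= 1")
    df["locus_order"] = df["locus_order"].astype(int)
    if not all(c in df.columns for c in _SIGMA_COLS):
        logger.warning("%s: no localization uncertainties; assuming %g nm per axis",
                       path, sigma_default_nm)
        for c in _SIGMA_COLS:
            df[c] = sigma_default_nm
    return df


def read_reference(path) -> dict[str, ReferenceMap]:
    """Read imaged-locus positions from a BED-like file.

    Columns: chromosome, start, end (0-based half-open, whitespace separated,
    no header; extra columns ignored).  The locus position is the interval
    midpoint.  Unsorted rows are sorted by coordinate with a warning.
    Returns one :class:`ReferenceMap` per chromosome.
    """
    bed = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if bed.shape[1] < 3:
        raise ValueError(f"{path}: BED needs chromosome, start, end columns")
    bed = bed.iloc[:, :3]
    bed.columns = ["chrom", "start", "end"]
    refs = {}
    for chrom, grp in bed.groupby("chrom", sort=False):
        mid = ((grp["start"] + grp["end"]) / 2.0).to_numpy(dtype=float)
        if mid.size < 2:
            logger.warning("%s: %s has fewer than two loci; skipped", path, chrom)
            continue
        if not np.all(np.diff(mid) > 0):
            logger.warning("%s: %s loci not sorted; sorting by coordinate",
                           path, chrom)
            mid = np.sort(mid)
        refs[str(chrom)] = ReferenceMap(str(chrom), mid)
    return refs


def _trace_rows(trace: PolymerTrace, trace_id, ref: ReferenceMap):
    sel = {int(t): k for k, t in enumerate(trace.orders)}
    # edge_costs: first entry is the source pseudo-bond; assign each
    # subsequent edge cost to the locus row it lands on, and the final sink
    # pseudo-bond to a trailing pseudo column via the trace score instead.
    cost_at = {}
    for k, t in enumerate(trace.orders):
        cost_at[int(t)] = float(trace.edge_costs[k]) if k < len(trace.edge_costs) else np.nan
    for t in range(1, trace.n_loci + 1):
        row = {
            "trace_id": trace_id,
            "cell_id": trace.cell_id,
            "chromosome": trace.chromosome,
            "locus_order": t,
            "chrom_pos_bp": float(ref.positions_bp[t - 1]) if ref is not None else np.nan,
            "gap": t not in sel,
            "edge_cost": cost_at.get(t, np.nan),
            "trace_score": trace.score,
        }
        if t in sel:
            k = sel[t]
            row.update(x_nm=trace.coords_nm[k, 0], y_nm=trace.coords_nm[k, 1],
                       z_nm=trace.coords_nm[k, 2])
        else:
            row.update(x_nm=np.nan, y_nm=np.nan, z_nm=np.nan)
        yield row


def write_traces(results, path, refs: dict[str, ReferenceMap] | None = None) -> None:
    """Write traces to a FOF-CT-core-style CSV.

    ``results`` may be PolymerTraces, KaryotypeResults, or a mapping of
    chromosome -> KaryotypeResult.  One row per reference locus per trace;
    gap loci carry NaN coordinates and gap=True.
    """
    traces = []
    if isinstance(results, dict):
        results = list(results.values())
    for item in results:
        if isinstance(item, KaryotypeResult):
            traces.extend(item.traces)
        else:
            traces.append(item)
    rows = []
    for k, tr in enumerate(traces):
        ref = (refs or {}).get(tr.chromosome)
        rows.extend(_trace_rows(tr, k, ref))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces(path) -> pd.DataFrame:
    """Read a trace table written by :func:`write_traces`."""
    return pd.read_csv(path, float_precision="round_trip")


def write_karyotype(results, path) -> None:
    """Per-cell, per-chromosome karyotype summary CSV.

    ``results`` is a mapping chromosome -> KaryotypeResult or an iterable of
    such mappings (one per cell).
    """
    if isinstance(results, dict):
        results = [results]
    rows = []
    for cell in results:
        for chrom, res in cell.items():
            rows.append({
                "cell_id": res.cell_id,
                "chromosome": chrom,
                "copy_number": res.copy_number,
                "n_residual_spots": len(res.residual_spot_ids),
                "threshold": res.threshold,
                "trace_scores": ";".join(f"{s:.6g}" for s in res.scores),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contact_matrix(path) -> np.ndarray:
    """Dense contact matrix from CSV/TSV (no header); must be square."""
    mat = pd.read_csv(path, sep=None, engine="python", header=None).to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: contact matrix must be square, got {mat.shape}")
    return mat


def load_params(path) -> ChainParams:
    """ChainParams from a flat YAML mapping (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    valid = set(ChainParams.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown parameters {sorted(unknown)}")
    return ChainParams(**raw)


def save_params(params: ChainParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=False)
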