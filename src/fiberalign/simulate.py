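"""Synthetic chromatin-tracing data: confined Gaussian-chain polymers.

The generator emulates seqFISH+-like multiplexed DNA FISH data: 20 mouse
chromosomes with ~0.3-1.9 Mb locus spacing, 0-4 copies per chromosome, each
copy confined to a spherical territory inside a spherical nucleus, with
tunable signal dropout (false negatives), stray localizations (false
positives) and sister-chromatid pairing.  Chains are sampled as sequential
Gaussian steps whose per-axis, per-interval variance (2/3)*tau^2*l_p*L
matches the alignment model's bond statistics by construction; steps leaving
the confinement sphere are rejection-resampled.  This is a desk-scale
statistical stand-in for molecular-dynamics polymer simulation: second
moments and confinement are reproduced, loop extrusion and excluded volume
are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ChainParams
from .reference import ReferenceMap

__all__ = [
    "MOUSE_CHROM_LENGTHS_BP",
    "SimulatedCell",
    "simulation_params",
    "territory_radius_nm",
    "default_reference_maps",
    "simulate_polymer",
    "fiber_spot_table",
    "inject_noise",
    "simulate_aneuploid_cell",
    "renoise_cell",
    "simulate_sister_pair",
]

# Approximate mm10 chromosome lengths (bp); 19 autosomes + X.
MOUSE_CHROM_LENGTHS_BP = {
    "chr1": 195_471_971, "chr2": 182_113_224, "chr3": 160_039_680,
    "chr4": 156_508_116, "chr5": 151_834_684, "chr6": 149_736_546,
    "chr7": 145_441_459, "chr8": 129_401_213, "chr9": 124_595_110,
    "chr10": 130_694_993, "chr11": 122_082_543, "chr12": 120_129_022,
    "chr13": 120_421_639, "chr14": 124_902_244, "chr15": 104_043_685,
    "chr16": 98_207_768, "chr17": 94_987_271, "chr18": 90_702_639,
    "chr19": 61_431_566, "chrX": 171_031_299,
}

#: Generator compaction scale, nm per bp.  Chosen so the RMS spatial
#: separation of loci 1 Mb apart is ~0.6 um, typical of chromatin-tracing
#: measurements at this genomic scale.
DEFAULT_SIM_TAU = 0.035

#: Nuclear radius, nm (mESC-like nucleus of ~5 um radius).
DEFAULT_NUCLEAR_RADIUS_NM = 5_000.0

#: Per-axis localization jitter added to true spots, nm.
DEFAULT_LOC_JITTER_NM = 50.0


def simulation_params(**overrides) -> ChainParams:
    """ChainParams preset with the generator's compaction scale."""
    kw = dict(tau=DEFAULT_SIM_TAU)
    kw.update(overrides)
    return ChainParams(**kw)


def territory_radius_nm(chrom_length_bp: float,
                        genome_length_bp: float | None = None,
                        nuclear_radius_nm: float = DEFAULT_NUCLEAR_RADIUS_NM) -> float:
    """Chromosome-territory radius: nuclear volume shared pro rata by length."""
    genome = genome_length_bp or sum(MOUSE_CHROM_LENGTHS_BP.values())
    return nuclear_radius_nm * (chrom_length_bp / genome) ** (1.0 / 3.0)


def default_reference_maps(seed: int = 0, spacing_range_bp=(0.3e6, 1.9e6),
                           first_locus_bp: float = 3e6,
                           chrom_lengths=None) -> dict[str, ReferenceMap]:
    """Reference locus maps with irregular (uniform) inter-locus spacing.

    Loci start after a centromere-proximal gap and are spaced i.i.d.
    uniformly in ``spacing_range_bp`` (mean ~1.1 Mb, so chr1 carries ~175
    loci).  Irregular spacing matters: the karyotype null threshold is built
    by permuting the interval sequence, which is only informative when the
    intervals differ.
    """
    chrom_lengths = chrom_lengths or MOUSE_CHROM_LENGTHS_BP
    rng = np.random.default_rng(seed)
    lo, hi = spacing_range_bp
    refs = {}
    for chrom, length in chrom_lengths.items():
        pos = [first_locus_bp]
        while True:
            nxt = pos[-1] + rng.uniform(lo, hi)
            if nxt > length:
                break
            pos.append(nxt)
        refs[chrom] = ReferenceMap(chrom, np.array(pos))
    return refs


def _uniform_in_sphere(rng: np.random.Generator, radius: float, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * r


def simulate_polymer(ref: ReferenceMap, params: ChainParams, radius_nm: float,
                     seed=None, center=(0.0, 0.0, 0.0), max_tries: int = 1000) -> np.ndarray:
    """Sample one confined Gaussian-chain fiber; returns (T, 3) nm coordinates.

    Successive loci are separated by Gaussian steps with per-axis variance
    (2/3)*tau^2*l_p*dL; any step leaving the sphere of ``radius_nm`` around
    ``center`` is resampled.  ``radius_nm = inf`` gives an unconfined random
    walk.  Deterministic under ``seed`` (an int or a Generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    step_sd = np.sqrt((2.0 / 3.0) * params.tau**2 * params.l_p * ref.intervals())
    if np.isfinite(radius_nm) and radius_nm <= step_sd.min() / 10:
        raise ValueError("confinement radius too small for the chain step size")
    coords = np.empty((ref.n_loci, 3))
    if np.isfinite(radius_nm):
        coords[0] = center + _uniform_in_sphere(rng, radius_nm, 1)[0]
    else:
        coords[0] = center
    for i, sd in enumerate(step_sd):
        for attempt in range(max_tries):
            nxt = coords[i] + rng.normal(scale=sd, size=3)
            if not np.isfinite(radius_nm) or np.linalg.norm(nxt - center) <= radius_nm:
                coords[i + 1] = nxt
                break
        else:
            raise RuntimeError("rejection sampling failed: radius too small for chain")
    return coords


def fiber_spot_table(chrom: str, cell_id, fiber_xyz: np.ndarray,
                     fiber_id: int = 0, jitter_nm: float = DEFAULT_LOC_JITTER_NM,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Spot table for one ground-truth fiber, with localization jitter."""
    rng = rng if rng is not None else np.random.default_rng()
    T = fiber_xyz.shape[0]
    obs = fiber_xyz + rng.normal(scale=jitter_nm, size=fiber_xyz.shape)
    return pd.DataFrame({
        "cell_id": cell_id,
        "chromosome": chrom,
        "locus_order": np.arange(1, T + 1),
        "x_nm": obs[:, 0], "y_nm": obs[:, 1], "z_nm": obs[:, 2],
        "sigma_x_nm": jitter_nm, "sigma_y_nm": jitter_nm, "sigma_z_nm": jitter_nm,
        "label": "TP",
        "fiber_id": fiber_id,
    })


def inject_noise(truth: pd.DataFrame, ref: ReferenceMap, fnr: float, fpr: float,
                 nuclear_radius_nm: float = DEFAULT_NUCLEAR_RADIUS_NM,
                 seed=None, n_slots: int | None = None,
                 center=(0.0, 0.0, 0.0)) -> pd.DataFrame:
    """Apply signal dropout and stray localizations to a true spot table.

    Each true spot is dropped independently with probability ``fnr``; stray
    spots (label "FP", fiber_id -1) are added at rate ``fpr`` per true locus
    slot (``n_slots``, default the number of true spots), placed uniformly in
    the nuclear sphere with uniform random locus identities.
    """
    if not (0 <= fnr <= 1 and 0 <= fpr <= 1):
        raise ValueError("fnr and fpr must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = rng.uniform(size=len(truth)) >= fnr
    kept = truth.loc[keep]
    slots = len(truth) if n_slots is None else int(n_slots)
    n_stray = int(rng.binomial(slots, fpr)) if slots > 0 and fpr > 0 else 0
    if n_stray:
        xyz = np.asarray(center, dtype=float) + _uniform_in_sphere(rng, nuclear_radius_nm, n_stray)
        cell_id = truth["cell_id"].iloc[0] if len(truth) else None
        stray = pd.DataFrame({
            "cell_id": cell_id,
            "chromosome": ref.chromosome,
            "locus_order": rng.integers(1, ref.n_loci + 1, size=n_stray),
            "x_nm": xyz[:, 0], "y_nm": xyz[:, 1], "z_nm": xyz[:, 2],
            "sigma_x_nm": DEFAULT_LOC_JITTER_NM, "sigma_y_nm": DEFAULT_LOC_JITTER_NM,
            "sigma_z_nm": DEFAULT_LOC_JITTER_NM,
            "label": "FP", "fiber_id": -1,
        })
        out = pd.concat([kept, stray], ignore_index=True)
    else:
        out = kept.reset_index(drop=True)
    return out.sort_values(["locus_order"], kind="stable").reset_index(drop=True)


@dataclass
class SimulatedCell:
    """Ground truth plus noisy observations for one simulated nucleus."""

    cell_id: object
    nuclear_radius_nm: float
    copy_numbers: dict            # chromosome -> true copy number (0-4)
    truth_xyz: dict               # chromosome -> (copies, T, 3) fiber coordinates, nm
    spots: pd.DataFrame           # noisy spot table with label / fiber_id columns
    truth_spots: pd.DataFrame | None = None   # jittered, pre-dropout spot table
    seed: int | None = None

    def chromosome_spots(self, chrom: str) -> pd.DataFrame:
        return self.spots[self.spots["chromosome"] == chrom]


def _territory_centers(rng: np.random.Generator, copies: int, c_max: float,
                       min_sep: float, max_tries: int = 100) -> np.ndarray:
    """Territory centers with mutual repulsion (dart throwing).

    Centers are drawn uniformly in the sphere of radius ``c_max`` and
    re-drawn until at least ``min_sep`` from every previous same-chromosome
    center; if that fails within ``max_tries`` the best (most separated)
    proposal is kept, so crowded nuclei degrade gracefully toward partial
    territory overlap rather than erroring.
    """
    centers = np.empty((copies, 3))
    for k in range(copies):
        best, best_d = None, -1.0
        for _ in range(max_tries):
            cand = _uniform_in_sphere(rng, c_max, 1)[0]
            d = (np.min(np.linalg.norm(centers[:k] - cand, axis=1))
                 if k else np.inf)
            if d >= min_sep:
                best = cand
                break
            if d > best_d:
                best, best_d = cand, d
        centers[k] = best
    return centers


def simulate_aneuploid_cell(refs: dict[str, ReferenceMap],
                            params: ChainParams | None = None,
                            fnr: float = 0.0, fpr: float = 0.0,
                            nuclear_radius_nm: float = DEFAULT_NUCLEAR_RADIUS_NM,
                            copy_range: tuple[int, int] = (0, 4),
                            loc_jitter_nm: float = DEFAULT_LOC_JITTER_NM,
                            territory_separation: float = 0.8,
                            seed=None, cell_id=0) -> SimulatedCell:
    """Simulate one aneuploid nucleus.

    Copy numbers are drawn independently and uniformly over ``copy_range``
    for every chromosome (the copy number of one chromosome cannot inform
    another's).  Each copy occupies its own spherical territory whose radius
    scales with the cube root of the chromosome's share of the genome.
    Same-chromosome territories repel each other: centers are re-drawn until
    separated by ``territory_separation`` times the territory diameter,
    emulating the near-exclusive territorial organization of interphase
    chromosomes while still permitting partial overlap in crowded (3N/4N)
    nuclei.  Dropout and strays are then injected per chromosome at the
    requested rates.
    """
    params = params or simulation_params()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genome_bp = sum(MOUSE_CHROM_LENGTHS_BP.get(c, ref.positions_bp[-1])
                    for c, ref in refs.items())
    copy_numbers, truth_xyz, frames = {}, {}, []
    for chrom, ref in refs.items():
        copies = int(rng.integers(copy_range[0], copy_range[1] + 1))
        copy_numbers[chrom] = copies
        chrom_bp = MOUSE_CHROM_LENGTHS_BP.get(chrom, ref.positions_bp[-1])
        terr_radius = territory_radius_nm(chrom_bp, genome_bp, nuclear_radius_nm)
        c_max = max(nuclear_radius_nm - terr_radius, 0.0)
        centers = _territory_centers(rng, copies, c_max,
                                     territory_separation * 2.0 * terr_radius)
        fibers = np.empty((copies, ref.n_loci, 3))
        truth_frames = []
        for k in range(copies):
            fibers[k] = simulate_polymer(ref, params, terr_radius, rng, centers[k])
            truth_frames.append(fiber_spot_table(chrom, cell_id, fibers[k], k,
                                             loc_jitter_nm, rng))
        truth_xyz[chrom] = fibers
        truth = (pd.concat(truth_frames, ignore_index=True) if truth_frames
                 else _empty_spot_frame())
        frames.append((truth, inject_noise(truth, ref, fnr, fpr,
                                           nuclear_radius_nm, rng)))
    truth_all = pd.concat([t for t, _ in frames if len(t)], ignore_index=True) \
        if any(len(t) for t, _ in frames) else _empty_spot_frame()
    spots = pd.concat([f for _, f in frames if len(f)], ignore_index=True) \
        if any(len(f) for _, f in frames) else _empty_spot_frame()
    return SimulatedCell(cell_id, nuclear_radius_nm, copy_numbers, truth_xyz, spots,
                         truth_spots=truth_all,
                         seed=None if isinstance(seed, np.random.Generator) else seed)


def renoise_cell(cell: SimulatedCell, refs: dict[str, ReferenceMap],
                 fnr: float, fpr: float, seed: int) -> SimulatedCell:
    """Re-apply dropout and strays to a cell's pre-noise truth table.

    Noise seeds are derived per (seed, chromosome index), and dropout draws
    are consumed before stray draws, so two calls with the same ``seed`` but
    different ``fpr`` share the *identical* dropout realization -- the
    paired design needed to isolate the placeholding effect of added noise.
    """
    if cell.truth_spots is None:
        raise ValueError("cell carries no pre-noise truth table")
    frames = []
    for idx, (chrom, ref) in enumerate(refs.items()):
        truth = cell.truth_spots[cell.truth_spots["chromosome"] == chrom]
        child = np.random.default_rng(np.random.SeedSequence((seed, idx)))
        frames.append(inject_noise(truth, ref, fnr, fpr, cell.nuclear_radius_nm,
                                   child))
    spots = pd.concat([f for f in frames if len(f)], ignore_index=True) \
        if any(len(f) for f in frames) else _empty_spot_frame()
    return SimulatedCell(cell.cell_id, cell.nuclear_radius_nm, cell.copy_numbers,
                         cell.truth_xyz, spots, truth_spots=cell.truth_spots,
                         seed=seed)


def _empty_spot_frame() -> pd.DataFrame:
    cols = ["cell_id", "chromosome", "locus_order", "x_nm", "y_nm", "z_nm",
            "sigma_x_nm", "sigma_y_nm", "sigma_z_nm", "label", "fiber_id"]
    return pd.DataFrame({c: [] for c in cols})


def simulate_sister_pair(ref: ReferenceMap, params: ChainParams | None = None,
                         pairing_strength: float = 1.0,
                         radius_nm: float = 2_000.0,
                         shadow_scale_nm: float = 500.0,
                         seed=None, center=(0.0, 0.0, 0.0)):
    """Two coupled sister-chromatid fibers; returns (fiber_a, fiber_b), nm.

    Fiber B shadows fiber A with a locus-wise isotropic Gaussian displacement
    of standard deviation ``shadow_scale_nm / pairing_strength``; stronger
    pairing pulls the sisters together, ``pairing_strength = 0`` yields an
    independent second fiber in the same territory.
    """
    if pairing_strength < 0:
        raise ValueError("pairing_strength must be >= 0")
    params = params or simulation_params()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = simulate_polymer(ref, params, radius_nm, rng, center)
    if pairing_strength == 0:
        b = simulate_polymer(ref, params, radius_nm, rng, center)
    else:
        sd = shadow_scale_nm / pairing_strength
        b = a + rng.normal(scale=sd, size=a.shape)
    return a, b
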