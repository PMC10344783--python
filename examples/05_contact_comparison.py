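"""Comparing traced distance matrices with a contact map.

Builds the median pairwise distance matrix of an ensemble of traced fibers
and correlates it (Spearman) with a synthetic contact matrix whose
frequencies decay with spatial distance -- the benchmarking route used to
validate alignment output against proximity-ligation data.  Real Hi-C
matrices are supplied by the user as dense CSV/TSV.
"""

import numpy as np

from fiberalign import (align, contact_comparison, default_reference_maps,
                        fiber_spot_table, match_bins, median_distance_matrix,
                        simulate_polymer, simulation_params)

ref = default_reference_maps(0)["chr19"]
params = simulation_params()
rng = np.random.default_rng(8)

traces = []
for k in range(40):
    chain = simulate_polymer(ref, params, 1800.0, rng)
    spots = fiber_spot_table("chr19", k, chain, rng=rng)
    tr = align(spots, ref, params)
    if tr is not None:
        traces.append(tr)

med = median_distance_matrix(traces)
print(f"{len(traces)} traces; median adjacent-locus distance "
      f"{np.nanmedian(np.diag(med, 1)):.0f} nm")

# synthetic "contact map": frequency decays exponentially with distance.
# It is locus-indexed here, so both sides of the bin map use locus indices;
# a real Hi-C matrix is bin-indexed and would use (locus_idx, bin_idx).
contacts = np.exp(-med / 700.0)
locus_idx, bin_idx = match_bins(ref, 1e6)
rho = contact_comparison(med, contacts, bin_map=(locus_idx, locus_idx))
print(f"kept {len(locus_idx)} loci closest to integer 1-Mb bins")
print(f"Spearman rho, log distance vs log contact: {rho:+.3f}")
# A perfect monotone decay gives rho = -1; traced distances against real
# Hi-C typically give strongly negative correlations when tracing is sound.
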