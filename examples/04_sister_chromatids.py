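"""Sister-chromatid geometry: pairing, cis/trans profiles, misselection.

Simulates tightly paired sister fibers, shows that sister assignment by
closest starts (SA) recovers the true pairs, builds cis/trans distance
profiles, and scans for loci a tracer would misselect from the wrong
sister.
"""

import numpy as np

from fiberalign import (assign_sisters, cis_trans_profiles,
                        default_reference_maps, misselection_scan,
                        simulate_sister_pair, simulation_params)
from fiberalign.aligner import PolymerTrace

ref = default_reference_maps(0)["chr19"]
params = simulation_params()


def as_trace(xyz, cell=0):
    T = len(xyz)
    return PolymerTrace("chr19", cell, np.arange(1, T + 1), np.arange(T),
                        np.asarray(xyz), np.zeros(T), 0.0, T)


# two sister pairs in two territories of one tetraploid nucleus
rng = np.random.default_rng(3)
a1, b1 = simulate_sister_pair(ref, params, pairing_strength=2.0, seed=rng)
a2, b2 = simulate_sister_pair(ref, params, pairing_strength=2.0, seed=rng,
                              center=(8000.0, 0.0, 0.0))
traces = [as_trace(a1), as_trace(b1), as_trace(a2), as_trace(b2)]

sa = assign_sisters(traces)
print("matchings (trace index pairs) ranked by start-start distance:")
for name, m, s in zip(("SA", "alt1", "alt2"),
                      (sa.sa, sa.alt1, sa.alt2),
                      np.sort(sa.start_sums)):
    print(f"  {name:>4}: {m}  summed start distance {s:8.0f} nm")
print(f"  EA matching (closest ends): {sa.ea}")
print(f"  same-fiber start-to-end control: "
      f"{np.round(sa.control_nm).astype(int).tolist()} nm")

profile, shadow = cis_trans_profiles([(traces[0], traces[1])], ref)
short = profile[profile["bin_mid_bp"] < 3e6]
print("\nshort-range distances (separation < 3 Mb):")
for kind in ("cis", "trans"):
    sel = short[short["kind"] == kind]
    print(f"  {kind:>5}: mean {sel['mean_nm'].mean():6.0f} nm over "
          f"{int(sel['n'].sum())} pairs")
print(f"  trans same-locus (shadowing) median: {np.median(shadow):.0f} nm")

scan = misselection_scan(traces[0], traces[1], ref, params)
print(f"\nmisselection scan: {scan.n_misselections} flagged windows of "
      f"{len(scan.window_starts)} ({100 * scan.misselection_rate:.1f}%), "
      f"{scan.n_crossovers} cross-over events")
# SA recovers the true sister pairs; trans distances exceed cis at short
# range by the shadowing displacement; flagged windows mark 3-locus blocks
# whose exchange would improve both fibers' bond likelihoods.
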