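"""Independent oracles used to cross-check the implementation.

The enumeration oracle is a from-scratch exhaustive sweep of the
bounded CHNOSP grid built with numpy masks; it shares no code with the
package's per-mass pruned search and applies the plausibility rules
independently.
"""

from __future__ import annotations

import numpy as np

# masses restated independently (IUPAC monoisotopic)
_M = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048,
      "O": 15.9949146196, "S": 31.97207100, "P": 30.97376163}

_GRID_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _build_grid(c_max=60, h_max=120, n_max=4, o_max=40, s_max=2, p_max=2,
                lo=90.0, hi=1010.0):
    """All valence-plausible formulas in the bounds, sorted by mass."""
    key = (c_max, h_max, n_max, o_max, s_max, p_max, lo, hi)
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]
    all_counts = []
    all_masses = []
    o = np.arange(o_max + 1, dtype=np.int32)
    c = np.arange(1, c_max + 1, dtype=np.int32)
    h = np.arange(h_max + 1, dtype=np.int32)
    O, C, H = np.meshgrid(o, c, h, indexing="ij")
    base_mass = _M["O"] * O + _M["C"] * C + _M["H"] * H
    for n in range(n_max + 1):
        for s in range(s_max + 1):
            for p in range(p_max + 1):
                mass = base_mass + _M["N"] * n + _M["S"] * s + _M["P"] * p
                dbe = 1 + C - H / 2 + (n + p) / 2
                ok = ((H / C >= 0.3) & (H / C <= 2.5) & (O / C <= 1.5)
                      & (H >= 1) & (dbe >= 0) & ((H + n + p) % 2 == 0)
                      & (mass >= lo) & (mass <= hi))
                m = mass[ok]
                cnt = np.stack([C[ok], H[ok],
                                np.full(m.size, n, dtype=np.int32),
                                O[ok],
                                np.full(m.size, s, dtype=np.int32),
                                np.full(m.size, p, dtype=np.int32)], axis=1)
                all_masses.append(m)
                all_counts.append(cnt)
    masses = np.concatenate(all_masses)
    counts = np.concatenate(all_counts)
    order = np.argsort(masses, kind="stable")
    _GRID_CACHE[key] = (masses[order], counts[order])
    return _GRID_CACHE[key]


def brute_force_candidates(neutral_mass: float, tol_ppm: float,
                           **bounds) -> set[tuple[int, int, int, int, int, int]]:
    """Exhaustive candidate set as (c, h, n, o, s, p) tuples."""
    masses, counts = _build_grid(**bounds)
    lo = neutral_mass * (1 - tol_ppm * 1e-6)
    hi = neutral_mass * (1 + tol_ppm * 1e-6)
    i0, i1 = np.searchsorted(masses, [lo, hi])
    return {tuple(int(x) for x in row) for row in counts[i0:i1]}
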