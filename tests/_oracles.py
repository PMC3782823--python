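"""Independent brute-force oracles for the graph-cut energy.

These recompute the segmentation energy and its global minimum directly from
the energy definition (negative-log likelihoods, contrast-weighted Potts
pairs) with plain loops / exhaustive enumeration, without touching the
package's energy or solver code paths.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_energy(image, labeling, models, seed_map, lam, mu, sigma, hard_cost,
                  neighborhood=8) -> float:
    """Direct loop evaluation of the energy of one labeling."""
    h, w = image.shape
    data = 0.0
    for r in range(h):
        for c in range(w):
            lab = int(labeling[r, c])
            if seed_map[r, c] >= 0:
                data += 0.0 if lab == seed_map[r, c] else hard_cost
            else:
                data += -math.log(models[lab][int(image[r, c])])
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighborhood == 8:
        offsets += [(1, 1, math.sqrt(2)), (1, -1, math.sqrt(2))]
    smooth = 0.0
    for r in range(h):
        for c in range(w):
            for dr, dc, dist in offsets:
                rn, cn = r + dr, c + dc
                if 0 <= rn < h and 0 <= cn < w and labeling[r, c] != labeling[rn, cn]:
                    d = float(image[r, c]) - float(image[rn, cn])
                    smooth += math.exp(-(d * d) / (2 * sigma**2)) / dist
    return lam * data + mu * smooth


def brute_force_min_energy_binary(image, models, seed_map, lam, mu, sigma,
                                  hard_cost, neighborhood=8) -> float:
    """Exhaustive minimum over all 2^n binary labelings (vectorized).

    ``models`` must hold exactly two labels; returns the global minimum
    energy.  Feasible up to 4x4 images.
    """
    labs = sorted(models)
    assert len(labs) == 2
    h, w = image.shape
    n = h * w
    flat = image.reshape(-1).astype(float)
    sl = seed_map.reshape(-1)

    D = np.empty((n, 2))
    for j, lab in enumerate(labs):
        D[:, j] = [-math.log(models[lab][int(v)]) for v in flat]
    for i in range(n):
        if sl[i] >= 0:
            for j, lab in enumerate(labs):
                D[i, j] = 0.0 if lab == sl[i] else hard_cost

    pairs = []
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighborhood == 8:
        offsets += [(1, 1, math.sqrt(2)), (1, -1, math.sqrt(2))]
    for r in range(h):
        for c in range(w):
            for dr, dc, dist in offsets:
                rn, cn = r + dr, c + dc
                if 0 <= rn < h and 0 <= cn < w:
                    d = flat[r * w + c] - flat[rn * w + cn]
                    v = math.exp(-(d * d) / (2 * sigma**2)) / dist
                    pairs.append((r * w + c, rn * w + cn, v))

    codes = np.arange(2**n, dtype=np.int64)
    bits = ((codes[:, None] >> np.arange(n)) & 1).astype(np.float64)  # (2^n, n)
    # two separate matmuls: never subtracts the huge hard-constraint costs,
    # which would otherwise lose ~1e-7 to float cancellation
    energies = lam * (bits @ D[:, 1] + (1.0 - bits) @ D[:, 0])
    for p, q, v in pairs:
        energies += mu * v * (bits[:, p] != bits[:, q])
    return float(energies.min())
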