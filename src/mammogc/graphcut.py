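"""Seed-constrained multi-label segmentation by graph cuts.

The segmentation minimizes a Potts-style energy over labelings ``L``:

    E(L) = lambda * sum_p D_p(L_p)  +  mu * sum_{p,q in N} V_pq * [L_p != L_q]

``D_p`` is the negative log-likelihood of pixel ``p``'s intensity under a
per-label model estimated from that label's seed pixels (a 256-bin histogram,
optionally Parzen-smoothed, floored and renormalized).  Seed pixels are hard
constraints: their own label costs 0 and every other label a large finite
``hard_cost``.  ``V_pq = exp(-(I_p - I_q)^2 / (2 sigma^2)) / dist(p, q)`` is
the contrast-sensitive boundary weight, charged only across label
discontinuities.

Minimization uses alpha-expansion: sweeps over the labels in ascending id
order, each move solved exactly by a single min-cut on the standard expansion
graph (auxiliary nodes between unequal-labeled neighbor pairs).  Min-cuts are
computed with scipy's max-flow on fixed-point integer capacities; a move is
accepted only if it strictly lowers the (float) energy, so the energy is
non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .labels import REGION_NAMES
from .maxflow import min_cut

# Fixed-point scaling of float edge costs to int64 max-flow capacities.
_SCALE = float(2**40)
_CAP_FLOAT_MAX = float(2**20)  # costs at or above this saturate (hard constraints)


@dataclass(frozen=True)
class GCParams:
    """Energy weights and solver settings.

    lam, mu
        Data- and smoothness-term weights (defaults 10 and 20).
    neighborhood
        4 or 8-connected pixel grid (default 8).
    sigma
        Boundary contrast scale in gray levels (default 10).
    hard_cost
        Large finite penalty for violating a seed (default 1e9); must dwarf
        any achievable regular energy.
    epsilon
        Likelihood floor for histogram bins (default 1e-6).
    max_sweeps
        Upper bound on full expansion sweeps (default 10).
    model_sigma
        Parzen width (gray levels) for smoothing seed histograms; 0 keeps the
        raw histogram.
    """

    lam: float = 10.0
    mu: float = 20.0
    neighborhood: int = 8
    sigma: float = 10.0
    hard_cost: float = 1e9
    epsilon: float = 1e-6
    max_sweeps: int = 10
    model_sigma: float = 0.0

    def validate(self) -> None:
        if self.lam < 0 or self.mu < 0:
            raise ValueError("lambda and mu must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        if self.epsilon <= 0 or self.epsilon >= 1 / 256:
            raise ValueError("epsilon must lie in (0, 1/256)")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if self.model_sigma < 0:
            raise ValueError("model_sigma must be >= 0")
        # hard constraints must dominate any achievable regular energy
        if self.hard_cost <= 100 * (self.lam * -np.log(self.epsilon) + 8 * self.mu):
            raise ValueError("hard_cost too small to act as a hard constraint")


@dataclass(frozen=True)
class SeedSet:
    """Pixel -> label hard constraints: entries of (row, col, label id)."""

    entries: tuple[tuple[int, int, int], ...]

    def __init__(self, entries):
        object.__setattr__(
            self, "entries", tuple((int(r), int(c), int(l)) for r, c, l in entries)
        )

    @property
    def labels_in_use(self) -> tuple[int, ...]:
        return tuple(sorted({l for _, _, l in self.entries}))

    def validate(self, shape: tuple[int, int]) -> None:
        seen: dict[tuple[int, int], int] = {}
        for r, c, l in self.entries:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"seed ({r},{c}) out of bounds for image {shape}")
            if l not in REGION_NAMES or l > 5:
                raise ValueError(f"seed label id {l} is not a segmentation label")
            if seen.setdefault((r, c), l) != l:
                raise ValueError(f"conflicting seed labels at pixel ({r},{c})")

    def seed_label_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel seed label, -1 where unseeded."""
        m = np.full(shape, -1, dtype=np.int64)
        for r, c, l in self.entries:
            m[r, c] = l
        return m


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy split into its unweighted sums: total = lam*data + mu*smooth."""

    total: float
    data_term: float
    smooth_term: float


def _as_seedset(seeds) -> SeedSet:
    return seeds if isinstance(seeds, SeedSet) else SeedSet(seeds)


def estimate_label_models(
    image: np.ndarray, seeds, params: GCParams = GCParams()
) -> dict[int, np.ndarray]:
    """Per-label normalized 256-bin intensity histograms from seed pixels.

    Raw seed histograms may be Parzen-smoothed (``params.model_sigma`` gray
    levels), are floored at ``params.epsilon`` and renormalized to sum to 1.
    """
    image = np.asarray(image)
    seeds = _as_seedset(seeds)
    seeds.validate(image.shape)
    if not seeds.entries:
        raise ValueError("unseeded label: no seeds supplied")
    models: dict[int, np.ndarray] = {}
    for lab in seeds.labels_in_use:
        vals = [int(image[r, c]) for r, c, l in seeds.entries if l == lab]
        hist = np.bincount(vals, minlength=256).astype(np.float64)
        hist /= hist.sum()
        if params.model_sigma > 0:
            hist = ndimage.gaussian_filter1d(hist, params.model_sigma, mode="constant")
        hist = np.maximum(hist, params.epsilon)
        hist /= hist.sum()
        models[lab] = hist
    return models


def data_cost(
    models: dict[int, np.ndarray],
    intensity: int,
    label: int,
    seed_label: int | None = None,
    params: GCParams = GCParams(),
) -> float:
    """-ln likelihood of ``intensity`` under ``label``'s model.

    For a seeded pixel (``seed_label`` given) the cost is 0 for the seed
    label and ``params.hard_cost`` for every other label.
    """
    if seed_label is not None:
        return 0.0 if int(label) == int(seed_label) else float(params.hard_cost)
    if label not in models:
        raise ValueError(f"no model for label {label}")
    return float(-np.log(models[int(label)][int(intensity)]))


def smooth_weight(ip: float, iq: float, dist: float, params: GCParams = GCParams()) -> float:
    """Contrast-sensitive boundary weight exp(-(ip-iq)^2 / (2 sigma^2)) / dist."""
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    d = float(ip) - float(iq)
    return float(np.exp(-(d * d) / (2.0 * params.sigma**2)) / float(dist))


def _neighbor_pairs(shape: tuple[int, int], neighborhood: int):
    """Unordered neighbor pairs as flat index arrays (p, q) plus distances."""
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    pairs_p, pairs_q, dist = [], [], []

    def add(a, b, d):
        pairs_p.append(a.ravel())
        pairs_q.append(b.ravel())
        dist.append(np.full(a.size, d))

    add(idx[:, :-1], idx[:, 1:], 1.0)  # horizontal
    add(idx[:-1, :], idx[1:, :], 1.0)  # vertical
    if neighborhood == 8:
        add(idx[:-1, :-1], idx[1:, 1:], np.sqrt(2.0))  # diagonal \
        add(idx[:-1, 1:], idx[1:, :-1], np.sqrt(2.0))  # diagonal /
    return (
        np.concatenate(pairs_p),
        np.concatenate(pairs_q),
        np.concatenate(dist),
    )


def _pair_weights(image: np.ndarray, params: GCParams):
    p, q, dist = _neighbor_pairs(image.shape, params.neighborhood)
    flat = image.reshape(-1).astype(np.float64)
    d = flat[p] - flat[q]
    v = np.exp(-(d * d) / (2.0 * params.sigma**2)) / dist
    return p, q, v


def _data_volume(image: np.ndarray, models: dict[int, np.ndarray],
                 seed_map: np.ndarray, params: GCParams, scheme: tuple[int, ...]):
    """(N, L) matrix of D_p(label) with seed overrides applied."""
    flat = image.reshape(-1).astype(np.int64)
    sl = seed_map.reshape(-1)
    D = np.empty((flat.size, len(scheme)), dtype=np.float64)
    for j, lab in enumerate(scheme):
        D[:, j] = -np.log(models[lab][flat])
    seeded = sl >= 0
    if seeded.any():
        for j, lab in enumerate(scheme):
            D[seeded, j] = np.where(sl[seeded] == lab, 0.0, params.hard_cost)
    return D


def energy(
    image: np.ndarray,
    labeling: np.ndarray,
    models: dict[int, np.ndarray],
    seeds,
    params: GCParams = GCParams(),
) -> EnergyBreakdown:
    """Evaluate the segmentation energy of an arbitrary labeling."""
    image = np.asarray(image)
    labeling = np.asarray(labeling)
    if image.shape != labeling.shape:
        raise ValueError("image and labeling shapes differ")
    params.validate()
    seeds = _as_seedset(seeds)
    seeds.validate(image.shape)
    scheme = tuple(sorted(models))
    present = np.unique(labeling)
    if not set(int(x) for x in present) <= set(scheme):
        raise ValueError(f"labeling uses labels outside the scheme {scheme}")
    seed_map = seeds.seed_label_map(image.shape)
    D = _data_volume(image, models, seed_map, params, scheme)
    col = {lab: j for j, lab in enumerate(scheme)}
    lflat = np.vectorize(col.__getitem__, otypes=[np.int64])(labeling.reshape(-1))
    data_sum = float(D[np.arange(D.shape[0]), lflat].sum())
    p, q, v = _pair_weights(image, params)
    lab_flat = labeling.reshape(-1)
    smooth_sum = float(v[lab_flat[p] != lab_flat[q]].sum())
    return EnergyBreakdown(
        total=params.lam * data_sum + params.mu * smooth_sum,
        data_term=data_sum,
        smooth_term=smooth_sum,
    )


def _to_caps(x: np.ndarray) -> np.ndarray:
    return np.rint(np.minimum(x, _CAP_FLOAT_MAX) * _SCALE).astype(np.int64)


def _expansion_mincut(labeling_flat, alpha_col, lamD, pair_p, pair_q, muV):
    """One exact alpha-expansion min-cut; returns the proposed flat labeling.

    Graph convention: source side = keep the current label, sink side = take
    alpha.  Pairs with unequal current labels (neither alpha) go through an
    auxiliary node; pairs with one endpoint already alpha reduce to a unary
    cost on the other endpoint.
    """
    n = labeling_flat.size
    scap = lamD[:, alpha_col].copy()  # s->p, cut iff p takes alpha
    tcap = lamD[np.arange(n), labeling_flat].copy()  # p->t, cut iff p keeps

    is_alpha_p = labeling_flat[pair_p] == alpha_col
    is_alpha_q = labeling_flat[pair_q] == alpha_col
    same = labeling_flat[pair_p] == labeling_flat[pair_q]

    # one endpoint fixed at alpha -> unary on the other
    m = is_alpha_p & ~is_alpha_q
    np.add.at(tcap, pair_q[m], muV[m])
    m = is_alpha_q & ~is_alpha_p
    np.add.at(tcap, pair_p[m], muV[m])

    m_same = same & ~is_alpha_p  # undirected p<->q
    m_diff = ~same & ~is_alpha_p & ~is_alpha_q  # auxiliary node per pair

    k = int(m_diff.sum())
    s_node, t_node = n + k, n + k + 1
    aux = np.arange(n, n + k)

    eu, ev, fwd, bwd = [], [], [], []

    def add(u, v, cf, cb):
        u = np.asarray(u, dtype=np.int64).ravel()
        eu.append(u)
        ev.append(np.asarray(v, dtype=np.int64).ravel())
        fwd.append(_to_caps(np.asarray(cf, dtype=np.float64).ravel()))
        if np.isscalar(cb):
            bwd.append(np.zeros(u.size, dtype=np.int64))
        else:
            bwd.append(_to_caps(np.asarray(cb, dtype=np.float64).ravel()))

    pix = np.arange(n)
    add(np.full(n, s_node), pix, scap, 0)
    add(pix, np.full(n, t_node), tcap, 0)
    w = muV[m_same]
    add(pair_p[m_same], pair_q[m_same], w, w)
    if k:
        w = muV[m_diff]
        add(pair_p[m_diff], aux, w, w)
        add(pair_q[m_diff], aux, w, w)
        add(aux, np.full(k, t_node), w, 0)

    _, source_side = min_cut(
        n + k + 2, s_node, t_node,
        np.concatenate(eu), np.concatenate(ev),
        np.concatenate(fwd), np.concatenate(bwd),
    )
    new = labeling_flat.copy()
    new[~source_side[:n]] = alpha_col  # sink side takes alpha
    return new


def expansion_move(
    labeling: np.ndarray,
    alpha: int,
    image: np.ndarray,
    models: dict[int, np.ndarray],
    seeds,
    params: GCParams = GCParams(),
) -> np.ndarray:
    """Optimal single alpha-expansion from ``labeling``; never raises the energy."""
    image = np.asarray(image)
    labeling = np.asarray(labeling)
    params.validate()
    seeds = _as_seedset(seeds)
    scheme = tuple(sorted(models))
    if int(alpha) not in scheme:
        raise ValueError(f"alpha {alpha} not in scheme {scheme}")
    seed_map = seeds.seed_label_map(image.shape)
    D = _data_volume(image, models, seed_map, params, scheme)
    pair_p, pair_q, v = _pair_weights(image, params)
    col = {lab: j for j, lab in enumerate(scheme)}
    lflat = np.vectorize(col.__getitem__, otypes=[np.int64])(labeling.reshape(-1))
    new_flat = _expansion_mincut(
        lflat, col[int(alpha)], params.lam * D, pair_p, pair_q, params.mu * v
    )
    inv = np.asarray(scheme)
    new_lab = inv[new_flat].reshape(labeling.shape)
    e_old = energy(image, labeling, models, seeds, params).total
    e_new = energy(image, new_lab, models, seeds, params).total
    return new_lab if e_new <= e_old else labeling.copy()


def _energy_from_flat(lflat, lamD, pair_p, pair_q, muV):
    data = lamD[np.arange(lflat.size), lflat].sum()
    smooth = muV[lflat[pair_p] != lflat[pair_q]].sum()
    return float(data + smooth)


def segment(
    image: np.ndarray,
    seeds,
    params: GCParams = GCParams(),
    return_history: bool = False,
):
    """Full seeded multi-label segmentation.

    Starts from the per-pixel argmin of the data cost (ties to the smallest
    label id) and sweeps alpha-expansions over the labels in ascending id
    order until a full sweep brings no energy decrease or ``max_sweeps`` is
    reached.  Returns ``(label_map, EnergyBreakdown)`` — plus the per-move
    energy history when ``return_history`` is set.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    params.validate()
    seeds = _as_seedset(seeds)
    seeds.validate(image.shape)
    # 3-6 labels is the anatomically meaningful range; 2 is permitted for
    # plain binary foreground/background problems.
    scheme = seeds.labels_in_use
    if not 2 <= len(scheme) <= 6:
        raise ValueError(f"2 to 6 labels must be in use, got {len(scheme)}")
    models = estimate_label_models(image, seeds, params)
    seed_map = seeds.seed_label_map(image.shape)
    D = _data_volume(image, models, seed_map, params, scheme)
    pair_p, pair_q, v = _pair_weights(image, params)
    lamD, muV = params.lam * D, params.mu * v

    lflat = np.argmin(D, axis=1).astype(np.int64)  # ties -> smallest label id
    e_cur = _energy_from_flat(lflat, lamD, pair_p, pair_q, muV)
    history = [e_cur]
    for _ in range(params.max_sweeps):
        improved = False
        for j, _lab in enumerate(scheme):
            proposal = _expansion_mincut(lflat, j, lamD, pair_p, pair_q, muV)
            e_new = _energy_from_flat(proposal, lamD, pair_p, pair_q, muV)
            if e_new < e_cur:
                lflat, e_cur = proposal, e_new
                improved = True
            history.append(e_cur)
        if not improved:
            break

    inv = np.asarray(scheme)
    label_map = inv[lflat].reshape(image.shape)
    breakdown = energy(image, label_map, models, seeds, params)
    if return_history:
        return label_map, breakdown, history
    return label_map, breakdown
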