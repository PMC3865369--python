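"""Genetical-genomics simulation: the generative benchmark for the joint model.

The generator emulates a backcross eQTL study observed in T = 3 conditions
(tissues): a single 1000 cM chromosome carrying q = 10 equally spaced
markers, p = 30 genes whose conditional dependence graph is a
Barabasi-Albert scale-free network shared across conditions up to 10%
condition-specific edges, precision matrices with Unif(+-[0.5, 1]) edge
weights and diagonally dominant diagonals, and expression

    Y_t = X B_t^T + E_t,     rows of E_t ~ N_p(0, Omega_t^{-1}).

Two regimes for the marker coefficients B_t (p genes x q markers):

* Case 1 - three isolated marker effects per condition, genes 1..3 driven
  by markers 1, 4, 8 with fixed coefficients; covariates barely matter, so
  conditioning offers no advantage.
* Case 2 - hotspots: genes 1-18 load on marker 1, genes 19-25 on marker 4,
  genes 26-30 on marker 8, coefficients equal to the Case-1 values
  perturbed by N(0, 0.1^2); marker-induced marginal association is strong
  and conditioning pays off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import networkx as nx
import numpy as np

from .io import GeneticMap

# study-design constants of the benchmark
N_CONDITIONS = 3
N_GENES = 30
N_MARKERS = 10
MAP_LENGTH_CM = 1000.0
BA_SEED_NODES = 7  # a path on 7 nodes carries the 6 seed edges

#: Case-1 coefficients: condition -> values at (gene, marker) positions
#: (1,1), (2,4), (3,8) (1-based).
CASE1_COEFFS = (
    (-0.09, 0.789, -0.667),
    (1.361, 1.508, -2.608),
    (0.687, 0.316, 2.020),
)
CASE1_POSITIONS = ((0, 0), (1, 3), (2, 7))  # 0-based (gene, marker)

#: Case-2 hotspot gene blocks (0-based, half-open) and their markers.
CASE2_BLOCKS = (((0, 18), 0), ((18, 25), 3), ((25, 30), 7))
CASE2_SD = 0.1


def default_map(q: int = N_MARKERS, length_cM: float = MAP_LENGTH_CM) -> GeneticMap:
    """``q`` equally spaced markers on a single chromosome of the given length."""
    positions = np.linspace(0.0, length_cM, q)
    return GeneticMap(markers=[(f"M{i + 1}", "1", float(pos))
                               for i, pos in enumerate(positions)])


def haldane(d_cM: np.ndarray) -> np.ndarray:
    """Haldane map function: recombination fraction r = (1 - exp(-2d/100)) / 2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def simulate_backcross(n: int, gmap: GeneticMap, rng) -> np.ndarray:
    """Backcross genotypes (0/1) for ``n`` individuals along a genetic map.

    Within a chromosome the genotype is a Markov chain: the first marker is
    Bernoulli(1/2) and each subsequent marker flips with the Haldane
    recombination fraction of the inter-marker distance.  Chromosomes are
    independent.
    """
    rng = np.random.default_rng(rng)
    if not gmap.markers:
        raise ValueError("genetic map is empty")
    cols = []
    for _, group in _by_chromosome(gmap):
        pos = np.array([m[2] for m in group])
        g = rng.integers(0, 2, size=n)
        cols.append(g.copy())
        for d in np.diff(pos):
            flip = rng.random(n) < haldane(d)
            g = np.where(flip, 1 - g, g)
            cols.append(g.copy())
    return np.column_stack(cols).astype(float)


def _by_chromosome(gmap: GeneticMap):
    groups: dict[str, list] = {}
    order: list[str] = []
    for m in gmap.markers:
        if m[1] not in groups:
            groups[m[1]] = []
            order.append(m[1])
        groups[m[1]].append(m)
    return [(c, groups[c]) for c in order]


def simulate_scale_free(p: int = N_GENES, *, n_conditions: int = N_CONDITIONS,
                        specific_fraction: float = 0.1, seed=None):
    """Common scale-free adjacency plus condition-specific augmentations.

    The common graph grows by preferential attachment (one edge per new
    node) from a path seed graph on 7 nodes, giving M = 6 + (p - 7) common
    edges.  Each condition then receives ``round(specific_fraction * M)``
    uniformly chosen extra non-edges of its own.

    Returns ``(common, [adj_1, ..., adj_T])`` as boolean (p, p) arrays.
    """
    if p < BA_SEED_NODES + 1:
        raise ValueError(f"p must be at least {BA_SEED_NODES + 1}")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(
        p, 1, seed=int(rng.integers(2**31)), initial_graph=nx.path_graph(BA_SEED_NODES))
    common = np.zeros((p, p), dtype=bool)
    for a, b in g.edges:
        common[a, b] = common[b, a] = True
    M = int(common.sum() // 2)
    n_extra = int(np.floor(specific_fraction * M + 0.5))  # round half away from zero
    iu = np.triu_indices(p, 1)
    non_edges = np.flatnonzero(~common[iu])
    adjacencies = []
    for _ in range(n_conditions):
        adj = common.copy()
        pick = rng.choice(non_edges, size=n_extra, replace=False)
        adj[iu[0][pick], iu[1][pick]] = True
        adj[iu[1][pick], iu[0][pick]] = True
        adjacencies.append(adj)
    return common, adjacencies


def build_precision(adjacency: np.ndarray, rng, *, min_eig: float = 1e-8,
                    max_tries: int = 1000) -> np.ndarray:
    """Draw a PD precision matrix supported on ``adjacency``.

    Edge weights are Unif([-1, -0.5] U [0.5, 1]); each diagonal entry is
    the absolute row sum of the off-diagonals (isolated nodes get 1, since
    a zero diagonal would be singular).  Diagonal dominance makes the
    matrix PSD (Gershgorin); sign-consistent configurations (every tree,
    for instance) are exactly singular, so the draw is rejected and all
    off-diagonals resampled until the smallest eigenvalue exceeds
    ``min_eig``.
    """
    adj = np.asarray(adjacency, dtype=bool)
    if adj.shape[0] != adj.shape[1] or np.any(adj != adj.T) or np.any(np.diag(adj)):
        raise ValueError("adjacency must be symmetric with a zero diagonal")
    if not adj.any():
        raise ValueError("adjacency has no edges")
    rng = np.random.default_rng(rng)
    p = adj.shape[0]
    iu = np.triu_indices(p, 1)
    edge_mask = adj[iu]
    n_edges = int(edge_mask.sum())
    for _ in range(max_tries):
        vals = rng.uniform(0.5, 1.0, size=n_edges) * rng.choice([-1.0, 1.0], size=n_edges)
        omega = np.zeros((p, p))
        omega[iu[0][edge_mask], iu[1][edge_mask]] = vals
        omega = omega + omega.T
        d = np.abs(omega).sum(axis=1)
        d[d == 0] = 1.0  # isolated node: unit variance
        omega[np.diag_indices(p)] = d
        if np.linalg.eigvalsh(omega)[0] > min_eig:
            return omega
    raise RuntimeError(f"no positive definite draw in {max_tries} attempts "
                       "(pathological adjacency)")


def simulate_expression(X: np.ndarray, B_t: np.ndarray, Omega_t: np.ndarray,
                        rng) -> np.ndarray:
    """Expression ``Y = X B_t^T + E`` with rows of E ~ N_p(0, Omega_t^{-1}).

    Noise is drawn by back-solving with the Cholesky factor of ``Omega_t``
    (``E_i = L^{-T} z_i``), which samples exactly from the inverse without
    forming it.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    B_t = np.asarray(B_t, dtype=float)
    Omega_t = np.asarray(Omega_t, dtype=float)
    try:
        L = np.linalg.cholesky(Omega_t)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Omega_t must be positive definite") from exc
    n, p = X.shape[0], Omega_t.shape[0]
    Z = rng.standard_normal((n, p))
    from scipy.linalg import solve_triangular
    E = solve_triangular(L, Z.T, trans="T", lower=True).T
    return X @ B_t.T + E


def make_case1_B() -> list:
    """The three deterministic Case-1 coefficient matrices (p x q)."""
    Bs = []
    for coeffs in CASE1_COEFFS:
        B = np.zeros((N_GENES, N_MARKERS))
        for (g, m), v in zip(CASE1_POSITIONS, coeffs):
            B[g, m] = v
        Bs.append(B)
    return Bs


def make_case2_B(rng) -> list:
    """Case-2 hotspot coefficient matrices: Case-1 values broadcast to gene
    blocks and perturbed by independent N(0, 0.1^2)."""
    rng = np.random.default_rng(rng)
    Bs = []
    for coeffs in CASE1_COEFFS:
        B = np.zeros((N_GENES, N_MARKERS))
        for ((lo, hi), marker), base in zip(CASE2_BLOCKS, coeffs):
            B[lo:hi, marker] = base + rng.normal(0.0, CASE2_SD, size=hi - lo)
        Bs.append(B)
    return Bs


@dataclass
class SimScenario:
    """One generated replicate: inputs plus ground truth."""

    case: str
    n: int
    X: np.ndarray
    Ys: list
    B: list
    true_omegas: list
    true_adjacencies: list
    common_adjacency: np.ndarray
    gmap: GeneticMap
    seed: object = None

    @property
    def T(self) -> int:
        return len(self.Ys)

    @property
    def p(self) -> int:
        return self.true_omegas[0].shape[0]


def simulate_scenario(case: str, n: int, seed=None, *, p: int = N_GENES,
                      q: int = N_MARKERS, gmap: GeneticMap | None = None) -> SimScenario:
    """Generate one replicate of the benchmark (Case 1 or Case 2)."""
    if case not in ("case1", "case2"):
        raise ValueError("case must be 'case1' or 'case2'")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_geno, s_net, s_prec, s_B, s_noise = ss.spawn(5)
    gmap = gmap or default_map(q)
    X = simulate_backcross(n, gmap, np.random.default_rng(s_geno))
    common, adjacencies = simulate_scale_free(p, seed=s_net)
    prec_rng = np.random.default_rng(s_prec)
    omegas = [build_precision(adj, prec_rng) for adj in adjacencies]
    if case == "case1":
        Bs = make_case1_B()
    else:
        Bs = make_case2_B(np.random.default_rng(s_B))
    noise_rng = np.random.default_rng(s_noise)
    Ys = [simulate_expression(X, B, om, noise_rng) for B, om in zip(Bs, omegas)]
    return SimScenario(case=case, n=n, X=X, Ys=Ys, B=Bs, true_omegas=omegas,
                       true_adjacencies=adjacencies, common_adjacency=common,
                       gmap=gmap, seed=seed)


def run_scenario(case: str, n: int, n_reps: int, seed=None) -> Iterator[SimScenario]:
    """Stream of independent replicates, deterministic given ``seed``.

    The marker map is fixed across replicates; genotypes, network,
    precisions, Case-2 coefficients and noise are redrawn each replicate.
    """
    ss = np.random.SeedSequence(seed)
    gmap = default_map()
    for child in ss.spawn(n_reps):
        yield simulate_scenario(case, n, seed=child, gmap=gmap)
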