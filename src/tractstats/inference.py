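"""Vertex-wise GLM statistics and cluster permutation inference.

A two-sample comparison with nuisance covariates is fit at every skeleton
vertex; supra-threshold vertices are grouped into connected clusters whose
mass is their surface area; and family-wise-error-corrected p-values come
from the permutation distribution of the maximal cluster mass pooled over
all tracts.  Label permutation respects covariates via the Freedman-Lane
scheme; tiny designs without covariates fall back to exhaustive
enumeration of the label splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .errors import ConfigError, DesignError
from .mesh import SkeletonMesh
from .projection import VertexDataset, vertex_area_weights

log = logging.getLogger(__name__)

DIRECTIONS = ("group1_lower", "group2_lower", "both")


@dataclass
class GlmDesign:
    """Two-group design with optional covariate columns (age, sex, ...).

    The model fit at each vertex is ``value ~ 1 + [group == group_b] +
    covariates``; a positive group coefficient means ``group_b`` has the
    higher adjusted mean, so "group2_lower" clusters live in the negative
    tail of the t map.
    """

    group_a: str
    group_b: str
    labels: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: tuple = ()
    contrast_direction: str = "both"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim != 2 or len(self.covariates) != len(self.labels):
                raise DesignError("covariates must be (n_subjects, k)")
        if self.contrast_direction not in DIRECTIONS:
            raise DesignError(
                f"contrast_direction must be one of {DIRECTIONS}"
            )
        present = set(self.labels.tolist())
        if present != {self.group_a, self.group_b}:
            raise DesignError(
                f"labels must contain exactly {{{self.group_a}, {self.group_b}}}, "
                f"got {sorted(present)}"
            )
        for g in (self.group_a, self.group_b):
            if np.count_nonzero(self.labels == g) < 2:
                raise DesignError(f"group {g} needs at least 2 subjects")
        X = self.matrix()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError("design matrix is rank deficient")

    @classmethod
    def from_records(cls, records, group_a: str, group_b: str,
                     covariates=("age", "sex"),
                     contrast_direction: str = "both") -> "GlmDesign":
        """Build a design from subject records, keeping only the two groups."""
        sel = [r for r in records if r.group in (group_a, group_b)]
        labels = np.array([r.group for r in sel])
        cols = []
        for name in covariates:
            if name == "age":
                cols.append([r.age for r in sel])
            elif name == "sex":
                cols.append([1.0 if r.sex == "F" else 0.0 for r in sel])
            else:
                raise DesignError(f"unknown covariate {name!r}")
        cov = np.array(cols).T if cols else None
        return cls(group_a, group_b, labels, cov, tuple(covariates),
                   contrast_direction)

    @property
    def n(self) -> int:
        return len(self.labels)

    def group_indicator(self) -> np.ndarray:
        return (self.labels == self.group_b).astype(float)

    def matrix(self) -> np.ndarray:
        cols = [np.ones(self.n), self.group_indicator()]
        if self.covariates is not None:
            cols.extend(self.covariates.T)
        return np.column_stack(cols)

    def subject_subset(self, records):
        """Subject ids belonging to the two groups, in record order."""
        return [r.subject_id for r in records if r.group in (self.group_a, self.group_b)]


@dataclass
class ClusterConfig:
    """Cluster-forming threshold, permutation count, and FWER level.

    ``cluster_forming_p`` is a two-sided vertex-level tail probability
    mapped to the t threshold through the Student quantile at the design's
    residual degrees of freedom (default .01); the default permutation
    count is 10,000 and significance is declared at ``fwer_alpha``.
    """

    cluster_forming_p: float = 0.01
    n_permutations: int = 10_000
    fwer_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.cluster_forming_p < 1.0:
            raise ConfigError("cluster_forming_p must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be at least 100")
        if not 0.0 < self.fwer_alpha < 1.0:
            raise ConfigError("fwer_alpha must lie in (0, 1)")

    def t_threshold(self, df: int) -> float:
        return float(stats.t.ppf(1.0 - self.cluster_forming_p / 2.0, df))


@dataclass
class Cluster:
    """A connected supra-threshold region on one mesh."""

    vertices: np.ndarray
    mass: float
    peak_t: float
    direction: str


@dataclass
class ClusterResult:
    """A cluster with its FWER-corrected permutation p-value."""

    tract: str
    vertices: np.ndarray
    mass: float
    peak_t: float
    direction: str
    p_fwer: float
    significant: bool


def _t_from_design(X: np.ndarray, Y: np.ndarray, pinv: np.ndarray | None = None):
    """t statistic of the group column (index 1) at every vertex.

    Returns (t, zero_variance_mask); zero residual variance yields t = 0.
    """
    if pinv is None:
        pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = X.shape[0] - np.linalg.matrix_rank(X)
    rss = np.einsum("ij,ij->j", resid, resid)
    # Exact fits leave round-off residuals; treat those as zero variance.
    scale = np.max(np.abs(Y), axis=0)
    zero = rss <= X.shape[0] * (1e-10 * (scale + 1e-300)) ** 2
    cgg = (pinv @ pinv.T)[1, 1]
    se = np.sqrt(np.clip(rss, 0.0, None) / df * cgg)
    good = ~zero & (se > 0)
    t = np.where(good, beta[1] / np.where(se > 0, se, 1.0), 0.0)
    return t, ~good


def vertexwise_tstat(dataset: VertexDataset | np.ndarray, design: GlmDesign):
    """Per-vertex GLM t map for the group coefficient.

    Returns (t, zero_variance_flags).  Degrees of freedom are
    ``n - rank(design)``; vertices with zero residual variance are flagged
    and report t = 0.
    """
    Y = dataset.values if isinstance(dataset, VertexDataset) else np.asarray(dataset, float)
    if Y.ndim != 2 or Y.shape[0] != design.n:
        raise DesignError("dataset rows must match the design's subjects")
    t, flags = _t_from_design(design.matrix(), Y)
    if np.any(flags):
        log.warning("%d vertices with zero residual variance; t set to 0",
                    int(flags.sum()))
    return t, flags


def _direction_mask(t: np.ndarray, t0: float, direction: str) -> np.ndarray:
    # group1_lower: group_b adjusted mean higher -> positive tail.
    if direction == "group1_lower":
        return t >= t0
    if direction == "group2_lower":
        return t <= -t0
    raise ConfigError(f"unknown direction {direction!r}")


def _connected_components(mask: np.ndarray, edges: np.ndarray):
    """Components of the supra-threshold subgraph as lists of vertex ids."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    parent = {int(i): int(i) for i in idx}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    both = mask[edges[:, 0]] & mask[edges[:, 1]]
    for a, b in edges[both]:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    comps = {}
    for i in idx:
        comps.setdefault(find(int(i)), []).append(int(i))
    return [np.array(sorted(c)) for c in comps.values()]


def _max_component_mass(mask: np.ndarray, edges: np.ndarray,
                        areas: np.ndarray) -> float:
    comps = _connected_components(mask, edges)
    if not comps:
        return 0.0
    return max(float(areas[c].sum()) for c in comps)


def extract_clusters(t_map: np.ndarray, mesh: SkeletonMesh, t0: float,
                     direction: str = "both",
                     areas: np.ndarray | None = None) -> list[Cluster]:
    """Connected supra-threshold clusters, sorted by decreasing mass.

    Ties are broken by the smallest member vertex index.  An empty list is
    a legitimate result.
    """
    t_map = np.asarray(t_map, dtype=float)
    if len(t_map) != mesh.n_vertices:
        raise ConfigError("t map length must equal the vertex count")
    if t0 <= 0:
        raise ConfigError("t0 must be positive")
    if areas is None:
        areas = vertex_area_weights(mesh)
    dirs = ["group1_lower", "group2_lower"] if direction == "both" else [direction]
    clusters = []
    for d in dirs:
        for verts in _connected_components(_direction_mask(t_map, t0, d),
                                           mesh.edges()):
            clusters.append(Cluster(
                vertices=verts,
                mass=float(areas[verts].sum()),
                peak_t=float(t_map[verts][np.argmax(np.abs(t_map[verts]))]),
                direction=d,
            ))
    clusters.sort(key=lambda c: (-c.mass, int(c.vertices[0])))
    return clusters


def _check_common_order(datasets: dict):
    orders = {tuple(d.subject_ids) for d in datasets.values()}
    if len(orders) > 1:
        raise ConfigError("all tract datasets must share the same subject order")


def permutation_fwer(datasets_by_tract: dict, meshes: dict, design: GlmDesign,
                     config: ClusterConfig, method: str = "auto",
                     return_null: bool = False):
    """Cluster inference with the permutation null pooled over all tracts.

    For every permutation the group labels are permuted under the
    Freedman-Lane scheme (covariate-only fit, residual permutation,
    covariate effects re-added) and the single maximal cluster mass over
    ALL tracts — and over both tails when the contrast direction is
    "both" — is recorded.  Each observed cluster's FWER p-value is
    ``(1 + #{null maxima >= mass}) / (n_permutations + 1)``.

    When the design has no covariates and the number of distinct label
    splits is at most ``n_permutations``, the splits are enumerated
    exhaustively instead (logged), and the p-value is the exact rank of the
    observed mass among all splits.
    """
    if not datasets_by_tract:
        raise ConfigError("need at least one tract dataset")
    if method not in ("auto", "exhaustive", "monte_carlo"):
        raise ConfigError(f"unknown method {method!r}")
    _check_common_order(datasets_by_tract)
    tracts = sorted(datasets_by_tract)
    for tr in tracts:
        if tr not in meshes:
            raise ConfigError(f"no mesh for tract {tr!r}")
        if datasets_by_tract[tr].n_vertices != meshes[tr].n_vertices:
            raise ConfigError(f"dataset/mesh vertex mismatch for {tr!r}")

    Y = np.hstack([datasets_by_tract[t].values for t in tracts])
    n = Y.shape[0]
    if n != design.n:
        raise DesignError("design does not match the datasets' subjects")

    sizes = [datasets_by_tract[t].n_vertices for t in tracts]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    areas_all = np.concatenate(
        [vertex_area_weights(meshes[t]) for t in tracts])
    edges_all = np.concatenate(
        [meshes[t].edges() + offsets[i] for i, t in enumerate(tracts)])

    X = design.matrix()
    pinv = np.linalg.pinv(X)
    df = n - np.linalg.matrix_rank(X)
    t0 = config.t_threshold(df)
    dirs = (["group1_lower", "group2_lower"]
            if design.contrast_direction == "both"
            else [design.contrast_direction])

    # Observed clusters, tract by tract (vertex indices are tract-local).
    t_obs, _ = _t_from_design(X, Y, pinv)
    observed = []
    for i, tr in enumerate(tracts):
        lo, hi = offsets[i], offsets[i + 1]
        for c in extract_clusters(t_obs[lo:hi], meshes[tr], t0,
                                  design.contrast_direction,
                                  areas_all[lo:hi]):
            observed.append((tr, c))

    def max_mass(t_vals):
        return max(
            _max_component_mass(_direction_mask(t_vals, t0, d),
                                edges_all, areas_all)
            for d in dirs
        )

    n_b = int(design.group_indicator().sum())
    exhaustible = design.covariates is None and comb(n, n_b) <= config.n_permutations
    if method == "exhaustive" and not (design.covariates is None):
        raise ConfigError("exhaustive enumeration requires a covariate-free design")
    use_exhaustive = (method == "exhaustive"
                      or (method == "auto" and exhaustible))

    if use_exhaustive:
        n_splits = comb(n, n_b)
        log.info("exhaustive enumeration over %d label splits "
                 "(fewer than %d requested permutations)",
                 n_splits, config.n_permutations)
        null_max = np.empty(n_splits)
        Xp = X.copy()
        for k, idx in enumerate(combinations(range(n), n_b)):
            ind = np.zeros(n)
            ind[list(idx)] = 1.0
            Xp[:, 1] = ind
            t_perm, _ = _t_from_design(Xp, Y)
            null_max[k] = max_mass(t_perm)
        def pval(mass):
            return float(np.count_nonzero(null_max >= mass)) / n_splits
    else:
        # Freedman-Lane: permute residuals of the covariate-only model.
        Z = np.delete(X, 1, axis=1)
        fitted = Z @ (np.linalg.pinv(Z) @ Y)
        resid = Y - fitted
        rng = np.random.default_rng(config.seed)
        B = config.n_permutations
        null_max = np.empty(B)
        for k in range(B):
            perm = rng.permutation(n)
            t_perm, _ = _t_from_design(X, fitted + resid[perm], pinv)
            null_max[k] = max_mass(t_perm)
        def pval(mass):
            return (1.0 + np.count_nonzero(null_max >= mass)) / (B + 1.0)

    results = [
        ClusterResult(
            tract=tr,
            vertices=c.vertices,
            mass=c.mass,
            peak_t=c.peak_t,
            direction=c.direction,
            p_fwer=pval(c.mass),
            significant=pval(c.mass) <= config.fwer_alpha,
        )
        for tr, c in observed
    ]
    results.sort(key=lambda r: (r.p_fwer, -r.mass, r.tract))
    if return_null:
        return results, null_max
    return results
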