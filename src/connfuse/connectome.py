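"""Construction of structural-covariance and functional-connectivity networks.

Nodes are the 90 cortical/subcortical regions of the AAL parcellation
(cerebellum excluded).  Edges are indexed by the lower triangle of the
90 x 90 matrix in row-major order -- pairs (2,1), (3,1), (3,2), ...,
(90,89) in 1-based region numbering -- giving 90*89/2 = 4005 features
shared by both modalities.

Structural networks are group-level: the Pearson correlation of regional
gray-matter volumes *across subjects* within a group.  Functional networks
are subject-level: the Pearson correlation of two regions' mean time
courses, Fisher-z transformed.  Both arms remove the linear effects of age,
sex, and education by OLS residualization before inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Standard AAL-90 region labels (cerebrum only), 1-based atlas order.
AAL90_LABELS: tuple[str, ...] = (
    "Precentral_L", "Precentral_R", "Frontal_Sup_L", "Frontal_Sup_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R", "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R", "Frontal_Inf_Oper_L",
    "Frontal_Inf_Oper_R", "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
    "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R", "Rolandic_Oper_L",
    "Rolandic_Oper_R", "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Olfactory_L", "Olfactory_R", "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
    "Frontal_Med_Orb_L", "Frontal_Med_Orb_R", "Rectus_L", "Rectus_R",
    "Insula_L", "Insula_R", "Cingulum_Ant_L", "Cingulum_Ant_R",
    "Cingulum_Mid_L", "Cingulum_Mid_R", "Cingulum_Post_L", "Cingulum_Post_R",
    "Hippocampus_L", "Hippocampus_R", "ParaHippocampal_L", "ParaHippocampal_R",
    "Amygdala_L", "Amygdala_R", "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R", "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R", "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R", "Fusiform_L", "Fusiform_R",
    "Postcentral_L", "Postcentral_R", "Parietal_Sup_L", "Parietal_Sup_R",
    "Parietal_Inf_L", "Parietal_Inf_R", "SupraMarginal_L", "SupraMarginal_R",
    "Angular_L", "Angular_R", "Precuneus_L", "Precuneus_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R", "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R", "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R", "Heschl_L", "Heschl_R",
    "Temporal_Sup_L", "Temporal_Sup_R", "Temporal_Pole_Sup_L",
    "Temporal_Pole_Sup_R", "Temporal_Mid_L", "Temporal_Mid_R",
    "Temporal_Pole_Mid_L", "Temporal_Pole_Mid_R", "Temporal_Inf_L",
    "Temporal_Inf_R",
)

#: Correlation clipping bound applied before the Fisher z transform.
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class EdgeIndex:
    """Bijective mapping between lower-triangle edges and vector positions.

    ``pairs[p] = (i, j)`` with ``j < i`` (0-based region indices), ordered
    row-major over the lower triangle.
    """

    n_regions: int
    region_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("need at least two regions")
        labels = self.region_labels
        if not labels:
            if self.n_regions == 90:
                labels = AAL90_LABELS
            else:
                labels = tuple(f"R{i + 1}" for i in range(self.n_regions))
        if len(labels) != self.n_regions:
            raise ValueError("region_labels length must equal n_regions")
        object.__setattr__(self, "region_labels", tuple(labels))
        rows, cols = np.tril_indices(self.n_regions, -1)
        object.__setattr__(self, "_rows", rows)
        object.__setattr__(self, "_cols", cols)

    @property
    def n_edges(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self._rows.tolist(), self._cols.tolist()))

    def position(self, i: int, j: int) -> int:
        """Vector position of edge between regions ``i`` and ``j`` (0-based)."""
        if i == j:
            raise ValueError("diagonal entries are not edges")
        a, b = (i, j) if i > j else (j, i)
        if not (0 <= b < a < self.n_regions):
            raise ValueError(f"region pair ({i}, {j}) out of range")
        return a * (a - 1) // 2 + b

    def vector_from_matrix(self, matrix: np.ndarray) -> np.ndarray:
        m = np.asarray(matrix)
        if m.shape != (self.n_regions, self.n_regions):
            raise ValueError("matrix shape does not match n_regions")
        return m[self._rows, self._cols]

    def matrix_from_vector(self, vector: np.ndarray, diagonal: float = 0.0) -> np.ndarray:
        v = np.asarray(vector)
        if v.shape != (self.n_edges,):
            raise ValueError("vector length does not match edge count")
        m = np.full((self.n_regions, self.n_regions), diagonal, dtype=float)
        m[self._rows, self._cols] = v
        m[self._cols, self._rows] = v
        return m

    def edge_labels(self) -> list[str]:
        return [
            f"{self.region_labels[i]}-{self.region_labels[j]}"
            for i, j in zip(self._rows, self._cols)
        ]


@dataclass
class StructuralNet:
    """Group structural-covariance network (inter-subject volume correlation)."""

    group_label: object
    matrix: np.ndarray
    edge_vector: np.ndarray
    edge_index: EdgeIndex


def residualize(
    y: np.ndarray, covariates: np.ndarray, add_intercept: bool = True
) -> np.ndarray:
    """Column-wise OLS residuals of ``y`` against the covariates.

    Constant covariate columns other than the intercept are dropped with a
    warning; residuals are orthogonal to every retained covariate column.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("covariates and data must have the same number of rows")

    keep = np.ptp(x, axis=0) > 0
    if not np.all(keep):
        warnings.warn(
            f"dropped {int((~keep).sum())} constant covariate column(s)", stacklevel=2
        )
        x = x[:, keep]
    if add_intercept:
        x = np.column_stack([np.ones(x.shape[0]), x])

    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def corrected_volumes(volumes: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Corrected regional volumes: per-region residuals on age/sex/education."""
    return residualize(volumes, covariates)


def correct_functional(features: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Remove linear covariate effects from each edge across subjects."""
    return residualize(features, covariates)


def _safe_corrcoef(columns: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns; zero-variance columns give zero
    correlations (with a warning) instead of NaN."""
    x = np.asarray(columns, dtype=float)
    bad = x.std(axis=0) == 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} zero-variance column(s): their edges set to 0",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    return c


def structural_network(
    group_volumes: np.ndarray, group_label=None, edge_index: EdgeIndex | None = None
) -> StructuralNet:
    """Group structural network: Pearson r between region-volume columns
    across the subjects of one group."""
    v = np.asarray(group_volumes, dtype=float)
    if v.shape[0] < 4:
        raise ValueError("need at least 4 subjects per group for a structural network")
    idx = edge_index or EdgeIndex(v.shape[1])
    c = _safe_corrcoef(v)
    return StructuralNet(
        group_label=group_label, matrix=c, edge_vector=idx.vector_from_matrix(c), edge_index=idx
    )


def functional_network(
    timeseries: np.ndarray, edge_index: EdgeIndex | None = None
) -> np.ndarray:
    """Subject functional edge vector: Fisher z of pairwise Pearson r.

    Correlations are clipped to +/-(1 - 1e-7) before ``atanh`` so perfectly
    (anti)correlated signals stay finite.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.shape[0] < 30:
        raise ValueError("need at least 30 retained volumes for functional connectivity")
    idx = edge_index or EdgeIndex(ts.shape[1])
    r = _safe_corrcoef(ts)
    r = np.clip(r, -R_CLIP, R_CLIP)
    return np.arctanh(idx.vector_from_matrix(r))


def _group_edge_corr(volumes: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    z = volumes - volumes.mean(axis=0)
    norm = np.sqrt((z**2).sum(axis=0))
    norm[norm == 0] = np.inf
    zn = z / norm
    c = zn.T @ zn
    return c[rows, cols]


def permutation_test_structural(
    group_a_volumes: np.ndarray,
    group_b_volumes: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    edge_index: EdgeIndex | None = None,
) -> np.ndarray:
    """Edge-wise two-tailed permutation p-values for the structural networks.

    The statistic is ``r_A - r_B`` per edge.  Each permutation reassigns the
    (already covariate-corrected) volume rows to two groups of the original
    sizes; p = (1 + #{|Delta_perm| >= |Delta_obs|}) / (n_perm + 1).
    """
    a = np.asarray(group_a_volumes, dtype=float)
    b = np.asarray(group_b_volumes, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must have the same number of regions")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values", stacklevel=2)
    idx = edge_index or EdgeIndex(a.shape[1])
    rows, cols = np.tril_indices(idx.n_regions, -1)

    obs = np.abs(_group_edge_corr(a, rows, cols) - _group_edge_corr(b, rows, cols))
    pooled = np.vstack([a, b])
    n_a, n = a.shape[0], a.shape[0] + b.shape[0]
    rng = np.random.default_rng(seed)
    count = np.zeros(idx.n_edges, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pa = pooled[perm[:n_a]]
        pb = pooled[perm[n_a:]]
        delta = np.abs(_group_edge_corr(pa, rows, cols) - _group_edge_corr(pb, rows, cols))
        count += delta >= obs
    return (1.0 + count) / (n_perm + 1.0)
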