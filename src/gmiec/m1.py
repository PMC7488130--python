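"""M1 strategy: unsupervised random-forest proximity + k-means per patient.

For each patient i the omics layers are sliced into a genes-x-layers matrix
M_i = (G x m). A classification forest is trained to separate the real rows
from a synthetic class built by independently permuting each column (the
Breiman product-of-marginals device), and the gene-gene proximity is the
fraction of trees in which two genes land in the same terminal node.
Genes are then clustered by k-means on the rows of the proximity matrix;
the number of modules can be fixed or chosen by silhouette analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_score

from .io import OmicsBundle, ValidationError


@dataclass
class PatientFeatureMatrix:
    """Per-patient matrix M_i = (G x m): gene rows, one column per omics layer.

    ``values`` holds the analysis matrix (continuous columns z-scored across
    genes; binary mutation indicators untouched); ``raw`` keeps the
    unstandardized layer values for rules with absolute thresholds.
    """

    patient: str
    genes: list[str]
    layers: list[str]
    values: np.ndarray
    raw: np.ndarray

    def column(self, layer: str, raw: bool = False) -> np.ndarray:
        j = self.layers.index(layer)
        return (self.raw if raw else self.values)[:, j]


@dataclass
class ModuleAssignment:
    """Partition of the gene set of one patient into k modules (labels 1..k)."""

    patient: str
    labels: dict[str, int]
    k: int

    def module_genes(self, index: int) -> list[str]:
        return [g for g, lab in self.labels.items() if lab == index]


def _standardize_column(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd < 1e-12:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def assemble_patient_matrix(
    bundle: OmicsBundle, patient: str, standardize: bool = True
) -> PatientFeatureMatrix:
    """Slice one patient's column out of every layer into M_i = (G x m).

    Continuous columns are standardized to zero mean / unit variance across
    genes (constant columns become all-zero); a mutation column that is
    already a 0/1 indicator is left as is, so tree splits see it unscaled.
    """
    if patient not in bundle.samples:
        raise ValidationError(f"patient {patient!r} not in bundle samples")
    raw = np.column_stack(
        [d.values[patient].to_numpy(dtype=float) for d in bundle.datasets]
    )
    values = raw.copy()
    if standardize:
        for j, d in enumerate(bundle.datasets):
            col = raw[:, j]
            if d.layer_kind == "mutation" and set(np.unique(col)) <= {0.0, 1.0}:
                continue
            values[:, j] = _standardize_column(col)
    return PatientFeatureMatrix(
        patient=patient,
        genes=list(bundle.genes),
        layers=list(bundle.layer_kinds),
        values=values,
        raw=raw,
    )


@dataclass
class ProximityMatrix:
    """Symmetric gene-gene co-occurrence matrix: values in [0, 1], unit diagonal."""

    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.genes):
            raise ValidationError("proximity matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValidationError("proximity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValidationError("proximity matrix diagonal must be 1")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValidationError("proximity values must lie in [0, 1]")


def rf_proximity(
    matrix: PatientFeatureMatrix,
    n_trees: int = 500,
    seed: int = 0,
    mtry: int | None = None,
) -> ProximityMatrix:
    """Unsupervised random-forest proximity between genes.

    A synthetic second class is drawn by independently permuting each column
    of M_i, destroying the joint structure while keeping the marginals; a
    forest is trained on real-vs-synthetic and proximity(a, b) is the
    proportion of all trees in which real rows a and b share a terminal
    node. Counting over all trees (not just out-of-bag ones) makes identical
    gene rows come out at proximity exactly 1.
    """
    X = matrix.values
    n, m = X.shape
    if n < 4:
        raise ValidationError(
            f"random-forest proximity needs >= 4 genes, got {n}; use a larger gene set"
        )
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    synthetic = np.column_stack([rng.permutation(X[:, j]) for j in range(m)])
    X_train = np.vstack([X, synthetic])
    y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
    if mtry is None:
        mtry = max(1, int(np.sqrt(m)))
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X_train, y)
    leaves = forest.apply(X)  # (n_genes, n_trees) terminal-node ids
    same = leaves[:, None, :] == leaves[None, :, :]
    prox = same.mean(axis=2)
    prox = (prox + prox.T) / 2.0
    np.fill_diagonal(prox, 1.0)
    return ProximityMatrix(genes=list(matrix.genes), values=prox)


def _canonical_relabel(genes: list[str], raw_labels: np.ndarray) -> tuple[dict[str, int], int]:
    """Renumber clusters 1..k in order of their lexicographically first gene."""
    order = sorted(range(len(genes)), key=lambda i: genes[i])
    mapping: dict[int, int] = {}
    for i in order:
        lab = int(raw_labels[i])
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    labels = {genes[i]: mapping[int(raw_labels[i])] for i in range(len(genes))}
    return labels, len(mapping)


def cluster_proximity(
    prox: ProximityMatrix, k: int, seed: int = 0, n_init: int = 10
) -> ModuleAssignment:
    """K-means on the rows of the proximity matrix.

    Each gene is represented by its proximity profile to all genes and
    clustered with Euclidean k-means (k-means++ seeding, ``n_init``
    restarts). Labels are renumbered canonically so module 1 contains the
    lexicographically first gene.
    """
    n = len(prox.genes)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range [1, {n}]")
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        init="k-means++",
        max_iter=300,
        random_state=int(seed) % (2**31),
    )
    raw_labels = km.fit_predict(prox.values)
    labels, k_eff = _canonical_relabel(prox.genes, raw_labels)
    return ModuleAssignment(patient="", labels=labels, k=k_eff)


def select_k_silhouette(
    prox: ProximityMatrix,
    k_min: int = 2,
    k_max: int | None = None,
    seed: int = 0,
    n_init: int = 10,
) -> int:
    """Pick k in [k_min, k_max] maximizing the mean silhouette coefficient.

    Silhouettes are computed with Euclidean distance on proximity rows; ties
    break toward smaller k (parsimony). Default search range 2..min(10, n-1).
    """
    n = len(prox.genes)
    if k_max is None:
        k_max = min(10, n - 1)
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValidationError(f"silhouette k range [{k_min}, {k_max}] invalid for {n} genes")
    if k_min == k_max:
        return k_min
    best_k, best_score = k_min, -np.inf
    for k in range(k_min, k_max + 1):
        assignment = cluster_proximity(prox, k, seed=seed, n_init=n_init)
        lab = np.array([assignment.labels[g] for g in prox.genes])
        if len(np.unique(lab)) < 2:
            continue
        score = silhouette_score(prox.values, lab, metric="euclidean")
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    return best_k


def run_m1(
    bundle: OmicsBundle,
    k: int | str = "auto",
    n_trees: int = 500,
    seed: int = 0,
    n_init: int = 10,
    standardize: bool = True,
) -> list[ModuleAssignment]:
    """Full M1 pipeline over every patient of the bundle.

    Patients are processed independently with a per-patient seed derived as
    ``seed + patient_index``, so results do not depend on processing order
    and the whole run is reproducible from one seed.
    """
    assignments = []
    for idx, patient in enumerate(bundle.samples):
        pseed = seed + idx
        pfm = assemble_patient_matrix(bundle, patient, standardize=standardize)
        prox = rf_proximity(pfm, n_trees=n_trees, seed=pseed)
        k_i = select_k_silhouette(prox, seed=pseed, n_init=n_init) if k == "auto" else int(k)
        assignment = cluster_proximity(prox, k_i, seed=pseed, n_init=n_init)
        assignment.patient = patient
        assignments.append(assignment)
    return assignments
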