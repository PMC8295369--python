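"""Intra-tumor habitat segmentation with a hidden Markov random field.

Pixels of the four co-registered parametric maps (ESD, EAC, MBF, SI)
are modelled as class-conditional multivariate Gaussians with a Potts
(Gibbs) spatial prior on the labels: the MAP labeling maximizes

    P(X | Y, θ) · P(Y),    P(Y) ∝ exp(−β · Σ_{i~j} 1[y_i ≠ y_j])

over an 8-connected pixel lattice.  Fitting alternates iterated
conditional modes (ICM) for the labels with EM updates of the class
means and covariances, initialized by K-means.  The number of regions
is chosen by the elbow of the Bayesian information criterion, regions
are ordered by their training-set MBF means (region 1 = highest), and
reproducibility is scored with the in-group proportion (IGP).

One pooled model is fitted across the planes of all training tumors;
at test time the frozen Gaussian parameters drive ICM labeling only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .spectral import ParametricMapSet

__all__ = [
    "SEGMENTATION_CHANNELS",
    "ChannelStandardizer",
    "Plane",
    "HMRFModel",
    "standardize_channels",
    "kmeans_init",
    "map_estimate_labels",
    "hmrf_em",
    "select_num_regions",
    "apply_model",
    "order_regions",
    "compute_igp",
]

SEGMENTATION_CHANNELS = ("ESD", "EAC", "MBF", "SI")
_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)
_RIDGE = 1e-6


@dataclass
class ChannelStandardizer:
    """Per-channel z-scoring with pooled training statistics."""

    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "ChannelStandardizer":
        if X.shape[0] < 2:
            raise ValueError("need at least 2 pixels to standardize")
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        if np.any(scale == 0):
            raise ValueError("zero-variance channel cannot be standardized")
        return cls(center=center, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.scale

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return X * self.scale + self.center


def standardize_channels(
    planes: list["Plane"],
) -> tuple[ChannelStandardizer, list["Plane"]]:
    """Fit pooled z-scoring on the planes' valid pixels and transform them."""
    X = np.concatenate([p.values[p.valid] for p in planes])
    std = ChannelStandardizer.fit(X)
    out = [Plane(values=np.where(p.valid[..., None], std.transform(p.values), 0.0),
                 valid=p.valid) for p in planes]
    return std, out


@dataclass
class Plane:
    """One tumor plane for segmentation: (H, W, C) channel values + validity."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape[:2] != self.valid.shape:
            raise ValueError("values and valid mask must share the pixel grid")

    @classmethod
    def from_maps(cls, maps: dict[str, np.ndarray] | ParametricMapSet,
                  valid: np.ndarray | None = None) -> "Plane":
        if isinstance(maps, ParametricMapSet):
            valid = maps.valid if valid is None else valid & maps.valid
            maps = maps.channels
        arrs = [np.asarray(maps[ch], dtype=float) for ch in SEGMENTATION_CHANNELS]
        values = np.stack(arrs, axis=-1)
        finite = np.isfinite(values).all(axis=-1)
        valid = finite if valid is None else (np.asarray(valid, dtype=bool) & finite)
        return cls(values=np.where(valid[..., None], values, 0.0), valid=valid)


@dataclass
class HMRFModel:
    """Fitted habitat model: K Gaussians + Potts weight + normalization stats.

    Means/covariances live in standardized channel space; ``means_raw``
    maps them back to physical units.  ``region_mbf_means`` records the
    raw training MBF mean per (ordered) region.
    """

    K: int
    means: np.ndarray  # (K, C), standardized space
    covariances: np.ndarray  # (K, C, C)
    beta: float
    standardizer: ChannelStandardizer
    channels: tuple[str, ...] = SEGMENTATION_CHANNELS
    region_mbf_means: np.ndarray | None = None
    ordered: bool = False
    # complete-data pseudo-log-likelihood per EM iteration (diagnostics)
    history: list[float] = field(default_factory=list)

    @property
    def means_raw(self) -> np.ndarray:
        return self.standardizer.inverse_transform(self.means)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "beta": self.beta,
            "channels": list(self.channels),
            "standardizer": {
                "center": self.standardizer.center.tolist(),
                "scale": self.standardizer.scale.tolist(),
            },
            "region_mbf_means": None if self.region_mbf_means is None
            else self.region_mbf_means.tolist(),
            "ordered": self.ordered,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMRFModel":
        return cls(
            K=int(d["K"]),
            means=np.asarray(d["means"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
            beta=float(d["beta"]),
            standardizer=ChannelStandardizer(
                center=np.asarray(d["standardizer"]["center"], dtype=float),
                scale=np.asarray(d["standardizer"]["scale"], dtype=float),
            ),
            channels=tuple(d["channels"]),
            region_mbf_means=None if d.get("region_mbf_means") is None
            else np.asarray(d["region_mbf_means"], dtype=float),
            ordered=bool(d.get("ordered", False)),
        )


def _class_neg_loglik(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Negative Gaussian log-density, shape (N, K)."""
    N, C = X.shape
    K = means.shape[0]
    out = np.empty((N, K))
    for l in range(K):
        cov = covs[l]
        chol = np.linalg.cholesky(cov)
        diff = X - means[l]
        sol = np.linalg.solve(chol, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, l] = 0.5 * (maha + logdet + C * np.log(2.0 * np.pi))
    return out


def kmeans_init(
    X: np.ndarray, K: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K-means initialization of labels and class Gaussians.

    Returns ``(labels in 0..K−1, means, covariances)``; re-seeds up to 10
    times if a cluster comes back with fewer than 2 members.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < K:
        raise ValueError("need at least K pixels")
    if K == 1:
        cov = np.atleast_2d(np.cov(X.T, ddof=0)) + _RIDGE * np.eye(X.shape[1])
        return np.zeros(X.shape[0], dtype=int), X.mean(axis=0)[None, :], cov[None]
    for attempt in range(10):
        km = KMeans(n_clusters=K, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(X)
        counts = np.bincount(labels, minlength=K)
        if counts.min() >= 2:
            break
    else:
        raise RuntimeError("K-means produced a near-empty cluster after 10 re-seeds")
    means = km.cluster_centers_
    covs = np.empty((K, X.shape[1], X.shape[1]))
    for l in range(K):
        covs[l] = np.cov(X[labels == l].T, ddof=0) + _RIDGE * np.eye(X.shape[1])
    return labels, means, covs


def _neighbor_same_counts(labels: np.ndarray, valid: np.ndarray, K: int) -> np.ndarray:
    """(H, W, K) count of valid 8-neighbors carrying each label."""
    same = np.empty(labels.shape + (K,))
    for l in range(K):
        ind = ((labels == l) & valid).astype(float)
        same[..., l] = ndimage.convolve(ind, _NEIGH, mode="constant", cval=0.0)
    return same


def _icm_sweeps(
    plane: Plane,
    labels: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
    beta: float,
    max_inner: int = 10,
) -> np.ndarray:
    """Red-black ICM: minimize neg-log-likelihood + β·(disagreeing neighbors)."""
    H, W = plane.valid.shape
    K = means.shape[0]
    D = np.full((H, W, K), np.inf)
    D[plane.valid] = _class_neg_loglik(plane.values[plane.valid], means, covs)
    if beta == 0.0 or K == 1:
        new = np.argmin(D, axis=-1)
        new[~plane.valid] = -1
        return new
    parity = (np.add.outer(np.arange(H), np.arange(W)) % 2).astype(bool)
    labels = labels.copy()
    n_valid_neigh = ndimage.convolve(
        plane.valid.astype(float), _NEIGH, mode="constant", cval=0.0
    )
    for _ in range(max_inner):
        changed = False
        for mask in (parity, ~parity):
            same = _neighbor_same_counts(labels, plane.valid, K)
            energy = D + beta * (n_valid_neigh[..., None] - same)
            new = np.argmin(energy, axis=-1)
            upd = mask & plane.valid & (new != labels)
            if upd.any():
                labels[upd] = new[upd]
                changed = True
        if not changed:
            break
    labels[~plane.valid] = -1
    return labels


def map_estimate_labels(
    planes: list[Plane],
    means: np.ndarray,
    covs: np.ndarray,
    beta: float,
    init_labels: list[np.ndarray] | None = None,
    max_inner: int = 10,
) -> list[np.ndarray]:
    """MAP labels for each plane under frozen Gaussian parameters.

    With ``beta = 0`` this is exactly independent per-pixel maximum-
    likelihood Gaussian classification.  Invalid pixels carry label −1
    and count as missing neighbors.
    """
    out = []
    for i, plane in enumerate(planes):
        if init_labels is not None:
            init = init_labels[i]
        else:
            init = _icm_sweeps(plane, np.zeros(plane.valid.shape, int),
                               means, covs, 0.0, 1)
        out.append(_icm_sweeps(plane, init, means, covs, beta, max_inner))
    return out


def _posterior(
    plane: Plane, labels: np.ndarray, means: np.ndarray, covs: np.ndarray, beta: float
) -> np.ndarray:
    """P(l | x_i) over valid pixels via Bayes rule with the neighbor-field prior."""
    K = means.shape[0]
    same = _neighbor_same_counts(labels, plane.valid, K)
    n_valid = ndimage.convolve(plane.valid.astype(float), _NEIGH,
                               mode="constant", cval=0.0)
    log_prior = -beta * (n_valid[..., None] - same)
    neg_ll = _class_neg_loglik(plane.values[plane.valid], means, covs)
    logp = -neg_ll + log_prior[plane.valid]
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def hmrf_em(
    planes: list[Plane],
    K: int,
    beta: float = 1.0,
    max_em: int = 15,
    max_inner: int = 10,
    tol: float = 1e-4,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[HMRFModel, list[np.ndarray]]:
    """Fit the pooled HMRF model over all training planes.

    Alternates ICM MAP labeling with posterior-weighted updates of the
    class means/covariances, for at most ``max_em`` outer iterations or
    until the maximum relative parameter change drops below ``tol``.
    Singular covariances are regularized with a small diagonal ridge.
    Deterministic given ``seed``.
    """
    if sum(int(p.valid.sum()) for p in planes) < 10 * K:
        raise ValueError("need at least 10·K valid pixels")
    if standardize:
        std, zplanes = standardize_channels(planes)
    else:
        C = planes[0].values.shape[-1]
        std = ChannelStandardizer(center=np.zeros(C), scale=np.ones(C))
        zplanes = planes

    X = np.concatenate([p.values[p.valid] for p in zplanes])
    flat_labels, means, covs = kmeans_init(X, K, seed=seed)
    labels = []
    pos = 0
    for p in zplanes:
        n = int(p.valid.sum())
        lab = np.full(p.valid.shape, -1, dtype=int)
        lab[p.valid] = flat_labels[pos:pos + n]
        labels.append(lab)
        pos += n

    C = X.shape[1]
    history: list[float] = []
    for _ in range(max_em):
        labels = [
            _icm_sweeps(p, lab, means, covs, beta, max_inner)
            for p, lab in zip(zplanes, labels)
        ]
        posts = [_posterior(p, lab, means, covs, beta)
                 for p, lab in zip(zplanes, labels)]
        W = np.concatenate(posts)  # (N, K)
        wsum = W.sum(axis=0)
        new_means = (W.T @ X) / wsum[:, None]
        new_covs = np.empty_like(covs)
        for l in range(K):
            diff = X - new_means[l]
            new_covs[l] = (diff.T * W[:, l]) @ diff / wsum[l]
            if np.linalg.eigvalsh(new_covs[l]).min() < _RIDGE:
                new_covs[l] += _RIDGE * np.eye(C)
        denom = max(np.abs(means).max(), np.abs(covs).max(), 1e-12)
        delta = max(np.abs(new_means - means).max(),
                    np.abs(new_covs - covs).max()) / denom
        means, covs = new_means, new_covs
        history.append(_pseudo_loglik(zplanes, labels, means, covs, beta))
        if delta < tol:
            break

    labels = [
        _icm_sweeps(p, lab, means, covs, beta, max_inner)
        for p, lab in zip(zplanes, labels)
    ]
    model = HMRFModel(K=K, means=means, covariances=covs, beta=beta,
                      standardizer=std, history=history)
    return model, labels


def _pseudo_loglik(
    zplanes: list[Plane],
    labels: list[np.ndarray],
    means: np.ndarray,
    covs: np.ndarray,
    beta: float,
) -> float:
    """Complete-data pseudo-log-likelihood Σ_i log N(x_i|y_i) + log P(y_i|neigh)."""
    total = 0.0
    K = means.shape[0]
    for p, lab in zip(zplanes, labels):
        neg = _class_neg_loglik(p.values[p.valid], means, covs)
        y = lab[p.valid]
        total -= float(neg[np.arange(y.size), y].sum())
        same = _neighbor_same_counts(lab, p.valid, K)
        n_valid = ndimage.convolve(p.valid.astype(float), _NEIGH,
                                   mode="constant", cval=0.0)
        u = (n_valid[..., None] - same)[p.valid]  # (N, K) disagreement counts
        logz = -beta * u
        m = logz.max(axis=1, keepdims=True)
        log_norm = m.squeeze(1) + np.log(np.exp(logz - m).sum(axis=1))
        total += float((-beta * u[np.arange(y.size), y] - log_norm).sum())
    return total


def mixture_bic(model: HMRFModel, planes: list[Plane],
                labels: list[np.ndarray] | None = None) -> float:
    """BIC of the non-spatial Gaussian mixture implied by the fitted model.

    Class proportions come from the current labeling (uniform if absent);
    the spatial prior is ignored in the criterion.  Free-parameter count:
    ``K−1`` proportions plus ``K·(C + C(C+1)/2)`` Gaussian parameters.
    """
    K, C = model.K, model.means.shape[1]
    if labels is not None:
        counts = np.zeros(K)
        for lab in labels:
            for l in range(K):
                counts[l] += np.sum(lab == l)
        pi = counts / counts.sum() if counts.sum() else np.full(K, 1.0 / K)
        pi = np.maximum(pi, 1e-12)
    else:
        pi = np.full(K, 1.0 / K)
    std = model.standardizer
    X = np.concatenate([std.transform(p.values[p.valid]) for p in planes])
    neg_ll = _class_neg_loglik(X, model.means, model.covariances)
    logp = np.log(pi)[None, :] - neg_ll
    m = logp.max(axis=1, keepdims=True)
    loglik = float(np.sum(m.squeeze(1) + np.log(np.exp(logp - m).sum(axis=1))))
    p_free = (K - 1) + K * (C + C * (C + 1) // 2)
    return -2.0 * loglik + p_free * np.log(X.shape[0])


def select_num_regions(
    planes: list[Plane],
    K_range: range = range(1, 7),
    beta: float = 1.0,
    seed: int = 0,
    elbow_fraction: float = 0.1,
    **em_kwargs,
) -> tuple[int, dict[int, float]]:
    """Elbow of the BIC over candidate region counts.

    Fits the HMRF per K and computes the mixture BIC; the elbow is the
    smallest K whose improvement to K+1 falls below ``elbow_fraction`` of
    the largest single-step improvement (ties and a monotone decline
    resolve to the smallest K in the range).
    """
    Ks = list(K_range)
    if not Ks:
        raise ValueError("K_range must be non-empty")
    bics: dict[int, float] = {}
    for K in Ks:
        model, labels = hmrf_em(planes, K, beta=beta, seed=seed, **em_kwargs)
        bics[K] = mixture_bic(model, planes, labels)
    return _elbow_from_bics(bics, elbow_fraction), bics


def _elbow_from_bics(bics: dict[int, float], elbow_fraction: float = 0.1) -> int:
    """Smallest K whose improvement to K+1 drops below the elbow threshold.

    The threshold is ``elbow_fraction`` of the largest single-step BIC
    improvement; a monotone (or increasing) decline with no sub-threshold
    step resolves to the smallest K in the range.
    """
    Ks = sorted(bics)
    if len(Ks) == 1:
        return Ks[0]
    imps = np.array([bics[Ks[i]] - bics[Ks[i + 1]] for i in range(len(Ks) - 1)])
    max_imp = imps.max()
    if max_imp <= 0:
        return Ks[0]
    below = np.nonzero(imps < elbow_fraction * max_imp)[0]
    return Ks[below[0]] if below.size else Ks[0]


def apply_model(
    model: HMRFModel, plane: Plane, max_inner: int = 10
) -> np.ndarray:
    """Label an unseen plane with frozen Gaussian parameters (no EM update).

    Channels are standardized with the training statistics; an all-invalid
    plane returns an empty (all −1) labeling.
    """
    z = Plane(values=np.where(plane.valid[..., None],
                              model.standardizer.transform(plane.values), 0.0),
              valid=plane.valid)
    if not plane.valid.any():
        import warnings

        warnings.warn("plane has no valid pixels; returning empty labeling")
        return np.full(plane.valid.shape, -1, dtype=int)
    init = _icm_sweeps(z, np.zeros(z.valid.shape, int), model.means,
                       model.covariances, 0.0, 1)
    return _icm_sweeps(z, init, model.means, model.covariances,
                       model.beta, max_inner)


def order_regions(
    model: HMRFModel,
    planes: list[Plane],
    labels: list[np.ndarray],
) -> tuple[HMRFModel, list[np.ndarray]]:
    """Renumber regions by training-set MBF mean, highest first.

    Region 1 gets the highest raw MBF mean, region K the lowest.  Exact
    ties break by EAC mean descending, then original class index.  The
    permutation is applied to the model parameters and to the labelings;
    returned labels are 1-based (0 = background/invalid).
    """
    mbf_idx = model.channels.index("MBF")
    eac_idx = model.channels.index("EAC")
    K = model.K
    mbf_means = np.full(K, -np.inf)
    eac_means = np.full(K, -np.inf)
    for l in range(K):
        vals_mbf, vals_eac = [], []
        for p, lab in zip(planes, labels):
            sel = (lab == l) & p.valid
            if sel.any():
                vals_mbf.append(p.values[sel][:, mbf_idx])
                vals_eac.append(p.values[sel][:, eac_idx])
        if vals_mbf:
            mbf_means[l] = np.concatenate(vals_mbf).mean()
            eac_means[l] = np.concatenate(vals_eac).mean()
    order = sorted(range(K), key=lambda l: (-mbf_means[l], -eac_means[l], l))
    perm = np.empty(K, dtype=int)
    for new, old in enumerate(order):
        perm[old] = new
    new_model = HMRFModel(
        K=K,
        means=model.means[order],
        covariances=model.covariances[order],
        beta=model.beta,
        standardizer=model.standardizer,
        channels=model.channels,
        region_mbf_means=mbf_means[order],
        ordered=True,
    )
    new_labels = []
    for lab in labels:
        out = np.zeros_like(lab)
        v = lab >= 0
        out[v] = perm[lab[v]] + 1
        new_labels.append(out)
    return new_model, new_labels


def relabel_with_order(labels: np.ndarray) -> np.ndarray:
    """Convert 0-based ICM labels (−1 background) to 1-based ordered labels."""
    out = np.zeros_like(labels)
    v = labels >= 0
    out[v] = labels[v] + 1
    return out


def compute_igp(
    X: np.ndarray,
    labels: np.ndarray,
    patient_ids: np.ndarray,
) -> dict:
    """In-group proportion per group per patient, plus cohort summaries.

    For each patient, each pixel's nearest neighbor (Euclidean in the
    standardized channel space, within that patient's pixels) is found;
    a group's IGP is the fraction of its members whose nearest neighbor
    shares the group.  Singleton groups are undefined and excluded.
    Returns ``{"per_patient": {pid: {group: igp}}, "mean": ..., "median": ...}``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    per_patient: dict = {}
    all_igps: list[float] = []
    for pid in np.unique(patient_ids):
        sel = patient_ids == pid
        Xp, lp = X[sel], labels[sel]
        if Xp.shape[0] < 2:
            raise ValueError(f"patient {pid} has fewer than 2 pixels")
        tree = cKDTree(Xp)
        _, nn = tree.query(Xp, k=2)
        nn_label = lp[nn[:, 1]]
        groups = {}
        for g in np.unique(lp):
            members = lp == g
            if members.sum() < 2:
                import warnings

                warnings.warn(f"singleton group {g} for patient {pid}; IGP undefined")
                continue
            igp = float(np.mean(nn_label[members] == g))
            groups[int(g)] = igp
            all_igps.append(igp)
        per_patient[pid] = groups
    return {
        "per_patient": per_patient,
        "mean": float(np.mean(all_igps)) if all_igps else np.nan,
        "median": float(np.median(all_igps)) if all_igps else np.nan,
    }
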