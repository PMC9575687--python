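"""Spectral embedding of one projection direction's image stack.

The default route is a diffusion map with density normalization
(alpha = 1), whose eigenvectors approximate eigenfunctions of the
Laplace-Beltrami operator on the conformational manifold; on a
quasi-continuous 1D motion x in [0, 1] they approach cos(k pi x) (Neumann
boundary conditions), so consecutive eigenvector pairs trace Lissajous
curves and the leading pair {Psi_1 x Psi_2} traces a parabola (the
Chebyshev identity cos 2t = 2 cos^2 t - 1).  A PCA route is provided for
cross-checks; at low SNR the two converge.

For CTF-modulated images the double-filter distance is used: each image is
filtered by the other image's CTF before differencing, which symmetrizes
the CTF distortion of the manifold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import eigsh

from .synthetic import ImageStack, MicroscopeParams, ctf_array


@dataclass
class DistanceMatrix:
    D: np.ndarray
    method: str = "plain"   # plain | double_filter

    def __post_init__(self):
        D = self.D
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be square")
        if not np.isfinite(D).all() or (D < 0).any():
            raise ValueError("D must be finite and nonnegative")
        if np.abs(D - D.T).max() > 1e-10 * max(1.0, D.max()):
            raise ValueError("D must be symmetric")
        np.fill_diagonal(self.D, 0.0)

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass
class Embedding:
    """Leading spectral coordinates of one PD manifold.

    eigvals are sorted descending with the trivial constant mode removed;
    eigvecs columns Psi_1..Psi_d are unit-norm with sign fixed so each
    column's third moment is nonnegative.
    """

    eigvals: np.ndarray
    eigvecs: np.ndarray        # (N, d)
    eps: float
    method: str                # DM | PCA
    pd_id: int = -1
    degenerate: bool = False

    @property
    def d(self) -> int:
        return self.eigvecs.shape[1]

    @property
    def n(self) -> int:
        return self.eigvecs.shape[0]

    def column(self, i: int) -> np.ndarray:
        """Eigenvector Psi_i, 1-based as conventional for spectral indices."""
        return self.eigvecs[:, i - 1]

    def copy(self) -> "Embedding":
        return Embedding(self.eigvals.copy(), self.eigvecs.copy(), self.eps,
                         self.method, self.pd_id, self.degenerate)


def _as_pixel_matrix(stack) -> np.ndarray:
    imgs = stack.images if isinstance(stack, ImageStack) else np.asarray(stack)
    X = imgs.reshape(imgs.shape[0], -1).astype(np.float64)
    if not np.isfinite(X).all():
        raise ValueError("stack contains non-finite pixels")
    return X


def variance_weights(images) -> np.ndarray:
    """Per-pixel relevance weights from the ensemble variance map.

    Pixels whose values never change across the ensemble carry no
    conformational signal but contribute noise to every distance; their
    ensemble variance equals the (flat) noise floor, estimated by the
    median over pixels.  The excess variance above the floor is the
    conformational signal power, used as the quadratic-form weight of the
    distance metric.  Returns weights normalized to max 1.
    """
    X = _as_pixel_matrix(images)
    var = X.var(axis=0)
    w = np.clip(var - np.median(var), 0.0, None)
    if w.max() <= 0:
        return np.ones_like(var)
    return w / w.max()


def pairwise_distances(stack, weights: np.ndarray | None = None) -> DistanceMatrix:
    """Euclidean distance between image pixel vectors, optionally under a
    diagonal pixel-weighting (see ``variance_weights``)."""
    X = _as_pixel_matrix(stack)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 images")
    if weights is not None:
        X = X * np.sqrt(np.asarray(weights, dtype=float).ravel())
    sq = (X * X).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.clip(D2, 0.0, None, out=D2)
    D = np.sqrt(D2)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=D, method="plain")


def double_filter_distances(stack: ImageStack,
                            params: MicroscopeParams | None = None,
                            defocus_um: np.ndarray | None = None,
                            variance_weighting: bool = False) -> DistanceMatrix:
    """Cross-filtered distance D_ij = || CTF_j * I_i - CTF_i * I_j ||_2.

    Expanding the norm in Fourier space factorizes into three Gram products,
    so the full matrix costs the same as plain distances:
      D_ij^2 = sum_k C_j^2 |F_i|^2 + C_i^2 |F_j|^2 - 2 C_i C_j Re(F_i F_j*).

    ``variance_weighting`` applies the Fourier-domain analogue of
    ``variance_weights``: each frequency is weighted by the ensemble
    variance in excess of the flat noise floor (a Wiener-type relevance
    weighting compatible with the per-image CTFs).
    """
    if params is None:
        params = MicroscopeParams(pixel_size_A=stack.pixel_size_A)
    if defocus_um is None:
        if "defocus_um" not in stack.meta:
            raise ValueError("missing per-image defocus (meta column defocus_um)")
        defocus_um = stack.meta["defocus_um"].to_numpy(float)
    defocus_um = np.asarray(defocus_um, float)
    if defocus_um.shape[0] != stack.n_images or not np.isfinite(defocus_um).all():
        raise ValueError("one finite defocus value per image is required")
    P = stack.P
    F = np.fft.fft2(stack.images.astype(np.float64)).reshape(stack.n_images, -1)
    if variance_weighting:
        psd = (F.real ** 2 + F.imag ** 2)
        var_k = psd.mean(axis=0) - np.abs(F.mean(axis=0)) ** 2
        w = np.clip(var_k - np.median(var_k), 0.0, None)
        if w.max() > 0:
            F = F * np.sqrt(w / w.max())
    # cache CTFs by defocus value (ensembles often share a few defoci)
    uniq, inv = np.unique(defocus_um, return_inverse=True)
    ctfs = np.stack([ctf_array(P, d, params).ravel() for d in uniq])[inv]
    A = (F.real ** 2 + F.imag ** 2)
    C2 = ctfs ** 2
    W = ctfs * F
    term = A @ C2.T
    cross = (W @ W.conj().T).real
    D2 = term + term.T - 2.0 * cross
    np.clip(D2, 0.0, None, out=D2)
    D = np.sqrt(D2) / P  # Parseval: back to pixel-space scale
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=D, method="double_filter")


def bandwidth_scan(D: DistanceMatrix, n_eps: int = 160):
    """Kernel-sum curve S(eps) = sum_ij exp(-D_ij^2 / 2 eps) over a log grid."""
    d2 = D.D[np.triu_indices(D.n, 1)] ** 2
    d2 = d2[d2 > 0]
    if d2.size == 0:
        raise ValueError("degenerate all-zero distance matrix")
    eps = np.logspace(np.log10(d2.min() / 1e3), np.log10(d2.max() * 1e3), n_eps)
    S = np.array([1.0 + 2.0 * np.exp(-d2 / (2 * e)).sum() / D.n for e in eps])
    return eps, S


def select_bandwidth(D: DistanceMatrix, occupancy: float = 0.3) -> float:
    """Bandwidth at which the kernel sum S(eps) reaches ``occupancy`` * N.

    S(eps)/N is the mean effective-neighbor fraction, a monotone sigmoid in
    log eps between 1/N (diagonal only) and 1 (saturated); fixing its level
    lands eps on the transition region of the kernel-sum curve regardless
    of the noise floor that offsets all squared distances.  Deterministic
    (bisection in log space).
    """
    if D.n < 10:
        raise ValueError("need at least 10 images to select a bandwidth")
    if not 0 < occupancy < 1:
        raise ValueError("occupancy must be in (0, 1)")
    d2 = D.D[np.triu_indices(D.n, 1)] ** 2
    d2 = d2[d2 > 0]
    if d2.size == 0:
        raise ValueError("degenerate all-zero distance matrix")
    target = occupancy * D.n

    def S_of(log_eps):
        return 1.0 + 2.0 * np.exp(-d2 / (2.0 * 10.0 ** log_eps)).sum() / D.n

    lo = np.log10(d2.min() / 1e4)
    hi = np.log10(d2.max() * 1e4)
    if S_of(hi) < target:      # tiny N: even a saturated kernel stays below
        return float(10.0 ** hi / 1e4)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if S_of(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(10.0 ** (0.5 * (lo + hi)))


def _fix_signs(psi: np.ndarray) -> np.ndarray:
    for j in range(psi.shape[1]):
        m3 = (psi[:, j] ** 3).sum()
        if abs(m3) < 1e-12:
            nz = np.nonzero(np.abs(psi[:, j]) > 1e-12)[0]
            m3 = psi[nz[0], j] if nz.size else 1.0
        if m3 < 0:
            psi[:, j] = -psi[:, j]
    return psi


def diffusion_map(D: DistanceMatrix, eps: float, d: int = 15, pd_id: int = -1) -> Embedding:
    """Diffusion-map embedding with alpha = 1 density normalization.

    K = exp(-D^2/2 eps) is divided by the outer product of its row sums
    (removing the sampling density, the Laplace-Beltrami limit), then
    Markov-normalized; eigenvectors of the symmetric conjugate give the
    embedding with the constant mode dropped and columns scaled to unit norm.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    N = D.n
    if d >= N:
        raise ValueError("d must be < N")
    K = np.exp(-D.D ** 2 / (2.0 * eps))
    offdiag = K.sum(axis=1) - 1.0
    isolated = np.nonzero(offdiag < 1e-12)[0]
    if isolated.size:
        raise ValueError(
            f"kernel graph disconnected at eps={eps:.3g}: isolated images {isolated[:10].tolist()}")
    q = K.sum(axis=1)
    K1 = K / np.outer(q, q)
    d1 = K1.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    A = K1 * np.outer(inv_sqrt, inv_sqrt)
    A = 0.5 * (A + A.T)
    k = d + 1
    if N <= 1200:
        vals, vecs = np.linalg.eigh(A)
        vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    else:
        v0 = np.random.default_rng(0).standard_normal(N)  # deterministic start
        vals, vecs = eigsh(A, k=k, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    np.clip(vals, 0.0, 1.0, out=vals)
    psi = vecs[:, 1:] * inv_sqrt[:, None]       # drop constant mode
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    psi = _fix_signs(psi)
    degenerate = bool(vals[1] < 1e-12)
    return Embedding(eigvals=vals[1:], eigvecs=psi, eps=float(eps),
                     method="DM", pd_id=pd_id, degenerate=degenerate)


def pca_embed(stack, d: int = 15, pd_id: int = -1) -> Embedding:
    """Principal-component scores as embedding columns (unit-normalized)."""
    from sklearn.decomposition import PCA
    X = _as_pixel_matrix(stack)
    if d >= min(X.shape[0], X.shape[1]):
        raise ValueError("d must be < min(N, P^2)")
    pca = PCA(n_components=d, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(X)
    norms = np.linalg.norm(scores, axis=0)
    norms[norms == 0] = 1.0
    psi = _fix_signs(scores / norms)
    return Embedding(eigvals=pca.explained_variance_.copy(), eigvecs=psi,
                     eps=float("nan"), method="PCA", pd_id=pd_id)


def lowpass(images: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian low-pass of each image; sigma in pixels (0 = passthrough).

    Image information is band-limited by the density's resolution, so a
    matched low-pass suppresses out-of-band noise before distances are
    computed without touching the conformational signal."""
    if sigma <= 0:
        return np.asarray(images)
    from scipy import ndimage
    return ndimage.gaussian_filter(np.asarray(images, dtype=float),
                                   sigma=(0, sigma, sigma))


def embed_stack(stack, method: str = "DM", d: int = 15, pd_id: int = -1,
                distances: DistanceMatrix | None = None,
                lowpass_sigma: float = 0.0) -> Embedding:
    """Convenience front end: (low-pass) -> distances -> bandwidth -> DM/PCA."""
    imgs = stack.images if isinstance(stack, ImageStack) else np.asarray(stack)
    imgs = lowpass(imgs, lowpass_sigma)
    if method.upper() == "PCA":
        return pca_embed(imgs, d=d, pd_id=pd_id)
    D = distances if distances is not None else pairwise_distances(imgs)
    eps = select_bandwidth(D)
    return diffusion_map(D, eps, d=d, pd_id=pd_id)
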