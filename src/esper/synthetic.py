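"""Synthetic ground-truth conformational continua and projection-image ensembles.

A toy molecular machine is a set of pseudo-atoms partitioned into a static
core and mobile domains.  Each mobile domain carries one motion: either a
rigid rotation about a hinge axis, or a per-atom displacement field (a
generalized hinge used for non-rigid, concerted translations).  Exercising
the motions on an equispaced grid produces a quasi-continuous state space
SSn with M**n states, whose 2D projections — optionally degraded by noise,
a contrast transfer function (CTF) and non-uniform state occupancies — form
the four progressively realistic data-types I-IV:

  I   clean images, one copy per state (tau = 1)
  II  tau noisy copies per state at a stated SNR
  III additionally CTF with per-image random defocus
  IV  additionally a non-uniform (weighted) occupancy map

Every image carries full ground-truth metadata (state multi-index, defocus,
per-image noise seed) so each downstream stage can be audited exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Hinge:
    """Rigid rotation of a domain about an axis (anchor + unit direction).

    ``theta_range`` is the admissible angle interval in degrees.
    """

    anchor: np.ndarray
    axis: np.ndarray
    theta_range: tuple[float, float] = (0.0, 40.0)

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError(f"hinge axis must have unit norm, got |axis|={n:.6g}")

    def displace(self, coords: np.ndarray, value: float) -> np.ndarray:
        rot = Rotation.from_rotvec(np.deg2rad(value) * np.asarray(self.axis, float))
        return (coords - self.anchor) @ rot.as_matrix().T + self.anchor


@dataclass(frozen=True)
class TranslationField:
    """Per-atom displacement field: atom a moves by value * displacements[a].

    Generalizes a hinge to concerted, non-rigid translations; ``value`` is
    dimensionless and spans ``amp_range`` (the per-atom vectors carry the
    direction and relative magnitude).
    """

    displacements: np.ndarray  # (n_domain_atoms, 3)
    amp_range: tuple[float, float] = (0.0, 1.0)

    @property
    def theta_range(self) -> tuple[float, float]:
        return self.amp_range

    def displace(self, coords: np.ndarray, value: float) -> np.ndarray:
        return coords + value * np.asarray(self.displacements, float)


@dataclass
class ToyModel:
    """Pseudo-atomic machine: atoms, domain labels, one motion per mobile domain.

    domain 0 is the static core; domains >= 1 are mobile and each must own
    exactly one motion (Hinge or TranslationField).
    """

    atoms: np.ndarray                 # (A, 3)
    domain_of_atom: np.ndarray        # (A,) int
    motions: dict[int, Hinge | TranslationField]
    preset: str = ""

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        self.domain_of_atom = np.asarray(self.domain_of_atom, dtype=int)
        if self.atoms.shape[0] != self.domain_of_atom.shape[0]:
            raise ValueError("atoms and domain_of_atom length mismatch")
        for dom in np.unique(self.domain_of_atom):
            if (self.domain_of_atom == dom).sum() < 3:
                raise ValueError(f"domain {dom} has fewer than 3 atoms")
        mobile = set(np.unique(self.domain_of_atom)) - {0}
        if mobile != set(self.motions):
            raise ValueError(
                f"every mobile domain needs exactly one motion; "
                f"domains {sorted(mobile)} vs motions {sorted(self.motions)}"
            )

    @property
    def n_mobile(self) -> int:
        return len(self.motions)

    def conformation(self, values: "np.ndarray | list[float]") -> np.ndarray:
        """Atom coordinates after moving mobile domain g by values[g-1]."""
        values = np.asarray(values, dtype=float)
        if values.shape[0] > self.n_mobile:
            raise ValueError(f"expected <= {self.n_mobile} motion values, got {values.shape[0]}")
        coords = self.atoms.copy()
        for g, motion in sorted(self.motions.items()):
            sel = self.domain_of_atom == g
            # domains beyond the exercised state space rest at their range start
            v = values[g - 1] if g - 1 < values.shape[0] else motion.theta_range[0]
            coords[sel] = motion.displace(coords[sel], v)
        return coords


@dataclass
class StateSpace:
    """Equispaced state grid over n conformational motions, M states each.

    State multi-indices (s_1, ..., s_n), s in {0..M-1}, are enumerated in
    row-major order; ``value_grids[g]`` holds the motion parameter (hinge
    angle in degrees, or field amplitude) of CM_{g+1} at each grid index.
    """

    n: int
    M: int
    value_grids: list[np.ndarray]

    @property
    def n_states(self) -> int:
        return self.M ** self.n

    def states(self) -> np.ndarray:
        """All multi-indices in row-major order, shape (M**n, n)."""
        grids = np.meshgrid(*[np.arange(self.M)] * self.n, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def values(self, state) -> np.ndarray:
        state = np.asarray(state, dtype=int)
        return np.array([self.value_grids[g][state[g]] for g in range(self.n)])

    def coordinate(self, state) -> np.ndarray:
        """Conformational coordinate x in [0, 1]**n of a state."""
        return np.asarray(state, dtype=float) / (self.M - 1)


@dataclass(frozen=True)
class ProjectionDirection:
    """Viewing direction: model is rotated by ``orientation`` then projected
    along +z.  ``orientation`` is a unit quaternion (w, x, y, z)."""

    id: int
    orientation: tuple[float, float, float, float]
    aperture_deg: float = 3.0

    def __post_init__(self):
        q = np.asarray(self.orientation, dtype=float)
        if not np.isclose(np.linalg.norm(q), 1.0, atol=1e-8):
            raise ValueError("orientation quaternion must be unit-norm")
        if self.aperture_deg <= 0:
            raise ValueError("aperture_deg must be positive")

    def matrix(self) -> np.ndarray:
        w, x, y, z = self.orientation
        return Rotation.from_quat([x, y, z, w]).as_matrix()


@dataclass(frozen=True)
class MicroscopeParams:
    voltage_kV: float = 300.0
    spherical_aberration_mm: float = 2.7
    amplitude_contrast: float = 0.1
    pixel_size_A: float = 1.0
    defocus_range_um: tuple[float, float] = (0.5, 2.5)

    def __post_init__(self):
        if min(self.voltage_kV, self.spherical_aberration_mm, self.pixel_size_A) <= 0:
            raise ValueError("microscope parameters must be positive")
        if not (0 <= self.amplitude_contrast < 1):
            raise ValueError("amplitude_contrast must be a fraction in [0, 1)")
        if self.defocus_range_um[0] > self.defocus_range_um[1]:
            raise ValueError("defocus range min must be <= max")

    @property
    def wavelength_A(self) -> float:
        """Relativistic electron wavelength in Angstrom."""
        v = self.voltage_kV * 1e3
        return 12.2639 / math.sqrt(v * (1.0 + 0.97845e-6 * v))


@dataclass
class OccupancySpec:
    """How many image copies each state receives.

    uniform: tau copies per state.  weighted: copies proportional to
    ``weights`` with the same total budget tau * n_states (largest-remainder
    rounding, deterministic).
    """

    mode: str = "uniform"
    tau: int = 1
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("uniform", "weighted"):
            raise ValueError(f"unknown occupancy mode {self.mode!r}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError("tau must be an integer >= 1")
        if self.mode == "weighted":
            if self.weights is None:
                raise ValueError("weighted mode requires weights")
            w = np.asarray(self.weights, dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("weights must be nonnegative with positive sum")
            self.weights = w

    def copies(self, n_states: int) -> np.ndarray:
        if self.mode == "uniform":
            return np.full(n_states, int(self.tau), dtype=int)
        if self.weights.shape[0] != n_states:
            raise ValueError("weights length must equal number of states")
        total = int(self.tau) * n_states
        exact = self.weights / self.weights.sum() * total
        base = np.floor(exact).astype(int)
        remainder = total - base.sum()
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:remainder]] += 1
        return base


@dataclass
class ImageStack:
    """N projection images of edge P with per-image ground-truth metadata."""

    images: np.ndarray            # (N, P, P)
    pixel_size_A: float
    meta: pd.DataFrame

    def __post_init__(self):
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be (N, P, P)")
        if self.images.shape[1] % 2 != 0:
            raise ValueError("P must be even")
        if len(self.meta) != self.images.shape[0]:
            raise ValueError("meta rows must match image count")
        if not np.isfinite(self.images).all():
            raise ValueError("images contain non-finite values")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def P(self) -> int:
        return self.images.shape[1]


# --------------------------------------------------------------------------
# toy models
# --------------------------------------------------------------------------

def _rod(p0, p1, n):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return np.asarray(p0, float) + t * (np.asarray(p1, float) - np.asarray(p0, float))


def _bundle(p0, p1, n, spread=1.6):
    """Four parallel rods in a square cross-section: a thick 3D arm."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    d = d / np.linalg.norm(d)
    a = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(a) < 1e-6:
        a = np.cross(d, [1.0, 0.0, 0.0])
    a = a / np.linalg.norm(a)
    b = np.cross(d, a)
    rods = []
    for sa, sb in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        off = 0.5 * spread * (sa * a + sb * b)
        rods.append(_rod(p0 + off, p1 + off, n))
    return np.vstack(rods)


def build_toy_model(preset: str = "two_arm_v", atoms_per_domain: int = 12) -> ToyModel:
    """Build a preset toy machine.

    two_arm_v: a static V-shaped frame whose two arms rotate about hinge
    axes at the frame tips (in-plane swing for arm 1, out-of-plane flap for
    arm 2), giving two decoupled quasi-rigid degrees of freedom with
    distinct path lengths.

    mouth_wings: the mobile groups move by concerted per-atom translations
    of varying direction and magnitude (no rigid hinge), so intra-domain
    distances change under motion.
    """
    if atoms_per_domain < 3:
        raise ValueError("atoms_per_domain must be >= 3")
    app = atoms_per_domain

    if preset == "two_arm_v":
        left_tip = np.array([-8.0, 10.0, 0.0])
        right_tip = np.array([8.0, 10.0, 0.0])
        # the static frame has genuine z-extent so no viewing direction sees
        # the machine edge-on as a featureless line
        core = np.vstack([
            _rod([0, 0, 0], left_tip, max(4, app // 3)),
            _rod([0, 0, 0], right_tip, max(4, app // 3)),
            _rod([0, 2, -4], [0, 8, 4], max(4, app // 3)),
            _rod([0, 0, 0], [0, 3, 5], 3),
        ])
        # arms are thick 4-rod bundles: most of the machine's mass moves, so
        # the conformational signal dominates the clean-ensemble variance
        arm1 = _bundle(left_tip, left_tip + 12.0 * np.array([-0.6, 0.8, 0.0]), app)
        arm2 = _bundle(right_tip, right_tip + 11.0 * np.array([0.6, 0.8, 0.0]), app)
        atoms = np.vstack([core, arm1, arm2])
        domains = np.concatenate([
            np.zeros(len(core), int), np.ones(len(arm1), int), np.full(len(arm2), 2),
        ])
        # arm 1 swings in the frame plane; arm 2 rotates about a tilted axis so
        # its displacement has generic in-plane and out-of-plane components
        # (no viewing direction sees either motion vanish to second order);
        # the arc lengths differ, keeping the two eigenfunction families
        # spectrally non-degenerate
        axis2 = np.array([0.35, 0.0, 0.937])
        motions = {
            1: Hinge(anchor=left_tip, axis=np.array([0.0, 0.0, 1.0]), theta_range=(0.0, 40.0)),
            2: Hinge(anchor=right_tip, axis=axis2 / np.linalg.norm(axis2), theta_range=(0.0, 40.0)),
        }
        return ToyModel(atoms, domains, motions, preset=preset)

    if preset == "mouth_wings":
        core = _rod([-10, 0, 0], [10, 0, 0], max(3, app))
        # mouth: two lips opening apart; direction and magnitude vary per atom
        half = max(3, app // 2)
        xs = np.linspace(-6.0, 6.0, half)
        upper = np.stack([xs, np.full(half, 1.5), np.zeros(half)], axis=1)
        lower = np.stack([xs, np.full(half, -1.5), np.zeros(half)], axis=1)
        mouth = np.vstack([upper, lower])
        bulge = 1.0 - np.abs(xs) / 9.0
        disp_up = np.stack([0.15 * np.sin(xs), 0.9 * bulge, 0.1 * np.cos(xs)], axis=1)
        disp_lo = np.stack([0.15 * np.sin(xs), -0.9 * bulge, -0.1 * np.cos(xs)], axis=1)
        mouth_field = TranslationField(
            displacements=np.vstack([disp_up, disp_lo]), amp_range=(0.0, 6.0))
        # wings: flat plates flapping out of plane, magnitude grows outward
        wxs = np.linspace(8.0, 14.0, half)
        wing_r = np.stack([wxs, np.full(half, 3.0), np.zeros(half)], axis=1)
        wing_l = np.stack([-wxs, np.full(half, 3.0), np.zeros(half)], axis=1)
        wings = np.vstack([wing_r, wing_l])
        wmag = np.abs(np.concatenate([wxs, wxs])) / 14.0
        wings_field = TranslationField(
            displacements=np.stack([np.zeros(half * 2), 0.2 * wmag, wmag], axis=1),
            amp_range=(0.0, 4.5))
        atoms = np.vstack([core, mouth, wings])
        domains = np.concatenate([
            np.zeros(len(core), int), np.ones(len(mouth), int), np.full(len(wings), 2),
        ])
        motions = {1: mouth_field, 2: wings_field}
        return ToyModel(atoms, domains, motions, preset=preset)

    raise ValueError(f"unknown preset {preset!r}")


def generate_state_space(model: ToyModel, n: int, M: int = 20) -> StateSpace:
    """Equispaced M**n state grid over the model's first n motions."""
    if n > model.n_mobile:
        raise ValueError(f"n={n} exceeds the model's {model.n_mobile} mobile domains")
    if M < 2:
        raise ValueError("M must be >= 2")
    grids = []
    for g in range(1, n + 1):
        lo, hi = model.motions[g].theta_range
        grids.append(np.linspace(lo, hi, M))
    return StateSpace(n=n, M=M, value_grids=grids)


# --------------------------------------------------------------------------
# rendering and projection
# --------------------------------------------------------------------------

def _check_inside(coords, lo, hi, state, margin):
    bad = np.where((coords < lo + margin).any(axis=1) | (coords > hi - margin).any(axis=1))[0]
    if bad.size:
        raise ValueError(
            f"atom {bad[0]} of state {tuple(np.atleast_1d(state))} at "
            f"{coords[bad[0]]} falls outside the grid")


def render_density(model: ToyModel, state_space: StateSpace, state,
                   grid_size: int = 64, blob_sigma: float = 1.5,
                   pixel_size: float = 1.0) -> np.ndarray:
    """Render one state as a 3D map: a sum of unit-integral Gaussian blobs.

    Volume axes are (y, x, z) so that summing along the last axis gives the
    untilted projection with image rows = y, columns = x; the coordinate
    origin sits at the geometric grid center (grid_size - 1) / 2.
    """
    coords = model.conformation(state_space.values(state)) / pixel_size
    c0 = (grid_size - 1) / 2.0
    pix = coords + c0  # (x, y, z) in pixel units
    _check_inside(pix, 0.0, grid_size - 1.0, state, margin=4.0 * blob_sigma)
    vol = np.zeros((grid_size, grid_size, grid_size))
    w = int(math.ceil(4 * blob_sigma))
    amp = (2 * math.pi * blob_sigma ** 2) ** -1.5
    for x, y, z in pix:
        iy, ix, iz = int(round(y)), int(round(x)), int(round(z))
        sl = tuple(slice(i - w, i + w + 1) for i in (iy, ix, iz))
        gy = np.arange(iy - w, iy + w + 1) - y
        gx = np.arange(ix - w, ix + w + 1) - x
        gz = np.arange(iz - w, iz + w + 1) - z
        blob = np.exp(-(gy[:, None, None] ** 2 + gx[None, :, None] ** 2
                        + gz[None, None, :] ** 2) / (2 * blob_sigma ** 2))
        vol[sl] += amp * blob
    return vol


def project(volume: np.ndarray, pd_: ProjectionDirection) -> np.ndarray:
    """Line integral along +z after rotating the volume by pd.orientation."""
    if volume.ndim != 3 or len(set(volume.shape)) != 1:
        raise ValueError("volume must be cubic")
    R = pd_.matrix()
    P = volume.shape[0]
    c0 = (P - 1) / 2.0
    # volume axes are (y, x, z); rotation acts on (x, y, z) coordinates.
    perm = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)  # (y,x,z)->(x,y,z)
    A = perm.T @ R.T @ perm  # inverse map in index space: out idx -> in idx
    offset = c0 * (np.ones(3) - A.sum(axis=1))
    rotated = ndimage.affine_transform(volume, A, offset=offset, order=1,
                                       mode="constant", cval=0.0)
    return rotated.sum(axis=2)


def render_projection(model: ToyModel, state_space: StateSpace, state,
                      pd_: ProjectionDirection, P: int = 64,
                      blob_sigma: float = 1.5, pixel_size: float = 1.0) -> np.ndarray:
    """Project one state analytically: isotropic 3D Gaussians project to
    isotropic 2D Gaussians of the same sigma, so the rotated atom (x, y)
    positions are splatted directly.  Agrees with render_density + project
    up to interpolation error, at a fraction of the cost."""
    coords = model.conformation(state_space.values(state)) / pixel_size
    rot = coords @ pd_.matrix().T
    c0 = (P - 1) / 2.0
    pix = rot + c0
    _check_inside(pix[:, :2], 0.0, P - 1.0, state, margin=4.0 * blob_sigma)
    img = np.zeros((P, P))
    w = int(math.ceil(4 * blob_sigma))
    amp = 1.0 / (2 * math.pi * blob_sigma ** 2)
    for x, y, _ in pix:
        iy, ix = int(round(y)), int(round(x))
        gy = np.arange(iy - w, iy + w + 1) - y
        gx = np.arange(ix - w, ix + w + 1) - x
        img[iy - w: iy + w + 1, ix - w: ix + w + 1] += amp * np.exp(
            -(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * blob_sigma ** 2))
    return img


def fibonacci_hemisphere(n_pd: int, aperture_deg: float = 3.0) -> list[ProjectionDirection]:
    """Deterministic Fibonacci-sphere sampling of viewing directions on the
    upper hemisphere; each direction v is turned into the rotation mapping v
    to +z (so projecting along +z views the model along v)."""
    golden = (1 + 5 ** 0.5) / 2
    pds = []
    for i in range(n_pd):
        z = (i + 0.5) / n_pd          # upper hemisphere only
        r = math.sqrt(max(0.0, 1 - z * z))
        phi = 2 * math.pi * i / golden
        v = np.array([r * math.cos(phi), r * math.sin(phi), z])
        zhat = np.array([0.0, 0.0, 1.0])
        axis = np.cross(v, zhat)
        s = np.linalg.norm(axis)
        if s < 1e-12:
            rot = Rotation.identity()
        else:
            rot = Rotation.from_rotvec(axis / s * math.atan2(s, v @ zhat))
        x, y, zq, w = rot.as_quat()
        pds.append(ProjectionDirection(id=i, orientation=(w, x, y, zq),
                                       aperture_deg=aperture_deg))
    return pds


# --------------------------------------------------------------------------
# CTF and noise
# --------------------------------------------------------------------------

def ctf_array(P: int, defocus_um: float, params: MicroscopeParams) -> np.ndarray:
    """CTF(k) = -[sqrt(1 - A^2) sin(chi) + A cos(chi)] on the fft2 frequency
    grid, chi(k) = pi lambda k^2 (df - lambda^2 Cs k^4 / (2 k^2) ...),
    i.e. chi = pi lam |k|^2 (df - 0.5 lam^2 Cs |k|^2).  Underfocus (df > 0)
    gives negative contrast at low frequency (standard convention)."""
    lam = params.wavelength_A
    df_A = defocus_um * 1e4
    cs_A = params.spherical_aberration_mm * 1e7
    k = np.fft.fftfreq(P, d=params.pixel_size_A)
    k2 = k[:, None] ** 2 + k[None, :] ** 2
    chi = math.pi * lam * k2 * (df_A - 0.5 * lam ** 2 * cs_A * k2)
    A = params.amplitude_contrast
    return -(math.sqrt(1 - A ** 2) * np.sin(chi) + A * np.cos(chi))


def apply_ctf(image: np.ndarray, defocus_um: float, params: MicroscopeParams) -> np.ndarray:
    """Multiply the image by the CTF in Fourier space (no envelope)."""
    if image.shape[0] % 2 != 0:
        raise ValueError("P must be even")
    if defocus_um <= 0:
        warnings.warn("nonpositive defocus: overfocus convention", stacklevel=2)
    ctf = ctf_array(image.shape[0], defocus_um, params)
    return np.fft.ifft2(np.fft.fft2(image) * ctf).real


def add_noise(images: np.ndarray, snr: float, rng_seed: int,
              signal_var: float | None = None):
    """Additive i.i.d. Gaussian noise at the stated SNR.

    SNR is defined as var(clean ensemble pixels) / var(noise); the signal
    variance is computed once over the whole clean stack (constant noise
    variance per regime) unless passed explicitly.  Returns (noisy stack,
    per-image seeds) for exact replay.
    """
    images = np.asarray(images)
    single = images.ndim == 2
    stack = images[None] if single else images
    if np.isinf(snr):
        return (stack[0].copy() if single else stack.copy()), np.zeros(len(stack), dtype=np.int64)
    if snr <= 0:
        raise ValueError("snr must be positive (or inf for noiseless)")
    if signal_var is None:
        signal_var = float(stack.var())
    sigma = math.sqrt(signal_var / snr)
    master = np.random.default_rng(rng_seed)
    seeds = master.integers(0, 2 ** 31, size=len(stack))
    out = np.empty_like(stack, dtype=float)
    for i, (img, s) in enumerate(zip(stack, seeds)):
        out[i] = img + np.random.default_rng(int(s)).normal(0.0, sigma, img.shape)
    return (out[0] if single else out), seeds


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

DATATYPES = ("I", "II", "III", "IV")


def assemble_dataset(model: ToyModel, state_space: StateSpace,
                     pd_list: list[ProjectionDirection],
                     occupancy: OccupancySpec, datatype: str,
                     params: MicroscopeParams | None = None, seed: int = 0,
                     P: int = 64, blob_sigma: float = 1.5,
                     snr: float = math.inf, out_dir=None) -> dict[int, ImageStack]:
    """Render one ImageStack per projection direction at the given realism tier.

    Ground-truth metadata (state indices, defocus, per-image noise seed and
    the PD orientation quaternion) is recorded per image.  All randomness
    (defocus draws, noise) flows from ``seed`` with recorded per-image seeds.
    """
    if datatype not in DATATYPES:
        raise ValueError(f"unknown datatype {datatype!r}")
    if params is None:
        params = MicroscopeParams()
    if datatype == "I":
        if occupancy.mode != "uniform" or occupancy.tau != 1 or not np.isinf(snr):
            raise ValueError("data-type I requires uniform occupancy, tau=1 and no noise")
    if datatype in ("II", "III") and occupancy.mode != "uniform":
        raise ValueError(f"data-type {datatype} uses uniform occupancy")
    if datatype == "IV" and occupancy.mode != "weighted":
        raise ValueError("data-type IV requires weighted occupancy")
    if datatype in ("II", "III", "IV") and not np.isfinite(snr):
        warnings.warn("data-type %s normally carries finite SNR" % datatype, stacklevel=2)

    with_ctf = datatype in ("III", "IV")
    states = state_space.states()
    copies = occupancy.copies(state_space.n_states)
    master = np.random.default_rng(seed)
    stacks: dict[int, ImageStack] = {}
    next_image_id = 0
    for pd_ in pd_list:
        pd_rng = np.random.default_rng(master.integers(0, 2 ** 31))
        clean = np.stack([
            render_projection(model, state_space, s, pd_, P=P,
                              blob_sigma=blob_sigma, pixel_size=params.pixel_size_A)
            for s in states
        ])
        imgs, rows = [], []
        for s_idx, (state, c) in enumerate(zip(states, copies)):
            for _ in range(c):
                img = clean[s_idx]
                defocus = math.nan
                if with_ctf:
                    lo, hi = params.defocus_range_um
                    defocus = float(pd_rng.uniform(lo, hi))
                    img = apply_ctf(img, defocus, params)
                imgs.append(img)
                rows.append((pd_.id, tuple(int(v) for v in state), defocus))
        imgs = np.asarray(imgs)
        signal_var = float(imgs.var())  # clean ensemble of this PD (post-CTF)
        noisy, seeds = add_noise(imgs, snr, int(pd_rng.integers(0, 2 ** 31)),
                                 signal_var=signal_var)
        meta = pd.DataFrame({
            "image_id": np.arange(next_image_id, next_image_id + len(imgs)),
            "pd_id": [r[0] for r in rows],
            **{f"state_{g}": [r[1][g] for r in rows] for g in range(state_space.n)},
            "defocus_um": [r[2] for r in rows],
            "snr": snr,
            "noise_seed": seeds,
        })
        w, x, y, z = pd_.orientation
        meta["q_w"], meta["q_x"], meta["q_y"], meta["q_z"] = w, x, y, z
        next_image_id += len(imgs)
        stacks[pd_.id] = ImageStack(images=noisy.astype(np.float32),
                                    pixel_size_A=params.pixel_size_A, meta=meta)

    if out_dir is not None:
        from . import mrc, star
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pid, stack in stacks.items():
            mrc.write_mrcs(stack.images, stack.pixel_size_A, out / f"pd_{pid:03d}.mrcs")
            star.write_star(stack.meta, out / f"pd_{pid:03d}.star")
    return stacks
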