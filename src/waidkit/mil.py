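"""Multiple-instance machinery and the weakly annotated image descriptor.

A weakly labeled image is treated as a *bag* of m randomly sub-sampled
patches; each patch is summarized by its CKD (an 8x8 SPD matrix). The
image's descriptor — the WAID — is the decision boundary [w; b] of a
max-margin classifier separating the image's own instances from
instances of background (negative) bags, subject to the constraint that
at least a fraction eta of the positive bag's instances end up on the
positive side. The constraint is enforced by re-solving the SVM with a
geometrically growing misclassification cost C until it holds.

Instances are vectorized by concatenating the columns of Log(D) — the
tangent-space (log-Euclidean) embedding — then lifted through an
explicit finite-dimensional feature map approximating the
Jensen-Shannon additive homogeneous kernel, so the boundary can be
learned with a linear solver while retaining a non-linear decision
surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .config import MILConfig
from .descriptors import CKD, ckd_from_patch
from .spd import matrix_log
from .synthetic import noise_tile

logger = logging.getLogger(__name__)

__all__ = [
    "Bag",
    "EtaSVMResult",
    "WAID",
    "sample_patches",
    "make_bag",
    "make_negative_bag",
    "vectorize_logm",
    "js_kernel_exact",
    "js_feature_map",
    "train_eta_svm",
    "compute_waid",
    "waid_dataset",
]

NEGATIVE_STRATEGIES = ("noise", "texture", "healthy")


@dataclass(frozen=True)
class Bag:
    """An ordered set of instance descriptors from one image/source."""

    instances: list[np.ndarray]
    label: int
    source_id: str = ""

    def __post_init__(self):
        if len(self.instances) < 1:
            raise ValueError("a bag needs at least one instance")
        if self.label not in (-1, 1):
            raise ValueError(f"bag label must be +1 or -1, got {self.label}")


@dataclass(frozen=True)
class EtaSVMResult:
    """Outcome of the eta-constrained SVM with its C-rescaling history."""

    w: np.ndarray
    b: float
    positive_set: np.ndarray      # indices (into the positive bag) labeled +1
    C_final: float
    satisfied: bool
    history: list[tuple[float, float]] = field(default_factory=list)  # (C, frac)


@dataclass(frozen=True)
class WAID:
    """The weakly annotated image descriptor [w; b] for one image."""

    vector: np.ndarray
    image_id: str = ""
    satisfied: bool = True
    C_final: float = float("nan")


# ---------------------------------------------------------------------------
# bags

def sample_patches(
    image: np.ndarray, m: int = 25, n: int = 50, seed: int = 0
) -> tuple[list[np.ndarray], np.ndarray]:
    """Sample m square n x n patches at uniform top-left offsets.

    Sampling is with replacement over the (h-n+1) x (w-n+1) offset grid
    and reproducible under the seed. Returns (patches, offsets) with
    offsets of shape (m, 2) as (row, col).
    """
    h, w = image.shape[:2]
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if h < n or w < n:
        raise ValueError(f"image {h}x{w} smaller than patch size {n}")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - n + 1, size=m)
    cols = rng.integers(0, w - n + 1, size=m)
    patches = [image[r:r + n, c:c + n] for r, c in zip(rows, cols)]
    return patches, np.column_stack([rows, cols])


def make_bag(image: np.ndarray, label: int, m: int = 25, n: int = 50,
             seed: int = 0, source_id: str = "", descriptor_config=None) -> Bag:
    """Sub-sample an image and wrap its patch CKDs into a bag."""
    patches, _ = sample_patches(image, m=m, n=n, seed=seed)
    ckds = [ckd_from_patch(p, descriptor_config).matrix for p in patches]
    return Bag(instances=ckds, label=label, source_id=source_id)


def make_negative_bag(
    strategy: str = "noise",
    m: int = 25,
    n: int = 50,
    seed: int = 0,
    source_pool: list[np.ndarray] | None = None,
    source_id: str = "",
    descriptor_config=None,
) -> Bag:
    """Build one background bag of m patch CKDs, label -1.

    Strategies: ``noise`` (i.i.d. uniform RGB noise tiles, the default —
    the background class farthest from tissue), ``texture`` (patches from
    a surrogate texture pool), ``healthy`` (patches from supplied benign
    tiles).
    """
    if strategy not in NEGATIVE_STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose from {NEGATIVE_STRATEGIES}"
        )
    rng = np.random.default_rng(seed)
    patches: list[np.ndarray] = []
    if strategy == "noise":
        patches = [noise_tile((n, n), rng) for _ in range(m)]
    else:
        if not source_pool:
            raise ValueError(f"strategy {strategy!r} requires a nonempty source_pool")
        for _ in range(m):
            img = source_pool[rng.integers(0, len(source_pool))]
            ps, _ = sample_patches(img, m=1, n=n, seed=int(rng.integers(2**31)))
            patches.append(ps[0])
    ckds = [ckd_from_patch(p, descriptor_config).matrix for p in patches]
    return Bag(instances=ckds, label=-1, source_id=source_id or f"{strategy}-{seed}")


# ---------------------------------------------------------------------------
# vectorization and the Jensen-Shannon feature map

def vectorize_logm(D: CKD | np.ndarray) -> np.ndarray:
    """Tangent-space vectorization: columns of Log(D), concatenated.

    For the 8x8 CKD this is a 64-vector (column-major flatten of the
    matrix logarithm).
    """
    mat = D.matrix if isinstance(D, CKD) else D
    return matrix_log(mat).ravel(order="F")


def js_kernel_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact additive Jensen-Shannon kernel between nonnegative vectors:
    ``sum_j x_j/2 log2((x_j+y_j)/x_j) + y_j/2 log2((x_j+y_j)/y_j)``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    m = (x > 0) & (y > 0)
    xs, ys = x[m], y[m]
    return float(np.sum(xs / 2 * np.log2((xs + ys) / xs)
                        + ys / 2 * np.log2((xs + ys) / ys)))


def _js_signature(lam: float) -> float:
    """Kernel signature K(lam) = k_JS(e^{lam/2}, e^{-lam/2})."""
    x = np.exp(lam / 2.0)
    y = np.exp(-lam / 2.0)
    return x / 2 * np.log2((x + y) / x) + y / 2 * np.log2((x + y) / y)


@lru_cache(maxsize=None)
def _js_coefficients(order: int, period: float) -> tuple[float, ...]:
    """Spectral weights c_j, j = 0..order, of the JS feature map.

    These are the Fourier-series coefficients of the kernel signature
    truncated to the window [-pi/period, pi/period] (frequency spacing =
    ``period``). Small negative higher-order coefficients are clamped to
    0, since a real-valued feature map needs nonnegative weights.
    """
    half_window = np.pi / period
    coeffs = []
    for j in range(order + 1):
        val, _ = quad(lambda lam: _js_signature(lam) * np.cos(j * period * lam),
                      0.0, half_window, limit=400)
        coeffs.append(max(val / half_window, 0.0))
    return tuple(coeffs)


def js_feature_map(d: np.ndarray, order: int = 1, period: float = 0.6) -> np.ndarray:
    """Explicit finite-dimensional approximation of the JS kernel.

    Each (signed) coordinate x is split into its nonnegative parts
    (max(x,0), max(-x,0)); each part is expanded into 2*order+1 features

        [sqrt(c0 x), sqrt(2 c_j x) cos(j L log x), sqrt(2 c_j x) sin(j L log x)]

    with L = ``period``, so that <Psi(x), Psi(y)> ~= sum_j k_JS(x_j', y_j')
    summed over both signed parts. Output length = len(d) * 2 * (2*order+1);
    zero coordinates map to zero features (homogeneous kernels vanish at 0).
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    d = np.atleast_1d(np.asarray(d, dtype=np.float64))
    parts = np.concatenate([np.maximum(d, 0.0), np.maximum(-d, 0.0)])
    c = np.asarray(_js_coefficients(order, period))
    out = np.zeros((parts.size, 2 * order + 1))
    m = parts > 0
    x = parts[m]
    lx = np.log(x)
    out[m, 0] = np.sqrt(c[0] * x)
    for j in range(1, order + 1):
        a = np.sqrt(2.0 * c[j] * x)
        out[m, 2 * j - 1] = a * np.cos(j * period * lx)
        out[m, 2 * j] = a * np.sin(j * period * lx)
    return out.ravel()


# ---------------------------------------------------------------------------
# eta-constrained SVM

def train_eta_svm(
    X: np.ndarray,
    from_positive_bag: np.ndarray,
    eta: float = 0.9,
    C0: float = 0.01,
    growth: float = 2.0,
    C_max: float = 1e6,
) -> EtaSVMResult:
    """Linear max-margin boundary with the eta proportionality constraint.

    All instances of the positive bag get label +1 and all background
    instances -1; the soft-margin SVM is solved at C = C0 and the
    fraction of positive-bag instances classified positive (by the sign
    of the decision function) is checked against eta. While the fraction
    falls short, C is multiplied by ``growth`` — making misclassified
    positives costlier and steering the boundary to enclose them — and
    the problem is re-solved. Returns the first satisfying boundary, or
    the last one with ``satisfied=False`` if C exceeds ``C_max``.
    """
    X = np.asarray(X, dtype=np.float64)
    from_positive_bag = np.asarray(from_positive_bag, dtype=bool)
    if X.shape[0] != from_positive_bag.shape[0]:
        raise ValueError("X and from_positive_bag length mismatch")
    n_pos = int(from_positive_bag.sum())
    n_neg = int((~from_positive_bag).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive-bag and one negative instance")
    if not 0 <= eta <= 1:
        raise ValueError(f"eta must lie in [0, 1], got {eta}")
    if C0 <= 0 or growth <= 1:
        raise ValueError("C0 must be > 0 and growth > 1")

    y = np.where(from_positive_bag, 1.0, -1.0)
    pos_idx = np.flatnonzero(from_positive_bag)
    history: list[tuple[float, float]] = []
    C = float(C0)
    result = None
    while True:
        svm = _solve_linear_svm(X, y, C)
        scores = X @ svm.coef_.ravel() + float(svm.intercept_[0])
        pos_mask = scores[pos_idx] > 0
        frac = float(pos_mask.mean())
        history.append((C, frac))
        result = EtaSVMResult(
            w=svm.coef_.ravel().copy(),
            b=float(svm.intercept_[0]),
            positive_set=pos_idx[pos_mask],
            C_final=C,
            satisfied=frac >= eta,
            history=history,
        )
        if result.satisfied:
            return result
        if C * growth > C_max:
            logger.warning(
                "eta-constraint unmet at C_max=%g (fraction %.3f < eta %.3f); "
                "returning last boundary", C_max, frac, eta)
            return result
        C *= growth


def _solve_linear_svm(X: np.ndarray, y: np.ndarray, C: float) -> LinearSVC:
    """One linear soft-margin solve (liblinear hinge dual).

    Retried once with a looser tolerance if the iteration budget is hit;
    a still-unconverged solve returns the approximate boundary with a
    logged warning — at extreme C on overlapping instances liblinear's
    iterate is a usable feasible solution, and the C-rescaling loop only
    needs the sign pattern it induces.
    """
    svm = None
    for tol in (1e-4, 1e-2):
        svm = LinearSVC(loss="hinge", C=C, tol=tol, max_iter=100_000,
                        intercept_scaling=10.0, random_state=0)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            svm.fit(X, y)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            return svm
    logger.warning("linear SVM not fully converged at C=%g; using approximate "
                   "solution", C)
    return svm


# ---------------------------------------------------------------------------
# WAID

def _featurize_bag_instances(bags: list[Bag], config: MILConfig) -> np.ndarray:
    rows = [js_feature_map(vectorize_logm(D), order=config.order,
                           period=config.period)
            for bag in bags for D in bag.instances]
    return np.vstack(rows)


def compute_waid(pos_bag: Bag, neg_bags: list[Bag],
                 config: MILConfig | None = None) -> WAID:
    """Fit the eta-constrained boundary of one positive bag vs. background
    bags and return the descriptor [w; b].

    Negative bags are canonicalized by source_id before instance
    aggregation so the result is invariant to their order.
    """
    config = config or MILConfig()
    if pos_bag.label != 1:
        raise ValueError("pos_bag must have label +1")
    if len(neg_bags) < 1:
        raise ValueError("need at least one negative bag")
    neg_sorted = sorted(neg_bags, key=lambda b: b.source_id)
    X = _featurize_bag_instances([pos_bag] + neg_sorted, config)
    from_pos = np.zeros(X.shape[0], dtype=bool)
    from_pos[: len(pos_bag.instances)] = True
    res = train_eta_svm(X, from_pos, eta=config.eta, C0=config.C0,
                        growth=config.growth, C_max=config.C_max)
    vec = np.concatenate([res.w, [res.b]])
    return WAID(vector=vec, image_id=pos_bag.source_id,
                satisfied=res.satisfied, C_final=res.C_final)


def _stable_image_seed(master_seed: int, image_id: str) -> int:
    import zlib

    return int(np.random.SeedSequence(
        [master_seed, zlib.crc32(image_id.encode())]).generate_state(1)[0] % (2**31))


def make_negative_pool(config: MILConfig, master_seed: int,
                       source_pool=None, descriptor_config=None) -> list[Bag]:
    """The shared set of background bags used for every image of a dataset."""
    return [
        make_negative_bag(
            strategy=config.neg_strategy,
            m=config.patches_per_bag,
            n=config.patch_size,
            seed=_stable_image_seed(master_seed, f"neg-{k}"),
            source_pool=source_pool,
            source_id=f"neg-{k:03d}",
            descriptor_config=descriptor_config,
        )
        for k in range(config.n_neg_bags)
    ]


def waid_dataset(
    images: list[np.ndarray],
    labels: list[int] | np.ndarray,
    config: MILConfig | None = None,
    seed: int = 0,
    image_ids: list[str] | None = None,
    neg_source_pool=None,
    descriptor_config=None,
) -> tuple[np.ndarray, np.ndarray, list[WAID]]:
    """Compute one WAID per image; returns (matrix, labels, per-image info).

    Every image — benign-diseased or malignant, both contain tissue of
    interest — is treated as its own positive bag against one shared set
    of background bags; the image-level label is only attached afterward
    for downstream classification. Per-image sampling seeds derive from
    the master seed and the image id, so results do not depend on image
    order.
    """
    if len(images) != len(labels):
        raise ValueError("images and labels length mismatch")
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    config = config or MILConfig()
    ids = image_ids or [f"img-{k:04d}" for k in range(len(images))]
    neg_bags = make_negative_pool(config, seed, source_pool=neg_source_pool,
                                  descriptor_config=descriptor_config)
    rows, out_labels, infos = [], [], []
    for image, label, image_id in zip(images, labels, ids):
        try:
            bag = make_bag(
                image, label=1, m=config.patches_per_bag, n=config.patch_size,
                seed=_stable_image_seed(seed, image_id), source_id=image_id,
                descriptor_config=descriptor_config)
            waid = compute_waid(bag, neg_bags, config)
        except Exception:
            logger.exception("WAID computation failed for %s; skipping", image_id)
            continue
        rows.append(waid.vector)
        out_labels.append(int(label))
        infos.append(waid)
    if not rows:
        raise ValueError("no image produced a WAID")
    return np.vstack(rows), np.asarray(out_labels), infos
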