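"""Per-pixel feature extraction with a static bank of 80 parametrized filters.

Pixel classification turns semantic segmentation into tabular learning:
every pixel becomes a feature vector of filter responses sampled at that
location, and a conventional classifier labels it lipid / non-lipid.  The
default bank covers the classic trainable-segmentation families — Gaussian
smoothing, difference of Gaussians, Laplacian of Gaussian, Sobel magnitude
after smoothing, Gaussian gradient magnitude, structure-tensor eigenvalues,
median smoothing and per-image intensity-quantile threshold maps — over a
geometric sigma ladder, plus the original normalized 8-bit image retained
as the first layer.  Exactly 80 layers in total.

All convolutions reflect at the image edge so borders do not produce
spurious derivative responses.  Features are computed on the 8-bit
normalized image and stored as float32.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from skimage.feature import structure_tensor, structure_tensor_eigenvalues

from .io import BinaryMask, NormalizedImage

SIGMAS = (0.3, 0.7, 1.0, 1.6, 2.5, 3.5, 5.0, 7.5, 10.0)
MEDIAN_WINDOWS = (3, 5, 7, 9, 11, 15, 19, 25, 31)
THRESHOLD_QUANTILES = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)

FAMILIES = frozenset(
    {
        "identity",
        "gaussian",
        "difference_of_gaussians",
        "laplacian_of_gaussian",
        "sobel_of_gaussian",
        "gradient_magnitude",
        "structure_tensor_eig_large",
        "structure_tensor_eig_small",
        "median",
        "intensity_threshold",
    }
)


@dataclass(frozen=True)
class FilterSpec:
    """One parametrized filter: a family name plus its scalar parameters."""

    id: str
    family: str
    params: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown filter family {self.family!r}")
        p = dict(self.params)
        if "sigma" in p and p["sigma"] <= 0:
            raise ValueError(f"{self.id}: sigma must be > 0")
        if "window" in p:
            w = int(p["window"])
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{self.id}: window must be odd and >= 3")
        if "quantile" in p and not (0 < p["quantile"] < 1):
            raise ValueError(f"{self.id}: quantile must lie in (0, 1)")

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(self.params)


@dataclass(frozen=True)
class FilterBank:
    """An ordered, immutable set of filter specs; order defines layer order."""

    specs: tuple[FilterSpec, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.specs]
        if len(set(ids)) != len(ids):
            raise ValueError("filter ids must be unique within a bank")

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def bank_id(self) -> str:
        """Stable content hash: two banks with identical specs share an id."""
        payload = json.dumps(
            [[s.id, s.family, list(s.params)] for s in self.specs]
        ).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def build_default_bank() -> FilterBank:
    """The default 80-filter bank.

    Composition: identity (1) + gaussian over 9 sigmas + difference of
    gaussians over the 8 consecutive sigma pairs + laplacian of gaussian,
    sobel-after-gaussian and gradient magnitude over the 9 sigmas (27) +
    structure-tensor large/small eigenvalues over the 9 sigmas (18) +
    median over 9 window sizes + intensity-threshold maps at 8 quantiles
    = 80 layers, deterministic order, identity first.
    """
    specs: list[FilterSpec] = [FilterSpec("identity", "identity")]
    for s in SIGMAS:
        specs.append(FilterSpec(f"gaussian_s{s}", "gaussian", (("sigma", s),)))
    for lo, hi in zip(SIGMAS[:-1], SIGMAS[1:]):
        specs.append(
            FilterSpec(
                f"dog_s{lo}_{hi}",
                "difference_of_gaussians",
                (("sigma_low", lo), ("sigma_high", hi)),
            )
        )
    for s in SIGMAS:
        specs.append(FilterSpec(f"log_s{s}", "laplacian_of_gaussian", (("sigma", s),)))
    for s in SIGMAS:
        specs.append(FilterSpec(f"sobel_s{s}", "sobel_of_gaussian", (("sigma", s),)))
    for s in SIGMAS:
        specs.append(FilterSpec(f"gradmag_s{s}", "gradient_magnitude", (("sigma", s),)))
    for s in SIGMAS:
        specs.append(
            FilterSpec(f"st_large_s{s}", "structure_tensor_eig_large", (("sigma", s),))
        )
    for s in SIGMAS:
        specs.append(
            FilterSpec(f"st_small_s{s}", "structure_tensor_eig_small", (("sigma", s),))
        )
    for w in MEDIAN_WINDOWS:
        specs.append(FilterSpec(f"median_w{w}", "median", (("window", float(w)),)))
    for q in THRESHOLD_QUANTILES:
        specs.append(
            FilterSpec(f"thresh_q{q}", "intensity_threshold", (("quantile", q),))
        )
    return FilterBank(specs=tuple(specs))


def save_bank(bank: FilterBank, path: str) -> None:
    """Serialize a bank to YAML, one record per filter."""
    records = [
        {"id": s.id, "family": s.family, "params": dict(s.params)}
        for s in bank.specs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"filters": records}, fh, sort_keys=False)


def load_bank(path: str) -> FilterBank:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = tuple(
        FilterSpec(
            id=rec["id"],
            family=rec["family"],
            params=tuple(rec.get("params", {}).items()),
        )
        for rec in doc["filters"]
    )
    return FilterBank(specs=specs)


@dataclass
class FeatureStack:
    """The (height, width, k) response tensor of one image under a bank."""

    values: np.ndarray
    bank_id: str

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("FeatureStack.values must be 3D (h, w, k)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureStack values must be finite")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def k(self) -> int:
        return self.values.shape[2]


def _structure_tensor_eigs(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    A = structure_tensor(img, sigma=sigma, mode="reflect")
    large, small = structure_tensor_eigenvalues(A)
    return large, small


def _apply_one(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply a single filter to a float image (reflect boundary everywhere)."""
    p = spec.param_dict
    fam = spec.family
    if fam == "identity":
        return img.copy()
    if fam == "gaussian":
        return ndimage.gaussian_filter(img, p["sigma"], mode="reflect")
    if fam == "difference_of_gaussians":
        return ndimage.gaussian_filter(
            img, p["sigma_low"], mode="reflect"
        ) - ndimage.gaussian_filter(img, p["sigma_high"], mode="reflect")
    if fam == "laplacian_of_gaussian":
        # discrete Laplacian of the smoothed image: the 3x3 stencil is
        # exactly zero-sum, so constants map to 0 at every sigma
        smoothed = ndimage.gaussian_filter(img, p["sigma"], mode="reflect")
        return ndimage.laplace(smoothed, mode="reflect")
    if fam == "sobel_of_gaussian":
        smoothed = ndimage.gaussian_filter(img, p["sigma"], mode="reflect")
        gy = ndimage.sobel(smoothed, axis=0, mode="reflect")
        gx = ndimage.sobel(smoothed, axis=1, mode="reflect")
        return np.hypot(gy, gx)
    if fam == "gradient_magnitude":
        return ndimage.gaussian_gradient_magnitude(img, p["sigma"], mode="reflect")
    if fam == "structure_tensor_eig_large":
        return _structure_tensor_eigs(img, p["sigma"])[0]
    if fam == "structure_tensor_eig_small":
        return _structure_tensor_eigs(img, p["sigma"])[1]
    if fam == "median":
        return ndimage.median_filter(img, size=int(p["window"]), mode="reflect")
    if fam == "intensity_threshold":
        cutoff = np.quantile(img, p["quantile"])
        return np.where(img >= cutoff, 255.0, 0.0)
    raise ValueError(f"unknown filter family {fam!r}")  # pragma: no cover


def apply_bank(image: NormalizedImage | np.ndarray, bank: FilterBank) -> FeatureStack:
    """Expand a 2D image into an (h, w, k) feature stack, layer j = filter j."""
    if len(bank) == 0:
        raise ValueError("cannot apply an empty filter bank")
    pix = image.pixels if isinstance(image, NormalizedImage) else np.asarray(image)
    img = pix.astype(np.float64)
    # structure-tensor eigenvalues come in pairs; compute each sigma once
    st_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    layers = np.empty(img.shape + (len(bank),), dtype=np.float32)
    for j, spec in enumerate(bank.specs):
        if spec.family.startswith("structure_tensor_eig"):
            s = spec.param_dict["sigma"]
            if s not in st_cache:
                st_cache[s] = _structure_tensor_eigs(img, s)
            idx = 0 if spec.family.endswith("large") else 1
            layers[:, :, j] = st_cache[s][idx]
        else:
            layers[:, :, j] = _apply_one(img, spec)
    return FeatureStack(values=layers, bank_id=bank.bank_id)


@dataclass
class PixelMatrix:
    """Flattened training data: n pixels x k features plus aligned labels."""

    data: np.ndarray
    labels: np.ndarray
    image_index: np.ndarray
    bank_id: str

    def __post_init__(self) -> None:
        n, _k = self.data.shape
        if self.labels.shape != (n,) or self.image_index.shape != (n,):
            raise ValueError("labels and image_index must have one entry per row")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def k(self) -> int:
        return self.data.shape[1]


def flatten_dataset(items: list[tuple[FeatureStack, BinaryMask]]) -> PixelMatrix:
    """Flatten (stack, mask) pairs into one long pixel matrix.

    Row order is image order, then row-major within each image, so the
    operation is exactly invertible given the original shapes.
    """
    if not items:
        raise ValueError("flatten_dataset requires at least one item")
    k = items[0][0].k
    bank_id = items[0][0].bank_id
    blocks, labels, index = [], [], []
    for i, (stack, mask) in enumerate(items):
        if stack.k != k:
            raise ValueError(f"item {i}: mixed feature depth {stack.k} != {k}")
        if stack.bank_id != bank_id:
            raise ValueError(f"item {i}: mixed bank provenance")
        if (stack.height, stack.width) != (mask.height, mask.width):
            raise ValueError(
                f"item {i}: stack {stack.height}x{stack.width} does not match "
                f"mask {mask.height}x{mask.width}"
            )
        npix = stack.height * stack.width
        blocks.append(stack.values.reshape(npix, k))
        labels.append(mask.pixels.reshape(npix))
        index.append(np.full(npix, i, dtype=np.int32))
    return PixelMatrix(
        data=np.concatenate(blocks, axis=0),
        labels=np.concatenate(labels).astype(np.uint8),
        image_index=np.concatenate(index),
        bank_id=bank_id,
    )


class FilterBankFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer from images to per-pixel feature rows.

    ``transform`` maps a list of 2D arrays (or :class:`NormalizedImage`) to
    a single (n_pixels, k) matrix in image order, row-major within each
    image — the layout the pixel classifiers train on.  ``fit`` only
    records the bank; there is nothing to estimate.
    """

    def __init__(self, bank: FilterBank | None = None):
        self.bank = bank

    def _resolved_bank(self) -> FilterBank:
        return self.bank if self.bank is not None else build_default_bank()

    def fit(self, X, y=None):
        self.bank_ = self._resolved_bank()
        self.n_features_out_ = len(self.bank_)
        return self

    def transform(self, X) -> np.ndarray:
        bank = getattr(self, "bank_", None) or self._resolved_bank()
        stacks = [apply_bank(img, bank) for img in X]
        k = len(bank)
        return np.concatenate(
            [s.values.reshape(-1, k) for s in stacks], axis=0
        )

    def transform_stacks(self, X) -> list[FeatureStack]:
        """Like :meth:`transform` but keeps per-image (h, w, k) stacks."""
        bank = getattr(self, "bank_", None) or self._resolved_bank()
        return [apply_bank(img, bank) for img in X]


def unflatten(matrix: PixelMatrix, shapes: list[tuple[int, int]]) -> list[np.ndarray]:
    """Reconstruct per-image stacks from a pixel matrix (inverse of flatten)."""
    out = []
    start = 0
    for h, w in shapes:
        npix = h * w
        out.append(matrix.data[start : start + npix].reshape(h, w, matrix.k))
        start += npix
    if start != matrix.n:
        raise ValueError("shapes do not account for every row")
    return out
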