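"""Random-forest pixel/voxel classification with morphological features.

Mirrors the trainable-segmentation workflow of the common interactive
tools: a bank of Gaussian-derivative features is computed per pixel, a
random forest is trained on sparsely annotated pixels with balanced
class weights, and the per-pixel class posterior (fraction of trees
voting) is thresholded to produce a segmentation mask.  Defaults follow
the usual tool configurations: 200 trees with 2 random features per
node in 2-D, 100 trees in 3-D.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.measure import label as sk_label
from sklearn.ensemble import RandomForestClassifier

from .codecs import CompressedVariant
from .exceptions import InsufficientDataError
from .replicas import RawImage

OPERATORS_2D = ("gaussian_smoothing", "hessian", "sobel",
                "difference_of_gaussians")
OPERATORS_3D = ("gaussian_smoothing", "laplacian_of_gaussian",
                "gaussian_gradient_magnitude", "difference_of_gaussians")
_KNOWN_OPERATORS = frozenset(OPERATORS_2D) | frozenset(OPERATORS_3D)
DEFAULT_SIGMAS = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class FeatureBank:
    """Set of (operator, sigma) image features for pixel classification."""

    operators: tuple[str, ...]
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    ndim: int = 2

    def __post_init__(self) -> None:
        for op in self.operators:
            if op not in _KNOWN_OPERATORS:
                raise ValueError(f"unknown operator {op!r}")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigma values must be positive")

    @classmethod
    def default_2d(cls) -> "FeatureBank":
        return cls(OPERATORS_2D, DEFAULT_SIGMAS, 2)

    @classmethod
    def default_3d(cls) -> "FeatureBank":
        return cls(OPERATORS_3D, DEFAULT_SIGMAS, 3)

    def content_hash(self) -> str:
        text = repr((self.operators, self.sigmas, self.ndim))
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _operator_planes(img: np.ndarray, op: str, sigma: float):
    """Feature planes for one (operator, sigma); names included."""
    if op == "gaussian_smoothing":
        yield f"GS_s{sigma:g}", ndi.gaussian_filter(img, sigma, mode="reflect")
    elif op == "difference_of_gaussians":
        a = ndi.gaussian_filter(img, sigma, mode="reflect")
        b = ndi.gaussian_filter(img, 2 * sigma, mode="reflect")
        yield f"DoG_s{sigma:g}", a - b
    elif op == "laplacian_of_gaussian":
        yield f"LoG_s{sigma:g}", ndi.gaussian_laplace(img, sigma,
                                                      mode="reflect")
    elif op == "gaussian_gradient_magnitude":
        yield f"GGM_s{sigma:g}", ndi.gaussian_gradient_magnitude(
            img, sigma, mode="reflect")
    elif op == "sobel":
        sm = ndi.gaussian_filter(img, sigma, mode="reflect")
        grads = [ndi.sobel(sm, axis=a, mode="reflect")
                 for a in range(img.ndim)]
        yield f"sobel_s{sigma:g}", np.sqrt(sum(g * g for g in grads))
    elif op == "hessian":
        # eigenvalues of the Gaussian-smoothed Hessian, largest first
        H = hessian_matrix(img, sigma=sigma, mode="reflect",
                           use_gaussian_derivatives=True)
        eigs = hessian_matrix_eigvals(H)
        for i, plane in enumerate(eigs):
            yield f"hessian_e{i}_s{sigma:g}", plane
    else:  # pragma: no cover - guarded by FeatureBank
        raise ValueError(op)


def compute_features(img: RawImage | np.ndarray, bank: FeatureBank
                     ) -> tuple[np.ndarray, list[str]]:
    """Compute the feature stack (..., n_features) plus plane names.

    The raw intensity is always the first plane.  Operators whose sigma
    exceeds half the smallest image dimension are skipped with a warning
    (their support would wrap the whole image).
    """
    arr = img.pixels if isinstance(img, RawImage) else img
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != bank.ndim:
        raise ValueError(f"image is {arr.ndim}-D but bank is {bank.ndim}-D")
    planes, names = [arr], ["raw"]
    limit = min(arr.shape) / 2
    for op in bank.operators:
        for sigma in bank.sigmas:
            if sigma > limit:
                warnings.warn(f"sigma {sigma} exceeds half the smallest "
                              f"image dimension; skipping {op}", stacklevel=2)
                continue
            for name, plane in _operator_planes(arr, op, sigma):
                planes.append(plane)
                names.append(name)
    return np.stack(planes, axis=-1), names


@dataclass
class AnnotationSet:
    """Sparse training labels: 0 = unlabeled, 1..C = class ids."""

    labels: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        expected = set(range(1, len(self.class_names) + 1))
        missing = expected - present
        if missing:
            raise InsufficientDataError(
                f"classes without annotations: "
                f"{[self.class_names[i - 1] for i in sorted(missing)]}")

    def counts(self) -> dict[str, int]:
        return {name: int((self.labels == i + 1).sum())
                for i, name in enumerate(self.class_names)}

    def to_tiff(self, path) -> None:
        import json
        from pathlib import Path

        import tifffile
        tifffile.imwrite(path, self.labels.astype(np.uint8))
        Path(path).with_suffix(".json").write_text(
            json.dumps({"class_names": list(self.class_names)}))

    @classmethod
    def from_tiff(cls, path) -> "AnnotationSet":
        import json
        from pathlib import Path

        import tifffile
        names = json.loads(Path(path).with_suffix(".json").read_text())
        return cls(tifffile.imread(path),
                   tuple(names["class_names"]))


@dataclass
class PixelClassifier:
    """A fitted forest bound to the feature bank it was trained with."""

    forest: RandomForestClassifier
    class_names: tuple[str, ...]
    bank: FeatureBank
    seed: int
    n_features: int
    train_hash: str = ""

    def content_hash(self) -> str:
        return self.train_hash

    def save(self, path) -> None:
        """Serialize forest + provenance (version, seed, bank hash)."""
        import joblib
        joblib.dump({"format_version": 1, "forest": self.forest,
                     "class_names": self.class_names, "bank": self.bank,
                     "seed": self.seed, "n_features": self.n_features,
                     "bank_hash": self.bank.content_hash(),
                     "train_hash": self.train_hash}, path)

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        import joblib
        d = joblib.load(path)
        return cls(forest=d["forest"], class_names=d["class_names"],
                   bank=d["bank"], seed=d["seed"],
                   n_features=d["n_features"], train_hash=d["train_hash"])


def train_classifier(features: np.ndarray, annotations: AnnotationSet,
                     n_trees: int | None = None, max_features: int = 2,
                     seed: int = 0) -> PixelClassifier:
    """Fit a random forest on the annotated pixels only.

    Classes are balanced ("identical weight"); defaults are 200 trees
    with 2 random features per node for 2-D images and 100 trees for
    3-D stacks.
    """
    ndim = features.ndim - 1
    if n_trees is None:
        n_trees = 200 if ndim == 2 else 100
    mask = annotations.labels > 0
    X = features[mask]
    y = annotations.labels[mask]
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=max_features,
        class_weight="balanced", random_state=seed, n_jobs=1)
    forest.fit(X, y)
    digest = hashlib.sha256()
    digest.update(X.tobytes())
    digest.update(y.tobytes())
    digest.update(repr((n_trees, max_features, seed)).encode())
    return PixelClassifier(
        forest=forest, class_names=annotations.class_names,
        bank=FeatureBank(OPERATORS_2D if ndim == 2 else OPERATORS_3D,
                         ndim=ndim),
        seed=seed, n_features=features.shape[-1],
        train_hash=digest.hexdigest()[:16])


@dataclass
class ProbabilityMap:
    """Per-pixel class posteriors (..., n_classes), rows summing to 1."""

    probabilities: np.ndarray
    class_names: tuple[str, ...]

    def for_class(self, class_name: str) -> np.ndarray:
        try:
            idx = self.class_names.index(class_name)
        except ValueError:
            raise KeyError(f"unknown class {class_name!r}") from None
        return self.probabilities[..., idx]


def predict_probability(classifier: PixelClassifier, features: np.ndarray
                        ) -> ProbabilityMap:
    """Class posterior per pixel = fraction of trees voting per class."""
    if features.shape[-1] != classifier.n_features:
        raise ValueError("feature stack does not match the training bank")
    flat = features.reshape(-1, features.shape[-1])
    probs = classifier.forest.predict_proba(flat)
    full = np.zeros((flat.shape[0], len(classifier.class_names)))
    for col, cls in enumerate(classifier.forest.classes_):
        full[:, int(cls) - 1] = probs[:, col]
    return ProbabilityMap(full.reshape(features.shape[:-1] + (-1,)),
                          classifier.class_names)


def threshold_mask(probmap: ProbabilityMap, class_name: str,
                   threshold: float = 0.5) -> np.ndarray:
    """Binary mask where P(class) strictly exceeds the threshold.

    The conventional thresholds are 0.5 (cells, nuclei, plaques) and
    0.7 (brain anatomy); ties fall to background.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return probmap.for_class(class_name) > threshold


@dataclass
class LabeledMask:
    """Connected-component labels; 0 is background."""

    labels: np.ndarray
    connectivity: int

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


def label_objects(mask: np.ndarray, connectivity: int | None = None
                  ) -> LabeledMask:
    """8-connected (2-D) / 26-connected (3-D) component labeling."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity is None:
        connectivity = mask.ndim  # full connectivity in skimage terms
    return LabeledMask(sk_label(mask, connectivity=connectivity),
                       connectivity=connectivity)


def upsample_for_model(variant: CompressedVariant) -> RawImage:
    """Type a decoded variant as a 16-bit RawImage for model testing."""
    return RawImage(variant.decoded_16bit.astype(np.uint16),
                    provenance=f"decoded:{variant.method}")
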