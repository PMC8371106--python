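"""Classical grading pipeline: preprocessing, GLCM texture statistics,
HOG descriptors, feature merging, and an SVM head.

The recipe: weighted-mean grayscale conversion, edge-preserving bilateral
smoothing (neighbourhood diameter 90, colour and spatial sigmas 75), then
two descriptor families computed on the filtered image —

* GLCM: the normalized, symmetric co-occurrence distribution of quantized
  gray levels at a fixed pixel offset, summarized by four Haralick
  statistics (angular second moment, entropy, contrast, correlation) whose
  mean and variance over the angle set give an 8-value texture block;
* HOG: square-root gamma compression, [-1, 0, 1] centred-difference
  gradients, magnitude-weighted unsigned-orientation histograms over cells,
  L2-normalized within 4x4-cell blocks and concatenated.

The merged vector (GLCM block first) feeds a multiclass RBF SVM.

Parameters the recipe leaves open (GLCM offsets and quantization, HOG cell
geometry and bin count, SVM kernel constants) follow the Haralick / Dalal-
Triggs / libsvm conventions and are configurable.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.feature import graycomatrix
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .sample import ImageSample

_BT601 = np.array([0.299, 0.587, 0.114])
_BLOCK_EPS = 1e-5


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def to_grayscale_weighted(image: np.ndarray) -> np.ndarray:
    """BT.601 weighted mean: gray = round(0.299 R + 0.587 G + 0.114 B)."""
    px = np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an RGB HxWx3 image, got shape {px.shape}")
    gray = px.astype(np.float64) @ _BT601
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def bilateral_filter(gray: np.ndarray, diameter: int = 90,
                     sigma_color: float = 75.0,
                     sigma_space: float = 75.0) -> np.ndarray:
    """Edge-preserving smoothing on a single-channel image.

    Each output pixel is a per-pixel-renormalized sum of neighbours within
    the diameter window, weighted by Gaussian spatial closeness
    (sigma_space, pixels) and Gaussian intensity similarity (sigma_color,
    gray levels on the 0-255 scale).
    """
    g = np.asarray(gray)
    if g.ndim != 2:
        raise ValueError("bilateral_filter expects a single-channel image")
    if sigma_color <= 0 or sigma_space <= 0:
        raise ValueError("sigmas must be positive")
    win = int(diameter)
    if win % 2 == 0:
        win += 1  # window needs a centre pixel
    r = win // 2
    gf = g.astype(np.float64)
    gp = np.pad(gf, r, mode="edge")
    h, w = gf.shape
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    inv2ss = 1.0 / (2.0 * sigma_space ** 2)
    inv2sc = 1.0 / (2.0 * sigma_color ** 2)
    for di in range(-r, r + 1):
        ws_row = np.exp(-(di * di) * inv2ss)
        for dj in range(-r, r + 1):
            v = gp[r + di:r + di + h, r + dj:r + dj + w]
            wgt = ws_row * np.exp(-(dj * dj) * inv2ss
                                  - (v - gf) ** 2 * inv2sc)
            num += wgt * v
            den += wgt
    out = num / den
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

@dataclass
class GLCMatrix:
    """Normalized symmetric co-occurrence distribution at one offset.

    The offset convention follows the co-occurrence direction
    (round(sin a * d), round(cos a * d)) in (row, col) array coordinates;
    symmetrization counts every pair in both directions.
    """

    probs: np.ndarray  # L x L, entries >= 0, sums to 1
    distance: int
    angle_deg: float
    n_levels: int


def quantize_gray(gray: np.ndarray, n_levels: int) -> np.ndarray:
    """Uniform binning of 0-255 gray values into n_levels levels."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    return (np.asarray(gray).astype(np.int64) * n_levels // 256).astype(np.uint8)


def glcm(gray: np.ndarray, distance: int = 1, angle_deg: float = 0.0,
         n_levels: int = 64) -> GLCMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix."""
    g = np.asarray(gray)
    if g.ndim != 2:
        raise ValueError("glcm expects a single-channel image")
    if distance >= max(g.shape):
        raise ValueError(f"offset distance {distance} exceeds image extent")
    q = quantize_gray(g, n_levels)
    m = graycomatrix(q, distances=[distance],
                     angles=[np.deg2rad(angle_deg)], levels=n_levels,
                     symmetric=True, normed=True)[:, :, 0, 0]
    return GLCMatrix(probs=m, distance=distance, angle_deg=angle_deg,
                     n_levels=n_levels)


@dataclass
class GLCMFeatures:
    asm: float
    ent: float
    con: float
    cor: float

    def as_array(self) -> np.ndarray:
        return np.array([self.asm, self.ent, self.con, self.cor])


def glcm_features(m: GLCMatrix) -> GLCMFeatures:
    """Angular second moment, entropy (nats), contrast, correlation.

    Asm = sum P^2; Ent = -sum_{P>0} P ln P; Con = sum (i-j)^2 P;
    Cor = sum (i - mu_i)(j - mu_j) P / (sigma_i sigma_j), with Cor defined
    as 0 when either marginal is degenerate (sigma = 0).
    """
    p = np.asarray(m.probs, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise ValueError("matrix must be normalized to probabilities")
    asm = float((p ** 2).sum())
    nz = p[p > 0]
    ent = float(-(nz * np.log(nz)).sum())
    i = np.arange(p.shape[0])[:, None]
    j = np.arange(p.shape[1])[None, :]
    con = float(((i - j) ** 2 * p).sum())
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    mu_i, mu_j = float(pi @ np.arange(len(pi))), float(pj @ np.arange(len(pj)))
    var_i = float(pi @ (np.arange(len(pi)) - mu_i) ** 2)
    var_j = float(pj @ (np.arange(len(pj)) - mu_j) ** 2)
    if var_i <= 0 or var_j <= 0:
        cor = 0.0
    else:
        cov = float(((i - mu_i) * (j - mu_j) * p).sum())
        cor = cov / np.sqrt(var_i * var_j)
    return GLCMFeatures(asm=asm, ent=ent, con=con, cor=cor)


def glcm_feature_block(gray: np.ndarray,
                       distances: Sequence[int] = (1,),
                       angles: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
                       n_levels: int = 64) -> np.ndarray:
    """Mean and population variance of (Asm, Ent, Con, Cor) over offsets.

    Returns the fixed-order 8-vector (asm_mean, ent_mean, con_mean,
    cor_mean, asm_var, ent_var, con_var, cor_var).
    """
    if len(angles) < 2:
        raise ValueError("need at least 2 angles for variance pooling")
    feats = np.array([
        glcm_features(glcm(gray, d, a, n_levels)).as_array()
        for d in distances for a in angles
    ])
    return np.concatenate([feats.mean(axis=0), feats.var(axis=0)])


# --------------------------------------------------------------------------
# HOG
# --------------------------------------------------------------------------

def gamma_compress(image: np.ndarray) -> np.ndarray:
    """Square-root gamma compression: out = sqrt(in / 255) * 255.

    Fixes 0 and 255; uint8 input yields rounded uint8, float stays float.
    """
    arr = np.asarray(image)
    out = np.sqrt(arr.astype(np.float64) / 255.0) * 255.0
    if arr.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def gradients(gray: np.ndarray
              ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """[-1, 0, 1] centred differences with replicate borders.

    Returns (gx, gy, magnitude, orientation) with the unsigned orientation
    in degrees in [0, 180).
    """
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("gradients expects a single-channel image")
    gp = np.pad(g, 1, mode="edge")
    gx = gp[1:-1, 2:] - gp[1:-1, :-2]
    gy = gp[2:, 1:-1] - gp[:-2, 1:-1]
    mag = np.hypot(gx, gy)
    ori = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    return gx, gy, mag, ori


@dataclass
class HOGDescriptor:
    vector: np.ndarray
    cell_px: int
    cells_per_block: int
    n_bins: int
    block_stride_cells: int
    n_blocks: Tuple[int, int]

    def __len__(self) -> int:
        return self.vector.size


def hog(gray: np.ndarray, cell_px: int = 8, cells_per_block: int = 4,
        n_bins: int = 9, block_stride_cells: int = 1,
        gamma: bool = True) -> HOGDescriptor:
    """Block-normalized histogram-of-oriented-gradients descriptor.

    Magnitude-weighted cell histograms over unsigned orientations with
    linear interpolation between adjacent bins; blocks of
    cells_per_block^2 cells are L2-normalized (v / sqrt(|v|^2 + eps^2))
    and concatenated row-major. The image is edge-padded up to a whole
    number of cells if needed.
    """
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("hog expects a single-channel image")
    if gamma:
        g = gamma_compress(g)
    h, w = g.shape
    hh = -(-h // cell_px) * cell_px
    ww = -(-w // cell_px) * cell_px
    if (hh, ww) != (h, w):
        g = np.pad(g, ((0, hh - h), (0, ww - w)), mode="edge")
    ncy, ncx = hh // cell_px, ww // cell_px
    if ncy < cells_per_block or ncx < cells_per_block:
        raise ValueError("image smaller than one block of cells")

    _, _, mag, ori = gradients(g)
    bin_width = 180.0 / n_bins
    pos = ori / bin_width
    b0 = np.floor(pos).astype(int) % n_bins
    frac = pos - np.floor(pos)
    b1 = (b0 + 1) % n_bins
    cy = (np.arange(hh) // cell_px)[:, None].repeat(ww, axis=1)
    cx = (np.arange(ww) // cell_px)[None, :].repeat(hh, axis=0)
    cells = np.zeros((ncy, ncx, n_bins))
    np.add.at(cells, (cy, cx, b0), mag * (1.0 - frac))
    np.add.at(cells, (cy, cx, b1), mag * frac)

    bs, st = cells_per_block, block_stride_cells
    win = sliding_window_view(cells, (bs, bs), axis=(0, 1))[::st, ::st]
    nby, nbx = win.shape[:2]
    blocks = win.transpose(0, 1, 3, 4, 2).reshape(nby, nbx, bs * bs * n_bins)
    norms = np.sqrt((blocks ** 2).sum(axis=-1, keepdims=True) + _BLOCK_EPS ** 2)
    blocks = blocks / norms
    return HOGDescriptor(vector=blocks.reshape(-1), cell_px=cell_px,
                         cells_per_block=bs, n_bins=n_bins,
                         block_stride_cells=st, n_blocks=(nby, nbx))


# --------------------------------------------------------------------------
# merged features and the SVM head
# --------------------------------------------------------------------------

def merge_features(glcm_block: np.ndarray, hog_desc: HOGDescriptor
                   ) -> np.ndarray:
    """Concatenate texture and structure features, GLCM block first."""
    return np.concatenate([np.asarray(glcm_block, dtype=np.float64),
                           hog_desc.vector])


@dataclass
class ClassicalConfig:
    bilateral_diameter: int = 90
    bilateral_sigma_color: float = 75.0
    bilateral_sigma_space: float = 75.0
    glcm_distances: Tuple[int, ...] = (1,)
    glcm_angles: Tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    glcm_levels: int = 64
    hog_cell_px: int = 8
    hog_cells_per_block: int = 4
    hog_bins: int = 9
    hog_block_stride: int = 1
    svm_c: float = 1.0
    svm_kernel: str = "rbf"
    svm_gamma: object = "scale"
    standardize: bool = True


def extract_features(image: ImageSample, config: ClassicalConfig
                     ) -> np.ndarray:
    """Full per-image descriptor: preprocess, GLCM block, HOG, merge."""
    gray = to_grayscale_weighted(image.pixels)
    filtered = bilateral_filter(gray, config.bilateral_diameter,
                                config.bilateral_sigma_color,
                                config.bilateral_sigma_space)
    gblock = glcm_feature_block(filtered, config.glcm_distances,
                                config.glcm_angles, config.glcm_levels)
    hdesc = hog(filtered, config.hog_cell_px, config.hog_cells_per_block,
                config.hog_bins, config.hog_block_stride)
    return merge_features(gblock, hdesc)


def train_svm(features: np.ndarray, labels: np.ndarray,
              config: Optional[ClassicalConfig] = None) -> SVC:
    """Multiclass SVM (one-vs-one under the hood) on merged features."""
    config = config or ClassicalConfig()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to train an SVM")
    svc = SVC(C=config.svm_c, kernel=config.svm_kernel, gamma=config.svm_gamma,
              random_state=0)
    svc.fit(np.asarray(features, dtype=np.float64), labels)
    return svc


@dataclass
class ClassicalModel:
    """Fitted classical grader: feature geometry, scaler and SVM together."""

    config: ClassicalConfig
    scaler: Optional[StandardScaler] = None
    svc: Optional[SVC] = None

    def fit(self, samples: Sequence[ImageSample]) -> "ClassicalModel":
        x = np.stack([extract_features(s, self.config) for s in samples])
        y = np.array([s.label.code for s in samples])
        if self.config.standardize:
            self.scaler = StandardScaler().fit(x)
            x = self.scaler.transform(x)
        self.svc = train_svm(x, y, self.config)
        return self

    def features(self, samples: Sequence[ImageSample]) -> np.ndarray:
        x = np.stack([extract_features(s, self.config) for s in samples])
        if self.scaler is not None:
            if x.shape[1] != self.scaler.n_features_in_:
                raise ValueError(
                    f"feature length {x.shape[1]} does not match the fitted "
                    f"scaler ({self.scaler.n_features_in_})")
            x = self.scaler.transform(x)
        return x

    def predict(self, samples: Sequence[ImageSample]) -> np.ndarray:
        if self.svc is None:
            raise RuntimeError("model is not fitted")
        return self.svc.predict(self.features(samples))

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str) -> "ClassicalModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise ValueError(f"{path} does not contain a ClassicalModel")
        return model
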