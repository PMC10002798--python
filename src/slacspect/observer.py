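"""Task-based and fidelity evaluation.

Channelized Hotelling observer (CHO) with rotationally symmetric
frequency-domain channels and leave-one-out scoring, empirical ROC/AUC with
bootstrap confidence intervals, a conventional binormal ROC fit on
rank-discretized continuous ratings (LABROC-style), and RMSE/SSIM fidelity
metrics against a reference reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm, rankdata
from skimage.metrics import structural_similarity
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ChannelBank",
    "ObserverStudyResult",
    "BinormalFit",
    "make_channel_bank",
    "cho_scores",
    "empirical_roc_auc",
    "binormal_fit",
    "fidelity_metrics",
]

DEFAULT_BAND_EDGES = (1 / 64, 1 / 32, 1 / 16, 1 / 8, 1 / 4)


@dataclass
class ChannelBank:
    """Rotationally symmetric frequency channels for a square image.

    ``matrix`` has one unit-norm spatial template per column; the bands are
    disjoint annuli in the 2-D DFT plane (cycles/pixel).
    """

    image_size: int
    band_edges: tuple[float, ...]
    matrix: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]

    def channelize(self, images: np.ndarray) -> np.ndarray:
        """Project images (n, s, s) or (s, s) onto the channels -> (n, c)."""
        imgs = np.asarray(images, dtype=np.float64)
        single = imgs.ndim == 2
        if single:
            imgs = imgs[None]
        v = imgs.reshape(imgs.shape[0], -1) @ self.matrix
        return v[0] if single else v


def make_channel_bank(
    image_size: int = 32,
    band_edges=DEFAULT_BAND_EDGES,
) -> ChannelBank:
    """Square-profile octave frequency channels.

    Each channel is the indicator of an annulus ``lo < nu <= hi`` (radial
    spatial frequency, cycles/pixel) in the DFT domain, inverse-transformed
    to a real spatial template and unit-normalized.  The half-open-right
    convention puts the fundamental ring of a 32x32 image (1/32 cycles per
    pixel) inside the lowest octave band.
    """
    if image_size % 2:
        raise ValueError("image size must be even")
    edges = list(band_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("band edges must be strictly increasing (disjoint bands)")
    f = np.fft.fftfreq(image_size)
    nu = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    cols = []
    for lo, hi in zip(edges, edges[1:]):
        ind = ((nu > lo) & (nu <= hi)).astype(np.float64)
        tmpl = np.real(np.fft.ifft2(ind)).ravel()
        nrm = np.linalg.norm(tmpl)
        if nrm == 0:
            raise ValueError(f"band [{lo}, {hi}) contains no frequencies")
        cols.append(tmpl / nrm)
    return ChannelBank(
        image_size=image_size,
        band_edges=tuple(edges),
        matrix=np.column_stack(cols),
    )


def cho_scores(
    images: np.ndarray,
    labels: np.ndarray,
    bank: ChannelBank,
    leave_one_out: bool = True,
    ridge: float = 1e-6,
    groups=None,
) -> np.ndarray:
    """CHO test statistics, one per image.

    Each image is projected onto the channels; the Hotelling template
    ``S^-1 (mu_present - mu_absent)`` is estimated from class means and the
    pooled channel covariance.  With ``leave_one_out`` the template for image
    ``i`` is estimated from all other images.  When ``groups`` is given
    (e.g. a patient id per image), all images sharing the held-out image's
    group are excluded too — the appropriate independence unit when several
    samples derive from the same patient.  The covariance is regularized by
    ``ridge * trace(S) / n_channels`` on its diagonal.
    """
    labels = np.asarray(labels).astype(bool)
    v = bank.channelize(images)
    n, c = v.shape
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least two images per class")
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != n:
            raise ValueError("one group per image required")

    def template_stats(exclude=None):
        keep = np.ones(n, dtype=bool)
        if exclude is not None:
            keep &= ~exclude
        v1, v0 = v[keep & labels], v[keep & ~labels]
        if len(v1) < 2 or len(v0) < 2:
            raise ValueError("too few images per class after exclusion")
        m1, m0 = v1.mean(axis=0), v0.mean(axis=0)
        s = (
            (v1 - m1).T @ (v1 - m1) + (v0 - m0).T @ (v0 - m0)
        ) / (len(v1) + len(v0) - 2)
        s = s + np.eye(c) * (ridge * np.trace(s) / c)
        return m1 - m0, s

    def solve(s, dmu):
        try:
            return np.linalg.solve(s, dmu)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "channel covariance singular despite ridge"
            ) from exc

    if not leave_one_out:
        dmu, s = template_stats()
        return v @ solve(s, dmu)

    scores = np.empty(n)
    if groups is None:
        for i in range(n):
            excl = np.zeros(n, dtype=bool)
            excl[i] = True
            dmu, s = template_stats(excl)
            scores[i] = v[i] @ solve(s, dmu)
        return scores
    for g in np.unique(groups):
        excl = groups == g
        dmu, s = template_stats(excl)
        w = solve(s, dmu)
        scores[excl] = v[excl] @ w
    return scores


def empirical_roc_auc(
    statistics: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
):
    """Empirical ROC curve, AUC (Mann-Whitney, ties counted half) and a
    class-stratified percentile-bootstrap 95% CI.

    Returns ``(fpr, tpr), auc, (lo, hi)``.
    """
    t = np.asarray(statistics, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, t)
    auc = float(roc_auc_score(y, t))
    idx1, idx0 = np.nonzero(y)[0], np.nonzero(~y)[0]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        r1 = rng.choice(idx1, size=len(idx1), replace=True)
        r0 = rng.choice(idx0, size=len(idx0), replace=True)
        tt = np.concatenate([t[r1], t[r0]])
        yy = np.concatenate([np.ones(len(r1), bool), np.zeros(len(r0), bool)])
        boots[b] = roc_auc_score(yy, tt)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return (fpr, tpr), auc, (float(lo), float(hi))


@dataclass
class BinormalFit:
    """Conventional binormal ROC fit: absent latent ~ N(0,1), present latent
    ~ N(a/b, 1/b); AUC = Phi(a / sqrt(1 + b^2))."""

    a: float
    b: float
    auc: float
    converged: bool
    n_categories: int = 0


def _runs_categories(t: np.ndarray, y: np.ndarray, max_cats: int = 20) -> np.ndarray:
    """Discretize continuous ratings into ordered categories at truth-state
    run boundaries of the sorted data (LABROC-style), capped at ``max_cats``
    categories by quantile merging."""
    order = np.argsort(t, kind="mergesort")
    runs = np.cumsum(np.r_[0, np.diff(y[order].astype(int)) != 0])
    cats = np.empty(len(t), dtype=np.int64)
    cats[order] = runs
    n_cats = cats.max() + 1
    if n_cats > max_cats:
        # merge adjacent categories to at most max_cats by rank quantiles
        ranks = rankdata(cats, method="dense") - 1
        cats = np.floor(ranks * max_cats / n_cats).astype(np.int64)
    return cats


def binormal_fit(statistics: np.ndarray, labels: np.ndarray) -> BinormalFit:
    """Maximum-likelihood conventional binormal ROC fit.

    Continuous ratings are first discretized into ordered categories at the
    truth-state runs of the ordered data; the category counts are then fit
    with the two-parameter binormal model by maximizing the multinomial
    likelihood over (a, b, thresholds).  Non-convergence is flagged and the
    empirical AUC reported instead.
    """
    t = np.asarray(statistics, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if y.sum() < 10 or (~y).sum() < 10:
        raise ValueError("need >= 10 ratings per class")
    cats = _runs_categories(t, y)
    k = cats.max() + 1
    n0 = np.bincount(cats[~y], minlength=k).astype(float)
    n1 = np.bincount(cats[y], minlength=k).astype(float)

    m0, s0 = t[~y].mean(), max(t[~y].std(), 1e-9)
    m1, s1 = t[y].mean(), max(t[y].std(), 1e-9)
    a0 = (m1 - m0) / s1
    b0 = s0 / s1
    # initial thresholds from pooled standardized quantiles
    qs = np.quantile((t - m0) / s0, np.linspace(0.05, 0.95, k - 1))
    qs = np.maximum.accumulate(qs)

    def unpack(p):
        a, logb = p[0], p[1]
        b = np.exp(logb)
        c = np.concatenate([[p[2]], p[2] + np.cumsum(np.exp(p[3:]))])
        return a, b, c

    def nll(p):
        a, b, c = unpack(p)
        edges0 = np.r_[0.0, norm.cdf(c), 1.0]
        edges1 = np.r_[0.0, norm.cdf(b * c - a), 1.0]
        p0 = np.clip(np.diff(edges0), 1e-12, None)
        p1 = np.clip(np.diff(edges1), 1e-12, None)
        return -(n0 @ np.log(p0) + n1 @ np.log(p1))

    d0 = np.diff(qs)
    p_init = np.r_[a0, np.log(b0), qs[0], np.log(np.maximum(d0, 1e-3))]
    res = minimize(nll, p_init, method="L-BFGS-B",
                   options={"maxiter": 5000})
    a, b, _ = unpack(res.x)
    converged = bool(res.success) and np.isfinite(a) and np.isfinite(b)
    if converged:
        auc = float(norm.cdf(a / np.sqrt(1.0 + b**2)))
    else:
        auc = float(roc_auc_score(y, t))
        a, b = float("nan"), float("nan")
    return BinormalFit(a=float(a), b=float(b), auc=auc, converged=converged,
                       n_categories=int(k))


def binormal_roc_curve(fit: BinormalFit, n: int = 201):
    """(FPF, TPF) points of a fitted binormal ROC curve."""
    z = norm.ppf(np.linspace(1e-6, 1 - 1e-6, n))
    fpf = norm.cdf(z)
    tpf = norm.cdf(fit.a + fit.b * z)
    return fpf, tpf


@dataclass
class ObserverStudyResult:
    """Per-arm observer-study summary."""

    method: str
    statistics: np.ndarray
    labels: np.ndarray
    roc: tuple[np.ndarray, np.ndarray]
    auc: float
    auc_ci: tuple[float, float]
    binormal: BinormalFit | None = None

    def __post_init__(self) -> None:
        if len(self.statistics) != len(self.labels):
            raise ValueError("one statistic per image required")
        lo, hi = self.auc_ci
        if not (lo <= hi):
            raise ValueError("invalid confidence interval")


def fidelity_metrics(
    test: np.ndarray,
    reference: np.ndarray,
    normalize: bool = True,
) -> tuple[float, float]:
    """RMSE and mean SSIM of ``test`` against ``reference``.

    With ``normalize`` each volume is scaled by its own maximum (the usual
    display normalization for perfusion images) before comparison; SSIM uses
    the standard constants on the unit dynamic range.
    """
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError("volumes must share a shape")
    if ref.max() <= 0:
        raise ValueError("reference volume is empty")
    if normalize:
        ref = ref / ref.max()
        tst = tst / tst.max() if tst.max() > 0 else tst
    rmse = float(np.sqrt(np.mean((tst - ref) ** 2)))
    ssim = float(structural_similarity(tst, ref, data_range=1.0))
    return rmse, ssim
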